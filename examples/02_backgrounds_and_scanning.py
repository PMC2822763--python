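"""Shuffled backgrounds and calibrated matrix scanning.

Builds a small matrix library, calibrates detection thresholds that
minimise false positives plus false negatives, plants one strong site in
a random promoter, and shows that scanning finds it in the real sequence
but not in its shuffled background.
"""

import numpy as np

from concordtf.pipeline import calibrate_library
from concordtf.pwm import scan
from concordtf.sequences import PromoterRecord, make_background_set
from concordtf.simulate import generate_pwm_library

rng = np.random.default_rng(7)
library = calibrate_library(
    generate_pwm_library(n=5, length_range=(10, 14), ic_target=1.8, seed=7),
    base_composition=[0.25, 0.25, 0.25, 0.25],
    seed=7,
)
pwm = library[0]
print(f"library of {len(library)} matrices; {pwm.id} consensus {pwm.consensus}")
print(f"calibrated threshold for {pwm.id}: {pwm.threshold:.2f}\n")

seq = "".join(rng.choice(list("ACGT"), 1000))
seq = seq[:400] + pwm.consensus + seq[400 + pwm.length :]
promoter = PromoterRecord("demo_gene", "human", seq)

hits = scan(library, [promoter])
top = hits.sort_values("score", ascending=False).iloc[0]
print(f"real promoter: {len(hits)} hits; best = {top.pwm} at "
      f"[{top.start},{top.end}) strand {top.strand} score {top.score:.3f}")

background = make_background_set([promoter], mode="complete", n_replicates=1, seed=7)
bg_hits = scan(library, background)
planted_in_bg = bg_hits[(bg_hits.pwm == pwm.id) & (bg_hits.score > 0.999)]
print(f"shuffled background: {len(bg_hits)} hits, "
      f"{len(planted_in_bg)} perfect {pwm.id} sites")
print("\nThe planted site scores 1.0 in the real promoter; shuffling the")
print("same letters destroys it, which is exactly why per-promoter")
print("shuffles serve as the enrichment background.")
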