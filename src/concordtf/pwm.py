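"""Match-style PWM scanning with per-matrix calibrated thresholds.

Scoring follows the matrix-similarity-score (MSS) convention: each
position i contributes its information content
``I_i = sum_b f(i,b) * ln(4 f(i,b))`` times the frequency of the observed
base, and the weighted sum is min-max normalised to [0,1] over the
worst/best letter per position.  The detection threshold of each matrix
is calibrated on synthetic positives (sampled from the matrix) and
negatives (sampled from the background composition) to minimise the sum
of false-positive and false-negative rates, on a 0.01 score grid.

Both strands are scanned; reverse-strand hits are reported in forward
coordinates.  Overlapping hits of one matrix are all kept: downstream
counting is gene-level presence, insensitive to multiplicity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs

__all__ = [
    "PWM",
    "CalibrationError",
    "score_window",
    "calibrate_threshold",
    "scan",
    "read_pwm_library",
    "write_pwm_library",
    "encode_sequences",
    "HIT_COLUMNS",
]

logger = logging.getLogger(__name__)

ALPHABET = "ACGT"
_CODE = {c: i for i, c in enumerate("ACGTN")}
HIT_COLUMNS = ["gene", "species", "pwm", "start", "end", "strand", "score"]


class CalibrationError(ValueError):
    """Raised for matrices with no information content: no threshold separates
    signal from background."""


@dataclass(frozen=True)
class PWM:
    """Positional nucleotide frequency model with a calibrated threshold."""

    id: str
    matrix: np.ndarray  # L x 4, rows sum to 1, columns ordered A,C,G,T
    name: str = ""
    threshold: float | None = None
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25), compare=False
    )

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if m.ndim != 2 or m.shape[1] != 4 or m.shape[0] < 5:
            raise ValueError("matrix must be L x 4 with L >= 5")
        if np.any(m < 0) or np.any(np.abs(m.sum(axis=1) - 1) > 1e-9):
            raise ValueError("rows must be frequencies summing to 1")

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    @property
    def information(self) -> np.ndarray:
        """Per-position information I_i = sum_b f ln(4f) (nats), 0 ln 0 = 0."""
        with np.errstate(divide="ignore", invalid="ignore"):
            t = self.matrix * np.log(4.0 * self.matrix)
        return np.nan_to_num(t).sum(axis=1)

    @property
    def core_positions(self) -> np.ndarray:
        """Indices of the 5 most informative positions (sorted)."""
        return np.sort(np.argsort(-self.information, kind="stable")[:5])

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.matrix.argmax(axis=1))

    def reverse_complement(self) -> "PWM":
        return replace(self, matrix=self.matrix[::-1, ::-1])

    # -- scoring tables -------------------------------------------------

    def _weights(self) -> np.ndarray:
        """L x 5 table of I_i * f(i, base); code 4 (N) scores the
        background-expected frequency of the column."""
        info = self.information
        w = info[:, None] * self.matrix
        n_col = info * (self.matrix @ self.background)
        return np.hstack([w, n_col[:, None]])

    def _score_range(self) -> tuple[float, float]:
        info = self.information
        lo = float((info * self.matrix.min(axis=1)).sum())
        hi = float((info * self.matrix.max(axis=1)).sum())
        return lo, hi


def score_window(pwm: PWM, window: str) -> float:
    """MSS similarity of one L-mer to the matrix, in [0,1]."""
    if len(window) != pwm.length:
        raise ValueError(f"window length {len(window)} != matrix length {pwm.length}")
    try:
        codes = np.array([_CODE[c] for c in window.upper()])
    except KeyError as e:
        raise ValueError(f"invalid letter {e} in window") from e
    lo, hi = pwm._score_range()
    if hi - lo <= 0:
        raise CalibrationError(f"PWM {pwm.id} has zero information content")
    raw = float(pwm._weights()[np.arange(pwm.length), codes].sum())
    return (raw - lo) / (hi - lo)


def _sample_scores(
    pwm: PWM, probs: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Scores of n windows drawn column-wise from ``probs`` (L x 4)."""
    L = pwm.length
    cum = np.cumsum(probs, axis=1)
    cum[:, -1] = 1.0
    u = rng.random((n, L))
    codes = (u[:, :, None] > cum[None, :, :]).sum(axis=2)
    w = pwm._weights()
    lo, hi = pwm._score_range()
    raw = w[np.arange(L), codes].sum(axis=1)
    return (raw - lo) / (hi - lo)


def calibrate_threshold(
    pwm: PWM,
    background_composition: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    n_samples: int = 1000,
    seed: int = 0,
) -> float:
    """Threshold on the 0.01 grid minimising FP rate + FN rate.

    Positives are sampled from the matrix columns, negatives i.i.d. from
    the background composition.  Ties break toward the higher threshold.
    """
    if n_samples < 200:
        raise ValueError("n_samples must be >= 200 for a stable calibration")
    lo, hi = pwm._score_range()
    if hi - lo <= 0:
        raise CalibrationError(f"PWM {pwm.id} has zero information content")
    bg = np.asarray(background_composition, dtype=float)
    bg = bg / bg.sum()
    rng = np.random.default_rng(seed)
    pos = _sample_scores(pwm, pwm.matrix, n_samples, rng)
    neg = _sample_scores(pwm, np.tile(bg, (pwm.length, 1)), n_samples, rng)
    grid = np.round(np.arange(101) / 100.0, 2)
    fn = (pos[None, :] < grid[:, None]).mean(axis=1)
    fp = (neg[None, :] >= grid[:, None]).mean(axis=1)
    total = fp + fn
    best = np.flatnonzero(total <= total.min() + 1e-12)[-1]  # highest tied cell
    return float(grid[best])


def encode_sequences(sequences: Iterable[str]) -> np.ndarray:
    """Encode equal-length sequences as an int8 matrix (A,C,G,T,N -> 0..4)."""
    table = np.full(256, -1, dtype=np.int8)
    for c, i in _CODE.items():
        table[ord(c)] = i
        table[ord(c.lower())] = i
    mat = np.frombuffer("".join(sequences).encode(), dtype=np.uint8)
    codes = table[mat]
    if np.any(codes < 0):
        raise ValueError("sequence contains non-ACGTN letters")
    return codes


def _scan_matrix(w: np.ndarray, codes: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Score every window of every row: (n_seq, W) matrix of MSS scores."""
    L = w.shape[0]
    n, m = codes.shape
    W = m - L + 1
    raw = np.zeros((n, W), dtype=np.float64)
    for i in range(L):
        raw += w[i][codes[:, i : i + W]]
    return (raw - lo) / (hi - lo)


def scan(
    library: Sequence[PWM],
    promoters,
    species: str | None = None,
) -> pd.DataFrame:
    """Scan promoters with every matrix on both strands.

    ``promoters`` is an iterable of records with .gene_id, .species and
    .sequence.  Returns a hit table (gene, species, pwm, start, end,
    strand, score), sorted by (gene, start); every window scoring at or
    above the matrix's calibrated threshold is reported.
    """
    records = list(promoters)
    frames = []
    by_len: dict[int, list] = {}
    for rec in records:
        by_len.setdefault(len(rec.sequence), []).append(rec)
    for seqlen, recs in sorted(by_len.items()):
        codes = encode_sequences([r.sequence for r in recs]).reshape(len(recs), seqlen)
        genes = np.array([r.gene_id for r in recs])
        sp = np.array([species or r.species for r in recs])
        for pwm in library:
            if pwm.threshold is None:
                raise ValueError(f"PWM {pwm.id} has no calibrated threshold")
            if seqlen < pwm.length:
                for r in recs:
                    logger.info(
                        "gene %s shorter than PWM %s (%d < %d): skipped",
                        r.gene_id, pwm.id, seqlen, pwm.length,
                    )
                continue
            lo, hi = pwm._score_range()
            if hi - lo <= 0:
                raise CalibrationError(f"PWM {pwm.id} has zero information content")
            for strand, mat in (("+", pwm), ("-", pwm.reverse_complement())):
                scores = _scan_matrix(mat._weights(), codes, lo, hi)
                rows, cols = np.nonzero(scores >= pwm.threshold)
                if rows.size == 0:
                    continue
                frames.append(
                    pd.DataFrame(
                        {
                            "gene": genes[rows],
                            "species": sp[rows],
                            "pwm": pwm.id,
                            "start": cols,
                            "end": cols + pwm.length,
                            "strand": strand,
                            "score": scores[rows, cols],
                        }
                    )
                )
    if not frames:
        return pd.DataFrame(columns=HIT_COLUMNS)
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["gene", "start", "pwm", "strand"], kind="stable").reset_index(
        drop=True
    )


# -- library IO ---------------------------------------------------------


def read_pwm_library(path, fmt: str = "jaspar", pseudocount: float = 0.0) -> list[PWM]:
    """Read a matrix library in JASPAR PFM or TRANSFAC-flat format.

    Counts are normalised to frequencies per position, with an optional
    additive pseudocount.
    """
    if fmt not in {"jaspar", "transfac"}:
        raise ValueError("fmt must be 'jaspar' or 'transfac'")
    with open(path) as handle:
        parsed = bio_motifs.parse(handle, fmt)
    out = []
    for m in parsed:
        counts = np.array([m.counts[b] for b in ALPHABET], dtype=float).T
        counts = counts + pseudocount
        freqs = counts / counts.sum(axis=1, keepdims=True)
        ident = getattr(m, "matrix_id", None) or m.name
        out.append(PWM(id=str(ident), name=str(m.name or ident), matrix=freqs))
    return out


def write_pwm_library(library: Sequence[PWM], path, scale: int = 100) -> None:
    """Write matrices as JASPAR PFM text (frequencies scaled to counts)."""
    with open(path, "w") as fh:
        for pwm in library:
            fh.write(f">{pwm.id} {pwm.name or pwm.id}\n")
            counts = np.round(pwm.matrix * scale).astype(int)
            for j, base in enumerate(ALPHABET):
                row = " ".join(str(v) for v in counts[:, j])
                fh.write(f"{base} [ {row} ]\n")
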