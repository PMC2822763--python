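# Methods

## Model and procedure

`concordtf` implements a function-conservation screen for interacting
transcription factors. Its premise is twofold: functional TF-pair
binding sites are more distance-constrained than chance co-occurrence,
and a pair that regulates the same program in two closely related
species is enriched on promoters of *orthologous* genes rather than
arbitrary ones. Neither property alone is specific; the screen couples
them.

For every unordered PWM pair (self-pairs included; k matrices give
k(k+1)/2 pairs) and every maximum-gap cutoff d on the grid
20–200 bp (step 20), two quantities are computed over a gene list:
the number of genes whose promoter carries one site of each member with
edge-to-edge gap ≤ d (overlapping sites never count; a gene counts once
however many arrangements it has), in the real corpus and in
per-promoter shuffled backgrounds; and the number of orthologous gene
pairs carrying the pair within d in both species, again real versus
background. Both are expressed as ratios with a zero-background floor of
1 (`x / max(bg, 1)`), giving two 10-point profiles. Candidate pairs
must exceed ratio 1 at more than five cutoffs and show ≥ 10 %
orthologous overlap (overlap / smaller species gene set) at every
cutoff where both species have carriers ("all" scope; an "any" scope is
a config switch). The test statistic is the Pearson correlation between
the two profiles; significance comes from a one-sided permutation test
(re-pairing the ten overlap values against the ten site values;
exhaustive for profiles of length ≤ 6, otherwise 10,000 draws, p =
(1 + #{r\* ≥ r}) / (n + 1)), with Benjamini–Hochberg adjustment per gene
list. The whole procedure runs once with each species as foreground;
only pairs with q < 0.05 in both are called. Downstream stages
(housekeeping subtraction, tissue-unique pairs, binary-distance
complete-linkage tissue grouping, ≥ 50 % tissue-type pairs, network
assembly, 3-TF module composition with order/orientation conservation
and hypergeometric target-overlap calling) operate on these calls.

## Statistical conventions

* Binomial enrichment exposes both tail conventions behind
  `strict_tail`: P(X > n) and P(X ≥ n). Published worked examples of
  this test are reproducible only under one or the other depending on
  the example (the liver evaluation needs the strict tail), so the
  ambiguity is surfaced rather than hidden; the library default is the
  inclusive tail. Tail sums are delegated to scipy's stable survival
  functions, which remain accurate to p ~ 1e-300.
* The hypergeometric overlap tail P(overlap ≥ c) doubles as the
  one-sided Fisher enrichment test (identical 2×2 tail); q-values are
  Benjamini–Hochberg step-up, chosen because it is deterministic and
  parameter-free.
* The permutation test is one-sided for positive correlation: function
  conservation predicts positive coupling of the two profiles. A
  two-sided option would halve power for no interpretable alternative.
* Constant profiles have no defined correlation; such pairs are
  reported as untestable (`status` column) rather than silently
  dropped.

## Scanning and calibration

Scoring is the TRANSFAC/Match matrix-similarity convention: position i
contributes I_i · f(i, base) with I_i = Σ_b f ln(4f), min–max normalised
over the per-position worst/best letters, so consensus scores 1 and the
anti-consensus 0. `N` bases score the background-weighted column mean,
keeping composition invariants of the shuffles exact. Thresholds are
calibrated per matrix on a 0.01 grid by minimising (false-positive rate
on background-composition windows) + (false-negative rate on
matrix-sampled windows), 1000 samples each, ties toward the higher
cutoff. Both strands are scanned; reverse-strand hits are reported in
forward coordinates; overlapping hits of one matrix are all kept since
downstream counting is gene-level presence. Core-score prefiltering is
omitted — it is a speed optimisation that cannot change the hit set
when its cutoff does not exceed the matrix cutoff.

## The synthetic-data generator

The generator emulates the statistical *shape* of a two-species promoter
screen: 1 kb i.i.d. promoters (optional first-order Markov background),
a PWM library with controlled per-column information, per-tissue gene
lists plus a large housekeeping list, a 1:1 ortholog map, and planted
signal. The second species' promoter is a per-base diverged copy of the
first (default substitution rate 0.5 at neutral positions — the
effective divergence of nonfunctional promoter sequence between
human-mouse-distance genomes once alignability is accounted for).
Conserved planted arrangements are planted independently in each
species: same site letters, order, orientation and gap, but an
independent promoter coordinate. Conservation of a module is a property
of the arrangement, not of its position; planting at identical
coordinates would also fabricate cross-module composites with perfectly
matched spacing in both species, which real promoters do not do.

Design choices that matter:

* **Library regime.** Default: 40 matrices, lengths 14–18, 1.9
  bits/column (5 % column jitter), information-ranked ids (M000 = most
  informative). Under minimise-(FP+FN) calibration this yields on the
  order of 0.1–0.5 sites/kb per matrix. The default study deliberately
  sits in this sparse-signal regime: with 250-gene lists, shuffled
  backgrounds contain essentially no chance co-occurrence, both
  enrichment profiles reduce to stepped carrier counts, and the
  correlation statistic is well-behaved. At database-average column
  information (~1.3 bits, which includes uninformative flanking
  positions that these synthetic matrices do not have), per-window
  false-positive rates near 1 % make every pair co-occur in nearly
  every promoter and no distance-constrained enrichment is measurable
  at desk scale — that regime is reachable through `StudyConfig` but is
  not what the recovery tests target, and passing tests here say
  nothing about the method's power on dense, genome-scale data.
* **Disjoint carriers.** Within a gene list, a promoter hosts at most
  one planted module: triplet carriers are exact-size draws, then a
  single uniform draw per gene is partitioned into the pair specs'
  gene-fraction intervals, so each spec's carrier count remains
  marginally Binomial(n, f). Overlapping carrier sets would let two
  different planted modules compose conserved cross-pairs inside one
  promoter and blur the planted/decoy boundary that recovery tests
  depend on. Composites that do arise (e.g. the flanking pair of a
  planted triplet) are recorded in `GroundTruth.induced_pairs`
  (co-occurrence ≤ 200 bp in ≥ 10 genes of the list in both species)
  and count as signal.
* **Planted sites are strong sites.** Site letters are sampled from the
  matrix columns and re-drawn until they score above the matrix's
  calibrated threshold (+0.02 margin, up to 60 draws). Functional sites
  are strong sites; recovery then measures the analysis, not site
  strength.
* **Default study** (`default_study_config`): 4 tissues × 250 genes,
  900 housekeeping orthologs, 5 planted conserved pairs (gap ≤ 60 bp,
  gene fraction 0.3, conservation 0.9; one homotypic), 2 ubiquitous
  pairs planted in housekeeping (and, at fraction 0.12, in every
  tissue — a pair absent from tissues could never demonstrate the
  subtraction step), and 1 fully conserved triplet (30 carriers) whose
  adjacent pairs are two of the planted pairs — by construction a
  triplet can only be called if its constituent pairs are tissue
  pairs.

What the generator does **not** emulate: indels and alignment
uncertainty, CpG and composition heterogeneity along promoters,
expression noise in gene-list selection, matrix redundancy
(near-duplicate PWMs), and position-dependent selection on sites.
Passing recovery tests therefore demonstrates internal correctness of
the pipeline under its own assumptions, not performance on real
genomes.

## Numerical and procedural details

* Gaps are edge-to-edge between site intervals (0-based, half-open);
  negative gaps (overlap) never count.
* One shuffled background replicate per promoter by default (complete
  shuffle; dinucleotide-preserving mode available); with more
  replicates, background counts are replicate means before the ratio
  floor is applied.
* Minimum-gap tables are computed by an offset sweep over the
  start-sorted hit table; offsets stop once no same-gene hit pair
  remains within the largest cutoff, which bounds work by the local hit
  density rather than the square of per-gene hit counts.
* All randomness flows from one global seed through named substreams
  (CRC-32 of stage/entity tokens mixed into a `SeedSequence`), so
  per-pair permutation p-values, per-promoter shuffles and per-matrix
  calibrations are independent of iteration order and of which other
  entities are present.
* The 10 % overlap filter's scope ("every populated cutoff" vs "any")
  is configurable because the strictest reading was adopted as the
  default; the boundary at exactly 10 % passes, as does the 50 %
  tissue-type boundary and the ≥ 6-of-10 candidate rule's boundary at
  six.
* Tissue clustering is an O(n³) agglomerative complete-linkage
  implementation with deterministic lexicographic tie-breaks on member
  labels (n ≤ ~100 tissues, so cubic cost is irrelevant); it matches
  scipy's complete linkage on tie-free inputs, which is asserted in the
  test suite. The number of groups to cut is an explicit argument —
  selecting groups from a dendrogram is a judgement call and no
  automatic heuristic is offered.
* Network-placement significance uses label resampling without
  replacement per network, independently across networks and
  replicates; bootstrap p-values are bounded below by 1/(n_boot+1) and
  claims beyond that resolution are reported at the bound.
* Problem sizes in the test suite: the recovery experiment runs the
  default study over 10 seeds and the null control over 5 seeds; unit
  and property tests use miniature corpora (tens of genes, ≤ 10
  matrices). These sizes were chosen so the whole suite exercises every
  stage end-to-end at desk scale.

## Known limitations

* Single-motif abundance confounds pair enrichment: a motif strongly
  enriched in real promoters elevates the ratio of *every* pair it
  belongs to. The screen inherits this from its real/shuffled design;
  the overlap filter and the both-species intersection mitigate but do
  not remove it.
* Palindromic motifs make the strand label of a hit ambiguous; triplet
  orientation conservation takes the scanner's label at face value.
* The hypergeometric triplet test treats the two species' carrier sets
  as independent draws, which is conservative-to-wrong for strongly
  conserved corpora; at high neutral divergence (the default study) the
  approximation is reasonable.
* With 10-point profiles the permutation p-value cannot fall below
  1/(10! ) in principle and 1/(n_perm+1) in practice; q-values within a
  small tested batch are correspondingly coarse.
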