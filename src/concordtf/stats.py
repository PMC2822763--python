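"""Enrichment statistics shared by every stage of the pipeline.

Exact tail probabilities (binomial, hypergeometric / one-sided Fisher),
Pearson correlation with a permutation null, and Benjamini-Hochberg
step-up q-values.  All operations are pure; anything stochastic takes an
explicit seed.

Tail probabilities routinely reach 1e-30 and below in this analysis, so
every tail sum is delegated to scipy's stable survival functions rather
than naive pmf accumulation.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "BinomialEnrichment",
    "HypergeomOverlap",
    "EnrichmentResult",
    "DegenerateProfileError",
    "binomial_upper_tail",
    "hypergeom_overlap_pvalue",
    "fisher_enrichment",
    "pearson_r",
    "permutation_corr_pvalue",
    "bh_qvalues",
]


class DegenerateProfileError(ValueError):
    """A correlation was requested on a constant vector.

    Downstream callers report the offending pair as untestable instead of
    silently dropping it, so this is a distinct error type.
    """


@dataclass(frozen=True)
class BinomialEnrichment:
    """Observed successes against a binomial background.

    ``strict_tail=True`` evaluates P(X > n_obs); ``False`` evaluates
    P(X >= n_obs).  Both conventions are exposed because published
    worked examples of this test are reproducible only under one or the
    other, depending on the example.
    """

    n_obs: int
    n_trials: int
    p_success: float
    strict_tail: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.n_obs <= self.n_trials):
            raise ValueError(
                f"need 0 <= n_obs <= n_trials, got n_obs={self.n_obs}, "
                f"n_trials={self.n_trials}"
            )
        if not (0.0 <= self.p_success <= 1.0):
            raise ValueError(f"p_success must be in [0,1], got {self.p_success}")


@dataclass(frozen=True)
class HypergeomOverlap:
    """Overlap c between two sets of sizes S1, S2 drawn from a universe N."""

    c: int
    N: int
    S1: int
    S2: int

    def __post_init__(self) -> None:
        if min(self.c, self.N, self.S1, self.S2) < 0:
            raise ValueError("counts must be non-negative")
        if self.c > min(self.S1, self.S2):
            raise ValueError(
                f"overlap c={self.c} exceeds min(S1,S2)={min(self.S1, self.S2)}"
            )
        if max(self.S1, self.S2) > self.N:
            raise ValueError("set sizes exceed universe size")


@dataclass(frozen=True)
class EnrichmentResult:
    """A statistic with its raw p-value and FDR-adjusted q-value."""

    statistic: float
    p_value: float
    q_value: float


def binomial_upper_tail(spec: BinomialEnrichment) -> float:
    """Exact upper-tail binomial probability.

    Returns P(X > n_obs) under the strict convention, else P(X >= n_obs).
    """
    if spec.strict_tail:
        return float(sps.binom.sf(spec.n_obs, spec.n_trials, spec.p_success))
    if spec.n_obs == 0:
        return 1.0
    return float(sps.binom.sf(spec.n_obs - 1, spec.n_trials, spec.p_success))


def hypergeom_overlap_pvalue(spec: HypergeomOverlap) -> float:
    """P(overlap >= c) for two sets drawn without replacement from N items.

    The null fixes one set and draws the other uniformly; the p-value is
    symmetric in (S1, S2).
    """
    if spec.c == 0:
        return 1.0
    # hypergeom(M=N, n=S1, N=S2): number of S1-items in a draw of S2
    return float(sps.hypergeom.sf(spec.c - 1, spec.N, spec.S1, spec.S2))


def fisher_enrichment(
    k_in_term: int, n_targets: int, K_term_total: int, N_genome: int
) -> float:
    """One-sided (enrichment) Fisher exact p-value for a 2x2 table.

    Identical to the hypergeometric overlap tail with c=k_in_term,
    S1=n_targets, S2=K_term_total, N=N_genome.
    """
    if k_in_term > min(n_targets, K_term_total):
        raise ValueError("k_in_term exceeds a margin of the table")
    if max(n_targets, K_term_total) > N_genome:
        raise ValueError("margins exceed the genome size")
    return hypergeom_overlap_pvalue(
        HypergeomOverlap(c=k_in_term, N=N_genome, S1=n_targets, S2=K_term_total)
    )


def pearson_r(x, y) -> float:
    """Pearson correlation coefficient, clipped to [-1, 1].

    Raises :class:`DegenerateProfileError` when either vector is constant,
    since r is undefined there and the caller must report the pair as
    untestable.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("x and y must be equal-length 1-d vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateProfileError("constant vector: correlation undefined")
    xc = x - x.mean()
    yc = y - y.mean()
    r = float(xc @ yc / math.sqrt((xc @ xc) * (yc @ yc)))
    return min(1.0, max(-1.0, r))


_TIE_EPS = 1e-9  # floating-point guard when counting r_perm >= r_obs


def permutation_corr_pvalue(
    x, y, n_perm: int = 10_000, seed: int = 0, alternative: str = "greater"
) -> float:
    """Permutation p-value for the correlation of x and y.

    Shuffles the pairing of y against x.  The default alternative is
    one-sided for positive correlation (function conservation predicts
    positive coupling of the profiles); ``alternative="two-sided"``
    compares |r| instead.  For vectors of length <= 6 the full
    permutation group is enumerated and p = #{r_perm >= r_obs} / n!;
    otherwise ``n_perm`` random permutations are drawn and
    p = (1 + #{r_perm >= r_obs}) / (n_perm + 1), which never reports zero.
    """
    if alternative not in {"greater", "two-sided"}:
        raise ValueError("alternative must be 'greater' or 'two-sided'")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    r_obs = pearson_r(x, y)  # validates shapes, raises on constant input
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a very coarse p-value", stacklevel=2)
    n = x.size
    xc = x - x.mean()
    xs = xc / math.sqrt(float(xc @ xc))
    if n <= 6:
        perms = np.array(list(itertools.permutations(range(n))))
    else:
        rng = np.random.default_rng(seed)
        perms = np.argsort(rng.random((n_perm, n)), axis=1)
    yp = y[perms]
    ypc = yp - yp.mean(axis=1, keepdims=True)
    norms = np.sqrt(np.einsum("ij,ij->i", ypc, ypc))
    r_perm = (ypc @ xs) / norms
    if alternative == "two-sided":
        hits = int(np.count_nonzero(np.abs(r_perm) >= abs(r_obs) - _TIE_EPS))
    else:
        hits = int(np.count_nonzero(r_perm >= r_obs - _TIE_EPS))
    if n <= 6:
        return hits / len(perms)
    return (1 + hits) / (n_perm + 1)


def bh_qvalues(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.empty(0)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0,1]")
    return multipletests(p, method="fdr_bh")[1]
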