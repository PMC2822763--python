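"""Distance-constrained TF-pair enrichment and cross-species conservation.

The core statistic couples two 10-point profiles computed over a grid of
maximum-gap cutoffs (20..200 bp by default):

* ``site_ratio[d]`` — genes whose promoter carries both sites within
  gap d in the real corpus, over the same count in per-promoter shuffled
  backgrounds;
* ``overlap_ratio[d]`` — orthologous gene pairs carrying the sites in
  both species within gap d, over the same overlap in the backgrounds.

A pair whose binding-site enrichment tracks its ortholog-overlap
enrichment across the grid (high Pearson r, permutation q < 0.05 with
each species in turn as the foreground) is called conserved.  Gaps are
edge-to-edge; overlapping sites do not count as a co-occurrence; counting
is gene-level presence.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import stats

__all__ = [
    "DEFAULT_GRID",
    "pair_key",
    "enumerate_pair_universe",
    "cooccurring_genes",
    "pair_gap_table",
    "gene_counts_by_cutoff",
    "overlap_counts_by_cutoff",
    "site_enrichment_profile",
    "select_candidate_pairs",
    "PairProfiles",
    "build_pair_profiles",
    "call_conserved_pairs",
]

DEFAULT_GRID: tuple[int, ...] = tuple(range(20, 201, 20))


def pair_key(a: str, b: str) -> tuple[str, str]:
    """Canonical (lexicographically sorted) unordered pair; self-pairs allowed."""
    return (a, b) if a <= b else (b, a)


def enumerate_pair_universe(pwm_ids: Iterable[str]) -> set[tuple[str, str]]:
    """All unordered pairs including homotypic ones: k(k+1)/2 for k ids."""
    ids = sorted(set(pwm_ids))
    if not ids:
        raise ValueError("need at least one PWM id")
    return {(ids[i], ids[j]) for i in range(len(ids)) for j in range(i, len(ids))}


def _min_gap(starts_a, ends_a, starts_b, ends_b, homotypic_skip=False) -> float:
    """Smallest non-negative edge-to-edge gap over all hit arrangements."""
    sa = np.asarray(starts_a)[:, None]
    ea = np.asarray(ends_a)[:, None]
    sb = np.asarray(starts_b)[None, :]
    eb = np.asarray(ends_b)[None, :]
    gap = np.maximum(sb - ea, sa - eb)
    if homotypic_skip:
        np.fill_diagonal(gap, -1)
    valid = gap >= 0
    return float(gap[valid].min()) if valid.any() else np.inf


def cooccurring_genes(
    hits: pd.DataFrame, pair: tuple[str, str], max_gap: int
) -> set[str]:
    """Genes with at least one arrangement of one hit per pair member at an
    edge-to-edge gap in [0, max_gap] (reference implementation; the
    pipeline uses :func:`pair_gap_table`)."""
    a, b = pair
    out = set()
    for gene, sub in hits[hits["pwm"].isin([a, b])].groupby("gene"):
        ha = sub[sub["pwm"] == a]
        hb = sub[sub["pwm"] == b]
        if a == b:
            if len(ha) < 2:
                continue
            g = _min_gap(ha["start"], ha["end"], ha["start"], ha["end"], True)
        else:
            if ha.empty or hb.empty:
                continue
            g = _min_gap(ha["start"], ha["end"], hb["start"], hb["end"])
        if g <= max_gap:
            out.add(gene)
    return out


def pair_gap_table(hits: pd.DataFrame, max_gap: int = 200) -> pd.DataFrame:
    """Per (gene, unordered pair) minimum edge-to-edge gap, gaps in [0, max_gap].

    Vectorised over the sorted hit table: for each offset k, hit i is
    paired with hit i+k of the same gene; because hits are sorted by
    start, the candidate gap is start[i+k] - end[i], and offsets stop as
    soon as no same-gene pair remains within max_gap.  Rows are
    (gene, pwm_a, pwm_b, min_gap) with pwm_a <= pwm_b.
    """
    if hits.empty:
        return pd.DataFrame(columns=["gene", "pwm_a", "pwm_b", "min_gap"])
    h = hits.sort_values(["gene", "start"], kind="stable")
    gene_codes, gene_index = pd.factorize(h["gene"], sort=True)
    pwm_codes, pwm_index = pd.factorize(h["pwm"], sort=True)
    s = h["start"].to_numpy(np.int64)
    e = h["end"].to_numpy(np.int64)
    n = len(h)
    parts = []
    k = 1
    while k < n:
        same = gene_codes[:-k] == gene_codes[k:]
        gap = s[k:] - e[:-k]
        within = same & (gap <= max_gap)
        if not within.any():
            break
        keep = within & (gap >= 0)
        if keep.any():
            pa = pwm_codes[:-k][keep]
            pb = pwm_codes[k:][keep]
            lo = np.minimum(pa, pb)
            hi = np.maximum(pa, pb)
            parts.append(
                pd.DataFrame(
                    {
                        "gene": gene_codes[:-k][keep],
                        "pa": lo,
                        "pb": hi,
                        "gap": gap[keep],
                    }
                )
            )
        k += 1
    if not parts:
        return pd.DataFrame(columns=["gene", "pwm_a", "pwm_b", "min_gap"])
    allp = pd.concat(parts, ignore_index=True)
    g = allp.groupby(["gene", "pa", "pb"], sort=False)["gap"].min().reset_index()
    return pd.DataFrame(
        {
            "gene": gene_index[g["gene"]],
            "pwm_a": pwm_index[g["pa"]],
            "pwm_b": pwm_index[g["pb"]],
            "min_gap": g["gap"],
        }
    )


def _cutoff_index(gaps: np.ndarray, grid: Sequence[int]) -> np.ndarray:
    """Index of the smallest cutoff admitting each gap."""
    return np.searchsorted(np.asarray(grid), gaps, side="left")


def gene_counts_by_cutoff(
    gap_table: pd.DataFrame, grid: Sequence[int] = DEFAULT_GRID
) -> pd.DataFrame:
    """Genes per (pair, cutoff): DataFrame indexed by (pwm_a, pwm_b) with one
    column per grid cutoff; counts are monotone along the grid."""
    grid = tuple(grid)
    if gap_table.empty:
        return pd.DataFrame(
            columns=list(grid),
            index=pd.MultiIndex.from_arrays([[], []], names=["pwm_a", "pwm_b"]),
        )
    t = gap_table[gap_table["min_gap"] <= grid[-1]]
    codes, pairs = pd.factorize(
        pd.Series(list(zip(t["pwm_a"], t["pwm_b"]))), sort=True
    )
    idx = _cutoff_index(t["min_gap"].to_numpy(), grid)
    flat = np.bincount(codes * len(grid) + idx, minlength=len(pairs) * len(grid))
    counts = flat.reshape(len(pairs), len(grid)).cumsum(axis=1)
    return pd.DataFrame(
        counts,
        index=pd.MultiIndex.from_tuples(list(pairs), names=["pwm_a", "pwm_b"]),
        columns=list(grid),
    )


def overlap_counts_by_cutoff(
    gap_h: pd.DataFrame,
    gap_m: pd.DataFrame,
    mouse_to_human: Mapping[str, str],
    grid: Sequence[int] = DEFAULT_GRID,
) -> pd.DataFrame:
    """Orthologous gene pairs carrying the pair in both species per cutoff.

    ``gap_h``/``gap_m`` are :func:`pair_gap_table` outputs; mouse genes are
    translated to their human partner through the 1:1 ortholog map before
    intersecting.  A gene
    pair counts at cutoff d when both species' minimum gaps are <= d.
    """
    grid = tuple(grid)
    empty = pd.DataFrame(
        columns=list(grid),
        index=pd.MultiIndex.from_arrays([[], []], names=["pwm_a", "pwm_b"]),
    )
    if gap_h.empty or gap_m.empty:
        return empty
    m = gap_m.copy()
    m["gene"] = m["gene"].map(dict(mouse_to_human))
    m = m.dropna(subset=["gene"])
    merged = gap_h.merge(
        m, on=["gene", "pwm_a", "pwm_b"], suffixes=("_h", "_m"), how="inner"
    )
    if merged.empty:
        return empty
    both = np.maximum(merged["min_gap_h"], merged["min_gap_m"]).to_numpy()
    merged = merged[both <= grid[-1]]
    both = both[both <= grid[-1]]
    if merged.empty:
        return empty
    codes, pairs = pd.factorize(
        pd.Series(list(zip(merged["pwm_a"], merged["pwm_b"]))), sort=True
    )
    idx = _cutoff_index(both, grid)
    flat = np.bincount(codes * len(grid) + idx, minlength=len(pairs) * len(grid))
    counts = flat.reshape(len(pairs), len(grid)).cumsum(axis=1)
    return pd.DataFrame(
        counts,
        index=pd.MultiIndex.from_tuples(list(pairs), names=["pwm_a", "pwm_b"]),
        columns=list(grid),
    )


def site_enrichment_profile(
    real_counts: np.ndarray, background_counts: np.ndarray
) -> np.ndarray:
    """Real/background gene-count ratio with a zero-background floor of 1."""
    real = np.asarray(real_counts, dtype=float)
    bg = np.asarray(background_counts, dtype=float)
    return real / np.maximum(bg, 1.0)


def select_candidate_pairs(site_ratios: pd.DataFrame) -> pd.Index:
    """Pairs whose site ratio exceeds 1 in more than half the grid
    (ratio > 1 at >= 6 of 10 cutoffs)."""
    keep = (site_ratios.to_numpy() > 1.0).sum(axis=1) >= 6
    return site_ratios.index[keep]


@dataclass
class PairProfiles:
    """All per-pair per-cutoff quantities for one gene-set analysis."""

    grid: tuple[int, ...]
    counts_real: dict[str, pd.DataFrame]  # species -> pair x cutoff gene counts
    counts_bg: dict[str, pd.DataFrame]
    overlap_real: pd.DataFrame  # pair x cutoff orthologous-overlap counts
    overlap_bg: pd.DataFrame
    site_ratio: dict[str, pd.DataFrame]
    overlap_ratio: pd.DataFrame
    overlap_fraction: pd.DataFrame


def _align(df: pd.DataFrame, index: pd.Index, grid) -> pd.DataFrame:
    return df.reindex(index=index, columns=list(grid), fill_value=0)


def build_pair_profiles(
    gap_real: Mapping[str, pd.DataFrame],
    gap_bg: Mapping[str, pd.DataFrame],
    mouse_to_human: Mapping[str, str],
    grid: Sequence[int] = DEFAULT_GRID,
) -> PairProfiles:
    """Assemble enrichment and overlap profiles from per-species gap tables.

    ``gap_real`` / ``gap_bg`` map species ("human"/"mouse") to
    :func:`pair_gap_table` outputs for the real and shuffled corpora of
    one gene set.  Background tables may carry a ``weight`` column
    (1/n_replicates) when several shuffle replicates are pooled; counts
    are then replicate means.
    """
    grid = tuple(grid)
    counts_real = {sp: gene_counts_by_cutoff(t, grid) for sp, t in gap_real.items()}
    counts_bg = {}
    for sp, t in gap_bg.items():
        if "replicate" in t.columns and t["replicate"].nunique() > 1:
            reps = [
                gene_counts_by_cutoff(r, grid) for _, r in t.groupby("replicate")
            ]
            idx = reps[0].index
            for r in reps[1:]:
                idx = idx.union(r.index)
            counts_bg[sp] = sum(_align(r, idx, grid) for r in reps) / len(reps)
        else:
            counts_bg[sp] = gene_counts_by_cutoff(t, grid)
    overlap_real = overlap_counts_by_cutoff(
        gap_real["human"], gap_real["mouse"], mouse_to_human, grid
    )
    overlap_bg = overlap_counts_by_cutoff(
        gap_bg["human"], gap_bg["mouse"], mouse_to_human, grid
    )
    index = counts_real["human"].index.union(counts_real["mouse"].index)
    site_ratio = {
        sp: pd.DataFrame(
            site_enrichment_profile(
                _align(counts_real[sp], index, grid).to_numpy(),
                _align(counts_bg[sp], index, grid).to_numpy(),
            ),
            index=index,
            columns=list(grid),
        )
        for sp in counts_real
    }
    ov_r = _align(overlap_real, index, grid).to_numpy().astype(float)
    ov_b = _align(overlap_bg, index, grid).to_numpy().astype(float)
    overlap_ratio = pd.DataFrame(
        ov_r / np.maximum(ov_b, 1.0), index=index, columns=list(grid)
    )
    min_counts = np.minimum(
        _align(counts_real["human"], index, grid).to_numpy(),
        _align(counts_real["mouse"], index, grid).to_numpy(),
    ).astype(float)
    overlap_fraction = pd.DataFrame(
        ov_r / np.maximum(min_counts, 1.0), index=index, columns=list(grid)
    )
    return PairProfiles(
        grid=grid,
        counts_real={sp: _align(c, index, grid) for sp, c in counts_real.items()},
        counts_bg={sp: _align(c, index, grid) for sp, c in counts_bg.items()},
        overlap_real=_align(overlap_real, index, grid),
        overlap_bg=_align(overlap_bg, index, grid),
        site_ratio=site_ratio,
        overlap_ratio=overlap_ratio,
        overlap_fraction=overlap_fraction,
    )


def _passes_overlap_filter(
    fraction: np.ndarray,
    count_h: np.ndarray,
    count_m: np.ndarray,
    minimum: float,
    scope: str,
) -> bool:
    populated = (count_h > 0) & (count_m > 0)
    if not populated.any():
        return False
    ok = fraction[populated] >= minimum
    return bool(ok.all() if scope == "all" else ok.any())


def _pair_seed(seed: int, pair: tuple[str, str]) -> int:
    return (zlib.crc32(f"{pair[0]}:{pair[1]}".encode()) ^ (seed & 0x7FFFFFFF)) & 0x7FFFFFFF


def call_conserved_pairs(
    profiles: PairProfiles,
    n_perm: int = 10_000,
    seed: int = 0,
    q_cutoff: float = 0.05,
    overlap_min: float = 0.10,
    overlap_scope: str = "all",
) -> pd.DataFrame:
    """Conservation calls for one gene set.

    The whole procedure runs once with each species as the foreground:
    candidates (site ratio > 1 at more than half the cutoffs, ortholog
    overlap >= ``overlap_min`` at the populated cutoffs) are correlated
    against the shared overlap-enrichment profile, permutation p-values
    are adjusted per species batch, and a pair is called when q <
    ``q_cutoff`` in both species.  Returns one row per tested pair with
    per-species r/p/q, called flags and a status column ("tested" or a
    reason the pair was untestable).
    """
    if overlap_scope not in {"all", "any"}:
        raise ValueError("overlap_scope must be 'all' or 'any'")
    species = sorted(profiles.site_ratio)
    index = profiles.overlap_ratio.index
    ov = profiles.overlap_ratio.to_numpy()
    frac = profiles.overlap_fraction.to_numpy()
    counts_h = profiles.counts_real["human"].to_numpy()
    counts_m = profiles.counts_real["mouse"].to_numpy()
    ratios = {sp: profiles.site_ratio[sp].to_numpy() for sp in species}
    rows = []
    for i, pair in enumerate(index):
        if not _passes_overlap_filter(
            frac[i], counts_h[i], counts_m[i], overlap_min, overlap_scope
        ):
            continue
        row: dict = {"pwm_a": pair[0], "pwm_b": pair[1], "status": "tested"}
        for sp in species:
            sr = ratios[sp][i]
            if (sr > 1.0).sum() < 6:
                row[f"candidate_{sp}"] = False
                row[f"r_{sp}"] = np.nan
                row[f"p_{sp}"] = np.nan
                continue
            row[f"candidate_{sp}"] = True
            try:
                row[f"r_{sp}"] = stats.pearson_r(sr, ov[i])
                row[f"p_{sp}"] = stats.permutation_corr_pvalue(
                    sr, ov[i], n_perm=n_perm, seed=_pair_seed(seed, pair)
                )
            except stats.DegenerateProfileError:
                row["status"] = "untestable:constant-profile"
                row[f"r_{sp}"] = np.nan
                row[f"p_{sp}"] = np.nan
        if any(row.get(f"candidate_{sp}", False) for sp in species):
            rows.append(row)
    out = pd.DataFrame(rows)
    if out.empty:
        cols = ["pwm_a", "pwm_b", "status"]
        for sp in species:
            cols += [f"candidate_{sp}", f"r_{sp}", f"p_{sp}", f"q_{sp}", f"called_{sp}"]
        return pd.DataFrame(columns=cols + ["called"])
    for sp in species:
        tested = out[f"p_{sp}"].notna()
        out[f"q_{sp}"] = np.nan
        if tested.any():
            out.loc[tested, f"q_{sp}"] = stats.bh_qvalues(
                out.loc[tested, f"p_{sp}"].to_numpy()
            )
        out[f"called_{sp}"] = out[f"q_{sp}"] < q_cutoff
    out["called"] = np.logical_and.reduce(
        [out[f"called_{sp}"].to_numpy() for sp in species]
    )
    return out.sort_values(["pwm_a", "pwm_b"]).reset_index(drop=True)
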