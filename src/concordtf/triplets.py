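"""Composition and calling of conserved 3-TF modules.

Candidate 3-site combinations arise from two pair occurrences on one
promoter that share one site at exactly the same location (same matrix,
interval and strand).  A candidate is conserved when the orthologous
promoter carries a candidate with the same 3-matrix key, the same
left-to-right matrix order and the same per-site strands.  A triplet is
called in a tissue when it is conserved on at least ``min_support``
orthologous gene pairs and the overlap of its human and mouse target
genes within the tissue list is significant by the hypergeometric tail
(q < 0.05 after per-tissue adjustment).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import stats

__all__ = [
    "TripletOccurrence",
    "pair_site_occurrences",
    "compose_triplets",
    "conserved_occurrences",
    "call_triplets",
]

Site = tuple  # (pwm, start, end, strand)


@dataclass(frozen=True)
class TripletOccurrence:
    """Three non-overlapping sites on one promoter, ordered by start."""

    gene: str
    key: tuple[str, str, str]  # sorted multiset of the 3 matrix ids
    sites: tuple[Site, Site, Site]

    @property
    def order(self) -> tuple[str, ...]:
        """Matrix ids in promoter (left-to-right) order."""
        return tuple(s[0] for s in self.sites)

    @property
    def strands(self) -> tuple[str, ...]:
        return tuple(s[3] for s in self.sites)


def pair_site_occurrences(
    hits: pd.DataFrame,
    pairs: Sequence[tuple[str, str]],
    max_gap: int = 200,
) -> pd.DataFrame:
    """Site-level occurrences of the given pairs: every arrangement of two
    hits (one per pair member, distinct hits for homotypic pairs) with an
    edge-to-edge gap in [0, max_gap].

    Returns rows (gene, pwm_a, pwm_b, start_a, end_a, strand_a, start_b,
    end_b, strand_b) with the two sites ordered by start.
    """
    wanted = {tuple(sorted(p)) for p in pairs}
    pwms = {x for p in wanted for x in p}
    h = hits[hits["pwm"].isin(pwms)].sort_values(["gene", "start"], kind="stable")
    if h.empty:
        return pd.DataFrame(
            columns=["gene", "pwm_a", "pwm_b", "start_a", "end_a", "strand_a",
                     "start_b", "end_b", "strand_b"]
        )
    gene = h["gene"].to_numpy()
    pwm = h["pwm"].to_numpy()
    s = h["start"].to_numpy(np.int64)
    e = h["end"].to_numpy(np.int64)
    strand = h["strand"].to_numpy()
    n = len(h)
    parts = []
    k = 1
    while k < n:
        same = gene[:-k] == gene[k:]
        gap = s[k:] - e[:-k]
        within = same & (gap <= max_gap)
        if not within.any():
            break
        keep = within & (gap >= 0)
        if keep.any():
            pa, pb = pwm[:-k][keep], pwm[k:][keep]
            lo = np.minimum(pa, pb)
            hi = np.maximum(pa, pb)
            df = pd.DataFrame(
                {
                    "gene": gene[:-k][keep],
                    "pwm_a": pa, "pwm_b": pb,
                    "start_a": s[:-k][keep], "end_a": e[:-k][keep],
                    "strand_a": strand[:-k][keep],
                    "start_b": s[k:][keep], "end_b": e[k:][keep],
                    "strand_b": strand[k:][keep],
                    "_lo": lo, "_hi": hi,
                }
            )
            df = df[[tuple(x) in wanted for x in zip(df["_lo"], df["_hi"])]]
            parts.append(df.drop(columns=["_lo", "_hi"]))
        k += 1
    if not parts:
        return pd.DataFrame(
            columns=["gene", "pwm_a", "pwm_b", "start_a", "end_a", "strand_a",
                     "start_b", "end_b", "strand_b"]
        )
    return pd.concat(parts, ignore_index=True)


def compose_triplets(
    occurrences: pd.DataFrame, tolerance: int = 0
) -> list[TripletOccurrence]:
    """All 3-site combinations from two pair occurrences sharing one site
    at the same location; duplicates (same 3 intervals) are emitted once,
    and combinations whose outer sites overlap are rejected (sites of a
    module must be disjoint).

    "Same location" is exact interval identity by default; a nonzero
    ``tolerance`` accepts shared sites of the same matrix and strand whose
    start and end each differ by at most that many bp (the first-seen
    interval represents the shared site).
    """
    out: dict[tuple, TripletOccurrence] = {}
    if occurrences.empty:
        return []
    for gene, sub in occurrences.groupby("gene"):
        by_site: dict[Site, list[Site]] = {}

        def site_bucket(site: Site) -> Site:
            if tolerance == 0:
                return site
            for seen in by_site:
                if (
                    seen[0] == site[0]
                    and seen[3] == site[3]
                    and abs(seen[1] - site[1]) <= tolerance
                    and abs(seen[2] - site[2]) <= tolerance
                ):
                    return seen
            return site

        for row in sub.itertuples(index=False):
            sa: Site = (row.pwm_a, int(row.start_a), int(row.end_a), row.strand_a)
            sb: Site = (row.pwm_b, int(row.start_b), int(row.end_b), row.strand_b)
            sa, sb = site_bucket(sa), site_bucket(sb)
            by_site.setdefault(sa, []).append(sb)
            by_site.setdefault(sb, []).append(sa)
        for shared, partners in by_site.items():
            uniq = sorted(set(partners))
            for i in range(len(uniq)):
                for j in range(i + 1, len(uniq)):
                    x, y = uniq[i], uniq[j]
                    if x[1] < y[2] and y[1] < x[2]:  # outer sites overlap
                        continue
                    sites = tuple(sorted((shared, x, y), key=lambda t: (t[1], t[2])))
                    sig = (gene, sites)
                    if sig not in out:
                        out[sig] = TripletOccurrence(
                            gene=gene,
                            key=tuple(sorted(s[0] for s in sites)),
                            sites=sites,  # type: ignore[arg-type]
                        )
    return sorted(out.values(), key=lambda t: (t.gene, t.sites))


def conserved_occurrences(
    human: Sequence[TripletOccurrence],
    mouse: Sequence[TripletOccurrence],
    human_to_mouse: Mapping[str, str],
) -> list[TripletOccurrence]:
    """Human candidates whose mouse ortholog carries a candidate with the
    same key, the same left-to-right matrix order and identical per-site
    strands."""
    inv = dict(human_to_mouse)
    mouse_index: dict[tuple, set] = {}
    for occ in mouse:
        mouse_index.setdefault((occ.gene, occ.key), set()).add(
            (occ.order, occ.strands)
        )
    kept = []
    for occ in human:
        mg = inv.get(occ.gene)
        if mg is None:
            continue
        if (occ.order, occ.strands) in mouse_index.get((mg, occ.key), ()):
            kept.append(occ)
    return kept


def call_triplets(
    conserved: Sequence[TripletOccurrence],
    human_candidates: Sequence[TripletOccurrence],
    mouse_candidates: Sequence[TripletOccurrence],
    n_tissue_genes: int,
    mouse_to_human: Mapping[str, str] | None = None,
    q_cutoff: float = 0.05,
    min_support: int = 10,
) -> pd.DataFrame:
    """Per-triplet support, hypergeometric overlap p and q, and call flag.

    Support is the number of distinct orthologous gene pairs with a
    conserved occurrence; S1/S2 are the tissue genes carrying the 3-site
    combination in human/mouse; N is the tissue gene-list size.
    """
    sup: dict[tuple, set] = {}
    for occ in conserved:
        sup.setdefault(occ.key, set()).add(occ.gene)
    s1: dict[tuple, set] = {}
    for occ in human_candidates:
        s1.setdefault(occ.key, set()).add(occ.gene)
    s2: dict[tuple, set] = {}
    for occ in mouse_candidates:
        g = mouse_to_human[occ.gene] if mouse_to_human else occ.gene
        s2.setdefault(occ.key, set()).add(g)
    rows = []
    for key in sorted(sup):
        c = len(sup[key])
        S1 = len(s1.get(key, sup[key]))
        S2 = len(s2.get(key, sup[key]))
        if max(S1, S2) > n_tissue_genes:
            raise ValueError("carrier sets exceed the tissue gene-list size")
        p = stats.hypergeom_overlap_pvalue(
            stats.HypergeomOverlap(c=c, N=n_tissue_genes, S1=S1, S2=S2)
        )
        rows.append(
            {
                "triplet": ":".join(key), "support": c, "S1": S1, "S2": S2,
                "p": p, "genes": ",".join(sorted(sup[key])),
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        return pd.DataFrame(
            columns=["triplet", "support", "S1", "S2", "p", "q", "called", "genes"]
        )
    out["q"] = stats.bh_qvalues(out["p"].to_numpy())
    out["called"] = (out["support"] >= min_support) & (out["q"] < q_cutoff)
    return out[["triplet", "support", "S1", "S2", "p", "q", "called", "genes"]]
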