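"""Housekeeping subtraction, tissue-unique pairs, tissue clustering and
tissue-type pair calling.

Tissues are grouped by complete-linkage agglomerative clustering on the
asymmetric-binary (Jaccard) distance between their pair-presence
profiles.  The dendrogram cut (number of groups) is an explicit input:
group selection from a dendrogram is inherently a judgement call, so no
automatic cut heuristic is provided.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TissueGroup",
    "subtract_housekeeping",
    "tissue_unique_pairs",
    "presence_matrix",
    "binary_distance_matrix",
    "complete_linkage_clusters",
    "tissue_type_pairs",
]

logger = logging.getLogger(__name__)

PairSet = set


@dataclass(frozen=True)
class TissueGroup:
    label: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("a tissue group needs at least one member")


def subtract_housekeeping(
    tissue_pairs: PairSet, housekeeping_pairs: PairSet
) -> tuple[PairSet, float]:
    """Remove pairs shared with the housekeeping set.

    Returns the filtered set and the fraction of the tissue's pairs that
    was removed (0 for an empty tissue set).
    """
    tissue_pairs = set(tissue_pairs)
    removed = tissue_pairs & set(housekeeping_pairs)
    kept = tissue_pairs - removed
    frac = len(removed) / len(tissue_pairs) if tissue_pairs else 0.0
    if tissue_pairs and not kept:
        logger.warning("all %d tissue pairs were housekeeping pairs", len(tissue_pairs))
    return kept, frac


def tissue_unique_pairs(tissue_sets: Mapping[str, PairSet]) -> dict[str, PairSet]:
    """Pairs occurring in exactly one tissue's set."""
    if len(tissue_sets) < 2:
        raise ValueError("need at least two tissues")
    counts: dict = {}
    for pairs in tissue_sets.values():
        for p in pairs:
            counts[p] = counts.get(p, 0) + 1
    return {
        t: {p for p in pairs if counts[p] == 1} for t, pairs in tissue_sets.items()
    }


def presence_matrix(tissue_sets: Mapping[str, PairSet]) -> pd.DataFrame:
    """0/1 pair-by-tissue matrix (rows: pairs, columns: tissues)."""
    all_pairs = sorted(set().union(*tissue_sets.values())) if tissue_sets else []
    data = {
        t: [1 if p in pairs else 0 for p in all_pairs]
        for t, pairs in tissue_sets.items()
    }
    return pd.DataFrame(
        data, index=pd.Index(all_pairs, tupleize_cols=False, name="pair")
    )


def binary_distance_matrix(presence: pd.DataFrame) -> pd.DataFrame:
    """Asymmetric-binary (Jaccard) distance between tissue columns:
    d = (b+c)/(a+b+c) with a = both present, b/c = present in exactly one;
    two all-zero columns are at distance 0 by convention."""
    x = (presence.to_numpy() > 0).astype(np.int64)
    both = x.T @ x
    totals = x.sum(axis=0)
    union = totals[:, None] + totals[None, :] - both
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(union > 0, (union - both) / np.maximum(union, 1), 0.0)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=presence.columns, columns=presence.columns)


def complete_linkage_clusters(
    distance: pd.DataFrame, n_groups: int
) -> list[TissueGroup]:
    """Agglomerative clustering with complete (maximum) linkage.

    Merges the closest cluster pair until ``n_groups`` remain; ties break
    deterministically on the lexicographically smallest member labels of
    the candidate clusters.  Each returned group is labelled by its
    smallest member.
    """
    labels = list(distance.index)
    n = len(labels)
    if not (1 <= n_groups <= n):
        raise ValueError(f"n_groups must be in [1, {n}]")
    if list(distance.columns) != labels:
        raise ValueError("distance matrix must be square with matching labels")
    d = distance.to_numpy(dtype=float)
    if not np.allclose(d, d.T) or np.any(np.diag(d) != 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    clusters: list[list[str]] = [[lab] for lab in labels]
    dist: dict[tuple[int, int], float] = {
        (i, j): d[i, j] for i in range(n) for j in range(i + 1, n)
    }
    active = list(range(n))
    next_id = n
    members = {i: clusters[i] for i in range(n)}
    while len(active) > n_groups:
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                key = (min(i, j), max(i, j))
                val = dist[key]
                tag = tuple(sorted((min(members[i]), min(members[j]))))
                cand = (val, tag, key)
                if best is None or cand < best:
                    best = cand
        _, _, (i, j) = best
        merged = sorted(members[i] + members[j])
        members[next_id] = merged
        for k in active:
            if k in (i, j):
                continue
            dij = max(
                dist[(min(i, k), max(i, k))], dist[(min(j, k), max(j, k))]
            )
            dist[(k, next_id)] = dij
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1
    return sorted(
        (TissueGroup(label=min(members[k]), members=tuple(members[k])) for k in active),
        key=lambda g: g.label,
    )


def tissue_type_pairs(
    group: TissueGroup | Sequence[str],
    tissue_sets: Mapping[str, PairSet],
    min_fraction: float = 0.5,
) -> PairSet:
    """Pairs present in at least ``min_fraction`` of the group's tissues
    (the exact-half boundary is included)."""
    members = group.members if isinstance(group, TissueGroup) else tuple(group)
    if len(members) < 2:
        raise ValueError("a tissue-type group needs at least 2 tissues")
    out = set()
    for p in set().union(*(tissue_sets[t] for t in members)):
        share = sum(p in tissue_sets[t] for t in members) / len(members)
        if share >= min_fraction:
            out.add(p)
    return out
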