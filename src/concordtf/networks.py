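"""TF-TF interaction networks from tissue-type pairs.

A network is a connected component of the pair graph with at least two
edges; homotypic pairs contribute self-loops, which count toward a
node's degree (one self-loop adds 2) but not toward connectivity.
"Internal" TFs are nodes of degree >= 2 — the articulating TFs of a
multi-input network motif.  The label-resampling bootstrap replaces each
network's node labels with a uniform draw from the matrix universe,
preserving topology, to test whether a designated TF subset (e.g. known
tissue-specific TFs) occupies internal positions more often than chance.
"""

from __future__ import annotations

import zlib
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "TFNetwork",
    "build_networks",
    "match_tissue_type_networks",
    "hub_census",
    "internal_enrichment_bootstrap",
]

PairKey = tuple


@dataclass(frozen=True)
class TFNetwork:
    nodes: frozenset
    edges: frozenset  # canonical pair keys; self-pairs allowed
    tissues: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.edges) < 2:
            raise ValueError("a network joins 2 or more TF pairs")
        for a, b in self.edges:
            if a not in self.nodes or b not in self.nodes:
                raise ValueError("edge endpoints must be nodes")

    @property
    def internal(self) -> frozenset:
        """Nodes of degree >= 2 (a self-loop contributes 2)."""
        deg = Counter()
        for a, b in self.edges:
            deg[a] += 1
            deg[b] += 1 if a != b else 0
            if a == b:
                deg[a] += 1
        return frozenset(n for n, d in deg.items() if d >= 2)


def build_networks(pairs: Iterable[PairKey], tissue: str = "") -> list[TFNetwork]:
    """Connected components of the pair graph with >= 2 edges.

    Self-loops are attached to whichever component their node lands in;
    a node whose only edge is its self-loop forms no network on its own
    unless a second edge joins it.
    """
    edges = {tuple(sorted(p)) for p in pairs}
    g = nx.Graph()
    g.add_edges_from(edges)
    out = []
    for comp in nx.connected_components(g):
        comp_edges = frozenset(e for e in edges if e[0] in comp)
        if len(comp_edges) >= 2:
            out.append(
                TFNetwork(
                    nodes=frozenset(comp),
                    edges=comp_edges,
                    tissues=(tissue,) if tissue else (),
                )
            )
    return sorted(out, key=lambda n: sorted(n.edges))


def _as_graph(net: TFNetwork) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(net.nodes)
    g.add_edges_from(net.edges)
    return g


def match_tissue_type_networks(
    networks_by_tissue: Mapping[str, Sequence[TFNetwork]],
    group: Sequence[str] | None = None,
    labeled: bool = True,
) -> list[TFNetwork]:
    """Networks with the same topology in >= 2 tissues of the group; each
    is reported once with its supporting tissue list.

    "Same topology" defaults to identical labelled edge sets (nodes are
    named TFs); ``labeled=False`` matches on unlabelled graph shape
    (graph isomorphism) instead.
    """
    tissues = sorted(group) if group is not None else sorted(networks_by_tissue)
    if len(tissues) < 2:
        raise ValueError("a tissue-type group needs >= 2 tissues")
    if labeled:
        key_of = lambda net: net.edges
    else:
        # bucket by representative up to isomorphism (networks are
        # motif-sized, so pairwise checks are cheap)
        reps: list[TFNetwork] = []

        def key_of(net):  # noqa: E306
            g = _as_graph(net)
            for i, rep in enumerate(reps):
                if nx.is_isomorphic(_as_graph(rep), g):
                    return i
            reps.append(net)
            return len(reps) - 1

    support: dict = {}
    first_net: dict = {}
    for t in tissues:
        for net in networks_by_tissue.get(t, ()):  # permutation-invariant
            key = key_of(net)
            support.setdefault(key, set()).add(t)
            if key not in first_net or sorted(net.edges) < sorted(first_net[key].edges):
                first_net[key] = net
    out = [
        TFNetwork(
            nodes=first_net[k].nodes,
            edges=first_net[k].edges,
            tissues=tuple(sorted(ts)),
        )
        for k, ts in support.items()
        if len(ts) >= 2
    ]
    return sorted(out, key=lambda n: sorted(n.edges))


def hub_census(networks: Sequence[TFNetwork]) -> list[tuple[str, int]]:
    """Per TF, the number of networks where it sits at an internal
    position; descending count, ties by label."""
    counts = Counter()
    for net in networks:
        for tf in net.internal:
            counts[tf] += 1
    for net in networks:
        for tf in net.nodes:
            counts.setdefault(tf, 0)
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))


def _observed_stats(networks: Sequence[TFNetwork], special: frozenset) -> tuple[int, int]:
    n_internal = sum(1 for net in networks if net.internal & special)
    n_total = sum(len(net.nodes & special) for net in networks)
    return n_internal, n_total


def internal_enrichment_bootstrap(
    networks: Sequence[TFNetwork],
    special_set: Iterable,
    universe: Iterable,
    n_boot: int = 10_000,
    seed: int = 0,
) -> dict[str, float]:
    """Label-resampling significance of a TF subset's placement.

    Each replicate redraws every network's node labels uniformly without
    replacement from the universe (independently per network), keeping
    the topology — and therefore which positions are internal — fixed.
    Returns one-sided p-values for (a) the number of networks with at
    least one special internal TF and (b) the total count of special TFs
    across networks, each computed as (1 + #{replicate >= observed}) /
    (n_boot + 1).
    """
    universe = sorted(set(universe))
    special = frozenset(special_set)
    if not special <= set(universe):
        raise ValueError("special_set must be a subset of the universe")
    if n_boot < 1000:
        raise ValueError("n_boot must be >= 1000")
    obs_internal, obs_total = _observed_stats(networks, special)
    rng = np.random.default_rng(
        np.random.SeedSequence([seed & 0x7FFFFFFF, zlib.crc32(b"netboot")])
    )
    uni = np.array(universe, dtype=object)
    special_mask = np.array([u in special for u in universe])
    shapes = []
    for net in networks:
        nodes = sorted(net.nodes)
        internal_pos = np.array([n in net.internal for n in nodes])
        shapes.append((len(nodes), internal_pos))
    ge_internal = 0
    ge_total = 0
    for _ in range(n_boot):
        rep_internal = 0
        rep_total = 0
        for size, internal_pos in shapes:
            draw = rng.choice(len(uni), size=size, replace=False)
            is_special = special_mask[draw]
            rep_total += int(is_special.sum())
            if is_special[internal_pos].any():
                rep_internal += 1
        ge_internal += rep_internal >= obs_internal
        ge_total += rep_total >= obs_total
    return {
        "observed_internal": float(obs_internal),
        "observed_total": float(obs_total),
        "p_internal": (1 + ge_internal) / (n_boot + 1),
        "p_total": (1 + ge_total) / (n_boot + 1),
    }
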