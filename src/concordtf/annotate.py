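"""Term enrichment of target-gene sets and set-overlap significance.

Terms come from a user-supplied map (GMT or two-column TSV); enrichment
is the one-sided Fisher exact test of a term's share among the targets
against its share of the genome, with Benjamini-Hochberg control at
q < 0.1 by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from . import stats

__all__ = ["TermMap", "read_gmt", "read_term_tsv", "enrich_terms", "overlap_significance"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TermMap:
    """term id -> gene set, over a fixed genome."""

    terms: dict[str, frozenset]
    genome: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        genome = self.genome or frozenset().union(*self.terms.values())
        object.__setattr__(self, "genome", frozenset(genome))
        for term, genes in self.terms.items():
            if not genes:
                raise ValueError(f"term {term} has no genes")
            if not genes <= self.genome:
                raise ValueError(f"term {term} contains genes outside the genome")

    @property
    def genome_size(self) -> int:
        return len(self.genome)


def read_gmt(path, genome: Iterable | None = None) -> TermMap:
    """Read a GMT file (term, description, genes...)."""
    terms = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            terms[parts[0]] = frozenset(g for g in parts[2:] if g)
    return TermMap(terms=terms, genome=frozenset(genome or ()))


def read_term_tsv(path, genome: Iterable | None = None) -> TermMap:
    """Read a two-column (term, gene) TSV, header optional."""
    df = pd.read_csv(path, sep="\t", header=None, names=["term", "gene"], comment="#")
    if df.iloc[0].tolist() == ["term", "gene"]:
        df = df.iloc[1:]
    terms = {
        t: frozenset(sub["gene"]) for t, sub in df.groupby("term")
    }
    return TermMap(terms=terms, genome=frozenset(genome or ()))


def enrich_terms(
    target_genes: Iterable, term_map: TermMap, q_cutoff: float = 0.1
) -> pd.DataFrame:
    """One-sided Fisher enrichment of every term among the targets.

    Returns one row per term (term, k, n_targets, K, N, p, q,
    significant), sorted by p.  Targets must lie inside the genome.
    """
    targets = frozenset(target_genes)
    if not targets:
        logger.warning("empty target set: no enrichment computed")
        return pd.DataFrame(
            columns=["term", "k", "n_targets", "K", "N", "p", "q", "significant"]
        )
    if not targets <= term_map.genome:
        raise ValueError("target genes must be a subset of the genome")
    N = term_map.genome_size
    rows = []
    for term in sorted(term_map.terms):
        genes = term_map.terms[term]
        k = len(targets & genes)
        p = stats.fisher_enrichment(k, len(targets), len(genes), N)
        rows.append({"term": term, "k": k, "n_targets": len(targets),
                     "K": len(genes), "N": N, "p": p})
    out = pd.DataFrame(rows)
    out["q"] = stats.bh_qvalues(out["p"].to_numpy())
    out["significant"] = out["q"] < q_cutoff
    return out.sort_values(["p", "term"]).reset_index(drop=True)


def overlap_significance(set_a: Iterable, set_b: Iterable, universe: Iterable) -> float:
    """Hypergeometric tail probability of the observed overlap of two sets
    drawn from the given universe; symmetric in its two sets."""
    a, b, u = frozenset(set_a), frozenset(set_b), frozenset(universe)
    if not (a <= u and b <= u):
        raise ValueError("sets must be subsets of the universe")
    return stats.hypergeom_overlap_pvalue(
        stats.HypergeomOverlap(c=len(a & b), N=len(u), S1=len(a), S2=len(b))
    )
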