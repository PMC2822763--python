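"""Promoter FASTA IO and shuffled background construction.

Backgrounds are built by shuffling each promoter against itself, either
as a complete permutation of its letters or as a dinucleotide-preserving
(Altschul-Erickson Eulerian-path) shuffle.  Per-promoter shuffles are
preferable to intergenic or exonic backgrounds, whose base composition is
systematically biased relative to promoters.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "PromoterRecord",
    "BackgroundRecord",
    "read_promoters",
    "write_promoters",
    "shuffle_complete",
    "shuffle_dinucleotide",
    "make_background_set",
]

logger = logging.getLogger(__name__)

VALID_LETTERS = frozenset("ACGTN")


@dataclass(frozen=True)
class PromoterRecord:
    """A 5'->3' upstream promoter; the TSS sits just right of the last base.

    Coordinates are 0-based, half-open throughout the package.
    """

    gene_id: str
    species: str
    sequence: str


@dataclass(frozen=True)
class BackgroundRecord:
    """One shuffled replicate of a source promoter."""

    gene_id: str
    species: str
    mode: str  # "complete" | "dinucleotide"
    replicate: int
    sequence: str


def read_promoters(fasta_path, species: str) -> list[PromoterRecord]:
    """Read a promoter FASTA; headers are gene identifiers."""
    records: list[PromoterRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate gene id in {fasta_path}: {rec.id}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        bad = set(seq) - VALID_LETTERS
        if bad:
            raise ValueError(
                f"non-ACGTN characters {sorted(bad)} in record {rec.id} of {fasta_path}"
            )
        records.append(PromoterRecord(gene_id=rec.id, species=species, sequence=seq))
    if not records:
        logger.warning("no records read from %s", fasta_path)
    return records


def write_promoters(records: Iterable[PromoterRecord | BackgroundRecord], path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(r.sequence), id=r.gene_id, description="") for r in records),
        str(path),
        "fasta",
    )


def _substream(seed: int, *tokens) -> np.random.Generator:
    """Named RNG substream: stable across runs and iteration order."""
    crc = zlib.crc32("\x1f".join(str(t) for t in tokens).encode())
    return np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, crc]))


def shuffle_complete(sequence: str, seed: int = 0, rng=None) -> str:
    """Uniform random permutation of the letters; composition preserved."""
    if not sequence:
        raise ValueError("empty sequence")
    rng = rng if rng is not None else np.random.default_rng(seed)
    arr = np.frombuffer(sequence.encode(), dtype="S1")
    return b"".join(rng.permutation(arr)).decode()


def shuffle_dinucleotide(sequence: str, seed: int = 0, rng=None) -> str:
    """Dinucleotide-preserving shuffle (Altschul-Erickson).

    Treats the sequence as an Eulerian walk on the letter multigraph and
    samples a new walk with identical edge (dinucleotide) counts; the first
    and last letters are fixed.
    """
    if len(sequence) < 2:
        raise ValueError("need length >= 2 for a dinucleotide shuffle")
    rng = rng if rng is not None else np.random.default_rng(seed)
    letters = sorted(set(sequence))
    idx = {c: i for i, c in enumerate(letters)}
    k = len(letters)
    # adjacency: for each source letter, multiset of target letter indices
    adj: list[list[int]] = [[] for _ in range(k)]
    for a, b in zip(sequence, sequence[1:]):
        adj[idx[a]].append(idx[b])
    first, last = idx[sequence[0]], idx[sequence[-1]]

    # Altschul-Erickson: choose a random last edge from every vertex except
    # the walk's end; accept if those edges form a tree oriented toward the
    # end vertex, then shuffle the remaining edges freely.
    while True:
        last_edge = [-1] * k
        for v in range(k):
            if v != last and adj[v]:
                last_edge[v] = adj[v][rng.integers(len(adj[v]))]
        ok = True
        for v in range(k):
            if v == last or not adj[v]:
                continue
            # walk toward `last` via chosen last-edges; must reach it
            seen = set()
            u = v
            while u != last:
                if u in seen or last_edge[u] == -1:
                    ok = False
                    break
                seen.add(u)
                u = last_edge[u]
            if not ok:
                break
        if ok:
            break

    remaining: list[list[int]] = []
    for v in range(k):
        pool = list(adj[v])
        if last_edge[v] != -1:
            pool.remove(last_edge[v])
        rng.shuffle(pool)
        if last_edge[v] != -1:
            pool.append(last_edge[v])
        remaining.append(pool[::-1])  # pop() from the end = next edge

    out = [sequence[0]]
    u = first
    for _ in range(len(sequence) - 1):
        v = remaining[u].pop()
        out.append(letters[v])
        u = v
    return "".join(out)


_SHUFFLERS = {"complete": shuffle_complete, "dinucleotide": shuffle_dinucleotide}


def make_background_set(
    promoters: Sequence[PromoterRecord],
    mode: str = "complete",
    n_replicates: int = 1,
    seed: int = 0,
) -> list[BackgroundRecord]:
    """Shuffle every promoter ``n_replicates`` times.

    Each shuffle is seeded by (seed, gene_id, replicate), so a record's
    backgrounds do not depend on the order promoters are supplied in.
    """
    if mode not in _SHUFFLERS:
        raise ValueError(f"unknown shuffle mode {mode!r}; use complete|dinucleotide")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    shuffler = _SHUFFLERS[mode]
    out = []
    for rec in promoters:
        for rep in range(n_replicates):
            rng = _substream(seed, "shuffle", mode, rec.species, rec.gene_id, rep)
            out.append(
                BackgroundRecord(
                    gene_id=rec.gene_id,
                    species=rec.species,
                    mode=mode,
                    replicate=rep,
                    sequence=shuffler(rec.sequence, rng=rng),
                )
            )
    return out
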