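"""Synthetic two-species promoter studies with planted regulatory signal.

The generator emulates the statistical shape of a comparative promoter
screen: a library of order-10^2 frequency matrices, per-tissue lists of a
few hundred genes plus a large housekeeping list, 1 kb orthologous
promoter pairs, and planted, distance-constrained, cross-species
conserved binding-site pairs and 3-site combinations.  Unplanted sequence
is i.i.d. (optionally first-order Markov); the second species' promoter
is a per-base diverged copy of the first, with conserved planted sites
copied exactly so that order and orientation survive.

Planted sites are sampled from their own matrix and re-drawn until they
score clearly above the matrix's calibrated detection threshold: the
planted signal represents functional (strong) sites, and the pipeline's
recall on it is then a property of the analysis, not of site strength.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .pwm import ALPHABET, PWM, calibrate_threshold, score_window, write_pwm_library
from .sequences import PromoterRecord, write_promoters

__all__ = [
    "PlantSpec",
    "TripletSpec",
    "StudyConfig",
    "GroundTruth",
    "StudyData",
    "PlantingError",
    "generate_pwm_library",
    "generate_study",
    "default_study_config",
    "write_study",
]

HOUSEKEEPING = "housekeeping"


class PlantingError(RuntimeError):
    """A planted arrangement could not be placed without collision."""


@dataclass(frozen=True)
class PlantSpec:
    """One planted, distance-constrained TF pair.

    ``tissues=None`` plants in every tissue list; ``housekeeping=True``
    additionally plants in the housekeeping list (a pair planted in both
    emulates a ubiquitously acting pair that the housekeeping subtraction
    is meant to remove).
    """

    pwm_a: str
    pwm_b: str
    gap_max: int = 60
    gene_fraction: float = 0.3
    conserve_fraction: float = 0.9
    tissues: tuple[str, ...] | None = None
    housekeeping: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.gap_max <= 200):
            raise ValueError("gap_max must be in [0, 200] for recoverable pairs")
        for f in (self.gene_fraction, self.conserve_fraction):
            if not (0.0 <= f <= 1.0):
                raise ValueError("fractions must be in [0,1]")

    @property
    def key(self) -> tuple[str, str]:
        return tuple(sorted((self.pwm_a, self.pwm_b)))


@dataclass(frozen=True)
class TripletSpec:
    """A planted 3-site combination A-B-C with B shared between the two
    constituent pairs; carriers get all three sites in promoter order."""

    pwm_a: str
    pwm_shared: str
    pwm_c: str
    tissue: str = ""
    gap_max: int = 60
    n_carriers: int = 30
    conserve_fraction: float = 1.0

    @property
    def key(self) -> tuple[str, str, str]:
        return tuple(sorted((self.pwm_a, self.pwm_shared, self.pwm_c)))

    @property
    def pair_keys(self) -> list[tuple[str, str]]:
        """Pair keys whose co-occurrence the planting induces (both adjacent
        pairs and the flanking pair, which co-occurs within the grid)."""
        return sorted(
            {
                tuple(sorted((self.pwm_a, self.pwm_shared))),
                tuple(sorted((self.pwm_shared, self.pwm_c))),
                tuple(sorted((self.pwm_a, self.pwm_c))),
            }
        )


@dataclass(frozen=True)
class StudyConfig:
    n_pwms: int = 40
    pwm_length_range: tuple[int, int] = (14, 18)
    ic_target: float = 1.9  # bits per column
    n_tissues: int = 4
    genes_per_tissue: int = 250
    n_housekeeping: int = 900
    promoter_length: int = 1000
    planted_pairs: tuple[PlantSpec, ...] = ()
    planted_triplets: tuple[TripletSpec, ...] = ()
    ortholog_divergence: float = 0.5
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    markov_transition: tuple | None = None  # optional 4x4 first-order background
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pwms < 2 or self.pwm_length_range[0] < 6:
            raise ValueError("need >= 2 PWMs of length >= 6")
        if min(self.n_tissues, self.genes_per_tissue, self.n_housekeeping) <= 0:
            raise ValueError("all counts must be positive")
        max_len = self.pwm_length_range[1]
        max_gap = max(
            [s.gap_max for s in self.planted_pairs]
            + [2 * t.gap_max + max_len for t in self.planted_triplets]
            + [0]
        )
        if self.promoter_length < 2 * max_len + max_gap:
            raise ValueError("promoter_length too short for planted arrangements")
        if not (0.0 <= self.ortholog_divergence <= 1.0):
            raise ValueError("ortholog_divergence must be in [0,1]")

    @property
    def tissue_names(self) -> list[str]:
        return [f"tissue{t}" for t in range(self.n_tissues)]


@dataclass
class GroundTruth:
    """What was planted where, in both species."""

    # gene-list name (tissue or "housekeeping") -> sorted planted pair keys
    pair_keys: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    triplet_keys: dict[str, list[tuple[str, str, str]]] = field(default_factory=dict)
    # species -> gene -> list of {pwm,start,end,strand,kind,list}
    sites: dict[str, dict[str, list[dict]]] = field(default_factory=dict)
    # (list name, pair key) -> carrier genes / conserved carrier genes
    carriers: dict[str, list[str]] = field(default_factory=dict)
    # list name -> every pair key whose sites co-occur (gap <= 200) in >= 10
    # genes of the list in BOTH species, whether planted as a pair or arising
    # as a composite of different planted arrangements in the same promoters
    induced_pairs: dict[str, list[tuple[str, str]]] = field(default_factory=dict)

    def signal_keys(self, list_name: str) -> set[tuple[str, str]]:
        """All pair keys carrying genuine planted co-occurrence signal in a
        gene list: the intended planted keys plus the induced composites."""
        return set(map(tuple, self.pair_keys.get(list_name, []))) | set(
            map(tuple, self.induced_pairs.get(list_name, []))
        )

    def to_dict(self) -> dict:
        return {
            "pair_keys": {k: [list(p) for p in v] for k, v in self.pair_keys.items()},
            "triplet_keys": {
                k: [list(p) for p in v] for k, v in self.triplet_keys.items()
            },
            "sites": self.sites,
            "carriers": self.carriers,
            "induced_pairs": {
                k: [list(p) for p in v] for k, v in self.induced_pairs.items()
            },
        }


@dataclass
class StudyData:
    config: StudyConfig
    library: list[PWM]
    promoters: dict[str, list[PromoterRecord]]  # species -> records
    ortholog_map: pd.DataFrame  # columns: human, mouse
    gene_lists: dict[str, list[str]]  # tissue / "housekeeping" -> human gene ids
    truth: GroundTruth


def _rng(seed: int, *tokens) -> np.random.Generator:
    crc = zlib.crc32("\x1f".join(str(t) for t in tokens).encode())
    return np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, crc]))


# -- PWM library --------------------------------------------------------

_C_GRID = np.linspace(0.2501, 1.0, 2000)
_IC_GRID = (
    2.0
    + _C_GRID * np.log2(_C_GRID)
    + (1 - _C_GRID) * np.log2(np.maximum((1 - _C_GRID) / 3, 1e-300))
)


def _consensus_prob(ic_bits: float) -> float:
    """Consensus-letter frequency whose column reaches ``ic_bits`` of
    information (remaining mass spread evenly on the other 3 letters)."""
    return float(np.interp(ic_bits, _IC_GRID, _C_GRID))


def generate_pwm_library(
    n: int,
    length_range: tuple[int, int] = (14, 18),
    ic_target: float = 1.9,
    seed: int = 0,
) -> list[PWM]:
    """n distinct frequency matrices with mean column information near
    ``ic_target`` bits; deterministic per seed."""
    if n < 2 or length_range[0] < 6:
        raise ValueError("need n >= 2 and lengths >= 6")
    if not (0.0 < ic_target <= 2.0):
        raise ValueError("ic_target must be in (0, 2] bits for a 4-letter alphabet")
    rng = _rng(seed, "pwmlib")
    library: list[PWM] = []
    consensi: set[str] = set()
    attempts = 0
    while len(library) < n:
        attempts += 1
        if attempts > 50 * n:
            raise RuntimeError("could not generate distinct matrices")
        L = int(rng.integers(length_range[0], length_range[1] + 1))
        col_ic = np.clip(rng.normal(ic_target, 0.05 * ic_target, L), 0.05, 2.0)
        if ic_target >= 2.0:
            col_ic[:] = 2.0
        mat = np.zeros((L, 4))
        for i in range(L):
            c = _consensus_prob(float(col_ic[i]))
            best = int(rng.integers(4))
            mat[i] = (1 - c) / 3
            mat[i, best] = c
        pwm = PWM(id=f"tmp{len(library)}", matrix=mat)
        if pwm.consensus in consensi:
            continue
        consensi.add(pwm.consensus)
        library.append(pwm)
    # canonical order: most informative matrix first, ids follow rank
    library.sort(key=lambda p: (-float(p.information.sum()), p.consensus))
    return [
        dataclasses.replace(p, id=f"M{i:03d}", name=f"TF{i:03d}")
        for i, p in enumerate(library)
    ]


def _sample_site(pwm: PWM, rng: np.random.Generator, min_score: float) -> str:
    """Sample an L-mer from the matrix columns, re-drawing (up to 60 times)
    until it scores at least ``min_score``; returns the best draw seen."""
    best, best_score = "", -1.0
    for _ in range(60):
        codes = [int(rng.choice(4, p=pwm.matrix[i])) for i in range(pwm.length)]
        site = "".join(ALPHABET[c] for c in codes)
        s = score_window(pwm, site)
        if s >= min_score:
            return site
        if s > best_score:
            best, best_score = site, s
    return best


_COMPL = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMPL)[::-1]


# -- study generation ---------------------------------------------------


def default_study_config(seed: int = 0) -> StudyConfig:
    """The standard desk-scale study: 40 matrices, 4 tissues x 250 genes
    plus 900 housekeeping orthologs, 5 planted conserved tissue pairs
    (gap <= 60, gene fraction 0.3, conservation 0.9), 2 ubiquitous pairs
    planted in the housekeeping list and, at a lower fraction, in every
    tissue, and one fully conserved triplet (M000-M001-M002, 30 carriers)
    whose constituent pairs are two of the planted tissue pairs.

    Planted modules use the most information-rich matrices of the library
    (ids follow the library's information ranking); carrier sets within a
    gene list are disjoint — a promoter hosts at most one planted module.
    """
    tissues = tuple(f"tissue{t}" for t in range(4))
    pairs = (
        # the triplet's two adjacent pairs live in tissue0
        PlantSpec("M000", "M001", tissues=("tissue0",)),
        PlantSpec("M001", "M002", tissues=("tissue0",)),
        PlantSpec("M003", "M004", tissues=("tissue1",)),
        PlantSpec("M005", "M005", tissues=("tissue2",)),  # homotypic
        PlantSpec("M006", "M007", tissues=("tissue3",)),
        # ubiquitous pairs: strong in housekeeping, present in all tissues
        PlantSpec("M008", "M009", gene_fraction=0.12,
                  housekeeping=True, tissues=tissues),
        PlantSpec("M010", "M011", gene_fraction=0.12,
                  housekeeping=True, tissues=tissues),
    )
    triplets = (
        TripletSpec("M000", "M001", "M002", tissue="tissue0", n_carriers=30),
    )
    return StudyConfig(planted_pairs=pairs, planted_triplets=triplets, seed=seed)


def _gen_background(
    n_bases: int, cfg: StudyConfig, rng: np.random.Generator
) -> np.ndarray:
    comp = np.asarray(cfg.base_composition, dtype=float)
    comp = comp / comp.sum()
    if cfg.markov_transition is None:
        return rng.choice(4, size=n_bases, p=comp)
    trans = np.asarray(cfg.markov_transition, dtype=float)
    trans = trans / trans.sum(axis=1, keepdims=True)
    out = np.empty(n_bases, dtype=np.int64)
    out[0] = rng.choice(4, p=comp)
    u = rng.random(n_bases)
    cum = np.cumsum(trans, axis=1)
    for i in range(1, n_bases):
        out[i] = np.searchsorted(cum[out[i - 1]], u[i])
    return out


class _Promoter:
    """Mutable promoter under construction, with collision tracking."""

    def __init__(self, seq_codes: np.ndarray):
        self.codes = seq_codes
        self.occupied: list[tuple[int, int]] = []

    def free(self, start: int, end: int) -> bool:
        return all(end <= s or start >= e for s, e in self.occupied)

    def plant(self, start: int, site: str) -> None:
        codes = np.array([ALPHABET.index(c) for c in site])
        self.codes[start : start + len(site)] = codes
        self.occupied.append((start, start + len(site)))


def _place_arrangement(
    prom: _Promoter,
    sites: list[str],
    gaps: list[int],
    rng: np.random.Generator,
    retries: int = 40,
) -> list[int] | None:
    """Place consecutive sites separated by the given gaps; returns start
    coordinates or None when no collision-free placement was found."""
    span = sum(len(s) for s in sites) + sum(gaps)
    limit = len(prom.codes) - span
    if limit < 0:
        raise PlantingError("arrangement longer than promoter")
    for _ in range(retries):
        start = int(rng.integers(0, limit + 1))
        starts = []
        pos = start
        for site, gap in zip(sites, gaps + [0]):
            starts.append(pos)
            pos += len(site) + gap
        if all(prom.free(s, s + len(site)) for s, site in zip(starts, sites)):
            return starts
    return None


def generate_study(config: StudyConfig) -> StudyData:
    """Generate the full paired-corpus study described by ``config``."""
    seed = config.seed
    library = generate_pwm_library(
        config.n_pwms, config.pwm_length_range, config.ic_target, seed=seed
    )
    by_id = {p.id: p for p in library}
    # thresholds used only to reject weak planted-site draws
    thr = {
        p.id: calibrate_threshold(
            p, config.base_composition, seed=zlib.crc32(p.id.encode()) ^ (seed & 0xFFFF)
        )
        for p in library
    }
    min_score = {k: min(v + 0.02, 0.97) for k, v in thr.items()}

    gene_lists: dict[str, list[str]] = {}
    for t, name in enumerate(config.tissue_names):
        gene_lists[name] = [
            f"g{t}_{i:04d}" for i in range(config.genes_per_tissue)
        ]
    gene_lists[HOUSEKEEPING] = [f"hk_{i:04d}" for i in range(config.n_housekeeping)]
    all_genes = [g for lst in gene_lists.values() for g in lst]

    # Per-species backgrounds: the mouse promoter is a per-base diverged
    # copy of the human background, built BEFORE planting; conserved
    # arrangements are then planted independently in each species, at an
    # independent location but with the same letters, order, orientation
    # and gap.  Conservation of a pair is a property of the arrangement,
    # not of its promoter coordinate.
    proms: dict[str, dict[str, _Promoter]] = {}
    for g in all_genes:
        hcodes = _gen_background(config.promoter_length, config, _rng(seed, "seq", g))
        rng = _rng(seed, "diverge", g)
        mcodes = hcodes.copy()
        mutate = rng.random(len(mcodes)) < config.ortholog_divergence
        shift = rng.integers(1, 4, size=len(mcodes))
        mcodes[mutate] = (mcodes[mutate] + shift[mutate]) % 4
        proms[g] = {"human": _Promoter(hcodes), "mouse": _Promoter(mcodes)}

    truth = GroundTruth(sites={"human": {}, "mouse": {}})

    def record(species: str, gene: str, pwm_id: str, start: int, length: int,
               strand: str, kind: str, list_name: str) -> None:
        truth.sites.setdefault(species, {}).setdefault(gene, []).append(
            {
                "pwm": pwm_id, "start": int(start), "end": int(start + length),
                "strand": strand, "kind": kind, "list": list_name,
            }
        )

    # ---- assign planted modules to disjoint carrier sets ----
    # A promoter hosts at most one planted module: within each gene list,
    # triplet carriers are drawn first as exact-size samples, and the
    # remaining genes are partitioned among the pair specs by a single
    # uniform draw per gene split into gene-fraction intervals, so each
    # spec's carrier count stays (marginally) Binomial(n, f).  Disjoint
    # carriers keep different planted modules from composing spurious
    # cross-module pairs inside one promoter.
    pair_targets: dict[str, list[int]] = {}
    for si, spec in enumerate(config.planted_pairs):
        targets: list[str] = []
        if spec.tissues is not None:
            targets.extend(spec.tissues)
        elif not spec.housekeeping:
            targets.extend(config.tissue_names)
        if spec.housekeeping:
            targets.append(HOUSEKEEPING)
        for list_name in targets:
            pair_targets.setdefault(list_name, []).append(si)
            truth.pair_keys.setdefault(list_name, [])
            if spec.key not in truth.pair_keys[list_name]:
                truth.pair_keys[list_name].append(spec.key)

    triplet_targets: dict[str, list[int]] = {}
    for ti, tspec in enumerate(config.planted_triplets):
        tissue = tspec.tissue or config.tissue_names[0]
        triplet_targets.setdefault(tissue, []).append(ti)
        truth.triplet_keys.setdefault(tissue, []).append(tspec.key)
        truth.pair_keys.setdefault(tissue, [])
        for pk in tspec.pair_keys:
            if pk not in truth.pair_keys[tissue]:
                truth.pair_keys[tissue].append(pk)

    for list_name in set(pair_targets) | set(triplet_targets):
        load = sum(
            config.planted_pairs[si].gene_fraction
            for si in pair_targets.get(list_name, [])
        ) + sum(
            config.planted_triplets[ti].n_carriers / len(gene_lists[list_name])
            for ti in triplet_targets.get(list_name, [])
        )
        if load > 1.0 + 1e-9:
            raise PlantingError(
                f"planted gene fractions for list {list_name!r} sum to {load:.2f} > 1"
            )

    def plant_pair(spec: PlantSpec, g: str, list_name: str, rng) -> bool:
        """Plant one pair arrangement in gene g; returns the conserved flag."""
        pa, pb = by_id[spec.pwm_a], by_id[spec.pwm_b]
        if rng.random() < 0.5:  # either order along the promoter
            pa, pb = pb, pa
        site_a = _sample_site(pa, rng, min_score[pa.id])
        site_b = _sample_site(pb, rng, min_score[pb.id])
        strand_a = "+" if rng.random() < 0.5 else "-"
        strand_b = "+" if rng.random() < 0.5 else "-"
        gap = int(rng.integers(0, spec.gap_max + 1))
        conserved = bool(rng.random() < spec.conserve_fraction)
        seq_a = site_a if strand_a == "+" else _revcomp(site_a)
        seq_b = site_b if strand_b == "+" else _revcomp(site_b)
        for sp in ["human", "mouse"] if conserved else ["human"]:
            starts = _place_arrangement(proms[g][sp], [seq_a, seq_b], [gap], rng)
            if starts is None:
                raise PlantingError(f"no room for pair {spec.key} in {g} ({sp})")
            for pwm, st, sd, sq in (
                (pa, starts[0], strand_a, seq_a),
                (pb, starts[1], strand_b, seq_b),
            ):
                proms[g][sp].plant(st, sq)
                record(sp, g, pwm.id, st, pwm.length, sd, "pair", list_name)
        return conserved

    def plant_triplet(tspec: TripletSpec, g: str, list_name: str, rng) -> None:
        pwms = [by_id[tspec.pwm_a], by_id[tspec.pwm_shared], by_id[tspec.pwm_c]]
        sites = [_sample_site(p, rng, min_score[p.id]) for p in pwms]
        strands = ["+" if rng.random() < 0.5 else "-" for _ in range(3)]
        seqs = [s if sd == "+" else _revcomp(s) for s, sd in zip(sites, strands)]
        gaps = [int(rng.integers(0, tspec.gap_max + 1)) for _ in range(2)]
        conserved = bool(rng.random() < tspec.conserve_fraction)
        for sp in ["human", "mouse"] if conserved else ["human"]:
            starts = _place_arrangement(proms[g][sp], seqs, gaps, rng)
            if starts is None:
                raise PlantingError(f"no room for triplet {tspec.key} in {g} ({sp})")
            for pwm, st, sd, sq in zip(pwms, starts, strands, seqs):
                proms[g][sp].plant(st, sq)
                record(sp, g, pwm.id, st, pwm.length, sd, "triplet", list_name)

    for list_name, genes in gene_lists.items():
        remaining = list(genes)
        for ti in triplet_targets.get(list_name, []):
            tspec = config.planted_triplets[ti]
            rng = _rng(seed, "planttriplet", ti, list_name)
            carriers = sorted(rng.choice(remaining, size=tspec.n_carriers, replace=False))
            taken = set(carriers)
            remaining = [g for g in remaining if g not in taken]
            for g in carriers:
                plant_triplet(tspec, g, list_name, rng)
            truth.carriers[f"{list_name}|triplet|{':'.join(tspec.key)}"] = carriers
        spec_ids = pair_targets.get(list_name, [])
        if not spec_ids:
            continue
        cum = np.cumsum(
            [config.planted_pairs[si].gene_fraction for si in spec_ids]
        )
        assign_rng = _rng(seed, "assign", list_name)
        carriers_of: dict[int, list[str]] = {si: [] for si in spec_ids}
        for g in remaining:
            k = int(np.searchsorted(cum, assign_rng.random(), side="right"))
            if k < len(spec_ids):
                carriers_of[spec_ids[k]].append(g)
        for si in spec_ids:
            spec = config.planted_pairs[si]
            rng = _rng(seed, "plantpair", si, list_name)
            carrier_genes, conserved_genes = [], []
            for g in carriers_of[si]:
                conserved = plant_pair(spec, g, list_name, rng)
                carrier_genes.append(g)
                if conserved:
                    conserved_genes.append(g)
            key = f"{spec.key[0]}:{spec.key[1]}"
            truth.carriers[f"{list_name}|{key}"] = carrier_genes
            truth.carriers[f"{list_name}|{key}|conserved"] = conserved_genes

    # ---- induced pair keys from the planted site records ----
    def _cooccurring_keys(sp: str, gene: str, max_gap: int = 200) -> set:
        sites = truth.sites.get(sp, {}).get(gene, [])
        keys = set()
        for i in range(len(sites)):
            for j in range(i + 1, len(sites)):
                a, b = sites[i], sites[j]
                gap = max(b["start"] - a["end"], a["start"] - b["end"])
                if 0 <= gap <= max_gap:
                    keys.add(tuple(sorted((a["pwm"], b["pwm"]))))
        return keys

    min_induced_genes = 10
    for list_name, genes in gene_lists.items():
        gene_keys_h = {g: _cooccurring_keys("human", g) for g in genes}
        gene_keys_m = {g: _cooccurring_keys("mouse", g) for g in genes}
        tally: dict[tuple, int] = {}
        for g in genes:
            for key in gene_keys_h[g] & gene_keys_m[g]:
                tally[key] = tally.get(key, 0) + 1
        truth.induced_pairs[list_name] = sorted(
            k for k, n in tally.items() if n >= min_induced_genes
        )

    # ---- materialise the two corpora ----
    human_records, mouse_records, orth_rows = [], [], []
    for g in all_genes:
        hseq = "".join(ALPHABET[c] for c in proms[g]["human"].codes)
        mseq = "".join(ALPHABET[c] for c in proms[g]["mouse"].codes)
        hid, mid = f"hs_{g}", f"mm_{g}"
        human_records.append(PromoterRecord(hid, "human", hseq))
        mouse_records.append(PromoterRecord(mid, "mouse", mseq))
        orth_rows.append((hid, mid))

    # rename truth genes/lists to species-prefixed ids
    truth.sites = {
        "human": {f"hs_{g}": v for g, v in truth.sites.get("human", {}).items()},
        "mouse": {f"mm_{g}": v for g, v in truth.sites.get("mouse", {}).items()},
    }
    truth.carriers = {
        k: [f"hs_{g}" for g in v] for k, v in truth.carriers.items()
    }
    gene_lists = {k: [f"hs_{g}" for g in v] for k, v in gene_lists.items()}

    return StudyData(
        config=config,
        library=library,
        promoters={"human": human_records, "mouse": mouse_records},
        ortholog_map=pd.DataFrame(orth_rows, columns=["human", "mouse"]),
        gene_lists=gene_lists,
        truth=truth,
    )


def write_study(study: StudyData, outdir) -> dict[str, Path]:
    """Write the study in plain-text exchange formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "human_fasta": outdir / "human_promoters.fasta",
        "mouse_fasta": outdir / "mouse_promoters.fasta",
        "orthologs": outdir / "orthologs.tsv",
        "gene_lists": outdir / "gene_lists.tsv",
        "pwms": outdir / "pwms.jaspar",
        "truth": outdir / "ground_truth.json",
    }
    write_promoters(study.promoters["human"], paths["human_fasta"])
    write_promoters(study.promoters["mouse"], paths["mouse_fasta"])
    study.ortholog_map.to_csv(paths["orthologs"], sep="\t", index=False)
    rows = [
        {"list": name, "gene": g}
        for name, genes in study.gene_lists.items()
        for g in genes
    ]
    pd.DataFrame(rows).to_csv(paths["gene_lists"], sep="\t", index=False)
    write_pwm_library(study.library, paths["pwms"])
    with open(paths["truth"], "w") as fh:
        json.dump(study.truth.to_dict(), fh, indent=1, sort_keys=True)
    return paths
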