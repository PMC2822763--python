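"""End-to-end orchestration: simulate/load -> shuffle -> scan -> pairs ->
housekeeping subtraction -> tissue grouping -> networks -> triplets.

`run_study` is the library entry point: it takes an in-memory
:class:`~concordtf.simulate.StudyData` (or equivalently loaded inputs)
and returns every stage's result.  `run_pipeline` is the file-based
variant behind the CLI: one YAML config, TSV/JSON stage outputs and a
manifest recording the config hash, seed and per-stage row counts.

All randomness flows from one global seed through named substreams
(stage, entity), so per-entity results are independent of iteration
order.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import networks as net
from . import pairs as prs
from . import tissues as tis
from . import triplets as tri
from .pwm import PWM, calibrate_threshold, read_pwm_library, scan
from .sequences import make_background_set, read_promoters
from .simulate import (
    HOUSEKEEPING,
    StudyConfig,
    StudyData,
    default_study_config,
    generate_study,
    write_study,
)

__all__ = ["RunParams", "StudyResults", "run_study", "run_pipeline", "StageDependencyError"]


class StageDependencyError(RuntimeError):
    """An upstream stage output required by this stage is missing."""


@dataclass(frozen=True)
class RunParams:
    grid: tuple[int, ...] = prs.DEFAULT_GRID
    q_pairs: float = 0.05
    q_terms: float = 0.1
    min_tissue_fraction: float = 0.5
    n_perm: int = 10_000
    n_boot: int = 10_000
    shuffle_mode: str = "complete"
    n_replicates: int = 1
    calib_samples: int = 1000
    overlap_min: float = 0.10
    overlap_scope: str = "all"
    min_support: int = 10
    n_groups: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for cut in (self.q_pairs, self.q_terms, self.min_tissue_fraction):
            if not (0.0 < cut < 1.0):
                raise ValueError("cutoffs must lie in (0,1)")
        grid = tuple(self.grid)
        if not grid or grid[0] <= 0 or any(b <= a for a, b in zip(grid, grid[1:])):
            raise ValueError("grid must be strictly increasing and positive")


@dataclass
class StudyResults:
    params: RunParams
    thresholds: dict[str, float]
    base_composition: np.ndarray
    hits_real: dict[str, pd.DataFrame]
    hits_bg: dict[str, pd.DataFrame]
    pair_calls: dict[str, pd.DataFrame]  # gene-list name -> call table
    called_sets: dict[str, set]  # gene-list name -> called pair keys
    housekeeping_pairs: set
    tissue_pairs: dict[str, set]  # post housekeeping subtraction
    removed_fraction: dict[str, float]
    unique_pairs: dict[str, set]
    triplet_calls: dict[str, pd.DataFrame]
    counts: dict[str, dict] = field(default_factory=dict)


def _sub_seed(seed: int, *tokens) -> int:
    return (zlib.crc32("\x1f".join(map(str, tokens)).encode()) ^ (seed & 0x7FFFFFFF)) & 0x7FFFFFFF


def corpus_base_composition(promoters) -> np.ndarray:
    """Pooled A,C,G,T frequencies of a promoter corpus (N excluded)."""
    counts = np.zeros(4)
    for rec in promoters:
        for i, b in enumerate("ACGT"):
            counts[i] += rec.sequence.count(b)
    return counts / counts.sum()


def calibrate_library(
    library, base_composition, n_samples: int = 1000, seed: int = 0
) -> list[PWM]:
    """Attach calibrated thresholds (seeded per matrix id)."""
    return [
        dataclasses.replace(
            p,
            threshold=calibrate_threshold(
                p, base_composition, n_samples, seed=_sub_seed(seed, "calib", p.id)
            ),
            background=np.asarray(base_composition, dtype=float),
        )
        for p in library
    ]


def _scan_background(library, promoters, mode, n_replicates, seed, species):
    """Scan shuffled replicates separately so one gene's replicates never
    mix inside a gap table."""
    frames = []
    for rep in range(n_replicates):
        recs = make_background_set(promoters, mode, 1, seed=_sub_seed(seed, "bgrep", rep))
        df = scan(library, recs, species=species)
        df["replicate"] = rep
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def run_study(
    study: StudyData,
    params: RunParams | None = None,
    gene_lists: dict[str, list[str]] | None = None,
) -> StudyResults:
    """Run the complete two-species analysis on one study."""
    params = params or RunParams()
    grid = tuple(params.grid)
    gene_lists = gene_lists or study.gene_lists
    h2m = dict(zip(study.ortholog_map["human"], study.ortholog_map["mouse"]))
    m2h = {v: k for k, v in h2m.items()}

    base = corpus_base_composition(
        study.promoters["human"] + study.promoters["mouse"]
    )
    library = calibrate_library(
        study.library, base, params.calib_samples, seed=params.seed
    )
    thresholds = {p.id: p.threshold for p in library}

    hits_real, hits_bg, gap_real, gap_bg = {}, {}, {}, {}
    for sp in ("human", "mouse"):
        hits_real[sp] = scan(library, study.promoters[sp], species=sp)
        hits_bg[sp] = _scan_background(
            library, study.promoters[sp], params.shuffle_mode,
            params.n_replicates, params.seed, sp,
        )
        gap_real[sp] = prs.pair_gap_table(hits_real[sp], max_gap=grid[-1])
        bg_parts = []
        for rep, sub in hits_bg[sp].groupby("replicate"):
            t = prs.pair_gap_table(sub, max_gap=grid[-1])
            t["replicate"] = rep
            bg_parts.append(t)
        gap_bg[sp] = pd.concat(bg_parts, ignore_index=True)

    pair_calls, called_sets = {}, {}
    for name, genes in gene_lists.items():
        hgenes = set(genes)
        mgenes = {h2m[g] for g in hgenes if g in h2m}
        greal = {
            "human": gap_real["human"][gap_real["human"]["gene"].isin(hgenes)],
            "mouse": gap_real["mouse"][gap_real["mouse"]["gene"].isin(mgenes)],
        }
        gbg = {
            "human": gap_bg["human"][gap_bg["human"]["gene"].isin(hgenes)],
            "mouse": gap_bg["mouse"][gap_bg["mouse"]["gene"].isin(mgenes)],
        }
        profiles = prs.build_pair_profiles(greal, gbg, m2h, grid)
        calls = prs.call_conserved_pairs(
            profiles,
            n_perm=params.n_perm,
            seed=_sub_seed(params.seed, "pairs", name),
            q_cutoff=params.q_pairs,
            overlap_min=params.overlap_min,
            overlap_scope=params.overlap_scope,
        )
        pair_calls[name] = calls
        called_sets[name] = (
            {
                (a, b)
                for a, b, c in zip(calls["pwm_a"], calls["pwm_b"], calls["called"])
                if c
            }
            if not calls.empty
            else set()
        )

    hk_pairs = called_sets.get(HOUSEKEEPING, set())
    tissue_names = [n for n in gene_lists if n != HOUSEKEEPING]
    tissue_pairs, removed = {}, {}
    for t in tissue_names:
        tissue_pairs[t], removed[t] = tis.subtract_housekeeping(
            called_sets[t], hk_pairs
        )
    unique = (
        tis.tissue_unique_pairs(tissue_pairs) if len(tissue_pairs) >= 2 else {}
    )

    triplet_calls = {}
    for t in tissue_names:
        pairs_t = sorted(tissue_pairs[t])
        if not pairs_t:
            triplet_calls[t] = tri.call_triplets([], [], [], len(gene_lists[t]))
            continue
        hgenes = set(gene_lists[t])
        mgenes = {h2m[g] for g in hgenes if g in h2m}
        occ_h = tri.pair_site_occurrences(
            hits_real["human"][hits_real["human"]["gene"].isin(hgenes)],
            pairs_t, max_gap=grid[-1],
        )
        occ_m = tri.pair_site_occurrences(
            hits_real["mouse"][hits_real["mouse"]["gene"].isin(mgenes)],
            pairs_t, max_gap=grid[-1],
        )
        cand_h = tri.compose_triplets(occ_h)
        cand_m = tri.compose_triplets(occ_m)
        conserved = tri.conserved_occurrences(cand_h, cand_m, h2m)
        triplet_calls[t] = tri.call_triplets(
            conserved, cand_h, cand_m, len(gene_lists[t]),
            mouse_to_human=m2h, q_cutoff=params.q_pairs,
            min_support=params.min_support,
        )

    counts = {
        "hits": {sp: int(len(df)) for sp, df in hits_real.items()},
        "called": {n: len(s) for n, s in called_sets.items()},
        "tissue_pairs": {t: len(s) for t, s in tissue_pairs.items()},
        "removed_fraction": {t: round(f, 4) for t, f in removed.items()},
        "triplets_called": {
            t: int(df["called"].sum()) if not df.empty else 0
            for t, df in triplet_calls.items()
        },
    }
    return StudyResults(
        params=params,
        thresholds=thresholds,
        base_composition=base,
        hits_real=hits_real,
        hits_bg=hits_bg,
        pair_calls=pair_calls,
        called_sets=called_sets,
        housekeeping_pairs=hk_pairs,
        tissue_pairs=tissue_pairs,
        removed_fraction=removed,
        unique_pairs=unique,
        triplet_calls=triplet_calls,
        counts=counts,
    )


# -- file-based pipeline (CLI backend) ----------------------------------

STAGES = ["simulate", "shuffle", "scan", "pairs", "tissues", "networks",
          "triplets", "enrich"]


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise StageDependencyError(
            f"stage '{stage}' requires missing upstream output: {path}"
        )
    return path


def run_pipeline(config: dict | str | Path, outdir=None) -> dict:
    """Run every stage from a single YAML-style config; returns the manifest.

    The config needs `outdir`, `seed`, and either `study: default` (or a
    mapping of :class:`StudyConfig` overrides) to simulate inputs, or
    explicit input paths (human_fasta, mouse_fasta, orthologs,
    gene_lists, pwms).  Analysis parameters mirror :class:`RunParams`.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    outdir = Path(outdir or config.get("outdir", "concordtf_run"))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    params = RunParams(
        **{
            k: v
            for k, v in config.items()
            if k in {f.name for f in dataclasses.fields(RunParams)}
        }
    )

    manifest: dict = {
        "config_hash": _config_hash(config),
        "seed": seed,
        "stages": [],
        "counts": {},
    }

    study_cfg = config.get("study", "default")
    if study_cfg is not None:
        if study_cfg == "default":
            scfg = default_study_config(seed=seed)
        else:
            scfg = StudyConfig(seed=seed, **study_cfg)
        study = generate_study(scfg)
        paths = write_study(study, outdir / "inputs")
        manifest["stages"].append("simulate")
        manifest["counts"]["simulate"] = {
            "promoters": len(study.promoters["human"]),
            "pwms": len(study.library),
        }
    else:
        from .simulate import GroundTruth

        inputs = {k: Path(config[k]) for k in
                  ("human_fasta", "mouse_fasta", "orthologs", "gene_lists", "pwms")}
        for k, p in inputs.items():
            _require(p, "load")
        human = read_promoters(inputs["human_fasta"], "human")
        mouse = read_promoters(inputs["mouse_fasta"], "mouse")
        orth = pd.read_csv(inputs["orthologs"], sep="\t")
        gl = pd.read_csv(inputs["gene_lists"], sep="\t")
        library = read_pwm_library(inputs["pwms"], fmt=config.get("pwm_format", "jaspar"))
        study = StudyData(
            config=None,  # type: ignore[arg-type]
            library=library,
            promoters={"human": human, "mouse": mouse},
            ortholog_map=orth,
            gene_lists={t: sorted(sub["gene"]) for t, sub in gl.groupby("list")},
            truth=GroundTruth(),
        )
        manifest["stages"].append("load")

    results = run_study(study, params)
    manifest["stages"] += ["shuffle", "scan", "pairs", "tissues", "triplets"]
    manifest["counts"].update(results.counts)

    for sp, df in results.hits_real.items():
        df.to_csv(outdir / f"hits_{sp}.tsv", sep="\t", index=False)
    for name, df in results.pair_calls.items():
        df.to_csv(outdir / f"pair_calls_{name}.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {"tissue": t, "pwm_a": a, "pwm_b": b}
            for t, s in results.tissue_pairs.items()
            for a, b in sorted(s)
        ],
        columns=["tissue", "pwm_a", "pwm_b"],
    ).to_csv(outdir / "tissue_pairs.tsv", sep="\t", index=False)
    for t, df in results.triplet_calls.items():
        df.to_csv(outdir / f"triplets_{t}.tsv", sep="\t", index=False)

    # tissue grouping + tissue-type pairs + networks
    tissue_sets = results.tissue_pairs
    if len(tissue_sets) >= 2:
        n_groups = params.n_groups or min(2, len(tissue_sets))
        presence = tis.presence_matrix(tissue_sets)
        dist = tis.binary_distance_matrix(presence)
        groups = tis.complete_linkage_clusters(dist, n_groups)
        ttp_rows, net_rows = [], []
        for g in groups:
            if len(g.members) < 2:
                continue
            ttp = tis.tissue_type_pairs(g, tissue_sets, params.min_tissue_fraction)
            ttp_rows += [
                {"group": g.label, "pwm_a": a, "pwm_b": b} for a, b in sorted(ttp)
            ]
            nets_by_tissue = {
                t: net.build_networks(ttp & tissue_sets[t], tissue=t)
                for t in g.members
            }
            for network in net.match_tissue_type_networks(nets_by_tissue, g.members):
                for a, b in sorted(network.edges):
                    net_rows.append(
                        {
                            "group": g.label,
                            "tissues": ",".join(network.tissues),
                            "pwm_a": a,
                            "pwm_b": b,
                        }
                    )
        pd.DataFrame(ttp_rows).to_csv(
            outdir / "tissue_type_pairs.tsv", sep="\t", index=False
        )
        pd.DataFrame(net_rows).to_csv(outdir / "networks.tsv", sep="\t", index=False)
        manifest["stages"].append("networks")
        manifest["counts"]["tissue_type_pairs"] = len(ttp_rows)

    manifest["stages"].append("enrich")  # term enrichment runs only with a term map
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def rerun_triplets(
    outdir,
    ortholog_path,
    gene_lists_path,
    params: RunParams | None = None,
) -> dict[str, pd.DataFrame]:
    """Recompute the triplet stage from saved pair-stage outputs.

    Requires ``hits_human.tsv``, ``hits_mouse.tsv`` and
    ``tissue_pairs.tsv`` in ``outdir``; a missing upstream file raises
    :class:`StageDependencyError` naming it.
    """
    params = params or RunParams()
    outdir = Path(outdir)
    hits = {
        sp: pd.read_csv(_require(outdir / f"hits_{sp}.tsv", "triplets"), sep="\t")
        for sp in ("human", "mouse")
    }
    tp = pd.read_csv(_require(outdir / "tissue_pairs.tsv", "triplets"), sep="\t")
    orth = pd.read_csv(ortholog_path, sep="\t")
    gl = pd.read_csv(gene_lists_path, sep="\t")
    h2m = dict(zip(orth["human"], orth["mouse"]))
    m2h = {v: k for k, v in h2m.items()}
    out = {}
    tissues = sorted(set(gl["list"]) - {HOUSEKEEPING})
    for tissue in tissues:
        sub = tp[tp["tissue"] == tissue]
        hgenes = set(gl[gl["list"] == tissue]["gene"])
        pairs_t = sorted({(a, b) for a, b in zip(sub["pwm_a"], sub["pwm_b"])})
        if not pairs_t:
            out[tissue] = tri.call_triplets([], [], [], len(hgenes))
            out[tissue].to_csv(
                outdir / f"triplets_{tissue}.tsv", sep="\t", index=False
            )
            continue
        mgenes = {h2m[g] for g in hgenes if g in h2m}
        occ_h = tri.pair_site_occurrences(
            hits["human"][hits["human"]["gene"].isin(hgenes)], pairs_t
        )
        occ_m = tri.pair_site_occurrences(
            hits["mouse"][hits["mouse"]["gene"].isin(mgenes)], pairs_t
        )
        cand_h, cand_m = tri.compose_triplets(occ_h), tri.compose_triplets(occ_m)
        conserved = tri.conserved_occurrences(cand_h, cand_m, h2m)
        out[tissue] = tri.call_triplets(
            conserved, cand_h, cand_m, len(hgenes), mouse_to_human=m2h,
            q_cutoff=params.q_pairs, min_support=params.min_support,
        )
        out[tissue].to_csv(outdir / f"triplets_{tissue}.tsv", sep="\t", index=False)
    return out
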