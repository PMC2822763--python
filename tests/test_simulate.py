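"""Synthetic study generator: determinism, planted-site properties and
carrier statistics."""

import dataclasses
import hashlib

import numpy as np
import pytest
from scipy import stats as sps

from concordtf.pairs import enumerate_pair_universe
from concordtf.pwm import calibrate_threshold, score_window
from concordtf.sequences import read_promoters
from concordtf.simulate import (
    PlantSpec,
    StudyConfig,
    generate_pwm_library,
    generate_study,
    write_study,
)
from tests.conftest import tiny_study_config


def file_hashes(paths):
    return {
        k: hashlib.sha256(p.read_bytes()).hexdigest() for k, p in paths.items()
    }


class TestLibrary:
    def test_deterministic_per_seed(self):
        a = generate_pwm_library(12, (8, 12), 1.5, seed=1)
        b = generate_pwm_library(12, (8, 12), 1.5, seed=1)
        assert all(np.array_equal(x.matrix, y.matrix) for x, y in zip(a, b))
        c = generate_pwm_library(12, (8, 12), 1.5, seed=2)
        assert any(not np.array_equal(x.matrix, y.matrix) for x, y in zip(a, c))

    def test_mean_information_near_target(self):
        for target in (1.0, 1.5, 1.9):
            lib = generate_pwm_library(20, (8, 12), target, seed=3)
            mean_bits = np.mean(
                [p.information.sum() / np.log(2) / p.length for p in lib]
            )
            assert abs(mean_bits - target) <= 0.2 * target

    def test_maximum_information_gives_point_mass_columns(self):
        lib = generate_pwm_library(5, (8, 10), 2.0, seed=4)
        for p in lib:
            assert np.allclose(p.matrix.max(axis=1), 1.0)

    def test_library_of_214_spans_published_universe(self):
        lib = generate_pwm_library(214, (8, 10), 1.8, seed=5)
        assert len(enumerate_pair_universe(p.id for p in lib)) == 23005

    def test_ids_ordered_by_information(self):
        lib = generate_pwm_library(15, (8, 14), 1.7, seed=6)
        info = [float(p.information.sum()) for p in lib]
        assert info == sorted(info, reverse=True)
        assert [p.id for p in lib] == [f"M{i:03d}" for i in range(15)]


class TestStudyGeneration:
    def test_regeneration_reproduces_identical_files(self, tmp_path):
        cfg = tiny_study_config(seed=7)
        h1 = file_hashes(write_study(generate_study(cfg), tmp_path / "a"))
        h2 = file_hashes(write_study(generate_study(cfg), tmp_path / "b"))
        assert h1 == h2

    def test_shapes_and_orthology(self, tiny_study):
        cfg = tiny_study.config
        n = cfg.n_tissues * cfg.genes_per_tissue + cfg.n_housekeeping
        assert len(tiny_study.promoters["human"]) == n
        assert len(tiny_study.promoters["mouse"]) == n
        assert len(tiny_study.ortholog_map) == n
        assert all(
            len(r.sequence) == cfg.promoter_length
            for r in tiny_study.promoters["human"]
        )

    def test_planted_sites_score_above_threshold(self, tiny_study):
        by_id = {p.id: p for p in tiny_study.library}
        seqs = {
            sp: {r.gene_id: r.sequence for r in tiny_study.promoters[sp]}
            for sp in ("human", "mouse")
        }
        thr = {
            p.id: calibrate_threshold(p, seed=99) for p in tiny_study.library
        }
        total = passed = 0
        for sp in ("human", "mouse"):
            for gene, sites in tiny_study.truth.sites[sp].items():
                for site in sites:
                    window = seqs[sp][gene][site["start"] : site["end"]]
                    if site["strand"] == "-":
                        window = window.translate(
                            str.maketrans("ACGT", "TGCA")
                        )[::-1]
                    total += 1
                    if score_window(by_id[site["pwm"]], window) >= thr[site["pwm"]]:
                        passed += 1
        assert total > 100
        assert passed / total >= 0.99

    def test_no_planting_leaves_no_ground_truth(self):
        cfg = tiny_study_config(seed=3, planted_pairs=(), planted_triplets=())
        study = generate_study(cfg)
        assert study.truth.sites["human"] == {}
        assert study.truth.pair_keys == {}

    def test_conserved_sites_identical_without_divergence(self, tmp_path):
        cfg = tiny_study_config(seed=5, ortholog_divergence=0.0)
        for spec in cfg.planted_pairs:
            cfg = dataclasses.replace(
                cfg,
                planted_pairs=tuple(
                    dataclasses.replace(s, conserve_fraction=1.0)
                    for s in cfg.planted_pairs
                ),
            )
        study = generate_study(cfg)
        hseq = {r.gene_id: r.sequence for r in study.promoters["human"]}
        mseq = {r.gene_id: r.sequence for r in study.promoters["mouse"]}
        # every human planted site's letters recur identically at the
        # recorded orthologous location
        for gene, sites in study.truth.sites["human"].items():
            mg = "mm_" + gene[3:]
            msites = {
                (s["pwm"], s["strand"]): s
                for s in study.truth.sites["mouse"].get(mg, [])
            }
            for s in sites:
                m = msites.get((s["pwm"], s["strand"]))
                if m is None:
                    continue
                assert (
                    hseq[gene][s["start"] : s["end"]]
                    == mseq[mg][m["start"] : m["end"]]
                )

    def test_carrier_counts_binomial_across_seeds(self):
        # single planted pair, tiny corpus: carrier counts across 50 seeds
        # follow Binomial(n, f) (chi-square goodness of fit, alpha=0.01)
        n, f = 60, 0.3
        counts = []
        for seed in range(50):
            cfg = StudyConfig(
                n_pwms=4,
                pwm_length_range=(8, 10),
                n_tissues=1,
                genes_per_tissue=n,
                n_housekeeping=5,
                planted_pairs=(
                    PlantSpec("M000", "M001", gene_fraction=f,
                              tissues=("tissue0",)),
                ),
                seed=seed,
            )
            study = generate_study(cfg)
            counts.append(len(study.truth.carriers["tissue0|M000:M001"]))
        counts = np.asarray(counts)
        # bin the binomial into quartile-ish cells and compare observed
        edges = [0, 14, 17, 20, n]
        probs = []
        binom = sps.binom(n, f)
        lo = 0
        for hi in edges[1:]:
            probs.append(binom.cdf(hi) - binom.cdf(lo))
            lo = hi
        probs = np.array(probs) / sum(probs)
        obs = np.histogram(counts, bins=[-0.5] + [e + 0.5 for e in edges[1:]])[0]
        stat, p = sps.chisquare(obs, probs * len(counts))
        assert p > 0.01

    def test_overcommitted_fractions_rejected(self):
        from concordtf.simulate import PlantingError

        cfg = tiny_study_config(
            seed=1,
            planted_pairs=tuple(
                PlantSpec(f"M00{i}", f"M00{i+1}", gene_fraction=0.4,
                          tissues=("tissue0",))
                for i in range(3)
            ),
            planted_triplets=(),
        )
        with pytest.raises(PlantingError):
            generate_study(cfg)

    def test_written_study_round_trips_fasta(self, tiny_study, tmp_path):
        paths = write_study(tiny_study, tmp_path)
        back = read_promoters(paths["human_fasta"], "human")
        assert len(back) == len(tiny_study.promoters["human"])
        orig = {r.gene_id: r.sequence for r in tiny_study.promoters["human"]}
        assert all(orig[r.gene_id] == r.sequence for r in back)
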