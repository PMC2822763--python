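"""Distance-constrained pair enrichment: universe arithmetic, gap rules,
profiles and the conservation call."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from concordtf import pairs as prs
from concordtf.pairs import (
    DEFAULT_GRID,
    build_pair_profiles,
    call_conserved_pairs,
    cooccurring_genes,
    enumerate_pair_universe,
    gene_counts_by_cutoff,
    overlap_counts_by_cutoff,
    pair_gap_table,
    select_candidate_pairs,
    site_enrichment_profile,
)


class TestUniverse:
    @pytest.mark.parametrize("k,size", [(214, 23005), (40, 820), (1, 1)])
    def test_published_universe_sizes(self, k, size):
        ids = [f"M{i}" for i in range(k)]
        assert len(enumerate_pair_universe(ids)) == size

    @pytest.mark.parametrize("k", range(1, 21))
    def test_matches_brute_force_enumeration(self, k):
        ids = [f"P{i}" for i in range(k)]
        brute = {
            tuple(sorted(p))
            for p in itertools.combinations_with_replacement(ids, 2)
        }
        assert enumerate_pair_universe(ids) == brute

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            enumerate_pair_universe([])


def hits_df(rows):
    return pd.DataFrame(
        rows, columns=["gene", "species", "pwm", "start", "end", "strand", "score"]
    )


class TestCooccurrence:
    def _two_hits(self, s2, e2):
        return hits_df(
            [
                ("g", "h", "A", 10, 20, "+", 0.9),
                ("g", "h", "B", s2, e2, "+", 0.9),
            ]
        )

    def test_gap_within_smallest_cutoff(self):
        h = self._two_hits(35, 45)  # edge-to-edge gap 15
        for d in DEFAULT_GRID:
            assert cooccurring_genes(h, ("A", "B"), d) == {"g"}

    def test_gap_counts_from_matching_cutoff_only(self):
        h = self._two_hits(75, 85)  # gap 55
        assert cooccurring_genes(h, ("A", "B"), 40) == set()
        for d in (60, 100, 200):
            assert cooccurring_genes(h, ("A", "B"), d) == {"g"}

    def test_overlapping_sites_do_not_count(self):
        h = self._two_hits(15, 25)  # negative gap
        assert cooccurring_genes(h, ("A", "B"), 200) == set()

    def test_homotypic_needs_two_distinct_hits(self):
        one = hits_df([("g", "h", "A", 10, 20, "+", 0.9)])
        assert cooccurring_genes(one, ("A", "A"), 200) == set()
        two = hits_df(
            [
                ("g", "h", "A", 10, 20, "+", 0.9),
                ("g", "h", "A", 50, 60, "-", 0.9),
            ]
        )
        assert cooccurring_genes(two, ("A", "A"), 200) == {"g"}


@st.composite
def random_hit_tables(draw):
    n_genes = draw(st.integers(1, 4))
    pwms = ["A", "B", "C"]
    rows = []
    for g in range(n_genes):
        for _ in range(draw(st.integers(0, 8))):
            start = draw(st.integers(0, 280))
            length = draw(st.integers(6, 14))
            rows.append(
                (f"g{g}", "h", draw(st.sampled_from(pwms)), start,
                 start + length, draw(st.sampled_from("+-")), 0.9)
            )
    return hits_df(rows)


class TestGapTable:
    @given(random_hit_tables())
    @settings(max_examples=60, deadline=None)
    def test_agrees_with_reference_per_pair_sets(self, hits):
        table = pair_gap_table(hits, max_gap=200)
        counts = gene_counts_by_cutoff(table, DEFAULT_GRID)
        for pair in itertools.combinations_with_replacement("ABC", 2):
            for d in (20, 100, 200):
                ref = cooccurring_genes(hits, pair, d)
                got = 0
                if pair in counts.index:
                    got = int(counts.loc[pair, d])
                assert got == len(ref), (pair, d)

    @given(random_hit_tables())
    @settings(max_examples=40, deadline=None)
    def test_counts_monotone_along_grid(self, hits):
        counts = gene_counts_by_cutoff(pair_gap_table(hits), DEFAULT_GRID)
        arr = counts.to_numpy()
        assert np.all(np.diff(arr, axis=1) >= 0)


class TestProfiles:
    def test_site_ratio_and_zero_background_floor(self):
        assert np.allclose(
            site_enrichment_profile([12] * 10, [6] * 10), [2.0] * 10
        )
        assert np.allclose(site_enrichment_profile([3], [0]), [3.0])

    def test_candidate_selection_boundary(self):
        idx = pd.MultiIndex.from_tuples([("A", "B"), ("A", "C"), ("B", "C")])
        ratios = pd.DataFrame(
            [
                [1.1] * 6 + [0.9] * 4,   # >1 at six cutoffs: selected
                [1.1] * 5 + [0.9] * 5,   # only five: rejected
                [1.0] * 10,              # never above 1: rejected
            ],
            index=idx,
            columns=list(DEFAULT_GRID),
        )
        assert list(select_candidate_pairs(ratios)) == [("A", "B")]

    def test_overlap_counts_and_fraction(self):
        gap_h = pd.DataFrame(
            {"gene": ["g1", "g2", "g3"], "pwm_a": "A", "pwm_b": "B",
             "min_gap": [10, 10, 10]}
        )
        gap_m = pd.DataFrame(
            {"gene": ["m1", "m2"], "pwm_a": "A", "pwm_b": "B", "min_gap": [10, 10]}
        )
        m2h = {"m1": "g1", "m2": "g9"}  # only g1 is a shared ortholog
        ov = overlap_counts_by_cutoff(gap_h, gap_m, m2h, DEFAULT_GRID)
        assert int(ov.loc[("A", "B"), 200]) == 1
        prof = build_pair_profiles(
            {"human": gap_h, "mouse": gap_m},
            {"human": gap_h.iloc[:0], "mouse": gap_m.iloc[:0]},
            m2h,
        )
        # fraction = overlap / min(|H|, |M|) = 1/2 at every cutoff
        assert prof.overlap_fraction.loc[("A", "B"), 200] == pytest.approx(0.5)

    def test_identical_corpora_give_full_overlap_fraction(self):
        gap = pd.DataFrame(
            {"gene": ["g1", "g2"], "pwm_a": "A", "pwm_b": "B", "min_gap": [5, 30]}
        )
        prof = build_pair_profiles(
            {"human": gap, "mouse": gap},
            {"human": gap.iloc[:0], "mouse": gap.iloc[:0]},
            {"g1": "g1", "g2": "g2"},
        )
        frac = prof.overlap_fraction.loc[("A", "B")]
        assert frac[200] == pytest.approx(1.0)


def _profiles_from_counts(ch, cm, ov, bg=None):
    """Assemble a one-pair PairProfiles from raw count vectors."""
    grid = DEFAULT_GRID
    idx = pd.MultiIndex.from_tuples([("A", "B")], names=["pwm_a", "pwm_b"])
    mk = lambda v: pd.DataFrame([v], index=idx, columns=list(grid), dtype=float)
    zeros = mk([0] * 10)
    bg = mk(bg) if bg is not None else zeros
    return prs.PairProfiles(
        grid=grid,
        counts_real={"human": mk(ch), "mouse": mk(cm)},
        counts_bg={"human": bg, "mouse": bg},
        overlap_real=mk(ov),
        overlap_bg=zeros,
        site_ratio={
            "human": mk(site_enrichment_profile(ch, bg.to_numpy()[0])),
            "mouse": mk(site_enrichment_profile(cm, bg.to_numpy()[0])),
        },
        overlap_ratio=mk(ov),
        overlap_fraction=mk(
            np.asarray(ov, float)
            / np.maximum(np.minimum(ch, cm), 1)
        ),
    )


class TestConservationCall:
    def test_identical_profiles_give_r_one_and_call(self):
        ch = [10, 20, 30, 35, 38, 40, 41, 42, 43, 44]
        prof = _profiles_from_counts(ch, ch, ch)
        out = call_conserved_pairs(prof, n_perm=2000, seed=1)
        row = out.iloc[0]
        assert row.r_human == pytest.approx(1.0)
        assert row.r_mouse == pytest.approx(1.0)
        assert bool(row.called)

    def test_species_label_swap_leaves_calls_unchanged(self):
        ch = [5, 12, 20, 24, 25, 26, 26, 27, 27, 28]
        cm = [4, 10, 18, 22, 24, 25, 25, 26, 26, 26]
        ov = [3, 9, 16, 20, 21, 22, 22, 23, 23, 23]
        a = call_conserved_pairs(_profiles_from_counts(ch, cm, ov), n_perm=2000, seed=3)
        b = call_conserved_pairs(_profiles_from_counts(cm, ch, ov), n_perm=2000, seed=3)
        assert bool(a.iloc[0].called) == bool(b.iloc[0].called)

    def test_candidate_filter_blocks_flat_profiles(self):
        flat = [1] * 10  # ratio never exceeds 1
        prof = _profiles_from_counts(flat, flat, flat, bg=[1] * 10)
        out = call_conserved_pairs(prof, n_perm=500, seed=1)
        assert out.empty

    def test_overlap_filter_blocks_low_fractions(self):
        ch = [10, 20, 30, 35, 38, 40, 41, 42, 43, 44]
        ov = [0, 0, 1, 1, 1, 1, 1, 2, 2, 2]  # < 10% of the smaller gene set
        prof = _profiles_from_counts(ch, ch, ov)
        out = call_conserved_pairs(prof, n_perm=500, seed=1)
        assert out.empty

    def test_call_requires_both_species(self):
        ch = [10, 20, 30, 35, 38, 40, 41, 42, 43, 44]
        cm_noise = [30, 9, 41, 12, 38, 15, 30, 11, 28, 30]  # uncorrelated
        ov = [9, 19, 29, 34, 36, 39, 40, 41, 42, 43]
        prof = _profiles_from_counts(ch, cm_noise, ov)
        out = call_conserved_pairs(prof, n_perm=4000, seed=2)
        row = out.iloc[0]
        assert bool(row.called_human)
        assert not bool(row.called)
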