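"""Resampled reference pools, spectra, overlaps and chi-square comparison."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from csdpop.nullmodels import (
    OccurrenceSpectrum,
    OverlapPartition,
    apiary_dedup,
    chi_square_compare,
    expected_overlap,
    expected_shared_analytic,
    expected_spectrum_analytic,
    mean_spectrum,
    overlap_partition,
    sample_pool,
    spectrum,
)


class TestSamplePool:
    def test_single_element_pool(self, rng):
        assert list(sample_pool(1, 5, rng)) == [1, 1, 1, 1, 1]

    def test_seed_determinism(self):
        a = sample_pool(133, 372, np.random.default_rng(3))
        b = sample_pool(133, 372, np.random.default_rng(3))
        assert np.array_equal(a, b)

    def test_mean_distinct_matches_closed_form(self):
        rng = np.random.default_rng(11)
        N, D, reps = 133, 372, 400
        distinct = [len(np.unique(sample_pool(N, D, rng))) for _ in range(reps)]
        expected = N * (1 - (1 - 1 / N) ** D)
        sem = np.std(distinct, ddof=1) / math.sqrt(reps)
        assert abs(np.mean(distinct) - expected) < 3 * sem


class TestSpectrum:
    @pytest.mark.parametrize(
        "obs,expected",
        [
            (["x", "x", "y"], {1: 1, 2: 1}),
            (["a", "a", "a", "b", "c"], {1: 2, 3: 1}),
            ([], {}),
        ],
    )
    def test_examples(self, obs, expected):
        assert spectrum(obs).counts == expected

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.integers(min_value=0, max_value=20), max_size=60))
    def test_invariants(self, obs):
        spec = spectrum(obs)
        assert spec.n_observations == len(obs)
        assert spec.n_distinct == len(set(obs))


class TestMeanSpectrum:
    def test_degenerate_pool(self, rng):
        assert mean_spectrum(1, 3, reps=5, rng=rng).counts == {3: 1.0}

    def test_two_sided_coin_enumeration(self):
        # pairs of draws from {1,2}: HH/TT give {2:1}, HT/TH give {1:2}
        rng = np.random.default_rng(5)
        spec = mean_spectrum(2, 2, reps=4000, rng=rng)
        assert spec.counts[1] == pytest.approx(1.0, abs=0.05)
        assert spec.counts[2] == pytest.approx(0.5, abs=0.03)

    def test_matches_analytic_binomial_oracle(self):
        """Mean count of alleles seen exactly k times equals
        N*C(D,k)(1/N)^k(1-1/N)^(D-k) within 3 Monte-Carlo standard errors."""
        N, D, reps = 133, 372, 300
        rng = np.random.default_rng(17)
        per_rep = {k: [] for k in range(1, 9)}
        for _ in range(reps):
            counts = spectrum(sample_pool(N, D, rng)).counts
            for k in per_rep:
                per_rep[k].append(counts.get(k, 0))
        for k, values in per_rep.items():
            mean = np.mean(values)
            sem = np.std(values, ddof=1) / math.sqrt(reps)
            assert abs(mean - expected_spectrum_analytic(N, D, k)) < 3 * sem + 1e-9, k


class TestOverlap:
    def test_partition_examples(self):
        assert overlap_partition({"a", "b", "c"}, {"b", "c", "d"}) == OverlapPartition(1, 1, 2)
        assert overlap_partition({"a"}, {"b"}).shared == 0
        p = overlap_partition({"a", "b"}, {"a", "b"})
        assert (p.only_a, p.only_b) == (0, 0)

    def test_expected_overlap_degenerate(self, rng):
        p = expected_overlap(1, 4, 4, reps=10, rng=rng)
        assert (p.only_a, p.only_b, p.shared) == (0.0, 0.0, 1.0)

    def test_expected_overlap_single_draws(self):
        rng = np.random.default_rng(23)
        p = expected_overlap(2, 1, 1, reps=4000, rng=rng)
        assert p.shared == pytest.approx(0.5, abs=0.03)

    def test_matches_independence_oracle(self):
        """Mean shared count approaches N(1-(1-1/N)^Da)(1-(1-1/N)^Db)."""
        N, Da, Db, reps = 133, 184, 188, 300
        rng = np.random.default_rng(29)
        shared = []
        for _ in range(reps):
            part = overlap_partition(sample_pool(N, Da, rng), sample_pool(N, Db, rng))
            shared.append(part.shared)
        sem = np.std(shared, ddof=1) / math.sqrt(reps)
        assert abs(np.mean(shared) - expected_shared_analytic(N, Da, Db)) < 3 * sem


class TestApiaryDedup:
    def table(self, rows):
        return pd.DataFrame(rows, columns=["allele_id", "apiary_id", "colony_id"])

    def test_within_apiary_duplicates_collapse(self):
        t = self.table([("x", "ap1", "c1"), ("x", "ap1", "c2"), ("x", "ap2", "c3")])
        out = apiary_dedup(t)
        assert sorted(zip(out["allele_id"], out["apiary_id"])) == [
            ("x", "ap1"),
            ("x", "ap2"),
        ]
        assert sorted(out["n_colonies"]) == [1, 2]

    def test_no_duplicates_unchanged(self):
        t = self.table([("x", "ap1", "c1"), ("y", "ap1", "c1")])
        out = apiary_dedup(t)
        assert len(out) == 2 and (out["n_colonies"] == 1).all()

    def test_all_same_collapses_to_one(self):
        t = self.table([("x", "ap1", f"c{i}") for i in range(5)])
        out = apiary_dedup(t)
        assert len(out) == 1 and out["n_colonies"].iloc[0] == 5

    def test_idempotent(self):
        t = self.table(
            [("x", "ap1", "c1"), ("x", "ap1", "c2"), ("y", "ap2", "c3"), ("x", "ap2", "c3")]
        )
        once = apiary_dedup(t)
        twice = apiary_dedup(once)
        pd.testing.assert_frame_equal(
            once.sort_values(["apiary_id", "allele_id"]).reset_index(drop=True),
            twice.sort_values(["apiary_id", "allele_id"]).reset_index(drop=True),
        )
        assert len(once) <= len(t)

    def test_missing_apiary_errors(self):
        t = pd.DataFrame({"allele_id": ["x"], "apiary_id": [None], "colony_id": ["c"]})
        with pytest.raises(ValueError, match="apiary_id"):
            apiary_dedup(t)


class TestChiSquare:
    def test_identical_distributions(self):
        res = chi_square_compare({1: 10.0, 2: 5.0}, {1: 10.0, 2: 5.0})
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_statistic(self):
        res = chi_square_compare({"a": 10, "b": 0}, {"a": 5, "b": 5})
        assert res.statistic == pytest.approx(10.0)
        assert res.df == 1

    def test_sparse_bin_pooled_into_tail(self):
        res = chi_square_compare(
            {1: 8, 2: 4, 3: 1}, {1: 7.5, 2: 5.0, 3: 0.2}
        )
        # the k=3 bin (expected 0.2) folds back into the last retained bin
        assert any(3 in group and 2 in group for group in res.categories_used)
        assert res.df == 1

    def test_all_zero_expected_errors(self):
        with pytest.raises(ValueError, match="categor"):
            chi_square_compare({1: 5}, {1: 0.0})

    def test_accepts_spectra_and_partitions(self):
        s_obs = OccurrenceSpectrum(counts={1: 40, 2: 12})
        s_exp = OccurrenceSpectrum(counts={1: 35.0, 2: 16.0})
        assert chi_square_compare(s_obs, s_exp).statistic > 0
        p_obs = OverlapPartition(47, 36, 38)
        p_exp = OverlapPartition(30.0, 32.0, 55.0)
        res = chi_square_compare(p_obs, p_exp)
        assert res.df == 2
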