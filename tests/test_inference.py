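"""Gate threshold, permutation p values, cluster correction, tables."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from itpcdecode import (
    PermutationConfig,
    PipelineConfig,
    cluster_table,
    compute_threshold,
    decode_over_time,
    find_clusters,
    permutation_null,
    permutation_p,
    permutation_test_curve,
)
from itpcdecode.decoding import DecodingResult

from conftest import toy_dataset


class TestComputeThreshold:
    def test_flat_baseline(self):
        times = np.array([-20.0, -10.0, 0.0, 10.0])
        curve = np.array([0.5, 0.5, 0.6, 0.7])
        assert compute_threshold(curve, times) == pytest.approx(0.5)

    def test_mean_plus_1p5_sd(self):
        times = np.arange(-40.0, 10.0, 10.0)
        curve = np.array([0.4, 0.6, 0.4, 0.6, 0.9])  # baseline mean .5, sd .1
        assert compute_threshold(curve, times) == pytest.approx(0.65)

    def test_single_sample_baseline_warns(self):
        with pytest.warns(UserWarning, match="single-sample"):
            thr = compute_threshold(
                np.array([0.55, 0.7]), np.array([-2.0, 2.0])
            )
        assert thr == pytest.approx(0.55)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError, match="no timepoints"):
            compute_threshold(np.array([0.5, 0.6]), np.array([2.0, 4.0]))


class TestPermutationP:
    @pytest.mark.parametrize(
        "b, m, expected",
        [(0, 2000, 1 / 2001), (99, 1999, 0.05), (50, 50, 1.0)],
    )
    def test_formula(self, b, m, expected):
        null = np.concatenate([np.full(b, 1.0), np.full(m - b, 0.0)])
        assert permutation_p(0.5, null) == pytest.approx(expected, abs=1e-15)

    def test_ties_count_as_extreme(self):
        assert permutation_p(0.7, np.array([0.7, 0.1])) == pytest.approx(2 / 3)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(0, 1), min_size=1, max_size=50),
        st.floats(0, 1),
        st.floats(0, 1),
    )
    def test_monotone_and_bounded(self, null, obs_lo, obs_hi):
        null = np.asarray(null)
        lo, hi = sorted([obs_lo, obs_hi])
        p_lo = permutation_p(lo, null)
        p_hi = permutation_p(hi, null)
        assert p_hi <= p_lo  # larger observed score never increases p
        assert 1 / (len(null) + 1) <= p_hi <= 1.0


class TestFindClusters:
    def cfg(self, **kw):
        return PermutationConfig(n_perm=10, **kw)

    def test_run_shorter_than_10ms_discarded(self):
        times = np.arange(0.0, 40.0, 2.0)
        p = np.full(20, np.nan)
        p[3:8] = 0.01  # spans 8 ms at 2-ms sampling
        assert find_clusters(p, times, self.cfg()) == []

    def test_run_of_exactly_10ms_retained(self):
        times = np.arange(0.0, 40.0, 2.0)
        p = np.full(20, np.nan)
        p[3:9] = 0.01  # spans 10 ms inclusive
        assert find_clusters(p, times, self.cfg()) == [(3, 8)]

    def test_all_significant_single_cluster(self):
        times = np.arange(0.0, 40.0, 2.0)
        p = np.full(20, 0.001)
        assert find_clusters(p, times, self.cfg()) == [(0, 19)]

    def test_non_gated_points_break_runs(self):
        times = np.arange(0.0, 60.0, 2.0)
        p = np.full(30, 0.01)
        p[10] = np.nan  # gate never passed here
        clusters = find_clusters(p, times, self.cfg())
        assert clusters == [(0, 9), (11, 29)]

    def test_alpha_boundary_inclusive(self):
        times = np.arange(0.0, 30.0, 2.0)
        p = np.full(15, 0.05)  # exactly at alpha
        assert find_clusters(p, times, self.cfg()) == [(0, 14)]


def _result_from_curves(fold_aucs, times):
    return DecodingResult(
        times=times,
        mean_auc=fold_aucs.mean(axis=0),
        fold_aucs=fold_aucs,
        fold_sd=fold_aucs.std(axis=0, ddof=1),
        selected=[],
        folds=[],
        config=PipelineConfig(),
    )


class TestClusterTable:
    def test_hand_computed_summary(self):
        times = np.arange(0.0, 10.0, 2.0)
        base = np.array([0.5, 0.8, 0.9, 0.85, 0.5])
        fold_aucs = np.stack([base - 0.1, base, base + 0.1])
        result = _result_from_curves(fold_aucs, times)
        table = cluster_table([(1, 3)], result, "gamma_low")
        row = table.iloc[0]
        assert row["Band"] == "gamma_low"
        assert row["Peak (%)"] == pytest.approx(90.0)
        assert row["Peak time (ms)"] == pytest.approx(4.0)
        assert row["Cluster start (ms)"] == pytest.approx(2.0)
        assert row["Cluster end (ms)"] == pytest.approx(6.0)
        assert row["Cluster length (ms)"] == pytest.approx(4.0)
        assert row["Cluster mean (%)"] == pytest.approx(85.0)
        # fold cluster means are mean±0.1 -> SD across folds = 0.1
        assert row["Cluster SD (%)"] == pytest.approx(10.0)

    def test_empty_cluster_list(self):
        result = _result_from_curves(np.full((3, 4), 0.5), np.arange(4.0))
        table = cluster_table([], result, "alpha")
        assert table.empty
        assert list(table.columns)[0] == "Band"

    def test_rows_sorted_by_start(self):
        times = np.arange(0.0, 20.0, 2.0)
        fold_aucs = np.tile(np.linspace(0.6, 0.9, 10), (3, 1))
        result = _result_from_curves(fold_aucs, times)
        table = cluster_table([(6, 8), (0, 2)], result, "beta")
        assert list(table["Cluster start (ms)"]) == [0.0, 12.0]


class TestPermutationNull:
    def test_deterministic_given_seed(self, rng):
        ds = toy_dataset(rng, n_subjects=9, n_features=4, n_times=2)
        pipe = PipelineConfig(n_alphas=6, seed=1)
        cfg = PermutationConfig(n_perm=20, seed=9)
        a = permutation_null(ds, 0, pipe, cfg)
        b = permutation_null(ds, 0, pipe, cfg)
        assert np.array_equal(a, b)
        c = permutation_null(ds, 1, pipe, cfg)
        assert not np.array_equal(a, c)

    def test_null_centered_near_half(self, rng):
        ds = toy_dataset(rng, n_subjects=14, n_features=5, n_times=1)
        null = permutation_null(
            ds, 0, PipelineConfig(n_alphas=8, seed=0), PermutationConfig(n_perm=60, seed=3)
        )
        assert 0.45 < null.mean() < 0.55

    def test_strong_effect_beats_null_quantile(self, rng):
        ds = toy_dataset(rng, n_subjects=14, n_features=5, n_times=1, effect=2.5)
        pipe = PipelineConfig(n_alphas=8, seed=0)
        observed = decode_over_time(ds, pipe).mean_auc[0]
        null = permutation_null(ds, 0, pipe, PermutationConfig(n_perm=80, seed=3))
        assert observed > np.quantile(null, 0.975)

    def test_within_subject_option_preserves_subject_blocks(self, rng):
        ds = toy_dataset(rng, n_subjects=10, n_features=4, n_times=1)
        cfg = PermutationConfig(n_perm=10, seed=0, within_subject=True)
        # within-subject shuffles keep each subject's label multiset: for a
        # 1:1 design every subject still contributes one of each class, so
        # every permuted labeling remains balanced overall
        null = permutation_null(ds, 0, PipelineConfig(n_alphas=6, seed=0), cfg)
        assert len(null) == 10


class TestPermutationTestCurve:
    def test_gate_and_clusters_on_injected_effect(self, rng):
        ds = toy_dataset(
            rng,
            n_subjects=14,
            n_features=6,
            n_times=30,
            effect=2.5,
            effect_times=slice(18, 28),
            t0=-20.0,  # 10 baseline points before the divergence point
        )
        result = decode_over_time(ds, PipelineConfig(n_alphas=8, seed=0))
        sig = permutation_test_curve(
            ds, result, PermutationConfig(n_perm=60, seed=1)
        )
        assert np.isnan(sig.p[~sig.tested]).all()
        assert len(sig.clusters) >= 1
        starts = [sig.times[i] for i, _ in sig.clusters]
        ends = [sig.times[j] for _, j in sig.clusters]
        # effect spans indices 18..27 -> times 16..34 ms after t0=-20
        assert any(s <= 20.0 <= e or s <= 30.0 <= e for s, e in zip(starts, ends))

    def test_null_data_rarely_yields_clusters(self, rng):
        ds = toy_dataset(rng, n_subjects=14, n_features=6, n_times=30, t0=-30.0)
        result = decode_over_time(ds, PipelineConfig(n_alphas=8, seed=0))
        sig = permutation_test_curve(ds, result, PermutationConfig(n_perm=60, seed=1))
        assert len(sig.clusters) == 0
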