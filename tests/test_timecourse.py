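import numpy as np
import pandas as pd
import pytest

from gliomanet import synthetic
from gliomanet._util import InputError
from gliomanet.timecourse import (
    TimeCourse,
    build_dynamic_map,
    classify_response,
    cluster_profiles,
    interpolate_profile,
    lag_correlation,
    timecourse_de_filter,
)

TIMES_10x12 = np.arange(0.0, 120.0, 12.0)  # 10 points, 12-hour spacing


def _tc(values, times=TIMES_10x12):
    values = np.atleast_2d(values)
    return TimeCourse(
        pd.DataFrame(values, index=[f"g{i}" for i in range(values.shape[0])]),
        times[: values.shape[1]],
    )


def _sigmoid(times, t50, amplitude=2.0, steep=0.25):
    return amplitude / (1.0 + np.exp(-steep * (times - t50)))


def _pulse(times, t50, amplitude=2.0, steep=0.25, width=36.0):
    """Transient rise-then-decay profile; non-monotone, so rank
    correlation can localize a time shift."""
    rise = 1.0 / (1.0 + np.exp(-steep * (times - t50)))
    fall = 1.0 / (1.0 + np.exp(steep * (times - t50 - width)))
    return amplitude * rise * fall


class TestDEFilter:
    def test_flat_profile_excluded(self):
        tc = _tc(np.zeros((1, 10)))
        assert timecourse_de_filter(tc) == set()

    def test_noiseless_sigmoid_retained(self):
        tc = _tc(_sigmoid(TIMES_10x12, 48.0))
        assert timecourse_de_filter(tc) == {"g0"}

    def test_too_few_time_points_rejected(self):
        with pytest.raises(InputError):
            timecourse_de_filter(_tc(np.zeros((1, 3)), TIMES_10x12[:3]))


class TestClustering:
    def test_two_opposite_shapes_separate_perfectly(self):
        up = _sigmoid(TIMES_10x12, 36.0)
        down = -up
        values = np.vstack([np.tile(up, (5, 1)), np.tile(down, (5, 1))])
        cs = cluster_profiles(_tc(values), k=2, seed=0)
        groups = sorted(frozenset(m) for m in cs.members.values())
        assert groups == sorted(
            [frozenset(f"g{i}" for i in range(5)), frozenset(f"g{i}" for i in range(5, 10))]
        )

    def test_single_cluster_medoid_minimizes_total_distance(self):
        rng = np.random.default_rng(7)
        values = rng.normal(size=(12, 10))
        cs = cluster_profiles(_tc(values), k=1, seed=0)
        corr = np.corrcoef(values)
        dist = 1.0 - corr
        totals = dist.sum(axis=1)
        medoid_profile = cs.medoids[0]
        best = int(np.argmin(totals))
        assert medoid_profile == pytest.approx(values[best])

    def test_k_larger_than_genes_rejected(self):
        with pytest.raises(Exception):
            cluster_profiles(_tc(np.random.default_rng(0).normal(size=(3, 10))), k=5)

    def test_planted_clusters_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        times = list(TIMES_10x12)
        response = list(np.linspace(12.0, 96.0, 8))
        tc, _ = synthetic.make_timecourse(
            8, 12, times, response, noise_sd=0.15, seed=9
        )
        cs = cluster_profiles(tc, k=8, seed=0)
        labels_true = [i // 12 for i in range(96)]
        pred = np.empty(96, dtype=int)
        for cid, members in cs.members.items():
            for g in members:
                pred[int(g[1:])] = cid
        assert adjusted_rand_score(labels_true, pred) >= 0.8


class TestClassifyResponse:
    def test_logistic_centred_at_48_is_delayed(self):
        t50, cls = classify_response(_sigmoid(TIMES_10x12, 48.0), TIMES_10x12)
        assert t50 == pytest.approx(48.0, abs=TIMES_10x12[-1] / 99 + 1e-9)
        assert cls == "delayed"

    def test_step_at_six_hours_is_rapid(self):
        profile = np.where(TIMES_10x12 >= 6.0, 1.0, 0.0)
        _, cls = classify_response(profile, TIMES_10x12)
        assert cls == "rapid"

    def test_ramp_crossing_at_thirty_unclassified(self):
        times = np.linspace(0.0, 60.0, 11)
        profile = times.copy()  # linear: crosses half-range at 30 h
        t50, cls = classify_response(profile, times)
        assert t50 == pytest.approx(30.0, abs=60.0 / 99 + 1e-9)
        assert cls == "unclassified"

    def test_affine_invariance(self):
        profile = _sigmoid(TIMES_10x12, 24.0)
        t1, c1 = classify_response(profile, TIMES_10x12)
        t2, c2 = classify_response(5.0 * profile - 3.0, TIMES_10x12)
        assert (t1, c1) == (t2, c2)

    def test_constant_profile_rejected(self):
        with pytest.raises(InputError):
            classify_response(np.ones(10), TIMES_10x12)


class TestInterpolation:
    def test_linear_profile_reproduced(self):
        times = TIMES_10x12
        profile = 0.3 * times + 1.0
        grid, values = interpolate_profile(profile, times)
        assert np.abs(values - (0.3 * grid + 1.0)).max() < 1e-9

    def test_endpoints_preserved(self):
        rng = np.random.default_rng(8)
        profile = rng.normal(size=10)
        _, values = interpolate_profile(profile, TIMES_10x12)
        assert values[0] == profile[0]
        assert values[-1] == profile[-1]

    def test_sine_error_below_five_percent(self):
        times = np.linspace(0.0, 2 * np.pi, 10)
        grid, values = interpolate_profile(np.sin(times), times)
        assert np.abs(values - np.sin(grid)).max() < 0.05

    def test_duplicate_times_rejected(self):
        with pytest.raises(InputError):
            interpolate_profile(np.arange(4.0), np.array([0.0, 1.0, 1.0, 2.0]))


class TestLagCorrelation:
    def test_identical_profiles_lag_zero(self):
        grid, p = interpolate_profile(_sigmoid(TIMES_10x12, 48.0), TIMES_10x12)
        lc = lag_correlation(p, p, grid[1] - grid[0])
        assert lc.best_rho == pytest.approx(1.0)
        assert lc.best_lag_h == 0.0
        assert lc.significant

    def test_planted_18h_delay_recovered(self):
        # transient (non-monotone) profiles: Spearman is invariant to
        # monotone reshaping, so only a pulse pins the lag down
        grid_step = (TIMES_10x12[-1] - TIMES_10x12[0]) / 99
        _, p1 = interpolate_profile(_pulse(TIMES_10x12, 24.0), TIMES_10x12)
        _, p2 = interpolate_profile(_pulse(TIMES_10x12, 42.0), TIMES_10x12)
        lc = lag_correlation(p1, p2, grid_step)
        # an 18-h lag is not a grid multiple, so the best alignment is off
        # by up to half a step; rho stays high but not exactly 1
        assert lc.best_rho > 0.95
        assert lc.significant
        assert lc.best_lag_h == pytest.approx(18.0, abs=grid_step + 1e-9)

    def test_anticorrelated_pair_not_significant(self):
        # the signed-maximum rule never calls an anti-correlated pair:
        # partial edge alignments can produce a weak positive rho at some
        # lag, but nothing near the significance threshold
        _, p = interpolate_profile(_pulse(TIMES_10x12, 36.0), TIMES_10x12)
        lc = lag_correlation(p, -p, (TIMES_10x12[-1] - TIMES_10x12[0]) / 99)
        assert lc.best_rho < 0.9
        assert not lc.significant

    def test_anticorrelated_pair_flagged_with_absolute_option(self):
        _, p = interpolate_profile(_pulse(TIMES_10x12, 36.0), TIMES_10x12)
        lc = lag_correlation(
            p, -p, (TIMES_10x12[-1] - TIMES_10x12[0]) / 99, absolute=True
        )
        assert lc.best_rho == pytest.approx(-1.0, abs=0.01)
        assert lc.significant

    def test_direction_swap_negates_lag(self):
        grid_step = (TIMES_10x12[-1] - TIMES_10x12[0]) / 99
        _, p1 = interpolate_profile(_pulse(TIMES_10x12, 24.0), TIMES_10x12)
        _, p2 = interpolate_profile(_pulse(TIMES_10x12, 42.0), TIMES_10x12)
        fwd = lag_correlation(p1, p2, grid_step)
        rev = lag_correlation(p2, p1, grid_step)
        assert fwd.best_lag_h == pytest.approx(-rev.best_lag_h, abs=grid_step + 1e-9)


class TestDynamicMap:
    def test_single_cluster_empty_map(self):
        tc, _ = synthetic.make_timecourse(1, 5, list(TIMES_10x12), [48.0], noise_sd=0.0, seed=0)
        cs = cluster_profiles(tc, k=1, seed=0)
        assert len(build_dynamic_map(cs)) == 0

    def test_independent_noise_clusters_nothing_significant(self):
        rng = np.random.default_rng(11)
        values = rng.normal(size=(30, 10))
        cs = cluster_profiles(_tc(values), k=6, seed=0)
        dyn = build_dynamic_map(cs, rho_threshold=0.9)
        assert dyn["significant"].sum() == 0

    def test_planted_lag_pair_found(self):
        # transient clusters with one planted 18-h lag: the pair is
        # significant at the planted lag (monotone sigmoid clusters would
        # be rank-identical at every lag, so the lag is planted in pulses)
        times = list(TIMES_10x12)
        tc, truth = synthetic.make_timecourse(
            2, 10, times, [24.0, 24.0], lags_h={(0, 1): 18.0},
            noise_sd=0.0, seed=13, shape="pulse",
        )
        cs = cluster_profiles(tc, k=2, seed=0)
        dyn = build_dynamic_map(cs)
        sig = dyn[dyn["significant"]]
        assert len(sig) == 1
        row = sig.iloc[0]
        # map the PAM cluster ids back to planted clusters via membership
        planted_of = {}
        for cid, members in cs.members.items():
            planted_of[cid] = {int(g[1:]) // 10 for g in members}.pop()
        pair = {planted_of[row["cluster_i"]], planted_of[row["cluster_j"]]}
        assert pair == {0, 1}
        grid_step = (times[-1] - times[0]) / 99
        assert abs(row["best_lag_h"]) == pytest.approx(18.0, abs=grid_step + 1e-9)
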