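import numpy as np
import pandas as pd
import pytest

from gliomanet import synthetic
from gliomanet._util import InputError
from gliomanet.survival import (
    SurvivalTable,
    fixed_group_compare,
    km_estimate,
    logrank_test,
    optimal_cutpoint,
)


def _table(times, events, covariate=None):
    n = len(times)
    return SurvivalTable(
        pd.DataFrame(
            {
                "id": [f"p{i}" for i in range(n)],
                "time": times,
                "event": events,
                "covariate": covariate if covariate is not None else np.zeros(n),
            }
        )
    )


def naive_logrank_chi2(times, events, groups):
    """Hand computation of the log-rank O-E statistic and variance."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups, dtype=int)
    o_minus_e, var = 0.0, 0.0
    for t in sorted(set(times[events == 1])):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (groups == 1)).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (groups == 1)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return 0.0 if var == 0 else o_minus_e**2 / var


class TestKaplanMeier:
    def test_no_events_survival_stays_one(self):
        km = km_estimate(_table([5.0, 6.0, 7.0], [0, 0, 0]))
        assert len(km.event_times) == 0
        assert km.at(100.0) == 1.0

    def test_three_uncensored_deaths(self):
        km = km_estimate(_table([1.0, 2.0, 3.0], [1, 1, 1]))
        assert km.survival == pytest.approx([2 / 3, 1 / 3, 0.0])

    def test_censoring_shrinks_risk_set(self):
        km = km_estimate(_table([1.0, 2.0, 3.0], [1, 0, 1]))
        # S(1) = 2/3; at t=3 only one subject remains at risk -> S(3) = 0
        assert km.at(1.0) == pytest.approx(2 / 3)
        assert km.at(3.0) == pytest.approx(0.0)
        assert km.at_risk.tolist() == [3, 1]

    def test_matches_empirical_survival_without_censoring(self):
        rng = np.random.default_rng(0)
        times = rng.exponential(10.0, size=50)
        km = km_estimate(_table(times, np.ones(50, dtype=int)))
        for t in [1.0, 5.0, 15.0]:
            assert km.at(t) == pytest.approx((times > t).mean())

    def test_matches_lifelines(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(1)
        times = rng.exponential(10.0, size=80)
        events = rng.integers(0, 2, size=80)
        if events.sum() == 0:
            events[0] = 1
        km = km_estimate(_table(times, events))
        kmf = KaplanMeierFitter().fit(times, events)
        for t in km.event_times:
            assert km.at(t) == pytest.approx(
                float(kmf.survival_function_at_times(t).iloc[0])
            )

    def test_nonpositive_time_rejected(self):
        with pytest.raises(InputError):
            _table([0.0, 1.0], [1, 1])


class TestLogrank:
    def test_identical_groups_give_zero(self):
        times = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        events = [1, 1, 1, 1, 1, 1]
        chi2, p = logrank_test(_table(times, events), [0, 0, 0, 1, 1, 1])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(2)
        times = rng.exponential(10.0, size=40)
        events = rng.integers(0, 2, size=40)
        events[:4] = 1
        g = rng.integers(0, 2, size=40)
        if len(np.unique(g)) < 2:
            g[0] = 1 - g[0]
        t = _table(times, events)
        chi2_a, _ = logrank_test(t, g)
        chi2_b, _ = logrank_test(t, 1 - g)
        assert chi2_a == pytest.approx(chi2_b)

    def test_matches_hand_computation(self):
        rng = np.random.default_rng(3)
        for trial in range(10):
            n = int(rng.integers(5, 30))
            times = np.round(rng.exponential(5.0, size=n), 1) + 0.1
            events = rng.integers(0, 2, size=n)
            g = rng.integers(0, 2, size=n)
            if events.sum() == 0 or len(np.unique(g)) < 2:
                continue
            chi2, _ = logrank_test(_table(times, events), g)
            assert chi2 == pytest.approx(naive_logrank_chi2(times, events, g))

    def test_matches_lifelines(self):
        from lifelines.statistics import logrank_test as ll_logrank

        rng = np.random.default_rng(4)
        times = rng.exponential(10.0, size=60)
        events = rng.integers(0, 2, size=60)
        events[:6] = 1
        g = rng.integers(0, 2, size=60)
        g[:2] = [0, 1]
        res = ll_logrank(
            times[g == 0], times[g == 1], events[g == 0], events[g == 1]
        )
        chi2, p = logrank_test(_table(times, events), g)
        assert chi2 == pytest.approx(res.test_statistic)
        assert p == pytest.approx(res.p_value)

    def test_single_group_rejected(self):
        with pytest.raises(InputError):
            logrank_test(_table([1.0, 2.0], [1, 1]), [1, 1])

    def test_strong_hazard_detected(self):
        truth = synthetic.SyntheticTruth(hazard_ratio=3.0, survival_gene="X")
        hits = 0
        for s in range(10):
            tab = synthetic.make_survival(200, truth, 0.01, seed=s, censoring_horizon=400.0)
            cov = tab.table["covariate"].to_numpy()
            _, p = logrank_test(tab, (cov > np.median(cov)).astype(int))
            hits += p < 0.01
        assert hits >= 9


class TestOptimalCutpoint:
    def _planted(self, seed, n=200, split=0.6, hr=3.0):
        rng = np.random.default_rng(seed)
        covariate = rng.normal(size=n)
        boundary = np.quantile(covariate, split)
        hazard = 0.01 * np.where(covariate > boundary, hr, 1.0)
        times = rng.exponential(1.0 / hazard)
        return _table(times, np.ones(n, dtype=int), covariate)

    def test_planted_split_recovered(self):
        table = self._planted(seed=10)
        res = optimal_cutpoint(table, n_perm=10, seed=0)
        assert abs(res.cutpoint_rank - 120) <= 10

    def test_adjusted_p_not_smaller_than_raw(self):
        rng = np.random.default_rng(11)
        table = _table(
            rng.exponential(10.0, size=60),
            np.ones(60, dtype=int),
            rng.normal(size=60),
        )
        res = optimal_cutpoint(table, n_perm=50, seed=1)
        assert res.adjusted_p >= res.p_value

    def test_median_only_scan_reduces_to_single_logrank(self):
        table = self._planted(seed=12, n=100, split=0.5)
        res = optimal_cutpoint(table, min_group_fraction=0.5, n_perm=100, seed=2)
        cov = table.table["covariate"].to_numpy()
        g = (cov > np.median(cov)).astype(int)
        chi2, p = logrank_test(table, g)
        assert res.chi_square == pytest.approx(chi2)
        assert res.p_value == pytest.approx(p)
        assert res.group_sizes == (50, 50)

    def test_constant_covariate_rejected(self):
        rng = np.random.default_rng(13)
        table = _table(rng.exponential(10.0, 30), np.ones(30, dtype=int), np.ones(30))
        with pytest.raises(InputError):
            optimal_cutpoint(table, n_perm=10, seed=0)

    def test_too_few_patients_rejected(self):
        rng = np.random.default_rng(14)
        table = _table(rng.exponential(10.0, 10), np.ones(10, dtype=int), rng.normal(size=10))
        with pytest.raises(InputError):
            optimal_cutpoint(table, n_perm=10, seed=0)


class TestFixedGroupCompare:
    def test_identical_categories_not_separable(self):
        times = [1.0, 2.0, 3.0] * 2
        events = [1, 1, 1] * 2
        table = _table(times, events)
        out = fixed_group_compare(table, ["amp", "amp", "amp", "del", "del", "del"])
        assert out.loc[0, "p_value"] == pytest.approx(1.0)

    def test_three_categories_make_three_pairs(self):
        rng = np.random.default_rng(15)
        table = _table(rng.exponential(10.0, 30), np.ones(30, dtype=int))
        labels = ["amp"] * 10 + ["norm"] * 10 + ["del"] * 10
        out = fixed_group_compare(table, labels)
        assert len(out) == 3
        assert {"q_value", "chi_square", "p_value"} <= set(out.columns)
        assert (out["q_value"] >= out["p_value"] - 1e-12).all()

    def test_small_category_dropped_with_warning(self):
        rng = np.random.default_rng(16)
        table = _table(rng.exponential(10.0, 21), np.ones(21, dtype=int))
        labels = ["a"] * 10 + ["b"] * 10 + ["tiny"]
        with pytest.warns(UserWarning):
            out = fixed_group_compare(table, labels)
        assert len(out) == 1

    def test_copy_number_ordering_detected(self):
        """Hazard increasing in copy number: amp vs del is the sharpest pair."""
        wins = 0
        for s in range(10):
            rng = np.random.default_rng(100 + s)
            n = 150
            cls = rng.integers(0, 3, size=n)  # 0=del, 1=norm, 2=amp
            hazard = 0.01 * (2.5 ** (cls / 2.0))
            times = rng.exponential(1.0 / hazard)
            table = _table(times, np.ones(n, dtype=int))
            labels = np.array(["del", "norm", "amp"])[cls]
            out = fixed_group_compare(table, labels)
            best = out.loc[out["p_value"].idxmin()]
            if {best["group_a"], best["group_b"]} == {"amp", "del"}:
                wins += 1
        assert wins >= 9
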