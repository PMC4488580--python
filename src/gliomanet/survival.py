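"""Survival stratification: Kaplan-Meier, log-rank, optimal cutpoints.

Implements the product-limit estimator, the two-group log-rank test, the
optimum-partitioning procedure (patients ranked by a covariate such as
expression or standardized copy number; every admissible split is scored
by the Cox score test for a binary group, which is exactly the log-rank
statistic; the minimum-p split is reported with a permutation-adjusted p
that accounts for the scan), and a fixed-category comparison with
pairwise log-rank tests under BH correction.

The log-rank computation is vectorized over candidate splits so the
permutation adjustment (a full scan per permutation) stays cheap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from gliomanet._util import InputError, ParameterError
from gliomanet.expression import bh_fdr

__all__ = [
    "SurvivalTable",
    "KMCurve",
    "km_estimate",
    "logrank_test",
    "CutpointResult",
    "optimal_cutpoint",
    "fixed_group_compare",
]


@dataclass
class SurvivalTable:
    """Per-patient follow-up records.

    ``table`` columns: ``id``, ``time`` (days, > 0), ``event`` (1 = death
    observed, 0 = censored), ``covariate`` (real; expression or
    standardized copy-number value).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = {"id", "time", "event", "covariate"}
        if not required <= set(t.columns):
            raise InputError(f"missing columns: {sorted(required - set(t.columns))}")
        if (t["time"] <= 0).any():
            raise InputError("times must be positive")
        if not t["event"].isin([0, 1]).all():
            raise InputError("event must be 0/1")
        if t["id"].duplicated().any():
            raise InputError("duplicate patient ids")

    def __len__(self) -> int:
        return len(self.table)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "SurvivalTable":
        return cls(pd.read_csv(path, sep="\t"))


@dataclass
class KMCurve:
    """Product-limit survival curve: event times, S(t) and at-risk counts."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray

    def at(self, t: float) -> float:
        """S(t); right-continuous step function with S(0) = 1."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(table: SurvivalTable) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    ``S(t) = prod_{t_i <= t} (1 - d_i / n_i)`` over distinct event times
    ``t_i`` with ``d_i`` deaths among ``n_i`` at risk; censored-only data
    give S = 1 everywhere.  Ties are handled with the standard
    simultaneous-risk-set convention.
    """
    t = table.table
    if len(t) < 1:
        raise InputError("need at least one subject")
    times = t["time"].to_numpy(dtype=float)
    events = t["event"].to_numpy(dtype=int)
    order = np.argsort(times, kind="mergesort")
    times, events = times[order], events[order]
    uniq = np.unique(times[events == 1])
    surv, at_risk, n_events = [], [], []
    s = 1.0
    for u in uniq:
        n_i = int(np.sum(times >= u))
        d_i = int(np.sum((times == u) & (events == 1)))
        s *= 1.0 - d_i / n_i
        surv.append(s)
        at_risk.append(n_i)
        n_events.append(d_i)
    return KMCurve(uniq, np.asarray(surv), np.asarray(at_risk, dtype=int), np.asarray(n_events, dtype=int))


def _logrank_many(times: np.ndarray, events: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """Log-rank chi-square for many binary groupings at once.

    ``groups`` is a ``(n_splits, n_patients)`` 0/1 matrix; returns one
    chi-square (1 df) per row.  Uses the hypergeometric mean/variance of
    the group-1 death count at each distinct event time.
    """
    uniq = np.unique(times[events == 1])
    if uniq.size == 0:
        return np.zeros(groups.shape[0])
    # at-risk and death indicator matrices, patients x event-times
    at_risk = times[:, None] >= uniq[None, :]
    death = (times[:, None] == uniq[None, :]) & (events[:, None] == 1)
    n_i = at_risk.sum(axis=0).astype(float)          # (T,)
    d_i = death.sum(axis=0).astype(float)            # (T,)
    g = groups.astype(float)
    n1_i = g @ at_risk                               # (S, T)
    o1_i = g @ death                                 # (S, T)
    with np.errstate(invalid="ignore", divide="ignore"):
        e1_i = d_i * n1_i / n_i
        v_i = d_i * (n1_i / n_i) * (1.0 - n1_i / n_i) * (n_i - d_i) / np.maximum(n_i - 1.0, 1.0)
    e1_i = np.nan_to_num(e1_i)
    v_i = np.nan_to_num(v_i)
    num = (o1_i - e1_i).sum(axis=1) ** 2
    den = v_i.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = np.where(den > 0, num / den, 0.0)
    return chi2


def logrank_test(table: SurvivalTable, groups) -> tuple[float, float]:
    """Two-group log-rank test.

    ``groups`` is a binary vector aligned with the table rows.  Returns
    ``(chi_square, p_value)`` with 1 degree of freedom; the statistic is
    invariant under swapping the group labels.
    """
    from scipy import stats as sps

    g = np.asarray(groups).astype(int)
    t = table.table
    if g.shape[0] != len(t):
        raise InputError("group labels must align with the table")
    if len(np.unique(g)) != 2:
        raise InputError("need exactly two non-empty groups")
    chi2 = float(
        _logrank_many(
            t["time"].to_numpy(dtype=float), t["event"].to_numpy(dtype=int), g[None, :]
        )[0]
    )
    return chi2, float(sps.chi2.sf(chi2, df=1))


@dataclass
class CutpointResult:
    """Outcome of the optimal-partitioning scan.

    ``cutpoint_rank`` is the number of patients in the low-covariate
    group; ``cut_value`` the covariate value at the boundary.  The
    ``adjusted_p`` is the permutation-adjusted p of the minimum-p scan
    (probability, under covariate permutation, of seeing an equal or
    smaller minimum p anywhere in the admissible range) and is never
    smaller than the raw p it adjusts.
    """

    cutpoint_rank: int
    cut_value: float
    group_sizes: tuple[int, int]
    chi_square: float
    p_value: float
    adjusted_p: float
    hazard_ratio: float
    hr_ci: tuple[float, float]
    scan: pd.DataFrame


def _scan_chi2(times, events, order, lo, hi) -> np.ndarray:
    n = len(order)
    splits = np.arange(lo, hi + 1)
    groups = np.zeros((splits.size, n), dtype=float)
    for i, r in enumerate(splits):
        groups[i, order[r:]] = 1.0  # high-covariate group
    return _logrank_many(times, events, groups)


def optimal_cutpoint(
    table: SurvivalTable,
    min_group_fraction: float = 0.1,
    n_perm: int = 200,
    seed: int = 0,
) -> CutpointResult:
    """Optimal covariate cutpoint maximizing log-rank significance.

    Patients are ranked by the covariate; every split leaving at least
    ``min_group_fraction`` of the cohort on each side is scored by the
    log-rank chi-square (the Cox score test for the binary grouping).
    The split with the largest chi-square (smallest p) is returned,
    together with a permutation-adjusted p: the covariate is permuted
    ``n_perm`` times, the full scan repeated, and the adjusted p is the
    fraction of permutations whose best chi-square beats the observed one
    (with the (r+1)/(n_perm+1) pseudocount).
    """
    from scipy import stats as sps

    t = table.table
    n = len(t)
    if n < 20:
        raise InputError("need at least 20 patients")
    cov = t["covariate"].to_numpy(dtype=float)
    if np.ptp(cov) == 0:
        raise InputError("covariate is constant")
    if not 0.0 < min_group_fraction <= 0.5:
        raise ParameterError("min_group_fraction must be in (0, 0.5]")
    times = t["time"].to_numpy(dtype=float)
    events = t["event"].to_numpy(dtype=int)
    order = np.argsort(cov, kind="mergesort")

    lo = max(1, int(np.ceil(min_group_fraction * n)))
    hi = n - lo
    if hi < lo:
        raise ParameterError("min_group_fraction leaves no admissible split")

    chi2s = _scan_chi2(times, events, order, lo, hi)
    best_idx = int(np.argmax(chi2s))
    best_rank = lo + best_idx
    best_chi2 = float(chi2s[best_idx])
    raw_p = float(sps.chi2.sf(best_chi2, df=1))

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm_order = np.argsort(rng.permutation(n), kind="mergesort")
        perm_chi2 = _scan_chi2(times, events, perm_order, lo, hi).max()
        if perm_chi2 >= best_chi2:
            exceed += 1
    adjusted_p = (exceed + 1) / (n_perm + 1)
    adjusted_p = max(adjusted_p, raw_p)

    high = np.zeros(n, dtype=int)
    high[order[best_rank:]] = 1
    hr, ci = _binary_cox_hr(times, events, high)

    scan = pd.DataFrame(
        {
            "rank": np.arange(lo, hi + 1),
            "chi_square": chi2s,
            "p_value": sps.chi2.sf(chi2s, df=1),
        }
    )
    return CutpointResult(
        cutpoint_rank=best_rank,
        cut_value=float(np.sort(cov)[best_rank - 1]),
        group_sizes=(best_rank, n - best_rank),
        chi_square=best_chi2,
        p_value=raw_p,
        adjusted_p=float(adjusted_p),
        hazard_ratio=hr,
        hr_ci=ci,
        scan=scan,
    )


def _binary_cox_hr(times, events, group) -> tuple[float, tuple[float, float]]:
    """Hazard ratio of a binary group from a univariate Cox fit (lifelines)."""
    from lifelines import CoxPHFitter

    df = pd.DataFrame({"time": times, "event": events, "group": group})
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph = CoxPHFitter()
            cph.fit(df, duration_col="time", event_col="event")
        hr = float(np.exp(cph.params_["group"]))
        ci_raw = cph.confidence_intervals_.loc["group"].to_numpy()
        ci = (float(np.exp(ci_raw[0])), float(np.exp(ci_raw[1])))
    except Exception:  # degenerate separation; HR undefined
        hr, ci = float("nan"), (float("nan"), float("nan"))
    return hr, ci


def fixed_group_compare(table: SurvivalTable, group_labels) -> pd.DataFrame:
    """Pairwise log-rank comparison of predefined patient categories.

    Categories with fewer than two patients are dropped with a warning.
    Returns one row per unordered category pair with the log-rank
    chi-square, raw p and BH q across the pairs; KM curves per category
    are available through :func:`km_estimate` on the per-category tables.
    """
    labels = pd.Series(list(group_labels), index=table.table.index)
    counts = labels.value_counts()
    keep = counts[counts >= 2].index
    dropped = sorted(set(counts.index) - set(keep))
    if dropped:
        warnings.warn(f"dropping categories with < 2 patients: {dropped}")
    if len(keep) < 2:
        raise InputError("need at least two categories with >= 2 patients")
    rows = []
    for a, b in combinations(sorted(keep), 2):
        mask = labels.isin([a, b]).to_numpy()
        sub = SurvivalTable(table.table[mask].reset_index(drop=True))
        g = (labels[mask] == b).astype(int).to_numpy()
        chi2, p = logrank_test(sub, g)
        rows.append((a, b, chi2, p))
    out = pd.DataFrame(rows, columns=["group_a", "group_b", "chi_square", "p_value"])
    out["q_value"] = bh_fdr(out["p_value"].to_numpy())
    return out
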