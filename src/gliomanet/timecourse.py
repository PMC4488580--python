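"""Time-course machinery for the tumour-implantation expression series.

Implements the dynamic-map pipeline for a genes x ordered-time-points
expression course sampled every 12 hours: a two-step differential
expression filter (minimum log2 range, then a permutation-calibrated
smoothness filter removing noisy genes), partitioning-around-medoids
clustering on correlation distance, response-time classification at 50%
of the dynamic range, cubic interpolation of medoid profiles to a dense
uniform grid, and the time-delay Spearman correlation map linking
clusters whose profiles match after a 13-24 hour shift.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import CubicSpline

from gliomanet._util import InputError, ParameterError

__all__ = [
    "TimeCourse",
    "timecourse_de_filter",
    "ClusterSet",
    "cluster_profiles",
    "classify_response",
    "interpolate_profile",
    "LagCorrelation",
    "lag_correlation",
    "build_dynamic_map",
]

#: response-class windows in hours on the continuous interpolated axis;
#: the (24, 36] gap deliberately maps to "unclassified"
RESPONSE_WINDOWS = {
    "rapid": (0.0, 12.0),
    "intermediate": (12.0, 24.0),
    "delayed": (36.0, 48.0),
}


@dataclass
class TimeCourse:
    """Genes x time-points log2 expression with a strictly increasing clock."""

    data: pd.DataFrame  # index: gene ids, columns: anything; times carried apart
    times_h: np.ndarray

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        if self.times_h.ndim != 1 or len(self.times_h) != self.data.shape[1]:
            raise InputError("times_h must match the number of columns")
        if np.any(np.diff(self.times_h) <= 0):
            raise InputError("times must be strictly increasing")
        if self.data.index.has_duplicates:
            raise InputError("duplicate gene identifiers")
        if not np.all(np.isfinite(self.data.to_numpy(dtype=float))):
            raise InputError("values must be finite")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    def to_tsv(self, path) -> None:
        out = self.data.copy()
        out.columns = [f"{t:g}" for t in self.times_h]
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "TimeCourse":
        df = pd.read_csv(path, sep="\t", index_col=0)
        times = np.array([float(c) for c in df.columns])
        return cls(df, times)


def _smoothness_stat(values: np.ndarray) -> np.ndarray:
    """Signal-to-residual variance ratio from a moving-average fit.

    A window-3 moving average is the low-frequency fit; the statistic is
    var(fit) / var(residual).  Smooth, genuinely time-structured profiles
    score high; profiles that are noise in time score near the ratio's
    null distribution.
    """
    v = np.atleast_2d(values)
    padded = np.pad(v, ((0, 0), (1, 1)), mode="edge")
    fit = (padded[:, :-2] + padded[:, 1:-1] + padded[:, 2:]) / 3.0
    resid = v - fit
    num = fit.var(axis=1)
    den = resid.var(axis=1)
    return num / np.maximum(den, 1e-12)


def timecourse_de_filter(
    tc: TimeCourse,
    min_log2_range: float = 1.0,
    alpha: float = 0.001,
    seed: int = 0,
    n_perm: int = 30,
) -> set[str]:
    """Two-step selection of genes regulated along the time course.

    Step 1 keeps genes whose profile spans at least ``min_log2_range``
    log2 units.  Step 2 removes noisy genes: each surviving profile's
    smoothness statistic (low-frequency variance over residual variance
    from a moving-average fit) is compared with a null built by
    time-shuffling all surviving profiles ``n_perm`` times, and genes
    below the pooled ``1 - alpha`` null quantile are dropped.
    """
    if len(tc.times_h) < 4:
        raise InputError("need at least 4 time points")
    x = tc.data.to_numpy(dtype=float)
    ranges = x.max(axis=1) - x.min(axis=1)
    step1 = ranges >= min_log2_range
    if not step1.any():
        return set()
    xs = x[step1]
    obs = _smoothness_stat(xs)
    rng = np.random.default_rng(seed)
    t = xs.shape[1]
    null = np.empty((n_perm, xs.shape[0]))
    for i in range(n_perm):
        null[i] = _smoothness_stat(xs[:, rng.permutation(t)])
    cutoff = np.quantile(null.ravel(), 1.0 - alpha)
    keep = obs > cutoff
    genes = np.asarray(tc.gene_ids)[step1]
    return set(genes[keep])


@dataclass
class ClusterSet:
    """PAM clustering result over a time course.

    ``members`` maps cluster id -> gene set; ``medoids`` maps cluster id
    -> medoid profile (vector over ``times_h``); ``summary`` carries
    dynamic range, response time and response class per cluster.
    """

    members: dict[int, set]
    medoids: dict[int, np.ndarray]
    times_h: np.ndarray
    summary: pd.DataFrame
    silhouette: float

    def __post_init__(self) -> None:
        seen: set = set()
        for c in self.members.values():
            if seen & c:
                raise InputError("clusters must be disjoint")
            seen |= c


def _correlation_distance(x: np.ndarray) -> np.ndarray:
    c = np.corrcoef(x)
    c = np.clip(np.nan_to_num(c, nan=0.0), -1.0, 1.0)
    np.fill_diagonal(c, 1.0)
    return 1.0 - c


def _pam(dist: np.ndarray, k: int, max_iter: int = 100):
    """Partitioning around medoids on a precomputed distance matrix.

    Greedy BUILD initialization followed by alternating assign/update
    (Voronoi iteration); fully deterministic (argmin/argmax break exact
    cost ties by index).
    """
    n = dist.shape[0]
    # BUILD: first medoid minimizes total distance, others maximize gain
    medoids = [int(np.argmin(dist.sum(axis=1)))]
    while len(medoids) < k:
        current = dist[:, medoids].min(axis=1)
        gain = np.maximum(current[None, :] - dist, 0.0).sum(axis=1)
        gain[medoids] = -np.inf
        medoids.append(int(np.argmax(gain)))
    medoids = np.asarray(medoids)
    for _ in range(max_iter):
        assign = np.argmin(dist[:, medoids], axis=1)
        new_medoids = medoids.copy()
        for j in range(k):
            idx = np.where(assign == j)[0]
            if idx.size == 0:
                continue
            within = dist[np.ix_(idx, idx)].sum(axis=1)
            new_medoids[j] = idx[int(np.argmin(within))]
        if np.array_equal(np.sort(new_medoids), np.sort(medoids)):
            break
        medoids = new_medoids
    assign = np.argmin(dist[:, medoids], axis=1)
    return medoids, assign


def cluster_profiles(tc: TimeCourse, k: int, seed: int = 0) -> ClusterSet:
    """PAM clustering of gene profiles on correlation distance.

    Distance is ``1 - Pearson(profile_i, profile_j)``; the medoid profile
    of each cluster is an actual member minimizing total within-cluster
    distance.  The mean silhouette width over the partition is reported
    so ``k`` can be chosen by scanning when it is not fixed a priori.
    """
    n = tc.data.shape[0]
    if k < 1:
        raise ParameterError("k must be >= 1")
    if k > n:
        raise ParameterError("k exceeds the number of genes")
    x = tc.data.to_numpy(dtype=float)
    dist = _correlation_distance(x)
    medoids, assign = _pam(dist, k)

    genes = np.asarray(tc.gene_ids)
    members = {j: set(genes[assign == j]) for j in range(k) if (assign == j).any()}
    medoid_profiles = {j: x[medoids[j]].copy() for j in members}

    sil = _mean_silhouette(dist, assign) if k > 1 else 0.0

    rows = []
    for j in sorted(members):
        profile = medoid_profiles[j]
        rng_dyn = float(profile.max() - profile.min())
        if rng_dyn > 0:
            t50, cls = classify_response(profile, tc.times_h)
        else:
            t50, cls = np.nan, "unclassified"
        rows.append((j, len(members[j]), rng_dyn, t50, cls))
    summary = pd.DataFrame(
        rows, columns=["cluster", "size", "dynamic_range", "response_time_h", "response_class"]
    ).set_index("cluster")
    return ClusterSet(members, medoid_profiles, tc.times_h, summary, float(sil))


def _mean_silhouette(dist: np.ndarray, assign: np.ndarray) -> float:
    n = dist.shape[0]
    labels = np.unique(assign)
    if len(labels) < 2:
        return 0.0
    s = np.zeros(n)
    for i in range(n):
        own = assign[i]
        same = (assign == own) & (np.arange(n) != i)
        a = dist[i, same].mean() if same.any() else 0.0
        b = min(dist[i, assign == lab].mean() for lab in labels if lab != own)
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return float(s.mean())


def interpolate_profile(medoid, times_h, n_points: int = 100) -> tuple[np.ndarray, np.ndarray]:
    """Cubic interpolation of a profile onto a dense uniform grid.

    A natural cubic spline through the knots, evaluated on ``n_points``
    uniformly spaced times spanning the sampled interval.  Endpoint
    values are preserved exactly.  Returns ``(grid_times, values)``.
    """
    times_h = np.asarray(times_h, dtype=float)
    medoid = np.asarray(medoid, dtype=float)
    if len(times_h) < 3:
        raise InputError("need at least 3 time points")
    if np.any(np.diff(times_h) <= 0):
        raise InputError("duplicate or decreasing times")
    grid = np.linspace(times_h[0], times_h[-1], n_points)
    spline = CubicSpline(times_h, medoid, bc_type="natural")
    values = spline(grid)
    values[0], values[-1] = medoid[0], medoid[-1]
    return grid, values


def classify_response(medoid, times_h, n_points: int = 100) -> tuple[float, str]:
    """Response time and class of a profile from the 50%-range crossing.

    The response time is the earliest interpolated time at which the
    profile has moved at least half of its dynamic range away from its
    initial value.  Classes: rapid (up to 12 h), intermediate (12-24 h],
    delayed (36-48 h]; crossings in the (24, 36] gap or beyond 48 h are
    unclassified.  The result is invariant to affine rescaling of the
    expression values.
    """
    medoid = np.asarray(medoid, dtype=float)
    dyn = medoid.max() - medoid.min()
    if dyn == 0:
        raise InputError("constant profile has zero dynamic range")
    grid, values = interpolate_profile(medoid, times_h, n_points)
    moved = np.abs(values - values[0]) >= 0.5 * dyn
    if not moved.any():
        return float("nan"), "unclassified"
    t50 = float(grid[int(np.argmax(moved))])
    # the crossing is reported at the first grid point past it, a bias of
    # up to one grid step; window upper edges are softened accordingly
    eps = float(grid[1] - grid[0]) + 1e-9
    for cls, (lo, hi) in RESPONSE_WINDOWS.items():
        if (lo < t50 <= hi + eps) or (cls == "rapid" and t50 <= hi + eps):
            return t50, cls
    return t50, "unclassified"


@dataclass
class LagCorrelation:
    """Best lagged Spearman correlation between two interpolated profiles."""

    cluster_i: int
    cluster_j: int
    best_rho: float
    best_lag_h: float
    significant: bool


def lag_correlation(
    p1,
    p2,
    grid_h: float,
    lag_window_h: tuple[float, float] = (13.0, 24.0),
    rho_threshold: float = 0.9,
    absolute: bool = False,
    min_overlap: int = 10,
    pair: tuple[int, int] = (0, 1),
) -> LagCorrelation:
    """Time-delay Spearman correlation between two dense profiles.

    Spearman rho is evaluated at lag zero and at every grid lag whose
    absolute hour value falls within ``lag_window_h`` (both directions,
    overlapping segments only).  The maximum signed rho wins (with
    ``absolute=True``, the maximum |rho|); a pair is significant iff the
    best rho exceeds ``rho_threshold`` (default 0.9).  Positive lag means
    the second profile lags the first.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if p1.shape != p2.shape or p1.ndim != 1:
        raise InputError("profiles must be equal-length vectors")
    n = p1.size
    lo, hi = lag_window_h
    max_steps = int(np.floor(hi / grid_h))
    min_steps = int(np.ceil(lo / grid_h))
    candidate_steps = [0] + [
        s for s in range(min_steps, max_steps + 1)
    ] + [-s for s in range(min_steps, max_steps + 1)]

    best_rho, best_lag = -np.inf, 0.0
    evaluated = 0
    for s in candidate_steps:
        if s >= 0:
            a, b = p1[: n - s] if s else p1, p2[s:]
        else:
            a, b = p1[-s:], p2[: n + s]
        if a.size < min_overlap:
            continue
        evaluated += 1
        rho = float(stats.spearmanr(a, b).statistic)
        if np.isnan(rho):
            continue
        score = abs(rho) if absolute else rho
        if score > (abs(best_rho) if absolute else best_rho) or best_rho == -np.inf:
            best_rho, best_lag = rho, s * grid_h
    if evaluated == 0:
        raise InputError("no lag leaves enough overlap between the profiles")
    sig_value = abs(best_rho) if absolute else best_rho
    return LagCorrelation(pair[0], pair[1], best_rho, best_lag, bool(sig_value > rho_threshold))


def build_dynamic_map(
    clusters: ClusterSet,
    rho_threshold: float = 0.9,
    n_points: int = 100,
    lag_window_h: tuple[float, float] = (13.0, 24.0),
    absolute: bool = False,
) -> pd.DataFrame:
    """Time-delay correlation map over all unordered cluster pairs.

    Each pair of medoid profiles is interpolated to ``n_points`` and
    scored with :func:`lag_correlation`.  Positive ``best_lag_h`` means
    the second cluster of the pair lags the first.  Returns a DataFrame
    with columns ``cluster_i``, ``cluster_j``, ``best_rho``,
    ``best_lag_h``, ``significant``.
    """
    ids = sorted(clusters.medoids)
    interpolated = {}
    grid_h = None
    for j in ids:
        grid, values = interpolate_profile(clusters.medoids[j], clusters.times_h, n_points)
        interpolated[j] = values
        grid_h = grid[1] - grid[0]
    rows = []
    for i, j in combinations(ids, 2):
        lc = lag_correlation(
            interpolated[i],
            interpolated[j],
            grid_h,
            lag_window_h=lag_window_h,
            rho_threshold=rho_threshold,
            absolute=absolute,
            pair=(i, j),
        )
        rows.append((i, j, lc.best_rho, lc.best_lag_h, lc.significant))
    return pd.DataFrame(
        rows, columns=["cluster_i", "cluster_j", "best_rho", "best_lag_h", "significant"]
    )
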