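"""Hub-anchored mutual-information co-expression networks.

ARACNE-style reverse engineering: mutual information between a set of
designated hub genes (e.g. the Rho GTPase family) and every other gene,
estimated per condition, thresholded against a permutation null with
exponential-tail extrapolation for very stringent cutoffs (p < 1e-5 and
below), and pruned with the data-processing inequality (DPI).  The
per-hub connectivity contrast between two condition networks yields the
grade-specificity statistic: a bounded score ``d`` in [-1, 1] whose
absolute value above 0.4 calls a hub condition-specific.

MI is reported in nats.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from gliomanet._util import InputError, ParameterError
from gliomanet.expression import ExpressionMatrix

__all__ = [
    "estimate_mi",
    "MINull",
    "fit_mi_null",
    "mi_threshold",
    "MINetwork",
    "apply_dpi",
    "build_hub_network",
    "ConnectivityProfile",
    "grade_specificity",
]


def _default_bins(n: int) -> int:
    return max(2, int(np.floor(n ** (1.0 / 3.0))))


def _rank_bins(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency bin index per observation (rank binning).

    Ties are broken by position, which for continuous expression data is
    immaterial and keeps bin occupancies maximally balanced.
    """
    n = x.size
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(n, dtype=np.int64)
    ranks[order] = np.arange(n)
    return (ranks * n_bins) // n


def _mi_from_bins(bx: np.ndarray, by: np.ndarray, n_bins: int) -> float:
    """Plug-in MI with Miller-Madow bias correction, clipped at zero."""
    n = bx.size
    joint = np.bincount(bx * n_bins + by, minlength=n_bins * n_bins).astype(float)
    joint /= n
    px = joint.reshape(n_bins, n_bins).sum(axis=1)
    py = joint.reshape(n_bins, n_bins).sum(axis=0)
    nz = joint > 0
    outer = np.outer(px, py).ravel()
    mi = float(np.sum(joint[nz] * np.log(joint[nz] / outer[nz])))
    # Miller-Madow: correct each plug-in entropy by (occupied cells - 1)/(2n)
    kx = int(np.sum(px > 0))
    ky = int(np.sum(py > 0))
    kxy = int(np.sum(nz))
    mi += ((kx - 1) + (ky - 1) - (kxy - 1)) / (2.0 * n)
    return max(mi, 0.0)


def estimate_mi(x, y, n_bins: int | None = None) -> float:
    """Mutual information (nats) between two samples by rank binning.

    Equal-frequency binning with ``B = max(2, floor(n^(1/3)))`` bins by
    default, plug-in estimate with Miller-Madow correction.  Symmetric in
    its arguments and non-negative; a constant vector gives MI = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("x and y must be equal-length vectors")
    n = x.size
    if n < 8:
        raise InputError("need at least 8 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0
    b = n_bins or _default_bins(n)
    return _mi_from_bins(_rank_bins(x, b), _rank_bins(y, b), b)


@dataclass
class MINull:
    """Permutation null of the MI estimator with an exponential upper tail.

    ``values`` holds the permutation MI draws; the tail above the
    ``(1 - tail_frac)`` quantile is summarized by its mean excess, which
    extrapolates thresholds and p-values far below 1/n_perm (the
    stringent cutoffs, p < 1e-5 .. 1e-8, are unreachable by counting).
    """

    n_samples: int
    n_bins: int
    values: np.ndarray
    tail_frac: float
    tail_start: float
    mean_excess: float

    def threshold(self, alpha: float) -> float:
        """MI value whose null exceedance probability is ``alpha``."""
        if not 0.0 < alpha < 0.5:
            raise ParameterError("alpha must be in (0, 0.5)")
        if alpha >= self.tail_frac:
            return float(np.quantile(self.values, 1.0 - alpha))
        return float(self.tail_start + self.mean_excess * np.log(self.tail_frac / alpha))

    def p_value(self, mi: float) -> float:
        """Null exceedance probability of an observed MI."""
        if mi <= self.tail_start:
            return float(np.mean(self.values >= mi))
        if self.mean_excess <= 0:
            return 0.0
        return float(self.tail_frac * np.exp(-(mi - self.tail_start) / self.mean_excess))


def fit_mi_null(
    n_samples: int, n_perm: int, seed: int, n_bins: int | None = None
) -> MINull:
    """Fit the permutation null of MI between independent vectors.

    The estimator depends only on ranks, so the null is generated by
    scoring MI between a fixed rank vector and ``n_perm`` random
    permutations of it.
    """
    if n_perm < 1000:
        raise ParameterError("n_perm must be >= 1000")
    if n_samples < 8:
        raise ParameterError("n_samples must be >= 8")
    b = n_bins or _default_bins(n_samples)
    rng = np.random.default_rng(seed)
    base = _rank_bins(np.arange(n_samples, dtype=float), b)
    vals = np.empty(n_perm)
    for i in range(n_perm):
        vals[i] = _mi_from_bins(base, base[rng.permutation(n_samples)], b)
    tail_frac = max(0.05, 20.0 / n_perm)
    tail_start = float(np.quantile(vals, 1.0 - tail_frac))
    exceed = vals[vals > tail_start] - tail_start
    mean_excess = float(exceed.mean()) if exceed.size else 0.0
    return MINull(n_samples, b, vals, tail_frac, tail_start, mean_excess)


def mi_threshold(
    n_samples: int,
    alpha: float,
    n_perm: int = 2000,
    seed: int = 0,
    n_bins: int | None = None,
) -> float:
    """MI significance threshold at level ``alpha`` (permutation null)."""
    return fit_mi_null(n_samples, n_perm, seed, n_bins).threshold(alpha)


@dataclass
class MINetwork:
    """Hub-anchored MI network for one condition.

    ``edges`` columns: ``hub``, ``target``, ``mi`` (nats), ``p_value``.
    Every edge is incident to at least one declared hub; hub-hub edges
    appear once with both endpoints in the hub list.
    """

    condition: str
    hubs: list[str]
    edges: pd.DataFrame
    n_samples: int
    alpha: float
    skipped_hubs: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.edges):
            hub_set = set(self.hubs)
            if not (
                self.edges["hub"].isin(hub_set) | self.edges["target"].isin(hub_set)
            ).all():
                raise InputError("every edge must be incident to a declared hub")
            if (self.edges["mi"] < 0).any():
                raise InputError("MI must be non-negative")

    def degree(self, node: str) -> int:
        return int(
            ((self.edges["hub"] == node) | (self.edges["target"] == node)).sum()
        )

    def to_tsv(self, path) -> None:
        self.edges.to_csv(path, sep="\t", index=False)


def apply_dpi(net: MINetwork, tolerance: float = 0.0) -> MINetwork:
    """Data-processing-inequality pruning over fully present triangles.

    For every triangle (i, j, k) present in the network, the edge (i, j)
    is removed iff ``MI_ij < (1 - tolerance) * min(MI_ik, MI_jk)``.  All
    triangles are evaluated against the pre-pruning network
    (simultaneously, not sequentially), so the result does not depend on
    edge order.
    """
    if not 0.0 <= tolerance < 1.0:
        raise ParameterError("tolerance must be in [0, 1)")
    if not len(net.edges):
        return net
    mi = {frozenset((r.hub, r.target)): r.mi for r in net.edges.itertuples()}
    adj: dict[str, set[str]] = {}
    for e in mi:
        u, v = tuple(e)
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    drop: set[frozenset] = set()
    for u, v in (tuple(e) for e in mi):
        for w in adj[u] & adj[v]:
            m_uv = mi[frozenset((u, v))]
            m_uw = mi[frozenset((u, w))]
            m_vw = mi[frozenset((v, w))]
            if m_uv < (1.0 - tolerance) * min(m_uw, m_vw):
                drop.add(frozenset((u, v)))
    keep = net.edges[
        [frozenset((r.hub, r.target)) not in drop for r in net.edges.itertuples()]
    ].reset_index(drop=True)
    return MINetwork(net.condition, net.hubs, keep, net.n_samples, net.alpha, net.skipped_hubs)


def build_hub_network(
    expr: ExpressionMatrix,
    condition: str | None,
    hubs,
    alpha: float = 1e-5,
    tolerance: float = 0.0,
    seed: int = 0,
    n_perm: int = 2000,
    null: MINull | None = None,
) -> MINetwork:
    """Infer the hub-anchored MI network for one condition.

    MI is computed hub-vs-all (including hub-vs-hub), edges above the
    permutation-null threshold at level ``alpha`` are kept with their
    extrapolated p-values, and DPI pruning is applied over triangles
    whose three nodes are all in the network.  Hubs absent from the
    matrix are reported in ``skipped_hubs`` rather than raising.

    ``condition=None`` uses every sample (the static time-course network).
    A pre-fitted ``null`` may be supplied to share one permutation null
    across conditions of equal sample size.
    """
    samples = expr.sample_ids if condition is None else expr.samples_for(condition)
    if len(samples) < 8:
        raise InputError(f"need >= 8 samples for condition {condition!r}")
    hubs = list(hubs)
    present = [h for h in hubs if h in expr.data.index]
    skipped = [h for h in hubs if h not in expr.data.index]
    label = condition if condition is not None else "all"
    columns = ["hub", "target", "mi", "p_value"]
    if not present:
        return MINetwork(label, present, pd.DataFrame(columns=columns), len(samples), alpha, skipped)

    x = expr.data[samples].to_numpy(dtype=float)
    genes = list(expr.data.index)
    n = len(samples)
    b = _default_bins(n)
    if null is None:
        null = fit_mi_null(n, n_perm, seed, b)
    thr = null.threshold(alpha)

    bins = np.empty((len(genes), n), dtype=np.int64)
    constant = np.zeros(len(genes), dtype=bool)
    for i in range(len(genes)):
        constant[i] = np.ptp(x[i]) == 0
        bins[i] = _rank_bins(x[i], b)
    gene_index = {g: i for i, g in enumerate(genes)}
    hub_set = set(present)

    rows = []
    seen_pairs: set[frozenset] = set()
    for h in present:
        hi = gene_index[h]
        if constant[hi]:
            continue
        for g in genes:
            if g == h:
                continue
            pair = frozenset((h, g))
            if g in hub_set and pair in seen_pairs:
                continue
            gi = gene_index[g]
            if constant[gi]:
                continue
            m = _mi_from_bins(bins[hi], bins[gi], b)
            if m >= thr:
                rows.append((h, g, m, null.p_value(m)))
                if g in hub_set:
                    seen_pairs.add(pair)
    net = MINetwork(label, present, pd.DataFrame(rows, columns=columns), n, alpha, skipped)
    return apply_dpi(net, tolerance)


@dataclass
class ConnectivityProfile:
    """Per-hub connectivity contrast between two condition networks.

    ``table`` columns: ``degree_a``, ``degree_b``, ``khat_a``, ``khat_b``
    (degree normalized by the network's total hub-incident edge count),
    ``d`` = (khat_a - khat_b)/(khat_a + khat_b) in [-1, 1] (positive
    toward condition A), ``specificity_class`` in {A-specific,
    B-specific, non-specific} and ``undefined`` flagging hubs with zero
    degree in both networks.
    """

    table: pd.DataFrame
    condition_a: str
    condition_b: str
    threshold: float

    def specific_hubs(self, condition: str) -> set[str]:
        cls = f"{condition}-specific"
        return set(self.table.index[self.table["specificity_class"] == cls])


def grade_specificity(
    net_a: MINetwork, net_b: MINetwork, threshold: float = 0.4
) -> ConnectivityProfile:
    """Condition-specificity of each hub from its normalized degrees.

    Degrees are normalized within each network by the total number of
    hub-incident edges, so networks of different size are comparable.
    A hub with ``|d| > threshold`` (default 0.4) is called specific to
    the condition with the larger normalized degree; a hub unconnected in
    both networks has undefined ``d`` and is flagged non-specific.
    """
    if set(net_a.hubs) != set(net_b.hubs):
        raise InputError("the two networks must share the hub list")
    tot_a = max(len(net_a.edges), 1)
    tot_b = max(len(net_b.edges), 1)
    rows = []
    for h in net_a.hubs:
        da, db = net_a.degree(h), net_b.degree(h)
        ka, kb = da / tot_a, db / tot_b
        if da == 0 and db == 0:
            d, cls, undef = 0.0, "non-specific", True
        else:
            d = (ka - kb) / (ka + kb)
            undef = False
            if d > threshold:
                cls = f"{net_a.condition}-specific"
            elif d < -threshold:
                cls = f"{net_b.condition}-specific"
            else:
                cls = "non-specific"
        rows.append((da, db, ka, kb, d, cls, undef))
    table = pd.DataFrame(
        rows,
        index=pd.Index(net_a.hubs, name="hub"),
        columns=["degree_a", "degree_b", "khat_a", "khat_b", "d", "specificity_class", "undefined"],
    )
    return ConnectivityProfile(table, net_a.condition, net_b.condition, threshold)
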