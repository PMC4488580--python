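"""Synthetic inputs with planted ground truth for every pipeline stage.

The generators emulate the study conditions the pipeline was designed
for — a two-condition clinical expression contrast (45 low-grade vs 81
high-grade samples), a scale-free protein interactome with a planted
high-prize module, a 10-point time course sampled every 12 hours with
sigmoidal cluster responses and planted 13-24 h lags, interactor lists
overlapping the planted module, and survival cohorts with a
proportional-hazards link to one gene — while recording the planted
truth so downstream recovery is checkable.

All generators are bit-reproducible given their parameters and seed, and
use one explicit :class:`numpy.random.Generator` per call (no hidden
global state).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from gliomanet._util import InputError, ParameterError
from gliomanet.expression import ExpressionMatrix
from gliomanet.survival import SurvivalTable
from gliomanet.timecourse import TimeCourse

__all__ = [
    "SyntheticTruth",
    "make_interactome",
    "plant_regulators",
    "make_two_condition_expression",
    "make_timecourse",
    "make_survival",
]


@dataclass
class SyntheticTruth:
    """The planted ground truth behind one synthetic dataset family."""

    gene_ids: list[str] = field(default_factory=list)
    regulator_ids: list[str] = field(default_factory=list)
    #: hub -> (targets coupled in condition A, targets coupled in condition B)
    condition_specific_targets: dict[str, tuple[set, set]] = field(default_factory=dict)
    planted_module: set = field(default_factory=set)
    de_genes: set = field(default_factory=set)
    #: (cluster_i, cluster_j) -> lag in hours (j lags i)
    planted_lags: dict[tuple[int, int], float] = field(default_factory=dict)
    response_times_h: list[float] = field(default_factory=list)
    survival_gene: str | None = None
    hazard_ratio: float = 1.0
    seed: int = 0

    def validate(self, graph: nx.Graph | None = None) -> None:
        universe = set(self.gene_ids)
        for hub, (ta, tb) in self.condition_specific_targets.items():
            if ta & tb:
                raise InputError(f"targets of hub {hub!r} overlap across conditions")
            if universe and not ({hub} | ta | tb) <= universe:
                raise InputError(f"hub {hub!r} references genes outside the universe")
        if universe and not self.planted_module <= universe:
            raise InputError("planted module references genes outside the universe")
        if graph is not None and self.planted_module:
            sub = graph.subgraph(self.planted_module)
            if not nx.is_connected(sub):
                raise InputError("planted module must induce a connected subgraph")

    def to_yaml(self, path) -> None:
        doc = {
            "gene_ids": list(self.gene_ids),
            "regulator_ids": list(self.regulator_ids),
            "condition_specific_targets": {
                h: {"A": sorted(ta), "B": sorted(tb)}
                for h, (ta, tb) in self.condition_specific_targets.items()
            },
            "planted_module": sorted(self.planted_module),
            "de_genes": sorted(self.de_genes),
            "planted_lags": {f"{i},{j}": float(v) for (i, j), v in self.planted_lags.items()},
            "response_times_h": [float(t) for t in self.response_times_h],
            "survival_gene": self.survival_gene,
            "hazard_ratio": float(self.hazard_ratio),
            "seed": int(self.seed),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)


def _gene_names(n: int, prefix: str = "G") -> list[str]:
    width = max(4, len(str(n)))
    return [f"{prefix}{i:0{width}d}" for i in range(n)]


def make_interactome(
    n_nodes: int,
    attach_m: int,
    module_size: int,
    seed: int,
    module_edge_prob: float = 0.0,
) -> tuple[nx.Graph, SyntheticTruth]:
    """Scale-free interactome with a planted connected module.

    Preferential attachment (Barabasi-Albert with ``attach_m`` edges per
    new node) gives the heavy-tailed degree structure that makes hub
    detection meaningful.  The planted module is grown as a randomized
    breadth-first neighbourhood from a random root, so it induces a
    connected subgraph without altering the degree sequence; with
    ``module_edge_prob > 0`` each missing internal pair is additionally
    wired with that probability, giving the module the internal density
    real functional modules show (and community detection something to
    find).  The graph stays simple and connected.
    """
    if attach_m < 1:
        raise ParameterError("attach_m must be >= 1")
    if not 0 < module_size < n_nodes:
        raise ParameterError("module_size must satisfy 0 < module_size < n_nodes")
    if not 0.0 <= module_edge_prob <= 1.0:
        raise ParameterError("module_edge_prob must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    g_int = nx.barabasi_albert_graph(n_nodes, attach_m, seed=int(rng.integers(2**31 - 1)))
    names = _gene_names(n_nodes)
    graph = nx.relabel_nodes(g_int, dict(enumerate(names)))

    # randomized BFS: the visited set at any prefix induces a connected subgraph
    root = names[int(rng.integers(n_nodes))]
    module: list[str] = [root]
    frontier = [root]
    visited = {root}
    while len(module) < module_size:
        candidates = sorted(
            {nb for v in frontier for nb in graph.neighbors(v)} - visited
        )
        if not candidates:  # cannot happen on a connected graph before n_nodes
            break
        pick = candidates[int(rng.integers(len(candidates)))]
        visited.add(pick)
        module.append(pick)
        frontier.append(pick)
    if module_edge_prob > 0:
        for i in range(len(module)):
            for j in range(i + 1, len(module)):
                u, v = module[i], module[j]
                if not graph.has_edge(u, v) and rng.random() < module_edge_prob:
                    graph.add_edge(u, v)

    truth = SyntheticTruth(
        gene_ids=names, planted_module=set(module), seed=seed
    )
    truth.validate(graph)
    return graph, truth


def plant_regulators(
    truth: SyntheticTruth,
    n_hubs: int,
    targets_per_condition: int,
    seed: int,
) -> SyntheticTruth:
    """Designate hub genes with condition-specific target sets.

    The first half of the hubs couple to their targets in condition A
    only, the second half in condition B only — the planted connectivity
    switch the grade-specificity statistic is meant to recover.  Hubs and
    target sets never overlap.
    """
    n_genes = len(truth.gene_ids)
    need = n_hubs * (1 + targets_per_condition)
    if need > n_genes:
        raise ParameterError("gene universe too small for the requested regulators")
    rng = np.random.default_rng(seed)
    picks = rng.choice(n_genes, size=need, replace=False)
    genes = np.asarray(truth.gene_ids)
    hubs = [str(g) for g in genes[picks[:n_hubs]]]
    rest = genes[picks[n_hubs:]]
    truth.regulator_ids = hubs
    truth.condition_specific_targets = {}
    n_a = n_hubs // 2 + n_hubs % 2
    for i, hub in enumerate(hubs):
        base = i * targets_per_condition
        targets = {str(g) for g in rest[base : base + targets_per_condition]}
        truth.condition_specific_targets[hub] = (
            (targets, set()) if i < n_a else (set(), targets)
        )
    truth.validate()
    return truth


def make_two_condition_expression(
    truth: SyntheticTruth,
    n_samples_a: int = 45,
    n_samples_b: int = 81,
    target_corr: float = 0.8,
    noise_sd: float = 1.0,
    seed: int = 0,
    n_de_genes: int = 0,
    de_shift: float = 2.0,
    cond_a: str = "gradeII",
    cond_b: str = "gradeIV",
) -> ExpressionMatrix:
    """Two-condition log2 expression with condition-specific coupling.

    Every gene is baseline independent Gaussian noise with standard
    deviation ``noise_sd``.  For each hub in the truth, its condition-A
    targets are linearly coupled to the hub only within condition-A
    samples (``target = a * hub + e`` with the slope chosen so the
    population correlation equals ``target_corr``), and analogously for
    condition B.  ``n_de_genes`` genes (preferentially drawn from the
    planted module) additionally receive a ``de_shift`` mean offset in
    condition B, creating a differential-expression signature.

    The default sample sizes mirror a 45 vs 81 clinical contrast.
    """
    if not 0.0 < target_corr < 1.0:
        # the degenerate noiseless case is handled by clamping just below 1
        raise ParameterError("target_corr must lie strictly between 0 and 1")
    if n_samples_a < 1 or n_samples_b < 1:
        raise ParameterError("both conditions need at least one sample")
    if noise_sd < 0:
        raise ParameterError("noise_sd must be positive")
    rng = np.random.default_rng(seed)
    genes = truth.gene_ids
    if not genes:
        raise InputError("truth carries no gene universe")
    n = n_samples_a + n_samples_b
    index = {g: i for i, g in enumerate(genes)}
    sd = noise_sd if noise_sd > 0 else 1.0
    x = rng.normal(0.0, sd, size=(len(genes), n))

    cols_a = np.arange(n_samples_a)
    cols_b = np.arange(n_samples_a, n)
    r = target_corr
    slope = r / np.sqrt(1.0 - r * r)  # with unit-variance residual noise
    for hub, (targets_a, targets_b) in truth.condition_specific_targets.items():
        h = x[index[hub]]
        for targets, cols in ((targets_a, cols_a), (targets_b, cols_b)):
            for tgt in targets:
                ti = index[tgt]
                if noise_sd == 0:
                    x[ti, cols] = h[cols]  # exact linear dependence
                else:
                    x[ti, cols] = slope * h[cols] + x[ti, cols]

    de_genes: set = set()
    if n_de_genes:
        pool = sorted(truth.planted_module) + [
            g for g in genes if g not in truth.planted_module
        ]
        de_genes = set(pool[:n_de_genes])
        for g in de_genes:
            x[index[g], cols_b] += de_shift
    truth.de_genes = de_genes

    samples = [f"{cond_a}_{i:03d}" for i in range(n_samples_a)] + [
        f"{cond_b}_{i:03d}" for i in range(n_samples_b)
    ]
    conditions = {s: cond_a for s in samples[:n_samples_a]}
    conditions.update({s: cond_b for s in samples[n_samples_a:]})
    return ExpressionMatrix(pd.DataFrame(x, index=genes, columns=samples), conditions)


def _logistic_profile(times: np.ndarray, t50: float, amplitude: float, steep: float) -> np.ndarray:
    return amplitude / (1.0 + np.exp(-steep * (times - t50)))


def _pulse_profile(
    times: np.ndarray, t50: float, amplitude: float, steep: float, width: float
) -> np.ndarray:
    """Transient response: logistic rise at ``t50`` and decay ``width`` later.

    Non-monotone in time, which is what lets rank correlation localize a
    time shift — a rank statistic cannot tell two monotone profiles apart
    at any lag.
    """
    rise = 1.0 / (1.0 + np.exp(-steep * (times - t50)))
    fall = 1.0 / (1.0 + np.exp(steep * (times - t50 - width)))
    return amplitude * rise * fall


def make_timecourse(
    n_clusters: int,
    genes_per_cluster: int,
    times_h,
    response_times_h,
    lags_h: dict[tuple[int, int], float] | None = None,
    noise_sd: float = 0.1,
    seed: int = 0,
    amplitude: float = 2.0,
    steepness: float = 0.25,
    shape: str = "sigmoid",
    pulse_width_h: float = 36.0,
) -> tuple[TimeCourse, SyntheticTruth]:
    """Sigmoidal cluster time course with planted lags.

    Each cluster's genes share a logistic (in time) profile crossing half
    its dynamic range at that cluster's response time; for every planted
    lag ``(i, j) -> L`` the response time of cluster ``j`` is forced to
    that of cluster ``i`` plus ``L`` hours, so profile ``j`` is a
    time-shifted copy of profile ``i``.  Alternate clusters respond
    downward so the map contains both signs.  Gaussian noise of standard
    deviation ``noise_sd`` is added per gene.

    ``shape="pulse"`` replaces the monotone sigmoid with a transient
    rise-then-decay profile (decay ``pulse_width_h`` after the rise).
    Rank correlation is invariant to monotone reshaping, so only
    non-monotone profiles let the time-delay procedure localize a
    planted lag; the pulse is the shape to plant lags with.
    """
    if shape not in ("sigmoid", "pulse"):
        raise ParameterError("shape must be 'sigmoid' or 'pulse'")
    times = np.asarray(times_h, dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ParameterError("times_h must be strictly increasing")
    response = list(np.asarray(response_times_h, dtype=float))
    if len(response) != n_clusters:
        raise ParameterError("need one response time per cluster")
    span = times[-1] - times[0]
    lags_h = dict(lags_h or {})
    for (i, j), lag in lags_h.items():
        if abs(lag) > span:
            raise ParameterError(f"lag {lag} h exceeds the sampled span {span} h")
        response[j] = response[i] + lag
    for t50 in response:
        if not times[0] <= t50 <= times[-1]:
            raise ParameterError(f"response time {t50} h outside the sampled span")

    rng = np.random.default_rng(seed)
    lagged_followers = {j for (_, j) in lags_h}
    n_genes = n_clusters * genes_per_cluster
    names = _gene_names(n_genes, prefix="T")
    rows = np.empty((n_genes, times.size))
    for c in range(n_clusters):
        sign = 1.0 if c % 2 == 0 else -1.0
        if c in lagged_followers:
            source = next(i for (i, j) in lags_h if j == c)
            sign = 1.0 if source % 2 == 0 else -1.0  # shifted copy keeps the source shape
        if shape == "pulse":
            base = sign * _pulse_profile(times, response[c], amplitude, steepness, pulse_width_h)
        else:
            base = sign * _logistic_profile(times, response[c], amplitude, steepness)
        for g in range(genes_per_cluster):
            idx = c * genes_per_cluster + g
            rows[idx] = base + rng.normal(0.0, noise_sd, size=times.size)
    tc = TimeCourse(pd.DataFrame(rows, index=names, columns=[f"{t:g}" for t in times]), times)
    truth = SyntheticTruth(
        gene_ids=names,
        planted_lags=lags_h,
        response_times_h=[float(t) for t in response],
        seed=seed,
    )
    truth.condition_specific_targets = {}
    # record the planted membership through the gene naming convention:
    # genes T<k> with k // genes_per_cluster == c belong to cluster c
    return tc, truth


def make_survival(
    n_patients: int,
    truth: SyntheticTruth,
    baseline_hazard: float = 0.01,
    seed: int = 0,
    censoring_horizon: float | None = None,
) -> SurvivalTable:
    """Exponential survival with a hazard step at the covariate median.

    The covariate is the (standard normal) level of ``truth.survival_gene``;
    patients above the cohort median have their hazard multiplied by
    ``truth.hazard_ratio``.  Censoring is independent uniform on
    ``(0, censoring_horizon)``; ``censoring_horizon=None`` disables
    censoring (all events observed), matching a censoring rate of zero.
    """
    if n_patients < 2:
        raise ParameterError("need at least 2 patients")
    if baseline_hazard <= 0:
        raise ParameterError("baseline_hazard must be positive")
    if truth.hazard_ratio <= 0:
        raise ParameterError("hazard_ratio must be positive")
    rng = np.random.default_rng(seed)
    covariate = rng.normal(size=n_patients)
    high = covariate > np.median(covariate)
    hazard = baseline_hazard * np.where(high, truth.hazard_ratio, 1.0)
    event_time = rng.exponential(1.0 / hazard)
    if censoring_horizon is None:
        time, event = event_time, np.ones(n_patients, dtype=int)
    else:
        censor_time = rng.uniform(0.0, censoring_horizon, size=n_patients)
        time = np.minimum(event_time, censor_time)
        event = (event_time <= censor_time).astype(int)
    time = np.maximum(time, 1e-9)
    ids = [f"P{i:04d}" for i in range(n_patients)]
    return SurvivalTable(
        pd.DataFrame({"id": ids, "time": time, "event": event, "covariate": covariate})
    )
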