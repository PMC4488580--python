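"""Multi-evidence active-module detection in the prize-collecting
Steiner tree framework.

Nodes of a protein-interaction graph receive additive prizes from three
independent evidence layers: a differential-expression score derived
from a beta-uniform mixture (BUM) fit of the p-value distribution,
membership in an experimentally defined interactor list for the seed
(bait) protein, and co-expression with the seed along a time course.
The module is the connected subtree anchored at the seed that maximizes
collected prizes minus edge costs; its significance is assessed by
permuting prizes over nodes and re-solving.

The BUM scoring follows the classic active-module formulation: with
mixture density ``f(p) = lambda + (1 - lambda) * a * p^(a-1)`` on (0, 1],
the node score is ``(a - 1) * (ln p - ln tau)``, zero at the
FDR-controlled threshold ``tau`` and positive for smaller p.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import optimize, stats

from gliomanet._util import InputError, ParameterError

__all__ = [
    "BUMFit",
    "fit_bum",
    "de_score",
    "NodeScoreTable",
    "score_nodes",
    "SteinerModule",
    "solve_pcst",
    "module_significance",
]

_TINY = 1e-300


@dataclass
class BUMFit:
    """Maximum-likelihood beta-uniform mixture fit of a p-value set.

    ``lam`` is the uniform mixing weight, ``a`` the beta shape (a < 1
    for a signal spike near zero).  ``tau`` is the p-value threshold at
    which the local false discovery level equals the requested FDR; node
    scores are positive below it.
    """

    lam: float
    a: float
    log_likelihood: float
    fdr: float
    tau: float
    n: int

    def density(self, p: np.ndarray) -> np.ndarray:
        p = np.asarray(p, dtype=float)
        return self.lam + (1.0 - self.lam) * self.a * p ** (self.a - 1.0)

    @property
    def signal_fraction(self) -> float:
        """Estimated fraction of p-values from the signal component."""
        return (1.0 - self.lam) * (1.0 - self.a)


def _bum_negloglik(params: np.ndarray, logp: np.ndarray) -> float:
    lam = 1.0 / (1.0 + np.exp(-params[0]))
    a = 1.0 / (1.0 + np.exp(-params[1]))
    dens = lam + (1.0 - lam) * a * np.exp((a - 1.0) * logp)
    return -float(np.sum(np.log(np.maximum(dens, _TINY))))


def _bum_tau(lam: float, a: float, fdr: float) -> float:
    """FDR-controlled score threshold of the fitted mixture.

    ``pi_upper = lam + (1 - lam) * a`` is the upper bound on the null
    density; tau solves ``pi_upper / f(tau) = fdr`` which gives
    ``tau = ((pi_upper - fdr * lam) / (fdr * (1 - lam)))^(1 / (a - 1))``.
    """
    pi_upper = lam + (1.0 - lam) * a
    num = pi_upper - fdr * lam
    den = fdr * (1.0 - lam)
    if num <= 0 or den <= 0:
        return 1.0
    tau = (num / den) ** (1.0 / (a - 1.0))
    return float(np.clip(tau, _TINY, 1.0))


def fit_bum(p_values, fdr: float = 0.05) -> BUMFit:
    """Fit the beta-uniform mixture to a p-value distribution.

    Maximum likelihood over (lambda, a), both constrained to (0, 1)
    through a logistic reparametrization, from several starts.  P-values
    of exactly zero are floored at a machine-tiny value with a warning.
    """
    import warnings

    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size < 100:
        raise InputError("need at least 100 p-values")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise InputError("p-values must lie in [0, 1]")
    if np.any(p == 0):
        warnings.warn("p-values of exactly 0 floored at 1e-300")
        p = np.maximum(p, _TINY)
    if np.ptp(p) == 0:
        raise InputError("degenerate input: all p-values identical")
    logp = np.log(p)
    best = None
    for lam0, a0 in [(0.5, 0.5), (0.9, 0.3), (0.2, 0.7), (0.7, 0.1)]:
        x0 = np.array([np.log(lam0 / (1 - lam0)), np.log(a0 / (1 - a0))])
        res = optimize.minimize(_bum_negloglik, x0, args=(logp,), method="Nelder-Mead")
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise InputError(f"BUM fit failed to converge: {best}")
    lam = float(1.0 / (1.0 + np.exp(-best.x[0])))
    a = float(1.0 / (1.0 + np.exp(-best.x[1])))
    tau = _bum_tau(lam, a, fdr)
    return BUMFit(lam, a, -float(best.fun), fdr, tau, p.size)


def de_score(p: float, fit: BUMFit) -> float:
    """Differential-expression node score from the BUM fit.

    ``score = (a - 1) * (ln p - ln tau)``: zero at ``p = tau``, positive
    for smaller p, strictly decreasing in p (a < 1).
    """
    if not 0.0 < p <= 1.0:
        raise InputError("p must lie in (0, 1]")
    return float((fit.a - 1.0) * (np.log(p) - np.log(fit.tau)))


@dataclass
class NodeScoreTable:
    """Per-node prizes from the three evidence layers.

    ``table`` columns: ``p_de``, ``de_score``, ``interactor_flag``,
    ``coexpr`` in [0, 1], ``prize`` = de_score + beta * interactor_flag
    + gamma * coexpr.  ``missing_coexpr`` counts nodes that defaulted to
    zero co-expression evidence.
    """

    table: pd.DataFrame
    beta: float
    gamma: float
    missing_coexpr: int = 0

    def prize(self, node) -> float:
        return float(self.table.loc[node, "prize"])

    @property
    def prizes(self) -> pd.Series:
        return self.table["prize"]


def score_nodes(
    graph: nx.Graph,
    p_de: dict,
    interactors,
    coexpr: dict,
    fit: BUMFit,
    beta: float = 1.0,
    gamma: float = 1.0,
) -> NodeScoreTable:
    """Combine the three evidence layers into one prize per node."""
    import warnings

    if beta < 0 or gamma < 0:
        raise ParameterError("beta and gamma must be non-negative")
    nodes = list(graph.nodes)
    missing_p = [v for v in nodes if v not in p_de]
    if missing_p:
        raise InputError(f"p_de missing for {len(missing_p)} nodes, e.g. {missing_p[:5]}")
    interactors = set(interactors)
    if interactors and not (interactors & set(nodes)):
        warnings.warn("interactor list is disjoint from the graph")
    rows = []
    missing_co = 0
    for v in nodes:
        c = coexpr.get(v)
        if c is None:
            c, missing_co = 0.0, missing_co + 1
        if not 0.0 <= c <= 1.0:
            raise InputError(f"coexpr values must lie in [0, 1]; got {c} for {v!r}")
        s = de_score(float(p_de[v]), fit)
        flag = int(v in interactors)
        rows.append((float(p_de[v]), s, flag, c, s + beta * flag + gamma * c))
    table = pd.DataFrame(
        rows,
        index=pd.Index(nodes, name="node"),
        columns=["p_de", "de_score", "interactor_flag", "coexpr", "prize"],
    )
    return NodeScoreTable(table, beta, gamma, missing_co)


@dataclass
class SteinerModule:
    """A connected prize-collecting subtree anchored at the seed node."""

    nodes: set
    edges: list[tuple]
    seed_node: object
    net_score: float
    p_value: float | None = None
    parametric_p: float | None = None

    def __post_init__(self) -> None:
        if self.seed_node not in self.nodes:
            raise InputError("seed node must be in the module")
        if len(self.edges) != len(self.nodes) - 1:
            raise InputError("module edges must form a tree")
        g = nx.Graph(self.edges)
        g.add_nodes_from(self.nodes)
        if not nx.is_connected(g):
            raise InputError("module must be connected")


def _net_score(nodes, n_edges: int, prizes: dict, edge_cost: float) -> float:
    return float(sum(prizes[v] for v in nodes) - edge_cost * n_edges)


def _strong_prune(tree: nx.Graph, root, prizes: dict, edge_cost: float) -> nx.Graph:
    """Optimal pruning of a fixed tree: drop negative-margin branches.

    Bottom-up dynamic program; the value of a subtree is its prize sum
    minus edge costs, and a child subtree is kept only if its value
    exceeds the cost of the edge reaching it.  Optimal for the given
    tree, guaranteeing the result is never worse than the root alone.
    """
    kept = nx.Graph()
    kept.add_node(root)
    value: dict = {}
    order = list(nx.dfs_postorder_nodes(tree, root))
    parent = {v: u for u, v in nx.bfs_edges(tree, root)}
    keep_children: dict = {v: [] for v in tree.nodes}
    for v in order:
        val = prizes[v]
        for c in tree.neighbors(v):
            if parent.get(c) != v:
                continue
            margin = value[c] - edge_cost
            if margin > 0:
                val += margin
                keep_children[v].append(c)
        value[v] = val

    stack = [root]
    while stack:
        v = stack.pop()
        for c in keep_children[v]:
            kept.add_edge(v, c)
            stack.append(c)
    return kept


def solve_pcst(
    graph: nx.Graph,
    prizes,
    seed_node,
    edge_cost: float = 1.0,
) -> SteinerModule:
    """Rooted prize-collecting Steiner tree heuristic.

    Grows a tree from the seed by repeatedly attaching the positive-prize
    node with the largest marginal profit (path prize gain minus path
    edge cost) via its cheapest path — continuing through locally
    unprofitable attachments, since a later prize can redeem an earlier
    detour.  After every attachment the tree is strong-pruned (optimal
    removal of negative-margin branches for a fixed tree) and the best
    pruned checkpoint is returned.  The result is always a tree
    containing the seed and never scores worse than the singleton
    ``{seed_node}``.
    """
    if seed_node not in graph:
        raise InputError("seed node not in graph")
    if edge_cost < 0:
        raise ParameterError("edge_cost must be non-negative")
    prize_map = dict(prizes.prizes) if isinstance(prizes, NodeScoreTable) else dict(prizes)

    best_nodes = {seed_node}
    best_score = _net_score(best_nodes, 0, prize_map, edge_cost)
    for strategy in ("profit", "nearest"):
        for metric in ("floor", "shift"):
            nodes, _, score = _grow_and_prune(
                graph, prize_map, seed_node, edge_cost, strategy, metric
            )
            if score > best_score:
                best_nodes, best_score = nodes, score
    # with uniform edge costs the score depends only on the connected node
    # set, so polish the set directly
    best_nodes = _local_search(graph, prize_map, seed_node, best_nodes, edge_cost)
    tree = nx.bfs_tree(graph.subgraph(best_nodes), seed_node).to_undirected()
    edges = list(tree.edges)
    return SteinerModule(
        set(best_nodes),
        edges,
        seed_node,
        _net_score(best_nodes, len(edges), prize_map, edge_cost),
    )


def _local_search(graph, prize_map, seed_node, nodes, edge_cost, max_iter=None):
    """Hill climbing on connected seed-containing node sets.

    Moves: add a boundary node together with its positive outside
    neighbours (a star move — the pattern that pays for a negative hub
    through the prizes behind it), the depth-2 variant reaching a star
    one step further out, or remove a non-articulation member.  Uniform
    edge costs make the set's score ``sum(prize) - edge_cost * (|S| -
    1)``, so moves are scored by node weight ``prize - edge_cost``
    alone.
    """
    s = set(nodes)
    weight = {v: prize_map.get(v, 0.0) - edge_cost for v in graph.nodes}
    if max_iter is None:
        max_iter = 4 * graph.number_of_nodes()
    order = {v: i for i, v in enumerate(graph.nodes)}  # deterministic tie-break

    def star(center, exclude):
        """The centre plus its positive-weight neighbours outside ``exclude``."""
        members = {center}
        members |= {
            t for t in graph.neighbors(center)
            if t not in exclude and t not in members and weight[t] > 0
        }
        return members

    def removal_cleanup(members: set) -> set:
        """Greedily drop negative-weight non-articulation nodes."""
        current = set(members)
        while len(current) > 1:
            articulation = set(nx.articulation_points(graph.subgraph(current)))
            removable = [
                v for v in sorted(current, key=order.get)
                if v != seed_node and v not in articulation and weight[v] < 0
            ]
            if not removable:
                break
            current.remove(min(removable, key=lambda v: (weight[v], order[v])))
        return current

    def candidates(members: set):
        boundary = {u for v in members for u in graph.neighbors(v)} - members
        for v in sorted(boundary, key=order.get):
            yield {v}
            yield star(v, members)
            for u in sorted(set(graph.neighbors(v)) - members - {v}, key=order.get):
                yield {v} | star(u, members | {v})

    for _ in range(max_iter):
        best_gain, best_move = 1e-12, None

        for members in candidates(s):
            gain = sum(weight[m] for m in members)
            if gain > best_gain:
                best_gain, best_move = gain, ("add", frozenset(members))
        if len(s) > 1:
            articulation = set(nx.articulation_points(graph.subgraph(s)))
            for v in sorted(s, key=order.get):
                if v == seed_node or v in articulation:
                    continue
                if -weight[v] > best_gain:
                    best_gain, best_move = -weight[v], ("remove", frozenset({v}))
        if best_move is None:
            # stalled: try each add candidate followed by removal cleanup
            # (a swap can pay even when the add alone does not); the
            # quadratic pass is reserved for modest instances
            if graph.number_of_nodes() > 150:
                break
            base = sum(weight[m] for m in s)
            for members in candidates(s):
                trial = removal_cleanup(s | members)
                gain = sum(weight[m] for m in trial) - base
                if gain > best_gain:
                    best_gain, best_move = gain, ("replace", frozenset(trial))
            if best_move is None:
                break
        kind, members = best_move
        if kind == "add":
            s = s | members
        elif kind == "remove":
            s = s - members
        else:
            s = set(members)
    return s


def _grow_and_prune(graph, prize_map, seed_node, edge_cost, strategy, metric="floor"):
    """One greedy growth pass; returns the best strong-pruned checkpoint.

    ``strategy`` orders candidate attachments: ``"profit"`` takes the
    path with the largest marginal profit first, ``"nearest"`` the
    positive-prize target with the cheapest discounted path.
    ``metric`` selects the Dijkstra step weight (see
    :func:`_profit_dijkstra`).  The variants fail on different
    instances, and the caller keeps the best outcome.
    """
    tree = nx.Graph()
    tree.add_node(seed_node)
    targets = {v for v, p in prize_map.items() if p > 0 and v in graph and v != seed_node}

    def pruned_snapshot(t: nx.Graph):
        pruned = _strong_prune(t, seed_node, prize_map, edge_cost)
        nodes = set(pruned.nodes)
        return nodes, list(pruned.edges), _net_score(
            nodes, pruned.number_of_edges(), prize_map, edge_cost
        )

    best_nodes, best_edges, best_score = pruned_snapshot(tree)
    while targets - set(tree.nodes):
        best = None  # (selection key, path)
        dist, paths = _profit_dijkstra(graph, tree, prize_map, edge_cost, metric)
        for v in targets - set(tree.nodes):
            if v not in dist:
                continue
            path = paths[v]
            new_nodes = [w for w in path if w not in tree.nodes]
            profit = sum(prize_map.get(w, 0.0) for w in new_nodes) - edge_cost * (
                len(path) - 1
            )
            key = profit if strategy == "profit" else -dist[v]
            if best is None or key > best[0]:
                best = (key, path)
        if best is None:
            break  # remaining targets unreachable
        for u, v in zip(best[1][:-1], best[1][1:]):
            tree.add_edge(u, v)
        nodes, edges, score = pruned_snapshot(tree)
        if score > best_score:
            best_nodes, best_edges, best_score = nodes, edges, score
    return best_nodes, best_edges, best_score


def _profit_dijkstra(graph, tree, prize_map, edge_cost, metric="floor"):
    """Shortest net-cost paths from the current tree to all nodes.

    The cost of stepping across an edge into node ``v`` is
    ``edge_cost - prize(v)`` for nodes outside the tree (so positive
    prizes discount a path and negative ones penalize it), made
    non-negative either by clipping at a small positive floor
    (``metric="floor"``) or by shifting every step up by the largest
    positive prize (``metric="shift"``).  Clipping ranks same-length
    paths poorly when large prizes saturate; shifting penalizes hop
    count but preserves the prize ordering.  The true marginal profit of
    a returned path is re-evaluated by the caller.  Returns distance and
    path maps keyed by target node.
    """
    floor = 1e-9
    shift = 0.0
    if metric == "shift":
        shift = max((p for p in prize_map.values() if p > 0), default=0.0)
    dist: dict = {}
    paths: dict = {}
    heap = []
    counter = 0
    for s in tree.nodes:
        dist[s] = 0.0
        paths[s] = [s]
        heapq.heappush(heap, (0.0, counter, s))
        counter += 1
    while heap:
        d, _, u = heapq.heappop(heap)
        if d > dist.get(u, np.inf):
            continue
        for v in graph.neighbors(u):
            if v in tree.nodes:
                continue
            step = max(edge_cost - prize_map.get(v, 0.0) + shift, floor)
            nd = d + step
            if nd < dist.get(v, np.inf):
                dist[v] = nd
                paths[v] = paths[u] + [v]
                counter += 1
                heapq.heappush(heap, (nd, counter, v))
    return dist, paths


def brute_force_pcst(graph: nx.Graph, prizes, seed_node, edge_cost: float) -> float:
    """Exact optimum by enumerating connected seed-containing subsets.

    With uniform edge costs the best tree on a node set S spends
    ``edge_cost * (|S| - 1)``, so the optimum is a search over connected
    subsets.  Exponential; intended as a test oracle for graphs of a
    dozen nodes.
    """
    prize_map = dict(prizes.prizes) if isinstance(prizes, NodeScoreTable) else dict(prizes)
    best = prize_map.get(seed_node, 0.0)
    frontier = [frozenset([seed_node])]
    seen = {frozenset([seed_node])}
    while frontier:
        nxt = []
        for s in frontier:
            boundary = set()
            for v in s:
                boundary |= set(graph.neighbors(v))
            for v in boundary - s:
                s2 = s | {v}
                if s2 in seen:
                    continue
                seen.add(s2)
                nxt.append(s2)
                score = _net_score(s2, len(s2) - 1, prize_map, edge_cost)
                best = max(best, score)
        frontier = nxt
    return float(best)


def module_significance(
    graph: nx.Graph,
    prizes,
    observed: SteinerModule,
    n_perm: int = 100,
    seed: int = 0,
    edge_cost: float = 1.0,
) -> tuple[float, float]:
    """Significance of a module score under prize permutation.

    Prizes are uniformly permuted across graph nodes ``n_perm`` times and
    the solver re-run from the seed each time.  Returns the empirical p
    with the (r+1)/(n_perm+1) pseudocount and a normal-tail parametric p
    from the permuted scores' mean and SD — the parametric tail is how a
    p far below 1/n_perm remains representable.
    """
    if n_perm < 100:
        raise ParameterError("n_perm must be >= 100")
    if observed is None or observed.net_score is None:
        raise InputError("observed module score missing")
    prize_map = dict(prizes.prizes) if isinstance(prizes, NodeScoreTable) else dict(prizes)
    nodes = list(graph.nodes)
    values = np.array([prize_map[v] for v in nodes], dtype=float)
    rng = np.random.default_rng(seed)
    null_scores = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(len(nodes))
        permuted = {v: values[perm[j]] for j, v in enumerate(nodes)}
        null_scores[i] = solve_pcst(graph, permuted, observed.seed_node, edge_cost).net_score
    r = int(np.sum(null_scores >= observed.net_score))
    empirical = (r + 1) / (n_perm + 1)
    sd = float(null_scores.std(ddof=1))
    if sd == 0:
        parametric = 1.0 if observed.net_score <= null_scores.mean() else 0.0
    else:
        parametric = float(stats.norm.sf((observed.net_score - null_scores.mean()) / sd))
    return empirical, parametric
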