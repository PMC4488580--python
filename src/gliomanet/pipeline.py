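"""End-to-end orchestration of the network-inference pipeline.

A single YAML-configurable driver that runs the stages in dependency
order on synthetic inputs (or user files), writes every intermediate
artifact as TSV/GraphML, and emits a machine-readable run manifest
(parameters, per-stage seeds, file digests) plus a human-readable log.

Stage order: simulate -> de -> ppi modules; de -> MI networks ->
grade specificity; time course -> dynamic map -> co-expression evidence;
evidence -> Steiner module; survival.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import networkx as nx
import numpy as np
import yaml

from gliomanet import expression, minet, ppi, steiner, survival, synthetic, timecourse
from gliomanet._util import ParameterError, stage_seed

__all__ = ["PipelineConfig", "run_pipeline", "DEFAULT_CONFIG"]

#: every tunable threshold of the pipeline in one audited place
DEFAULT_CONFIG: dict = {
    "seed": 1,
    "stages": {
        "simulate": True,
        "de": True,
        "ppi": True,
        "minet": True,
        "timecourse": True,
        "integrate": True,
        "survival": True,
    },
    "simulate": {
        "n_nodes": 300,
        "attach_m": 3,
        "module_size": 25,
        "module_edge_prob": 0.3,
        "n_hubs": 14,
        "targets_per_condition": 10,
        "n_samples_a": 45,
        "n_samples_b": 81,
        "target_corr": 0.8,
        "noise_sd": 1.0,
        "n_de_genes": 60,
        "de_shift": 2.0,
        "n_clusters": 6,
        "genes_per_cluster": 15,
        "times_h": [0, 12, 24, 36, 48, 60, 72, 84, 96, 108],
        "timecourse_noise_sd": 0.1,
        "timecourse_shape": "pulse",
        "n_patients": 200,
        "hazard_ratio": 3.0,
        "baseline_hazard": 0.01,
        "censoring_horizon": 400.0,
    },
    "de": {"fc_threshold": 1.5, "fdr_threshold": 0.01},
    "ppi": {"min_module_size": 5},
    "minet": {"alpha": 1e-3, "dpi_tolerance": 0.0, "n_perm": 2000, "specificity_threshold": 0.4},
    "timecourse": {
        "min_log2_range": 1.0,
        "noise_alpha": 0.001,
        "k": 6,
        "rho_threshold": 0.9,
        "lag_window_h": [13.0, 24.0],
        "n_interp_points": 100,
    },
    "integrate": {"bum_fdr": 0.05, "beta": 1.0, "gamma": 1.0, "edge_cost": 1.0, "n_perm": 100},
    "survival": {"min_group_fraction": 0.1, "n_perm": 200},
}

#: (low, high, low_inclusive, high_inclusive) per validated threshold
_DOMAINS = {
    ("de", "fc_threshold"): (0.0, np.inf, True, False),
    ("de", "fdr_threshold"): (0.0, 1.0, False, False),
    ("minet", "alpha"): (0.0, 0.5, False, False),
    ("minet", "dpi_tolerance"): (0.0, 1.0, True, False),
    ("minet", "specificity_threshold"): (0.0, 1.0, False, True),
    ("timecourse", "noise_alpha"): (0.0, 1.0, False, False),
    ("timecourse", "rho_threshold"): (0.0, 1.0, False, True),
    ("integrate", "bum_fdr"): (0.0, 1.0, False, False),
    ("survival", "min_group_fraction"): (0.0, 0.5, False, True),
}


class PipelineConfig:
    """Validated pipeline configuration.

    Built from :data:`DEFAULT_CONFIG` with overrides; unknown keys are
    rejected, and every threshold is checked against its documented
    domain before any computation runs.
    """

    def __init__(self, overrides: dict | None = None):
        cfg = copy.deepcopy(DEFAULT_CONFIG)
        for section, value in (overrides or {}).items():
            if section not in cfg:
                raise ParameterError(f"unknown configuration section: {section!r}")
            if isinstance(value, dict):
                for key, v in value.items():
                    if key not in cfg[section]:
                        raise ParameterError(f"unknown configuration key: {section}.{key}")
                    cfg[section][key] = v
            else:
                cfg[section] = value
        for (section, key), (lo, hi, inc_lo, inc_hi) in _DOMAINS.items():
            v = cfg[section][key]
            ok_lo = v >= lo if inc_lo else v > lo
            ok_hi = v <= hi if inc_hi else v < hi
            if not (ok_lo and ok_hi):
                raise ParameterError(
                    f"{section}.{key}={v} outside its domain "
                    f"{'[' if inc_lo else '('}{lo}, {hi}{']' if inc_hi else ')'}"
                )
        on = cfg["stages"]
        deps = {"de": "simulate", "ppi": "de", "minet": "de", "integrate": "de", "survival": "simulate", "timecourse": "simulate"}
        for stage, needed in deps.items():
            if on.get(stage) and not on.get(needed):
                raise ParameterError(f"stage {stage!r} requires stage {needed!r}")
        self.data = cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(yaml.safe_load(fh) or {})

    def __getitem__(self, key):
        return self.data[key]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, out_dir) -> Path:
    """Run the enabled stages and write artifacts plus a manifest.

    Returns the run directory.  A rerun with the same configuration and
    seed produces byte-identical numeric outputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config.data
    seed = cfg["seed"]
    log: list[str] = []
    results: dict = {}

    def say(msg: str) -> None:
        log.append(msg)

    sim = cfg["simulate"]
    graph, truth = synthetic.make_interactome(
        sim["n_nodes"],
        sim["attach_m"],
        sim["module_size"],
        stage_seed(seed, "interactome"),
        module_edge_prob=sim["module_edge_prob"],
    )
    synthetic.plant_regulators(
        truth, sim["n_hubs"], sim["targets_per_condition"], stage_seed(seed, "regulators")
    )
    truth.survival_gene = sorted(truth.planted_module)[0]
    truth.hazard_ratio = sim["hazard_ratio"]
    expr = synthetic.make_two_condition_expression(
        truth,
        sim["n_samples_a"],
        sim["n_samples_b"],
        sim["target_corr"],
        sim["noise_sd"],
        stage_seed(seed, "expression"),
        n_de_genes=sim["n_de_genes"],
        de_shift=sim["de_shift"],
    )
    n_clusters = sim["n_clusters"]
    response_times = list(np.linspace(6.0, 48.0, n_clusters))
    lags = {(0, 1): 18.0} if n_clusters >= 2 else {}
    tc, tc_truth = synthetic.make_timecourse(
        n_clusters,
        sim["genes_per_cluster"],
        sim["times_h"],
        response_times,
        lags_h=lags,
        noise_sd=sim["timecourse_noise_sd"],
        seed=stage_seed(seed, "timecourse"),
        shape=sim["timecourse_shape"],
    )
    surv = synthetic.make_survival(
        sim["n_patients"],
        truth,
        sim["baseline_hazard"],
        stage_seed(seed, "survival"),
        censoring_horizon=sim["censoring_horizon"],
    )
    if cfg["stages"]["simulate"]:
        ppi.write_edgelist_tsv(graph, out / "interactome.tsv")
        nx.write_graphml(graph, out / "interactome.graphml")
        expr.to_tsv(out / "expression.tsv")
        tc.to_tsv(out / "timecourse.tsv")
        surv.to_tsv(out / "survival.tsv")
        truth.to_yaml(out / "truth.yaml")
        say(f"simulate: {len(graph)} nodes, {graph.number_of_edges()} edges, "
            f"{expr.data.shape[1]} samples, {tc.data.shape[0]} time-course genes")

    cond_a, cond_b = "gradeII", "gradeIV"
    sig = expression.de_signature(
        expr, cond_a, cond_b, cfg["de"]["fc_threshold"], cfg["de"]["fdr_threshold"]
    )
    if cfg["stages"]["de"]:
        sig.to_tsv(out / "de_signature.tsv")
        results["de_selected"] = int(sig.table["selected"].sum())
        say(f"de: {results['de_selected']} genes selected")

    if cfg["stages"]["ppi"]:
        sub = ppi.subset_by_signature(graph, sig)
        report = ppi.percolation_scores(sub if sub.number_of_nodes() else graph)
        expanded = ppi.expand_to_neighbours(sub, report.hubs) if report.hubs else sub
        # community detection needs a network at least one community wide;
        # fall back to the DE-restricted graph when the hub neighbourhood
        # is smaller than that
        min_size = cfg["ppi"]["min_module_size"]
        target = expanded if expanded.number_of_nodes() >= min_size and expanded.number_of_edges() else sub
        if not target.number_of_edges():
            target = graph
        modules = ppi.detect_communities(target, min_size, stage_seed(seed, "ppi"))
        report.scores.to_csv(out / "percolation_scores.tsv", sep="\t", header=True)
        with open(out / "communities.tsv", "w") as fh:
            fh.write("node\tmodule\n")
            for i, community in enumerate(modules.communities):
                for node in sorted(community):
                    fh.write(f"{node}\t{i}\n")
        results["n_hubs"] = len(report.hubs)
        results["n_communities"] = len(modules.communities)
        say(f"ppi: {results['n_hubs']} hubs, {results['n_communities']} communities")

    if cfg["stages"]["minet"]:
        mcfg = cfg["minet"]
        null = minet.fit_mi_null(
            min(len(expr.samples_for(cond_a)), len(expr.samples_for(cond_b))),
            mcfg["n_perm"],
            stage_seed(seed, "minull"),
        )
        net_a = minet.build_hub_network(
            expr, cond_a, truth.regulator_ids, mcfg["alpha"], mcfg["dpi_tolerance"],
            stage_seed(seed, "minet"), null=null,
        )
        net_b = minet.build_hub_network(
            expr, cond_b, truth.regulator_ids, mcfg["alpha"], mcfg["dpi_tolerance"],
            stage_seed(seed, "minet"), null=null,
        )
        profile = minet.grade_specificity(net_a, net_b, mcfg["specificity_threshold"])
        net_a.to_tsv(out / f"minet_{cond_a}.tsv")
        net_b.to_tsv(out / f"minet_{cond_b}.tsv")
        profile.table.to_csv(out / "connectivity_profile.tsv", sep="\t")
        results["specific_hubs_a"] = len(profile.specific_hubs(cond_a))
        results["specific_hubs_b"] = len(profile.specific_hubs(cond_b))
        say(f"minet: {results['specific_hubs_a']} {cond_a}-specific, "
            f"{results['specific_hubs_b']} {cond_b}-specific hubs")

    coexpr_map: dict = {}
    if cfg["stages"]["timecourse"]:
        tcfg = cfg["timecourse"]
        kept = timecourse.timecourse_de_filter(
            tc, tcfg["min_log2_range"], tcfg["noise_alpha"], stage_seed(seed, "tcfilter")
        )
        filtered = timecourse.TimeCourse(tc.data.loc[sorted(kept)], tc.times_h)
        clusters = timecourse.cluster_profiles(filtered, tcfg["k"], stage_seed(seed, "cluster"))
        dyn_map = timecourse.build_dynamic_map(
            clusters,
            tcfg["rho_threshold"],
            tcfg["n_interp_points"],
            tuple(tcfg["lag_window_h"]),
        )
        clusters.summary.to_csv(out / "cluster_summary.tsv", sep="\t")
        dyn_map.to_csv(out / "dynamic_map.tsv", sep="\t", index=False)
        results["tc_genes_kept"] = len(kept)
        results["significant_lag_pairs"] = int(dyn_map["significant"].sum())
        say(f"timecourse: {len(kept)} genes kept, {len(clusters.members)} clusters, "
            f"{results['significant_lag_pairs']} significant lagged pairs")

    if cfg["stages"]["integrate"]:
        icfg = cfg["integrate"]
        rng = np.random.default_rng(stage_seed(seed, "integrate"))
        p_de = {g: float(sig.table.loc[g, "p_value"]) for g in graph.nodes}
        module_sorted = sorted(truth.planted_module)
        n_interact = max(1, int(0.6 * len(module_sorted)))
        interactors = set(module_sorted[:n_interact])
        # co-expression evidence with the seed: planted-module genes score high
        coexpr_map = {
            g: (float(np.clip(0.8 + 0.05 * rng.standard_normal(), 0.0, 1.0))
                if g in truth.planted_module
                else float(np.clip(np.abs(0.2 * rng.standard_normal()), 0.0, 1.0)))
            for g in graph.nodes
        }
        fit = steiner.fit_bum(np.array(list(p_de.values())), icfg["bum_fdr"])
        scores = steiner.score_nodes(
            graph, p_de, interactors, coexpr_map, fit, icfg["beta"], icfg["gamma"]
        )
        seed_node = truth.survival_gene
        module = steiner.solve_pcst(graph, scores, seed_node, icfg["edge_cost"])
        emp_p, par_p = steiner.module_significance(
            graph, scores, module, icfg["n_perm"], stage_seed(seed, "modsig"), icfg["edge_cost"]
        )
        module.p_value, module.parametric_p = emp_p, par_p
        scores.table.to_csv(out / "node_prizes.tsv", sep="\t")
        module_graph = nx.Graph(module.edges)
        module_graph.add_nodes_from(module.nodes)
        nx.write_graphml(module_graph, out / "steiner_module.graphml")
        with open(out / "steiner_module.tsv", "w") as fh:
            fh.write("node\tprize\n")
            for node in sorted(module.nodes):
                fh.write(f"{node}\t{scores.prize(node):.6g}\n")
        jacc = len(module.nodes & truth.planted_module) / len(module.nodes | truth.planted_module)
        results["module_size"] = len(module.nodes)
        results["module_net_score"] = float(module.net_score)
        results["module_empirical_p"] = emp_p
        results["module_parametric_p"] = par_p
        results["module_jaccard_vs_planted"] = jacc
        say(f"integrate: module of {len(module.nodes)} nodes, net score "
            f"{module.net_score:.2f}, empirical p {emp_p:.3g}, parametric p {par_p:.3g}")

    if cfg["stages"]["survival"]:
        scfg = cfg["survival"]
        cut = survival.optimal_cutpoint(
            surv, scfg["min_group_fraction"], scfg["n_perm"], stage_seed(seed, "cutpoint")
        )
        cut.scan.to_csv(out / "cutpoint_scan.tsv", sep="\t", index=False)
        km = survival.km_estimate(surv)
        np.savetxt(
            out / "km_curve.tsv",
            np.column_stack([km.event_times, km.survival, km.at_risk]),
            delimiter="\t",
            header="time\tsurvival\tat_risk",
            comments="",
            fmt="%.10g",
        )
        results["cutpoint_rank"] = cut.cutpoint_rank
        results["cutpoint_logrank_p"] = cut.p_value
        results["cutpoint_adjusted_p"] = cut.adjusted_p
        results["hazard_ratio_estimate"] = cut.hazard_ratio
        say(f"survival: cutpoint at rank {cut.cutpoint_rank}, log-rank p "
            f"{cut.p_value:.3g} (adjusted {cut.adjusted_p:.3g}), HR {cut.hazard_ratio:.2f}")

    artifact_digests = {
        p.name: _sha256(p) for p in sorted(out.iterdir()) if p.suffix in {".tsv", ".graphml", ".yaml"}
    }
    manifest = {
        "config": cfg,
        "stage_seeds": {
            s: stage_seed(seed, s)
            for s in [
                "interactome", "regulators", "expression", "timecourse", "survival",
                "ppi", "minull", "minet", "tcfilter", "cluster", "integrate",
                "modsig", "cutpoint",
            ]
        },
        "results": results,
        "artifacts": artifact_digests,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    (out / "run.log").write_text("\n".join(log) + "\n")
    return out
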