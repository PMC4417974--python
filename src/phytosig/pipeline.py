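"""End-to-end orchestration: simulate → adjust → QC → signature → cliques →
enrichment → connectivity → synergy, with a deterministic JSON run manifest.

All stage parameters live in a single nested config (YAML/JSON-friendly
dict). One master seed drives every stochastic stage through fixed offsets,
so a rerun with the same config is bit-identical for all non-image outputs.
Stage intermediates are plain-text files in the output directory, enabling
resume and inspection.
"""

from __future__ import annotations

import copy
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__, connectivity, consistency, enrichment, io, network, preprocess
from . import signature as sig
from . import simulate as sim
from . import synergy as syn

logger = logging.getLogger(__name__)

# fixed per-stage seed offsets derived from the single master seed
SEED_OFFSETS = {
    "simulate": 0,
    "ppi": 101,
    "gene_sets": 211,
    "profiles": 307,
    "robustness": 401,
    "permutation": 503,
}

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "outdir": "results/run",
    "stages": {
        "simulate": True,
        "preprocess": True,
        "qc": True,
        "signature": True,
        "cliques": True,
        "enrich": True,
        "connect": True,
        "synergy": True,
    },
    "simulate": {
        "n_probes": 5000,
        "frac_de": 0.1,
        "effect_log2": 1.0,
        "batch_shift_sd": 1.0,
        "batch_scale_shape": 0.25,
        "noise_sd": 0.5,
        "probes_per_gene": 3,
    },
    "preprocess": {"preserve_group": True},
    "signature": {"p_threshold": 0.01, "fold_threshold": 1.3, "test": "moderated"},
    "cliques": {"k_values": [3, 4], "edge_prob": 0.004, "n_planted_3": 1, "n_planted_4": 1},
    "enrich": {"p_max": 0.05, "q_max": 0.05, "min_overlap": 4, "n_background_sets": 20},
    "connect": {
        "n_instances": 20,
        "sizes": [100, 200, 300, 400, 500],
        "n_rep": 1000,
        "top_k": 5,
        "n_perm": 1000,
    },
    "synergy": {"synergy_threshold": 1.15, "antagonism_threshold": 0.85},
    "inputs": {"combinations": None},
}

# the two printed combination arms (percent dead cells) used as the default
# worked example: drug 1 at two doses, drug 2 fixed, and their combinations
DEFAULT_COMBINATION_ARMS = [
    {"label": "PG2-1mg/mL+doxorubicin", "D1": 0.0169, "D2": 0.3063, "D12": 0.4720},
    {"label": "PG2-2mg/mL+doxorubicin", "D1": 0.0179, "D2": 0.3063, "D12": 0.5218},
]


class ConfigError(ValueError):
    """Raised when a run configuration is out of range or has unknown keys."""


def _merge(defaults: Mapping, overrides: Mapping, path: str = "") -> dict:
    out = copy.deepcopy(dict(defaults))
    for key, value in overrides.items():
        if key not in defaults:
            raise ConfigError(f"unknown config key {path + key!r}")
        if isinstance(defaults[key], dict) and isinstance(value, Mapping):
            out[key] = _merge(defaults[key], value, path=f"{path}{key}.")
        else:
            out[key] = copy.deepcopy(value)
    return out


def validate_config(config: Mapping | None = None) -> dict:
    """Merge with documented defaults and range-check every parameter."""
    cfg = _merge(DEFAULT_CONFIG, config or {})

    def _require(cond: bool, msg: str) -> None:
        if not cond:
            raise ConfigError(msg)

    _require(isinstance(cfg["seed"], int) and 0 <= cfg["seed"] < 2**31, "seed must be a small non-negative integer")
    s = cfg["simulate"]
    _require(s["n_probes"] >= 30, "simulate.n_probes must be >= 30")
    _require(0.0 <= s["frac_de"] <= 1.0, "simulate.frac_de must be in [0, 1]")
    for key in ("batch_shift_sd", "batch_scale_shape", "noise_sd"):
        _require(s[key] >= 0.0, f"simulate.{key} must be >= 0")
    g = cfg["signature"]
    _require(0.0 < g["p_threshold"] < 1.0, "signature.p_threshold must be in (0, 1)")
    _require(g["fold_threshold"] > 1.0, "signature.fold_threshold must exceed 1")
    _require(g["test"] in ("moderated", "ttest"), "signature.test must be moderated|ttest")
    _require(all(2 <= k <= 6 for k in cfg["cliques"]["k_values"]), "cliques.k_values must be in 2..6")
    _require(0.0 <= cfg["cliques"]["edge_prob"] <= 1.0, "cliques.edge_prob must be in [0, 1]")
    e = cfg["enrich"]
    _require(0.0 < e["p_max"] <= 1.0 and 0.0 < e["q_max"] <= 1.0, "enrich thresholds must be in (0, 1]")
    _require(e["min_overlap"] >= 0, "enrich.min_overlap must be >= 0")
    c = cfg["connect"]
    _require(c["n_instances"] >= 2, "connect.n_instances must be >= 2")
    _require(all(sz >= 2 for sz in c["sizes"]), "connect.sizes must be >= 2")
    _require(c["top_k"] >= 1, "connect.top_k must be >= 1")
    _require(c["n_perm"] >= 100, "connect.n_perm must be >= 100")
    y = cfg["synergy"]
    _require(
        0.0 < y["antagonism_threshold"] <= y["synergy_threshold"],
        "synergy thresholds must satisfy 0 < antagonism <= synergy",
    )
    return cfg


def load_config(path) -> dict:
    import yaml

    with open(path) as fh:
        return validate_config(yaml.safe_load(fh) or {})


def run_pipeline(config: Mapping | None = None) -> dict:
    """Run all enabled stages; return (and write) the run manifest."""
    cfg = validate_config(config)
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = cfg["seed"]
    manifest: dict[str, Any] = {
        "package": "phytosig",
        "version": __version__,
        "seed": seed,
        "config": cfg,
        "stages": {},
    }
    state: dict[str, Any] = {}

    stage_fns = [
        ("simulate", _stage_simulate),
        ("preprocess", _stage_preprocess),
        ("qc", _stage_qc),
        ("signature", _stage_signature),
        ("cliques", _stage_cliques),
        ("enrich", _stage_enrich),
        ("connect", _stage_connect),
        ("synergy", _stage_synergy),
    ]
    for name, fn in stage_fns:
        if not cfg["stages"][name]:
            manifest["stages"][name] = {"status": "skipped"}
            logger.info("stage %s: skipped", name)
            continue
        try:
            record = fn(cfg, state, outdir, seed)
        except Exception as exc:
            manifest["stages"][name] = {"status": "failed", "error": str(exc)}
            (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        record["status"] = "ok"
        manifest["stages"][name] = record
        logger.info("stage %s: ok", name)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def _stage_simulate(cfg, state, outdir, seed):
    conf = sim.SimulationConfig(seed=seed + SEED_OFFSETS["simulate"], **cfg["simulate"])
    matrix, truth = sim.generate_expression(conf)
    probe_map = sim.generate_probe_map(conf)
    io.write_expression(matrix, outdir / "expression.tsv", outdir / "annotations.tsv")
    io.write_probe_map(probe_map, outdir / "probe_map.tsv")
    truth.to_json(outdir / "truth.json")
    state.update(matrix=matrix, truth=truth, probe_map=probe_map, sim_config=conf)
    return {
        "n_probes": conf.n_probes,
        "n_samples": len(matrix.sample_ids),
        "n_de_probes": len(truth.de_probes_up) + len(truth.de_probes_down),
    }


def _stage_preprocess(cfg, state, outdir, seed):
    matrix = state["matrix"]
    adjusted = preprocess.adjust_treatment_arm(
        matrix, preserve_group=cfg["preprocess"]["preserve_group"]
    )
    io.write_expression(adjusted, outdir / "adjusted.tsv", outdir / "annotations.tsv")
    state["adjusted"] = adjusted
    return {"n_samples_adjusted": int((matrix.groups().isin(["vehicle", "treated"])).sum())}


def _stage_qc(cfg, state, outdir, seed):
    # the consistency map compares the treated samples with the comparator
    # agents; vehicle controls belong to the signature contrast, not the map
    adjusted = state["adjusted"]
    qc_samples = [s for s, g in adjusted.groups().items() if g in ("treated", "comparator")]
    if len(qc_samples) >= 3:
        adjusted = adjusted.subset_samples(qc_samples)
    rel = preprocess.relative_expression(adjusted)
    pairs, summary = consistency.pairwise_consistency(rel)
    pairs.to_csv(outdir / "pairs.tsv", sep="\t", index=False)
    corr = consistency.pearson_matrix(rel, axis="samples")
    seriation = consistency.hct_r2e(corr)
    pd.DataFrame({"sample_id": seriation.order}).to_csv(
        outdir / "seriation_order.tsv", sep="\t", index=False
    )
    pca = consistency.pca_correlation(rel)
    pd.DataFrame(
        pca.coordinates, index=pca.labels, columns=["pc1", "pc2"]
    ).to_csv(outdir / "pca.tsv", sep="\t")
    consistency.render_matrix_map(
        corr.values, corr.labels, seriation.order, outdir / "corr_sorted.png"
    )
    consistency.render_matrix_map(
        corr.values, corr.labels, corr.labels, outdir / "corr_unsorted.png"
    )
    state.update(rel=rel, corr=corr, seriation=seriation)
    return {
        "n_pairs": summary["n_pairs"],
        "min_r": summary["min_r"],
        "max_r": summary["max_r"],
        "dropped_constant_probes": len(rel.dropped_probes),
    }


def _treatment_arm(state):
    matrix = state["adjusted"]
    arm = [s for s, g in matrix.groups().items() if g in ("vehicle", "treated")]
    return matrix.subset_samples(arm)


def _stage_signature(cfg, state, outdir, seed):
    arm = _treatment_arm(state)
    res = sig.run_signature_stage(arm, state["probe_map"], **cfg["signature"])
    state["signature_first_pass"] = res
    res.stats.to_csv(outdir / "stats.tsv", sep="\t")
    return {"accounting": res.accounting}


def _stage_cliques(cfg, state, outdir, seed):
    res = state["signature_first_pass"]
    truth = state["truth"]
    probe_map = state["probe_map"]
    gene_universe = sorted({s[0] for s in probe_map.values() if len(s) == 1})
    rng = np.random.default_rng(seed + SEED_OFFSETS["ppi"])
    planted = []
    up = sorted(truth.de_genes_up)
    down = sorted(truth.de_genes_down)
    if len(up) >= 4 * cfg["cliques"]["n_planted_4"]:
        for i in range(cfg["cliques"]["n_planted_4"]):
            planted.append(list(rng.choice(up, size=4, replace=False)))
    if len(down) >= 3 * cfg["cliques"]["n_planted_3"]:
        for i in range(cfg["cliques"]["n_planted_3"]):
            planted.append(list(rng.choice(down, size=3, replace=False)))
    edges, ppi_truth = sim.generate_ppi(
        gene_universe, cfg["cliques"]["edge_prob"], planted, seed + SEED_OFFSETS["ppi"]
    )
    truth.planted_cliques = ppi_truth.planted_cliques
    io.write_edges(edges, outdir / "ppi_edges.tsv")
    graph = network.build_graph(edges)
    clique_sets, members = network.signature_clique_genes(
        graph, list(res.collapse.genes), cfg["cliques"]["k_values"]
    )
    for k, cs in clique_sets.items():
        with open(outdir / f"cliques_k{k}.tsv", "w") as fh:
            for c in cs.cliques:
                fh.write("\t".join(c) + "\n")
    io.write_tags(members, outdir / "clique_genes.grp")
    clique_dirs = {g: res.collapse.genes[g] for g in members}
    final = sig.assemble_enriched_signature(
        {**{g: "up" for g in res.signature.up}, **{g: "down" for g in res.signature.down}},
        clique_dirs,
        res.collapse.gene_log2fc,
    )
    state.update(graph=graph, clique_sets=clique_sets, final_signature=final)
    io.write_tags(sorted(final.up), outdir / "signature_up.grp")
    io.write_tags(sorted(final.down), outdir / "signature_down.grp")
    return {
        "n_cliques": {str(k): len(cs) for k, cs in clique_sets.items()},
        "n_clique_genes": len(members),
        "signature_up": len(final.up),
        "signature_down": len(final.down),
    }


def _final_signature(state):
    if "final_signature" in state:
        return state["final_signature"]
    return state["signature_first_pass"].signature


def _stage_enrich(cfg, state, outdir, seed):
    final = _final_signature(state)
    probe_map = state["probe_map"]
    universe = sorted({s[0] for s in probe_map.values() if len(s) == 1})
    query = sorted(final.up | final.down)
    collection = sim.generate_gene_sets(
        query, universe, n_background=cfg["enrich"]["n_background_sets"],
        seed=seed + SEED_OFFSETS["gene_sets"],
    )
    io.write_gmt(collection, outdir / "gene_sets.gmt")
    table = enrichment.run_ora(
        query,
        collection,
        universe,
        p_max=cfg["enrich"]["p_max"],
        q_max=cfg["enrich"]["q_max"],
        min_overlap=cfg["enrich"]["min_overlap"],
    )
    table.to_csv(outdir / "ora.tsv", sep="\t", index=False)
    state["ora"] = table
    return {
        "n_sets": len(table),
        "n_retained": int(table["retained"].sum()) if len(table) else 0,
        "top_set": table.iloc[0]["name"] if len(table) else None,
    }


def _stage_connect(cfg, state, outdir, seed):
    res = state["signature_first_pass"]
    stats_table = res.stats
    n_probes = len(stats_table)
    p_col = "p_moderated" if res.accounting["test"] == "moderated" else "p_ordinary"
    sig_mask = stats_table[p_col] < res.accounting["p_threshold"]
    cap = n_probes // 10
    up_tags = list(
        stats_table[sig_mask & (stats_table["log2fc"] > 0)]
        .sort_values(p_col, kind="stable")
        .index[:cap]
    )
    down_tags = list(
        stats_table[sig_mask & (stats_table["log2fc"] < 0)]
        .sort_values(p_col, kind="stable")
        .index[:cap]
    )
    profiles = sim.generate_reference_profiles(
        cfg["connect"]["n_instances"],
        n_probes,
        (up_tags, down_tags),
        seed + SEED_OFFSETS["profiles"],
    )
    state["truth"].connected_instance = profiles[-1].instance
    io.write_profiles(profiles, outdir / "profiles.tsv")
    scores = connectivity.score_instances(profiles, up_tags, down_tags)
    best = scores.iloc[0]
    best_profile = next(p for p in profiles if p.instance == best["instance"])
    p_val = connectivity.permutation_p(
        best_profile,
        len(up_tags),
        len(down_tags),
        float(best["raw"]),
        n_perm=cfg["connect"]["n_perm"],
        seed=seed + SEED_OFFSETS["permutation"],
    )
    scores.to_csv(outdir / "connectivity_scores.tsv", sep="\t", index=False)
    robustness = connectivity.random_query_robustness(
        profiles,
        sizes=cfg["connect"]["sizes"],
        n_rep=cfg["connect"]["n_rep"],
        top_k=cfg["connect"]["top_k"],
        seed=seed + SEED_OFFSETS["robustness"],
    )
    robustness.to_csv(outdir / "robustness.tsv", sep="\t", index=False)
    state.update(profiles=profiles, scores=scores, robustness=robustness)
    return {
        "n_instances": len(profiles),
        "top_instance": best["instance"],
        "top_agent": best["agent"],
        "top_scaled": float(best["scaled"]),
        "top_permutation_p": p_val,
        "n_up_tags": len(up_tags),
        "n_down_tags": len(down_tags),
    }


def _stage_synergy(cfg, state, outdir, seed):
    path = cfg["inputs"].get("combinations")
    if path:
        table = io.read_combinations(path)
    else:
        table = io.CombinationTable(pd.DataFrame(DEFAULT_COMBINATION_ARMS))
    io.write_combinations(table, outdir / "combinations.csv")
    result = syn.evaluate_table(table)
    result.to_csv(outdir / "synergy.tsv", sep="\t", index=False)
    state["synergy"] = result
    return {
        "n_rows": len(result),
        "q_rounded": [float(q) for q in result["q_rounded"]],
        "interaction": list(result["interaction"]),
    }
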