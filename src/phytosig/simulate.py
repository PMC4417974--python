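"""Synthetic-data generators emulating the multi-batch microarray study design.

The default design mirrors the study this package targets: 16 arrays from one
cell line — 3 vehicle controls and 11 drug-treated samples spread over three
independently manufactured product batches (6J1: 4, 6J2: 4, 9J1: 3), plus five
single-sample comparator agents hybridized in their own experimental batch.

The expression model per probe *i*, sample *j* is

    a_ij = mu_i + beta_i * treat_j + kappa_{g(j),i} + gamma_{b(j),i}
           + delta_{b(j),i} * eps_ij

with mu_i ~ N(8, 2^2) (baseline log2 intensity), eps_ij ~ N(0, noise_sd^2),
additive batch shifts gamma ~ N(0, batch_shift_sd^2), multiplicative batch
scales delta drawn log-normal with E[delta] = 1, beta_i = ±effect_log2 for
planted differentially expressed probes, and kappa an agent-specific effect
giving each comparator its own expression signature.

Differential expression is planted gene-coherently: probes are grouped into
genes (``probes_per_gene`` single-mapped probes each, plus small unmapped and
multi-mapped tails that exercise the downstream symbol-exclusion rule), and
whole genes are flipped up or down until exactly
``round(frac_de * n_probes)`` probes carry an effect.

Everything a downstream recovery test needs (DE probe/gene sets, batch
location/scale parameters, comparator signatures, planted cliques, the
constructed "connected" reference instance) is recorded in
:class:`SimulationTruth`; recovery tests consume only this record.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import ExpressionMatrix, PPIEdgeList
import pandas as pd

DesignRow = tuple[str, str, str, int]  # (agent, group, batch, n_replicates)


def default_design() -> list[DesignRow]:
    """3 vehicle + 4/4/3 treated across product batches + 5 comparators."""
    return [
        ("vehicle", "vehicle", "6J1", 1),
        ("vehicle", "vehicle", "6J2", 1),
        ("vehicle", "vehicle", "9J1", 1),
        ("PG2", "treated", "6J1", 4),
        ("PG2", "treated", "6J2", 4),
        ("PG2", "treated", "9J1", 3),
        ("15d-PGJ2", "comparator", "comp", 1),
        ("clopidogrel", "comparator", "comp", 1),
        ("etoposide", "comparator", "comp", 1),
        ("EH", "comparator", "comp", 1),
        ("Ac9", "comparator", "comp", 1),
    ]


@dataclass
class SimulationConfig:
    n_probes: int = 5000
    design: list[DesignRow] = field(default_factory=default_design)
    frac_de: float = 0.1
    effect_log2: float = 1.0
    batch_shift_sd: float = 1.0
    batch_scale_shape: float = 0.25
    noise_sd: float = 0.5
    probes_per_gene: int = 3
    frac_unmapped: float = 0.04
    frac_multi: float = 0.02
    comparator_frac_de: float = 0.1
    frac_up: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.frac_de <= 1.0:
            raise ValueError(f"frac_de must be in [0, 1], got {self.frac_de}")
        if not 0.0 <= self.frac_up <= 1.0:
            raise ValueError(f"frac_up must be in [0, 1], got {self.frac_up}")
        for name in ("batch_shift_sd", "batch_scale_shape", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if any(n < 1 for *_, n in self.design):
            raise ValueError("every design row needs n_replicates >= 1")
        if self.probes_per_gene < 1:
            raise ValueError("probes_per_gene must be >= 1")


@dataclass
class SimulationTruth:
    """Ground-truth record accompanying every generated artifact."""

    de_probes_up: set = field(default_factory=set)
    de_probes_down: set = field(default_factory=set)
    de_genes_up: set = field(default_factory=set)
    de_genes_down: set = field(default_factory=set)
    batch_params: dict = field(default_factory=dict)  # batch -> {"gamma": .., "delta": ..}
    comparator_probes: dict = field(default_factory=dict)  # agent -> {"up": .., "down": ..}
    planted_cliques: list = field(default_factory=list)
    connected_instance: str | None = None

    def __post_init__(self) -> None:
        if self.de_probes_up & self.de_probes_down:
            raise ValueError("up/down DE probe sets must be disjoint")
        if any(len(c) < 3 for c in self.planted_cliques):
            raise ValueError("planted cliques must each have size >= 3")

    def to_json(self, path) -> None:
        payload = {
            "de_probes_up": sorted(self.de_probes_up),
            "de_probes_down": sorted(self.de_probes_down),
            "de_genes_up": sorted(self.de_genes_up),
            "de_genes_down": sorted(self.de_genes_down),
            "batch_params": {
                b: {"gamma": list(map(float, p["gamma"])), "delta": list(map(float, p["delta"]))}
                for b, p in self.batch_params.items()
            },
            "comparator_probes": {
                a: {"up": sorted(s["up"]), "down": sorted(s["down"])}
                for a, s in self.comparator_probes.items()
            },
            "planted_cliques": [list(c) for c in self.planted_cliques],
            "connected_instance": self.connected_instance,
        }
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(json.dumps(payload, indent=1))


def probe_names(n: int) -> list[str]:
    return [f"P{i:05d}" for i in range(n)]


def _gene_layout(config: SimulationConfig):
    """Deterministic probe→gene layout shared by the matrix and map generators.

    The first block of probes is single-mapped, ``probes_per_gene`` per gene;
    a short tail is multi-mapped (two symbols) and a final tail unmapped.
    """
    n = config.n_probes
    n_unmapped = int(round(config.frac_unmapped * n))
    n_multi = int(round(config.frac_multi * n))
    n_single = n - n_unmapped - n_multi
    n_genes = max(1, n_single // config.probes_per_gene)
    probes = probe_names(n)
    gene_of = {}
    for i in range(n_single):
        gene_of[probes[i]] = [f"GENE{min(i // config.probes_per_gene, n_genes - 1):05d}"]
    for j, i in enumerate(range(n_single, n_single + n_multi)):
        gene_of[probes[i]] = [f"GENE{j % n_genes:05d}", f"GENE{(j * 7 + 1) % n_genes:05d}"]
    for i in range(n_single + n_multi, n):
        gene_of[probes[i]] = []
    return probes, gene_of, n_single, n_genes


def generate_probe_map(config: SimulationConfig) -> dict[str, list[str]]:
    """Probe→gene-symbol map matching :func:`generate_expression`'s layout."""
    _, gene_of, _, _ = _gene_layout(config)
    return gene_of


def generate_expression(config: SimulationConfig) -> tuple[ExpressionMatrix, SimulationTruth]:
    """Simulate a log2 expression matrix with planted effects; record the truth."""
    rng = np.random.default_rng(config.seed)
    probes, gene_of, n_single, n_genes = _gene_layout(config)
    n = config.n_probes

    sample_ids, groups_, batches_, agents_ = [], [], [], []
    for agent, group, batch, reps in config.design:
        for r in range(reps):
            sample_ids.append(f"{agent}_{batch}_{r + 1}")
            groups_.append(group)
            batches_.append(batch)
            agents_.append(agent)
    if len(set(groups_)) == 1:
        import logging

        logging.getLogger(__name__).warning("degenerate design: a single group only")

    # --- plant DE gene-coherently until exactly round(frac_de * n) probes
    n_de = int(round(config.frac_de * n))
    gene_order = rng.permutation(n_genes)
    de_probes_up: set[str] = set()
    de_probes_down: set[str] = set()
    de_genes_up: set[str] = set()
    de_genes_down: set[str] = set()
    beta = np.zeros(n)
    quota = n_de
    for g in gene_order:
        if quota <= 0:
            break
        gene = f"GENE{g:05d}"
        members = [
            probes[i]
            for i in range(
                g * config.probes_per_gene, min((g + 1) * config.probes_per_gene, n_single)
            )
        ]
        take = members[:quota]
        if not take:
            continue
        up = rng.random() < config.frac_up
        for p in take:
            beta[int(p[1:])] = config.effect_log2 if up else -config.effect_log2
        (de_probes_up if up else de_probes_down).update(take)
        (de_genes_up if up else de_genes_down).add(gene)
        quota -= len(take)

    # --- comparator-agent-specific signatures
    comparator_probes: dict[str, dict[str, set]] = {}
    kappa: dict[str, np.ndarray] = {}
    for agent, group, _, _ in config.design:
        if group != "comparator" or agent in kappa:
            continue
        k = np.zeros(n)
        n_eff = int(round(config.comparator_frac_de * n))
        idx = rng.choice(n, size=n_eff, replace=False)
        signs = np.where(rng.random(n_eff) < 0.5, 1.0, -1.0)
        k[idx] = signs * config.effect_log2
        kappa[agent] = k
        comparator_probes[agent] = {
            "up": {probes[i] for i, s in zip(idx, signs) if s > 0},
            "down": {probes[i] for i, s in zip(idx, signs) if s < 0},
        }

    # --- batch location/scale parameters
    batch_params: dict[str, dict[str, np.ndarray]] = {}
    for batch in dict.fromkeys(batches_):
        gamma = rng.normal(0.0, config.batch_shift_sd, size=n)
        s = config.batch_scale_shape
        delta = np.exp(rng.normal(-0.5 * s * s, s, size=n)) if s > 0 else np.ones(n)
        batch_params[batch] = {"gamma": gamma, "delta": delta}

    mu = rng.normal(8.0, 2.0, size=n)
    values = np.empty((n, len(sample_ids)))
    for j, (group, batch, agent) in enumerate(zip(groups_, batches_, agents_)):
        eps = rng.normal(0.0, config.noise_sd, size=n)
        col = mu + batch_params[batch]["gamma"] + batch_params[batch]["delta"] * eps
        if group == "treated":
            col = col + beta
        if agent in kappa:
            col = col + kappa[agent]
        values[:, j] = col

    ann = pd.DataFrame(
        {"group": groups_, "batch": batches_, "agent": agents_}, index=sample_ids
    )
    matrix = ExpressionMatrix(probes, sample_ids, values, ann)
    truth = SimulationTruth(
        de_probes_up=de_probes_up,
        de_probes_down=de_probes_down,
        de_genes_up=de_genes_up,
        de_genes_down=de_genes_down,
        batch_params=batch_params,
        comparator_probes=comparator_probes,
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# PPI graphs with planted cliques
# ---------------------------------------------------------------------------


def generate_ppi(
    nodes: int | Sequence[str],
    edge_prob: float,
    planted_cliques: Sequence[Sequence[str]],
    seed: int,
) -> tuple[PPIEdgeList, SimulationTruth]:
    """Erdős–Rényi background plus all within-clique edges.

    ``nodes`` is either a node count (auto-named ``G00000``…) or an explicit
    gene-symbol list. Every planted clique member must be a node.
    """
    if isinstance(nodes, int):
        node_list = [f"G{i:05d}" for i in range(nodes)]
    else:
        node_list = list(nodes)
    node_set = set(node_list)
    for clique in planted_cliques:
        missing = set(clique) - node_set
        if missing:
            raise ValueError(f"planted clique member(s) not in node set: {sorted(missing)}")
        if len(clique) < 3:
            raise ValueError("planted cliques must have size >= 3")

    rng = np.random.default_rng(seed)
    m = len(node_list)
    pairs: list[tuple[str, str]] = []
    if edge_prob > 0:
        iu, ju = np.triu_indices(m, k=1)
        mask = rng.random(iu.shape[0]) < edge_prob
        pairs = [(node_list[i], node_list[j]) for i, j in zip(iu[mask], ju[mask])]
    for clique in planted_cliques:
        pairs.extend(itertools.combinations(clique, 2))
    edges = PPIEdgeList.from_pairs(pairs)
    truth = SimulationTruth(planted_cliques=[sorted(c) for c in planted_cliques])
    return edges, truth


# ---------------------------------------------------------------------------
# Ranked reference profiles for connectivity scoring
# ---------------------------------------------------------------------------


def generate_reference_profiles(
    n_instances: int,
    n_probes: int,
    signature: tuple[Sequence[str], Sequence[str]],
    seed: int,
    connected_agent: str = "connected",
):
    """Random reference profiles plus one signature-"connected" instance.

    Returns ``n_instances - 1`` uniformly random permutations of the probe
    universe and one constructed instance whose up-tags occupy the top decile
    of ranks and down-tags the bottom decile (connectivity-positive by
    construction). Instance *i* carries agent label ``agent{i:02d}``; the
    connected instance is labeled ``connected_agent``.
    """
    from .connectivity import RankedProfile

    universe = probe_names(n_probes)
    uni_set = set(universe)
    up, down = list(signature[0]), list(signature[1])
    extra = (set(up) | set(down)) - uni_set
    if extra:
        raise ValueError(f"signature tag(s) outside the probe universe: {sorted(extra)[:5]}")
    if len(up) > n_probes // 10 or len(down) > n_probes // 10:
        raise ValueError("signature larger than a decile of the universe")

    rng = np.random.default_rng(seed)
    profiles = []
    for i in range(n_instances - 1):
        perm = rng.permutation(n_probes)
        profiles.append(
            RankedProfile(f"inst{i:03d}", f"agent{i % 20:02d}", [universe[k] for k in perm])
        )
    # connected instance: up tags in the top decile, down tags in the bottom
    decile = n_probes // 10
    top_slots = rng.choice(decile, size=len(up), replace=False)
    bottom_slots = rng.choice(decile, size=len(down), replace=False) + (n_probes - decile)
    ranked: list[str | None] = [None] * n_probes
    for slot, tag in zip(top_slots, up):
        ranked[slot] = tag
    for slot, tag in zip(bottom_slots, down):
        ranked[slot] = tag
    rest = [p for p in universe if p not in set(up) | set(down)]
    rest = [rest[k] for k in rng.permutation(len(rest))]
    it = iter(rest)
    ranked = [tag if tag is not None else next(it) for tag in ranked]
    profiles.append(RankedProfile(f"inst{n_instances - 1:03d}", connected_agent, ranked))
    return profiles


# ---------------------------------------------------------------------------
# Gene-set collections with a planted enriched set
# ---------------------------------------------------------------------------


def generate_gene_sets(
    query_genes: Sequence[str],
    universe: Sequence[str],
    n_background: int = 20,
    background_size: tuple[int, int] = (30, 120),
    planted_fraction: float = 0.8,
    seed: int = 0,
):
    """A collection with one set planted to contain ``planted_fraction`` of the
    query plus filler, and background sets drawn from the non-query universe
    (null pathways unrelated to the signature)."""
    from .io import GeneSet, GeneSetCollection

    rng = np.random.default_rng(seed)
    query = list(dict.fromkeys(query_genes))
    pool = [g for g in universe if g not in set(query)]
    if not pool:
        raise ValueError("universe must contain genes outside the query")
    n_hit = max(1, int(round(planted_fraction * len(query))))
    hit = [query[i] for i in rng.choice(len(query), size=n_hit, replace=False)]
    filler = [pool[i] for i in rng.choice(len(pool), size=min(20, len(pool)), replace=False)]
    collection = GeneSetCollection()
    collection.add(GeneSet("PLANTED", "signature-enriched set", frozenset(hit + filler)))
    lo, hi = background_size
    for b in range(n_background):
        size = int(rng.integers(lo, hi + 1))
        members = [pool[i] for i in rng.choice(len(pool), size=min(size, len(pool)), replace=False)]
        collection.add(GeneSet(f"NULL{b:03d}", "background set", frozenset(members)))
    return collection
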