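"""Per-probe differential statistics and gene-signature assembly.

Two routes to per-probe significance are provided: a pooled-variance
two-sample Student t (the classical exploratory choice, no multiplicity
adjustment) and an empirical-Bayes moderated t in which each probe's variance
is shrunk toward a common prior value,

    s_tilde_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g),

with the prior degrees of freedom d0 and prior variance s0^2 estimated by
moment-matching the log sample variances (digamma/trigamma inversion); the
moderated statistic is referred to a t distribution on d0 + d_g degrees of
freedom. The moderated route is the canonical small-sample choice when only a
handful of replicates per group is available.

Downstream, significant probes are collapsed to gene symbols (probes mapping
to zero or more than one symbol are excluded), a fold-change criterion is
applied, and the enriched signature is assembled as the union of
fold-change-selected genes and PPI-clique member genes with provenance tags.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

logger = logging.getLogger(__name__)


@dataclass
class GeneSignature:
    """Directed gene sets with per-gene provenance tags."""

    up: set
    down: set
    provenance: dict = field(default_factory=dict)  # gene -> set of tags

    def __post_init__(self) -> None:
        self.up, self.down = set(self.up), set(self.down)
        if self.up & self.down:
            raise ValueError(f"up/down overlap: {sorted(self.up & self.down)}")
        for g in self.up | self.down:
            if not self.provenance.get(g):
                raise ValueError(f"gene {g!r} lacks a provenance tag")

    def __len__(self) -> int:
        return len(self.up) + len(self.down)


def _split_groups(matrix, group_labels: Sequence[str] | None):
    values = matrix.values if hasattr(matrix, "values") else np.asarray(matrix, float)
    if group_labels is None:
        group_labels = list(matrix.groups())
    labels = np.asarray(group_labels)
    treated = values[:, labels == "treated"]
    control = values[:, labels == "vehicle"]
    if treated.shape[1] < 2 or control.shape[1] < 2:
        raise ValueError("both groups need at least 2 samples")
    return values, treated, control


def two_sample_ttest(
    matrix, group_labels: Sequence[str] | None = None, df_loss: int = 0
) -> pd.DataFrame:
    """Pooled-variance Student t per probe, two-sided p, no multiplicity adjustment.

    Zero-pooled-variance probes get t undefined: p = 1 and a ``zero_variance``
    flag instead of a spurious rejection. ``df_loss`` discounts residual
    degrees of freedom consumed upstream of the test — when the matrix was
    batch-adjusted, the removed per-batch means cost (n_batches - 1) df, and
    ignoring that makes the test anticonservative.
    """
    _, treated, control = _split_groups(matrix, group_labels)
    n1, n2 = treated.shape[1], control.shape[1]
    m1, m2 = treated.mean(axis=1), control.mean(axis=1)
    ss1 = ((treated - m1[:, None]) ** 2).sum(axis=1)
    ss2 = ((control - m2[:, None]) ** 2).sum(axis=1)
    df = n1 + n2 - 2 - df_loss
    if df < 1:
        raise ValueError("df_loss leaves no residual degrees of freedom")
    sp2 = (ss1 + ss2) / df
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    zero = se == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / se
    t = np.where(zero, 0.0, t)
    p = np.where(zero, 1.0, 2.0 * stats.t.sf(np.abs(t), df))
    probe_ids = matrix.probe_ids if hasattr(matrix, "probe_ids") else range(len(m1))
    out = pd.DataFrame(
        {
            "mean_treated": m1,
            "mean_control": m2,
            "log2fc": m1 - m2,
            "t_ordinary": t,
            "p_ordinary": p,
            "df_ordinary": float(df),
            "zero_variance": zero,
        },
        index=list(probe_ids),
    )
    out.index.name = "probe_id"
    return out


def trigamma_inverse(y: np.ndarray) -> np.ndarray:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    y = np.asarray(y, dtype=float)
    x = np.where(y > 1e7, 1.0 / np.sqrt(y), 0.5 + 1.0 / y)
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if np.all(np.abs(dif) / x < 1e-8):
            break
    return x


def fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment estimates (d0, s0^2) of the scaled-F model for sample variances.

    Matches the mean and variance of log(s2) to the theoretical digamma /
    trigamma expressions. Returns ``d0 = inf`` when the observed spread of log
    variances is no larger than expected under equal true variances.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        raise ValueError("need at least 2 positive sample variances")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_bar = e.mean()
    n = len(e)
    e_var = ((e - e_bar) ** 2).sum() / (n - 1)
    resid = e_var - special.polygamma(1, df / 2.0)
    if resid <= 0:
        return np.inf, float(np.exp(e_bar))
    d0 = 2.0 * float(trigamma_inverse(np.array([resid]))[0])
    s0_2 = float(np.exp(e_bar + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_2


def moderated_ttest(
    matrix, group_labels: Sequence[str] | None = None, df_loss: int = 0
) -> pd.DataFrame:
    """Empirical-Bayes moderated t per probe; hyperparameters in ``.attrs``."""
    values, treated, control = _split_groups(matrix, group_labels)
    if values.shape[0] < 30:
        raise ValueError("moderated t needs >= 30 probes for hyperparameter estimation")
    out = two_sample_ttest(matrix, group_labels, df_loss=df_loss)
    n1, n2 = treated.shape[1], control.shape[1]
    df = n1 + n2 - 2 - df_loss
    diff = out["log2fc"].to_numpy()
    se_unit = np.sqrt(1.0 / n1 + 1.0 / n2)
    ss1 = ((treated - treated.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ss2 = ((control - control.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    sp2 = (ss1 + ss2) / df

    d0, s0_2 = fit_f_dist(sp2[sp2 > 0], df)
    if np.isinf(d0):
        s_tilde2 = np.full_like(sp2, s0_2)
        df_mod = np.inf
    else:
        s_tilde2 = (d0 * s0_2 + df * sp2) / (d0 + df)
        df_mod = d0 + df
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = diff / (np.sqrt(s_tilde2) * se_unit)
    t_mod = np.where(np.isfinite(t_mod), t_mod, 0.0)
    if np.isinf(df_mod):
        p_mod = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p_mod = 2.0 * stats.t.sf(np.abs(t_mod), df_mod)
    out["t_moderated"] = t_mod
    out["p_moderated"] = p_mod
    out["df_moderated"] = df_mod
    out.attrs["d0"] = d0
    out.attrs["s0_2"] = s0_2
    return out


def fold_change_filter(stats_table: pd.DataFrame, threshold: float = 1.3) -> tuple[list, list]:
    """Split a stats table (any table with a ``log2fc`` column) at ±log2(threshold).

    Boundary inclusive: log2fc == log2(threshold) counts as up.
    """
    if threshold <= 1.0:
        raise ValueError("fold-change threshold must exceed 1")
    cut = np.log2(threshold)
    fc = stats_table["log2fc"]
    up = list(stats_table.index[fc >= cut])
    down = list(stats_table.index[fc <= -cut])
    return up, down


@dataclass
class CollapseResult:
    genes: dict  # gene -> direction ("up"/"down")
    gene_log2fc: dict  # gene -> mean log2fc over its surviving probes
    n_unmapped: int
    n_multimapped: int
    n_conflicting: int
    dropped_conflicts: list


def collapse_probes_to_genes(
    probe_set: Sequence[str],
    probe_map: Mapping[str, Sequence[str]],
    stats_table: pd.DataFrame,
) -> CollapseResult:
    """Collapse selected probes to uniquely mapped gene symbols.

    Probes mapping to zero or >1 symbols are excluded (counted). A gene's
    direction is the sign of the mean log2fc of its surviving probes; genes
    whose selected probes disagree in fold-change sign are dropped and logged.
    """
    missing = [p for p in probe_set if p not in probe_map]
    if missing:
        raise ValueError(f"probe(s) absent from map: {missing[:5]}")
    per_gene: dict[str, list[str]] = {}
    n_unmapped = n_multi = 0
    for p in probe_set:
        symbols = probe_map[p]
        if len(symbols) == 0:
            n_unmapped += 1
        elif len(symbols) > 1:
            n_multi += 1
        else:
            per_gene.setdefault(symbols[0], []).append(p)
    genes: dict[str, str] = {}
    gene_fc: dict[str, float] = {}
    dropped = []
    fc = stats_table["log2fc"]
    for gene, probes in per_gene.items():
        fcs = fc.loc[probes].to_numpy()
        if np.any(fcs > 0) and np.any(fcs < 0):
            dropped.append(gene)
            continue
        mean_fc = float(fcs.mean())
        genes[gene] = "up" if mean_fc > 0 else "down"
        gene_fc[gene] = mean_fc
    if n_unmapped or n_multi or dropped:
        logger.info(
            "collapse: excluded %d unmapped, %d multi-mapped probe(s); "
            "dropped %d direction-conflicting gene(s)",
            n_unmapped,
            n_multi,
            len(dropped),
        )
    return CollapseResult(genes, gene_fc, n_unmapped, n_multi, len(dropped), sorted(dropped))


def assemble_enriched_signature(
    fc_genes: Mapping[str, str],
    clique_genes: Mapping[str, str],
    gene_log2fc: Mapping[str, float],
) -> GeneSignature:
    """Union of fold-change and clique gene sets with provenance tags.

    Direction conflicts between the two inputs are resolved by the sign of the
    gene-level log2 fold change.
    """
    provenance: dict[str, set] = {}
    direction: dict[str, str] = {}
    for source, tag in ((fc_genes, "foldchange"), (clique_genes, "clique")):
        for gene, d in source.items():
            provenance.setdefault(gene, set()).add(tag)
            if gene in direction and direction[gene] != d:
                resolved = "up" if gene_log2fc.get(gene, 0.0) > 0 else "down"
                logger.warning(
                    "direction conflict for %s: resolved to %s by fold-change sign",
                    gene,
                    resolved,
                )
                direction[gene] = resolved
            else:
                direction[gene] = d
    up = {g for g, d in direction.items() if d == "up"}
    down = {g for g, d in direction.items() if d == "down"}
    return GeneSignature(up=up, down=down, provenance=provenance)


@dataclass
class SignatureStageResult:
    stats: pd.DataFrame
    signature: GeneSignature
    accounting: dict
    collapse: CollapseResult


def run_signature_stage(
    matrix,
    probe_map: Mapping[str, Sequence[str]],
    p_threshold: float = 0.01,
    fold_threshold: float = 1.3,
    test: str = "moderated",
    clique_genes: Mapping[str, str] | None = None,
    group_labels: Sequence[str] | None = None,
    df_loss: int | None = None,
) -> SignatureStageResult:
    """Full signature stage: test → collapse → gene-level fold filter → assemble.

    Selection is two-staged: probes significant at ``p_threshold`` (moderated t
    by default) are collapsed to uniquely mapped genes, and the fold-change
    criterion is then applied to the gene-level mean log2fc — averaging across
    a gene's probes is what gives the fold filter discriminating power at
    small replicate numbers.
    """
    if test not in ("moderated", "ttest"):
        raise ValueError("test must be 'moderated' or 'ttest'")
    if df_loss is None:
        # a batch-adjusted matrix has had one mean per batch removed per probe
        df_loss = (
            max(0, matrix.batches().nunique() - 1) if hasattr(matrix, "batches") else 0
        )
    stats_table = moderated_ttest(matrix, group_labels, df_loss=df_loss)
    p_col = "p_moderated" if test == "moderated" else "p_ordinary"
    sig_probes = list(stats_table.index[stats_table[p_col] < p_threshold])
    collapse = collapse_probes_to_genes(sig_probes, probe_map, stats_table)
    # gene-level fold change over ALL of a gene's uniquely mapped probes (not
    # only the significant ones): averaging across probes is what lets the
    # fold criterion separate real effects from noise-selected genes
    probes_of: dict[str, list[str]] = {}
    for p, symbols in probe_map.items():
        if len(symbols) == 1 and p in stats_table.index:
            probes_of.setdefault(symbols[0], []).append(p)
    fc = stats_table["log2fc"]
    gene_fc_all = {
        g: float(fc.loc[probes_of[g]].mean()) for g in collapse.genes if g in probes_of
    }
    gene_table = pd.DataFrame({"log2fc": pd.Series(gene_fc_all)}, index=list(gene_fc_all))
    up_genes, down_genes = fold_change_filter(gene_table, fold_threshold)
    fc_genes = {g: "up" for g in up_genes}
    fc_genes.update({g: "down" for g in down_genes})
    signature = assemble_enriched_signature(fc_genes, clique_genes or {}, gene_fc_all)
    accounting = {
        "probes_tested": int(len(stats_table)),
        "probes_significant": len(sig_probes),
        "probes_excluded_no_symbol": collapse.n_unmapped,
        "probes_excluded_multi_symbol": collapse.n_multimapped,
        "genes_candidate": len(collapse.genes),
        "genes_conflicting_dropped": collapse.n_conflicting,
        "genes_fold_change": len(fc_genes),
        "genes_clique": len(clique_genes or {}),
        "signature_up": len(signature.up),
        "signature_down": len(signature.down),
        "test": test,
        "df_loss": df_loss,
        "p_threshold": p_threshold,
        "fold_threshold": fold_threshold,
    }
    return SignatureStageResult(stats_table, signature, accounting, collapse)
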