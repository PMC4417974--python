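"""Relative-expression transform and empirical-Bayes batch adjustment.

``relative_expression`` rescales every probe row to [0, 1] by its own min and
max, r_ij = (a_ij - m_i) / (M_i - m_i), the within-gene transform used before
correlation mapping so that between-sample similarity is not dominated by
baseline intensity.

``batch_adjust`` is a parametric empirical-Bayes location/scale adjustment
(the ComBat model): per-probe standardization against a design that optionally
keeps the biological group indicator, per-batch-per-probe location (gamma) and
scale (delta^2) estimates, shrinkage of gamma toward a Normal prior and of
delta^2 toward an Inverse-Gamma prior (both fit by method of moments across
probes), iterated to convergence, then back-transformation. With
``preserve_group=True`` (default) the treatment contrast survives adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class RelativeExpressionMatrix:
    """Probes × samples matrix of within-probe min-max relative expression."""

    probe_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    dropped_probes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size and (self.values.min() < 0.0 or self.values.max() > 1.0):
            raise ValueError("relative expression values must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.probe_ids, columns=self.sample_ids)


def relative_expression(matrix) -> RelativeExpressionMatrix:
    """Min-max rescale each probe row to [0, 1]; constant rows are dropped.

    Accepts an :class:`ExpressionMatrix` or a :class:`RelativeExpressionMatrix`
    (the transform is idempotent).
    """
    if matrix.values.shape[1] < 2:
        raise ValueError("relative expression needs at least 2 samples")
    values = matrix.values
    lo = values.min(axis=1, keepdims=True)
    hi = values.max(axis=1, keepdims=True)
    rng_ = (hi - lo).ravel()
    keep = rng_ > 0
    dropped = [p for p, k in zip(matrix.probe_ids, keep) if not k]
    if dropped:
        logger.info("relative_expression: dropped %d constant probe(s)", len(dropped))
    rel = (values[keep] - lo[keep]) / (hi[keep] - lo[keep])
    return RelativeExpressionMatrix(
        probe_ids=[p for p, k in zip(matrix.probe_ids, keep) if k],
        sample_ids=list(matrix.sample_ids),
        values=np.clip(rel, 0.0, 1.0),
        dropped_probes=dropped,
    )


# ---------------------------------------------------------------------------
# Empirical-Bayes batch adjustment
# ---------------------------------------------------------------------------


def _design_matrix(batches: pd.Series, groups: pd.Series | None) -> tuple[np.ndarray, list[str], int]:
    batch_levels = list(dict.fromkeys(batches))
    cols = [np.asarray(batches == b, dtype=float) for b in batch_levels]
    if groups is not None:
        group_levels = list(dict.fromkeys(groups))
        for g in group_levels[1:]:  # reference-coded to avoid collinearity
            cols.append(np.asarray(groups == g, dtype=float))
    design = np.column_stack(cols)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError(
            "batch and group are confounded (singular design); "
            "adjust a subset where every batch contains more than one group"
        )
    return design, batch_levels, len(batch_levels)


def _postmean(g_hat, g_bar, n, d_star, t2):
    return (t2 * n * g_hat + d_star * g_bar) / (t2 * n + d_star)


def _postvar(sum2, n, a, b):
    return (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)


def _it_sol(s_data, g_hat, d_hat, g_bar, t2, a, b, conv=1e-4, max_iter=100):
    """Iterate the coupled posterior-mean equations for one batch."""
    n = s_data.shape[1]
    g_old, d_old = g_hat.copy(), d_hat.copy()
    for _ in range(max_iter):
        g_new = _postmean(g_hat, g_bar, n, d_old, t2)
        sum2 = ((s_data - g_new[:, None]) ** 2).sum(axis=1)
        d_new = _postvar(sum2, n, a, b)
        change = max(
            np.max(np.abs(g_new - g_old) / np.abs(g_old)),
            np.max(np.abs(d_new - d_old) / np.abs(d_old)),
        )
        g_old, d_old = g_new, d_new
        if change < conv:
            break
    return g_old, d_old


def batch_adjust(matrix: ExpressionMatrix, preserve_group: bool = True) -> ExpressionMatrix:
    """Remove per-batch location/scale effects by parametric EB shrinkage.

    Probe and sample identifiers and ordering are preserved. Constant probes
    are excluded from standardization and passed through unchanged. A matrix
    with a single batch is returned unchanged (with a warning); a batch with a
    single sample is rejected because its scale is not estimable.
    """
    batches = matrix.batches()
    batch_levels = list(dict.fromkeys(batches))
    if len(batch_levels) < 2:
        logger.warning("batch_adjust: single batch, nothing to adjust")
        return ExpressionMatrix(
            list(matrix.probe_ids),
            list(matrix.sample_ids),
            matrix.values.copy(),
            matrix.annotations.copy(),
        )
    sizes = batches.value_counts()
    tiny = sizes[sizes < 2]
    if len(tiny):
        raise ValueError(
            f"batch(es) with a single sample (scale not estimable): {list(tiny.index)}"
        )

    groups = matrix.groups() if preserve_group else None
    design, batch_levels, n_batch = _design_matrix(batches, groups)
    batch_design = design[:, :n_batch]
    n_array = design.shape[0]
    n_batches = batch_design.sum(axis=0)

    dat = matrix.values
    const = dat.std(axis=1) == 0.0
    if const.any():
        logger.info("batch_adjust: passing through %d constant probe(s)", int(const.sum()))
    X = dat[~const]

    # per-probe OLS of expression on [batch | group] design
    B_hat = np.linalg.solve(design.T @ design, design.T @ X.T)  # (p_design, n_probes)
    grand_mean = (n_batches / n_array) @ B_hat[:n_batch]
    resid = X - (design @ B_hat).T
    var_pooled = (resid**2).mean(axis=1)
    var_pooled = np.where(var_pooled == 0.0, np.finfo(float).tiny, var_pooled)

    stand_mean = grand_mean[:, None] @ np.ones((1, n_array))
    if design.shape[1] > n_batch:
        tmp = design.copy()
        tmp[:, :n_batch] = 0.0
        stand_mean = stand_mean + (tmp @ B_hat).T
    s_data = (X - stand_mean) / np.sqrt(var_pooled)[:, None]

    gamma_hat = np.linalg.solve(batch_design.T @ batch_design, batch_design.T @ s_data.T)
    delta_hat = np.vstack(
        [s_data[:, batch_design[:, k] == 1].var(axis=1, ddof=1) for k in range(n_batch)]
    )
    gamma_bar = gamma_hat.mean(axis=1)
    t2 = gamma_hat.var(axis=1, ddof=1)
    m = delta_hat.mean(axis=1)
    s2 = delta_hat.var(axis=1, ddof=1)
    a_prior = (2.0 * s2 + m**2) / s2
    b_prior = (m * s2 + m**3) / s2

    bayes = s_data.copy()
    for k in range(n_batch):
        members = batch_design[:, k] == 1
        g_star, d_star = _it_sol(
            s_data[:, members], gamma_hat[k], delta_hat[k], gamma_bar[k], t2[k], a_prior[k], b_prior[k]
        )
        bayes[:, members] = (s_data[:, members] - g_star[:, None]) / np.sqrt(d_star)[:, None]

    adjusted = bayes * np.sqrt(var_pooled)[:, None] + stand_mean
    out = dat.copy()
    out[~const] = adjusted
    return ExpressionMatrix(
        list(matrix.probe_ids), list(matrix.sample_ids), out, matrix.annotations.copy()
    )


def adjust_treatment_arm(matrix: ExpressionMatrix, preserve_group: bool = True) -> ExpressionMatrix:
    """Batch-adjust the vehicle+treated samples in place, leaving others as-is.

    Comparator agents typically sit in their own hybridization batch whose
    batch label is confounded with their group label, so they cannot be
    adjusted; the multi-batch treatment arm can.
    """
    groups = matrix.groups()
    arm = [s for s, g in groups.items() if g in ("vehicle", "treated")]
    if len(arm) == len(matrix.sample_ids):
        return batch_adjust(matrix, preserve_group=preserve_group)
    sub = matrix.subset_samples(arm)
    adj = batch_adjust(sub, preserve_group=preserve_group)
    out = matrix.values.copy()
    for s in arm:
        out[:, matrix.sample_ids.index(s)] = adj.values[:, adj.sample_ids.index(s)]
    return ExpressionMatrix(
        list(matrix.probe_ids), list(matrix.sample_ids), out, matrix.annotations.copy()
    )


def batch_f_statistics(matrix: ExpressionMatrix, remove_group: bool = True) -> np.ndarray:
    """Per-probe one-way F statistic across batches (between-/within-batch MS).

    With ``remove_group`` the group means are subtracted first so the statistic
    measures residual technical batch signal, not treatment.
    """
    values = matrix.values.copy()
    batches = matrix.batches().to_numpy()
    if remove_group:
        groups = matrix.groups().to_numpy()
        for g in np.unique(groups):
            cols = groups == g
            values[:, cols] -= values[:, cols].mean(axis=1, keepdims=True)
    levels = np.unique(batches)
    n = values.shape[1]
    overall = values.mean(axis=1, keepdims=True)
    ss_between = np.zeros(values.shape[0])
    ss_within = np.zeros(values.shape[0])
    for b in levels:
        cols = batches == b
        bm = values[:, cols].mean(axis=1, keepdims=True)
        ss_between += cols.sum() * ((bm - overall) ** 2).ravel()
        ss_within += ((values[:, cols] - bm) ** 2).sum(axis=1)
    df_b = len(levels) - 1
    df_w = n - len(levels)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_between / df_b) / (ss_within / df_w)
    return f
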