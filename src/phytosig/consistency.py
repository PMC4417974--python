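"""Sample-consistency analytics: correlation maps, R2E seriation, PCA.

The centerpiece is rank-two elliptical (R2E) seriation: iterating the
correlation-of-correlation map R_{k+1} = corr(R_k) drives the matrix toward
rank two, at which point the objects lie on an ellipse in the plane of the two
leading eigenvectors; ordering them by angle and cutting the circle at the
largest angular gap yields a one-dimensional seriation. ``hct_r2e`` combines
an average-linkage dendrogram (distance 1 - r) with internal-node flips chosen
to agree with the R2E order — the leaf order used to sort correlation matrix
maps for batch-consistency QC.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)


@dataclass
class CorrelationMatrix:
    """Symmetric Pearson correlation matrix with unit diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape[0] != v.shape[1] or v.shape[0] != len(self.labels):
            raise ValueError("correlation matrix shape must match labels")
        if np.max(np.abs(v - v.T)) > 1e-12:
            raise ValueError("correlation matrix must be symmetric to 1e-12")
        v = (v + v.T) / 2.0
        np.fill_diagonal(v, 1.0)
        if np.min(v) < -1.0 - 1e-12 or np.max(v) > 1.0 + 1e-12:
            raise ValueError("correlation entries must lie in [-1, 1]")
        self.values = np.clip(v, -1.0, 1.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass
class SeriationResult:
    order: list[str]
    angles: dict
    n_iterations: int
    dendrogram: np.ndarray | None = None  # scipy linkage matrix, if tree-based

    def __post_init__(self) -> None:
        if sorted(self.order) != sorted(self.angles.keys()):
            raise ValueError("order must be a permutation of the labeled objects")


def pearson_matrix(matrix, axis: str = "samples") -> CorrelationMatrix:
    """Pearson product-moment correlation between samples (or probes)."""
    if axis not in ("samples", "probes"):
        raise ValueError("axis must be 'samples' or 'probes'")
    values = matrix.values if hasattr(matrix, "values") else np.asarray(matrix, float)
    labels = (
        list(matrix.sample_ids if axis == "samples" else matrix.probe_ids)
        if hasattr(matrix, "sample_ids")
        else [str(i) for i in range(values.shape[1] if axis == "samples" else values.shape[0])]
    )
    obs = values.T if axis == "samples" else values  # rows = objects to correlate
    if obs.shape[1] < 3:
        raise ValueError("pearson_matrix needs at least 3 observations per object")
    sd = obs.std(axis=1)
    if np.any(sd == 0):
        bad = [labels[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero-variance object(s): {bad}")
    corr = np.corrcoef(obs)
    corr = (corr + corr.T) / 2.0
    np.fill_diagonal(corr, 1.0)
    return CorrelationMatrix(labels, np.clip(corr, -1.0, 1.0))


def pairwise_consistency(matrix) -> tuple[pd.DataFrame, dict]:
    """All C(n, 2) unordered sample pairs with their Pearson r, plus a summary."""
    values = matrix.values if hasattr(matrix, "values") else np.asarray(matrix, float)
    if values.shape[1] < 2:
        raise ValueError("pairwise consistency needs at least 2 samples")
    corr = pearson_matrix(matrix, axis="samples")
    rows = [
        (a, b, corr.values[i, j])
        for (i, a), (j, b) in combinations(enumerate(corr.labels), 2)
    ]
    table = pd.DataFrame(rows, columns=["sample_a", "sample_b", "r"])
    imin, imax = int(table["r"].idxmin()), int(table["r"].idxmax())
    summary = {
        "n_pairs": len(table),
        "min_r": float(table.loc[imin, "r"]),
        "min_pair": (table.loc[imin, "sample_a"], table.loc[imin, "sample_b"]),
        "max_r": float(table.loc[imax, "r"]),
        "max_pair": (table.loc[imax, "sample_a"], table.loc[imax, "sample_b"]),
    }
    return table, summary


def _fix_sign(v: np.ndarray) -> np.ndarray:
    i = int(np.argmax(np.abs(v)))
    return v if v[i] > 0 else -v


def r2e_seriation(corr: CorrelationMatrix, tol: float = 1e-9, max_iter: int = 100) -> SeriationResult:
    """Order objects by angle on the rank-two ellipse of iterated correlations.

    Iterates R -> corr(R) (rows as observations) until |lambda_3|/|lambda_1| <
    ``tol``, then sorts objects by theta_i = atan2(v2_i, v1_i) of the two
    leading eigenvectors and cuts the circular order at the largest angular
    gap. Equal angles tie-break by original index. A fully degenerate map
    (identical correlations everywhere) returns the stable input order.
    """
    R = corr.values.copy()
    n = R.shape[0]
    if n < 3:
        raise ValueError("r2e_seriation needs at least 3 objects")
    n_iter = 0
    converged = False
    for n_iter in range(max_iter + 1):
        off_diag = R[~np.eye(n, dtype=bool)]
        if off_diag.max() - off_diag.min() < 1e-12 or np.any(R.std(axis=1) == 0):
            logger.warning("r2e_seriation: degenerate correlation map; stable order returned")
            return SeriationResult(
                order=list(corr.labels),
                angles={lab: 0.0 for lab in corr.labels},
                n_iterations=n_iter,
            )
        lam = np.linalg.eigvalsh(R)
        mag = np.sort(np.abs(lam))[::-1]
        if mag[2] / mag[0] < tol:
            converged = True
            break
        if n_iter == max_iter:
            break
        R = np.corrcoef(R)
        R = (R + R.T) / 2.0
        np.fill_diagonal(R, 1.0)
    if not converged:
        warnings.warn("r2e_seriation did not converge to rank 2; using current map")

    lam, vec = np.linalg.eigh(R)
    idx = np.argsort(np.abs(lam))[::-1]
    v1 = _fix_sign(vec[:, idx[0]])
    v2 = _fix_sign(vec[:, idx[1]])
    theta = np.arctan2(v2, v1)
    order_idx = np.lexsort((np.arange(n), theta))
    sorted_theta = theta[order_idx]
    gaps = np.diff(np.concatenate([sorted_theta, [sorted_theta[0] + 2 * np.pi]]))
    cut = int(np.argmax(gaps)) + 1  # linear order starts after the widest gap
    order_idx = np.concatenate([order_idx[cut:], order_idx[:cut]])
    return SeriationResult(
        order=[corr.labels[i] for i in order_idx],
        angles={corr.labels[i]: float(theta[i]) for i in range(n)},
        n_iterations=n_iter,
    )


def _optimal_flip(node, ranks: dict[int, float], offset: int, memo: dict):
    """Minimal total |leaf position - R2E rank| over all internal-node flips.

    Exact per-node dynamic programme: each binary node independently chooses
    which child block comes first, given the node's leaf offset.
    """
    key = (id(node), offset)
    if key in memo:
        return memo[key]
    if node.is_leaf():
        res = (abs(offset - ranks[node.id]), [node.id])
        memo[key] = res
        return res
    nl, nr = node.left.count, node.right.count
    cl1, ol1 = _optimal_flip(node.left, ranks, offset, memo)
    cr1, or1 = _optimal_flip(node.right, ranks, offset + nl, memo)
    cl2, ol2 = _optimal_flip(node.right, ranks, offset, memo)
    cr2, or2 = _optimal_flip(node.left, ranks, offset + nr, memo)
    if cl1 + cr1 <= cl2 + cr2:
        res = (cl1 + cr1, ol1 + or1)
    else:
        res = (cl2 + cr2, ol2 + or2)
    memo[key] = res
    return res


def hct_r2e(corr: CorrelationMatrix) -> SeriationResult:
    """Average-linkage tree on 1 - r with leaf order flipped toward the R2E rank."""
    r2e = r2e_seriation(corr)
    rank = {lab: i for i, lab in enumerate(r2e.order)}
    dist = 1.0 - corr.values
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    tree = to_tree(Z)
    _, leaf_ids = _optimal_flip(tree, {i: rank[lab] for i, lab in enumerate(corr.labels)}, 0, {})
    return SeriationResult(
        order=[corr.labels[i] for i in leaf_ids],
        angles=dict(r2e.angles),
        n_iterations=r2e.n_iterations,
        dendrogram=Z,
    )


@dataclass
class PCAResult:
    labels: list[str]
    coordinates: np.ndarray  # (n_samples, 2)
    variance_fractions: tuple[float, float]
    eigenvalues: np.ndarray


def pca_correlation(rel) -> PCAResult:
    """PCA of the sample correlation matrix of relative expression.

    Coordinates are eigenvector * sqrt(eigenvalue) for the two leading
    components; each component's sign is fixed so its largest-magnitude
    loading is positive.
    """
    corr = pearson_matrix(rel, axis="samples")
    if len(corr.labels) < 3:
        raise ValueError("pca_correlation needs at least 3 samples")
    lam, vec = np.linalg.eigh(corr.values)
    idx = np.argsort(lam)[::-1]
    lam, vec = lam[idx], vec[:, idx]
    v1, v2 = _fix_sign(vec[:, 0]), _fix_sign(vec[:, 1])
    coords = np.column_stack([v1 * np.sqrt(max(lam[0], 0.0)), v2 * np.sqrt(max(lam[1], 0.0))])
    total = lam.sum()
    return PCAResult(
        labels=list(corr.labels),
        coordinates=coords,
        variance_fractions=(float(lam[0] / total), float(lam[1] / total)),
        eigenvalues=lam,
    )


def render_matrix_map(values, labels, order, path, vmin=-1.0, vmax=1.0, cmap="RdBu_r") -> None:
    """Write a deterministic one-pixel-per-cell raster of a reordered matrix."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    from matplotlib import image as mimage

    values = np.asarray(values, dtype=float)
    idx = [list(labels).index(lab) for lab in order]
    reordered = values[np.ix_(idx, idx)]
    scaled = np.clip((reordered - vmin) / (vmax - vmin), 0.0, 1.0)
    mimage.imsave(path, scaled, cmap=cmap, vmin=0.0, vmax=1.0, origin="upper")
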