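"""Over-representation analysis of a query gene set against a collection.

For each gene set the overlap with the query is scored by the upper-tail
hypergeometric probability P(X >= k) with the measured-and-uniquely-mapped
gene universe as background; q-values are Benjamini–Hochberg. A set is
*retained* when p < 0.05, q < 0.05 and the overlap has at least 4 genes (all
three thresholds configurable).
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GeneSetCollection

logger = logging.getLogger(__name__)


def hypergeom_p(overlap: int, query_size: int, set_size: int, universe_size: int) -> float:
    """Exact upper-tail hypergeometric probability P(X >= overlap)."""
    if overlap > min(query_size, set_size):
        raise ValueError("overlap cannot exceed min(query size, set size)")
    if query_size > universe_size or set_size > universe_size:
        raise ValueError("query and set must fit inside the universe")
    if overlap <= 0:
        return 1.0
    return float(stats.hypergeom.sf(overlap - 1, universe_size, set_size, query_size))


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values with monotonicity, clipped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_ora(
    query_genes: Iterable[str],
    collection: GeneSetCollection,
    universe: Iterable[str],
    p_max: float = 0.05,
    q_max: float = 0.05,
    min_overlap: int = 4,
) -> pd.DataFrame:
    """Hypergeometric ORA of ``query_genes`` against every set in ``collection``.

    Query genes outside the universe are logged and dropped; every gene set is
    likewise intersected with the universe. Results are sorted by p ascending
    (ties by set name) with a ``retained`` flag applying the three filters.
    """
    universe = set(universe)
    query = set(query_genes)
    outside = query - universe
    if outside:
        logger.warning("run_ora: %d query gene(s) outside the universe dropped", len(outside))
    query &= universe
    rows = []
    for gs in collection:
        members = gs.genes & universe
        if not members:
            continue
        hit = query & members
        p = hypergeom_p(len(hit), len(query), len(members), len(universe)) if query else 1.0
        rows.append(
            {
                "name": gs.name,
                "set_size": len(members),
                "overlap_count": len(hit),
                "overlap_genes": ",".join(sorted(hit)),
                "p_hyper": p,
            }
        )
    table = pd.DataFrame(rows)
    if table.empty:
        return pd.DataFrame(
            columns=["name", "set_size", "overlap_count", "overlap_genes", "p_hyper", "q_bh", "retained"]
        )
    table = table.sort_values("name", kind="stable")  # order-independent of file order
    table["q_bh"] = bh_fdr(table["p_hyper"].to_numpy())
    table["retained"] = (
        (table["p_hyper"] < p_max) & (table["q_bh"] < q_max) & (table["overlap_count"] >= min_overlap)
    )
    table = table.sort_values(["p_hyper", "name"], kind="stable").reset_index(drop=True)
    return table
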