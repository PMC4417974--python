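"""Jin's combination-index analysis of two-drug effect fractions.

For arm-level effect fractions D1, D2 (each drug alone) and D12 (the
combination), the combination index is

    q = D12 / (D1 + D2 − D1·D2),

the observed combined effect relative to the effect expected under
probabilistic independence of the two drugs. q > 1.15 is scored synergistic,
q < 0.85 antagonistic, and values between the two (inclusive) additive.
Effects are *fractions affected* (e.g. dead-cell proportion), not viability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CombinationTable

SYNERGY_THRESHOLD = 1.15
ANTAGONISM_THRESHOLD = 0.85


@dataclass
class CombinationMeasurement:
    D1: float
    D2: float
    D12: float

    def __post_init__(self) -> None:
        for name in ("D1", "D2", "D12"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be an effect fraction in [0, 1], got {v}")


@dataclass
class SynergyResult:
    q: float
    q_rounded: float
    interaction: str  # synergistic | additive | antagonistic


def combination_index(m: CombinationMeasurement) -> float:
    """q = D12 / (D1 + D2 − D1·D2); undefined when both single effects are 0."""
    denom = m.D1 + m.D2 - m.D1 * m.D2
    if denom <= 0.0:
        raise ValueError("combination index undefined: D1 + D2 - D1*D2 must be > 0")
    return m.D12 / denom


def classify_interaction(
    q: float,
    synergy_threshold: float = SYNERGY_THRESHOLD,
    antagonism_threshold: float = ANTAGONISM_THRESHOLD,
) -> str:
    """Boundaries inclusive for additivity: 0.85 <= q <= 1.15 is additive."""
    if not np.isfinite(q):
        raise ValueError("q must be finite")
    if q > synergy_threshold:
        return "synergistic"
    if q < antagonism_threshold:
        return "antagonistic"
    return "additive"


def evaluate(m: CombinationMeasurement) -> SynergyResult:
    q = combination_index(m)
    # round-half-even to 2 decimals for reporting; full precision retained in q
    return SynergyResult(q=q, q_rounded=round(q, 2), interaction=classify_interaction(q))


def effects_from_percentages(d1_pct: float, d2_pct: float, d12_pct: float) -> CombinationMeasurement:
    """Convert arm-level percentages (e.g. % dead cells) to effect fractions."""
    for name, v in (("D1", d1_pct), ("D2", d2_pct), ("D12", d12_pct)):
        if not 0.0 <= v <= 100.0:
            raise ValueError(f"{name} percentage must be in [0, 100], got {v}")
    return CombinationMeasurement(d1_pct / 100.0, d2_pct / 100.0, d12_pct / 100.0)


def evaluate_table(table: CombinationTable) -> pd.DataFrame:
    """Jin's q and interaction class for every row of a combination table."""
    rows = []
    for _, row in table.table.iterrows():
        res = evaluate(CombinationMeasurement(float(row.D1), float(row.D2), float(row.D12)))
        rows.append(
            {
                "label": row.label,
                "D1": row.D1,
                "D2": row.D2,
                "D12": row.D12,
                "q": res.q,
                "q_rounded": res.q_rounded,
                "interaction": res.interaction,
            }
        )
    return pd.DataFrame(rows)
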