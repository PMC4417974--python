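"""Rank-based KS connectivity scoring of a signature against reference profiles.

This is the Connectivity-Map-style pattern match: a reference *instance* is
the full probe universe ranked by differential expression (rank 1 = most
up-regulated). For an ordered tag set of size t whose tags sit at ascending
ranks V(1) < … < V(t) in a universe of size n, the signed KS enrichment is

    a  = max_j [ j/t − V(j)/n ]
    b  = max_j [ V(j)/n − (j−1)/t ]
    ks = a  if a > b  else  −b

so ks → +1 when the tags crowd the top of the ranking and → −1 at the bottom.
A query signature (up-tags, down-tags) scores

    raw = ks_up − ks_down   if the two have opposite signs, else 0,

positive raw meaning the reference instance mimics the query. Raw scores are
scaled per batch of instances (positives by the max positive, negatives by
the magnitude of the most negative) to [−1, 1]. Empirical p-values come from
random tag sets of the same sizes, and a robustness analysis measures how
often each reference agent lands in the top-k under thousands of random
queries of sizes 100–500.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass
class RankedProfile:
    """One reference instance: every probe id in rank order (rank 1 first)."""

    instance: str
    agent: str
    probes: list[str]
    _rank: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.probes = list(self.probes)
        if len(self.probes) < 2:
            raise ValueError("a ranked profile needs at least 2 probes")
        self._rank = {p: i + 1 for i, p in enumerate(self.probes)}
        if len(self._rank) != len(self.probes):
            raise ValueError(f"profile {self.instance!r}: ranked probes are not unique")

    @property
    def n(self) -> int:
        return len(self.probes)

    def ranks_of(self, tags: Sequence[str]) -> np.ndarray:
        missing = [t for t in tags if t not in self._rank]
        if missing:
            raise ValueError(f"tag(s) absent from profile universe: {missing[:5]}")
        return np.sort(np.array([self._rank[t] for t in tags], dtype=float))


def _ks_from_sorted_ranks(v: np.ndarray, n: int) -> float:
    t = v.shape[0]
    j = np.arange(1, t + 1, dtype=float)
    a = np.max(j / t - v / n)
    b = np.max(v / n - (j - 1.0) / t)
    return float(a) if a > b else float(-b)


def ks_enrichment(profile: RankedProfile, tags: Sequence[str]) -> float:
    """Signed KS enrichment of a tag set within a ranked profile, in (−1, 1]."""
    if len(tags) < 1:
        raise ValueError("tag set must be non-empty")
    v = profile.ranks_of(tags)
    return _ks_from_sorted_ranks(v, profile.n)


def connectivity_score(
    profile: RankedProfile, up_tags: Sequence[str], down_tags: Sequence[str]
) -> tuple[float, float, float]:
    """(raw, ks_up, ks_down); raw = ks_up − ks_down when signs differ, else 0."""
    if set(up_tags) & set(down_tags):
        raise ValueError("up and down tag sets must be disjoint")
    ks_up = ks_enrichment(profile, up_tags)
    ks_down = ks_enrichment(profile, down_tags)
    raw = 0.0 if ks_up * ks_down > 0 else ks_up - ks_down
    return raw, ks_up, ks_down


def scale_scores(raw_scores: Sequence[float]) -> np.ndarray:
    """Sign-specific rescale of raw scores to [−1, 1]; zeros stay 0."""
    raw = np.asarray(raw_scores, dtype=float)
    if raw.size == 0:
        raise ValueError("need at least one instance")
    scaled = np.zeros_like(raw)
    pos, neg = raw > 0, raw < 0
    if pos.any():
        scaled[pos] = raw[pos] / raw[pos].max()
    if neg.any():
        scaled[neg] = raw[neg] / np.abs(raw[neg].min())
    return scaled


def score_instances(
    profiles: Sequence[RankedProfile], up_tags: Sequence[str], down_tags: Sequence[str]
) -> pd.DataFrame:
    """Score every reference instance against one query; add scaled scores."""
    rows = []
    for p in profiles:
        raw, ks_up, ks_down = connectivity_score(p, up_tags, down_tags)
        rows.append({"instance": p.instance, "agent": p.agent, "ks_up": ks_up, "ks_down": ks_down, "raw": raw})
    table = pd.DataFrame(rows)
    table["scaled"] = scale_scores(table["raw"].to_numpy())
    return table.sort_values(["scaled", "instance"], ascending=[False, True], kind="stable").reset_index(
        drop=True
    )


def permutation_p(
    profile: RankedProfile,
    t_up: int,
    t_down: int,
    observed_raw: float,
    n_perm: int = 1000,
    seed: int = 0,
) -> float:
    """Empirical p = (1 + #{null >= observed}) / (n_perm + 1) from random tags."""
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    n = profile.n
    count = 0
    j_up = np.arange(1, t_up + 1, dtype=float)
    j_down = np.arange(1, t_down + 1, dtype=float)
    for _ in range(n_perm):
        ranks = rng.choice(n, size=t_up + t_down, replace=False) + 1.0
        vu = np.sort(ranks[:t_up])
        vd = np.sort(ranks[t_up:])
        ks_u = _ks_from_sorted_ranks(vu, n)
        ks_d = _ks_from_sorted_ranks(vd, n)
        raw = 0.0 if ks_u * ks_d > 0 else ks_u - ks_d
        if raw >= observed_raw:
            count += 1
    return (1.0 + count) / (n_perm + 1.0)


def random_query_robustness(
    profiles: Sequence[RankedProfile],
    sizes: Sequence[int] = (100, 200, 300, 400, 500),
    n_rep: int = 1000,
    top_k: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-agent fraction of random queries in which the agent reaches the top-k.

    For each query size, ``n_rep`` random queries are drawn from the common
    probe universe without replacement and split evenly into up/down tags;
    every reference instance is scored and the agents of the ``top_k``
    instances by scaled score are recorded. The returned table gives each
    agent's occupancy ratio overall and per size.
    """
    if not profiles:
        raise ValueError("need at least one reference profile")
    n = profiles[0].n
    if any(p.n != n for p in profiles):
        raise ValueError("all profiles must share one probe universe size")
    if max(sizes) > n // 2:
        raise ValueError("query sizes must not exceed half the universe")
    universe = profiles[0].probes
    if any(set(p.probes) != set(universe) for p in profiles[1:]):
        raise ValueError("all profiles must share one probe universe")

    # rank lookup matrix: instance × universe position -> rank
    index_of = {p: i for i, p in enumerate(universe)}
    rank_matrix = np.empty((len(profiles), n), dtype=np.int64)
    for i, prof in enumerate(profiles):
        for r, probe in enumerate(prof.probes, start=1):
            rank_matrix[i, index_of[probe]] = r

    rng = np.random.default_rng(seed)
    agents = [p.agent for p in profiles]
    instances = [p.instance for p in profiles]
    counts: dict[tuple[int, str], int] = {(s, a): 0 for s in sizes for a in set(agents)}
    for size in sizes:
        t_up = size // 2
        for _ in range(n_rep):
            pick = rng.choice(n, size=size, replace=False)
            up_idx, down_idx = pick[:t_up], pick[t_up:]
            vu = np.sort(rank_matrix[:, up_idx], axis=1).astype(float)
            vd = np.sort(rank_matrix[:, down_idx], axis=1).astype(float)
            ju = np.arange(1, vu.shape[1] + 1, dtype=float)
            jd = np.arange(1, vd.shape[1] + 1, dtype=float)
            au = np.max(ju / vu.shape[1] - vu / n, axis=1)
            bu = np.max(vu / n - (ju - 1.0) / vu.shape[1], axis=1)
            ks_u = np.where(au > bu, au, -bu)
            ad = np.max(jd / vd.shape[1] - vd / n, axis=1)
            bd = np.max(vd / n - (jd - 1.0) / vd.shape[1], axis=1)
            ks_d = np.where(ad > bd, ad, -bd)
            raw = np.where(ks_u * ks_d > 0, 0.0, ks_u - ks_d)
            scaled = scale_scores(raw)
            # ties (notably the atom of zero scores) are broken by a fresh
            # seeded permutation so no agent is favored by its label
            tiebreak = rng.permutation(len(profiles))
            order = np.lexsort((tiebreak, -scaled))[:top_k]
            for i in order:
                counts[(size, agents[i])] += 1
    rows = []
    for agent in sorted(set(agents)):
        row = {"agent": agent}
        total = 0
        for size in sizes:
            c = counts[(size, agent)]
            row[f"ratio_{size}"] = c / n_rep
            total += c
        row["ratio"] = total / (n_rep * len(sizes))
        rows.append(row)
    return pd.DataFrame(rows)
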