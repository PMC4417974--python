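"""KS enrichment statistic, connectivity scores, permutation null, robustness."""

import numpy as np
import pytest

from phytosig import connectivity as conn
from phytosig import simulate as sim


def _profile(n, seed=None, instance="i", agent="a"):
    probes = [f"P{i:05d}" for i in range(n)]
    if seed is not None:
        rng = np.random.default_rng(seed)
        probes = [probes[k] for k in rng.permutation(n)]
    return conn.RankedProfile(instance, agent, probes)


def _literal_ks(ranks, n):
    """Brute-force scan of the definition, one j at a time."""
    v = sorted(ranks)
    t = len(v)
    a = max(j / t - v[j - 1] / n for j in range(1, t + 1))
    b = max(v[j - 1] / n - (j - 1) / t for j in range(1, t + 1))
    return a if a > b else -b


class TestKSEnrichment:
    def test_tags_at_top(self):
        p = _profile(10)
        assert conn.ks_enrichment(p, ["P00000", "P00001"]) == pytest.approx(0.8)

    def test_tags_at_bottom(self):
        p = _profile(10)
        assert conn.ks_enrichment(p, ["P00008", "P00009"]) == pytest.approx(-0.9)

    def test_matches_literal_scan_random_cases(self):
        rng = np.random.default_rng(0)
        p = _profile(500)
        for _ in range(200):
            t = int(rng.integers(1, 60))
            tags = [f"P{i:05d}" for i in rng.choice(500, size=t, replace=False)]
            ranks = [p.probes.index(x) + 1 for x in tags]
            assert conn.ks_enrichment(p, tags) == pytest.approx(
                _literal_ks(ranks, 500), abs=1e-12
            )

    def test_antisymmetric_under_profile_reversal(self):
        """Reversing the ranking swaps the top/bottom maxima exactly:
        a' = b - 1/n and b' = a + 1/n, so ks flips sign up to 1/n except
        where the a-vs-b decision itself is within 2/n of a tie."""
        rng = np.random.default_rng(1)
        for seed in range(20):
            p = _profile(200, seed=seed)
            n, t = p.n, 15
            rev = conn.RankedProfile("r", "a", p.probes[::-1])
            tags = [p.probes[i] for i in rng.choice(200, size=t, replace=False)]
            v = sorted(p.probes.index(x) + 1 for x in tags)
            a = max(j / t - v[j - 1] / n for j in range(1, t + 1))
            b = max(v[j - 1] / n - (j - 1) / t for j in range(1, t + 1))
            a_rev, b_rev = b - 1.0 / n, a + 1.0 / n
            predicted = a_rev if a_rev > b_rev else -b_rev
            assert conn.ks_enrichment(rev, tags) == pytest.approx(predicted, abs=1e-12)
            if abs(a - b) > 2.0 / n:
                assert abs(conn.ks_enrichment(rev, tags) + conn.ks_enrichment(p, tags)) <= (
                    1.0 / n + 1e-12
                )

    def test_unknown_tag_named(self):
        with pytest.raises(ValueError, match="PXXXXX"):
            conn.ks_enrichment(_profile(10), ["PXXXXX"])


class TestConnectivityScore:
    def test_opposite_signs_subtract(self):
        p = _profile(100)
        up = [f"P{i:05d}" for i in range(5)]  # top
        down = [f"P{i:05d}" for i in range(95, 100)]  # bottom
        raw, ks_up, ks_down = conn.connectivity_score(p, up, down)
        assert ks_up > 0 > ks_down
        assert raw == pytest.approx(ks_up - ks_down)
        assert raw > 1.8  # approaches 2 as t/n -> 0

    def test_same_sign_zero_rule(self):
        p = _profile(100)
        up = [f"P{i:05d}" for i in range(5)]
        down = [f"P{i:05d}" for i in range(5, 10)]  # also at the top
        raw, ks_up, ks_down = conn.connectivity_score(p, up, down)
        assert ks_up > 0 and ks_down > 0
        assert raw == 0.0

    def test_overlapping_tags_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            conn.connectivity_score(_profile(10), ["P00001"], ["P00001"])

    def test_raw_bounded(self):
        rng = np.random.default_rng(5)
        for seed in range(30):
            p = _profile(100, seed=seed)
            pick = rng.choice(100, size=20, replace=False)
            up = [f"P{i:05d}" for i in pick[:10]]
            down = [f"P{i:05d}" for i in pick[10:]]
            raw, *_ = conn.connectivity_score(p, up, down)
            assert -2.0 <= raw <= 2.0


class TestScaleScores:
    def test_singleton_positive(self):
        np.testing.assert_allclose(conn.scale_scores([0.7]), [1.0])

    def test_all_zero(self):
        np.testing.assert_allclose(conn.scale_scores([0.0, 0.0]), [0.0, 0.0])

    def test_sign_specific_scaling(self):
        scaled = conn.scale_scores([1.0, 0.5, -0.2, -0.8, 0.0])
        np.testing.assert_allclose(scaled, [1.0, 0.5, -0.25, -1.0, 0.0])
        assert np.argmax(scaled) == 0


class TestPermutationP:
    def test_add_one_rule_lower_bound(self):
        p = _profile(200, seed=0)
        pv = conn.permutation_p(p, 5, 5, observed_raw=2.5, n_perm=100, seed=1)
        assert pv == pytest.approx(1 / 101)

    def test_observed_zero_near_null_mass_above_zero(self):
        """p(0) estimates P(null >= 0), which includes the atom at zero."""
        p = _profile(500, seed=2)
        pv = conn.permutation_p(p, 10, 10, observed_raw=0.0, n_perm=400, seed=3)
        assert 0.5 <= pv <= 0.95

    def test_deterministic_under_seed(self):
        p = _profile(300, seed=4)
        args = dict(t_up=8, t_down=8, observed_raw=0.9, n_perm=150, seed=9)
        assert conn.permutation_p(p, **args) == conn.permutation_p(p, **args)

    def test_super_uniform_under_null(self):
        """For random queries, P(p <= t) <= t + 3 SE for every t (validity);
        exact uniformity is impossible because the null has an atom at 0."""
        prof = _profile(400, seed=6)
        rng = np.random.default_rng(7)
        pvals = []
        for i in range(150):
            pick = rng.choice(400, size=20, replace=False)
            up = [f"P{k:05d}" for k in pick[:10]]
            down = [f"P{k:05d}" for k in pick[10:]]
            raw, *_ = conn.connectivity_score(prof, up, down)
            pvals.append(conn.permutation_p(prof, 10, 10, raw, n_perm=200, seed=1000 + i))
        pvals = np.asarray(pvals)
        for t in (0.05, 0.1, 0.2, 0.5):
            se = np.sqrt(t * (1 - t) / pvals.size)
            assert (pvals <= t).mean() <= t + 3 * se


class TestRobustness:
    def test_exchangeable_profiles_uniform_occupancy(self):
        """20 random-agent profiles: each agent's top-5 ratio ~ 5/20."""
        profiles = [
            _profile(2000, seed=i, instance=f"inst{i:02d}", agent=f"agent{i:02d}")
            for i in range(20)
        ]
        table = conn.random_query_robustness(
            profiles, sizes=(100, 200), n_rep=250, top_k=5, seed=0
        )
        n_queries = 2 * 250
        se = np.sqrt(0.25 * 0.75 / n_queries)
        assert np.all(np.abs(table["ratio"] - 0.25) <= 3 * se)

    def test_connected_instance_dominates_real_query_not_random(self):
        up = [f"P{i:05d}" for i in range(30)]
        down = [f"P{i:05d}" for i in range(30, 60)]
        profiles = sim.generate_reference_profiles(20, 1000, (up, down), seed=5)
        scores = conn.score_instances(profiles, up, down)
        assert scores.iloc[0]["agent"] == "connected"
        table = conn.random_query_robustness(profiles, sizes=(60,), n_rep=150, top_k=5, seed=2)
        connected_ratio = float(table.set_index("agent").loc["connected", "ratio"])
        assert connected_ratio < 0.6  # no privileged role under random queries

    def test_single_rep_deterministic(self):
        profiles = [
            _profile(500, seed=i, instance=f"i{i}", agent=f"a{i}") for i in range(6)
        ]
        t1 = conn.random_query_robustness(profiles, sizes=(50,), n_rep=1, top_k=2, seed=3)
        t2 = conn.random_query_robustness(profiles, sizes=(50,), n_rep=1, top_k=2, seed=3)
        assert t1.equals(t2)
        assert t1["ratio"].sum() == pytest.approx(2.0)  # ratios sum to top_k
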