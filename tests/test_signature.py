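"""Differential statistics, fold-change filtering, and signature assembly."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats as st

from phytosig import signature as sg
from phytosig import simulate as sim


class TestOrdinaryT:
    def test_identical_groups_give_t0_p1(self):
        m = np.array([[1.0, 2.0, 3.0, 1.0, 2.0, 3.0]])
        out = sg.two_sample_ttest(m, ["treated"] * 3 + ["vehicle"] * 3)
        assert out["t_ordinary"].iloc[0] == 0.0
        assert out["p_ordinary"].iloc[0] == pytest.approx(1.0)

    def test_matches_pooled_closed_form(self):
        x, y = np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0])
        out = sg.two_sample_ttest(
            np.array([np.concatenate([x, y])]), ["treated"] * 3 + ["vehicle"] * 3
        )
        sp2 = (((x - x.mean()) ** 2).sum() + ((y - y.mean()) ** 2).sum()) / 4
        t_expected = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
        p_expected = 2 * st.t.sf(abs(t_expected), 4)
        assert out["t_ordinary"].iloc[0] == pytest.approx(t_expected, abs=1e-10)
        assert out["p_ordinary"].iloc[0] == pytest.approx(p_expected, abs=1e-10)

    def test_zero_variance_probe_flagged(self):
        m = np.array([[1.0, 1.0, 2.0, 2.0]])
        out = sg.two_sample_ttest(m, ["treated", "treated", "vehicle", "vehicle"])
        assert bool(out["zero_variance"].iloc[0])
        assert out["p_ordinary"].iloc[0] == 1.0

    def test_null_rejection_rate_calibrated(self):
        cfg = sim.SimulationConfig(
            seed=1,
            n_probes=5000,
            frac_de=0.0,
            batch_shift_sd=0.0,
            batch_scale_shape=0.0,
            design=[("vehicle", "vehicle", "B1", 3), ("PG2", "treated", "B1", 11)],
        )
        matrix, _ = sim.generate_expression(cfg)
        out = sg.two_sample_ttest(matrix)
        rate = float((out["p_ordinary"] < 0.01).mean())
        assert 0.005 <= rate <= 0.015


class TestModeratedT:
    def test_equal_variance_limit_matches_ordinary_ranking(self):
        """With identical true variances d0 -> inf and the moderated ranking
        equals the |mean difference| ranking (common shrunk variance)."""
        rng = np.random.default_rng(0)
        m = rng.normal(0, 1.0, size=(500, 8))
        labels = ["treated"] * 4 + ["vehicle"] * 4
        out = sg.moderated_ttest(m, labels)
        assert np.isinf(out.attrs["d0"]) or out.attrs["d0"] > 50
        if np.isinf(out.attrs["d0"]):
            rank_t = np.argsort(np.abs(out["t_moderated"].to_numpy()))
            rank_d = np.argsort(np.abs(out["log2fc"].to_numpy()))
            np.testing.assert_array_equal(rank_t, rank_d)

    def test_d0_recovered_from_scaled_inv_chi2(self):
        """Variances drawn scaled-inverse-chi^2 with d0=4: estimate in [2, 8]."""
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n, d0, s0_2 = 1000, 4.0, 0.05
            s2 = s0_2 * d0 / rng.chisquare(d0, size=n)
            x = rng.normal(0, np.sqrt(s2)[:, None], size=(n, 7))
            out = sg.moderated_ttest(x, ["treated"] * 4 + ["vehicle"] * 3)
            hits += 2.0 <= out.attrs["d0"] <= 8.0
        assert hits == 100

    def test_pvalues_valid_and_monotone_in_t(self):
        rng = np.random.default_rng(3)
        m = rng.normal(0, rng.uniform(0.2, 2.0, size=(200, 1)), size=(200, 7))
        out = sg.moderated_ttest(m, ["treated"] * 4 + ["vehicle"] * 3)
        p = out["p_moderated"].to_numpy()
        assert np.all((p >= 0) & (p <= 1))
        order = np.argsort(np.abs(out["t_moderated"].to_numpy()))
        assert np.all(np.diff(p[order]) <= 1e-12)

    def test_sign_agrees_with_ordinary_t(self, signature_result):
        stats = signature_result.stats
        s1 = np.sign(stats["t_ordinary"])
        s2 = np.sign(stats["t_moderated"])
        assert np.all((s1 == s2) | (s1 == 0) | (s2 == 0))

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
    def test_matches_limma_ebayes(self, tmp_path):
        """Independent oracle: Bioconductor limma on heterogeneous variances."""
        rng = np.random.default_rng(42)
        n = 200
        s2 = 0.04 * 4 / rng.chisquare(4, size=n)
        x = np.hstack(
            [
                rng.normal(0, np.sqrt(s2)[:, None], (n, 4)) + rng.normal(0, 0.5, (n, 1)),
                rng.normal(0, np.sqrt(s2)[:, None], (n, 3)),
            ]
        )
        pd.DataFrame(x).to_csv(tmp_path / "x.csv", index=False)
        script = f"""
        suppressMessages(library(limma))
        x <- as.matrix(read.csv("{tmp_path}/x.csv", check.names=FALSE))
        design <- cbind(Intercept=1, Treat=c(1,1,1,1,0,0,0))
        fit <- eBayes(lmFit(x, design))
        write.csv(data.frame(t=fit$t[,"Treat"], p=fit$p.value[,"Treat"],
                             d0=fit$df.prior, s02=fit$s2.prior),
                  "{tmp_path}/out.csv", row.names=FALSE)
        """
        subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
        ref = pd.read_csv(tmp_path / "out.csv")
        out = sg.moderated_ttest(x, ["treated"] * 4 + ["vehicle"] * 3)
        assert out.attrs["d0"] == pytest.approx(ref["d0"].iloc[0], rel=1e-6)
        np.testing.assert_allclose(out["t_moderated"], ref["t"], atol=1e-10)
        np.testing.assert_allclose(out["p_moderated"], ref["p"], atol=1e-10)


class TestFoldChange:
    def test_boundary_inclusive_and_zero_excluded(self):
        table = pd.DataFrame(
            {"log2fc": [np.log2(1.3), 0.0, -np.log2(1.3), 0.2]},
            index=["a", "b", "c", "d"],
        )
        up, down = sg.fold_change_filter(table, threshold=1.3)
        assert up == ["a"] and down == ["c"]

    def test_matches_bruteforce_scan(self):
        rng = np.random.default_rng(9)
        table = pd.DataFrame({"log2fc": rng.normal(0, 1, 500)})
        up, down = sg.fold_change_filter(table, threshold=1.3)
        cut = np.log2(1.3)
        expected_up = [i for i in table.index if table.loc[i, "log2fc"] >= cut]
        expected_down = [i for i in table.index if table.loc[i, "log2fc"] <= -cut]
        assert up == expected_up and down == expected_down

    def test_threshold_must_exceed_one(self):
        with pytest.raises(ValueError):
            sg.fold_change_filter(pd.DataFrame({"log2fc": [0.5]}), threshold=1.0)


class TestCollapse:
    @pytest.fixture
    def stats_table(self):
        return pd.DataFrame(
            {"log2fc": [1.0, 0.5, -0.8, 0.3, -0.4]},
            index=["P1", "P2", "P3", "P4", "P5"],
        )

    def test_unmapped_and_multimapped_excluded(self, stats_table):
        pmap = {"P1": [], "P2": ["A", "B"], "P3": ["C"], "P4": ["D"], "P5": ["D"]}
        res = sg.collapse_probes_to_genes(["P1", "P2", "P3"], pmap, stats_table)
        assert res.n_unmapped == 1 and res.n_multimapped == 1
        assert res.genes == {"C": "down"}

    def test_same_sign_probes_averaged(self, stats_table):
        pmap = {"P1": ["G"], "P2": ["G"], "P3": [], "P4": [], "P5": []}
        res = sg.collapse_probes_to_genes(["P1", "P2"], pmap, stats_table)
        assert res.genes == {"G": "up"}
        assert res.gene_log2fc["G"] == pytest.approx(0.75)

    def test_conflicting_directions_dropped(self, stats_table):
        pmap = {"P1": ["G"], "P3": ["G"], "P2": [], "P4": [], "P5": []}
        res = sg.collapse_probes_to_genes(["P1", "P3"], pmap, stats_table)
        assert res.genes == {} and res.dropped_conflicts == ["G"]


class TestAssembleAndStage:
    def test_union_with_provenance(self):
        res = sg.assemble_enriched_signature(
            {"A": "up"}, {"A": "up", "B": "down"}, {"A": 1.0, "B": -1.0}
        )
        assert res.up == {"A"} and res.down == {"B"}
        assert res.provenance["A"] == {"foldchange", "clique"}

    def test_disjoint_inputs_sizes_add(self):
        res = sg.assemble_enriched_signature(
            {"A": "up"}, {"B": "down", "C": "up"}, {"A": 1, "B": -1, "C": 1}
        )
        assert len(res) == 3

    def test_conflict_resolved_by_fold_sign(self):
        res = sg.assemble_enriched_signature({"A": "up"}, {"A": "down"}, {"A": -0.7})
        assert res.down == {"A"} and res.up == set()

    def test_accounting_internally_consistent(self, signature_result):
        acc = signature_result.accounting
        surviving = acc["probes_significant"] - (
            acc["probes_excluded_no_symbol"] + acc["probes_excluded_multi_symbol"]
        )
        # every surviving gene is backed by at least one surviving probe
        assert 0 < acc["genes_candidate"] + acc["genes_conflicting_dropped"] <= surviving
        assert acc["genes_fold_change"] <= acc["genes_candidate"]
        assert acc["signature_up"] + acc["signature_down"] <= (
            acc["genes_fold_change"] + acc["genes_clique"]
        )
        assert acc["signature_up"] == len(signature_result.signature.up)
        assert acc["signature_down"] == len(signature_result.signature.down)

    def test_planted_genes_recovered(self, signature_result, default_sim):
        """Sensitivity >= 0.9 and FDR <= 0.15 on the default design (the FDR
        bound is checked as a mean over replicates in the acceptance suite)."""
        _, _, truth, _ = default_sim
        signature = signature_result.signature
        tp = len(signature.up & truth.de_genes_up) + len(signature.down & truth.de_genes_down)
        sens = tp / len(truth.de_genes_up | truth.de_genes_down)
        assert sens >= 0.9
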