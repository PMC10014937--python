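import subprocess
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import brainscape as bs
from brainscape.pathways import estimate_variance_prior

from conftest import make_matrix
from oracles import brute_gsva_walk


class TestReadGmt:
    def test_basic(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("SET1\tdesc one\tG1\tG2\nSET2\tdesc two\tG3\tG4\tG5\n")
        c = bs.read_gmt(p)
        assert c["SET1"] == frozenset({"G1", "G2"})
        assert len(c["SET2"]) == 3
        assert c.descriptions["SET1"] == "desc one"

    def test_duplicate_genes_deduplicated(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("SET1\tdesc\tG1\tG1\n")
        assert bs.read_gmt(p)["SET1"] == frozenset({"G1"})

    def test_malformed_line(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("SET1\tdesc\n")
        with pytest.raises(ValueError, match="fewer than 3"):
            bs.read_gmt(p)

    def test_duplicate_name(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("SET1\td\tG1\tG2\nSET1\td\tG3\tG4\n")
        with pytest.raises(ValueError, match="duplicate"):
            bs.read_gmt(p)


def planted_matrix(rng, n_genes=200, n_samples=20, shift=3.0, set_size=10):
    genes = [f"G{i:03d}" for i in range(n_genes)]
    X = rng.normal(0, 1, (n_genes, n_samples))
    X[:set_size, 0] += shift  # planted up-regulation in sample 0
    m = bs.ExpressionMatrix.corrected(
        pd.DataFrame(X, index=genes, columns=[f"S{j}" for j in range(n_samples)]),
        bs.Unit.LOG2TPM, "sim",
    )
    sets = bs.GeneSetCollection(
        {"PLANTED": frozenset(genes[:set_size]),
         "RANDOM": frozenset(genes[n_genes // 2: n_genes // 2 + 3 * set_size])}
    )
    return m, sets


class TestGsvaScores:
    def test_bounded(self):
        rng = np.random.default_rng(0)
        m, sets = planted_matrix(rng)
        scores = bs.gsva_scores(m, sets)
        assert scores.shape == (2, 20)
        assert (scores.to_numpy() >= -1).all() and (scores.to_numpy() <= 1).all()

    @pytest.mark.parametrize("seed", range(10))
    def test_planted_set_peaks_in_planted_sample(self, seed):
        rng = np.random.default_rng(seed)
        m, sets = planted_matrix(rng)
        scores = bs.gsva_scores(m, sets)
        planted = scores.loc["PLANTED"]
        assert planted["S0"] > 0
        assert planted.idxmax() == "S0"
        assert (planted.drop("S0") < planted["S0"]).all()

    def test_sign_flips_under_negated_shift(self):
        rng = np.random.default_rng(3)
        m, sets = planted_matrix(rng, shift=-3.0)
        scores = bs.gsva_scores(m, sets)
        assert scores.loc["PLANTED", "S0"] < 0
        assert scores.loc["PLANTED"].idxmin() == "S0"

    def test_size_filter_excludes(self):
        rng = np.random.default_rng(4)
        m, _ = planted_matrix(rng)
        sets = bs.GeneSetCollection(
            {"TINY": frozenset(m.genes[:2]), "OK": frozenset(m.genes[:30])}
        )
        scores = bs.gsva_scores(m, sets, min_size=5, max_size=500)
        assert list(scores.index) == ["OK"]
        with pytest.raises(ValueError, match="size filter"):
            bs.gsva_scores(m, bs.GeneSetCollection({"TINY": frozenset(m.genes[:2])}))

    def test_needs_three_samples(self):
        m = make_matrix(np.ones((10, 2)) + np.arange(2), unit=bs.Unit.LOG2TPM)
        with pytest.raises(ValueError, match="3 samples"):
            bs.gsva_scores(m, bs.GeneSetCollection({"S": frozenset(m.genes[:6])}))

    def test_invariant_to_gene_and_sample_order(self):
        rng = np.random.default_rng(5)
        m, sets = planted_matrix(rng, n_genes=80, n_samples=8)
        scores = bs.gsva_scores(m, sets, min_size=2)
        gperm = rng.permutation(m.genes)
        sperm = rng.permutation(m.samples)
        m2 = bs.ExpressionMatrix.corrected(
            m.values.loc[gperm, sperm], m.unit, m.dataset
        )
        scores2 = bs.gsva_scores(m2, sets, min_size=2)
        assert np.allclose(
            scores.to_numpy(), scores2[scores.columns].to_numpy(), atol=1e-12
        )

    def test_matches_loop_oracle(self):
        """Vectorized walk equals the from-scratch per-sample loop oracle."""
        from brainscape.pathways import _kernel_cdf_statistic

        rng = np.random.default_rng(6)
        m, sets = planted_matrix(rng, n_genes=60, n_samples=6)
        scores = bs.gsva_scores(m, sets, min_size=2)
        Z = _kernel_cdf_statistic(m.values.to_numpy())
        for name, members in sets.sets.items():
            for j, s in enumerate(m.samples):
                expected = brute_gsva_walk(Z[:, j], m.genes, members)
                assert scores.loc[name, s] == pytest.approx(expected, abs=1e-12)


class TestModeratedT:
    def _scores(self, rng, n_path=100, na=10, nb=10, scales=None):
        X = rng.normal(0, 1, (n_path, na + nb))
        if scales is not None:
            X *= scales[:, None]
        return pd.DataFrame(
            X, index=[f"P{i}" for i in range(n_path)],
            columns=[f"A{i}" for i in range(na)] + [f"B{i}" for i in range(nb)],
        )

    def test_d0_zero_equals_pooled_t(self):
        rng = np.random.default_rng(0)
        scores = self._scores(rng)
        ga = [c for c in scores if c.startswith("A")]
        gb = [c for c in scores if c.startswith("B")]
        table = bs.moderated_t_test(scores, ga, gb, d0=0.0)
        t_ref, p_ref = stats.ttest_ind(
            scores[ga], scores[gb], axis=1, equal_var=True
        )
        assert np.allclose(table["t"], t_ref, atol=1e-12)
        assert np.allclose(table["p_value"], p_ref, atol=1e-12)

    def test_identical_groups_null_point(self):
        scores = pd.DataFrame(
            {"A1": [1.0], "A2": [2.0], "B1": [1.0], "B2": [2.0]}, index=["P"]
        )
        table = bs.moderated_t_test(scores, ["A1", "A2"], ["B1", "B2"], d0=0.0)
        assert table.loc["P", "mean_diff"] == 0
        assert table.loc["P", "t"] == 0
        assert table.loc["P", "p_value"] == 1

    def test_null_calibration(self):
        rng = np.random.default_rng(1234)
        scores = self._scores(rng, n_path=1000, na=20, nb=20)
        ga = [c for c in scores if c.startswith("A")]
        gb = [c for c in scores if c.startswith("B")]
        table = bs.moderated_t_test(scores, ga, gb)
        frac = (table["p_value"] < 0.05).mean()
        assert frac == pytest.approx(0.05, abs=0.02)

    def test_d0_infinity_pins_variance_to_prior(self):
        rng = np.random.default_rng(2)
        scores = self._scores(rng, n_path=50)
        ga = [c for c in scores if c.startswith("A")]
        gb = [c for c in scores if c.startswith("B")]
        table = bs.moderated_t_test(scores, ga, gb, d0=np.inf, s0_squared=1.0)
        diff = scores[ga].mean(axis=1) - scores[gb].mean(axis=1)
        expected = diff / np.sqrt(1.0 * (1 / 10 + 1 / 10))
        assert np.allclose(table["t"], expected)

    def test_group_validation(self):
        rng = np.random.default_rng(3)
        scores = self._scores(rng, n_path=5)
        with pytest.raises(ValueError, match="overlap"):
            bs.moderated_t_test(scores, ["A0", "A1"], ["A1", "B0"])
        with pytest.raises(ValueError, match="at least 2"):
            bs.moderated_t_test(scores, ["A0"], ["B0", "B1"])

    def test_bh_monotone(self):
        rng = np.random.default_rng(4)
        scores = self._scores(rng, n_path=200)
        ga = [c for c in scores if c.startswith("A")]
        gb = [c for c in scores if c.startswith("B")]
        table = bs.moderated_t_test(scores, ga, gb)
        assert (table["p_adjusted"] >= table["p_value"] - 1e-15).all()
        by_p = table.sort_values("p_value")
        assert (np.diff(by_p["p_adjusted"]) >= -1e-15).all()

    def test_hyperprior_recovers_heterogeneous_variances(self):
        """Variances drawn from a scaled inverse-chi-square: the moment fit
        finds a finite d0 and a prior near the true scale."""
        rng = np.random.default_rng(5)
        d0_true, s0_true = 8.0, 0.5
        n_path, na, nb = 2000, 10, 10
        s2 = s0_true * d0_true / rng.chisquare(d0_true, n_path)
        scores = self._scores(rng, n_path=n_path, na=na, nb=nb, scales=np.sqrt(s2))
        d = na + nb - 2
        ss = scores.iloc[:, :na], scores.iloc[:, na:]
        pooled = (
            ((ss[0].sub(ss[0].mean(axis=1), axis=0)) ** 2).sum(axis=1)
            + ((ss[1].sub(ss[1].mean(axis=1), axis=0)) ** 2).sum(axis=1)
        ) / d
        d0_hat, s0_hat = estimate_variance_prior(pooled.to_numpy(), d)
        assert d0_hat == pytest.approx(d0_true, rel=0.35)
        assert s0_hat == pytest.approx(s0_true, rel=0.2)

    def test_matches_limma_ebayes(self, tmp_path):
        """Independent oracle: Bioconductor limma's lmFit + eBayes."""
        rng = np.random.default_rng(7)
        scales = np.sqrt(0.5 * 5 / rng.chisquare(5, 300))
        scores = self._scores(rng, n_path=300, na=8, nb=8, scales=scales)
        ga = [c for c in scores if c.startswith("A")]
        gb = [c for c in scores if c.startswith("B")]
        ours = bs.moderated_t_test(scores, ga, gb)
        csv = tmp_path / "scores.csv"
        scores.to_csv(csv)
        out_csv = tmp_path / "limma.csv"
        rscript = tmp_path / "check.R"
        rscript.write_text(
            f'''
x <- as.matrix(read.csv("{csv}", row.names=1))
suppressMessages(library(limma))
group <- factor(c(rep("A",8), rep("B",8)), levels=c("B","A"))
fit <- eBayes(lmFit(x, model.matrix(~group)))
write.csv(data.frame(t=fit$t[,2], p=fit$p.value[,2]), "{out_csv}")
'''
        )
        subprocess.run(["Rscript", str(rscript)], check=True, capture_output=True)
        theirs = pd.read_csv(out_csv, index_col=0)
        assert np.allclose(ours["t"], theirs["t"], atol=1e-8)
        assert np.allclose(ours["p_value"], theirs["p"], atol=1e-8)


class TestConsensusPathways:
    def _table(self, mapping):
        rows = []
        for name, (padj, direction) in mapping.items():
            rows.append({"p_adjusted": padj, "direction": direction,
                         "p_value": padj, "t": 0.0, "mean_diff": 0.0})
        return pd.DataFrame(rows, index=list(mapping))

    def test_intersection_by_hand(self):
        t1 = self._table({"A": (0.01, "up"), "B": (0.01, "up"), "C": (0.04, "up")})
        t2 = self._table({"B": (0.02, "up"), "C": (0.03, "up"), "A": (0.5, "up")})
        t3 = self._table({"B": (0.001, "up"), "A": (0.01, "down")})
        assert bs.consensus_pathways([t1, t2, t3], alpha=0.05, direction="up") == {"B"}

    def test_idempotent(self):
        t = self._table({"A": (0.01, "up"), "B": (0.2, "up")})
        assert bs.consensus_pathways([t, t, t], 0.05, "up") == {"A"}

    def test_empty_absorbing(self):
        t1 = self._table({"A": (0.01, "up")})
        t2 = self._table({"A": (0.9, "up")})
        assert bs.consensus_pathways([t1, t2], 0.05, "up") == set()
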