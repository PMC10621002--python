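"""Moderated-t stage: closed-form limits, brute-force and limma oracles."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import magcoex as m
from magcoex.de import DEFit
from magcoex.errors import UsageError, ValidationError

from conftest import meta_df, quant_df, samples_df

SAMPLES_3V3 = samples_df(
    [("t1", "treatment"), ("t2", "treatment"), ("t3", "treatment"),
     ("c1", "control"), ("c2", "control"), ("c3", "control")]
)


def random_log_cpm(rng, n_genes, samples=SAMPLES_3V3):
    mat = rng.normal(5, 2, (n_genes, len(samples)))
    return pd.DataFrame(mat, index=[f"g{i}" for i in range(n_genes)],
                        columns=samples["sample_id"])


class TestLogCpm:
    def test_zero_count_hand_value(self):
        # library 1e6: log2(0.5 / (1e6 + 1) * 1e6) ~ -1.0000014
        q = quant_df([("g0", "s1", 0, 100), ("g1", "s1", 1e6, 100)])
        out = m.log_cpm(q, prior_count=0.5)
        assert out.loc["g0", "s1"] == pytest.approx(
            np.log2(0.5 / (1e6 + 1) * 1e6), rel=1e-12
        )
        assert out.loc["g0", "s1"] == pytest.approx(-1.0000014, abs=1e-6)

    def test_equal_counts_equal_logcpm(self):
        q = quant_df([("g0", "s1", 7, 10), ("g1", "s1", 7, 999)])
        out = m.log_cpm(q)
        assert out.loc["g0", "s1"] == out.loc["g1", "s1"]

    def test_depth_invariance_when_prior_negligible(self):
        q1 = quant_df([("g0", "s1", 1e6, 1), ("g1", "s1", 9e6, 1)])
        q2 = q1.copy()
        q2["est_count"] *= 2
        d = (m.log_cpm(q1) - m.log_cpm(q2)).abs().to_numpy().max()
        assert d < 1e-6

    def test_zero_library_names_sample(self):
        q = quant_df([("g0", "sEmpty", 0, 10)])
        with pytest.raises(ValidationError, match="sEmpty"):
            m.log_cpm(q)


class TestModeratedT:
    def test_no_moderation_equals_classical_pooled_t(self):
        """d0 = 0 reproduces the textbook two-sample statistic, checked
        against scipy on 20 random genes."""
        rng = np.random.default_rng(0)
        lc = random_log_cpm(rng, 20)
        fit = m.moderated_t(lc, SAMPLES_3V3, d0=0.0)
        ref = stats.ttest_ind(
            lc[["t1", "t2", "t3"]], lc[["c1", "c2", "c3"]], axis=1,
            equal_var=True,
        )
        assert np.allclose(fit.table["t_mod"], ref.statistic, atol=1e-9)
        assert np.allclose(fit.table["p"], ref.pvalue, atol=1e-9)

    def test_infinite_prior_df_closed_form(self):
        rng = np.random.default_rng(1)
        lc = random_log_cpm(rng, 30)
        s02 = 2.0
        fit = m.moderated_t(lc, SAMPLES_3V3, d0=np.inf, s02=s02)
        b = lc[["t1", "t2", "t3"]].mean(1) - lc[["c1", "c2", "c3"]].mean(1)
        u = np.sqrt(1 / 3 + 1 / 3)
        assert np.allclose(fit.table["t_mod"], b / (u * np.sqrt(s02)),
                           atol=1e-9)
        assert np.isinf(fit.table["df_total"]).all()

    def test_shrinkage_is_identity_at_its_fixed_point(self):
        """When every gene's variance equals the prior, moderation is a
        no-op for any d0."""
        rng = np.random.default_rng(2)
        base = rng.normal(0, 1, 6)
        shifts = rng.normal(0, 3, 15)
        lc = pd.DataFrame(
            np.add.outer(shifts, base),
            index=[f"g{i}" for i in range(15)],
            columns=SAMPLES_3V3["sample_id"],
        )
        plain = m.moderated_t(lc, SAMPLES_3V3, d0=0.0)
        s2 = plain.table["s2"].iloc[0]
        assert np.allclose(plain.table["s2"], s2)
        moderated = m.moderated_t(lc, SAMPLES_3V3, d0=7.0, s02=s2)
        assert np.allclose(moderated.table["t_mod"], plain.table["t_mod"],
                           atol=1e-12)

    def test_increasing_prior_df_moves_toward_the_limit(self):
        rng = np.random.default_rng(3)
        lc = random_log_cpm(rng, 40)
        s02 = 1.7
        lim = m.moderated_t(lc, SAMPLES_3V3, d0=np.inf, s02=s02).table["t_mod"]
        gap = None
        for d0 in (1.0, 10.0, 100.0, 1000.0):
            t = m.moderated_t(lc, SAMPLES_3V3, d0=d0, s02=s02).table["t_mod"]
            new_gap = np.abs(t - lim).to_numpy()
            if gap is not None:
                assert (new_gap <= gap + 1e-12).all()
            gap = new_gap

    def test_small_group_rejected(self):
        lc = random_log_cpm(np.random.default_rng(4), 5)
        bad = samples_df([("t1", "treatment"), ("c1", "control"),
                          ("c2", "control")])
        with pytest.raises(UsageError):
            m.moderated_t(lc[["t1", "c1", "c2"]], bad)

    def test_two_vs_two_warns_about_moderation_dependence(self, caplog):
        lc = random_log_cpm(np.random.default_rng(5), 10)
        s22 = samples_df([("t1", "treatment"), ("t2", "treatment"),
                          ("c1", "control"), ("c2", "control")])
        with caplog.at_level("WARNING"):
            m.moderated_t(lc[["t1", "t2", "c1", "c2"]], s22)
        assert "moderation" in caplog.text

    def test_matches_bioconductor_limma(self, tmp_path):
        """Full agreement with limma's lmFit+eBayes on one random matrix."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript not available for the limma cross-check")
        rng = np.random.default_rng(6)
        lc = random_log_cpm(rng, 200)
        fit = m.moderated_t(lc, SAMPLES_3V3)
        lc.to_csv(tmp_path / "mat.tsv", sep="\t")
        script = tmp_path / "check.R"
        script.write_text(
            "suppressMessages(library(limma))\n"
            f"mat <- as.matrix(read.delim('{tmp_path}/mat.tsv', row.names=1))\n"
            "cond <- factor(c('t','t','t','c','c','c'), levels=c('c','t'))\n"
            "fit <- eBayes(lmFit(mat, model.matrix(~cond)))\n"
            "out <- data.frame(t=fit$t[,2], p=fit$p.value[,2],\n"
            "                  b=fit$coefficients[,2])\n"
            f"write.table(out, '{tmp_path}/ref.tsv', sep='\\t')\n"
            f"writeLines(as.character(c(fit$df.prior, fit$s2.prior)),\n"
            f"           '{tmp_path}/prior.txt')\n"
        )
        subprocess.run(["Rscript", str(script)], check=True,
                       capture_output=True)
        ref = pd.read_csv(tmp_path / "ref.tsv", sep="\t")
        d0_ref, s02_ref = map(float,
                              (tmp_path / "prior.txt").read_text().split())
        assert fit.d0 == pytest.approx(d0_ref, rel=1e-6)
        assert fit.s02 == pytest.approx(s02_ref, rel=1e-6)
        assert np.allclose(fit.table["t_mod"], ref["t"], atol=1e-8)
        assert np.allclose(fit.table["p"], ref["p"], atol=1e-8)
        assert np.allclose(fit.table["log2_fc"], ref["b"], atol=1e-8)

    def test_planted_genes_outrank_null_genes(self):
        """AUC of |t_mod| separating planted-lfc genes from background
        exceeds 0.9 in a low-dispersion simulation at n = 3 per group."""
        cfg = m.SyntheticConfig(
            seed=21, n_mags=30, genes_per_mag=(20, 30),
            n_samples_per_condition=3, nb_dispersion=0.05,
            treatment_enrichment_lfc=4.0, background_lfc_sd=0.0,
            target_block=frozenset(range(5)), anti_block=frozenset(),
            role_plantings={}, frac_rrna=0.0,
        )
        c = m.simulate(cfg)
        fit = m.moderated_t(m.log_cpm(c.quant), c.samples)
        block = {f"MAG{i:03d}" for i in range(5)}
        mags = c.gene_meta.set_index("gene_id")["mag_id"]
        is_block = mags.reindex(fit.table.index).isin(block).to_numpy()
        t_abs = fit.table["t_mod"].abs().to_numpy()
        n1, n2 = is_block.sum(), (~is_block).sum()
        ranks = stats.rankdata(t_abs)
        auc = (ranks[is_block].sum() - n1 * (n1 + 1) / 2) / (n1 * n2)
        assert auc > 0.9


class TestSelectEnriched:
    def _fit(self, rows):
        table = pd.DataFrame(rows, columns=["log2_fc", "p"],
                             index=[f"g{i}" for i in range(len(rows))])
        table["s2"] = 1.0
        table["t_mod"] = 0.0
        table["df_total"] = 10.0
        return DEFit(table=table, d0=1.0, s02=1.0)

    def _meta(self, biotypes):
        return meta_df([(f"g{i}", "A", bt, set())
                        for i, bt in enumerate(biotypes)])

    def test_negative_fold_change_is_never_enriched(self):
        fit = self._fit([(-2.0, 1e-4), (3.0, 1e-4)])
        out = m.select_enriched(fit, self._meta(["CDS", "CDS"]))
        assert out == {"g1"}

    def test_noncoding_genes_are_never_enriched(self):
        fit = self._fit([(3.0, 1e-6), (3.0, 1e-6)])
        out = m.select_enriched(fit, self._meta(["rRNA", "CDS"]))
        assert out == {"g1"}

    def test_no_discoveries_gives_empty_set(self):
        fit = self._fit([(3.0, 0.5), (2.0, 0.9)])
        assert m.select_enriched(fit, self._meta(["CDS", "CDS"])) == set()

    def test_adjusted_p_never_below_raw(self):
        fit = self._fit([(1.0, 0.01), (1.0, 0.2), (1.0, 0.04)])
        m.select_enriched(fit, self._meta(["CDS"] * 3))
        assert (fit.table["p_adj"] >= fit.table["p"] - 1e-15).all()
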