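"""Moderated t, BH q-values, plain t-tests, glycan-class summaries."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from glycopanel import quant, simulate, stats
from glycopanel.fixtures import psa_fixture
from glycopanel.stats import EBayesPrior, bh_qvalues, estimate_prior, moderated_t, two_sample_t


class TestModeratedT:
    def test_hand_computed_posterior(self):
        # s_g^2 = s0^2 = 0.25, d0 = d_g = 4 -> posterior variance 0.25;
        # t = 1 / (0.5 * sqrt(2/3)) = 2.4495 on 8 df.
        t, df, p = moderated_t(
            np.array([1.0]), np.array([0.25]), np.array([4.0]),
            np.array([3.0]), np.array([3.0]), EBayesPrior(0.25, 4.0),
        )
        assert t[0] == pytest.approx(2.4495, abs=1e-4)
        assert df[0] == 8.0

    def test_d0_zero_limit_is_ordinary_t(self, rng):
        a, b = rng.normal(0, 1, 6), rng.normal(0.5, 1, 5)
        expected_t, expected_p = sps.ttest_ind(a, b)
        sp = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / (len(a) + len(b) - 2)
        t, df, p = moderated_t(
            np.array([a.mean() - b.mean()]), np.array([sp]), np.array([9.0]),
            np.array([6.0]), np.array([5.0]), EBayesPrior(1.0, 0.0),
        )
        assert t[0] == pytest.approx(expected_t, abs=1e-12)
        assert p[0] == pytest.approx(expected_p, abs=1e-12)

    def test_d0_infinite_limit_fixes_variance(self):
        t, df, p = moderated_t(
            np.array([1.0]), np.array([123.0]), np.array([4.0]),
            np.array([5.0]), np.array([5.0]), EBayesPrior(1.0, np.inf),
        )
        assert t[0] == pytest.approx(1.0 / np.sqrt(0.4))
        # infinite df: p equals the normal tail
        assert p[0] == pytest.approx(2 * sps.norm.sf(abs(t[0])), abs=1e-12)

    def test_prior_estimator_recovers_planted_hyperparameters(self, rng):
        d0_true, s0_true, dg = 6.0, 0.5, 8.0
        sigma_sq = d0_true * s0_true / rng.chisquare(d0_true, 4000)
        s_sq = sigma_sq * rng.chisquare(dg, 4000) / dg
        prior = estimate_prior(s_sq, np.full(4000, dg))
        assert prior.d0 == pytest.approx(d0_true, rel=0.25)
        assert prior.s0_sq == pytest.approx(s0_true, rel=0.1)

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
    def test_agrees_with_bioconductor_limma(self, tmp_path, rng):
        n1, n2, n_feat = 5, 4, 60
        x = rng.normal(0, 1, (n_feat, n1 + n2)) * rng.uniform(0.3, 2.0, (n_feat, 1))
        x[:10, :n1] += 1.0
        xpath = tmp_path / "x.tsv"
        pd.DataFrame(x).to_csv(xpath, sep="\t", index=False, header=False)
        script = tmp_path / "fit.R"
        script.write_text(textwrap.dedent(f"""
            suppressMessages(library(limma))
            x <- as.matrix(read.delim("{xpath}", header=FALSE))
            design <- cbind(Intercept=1, Case=c(rep(1,{n1}), rep(0,{n2})))
            fit <- eBayes(lmFit(x, design))
            out <- data.frame(t=fit$t[,"Case"], p=fit$p.value[,"Case"])
            write.table(format(out, digits=12), "{tmp_path}/out.tsv", sep="\\t",
                        quote=FALSE, row.names=FALSE)
        """))
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        ref = pd.read_csv(tmp_path / "out.tsv", sep="\t")
        mean1, mean2 = x[:, :n1].mean(1), x[:, n1:].mean(1)
        rss = ((x[:, :n1] - mean1[:, None]) ** 2).sum(1) + ((x[:, n1:] - mean2[:, None]) ** 2).sum(1)
        dg = np.full(n_feat, n1 + n2 - 2.0)
        s_sq = rss / dg
        prior = estimate_prior(s_sq, dg)
        t, _, p = moderated_t(mean1 - mean2, s_sq, dg, np.full(n_feat, float(n1)),
                              np.full(n_feat, float(n2)), prior)
        np.testing.assert_allclose(t, ref["t"], atol=1e-9)
        np.testing.assert_allclose(p, ref["p"], atol=1e-9)

    def test_null_cohort_pvalues_uniform(self):
        config = simulate.SyntheticConfig(
            seed=7, plant_table1=False,
            n_null_features={"intact_n": 2000, "desialo_o": 0, "de_n": 0, "nonmod": 0},
        )
        tables, _ = simulate.generate_cohort(config)
        m = quant.aggregate_to_features(
            quant.fdr_filter(quant.filter_psms(tables["intact_n"])),
            "intact_n", groups=config.groups,
        ).drop_channels(["131"])
        diff = stats.fit_moderated_t(quant.normalize(m))
        assert sps.kstest(diff["p"], "uniform").pvalue > 0.01

    def test_rejects_single_sample_group(self, default_cohort):
        config, tables, _ = default_cohort
        m = quant.aggregate_to_features(tables["nonmod"].head(50), "nonmod", groups=config.groups)
        m = m.drop_channels(["127N", "127C", "128N", "128C"])  # one case channel left
        with pytest.raises(ValueError, match=">= 2 channels"):
            stats.fit_moderated_t(quant.normalize(m))


class TestBhQvalues:
    def test_hand_example(self):
        np.testing.assert_allclose(bh_qvalues([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04])

    def test_degenerate_inputs(self):
        assert bh_qvalues([]).size == 0
        np.testing.assert_allclose(bh_qvalues([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])
        np.testing.assert_allclose(bh_qvalues([0.2]), [0.2])

    def test_matches_statsmodels_and_is_permutation_invariant(self, rng):
        for _ in range(20):
            p = rng.random(int(rng.integers(1, 200)))
            q = bh_qvalues(p)
            _, q_ref, _, _ = multipletests(p, method="fdr_bh")
            np.testing.assert_allclose(q, q_ref, atol=1e-12)
            perm = rng.permutation(len(p))
            np.testing.assert_allclose(bh_qvalues(p[perm]), q[perm], atol=1e-12)
            assert (q >= p - 1e-12).all()


class TestTwoSampleT:
    def test_identical_groups(self):
        t, p = two_sample_t([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3)
        assert (t, p) == (0.0, 1.0)

    def test_hand_computed_pooled_t(self):
        t, p = two_sample_t([1, 2, 3, 4, 5, 6], ["a"] * 3 + ["b"] * 3)
        assert abs(t) == pytest.approx(3.674, abs=1e-3)

    def test_welch_option_differs_under_heteroscedasticity(self, rng):
        x = np.r_[rng.normal(0, 0.2, 5), rng.normal(1, 3.0, 10)]
        labels = ["a"] * 5 + ["b"] * 10
        _, p_pooled = two_sample_t(x, labels, welch=False)
        _, p_welch = two_sample_t(x, labels, welch=True)
        assert p_pooled != p_welch

    def test_psa_levels_do_not_separate_groups(self):
        """Serum PSA (7.17+/-3.02 vs 8.02+/-7.30 ng/ml, n=6 each) is not
        significantly different between the cancer and benign groups."""
        pca_group, bph_group = psa_fixture()
        _, p = two_sample_t(
            np.r_[pca_group, bph_group], ["PCa"] * 6 + ["BPH"] * 6, welch=True
        )
        assert p >= 0.05


class TestGlycanClassSummaries:
    def _matrix(self, glycans, values, groups):
        channels = list(groups)
        vals = pd.DataFrame(values, columns=channels,
                            index=[f"f{i}" for i in range(len(values))])
        meta = pd.DataFrame({"glycan": glycans}, index=vals.index)
        return quant.QuantMatrix(values=vals, meta=meta, groups=groups, scale="linear")

    def test_equal_intensities_split_evenly(self):
        groups = {"126": "case", "127N": "case", "129N": "control", "129C": "control"}
        m = self._matrix(["HexNAc(2)Hex(9)", "HexNAc(2)Hex(2)"], np.full((2, 4), 10.0), groups)
        shares, tests = stats.summarize_glyco_classes(m)
        assert np.allclose(shares, 0.5)

    def test_shares_sum_to_one_per_channel(self, rng):
        groups = {c: ("case" if i < 2 else "control") for i, c in enumerate(["126", "127N", "129N", "129C"])}
        glycans = ["HexNAc(2)Hex(9)", "HexNAc(4)Hex(5)Fuc(1)", "HexNAc(4)Hex(5)NeuAc(2)",
                   "HexNAc(5)Hex(6)Fuc(1)NeuAc(3)", "HexNAc(3)Hex(4)"]
        m = self._matrix(glycans, rng.uniform(1, 100, (5, 4)), groups)
        shares, _ = stats.summarize_glyco_classes(m)
        np.testing.assert_allclose(shares.sum(axis=0), 1.0)

    def test_planted_fucosylation_enrichment_detected(self):
        """A case group enriched for fucosylated glycopeptides shows a
        significant C/H+Fuc class difference (t-test p < 0.05)."""
        config = simulate.SyntheticConfig(
            seed=5, plant_table1=False, fuc_effect_o=1.8, outlier_channel=None,
            n_null_features={"intact_n": 0, "desialo_o": 300, "de_n": 0, "nonmod": 0},
        )
        tables, _ = simulate.generate_cohort(config)
        m = quant.aggregate_to_features(
            quant.fdr_filter(quant.filter_psms(tables["desialo_o"])),
            "desialo_o", groups=config.groups,
        )
        _, tests = stats.summarize_glyco_classes(m)
        assert tests.loc["C/H+Fuc", "p"] < 0.05
        assert tests.loc["C/H+Fuc", "mean_case"] > tests.loc["C/H+Fuc", "mean_control"]
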