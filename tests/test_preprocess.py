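"""Normalization, filtering, standardization, PCA and imputation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cx3sig as cx
from cx3sig import PopulationLabel
from cx3sig.preprocess import anova_pvalues

from conftest import five_group_labels, make_expression


def _cm(values, genes, samples, pops=None):
    pops = pops or [PopulationLabel.NAIVE, PopulationLabel.CX3CR1P_CD62LHI]
    labels = {s: pops[i % len(pops)] for i, s in enumerate(samples)}
    return cx.CountMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples),
        labels=labels,
    )


class TestSizeFactors:
    def test_median_of_ratios_closed_form(self):
        # geometric means (sqrt(8), sqrt(72)); per-sample ratios constant
        cm = _cm([[2, 4], [6, 12]], ["g1", "g2"], ["s1", "s2"])
        f = cx.size_factors(cm)
        assert f["s1"] == pytest.approx(1 / np.sqrt(2), rel=1e-12)
        assert f["s2"] == pytest.approx(np.sqrt(2), rel=1e-12)

    def test_identical_samples_give_unit_factors(self):
        cm = _cm([[5, 5, 5], [9, 9, 9]], ["g1", "g2"], ["s1", "s2", "s3"])
        assert np.allclose(cx.size_factors(cm), 1.0)

    def test_scale_equivariance_on_random_matrices(self):
        """Scaling one sample's counts by c scales its factor by c^(1-1/n)
        and every other factor by c^(-1/n): the factor *ratios* carry the
        full scaling, because the geometric-mean reference moves too."""
        rng = np.random.default_rng(42)
        n = 4
        for _ in range(10):
            counts = rng.integers(1, 1000, size=(20, n))
            cm = _cm(counts, [f"g{i}" for i in range(20)],
                     [f"s{j}" for j in range(n)])
            doubled = counts.copy()
            doubled[:, 1] *= 2
            cm2 = _cm(doubled, [f"g{i}" for i in range(20)],
                      [f"s{j}" for j in range(n)])
            f1, f2 = cx.size_factors(cm), cx.size_factors(cm2)
            assert f2["s1"] == pytest.approx(
                2 ** (1 - 1 / n) * f1["s1"], rel=1e-9)
            for other in ("s0", "s2", "s3"):
                assert f2[other] == pytest.approx(
                    2 ** (-1 / n) * f1[other], rel=1e-9)
            # factor ratios scale exactly with c
            assert f2["s1"] / f2["s0"] == pytest.approx(
                2 * f1["s1"] / f1["s0"], rel=1e-9)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.integers(1, 500), min_size=8, max_size=8),
           st.sampled_from([2.0, 3.0, 5.0]))
    def test_equivariance_of_factor_ratios(self, flat, c):
        counts = np.array(flat, dtype=float).reshape(4, 2)
        cm = _cm(counts, [f"g{i}" for i in range(4)], ["s1", "s2"])
        scaled = counts.copy()
        scaled[:, 1] *= c
        cm2 = _cm(scaled, [f"g{i}" for i in range(4)], ["s1", "s2"])
        f1, f2 = cx.size_factors(cm), cx.size_factors(cm2)
        assert f2["s2"] / f2["s1"] == pytest.approx(
            c * f1["s2"] / f1["s1"], rel=1e-9)

    def test_no_universally_expressed_gene_is_an_error(self):
        cm = _cm([[0, 4], [6, 0]], ["g1", "g2"], ["s1", "s2"])
        with pytest.raises(ValueError, match="pseudo-reference"):
            cx.size_factors(cm)


class TestNormalize:
    def test_floor_and_scaling(self):
        cm = _cm([[0, 10], [20, 40]], ["g1", "g2"], ["s1", "s2"])
        em = cx.normalize_counts(
            cm, pd.Series({"s1": 1.0, "s2": 2.0}))
        assert em.values.loc["g1", "s1"] == 1.0   # floored
        assert em.values.loc["g1", "s2"] == 5.0   # 10 / 2
        assert (em.values.to_numpy() >= 1.0).all()

    def test_renormalization_factors_are_ones(self, small_synth,
                                              small_normalized):
        """Median-of-ratios is idempotent: factors recomputed on the
        normalized matrix are exactly ones."""
        # restrict to genes never floored so the ratios are unperturbed
        cm, _ = small_synth
        unfloored = (small_normalized.values > 1.0).all(axis=1)
        renorm = cx.CountMatrix(
            values=cm.values.loc[unfloored], labels=cm.labels)
        f1 = cx.size_factors(renorm)
        em = cx.normalize_counts(renorm, f1)
        f2 = cx.preprocess.size_factors_from_values(em.values)
        assert np.allclose(f2, 1.0, atol=1e-9)


class TestPresentFilters:
    def test_rna_kept_when_one_group_exceeds_threshold(self):
        em = make_expression({"hi": [12, 5, 1, 1, 1], "lo": [1, 1, 1, 1, 1]})
        out = cx.filter_present_rna(em, min_mean=10)
        assert list(out.values.index) == ["hi"]

    def test_rna_threshold_is_strict(self):
        em = make_expression({"edge": [10, 10, 10, 10, 10]})
        assert len(cx.filter_present_rna(em, min_mean=10).values) == 0

    def test_microarray_background_rule(self):
        em = make_expression(
            {"kept": [7.0, 6.0, 6.0, 6.0, 6.0],
             "dropped": [6.5, 6.5, 6.5, 6.5, 6.5],
             "at_background": [6.7886, 6.0, 6.0, 6.0, 6.0]},
            scale="log2",
        )
        out = cx.filter_present_microarray(em, background=6.7886)
        assert set(out.values.index) == {"kept", "at_background"}


class TestVariableFilter:
    def test_equal_group_means_dropped(self):
        labels = five_group_labels(3)
        rng = np.random.default_rng(0)
        base = np.tile([1.0, 2.0, 3.0], 5)  # same triple in every group
        df = pd.DataFrame([base], index=["flat"], columns=list(labels))
        em = cx.ExpressionMatrix(df, labels)
        p = anova_pvalues(em)
        assert p["flat"] == pytest.approx(1.0)
        assert len(cx.filter_variable(em).values) == 0

    def test_constant_gene_dropped_without_error(self):
        labels = five_group_labels(2)
        df = pd.DataFrame([[5.0] * 10], index=["const"],
                          columns=list(labels))
        em = cx.ExpressionMatrix(df, labels)
        out = cx.filter_variable(em)
        assert len(out.values) == 0

    def test_planted_signature_genes_survive(self, small_synth,
                                             small_present):
        _, truth = small_synth
        out = cx.filter_variable(small_present, alpha=0.05)
        planted = [g for g in truth.signature_genes
                   if g in small_present.values.index]
        frac = np.mean([g in set(out.values.index) for g in planted])
        assert frac >= 0.95


class TestZTransformAndPCA:
    def test_z_transform_row(self):
        labels = {"s1": PopulationLabel.NAIVE,
                  "s2": PopulationLabel.CX3CR1P_CD62LHI,
                  "s3": PopulationLabel.CX3CR1P_CD62LLO}
        df = pd.DataFrame([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]],
                          index=["g1", "const"], columns=list(labels))
        z = cx.z_transform(cx.ExpressionMatrix(df, labels))
        assert list(z.index) == ["g1"]  # constant gene dropped
        assert np.allclose(z.loc["g1"], [-1.0, 0.0, 1.0])
        assert abs(z.loc["g1"].mean()) < 1e-12

    def test_pca_identities(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=8)
        df = pd.DataFrame(
            {"gA": base, "gB": 2 * base + 1, "gC": rng.normal(size=8)}
        ).T
        df.columns = [f"s{i}" for i in range(8)]
        scores, loadings, ev = cx.pca(df)
        # orthonormal loadings
        assert np.allclose(loadings.T @ loadings, np.eye(3), atol=1e-9)
        # full reconstruction
        x = df.to_numpy().T
        recon = scores.to_numpy() @ loadings.to_numpy().T + x.mean(axis=0)
        assert np.allclose(recon, x, atol=1e-9)
        # explained variance sums to total
        total = x.var(axis=0, ddof=1).sum()
        assert ev.sum() == pytest.approx(total, rel=1e-9)

    def test_perfectly_correlated_genes_load_on_single_component(self):
        base = np.arange(6, dtype=float)
        df = pd.DataFrame([base, 3 * base], index=["g1", "g2"],
                          columns=[f"s{i}" for i in range(6)])
        _, _, ev = cx.pca(df)
        assert ev.iloc[0] / ev.sum() == pytest.approx(1.0, abs=1e-12)


class TestProteinFilter:
    def _pt(self, rows, flags=None):
        labels = five_group_labels(3)  # 15 samples, 3 per group
        samples = list(labels)
        accs = list(rows)
        inten = pd.DataFrame(
            [rows[a] for a in accs], index=accs, columns=samples,
            dtype=float,
        )
        fl = pd.DataFrame(
            {"contaminant": [False] * len(accs),
             "reverse": [False] * len(accs),
             "site_only": [False] * len(accs)},
            index=accs,
        )
        if flags:
            for a, k in flags.items():
                fl.loc[a, k] = True
        return cx.ProteinTable(intensities=inten,
                               gene_names=pd.Series("", index=accs),
                               flags=fl, labels=labels)

    def test_valid_in_one_group_suffices(self):
        full_row = [np.nan] * 15
        row = list(full_row)
        row[0:3] = [10.0, 12.0, 9.0]  # 3 valid values in the first group
        pt = self._pt({"P1": row})
        out = cx.filter_proteins(pt, min_valid=3)
        assert list(out.values.index) == ["P1"]
        assert out.scale == "log2"
        assert out.values.loc["P1"].dropna().iloc[0] == pytest.approx(
            np.log2(10.0))

    def test_contaminant_dropped_despite_full_data(self):
        pt = self._pt({"P1": [10.0] * 15}, flags={"P1": "contaminant"})
        assert len(cx.filter_proteins(pt).values) == 0

    def test_two_valid_per_group_insufficient(self):
        row = [np.nan] * 15
        for g in range(5):
            row[3 * g] = 10.0
            row[3 * g + 1] = 11.0  # 2 valid in every group
        pt = self._pt({"P1": row})
        assert len(cx.filter_proteins(pt, min_valid=3).values) == 0


class TestImputation:
    def _em_with_missing(self, n_obs=5000, n_missing=10000, seed=5):
        rng = np.random.default_rng(seed)
        obs = rng.normal(25.0, 2.0, size=n_obs)
        col = np.concatenate([obs, np.full(n_missing, np.nan)])
        labels = {"s1": PopulationLabel.NAIVE}
        df = pd.DataFrame({"s1": col},
                          index=[f"p{i}" for i in range(len(col))])
        return cx.ExpressionMatrix(df, labels, scale="log2")

    def test_downshifted_normal_moments(self):
        """Imputed values follow Normal(mu - 1.8 s, (0.3 s)^2) of the
        observed column statistics, within 3 standard errors at n=10,000."""
        em = self._em_with_missing()
        obs = em.values["s1"].dropna()
        mu, sd = obs.mean(), obs.std(ddof=1)
        out = cx.impute_missing(em, shift=1.8, width=0.3, seed=11)
        imputed = out.values["s1"][em.values["s1"].isna()]
        n = len(imputed)
        target_mean, target_sd = mu - 1.8 * sd, 0.3 * sd
        assert abs(imputed.mean() - target_mean) < 3 * target_sd / np.sqrt(n)
        assert abs(imputed.std(ddof=1) - target_sd) < \
            3 * target_sd / np.sqrt(2 * n)

    def test_no_missing_is_identity(self):
        labels = five_group_labels(2)
        df = pd.DataFrame(
            np.arange(20.0).reshape(2, 10) + 10, index=["p1", "p2"],
            columns=list(labels))
        em = cx.ExpressionMatrix(df, labels, scale="log2")
        out = cx.impute_missing(em, seed=0)
        pd.testing.assert_frame_equal(out.values, em.values)

    def test_same_seed_reproduces(self):
        em = self._em_with_missing(n_obs=50, n_missing=20)
        a = cx.impute_missing(em, seed=7)
        b = cx.impute_missing(em, seed=7)
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_all_missing_column_is_an_error(self):
        labels = {"s1": PopulationLabel.NAIVE}
        df = pd.DataFrame({"s1": [np.nan, np.nan]}, index=["p1", "p2"])
        em = cx.ExpressionMatrix(df, labels, scale="log2")
        with pytest.raises(ValueError, match="s1"):
            cx.impute_missing(em, seed=0)


class TestQuantileNormalize:
    def test_columns_share_distribution(self):
        labels = five_group_labels(1)
        rng = np.random.default_rng(8)
        df = pd.DataFrame(rng.normal(size=(40, 5)) * [1, 2, 3, 4, 5],
                          index=[f"g{i}" for i in range(40)],
                          columns=list(labels))
        out = cx.quantile_normalize(
            cx.ExpressionMatrix(df, labels, scale="log2"))
        ref = np.sort(out.values.iloc[:, 0].to_numpy())
        for j in range(1, 5):
            assert np.allclose(np.sort(out.values.iloc[:, j]), ref)
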