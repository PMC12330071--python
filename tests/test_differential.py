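import numpy as np
import pandas as pd
import pytest
from scipy import stats

import scplm
from scplm.differential import test_contrasts as contrast_tests
from scplm.differential import (
    PROTEIN_METHODS,
    adjust_pvalues,
    build_contrast,
    combine_to_protein,
    vcov_ridge,
)
from scplm.modeling import ModelSpec, Variable, build_design, fit_model, \
    fit_peptide


def _binary_dataset(y_a, y_b):
    y = np.concatenate([y_a, y_b])
    values = pd.DataFrame([y], index=["p0"],
                          columns=[f"c{i}" for i in range(len(y))])
    return scplm.ScpDataset(
        intensities=values,
        feature_annotations=pd.DataFrame(index=values.index),
        cell_annotations=pd.DataFrame(
            {"group": ["A"] * len(y_a) + ["B"] * len(y_b)},
            index=values.columns,
        ),
        level="peptide", log_transformed=True,
    )


class TestBuildContrast:
    def test_two_level_contrast_is_plus_minus_two(self):
        cells = pd.DataFrame({"g": ["A", "B", "A", "B"]},
                             index=[f"c{i}" for i in range(4)])
        d = build_design(cells, ModelSpec(variables=(Variable("g"),)))
        L = build_contrast(d, "g", "A", "B")
        # sum coding: encoding(A) = +1, encoding(B) = -1 -> difference 2
        assert L.matrix[0].tolist() == [0.0, 2.0]

    def test_self_contrast_is_zero(self):
        cells = pd.DataFrame({"g": ["A", "B"] * 2},
                             index=[f"c{i}" for i in range(4)])
        d = build_design(cells, ModelSpec(variables=(Variable("g"),)))
        L = build_contrast(d, "g", "A", "A")
        assert np.all(L.matrix == 0)

    def test_three_level_contrast_encoding_arithmetic(self):
        cells = pd.DataFrame({"g": ["A", "B", "C"] * 2},
                             index=[f"c{i}" for i in range(6)])
        d = build_design(cells, ModelSpec(variables=(Variable("g"),)))
        L = build_contrast(d, "g", "A", "C")
        # encoding(A) - encoding(C) = (1, 0) - (-1, -1) = (2, 1)
        assert L.matrix[0].tolist() == [0.0, 2.0, 1.0]

    def test_unknown_level_errors(self):
        cells = pd.DataFrame({"g": ["A", "B"] * 2},
                             index=[f"c{i}" for i in range(4)])
        d = build_design(cells, ModelSpec(variables=(Variable("g"),)))
        with pytest.raises(KeyError):
            build_contrast(d, "g", "A", "Z")


class TestVcovRidge:
    def test_lambda_zero_reduces_to_classic(self):
        rng = np.random.default_rng(3)
        x = np.column_stack([np.ones(20), rng.normal(size=(20, 2))])
        y = rng.normal(size=20)
        fit = fit_peptide(y, x, ridge_lambda=0.0)
        v = vcov_ridge(fit, x, 0.0)
        classic = fit.sigma2 * np.linalg.inv(x.T @ x)
        assert np.allclose(v, classic, atol=1e-10)

    def test_intercept_only_scalar_formula(self):
        # variance = sigma2 * n / (n + lambda)^2
        y = np.array([1.0, 2.0, 4.0])
        x = np.ones((3, 1))
        lam = 0.5
        fit = fit_peptide(y, x, ridge_lambda=lam)
        v = vcov_ridge(fit, x, lam)
        assert v[0, 0] == pytest.approx(fit.sigma2 * 3 / (3 + lam) ** 2)

    def test_symmetric(self):
        rng = np.random.default_rng(4)
        x = np.column_stack([np.ones(15), rng.normal(size=(15, 3))])
        fit = fit_peptide(rng.normal(size=15), x)
        v = vcov_ridge(fit, x, 1e-3)
        assert np.allclose(v, v.T, atol=1e-12)


class TestTestContrasts:
    def test_matches_pooled_two_sample_t(self):
        rng = np.random.default_rng(5)
        y_a, y_b = rng.normal(0, 1, 6), rng.normal(1, 1, 6)
        ds = _binary_dataset(y_a, y_b)
        res = fit_model(ds, ModelSpec(variables=(Variable("group"),),
                                      ridge_lambda=0.0))
        L = build_contrast(res.design, "group", "A", "B")
        inf = contrast_tests(res, L).iloc[0]
        t_ref, p_ref = stats.ttest_ind(y_a, y_b, equal_var=True)
        assert inf.estimate == pytest.approx(y_a.mean() - y_b.mean())
        assert inf.t == pytest.approx(t_ref)
        assert inf.p == pytest.approx(p_ref)
        assert inf.df == 10

    def test_peptide_in_single_group_non_estimable(self):
        ds = _binary_dataset([7.0, 7.5, 7.2], [np.nan, np.nan, np.nan])
        res = fit_model(ds, ModelSpec(variables=(Variable("group"),)))
        L = build_contrast(res.design, "group", "A", "B")
        inf = contrast_tests(res, L).iloc[0]
        assert not inf.estimable and np.isnan(inf.p)

    def test_sign_coherence(self, fitted):
        _, _, result = fitted
        fwd = contrast_tests(
            result, build_contrast(result.design, "celltype", "type0", "type1")
        )
        rev = contrast_tests(
            result, build_contrast(result.design, "celltype", "type1", "type0")
        )
        ok = fwd.estimable.to_numpy()
        assert np.allclose(fwd.estimate[ok], -rev.estimate[ok])
        assert np.allclose(fwd.p[ok], rev.p[ok])

    def test_baseline_is_intercept_estimate(self, fitted):
        _, _, result = fitted
        inf = contrast_tests(
            result, build_contrast(result.design, "celltype", "type0", "type1")
        )
        fid = inf.feature.iloc[0]
        fit = result.fits[fid]
        assert inf.baseline.iloc[0] == pytest.approx(fit.coefficients[0])


class TestAdjustPvalues:
    @staticmethod
    def _frame(p, baseline=None):
        n = len(p)
        return pd.DataFrame(
            {
                "feature": [f"p{i}" for i in range(n)],
                "contrast": "c",
                "estimate": 1.0,
                "se": 1.0,
                "t": 1.0,
                "df": 10,
                "p": p,
                "baseline": baseline if baseline is not None else np.ones(n),
                "estimable": [not np.isnan(x) for x in p],
            }
        )

    def test_single_test_unchanged_under_bh(self):
        out = adjust_pvalues(self._frame([0.03]))
        assert out.adjusted_p.iloc[0] == pytest.approx(0.03)

    def test_bh_step_up_hand_example(self):
        out = adjust_pvalues(self._frame([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(out.adjusted_p, 0.04)

    def test_bh_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(6)
        p = rng.uniform(size=100)
        out = adjust_pvalues(self._frame(p))
        ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(out.adjusted_p, ref)

    def test_ihw_falls_back_to_bh_when_few_tests(self):
        p = [0.01, 0.2, 0.5, 0.9]
        bh = adjust_pvalues(self._frame(p), method="bh")
        ihw = adjust_pvalues(self._frame(p), method="ihw-binned")
        assert np.allclose(bh.adjusted_p, ihw.adjusted_p)

    def test_ihw_valid_adjusted_pvalues_on_nulls(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(size=400)
        out = adjust_pvalues(self._frame(p, baseline=rng.normal(7, 1, 400)),
                             method="ihw-binned", seed=1)
        assert out.adjusted_p.between(0, 1).all()
        # null data: essentially nothing should be called at 5% FDR
        assert (out.adjusted_p < 0.05).mean() < 0.02

    def test_all_missing_p_gives_empty_adjustment(self):
        out = adjust_pvalues(self._frame([np.nan, np.nan]))
        assert out.adjusted_p.isna().all()


class TestProteinCombination:
    def test_fisher_hand_value(self):
        p_comb, _ = PROTEIN_METHODS["fisher"](np.array([0.5, 0.5]))
        # statistic -2(ln 0.5 + ln 0.5) = 2.7726 on 4 df
        assert p_comb == pytest.approx(stats.chi2.sf(2.772588722, 4))
        assert p_comb == pytest.approx(0.5966, abs=2e-4)

    def test_simes_hand_value(self):
        p_comb, rep = PROTEIN_METHODS["simes"](np.array([0.01, 0.04]))
        assert p_comb == pytest.approx(0.02)  # min(2*0.01, 0.04)
        assert rep == 0

    def test_berger_is_max_p(self):
        p_comb, rep = PROTEIN_METHODS["berger"](np.array([0.01, 0.04]))
        assert p_comb == pytest.approx(0.04) and rep == 1

    @pytest.mark.parametrize("method", sorted(PROTEIN_METHODS))
    def test_single_peptide_protein_equals_peptide_p(self, method):
        for p in (0.001, 0.2, 0.8):
            p_comb, rep = PROTEIN_METHODS[method](np.array([p]))
            assert p_comb == pytest.approx(p, rel=1e-9)
            assert rep == 0

    def test_combine_to_protein_representative_and_logfc(self):
        inf = pd.DataFrame(
            {
                "feature": ["a", "b", "c"],
                "contrast": "g:A-B",
                "estimate": [2.0, -1.0, 0.5],
                "se": 1.0,
                "t": 1.0,
                "df": 10,
                "p": [0.001, 0.5, 0.03],
                "baseline": 7.0,
                "estimable": True,
            }
        )
        mapping = pd.Series({"a": "Q1", "b": "Q1", "c": "Q2"})
        out = combine_to_protein(inf, mapping, method="simes")
        q1 = out[out.protein == "Q1"].iloc[0]
        assert q1.representative == "a" and q1.logfc == 2.0
        assert q1.n_peptides == 2

    def test_protein_with_no_estimable_peptides_skipped(self):
        inf = pd.DataFrame(
            {
                "feature": ["a"],
                "contrast": "g:A-B",
                "estimate": [np.nan],
                "se": np.nan,
                "t": np.nan,
                "df": 5,
                "p": [np.nan],
                "baseline": 7.0,
                "estimable": False,
            }
        )
        out = combine_to_protein(inf, pd.Series({"a": "Q1"}))
        assert out.empty

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            combine_to_protein(pd.DataFrame(), pd.Series(dtype=object),
                               method="magic")
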