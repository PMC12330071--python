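import numpy as np
import pandas as pd
import pytest

import scplm
from scplm.modeling import (
    ModelSpec,
    Variable,
    batch_corrected,
    build_design,
    effect_matrix,
    fit_model,
    fit_peptide,
    subset_model,
)
from scplm.pipeline import parse_variables


@pytest.fixture()
def three_level_design():
    cells = pd.DataFrame(
        {"group": ["a", "a", "b", "b", "c", "c"],
         "x": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]},
        index=[f"c{i}" for i in range(6)],
    )
    spec = ModelSpec(variables=(
        Variable("group", kind="categorical"),
        Variable("x", kind="numeric"),
    ))
    return build_design(cells, spec)


class TestBuildDesign:
    def test_three_level_categorical_gives_two_columns(self, three_level_design):
        assert three_level_design.variable_columns["group"].tolist() == [1, 2]
        assert three_level_design.matrix.shape == (6, 4)

    def test_last_level_encoded_minus_one(self, three_level_design):
        # sum-to-zero: the last level is minus the sum of the others
        assert three_level_design.matrix[4, 1:3].tolist() == [-1.0, -1.0]

    def test_numeric_centered(self):
        cells = pd.DataFrame({"x": [1.0, 2.0, 3.0]}, index=list("abc"))
        spec = ModelSpec(variables=(Variable("x", kind="numeric"),))
        d = build_design(cells, spec)
        assert d.matrix[:, 1].tolist() == [-1.0, 0.0, 1.0]

    def test_intercept_is_column_zero(self, three_level_design):
        assert np.all(three_level_design.matrix[:, 0] == 1.0)
        assert three_level_design.parameter_names[0] == "intercept"

    def test_single_level_categorical_rejected(self):
        cells = pd.DataFrame({"g": ["a", "a"]}, index=["c1", "c2"])
        with pytest.raises(ValueError, match="single level"):
            build_design(cells, ModelSpec(variables=(Variable("g"),)))


class TestSubsetModel:
    def test_all_cells_keeps_all_parameters(self, three_level_design):
        s = subset_model(three_level_design, np.arange(6))
        assert s.tolist() == [0, 1, 2, 3]

    def test_single_observation_keeps_intercept_only(self, three_level_design):
        s = subset_model(three_level_design, np.array([2]))
        assert s.tolist() == [0]

    def test_single_group_drops_its_contrast_columns(self):
        cells = pd.DataFrame({"run": ["r1"] * 3 + ["r2"] * 3},
                             index=[f"c{i}" for i in range(6)])
        d = build_design(cells, ModelSpec(variables=(Variable("run"),)))
        s = subset_model(d, np.array([0, 1, 2]))  # observed in run r1 only
        assert s.tolist() == [0]

    def test_missing_level_drops_aliased_column(self):
        # with one of three levels absent no column is constant, but the
        # subsetted design is rank-deficient; one column must go
        cells = pd.DataFrame({"run": ["r1", "r1", "r2", "r2", "r3", "r3"]},
                             index=[f"c{i}" for i in range(6)])
        d = build_design(cells, ModelSpec(variables=(Variable("run"),)))
        s = subset_model(d, np.array([2, 3, 4, 5]))  # r1 never observed
        sub = d.matrix[np.ix_([2, 3, 4, 5], s)]
        assert np.linalg.matrix_rank(sub) == len(s) == 2


class TestFitPeptide:
    def test_intercept_only_scalar_closed_form(self):
        # beta = sum(y) / (n + lambda) = 2 / 3
        fit = fit_peptide(np.array([1.0, 1.0]), np.ones((2, 1)), ridge_lambda=1.0)
        assert fit.coefficients[0] == pytest.approx(2.0 / 3.0)

    def test_zero_data_zero_fit(self):
        fit = fit_peptide(np.zeros(4), np.column_stack([np.ones(4),
                                                        np.arange(4.0)]),
                          ridge_lambda=1e-3)
        assert np.allclose(fit.coefficients, 0) and fit.sse == 0

    def test_lambda_zero_matches_ols(self):
        rng = np.random.default_rng(7)
        x = np.column_stack([np.ones(5), rng.normal(size=(5, 2))])
        y = rng.normal(size=5)
        fit = fit_peptide(y, x, ridge_lambda=0.0)
        beta_ols = np.linalg.pinv(x) @ y
        assert np.allclose(fit.coefficients, beta_ols, atol=1e-10)

    def test_reconstruction_identity(self):
        rng = np.random.default_rng(8)
        x = np.column_stack([np.ones(10), rng.normal(size=(10, 3))])
        y = rng.normal(size=10)
        fit = fit_peptide(y, x)
        assert np.allclose(x @ fit.coefficients + fit.residuals, y, rtol=1e-9)

    def test_coefficient_norm_decreases_with_lambda(self):
        rng = np.random.default_rng(9)
        x = np.column_stack([np.ones(12), rng.normal(size=(12, 3))])
        y = rng.normal(size=12)
        norms = [
            np.linalg.norm(fit_peptide(y, x, ridge_lambda=lam).coefficients)
            for lam in (0.0, 0.1, 1.0, 10.0)
        ]
        assert norms == sorted(norms, reverse=True)


class TestFitModel:
    def test_np_ratio_definition(self, fitted):
        _, _, result = fitted
        for fit in result.fits.values():
            assert fit.n_over_p == pytest.approx(
                len(fit.observed) / len(fit.retained)
            )

    def test_low_np_always_skipped(self):
        # 4 cells, 2-level group: p = 2, so a peptide observed twice has
        # n/p = 1 and cannot be modeled
        intensities = pd.DataFrame(
            [[7.0, np.nan, 6.5, np.nan], [7.0, 7.5, 6.5, 7.2]],
            index=["p1", "p2"], columns=[f"c{i}" for i in range(4)],
        )
        ds = scplm.ScpDataset(
            intensities=intensities,
            feature_annotations=pd.DataFrame(index=intensities.index),
            cell_annotations=pd.DataFrame(
                {"group": ["A", "A", "B", "B"]}, index=intensities.columns
            ),
            level="peptide", log_transformed=True,
        )
        result = fit_model(ds, ModelSpec(variables=(Variable("group"),)))
        assert "p1" in result.skipped and "p2" in result.fits

    def test_threshold_skips_between_one_and_threshold(self, default_sim):
        ds, _ = default_sim
        spec = ModelSpec(variables=parse_variables("run + label + celltype"))
        strict = fit_model(ds, spec, np_threshold=3.0)
        loose = fit_model(ds, spec, np_threshold=1.0)
        assert set(strict.fits) <= set(loose.fits)
        for fid, fit in loose.fits.items():
            if fid not in strict.fits:
                assert fit.n_over_p < 3.0

    def test_permutation_equivariance(self, default_sim):
        ds, _ = default_sim
        spec = ModelSpec(variables=parse_variables("run + label + celltype"))
        res = fit_model(ds, spec)
        rng = np.random.default_rng(0)
        perm = rng.permutation(ds.n_cells)
        ds_perm = scplm.ScpDataset(
            intensities=ds.intensities.iloc[:, perm],
            feature_annotations=ds.feature_annotations,
            cell_annotations=ds.cell_annotations.iloc[perm],
            level="peptide", log_transformed=True,
        )
        res_perm = fit_model(ds_perm, spec)
        for fid in list(res.fits)[:20]:
            assert np.allclose(res.fits[fid].coefficients,
                               res_perm.fits[fid].coefficients, atol=1e-9)

    def test_determinism(self, default_sim):
        ds, _ = default_sim
        spec = ModelSpec(variables=parse_variables("run + label + celltype"))
        a = fit_model(ds, spec)
        b = fit_model(ds, spec)
        for fid in a.fits:
            assert np.array_equal(a.fits[fid].coefficients,
                                  b.fits[fid].coefficients)


class TestEffectMatrices:
    def test_effects_plus_residuals_reconstruct_data(self, fitted):
        ds, _, result = fitted
        recon = effect_matrix(result, "intercept") + effect_matrix(
            result, "residuals"
        )
        for f in result.variables:
            recon = recon + effect_matrix(result, f)
        y = ds.intensities.loc[recon.index]
        np.testing.assert_allclose(recon.to_numpy(), y.to_numpy(), rtol=1e-9,
                                   atol=1e-9)

    def test_dropped_variable_row_is_zero(self):
        # peptide observed in one run only: run effect contributes nothing
        intensities = pd.DataFrame(
            [[7.0, 7.5, 6.9, np.nan, np.nan, np.nan]],
            index=["p1"], columns=[f"c{i}" for i in range(6)],
        )
        ds = scplm.ScpDataset(
            intensities=intensities,
            feature_annotations=pd.DataFrame(index=intensities.index),
            cell_annotations=pd.DataFrame(
                {"run": ["r1"] * 3 + ["r2"] * 3}, index=intensities.columns
            ),
            level="peptide", log_transformed=True,
        )
        result = fit_model(ds, ModelSpec(variables=(Variable("run"),)))
        eff = effect_matrix(result, "run")
        assert np.all(eff.loc["p1"].dropna() == 0)

    def test_balanced_binary_effect_is_group_mean_deviation(self, tiny_dataset):
        spec = ModelSpec(variables=(Variable("group"),), ridge_lambda=0.0)
        result = fit_model(tiny_dataset, spec)
        eff = effect_matrix(result, "group")
        y = tiny_dataset.intensities
        for pep in y.index:
            grand = y.loc[pep].mean()
            for grp, cells in (("A", ["c1", "c2"]), ("B", ["c3", "c4"])):
                dev = y.loc[pep, cells].mean() - grand
                assert eff.loc[pep, cells].to_numpy() == pytest.approx(
                    [dev, dev]
                )

    def test_unknown_variable_errors(self, fitted):
        _, _, result = fitted
        with pytest.raises(KeyError):
            effect_matrix(result, "nope")


class TestBatchCorrected:
    def test_keep_all_reproduces_data(self, fitted):
        ds, _, result = fitted
        full = batch_corrected(result, keep=result.variables)
        y = ds.intensities.loc[full.index]
        np.testing.assert_allclose(full.to_numpy(), y.to_numpy(), rtol=1e-9,
                                   atol=1e-9)

    def test_keep_none_is_intercept_plus_residuals(self, fitted):
        _, _, result = fitted
        none = batch_corrected(result, keep=[])
        expected = effect_matrix(result, "intercept") + effect_matrix(
            result, "residuals"
        )
        pd.testing.assert_frame_equal(none, expected)

    def test_missing_pattern_preserved(self, fitted):
        ds, _, result = fitted
        corr = batch_corrected(result, keep=["celltype"])
        assert corr.notna().equals(ds.intensities.loc[corr.index].notna())

    def test_correction_removes_run_variance_on_refit(self, fitted):
        ds, _, result = fitted
        corr = batch_corrected(result, keep=["celltype"])
        ds2 = scplm.ScpDataset(
            intensities=corr,
            feature_annotations=result.feature_annotations,
            cell_annotations=ds.cell_annotations,
            level="peptide", log_transformed=True,
        )
        res2 = fit_model(ds2, result.spec)
        gv = scplm.global_variance(scplm.variance_analysis(res2))
        assert gv["run"] < 1.0
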