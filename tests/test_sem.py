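"""SEM engine: topology validation, perfect-fit identities, OLS/F_ML
oracle agreement, conditional prediction semantics and batch fitting."""

import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import LinearRegression

from soilniche.io import AbundanceTable, EnvTable, ENV_COLUMNS
from soilniche.sem import (
    SemSpec,
    StructuralEquationModel,
    build_spec,
    default_spec,
    fit_indices,
    fit_many,
    holdout_validate,
    implied_covariance,
)
from soilniche.synthetic import GeneratorConfig, default_config, generate_dataset


@pytest.fixture(scope="module")
def fitted_world():
    config, spec = default_config(n_samples=2000, seed=3)
    ds = generate_dataset(config, spec)
    model = StructuralEquationModel(spec=spec).fit(ds.data)
    return config, spec, ds, model


class TestSpec:
    def test_default_topology_oc_parents(self):
        spec = default_spec()
        assert spec.parents("OC") == sorted(
            ["conductivity", "pH", "humidity", "precipitation", "C3_macrothermal"]
        )

    def test_default_topology_taxon_has_all_nine_drivers(self):
        spec = default_spec()
        assert set(spec.parents("taxon")) == set(ENV_COLUMNS)

    def test_cycle_detected(self):
        with pytest.raises(ValueError, match="cyclic"):
            SemSpec(["a", "b"], [("a", "b"), ("b", "a")], exogenous=[])

    def test_edge_out_of_terminal_taxon_rejected(self):
        spec_dict = default_spec().to_dict()
        spec_dict["edges"].append(["taxon", "pH"])
        with pytest.raises(ValueError, match="cyclic|terminal"):
            build_spec(spec_dict)
        # a terminal-violating edge that creates no cycle is also rejected
        spec_dict2 = default_spec().to_dict()
        spec_dict2["variables"].append("extra")
        spec_dict2["edges"] = [list(e) for e in default_spec().edges] + [
            ["taxon", "extra"]
        ]
        with pytest.raises(ValueError, match="terminal"):
            build_spec(spec_dict2)

    def test_two_variable_free_parameter_count(self):
        spec = SemSpec(["x", "y"], [("x", "y")], exogenous=["x"])
        # 1 coefficient + 1 residual variance + 1 exogenous variance
        assert spec.n_free_params == 3
        assert spec.df == 0

    def test_yaml_round_trip(self, tmp_path):
        spec = default_spec()
        spec.to_yaml(tmp_path / "spec.yaml")
        back = SemSpec.from_yaml(tmp_path / "spec.yaml")
        assert back.to_dict() == spec.to_dict()


class TestFit:
    def test_perfect_fit_identity(self, fitted_world):
        _, spec, _, model = fitted_world
        sigma = model.implied_cov_.to_numpy()
        fi = fit_indices(sigma, sigma, model.n_, spec.df, len(spec.variables))
        assert fi["chi2"] == pytest.approx(0.0, abs=1e-8)
        assert fi["CFI"] == 1.0
        assert fi["RMSEA"] == 0.0
        assert fi["SRMR"] == pytest.approx(0.0, abs=1e-12)

    def test_standardization_identity(self, fitted_world):
        _, spec, _, model = fitted_world
        for child in spec.endogenous:
            for parent in spec.parents(child):
                rebuilt = (
                    model.std_coefs_[child][parent]
                    * model.sds_[child]
                    / model.sds_[parent]
                )
                assert rebuilt == pytest.approx(model.coefs_[child][parent], abs=1e-10)

    def test_implied_covariance_at_truth_matches_population_algebra(self):
        config, spec = default_config(n_samples=10, seed=0)
        resid = {k: v**2 for k, v in config.residual_sds.items()}
        sigma = implied_covariance(
            spec, config.structural_coeffs, config.exogenous_cov, resid
        )
        # taxon variance = w' Sigma_parents w + psi
        w = pd.Series(
            {k: v for k, v in config.structural_coeffs["taxon_1"].items()
             if k != "intercept"}
        )
        parents = list(w.index)
        expected = float(
            w.to_numpy() @ sigma.loc[parents, parents].to_numpy() @ w.to_numpy()
            + resid["taxon_1"]
        )
        assert sigma.loc["taxon_1", "taxon_1"] == pytest.approx(expected)

    def test_zero_variance_variable_rejected(self, fitted_world):
        _, spec, ds, _ = fitted_world
        data = ds.data.copy()
        data["taxon_1"] = 1.0
        with pytest.raises(ValueError, match="zero-variance"):
            StructuralEquationModel(spec=spec).fit(data)

    def test_missing_rows_are_dropped_and_counted(self, fitted_world):
        _, spec, ds, _ = fitted_world
        data = ds.data.copy()
        data.iloc[0, 0] = np.nan
        model = StructuralEquationModel(spec=spec).fit(data)
        assert model.n_dropped_ == 1
        assert model.n_ == len(data) - 1


class TestPredict:
    def test_noise_free_predictions_equal_observations(self):
        config, spec = default_config(n_samples=200, seed=8)
        # drivers keep their residuals (a fully noise-free driver system
        # is collinear by construction); only the taxon response is exact
        resid = dict(config.residual_sds)
        resid["taxon_1"] = 0.0
        quiet = GeneratorConfig(
            n_samples=200,
            exogenous_means=config.exogenous_means,
            exogenous_cov=config.exogenous_cov,
            structural_coeffs=config.structural_coeffs,
            residual_sds=resid,
            seed=8,
        )
        ds = generate_dataset(quiet, spec)
        model = StructuralEquationModel(spec=spec).fit(ds.data)
        pred = model.predict(ds.data)
        assert np.allclose(pred, ds.data["taxon_1"], atol=1e-8)

    def test_prediction_ignores_the_taxon_column(self, fitted_world):
        _, spec, ds, model = fitted_world
        shuffled = ds.data.copy()
        shuffled["taxon_1"] = np.random.default_rng(0).permutation(
            shuffled["taxon_1"].to_numpy()
        )
        pd.testing.assert_series_equal(model.predict(ds.data), model.predict(shuffled))

    def test_conditional_prediction_matches_ols_oracle(self, fitted_world):
        _, spec, ds, model = fitted_world
        parents = spec.parents("taxon_1")
        ols = LinearRegression().fit(ds.data[parents], ds.data["taxon_1"])
        assert np.allclose(
            model.predict(ds.data).to_numpy(),
            ols.predict(ds.data[parents]),
            atol=1e-8,
        )

    def test_missing_parent_column_reported(self, fitted_world):
        _, _, ds, model = fitted_world
        with pytest.raises(ValueError, match="pH"):
            model.predict(ds.data.drop(columns=["pH"]))


class TestHoldout:
    def test_split_sizes_match_design(self):
        config, spec = default_config(n_samples=1381, seed=2)
        ds = generate_dataset(config, spec)
        out = holdout_validate(spec, ds.data, n_train=1000, seed=0)
        assert out["n_train"] == 1000
        assert out["n_test"] == 381

    def test_same_seed_same_split_and_metrics(self):
        config, spec = default_config(n_samples=600, seed=4)
        ds = generate_dataset(config, spec)
        a = holdout_validate(spec, ds.data, n_train=400, seed=5)
        b = holdout_validate(spec, ds.data, n_train=400, seed=5)
        assert a["r2"] == b["r2"] and a["pearson_r"] == b["pearson_r"]
        pd.testing.assert_series_equal(a["predictions"], b["predictions"])

    def test_train_size_must_be_below_n(self):
        config, spec = default_config(n_samples=50, seed=0)
        ds = generate_dataset(config, spec)
        with pytest.raises(ValueError, match="n_train"):
            holdout_validate(spec, ds.data, n_train=50)


class TestFitMany:
    def test_one_fit_per_taxon_with_summary(self, small_world):
        config, spec, ds = small_world
        from soilniche.sem import default_spec as make_spec

        taxa_spec = make_spec("taxon")
        result = fit_many(taxa_spec, ds.abundances, ds.env)
        assert len(result.fits) == 3
        assert len(result.summary) == 3
        assert result.summary["converged"].all()

    def test_constant_taxon_flagged_others_unaffected(self, small_world):
        config, spec, ds = small_world
        from soilniche.sem import default_spec as make_spec

        data = ds.abundances.data.copy()
        data.loc["flatliner"] = 1.0
        table = AbundanceTable(data, mode="raw")
        result = fit_many(make_spec("taxon"), table, ds.env)
        assert "flatliner" in result.failures
        assert "zero-variance" in result.failures["flatliner"]
        assert len(result.fits) == 3
        assert not result.summary.loc["flatliner", "converged"]
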