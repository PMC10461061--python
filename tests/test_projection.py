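"""Future-scenario projection, ln-fold change with zero replacement,
Bray-Curtis / PCoA ordination and the functional (gene copy) projection."""

import numpy as np
import pandas as pd
import pytest

from soilniche.io import ENV_COLUMNS, AbundanceTable, EnvTable
from soilniche.projection import (
    PCoA,
    ScenarioTable,
    bray_curtis,
    community_change,
    displacement,
    functional_projection,
    grid_interpolate,
    lnfold_change,
    pcoa,
    project_future,
)
from soilniche.sem import StructuralEquationModel, default_spec, fit_many
from soilniche.synthetic import GeneratorConfig, default_config, generate_dataset


@pytest.fixture(scope="module")
def projected_world():
    config, spec = default_config(n_samples=600, n_taxa=3, seed=21)
    ds = generate_dataset(config, spec)
    collection = fit_many(default_spec("taxon"), ds.abundances, ds.env)
    return ds, collection


class TestProjectFuture:
    def test_identity_scenario_returns_conditional_fitted_values(self, projected_world):
        ds, collection = projected_world
        future = project_future(collection, ds.env, ds.env.data[list(ENV_COLUMNS)])
        taxon = ds.abundances.taxon_ids[0]
        fit = collection.fits[taxon]
        direct = fit.predict(ds.env.data, target="taxon")
        assert np.allclose(
            future.data.loc[taxon].to_numpy(), np.clip(direct.to_numpy(), 0, None)
        )

    def test_projection_is_linear_in_driver_changes(self, projected_world):
        ds, collection = projected_world
        base = ds.env.data[list(ENV_COLUMNS)]
        bump1 = base.copy()
        bump1["MAT"] += 0.5
        bump2 = base.copy()
        bump2["MAT"] += 1.0
        taxon = ds.abundances.taxon_ids[0]
        f0 = project_future(collection, ds.env, base).data.loc[taxon]
        f1 = project_future(collection, ds.env, bump1).data.loc[taxon]
        f2 = project_future(collection, ds.env, bump2).data.loc[taxon]
        assert np.allclose(f2 - f0, 2 * (f1 - f0), atol=1e-10)

    def test_unsupplied_endogenous_drivers_are_propagated(self, projected_world):
        ds, collection = projected_world
        exo_only = ds.env.data[
            ["MAT", "humidity", "precipitation", "pH", "conductivity"]
        ]
        future = project_future(collection, ds.env, exo_only)
        assert future.data.shape[1] == len(ds.env.sample_ids)

    def test_missing_exogenous_column_reported(self, projected_world):
        ds, collection = projected_world
        with pytest.raises(ValueError, match="MAT"):
            project_future(
                collection, ds.env, ds.env.data[["humidity", "precipitation"]]
            )

    def test_printed_climate_paths_move_prediction_by_their_standardized_size(self):
        """A +1 sd humidity shift moves the prediction by the humidity
        standardized path (-0.46 for the strongly climate-driven class)."""
        rng = np.random.default_rng(0)
        n = 20_000
        paths = {
            "MAT": -0.22, "humidity": -0.46, "precipitation": -0.21,
            "C3_macrothermal": 0.03, "C3_mesothermal": 0.06,
            "C4_megathermal": 0.19, "conductivity": -0.08, "pH": -0.03,
            "OC": -0.12,
        }
        X = pd.DataFrame(
            rng.normal(size=(n, 9)), columns=list(paths)
        )
        resid_sd = np.sqrt(1 - sum(v**2 for v in paths.values()))
        y = sum(X[k].to_numpy() * v for k, v in paths.items())
        X["taxon"] = y + rng.normal(0, resid_sd, n)
        from soilniche.sem import SemSpec

        spec = SemSpec(
            variables=list(paths) + ["taxon"],
            edges=[(d, "taxon") for d in paths],
            exogenous=list(paths),
            sink="taxon",
        )
        model = StructuralEquationModel(spec=spec).fit(X)
        shifted = X.copy()
        shifted["humidity"] += X["humidity"].std(ddof=1)
        delta = (model.predict(shifted) - model.predict(X)) / X["taxon"].std(ddof=1)
        assert delta.iloc[0] == pytest.approx(
            model.std_coefs_["taxon"]["humidity"], abs=1e-10
        )
        assert delta.iloc[0] == pytest.approx(-0.46, abs=0.02)


class TestLnFold:
    def _tables(self, cur, fut):
        taxa = [f"t{i}" for i in range(cur.shape[0])]
        samples = [f"s{j}" for j in range(cur.shape[1])]
        return (
            pd.DataFrame(cur, index=taxa, columns=samples),
            pd.DataFrame(fut, index=taxa, columns=samples),
        )

    def test_replacement_is_half_the_lowest_positive_current_value(self):
        cur, fut = self._tables(
            np.array([[0.066, 0.0], [0.5, 0.2]]), np.array([[0.1, 0.1], [0.5, 0.2]])
        )
        _, repl = lnfold_change(cur, fut)
        assert repl == pytest.approx(0.033)

    def test_identical_matrices_give_zero_lnfold(self):
        cur, fut = self._tables(np.full((2, 3), 0.2), np.full((2, 3), 0.2))
        ln, _ = lnfold_change(cur, fut)
        assert np.max(np.abs(ln.to_numpy())) < 1e-12

    def test_doubling_gives_ln_two(self):
        cur, fut = self._tables(np.array([[0.1]]), np.array([[0.2]]))
        ln, _ = lnfold_change(cur, fut)
        assert ln.iloc[0, 0] == pytest.approx(np.log(2))

    def test_all_zero_taxon_set_rejected(self):
        cur, fut = self._tables(np.zeros((2, 2)), np.ones((2, 2)))
        with pytest.raises(ValueError, match="no positive"):
            lnfold_change(cur, fut)


class TestBrayCurtis:
    def test_identical_and_disjoint_samples(self):
        df = pd.DataFrame(
            {"a": [1.0, 2.0, 0.0], "b": [1.0, 2.0, 0.0], "c": [0.0, 0.0, 5.0]},
            index=["t1", "t2", "t3"],
        )
        D = bray_curtis(df)
        assert D.loc["a", "b"] == 0.0
        assert D.loc["a", "c"] == 1.0

    def test_hand_computed_example(self):
        df = pd.DataFrame({"u": [1.0, 0.0, 3.0], "v": [2.0, 2.0, 0.0]},
                          index=["t1", "t2", "t3"])
        assert bray_curtis(df).loc["u", "v"] == pytest.approx(0.75)

    def test_zero_total_sample_rejected(self):
        df = pd.DataFrame({"a": [1.0, 1.0], "b": [0.0, 0.0]}, index=["t1", "t2"])
        with pytest.raises(ValueError, match="'b'"):
            bray_curtis(df)


class TestPCoA:
    def test_recovers_planted_planar_configuration(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(15, 2))
        D = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        model = PCoA()
        coords = model.fit_transform(D)[:, :2]
        # Procrustes alignment residual
        A = pts - pts.mean(0)
        B = coords - coords.mean(0)
        U, _, Vt = np.linalg.svd(B.T @ A)
        R = U @ Vt
        resid = np.linalg.norm(B @ R - A)
        assert resid < 1e-8

    def test_eigenvalues_nonincreasing_and_negatives_reported(self):
        df = pd.DataFrame(
            {"a": [1.0, 0.0, 0.2], "b": [0.0, 1.0, 0.4], "c": [0.5, 0.5, 0.1]},
            index=["t1", "t2", "t3"],
        )
        coords, eigval = pcoa(bray_curtis(df))
        assert np.all(np.diff(eigval) <= 1e-12)

    def test_agrees_with_independent_reference_implementation(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(2)
        X = rng.random((6, 10))
        D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
        ours = PCoA().fit_transform(D)
        ref = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(D)).samples.to_numpy()
        k = min(ours.shape[1], 4)
        for axis in range(k):
            r = np.corrcoef(ours[:, axis], ref[:, axis])[0, 1]
            assert abs(abs(r) - 1.0) < 1e-6

    def test_asymmetric_matrix_rejected(self):
        D = np.array([[0.0, 1.0], [0.5, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            PCoA().fit_transform(D)

    def test_sample_order_permutation_equivariance(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(
            rng.random((4, 8)),
            index=[f"t{i}" for i in range(4)],
            columns=[f"s{j}" for j in range(8)],
        )
        D = bray_curtis(df)
        coords, _ = pcoa(D)
        perm = ["s3", "s0", "s7", "s1", "s2", "s6", "s4", "s5"]
        coords_p, _ = pcoa(D.loc[perm, perm])
        for s in perm:
            d = np.abs(np.abs(coords_p.loc[s].to_numpy()[:2])
                       - np.abs(coords.loc[s].to_numpy()[:2]))
            assert np.all(d < 1e-8)


class TestDisplacement:
    def _coords(self, cur, fut):
        idx = [f"s{i}|c" for i in range(len(cur))] + [f"s{i}|f" for i in range(len(fut))]
        return (
            pd.DataFrame(np.vstack([cur, fut]), index=idx, columns=["PCo1", "PCo2"]),
            [f"s{i}|c" for i in range(len(cur))],
            [f"s{i}|f" for i in range(len(fut))],
        )

    def test_identical_positions_give_zero(self):
        pts = np.array([[0.0, 0.0], [1.0, 2.0]])
        coords, cur, fut = self._coords(pts, pts)
        assert (displacement(coords, cur, fut) == 0).all()

    def test_translation_three_four_gives_five(self):
        pts = np.array([[0.0, 0.0]])
        coords, cur, fut = self._coords(pts, pts + [3.0, 4.0])
        assert displacement(coords, cur, fut).iloc[0] == pytest.approx(5.0)

    def test_unmatched_site_rejected(self):
        pts = np.array([[0.0, 0.0]])
        coords, cur, fut = self._coords(pts, pts)
        with pytest.raises(ValueError, match="unmatched"):
            displacement(coords, cur, ["missing"])


class TestFunctionalProjection:
    def test_identity_trait_table_returns_taxon_profile(self):
        df = pd.DataFrame({"s1": [0.3, 0.7], "s2": [0.5, 0.5]}, index=["a", "b"])
        traits = pd.DataFrame(np.eye(2), index=["a", "b"], columns=["gA", "gB"])
        genes, dropped = functional_projection(df, traits)
        assert dropped == 0.0
        assert np.allclose(genes.to_numpy(), df.to_numpy())

    def test_shared_single_copy_gene_tracks_total_abundance(self):
        df = pd.DataFrame({"s1": [0.3, 0.7]}, index=["a", "b"])
        traits = pd.DataFrame({"g1": [1.0, 1.0], "g2": [2.0, 0.0]}, index=["a", "b"])
        genes, _ = functional_projection(df, traits)
        # unnormalised g1 = total community abundance = 1.0 -> share 1/1.6
        assert genes.loc["g1", "s1"] == pytest.approx(1.0 / 1.6)

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(
            rng.random((5, 3)), index=[f"t{i}" for i in range(5)],
            columns=["s1", "s2", "s3"],
        )
        traits = pd.DataFrame(
            rng.integers(0, 4, size=(5, 4)).astype(float),
            index=[f"t{i}" for i in range(5)],
            columns=[f"g{i}" for i in range(4)],
        )
        genes, _ = functional_projection(df, traits)
        brute = np.zeros((4, 3))
        for gi in range(4):
            for sj in range(3):
                brute[gi, sj] = sum(
                    traits.iloc[ti, gi] * df.iloc[ti, sj] for ti in range(5)
                )
        brute = brute / brute.sum(axis=0, keepdims=True)
        assert np.allclose(genes.to_numpy(), brute)

    def test_dropped_fraction_reported(self):
        df = pd.DataFrame({"s1": [0.4, 0.6]}, index=["a", "unknown"])
        traits = pd.DataFrame({"g": [1.0]}, index=["a"])
        _, dropped = functional_projection(df, traits)
        assert dropped == pytest.approx(0.5)


class TestGrid:
    def test_constant_field_gives_constant_grid(self):
        rng = np.random.default_rng(0)
        lon, lat = rng.uniform(0, 2, 10), rng.uniform(0, 2, 10)
        _, _, grid = grid_interpolate(lon, lat, np.full(10, 3.3), resolution=0.2)
        assert np.allclose(grid.compressed(), 3.3)

    def test_exact_at_coincident_node(self):
        lon = np.array([0.0, 1.0, 2.0])
        lat = np.array([0.0, 1.0, 2.0])
        vals = np.array([5.0, 7.0, 9.0])
        gx, gy, grid = grid_interpolate(lon, lat, vals, resolution=1.0)
        assert grid[0, 0] == 5.0 and grid[1, 1] == 7.0 and grid[2, 2] == 9.0

    def test_default_resolution_fifth_of_degree(self):
        import inspect

        from soilniche.projection import grid_interpolate as gi

        assert inspect.signature(gi).parameters["resolution"].default == 0.2


class TestCommunityChange:
    def test_end_to_end_change_summary(self, projected_world):
        ds, collection = projected_world
        scenario = ds.env.data[list(ENV_COLUMNS)].copy()
        scenario["MAT"] += 0.5
        future = project_future(collection, ds.env, scenario)
        sub = ds.abundances.data.iloc[:, :40]
        cur = AbundanceTable(sub, mode="raw")
        fut = AbundanceTable(future.data.loc[sub.index, sub.columns], mode="raw")
        change = community_change(cur, fut)
        assert change.lnfold.shape == sub.shape
        assert (change.displacement >= 0).all()
        assert np.all(np.diff(change.eigenvalues) <= 1e-10)
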