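import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import snowrsf as s
from snowrsf.raster import GridRaster, HomeRangePolygon
from snowrsf.rsf import COVARIATES


def _polygon_from_mask(grid, mask_vals):
    return HomeRangePolygon(grid.like(mask_vals.astype(float)), 0.99)


class TestSubsample:
    @staticmethod
    def _fixes(n_animals, n_days, per_day, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for a in range(n_animals):
            for d in range(n_days):
                for _ in range(per_day):
                    rows.append(
                        {
                            "animal_id": f"a{a}",
                            "date": f"d{d}",
                            "month": "Jan",
                            "x": rng.uniform(0, 100),
                            "y": rng.uniform(0, 100),
                        }
                    )
        return pd.DataFrame(rows)

    def test_one_per_day_input_is_identity(self):
        fixes = self._fixes(3, 10, 1)
        out = s.subsample_one_per_animal_day(fixes, seed=1)
        assert len(out) == len(fixes)
        assert set(map(tuple, out[["x", "y"]].round(6).to_numpy())) == set(
            map(tuple, fixes[["x", "y"]].round(6).to_numpy())
        )

    def test_exact_row_count(self):
        out = s.subsample_one_per_animal_day(self._fixes(3, 10, 8), seed=2)
        assert len(out) == 30
        assert out.groupby(["animal_id", "date"]).size().max() == 1

    def test_seed_contract(self):
        fixes = self._fixes(4, 20, 6)
        a = s.subsample_one_per_animal_day(fixes, seed=3)
        b = s.subsample_one_per_animal_day(fixes, seed=3)
        c = s.subsample_one_per_animal_day(fixes, seed=4)
        assert a.equals(b)
        assert not a[["x", "y"]].equals(c[["x", "y"]])


class TestSampleAvailable:
    def test_points_inside_mask_and_balance(self, flat_grid):
        mask = np.zeros(flat_grid.shape)
        mask[10:30, 15:40] = 1
        poly = _polygon_from_mask(flat_grid, mask)
        pts = s.sample_available(poly, 500, seed=5)
        assert len(pts) == 500
        assert poly.contains(pts[:, 0], pts[:, 1]).all()

    def test_empirically_uniform_over_cells(self):
        grid = GridRaster(np.zeros((2, 5)), 0.0, 0.0, 10.0)
        poly = _polygon_from_mask(grid, np.ones((2, 5)))
        pts = s.sample_available(poly, 50_000, seed=6)
        row, col = grid.index_of(pts[:, 0], pts[:, 1])
        counts = np.bincount(row * 5 + col, minlength=10)
        chi2 = ((counts - counts.mean()) ** 2 / counts.mean()).sum()
        assert stats.chi2.sf(chi2, 9) > 0.01

    def test_empty_polygon_rejected(self, flat_grid):
        poly = _polygon_from_mask(flat_grid, np.zeros(flat_grid.shape))
        with pytest.raises(ValueError):
            s.sample_available(poly, 10, seed=0)


class TestAttachCovariates:
    def test_toy_raster_rows_match_hand_computation(self, toy3x3):
        # canopy = identity of cell parity, snow = toy values, dist = toy*10
        canopy = toy3x3.like((toy3x3.values % 2 == 0).astype(float))
        snow = {"Jan": toy3x3}
        dist = toy3x3.like(toy3x3.values * 10.0)
        pts = np.array([[5.0, 5.0], [25.0, 25.0]])  # cells (0,0) and (2,2)
        rows = s.attach_covariates(pts, "Jan", snow, canopy, dist, dist_floor_m=5.0)
        # cell (0,0): cc=0, sd=1, dist=10 -> prox=0.1, inter=0.1
        assert rows.iloc[0][["cc", "sd", "prox", "inter"]].tolist() == [0.0, 1.0, 0.1, 0.1]
        # cell (2,2): cc=0 (9 odd), sd=9, dist=90 -> prox=1/90
        assert rows.iloc[1]["prox"] == pytest.approx(1 / 90)
        assert rows.iloc[1]["inter"] == pytest.approx(9 / 90)

    def test_distance_floor_at_feeding_site(self, toy3x3):
        canopy = toy3x3.like(np.zeros((3, 3)))
        dist = toy3x3.like(np.zeros((3, 3)))  # on-site everywhere
        rows = s.attach_covariates(
            np.array([[15.0, 15.0]]), "Jan", {"Jan": toy3x3}, canopy, dist, dist_floor_m=5.0
        )
        assert rows.iloc[0]["prox"] == pytest.approx(0.2)

    def test_zero_snow_zeroes_interaction(self, toy3x3):
        canopy = toy3x3.like(np.zeros((3, 3)))
        snow = {"Jan": toy3x3.like(np.zeros((3, 3)))}
        dist = toy3x3.like(np.full((3, 3), 100.0))
        rows = s.attach_covariates(np.array([[5.0, 25.0]]), "Jan", snow, canopy, dist, 5.0)
        assert rows.iloc[0]["inter"] == 0.0

    def test_point_on_nodata_cell_rejected(self, toy3x3):
        canopy = toy3x3.like(np.zeros((3, 3)))
        vals = toy3x3.values.copy()
        vals[1, 1] = np.nan
        snow = {"Jan": toy3x3.like(vals)}
        dist = toy3x3.like(np.full((3, 3), 50.0))
        with pytest.raises(ValueError, match="nodata"):
            s.attach_covariates(np.array([[15.0, 15.0]]), "Jan", snow, canopy, dist, 5.0)


class TestFitRsf:
    @staticmethod
    def _logistic_design(n=4000, seed=0):
        """Case-control rows with a known logistic data-generating process."""
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(
            {
                "cc": rng.integers(0, 2, n).astype(float),
                "sd": rng.uniform(0, 80, n),
                "prox": rng.uniform(0.0002, 0.02, n),
            }
        )
        X["inter"] = X["sd"] * X["prox"]
        beta = {"cc": 0.8, "sd": -0.05, "prox": 300.0, "inter": 5.0}
        lp = -0.5 + sum(beta[k] * X[k] for k in beta)
        X["case"] = (rng.uniform(size=n) < 1 / (1 + np.exp(-lp))).astype(int)
        X["month"] = "Jan"
        return X, beta

    def test_recovers_known_logistic_coefficients(self):
        design, beta = self._logistic_design(20_000, seed=1)
        model = s.fit_rsf(design)
        for k in COVARIATES:
            assert abs(model.beta[k] - beta[k]) < 3 * model.se[k]
        assert model.converged
        assert all(v > 0 for v in model.se.values())

    def test_duplicating_rows_halves_variance(self):
        design, _ = self._logistic_design(3000, seed=2)
        m1 = s.fit_rsf(design)
        m2 = s.fit_rsf(pd.concat([design, design], ignore_index=True))
        for k in COVARIATES:
            assert m2.beta[k] == pytest.approx(m1.beta[k], rel=1e-6)
            assert m2.se[k] == pytest.approx(m1.se[k] / np.sqrt(2), rel=1e-6)

    def test_stratified_intercepts_leave_slopes_estimable(self):
        a, _ = self._logistic_design(3000, seed=3)
        b, _ = self._logistic_design(3000, seed=4)
        b["month"] = "Feb"
        design = pd.concat([a, b], ignore_index=True)
        plain = s.fit_rsf(design)
        strat = s.fit_rsf(design, strata="month")
        # same DGP in both strata: estimates agree within joint noise
        for k in COVARIATES:
            assert abs(strat.beta[k] - plain.beta[k]) < 3 * plain.se[k]

    def test_separation_detected(self):
        n = 200
        design = pd.DataFrame(
            {
                "case": np.repeat([1, 0], n // 2),
                "cc": np.repeat([1.0, 0.0], n // 2),
                "sd": np.r_[np.zeros(n // 2), np.full(n // 2, 50.0)],
                "prox": np.tile(np.linspace(0.001, 0.02, n // 2), 2),
            }
        )
        design["inter"] = design["sd"] * design["prox"]
        with pytest.raises((s.SeparationError, Exception)):
            s.fit_rsf(design)

    def test_single_class_and_constant_column_rejected(self):
        design, _ = self._logistic_design(500, seed=5)
        with pytest.raises(ValueError):
            s.fit_rsf(design[design["case"] == 1])
        bad = design.copy()
        bad["cc"] = 1.0
        with pytest.raises(ValueError, match="cc"):
            s.fit_rsf(bad)


class TestLinScaleAndPredict:
    def test_lin_scale_examples(self):
        out, lo, hi, degen = s.lin_scale([2.0, 4.0, 6.0])
        assert np.allclose(out, [0.0, 0.5, 1.0]) and not degen
        out, _, _, _ = s.lin_scale([-3.0, 0.0, 9.0])
        assert np.allclose(out, [0.0, 0.25, 1.0])

    def test_lin_scale_preserves_order(self):
        rng = np.random.default_rng(20)
        x = rng.normal(size=200)
        out, *_ = s.lin_scale(x)
        assert np.array_equal(np.argsort(out), np.argsort(x))

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(
            st.floats(-1e6, 1e6, allow_nan=False), min_size=1, max_size=50
        )
    )
    def test_output_always_in_unit_interval_and_affine(self, xs):
        out, lo, hi, degen = s.lin_scale(xs)
        if not degen:
            assert out.min() == 0.0 and out.max() == 1.0
            # affine: differences scale by the same factor
            x = np.asarray(xs)
            assert np.allclose(out, (x - lo) / (hi - lo))

    def test_degenerate_constant_input_flagged(self):
        out, lo, hi, degen = s.lin_scale([3.0, 3.0, 3.0])
        assert degen and np.all(out == 0.0)

    @staticmethod
    def _model(beta):
        return s.RSFModel(
            beta=dict(zip(COVARIATES, beta)),
            se={k: 1.0 for k in COVARIATES},
            intercept=0.0, loglik=0.0, converged=True, n_used=1, n_available=1,
        )

    def test_2x2_toy_map_matches_hand_computation(self):
        grid = GridRaster(np.zeros((2, 2)), 0.0, 0.0, 10.0)
        cc = grid.like(np.array([[1.0, 0.0], [0.0, 1.0]]))
        sd = grid.like(np.array([[0.0, 10.0], [20.0, 30.0]]))
        dist = grid.like(np.array([[10.0, 20.0], [40.0, 80.0]]))
        model = self._model([1.0, -0.1, 100.0, 0.0])
        rp = s.predict_rp(model, sd, cc, dist, dist_floor_m=5.0)
        w = np.exp(
            1.0 * cc.values - 0.1 * sd.values + 100.0 / np.maximum(dist.values, 5.0)
        )
        expect = (w - w.min()) / (w.max() - w.min())
        assert np.allclose(rp.raster.values, expect)
        assert rp.raster.values.min() == 0.0 and rp.raster.values.max() == 1.0

    def test_all_zero_betas_give_degenerate_map(self, toy3x3):
        model = self._model([0.0, 0.0, 0.0, 0.0])
        rp = s.predict_rp(model, toy3x3, toy3x3.like(np.zeros((3, 3))),
                          toy3x3.like(np.full((3, 3), 50.0)), 5.0)
        assert rp.degenerate
        assert np.all(rp.raster.values == 0.0)

    def test_invariant_to_constant_offset_in_linear_predictor(self, small_landscape):
        model = self._model([0.8, -0.05, 300.0, 5.0])
        shifted = self._model([0.8, -0.05, 300.0, 5.0])
        shifted.intercept = 42.0  # never enters prediction
        args = (
            small_landscape["snow"]["Jan"], small_landscape["canopy"],
            small_landscape["dist"], 50.0,
        )
        assert np.allclose(
            s.predict_rp(model, *args).raster.values,
            s.predict_rp(shifted, *args).raster.values,
        )

    def test_rp_nonincreasing_in_snow_depth(self):
        grid = GridRaster(np.zeros((5, 5)), 0.0, 0.0, 10.0)
        cc = grid.like(np.zeros((5, 5)))
        dist = grid.like(np.full((5, 5), 100.0))
        sd = grid.like(np.linspace(0, 80, 25).reshape(5, 5))
        model = self._model([0.0, -0.05, 0.0, 0.0])
        rp = s.predict_rp(model, sd, cc, dist, 5.0)
        flat = rp.raster.values.ravel()
        assert np.all(np.diff(flat) <= 1e-12)


class TestBuildDesign:
    def test_one_to_one_balance_and_polygon_clip(self, small_landscape):
        dem = small_landscape["dem"]
        rng = np.random.default_rng(30)
        mask = np.zeros(dem.shape)
        mask[10:40, 10:40] = 1
        poly = _polygon_from_mask(dem, mask)
        n = 300
        used = pd.DataFrame(
            {
                "x": rng.uniform(500, 4500, n),
                "y": rng.uniform(500, 4500, n),
                "month": "Jan",
                "animal_id": "a0",
            }
        )
        design = s.build_design(
            used, poly, {"Jan": small_landscape["snow"]["Jan"]},
            small_landscape["canopy"], small_landscape["dist"], 50.0, seed=1,
        )
        n_used = (design["case"] == 1).sum()
        n_avail = (design["case"] == 0).sum()
        assert n_used == n_avail
        inside = poly.contains(used["x"].to_numpy(), used["y"].to_numpy())
        assert n_used == inside.sum()  # clipped to the polygon
        assert (design["prox"] > 0).all() and np.isfinite(design["prox"]).all()
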