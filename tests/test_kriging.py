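import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Polygon

import geograin as gg
from geograin.kriging import (SSPE_MEDIAN, block_krige, cross_validate,
                              discretize_polygon, krige_grid, median_sspe_interval,
                              ordinary_krige, select_model, variance_mask)
from geograin.variogram import VariogramModel
from conftest import random_field_survey

MODEL = VariogramModel(nugget=0.0, partial_sill=1.0, range_a=30.0)
MODEL_NUGGET = VariogramModel(nugget=0.2, partial_sill=0.8, range_a=30.0)


class TestOrdinaryKrige:
    def test_exact_interpolation_with_zero_nugget(self, tiny_survey):
        df = tiny_survey
        i = 7
        res = ordinary_krige(df, MODEL, (df.loc[i, "lon"], df.loc[i, "lat"]))
        assert res.prediction == pytest.approx(df.loc[i, "value"], abs=1e-6)
        assert res.variance == pytest.approx(0.0, abs=1e-8)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_weights_sum_to_one(self, tiny_survey, seed):
        rng = np.random.default_rng(seed)
        target = (36.0 + rng.uniform(0, 1.5), rng.uniform(0, 1.5))
        res = ordinary_krige(tiny_survey, MODEL_NUGGET, target)
        assert res.weights.sum() == pytest.approx(1.0, abs=1e-8)

    def test_pure_nugget_closed_form(self):
        """Three collinear equidistant data, pure nugget: prediction is the
        simple mean and the variance is c0 (1 + 1/3) from the 4x4 system."""
        c0 = 0.5
        df = pd.DataFrame({"lon": [0.0, 0.1, 0.2], "lat": [0.0] * 3,
                           "value": [1.0, 2.0, 6.0]})
        res = ordinary_krige(df, VariogramModel(c0, 0.0, 1.0), (0.05, 0.3))
        assert res.prediction == pytest.approx(3.0, abs=1e-10)
        assert res.variance == pytest.approx(c0 * (1 + 1.0 / 3.0), abs=1e-10)
        np.testing.assert_allclose(res.weights, 1.0 / 3.0, atol=1e-10)

    def test_variance_invariant_to_value_permutation(self, tiny_survey):
        rng = np.random.default_rng(4)
        df2 = tiny_survey.copy()
        df2["value"] = rng.permutation(df2["value"].to_numpy())
        t = (36.7, 0.9)
        r1 = ordinary_krige(tiny_survey, MODEL_NUGGET, t)
        r2 = ordinary_krige(df2, MODEL_NUGGET, t)
        assert r1.variance == pytest.approx(r2.variance, rel=1e-12)

    def test_nearest_neighborhood_restricts_system(self, tiny_survey):
        res = ordinary_krige(tiny_survey, MODEL_NUGGET, (36.7, 0.9), neighborhood=8)
        assert res.weights.size == 8
        assert res.weights.sum() == pytest.approx(1.0, abs=1e-8)

    def test_duplicate_sites_with_zero_nugget_fail(self):
        df = pd.DataFrame({"lon": [0.0, 0.0, 0.3], "lat": [0.0, 0.0, 0.0],
                           "value": [1.0, 2.0, 3.0]})
        with pytest.raises(np.linalg.LinAlgError):
            ordinary_krige(df, MODEL, (0.1, 0.1))


class TestCrossValidation:
    def test_matches_explicit_leave_one_out(self, tiny_survey):
        """The vectorised LOO equals removing each site and re-kriging."""
        rep = cross_validate(tiny_survey, MODEL_NUGGET)
        for i in [0, 13, 39]:
            rest = tiny_survey.drop(index=i)
            res = ordinary_krige(rest, MODEL_NUGGET,
                                 (tiny_survey.loc[i, "lon"], tiny_survey.loc[i, "lat"]))
            theta = (tiny_survey.loc[i, "value"] - res.prediction) ** 2 / res.variance
            assert rep.sspe[i] == pytest.approx(theta, rel=1e-8)

    def test_valid_model_is_consistent(self, field_survey_200, truth_model):
        rep = cross_validate(field_survey_200, truth_model)
        assert rep.interval[0] < SSPE_MEDIAN < rep.interval[1]
        assert rep.verdict == "consistent"

    def test_doubled_sill_understates_sspe(self):
        """Inflating the variogram halves the standardized errors."""
        df = random_field_survey(300, seed=17)
        bad = VariogramModel(0.4, 1.6, 30.0)
        rep_true = cross_validate(df, gg.VariogramModel(0.2, 0.8, 30.0))
        rep_bad = cross_validate(df, bad)
        assert rep_bad.median_sspe == pytest.approx(rep_true.median_sspe / 2,
                                                    rel=1e-6)
        assert rep_bad.median_sspe < rep_bad.interval[0]
        assert rep_bad.verdict == "inconsistent"

    def test_median_interval_shrinks_and_brackets_chi2_median(self):
        lo1, hi1 = median_sspe_interval(100)
        lo2, hi2 = median_sspe_interval(1000)
        assert lo1 < SSPE_MEDIAN < hi1
        assert lo2 < SSPE_MEDIAN < hi2
        assert (hi2 - lo2) < (hi1 - lo1)

    def test_needs_ten_samples(self, tiny_survey):
        with pytest.raises(ValueError):
            cross_validate(tiny_survey.head(5), MODEL_NUGGET)


class TestSelectModel:
    def test_consistent_matheron_is_kept(self, field_survey_200, truth_model):
        robust_alt = VariogramModel(0.5, 2.0, 10.0)
        sel = select_model(field_survey_200,
                          {"matheron": truth_model, "dowd": robust_alt})
        assert sel.estimator == "matheron"
        assert "dowd" not in sel.reports  # alternatives untouched

    def test_inconsistent_matheron_falls_back_to_closest(self, field_survey_200,
                                                         truth_model):
        t = truth_model
        bad = VariogramModel(4 * t.nugget, 4 * t.partial_sill, t.range_a)
        mild = VariogramModel(1.3 * t.nugget, 1.3 * t.partial_sill, t.range_a)
        sel = select_model(field_survey_200,
                          {"matheron": bad, "cressie_hawkins": mild,
                           "dowd": t})
        assert sel.estimator != "matheron"
        others = {k: v for k, v in sel.reports.items() if k != "matheron"}
        best = min(others, key=lambda k: abs(others[k].median_sspe - SSPE_MEDIAN))
        assert sel.estimator == best

    def test_requires_matheron_candidate(self, field_survey_200, truth_model):
        with pytest.raises(ValueError):
            select_model(field_survey_200, {"dowd": truth_model})


class TestKrigeGrid:
    def test_log_back_transform_is_exponential(self, tiny_survey):
        work = tiny_survey.copy()
        work["value"] = np.log(work["value"].abs() + 1.0)
        grid = pd.DataFrame({"lon": [36.5, 36.9], "lat": [0.5, 1.0]})
        raw = krige_grid(work, MODEL_NUGGET, grid, scale="original")
        back = krige_grid(work, MODEL_NUGGET, grid, scale="log_e")
        np.testing.assert_allclose(back["prediction"], np.exp(raw["prediction"]))
        np.testing.assert_allclose(back["variance"], raw["variance"])

    def test_constant_samples_predict_the_constant(self, tiny_survey):
        df = tiny_survey.copy()
        df["value"] = 5.5
        grid = pd.DataFrame({"lon": [36.4, 36.8, 37.1], "lat": [0.3, 0.8, 1.2]})
        out = krige_grid(df, MODEL_NUGGET, grid)
        np.testing.assert_allclose(out["prediction"], 5.5, atol=1e-8)
        assert np.all(out["variance"] > 0)

    def test_median_unbiased_back_transform_on_lognormal_field(self):
        """Back-transformed predictions at held-out sites have about the
        same median as the true values (ratio averaged over replicate
        fields, since a 200-site holdout median alone carries ~10% noise)."""
        ratios = []
        for seed in (20, 21, 22, 23, 24):
            df = random_field_survey(1000, seed=seed, model=MODEL_NUGGET,
                                     mean=1.0, log_scale=True)
            fitdf = df.head(800).copy()
            hold = df.tail(200)
            fitdf["value"] = np.log(fitdf["value"])
            out = krige_grid(fitdf, MODEL_NUGGET, hold[["lon", "lat"]],
                             scale="log_e")
            ratios.append(np.median(out["prediction"]) / np.median(hold["value"]))
        assert 0.9 < np.mean(ratios) < 1.1

    def test_empty_grid_rejected(self, tiny_survey):
        with pytest.raises(ValueError):
            krige_grid(tiny_survey, MODEL_NUGGET, pd.DataFrame({"lon": [], "lat": []}))


class TestBlockKrige:
    def test_degenerate_block_equals_point_kriging(self, tiny_survey):
        t = (36.6, 0.7)
        point = ordinary_krige(tiny_survey, MODEL_NUGGET, t)
        block = block_krige(tiny_survey, MODEL_NUGGET,
                            (np.array([t[0]]), np.array([t[1]])))
        assert block.prediction == pytest.approx(point.prediction, abs=1e-6)
        assert block.variance == pytest.approx(point.variance, abs=1e-6)

    def test_constant_field_block_mean_is_the_constant(self, tiny_survey):
        df = tiny_survey.copy()
        df["value"] = 2.25
        poly = Polygon([(36.3, 0.3), (36.8, 0.3), (36.8, 0.8), (36.3, 0.8)])
        res = block_krige(df, MODEL_NUGGET, poly, spacing_km=10.0, min_nodes=25)
        assert res.prediction == pytest.approx(2.25, abs=1e-8)

    def test_block_variance_below_point_variance_at_centroid(self, field_survey_200,
                                                             truth_model):
        """Averaging over a 50x50 km block reduces prediction variance."""
        rng = np.random.default_rng(9)
        diffs = []
        for _ in range(5):
            cx = 36.0 + rng.uniform(0.4, 2.0)
            cy = rng.uniform(0.4, 2.0)
            half = 0.225  # ~25 km
            poly = Polygon([(cx - half, cy - half), (cx + half, cy - half),
                            (cx + half, cy + half), (cx - half, cy + half)])
            block = block_krige(field_survey_200, truth_model, poly,
                                spacing_km=10.0, min_nodes=25)
            point = ordinary_krige(field_survey_200, truth_model, (cx, cy))
            diffs.append(point.variance - block.variance)
        assert np.mean(diffs) > 0

    def test_discretization_convergence(self, field_survey_200, truth_model):
        """Halving the block node spacing changes the prediction < 1%."""
        poly = Polygon([(36.5, 0.5), (37.0, 0.5), (37.0, 1.0), (36.5, 1.0)])
        r1 = block_krige(field_survey_200, truth_model, poly, spacing_km=5.0,
                         min_nodes=4)
        r2 = block_krige(field_survey_200, truth_model, poly, spacing_km=2.5,
                         min_nodes=4)
        assert abs(r1.prediction - r2.prediction) < 0.01 * abs(r2.prediction)

    def test_polygon_without_interior_nodes_suggests_finer_spacing(self):
        poly = Polygon([(0, 0), (1e-7, 0), (1e-7, 1e-7)])
        with pytest.raises(ValueError, match="finer"):
            discretize_polygon(poly, spacing_km=100.0, min_nodes=1)


class TestVarianceMask:
    def test_strict_threshold(self):
        v = np.array([0.74, 0.75, 0.7501, 1.0])
        m = variance_mask(v, data_variance=1.0, fraction=0.75)
        np.testing.assert_array_equal(m, [False, False, True, True])

    def test_sparse_extrapolation_nodes_masked(self):
        """Nodes far outside the sampled area are masked; interior ones not."""
        df = random_field_survey(120, seed=29, model=MODEL_NUGGET)
        inside = pd.DataFrame({"lon": [37.0], "lat": [1.3]})
        far = pd.DataFrame({"lon": [42.0], "lat": [8.0]})
        grid = pd.concat([inside, far], ignore_index=True)
        out = krige_grid(df, MODEL_NUGGET, grid)
        data_var = float(np.var(df["value"], ddof=1))
        m = variance_mask(out["variance"].to_numpy(), data_var)
        assert not m[0] and m[1]

    def test_nonpositive_data_variance_rejected(self):
        with pytest.raises(ValueError):
            variance_mask(np.array([1.0]), 0.0)
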