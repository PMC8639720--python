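"""Growth-rate reduction, least-squares fitting, fit metrics and model ranking."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from thermovir import Briere1Params, Logan1Params, eval_briere1, eval_logan1
from thermovir.fitting import (
    ResponseDataset,
    default_bounds,
    fit_linear_growth,
    fit_nonlinear,
    goodness_of_fit,
    radial_growth_rate,
    select_best,
)


def _growth_frame(rows):
    return pd.DataFrame(
        rows, columns=["isolate", "temperature_c", "replicate", "day",
                       "diameter1_mm", "diameter2_mm"]
    )


class TestRadialGrowthRate:
    def test_exact_line(self):
        df = _growth_frame([
            ("A", 25.0, 1, 0, 8.0, 8.0),
            ("A", 25.0, 1, 4, 16.0, 16.0),
            ("A", 15.0, 1, 0, 8.0, 8.0),
            ("A", 15.0, 1, 4, 12.0, 12.0),
        ])
        ds = radial_growth_rate(df, plug_diameter=8.0)
        by_temp = dict(zip(ds.temperature_c, ds.response))
        assert by_temp[25.0] == pytest.approx(1.0)
        assert by_temp[15.0] == pytest.approx(0.5)

    def test_orthogonal_diameters_are_averaged(self):
        df = _growth_frame([
            ("A", 25.0, 1, 0, 8.0, 8.0),
            ("A", 25.0, 1, 2, 10.0, 14.0),
            ("A", 20.0, 1, 0, 8.0, 8.0),
            ("A", 20.0, 1, 2, 8.0, 8.0),
        ])
        ds = radial_growth_rate(df)
        by_temp = dict(zip(ds.temperature_c, ds.response))
        assert by_temp[25.0] == pytest.approx(1.0)  # mean diameter 12 -> radius 2 over 2 days
        assert by_temp[20.0] == 0.0  # constant plates do not grow

    def test_negative_slope_floored(self):
        df = _growth_frame([
            ("A", 35.0, 1, 0, 12.0, 12.0),
            ("A", 35.0, 1, 4, 9.0, 9.0),
            ("A", 30.0, 1, 0, 8.0, 8.0),
            ("A", 30.0, 1, 4, 9.0, 9.0),
        ])
        ds = radial_growth_rate(df)
        assert dict(zip(ds.temperature_c, ds.response))[35.0] == 0.0

    def test_rejects_single_day(self):
        df = _growth_frame([
            ("A", 25.0, 1, 0, 8.0, 8.0),
            ("A", 20.0, 1, 0, 8.0, 8.0),
            ("A", 20.0, 1, 1, 9.0, 9.0),
        ])
        with pytest.raises(ValueError, match="fewer than 2 days"):
            radial_growth_rate(df)


class TestLinearFit:
    def test_collinear_points_recovered_exactly(self):
        t = np.array([15.0, 20.0, 25.0, 30.0])
        ds = ResponseDataset(t, -1.0 + 0.1 * t, np.arange(4))
        res = fit_linear_growth(ds, exclude_temps=())
        assert res.params.a == pytest.approx(-1.0, abs=1e-12)
        assert res.params.b == pytest.approx(0.1, abs=1e-12)
        assert res.gof.r2 == 1.0

    def test_supraoptimal_points_omitted_by_default(self):
        t = np.array([15.0, 20.0, 25.0, 30.0, 33.0, 35.0])
        y = -1.0 + 0.1 * t
        y[-2:] = 0.1  # crash past the optimum
        ds = ResponseDataset(t, y, np.arange(6))
        res = fit_linear_growth(ds)
        assert res.excluded_temperatures == (33.0, 35.0)
        assert res.params.a == pytest.approx(-1.0, abs=1e-12)
        assert res.params.b == pytest.approx(0.1, abs=1e-12)

    def test_near_noiseless_coefficients_recovered(self, rng):
        t = np.repeat([15.0, 20.0, 25.0, 30.0], 4)
        y = -0.93 + 0.11 * t + rng.normal(0, 1e-9, t.size)
        res = fit_linear_growth(ResponseDataset(t, y, np.arange(t.size)), exclude_temps=())
        assert res.params.a == pytest.approx(-0.93, abs=1e-6)
        assert res.params.b == pytest.approx(0.11, abs=1e-6)
        # the quantities feeding the threshold formulas are populated
        assert res.y_mean == pytest.approx(y.mean())
        assert math.isfinite(res.residual_mean_square)
        assert math.isfinite(res.params.se_b)

    def test_all_points_excluded_is_an_error(self):
        ds = ResponseDataset(np.array([33.0, 35.0]), np.array([0.1, 0.2]), np.array([1, 2]))
        with pytest.raises(ValueError):
            fit_linear_growth(ds, exclude_temps=(33.0, 35.0))


class TestGoodnessOfFit:
    def test_perfect_fit(self):
        y = np.array([1.0, 2.0, 3.0])
        g = goodness_of_fit(y, y, 2)
        assert g.rss == 0.0 and g.r2 == 1.0 and g.rmse == 0.0
        assert g.aic == -math.inf and g.msc == math.inf

    def test_hand_computed_aic(self):
        y = np.zeros(5)
        yhat = np.full(5, 0.1)
        y[0] = 1.0  # give TSS > 0 without touching residual structure
        g = goodness_of_fit(y, y - 0.1, 2)
        assert g.rss == pytest.approx(0.05)
        assert g.aic == pytest.approx(5 * math.log(0.01) + 4)  # -19.0259...
        assert g.msc == pytest.approx(math.log(g.tss / 0.05) - 4 / 5)

    def test_residual_scaling_law(self, rng):
        y = rng.normal(size=12)
        resid = rng.normal(size=12)
        g1 = goodness_of_fit(y, y - resid, 3)
        g2 = goodness_of_fit(y, y - 2 * resid, 3)
        assert g2.rss == pytest.approx(4 * g1.rss)
        assert g2.rmse == pytest.approx(2 * g1.rmse)

    def test_order_invariance(self, rng):
        y = rng.normal(size=10)
        yhat = y + rng.normal(size=10) * 0.1
        perm = rng.permutation(10)
        g1 = goodness_of_fit(y, yhat, 2)
        g2 = goodness_of_fit(y[perm], yhat[perm], 2)
        for fld in ("rss", "r2", "adj_r2", "rmse", "aic", "msc"):
            assert getattr(g1, fld) == pytest.approx(getattr(g2, fld))

    def test_constant_observations_flagged(self):
        g = goodness_of_fit(np.ones(5), np.full(5, 1.1), 2)
        assert g.tss_zero and math.isnan(g.r2)


class TestNonlinearFit:
    def test_noiseless_briere_recovery(self, noiseless_growth, briere_truth):
        res = fit_nonlinear(noiseless_growth, "briere1", seed=0)
        assert res.converged
        assert res.params.t_min == pytest.approx(briere_truth.t_min, abs=1e-4)
        assert res.params.t_max == pytest.approx(briere_truth.t_max, abs=1e-4)
        assert res.params.n == pytest.approx(briere_truth.n, rel=1e-4)

    def test_noiseless_logan1_self_consistency(self, icipe20_logan1):
        temps = np.repeat([10.0, 15.0, 20.0, 25.0, 30.0], 4)
        y = np.clip(eval_logan1(icipe20_logan1, temps), 0.0, 1.0)
        ds = ResponseDataset(temps, y, np.tile([1, 2, 3, 4], 5),
                             response_kind="mortality_proportion")
        res = fit_nonlinear(ds, "logan1", seed=0)
        assert res.gof.rss < 1e-10

    def test_linear_route_equals_closed_form(self, rng):
        t = np.repeat([15.0, 20.0, 25.0, 30.0], 3)
        y = -0.8 + 0.09 * t + rng.normal(0, 0.01, t.size)
        ds = ResponseDataset(t, y, np.arange(t.size))
        via_nl = fit_nonlinear(ds, "linear")
        direct = fit_linear_growth(ds, exclude_temps=())
        assert via_nl.params.a == pytest.approx(direct.params.a)
        assert via_nl.params.b == pytest.approx(direct.params.b)

    def test_unknown_model_rejected(self, noiseless_growth):
        with pytest.raises(KeyError):
            fit_nonlinear(noiseless_growth, "logan99")

    def test_dominates_brute_force_grid(self, briere_truth, rng):
        """Multi-start least squares must never lose to a dense parameter grid."""
        from thermovir import synthdata

        design = synthdata.SimulationDesign(noise_sd=0.01, seed=5)
        ds = synthdata.simulate_growth(design, briere_truth)
        res = fit_nonlinear(ds, "briere1", seed=1)
        box = default_bounds("briere1", ds)
        grids = [
            np.geomspace(box["n"][0] + 1e-15, box["n"][1], 20),
            np.linspace(*box["t_min"], 20),
            np.linspace(*box["t_max"], 20),
        ]
        best = math.inf
        t, y = ds.temperature_c, ds.response
        for n, tmin, tmax in itertools.product(*grids):
            if tmin >= tmax:
                continue
            rss = float(np.sum((eval_briere1(Briere1Params(n, tmin, tmax), t) - y) ** 2))
            best = min(best, rss)
        assert res.gof.rss <= best + 1e-12


class TestSelectBest:
    def _fit(self, aic, adj_r2=0.9, rmse=0.1, converged=True, name="m"):
        from thermovir.fitting import FitResult, GoodnessOfFit

        gof = GoodnessOfFit(rss=1.0, tss=10.0, r2=0.9, adj_r2=adj_r2, rmse=rmse,
                            aic=aic, msc=1.0, n_obs=10, k_params=3)
        return FitResult(model=name, params=None, gof=gof, converged=converged)

    def test_lower_aic_wins(self):
        a, b = self._fit(-10, name="a"), self._fit(-5, name="b")
        assert select_best([b, a]).best.model == "a"

    def test_aic_tie_broken_by_adjusted_r2(self):
        a = self._fit(-10, adj_r2=0.9, name="a")
        b = self._fit(-10, adj_r2=0.8, name="b")
        assert select_best([b, a]).best.model == "a"

    def test_non_converged_ranked_last(self):
        good = self._fit(0.0, name="good")
        bad = self._fit(-100.0, converged=False, name="bad")
        ranking = select_best([bad, good])
        assert ranking.best.model == "good"
        assert ranking.fits[-1].model == "bad"

    def test_permutation_invariant_winner(self, rng):
        fits = [self._fit(aic, adj_r2=r, name=str(i))
                for i, (aic, r) in enumerate([(-3, 0.8), (-7, 0.9), (-7, 0.95), (2, 0.5)])]
        winners = set()
        for _ in range(10):
            perm = rng.permutation(len(fits))
            winners.add(select_best([fits[i] for i in perm]).best.model)
        assert winners == {"2"}

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            select_best([])

    def test_single_fit(self):
        f = self._fit(0.0, name="only")
        assert select_best([f]).best is f


class TestResponseDataset:
    def test_csv_round_trip(self, tmp_path, noiseless_growth):
        p = tmp_path / "growth.csv"
        noiseless_growth.to_csv(p)
        back = ResponseDataset.from_csv(p)
        np.testing.assert_allclose(back.temperature_c, noiseless_growth.temperature_c)
        np.testing.assert_allclose(back.response, noiseless_growth.response)
        assert back.isolate == noiseless_growth.isolate

    def test_mortality_range_validated(self):
        with pytest.raises(ValueError):
            ResponseDataset(np.array([10.0, 20.0]), np.array([0.5, 1.5]),
                            np.array([1, 1]), response_kind="mortality_proportion")

    def test_needs_two_temperatures(self):
        with pytest.raises(ValueError):
            ResponseDataset(np.array([10.0, 10.0]), np.array([0.1, 0.2]), np.array([1, 2]))
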