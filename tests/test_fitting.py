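import itertools
import math

import numpy as np
import pytest

from spotfit.fitting import (
    InsufficientDataError,
    _eval_1d,
    _eval_2d,
    fit_r2_2d,
    fit_richards_1d,
    initial_guess,
    profile_confidence_intervals,
)
from spotfit.model_core import (
    RichardsParams,
    TwoDimParams,
    eval_ln_r2,
    eval_ln_richards,
)
from spotfit.preprocess import BindingTable, aggregate_replicates
from spotfit.synthetic_data import (
    ArrayLayout,
    BindingModelParams,
    bound_complex_concentration,
    detection_transform,
    simulate_from_surface,
)

from conftest import make_surface_table


def _table_from_params(p: RichardsParams, x=None):
    if x is None:
        x = np.linspace(p.x_i - 3, p.x_i + 3, 12)
    return BindingTable.from_arrays(x, eval_ln_richards(x, p)), x


class TestJacobians:
    @pytest.mark.parametrize("fix_k", [True, False])
    def test_1d_jacobian_matches_finite_differences(self, fix_k):
        x = np.linspace(-13, -7, 9)
        theta = np.array([9.2, -10.3, 0.4, 0.1][: 3 if fix_k else 4])
        f0, J = _eval_1d(theta, x, fix_k)
        h = 1e-7
        for j in range(theta.size):
            tp, tm = theta.copy(), theta.copy()
            tp[j] += h
            tm[j] -= h
            fd = (_eval_1d(tp, x, fix_k)[0] - _eval_1d(tm, x, fix_k)[0]) / (2 * h)
            np.testing.assert_allclose(J[:, j], fd, rtol=1e-5, atol=1e-7)

    def test_2d_jacobian_matches_finite_differences(self):
        x = np.tile(np.linspace(-12, -8, 6), 3)
        z = np.repeat([100.0, 300.0, 900.0], 6)
        theta = np.array([10.5, -0.2, 3.9, -10.2, 0.7])
        f0, J = _eval_2d(theta, x, z)
        h = 1e-7
        for j in range(5):
            tp, tm = theta.copy(), theta.copy()
            tp[j] += h
            tm[j] -= h
            fd = (_eval_2d(tp, x, z)[0] - _eval_2d(tm, x, z)[0]) / (2 * h)
            np.testing.assert_allclose(J[:, j], fd, rtol=1e-5, atol=1e-7)


class TestInitialGuess:
    def test_deterministic_under_permutation(self, noiseless_surface_table):
        tbl = noiseless_surface_table
        shuffled = BindingTable(
            frame=tbl.frame.sample(frac=1.0, random_state=0).reset_index(
                drop=True
            ),
            background=tbl.background,
        )
        np.testing.assert_array_equal(
            initial_guess(tbl, "r2_2d"), initial_guess(shuffled, "r2_2d")
        )

    def test_initial_sse_beats_flat_model(self, noiseless_surface_table):
        from spotfit.fitting import _eval_2d, _fittable_xyz

        tbl = noiseless_surface_table
        x, z, y = _fittable_xyz(tbl, "IgG")
        theta0 = initial_guess(tbl, "r2_2d")
        f0, _ = _eval_2d(theta0, x, z)
        sse0 = float(((y - f0) ** 2).sum())
        sse_flat = float(((y - y.mean()) ** 2).sum())
        assert math.isfinite(sse0) and sse0 < sse_flat

    def test_one_dilution_rejected_for_2d(self):
        x = np.linspace(-12, -8, 6)
        tbl = BindingTable.from_arrays(x, x * 0.5, z=100.0)
        with pytest.raises(InsufficientDataError, match="dilution"):
            initial_guess(tbl, "r2_2d")

    def test_too_few_points_rejected_for_1d(self):
        tbl = BindingTable.from_arrays([-10, -9, -8], [1.0, 2.0, 3.0])
        with pytest.raises(InsufficientDataError, match="4"):
            initial_guess(tbl, "richards_1d")


class TestFitRichards1D:
    def test_noiseless_parameter_recovery(self):
        true = RichardsParams(A=1e4, x_i=-10.5, d=1.6)
        tbl, _ = _table_from_params(true)
        fit = fit_richards_1d(tbl)
        assert fit.converged
        assert fit.params.A == pytest.approx(true.A, rel=1e-6)
        assert fit.params.x_i == pytest.approx(true.x_i, abs=1e-6)
        assert fit.params.d == pytest.approx(true.d, rel=1e-6)

    def test_free_k_on_binding_model_returns_unit_rate(self):
        # the binding equation forces growth rate 1: a free-k fit to
        # noiseless detection-transformed data must say k = 1
        p = BindingModelParams(ab_conc=1e-8, kd=1e-8, d_const=1e6, alpha=1e9)
        xm = p.midpoint_x()
        x = np.linspace(xm - 8, xm + 8, 60)
        sig = detection_transform(
            bound_complex_concentration(np.exp(x), p.ab_conc, p.kd, p.d_const),
            p.alpha,
        )
        tbl = BindingTable.from_arrays(x, np.log(sig))
        fit = fit_richards_1d(tbl, fix_k=False)
        assert fit.converged
        assert fit.params.k == pytest.approx(1.0, abs=1e-3)

    def test_constant_signal_no_crash(self):
        x = np.linspace(-12, -8, 8)
        tbl = BindingTable.from_arrays(x, np.full_like(x, 3.0))
        fit = fit_richards_1d(tbl)
        assert not fit.converged or fit.sse <= 1e-12 or fit.flags

    def test_multiple_dilutions_rejected(self, noiseless_surface_table):
        with pytest.raises(InsufficientDataError, match="single dilution"):
            fit_richards_1d(noiseless_surface_table, channel="IgG")

    def test_grid_search_oracle_equivalence(self):
        # dense grid search over (ln A, x_i, d) cannot beat Gauss-Newton
        true = RichardsParams(A=2e3, x_i=-10.0, d=1.4)
        x = np.linspace(-12.5, -8.0, 8)
        rng = np.random.default_rng(3)
        y = eval_ln_richards(x, true) + rng.normal(0, 0.05, x.size)
        tbl = BindingTable.from_arrays(x, y)
        fit = fit_richards_1d(tbl)
        assert fit.converged

        best = math.inf
        for ln_a, xi, d in itertools.product(
            np.linspace(math.log(true.A) - 0.5, math.log(true.A) + 0.5, 40),
            np.linspace(-11.0, -9.0, 60),
            np.linspace(1.05, 2.0, 40),
        ):
            p = RichardsParams(A=math.exp(ln_a), x_i=xi, d=d)
            sse = float(((y - eval_ln_richards(x, p)) ** 2).sum())
            best = min(best, sse)
        assert fit.sse <= best * (1 + 1e-4)


class TestFitR2:
    def test_noiseless_surface_recovery(self, noiseless_surface_table,
                                        surface_truth):
        fit = fit_r2_2d(noiseless_surface_table, channel="IgG")
        assert fit.converged
        q = fit.params
        assert q.C == pytest.approx(surface_truth.C, rel=1e-6)
        assert q.B == pytest.approx(surface_truth.B, rel=1e-6)
        assert q.m == pytest.approx(surface_truth.m, rel=1e-6)
        assert q.x_i == pytest.approx(surface_truth.x_i, abs=1e-6)
        assert q.d == pytest.approx(surface_truth.d, rel=1e-6)

    def test_monte_carlo_recovery_median(self, igg_layout, surface_truth):
        # median absolute error over 50 noisy replicates within 0.1 for
        # both x_i and d at noise 0.1
        err_xi, err_d = [], []
        for seed in range(1, 51):
            tbl = make_surface_table(igg_layout, surface_truth, 0.1, seed)
            fit = fit_r2_2d(tbl, channel="IgG")
            assert fit.converged
            err_xi.append(abs(fit.params.x_i - surface_truth.x_i))
            err_d.append(abs(fit.params.d - surface_truth.d))
        assert np.median(err_xi) <= 0.1
        assert np.median(err_d) <= 0.1

    def test_xi_out_of_range_flagged(self, igg_layout):
        truth = TwoDimParams(C=5e4, B=50.0, m=1.0, x_i=-7.0, d=1.7)
        tbl = make_surface_table(igg_layout, truth, 0.0, seed=1)
        fit = fit_r2_2d(tbl, channel="IgG")
        assert "xi_out_of_range" in fit.flags

    def test_basin_stability_from_perturbed_inits(self, noiseless_surface_table):
        base = fit_r2_2d(noiseless_surface_table, channel="IgG")
        theta0 = initial_guess(noiseless_surface_table, "r2_2d")
        rng = np.random.default_rng(11)
        for _ in range(10):
            init = theta0 + rng.normal(0, 0.2, theta0.size)
            fit = fit_r2_2d(noiseless_surface_table, init=init, channel="IgG")
            assert fit.converged
            assert fit.sse <= max(base.sse, 1e-20) * (1 + 1e-6) + 1e-12

    def test_scale_invariance_of_shape_parameters(self, igg_layout,
                                                  surface_truth):
        # multiplying all raw intensities by a constant shifts only ln C
        from spotfit.preprocess import aggregate_replicates
        from spotfit.synthetic_data import SpotTable

        spots = simulate_from_surface(igg_layout, surface_truth, 0.1, seed=4)
        fit1 = fit_r2_2d(aggregate_replicates(spots), channel="IgG")
        scaled_frame = spots.frame.copy()
        scaled_frame["rfi"] *= 137.0
        fit2 = fit_r2_2d(
            aggregate_replicates(SpotTable(frame=scaled_frame)), channel="IgG"
        )
        assert fit2.params.x_i == pytest.approx(fit1.params.x_i, abs=1e-6)
        assert fit2.params.d == pytest.approx(fit1.params.d, abs=1e-6)
        assert fit2.params.C == pytest.approx(fit1.params.C * 137.0, rel=1e-4)

    def test_serialization(self, noiseless_surface_table):
        import json

        fit = fit_r2_2d(noiseless_surface_table, channel="IgG")
        data = json.loads(fit.to_json())
        assert data["model_kind"] == "r2_2d"
        assert data["converged"] is True
        assert set(data["estimates"]) == {"C", "B", "m", "x_i", "d"}


class TestProfileCI:
    def test_noiseless_intervals_collapse(self, noiseless_surface_table):
        fit = fit_r2_2d(noiseless_surface_table, channel="IgG")
        fit = profile_confidence_intervals(fit, noiseless_surface_table,
                                           channel="IgG")
        for name, ci in fit.ci.items():
            assert ci.missing_reason is None
            assert ci.upper - ci.lower < 1e-3

    def test_intervals_bracket_estimates(self, igg_layout, surface_truth):
        tbl = make_surface_table(igg_layout, surface_truth, 0.1, seed=2)
        fit = fit_r2_2d(tbl, channel="IgG")
        fit = profile_confidence_intervals(fit, tbl, channel="IgG")
        est = {
            "C": fit.params.C, "B": fit.params.B, "m": fit.params.m,
            "x_i": fit.params.x_i, "d": fit.params.d,
        }
        for name, ci in fit.ci.items():
            if ci.missing_reason is None:
                assert ci.lower <= est[name] <= ci.upper

    def test_d_truncation_near_boundary(self, igg_layout):
        # truth at the symmetric (d = 2) edge: the upper bound of d is
        # truncated at the domain boundary and flagged
        truth = TwoDimParams(C=5e4, B=50.0, m=1.0, x_i=-10.4, d=1.999)
        tbl = make_surface_table(igg_layout, truth, 0.05, seed=6)
        fit = fit_r2_2d(tbl, channel="IgG")
        fit = profile_confidence_intervals(fit, tbl, parameters=["d"],
                                           channel="IgG")
        ci = fit.ci["d"]
        assert ci.missing_reason is None
        assert ci.truncated_upper
        assert ci.upper <= 2.0

    def test_calibration_options_nest(self, igg_layout, surface_truth):
        # chi-square intervals are narrower than (nested inside) F intervals
        tbl = make_surface_table(igg_layout, surface_truth, 0.15, seed=3)
        fit = fit_r2_2d(tbl, channel="IgG")
        fit_f = profile_confidence_intervals(
            fit, tbl, parameters=["x_i"], channel="IgG", calibration="f"
        )
        fit_c = profile_confidence_intervals(
            fit, tbl, parameters=["x_i"], channel="IgG", calibration="chisq"
        )
        ci_f, ci_c = fit_f.ci["x_i"], fit_c.ci["x_i"]
        assert ci_f.lower <= ci_c.lower <= ci_c.upper <= ci_f.upper
        # widths differ by a modest calibration factor, not qualitatively
        width_f = ci_f.upper - ci_f.lower
        width_c = ci_c.upper - ci_c.lower
        assert 0.75 < width_c / width_f < 1.0
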