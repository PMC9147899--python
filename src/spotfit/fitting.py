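"""Nonlinear least-squares fitting of the Richards models.

Both the single-curve model (ln signal vs ln antigen concentration) and the
two-dimensional product model (antigen x dilution surface) are fitted by a
Gauss-Newton iteration with step-halving line search and Levenberg damping
on rank deficiency, minimizing the residual sum of squares on the ln scale.

Parameters are estimated on an internal unconstrained scale —
d = 1 + expit(eta) keeps the asymmetry in (1, 2), while C, B, m, A, k are
log-transformed — and reported on the natural scale.  Confidence intervals
use the profile-likelihood technique: each natural parameter is fixed on a
grid, the remaining parameters are refitted, and the interval bounds are
located where n*ln(SSE_profile/SSE_min) crosses the calibration quantile
(small-sample F-based by default, asymptotic chi-square(1) optionally).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence, Union

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logit
from scipy.stats import chi2, f as f_dist

from .model_core import RichardsParams, TwoDimParams
from .preprocess import BindingTable

logger = logging.getLogger(__name__)

__all__ = [
    "FitResult",
    "ProfileCI",
    "FittingError",
    "InsufficientDataError",
    "initial_guess",
    "fit_richards_1d",
    "fit_r2_2d",
    "profile_confidence_intervals",
]

MAX_ITER = 200
SSE_RTOL = 1e-10
_D_LO = 1.0 + 1e-9
_D_HI = 2.0 - 1e-9


class FittingError(RuntimeError):
    pass


class InsufficientDataError(FittingError):
    pass


@dataclass(frozen=True)
class ProfileCI:
    """Profile-likelihood confidence bounds for one natural parameter."""

    lower: float
    upper: float
    level: float
    truncated_lower: bool = False
    truncated_upper: bool = False
    missing_reason: Optional[str] = None

    def to_dict(self) -> dict:
        return {
            "lower": self.lower,
            "upper": self.upper,
            "level": self.level,
            "truncated_lower": self.truncated_lower,
            "truncated_upper": self.truncated_upper,
            "missing_reason": self.missing_reason,
        }


@dataclass
class FitResult:
    """Estimates, diagnostics and (optionally) profile CIs for one fit."""

    model_kind: str  # "richards_1d" | "r2_2d"
    params: Union[RichardsParams, TwoDimParams]
    k_fixed: bool
    sse: float
    n_obs: int
    converged: bool
    n_iter: int
    residuals: np.ndarray
    flags: tuple = ()
    ci: dict = field(default_factory=dict)
    message: str = ""
    # internal state used by the profiler (not serialized)
    _theta: Optional[np.ndarray] = field(default=None, repr=False)
    _jac: Optional[np.ndarray] = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "model_kind": self.model_kind,
            "estimates": self.params.to_dict(),
            "k_fixed": self.k_fixed,
            "sse": self.sse,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "flags": list(self.flags),
            "ci": {k: v.to_dict() for k, v in self.ci.items()},
            "message": self.message,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


# ---------------------------------------------------------------------------
# internal parameterization
#
# richards_1d, k fixed : theta = (ln_A, x_i, eta)           d = 1 + expit(eta)
# richards_1d, k free  : theta = (ln_A, x_i, eta, ln_k)
# r2_2d                : theta = (ln_C, ln_m, ln_B, x_i, eta)
# ---------------------------------------------------------------------------


def _shape_and_grads(x: np.ndarray, x_i: float, d: float, k: float):
    """Shape term L/(1-d) with L = log(1 + (d-1)e^{-k(x-x_i)}) and pieces
    needed for analytic derivatives (sig = (d-1)e^u / (1 + (d-1)e^u))."""
    t = math.log(d - 1.0) - k * (x - x_i)
    L = np.logaddexp(0.0, t)
    sig = expit(t)
    shape = L / (1.0 - d)
    return shape, L, sig


#: clamp for internal coordinates so trial steps can never leave the domain
#: representable in floats (expit under/overflow, exp overflow)
_ETA_MAX = 30.0
_LOG_MAX = 40.0


def _eval_1d(theta: np.ndarray, x: np.ndarray, fix_k: bool):
    ln_A, x_i = theta[0], theta[1]
    eta = float(np.clip(theta[2], -_ETA_MAX, _ETA_MAX))
    k = 1.0 if fix_k else math.exp(float(np.clip(theta[3], -_LOG_MAX, _LOG_MAX)))
    d = 1.0 + expit(eta)
    shape, L, sig = _shape_and_grads(x, x_i, d, k)
    f = ln_A + shape

    n = x.size
    p = 3 if fix_k else 4
    J = np.empty((n, p))
    J[:, 0] = 1.0
    J[:, 1] = -k * sig / (d - 1.0)
    dln_dd = (L - sig) / (d - 1.0) ** 2
    J[:, 2] = dln_dd * (d - 1.0) * (2.0 - d)  # chain rule through expit
    if not fix_k:
        J[:, 3] = (x - x_i) * sig / (d - 1.0) * k
    return f, J


def _eval_2d(theta: np.ndarray, x: np.ndarray, z: np.ndarray):
    ln_C, ln_m, ln_B, x_i, eta = theta
    eta = float(np.clip(eta, -_ETA_MAX, _ETA_MAX))
    m = math.exp(float(np.clip(ln_m, -_LOG_MAX, _LOG_MAX)))
    B = math.exp(float(np.clip(ln_B, -_LOG_MAX, _LOG_MAX)))
    d = 1.0 + expit(eta)
    shape, L, sig = _shape_and_grads(x, x_i, d, 1.0)
    lbz = np.log(B + z)
    f = ln_C - m * lbz + shape

    J = np.empty((x.size, 5))
    J[:, 0] = 1.0
    J[:, 1] = -m * lbz  # d/d ln_m
    J[:, 2] = -m * B / (B + z)  # d/d ln_B
    J[:, 3] = -sig / (d - 1.0)
    dln_dd = (L - sig) / (d - 1.0) ** 2
    J[:, 4] = dln_dd * (d - 1.0) * (2.0 - d)
    return f, J


def _gauss_newton(
    fun_jac: Callable,
    theta0: np.ndarray,
    y: np.ndarray,
    free: Optional[np.ndarray] = None,
    max_iter: int = MAX_ITER,
    rtol: float = SSE_RTOL,
):
    """Gauss-Newton with step-halving; Levenberg damping on rank deficiency.

    ``free`` is a boolean mask of coordinates allowed to move (used by the
    profiler to fix one parameter).  Returns (theta, sse, n_iter, converged,
    flags, J_full) where J_full is the Jacobian at the solution.
    """
    theta = np.array(theta0, dtype=float)
    if free is None:
        free = np.ones(theta.size, dtype=bool)
    flags = set()

    f, J = fun_jac(theta)
    r = y - f
    sse = float(r @ r)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        Jf = J[:, free]
        # GN step: minimize ||Jf*delta - r||
        delta, _, rank, _ = np.linalg.lstsq(Jf, r, rcond=None)
        if rank < Jf.shape[1] or not np.all(np.isfinite(delta)):
            flags.add("damped")
            JtJ = Jf.T @ Jf
            lam = 1e-6 * max(np.trace(JtJ) / Jf.shape[1], 1e-12)
            for _ in range(20):
                try:
                    delta = np.linalg.solve(
                        JtJ + lam * np.eye(Jf.shape[1]), Jf.T @ r
                    )
                except np.linalg.LinAlgError:
                    delta = None
                if delta is not None and np.all(np.isfinite(delta)):
                    break
                lam *= 10.0
            if delta is None or not np.all(np.isfinite(delta)):
                return theta, sse, it, False, flags | {"singular"}, J

        # step halving line search
        alpha = 1.0
        improved = False
        for _ in range(50):
            trial = theta.copy()
            trial[free] += alpha * delta
            ft, Jt = fun_jac(trial)
            rt = y - ft
            sset = float(rt @ rt)
            if np.isfinite(sset) and sset <= sse:
                improved = True
                break
            alpha *= 0.5
        if not improved:
            # cannot decrease along the GN direction: accept as converged when
            # the gradient is (relatively) tiny, else report non-convergence
            grad = 2.0 * (Jf.T @ r)
            gscale = max(sse, 1e-300)
            converged = sse == 0.0 or float(np.linalg.norm(grad)) <= 1e-6 * (
                1.0 + gscale
            )
            break
        rel_drop = (sse - sset) / max(sse, 1e-300)
        theta, f, J, r, sse = trial, ft, Jt, rt, sset
        if rel_drop < rtol:
            converged = True
            break
    return theta, sse, it, converged, flags, J


def _safe_exp(v: float) -> float:
    return math.exp(float(np.clip(v, -_LOG_MAX, _LOG_MAX)))


def _safe_d(eta: float) -> float:
    d = 1.0 + float(expit(np.clip(eta, -_ETA_MAX, _ETA_MAX)))
    return min(max(d, _D_LO), 2.0)


def _theta_to_params_1d(theta: np.ndarray, fix_k: bool) -> RichardsParams:
    k = 1.0 if fix_k else _safe_exp(theta[3])
    return RichardsParams(
        A=_safe_exp(theta[0]), x_i=float(theta[1]), d=_safe_d(theta[2]), k=k
    )


def _theta_to_params_2d(theta: np.ndarray) -> TwoDimParams:
    return TwoDimParams(
        C=_safe_exp(theta[0]),
        m=_safe_exp(theta[1]),
        B=_safe_exp(theta[2]),
        x_i=float(theta[3]),
        d=_safe_d(theta[4]),
    )


def _fittable_xyz(tbl: BindingTable, channel: Optional[str] = None):
    fit_rows = tbl.fittable(channel)
    if len(fit_rows) == 0:
        raise InsufficientDataError("no fittable rows")
    channels = list(dict.fromkeys(fit_rows["channel"]))
    if len(channels) > 1:
        raise InsufficientDataError(
            f"table holds channels {channels}; select one with channel="
        )
    x = fit_rows["x"].to_numpy(dtype=float)
    z = fit_rows["z"].to_numpy(dtype=float)
    y = fit_rows["ln_signal"].to_numpy(dtype=float)
    return x, z, y


def initial_guess(tbl: BindingTable, model_kind: str,
                  channel: Optional[str] = None) -> np.ndarray:
    """Deterministic starting values on the internal scale.

    x_i starts at the x where the least-diluted curve crosses half of its
    ln-signal range, d at 1.5 (eta = 0), m at 1, B at min(z), and the scale
    so the model plateau matches the maximal observed signal.
    """
    x, z, y = _fittable_xyz(tbl, channel)
    order = np.lexsort((x, z))
    x, z, y = x[order], z[order], y[order]

    if model_kind == "richards_1d":
        n_x = np.unique(x).size
        if n_x < 4:
            raise InsufficientDataError(
                f"richards_1d needs >= 4 distinct antigen concentrations "
                f"with finite signal, got {n_x}"
            )
        xi0 = _half_range_x(x, y)
        return np.array([y.max() + 0.1, xi0, 0.0])

    if model_kind == "r2_2d":
        n_z = np.unique(z).size
        n_x = np.unique(x).size
        if n_z < 2 or n_x < 4:
            raise InsufficientDataError(
                f"r2_2d needs >= 2 dilutions and >= 4 antigen concentrations, "
                f"got {n_z} dilution(s) x {n_x} concentration(s)"
            )
        z_min = z.min()
        mask = z == z_min
        xi0 = _half_range_x(x[mask], y[mask])
        m0, B0 = 1.0, z_min
        ln_C0 = y.max() + m0 * math.log(B0 + z_min)
        return np.array([ln_C0, math.log(m0), math.log(B0), xi0, 0.0])

    raise ValueError(f"unknown model_kind {model_kind!r}")


def _half_range_x(x: np.ndarray, y: np.ndarray) -> float:
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    target = 0.5 * (ys.min() + ys.max())
    return float(np.interp(target, ys, xs)) if ys[-1] > ys[0] else float(
        np.median(xs)
    )


def _range_flags(x: np.ndarray, x_i: float) -> tuple:
    if not (x.min() <= x_i <= x.max()):
        return ("xi_out_of_range",)
    return ()


def fit_richards_1d(
    curve: BindingTable,
    fix_k: bool = True,
    init: Optional[Sequence[float]] = None,
    channel: Optional[str] = None,
    max_iter: int = MAX_ITER,
) -> FitResult:
    """Fit the single-curve log-Richards model to one titration curve.

    ``curve`` must hold one channel (and a single dilution series); requires
    >= 4 distinct x with finite ln_signal (>= 5 when k is free).  Returns a
    FitResult; non-convergence is reported via ``converged=False``, never
    silently.
    """
    x, z, y = _fittable_xyz(curve, channel)
    if np.unique(z).size > 1:
        raise InsufficientDataError(
            "richards_1d expects a single dilution; use fit_r2_2d for surfaces"
        )
    n_x = np.unique(x).size
    need = 5 if not fix_k else 4
    if n_x < need:
        raise InsufficientDataError(
            f"need >= {need} distinct concentrations (fix_k={fix_k}), got {n_x}"
        )

    if init is None:
        theta0 = initial_guess(curve, "richards_1d", channel)
        if not fix_k:
            theta0 = np.append(theta0, 0.0)
    else:
        theta0 = np.asarray(init, dtype=float)

    fun_jac = lambda th: _eval_1d(th, x, fix_k)
    theta, sse, n_iter, converged, flags, J = _gauss_newton(
        fun_jac, theta0, y, max_iter=max_iter
    )
    params = _theta_to_params_1d(theta, fix_k)
    f, _ = fun_jac(theta)
    all_flags = tuple(sorted(flags)) + _range_flags(x, params.x_i)
    if not converged:
        logger.warning("richards_1d did not converge after %d iterations", n_iter)
    return FitResult(
        model_kind="richards_1d",
        params=params,
        k_fixed=fix_k,
        sse=sse,
        n_obs=x.size,
        converged=converged,
        n_iter=n_iter,
        residuals=y - f,
        flags=all_flags,
        message="" if converged else "maximum iterations or stalled line search",
        _theta=theta,
        _jac=J,
    )


def fit_r2_2d(
    tbl: BindingTable,
    init: Optional[Sequence[float]] = None,
    channel: Optional[str] = None,
    max_iter: int = MAX_ITER,
) -> FitResult:
    """Fit the two-dimensional product model to a full antigen x dilution grid.

    A single (x_i, d) pair is shared across all dilutions.  When the fitted
    x_i falls outside the measured x range the result carries the
    ``xi_out_of_range`` flag and should not be reported as a reliable
    inflection estimate.
    """
    x, z, y = _fittable_xyz(tbl, channel)
    n_z, n_x = np.unique(z).size, np.unique(x).size
    if n_z < 2 or n_x < 4:
        raise InsufficientDataError(
            f"r2_2d needs >= 2 dilutions and >= 4 concentrations, "
            f"got {n_z} x {n_x}"
        )
    theta0 = (
        np.asarray(init, dtype=float)
        if init is not None
        else initial_guess(tbl, "r2_2d", channel)
    )
    fun_jac = lambda th: _eval_2d(th, x, z)
    theta, sse, n_iter, converged, flags, J = _gauss_newton(
        fun_jac, theta0, y, max_iter=max_iter
    )
    params = _theta_to_params_2d(theta)
    f, _ = fun_jac(theta)
    all_flags = tuple(sorted(flags)) + _range_flags(x, params.x_i)
    if not converged:
        logger.warning("r2_2d did not converge after %d iterations", n_iter)
    return FitResult(
        model_kind="r2_2d",
        params=params,
        k_fixed=True,
        sse=sse,
        n_obs=x.size,
        converged=converged,
        n_iter=n_iter,
        residuals=y - f,
        flags=all_flags,
        message="" if converged else "maximum iterations or stalled line search",
        _theta=theta,
        _jac=J,
    )


# ---------------------------------------------------------------------------
# profile-likelihood confidence intervals
# ---------------------------------------------------------------------------

#: natural-parameter name -> (theta index, to_internal, from_internal, domain)
def _profile_spec(fit: FitResult):
    if fit.model_kind == "richards_1d":
        spec = {
            "A": (0, math.log, _safe_exp, (0.0, math.inf)),
            "x_i": (1, lambda v: v, lambda v: v, (-math.inf, math.inf)),
            "d": (
                2,
                lambda v: float(logit(v - 1.0)),
                lambda v: 1.0 + float(expit(v)),
                (_D_LO, _D_HI),
            ),
        }
        if not fit.k_fixed:
            spec["k"] = (3, math.log, _safe_exp, (0.0, math.inf))
        return spec
    if fit.model_kind == "r2_2d":
        return {
            "C": (0, math.log, _safe_exp, (0.0, math.inf)),
            "m": (1, math.log, _safe_exp, (0.0, math.inf)),
            "B": (2, math.log, _safe_exp, (0.0, math.inf)),
            "x_i": (3, lambda v: v, lambda v: v, (-math.inf, math.inf)),
            "d": (
                4,
                lambda v: float(logit(v - 1.0)),
                lambda v: 1.0 + float(expit(v)),
                (_D_LO, _D_HI),
            ),
        }
    raise ValueError(fit.model_kind)


def _natural_estimates(fit: FitResult) -> dict:
    p = fit.params
    if fit.model_kind == "richards_1d":
        out = {"A": p.A, "x_i": p.x_i, "d": p.d}
        if not fit.k_fixed:
            out["k"] = p.k
        return out
    return {"C": p.C, "m": p.m, "B": p.B, "x_i": p.x_i, "d": p.d}


def profile_confidence_intervals(
    fit: FitResult,
    tbl: BindingTable,
    level: float = 0.95,
    parameters: Optional[Sequence[str]] = None,
    channel: Optional[str] = None,
    calibration: str = "f",
) -> FitResult:
    """Attach profile-likelihood CIs to a converged fit.

    For each natural parameter theta_j the profile SSE is obtained by fixing
    theta_j and refitting the others; the CI bounds are located where the
    likelihood-ratio statistic ``n * ln(SSE_profile / SSE_min)`` crosses the
    calibration quantile (outward step doubling plus Brent root bracketing).

    calibration: "f" (default) matches the exact small-sample profile-t
    criterion of Gaussian nonlinear regression, with threshold
    ``n * ln(1 + F(1, n-p; level)/(n-p))``; "chisq" uses the asymptotic
    chi-square(1) quantile (3.841 at 95%), which is slightly narrower.
    Bounds that run into the parameter domain edge are truncated and flagged.
    """
    if not fit.converged:
        raise FittingError("profiling requires a converged fit")
    x, z, y = _fittable_xyz(tbl, channel)
    if fit.model_kind == "richards_1d":
        fun_jac = lambda th: _eval_1d(th, x, fit.k_fixed)
    else:
        fun_jac = lambda th: _eval_2d(th, x, z)

    spec = _profile_spec(fit)
    estimates = _natural_estimates(fit)
    names = list(spec) if parameters is None else list(parameters)
    n = fit.n_obs
    sse0 = max(fit.sse, 1e-300)
    n_par = fit._theta.size
    if calibration == "chisq":
        q = float(chi2.ppf(level, 1))
    elif calibration == "f":
        dof = max(n - n_par, 1)
        q = n * math.log(1.0 + float(f_dist.ppf(level, 1, dof)) / dof)
    else:
        raise ValueError(f"unknown calibration {calibration!r}")
    theta_hat = fit._theta

    # internal-scale standard errors from the GN Jacobian set the step scale
    J = fit._jac
    try:
        cov = np.linalg.pinv(J.T @ J) * sse0 / max(n - theta_hat.size, 1)
        se_int = np.sqrt(np.clip(np.diag(cov), 1e-12, None))
    except np.linalg.LinAlgError:
        se_int = np.full(theta_hat.size, 0.1)

    ci_out = dict(fit.ci)
    for name in names:
        idx, to_int, from_int, (lo_dom, hi_dom) = spec[name]
        est = estimates[name]
        free = np.ones(theta_hat.size, dtype=bool)
        free[idx] = False

        def g(val_int: float, _idx=idx, _free=free) -> float:
            th = theta_hat.copy()
            th[_idx] = val_int
            _, sse_p, _, _, _, _ = _gauss_newton(fun_jac, th, y, free=_free)
            return n * math.log(max(sse_p, 1e-300) / sse0) - q

        try:
            center = theta_hat[idx]
            step0 = max(se_int[idx], 1e-6)
            bounds = []
            truncs = []
            for sign in (-1.0, +1.0):
                step = step0
                prev = center
                bound_int = None
                truncated = False
                for _ in range(80):
                    cand = center + sign * step
                    # respect the internal-domain image of the natural domain
                    nat = from_int(cand)
                    if not (lo_dom < nat < hi_dom) or not math.isfinite(nat):
                        truncated = True
                        bound_int = cand
                        break
                    if g(cand) >= 0.0:
                        bound_int = brentq(g, min(prev, cand), max(prev, cand),
                                           xtol=1e-8, rtol=1e-10)
                        break
                    prev = cand
                    step *= 2.0
                if bound_int is None:
                    truncated = True
                    bound_int = prev
                if truncated:
                    nat_bound = from_int(bound_int)
                    nat_bound = min(max(nat_bound, lo_dom), hi_dom)
                else:
                    nat_bound = from_int(bound_int)
                bounds.append(nat_bound)
                truncs.append(truncated)
            lower, upper = bounds
            t_lo, t_hi = truncs
            if lower > upper:  # non-monotone transform safety net
                lower, upper = upper, lower
                t_lo, t_hi = t_hi, t_lo
            ci_out[name] = ProfileCI(
                lower=lower,
                upper=upper,
                level=level,
                truncated_lower=t_lo,
                truncated_upper=t_hi,
            )
        except Exception as exc:  # profiling failure must not kill the others
            logger.warning("profiling %s failed: %s", name, exc)
            ci_out[name] = ProfileCI(
                lower=math.nan,
                upper=math.nan,
                level=level,
                missing_reason=str(exc),
            )

    return replace(fit, ci=ci_out)
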