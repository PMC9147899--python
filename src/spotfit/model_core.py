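"""Richards (generalized logistic) growth curves and the two-dimensional
antigen x dilution product model.

All evaluation happens on the natural-log scale: ``x`` is the natural log of
the molar antigen concentration (200 uM -> ``x = ln(2e-4) ~ -8.517``) and
``z`` is the fold-dilution of the sample (a 1:100 dilution is ``z = 100``).

The single-curve model is

    R(x) = A * (1 + (d - 1) * exp(-k*(x - x_i)))**(1/(1-d))

which is the ordinary logistic curve at ``d = 2`` and tends to the Gompertz
curve ``A * exp(-exp(-k*(x - x_i)))`` as ``d -> 1+``.  The two-dimensional
surface replaces the plateau ``A`` with a dilution-dependent plateau
``A(z) = C * (B + z)**(-m)`` and fixes the growth rate at 1.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Union

import numpy as np

__all__ = [
    "RichardsParams",
    "TwoDimParams",
    "ActivityCurve",
    "eval_richards",
    "eval_ln_richards",
    "eval_ln_r2",
    "activity_coefficient_curve",
    "limiting_slope",
]

#: below this distance from 1, evaluate d via the Gompertz closed form to
#: avoid catastrophic cancellation in the 1/(1-d) exponent.
GOMPERTZ_TOL = 1e-6

ArrayLike = Union[float, np.ndarray]


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass(frozen=True)
class RichardsParams:
    """Parameters of a single Richards curve.

    Attributes
    ----------
    A : float
        Upper asymptote (signal units), > 0.
    x_i : float
        Inflection location on the ln-molar-antigen axis.
    d : float
        Asymmetry parameter, > 1.  Fits constrain ``d`` to (1, 2]; evaluation
        is defined for any ``d > 1``.
    k : float
        Growth rate, > 0 (default 1, the value forced by the binding model).
    """

    A: float
    x_i: float
    d: float
    k: float = 1.0

    def __post_init__(self) -> None:
        _require(self.A > 0, f"A must be > 0, got {self.A}")
        _require(self.k > 0, f"k must be > 0, got {self.k}")
        _require(self.d > 1, f"d must be > 1, got {self.d}")
        _require(np.isfinite(self.x_i), f"x_i must be finite, got {self.x_i}")

    @property
    def slope_at_minus_infinity(self) -> float:
        return limiting_slope(self.k, self.d)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RichardsParams":
        return cls(**data)


@dataclass(frozen=True)
class TwoDimParams:
    """Parameters of the two-dimensional product model.

    The surface is ``ln R2(x, z) = ln C - m*ln(B + z) + ln_shape(x; x_i, d)``
    with growth rate fixed at 1; the effective plateau at dilution ``z`` is
    ``A(z) = C * (B + z)**(-m)``, strictly decreasing in ``z``.
    """

    C: float
    B: float
    m: float
    x_i: float
    d: float

    def __post_init__(self) -> None:
        _require(self.C > 0, f"C must be > 0, got {self.C}")
        _require(self.B > 0, f"B must be > 0, got {self.B}")
        _require(self.m > 0, f"m must be > 0, got {self.m}")
        _require(self.d > 1, f"d must be > 1, got {self.d}")
        _require(np.isfinite(self.x_i), f"x_i must be finite, got {self.x_i}")

    def plateau(self, z: ArrayLike) -> ArrayLike:
        """Effective upper asymptote A(z) = C*(B+z)**(-m)."""
        return self.C * (self.B + np.asarray(z, dtype=float)) ** (-self.m)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "TwoDimParams":
        return cls(**data)


@dataclass(frozen=True)
class ActivityCurve:
    """Concentration-normalized binding curve gamma(x) in (0, 1].

    gamma depends only on the shape parameters (k, x_i, d), never on the
    plateau/scale parameters, so curves from different samples, isotypes or
    intensity scales overlay directly.
    """

    x_grid: np.ndarray
    gamma: np.ndarray
    x_i: float
    d: float
    k: float = 1.0

    @property
    def limiting_index(self) -> float:
        """d - 1; the shape index reported alongside gamma curves."""
        return self.d - 1.0

    def to_dict(self) -> dict:
        return {
            "x_grid": np.asarray(self.x_grid).tolist(),
            "gamma": np.asarray(self.gamma).tolist(),
            "x_i": self.x_i,
            "d": self.d,
            "k": self.k,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def ln_shape(x: ArrayLike, x_i: float, d: float, k: float = 1.0) -> ArrayLike:
    """Stable evaluation of ``(1/(1-d)) * log(1 + (d-1)*exp(-k*(x - x_i)))``.

    Written as ``logaddexp(0, ln(d-1) - k*(x-x_i)) / (1-d)`` so the linear
    asymptote for ``x << x_i`` (slope ``k/(d-1)``) is exact, with a Gompertz
    branch ``-exp(-k*(x-x_i))`` when ``d`` is within GOMPERTZ_TOL of 1.
    """
    _require(d > 1, f"d must be > 1, got {d}")
    _require(k > 0, f"k must be > 0, got {k}")
    u = -k * (np.asarray(x, dtype=float) - x_i)
    if d - 1.0 < GOMPERTZ_TOL:
        # limit of log1p((d-1)e^u)/(1-d) as d -> 1+; clip keeps exp finite,
        # the true value is astronomically negative there anyway
        out = -np.exp(np.minimum(u, 709.0))
    else:
        out = np.logaddexp(0.0, np.log(d - 1.0) + u) / (1.0 - d)
    if np.ndim(x) == 0:
        return float(out)
    return out


def eval_ln_richards(x: ArrayLike, p: RichardsParams) -> ArrayLike:
    """ln R(x) = ln A + (1/(1-d)) * log(1 + (d-1)*exp(-k*(x - x_i)))."""
    return np.log(p.A) + ln_shape(x, p.x_i, p.d, p.k)


def eval_richards(x: ArrayLike, p: RichardsParams) -> ArrayLike:
    """R(x) = A * (1 + (d-1)*exp(-k*(x - x_i)))**(1/(1-d)).

    Evaluated as exp(ln R) for stability; strictly increasing in x, with
    R(-inf) = 0, R(+inf) = A and R(x_i) = A * d**(1/(1-d)).
    """
    with np.errstate(over="ignore"):
        out = np.exp(eval_ln_richards(x, p))
    if np.ndim(x) == 0:
        return float(out)
    return out


def eval_ln_r2(x: ArrayLike, z: ArrayLike, q: TwoDimParams) -> ArrayLike:
    """ln R2(x, z) = ln C - m*ln(B + z) + shape term (growth rate 1).

    ``z`` is the fold-dilution and must be >= 1.
    """
    z = np.asarray(z, dtype=float)
    if np.any(z < 1):
        raise ValueError("fold-dilution z must be >= 1 (1:100 -> z = 100)")
    out = (
        np.log(q.C)
        - q.m * np.log(q.B + z)
        + ln_shape(x, q.x_i, q.d, k=1.0)
    )
    if np.ndim(x) == 0 and np.ndim(out) == 0:
        return float(out)
    return out


def activity_coefficient_curve(
    x_grid: ArrayLike, x_i: float, d: float, k: float = 1.0
) -> ActivityCurve:
    """Activity-coefficient curve gamma(x) = exp(ln_shape(x; x_i, d, k)).

    This is the Richards curve with unit plateau: gamma in (0, 1], strictly
    increasing, gamma -> 1 as x -> +inf, and gamma(x_i) = d**(1/(1-d))
    (0.5 for the logistic case d = 2).
    """
    x_grid = np.atleast_1d(np.asarray(x_grid, dtype=float))
    _require(np.all(np.isfinite(x_grid)), "x_grid must be finite")
    gamma = np.exp(ln_shape(x_grid, x_i, d, k))
    return ActivityCurve(x_grid=x_grid, gamma=gamma, x_i=x_i, d=d, k=k)


def limiting_slope(k: float, d: float) -> float:
    """Asymptotic slope s = k/(d-1) of ln R(x) as x -> -inf.

    For k = 1 the slope grows from 1 (logistic, d = 2) to infinity as d
    approaches the Gompertz limit d -> 1.
    """
    _require(d > 1, f"d must be > 1, got {d}")
    _require(k > 0, f"k must be > 0, got {k}")
    return k / (d - 1.0)
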