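"""Conventional serum-titration endpoints per antigen density.

Mid-point titer: the fold-dilution at which a per-density logistic fit of
signal vs -ln(z) reaches half of its fitted plateau.  End-point titer: the
highest fold-dilution whose signal stays above a background-derived
threshold (background mean + c*SD), log-linearly interpolated to the
crossing.  Both depend on the antigen density — the behaviour the
two-dimensional fit is designed to avoid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.special import expit

from .preprocess import BindingTable

__all__ = [
    "TiterResult",
    "midpoint_titer",
    "endpoint_titer",
    "titer_vs_density",
]


@dataclass(frozen=True)
class TiterResult:
    """Titers for one (antigen concentration, channel) dilution curve."""

    concentration: float
    channel: str
    midpoint_titer: Optional[float]
    endpoint_titer: Optional[float]
    threshold_rule: str
    midpoint_flags: tuple = ()
    endpoint_flags: tuple = ()
    midpoint_reason: Optional[str] = None
    endpoint_reason: Optional[str] = None
    midpoint_fit: Optional[dict] = None

    def to_dict(self) -> dict:
        return {
            "concentration": self.concentration,
            "channel": self.channel,
            "midpoint_titer": self.midpoint_titer,
            "endpoint_titer": self.endpoint_titer,
            "threshold_rule": self.threshold_rule,
            "midpoint_flags": list(self.midpoint_flags),
            "endpoint_flags": list(self.endpoint_flags),
            "midpoint_reason": self.midpoint_reason,
            "endpoint_reason": self.endpoint_reason,
            "midpoint_fit": self.midpoint_fit,
        }


def _logistic_decay(t, plateau, t0, rate):
    # signal vs t = -ln z; lower asymptote pinned at 0 (background-subtracted)
    return plateau * expit(rate * (t - t0))


def midpoint_titer(
    z: np.ndarray, signal: np.ndarray
) -> Tuple[Optional[float], tuple, Optional[str], Optional[dict]]:
    """Fold-dilution at half the fitted plateau of a dilution curve.

    Fits ``signal = P * expit(r * (t - t0))`` with t = -ln z; the midpoint
    titer is z* = exp(-t0) + (P/2-crossing of the fitted curve).  Returns
    (titer, flags, reason, fit diagnostics); titer is None when undefined.
    """
    z = np.asarray(z, dtype=float)
    signal = np.asarray(signal, dtype=float)
    if z.size < 4:
        return None, (), "fewer than 4 dilutions", None
    order = np.argsort(z)
    z, signal = z[order], signal[order]
    if np.nanmax(signal) <= 0:
        return None, (), "no signal", None
    rng = signal.max() - signal.min()
    if rng <= 0:
        return None, (), "flat curve", None
    # overall the signal must decrease with dilution
    if signal[0] <= signal[-1]:
        return None, (), "signal not decreasing with dilution", None

    t = -np.log(z)
    p_max = signal.max()
    t0_init = float(np.interp(0.5 * p_max, signal[::-1], t[::-1]))
    try:
        popt, _ = curve_fit(
            _logistic_decay,
            t,
            signal,
            p0=(p_max, t0_init, 1.0),
            bounds=([1e-12, -np.inf, 1e-6], [np.inf, np.inf, np.inf]),
            maxfev=10000,
        )
    except (RuntimeError, ValueError) as exc:
        return None, (), f"fit failure: {exc}", None
    plateau, t0, rate = (float(v) for v in popt)
    titer = math.exp(-t0)
    flags = ()
    if not (z.min() <= titer <= z.max()):
        flags = ("extrapolated",)
    diag = {"plateau": plateau, "t0": t0, "rate": rate}
    return titer, flags, None, diag


def endpoint_titer(
    z: np.ndarray,
    signal: np.ndarray,
    background_mean: float,
    background_sd: float,
    c: float = 3.0,
) -> Tuple[Optional[float], tuple, Optional[str], str]:
    """Highest fold-dilution with signal above background mean + c*SD.

    The crossing between the last above-threshold dilution and the next one
    is log-linearly interpolated; if every tested dilution is above the
    threshold the maximum tested z is returned with a "right-censored" flag.
    Returns (titer, flags, reason, rule description).
    """
    rule = f"background_mean + {c:g}*SD (= {background_mean + c * background_sd:.6g})"
    z = np.asarray(z, dtype=float)
    signal = np.asarray(signal, dtype=float)
    order = np.argsort(z)
    z, signal = z[order], signal[order]
    threshold = background_mean + c * background_sd

    above = signal > threshold
    if not above.any():
        return None, (), "no signal above threshold", rule
    i_last = int(np.max(np.nonzero(above)))
    if i_last == z.size - 1:
        return float(z[-1]), ("right-censored",), None, rule

    # log-linear interpolation of the threshold crossing
    z0, z1 = z[i_last], z[i_last + 1]
    s0, s1 = signal[i_last], signal[i_last + 1]
    if threshold > 0 and s1 > 0:
        frac = (math.log(s0) - math.log(threshold)) / (math.log(s0) - math.log(s1))
    else:  # fall back to linear interpolation when logs are unusable
        frac = (s0 - threshold) / (s0 - s1)
    frac = min(max(frac, 0.0), 1.0)
    titer = math.exp(math.log(z0) + frac * (math.log(z1) - math.log(z0)))
    return float(titer), (), None, rule


def titer_vs_density(
    tbl: BindingTable, c: float = 3.0, min_dilutions: int = 4
) -> pd.DataFrame:
    """Mid-point and end-point titers for every (antigen density, channel).

    Operates on the background-subtracted linear signals exp(ln_signal);
    the end-point threshold uses the spot-level background SD pooled per
    channel (the background mean is 0 after subtraction).
    """
    frame = tbl.frame
    if tbl.background is not None:
        bg_sd = tbl.background.groupby("channel")["bg_sd"].mean().to_dict()
    else:
        bg_sd = {}

    results = []
    grouped = frame[~frame["excluded"]].groupby(["channel", "x"], sort=True)
    for (channel, x), g in grouped:
        g = g[np.isfinite(g["ln_signal"])]
        conc = math.exp(x)
        if len(g) < min_dilutions:
            results.append(
                TiterResult(
                    concentration=conc,
                    channel=channel,
                    midpoint_titer=None,
                    endpoint_titer=None,
                    threshold_rule="n/a",
                    midpoint_reason=f"fewer than {min_dilutions} dilutions",
                    endpoint_reason=f"fewer than {min_dilutions} dilutions",
                )
            )
            continue
        z = g["z"].to_numpy(dtype=float)
        sig = np.exp(g["ln_signal"].to_numpy(dtype=float))
        mt, mflags, mreason, mdiag = midpoint_titer(z, sig)
        et, eflags, ereason, rule = endpoint_titer(
            z, sig, background_mean=0.0, background_sd=bg_sd.get(channel, 0.0),
            c=c,
        )
        results.append(
            TiterResult(
                concentration=conc,
                channel=channel,
                midpoint_titer=mt,
                endpoint_titer=et,
                threshold_rule=rule,
                midpoint_flags=mflags,
                endpoint_flags=eflags,
                midpoint_reason=mreason,
                endpoint_reason=ereason,
                midpoint_fit=mdiag,
            )
        )
    if not results:
        raise ValueError("no antigen densities with dilution curves")
    return pd.DataFrame([r.to_dict() for r in results])
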