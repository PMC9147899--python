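"""Simulated antigen-microspot datasets.

Generates spot-level intensity tables with the statistical structure the
downstream analysis assumes: equilibrium immune-complex formation with
steric inhibition, a log-linear fluorescence detection transform, and
multiplicative (lognormal) noise that becomes constant-variance after the
log transform.

The default layout mirrors the physical arrays: seven half serial antigen
dilutions starting from 200 uM printed in quintuplicate, incubated with a
serum dilution series.  The least-concentrated spots act as background:
the simulator emits pure background signal there, so the background
subtraction performed downstream is exactly self-consistent on noiseless
data.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .model_core import TwoDimParams, eval_ln_r2

__all__ = [
    "BindingModelParams",
    "ArrayLayout",
    "SpotTable",
    "bound_complex_concentration",
    "detection_transform",
    "default_layout",
    "simulate_experiment",
    "simulate_from_surface",
    "write_csv",
    "write_gpr",
]

SPOT_COLUMNS = [
    "block",
    "row",
    "column",
    "antigen_id",
    "concentration",
    "replicate",
    "dilution",
    "channel",
    "rfi",
]

#: pseudo-wavelengths used to name GPR-dialect intensity columns, in channel order
GPR_WAVELENGTHS = (635, 532, 488, 594, 447)


@dataclass(frozen=True)
class BindingModelParams:
    """Ground-truth physical parameters of the binding + detection simulator.

    Attributes
    ----------
    ab_conc : float
        Total antibody concentration in the undiluted sample (M).
    kd : float
        Equilibrium dissociation constant (M).
    d_const : float
        Steric-inhibition constant D (1/M); the bound-complex concentration
        saturates at 1/D.
    alpha, beta : float
        Detection transform RFI = alpha * [AbAg]**beta (log-log linear with
        slope beta).
    noise_sigma : float
        SD of the Gaussian noise added to ln RFI (multiplicative on the
        linear scale).
    """

    ab_conc: float
    kd: float
    d_const: float
    alpha: float = 1.0
    beta: float = 1.0
    noise_sigma: float = 0.0

    def __post_init__(self) -> None:
        for name in ("ab_conc", "kd", "d_const", "alpha", "beta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    def midpoint_x(self, z: float = 1.0) -> float:
        """ln antigen concentration of the half-asymptote, at fold-dilution z.

        Solving [AbAg] = 1/(2D) gives ag = (K_D + [Ab]) / (D * [Ab]) with
        [Ab] = ab_conc / z; this is the inflection point the fits recover.
        """
        ab = self.ab_conc / z
        return math.log((self.kd + ab) / (self.d_const * ab))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "BindingModelParams":
        return cls(**data)


@dataclass(frozen=True)
class ArrayLayout:
    """Array geometry: printed antigen concentrations, replicates, dilutions."""

    antigen_concs: tuple
    n_replicates: int = 5
    dilutions: tuple = (100.0, 300.0, 900.0, 2700.0, 8100.0)
    channels: tuple = ("IgG", "IgA")

    def __post_init__(self) -> None:
        concs = np.asarray(self.antigen_concs, dtype=float)
        if concs.size < 2:
            raise ValueError("need at least 2 antigen concentrations")
        if np.any(concs <= 0):
            raise ValueError("antigen concentrations must be > 0")
        if np.any(np.diff(concs) >= 0):
            raise ValueError("antigen concentrations must be strictly decreasing")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if np.any(np.asarray(self.dilutions, dtype=float) < 1):
            raise ValueError("fold-dilutions must be >= 1")
        if len(self.channels) < 1:
            raise ValueError("need at least one channel")
        if len(self.channels) > len(GPR_WAVELENGTHS):
            raise ValueError("too many channels for the GPR dialect")

    @property
    def background_conc(self) -> float:
        """The least printed concentration; its spots serve as background."""
        return float(min(self.antigen_concs))

    def n_spots(self) -> int:
        return len(self.antigen_concs) * self.n_replicates * len(self.dilutions)

    def to_dict(self) -> dict:
        return {
            "antigen_concs": list(self.antigen_concs),
            "n_replicates": self.n_replicates,
            "dilutions": list(self.dilutions),
            "channels": list(self.channels),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ArrayLayout":
        return cls(
            antigen_concs=tuple(data["antigen_concs"]),
            n_replicates=int(data["n_replicates"]),
            dilutions=tuple(data["dilutions"]),
            channels=tuple(data["channels"]),
        )


@dataclass(frozen=True)
class SpotTable:
    """Per-spot records: coordinates, nominal concentration, dilution, RFI."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SPOT_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"SpotTable missing columns: {missing}")
        if len(self.frame) == 0:
            raise ValueError("SpotTable has no records")
        if (self.frame["rfi"] < 0).any():
            raise ValueError("raw RFI must be >= 0")
        key = ["concentration", "replicate", "dilution", "channel"]
        if self.frame.duplicated(subset=key).any():
            raise ValueError(
                "duplicate spot key (concentration, replicate, dilution, channel)"
            )

    def __len__(self) -> int:
        return len(self.frame)


def bound_complex_concentration(
    ag: Union[float, np.ndarray],
    ab: float,
    kd: float,
    d_const: float,
) -> Union[float, np.ndarray]:
    """Equilibrium immune-complex concentration with steric inhibition.

        [AbAg] = [Ab]*[Ag] / (K_D + [Ab] + D*[Ab]*[Ag])

    A logistic function of ln[Ag] with growth rate 1, saturating at 1/D;
    the half-asymptote sits at ag = (K_D + [Ab]) / (D*[Ab]).
    """
    ag_arr = np.asarray(ag, dtype=float)
    ab_arr = np.asarray(ab, dtype=float)
    if (
        np.any(ag_arr < 0)
        or np.any(ab_arr < 0)
        or kd < 0
        or d_const < 0
    ):
        raise ValueError("concentrations and constants must be >= 0")
    if np.any(kd + ab_arr <= 0):
        raise ValueError("kd + ab must be > 0")
    out = ab_arr * ag_arr / (kd + ab_arr + d_const * ab_arr * ag_arr)
    if np.ndim(ag) == 0 and np.ndim(ab) == 0:
        return float(out)
    return out


def detection_transform(
    complex_conc: Union[float, np.ndarray], alpha: float, beta: float = 1.0
) -> Union[float, np.ndarray]:
    """Fluorescence readout RFI = alpha * [AbAg]**beta (log-log linear)."""
    conc = np.asarray(complex_conc, dtype=float)
    if np.any(conc < 0):
        raise ValueError("complex concentration must be >= 0")
    out = alpha * conc**beta
    if np.ndim(complex_conc) == 0:
        return float(out)
    return out


def default_layout(monoclonal: bool = False) -> ArrayLayout:
    """Standard array layout.

    Serum mode: 7 half serial antigen dilutions from 200 uM (200 ... 3.125 uM)
    in quintuplicate, with serum fold-dilutions in three-fold steps from 100.
    Monoclonal mode: same antigen series but a 10-step two-fold analyte
    dilution series on a single channel.
    """
    concs = tuple(2e-4 * 0.5**j for j in range(7))
    if monoclonal:
        return ArrayLayout(
            antigen_concs=concs,
            n_replicates=5,
            dilutions=tuple(float(2**j) for j in range(10)),
            channels=("mAb",),
        )
    return ArrayLayout(antigen_concs=concs, n_replicates=5)


def _as_channel_map(layout: ArrayLayout, params) -> dict:
    if isinstance(params, BindingModelParams) or isinstance(params, TwoDimParams):
        return {ch: params for ch in layout.channels}
    params = dict(params)
    missing = [ch for ch in layout.channels if ch not in params]
    if missing:
        raise ValueError(f"no parameters for channels: {missing}")
    return params


def _assemble(layout: ArrayLayout, records: list) -> SpotTable:
    frame = pd.DataFrame.from_records(records, columns=SPOT_COLUMNS)
    return SpotTable(frame=frame)


def _spot_grid(layout: ArrayLayout):
    """Yield (block, row, column, antigen_id, conc, replicate, dilution)."""
    for bi, z in enumerate(layout.dilutions):
        for ci, conc in enumerate(layout.antigen_concs):
            for ri in range(layout.n_replicates):
                yield (
                    bi + 1,
                    ri + 1,
                    ci + 1,
                    f"AG{ci + 1:02d}",
                    float(conc),
                    ri + 1,
                    float(z),
                )


def simulate_experiment(
    layout: ArrayLayout,
    params: Union[BindingModelParams, Mapping[str, BindingModelParams]],
    seed: int,
    background: Union[float, str] = "auto",
) -> SpotTable:
    """Simulate a full spot table from the equilibrium binding model.

    For each spot: the antibody is diluted ideally (ab = ab_conc / z), the
    bound-complex concentration follows the inhibition binding equation, and
    detection is log-log linear.  The least-concentrated spots carry pure
    background; every spot receives the additive per-channel background
    offset and per-spot lognormal noise exp(eps), eps ~ N(0, noise_sigma^2).

    background: "auto" pegs the offset to the expected specific signal the
    background concentration would have produced at the least dilution;
    a float fixes it explicitly (0 allowed).
    """
    channel_params = _as_channel_map(layout, params)
    rng = np.random.default_rng(seed)
    bg_conc = layout.background_conc

    backgrounds = {}
    for ch, p in channel_params.items():
        if background == "auto":
            ab = p.ab_conc / min(layout.dilutions)
            backgrounds[ch] = detection_transform(
                bound_complex_concentration(bg_conc, ab, p.kd, p.d_const),
                p.alpha,
                p.beta,
            )
        else:
            backgrounds[ch] = float(background)

    records = []
    for ch in layout.channels:
        p = channel_params[ch]
        bg = backgrounds[ch]
        for block, row, col, ag_id, conc, rep, z in _spot_grid(layout):
            if conc == bg_conc:
                specific = 0.0
            else:
                ab = p.ab_conc / z
                specific = detection_transform(
                    bound_complex_concentration(conc, ab, p.kd, p.d_const),
                    p.alpha,
                    p.beta,
                )
            eps = rng.normal(0.0, p.noise_sigma) if p.noise_sigma > 0 else 0.0
            rfi = (specific + bg) * math.exp(eps)
            records.append((block, row, col, ag_id, conc, rep, z, ch, rfi))
    return _assemble(layout, records)


def simulate_from_surface(
    layout: ArrayLayout,
    surface: Union[TwoDimParams, Mapping[str, TwoDimParams]],
    noise_sigma: float,
    seed: int,
    background: float = 0.0,
) -> SpotTable:
    """Simulate spots directly from a two-dimensional model surface.

    Used for calibration studies where the generating model must equal the
    fitted model exactly.  Background spots (least concentration) emit the
    constant ``background`` only; all spots get lognormal noise.
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    channel_params = _as_channel_map(layout, surface)
    rng = np.random.default_rng(seed)
    bg_conc = layout.background_conc

    records = []
    for ch in layout.channels:
        q = channel_params[ch]
        for block, row, col, ag_id, conc, rep, z in _spot_grid(layout):
            if conc == bg_conc:
                specific = 0.0
            else:
                specific = math.exp(eval_ln_r2(math.log(conc), z, q))
            eps = rng.normal(0.0, noise_sigma) if noise_sigma > 0 else 0.0
            rfi = (specific + background) * math.exp(eps)
            records.append((block, row, col, ag_id, conc, rep, z, ch, rfi))
    return _assemble(layout, records)


def write_csv(table: SpotTable, path) -> None:
    """Write the long-format CSV schema (one row per spot per channel)."""
    table.frame.to_csv(path, index=False, columns=SPOT_COLUMNS)


def write_gpr(table: SpotTable, path) -> None:
    """Write a minimal GenePix-results-like tab-separated dialect.

    Header block carries the channel map; the table has one row per spot with
    Block/Row/Column/ID coordinates and one median-intensity column per
    channel (named after pseudo-wavelengths, e.g. "F635 Median").
    """
    channels = list(dict.fromkeys(table.frame["channel"]))
    col_names = [f"F{GPR_WAVELENGTHS[i]} Median" for i in range(len(channels))]
    channel_map = ";".join(f"{c}:{ch}" for c, ch in zip(col_names, channels))

    wide = table.frame.pivot_table(
        index=["block", "row", "column", "antigen_id", "concentration",
               "replicate", "dilution"],
        columns="channel",
        values="rfi",
        aggfunc="first",
        sort=False,
    ).reset_index()
    wide = wide.rename(columns=dict(zip(channels, col_names)))
    wide = wide.sort_values(["block", "column", "row"], kind="stable")

    header_cols = ["Block", "Row", "Column", "ID", "Concentration",
                   "Dilution", "Replicate"] + col_names
    with open(path, "w") as fh:
        fh.write("ATF\t1.0\n")
        fh.write(f"3\t{len(header_cols)}\n")
        fh.write('"Type=MicrospotResults 1.0"\n')
        fh.write(f'"ChannelMap={channel_map}"\n')
        fh.write(f'"SpotCount={len(wide)}"\n')
        fh.write("\t".join(header_cols) + "\n")
        for _, r in wide.iterrows():
            vals = [
                str(int(r["block"])),
                str(int(r["row"])),
                str(int(r["column"])),
                str(r["antigen_id"]),
                repr(float(r["concentration"])),
                repr(float(r["dilution"])),
                str(int(r["replicate"])),
            ] + [repr(float(r[c])) for c in col_names]
            fh.write("\t".join(vals) + "\n")
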