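"""Spot-table ingestion and reduction to the fitting grid.

The reduction follows the measurement protocol: replicate spot intensities
are averaged on the linear scale, the mean intensity of the least
concentrated (background) spots is subtracted per dilution and channel, and
the surviving positive values are log-transformed.  Background rows are kept
but flagged excluded; cells that become non-positive after subtraction are
dropped and counted.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .synthetic_data import SPOT_COLUMNS, SpotTable

logger = logging.getLogger(__name__)

__all__ = [
    "BindingTable",
    "read_spot_table",
    "aggregate_replicates",
    "write_binding_table",
    "PreprocessError",
    "MissingColumnError",
    "MalformedValueError",
    "DuplicateSpotError",
    "EmptyTableError",
    "NoFittableDataError",
]


class PreprocessError(ValueError):
    """Base class for ingestion/reduction failures."""


class MissingColumnError(PreprocessError):
    pass


class MalformedValueError(PreprocessError):
    pass


class DuplicateSpotError(PreprocessError):
    pass


class EmptyTableError(PreprocessError):
    pass


class NoFittableDataError(PreprocessError):
    pass


BINDING_COLUMNS = ["x", "z", "channel", "ln_signal", "excluded", "n_used"]


@dataclass
class BindingTable:
    """Reduced (x = ln molar antigen conc, z = fold dilution) signal grid.

    One row per (antigen concentration, dilution, channel).  Background rows
    (the least concentration) are flagged ``excluded`` and carry no
    ln_signal.  ``background`` holds the per-(channel, dilution) background
    mean/SD computed from the excluded spots; ``n_dropped`` counts cells
    removed because their background-subtracted mean was non-positive.
    """

    frame: pd.DataFrame
    background: Optional[pd.DataFrame] = None
    n_dropped: int = 0

    def __post_init__(self) -> None:
        missing = [c for c in BINDING_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"BindingTable missing columns: {missing}")

    @classmethod
    def from_arrays(cls, x, ln_signal, z=1.0, channel="IgG") -> "BindingTable":
        """Build a minimal fittable table directly from arrays (test helper)."""
        x = np.asarray(x, dtype=float)
        ln_signal = np.asarray(ln_signal, dtype=float)
        z = np.broadcast_to(np.asarray(z, dtype=float), x.shape)
        frame = pd.DataFrame(
            {
                "x": x,
                "z": z,
                "channel": channel,
                "ln_signal": ln_signal,
                "excluded": False,
                "n_used": 1,
            }
        )
        return cls(frame=frame)

    def fittable(self, channel: Optional[str] = None) -> pd.DataFrame:
        """Rows usable for fitting: not excluded, finite ln_signal."""
        f = self.frame
        mask = (~f["excluded"]) & np.isfinite(f["ln_signal"])
        if channel is not None:
            mask &= f["channel"] == channel
        return f.loc[mask].reset_index(drop=True)

    @property
    def channels(self) -> list:
        return list(dict.fromkeys(self.frame["channel"]))


def _read_csv_spots(path) -> pd.DataFrame:
    try:
        raw = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError:
        raise EmptyTableError(f"{path}: no records") from None
    missing = [c for c in SPOT_COLUMNS if c not in raw.columns]
    if missing:
        raise MissingColumnError(f"{path}: missing column(s) {missing}")
    if len(raw) == 0:
        raise EmptyTableError(f"{path}: no records")
    numeric = ["block", "row", "column", "concentration", "replicate",
               "dilution", "rfi"]
    frame = raw.copy()
    for col in numeric:
        parsed = pd.to_numeric(raw[col], errors="coerce")
        bad = parsed.isna() & raw[col].notna()
        if bad.any():
            lines = (raw.index[bad] + 2).tolist()  # +2: header + 1-based
            raise MalformedValueError(
                f"{path}: unparseable value(s) in column '{col}' "
                f"at line(s) {lines[:10]}"
            )
        if parsed.isna().any():
            lines = (raw.index[parsed.isna()] + 2).tolist()
            raise MalformedValueError(
                f"{path}: missing value(s) in column '{col}' at line(s) {lines[:10]}"
            )
        frame[col] = parsed
    return frame[SPOT_COLUMNS]


def _read_gpr_spots(path, channel_map: Optional[dict]) -> pd.DataFrame:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("ATF"):
            raise MalformedValueError(f"{path}: not an ATF/GPR-dialect file")
        counts = fh.readline().split("\t")
        try:
            n_header = int(counts[0])
        except (ValueError, IndexError):
            raise MalformedValueError(f"{path}: malformed ATF count line") from None
        meta = {}
        for _ in range(n_header):
            line = fh.readline().strip().strip('"')
            if "=" in line:
                key, val = line.split("=", 1)
                meta[key] = val
        table = pd.read_csv(fh, sep="\t")
    if len(table) == 0:
        raise EmptyTableError(f"{path}: no records")

    if channel_map is None:
        if "ChannelMap" not in meta:
            raise MissingColumnError(
                f"{path}: no ChannelMap header and no channel_map given"
            )
        channel_map = dict(
            item.split(":", 1) for item in meta["ChannelMap"].split(";")
        )

    required = ["Block", "Row", "Column", "ID", "Concentration", "Dilution",
                "Replicate"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise MissingColumnError(f"{path}: missing column(s) {missing}")
    missing_int = [c for c in channel_map if c not in table.columns]
    if missing_int:
        raise MissingColumnError(
            f"{path}: missing intensity column(s) {missing_int}"
        )

    long_parts = []
    for col, channel in channel_map.items():
        part = pd.DataFrame(
            {
                "block": table["Block"].astype(int),
                "row": table["Row"].astype(int),
                "column": table["Column"].astype(int),
                "antigen_id": table["ID"].astype(str),
                "concentration": table["Concentration"].astype(float),
                "replicate": table["Replicate"].astype(int),
                "dilution": table["Dilution"].astype(float),
                "channel": channel,
                "rfi": table[col].astype(float),
            }
        )
        long_parts.append(part)
    return pd.concat(long_parts, ignore_index=True)[SPOT_COLUMNS]


def read_spot_table(path, format: Optional[str] = None,
                    channel_map: Optional[dict] = None) -> SpotTable:
    """Read a spot table from the CSV schema or the GPR-like dialect.

    ``format`` is "csv" or "gpr"; inferred from the extension when omitted
    (.gpr/.txt -> gpr, otherwise csv).  ``channel_map`` maps intensity column
    names to isotype labels and overrides the file header for the dialect.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format is None:
        ext = os.path.splitext(str(path))[1].lower()
        format = "gpr" if ext in (".gpr", ".txt") else "csv"
    if format == "csv":
        frame = _read_csv_spots(path)
    elif format == "gpr":
        frame = _read_gpr_spots(path, channel_map)
    else:
        raise ValueError(f"unknown format {format!r}")

    key = ["concentration", "replicate", "dilution", "channel"]
    dup = frame.duplicated(subset=key)
    if dup.any():
        lines = (frame.index[dup] + 2).tolist()
        raise DuplicateSpotError(
            f"{path}: duplicate spot key at row(s) {lines[:10]}"
        )
    return SpotTable(frame=frame)


def aggregate_replicates(spots: SpotTable) -> BindingTable:
    """Reduce spot records to the fitting grid.

    Per (concentration, dilution, channel) cell the replicate RFIs are
    averaged on the linear scale; per (dilution, channel) the mean of the
    least-concentration cell is subtracted from every cell; the background
    cell is flagged excluded; remaining positive values are log-transformed
    and non-positive values are dropped (count reported on the table).
    """
    frame = spots.frame
    min_conc = frame["concentration"].min()

    cell = (
        frame.groupby(["channel", "dilution", "concentration"], sort=True)["rfi"]
        .agg(["mean", "count"])
        .reset_index()
    )

    bg_spots = frame[frame["concentration"] == min_conc]
    background = (
        bg_spots.groupby(["channel", "dilution"], sort=True)["rfi"]
        .agg(bg_mean="mean", bg_sd="std", n_spots="count")
        .reset_index()
    )
    background["bg_sd"] = background["bg_sd"].fillna(0.0)

    merged = cell.merge(background, on=["channel", "dilution"], how="left")
    if merged["bg_mean"].isna().any():
        missing = merged.loc[merged["bg_mean"].isna(), ["channel", "dilution"]]
        raise NoFittableDataError(
            f"no background (least-concentration) spots for cells:\n{missing}"
        )

    merged["signal"] = merged["mean"] - merged["bg_mean"]
    merged["excluded"] = merged["concentration"] == min_conc
    merged["x"] = np.log(merged["concentration"])

    keep = merged["excluded"] | (merged["signal"] > 0)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info(
            "dropped %d cell(s) with non-positive background-subtracted signal",
            n_dropped,
        )
    merged = merged[keep].copy()

    with np.errstate(divide="ignore", invalid="ignore"):
        merged["ln_signal"] = np.where(
            merged["excluded"], np.nan, np.log(merged["signal"].where(merged["signal"] > 0))
        )

    out = merged.rename(columns={"dilution": "z", "count": "n_used"})
    out = out[["x", "z", "channel", "ln_signal", "excluded", "n_used"]]
    out = out.sort_values(["channel", "z", "x"], ascending=[True, True, False])
    out = out.reset_index(drop=True)

    if not (~out["excluded"] & np.isfinite(out["ln_signal"])).any():
        raise NoFittableDataError(
            "no fittable data: all values non-positive after background subtraction"
        )
    return BindingTable(frame=out, background=background, n_dropped=n_dropped)


def write_binding_table(tbl: BindingTable, path) -> None:
    tbl.frame.to_csv(path, index=False, columns=BINDING_COLUMNS)
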