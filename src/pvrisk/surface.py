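"""Affiliate x month risk surfaces with min/average/max color anchors.

The consolidated output of the pipeline is, per impact factor, a heatmap:
one row per affiliate, one column per month, each cell the estimated risk
(or, for descriptive-only factors, a raw feature value).  The color scheme
has three anchors — the minimum, average and maximum over the displayed
cells — rendered pure green, pure yellow and pure red, with per-channel
linear interpolation between them.  Surfaces start at the first month whose
long trailing window lies fully inside the corpus span, so every displayed
cell rests on a complete window of data.

The canonical outputs are deterministic CSV / JSON exports of cell values
and colors; rendering is left to downstream dashboards.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .features import add_months, month_start
from .taxonomy import ImpactFactor

__all__ = [
    "CellColor",
    "RiskSurface",
    "build_risk_surface",
    "assign_colors",
    "cell_color",
    "export_surface",
    "read_surface_csv",
]


@dataclass(frozen=True)
class CellColor:
    red: int
    green: int
    blue: int

    def __post_init__(self) -> None:
        for v in (self.red, self.green, self.blue):
            if not 0 <= v <= 255:
                raise ValueError(f"channel out of range: {v}")

    @property
    def hex(self) -> str:
        return f"#{self.red:02x}{self.green:02x}{self.blue:02x}"

    @classmethod
    def from_hex(cls, text: str) -> "CellColor":
        text = text.lstrip("#")
        return cls(int(text[0:2], 16), int(text[2:4], 16), int(text[4:6], 16))


@dataclass
class RiskSurface:
    """Matrix of estimated risk (or a descriptive feature) with anchors."""

    impact_factor: ImpactFactor
    kind: str  # "risk" | "descriptive"
    values: pd.DataFrame  # index: affiliates, columns: months
    anchors: tuple[float, float, float]  # (min, average, max)


def build_risk_surface(
    values: Union[pd.Series, pd.DataFrame],
    impact_factor: ImpactFactor,
    kind: str = "risk",
    span: Optional[tuple] = None,
    long_window_months: int = 24,
    anchor_stat: str = "mean",
) -> RiskSurface:
    """Arrange per-(affiliate, month) values into the display matrix.

    ``values`` is either a Series indexed by (affiliate_id, month) — the
    shape :func:`pvrisk.model.predict_risk_series` returns — or an already
    pivoted affiliate x month frame.  When ``span`` is given, columns are
    trimmed to months whose ``long_window_months`` trailing window is fully
    inside it.  Anchors are min / mean (or median) / max over the
    non-MISSING displayed cells.
    """
    if kind not in ("risk", "descriptive"):
        raise ValueError(f"unknown surface kind {kind!r}")
    if isinstance(values, pd.Series):
        mat = values.unstack(level=-1)
    else:
        mat = values.copy()
    mat = mat.sort_index(axis=0).sort_index(axis=1)
    if span is not None:
        first = add_months(month_start(span[0]), long_window_months)
        mat = mat.loc[:, [c for c in mat.columns if pd.Timestamp(c) >= first]]
    arr = mat.to_numpy(dtype=float)
    defined = ~np.isnan(arr)
    if not defined.any():
        raise ValueError("surface has no defined cells")
    if kind == "risk":
        vals = arr[defined]
        if ((vals <= 0) | (vals >= 1)).any():
            raise ValueError("risk surface cells must lie strictly inside (0, 1)")
    if anchor_stat == "mean":
        avg = float(np.nanmean(arr))
    elif anchor_stat == "median":
        avg = float(np.nanmedian(arr))
    else:
        raise ValueError(f"unknown anchor_stat {anchor_stat!r}")
    anchors = (float(np.nanmin(arr)), avg, float(np.nanmax(arr)))
    return RiskSurface(impact_factor=impact_factor, kind=kind, values=mat, anchors=anchors)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def cell_color(value: float, anchors: tuple[float, float, float]) -> Optional[CellColor]:
    """Green→yellow→red gradient through the three anchors; None for MISSING.

    Values at or below the minimum are pure green (0,255,0), at the average
    pure yellow (255,255,0), at or above the maximum pure red (255,0,0);
    channels interpolate linearly within each segment with round-half-up.
    Fully degenerate anchors (min = average = max) render all-yellow.
    """
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    lo, mid, hi = anchors
    if lo == mid == hi:
        return CellColor(255, 255, 0)
    if value <= lo:
        return CellColor(0, 255, 0)
    if value >= hi:
        return CellColor(255, 0, 0)
    if value <= mid:
        frac = 1.0 if mid == lo else (value - lo) / (mid - lo)
        return CellColor(_round_half_up(255 * frac), 255, 0)
    frac = 0.0 if hi == mid else (value - mid) / (hi - mid)
    return CellColor(255, _round_half_up(255 * (1.0 - frac)), 0)


def assign_colors(surface: RiskSurface) -> pd.DataFrame:
    """Per-cell :class:`CellColor` (None for MISSING), same shape as the
    surface values."""
    return surface.values.map(lambda v: cell_color(v, surface.anchors))


def export_surface(
    surface: RiskSurface,
    colors: pd.DataFrame,
    destination: Union[str, Path],
    fmt: str = "csv",
) -> Path:
    """Write the surface as long-format CSV or structured JSON.

    Output bytes are a pure function of the inputs.  MISSING cells have
    empty value and color fields (CSV) or nulls (JSON).
    """
    destination = Path(destination)
    rows_aff = list(surface.values.index)
    cols = list(surface.values.columns)
    if fmt == "csv":
        records = []
        for aff in rows_aff:
            for month in cols:
                v = surface.values.at[aff, month]
                c = colors.at[aff, month]
                records.append(
                    {
                        "affiliate_id": aff,
                        "month": pd.Timestamp(month).strftime("%Y-%m"),
                        "impact_factor": surface.impact_factor.value,
                        "kind": surface.kind,
                        "value": "" if pd.isna(v) else repr(float(v)),
                        "hex_color": "" if c is None else c.hex,
                    }
                )
        pd.DataFrame(records).to_csv(destination, index=False)
    elif fmt == "json":
        payload = {
            "impact_factor": surface.impact_factor.value,
            "kind": surface.kind,
            "anchors": list(surface.anchors),
            "affiliates": rows_aff,
            "months": [pd.Timestamp(m).strftime("%Y-%m") for m in cols],
            "values": [
                [None if pd.isna(surface.values.at[a, m]) else float(surface.values.at[a, m]) for m in cols]
                for a in rows_aff
            ],
            "colors": [
                [None if colors.at[a, m] is None else colors.at[a, m].hex for m in cols]
                for a in rows_aff
            ],
        }
        with open(destination, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, sort_keys=True)
            fh.write("\n")
    else:
        raise ValueError(f"unknown export format {fmt!r}")
    return destination


def read_surface_csv(path: Union[str, Path]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read back an exported CSV surface: (values, hex colors) matrices."""
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    raw["month"] = pd.to_datetime(raw["month"], format="%Y-%m")
    values = raw.pivot(index="affiliate_id", columns="month", values="value")
    values = values.map(lambda s: float("nan") if s == "" else float(s))
    hexes = raw.pivot(index="affiliate_id", columns="month", values="hex_color")
    hexes = hexes.map(lambda s: None if s == "" else s)
    values.columns.name = None
    hexes.columns.name = None
    return values, hexes
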