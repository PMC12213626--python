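"""ROI placement relative to the optic nerve head and layer thickness.

Two measurement regions per B-scan, one on each side of the detected
ONH centre, spanning 350-630 um laterally (200 A-scans at the default
1.4 um pitch).  Boundaries are sub-pixel, so ROI-averaged thicknesses
resolve well below one pixel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .segmentation import Segmentation

__all__ = [
    "RoiSpec",
    "RoiError",
    "locate_onh",
    "select_rois",
    "layer_thickness",
    "aggregate_eye",
    "normalize_baseline",
]


class RoiError(ValueError):
    """ROI does not fit inside the image."""


@dataclass(frozen=True)
class RoiSpec:
    """Lateral measurement band relative to the ONH centre."""

    inner_offset_um: float = 350.0
    outer_offset_um: float = 630.0

    def __post_init__(self):
        if self.outer_offset_um <= self.inner_offset_um:
            raise ValueError("outer offset must exceed inner offset")

    def n_ascans(self, lateral_pitch_um: float) -> int:
        return round((self.outer_offset_um - self.inner_offset_um) / lateral_pitch_um)


def locate_onh(seg: Segmentation, image_center: int | None = None) -> int:
    """Centre column of the invalid (ONH) A-scan run nearest the image
    centre; falls back to the image centre when nothing is flagged."""
    valid = seg.valid_mask
    center = seg.n_ascans // 2 if image_center is None else image_center
    invalid = ~valid
    if not invalid.any():
        return center
    # contiguous invalid runs
    edges = np.flatnonzero(np.diff(np.concatenate([[0], invalid.view(np.int8), [0]])))
    starts, stops = edges[::2], edges[1::2]
    centers = (starts + stops - 1) / 2.0
    if len(centers) > 1:
        spread = stops.max() - starts.min()
        if spread > 3 * (stops - starts).max():
            warnings.warn("multiple distant ONH candidate runs; "
                          "choosing the one nearest the image centre")
    return int(round(centers[np.argmin(np.abs(centers - center))]))


def select_rois(onh_col: int, lateral_pitch_um: float, n_ascans: int,
                spec: RoiSpec = RoiSpec()) -> dict:
    """Half-open column ranges of the left and right ROIs.

    left = [onh - outer/p, onh - inner/p), right = [onh + inner/p,
    onh + outer/p); raises :class:`RoiError` when either falls outside
    the image.
    """
    inner = round(spec.inner_offset_um / lateral_pitch_um)
    outer = round(spec.outer_offset_um / lateral_pitch_um)
    rois = {"left": (onh_col - outer, onh_col - inner),
            "right": (onh_col + inner, onh_col + outer)}
    for side, (c0, c1) in rois.items():
        if c0 < 0 or c1 > n_ascans:
            raise RoiError(f"{side} ROI [{c0}, {c1}) outside image "
                           f"of width {n_ascans}")
    return rois


def layer_thickness(seg: Segmentation, roi, axial_pitch_um: float,
                    min_valid_frac: float = 0.5) -> dict:
    """Mean per-layer thickness (um) over the ROI's valid A-scans.

    Thickness per A-scan is (lower boundary - upper boundary) * pitch
    with sub-pixel boundaries used directly.  Invalid A-scans are
    skipped; more than 50% invalid yields NaN for every layer.  For the
    intact schema an ``OR`` entry (IS+OS + RPE) is added so the merged
    outer-retina band is comparable across the schema switch.
    """
    c0, c1 = int(roi[0]), int(roi[1])
    if c0 < 0 or c1 > seg.n_ascans or c0 >= c1:
        raise RoiError(f"ROI [{c0}, {c1}) invalid for width {seg.n_ascans}")
    use = seg.valid_mask[c0:c1]
    out = {}
    n_cols = c1 - c0
    if use.sum() < min_valid_frac * n_cols:
        out = {l: float("nan") for l in seg.schema.layer_names}
        if "IS+OS" in out:
            out["OR"] = float("nan")
        return out
    b = seg.boundaries[:, c0:c1][:, use]
    widths = np.diff(b, axis=0) * axial_pitch_um
    for i, layer in enumerate(seg.schema.layer_names):
        out[layer] = float(widths[i].mean())
    if "IS+OS" in out:
        out["OR"] = out["IS+OS"] + out["RPE"]
    return out


def aggregate_eye(records: pd.DataFrame, expected_rois: int = 8,
                  min_rois: int = 4) -> pd.DataFrame:
    """Per-layer unweighted mean of one eye/day's ROI measurements.

    ``records`` is long-format with at least ``layer`` and
    ``thickness_um`` columns (one row per ROI x layer).  Rows with NaN
    are dropped per layer; fewer than ``min_rois`` contributing ROIs
    flags the layer as incomplete (value still reported).
    """
    rows = []
    for layer, grp in records.groupby("layer", sort=False):
        vals = grp["thickness_um"].dropna()
        rows.append({
            "layer": layer,
            "thickness_um": float(vals.mean()) if len(vals) else float("nan"),
            "n_rois": int(len(vals)),
            "complete": bool(len(vals) >= min_rois),
        })
    return pd.DataFrame(rows)


def normalize_baseline(series: pd.DataFrame, value_col: str = "thickness_um",
                       baseline_day: float = 0.0) -> pd.DataFrame:
    """Normalise each eye/layer series to its baseline, then average
    across eyes per (day, layer).

    ``series`` columns: mouse, eye, day, layer, ``value_col``.  A zero
    baseline raises ValueError.
    """
    df = series.copy()
    out = []
    for (m, e, layer), grp in df.groupby(["mouse", "eye", "layer"]):
        base = grp.loc[grp["day"] == baseline_day, value_col]
        if base.empty:
            raise ValueError(f"no baseline value for mouse {m} eye {e} layer {layer}")
        b = float(base.mean())
        if b == 0:
            raise ValueError(f"zero baseline for mouse {m} eye {e} layer {layer}")
        g = grp.copy()
        g["normalized"] = g[value_col] / b
        out.append(g)
    norm = pd.concat(out, ignore_index=True)
    return (norm.groupby(["day", "layer"], as_index=False)["normalized"]
            .mean())
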