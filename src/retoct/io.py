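"""File I/O: B-scan TIFF/PNG with JSON metadata sidecars, boundary
CSV/JSON, study tables, and run configuration files."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .bscan import BScan
from .reflectance import log_compress
from .segmentation import Segmentation, get_schema

__all__ = [
    "write_bscan", "read_bscan", "write_png_display",
    "write_segmentation", "read_segmentation",
    "write_study_table", "read_study_table",
    "load_config", "dump_config",
]

STUDY_TABLE_COLUMNS = ["mouse", "eye", "day", "layer", "metric", "value", "n"]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_bscan(path, bscan: BScan, dtype: str = "uint16") -> None:
    """Write a linear-scale B-scan as TIFF plus a JSON metadata sidecar.

    ``uint16`` stores round(data / scale) with the scale recorded in the
    sidecar (lossless for integer-valued data within range); ``float32``
    stores values directly.
    """
    path = Path(path)
    meta = {"axial_pitch_um": bscan.axial_pitch_um,
            "lateral_pitch_um": bscan.lateral_pitch_um,
            "scale": bscan.scale, "meta": bscan.meta}
    if dtype == "uint16":
        peak = float(bscan.data.max()) if bscan.data.size else 0.0
        factor = 1.0 if peak <= 65535 else peak / 65535.0
        arr = np.round(bscan.data / factor).astype(np.uint16)
        meta["intensity_factor"] = factor
    elif dtype == "float32":
        arr = bscan.data.astype(np.float32)
        meta["intensity_factor"] = 1.0
    else:
        raise ValueError("dtype must be 'uint16' or 'float32'")
    tifffile.imwrite(str(path), arr)
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_bscan(path) -> BScan:
    """Read a TIFF B-scan; the metadata sidecar is required (pixel
    pitches are never silently defaulted)."""
    path = Path(path)
    side = _sidecar(path)
    if not side.exists():
        raise FileNotFoundError(f"metadata sidecar {side} missing")
    meta = json.loads(side.read_text())
    for key in ("axial_pitch_um", "lateral_pitch_um"):
        if key not in meta:
            raise KeyError(f"sidecar {side} missing required key {key!r}")
    data = tifffile.imread(str(path)).astype(float) * meta.get("intensity_factor", 1.0)
    return BScan(data=data, axial_pitch_um=meta["axial_pitch_um"],
                 lateral_pitch_um=meta["lateral_pitch_um"],
                 scale=meta.get("scale", "linear"), meta=meta.get("meta", {}))


def write_png_display(path, bscan: BScan, scale: float = None) -> dict:
    """8-bit log-compressed display PNG; returns (and sidecars) the
    compression parameters so the transform stays invertible."""
    from imageio import v3 as iio
    path = Path(path)
    peak = float(bscan.data.max()) or 1.0
    s = scale if scale is not None else max(peak * 1e-3, 1e-12)
    params = {"scale": s, "max_value": peak}
    disp = np.round(255 * log_compress(bscan.data, s, peak)).astype(np.uint8)
    iio.imwrite(str(path), disp)
    _sidecar(path).write_text(json.dumps({"display_params": params}, indent=1))
    return params


def write_segmentation(path, seg: Segmentation) -> None:
    """Boundary CSV: ascan_index, boundary_name, row_position, valid."""
    path = Path(path)
    rows = []
    for k, name in enumerate(seg.schema.boundary_names):
        for c in range(seg.n_ascans):
            rows.append((c, name, seg.boundaries[k, c], bool(seg.valid_mask[c])))
    df = pd.DataFrame(rows, columns=["ascan_index", "boundary_name",
                                     "row_position", "valid"])
    df.insert(0, "schema", seg.schema.name)
    df.to_csv(path, index=False)


def read_segmentation(path) -> Segmentation:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ValueError(f"malformed boundary file {path}: {exc}") from exc
    required = {"schema", "ascan_index", "boundary_name", "row_position", "valid"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"boundary file {path} missing columns {sorted(missing)}")
    bad = df[~np.isfinite(df["row_position"])]
    if len(bad):
        raise ValueError(f"boundary file {path}: non-finite row_position "
                         f"at line {bad.index[0] + 2}")
    schema = get_schema(df["schema"].iloc[0])
    width = int(df["ascan_index"].max()) + 1
    boundaries = np.full((schema.n_boundaries, width), np.nan)
    valid = np.ones(width, dtype=bool)
    name_idx = {n: i for i, n in enumerate(schema.boundary_names)}
    for _, row in df.iterrows():
        boundaries[name_idx[row["boundary_name"]], int(row["ascan_index"])] = \
            row["row_position"]
        valid[int(row["ascan_index"])] &= bool(row["valid"])
    if np.isnan(boundaries).any():
        raise ValueError(f"boundary file {path}: incomplete boundary grid")
    return Segmentation(schema=schema, boundaries=boundaries, valid_mask=valid)


def write_study_table(path, table: pd.DataFrame) -> None:
    """Long-format study table CSV with a fixed, documented column order."""
    missing = set(STUDY_TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"study table missing columns {sorted(missing)}")
    table[STUDY_TABLE_COLUMNS].to_csv(path, index=False)


def read_study_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(STUDY_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"study table {path} missing columns {sorted(missing)}")
    return df


def load_config(path) -> dict:
    """Read a JSON or YAML run-configuration file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def dump_config(path, config: dict) -> None:
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(config, sort_keys=True))
    else:
        path.write_text(json.dumps(config, indent=2, sort_keys=True))
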