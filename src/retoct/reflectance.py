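"""Estimated attenuation coefficient (eAC) images and reflectance stats.

Per pixel i of each A-scan, the estimator is

    mu_hat[i] = I[i] / (2 * dz * sum_{j>i} I[j])

with I the background-subtracted linear-scale intensity and dz the
axial pitch in meters — a depth-resolved estimator under a
complete-attenuation assumption at the image bottom, with the signal
decay factor dropped.  Layer statistics are reported as mean
log10(mu_hat).  The Dip ratio (IS-band intensity peak over the
hyporeflective minimum between IS and OS) is computed from the linear
image directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bscan import BScan
from .segmentation import Segmentation

__all__ = [
    "LinearBScan",
    "EacImage",
    "LayerEacResult",
    "DisplayTransformError",
    "log_compress",
    "log_expand",
    "linearize",
    "compute_eac",
    "layer_eac",
    "dip_ratio",
]

#: Image rows at the very bottom excluded from layer statistics (the
#: complete-attenuation boundary condition makes them biased).
BOTTOM_EXCLUDE_PX = 5


class DisplayTransformError(ValueError):
    """Display-compressed input without recorded transform parameters."""


@dataclass
class LinearBScan:
    """Background-subtracted intensities proportional to signal power."""

    data: np.ndarray
    axial_pitch_um: float
    background: float = 0.0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.axial_pitch_um <= 0:
            raise ValueError("axial pitch must be positive")
        if np.any(self.data < 0):
            raise ValueError("linearized intensities must be >= 0")


@dataclass
class EacImage:
    """Per-pixel estimated attenuation coefficients, 1/m; NaN = masked."""

    data: np.ndarray
    axial_pitch_um: float
    log10_scale: bool = False


@dataclass
class LayerEacResult:
    mean_log10: float
    n_pixels: int


def log_compress(linear: np.ndarray, scale: float, max_value: float) -> np.ndarray:
    """Invertible display transform D = log1p(U/scale)/log1p(max/scale)."""
    if scale <= 0 or max_value <= 0:
        raise ValueError("scale and max_value must be positive")
    return np.log1p(np.asarray(linear, float) / scale) / np.log1p(max_value / scale)


def log_expand(display: np.ndarray, scale: float, max_value: float) -> np.ndarray:
    """Exact inverse of :func:`log_compress` (before any quantisation)."""
    return scale * np.expm1(np.asarray(display, float) * np.log1p(max_value / scale))


def linearize(raw: BScan, display_params: dict | None = None,
              vitreous_region=None) -> LinearBScan:
    """Undo any display compression and subtract the background floor.

    The background N is estimated as the mean over ``vitreous_region``
    (a boolean mask or an index tuple of a particle-free vitreous
    patch); without a region, ``raw.meta['background_level']`` is used
    if present, else 0.  ``I = U - N`` is clamped at 0.

    Raises
    ------
    DisplayTransformError
        For log-scale input with no recorded transform parameters —
        parameters are never guessed.
    """
    u = np.asarray(raw.data, dtype=float)
    if raw.scale == "log":
        params = display_params or raw.meta.get("display_params")
        if not params:
            raise DisplayTransformError(
                "log-compressed input: display transform parameters required")
        u = log_expand(u, params["scale"], params["max_value"])
    elif raw.scale != "linear":
        raise DisplayTransformError(f"unknown intensity scale {raw.scale!r}")

    if vitreous_region is not None:
        n = float(np.mean(u[vitreous_region]))
    else:
        n = float(raw.meta.get("background_level", 0.0))
    return LinearBScan(data=np.clip(u - n, 0.0, None),
                       axial_pitch_um=raw.axial_pitch_um, background=n)


def compute_eac(lin: LinearBScan, tail_floor_frac: float = 1e-3) -> EacImage:
    """Depth-resolved attenuation estimate for every pixel.

    Pixels whose remaining tail energy falls below
    ``tail_floor_frac`` times the A-scan's total energy are masked
    (NaN) — the ratio is numerically meaningless there.  All-zero
    A-scans come back fully masked.  The estimate is invariant to any
    positive rescaling of the intensities.
    """
    I = lin.data
    dz_m = lin.axial_pitch_um * 1e-6
    total = I.sum(axis=0, keepdims=True)
    # tail[i] = sum of strictly deeper pixels
    tail = total - np.cumsum(I, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        mu = I / (2.0 * dz_m * tail)
    floor = tail_floor_frac * total
    mu[tail <= np.maximum(floor, 0.0)] = np.nan
    mu[:, total[0] == 0] = np.nan
    return EacImage(data=mu, axial_pitch_um=lin.axial_pitch_um)


def layer_eac(eac: EacImage, seg: Segmentation, layer_name: str,
              roi=None, exclude_bottom_px: int = BOTTOM_EXCLUDE_PX) -> LayerEacResult:
    """Mean log10 attenuation over one layer's unmasked pixels in a ROI.

    ``roi`` is a (start, stop) column range (half-open) or None for the
    whole width.  All pixels masked (or an empty ROI) returns a
    missing-value result with ``n_pixels`` 0 rather than raising.
    """
    H = eac.data.shape[0]
    mask = seg.layer_mask(layer_name, H)
    if roi is not None:
        cols = np.zeros(mask.shape[1], dtype=bool)
        cols[int(roi[0]):int(roi[1])] = True
        mask &= cols[None, :]
    if exclude_bottom_px > 0:
        mask[H - exclude_bottom_px:, :] = False
    vals = eac.data[mask]
    vals = vals[np.isfinite(vals) & (vals > 0)]
    if vals.size == 0:
        return LayerEacResult(float("nan"), 0)
    return LayerEacResult(float(np.mean(np.log10(vals))), int(vals.size))


def dip_ratio(lin: LinearBScan, seg: Segmentation, roi=None) -> float:
    """IS-peak over Dip intensity ratio, averaged across ROI A-scans.

    Per A-scan: the intensity maximum in the upper half of the IS+OS
    layer is the IS peak; the minimum between that peak and the layer's
    lower boundary is the Dip.  Ratio = mean(peaks) / mean(dips).
    Requires the intact-retina schema (raises ValueError on the merged
    OR schema).
    """
    if "IS+OS" not in seg.schema.layer_names:
        raise ValueError("Dip ratio needs the IS+OS layer "
                         "(not applicable to the degenerative schema)")
    k = seg.schema.layer_names.index("IS+OS")
    top = seg.boundaries[k]
    bot = seg.boundaries[k + 1]
    W = seg.n_ascans
    cols = np.arange(W)
    use = seg.valid_mask.copy()
    if roi is not None:
        sel = np.zeros(W, dtype=bool)
        sel[int(roi[0]):int(roi[1])] = True
        use &= sel

    peaks, dips = [], []
    I = lin.data
    H = I.shape[0]
    for c in cols[use]:
        r0 = int(np.ceil(top[c]))
        r2 = int(np.floor(bot[c]))
        r1 = int(np.floor((top[c] + bot[c]) / 2.0))
        r0, r1, r2 = max(r0, 0), min(r1, H - 1), min(r2, H - 1)
        if r1 < r0 or r2 <= r0:
            continue
        upper = I[r0:r1 + 1, c]
        p = int(np.argmax(upper)) + r0
        lower = I[p:r2 + 1, c]
        if lower.size == 0:
            continue
        peaks.append(I[p, c])
        dips.append(float(np.min(lower)))
    if not peaks:
        return float("nan")
    mean_dip = float(np.mean(dips))
    if mean_dip <= 0:
        return float("nan")
    return float(np.mean(peaks)) / mean_dip
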