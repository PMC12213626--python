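"""Retinal boundary extraction by shortest-path search over cost maps.

Boundaries are found top-to-bottom sequentially, each search band
constrained below the previous boundary.  Several parameterised
segmenter variants emulate a pool of models; their outputs can be
combined per A-scan by the median (``ensemble_median``) and compared
with DICE scores and usage rates.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .bscan import BScan

__all__ = [
    "LayerSchema",
    "NORMAL_SCHEMA",
    "DEGENERATIVE_SCHEMA",
    "get_schema",
    "CostMap",
    "Segmentation",
    "SegmentationError",
    "VariantParams",
    "DEFAULT_VARIANTS",
    "boundary_cost",
    "shortest_path_boundary",
    "segment",
    "ensemble_median",
    "dice_score",
    "usage_rate",
]


class SegmentationError(RuntimeError):
    """Raised when no plausible retina can be found in an image."""


@dataclass(frozen=True)
class LayerSchema:
    """Named, ordered set of boundaries and the layers between them."""

    name: str
    boundary_names: tuple
    layer_names: tuple

    def __post_init__(self):
        if len(self.layer_names) != len(self.boundary_names) - 1:
            raise ValueError("layer count must equal boundary count - 1")

    @property
    def n_boundaries(self) -> int:
        return len(self.boundary_names)

    @property
    def n_layers(self) -> int:
        return len(self.layer_names)

    def layer_index(self, layer_name: str) -> int:
        try:
            return self.layer_names.index(layer_name)
        except ValueError:
            raise KeyError(f"unknown layer {layer_name!r} in schema {self.name!r}")


#: Intact retina: 9 boundary lines -> 7 retinal layers + choroid.
NORMAL_SCHEMA = LayerSchema(
    name="normal",
    boundary_names=(
        "vitreous/NFL", "NFL/IPL", "IPL/INL", "INL/OPL", "OPL/ONL",
        "ONL/IS+OS", "IS+OS/RPE", "RPE/choroid", "choroid/sclera",
    ),
    layer_names=("NFL", "IPL", "INL", "OPL", "ONL", "IS+OS", "RPE", "choroid"),
)

#: Degenerated retina: photoreceptor segments and RPE merged into a
#: single outer-retina (OR) band; 8 lines -> 6 retinal layers + choroid.
DEGENERATIVE_SCHEMA = LayerSchema(
    name="degenerative",
    boundary_names=(
        "vitreous/NFL", "NFL/IPL", "IPL/INL", "INL/OPL", "OPL/ONL",
        "ONL/OR", "OR/choroid", "choroid/sclera",
    ),
    layer_names=("NFL", "IPL", "INL", "OPL", "ONL", "OR", "choroid"),
)

_SCHEMAS = {s.name: s for s in (NORMAL_SCHEMA, DEGENERATIVE_SCHEMA)}


def get_schema(name: str) -> LayerSchema:
    try:
        return _SCHEMAS[name]
    except KeyError:
        raise KeyError(f"unknown schema {name!r}; choose from {sorted(_SCHEMAS)}")


# Edge polarity per boundary: +1 where intensity increases with depth
# (dark-to-bright), -1 for bright-to-dark.
_POLARITY = {
    "normal": (+1, -1, -1, +1, -1, +1, +1, -1, -1),
    "degenerative": (+1, -1, -1, +1, -1, +1, -1, -1),
}

# Plausible per-layer thickness bands (um) used to constrain each
# sequential search below the previous boundary.
_GAP_BOUNDS_UM = {
    "NFL": (4.0, 30.0),
    "IPL": (22.0, 78.0),
    "INL": (8.0, 48.0),
    "OPL": (4.0, 34.0),
    "ONL": (5.0, 90.0),
    # min gap sits above the internal IS/dip/OS banding so the search
    # cannot lock onto the dip->OS edge instead of the RPE surface
    "IS+OS": (32.0, 58.0),
    "RPE": (3.5, 18.0),
    "OR": (4.0, 65.0),
    "choroid": (40.0, 135.0),
}

# Mild per-row preference for the shallowest adequate edge inside a
# search band; keeps a thin inner layer's far boundary from capturing a
# stronger edge one layer deeper (e.g. a thinned INL whose band reaches
# the OPL/ONL edge).  Only the inner-retina boundaries need it; for the
# outer boundaries the bands already exclude competing edges and the
# penalty would fight the weak, deep choroid/sclera edge.  Applied to
# the integer DP only, so it does not bias sub-pixel positions.
_DEPTH_PENALTY_PER_ROW = 0.004
_DEPTH_PENALTY_LAYERS = frozenset({"NFL", "IPL", "INL", "OPL", "ONL"})


@dataclass
class CostMap:
    """Non-negative transition costs, same shape as the image."""

    costs: np.ndarray
    polarity: str  # "dark-to-bright" | "bright-to-dark"

    def __post_init__(self):
        c = np.asarray(self.costs, dtype=float)
        if not np.all(np.isfinite(c)) or np.any(c < 0):
            raise ValueError("costs must be finite and non-negative")
        self.costs = c


@dataclass
class Segmentation:
    """Ordered boundary curves under a layer schema.

    ``boundaries`` has shape (n_boundaries, n_ascans) with real-valued
    row positions; a boundary value b places the layer transition
    between pixel rows floor(b) and floor(b)+1.  ``valid_mask`` flags
    A-scans outside the optic-nerve-head gap.
    """

    schema: LayerSchema
    boundaries: np.ndarray
    valid_mask: np.ndarray = None
    source_model: str = ""

    def __post_init__(self):
        self.boundaries = np.asarray(self.boundaries, dtype=float)
        if self.boundaries.ndim != 2:
            raise ValueError("boundaries must be 2-D (n_boundaries x n_ascans)")
        if self.boundaries.shape[0] != self.schema.n_boundaries:
            raise ValueError(
                f"schema {self.schema.name!r} expects {self.schema.n_boundaries} "
                f"boundaries, got {self.boundaries.shape[0]}")
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.boundaries.shape[1], dtype=bool)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)

    @property
    def n_ascans(self) -> int:
        return self.boundaries.shape[1]

    def check_ordering(self, atol: float = 1e-9) -> bool:
        """True when boundaries are monotone in depth at all valid A-scans."""
        d = np.diff(self.boundaries[:, self.valid_mask], axis=0)
        return bool(d.size == 0 or d.min() >= -atol)

    def layer_mask(self, layer_name: str, image_height: int) -> np.ndarray:
        """Boolean pixel mask of one layer, zeroed at invalid A-scans."""
        i = self.schema.layer_index(layer_name)
        rows = np.arange(image_height)[:, None]
        top = self.boundaries[i][None, :]
        bot = self.boundaries[i + 1][None, :]
        mask = (rows > top) & (rows <= bot)
        mask[:, ~self.valid_mask] = False
        return mask


@dataclass(frozen=True)
class VariantParams:
    """One segmenter configuration (stand-in for one trained model)."""

    name: str = "v0"
    smoothing_sigma: float = 1.5
    lateral_sigma: float = 4.0
    max_step: int = 2
    gradient_gain: float = 1.0


#: Five differently-tuned variants so ensembling has a pool to draw on.
DEFAULT_VARIANTS = (
    VariantParams("v0", smoothing_sigma=1.0, lateral_sigma=3.0, max_step=2),
    VariantParams("v1", smoothing_sigma=1.5, lateral_sigma=4.0, max_step=2),
    VariantParams("v2", smoothing_sigma=1.8, lateral_sigma=5.0, max_step=2, gradient_gain=1.1),
    VariantParams("v3", smoothing_sigma=1.2, lateral_sigma=6.0, max_step=3, gradient_gain=1.3),
    VariantParams("v4", smoothing_sigma=0.8, lateral_sigma=2.5, max_step=2, gradient_gain=0.8),
)


def boundary_cost(bscan: BScan, polarity: str, smoothing_sigma: float = 1.5,
                  lateral_sigma: float = 0.0, gain: float = 1.0) -> CostMap:
    """Gradient-based transition cost: low where the signed vertical
    gradient of the log-intensity matches ``polarity``.

    The cost at row i, column c refers to a transition between pixel
    rows i and i+1 (last row padded).  Costs are normalised to [0, 1].
    A constant image yields a uniform map, not an error.
    """
    if polarity not in ("dark-to-bright", "bright-to-dark"):
        raise ValueError("polarity must be 'dark-to-bright' or 'bright-to-dark'")
    img = np.asarray(bscan.data, dtype=float)
    if img.ndim != 2 or img.shape[0] < 2:
        raise ValueError("image must be 2-D with at least 2 rows")
    if not np.all(np.isfinite(img)):
        raise ValueError("image must be finite")

    # log compresses the multiplicative depth decay so deep, dim edges
    # keep the same contrast as bright superficial ones.
    floor = max(np.median(img) * 1e-3, 1e-12)
    limg = np.log(np.clip(img, 0, None) + floor)
    if smoothing_sigma > 0 or lateral_sigma > 0:
        limg = ndimage.gaussian_filter(limg, (smoothing_sigma, lateral_sigma))
    grad = np.diff(limg, axis=0)
    # cost at row i refers to the transition between rows i-1 and i, so a
    # boundary value b (transition between floor(b) and floor(b)+1, with
    # pixel i covering depth [i, i+1)) sits at cost-row index b directly.
    grad = np.vstack([grad[:1], grad])
    sign = 1.0 if polarity == "dark-to-bright" else -1.0
    score = sign * gain * grad
    lo, hi = score.min(), score.max()
    if hi - lo < 1e-15:
        costs = np.full_like(score, 0.5)
    else:
        costs = (hi - score) / (hi - lo)
    return CostMap(costs=costs, polarity=polarity)


def shortest_path_boundary(cost: CostMap, row_band=None, max_step: int = 2) -> np.ndarray:
    """Exact minimum-total-cost left-to-right path through the cost grid.

    The path visits one row per column, moves at most ``max_step`` rows
    between adjacent columns, and stays inside ``row_band`` (inclusive
    [min, max]).  Ties break toward the smaller row index.  Classic
    dynamic program, O(rows * cols * window).
    """
    c = cost.costs if isinstance(cost, CostMap) else np.asarray(cost, dtype=float)
    n_rows, n_cols = c.shape
    if row_band is None:
        row_band = (0, n_rows - 1)
    rmin, rmax = int(row_band[0]), int(row_band[1])
    if rmin > rmax:
        raise ValueError(f"infeasible row band {row_band}")
    rmin = max(rmin, 0)
    rmax = min(rmax, n_rows - 1)
    if rmin > rmax:
        raise ValueError("row band lies outside the image")
    if max_step < 0:
        raise ValueError("max_step must be >= 0")

    band = c[rmin:rmax + 1, :]
    h = band.shape[0]
    size = 2 * max_step + 1

    acc = band[:, 0].copy()
    # Store the windowed minima of each column's accumulated costs so the
    # backward pass can recover argmins with deterministic tie-breaking.
    accs = np.empty((h, n_cols))
    accs[:, 0] = acc
    for j in range(1, n_cols):
        if max_step == 0:
            prev = acc
        else:
            prev = ndimage.minimum_filter1d(acc, size=size, mode="reflect")
            # reflect mode never picks values outside the band because the
            # filter only reflects the array itself (values, not indices).
        acc = band[:, j] + prev
        accs[:, j] = acc

    rows = np.empty(n_cols, dtype=int)
    rows[-1] = int(np.argmin(accs[:, -1]))  # argmin -> first (smallest) row
    for j in range(n_cols - 2, -1, -1):
        r = rows[j + 1]
        lo = max(0, r - max_step)
        hi = min(h - 1, r + max_step)
        window = accs[lo:hi + 1, j]
        rows[j] = lo + int(np.argmin(window))
    return rows + rmin


def _subpixel_refine(costs: np.ndarray, rows: np.ndarray) -> np.ndarray:
    """Parabolic refinement of per-column cost minima around the DP path."""
    n_rows, n_cols = costs.shape
    cols = np.arange(n_cols)
    r = rows.astype(float).copy()
    inner = (rows > 0) & (rows < n_rows - 1)
    ri = rows[inner]
    ci = cols[inner]
    c0 = costs[ri - 1, ci]
    c1 = costs[ri, ci]
    c2 = costs[ri + 1, ci]
    denom = c0 - 2 * c1 + c2
    ok = denom > 1e-12
    delta = np.zeros_like(c1)
    delta[ok] = 0.5 * (c0[ok] - c2[ok]) / denom[ok]
    r[inner] += np.clip(delta, -0.5, 0.5)
    return r


def _initial_band(bscan: BScan, sigma: float) -> tuple:
    """Locate the strongest dark-to-bright edge in the aggregated depth
    profile; used to seed the first boundary's search band."""
    img = np.asarray(bscan.data, dtype=float)
    floor = max(np.median(img) * 1e-3, 1e-12)
    prof = np.median(np.log(np.clip(img, 0, None) + floor), axis=1)
    prof = ndimage.gaussian_filter1d(prof, max(sigma, 1.0))
    g = np.diff(prof)
    r0 = int(np.argmax(g))
    half = max(25, int(12.0 / bscan.axial_pitch_um * 4))
    return max(0, r0 - half), min(img.shape[0] - 2, r0 + half)


def _detect_onh_gap(bscan: BScan, top: np.ndarray, bottom: np.ndarray,
                    grow: int = 20, frac: float = 0.3,
                    extent_frac: float = 0.95) -> np.ndarray:
    """Flag optic-nerve-head columns as invalid; returns a validity mask.

    A column is flagged when its intra-retinal gradient energy falls
    below ``frac`` of the B-scan median, or when the segmented retina
    envelope (bottom - top) is compressed below ``extent_frac`` of its
    median extent (the layered structure converging at the ONH).  The
    flagged run is grown by ``grow`` columns per side, which also covers
    the path-continuity recovery zone next to the gap.
    """
    img = np.asarray(bscan.data, dtype=float)
    n_rows, n_cols = img.shape
    floor = max(np.median(img) * 1e-3, 1e-12)
    g = np.abs(np.diff(np.log(np.clip(img, 0, None) + floor), axis=0))
    rows = np.arange(n_rows - 1)[:, None]
    inside = (rows >= np.floor(top)[None, :]) & (rows <= np.ceil(bottom)[None, :])
    energy = np.where(inside, g, 0.0).sum(axis=0)
    invalid = energy < frac * np.median(energy)
    extent = bottom - top
    invalid |= extent < extent_frac * np.median(extent)
    if grow > 0 and invalid.any():
        invalid = ndimage.binary_dilation(invalid, iterations=grow)
    return ~invalid


def segment(bscan: BScan, schema: LayerSchema | str = NORMAL_SCHEMA,
            variant: VariantParams = DEFAULT_VARIANTS[1]) -> Segmentation:
    """Extract all schema boundaries from one B-scan.

    Boundaries are searched top-to-bottom; each search band is anchored
    to the previous boundary using per-layer plausible thickness bounds,
    which enforces ordering by construction.  The optic-nerve-head gap
    is detected from intra-retinal gradient energy and masked out of
    ``valid_mask``; left and right halves of the image are processed
    independently (the DP is restarted on each side of the gap).

    Raises
    ------
    SegmentationError
        When the image carries no plausible retina (e.g. constant or
        all-background input).
    """
    if isinstance(schema, str):
        schema = get_schema(schema)
    img = np.asarray(bscan.data, dtype=float)
    n_rows, n_cols = img.shape
    min_extent = sum(_GAP_BOUNDS_UM[l][0] for l in schema.layer_names)
    if n_rows * bscan.axial_pitch_um < min_extent + 10:
        raise SegmentationError("image too short for the requested schema")
    if np.ptp(img) < 1e-12:
        raise SegmentationError("constant image: no retina found")

    polarities = _POLARITY[schema.name]
    costmaps = {}
    for pol_sign in set(polarities):
        pol = "dark-to-bright" if pol_sign > 0 else "bright-to-dark"
        costmaps[pol_sign] = boundary_cost(
            bscan, pol, variant.smoothing_sigma, variant.lateral_sigma,
            variant.gradient_gain)

    band0 = _initial_band(bscan, variant.smoothing_sigma)
    pitch = bscan.axial_pitch_um

    boundaries = np.empty((schema.n_boundaries, n_cols))
    prev = None
    for k in range(schema.n_boundaries):
        cm = costmaps[polarities[k]]
        if k == 0:
            rows = shortest_path_boundary(cm, band0, variant.max_step)
            # sanity: the surface edge must stand well above the image's
            # own gradient noise, else there is no retina to segment
            floor = max(np.median(img) * 1e-3, 1e-12)
            g_raw = np.diff(np.log(np.clip(img, 0, None) + floor), axis=0)
            g_raw = np.vstack([g_raw[:1], g_raw])
            along = np.median(g_raw[rows, np.arange(n_cols)])
            noise = np.median(np.abs(g_raw))
            if along < 4.0 * max(noise, 1e-12):
                raise SegmentationError("no plausible retina: weak surface edge")
        else:
            layer = schema.layer_names[k - 1]
            lo_um, hi_um = _GAP_BOUNDS_UM[layer]
            lo = np.floor(prev + lo_um / pitch).astype(int)
            hi = np.ceil(prev + hi_um / pitch).astype(int)
            hi = np.minimum(hi, n_rows - 1)
            lo = np.minimum(lo, hi)
            masked = cm.costs.copy()
            rr = np.arange(n_rows)[:, None]
            if layer in _DEPTH_PENALTY_LAYERS:
                masked += _DEPTH_PENALTY_PER_ROW * np.clip(rr - lo[None, :], 0, None)
            masked[(rr < lo[None, :]) | (rr > hi[None, :])] += 10.0
            rows = shortest_path_boundary(
                CostMap(masked, cm.polarity),
                (int(lo.min()), int(hi.max())), variant.max_step)
        sub = _subpixel_refine(cm.costs, rows)
        if prev is not None:
            sub = np.maximum(sub, prev)  # keep ordering after refinement
        boundaries[k] = sub
        prev = np.maximum(rows.astype(float), prev) if prev is not None else rows.astype(float)

    valid = _detect_onh_gap(bscan, boundaries[0], boundaries[-1])
    return Segmentation(schema=schema, boundaries=boundaries,
                        valid_mask=valid, source_model=variant.name)


def segment_all_variants(bscan: BScan, schema=NORMAL_SCHEMA,
                         variants=DEFAULT_VARIANTS) -> list:
    """Run every segmenter variant on one image."""
    return [segment(bscan, schema, v) for v in variants]


def ensemble_median(segs) -> Segmentation:
    """Per-boundary, per-A-scan median of several segmentations.

    Even counts use the mean of the two central values (numpy median).
    ``valid_mask`` is the AND of the inputs.  All inputs must share one
    schema and width.
    """
    segs = list(segs)
    if not segs:
        raise ValueError("need at least one segmentation")
    schema = segs[0].schema
    width = segs[0].n_ascans
    for s in segs[1:]:
        if s.schema.name != schema.name or s.n_ascans != width:
            raise ValueError("all segmentations must share schema and width")
    stack = np.stack([s.boundaries for s in segs])
    med = np.median(stack, axis=0)
    valid = np.logical_and.reduce([s.valid_mask for s in segs])
    return Segmentation(schema=schema, boundaries=med, valid_mask=valid,
                        source_model="Model_median")


def dice_score(seg_a: Segmentation, seg_b: Segmentation, layer_name: str,
               image_height: int) -> float:
    """DICE overlap 2|A∩B| / (|A|+|B|) of one layer's pixel masks,
    restricted to jointly valid A-scans.  Both masks empty -> 1.0."""
    if seg_a.schema.name != seg_b.schema.name or seg_a.n_ascans != seg_b.n_ascans:
        raise ValueError("segmentations must share schema and width")
    both = seg_a.valid_mask & seg_b.valid_mask
    ma = seg_a.layer_mask(layer_name, image_height) & both[None, :]
    mb = seg_b.layer_mask(layer_name, image_height) & both[None, :]
    denom = int(ma.sum()) + int(mb.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((ma & mb).sum()) / denom


def usage_rate(selections, model_ids) -> dict:
    """Fraction of images for which each model was chosen as best fit."""
    selections = list(selections)
    if not selections:
        raise ValueError("empty selection list")
    ids = list(model_ids)
    bad = set(selections) - set(ids)
    if bad:
        raise ValueError(f"selections not in model_ids: {sorted(bad)}")
    counts = Counter(selections)
    total = len(selections)
    return {m: counts.get(m, 0) / total for m in ids}
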