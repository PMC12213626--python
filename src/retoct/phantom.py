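"""Synthetic mouse-retina B-scan generator with ground truth.

Renders layered-retina OCT phantoms across a sodium-iodate degeneration
time course: per-layer reflectivity and attenuation, cumulative two-way
beam attenuation, fully developed multiplicative speckle with frame
averaging, an optic-nerve-head wedge at the image centre, and
hyper-reflective vitreous particles.  Every image is paired with exact
sub-pixel ground truth so downstream segmentation, reflectance and
morphometry code can be validated against the generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .bscan import BScan
from .segmentation import (DEGENERATIVE_SCHEMA, NORMAL_SCHEMA, LayerSchema,
                           Segmentation, get_schema)
from .timecourse import fit_exp_decay

__all__ = [
    "PhantomParams",
    "DegenerationModel",
    "PhantomTruth",
    "LayerProfile",
    "StudyDesign",
    "StudyImage",
    "StudyDataset",
    "PhantomConfigError",
    "PhantomGeometryError",
    "DEFAULT_TIMECOURSE_UM",
    "TIMEPOINT_DAYS",
    "BASELINE_CHOROID_UM",
    "make_profile",
    "render_bscan",
    "simulate_study",
]


class PhantomConfigError(ValueError):
    """Bad generator configuration (unknown layer, invalid override)."""


class PhantomGeometryError(ValueError):
    """Requested layer stack does not fit in the image."""


#: Captured timepoints, days post injection (0 = baseline).
TIMEPOINT_DAYS = (0.0, 1.0, 3.0, 6.0, 13.0, 20.0)

#: Group-mean layer thicknesses (um) over the degeneration time course;
#: the ground truth the phantom emulates.  OR = photoreceptor segments
#: + RPE complex ("outer retina").
DEFAULT_TIMECOURSE_UM = {
    "NFL": (14.63, 15.77, 16.21, 16.08, 15.01, 15.06),
    "IPL": (51.25, 52.62, 50.22, 47.53, 43.89, 43.19),
    "INL": (25.76, 27.54, 33.35, 32.72, 24.99, 22.52),
    "OPL": (15.99, 16.67, 21.67, 17.27, 15.44, 13.94),
    "ONL": (63.30, 53.63, 38.08, 31.60, 22.07, 16.81),
    "OR": (57.83, 47.56, 46.86, 27.32, 16.36, 13.07),
}

#: Baseline choroid thickness (um); the series below thins with time.
BASELINE_CHOROID_UM = 88.6
DEFAULT_CHOROID_SERIES_UM = (88.6, 82.0, 76.0, 70.0, 64.0, 60.0)

#: Expected in-range vitreous particle count per image: sharp rise at
#: day 1, decay back to baseline by day 13.
DEFAULT_PARTICLE_SERIES = (2.0, 30.0, 20.0, 12.0, 3.0, 2.0)

# Mean linear backscatter per layer (arbitrary units).  "IS", "dip" and
# "OS" are render-time sub-bands of the IS+OS layer that create the
# hyper/hypo-reflective photoreceptor banding behind the Dip ratio.
DEFAULT_REFLECTIVITY = {
    "vitreous": 0.0, "NFL": 220.0, "IPL": 120.0, "INL": 45.0,
    "OPL": 130.0, "ONL": 40.0, "IS+OS": 150.0, "IS": 230.0, "dip": 35.0,
    "OS": 180.0, "RPE": 300.0, "OR": 200.0, "choroid": 90.0, "sclera": 40.0,
}

# Attenuation coefficients, 1/m.
DEFAULT_ATTENUATION_M1 = {
    "vitreous": 0.0, "NFL": 2000.0, "IPL": 1500.0, "INL": 800.0,
    "OPL": 1500.0, "ONL": 600.0, "IS+OS": 3000.0, "RPE": 6000.0,
    "OR": 4000.0, "choroid": 2500.0, "sclera": 1500.0,
}

# Fractional split of the IS+OS band into IS peak / hyporeflective dip /
# OS sub-bands (top to bottom).  The OS fraction keeps the internal
# dip->OS edge well clear of the lower-boundary search band.
_ISOS_SUBBANDS = (("IS", 0.30), ("dip", 0.20), ("OS", 0.50))


@dataclass
class PhantomParams:
    """Geometry, optics and noise configuration of the generator.

    All physical quantities are in micrometers and 1/m; conversion to
    pixels happens only at render time.
    """

    axial_pitch_um: float = 1.7
    lateral_pitch_um: float = 1.4
    image_height_px: int = 512
    n_ascans: int = 1000
    retina_top_px: float = 130.0
    layer_thickness_um: dict = field(default_factory=dict)   # overrides
    layer_reflectivity: dict = field(default_factory=dict)   # overrides
    layer_attenuation_m1: dict = field(default_factory=dict)  # overrides
    background_level: float = 40.0
    speckle_shape: float | None = 40.0  # frames averaged; None = noise-free
    onh_center_col: int | None = None   # None -> image centre
    onh_width_px: int = 90              # 0 disables the ONH wedge
    particle_rate: float | None = None  # None -> degeneration model series
    particle_area_px_range: tuple = (8, 80)
    particle_reflectivity: float = 500.0
    particle_spread_px: float = 120.0
    seed: int | None = None

    def __post_init__(self):
        if self.axial_pitch_um <= 0 or self.lateral_pitch_um <= 0:
            raise PhantomConfigError("pixel pitches must be positive")
        if self.image_height_px < 4 or self.n_ascans < 1:
            raise PhantomConfigError("image dimensions too small")
        for name, t in self.layer_thickness_um.items():
            if t <= 0:
                raise PhantomConfigError(f"thickness of {name!r} must be > 0")
        for name, a in self.layer_attenuation_m1.items():
            if a < 0:
                raise PhantomConfigError(f"attenuation of {name!r} must be >= 0")
        if self.onh_center_col is not None and not (
                0 <= self.onh_center_col < self.n_ascans):
            raise PhantomConfigError("onh_center_col outside the image")
        lo, hi = self.particle_area_px_range
        if not (0 < lo <= hi):
            raise PhantomConfigError("invalid particle area range")

    @property
    def onh_col(self) -> int:
        return self.n_ascans // 2 if self.onh_center_col is None else self.onh_center_col

    def reflectivity(self, name: str) -> float:
        return self.layer_reflectivity.get(name, DEFAULT_REFLECTIVITY[name])

    def attenuation(self, name: str) -> float:
        return self.layer_attenuation_m1.get(name, DEFAULT_ATTENUATION_M1[name])


@dataclass
class DegenerationModel:
    """Longitudinal ground-truth model driving the phantom time course.

    ONL thins as ``C + A*exp(-k*t)``; inner layers follow piecewise-
    linear biphasic profiles through the reference time course; the
    photoreceptor/RPE complex merges into a single OR band at
    ``merge_day``; the choroid thins; vitreous particles spike early and
    regress.  ``eac_onl_elevation`` scales the per-eye link between the
    day-1 ONL attenuation rise and the final amount of ONL loss.
    """

    onl_floor_C: float
    onl_amplitude_A: float
    onl_rate_k: float
    inner_layer_biphasic: dict = field(default_factory=dict)  # layer -> series
    or_series_um: tuple = DEFAULT_TIMECOURSE_UM["OR"]
    rpe_base_um: float = 10.0
    rpe_swelling_um: float = 0.5
    choroid_series_um: tuple = DEFAULT_CHOROID_SERIES_UM
    merge_day: float = 6.0
    particle_series: tuple = DEFAULT_PARTICLE_SERIES
    eac_onl_elevation: float = 0.10
    onl_atten_rise: float = 0.25      # fractional ONL attenuation rise, day >= 1
    rpe_atten_drop: float = 0.22      # fractional RPE attenuation drop by day 3
    dip_fill_series: tuple = (0.0, 0.10, 0.50)  # at days 0, 1, 3
    days: tuple = TIMEPOINT_DAYS

    @classmethod
    def default(cls) -> "DegenerationModel":
        """Model whose ONL decay is the least-squares fit of
        C + A*exp(-k t) to the reference time-course means."""
        fit = fit_exp_decay(TIMEPOINT_DAYS, DEFAULT_TIMECOURSE_UM["ONL"])
        inner = {name: DEFAULT_TIMECOURSE_UM[name]
                 for name in ("NFL", "IPL", "INL", "OPL")}
        return cls(onl_floor_C=fit.floor_C, onl_amplitude_A=fit.amplitude_A,
                   onl_rate_k=fit.rate_k, inner_layer_biphasic=inner)

    def onl_um(self, day: float) -> float:
        return self.onl_floor_C + self.onl_amplitude_A * np.exp(-self.onl_rate_k * day)

    def _interp(self, series, day: float) -> float:
        return float(np.interp(day, self.days, series))

    def inner_um(self, layer: str, day: float) -> float:
        return self._interp(self.inner_layer_biphasic[layer], day)

    def or_um(self, day: float) -> float:
        return self._interp(self.or_series_um, day)

    def rpe_um(self, day: float) -> float:
        swell = float(np.interp(day, (0.0, 1.0), (0.0, self.rpe_swelling_um)))
        return self.rpe_base_um + swell

    def choroid_um(self, day: float) -> float:
        return self._interp(self.choroid_series_um, day)

    def particle_rate(self, day: float) -> float:
        return self._interp(self.particle_series, day)

    def onl_atten_factor(self, day: float) -> float:
        return float(np.interp(day, (0.0, 1.0), (1.0, 1.0 + self.onl_atten_rise)))

    def rpe_atten_factor(self, day: float) -> float:
        return float(np.interp(day, (0.0, 1.0, 3.0),
                               (1.0, 1.0 - 0.8 * self.rpe_atten_drop,
                                1.0 - self.rpe_atten_drop)))

    def dip_fill(self, day: float) -> float:
        return float(np.interp(day, (0.0, 1.0, 3.0), self.dip_fill_series))


@dataclass
class LayerProfile:
    """Per-layer thickness/reflectivity/attenuation snapshot for one day.

    ``segments`` is the render-time expansion (IS+OS split into IS, dip
    and OS sub-bands); ``thickness_um`` keeps the schema-level layers.
    """

    schema: LayerSchema
    day: float
    thickness_um: dict
    reflectivity: dict
    attenuation_m1: dict
    segments: list  # (name, thickness_um, reflectivity, attenuation_m1)

    @property
    def total_um(self) -> float:
        return float(sum(self.thickness_um.values()))


@dataclass
class PhantomTruth:
    """Generator-side ground truth paired with a rendered B-scan."""

    schema_name: str
    boundaries: np.ndarray          # (n_boundaries, n_ascans), sub-pixel rows
    layer_attenuation_m1: dict
    layer_reflectivity: dict
    thickness_um: dict
    particles: list                 # (centroid_row, centroid_col, area_px)
    onh_center_col: int
    valid_mask: np.ndarray          # False inside the ONH gap
    day: float = 0.0

    def to_segmentation(self) -> Segmentation:
        return Segmentation(schema=get_schema(self.schema_name),
                            boundaries=self.boundaries.copy(),
                            valid_mask=self.valid_mask.copy(),
                            source_model="truth")


def make_profile(params: PhantomParams, model: DegenerationModel, day: float,
                 schema: LayerSchema | str | None = None) -> LayerProfile:
    """Per-layer thickness and optics profile for one post-injection day.

    ONL thickness follows the closed-form decay ``C + A*exp(-k*day)``;
    inner layers interpolate their biphasic series; from ``merge_day``
    on the degenerative schema replaces IS+OS and RPE with a single OR
    band.  ``params.layer_thickness_um`` entries override the model
    (unknown layer names raise :class:`PhantomConfigError`).
    """
    if day < 0:
        raise PhantomConfigError("day must be >= 0")
    if schema is None:
        schema = DEGENERATIVE_SCHEMA if day >= model.merge_day else NORMAL_SCHEMA
    elif isinstance(schema, str):
        schema = get_schema(schema)

    thickness = {}
    for layer in schema.layer_names:
        if layer in ("NFL", "IPL", "INL", "OPL"):
            thickness[layer] = model.inner_um(layer, day)
        elif layer == "ONL":
            thickness[layer] = model.onl_um(day)
        elif layer == "RPE":
            thickness[layer] = model.rpe_um(day)
        elif layer == "IS+OS":
            thickness[layer] = model.or_um(day) - model.rpe_um(day)
        elif layer == "OR":
            thickness[layer] = model.or_um(day)
        elif layer == "choroid":
            thickness[layer] = model.choroid_um(day)
        else:  # pragma: no cover - schemas are fixed
            raise PhantomConfigError(f"no thickness rule for layer {layer!r}")

    unknown = set(params.layer_thickness_um) - set(schema.layer_names)
    if unknown:
        raise PhantomConfigError(
            f"thickness overrides for unknown layers: {sorted(unknown)}")
    thickness.update(params.layer_thickness_um)
    for layer, t in thickness.items():
        if t <= 0:
            raise PhantomConfigError(f"layer {layer!r} has non-positive "
                                     f"thickness {t:.2f} um at day {day:g}")

    refl = {l: params.reflectivity(l) for l in schema.layer_names}
    atten = {l: params.attenuation(l) for l in schema.layer_names}
    # degeneration changes scattering: backscatter and attenuation move
    # together (ONL up from day 1, RPE down), which is what makes the
    # reflectance readouts sensitive to them
    f_onl = model.onl_atten_factor(day)
    atten["ONL"] *= f_onl
    refl["ONL"] *= f_onl
    if "RPE" in atten:
        f_rpe = model.rpe_atten_factor(day)
        atten["RPE"] *= f_rpe
        refl["RPE"] *= f_rpe

    segments = []
    for layer in schema.layer_names:
        if layer == "IS+OS":
            fill = model.dip_fill(day)
            dip_refl = params.reflectivity("dip") + fill * (
                params.reflectivity("IS") - params.reflectivity("dip"))
            sub_refl = {"IS": params.reflectivity("IS"), "dip": dip_refl,
                        "OS": params.reflectivity("OS")}
            for sub, frac in _ISOS_SUBBANDS:
                segments.append((f"IS+OS:{sub}", thickness[layer] * frac,
                                 sub_refl[sub], atten[layer]))
        else:
            segments.append((layer, thickness[layer], refl[layer], atten[layer]))

    return LayerProfile(schema=schema, day=day, thickness_um=thickness,
                        reflectivity=refl, attenuation_m1=atten,
                        segments=segments)


def _segment_stack(profile: LayerProfile, params: PhantomParams):
    """Render segments (incl. vitreous and sclera) in pixel units."""
    pitch = params.axial_pitch_um
    names, lens_px, refls, attens = ["vitreous"], [params.retina_top_px], \
        [params.reflectivity("vitreous")], [params.attenuation("vitreous")]
    for name, t_um, r, a in profile.segments:
        names.append(name)
        lens_px.append(t_um / pitch)
        refls.append(r)
        attens.append(a)
    bottom = params.retina_top_px + sum(lens_px[1:])
    names.append("sclera")
    lens_px.append(max(params.image_height_px - bottom, 0.0))
    refls.append(params.reflectivity("sclera"))
    attens.append(params.attenuation("sclera"))
    return names, np.array(lens_px), np.array(refls), np.array(attens)


def _wedge_factor(params: PhantomParams) -> np.ndarray:
    """Per-column layer-collapse factor: 1 outside the ONH, ramping to 0
    at its centre so all boundaries converge toward the retina top."""
    cols = np.arange(params.n_ascans)
    if params.onh_width_px <= 0:
        return np.ones(params.n_ascans)
    half = params.onh_width_px / 2.0
    return np.clip(np.abs(cols - params.onh_col) / half, 0.0, 1.0)


def _noise_free_image(bounds_px: np.ndarray, refls, attens,
                      params: PhantomParams) -> np.ndarray:
    """Exact area-weighted rendering of the piecewise attenuation model.

    ``bounds_px``: (n_segments+1, n_ascans) segment edges, sub-pixel.
    Pixel (i, c) receives the integral over depth [i, i+1) of
    R(z) * exp(-2 * mu_cum(z)), evaluated in closed form per segment.
    """
    H, W = params.image_height_px, params.n_ascans
    dm = params.axial_pitch_um * 1e-6  # meters per pixel
    n_seg = len(refls)
    lens = np.diff(bounds_px, axis=0)                      # (n_seg, W)
    tau_step = 2.0 * np.asarray(attens)[:, None] * dm * lens
    tau_at_start = np.vstack([np.zeros(W), np.cumsum(tau_step, axis=0)])[:-1]

    z = np.arange(H + 1, dtype=float)[:, None]             # (H+1, 1)
    A = np.zeros((H + 1, W))
    for k in range(n_seg):
        s = bounds_px[k][None, :]
        e = bounds_px[k + 1][None, :]
        zc = np.clip(z, s, e)
        mu2 = 2.0 * attens[k] * dm                          # per pixel depth
        amp = refls[k] * np.exp(-tau_at_start[k])[None, :]
        if mu2 > 1e-300:
            A += amp / mu2 * (1.0 - np.exp(-mu2 * (zc - s)))
        else:
            A += amp * (zc - s)
    return np.diff(A, axis=0)


def _draw_particles(signal: np.ndarray, top_boundary: np.ndarray,
                    params: PhantomParams, rate: float, rng) -> list:
    """Add hyper-reflective blobs in the vitreous, clustered laterally
    around the ONH; returns (row, col, rasterised_area_px) records."""
    H, W = signal.shape
    particles = []
    n = rng.poisson(rate) if rate > 0 else 0
    lo, hi = params.particle_area_px_range
    for _ in range(n):
        col = rng.normal(params.onh_col, params.particle_spread_px)
        col = int(np.clip(col, 4, W - 5))
        target = rng.uniform(lo, hi)
        r = max(np.sqrt(target / np.pi), 0.9)
        top_limit = float(top_boundary[col])
        rmin = r + 2.0
        rmax = top_limit - r - 4.0
        if rmax <= rmin:
            continue
        row = rng.uniform(rmin, rmax)
        # rasterise, nudging the radius until the pixel count is in range
        for _ in range(8):
            rr0, rr1 = int(np.floor(row - r)), int(np.ceil(row + r)) + 1
            cc0, cc1 = int(np.floor(col - r)), int(np.ceil(col + r)) + 1
            rr0, cc0 = max(rr0, 0), max(cc0, 0)
            rr1, cc1 = min(rr1, H), min(cc1, W)
            yy, xx = np.mgrid[rr0:rr1, cc0:cc1]
            mask = (yy - row) ** 2 + (xx - col) ** 2 <= r ** 2
            area = int(mask.sum())
            if lo <= area <= hi:
                break
            r *= 0.92 if area > hi else 1.08
        if not (lo <= area <= hi):
            continue
        sub = signal[rr0:rr1, cc0:cc1]
        sub[mask] += params.particle_reflectivity
        particles.append((float(row), float(col), area))
    return particles


def render_bscan(profile: LayerProfile, params: PhantomParams,
                 seed=None, particle_rate: float | None = None):
    """Render one B-scan and its ground truth.

    Returns ``(BScan, PhantomTruth)``.  The linear-scale image is the
    closed-form reflectivity/attenuation model plus additive background,
    multiplied by per-pixel speckle (mean of ``speckle_shape``
    independent exponential draws, i.e. a Gamma variate).  ``seed`` may
    be an int or a ``numpy.random.Generator``.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(params.seed if seed is None else seed)
    H, W = params.image_height_px, params.n_ascans

    names, lens_px, refls, attens = _segment_stack(profile, params)
    retina_px = float(lens_px[1:-1].sum())
    if params.retina_top_px + retina_px > H:
        raise PhantomGeometryError(
            f"layer stack ({retina_px:.0f} px below row "
            f"{params.retina_top_px:.0f}) does not fit in {H} rows")

    wedge = _wedge_factor(params)                           # (W,)
    cum = np.concatenate([[0.0], np.cumsum(lens_px)])       # flat edges
    bounds = np.repeat(cum[:, None], W, axis=1)
    # collapse layers toward the retina top inside the ONH wedge; row 0
    # (image top) and the last row (image bottom) stay put
    bounds[1:-1] = params.retina_top_px + \
        (bounds[1:-1] - params.retina_top_px) * wedge[None, :]
    bounds[-1] = H

    signal = _noise_free_image(bounds, refls, attens, params)

    rate = particle_rate if particle_rate is not None else (
        params.particle_rate if params.particle_rate is not None else 0.0)
    particles = _draw_particles(signal, bounds[1], params, rate, rng)

    total = signal + params.background_level
    if params.speckle_shape:
        shape = float(params.speckle_shape)
        total = total * rng.gamma(shape, 1.0 / shape, size=total.shape)

    # layer-level boundaries: drop sub-band edges (e.g. IS/dip/OS inside
    # IS+OS).  bounds row 0 is the image top, row 1 + i the start of
    # rendered segment i, so a boundary sits wherever the base layer
    # name changes, plus the start and end of the stack.
    schema = profile.schema
    base = [name.split(":")[0] for name, *_ in profile.segments]
    keep = [0] + [i for i in range(1, len(base)) if base[i] != base[i - 1]] \
        + [len(base)]
    schema_bounds = bounds[np.array(keep) + 1]

    valid = wedge >= 1.0
    truth = PhantomTruth(
        schema_name=schema.name,
        boundaries=schema_bounds.copy(),
        layer_attenuation_m1=dict(profile.attenuation_m1),
        layer_reflectivity=dict(profile.reflectivity),
        thickness_um=dict(profile.thickness_um),
        particles=particles,
        onh_center_col=params.onh_col,
        valid_mask=valid,
        day=profile.day,
    )
    bscan = BScan(data=total, axial_pitch_um=params.axial_pitch_um,
                  lateral_pitch_um=params.lateral_pitch_um, scale="linear",
                  meta={"background_level": params.background_level,
                        "day": profile.day, "schema": schema.name})
    return bscan, truth


@dataclass
class StudyDesign:
    n_mice: int = 7
    eyes_per_mouse: int = 2
    bscans_per_eye: int = 4
    timepoints: tuple = TIMEPOINT_DAYS

    def __post_init__(self):
        if min(self.n_mice, self.eyes_per_mouse, self.bscans_per_eye) < 1 \
                or len(self.timepoints) < 1:
            raise PhantomConfigError("design values must be >= 1")

    @property
    def n_eyes(self) -> int:
        return self.n_mice * self.eyes_per_mouse

    @property
    def images_per_timepoint(self) -> int:
        return self.n_eyes * self.bscans_per_eye

    @property
    def total_images(self) -> int:
        return self.images_per_timepoint * len(self.timepoints)


@dataclass
class StudyImage:
    mouse: int
    eye: int
    day: float
    scan: int
    bscan: BScan
    truth: PhantomTruth
    severity: float = 0.0


@dataclass
class _EyeEffects:
    severity: float          # latent z-score shared across days
    atten_noise: float       # independent reflectance noise, same scale
    thickness_jitter: dict   # layer -> um offset, held across days


class StudyDataset:
    """Lazy, deterministic longitudinal phantom study.

    Per-eye random effects (latent severity, small thickness jitter) are
    drawn once per eye from ``structure_seed`` and held across days, so
    longitudinal correlation structure exists and ground-truth thickness
    means are identical across different speckle seeds.  Per-image noise
    (speckle, particles) derives from ``seed``.
    """

    def __init__(self, design: StudyDesign, params: PhantomParams,
                 model: DegenerationModel, seed: int = 0,
                 structure_seed: int = 0):
        self.design = design
        self.params = params
        self.model = model
        self.seed = seed
        self.structure_seed = structure_seed
        self._effects = {}
        for m in range(design.n_mice):
            for e in range(design.eyes_per_mouse):
                rng = np.random.default_rng([structure_seed, m, e])
                z = float(np.clip(rng.normal(), -2.0, 2.0))
                eta = float(np.clip(rng.normal(), -2.0, 2.0))
                jit = {layer: float(rng.normal(0.0, 0.6))
                       for layer in ("NFL", "IPL", "INL", "OPL", "choroid")}
                self._effects[(m, e)] = _EyeEffects(z, eta, jit)

    def eye_severity(self, mouse: int, eye: int) -> float:
        return self._effects[(mouse, eye)].severity

    def eye_model(self, mouse: int, eye: int) -> DegenerationModel:
        """Degeneration model adjusted by the eye's latent severity.

        Severity z shifts decay floor and amplitude in opposition, so the
        baseline ONL (C + A) is unchanged while the total ONL loss varies
        with z; the day-1 ONL attenuation rise carries z plus an equally
        sized independent component, putting the designed R^2 between
        day-1 ONL reflectance and final ONL loss at ~0.5.
        """
        eff = self._effects[(mouse, eye)]
        shift = 0.30 * self.model.onl_floor_C * eff.severity
        floor = max(self.model.onl_floor_C - shift, 2.0)
        amp = self.model.onl_amplitude_A + shift
        rise = self.model.onl_atten_rise + self.model.eac_onl_elevation * (
            eff.severity + eff.atten_noise)
        return replace(self.model, onl_floor_C=floor, onl_amplitude_A=amp,
                       onl_atten_rise=max(rise, 0.0))

    def profile(self, mouse: int, eye: int, day: float) -> LayerProfile:
        model = self.eye_model(mouse, eye)
        prof = make_profile(self.params, model, day)
        jit = self._effects[(mouse, eye)].thickness_jitter
        for layer, dz in jit.items():
            if layer in prof.thickness_um:
                prof.thickness_um[layer] = max(prof.thickness_um[layer] + dz, 1.0)
        # rebuild segments with the jittered thicknesses
        segs = []
        for name, t, r, a in prof.segments:
            base = name.split(":")[0]
            if base in jit:
                frac = t / sum(s[1] for s in prof.segments
                               if s[0].split(":")[0] == base)
                t = max(prof.thickness_um[base], 1.0) * frac
            segs.append((name, t, r, a))
        prof.segments = segs
        return prof

    def render(self, mouse: int, eye: int, day: float, scan: int) -> StudyImage:
        day_idx = list(self.design.timepoints).index(day)
        rng = np.random.default_rng([self.seed, mouse, eye, day_idx, scan])
        prof = self.profile(mouse, eye, day)
        rate = self.params.particle_rate if self.params.particle_rate is not None \
            else self.model.particle_rate(day)
        bscan, truth = render_bscan(prof, self.params, seed=rng,
                                    particle_rate=rate)
        return StudyImage(mouse, eye, day, scan, bscan, truth,
                          severity=self.eye_severity(mouse, eye))

    def __iter__(self):
        for day in self.design.timepoints:
            for m in range(self.design.n_mice):
                for e in range(self.design.eyes_per_mouse):
                    for s in range(self.design.bscans_per_eye):
                        yield self.render(m, e, day, s)

    def __len__(self) -> int:
        return self.design.total_images

    def truth_thickness_table(self):
        """Ground-truth per-eye, per-day layer thicknesses (no rendering)."""
        import pandas as pd
        rows = []
        for day in self.design.timepoints:
            for m in range(self.design.n_mice):
                for e in range(self.design.eyes_per_mouse):
                    prof = self.profile(m, e, day)
                    for layer, t in prof.thickness_um.items():
                        rows.append({"mouse": m, "eye": e, "day": day,
                                     "layer": layer, "thickness_um": t})
        return pd.DataFrame(rows)


def simulate_study(design: StudyDesign, params: PhantomParams,
                   model: DegenerationModel, seed: int = 0,
                   structure_seed: int = 0) -> StudyDataset:
    """Build a lazy study dataset; see :class:`StudyDataset`."""
    return StudyDataset(design, params, model, seed=seed,
                        structure_seed=structure_seed)
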