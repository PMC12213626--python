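"""End-to-end study orchestration.

phantom generation -> multi-variant segmentation + median ensembling ->
thickness / eAC / Dip-ratio / particle measurement -> eye-level
aggregation -> time-course statistics.  Fully seeded; per-image
failures are recorded and the run continues.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import morphometry, reflectance, segmentation, timecourse, vitreous
from .bscan import BScan
from .phantom import (DegenerationModel, PhantomParams, StudyDesign,
                      simulate_study)
from .segmentation import DEFAULT_VARIANTS, SegmentationError

__all__ = ["RunConfig", "StudyResult", "run_study", "measure_image"]

#: Layers whose mean log10 eAC is tracked per eye/day.
EAC_LAYERS = ("ONL", "RPE", "OR")


@dataclass
class RunConfig:
    """Serializable description of one reproducible study run."""

    design: dict = field(default_factory=dict)
    phantom: dict = field(default_factory=dict)
    model: dict | None = None          # None -> DegenerationModel.default()
    variants: list = field(default_factory=lambda: [v.name for v in DEFAULT_VARIANTS])
    seed: int = 0
    structure_seed: int = 0
    use_truth_boundaries: bool = False
    n_boot: int = 1000

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    def build(self):
        design = StudyDesign(**{**self.design,
                                "timepoints": tuple(self.design.get(
                                    "timepoints", StudyDesign().timepoints))})
        phantom_kwargs = dict(self.phantom)
        for key in ("particle_area_px_range",):
            if key in phantom_kwargs:
                phantom_kwargs[key] = tuple(phantom_kwargs[key])
        params = PhantomParams(**phantom_kwargs)
        if self.model is None:
            model = DegenerationModel.default()
        else:
            m = dict(self.model)
            for key in ("or_series_um", "choroid_series_um", "particle_series",
                        "dip_fill_series", "days"):
                if key in m:
                    m[key] = tuple(m[key])
            if "inner_layer_biphasic" in m:
                m["inner_layer_biphasic"] = {
                    k: tuple(v) for k, v in m["inner_layer_biphasic"].items()}
            model = DegenerationModel(**m)
        names = set(self.variants)
        variants = [v for v in DEFAULT_VARIANTS if v.name in names]
        if len(variants) != len(names):
            raise ValueError(f"unknown variant names in {sorted(names)}")
        return design, params, model, variants

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class StudyResult:
    study_table: pd.DataFrame
    summary: pd.DataFrame
    decay_fit: timecourse.ExpDecayFit | None
    correlation: timecourse.CorrelationResult | None
    ttests: pd.DataFrame
    failures: list
    manifest: dict

    @property
    def ok(self) -> bool:
        return not self.failures


def _estimate_background_region(bscan: BScan, seg) -> np.ndarray:
    """Particle-poor vitreous patch: rows well above the retina surface,
    outer image columns (particles cluster near the ONH)."""
    top = int(np.floor(seg.boundaries[0].min())) - 12
    H, W = bscan.data.shape
    top = max(min(top, H), 4)
    mask = np.zeros((H, W), dtype=bool)
    edge = max(W // 10, 8)
    mask[2:top, :edge] = True
    mask[2:top, W - edge:] = True
    return mask


def measure_image(bscan: BScan, schema, variants=DEFAULT_VARIANTS,
                  truth=None, use_truth_boundaries: bool = False) -> dict:
    """Segment one image and compute every per-image readout.

    Returns a dict with the ensemble segmentation, detected ONH column,
    ROI column ranges, per-ROI layer thicknesses, per-ROI layer eAC
    summaries, the Dip ratio (intact schema only) and the vitreous
    particle count.
    """
    if use_truth_boundaries:
        if truth is None:
            raise ValueError("use_truth_boundaries requires the phantom truth")
        ens = truth.to_segmentation()
    else:
        segs = [segmentation.segment(bscan, schema, v) for v in variants]
        ens = segmentation.ensemble_median(segs) if len(segs) > 1 else segs[0]

    onh = morphometry.locate_onh(ens)
    rois = morphometry.select_rois(onh, bscan.lateral_pitch_um, bscan.n_ascans)

    thickness = {side: morphometry.layer_thickness(ens, roi, bscan.axial_pitch_um)
                 for side, roi in rois.items()}

    bg = _estimate_background_region(bscan, ens)
    lin = reflectance.linearize(bscan, vitreous_region=bg)
    eac = reflectance.compute_eac(lin)
    eac_stats = {}
    for side, roi in rois.items():
        for layer in EAC_LAYERS:
            if layer in ens.schema.layer_names:
                eac_stats[(side, layer)] = reflectance.layer_eac(eac, ens, layer, roi)

    dip = {}
    if "IS+OS" in ens.schema.layer_names:
        for side, roi in rois.items():
            dip[side] = reflectance.dip_ratio(lin, ens, roi)

    vit = vitreous.vitreous_mask(bscan, ens, margin_px=2.0)
    particles = vitreous.count_particles(vit)

    return {"segmentation": ens, "onh_col": onh, "rois": rois,
            "thickness": thickness, "eac": eac_stats, "dip": dip,
            "particles": particles}


def _eye_rows(mouse, eye, day, per_scan) -> list:
    """Collapse one eye/day's per-scan measurements to StudyTable rows."""
    rows = []
    thick = {}
    eac = {}
    dips = []
    counts = []
    for m in per_scan:
        for side, layers in m["thickness"].items():
            for layer, v in layers.items():
                thick.setdefault(layer, []).append(v)
        for (side, layer), res in m["eac"].items():
            if res.n_pixels > 0:
                eac.setdefault(layer, []).append(res.mean_log10)
        dips.extend(v for v in m["dip"].values() if np.isfinite(v))
        counts.append(m["particles"].count)

    def add(layer, metric, values):
        vals = [v for v in values if np.isfinite(v)]
        if vals:
            rows.append({"mouse": mouse, "eye": eye, "day": day, "layer": layer,
                         "metric": metric, "value": float(np.mean(vals)),
                         "n": len(vals)})

    for layer, vals in thick.items():
        add(layer, "thickness_um", vals)
    for layer, vals in eac.items():
        add(layer, "log10_eac", vals)
    add("IS+OS", "dip_ratio", dips)
    add("vitreous", "particle_count", [float(c) for c in counts])
    return rows


def run_study(config: RunConfig) -> StudyResult:
    """Run a full simulated study from a :class:`RunConfig`.

    Per-image errors (segmentation failure, infeasible ROI) are recorded
    in ``failures`` and the run continues.
    """
    design, params, model, variants = config.build()
    dataset = simulate_study(design, params, model, seed=config.seed,
                             structure_seed=config.structure_seed)
    rows = []
    failures = []
    for day in design.timepoints:
        for m in range(design.n_mice):
            for e in range(design.eyes_per_mouse):
                per_scan = []
                for s in range(design.bscans_per_eye):
                    img = dataset.render(m, e, day, s)
                    try:
                        per_scan.append(measure_image(
                            img.bscan, img.truth.schema_name, variants,
                            truth=img.truth,
                            use_truth_boundaries=config.use_truth_boundaries))
                    except (SegmentationError, morphometry.RoiError) as exc:
                        failures.append({"mouse": m, "eye": e, "day": day,
                                         "scan": s, "error": str(exc)})
                if per_scan:
                    rows.extend(_eye_rows(m, e, day, per_scan))

    table = pd.DataFrame(rows, columns=["mouse", "eye", "day", "layer",
                                        "metric", "value", "n"])
    summary = summarize(table)
    decay = _fit_onl_decay(table)
    corr = _severity_correlation(table, design, n_boot=config.n_boot,
                                 seed=config.seed)
    ttests = _paired_vs_baseline(table)
    manifest = {"config": config.to_dict(), "config_hash": config.content_hash(),
                "n_images": len(dataset), "n_failures": len(failures)}
    return StudyResult(table, summary, decay, corr, ttests, failures, manifest)


def summarize(table: pd.DataFrame) -> pd.DataFrame:
    """Wide per-day mean +/- SD of layer thickness across eyes."""
    t = table[table["metric"] == "thickness_um"]
    if t.empty:
        return pd.DataFrame()
    g = t.groupby(["day", "layer"])["value"]
    out = g.agg(["mean", "std", "count"]).reset_index()
    return out.pivot(index="day", columns="layer", values=["mean", "std"])


def _fit_onl_decay(table: pd.DataFrame):
    t = table[(table["metric"] == "thickness_um") & (table["layer"] == "ONL")]
    means = t.groupby("day")["value"].mean()
    if len(means) < 4:
        return None
    return timecourse.fit_exp_decay(means.index.to_numpy(), means.to_numpy())


def _severity_correlation(table: pd.DataFrame, design: StudyDesign,
                          n_boot: int = 1000, seed: int = 0):
    """Day-1 ONL eAC vs total ONL loss (baseline - final day), per eye."""
    days = sorted(design.timepoints)
    if len(days) < 3 or 1.0 not in days or 0.0 not in days:
        return None
    final = days[-1]
    eac1 = table[(table["metric"] == "log10_eac") & (table["layer"] == "ONL")
                 & (table["day"] == 1.0)]
    th0 = table[(table["metric"] == "thickness_um") & (table["layer"] == "ONL")
                & (table["day"] == 0.0)]
    thf = table[(table["metric"] == "thickness_um") & (table["layer"] == "ONL")
                & (table["day"] == final)]
    keys = ["mouse", "eye"]
    merged = (eac1[keys + ["value"]].rename(columns={"value": "eac1"})
              .merge(th0[keys + ["value"]].rename(columns={"value": "t0"}), on=keys)
              .merge(thf[keys + ["value"]].rename(columns={"value": "tf"}), on=keys))
    if len(merged) < 3 or merged["eac1"].nunique() < 2:
        return None
    loss = merged["t0"] - merged["tf"]
    return timecourse.linfit_r2(merged["eac1"].to_numpy(), loss.to_numpy(),
                                n_boot=n_boot, seed=seed)


def _paired_vs_baseline(table: pd.DataFrame) -> pd.DataFrame:
    """Paired t-test of each layer/metric against baseline, across eyes."""
    rows = []
    keys = ["mouse", "eye"]
    for (metric, layer), grp in table.groupby(["metric", "layer"]):
        base = grp[grp["day"] == 0.0].set_index(keys)["value"]
        if base.empty:
            continue
        for day in sorted(grp["day"].unique()):
            if day == 0.0:
                continue
            cur = grp[grp["day"] == day].set_index(keys)["value"]
            joined = pd.concat([base, cur], axis=1, join="inner")
            if len(joined) < 2:
                continue
            res = timecourse.paired_t(joined.iloc[:, 0].to_numpy(),
                                      joined.iloc[:, 1].to_numpy())
            rows.append({"metric": metric, "layer": layer, "day": day,
                         "t_stat": res.t_stat, "df": res.df,
                         "p_two_sided": res.p_two_sided, "n": len(joined)})
    return pd.DataFrame(rows, columns=["metric", "layer", "day", "t_stat",
                                       "df", "p_two_sided", "n"])
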