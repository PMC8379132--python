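"""End-to-end synthetic study pipeline.

Mirrors the flow of a two-protocol pelvic CT comparison: every synthetic
subject is "scanned" with a standard-dose and a tin-filtered ultra-low-dose
(ULD) protocol (same anatomy, protocol-specific tissue HU and noise), a
virtual radiograph (VR) is computed from the ULD volume by cone-beam
projection, and the stages downstream produce per-volume image-quality
metrics, a dose report, hip-angle measurements on VR versus an idealized
parallel projection, and the agreement statistics between them.

Protocol defaults emulate the study conditions: cortical bone around
1500 HU (standard) vs 1124 HU (ULD, hardened spectrum), muscle 57.5 vs
54 HU, DLP medians 177.85 vs 28.85 mGy·cm, and ULD air noise above
standard. Angle "readings" add a small Gaussian landmark-placement jitter
(default SD 0.75 mm) on both images, emulating manual caliper placement —
without it the two projections of in-plane landmarks agree to floating-point
precision and agreement statistics degenerate.

All randomness flows from one root seed via ``numpy.random.SeedSequence``;
a fixed seed reproduces every output byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .agreement import bland_altman, cohen_kappa, icc, mcnemar, wilcoxon_signed_rank
from .angles import ce_angle, fit_circle, sharp_angle
from .dose import dose_reduction, effective_dose_ct, round_half_away
from .drr import Detector, ProjectionGeometry, project_cone, project_points, to_display
from .errors import DivisionError, UldctError
from .metrics import cohort_summary, noise as roi_noise, quality_indices, roi_stats
from .phantom import GroundTruth, HipSide, PhantomSpec, add_noise, build_phantom, default_rois

__all__ = ["ProtocolConfig", "RunConfig", "run_pipeline"]

_SIDE_LATERAL = {"left": (1.0, 0.0), "right": (-1.0, 0.0)}  # detector u toward patient left


@dataclass
class ProtocolConfig:
    """One acquisition protocol of the paired design."""

    name: str
    noise_sd_hu: float
    hu_cortical: float
    hu_muscle: float
    dlp_median_mgy_cm: float
    dlp_log_sigma: float = 0.0


def default_protocols() -> dict[str, ProtocolConfig]:
    return {
        "standard": ProtocolConfig(
            name="standard", noise_sd_hu=15.0, hu_cortical=1500.0, hu_muscle=57.5,
            dlp_median_mgy_cm=177.85, dlp_log_sigma=0.35,
        ),
        "uld": ProtocolConfig(
            name="uld", noise_sd_hu=20.0, hu_cortical=1124.0, hu_muscle=54.0,
            dlp_median_mgy_cm=28.85, dlp_log_sigma=0.03,
        ),
    }


@dataclass
class RunConfig:
    """Configuration of a full synthetic cohort run."""

    seed: int = 0
    n_subjects: int = 12
    output_dir: str = "uldct_run"
    volume_shape: tuple[int, int, int] = (180, 120, 110)
    spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    protocols: dict[str, ProtocolConfig] = field(default_factory=default_protocols)
    sdd_mm: float = 1200.0
    sod_mm: float = 1000.0
    detector_n: int = 220
    detector_pitch_mm: float = 2.0
    projection_step_mm: float = 1.0
    landmark_jitter_mm: float = 0.75
    dysplasia_ce_threshold_deg: float = 25.0
    ce_angle_range_deg: tuple[float, float] = (16.0, 40.0)
    sharp_angle_range_deg: tuple[float, float] = (33.0, 46.0)
    head_radius_range_mm: tuple[float, float] = (22.0, 26.0)
    save_images: bool = True
    save_plots: bool = False

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        protos = d.pop("protocols", None)
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in d.items()})
        if protos:
            cfg.protocols = {
                name: ProtocolConfig(name=name, **{k: v for k, v in p.items() if k != "name"})
                for name, p in protos.items()
            }
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def _measure_hip_angles(geometry, gt: GroundTruth, side: str, rng: np.random.Generator | None, jitter_mm: float):
    """Project the ground-truth landmarks of one hip onto a detector and
    measure CE and Sharp angles there, with optional placement jitter.

    The head center is recovered by circle-fitting the projected equator
    contour, as a reader would trace the femoral head outline.
    """
    lm = gt.landmarks[side]
    contour = project_points(geometry, gt.equator_points(side, n=24))
    rim, teardrop = project_points(geometry, np.stack([lm["rim"], lm["teardrop"]]))
    if rng is not None and jitter_mm > 0:
        contour = contour + rng.normal(0.0, jitter_mm, size=contour.shape)
        rim = rim + rng.normal(0.0, jitter_mm, size=2)
        teardrop = teardrop + rng.normal(0.0, jitter_mm, size=2)
    center, radius = fit_circle(contour)
    ce = ce_angle(center, rim, vertical=(0.0, 1.0), lateral=_SIDE_LATERAL[side])
    sharp = sharp_angle(teardrop, rim)
    return ce, sharp, center, radius


def _subject_spec(cfg: RunConfig, proto: ProtocolConfig, anatomy: dict) -> PhantomSpec:
    sides = {
        name: HipSide(
            head_center_mm=(90.0 if name == "left" else -90.0, 0.0, -40.0),
            head_radius_mm=anatomy["head_radius_mm"],
            ce_angle_deg=anatomy[f"ce_{name}"],
            sharp_angle_deg=anatomy[f"sharp_{name}"],
        )
        for name in ("left", "right")
    }
    return PhantomSpec(
        volume_shape=cfg.volume_shape,
        spacing_mm=cfg.spacing_mm,
        hu_muscle=proto.hu_muscle,
        hu_cortical=proto.hu_cortical,
        sides=sides,
        noise_sd_hu=proto.noise_sd_hu,
    )


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full synthetic study; writes result tables, reports, images
    and a manifest into ``cfg.output_dir`` and returns the summary dict."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    root_ss = np.random.SeedSequence(cfg.seed)
    subject_seeds = root_ss.spawn(cfg.n_subjects)

    cone_geom = ProjectionGeometry(
        mode="cone", sdd_mm=cfg.sdd_mm, sod_mm=cfg.sod_mm,
        detector=Detector(nu=cfg.detector_n, nv=cfg.detector_n, pitch_mm=cfg.detector_pitch_mm),
    )
    par_geom = ProjectionGeometry(
        mode="parallel", sdd_mm=cfg.sdd_mm, sod_mm=cfg.sod_mm,
        detector=Detector(nu=cfg.detector_n, nv=cfg.detector_n, pitch_mm=cfg.detector_pitch_mm),
    )

    metric_rows, dose_rows, angle_rows = [], [], []
    dysplasia_calls: dict[str, list[bool]] = {p: [] for p in cfg.protocols}
    dysplasia_grades: dict[str, list[str]] = {"vr": [], "parallel": []}

    for i, ss in enumerate(subject_seeds):
        rng_anat, rng_noise, rng_dose, rng_read = [np.random.default_rng(s) for s in ss.spawn(4)]
        anatomy = {
            "head_radius_mm": float(rng_anat.uniform(*cfg.head_radius_range_mm)),
            "ce_left": float(rng_anat.uniform(*cfg.ce_angle_range_deg)),
            "ce_right": float(rng_anat.uniform(*cfg.ce_angle_range_deg)),
            "sharp_left": float(rng_anat.uniform(*cfg.sharp_angle_range_deg)),
            "sharp_right": float(rng_anat.uniform(*cfg.sharp_angle_range_deg)),
        }

        uld_volume = None
        gt = None
        for pname, proto in cfg.protocols.items():
            try:
                spec = _subject_spec(cfg, proto, anatomy)
            except UldctError as exc:
                raise type(exc)(f"[stage phantom, subject {i}, protocol {pname}] {exc}") from exc
            volume, gt = build_phantom(spec)
            noisy = add_noise(volume, proto.noise_sd_hu, rng_noise)
            if pname == "uld":
                uld_volume = noisy

            dlp = proto.dlp_median_mgy_cm * float(np.exp(rng_dose.normal(0.0, proto.dlp_log_sigma))) \
                if proto.dlp_log_sigma > 0 else proto.dlp_median_mgy_cm
            eff_dose = effective_dose_ct(dlp)
            dose_rows.append({"subject": i, "protocol": pname, "dlp_mgy_cm": dlp, "effective_dose_msv": eff_dose})

            rois = {r.label: r for r in default_rois(spec)}
            air_sd = roi_noise(noisy, rois["air"])
            muscle = roi_stats(noisy, rois["muscle"])
            bone = roi_stats(noisy, rois["cortical_bone"])
            row = {
                "subject": i, "protocol": pname, "noise_sd_hu": air_sd,
                "mean_muscle_hu": muscle.mean_hu, "mean_bone_hu": bone.mean_hu,
                "sd_bone_hu": bone.sd_hu, "effective_dose_msv": eff_dose,
            }
            try:
                qi = quality_indices(bone.mean_hu, bone.sd_hu, muscle.mean_hu, air_sd, eff_dose)
                row.update({"snr": qi.snr, "cnr": qi.cnr, "fom": qi.fom})
            except DivisionError:
                row.update({"snr": np.nan, "cnr": np.nan, "fom": np.nan})
            metric_rows.append(row)

            # pathology call: dysplasia if the CE angle measured on an
            # idealized (jitter-free) parallel projection is below threshold
            for side in ("left", "right"):
                ce, _, _, _ = _measure_hip_angles(par_geom, gt, side, None, 0.0)
                dysplasia_calls[pname].append(ce < cfg.dysplasia_ce_threshold_deg)

        # VR (cone) vs parallel angle measurements on the ULD anatomy
        assert gt is not None and uld_volume is not None
        for side in ("left", "right"):
            ce_vr, sharp_vr, _, _ = _measure_hip_angles(cone_geom, gt, side, rng_read, cfg.landmark_jitter_mm)
            ce_par, sharp_par, _, _ = _measure_hip_angles(par_geom, gt, side, rng_read, cfg.landmark_jitter_mm)
            angle_rows.append({
                "subject": i, "side": side,
                "ce_vr_deg": round(ce_vr, 1), "ce_parallel_deg": round(ce_par, 1),
                "sharp_vr_deg": round(sharp_vr, 1), "sharp_parallel_deg": round(sharp_par, 1),
                "ce_true_deg": gt.ce_angle_deg[side], "sharp_true_deg": gt.sharp_angle_deg[side],
            })
            for img, ce in (("vr", ce_vr), ("parallel", ce_par)):
                grade = "dysplastic" if ce < 20 else ("borderline" if ce < cfg.dysplasia_ce_threshold_deg else "normal")
                dysplasia_grades[img].append(grade)

        if cfg.save_images and uld_volume is not None and i == 0:
            vr = project_cone(uld_volume, cone_geom, step_mm=cfg.projection_step_mm)
            img = to_display(vr)
            try:
                import imageio.v3 as iio

                iio.imwrite(out / "vr_subject00.png", img)
            except Exception:
                np.save(out / "vr_subject00.npy", vr.raw)
            cone_geom.to_json(out / "vr_geometry.json")

    metrics_df = pd.DataFrame(metric_rows)
    dose_df = pd.DataFrame(dose_rows)
    angles_df = pd.DataFrame(angle_rows)
    metrics_df.to_csv(out / "metrics.csv", index=False, float_format="%.6g")
    dose_df.to_csv(out / "dose.csv", index=False, float_format="%.6g")
    angles_df.to_csv(out / "angles.csv", index=False, float_format="%.6g")

    # ---- cohort summaries -------------------------------------------------
    summary: dict = {"per_protocol": {}, "n_subjects": cfg.n_subjects}
    for pname in cfg.protocols:
        sub = metrics_df[metrics_df.protocol == pname]
        entry = {}
        for col in ("noise_sd_hu", "snr", "cnr", "fom", "effective_dose_msv"):
            vals = sub[col].to_numpy(dtype=float)
            if np.isnan(vals).any():
                entry[col] = {"median": None, "q1": None, "q3": None, "note": "undefined (division by zero)"}
            else:
                med, q1, q3 = cohort_summary(vals)
                entry[col] = {"median": med, "q1": q1, "q3": q3}
        summary["per_protocol"][pname] = entry

    if {"standard", "uld"} <= set(cfg.protocols):
        ref = summary["per_protocol"]["standard"]["effective_dose_msv"]["median"]
        new = summary["per_protocol"]["uld"]["effective_dose_msv"]["median"]
        if ref and new:
            pct, fold = dose_reduction(round_half_away(ref, 2), round_half_away(new, 2))
            summary["dose_reduction"] = {"percent": pct, "fold": fold}

    # ---- agreement --------------------------------------------------------
    agreement: dict = {}
    for method in ("ce", "sharp"):
        for side in ("left", "right"):
            sub = angles_df[angles_df.side == side]
            a = sub[f"{method}_vr_deg"].to_numpy(dtype=float)
            b = sub[f"{method}_parallel_deg"].to_numpy(dtype=float)
            if a.size >= 3:
                ba = bland_altman(a, b)
                w, p = wilcoxon_signed_rank(a, b)
                agreement[f"{method}_{side}"] = {
                    "bias_deg": ba.bias, "lower_limit_deg": ba.lower_limit,
                    "upper_limit_deg": ba.upper_limit, "range_deg": ba.range,
                    "icc": icc(a, b), "wilcoxon_p": p, "n": ba.n,
                }
                if cfg.save_plots:
                    from .agreement import bland_altman_plot

                    bland_altman_plot(a, b, out / f"bland_altman_{method}_{side}.png", f"{method} {side}")

    if {"standard", "uld"} <= set(dysplasia_calls.keys()):
        b_ct, c_ct, p = mcnemar(dysplasia_calls["standard"], dysplasia_calls["uld"])
        n_hips = len(dysplasia_calls["uld"])
        agreement["dysplasia_prevalence"] = {
            "standard": float(np.mean(dysplasia_calls["standard"])),
            "uld": float(np.mean(dysplasia_calls["uld"])),
            "mcnemar_discordant": [b_ct, c_ct],
            "mcnemar_p": p,
            "n_hips": n_hips,
        }
    agreement["dysplasia_grade_kappa_vr_vs_parallel"] = cohen_kappa(
        dysplasia_grades["vr"], dysplasia_grades["parallel"]
    )
    summary["agreement"] = agreement

    with open(out / "agreement.json", "w") as fh:
        json.dump(agreement, fh, indent=2, sort_keys=True)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)

    cfg_dict = cfg.to_dict()
    manifest = {
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(json.dumps(cfg_dict, sort_keys=True, default=str).encode()).hexdigest(),
        "seed": cfg.seed,
        "package_version": __version__,
        "numpy_version": np.__version__,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return summary
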