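"""End-to-end orchestration and file I/O.

``run_all`` mirrors the full study on synthetic subjects: simulate a cohort
(ischemia–reperfusion animals with infarcts, controls without; one IR
subject optionally corrupted by motion streaks), acquire the gated
diastole/systole blood-pool pair and the delayed-enhancement scan per
subject, run both quantification arms (CT and TTC histology), and assemble
the per-subject table plus the cross-modality agreement report.

Volumes are written as NIfTI (.nii.gz), histology faces as PNG, tables as
CSV — all lossless and language-neutral.  Every stochastic step derives its
seed from the run seed, so a run is bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import ct_quant, gating, histo_quant, phantom, stats

__all__ = [
    "RunConfig",
    "RunResult",
    "run_all",
    "auto_blood_seed",
    "quantify_ct_subject",
    "read_volume",
    "write_volume",
    "read_image",
    "write_image",
    "read_table",
    "write_table",
]

log = logging.getLogger("murine_dce_quant")


# ---------------------------------------------------------------------------
# File I/O (round-trip lossless)

def write_volume(vol: phantom.VoxelVolume, path) -> Path:
    """Write a volume as NIfTI with the spacing in the header.

    NIfTI-2 is used because its header carries double-precision geometry,
    so spacing and origin round-trip exactly."""
    import nibabel as nib
    path = Path(path)
    affine = np.diag([vol.spacing_mm] * 3 + [1.0])
    affine[:3, 3] = vol.origin_mm
    img = nib.Nifti2Image(vol.values.astype(np.float64), affine)
    img.header.set_zooms((vol.spacing_mm,) * 3)
    nib.save(img, str(path))
    return path


def read_volume(path) -> phantom.VoxelVolume:
    import nibabel as nib
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float64)
        # spacing from the (float64) affine: header zooms are only float32
        zooms = np.abs(np.diag(img.affine)[:3])
        origin = np.asarray(img.affine[:3, 3], dtype=float)
    except Exception as exc:  # pragma: no cover - malformed input
        raise ValueError(f"cannot parse volume file {path}: {exc}") from exc
    if max(zooms) - min(zooms) > 1e-6:
        raise ValueError(f"{path}: anisotropic spacing {zooms} unsupported")
    return phantom.VoxelVolume(values=data, spacing_mm=float(zooms[0]),
                               origin_mm=origin)


def write_image(image: np.ndarray, path) -> Path:
    from PIL import Image
    path = Path(path)
    Image.fromarray(np.asarray(image, dtype=np.uint8)).save(str(path))
    return path


def read_image(path) -> np.ndarray:
    from PIL import Image
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    return np.asarray(Image.open(str(path)).convert("RGB"))


def write_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def read_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"table file not found: {path}")
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# Configuration

@dataclass(frozen=True)
class RunConfig:
    """Parameters of an end-to-end synthetic study run."""

    n_ir: int = 8
    n_control: int = 7
    seed: int = 17
    spacing_mm: float = 0.077
    noise_sd_hu: float = 30.0
    delayed_time_min: float = 13.0      # first post-Iohexol acquisition
    blood_pool_time_min: float = 5.0    # intravascular-agent pair
    motion_subject_id: int | None = 5   # mirrors the study's subject #5
    motion_severity: float = 1.0
    ttc_thickness_mm: float = 1.0
    ttc_pixel_size_mm: float = 0.02
    cardiac_bpm_mean: float = 420.0
    cardiac_bpm_sd: float = 70.0
    resp_bpm_mean: float = 108.0
    resp_bpm_sd: float = 17.0
    physio_jitter_cv: float = 0.05
    gating_config: gating.GatingConfig = field(default_factory=gating.GatingConfig)
    seg_params: ct_quant.SegmentationParams = field(
        default_factory=ct_quant.SegmentationParams)
    histology_thresholds: histo_quant.HistologyThresholds = field(
        default_factory=histo_quant.HistologyThresholds)
    simulate_gating: bool = True
    save_volumes: bool = False
    save_images: bool = False
    out_dir: str | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class RunResult:
    records: list[stats.SubjectRecord]
    report: stats.AgreementReport | None
    subject_table: pd.DataFrame
    scan_times_s: dict[int, float]
    group_ef_p: float | None


# ---------------------------------------------------------------------------
# Quantification helpers

def auto_blood_seed(vol: phantom.VoxelVolume,
                    hu_range: tuple[float, float]) -> tuple[int, int, int]:
    """Pick a seed voxel near the grid centre whose HU is inside the blood
    window — the synthetic counterpart of the operator's manual seed click."""
    low, high = hu_range
    c = tuple(n // 2 for n in vol.values.shape)
    for radius in range(0, 6):
        for dz in range(-radius, radius + 1):
            for dy in range(-radius, radius + 1):
                for dx in range(-radius, radius + 1):
                    p = (c[0] + dx, c[1] + dy, c[2] + dz)
                    if all(0 <= pi < n for pi, n in zip(p, vol.values.shape)):
                        if low <= vol.values[p] <= high:
                            return p
    raise ct_quant.SeedRejectedError(c, "no in-range voxel near grid centre")


def quantify_ct_subject(dia_vol: phantom.VoxelVolume,
                        sys_vol: phantom.VoxelVolume,
                        delayed_vol: phantom.VoxelVolume | None,
                        params: ct_quant.SegmentationParams) -> dict:
    """The full CT arm for one subject: LV volumes, EF and, when a delayed
    scan is supplied, percent infarct of the LV myocardium."""
    out: dict = {}
    masks = {}
    for name, vol in [("dia", dia_vol), ("sys", sys_vol)]:
        seed = auto_blood_seed(vol, params.blood_hu_range)
        p = dataclasses.replace(params, seed_points=(seed,))
        masks[name] = ct_quant.segment_lv_blood(vol, p)
        out[f"v_{name}_mm3"] = ct_quant.mask_volume_mm3(masks[name],
                                                        vol.spacing_mm)
    out["ef"] = ct_quant.ejection_fraction(out["v_dia_mm3"], out["v_sys_mm3"])
    if delayed_vol is not None:
        myo = ct_quant.segment_myocardium(delayed_vol, masks["dia"], params)
        infarct = ct_quant.segment_infarct(delayed_vol, myo, params)
        out["ct_infarct_pct"] = ct_quant.percent_infarct_ct(infarct, myo)
        out["roi_myo"] = ct_quant.roi_mean_hu(delayed_vol, myo & ~infarct)
    return out


def quantify_histology_subject(slices, thickness_mm: float,
                               thresholds) -> float:
    measurements = [histo_quant.measure_slice(s, thresholds) for s in slices]
    return histo_quant.percent_infarct_histology(measurements, thickness_mm)


# ---------------------------------------------------------------------------
# End-to-end run

def _subject_scan_time(cfg: RunConfig, rng: np.random.Generator) -> float:
    cardiac = float(np.clip(rng.normal(cfg.cardiac_bpm_mean, cfg.cardiac_bpm_sd),
                            150.0, 900.0))
    resp = float(np.clip(rng.normal(cfg.resp_bpm_mean, cfg.resp_bpm_sd),
                         40.0, 300.0))
    duration = 900.0
    for _ in range(4):
        trace = gating.simulate_physio(
            cardiac, resp, cfg.physio_jitter_cv, duration,
            seed=int(rng.integers(2 ** 31)),
            plateau_fraction=cfg.gating_config.exhalation_window_fraction)
        try:
            sched = gating.schedule_projections(trace, cfg.gating_config)
            return gating.scan_duration(sched)
        except gating.InsufficientTraceError:
            duration *= 2.0
    raise RuntimeError("gated scan did not complete within the trace budget")


def run_all(config: RunConfig) -> RunResult:
    """Run the full synthetic study and assemble the agreement report."""
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(config.seed)
    specs = phantom.simulate_cohort(config.n_ir, config.n_control, config.seed,
                                    spacing_mm=config.spacing_mm,
                                    noise_sd_hu=config.noise_sd_hu)
    records: list[stats.SubjectRecord] = []
    scan_times: dict[int, float] = {}
    for spec in specs:
        sid = spec.subject_id
        stage = "simulate"
        try:
            s_pair, s_delayed, s_motion, s_ttc, s_gate = (
                int(master.integers(2 ** 31)) for _ in range(5))
            stage = "acquire-blood-pool"
            dia_vol, dia_mask = phantom.build_heart_phantom(
                spec, "diastole", config.blood_pool_time_min, seed=s_pair,
                washout=spec.washout_blood_pool)
            sys_vol, _ = phantom.build_heart_phantom(
                spec, "systole", config.blood_pool_time_min, seed=s_pair,
                washout=spec.washout_blood_pool)
            is_ir = spec.group == "IR"
            delayed_vol = None
            if is_ir:
                stage = "acquire-delayed"
                delayed_vol, delayed_mask = phantom.build_heart_phantom(
                    spec, "diastole", config.delayed_time_min, seed=s_delayed)
                motion = (config.motion_subject_id == sid)
                if motion:
                    delayed_vol = phantom.add_motion_streaks(
                        delayed_vol, config.motion_severity, seed=s_motion)
            stage = "quantify-ct"
            ct = quantify_ct_subject(dia_vol, sys_vol, delayed_vol,
                                     config.seg_params)
            hist_pct = None
            if is_ir:
                stage = "histology"
                slices = phantom.render_ttc_slices(
                    spec, config.ttc_thickness_mm, config.ttc_pixel_size_mm,
                    seed=s_ttc)
                hist_pct = quantify_histology_subject(
                    slices, config.ttc_thickness_mm,
                    config.histology_thresholds)
                if config.save_images and out_dir:
                    for k, sl in enumerate(slices):
                        write_image(sl.front_image,
                                    out_dir / f"subject{sid}_slice{k}_front.png")
                        write_image(sl.back_image,
                                    out_dir / f"subject{sid}_slice{k}_back.png")
            if config.simulate_gating:
                stage = "gating"
                scan_times[sid] = _subject_scan_time(
                    config, np.random.default_rng(s_gate))
            if config.save_volumes and out_dir:
                stage = "write-volumes"
                write_volume(dia_vol, out_dir / f"subject{sid}_dia.nii.gz")
                write_volume(sys_vol, out_dir / f"subject{sid}_sys.nii.gz")
                if delayed_vol is not None:
                    write_volume(delayed_vol,
                                 out_dir / f"subject{sid}_delayed.nii.gz")
        except Exception as exc:
            raise RuntimeError(
                f"stage '{stage}' failed for subject {sid}: {exc}") from exc
        records.append(stats.SubjectRecord(
            subject_id=sid, group=spec.group,
            ct_infarct_pct=ct.get("ct_infarct_pct"),
            hist_infarct_pct=hist_pct,
            v_dia_mm3=ct["v_dia_mm3"], v_sys_mm3=ct["v_sys_mm3"],
            ef=ct["ef"],
            motion_artifact=(config.motion_subject_id == sid
                             and spec.group == "IR")))
        log.info("subject %d (%s): EF=%.3f ct%%=%s hist%%=%s", sid, spec.group,
                 ct["ef"], ct.get("ct_infarct_pct"), hist_pct)

    report = None
    if config.n_ir == 0:
        warnings.warn("no IR subjects: agreement stage skipped")
    else:
        usable = [r for r in records if r.ct_infarct_pct is not None]
        if len(usable) >= 2:
            exclude = [config.motion_subject_id] if any(
                r.motion_artifact for r in records) else []
            report = stats.agreement_report(records, exclude_ids=exclude)

    group_p = None
    ir_ef = [r.ef for r in records if r.group == "IR" and r.ef is not None]
    co_ef = [r.ef for r in records if r.group == "control" and r.ef is not None]
    if len(ir_ef) >= 2 and len(co_ef) >= 2:
        _, group_p = stats.group_test(ir_ef, co_ef)

    table = pd.DataFrame([{
        "subject_id": r.subject_id, "group": r.group,
        "v_dia_mm3": r.v_dia_mm3, "v_sys_mm3": r.v_sys_mm3, "ef": r.ef,
        "ct_infarct_pct": r.ct_infarct_pct,
        "hist_infarct_pct": r.hist_infarct_pct,
        "motion_artifact": r.motion_artifact,
        "scan_time_s": scan_times.get(r.subject_id),
    } for r in records])
    if out_dir:
        write_table(table, out_dir / "subjects.csv")
        payload = {
            "config": config.to_dict(),
            "group_ef_p": group_p,
            "agreement": report.to_dict() if report else None,
        }
        (out_dir / "report.json").write_text(
            json.dumps(payload, indent=2, default=_jsonable))
    return RunResult(records=records, report=report, subject_table=table,
                     scan_times_s=scan_times, group_ef_p=group_p)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
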