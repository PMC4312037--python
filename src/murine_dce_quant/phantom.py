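"""Digital mouse-heart phantoms for delayed-contrast-enhanced cardiac micro-CT.

The phantom emulates what the scanner sees in a murine ischemia–reperfusion
study: a left-ventricular (LV) blood cavity, a myocardial wall of uniform
thickness, and an infarcted wedge in the anterior (LAD) territory that
retains an extracellular iodinated contrast agent after the blood pool has
begun to clear ("delayed enhancement").  Each tissue's Hounsfield value
follows a mono-exponential washout curve calibrated to two measured time
points; voxel noise is additive Gaussian.  The same label field drives a
matched synthetic histology arm: 1 mm short-axis slices rendered as
TTC-stained photographs (viable myocardium brick red, infarct pale pink).

Geometry is deliberately simple — an ellipsoidal cavity with a
uniform-thickness parallel shell — so that every derived quantity
(cavity volume, infarct fraction, ejection fraction) has an independent
analytic or voxel-count oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "BACKGROUND",
    "MYOCARDIUM",
    "LV_BLOOD",
    "INFARCT",
    "VoxelVolume",
    "LabelMask",
    "WashoutCurve",
    "WashoutModel",
    "PhantomSpec",
    "HistologySlice",
    "calibrate_washout",
    "washout_hu",
    "iohexol_reference",
    "blood_pool_reference",
    "build_heart_phantom",
    "add_motion_streaks",
    "render_ttc_slices",
    "simulate_cohort",
    "ellipsoid_volume_mm3",
    "azimuth_span_for_infarct_fraction",
]

# Label codes shared across the whole package.
BACKGROUND = 0
MYOCARDIUM = 1
LV_BLOOD = 2
INFARCT = 3

# TTC rendering constants (documented so the histology thresholds can be
# tested against them).
VIABLE_RGB = (180, 40, 50)      # brick red, TTC-positive viable myocardium
INFARCT_RGB = (235, 190, 190)   # pale pink, TTC-negative infarct
BACKGROUND_RGB = (255, 255, 255)
COLOR_JITTER_SD = 10.0          # per-channel Gaussian jitter, 8-bit units

Phase = Literal["diastole", "systole"]
_PHASE_CODE = {"diastole": 0, "systole": 1}


@dataclass(frozen=True)
class VoxelVolume:
    """A 3-D scalar grid of Hounsfield values with isotropic spacing."""

    values: np.ndarray
    spacing_mm: float
    origin_mm: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 3 or min(values.shape) < 1:
            raise ValueError("values must be a non-empty 3-D grid")
        if not np.all(np.isfinite(values)):
            raise ValueError("all HU values must be finite")
        if not (self.spacing_mm > 0):
            raise ValueError(f"spacing_mm must be positive, got {self.spacing_mm}")
        origin = (np.zeros(3) if self.origin_mm is None
                  else np.asarray(self.origin_mm, dtype=np.float64))
        if origin.shape != (3,):
            raise ValueError("origin_mm must be a 3-vector")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "origin_mm", origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def axis_coords_mm(self, axis: int) -> np.ndarray:
        """Physical coordinates of voxel centres along one axis."""
        n = self.values.shape[axis]
        return self.origin_mm[axis] + self.spacing_mm * np.arange(n)


@dataclass(frozen=True)
class LabelMask:
    """Companion integer grid: 0 background, 1 myocardium, 2 LV blood, 3 infarct."""

    labels: np.ndarray
    spacing_mm: float
    origin_mm: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise ValueError("labels must be 3-D")
        if not np.issubdtype(labels.dtype, np.integer):
            raise ValueError("labels must be integer-typed")
        bad = set(np.unique(labels)) - {BACKGROUND, MYOCARDIUM, LV_BLOOD, INFARCT}
        if bad:
            raise ValueError(f"unknown label codes {sorted(bad)}")
        if not (self.spacing_mm > 0):
            raise ValueError("spacing_mm must be positive")
        origin = (np.zeros(3) if self.origin_mm is None
                  else np.asarray(self.origin_mm, dtype=np.float64))
        object.__setattr__(self, "labels", labels.astype(np.uint8))
        object.__setattr__(self, "origin_mm", origin)

    def count(self, label: int) -> int:
        return int(np.count_nonzero(self.labels == label))

    def volume_mm3(self, label: int) -> float:
        """Ground-truth volume of one label (voxel count x spacing^3)."""
        return self.count(label) * self.spacing_mm ** 3


@dataclass(frozen=True)
class WashoutCurve:
    """Mono-exponential contrast kinetics for one tissue: HU(t) = A0 exp(-lambda t)."""

    a0_hu: float
    rate_per_min: float

    def __post_init__(self):
        if not (self.a0_hu > 0):
            raise ValueError("A0 must be positive")
        if self.rate_per_min < 0:
            raise ValueError("decay rate must be non-negative")

    def hu(self, t_min: float) -> float:
        if t_min < 0:
            raise ValueError("time must be non-negative")
        return self.a0_hu * math.exp(-self.rate_per_min * t_min)


@dataclass(frozen=True)
class WashoutModel:
    """Per-tissue washout curves for blood, infarct and viable myocardium."""

    blood: WashoutCurve
    infarct: WashoutCurve
    myocardium: WashoutCurve

    def hu(self, tissue: str, t_min: float) -> float:
        try:
            curve: WashoutCurve = getattr(self, tissue)
        except AttributeError:
            raise ValueError(f"unknown tissue {tissue!r}") from None
        return curve.hu(t_min)


def calibrate_washout(hu_early: float, hu_late: float,
                      t_early_min: float, t_late_min: float) -> WashoutCurve:
    """Fit the unique mono-exponential through two (time, HU) measurements.

    lambda = ln(HU_early / HU_late) / (t_late - t_early); A0 follows by
    evaluating the curve back at t = 0.  The calibration is exact: the
    returned curve reproduces both inputs.
    """
    if hu_early <= 0 or hu_late <= 0:
        raise ValueError("HU values must be positive for washout calibration")
    if t_late_min <= t_early_min:
        raise ValueError("t_late_min must exceed t_early_min")
    if hu_late > hu_early:
        raise ValueError("HU must not increase over time (washout only)")
    rate = math.log(hu_early / hu_late) / (t_late_min - t_early_min)
    a0 = hu_early * math.exp(rate * t_early_min)
    return WashoutCurve(a0_hu=a0, rate_per_min=rate)


def washout_hu(curve: WashoutCurve, t_min: float) -> float:
    """Evaluate a washout curve: A0 * exp(-lambda * t)."""
    return curve.hu(t_min)


# Measured Iohexol enhancement (HU) at the two gated acquisitions,
# on average 13 and 30 minutes after injection.
IOHEXOL_TIMES_MIN = (13.0, 30.0)
IOHEXOL_HU = {"blood": (411.0, 245.0), "infarct": (431.0, 281.0),
              "myocardium": (182.0, 139.0)}


def iohexol_reference() -> WashoutModel:
    """Washout model calibrated to the measured Iohexol tissue enhancement."""
    t0, t1 = IOHEXOL_TIMES_MIN
    return WashoutModel(
        blood=calibrate_washout(*IOHEXOL_HU["blood"], t0, t1),
        infarct=calibrate_washout(*IOHEXOL_HU["infarct"], t0, t1),
        myocardium=calibrate_washout(*IOHEXOL_HU["myocardium"], t0, t1),
    )


def blood_pool_reference() -> WashoutModel:
    """Intravascular lipid-emulsion agent used for the diastole/systole pair.

    The agent is long-circulating, so the blood pool stays strongly enhanced
    over the scan and neither viable nor infarcted myocardium enhances.
    Levels are the generator's own (500 HU blood, 120 HU tissue); the study
    never tabulated this agent's HU.
    """
    return WashoutModel(
        blood=WashoutCurve(a0_hu=500.0, rate_per_min=0.002),
        infarct=WashoutCurve(a0_hu=120.0, rate_per_min=0.0),
        myocardium=WashoutCurve(a0_hu=120.0, rate_per_min=0.0),
    )


@dataclass(frozen=True)
class PhantomSpec:
    """Everything needed to generate one synthetic subject.

    The LV cavity is an axis-aligned ellipsoid (long axis = z, apex at -z);
    the myocardium is the uniform band within ``wall_thickness_mm`` of the
    cavity surface; the infarct is the part of that band inside an azimuthal
    wedge extending a fraction of the heart's length up from the apex.
    ``infarct_wedge`` is (azimuth_start_deg, azimuth_end_deg,
    apical_extent_fraction); a zero angular span means no infarct.
    """

    lv_cavity_semiaxes_dia_mm: tuple[float, float, float] = (2.0, 2.0, 3.3)
    lv_cavity_semiaxes_sys_mm: tuple[float, float, float] = (1.725, 1.725, 2.847)
    wall_thickness_mm: float = 1.0
    infarct_wedge: tuple[float, float, float] = (0.0, 0.0, 0.0)
    washout: WashoutModel = field(default_factory=iohexol_reference)
    washout_blood_pool: WashoutModel = field(default_factory=blood_pool_reference)
    noise_sd_hu: float = 30.0
    background_hu: float = 50.0
    spacing_mm: float = 0.077
    margin_mm: float = 0.4
    seed: int = 0
    # cohort bookkeeping (not part of the imaging model)
    subject_id: int = 0
    group: str = "IR"
    motion_severity: float = 0.0

    def __post_init__(self):
        dia = np.asarray(self.lv_cavity_semiaxes_dia_mm, dtype=float)
        sys_ = np.asarray(self.lv_cavity_semiaxes_sys_mm, dtype=float)
        if dia.shape != (3,) or sys_.shape != (3,):
            raise ValueError("semiaxes must be 3-vectors")
        if np.any(dia <= 0) or np.any(sys_ <= 0):
            raise ValueError("semiaxes must be positive")
        if np.prod(sys_) >= np.prod(dia):
            raise ValueError("systolic cavity volume must be below diastolic")
        if not (self.wall_thickness_mm > 0):
            raise ValueError("wall_thickness_mm must be positive")
        if self.noise_sd_hu < 0:
            raise ValueError("noise_sd_hu must be non-negative")
        if not (self.spacing_mm > 0):
            raise ValueError("spacing_mm must be positive")
        a0, a1, frac = self.infarct_wedge
        if not (0.0 <= frac <= 1.0):
            raise ValueError("apical extent fraction must be in [0, 1]")

    @property
    def true_ef(self) -> float:
        """Analytic ejection fraction of the two cavity ellipsoids."""
        dia = np.prod(self.lv_cavity_semiaxes_dia_mm)
        sys_ = np.prod(self.lv_cavity_semiaxes_sys_mm)
        return float(1.0 - sys_ / dia)

    @classmethod
    def from_ef(cls, true_ef: float,
                lv_cavity_semiaxes_dia_mm: Sequence[float] = (2.0, 2.0, 3.3),
                **kwargs) -> "PhantomSpec":
        """Build a spec whose systolic cavity is an isotropic contraction
        of the diastolic one chosen to hit ``true_ef`` exactly."""
        if not (0.0 <= true_ef < 1.0):
            raise ValueError("true_ef must lie in [0, 1)")
        dia = tuple(float(s) for s in lv_cavity_semiaxes_dia_mm)
        scale = (1.0 - true_ef) ** (1.0 / 3.0)
        sys_ = tuple(s * scale for s in dia)
        return cls(lv_cavity_semiaxes_dia_mm=dia,
                   lv_cavity_semiaxes_sys_mm=sys_, **kwargs)

    def heart_extent_mm(self) -> float:
        """Long-axis (z) extent of the diastolic heart, epicardium to epicardium."""
        return 2.0 * (self.lv_cavity_semiaxes_dia_mm[2] + self.wall_thickness_mm)


@dataclass
class HistologySlice:
    """One 1 mm TTC-stained slab photographed on both cut faces."""

    front_image: np.ndarray  # (H, W, 3) uint8; lower-z face of the slab
    back_image: np.ndarray
    pixel_size_mm: float
    thickness_mm: float
    true_infarct_area_front_mm2: float
    true_infarct_area_back_mm2: float
    true_tissue_area_front_mm2: float
    true_tissue_area_back_mm2: float

    def __post_init__(self):
        if self.front_image.shape != self.back_image.shape:
            raise ValueError("front and back images must share dimensions")
        if not (self.thickness_mm > 0):
            raise ValueError("thickness_mm must be positive")
        for area, tissue in [
            (self.true_infarct_area_front_mm2, self.true_tissue_area_front_mm2),
            (self.true_infarct_area_back_mm2, self.true_tissue_area_back_mm2),
        ]:
            if area < 0 or area > tissue + 1e-9:
                raise ValueError("infarct area must lie in [0, tissue area]")


def ellipsoid_volume_mm3(semiaxes_mm: Sequence[float]) -> float:
    """Analytic ellipsoid volume (4/3) * pi * a * b * c."""
    a, b, c = semiaxes_mm
    return 4.0 / 3.0 * math.pi * a * b * c


def _grid_coords(spec: PhantomSpec):
    """Voxel-centre coordinate axes of a grid that holds the diastolic heart
    plus margin; identical for both phases so volumes are comparable."""
    dia = np.asarray(spec.lv_cavity_semiaxes_dia_mm)
    half = dia + spec.wall_thickness_mm + spec.margin_mm
    n = 2 * np.ceil(half / spec.spacing_mm).astype(int) + 1
    axes = [(np.arange(k) - (k - 1) / 2.0) * spec.spacing_mm for k in n]
    origin = np.array([ax[0] for ax in axes])
    return axes, origin


def _phantom_labels(spec: PhantomSpec, phase: Phase) -> LabelMask:
    if phase not in _PHASE_CODE:
        raise ValueError(f"phase must be 'diastole' or 'systole', got {phase!r}")
    if spec.wall_thickness_mm < 2.0 * spec.spacing_mm:
        raise ValueError(
            "spacing too coarse to resolve the wall: requires "
            f"wall_thickness >= 2*spacing, got {spec.wall_thickness_mm} vs "
            f"spacing {spec.spacing_mm}")
    semi = np.asarray(spec.lv_cavity_semiaxes_dia_mm if phase == "diastole"
                      else spec.lv_cavity_semiaxes_sys_mm)
    (xs, ys, zs), origin = _grid_coords(spec)
    X = xs[:, None, None]
    Y = ys[None, :, None]
    Z = zs[None, None, :]
    cavity = (X / semi[0]) ** 2 + (Y / semi[1]) ** 2 + (Z / semi[2]) ** 2 <= 1.0
    # Uniform-thickness wall: all voxels within wall_thickness of the cavity.
    dist = ndimage.distance_transform_edt(~cavity, sampling=spec.spacing_mm)
    myo = (dist <= spec.wall_thickness_mm) & ~cavity

    labels = np.zeros(cavity.shape, dtype=np.uint8)
    labels[myo] = MYOCARDIUM
    labels[cavity] = LV_BLOOD

    az0, az1, apical_frac = spec.infarct_wedge
    span = (az1 - az0) % 360.0
    if span > 0.0 and apical_frac > 0.0:
        az = np.degrees(np.arctan2(Y, X))
        in_wedge = ((az - az0) % 360.0) <= span
        heart_z = zs[np.any(myo | cavity, axis=(0, 1))]
        z_lo, z_hi = heart_z[0], heart_z[-1]
        apical = Z <= z_lo + apical_frac * (z_hi - z_lo)
        labels[myo & in_wedge & np.broadcast_to(apical, myo.shape)] = INFARCT
    return LabelMask(labels=labels, spacing_mm=spec.spacing_mm, origin_mm=origin)


_TISSUE_OF_LABEL = {MYOCARDIUM: "myocardium", LV_BLOOD: "blood", INFARCT: "infarct"}


def build_heart_phantom(spec: PhantomSpec, phase: Phase, t_min: float,
                        seed: int | None = None,
                        washout: WashoutModel | None = None
                        ) -> tuple[VoxelVolume, LabelMask]:
    """Generate one gated CT volume and its ground-truth label mask.

    Each voxel receives the washout HU of its tissue at ``t_min`` plus
    i.i.d. Gaussian noise of SD ``spec.noise_sd_hu``; background sits at a
    fixed soft-tissue level.  ``washout`` defaults to the spec's
    delayed-enhancement (Iohexol) model; pass ``spec.washout_blood_pool``
    for the intravascular-agent ventricular-volume scans.
    """
    if t_min < 0:
        raise ValueError("t_min must be non-negative")
    mask = _phantom_labels(spec, phase)
    model = spec.washout if washout is None else washout
    values = np.full(mask.labels.shape, float(spec.background_hu))
    for label, tissue in _TISSUE_OF_LABEL.items():
        values[mask.labels == label] = model.hu(tissue, t_min)
    if spec.noise_sd_hu > 0:
        seed_val = spec.seed if seed is None else seed
        rng = np.random.default_rng(
            np.random.SeedSequence([int(seed_val), _PHASE_CODE[phase]]))
        values = values + rng.normal(0.0, spec.noise_sd_hu, size=values.shape)
    vol = VoxelVolume(values=values, spacing_mm=spec.spacing_mm,
                      origin_mm=mask.origin_mm)
    return vol, mask


def add_motion_streaks(vol: VoxelVolume, severity: float,
                       seed: int | None = None,
                       n_streaks: int = 15,
                       amplitude_hu_per_unit: float = 220.0) -> VoxelVolume:
    """Corrupt a volume with bright oriented streaks, as produced by
    residual cardiorespiratory motion under suboptimal gating.

    Streaks are in-plane lines through the heart with a Gaussian
    cross-section (~2 voxels) and a limited axial footprint; their amplitude
    is ``amplitude_hu_per_unit * severity``, bright enough that myocardium
    under a streak crosses any delayed-enhancement threshold, so downstream
    infarct segmentation over-counts.  ``severity = 0`` returns the input
    unchanged.
    """
    if severity < 0:
        raise ValueError("severity must be non-negative")
    if severity == 0:
        return VoxelVolume(values=vol.values.copy(), spacing_mm=vol.spacing_mm,
                           origin_mm=vol.origin_mm)
    rng = np.random.default_rng(seed)
    xs = vol.axis_coords_mm(0)
    ys = vol.axis_coords_mm(1)
    zs = vol.axis_coords_mm(2)
    X = xs[:, None]
    Y = ys[None, :]
    width_mm = 2.0 * vol.spacing_mm
    sigma_z_mm = 0.8
    amp = amplitude_hu_per_unit * severity
    r_max = 0.6 * min(xs[-1], ys[-1])
    out = vol.values.copy()
    # Super-Gaussian cross-sections: a saturated bright core with steep
    # flanks, like the hard streaks of inconsistent projections, rather than
    # a soft haze that would shift the whole myocardial HU distribution.
    for _ in range(n_streaks):
        theta = rng.uniform(0.0, math.pi)
        offset = rng.uniform(-r_max, r_max)
        z0 = rng.uniform(zs[0], zs[-1])
        d = np.abs(X * math.sin(theta) - Y * math.cos(theta) - offset)
        plane = amp * np.exp(-0.5 * (d / width_mm) ** 4)
        zprof = np.exp(-0.5 * ((zs - z0) / sigma_z_mm) ** 4)
        out += plane[:, :, None] * zprof[None, None, :]
    return VoxelVolume(values=out, spacing_mm=vol.spacing_mm,
                       origin_mm=vol.origin_mm)


def render_ttc_slices(spec: PhantomSpec, thickness_mm: float = 1.0,
                      pixel_size_mm: float = 0.02,
                      seed: int | None = None) -> list[HistologySlice]:
    """Cut the (diastolic) phantom into short-axis slabs and photograph both
    faces of each as a TTC-stained slice.

    Viable myocardium renders brick red, infarct pale pink, everything else
    (background and the open cavity) white, with per-pixel colour jitter.
    The true per-face areas are recorded from the same sampled label plane
    the image is rendered from.
    """
    if thickness_mm <= 0 or pixel_size_mm <= 0:
        raise ValueError("thickness_mm and pixel_size_mm must be positive")
    if thickness_mm < spec.spacing_mm:
        raise ValueError("slice thickness cannot be below the voxel spacing")
    mask = _phantom_labels(spec, "diastole")
    zs = mask.origin_mm[2] + spec.spacing_mm * np.arange(mask.labels.shape[2])
    z_lo = -0.5 * spec.heart_extent_mm()
    extent = spec.heart_extent_mm()
    n_slices = max(1, math.ceil(extent / thickness_mm - 1e-9))

    xs = mask.origin_mm[0] + spec.spacing_mm * np.arange(mask.labels.shape[0])
    ys = mask.origin_mm[1] + spec.spacing_mm * np.arange(mask.labels.shape[1])
    px = np.arange(xs[0], xs[-1] + pixel_size_mm / 2, pixel_size_mm)
    py = np.arange(ys[0], ys[-1] + pixel_size_mm / 2, pixel_size_mm)
    ix = np.clip(np.round((px - xs[0]) / spec.spacing_mm).astype(int), 0, len(xs) - 1)
    iy = np.clip(np.round((py - ys[0]) / spec.spacing_mm).astype(int), 0, len(ys) - 1)

    rng = np.random.default_rng(spec.seed if seed is None else seed)
    palette = np.array([BACKGROUND_RGB, VIABLE_RGB, BACKGROUND_RGB, INFARCT_RGB],
                       dtype=float)
    pixel_area = pixel_size_mm ** 2

    def face(z_mm: float):
        iz = int(np.clip(np.round((z_mm - zs[0]) / spec.spacing_mm), 0,
                         len(zs) - 1))
        plane = mask.labels[:, :, iz]
        sampled = plane[np.ix_(ix, iy)].T  # rows = y, cols = x
        img = palette[sampled]
        img = img + rng.normal(0.0, COLOR_JITTER_SD, size=img.shape)
        img = np.clip(img, 0, 255).astype(np.uint8)
        infarct_area = float(np.count_nonzero(sampled == INFARCT) * pixel_area)
        tissue_area = float(np.count_nonzero(
            (sampled == MYOCARDIUM) | (sampled == INFARCT)) * pixel_area)
        return img, infarct_area, tissue_area

    slices = []
    for k in range(n_slices):
        z_front = z_lo + k * thickness_mm + spec.spacing_mm / 2
        z_back = min(z_lo + (k + 1) * thickness_mm, z_lo + extent) - spec.spacing_mm / 2
        f_img, f_inf, f_tis = face(z_front)
        b_img, b_inf, b_tis = face(z_back)
        slices.append(HistologySlice(
            front_image=f_img, back_image=b_img,
            pixel_size_mm=pixel_size_mm, thickness_mm=thickness_mm,
            true_infarct_area_front_mm2=f_inf, true_infarct_area_back_mm2=b_inf,
            true_tissue_area_front_mm2=f_tis, true_tissue_area_back_mm2=b_tis))
    return slices


@lru_cache(maxsize=8)
def _shell_apical_fraction(dia_semiaxes: tuple, wall_mm: float,
                           apical_fraction: float,
                           coarse_spacing_mm: float = 0.12) -> float:
    """Fraction of the myocardial shell volume lying within the apical
    ``apical_fraction`` of the heart's long axis (coarse voxel estimate)."""
    probe = PhantomSpec(lv_cavity_semiaxes_dia_mm=dia_semiaxes,
                        lv_cavity_semiaxes_sys_mm=tuple(0.9 * s for s in dia_semiaxes),
                        wall_thickness_mm=wall_mm,
                        infarct_wedge=(0.0, 360.0 - 1e-9, apical_fraction),
                        noise_sd_hu=0.0, spacing_mm=coarse_spacing_mm)
    mask = _phantom_labels(probe, "diastole")
    shell = mask.count(MYOCARDIUM) + mask.count(INFARCT)
    return mask.count(INFARCT) / shell


def azimuth_span_for_infarct_fraction(target_fraction: float,
                                      dia_semiaxes: Sequence[float],
                                      wall_mm: float,
                                      apical_fraction: float) -> float:
    """Azimuthal wedge span (degrees) whose infarct occupies
    ``target_fraction`` of the myocardial shell, for the given geometry."""
    if not (0.0 <= target_fraction < 1.0):
        raise ValueError("target_fraction must lie in [0, 1)")
    if target_fraction == 0.0:
        return 0.0
    g = _shell_apical_fraction(tuple(float(s) for s in dia_semiaxes),
                               float(wall_mm), float(apical_fraction))
    span = 360.0 * target_fraction / g
    return float(min(span, 360.0 - 1e-6))


# Study-condition cohort parameters: group EF means/SDs as reported for the
# seven ischemia-reperfusion and seven control animals, infarct load centred
# near the observed ~32% of the LV wall.
IR_EF_MEAN, IR_EF_SD = 0.36, 0.11
CONTROL_EF_MEAN, CONTROL_EF_SD = 0.59, 0.07
IR_INFARCT_FRACTION_MEAN, IR_INFARCT_FRACTION_SD = 0.32, 0.08
_APICAL_EXTENT_FRACTION = 0.75
_INFARCT_AZ_START = -100.0  # anterior (LAD-territory) wedge centre


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo < x < hi:
            return float(x)
    raise RuntimeError("truncated normal rejection sampling failed")


def simulate_cohort(n_ir: int, n_control: int, seed: int,
                    **spec_kwargs) -> list[PhantomSpec]:
    """Draw a cohort of phantom specs matching the study's group structure.

    IR subjects draw true EF from N(0.36, 0.11) truncated to (0.05, 0.95)
    and infarct load from N(0.32, 0.08) truncated to (0, 0.6); controls draw
    EF from N(0.59, 0.07) and carry no infarct.
    """
    if n_ir < 0 or n_control < 0:
        raise ValueError("cohort sizes must be non-negative")
    rng = np.random.default_rng(seed)
    kwargs = dict(spec_kwargs)
    dia = tuple(kwargs.pop("lv_cavity_semiaxes_dia_mm", (2.0, 2.0, 3.3)))
    wall = kwargs.get("wall_thickness_mm", 1.0)
    specs: list[PhantomSpec] = []
    for i in range(n_ir):
        ef = _truncated_normal(rng, IR_EF_MEAN, IR_EF_SD, 0.05, 0.95)
        frac = _truncated_normal(rng, IR_INFARCT_FRACTION_MEAN,
                                 IR_INFARCT_FRACTION_SD, 0.0, 0.6)
        span = azimuth_span_for_infarct_fraction(
            frac, dia, wall, _APICAL_EXTENT_FRACTION)
        spec = PhantomSpec.from_ef(
            ef, lv_cavity_semiaxes_dia_mm=dia,
            **{**kwargs,
               "infarct_wedge": (_INFARCT_AZ_START, _INFARCT_AZ_START + span,
                                 _APICAL_EXTENT_FRACTION),
               "seed": int(rng.integers(2 ** 31)),
               "subject_id": i + 1, "group": "IR"})
        specs.append(spec)
    for j in range(n_control):
        ef = _truncated_normal(rng, CONTROL_EF_MEAN, CONTROL_EF_SD, 0.05, 0.95)
        spec = PhantomSpec.from_ef(
            ef, lv_cavity_semiaxes_dia_mm=dia,
            **{**kwargs, "seed": int(rng.integers(2 ** 31)),
               "subject_id": n_ir + j + 1, "group": "control"})
        specs.append(spec)
    return specs
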