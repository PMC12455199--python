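"""Synthetic cystic-kidney CT phantoms and a matching clinical cohort.

The generator plants a single latent disease-severity axis ``s`` per patient
that simultaneously drives kidney volume (ht-TKV), baseline eGFR, the rate
of eGFR decline, and the textural heterogeneity ``h`` of the parenchyma —
so that every downstream stage (feature extraction, univariate screening,
logistic modelling) can be exercised and its parameter recovery tested with
no external data.

Texture model. The parenchyma HU field is a mixture of three zero-mean
components: fine-grained voxel speckle (weight falling with heterogeneity
``h``), an in-plane smooth structural field (fixed weight) and a slice-wise
attenuation drift along the organ axis (weight rising with ``h``); the
mixed field is rank-remapped to an exact Gaussian marginal so that the
grey-level *histogram* of a cyst-free phantom carries no information about
``h`` — heterogeneity is encoded purely in the spatial arrangement of the
values. Cysts are spheres of near-uniform fluid attenuation below the
parenchyma mean; their number, size and HU contrast grow with ``h``.
Rising ``h`` therefore replaces fine in-plane speckle with large coherent
structures: the in-plane lag-1 correlation rises while the in-plane
variance falls, which moves the co-occurrence correlation up and the
(merged) cluster tendency down — the direction observed when comparing
heterogeneous cystic tissue with homogeneous parenchyma.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .endpoints import invert_ckd_epi, mic_class
from .imaging import CTVolume, SegmentationMask

__all__ = [
    "PhantomParams",
    "CohortParams",
    "Cohort",
    "generate_phantom",
    "generate_cohort",
]


@dataclass(frozen=True)
class PhantomParams:
    """Geometry, attenuation and texture parameters of one phantom."""

    shape: tuple[int, int, int] = (48, 96, 96)  # (slice, row, col) voxels
    spacing: tuple[float, float, float] = (1.5, 1.0, 1.0)  # mm
    semi_axes_mm: tuple[float, float, float] = (30.0, 25.0, 16.0)  # per kidney (z, y, x)
    parenchyma_hu: float = 35.0
    parenchyma_sd: float = 12.0  # fine-grained noise scale at h = 0
    cyst_hu_offset: float = 6.0  # cyst contrast below parenchyma at h = 0
    cyst_sd: float = 2.0  # between-cyst HU spread
    n_cysts: int = 30  # nominal count, modulated by h
    cyst_r_logmean: float = 1.25  # ln(mm)
    cyst_r_logsd: float = 0.35
    heterogeneity: float = 0.5  # h in [0, 1]
    smooth_width: float = 2.0  # voxels, structural-field smoothing sigma
    background_hu: float = -80.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.heterogeneity <= 1.0:
            raise ValueError("heterogeneity must lie in [0, 1]")
        if self.n_cysts < 0:
            raise ValueError("cyst count must be non-negative")
        if min(self.parenchyma_sd, self.cyst_sd, self.cyst_r_logsd) < 0:
            raise ValueError("standard deviations must be non-negative")


class GeometryError(ValueError):
    """Kidneys overlap or do not fit inside the grid."""


def _ellipsoid_mask(shape, spacing, center_mm, semi_axes_mm) -> np.ndarray:
    grids = np.ogrid[: shape[0], : shape[1], : shape[2]]
    q = sum(
        ((g * sp - c) / ax) ** 2
        for g, sp, c, ax in zip(grids, spacing, center_mm, semi_axes_mm)
    )
    return q <= 1.0


def _kidney_centers_mm(shape, spacing) -> tuple[np.ndarray, np.ndarray]:
    extent = np.array(shape) * np.array(spacing)
    left = extent * np.array([0.5, 0.5, 0.27])
    right = extent * np.array([0.5, 0.5, 0.73])
    return left, right


def generate_phantom(
    params: PhantomParams,
) -> tuple[CTVolume, SegmentationMask, SegmentationMask]:
    """Simulate one non-contrast CT of two cystic kidneys.

    Returns the volume and the left/right parenchyma masks. Deterministic
    for a fixed parameter set (including the seed).
    """
    p = params
    h = p.heterogeneity
    rng = np.random.default_rng(p.seed)
    shape, spacing = p.shape, p.spacing
    extent = np.array(shape) * np.array(spacing)

    c_left, c_right = _kidney_centers_mm(shape, spacing)
    for c in (c_left, c_right):
        if np.any(c - p.semi_axes_mm < 0) or np.any(c + p.semi_axes_mm > extent):
            raise GeometryError("kidney ellipsoid exceeds the grid")
    mask_l = _ellipsoid_mask(shape, spacing, c_left, p.semi_axes_mm)
    mask_r = _ellipsoid_mask(shape, spacing, c_right, p.semi_axes_mm)
    if (mask_l & mask_r).any():
        raise GeometryError("kidney ellipsoids overlap")

    both = mask_l | mask_r

    # noise budget: heterogeneity shifts variance from fine in-plane speckle
    # to a slowly varying slice-wise attenuation drift, keeping the global
    # histogram spread roughly constant while in-plane spatial correlation
    # rises and in-plane variance falls
    w = np.sqrt(max(1.0 - 0.9 * h, 0.08))
    b = np.sqrt(0.9 * h)
    # in-plane smooth structural field: fixed amplitude
    a = 0.55
    smooth = ndimage.gaussian_filter(rng.standard_normal(shape), p.smooth_width)
    smooth /= smooth.std()
    drift = ndimage.gaussian_filter1d(rng.standard_normal(shape[0]), 1.5)
    drift /= drift.std()

    field = (
        a * smooth[both]
        + (b * drift)[np.nonzero(both)[0]]
        + w * rng.standard_normal(int(both.sum()))
    )
    # rank-remap the parenchyma field to an exact Gaussian marginal: the
    # grey-level histogram then carries no heterogeneity information and
    # h is encoded purely in the spatial arrangement of the values
    n_vox = field.size
    quantiles = stats.norm.ppf((np.arange(n_vox) + 0.5) / n_vox)
    ranks = np.argsort(np.argsort(field))
    vol = np.full(shape, p.background_hu, dtype=float)
    vol[both] = p.parenchyma_hu + p.parenchyma_sd * quantiles[ranks]

    # fluid-filled cysts: more, larger and more contrasted at high h
    n_cysts = int(round(p.n_cysts * (0.4 + 1.2 * h)))
    contrast = p.cyst_hu_offset + 4.0 * h
    zz, yy, xx = np.meshgrid(
        np.arange(shape[0]) * spacing[0],
        np.arange(shape[1]) * spacing[1],
        np.arange(shape[2]) * spacing[2],
        indexing="ij",
    )
    for k in range(n_cysts):
        center_kidney = c_left if k % 2 == 0 else c_right
        # rejection-sample a center inside the shrunken ellipsoid
        for _ in range(100):
            u = rng.uniform(-0.8, 0.8, size=3)
            if (u**2).sum() <= 0.64:
                break
        center = center_kidney + u * np.asarray(p.semi_axes_mm)
        radius = float(np.exp(rng.normal(p.cyst_r_logmean + 0.35 * h, p.cyst_r_logsd)))
        cyst_val = p.parenchyma_hu - contrast + rng.normal(0.0, p.cyst_sd)
        sphere = (
            (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2
        ) <= radius**2
        sel = sphere & both
        if sel.any():
            # cyst fluid is nearly uniform: small residual noise only
            vol[sel] = cyst_val + 1.5 * rng.standard_normal(int(sel.sum()))

    volume = CTVolume(intensities=vol, spacing=spacing)
    left = SegmentationMask(labels=mask_l, side="left", spacing=spacing)
    right = SegmentationMask(labels=mask_r, side="right", spacing=spacing)
    return volume, left, right


@dataclass(frozen=True)
class CohortParams:
    """Statistical structure of the synthetic cohort.

    The severity-effect coefficients couple the latent severity ``s`` to
    ht-TKV (log scale), baseline eGFR, texture heterogeneity (logit scale)
    and the eGFR slope; noise SDs control how tightly each observable
    tracks severity.
    """

    n: int = 58
    beta_tkv: float = 0.5  # ln(mL/m) per severity SD
    beta_egfr: float = 70.0  # mL/min/1.73 m^2 per severity SD
    beta_slope: float = 3.0  # extra yearly decline over the h range
    beta_texture: float = 1.5  # logit(h) per severity SD
    sd_tkv: float = 0.25
    sd_egfr: float = 8.0
    sd_texture: float = 0.6
    sd_slope: float = 0.8
    sd_measurement: float = 2.5  # per-visit eGFR noise
    visit_interval_months: float = 4.6
    span_months: float = 18.4
    n_visit_deficient: int = 0  # patients given < 3 creatinine values
    rapid_threshold: float = 3.0
    baseline_cutoff: float = 60.0
    egfr_equation: str = "2009"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 10:
            raise ValueError("cohort size must be at least 10")
        if self.span_months < 6:
            raise ValueError("follow-up span must be at least 6 months")
        if int(self.span_months // self.visit_interval_months) + 1 < 3:
            raise ValueError("schedule must yield at least 3 visits")
        if not 0 <= self.n_visit_deficient <= self.n:
            raise ValueError("n_visit_deficient out of range")


@dataclass
class Cohort:
    """Synthetic cohort: per-patient truth, visit-level clinical table and
    per-patient phantom parameters."""

    patients: pd.DataFrame  # indexed by patient_id; includes latent truth
    visits: pd.DataFrame  # long clinical table (the CSV schema)
    phantom_params: dict[str, PhantomParams]
    params: CohortParams


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_cohort(cp: CohortParams, pp: PhantomParams | None = None) -> Cohort:
    """Draw a synthetic patient cohort with a planted texture-outcome link.

    Per patient: severity s ~ N(0,1); age ~ N(47, 11) truncated to
    [25, 75]; 45% male; ln ht-TKV = ln 900 + beta_tkv*s + noise;
    heterogeneity h = sigmoid(beta_texture*s + noise); baseline
    eGFR = 100 - (age - 40) - beta_egfr*s + noise (floored at 5);
    true slope = -(1.5 + beta_slope*h) + noise. Visit-level eGFR adds
    measurement noise and is converted to serum creatinine by numerically
    inverting the CKD-EPI equation, so the clinical table round-trips
    through the endpoint derivation.
    """
    if pp is None:
        pp = PhantomParams()
    rng = np.random.default_rng(cp.seed)
    n = cp.n

    s = rng.standard_normal(n)
    # rounded to the precision written in the clinical table, so that the
    # creatinine inversion is consistent with the recorded covariates
    age = np.round(np.clip(rng.normal(47.0, 11.0, n), 25.0, 75.0), 1)
    male = rng.random(n) < 0.45
    sex = np.where(male, "M", "F")
    height = np.round(np.where(male, rng.normal(1.76, 0.07, n), rng.normal(1.63, 0.065, n)), 3)
    ht_tkv = np.exp(np.log(900.0) + cp.beta_tkv * s + rng.normal(0, cp.sd_tkv, n))
    h = _sigmoid(cp.beta_texture * s + rng.normal(0, cp.sd_texture, n))
    # floored at 5 (dialysis range) and capped at a physiological 120
    egfr0 = np.clip(
        100.0 - 1.0 * (age - 40.0) - cp.beta_egfr * s + rng.normal(0, cp.sd_egfr, n),
        5.0,
        120.0,
    )
    slope = -(1.5 + cp.beta_slope * h) + rng.normal(0, cp.sd_slope, n)
    tolvaptan = rng.random(n) < _sigmoid(1.2 * s - 1.3)

    n_full_visits = int(cp.span_months // cp.visit_interval_months) + 1
    deficient = np.zeros(n, dtype=bool)
    if cp.n_visit_deficient:
        deficient[rng.choice(n, size=cp.n_visit_deficient, replace=False)] = True

    width = len(str(n))
    pids = [f"P{i + 1:0{width}d}" for i in range(n)]
    phantom_params: dict[str, PhantomParams] = {}
    visit_rows = []
    patient_rows = []
    child_seeds = rng.integers(0, 2**31 - 1, size=2 * n)

    for i, pid in enumerate(pids):
        n_vis = 2 if deficient[i] else n_full_visits
        vrng = np.random.default_rng(child_seeds[2 * i])
        for v in range(n_vis):
            t_months = v * cp.visit_interval_months
            g = egfr0[i] + slope[i] * (t_months / 12.0) + vrng.normal(0, cp.sd_measurement)
            g = float(np.clip(g, 5.0, 120.0))
            creat = invert_ckd_epi(g, float(age[i]), str(sex[i]), cp.egfr_equation)
            visit_rows.append(
                {
                    "patient_id": pid,
                    "age": round(float(age[i]), 1),
                    "sex": str(sex[i]),
                    "height_m": round(float(height[i]), 3),
                    "visit_month": round(t_months, 2),
                    "creatinine_mg_dl": round(float(creat), 6),
                    "ht_tkv_ml_per_m": round(float(ht_tkv[i]), 1),
                    "tolvaptan_flag": int(tolvaptan[i]),
                }
            )

        # kidney size tracks ht-TKV so morphology co-varies with severity
        scale = float(np.clip((ht_tkv[i] / 900.0) ** (1.0 / 3.0), 0.8, 1.18))
        phantom_params[pid] = dataclasses.replace(
            pp,
            heterogeneity=float(h[i]),
            semi_axes_mm=tuple(ax * scale for ax in pp.semi_axes_mm),
            seed=int(child_seeds[2 * i + 1]),
        )
        patient_rows.append(
            {
                "patient_id": pid,
                "age": round(float(age[i]), 1),
                "sex": str(sex[i]),
                "height_m": round(float(height[i]), 3),
                "ht_tkv": round(float(ht_tkv[i]), 1),
                "tolvaptan": bool(tolvaptan[i]),
                "mic": mic_class(float(ht_tkv[i]), float(age[i])),
                "severity": float(s[i]),
                "heterogeneity": float(h[i]),
                "egfr0_true": float(egfr0[i]),
                "slope_true": float(slope[i]),
                "n_visits": n_vis,
            }
        )

    patients = pd.DataFrame(patient_rows).set_index("patient_id")
    visits = pd.DataFrame(visit_rows)
    return Cohort(patients=patients, visits=visits, phantom_params=phantom_params, params=cp)
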