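"""Synthetic en-face OCT-A eyes and cohorts with known ground truth.

The study design this package targets compares perfusion metrics between
multiple-sclerosis (MS) and control eyes, but raw angiograms of such studies
are rarely deposited.  This module generates synthetic eyes — three slab
images (SCP, DCP, CC), FAZ boundary polygons, a large-vessel truth mask —
whose ground-truth metrics are controllable, plus whole cohorts whose
covariate distributions and per-group outcome means/SDs are configurable,
including the inter-eye correlation within a participant.

Generator model
---------------
* Capillary beds are band-pass-filtered Gaussian random fields thresholded
  at the exact quantile that yields the requested vessel density; vessel
  pixels are rendered bright on a dark background with additive noise.
* Large vessels are smooth, slightly curved strokes crossing the image,
  avoiding the foveal center; stroke width is solved by bisection so the
  large-vessel density inside the analysis annulus matches its target.
* The FAZ is a star-convex polygon: a circle of exact target area whose
  radius is modulated by low-order random harmonics; the modulation
  amplitude can be calibrated by bisection to reach a target circularity.
* The choriocapillaris is a bright granular field with dark "void" blobs
  occupying a controllable fraction of the annulus; void and background
  intensities are separated well beyond the noise scale so the mean-minus-SD
  threshold recovers the planted voids.
* Cohort outcomes are drawn per eye as group mean + participant effect +
  eye effect, giving an exchangeable inter-eye correlation rho; images are
  then synthesized so that the measured ground truth (counted directly on
  the emitted masks) matches the drawn targets.

Determinism: a master seed spawns per-eye seeds through
``numpy.random.SeedSequence(master_seed).spawn``; identical configuration
and seed reproduce cohorts bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import shapely
from scipy.ndimage import binary_dilation, gaussian_filter
from shapely.geometry import LineString

from .magnification import AnnulusSpec, EyeBiometry, annulus_mask, bennett_actual_scan_length, pixel_scale
from .metrics import OUTCOME_COLUMNS, EyeMetrics, _disk, faz_area, faz_circularity
from .segmentation import EnFaceAngiogram, FazAnnotation, rasterize_faz

__all__ = [
    "VesselFieldParams",
    "FazParams",
    "CcParams",
    "GroupConfig",
    "CohortConfig",
    "EyeRecord",
    "EyeBundle",
    "generate_capillary_bed",
    "generate_faz",
    "calibrate_faz_irregularity",
    "generate_eye",
    "generate_truth_table",
    "generate_cohort",
    "iter_cohort",
    "default_cohort_config",
]

DEFAULT_GRID = 245

_BG_LEVEL = 40.0
_CAP_LEVEL = 170.0
_LV_LEVEL = 230.0
_CC_VOID_DEPTH = 100.0


# --------------------------------------------------------------------------
# parameter blocks


@dataclass(frozen=True)
class VesselFieldParams:
    """Capillary-bed and large-vessel generation parameters for one plexus.

    ``target_density`` is the vessel fraction of the full grid (exact up to
    one pixel).  When ``lv_target_density`` is given, the stroke width is
    solved so the large-vessel fraction of the analysis annulus matches it;
    otherwise ``lv_width_px`` is used as drawn.
    """

    target_density: float
    capillary_scale: float = 2.0
    n_large_vessels: int = 4
    lv_width_px: float = 4.0
    lv_target_density: Optional[float] = None
    noise_sd: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.target_density <= 1.0):
            raise ValueError("target_density must be in [0, 1]")
        if self.capillary_scale <= 0:
            raise ValueError("capillary_scale must be positive")
        if self.n_large_vessels < 0:
            raise ValueError("n_large_vessels must be >= 0")
        if self.lv_width_px <= 0:
            raise ValueError("lv_width_px must be positive")
        if self.lv_target_density is not None and not (
            0.0 <= self.lv_target_density < 0.5
        ):
            raise ValueError("lv_target_density must be in [0, 0.5)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class FazParams:
    """FAZ polygon parameters: target area, boundary irregularity, resolution."""

    area_mm2: float
    irregularity: float = 0.0
    n_vertices: int = 180
    seed: int = 0

    def __post_init__(self) -> None:
        if self.area_mm2 <= 0:
            raise ValueError("area_mm2 must be positive")
        if self.irregularity < 0:
            raise ValueError("irregularity must be >= 0")
        if self.n_vertices < 8:
            raise ValueError("need at least 8 vertices")


@dataclass(frozen=True)
class CcParams:
    """Choriocapillaris texture parameters.

    ``deficit_fraction`` is the flow-void fraction of the analysis annulus;
    ``granule_scale`` sets the blob size of the void texture;
    ``sd_intensity`` is the additive pixel noise SD.
    """

    deficit_fraction: float
    mean_intensity: float = 170.0
    sd_intensity: float = 8.0
    granule_scale: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.deficit_fraction <= 1.0):
            raise ValueError("deficit_fraction must be in [0, 1]")
        if self.granule_scale <= 0:
            raise ValueError("granule_scale must be positive")


@dataclass
class EyeRecord:
    """Biometry, covariates and group label for one eye."""

    participant_id: str
    eye: str  # OD | OS
    group: str  # MS | control
    age: float
    gender: str  # male | female
    iop_mmHg: float
    axial_length_mm: float
    hypertension: int
    signal_strength: int
    duration_years: float
    episodes: int
    rnfl_um: float


@dataclass
class EyeBundle:
    """One synthetic eye: images, annotations, truth masks and truth metrics."""

    record: EyeRecord
    images: Dict[str, EnFaceAngiogram]
    faz: Dict[str, FazAnnotation]
    lv_mask: np.ndarray
    capillary_masks: Dict[str, np.ndarray]
    void_mask: np.ndarray
    truth: EyeMetrics


# --------------------------------------------------------------------------
# low-level texture generators


def _bandpass_field(rng: np.random.Generator, shape: Tuple[int, int], scale: float) -> np.ndarray:
    white = rng.standard_normal(shape)
    return gaussian_filter(white, scale) - gaussian_filter(white, 3.0 * scale)


def _threshold_top_k(field_vals: np.ndarray, k: int) -> np.ndarray:
    """Boolean mask of the k largest entries (exact count, ties broken by order)."""
    flat = field_vals.ravel()
    mask = np.zeros(flat.shape, dtype=bool)
    if k > 0:
        idx = np.argpartition(flat, flat.size - k)[flat.size - k :]
        mask[idx] = True
    return mask.reshape(field_vals.shape)


def _region_exact_mask(
    field_vals: np.ndarray,
    region_in: np.ndarray,
    region_out: np.ndarray,
    k_in: int,
) -> np.ndarray:
    """Select exactly ``k_in`` top-field pixels inside ``region_in`` and the
    density-matched count inside ``region_out`` (one shared texture field,
    so the pattern stays visually continuous across the region boundary)."""
    n_in, n_out = int(region_in.sum()), int(region_out.sum())
    k_in = int(np.clip(k_in, 0, n_in))
    mask = np.zeros(field_vals.shape, dtype=bool)
    if k_in > 0:
        mask |= _threshold_top_k(np.where(region_in, field_vals, -np.inf), k_in)
    if n_in > 0 and n_out > 0:
        k_out = int(round(k_in / n_in * n_out))
        if k_out > 0:
            mask |= _threshold_top_k(np.where(region_out, field_vals, -np.inf), k_out)
    return mask


def generate_capillary_bed(
    params: VesselFieldParams,
    shape: Tuple[int, int] = (DEFAULT_GRID, DEFAULT_GRID),
) -> Tuple[np.ndarray, np.ndarray]:
    """Generate a capillary plexus image and its true vessel mask.

    The mask density over the full grid equals ``target_density`` to within
    one pixel; vessel pixels are rendered at a brighter level than the
    background, with additive Gaussian noise.
    """
    if shape[0] <= 0 or shape[1] <= 0:
        raise ValueError("grid must be positive")
    rng = np.random.default_rng(params.seed)
    n = shape[0] * shape[1]
    k = int(round(params.target_density * n))
    if k == 0:
        mask = np.zeros(shape, dtype=bool)
    elif k == n:
        mask = np.ones(shape, dtype=bool)
    else:
        field_vals = _bandpass_field(rng, shape, params.capillary_scale)
        mask = _threshold_top_k(field_vals, k)
    img = np.full(shape, _BG_LEVEL)
    img[mask] = _CAP_LEVEL
    if params.noise_sd > 0:
        img = img + params.noise_sd * rng.standard_normal(shape)
    return np.clip(img, 0.0, 255.0), mask


def _stroke_geometry(
    rng: np.random.Generator,
    shape: Tuple[int, int],
    n_strokes: int,
    avoid_radius_px: float,
    outer_radius_px: float,
) -> List[np.ndarray]:
    """Centerlines of large-vessel strokes: slightly curved chords that
    cross the annulus while avoiding the foveal center."""
    ny, nx = shape
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    half = max(nx, ny) / 2.0
    lines = []
    for _ in range(n_strokes):
        phi = rng.uniform(0.0, np.pi)
        lo = avoid_radius_px + 4.0
        hi = max(lo + 5.0, 0.85 * outer_radius_px)
        d_perp = rng.uniform(lo, hi) * rng.choice([-1.0, 1.0])
        bend = rng.uniform(-10.0, 10.0)
        u = np.array([np.cos(phi), np.sin(phi)])
        nvec = np.array([-np.sin(phi), np.cos(phi)])
        t = np.linspace(-1.6 * half, 1.6 * half, 61)
        pts = (
            np.array([cx, cy])
            + d_perp * nvec
            + t[:, None] * u
            + bend * (t[:, None] / (1.6 * half)) ** 2 * nvec
        )
        lines.append(pts)
    return lines


def _rasterize_buffered(
    lines: Sequence[np.ndarray], width_px: float, shape: Tuple[int, int]
) -> np.ndarray:
    """Pixel-center rasterization of the union of buffered centerlines."""
    ny, nx = shape
    mask = np.zeros(shape, dtype=bool)
    for pts in lines:
        geom = LineString(pts).buffer(width_px / 2.0)
        xmin, ymin, xmax, ymax = geom.bounds
        x0, x1 = max(0, int(np.floor(xmin))), min(nx - 1, int(np.ceil(xmax)))
        y0, y1 = max(0, int(np.floor(ymin))), min(ny - 1, int(np.ceil(ymax)))
        if x1 < x0 or y1 < y0:
            continue
        yy, xx = np.mgrid[y0 : y1 + 1, x0 : x1 + 1]
        inside = shapely.contains_xy(geom, xx.ravel(), yy.ravel()).reshape(yy.shape)
        mask[y0 : y1 + 1, x0 : x1 + 1] |= inside
    return mask


def _draw_large_vessels(
    rng: np.random.Generator,
    shape: Tuple[int, int],
    n_strokes: int,
    width_px: float,
    annulus: np.ndarray,
    avoid_radius_px: float,
    target_annulus_density: Optional[float] = None,
) -> np.ndarray:
    """Draw large-vessel strokes; optionally solve the width by bisection so
    the in-annulus density matches the target."""
    if n_strokes == 0 or (target_annulus_density is not None and target_annulus_density <= 0):
        return np.zeros(shape, dtype=bool)
    ny, nx = shape
    r_out = float(np.hypot(*np.nonzero(annulus)).max()) if annulus.any() else min(nx, ny) / 2.5
    # outer radius of the annulus in pixels, from the mask itself
    yy, xx = np.nonzero(annulus)
    if len(xx):
        cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
        r_out = float(np.hypot(xx - cx, yy - cy).max())
    lines = _stroke_geometry(rng, shape, n_strokes, avoid_radius_px, r_out)
    if target_annulus_density is None:
        return _rasterize_buffered(lines, width_px, shape)
    n_ann = int(annulus.sum())
    target_count = target_annulus_density * n_ann

    def count(w: float) -> int:
        return int((_rasterize_buffered(lines, w, shape) & annulus).sum())

    lo, hi = 0.3, 16.0
    if count(hi) < target_count:
        raise ValueError("large-vessel density target unreachable with this geometry")
    for _ in range(28):
        mid = 0.5 * (lo + hi)
        if count(mid) < target_count:
            lo = mid
        else:
            hi = mid
    return _rasterize_buffered(lines, hi, shape)


def generate_faz(
    params: FazParams,
    pixel_scale_mm: float,
    slab: str = "SCP",
    grid_px: int = DEFAULT_GRID,
    center_px: Optional[Tuple[float, float]] = None,
) -> FazAnnotation:
    """Generate a star-convex FAZ boundary polygon in pixel coordinates.

    The polygon area equals ``area_mm2`` exactly (radii are rescaled after
    perturbation); ``irregularity`` is the RMS amplitude of the low-order
    harmonic modulation of the radius, with 0 yielding a regular polygon
    approximating a circle (circularity -> 1).
    """
    if pixel_scale_mm <= 0:
        raise ValueError("pixel scale must be positive")
    rng = np.random.default_rng(params.seed)
    theta = np.linspace(0.0, 2.0 * np.pi, params.n_vertices, endpoint=False)
    pert = np.zeros_like(theta)
    if params.irregularity > 0:
        for m in range(2, 8):
            a = rng.standard_normal() / m
            phi = rng.uniform(0.0, 2.0 * np.pi)
            pert += a * np.cos(m * theta + phi)
        rms = float(np.sqrt(np.mean(pert**2)))
        if rms > 0:
            pert = pert / rms * params.irregularity
        pert = np.clip(pert, -0.85, 1.5)
    r0 = math.sqrt(params.area_mm2 / math.pi)
    r = r0 * (1.0 + pert)
    x = r * np.cos(theta)
    y = r * np.sin(theta)
    # shoelace area of the perturbed polygon, then rescale to the exact target
    area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    s = math.sqrt(params.area_mm2 / area)
    x, y = x * s, y * s
    if center_px is None:
        c = (grid_px - 1) / 2.0
        center_px = (c, c)
    px = np.column_stack([x, y]) / pixel_scale_mm + np.asarray(center_px)
    if np.max(np.hypot(x, y)) / pixel_scale_mm > grid_px / 2.0:
        raise ValueError("FAZ does not fit inside the image grid")
    return FazAnnotation(slab=slab, polygon_px=px)


def calibrate_faz_irregularity(
    area_mm2: float,
    circularity_target: float,
    seed: int,
    n_vertices: int = 180,
) -> float:
    """Solve (by bisection) the irregularity giving a target circularity.

    The mapping irregularity -> circularity is monotone for the harmonic
    boundary model, so bisection converges; targets at or below the regular
    polygon's circularity return 0.
    """
    def circ(irr: float) -> float:
        p = FazParams(area_mm2=area_mm2, irregularity=irr, n_vertices=n_vertices, seed=seed)
        try:
            return faz_circularity(generate_faz(p, pixel_scale_mm=3.0 / DEFAULT_GRID))
        except ValueError:
            return np.inf  # off-grid amplitude: treat as over-shoot

    if circularity_target <= circ(0.0) + 1e-6:
        return 0.0
    lo, hi = 0.0, 0.6
    while circ(hi) < circularity_target and hi < 1.5:
        hi *= 1.25
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if circ(mid) < circularity_target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _generate_cc(
    params: CcParams,
    shape: Tuple[int, int],
    annulus: np.ndarray,
) -> Tuple[np.ndarray, np.ndarray]:
    """CC image and true void mask.

    Voids are planted uniformly (region-exact in the annulus), so their
    density is the same in any subregion in expectation; the in-annulus
    void fraction matches ``deficit_fraction`` to within one pixel.
    """
    rng = np.random.default_rng(params.seed)
    n_ann = int(annulus.sum())
    if n_ann == 0:
        raise ValueError("empty annulus")
    mask = np.zeros(shape, dtype=bool)
    if params.deficit_fraction > 0:
        k_ann = int(round(params.deficit_fraction * n_ann))
        field_vals = _bandpass_field(rng, shape, params.granule_scale)
        mask = _region_exact_mask(field_vals, annulus, ~annulus, k_ann)
    img = np.full(shape, params.mean_intensity)
    img[mask] = params.mean_intensity - _CC_VOID_DEPTH
    if params.sd_intensity > 0:
        img = img + params.sd_intensity * rng.standard_normal(shape)
    return np.clip(img, 0.0, 255.0), mask


# --------------------------------------------------------------------------
# whole-eye assembly


def _quantize(img: np.ndarray) -> np.ndarray:
    """Round to the 8-bit grid the images are stored on."""
    return np.round(np.clip(img, 0.0, 255.0)).astype(np.uint8).astype(float)


def generate_eye(
    vf_scp: VesselFieldParams,
    vf_dcp: VesselFieldParams,
    faz_s: FazParams,
    faz_d: FazParams,
    cc: CcParams,
    record: EyeRecord,
    grid_px: int = DEFAULT_GRID,
    annulus_spec: AnnulusSpec = AnnulusSpec(),
    camera_factor_p: float = 3.382,
    lv_removal_radius_px: float = 5.0,
    annulus_targets: bool = True,
) -> EyeBundle:
    """Assemble one synthetic eye: three slabs, FAZ annotations, truth masks.

    When ``annulus_targets`` is true (the default), ``target_density`` of
    each plexus and ``deficit_fraction`` of the CC are interpreted as the
    desired *annulus* densities of the final composite (after FAZ carving
    and large-vessel overlay), and the full-grid field densities are solved
    accordingly; otherwise the raw full-grid semantics are used.

    The FAZ region is carved vessel-free in both plexus images; large-vessel
    strokes appear only in the SCP.  Ground-truth metrics are obtained by
    direct counting on the emitted masks, so they are exactly reproducible
    from the bundle.
    """
    shape = (grid_px, grid_px)
    biometry = EyeBiometry(record.axial_length_mm, camera_factor_p=camera_factor_p)
    scale = pixel_scale(bennett_actual_scan_length(biometry), grid_px)
    ann = annulus_mask(shape, annulus_spec, scale)
    n_ann = int(ann.sum())

    faz_s_annot = generate_faz(faz_s, scale, slab="SCP", grid_px=grid_px)
    faz_d_annot = generate_faz(faz_d, scale, slab="DCP", grid_px=grid_px)
    faz_s_mask = rasterize_faz(faz_s_annot, shape).mask
    faz_d_mask = rasterize_faz(faz_d_annot, shape).mask

    # large vessels on the SCP, avoiding the superficial FAZ
    c = (grid_px - 1) / 2.0
    verts = faz_s_annot.polygon_px - np.array([c, c])
    avoid_r = float(np.hypot(verts[:, 0], verts[:, 1]).max())
    lv_rng = np.random.default_rng(np.random.SeedSequence((vf_scp.seed, 7)))
    lv = _draw_large_vessels(
        lv_rng,
        shape,
        vf_scp.n_large_vessels,
        vf_scp.lv_width_px,
        ann,
        avoid_r,
        vf_scp.lv_target_density,
    )

    # capillary masks; with annulus targets the in-annulus counts are exact
    if annulus_targets:
        lv_in_ann = int((lv & ann).sum())
        rng_cap_s = np.random.default_rng(vf_scp.seed)
        field_s = _bandpass_field(rng_cap_s, shape, vf_scp.capillary_scale)
        region_in = ann & ~lv & ~faz_s_mask
        region_out = ~ann & ~lv & ~faz_s_mask
        k_in = int(round(vf_scp.target_density * n_ann)) - lv_in_ann
        cap_s = _region_exact_mask(field_s, region_in, region_out, k_in)
        rng_cap_d = np.random.default_rng(vf_dcp.seed)
        field_d = _bandpass_field(rng_cap_d, shape, vf_dcp.capillary_scale)
        region_in_d = ann & ~faz_d_mask
        region_out_d = ~ann & ~faz_d_mask
        k_in_d = int(round(vf_dcp.target_density * n_ann))
        cap_d = _region_exact_mask(field_d, region_in_d, region_out_d, k_in_d)
    else:
        _, cap_s = generate_capillary_bed(vf_scp, shape)
        _, cap_d = generate_capillary_bed(vf_dcp, shape)

    # compose the SCP: capillaries + LV strokes, FAZ carved vessel-free
    rng_s = np.random.default_rng(np.random.SeedSequence((vf_scp.seed, 11)))
    vessel_s = (cap_s | lv) & ~faz_s_mask
    base_s = np.full(shape, _BG_LEVEL)
    base_s[cap_s & ~faz_s_mask] = _CAP_LEVEL
    base_s[lv] = _LV_LEVEL
    if vf_scp.noise_sd > 0:
        base_s = base_s + vf_scp.noise_sd * rng_s.standard_normal(shape)
    img_scp = _quantize(base_s)

    rng_d = np.random.default_rng(np.random.SeedSequence((vf_dcp.seed, 11)))
    vessel_d = cap_d & ~faz_d_mask
    base_d = np.full(shape, _BG_LEVEL)
    base_d[vessel_d] = _CAP_LEVEL
    if vf_dcp.noise_sd > 0:
        base_d = base_d + vf_dcp.noise_sd * rng_d.standard_normal(shape)
    img_dcp = _quantize(base_d)

    img_cc_raw, void_mask = _generate_cc(cc, shape, ann)
    img_cc = _quantize(img_cc_raw)

    lv_dil = binary_dilation(lv, structure=_disk(lv_removal_radius_px)) if lv.any() else lv
    truth = EyeMetrics(
        pd_scp_pct=100.0 * int((vessel_s & ann).sum()) / n_ann,
        pd_scp_wo_lv_pct=100.0 * int((vessel_s & ~lv_dil & ann).sum()) / n_ann,
        pd_lv_pct=100.0 * int((lv & ann).sum()) / n_ann,
        pd_dcp_pct=100.0 * int((vessel_d & ann).sum()) / n_ann,
        faz_area_s_mm2=faz_area(faz_s_annot, scale),
        faz_circ_s=faz_circularity(faz_s_annot),
        faz_area_d_mm2=faz_area(faz_d_annot, scale),
        faz_circ_d=faz_circularity(faz_d_annot),
        fd_cc_pct=100.0 * int((void_mask & ann).sum()) / n_ann,
    )

    return EyeBundle(
        record=record,
        images={
            "SCP": EnFaceAngiogram(img_scp, "SCP"),
            "DCP": EnFaceAngiogram(img_dcp, "DCP"),
            "CC": EnFaceAngiogram(img_cc, "CC"),
        },
        faz={"SCP": faz_s_annot, "DCP": faz_d_annot},
        lv_mask=lv,
        capillary_masks={"SCP": cap_s, "DCP": cap_d},
        void_mask=void_mask,
        truth=truth,
    )


# --------------------------------------------------------------------------
# cohorts


@dataclass
class GroupConfig:
    """Per-group cohort configuration: counts, covariates, outcome truth."""

    n_participants: int
    n_eyes: int
    age_mean: float
    age_sd: float
    male_fraction: float
    iop_mean: float
    iop_sd: float
    axial_length_mean: float
    axial_length_sd: float
    hypertension_prev: float
    signal_mean: float
    signal_sd: float
    duration_mean: float
    duration_sd: float
    episodes_rate: float
    rnfl_mean: float
    rnfl_sd: float
    outcome_means: Dict[str, float]
    outcome_sds: Dict[str, float]

    def __post_init__(self) -> None:
        if self.n_eyes > 2 * self.n_participants or self.n_eyes < self.n_participants:
            raise ValueError("need n_participants <= n_eyes <= 2*n_participants")


@dataclass
class CohortConfig:
    """Full cohort configuration: two groups, correlation, generator knobs."""

    ms: GroupConfig
    control: GroupConfig
    rho: float = 0.5
    master_seed: int = 0
    grid_px: int = DEFAULT_GRID
    camera_factor_p: float = 3.382
    n_large_vessels: int = 4
    capillary_scale: float = 2.0
    noise_sd: float = 12.0
    cc_granule_scale: float = 4.0
    cc_noise_sd: float = 8.0
    faz_n_vertices: int = 180
    lv_removal_radius_px: float = 5.0
    annulus: AnnulusSpec = field(default_factory=AnnulusSpec)
    #: optional per-outcome (duration_slope, episodes_slope) applied to MS eyes
    association_slopes: Dict[str, Tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.rho < 1.0):
            raise ValueError("rho must be in [0, 1)")


def _clustered_sd(se: float, n_eyes: int, n_participants: int, rho: float) -> float:
    """Per-eye SD implied by a reported standard error of a clustered mean."""
    m = n_eyes / n_participants
    deff = 1.0 + rho * (m - 1.0)
    return se * math.sqrt(n_eyes / deff)


def default_cohort_config(master_seed: int = 0, adjusted_means: bool = False) -> CohortConfig:
    """Cohort configuration reproducing the reference study's design.

    Group sizes, covariate distributions and per-group outcome means/SDs
    follow the study's printed characteristics and outcome tables
    (``adjusted_means`` switches the outcome means from the unadjusted to
    the covariate-adjusted set).  Per-eye SDs are recovered from the
    printed standard errors of clustered means with an exchangeable
    design-effect correction at rho = 0.5.
    """
    rho = 0.5
    nC, pC, nM, pM = 136, 78, 100, 58

    def sds(se_map: Mapping[str, float], n: int, p: int) -> Dict[str, float]:
        return {k: _clustered_sd(v, n, p, rho) for k, v in se_map.items()}

    se_control = {
        "pd_scp_pct": 0.3, "pd_scp_wo_lv_pct": 0.3, "pd_lv_pct": 0.1,
        "pd_dcp_pct": 0.4, "faz_area_s_mm2": 0.01, "faz_circ_s": 0.01,
        "faz_area_d_mm2": 0.03, "faz_circ_d": 0.01, "fd_cc_pct": 0.1,
    }
    se_ms = {
        "pd_scp_pct": 0.3, "pd_scp_wo_lv_pct": 0.3, "pd_lv_pct": 0.1,
        "pd_dcp_pct": 0.6, "faz_area_s_mm2": 0.01, "faz_circ_s": 0.02,
        "faz_area_d_mm2": 0.06, "faz_circ_d": 0.02, "fd_cc_pct": 0.2,
    }
    if adjusted_means:
        means_control = {
            "pd_scp_pct": 41.9, "pd_scp_wo_lv_pct": 28.7, "pd_lv_pct": 6.70,
            "pd_dcp_pct": 41.5, "faz_area_s_mm2": 0.25, "faz_circ_s": 1.12,
            "faz_area_d_mm2": 1.06, "faz_circ_d": 1.18, "fd_cc_pct": 16.4,
        }
        means_ms = {
            "pd_scp_pct": 43.1, "pd_scp_wo_lv_pct": 29.8, "pd_lv_pct": 6.55,
            "pd_dcp_pct": 39.2, "faz_area_s_mm2": 0.25, "faz_circ_s": 1.16,
            "faz_area_d_mm2": 1.23, "faz_circ_d": 1.27, "fd_cc_pct": 16.6,
        }
    else:
        means_control = {
            "pd_scp_pct": 41.9, "pd_scp_wo_lv_pct": 28.7, "pd_lv_pct": 6.7,
            "pd_dcp_pct": 41.6, "faz_area_s_mm2": 0.25, "faz_circ_s": 1.12,
            "faz_area_d_mm2": 1.06, "faz_circ_d": 1.17, "fd_cc_pct": 16.4,
        }
        means_ms = {
            "pd_scp_pct": 43.0, "pd_scp_wo_lv_pct": 29.7, "pd_lv_pct": 6.6,
            "pd_dcp_pct": 39.1, "faz_area_s_mm2": 0.25, "faz_circ_s": 1.17,
            "faz_area_d_mm2": 1.24, "faz_circ_d": 1.28, "fd_cc_pct": 16.6,
        }

    control = GroupConfig(
        n_participants=pC, n_eyes=nC,
        age_mean=39.0, age_sd=11.0, male_fraction=0.36,
        iop_mean=15.4, iop_sd=2.5,
        axial_length_mean=23.3, axial_length_sd=0.9,
        hypertension_prev=0.10,
        signal_mean=9.5, signal_sd=0.9,
        duration_mean=0.0, duration_sd=0.0, episodes_rate=0.0,
        rnfl_mean=95.3, rnfl_sd=_clustered_sd(1.0, nC, pC, rho),
        outcome_means=means_control, outcome_sds=sds(se_control, nC, pC),
    )
    ms = GroupConfig(
        n_participants=pM, n_eyes=nM,
        age_mean=41.0, age_sd=11.0, male_fraction=0.33,
        iop_mean=17.3, iop_sd=2.8,
        axial_length_mean=23.2, axial_length_sd=0.9,
        hypertension_prev=0.10,
        signal_mean=9.5, signal_sd=0.9,
        duration_mean=8.0, duration_sd=6.0, episodes_rate=2.5,
        rnfl_mean=86.7, rnfl_sd=_clustered_sd(1.6, nM, pM, rho),
        outcome_means=means_ms, outcome_sds=sds(se_ms, nM, pM),
    )
    return CohortConfig(ms=ms, control=control, rho=rho, master_seed=master_seed)


#: bounds keeping drawn outcome targets physically realizable
_OUTCOME_BOUNDS = {
    "pd_scp_pct": (5.0, 90.0),
    "pd_scp_wo_lv_pct": (2.0, 90.0),
    "pd_lv_pct": (0.5, 30.0),
    "pd_dcp_pct": (5.0, 90.0),
    "faz_area_s_mm2": (0.03, 0.7),
    "faz_circ_s": (1.0, 1.7),
    "faz_area_d_mm2": (0.1, 2.0),
    "faz_circ_d": (1.0, 1.7),
    "fd_cc_pct": (1.0, 60.0),
}


def _draw_group_frame(
    cfg: GroupConfig,
    group: str,
    rho: float,
    slopes: Mapping[str, Tuple[float, float]],
    rng: np.random.Generator,
    id_prefix: str,
) -> pd.DataFrame:
    outcomes = list(OUTCOME_COLUMNS)
    # assign 2 eyes to everyone, demote random participants to 1 eye
    n_demote = 2 * cfg.n_participants - cfg.n_eyes
    demoted = set(rng.choice(cfg.n_participants, size=n_demote, replace=False))
    rows = []
    for i in range(cfg.n_participants):
        pid = f"{id_prefix}{i + 1:03d}"
        age = float(rng.normal(cfg.age_mean, cfg.age_sd))
        gender = "male" if rng.random() < cfg.male_fraction else "female"
        iop = float(rng.normal(cfg.iop_mean, cfg.iop_sd))
        al = float(np.clip(rng.normal(cfg.axial_length_mean, cfg.axial_length_sd), 21.0, 26.5))
        htn = int(rng.random() < cfg.hypertension_prev)
        if group == "MS":
            duration = float(np.clip(rng.normal(cfg.duration_mean, cfg.duration_sd), 0.5, 40.0))
            episodes = int(1 + rng.poisson(cfg.episodes_rate))
        else:
            duration, episodes = 0.0, 0
        z_part = {k: rng.standard_normal() for k in outcomes + ["rnfl_um"]}
        eyes = ["OD"] if i in demoted else ["OD", "OS"]
        for eye in eyes:
            signal = int(np.clip(round(rng.normal(cfg.signal_mean, cfg.signal_sd)), 6, 10))
            al_eye = float(np.clip(al + rng.normal(0.0, 0.05), 21.0, 26.5))
            row = {
                "participant_id": pid, "eye": eye, "group": group,
                "age": age, "gender": gender, "iop_mmHg": iop,
                "axial_length_mm": al_eye, "hypertension": htn,
                "signal_strength": signal, "duration_years": duration,
                "episodes": episodes,
            }
            sr, se_ = math.sqrt(rho), math.sqrt(1.0 - rho)
            row["rnfl_um"] = cfg.rnfl_mean + cfg.rnfl_sd * (
                sr * z_part["rnfl_um"] + se_ * rng.standard_normal()
            )
            for k in outcomes:
                val = cfg.outcome_means[k] + cfg.outcome_sds[k] * (
                    sr * z_part[k] + se_ * rng.standard_normal()
                )
                if group == "MS" and k in slopes:
                    sd_dur, sd_epi = slopes[k]
                    val += sd_dur * (duration - cfg.duration_mean)
                    val += sd_epi * (episodes - (1.0 + cfg.episodes_rate))
                lo, hi = _OUTCOME_BOUNDS[k]
                row[k] = float(np.clip(val, lo, hi))
            rows.append(row)
    return pd.DataFrame(rows)


def generate_truth_table(config: CohortConfig) -> pd.DataFrame:
    """Draw the cohort's ground-truth outcome table without synthesizing images.

    One row per eye, carrying covariates and the latent true outcome values
    (group mean + participant effect + eye effect).  This is the fast path
    used by statistical simulations; :func:`generate_cohort` synthesizes
    images whose measured truths match these targets.
    """
    ss = np.random.SeedSequence(config.master_seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    frames = [
        _draw_group_frame(config.control, "control", config.rho,
                          config.association_slopes, rng, "C"),
        _draw_group_frame(config.ms, "MS", config.rho,
                          config.association_slopes, rng, "M"),
    ]
    return pd.concat(frames, ignore_index=True)


def _bundle_from_row(
    row: pd.Series, config: CohortConfig, eye_seed: np.random.SeedSequence
) -> EyeBundle:
    sub = eye_seed.spawn(6)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in sub]
    record = EyeRecord(
        participant_id=row["participant_id"], eye=row["eye"], group=row["group"],
        age=row["age"], gender=row["gender"], iop_mmHg=row["iop_mmHg"],
        axial_length_mm=row["axial_length_mm"], hypertension=int(row["hypertension"]),
        signal_strength=int(row["signal_strength"]),
        duration_years=row["duration_years"], episodes=int(row["episodes"]),
        rnfl_um=row["rnfl_um"],
    )
    vf_scp = VesselFieldParams(
        target_density=row["pd_scp_pct"] / 100.0,
        capillary_scale=config.capillary_scale,
        n_large_vessels=config.n_large_vessels,
        lv_target_density=row["pd_lv_pct"] / 100.0,
        noise_sd=config.noise_sd,
        seed=seeds[0],
    )
    vf_dcp = VesselFieldParams(
        target_density=row["pd_dcp_pct"] / 100.0,
        capillary_scale=config.capillary_scale,
        n_large_vessels=0,
        noise_sd=config.noise_sd,
        seed=seeds[1],
    )
    irr_s = calibrate_faz_irregularity(
        row["faz_area_s_mm2"], row["faz_circ_s"], seeds[2], config.faz_n_vertices
    )
    irr_d = calibrate_faz_irregularity(
        row["faz_area_d_mm2"], row["faz_circ_d"], seeds[3], config.faz_n_vertices
    )
    cc = CcParams(
        deficit_fraction=row["fd_cc_pct"] / 100.0,
        granule_scale=config.cc_granule_scale,
        sd_intensity=config.cc_noise_sd,
        seed=seeds[4],
    )
    # extreme area x irregularity draws can push the boundary off-grid for
    # short eyes; back the irregularity off deterministically until it fits
    for attempt in range(9):
        shrink = 0.75**attempt
        faz_s = FazParams(row["faz_area_s_mm2"], irr_s * shrink, config.faz_n_vertices, seeds[2])
        faz_d = FazParams(row["faz_area_d_mm2"], irr_d * shrink, config.faz_n_vertices, seeds[3])
        try:
            return generate_eye(
                vf_scp, vf_dcp, faz_s, faz_d, cc, record,
                grid_px=config.grid_px,
                annulus_spec=config.annulus,
                camera_factor_p=config.camera_factor_p,
                lv_removal_radius_px=config.lv_removal_radius_px,
            )
        except ValueError as exc:
            if "FAZ does not fit" not in str(exc):
                raise
    raise ValueError(
        f"could not fit FAZ for eye {record.participant_id}_{record.eye}"
    )


def iter_cohort(config: CohortConfig):
    """Yield ``(row_index, EyeBundle)`` lazily; memory stays per-eye."""
    frame = generate_truth_table(config)
    ss = np.random.SeedSequence(config.master_seed)
    eye_seeds = ss.spawn(1 + len(frame))[1:]
    for i, (_, row) in enumerate(frame.iterrows()):
        yield i, _bundle_from_row(row, config, eye_seeds[i])


def generate_cohort(config: CohortConfig) -> Tuple[List[EyeBundle], pd.DataFrame]:
    """Generate the full cohort in memory.

    Returns the eye bundles plus a metadata frame (one row per eye with
    covariates and drawn outcome targets).  For large cohorts prefer
    :func:`iter_cohort` or the disk-backed pipeline writer.
    """
    frame = generate_truth_table(config)
    bundles = [b for _, b in iter_cohort(config)]
    return bundles, frame
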