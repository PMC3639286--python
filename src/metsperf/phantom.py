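"""Digital mouse-brain phantom: anatomy, multifocal lesions, MR signals, histology.

The phantom is a stylized 2.5D coronal label map (per-slice 2D regions
stacked along the slice axis) that is exactly mirror-symmetric about a
stored midline column.  Cohort presets seed multifocal metastatic lesions
with a configurable regional incidence, size distribution, blood-volume
ratio relative to the local normal tissue, and blood-tumor-barrier
permeability class, then synthesize:

* anatomic T2-weighted and T1-weighted (pre/post contrast) volumes;
* a 4D DSC series from the gamma-variate forward model
  ΔR2*(t) = K (t-t0)^α exp(-(t-t0)/β) with the per-voxel amplitude scaled so
  the area under the curve equals the ground-truth CBV, converted to signal
  via S(t) = S0 exp(-TE ΔR2*(t));
* two-channel fluorescence histology fields (tumor mask in green, vessels
  in red) with Poisson vessel counts at a target density per mm².

All generators are deterministic given (preset, seed).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .dsc import DSCSeries, gamma_variate_area
from .errors import ConfigurationError, PlacementError
from .geometry import AcquisitionGeometry


class Region(enum.IntEnum):
    """Anatomical region codes of the label map."""

    BACKGROUND = 0
    CORTEX = 1
    OLFACTORY_BULB = 2
    BASAL_GANGLIA = 3
    HIPPOCAMPUS = 4
    THALAMUS_MIDBRAIN = 5   # thalamus / midbrain / cerebellum pooled
    VENTRICLE = 6


#: regions in which lesions may seed (ventricles and background excluded)
SEEDABLE_REGIONS = (
    Region.CORTEX, Region.OLFACTORY_BULB, Region.BASAL_GANGLIA,
    Region.HIPPOCAMPUS, Region.THALAMUS_MIDBRAIN,
)

REGION_NAMES = {
    Region.CORTEX: "cortex",
    Region.OLFACTORY_BULB: "olfactory_bulb",
    Region.BASAL_GANGLIA: "basal_ganglia",
    Region.HIPPOCAMPUS: "hippocampus",
    Region.THALAMUS_MIDBRAIN: "thalamus_midbrain_cerebellum",
    Region.VENTRICLE: "ventricle",
    Region.BACKGROUND: "background",
}


# ---------------------------------------------------------------------------
# containers


@dataclass
class BrainLabelMap:
    """Integer region labels (row, col, slice) with a midline column per slice."""

    labels: np.ndarray
    midline: np.ndarray            # integer column index, one per slice
    geometry: AcquisitionGeometry

    @property
    def brain_mask(self) -> np.ndarray:
        return self.labels > 0

    @property
    def tissue_mask(self) -> np.ndarray:
        """Brain excluding CSF-filled ventricles."""
        return (self.labels > 0) & (self.labels != Region.VENTRICLE)

    def region_mask(self, region: Region) -> np.ndarray:
        return self.labels == int(region)

    @property
    def dsc_midline(self) -> float:
        """Midline column on the DSC grid (between columns for even grids)."""
        f = self.geometry.downsample
        return float(self.midline[0]) / f - 0.5

    def reflected_labels(self) -> np.ndarray:
        """Labels reflected about the midline column (for symmetry checks)."""
        out = np.zeros_like(self.labels)
        cols = np.arange(self.labels.shape[1])
        for s in range(self.labels.shape[2]):
            ref = 2 * int(self.midline[s]) - cols
            ok = (ref >= 0) & (ref < self.labels.shape[1])
            out[:, cols[ok], s] = self.labels[:, ref[ok], s]
        return out


@dataclass
class GroundTruthLesion:
    """One seeded metastasis with its ground-truth properties."""

    id: int
    slice_index: int
    rows: np.ndarray               # lesion pixel coordinates (anatomic grid)
    cols: np.ndarray
    region: Region
    area_mm2: float
    ratio: float                   # true CBV ratio vs local normal tissue
    enh_class: str                 # none | partial | full
    enh_fraction: float
    enh_rows: np.ndarray = field(default_factory=lambda: np.array([], int))
    enh_cols: np.ndarray = field(default_factory=lambda: np.array([], int))
    birth_week: int = 3

    @property
    def centroid(self) -> Tuple[float, float]:
        return float(self.rows.mean()), float(self.cols.mean())

    def mask(self, shape2d: Tuple[int, int]) -> np.ndarray:
        m = np.zeros(shape2d, dtype=bool)
        m[self.rows, self.cols] = True
        return m


def _default_incidence() -> Dict[Region, float]:
    # cortex 49% and thalamus/midbrain/cerebellum 5% are the reported
    # extremes; the remainder is split over olfactory bulb, basal ganglia
    # and hippocampus
    return {
        Region.CORTEX: 0.49,
        Region.OLFACTORY_BULB: 0.17,
        Region.BASAL_GANGLIA: 0.16,
        Region.HIPPOCAMPUS: 0.13,
        Region.THALAMUS_MIDBRAIN: 0.05,
    }


@dataclass(frozen=True)
class CohortPreset:
    """Everything that defines a synthetic study cohort.

    Defaults emulate the week-5 cross-sectional cohort: 9 animals, ~464
    lesions in total, 34% contrast-enhancing, tumor-to-normal CBV ratio with
    arithmetic mean 0.89 and heterogeneity spanning roughly 0.16-2.84.
    """

    n_animals: int = 9
    lesions_per_animal: float = 51.5         # Poisson mean per animal
    lesions_per_animal_exact: Optional[Tuple[int, ...]] = None
    new_lesions_per_week: float = 30.0       # appearance rate at follow-up weeks
    regional_incidence: Tuple[Tuple[int, float], ...] = tuple(
        (int(k), v) for k, v in _default_incidence().items()
    )
    slice_center: float = 6.5                # lesion slice placement (anatomic index)
    slice_sigma: float = 2.5
    # lesion size: lognormal, clipped to the observed range
    area_log_mean: float = float(np.log(0.38))
    area_log_sd: float = 0.6
    area_range_mm2: Tuple[float, float] = (0.09, 1.7)
    growth_log_mean: float = float(np.log(1.6))   # weekly area multiplier
    growth_log_sd: float = 0.25
    # blood-tumor-barrier permeability
    enhancing_proportion: float = 0.34
    partial_proportion: float = 0.4          # of enhancing lesions
    partial_fraction_range: Tuple[float, float] = (0.25, 0.75)
    # tumor CBV ratio vs local normal tissue
    tumor_ratio_mean: float = 0.89
    tumor_ratio_log_sd: float = 0.505
    ratio_decline_mean: float = 1.0          # weekly multiplicative ratio drift
    ratio_decline_log_sd: float = 0.0
    # normal-tissue CBV field
    normal_cbv_area: float = 1300.0          # mean bolus area (s^-1 * s)
    normal_field_cv: float = 0.12
    field_corr_length_mm: float = 1.5
    ventricle_cbv_factor: float = 0.1
    # DSC forward model
    bolus_alpha: float = 2.5
    bolus_beta_s: float = 4.0
    bolus_arrival_frame: int = 20
    recirculation_fraction: float = 0.12     # area fraction of the first pass
    recirculation_delay_s: float = 30.0
    recirculation_broadening: float = 1.6
    dsc_s0: float = 1000.0
    dsc_background_s0: float = 50.0
    dsc_noise_sd: float = 10.0
    dsc_drift_per_s: float = 0.0             # optional linear post-bolus ΔR2* drift
    noise_model: str = "gaussian"            # or "rician"
    # anatomic image contrasts
    t2_lesion_contrast: float = 1.5
    t1_enhancement_contrast: float = 1.4
    ventricle_t2_contrast: float = 1.0
    anat_noise_sd: float = 0.05
    # histology
    mvd_tumor_per_mm2: float = 669.0
    mvd_normal_per_mm2: float = 965.0
    hist_scale_um_per_px: float = 1.0
    hist_field_px: int = 450
    hist_irregular_fraction: float = 0.3     # dilated/irregular vessels in tumor mode
    first_week: int = 3

    def __post_init__(self) -> None:
        inc = dict(self.regional_incidence)
        if abs(sum(inc.values()) - 1.0) > 1e-9:
            raise ConfigurationError("regional incidence must sum to 1")
        for p in (self.enhancing_proportion, self.partial_proportion):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError("proportions must lie in [0, 1]")
        if self.noise_model not in ("gaussian", "rician"):
            raise ConfigurationError(f"unknown noise model {self.noise_model!r}")

    @property
    def incidence(self) -> Dict[Region, float]:
        return {Region(k): v for k, v in self.regional_incidence}


def week5_preset(**overrides) -> CohortPreset:
    """The week-5 cross-sectional study-emulation preset."""
    return CohortPreset(**overrides)


def longitudinal_preset(**overrides) -> CohortPreset:
    """Two-week longitudinal preset: 5 animals, 32 tracked lesions.

    Tracked lesions start with CBV ratio ~1.05 (week 3) and decline to a
    mean of 0.88 a week later.  Per-lesion dispersion is kept modest
    (sigma_ln 0.15, decline sigma_ln 0.10): a tracked lesion is compared to
    its own mirrored reference, which removes the regional variation that
    dominates the cross-sectional spread.
    """
    # tracked lesions all lay on the DSC-covered central slices, so the
    # olfactory bulb (anterior to DSC coverage) is excluded and its share
    # redistributed proportionally
    incidence = tuple(
        (int(k), v / 0.83) for k, v in _default_incidence().items()
        if k != Region.OLFACTORY_BULB
    )
    kw = dict(
        n_animals=5,
        lesions_per_animal_exact=(7, 7, 6, 6, 6),
        new_lesions_per_week=25.0,
        regional_incidence=incidence,
        slice_center=6.5,
        slice_sigma=0.9,
        area_log_mean=float(np.log(0.35)),
        area_log_sd=0.35,
        area_range_mm2=(0.2, 1.7),
        tumor_ratio_mean=1.05,
        tumor_ratio_log_sd=0.15,
        ratio_decline_mean=0.88 / 1.05,
        ratio_decline_log_sd=0.10,
    )
    kw.update(overrides)
    return CohortPreset(**kw)


# ---------------------------------------------------------------------------
# anatomy


def _ellipse(rows, cols, r0, c0, b, a):
    return ((rows - r0) / b) ** 2 + ((cols - c0) / a) ** 2 <= 1.0


def build_anatomy(geometry: AcquisitionGeometry, seed: int = 0) -> BrainLabelMap:
    """Build the mirror-symmetric multi-region label map.

    The construction is per-slice: a brain ellipse whose size tracks the
    anterior-posterior position, a cortical shell, deep nuclei that change
    identity along the slice axis (basal ganglia -> hippocampus/thalamus ->
    midbrain/cerebellum), paired ventricles, and an olfactory bulb on the
    two most anterior slices.  All shapes are centered on (or placed
    symmetrically about) the midline column, so reflection about the
    midline reproduces the labels exactly.
    """
    M, S = geometry.matrix, geometry.n_slices
    if M < 64:
        raise ConfigurationError(f"matrix {M} too small to place all regions (need >= 64)")
    labels = np.zeros((M, M, S), dtype=np.int16)
    m = M // 2                      # midline column
    r0 = M * 0.5                    # brain center row
    rows, cols = np.mgrid[0:M, 0:M]
    for s in range(S):
        p = s / max(S - 1, 1)
        sl = np.zeros((M, M), dtype=np.int16)
        if p <= 0.10:
            # olfactory bulb slices
            a, b = 0.18 * M, 0.16 * M
            sl[_ellipse(rows, cols, r0, m, b, a)] = Region.OLFACTORY_BULB
        else:
            q = (p - 0.10) / 0.90
            grow = np.sin(np.pi * q ** 0.8)
            a = M * (0.26 + 0.14 * grow)
            b = M * (0.22 + 0.10 * grow)
            brain = _ellipse(rows, cols, r0, m, b, a)
            inner = _ellipse(rows, cols, r0, m, 0.70 * b, 0.70 * a)
            sl[brain] = Region.CORTEX
            if p < 0.45:
                sl[inner] = Region.BASAL_GANGLIA
            elif p < 0.75:
                core = _ellipse(rows, cols, r0, m, 0.40 * b, 0.40 * a)
                sl[inner] = Region.HIPPOCAMPUS
                sl[core] = Region.THALAMUS_MIDBRAIN
            else:
                sl[inner] = Region.THALAMUS_MIDBRAIN
            if 0.25 < p < 0.70:
                off = 0.12 * M
                vb, va = 0.055 * M, 0.018 * M
                for c0 in (m - off, m + off):
                    sl[_ellipse(rows, cols, r0, c0, vb, va)] = Region.VENTRICLE
        labels[:, :, s] = sl
    midline = np.full(S, m, dtype=int)
    return BrainLabelMap(labels=labels, midline=midline, geometry=geometry)


# ---------------------------------------------------------------------------
# lesion seeding


def _blob(rng: np.random.Generator, area_px: float, irregularity: float = 0.22):
    """Rasterize a perturbed-ellipse blob of approximately ``area_px`` pixels.

    Returns (drows, dcols) integer offsets relative to the blob center.
    """
    r0 = max(np.sqrt(area_px / np.pi), 1.0)
    amps = irregularity * rng.standard_normal(3) / np.arange(1, 4)
    phases = rng.uniform(0, 2 * np.pi, 3)
    half = int(np.ceil(r0 * (1 + 3 * irregularity))) + 1
    dr, dc = np.mgrid[-half:half + 1, -half:half + 1]
    rho = np.hypot(dr, dc)
    theta = np.arctan2(dr, dc)
    rim = r0 * (1.0 + sum(a * np.cos((k + 2) * theta + ph)
                          for k, (a, ph) in enumerate(zip(amps, phases))))
    rim = np.clip(rim, 0.35 * r0, None)
    mask = rho <= rim
    # one corrective rescale toward the requested area
    actual = mask.sum()
    if actual > 0:
        scale = np.sqrt(area_px / actual)
        mask = rho <= rim * scale
    return dr[mask], dc[mask]


def _pick_slice(rng, preset, region_slices, weights):
    probs = weights / weights.sum()
    return int(rng.choice(region_slices, p=probs))


def _slice_weights(preset: CohortPreset, slices: np.ndarray) -> np.ndarray:
    w = np.exp(-0.5 * ((slices - preset.slice_center) / preset.slice_sigma) ** 2)
    return np.clip(w, 1e-6, None)


def _draw_enhancement(rng, preset: CohortPreset):
    if rng.uniform() < preset.enhancing_proportion:
        if rng.uniform() < preset.partial_proportion:
            lo, hi = preset.partial_fraction_range
            return "partial", float(rng.uniform(lo, hi))
        return "full", 1.0
    return "none", 0.0


def _enhancing_submask(rng, rows, cols, fraction):
    """A connected sub-blob holding ~``fraction`` of the lesion pixels."""
    n = len(rows)
    k = int(round(fraction * n))
    if k <= 0:
        return np.array([], int), np.array([], int)
    if k >= n:
        return rows.copy(), cols.copy()
    seed = rng.integers(n)
    d2 = (rows - rows[seed]) ** 2 + (cols - cols[seed]) ** 2
    order = np.argsort(d2, kind="stable")[:k]
    return rows[order], cols[order]


def _place_one(rng, anatomy, occupancy, preset, region, area_mm2, week,
               lesion_id, max_tries=300):
    """Place a single non-overlapping lesion blob; returns GroundTruthLesion."""
    geo = anatomy.geometry
    area_px = area_mm2 / geo.pixel_area_mm2
    region_mask3d = anatomy.region_mask(region)
    region_slices = np.flatnonzero(region_mask3d.sum(axis=(0, 1)) > 3 * area_px)
    if region_slices.size == 0:
        raise PlacementError(f"region {region.name} has no slice large enough")
    weights = _slice_weights(preset, region_slices)
    M = geo.matrix
    for attempt in range(max_tries):
        s = _pick_slice(rng, preset, region_slices, weights)
        rmask = region_mask3d[:, :, s]
        cand = np.argwhere(rmask)
        cr, cc = cand[rng.integers(len(cand))]
        drows, dcols = _blob(rng, area_px)
        rr, cc_ = cr + drows, cc + dcols
        if rr.min() < 0 or cc_.min() < 0 or rr.max() >= M or cc_.max() >= M:
            continue
        lab = anatomy.labels[rr, cc_, s]
        if (lab == 0).any() or (lab == Region.VENTRICLE).any():
            continue
        if (lab == int(region)).mean() <= 0.5:
            continue                       # majority rule must recover the region
        # require a 1-pixel gap to existing lesions
        if occupancy[rr, cc_, s].any():
            continue
        patch = np.zeros((M, M), bool)
        patch[rr, cc_] = True
        if (ndimage.binary_dilation(patch) & occupancy[:, :, s]).any():
            continue
        occupancy[rr, cc_, s] = True
        enh_class, enh_fraction = _draw_enhancement(rng, preset)
        erows, ecols = _enhancing_submask(rng, rr, cc_, enh_fraction)
        actual_fraction = len(erows) / len(rr) if enh_class != "none" else 0.0
        if enh_class == "full":
            actual_fraction = 1.0
            erows, ecols = rr.copy(), cc_.copy()
        ratio = float(rng.lognormal(
            np.log(preset.tumor_ratio_mean) - preset.tumor_ratio_log_sd ** 2 / 2,
            preset.tumor_ratio_log_sd))
        return GroundTruthLesion(
            id=lesion_id, slice_index=s, rows=rr, cols=cc_, region=region,
            area_mm2=float(len(rr) * geo.pixel_area_mm2), ratio=ratio,
            enh_class=enh_class, enh_fraction=float(actual_fraction),
            enh_rows=erows, enh_cols=ecols, birth_week=week)
    raise PlacementError(
        f"could not place lesion of {area_mm2:.2f} mm^2 in {region.name} "
        f"after {max_tries} tries")


def _grow_lesion(rng, anatomy, occupancy, lesion: GroundTruthLesion,
                 preset: CohortPreset) -> GroundTruthLesion:
    """Grow an existing lesion by a lognormal area factor (never shrinks)."""
    geo = anatomy.geometry
    factor = max(float(rng.lognormal(preset.growth_log_mean, preset.growth_log_sd)), 1.0)
    target_px = int(round(len(lesion.rows) * factor))
    M = geo.matrix
    s = lesion.slice_index
    mask = np.zeros((M, M), bool)
    mask[lesion.rows, lesion.cols] = True
    occupancy[lesion.rows, lesion.cols, s] = False   # free own pixels during growth
    allowed = anatomy.tissue_mask[:, :, s] & ~ndimage.binary_dilation(occupancy[:, :, s])
    while mask.sum() < target_px:
        ring = ndimage.binary_dilation(mask) & ~mask & allowed
        if not ring.any():
            break
        mask |= ring
        if mask.sum() > target_px:
            # trim the surplus ring pixels farthest from the centroid
            rr, cc = np.nonzero(mask)
            surplus = mask.sum() - target_px
            ring_idx = np.argwhere(ring)
            c0 = np.array(lesion.centroid)
            d2 = ((ring_idx - c0) ** 2).sum(axis=1)
            drop = ring_idx[np.argsort(-d2, kind="stable")[:surplus]]
            mask[drop[:, 0], drop[:, 1]] = False
    rr, cc = np.nonzero(mask)
    occupancy[rr, cc, s] = True
    decline = float(rng.lognormal(
        np.log(preset.ratio_decline_mean) - preset.ratio_decline_log_sd ** 2 / 2,
        preset.ratio_decline_log_sd)) if preset.ratio_decline_mean != 1.0 or \
        preset.ratio_decline_log_sd > 0 else 1.0
    erows, ecols = lesion.enh_rows, lesion.enh_cols
    return replace(
        lesion, rows=rr, cols=cc,
        area_mm2=float(len(rr) * geo.pixel_area_mm2),
        ratio=lesion.ratio * decline,
        enh_rows=erows, enh_cols=ecols)


def seed_lesions(anatomy: BrainLabelMap, preset: CohortPreset, week: int,
                 seed: int = 0, existing: Optional[List[GroundTruthLesion]] = None,
                 n_lesions: Optional[int] = None,
                 animal_index: int = 0) -> List[GroundTruthLesion]:
    """Seed (and, at follow-up weeks, grow) ground-truth lesions.

    At the first week the lesion count is Poisson with the preset mean (or
    the preset's exact per-animal counts).  At later weeks every existing
    lesion persists with area grown by the multiplicative weekly model and
    new lesions are appended.
    """
    if week < preset.first_week:
        raise ValueError(f"week {week} precedes first-appearance week {preset.first_week}")
    rng = np.random.default_rng(seed)
    occupancy = np.zeros(anatomy.labels.shape, dtype=bool)
    out: List[GroundTruthLesion] = []
    if existing:
        for les in existing:
            occupancy[les.rows, les.cols, les.slice_index] = True
        for les in existing:
            out.append(_grow_lesion(rng, anatomy, occupancy, les, preset))
    if n_lesions is None:
        if existing:
            n_new = int(rng.poisson(preset.new_lesions_per_week))
        elif preset.lesions_per_animal_exact is not None:
            n_new = int(preset.lesions_per_animal_exact[
                animal_index % len(preset.lesions_per_animal_exact)])
        else:
            n_new = int(rng.poisson(preset.lesions_per_animal))
    else:
        n_new = int(n_lesions)
    incidence = preset.incidence
    regions = list(incidence.keys())
    probs = np.array([incidence[r] for r in regions])
    lo, hi = preset.area_range_mm2
    next_id = (max((l.id for l in out), default=-1)) + 1
    for i in range(n_new):
        region = regions[int(rng.choice(len(regions), p=probs))]
        area = float(np.clip(rng.lognormal(preset.area_log_mean, preset.area_log_sd), lo, hi))
        out.append(_place_one(rng, anatomy, occupancy, preset, region, area,
                              week, next_id))
        next_id += 1
    return out


def lesion_label_volume(anatomy: BrainLabelMap,
                        lesions: Sequence[GroundTruthLesion]) -> np.ndarray:
    """Integer volume with each lesion's (id + 1) painted at its pixels."""
    vol = np.zeros(anatomy.labels.shape, dtype=np.int32)
    for les in lesions:
        vol[les.rows, les.cols, les.slice_index] = les.id + 1
    return vol


# ---------------------------------------------------------------------------
# anatomic MR signal simulation


def _add_noise(rng, image, sd, model):
    if sd <= 0:
        return image
    if model == "rician":
        re = image + rng.normal(0, sd, image.shape)
        im = rng.normal(0, sd, image.shape)
        return np.hypot(re, im)
    return image + rng.normal(0, sd, image.shape)


def simulate_mri(anatomy: BrainLabelMap, lesions: Sequence[GroundTruthLesion],
                 preset: CohortPreset, modality: str, seed: int = 0) -> np.ndarray:
    """Synthesize a 3D anatomic volume (T2w, T1w_pre or T1w_post).

    T2w: lesions are hyperintense by the preset contrast factor.  T1w_post:
    only the enhancing sub-region of permeable lesions is brightened;
    non-permeable lesions stay isointense.
    """
    if modality not in ("T2w", "T1w_pre", "T1w_post"):
        raise ValueError(f"unknown modality {modality!r}")
    rng = np.random.default_rng(seed)
    img = np.full(anatomy.labels.shape, 0.05, dtype=float)
    img[anatomy.brain_mask] = 1.0
    if modality == "T2w":
        img[anatomy.region_mask(Region.VENTRICLE)] = preset.ventricle_t2_contrast
        for les in lesions:
            img[les.rows, les.cols, les.slice_index] = preset.t2_lesion_contrast
    elif modality == "T1w_post":
        for les in lesions:
            if les.enh_class != "none" and len(les.enh_rows):
                img[les.enh_rows, les.enh_cols, les.slice_index] = \
                    preset.t1_enhancement_contrast
    return _add_noise(rng, img, preset.anat_noise_sd, preset.noise_model)


# ---------------------------------------------------------------------------
# DSC forward model


@dataclass
class DSCGroundTruth:
    """Ground truth stored alongside a simulated DSC series."""

    cbv_map: np.ndarray            # first-pass bolus area per DSC voxel
    tumor_occupancy: np.ndarray    # lesion pixel-occupancy fraction per DSC voxel
    lesion_voxels: Dict[int, np.ndarray]   # lesion id -> boolean DSC mask
    dsc_slices: np.ndarray         # anatomic slice indices covered by DSC
    field: np.ndarray              # normal-tissue CBV modulation field
    labels_dsc: np.ndarray         # majority-label anatomy on the DSC window
    alpha: float
    beta: float
    arrival_time_s: float


def choose_dsc_slices(lesions: Sequence[GroundTruthLesion],
                      geometry: AcquisitionGeometry) -> np.ndarray:
    """The consecutive slice window containing the most lesions."""
    counts = np.zeros(geometry.n_slices, int)
    for les in lesions:
        counts[les.slice_index] += 1
    w = geometry.n_dsc_slices
    sums = np.array([counts[i:i + w].sum() for i in range(geometry.n_slices - w + 1)])
    start = int(np.argmax(sums))
    return np.arange(start, start + w)


def _downsample_blocks(plane: np.ndarray, f: int) -> np.ndarray:
    """Block-mean downsample a 2D array by factor f."""
    n = plane.shape[0] // f
    return plane.reshape(n, f, n, f).swapaxes(1, 2).reshape(n, n, f * f).mean(axis=-1)


def downsample_labels(anatomy: BrainLabelMap) -> np.ndarray:
    """Majority-label downsampling of the anatomy onto the full DSC grid stack."""
    f = anatomy.geometry.downsample
    M, S = anatomy.geometry.dsc_matrix, anatomy.geometry.n_slices
    codes = [int(r) for r in Region if r != Region.BACKGROUND]
    out = np.zeros((M, M, S), dtype=np.int16)
    best = np.zeros((M, M, S))
    for code in codes:
        frac = np.stack([_downsample_blocks((anatomy.labels[:, :, s] == code).astype(float), f)
                         for s in range(S)], axis=-1)
        win = frac > best
        out[win] = code
        best[win] = frac[win]
    out[best <= 0.5] = np.where(best[best <= 0.5] > 0.25, out[best <= 0.5], 0)
    return out


def lesion_dsc_mask(lesion: GroundTruthLesion, anatomy: BrainLabelMap,
                    dsc_slices: np.ndarray, min_occupancy: float = 0.5) -> np.ndarray:
    """Lesion mask on the DSC grid: voxels with pixel occupancy >= threshold."""
    geo = anatomy.geometry
    f = geo.downsample
    out = np.zeros((geo.dsc_matrix, geo.dsc_matrix, len(dsc_slices)), bool)
    where = np.flatnonzero(dsc_slices == lesion.slice_index)
    if where.size == 0:
        return out
    plane = np.zeros((geo.matrix, geo.matrix))
    plane[lesion.rows, lesion.cols] = 1.0
    occ = _downsample_blocks(plane, f)
    out[:, :, where[0]] = occ >= min_occupancy
    return out


def _symmetric_field(rng, shape, cv, corr_px):
    """Smooth, mirror-symmetric multiplicative CBV heterogeneity field."""
    g = rng.standard_normal(shape)
    g = ndimage.gaussian_filter(g, sigma=(corr_px, corr_px, max(corr_px / 4, 0.5)))
    g = 0.5 * (g + g[:, ::-1, :])          # mirror about the between-column axis
    sd = g.std()
    if sd > 0:
        g = g / sd
    return np.clip(1.0 + cv * g, 0.3, None)


def simulate_dsc(anatomy: BrainLabelMap, lesions: Sequence[GroundTruthLesion],
                 preset: CohortPreset, seed: int = 0,
                 dsc_slices: Optional[np.ndarray] = None
                 ) -> Tuple[DSCSeries, DSCGroundTruth]:
    """Simulate the 4D DSC series from the gamma-variate forward model.

    Per voxel the true concentration curve is a gamma-variate whose area
    equals the ground-truth CBV (plus an optional delayed recirculation bump
    and linear drift), converted to signal via S = S0 exp(-TE ΔR2*) with
    additive noise on the signal.
    """
    geo = anatomy.geometry
    rng = np.random.default_rng(seed)
    if dsc_slices is None:
        dsc_slices = choose_dsc_slices(lesions, geo)
    dsc_slices = np.asarray(dsc_slices, int)

    alpha, beta = preset.bolus_alpha, preset.bolus_beta_s
    t = geo.frame_times
    t0 = preset.bolus_arrival_frame * geo.frame_interval_s
    support = (alpha + 5.0) * beta
    if t0 + support > t[-1]:
        raise ConfigurationError("frame window shorter than bolus support")

    labels_dsc = downsample_labels(anatomy)[:, :, dsc_slices]
    Md = geo.dsc_matrix
    field = _symmetric_field(rng, (Md, Md, len(dsc_slices)),
                             preset.normal_field_cv,
                             preset.field_corr_length_mm / geo.dsc_pixel_size_mm)
    cbv = preset.normal_cbv_area * field
    cbv[labels_dsc == Region.VENTRICLE] *= preset.ventricle_cbv_factor
    cbv[labels_dsc == 0] = 0.0
    occupancy = np.zeros((Md, Md, len(dsc_slices)))
    lesion_voxels: Dict[int, np.ndarray] = {}
    f = geo.downsample
    for les in lesions:
        where = np.flatnonzero(dsc_slices == les.slice_index)
        if where.size == 0:
            continue
        plane = np.zeros((geo.matrix, geo.matrix))
        plane[les.rows, les.cols] = 1.0
        occ = _downsample_blocks(plane, f)
        occupancy[:, :, where[0]] = np.maximum(occupancy[:, :, where[0]], occ)
        vox = occ >= 0.5
        if vox.any():
            mask3 = np.zeros_like(cbv, dtype=bool)
            mask3[:, :, where[0]] = vox
            cbv[mask3] = preset.normal_cbv_area * field[mask3] * les.ratio
            lesion_voxels[les.id] = mask3

    # unit-area first-pass curve and recirculation bump
    tau = t - t0
    base = np.zeros_like(t)
    pos = tau > 0
    base[pos] = tau[pos] ** alpha * np.exp(-tau[pos] / beta)
    unit = base / gamma_variate_area(1.0, alpha, beta)
    beta2 = beta * preset.recirculation_broadening
    tau2 = t - (t0 + preset.recirculation_delay_s)
    rec = np.zeros_like(t)
    pos2 = tau2 > 0
    rec[pos2] = tau2[pos2] ** alpha * np.exp(-tau2[pos2] / beta2)
    rec_unit = rec / gamma_variate_area(1.0, alpha, beta2)
    shape_t = unit + preset.recirculation_fraction * rec_unit

    dr2s = cbv[..., None] * shape_t[None, None, None, :]
    if preset.dsc_drift_per_s != 0.0:
        drift = preset.dsc_drift_per_s * np.clip(t - t0, 0.0, None)
        dr2s = dr2s + drift[None, None, None, :]
    s0 = np.where(labels_dsc > 0, preset.dsc_s0, preset.dsc_background_s0)
    signal = s0[..., None] * np.exp(-geo.te_s * dr2s)
    signal = _add_noise(rng, signal, preset.dsc_noise_sd, preset.noise_model)

    series = DSCSeries(
        signal=signal,
        baseline_frames=np.arange(max(preset.bolus_arrival_frame - 2, 5)),
        geometry=geo,
        mask=labels_dsc > 0,
    )
    truth = DSCGroundTruth(
        cbv_map=cbv, tumor_occupancy=occupancy, lesion_voxels=lesion_voxels,
        dsc_slices=dsc_slices, field=field, labels_dsc=labels_dsc,
        alpha=alpha, beta=beta, arrival_time_s=t0)
    return series, truth


# ---------------------------------------------------------------------------
# histology


@dataclass
class HistologyPair:
    """Co-registered two-channel fluorescence field (green tumor, red vessels)."""

    green: np.ndarray
    red: np.ndarray
    scale_um_per_px: float
    field_id: int = 0
    tissue_class: str = "tumor"     # or "contralateral_normal"

    def __post_init__(self) -> None:
        if self.green.shape != self.red.shape:
            raise ValueError("channels must have the same shape")
        if self.scale_um_per_px <= 0:
            raise ValueError("scale must be positive")


@dataclass
class HistologyTruth:
    mask: np.ndarray               # ground-truth analysis mask
    n_vessels_inside: int          # vessels with centroid inside the mask
    density_per_mm2: float         # generating Poisson intensity


def _vessel_stamp(rng, irregular: bool):
    """Pixel offsets of one vessel cross-section (round, or dilated/elongated)."""
    if irregular:
        a = rng.uniform(3.0, 6.0)       # dilated, elongated lumen
        b = rng.uniform(1.5, 3.0)
        ang = rng.uniform(0, np.pi)
    else:
        a = b = rng.uniform(1.5, 2.6)   # round capillary
        ang = 0.0
    half = int(np.ceil(a)) + 1
    dr, dc = np.mgrid[-half:half + 1, -half:half + 1]
    x = dc * np.cos(ang) + dr * np.sin(ang)
    y = -dc * np.sin(ang) + dr * np.cos(ang)
    mask = (x / a) ** 2 + (y / b) ** 2 <= 1.0
    return dr[mask], dc[mask], a

def simulate_histology(preset: CohortPreset, seed: int = 0, mode: str = "tumor",
                       field_id: int = 0) -> Tuple[HistologyPair, HistologyTruth]:
    """Simulate one two-channel fluorescence field with known vessel count.

    ``mode='tumor'``: the green channel holds a tumor blob of known area and
    the red channel carries vessels at the tumor density inside the blob
    (a preset fraction irregular/dilated) and at the normal density outside.
    ``mode='normal'``: a large reference-tissue region at the normal density
    with round vessels.
    """
    if mode not in ("tumor", "normal"):
        raise ValueError(f"unknown histology mode {mode!r}")
    rng = np.random.default_rng(seed)
    N = preset.hist_field_px
    scale = preset.hist_scale_um_per_px
    px_mm2 = (scale / 1000.0) ** 2
    green = np.full((N, N), 0.05)
    rows, cols = np.mgrid[0:N, 0:N]
    if mode == "tumor":
        density = preset.mvd_tumor_per_mm2
        r_blob = rng.uniform(0.32, 0.42) * N
        c0 = (rng.uniform(0.4, 0.6) * N, rng.uniform(0.4, 0.6) * N)
        theta = np.arctan2(rows - c0[0], cols - c0[1])
        rim = r_blob * (1 + 0.12 * np.cos(2 * theta + rng.uniform(0, np.pi))
                        + 0.06 * np.cos(3 * theta + rng.uniform(0, np.pi)))
        mask = np.hypot(rows - c0[0], cols - c0[1]) <= rim
        irregular_frac = preset.hist_irregular_fraction
        outside_density = preset.mvd_normal_per_mm2
    else:
        density = preset.mvd_normal_per_mm2
        mask = (rows > 0.05 * N) & (rows < 0.95 * N) & \
               (cols > 0.05 * N) & (cols < 0.95 * N)
        irregular_frac = 0.0
        outside_density = 0.0
    green[mask] = 0.9

    red = np.full((N, N), 0.05)
    area_in_mm2 = mask.sum() * px_mm2
    area_out_mm2 = (~mask).sum() * px_mm2
    n_in = int(rng.poisson(density * area_in_mm2))
    n_out = int(rng.poisson(outside_density * area_out_mm2))
    centers: List[Tuple[int, int, float]] = []

    def place(n, inside, dens):
        pool = np.argwhere(mask if inside else ~mask)
        # disjointness is impossible once exclusion discs exceed ~35% packing
        if n * np.pi * 6.0 ** 2 > 0.35 * len(pool):
            raise PlacementError(
                f"density {dens}/mm^2 too high for disjoint vessels")
        placed = 0
        tries = 0
        max_tries = 50 * max(n, 1)
        while placed < n:
            tries += 1
            if tries > max_tries:
                raise PlacementError(
                    f"density {dens}/mm^2 too high for disjoint vessels")
            r, c = pool[rng.integers(len(pool))]
            irregular = inside and mode == "tumor" and rng.uniform() < irregular_frac
            dr, dc, rad = _vessel_stamp(rng, irregular)
            if any((r - r2) ** 2 + (c - c2) ** 2 < (rad + rad2 + 2.0) ** 2
                   for r2, c2, rad2 in centers):
                continue
            rr, cc2 = r + dr, c + dc
            ok = (rr >= 0) & (rr < N) & (cc2 >= 0) & (cc2 < N)
            red[rr[ok], cc2[ok]] = 0.95
            centers.append((r, c, rad))
            placed += 1

    place(n_in, True, density)
    if n_out:
        place(n_out, False, outside_density)

    green = np.clip(green + rng.normal(0, 0.02, green.shape), 0, 1)
    red = np.clip(red + rng.normal(0, 0.02, red.shape), 0, 1)
    pair = HistologyPair(green=green, red=red, scale_um_per_px=scale,
                         field_id=field_id,
                         tissue_class="tumor" if mode == "tumor" else "contralateral_normal")
    truth = HistologyTruth(mask=mask, n_vessels_inside=n_in,
                           density_per_mm2=density)
    return pair, truth
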