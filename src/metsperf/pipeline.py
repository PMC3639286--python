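"""End-to-end cohort analyses on the digital phantom.

These drivers chain the modules the way the study was run: synthesize the
animal, detect and classify lesions on the anatomic images, run the DSC
chain (ΔR2* -> FPPM bolus window -> three-segment baseline -> gamma-variate
CBV) on ROI-mean curves, and normalize with the multi-reference
contralateral scheme.  Lesions are rCBV-eligible only when they fall on a
DSC-covered slice and occupy at least one DSC voxel at >= 50% - the
analogue of running perfusion on the 4 slices containing most of the
metastases.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import dsc as _dsc
from .geometry import AcquisitionGeometry
from .lesions import (LesionRecord, assign_region, classify_enhancement,
                      detect_lesions, match_lesions, records_to_frame)
from .phantom import (BrainLabelMap, CohortPreset, GroundTruthLesion, Region,
                      build_anatomy, choose_dsc_slices, longitudinal_preset,
                      seed_lesions, simulate_dsc, simulate_mri, week5_preset,
                      _downsample_blocks)
from .rcbv import ROI, build_reference_rois, compute_rcbv

MIN_ROI_OCCUPANCY = 0.5      # DSC-voxel occupancy for a tumor ROI voxel
ABNORMAL_OCCUPANCY = 0.25    # occupancy above which a voxel is "abnormal"


def _spawn_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n)


def record_dsc_mask(record: LesionRecord, geometry: AcquisitionGeometry,
                    dsc_slices: np.ndarray,
                    min_occupancy: float = MIN_ROI_OCCUPANCY) -> np.ndarray:
    """Transfer a detected lesion mask to the DSC grid by block occupancy."""
    f = geometry.downsample
    out = np.zeros((geometry.dsc_matrix, geometry.dsc_matrix, len(dsc_slices)),
                   dtype=bool)
    where = np.flatnonzero(np.asarray(dsc_slices) == record.slice_index)
    if where.size == 0:
        return out
    plane = np.zeros((geometry.matrix, geometry.matrix))
    plane[record.rows, record.cols] = 1.0
    occ = _downsample_blocks(plane, f)
    out[:, :, where[0]] = occ >= min_occupancy
    return out


def _detected_occupancy(records: Sequence[LesionRecord],
                        geometry: AcquisitionGeometry,
                        dsc_slices: np.ndarray) -> np.ndarray:
    """DSC voxels touched by any detected lesion above the abnormal threshold."""
    f = geometry.downsample
    occ = np.zeros((geometry.dsc_matrix, geometry.dsc_matrix, len(dsc_slices)))
    for rec in records:
        where = np.flatnonzero(np.asarray(dsc_slices) == rec.slice_index)
        if where.size == 0:
            continue
        plane = np.zeros((geometry.matrix, geometry.matrix))
        plane[rec.rows, rec.cols] = 1.0
        occ[:, :, where[0]] = np.maximum(occ[:, :, where[0]],
                                         _downsample_blocks(plane, f))
    return occ >= ABNORMAL_OCCUPANCY


def _classify_records(records: Sequence[LesionRecord], t1w_post: np.ndarray,
                      anatomy: BrainLabelMap) -> None:
    shape = t1w_post.shape
    all_masks = np.zeros(shape, dtype=bool)
    for rec in records:
        all_masks[rec.rows, rec.cols, rec.slice_index] = True
    for rec in records:
        assign_region(rec, anatomy)
        classify_enhancement(rec, t1w_post, int(anatomy.midline[rec.slice_index]),
                             exclude_masks=all_masks)


def _roi_rcbv(records: Sequence[LesionRecord], anatomy: BrainLabelMap,
              series: _dsc.DSCSeries, labels_dsc: np.ndarray,
              dsc_slices: np.ndarray, animal: str, week: int) -> pd.DataFrame:
    """ROI-level DSC chain + multi-reference normalization for one scan."""
    geometry = anatomy.geometry
    tumor_rois: List[ROI] = []
    for rec in records:
        mask = record_dsc_mask(rec, geometry, dsc_slices)
        if mask.any():
            where = int(np.flatnonzero(np.asarray(dsc_slices) == rec.slice_index)[0])
            tumor_rois.append(ROI(roi_id=f"les{rec.id:03d}", mask=mask,
                                  cls="tumor", slice_index=where,
                                  region=rec.region))
    if not tumor_rois:
        return pd.DataFrame()
    abnormal = _detected_occupancy(records, geometry, dsc_slices)
    abnormal |= labels_dsc == int(Region.VENTRICLE)
    rois, _excluded = build_reference_rois(tumor_rois, abnormal, labels_dsc,
                                           anatomy.dsc_midline)
    if not rois:
        return pd.DataFrame()
    dr2s = _dsc.delta_r2star(series)
    times = series.frame_times
    window = _dsc.detect_bolus_fppm(_dsc.roi_curve(dr2s, series.mask), times,
                                    series.baseline_frames)
    cbv_by_roi: Dict[str, float] = {}
    for roi in rois:
        fit = _dsc.fit_curve(_dsc.roi_curve(dr2s, roi.mask), times, window)
        good = fit.converged and np.isfinite(fit.cbv) and fit.cbv > 0
        cbv_by_roi[roi.roi_id] = fit.cbv if good else float("nan")
    return compute_rcbv(cbv_by_roi, rois, animal, week)


def _join_rcbv(records: Sequence[LesionRecord], table: pd.DataFrame) -> None:
    if len(table) == 0:
        return
    by_id = table.set_index("roi_id")
    for rec in records:
        rid = f"les{rec.id:03d}"
        if rid in by_id.index and by_id.loc[rid, "class"] == "tumor":
            rec.rcbv = float(by_id.loc[rid, "rcbv"])
            pair = by_id.loc[rid, "pair_id"]
            if pair in by_id.index:
                rec.normal_rcbv = float(by_id.loc[pair, "rcbv"])


def _attach_truth(records: Sequence[LesionRecord],
                  lesions: Sequence[GroundTruthLesion],
                  geometry: AcquisitionGeometry) -> pd.DataFrame:
    """Match detected records to seeded lesions by slice and centroid."""
    rows = []
    radius_px = 0.3 / geometry.pixel_size_mm
    for rec in records:
        best, best_d = None, np.inf
        for les in lesions:
            if les.slice_index != rec.slice_index:
                continue
            c = les.centroid
            d = float(np.hypot(c[0] - rec.centroid[0], c[1] - rec.centroid[1]))
            if d < best_d:
                best, best_d = les, d
        if best is not None and best_d <= radius_px:
            rows.append({"id": rec.id, "true_id": best.id, "true_ratio": best.ratio,
                         "true_enh_class": best.enh_class,
                         "true_area_mm2": best.area_mm2,
                         "true_region": int(best.region)})
        else:
            rows.append({"id": rec.id, "true_id": -1, "true_ratio": np.nan,
                         "true_enh_class": "unknown", "true_area_mm2": np.nan,
                         "true_region": 0})
    return pd.DataFrame(rows)


def analyze_week5_animal(seed: int, preset: Optional[CohortPreset] = None,
                         geometry: Optional[AcquisitionGeometry] = None,
                         animal: str = "a0", week: int = 5,
                         return_roi_table: bool = False):
    """Simulate and analyze one animal's final-week scan session.

    Returns the per-lesion table; with ``return_roi_table`` also the raw
    per-ROI rCBV table (tumor and normal-reference rows)."""
    preset = preset or week5_preset()
    geometry = geometry or AcquisitionGeometry()
    s = _spawn_seeds(seed, 5)
    anatomy = build_anatomy(geometry, seed=int(s[0]) % (2 ** 31))
    idx = int(animal[1:]) if animal[1:].isdigit() else 0
    lesions = seed_lesions(anatomy, preset, week=week, seed=int(s[1]) % (2 ** 31),
                           animal_index=idx)
    t2w = simulate_mri(anatomy, lesions, preset, "T2w", seed=int(s[2]) % (2 ** 31))
    t1p = simulate_mri(anatomy, lesions, preset, "T1w_post", seed=int(s[3]) % (2 ** 31))
    records = detect_lesions(t2w, anatomy.brain_mask, geometry, animal, week)
    _classify_records(records, t1p, anatomy)
    series, truth = simulate_dsc(anatomy, lesions, preset, seed=int(s[4]) % (2 ** 31))
    table = _roi_rcbv(records, anatomy, series, truth.labels_dsc,
                      truth.dsc_slices, animal, week)
    _join_rcbv(records, table)
    df = records_to_frame(records)
    df = df.merge(_attach_truth(records, lesions, geometry), on="id", how="left")
    df["on_dsc_slice"] = df["slice"].isin(truth.dsc_slices)
    if return_roi_table:
        return df, table
    return df


def run_week5_cohort(seed: int, preset: Optional[CohortPreset] = None,
                     geometry: Optional[AcquisitionGeometry] = None) -> pd.DataFrame:
    """The week-5 cross-sectional cohort: one row per detected lesion."""
    preset = preset or week5_preset()
    geometry = geometry or AcquisitionGeometry()
    seeds = _spawn_seeds(seed, preset.n_animals)
    frames = []
    for i in range(preset.n_animals):
        frames.append(analyze_week5_animal(int(seeds[i]) % (2 ** 31), preset,
                                           geometry, animal=f"a{i}"))
    return pd.concat(frames, ignore_index=True)


def _analyze_scan(anatomy: BrainLabelMap, lesions: Sequence[GroundTruthLesion],
                  preset: CohortPreset, dsc_slices: np.ndarray, animal: str,
                  week: int, seeds: np.ndarray):
    geometry = anatomy.geometry
    t2w = simulate_mri(anatomy, lesions, preset, "T2w", seed=int(seeds[0]) % (2 ** 31))
    t1p = simulate_mri(anatomy, lesions, preset, "T1w_post", seed=int(seeds[1]) % (2 ** 31))
    records = detect_lesions(t2w, anatomy.brain_mask, geometry, animal, week)
    _classify_records(records, t1p, anatomy)
    series, truth = simulate_dsc(anatomy, lesions, preset,
                                 seed=int(seeds[2]) % (2 ** 31),
                                 dsc_slices=dsc_slices)
    table = _roi_rcbv(records, anatomy, series, truth.labels_dsc, dsc_slices,
                      animal, week)
    _join_rcbv(records, table)
    return records


def run_longitudinal_animal(seed: int, preset: Optional[CohortPreset] = None,
                            geometry: Optional[AcquisitionGeometry] = None,
                            animal: str = "a0", animal_index: int = 0,
                            weeks: Tuple[int, int] = (3, 4)) -> pd.DataFrame:
    """Two-week follow-up of one animal: detection, tracking, DSC, rCBV.

    Returns one row per matched track with rCBV (tumor and paired normal)
    at both weeks; tracks missing a measurement carry NaN.
    """
    preset = preset or longitudinal_preset()
    geometry = geometry or AcquisitionGeometry()
    s = _spawn_seeds(seed, 9)
    anatomy = build_anatomy(geometry, seed=int(s[0]) % (2 ** 31))
    early = seed_lesions(anatomy, preset, week=weeks[0], seed=int(s[1]) % (2 ** 31),
                         animal_index=animal_index)
    late = seed_lesions(anatomy, preset, week=weeks[1], seed=int(s[2]) % (2 ** 31),
                        existing=early)
    dsc_slices = choose_dsc_slices(early, geometry)
    recs_early = _analyze_scan(anatomy, early, preset, dsc_slices, animal,
                               weeks[0], s[3:6])
    recs_late = _analyze_scan(anatomy, late, preset, dsc_slices, animal,
                              weeks[1], s[6:9])
    tracks, _log = match_lesions(recs_early, recs_late, geometry)
    by_id_early = {r.id: r for r in recs_early}
    by_id_late = {r.id: r for r in recs_late}
    rows = []
    for tr in tracks:
        if len(tr.weeks) != 2:
            continue
        a = by_id_early[tr.record_ids[0]]
        b = by_id_late[tr.record_ids[1]]
        rows.append({
            "animal": animal, "track_id": tr.track_id,
            "slice": a.slice_index,
            "area_early": a.area_mm2, "area_late": b.area_mm2,
            "rcbv_early": a.rcbv, "rcbv_late": b.rcbv,
            "normal_early": a.normal_rcbv, "normal_late": b.normal_rcbv,
            "enh_class_early": a.enh_class, "enh_class_late": b.enh_class,
        })
    return pd.DataFrame(rows)


def run_longitudinal_cohort(seed: int, preset: Optional[CohortPreset] = None,
                            geometry: Optional[AcquisitionGeometry] = None
                            ) -> pd.DataFrame:
    """Tracked-lesion table pooled over the longitudinal cohort."""
    preset = preset or longitudinal_preset()
    geometry = geometry or AcquisitionGeometry()
    seeds = _spawn_seeds(seed, preset.n_animals)
    frames = []
    for i in range(preset.n_animals):
        frames.append(run_longitudinal_animal(int(seeds[i]) % (2 ** 31), preset,
                                              geometry, animal=f"a{i}",
                                              animal_index=i))
    return pd.concat(frames, ignore_index=True)


def seeded_region_fractions(n_lesions: int, seed: int,
                            preset: Optional[CohortPreset] = None,
                            geometry: Optional[AcquisitionGeometry] = None,
                            batch: int = 100) -> pd.Series:
    """Empirical regional distribution of many seeded lesions.

    Lesions are seeded in batches on a fresh occupancy grid (one anatomy is
    reused; placement is the only per-batch state) and each is assigned to
    the region of the majority label under its pixels.
    """
    preset = preset or week5_preset()
    geometry = geometry or AcquisitionGeometry()
    anatomy = build_anatomy(geometry)
    seeds = _spawn_seeds(seed, (n_lesions + batch - 1) // batch)
    counts: Dict[str, int] = {}
    done = 0
    for b, s in enumerate(seeds):
        n = min(batch, n_lesions - done)
        lesions = seed_lesions(anatomy, preset, week=preset.first_week,
                               seed=int(s) % (2 ** 31), n_lesions=n)
        for les in lesions:
            labs = anatomy.labels[les.rows, les.cols, les.slice_index]
            labs = labs[labs > 0]
            codes, cnt = np.unique(labs, return_counts=True)
            name = Region(int(codes[np.argmax(cnt)])).name.lower()
            counts[name] = counts.get(name, 0) + 1
        done += n
    return pd.Series(counts, dtype=float) / n_lesions
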