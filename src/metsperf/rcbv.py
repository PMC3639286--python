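"""Multi-reference contralateral rCBV normalization.

Each tumor ROI is paired with a mirror-position normal ROI on the same
slice.  When the mirrored site is itself abnormal (overlaps a lesion or
QC-failed voxels above a tolerance), the nearest lesion-free, equal-area
site in the same anatomical region and hemisphere substitutes.  The mean
CBV of all the normal ROIs in an animal serves as the per-animal reference;
rCBV of every ROI (tumor and normal) is its mean CBV divided by that
reference, so the mean rCBV over an animal's normal ROIs is 1 exactly by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ROIError

#: fraction of candidate voxels overlapping lesions that triggers substitution
OVERLAP_TOLERANCE = 0.05
#: ROI dropped when fewer than this fraction of voxels pass QC
MIN_QC_FRACTION = 0.5


@dataclass
class ROI:
    """One region of interest on the DSC grid."""

    roi_id: str
    mask: np.ndarray               # boolean, DSC grid (x, y, slice)
    cls: str                       # "tumor" | "normal_reference"
    slice_index: int               # index within the DSC stack
    region: int = 0
    pair_id: Optional[str] = None
    provenance: str = ""           # "mirrored" | "neighbor_substitute"

    @property
    def centroid(self) -> Tuple[float, float]:
        rr, cc = np.nonzero(self.mask[:, :, self.slice_index])
        return float(rr.mean()), float(cc.mean())


def mirror_mask(mask2d: np.ndarray, midline: float) -> np.ndarray:
    """Reflect a 2D mask across the midline column (col' = 2*mid - col)."""
    rr, cc = np.nonzero(mask2d)
    ref = np.rint(2.0 * midline - cc).astype(int)
    if ref.min() < 0 or ref.max() >= mask2d.shape[1]:
        raise ROIError("reflected mask exits image bounds")
    out = np.zeros_like(mask2d, dtype=bool)
    out[rr, ref] = True
    return out


def mirror_roi(roi: ROI, midline: float) -> np.ndarray:
    """Reflect a tumor ROI to its contralateral candidate on the same slice."""
    s = roi.slice_index
    out = np.zeros_like(roi.mask)
    try:
        out[:, :, s] = mirror_mask(roi.mask[:, :, s], midline)
    except ROIError as exc:
        raise ROIError(f"{roi.roi_id}: {exc}") from exc
    return out


def _majority_region(labels2d: np.ndarray, mask2d: np.ndarray) -> int:
    vals = labels2d[mask2d]
    vals = vals[vals > 0]
    if vals.size == 0:
        return 0
    codes, counts = np.unique(vals, return_counts=True)
    return int(codes[np.argmax(counts)])


def _disc_offsets(n_vox: int):
    r = max(np.sqrt(n_vox / np.pi), 0.8)
    half = int(np.ceil(r)) + 1
    dr, dc = np.mgrid[-half:half + 1, -half:half + 1]
    d2 = dr ** 2 + dc ** 2
    order = np.argsort(d2.ravel(), kind="stable")[:n_vox]
    return dr.ravel()[order], dc.ravel()[order]


def resolve_reference(candidate: np.ndarray, slice_index: int,
                      abnormal: np.ndarray, labels_dsc: np.ndarray,
                      midline: float,
                      overlap_tol: float = OVERLAP_TOLERANCE):
    """Validate a mirrored candidate or substitute a neighboring site.

    ``abnormal`` marks lesion-overlapping or QC-failed voxels.  If the
    candidate overlaps it above ``overlap_tol`` (fraction of candidate
    voxels), the nearest equal-area disc in the same region code and
    hemisphere that is lesion-free is returned instead.

    Returns ``(mask, provenance)``; raises :class:`ROIError` when no valid
    reference exists.
    """
    cand2d = candidate[:, :, slice_index]
    n_vox = int(cand2d.sum())
    if n_vox == 0:
        raise ROIError("empty candidate mask")
    lab2d = labels_dsc[:, :, slice_index]
    abn2d = abnormal[:, :, slice_index]
    overlap = (cand2d & abn2d).sum() / n_vox
    if overlap <= overlap_tol:
        return candidate, "mirrored"

    region = _majority_region(lab2d, cand2d)
    rr, cc = np.nonzero(cand2d)
    c0 = np.array([rr.mean(), cc.mean()])
    hemisphere_right = c0[1] > midline
    cols = np.arange(lab2d.shape[1])
    hemi = cols > midline if hemisphere_right else cols < midline
    allowed = (lab2d == region) & ~abn2d & hemi[None, :]
    pool = np.argwhere(allowed)
    if pool.size == 0:
        raise ROIError(f"no lesion-free region-{region} tissue in hemisphere")
    d2 = ((pool - c0) ** 2).sum(axis=1)
    dr, dc = _disc_offsets(n_vox)
    H, W = lab2d.shape
    for idx in np.argsort(d2, kind="stable"):
        r, c = pool[idx]
        rr2, cc2 = r + dr, c + dc
        if rr2.min() < 0 or cc2.min() < 0 or rr2.max() >= H or cc2.max() >= W:
            continue
        if not allowed[rr2, cc2].all():
            continue
        out = np.zeros_like(candidate)
        out[rr2, cc2, slice_index] = True
        return out, "neighbor_substitute"
    raise ROIError(f"no lesion-free same-region area of {n_vox} voxels available")


def build_reference_rois(tumor_rois: Sequence[ROI], abnormal: np.ndarray,
                         labels_dsc: np.ndarray, midline: float,
                         overlap_tol: float = OVERLAP_TOLERANCE):
    """Pair every tumor ROI with a contralateral normal ROI.

    Returns ``(rois, excluded)`` where ``rois`` holds the tumor ROIs (with
    pair ids filled) followed by their normal references, and ``excluded``
    maps tumor roi_ids to the reason no reference could be found.
    Processing order is sorted by roi_id, so permuting the input changes
    nothing.
    """
    abnormal = abnormal.astype(bool).copy()
    out: List[ROI] = []
    excluded: Dict[str, str] = {}
    for roi in sorted(tumor_rois, key=lambda r: r.roi_id):
        try:
            candidate = mirror_roi(roi, midline)
            mask, provenance = resolve_reference(candidate, roi.slice_index,
                                                 abnormal, labels_dsc, midline,
                                                 overlap_tol)
        except ROIError as exc:
            excluded[roi.roi_id] = str(exc)
            continue
        normal_id = f"{roi.roi_id}_ref"
        region = _majority_region(labels_dsc[:, :, roi.slice_index],
                                  mask[:, :, roi.slice_index])
        tumor = ROI(roi_id=roi.roi_id, mask=roi.mask, cls="tumor",
                    slice_index=roi.slice_index, region=roi.region,
                    pair_id=normal_id, provenance="")
        normal = ROI(roi_id=normal_id, mask=mask, cls="normal_reference",
                     slice_index=roi.slice_index, region=region,
                     pair_id=roi.roi_id, provenance=provenance)
        # reserve substituted sites so two normals never overlap
        if provenance == "neighbor_substitute":
            abnormal |= mask
        out.extend([tumor, normal])
    return out, excluded


def roi_mean_cbv(cbv_values: np.ndarray, qc_failed: np.ndarray, roi: ROI,
                 min_qc_fraction: float = MIN_QC_FRACTION) -> float:
    """Mean CBV over the QC-passed voxels of an ROI (NaN if too few pass)."""
    vals = cbv_values[roi.mask]
    ok = ~qc_failed[roi.mask] & np.isfinite(vals)
    if ok.mean() < min_qc_fraction:
        return float("nan")
    return float(vals[ok].mean())


def compute_rcbv(cbv_by_roi: Dict[str, float], rois: Sequence[ROI],
                 animal: str, week: int) -> pd.DataFrame:
    """Normalize per-ROI mean CBV by the animal's multi-reference value.

    ``cbv_by_roi`` maps roi_id to mean CBV (NaN entries are dropped).  The
    reference is the mean over the normal-reference ROIs; every ROI's rCBV
    is its CBV divided by that reference.
    """
    rows = []
    for roi in rois:
        cbv = cbv_by_roi.get(roi.roi_id, float("nan"))
        if not np.isfinite(cbv):
            continue
        rows.append({
            "roi_id": roi.roi_id, "class": roi.cls, "slice": roi.slice_index,
            "region": roi.region, "pair_id": roi.pair_id,
            "provenance": roi.provenance, "mean_cbv": cbv,
        })
    df = pd.DataFrame(rows)
    normals = df[df["class"] == "normal_reference"] if len(df) else df
    if len(df) == 0 or len(normals) == 0:
        raise ROIError(f"animal {animal}: no normal reference ROIs")
    reference = float(normals["mean_cbv"].mean())
    if reference <= 0:
        raise ROIError(f"animal {animal}: non-positive reference CBV {reference}")
    df["rcbv"] = df["mean_cbv"] / reference
    df["animal"] = animal
    df["week"] = week
    df.attrs["reference_cbv"] = reference
    return df
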