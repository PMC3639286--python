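"""Readers/writers for the standard formats the pipeline exchanges:
NIfTI volumes/series, YAML acquisition sidecars, TIFF histology fields."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import nibabel as nib
import numpy as np
import yaml

from .geometry import AcquisitionGeometry
from .phantom import HistologyPair

PathLike = Union[str, Path]


def _affine(geometry: AcquisitionGeometry, dsc: bool = False) -> np.ndarray:
    px = geometry.dsc_pixel_size_mm if dsc else geometry.pixel_size_mm
    return np.diag([px, px, geometry.slice_thickness_mm, 1.0])


def write_nifti(volume: np.ndarray, path: PathLike,
                geometry: AcquisitionGeometry, dsc: bool = False) -> None:
    img = nib.Nifti1Image(np.asarray(volume), _affine(geometry, dsc))
    if volume.ndim == 4:
        img.header.set_zooms((*img.header.get_zooms()[:3], geometry.frame_interval_s))
    nib.save(img, str(path))


def read_nifti(path: PathLike) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj)


def write_acquisition_sidecar(geometry: AcquisitionGeometry, path: PathLike,
                              baseline_frames: Optional[np.ndarray] = None) -> None:
    data = {
        "te_ms": geometry.te_dsc_ms,
        "tr_ms": geometry.tr_dsc_ms,
        "frame_interval_s": geometry.frame_interval_s,
        "n_frames": geometry.n_frames,
        "pixel_size_um": geometry.pixel_size_um,
        "slice_thickness_mm": geometry.slice_thickness_mm,
    }
    if baseline_frames is not None:
        data["baseline_frames"] = [int(i) for i in baseline_frames]
    Path(path).write_text(yaml.safe_dump(data))


def read_acquisition_sidecar(path: PathLike) -> dict:
    return yaml.safe_load(Path(path).read_text())


def write_histology_tiff(pair: HistologyPair, path: PathLike) -> None:
    """2-page TIFF (green, red) with the µm/pixel scale in the metadata."""
    import tifffile

    stack = np.stack([pair.green, pair.red]).astype(np.float32)
    res_ppcm = 1e4 / pair.scale_um_per_px      # pixels per centimeter
    tifffile.imwrite(str(path), stack, resolution=(res_ppcm, res_ppcm),
                     resolutionunit="CENTIMETER",
                     metadata={"scale_um_per_px": pair.scale_um_per_px,
                               "tissue_class": pair.tissue_class})


def read_histology_tiff(path: PathLike, tissue_class: str = "tumor",
                        field_id: int = 0) -> HistologyPair:
    import tifffile

    with tifffile.TiffFile(str(path)) as tf:
        stack = tf.asarray()
        scale = None
        meta = tf.shaped_metadata or tf.imagej_metadata
        if meta:
            entry = meta[0] if isinstance(meta, (list, tuple)) else meta
            scale = entry.get("scale_um_per_px")
            tissue_class = entry.get("tissue_class", tissue_class)
        if scale is None:
            tags = tf.pages[0].tags
            if "XResolution" in tags:
                num, den = tags["XResolution"].value
                scale = 1e4 * den / num
    if scale is None:
        raise ValueError(f"{path}: no µm/pixel scale in TIFF metadata")
    return HistologyPair(green=np.asarray(stack[0], float),
                         red=np.asarray(stack[1], float),
                         scale_um_per_px=float(scale),
                         field_id=field_id, tissue_class=tissue_class)


def write_preset_sidecar(preset, path: PathLike) -> None:
    from dataclasses import asdict

    Path(path).write_text(json.dumps(asdict(preset), indent=2, default=list))
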