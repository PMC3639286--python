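"""Acquisition geometry shared by the phantom and the analysis modules.

The defaults mirror a preclinical 9.4 T protocol: 256x256 anatomic matrix at
78 um in-plane over a 20 mm FOV with 14 contiguous 1 mm coronal slices, and a
64x64 dynamic susceptibility contrast (DSC) series (TE = 4 ms) covering 4 of
those slices at one frame every 2 s for 5 minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Pixel sizes, slice layout and DSC frame timing.

    The DSC grid must be an integer in-plane downsampling of the anatomic
    grid so that lesion masks drawn on anatomic images can be transferred to
    the perfusion series by block occupancy.
    """

    pixel_size_um: float = 78.0          # anatomic in-plane pixel size
    matrix: int = 256                    # anatomic in-plane matrix (square)
    dsc_matrix: int = 64                 # DSC in-plane matrix (square)
    slice_thickness_mm: float = 1.0
    n_slices: int = 14                   # anatomic slices (coronal)
    n_dsc_slices: int = 4                # DSC covers a subset of slices
    te_dsc_ms: float = 4.0               # DSC echo time
    tr_dsc_ms: float = 27.0
    frame_interval_s: float = 2.0
    n_frames: int = 150

    def __post_init__(self) -> None:
        positive = (
            self.pixel_size_um, self.matrix, self.dsc_matrix,
            self.slice_thickness_mm, self.n_slices, self.n_dsc_slices,
            self.te_dsc_ms, self.frame_interval_s, self.n_frames,
        )
        if any(v <= 0 for v in positive):
            raise ConfigurationError("all geometry parameters must be positive")
        if self.matrix % self.dsc_matrix != 0:
            raise ConfigurationError(
                f"DSC matrix {self.dsc_matrix} must evenly divide anatomic matrix {self.matrix}"
            )
        if self.n_dsc_slices > self.n_slices:
            raise ConfigurationError("DSC cannot cover more slices than acquired")

    # -- derived quantities -------------------------------------------------

    @property
    def downsample(self) -> int:
        """In-plane block size mapping anatomic pixels to one DSC voxel."""
        return self.matrix // self.dsc_matrix

    @property
    def pixel_size_mm(self) -> float:
        return self.pixel_size_um / 1000.0

    @property
    def pixel_area_mm2(self) -> float:
        return self.pixel_size_mm ** 2

    @property
    def dsc_pixel_size_mm(self) -> float:
        return self.pixel_size_mm * self.downsample

    @property
    def te_s(self) -> float:
        return self.te_dsc_ms / 1000.0

    @property
    def frame_times(self) -> np.ndarray:
        """Time of each DSC frame in seconds (frame 0 at t = 0)."""
        return np.arange(self.n_frames) * self.frame_interval_s
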