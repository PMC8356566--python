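"""Acquisition geometry and the canonical volume container.

The canonical axis order for raw acquisitions is ``(repeat, bscan, depth,
ascan)``.  Depth index 0 is the vitreous side and increases toward the
choroid, so "above a junction" always means a *smaller* depth index.
All coordinates are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Axial sampling of the investigational handheld swept-source device, µm per
#: depth pixel.  One pixel of slab offset therefore corresponds to 4.37 µm.
DEFAULT_AXIAL_PIXEL_DEPTH_UM = 4.37

CANONICAL_AXES = "rbza"  # repeat, bscan, depth (z), ascan


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Scan-pattern metadata for a repeated-B-scan OCT-A acquisition.

    Parameters
    ----------
    n_repeats:
        B-scan repeats per lateral location.  Flow detection is a temporal
        variance, so at least two repeats are required.
    n_bscans, n_ascans:
        Lateral raster dimensions (slow and fast axes).
    axial_pixel_depth_um:
        Depth sampling in µm per pixel.
    lateral_extent_mm:
        Physical (slow, fast) scan extent in millimetres.
    """

    n_repeats: int
    n_bscans: int
    n_ascans: int
    axial_pixel_depth_um: float = DEFAULT_AXIAL_PIXEL_DEPTH_UM
    lateral_extent_mm: tuple[float, float] = (2.5, 5.0)

    def __post_init__(self) -> None:
        if self.n_repeats < 2:
            raise ValueError(
                f"n_repeats must be >= 2 for temporal variance, got {self.n_repeats}"
            )
        if self.n_bscans < 1 or self.n_ascans < 1:
            raise ValueError("lateral dimensions must be positive")
        if not self.axial_pixel_depth_um > 0:
            raise ValueError("axial_pixel_depth_um must be positive")

    def to_dict(self) -> dict:
        return {
            "n_repeats": int(self.n_repeats),
            "n_bscans": int(self.n_bscans),
            "n_ascans": int(self.n_ascans),
            "axial_pixel_depth_um": float(self.axial_pixel_depth_um),
            "lateral_extent_mm": [float(v) for v in self.lateral_extent_mm],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionGeometry":
        return cls(
            n_repeats=int(d["n_repeats"]),
            n_bscans=int(d["n_bscans"]),
            n_ascans=int(d["n_ascans"]),
            axial_pixel_depth_um=float(
                d.get("axial_pixel_depth_um", DEFAULT_AXIAL_PIXEL_DEPTH_UM)
            ),
            lateral_extent_mm=tuple(d.get("lateral_extent_mm", (2.5, 5.0))),
        )


@dataclass
class AcquisitionVolume:
    """Raw structural intensities indexed ``(repeat, bscan, depth, ascan)``."""

    geometry: AcquisitionGeometry
    intensities: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=np.float64)
        if arr.ndim != 4:
            raise ValueError(f"intensities must be 4-D, got ndim={arr.ndim}")
        expected = (self.geometry.n_repeats, self.geometry.n_bscans)
        if arr.shape[0] != expected[0] or arr.shape[1] != expected[1] or arr.shape[3] != self.geometry.n_ascans:
            raise ValueError(
                f"intensity shape {arr.shape} inconsistent with geometry "
                f"(repeats={self.geometry.n_repeats}, bscans={self.geometry.n_bscans}, "
                f"ascans={self.geometry.n_ascans})"
            )
        if not np.all(np.isfinite(arr)):
            raise ValueError("intensities contain non-finite voxels")
        if arr.min() < 0:
            raise ValueError("intensities must be nonnegative")
        self.intensities = arr

    @property
    def depth(self) -> int:
        return self.intensities.shape[2]

    def mean_structural(self) -> np.ndarray:
        """Repeat-averaged structural volume, shape (bscan, depth, ascan)."""
        return self.intensities.mean(axis=0)


def round_half_up(x) -> np.ndarray:
    """Round fractional pixel positions with ties going toward the choroid.

    ``np.round`` rounds half-to-even; boundary positions use half-up so that
    a boundary at z = 12.5 places the interval endpoint at 13 deterministically.
    """
    return np.floor(np.asarray(x, dtype=np.float64) + 0.5).astype(np.int64)
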