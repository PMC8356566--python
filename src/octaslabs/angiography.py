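"""Flow computation from repeated B-scans via speckle variance.

Perfused voxels decorrelate between consecutive B-scan repeats while static
tissue does not, so the temporal intensity variance across the repeats is a
flow contrast.  The variance here is the population (divide-by-N) variance:
the repeats are the complete set of observations at each voxel, and the
choice of N versus N-1 only rescales the flow volume globally.  Variance is
computed on intensities as stored; if the acquisition is log-compressed the
caller must linearise first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import AcquisitionGeometry, AcquisitionVolume


@dataclass
class FlowVolume:
    """Per-voxel flow (speckle variance) indexed ``(bscan, depth, ascan)``."""

    geometry: AcquisitionGeometry
    flow: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = np.asarray(self.flow, dtype=np.float64)
        if arr.ndim != 3:
            raise ValueError(f"flow must be 3-D, got ndim={arr.ndim}")
        if arr.shape[0] != self.geometry.n_bscans or arr.shape[2] != self.geometry.n_ascans:
            raise ValueError(
                f"flow shape {arr.shape} inconsistent with geometry "
                f"({self.geometry.n_bscans} B-scans, {self.geometry.n_ascans} A-scans)"
            )
        if arr.min() < -1e-12:
            raise ValueError("flow values must be nonnegative")
        self.flow = np.maximum(arr, 0.0)

    @property
    def depth(self) -> int:
        return self.flow.shape[1]


def align_repeats(volume: AcquisitionVolume, max_shift_px: int = 5) -> AcquisitionVolume:
    """Axially register each repeat B-scan to the first repeat.

    For every (repeat, B-scan) pair the integer axial shift in
    ``[-max_shift_px, +max_shift_px]`` maximising the cross-correlation with
    repeat 0 of the same B-scan is applied (rigid, zero-filled edges).  Ties
    prefer the smaller |shift|.  Recovered shifts are recorded in the returned
    volume's provenance under ``"repeat_shifts_px"``.
    """
    if max_shift_px < 0:
        raise ValueError("max_shift_px must be >= 0")
    arr = volume.intensities
    nr, nb = arr.shape[:2]
    shifts = np.zeros((nr, nb), dtype=np.int64)
    if max_shift_px == 0:
        out = arr.copy()
    else:
        out = arr.copy()
        candidates = sorted(range(-max_shift_px, max_shift_px + 1), key=abs)
        for b in range(nb):
            ref = arr[0, b]
            for r in range(1, nr):
                img = arr[r, b]
                best_s, best_score = 0, -np.inf
                for s in candidates:
                    score = _overlap_corr(ref, img, s)
                    if score > best_score + 1e-12:
                        best_score, best_s = score, s
                shifts[r, b] = best_s
                if best_s != 0:
                    out[r, b] = _axial_shift(img, best_s)
    prov = dict(volume.provenance)
    prov["alignment"] = {
        "max_shift_px": int(max_shift_px),
        "repeat_shifts_px": shifts.tolist(),
    }
    return AcquisitionVolume(geometry=volume.geometry, intensities=out, provenance=prov)


def _overlap_corr(ref: np.ndarray, img: np.ndarray, s: int) -> float:
    """Correlation of ref with img shifted by s pixels in depth, on the overlap."""
    nz = ref.shape[0]
    if s >= 0:
        a, b = ref[s:], img[: nz - s]
    else:
        a, b = ref[:nz + s], img[-s:]
    if a.size == 0:
        return -np.inf
    return float(np.sum(a * b) / a.size)


def _axial_shift(img: np.ndarray, s: int) -> np.ndarray:
    """Shift a (depth, ascan) image by s pixels toward the choroid (s > 0)."""
    out = np.zeros_like(img)
    if s > 0:
        out[s:] = img[:-s]
    elif s < 0:
        out[:s] = img[-s:]
    else:
        out[:] = img
    return out


def speckle_variance(volume: AcquisitionVolume) -> FlowVolume:
    """Per-voxel population variance over the repeat axis.

    flow[b, z, x] = (1/N) * sum_r (I[r, b, z, x] - mean_r I)^2
    """
    if volume.geometry.n_repeats < 2:
        raise ValueError("speckle variance requires at least 2 repeats")
    flow = volume.intensities.var(axis=0, ddof=0)
    prov = dict(volume.provenance)
    prov["speckle_variance"] = {"estimator": "population", "n_repeats": volume.geometry.n_repeats}
    return FlowVolume(geometry=volume.geometry, flow=flow, provenance=prov)


def mask_low_signal(
    flow: FlowVolume, structural: AcquisitionVolume, floor: float = 0.05
) -> FlowVolume:
    """Zero flow where mean structural intensity falls below a quantile.

    Variance in signal-free regions (vitreous, deep shadow) is pure noise;
    voxels whose repeat-averaged structural intensity is strictly below the
    ``floor`` quantile of the whole volume are suppressed.  ``floor=0``
    leaves the flow unchanged.
    """
    if not 0 <= floor < 1:
        raise ValueError(f"floor must be in [0, 1), got {floor}")
    if floor == 0:
        return FlowVolume(geometry=flow.geometry, flow=flow.flow.copy(),
                          provenance=dict(flow.provenance))
    mean_struct = structural.mean_structural()
    cutoff = float(np.quantile(mean_struct, floor))
    masked = np.where(mean_struct < cutoff, 0.0, flow.flow)
    prov = dict(flow.provenance)
    prov["signal_mask"] = {"floor_quantile": float(floor), "intensity_cutoff": cutoff}
    return FlowVolume(geometry=flow.geometry, flow=masked, provenance=prov)
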