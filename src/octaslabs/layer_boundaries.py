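"""Retinal layer boundary surfaces and a baseline automatic segmenter.

The slab pipeline is anchored to three anatomical junctions:

* ``ILM`` — vitreous / inner limiting membrane (dark-to-bright transition),
* ``IPL_INL`` — inner plexiform / inner nuclear layer (bright-to-dark),
* ``OPL_ONL`` — outer plexiform / outer nuclear layer (bright-to-dark).

The segmenter here is a deliberately simple baseline: a per-B-scan shortest
path through an axial-gradient cost image, searched sequentially in
anatomically ordered bands so the non-crossing invariant
``ILM <= IPL_INL <= OPL_ONL`` holds by construction.  The pipeline's real
contract is "boundaries in, slabs out": surfaces segmented elsewhere and
imported (optionally with manual corrections) are first-class inputs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .geometry import AcquisitionGeometry, AcquisitionVolume

logger = logging.getLogger(__name__)

#: Junction names in vitreous-to-choroid order.
JUNCTIONS = ("ILM", "IPL_INL", "OPL_ONL")


@dataclass
class BoundarySet:
    """Named junction surfaces as fractional-pixel depth maps.

    ``surfaces[name]`` has shape ``(n_bscans, n_ascans)``; values are depth
    positions in pixels (fractional allowed), satisfying the non-crossing
    order ILM <= IPL_INL <= OPL_ONL at every lateral position.
    """

    surfaces: dict[str, np.ndarray]
    geometry: AcquisitionGeometry | None = None
    depth_extent: int | None = None

    def __post_init__(self) -> None:
        for name in self.surfaces:
            if name not in JUNCTIONS:
                raise ValueError(f"unknown junction name {name!r}; expected one of {JUNCTIONS}")
        shapes = {s.shape for s in self.surfaces.values()}
        if len(shapes) > 1:
            raise ValueError(f"junction surfaces disagree in shape: {shapes}")
        self.surfaces = {k: np.asarray(v, dtype=np.float64) for k, v in self.surfaces.items()}
        self.validate()

    def validate(self) -> None:
        present = [j for j in JUNCTIONS if j in self.surfaces]
        for upper, lower in zip(present[:-1], present[1:]):
            if np.any(self.surfaces[upper] > self.surfaces[lower] + 1e-9):
                raise ValueError(f"junction order violated: {upper} deeper than {lower}")
        if self.depth_extent is not None:
            for name, s in self.surfaces.items():
                if s.min() < 0 or s.max() >= self.depth_extent:
                    raise ValueError(
                        f"{name} positions outside [0, {self.depth_extent})"
                    )

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.surfaces.values())).shape

    def __getitem__(self, name: str) -> np.ndarray:
        return self.surfaces[name]

    def copy(self) -> "BoundarySet":
        return BoundarySet(
            surfaces={k: v.copy() for k, v in self.surfaces.items()},
            geometry=self.geometry,
            depth_extent=self.depth_extent,
        )


@dataclass(frozen=True)
class BoundaryCorrection:
    """A manual replacement trace for part of one junction surface.

    ``depth`` must have shape ``(bscan_stop - bscan_start,
    ascan_stop - ascan_start)``.
    """

    junction: str
    bscan_range: tuple[int, int]
    ascan_range: tuple[int, int]
    depth: np.ndarray

    def __post_init__(self) -> None:
        if self.junction not in JUNCTIONS:
            raise ValueError(f"unknown junction {self.junction!r}")
        b0, b1 = self.bscan_range
        a0, a1 = self.ascan_range
        want = (b1 - b0, a1 - a0)
        got = np.asarray(self.depth).shape
        if got != want:
            raise ValueError(f"replacement trace shape {got} != range shape {want}")


def _enforce_order(surfaces: dict[str, np.ndarray]) -> int:
    """Clip deeper junctions to lie at or below shallower ones, in place.

    Processed vitreous-to-choroid; returns the number of clipped positions.
    """
    n_clipped = 0
    present = [j for j in JUNCTIONS if j in surfaces]
    for upper, lower in zip(present[:-1], present[1:]):
        bad = surfaces[upper] > surfaces[lower]
        n_clipped += int(bad.sum())
        surfaces[lower] = np.maximum(surfaces[lower], surfaces[upper])
    return n_clipped


def _dp_shortest_path(cost: np.ndarray, max_jump: int = 2) -> np.ndarray:
    """Minimum-cost left-to-right path through a (depth, ascan) cost image.

    Transitions between adjacent A-scans are limited to ``max_jump`` pixels of
    axial movement, which regularises the trace against speckle.
    Returns the depth index per A-scan.
    """
    nz, nx = cost.shape
    size = 2 * max_jump + 1
    dp = np.empty((nx, nz))
    dp[0] = cost[:, 0]
    for x in range(1, nx):
        dp[x] = cost[:, x] + ndimage.minimum_filter1d(dp[x - 1], size, mode="nearest")
    path = np.empty(nx, dtype=np.int64)
    path[-1] = int(np.argmin(dp[-1]))
    for x in range(nx - 2, -1, -1):
        lo = max(0, path[x + 1] - max_jump)
        hi = min(nz, path[x + 1] + max_jump + 1)
        path[x] = lo + int(np.argmin(dp[x][lo:hi]))
    return path


#: Transition polarity per junction: +1 means dark above / bright below
#: (intensity increases with depth), -1 the opposite.
_POLARITY = {"ILM": +1, "IPL_INL": -1, "OPL_ONL": -1}

#: Anatomical band below the previously found junction in which the next one
#: is searched: at least the minimum gap (keeps the search out of the
#: transition just found), at most the maximum (keeps it off outer-retinal
#: transitions such as the RPE).
_MIN_GAP = {"IPL_INL": 8, "OPL_ONL": 6}
_MAX_GAP = {"IPL_INL": 45, "OPL_ONL": 30}


@dataclass(frozen=True)
class SegmentationParams:
    """Smoothing and regularisation settings for the baseline segmenter."""

    lateral_sigma_px: float = 2.0
    axial_sigma_px: float = 0.8
    max_jump_px: int = 2
    flat_tolerance: float = 1e-9


def segment_boundaries(
    structural: AcquisitionVolume,
    params: SegmentationParams | None = None,
) -> BoundarySet:
    """Locate ILM, IPL/INL and OPL/ONL on each repeat-averaged B-scan.

    Each junction is traced as a shortest path through a signed axial
    derivative of the smoothed B-scan; ILM rewards dark-to-bright transitions
    and the two plexiform junctions reward bright-to-dark transitions.  The
    three surfaces are searched in order with a band restriction below the
    previous one, so the returned set always satisfies the non-crossing
    invariant.  Degenerate (constant) B-scans yield flat traces at the band
    centre and emit a warning.
    """
    params = params or SegmentationParams()
    mean_vol = structural.mean_structural()  # (bscan, depth, ascan)
    nb, nz, nx = mean_vol.shape
    out = {j: np.empty((nb, nx)) for j in JUNCTIONS}

    for b in range(nb):
        img = ndimage.gaussian_filter(
            mean_vol[b], sigma=(params.axial_sigma_px, params.lateral_sigma_px)
        )
        # backward difference peaks on the first pixel of the new layer
        grad = np.empty_like(img)
        grad[1:] = img[1:] - img[:-1]
        grad[0] = 0.0
        degenerate = np.ptp(img) < params.flat_tolerance
        prev = np.zeros(nx)
        for j in JUNCTIONS:
            lo_band = prev + _MIN_GAP.get(j, 1)
            hi_band = np.minimum(prev + _MAX_GAP.get(j, nz), nz)
            if degenerate:
                centre = (lo_band + hi_band - 1) / 2.0
                out[j][b] = np.clip(centre, lo_band, nz - 1)
                prev = out[j][b]
                continue
            cost = -_POLARITY[j] * grad
            # band-restrict to the anatomically plausible depth window
            zidx = np.arange(nz)[:, None]
            cost = np.where(
                (zidx < lo_band[None, :]) | (zidx >= hi_band[None, :]), np.inf, cost
            )
            out[j][b] = _dp_shortest_path(cost, params.max_jump_px)
            prev = out[j][b]
        if degenerate:
            warnings.warn(
                f"B-scan {b} is constant; boundaries set to band centres",
                stacklevel=2,
            )

    _enforce_order(out)
    return BoundarySet(surfaces=out, geometry=structural.geometry, depth_extent=nz)


def apply_corrections(
    boundaries: BoundarySet,
    corrections: list[BoundaryCorrection],
    fade_margin_px: int = 4,
) -> BoundarySet:
    """Splice manual replacement traces into the boundary set.

    Each correction is blended in with a linear cross-fade over
    ``fade_margin_px`` pixels at the patch edges (no fade where the patch
    touches the volume edge).  Positions where the corrected surface would
    cross a neighbouring junction are clipped back into the valid band and
    logged; the clip count is recorded in the returned set's surfaces.
    """
    result = boundaries.copy()
    for corr in corrections:
        surf = result.surfaces[corr.junction]
        b0, b1 = corr.bscan_range
        a0, a1 = corr.ascan_range
        nb, nx = surf.shape
        if not (0 <= b0 < b1 <= nb and 0 <= a0 < a1 <= nx):
            raise ValueError(
                f"correction range b[{b0}:{b1}], a[{a0}:{a1}] outside surface {surf.shape}"
            )
        w = _crossfade_weights((b1 - b0, a1 - a0), fade_margin_px,
                               edges=(b0 == 0, b1 == nb, a0 == 0, a1 == nx))
        patch = np.asarray(corr.depth, dtype=np.float64)
        surf[b0:b1, a0:a1] = w * patch + (1.0 - w) * surf[b0:b1, a0:a1]

        # project the corrected junction back between its neighbours
        idx = JUNCTIONS.index(corr.junction)
        n_clip = 0
        if idx > 0:
            shallow = result.surfaces[JUNCTIONS[idx - 1]]
            bad = surf < shallow
            n_clip += int(bad.sum())
            np.maximum(surf, shallow, out=surf)
        if idx < len(JUNCTIONS) - 1:
            deep = result.surfaces[JUNCTIONS[idx + 1]]
            bad = surf > deep
            n_clip += int(bad.sum())
            np.minimum(surf, deep, out=surf)
        if n_clip:
            logger.warning(
                "correction to %s clipped at %d positions to preserve junction order",
                corr.junction, n_clip,
            )
    _enforce_order(result.surfaces)
    result.validate()
    return result


def _crossfade_weights(
    shape: tuple[int, int], margin: int, edges: tuple[bool, bool, bool, bool]
) -> np.ndarray:
    """Weight map ramping 0 -> 1 over ``margin`` pixels inside patch borders."""
    nb, nx = shape
    at_b0, at_b1, at_a0, at_a1 = edges

    def ramp(n: int, fade_lo: bool, fade_hi: bool) -> np.ndarray:
        w = np.ones(n)
        m = min(margin, n)
        if m > 0:
            edge = np.arange(1, m + 1) / (m + 1)
            if fade_lo:
                w[:m] = np.minimum(w[:m], edge)
            if fade_hi:
                w[-m:] = np.minimum(w[-m:], edge[::-1])
        return w

    wb = ramp(nb, not at_b0, not at_b1)
    wa = ramp(nx, not at_a0, not at_a1)
    return np.minimum.outer(wb, wa)


def smooth_boundaries(boundaries: BoundarySet, window: int = 3) -> BoundarySet:
    """Median-filter each surface over (bscan, ascan) with an odd window."""
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    if window == 1:
        return boundaries.copy()
    out = {
        k: ndimage.median_filter(v, size=window, mode="nearest")
        for k, v in boundaries.surfaces.items()
    }
    _enforce_order(out)
    return BoundarySet(surfaces=out, geometry=boundaries.geometry,
                       depth_extent=boundaries.depth_extent)
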