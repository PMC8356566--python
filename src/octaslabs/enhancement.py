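"""Per-slab display enhancement: normalise, threshold, row-wise CLAHE.

The chain applied to each projected slab, in order:

1. min-max normalisation to [0, 1];
2. a low-intensity-preserving threshold: values at or above the threshold
   (default 0.25) are saturated to it and the result is rescaled back to
   [0, 1].  Capillary flow signal is faint relative to large vessels, so
   saturating the bright tail stretches the sub-threshold range where the
   capillaries live.  Zeroing supra-threshold pixels instead is available
   via ``mode="zero"``;
3. contrast-limited adaptive histogram equalisation applied independently to
   each image row, the row split into eight tiles (1-D CLAHE with per-pixel
   linear interpolation between adjacent tile mappings).

Every stage maps [0, 1] into [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .slab_engine import EnFaceSlab


@dataclass(frozen=True)
class EnhanceParams:
    threshold: float = 0.25
    tiles_per_row: int = 8
    clip_limit: float = 0.01
    n_bins: int = 256
    threshold_mode: str = "rescale"  # or "zero"

    def __post_init__(self) -> None:
        if not 0 < self.threshold <= 1:
            raise ValueError("threshold must be in (0, 1]")
        if self.tiles_per_row < 1:
            raise ValueError("tiles_per_row must be >= 1")
        if self.threshold_mode not in ("rescale", "zero"):
            raise ValueError("threshold_mode must be 'rescale' or 'zero'")


def _as_image(img) -> np.ndarray:
    return img.image if isinstance(img, EnFaceSlab) else np.asarray(img, dtype=np.float64)


def _wrap(img, result: np.ndarray, step: str) -> EnFaceSlab:
    if isinstance(img, EnFaceSlab):
        prov = dict(img.provenance)
        prov["enhancement"] = [*prov.get("enhancement", []), step]
        return EnFaceSlab(image=result, name=img.name, provenance=prov)
    return EnFaceSlab(image=result, name="", provenance={"enhancement": [step]})


def normalize(img) -> EnFaceSlab:
    """Min-max normalise so pixel values span [0, 1]; a constant image maps to zeros."""
    arr = _as_image(img)
    if not np.all(np.isfinite(arr)):
        raise ValueError("image contains non-finite values")
    lo, hi = arr.min(), arr.max()
    out = np.zeros_like(arr) if hi == lo else (arr - lo) / (hi - lo)
    return _wrap(img, out, "normalize")


def threshold_preserve(img, threshold: float = 0.25, mode: str = "rescale") -> EnFaceSlab:
    """Saturate values at or above ``threshold``, keeping sub-threshold structure.

    In the default ``"rescale"`` mode the clipped image is divided by the
    threshold so the preserved low intensities span the full [0, 1] range;
    ``threshold=1.0`` is the identity.  ``"zero"`` mode instead sets
    supra-threshold pixels to 0 without rescaling.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    arr = _as_image(img)
    if mode == "rescale":
        out = np.minimum(arr, threshold) / threshold
    elif mode == "zero":
        out = np.where(arr >= threshold, 0.0, arr)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return _wrap(img, out, f"threshold_preserve({threshold}, {mode})")


def _tile_mapping(values: np.ndarray, n_bins: int, clip_limit: float) -> np.ndarray:
    """Clipped-histogram equalisation mapping for one tile.

    Returns the CDF sampled at the ``n_bins`` bin centres; the histogram is
    clipped at ``clip_limit * tile_size`` counts per bin (never below the
    uniform level ``tile_size / n_bins``, since redistribution refills bins
    to at least that) and the excess redistributed uniformly, repeated until
    the residual excess is negligible.  A very small clip limit therefore
    drives the mapping toward the identity.
    """
    # a single-valued tile has no meaningful histogram to equalise; map it
    # through the identity so constant regions (e.g. empty slab columns,
    # all-zero images) pass through unchanged
    if values.size == 0 or values.min() == values.max():
        return np.linspace(0.0, 1.0, n_bins)
    hist, _ = np.histogram(values, bins=n_bins, range=(0.0, 1.0))
    hist = hist.astype(np.float64)
    # the effective clip can never drop below the uniform level: redistributing
    # the excess always refills bins back up to it
    uniform = hist.sum() / n_bins
    clip = max(clip_limit * values.size, uniform)
    if clip <= uniform * (1 + 1e-9):
        hist = np.full(n_bins, uniform)
    else:
        for _ in range(8):
            excess = np.sum(np.maximum(hist - clip, 0.0))
            if excess <= 1e-9:
                break
            hist = np.minimum(hist, clip) + excess / n_bins
    cdf = np.cumsum(hist)
    return cdf / cdf[-1]


def clahe_rows(img, params: EnhanceParams | None = None) -> EnFaceSlab:
    """Contrast-limited adaptive histogram equalisation, one row at a time.

    Each row is treated as an independent 1-D signal partitioned into
    ``tiles_per_row`` contiguous tiles.  A clipped-histogram equalisation
    mapping is built per tile and each pixel's output linearly interpolates
    between the mappings of the two nearest tile centres (pixels outside the
    first/last centre use that tile's mapping alone).  Output values stay in
    [0, 1]; rows never influence one another.
    """
    params = params or EnhanceParams()
    arr = _as_image(img)
    if arr.min() < -1e-9 or arr.max() > 1 + 1e-9:
        raise ValueError("clahe_rows expects input in [0, 1]")
    arr = np.clip(arr, 0.0, 1.0)
    nrows, ncols = arr.shape
    tiles = params.tiles_per_row
    if ncols < tiles:
        warnings.warn(
            f"row length {ncols} < tiles_per_row {tiles}; reducing tile count",
            stacklevel=2,
        )
        tiles = ncols

    edges = np.linspace(0, ncols, tiles + 1).astype(int)
    centres = (edges[:-1] + edges[1:]) / 2.0 - 0.5
    bin_of = np.clip((arr * params.n_bins).astype(int), 0, params.n_bins - 1)

    x = np.arange(ncols)
    # per-pixel flanking tiles and interpolation weight
    right = np.clip(np.searchsorted(centres, x, side="left"), 0, tiles - 1)
    left = np.clip(right - 1, 0, tiles - 1)
    span = centres[right] - centres[left]
    with np.errstate(invalid="ignore", divide="ignore"):
        alpha = np.where(span > 0, (x - centres[left]) / np.where(span > 0, span, 1.0), 0.0)
    alpha = np.clip(alpha, 0.0, 1.0)

    out = np.empty_like(arr)
    for r in range(nrows):
        maps = np.stack([
            _tile_mapping(arr[r, edges[t]:edges[t + 1]], params.n_bins, params.clip_limit)
            for t in range(tiles)
        ])
        b = bin_of[r]
        out[r] = (1.0 - alpha) * maps[left, b] + alpha * maps[right, b]
    return _wrap(img, np.clip(out, 0.0, 1.0), f"clahe_rows(tiles={tiles})")


def enhance_slab(img, params: EnhanceParams | None = None) -> EnFaceSlab:
    """Full display chain: normalise, then threshold, then row-wise CLAHE."""
    params = params or EnhanceParams()
    step1 = normalize(img)
    step2 = threshold_preserve(step1, params.threshold, params.threshold_mode)
    return clahe_rows(step2, params)
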