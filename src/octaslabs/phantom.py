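"""Synthetic retinal OCT-A phantom with known layers, plexuses and flow.

No clinical volumes ship with the package, so every pipeline stage is
exercised against a generated phantom whose ground truth (junction surfaces,
per-voxel plexus labels, cyst mask) is known exactly.

The phantom emulates the features the pipeline depends on:

* layered axial reflectivity — dark vitreous, a bright NFL/GCL/IPL band, a
  darker INL, a bright OPL, a dark ONL, and a bright RPE — deformed by a
  smooth foveal pit;
* three vascular plexuses as tortuous tube-like vessels: SCP spread through
  the GCL/IPL band, ICP hugging the inner INL just below the IPL/INL
  junction, DCP in the stratum just above the OPL/ONL junction; all avoid a
  small foveal avascular zone (largest for the DCP);
* flow contrast as independent per-repeat multiplicative intensity jitter at
  vessel voxels.  Static tissue keeps a frozen speckle pattern shared across
  repeats (motionless scatterers decorrelate only where there is flow),
  plus a small additive per-repeat sensor noise identical everywhere;
* optional INL cystoid spaces (macular edema) as dark ellipsoids;
* an "early" (35-week-like) mode with dilated, tortuous superficial vessels
  and no ICP/DCP at all.

Everything is reproducible from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import AcquisitionGeometry, AcquisitionVolume
from .layer_boundaries import BoundarySet

#: vessel_labels codes
LABEL_NONE, LABEL_SCP, LABEL_ICP, LABEL_DCP = 0, 1, 2, 3
LABEL_NAMES = {LABEL_SCP: "SCP", LABEL_ICP: "ICP", LABEL_DCP: "DCP"}


@dataclass
class PhantomConfig:
    """Generation settings; defaults are a desk-scale version of the scan pattern.

    The acquisition geometry keeps the four repeats per lateral location of
    the real protocol but shrinks the raster to 64 x 128 lateral positions
    and 160 depth pixels so a full phantom generates in seconds.
    """

    n_repeats: int = 4
    n_bscans: int = 64
    n_ascans: int = 128
    depth: int = 160
    axial_pixel_depth_um: float = 4.37

    stage: str = "term"  # "term" (three-layer) or "early" (SVC only)

    foveal_pit: bool = True
    pit_depth_px: float = 16.0
    pit_sigma_frac: float = 0.12  # of each lateral extent

    edema: bool = False
    n_cysts: int = 3
    cyst_semiaxes_px: tuple[float, float, float] = (4.0, 4.5, 9.0)  # (bscan, depth, ascan)

    n_scp_vessels: int = 12
    n_icp_vessels: int = 14
    n_dcp_vessels: int = 14
    n_scp_large_vessels: int = 3  # large-caliber arterioles/venules in the SCP

    flow_amplitude: float = 0.3   # fractional per-repeat jitter at flow voxels
    speckle_sigma: float = 0.1    # frozen multiplicative speckle, fraction of intensity
    sensor_noise: float = 0.01    # additive per-repeat noise, intensity units

    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_repeats", "n_bscans", "n_ascans", "depth"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_repeats < 2:
            raise ValueError("n_repeats must be >= 2")
        if self.stage not in ("term", "early"):
            raise ValueError(f"stage must be 'term' or 'early', got {self.stage!r}")
        if self.stage == "early":
            # no secondary vasculature before it has formed
            self.n_icp_vessels = 0
            self.n_dcp_vessels = 0
        if self.flow_amplitude < 0 or self.speckle_sigma < 0 or self.sensor_noise < 0:
            raise ValueError("noise amplitudes must be nonnegative")

    @property
    def geometry(self) -> AcquisitionGeometry:
        return AcquisitionGeometry(
            n_repeats=self.n_repeats,
            n_bscans=self.n_bscans,
            n_ascans=self.n_ascans,
            axial_pixel_depth_um=self.axial_pixel_depth_um,
        )


@dataclass
class PhantomTruth:
    """Ground truth accompanying a generated phantom volume."""

    boundaries: BoundarySet
    vessel_labels: np.ndarray  # (bscan, depth, ascan) uint8, codes LABEL_*
    cyst_mask: np.ndarray      # (bscan, depth, ascan) bool
    config: PhantomConfig


# layer reflectivities (arbitrary linear units); chosen so the strongest
# bright-to-dark axial transition is the IPL/INL junction, the next the
# OPL/ONL junction, and the vitreous/ILM step is the strongest dark-to-bright
_REFLECT = {
    "vitreous": 0.02,
    "nfl_gcl_ipl": 0.65,
    "inl": 0.25,
    "opl": 0.45,
    "onl": 0.18,
    "rpe": 0.70,
    "choroid": 0.35,
}

# nominal band thicknesses in pixels (vitreous thickness = ILM position)
_ILM0 = 12.0
_GCL_IPL_TH = 34.0
_INL_TH = 12.0
_OPL_TH = 8.0
_ONL_TH = 30.0
_RPE_TH = 6.0

_VESSEL_REFLECT = {"large": 0.25, "capillary": 0.12}


def _pit_displacement(cfg: PhantomConfig) -> np.ndarray:
    """Smooth foveal depression, (bscan, ascan), in depth pixels (>= 0)."""
    if not cfg.foveal_pit:
        return np.zeros((cfg.n_bscans, cfg.n_ascans))
    yb = np.arange(cfg.n_bscans)[:, None] - (cfg.n_bscans - 1) / 2.0
    xa = np.arange(cfg.n_ascans)[None, :] - (cfg.n_ascans - 1) / 2.0
    sb = cfg.pit_sigma_frac * cfg.n_bscans
    sx = cfg.pit_sigma_frac * cfg.n_ascans
    return cfg.pit_depth_px * np.exp(-0.5 * ((yb / sb) ** 2 + (xa / sx) ** 2))


def _truth_boundaries(cfg: PhantomConfig) -> dict[str, np.ndarray]:
    """All six band boundaries; the pit deepens the inner surfaces most."""
    d = _pit_displacement(cfg)
    ilm = _ILM0 + d
    ipl_inl = _ILM0 + _GCL_IPL_TH + 0.55 * d
    inl_opl = ipl_inl + _INL_TH - 0.25 * d
    opl_onl = inl_opl + _OPL_TH - 0.05 * d
    onl_rpe = opl_onl + _ONL_TH - 0.05 * d
    rpe_end = onl_rpe + _RPE_TH
    return {
        "ILM": ilm, "IPL_INL": ipl_inl, "INL_OPL": inl_opl,
        "OPL_ONL": opl_onl, "ONL_RPE": onl_rpe, "RPE_END": rpe_end,
    }


def _layered_reflectivity(cfg: PhantomConfig, bounds: dict[str, np.ndarray]) -> np.ndarray:
    """Structural volume (bscan, depth, ascan) from the boundary stack."""
    z = np.arange(cfg.depth)[None, :, None].astype(np.float64)
    order = [
        ("vitreous", None),
        ("nfl_gcl_ipl", "ILM"),
        ("inl", "IPL_INL"),
        ("opl", "INL_OPL"),
        ("onl", "OPL_ONL"),
        ("rpe", "ONL_RPE"),
        ("choroid", "RPE_END"),
    ]
    vol = np.full((cfg.n_bscans, cfg.depth, cfg.n_ascans), _REFLECT["vitreous"])
    for name, bound in order[1:]:
        # voxel z joins the layer once z >= round-half-up(boundary)
        start = np.floor(bounds[bound] + 0.5)[:, None, :]
        vol = np.where(z >= start, _REFLECT[name], vol)
    return vol


def _vessel_paths(rng: np.random.Generator, cfg: PhantomConfig, n: int,
                  tortuosity: float) -> list[np.ndarray]:
    """Smooth tortuous lateral paths, each an (m, 2) array of (bscan, ascan)."""
    nb, nx = cfg.n_bscans, cfg.n_ascans
    diag = float(np.hypot(nb, nx))
    paths = []
    for _ in range(n):
        theta = rng.uniform(0, np.pi)
        u = np.array([np.cos(theta), np.sin(theta)])
        nvec = np.array([-u[1], u[0]])
        c = np.array([rng.uniform(0.15, 0.85) * nb, rng.uniform(0.15, 0.85) * nx])
        t = np.arange(-diag, diag, 1.0)
        wob = np.zeros_like(t)
        for _h in range(2):
            amp = tortuosity * rng.uniform(2.0, 6.0)
            lam = rng.uniform(25.0, 70.0)
            phase = rng.uniform(0, 2 * np.pi)
            wob += amp * np.sin(2 * np.pi * t / lam + phase)
        pts = c[None, :] + t[:, None] * u[None, :] + wob[:, None] * nvec[None, :]
        keep = (
            (pts[:, 0] >= 0) & (pts[:, 0] <= nb - 1)
            & (pts[:, 1] >= 0) & (pts[:, 1] <= nx - 1)
        )
        if keep.any():
            paths.append(pts[keep])
    return paths


def _stamp_vessel(weight: np.ndarray, path: np.ndarray, zc: np.ndarray,
                  radius: float, z_radius: float) -> None:
    """Accumulate (by max) a Gaussian tube into a (bscan, depth, ascan) weight map."""
    nb, nz, nx = weight.shape
    wlat = max(2, int(np.ceil(2.5 * radius)))
    wz = max(2, int(np.ceil(2.5 * z_radius)))
    for (py, px), pz in zip(path, zc):
        b0, b1 = max(0, int(py) - wlat), min(nb, int(py) + wlat + 1)
        x0, x1 = max(0, int(px) - wlat), min(nx, int(px) + wlat + 1)
        z0, z1 = max(0, int(pz) - wz), min(nz, int(pz) + wz + 1)
        if b0 >= b1 or x0 >= x1 or z0 >= z1:
            continue
        db = (np.arange(b0, b1) - py)[:, None, None]
        dz = (np.arange(z0, z1) - pz)[None, :, None]
        dx = (np.arange(x0, x1) - px)[None, None, :]
        w = np.exp(-0.5 * ((db ** 2 + dx ** 2) / radius ** 2 + dz ** 2 / z_radius ** 2))
        np.maximum(weight[b0:b1, z0:z1, x0:x1], w, out=weight[b0:b1, z0:z1, x0:x1])


def _faz_mask(path: np.ndarray, cfg: PhantomConfig, faz_radius: float) -> np.ndarray:
    cy, cx = (cfg.n_bscans - 1) / 2.0, (cfg.n_ascans - 1) / 2.0
    r = np.hypot(path[:, 0] - cy, path[:, 1] - cx)
    return r > faz_radius


def _sample_surface(surface: np.ndarray, path: np.ndarray) -> np.ndarray:
    iy = np.clip(np.round(path[:, 0]).astype(int), 0, surface.shape[0] - 1)
    ix = np.clip(np.round(path[:, 1]).astype(int), 0, surface.shape[1] - 1)
    return surface[iy, ix]


def generate_phantom(config: PhantomConfig | None = None) -> tuple[AcquisitionVolume, PhantomTruth]:
    """Generate a repeated-B-scan phantom acquisition and its ground truth.

    Returns the 4-D volume (repeat, bscan, depth, ascan) plus a
    :class:`PhantomTruth` holding the true junction surfaces, the per-voxel
    plexus label array and the cyst mask.  Deterministic for a given config.
    """
    cfg = config or PhantomConfig()
    ss = np.random.SeedSequence(cfg.seed)
    rng_vessels, rng_cysts, rng_noise = (np.random.default_rng(s) for s in ss.spawn(3))

    bounds = _truth_boundaries(cfg)
    if bounds["RPE_END"].max() >= cfg.depth:
        raise ValueError("depth too small for the layer stack; increase config.depth")
    structural = _layered_reflectivity(cfg, bounds)
    nb, nz, nx = structural.shape
    labels = np.zeros((nb, nz, nx), dtype=np.uint8)

    # --- vasculature -------------------------------------------------------
    tortuosity = 2.5 if cfg.stage == "early" else 1.0
    plexus_specs = []  # (label, n, radius, z_radius, reflect, centre_fn, faz_radius)
    gcl_gap = bounds["IPL_INL"] - bounds["ILM"]

    def scp_centre(path, frac):
        return _sample_surface(bounds["ILM"] + frac * gcl_gap, path)

    def icp_centre(path, frac):
        return _sample_surface(bounds["IPL_INL"], path) + 2.0

    def dcp_centre(path, frac):
        return _sample_surface(bounds["OPL_ONL"], path) - 4.5

    n_large = cfg.n_scp_large_vessels if cfg.stage == "term" else cfg.n_scp_vessels // 2
    large_radius = 1.8 if cfg.stage == "term" else 2.4  # dilated in the early eye
    plexus_specs.append((LABEL_SCP, n_large, large_radius, 1.3,
                         _VESSEL_REFLECT["large"], scp_centre, 8.0))
    plexus_specs.append((LABEL_SCP, max(cfg.n_scp_vessels - n_large, 0), 1.0, 1.0,
                         _VESSEL_REFLECT["capillary"], scp_centre, 8.0))
    plexus_specs.append((LABEL_ICP, cfg.n_icp_vessels, 1.0, 0.9,
                         _VESSEL_REFLECT["capillary"], icp_centre, 8.0))
    plexus_specs.append((LABEL_DCP, cfg.n_dcp_vessels, 1.0, 0.9,
                         _VESSEL_REFLECT["capillary"], dcp_centre, 12.0))

    for label, n, radius, z_radius, reflect, centre_fn, faz in plexus_specs:
        if n <= 0:
            continue
        weight = np.zeros_like(structural)
        for path in _vessel_paths(rng_vessels, cfg, n, tortuosity):
            keep = _faz_mask(path, cfg, faz)
            path = path[keep]
            if path.shape[0] == 0:
                continue
            frac = rng_vessels.uniform(0.12, 0.72)
            zc = centre_fn(path, frac)
            # gentle axial meander along the vessel
            zc = zc + 0.8 * np.sin(
                2 * np.pi * np.arange(path.shape[0]) / rng_vessels.uniform(40.0, 90.0)
                + rng_vessels.uniform(0, 2 * np.pi)
            )
            _stamp_vessel(weight, path, zc, radius, z_radius)
        structural = structural + reflect * weight
        labels[weight > 0.5] = label

    # --- cystoid spaces (macular edema) -----------------------------------
    cyst_mask = np.zeros((nb, nz, nx), dtype=bool)
    if cfg.edema and cfg.n_cysts > 0:
        inl_mid = (bounds["IPL_INL"] + bounds["INL_OPL"]) / 2.0
        sb, sz, sx = cfg.cyst_semiaxes_px
        cy, cx = (nb - 1) / 2.0, (nx - 1) / 2.0
        for _ in range(cfg.n_cysts):
            ang = rng_cysts.uniform(0, 2 * np.pi)
            rad = rng_cysts.uniform(8.0, 0.22 * min(nb, nx) + 8.0)
            by, bx = cy + rad * np.sin(ang), cx + rad * np.cos(ang) * (nx / nb)
            iy = int(np.clip(round(by), 0, nb - 1))
            ix = int(np.clip(round(bx), 0, nx - 1))
            bz = inl_mid[iy, ix]
            db = (np.arange(nb) - by)[:, None, None]
            dz = (np.arange(nz) - bz)[None, :, None]
            dx = (np.arange(nx) - bx)[None, None, :]
            inside = (db / sb) ** 2 + (dz / sz) ** 2 + (dx / sx) ** 2 <= 1.0
            cyst_mask |= inside
        structural = np.where(cyst_mask, 0.05, structural)
        labels[cyst_mask] = LABEL_NONE

    # --- repeats, flow jitter and noise ------------------------------------
    speckle = 1.0 + cfg.speckle_sigma * rng_noise.standard_normal(structural.shape)
    static = structural * np.clip(speckle, 0.0, None)

    reps = np.broadcast_to(static, (cfg.n_repeats,) + static.shape).copy()
    flow_vox = labels > 0
    if cfg.flow_amplitude > 0 and flow_vox.any():
        jitter = cfg.flow_amplitude * rng_noise.standard_normal(
            (cfg.n_repeats, int(flow_vox.sum()))
        )
        reps[:, flow_vox] = reps[:, flow_vox] * (1.0 + jitter)
    if cfg.sensor_noise > 0:
        reps = reps + cfg.sensor_noise * rng_noise.standard_normal(reps.shape)
    reps = np.clip(reps, 0.0, None)

    volume = AcquisitionVolume(
        geometry=cfg.geometry,
        intensities=reps,
        provenance={"phantom": {"stage": cfg.stage, "seed": cfg.seed}},
    )
    truth = PhantomTruth(
        boundaries=BoundarySet(
            surfaces={k: bounds[k] for k in ("ILM", "IPL_INL", "OPL_ONL")},
            geometry=cfg.geometry,
            depth_extent=cfg.depth,
        ),
        vessel_labels=labels,
        cyst_mask=cyst_mask,
        config=cfg,
    )
    return volume, truth


# ---------------------------------------------------------------------------
# slab assignment scoring
# ---------------------------------------------------------------------------

@dataclass
class SlabAssignment:
    """Confusion counts of true plexus voxels against slab intervals."""

    counts: "object"           # pandas DataFrame: rows = plexus, cols = slabs + unassigned
    recall: dict[str, float]   # plexus -> fraction inside its namesake slab


def evaluate_slab_assignment(truth: PhantomTruth, slab_surfaces: list) -> SlabAssignment:
    """Score how well a resolved scheme captures the true plexus voxels.

    For every labelled flow voxel, records which slab's rounded depth
    interval contains it (or ``unassigned`` if none).  Recall for a plexus is
    only defined when a slab with the same name exists in the scheme.
    """
    labels = truth.vessel_labels
    nb, nz, nx = labels.shape
    slab_names = [s.name for s in slab_surfaces]
    plexuses = [LABEL_NAMES[c] for c in sorted(LABEL_NAMES) if (labels == c).any()]
    counts = pd.DataFrame(0, index=plexuses, columns=slab_names + ["unassigned"], dtype=int)
    if not plexuses:
        return SlabAssignment(counts=counts, recall={})

    zidx = np.arange(nz)[None, :, None]
    assigned = np.zeros((nb, nz, nx), dtype=bool)
    for s in slab_surfaces:
        z0, z1 = s.depth_index_range(nz)
        member = (zidx >= z0[:, None, :]) & (zidx < z1[:, None, :]) & ~assigned
        assigned |= member
        for code, name in LABEL_NAMES.items():
            if name in plexuses:
                counts.loc[name, s.name] = int((member & (labels == code)).sum())
    for code, name in LABEL_NAMES.items():
        if name in plexuses:
            total = int((labels == code).sum())
            counts.loc[name, "unassigned"] = total - int(counts.loc[name, slab_names].sum())
    recall = {
        p: float(counts.loc[p, p]) / float(counts.loc[p].sum())
        for p in plexuses
        if p in slab_names and counts.loc[p].sum() > 0
    }
    return SlabAssignment(counts=counts, recall=recall)
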