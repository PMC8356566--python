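"""Anatomically referenced slab schemes, en face projection, offset sweeps.

A slab boundary is a named junction plus a signed pixel offset: negative
offsets move the boundary toward the vitreous ("above" the junction, since
depth index 0 is the vitreous side), positive offsets move it toward the
choroid ("below").  Offsets are specified in pixels; at the device's axial
sampling of 4.37 µm/pixel, one pixel of offset is 4.37 µm.

Two schemes are provided as defaults:

* *term* (three-layer, for eyes with a formed secondary vasculature):
  SCP from the ILM to 2 px (8.74 µm) above the IPL/INL junction; ICP from
  there to 8 px (34.96 µm) above the OPL/ONL junction; DCP from there to the
  OPL/ONL junction.
* *early* (two-layer, before secondary vasculature is detectable):
  SVC from the ILM to the IPL/INL junction; DVC from the IPL/INL junction
  to the OPL/ONL junction.

Slab intervals are half-open ``[upper, lower)`` after rounding fractional
boundary positions half-up, except the deepest slab of a scheme whose outer
boundary is inclusive — so the scheme exactly partitions the ILM→OPL/ONL
band.  Columns where the upper surface is at or below the lower one (e.g.
inside a thin foveal pit) are empty, not inverted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .angiography import FlowVolume
from .geometry import DEFAULT_AXIAL_PIXEL_DEPTH_UM, round_half_up
from .layer_boundaries import JUNCTIONS, BoundarySet

logger = logging.getLogger(__name__)


def offset_um_to_px(offset_um: float, axial_pixel_depth_um: float = DEFAULT_AXIAL_PIXEL_DEPTH_UM) -> int:
    """Convert a physical slab offset in µm to a signed whole-pixel count.

    Offsets are tested in whole-pixel increments, so the µm value must be an
    integer multiple of the pixel depth; a residual above 0.01 px indicates a
    unit mismatch and raises.
    """
    if not axial_pixel_depth_um > 0:
        raise ValueError("axial_pixel_depth_um must be positive")
    px_f = offset_um / axial_pixel_depth_um
    px = int(np.floor(px_f + 0.5))
    if abs(px_f - px) > 0.01:
        raise ValueError(
            f"offset {offset_um} µm is not a whole number of {axial_pixel_depth_um} µm "
            f"pixels (residual {abs(px_f - px):.4f} px); check units"
        )
    return px


@dataclass(frozen=True)
class SlabBoundary:
    """One slab boundary: a reference junction plus a signed pixel offset."""

    reference: str
    offset_px: int

    def __post_init__(self) -> None:
        if self.reference not in JUNCTIONS:
            raise ValueError(f"unknown reference junction {self.reference!r}")

    def offset_um(self, axial_pixel_depth_um: float = DEFAULT_AXIAL_PIXEL_DEPTH_UM) -> float:
        return self.offset_px * axial_pixel_depth_um

    def label(self) -> str:
        return f"{self.reference}{self.offset_px:+d}px"


@dataclass(frozen=True)
class Slab:
    name: str
    upper: SlabBoundary
    lower: SlabBoundary


@dataclass(frozen=True)
class SlabScheme:
    """An ordered, contiguous list of named slabs spanning ILM to OPL/ONL."""

    name: str
    slabs: tuple[Slab, ...]

    def __post_init__(self) -> None:
        if not self.slabs:
            raise ValueError("scheme must contain at least one slab")
        for a, b in zip(self.slabs[:-1], self.slabs[1:]):
            if a.lower != b.upper:
                raise ValueError(
                    f"scheme not contiguous: {a.name}.lower={a.lower} != {b.name}.upper={b.upper}"
                )
        first, last = self.slabs[0], self.slabs[-1]
        if first.upper != SlabBoundary("ILM", 0):
            raise ValueError("outermost upper boundary must be ILM+0")
        if last.lower != SlabBoundary("OPL_ONL", 0):
            raise ValueError("outermost lower boundary must be OPL_ONL+0")

    @property
    def slab_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.slabs)

    def __iter__(self):
        return iter(self.slabs)


def make_term_scheme(
    scp_icp_above_ipl_px: int = 2, icp_dcp_above_opl_px: int = 8
) -> SlabScheme:
    """Three-layer scheme for term-equivalent eyes (formed secondary vasculature).

    Defaults place the SCP/ICP boundary 8.74 µm (2 px) above the IPL/INL
    junction and the ICP/DCP boundary 34.96 µm (8 px) above the OPL/ONL
    junction.  The OPL/ONL junction is used as the ICP/DCP reference (rather
    than the IPL/INL junction) so that anomalous microvasculature inside INL
    cystoid spaces is assigned to the ICP, which it appears continuous with.
    """
    scp_icp = SlabBoundary("IPL_INL", -abs(scp_icp_above_ipl_px))
    icp_dcp = SlabBoundary("OPL_ONL", -abs(icp_dcp_above_opl_px))
    return SlabScheme(
        name="term",
        slabs=(
            Slab("SCP", SlabBoundary("ILM", 0), scp_icp),
            Slab("ICP", scp_icp, icp_dcp),
            Slab("DCP", icp_dcp, SlabBoundary("OPL_ONL", 0)),
        ),
    )


def make_early_scheme() -> SlabScheme:
    """Two-layer scheme for eyes without detectable secondary vasculature.

    The superficial vascular complex (SVC) runs from the ILM to the IPL/INL
    junction; the deep vascular complex (DVC) from there to the OPL/ONL
    junction.
    """
    svc_dvc = SlabBoundary("IPL_INL", 0)
    return SlabScheme(
        name="early",
        slabs=(
            Slab("SVC", SlabBoundary("ILM", 0), svc_dvc),
            Slab("DVC", svc_dvc, SlabBoundary("OPL_ONL", 0)),
        ),
    )


@dataclass
class SlabSurfaces:
    """Resolved depth surfaces for one slab of a scheme."""

    name: str
    upper: np.ndarray  # fractional px, (bscan, ascan)
    lower: np.ndarray
    inclusive_lower: bool
    upper_boundary: SlabBoundary
    lower_boundary: SlabBoundary

    @property
    def empty_fraction(self) -> float:
        return float(np.mean(self.upper >= self.lower + (1 if self.inclusive_lower else 0)))

    def depth_index_range(self, depth_extent: int) -> tuple[np.ndarray, np.ndarray]:
        """Integer half-open [z0, z1) voxel ranges per column, clipped to volume."""
        z0 = round_half_up(self.upper)
        z1 = round_half_up(self.lower) + (1 if self.inclusive_lower else 0)
        z0 = np.clip(z0, 0, depth_extent)
        z1 = np.clip(z1, 0, depth_extent)
        return z0, z1


def resolve_surfaces(scheme: SlabScheme, boundaries: BoundarySet) -> list[SlabSurfaces]:
    """Turn a scheme's junction+offset boundaries into per-slab depth surfaces.

    The deepest slab is marked inclusive of its outer boundary.  Columns with
    ``upper >= lower`` are left as-is (they become empty during projection);
    the empty fraction per slab is logged.
    """
    out: list[SlabSurfaces] = []
    for i, slab in enumerate(scheme.slabs):
        upper = boundaries[slab.upper.reference] + slab.upper.offset_px
        lower = boundaries[slab.lower.reference] + slab.lower.offset_px
        ss = SlabSurfaces(
            name=slab.name,
            upper=upper,
            lower=lower,
            inclusive_lower=(i == len(scheme.slabs) - 1),
            upper_boundary=slab.upper,
            lower_boundary=slab.lower,
        )
        if ss.empty_fraction > 0:
            logger.info("slab %s empty at %.1f%% of columns", slab.name,
                        100 * ss.empty_fraction)
        out.append(ss)
    return out


@dataclass
class EnFaceSlab:
    """A 2-D depth-projected slab image, (bscan, ascan)."""

    image: np.ndarray
    name: str = ""
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = np.asarray(self.image, dtype=np.float64)
        if arr.ndim != 2:
            raise ValueError(f"en face image must be 2-D, got ndim={arr.ndim}")
        self.image = arr


PROJECTIONS = ("max", "mean", "sum")


def project_slab(
    flow: FlowVolume,
    surfaces: SlabSurfaces,
    projection: str = "max",
) -> EnFaceSlab:
    """Project the flow volume between two depth surfaces onto the lateral plane.

    Per (bscan, ascan) column, the depth samples in the slab's rounded
    half-open interval are reduced with ``max`` (default — the prevailing
    convention for en face capillary rendering), ``mean`` or ``sum``.
    Empty columns project to 0.
    """
    if projection not in PROJECTIONS:
        raise ValueError(f"projection must be one of {PROJECTIONS}, got {projection!r}")
    vol = flow.flow  # (bscan, depth, ascan)
    nb, nz, nx = vol.shape
    z0, z1 = surfaces.depth_index_range(nz)
    zidx = np.arange(nz)[None, :, None]
    member = (zidx >= z0[:, None, :]) & (zidx < z1[:, None, :])
    count = member.sum(axis=1)
    if projection == "max":
        img = np.where(member, vol, -np.inf).max(axis=1)
        img = np.where(count > 0, img, 0.0)
    else:
        total = np.where(member, vol, 0.0).sum(axis=1)
        if projection == "sum":
            img = total
        else:
            img = np.divide(total, count, out=np.zeros_like(total), where=count > 0)
    return EnFaceSlab(
        image=img,
        name=surfaces.name,
        provenance={
            "projection": projection,
            "upper": surfaces.upper_boundary.label(),
            "lower": surfaces.lower_boundary.label(),
            "inclusive_lower": surfaces.inclusive_lower,
            "empty_fraction": surfaces.empty_fraction,
        },
    )


def project_scheme(
    flow: FlowVolume, boundaries: BoundarySet, scheme: SlabScheme, projection: str = "max"
) -> dict[str, EnFaceSlab]:
    """Resolve a scheme and project every slab; returns name -> EnFaceSlab."""
    return {
        ss.name: project_slab(flow, ss, projection)
        for ss in resolve_surfaces(scheme, boundaries)
    }


# ---------------------------------------------------------------------------
# offset sweep / collage
# ---------------------------------------------------------------------------

#: Published sweep grid: SCP/ICP boundary 0..4 px above IPL/INL; ICP/DCP
#: boundary either 1..5 px below IPL/INL or 5..10 px above OPL/ONL.
DEFAULT_SCIP_RANGE_PX = tuple(range(0, 5))
DEFAULT_ICPDCP_SPECS = (
    ("IPL_INL", tuple(range(1, 6))),   # px below the IPL/INL junction
    ("OPL_ONL", tuple(range(5, 11))),  # px above the OPL/ONL junction
)


@dataclass
class SweepCell:
    slab: EnFaceSlab
    scip_above_ipl_px: int
    icp_dcp_reference: str
    icp_dcp_offset_px: int

    @property
    def label(self) -> str:
        ref = "IPL/INL" if self.icp_dcp_reference == "IPL_INL" else "OPL/ONL"
        sign = "below" if self.icp_dcp_reference == "IPL_INL" else "above"
        return (
            f"SCP/ICP +{self.scip_above_ipl_px}px | "
            f"ICP/DCP {abs(self.icp_dcp_offset_px)}px {sign} {ref}"
        )


def sweep_offsets(
    flow: FlowVolume,
    boundaries: BoundarySet,
    scip_range_px=DEFAULT_SCIP_RANGE_PX,
    icp_dcp_specs=DEFAULT_ICPDCP_SPECS,
    target: str = "ICP",
    projection: str = "max",
) -> list[list[SweepCell]]:
    """Project the target slab for every offset combination in the grid.

    Rows index the SCP/ICP offset (px above IPL/INL), columns the flattened
    ICP/DCP specifications ``(reference junction, px magnitude)``.  With the
    default published ranges, the ICP grid has 5 x (5 + 6) = 55 cells.
    """
    if not scip_range_px or not any(r for _, r in icp_dcp_specs):
        raise ValueError("sweep ranges must be nonempty")
    cols: list[tuple[str, int]] = [
        (ref, off) for ref, offs in icp_dcp_specs for off in offs
    ]
    grid: list[list[SweepCell]] = []
    for scip in scip_range_px:
        row = []
        for ref, off in cols:
            # "above" = toward the vitreous = negative offset; the IPL/INL
            # specs are "px below", which is a positive offset.
            icp_dcp_px = off if ref == "IPL_INL" else -off
            scp_icp = SlabBoundary("IPL_INL", -abs(scip))
            icp_dcp = SlabBoundary(ref, icp_dcp_px)
            scheme = SlabScheme(
                name=f"sweep_{scip}_{ref}_{off}",
                slabs=(
                    Slab("SCP", SlabBoundary("ILM", 0), scp_icp),
                    Slab("ICP", scp_icp, icp_dcp),
                    Slab("DCP", icp_dcp, SlabBoundary("OPL_ONL", 0)),
                ),
            )
            surfaces = {s.name: s for s in resolve_surfaces(scheme, boundaries)}
            cell = SweepCell(
                slab=project_slab(flow, surfaces[target], projection),
                scip_above_ipl_px=scip,
                icp_dcp_reference=ref,
                icp_dcp_offset_px=icp_dcp_px,
            )
            row.append(cell)
        grid.append(row)
    return grid


def montage(grid: list[list[SweepCell]], pad_px: int = 2, normalize_cells: bool = True) -> np.ndarray:
    """Tile a sweep grid into one grayscale collage image in [0, 1].

    Cells are separated by a white border of ``pad_px`` pixels; each cell is
    min-max normalised independently by default so dim parameter choices
    remain visible side by side.
    """
    nrow, ncol = len(grid), len(grid[0])
    h, w = grid[0][0].slab.image.shape
    out = np.ones((nrow * (h + pad_px) + pad_px, ncol * (w + pad_px) + pad_px))
    for i, row in enumerate(grid):
        for j, cell in enumerate(row):
            img = cell.slab.image
            if normalize_cells:
                rng = img.max() - img.min()
                img = (img - img.min()) / rng if rng > 0 else np.zeros_like(img)
            else:
                img = np.clip(img, 0.0, 1.0)
            y0 = pad_px + i * (h + pad_px)
            x0 = pad_px + j * (w + pad_px)
            out[y0:y0 + h, x0:x0 + w] = img
    return out
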