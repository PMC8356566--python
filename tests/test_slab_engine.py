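"""Slab schemes, offset arithmetic, en face projection and the offset sweep."""

import numpy as np
import pytest

from octaslabs import (
    make_early_scheme,
    make_term_scheme,
    offset_um_to_px,
    project_slab,
    project_scheme,
    resolve_surfaces,
    speckle_variance,
    sweep_offsets,
)
from octaslabs.geometry import AcquisitionGeometry, round_half_up
from octaslabs.layer_boundaries import BoundarySet
from octaslabs.angiography import FlowVolume
from octaslabs.slab_engine import (
    DEFAULT_ICPDCP_SPECS,
    DEFAULT_SCIP_RANGE_PX,
    SlabBoundary,
    montage,
)


def random_flow(rng, nb=5, nz=24, nx=7) -> FlowVolume:
    geometry = AcquisitionGeometry(2, nb, nx)
    return FlowVolume(geometry=geometry, flow=rng.random((nb, nz, nx)))


def random_bounds(rng, nb=5, nx=7, nz=24) -> BoundarySet:
    ilm = rng.uniform(1, 4, (nb, nx))
    ipl = ilm + rng.uniform(4, 8, (nb, nx))
    opl = ipl + rng.uniform(4, 8, (nb, nx))
    return BoundarySet(surfaces={"ILM": ilm, "IPL_INL": ipl, "OPL_ONL": opl},
                       depth_extent=nz)


def brute_force_project(flow, upper, lower, inclusive, projection):
    """Per-column voxel classification loop (independent oracle)."""
    nb, nz, nx = flow.shape
    out = np.zeros((nb, nx))
    for b in range(nb):
        for x in range(nx):
            z0 = int(np.floor(upper[b, x] + 0.5))
            z1 = int(np.floor(lower[b, x] + 0.5)) + (1 if inclusive else 0)
            vals = [flow[b, z, x] for z in range(max(z0, 0), min(z1, nz))]
            if not vals:
                out[b, x] = 0.0
            elif projection == "max":
                out[b, x] = max(vals)
            elif projection == "sum":
                out[b, x] = sum(vals)
            else:
                out[b, x] = sum(vals) / len(vals)
    return out


class TestOffsetArithmetic:
    @pytest.mark.parametrize("um,px", [
        (17.48, 4), (8.74, 2), (21.85, 5), (34.96, 8), (43.7, 10), (0.0, 0),
        (-34.96, -8),
    ])
    def test_published_um_px_pairs(self, um, px):
        assert offset_um_to_px(um, 4.37) == px

    def test_unit_mismatch_rejected(self):
        with pytest.raises(ValueError, match="units"):
            offset_um_to_px(10.0, 4.37)  # 2.29 px: not a whole-pixel offset

    def test_boundary_offset_um_consistency(self):
        b = SlabBoundary("OPL_ONL", -8)
        assert abs(b.offset_um() - (-34.96)) < 0.005


class TestSchemes:
    def test_term_scheme_matches_recommended_parameters(self):
        scheme = make_term_scheme()
        assert scheme.slab_names == ("SCP", "ICP", "DCP")
        scp, icp, dcp = scheme.slabs
        assert scp.upper == SlabBoundary("ILM", 0)
        assert scp.lower == SlabBoundary("IPL_INL", -2)      # 8.74 µm above IPL/INL
        assert icp.lower == SlabBoundary("OPL_ONL", -8)      # 34.96 µm above OPL/ONL
        assert dcp.lower == SlabBoundary("OPL_ONL", 0)
        assert scp.lower.offset_um() == pytest.approx(-8.74)
        assert icp.lower.offset_um() == pytest.approx(-34.96)

    def test_term_scheme_contiguity(self):
        scheme = make_term_scheme()
        for a, b in zip(scheme.slabs[:-1], scheme.slabs[1:]):
            assert a.lower == b.upper

    def test_early_scheme_two_layers_at_ipl_inl(self):
        scheme = make_early_scheme()
        assert scheme.slab_names == ("SVC", "DVC")
        svc, dvc = scheme.slabs
        assert svc.lower == SlabBoundary("IPL_INL", 0)
        assert svc.upper == SlabBoundary("ILM", 0)
        assert dvc.lower == SlabBoundary("OPL_ONL", 0)

    def test_non_contiguous_scheme_rejected(self):
        from octaslabs.slab_engine import Slab, SlabScheme

        with pytest.raises(ValueError, match="contiguous"):
            SlabScheme(name="bad", slabs=(
                Slab("A", SlabBoundary("ILM", 0), SlabBoundary("IPL_INL", -2)),
                Slab("B", SlabBoundary("IPL_INL", 0), SlabBoundary("OPL_ONL", 0)),
            ))


class TestResolveSurfaces:
    def test_zero_offsets_equal_junctions(self):
        rng = np.random.default_rng(0)
        bounds = random_bounds(rng)
        surfaces = resolve_surfaces(make_early_scheme(), bounds)
        np.testing.assert_array_equal(surfaces[0].upper, bounds["ILM"])
        np.testing.assert_array_equal(surfaces[0].lower, bounds["IPL_INL"])
        np.testing.assert_array_equal(surfaces[1].lower, bounds["OPL_ONL"])

    def test_thin_retina_gives_locally_empty_icp(self):
        # IPL/INL to OPL/ONL gap of 6 px: the term ICP interval
        # [IPL-2, OPL-8) = [IPL-2, IPL-2) is empty there
        nb, nx = 2, 4
        bounds = BoundarySet(surfaces={
            "ILM": np.full((nb, nx), 2.0),
            "IPL_INL": np.full((nb, nx), 10.0),
            "OPL_ONL": np.full((nb, nx), 16.0),
        })
        surfaces = {s.name: s for s in resolve_surfaces(make_term_scheme(), bounds)}
        assert surfaces["ICP"].empty_fraction == 1.0
        geometry = AcquisitionGeometry(2, nb, nx)
        flow = FlowVolume(geometry=geometry, flow=np.ones((nb, 24, nx)))
        img = project_slab(flow, surfaces["ICP"], "max").image
        assert np.all(img == 0)

    def test_flat_junctions_give_constant_surfaces(self):
        nb, nx = 3, 5
        bounds = BoundarySet(surfaces={
            "ILM": np.full((nb, nx), 4.0),
            "IPL_INL": np.full((nb, nx), 12.0),
            "OPL_ONL": np.full((nb, nx), 20.0),
        })
        for s in resolve_surfaces(make_term_scheme(), bounds):
            assert np.ptp(s.upper) == 0 and np.ptp(s.lower) == 0


class TestProjection:
    def test_constant_flow_max_projection(self):
        rng = np.random.default_rng(1)
        bounds = random_bounds(rng)
        geometry = AcquisitionGeometry(2, 5, 7)
        flow = FlowVolume(geometry=geometry, flow=np.full((5, 24, 7), 0.7))
        for s in resolve_surfaces(make_early_scheme(), bounds):
            img = project_slab(flow, s, "max").image
            assert np.all(img == pytest.approx(0.7))

    def test_single_bright_voxel_delta(self):
        nb, nz, nx = 4, 20, 6
        bounds = BoundarySet(surfaces={
            "ILM": np.full((nb, nx), 2.0),
            "IPL_INL": np.full((nb, nx), 10.0),
            "OPL_ONL": np.full((nb, nx), 16.0),
        })
        flow_arr = np.zeros((nb, nz, nx))
        flow_arr[2, 5, 3] = 9.0  # inside the SVC interval [2, 10)
        flow = FlowVolume(geometry=AcquisitionGeometry(2, nb, nx), flow=flow_arr)
        svc = resolve_surfaces(make_early_scheme(), bounds)[0]
        img = project_slab(flow, svc, "max").image
        assert img[2, 3] == 9.0
        assert img.sum() == 9.0

    @pytest.mark.parametrize("projection", ["max", "mean", "sum"])
    @pytest.mark.parametrize("seed", range(7))
    def test_matches_brute_force_oracle(self, projection, seed):
        rng = np.random.default_rng(seed)
        flow = random_flow(rng)
        bounds = random_bounds(rng)
        for s in resolve_surfaces(make_term_scheme(), bounds):
            expected = brute_force_project(
                flow.flow, s.upper, s.lower, s.inclusive_lower, projection
            )
            got = project_slab(flow, s, projection).image
            np.testing.assert_allclose(got, expected, atol=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_conservation_zero_offset_partition(self, seed):
        """Sum projections of a zero-offset scheme partition the full band."""
        rng = np.random.default_rng(100 + seed)
        flow = random_flow(rng)
        bounds = random_bounds(rng)
        slabs = project_scheme(flow, bounds, make_early_scheme(), "sum")
        total = sum(s.image for s in slabs.values())
        # reference: single band ILM -> OPL/ONL inclusive
        z0 = round_half_up(bounds["ILM"])
        z1 = round_half_up(bounds["OPL_ONL"]) + 1
        nb, nz, nx = flow.flow.shape
        expected = np.zeros((nb, nx))
        for b in range(nb):
            for x in range(nx):
                expected[b, x] = flow.flow[b, z0[b, x]:z1[b, x], x].sum()
        np.testing.assert_allclose(total, expected, atol=1e-10)

    def test_icp_thickness_monotone_in_scip_offset(self):
        rng = np.random.default_rng(8)
        bounds = random_bounds(rng)
        from octaslabs.slab_engine import make_term_scheme as term

        prev = None
        for above in range(0, 5):
            scheme = term(scp_icp_above_ipl_px=above)
            icp = [s for s in resolve_surfaces(scheme, bounds) if s.name == "ICP"][0]
            thickness = np.maximum(icp.lower - icp.upper, 0.0)
            if prev is not None:
                assert np.all(thickness >= prev - 1e-12)
            prev = thickness


class TestSweep:
    def test_default_ranges_give_55_cells(self, term_flow, term_bounds):
        grid = sweep_offsets(term_flow, term_bounds)
        assert len(grid) == len(DEFAULT_SCIP_RANGE_PX) == 5
        ncols = sum(len(r) for _, r in DEFAULT_ICPDCP_SPECS)
        assert all(len(row) == ncols == 11 for row in grid)
        assert sum(len(row) for row in grid) == 55

    def test_single_cell_equals_direct_projection(self, term_flow, term_bounds):
        grid = sweep_offsets(
            term_flow, term_bounds,
            scip_range_px=(2,), icp_dcp_specs=(("OPL_ONL", (8,)),),
        )
        assert len(grid) == 1 and len(grid[0]) == 1
        cell = grid[0][0]
        surfaces = {s.name: s for s in resolve_surfaces(make_term_scheme(), term_bounds)}
        direct = project_slab(term_flow, surfaces["ICP"], "max")
        np.testing.assert_array_equal(cell.slab.image, direct.image)
        assert "ICP/DCP 8px above OPL/ONL" in cell.label

    def test_swapping_scip_order_permutes_rows(self, term_flow, term_bounds):
        fwd = sweep_offsets(term_flow, term_bounds, scip_range_px=(0, 2),
                            icp_dcp_specs=(("OPL_ONL", (8,)),))
        rev = sweep_offsets(term_flow, term_bounds, scip_range_px=(2, 0),
                            icp_dcp_specs=(("OPL_ONL", (8,)),))
        np.testing.assert_array_equal(fwd[0][0].slab.image, rev[1][0].slab.image)
        np.testing.assert_array_equal(fwd[1][0].slab.image, rev[0][0].slab.image)

    def test_empty_range_rejected(self, term_flow, term_bounds):
        with pytest.raises(ValueError):
            sweep_offsets(term_flow, term_bounds, scip_range_px=())

    def test_montage_tiles_all_cells(self, term_flow, term_bounds):
        grid = sweep_offsets(term_flow, term_bounds, scip_range_px=(0, 1),
                             icp_dcp_specs=(("OPL_ONL", (7, 8)),))
        h, w = grid[0][0].slab.image.shape
        img = montage(grid, pad_px=2)
        assert img.shape == (2 * (h + 2) + 2, 2 * (w + 2) + 2)
        assert img.min() >= 0 and img.max() <= 1
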