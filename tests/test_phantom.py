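"""Phantom generator: determinism, flow statistics, truth geometry, scoring."""

import numpy as np
import pytest
from scipy import stats

from octaslabs import (
    PhantomConfig,
    evaluate_slab_assignment,
    generate_phantom,
    make_early_scheme,
    make_term_scheme,
    resolve_surfaces,
    speckle_variance,
)
from octaslabs.phantom import LABEL_DCP, LABEL_ICP, LABEL_SCP, PhantomTruth


def test_fixed_seed_is_reproducible():
    a_vol, a_truth = generate_phantom(PhantomConfig(seed=42))
    b_vol, b_truth = generate_phantom(PhantomConfig(seed=42))
    np.testing.assert_array_equal(a_vol.intensities, b_vol.intensities)
    np.testing.assert_array_equal(a_truth.vessel_labels, b_truth.vessel_labels)
    for j in a_truth.boundaries.surfaces:
        np.testing.assert_array_equal(a_truth.boundaries[j], b_truth.boundaries[j])


def test_different_seeds_differ():
    a, _ = generate_phantom(PhantomConfig(seed=1, n_bscans=8, n_ascans=32))
    b, _ = generate_phantom(PhantomConfig(seed=2, n_bscans=8, n_ascans=32))
    assert not np.array_equal(a.intensities, b.intensities)


def test_early_stage_has_no_secondary_plexuses(early_phantom):
    _, truth = early_phantom
    assert not np.any(truth.vessel_labels == LABEL_ICP)
    assert not np.any(truth.vessel_labels == LABEL_DCP)
    assert np.any(truth.vessel_labels == LABEL_SCP)


def test_truth_strata_lie_in_their_anatomical_bands(term_phantom):
    _, truth = term_phantom
    labels = truth.vessel_labels
    nb, nz, nx = labels.shape
    zidx = np.broadcast_to(np.arange(nz)[None, :, None], labels.shape)
    ilm = truth.boundaries["ILM"][:, None, :]
    ipl = truth.boundaries["IPL_INL"][:, None, :]
    opl = truth.boundaries["OPL_ONL"][:, None, :]
    scp = labels == LABEL_SCP
    assert np.all(zidx[scp] >= (ilm - 0.5 + np.zeros_like(zidx))[scp])
    assert np.all(zidx[scp] < np.broadcast_to(ipl, labels.shape)[scp])
    icp = labels == LABEL_ICP
    assert np.all(np.abs(zidx[icp] - (np.broadcast_to(ipl, labels.shape)[icp] + 2)) <= 2.5)
    dcp = labels == LABEL_DCP
    assert np.all(np.abs(zidx[dcp] - (np.broadcast_to(opl, labels.shape)[dcp] - 4.5)) <= 3.0)


def test_zero_flow_amplitude_equalises_variance_distributions():
    """Without flow jitter, vessel and tissue voxels share one noise model."""
    cfg = PhantomConfig(seed=11, flow_amplitude=0.0)
    volume, truth = generate_phantom(cfg)
    flow = speckle_variance(volume).flow
    labels = truth.vessel_labels
    nz = volume.depth
    zidx = np.broadcast_to(np.arange(nz)[None, :, None], labels.shape)
    in_tissue = (
        (zidx >= truth.boundaries["ILM"][:, None, :] + 1)
        & (zidx < truth.boundaries["OPL_ONL"][:, None, :] - 1)
    )
    vessel = flow[(labels > 0)]
    background = flow[(labels == 0) & in_tissue]
    rng = np.random.default_rng(0)
    n = 10_000
    vessel_s = rng.choice(vessel, n, replace=False)
    background_s = rng.choice(background, n, replace=False)
    assert stats.ks_2samp(vessel_s, background_s).pvalue > 0.01


def test_vessel_variance_dominates_background(term_phantom):
    volume, truth = term_phantom
    flow = speckle_variance(volume).flow
    labels = truth.vessel_labels
    vessel = flow[labels > 0]
    background = flow[labels == 0]
    assert vessel.size >= 10_000
    assert np.median(vessel) > np.quantile(background, 0.99)


def test_edema_adds_dark_inl_cysts():
    cfg = PhantomConfig(seed=13, edema=True)
    volume, truth = generate_phantom(cfg)
    assert truth.cyst_mask.any()
    mean = volume.mean_structural()
    assert mean[truth.cyst_mask].mean() < 0.1
    # cysts live between the IPL/INL and OPL/ONL junctions
    nz = volume.depth
    zidx = np.broadcast_to(np.arange(nz)[None, :, None], truth.cyst_mask.shape)
    ipl = np.broadcast_to(truth.boundaries["IPL_INL"][:, None, :], truth.cyst_mask.shape)
    opl = np.broadcast_to(truth.boundaries["OPL_ONL"][:, None, :], truth.cyst_mask.shape)
    inside = truth.cyst_mask
    assert np.all(zidx[inside] >= ipl[inside] - 1)
    assert np.all(zidx[inside] <= opl[inside] + 1)


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        PhantomConfig(n_repeats=1)
    with pytest.raises(ValueError):
        PhantomConfig(stage="adult")
    with pytest.raises(ValueError):
        PhantomConfig(flow_amplitude=-0.1)


class TestEvaluateSlabAssignment:
    @staticmethod
    def _aligned_truth(nb=4, nx=8, nz=40):
        from octaslabs.layer_boundaries import BoundarySet

        bounds = BoundarySet(surfaces={
            "ILM": np.full((nb, nx), 4.0),
            "IPL_INL": np.full((nb, nx), 18.0),
            "OPL_ONL": np.full((nb, nx), 32.0),
        }, depth_extent=nz)
        labels = np.zeros((nb, nz, nx), dtype=np.uint8)
        labels[:, 8, :] = LABEL_SCP    # inside [4, 16)
        labels[:, 20, :] = LABEL_ICP   # inside [16, 24)
        labels[:, 28, :] = LABEL_DCP   # inside [24, 33)
        return PhantomTruth(boundaries=bounds, vessel_labels=labels,
                            cyst_mask=np.zeros_like(labels, bool), config=None)

    def test_exactly_aligned_strata_give_full_recall(self):
        truth = self._aligned_truth()
        surfaces = resolve_surfaces(make_term_scheme(), truth.boundaries)
        result = evaluate_slab_assignment(truth, surfaces)
        assert result.recall == {"SCP": 1.0, "ICP": 1.0, "DCP": 1.0}

    def test_shifted_dcp_lands_in_interval_below(self):
        truth = self._aligned_truth()
        labels = truth.vessel_labels.copy()
        labels[labels == LABEL_DCP] = 0
        labels[:, 34, :] = LABEL_DCP  # 4 px deeper than the scheme expects: below OPL/ONL+0
        shifted = PhantomTruth(boundaries=truth.boundaries, vessel_labels=labels,
                               cyst_mask=truth.cyst_mask, config=None)
        result = evaluate_slab_assignment(
            shifted, resolve_surfaces(make_term_scheme(), truth.boundaries)
        )
        assert result.recall["DCP"] == 0.0
        assert result.counts.loc["DCP", "unassigned"] == int((labels == LABEL_DCP).sum())

    def test_empty_truth_gives_empty_table(self):
        truth = self._aligned_truth()
        empty = PhantomTruth(boundaries=truth.boundaries,
                             vessel_labels=np.zeros_like(truth.vessel_labels),
                             cyst_mask=truth.cyst_mask, config=None)
        result = evaluate_slab_assignment(
            empty, resolve_surfaces(make_term_scheme(), truth.boundaries)
        )
        assert result.counts.empty
        assert result.recall == {}

    def test_early_scheme_on_early_phantom(self, early_phantom):
        _, truth = early_phantom
        surfaces = resolve_surfaces(make_early_scheme(), truth.boundaries)
        result = evaluate_slab_assignment(truth, surfaces)
        assert set(result.counts.index) == {"SCP"}  # only superficial voxels exist
        # all superficial voxels fall in the SVC interval
        assert result.counts.loc["SCP", "SVC"] == result.counts.loc["SCP"].sum()


def test_end_to_end_term_recall(term_phantom, term_bounds):
    """Generated flow + segmented boundaries + term scheme recovers each plexus."""
    _, truth = term_phantom
    surfaces = resolve_surfaces(make_term_scheme(), term_bounds)
    result = evaluate_slab_assignment(truth, surfaces)
    for plexus in ("SCP", "ICP", "DCP"):
        assert result.recall[plexus] >= 0.9, result.counts
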