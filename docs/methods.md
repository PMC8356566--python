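# Methods

This note records the models, conventions and numerical choices behind
`octaslabs`, and what the synthetic phantom does and does not establish
about real infant OCT-A data.

## Coordinate model

All volumes are canonicalised to `(repeat, bscan, depth, ascan)`. Depth
index 0 is the vitreous side and increases toward the choroid, so "N pixels
above a junction" always means *subtracting* N from its depth position and
"below" means adding. Coordinates are 0-based; boundary positions are
fractional pixels. The axial sampling defaults to 4.37 µm/pixel, the value
for the handheld swept-source device the pipeline targets, so one pixel of
slab offset is 4.37 µm; `offset_um_to_px` refuses conversions whose residual
exceeds 0.01 px as a guard against µm/px unit mix-ups.

## Flow model

Flow contrast is the population (divide-by-N) temporal variance of intensity
over the repeats. The N repeats are the complete set of observations at a
voxel, and N versus N−1 only rescales the volume globally; the choice is
recorded in the flow volume's provenance. Variance is computed on intensity
as stored — log-compressed data must be linearised by the caller. Repeat
registration is integer-pixel, axial-only rigid shift per (repeat, B-scan)
pair, maximising plain cross-correlation against the first repeat with ties
broken toward zero shift; full 2-D/3-D motion correction is out of scope.
`mask_low_signal` zeroes flow where the repeat-averaged structural intensity
falls strictly below a volume-wide quantile (default 0.05), suppressing
variance noise in the vitreous and in deep shadow.

## Layer segmentation

The built-in segmenter is a *baseline*, not a re-implementation of any
clinical-grade tool: the pipeline's contract is "boundaries in, slabs out",
and imported surfaces with manual corrections are first-class. Each
repeat-averaged B-scan is Gaussian-smoothed (axial σ 0.8 px, lateral σ 2 px)
and differentiated axially with a backward difference, which peaks on the
first pixel of a new layer. Each junction is then the minimum-cost
left-to-right path (dynamic programming, per-column jump limited to ±2 px)
through the signed gradient: ILM rewards dark→bright, IPL/INL and OPL/ONL
reward bright→dark. Junctions are searched vitreous→choroid inside
anatomical bands relative to the previous junction (IPL/INL within 8–45 px
below the ILM, OPL/ONL within 6–30 px below IPL/INL); the band keeps the
search off the stronger outer-retinal transitions (ONL/RPE, RPE/choroid) and
makes the non-crossing invariant `ILM ≤ IPL_INL ≤ OPL_ONL` hold by
construction. A constant B-scan has no gradient structure; it yields flat
traces at the band centres and a warning.

Manual corrections are spliced in with a linear cross-fade (default 4 px)
at patch edges. A corrected trace that would cross a neighbouring junction
is projected back into the valid band — clamped between its shallower and
deeper neighbours — with the clip count logged; a final vitreous→choroid
pass clips any remaining deeper-surface violations. Cystoid edema is handled
only through imported corrections; there is no automatic cyst model.

## Slab geometry

A slab boundary is `(junction, signed px offset)`. Schemes are ordered,
contiguous (each slab's lower boundary is the next slab's upper) and span
ILM+0 to OPL/ONL+0 exactly. Intervals are half-open `[upper, lower)` after
rounding fractional positions half-up (ties toward the choroid,
deterministic), except the deepest slab, which closes inclusively at
OPL/ONL so the scheme partitions the band with no voxel dropped or
double-counted — verified by the sum-projection conservation tests. Columns
where `upper ≥ lower` (thin retina near the foveal pit) are empty, never
inverted; the empty fraction is logged per slab.

The term scheme references the ICP/DCP boundary to the OPL/ONL junction
(rather than IPL/INL) so that anomalous microvasculature inside INL cystoid
spaces — which appears continuous with the ICP — is assigned to the ICP.

The projection operator is selectable (`max`, `mean`, `sum`) and defaults
to maximum intensity, the prevailing convention for en face capillary
rendering. Whether boundary pixels are inclusive and which projector is
used were genuinely open choices; both are explicit parameters and the
defaults above are the package's own convention.

## Enhancement chain

`normalize → threshold_preserve → clahe_rows`, in that order.

* Normalisation is min–max; a constant image maps to zeros (the degenerate
  rule is documented rather than raising, since empty slabs are legitimate).
* "Preserving intensities below 0.25" is interpreted as saturating values at
  or above the threshold and rescaling by 1/threshold, which keeps all
  sub-threshold capillary structure while flattening bright large vessels.
  The alternative reading — zeroing supra-threshold pixels — is available as
  `mode="zero"`.
* Row-wise CLAHE treats each row as an independent 1-D signal split into 8
  contiguous tiles. Per tile, a 256-bin histogram is clipped at
  `clip_limit × tile_size` counts (default clip fraction 0.01) and the
  excess redistributed uniformly; per-pixel output linearly interpolates the
  CDF mappings of the two flanking tile centres. Two boundary rules matter:
  the effective clip never falls below the uniform level `tile/bins`
  (redistribution refills bins to at least that), so a very small clip limit
  drives the mapping to the identity; and a single-valued tile maps through
  the identity, so constant regions and all-zero slabs pass through
  unchanged. Rows shorter than the tile count reduce the tile count with a
  warning. The clip fraction and bin count are package defaults — only the
  tile count is externally prescribed.

## Compositing

`subtract` is `clamp(base − layer, 0, 1)` with no scale or offset terms, and
is applied once: SCP shadows are removed from the ICP only; the DCP is never
attenuated. Gradient maps are linear black→colour ramps with pure yellow
(1,1,0), cyan (0,1,1) and magenta (1,0,1) endpoints (overridable); display
gamma is left to the viewer. `lighten` is the per-pixel, per-channel
maximum, hence commutative and associative. The two-layer (SVC/DVC) overlay
mirrors the chain: SVC shadows are subtracted from the DVC, colours yellow
and magenta.

## Phantom

The phantom exists to give every stage a known ground truth at desk scale.
Defaults: 4 repeats (matching the acquisition protocol), 64 × 128 lateral
positions, 160 depth px — a deliberately scaled-down raster chosen so a
full volume generates in roughly two seconds while preserving all the
geometry the pipeline depends on.

* **Structure**: axial reflectivity bands (vitreous 0.02, NFL/GCL/IPL 0.65,
  INL 0.25, OPL 0.45, ONL 0.18, RPE 0.70, choroid 0.35, arbitrary linear
  units) with the ILM 12 px deep and band thicknesses 34/12/8/30/6 px. The
  contrasts are ordered so the strongest dark→bright step is the vitreous/ILM
  junction and the strongest bright→dark step is IPL/INL, mirroring the
  qualitative contrast ordering of real inner-retinal B-scans. A Gaussian
  foveal pit (16 px deep, σ = 12% of each lateral extent) displaces the
  inner surfaces most.
* **Vasculature**: vessels are smooth tortuous 2-D paths (sinusoidal
  perturbation of a random chord) swept into Gaussian tubes. SCP tubes
  (including a few large-calibre ones) spread through the GCL/IPL band; ICP
  tubes hug the inner INL 2 px below the IPL/INL junction; DCP tubes sit
  4.5 px above the OPL/ONL junction — the middle of the 8-px DCP stratum, so
  the anatomy, not the scheme, places them. All avoid a foveal avascular
  zone, largest for the DCP. Voxels with tube weight > 0.5 are labelled.
* **Noise and flow**: static tissue carries a *frozen* multiplicative
  speckle pattern (default σ 10% of intensity) shared across repeats —
  motionless scatterers produce correlated speckle, which is precisely why
  temporal variance is a flow contrast. Flow voxels get independent
  per-repeat multiplicative jitter (default 30%); every voxel gets a small
  additive per-repeat sensor noise (σ 0.01) that is identical in
  distribution everywhere, so with zero flow amplitude vessel and tissue
  voxels are statistically indistinguishable in variance.
* **Pathology modes**: `edema` adds dark ellipsoidal cysts centred mid-INL;
  `stage="early"` forces ICP/DCP densities to zero and dilates/contorts the
  superficial vessels.

One seed drives everything through deterministically spawned sub-streams,
so a config is exactly reproducible.

What passing phantom tests shows: the geometry, arithmetic and statistics
of the pipeline are correct end to end. What it does not show: performance
on real handheld acquisitions, whose speckle is partially decorrelated even
in static tissue, whose motion is 3-D and nonrigid, and whose layer
contrast varies with probe alignment and media opacity. The baseline
segmenter's sub-pixel accuracy is a phantom-internal statement only; real
infant B-scans are expected to need imported, manually corrected
boundaries.

## Numerical conventions and degenerate inputs

* Rounding of boundary positions is half-up (`floor(x + 0.5)`), never
  banker's rounding, for determinism across platforms.
* Empty projection columns yield 0 under every projector.
* Alignment ties prefer zero shift; degenerate (empty-overlap) correlations
  score −∞ and cannot be selected.
* Image quantisation is round-to-nearest on `[0, 2^bits − 1]`; 16-bit RGB
  is written as TIFF (the PNG encoder in use does not support it).
* HDF5 datasets are written with `track_times=False` so identical data
  produce identical bytes, which is what makes the pipeline's rerun
  hash-identity guarantee possible.

## Problem sizes

The test suite and the acceptance script use the default 64 × 128 × 160
phantom for recovery statistics (≈ 1.3 M voxels, ≈ 17 k labelled flow
voxels) and 24 × 48 × 128 phantoms for the end-to-end pipeline runs; oracle
equivalence checks run on 20 small random fixtures each. These sizes were
chosen so the whole suite completes in well under a minute on one core
while keeping every statistic comfortably away from small-sample noise.

## Known limitations

* No phase/complex-signal OCT-A, no SSADA-style decorrelation, no bulk
  inter-B-scan motion removal, no projection-artifact removal beyond the
  subtract blend.
* The segmenter traces exactly three junctions and assumes the standard
  contrast polarity; pathologies that invert layer contrast defeat it.
* The phantom's vessels are geometric tubes; loop/dendritic morphology is
  approximated only by tortuosity parameters, sufficient for testing slab
  assignment but not for visual realism claims.
* Vendor formats and DICOM are out of scope; the HDF5/TIFF containers are
  the package's own convention.
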