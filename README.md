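# octaslabs

Depth-resolved en face slab processing for handheld OCT angiography of the
preterm-infant perifovea.

OCT angiography (OCT-A) detects blood flow as the decorrelation of repeated
B-scans at the same retinal location. In adults, en face projection of the
flow volume between retinal layer boundaries separates three capillary
plexuses — superficial (SCP), intermediate (ICP) and deep (DCP). Infant
retinas are thinner, frequently edematous, and imaged with handheld probes,
so adult slab definitions do not transfer. `octaslabs` implements a full
pipeline tuned for this setting:

1. **Flow computation** — per-voxel speckle variance across N repeated
   B-scans, `flow[b,z,x] = (1/N) Σ_r (I_r − Ī)²`, after rigid axial
   registration of the repeats and suppression of variance in signal-free
   regions.
2. **Layer boundaries** — the vitreous/ILM, IPL/INL and OPL/ONL junctions,
   either imported from external segmentation (CSV/JSON, with support for
   splicing in manual corrections) or traced by a built-in baseline
   segmenter (per-B-scan shortest path on an axial-gradient cost, searched
   in anatomically ordered bands).
3. **Slab schemes** — anatomical junction + signed pixel offset, at the
   device's axial sampling of 4.37 µm/pixel:
   - *term* (three-layer, formed secondary vasculature):
     SCP = [ILM, IPL/INL − 2 px), ICP = [IPL/INL − 2 px, OPL/ONL − 8 px),
     DCP = [OPL/ONL − 8 px, OPL/ONL]; the SCP/ICP boundary sits 8.74 µm
     above the IPL/INL junction and the ICP/DCP boundary 34.96 µm above the
     OPL/ONL junction.
   - *early* (two-layer, before secondary vasculature is detectable):
     SVC = [ILM, IPL/INL), DVC = [IPL/INL, OPL/ONL].
4. **Offset sweep** — projects the target slab at every combination of
   SCP/ICP offsets (0 to +4 px above IPL/INL) and ICP/DCP offsets (1–5 px
   below IPL/INL, or 5–10 px above OPL/ONL) and tiles the 55 cells into a
   labelled collage for side-by-side grading.
5. **Enhancement** — min-max normalisation, saturation of intensities above
   0.25 (preserving the faint capillary range), and contrast-limited
   adaptive histogram equalisation applied independently to each image row
   with eight tiles per row.
6. **Compositing** — "subtract" blend to remove SCP decorrelation shadows
   from the ICP, linear gradient maps (SCP yellow, ICP cyan, DCP magenta)
   and a "lighten" (per-channel maximum) blend into one overlay.

No clinical volumes ship with the package. A synthetic retinal phantom with
layered reflectivity, a foveal pit, three vascular plexuses, per-repeat flow
jitter, optional INL cystoid edema and an "early" mode (dilated tortuous
superficial vessels, absent deep plexuses) provides ground truth for every
stage.

## Worked example

```python
import numpy as np
from octaslabs import (
    PhantomConfig, generate_phantom, align_repeats, speckle_variance,
    mask_low_signal, segment_boundaries, smooth_boundaries,
    make_term_scheme, resolve_surfaces, project_slab, enhance_slab,
    compose_three_color, evaluate_slab_assignment,
)

volume, truth = generate_phantom(PhantomConfig(stage="term", seed=7))
aligned = align_repeats(volume, max_shift_px=3)
flow = mask_low_signal(speckle_variance(aligned), aligned, floor=0.05)
bounds = smooth_boundaries(segment_boundaries(aligned), window=5)

for j in ("ILM", "IPL_INL", "OPL_ONL"):
    rms = np.sqrt(np.mean((bounds[j] - truth.boundaries[j]) ** 2))
    print(f"{j:8s} boundary RMS error: {rms:.2f} px")

surfaces = resolve_surfaces(make_term_scheme(), bounds)
slabs = {s.name: enhance_slab(project_slab(flow, s)) for s in surfaces}
overlay = compose_three_color(slabs["SCP"], slabs["ICP"], slabs["DCP"])
print("composite shape:", overlay.rgb.shape)

result = evaluate_slab_assignment(truth, surfaces)
for plexus, r in result.recall.items():
    print(f"{plexus} recall: {r:.3f}")
```

prints

```
ILM      boundary RMS error: 0.20 px
IPL_INL  boundary RMS error: 0.19 px
OPL_ONL  boundary RMS error: 0.17 px
composite shape: (64, 128, 3)
SCP recall: 1.000
ICP recall: 1.000
DCP recall: 1.000
```

The RMS lines say the baseline segmenter recovered each junction surface to
a fraction of a pixel under 10% multiplicative speckle; the recall lines say
that every ground-truth flow voxel of each plexus fell inside its designated
slab of the term scheme, boundaries and all computed from the noisy volume
alone.

## Command line

Each stage is also a subcommand of `octaslabs`:

```
octaslabs simulate --stage term --seed 7 --out phantom.h5 --truth truth.h5
octaslabs angiography --in phantom.h5 --out flow.h5 --max-shift 5 --mask-floor 0.05
octaslabs segment --in phantom.h5 --out bounds.csv
octaslabs slab --flow flow.h5 --bounds bounds.csv --scheme term --out-dir slabs/
octaslabs sweep --flow flow.h5 --bounds bounds.csv --slab ICP --montage collage.png
octaslabs composite --scp slabs/slab_SCP.png --icp slabs/slab_ICP.png \
    --dcp slabs/slab_DCP.png --out overlay.png
octaslabs run --config config.yaml --out-dir out/
```

`run` chains everything from a YAML config and writes a `provenance.json`
with parameters and SHA-256 hashes of every artifact; identical configs
reproduce identical bytes.

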