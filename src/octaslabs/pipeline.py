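"""End-to-end orchestration: acquisition -> flow -> boundaries -> slabs -> overlay.

``run_pipeline`` chains the module operations exactly as a manual
composition would, writing every intermediate artifact plus a provenance
record (parameters and SHA-256 hashes of all outputs).  All stages are
deterministic, so re-running an identical configuration reproduces
byte-identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import tifffile

from . import __version__
from .angiography import align_repeats, mask_low_signal, speckle_variance
from .compositing import compose_three_color, compose_two_color
from .enhancement import EnhanceParams, enhance_slab
from .layer_boundaries import SegmentationParams, segment_boundaries, smooth_boundaries
from .phantom import PhantomConfig, generate_phantom
from .slab_engine import (
    make_early_scheme,
    make_term_scheme,
    montage,
    project_scheme,
    sweep_offsets,
)
from .volume_io import load_boundaries, load_volume, save_boundaries, save_enface, save_flow

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "input": {},                      # {"phantom": {...}} or {"volume": path, "layout": "rbza"}
    "alignment": {"max_shift_px": 5},
    "flow": {"mask_floor": 0.05},
    "segmentation": {"smooth_window": 5},
    "boundaries": None,               # optional path to pre-segmented boundaries
    "scheme": "term",
    "projection": "max",
    "enhancement": {},
    "sweep": {"enabled": False, "target": "ICP"},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict, output_dir: str | Path) -> dict:
    """Run the full slab pipeline and write all artifacts under ``output_dir``.

    Returns a manifest mapping artifact names to paths.  The same manifest
    (with hashes) is written to ``provenance.json``.
    """
    cfg = _merge(DEFAULT_CONFIG, config or {})
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    # --- input volume ------------------------------------------------------
    stage = "input"
    try:
        if "phantom" in cfg["input"]:
            pcfg = PhantomConfig(**cfg["input"]["phantom"])
            volume, truth = generate_phantom(pcfg)
        elif "volume" in cfg["input"]:
            volume = load_volume(cfg["input"]["volume"], cfg["input"].get("layout", "rbza"))
            truth = None
        else:
            raise ValueError("config.input must specify 'phantom' or 'volume'")

        stage = "angiography"
        aligned = align_repeats(volume, int(cfg["alignment"]["max_shift_px"]))
        flow = speckle_variance(aligned)
        flow = mask_low_signal(flow, aligned, float(cfg["flow"]["mask_floor"]))
        artifacts["flow"] = save_flow(flow, out / "flow.h5")

        stage = "boundaries"
        if cfg.get("boundaries"):
            boundaries = load_boundaries(cfg["boundaries"], depth_extent=volume.depth)
        else:
            boundaries = segment_boundaries(aligned, SegmentationParams())
            boundaries = smooth_boundaries(
                boundaries, int(cfg["segmentation"]["smooth_window"])
            )
        artifacts["boundaries"] = save_boundaries(boundaries, out / "boundaries.csv")

        stage = "slabs"
        scheme = make_term_scheme() if cfg["scheme"] == "term" else make_early_scheme()
        slabs = project_scheme(flow, boundaries, scheme, cfg["projection"])
        enhance_params = EnhanceParams(**cfg["enhancement"])
        enhanced = {}
        for name, slab in slabs.items():
            raw_path = out / f"slab_{name}_raw.tif"
            tifffile.imwrite(raw_path, slab.image.astype(np.float32))
            artifacts[f"slab_{name}_raw"] = raw_path
            enhanced[name] = enhance_slab(slab, enhance_params)
            artifacts[f"slab_{name}"] = save_enface(
                enhanced[name], out / f"slab_{name}.png"
            )

        stage = "composite"
        if cfg["scheme"] == "term":
            composite = compose_three_color(
                enhanced["SCP"], enhanced["ICP"], enhanced["DCP"]
            )
        else:
            composite = compose_two_color(enhanced["SVC"], enhanced["DVC"])
        artifacts["composite"] = save_enface(composite, out / "composite.png")

        if cfg["sweep"].get("enabled"):
            stage = "sweep"
            grid = sweep_offsets(
                flow, boundaries, target=cfg["sweep"].get("target", "ICP"),
                projection=cfg["projection"],
            )
            artifacts["sweep_collage"] = save_enface(
                montage(grid), out / "sweep_collage.png"
            )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    provenance = {
        "version": __version__,
        "config": cfg,
        "artifacts": {
            name: {"path": p.name, "sha256": _sha256(p)} for name, p in artifacts.items()
        },
    }
    prov_path = out / "provenance.json"
    prov_path.write_text(json.dumps(provenance, indent=1, sort_keys=True, default=str))
    artifacts["provenance"] = prov_path
    logger.info("pipeline complete: %d artifacts in %s", len(artifacts), out)
    return {name: str(p) for name, p in artifacts.items()}
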