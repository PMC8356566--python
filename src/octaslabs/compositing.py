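"""Shadow subtraction and multi-colour overlay of enhanced slabs.

Superficial vessels cast decorrelation shadows onto deeper slabs; the
"subtract" blend (clamped base - layer) removes SCP shadows from the ICP
slab before colouring.  Each slab is then mapped through a linear
black-to-colour gradient (SCP yellow, ICP cyan, DCP magenta) and the
coloured layers are superimposed with the "lighten" blend — the per-pixel,
per-channel maximum.  DCP pixels are never attenuated: the shadow
subtraction applies to the ICP only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .slab_engine import EnFaceSlab

YELLOW = (1.0, 1.0, 0.0)
CYAN = (0.0, 1.0, 1.0)
MAGENTA = (1.0, 0.0, 1.0)


@dataclass
class CompositeImage:
    """RGB overlay of coloured slabs, channels in [0, 1]."""

    rgb: np.ndarray
    channel_provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = np.asarray(self.rgb, dtype=np.float64)
        if arr.ndim != 3 or arr.shape[2] != 3:
            raise ValueError(f"rgb must have shape (H, W, 3), got {arr.shape}")
        if arr.min() < -1e-9 or arr.max() > 1 + 1e-9:
            raise ValueError("rgb channels must lie in [0, 1]")
        self.rgb = np.clip(arr, 0.0, 1.0)


def _img(x) -> np.ndarray:
    return x.image if isinstance(x, EnFaceSlab) else np.asarray(x, dtype=np.float64)


def subtract_blend(base, layer) -> EnFaceSlab:
    """Element-wise ``clamp(base - layer, 0, 1)``."""
    b, l = _img(base), _img(layer)
    if b.shape != l.shape:
        raise ValueError(f"shape mismatch: {b.shape} vs {l.shape}")
    name = base.name if isinstance(base, EnFaceSlab) else ""
    return EnFaceSlab(image=np.clip(b - l, 0.0, 1.0), name=name,
                      provenance={"blend": "subtract"})


def gradient_map(gray, color: tuple[float, float, float]) -> CompositeImage:
    """Colour a grayscale slab along a linear black-to-colour ramp."""
    g = _img(gray)
    if g.min() < -1e-9 or g.max() > 1 + 1e-9:
        raise ValueError("gradient_map expects input in [0, 1]")
    rgb = np.clip(g, 0.0, 1.0)[..., None] * np.asarray(color, dtype=np.float64)
    name = gray.name if isinstance(gray, EnFaceSlab) else ""
    return CompositeImage(rgb=rgb, channel_provenance={name or "slab": tuple(color)})


def lighten_blend(images: list[CompositeImage]) -> CompositeImage:
    """Per-pixel, per-channel maximum across coloured layers."""
    if not images:
        raise ValueError("lighten_blend requires at least one image")
    stack = [im.rgb if isinstance(im, CompositeImage) else np.asarray(im) for im in images]
    shapes = {a.shape for a in stack}
    if len(shapes) > 1:
        raise ValueError(f"shape mismatch across layers: {shapes}")
    prov: dict = {}
    for im in images:
        if isinstance(im, CompositeImage):
            prov.update(im.channel_provenance)
    return CompositeImage(rgb=np.maximum.reduce(stack), channel_provenance=prov)


def compose_three_color(
    scp, icp, dcp,
    colors: tuple = (YELLOW, CYAN, MAGENTA),
) -> CompositeImage:
    """Three-colour plexus overlay with SCP-shadow removal from the ICP.

    ``composite = lighten(gradient(scp, yellow), gradient(icp - scp, cyan),
    gradient(dcp, magenta))``.
    """
    icp_clean = subtract_blend(icp, scp)
    return lighten_blend([
        gradient_map(scp, colors[0]),
        gradient_map(icp_clean, colors[1]),
        gradient_map(dcp, colors[2]),
    ])


def compose_two_color(
    svc, dvc,
    colors: tuple = (YELLOW, MAGENTA),
) -> CompositeImage:
    """Two-colour overlay for the early (SVC/DVC) scheme.

    SVC shadows are subtracted from the DVC before colouring, mirroring the
    three-layer chain's treatment of the slab immediately below the
    superficial vessels.
    """
    dvc_clean = subtract_blend(dvc, svc)
    return lighten_blend([
        gradient_map(svc, colors[0]),
        gradient_map(dvc_clean, colors[1]),
    ])
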