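"""Deterministic synthetic grayscale phantoms for exercising the codec.

Four families:

* ``gradient`` — a smooth 2-D ramp, the easy case for any block coder;
* ``ellipse`` — overlapping soft-edged ellipses on a dark background,
  loosely in the spirit of the Shepp-Logan head phantom, exercising
  smooth-tissue-like regions with curved boundaries;
* ``mosaic`` — blocks drawn uniformly from a small set of known block
  prototypes plus optional Gaussian noise: codebook recovery on these has
  an analytic ground truth;
* ``noise`` — i.i.d. uniform pixels, the incompressible control.

Everything is a pure function of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PhantomSpec", "generate", "generate_suite", "default_prototypes"]

KINDS = ("gradient", "ellipse", "mosaic", "noise")


def default_prototypes(block_side: int = 4) -> np.ndarray:
    """Four well-separated block prototypes: two flats, a ramp, a checkerboard."""
    b = block_side
    flat_dark = np.full((b, b), 30.0)
    flat_bright = np.full((b, b), 220.0)
    ramp = np.rint(np.tile(np.linspace(60.0, 140.0, b), (b, 1)))
    checker = np.where(np.indices((b, b)).sum(axis=0) % 2 == 0, 100.0, 180.0)
    return np.stack([p.ravel() for p in (flat_dark, flat_bright, ramp, checker)])


@dataclass
class PhantomSpec:
    kind: str
    height: int = 128
    width: int = 128
    prototypes: np.ndarray | None = None  # mosaic only; (M_true, b*b)
    block_side: int = 4  # mosaic tile side
    noise_sigma: float = 0.0  # mosaic pixel noise, intensity units
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown phantom kind {self.kind!r}; use one of {KINDS}")
        if self.height < 8 or self.width < 8:
            raise ValueError("phantoms must be at least 8x8")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.kind == "mosaic":
            if self.prototypes is None:
                self.prototypes = default_prototypes(self.block_side)
            self.prototypes = np.asarray(self.prototypes, dtype=np.float64)
            if self.prototypes.shape[1] != self.block_side**2:
                raise ValueError("prototypes must have length block_side^2")


def _gradient(spec: PhantomSpec) -> np.ndarray:
    h, w = spec.height, spec.width
    yy, xx = np.mgrid[0:h, 0:w]
    ramp = (yy / max(h - 1, 1) + xx / max(w - 1, 1)) / 2.0
    return np.rint(ramp * 255.0)


def _ellipse(spec: PhantomSpec) -> np.ndarray:
    h, w = spec.height, spec.width
    rng = np.random.default_rng(spec.seed)
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    img = np.full((h, w), 10.0)
    # (center frac y/x, semi-axis frac y/x, angle, intensity) — skull-like
    # outer shell plus interior structures, jittered slightly by seed
    params = [
        (0.50, 0.50, 0.46, 0.38, 0.0, 170.0),
        (0.50, 0.50, 0.40, 0.32, 0.0, 60.0),
        (0.42, 0.40, 0.14, 0.10, 0.4, 120.0),
        (0.42, 0.62, 0.12, 0.09, -0.4, 140.0),
        (0.68, 0.50, 0.10, 0.14, 0.0, 95.0),
    ]
    for fy, fx, fa, fb, ang, level in params:
        jitter = rng.uniform(-0.01, 0.01, size=2)
        ecy = (fy + jitter[0]) * h
        ecx = (fx + jitter[1]) * w
        a = fa * h
        b = fb * w
        dy, dx = yy - ecy, xx - ecx
        ry = dy * np.cos(ang) + dx * np.sin(ang)
        rx = -dy * np.sin(ang) + dx * np.cos(ang)
        r = np.sqrt((ry / a) ** 2 + (rx / b) ** 2)
        # soft edge: smoothstep from 1 inside to 0 past the boundary
        t = np.clip((1.1 - r) / 0.2, 0.0, 1.0)
        soft = t * t * (3.0 - 2.0 * t)
        img = img * (1.0 - soft) + level * soft
    _ = cy, cx
    return np.rint(np.clip(img, 0, 255))


def _mosaic(spec: PhantomSpec) -> np.ndarray:
    b = spec.block_side
    if spec.height % b or spec.width % b:
        raise ValueError("mosaic dimensions must be multiples of block_side")
    rng = np.random.default_rng(spec.seed)
    gr, gc = spec.height // b, spec.width // b
    choice = rng.integers(0, spec.prototypes.shape[0], size=gr * gc)
    tiles = spec.prototypes[choice].astype(np.float64)
    if spec.noise_sigma > 0:
        tiles = tiles + rng.normal(0.0, spec.noise_sigma, size=tiles.shape)
    img = (
        tiles.reshape(gr, gc, b, b)
        .transpose(0, 2, 1, 3)
        .reshape(spec.height, spec.width)
    )
    return np.rint(np.clip(img, 0, 255))


def _noise(spec: PhantomSpec) -> np.ndarray:
    rng = np.random.default_rng(spec.seed)
    return rng.integers(0, 256, size=(spec.height, spec.width)).astype(np.float64)


def generate(spec: PhantomSpec) -> np.ndarray:
    """Render a phantom as a uint8 grayscale image (pure in (spec, seed))."""
    img = {
        "gradient": _gradient,
        "ellipse": _ellipse,
        "mosaic": _mosaic,
        "noise": _noise,
    }[spec.kind](spec)
    return np.clip(img, 0, 255).astype(np.uint8)


def generate_suite(seed: int = 0) -> list[tuple[str, np.ndarray, dict]]:
    """Fixed battery of phantoms with machine-readable ground truth.

    Returns (name, image, annotations) triples; annotation keys include
    the generating spec and, for mosaics, the prototype matrix and noise
    level, so tests can verify codebook recovery analytically.
    """
    protos = default_prototypes(4)
    entries = [
        ("gradient_64", PhantomSpec("gradient", 64, 64, seed=seed)),
        ("ellipse_128", PhantomSpec("ellipse", 128, 128, seed=seed)),
        ("mosaic_128", PhantomSpec("mosaic", 128, 128, prototypes=protos,
                                   noise_sigma=0.0, seed=seed)),
        ("mosaic_128_noisy", PhantomSpec("mosaic", 128, 128, prototypes=protos,
                                         noise_sigma=2.0, seed=seed + 1)),
        ("noise_64", PhantomSpec("noise", 64, 64, seed=seed)),
        ("gradient_256", PhantomSpec("gradient", 256, 256, seed=seed)),
    ]
    suite = []
    for name, spec in entries:
        annotations: dict = {
            "kind": spec.kind,
            "height": spec.height,
            "width": spec.width,
            "seed": spec.seed,
        }
        if spec.kind == "mosaic":
            annotations["prototypes"] = spec.prototypes
            annotations["noise_sigma"] = spec.noise_sigma
            annotations["block_side"] = spec.block_side
        suite.append((name, generate(spec), annotations))
    return suite
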