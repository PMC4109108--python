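"""Synthetic test phantoms with exact ground-truth masks.

Phantoms are built as piecewise-constant fields on the [0, 1] intensity
scale, optionally corrupted by a smooth multiplicative bias field (emulating
intensity inhomogeneity such as an MR coil profile) and additive zero-mean
Gaussian noise, then clipped to [0, 1] and mapped to [0, 255].  Because the
corruption is applied on [0, 1], the conventional noise-variance levels
(0.01, 0.05, 0.1) keep their usual meaning.  The ground-truth mask is the
union of the object supports, exact by construction, and every phantom is
deterministic given its seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Literal, Optional, Tuple

import numpy as np
from scipy import ndimage
from skimage import draw as skdraw

from .errors import InvalidParameterError

__all__ = [
    "ObjectSpec",
    "PhantomSpec",
    "render_phantom",
    "brainlike_phantom",
    "two_level_disc",
    "fig2_style",
    "three_objects",
    "two_discs",
    "PHANTOM_PRESETS",
    "make_preset_phantom",
]

#: the noise-variance levels used throughout the test protocols
STANDARD_NOISE_VARIANCES = (0.0, 0.01, 0.05, 0.1)

BiasFamily = Literal["none", "linear", "quadratic", "gaussian_blob"]


@dataclass(frozen=True)
class ObjectSpec:
    """One foreground object of a phantom.

    ``disc``:      geometry = (row, col, radius)
    ``rectangle``: geometry = (r0, c0, r1, c1), half-open
    ``star``:      geometry = (row, col, outer_radius[, inner_radius]),
                   a 5-pointed polygon (inner radius defaults to 0.45 outer)

    `noise_ramp`, if given, adds extra zero-mean Gaussian noise inside the
    object's bounding box whose variance ramps linearly left-to-right
    between the two values — the "strong nonuniform noise" hard case.
    """

    shape: Literal["disc", "rectangle", "star"]
    geometry: Tuple[float, ...]
    level: float
    noise_ramp: Optional[Tuple[float, float]] = None

    def support(self, grid_shape: Tuple[int, int]) -> np.ndarray:
        h, w = grid_shape
        m = np.zeros(grid_shape, dtype=bool)
        if self.shape == "disc":
            r, c, rad = self.geometry
            rr, cc = skdraw.disk((r, c), rad, shape=grid_shape)
            m[rr, cc] = True
        elif self.shape == "rectangle":
            r0, c0, r1, c1 = (int(v) for v in self.geometry)
            m[max(r0, 0):min(r1, h), max(c0, 0):min(c1, w)] = True
        elif self.shape == "star":
            g = self.geometry
            r, c, r_out = g[0], g[1], g[2]
            r_in = g[3] if len(g) > 3 else 0.45 * r_out
            ang = -np.pi / 2 + np.arange(10) * np.pi / 5
            rad = np.where(np.arange(10) % 2 == 0, r_out, r_in)
            rr, cc = skdraw.polygon(
                r + rad * np.sin(ang), c + rad * np.cos(ang), shape=grid_shape
            )
            m[rr, cc] = True
        else:
            raise InvalidParameterError(f"unknown object shape {self.shape!r}")
        return m


@dataclass(frozen=True)
class PhantomSpec:
    """Full recipe for one phantom: geometry, bias, noise, seed."""

    size: Tuple[int, int] = (128, 128)
    objects: Tuple[ObjectSpec, ...] = ()
    background_level: float = 0.2
    bias_family: BiasFamily = "none"
    bias_amplitude: float = 0.0
    noise_variance: float = 0.0
    seed: int = 0

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=2, default=lambda o: list(o))


def _bias_field(family: BiasFamily, amplitude: float,
                shape: Tuple[int, int]) -> np.ndarray:
    """Smooth multiplicative modulation (1 + b) with b in [-a/2, +a/2]."""
    h, w = shape
    if family == "none" or amplitude == 0.0:
        return np.zeros(shape)
    if not 0.0 <= amplitude < 1.0:
        raise InvalidParameterError(f"bias amplitude must lie in [0, 1), got {amplitude}")
    rr, cc = np.mgrid[0:h, 0:w].astype(np.float64)
    if family == "linear":
        u = cc / (w - 1)
    elif family == "quadratic":
        d2 = (rr - (h - 1) / 2) ** 2 + (cc - (w - 1) / 2) ** 2
        u = 1.0 - d2 / d2.max()
    elif family == "gaussian_blob":
        s = 0.25 * min(h, w)
        d2 = (rr - (h - 1) / 2) ** 2 + (cc - (w - 1) / 2) ** 2
        u = np.exp(-d2 / (2.0 * s**2))
    else:
        raise InvalidParameterError(f"unknown bias family {family!r}")
    return amplitude * (u - 0.5)


def render_phantom(spec: PhantomSpec) -> Tuple[np.ndarray, np.ndarray]:
    """Render `spec` to a [0, 255] image plus its exact truth mask.

    Overlapping objects with different intensity levels are rejected — the
    ground truth would be ambiguous there.
    """
    shape = tuple(spec.size)
    clean = np.full(shape, float(spec.background_level))
    truth = np.zeros(shape, dtype=bool)
    for obj in spec.objects:
        m = obj.support(shape)
        clash = truth & m
        if clash.any() and not np.allclose(clean[clash], obj.level):
            raise InvalidParameterError(
                "objects with different levels overlap; ground truth ambiguous"
            )
        clean[m] = float(obj.level)
        truth |= m

    img = clean * (1.0 + _bias_field(spec.bias_family, spec.bias_amplitude, shape))

    rng = np.random.default_rng(spec.seed)
    if spec.noise_variance > 0:
        img = img + rng.normal(0.0, np.sqrt(spec.noise_variance), shape)
    for obj in spec.objects:
        if obj.noise_ramp is None:
            continue
        m = obj.support(shape)
        rows = np.any(m, axis=1).nonzero()[0]
        cols = np.any(m, axis=0).nonzero()[0]
        v0, v1 = obj.noise_ramp
        ramp = np.zeros(shape)
        span = max(cols[-1] - cols[0], 1)
        ramp[:, cols[0]:cols[-1] + 1] = v0 + (v1 - v0) * (
            np.arange(cols[0], cols[-1] + 1) - cols[0]
        ) / span
        sd = np.sqrt(np.where(m, ramp, 0.0))
        img = img + rng.normal(0.0, 1.0, shape) * sd

    return np.clip(img, 0.0, 1.0) * 255.0, truth


def brainlike_phantom(size: Tuple[int, int] = (128, 128),
                      seed: int = 0) -> Tuple[np.ndarray, np.ndarray]:
    """Two-tissue phantom with a cortex-like blobby foreground.

    A Gaussian-smoothed random field is thresholded at its 60th percentile
    to produce an irregular, possibly multi-component foreground (intensity
    0.7) over background (0.3), then corrupted by a quadratic bias field of
    amplitude 0.4 and variance-0.01 Gaussian noise.  Returns the image on
    [0, 255] and the exact foreground mask.
    """
    h, w = size
    if h < 64 or w < 64:
        raise InvalidParameterError(f"brain-like phantom needs size >= 64x64, got {size}")
    rng = np.random.default_rng(seed)
    field = ndimage.gaussian_filter(rng.standard_normal(size), sigma=min(h, w) / 16)
    mask = field > np.percentile(field, 60)
    clean = np.where(mask, 0.7, 0.3)
    img = clean * (1.0 + _bias_field("quadratic", 0.4, size))
    img = img + rng.normal(0.0, 0.1, size)  # sd 0.1 -> variance 0.01
    return np.clip(img, 0.0, 1.0) * 255.0, mask


# --------------------------------------------------------------------------
# named phantom families used by the test protocols and the CLI
# --------------------------------------------------------------------------

def two_level_disc(size=(128, 128), noise_variance=0.0, seed=0,
                   bias_family="none", bias_amplitude=0.0) -> PhantomSpec:
    """Clean two-level phantom: one disc (0.6) on a darker background (0.2)."""
    h, w = size
    return PhantomSpec(
        size=tuple(size),
        objects=(ObjectSpec("disc", (h / 2, w / 2, min(h, w) / 4), 0.6),),
        background_level=0.2,
        bias_family=bias_family,
        bias_amplitude=bias_amplitude,
        noise_variance=noise_variance,
        seed=seed,
    )


def fig2_style(size=(128, 128), noise_variance=0.01, seed=0) -> PhantomSpec:
    """Noise-robustness family: the two-level disc at a chosen noise level."""
    return two_level_disc(size=size, noise_variance=noise_variance, seed=seed)


def three_objects(size=(128, 128), seed=0, noise_variance=0.0) -> PhantomSpec:
    """Hard multi-object phantom: three objects at distinct levels.

    A faint disc (0.35), a mid rectangle (0.65) and a bright star (0.95)
    carrying strongly nonuniform extra noise (variance ramping 0.02 -> 0.1
    across its bounding box) on background 0.15.  A single global two-phase
    threshold cannot separate the faint disc from the background without
    also mislabelling brighter structure, while local statistics can.
    """
    h, w = size
    return PhantomSpec(
        size=tuple(size),
        objects=(
            ObjectSpec("disc", (0.30 * h, 0.25 * w, 0.13 * min(h, w)), 0.35),
            ObjectSpec("rectangle",
                       (int(0.58 * h), int(0.12 * w), int(0.82 * h), int(0.42 * w)),
                       0.65),
            ObjectSpec("star", (0.50 * h, 0.72 * w, 0.21 * min(h, w)), 0.95,
                       noise_ramp=(0.02, 0.1)),
        ),
        background_level=0.15,
        noise_variance=noise_variance,
        seed=seed,
    )


def two_discs(size=(128, 128), seed=0, noise_variance=0.0) -> PhantomSpec:
    """Two disjoint equal-level discs (topology-change test case)."""
    h, w = size
    return PhantomSpec(
        size=tuple(size),
        objects=(
            ObjectSpec("disc", (h / 2, 0.28 * w, 0.14 * min(h, w)), 0.6),
            ObjectSpec("disc", (h / 2, 0.72 * w, 0.14 * min(h, w)), 0.6),
        ),
        background_level=0.2,
        noise_variance=noise_variance,
        seed=seed,
    )


PHANTOM_PRESETS = {
    "two-level-disc": two_level_disc,
    "fig2-style": fig2_style,
    "three-objects": three_objects,
    "two-discs": two_discs,
    # brainlike is generated directly, not via a PhantomSpec
}


def make_preset_phantom(name: str, size=(128, 128), seed: int = 0,
                        noise_variance: Optional[float] = None,
                        bias: str = "none",
                        bias_amplitude: float = 0.0):
    """Build (image, truth, spec_json) for a named phantom family."""
    if name == "brainlike":
        img, truth = brainlike_phantom(tuple(size), seed)
        meta = json.dumps({"preset": "brainlike", "size": list(size), "seed": seed},
                          indent=2)
        return img, truth, meta
    if name not in PHANTOM_PRESETS:
        raise InvalidParameterError(
            f"unknown phantom preset {name!r}; choose from "
            f"{sorted(PHANTOM_PRESETS) + ['brainlike']}"
        )
    kwargs = {"size": tuple(size), "seed": seed}
    if noise_variance is not None:
        kwargs["noise_variance"] = noise_variance
    if name == "two-level-disc" and bias != "none":
        kwargs["bias_family"] = bias
        kwargs["bias_amplitude"] = bias_amplitude
    spec = PHANTOM_PRESETS[name](**kwargs)
    img, truth = render_phantom(spec)
    return img, truth, spec.to_json()
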