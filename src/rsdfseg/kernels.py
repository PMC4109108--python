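"""Window kernels and the smoothed Heaviside/Dirac pair.

The region-scalable energies weigh intensities through a window function
K_sigma centred on each pixel.  Two families are provided:

* ``uniform`` -- the truncated uniform window, constant 1/(2*sigma+1)^2 on the
  (2*sigma+1) x (2*sigma+1) square and zero outside;
* ``gaussian`` -- a Gaussian exp(-r^2 / 2 sigma^2) truncated on the square of
  half-width ceil(4*sigma) and renormalised to unit sum.

Both families are separable on their square support, so convolution with an
image is done as two 1-D correlations.  The level-set formulation uses a
smoothed step H_eps and its companion impulse delta_eps; the step is the
piecewise arctan profile saturating exactly at 0/1 beyond +-eps, and the
impulse is the full-support Cauchy kernel eps / (pi (eps^2 + x^2)).  Note the
step as defined is only continuous up to a jump of about 0.25 at +-eps; the
impulse is taken from its own closed form (it is the exact derivative of the
arctan branch), not from differencing the step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import ndimage

from .errors import InvalidParameterError

__all__ = [
    "WindowKernel",
    "make_uniform_kernel",
    "make_gaussian_kernel",
    "heaviside_eps",
    "dirac_eps",
]

#: default smoothing width of the Heaviside/Dirac pair
DEFAULT_EPS = 1.5

#: Gaussian windows are truncated at this many sigmas (rounded up)
GAUSSIAN_TRUNCATE = 4.0


@dataclass(frozen=True)
class WindowKernel:
    """A normalised, square-supported window stencil.

    Attributes
    ----------
    family : {"uniform", "gaussian"}
        Kernel family.
    radius_or_sigma : float
        The scale parameter sigma, in pixels.
    support : int
        Half-width of the square support, in pixels.
    weights : ndarray
        The (2*support+1) x (2*support+1) stencil; nonnegative, sums to 1.
    weights_1d : ndarray
        The 1-D factor such that ``weights == outer(weights_1d, weights_1d)``.
        Both families are exactly separable on their square support.
    """

    family: Literal["uniform", "gaussian"]
    radius_or_sigma: float
    support: int
    weights: np.ndarray = field(repr=False)
    weights_1d: np.ndarray = field(repr=False)

    def convolve(self, image: np.ndarray, mode: str = "nearest") -> np.ndarray:
        """Correlate `image` with the stencil via two 1-D passes.

        ``mode="nearest"`` replicates edge values (the default for all
        image-valued convolutions); ``mode="constant"`` zero-pads, which is
        used to integrate the kernel over the image domain only.
        """
        out = ndimage.correlate1d(
            np.ascontiguousarray(image, dtype=np.float64),
            self.weights_1d, axis=0, mode=mode, cval=0.0,
        )
        return ndimage.correlate1d(out, self.weights_1d, axis=1, mode=mode, cval=0.0)

    def convolve_generic(self, image: np.ndarray, mode: str = "nearest") -> np.ndarray:
        """Reference 2-D stencil correlation (slow path; for verification)."""
        return ndimage.correlate(
            np.asarray(image, dtype=np.float64), self.weights, mode=mode, cval=0.0
        )

    def domain_mass(self, shape: tuple[int, int]) -> np.ndarray:
        """Kernel mass integrated over the image domain only.

        Returns sum_{y in Omega} K(x - y) for every x: exactly 1 in the
        interior, tapering below 1 within `support` pixels of the border.
        """
        return self.convolve(np.ones(shape, dtype=np.float64), mode="constant")

    def to_text(self) -> str:
        """Serialise the stencil as a plain-text 2-D array (one row per line)."""
        return "\n".join(
            " ".join(f"{w:.17g}" for w in row) for row in self.weights
        )


def make_uniform_kernel(sigma: int) -> WindowKernel:
    """Truncated uniform window of radius `sigma` (an integer >= 1).

    Every weight inside the (2*sigma+1) x (2*sigma+1) square is exactly
    1/(2*sigma+1)^2; the implied weight outside is zero.
    """
    if not isinstance(sigma, (int, np.integer)) or isinstance(sigma, bool):
        raise InvalidParameterError(f"uniform window radius must be an integer, got {sigma!r}")
    if sigma < 1:
        raise InvalidParameterError(f"uniform window radius must be >= 1, got {sigma}")
    sigma = int(sigma)
    n = 2 * sigma + 1
    w1 = np.full(n, 1.0 / n)
    return WindowKernel(
        family="uniform",
        radius_or_sigma=float(sigma),
        support=sigma,
        weights=np.full((n, n), 1.0 / n**2),
        weights_1d=w1,
    )


def make_gaussian_kernel(sigma: float) -> WindowKernel:
    """Gaussian window of scale `sigma`, truncated at ceil(4*sigma) and
    renormalised to unit sum."""
    sigma = float(sigma)
    if not np.isfinite(sigma) or sigma <= 0:
        raise InvalidParameterError(f"gaussian window sigma must be > 0, got {sigma}")
    half = int(np.ceil(GAUSSIAN_TRUNCATE * sigma))
    x = np.arange(-half, half + 1, dtype=np.float64)
    g1 = np.exp(-(x**2) / (2.0 * sigma**2))
    # square truncation keeps the kernel exactly separable; normalising the
    # 1-D factor normalises the outer product as well
    g1 /= g1.sum()
    return WindowKernel(
        family="gaussian",
        radius_or_sigma=sigma,
        support=half,
        weights=np.outer(g1, g1),
        weights_1d=g1,
    )


def make_kernel(family: str, sigma: float) -> WindowKernel:
    """Dispatch on kernel family name."""
    if family == "uniform":
        return make_uniform_kernel(int(sigma))
    if family == "gaussian":
        return make_gaussian_kernel(sigma)
    raise InvalidParameterError(f"unknown kernel family {family!r}")


def _check_eps(eps: float) -> float:
    eps = float(eps)
    if not np.isfinite(eps) or eps <= 0:
        raise InvalidParameterError(f"smoothing width eps must be > 0, got {eps}")
    return eps


def heaviside_eps(x, eps: float = DEFAULT_EPS):
    """Smoothed step: (1/2)(1 + (2/pi) arctan(x/eps)) on |x| <= eps,
    exactly 1 for x > eps and exactly 0 for x < -eps.

    The arctan branch does not reach 0/1 at +-eps, so the function has a jump
    of 1/2 - arctan(1)/pi ~= 0.25 there; this is deliberate (the companion
    impulse `dirac_eps`, not a derivative of this step, drives the flow).
    Accepts scalars or arrays.
    """
    eps = _check_eps(eps)
    x = np.asarray(x, dtype=np.float64)
    out = 0.5 * (1.0 + (2.0 / np.pi) * np.arctan(x / eps))
    out = np.where(x > eps, 1.0, out)
    out = np.where(x < -eps, 0.0, out)
    return out if out.ndim else float(out)


def dirac_eps(x, eps: float = DEFAULT_EPS):
    """Full-support smoothed impulse eps / (pi (eps^2 + x^2)).

    Strictly positive everywhere, so the data forces act on all level curves
    and new contours can appear away from the current zero set.  Accepts
    scalars or arrays.
    """
    eps = _check_eps(eps)
    x = np.asarray(x, dtype=np.float64)
    out = eps / (np.pi * (eps**2 + x**2))
    return out if out.ndim else float(out)
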