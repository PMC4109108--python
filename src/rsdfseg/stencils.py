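"""Central-difference stencils on a unit grid with replicate boundaries.

Axis convention: x runs along columns (axis 1), y along rows (axis 0), so a
field equal to its column index has unit x-derivative.  All operators pad the
field by replicating edge values before differencing, so outputs keep the
input shape; quoted stencil identities (e.g. exactness on quadratics) hold on
interior nodes.
"""

from __future__ import annotations

import numpy as np

__all__ = ["gradient", "spatial_derivatives", "curvature", "laplacian"]

# floor on |grad phi| inside the curvature quotient, avoids 0/0 on flats
GRADIENT_FLOOR = 1e-10


def _pad(phi: np.ndarray) -> np.ndarray:
    return np.pad(np.asarray(phi, dtype=np.float64), 1, mode="edge")


def gradient(phi):
    """First-order central differences (phi_x, phi_y)."""
    p = _pad(phi)
    px = 0.5 * (p[1:-1, 2:] - p[1:-1, :-2])
    py = 0.5 * (p[2:, 1:-1] - p[:-2, 1:-1])
    return px, py


def spatial_derivatives(phi):
    """All five central-difference fields (phi_x, phi_y, phi_xx, phi_yy,
    phi_xy) on a unit grid.

    The mixed derivative is the standard four-corner stencil
    (phi_{i+1,j+1} + phi_{i-1,j-1} - phi_{i-1,j+1} - phi_{i+1,j-1}) / 4,
    exact for bilinear fields.
    """
    p = _pad(phi)
    c = p[1:-1, 1:-1]
    px = 0.5 * (p[1:-1, 2:] - p[1:-1, :-2])
    py = 0.5 * (p[2:, 1:-1] - p[:-2, 1:-1])
    pxx = p[1:-1, 2:] - 2.0 * c + p[1:-1, :-2]
    pyy = p[2:, 1:-1] - 2.0 * c + p[:-2, 1:-1]
    pxy = 0.25 * (p[2:, 2:] + p[:-2, :-2] - p[:-2, 2:] - p[2:, :-2])
    return px, py, pxx, pyy, pxy


def curvature(phi, clip: float | None = None):
    """div(grad phi / |grad phi|) via the rational central-difference form
    (phi_xx phi_y^2 - 2 phi_xy phi_x phi_y + phi_yy phi_x^2) / |grad phi|^3,
    with |grad phi| floored at a tiny constant.

    On near-flat plateaus the quotient is ill-conditioned (the normal
    direction is undefined there) and can reach arbitrarily large values;
    passing ``clip`` bounds the result to [-clip, clip].  A unit grid cannot
    represent curvature radii below one pixel, so the evolution uses
    clip = 2 (= 2/dh); diagnostics on smooth fields use the raw quotient.
    """
    px, py, pxx, pyy, pxy = spatial_derivatives(phi)
    g = np.hypot(px, py)
    g3 = np.maximum(g, GRADIENT_FLOOR) ** 3
    kappa = (pxx * py**2 - 2.0 * pxy * px * py + pyy * px**2) / g3
    if clip is not None:
        np.clip(kappa, -clip, clip, out=kappa)
    return kappa


def laplacian(phi):
    """Five-point Laplacian phi_xx + phi_yy."""
    _, _, pxx, pyy, _ = spatial_derivatives(phi)
    return pxx + pyy
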