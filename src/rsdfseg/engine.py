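"""Contour initialisation, explicit time stepping, and the stopping rule.

The level set starts as a binary field (+c0 inside the seed region, -c0
outside) and evolves by forward Euler,  phi <- phi + dt * force,  with the
region statistics refit before every step (alternating minimisation).  No
reinitialisation is ever performed; the distance-regularisation term keeps
phi well behaved.  Evolution stops once the set of sign-change pixels
stabilises: fewer than `stop_pixels` pixels flip sign per iteration for
`stop_window` consecutive iterations, or at `max_iter`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, List, Literal, Optional, Tuple, Union

import numpy as np

from .energy import (
    EnergyBreakdown,
    RSDFParams,
    compute_stats,
    force_field,
    membership_fields,
    total_energy,
)
from .errors import (
    InvalidInitializationError,
    NumericalBlowupError,
    OneSidedRegionError,
    ShapeMismatchError,
)
from .stencils import curvature, spatial_derivatives  # noqa: F401  (re-export)

__all__ = [
    "InitialContourSpec",
    "SegmentationResult",
    "initialize_phi",
    "step",
    "zero_crossing_count_delta",
    "run",
    "curvature",
    "spatial_derivatives",
]


@dataclass(frozen=True)
class InitialContourSpec:
    """Seed region for the binary initial level set.

    ``rectangle``: geometry = (r0, c0, r1, c1), half-open pixel slices.
    ``circle``:    geometry = (row, col, radius).
    ``mask``:      geometry = a boolean array marking the inside.
    Coordinates are 0-based, row-major.
    """

    shape: Literal["rectangle", "circle", "mask"]
    geometry: Union[Tuple, np.ndarray]
    c0: float = 2.0

    def inside_mask(self, grid_shape: Tuple[int, int]) -> np.ndarray:
        h, w = grid_shape
        if self.shape == "rectangle":
            r0, c0, r1, c1 = (int(v) for v in self.geometry)
            if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
                raise InvalidInitializationError(
                    f"rectangle ({r0},{c0},{r1},{c1}) does not fit in grid {grid_shape}"
                )
            m = np.zeros(grid_shape, dtype=bool)
            m[r0:r1, c0:c1] = True
            return m
        if self.shape == "circle":
            r, c, rad = self.geometry
            if rad <= 0:
                raise InvalidInitializationError(f"circle radius must be > 0, got {rad}")
            rr, cc = np.ogrid[:h, :w]
            return (rr - float(r)) ** 2 + (cc - float(c)) ** 2 <= float(rad) ** 2
        if self.shape == "mask":
            m = np.asarray(self.geometry, dtype=bool)
            if m.shape != grid_shape:
                raise ShapeMismatchError(
                    f"mask shape {m.shape} does not match grid {grid_shape}"
                )
            return m.copy()
        raise InvalidInitializationError(f"unknown init shape {self.shape!r}")


@dataclass
class SegmentationResult:
    """Final state and per-iteration diagnostics of one evolution."""

    mask: np.ndarray
    phi_final: np.ndarray
    energy_trace: List[EnergyBreakdown]
    n_iter: int
    converged: bool
    zero_crossing_deltas: List[int]
    diagnostic: str = ""

    @property
    def energy_totals(self) -> np.ndarray:
        return np.array([e.F_total for e in self.energy_trace])


def initialize_phi(spec: InitialContourSpec, grid_shape: Tuple[int, int]) -> np.ndarray:
    """Binary initial level set: +c0 on the seed region, -c0 elsewhere.

    The seed must be a proper subset of the grid (nonempty, not everything).
    """
    inside = spec.inside_mask(tuple(grid_shape))
    n_in = int(inside.sum())
    if n_in == 0:
        raise InvalidInitializationError("initial inside region is empty")
    if n_in == inside.size:
        raise InvalidInitializationError("initial inside region fills the whole grid")
    return np.where(inside, float(spec.c0), -float(spec.c0))


def step(phi: np.ndarray, force: np.ndarray, dt: float,
         iteration: Optional[int] = None) -> np.ndarray:
    """Forward-Euler update phi + dt * force; rejects non-finite forces."""
    force = np.asarray(force, dtype=np.float64)
    if force.shape != np.shape(phi):
        raise ShapeMismatchError(
            f"force shape {force.shape} does not match phi {np.shape(phi)}"
        )
    if not np.all(np.isfinite(force)):
        raise NumericalBlowupError(
            "non-finite values in the evolution force", iteration=iteration
        )
    return np.asarray(phi, dtype=np.float64) + float(dt) * force


def zero_crossing_count_delta(phi_prev: np.ndarray, phi_next: np.ndarray) -> int:
    """Number of grid pixels whose sign of phi changed between iterations."""
    a = np.asarray(phi_prev)
    b = np.asarray(phi_next)
    if a.shape != b.shape:
        raise ShapeMismatchError(f"shapes differ: {a.shape} vs {b.shape}")
    return int(np.count_nonzero((a > 0) != (b > 0)))


def run(
    image: np.ndarray,
    params: RSDFParams,
    init: Union[InitialContourSpec, np.ndarray],
    callback: Optional[Callable[[int, np.ndarray, EnergyBreakdown], None]] = None,
) -> SegmentationResult:
    """Evolve the contour on `image` from the given initialisation.

    Each iteration refits the region statistics for the current phi, builds
    the gradient-flow force, takes one Euler step, and logs the full energy
    breakdown plus the count of sign-change pixels.  ``init`` may be an
    `InitialContourSpec` or a ready-made phi array.  An optional ``callback``
    receives (iteration, phi, energy) after every step.

    A collapsed contour (one region's effective mass gone) terminates the
    run with ``converged=False`` and a diagnostic instead of raising.
    """
    I = np.asarray(image, dtype=np.float64)
    if I.ndim != 2:
        raise ShapeMismatchError(f"image must be 2-D, got shape {I.shape}")
    if not np.all(np.isfinite(I)):
        raise NumericalBlowupError("image contains non-finite values")

    if isinstance(init, InitialContourSpec):
        phi = initialize_phi(init, I.shape)
    else:
        phi = np.asarray(init, dtype=np.float64).copy()
        if phi.shape != I.shape:
            raise ShapeMismatchError(
                f"initial phi shape {phi.shape} does not match image {I.shape}"
            )

    kernel_local = params.local_kernel()
    kernel_global = params.global_kernel()

    trace: List[EnergyBreakdown] = []
    deltas: List[int] = []
    converged = False
    diagnostic = ""
    n_iter = 0

    for it in range(1, params.max_iter + 1):
        M1, M2 = membership_fields(phi, params.eps)
        try:
            stats = compute_stats(I, M1, M2, params, kernel_local, kernel_global)
            force = force_field(I, phi, params, stats)
        except OneSidedRegionError as exc:
            diagnostic = f"iteration {it}: {exc}"
            break
        energy = total_energy(I, phi, params, stats, kernel_local, kernel_global)
        phi_next = step(phi, force, params.dt, iteration=it)
        deltas.append(zero_crossing_count_delta(phi, phi_next))
        trace.append(energy)
        phi = phi_next
        n_iter = it
        if callback is not None:
            callback(it, phi, energy)
        if len(deltas) >= params.stop_window and all(
            d < params.stop_pixels for d in deltas[-params.stop_window:]
        ):
            converged = True
            break

    mask = phi > 0
    if mask.all() or not mask.any():
        converged = False
        if not diagnostic:
            diagnostic = "final mask is one-sided (empty or full)"
    return SegmentationResult(
        mask=mask,
        phi_final=phi,
        energy_trace=trace,
        n_iter=n_iter,
        converged=converged,
        zero_crossing_deltas=deltas,
        diagnostic=diagnostic,
    )
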