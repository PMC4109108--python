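"""Region statistics, energy terms, and the pointwise evolution force.

The model drives a two-phase level-set contour by a weighted combination of
four data energies plus two geometric regularisers:

* global fitting  E_G  -- squared deviation of intensity from per-side means
  (the Chan--Vese data term when the window covers the whole image);
* local fitting   E_L  -- the region-scalable fitting energy: squared
  deviation from spatially varying windowed means f_i(x);
* global / local discriminant J_G, J_L -- an inverse Fisher criterion,
  (V_1 + V_2) / (C_1 - C_2)^2, the within-class scatter over the squared
  between-class mean separation;
* contour length  L    -- the co-area length of the zero level set;
* distance regularisation R -- (1/2) integral (|grad phi| - 1)^2, keeping phi
  near a signed distance profile without reinitialisation.

The total is  F = (1-w) E_G + w E_L + k [(1-w) J_G + w J_L] + nu L + mu R,
with w in [0,1] blending local against global information and k >= 0 weighing
the discriminant against the fitting terms.  Minimisation alternates: the
region statistics (f_i, C_i, N_i) are refit with phi frozen, then phi takes an
explicit gradient step with the statistics frozen.

Conventions.  Images are floats on [0, 255]; grid spacing is 1 pixel; phi > 0
marks the inside of the contour.  Image-valued window convolutions replicate
edge values; the window-mass integrals that define the discriminant means
C_i and effective counts N_i integrate over the image domain only, so near
the border the mass tapers below 1.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .errors import (
    DegenerateDiscriminantError,
    InvalidParameterError,
    OneSidedRegionError,
    ShapeMismatchError,
)
from .kernels import (
    DEFAULT_EPS,
    WindowKernel,
    dirac_eps,
    heaviside_eps,
    make_kernel,
)
from .stencils import curvature, laplacian

__all__ = [
    "RSDFParams",
    "RegionStats",
    "EnergyBreakdown",
    "membership_fields",
    "local_fitting_means",
    "region_means_counts",
    "discriminant_energy",
    "fitting_energy",
    "length_energy",
    "distreg_energy",
    "compute_stats",
    "total_energy",
    "force_field",
]

# relative threshold on (C1-C2)^2 below which the discriminant is degenerate
DEGENERATE_DISCRIMINANT_REL = 1e-6
# effective count below which a region is considered collapsed
COLLAPSED_REGION_COUNT = 1e-3
# denominator of the local-fitting-mean ratio below which f_i is undefined
FITTING_DENOMINATOR_FLOOR = 1e-8
# curvature bound used inside the flow: a unit grid cannot represent radii
# below one pixel, and the unbounded quotient is ill-conditioned on flats
CURVATURE_CLIP = 2.0


# --------------------------------------------------------------------------
# parameters
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RSDFParams:
    """All model weights and numeric controls.

    Parameters
    ----------
    w : float in [0, 1]
        Local-vs-global mixing weight; large w emphasises local information
        (appropriate for inhomogeneous images).
    k : float >= 0
        Weight of the discriminant terms relative to the fitting terms.
    nu : float >= 0
        Contour-length penalty; natural scale 0.001*255^2 .. 0.005*255^2 for
        images on [0, 255].
    mu : float > 0
        Distance-regularisation weight.  The explicit scheme requires the
        CFL-type bound mu * dt < 0.25, enforced at construction.
    lambda1, lambda2, lambda3, lambda4 : float >= 0
        Per-side fitting weights (global pair, then local pair).
    eps : float > 0
        Smoothing width of the Heaviside/Dirac pair (default 1.5).
    dt : float > 0
        Time step of the forward-Euler update (default 0.1).
    sigma_local : float
        Scale of the local window, in pixels.
    sigma_global : float or None
        Scale of the global window; ``None`` (the default) selects the exact
        whole-image limit, computed as plain means rather than a huge
        convolution.
    kernel_family : {"gaussian", "uniform"}
        Window family used for both scales.
    dr_dirac : bool
        If False (default), the distance-regularisation force acts on the
        whole grid, as in the classic reinitialisation-free formulation whose
        descent flow mu (lap phi - div(grad phi/|grad phi|)) it is; if True
        the force additionally carries a smoothed-Dirac factor, which
        confines it to a band around the contour and lets far-field pixels
        freeze at large |phi|.
    max_iter, stop_pixels, stop_window : int
        Iteration cap and the stopping rule: stop once fewer than
        `stop_pixels` grid points change sign per iteration for
        `stop_window` consecutive iterations.
    c0 : float
        Magnitude of the binary initial level set (+c0 inside, -c0 outside).
    """

    w: float = 0.98
    k: float = 0.3
    nu: float = 0.002 * 255.0**2
    mu: float = 2.0
    lambda1: float = 1.0
    lambda2: float = 1.0
    lambda3: float = 1.0
    lambda4: float = 1.0
    eps: float = DEFAULT_EPS
    dt: float = 0.1
    sigma_local: float = 3.0
    sigma_global: Optional[float] = None
    kernel_family: str = "gaussian"
    dr_dirac: bool = False
    max_iter: int = 1000
    stop_pixels: int = 10
    stop_window: int = 5
    c0: float = 2.0

    def __post_init__(self):
        if not 0.0 <= self.w <= 1.0:
            raise InvalidParameterError(f"w must lie in [0, 1], got {self.w}")
        if self.k < 0:
            raise InvalidParameterError(f"k must be >= 0, got {self.k}")
        if self.nu < 0:
            raise InvalidParameterError(f"nu must be >= 0, got {self.nu}")
        if self.mu <= 0:
            raise InvalidParameterError(f"mu must be > 0, got {self.mu}")
        if self.dt <= 0:
            raise InvalidParameterError(f"dt must be > 0, got {self.dt}")
        if self.mu * self.dt >= 0.25:
            raise InvalidParameterError(
                f"CFL condition violated: mu*dt = {self.mu * self.dt:.4g} "
                f"must be < 0.25 for the explicit scheme to be stable"
            )
        for name in ("lambda1", "lambda2", "lambda3", "lambda4"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        if self.eps <= 0:
            raise InvalidParameterError(f"eps must be > 0, got {self.eps}")
        if self.kernel_family not in ("gaussian", "uniform"):
            raise InvalidParameterError(
                f"kernel_family must be 'gaussian' or 'uniform', got {self.kernel_family!r}"
            )
        if self.sigma_local <= 0:
            raise InvalidParameterError("sigma_local must be > 0")
        if self.sigma_global is not None and self.sigma_global <= 0:
            raise InvalidParameterError("sigma_global must be > 0 or None")
        if self.max_iter < 1 or self.stop_window < 1 or self.stop_pixels < 0:
            raise InvalidParameterError("max_iter, stop_window must be >= 1; stop_pixels >= 0")
        if self.c0 <= 0:
            raise InvalidParameterError("c0 must be > 0")

    @property
    def global_window(self) -> bool:
        """True when the global branch uses the exact whole-image limit."""
        return self.sigma_global is None

    def with_overrides(self, **kwargs) -> "RSDFParams":
        return replace(self, **kwargs)

    def local_kernel(self) -> WindowKernel:
        return make_kernel(self.kernel_family, self.sigma_local)

    def global_kernel(self) -> Optional[WindowKernel]:
        if self.global_window:
            return None
        return make_kernel(self.kernel_family, self.sigma_global)


@dataclass
class RegionStats:
    """Fitted statistics of the two sides of the contour for a frozen phi.

    f1, f2 are the spatially varying local fitting means; C/N pairs are the
    scalar discriminant means and effective pixel counts at the local and
    global scales.
    """

    f1: np.ndarray
    f2: np.ndarray
    C1L: float
    C2L: float
    N1L: float
    N2L: float
    C1G: float
    C2G: float
    N1G: float
    N2G: float


@dataclass
class EnergyBreakdown:
    """The six energy terms and their weighted total."""

    E_G: float
    E_L: float
    J_G: float
    J_L: float
    L_len: float
    R_reg: float
    F_total: float

    @staticmethod
    def combine(E_G, E_L, J_G, J_L, L_len, R_reg, params: RSDFParams) -> "EnergyBreakdown":
        w, k = params.w, params.k
        F = (
            (1.0 - w) * E_G + w * E_L
            + k * ((1.0 - w) * J_G + w * J_L)
            + params.nu * L_len + params.mu * R_reg
        )
        return EnergyBreakdown(E_G, E_L, J_G, J_L, L_len, R_reg, F)


# --------------------------------------------------------------------------
# region statistics
# --------------------------------------------------------------------------

def _check_same_shape(*fields_):
    shapes = {np.asarray(f).shape for f in fields_}
    if len(shapes) != 1:
        raise ShapeMismatchError(f"fields must share one shape, got {sorted(shapes)}")


def membership_fields(phi: np.ndarray, eps: float = DEFAULT_EPS):
    """Soft inside/outside memberships M1 = H_eps(phi), M2 = 1 - M1."""
    M1 = heaviside_eps(phi, eps)
    return M1, 1.0 - M1


def local_fitting_means(I, M1, M2, kernel: WindowKernel):
    """Spatially varying windowed means f_i = K * (M_i I) / K * M_i.

    Where the denominator K * M_i falls below a tiny floor no pixel of side i
    lies within window reach, and the ratio is undefined; there f_i is set to
    the windowed image average (K * I), so the local fitting difference
    (I - f_1)^2 - (I - f_2)^2 vanishes wherever one-sided local information
    is absent and the contour is steered by the global terms alone.
    """
    I = np.asarray(I, dtype=np.float64)
    _check_same_shape(I, M1, M2)
    KI1 = kernel.convolve(I * M1)
    KI2 = kernel.convolve(I * M2)
    K1 = kernel.convolve(np.asarray(M1, dtype=np.float64))
    K2 = kernel.convolve(np.asarray(M2, dtype=np.float64))
    # M1 + M2 = 1, so the windowed image average costs no extra convolution
    KI = KI1 + KI2

    out = []
    for KIi, Ki in ((KI1, K1), (KI2, K2)):
        bad = Ki < FITTING_DENOMINATOR_FLOOR
        fi = np.divide(KIi, Ki, out=np.zeros_like(KIi), where=~bad)
        if np.any(bad):
            fi[bad] = KI[bad]
        out.append(fi)
    return out[0], out[1]


def region_means_counts(I, M1, M2, kernel: Optional[WindowKernel] = None):
    """Scalar discriminant means C_i and effective counts N_i.

    With ``kernel=None`` (global window) these are the plain soft means
    C_i = sum(I M_i) / sum(M_i) and counts N_i = sum(M_i).  With a finite
    window they are the window-mass-weighted analogues: each pixel x is
    weighted by m(x) = sum_{y in domain} K(x - y), which equals 1 in the
    interior and tapers near the border.

    Raises
    ------
    OneSidedRegionError
        If either effective count is (numerically) zero -- the contour has
        collapsed to one side.
    """
    I = np.asarray(I, dtype=np.float64)
    _check_same_shape(I, M1, M2)
    if kernel is None:
        mass = 1.0
    else:
        mass = kernel.domain_mass(I.shape)
    N1 = float(np.sum(mass * M1))
    N2 = float(np.sum(mass * M2))
    if N1 < COLLAPSED_REGION_COUNT or N2 < COLLAPSED_REGION_COUNT:
        raise OneSidedRegionError(
            f"contour collapsed: effective counts N1={N1:.3g}, N2={N2:.3g}"
        )
    C1 = float(np.sum(mass * I * M1)) / N1
    C2 = float(np.sum(mass * I * M2)) / N2
    return C1, C2, N1, N2


def compute_stats(I, M1, M2, params: RSDFParams,
                  kernel_local: Optional[WindowKernel] = None,
                  kernel_global: Optional[WindowKernel] = None) -> RegionStats:
    """Refit every region statistic for the current memberships.

    Kernels may be passed in to avoid rebuilding them each iteration.
    """
    if kernel_local is None:
        kernel_local = params.local_kernel()
    if kernel_global is None and not params.global_window:
        kernel_global = params.global_kernel()

    C1G, C2G, N1G, N2G = region_means_counts(I, M1, M2, kernel_global)
    C1L, C2L, N1L, N2L = region_means_counts(I, M1, M2, kernel_local)
    f1, f2 = local_fitting_means(I, M1, M2, kernel_local)
    return RegionStats(f1, f2, C1L, C2L, N1L, N2L, C1G, C2G, N1G, N2G)


# --------------------------------------------------------------------------
# energy terms
# --------------------------------------------------------------------------

def discriminant_energy(I, M1, M2, C1, C2, N1, N2) -> float:
    """Inverse Fisher criterion J = (V1 + V2) / (C1 - C2)^2 with
    V_i = sum((I - C_i)^2 M_i) / (N_i - 1).

    Raises ``DegenerateDiscriminantError`` when the means coincide (within a
    relative threshold) and ``OneSidedRegionError`` when an effective count
    does not exceed 1.
    """
    I = np.asarray(I, dtype=np.float64)
    _check_same_shape(I, M1, M2)
    if N1 <= 1.0 or N2 <= 1.0:
        raise OneSidedRegionError(
            f"effective counts must exceed 1 for the variance estimate, "
            f"got N1={N1:.3g}, N2={N2:.3g}"
        )
    rng = float(I.max() - I.min())
    tau = DEGENERATE_DISCRIMINANT_REL * (rng * rng if rng > 0 else 1.0)
    sep = (C1 - C2) ** 2
    if sep < tau:
        raise DegenerateDiscriminantError(
            f"region means coincide: (C1-C2)^2 = {sep:.3g} < {tau:.3g}"
        )
    V1 = float(np.sum((I - C1) ** 2 * M1)) / (N1 - 1.0)
    V2 = float(np.sum((I - C2) ** 2 * M2)) / (N2 - 1.0)
    return (V1 + V2) / sep


def fitting_energy(I, M1, M2, f1, f2, kernel: Optional[WindowKernel] = None,
                   lambda1: float = 1.0, lambda2: float = 1.0) -> float:
    """Region-scalable fitting energy.

    With ``kernel=None`` (global window) and scalar means this is the
    Chan--Vese data term  sum_i lambda_i sum((I - C_i)^2 M_i).  With a finite
    window and mean fields f_i it is the double sum
    sum_i lambda_i sum_x sum_y K(x-y) (I(y) - f_i(x))^2 M_i(y),
    evaluated by expanding the square into three window convolutions.
    Scalar means with a finite window give the window-mass-weighted
    Chan--Vese term (the form whose variation the global force uses).
    """
    I = np.asarray(I, dtype=np.float64)
    _check_same_shape(I, M1, M2)
    lam = (float(lambda1), float(lambda2))

    if kernel is None:
        total = 0.0
        for li, fi, Mi in zip(lam, (f1, f2), (M1, M2)):
            total += li * float(np.sum((I - fi) ** 2 * Mi))
        return total

    total = 0.0
    for li, fi, Mi in zip(lam, (f1, f2), (M1, M2)):
        fi = np.asarray(fi, dtype=np.float64)
        if fi.ndim == 0:
            mass = kernel.domain_mass(I.shape)
            total += li * float(np.sum(mass * (I - fi) ** 2 * Mi))
            continue
        _check_same_shape(I, fi)
        Mi = np.asarray(Mi, dtype=np.float64)
        A = kernel.convolve(I * I * Mi)  # sum_y K (I^2 M_i)
        B = kernel.convolve(I * Mi)      # sum_y K (I M_i)
        D = kernel.convolve(Mi)          # sum_y K M_i
        total += li * float(np.sum(A - 2.0 * fi * B + fi * fi * D))
    return total


def length_energy(phi, eps: float = DEFAULT_EPS) -> float:
    """Co-area contour length  sum delta_eps(phi) |grad phi|  (central
    differences, replicate boundary)."""
    from .stencils import gradient  # local import avoids cycle at module load

    px, py = gradient(phi)
    return float(np.sum(dirac_eps(phi, eps) * np.hypot(px, py)))


def distreg_energy(phi) -> float:
    """Distance-regularisation energy (1/2) sum (|grad phi| - 1)^2."""
    from .stencils import gradient

    px, py = gradient(phi)
    return 0.5 * float(np.sum((np.hypot(px, py) - 1.0) ** 2))


def total_energy(I, phi, params: RSDFParams, stats: RegionStats,
                 kernel_local: Optional[WindowKernel] = None,
                 kernel_global: Optional[WindowKernel] = None) -> EnergyBreakdown:
    """Evaluate every term of the combined functional for frozen statistics.

    A degenerate discriminant (coincident means) contributes zero for the
    iteration rather than raising, matching the guard used in the force.
    """
    if kernel_local is None:
        kernel_local = params.local_kernel()
    if kernel_global is None and not params.global_window:
        kernel_global = params.global_kernel()

    M1, M2 = membership_fields(phi, params.eps)
    E_G = fitting_energy(I, M1, M2, stats.C1G, stats.C2G, kernel_global,
                         params.lambda1, params.lambda2)
    E_L = fitting_energy(I, M1, M2, stats.f1, stats.f2, kernel_local,
                         params.lambda3, params.lambda4)

    def _J(C1, C2, N1, N2):
        try:
            return discriminant_energy(I, M1, M2, C1, C2, N1, N2)
        except DegenerateDiscriminantError:
            return 0.0

    J_G = _J(stats.C1G, stats.C2G, stats.N1G, stats.N2G)
    J_L = _J(stats.C1L, stats.C2L, stats.N1L, stats.N2L)
    L_len = length_energy(phi, params.eps)
    R_reg = distreg_energy(phi)
    return EnergyBreakdown.combine(E_G, E_L, J_G, J_L, L_len, R_reg, params)


# --------------------------------------------------------------------------
# gradient-flow force
# --------------------------------------------------------------------------

def _discriminant_force_branch(I, C1, C2, N1, N2, tau) -> np.ndarray:
    """Pointwise bracket  [(I-C1)^2/(N1-1) - (I-C2)^2/(N2-1)] / (C1-C2)^2,
    with the collapse guards applied."""
    if N1 < COLLAPSED_REGION_COUNT or N2 < COLLAPSED_REGION_COUNT:
        raise OneSidedRegionError(
            f"contour collapsed in discriminant force: N1={N1:.3g}, N2={N2:.3g}"
        )
    sep = (C1 - C2) ** 2
    if sep < tau:
        # coincident means: the discriminant provides no direction this step
        return np.zeros_like(I)
    d1 = N1 - 1.0 if N1 > 1.0 + 1e-6 else 1.0
    d2 = N2 - 1.0 if N2 > 1.0 + 1e-6 else 1.0
    return ((I - C1) ** 2 / d1 - (I - C2) ** 2 / d2) / sep


def force_field(I, phi, params: RSDFParams, stats: RegionStats) -> np.ndarray:
    """Right-hand side of the gradient flow  d(phi)/dt  for frozen statistics.

    Four contributions:

    * fitting:       -delta_eps(phi) [ (1-w)(l1 (I-C1G)^2 - l2 (I-C2G)^2)
                                       + w (l3 (I-f1)^2 - l4 (I-f2)^2) ]
    * discriminant:  -k delta_eps(phi) [ (1-w) B_G + w B_L ], with B the
      bracket of ``_discriminant_force_branch`` at the matching scale;
    * length:        nu delta_eps(phi) div(grad phi / |grad phi|);
    * distance reg.: mu (delta factor, see ``dr_dirac``)
                        (lap phi - div(grad phi / |grad phi|)).
    """
    I = np.asarray(I, dtype=np.float64)
    phi = np.asarray(phi, dtype=np.float64)
    _check_same_shape(I, phi)
    w, k = params.w, params.k
    delta = dirac_eps(phi, params.eps)

    fit = (1.0 - w) * (
        params.lambda1 * (I - stats.C1G) ** 2
        - params.lambda2 * (I - stats.C2G) ** 2
    ) + w * (
        params.lambda3 * (I - stats.f1) ** 2
        - params.lambda4 * (I - stats.f2) ** 2
    )
    force = -delta * fit

    if k > 0.0:
        rng = float(I.max() - I.min())
        tau = DEGENERATE_DISCRIMINANT_REL * (rng * rng if rng > 0 else 1.0)
        bg = _discriminant_force_branch(I, stats.C1G, stats.C2G,
                                        stats.N1G, stats.N2G, tau)
        bl = _discriminant_force_branch(I, stats.C1L, stats.C2L,
                                        stats.N1L, stats.N2L, tau)
        force -= k * delta * ((1.0 - w) * bg + w * bl)

    kappa = curvature(phi, clip=CURVATURE_CLIP)
    if params.nu > 0.0:
        force += params.nu * delta * kappa
    dr = laplacian(phi) - kappa
    force += params.mu * (delta * dr if params.dr_dirac else dr)
    return force
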