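"""One two-phase active-contour pass on a restricted sub-region.

The model
---------
A curve C is the zero level set of phi : Omega -> R, with the *inside*
defined as {phi < 0}.  Restricted to the current base region (binary mask
M), the pass minimizes the piecewise-constant two-phase energy

    E(c1, c2, phi) = lambda1 * sum (I - c1)^2 H(-phi) M
                   + lambda2 * sum (I - c2)^2 H( phi) M
                   + mu * sum g delta(phi) |grad phi|          (weighted length)
                   + v  * sum g H(-phi)                        (weighted area)
                   + alpha * sum (|grad phi| - 1)^2 / 2        (SDF penalty)

where H/delta are the arctangent-regularized Heaviside/Dirac pair, g is
the edge indicator, and c1/c2 are the mean intensities of the inner and
outer sub-regions.  The SDF penalty keeps phi close to a signed distance
function during the evolution, so no re-initialization step is ever
needed, and the initial phi may be an arbitrary binary +/-rho field.

Minimization alternates closed-form updates of (c1, c2) with explicit
Euler steps phi <- phi + tau * Q(phi) on the gradient flow

    Q(phi) = delta(phi) [ lambda1 (I-c1)^2 M - lambda2 (I-c2)^2 M + v g ]
           + mu * d/d(phi)[ -g delta(phi) |grad phi| ]
           + alpha [ div( (1 - 1/|grad phi|) grad phi ) ]

which is the negative discrete energy gradient, exact in the grid
interior.  The length term's continuum limit is the familiar
mu delta(phi) div(g grad phi / |grad phi|).

Intensity scale
---------------
Intensities are nominally 0-255.  The data fidelity terms divide both I
and c1/c2 by ``AlgoParams.intensity_scale`` (default 255), so that the
default weights lambda1 = lambda2 = 100 with tau = 1 produce updates of
order 1 per iteration -- the regime in which the penalty (tau*alpha = 0.2)
can actually maintain the signed-distance property.  Initialization
offsets (kappa) and the reported region means stay on the raw scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .errors import DegenerateRegionError, NumericalStabilityError, ParameterError
from .numerics import sdf_penalty_diffusion, smooth_dirac, smooth_heaviside
from .preprocessing import as_image_field

__all__ = [
    "AlgoParams",
    "Termination",
    "PassResult",
    "init_level_set",
    "region_means",
    "total_energy",
    "gradient_flow",
    "evolve_pass",
]


class Termination(str, Enum):
    """Why a pass stopped iterating."""

    STATIONARY = "stationary"
    MAX_ITERS = "max_iters"
    DEGENERATE_EMPTY_INNER = "degenerate_empty_inner"
    DEGENERATE_EMPTY_OUTER = "degenerate_empty_outer"


@dataclass(frozen=True)
class AlgoParams:
    """Weights and numerical constants of the two-phase evolution.

    Defaults are the printed reference regime: lambda1 = lambda2 = 100,
    mu = 200/225^2, v = 0, alpha = 0.2/tau with tau = 1, eps = 1.5,
    rho = 4*eps, kappa = 1.  The explicit scheme requires
    tau * alpha < 1/4 for stable level-set evolution; violating it is
    rejected at construction.

    Attributes
    ----------
    lambda1, lambda2 : float
        Weights of the inner/outer region fidelity terms.
    mu : float
        Weight of the edge-weighted contour length term.
    v : float
        Weight of the edge-weighted inner area term (0 disables it;
        positive shrinks contours initialized outside the object).
    alpha : float
        Weight of the signed-distance penalty.
    tau : float
        Explicit Euler time step.
    eps : float
        Width of the smoothed Heaviside/Dirac pair.
    eps_d : float
        Division guard inside gradient magnitudes.
    rho : float
        Magnitude of the binary initial level set (+/- rho).
    kappa : float
        Intensity offset above the regional minimum used to seed the
        initial outside set (raw intensity units).  Must exceed the
        residual intensity spread that denoising leaves on a homogeneous
        region, or the seed degenerates to isolated outlier pixels that
        the regularizers absorb before the evolution can respond; the
        default is about three times the residual standard deviation the
        default denoiser leaves on plateaus carrying 5% uniform noise.
    intensity_scale : float
        Scale by which intensities are divided inside the data terms.
    mean_weighting : str
        How the evolving region means are computed: ``"sharp"`` (default)
        uses the binary partition {phi < 0}, ``"smoothed"`` the
        Heaviside-weighted means of :func:`region_means`.  The smoothed
        Cauchy-kernel weights mix a fixed ~8% of the complementary region
        into each mean regardless of distance (H_eps(-rho) with rho = 4 eps
        is 0.078), which collapses the darkest-seed initialization on
        large domains; the sharp means are the H -> binary limit and keep
        the seed meaningful.
    max_iters_per_pass : int
        Cap on Euler steps per pass.  Sized to cover the transit time of
        a pixel through the Dirac well, ~pi (rho^3/3 + eps^2 rho)/(eps F),
        for the weakest data force F of interest.
    stationary_window : int
        Number of consecutive quiet iterations (inside-pixel set
        unchanged) required before the pass may be declared stationary.
        On top of the window, the pass must outlast the soonest predicted
        sign flip: a pixel whose data term prefers the other side crosses
        the Dirac well of the flow in roughly
        pi (|phi|^3/3 + eps^2 |phi|) / (eps |F| tau) iterations, where F
        is its data-force coefficient; the quiet requirement is extended
        by the minimum such transit time so that the slow pre-cascade
        latency of weakly forced pixels is never mistaken for
        convergence.
    """

    lambda1: float = 100.0
    lambda2: float = 100.0
    mu: float = 200.0 / 225.0**2
    v: float = 0.0
    alpha: float = 0.2
    tau: float = 1.0
    eps: float = 1.5
    eps_d: float = 1e-8
    rho: float = 6.0
    kappa: float = 4.0
    intensity_scale: float = 255.0
    mean_weighting: str = "sharp"
    max_iters_per_pass: int = 800
    stationary_window: int = 3

    def __post_init__(self) -> None:
        for name in ("lambda1", "lambda2", "tau", "eps", "eps_d", "rho", "kappa", "intensity_scale"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive, got {getattr(self, name)}")
        if self.mu < 0:
            raise ParameterError(f"mu must be non-negative, got {self.mu}")
        if self.alpha <= 0:
            raise ParameterError(f"alpha must be positive, got {self.alpha}")
        if self.tau * self.alpha >= 0.25:
            raise ParameterError(
                f"tau*alpha = {self.tau * self.alpha:g} violates the stability "
                "condition tau*alpha < 1/4 for stable level set evolution"
            )
        if self.mean_weighting not in ("sharp", "smoothed"):
            raise ParameterError(
                f"mean_weighting must be 'sharp' or 'smoothed', got {self.mean_weighting!r}"
            )
        if self.max_iters_per_pass < 1:
            raise ParameterError("max_iters_per_pass must be a positive integer")
        if self.stationary_window < 1:
            raise ParameterError("stationary_window must be a positive integer")


@dataclass
class PassResult:
    """Outcome of one converged (or degenerated) two-phase pass.

    ``inner_mask`` and ``outer_mask`` partition the parent mask exactly:
    disjoint, union equal to the parent.  ``c1``/``c2`` are the plain mean
    intensities of the denoised image over the final binary inner/outer
    masks (NaN when the corresponding region is empty).
    """

    phi_final: np.ndarray
    inner_mask: np.ndarray
    outer_mask: np.ndarray
    c1: float
    c2: float
    n_iters: int
    terminated_by: Termination
    energy_trace: list[float] = field(default_factory=list)
    initial_inner_mask: np.ndarray | None = None

    @property
    def inner_area(self) -> int:
        return int(self.inner_mask.sum())

    @property
    def outer_area(self) -> int:
        return int(self.outer_mask.sum())


def _as_mask(mask, shape) -> np.ndarray:
    m = np.asarray(mask)
    if m.shape != shape:
        raise ParameterError(f"mask shape {m.shape} does not match image shape {shape}")
    return m.astype(bool)


def _as_field(image) -> np.ndarray:
    """2-D finite intensity grid, any size -- for pointwise operations.

    Stencil-based operations go through the stricter
    :func:`~mpcontour.preprocessing.as_image_field` (>= 3x3) instead.
    """
    arr = np.asarray(image, dtype=float)
    if arr.ndim != 2:
        raise ParameterError(f"expected a 2-D field, got ndim={arr.ndim}")
    if not np.all(np.isfinite(arr)):
        raise ParameterError("field contains NaN or Inf values")
    return arr


def init_level_set(image, mask, rho: float = 6.0, kappa: float = 1.0) -> np.ndarray:
    """Binary initial level set from the darkest pixels of the masked region.

    Returns +rho outside the mask and on pixels darker than the regional
    minimum plus ``kappa`` (these seed the *outside*), -rho everywhere
    else.  Starting the contour in the darkest part of the region means
    local optima are spent on the least informative intensities, leaving
    the brighter structures for later passes.
    """
    if rho <= 0 or kappa <= 0:
        raise ParameterError(f"rho and kappa must be positive, got rho={rho}, kappa={kappa}")
    img = _as_field(image)
    m = _as_mask(mask, img.shape)
    if not m.any():
        raise DegenerateRegionError("inner", "cannot initialize a level set on an empty mask")
    vmin = img[m].min()
    outside = (~m) | (img < vmin + kappa)
    return np.where(outside, rho, -rho).astype(float)


def region_means(
    image,
    phi,
    mask,
    eps: float = 1.5,
    min_area: float = 0.5,
) -> tuple[float, float]:
    """Smoothed-Heaviside weighted mean intensities of the two phases.

    c1 weights pixels by H_eps(-phi) * M (inside), c2 by H_eps(phi) * M
    (outside).  Both lie between the min and max intensity over the mask.
    If either weighted area falls below ``min_area`` pixel-equivalents the
    corresponding region is declared empty and
    :class:`~mpcontour.errors.DegenerateRegionError` is raised -- the
    smoothed Heaviside is never exactly zero, so a hard threshold is
    needed.
    """
    img = _as_field(image)
    p = np.asarray(phi, dtype=float)
    m = _as_mask(mask, img.shape).astype(float)
    w_in = smooth_heaviside(-p, eps) * m
    w_out = smooth_heaviside(p, eps) * m
    a_in = float(w_in.sum())
    a_out = float(w_out.sum())
    if a_in < min_area:
        raise DegenerateRegionError("inner")
    if a_out < min_area:
        raise DegenerateRegionError("outer")
    c1 = float((img * w_in).sum() / a_in)
    c2 = float((img * w_out).sum() / a_out)
    return c1, c2


def sharp_region_means(image, phi, mask) -> tuple[float, float]:
    """Mean intensities over the binary partition {phi < 0} / {phi >= 0} of the mask.

    The limit of :func:`region_means` as the Heaviside sharpens to a step.
    Raises :class:`~mpcontour.errors.DegenerateRegionError` when either
    side of the partition is empty.
    """
    img = _as_field(image)
    p = np.asarray(phi, dtype=float)
    m = _as_mask(mask, img.shape)
    inner = (p < 0) & m
    outer = m & ~inner
    if not inner.any():
        raise DegenerateRegionError("inner")
    if not outer.any():
        raise DegenerateRegionError("outer")
    return float(img[inner].mean()), float(img[outer].mean())


def _grad_mag_forward(phi: np.ndarray, eps_d: float) -> np.ndarray:
    from .numerics import finite_differences

    gx = finite_differences(phi, "x", "forward")
    gy = finite_differences(phi, "y", "forward")
    return np.sqrt(gx * gx + gy * gy + eps_d)


def total_energy(phi, image, g, mask, c1: float, c2: float, params: AlgoParams) -> float:
    """Discrete two-phase energy E(c1, c2, phi) -- see the module docstring.

    Gradient magnitudes in the length and penalty terms use forward
    differences with ``eps_d`` inside the square root, matching the
    discretization whose negative gradient :func:`gradient_flow` returns.
    Finite and non-negative whenever ``v >= 0``.
    """
    img = as_image_field(image)
    p = np.asarray(phi, dtype=float)
    m = _as_mask(mask, img.shape).astype(float)
    gf = np.asarray(g, dtype=float)
    u = img / params.intensity_scale
    k1 = c1 / params.intensity_scale
    k2 = c2 / params.intensity_scale
    h_in = smooth_heaviside(-p, params.eps)
    h_out = smooth_heaviside(p, params.eps)
    d = smooth_dirac(p, params.eps)
    s = _grad_mag_forward(p, params.eps_d)
    e_f1 = params.lambda1 * float(((u - k1) ** 2 * h_in * m).sum())
    e_f2 = params.lambda2 * float(((u - k2) ** 2 * h_out * m).sum())
    e_len = params.mu * float((gf * d * s).sum())
    e_area = params.v * float((gf * h_in).sum())
    e_pen = params.alpha * 0.5 * float(((s - 1.0) ** 2).sum())
    return e_f1 + e_f2 + e_len + e_area + e_pen


def gradient_flow(phi, image, g, mask, c1: float, c2: float, params: AlgoParams) -> np.ndarray:
    """Right-hand side Q(phi) of the evolution d(phi)/dt = Q(phi).

    Assembled so that -Q is exactly the variation of :func:`total_energy`
    with respect to phi in the grid interior (c1, c2 held fixed): data
    and area terms are pointwise exact; the weighted-length term is the
    discrete gradient of mu * sum g delta(phi) |grad phi| -- the backward
    divergence of the Dirac-weighted normalized flux minus the
    delta'(phi) |grad phi| contribution, whose continuum limit is the
    familiar mu delta(phi) div(g grad phi / |grad phi|); the penalty uses
    the adjoint forward/backward pairing of its diffusion form.
    """
    from .numerics import finite_differences

    img = as_image_field(image)
    p = np.asarray(phi, dtype=float)
    m = _as_mask(mask, img.shape).astype(float)
    gf = np.asarray(g, dtype=float)
    u = img / params.intensity_scale
    k1 = c1 / params.intensity_scale
    k2 = c2 / params.intensity_scale
    d = smooth_dirac(p, params.eps)
    data = params.lambda1 * (u - k1) ** 2 - params.lambda2 * (u - k2) ** 2
    # Weighted length: exact discrete gradient of sum g delta(phi) s with
    # s the forward-difference magnitude (eps_d inside the square root).
    gx = finite_differences(p, "x", "forward")
    gy = finite_differences(p, "y", "forward")
    s = np.sqrt(gx * gx + gy * gy + params.eps_d)
    w = gf * d
    length_term = (
        finite_differences(w * gx / s, "x", "backward")
        + finite_differences(w * gy / s, "y", "backward")
        + 2.0 * p * d / (p * p + params.eps**2) * gf * s  # -g delta'(phi) s
    )
    q = (
        d * (data * m + params.v * gf)
        + params.mu * length_term
        + params.alpha * sdf_penalty_diffusion(p, params.eps_d)
    )
    if not np.all(np.isfinite(q)):
        raise NumericalStabilityError("NaN/Inf in gradient flow assembly")
    return q


def evolve_pass(image, g, mask, params: AlgoParams | None = None) -> PassResult:
    """Run one full two-phase pass to convergence on the masked region.

    Initializes phi from the darkest pixels, then alternates mean updates
    (c1, c2) with explicit Euler steps until the inside-pixel set
    {phi < 0} within the mask is unchanged for ``stationary_window``
    consecutive iterations, the iteration cap is reached, or a region
    degenerates (empties).  Deterministic: identical inputs give
    bit-identical results.
    """
    params = params or AlgoParams()
    img = as_image_field(image)
    m = _as_mask(mask, img.shape)
    phi = init_level_set(img, m, params.rho, params.kappa)
    init_inner = (phi < 0) & m
    inside = init_inner.copy()

    def _finish(term: Termination, n: int, trace: list[float]) -> PassResult:
        inner = (phi < 0) & m
        outer = m & ~inner
        c1f = float(img[inner].mean()) if inner.any() else float("nan")
        c2f = float(img[outer].mean()) if outer.any() else float("nan")
        return PassResult(phi, inner, outer, c1f, c2f, n, term, trace, init_inner)

    if not inside.any():
        return _finish(Termination.DEGENERATE_EMPTY_INNER, 0, [])
    if inside.sum() == m.sum():
        return _finish(Termination.DEGENERATE_EMPTY_OUTER, 0, [])

    trace: list[float] = []
    stable = 0
    horizon = 0.0  # latched forecast of the soonest future sign flip
    term = Termination.MAX_ITERS
    n = 0
    for it in range(1, params.max_iters_per_pass + 1):
        try:
            if params.mean_weighting == "sharp":
                c1, c2 = sharp_region_means(img, phi, m)
            else:
                c1, c2 = region_means(img, phi, m, params.eps)
        except DegenerateRegionError as err:
            term = (
                Termination.DEGENERATE_EMPTY_INNER
                if err.side == "inner"
                else Termination.DEGENERATE_EMPTY_OUTER
            )
            break
        trace.append(total_energy(phi, img, g, m, c1, c2, params))
        q = gradient_flow(phi, img, g, m, c1, c2, params)
        phi = phi + params.tau * q
        if not np.all(np.isfinite(phi)):
            raise NumericalStabilityError(f"NaN/Inf in level set after Euler step {it}")
        n = it
        remaining = params.max_iters_per_pass - it
        horizon = max(horizon - 1.0, _soonest_flip(phi, q, m, remaining, params))
        new_inside = (phi < 0) & m
        if np.array_equal(new_inside, inside):
            stable += 1
            if stable >= params.stationary_window + horizon:
                term = Termination.STATIONARY
                break
        else:
            stable = 0
            inside = new_inside
        if not inside.any():
            term = Termination.DEGENERATE_EMPTY_INNER
            break
        if inside.sum() == m.sum():
            term = Termination.DEGENERATE_EMPTY_OUTER
            break
    return _finish(term, n, trace)


def _soonest_flip(
    phi: np.ndarray, q: np.ndarray, m: np.ndarray, remaining: int, params: AlgoParams
) -> float:
    """Forecast, in iterations, of the soonest sign flip still to come.

    A quiet spell says nothing about convergence while some pixel is
    still in transit toward zero: the Dirac factor throttles its drift,
    so a pixel moving at rate |q| from level |phi| needs about

        T = (|phi|^3/3 + eps^2 |phi|) / ((phi^2 + eps^2) |q| tau)

    iterations to cross -- the exact transit time of
    d(phi)/dt = -delta_eps(phi) F for a constant force coefficient F
    inferred from the current rate.  Only pixels outside the well core
    (|phi| >= 2 eps) are forecast: interface pixels held in balance by
    the regularizers would otherwise signal perpetual imminence, while a
    genuine well-core drifter flips (and resets the quiet counter)
    within its own short transit.  Forecasts beyond the remaining
    iteration budget cannot be realized within this pass and are
    ignored.  The caller latches the returned value and counts it down,
    bridging the interval in which an en-route cohort has left the
    forecast zone but not yet crossed zero.
    """
    a = np.abs(phi)
    cand = m & (phi * q < 0) & (np.abs(q) > 0) & (a >= 2.0 * params.eps)
    if not cand.any():
        return 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        transit = (a**3 / 3.0 + params.eps**2 * a) / (
            (phi * phi + params.eps**2) * np.abs(q) * params.tau
        )
    live = transit[cand]
    live = live[np.isfinite(live) & (live < remaining)]
    if live.size == 0:
        return 0.0
    return 1.5 * float(live.min())
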