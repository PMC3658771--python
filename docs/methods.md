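# Methods

This note records the model, the numerical scheme, the tunable
parameters and the design choices behind `mpcontour`, including the
places where the design was genuinely open and what was decided.

## Model and assumptions

The pipeline assumes images whose informative structure is a nested
hierarchy of increasingly bright regions with reasonably sharp
boundaries, on a nominal 8-bit (0–255) intensity scale. Each pass
solves a two-phase piecewise-constant segmentation problem restricted to
the current base region: the data terms score every pixel against the
inner and outer mean intensities, an edge-weighted length term
regularizes the contour, an optional edge-weighted area term can
accelerate shrinkage (off by default, `v = 0`), and an internal penalty
`α ∫ ½(|∇φ|−1)²` keeps the level-set field near a signed distance
function throughout, which is what allows the crude binary
initialization and removes any re-initialization step. Only the inner
(brighter) sub-region is ever re-split, so the recursion produces a
path-shaped inclusion tree; the darker side of each split is final.
Starting each pass from the region's darkest pixels places the
unavoidable local optima in the least informative intensities and
reserves the bright structures for later, finer passes.

## Preprocessing

Denoising minimizes the ROF total-variation energy
`∫|∇I| + λ∫(I₀−I)²` by explicit gradient descent on its Euler–Lagrange
equation, with the fidelity term handled semi-implicitly (so the update
is stable for any λ and converges to the input as λ → ∞). Gradient
magnitudes are regularized by the same guard `ε_d` used everywhere else.
The denoised field is clamped to the input's range and, in the pipeline,
rounded back onto the 8-bit integer grid: the initialization offset κ
selects whole quantization bins, and a region that is uniform to better
than half an intensity unit becomes exactly constant — the natural
termination granularity for an isocontour decomposition of 8-bit
images.

The pipeline default `λ = 0.02` with 300 steps of size 0.1 is calibrated
to the 5%-uniform-noise study condition: the admitted residual deviation
(≈ 1/(2λ) = 25 units) covers the ±12.75-unit noise, flattening plateaus
into large near-constant facets while leaving 50+-unit edges sharp. For
clean or lightly noisy inputs a larger λ (0.1) with fewer iterations
preserves corners better; the `rof_denoise` function itself defaults to
that gentler regime. The residual plateau spread after the default
denoiser is σ ≈ 1.2 intensity units — the quantity κ must dominate (see
below).

## Intensity scale of the data terms

The reference weight regime is λ₁ = λ₂ = 100, μ = 200/225², v = 0,
τ = 1, α = 0.2/τ, ε = 1.5, ρ = 4ε. These weights are mutually consistent
only if the data terms act on intensities of order one: with raw 0–255
values, λ(I−c)² reaches 10⁶ and a single Euler step throws φ to ±10⁴,
turning the evolution into one-shot thresholding that the penalty
(τα = 0.2 per step) can never regularize. The data fidelity terms
therefore divide intensities by `intensity_scale` (255 by default);
initialization offsets, reported means, denoising and the edge
indicator stay on the raw scale. Under this convention data forces are
O(1–20) per step, the explicit scheme is stable, and the penalty is a
meaningful fraction of the dynamics.

## Region means

The evolving means are computed over the binary partition {φ < 0} by
default (`mean_weighting="sharp"`). The smoothed alternative — weights
`H_ε(∓φ)` as in the energy — is available, but the Cauchy-tailed
arctangent Heaviside assigns weight H_ε(−ρ) ≈ 0.078 to *every* pixel of
the opposite region regardless of distance, so on a 16k-pixel domain a
small darkest-pixel seed contributes ~6% of its own mean: c₁ ≈ c₂ at
initialization and the darkest-first recursion cannot start. The sharp
means are the H → step limit of the same formulas and keep the seed
meaningful; `region_means` retains the smoothed contract for callers
who want it.

## Initialization

φ₀ is binary: +ρ outside the mask and on pixels with
`I < min(I|mask) + κ`, −ρ elsewhere. κ (default 4.0) must exceed the
residual intensity spread the denoiser leaves on homogeneous regions
(≈ 3σ with σ ≈ 1.2 under the default denoiser); a κ at or below the
residual spread reduces the seed to a few isolated extreme pixels,
which the curvature and penalty terms absorb within ~5 iterations —
long before the data cascade (tens of iterations, see next section) can
respond — and the recursion aborts early. For exactly flat darkest
regions (clean synthetic backgrounds, black mammogram borders) any
small κ behaves identically.

## Time stepping, stationarity, termination

Explicit Euler with τ = 1 under the stability bound τα < ¼ (enforced at
construction and at configuration load). Each pass alternates a mean
update with one Euler step.

A pixel parked at φ = ±ρ whose data term prefers the other side crosses
zero only after the Dirac factor lets it: integrating
dφ/dt = −δ_ε(φ)·F gives a transit time of
`π(|φ|³/3 + ε²|φ|)/(ε F τ)` iterations — several hundred for weak
contrasts. A pass therefore must not be declared stationary merely
because the inside set has been quiet for a few iterations: the
stationarity detector requires the inside set unchanged for
`stationary_window` (3) consecutive iterations *plus* the soonest
predicted sign flip, computed per iteration from each drifting pixel's
current rate and level via the transit integral (pixels inside the well
core |φ| < 2ε are excluded — if they are genuinely moving they flip and
reset the quiet counter; if they are pinned at the interface they would
otherwise forecast perpetual imminence). The forecast is latched and
counted down to bridge the interval in which a cohort has left the
forecast zone but not yet crossed zero. `max_iters_per_pass` (800) is
sized to the transit time of the weakest contrast worth resolving
(≈ 30 intensity units).

The recursion over passes ends when

* a pass degenerates — its inner or outer region empties (a constant
  region degenerates immediately: every pixel is within κ of the
  minimum, so φ₀ ≡ +ρ);
* a pass peels nothing (inner region equals its parent); or
* the converged split's contrast falls below the model's own holding
  floor: a pixel midway between the means feels at most
  `δ_ε(0)·λ·((c₁−c₂)/S)²` of data force, so when
  `|c₁−c₂| ≤ S·√(απε/λ)` (≈ 24.8 units for the defaults) the
  signed-distance penalty out-muscles the split everywhere and the
  remaining structure is below the model's resolution. This is what
  stops noise- and staircase-scale micro-splitting, which a two-means
  criterion would otherwise continue indefinitely.

`max_passes` (20) is a safety cap only.

## Discretization

First differences with replicate-edge (zero normal derivative)
boundaries everywhere. The curvature operator uses backward differences
of normalized forward fluxes with the other axis' central difference in
each magnitude (the mixed pairing), `ε_d = 10⁻⁸` inside the square
root; on disk signed-distance fields it recovers 1/r within a few
percent. In the evolution itself, the penalty and weighted-length terms
are assembled as the *exact* discrete gradients of their discrete
energies (backward divergence of forward-difference fluxes; the length
term carries the Dirac weight inside the flux plus the δ′ correction).
This makes −Q(φ) match finite-difference perturbations of the discrete
energy to ~10⁻⁴ relative at interior pixels, which is the property that
pins down every sign in the assembly; the continuum limits are the
familiar `δ(φ)div(g∇φ/|∇φ|)` and `Δφ − div(∇φ/|∇φ|)` forms. The mixed
pairing normalizes the two flux components by different magnitude
estimates, so Nx²+Ny² can exceed 1 by O(h²·curvature) at kinks; each
component is bounded by 1.

Degenerate inputs: constant images terminate with zero passes; empty
masks raise; NaN/Inf anywhere raises a stability error naming the step.
All computation is deterministic — identical inputs give bit-identical
results.

## What the phantom generator emulates — and what it does not

`make_nested_phantom` produces the structure the algorithm assumes:
2–8 strictly nested regions (squares, concentric disks, or seeded
offset blobs) at strictly increasing plateau intensities, plus additive
i.i.d. uniform noise on ±(noise_frac·255), clamped to [0, 255] —
"5% uniform noise" is `noise_frac = 0.05`. Ground-truth masks
("this level and brighter") accompany every phantom.

The phantoms deliberately lack the difficult features of real
mammograms: textured, cluttered backgrounds; blurred, low-contrast
boundaries; intensity gradients within anatomical regions; and
structured (non-i.i.d.) acquisition noise. Passing the recovery tests
therefore shows that the recursion correctly peels nested sharp-edged
plateaus through moderate noise — it does not certify performance on
clinical images, where denoising strength, κ and the contrast floor all
interact with real texture.

## Known limitations

* Near a contour separating plateaus that differ by ΔI, the steady state
  balances a data pinning rate `δ_ε(0)·λ·(ΔI/S)²` against the penalty
  rate τα; for ΔI ≈ 60 this equilibrium fixes the transition slope of φ
  at ≈ 3.4, not 1. The penalty keeps |∇φ| bounded and the evolution
  re-initialization-free, but the field next to a strong contour is a
  compressed, not unit-slope, distance function. A unit-slope band
  would require contrasts below the ~25-unit floor — i.e. the two goals
  "resolve strong contrasts" and "unit gradient at the interface"
  exclude each other under this weight regime.
* Convergence of weak-contrast passes is slow (hundreds of iterations):
  the Dirac throttling that protects the binary initialization also
  delays legitimate cascades.
* The contrast floor, κ, and the denoiser strength are coupled: much
  weaker denoising than the default leaves residual spreads that κ must
  chase upward.
* Only single-channel 2-D images; no multi-phase (2ⁿ-region) splitting;
  the outer region of each split is never revisited.
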