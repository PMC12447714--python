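# Methods

## Model

The latent variable is Gaussian, x ~ 𝒩(μ, Σ) in ℝⁿ with Σ symmetric
positive definite. The observed variable divides x by a denominator built
from its own magnitude:

    y = x / sqrt(xᵀBx + c),      B SPD,  c ≥ 0.

With B = I and c = 0 this is the classic projected normal on the unit
sphere. c > 0 moves the support to the open unit ball, a non-identity B to
the surface (c = 0) or interior (c > 0) of the ellipsoid yᵀBy ≤ 1. The
distribution is invariant under (μ, Σ, c) → (kμ, k²Σ, k²c) for k > 0, which
matters for identifiability when fitting.

## Densities

*Sphere.* The density of y = x/‖x‖ with respect to the surface measure is
the radial integral ∫₀^∞ r^{n−1} 𝒩(ry; μ, Σ) dr, which evaluates to

    p(y) = exp((q₂²/q₃ − q₁)/2) · ℳ_{n−1}(q₂/√q₃)
           / ((2π)^{(n−1)/2} |Σ|^{1/2} q₃^{n/2})

with q₁ = μᵀΣ⁻¹μ, q₂ = μᵀΣ⁻¹y, q₃ = yᵀΣ⁻¹y and the radial moments
ℳₖ(α) = ∫₀^∞ rᵏ φ(r − α) dr satisfying ℳ_{k+1} = αℳₖ + kℳ_{k−1},
ℳ₀ = Φ(α), ℳ₁ = αΦ(α) + φ(α). The (2π) power was fixed against two
independent oracles (numerical normalization over the sphere, and direct
quadrature of the radial integral); published renderings of this constant
differ by a factor √(2π). Far from the mean direction α is very negative
and Φ(α) underflows; the implementation therefore runs the recursion on
scaled values ℳ̂ₖ = ℳₖ e^{α²/2} (via the scaled complementary error
function), which combine with the Gaussian prefactor as e^{−q₁/2}ℳ̂_{n−1},
stable for all α. The forward recursion loses relative digits slowly as k
grows; for k beyond ~50 (far above any dimension used here) direct
quadrature of the defining integral is the appropriate cross-check.
Σ with condition number above 1e12 is rejected rather than inverted.

*Ball.* For c > 0 the map y = x/√(xᵀx + c) is invertible,
x = y·√(c/(1 − ‖y‖²)), with Jacobian determinant
(c/(1 − ‖y‖²))^{n/2}/(1 − ‖y‖²); the density is the Gaussian density at
the preimage times this determinant, evaluated in log space near the
boundary. Points outside the support give zero density (−∞ log density)
rather than an exception; c = 0 is rejected because the support degenerates
to the sphere. The closed-form determinant is verified against a
finite-difference Jacobian in the tests.

*Ellipsoid interior.* With y′ = B^{1/2}y distributed on the ball with
parameters (B^{1/2}μ, B^{1/2}ΣB^{1/2}, c), linear change of variables
gives p(y) = p_ball(B^{1/2}y)·det(B)^{1/2}. The direction of this
transform (evaluate at B^{1/2}y, not B^{−1/2}y) was pinned by the
normalization quadrature and a sampler histogram, either of which would
flag the wrong convention by tens of percent.

*Ellipsoid surface.* Not provided: mapping the sphere's surface measure
through B^{−1/2} changes the local area element in a way with no simple
closed form. The CLI rejects density requests for this case explicitly.

## Moment approximations

Each coordinate is written yᵢ = f(xᵢ, zᵢ) = xᵢ/√(xᵢ² + zᵢ) with
zᵢ = Σ_{j≠i} xⱼ² + c. A second-order Taylor expansion of f about
(μᵢ, z̄ᵢ), using the re-derived second derivatives

    ∂²f/∂x² = −3xz·u^{−5/2},  ∂²f/∂z² = (3x/4)·u^{−5/2},
    ∂²f/∂x∂z = (x² − z/2)·u^{−5/2},   u = x² + z,

combined with the quadratic-form moments of zᵢ (mean tr(Σ₋ᵢ) + μ₋ᵢᵀμ₋ᵢ + c,
variance 2tr(Σ₋ᵢΣ₋ᵢ) + 4μ₋ᵢᵀΣ₋ᵢμ₋ᵢ, and cov(xᵢ, zᵢ) =
2(μᵀcolᵢ(Σ) − μᵢΣᵢᵢ)) gives the first moment. The factor-2 scope in the
covariance term — ambiguous in some renderings — follows from
cov(xᵢ, xⱼ²) = 2μⱼΣᵢⱼ for jointly Gaussian coordinates and is locked by a
Monte-Carlo oracle test. The second moment E[yᵢyⱼ] = E[nᵢⱼ/d] with
nᵢⱼ = xᵢxⱼ and d = xᵀx + c uses the standard second-order expansion
E[n/d] ≈ (n̄/d̄)(1 − cov(n,d)/(n̄d̄) + var(d)/d̄²), computed in the expanded
form n̄/d̄ − cov/d̄² + n̄·var/d̄³ so that near-zero n̄ entries never appear in a
denominator. The covariance is Ψ̃ = Ẽ[yyᵀ] − γ̃γ̃ᵀ. The constant c enters
only through z̄ᵢ and d̄. Both routines are exactly invariant under
(μ, Σ) → (kμ, k²Σ), matching the distribution. B cases are handled by the
x′ = B^{1/2}x reduction with B^{1/2} from the symmetric eigendecomposition
(so that it is itself symmetric), and moments mapped back through B^{−1/2}.

For Σ = σ²I the moments are exact: γ = a·μ and Ψ = b·μμᵀ + c·I with

    a = Γ((n+1)/2) / (√(2σ²)·Γ(n/2+1)) · ₁F₁(1/2; (n+2)/2; −t)
    b = ₁F₁(1; (n+4)/2; −t) / (σ²(n+2)) − a²
    c = ₁F₁(1; (n+2)/2; −t) / n,        t = ‖μ‖²/(2σ²).

The constant in a is pinned by the n = 1 reduction E[sign(x)] = 2Φ(μ/σ) − 1
(an ₁F₁–erf identity), and tr E[yyᵀ] = 1 holds exactly by a contiguous-₁F₁
identity — both are asserted in tests. scipy's `hyp1f1` is used directly
for all arguments: it is internally stable for large negative arguments,
whereas an explicit Kummer transform e^z·₁F₁(b−a; b; −z) overflows once
−z exceeds ~709.

## Moment matching

Parameters are fitted to observed moments (γ, Ψ) by minimizing
(1 − λ)‖γ̃ − γ‖² + λ‖Ψ̃ − Ψ‖²_F, λ = 0.9 by default. Constraints are
enforced by construction through trivializations — sphere: raw/‖raw‖; SPD:
matrix exponential of a symmetric matrix built from n(n+1)/2 raw entries;
positive scalars: softplus — so every iterate is feasible exactly.
Initialization: μ̂ = γ/‖γ‖ and Σ̂ = Ψ (eigenvalues floored at 1e−10 for the
log map) for the sphere fit. The constrained ellipsoid-interior model
(Σ̂ = σ̂²I, B̂ = I + b̂v̂v̂ᵀ) initializes σ̂² = tr(Ψ)/n, v̂ to the
minimal-eigenvalue eigenvector of Ψ (the denominator attenuates y most
along B's dominant axis, so the observed covariance is smallest there),
then μ̂ = B̂^{1/2}γ/‖γ‖ using the just-initialized B̂; b̂ and ĉ start at 1.0
(no principled data-driven start presented itself; sensitivity to these two
is absorbed by the optimizer). v̂ and −v̂ give the same B̂, so axis recovery
is always reported as |cosine|. For B̂ of this rank-one-update form the
matrix roots are closed-form, B̂^{±1/2} = I + ((1+b̂)^{±1/2} − 1)v̂v̂ᵀ,
avoiding eigendecompositions in the optimizer's inner loop.

The optimizer is a NAdam-type adaptive gradient method under a cyclic
learning-rate schedule: 12 cycles of 80 iterations; the rate starts at 0.4,
is multiplied by 0.85 every 5 iterations within a cycle, and each cycle
restarts at 0.85 times the previous cycle's starting rate. Gradients are
central finite differences with per-coordinate step 1e−6·(1 + |θ|); all
2p + 1 evaluations of an iteration are computed in one vectorized batch
(the moment routines are written to broadcast over stacked parameter sets),
which makes a full schedule a few seconds even at n = 12. Optimizer state
carries across cycle boundaries; only the learning rate resets.

Adaptive gradient methods take steps of order the learning rate regardless
of gradient magnitude, so they equilibrate at a step-size-limited distance
from the minimum; on the narrow curved valley that couples (b̂, ĉ, v̂) in the
constrained fit this can stop far short (and measurably: the loss at the
true parameters sits orders of magnitude below such stall points). A
deterministic polish stage therefore follows the schedule by default:
L-BFGS (with the same batched finite-difference gradients) started from
both the schedule endpoint and the initialization, keeping whichever ends
at the lower loss. The dual start matters because the schedule can carry
the iterate across a ridge into a genuinely different basin. The polish is
capped at 500 iterations, past which recovery metrics no longer improve.

The loss weight λ for the constrained fit is chosen from the grid
{0.66, 0.9, 0.95, 0.98}. Two selection rules are exposed: simulation
studies with known ground truth pick the grid value minimizing the median
relative error of B̂ across replicates (the rule used in the original
experiments, which requires the truth); the end-user fit
(`fit_pnbc_constrained`) picks the value minimizing a standardized final
discrepancy, ‖γ̃ − γ‖²/‖γ‖² + ‖Ψ̃ − Ψ‖²_F/‖Ψ‖²_F, which is scale-free and
computable from data alone.

An unconstrained full-(B, Σ) fit is not offered: the parameter count and
the nonlinear coupling make it unreliable, and the CLI says so rather than
silently attempting it. The ball fit (`fit_pnc`) adds one softplus-mapped
constant to the sphere fit.

## Simulation studies and the synthetic truth samplers

The study harness draws truth parameters, estimates ground-truth moments
from Monte-Carlo samples, and scores approximations or fits with two
metrics: relative squared error in percent, 100·‖est − true‖²/‖true‖²
(Frobenius for matrices), and (Frobenius) cosine similarity. Aggregates are
medians and interquartile ranges over replicates.

Truth samplers: μ uniform on the sphere (normalized standard normal);
Σ = VDVᵀ with eigenvalues (Exp(1) + 0.01)·s²/n — the 0.01 floor added
before the scale factor, following the construction order — and V the
matrix exponential of a skew-symmetric matrix with standard-normal
lower-triangle entries (variance unstated in the source description;
standard normal assumed). The s²/n scaling keeps per-coordinate variance
comparable to μᵢ² ~ 1/n across dimensions. The denominator matrix B is
drawn like Σ but unscaled; c = c_mult·E[‖x‖²] with c_mult ~ Exp(1), making
the constant's influence comparable across conditions. The constrained-fit
truth uses σ² ~ U(0.05, 1)·s²/n, v uniform on the sphere, and
b = 2 + Exp(4); the exponential is parameterized by its *mean* (4), read as
numpy's scale convention — the rate reading (mean 1/4) is also plausible,
and parameter recovery was verified to succeed under both. Ground-truth
moments use the N − 1 covariance divisor (immaterial at the sample sizes
used).

Default study sizes are desk-scale: 30 replicates with 1e5-sample ground
truth for approximation studies, 10–20 replicates with 1e6-sample observed
moments for fit studies (the original experiments used 100/50 replicates
and 1e6/1e7 samples; all counts are plain fields on `StudyCondition`).
These sizes keep every study to minutes while leaving Monte-Carlo noise
well below the effects being measured. What the harness does *not* emulate:
real neural data has non-Gaussian inputs, stimulus-dependent parameters,
and finite trial counts far below 1e5 — passing studies here certify the
approximation and optimization machinery on the model's own terms, not the
model's fit to any particular dataset.

Per-replicate seeds are spawned from each condition's seed, so tables are
bitwise reproducible.

## Numerical choices and limitations

- Symmetric inputs are accepted within max|M − Mᵀ| ≤ 1e−8·max|M| and
  symmetrized as (M + Mᵀ)/2; quadratic forms only see the symmetric part.
- Sampling uses the symmetric eigendecomposition square root of Σ; a drawn
  x with zero norm (probability zero) raises rather than being resampled.
- Normalization quadrature tolerances in tests are 1e−5: loose enough for
  adaptive integrators, tight enough to catch any wrong (2π) power or
  determinant factor (≥ 10% effects).
- The Taylor moment error grows with the covariance scale s and shrinks
  with dimension n; at s = 1 and n = 3 covariance errors of several
  percent are expected. The expansion assumes the denominator's mean
  dominates its fluctuations; it degrades when Σ's eigenvalues are large
  relative to ‖μ‖² + c.
- The fitted b̂ of the constrained model is mildly biased low (a
  consequence of matching approximate moments, not an optimizer failure);
  axis and structure recovery (cosines) are unaffected.
- Fits are deterministic given their inputs; the `seed` field on
  `FitConfig` exists for interface uniformity and provenance stamping, not
  because the optimizer draws random numbers.
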