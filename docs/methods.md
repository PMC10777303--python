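# Methods

## The model

A cell of age τ carries luciferase z(τ) = x + y(τ): the inherited amount
x, fixed at birth, plus the amount synthesized since birth.  Synthesis
starts immediately after division (release of the operator from the
repressor), runs at constant rate α, and stops for the rest of the cycle
when the repressor rebinds — a single irreversible event at exponential
waiting time τ′ ~ Exp(A), reflecting a constant repressor supply.  Hence
y(τ) = α·min(τ, τ′), and conditional on age the synthesized amount has
density (A/α)·e^{−Ay/α} on [0, ατ) plus a survivor atom of weight e^{−Aτ}
at y = ατ.  A = 0 is the constitutive limit: y(τ) = ατ exactly.

Division is an age-dependent hazard ω(τ) = C·θ(τ − τ₁): no division below
the minimum age τ₁, constant intensity C above it.  The lineage cycle
length is therefore T = τ₁ + Exp(C); at C = 4, τ₁ = 3/4 the mean cycle is
exactly one generation time with CV 25 %, consistent with measured
cell-size distributions of gram-negative bacteria.  In an exponentially
growing culture the stationary age-frequency density solves
dΨ/dτ = −(μ + ω(τ))Ψ, and μ is fixed by the binary-fission renewal
closure (newborn flux = 2 × division flux), which reduces to the
characteristic equation (μ + C)·e^{μτ₁} = 2C.  The dividing-age density
is Ω(τ) ∝ ω(τ)Ψ(τ): a shifted exponential with rate μ + C starting at τ₁.

The newborn distribution f(x) is the fixed point of the generation map
f ⟼ halve(∫Ω(τ)[f ∗ P(·,τ)]dτ) (synthesize to the age of division, halve
at division), and the observable population distribution is
Φ(z) = ∫Ψ(τ)[f ∗ P(·,τ)]dτ, which treats x and current age as
independent.  Daughters receive exactly half the mother's content:
volume-partitioning noise is deliberately omitted, because it is far too
small to account for the observed variability and the model's point is
that the operon clock plus the cycle structure suffice.

Assumptions worth keeping in mind: one shut-off event per cycle, no
re-activation before division; luminescence strictly proportional to
luciferase amount (no substrate or O₂ limitation); no active luciferase
degradation (an optional external "inactivation" operator shrinks all
amounts by a factor 1−k if needed); no quorum-sensing induction.

## Parameters

| name | meaning | unit | default |
|------|---------|------|---------|
| A    | repressor–operator binding intensity | events per τ₀ | 2 (the fitted value; 0 = constitutive) |
| α    | synthesis rate; pure scale factor of the intensity axis | amount per τ₀ | 1 |
| C    | division intensity above the minimum age | events per τ₀ | 4 |
| τ₁   | minimum division age | τ₀ | 3/4 |
| τ₀   | mean generation time, the time unit | — | 1 (fixed) |

C and τ₁ are calibrated jointly so that the constitutive (A = 0) steady
state has CV ≈ 24 %, matching independent cell-volume variability; they
are treated as known, leaving A as the single shape parameter and α as
the instrument-gain factor.

## Numerics

*Amount axis.*  Distributions are bin-mass vectors on a uniform grid,
default z_max = 8α, 2048 bins.  Dirac atoms are assigned to the
(left-closed) bin containing their position; mass beyond z_max is kept
in an explicit overflow accumulator so totals are conserved to 1e-9.
Continuous parts are integrated exactly per bin (differences of the
exponential CDF), not sampled at bin centers.

*Age axis.*  Closed-form Ψ and Ω are evaluated on a uniform grid with
step 1/512 up to τ₁ + 30/C (truncated survivor mass < 1e-13) and
normalized with the trapezoidal rule.  The trapezoid straddling the
hazard jump at τ₁ biases the mean dividing age by ~1e-3, below every
tolerance used.

*Composition.*  By linearity of convolution, ∫w(τ)[f ∗ P(·,τ)]dτ =
f ∗ ∫w(τ)P(·,τ)dτ; both age integrals are therefore evaluated as a
single convolution of f with a precomputed age-mixture kernel, making
one fixed-point sweep one `np.convolve` call.  The identity with the
explicit per-age quadrature is asserted in the test suite.

*Fixed point.*  Successive approximations start from an atom at 0
(the map is a contraction — inherited variance is quartered per
generation — so the fixed point is initialization-independent, which is
also tested) and stop when the L1 change falls below 1e-8, typically
~30 iterations.  Non-convergence is reported explicitly, never raised
silently.  Halving and the inactivation operator move bin-center mass
with linear interpolation between the two nearest target bins, which
conserves mass exactly and means exactly up to boundary clipping.

*Growth rate.*  Brent root-finding on (μ + C)e^{μτ₁} − 2C over (0, C]
to 1e-13; τ₁ = 0 returns μ = C analytically.

*Quantiles* are interpolated from the cumulative mass at bin edges;
moments use bin centers.

## Agent-based oracle

The Monte-Carlo simulator draws, per cell, a cycle length τ₁ + Exp(C)
and a shut-off time Exp(A) (infinite when A = 0), halves the content at
division, and is vectorized in rounds: all divisions due before the next
checkpoint are processed together in array order, so runs are
bit-reproducible given the seed.  Above the population cap the
population is uniformly subsampled — unbiased for snapshot distributions
in a branching process since every lineage is equally likely to survive —
and the discarded growth factor is retained so the growth rate remains
measurable from the log-size trajectory.  Snapshots are taken after 12
generations, long enough that initial-condition memory (halved each
generation) is below 2⁻¹².

The oracle shares no numerical machinery with the solver, so their
agreement (L1 < 0.05 and |ΔCV| < 0.02 at n = 50 000 for A ∈ {0,1,2,4})
is a genuine cross-validation.  The L1 comparison aggregates both
histograms to 256 bins: at n = 50 000, multinomial noise alone on the
full 2048-bin grid contributes an expected L1 of ≈ 0.07 (Σ√(2pᵢ/πn)),
which would swamp any real discrepancy; at 256 bins the noise floor is
≈ 0.026.  The resolution was fixed from this noise budget, not tuned to
the observed distances.

## Batch dynamics

The growth curve is a lagged logistic, dN/dt = μ(t,N)·N with
μ = μ_max·(1 − e^{−t/lag})·(1 − N/K), integrated by fixed-step RK4
(default μ_max = μ_ref ≈ 0.7071, K = 1000, N₀ = 1, lag = 1, dt = 0.01).
The specific form is a modeling choice: any sigmoidal curve with a lag
gives the same qualitative behavior, and no measured optical-density
table is fitted.

Coupling is quasi-static.  Elapsed generations accumulate as
∫μ(t)/μ_ref dt; each whole generation triggers one generation-map
application at the current effective parameters.  On the cell's own time
scale α, C and τ₁ are unchanged while the (absolute-time, energy-
independent) binding process appears faster when growth slows:
A_eff(t) = A·μ_ref/max(μ(t), μ_ref/20).  The floor caps A_eff at 20A so
the deep-stationary limit stays finite; the inoculum is the fixed point
at A_eff(μ(0)) — dim cells from a stationary pre-culture — which
produces the initial rise of mean intensity after inoculation, and the
post-inflection decline follows from the same scaling in reverse.  Note
that total elapsed generations are bounded by ln(K/N₀)/μ_ref, so in deep
stationary phase the newborn distribution freezes while the composition
term (synthesis within the current cycle) keeps shrinking with μ.

## Fixtures and fitting

`generate_fixture_histogram` emulates a measured single-cell intensity
histogram: an agent-based snapshot re-counted with multinomial noise at
n_cells.  It reproduces the model's own counting statistics but none of
the instrument effects of a real photon-counting experiment (dead time,
discriminator threshold, background), so passing the recovery tests
shows identifiability of A under the model, not robustness to real
measurement distortions.

`fit_binding_intensity` scans a user-supplied A grid; for each candidate
the steady state is solved at α = 1, dilated so its mean matches the
observed mean (α and all instrument gains are absorbed by this single
scale), and scored by L1 distance on a 256-bin comparison grid, ties
going to the smaller A.  The mean-matched-L1 objective is an artifact
choice — the original comparison of model and experiment was visual —
and the observed histograms of real experiments are not tabulated
anywhere, so fitting is validated by synthetic parameter recovery only.

## Problem sizes

Defaults throughout (2048 amount bins, 1/512 age step, 50 000-cell
agent-based snapshots, 12-generation burn-in, 24-generation batch
horizon at dt = 0.01) solve the steady state in well under a second and
run the complete validation suite in under a minute on one core.

## Known limitations

- Quasi-static batch coupling never solves the time-dependent
  age-structure PDE; fast transients (diauxie, upshifts) are outside its
  validity.
- The constant-repressor, single-event shut-off clock is phenomenology;
  bursty transcription or repressor copy-number fluctuations would need
  a different g(τ′).
- Exact halving ignores partition noise by design; adding it would
  slightly inflate the low-A CV.
- Amounts beyond z_max are tracked only as total overflow mass; choose
  z_max generously when A is very small and α large.
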