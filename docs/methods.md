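# Methods

## Model

`neqprf` implements a Poisson random field (PRF) description of allele
frequencies in a haploid population whose size is a step function of time:
size N (the reference) before a change time t\*, size κN afterwards, with
optional further epochs.  Time is measured in units of N generations.
Assumptions inherited from the PRF framework:

- infinitely many independent (freely recombining) sites; each segregating
  site carries one derived allele whose frequency follows the Wright–Fisher
  diffusion with additive selection,
- mutations arise at monomorphic sites as a Poisson stream with intensity
  θ per generation (reference population), entering at frequency 1/N_κ,
- selection coefficients are fixed per mutation: either one class with
  scaled coefficient γ (relative to the reference size N), or drawn from a
  negative Gamma distribution of fitness effects (DFE) with shape a and
  mean −ab; beneficial mutations are outside scope,
- additive fitness, so a diploid population of size N/2 is equivalent.

Under these assumptions the expected value of any site functional
⟨X_t, f⟩ = Σ_i f(y_i), including a point mass at y = 1 for accumulated
fixations, is an integral of f against a deterministic intensity.  In a
constant-size population this intensity is the classical equilibrium
spectrum θ ω_{γ,κ} ψ_{γ,κ}(y) dy plus a linear-in-t fixation term
θ ω_{γ,κ} f(1) t.  After a size change a third, transient term appears: the
standing variation keeps the weights of the ancestral spectrum but evolves
under the new drift strength, entering through conditional expectations
E_y^{γ,κ}[f(ξ_u)] with u the time elapsed since the change, and through the
fixation-time distribution P_y^{γ,κ}(τ₁ ≤ u) when f counts fixations.

A note on the neutral spectrum: the neutral intensity density is the
γ → 0 limit of the general expression, ψ_{0,κ}(y) = 2κ/y.  This is forced
by consistency with the neutral equilibrium diversity 2θκ.

### Multi-epoch histories

For histories with several size changes the package propagates the
*deviation* of the polymorphic intensity from each epoch's own equilibrium:
every change at time t\*_k creates a jump equal to the difference of the
outgoing and incoming equilibrium intensities, and that jump then relaxes
under the composed diffusion dynamics of all subsequent epochs.  The
resulting functional is

E⟨X_t, f⟩ = θ f(1) ∫₀ᵗ ω(s) ds + θ ∫ f ω_cur ψ_cur dy
          + Σ_k θ ∫ S_k f(y) [ω_{k−1}ψ_{k−1} − ω_k ψ_k] dy,

where S_k is the full conditional expectation from t\*_k to t, computed by
marching the backward equation through every intervening epoch.  With one
change this reduces *exactly* (bit-for-bit in the implementation) to the
single-change formula, and the two-epoch neutral case is validated against
the finite-N field simulator.  Because S_k requires composed semigroups,
multi-epoch functionals are only available with the deterministic engine.

## Engines

All nonequilibrium quantities consume E_y[f] and P_y(τ₁ ≤ u) through a
small engine interface, evaluated for the *reduced* dynamics: a population
of size κN with selection γ equals the reference-size population with
effective selection γκ and time divided by κ.  Tables are therefore keyed
by γκ and shared across κ values.

**PDE engine (default).**  Crank–Nicolson solution of the backward
Kolmogorov equation u_t = γκ y(1−y) u_y + ½ y(1−y) u_yy with Dirichlet
(absorbing) boundaries, on a uniform grid of ny = 2001 frequency points.
Choices that matter:

- *Time stepping*: geometric ramp from dt = 1e-4 to 0.02 (reduced units,
  growth 1.05).  Transients decay like e^{−λτ} with λ = O(1), so late
  steps of 0.02 keep the temporal error at roughly dt²/12 ≈ 3e-5 relative,
  matched to the O(dy²) ≈ 2.5e-7 spatial error at ny = 2001.
- *Rannacher startup*: the first 4 steps are implicit Euler, damping the
  oscillations Crank–Nicolson produces for discontinuous initial data (the
  fixation indicator).
- *Upwinding*: when the cell Peclet number |γκ|·dy exceeds 1 (|γκ| ≳ 2000
  at the default grid) the convection term switches to first-order upwind
  differencing.  Accuracy there is secondary: such strongly selected
  classes contribute essentially nothing to diversity or fixations, but
  the solve must stay bounded.
- Moment tables may undershoot 0 by ≲1e-6 in the advection-dominated
  limit; downstream integrals treat this as numerical zero.

**Wright–Fisher engine.**  Forward binomial resampling at size N = 1000:
given frequency y and per-generation coefficient s = γκ/N, the next
count is Binomial(N, p\*) with p\* = y(1+s)/(1+sy), which matches the
diffusion drift to O(s²).  Defaults follow the simulation protocol the
analytic results are compared against: horizon 20000 generations, 100000
replicates for neutral fixation-time CDFs, 10000 for selected ones, 1000
replicates for moment estimates.  Censored paths (unabsorbed at the
horizon) are counted as never fixing; the induced CDF-tail bias is
monitored against the analytic fixation probability and warned about above
1%.  RNG streams are derived per (purpose, γκ, initial count) from the
master seed, so tables are reproducible regardless of evaluation order.
Moment/CDF tables use an initial-frequency grid of 1/N plus 40 log-spaced
points up to 1−1/N; time-snapshot generations are rounded from the
requested evolutionary times.

**Transient y-integral.**  The integrand E_y[f]·[ω₁ψ₁ − ω_κψ_κ] is
continuous on [0,1] once its endpoint limits are attached: near y = 0 the
1/y singularity of the intensity bracket cancels against the O(y) decay of
E_y[f] (the small-y slope is fitted through the origin from the three
smallest grid frequencies); at y = 1 the bracket tends to
2(ω₁ − κω_κ)·f(1)-weighted values.  Integration is the trapezoid rule on
the closed grid; intensity products are always evaluated through the
overflow-free identity ωψ = 2κ·q(1−y)/(y(1−y)) with the bounded fixation
probability q.

## DFE handling

The negative Gamma DFE (defaults a = 0.15, mean strength ab = 2500) is
integrated with a quadrature built for a < 1: on the magnitude axis
u = bz, the substitution w = z^a removes the z^{a−1} singularity exactly
and concentrates half of the Gauss–Legendre nodes in the nearly neutral
range where ω and π vary fastest.  Mass beyond a truncation bound
gamma_min = −1000 (the limit of the discrete engine, s = γ/N ≥ −1, and of
any realistic contribution to diversity or fixations — with these defaults
about 30% of the DFE mass) is *clamped* to the bound as a point mass
rather than discarded, so that expectations of constants are exact and the
ultra-deleterious tail contributes its (vanishing) boundary value.  An
untruncated mode extends the integration interval to the 1−1e−15 quantile
instead.  Weights are renormalized to total mass 1.  Engine-driven time
series default to 24 nodes (12 in the scaled-down sweeps used by the test
suite); equilibrium-only tables use 200.

## Synthetic data

The package needs no external data; the finite-(N, L) Poisson-field
simulator doubles as the synthetic-data generator and as an independent
stochastic oracle for the analytic spectrum.  It emulates: Poisson
mutation inflow (θκ per generation, one copy each), independent binomial
Wright–Fisher evolution per segregating site, instantaneous size changes
(counts resampled binomially at the new size), and standing variation
initialized from the discretized ancestral equilibrium intensity.  It does
*not* emulate linkage, recombination within sites, dominance, population
structure, migration, or sampling noise of finite sequence samples —
agreement between the simulator and the analytic formulas therefore
validates the PRF mathematics at finite N, not the fit of the model to
real sequence data.  Default oracle settings (N = 200, horizon 5 time
units, 20 replicates) put the Monte-Carlo standard error of the pairwise
functional near 0.08, comfortably resolving the O(1/N) discreteness bias.

## Study conditions and problem sizes

The analysis defaults reproduce the published study conditions: θ = 1,
N = 1000, κ ∈ {0.1, 0.25, 0.5, 1, 2, 4}, an ancient change at t\* = 1
observed on [0, 20] (grid step 0.1) and a recent change at t\* = 18
observed at t = 20, DFE a = 0.15, ab = 2500.  The test suite runs the same
pipelines at reduced sizes chosen to keep every Monte-Carlo comparison
inside three standard errors of its analytic target: 2000 fixation
replicates and 200 moment replicates for the triple-oracle grid, 12 DFE
nodes and a 0.2 time step for the measure sweeps, κ ∈ {0.25, 1, 4}.

## Numerical tolerances and degenerate inputs

- |2γκ| < 1e-8 is treated as neutral (analytic limits for q, ω, ψ);
  the closed-form diversity switches to a series below |2γκ| = 1e-3 to
  avoid cancellation.
- Beyond 2γκ < −700 all exponentials move to log space; quantities that
  genuinely underflow double precision (ω, ωψ deep in the deleterious
  tail) return 0, and the standalone density ψ may return inf — integrals
  never evaluate it directly.
- Equilibrium quadrature targets 1e-8 relative accuracy and raises if the
  adaptive routine cannot certify 1e-6.
- Monotonicity/bracketing assertions on deterministic series allow 2e-4
  absolute slack for discretization error of the PDE engine.
- y outside [0,1], κ ≤ 0, t < t\* in weighted ratios, and nonpositive
  times for harmonic means are rejected with `ValueError`.

## Known limitations

- ω̄(t) is the population functional; finite-sample dN/dS estimators and
  their short-branch polymorphism bias are out of scope.
- No beneficial mutations, dominance, linkage, migration or structure.
- The Wright–Fisher engine cannot represent γκ < −N (s < −1); the DFE
  clamp keeps requests inside the representable range.
- Multi-epoch functionals require the PDE engine; Monte-Carlo tables
  cover single-change histories only.
- The harmonic-mean Neff uses the exact step-function integral; no
  coalescent/SMC-style inference of size histories is attempted.
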