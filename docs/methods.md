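# Methods

## Model

The package simulates recurrent firing-rate networks of N units,

    τ dxᵢ/dt = −xᵢ + Σⱼ Wᵢⱼ φ(xⱼ) + Iᵢ u(t),        φ = tanh,

where xᵢ is the total input current to unit i, Wᵢⱼ the weight from unit j
to unit i (rows = receiving units), and I a feedforward input pattern
driven by a scalar signal u(t).  Because φ(0) = 0 and φ′(0) = 1, the zero
state is always a fixed point and its stability is governed directly by
the eigenvalues of W: it destabilises when any eigenvalue's real part
exceeds one.

Couplings come in three families:

* **Gaussian** — entries iid N(0, g²/N); eigenvalues fill a disk of radius
  ≈ g (circular law).
* **Rank-one, scaled** — `W = m nᵀ / N` from a pair of connectivity vectors
  with Var(mᵢ) = Var(nᵢ) = σ² and cov(mᵢ, nᵢ) = σ_mn.  The single non-zero
  eigenvalue is mᵀn/N → σ_mn, with right eigenvector m.
* **Rank-one, rescaled** — `W = m nᵀ` (no 1/N).  Used in the high-sparsity
  limit where a fixed number C of connections per unit is kept while N
  grows: the weight scale must then stay O(1) per connection for the
  spectrum not to vanish.

The vector pair is built from three independent standard-normal vectors
x, y, z as `m = √(σ² − σ_mn) x + √σ_mn z`, `n = √(σ² − σ_mn) y + √σ_mn z`,
which forces 0 ≤ σ_mn ≤ σ².  (Covariance cannot exceed variance for equal-
variance pairs; parameter points that would require σ_mn > σ² are rejected.)

**Sparsification** multiplies W elementwise with a binary mask: Bernoulli
(each connection kept independently with probability 1 − s), fixed
in-degree (exactly C surviving inputs per unit, sampled uniformly per row)
or fixed out-degree (per column).  The in-degree convention is the default
for dynamics and task experiments because the recurrent drive each unit
receives is what shapes the dynamics; the spectral formulas are identical
under either convention.

## Spectral theory

Sparsity splits a rank-one spectrum into an isolated real **outlier** and a
circular **bulk**:

* outlier: λ₁ = (1 − s) mᵀn/N for the scaled branch (population form
  (1 − s) σ_mn, equivalently C σ_mn/N), and λ₁ = C σ_mn for the rescaled
  branch — independent of both s and N.
* bulk: applying the circular law `R = √(Var·N)` to the outlier-deflated
  matrix `P* = P̃ − (1 − s) P`, whose entrywise variance is
  σ⁴ s(1 − s)/N², gives `R = σ² √(s(1−s)/N)` (scaled; symmetric in
  s ↔ 1 − s, maximal at s = 0.5) and `R = σ² √(C(N−C)/N)` (rescaled;
  → σ² √C as N → ∞ at fixed C).

The empirical estimators follow the same convention throughout: the
eigenvalue with largest real part is declared a measurable outlier iff its
real part strictly exceeds the largest modulus of the remaining
eigenvalues (margin configurable); the bulk radius is the largest modulus
after outlier exclusion.  When the predicted outlier sits inside the bulk
its location cannot be measured and the report says so rather than
returning a number.

### Known finite-size discrepancies (measured by this package's tests)

1. **Outlier sampling noise.**  The realised overlap mᵀn/N has standard
   deviation √((σ⁴ + σ_mn²)/N) — 13% of σ_mn at (σ² = 16, σ_mn = 4,
   N = 1000).  The empirical outlier tracks the *realised* overlap to well
   under 1%; comparisons against the population value σ_mn must average
   over instances and budget for this noise.  The acceptance test therefore
   checks the structural law (1 − s)·mᵀn/N per instance at 5% and the
   population form within three standard errors.

2. **Bulk radius exceeds the deflated-variance prediction.**  The deflated
   matrix equals `diag(m) Z diag(n) / N` with Z iid centred Bernoulli,
   which is similar to `Z diag(mⱼnⱼ) / N` — a variance-profile matrix.
   Its support radius carries an extra factor √(1 + 2 (σ_mn/σ²)²) relative
   to the entrywise-variance formula (the same-index product mⱼnⱼ is what
   the spectrum sees, and E[m²n²] = σ⁴(1 + 2(σ_mn/σ²)²)); at σ_mn/σ² = 0.25
   this alone is +6%.  On top of that, the heavy-tailed (product-normal)
   profile produces a few straggler eigenvalues beyond the continuum edge,
   so the max-modulus estimator sits ~5–10% above the edge at N ≤ 4000 and
   converges only slowly.  The 99th-percentile modulus agrees with the
   variance formula to ~2%.  The corresponding acceptance check asserts the
   5% band on the max-modulus estimator and is expected to fail; it is kept
   failing deliberately rather than re-tuned, with this analysis as the
   explanation.  The Gaussian branch shows none of this (light tails, no
   profile): its radius matches g√(1 − s) to ~1.5% at N = 1000.

## Dynamics

Integration is forward Euler with default dt = τ/20 and a hard cap
dt ≤ τ/10; τ defaults to 100 ms and all durations are in ms.  First-order
convergence is verified by a dt-halving test.  Noise (per-unit, and
stimulus fluctuations in the task) enters with Euler–Maruyama √dt scaling.
Couplings with density < 0.3 are applied through a CSR sparse operator —
an internal optimisation only; results are identical to the dense path.

Latent variables: κ_r = mᵀx/‖m‖², κ_I = Iᵀx/‖I‖², and the recurrent drive
κ_rec = (1/N) Σⱼ nⱼ φ(xⱼ); at any autonomous equilibrium κ_r = κ_rec.  For
dense rank-one networks the activity is confined to span{m, I}; the
reconstruction error of x from (κ_r, κ_I) is limited by the non-orthogonality
of m and I, which scales as ~1/√N.  Dimensionality is quantified by the
participation ratio (Σλᵢ)²/Σλᵢ² of the activation covariance (computed via
singular values of the centred trajectory), and by PCA variance fractions
plus |cos| alignment of leading components with m and I.

Fixed points are located by integrating the autonomous dynamics from a
small kick ε·direction (ε = 10⁻² relative) until ‖ẋ‖∞ < 10⁻⁶ per unit
time; non-convergence raises rather than truncating.  For dense rank-one
networks the resulting κ_r satisfies the scalar self-consistency
κ = (1/N) Σⱼ nⱼ φ(κ mⱼ), which the tests verify against an independent 1-D
root find.

## Dynamical regimes

Theory labels (rescaled branch, λ₁ = C σ_mn, R = σ² √(C(N−C)/N)):
decaying if max(λ₁, R) ≤ 1; structured stationary if λ₁ > 1 and λ₁ ≥ R
(ties go to structured — chaos requires the bulk to strictly surpass the
outlier); chaotic if R > 1 and R > λ₁.  Phase diagrams over the (σ², σ_mn)
plane carry the three boundary curves σ_mn = 1/C, σ² = 1/√(C(N−C)/N) and
C σ_mn = σ² √(C(N−C)/N).

The empirical diagnostic, applied after discarding the first 25% of a
≥ 50 τ post-transient window: **decaying** if RMS activity < 10⁻³;
**structured stationary** if κ_r settles to a non-zero constant (temporal
CV < 0.05) *and* the time-averaged state aligns with m
(|cos(x̄, m)| ≥ 0.9); **chaotic** otherwise.  The alignment requirement is
essential: every row of the sparse rank-one coupling is proportional to
mᵢ, so in the theory-chaotic region roughly a third of network
realisations converge to saturation-stabilised frozen fixed points of the
form xᵢ = mᵢ cᵢ with heterogeneous c.  These carry a large constant κ_r
but their pattern is only weakly aligned with m (measured |cos| ≤ 0.79
versus ≥ 0.96 for genuine structured states); they are bulk-generated and
are grouped with chaotic.  All thresholds are configuration values.
Theory–simulation concordance is evaluated away from 10% bands around the
boundary curves, since finite-size fluctuations of the realised outlier
(std √C σ² per row sum) blur them; residual disagreement concentrates in
cells where both λ₁ and R exceed unity and lie close together, where the
linearised-at-zero boundary is known to be approximate once saturation is
taken into account.

## The Go-Nogo integration task

Construction: draw (m, n), set I = n (input picked up by the recurrence)
and w = m (readout taps the recurrent axis), rescale (`m nᵀ`) and keep C
inputs per unit; choose σ_mn so that λ₁ = C σ_mn > 1, giving bistable fixed
points ±κ* along m.  Each trial starts in the lower (negative-readout)
fixed point, receives a fluctuating stimulus c(t) I + η(t) with
c(t) = c̄ + white noise, and answers Go iff the mean readout
z = (1/N) wᵀ φ(x) over the final decision window (default 50 ms of a
500 ms trial) is positive; an exact tie counts as Nogo.  The switching
threshold θ is not a parameter: it emerges from the bistability and is
located when needed by bisection on noise-free trials.  Default noise
amplitudes (stimulus fluctuation std 1.0, per-unit noise std 0.05) were
chosen once so that the noise-free threshold is recoverable from 50-repeat
psychometric curves with a clearly resolved sigmoid; the readout
normalisation (1/N and φ(x) rather than raw x) keeps z order-one and ties
it to κ_rec.

Two behaviours are robust in this construction and verified by the tests:
the psychometric curve is monotone in c̄, and lowering C at fixed σ_mn
shifts it toward lower stimulus strengths (increased sensitivity).  A third
property — that fixing λ₁ = C σ_mn while varying C leaves the curve
unchanged — does *not* hold here, and the corresponding acceptance check is
left failing by design.  In mean field the input pickup gain is
C σ² ⟨φ′⟩ (Gaussian integration of E[n φ(c n + κ m)] gives
C (c σ² + κ σ_mn) ⟨φ′⟩), so at fixed λ₁ the switching threshold scales as
~1/(C σ²): measured noise-free thresholds 3.93 / 2.63 / 2.02 for
C = 60 / 80 / 100 at λ₁ = 4.8, i.e. θ·C ≈ constant.  Only the κ-feedback
term is governed by λ₁ alone.  Note also that fixing λ₁ at large values
across small C can demand σ_mn > σ², which the generative construction
forbids; the fixed-outlier comparisons therefore use λ₁ = 4.8, for which
C ∈ {60, 80, 100} yields bulk radii 0.76 / 0.87 / 0.97 at σ² = 0.1,
N = 2000 while keeping σ_mn < σ².

A dense control network (Gaussian g plus dense scaled rank-one with the
same I = n, w = m geometry) is provided for sparse-vs-dense comparisons,
including a convenience preset (σ² = 9, σ_mn = 2.3, g = 1.3); its claimed
spectral equivalence to a particular sparse network is not certified,
since the scaling convention behind that parameterisation cannot be
reconstructed unambiguously.

## Synthetic conditions, sizes, and what the tests do and do not show

All inputs are generated internally — connectivity vectors, masks and
stimuli; there is no real neural data anywhere, so passing tests
demonstrate internal consistency of theory and simulation under the
model's own assumptions (iid Gaussian vectors, random masks, tanh units,
white noise), not agreement with biology.  Default experiment conditions
follow the figure-scale settings: spectral sweeps at N = 1000 (g = 1;
σ² = 16, σ_mn = 4), regime grids at C = 200, N = 1000, input-driven runs
at σ² = 0.043, σ_nI = 0.2, and the task at N = 2000, C = 200, σ² = 0.1,
σ_mn = 0.04 with 50 repeats per stimulus strength.  The test suite scales
instance counts down (e.g. 8–10 spectra per grid point rather than 50,
5–6 seeds per trend point) as the package's own choice of desk-scale
statistics; tolerances are not adjusted.  Statistical checks use 3-standard-
error bands for Monte-Carlo moments and binomial confidence widths for
psychometric crossings.

## Reproducibility

Every random draw flows through an explicit numpy Generator; experiment
drivers derive per-instance generators from (base_seed, instance_index), so
identical configs reproduce all stochastic outputs bitwise (verified by
hashing outputs).  Matrices and trajectories persist to compressed array
containers with JSON parameter sidecars; experiment results are tidy CSV
plus a JSON manifest recording parameters, seeds, package versions and wall
time.

## Limitations

* Ranks above one, structured (non-random) sparsity, Hebbian learning and
  Lyapunov-based chaos quantification are out of scope; chaos is
  characterised only through the regime diagnostic.
* Only the bulk *radius* is predicted; the bulk density is visibly
  non-uniform and no density profile is computed.
* The three-regime boundary λ₁ = R is a linearised criterion; near it, and
  wherever both components exceed unity, saturation shifts the true
  transition and frozen states appear (see above).
* Dense storage is used up to a CSR switch for simulation; N beyond a few
  thousand is untested territory for the eigendecomposition paths.
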