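# Methods

## The model class

A model is a set of named variables. Each *dependent* variable X_i evolves by
the explicit fixed-step recursion

    X_i(t + ϑ) = X_i(t) + ϑ · F_i(X(t)),
    F_i(X) = Σ_k s_k · γ_k · ∏_j (X_j + c_jk)^{f_jk},

with signs s_k ∈ {+1, −1}, nonnegative rate constants γ_k, real kinetic
orders f_jk (negative orders encode inhibition), and optional per-variable
offsets c_jk (the `(X+1)^g` device that keeps an inhibition factor finite
when its variable is zero). *Independent* variables carry no equation; they
are held constant or driven by an event process. The recursion is always
evaluated at the previous grid state — there is no implicit or adaptive
stepping, because the fixed-step recursion *is* the model, not an
approximation of one. As ϑ → 0 the trajectories converge (first order in ϑ)
to those of the corresponding power-law ODE system; the test suite verifies
the convergence order on the linear-pathway model.

Rate constants are stored nonnegative with explicit signs, the BST
convention; configs with signed constants are normalized by folding the sign.

### Delays

Any term may read a referenced variable at t − τ instead of t. Lags are
resolved against a history buffer of past grid states with a
constant-at-initial-state pre-history: lookups at or before t₀ return the
initial value, which models a system that sat at rest before the experiment
began. Delays must sit on the ϑ grid; `validate_model` snaps off-grid lags to
the nearest multiple of ϑ with a warning (a hard error in strict mode),
because the recursion only possesses grid states. A fixed point of the
delayed system equals that of the undelayed skeleton, so steady-state
computations ignore lags.

### Threshold regimes

A dependent variable may switch between three term lists according to a
switch variable s and thresholds (L, H): the lower regime applies for s < L,
the upper for s > H, and the middle — inclusively — for L ≤ s ≤ H, so at a
boundary the middle regime wins. This matches the convention of writing the
middle condition as L ≤ s ≤ H with strict outer inequalities.

### Numerical domain policy

A fractional power of a non-positive base is a hard error naming the term
and variable. Silent clamping would mask modeling mistakes (well-posed
power-law models keep their bases positive by construction, e.g. via
offsets); an opt-in clamp to a configurable floor (default 1e-12) exists for
exploratory runs only. Overflowing fluxes become +∞ and surface as a step
failure naming the variable; `simulate` raises with the partial trajectory
attached so the blow-up can be inspected.

## Stochastic machinery

Four mechanisms, all driven by `numpy.random.Generator` sub-streams:

* **Rate jitter** — a rate constant resampled uniformly on
  [γ(1−f), γ(1+f)] every step (or every `refresh` steps). The uniform shape
  on the ±f band is a package choice — only the band itself is part of the
  model class — and is swappable via the modifier's distribution field.
* **Flux noise** — multiplicative N(μ, σ) or truncated-normal draws applied
  to the fluxes of the terms carrying the modifier's id, one draw per
  refresh interval.
* **Event processes** — an independent variable follows (a) a step-and-hold
  schedule table; (b) an exponential renewal process (rate λ) whose events
  reset the variable to truncated-normal magnitudes; or (c) a state-coupled
  rule: each step a Bernoulli trial with success probability
  clamp(X_p, 0, 1) fires an event whose magnitude is a truncated normal with
  a standard deviation read from the state. The identity map with clamping
  for the success probability is a package default (any calibrated
  probability map could be substituted); it is recorded in the event log.
* **Truncation policy** — normal magnitudes that must be nonnegative are
  *resampled*, not clipped, to avoid a spurious point mass at zero
  (an N(0.5, 0.25) magnitude has ≈2.3% negative mass).

Event times that fall between grid points take effect at the first grid
point ≥ the event time (step-and-hold evaluation at grid times does this
automatically) and are logged.

Reproducibility: every modifier and event process draws from its own
sub-stream keyed by `(seed, kind:id)`, so adding or removing one mechanism
never changes another's draws; two runs with the same spec and seed are
bit-identical; and the per-step draw log stored in the trajectory can be
replayed verbatim (`noise_override`), reproducing a stochastic trajectory
exactly under a different seed.

## Steady states

S-systems (exactly one production and one degradation term per variable,
no offsets/regimes) are solved in closed form: equating the two terms and
taking logarithms yields a linear system A·y = b in y = log X, with A the
kinetic-order differences over dependent variables and independent variables
absorbed into b. General GMA systems use damped Newton iteration on
F(exp(y)) = 0 in log coordinates — positivity is structural, no constraint
handling needed — with a central-difference Jacobian, backtracking line
search, deterministic perturb-and-retry on singular Jacobians, and an
∞-norm tolerance of 1e-10. Roots pinned against the positivity floor are
flagged non-interior. A guess-grid front end returns distinct roots
(relative dedup at 1e-6) for multistable systems.

## Parameter estimation

Because the model is a recursion, collocation needs no slope estimation:
for observations spaced τ_obs = m·ϑ apart, the candidate model is advanced m
sub-steps from each observed state and the squared deviations from the next
observations are summed (`difference_sse`). m = 1 recovers the pure
difference method; m > 1 realizes fits where the recursion step is finer
than the data spacing (e.g. τ_obs = 1 with ϑ = 0.5, or τ_obs = 3 with
ϑ = 1). The sub-stepping per observation interval is the natural discrete
analogue of per-interval shooting. The slope objective (central differences
interior, one-sided at the ends, exact for quadratics) is provided for the
ODE-style comparison.

The optimizer is Nelder–Mead with the restart protocol: each restart
rebuilds the simplex at the previous optimum, and the sequence stops when
consecutive optima improve by less than 10⁻³ (absolute, on the SSE scale) or
a restart cap (default 50) is reached. Rate constants are searched in log
space (positivity built in); kinetic orders are searched linearly inside
[−5, 5], enforced by a smooth quadratic penalty. Infeasible evaluations
(domain failures during sub-stepping) return a large penalty
(10¹² scaled by the infeasible fraction) instead of raising, so the simplex
can retreat; the stopping rule never fires while on the penalty plateau.
Because a single simplex occasionally stalls in a poor basin on multi-step
(m > 1) objectives, the driver runs `n_starts` independent repetitions of
the whole protocol (default 3) from seeded log-uniform initial draws and
keeps the best optimum. Fits are deterministic given the seed.

Initial-draw ranges for the packaged branched-pathway fit are generic
kinetic ranges with sign information from the pathway diagram (the feedback
order g₁ is inhibitory, hence negative); no range is centered on the truth
values.

## The synthetic-data generator

`generate_synthetic_timeseries` samples a model at an observation grid using
either (a) the model's own recursion, or (b) a high-accuracy adaptive ODE
integration (rtol 1e-9) of the deterministic, delay-free skeleton — the
benchmark case where data originate from a continuous-time process and the
discrete model is fitted to them. Optional multiplicative Gaussian noise
(resampled until positive) is controlled by the seed. Initial conditions
default to (1, 1, 1, 1) for the branched-pathway benchmark and are always
recorded in the series metadata.

What the generator emulates — and does not. Noiseless, evenly sampled,
fully observed trajectories from a known model family are the cleanest
possible estimation setting. Passing the estimation tests therefore shows
correctness of the objectives and driver, and the size of the
discretization floor; it does not demonstrate robustness to measurement
noise, missing species, or model misspecification beyond the
discrete-vs-continuous mismatch built into the reference generator.

### Estimation benchmark measurements

On the ϑ = 1 recursion fitted to the dense (τ_obs = 1) reference data, the
collocation SSE per datum reaches ~1e-5, below the 5e-4 benchmark and at
the discretization floor; refitting with ϑ = 0.5 shrinks the fitted SSE by
a factor ~4–5 (the test asserts at least a ~linear improvement). Sparse
(τ_obs = 3) and dense fits are compared with a *common* error functional —
the regeneration error of each fitted recursion simulated over the full
span against the dense reference grid — because their collocation
objectives (one- vs three-step-ahead prediction) are different functionals
whose raw values are not comparable. Under the common functional the sparse
fit is within ~10% of the dense one: data sparsity hardly affects the
quality of the estimated model.

## The AhR case-study fixture

Nine species: free AhR (X1), ligand-bound AhR (X2), free ARNT (X3), the
AhR·L·ARNT transcription factor (X4), the repressor protein AhRR (X5), the
AhRR·ARNT repressor complex (X6), AhRR mRNA (X7), target-protein mRNA (X8),
and target protein TP (X9), with the ligand L an independent scheduled
input. Binding steps are mass action; both genes are transcribed at
k·X4·(X6+1)^g with g = −4, so repression by the AhRR·ARNT complex is finite
at X6 = 0. Transcription terms read X4 and X6 at t − τ₁ (τ₁ = 3 h);
translation terms read their mRNA at t − τ₂ (τ₂ = 4 h). The two mRNAs share
all constants and therefore coincide exactly in the deterministic
scenarios. AhRR and TP share a first-order turnover; AhRR is additionally
sequestered by ARNT binding, and its turnover is what lets the system
return to the ligand-free rest state after the stimulus ends. Mass
conservation holds for total AhR and total ARNT up to protein turnover.

The ligand-free state (10, 0, 10, 0, …, 0) is a fixed point of the
deterministic equations; fixture construction *fails* if this invariant is
broken, which pins the transcription of the equation system. Scenario A
strips delays and noise; B applies the delays; C additionally multiplies
the four expression fluxes by N(1, 0.1) draws (σ₁–σ₄) and lets ligand
availability fluctuate multiplicatively with the same distribution (the
form of the ligand noise is a package choice). Under the standard protocol
(ligand 2 on t ∈ [2, 12)), scenario A's TP peak is ≈22% of scenario B's:
without delays, repression builds almost immediately and throttles
expression; with delays, transcription and translation run unabated for
τ₁ + τ₂ ≈ 7 h.

## Lac operon thresholds

The threshold-switched transcription variant needs numeric thresholds and
low/high rate constants that the base model does not supply. The fixture
uses X3_low = 0.3 and X3_high = 0.7 — straddling the base steady state's
internal lactose level 0.1^(1/3) ≈ 0.464 — with α_low = 0.2·X3_low² and
α_high = 0.2·X3_high² chosen so the transcription rate law is continuous at
both boundaries. These four numbers are package choices, recorded in the
fixture metadata.

## Problem sizes and tolerances

Simulations in the tests use the models' native step sizes (ϑ = 0.5 for the
linear pathway, 0.1 for the oscillator, lac operon and AhR, 1 for the
chaotic system) over spans long enough for the asserted feature: ≥ 3 full
oscillation periods (the oscillator's period is ≈ 250 time units at
ϑ = 0.1), 10⁴ steps for boundedness of the chaotic regime, 80 h for the
AhR return-to-rest check. Steady-state residuals are asserted at 1e-10
(∞-norm), closed-form-vs-Newton agreement at 1e-8, fixed-point drift over
1000 steps at 1e-8, and printed steady-state values at the precision with
which they are conventionally quoted. Statistical assertions on random
draws use three standard errors around the expected moment at fixed seeds.

## Known limitations

* Explicit stepping only: stiff systems need small ϑ; the package will not
  rescue a model whose fluxes explode at the chosen step (it reports the
  failing variable and returns the partial trajectory instead).
* No exact-stochastic (Gillespie-type) propensity simulation; noise enters
  through the multiplicative and event mechanisms above.
* The closed-form solver covers S-systems only; general GMA fixed points
  rely on Newton from a (grid of) guesses and can miss roots in other
  basins.
* Estimation assumes fully observed, evenly sampled series with positive
  values wherever fractional kinetic orders apply.
* No stability/eigenvalue analysis of the discrete map and no bifurcation
  tracking; no SBML import/export.
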