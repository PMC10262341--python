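# Methods

## Model and assumptions

`swalloc` works with the individually randomized stepped-wedge design in
which all `J` sequences start in control and exactly one sequence crosses
over to the intervention at the start of each period, giving `T = J + 1`
periods with a measurement at the end of each. The outcome model is

    Y_ijt = β + τ_t + x_jt γ + ε_ijt,    τ_1 = 0,

with a *sustained* treatment effect: `γ` does not depend on time since the
switch. Residuals within an individual are jointly normal with variance
`σ²_ε` and correlation `ρ^|t−t'|` — the exponential-decay (AR(1)-type)
family, chosen over compound symmetry because correlation realistically
weakens with time lag. `ρ` and `σ²_ε` (and the attrition rate `r`) are
design inputs assumed known a priori, e.g. from the literature; estimating
them from data is out of scope. Designs with several sequences sharing a
switch time, transition periods, cluster-level randomization, time-varying
treatment effects, and non-constant or outcome-dependent attrition are all
out of scope.

### Parameterization

The fixed-effects vector is `θ = (β, τ_2, …, τ_T, γ)`, length `T + 1`:
an intercept, `T − 1` period dummies (period 1 as reference), and the
treatment indicator as the *last* column of the per-individual design
matrix `X_j` (`T × (T+1)`). `var(γ̂)` is therefore the last diagonal entry
of `cov(θ̂)`. A single sequence's `X_j` has column rank `T`, one short —
pooling at least two distinct sequences is what identifies `γ`; this is
why `J ≥ 2` is enforced at the type level.

### Attrition

Dropout is monotone and independent of outcomes (MCAR). With a constant
per-period rate `r`, the probability that an individual's last observation
falls at period `t` is

    w_t = (1−r)^(t−1) − (1−r)^t     for t = 1 … T−1,
    w_T = (1−r)^(T−1)               (completers).

The completer convention at `t = T` makes `w` a proper distribution
(mass conserved); the geometric recursion `w_{t+1}/w_t = 1 − r` holds for
all `t ≤ T − 2`. Everyone contributes at least the baseline measurement —
dropout before period 1 is not modeled. This choice matters: dropping the
completer mass (i.e. applying the dropout expression at `t = T` as well)
changes the relative-efficiency surface by up to a percentage point at
high attrition, enough to move near-flat curve maxima between adjacent
grid points; see "Known limitations".

## Variance and optimization

Per unit total sample size, the information contributed by one
sequence-`j` individual in expectation over dropout is

    A_j = Σ_t  w_t  X'_jt V_t⁻¹ X_jt,

computed once per design with linear solves (never explicit inverses
in the hot path). An allocation `p` on the simplex then has
`var(γ̂) = [(Σ_j p_j A_j)⁻¹]` at the treatment entry; variance at absolute
sample size `n` is this divided by `n`, so the optimum is invariant to `n`.
A condition-number guard warns above 1e12 and treats the information as
singular above 1e15 (e.g. all mass on one sequence when `J = 2`).

No closed form links `p` to `var(γ̂)` under exponential decay and/or
attrition, so the minimizer is found numerically: the simplex equality
constraint is eliminated by optimizing the first `J − 1` proportions with
the last implied, SLSQP handles the box constraints (user bounds
intersected with an interior floor of 1e−9) with an analytic gradient
`∂var/∂p_j = −x' A_j x`, `x = M⁻¹ e_γ`. The uniform allocation plus 10
flat-Dirichlet draws (seed 2023 by default) serve as starts; in practice
the objective appears unimodal on the feasible region and all starts
agree, but the restarts are kept as insurance. Ties within 1e−12 in the
objective resolve to the lexicographically smallest `p`, making results
bit-for-bit reproducible for a fixed seed. Convergence tolerance is 1e−10
on the objective; proportions are only rounded at presentation time.
Bounds must satisfy `Σ p_Lj ≤ 1 ≤ Σ p_Uj`, checked before any
optimization. An independent check, `grid_oracle`, enumerates every
lattice allocation at a chosen resolution (batched linear solves, refused
above a configurable point cap) — the optimizer must match or beat it.

## What the simulator emulates

`simulate_trial` generates data exactly under the model above: headcounts
by largest-remainder apportionment of `p·n` (deterministic, ties to the
earlier sequence), multivariate-normal residual vectors with the
exponential-decay covariance, and last-observation periods drawn from `w`
independently of outcomes. `fit_gls` fits with `V` treated as *known* —
the design-stage assumption under which the analytic covariance is exact —
accumulating each individual's truncated contribution `X'_jt V_t⁻¹`.
`monte_carlo_variance` compares the empirical variance of `γ̂` across
replicates with the analytic expected-information value `var(γ̂; p)/n`;
the mean of the per-replicate realized-information variances is reported
as a diagnostic. The standard error of the empirical variance uses the
normal-theory form `s²√(2/(m−1))`, exact here because `γ̂` is Gaussian.

What passing simulations do **not** show about real data: robustness to
estimated (rather than known) `ρ` and `σ²_ε`, to informative or
non-constant dropout, to non-normal outcomes, or to treatment effects
that vary after the switch. The validation closes the loop between the
analytic criterion and the generating model, nothing more.

Default study conditions for validation runs: `n = 300` individuals,
1000 replicates, effects `β = 1`, modest increasing period effects, and
`γ = 0.5`; three parameter cells spanning no/moderate/heavy attrition.
These sizes give Monte Carlo standard errors near 4% of the variance,
tight enough to detect a wrong weighting scheme while keeping the full
suite fast.

## Numerical and design choices

- `σ²_ε` defaults to 1: it scales `var(γ̂)` linearly and cancels from both
  `p*` and RE; it is kept as a parameter for the simulator.
- Sequences and periods are labelled 1-based in every public contract
  (matrices are stored 0-based internally).
- The efficiency grid convention is `J ∈ {3,4,5,6}`, `ρ ∈ {0.1,…,0.9}`
  in steps of 0.1, `r ∈ {0, 0.05, 0.2}`; all configurable. Per-cell
  failures are recorded as NaN rows rather than aborting a sweep.
- The CLI prints proportions at 4 decimals by default (2-decimal display
  via `--decimals 2`); every output embeds the tool version, resolved
  parameters and seed.

## Known limitations

- The optimum is *locally* optimal in the design-parameter sense: it
  depends on the assumed `ρ` and `r`. A sensitivity sweep over plausible
  values (via `efficiency_grid`) is the supported workflow; formal maximin
  robustness is not implemented.
- Under heavy attrition the RE-versus-`ρ` curve is non-monotone but very
  flat near its maximum (differences of ~0.003 across adjacent grid
  points for `J = 4`); the *location* of the grid argmax is therefore
  sensitive to the attrition-weight convention, while every qualitative
  dominance property (in `r`, in `J`, and the ≥ 0.8 floor) is stable.
  For `J = 4, r = 0.2` the completer-mass convention places the argmax at
  `ρ = 0.7`; the visible peak at `ρ = 0.6` occurs at `J = 6`.
- `grid_oracle` is exponential in `J` and intended for `J ≤ 4` at fine
  resolutions.
- No global-optimality certificate is produced; confidence comes from
  multi-start agreement and lattice-oracle dominance checks.
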