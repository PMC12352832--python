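# Methods

## Model

The marker Y at age t is assumed to follow the conditional location-scale
model F_t(y) = F((y − μ(t))/σ(t)): a continuous mean curve, a continuous
positive scale function, and a continuous but otherwise unspecified
baseline distribution F for the standardized residual. Everything the
package does — band construction, the precision criterion, the planner —
lives inside this model. What the model excludes: age-varying shape
(skewness or kurtosis changing with t), discrete or rounded markers
(ties), and covariates other than age.

### Mean curves

Two families are implemented, chosen to cover the two study templates:

* **Growth model** μ(t) = c·(d + I_x(a, b)), x = (t − t′)/(t″ − t′), with
  I_x(a,b) the regularized incomplete beta function. Bounded, monotone
  increasing for a, b > 0; suited to fetal biometric quantities that rise
  from c·d at the start of the age range to c·(d+1) at its end. Fitting is
  nonlinear OLS, solved by variable projection: for fixed (a, b) the model
  is linear in (c·d, c), so the inner pair is profiled out in closed form
  and a trust-region least-squares iteration runs over (a, b) only.
  Because observations sit on a grid of at most a few hundred distinct
  ages, the profiled objective is aggregated to per-age means with count
  weights, making each fit O(grid size) per iteration. Convergence
  tolerance 1e−10 on the relative objective change, at most ~200
  iterations; in simulations the iteration starts at the generating
  parameters, for user data at a heuristic (c ≈ range(Y), d ≈ min(Y)/c,
  a = b = 1).
* **Quartic polynomial** μ(t) = a0 + a1·t + … + a4·t^4, fitted by OLS on an
  orthogonalized, centered/scaled age basis (raw powers of ages up to 280
  days would be badly conditioned), with coefficients mapped back to raw
  powers.

### Dispersion

σ(t) = γ0 + γ1·s(t) with s(t) = (t − t_lo)/(t_hi − t_lo) scaled to [0, 1],
estimated by the least-squares line of the absolute residuals
|Y_i − μ̂(t_i)| on s(t_i). Parameterizing on scaled age makes slope values
comparable between age ranges measured in weeks and in days; the raw-age
slope is γ1/(t_hi − t_lo). The line estimates E|Y − μ(t)| rather than
σ(t) itself (for Gaussian residuals the factor is √(2/π)), but any
positive proportionality constant cancels exactly between σ̂ and the band
coefficients, so no correction is applied. A fitted line that is not
strictly positive over the working age grid is treated as a failed fit.

## Band construction

With ranks r_l = ⌈n(1−q)/2⌉⁺ and r_u = ⌈n(1+q)/2⌉⁺ (smallest integer
*exceeding* the product; at an integer boundary the rule steps up, so
n=100, q=0.90 gives rank 6), the band coefficients k_l, k_u are the r_l-th
and r_u-th order statistics of the scaled residuals, and

L_n(t) = μ̂(t) + k_l·σ̂(t),  U_n(t) = μ̂(t) + k_u·σ̂(t).

For continuous data exactly r_l − 1 points fall strictly below L_n and
n − r_u strictly above U_n. Ties in scaled residuals are measure-zero
under the model; if they occur in rounded user data, the strict
inequalities break them toward the band interior. The rank rule is
computed with a 1e−9 relative guard so that floating-point noise at
integer boundaries (e.g. 100 × 0.05) cannot shift a rank.

## Confidence probability

The precision criterion is the smallest local confidence probability over
the measurement grid 𝒯: for the lower limit,
β_L(n) = min_t P[(1−q)/2 − δ1 < F((L_n(t) − μ(t))/σ(t)) < (1−q)/2 + δ2],
analogously β_U(n), and β_(L,U)(n) with both windows required jointly at
the same age. The minimum is taken outside the probability — per-age event
frequencies are estimated first, then minimized — and the window
inequalities are strict. The windows must lie inside (0, 1), which bounds
the admissible tolerances by the tail mass (1−q)/2.

Estimation is by Monte Carlo: n_rep replicated band estimations on a fixed
realized design. Defaults follow the study conditions: q = 0.90,
δ1 = δ2 = 0.02, β0 = 0.90, n_rep = 10,000 where affordable. Replicates
whose growth fit fails to converge or whose dispersion line goes
non-positive on the grid count as failures of the precision event
(conservative) and are tallied in `n_failed`; in the configurations
shipped they are essentially absent.

Randomness: all replicate data of one evaluation come from a single
counter-based Philox stream keyed on (master seed, sample size). The three
criteria and both one-sided variants therefore share replicates — which is
what makes "n_L and n_U coincide for symmetric baselines" testable without
extra variance — and every result is reproducible from the master seed.
The quartic scenario is vectorized across replicates in blocks (the OLS
projectors are fixed by the design, so a replicate costs a few matrix
products); the growth scenario iterates per replicate over the aggregated
profiled objective.

### Validation oracle

With a single measurement age and known constant curves the band reduces
to raw order statistics of n i.i.d. draws, and F(L_n) = U_(r_l) follows a
Beta(r_l, n − r_l + 1) law, giving the one-sided criterion in closed form.
The Monte Carlo engine run in this degenerate mode (`use_true_curves`)
must agree with the closed form within binomial error; this is the primary
correctness check of the whole simulation chain, and the fast engines are
additionally checked replicate-by-replicate against the public
Model-fit-Results path.

## Sample-size search

The planner seeks the smallest multiple of `step` (default 10) with
β̂ ≥ β0 inside [n_min, n_max] (default bracket 100..120,000, covering the
largest published entry with headroom). The default strategy is geometric
doubling to bracket the target, bisection on step multiples, then a
downward slide while the next smaller multiple still qualifies, so the
reported n* satisfies β̂(n*) ≥ β0 and β̂(n* − step) < β0 under the recorded
seed policy. This assumes β(n) is approximately increasing; observed
order violations among evaluated points are counted on the result object.
The exact single-age profile is in fact sawtoothed in n (the anchoring
rank advances every other step), so an `exhaustive` mode replaces
bisection with a linear upward scan and returns the literal first
crossing; it is the mode to use with cheap closed-form evaluators. An
optional confirmation pass re-evaluates n* at doubled n_rep and walks
upward if the confirmation fails. Evaluations at different sample sizes
reuse the same seed-derivation policy so the β-profile over n is as smooth
as the estimator allows, and a per-n cache shares evaluations between the
three criteria of one configuration.

## Synthetic-data generator

`scenario_truth` reproduces the two study templates: Scenario I, growth
model with a = 1.1494, b = 1.5265, c = 84.0244, d = 0.1992 on the weekly
grid {10 + j/7, 0 ≤ j ≤ 217} (biparietal diameter in mm); Scenario II,
quartic with coefficients (275.548, −19.4763, 1.00317, −0.021839,
0.000171349) on integer days 77..280 (frontal fetal facial angle in
degrees). Age designs are drawn from a discretized beta(a*, b*) law —
inverse-cdf mapping to the age range, snap to the nearest grid point,
ties to the lower point — drawn once per experiment and fixed across
replications; a* = b* = 1 is a deterministic even allocation over grid
indices (⌊K(i − 0.5)/n⌋), so n = m·K places every grid point exactly m
times. Non-uniform designs are redrawn per sample-size cell from subseeds
of the master seed.

Baseline residual families: standard Gaussian; unit-scale Laplace
(variance 2); mean-zero shifted lognormal (X − e^{μ0+σ0²/2}); mean-zero
shifted gamma (λ0·(G − α)). Defaults σ0 = 0.5, α = 4, λ0 = 0.5 are the
package's own choice of a moderately and a mildly right-skewed law
(skewness ≈ 1.75 and 1.0); **they are not calibrated to any published
table**, so planner outputs for the skewed families are comparable only in
direction (upper limits need fewer subjects than lower ones), not in
value. The dispersion truth uses γ0 = 1 unless overridden; published
slope values are exposed directly as γ1 on scaled age.

What the generator does not emulate — and hence what passing tests cannot
show about real data: measurement rounding and the resulting ties,
age-varying residual shape, sampling designs that are informative about Y,
and nonlinear dispersion. The published data clouds are visibly grouped by
measurement precision; the generator produces continuous data.

## Problem sizes in the shipped checks

The test suite and the acceptance script scale replication to desk size:
the Scenario I searches run at n_rep = 2000–4000 (binomial stderr at
β ≈ 0.9 of 0.007–0.005), the Scenario II searches at the full
n_rep = 10,000, skew-direction checks at n_rep = 2000. Near the target the
β-profile has slope ≈ 5·10⁻⁵ per subject, so stderr 0.005 corresponds to
roughly ±100 subjects of search noise at n* ≈ 2000–3000; published entries
are reproduced within a ±10 % band that absorbs both this noise and the
unknown details of the original search protocol.

## Known limitations

* Quantile-regression competitors and parametric (LMS-type) centile
  methods are out of scope; no comparison is implemented.
* No simultaneous-in-t confidence statements about the band boundaries;
  the criterion is pointwise-in-t, minimized over the grid.
* The growth-model fit assumes the age range of the grid is the model's
  support; ages outside [t_lo, t_hi] are rejected rather than
  extrapolated.
* `find_min_n` trusts approximate monotonicity of β(n); heavily
  non-monotone regimes (tiny n, coarse steps) should use `exhaustive`
  mode with a cheap evaluator, or inspect `n_violations`.
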