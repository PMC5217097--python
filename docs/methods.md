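# Methods

## The weighted risk-difference statistic

For a two-arm trial with event types `k = 1..K` observed over a fixed
horizon `(0, tau]`, the package works with the weighted absolute-risk
difference

    T(w, tau) = sum_k w_k (p_Ak(tau) - p_Bk(tau)) = w' D(tau),

where `p_Ak(tau)` is the probability that a subject in arm A experiences
event type `k` in `(0, tau]`.  With weights standardized to sum to one,
`T` is a weighted average of absolute risk differences; with cost-valued
weights it is an expected cost difference.  An integrated variant

    T'(w, tau) = sum_k w_k  integral_0^tau h(t) (p_Ak(t) - p_Bk(t)) dt

(`h >= 0`, default `h == 1`) generalizes restricted-mean-difference tests
to multiple event types.

## Event types

Four event-type settings are supported for a set of component outcomes
ordered least to most severe, each a 0/1 linear map `L` of the exhaustive
setting:

* **exhaustive** — one type per observable combination of components.  The
  no-event category is always excluded, so the covariance matrix of the
  type indicators has full rank (required by the cone inference below).
* **competing risks** — the type of the first event only.
* **worst event** — the most severe component experienced.
* **marginal** — one (overlapping) indicator per component; e.g. for a
  non-fatal N and fatal F, `p(N+) = p(N+F-) + p(N+F+)` and
  `p(F+) = p(N-F+) + p(N+F+)`.

Conventions: events at exactly `tau` count as inside the interval;
same-time transitions for one subject are rejected as invalid; worst-event
severity is the component list order (most severe last).  For combinations
the first event is taken to be the least severe non-absorbing member
(absorbing components necessarily come last); this matches sequential
multistate models without "backward" transitions.

## Estimation

**Complete follow-up.**  Exhaustive type counts are multinomial; estimates
are observed proportions with covariance `(diag(p) - p p')/n`, mapped
through `L`.  For non-overlapping settings this equals the multinomial
covariance of the aggregated counts exactly.

**Right-censored data.**  Each exhaustive type is a node of a directed
multistate tree (one node per combination, each edge acquiring one
component).  State-occupation probabilities are estimated by the
Aalen-Johansen product-integral over the arm's event times.  The
covariance is a Greenwood-type plug-in derived from the martingale
representation: at each event time the running covariance is transported
by the transition factor `B = I + dA` and incremented by the conditional
multinomial covariance of the observed transitions, weighted by the
squared occupation probabilities of the origin states.  Without censoring
the estimator reduces exactly to observed proportions.  No Python library
offers tree-structured Aalen-Johansen with covariances, so both are
implemented here and validated three ways: a hand-computed product-limit
example, agreement with `lifelines`' competing-risks estimator on the
initial-state reduction, and agreement with the subject-level jackknife
within 15% relative Frobenius error at n = 500.

If every subject is censored before `tau`, the last estimable value is
carried forward and the estimate is flagged (`extrapolated=True`).

**Integrated statistic.**  A left-endpoint Riemann sum on a regular grid
(default step `tau/200`); the covariance is the sum over arms of
leave-one-subject-out jackknife covariances of the integrated probability
vector, `((n-1)/n) * sum_i (theta_(i) - theta_bar)(theta_(i) - theta_bar)'`.

## Cone-constrained simultaneous inference

Weight vectors are constrained to a closed convex cone in the form

    C = {w : a_i'w = 0 (i <= s),  a_i'w >= 0 (s < i <= K)},

with the stacked K x K coefficient matrix `M` of full rank and at least one
inequality.  The squared maximal standardized contrast
`Z^2 = (max_{w in C} w'(D_hat - D)/(w'Vw)^{1/2})^2` follows a
chi-bar-squared distribution: a mixture of chi-squared distributions with
0..K degrees of freedom.  Writing `x = V^{-1/2}(D_hat - D) ~ N(0, I)`,
`Z` is the Euclidean norm of the projection of `x` onto the transformed
cone `V^{1/2}C`, so the mixing weight on `i` df is the probability that
this projection lies on a face of dimension `i`.

**Exact weights.**  In constraint coordinates `u = Mw` the face
probabilities factorize (Kudo-type formula) into products of two
multivariate-normal orthant probabilities driven by
`G = (M V^{-1} M')^{-1}`: for the face with inactive inequality set `J`,

    P(face J) = P( N(0, (G_JJ)^{-1}) > 0 ) * P( N(0, G_BB - G_BJ G_JJ^{-1} G_JB) > 0 ),

`B` the active set.  Orthant probabilities use closed forms up to
dimension two (`1/4 + arcsin(r)/(2 pi)` in 2-D) and quasi-Monte-Carlo
integration above (internally seeded, so results are reproducible; the
integrator's tolerance is ~1e-6).  Enumerating `2^(K-s)` faces is
practical for the dimensions that arise here (K <= 10).

A note on conventions: the classical order-restricted-testing literature
derives mixing weights from the projection of `N(0, V)` onto `C` in the
`V^{-1}` metric.  That is a *different* mixture (the face-dimension
distribution of the polar construction) and does not match the
distribution of the maximal standardized contrast unless `V` is the
identity.  The implementation was checked against the empirical
0.975-quantile of `Z^2` simulated directly from the defining maximum.

**Monte-Carlo weights.**  Draw `y ~ N(0, V^{-1})` and project onto `C` in
the `V` metric; count face dimensions.  The projection solver enumerates
candidate active sets (each candidate is a linear map of the draw, so the
whole sweep is vectorized) and selects the feasible candidate with the
smallest objective, breaking ties toward the larger face (ties have
probability zero for continuous `V`).

**Critical values and intervals.**  All intervals have the Wald form
`w'D_hat -/+ eta^{1/2} (w'V_hat w)^{1/2}` with

* `eta = c_{0.975}`: the 0.975 chi-bar quantile given the cone and the
  *estimated* covariance (plug-in; simultaneous over all cone weights),
* `eta = chi2_{0.95, K}`: Scheffe, simultaneous over all contrasts,
* `eta = chi2_{0.95, 1} = 1.96^2`: unadjusted, pointwise.

Quantiles are found by bracketed root-finding on the mixture CDF to 1e-10.
Tests reject when zero falls outside the interval; the adjusted p-value is
the smallest alpha at which rejection occurs, available in closed form as
`2 * P(chibar >= t^2)` for the two-sided chi-bar test (the alpha -> quantile
map is strictly monotone, so no numerical search is needed).  The relative
efficiency `sqrt(eta)/1.96` is the interval-width inflation relative to
the unadjusted interval: 1.43 / 1.70 / 1.25 for Scheffe at K = 3 / 5 / 2,
and e.g. 1.36 (orthant) and 1.21 (severity-ordered cone) for the chi-bar
method in the three-type illness-death setting.

`power_optimal_direction` returns `w proportional to V^{-1} D`, the
maximizer of `w'D/(w'Vw)^{1/2}`, normalized to unit weight sum when the
sum is positive (scaled by its absolute value otherwise, since dividing by
a negative sum would flip the maximizing orientation).  It is advisory:
weights for confirmatory analyses should be pre-specified on clinical
grounds.

## Simulation machinery

**Simulator.**  Constant-hazard directed trees; at each state one
exponential is drawn per outgoing edge and the minimum wins (exact for
constant hazards by memorylessness).  Independent exponential censoring
(rate `censor_rate`) and administrative censoring at `tau` are applied to
the whole path.

**Scenarios.**  Three bundled models:

* illness-death (three event types): root rates 0.05 (non-fatal) and
  0.02 (fatal), 0.2 fatal after the non-fatal event; horizon 5 years;
* five event types: two transient states (0.08, 0.1), direct death 0.04,
  post-transient death 0.2 / 0.3;
* cardiovascular prevention (worst-event types MI < ST < DE): initial
  rates 0.04/0.06/0.015 (control) vs 0.03/0.04/0.01 (intervention),
  doubling after a first event; horizon 3 years; censoring rate 0.05.
  The directed tree lets a post-MI stroke patient continue to face the
  doubled death rate; this is the variant consistent with the model's
  three-year probabilities (29.2% any event in control, 21.3% in
  intervention).

An analytic oracle (matrix exponential of the intensity matrix) provides
exact state-occupation probabilities for truth values and convergence
tests.

**Coverage studies.**  Per replication both arms are generated and
`(D_hat, V_hat)` estimated — directly from multinomial counts when
follow-up is complete (distributionally identical to simulating paths and
classifying at `tau`, and much faster), by Aalen-Johansen otherwise.
Simultaneous coverage over the cone is approximated on a regular lattice
of the cone's intersection with the unit simplex (lattice resolution
chosen to hit a target point count; ~1000 points for the three-type
studies, ~3000 for five types); all grid intervals cover simultaneously
iff the maximal squared standardized deviation is below `eta`.  The
chi-bar critical value is recomputed from each replication's estimated
covariance.  Default 10,000 replications; the bundled validation runs use
2000 (MC s.e. about 0.5 percentage points), which keeps a full study
under a few minutes on one core.

**Power / sample size.**  Simulated rejection probability per candidate
per-group size; the reported size is the smallest candidate reaching the
target power, with linear interpolation between bracketing candidates.
For a cone spanned by a finite set of generator weight vectors (e.g. the
age-specific DALY vectors of the cardiovascular design), the spanning cone
is converted to constraint form via the inverse generator matrix and
detection requires rejection at every generator.  Validation runs use
3000 replications (MC s.e. ~0.55% near 90% power).

## What the synthetic data do and do not emulate

The generator reproduces the designed studies faithfully: constant
cause-specific hazards, independent exponential censoring, 1:1
randomization, and sample sizes of 100-910 per arm.  Real trials add
features deliberately out of scope here: time-varying hazards,
non-Markov dependence beyond event counts, dependent censoring, covariate
heterogeneity, and recurrent events of the same component.  Nominal
coverage in these studies therefore demonstrates correctness of the
inferential machinery under the stated models, not robustness to such
violations; the Aalen-Johansen point estimates remain consistent under
non-Markov dynamics, but the constant-hazard simulator cannot exercise
that case.

## Numerical choices and edge cases

* Covariances are symmetrized and checked PSD to 1e-10; tiny negative
  eigenvalues from floating-point accumulation are clipped to zero.
* Estimated covariances with smallest eigenvalue below 1e-10 of the
  largest are rejected with advice to drop redundant event types (the
  reason the no-event category is excluded by construction).
* Cone membership tolerance: equalities within 1e-10, inequalities above
  -1e-10; active constraints at a projection within 1e-9.
* The chi-bar quantile at `p <= w_tilde_0` is 0 (point mass).
* Replications with degenerate estimated covariance are dropped from
  coverage studies and counted.
* CSV output uses 17 significant digits and CSV input parses with
  round-trip float precision, so write-then-read is lossless and seeded
  runs are byte-reproducible.

## Known limitations

* Jackknife covariance for the integrated statistic refits the estimator
  n times per arm; fine for hundreds of subjects, expensive for tens of
  thousands.
* The exact mixing weights enumerate `2^(K-s)` faces; beyond ~10
  inequality constraints use the Monte-Carlo weights.
* Two arms only; no covariate adjustment or stratification; no bootstrap
  covariance alternative; single occurrence per component.
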