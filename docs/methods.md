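# Methods

## The model class

A categorical marginal model (CMM) constrains the expected-frequency vector
m of a J-way multinomial contingency table through its margins only:

    g(m) = Bᵀ f(Aᵀ m) − c = 0,

where Aᵀ selects marginal cells (each row one cell, represented here as a
`MarginSpec`: a subset of variables pinned to fixed scores), f is a smooth
link with analytic Jacobian, Bᵀ is a full-row-rank constraint matrix, and c
is a criterion vector.  The number of constraints D is the model's degrees
of freedom.  The only distributional assumption is multinomial sampling of
the table; the joint dependence of the items is otherwise unrestricted,
which is what makes the class suitable for hypothesis tests on summary
coefficients of dependent item sets.  When Bᵀ arises as the orthogonal
complement of a design matrix Z, the model parameter is
β = (ZᵀZ)⁻¹ Zᵀ f(Aᵀm).

Three families are built in:

* **Mean** (`mean_model`) — equality of the J item means. For binary items
  the mean numerators are the margins m^j_1; for polytomous items they are
  score-weighted sums of the univariate cells (carried by an internal
  collapse matrix, so Aᵀ itself stays 0/1).  f is the identity, Bᵀ the
  successive-difference matrix, D = J − 1, Z the normalized constant
  column.  Besides β = Σ_j m^j_1/√J we report the overall mean item score
  β/(√J·N), which is the natural scale for simulation summaries.
* **Alpha** (`alpha_model`) — Cronbach's alpha equal to a benchmark, D = 1.
  Alpha is computed from first- and second-order marginal moments with
  divisor-N covariances (the maximum-likelihood convention of the
  multinomial framework; users expecting the n−1 divisor should rescale).
  For binary items the margin set is reduced to {j=1} and {j=1,k=1}; cells
  at score zero are recovered through complements.
* **H_j** (`hj_model`) — every Mokken item-scalability coefficient equal to
  a lower bound, D = J, dichotomous items only.  H_j is one minus the ratio
  of observed to expected-under-independence mass in the Guttman-error
  cells {earlier item = 0, later item = 1} over the scale order.  The
  textbook definition assumes items ordered by ascending popularity; the
  builder's default is the order the items are given, because sample
  coefficients reported for tables in presentation order follow that
  convention, and an `item_order` argument exposes the popularity ordering.
  For J = 2 the two coefficients coincide; the duplicate constraint is
  collapsed to D = 1 with a warning.

All three links carry analytic Jacobians (checked against central finite
differences in the test suite), so constraint evaluation is exact and fast.

## Estimation: ML, MEL, MAEL on a sparse support

All three estimators maximize Σ n_i log m_i subject to g(m) = 0 and
Σ m_i = N, and differ only in the support carrying m:

* **ML** uses all L = Π c_j cells.  Dense materialization is refused above a
  configurable cap (default 10⁷ cells), because L grows exponentially in J.
* **MEL** (maximum empirical likelihood) uses only the observed cells;
  zero-count cells become structural zeros.  The support size is bounded by
  the sample size, so MEL scales to arbitrarily large tables — but on
  sparse data it fails in two characteristic ways (next section).
* **MAEL** adds a small set of deliberately chosen zero-count cells to the
  observed support before fitting.  No observations are added; only the
  support of the distribution is enlarged.

The solver is Aitchison–Silvey/Lang-style Fisher scoring on the
Lagrangian.  With G̃ the constraint Jacobian plus an appended
sum-constraint row and D_m = diag(m):

    solve (G̃ D_m G̃ᵀ) λ = g̃(m) + G̃ (n − m),     m⁺ = n − D_m G̃ᵀ λ,

followed by a damped step: trial iterates are projected onto m ≥ floor
(floor = 10⁻¹²·N, keeping D_m invertible while letting cells sit
numerically at zero) and the step is halved while a penalized merit
function −Σ n log m + κ‖g̃‖₁ (κ tied to the current multipliers) worsens.
Starting values are uniform, m_i = N/S; the iteration cap is 1000.
Convergence requires max|g̃| < 10⁻⁸·N together with either a small step or
a resolved likelihood: near boundary optima the iterate can keep moving
tangentially in directions the likelihood does not resolve, so stagnation
is also accepted when the log-likelihood range over the last 20 iterations
is below 10⁻⁸·(1+|ℓ|) with constraints satisfied.  Fixed points satisfy
the stationarity n_i/m̂_i = 1 + (G̃ᵀλ)_i on interior cells.

**Boundary optima and structural zeros.** On restricted supports, linear
constraints can pin cells to exactly zero even though the constraint set is
nonempty.  If such a cell carries observations the constrained likelihood
is unbounded below and plain scoring creeps geometrically.  For
identity-link models the pinned cells are identified exactly before
iterating: one max-min linear program certifies an interior feasible point;
failing that, per-cell LPs find every cell whose maximum feasible value is
zero.  The fit then runs on the free cells, the pinned cells are reported
at the floor and flagged as `boundary_cells`, and a positive count facing a
pinned expectation makes G² = +∞ (the value computed at the floored
expectation is kept in `G2_truncated`, since any finite number there is an
artifact of where an algorithm stops).  Degrees of freedom are not reduced
for boundary cells or structural zeros: df = D throughout.

**Goodness of fit.** G² = 2Σ_{n>0} n log(n/m̂) with 0·log 0 = 0, Pearson
X² over cells with positive expectation, and the upper-tail chi-square
probability at df = D.  Under the model, G² and X² are asymptotically
chi-square(D); the test suite checks the mean of G² against D under a null
population.

**Parameter uncertainty.** The asymptotic covariance of m̂ on the support
is D_m̂ − D_m̂ G̃ᵀ(G̃ D_m̂ G̃ᵀ)⁻¹ G̃ D_m̂ with the sum-constraint row included
in G̃ — the form that reduces to the multinomial covariance D − mmᵀ/N for
the saturated model.  Standard errors of β̂ follow by the delta method
through the link Jacobian, and are validated against the Monte-Carlo SD of
β̂ over thousands of simulated replications (15% relative agreement) and
against the closed-form multinomial SE √(m(N−m)/N) in the saturated case.

## The two estimation problems and support augmentation

MEL fails on sparse tables in two ways:

* **First-order (empty-set) problem** — g(m) = 0 has no solution on the
  restricted support.  For identity links this is settled exactly by an LP
  feasibility check over {m ≥ 0, Σm = N}; for nonlinear links a heuristic
  minimizes ‖g‖² over the simplex from several random starts and reports
  the problem when the residual cannot be driven to zero (status may also
  be `undetermined`).
* **Second-order problem** — the covariance of the constraint statistics is
  singular on the support, so no inference is possible even when a fit
  exists.  The detector evaluates V = G Σ₀ Gᵀ at the uniform distribution
  over the support, with Σ₀ = D_m − mmᵀ/N the multinomial covariance, and
  reports the problem when the smallest eigenvalue falls below 10⁻¹⁰ times
  the largest.  (Using D_m alone instead of Σ₀ would miss supports whose
  restricted Jacobian is full rank but whose statistic variance is still
  degenerate — e.g. a two-cell support on which every constraint statistic
  is a function of the single free coordinate.)  The first-order problem
  implies the second-order one; the fit routine diagnoses in that order.

`augment_support` repairs both.  Level "first" adds, for every model margin
cell with no contributing support cell, one uniformly random full pattern
consistent with it.  Level "second" additionally covers the pairwise joint
margin cells that drive the covariances of the margin statistics — skipping
incompatible pairs (overlapping variables pinned to conflicting scores,
whose covariance term vanishes identically) — and then adds random zero
cells in batches until the rank test passes, up to a cap of 50·D + 100
cells.  For models with more than 200 margin rows the pairwise sweep is
skipped (for 40 items the H_j model has 820 rows and ~335,000 pairs) and
the rank-test-driven random loop is used directly; random augmentation is
cheap, effective, and all that large models need in practice.  All
randomness flows through one seeded generator recorded in the plan, so
augmentations replay exactly.

## Synthetic data and the study harnesses

Null populations are built in two steps.  First, 1000 response patterns are
drawn from a two-parameter logistic IRT model (2PLM): latent trait
θ ~ N(0,1), P(X_j = 1|θ) = 1/(1+exp(−a_j(θ−b_j))).  Defaults are common
discrimination a = 1.5 and locations equally spaced in [−1.5, 1.5] — a
moderately discriminating, well-spread test, the kind of configuration a
psychometric simulation would call realistic.  Second, the CMM of interest
is fitted to that base table (ML when the full table is materializable,
MAEL otherwise) and π = m̂/N becomes the data-generating distribution.
Because the constraints are imposed exactly in this second step, the
resulting Type-I-error experiment is a genuine null experiment whatever the
2PLM parameters were; the item parameters only choose *where* in the null
hypothesis the population sits.  This emulates questionnaire-like
dependence structure but, deliberately, none of the messier features of
real data (missing responses, local dependence beyond the trait,
respondent heterogeneity) — passing tests certify the estimators and test
calibration under the stated sampling model, not robustness to violations
of it.

The **convergence harness** (`run_convergence_study`) thins a population by
setting a random fraction U of support cells to zero and rescaling (the
thinned population need no longer satisfy the model; only convergence is
scored), then samples tables of N = 50 and attempts ML, MEL and MAEL fits.
Failures are data, classified as first-order, second-order or plain
non-convergence.  Whether a particular thinned support breaks MEL is a
property of which cells survived, so comparisons are averaged over several
thinned populations.  Sample-dependent criteria (alpha benchmark = sample
value + 0.2; H_j benchmark = mean of the sample coefficients) are resolved
per replication; the population itself is built at the base sample's own
coefficient value, which is always feasible.

The **Type-I-error harness** (`run_type1_study`) draws multinomial samples
of size N from a null population and fits by MAEL (level-two augmentation,
fresh derived seed per replication), recording the rejection rate of the G²
test at the 5% level, the convergence rate, and — for the mean model —
bias and SD of the overall-mean parameter.  Non-converged replications
count as non-rejections and are reported separately.  Observed behaviour
with the shipped defaults: the 4-item mean model at N = 250 is calibrated
(rejection rate ≈ 0.05 over 1000 replications); the 40-item scalability
model at N = 250 — about 6 observations per degree of freedom, on a 2⁴⁰
cell table handled entirely through a support of a few hundred cells — is
markedly liberal, and the SD of the mean-model parameter shrinks by ≈ √2
per doubling of N.  β̂ carries a small O(1/N) bias (≈ −0.0015 at N = 250 on
a parameter of ≈ 0.5), ordinary for constrained maximum likelihood and
below the Monte-Carlo noise floor at the replication counts used.

Problem sizes in the shipped tests and acceptance script are chosen to
keep the whole suite in the minutes range on one CPU: worked examples run
in milliseconds; the calibration cell uses 1000 replications at J = 4 and
150 at J = 40; the SE-agreement harness uses 2000 replications.

## Numerical choices, in one place

* Cell order: ascending lexicographic index, last variable fastest.
* Solver: uniform start, max 1000 iterations, tolerance 10⁻⁸·N on both the
  constraint residual and the step; likelihood-stagnation window of 20
  iterations at 10⁻⁸·(1+|ℓ|); floor 10⁻¹²·N; merit halvings capped at 30.
* Boundary reporting: cells at or below 10⁻⁶·N are flagged; a positive
  count facing such an expectation makes G² = +∞ with the truncated value
  logged.
* Rank tolerance for the second-order test: eigenvalue ratio 10⁻¹⁰.
* First-order heuristic (nonlinear links): residual below 10⁻⁶·N counts as
  feasible, above 10⁻⁴·N as infeasible, in between `undetermined`.
* Covariances in the alpha link use divisor N.
* Dense-materialization cap: 10⁷ cells, explicit override required.
* Augmentation cap: 50·D + 100 added cells; pairwise coverage skipped above
  200 margin rows.

## Known limitations

* Polytomous H_j coefficients are out of scope (the scalability link is
  defined for dichotomous items); alpha and mean models accept polytomous
  items.
* First-order detection for nonlinear links is heuristic; `undetermined`
  is a possible status, and fits on such supports may simply fail to
  converge rather than raise a diagnosis.
* The structural-zero reduction is exact only for identity-link models;
  nonlinear models at boundary optima rely on the stagnation rule and may
  report non-convergence.
* Wall-clock performance is logged but never asserted; timing comparisons
  between ML, MEL and MAEL are hardware-bound.
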