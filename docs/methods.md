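# Methods

## Response models

Two item families are supported, both one-parameter exponential families
in the effective ability *t*:

* **Dichotomous** (Rasch / 2PL): `P(U=1|t) = logistic(a(t − b))`, with
  discrimination `a > 0` (default 1, the Rasch case) and difficulty `b`.
* **Polytomous** (adjacent-category partial credit): categories are
  scored `j = 1..h` with one step parameter per category, and
  `P(U=j|t) ∝ exp(j·t − Σ_{v≤j} b_v)`.  Note the `1..h` category scores:
  users of the usual `0..m` partial-credit parameterisation should add a
  unit shift to their category labels (the likelihood and information are
  unaffected; only the labels move).

The **longitudinal regime** models growth over two occasions: pretest
items are answered at `t = θ1`, posttest items at `t = θ1 + θ2`, where
`θ2` is the modifiability dimension added at the second occasion.
Pretest and posttest forms are disjoint item sets (overlapping designs
are representable by giving two items equal parameters).  Because the
two occasions partition the items, the log-likelihood separates as
`g(θ1) + h(θ1 + θ2)`: `θ1` is identified by the pretest block alone and
`θ1 + θ2` by the posttest block alone.  Two consequences matter in
practice: a form needs items on both occasions for the 2-D problem to be
well posed (enforced as a precondition), and a response pattern that is
all-extreme on *one* occasion has no finite maximiser in the
corresponding coordinate even when the overall pattern looks ordinary.

Item information is `a²PQ` for dichotomous items and the category-score
variance `Σ j²P_j − (Σ jP_j)²` for polytomous items; test information is
the scalar sum with every item evaluated at its own occasion's effective
ability.  Because each item model is an exponential family, the
derivatives needed everywhere come from the cumulants of the item score:
the score function is `x − E[x]`, the curvature `−Var[x]`, and the first
and second derivatives of the item information are the third and fourth
cumulants.  This gives exact analytic gradients and Hessians for the
likelihood and for Warm's `½ log I(θ)` penalty at negligible cost.

## Estimators

All five estimators maximise their objective with the same backbone: a
batch (vectorised across response patterns) damped Newton–Raphson with
box projection, an active-set reduction at the box faces, step halving
on the objective, and convergence declared when the box-projected
gradient's infinity norm falls below the tolerance (1e-6 by default) —
an interior stationary point or a boundary KKT point.  Rows that stall
fall back to a coarse-grid multi-start (0.25 spacing, ties broken toward
the smallest θ1 then θ2) followed by Newton polishing.

* **MLE** maximises the log-likelihood; the objective is concave, so
  Newton from the origin converges in a handful of iterations.
* **MAP** uses a non-informative uniform prior on the box `[−4, 4]` per
  dimension: it equals the MLE whenever the MLE is interior and sits on
  the boundary for extreme patterns, which is why it exists even for
  degenerate patterns.
* **WLE** (Warm) adds `½ log I(θ)` with exact first and second
  derivatives via the cumulant identities above.
* **TWLE** weights the dichotomous and polytomous log-likelihood blocks
  by `(I_d/I)^α` and `(I_p/I)^β`.  The tuning loop starts from the MLE:
  if the dichotomous block is already the less informative one, `α = β =
  1`; otherwise both start at `ε = 0.35` and `α` rises in increments of
  0.05 until the dichotomous weight falls below the polytomous weight,
  re-checked at each re-maximised estimate (cap 100 rounds; `ε`, the
  increment and the cap are configurable).  The inner Newton uses the
  exact gradient but approximates the Hessian by the weighted likelihood
  curvature `w₁H_d + w₂H_p` (negative definite by construction); since
  steps are safeguarded by line search and convergence is declared on
  the exact projected gradient, the approximation affects only the path,
  not the solution.
* **IWLE** is a two-stage procedure: compute the MLE, freeze the weights
  `w_i = I_i(θ̂_MLE)/I(θ̂_MLE)` (positive, summing to one), then maximise
  the weighted log-likelihood `Σ w_i ℓ_i(θ)`.  The weights are *not*
  profiled jointly with θ — a deliberate design choice: anchoring at the
  MLE keeps the objective concave and matches the estimator's intended
  use, and a joint mode is intentionally not offered.  With equal
  weights the objective is a positive multiple of the log-likelihood, so
  IWLE reduces to the MLE exactly.

### Search box and patterns without a finite maximiser

Fully extreme patterns (all correct + all top categories, or the
all-bottom mirror) are excluded from likelihood estimation and flagged
as degenerate.  Patterns that are extreme on one occasion only are kept,
but their likelihood increases monotonically in one coordinate; the
estimators therefore search the box `[−6, 6]` per free dimension (the
same domain the dense-grid cross-checks use) and return such patterns at
the boundary as KKT points.  This choice is the main lever behind the
extreme-ability behaviour of all estimators: an unbounded Newton
implementation would instead report whatever iterate it stopped at, and
comparisons between estimators at |θ1| ≥ 3 depend heavily on that
policy.  With the bounded search, Warm's WLE is the least biased
estimator at the grid extremes in our experiments, because its
information penalty holds interior solutions closer to the centre while
the boundary mass is identical across the likelihood estimators; the
item-weighted estimator concentrates its weight on the few items still
informative at an extreme anchor, which shortens the effective test and
raises both its bias and its spread there.

### Numerical details

Dichotomous log-probabilities are computed with `log_expit` (never
forming `log(1−p)` explicitly), polytomous category probabilities with
an exponent max-shift; no clamping is needed for finite abilities, and
information is never clamped.  The inert second coordinate of
unidimensional problems carries a dummy −1 curvature so the 2×2 solves
stay well posed.  Newton steps are capped at 5 in infinity norm; line
search halves up to 40 times and requires strict improvement.

## Simulation studies

The generator reproduces the two study layouts end to end.

**Study 1 (longitudinal).**  Nine test designs: lengths 10/30/60 crossed
with dichotomous:polytomous ratios λ ∈ {2, 1, 0.5} (30 items at λ = 2
means 20 dichotomous + 10 polytomous *per occasion*).  Dichotomous
difficulties are drawn from N(0, 1); each four-category item draws its
steps from N(−1.5, 0.2), N(−0.5, 0.2), N(0.5, 0.2), N(1.5, 0.2) — the
second argument read as an SD, the conventional notation in this
simulation literature, which also matches the tightly clustered step
values the design intends.  True initial abilities sit on the 17-point
grid −4.0(0.5)4.0, with growth tied to the initial level: θ2 = 1.0 for
θ1 < −2 (low starters gain most), 0.8 for −2 ≤ θ1 ≤ 2, and 0.6 for
θ1 > 2.  At each level 1000 patterns are simulated, degenerate patterns
are removed (logged per level), and every requested estimator scores the
identical surviving data.

**Study 2 (unidimensional).**  The same lengths, mixes, grid and
replication count on single-occasion forms combining the 2PL (default:
discriminations from Uniform(0.75, 4/3); a switch fixes a = 1, which
nests Study 1's single-occasion model) with the partial credit model;
MLE vs IWLE by default.

One item bank is drawn per condition per master seed and reused across
levels and replications — the layouts above describe constructed tests,
not per-replication redraws.  A consequence worth knowing: per-level
bias then includes a bank-specific component of up to roughly ±0.05
even mid-scale, which averaging over redrawn banks would remove.
Seeding is hierarchical (`numpy.random.SeedSequence`): master →
condition → {bank, level}, so any record is reproducible from the master
seed alone, and conditions are independent streams.

**What the generator does not emulate.**  Real mixed-format data depart
from these conditions in ways the simulations cannot detect: item
parameters are estimates, not truth; local independence can fail
(passage-based items, practice effects when occasions share content);
ability distributions are not grid-shaped; and real tests are not
centred by construction.  Passing the suite therefore demonstrates
correctness of the estimators under the stated generating process, not
robustness to model misfit.

## Evaluation criteria

Per level and estimator: `|Bias| = |mean(θ̂) − θ|`,
`RMSE = sqrt(mean((θ̂ − θ)²))`, and `RMSD = sqrt(mean((θ̂ − mean θ̂)²))`,
all with population (1/N) denominators, so `RMSE² = bias² + RMSD²`
exactly.  Pooled true-vs-estimated Pearson correlations are computed per
condition and estimator across all levels and replications jointly —
pooling is the only construction that yields one correlation per
condition; θ1 pooling is the headline and θ2 is reported separately.

## Problem sizes used by the checks

The acceptance script runs the full design it reports on (17 levels ×
1000 replications for the headline condition; 1000 replications at the
single levels it quotes elsewhere).  The test suite runs the three
30-item conditions at the full 1000 replications and the
length-comparison at 250 replications per level, sizes chosen so the
Monte-Carlo error is well inside the comparison tolerances.

## Known limitations

* Two occasions only; more occasions (one modifiability per new
  occasion) would generalise the effective-ability map but are not
  implemented.
* No standard errors are attached to the point estimates.
* Item parameters are taken as calibrated inputs; no item-parameter
  estimation is provided.
* 3PL and generalised-partial-credit items are out of scope.
* Warm's weight in the longitudinal case uses the scalar total
  information `I(θ)^{1/2}`.  Because posttest information keeps `I`
  bounded away from zero as θ1 alone diverges, this scalar weight does
  not regularise each coordinate separately — a determinant-based
  matrix weight would, but has no basis in the scalar formulation the
  estimator is defined with.
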