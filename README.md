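# iwlik — item-weighted likelihood scoring for mixed-format tests

Large-scale educational assessments routinely mix dichotomous
(right/wrong) items with polytomous (partial-credit) items, and
longitudinal programmes administer such mixed forms at several occasions
to measure growth. `iwlik` is a library and command-line tool for scoring
these tests: it implements the **item-weighted likelihood estimator
(IWLE)** of latent ability — where each item's log-likelihood
contribution is weighted by its share of the test information — together
with four comparators (MLE, boxed-uniform MAP, Warm's WLE, and the
type-weighted TWLE), and a complete Monte-Carlo framework for comparing
them.

## Models

Dichotomous items follow the Rasch / two-parameter logistic model.  With
effective ability *t* and item parameters *(a, b)*:

    P(U = 1 | t) = exp(a(t − b)) / (1 + exp(a(t − b)))

Polytomous items follow an adjacent-category partial-credit model with
categories *j = 1..h* and step parameters *b₁..b_h*:

    P(U = j | t) ∝ exp(j·t − Σ_{v≤j} b_v)

In the **longitudinal** regime a two-occasion growth design is used:
pretest items are answered at *t = θ₁* (initial ability) and posttest
items at *t = θ₁ + θ₂*, where θ₂ is the modifiability (growth) dimension;
pretest and posttest item sets are disjoint, so the likelihood is a
product over both occasions.  In the **unidimensional** regime a single
occasion is scored on θ₁ alone.

## Estimators

With item information Iᵢ(θ) (= a²PQ for dichotomous items, the
category-score variance for polytomous items) and test information
I(θ) = Σᵢ Iᵢ(θ):

| estimator | objective |
|---|---|
| MLE  | log L(θ) |
| MAP  | log L(θ) maximised over the uniform-prior box [−4, 4]ᵈ |
| WLE  | log L(θ) + ½·log I(θ) |
| TWLE | (I_d/I)^α·log L_d + (I_p/I)^β·log L_p, α/β tuned so the dichotomous block weight ends below the polytomous one |
| IWLE | Σᵢ wᵢ·log Lᵢ(θ) with wᵢ = Iᵢ(θ̂_MLE)/I(θ̂_MLE) fixed at the MLE |

All estimators share a vectorised projected damped Newton–Raphson
optimiser over the box [−6, 6] per free dimension with a coarse-grid
multi-start fallback.  All-extreme response patterns (all correct and
top categories, or all incorrect and bottom) have no finite likelihood
maximiser; they are detected and excluded from the likelihood
estimators (the MAP still exists, at the prior boundary).

## Worked example

Score one examinee on a 10-item mixed unidimensional form (5 dichotomous
2PL items, 5 four-category partial-credit items; true ability 1.2):

```python
import numpy as np
import iwlik as iw

design = iw.study2_design(seed=42, test_lengths=(10,), mixes=(1.0,))
form = iw.draw_item_bank(design, 10, 1.0, np.random.default_rng(42))
resp = iw.simulate_responses(form, iw.Ability(1.2), np.random.default_rng(7))[0]

for fn in (iw.mle, iw.wle, iw.iwle):
    r = fn(form, resp)
    print(f"{r.estimator:>5}: theta1_hat = {r.theta_hat.theta1:+.4f}")

print(np.round(iw.item_weights(form, iw.mle(form, resp).theta_hat), 4))
```

prints

```
  mle: theta1_hat = +1.3687
  wle: theta1_hat = +1.3058
 iwle: theta1_hat = +1.4122
[0.014  0.0455 0.0393 0.0485 0.0207 0.1681 0.167  0.1644 0.1607 0.1719]
```

The three estimators agree to within ~0.1 logit on this pattern; Warm's
WLE is pulled slightly toward the centre by its bias correction.  The
weight vector shows what drives the IWLE: each four-category item
carries roughly 16–17% of the test information at the estimated ability,
three to ten times the share of any single dichotomous item, so the
partial-credit responses dominate the weighted score.

The same operations are available from the shell:

```sh
iwlik simulate --study 1 --length 30 --mix 2 --reps 50 --seed 7 --out-dir out/
iwlik score --item-bank bank.csv --responses resp.csv --estimator iwle --out scores.csv
iwlik summarize --records out/records.csv --out-dir tables/
```

`simulate` writes per-condition tables of |bias|, RMSE and RMSD per
ability level, pooled true-vs-estimated correlations, a degenerate
pattern exclusion log, and a JSON manifest (seeds, config echo, output
digests) sufficient to reproduce the run exactly.

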