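"""Estimator contracts: likelihoods, degenerate handling, optimiser
agreement with dense-grid oracles, and the estimator-specific reductions."""

import numpy as np
import pytest

from iwlik import (
    Ability,
    Item,
    OptimizerConfig,
    TestForm,
    TwleTuning,
    detect_degenerate,
    estimate_batch,
    item_information,
    item_weights,
    iwle,
    log_likelihood,
    map_estimate,
    mle,
    prob_dichotomous,
    prob_polytomous,
    simulate_responses,
    test_information as total_information,
    twle,
    warm_weight,
    wle,
)
from iwlik.models import RegimeError, effective_theta

from conftest import make_long_form, make_uni_form


# --------------------------------------------------------------------------
# independent oracle: per-pattern log-likelihood from the scalar model API


def oracle_loglik(form, responses, ability):
    total = 0.0
    for item, x in zip(form.items, responses):
        if form.regime == "unidimensional":
            t = ability.theta1
        else:
            t = effective_theta(ability, item.occasion)
        if item.kind == "dichotomous":
            p = prob_dichotomous(t, item)
            total += np.log(p if x == 1 else 1.0 - p)
        else:
            total += np.log(prob_polytomous(t, item)[x - 1])
    return total


def grid_argmax_1d(objective, lo=-6.0, hi=6.0, step=0.001):
    grid = np.arange(lo, hi + step / 2, step)
    vals = np.array([objective(t) for t in grid])
    return grid[int(np.argmax(vals))]


class TestLogLikelihood:
    def test_single_item_half(self, rasch_item):
        form = TestForm((rasch_item,), "unidimensional")
        assert log_likelihood(form, [1], Ability(0.0)) == pytest.approx(
            -0.693147, abs=1e-6
        )

    def test_additivity_over_items(self, uni_form):
        resp = [1, 0, 1, 2, 4]
        ab = Ability(0.3)
        parts = oracle_loglik(uni_form, resp, ab)
        assert log_likelihood(uni_form, resp, ab) == pytest.approx(parts, rel=1e-12)

    def test_three_item_toy_against_product_of_logistics(self):
        form = make_uni_form(n_dich=3, n_poly=0)  # b = -1, 0, 1
        resp = [1, 1, 0]
        want = sum(
            np.log(p)
            for p in (
                prob_dichotomous(0.0, form.items[0]),
                prob_dichotomous(0.0, form.items[1]),
                1 - prob_dichotomous(0.0, form.items[2]),
            )
        )
        assert log_likelihood(form, resp, Ability(0.0)) == pytest.approx(want)

    def test_longitudinal_uses_occasion_thetas(self, long_form):
        resp = [1, 0, 2, 1, 1, 3]
        ab = Ability(0.5, 0.9)
        assert log_likelihood(long_form, resp, ab) == pytest.approx(
            oracle_loglik(long_form, resp, ab), rel=1e-12
        )

    def test_length_mismatch_rejected(self, uni_form):
        with pytest.raises(ValueError):
            log_likelihood(uni_form, [1, 0], Ability(0.0))


class TestDegenerate:
    def test_all_top_and_all_bottom(self):
        form = make_uni_form(n_dich=3, n_poly=2)
        assert detect_degenerate(form, [1, 1, 1, 4, 4])
        assert detect_degenerate(form, [0, 0, 0, 1, 1])
        assert not detect_degenerate(form, [1, 1, 0, 4, 4])
        assert not detect_degenerate(form, [0, 0, 0, 1, 2])

    def test_degenerate_pattern_not_estimated(self):
        form = make_uni_form(n_dich=3, n_poly=2)
        r = mle(form, [1, 1, 1, 4, 4])
        assert r.degenerate and r.theta_hat is None and not r.converged

    def test_map_estimates_degenerate_at_prior_boundary(self):
        form = make_uni_form(n_dich=3, n_poly=2)
        r = map_estimate(form, [1, 1, 1, 4, 4])
        assert r.degenerate
        assert r.theta_hat.theta1 == pytest.approx(4.0, abs=1e-9)


class TestMle:
    @pytest.mark.parametrize("r_correct", [1, 3, 5, 9])
    def test_rasch_closed_form_equal_difficulties(self, r_correct):
        n = 10
        items = tuple(
            Item(f"d{i}", "dichotomous", difficulty=0.0) for i in range(n)
        )
        form = TestForm(items, "unidimensional")
        resp = [1] * r_correct + [0] * (n - r_correct)
        res = mle(form, resp)
        assert res.converged
        assert res.theta_hat.theta1 == pytest.approx(
            np.log(r_correct / (n - r_correct)), abs=1e-5
        )

    def test_matches_dense_grid_argmax(self, uni_form):
        resp = [1, 0, 1, 3, 2]
        res = mle(form := uni_form, resp)
        star = grid_argmax_1d(lambda t: oracle_loglik(form, resp, Ability(t)))
        assert res.theta_hat.theta1 == pytest.approx(star, abs=0.005)

    def test_longitudinal_grid_argmax_2d(self, long_form):
        resp = [1, 0, 2, 1, 1, 3]
        res = mle(long_form, resp)
        g = np.arange(-3.0, 3.0001, 0.01)
        best, bval = None, -np.inf
        for t1 in g:
            for t2 in g:
                v = oracle_loglik(long_form, resp, Ability(t1, t2))
                if v > bval:
                    best, bval = (t1, t2), v
        assert res.theta_hat.theta1 == pytest.approx(best[0], abs=0.02)
        assert res.theta_hat.theta2 == pytest.approx(best[1], abs=0.02)

    def test_growth_recovery_near_zero_when_no_growth(self):
        form = make_long_form(6, 3)
        rng = np.random.default_rng(21)
        R = simulate_responses(form, Ability(0.0, 0.0), rng, size=400)
        res = estimate_batch(form, R, ("mle",))["mle"]
        t2 = res.theta2[~np.isnan(res.theta2)]
        assert abs(t2.mean()) < 4 * t2.std() / np.sqrt(t2.size) + 0.05

    def test_identifiability_needs_both_occasions(self):
        items = tuple(
            Item(f"d{i}", "dichotomous", "pretest", difficulty=0.0) for i in range(4)
        )
        form = TestForm(items, "longitudinal")
        with pytest.raises(RegimeError):
            mle(form, [1, 0, 1, 0])


class TestMap:
    def test_equals_mle_for_interior_solutions(self, uni_form):
        resp = [1, 0, 1, 3, 2]
        assert map_estimate(uni_form, resp).theta_hat.theta1 == pytest.approx(
            mle(uni_form, resp).theta_hat.theta1, abs=1e-6
        )

    def test_all_correct_hits_upper_boundary(self):
        form = make_uni_form(n_dich=4, n_poly=0)
        r = map_estimate(form, [1, 1, 1, 1])
        assert r.theta_hat.theta1 == pytest.approx(4.0, abs=1e-9)
        assert r.converged  # boundary KKT point

    def test_matches_grid_argmax_over_the_box(self, uni_form):
        resp = [1, 1, 1, 4, 3]
        star = grid_argmax_1d(
            lambda t: oracle_loglik(uni_form, resp, Ability(t)), -4.0, 4.0
        )
        assert map_estimate(uni_form, resp).theta_hat.theta1 == pytest.approx(
            star, abs=0.005
        )


class TestWarmWeightAndWle:
    def test_weight_is_root_information(self, rasch_item):
        form = TestForm((rasch_item,), "unidimensional")
        assert warm_weight(form, Ability(0.0)) == pytest.approx(0.5)

    def test_doubling_the_form_scales_by_sqrt2(self, uni_form):
        doubled = TestForm(
            tuple(it for it in uni_form.items for _ in range(2)), "unidimensional"
        )
        ab = Ability(0.7)
        assert warm_weight(doubled, ab) == pytest.approx(
            np.sqrt(2) * warm_weight(uni_form, ab), rel=1e-12
        )

    def test_composes_item_information_oracles(self, uni_form):
        ab = Ability(-0.4)
        total = sum(item_information(it, -0.4) for it in uni_form.items)
        assert warm_weight(uni_form, ab) == pytest.approx(np.sqrt(total), rel=1e-12)

    def test_wle_matches_weighted_grid_argmax(self, uni_form):
        resp = [1, 0, 0, 2, 3]

        def objective(t):
            return oracle_loglik(uni_form, resp, Ability(t)) + np.log(
                warm_weight(uni_form, Ability(t))
            )

        assert wle(uni_form, resp).theta_hat.theta1 == pytest.approx(
            grid_argmax_1d(objective), abs=0.005
        )

    def test_warm_bias_reduction_vs_mle(self):
        # Warm's estimator should cut the outward finite-test bias of the
        # MLE in a seeded dichotomous simulation
        items = tuple(
            Item(f"d{i}", "dichotomous", difficulty=b)
            for i, b in enumerate(np.linspace(-1.5, 1.5, 20))
        )
        form = TestForm(items, "unidimensional")
        rng = np.random.default_rng(3)
        theta = 1.0
        R = simulate_responses(form, Ability(theta), rng, size=2000)
        res = estimate_batch(form, R, ("mle", "wle"))
        b_mle = abs(np.nanmean(res["mle"].theta1) - theta)
        b_wle = abs(np.nanmean(res["wle"].theta1) - theta)
        assert b_wle < b_mle


class TestItemWeights:
    def test_identical_items_share_weight(self):
        items = tuple(
            Item(f"d{i}", "dichotomous", difficulty=0.3) for i in range(5)
        )
        form = TestForm(items, "unidimensional")
        np.testing.assert_allclose(item_weights(form, Ability(0.0)), np.full(5, 0.2))

    def test_information_ratio_toy(self, rasch_item, poly_uniform_item):
        form = TestForm((rasch_item, poly_uniform_item), "unidimensional")
        np.testing.assert_allclose(
            item_weights(form, Ability(0.0)), [0.25 / 1.5, 1.25 / 1.5], rtol=1e-12
        )

    def test_normalized_on_random_forms(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            form = make_uni_form(
                n_dich=int(rng.integers(1, 5)),
                n_poly=int(rng.integers(1, 4)),
                b=rng.normal(0, 1, 6),
                steps=rng.normal(0, 1, 4),
            )
            w = item_weights(form, Ability(float(rng.uniform(-3, 3))))
            assert (w > 0).all()
            assert w.sum() == pytest.approx(1.0, abs=1e-12)


class TestIwle:
    def test_reduces_to_mle_under_uniform_weights(self):
        items = tuple(
            Item(f"d{i}", "dichotomous", difficulty=0.4) for i in range(8)
        )
        form = TestForm(items, "unidimensional")
        resp = [1, 1, 0, 1, 0, 0, 1, 0]
        assert iwle(form, resp).theta_hat.theta1 == pytest.approx(
            mle(form, resp).theta_hat.theta1, abs=1e-7
        )

    def test_weights_recorded_at_the_mle_anchor(self, uni_form):
        resp = [1, 0, 1, 3, 2]
        res = iwle(uni_form, resp)
        anchor = mle(uni_form, resp).theta_hat
        np.testing.assert_allclose(
            res.weights_used, item_weights(uni_form, anchor), rtol=1e-9
        )

    def test_matches_weighted_grid_argmax(self, uni_form):
        resp = [1, 1, 0, 2, 2]
        anchor = mle(uni_form, resp).theta_hat
        w = item_weights(uni_form, anchor)

        def objective(t):
            ab = Ability(t)
            total = 0.0
            for wi, item, x in zip(w, uni_form.items, resp):
                if item.kind == "dichotomous":
                    p = prob_dichotomous(t, item)
                    total += wi * np.log(p if x == 1 else 1 - p)
                else:
                    total += wi * np.log(prob_polytomous(t, item)[x - 1])
            return total

        assert iwle(uni_form, resp).theta_hat.theta1 == pytest.approx(
            grid_argmax_1d(objective), abs=0.005
        )


class TestTwle:
    def test_ratios_stay_one_when_polytomous_block_dominates(self):
        form = make_uni_form(n_dich=2, n_poly=4)
        resp = [1, 0, 2, 3, 2, 1]
        res = twle(form, resp)
        assert res.twle_alpha == pytest.approx(1.0)
        assert res.twle_beta == pytest.approx(1.0)

    def test_equal_blocks_with_fixed_equal_ratios_reduce_to_mle(self):
        # each 2-category partial-credit item matches one dichotomous item
        # everywhere, so I_d(theta) == I_p(theta) for all theta; with
        # alpha == beta the objective is proportional to the log-likelihood
        bs = [-0.5, 0.4, 1.0]
        items = tuple(
            Item(f"d{i}", "dichotomous", difficulty=b) for i, b in enumerate(bs)
        ) + tuple(
            Item(f"p{i}", "polytomous", steps=(0.0, b)) for i, b in enumerate(bs)
        )
        form = TestForm(items, "unidimensional")
        resp = [1, 0, 0, 2, 2, 1]
        res = twle(form, resp, fixed_ratios=(0.5, 0.5))
        ref = mle(form, resp)
        assert res.theta_hat.theta1 == pytest.approx(ref.theta_hat.theta1, abs=1e-6)

    def test_tuned_weights_satisfy_the_ordering(self):
        rng = np.random.default_rng(29)
        checked = 0
        for _ in range(60):
            form = make_uni_form(
                n_dich=int(rng.integers(2, 7)),
                n_poly=int(rng.integers(1, 4)),
                b=rng.normal(0, 1, 6),
                steps=np.sort(rng.normal(0, 1, 4)),
            )
            ab = Ability(float(rng.uniform(-2, 2)))
            resp = simulate_responses(form, ab, rng)[0]
            res = twle(form, resp)
            if res.degenerate or not res.converged:
                continue
            th = res.theta_hat
            i_d = sum(
                item_information(it, th.theta1)
                for it in form.items
                if it.kind == "dichotomous"
            )
            i_p = sum(
                item_information(it, th.theta1)
                for it in form.items
                if it.kind == "polytomous"
            )
            total = i_d + i_p
            w1 = (i_d / total) ** res.twle_alpha
            w2 = (i_p / total) ** res.twle_beta
            assert w1 < w2
            checked += 1
        assert checked > 30

    def test_needs_both_item_types(self):
        form = make_uni_form(n_dich=3, n_poly=0)
        with pytest.raises(RegimeError):
            twle(form, [1, 0, 1])


class TestOptimizerContracts:
    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            OptimizerConfig(tolerance=0.0)
        with pytest.raises(ValueError):
            OptimizerConfig(max_iter=0)

    def test_rmse_decreases_with_test_length(self):
        # longer tests pin the ability down more tightly for every estimator
        rng = np.random.default_rng(4)
        rmses = {m: [] for m in ("mle", "map", "wle", "twle", "iwle")}
        for n_d, n_p in ((6, 4), (18, 12), (36, 24)):
            form = make_uni_form(
                n_dich=n_d,
                n_poly=n_p,
                b=rng.normal(0, 1, n_d),
                steps=(-1.5, -0.5, 0.5, 1.5),
            )
            R = simulate_responses(form, Ability(0.5), rng, size=200)
            res = estimate_batch(form, R, tuple(rmses))
            for m, r in res.items():
                e = r.theta1[~np.isnan(r.theta1)]
                rmses[m].append(np.sqrt(np.mean((e - 0.5) ** 2)))
        for m, vals in rmses.items():
            assert vals[0] > vals[1] > vals[2], (m, vals)

    def test_batch_and_single_pattern_agree(self, uni_form):
        rng = np.random.default_rng(31)
        R = simulate_responses(uni_form, Ability(-0.7), rng, size=12)
        batch = estimate_batch(uni_form, R, ("mle", "wle", "iwle"))
        for i in range(12):
            for m, fn in (("mle", mle), ("wle", wle), ("iwle", iwle)):
                single = fn(uni_form, R[i])
                if single.degenerate:
                    assert batch[m].degenerate[i]
                else:
                    assert single.theta_hat.theta1 == pytest.approx(
                        batch[m].theta1[i], abs=1e-8
                    )
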