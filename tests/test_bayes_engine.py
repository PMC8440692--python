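"""Grid posterior updating, marginal estimates, HWCI and reconstruction."""

import numpy as np
import pytest

from qsat import (
    ParameterGrid,
    Posterior,
    SATParams,
    estimate_params,
    hwci,
    hwci_from_samples,
    init_prior,
    marginal,
    pc_grid,
    posterior_mixture_curve,
    prob_correct,
    read_posterior_json,
    reconstruct_function,
    trial_likelihood,
    update,
    write_posterior_json,
)


def point_mass(grid, i, j, k):
    m = np.zeros(grid.shape)
    m[i, j, k] = 1.0
    return Posterior(grid, m)


class TestPrior:
    def test_default_grid_uniform(self, grid, uniform_prior):
        assert grid.shape == (21, 30, 25)
        assert np.allclose(uniform_prior.mass, 1.0 / 15750)
        assert uniform_prior.mass.sum() == pytest.approx(1.0, abs=1e-12)

    def test_toy_grid_uniform(self):
        g = ParameterGrid(np.array([0.4, 0.5]), np.array([1.0, 2.0]),
                          np.array([0.1, 0.2]))
        assert np.allclose(init_prior(g).mass, 1 / 8)

    def test_default_axes(self, grid):
        assert grid.lam_axis[0] == 0.4 and grid.lam_axis[-1] == 0.5
        assert grid.gam_axis[0] == 1.0 and grid.gam_axis[-1] == 30.0
        assert grid.del_axis[0] == 0.02 and grid.del_axis[-1] == 0.5

    def test_invalid_axes_rejected(self):
        with pytest.raises(ValueError):
            ParameterGrid(lam_axis=np.array([0.5, 0.4]))


class TestLikelihood:
    def test_flat_below_every_intercept(self, grid, task):
        lik = trial_likelihood(grid, task, 0.01, 1)
        assert np.allclose(lik, 0.5)
        lik0 = trial_likelihood(grid, task, 0.01, 0)
        assert np.allclose(lik0, 0.5)

    def test_correct_and_incorrect_sum_to_one(self, grid, task):
        lc = trial_likelihood(grid, task, 0.7, 1)
        li = trial_likelihood(grid, task, 0.7, 0)
        assert np.allclose(lc + li, 1.0)
        assert np.all((lc > 0) & (lc < 1))

    def test_matches_prob_correct_at_grid_point(self, grid, task):
        # observer-1 lam and delta lie on the grid; check that entry
        i = np.where(np.isclose(grid.lam_axis, 0.47))[0][0]
        k = np.where(np.isclose(grid.del_axis, 0.28))[0][0]
        j = np.where(np.isclose(grid.gam_axis, 7.0))[0][0]
        lik = trial_likelihood(grid, task, 0.7, 1)
        expected = prob_correct(SATParams(0.47, 7.0, 0.28), task, 0.7)
        assert lik[i, j, k] == pytest.approx(expected, abs=1e-12)

    def test_pc_grid_matches_direct_evaluation(self, tiny_grid, task):
        table = tiny_grid.param_table()
        for rt in (0.05, 0.3, 0.9):
            got = pc_grid(tiny_grid, task, rt).ravel()
            want = [prob_correct(SATParams(*row), task, rt) for row in table]
            assert np.allclose(got, want, atol=1e-12)


class TestUpdate:
    def test_uninformative_trial_keeps_prior(self, uniform_prior, task):
        post = update(uniform_prior, task, 0.01, 1)
        assert np.allclose(post.mass, uniform_prior.mass, atol=1e-15)

    def test_toy_two_point_hand_computation(self):
        # prior (0.5, 0.5), correct-likelihoods (0.9, 0.6) -> (0.6, 0.4)
        prior = np.array([0.5, 0.5])
        lik = np.array([0.9, 0.6])
        post = prior * lik / (prior * lik).sum()
        assert np.allclose(post, [0.6, 0.4])

    def test_sequential_equals_joint_product(self, tiny_grid, task, rng):
        trials = [(float(rng.uniform(0.1, 1.0)), int(rng.integers(2)))
                  for _ in range(25)]
        post = init_prior(tiny_grid)
        for rt, c in trials:
            post = update(post, task, rt, c)
        joint = np.ones(tiny_grid.shape)
        for rt, c in trials:
            joint *= trial_likelihood(tiny_grid, task, rt, c)
        joint /= tiny_grid.size
        joint /= joint.sum()
        assert np.allclose(post.mass, joint, atol=1e-10)

    def test_order_invariance(self, tiny_grid, task, rng):
        trials = [(float(rng.uniform(0.1, 1.2)), int(rng.integers(2)))
                  for _ in range(30)]
        def run(seq):
            p = init_prior(tiny_grid)
            for rt, c in seq:
                p = update(p, task, rt, c)
            return p.mass
        perm = list(trials)
        rng.shuffle(perm)
        assert np.allclose(run(trials), run(perm), atol=1e-12)

    def test_normalization_preserved(self, uniform_prior, task, rng):
        post = uniform_prior
        for _ in range(50):
            post = update(post, task, float(rng.uniform(0.1, 1.2)),
                          int(rng.integers(2)))
            assert abs(post.mass.sum() - 1.0) < 1e-12
            assert np.all(post.mass >= 0)

    def test_oracle_equivalence_small_grid(self, tiny_grid, task):
        """Posterior equals brute-force enumeration of prior x likelihoods."""
        trials = [(0.3, 1), (0.5, 0), (0.7, 1), (0.9, 1), (0.2, 0),
                  (0.45, 1), (1.1, 1), (0.15, 0), (0.6, 1), (0.8, 0)]
        post = init_prior(tiny_grid)
        for rt, c in trials:
            post = update(post, task, rt, c)
        # oracle: per-theta products via explicit Python loops
        table = tiny_grid.param_table()
        weights = []
        for lam, gam, dlt in table:
            p = 1.0 / len(table)
            params = SATParams(lam, gam, dlt)
            for rt, c in trials:
                pc = prob_correct(params, task, rt)
                p *= pc if c else 1 - pc
            weights.append(p)
        weights = np.array(weights) / np.sum(weights)
        assert np.allclose(post.mass.ravel(), weights, atol=1e-12)


class TestMarginalsAndEstimates:
    def test_uniform_marginals_and_means(self, uniform_prior):
        for ax, n in (("lam", 21), ("gam", 30), ("del", 25)):
            m = marginal(uniform_prior, ax)
            assert m.size == n and np.allclose(m, 1 / n)
        est = estimate_params(uniform_prior)
        assert est.lam == pytest.approx(0.45, abs=1e-12)
        assert est.gam == pytest.approx(15.5, abs=1e-12)
        assert est.delta == pytest.approx(0.26, abs=1e-12)

    def test_point_mass_estimate(self, grid):
        i = np.where(np.isclose(grid.lam_axis, 0.495))[0][0]
        j = np.where(np.isclose(grid.gam_axis, 22.0))[0][0]
        k = np.where(np.isclose(grid.del_axis, 0.24))[0][0]
        est = estimate_params(point_mass(grid, i, j, k))
        assert (est.lam, est.gam, est.delta) == pytest.approx((0.495, 22.0, 0.24))

    def test_marginal_matches_brute_force(self, tiny_grid, rng):
        m = rng.random(tiny_grid.shape)
        m /= m.sum()
        post = Posterior(tiny_grid, m)
        want = np.array([m[i].sum() for i in range(3)])
        assert np.allclose(marginal(post, "lam"), want)
        want_g = np.array([m[:, j, :].sum() for j in range(3)])
        assert np.allclose(marginal(post, "gam"), want_g)
        assert marginal(post, "del").sum() == pytest.approx(1.0)

    def test_estimates_inside_grid_hull(self, tiny_grid, task, rng):
        post = init_prior(tiny_grid)
        for _ in range(40):
            post = update(post, task, float(rng.uniform(0.1, 1.2)),
                          int(rng.integers(2)))
        est = estimate_params(post)
        assert tiny_grid.lam_axis[0] <= est.lam <= tiny_grid.lam_axis[-1]
        assert tiny_grid.gam_axis[0] <= est.gam <= tiny_grid.gam_axis[-1]
        assert tiny_grid.del_axis[0] <= est.delta <= tiny_grid.del_axis[-1]


class TestHWCI:
    def test_uniform_21_point_lambda_axis(self, grid):
        """ceil(0.682*21) = 15 points -> half-width 14*0.005/2 = 0.035."""
        m = np.full(21, 1 / 21)
        ci = hwci(m, grid.lam_axis)
        assert ci.half_width == pytest.approx(0.035, abs=1e-12)

    def test_point_mass_zero_width(self, grid):
        m = np.zeros(25)
        m[10] = 1.0
        assert hwci(m, grid.del_axis).half_width == 0.0

    def test_full_level_spans_axis(self, grid):
        m = np.full(30, 1 / 30)
        ci = hwci(m, grid.gam_axis, level=1.0)
        assert ci.lower == 1.0 and ci.upper == 30.0
        assert ci.half_width == pytest.approx(14.5)

    def test_shortest_interval_prefers_mode(self):
        # hand enumeration: 2-point windows hold 0.15 / 0.7 / 0.8 / 0.25;
        # both [1,2] and [2,3] qualify, tie breaks to the smaller lower bound
        values = np.arange(5.0)
        m = np.array([0.05, 0.1, 0.6, 0.2, 0.05])
        ci = hwci(m, values, level=0.682)
        assert (ci.lower, ci.upper) == (1.0, 2.0)

    def test_sample_hwci_matches_grid_limit(self, rng):
        x = rng.normal(0, 1, 100_000)
        hw = hwci_from_samples(x, 0.682)
        # shortest 68.2% interval of a standard normal ~ +-0.999 sigma
        assert hw == pytest.approx(1.0, abs=0.03)


class TestReconstruction:
    times = np.array([0.06, 0.12, 0.36, 0.7, 1.2])

    def test_point_mass_reproduces_true_curve(self, grid, task, rng):
        i, j, k = 14, 6, 13
        post = point_mass(grid, i, j, k)
        params = SATParams(grid.lam_axis[i], grid.gam_axis[j], grid.del_axis[k])
        mean, spread = reconstruct_function(post, task, self.times, 200, rng)
        assert np.allclose(mean, prob_correct(params, task, self.times))
        assert np.allclose(spread, 0.0)

    def test_resampled_mean_converges_to_exact_mixture(self, tiny_grid, task, rng):
        m = rng.random(tiny_grid.shape)
        m /= m.sum()
        post = Posterior(tiny_grid, m)
        exact = posterior_mixture_curve(post, task, self.times)
        mean, _ = reconstruct_function(post, task, self.times, 40_000, rng)
        assert np.allclose(mean, exact, atol=0.002)

    def test_values_within_probability_bounds(self, uniform_prior, task, rng):
        mean, spread = reconstruct_function(uniform_prior, task, self.times,
                                            500, rng)
        assert np.all((mean >= task.chance) & (mean <= 1.0))
        assert np.all(spread >= 0)

    def test_mixture_oracle_brute_force(self, tiny_grid, task):
        m = np.full(tiny_grid.shape, 1 / 27)
        post = Posterior(tiny_grid, m)
        got = posterior_mixture_curve(post, task, self.times)
        want = np.zeros_like(self.times)
        for row, w in zip(tiny_grid.param_table(), m.ravel()):
            want += w * np.asarray(prob_correct(SATParams(*row), task, self.times))
        assert np.allclose(got, want, atol=1e-12)


def test_posterior_json_round_trip(tiny_grid, task, rng, tmp_path):
    post = init_prior(tiny_grid)
    for _ in range(5):
        post = update(post, task, float(rng.uniform(0.2, 1.0)), 1)
    p = tmp_path / "post.json"
    write_posterior_json(post, p)
    back = read_posterior_json(p)
    assert np.allclose(back.mass, post.mass)
    assert np.allclose(back.grid.gam_axis, tiny_grid.gam_axis)


def test_invalid_posterior_rejected(tiny_grid):
    with pytest.raises(ValueError):
        Posterior(tiny_grid, np.full(tiny_grid.shape, 1.0))  # sums to 27
    bad = np.zeros(tiny_grid.shape)
    bad[0, 0, 0] = 1.5
    bad[1, 1, 1] = -0.5
    with pytest.raises(ValueError):
        Posterior(tiny_grid, bad)
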