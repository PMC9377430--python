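import numpy as np
import pytest
from scipy.special import gammaln
from scipy.stats import gamma as gamma_dist, norm
from sklearn.base import clone

from greenrisk.bym import (BYMPoissonModel, PosteriorSamples, compute_psi,
                           icar_quadratic, log_unnormalized_posterior,
                           relative_risk, summarize)
from greenrisk.geography import generate_lattice
from tests.conftest import make_synthetic_stratum

# 4-region path graph used by the oracle tests
PATH4 = [[1], [0, 2], [1, 3], [2]]
PATH4_EDGES = [(0, 1), (1, 2), (2, 3)]


def oracle_log_posterior(beta, u, s, tau_u, tau_s, y, E, X, edges,
                         beta_sd=100.0, a=0.5, b=0.0005):
    """Naive term-by-term evaluation with scipy distributions and loops."""
    n = len(y)
    total = 0.0
    for i in range(n):
        mu = E[i] * np.exp(beta[0] + sum(beta[k + 1] * X[i][k]
                                         for k in range(len(X[i])))
                           + u[i] + s[i])
        total += y[i] * np.log(mu) - mu          # log y! dropped
    for bk in beta:
        total += norm.logpdf(bk, 0, beta_sd)
    for ui in u:
        total += norm.logpdf(ui, 0, 1 / np.sqrt(tau_u))
    quad = sum((s[i] - s[j]) ** 2 for i, j in edges)
    rank = n - 1  # connected path
    total += 0.5 * rank * (np.log(tau_s) - np.log(2 * np.pi)) - 0.5 * tau_s * quad
    for tau in (tau_u, tau_s):
        total += gamma_dist.logpdf(tau, a, scale=1 / b)
    return total


class TestIcarQuadratic:
    def test_constant_vector_is_zero(self, lattice_3x3):
        assert icar_quadratic(np.full(9, 3.7), lattice_3x3) == 0.0

    def test_single_pair(self):
        assert icar_quadratic([0.0, 1.0], [[1], [0]]) == 1.0

    def test_matches_brute_force_edge_loop(self, lattice_3x3):
        rng = np.random.default_rng(0)
        s = rng.standard_normal(9)
        brute = sum((s[i] - s[j]) ** 2
                    for i, nbrs in enumerate(lattice_3x3.adjacency)
                    for j in nbrs if i < j)
        assert icar_quadratic(s, lattice_3x3) == pytest.approx(brute, rel=1e-12)


class TestLogPosterior:
    @pytest.fixture()
    def toy(self):
        rng = np.random.default_rng(1)
        return dict(y=np.array([3.0, 0.0, 7.0, 2.0]),
                    E=np.array([2.5, 1.0, 5.0, 3.0]),
                    X=rng.normal(0, 1, (4, 2)))

    def test_matches_oracle_on_random_states(self, toy):
        rng = np.random.default_rng(2)
        for _ in range(10):
            beta = rng.normal(0, 1, 3)
            u = rng.normal(0, 1, 4)
            s = rng.normal(0, 1, 4)
            tau_u, tau_s = rng.gamma(2, 1, 2) + 0.1
            got = log_unnormalized_posterior(
                beta, u, s, tau_u, tau_s, y=toy["y"], expected=toy["E"],
                X=toy["X"], adjacency=PATH4)
            want = oracle_log_posterior(beta, u, s, tau_u, tau_s, toy["y"],
                                        toy["E"], toy["X"], PATH4_EDGES)
            assert got == pytest.approx(want, rel=1e-10)

    def test_zero_state_reduces_to_poisson_at_expected(self, toy):
        got = log_unnormalized_posterior(
            np.zeros(3), np.zeros(4), np.zeros(4), 1.0, 1.0,
            y=toy["y"], expected=toy["E"], X=toy["X"], adjacency=PATH4)
        want = oracle_log_posterior(np.zeros(3), np.zeros(4), np.zeros(4),
                                    1.0, 1.0, toy["y"], toy["E"], toy["X"],
                                    PATH4_EDGES)
        assert got == pytest.approx(want, rel=1e-12)

    def test_raising_u_toward_excess_counts_helps(self, toy):
        # region 2 observes more than its expected count; a small positive
        # u_2 must increase the likelihood-dominated posterior
        base = np.zeros(4)
        args = dict(y=toy["y"], expected=toy["E"], X=toy["X"], adjacency=PATH4)
        up = base.copy()
        up[2] = 0.01
        # tiny tau_u so the prior term barely moves and the Poisson score
        # dominates
        lo = log_unnormalized_posterior(np.zeros(3), base, np.zeros(4),
                                        1e-6, 1.0, **args)
        hi = log_unnormalized_posterior(np.zeros(3), up, np.zeros(4),
                                        1e-6, 1.0, **args)
        assert hi > lo

    def test_icar_kernel_ignores_constant_shift(self):
        rng = np.random.default_rng(3)
        s = rng.standard_normal(4)
        assert icar_quadratic(s + 5.0, PATH4) == pytest.approx(
            icar_quadratic(s, PATH4), rel=1e-12)

    def test_nonfinite_covariates_rejected(self, toy):
        X = toy["X"].copy()
        X[0, 0] = np.inf
        with pytest.raises(ValueError):
            log_unnormalized_posterior(np.zeros(3), np.zeros(4), np.zeros(4),
                                       1.0, 1.0, y=toy["y"],
                                       expected=toy["E"], X=X, adjacency=PATH4)


def _fake_samples(beta, u, s, tau=1.0):
    m = beta.shape[0]
    return PosteriorSamples(beta=beta, u=u, s=s,
                            tau_u=np.full(m, tau), tau_s=np.full(m, tau))


class TestPsi:
    def test_pure_spatial_gives_one(self):
        s = np.tile([1.0, -1.0, 0.5, -0.5], (5, 1))
        samples = _fake_samples(np.zeros((5, 2)), np.zeros((5, 4)), s)
        mean, lo, hi = compute_psi(samples)
        assert mean == 1.0 and lo == 1.0 and hi == 1.0

    def test_pure_unstructured_gives_zero(self):
        u = np.tile([1.0, -1.0, 0.5, -0.5], (5, 1))
        samples = _fake_samples(np.zeros((5, 2)), u, np.zeros((5, 4)))
        assert compute_psi(samples)[0] == 0.0

    def test_all_degenerate_draws_raise(self):
        samples = _fake_samples(np.zeros((3, 2)), np.zeros((3, 4)),
                                np.zeros((3, 4)))
        with pytest.raises(ValueError):
            compute_psi(samples)


class TestRelativeRisk:
    def test_all_zero_draw_gives_unit_risk(self):
        samples = _fake_samples(np.zeros((1, 6)), np.zeros((1, 4)),
                                np.zeros((1, 4)))
        rr = relative_risk(samples, np.zeros((4, 5)))
        np.testing.assert_allclose(rr["rr_mean"], 1.0)

    def test_matches_hand_computed_linear_predictor(self):
        rng = np.random.default_rng(4)
        X = rng.normal(0, 1, (4, 2))
        beta = rng.normal(0, 1, (3, 3))
        u = rng.normal(0, 1, (3, 4))
        s = rng.normal(0, 1, (3, 4))
        rr = relative_risk(_fake_samples(beta, u, s), X)
        manual = np.array([[np.exp(beta[d, 0] + X[i] @ beta[d, 1:]
                                   + u[d, i] + s[d, i])
                            for i in range(4)] for d in range(3)])
        np.testing.assert_allclose(rr["rr_mean"], manual.mean(axis=0),
                                   rtol=1e-12)

    def test_negative_slope_makes_risk_decrease_in_x1(self):
        X = np.linspace(0, 1, 6)[:, None]
        beta = np.array([[0.0, -2.0], [0.0, -1.0]])
        rr = relative_risk(_fake_samples(beta, np.zeros((2, 6)),
                                         np.zeros((2, 6))), X)
        assert (np.diff(rr["rr_mean"]) < 0).all()

    def test_misaligned_covariates_rejected(self):
        samples = _fake_samples(np.zeros((1, 6)), np.zeros((1, 4)),
                                np.zeros((1, 4)))
        with pytest.raises(ValueError):
            relative_risk(samples, np.zeros((3, 5)))


class TestSummarize:
    def _samples_with_beta1(self, draws):
        m = len(draws)
        beta = np.zeros((m, 2))
        beta[:, 1] = draws
        rng = np.random.default_rng(5)
        return _fake_samples(beta, rng.normal(0, 1, (m, 4)),
                             rng.normal(0, 1, (m, 4)))

    def test_interval_excluding_zero_is_significant(self):
        draws = np.linspace(-13.130, -0.980, 400)
        summ = summarize(self._samples_with_beta1(draws), np.zeros((4, 1)))
        assert bool(summ.coefficients.loc["beta1", "significant"])

    def test_interval_straddling_zero_is_not(self):
        draws = np.linspace(-6.585, 0.721, 400)
        summ = summarize(self._samples_with_beta1(draws), np.zeros((4, 1)))
        assert not summ.coefficients.loc["beta1", "significant"]

    def test_endpoint_exactly_zero_is_not_flagged(self):
        draws = np.concatenate([np.zeros(20), np.linspace(1, 2, 380)])
        summ = summarize(self._samples_with_beta1(draws), np.zeros((4, 1)))
        assert summ.coefficients.loc["beta1", "q025"] == 0.0
        assert not summ.coefficients.loc["beta1", "significant"]


class TestFit:
    def test_same_seed_gives_identical_draws(self):
        g = generate_lattice(4, 4)
        X, y, E = make_synthetic_stratum(g, rep=1, sigma_s=0.3)
        kw = dict(n_iterations=600, n_burnin=200, random_state=11)
        m1 = BYMPoissonModel(**kw).fit(X, y, expected=E, adjacency=g)
        m2 = BYMPoissonModel(**kw).fit(X, y, expected=E, adjacency=g)
        np.testing.assert_array_equal(m1.samples_.beta, m2.samples_.beta)
        np.testing.assert_array_equal(m1.samples_.s, m2.samples_.s)
        np.testing.assert_array_equal(m1.samples_.tau_s, m2.samples_.tau_s)

    def test_every_retained_s_draw_sums_to_zero(self):
        g = generate_lattice(4, 5)
        X, y, E = make_synthetic_stratum(g, rep=2)
        m = BYMPoissonModel(n_iterations=800, n_burnin=300,
                            random_state=0).fit(X, y, expected=E, adjacency=g)
        assert np.abs(m.samples_.s.sum(axis=1)).max() < 1e-8 * g.n_regions
        assert (m.samples_.tau_u > 0).all() and (m.samples_.tau_s > 0).all()

    def test_recovers_strong_negative_vegetation_effect(self, lattice_10x14):
        X, y, E = make_synthetic_stratum(lattice_10x14, rep=3)
        m = BYMPoissonModel(n_iterations=6000, n_burnin=2000,
                            random_state=3).fit(X, y, expected=E,
                                                adjacency=lattice_10x14)
        coef = m.summary_.coefficients.loc["beta1"]
        assert coef["q975"] < 0            # decisively negative
        assert -8.0 < coef["mean"] < -2.0  # right order of magnitude

    def test_suppressed_effects_reduce_to_unit_relative_risk(self):
        """With zero covariates and near-degenerate precision priors the
        fitted mu_i/E_i collapses to the crude overall level (1 under
        internal standardization)."""
        g = generate_lattice(4, 4)
        X, y, E = make_synthetic_stratum(g, rep=4, beta=(0,) * 6,
                                         sigma_u=0.0, sigma_s=0.0)
        m = BYMPoissonModel(n_iterations=1500, n_burnin=500,
                            tau_shape=1e8, tau_rate=1e2,
                            random_state=5).fit(np.zeros((16, 1)), y,
                                                expected=E, adjacency=g)
        ratio = m.predict() / E
        np.testing.assert_allclose(ratio, 1.0, atol=0.1)

    def test_nonpositive_expected_rejected(self, lattice_3x3):
        X, y, E = make_synthetic_stratum(lattice_3x3, rep=5)
        E[0] = 0.0
        with pytest.raises(ValueError):
            BYMPoissonModel(n_iterations=10, n_burnin=5).fit(
                X, y, expected=E, adjacency=lattice_3x3)

    def test_estimator_interface_round_trips(self):
        m = BYMPoissonModel(n_iterations=123, random_state=9)
        m2 = clone(m)
        assert m2.get_params()["n_iterations"] == 123
        m2.set_params(thin=2)
        assert m2.thin == 2

    def test_geweke_scores_are_finite(self):
        g = generate_lattice(4, 4)
        X, y, E = make_synthetic_stratum(g, rep=6)
        m = BYMPoissonModel(n_iterations=1000, n_burnin=400,
                            random_state=7).fit(X, y, expected=E, adjacency=g)
        assert np.isfinite(m.geweke_).all()
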