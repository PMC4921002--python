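"""DP mixture: CRP conditionals, predictive, conjugate draws, model selection."""

import math

import numpy as np
import pytest
from scipy.stats import multivariate_normal, multivariate_t, wishart

import mdcall as md
from mdcall.dpgmm import (
    DPFit,
    DPHyperparams,
    DPState,
    _Cluster,
    _draw_cluster_params,
    _gibbs_sweep,
    _nw_posterior,
)

from conftest import three_cluster_data


def make_hyper(r=0.5, nu=4.0, scale=100.0):
    return DPHyperparams(m=np.array([0.0, 0.0]), r=r, nu=nu, S=scale * np.eye(2))


def random_state(rng, n=6, K=2, alpha=1.3):
    z = rng.integers(0, K, size=n)
    while len(np.unique(z)) < K:
        z = rng.integers(0, K, size=n)
    clusters = {}
    for k in range(K):
        A = rng.normal(size=(2, 2))
        prec = A @ A.T + 0.5 * np.eye(2)
        clusters[k] = _Cluster(rng.normal(size=2), prec, int(np.sum(z == k)))
    return DPState(z=z, clusters=clusters, alpha=alpha, _next_id=K)


def crp_oracle(i, state, X, hyper):
    """Naive scipy evaluation of the indicator conditional, cluster by cluster."""
    n = X.shape[0]
    weights = {}
    for k, cl in state.clusters.items():
        n_minus = cl.count - (1 if int(state.z[i]) == k else 0)
        if n_minus <= 0:
            continue
        dens = multivariate_normal.pdf(X[i], cl.mu, np.linalg.inv(cl.precision))
        weights[k] = n_minus / (n - 1 + state.alpha) * dens
    df = hyper.nu - 1
    shape = (1 + hyper.r) / (hyper.r * df) * hyper.S
    pred = multivariate_t.pdf(X[i], loc=hyper.m, shape=shape, df=df)
    weights[-1] = state.alpha / (n - 1 + state.alpha) * pred
    tot = sum(weights.values())
    return {k: v / tot for k, v in weights.items()}


class TestCRPConditional:
    @pytest.mark.parametrize("n", [2, 4, 6])
    def test_matches_enumeration_oracle(self, rng, n):
        hyper = make_hyper()
        for trial in range(5):
            X = rng.normal(scale=3.0, size=(n, 2))
            state = random_state(rng, n=n, K=min(2, n))
            for i in range(n):
                ids, w = md.crp_indicator_conditional(i, state, X, hyper)
                oracle = crp_oracle(i, state, X, hyper)
                assert set(ids) == set(oracle)
                for k, p in zip(ids, w):
                    assert p == pytest.approx(oracle[k], abs=1e-12)

    def test_probabilities_normalised(self, rng):
        hyper = make_hyper()
        X = rng.normal(size=(6, 2))
        state = random_state(rng, n=6, K=3)
        for i in range(6):
            _, w = md.crp_indicator_conditional(i, state, X, hyper)
            assert w.sum() == pytest.approx(1.0, abs=1e-12)

    def test_alpha_to_zero_kills_new_cluster(self, rng):
        hyper = make_hyper()
        X = rng.normal(size=(5, 2))
        state = random_state(rng, n=5, K=1)
        state.alpha = 1e-12
        ids, w = md.crp_indicator_conditional(0, state, X, hyper)
        assert ids[-1] == -1 and w[-1] < 1e-9

    def test_constant_likelihood_reduces_to_bare_crp(self, rng):
        """With identical cluster parameters the existing-cluster odds are the counts."""
        hyper = make_hyper()
        X = rng.normal(size=(7, 2))
        prec = np.eye(2)
        mu = np.zeros(2)
        z = np.array([0, 0, 0, 0, 1, 1, 2])
        clusters = {
            0: _Cluster(mu, prec, 4),
            1: _Cluster(mu, prec, 2),
            2: _Cluster(mu, prec, 1),
        }
        state = DPState(z=z, clusters=clusters, alpha=0.7, _next_id=3)
        ids, w = md.crp_indicator_conditional(6, state, X, hyper)
        # sample 6 was a singleton: menu is clusters 0, 1 and "new"
        probs = dict(zip(ids, w))
        assert probs[0] / probs[1] == pytest.approx(4 / 2, rel=1e-9)

    def test_rich_gets_richer(self, rng):
        """Joining probability increases with cluster size, likelihood held equal."""
        hyper = make_hyper()
        X = rng.normal(size=(10, 2))
        prec, mu = np.eye(2), np.zeros(2)
        z = np.array([0] * 6 + [1] * 3 + [2])
        state = DPState(
            z=z,
            clusters={0: _Cluster(mu, prec, 6), 1: _Cluster(mu, prec, 3), 2: _Cluster(mu, prec, 1)},
            alpha=1.0,
            _next_id=3,
        )
        ids, w = md.crp_indicator_conditional(9, state, X, hyper)
        probs = dict(zip(ids, w))
        assert probs[0] > probs[1]


class TestPredictive:
    def test_integrates_to_one(self):
        hyper = make_hyper(r=1.0, nu=5.0, scale=2.0)
        xs = np.linspace(-40, 40, 401)
        step = xs[1] - xs[0]
        grid = np.array([[a, b] for a in xs for b in xs])
        vals = np.array([md.new_cluster_predictive(p, hyper) for p in grid])
        assert vals.sum() * step**2 == pytest.approx(1.0, abs=1e-3)

    def test_symmetry_about_prior_mean(self):
        hyper = make_hyper()
        d = np.array([3.0, -1.0])
        assert md.new_cluster_predictive(hyper.m + d, hyper) == pytest.approx(
            md.new_cluster_predictive(hyper.m - d, hyper)
        )

    def test_matches_scipy_student_t(self):
        hyper = make_hyper(r=0.3, nu=6.0, scale=4.0)
        df = hyper.nu - 1
        shape = (1 + hyper.r) / (hyper.r * df) * hyper.S
        for pt in ([0.0, 0.0], [2.0, 1.0], [-5.0, 3.0]):
            expected = multivariate_t.pdf(np.array(pt), loc=hyper.m, shape=shape, df=df)
            assert md.new_cluster_predictive(pt, hyper) == pytest.approx(expected, rel=1e-10)

    def test_monte_carlo_prior_predictive(self, rng):
        """Average N(x|mu,R) over prior draws of (mu, R) reproduces the closed form."""
        hyper = make_hyper(r=0.5, nu=5.0, scale=3.0)
        n_draws = 50_000
        Rs = wishart.rvs(df=hyper.nu, scale=np.linalg.inv(hyper.S), size=n_draws, random_state=rng)
        for pt in ([0.0, 0.0], [2.0, -1.0]):
            dens = _mc_densities(np.array(pt), hyper, Rs, rng)
            se = dens.std() / math.sqrt(n_draws)
            assert abs(dens.mean() - md.new_cluster_predictive(pt, hyper)) < 3 * se


def _mc_densities(pt, hyper, Rs, rng):
    """Vectorised N(pt | mu_i, R_i^-1) with mu_i ~ N(m, (r R_i)^-1)."""
    a, b, c = Rs[:, 0, 0], Rs[:, 0, 1], Rs[:, 1, 1]
    det = a * c - b * b
    # sample mu via covariance (r R)^-1: closed-form 2x2 chol of the inverse
    covs = np.empty_like(Rs)
    covs[:, 0, 0] = c / (det * hyper.r)
    covs[:, 0, 1] = covs[:, 1, 0] = -b / (det * hyper.r)
    covs[:, 1, 1] = a / (det * hyper.r)
    l11 = np.sqrt(covs[:, 0, 0])
    l21 = covs[:, 0, 1] / l11
    l22 = np.sqrt(covs[:, 1, 1] - l21**2)
    z = rng.standard_normal((Rs.shape[0], 2))
    mu0 = hyper.m[0] + l11 * z[:, 0]
    mu1 = hyper.m[1] + l21 * z[:, 0] + l22 * z[:, 1]
    d0, d1 = pt[0] - mu0, pt[1] - mu1
    quad = a * d0**2 + 2 * b * d0 * d1 + c * d1**2
    return np.exp(-math.log(2 * math.pi) + 0.5 * np.log(det) - 0.5 * quad)


class TestConjugateDraws:
    def test_posterior_concentrates_at_sample_mean(self, rng):
        hyper = make_hyper(r=0.01, nu=4.0, scale=10.0)
        X = rng.multivariate_normal([5.0, -2.0], [[2.0, 0.3], [0.3, 1.0]], size=10_000)
        m_n, r_n, nu_n, S_n = _nw_posterior(X, hyper)
        post_sd = np.sqrt(np.diag(S_n / (nu_n - 3)) / r_n)
        draws = np.array([_draw_cluster_params(X, hyper, rng)[0] for _ in range(50)])
        assert np.all(np.abs(draws.mean(axis=0) - X.mean(axis=0)) < 4 * post_sd)

    def test_wishart_draw_matches_scipy_moments(self, rng):
        """Bartlett sampling reproduces the Wishart mean of the full conditional."""
        hyper = make_hyper(r=1.0, nu=6.0, scale=2.0)
        X = rng.normal(size=(20, 2))
        _, _, nu_n, S_n = _nw_posterior(X, hyper)
        draws = np.array([_draw_cluster_params(X, hyper, rng)[1] for _ in range(4000)])
        expected = nu_n * np.linalg.inv(S_n)
        np.testing.assert_allclose(draws.mean(axis=0), expected, rtol=0.1)

    def test_large_r_pins_mu_to_prior_mean(self, rng):
        hyper = make_hyper(r=1e9, nu=4.0, scale=10.0)
        X = rng.normal(loc=50.0, size=(30, 2))
        mu, _ = _draw_cluster_params(X, hyper, rng)
        assert np.linalg.norm(mu - hyper.m) < 1.0

    def test_fixed_seed_reproducible(self):
        hyper = make_hyper()
        X = np.random.default_rng(1).normal(size=(10, 2))
        a = _draw_cluster_params(X, hyper, np.random.default_rng(7))
        b = _draw_cluster_params(X, hyper, np.random.default_rng(7))
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])


class TestAlpha:
    def test_prior_recovery_without_likelihood(self):
        """With an empty dataset the sampler targets the bare 1/alpha ~ Gamma(1,1) prior."""
        hyper = make_hyper()
        state = DPState(z=np.zeros(0, dtype=np.int64), clusters={}, alpha=1.0)
        rng = np.random.default_rng(3)
        inv_draws = []
        for _ in range(20_000):
            md.sample_alpha(state, hyper, rng)
            inv_draws.append(1.0 / state.alpha)
        assert np.mean(inv_draws[2000:]) == pytest.approx(1.0, abs=0.1)

    def test_more_clusters_pull_alpha_up(self):
        """Posterior alpha is stochastically larger when many clusters are occupied."""
        hyper = make_hyper()
        means = []
        for K in (1, 20):
            state = DPState(
                z=np.zeros(50, dtype=np.int64),
                clusters={j: _Cluster(np.zeros(2), np.eye(2), 1) for j in range(K)},
                alpha=1.0,
            )
            rng_ = np.random.default_rng(11)
            draws = [md.sample_alpha(state, hyper, rng_) for _ in range(5000)]
            means.append(float(np.mean(draws[500:])))
        assert means[1] > means[0]


class TestInitAndState:
    def test_single_initial_cluster(self, rng):
        X = rng.normal(size=(5, 2))
        state = md.init_dp_state(X, make_hyper(), seed=0)
        assert state.n_occupied == 1
        assert list(state.clusters.values())[0].count == 5
        state.check_counts()

    def test_same_seed_same_state(self, rng):
        X = rng.normal(size=(8, 2))
        a = md.init_dp_state(X, make_hyper(), seed=4)
        b = md.init_dp_state(X, make_hyper(), seed=4)
        np.testing.assert_array_equal(a.z, b.z)
        np.testing.assert_allclose(list(a.clusters.values())[0].mu, list(b.clusters.values())[0].mu)

    def test_non_pd_scale_rejected(self):
        with pytest.raises(md.ValidationError):
            DPHyperparams(m=np.zeros(2), r=1.0, nu=4.0, S=np.array([[1.0, 2.0], [2.0, 1.0]]))

    def test_counts_conserved_over_sweeps(self, rng):
        X, _ = three_cluster_data(counts=(20, 10, 5), sep_sigma=8, seed=9)
        hyper = DPHyperparams.from_data(X)
        state = md.init_dp_state(X, hyper, seed=1)
        g = np.random.default_rng(2)
        for _ in range(20):
            _gibbs_sweep(state, X, hyper, g)
            md.sample_cluster_params(state, X, hyper, g)
            md.sample_alpha(state, hyper, g)
            state.check_counts()
            assert sum(c.count for c in state.clusters.values()) == X.shape[0]


class TestFit:
    def test_single_point_single_cluster(self):
        fit = md.fit_dp_gmm(np.array([[100.0, 50.0]]), n_iter=50, burn_in=10, seed=0)
        assert fit.n_occupied == 1
        assert fit.consensus_z.tolist() == [0]

    def test_invalid_iterations_rejected(self):
        with pytest.raises(md.ValidationError):
            md.fit_dp_gmm(np.ones((3, 2)), n_iter=10, burn_in=10)

    def test_two_cluster_recovery(self):
        X, labels = three_cluster_data(counts=(140, 0, 60), sep_sigma=6, seed=10, clip=False)
        fit = md.fit_dp_gmm(X, n_iter=1200, burn_in=300, seed=21)
        assert fit.n_occupied == 2
        # partition agrees with truth up to labeling
        same = fit.consensus_z == fit.consensus_z[0]
        truth_same = labels == labels[0]
        assert np.mean(same == truth_same) > 0.98

    def test_small_minor_cluster_recovered(self):
        X, labels = three_cluster_data(counts=(100, 15, 5), sep_sigma=8, seed=11)
        fit = md.fit_dp_gmm(X, n_iter=1500, burn_in=400, seed=22)
        assert fit.n_occupied == 3
        minor_idx = np.flatnonzero(labels == 2)
        minor_z = fit.consensus_z[minor_idx]
        # at least 4 of the 5 minor points co-clustered
        assert np.max(np.bincount(minor_z)) >= 4

    def test_responsibility_rows_sum_to_one(self):
        X, _ = three_cluster_data(counts=(30, 20, 10), sep_sigma=8, seed=12)
        fit = md.fit_dp_gmm(X, n_iter=400, burn_in=100, seed=3)
        np.testing.assert_allclose(fit.responsibilities.sum(axis=1), 1.0, atol=1e-9)
        assert 0.0 <= fit.apr <= 1.0


class TestGenotypeMapping:
    def _fit(self, z, contrasts, pr=None):
        K = len(contrasts)
        n = len(z)
        pr = np.ones(n) if pr is None else np.asarray(pr)
        resp = np.zeros((n, K))
        resp[np.arange(n), z] = 1.0
        return DPFit(
            consensus_z=np.asarray(z),
            pis=np.full(K, 1 / K),
            mus=np.zeros((K, 2)),
            sigmas=np.array([np.eye(2)] * K),
            n_occupied=K,
            responsibilities=resp,
            pr=pr,
            apr=float(pr.mean()),
            cluster_contrast=np.asarray(contrasts, float),
        )

    def test_single_cluster_side_labels(self):
        for y, expected in ((0.8, "AA"), (0.0, "AB"), (-0.9, "BB")):
            fit = self._fit([0, 0], [y])
            assert [c.genotype for c in md.dp_calls_to_genotypes(fit)] == [expected] * 2

    def test_two_clusters_by_side(self):
        fit = self._fit([0, 1], [0.8, 0.0])
        assert [c.genotype for c in md.dp_calls_to_genotypes(fit)] == ["AA", "AB"]

    def test_two_clusters_same_region_share_label(self):
        fit = self._fit([0, 1], [0.3, -0.3])
        genos = [c.genotype for c in md.dp_calls_to_genotypes(fit)]
        assert genos == ["AB", "AB"]

    def test_three_clusters_standard_geometry(self):
        fit = self._fit([0, 1, 2], [0.8, 0.0, -0.8])
        assert [c.genotype for c in md.dp_calls_to_genotypes(fit)] == ["AA", "AB", "BB"]

    def test_spurious_high_contrast_cluster_does_not_shift_labels(self):
        """An outlier micro-cluster above the major cluster must not relabel it."""
        z = [0] + [1] * 4 + [2, 2]
        fit = self._fit(z, [0.95, 0.8, 0.0])
        calls = md.dp_calls_to_genotypes(fit)
        assert [c.genotype for c in calls] == ["AA", "AA", "AA", "AA", "AA", "AB", "AB"]

    def test_four_clusters_labeled_by_region(self):
        z = [0, 0, 1, 1, 2, 2, 3]
        fit = self._fit(z, [0.9, 0.3, -0.3, -0.9])
        genos = [c.genotype for c in md.dp_calls_to_genotypes(fit)]
        assert genos == ["AA", "AA", "AB", "AB", "AB", "AB", "BB"]

    def test_pr_threshold_applied(self):
        fit = self._fit([0, 0], [0.8], pr=[0.9, 0.5])
        calls = md.dp_calls_to_genotypes(fit, 0.85)
        assert calls[0].genotype == "AA" and calls[1].genotype == "NC"
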