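import numpy as np
import pytest
from scipy.stats import multivariate_normal

from mcalphabet import (
    ChainConfig,
    ClassAllocation,
    PhenotypeTable,
    PriorSpec,
    ResidualPrior,
    default_model_spec,
    enumerate_inclusion_labels,
    impute_and_center,
    inclusion_label_probabilities,
    predict_ebv,
    run_mcmc,
)
from mcalphabet.priors import ModelSpec
from mcalphabet.sampler import (
    sample_inv_wishart,
    sample_laplace_prior_scales,
    sample_laplace_scales,
    sample_pi,
    sample_scaled_inv_chisq,
)


def _single_marker_problem(seed=5, n=50, effect=0.8, noise=1.0):
    rng = np.random.default_rng(seed)
    mcol = rng.binomial(2, 0.4, n).astype(float)
    mcen = mcol - mcol.mean()
    y = effect * mcen + rng.standard_normal(n) * noise
    return mcen, y


def test_chain_config_defaults_and_validation():
    cfg = ChainConfig()
    assert cfg.chain_length == 100_000 and cfg.burn_in == 50_000
    with pytest.raises(ValueError):
        ChainConfig(chain_length=100, burn_in=100)


def test_conjugate_normal_oracle():
    """1 marker, fixed variances: the Gibbs posterior mean of alpha matches
    the closed-form conjugate posterior within 3 Monte-Carlo SEs."""
    mcen, y = _single_marker_problem()
    s2a, s2e = 0.5, 1.0
    alloc = ClassAllocation.single_class(1)
    spec = ModelSpec(
        1,
        [("all", PriorSpec("RR-BLUP", scale_beta=s2a, estimate_variance=False))],
        ResidualPrior(scale_e=s2e, estimate_variance=False),
    )
    s = run_mcmc(mcen[:, None], y[:, None], alloc, spec,
                 ChainConfig(22000, 2000, 1, seed=9))
    c = float(mcen @ mcen)
    closed_mean = (mcen @ y) / (c + s2e / s2a)
    closed_var = s2e / (c + s2e / s2a)
    n_kept = 20000
    mc_se = np.sqrt(closed_var / (n_kept / 10))  # generous autocorrelation allowance
    assert abs(s.alpha_mean[0, 0] - closed_mean) < 3 * mc_se


def test_constant_phenotype_no_signal():
    rng = np.random.default_rng(3)
    X = rng.binomial(2, 0.3, size=(40, 5)).astype(float)
    X -= X.mean(axis=0)
    y = np.full((40, 1), 2.5)
    alloc = ClassAllocation.single_class(5)
    spec = ModelSpec(
        1,
        [("all", PriorSpec("RR-BLUP", scale_beta=0.01))],
        ResidualPrior(scale_e=0.01),
    )
    s = run_mcmc(X, y, alloc, spec, ChainConfig(2000, 500, 5, seed=1))
    assert np.abs(s.alpha_mean).max() < 0.05
    assert s.mu_mean[0] == pytest.approx(2.5, abs=0.05)


def test_monomorphic_locus_inclusion_equals_pi():
    """With a zero genotype column the likelihood is flat in alpha, so the
    posterior inclusion frequency equals the fixed prior Pi."""
    rng = np.random.default_rng(4)
    X = rng.binomial(2, 0.4, size=(60, 4)).astype(float)
    X -= X.mean(axis=0)
    X[:, 2] = 0.0  # monomorphic after centering
    y = (X[:, 0] + rng.standard_normal(60))[:, None]
    alloc = ClassAllocation.single_class(4)
    spec = ModelSpec(
        1,
        [("all", PriorSpec("BayesCPi", scale_beta=0.1, pi_treatment="fixed",
                           pi_init=np.array([0.3, 0.7])))],
        ResidualPrior(scale_e=0.5),
    )
    s = run_mcmc(X, y, alloc, spec, ChainConfig(12000, 2000, 1, seed=2))
    assert s.delta_mean[2, 0] == pytest.approx(0.7, abs=0.03)


class TestReductionEquivalences:
    """Model identities hold chain-for-chain under identical seeds."""

    @staticmethod
    def _fit(kind, alloc, phen, X, chain, pi_init=None, pi_treatment="estimate"):
        spec = default_model_spec(kind, alloc, phen.values, X,
                                  pi_init=pi_init, pi_treatment=pi_treatment)
        return run_mcmc(X, phen, alloc, spec, chain)

    def test_one_class_equals_conventional(self, tiny_dataset, short_chain):
        g, _, phen, _ = tiny_dataset
        X, _ = impute_and_center(g)
        a1 = ClassAllocation.single_class(g.n_snps, "all")
        a2 = ClassAllocation.single_class(g.n_snps, "whole_genome")
        s1 = self._fit("BayesCPi", a1, phen, X, short_chain)
        s2 = self._fit("BayesCPi", a2, phen, X, short_chain)
        np.testing.assert_array_equal(s1.alpha_mean, s2.alpha_mean)
        np.testing.assert_array_equal(s1.residual_cov_mean, s2.residual_cov_mean)

    @pytest.mark.parametrize("pair", [("RR-BLUP", "BayesCPi"), ("BayesA", "BayesB")])
    def test_pi_pinned_at_all_ones(self, tiny_dataset_mt, short_chain, pair):
        base, mixture = pair
        g, alloc, phen, _ = tiny_dataset_mt
        X, _ = impute_and_center(g)
        allones = np.array([0.0, 0.0, 0.0, 1.0])
        s1 = self._fit(base, alloc, phen, X, short_chain)
        s2 = self._fit(mixture, alloc, phen, X, short_chain,
                       pi_init=allones, pi_treatment="fixed")
        np.testing.assert_array_equal(s1.alpha_mean, s2.alpha_mean)
        np.testing.assert_array_equal(s1.h2_mean, s2.h2_mean)

    def test_seed_determinism(self, tiny_dataset, short_chain):
        g, alloc, phen, _ = tiny_dataset
        X, _ = impute_and_center(g)
        s1 = self._fit("BayesB", alloc, phen, X, short_chain)
        s2 = self._fit("BayesB", alloc, phen, X, short_chain)
        np.testing.assert_array_equal(s1.alpha_mean, s2.alpha_mean)
        for k in s1.traces:
            np.testing.assert_array_equal(s1.traces[k], s2.traces[k])


def test_residual_bookkeeping_invariant(tiny_dataset_mt, short_chain):
    """After the last sweep, y - mu - M alpha equals the stored residuals."""
    g, alloc, phen, _ = tiny_dataset_mt
    X, _ = impute_and_center(g)
    spec = default_model_spec("BayesB", alloc, phen.values, X)
    s = run_mcmc(X, phen, alloc, spec, short_chain)
    fs = s.final_states[0]
    recon = phen.values - fs["mu"] - X[:, s.entry_cols] @ fs["alpha"]
    assert np.abs(recon - fs["residuals"]).max() < 1e-8
    np.testing.assert_allclose(fs["alpha"], fs["delta"] * fs["beta"])


def test_inclusion_conditional_matches_grid_integration():
    """t=2 label probabilities agree with brute-force numerical integration
    of beta over a grid (tolerance 1e-3)."""
    G = np.array([[0.3, 0.1], [0.1, 0.4]])
    R = np.array([[1.0, 0.2], [0.2, 1.5]])
    r = np.array([2.0, -1.0])
    c = 12.0
    pi = np.array([0.1, 0.2, 0.3, 0.4])
    probs = inclusion_label_probabilities(r, c, G, R, pi)

    labels = enumerate_inclusion_labels(2)
    Rinv = np.linalg.inv(R)
    xs = np.linspace(-4, 4, 801)
    bx, by = np.meshgrid(xs, xs, indexing="ij")
    B = np.stack([bx.ravel(), by.ravel()], axis=1)
    prior = multivariate_normal(np.zeros(2), G).pdf(B)
    w = []
    for k, d in enumerate(labels):
        A = B * d
        loglik = (A @ Rinv * r).sum(1) - 0.5 * c * np.einsum("ij,jk,ik->i", A, Rinv, A)
        w.append(pi[k] * np.sum(prior * np.exp(loglik)))
    w = np.array(w)
    w /= w.sum()
    np.testing.assert_allclose(probs, w, atol=1e-3)


class TestVarianceComponentUpdates:
    def test_prior_only_class_variance_mean(self):
        # no data contribution: draws come from the prior, mean nu*S/(nu-2)
        rng = np.random.default_rng(7)
        draws = np.array([sample_scaled_inv_chisq(rng, 4.0, 0.5) for _ in range(100000)])
        assert draws.mean() == pytest.approx(4.0 * 0.5 / 2.0, rel=0.01)

    def test_residual_prior_limit(self):
        rng = np.random.default_rng(8)
        draws = np.array([sample_scaled_inv_chisq(rng, 4.0, 0.25, ss=0.0, k=0)
                          for _ in range(100000)])
        assert draws.mean() == pytest.approx(4.0 * 0.25 / 2.0, rel=0.01)

    def test_inverse_wishart_degrees_of_freedom_bookkeeping(self):
        # posterior df nu_e + n: the mean of IW(S, nu+n) is S/(nu+n-t-1)
        rng = np.random.default_rng(9)
        S = np.array([[2.0, 0.3], [0.3, 1.0]])
        n = 7
        df = 4.0 + n
        draws = sample_inv_wishart(rng, df, np.broadcast_to(S, (60000, 2, 2)).copy())
        np.testing.assert_allclose(draws.mean(axis=0), S / (df - 3), rtol=0.03)

    def test_pi_posterior_mean_is_dirichlet_mean(self):
        rng = np.random.default_rng(10)
        draws = np.array([sample_pi(rng, [3, 5]) for _ in range(40000)])
        np.testing.assert_allclose(draws.mean(axis=0), [0.4, 0.6], atol=0.01)

    def test_pi_fixed_stays_fixed(self, tiny_dataset, short_chain):
        g, alloc, phen, _ = tiny_dataset
        X, _ = impute_and_center(g)
        pi0 = np.array([0.4, 0.6])
        spec = default_model_spec("BayesCPi", alloc, phen.values, X,
                                  pi_init=pi0, pi_treatment="fixed")
        s = run_mcmc(X, phen, alloc, spec, short_chain)
        for label in alloc.classes:
            np.testing.assert_allclose(s.pi_mean[label], pi0)


class TestBayesianLasso:
    def test_marginal_prior_variance(self):
        # mixing an N(0, v) over v ~ Exp(lam^2/2) reproduces the double
        # exponential variance 2/lam^2
        rng = np.random.default_rng(11)
        lam = 3.0
        v = sample_laplace_prior_scales(rng, lam, 1_000_000)
        a = rng.standard_normal(1_000_000) * np.sqrt(v)
        assert a.var() == pytest.approx(2.0 / lam ** 2, rel=0.02)

    def test_quadrature_oracle_single_marker(self):
        """Posterior mean of alpha under the double-exponential prior matches
        direct numerical integration within 1e-2."""
        rng = np.random.default_rng(12)
        n = 40
        mcol = rng.binomial(2, 0.3, n).astype(float)
        mcen = mcol - mcol.mean()
        y = 0.5 * mcen + rng.standard_normal(n) * 0.8
        s2e, lam = 0.64, 2.0
        alloc = ClassAllocation.single_class(1)
        spec = ModelSpec(
            1,
            [("all", PriorSpec("BayesianLASSO", laplace_rate=lam))],
            ResidualPrior(scale_e=s2e, estimate_variance=False),
        )
        s = run_mcmc(mcen[:, None], y[:, None], alloc, spec,
                     ChainConfig(40000, 4000, 1, seed=21))
        mus = np.linspace(y.mean() - 1.5, y.mean() + 1.5, 601)
        als = np.linspace(-2, 2, 1201)
        MU, AL = np.meshgrid(mus, als, indexing="ij")
        ll = np.zeros_like(MU)
        for i in range(n):
            ll += -((y[i] - MU - mcen[i] * AL) ** 2) / (2 * s2e)
        post = np.exp(ll - ll.max()) * np.exp(-lam * np.abs(AL))
        post /= post.sum()
        quad_mean = float((post * AL).sum())
        assert abs(s.alpha_mean[0, 0] - quad_mean) < 1e-2

    def test_shrinkage_monotone_in_rate(self):
        rng = np.random.default_rng(13)
        X = rng.binomial(2, 0.3, size=(50, 8)).astype(float)
        X -= X.mean(axis=0)
        y = (X[:, 0] - X[:, 3] + rng.standard_normal(50) * 0.5)[:, None]
        alloc = ClassAllocation.single_class(8)
        means = []
        for lam in (0.5, 5.0, 50.0):
            spec = ModelSpec(
                1,
                [("all", PriorSpec("BayesianLASSO", laplace_rate=lam))],
                ResidualPrior(scale_e=0.25, estimate_variance=False),
            )
            s = run_mcmc(X, y, alloc, spec, ChainConfig(4000, 1000, 2, seed=3))
            means.append(np.abs(s.alpha_mean).mean())
        assert means[0] > means[1] > means[2]

    def test_conditional_scale_sampler_moments(self):
        # full conditional of 1/v is inverse-Gaussian(lam/|alpha|, lam^2);
        # its mean must match
        rng = np.random.default_rng(14)
        lam, a = 2.0, 0.7
        v = sample_laplace_scales(rng, np.full(200000, a), lam)
        assert (1.0 / v).mean() == pytest.approx(lam / abs(a), rel=0.02)


class TestPredictEBV:
    def _summary(self, tiny_dataset, short_chain):
        g, alloc, phen, _ = tiny_dataset
        from mcalphabet import fit_model
        return g, fit_model(g, phen, alloc, "RR-BLUP", short_chain)

    def test_zero_effects_zero_ebv(self, tiny_dataset, short_chain):
        g, s = self._summary(tiny_dataset, short_chain)
        s.marker_effects = np.zeros_like(s.marker_effects)
        np.testing.assert_array_equal(predict_ebv(s, g), 0.0)

    def test_single_marker_hand_case(self, tiny_dataset, short_chain):
        g, s = self._summary(tiny_dataset, short_chain)
        s.marker_effects = np.zeros_like(s.marker_effects)
        s.marker_effects[0, 0] = 1.0
        s.col_means = np.zeros(g.n_snps)
        dos = np.zeros((3, g.n_snps))
        dos[:, 0] = [0, 1, 2]
        s.col_means[0] = 1.0
        np.testing.assert_allclose(predict_ebv(s, dos)[:, 0], [-1, 0, 1])

    def test_matrix_product_equals_locus_by_locus(self, tiny_dataset, short_chain):
        g, s = self._summary(tiny_dataset, short_chain)
        ebv = predict_ebv(s, g)
        X = g.dosages - s.col_means
        byhand = np.zeros_like(ebv)
        for j in range(g.n_snps):
            byhand += np.outer(X[:, j], s.marker_effects[j])
        np.testing.assert_allclose(ebv, byhand, atol=1e-10)

    def test_column_mismatch_rejected(self, tiny_dataset, short_chain):
        g, s = self._summary(tiny_dataset, short_chain)
        with pytest.raises(ValueError):
            predict_ebv(s, g.dosages[:, :-1])


def test_overlapping_classes_contribute_one_term_each(tiny_dataset, short_chain):
    """A marker in two classes carries two effect entries, one per class."""
    g, _, phen, _ = tiny_dataset
    X, _ = impute_and_center(g)
    m = g.n_snps
    alloc = ClassAllocation(
        ["first_half", "all"],
        {"first_half": np.arange(m // 2), "all": np.arange(m)},
    )
    spec = default_model_spec("RR-BLUP", alloc, phen.values, X)
    s = run_mcmc(X, phen, alloc, spec, short_chain)
    assert s.alpha_mean.shape[0] == m + m // 2
    # aggregated effects sum the per-entry posterior means marker-wise
    agg = np.zeros((m, 1))
    np.add.at(agg, s.entry_cols, s.alpha_mean)
    np.testing.assert_allclose(agg, s.marker_effects)


def test_multi_chain_traces_shape(tiny_dataset):
    g, alloc, phen, _ = tiny_dataset
    X, _ = impute_and_center(g)
    spec = default_model_spec("RR-BLUP", alloc, phen.values, X)
    s = run_mcmc(X, phen, alloc, spec, ChainConfig(200, 100, 2, seed=1, n_chains=3))
    assert s.traces["h2_0"].shape == (3, 50)
    # chains started from different spawned seeds differ
    assert not np.array_equal(s.traces["h2_0"][0], s.traces["h2_0"][1])
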