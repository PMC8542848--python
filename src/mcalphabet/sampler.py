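"""Single-site Gibbs sampler for multi-class Bayesian Alphabet models.

The model for genotyped individual i with t traits is

    y_i = mu + sum_l sum_{f in C_l} m_{if} alpha_f^{(l)} + e_i,
    e_i ~ N_t(0, R),

where the markers of each SNP class C_l share one Bayesian Alphabet prior
and a marker belonging to k classes contributes k additive effect terms,
one per class.  Variable-selection priors (BayesB, BayesCPi) write
alpha_f = D_f beta_f with D_f = diag(delta_f), delta_f a binary
trait-inclusion pattern with class-level pattern probabilities Pi.

Every sweep updates, in a fixed order: mu; then each class's loci in index
order, drawing delta_f from its full conditional with beta integrated out
analytically and then beta_f from its Gaussian full conditional; then the
variance components (locus or class effect covariances, Laplace mixing
scales); then each class's Pi; then R.  The sequential per-locus loop is
compiled with numba (it dominates the cost); block updates are vectorized
numpy/scipy.  All randomness flows through one numpy Generator per chain,
so a fixed seed reproduces the chain bit-for-bit.

Conjugate forms used (t = 1 uses the scaled-inverse-chi-square analogues):

* locus effect covariance (BayesA/B):   G_f  ~ IW(S_b + beta_f beta_f', nu_b + 1)
* class effect covariance (RR-BLUP/CPi): G   ~ IW(S_b + sum_incl beta beta', nu_b + #incl)
* residual covariance:                  R    ~ IW(S_e + E'E, nu_e + n)
* inclusion-pattern probabilities:      Pi   ~ Dirichlet(1 + pattern counts)
* Laplace mixing scale (t traits):      v_f  ~ GIG(1 - t/2, lambda^2, alpha_f'alpha_f)
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy import stats

from .datamodel import ClassAllocation, GenotypeMatrix, PhenotypeTable, impute_and_center
from .priors import (
    FAMILY_LAPLACE,
    FAMILY_MIXTURE_COMMON,
    FAMILY_MIXTURE_LOCUS,
    ModelSpec,
    default_model_spec,
    enumerate_inclusion_labels,
)

__all__ = [
    "ChainConfig",
    "PosteriorSummary",
    "run_mcmc",
    "fit_model",
    "predict_ebv",
    "inclusion_label_probabilities",
    "sample_scaled_inv_chisq",
    "sample_inv_wishart",
    "sample_pi",
    "sample_laplace_scales",
    "sample_laplace_prior_scales",
]

logger = logging.getLogger(__name__)

_RESID_REFRESH = 500  # recompute residuals from scratch every so many sweeps
_LOG_EVERY = 10_000   # structured variance-summary log cadence (sweeps)


@dataclass
class ChainConfig:
    """MCMC run configuration (defaults follow common practice for these
    models: chains of 100,000 with the first half discarded)."""

    chain_length: int = 100_000
    burn_in: int = 50_000
    thin: int = 10
    seed: int = 0
    n_chains: int = 1

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in < self.chain_length:
            raise ValueError("need 0 <= burn_in < chain_length")
        if self.thin < 1 or self.n_chains < 1:
            raise ValueError("thin and n_chains must be >= 1")


# ---------------------------------------------------------------------------
# numba kernels: the sequential per-locus sweep

@njit(cache=False)
def _sweep_t1(MT, cols, c, e, alpha, beta, delta, prior_var, use_mix, deg, pi1,
              s2e, rng):
    E = cols.shape[0]
    for j in range(E):
        f = cols[j]
        mf = MT[f]
        r = np.dot(mf, e) + c[j] * alpha[j]
        s2 = prior_var[j]
        if use_mix[j] == 1:
            if deg[j] >= 0:
                d = float(deg[j])
            else:
                p1 = pi1[j]
                if p1 <= 0.0:
                    d = 0.0
                elif p1 >= 1.0:
                    d = 1.0
                else:
                    A = c[j] / s2e
                    b = r / s2e
                    lw = (math.log(p1) - math.log(1.0 - p1)
                          - 0.5 * math.log1p(A * s2)
                          + 0.5 * b * b / (A + 1.0 / s2))
                    if lw > 35.0:
                        prob1 = 1.0
                    elif lw < -35.0:
                        prob1 = 0.0
                    else:
                        prob1 = 1.0 / (1.0 + math.exp(-lw))
                    d = 1.0 if rng.random() < prob1 else 0.0
            if d == 1.0:
                pv = 1.0 / (c[j] / s2e + 1.0 / s2)
                pm = pv * r / s2e
            else:
                pv = s2
                pm = 0.0
        else:  # Laplace: no point mass, v_j is the mixing scale
            pv = 1.0 / (c[j] / s2e + 1.0 / s2)
            pm = pv * r / s2e
            d = 1.0
        b_new = pm + math.sqrt(pv) * rng.standard_normal()
        a_new = d * b_new
        beta[j] = b_new
        delta[j] = d
        da = a_new - alpha[j]
        if da != 0.0:
            e -= mf * da
        alpha[j] = a_new


@njit(cache=False)
def _label_logweights(u, cj, Ginv, logdetG, Rinv, pi, labels):
    """log posterior weights of the 2^t inclusion patterns at one locus,
    with beta integrated out analytically.

    u = R^{-1} r with r the full-conditional data vector; cj = m'm.
    Uses |I + G A| = |G| |G^{-1} + A| with A = c (d d' ∘ R^{-1}).
    """
    K = labels.shape[0]
    t = labels.shape[1]
    logw = np.full(K, -1.0e308)
    for k in range(K):
        if pi[k] <= 0.0:
            continue
        d = labels[k]
        Mt = Ginv.copy()
        for a in range(t):
            if d[a] == 0.0:
                continue
            for b2 in range(t):
                if d[b2] != 0.0:
                    Mt[a, b2] += cj * Rinv[a, b2]
        bk = d * u
        x = np.linalg.solve(Mt, bk)
        quad = np.dot(bk, x)
        sign, ld = np.linalg.slogdet(Mt)
        logw[k] = math.log(pi[k]) - 0.5 * (logdetG + ld) + 0.5 * quad
    return logw


@njit(cache=False)
def _sweep_mt(MT, cols, c, Emat, alpha, beta, delta, Ginv_ent, logdetG_ent,
              use_mix, deg, pi_ent, labels, Rinv, rng):
    E = cols.shape[0]
    n = MT.shape[1]
    t = Emat.shape[1]
    ones = np.ones(t)
    for j in range(E):
        f = cols[j]
        mf = MT[f]
        r = np.dot(mf, Emat) + c[j] * alpha[j]
        u = Rinv @ r
        Ginv = Ginv_ent[j]
        if use_mix[j] == 1:
            if deg[j] >= 0:
                d = labels[deg[j]]
            else:
                logw = _label_logweights(u, c[j], Ginv, logdetG_ent[j], Rinv,
                                         pi_ent[j], labels)
                mx = logw.max()
                w = np.exp(logw - mx)
                tot = w.sum()
                un = rng.random() * tot
                acc = 0.0
                k_pick = 0
                for k in range(logw.shape[0]):
                    acc += w[k]
                    if un <= acc:
                        k_pick = k
                        break
                d = labels[k_pick]
        else:
            d = ones
        # beta | delta: Gaussian with precision Ginv + c (d d' ∘ Rinv)
        Lam = Ginv.copy()
        for a in range(t):
            if d[a] == 0.0:
                continue
            for b2 in range(t):
                if d[b2] != 0.0:
                    Lam[a, b2] += c[j] * Rinv[a, b2]
        mean = np.linalg.solve(Lam, d * u)
        L = np.linalg.cholesky(Lam)
        z = rng.standard_normal(t)
        b_new = mean + np.linalg.solve(L.T.copy(), z)
        a_new = d * b_new
        beta[j] = b_new
        delta[j] = d
        changed = False
        for a in range(t):
            if a_new[a] != alpha[j, a]:
                changed = True
                break
        if changed:
            for i in range(n):
                mi = mf[i]
                for a in range(t):
                    Emat[i, a] -= mi * (a_new[a] - alpha[j, a])
        alpha[j] = a_new


# ---------------------------------------------------------------------------
# conditional samplers used by the block updates (exposed for testing)

def sample_scaled_inv_chisq(rng, nu: float, S: float, ss: float = 0.0, k: int = 0) -> float:
    """Draw sigma^2 from its scaled-inverse-chi-square full conditional:
    (nu*S + ss) / chi2(nu + k); k = 0, ss = 0 gives a prior draw."""
    return (nu * S + ss) / rng.chisquare(nu + k)


def sample_inv_wishart(rng, df: float, scales: np.ndarray, max_retries: int = 5) -> np.ndarray:
    """Batched inverse-Wishart draws via the Bartlett decomposition.

    ``scales`` is (..., t, t); one draw per leading index, all with the same
    degrees of freedom.  Non-positive-definite scale matrices are jittered
    (1e-8 on the diagonal, up to ``max_retries`` times) before failing.
    """
    S = np.asarray(scales, dtype=float)
    squeeze = S.ndim == 2
    if squeeze:
        S = S[None]
    B, t, _ = S.shape
    if df <= t - 1:
        raise ValueError(f"inverse-Wishart df {df} <= t-1 = {t - 1}")
    eye = np.eye(t)
    for attempt in range(max_retries + 1):
        try:
            L = np.linalg.cholesky(np.linalg.inv(S))
            break
        except np.linalg.LinAlgError:
            S = S + eye * 1e-8 * (10.0 ** attempt)
    else:  # pragma: no cover
        raise np.linalg.LinAlgError("scale matrix not positive definite after jitter")
    A = np.zeros((B, t, t))
    for i in range(t):
        A[:, i, i] = np.sqrt(rng.chisquare(df - i, size=B))
        for jj in range(i):
            A[:, i, jj] = rng.standard_normal(B)
    LA = L @ A
    W = LA @ np.swapaxes(LA, 1, 2)
    G = np.linalg.inv(W)
    G = 0.5 * (G + np.swapaxes(G, 1, 2))
    return G[0] if squeeze else G


def sample_pi(rng, counts: np.ndarray) -> np.ndarray:
    """Pi | delta ~ Dirichlet(1 + pattern counts): the uniform prior on the
    simplex plus multinomial pattern counts."""
    return rng.dirichlet(1.0 + np.asarray(counts, dtype=float))


def sample_laplace_scales(rng, alpha: np.ndarray, lam: float) -> np.ndarray:
    """Mixing scales v_f | alpha_f for a Bayesian LASSO class.

    alpha is (E,) or (E, t).  t = 1: 1/v ~ inverse-Gaussian(lam/|alpha|,
    lam^2).  t > 1: v ~ GIG(1 - t/2, lam^2, alpha'alpha), sampled with
    scipy's generalized-inverse-Gaussian generator.
    """
    if lam <= 0:
        raise ValueError("laplace rate must be positive")
    a = np.asarray(alpha, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    t = a.shape[1]
    if t == 1:
        mag = np.maximum(np.abs(a[:, 0]), 1e-8)
        inv_v = rng.wald(lam / mag, lam ** 2)
        return 1.0 / inv_v
    b2 = np.maximum((a ** 2).sum(axis=1), 1e-12)
    p = 1.0 - t / 2.0
    return stats.geninvgauss.rvs(
        p, np.sqrt(lam ** 2 * b2), scale=np.sqrt(b2) / lam, random_state=rng
    )


def sample_laplace_prior_scales(rng, lam: float, size: int) -> np.ndarray:
    """Prior draws of the mixing scale: v ~ Exponential(rate lam^2/2), so
    that alpha | v ~ N(0, v) marginalizes to a double exponential with
    variance 2/lam^2 per coordinate."""
    return rng.exponential(2.0 / lam ** 2, size=size)


def inclusion_label_probabilities(r, c: float, G, R, pi) -> np.ndarray:
    """Posterior probabilities of the 2^t inclusion patterns at one locus.

    ``r`` is the full-conditional data vector m'(E + m alpha'), ``c = m'm``,
    ``G`` the effect covariance, ``R`` the residual covariance and ``pi``
    the pattern prior.  beta is integrated out analytically; this is the
    same code the sweep kernel samples from.
    """
    t = 1 if np.isscalar(r) else len(np.atleast_1d(r))
    rv = np.atleast_1d(np.asarray(r, dtype=float))
    Gm = np.atleast_2d(np.asarray(G, dtype=float))
    Rm = np.atleast_2d(np.asarray(R, dtype=float))
    labels = enumerate_inclusion_labels(t)
    pi = np.asarray(pi, dtype=float)
    Rinv = np.linalg.inv(Rm)
    Ginv = np.linalg.inv(Gm)
    sign, logdetG = np.linalg.slogdet(Gm)
    u = Rinv @ rv
    logw = _label_logweights(u, float(c), Ginv, logdetG, Rinv, pi, labels)
    w = np.exp(logw - logw.max())
    return w / w.sum()


# ---------------------------------------------------------------------------
# model plan

class _ClassPlan:
    __slots__ = ("label", "family", "sl", "nu", "S", "pi", "pi_fixed",
                 "estimate", "lam")

    def __init__(self, label, family, sl, nu, S, pi, pi_fixed, estimate, lam):
        self.label = label
        self.family = family
        self.sl = sl  # slice into entry arrays
        self.nu = nu
        self.S = S
        self.pi = pi
        self.pi_fixed = pi_fixed
        self.estimate = estimate
        self.lam = lam


def _build_plan(alloc: ClassAllocation, spec: ModelSpec):
    t = spec.trait_count
    cols_parts, plans = [], []
    start = 0
    for (label, prior) in spec.class_priors:
        idx = alloc.members[label]
        prior.validate(t)
        sl = slice(start, start + idx.size)
        start += idx.size
        cols_parts.append(idx)
        pi, pi_fixed = prior.resolved_pi(t)
        if prior.family == FAMILY_LAPLACE:
            S = None
        elif t == 1:
            S = float(np.squeeze(prior.scale_beta))
        else:
            S = np.atleast_2d(np.asarray(prior.scale_beta, dtype=float))
        plans.append(
            _ClassPlan(label, prior.family, sl, float(prior.df_beta), S, pi,
                       pi_fixed, prior.estimate_variance, prior.laplace_rate)
        )
    cols = np.concatenate(cols_parts).astype(np.int64)
    return cols, plans


@dataclass
class PosteriorSummary:
    """Posterior means and retained samples from one (or several averaged)
    chains, plus everything needed to predict new individuals."""

    alpha_mean: np.ndarray          # (E, t) per effect entry
    marker_effects: np.ndarray      # (m, t) entries summed per marker
    delta_mean: np.ndarray          # (E, t) posterior inclusion frequency
    mu_mean: np.ndarray             # (t,)
    residual_cov_mean: np.ndarray   # (t, t)
    class_cov_mean: dict            # label -> (t, t)  (common-covariance classes)
    locus_cov_mean: dict            # label -> (E_c, t, t)  (locus-covariance classes)
    laplace_scale_mean: dict        # label -> (E_c,)
    pi_mean: dict                   # label -> (2^t,)
    genetic_cov_mean: np.ndarray    # (t, t) realized genic covariance
    h2_mean: np.ndarray             # (t,) genomic heritability
    genetic_corr_mean: np.ndarray   # (t, t)
    ebv: np.ndarray                 # (n, t)
    entry_cols: np.ndarray          # (E,) genotype column per entry
    entry_class: np.ndarray         # (E,) class label per entry
    col_means: np.ndarray | None    # training centering means (m,)
    traces: dict                    # name -> (n_chains, n_samples)
    n_samples: int
    final_states: list = field(default_factory=list)

    @property
    def n_traits(self) -> int:
        return self.alpha_mean.shape[1]


def _aggregate_marker_effects(alpha_mean, cols, m):
    out = np.zeros((m, alpha_mean.shape[1]))
    np.add.at(out, cols, alpha_mean)
    return out


# ---------------------------------------------------------------------------
# main driver

def run_mcmc(genotypes, phenotypes, alloc: ClassAllocation, spec: ModelSpec,
             cfg: ChainConfig, col_means=None) -> PosteriorSummary:
    """Fit the multi-class model by Gibbs sampling.

    ``genotypes`` is the centered n×m covariate matrix (see
    :func:`mcalphabet.datamodel.impute_and_center`); ``phenotypes`` a
    PhenotypeTable or an n×t array.  With ``cfg.n_chains > 1`` the chains
    run sequentially from seeds spawned off ``cfg.seed`` and the summary
    averages their posterior means; per-chain scalar traces are kept for
    convergence diagnostics.
    """
    X = np.ascontiguousarray(np.asarray(genotypes, dtype=float))
    Y = phenotypes.values if isinstance(phenotypes, PhenotypeTable) else np.asarray(phenotypes, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, m = X.shape
    t = spec.trait_count
    if Y.shape != (n, t):
        raise ValueError(f"phenotypes have shape {Y.shape}, expected {(n, t)}")
    spec.validate(alloc)
    alloc.validate(m)

    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_chains)
    chains = [_run_chain(X, Y, alloc, spec, cfg, np.random.default_rng(s))
              for s in seeds]

    first = chains[0]
    def _avg(key):
        vals = [ch[key] for ch in chains]
        if isinstance(vals[0], dict):
            return {k: np.mean([v[k] for v in vals], axis=0) for k in vals[0]}
        return np.mean(vals, axis=0)

    alpha_mean = _avg("alpha_mean")
    cols = first["cols"]
    marker_effects = _aggregate_marker_effects(alpha_mean, cols, m)
    traces = {k: np.stack([ch["traces"][k] for ch in chains]) for k in first["traces"]}
    summary = PosteriorSummary(
        alpha_mean=alpha_mean,
        marker_effects=marker_effects,
        delta_mean=_avg("delta_mean"),
        mu_mean=_avg("mu_mean"),
        residual_cov_mean=_avg("residual_cov_mean"),
        class_cov_mean=_avg("class_cov_mean"),
        locus_cov_mean=_avg("locus_cov_mean"),
        laplace_scale_mean=_avg("laplace_scale_mean"),
        pi_mean=_avg("pi_mean"),
        genetic_cov_mean=_avg("genetic_cov_mean"),
        h2_mean=_avg("h2_mean"),
        genetic_corr_mean=_avg("genetic_corr_mean"),
        ebv=X @ marker_effects,
        entry_cols=cols,
        entry_class=first["entry_class"],
        col_means=None if col_means is None else np.asarray(col_means, dtype=float),
        traces=traces,
        n_samples=first["n_samples"],
        final_states=[ch["final_state"] for ch in chains],
    )
    return summary


def _run_chain(X, Y, alloc, spec, cfg, rng):
    n, m = X.shape
    t = spec.trait_count
    cols, plans = _build_plan(alloc, spec)
    E = cols.size
    MT = np.ascontiguousarray(X.T)
    c = (MT ** 2).sum(axis=1)[cols]
    labels = enumerate_inclusion_labels(t)
    K = labels.shape[0]

    # --- state ---
    mu = Y.mean(axis=0)
    Emat = Y - mu
    alpha = np.zeros((E, t))
    beta = np.zeros((E, t))
    delta = np.ones((E, t))
    # with estimation switched off the scale is interpreted as the fixed value
    rp = spec.residual_prior
    if t == 1:
        S_e = float(np.squeeze(rp.scale_e))
        R = np.atleast_2d(
            rp.df_e * S_e / (rp.df_e - 2.0) if rp.estimate_variance else S_e
        )
    else:
        S_e = np.atleast_2d(np.asarray(rp.scale_e, dtype=float))
        R = (S_e / (rp.df_e - t - 1.0) if rp.estimate_variance else S_e).copy()
    class_G = {}      # label -> (t,t) current value (mixture-common)
    locus_G = {}      # label -> (E_c,t,t)
    lap_v = {}        # label -> (E_c,)
    pi_cur = {}       # label -> (K,)
    for p in plans:
        Ec = p.sl.stop - p.sl.start
        pi_cur[p.label] = p.pi.copy()
        if p.family == FAMILY_LAPLACE:
            lap_v[p.label] = np.full(Ec, 2.0 / p.lam ** 2)
        else:
            if not p.estimate:
                init = p.S  # fixed at the given value
            else:
                init = (p.nu * p.S / (p.nu - 2.0)) if t == 1 else p.S / (p.nu - t - 1.0)
            if p.family == FAMILY_MIXTURE_COMMON:
                class_G[p.label] = np.atleast_2d(init).astype(float).copy()
            else:
                locus_G[p.label] = np.broadcast_to(
                    np.atleast_2d(init), (Ec, t, t)
                ).astype(float).copy()

    # per-entry static arrays
    use_mix = np.zeros(E, dtype=np.uint8)
    deg = np.full(E, -1, dtype=np.int64)
    pi_ent = np.zeros((E, K))
    for p in plans:
        if p.family != FAMILY_LAPLACE:
            use_mix[p.sl] = 1
    pow2 = 2 ** np.arange(t - 1, -1, -1, dtype=np.int64)

    def _refresh_entry_arrays():
        for p in plans:
            pi = pi_cur[p.label]
            pi_ent[p.sl] = pi
            if p.family == FAMILY_LAPLACE:
                deg[p.sl] = K - 1
            elif p.pi_fixed and (pi >= 1.0 - 1e-15).any():
                deg[p.sl] = int(np.argmax(pi))
            else:
                deg[p.sl] = -1

    _refresh_entry_arrays()

    # --- accumulators ---
    n_keep = (cfg.chain_length - cfg.burn_in + cfg.thin - 1) // cfg.thin
    acc = {
        "alpha": np.zeros((E, t)), "delta": np.zeros((E, t)), "mu": np.zeros(t),
        "R": np.zeros((t, t)), "vG": np.zeros((t, t)), "h2": np.zeros(t),
        "corr": np.zeros((t, t)),
        "classG": {p.label: np.zeros((t, t)) for p in plans if p.family == FAMILY_MIXTURE_COMMON},
        "locusG": {p.label: np.zeros((p.sl.stop - p.sl.start, t, t)) for p in plans if p.family == FAMILY_MIXTURE_LOCUS},
        "lapv": {p.label: np.zeros(p.sl.stop - p.sl.start) for p in plans if p.family == FAMILY_LAPLACE},
        "pi": {p.label: np.zeros(K) for p in plans},
    }
    trace_names = [f"h2_{i}" for i in range(t)] + [f"genvar_{i}" for i in range(t)] \
        + [f"resvar_{i}" for i in range(t)]
    trace_names += [f"gencorr_{i}_{jj}" for i in range(t) for jj in range(i + 1, t)]
    for p in plans:
        if p.family == FAMILY_MIXTURE_COMMON:
            trace_names += [f"classvar_{p.label}_{i}" for i in range(t)]
    traces = {name: np.zeros(n_keep) for name in trace_names}

    n_acc = 0
    keep_i = 0
    for it in range(cfg.chain_length):
        if it % _RESID_REFRESH == 0 and it > 0:
            Emat = Y - mu - MT[cols].T @ alpha
        # mu | rest  (flat prior)
        ebar = Emat.mean(axis=0)
        if t == 1:
            step = ebar + math.sqrt(R[0, 0] / n) * rng.standard_normal(1)
        else:
            step = ebar + np.linalg.cholesky(R / n) @ rng.standard_normal(t)
        mu = mu + step
        Emat = Emat - step

        # loci
        s2e = R[0, 0]
        if t == 1:
            prior_var = np.empty(E)
            for p in plans:
                if p.family == FAMILY_MIXTURE_COMMON:
                    prior_var[p.sl] = class_G[p.label][0, 0]
                elif p.family == FAMILY_MIXTURE_LOCUS:
                    prior_var[p.sl] = locus_G[p.label][:, 0, 0]
                else:
                    prior_var[p.sl] = lap_v[p.label]
            e1 = Emat[:, 0]
            a1, b1, d1 = alpha[:, 0], beta[:, 0], delta[:, 0]
            pi1 = pi_ent[:, 1] if K == 2 else pi_ent[:, -1]
            deg1 = np.where(deg < 0, -1, deg).astype(np.int64)
            _sweep_t1(MT, cols, c, e1, a1, b1, d1, prior_var, use_mix, deg1,
                      pi1, s2e, rng)
            alpha[:, 0], beta[:, 0], delta[:, 0] = a1, b1, d1
            Emat = e1[:, None]
        else:
            Rinv = np.linalg.inv(R)
            Ginv_ent = np.empty((E, t, t))
            logdetG_ent = np.empty(E)
            eye = np.eye(t)
            for p in plans:
                if p.family == FAMILY_MIXTURE_COMMON:
                    G = class_G[p.label]
                    Ginv_ent[p.sl] = np.linalg.inv(G)
                    logdetG_ent[p.sl] = np.linalg.slogdet(G)[1]
                elif p.family == FAMILY_MIXTURE_LOCUS:
                    Gl = locus_G[p.label]
                    Ginv_ent[p.sl] = np.linalg.inv(Gl)
                    logdetG_ent[p.sl] = np.linalg.slogdet(Gl)[1]
                else:
                    v = lap_v[p.label]
                    Ginv_ent[p.sl] = eye[None] / v[:, None, None]
                    logdetG_ent[p.sl] = t * np.log(v)
            _sweep_mt(MT, cols, c, Emat, alpha, beta, delta, Ginv_ent,
                      logdetG_ent, use_mix, deg, pi_ent, labels, Rinv, rng)

        # variance components (class order fixed)
        for p in plans:
            Ec = p.sl.stop - p.sl.start
            if p.family == FAMILY_MIXTURE_COMMON:
                if not p.estimate:
                    continue
                incl = delta[p.sl].any(axis=1)
                B = beta[p.sl][incl]
                k = int(incl.sum())
                if t == 1:
                    ss = float((B ** 2).sum())
                    class_G[p.label][0, 0] = sample_scaled_inv_chisq(rng, p.nu, p.S, ss, k)
                else:
                    class_G[p.label] = sample_inv_wishart(rng, p.nu + k, p.S + B.T @ B)
            elif p.family == FAMILY_MIXTURE_LOCUS:
                if not p.estimate:
                    continue
                Bc = beta[p.sl]
                if t == 1:
                    ss = Bc[:, 0] ** 2
                    locus_G[p.label][:, 0, 0] = (p.nu * p.S + ss) / rng.chisquare(p.nu + 1, size=Ec)
                else:
                    scales = p.S[None] + Bc[:, :, None] * Bc[:, None, :]
                    locus_G[p.label] = sample_inv_wishart(rng, p.nu + 1, scales)
            else:
                lap_v[p.label] = sample_laplace_scales(rng, alpha[p.sl] if t > 1 else alpha[p.sl, 0], p.lam)

        # Pi
        for p in plans:
            if p.family == FAMILY_LAPLACE or p.pi_fixed:
                continue
            codes = (delta[p.sl].astype(np.int64) @ pow2)
            counts = np.bincount(codes, minlength=K)
            pi_cur[p.label] = sample_pi(rng, counts)
        _refresh_entry_arrays()

        # R
        if rp.estimate_variance:
            if t == 1:
                sse = float(Emat[:, 0] @ Emat[:, 0])
                R[0, 0] = sample_scaled_inv_chisq(rng, rp.df_e, S_e, sse, n)
            else:
                R = sample_inv_wishart(rng, rp.df_e + n, S_e + Emat.T @ Emat)

        if not np.isfinite(Emat).all():
            raise RuntimeError(f"NaN/inf in residuals at iteration {it}")

        if (it + 1) % _LOG_EVERY == 0:
            gv = np.var(Y - mu - Emat, axis=0, ddof=1)
            logger.info(
                "sweep %d: genetic var %s, residual var %s", it + 1,
                np.array2string(np.atleast_1d(gv), precision=4),
                np.array2string(np.diag(R), precision=4),
            )

        # tracking
        if it >= cfg.burn_in:
            gmat = Y - mu - Emat
            vG = np.atleast_2d(np.cov(gmat, rowvar=False))
            h2 = np.diag(vG) / (np.diag(vG) + np.diag(R))
            dcor = np.sqrt(np.diag(vG))
            corr = vG / np.outer(dcor, dcor)
            n_acc += 1
            acc["alpha"] += alpha
            acc["delta"] += delta
            acc["mu"] += mu
            acc["R"] += R
            acc["vG"] += vG
            acc["h2"] += h2
            acc["corr"] += corr
            for p in plans:
                acc["pi"][p.label] += pi_cur[p.label]
                if p.family == FAMILY_MIXTURE_COMMON:
                    acc["classG"][p.label] += class_G[p.label]
                elif p.family == FAMILY_MIXTURE_LOCUS:
                    acc["locusG"][p.label] += locus_G[p.label]
                else:
                    acc["lapv"][p.label] += lap_v[p.label]
            if (it - cfg.burn_in) % cfg.thin == 0:
                for i in range(t):
                    traces[f"h2_{i}"][keep_i] = h2[i]
                    traces[f"genvar_{i}"][keep_i] = vG[i, i]
                    traces[f"resvar_{i}"][keep_i] = R[i, i]
                for i in range(t):
                    for jj in range(i + 1, t):
                        traces[f"gencorr_{i}_{jj}"][keep_i] = corr[i, jj]
                for p in plans:
                    if p.family == FAMILY_MIXTURE_COMMON:
                        for i in range(t):
                            traces[f"classvar_{p.label}_{i}"][keep_i] = class_G[p.label][i, i]
                keep_i += 1

    inv = 1.0 / max(n_acc, 1)
    entry_class = np.concatenate([
        np.full(p.sl.stop - p.sl.start, p.label, dtype=object) for p in plans
    ])
    return {
        "alpha_mean": acc["alpha"] * inv,
        "delta_mean": acc["delta"] * inv,
        "mu_mean": acc["mu"] * inv,
        "residual_cov_mean": acc["R"] * inv,
        "genetic_cov_mean": acc["vG"] * inv,
        "h2_mean": acc["h2"] * inv,
        "genetic_corr_mean": acc["corr"] * inv,
        "class_cov_mean": {k: v * inv for k, v in acc["classG"].items()},
        "locus_cov_mean": {k: v * inv for k, v in acc["locusG"].items()},
        "laplace_scale_mean": {k: v * inv for k, v in acc["lapv"].items()},
        "pi_mean": {k: v * inv for k, v in acc["pi"].items()},
        "traces": traces,
        "cols": cols,
        "entry_class": entry_class,
        "n_samples": keep_i,
        "final_state": {
            "alpha": alpha.copy(), "beta": beta.copy(), "delta": delta.copy(),
            "mu": mu.copy(), "residuals": Emat.copy(), "R": R.copy(),
        },
    }


# ---------------------------------------------------------------------------
# convenience wrappers

def fit_model(g: GenotypeMatrix, phenotypes: PhenotypeTable, alloc: ClassAllocation,
              model, cfg: ChainConfig) -> PosteriorSummary:
    """Impute, center and fit.  ``model`` is a ModelSpec, a prior-kind name
    applied to every class, or a mapping class label → prior-kind name."""
    X, col_means = impute_and_center(g)
    if isinstance(model, ModelSpec):
        spec = model
    else:
        spec = default_model_spec(model, alloc, phenotypes.values, X)
    return run_mcmc(X, phenotypes, alloc, spec, cfg, col_means=col_means)


def predict_ebv(summary: PosteriorSummary, genotypes) -> np.ndarray:
    """Estimated breeding values for (new) individuals: centered dosages
    times posterior-mean marker effects.  Centering uses the training-time
    column means stored in the summary."""
    dos = genotypes.dosages if isinstance(genotypes, GenotypeMatrix) else np.asarray(genotypes, dtype=float)
    m = summary.marker_effects.shape[0]
    if dos.shape[1] != m:
        raise ValueError(f"genotypes have {dos.shape[1]} markers, model has {m}")
    if summary.col_means is not None:
        X = dos - summary.col_means
        nan_r, nan_c = np.where(np.isnan(X))
        X[nan_r, nan_c] = 0.0  # missing -> imputed to the training mean
    else:
        X = dos
    return X @ summary.marker_effects
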