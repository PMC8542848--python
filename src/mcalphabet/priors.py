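"""Per-class marker-effect priors and default hyperparameter derivation.

Five Bayesian Alphabet prior families are supported for the marker effects
of a SNP class:

* ``RR-BLUP`` — all effects normal with one common (co)variance;
* ``BayesA`` — normal with a locus-specific (co)variance, i.e. a scaled-t
  marginal;
* ``BayesB`` — point mass at zero plus the BayesA slab, with
  inclusion-pattern probabilities Π;
* ``BayesCPi`` — point mass plus a common-covariance normal slab, Π
  estimated (or fixed);
* ``BayesianLASSO`` — double-exponential (t = 1) or multivariate Laplace
  (t > 1) prior on the effects, handled through its normal scale-mixture
  representation.

In multi-trait models a locus may affect any combination of traits; the
2^t binary inclusion patterns δ are enumerated in a fixed order and Π is a
probability vector over them.  RR-BLUP is stored as BayesCPi with Π fixed
at the all-ones pattern, and BayesA as BayesB likewise — these are exact
model identities, and enforcing them in the constructor makes the
equivalences hold chain-for-chain.

Default scales follow the convention that the prior mean of the residual
covariance equals half the phenotypic (co)variance and the prior mean of
the total genetic (co)variance contributed by a class's markers equals the
other half, apportioned to classes by marker count.  Mean conventions:
``E[inv-Wishart(S, ν)] = S/(ν−t−1)`` and ``E[scaled-inv-χ²(ν, S)] =
νS/(ν−2)``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .datamodel import ClassAllocation

__all__ = [
    "PRIOR_KINDS",
    "PriorSpec",
    "ResidualPrior",
    "ModelSpec",
    "enumerate_inclusion_labels",
    "default_residual_prior",
    "default_marker_prior",
    "default_model_spec",
]

PRIOR_KINDS = ("RR-BLUP", "BayesA", "BayesB", "BayesCPi", "BayesianLASSO")

#: internal family codes after constructor reduction
FAMILY_MIXTURE_COMMON = "mixture-common"   # BayesCPi / RR-BLUP
FAMILY_MIXTURE_LOCUS = "mixture-locus"     # BayesB / BayesA
FAMILY_LAPLACE = "laplace"                 # Bayesian LASSO


def enumerate_inclusion_labels(t: int) -> np.ndarray:
    """All 2^t binary trait-inclusion patterns, in a fixed deterministic
    order: all-zeros first, all-ones last (binary counting, most significant
    trait first)."""
    if t < 1:
        raise ValueError("trait count must be >= 1")
    return np.array(list(itertools.product((0, 1), repeat=t)), dtype=float)


def _as_cov(x, t: int) -> np.ndarray:
    a = np.atleast_2d(np.asarray(x, dtype=float))
    if a.shape != (t, t):
        raise ValueError(f"expected {t}x{t} covariance, got {a.shape}")
    return a


def _check_pd(a: np.ndarray, what: str) -> None:
    if not np.allclose(a, a.T):
        raise ValueError(f"{what} is not symmetric")
    if np.linalg.eigvalsh(a).min() <= 0:
        raise ValueError(f"{what} is not positive definite")


@dataclass
class PriorSpec:
    """Prior specification for the marker effects of one SNP class.

    ``scale_beta`` is the t×t inverse-Wishart scale (a scalar for t = 1);
    when None it is derived from the phenotypic covariance by
    :func:`default_marker_prior`.  ``pi_init`` is a probability vector over
    the 2^t inclusion patterns of :func:`enumerate_inclusion_labels`.
    """

    kind: str
    df_beta: float = 4.0
    scale_beta: np.ndarray | float | None = None
    pi_treatment: str = "estimate"
    pi_init: np.ndarray | None = None
    laplace_rate: float | None = None
    estimate_variance: bool = True

    def __post_init__(self) -> None:
        if self.kind not in PRIOR_KINDS:
            raise ValueError(f"unknown prior kind {self.kind!r}; pick from {PRIOR_KINDS}")
        if self.pi_treatment not in ("estimate", "fixed"):
            raise ValueError("pi_treatment must be 'estimate' or 'fixed'")
        if self.laplace_rate is not None and self.laplace_rate <= 0:
            raise ValueError("laplace_rate must be positive")

    @property
    def family(self) -> str:
        if self.kind in ("RR-BLUP", "BayesCPi"):
            return FAMILY_MIXTURE_COMMON
        if self.kind in ("BayesA", "BayesB"):
            return FAMILY_MIXTURE_LOCUS
        return FAMILY_LAPLACE

    def resolved_pi(self, t: int) -> tuple[np.ndarray, bool]:
        """(pi vector over 2^t patterns, fixed flag) after the constructor
        reductions: RR-BLUP/BayesA pin Π at the all-ones pattern."""
        K = 2 ** t
        if self.kind in ("RR-BLUP", "BayesA", "BayesianLASSO"):
            pi = np.zeros(K)
            pi[-1] = 1.0
            return pi, True
        if self.pi_init is None:
            pi = np.full(K, 1.0 / K)
        else:
            pi = np.asarray(self.pi_init, dtype=float)
            if pi.shape != (K,):
                raise ValueError(f"pi_init must have length 2^t = {K}")
            if abs(pi.sum() - 1.0) > 1e-9 or (pi < 0).any():
                raise ValueError("pi_init must be a probability vector")
        return pi, self.pi_treatment == "fixed"

    def validate(self, t: int) -> None:
        if t > 1 and self.df_beta <= t + 1:
            raise ValueError(
                f"df_beta={self.df_beta} <= t+1={t + 1}: prior covariance mean undefined"
            )
        if t == 1 and self.df_beta <= 2:
            raise ValueError("df_beta must exceed 2 for a finite prior mean")
        if self.family == FAMILY_LAPLACE and self.laplace_rate is None:
            raise ValueError("BayesianLASSO requires laplace_rate")
        if self.family != FAMILY_LAPLACE and self.scale_beta is None:
            raise ValueError(f"{self.kind} prior has no scale_beta set")


@dataclass
class ResidualPrior:
    """Inverse-Wishart (t > 1) / scaled-inverse-χ² (t = 1) residual prior."""

    df_e: float = 4.0
    scale_e: np.ndarray | float = 1.0
    estimate_variance: bool = True

    def validate(self, t: int) -> None:
        if t > 1 and self.df_e <= t + 1:
            raise ValueError(f"df_e={self.df_e} <= t+1={t + 1}")
        if t == 1 and self.df_e <= 2:
            raise ValueError("df_e must exceed 2")

    def prior_mean(self, t: int) -> np.ndarray:
        if t == 1:
            return np.atleast_2d(self.df_e * float(np.squeeze(self.scale_e)) / (self.df_e - 2))
        return _as_cov(self.scale_e, t) / (self.df_e - t - 1)


@dataclass
class ModelSpec:
    """Trait count, one PriorSpec per class (order = class order), and the
    residual prior: the full hierarchical model."""

    trait_count: int
    class_priors: list  # of (class label, PriorSpec)
    residual_prior: ResidualPrior

    def validate(self, alloc: ClassAllocation) -> None:
        labels = [lbl for lbl, _ in self.class_priors]
        if labels != list(alloc.classes):
            raise ValueError(
                f"class priors {labels} do not match allocation classes {list(alloc.classes)}"
            )
        for _, p in self.class_priors:
            p.validate(self.trait_count)
        self.residual_prior.validate(self.trait_count)


# ---------------------------------------------------------------------------
# default hyperparameters

def default_residual_prior(phenotypic_cov, df_e: float = 4.0) -> ResidualPrior:
    """Scale the residual prior so its mean equals phenotypic_cov / 2."""
    P = np.atleast_2d(np.asarray(phenotypic_cov, dtype=float))
    t = P.shape[0]
    _check_pd(P, "phenotypic covariance")
    target = P / 2.0
    if t == 1:
        scale = float(target[0, 0]) * (df_e - 2.0) / df_e
        return ResidualPrior(df_e=df_e, scale_e=scale)
    if df_e <= t + 1:
        raise ValueError(f"df_e={df_e} <= t+1={t + 1}: cannot match a prior mean")
    return ResidualPrior(df_e=df_e, scale_e=(df_e - t - 1.0) * target)


def expected_inclusion_fraction(pi: np.ndarray, t: int) -> float:
    """Expected fraction of trait slots a locus occupies under Π: the mean
    per-trait inclusion probability."""
    labels = enumerate_inclusion_labels(t)
    return float(np.asarray(pi) @ labels.mean(axis=1))


def default_marker_prior(
    phenotypic_cov,
    centered_genotypes: np.ndarray,
    class_members: np.ndarray,
    kind: str,
    pi_init: np.ndarray | None = None,
    df_beta: float = 4.0,
    marker_share: float | None = None,
    pi_treatment: str = "estimate",
) -> PriorSpec:
    """Derive the class's scale hyperparameter from the phenotypic
    (co)variance.

    The class's markers are given a prior mean of total genetic
    (co)variance of ``phenotypic_cov/2`` times the class's share of
    markers (``marker_share``; defaults to |class| / m).  Writing v_f for
    the sample variance of centered genotype column f and q for the
    expected inclusion fraction under ``pi_init``, the per-marker target is

        E[G] = (phenotypic_cov / 2) * share / (q * Σ_f v_f)

    and the inverse-Wishart / scaled-inv-χ² scale follows from the mean
    conventions.  For the LASSO the double-exponential rate λ matches its
    per-coordinate variance 2/λ² to the per-marker target.
    """
    P = np.atleast_2d(np.asarray(phenotypic_cov, dtype=float))
    t = P.shape[0]
    _check_pd(P, "phenotypic covariance")
    members = np.asarray(class_members, dtype=np.int64)
    if members.size == 0:
        raise ValueError("class is empty")
    n, m = centered_genotypes.shape
    cols = centered_genotypes[:, members]
    v = (cols ** 2).sum(axis=0) / max(n - 1, 1)
    sum_v = float(v.sum())
    if sum_v <= 0:
        raise ValueError("class has zero genotypic variance (all markers monomorphic)")
    share = members.size / m if marker_share is None else float(marker_share)

    spec = PriorSpec(kind=kind, df_beta=df_beta, pi_init=pi_init, pi_treatment=pi_treatment)
    pi, _fixed = spec.resolved_pi(t)
    q = expected_inclusion_fraction(pi, t)
    if q <= 0:
        raise ValueError("pi_init places no mass on any included pattern")
    EG = (P / 2.0) * share / (q * sum_v)

    if kind == "BayesianLASSO":
        per_coord = float(np.mean(np.diag(EG)))
        spec.laplace_rate = float(np.sqrt(2.0 / per_coord))
        return spec
    if t == 1:
        spec.scale_beta = float(EG[0, 0]) * (df_beta - 2.0) / df_beta
    else:
        if df_beta <= t + 1:
            raise ValueError(f"df_beta={df_beta} <= t+1={t + 1}")
        spec.scale_beta = (df_beta - t - 1.0) * EG
    return spec


def default_model_spec(
    kind,
    alloc: ClassAllocation,
    phenotypes: np.ndarray,
    centered_genotypes: np.ndarray,
    pi_init: np.ndarray | None = None,
    pi_treatment: str = "estimate",
) -> ModelSpec:
    """Build a full ModelSpec with default hyperparameters.

    ``kind`` is one prior name applied to every class, or a mapping
    class label → prior name (prior kinds may differ across classes).
    The phenotypic covariance is the sample covariance of ``phenotypes``
    (n×t).
    """
    Y = np.atleast_2d(np.asarray(phenotypes, dtype=float))
    if Y.shape[0] == 1:
        Y = Y.T
    t = Y.shape[1]
    P = np.atleast_2d(np.cov(Y, rowvar=False))
    total_entries = sum(alloc.members[c].size for c in alloc.classes)
    priors = []
    for label in alloc.classes:
        k = kind[label] if isinstance(kind, dict) else kind
        share = alloc.members[label].size / total_entries
        priors.append(
            (
                label,
                default_marker_prior(
                    P,
                    centered_genotypes,
                    alloc.members[label],
                    kind=k,
                    pi_init=pi_init,
                    marker_share=share,
                    pi_treatment=pi_treatment,
                ),
            )
        )
    spec = ModelSpec(t, priors, default_residual_prior(P))
    spec.validate(alloc)
    return spec
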