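"""Cross-validation, prediction accuracy, ensembling, significance testing
and MCMC convergence diagnostics.

Prediction accuracy is the Pearson correlation between estimated breeding
values and the phenotypic records of validation individuals; replicate
splits follow an 8:2 train:validation ratio by default.  Competing methods
are compared replicate-paired with a two-sided paired t-test at
significance level 0.1, with no multiple-testing correction across priors.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import ClassAllocation, GenotypeMatrix, PhenotypeTable, impute_and_center
from .priors import default_model_spec
from .sampler import ChainConfig, run_mcmc

logger = logging.getLogger(__name__)

__all__ = [
    "CVPlan",
    "make_cv_plan",
    "prediction_accuracy",
    "ensemble_ebv",
    "paired_t_test",
    "gelman_rubin",
    "cross_validate",
]


@dataclass
class CVPlan:
    replicate: int
    train: np.ndarray
    validation: np.ndarray
    ratio: float
    seed: int

    def __post_init__(self) -> None:
        self.train = np.asarray(self.train, dtype=np.int64)
        self.validation = np.asarray(self.validation, dtype=np.int64)
        if np.intersect1d(self.train, self.validation).size:
            raise ValueError("train and validation sets overlap")


def make_cv_plan(n: int, n_replicates: int, ratio: float = 0.8, seed: int = 0) -> list:
    """Independent uniform train/validation splits, one per replicate.

    The training-set size is round-half-even of ratio*n.  Deterministic
    under ``seed``; different replicates use different permutations.
    """
    if n < 5:
        raise ValueError("need at least 5 individuals")
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must lie in (0, 1)")
    n_train = int(round(ratio * n))
    n_train = min(max(n_train, 1), n - 1)
    rng = np.random.default_rng(seed)
    plans = []
    for rep in range(n_replicates):
        perm = rng.permutation(n)
        plans.append(
            CVPlan(rep, np.sort(perm[:n_train]), np.sort(perm[n_train:]), ratio, seed)
        )
    return plans


def prediction_accuracy(ebv, phenotypes) -> float:
    """Pearson correlation between EBVs and phenotypic records."""
    a = np.asarray(ebv, dtype=float).ravel()
    b = np.asarray(phenotypes, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError(f"length mismatch: {a.size} vs {b.size}")
    if a.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("accuracy undefined for a constant vector")
    return float(stats.pearsonr(a, b).statistic)


def ensemble_ebv(ebv_by_method) -> np.ndarray:
    """Elementwise mean EBV across methods (the ensemble prediction)."""
    arrs = [np.asarray(v, dtype=float) for v in ebv_by_method]
    if len({a.shape for a in arrs}) != 1:
        raise ValueError("EBV vectors have mismatching shapes")
    return np.mean(arrs, axis=0)


def paired_t_test(acc_a, acc_b, alpha: float = 0.1):
    """Two-sided paired t-test on replicate-paired accuracies.

    Returns (t statistic, p value, significant flag).  Zero variance of the
    differences makes the statistic undefined; p is then reported as 1 and
    the comparison is not significant.
    """
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equal-length vectors with >= 2 replicates")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        logger.info("paired t-test: zero variance of differences; p set to 1")
        return 0.0, 1.0, False
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue), bool(res.pvalue < alpha)


def gelman_rubin(chains) -> float:
    """Potential scale reduction factor of a scalar parameter.

    ``chains`` is k×s (k >= 2 chains, s >= 10 retained samples).  With W the
    mean within-chain variance and B/s the variance of the chain means,

        PSRF = sqrt((W + B/s) / W).

    This is the large-sample form of the between/within variance ratio: it
    equals 1 exactly when the chains are identical and exceeds 1 when the
    chain means disagree relative to the within-chain spread.
    """
    X = np.atleast_2d(np.asarray(chains, dtype=float))
    k, s = X.shape
    if k < 2:
        raise ValueError("Gelman-Rubin diagnostic needs at least 2 chains")
    if s < 10:
        raise ValueError("need at least 10 samples per chain")
    W = X.var(axis=1, ddof=1).mean()
    B_over_s = X.mean(axis=1).var(ddof=1)
    if W == 0:
        return 1.0 if B_over_s == 0 else np.inf
    return float(np.sqrt((W + B_over_s) / W))


# ---------------------------------------------------------------------------
# CV harness

def cross_validate(
    g: GenotypeMatrix,
    phenotypes: PhenotypeTable,
    schemes: dict,
    methods,
    cfg: ChainConfig,
    n_replicates: int = 5,
    ratio: float = 0.8,
    seed: int = 0,
    truth=None,
    ensemble: bool = False,
) -> pd.DataFrame:
    """Run the replicate × method × class-scheme grid and tabulate accuracy.

    ``schemes`` maps scheme name → ClassAllocation; ``methods`` is a list of
    prior-kind names.  Each replicate re-centers genotypes on its training
    individuals, fits every (method, scheme) model on the training split and
    correlates predicted EBVs with validation phenotypes.  When a
    :class:`~mcalphabet.simulator.TruthRecord` is supplied, the accuracy
    against true breeding values is reported in a separate column.  With
    ``ensemble=True`` the across-method mean EBV is scored as method
    ``"Ensemble"`` per scheme.
    """
    plans = make_cv_plan(g.n_individuals, n_replicates, ratio, seed)
    rows = []
    for plan in plans:
        gtr = GenotypeMatrix(
            g.dosages[plan.train], g.snp_ids, g.chromosomes, g.positions,
            g.individual_ids[plan.train],
        )
        Xtr, col_means = impute_and_center(gtr)
        Ytr = phenotypes.values[plan.train]
        Xval = g.dosages[plan.validation] - col_means
        np.nan_to_num(Xval, copy=False)
        Yval = phenotypes.values[plan.validation]
        for scheme_name, alloc in schemes.items():
            ebvs = {}
            for method in methods:
                spec = default_model_spec(method, alloc, Ytr, Xtr)
                token = f"{plan.replicate}|{scheme_name}|{method}|{cfg.seed}"
                run_seed = zlib.crc32(token.encode()) & 0x7FFFFFFF
                run_cfg = ChainConfig(cfg.chain_length, cfg.burn_in, cfg.thin,
                                      run_seed, cfg.n_chains)
                summary = run_mcmc(Xtr, Ytr, alloc, spec, run_cfg)
                ebvs[method] = Xval @ summary.marker_effects
            if ensemble:
                ebvs["Ensemble"] = ensemble_ebv(list(ebvs.values()))
            for method, ebv in ebvs.items():
                for ti, trait in enumerate(phenotypes.trait_names):
                    row = {
                        "replicate": plan.replicate,
                        "method": method,
                        "scheme": scheme_name,
                        "trait": trait,
                    }
                    try:
                        row["accuracy"] = prediction_accuracy(ebv[:, ti], Yval[:, ti])
                    except ValueError as exc:
                        logger.warning("replicate %d %s/%s trait %s: %s",
                                       plan.replicate, method, scheme_name, trait, exc)
                        row["accuracy"] = np.nan
                    if truth is not None:
                        row["accuracy_vs_truth"] = prediction_accuracy(
                            ebv[:, ti], truth.breeding_values[plan.validation, ti]
                        )
                    rows.append(row)
    return pd.DataFrame(rows)


def compare_schemes(acc: pd.DataFrame, scheme_a: str, scheme_b: str,
                    alpha: float = 0.1) -> pd.DataFrame:
    """Per (method, trait): mean accuracies of two schemes and the paired
    t-test over replicates."""
    out = []
    for (method, trait), sub in acc.groupby(["method", "trait"]):
        pa = sub[sub.scheme == scheme_a].sort_values("replicate")["accuracy"].to_numpy()
        pb = sub[sub.scheme == scheme_b].sort_values("replicate")["accuracy"].to_numpy()
        tstat, p, sig = paired_t_test(pa, pb, alpha)
        out.append({
            "method": method, "trait": trait,
            f"mean_{scheme_a}": pa.mean(), f"mean_{scheme_b}": pb.mean(),
            "t": tstat, "p": p, "significant": sig,
        })
    return pd.DataFrame(out)
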