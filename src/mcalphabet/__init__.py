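"""Multi-class Bayesian Alphabet genomic prediction.

Whole-genome Bayesian regression in which markers are partitioned (possibly
overlappingly) into SNP classes defined by biological information and each
class receives its own Bayesian Alphabet prior (RR-BLUP, BayesA, BayesB,
BayesCPi or Bayesian LASSO), for single- and multiple-trait analysis, with
simulation, cross-validation, ensembling and convergence diagnostics.
"""

__version__ = "0.1.0"

from .datamodel import (
    ClassAllocation,
    GenotypeMatrix,
    PhenotypeTable,
    align_individuals,
    impute_and_center,
    read_class_map,
    read_genotypes,
    read_phenotypes,
    write_class_map,
    write_genotypes,
    write_phenotypes,
)
from .allocation import (
    AnnotationTable,
    allocate_by_annotation,
    allocate_by_chromosome,
    allocate_two_class,
)
from .priors import (
    ModelSpec,
    PriorSpec,
    ResidualPrior,
    default_marker_prior,
    default_model_spec,
    default_residual_prior,
    enumerate_inclusion_labels,
)
from .sampler import (
    ChainConfig,
    PosteriorSummary,
    fit_model,
    inclusion_label_probabilities,
    predict_ebv,
    run_mcmc,
)
from .simulator import (
    SimulationConfig,
    TruthRecord,
    assign_annotation_classes,
    simulate_dataset,
    simulate_genotypes,
    simulate_traits,
)
from .evaluation import (
    CVPlan,
    cross_validate,
    ensemble_ebv,
    gelman_rubin,
    make_cv_plan,
    paired_t_test,
    prediction_accuracy,
)

__all__ = [name for name in dir() if not name.startswith("_")]
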