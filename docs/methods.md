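# Methods

## Model

For genotyped individual *i* with *t* traits the model is

    y_i = μ + Σ_l Σ_{f ∈ C_l} m_{if} α_f^(l) + e_i,      e_i ~ N_t(0, R)

where `m_{if}` is the centered allele dosage at marker *f*, `C_l` is the
*l*-th SNP class and `α_f^(l)` the *t*-vector of allele-substitution
effects the marker carries *within that class*.  The only fixed effect is
the general mean μ (flat prior).  Classes are sets of markers sharing
biological annotation — genome-annotation feature types, chromosomes, or a
focal list such as previous GWAS hits — and each class receives its own
Bayesian Alphabet prior.  Classes may overlap; a marker belonging to k
classes contributes k additive effect terms, one under each class's prior.
The one-class model is exactly the conventional (single-prior) analysis.

Marker-effect priors per class (`t` = 1 replaces inverse-Wishart by
scaled-inverse-χ² and multivariate normal by normal):

| kind          | effect prior within the class                                   |
|---------------|-----------------------------------------------------------------|
| RR-BLUP       | α ~ N(0, G), common G ~ IW(S_β, ν_β)                            |
| BayesA        | α ~ N(0, G_f), locus-specific G_f ~ IW(S_β, ν_β)                |
| BayesB        | α = D β, β ~ N(0, G_f), G_f ~ IW(S_β, ν_β), patterns δ ~ Π      |
| BayesCΠ       | α = D β, β ~ N(0, G) common, patterns δ ~ Π                     |
| Bayesian LASSO| α double-exponential (t=1) / multivariate Laplace (t>1), rate λ |

`D = diag(δ)` with δ a binary trait-inclusion pattern; the 2^t patterns
are enumerated in a fixed order (all-zeros first, all-ones last) and Π is
a class-level probability vector over them with a uniform (Dirichlet(1))
prior, estimated by default or optionally fixed.  RR-BLUP is stored as
BayesCΠ with Π fixed at the all-ones pattern and BayesA as BayesB
likewise.  These are exact model identities; enforcing them in the
constructor makes the pairs equivalent *chain-for-chain* under a common
seed, which the tests assert bit-for-bit.

## Default hyperparameters

ν_β = ν_e = 4 throughout.  Scales are set from the sample phenotypic
(co)variance P so that the prior mean of R is P/2 and the prior mean of
the total genetic (co)variance is P/2, using the mean conventions
E[IW(S, ν)] = S/(ν − t − 1) and E[scaled-inv-χ²(ν, S)] = νS/(ν − 2).
Since nothing dictates how the genetic-variance target splits across
classes, it is apportioned proportionally to class marker count, which
makes the one-class model reproduce the conventional default exactly.
Within a class the per-marker effect-variance target divides the class
target by Σ_f v_f (v_f = sample variance of the centered dosage column)
times the expected inclusion fraction implied by the initial Π (1 for
RR-BLUP/BayesA, 1/2 per trait for a uniform Π).  For the LASSO the rate λ
matches the double-exponential variance 2/λ² to the per-marker target; λ
has no hyperprior.  Note ν = 4 only admits a prior mean for t ≤ 2; for
t ≥ 3 a larger ν_β must be supplied explicitly.

With `estimate_variance=False` a prior's scale is interpreted as the fixed
value of the (co)variance rather than as an inverse-Wishart scale — used
for conjugate-oracle validation and available for sensitivity analysis.

## Gibbs sampler

Each sweep updates, in a fixed order chosen for reproducibility: μ; every
class's loci in index order; variance components; each class's Π; R.
At a BayesB/BayesCΠ locus the inclusion pattern δ is drawn from its full
conditional with β integrated out analytically — the marginal weight of
pattern d is

    Π_d · |I + G A_d|^(−1/2) · exp(½ b_d' (A_d + G⁻¹)⁻¹ b_d),
    A_d = c (d d' ∘ R⁻¹),  b_d = d ∘ (R⁻¹ r),  c = m'm,

with r the full-conditional data vector — and β is then drawn from its
Gaussian full conditional given δ (coordinates excluded by δ come from
the prior conditional, so the full β vector always exists).  Joint
(δ, β) sampling is required for mixing; updating δ given the current β
would almost never flip a pattern.  Conjugate block updates:

* BayesA/B locus covariance: G_f ~ IW(S_β + β_f β_f', ν_β + 1);
* RR-BLUP/BayesCΠ class covariance: G ~ IW(S_β + Σ_incl β β', ν_β + #incl),
  summing loci with δ ≠ 0 — the β values of fully-excluded loci are
  regenerated every sweep and feed nothing downstream, so the chain is a
  valid collapsed Gibbs sampler;
* residual: R ~ IW(S_e + E'E, ν_e + n);
* Π ~ Dirichlet(1 + pattern counts);
* LASSO mixing scales: the double exponential is handled as a normal
  scale mixture, α_f | v_f ~ N(0, v_f I), v_f ~ Exp(λ²/2); the full
  conditional of v_f is generalized-inverse-Gaussian
  GIG(1 − t/2, λ², α_f'α_f) (t = 1: 1/v inverse-Gaussian(λ/|α|, λ²)),
  drawn with scipy's generator (t > 1) or the Wald sampler (t = 1), with
  |α| floored at 1e-8 to keep the conditional proper.

The sequential per-locus loop is compiled with numba; all other updates
are vectorized numpy/scipy.  numba's `np.random.Generator` support
produces streams bit-identical to numpy's, so one seeded generator per
chain makes runs exactly reproducible; multiple chains use seeds spawned
from the master seed via `SeedSequence`.  Numerical safeguards: residuals
are recomputed from scratch every 500 sweeps to cancel float drift (the
bookkeeping invariant y − μ − Mα = E is asserted to 1e-8 in tests);
non-positive-definite inverse-Wishart scales are jittered by 1e-8 on the
diagonal with up to 5 retries; pattern weights are computed in log space.

Posterior summaries average every post-burn-in sweep; thinned scalar
traces (heritabilities, variance components, genetic correlations, class
variances) are retained for diagnostics.  Genomic quantities are
functionals of the sampled state: per sweep the genic values g = y − μ − e
give the realized genetic covariance across individuals, heritability
var(g)/(var(g) + R_tt) and genetic correlation; their posterior means are
reported.  EBVs are centered dosages times posterior-mean effects, with
validation individuals centered at the *training* column means.

## Simulator

The generator emulates a livestock-panel simulation design: binomial
dosages at MAF ~ U(0.05, 0.5), one annotation label per SNP drawn with
the class proportions of a 42K pig panel (protein_coding 0.357, ncRNA
0.044, processed_pseudogene 0.003, pseudogene 0.009, intergenic 0.588),
500 QTL drawn from the protein_coding class plus 20 genome-wide (disjoint
sets), pleiotropic QTL effects MVN(0, [[1, .5], [.5, 1]]), and target
heritabilities 0.5 and 0.9.  Residuals are diagonal-covariance normals
calibrated against the *realized* genetic variance so every replicate hits
its target heritability; trait correlation is induced genetically.  What
it does not emulate: linkage disequilibrium, pedigree/selection structure,
and minor-allele-frequency spectra of real panels — so passing tests show
correct inference *under the model*, not robustness to LD between markers
and unobserved causal variants.

## Evaluation

Replicate 8:2 train:validation splits (training size = round-half-even of
0.8·n); accuracy = Pearson correlation of EBV with validation phenotypes
(accuracy against true breeding values is reported in a separate, labelled
column when simulation truth is available); the across-method mean EBV is
scored as the ensemble; methods are compared with a two-sided paired
t-test at α = 0.1 and no multiple-testing correction.  Zero-variance
degenerate cases: a constant EBV vector makes accuracy undefined (logged
and excluded); zero-variance paired differences report p = 1.

The Gelman–Rubin PSRF is implemented in its large-sample form
sqrt((W + B/s)/W) — without the (s−1)/s finite-sample deflation — so that
identical chains give exactly 1 and the statistic is a pure
between/within variance ratio.

## Problem sizes and stochastic checks

Recovery checks run at n = 1000 individuals × m = 3000 SNPs with chains
of 5000 (single trait) or 3000 (two traits) sweeps, and the directional
multi-class vs conventional comparison at n = 600 × m = 2000 with 100 + 5
QTL over 10 replicate datasets with one 8:2 split each — sizes chosen so
the full suite runs on a desktop.  At n = 1000 × m = 3000 a *single*
genomic-heritability estimate has a sampling SD of ≈ 0.07 around the
simulation target (REML on the same data shows the same spread, so this
is a property of the estimand, not of the sampler); recovery is therefore
asserted on means over replicate simulated datasets, exactly as
replicated simulation studies report these quantities.

## Known limitations

No fixed effects beyond the general mean; no missing-phenotype machinery
(rows with any missing trait are dropped); mean imputation of missing
dosages; no single-step extension to non-genotyped individuals; BayesR-
style multi-component mixtures and window-based GWAS summaries are out of
scope.  ν_β = 4 is used uniformly for all prior kinds, including the
locus-specific BayesA/BayesB covariances.
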