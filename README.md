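# mcalphabet

Multi-class Bayesian Alphabet whole-genome regression for single- and
multiple-trait genomic prediction.

Genomic prediction estimates breeding values from genome-wide SNP dosages.
Conventional Bayesian Alphabet methods (RR-BLUP, BayesA, BayesB, BayesCΠ,
Bayesian LASSO) give every marker the same prior, ignoring biology: markers
in protein-coding genes, near known GWAS hits, or on particular chromosomes
can follow very different effect-size distributions.  `mcalphabet` fits the
*multi-class* generalization, for breeders and quantitative geneticists who
want to fold annotation into prediction:

    y_i = μ + Σ_l Σ_{f ∈ C_l} m_{if} α_f^(l) + e_i,     e_i ~ N_t(0, R)

Markers are allocated to SNP classes `C_l` (by genome-annotation feature
type, by chromosome, or focal-vs-rest around prior GWAS signals; classes
may overlap), and **each class gets its own Bayesian Alphabet prior** — a
BayesA prior on one class and BayesCΠ on another is fine.  In multi-trait
models each locus may affect any combination of traits through binary
inclusion patterns δ with class-level pattern probabilities Π
(α_f = diag(δ_f)·β_f).  Everything is fit by a seeded, exactly
reproducible Gibbs sampler.  The package also ships the matching
simulation engine (class-enriched QTL, pleiotropic effects, calibrated
heritabilities), replicated cross-validation with paired t-tests and
across-method ensembling, and Gelman–Rubin convergence diagnostics.
See `docs/methods.md` for the full model and algorithm.

## Worked example

```python
import mcalphabet as mc

# simulate a pig-panel-like dataset: 600 individuals, 2000 LD-free SNPs,
# 100 QTL concentrated in the protein_coding class + 5 genome-wide
cfg = mc.SimulationConfig(n_individuals=600, n_snps=2000,
                          n_qtl_enriched=100, n_qtl_genomewide=5,
                          heritabilities=(0.5,), seed=1000)
g, alloc, phen, truth = mc.simulate_dataset(cfg)

# conventional = one class; multi-class = one class per annotation label
schemes = {"multi-class": alloc,
           "conventional": mc.ClassAllocation.single_class(g.n_snps)}
acc = mc.cross_validate(g, phen, schemes, ["RR-BLUP", "BayesCPi"],
                        mc.ChainConfig(1500, 500, 10, seed=0),
                        n_replicates=1, ratio=0.8, seed=0)
print(acc[["method", "scheme", "accuracy"]])
```

Output (validation-set accuracy = Pearson correlation of EBVs with
phenotypes):

```
     method        scheme  accuracy
0   RR-BLUP   multi-class  0.493530
1  BayesCPi   multi-class  0.571522
2   RR-BLUP  conventional  0.375905
3  BayesCPi  conventional  0.555306
```

Giving the QTL-enriched protein-coding class its own prior raises RR-BLUP
accuracy by ~0.12 here: the multi-class model learns a large effect
variance for that class and shrinks the rest harder.  Accuracies are
bounded well below 1 because phenotypes contain 50% residual variance
(with h² = 0.5 the ceiling is about √0.5 ≈ 0.71).

The same analysis is available from the shell:

```bash
mcalphabet simulate --n-individuals 600 --n-snps 2000 --heritabilities 0.5 --out sim/
mcalphabet fit --genotypes sim/genotypes.csv --phenotypes sim/phenotypes.csv \
               --class-map sim/class_map.csv --method BayesCPi \
               --chain-length 100000 --burn-in 50000 --out fit/
mcalphabet evaluate --genotypes sim/genotypes.csv --phenotypes sim/phenotypes.csv \
               --class-map sim/class_map.csv --out eval/
mcalphabet run pipeline.yaml     # simulate → allocate → fit → evaluate + manifest
```

`fit` writes posterior-mean marker effects, EBVs, variance components,
per-class Π, thinned traces and a JSON manifest that reproduces the run
bit-identically.

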