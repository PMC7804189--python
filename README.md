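# grexdissect

Case/control differences in blood gene expression can come from two very
different places: the carrier's cis-genetic background, or everything else —
environment, exposures, clinical state.  `grexdissect` separates the two.
Per gene, it imputes the **genetically regulated expression** (GReX) as a
sparse linear combination of cis-SNP dosages,

    GReX_sg = Σ_v  w_gv · d_sv ,

and defines the **environmentally regulated expression** (EReX) as the
residual of observed expression on GReX.  Each component — observed, GReX,
EReX — is then tested against binary case/control status with a logistic
likelihood-ratio test, Λ = 2(ℓ_full − ℓ_null), calibrated by Freedman–Lane
permutations (p = b/B over 8000 initial permutations, escalating to 10⁶ when
no permutation reaches the observed statistic).  Downstream utilities cover
top-N hypergeometric pathway enrichment over ranked genes, strict threshold
counting, BH-FDR, and π₁ estimation (the proportion of true-alternative
tests under a uniform null, π₁ = 1 − #{p > λ}/((1−λ)m) at λ = 0.5).

It is written for statistical geneticists and psychiatric-genomics analysts
who want to ask, for a cohort with genotypes and expression: *is this
differential-expression signal driven by cis-regulatory variants, or by the
environment?*  A synthetic-cohort generator with known genetic/environmental
architecture makes every stage testable end to end without access-restricted
data.

Supporting machinery: variant QC (MAF > 0.05 and Hardy–Weinberg exact test
p > 0.05, both strict), elastic-net weight training on reference cohorts
with tenfold cross-validated R², and single-component REML estimation of
local (cis-window) heritability — the R²–h² correlation across genes is the
standard check that a weight model captures the cis-genetic signal.

## Worked example

Simulate a cohort where half the genes carry a purely environmental
case/control shift (0.8 SD), dissect it, and test both components:

```python
from grexdissect import (SimulationConfig, simulate_cohort, qc_filter,
                         predict_grex, compute_erex, run_association,
                         threshold_counts)
from grexdissect.datatypes import ExpressionBundle
from grexdissect.simulate import default_gene_ids

genes = default_gene_ids(40)
cfg = SimulationConfig(n_samples=300, n_cases=150, n_genes=40,
                       snps_per_gene=10, n_causal_weights_per_gene=4,
                       h2_per_gene=0.2, maf_range=(0.1, 0.4),
                       env_effect_genes=genes[:20], env_effect_size=0.8,
                       n_covariates=2, n_genotype_pcs=2, seed=7)
geno, bundle, cov, pheno, weights, truth = simulate_cohort(cfg)

geno_qc, qc = qc_filter(geno)                       # MAF/HWE filters
grex, kept, _ = predict_grex(geno_qc, weights)      # impute GReX
idx = [bundle.gene_ids.index(g) for g in kept]
erex, fit = compute_erex(bundle.observed[:, idx], grex, kept)
bundle = ExpressionBundle(bundle.sample_ids, kept,
                          bundle.observed[:, idx], grex, erex)
table = run_association(bundle, pheno, cov, B_initial=500, B_max=500,
                        seed=7, n_expression_pcs=0)
counts, overlap, sig = threshold_counts(table)
print(counts.to_string())
```

Output:

```
observed    19
grex         0
erex        20
```

Of the 40 genes, the 20 environment-linked ones light up in the EReX test
(19/20 also nominally differentially expressed in the observed data), while
the GReX test — whose genetic component is unlinked to status by
construction — rejects nothing at α = 0.05.  That is the dissection the
package exists for: the observed signal is carried by the environmental
component, not the cis-genetic one.

## Command line

```sh
dissect simulate --config sim.yaml --out cohort/ --seed 1
dissect grex  --dosages cohort/dosages.tsv --weights cohort/weights.tsv --out grex.tsv
dissect erex  --observed cohort/expression.tsv --grex grex.tsv --out erex.tsv
dissect assoc --observed cohort/expression.tsv --grex grex.tsv --erex erex.tsv \
              --phenotype cohort/phenotype.tsv --covariates cohort/covariates.tsv \
              --perms 8000 --seed 1 --out assoc.tsv
dissect enrich --assoc assoc.tsv --component erex --gene-set ifn.txt --out enrich.tsv
dissect run   --config run.yaml            # full pipeline, manifest + hashes
```

VCF (GT or DS) and plain dosage TSVs are accepted; expression, weight and
covariate tables are tab-separated; gene sets are one symbol per line.

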