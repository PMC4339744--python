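# mfqls

Family-based multivariate quasi-likelihood score tests: joint association
of M genetic variants with Q quantitative and/or dichotomous phenotypes in
family samples.

The statistic is a retrospective score test. Phenotypes are first adjusted
by an offset — the BLUP-based fitted values of a per-phenotype null linear
mixed model (variance components by profile REML), or the disease
prevalence for dichotomous traits under ascertained sampling. With
`A = Phi^-1 - Phi^-1 1 (1' Phi^-1 1)^-1 1' Phi^-1` and adjusted phenotypes
`T`, the score is `S = vec(T' Phi A X)` with variance
`Psi kron (T' Phi A Phi T)`, where `Phi` is the relationship matrix
(pedigree kinship, or an empirical genomic relationship matrix under
population substructure) and `Psi` the sample covariance of the tested
genotypes; `S' var(S)^-1 S` is chi-square with `M*Q` degrees of freedom
under the null. Individuals with missing phenotypes (zeroed offsets) or
missing genotypes (kinship-conditional expectations) are retained.

Three working-variance/offset configurations are exposed: `MFQLS`
(identity variance, BLUP offset), `MMQLS` (identity variance, prevalence
offset) and `MMASTOR` (per-phenotype mixed-model covariance, BLUP offset).

The package also contains the full generative model used to validate the
test: two-locus founder haplotypes at a configurable Lewontin D', Mendelian
transmission through a canonical 10-member three-generation family,
additive polygenic effects, liability-threshold dichotomization, and
optional two-subpopulation Balding-Nichols structure with a dense null
marker panel for GRM estimation.

## CLI

```sh
# simulate a dataset (PLINK .bed/.bim/.fam + phenotype/covariate TSVs)
mfqls simulate --out-prefix sim --n-families 100 --q 2 --seed 7

# association scan (one test per marker, or per set with --set-file)
mfqls test --bfile sim --pheno sim.pheno.tsv --method MFQLS --out results.tsv

# null replicate study (empirical type-I error)
mfqls calibrate --n-replicates 2000 --q 2 --out calibration.tsv

# relationship matrices (GCTA text GRM format)
mfqls grm --fam sim.fam --out-prefix kinship         # pedigree expectation
mfqls grm --bfile nullpanel --out-prefix grm         # empirical GRM
```

Result tables are TSV with columns
`SET_ID CHR SNP_LIST M Q METHOD STAT DF P`.

## Python API

```python
import numpy as np
from mfqls import (
    Pedigree, kinship_from_pedigree, PhenotypeMatrix, CovariateMatrix,
    variant_test,
)

ped = Pedigree.from_fam("sim.fam")
phi = kinship_from_pedigree(ped)
result = variant_test("MFQLS", phenotypes, covariates, phi, genotypes)
print(result.statistic, result.df, result.p_value)
```

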