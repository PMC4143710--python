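# famt2

Windowed multivariate (Hotelling-type) association testing for case/control
sequencing data in families, with optional longitudinal covariate blocks.

The scan splits the genome into fixed-width windows (default 10 kbp),
collapses rare variants (folded MAF < 0.05) between adjacent common variants
by sum or maximum, and compares case vs control mean vectors of the common
(Z), collapsed-rare (V) and longitudinal covariate (A) blocks while jointly
modelling three correlation sources:

* LD between variants — pooled within-group covariance per block;
* kinship between individuals — the pedigree-derived matrix `Phi`
  (and `Phi*` in `{I, Phi}` for the covariate block);
* repeated covariate measures — covariance over the covariate-by-time layout.

For unrelated individuals and a single block the statistic reduces exactly to
the classical two-sample Hotelling T². Six method variants are provided:

| method              | rare collapsing | genetic covariance | covariate block |
|---------------------|-----------------|--------------------|-----------------|
| `T2`                | sum             | joint `[Z \| V]`   | no              |
| `CMC.ZXpaper`       | sum             | separate Z and V   | no              |
| `CMC.ZXcode`        | max             | joint `[Z \| V]`   | no              |
| `T2.longi`          | sum             | joint `[Z \| V]`   | yes             |
| `CMC.ZXpaper.longi` | sum             | separate Z and V   | yes             |
| `CMC.ZXcode.longi`  | max             | joint `[Z \| V]`   | yes             |

Longitudinal methods define a case as an event at **any** measurement point;
the single-time-point comparators use the first measurement. P-values come
from a chi-square approximation (df = number of variables or matrix rank;
known to be anti-conservative under family structure) and from an empirical
null that permutes **genotype rows only**, preserving the
phenotype–covariate relationship.

A seeded gene-dropping simulator (founder haplotype pool with tunable LD,
Mendelian transmission with recombination, AR(1) covariates, per-time
logistic events with a shared liability intercept) generates every input the
package consumes, so all tests run without external data.

## CLI

```sh
# 1. simulate a dataset from a scenario YAML (fields of famt2.SimScenario)
famt2 simulate scenario.yaml --out-prefix sim        # VCF/PED/CSV/BEDs

# 2. scan: windows -> collapsing -> per-method T2 -> asymptotic + permutation p
famt2 scan --vcf sim.vcf --ped sim.ped --pheno sim.pheno.csv \
    --methods T2,T2.longi --width 10000 --maf-threshold 0.05 \
    -L 1000 --seed 1 --out results.tsv

# 3. calibration/power summaries against the truth windows
famt2 evaluate --results results.tsv --truth-bed sim.truth.bed --out summary.json
famt2 qq --results results.tsv --out qq.csv          # Q-Q table + lambda
```

Inputs: VCF with dosages (`DS` FORMAT field, genotype fallback), PED/FAM
pedigree, and a long-format phenotype CSV
(`individual,time,outcome,cov1,...`). All outputs are plain TSV/CSV/JSON.

## Python API

```python
from famt2 import (SimScenario, simulate_genotypes, simulate_phenotypes,
                   LongitudinalCovariates, ScanConfig, run_scan)

sc = SimScenario(n_families=10, sibship=4, n_variants=400,
                 causal_variants=(3,), causal_beta=0.4, seed=1)
vt, ped = simulate_genotypes(sc)
outcomes, A = simulate_phenotypes(sc, vt)
covs = LongitudinalCovariates(A, sc.n_covariates, sc.n_times)
report = run_scan(vt, ped, outcomes, covs,
                  ScanConfig(methods=("T2", "T2.longi"), permutations=1000))
report.to_tsv("results.tsv")
```

Lower-level pieces (`compute_kinship`, `make_windows`, `collapse`,
`t2_statistic`, `permutation_pvalue`, `compare_methods`,
`genomic_inflation`, ...) are exported from the package root.

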