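# crosspred

Across-population genomic prediction: principal component regression versus
GREML.

## The problem

In dairy-cattle breeding, genomic prediction estimates the additive genetic
merit (GEBV) of young animals from their SNP genotypes, using a reference
population with both genotypes and phenotypes.  Two statistical obstacles
dominate: many more markers than animals (n << p) and strong
multicollinearity from linkage disequilibrium.  The hardest setting is
*across-population* prediction, where the reference set contains no animals
from the population being predicted, so the relationships connecting
reference and test animals are weak.

`crosspred` implements and compares two families of predictors on
leave-one-population-out splits of multi-population SNP data:

* **PCR** — fixed-effect principal component regression
  `y = 1μ + Tg + e`, where `T = XV = UΣ` are PC scores from the thin SVD of
  the centred genotype matrix and the coefficients `g` are *unshrunken*
  ordinary least squares.  Components enter the model in one of two orders:
  by decreasing eigenvalue (`PCR_eigen`) or by decreasing contribution
  `(t_j'ỹ)² / (t_j't_j)` to the regression sum of squares in the reference
  set (`PCR_ss`).  The number of components is chosen by cross-validation
  inside the reference set (random 5-fold or population-stratified),
  minimising the pooled prediction MSE; the "best case" accuracy scan
  (adding PCs one by one and scoring against test phenotypes) gives the
  unattainable-in-practice upper bound.
* **SSPCR** — the semi-supervised variant: one SVD over reference *and* test
  genotypes, with the score matrix split afterwards; test phenotypes are
  never used.
* **GREML/GBLUP** — the animal model `y = 1μ + Wu + e`,
  `u ~ N(0, G σᵤ²)`, `e ~ N(0, I σₑ²)`, with the VanRaden genomic
  relationship matrix `G_VR = ZZ'/(2Σpᵢ(1-pᵢ))` blended toward the pedigree
  matrix A (`G = b·G_VR + (1-b)·A`), variance components estimated by REML
  via an exact eigen-rotation profile likelihood.

Prediction accuracy is the Pearson correlation between GEBV and
(pre-adjusted) phenotypes within the test population; dividing by √h²
converts it to an accuracy of GEBV.

A synthetic-data module generates multi-population pedigrees (random mating,
unrelated founders), genotypes (Balding–Nichols allele-frequency drift plus
gene dropping) and additive polygenic traits, so the whole pipeline is
testable without proprietary cattle data.  SNP quality control (call rate >
0.95, per-population MAF > 0.01, pooled HWE χ² < 600) and PLINK ped/map +
matrix-text IO round out the pipeline.

## Worked example

```python
import crosspred as cp

# five weakly related populations, 1609 genotyped cows, three traits
config = cp.SimulationConfig(n_snps=1200, n_qtl=200, seed=11,
                             n_generations=2, missing_rate=0.02)
study = cp.simulate_study(config)
cleaned, qc = cp.apply_qc(study.genotypes)
print(qc.summary())

design = cp.StudyDesign(seed=11, k_max=150)
result = cp.run_study(design, cleaned, study.phenotypes,
                      pedigree=study.pedigree,
                      true_breeding_values=study.true_breeding_values)
greml = result.report.query("method == 'greml'")
print(greml[["test_population", "trait", "accuracy"]].head(6).to_string(index=False))
```

prints (seed 11):

```
SNPs in: 1200
  removed by call_rate: 0
  removed by maf: 74
  removed by hwe: 0
SNPs out: 1126
test_population   trait  accuracy
           UK_1    milk  0.244909
           UK_1     fat  0.385631
           UK_1 protein  0.114630
           UK_2    milk  0.281594
           UK_2     fat  0.366788
           UK_2 protein  0.279186
```

Each row is one leave-one-population-out split: the model was trained on the
other four populations and the accuracy is the correlation between predicted
breeding values and phenotypes within the named test population.  The report
also contains, for every split and trait, the PCR/SSPCR accuracies at the
cross-validated number of PCs (both rankings, both CV schemes) and the
best-case scan maxima; `result.trajectories` holds the accuracy-versus-k
curves behind the scans, and `cp.summarize(result.report)` averages
accuracies over test populations per trait and method.

The same pipeline is scriptable from the shell:

```bash
crosspred full-demo --seed 11 --out demo/         # simulate -> QC -> compare
crosspred simulate --out sim/                     # individual stages
crosspred qc --in sim/genotypes.tsv --out qc/
crosspred compare --seed 11 --out cmp/ --plots
```

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's end-to-end demonstration from scratch: it simulates
the default five-population study (1609 animals, 5000 SNPs), applies SNP QC,
and runs the complete leave-one-population-out comparison — GREML with the
blended relationship matrix, PCR and SSPCR under both rankings and both CV
schemes, plus the best-case accuracy scans — writing the target JSON to
`--out` and the full report to `demo_outputs/` beside it.
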