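# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of `crosspred`.  Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Study design

The pooled multi-population dataset is split leave-one-population-out: each
population (or selection line) is the test set exactly once, with all other
populations forming the reference set, so every animal receives one
predicted breeding value per trait and method.  Accuracy is the Pearson
correlation between predictions and pre-adjusted phenotypes *within* the
test population; on simulated data a second column reports the correlation
with the true breeding values, which is only observable in simulation and
gives the tests a sharper target.  Dividing a phenotype correlation by √h²
converts it to an accuracy of GEBV; across the h² band 0.13–0.59 that
multiplier spans about 1.30–2.77.

## Models

### Principal component regression

The genotype matrix X (n × p, codes 0/1/2, mean-imputed) is centred —
scaling is available by flag but OFF by default, keeping PCR on the same
footing as the VanRaden Z matrix used by GREML — and decomposed by thin SVD,
X = UΣV′.  Scores are T = XV = UΣ.  The regression `y = 1μ + Tg + e` is
ordinary least squares: the coefficients are deliberately *fixed* effects
with no shrinkage, in contrast to the mixed model.  Two PC-ranking rules are
implemented:

* `eigen` — decreasing singular value (the natural SVD order; ties keep the
  lower index);
* `ss` — decreasing `(t̃_j'ỹ)² / (t̃_j't̃_j)` with mean-centred score column
  t̃_j and phenotype ỹ.  For mutually orthogonal score columns (exactly true
  on the decomposition's defining set) this equals the Type-I regression sum
  of squares of PC j regardless of entry order.  A sequential (entry-order
  dependent) decomposition would be ambiguous without a defined order, so
  the marginal form is used everywhere, including for SSPCR reference-subset
  scores where orthogonality is only approximate; that approximation is
  inherent to the split and is flagged here rather than handled specially.

Reference-only PCA centres on the reference animals and projects test
genotypes onto the reference loadings (`T_t = X_t V`).  Semi-supervised PCA
(SSPCR) computes a single decomposition over reference and test genotypes,
centring on all animals, and splits the score rows by membership — the
difference between the two *is* the method contrast under study, so each
variant uses its own defining set for centring.

The accuracy scan fits every prefix model k = 0..k_max in one pass via a QR
factorisation of the ordered design `[1, T_ranked]`: the span of the first
k+1 Q columns equals the span of the intercept plus the first k ranked PCs,
so per-k predictions are cumulative sums in the rotated basis.  This is
algebraically identical to refitting at every k (the tests assert agreement
with brute-force refits to 1e-10).  k = n−1 (interpolating fit) is permitted
— it is exactly the "all PCs" model when p > n — while k > n−1 is rejected.

### Cross-validated model size

Within the reference set, PCs are added one by one and the selected k
minimises the pooled (micro-averaged) MSE of held-out predictions; k = 0,
the intercept-only null model, is always a candidate, and ties resolve to
the smallest k.  Schemes: seeded random 5-fold (sizes differing by at most
one) and stratified (one fold per population).  Per fold, the decomposition
is recomputed from the training fold only (mode `pcr`, no leakage — a test
verifies that perturbing held-out genotypes leaves training loadings
unchanged) or from training plus held-out genotypes with held-out phenotypes
unseen (mode `sspcr`).  Selection by maximum accuracy instead of minimum MSE
is available behind a flag, default off.

A structural caveat established during development and worth recording: with
5-fold CV the expected MSE penalty for one superfluous PC and the sampling
fluctuation of that MSE increment are the same order of magnitude
(drift/sd ≈ m/(2√(m−1)) for m folds), so the argmin has a ~10–40% chance per
extra candidate PC of dipping below the true model size's MSE.  Minimum-MSE
CV therefore identifies the exact number of informative PCs reliably only
when the candidate set is very small; with realistic genotype matrices the
selected k scatters widely — which is precisely the behaviour the across-
population comparison is designed to expose (best-case accuracy is rarely
attained by CV selection).  The CV acceptance test uses a rank-1 genotype
fixture (one causal axis duplicated across SNPs) so that the decision being
verified — signal PC in, null model out — is well posed.

### GREML / GBLUP

The animal model has one record per animal, an intercept as the only fixed
effect (phenotypes arrive pre-adjusted), and `u ~ N(0, G σᵤ²)`.  The
genomic relationship matrix is VanRaden method 1,
`G_VR = ZZ'/(2Σpᵢ(1−pᵢ))` with allele frequencies pᵢ computed across **all**
genotyped animals (reference + test, as the design prescribes; a
reference-only option exists for leakage-sensitivity experiments).  G_VR is
regressed toward the pedigree expectation A:

* A is built by the tabular recursion (`A_ii = 1 + F_i`, unknown parents
  contributing zero); founders are assumed unrelated and non-inbred,
  matching the simulator contract.
* The blend coefficient b is estimated per bin of pedigree relationships as
  the attenuation `b = 1 − var(G−A)/var(G)` over off-diagonal pairs
  (quantile bins, default 5; bins with <2 pairs merge into a neighbour;
  values clipped to [0,1]).  The applied blend uses the pair-count-weighted
  scalar summary by default; per-bin blending and a fixed user override
  (including b = 1, no blending) are options.  The exact published estimator
  behind this blending is not reproduced in the material this package works
  from; the attenuation form above is the documented stand-in and is
  recorded in output metadata.  On marker-dense data b̂ approaches 1 and the
  blended and raw matrices give nearly identical predictions (asserted as a
  correlation > 0.99 between b = 0.99 and b = 1 GEBV).

REML exploits the single-random-effect structure exactly: one
eigendecomposition G = QΛQ′ rotates the model to a diagonal covariance,
the intercept and σₑ² profile out in closed form, and a bounded Brent search
over the signal fraction h = σᵤ²/(σᵤ²+σₑ²) on [0, 1) with tolerance 1e-10
maximises the restricted likelihood
`−½[(n−1)log 2π + log|V| + log|1'V⁻¹1| + y'Py]`.  The boundary h = 0 is
evaluated explicitly; estimates within 1e-10 of zero are reported as 0 with
a boundary flag.  A dense-matrix evaluation of the same restricted
likelihood (explicit V, slogdet and solves) is kept as an independent
cross-check; the tests require agreement to 1e-8.  Eigenvalues are clipped
at zero and a 1e-8 diagonal jitter is added (matrices more negative than
−1e-6 are rejected as non-PSD).

Prediction is BLUP: `û = σᵤ² G[:,ref] V_rr⁻¹ (y_r − 1μ̂)` with
`V_rr = G_rr σᵤ² + I σₑ²`.  With unblended `G = ZZ'/c` this is
algebraically identical to ridge regression on SNP effects with an
unpenalised intercept and penalty `λ = c σₑ²/σᵤ²`; the ridge solver is kept
in the package purely as the oracle for that equivalence.

## Synthetic data

The generator emulates the conditions the pipeline targets rather than any
particular real dataset:

* **Populations.** Final-generation sizes default to 206/210/181/394/618
  (total 1609) with labels UK_1, UK_2, SWE, IRL, NLD.  Differentiation
  follows the Balding–Nichols model: population frequency ~ Beta with mean p
  (ancestral, uniform on the base-MAF range 0.05–0.5 and mirrored to either
  allele) and variance F·p(1−p).  Default F: 0.10 for UK_1 and 0.04
  elsewhere, so one population drifts furthest and separates on PC1 of the
  pooled data — the qualitative pattern the study design relies on.
* **Pedigree and genotypes.** Each population has `n_generations` (default
  3) discrete generations of its final size; parents are drawn at random
  within population (distinct sire and dam), founders are unrelated across
  populations, and an optional migration rate (default 0, a free knob not a
  calibrated quantity) lets parents cross populations.  Genotypes descend by
  gene dropping: founders draw two alleles from their population frequency;
  offspring inherit one uniformly chosen allele per parent, independently
  across SNPs.  There is no linkage map — SNPs segregate independently, and
  LD-like covariance arises only through co-inheritance within families.
  This keeps the oracle tests exact; it also means the simulator does not
  reproduce chromosome-scale LD decay, so tests green on these data say
  nothing about LD-dependent behaviour.
* **Traits.** `n_qtl` SNPs (default 500 of 5000) are sampled without
  replacement; per-trait effects are iid standard normal; breeding values
  are centred-QTL-dosages × effects; the residual SD is set from the
  realised breeding-value variance so var(bv)/var(phenotype) equals the
  target h² in expectation.  Default traits milk/fat/protein with h² =
  0.30/0.35/0.25, inside the 0.13–0.59 band plausible for pre-adjusted
  yield phenotypes.  Non-QTL SNPs have exactly zero effect; there is no
  dominance, epistasis, selection or genotyping-error model.
* **Missingness** is completely at random (default rate 0) and exists to
  give the QC call-rate filter a target.

Everything is deterministic given the config seed (one `numpy` Generator
threaded through all stages); two end-to-end runs with the same seed produce
bit-identical reports.

## Quality control

Filters run in a fixed order with first-failure attribution — call rate
> 0.95, then minor allele frequency > 0.01 within *each* population
(computed on non-missing calls; a population with no call at a SNP counts as
failing), then pooled Hardy–Weinberg χ² < 600 — and the report reconciles
counts exactly.  The order is a reproducibility choice; the criteria
themselves do not prescribe one.  HWE uses the three-genotype-class Pearson
statistic without continuity correction (irrelevant at a 600 threshold),
pooled across populations by default with a per-population option, and
monomorphic SNPs take χ² = 0 by convention.  Missing calls are mean-imputed
per SNP, which preserves column means and hence downstream centring.
Platform-level genotype-score filters and sample-level QC are out of scope.

## Numerical choices

* Rank cutoff: singular values below 1e-10 × the largest are treated as
  zero and dropped.
* SVD sign convention: each loading column's largest-magnitude entry is made
  positive, so outputs are bit-reproducible.
* Null or zero-variance predictions (e.g. the k = 0 model giving every
  animal the same value) yield a missing accuracy, reported as NA rather
  than dropped; any stage failure marks its report cell `failed` and the run
  continues.
* Ties: best-case k and CV-selected k both resolve toward the smaller k
  (parsimony).
* k_max defaults to the full feasible rank, min(rank, n_ref − 2); the
  test suite caps it (and the SNP count) to stay inside its time budget,
  which is a compute choice and does not change any contract being tested.

## Limitations

* The simulator's populations are idealised (discrete generations, random
  mating, no selection); relationship magnitudes are in the right regime
  (within-population means and SDs exceed between-population ones, between
  means near zero) but are not calibrated to any real herd.
* The b̂ blending estimator is a documented stand-in (see above); only its
  mechanics and insensitivity are testable, not published coefficient
  values.
* Minimum-MSE CV selection of the number of PCs is intrinsically noisy (see
  the model-size section); users should read the selected k as one draw
  from a wide distribution, not as "the" dimensionality of the signal.
* All loci are treated as autosomal diploid; X-linked inheritance is not
  modelled.
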