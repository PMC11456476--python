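# Methods

## Scope and model

`mrscreen` implements two-sample summary-data Mendelian randomization (MR)
for batch screening of many exposures — bacterial taxon abundances from a
microbiome GWAS — against downstream clinical outcomes such as post-stroke
functional recovery. The causal parameter θ is the effect of a one-unit
change in the (unit-variance, rank-normalized) exposure on the outcome's
log-odds scale; results are reported as odds ratios exp(θ) with 95% Wald
intervals using the conventional 1.96 quantile exactly, so printed-CI
consistency checks are reproducible.

MR rests on three instrument assumptions: relevance (the variant affects the
exposure), independence (no confounding of the variant-outcome relation) and
exclusion restriction (no effect on the outcome except through the
exposure). The five estimators trade these off differently; the sensitivity
suite probes their failure modes.

## Instrument selection

Four filters, applied in a fixed order with per-stage provenance counts:

1. locus-wide significance, p < 1e-5 (the conventional genome-wide 5e-8
   leaves many taxa without instruments);
2. greedy LD clumping at r² < 0.001 within ±10,000 kb. Candidates are
   processed in ascending p order (ties: position, then SNP id) so the
   result is independent of input row order; SNP pairs absent from the LD
   table count as unlinked, which is conservative for retention and logged;
3. exclusion of palindromic (A/T, C/G) SNPs, whose strand cannot be
   resolved from alleles alone — no allele-frequency rescue is attempted;
4. weak-instrument filter F = (β/se)² ≥ 10.

The clump-before-palindrome order mirrors the enumeration of the selection
criteria; harmonization re-applies palindrome exclusion as a safety net.

## Estimators

With harmonized per-SNP effects (β_xj, se_xj) and (β_yj, se_yj), Wald ratios
r_j = β_yj/β_xj and outcome weights w_j = 1/se_yj²:

* **IVW**: weighted least squares of β_y on β_x through the origin,
  θ = Σw β_x β_y / Σw β_x². Default variance model is multiplicative random
  effects: SE_fixed · max(1, sqrt(Q/(J−1))). The floor at 1 means the
  random-effects SE is never smaller than the fixed-effect one; fixed
  effects are available by flag. The original analyses do not state their
  variance model, so this conservative default is pinned by tests.
* **MR-Egger**: weighted regression with a free intercept on the set
  oriented to non-negative β_x. The intercept estimates directional
  pleiotropy; coefficient SEs are inflated by max(1, σ̂) with
  σ̂² = RSS_w/(J−2), symmetric with the IVW treatment.
* **Weighted median**: interpolated weighted median of the r_j with
  first-order ratio-variance weights β_x²/se_y², consistent while valid
  instruments hold >50% of the weight. SE by parametric bootstrap
  (resampling β_x and β_y from normals at their SEs; 1000 draws by default,
  seeded).
* **Weighted mode**: argmax over a 512-point grid of a weighted normal KDE
  of the ratios; bandwidth by a modified Silverman rule
  h = φ·0.9·min(sd, 1.4826·MAD)·J^(−1/5) with φ = 1 default, floored at
  1e-12 for degenerate inputs; ties break to the smallest grid point.
  Same bootstrap SE.
* **Maximum likelihood**: profile likelihood of the bivariate normal
  measurement model with per-SNP true exposure effects as nuisance
  parameters (closed-form inner maximizer), profiled over θ by bounded
  scalar optimization started at the IVW estimate; SE from the numerically
  differentiated profile curvature. Unlike IVW, this model accounts for
  exposure-side sampling error.

Single-SNP sets degenerate to the Wald ratio for IVW and ML. All p-values
are two-sided normal unless the SE is bootstrap-based (still normal, with
the bootstrap SD as SE).

## Sensitivity suite

* Cochran's Q about the fixed-effect IVW fit (df = J−1) and about the Egger
  line (df = J−2), chi-square upper tails.
* Egger intercept test for directional pleiotropy.
* Leave-one-out IVW re-estimation; a row is "stable" when every LOO
  estimate keeps the full estimate's sign.
* MR-PRESSO: observed statistic is the weighted leave-one-out residual sum
  of squares Σ d_j²/se_yj² with d_j = β_yj − θ_(−j)β_xj. Weighting by
  1/se_y² makes the null distribution free of the outcome sample size. The
  null is simulated by redrawing both betas from normals centred on the
  observed exposure effects and the leave-one-out predictions. All
  Monte-Carlo p-values (global, per-SNP outlier, distortion) use the
  add-one position (1+#{≥obs})/(n_sim+1), so they are valid and never zero;
  per-SNP p-values are Bonferroni-multiplied by J. Note the granularity
  consequence: an outlier can only be declared at level α when
  n_sim ≳ J/α, hence the default n_sim = 1000. SNPs are processed in
  canonical id order so results are invariant to input row order.

## Screening decision rules

Per taxon: suggestive = IVW p < 0.05; Bonferroni-significant = IVW p below
0.05 divided by the number of registry taxa *at that taxon's rank* (0.05/9,
/16, /20, /35, /131 for the default registry); a whole-registry divisor
(0.05/211) is available because the published rule ("0.05 divided by the
number of each bacterial taxon") is ambiguous between the two readings.
A taxon whose Egger slope sign disagrees with IVW is excluded
(`excluded_direction`); all-method sign agreement is reported as a separate
flag rather than folded into a single verdict. Taxa with fewer than three
harmonized instruments are reported as `skipped_insufficient_ivs`, never
silently dropped. Reverse MR swaps the exposure and outcome roles with
identical selection thresholds.

## Synthetic data generator

The generator emulates the statistical structure of the study inputs so the
whole pipeline is testable offline: continuous unit-variance exposure
(n = 18,340, the microbiome-consortium size), binary outcome on the
log-odds scale (n = 6,021, the stroke-outcome GWAS size), per-SNP MAF
uniform on (0.05, 0.5), SE = 1/sqrt(2·maf(1−maf)·n) for both traits,
defaults of 10 candidate SNPs per taxon (≈ the study's 2,213 instruments
across 211 taxa) and a null causal effect. Outcome betas are drawn directly
with normal errors — no individual-level simulation — which keeps the truth
analytic.

Design choices worth noting:

* **Pleiotropy orientation.** The pleiotropic effect α_j ~ N(μ_α, τ_α²)
  attaches to the *exposure-increasing* allele:
  b_y = θ·b_x + sign(b_x)·α. This is the frame in which "directional"
  pleiotropy is defined and the MR-Egger intercept is its estimand; adding
  α in a random-allele frame would cancel its mean under orientation and
  make the intercept target zero regardless of μ_α. The InSIDE-violation
  knob correlates α with instrument strength |b_x| (standardized
  half-normal).
* **Weak-instrument effects are real.** With b_x ~ N(0, sd²) some true
  effects sit near zero; their observed sign is noise and systematically
  attenuates the Egger intercept if they are kept. The study design's own
  selection filter (p < 1e-5, F ≥ 10) removes them, so calibration and
  recovery checks run the generator output through instrument selection —
  as the real pipeline always would.
* **Monte-Carlo conditions.** Recovery/calibration suites use 200
  replicates of J = 50 candidate SNPs with instrument-effect SD 0.3 (mean
  F in the hundreds — strong instruments) and θ = 0.2. Two-sample IVW with
  noisy exposure betas carries a regression-dilution bias of roughly
  θ·se_x²/sd_b²; at these settings that bias is well below the Monte-Carlo
  resolution of 200 replicates, so the recovery checks measure estimator
  correctness rather than the (well-understood, irreducible) dilution term.
* One pseudo-chromosome per LD block, in-block SNPs 100 kb apart: the
  ±10,000 kb clumping window is testable both within and across windows.
* The batch generator (`simulate_screen_inputs`) draws one shared SNP
  universe (MAFs, alleles, positions) and per-taxon instrument effects;
  the single outcome accumulates the causal contributions of the designated
  causal taxa. Real taxa share correlated abundances and partially shared
  mbQTLs; the generator's taxa are independent, so cross-taxon correlation
  structure is *not* emulated and multiple-testing behaviour on real data
  may differ.

What passing tests show — and do not show. The synthetic data have exact
normal sampling errors, correct SEs, no LD misspecification, no sample
overlap and no allele-frequency errors. Passing recovery and calibration
suites therefore validates the estimators and decision rules as
implemented, not their robustness to real-data pathologies (population
stratification, winner's curse from discovery overlap, misreported
strands).

## Enrichment

Causal SNPs map to the nearest gene on the same chromosome (distance 0
inside an interval, else nearest-boundary distance; ties to the smaller
start, then gene id; unlimited distance). Over-representation uses the
hypergeometric upper tail against user-supplied GMT sets with
Benjamini-Hochberg adjustment across sets; the universe defaults to all
genes in the interval table. The original analysis used a web service with
curated GO/Reactome/KEGG releases; reproducing its specific enriched terms
requires those databases and is out of scope.

## Numerical conventions

Empirical p-values are add-one; analytic p-values are clipped to
[1e-300, 1]; 95% intervals use 1.96 exactly; clumping, mode ties and
nearest-gene ties have deterministic tie-breaks; all stochastic components
(bootstrap, MR-PRESSO, generator) take explicit seeds and identical inputs
give byte-identical outputs.

## Known limitations

No multivariable MR, Steiger filtering, proxy-SNP lookup or LD-aware
imputation; reverse MR requires the outcome GWAS to carry its own
instruments (a forward-causal pair alone makes outcome hits exposure
proxies, and reverse estimates then reflect the inverted forward effect —
visible in the generator when the outcome has no independent genetic
architecture); the per-rank Bonferroni divisor is a documented
interpretation of an ambiguous published rule.
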