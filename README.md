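# mrscreen

Two-sample Mendelian randomization (MR) screening toolkit for testing
whether genetically predicted gut-microbiota taxon abundances causally
influence downstream outcomes — built around the design of microbiome-GWAS
→ post-stroke functional-outcome screens, but applicable to any pair of
GWAS summary-statistic tables.

It is aimed at epidemiologists and statistical geneticists who want the
whole screen — instrument selection, harmonization, estimation, sensitivity
analysis, decision rules, reverse MR and downstream gene-set enrichment —
as a reproducible, scriptable pipeline with a synthetic-data generator so
every stage is testable without access to consortium data.

## The statistics

For taxon *T* with harmonized instruments j = 1..J (exposure effects
β_xj ± se_xj, outcome log-odds effects β_yj ± se_yj), the causal effect θ
is estimated five ways:

* **IVW** — weighted regression through the origin,
  θ̂ = Σ wⱼ β_xj β_yj / Σ wⱼ β_xj², wⱼ = 1/se_yj²; multiplicative
  random-effects SE floored at the fixed-effect SE;
* **MR-Egger** — the same regression with a free intercept α̂ estimating
  directional pleiotropy (consistent under InSIDE);
* **weighted median** — robust to <50% invalid instrument weight;
* **weighted mode** — the largest cluster of agreeing Wald ratios;
* **maximum likelihood** — profile likelihood of the bivariate measurement
  model.

Instruments pass p < 1e-5, LD clumping (r² < 0.001, ±10,000 kb),
palindrome exclusion and F = (β/se)² ≥ 10. Sensitivity: Cochran's Q (IVW
and Egger frames), the Egger intercept test, leave-one-out, and MR-PRESSO
(global RSS test, per-SNP outliers, outlier-corrected estimate with a
distortion test). Screening verdicts: suggestive (IVW p < 0.05),
per-rank Bonferroni significance (0.05 / number of taxa at the rank),
Egger-vs-IVW direction filtering, and all-method sign agreement. Effects
are reported as OR = exp(θ) with 95% CI exp(θ ± 1.96·se).

See `docs/methods.md` for the full model description and design choices.

## Worked example

```python
import mrscreen as m

# a synthetic taxon with a true protective effect theta = -0.5
cfg = m.SynthConfig(n_snps=40, theta_true=-0.5, instrument_effect_sd=0.3,
                    seed=7)
exposure, outcome, truth = m.simulate_summary_pair(cfg)
ld = m.simulate_ld_table(cfg)

instruments = m.select_instruments(exposure, ld)
print(instruments.provenance)
hset = m.harmonize(instruments, outcome)
for fit in (m.ivw(hset), m.egger(hset), m.weighted_median(hset),
            m.weighted_mode(hset), m.max_likelihood(hset)):
    lo, hi = fit.or_ci95
    print(f"{fit.method:16s} OR={fit.or_point:.2f} "
          f"95% CI {lo:.2f}-{hi:.2f} p={fit.pval:.2e}")
```

prints

```
{'input': 40, 'after_threshold': 31, 'after_clumping': 31, 'after_palindrome_filter': 25, 'after_f_filter': 25}
ivw              OR=0.62 95% CI 0.60-0.64 p=2.68e-190
egger            OR=0.62 95% CI 0.58-0.66 p=1.43e-50
weighted_median  OR=0.62 95% CI 0.59-0.65 p=1.71e-93
weighted_mode    OR=0.62 95% CI 0.59-0.65 p=3.61e-91
max_likelihood   OR=0.62 95% CI 0.60-0.64 p=2.08e-177
```

Nine SNPs fall below the locus-wide threshold and six palindromic SNPs
are excluded, leaving 25 instruments; all five estimators agree on
OR ≈ 0.61 = exp(-0.5), the simulated protective effect, within their CIs. `mrscreen.run_forward_screen` applies the same pipeline to a whole
dictionary of taxon tables and returns one audited verdict row per taxon;
`mrscreen.ora` tests nearest-gene sets for over-representation. The same
operations are exposed as a CLI:

```bash
mrscreen simulate --out-dir demo --seed 7 --n-snps 40 --theta-true -0.5 \
    --instrument-effect-sd 0.3
mrscreen select --sumstats demo/exposure.tsv --ld demo/ld.tsv --out demo/iv.tsv
mrscreen harmonize --exposure demo/iv.tsv --outcome demo/outcome.tsv \
    --out demo/harmonized.tsv
mrscreen mr --harmonized demo/harmonized.tsv --out demo/estimates.tsv
```

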