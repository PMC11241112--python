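# adcstab

Stability analysis of radiomic features on breast-lesion ADC maps under
segmentation perturbations.

Radiomic features extracted from apparent diffusion coefficient (ADC) maps
of breast lesions are sensitive to exactly where and how the lesion is
segmented. Before such features are used in diagnostic models, one needs to
know which of them survive realistic segmentation variability. `adcstab`
implements a complete, reproducible pipeline that quantifies this on
synthetic diffusion-weighted (DWI) phantoms:

1. **Phantoms** — single-slice lesions with mono-exponential DWI decay
   S(b) = S0·exp(−b·ADC) at b = 50/750/1500 s/mm², correlated intra-slice
   texture, Rician-like noise, solid (low-ADC) and cyst-like (high-ADC,
   T2 shine-through) lesions, and a rough ground-truth delineation.
2. **ADC mapping** — two-point fit from the b50/b750 images,
   ADC = ln(S₅₀/S₇₅₀)/(b₇₅₀−b₅₀), with fit outliers outside
   [0, 3.5] μm²/ms excluded.
3. **Segmentation variants** — Otsu's discriminant-criterion threshold on
   the b1500 image inside the delineation, then nine masks per lesion:
   the original (100 %), four *resizing* variants (threshold scaled to
   80/90/110/120 %), and four *shifting* variants (one-pixel translations).
4. **Features** — 102 radiomic features per lesion and variant, following
   IBSI-style definitions: 18 first-order, 9 2D shape, 24 GLCM, 16 GLRLM,
   16 GLSZM, 14 GLDM, 5 NGTDM.
5. **Stability statistics** — per feature and perturbation category:

   - the Overall Concordance Correlation Coefficient over J segmentations,

         OCCC = 2 Σ_{j<k} σ_jk / [ (J−1) Σ_j σ_j² + Σ_{j<k} (μ_j − μ_k)² ],

     with population moments over lesions (OCCC = 1 means perfect
     agreement, −1 a perfect inverse match);
   - the Dynamic Range,

         DR = 1 − (1/n) Σ_i |f(Test_i) − f(Retest_i)| / (Max − Min),

     averaged over the four retest segmentations, where Max/Min are the
     extreme feature values of the original segmentation across lesions;
   - 95 % percentile bootstrap confidence intervals (1000 resamples of
     lesions) for both.
6. **Scoring and ranking** — OCCC and DR each map to 0–4 points
   (breakpoints 0.75/0.85/0.90/0.95), giving a per-category stability score
   of at most 8 = 4 + 4; features are ranked by Euclidean distance of their
   (shifting, resizing) scores to the optimum (8, 8). Shape features only
   respond to resizing and are ranked on that axis alone.
7. **Threshold significance tests** — for a chosen feature, all 10 pairs of
   the five thresholds are compared with paired tests (Shapiro–Wilk-gated
   paired t vs Wilcoxon signed-rank) under Bonferroni correction
   (α = 0.05/10).

## Worked example

```python
from adcstab.pipeline import RunConfig, run_pipeline, summarize_top

cfg = RunConfig(n_lesions=30, cohort_seed=0, bootstrap_B=1000)
bundle = run_pipeline(cfg)                      # ~10 s on one CPU
print(summarize_top(bundle["records"], k=8)[
    ["feature", "class", "shifting_score", "resizing_score", "distance", "rank"]
].to_string(index=False))
```

prints

```
                   feature      class  shifting_score  resizing_score  distance  rank
   firstorder_10Percentile firstorder               8               8       0.0     1
   firstorder_90Percentile firstorder               8               8       0.0     1
           firstorder_Mean firstorder               8               8       0.0     1
         firstorder_Median firstorder               8               8       0.0     1
        firstorder_Minimum firstorder               8               8       0.0     1
firstorder_RootMeanSquared firstorder               8               8       0.0     1
      glcm_Autocorrelation       glcm               8               8       0.0     1
                  glcm_Idm       glcm               8               8       0.0     1
```

Location and intensity-level summaries (Mean, Median, RootMeanSquared,
percentiles) earn the full 8 points in both categories: their OCCC and DR
exceed 0.95, i.e. segmentation perturbations move them far less than the
natural between-lesion spread. At the other end, on this same cohort the
shape-of-histogram feature Kurtosis reaches only OCCC ≈ 0.48 under
resizing and ≈ 0.42 under shifting — it mostly measures segmentation, not
lesion biology. The full per-feature table, with CIs and point scores, is
in `bundle["stability"]`:

```
firstorder_Mean shifting OCCC = 1.000 [0.999, 1.000], DR = 0.989
```

The same pipeline is available from the shell:

```bash
adcstab run-all --out results/run1           # full pipeline, default config
adcstab simulate --out results/cohort       # phantom NIfTIs + manifest only
adcstab extract --out results/features.csv  # long-format feature table
```

with YAML configuration via `--config` (see `RunConfig.from_yaml`).

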