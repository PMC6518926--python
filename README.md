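# ogttbcf

Beta-cell function (BCF) from the oral glucose tolerance test: index
computation, WHO 2006 glycemic-status classification, and ROC/DeLong
discrimination analysis, with a synthetic cohort generator that makes the
whole pipeline runnable end to end without patient data.

The package is aimed at epidemiologists and biostatisticians comparing simple
OGTT-based estimates of insulin secretory function — the kind of analysis that
asks *which cheap index best identifies people who will progress to
prediabetes or type 2 diabetes?*

## What it computes

From a 4-point OGTT (plasma glucose G, insulin I and C-peptide CP at 0, 30,
60, 120 min; G in mmol/l, I and CP in pmol/l) plus sex and BMI:

* **20 formula-defined BCF indices**, grouped by secretory phase — fasting
  (HOMA-B1 = 20·I₀/(G₀−3.5) with I in μU/ml; I₀/G₀; CP₀/G₀), early phase
  (I₃₀/I₀, CP₃₀/CP₀, the insulinogenic index ΔI₃₀/ΔG₃₀, the C-peptidogenic
  index ΔCP₃₀/ΔG₃₀, ΔI₃₀/G₃₀, CIR₃₀ = I₃₀/[G₃₀(G₃₀−3.89)], the Stumvoll
  first-phase regression, and the two BIGTT-AIR regressions), late phase
  (Stumvoll second phase, 120 min ratio/incremental indices, CIR₁₂₀) and
  overall (trapezoidal AUC ratios AUC_I/AUC_G and AUC_CP/AUC_G).
  A 21st catalog slot is reserved for HOMA-B2, which requires the HOMA2
  computer model and is reported as not available.
* the **Matsuda index** of whole-body insulin sensitivity,
  10000/√(G₀·I₀·Ḡ·Ī) in mg/dl and μU/ml, and **disposition indices**
  DI = BCF index × Matsuda index;
* **glucose metabolism status** per WHO 2006 (NGM / prediabetes / T2DM from
  fasting and 2 h glucose, diabetic thresholds 7.0 and 11.1 mmol/l
  inclusive);
* **discrimination statistics**: mid-rank ROC AUC with DeLong
  variance/covariance, 95 % Wald CIs, paired DeLong tests between
  consecutively ranked indices and between disposition indices and the
  Matsuda index alone, Kruskal–Wallis and Mann–Whitney group comparisons, and
  a log–log slope test of the secretion–sensitivity hyperbola.

The synthetic generator produces label-consistent cohorts (default 294 NGM /
122 prediabetes / 60 T2DM) anchored to published per-class medians, with
lognormal assay noise at the stated interassay CVs (9.7 % insulin, 7.9 %
C-peptide), assay detection-limit censoring, and calibrated 7-year
progression (24.8 % NGM→prediabetes, 5.8 % NGM→T2DM, 37.7 %
prediabetes→T2DM) driven by latent secretion and sensitivity scalars.

## Worked example

```python
import ogttbcf as o

cohort = o.generate_cohort(o.CohortConfig(seed=1), seed=1)
matrix = o.compute_index_matrix(cohort)
longi  = o.run_longitudinal(cohort, matrix)
print(longi["incident_t2dm_in_non_t2dm"].table.head(4))
```

prints (seed 1):

```
             index rank  auc_pct  ci_low_pct  ci_high_pct  p_vs_next
             ir_30    1     83.0        77.0         88.0   0.187567
            cpr_30    2     80.0        75.0         86.0   0.291193
            cgi_30    3     78.0        71.0         84.0   0.709147
            cir_30    4     77.0        71.0         83.0   0.649652
```

i.e. for incident type 2 diabetes among at-baseline non-diabetic subjects the
top-ranked discriminators are all early-phase indices (AUC ≈ 77–83 %), with
no significant difference between consecutive ranks; fasting and late-phase
indices rank far lower. Running `o.run_di_analysis(cohort, matrix, longi)`
shows every AUC-gated disposition index beating the Matsuda index alone
(AUC ≈ 0.81–0.85 vs 0.64, paired DeLong p < 0.05) — secretion information
adds discrimination beyond insulin sensitivity.

The `examples/` directory contains one short script per capability
(`01_compute_indices.py` … `05_hyperbolicity.py`); each prints the numbers it
computes and a line on what they mean. A thin CLI wraps the same functions:

```bash
ogttbcf pipeline --simulate --seed 7 --outdir out/
ogttbcf simulate --seed 7 --out cohort.csv
ogttbcf indices --input cohort.csv --out indices.csv
```

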