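# Methods

## Index catalog and unit conventions

Each of the 20 implemented indices is evaluated exactly as published, which
fixes the units per formula rather than globally:

* All ratio and incremental indices use insulin/C-peptide in pmol/l and
  glucose in mmol/l. The C-peptide ratios are computed in the record's
  native pmol/l; any nmol/l presentation is a pure display scale and cannot
  affect ranks or AUCs.
* HOMA-B1 converts insulin to μU/ml (its 3.5 mmol/l offset and factor 20
  assume that unit); the pmol/l-per-μU/ml factor defaults to 6.945 and is
  configurable in `UnitConventions`. Because the factor rescales the index
  monotonically it never changes a ROC AUC, only the printed value.
* The Stumvoll and BIGTT regressions take insulin in pmol/l and glucose in
  mmol/l, as their coefficients require. BIGTT sex coding is female = 1,
  male = 0 (configurable); BMI in kg/m².
* The Matsuda index uses mg/dl and μU/ml, with unweighted arithmetic means
  of the four sampled values — the original definition, not a time-weighted
  mean.
* The overall AUC-ratio indices use the trapezoid rule on the 0/30/60/120 min
  grid: AUC(x) = 15(x₀+x₃₀) + 15(x₃₀+x₆₀) + 30(x₆₀+x₁₂₀). Published
  renderings of the final trapezoid sometimes print a product of the 60 and
  120 min values; a product inside a trapezoidal sum is dimensionally
  inconsistent, so the sum is used.

"×10⁻²" display factors attached to CIR, Stumvoll and BIGTT columns in the
literature are stored in the catalog as presentation metadata and are never
applied before ROC or disposition-index computation (a positive scale factor
cannot alter ranks; this is asserted by a test).

Missing-data policy is complete-case per index: a subject contributes to an
index only if every input of that index is observed. Ratio denominators with
magnitude below 1e-9 (e.g. G₃₀ = G₀) yield a missing value flagged
`degenerate_denominator`; negative incremental indices (G₁₂₀ < G₀ with
I₁₂₀ > I₀) are retained as computed, since no exclusion rule is part of the
index definitions. HOMA-B2 has no closed form (it requires the iterative
HOMA2 computer model), so its catalog entry is reserved and reported
not-available.

## Classification

WHO 2006, from fasting and 2 h glucose: T2DM if G₀ ≥ 7.0 or G₂ₕ ≥ 11.1
mmol/l; else prediabetes if G₀ ≥ 6.1 or G₂ₕ ≥ 7.8; else NGM. The textual
ranges "6.1–6.9" and "7.8–11.1" are implemented half-open ([6.1, 7.0),
[7.8, 11.1)) so the three rules partition the positive quadrant with no gap
at unrounded values such as 6.95; values are classified unrounded.

## ROC and DeLong inference

AUC is the tie-corrected (mid-rank) Mann–Whitney probability that a random
case scores above a random control. Variances and covariances come from
DeLong placement values: V₁₀ᵢ = mean over controls of ψ(sᵢ, sⱼ),
V₀₁ⱼ likewise over cases, ψ = 1 / ½ / 0 for win/tie/loss;
var(AUC) = S₁₀/m + S₀₁/n with sample (co)variances S. Paired comparisons on
the same subjects use the covariance of the shared placement values and a
two-sided normal p; a zero-variance difference with equal AUCs returns
z = 0, p = 1.

Confidence intervals are Wald on the AUC scale, clipped to [0, 1] — no logit
transform, matching the plain-CI reporting convention of index-comparison
studies. Orientation comes from the catalog (+1 higher = better BCF, −1 for
I₀/G₀ and CP₀/G₀); scores are negated accordingly before ROC computation and
never auto-flipped to force AUC ≥ 0.5, so genuinely uninformative indices can
report AUCs below 50 %. Ranking ties are defined at whole-percent reporting
precision and shown as tied ranges ("9–11"). Consecutive-pair and
DI-vs-Matsuda tests are reported without multiplicity correction,
deliberately mirroring standard practice for these analyses; readers should
treat borderline p-values accordingly.

Kruskal–Wallis and Mann–Whitney go through scipy.stats; Mann–Whitney uses the
exact distribution for groups of ≤ 8 without ties and the tie-corrected
normal approximation otherwise.

The hyperbolicity check fits ln(index) on ln(sensitivity) by OLS and calls
the pair "hyperbolic" iff the slope's 95 % CI contains −1 and excludes 0.
The criterion is a documented convention of this package: the underlying
disposition-index theory requires index·sensitivity ≈ constant, which is a
log–log slope of −1, but there is no single canonical test for it.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, not
any particular study population's joint distribution. Per subject of class c
(NGM / prediabetes / T2DM, default sizes 294/122/60):

* Latent insulin sensitivity S = S_med(c)·exp(0.5·z_S) (lognormal anchored
  to the class Matsuda medians 3.57/2.46/1.45) and latent early-phase
  secretion capacity B = exp(0.45·z_B).
* Glucose: G_t = Gmed_c[t]·exp(ε_t), ε sharing 40 % of its log-variance
  through a common subject factor; per-time sds from the published fasting
  and 2 h IQRs (mid-curve sd 0.15). (G₀, G₁₂₀) are rejection-sampled until
  the WHO classifier reproduces the intended class, so generated labels are
  exactly consistent. Small per-class log offsets on the (G₀, G₁₂₀) draw
  pre-compensate the truncation bias of that rejection step so realized
  sample medians land on the configured anchors (within ~2 %).
* Insulin: I_t = Imed_c[t]·(G_t/Gmed_c[t])·(S/S_med)^(−k_t)·B^(w_t)·noise,
  with secretion weights w = (0.3, 1.0, 0.8, 0.4) concentrating the latent
  secretion signal on the 30/60 min response and compensation exponents
  k = (0.7, 0.3, 0.4, 0.6) raising fasting/late insulin when sensitivity is
  low. Imed anchors come from published fasting/2 h insulin medians; the
  30/60 min medians are free parameters chosen so the class medians of
  I₃₀/I₀ (≈ 8.0/5.8/3.6) and ΔI₃₀/ΔG₃₀ reproduce the published
  cross-sectional pattern, with the early peak blunted and delayed in T2DM.
* C-peptide: CP_t = I_t(clean)·R·d_c[t], R a per-subject lognormal fasting
  CP/I molar ratio (median 10.3, sd 0.15) and d_c a class decay profile
  encoding C-peptide's slower kinetics (e.g. NGM d = 1/0.42/0.52/0.70).
* Multiplicative lognormal assay noise at CV 9.7 % (insulin) and 7.9 %
  (C-peptide); censoring at the assay detection ranges 35–25,000 pg/ml
  (insulin) and 70–50,000 pg/ml (C-peptide), converted to pmol/l with molar
  masses 5808 and 3010 g/mol. Under defaults far less than 1 % of values
  censor.
* Sex is drawn with class-specific female fractions (0.408/0.385/0.279) and
  BMI lognormally around class medians (27.3/28.0/30.6 kg/m²).

Seven-year progression is Bernoulli with
P = sigmoid(α_class − β·z_B − γ·z_S), β = 1.2 (secretion effect) and
γ = 0.6 (sensitivity effect) by default. α is calibrated per transition by
Brent root-finding on the realized cohort so expected marginal rates equal
the configured 24.8 %/5.8 %/37.7 %; NGM→T2DM is drawn first and NGM→
prediabetes calibrated on the remainder, prediabetes never regresses to NGM,
and baseline T2DM stays T2DM. Because progression loads on the latent
early-secretion deficit over and above sensitivity, early-phase indices and
their disposition indices out-discriminate fasting/late indices and the
Matsuda index *by construction* — passing tests validate the pipeline's
machinery and this qualitative structure, not any real cohort's AUC values.

What the generator does **not** model: physiological glucose–insulin
dynamics (no ODEs), cross-analyte correlation structure beyond the shared
latent scalars and glucose stimulus, covariate effects of sex/BMI/age on
concentrations, between-visit variability, or regression from prediabetes to
NGM (observed in real cohorts). Results on synthetic data therefore say
nothing about real-world AUC magnitudes.

All randomness flows from a single integer seed through numpy Generators
(separate streams for baseline and follow-up derived as `[seed, 0]` and
`[seed, 1]`); identical (config, seed) reproduce cohorts bit for bit.
Subjects consume draws in fixed vectorized blocks rather than one RNG stream
per subject; rejection re-draws affect only the glucose block of rejected
rows, preserving determinism.

## Analysis pipeline

Outcome strata mirror the longitudinal design: incident T2DM among
at-baseline non-T2DM subjects with follow-up; incident T2DM among at-baseline
NGM; incident prediabetes among at-baseline NGM, with stayed-NGM controls
(T2DM progressors belong to the other outcome). Prevalent outcomes use NGM
(for prediabetes) or all non-diabetic subjects (for T2DM) as reference. The
disposition-index stage admits indices with AUC ≥ 0.70 in at least one
incident outcome (inclusive threshold), computes DI = index × Matsuda per
subject, and tests each DI against the Matsuda index alone with the paired
DeLong test at p < 0.05.

Human-readable tables round AUCs and CIs to whole percents; the CSV outputs
keep full precision (17 significant digits, "NA" for missing), and repeated
runs with the same seed are byte-identical.

## Problem sizes used in verification

The test suite and acceptance script use: 1000 random small instances
(n ≤ 12, heavy ties) for the ROC pair-counting oracle; 2000 replicates at
100 cases/100 controls for DeLong null calibration and CI coverage; 50
seeded replicates (tenfold cohorts, n = 4760) for generator calibration; 100
(tests) or 50 (script) default-size replicates for the early-phase ranking
property; and a 2000-subject cohort for the DI-vs-Matsuda comparison. These
sizes give binomial/Monte-Carlo standard errors comfortably inside the
asserted tolerances.

## Known limitations

* The generator's 30/60 min curve shapes and the cross-analyte correlation
  structure are assumptions, not estimates; only the fasting/2 h marginals
  and progression rates are anchored to published summaries.
* Wald CIs on the AUC scale can touch the [0, 1] clip for extreme AUCs at
  small n.
* The exact Mann–Whitney p is only used for tiny groups; mid-size groups
  with many ties rely on the normal approximation.
* No covariate-adjusted ROC, partial AUC, or optimal-threshold selection;
  no HbA1c/ADA classification; no model-based secretion parameters.
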