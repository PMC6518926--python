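"""Synthetic OGTT cohort generator.

Emulates the statistical structure of a mixed glucose-tolerance cohort (294
normal glucose metabolism / 122 prediabetes / 60 newly diagnosed type 2
diabetes) observed with a 4-point 75 g OGTT, so the full index-discrimination
analysis can be exercised without access to patient data.

The generative model, per subject of class c:

* latent insulin sensitivity  S = S_med(c) * exp(sigma_S * zS)
* latent early-phase secretion capacity  B = exp(sigma_B * zB)
* glucose curve  G_t = Gmed_c[t] * exp(eps_t) with a shared lognormal
  subject factor plus per-time jitter; (G_0, G_120) are rejection-sampled
  until the WHO 2006 classifier reproduces the intended class, so generated
  labels are exactly consistent with the generated curves
* insulin curve  I_t = Imed_c[t] * (G_t/Gmed_c[t])^h * (S/S_med)^(-k_t) * B^(w_t)
  -- secretion capacity loads most on the 30/60 min response (w), while low
  sensitivity raises insulin compensatorily, most at 0/120 min (k)
* C-peptide  CP_t = I_t(clean) * R * d_c[t], with R a per-subject lognormal
  fasting CP/I molar ratio and d_c[t] a class decay profile encoding the
  slower plasma kinetics of C-peptide
* multiplicative lognormal assay noise at the stated interassay CVs, then
  censoring at the assay detection limits

Seven-year progression is a Bernoulli draw per subject with

    P(progress) = sigmoid(alpha_class - beta * zB - gamma * zS)

where alpha_class is calibrated by root-finding on the realized cohort so the
expected marginal rates equal the configured rates (24.8% NGM->prediabetes,
5.8% NGM->T2DM, 37.7% prediabetes->T2DM).  Progression therefore loads on the
latent early-secretion deficit over and above insulin resistance, which is
what gives early-phase secretion indices and their disposition indices their
built-in discriminative advantage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .io import Cohort, OGTTRecord, UnitConventions, convert_mass_to_molar
from .status import NGM, PREDIABETES, T2DM, classify_pairs

OGTT_TIMES = (0, 30, 60, 120)


class GenerationError(RuntimeError):
    """Raised when a config cannot produce label-consistent curves."""


@dataclass(frozen=True)
class ClassParams:
    """Per-class anchors of the generative model (medians from cohort tables)."""

    n: int
    glucose_median: tuple[float, float, float, float]   # mmol/l at 0/30/60/120
    insulin_median: tuple[float, float, float, float]   # pmol/l
    sigma_g0: float            # lognormal sd of fasting glucose
    sigma_g120: float          # lognormal sd of 2 h glucose
    matsuda_median: float      # anchors the latent sensitivity scalar
    cp_decay: tuple[float, float, float, float]  # CP/I profile vs fasting ratio
    female_fraction: float
    bmi_median: float          # kg/m^2
    bmi_sigma: float = 0.12
    #: log offsets applied when drawing (G0, G120), pre-compensating the
    #: truncation bias of label-consistent rejection sampling so realized
    #: sample medians land on glucose_median
    glucose_log_offset: tuple[float, float] = (0.0, 0.0)


def _default_classes() -> dict[str, ClassParams]:
    return {
        NGM: ClassParams(
            n=294, glucose_median=(5.27, 8.4, 7.2, 5.65),
            insulin_median=(61.2, 488.0, 420.0, 352.0),
            sigma_g0=0.075, sigma_g120=0.253,
            glucose_log_offset=(0.009, 0.038), matsuda_median=3.57,
            cp_decay=(1.0, 0.42, 0.52, 0.70),
            female_fraction=0.408, bmi_median=27.3),
        PREDIABETES: ClassParams(
            n=122, glucose_median=(6.00, 10.2, 9.8, 8.79),
            insulin_median=(78.8, 458.0, 520.0, 664.0),
            sigma_g0=0.095, sigma_g120=0.175,
            glucose_log_offset=(-0.015, -0.026), matsuda_median=2.46,
            cp_decay=(1.0, 0.46, 0.50, 0.54),
            female_fraction=0.385, bmi_median=28.0),
        T2DM: ClassParams(
            n=60, glucose_median=(7.14, 12.1, 12.6, 12.3),
            insulin_median=(110.0, 398.0, 480.0, 744.0),
            sigma_g0=0.115, sigma_g120=0.21,
            glucose_log_offset=(-0.040, -0.070), matsuda_median=1.45,
            cp_decay=(1.0, 0.54, 0.55, 0.50),
            female_fraction=0.279, bmi_median=30.6, bmi_sigma=0.13),
    }


@dataclass(frozen=True)
class CohortConfig:
    """All generator parameters; defaults are the study conditions."""

    classes: dict[str, ClassParams] = field(default_factory=_default_classes)
    #: lognormal sd of the mid-curve (30/60 min) glucose jitter
    sigma_g_mid: float = 0.15
    #: share of glucose log-variance from the common subject factor
    glucose_rho: float = 0.4
    #: lognormal sds of the latent sensitivity / secretion scalars
    sigma_sensitivity: float = 0.5
    sigma_secretion: float = 0.45
    #: secretion-capacity loading per time point (early-phase weighted)
    secretion_weights: tuple[float, float, float, float] = (0.3, 1.0, 0.8, 0.4)
    #: compensatory hyperinsulinaemia exponent per time point
    sensitivity_exponents: tuple[float, float, float, float] = (0.7, 0.3, 0.4, 0.6)
    #: glucose-stimulus exponent linking insulin to the subject's glucose
    stimulus_exponent: float = 1.0
    #: fasting C-peptide : insulin molar ratio (median, lognormal sd)
    cp_ratio_median: float = 10.3
    cp_ratio_sigma: float = 0.15
    #: interassay CVs
    assay_cv_insulin: float = 0.097
    assay_cv_cpeptide: float = 0.079
    #: assay detection ranges, pg/ml
    insulin_detection_pgml: tuple[float, float] = (35.0, 25_000.0)
    cpeptide_detection_pgml: tuple[float, float] = (70.0, 50_000.0)
    #: 7-year marginal progression rates
    rate_ngm_to_prediabetes: float = 0.248
    rate_ngm_to_t2dm: float = 0.058
    rate_prediabetes_to_t2dm: float = 0.377
    #: progression loadings on the standardized latent log-scalars
    secretion_effect: float = 1.2
    sensitivity_effect: float = 0.6
    #: fraction lost to follow-up (0 = total participation)
    dropout_rate: float = 0.0
    seed: int = 0
    max_rejection_rounds: int = 200

    def __post_init__(self) -> None:
        rates = (self.rate_ngm_to_prediabetes, self.rate_ngm_to_t2dm,
                 self.rate_prediabetes_to_t2dm)
        if not all(0.0 <= r <= 1.0 for r in rates):
            raise ValueError("progression rates must lie in [0, 1]")
        if self.rate_ngm_to_prediabetes + self.rate_ngm_to_t2dm > 1.0:
            raise ValueError("NGM outflow rates must sum to <= 1")
        if self.assay_cv_insulin <= 0 or self.assay_cv_cpeptide <= 0:
            raise ValueError("assay CVs must be positive")
        for lo, hi in (self.insulin_detection_pgml, self.cpeptide_detection_pgml):
            if not 0 < lo < hi:
                raise ValueError("detection limits must be ordered and positive")

    def scaled(self, factor: int) -> "CohortConfig":
        """Config with every class size multiplied by ``factor``."""
        classes = {k: replace(v, n=v.n * factor) for k, v in self.classes.items()}
        return replace(self, classes=classes)

    def total_n(self) -> int:
        return sum(p.n for p in self.classes.values())


def _cv_to_sigma(cv: float) -> float:
    return float(np.sqrt(np.log1p(cv * cv)))


def _draw_glucose(rng: np.random.Generator, params: ClassParams,
                  cfg: CohortConfig, n: int, class_name: str) -> np.ndarray:
    """Label-consistent glucose curves, shape (n, 4)."""
    sig = np.array([params.sigma_g0, cfg.sigma_g_mid, cfg.sigma_g_mid,
                    params.sigma_g120])
    off0, off120 = params.glucose_log_offset
    med = np.asarray(params.glucose_median) * np.exp([off0, 0.0, 0.0, off120])
    rho = cfg.glucose_rho
    out = np.empty((n, 4))
    todo = np.arange(n)
    for _ in range(cfg.max_rejection_rounds):
        m = len(todo)
        zc = rng.standard_normal((m, 1))
        zt = rng.standard_normal((m, 4))
        eps = sig * (np.sqrt(rho) * zc + np.sqrt(1.0 - rho) * zt)
        cand = med * np.exp(eps)
        out[todo] = cand
        ok = classify_pairs(cand[:, 0], cand[:, 3]) == class_name
        todo = todo[~ok]
        if len(todo) == 0:
            return out
    raise GenerationError(
        f"could not generate label-consistent glucose for class {class_name} "
        f"after {cfg.max_rejection_rounds} rounds ({len(todo)} subjects left)")


def generate_baseline(config: CohortConfig | None = None,
                      seed: int | None = None) -> Cohort:
    """Generate a baseline cohort with exact class counts and latent states.

    The returned :class:`Cohort` carries ``baseline_status`` (guaranteed
    consistent with ``classify_who2006`` on the generated curves) and a
    ``latent`` frame with the per-subject sensitivity/secretion scalars and
    censoring counts that :func:`generate_followup` consumes.
    """
    cfg = config or CohortConfig()
    rng = np.random.default_rng([seed if seed is not None else cfg.seed, 0])
    conv = UnitConventions()

    ins_lo, ins_hi = (convert_mass_to_molar(v, conv.insulin_molar_mass)
                      for v in cfg.insulin_detection_pgml)
    cp_lo, cp_hi = (convert_mass_to_molar(v, conv.cpeptide_molar_mass)
                    for v in cfg.cpeptide_detection_pgml)
    sig_i = _cv_to_sigma(cfg.assay_cv_insulin)
    sig_cp = _cv_to_sigma(cfg.assay_cv_cpeptide)
    w = np.asarray(cfg.secretion_weights)
    k = np.asarray(cfg.sensitivity_exponents)
    h = cfg.stimulus_exponent

    frames = []
    latents = []
    status: dict[str, str] = {}
    for class_name in (NGM, PREDIABETES, T2DM):
        p = cfg.classes[class_name]
        n = p.n
        glucose = _draw_glucose(rng, p, cfg, n, class_name)
        z_s = rng.standard_normal(n)
        z_b = rng.standard_normal(n)
        sens = p.matsuda_median * np.exp(cfg.sigma_sensitivity * z_s)
        secr = np.exp(cfg.sigma_secretion * z_b)

        gmed = np.asarray(p.glucose_median)
        imed = np.asarray(p.insulin_median)
        stimulus = (glucose / gmed) ** h
        insulin_clean = (imed * stimulus
                         * (sens / p.matsuda_median)[:, None] ** (-k)
                         * secr[:, None] ** w)
        cp_ratio = cfg.cp_ratio_median * np.exp(
            cfg.cp_ratio_sigma * rng.standard_normal(n))
        cpeptide_clean = insulin_clean * cp_ratio[:, None] * np.asarray(p.cp_decay)

        insulin = insulin_clean * np.exp(sig_i * rng.standard_normal((n, 4)))
        cpeptide = cpeptide_clean * np.exp(sig_cp * rng.standard_normal((n, 4)))
        cens_i = (insulin < ins_lo) | (insulin > ins_hi)
        cens_cp = (cpeptide < cp_lo) | (cpeptide > cp_hi)
        insulin = np.clip(insulin, ins_lo, ins_hi)
        cpeptide = np.clip(cpeptide, cp_lo, cp_hi)

        female = rng.random(n) < p.female_fraction
        bmi = p.bmi_median * np.exp(p.bmi_sigma * rng.standard_normal(n))
        bmi = np.clip(bmi, 15.0, 60.0)

        ids = [f"{class_name.lower()}_{i:05d}" for i in range(n)]
        frame = pd.DataFrame({"subject_id": ids,
                              "sex": np.where(female, "female", "male"),
                              "bmi": bmi})
        for j, t in enumerate(OGTT_TIMES):
            frame[f"g{t}"] = glucose[:, j]
        for j, t in enumerate(OGTT_TIMES):
            frame[f"i{t}"] = insulin[:, j]
        for j, t in enumerate(OGTT_TIMES):
            frame[f"cp{t}"] = cpeptide[:, j]
        frames.append(frame)
        latents.append(pd.DataFrame({
            "subject_id": ids, "class": class_name,
            "z_sensitivity": z_s, "z_secretion": z_b,
            "sensitivity": sens, "secretion": secr,
            "n_censored_insulin": cens_i.sum(axis=1),
            "n_censored_cpeptide": cens_cp.sum(axis=1),
        }))
        status.update({i: class_name for i in ids})

    data = pd.concat(frames, ignore_index=True)
    latent = pd.concat(latents, ignore_index=True)
    return Cohort(data=data, baseline_status=status, latent=latent)


def _calibrate_alpha(risk: np.ndarray, target: float,
                     damp: np.ndarray | None = None) -> float:
    """Solve mean(damp * sigmoid(alpha - risk)) = target for alpha."""
    if target <= 0.0:
        return -np.inf
    d = np.ones_like(risk) if damp is None else damp
    if target >= float(d.mean()):
        raise GenerationError(
            f"target rate {target} unreachable (max {float(d.mean()):.3f})")

    def f(alpha: float) -> float:
        return float(np.mean(d * expit(alpha - risk))) - target

    try:
        return float(brentq(f, -60.0, 60.0, xtol=1e-12))
    except ValueError as exc:
        raise GenerationError(f"progression calibration failed: {exc}") from exc


def generate_followup(cohort: Cohort, config: CohortConfig | None = None,
                      seed: int | None = None) -> dict[str, str]:
    """Draw 7-year follow-up statuses from the retained latent states.

    Baseline T2DM subjects remain T2DM; NGM subjects may progress to
    prediabetes or T2DM, prediabetes subjects to T2DM (no regression toward
    NGM).  Marginal progression probabilities are calibrated on the realized
    cohort, so the configured rates are recovered in expectation.  With
    ``dropout_rate > 0`` a random subset is omitted from the returned map.
    """
    cfg = config or CohortConfig()
    if cohort.latent is None:
        raise ValueError("cohort has no latent states; generate it with "
                         "generate_baseline")
    rng = np.random.default_rng([seed if seed is not None else cfg.seed, 1])
    lat = cohort.latent
    followup: dict[str, str] = {}

    cls = lat["class"].to_numpy()
    ids = lat["subject_id"].to_numpy()

    # NGM: competing progression to T2DM (rare) then prediabetes
    ngm = cls == NGM
    protect = (cfg.secretion_effect * lat.loc[ngm, "z_secretion"].to_numpy()
               + cfg.sensitivity_effect * lat.loc[ngm, "z_sensitivity"].to_numpy())
    a_t2 = _calibrate_alpha(protect, cfg.rate_ngm_to_t2dm)
    p_t2 = expit(a_t2 - protect) if np.isfinite(a_t2) else np.zeros(ngm.sum())
    a_pre = _calibrate_alpha(protect, cfg.rate_ngm_to_prediabetes,
                             damp=1.0 - p_t2)
    p_pre = expit(a_pre - protect) if np.isfinite(a_pre) else np.zeros(ngm.sum())
    u1 = rng.random(int(ngm.sum()))
    u2 = rng.random(int(ngm.sum()))
    to_t2 = u1 < p_t2
    to_pre = ~to_t2 & (u2 < p_pre)
    out = np.where(to_t2, T2DM, np.where(to_pre, PREDIABETES, NGM))
    followup.update(zip(ids[ngm], out))

    pre = cls == PREDIABETES
    protect_p = (cfg.secretion_effect * lat.loc[pre, "z_secretion"].to_numpy()
                 + cfg.sensitivity_effect * lat.loc[pre, "z_sensitivity"].to_numpy())
    a3 = _calibrate_alpha(protect_p, cfg.rate_prediabetes_to_t2dm)
    p3 = expit(a3 - protect_p) if np.isfinite(a3) else np.zeros(pre.sum())
    out_p = np.where(rng.random(int(pre.sum())) < p3, T2DM, PREDIABETES)
    followup.update(zip(ids[pre], out_p))

    followup.update({i: T2DM for i in ids[cls == T2DM]})

    if cfg.dropout_rate > 0:
        keep = rng.random(len(ids)) >= cfg.dropout_rate
        kept = set(ids[keep])
        followup = {k: v for k, v in followup.items() if k in kept}
    return followup


def generate_cohort(config: CohortConfig | None = None,
                    seed: int | None = None) -> Cohort:
    """Baseline cohort plus follow-up statuses in one call."""
    cfg = config or CohortConfig()
    cohort = generate_baseline(cfg, seed=seed)
    cohort.followup_status = generate_followup(cohort, cfg, seed=seed)
    return cohort


def worked_fixture() -> Cohort:
    """Deterministic 6-subject cohort (2 per class) with round-number curves.

    Every concentration is chosen so the index formulas are hand-computable;
    subject ``ngm_2`` has G_120 = G_0 on purpose, to exercise the
    degenerate-denominator path of the 120 min incremental indices.
    """
    rows = [
        # sid, sex, bmi, glucose, insulin, cpeptide
        ("ngm_1", "female", 25.0, (5.0, 8.0, 7.0, 6.0),
         (60.0, 300.0, 250.0, 150.0), (600.0, 1800.0, 1700.0, 1500.0)),
        ("ngm_2", "male", 27.0, (5.5, 7.5, 6.5, 5.5),
         (50.0, 400.0, 300.0, 100.0), (500.0, 2000.0, 1800.0, 1200.0)),
        ("pre_1", "female", 29.0, (6.5, 10.0, 9.5, 9.0),
         (80.0, 320.0, 360.0, 400.0), (800.0, 1600.0, 1800.0, 2000.0)),
        ("pre_2", "male", 28.0, (5.8, 9.0, 9.2, 8.0),
         (90.0, 270.0, 300.0, 330.0), (900.0, 1800.0, 2000.0, 2200.0)),
        ("t2dm_1", "male", 31.0, (8.0, 13.0, 14.0, 12.0),
         (120.0, 240.0, 300.0, 360.0), (1200.0, 1900.0, 2200.0, 2600.0)),
        ("t2dm_2", "female", 32.0, (7.5, 12.0, 13.0, 11.5),
         (100.0, 200.0, 260.0, 320.0), (1000.0, 1700.0, 2000.0, 2400.0)),
    ]
    records = [
        OGTTRecord(subject_id=sid, sex=sex, bmi=bmi,
                   glucose=dict(zip(OGTT_TIMES, g)),
                   insulin=dict(zip(OGTT_TIMES, i)),
                   cpeptide=dict(zip(OGTT_TIMES, cp)))
        for sid, sex, bmi, g, i, cp in rows
    ]
    data = pd.DataFrame([r.to_series() for r in records])
    status = {"ngm_1": NGM, "ngm_2": NGM,
              "pre_1": PREDIABETES, "pre_2": PREDIABETES,
              "t2dm_1": T2DM, "t2dm_2": T2DM}
    return Cohort(data=data, baseline_status=status)
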