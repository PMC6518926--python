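"""WHO 2006 classification of glucose metabolism status.

Classification uses the fasting (0 min) and 2 h post-load (120 min) plasma
glucose of a 75 g OGTT:

* type 2 diabetes:  fasting >= 7.0 mmol/l  or  2 h >= 11.1 mmol/l
* prediabetes:      fasting in [6.1, 7.0)  or  2 h in [7.8, 11.1)
* NGM:              fasting < 6.1 and 2 h < 7.8

Precedence is T2DM > prediabetes > NGM, so the three rules partition the
positive quadrant: the prediabetes intervals are half-open at the diabetic
thresholds.
"""

from __future__ import annotations

import numpy as np

from .io import Cohort, InvalidInputError

NGM = "NGM"
PREDIABETES = "prediabetes"
T2DM = "T2DM"

STATUSES = (NGM, PREDIABETES, T2DM)

#: worsening order used for monotonicity reasoning
STATUS_ORDER = {NGM: 0, PREDIABETES: 1, T2DM: 2}

FPG_T2DM = 7.0    # mmol/l
G2H_T2DM = 11.1
FPG_PREDIABETES = 6.1
G2H_PREDIABETES = 7.8


def classify_who2006(fpg: float, g2h: float) -> str:
    """Classify one (fasting, 2 h) glucose pair, both in mmol/l."""
    if not (np.isfinite(fpg) and np.isfinite(g2h) and fpg > 0 and g2h > 0):
        raise InvalidInputError(
            f"glucose values must be positive and finite, got ({fpg}, {g2h})"
        )
    if fpg >= FPG_T2DM or g2h >= G2H_T2DM:
        return T2DM
    if fpg >= FPG_PREDIABETES or g2h >= G2H_PREDIABETES:
        return PREDIABETES
    return NGM


def classify_pairs(fpg, g2h) -> np.ndarray:
    """Vectorised :func:`classify_who2006` for equal-length arrays."""
    fpg = np.asarray(fpg, dtype=float)
    g2h = np.asarray(g2h, dtype=float)
    if np.any(~np.isfinite(fpg)) or np.any(~np.isfinite(g2h)) \
            or np.any(fpg <= 0) or np.any(g2h <= 0):
        raise InvalidInputError("glucose values must be positive and finite")
    out = np.full(fpg.shape, NGM, dtype=object)
    out[(fpg >= FPG_PREDIABETES) | (g2h >= G2H_PREDIABETES)] = PREDIABETES
    out[(fpg >= FPG_T2DM) | (g2h >= G2H_T2DM)] = T2DM
    return out


def classify_cohort(cohort: Cohort) -> tuple[dict[str, str], list[str]]:
    """Classify every record from its (G_0, G_120) pair.

    Returns the subject_id -> status map and the list of subject_ids that
    could not be classified because either glucose value is missing or
    non-positive.
    """
    statuses: dict[str, str] = {}
    unclassifiable: list[str] = []
    df = cohort.data
    for sid, g0, g120 in zip(df["subject_id"], df["g0"], df["g120"]):
        try:
            statuses[str(sid)] = classify_who2006(float(g0), float(g120))
        except (InvalidInputError, TypeError, ValueError):
            unclassifiable.append(str(sid))
    return statuses, unclassifiable
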