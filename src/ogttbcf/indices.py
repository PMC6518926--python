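"""OGTT-based beta-cell-function indices, the Matsuda index and disposition indices.

Twenty formula-defined indices are implemented, grouped by the phase of the
insulin secretory response they probe:

* fasting (3): HOMA-B1, I_0/G_0, CP_0/G_0
* early phase, first 30 min (9): I_30/I_0, CP_30/CP_0, insulinogenic and
  C-peptidogenic indices, the modified insulinogenic index, CIR_30, the
  Stumvoll first-phase estimate and the two BIGTT-AIR regression estimates
* late phase (6): Stumvoll second phase, 120 min ratio and incremental
  indices, CIR_120
* overall (2): trapezoidal AUC ratios of insulin:glucose and
  C-peptide:glucose over the full 0-120 min curve

Unless noted otherwise the formulas take insulin and C-peptide in pmol/l and
glucose in mmol/l; HOMA-B1 converts insulin to uU/ml and the Matsuda index
uses mg/dl and uU/ml, following each formula's original unit convention.
HOMA-B2 requires the HOMA2 computer model, which is not an explicit formula;
the catalog reserves its name and reports it as not available.

Higher values indicate better beta-cell function for every index except the
two fasting ratios I_0/G_0 and CP_0/G_0, whose orientation is inverted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .io import Cohort, InvalidInputError, OGTTRecord, UnitConventions

#: |denominator| below this is treated as degenerate (division blow-up)
DENOMINATOR_EPS = 1e-9

#: BIGTT sex coding (the published regression's dummy variable)
FEMALE_CODE = 1.0
MALE_CODE = 0.0

INCOMPLETE = "incomplete_inputs"
DEGENERATE = "degenerate_denominator"

Cols = Mapping[str, np.ndarray]


def trapezoid_auc(x0, x30, x60, x120):
    """Trapezoidal area over 0-120 min with nodes at 0/30/60/120 min.

    AUC = 15*(x0+x30) + 15*(x30+x60) + 30*(x60+x120), in (unit of x)*min.
    """
    return 15.0 * (x0 + x30) + 15.0 * (x30 + x60) + 30.0 * (x60 + x120)


@dataclass(frozen=True)
class IndexCatalogEntry:
    """One beta-cell-function index definition."""

    name: str
    label: str                     # human-readable, journal-style
    phase: str                     # fasting | early | late | overall
    formula: str                   # display string
    required: tuple[str, ...]      # canonical column names
    orientation: int = +1          # +1: higher = better BCF; -1: inverted
    display_scale: float = 1.0     # presentation multiplier, e.g. 1e-2
    available: bool = True
    _fn: Callable[[Cols, UnitConventions], np.ndarray] | None = field(
        default=None, repr=False, compare=False)
    _den: Callable[[Cols], np.ndarray] | None = field(
        default=None, repr=False, compare=False)

    def evaluate(self, cols: Cols, conv: UnitConventions) -> np.ndarray:
        assert self._fn is not None
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            return np.asarray(self._fn(cols, conv), dtype=float)

    def degenerate_mask(self, cols: Cols) -> np.ndarray:
        n = len(next(iter(cols.values())))
        if self._den is None:
            return np.zeros(n, dtype=bool)
        with np.errstate(invalid="ignore"):
            den = np.asarray(self._den(cols), dtype=float)
        return np.isfinite(den) & (np.abs(den) < DENOMINATOR_EPS)


def _sex_code(cols: Cols) -> np.ndarray:
    return np.asarray(cols["sex_code"], dtype=float)


def _bigtt(intercept, ci0, cim, cimt, cg0, cgm, cg120, csex, cbmi, tm):
    """BIGTT-AIR log-linear regression with mid sample at tm (30 or 60) min."""
    def fn(c: Cols, conv: UnitConventions) -> np.ndarray:
        expo = (intercept
                + ci0 * c["i0"] + cim * c[f"i{tm}"] - cimt * c["i120"]
                - cg0 * c["g0"] - cgm * c[f"g{tm}"] + cg120 * c["g120"]
                + csex * _sex_code(c) + cbmi * c["bmi"])
        return np.exp(expo)
    return fn


def _build_catalog() -> tuple[IndexCatalogEntry, ...]:
    E = IndexCatalogEntry
    entries = [
        # --- fasting -------------------------------------------------------
        E("homa_b1", "HOMA-B1 (%)", "fasting", "(20 * I0[uU/ml]) / (G0 - 3.5)",
          ("i0", "g0"),
          _fn=lambda c, v: (20.0 * v.insulin_uU_per_ml(c["i0"])) / (c["g0"] - 3.5),
          _den=lambda c: c["g0"] - 3.5),
        E("igr_0", "I0/G0 ratio", "fasting", "I0 / G0",
          ("i0", "g0"), orientation=-1,
          _fn=lambda c, v: c["i0"] / c["g0"], _den=lambda c: c["g0"]),
        E("cgr_0", "CP0/G0 ratio", "fasting", "CP0 / G0",
          ("cp0", "g0"), orientation=-1,
          _fn=lambda c, v: c["cp0"] / c["g0"], _den=lambda c: c["g0"]),
        # --- early phase ---------------------------------------------------
        E("ir_30", "I30/I0 ratio", "early", "I30 / I0",
          ("i30", "i0"),
          _fn=lambda c, v: c["i30"] / c["i0"], _den=lambda c: c["i0"]),
        E("cpr_30", "CP30/CP0 ratio", "early", "CP30 / CP0",
          ("cp30", "cp0"),
          _fn=lambda c, v: c["cp30"] / c["cp0"], _den=lambda c: c["cp0"]),
        E("igi_30", "Insulinogenic index t30", "early", "(I30 - I0) / (G30 - G0)",
          ("i30", "i0", "g30", "g0"),
          _fn=lambda c, v: (c["i30"] - c["i0"]) / (c["g30"] - c["g0"]),
          _den=lambda c: c["g30"] - c["g0"]),
        E("igi_mod_30", "Modified insulinogenic index t30", "early",
          "(I30 - I0) / G30", ("i30", "i0", "g30"),
          _fn=lambda c, v: (c["i30"] - c["i0"]) / c["g30"],
          _den=lambda c: c["g30"]),
        E("cgi_30", "C-peptidogenic index t30", "early",
          "(CP30 - CP0) / (G30 - G0)", ("cp30", "cp0", "g30", "g0"),
          _fn=lambda c, v: (c["cp30"] - c["cp0"]) / (c["g30"] - c["g0"]),
          _den=lambda c: c["g30"] - c["g0"]),
        E("cir_30", "CIR30", "early", "I30 / (G30 * (G30 - 3.89))",
          ("i30", "g30"), display_scale=1e-2,
          _fn=lambda c, v: c["i30"] / (c["g30"] * (c["g30"] - 3.89)),
          _den=lambda c: c["g30"] * (c["g30"] - 3.89)),
        E("stumvoll_first", "Stumvoll first phase", "early",
          "1283 + 1.829*I30 - 138.7*G30 + 3.772*I0",
          ("i30", "g30", "i0"), display_scale=1e-2,
          _fn=lambda c, v: 1283.0 + 1.829 * c["i30"] - 138.7 * c["g30"]
          + 3.772 * c["i0"]),
        E("bigtt_air_0_30_120", "BIGTT-AIR 0-30-120", "early",
          "exp(8.20 + 0.00178*I0 + 0.00168*I30 - 0.000383*I120 - 0.314*G0 "
          "- 0.109*G30 + 0.0781*G120 + 0.180*sex - 0.032*BMI)",
          ("i0", "i30", "i120", "g0", "g30", "g120", "sex_code", "bmi"),
          display_scale=1e-2,
          _fn=_bigtt(8.20, 0.00178, 0.00168, 0.000383, 0.314, 0.109, 0.0781,
                     0.180, -0.032, 30)),
        E("bigtt_air_0_60_120", "BIGTT-AIR 0-60-120", "early",
          "exp(8.19 + 0.00339*I0 + 0.00152*I60 - 0.000959*I120 - 0.389*G0 "
          "- 0.142*G60 + 0.164*G120 + 0.256*sex + 0.038*BMI)",
          ("i0", "i60", "i120", "g0", "g60", "g120", "sex_code", "bmi"),
          display_scale=1e-2,
          _fn=_bigtt(8.19, 0.00339, 0.00152, 0.000959, 0.389, 0.142, 0.164,
                     0.256, 0.038, 60)),
        # --- late phase ----------------------------------------------------
        E("stumvoll_second", "Stumvoll second phase", "late",
          "287 + 0.4164*I30 - 26.07*G30 + 0.9226*I0", ("i30", "g30", "i0"),
          _fn=lambda c, v: 287.0 + 0.4164 * c["i30"] - 26.07 * c["g30"]
          + 0.9226 * c["i0"]),
        E("ir_120", "I120/I0 ratio", "late", "I120 / I0",
          ("i120", "i0"),
          _fn=lambda c, v: c["i120"] / c["i0"], _den=lambda c: c["i0"]),
        E("cpr_120", "CP120/CP0 ratio", "late", "CP120 / CP0",
          ("cp120", "cp0"),
          _fn=lambda c, v: c["cp120"] / c["cp0"], _den=lambda c: c["cp0"]),
        E("igi_120", "Insulinogenic index t120", "late",
          "(I120 - I0) / (G120 - G0)", ("i120", "i0", "g120", "g0"),
          _fn=lambda c, v: (c["i120"] - c["i0"]) / (c["g120"] - c["g0"]),
          _den=lambda c: c["g120"] - c["g0"]),
        E("cgi_120", "C-peptidogenic index t120", "late",
          "(CP120 - CP0) / (G120 - G0)", ("cp120", "cp0", "g120", "g0"),
          _fn=lambda c, v: (c["cp120"] - c["cp0"]) / (c["g120"] - c["g0"]),
          _den=lambda c: c["g120"] - c["g0"]),
        E("cir_120", "CIR120", "late", "I120 / (G120 * (G120 - 3.89))",
          ("i120", "g120"), display_scale=1e-2,
          _fn=lambda c, v: c["i120"] / (c["g120"] * (c["g120"] - 3.89)),
          _den=lambda c: c["g120"] * (c["g120"] - 3.89)),
        # --- overall -------------------------------------------------------
        E("auc_i_g", "AUC insulin:glucose ratio", "overall",
          "AUC(I) / AUC(G), trapezoid over 0/30/60/120 min",
          ("i0", "i30", "i60", "i120", "g0", "g30", "g60", "g120"),
          _fn=lambda c, v: trapezoid_auc(c["i0"], c["i30"], c["i60"], c["i120"])
          / trapezoid_auc(c["g0"], c["g30"], c["g60"], c["g120"]),
          _den=lambda c: trapezoid_auc(c["g0"], c["g30"], c["g60"], c["g120"])),
        E("auc_cp_g", "AUC C-peptide:glucose ratio", "overall",
          "AUC(CP) / AUC(G), trapezoid over 0/30/60/120 min",
          ("cp0", "cp30", "cp60", "cp120", "g0", "g30", "g60", "g120"),
          _fn=lambda c, v: trapezoid_auc(c["cp0"], c["cp30"], c["cp60"], c["cp120"])
          / trapezoid_auc(c["g0"], c["g30"], c["g60"], c["g120"]),
          _den=lambda c: trapezoid_auc(c["g0"], c["g30"], c["g60"], c["g120"])),
        # --- reserved, not computable from an explicit formula -------------
        E("homa_b2", "HOMA-B2 (%)", "fasting",
          "HOMA2 computer model (no closed form)", (), available=False),
    ]
    return tuple(entries)


CATALOG: tuple[IndexCatalogEntry, ...] = _build_catalog()

#: implemented entries only (excludes the reserved HOMA-B2 slot)
IMPLEMENTED: tuple[IndexCatalogEntry, ...] = tuple(
    e for e in CATALOG if e.available)

_BY_NAME = {e.name: e for e in CATALOG}

EARLY_PHASE = tuple(e.name for e in IMPLEMENTED if e.phase == "early")


def get_entry(name: str) -> IndexCatalogEntry:
    try:
        return _BY_NAME[name]
    except KeyError:
        raise KeyError(f"unknown index {name!r}; known: {sorted(_BY_NAME)}")


def catalog_table() -> pd.DataFrame:
    """Machine-readable catalog (name, phase, formula, orientation, scale)."""
    return pd.DataFrame(
        [{"name": e.name, "label": e.label, "phase": e.phase,
          "formula": e.formula, "orientation": e.orientation,
          "display_scale": e.display_scale, "available": e.available}
         for e in CATALOG]
    )


def _record_cols(record: OGTTRecord,
                 female_code: float, male_code: float) -> dict[str, np.ndarray]:
    cols: dict[str, np.ndarray] = {}
    for name, prefix in (("glucose", "g"), ("insulin", "i"), ("cpeptide", "cp")):
        curve = getattr(record, name)
        for t in (0, 30, 60, 120):
            cols[f"{prefix}{t}"] = np.array([curve.get(t, np.nan)], dtype=float)
    cols["bmi"] = np.array([record.bmi], dtype=float)
    cols["sex_code"] = np.array(
        [female_code if record.sex == "female" else male_code], dtype=float)
    return cols


def compute_index(
    entry: IndexCatalogEntry | str,
    record: OGTTRecord,
    conv: UnitConventions | None = None,
    female_code: float = FEMALE_CODE,
    male_code: float = MALE_CODE,
) -> tuple[float | None, str | None]:
    """Evaluate one index for one record.

    Returns ``(value, None)`` on success or ``(None, reason)`` where reason is
    ``"incomplete_inputs"`` or ``"degenerate_denominator"``.  Missing inputs
    never raise for a single record.
    """
    if isinstance(entry, str):
        entry = get_entry(entry)
    if not entry.available:
        return None, INCOMPLETE
    conv = conv or UnitConventions()
    cols = _record_cols(record, female_code, male_code)
    if any(not np.isfinite(cols[r][0]) for r in entry.required):
        return None, INCOMPLETE
    if entry.degenerate_mask(cols)[0]:
        return None, DEGENERATE
    value = float(entry.evaluate(cols, conv)[0])
    if not np.isfinite(value):
        return None, DEGENERATE
    return value, None


def compute_auc_ratio(numerator: Mapping[int, float],
                      denominator: Mapping[int, float]) -> float:
    """Trapezoidal AUC ratio of an analyte curve over the glucose curve."""
    times = (0, 30, 60, 120)
    if any(t not in numerator or t not in denominator for t in times):
        raise InvalidInputError("all four time points required for AUC ratio")
    num = trapezoid_auc(*(float(numerator[t]) for t in times))
    den = trapezoid_auc(*(float(denominator[t]) for t in times))
    if abs(den) < DENOMINATOR_EPS:
        raise InvalidInputError("degenerate glucose AUC")
    return num / den


def matsuda_index(record: OGTTRecord | Mapping[str, float],
                  conv: UnitConventions | None = None) -> float:
    """Whole-body insulin-sensitivity index of Matsuda and DeFronzo.

    10000 / sqrt(G0 * I0 * meanG * meanI) with glucose in mg/dl and insulin
    in uU/ml; meanG and meanI are unweighted means of the four sampled values.
    """
    conv = conv or UnitConventions()
    if isinstance(record, OGTTRecord):
        g = [record.glucose.get(t, np.nan) for t in (0, 30, 60, 120)]
        i = [record.insulin.get(t, np.nan) for t in (0, 30, 60, 120)]
    else:
        g = [record[f"g{t}"] for t in (0, 30, 60, 120)]
        i = [record[f"i{t}"] for t in (0, 30, 60, 120)]
    g = conv.glucose_mgdl(g)
    i = conv.insulin_uU_per_ml(i)
    product = g[0] * i[0] * g.mean() * i.mean()
    if not np.isfinite(product) or product <= 0:
        raise InvalidInputError("Matsuda index requires positive glucose and insulin")
    return 10000.0 / float(np.sqrt(product))


def matsuda_column(df: pd.DataFrame, conv: UnitConventions | None = None) -> pd.Series:
    """Vectorised Matsuda index over a cohort frame (NaN where incomplete)."""
    conv = conv or UnitConventions()
    g = conv.glucose_mgdl(df[["g0", "g30", "g60", "g120"]].to_numpy())
    i = conv.insulin_uU_per_ml(df[["i0", "i30", "i60", "i120"]].to_numpy())
    with np.errstate(invalid="ignore"):
        product = g[:, 0] * i[:, 0] * g.mean(axis=1) * i.mean(axis=1)
        out = np.where(product > 0, 10000.0 / np.sqrt(product), np.nan)
    return pd.Series(out, index=df.index, name="matsuda")


def disposition_index(index_value, matsuda_value):
    """Disposition index: secretion index * insulin-sensitivity index.

    Accepts scalars or arrays; missing (NaN/None) inputs propagate to a
    missing output.
    """
    a = np.asarray(index_value, dtype=float)
    b = np.asarray(matsuda_value, dtype=float)
    out = a * b
    if out.ndim == 0:
        return float(out) if np.isfinite(out) else None
    return out


@dataclass
class IndexMatrix:
    """Per-subject index values with missingness reasons.

    ``values`` is a subjects x indices frame (NaN = missing); ``missing_reason``
    has the same shape with ``None`` / ``"incomplete_inputs"`` /
    ``"degenerate_denominator"`` entries.
    """

    values: pd.DataFrame
    missing_reason: pd.DataFrame

    def missing_counts(self) -> pd.Series:
        return self.values.isna().sum()


def compute_index_matrix(
    cohort: Cohort,
    catalog: tuple[IndexCatalogEntry, ...] = IMPLEMENTED,
    conv: UnitConventions | None = None,
    female_code: float = FEMALE_CODE,
    male_code: float = MALE_CODE,
) -> IndexMatrix:
    """Evaluate every catalog index for every subject, vectorised."""
    conv = conv or UnitConventions()
    df = cohort.data
    cols: dict[str, np.ndarray] = {
        c: df[c].to_numpy(dtype=float)
        for c in df.columns if c not in ("subject_id", "sex")
    }
    cols["sex_code"] = np.where(
        df["sex"].to_numpy() == "female", female_code, male_code)

    values: dict[str, np.ndarray] = {}
    reasons: dict[str, np.ndarray] = {}
    n = len(df)
    for entry in catalog:
        if not entry.available:
            continue
        incomplete = np.zeros(n, dtype=bool)
        for r in entry.required:
            incomplete |= ~np.isfinite(cols[r])
        degenerate = entry.degenerate_mask(cols) & ~incomplete
        vals = entry.evaluate(cols, conv)
        blowup = ~np.isfinite(vals) & ~incomplete & ~degenerate
        vals = np.where(incomplete | degenerate | blowup, np.nan, vals)
        reason = np.full(n, None, dtype=object)
        reason[incomplete] = INCOMPLETE
        reason[degenerate | blowup] = DEGENERATE
        values[entry.name] = vals
        reasons[entry.name] = reason

    idx = pd.Index(df["subject_id"].astype(str), name="subject_id")
    return IndexMatrix(
        values=pd.DataFrame(values, index=idx),
        missing_reason=pd.DataFrame(reasons, index=idx),
    )
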