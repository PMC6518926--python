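"""Domain types, unit conversions and tabular I/O for OGTT cohort data.

The canonical in-memory container is a :class:`Cohort`, a thin wrapper around a
pandas DataFrame with one row per subject and columns

    subject_id, sex, bmi, g0, g30, g60, g120, i0, i30, i60, i120,
    cp0, cp30, cp60, cp120

holding plasma glucose in mmol/l and insulin / C-peptide in pmol/l at the four
75 g-OGTT sampling times (0, 30, 60, 120 min).  Baseline and follow-up glucose
metabolism statuses, when known, travel with the cohort as per-subject maps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

OGTT_TIMES: tuple[int, ...] = (0, 30, 60, 120)

#: analyte -> column prefix
_PREFIX = {"glucose": "g", "insulin": "i", "cpeptide": "cp"}

#: canonical numeric concentration columns, in schema order
CONCENTRATION_COLUMNS: tuple[str, ...] = tuple(
    f"{p}{t}" for p in ("g", "i", "cp") for t in OGTT_TIMES
)

REQUIRED_COLUMNS: tuple[str, ...] = ("subject_id", "sex", "bmi") + CONCENTRATION_COLUMNS

SEX_CODES = {
    "f": "female", "female": "female", "1": "female",
    "m": "male", "male": "male", "0": "male",
}


class InvalidInputError(ValueError):
    """Raised when a scalar operation receives out-of-contract input."""


class SchemaError(ValueError):
    """Raised when an input table is missing required columns."""


@dataclass(frozen=True)
class UnitConventions:
    """Unit-conversion constants used throughout the index formulas.

    insulin_molar_mass and cpeptide_molar_mass convert assay mass
    concentrations (pg/ml) to molar (pmol/l).  glucose_mmol_to_mgdl and
    insulin_pmol_per_uU convert to the conventional units (mg/dl, uU/ml)
    assumed by the HOMA-B and Matsuda formulas.
    """

    insulin_molar_mass: float = 5808.0   # g/mol
    cpeptide_molar_mass: float = 3010.0  # g/mol
    glucose_mmol_to_mgdl: float = 18.016
    insulin_pmol_per_uU: float = 6.945

    def __post_init__(self) -> None:
        for name in ("insulin_molar_mass", "cpeptide_molar_mass",
                     "glucose_mmol_to_mgdl", "insulin_pmol_per_uU"):
            if not getattr(self, name) > 0:
                raise InvalidInputError(f"{name} must be strictly positive")

    def insulin_uU_per_ml(self, pmol_l):
        """Insulin pmol/l -> uU/ml."""
        return np.asarray(pmol_l, dtype=float) / self.insulin_pmol_per_uU

    def glucose_mgdl(self, mmol_l):
        """Glucose mmol/l -> mg/dl."""
        return np.asarray(mmol_l, dtype=float) * self.glucose_mmol_to_mgdl


def convert_mass_to_molar(value, molar_mass: float):
    """Convert a mass concentration in pg/ml to pmol/l.

    pg/ml * 1000 / (g/mol) = pmol/l.  Accepts scalars or arrays; values must
    be non-negative and the molar mass strictly positive.
    """
    arr = np.asarray(value, dtype=float)
    if not molar_mass > 0:
        raise InvalidInputError("molar_mass must be strictly positive")
    if np.any(arr < 0) or not np.all(np.isfinite(arr)):
        raise InvalidInputError("mass concentration must be finite and >= 0")
    out = arr * 1000.0 / molar_mass
    return float(out) if np.isscalar(value) else out


@dataclass(frozen=True)
class OGTTRecord:
    """One subject's four-point OGTT curves plus sex and BMI.

    Concentration maps are keyed by sampling time in minutes; glucose in
    mmol/l, insulin and C-peptide in pmol/l.  A map may be missing time
    points, in which case the record is incomplete for indices that need
    them.
    """

    subject_id: str
    sex: str                      # "female" | "male"
    bmi: float                    # kg/m^2
    glucose: Mapping[int, float] = field(default_factory=dict)
    insulin: Mapping[int, float] = field(default_factory=dict)
    cpeptide: Mapping[int, float] = field(default_factory=dict)

    def is_complete(self) -> bool:
        return all(
            t in m and np.isfinite(m[t]) and m[t] > 0
            for m in (self.glucose, self.insulin, self.cpeptide)
            for t in OGTT_TIMES
        )

    @classmethod
    def from_series(cls, row: pd.Series) -> "OGTTRecord":
        def curve(prefix: str) -> dict[int, float]:
            out = {}
            for t in OGTT_TIMES:
                v = row.get(f"{prefix}{t}")
                if v is not None and np.isfinite(v):
                    out[t] = float(v)
            return out

        return cls(
            subject_id=str(row["subject_id"]),
            sex=str(row["sex"]),
            bmi=float(row["bmi"]),
            glucose=curve("g"),
            insulin=curve("i"),
            cpeptide=curve("cp"),
        )

    def to_series(self) -> pd.Series:
        data: dict[str, object] = {
            "subject_id": self.subject_id, "sex": self.sex, "bmi": self.bmi,
        }
        for name, prefix in _PREFIX.items():
            curve = getattr(self, name)
            for t in OGTT_TIMES:
                data[f"{prefix}{t}"] = curve.get(t, np.nan)
        return pd.Series(data)


@dataclass
class Cohort:
    """An ordered collection of OGTT records with optional status maps."""

    data: pd.DataFrame
    baseline_status: dict[str, str] = field(default_factory=dict)
    followup_status: dict[str, str] = field(default_factory=dict)
    #: per-subject latent scalars retained by the synthetic generator
    latent: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        ids = self.data["subject_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValueError(f"duplicate subject_id {dup!r}")
        unknown = set(self.followup_status) - set(ids.astype(str))
        if unknown:
            raise ValueError(
                f"followup_status keys not in cohort: {sorted(unknown)[:5]}"
            )

    def __len__(self) -> int:
        return len(self.data)

    def records(self) -> list[OGTTRecord]:
        return [OGTTRecord.from_series(row) for _, row in self.data.iterrows()]

    def subset(self, subject_ids: Sequence[str]) -> "Cohort":
        keep = self.data["subject_id"].isin(set(subject_ids))
        df = self.data.loc[keep].reset_index(drop=True)
        ids = set(df["subject_id"].astype(str))
        return Cohort(
            data=df,
            baseline_status={k: v for k, v in self.baseline_status.items() if k in ids},
            followup_status={k: v for k, v in self.followup_status.items() if k in ids},
            latent=None if self.latent is None
            else self.latent.loc[keep.values].reset_index(drop=True),
        )


def _normalise_sex(value) -> str | None:
    key = str(value).strip().lower()
    # "1.0" from numeric columns
    if key.endswith(".0"):
        key = key[:-2]
    return SEX_CODES.get(key)


@dataclass(frozen=True)
class ReadReport:
    n_read: int
    n_kept: int
    n_excluded: int
    exclusions: tuple[tuple[str, str], ...]  # (subject_id, reason)
    #: kept records with missing time points; they drop out per index only
    incomplete: tuple[str, ...] = ()


def read_cohort(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    units: str = "pmol/l",
    conventions: UnitConventions | None = None,
) -> tuple[Cohort, ReadReport]:
    """Read a cohort from a delimited text file.

    Parameters
    ----------
    path:
        CSV file with a header row.
    schema:
        Optional mapping from canonical column names (``subject_id``, ``sex``,
        ``bmi``, ``g0`` ... ``cp120``, optionally ``baseline_status`` /
        ``followup_status``) to the file's column names.  Identity by default.
    units:
        ``"pmol/l"`` (default) or ``"pg/ml"``; in the latter case insulin and
        C-peptide columns are converted to pmol/l on read.
    conventions:
        Molar masses used for the pg/ml conversion.

    Returns the validated :class:`Cohort` and a :class:`ReadReport` with
    (read, kept, excluded) counts and per-record exclusion reasons.  Rows
    failing validation are excluded, never repaired.
    """
    conv = conventions or UnitConventions()
    try:
        raw = pd.read_csv(path, na_values=["NA"], keep_default_na=True)
    except OSError as exc:
        raise IOError(f"cannot read {path}: {exc}") from exc

    rename = {v: k for k, v in (schema or {}).items()}
    raw = raw.rename(columns=rename)
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")

    if units == "pg/ml":
        for t in OGTT_TIMES:
            raw[f"i{t}"] = convert_mass_to_molar(
                raw[f"i{t}"].to_numpy(), conv.insulin_molar_mass)
            raw[f"cp{t}"] = convert_mass_to_molar(
                raw[f"cp{t}"].to_numpy(), conv.cpeptide_molar_mass)
    elif units != "pmol/l":
        raise InvalidInputError(f"unknown units {units!r}")

    exclusions: list[tuple[str, str]] = []
    kept_rows: list[int] = []
    for idx, row in raw.iterrows():
        sid = str(row["subject_id"])
        reason = _validate_row(row)
        if reason is None:
            kept_rows.append(idx)
        else:
            exclusions.append((sid, reason))
            logger.warning("excluding subject %s: %s", sid, reason)

    kept = raw.loc[kept_rows].reset_index(drop=True)
    kept["sex"] = [_normalise_sex(v) for v in kept["sex"]]
    kept["subject_id"] = kept["subject_id"].astype(str)

    def status_map(col: str) -> dict[str, str]:
        if col not in kept.columns:
            return {}
        ok = kept[col].notna()
        return dict(zip(kept.loc[ok, "subject_id"], kept.loc[ok, col].astype(str)))

    cohort = Cohort(
        data=kept[list(REQUIRED_COLUMNS)].copy(),
        baseline_status=status_map("baseline_status"),
        followup_status=status_map("followup_status"),
    )
    has_gap = kept[list(CONCENTRATION_COLUMNS)].isna().any(axis=1)
    incomplete = tuple(kept.loc[has_gap, "subject_id"])
    if incomplete:
        logger.warning("%d records have missing time points (complete-case "
                       "per index): %s", len(incomplete), incomplete[:5])
    report = ReadReport(
        n_read=len(raw), n_kept=len(kept),
        n_excluded=len(exclusions), exclusions=tuple(exclusions),
        incomplete=incomplete,
    )
    return cohort, report


def _validate_row(row: pd.Series) -> str | None:
    """Return an exclusion reason, or None if the row is valid.

    Missing concentrations are tolerated (complete-case handling happens per
    index); non-positive or non-finite observed values, bad BMI and unknown
    sex codes are not.
    """
    if _normalise_sex(row["sex"]) is None:
        return f"unrecognised sex code {row['sex']!r}"
    bmi = row["bmi"]
    if not (np.isfinite(bmi) and 10 < bmi < 80):
        return f"BMI {bmi!r} outside (10, 80)"
    for col in CONCENTRATION_COLUMNS:
        v = row[col]
        if pd.isna(v):
            continue  # incomplete, handled per index
        if not np.isfinite(v) or v <= 0:
            return f"non-positive or non-finite {col}={v!r}"
    return None


def write_table(rows: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as CSV with full floating precision.

    Missing values serialise as the literal "NA"; repeated writes of the same
    frame are byte-identical.  An empty frame is a contract violation.
    """
    if len(rows) == 0:
        raise ValueError("refusing to write an empty table")
    rows.to_csv(path, index=False, na_rep="NA", float_format="%.17g")


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort (with any status columns) in the schema read_cohort reads."""
    df = cohort.data.copy()
    if cohort.baseline_status:
        df["baseline_status"] = df["subject_id"].map(cohort.baseline_status)
    if cohort.followup_status:
        df["followup_status"] = df["subject_id"].map(cohort.followup_status)
    write_table(df, path)
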