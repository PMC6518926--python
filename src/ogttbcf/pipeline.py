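"""End-to-end analysis: index values by glycemic status, ROC discrimination
of incident outcomes, and the disposition-index comparison against the
Matsuda index alone.

The three stages mirror the classical reporting layout of an index-comparison
study: a cross-sectional table of per-class medians with nonparametric tests,
a longitudinal table of ROC AUCs with DeLong confidence intervals and
consecutive-pair tests for each incident outcome, and a disposition-index
table for the indices passing the AUC gate.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .discrimination import (DegenerateInputError, ROCResult,
                             delong_paired_test, di_gate, kruskal_wallis,
                             mann_whitney, rank_indices, roc_auc)
from .indices import (IMPLEMENTED, CATALOG, IndexMatrix, compute_index_matrix,
                      get_entry, matsuda_column)
from .io import Cohort, UnitConventions, read_cohort, write_cohort, write_table
from .simulate import CohortConfig, generate_cohort
from .status import NGM, PREDIABETES, T2DM, classify_cohort

logger = logging.getLogger(__name__)

PREVALENT_OUTCOMES = ("prevalent_prediabetes", "prevalent_t2dm")
INCIDENT_OUTCOMES = ("incident_t2dm_in_non_t2dm", "incident_t2dm_in_ngm",
                     "incident_prediabetes_in_ngm")


@dataclass(frozen=True)
class AnalysisConfig:
    """Pipeline configuration (one input source: simulate or a cohort CSV)."""

    simulate: bool = True
    input_path: str | None = None
    input_units: str = "pmol/l"
    cohort: CohortConfig = field(default_factory=CohortConfig)
    di_gate_threshold: float = 0.70
    outdir: str = "ogttbcf_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.simulate == (self.input_path is not None):
            raise ValueError("exactly one of simulate / input_path required")
        if not 0.5 < self.di_gate_threshold < 1.0:
            raise ValueError("di_gate_threshold must lie in (0.5, 1)")


def outcome_labels(cohort: Cohort) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-outcome (subject_id array, 0/1 label array) case/control strata.

    Prevalent outcomes compare baseline classes (reference NGM for
    prediabetes, non-diabetes for T2DM).  Incident outcomes are restricted to
    subjects with a follow-up status: T2DM incidence among at-baseline
    non-T2DM or NGM, and prediabetes incidence among at-baseline NGM with
    stayed-NGM controls (T2DM progressors are a different outcome).
    """
    ids = cohort.data["subject_id"].astype(str).to_numpy()
    base = np.array([cohort.baseline_status.get(i) for i in ids], dtype=object)
    fup = np.array([cohort.followup_status.get(i) for i in ids], dtype=object)

    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    sel = (base == NGM) | (base == PREDIABETES)
    out["prevalent_prediabetes"] = (ids[sel], (base[sel] == PREDIABETES).astype(int))
    sel = base != None  # noqa: E711  (keep subjects with a known status)
    out["prevalent_t2dm"] = (ids[sel], (base[sel] == T2DM).astype(int))

    has_fup = fup != None  # noqa: E711
    sel = (base != T2DM) & (base != None) & has_fup  # noqa: E711
    out["incident_t2dm_in_non_t2dm"] = (ids[sel], (fup[sel] == T2DM).astype(int))
    sel = (base == NGM) & has_fup
    out["incident_t2dm_in_ngm"] = (ids[sel], (fup[sel] == T2DM).astype(int))
    sel = (base == NGM) & ((fup == PREDIABETES) | (fup == NGM))
    out["incident_prediabetes_in_ngm"] = (
        ids[sel], (fup[sel] == PREDIABETES).astype(int))
    return out


def run_cross_sectional(cohort: Cohort, matrix: IndexMatrix) -> pd.DataFrame:
    """Per-index medians (IQR) by baseline class with KW and pairwise MW tests."""
    ids = matrix.values.index.astype(str)
    base = pd.Series([cohort.baseline_status.get(i) for i in ids], index=ids)
    present = [c for c in (NGM, PREDIABETES, T2DM) if (base == c).sum() > 0]
    if len(present) < 2:
        raise ValueError("cross-sectional analysis needs at least two classes")

    rows = []
    pairs = [(PREDIABETES, NGM), (T2DM, NGM), (T2DM, PREDIABETES)]
    for entry in IMPLEMENTED:
        vals = matrix.values[entry.name]
        groups = {c: vals[(base == c).to_numpy()].dropna().to_numpy()
                  for c in (NGM, PREDIABETES, T2DM)}
        usable = {c: g for c, g in groups.items() if len(g) >= 1}
        if len(usable) < len(present):
            logger.warning("skipping %s: a class has no usable values",
                           entry.name)
            continue
        _, kw_p = kruskal_wallis(*usable.values())
        row: dict[str, object] = {"index": entry.name, "phase": entry.phase,
                                  "kruskal_wallis_p": kw_p}
        for c in (NGM, PREDIABETES, T2DM):
            g = groups[c]
            if len(g):
                row[f"median_{c}"] = float(np.median(g))
                row[f"q1_{c}"] = float(np.percentile(g, 25))
                row[f"q3_{c}"] = float(np.percentile(g, 75))
            else:
                row[f"median_{c}"] = row[f"q1_{c}"] = row[f"q3_{c}"] = np.nan
        for a, b in pairs:
            if a in usable and b in usable:
                _, p = mann_whitney(usable[a], usable[b])
                row[f"mw_{a}_vs_{b}_sig"] = bool(p < 0.05)
                row[f"mw_{a}_vs_{b}_p"] = p
            else:
                row[f"mw_{a}_vs_{b}_sig"] = None
                row[f"mw_{a}_vs_{b}_p"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class OutcomeDiscrimination:
    """ROC results for one incident outcome, with the inputs kept for pairing."""

    outcome: str
    table: pd.DataFrame                 # ranked, with AUC(%), CI, pair tests
    results: dict[str, ROCResult]
    scores: dict[str, np.ndarray]       # aligned with labels
    labels: np.ndarray
    subject_ids: np.ndarray


def _discriminate(matrix: IndexMatrix, ids: np.ndarray, labels: np.ndarray,
                  outcome: str) -> OutcomeDiscrimination | None:
    if labels.sum() == 0 or labels.sum() == len(labels):
        logger.warning("outcome %s has a single class; skipped", outcome)
        return None
    sub = matrix.values.reindex(pd.Index(ids))
    results: dict[str, ROCResult] = {}
    scores: dict[str, np.ndarray] = {}
    for entry in IMPLEMENTED:
        s = sub[entry.name].to_numpy(dtype=float)
        try:
            res = roc_auc(s, labels, orientation=-entry.orientation)
        except DegenerateInputError:
            continue
        results[entry.name] = res
        scores[entry.name] = s
    ranked = rank_indices(results, scores, labels)
    ranked.insert(0, "outcome", outcome)
    ranked["auc_pct"] = (100.0 * ranked["auc"]).round(0)
    ranked["ci_low_pct"] = (100.0 * ranked["ci_low"]).round(0)
    ranked["ci_high_pct"] = (100.0 * ranked["ci_high"]).round(0)
    ranked["n_pos"] = [results[k].n_pos for k in ranked["index"]]
    ranked["n_neg"] = [results[k].n_neg for k in ranked["index"]]
    # reserved catalog entries appear as explicit not-available rows
    for entry in CATALOG:
        if not entry.available:
            ranked = pd.concat([ranked, pd.DataFrame([{
                "outcome": outcome, "index": entry.name, "auc": np.nan,
                "rank": "NA"}])], ignore_index=True)
    return OutcomeDiscrimination(outcome=outcome, table=ranked,
                                 results=results, scores=scores,
                                 labels=labels, subject_ids=ids)


def run_longitudinal(cohort: Cohort, matrix: IndexMatrix
                     ) -> dict[str, OutcomeDiscrimination]:
    """Baseline-index discrimination of the three incident outcomes."""
    if not cohort.followup_status:
        raise ValueError("cohort has no follow-up statuses")
    labels = outcome_labels(cohort)
    out: dict[str, OutcomeDiscrimination] = {}
    for outcome in INCIDENT_OUTCOMES:
        ids, y = labels[outcome]
        res = _discriminate(matrix, ids, y, outcome)
        if res is not None:
            logger.info("%s: %d cases / %d controls", outcome, y.sum(),
                        len(y) - y.sum())
            out[outcome] = res
    return out


def run_prevalent(cohort: Cohort, matrix: IndexMatrix
                  ) -> dict[str, OutcomeDiscrimination]:
    """Cross-sectional ROC discrimination of the prevalent outcomes."""
    labels = outcome_labels(cohort)
    out: dict[str, OutcomeDiscrimination] = {}
    for outcome in PREVALENT_OUTCOMES:
        ids, y = labels[outcome]
        res = _discriminate(matrix, ids, y, outcome)
        if res is not None:
            out[outcome] = res
    return out


def run_di_analysis(
    cohort: Cohort,
    matrix: IndexMatrix,
    longitudinal: dict[str, OutcomeDiscrimination],
    conv: UnitConventions | None = None,
    gate_threshold: float = 0.70,
) -> pd.DataFrame:
    """Disposition-index ROC analysis for gate-passing indices.

    The gate admits indices whose AUC reaches the threshold for incident
    prediabetes and/or incident T2DM.  For each incident outcome the table
    reports the DI AUC per gated index, the Matsuda-alone AUC, and the paired
    DeLong p-value of DI vs Matsuda with a significance flag at p < 0.05.
    """
    conv = conv or UnitConventions()
    gated = sorted(di_gate(
        {k: v.results for k, v in longitudinal.items()}, gate_threshold))
    if not gated:
        logger.warning("no index passed the DI gate (threshold %.2f); "
                       "reporting Matsuda alone", gate_threshold)
    matsuda = matsuda_column(cohort.data, conv)
    matsuda.index = cohort.data["subject_id"].astype(str)

    rows = []
    for outcome, disc in longitudinal.items():
        m = matsuda.reindex(pd.Index(disc.subject_ids)).to_numpy(dtype=float)
        res_m = roc_auc(m, disc.labels, orientation=-1)
        rows.append({"outcome": outcome, "score": "matsuda",
                     "auc": res_m.auc, "ci_low": res_m.ci_low,
                     "ci_high": res_m.ci_high, "p_vs_matsuda": np.nan,
                     "significant_vs_matsuda": None})
        for name in gated:
            entry = get_entry(name)
            di = disc.scores[name] * m
            res_di = roc_auc(di, disc.labels, orientation=-entry.orientation)
            cmpres = delong_paired_test(di, m, disc.labels,
                                        orientation_a=-entry.orientation,
                                        orientation_b=-1)
            rows.append({"outcome": outcome, "score": f"di_{name}",
                         "auc": res_di.auc, "ci_low": res_di.ci_low,
                         "ci_high": res_di.ci_high, "p_vs_matsuda": cmpres.p,
                         "significant_vs_matsuda": bool(cmpres.p < 0.05)})
    return pd.DataFrame(rows)


def run_pipeline(config: AnalysisConfig) -> dict[str, object]:
    """Execute every stage and write result tables under ``config.outdir``.

    Returns the in-memory results keyed by stage.  Given the same config and
    seed the written tables are byte-identical across runs.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    conv = UnitConventions()

    if config.simulate:
        cfg = dataclasses.replace(config.cohort, seed=config.seed)
        cohort = generate_cohort(cfg, seed=config.seed)
        write_cohort(cohort, outdir / "cohort.csv")
        logger.info("simulated cohort of %d subjects", len(cohort))
    else:
        cohort, report = read_cohort(config.input_path, units=config.input_units)
        logger.info("read %d records, kept %d, excluded %d",
                    report.n_read, report.n_kept, report.n_excluded)
        if not cohort.baseline_status:
            statuses, bad = classify_cohort(cohort)
            cohort.baseline_status = statuses
            if bad:
                logger.warning("%d records unclassifiable at baseline", len(bad))

    matrix = compute_index_matrix(cohort, conv=conv)
    write_table(matrix.values.reset_index(), outdir / "index_matrix.csv")

    cross = run_cross_sectional(cohort, matrix)
    write_table(cross, outdir / "cross_sectional.csv")

    results: dict[str, object] = {"cohort": cohort, "matrix": matrix,
                                  "cross_sectional": cross}
    if cohort.followup_status:
        longitudinal = run_longitudinal(cohort, matrix)
        longi_table = pd.concat([d.table for d in longitudinal.values()],
                                ignore_index=True)
        write_table(longi_table, outdir / "longitudinal.csv")
        di_table = run_di_analysis(cohort, matrix, longitudinal, conv,
                                   config.di_gate_threshold)
        write_table(di_table, outdir / "di_analysis.csv")
        results["longitudinal"] = longitudinal
        results["di_analysis"] = di_table

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "simulate": config.simulate,
        "input_path": config.input_path,
        "di_gate_threshold": config.di_gate_threshold,
        "n_subjects": len(cohort),
        "n_followed": len(cohort.followup_status),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    results["manifest"] = manifest
    return results
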