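"""ROC-AUC discrimination analysis with DeLong inference.

The AUC is the mid-rank (tie-corrected) Mann-Whitney probability that a
randomly chosen case scores above a randomly chosen control.  Variances and
covariances of correlated AUCs come from the nonparametric placement-value
estimator of DeLong, DeLong & Clarke-Pearson: with cases i = 1..m and
controls j = 1..n,

    V10_i = (1/n) sum_j psi(s_i, s_j),   V01_j = (1/m) sum_i psi(s_i, s_j),
    psi = 1 if case > control, 1/2 on ties, else 0,

    var(AUC) = S10/m + S01/n

with S10, S01 the sample (co)variances of the placement values.  Paired AUC
differences on the same subjects use the placement covariance, yielding the
standard-normal z test used to compare consecutively ranked indices and the
disposition indices against the Matsuda index alone.

Nonparametric group comparisons (Kruskal-Wallis, Mann-Whitney U) are thin
wrappers over scipy.stats with the sample-size-dependent exact/asymptotic
policy documented on each function.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


class DegenerateInputError(ValueError):
    """Labels contain a single class, or inputs are otherwise unusable."""


@dataclass(frozen=True)
class ROCResult:
    """AUC with DeLong variance and 95% Wald CI (clipped to [0, 1])."""

    auc: float
    variance: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int
    orientation_applied: int = +1

    @property
    def auc_pct(self) -> float:
        return 100.0 * self.auc


@dataclass(frozen=True)
class PairedComparison:
    """DeLong paired comparison of two AUCs measured on the same subjects."""

    auc_a: float
    auc_b: float
    z: float
    p: float
    var_diff: float
    n: int


def _placements(scores: np.ndarray, labels: np.ndarray
                ) -> tuple[float, np.ndarray, np.ndarray]:
    """Mid-rank AUC and DeLong placement values (V10 for cases, V01 controls)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    all_ranks = stats.rankdata(np.concatenate([pos, neg]))
    pos_ranks = stats.rankdata(pos)
    neg_ranks = stats.rankdata(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    auc = float(v10.mean())
    return auc, v10, v01


def _clean(scores, labels) -> tuple[np.ndarray, np.ndarray, int]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    keep = np.isfinite(s)
    n_dropped = int((~keep).sum())
    s, y = s[keep], y[keep].astype(int)
    if not set(np.unique(y)) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if (y == 1).sum() < 1 or (y == 0).sum() < 1:
        raise DegenerateInputError("need at least one case and one control")
    return s, y, n_dropped


def roc_auc(scores, labels, orientation: int = +1) -> ROCResult:
    """Mid-rank AUC with DeLong variance and a 95% Wald CI.

    ``orientation=-1`` negates the scores first (for markers where a *lower*
    value indicates the outcome); no automatic flipping toward AUC >= 0.5 is
    performed.  Missing scores are dropped (pairwise-complete).
    """
    if orientation not in (+1, -1):
        raise ValueError("orientation must be +1 or -1")
    s, y, _ = _clean(scores, labels)
    auc, v10, v01 = _placements(orientation * s, y)
    m, n = len(v10), len(v01)
    s10 = float(np.var(v10, ddof=1)) if m > 1 else 0.0
    s01 = float(np.var(v01, ddof=1)) if n > 1 else 0.0
    var = s10 / m + s01 / n
    half = 1.959963984540054 * np.sqrt(max(var, 0.0))
    return ROCResult(
        auc=auc, variance=var,
        ci_low=float(max(0.0, auc - half)), ci_high=float(min(1.0, auc + half)),
        n_pos=m, n_neg=n, orientation_applied=orientation,
    )


def delong_paired_test(scores_a, scores_b, labels,
                       orientation_a: int = +1,
                       orientation_b: int = +1) -> PairedComparison:
    """DeLong test for the difference of two AUCs on the same subjects.

    Subjects with a missing score in either marker are excluded pairwise.
    Returns a two-sided normal p-value; a zero-variance difference with equal
    AUCs yields z = 0, p = 1.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels)
    if not (a.shape == b.shape == y.shape):
        raise ValueError("scores_a, scores_b and labels must have equal length")
    keep = np.isfinite(a) & np.isfinite(b)
    a, b, y = a[keep], b[keep], y[keep].astype(int)
    if (y == 1).sum() < 1 or (y == 0).sum() < 1:
        raise DegenerateInputError("need at least one case and one control")

    auc_a, v10a, v01a = _placements(orientation_a * a, y)
    auc_b, v10b, v01b = _placements(orientation_b * b, y)
    m, n = len(v10a), len(v01a)

    def cov2(x, z, size):
        if size < 2:
            return np.zeros((2, 2))
        return np.cov(np.vstack([x, z]), ddof=1)

    c10 = cov2(v10a, v10b, m)
    c01 = cov2(v01a, v01b, n)
    var_diff = ((c10[0, 0] + c10[1, 1] - 2 * c10[0, 1]) / m
                + (c01[0, 0] + c01[1, 1] - 2 * c01[0, 1]) / n)
    diff = auc_a - auc_b
    if var_diff <= 0:
        z = 0.0 if np.isclose(diff, 0.0) else np.sign(diff) * np.inf
    else:
        z = diff / np.sqrt(var_diff)
    p = float(2.0 * stats.norm.sf(abs(z))) if np.isfinite(z) else 0.0
    if z == 0.0:
        p = 1.0
    return PairedComparison(auc_a=auc_a, auc_b=auc_b, z=float(z), p=p,
                            var_diff=float(max(var_diff, 0.0)), n=m + n)


def compare_vs_matsuda(di_scores, matsuda_scores, labels) -> PairedComparison:
    """Paired DeLong comparison of a disposition index against Matsuda alone."""
    return delong_paired_test(di_scores, matsuda_scores, labels)


def rank_indices(
    results: Mapping[str, ROCResult],
    scores: Mapping[str, Sequence[float]] | None = None,
    labels: Sequence[int] | None = None,
    precision_pct: int = 0,
) -> pd.DataFrame:
    """Rank indices by AUC (descending) with tied-rank ranges and pair tests.

    Ties are defined at the reporting precision (whole percent by default), so
    indices printing the same AUC share a rank range such as "9-11".  When the
    per-subject ``scores`` and ``labels`` are supplied, each consecutive pair
    of distinct ranks is compared with the paired DeLong test (orientation as
    applied in ``results``).
    """
    if len(results) < 2:
        raise ValueError("need at least two indices to rank")
    order = sorted(results, key=lambda k: results[k].auc, reverse=True)
    rounded = {k: round(100.0 * results[k].auc, precision_pct) for k in order}

    rank_label: dict[str, str] = {}
    pos = 0
    groups: list[list[str]] = []
    while pos < len(order):
        group = [order[pos]]
        while (pos + len(group) < len(order)
               and rounded[order[pos + len(group)]] == rounded[group[0]]):
            group.append(order[pos + len(group)])
        lo, hi = pos + 1, pos + len(group)
        label = f"{lo}" if lo == hi else f"{lo}-{hi}"
        for k in group:
            rank_label[k] = label
        groups.append(group)
        pos += len(group)

    p_next: dict[str, float] = {}
    if scores is not None and labels is not None:
        y = np.asarray(labels)
        for ka, kb in zip(order[:-1], order[1:]):
            cmpres = delong_paired_test(
                np.asarray(scores[ka], dtype=float),
                np.asarray(scores[kb], dtype=float), y,
                orientation_a=results[ka].orientation_applied,
                orientation_b=results[kb].orientation_applied)
            p_next[ka] = cmpres.p

    rows = []
    for k in order:
        r = results[k]
        rows.append({
            "index": k, "auc": r.auc, "ci_low": r.ci_low, "ci_high": r.ci_high,
            "rank": rank_label[k], "p_vs_next": p_next.get(k, np.nan),
        })
    return pd.DataFrame(rows)


def di_gate(
    auc_tables: Mapping[str, Mapping[str, ROCResult]] | Mapping[str, ROCResult],
    threshold: float = 0.70,
) -> set[str]:
    """Indices whose AUC reaches the gate threshold in at least one outcome.

    Accepts either a single ``{index: ROCResult}`` table or a nested
    ``{outcome: {index: ROCResult}}`` mapping.  The threshold is inclusive
    ("0.70 or above").
    """
    if not auc_tables:
        return set()
    first = next(iter(auc_tables.values()))
    tables = (auc_tables.values() if isinstance(first, Mapping)
              else [auc_tables])
    gated: set[str] = set()
    for table in tables:
        gated |= {name for name, res in table.items() if res.auc >= threshold}
    return gated


def kruskal_wallis(*groups) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected mid-rank) with chi-square p on k-1 df."""
    if len(groups) < 2:
        raise ValueError("Kruskal-Wallis needs at least two groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("all groups must be non-empty")
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def mann_whitney(a, b) -> tuple[float, float]:
    """Mann-Whitney U (tie-corrected) with a two-sided p-value.

    The p-value is exact for groups of at most 8 without ties, and otherwise
    uses the tie-corrected normal approximation.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (max(len(a), len(b)) <= 8 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def check_hyperbolicity(index_values, sensitivity_values
                        ) -> tuple[float, tuple[float, float], str]:
    """Test whether secretion vs sensitivity follows a hyperbola.

    Fits ln(index) = a + slope * ln(sensitivity) by OLS.  A strict hyperbola
    index = c / sensitivity has slope -1, so the verdict is "hyperbolic" iff
    the slope's 95% CI contains -1 and excludes 0.  Non-positive pairs are
    excluded; at least 10 usable pairs are required.
    """
    x = np.asarray(sensitivity_values, dtype=float)
    y = np.asarray(index_values, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    keep = np.isfinite(x) & np.isfinite(y) & (x > 0) & (y > 0)
    n_excluded = int((~keep).sum())
    x, y = x[keep], y[keep]
    if len(x) < 10:
        raise ValueError(
            f"need at least 10 positive pairs, have {len(x)} "
            f"({n_excluded} excluded)")
    fit = stats.linregress(np.log(x), np.log(y))
    tcrit = stats.t.ppf(0.975, len(x) - 2)
    lo = fit.slope - tcrit * fit.stderr
    hi = fit.slope + tcrit * fit.stderr
    tol = 1e-9  # guard for exact fits, where the CI collapses to a point
    hyperbolic = (lo - tol <= -1.0 <= hi + tol) and not (lo <= 0.0 <= hi)
    return float(fit.slope), (float(lo), float(hi)), (
        "hyperbolic" if hyperbolic else "not hyperbolic")
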