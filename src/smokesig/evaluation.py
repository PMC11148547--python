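"""Discrimination and association statistics for signature scores.

AUC in its Mann–Whitney form with DeLong placement-value confidence
intervals, Wilcoxon rank tests (paired and unpaired), and rank-based
dose-response correlation with pack-years.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AucReport",
    "EvaluationError",
    "auc",
    "delong_ci",
    "auc_report",
    "rank_test",
    "dose_correlation",
]


class EvaluationError(ValueError):
    pass


@dataclass
class AucReport:
    """AUC with a DeLong confidence interval for one comparison."""

    auc: float
    ci_low: float
    ci_high: float
    n_case: int
    n_control: int
    comparison: str = ""

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.auc <= self.ci_high):
            raise EvaluationError("CI bounds must bracket the AUC")


def _split(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise EvaluationError("scores and labels must align")
    cases = scores[labels]
    controls = scores[~labels]
    if len(cases) == 0 or len(controls) == 0:
        raise EvaluationError("both classes must be non-empty")
    return cases, controls


def _placements(cases: np.ndarray, controls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong structural components: per-case and per-control placements."""
    diff = cases[:, None] - controls[None, :]
    wins = (diff > 0).astype(float) + 0.5 * (diff == 0)
    return wins.mean(axis=1), 1.0 - wins.mean(axis=0)


def auc(scores, labels) -> float:
    """Probability a random case outscores a random control (ties count half)."""
    cases, controls = _split(scores, labels)
    v10, _ = _placements(cases, controls)
    return float(v10.mean())


def delong_ci(scores, labels, level: float = 0.95) -> tuple[float, float]:
    """Normal-theory CI from DeLong's placement-value variance, clipped to [0,1]."""
    cases, controls = _split(scores, labels)
    if len(cases) < 2 or len(controls) < 2:
        raise EvaluationError("DeLong CI needs >= 2 samples per class")
    v10, v01 = _placements(cases, controls)
    a = float(v10.mean())
    var = v10.var(ddof=1) / len(cases) + v01.var(ddof=1) / len(controls)
    if var <= 0:
        warnings.warn(
            "degenerate DeLong variance (perfect separation); CI collapses",
            stacklevel=2,
        )
        return a, a
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(var)
    return float(np.clip(a - half, 0.0, 1.0)), float(np.clip(a + half, 0.0, 1.0))


def auc_report(scores, labels, level: float = 0.95, comparison: str = "") -> AucReport:
    cases, controls = _split(scores, labels)
    lo, hi = delong_ci(scores, labels, level=level)
    return AucReport(
        auc=auc(scores, labels),
        ci_low=lo,
        ci_high=hi,
        n_case=len(cases),
        n_control=len(controls),
        comparison=comparison,
    )


def rank_test(x, y, paired: bool = False) -> float:
    """Two-sided Wilcoxon p: rank-sum if unpaired, signed-rank if paired.

    Exact enumeration below 10 per group (no ties), normal approximation
    with tie correction otherwise.  Identical paired samples return p = 1
    by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if paired:
        if len(x) != len(y):
            raise EvaluationError("paired test needs equal-length samples")
        d = x - y
        if np.all(d == 0):
            return 1.0
        return float(
            stats.wilcoxon(x, y, alternative="two-sided", method="auto").pvalue
        )
    if len(x) == 0 or len(y) == 0:
        raise EvaluationError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(x) < 10 and len(y) < 10 and not ties) else "asymptotic"
    return float(
        stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
    )


def dose_correlation(
    scores, pack_years, method: str = "spearman"
) -> tuple[float, float]:
    """Correlation of scores with cumulative smoking dose (pack-years).

    Spearman by default (no linearity assumption), Pearson on request.
    Returns (r, two-sided p) over complete pairs.
    """
    s = np.asarray(scores, dtype=float)
    d = np.asarray(pack_years, dtype=float)
    mask = ~np.isnan(s) & ~np.isnan(d)
    s, d = s[mask], d[mask]
    if len(s) < 3:
        raise EvaluationError("need >= 3 complete pairs")
    if np.std(s) == 0 or np.std(d) == 0:
        raise EvaluationError("zero variance in scores or pack-years")
    if method == "spearman":
        r, p = stats.spearmanr(s, d)
    elif method == "pearson":
        r, p = stats.pearsonr(s, d)
    else:
        raise EvaluationError(f"unknown correlation method {method!r}")
    return float(r), float(p)


def evaluate_comparisons(
    table: pd.DataFrame,
    comparisons: list[tuple[str, str]],
    value: str = "corrected",
) -> pd.DataFrame:
    """AUC + rank-test rows for (case_type, control_type) pairs per set.

    ``table`` is a long score table (columns set, type, plus the value
    column).  Output columns: set, comparison, auc, ci_low, ci_high,
    p_wilcoxon, n_case, n_control.
    """
    rows = []
    for set_name, sub in table.groupby("set", sort=True):
        for case_t, control_t in comparisons:
            cases = sub.loc[sub["type"] == case_t, value].dropna()
            controls = sub.loc[sub["type"] == control_t, value].dropna()
            if cases.empty or controls.empty:
                continue
            scores = np.concatenate([cases, controls])
            labels = np.concatenate(
                [np.ones(len(cases), bool), np.zeros(len(controls), bool)]
            )
            rep = auc_report(
                scores, labels, comparison=f"{case_t}_vs_{control_t}"
            )
            rows.append(
                {
                    "set": set_name,
                    "comparison": rep.comparison,
                    "auc": rep.auc,
                    "ci_low": rep.ci_low,
                    "ci_high": rep.ci_high,
                    "p_wilcoxon": rank_test(cases, controls),
                    "n_case": rep.n_case,
                    "n_control": rep.n_control,
                }
            )
    return pd.DataFrame(rows)
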