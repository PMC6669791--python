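"""Cohort evaluation and model-comparison statistics.

Per case and organ the report carries the Dice coefficient, the directed
RMS surface distance (mm) and the symmetric Hausdorff distance (mm).
Cohort summaries report the median (robust to the occasional failed
segmentation) with the mean alongside.  A case is excluded per organ —
with the reason recorded — when either mask is empty, instead of
receiving an arbitrary score.

Models are compared with a paired two-tailed t-test per organ and metric;
with three organs the significance level is Bonferroni-adjusted to
alpha = 0.05 / 3 = 0.0167.  Raw p-values are always reported alongside
the decision.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import StructureSet
from . import metrics as M

__all__ = [
    "MetricsReport",
    "evaluate_cohort",
    "paired_t_test",
    "bonferroni_alpha",
    "compare_reports",
    "TTestResult",
]

REPORT_COLUMNS = ["case", "organ", "dice", "rms_surface_mm", "hausdorff_mm",
                  "excluded", "reason"]


@dataclass(frozen=True)
class MetricsReport:
    """Per-case rows plus per-organ summary statistics."""

    rows: pd.DataFrame      # one row per (case, organ)
    summary: pd.DataFrame   # one row per (organ, statistic)

    def to_csv(self, path) -> None:
        rows = self.rows.assign(kind="case")
        summary = self.summary.assign(kind="summary")
        pd.concat([rows, summary], ignore_index=True).to_csv(path, index=False)

    @staticmethod
    def from_csv(path) -> "MetricsReport":
        df = pd.read_csv(path)
        rows = df[df["kind"] == "case"].drop(columns="kind").reset_index(drop=True)
        summary = df[df["kind"] == "summary"].drop(columns="kind").reset_index(drop=True)
        return MetricsReport(rows=rows, summary=summary)


def evaluate_cohort(
    predictions: Mapping[str, StructureSet],
    ground_truth: Mapping[str, StructureSet],
    organs: Sequence[str] | None = None,
) -> MetricsReport:
    """Score matched prediction/reference structure sets case by case."""
    if set(predictions) != set(ground_truth):
        missing = set(predictions) ^ set(ground_truth)
        raise ValueError(f"unmatched case ids: {sorted(missing)}")
    case_ids = sorted(predictions)
    if organs is None:
        organs = list(ground_truth[case_ids[0]].organs)

    records = []
    for cid in case_ids:
        pred_set, truth_set = predictions[cid], ground_truth[cid]
        for organ in organs:
            pred = pred_set[organ]
            truth = truth_set[organ]
            pred_empty = not np.asarray(pred.values).any()
            truth_empty = not np.asarray(truth.values).any()
            if pred_empty or truth_empty:
                which = "prediction" if pred_empty else "reference"
                if pred_empty and truth_empty:
                    which = "prediction and reference"
                records.append((cid, organ, np.nan, np.nan, np.nan, True,
                                f"empty {which} mask"))
                continue
            dice = M.dice_coefficient(pred.values, truth.values)
            ps = M.surface_points(pred)
            gs = M.surface_points(truth)
            records.append((
                cid, organ, dice,
                M.rms_surface_distance(ps, gs),
                M.hausdorff_distance(ps, gs),
                False, "",
            ))
    rows = pd.DataFrame.from_records(records, columns=REPORT_COLUMNS)

    scored = rows[~rows["excluded"]]
    summaries = []
    for organ in organs:
        sub = scored[scored["organ"] == organ]
        for stat, fn in (("median", np.median), ("mean", np.mean)):
            vals = [
                fn(sub[c].to_numpy()) if len(sub) else np.nan
                for c in ("dice", "rms_surface_mm", "hausdorff_mm")
            ]
            summaries.append((f"{stat}", organ, *vals, False,
                              f"n={len(sub)} scored"))
    summary = pd.DataFrame.from_records(
        summaries, columns=["case", "organ", "dice", "rms_surface_mm",
                            "hausdorff_mm", "excluded", "reason"]
    )
    return MetricsReport(rows=rows, summary=summary)


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    n: int
    degenerate: bool = False


def paired_t_test(a: Sequence[float], b: Sequence[float]) -> TTestResult:
    """Classical paired two-tailed t-test on the differences a - b.

    All-zero-variance differences make the statistic undefined; the result
    is then flagged degenerate with NaN t and p.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("paired samples must be equal-length 1-D with n >= 2")
    diff = a - b
    if np.allclose(diff.std(ddof=1), 0.0):
        return TTestResult(t=float("nan"), p=float("nan"), n=len(a), degenerate=True)
    res = stats.ttest_rel(a, b, alternative="two-sided")
    return TTestResult(t=float(res.statistic), p=float(res.pvalue), n=len(a))


def bonferroni_alpha(alpha: float, m: int) -> float:
    """Bonferroni-adjusted per-comparison significance level ``alpha / m``."""
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    if m < 1:
        raise ValueError("number of comparisons must be >= 1")
    return alpha / m


def compare_reports(
    report_a: MetricsReport,
    report_b: MetricsReport,
    alpha: float = 0.05,
    n_comparisons: int = 3,
) -> pd.DataFrame:
    """Per-organ paired t-tests between two cohort reports.

    Compares Dice and RMS surface distance on the cases scored in both
    reports; significance is decided at the Bonferroni-adjusted level.
    """
    adj = bonferroni_alpha(alpha, n_comparisons)
    out = []
    organs = sorted(set(report_a.rows["organ"]))
    for organ in organs:
        for metric in ("dice", "rms_surface_mm"):
            sa = report_a.rows[(report_a.rows["organ"] == organ)
                               & ~report_a.rows["excluded"]].set_index("case")[metric]
            sb = report_b.rows[(report_b.rows["organ"] == organ)
                               & ~report_b.rows["excluded"]].set_index("case")[metric]
            common = sorted(set(sa.index) & set(sb.index))
            if len(common) < 2:
                out.append((organ, metric, np.nan, np.nan, len(common), adj, False))
                continue
            res = paired_t_test(sa.loc[common].to_numpy(), sb.loc[common].to_numpy())
            significant = (not res.degenerate) and res.p < adj
            out.append((organ, metric, res.t, res.p, res.n, adj, significant))
    return pd.DataFrame(
        out, columns=["organ", "metric", "t", "p", "n", "alpha_adjusted", "significant"]
    )
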