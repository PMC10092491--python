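"""Cohort statistics: ROC with TPR=1 thresholding, Mann–Whitney U, paired
Wilcoxon signed-rank with Holm correction, and paired plan-difference tables.

The ROC AUC is computed from midranks, which makes the identity
``AUC = U / (n_pos · n_neg)`` (tie-adjusted) exact by construction.  The
reported classifier cutoff is the least permissive threshold that still
captures every positive (true positive rate 1) — the clinically conservative
choice that never misses a sparing candidate — and a threshold is *reported*
only when AUC ≥ 0.8 and the Mann–Whitney p-value is ≤ 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .constraints import ConstraintSpec
from .dose_metrics import DoseMetricSpec, eqd2_metric
from .volumetric_core import PLAN_CSP, PLAN_NONCS, PatientBundle, base_of_heart

SMALLER_IS_POSITIVE = "smaller_is_positive"
LARGER_IS_POSITIVE = "larger_is_positive"

#: Exact-test budget: full enumeration is used when the number of
#: arrangements (C(n1+n2, n1) or 2^n) does not exceed this.
MAX_EXACT_ARRANGEMENTS = 10_000_000


@dataclass(frozen=True)
class ROCResult:
    predictor: str
    direction: str
    auc: float
    p_value: float
    p_method: str
    threshold_tpr1: float
    n_pos: int
    n_neg: int
    false_positives: int
    threshold_reported: bool
    degenerate: bool = False

    @property
    def false_positive_rate(self) -> float:
        return self.false_positives / self.n_neg


@dataclass(frozen=True)
class PairedTestResult:
    metric: str
    differences: np.ndarray          # b − a, per patient
    statistic: float
    p_value: float
    p_method: str
    p_holm: float | None = None
    n_increased: int = 0
    n_decreased: int = 0

    def significant(self, alpha: float = 0.05) -> bool:
        p = self.p_holm if self.p_holm is not None else self.p_value
        return p <= alpha


def _tie_adjusted_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """AUC as the tie-adjusted pairwise probability via midranks.

    Equals U/(n1·n2) where U counts pos>neg pairs with ties at half weight;
    orientation: larger positive values → AUC above 0.5.
    """
    pooled = np.concatenate([pos, neg])
    ranks = stats.rankdata(pooled)
    r_pos = ranks[: pos.size].sum()
    u = r_pos - pos.size * (pos.size + 1) / 2.0
    return u / (pos.size * neg.size)


def mann_whitney(
    pos: np.ndarray | list,
    neg: np.ndarray | list,
    alternative: str = "two-sided",
) -> tuple[float, float, str]:
    """Mann–Whitney U test; returns (U, p, method).

    Exact null distribution when the samples have no ties and the arrangement
    count C(n1+n2, n1) is enumerable; otherwise the normal approximation with
    tie correction and continuity correction.  All-tied data gives p = 1.
    """
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be nonempty")
    pooled = np.concatenate([pos, neg])
    if np.all(pooled == pooled[0]):
        u = pos.size * neg.size / 2.0
        return u, 1.0, "degenerate"
    has_ties = np.unique(pooled).size < pooled.size
    exact = not has_ties and math.comb(pos.size + neg.size, pos.size) <= MAX_EXACT_ARRANGEMENTS
    method = "exact" if exact else "asymptotic"
    res = stats.mannwhitneyu(pos, neg, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue), method


def roc(
    pos: np.ndarray | list,
    neg: np.ndarray | list,
    direction: str = SMALLER_IS_POSITIVE,
    predictor: str = "",
) -> ROCResult:
    """ROC over all observed thresholds with TPR=1 threshold selection.

    For smaller-is-positive predictors the TPR=1 threshold is ``max(pos)``
    (classify positive when value ≤ threshold); for larger-is-positive it is
    ``min(pos)`` (positive when value ≥ threshold).  No threshold attaining
    TPR=1 has fewer false positives.  A constant predictor is flagged
    degenerate (AUC 0.5).
    """
    if direction not in (SMALLER_IS_POSITIVE, LARGER_IS_POSITIVE):
        raise ValueError(f"unknown direction {direction!r}")
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("roc needs at least one value in each class")

    sign = -1.0 if direction == SMALLER_IS_POSITIVE else 1.0
    auc = _tie_adjusted_auc(sign * pos, sign * neg)
    _, p, method = mann_whitney(pos, neg)
    degenerate = bool(np.all(np.concatenate([pos, neg]) == pos.flat[0]))

    if direction == SMALLER_IS_POSITIVE:
        threshold = float(pos.max())
        fp = int((neg <= threshold).sum())
    else:
        threshold = float(pos.min())
        fp = int((neg >= threshold).sum())

    return ROCResult(
        predictor=predictor,
        direction=direction,
        auc=float(auc),
        p_value=p,
        p_method=method,
        threshold_tpr1=threshold,
        n_pos=pos.size,
        n_neg=neg.size,
        false_positives=fp,
        threshold_reported=bool(auc >= 0.8 and p <= 0.05 and not degenerate),
        degenerate=degenerate,
    )


def wilcoxon_paired(
    a: np.ndarray | list,
    b: np.ndarray | list,
    metric: str = "",
) -> PairedTestResult:
    """Two-sided Wilcoxon signed-rank test on paired values (b − a).

    Zero differences are discarded (classical Wilcoxon); the exact null is
    used for n ≤ 25 nonzero differences, else the normal approximation with
    continuity correction.  All-zero differences give p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    diff = b - a
    nonzero = diff[diff != 0]
    if nonzero.size == 0:
        return PairedTestResult(metric, diff, 0.0, 1.0, "all_zero")
    if nonzero.size < 2:
        # a single informative pair carries no distributional signal
        return PairedTestResult(
            metric, diff, 0.0, 1.0, "insufficient_pairs",
            n_increased=int((diff > 0).sum()), n_decreased=int((diff < 0).sum()),
        )
    method = "exact" if nonzero.size <= 25 else "approx"
    res = stats.wilcoxon(
        nonzero,
        zero_method="wilcox",
        correction=(method == "approx"),
        alternative="two-sided",
        method=method,
    )
    return PairedTestResult(
        metric=metric,
        differences=diff,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        p_method=method,
        n_increased=int((diff > 0).sum()),
        n_decreased=int((diff < 0).sum()),
    )


def holm_adjust(p_values: np.ndarray | list) -> np.ndarray:
    """Holm step-down adjusted p-values, returned in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


# ---------------------------------------------------------------------------
# paired plan-difference tables
# ---------------------------------------------------------------------------

#: Target coverage/dose metrics reported alongside OAR metrics.
TARGET_METRICS: tuple[tuple[str, str], ...] = (
    ("PTV", "D95%"),
    ("GTV", "D98%"),
    ("GTV", "D2%"),
)


def _metric_value(
    bundle: PatientBundle, plan: str, structure: str, spec: DoseMetricSpec, ab: float
) -> float | None:
    mask = bundle.masks.get(structure)
    if mask is None and structure == "base_of_heart":
        try:
            mask = base_of_heart(bundle.masks)
        except ValueError:
            mask = None
    if mask is None or mask.voxel_count == 0 or plan not in bundle.doses:
        return None
    return eqd2_metric(
        mask, bundle.doses[plan], bundle.schemes[plan], spec, ab
    ).eqd2_gy


def plan_difference_table(
    cohort: list[PatientBundle],
    constraint_table: list[ConstraintSpec],
    include_targets: bool = True,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Paired (csp − noncs) EQD2 differences per constraint metric with
    Wilcoxon raw and Holm-adjusted p-values and direction summaries.

    Only patients carrying both plans contribute.  With fewer than two such
    patients the table is still emitted with the tests marked unevaluable.
    """
    paired = [b for b in cohort if PLAN_CSP in b.doses and PLAN_NONCS in b.doses]
    metrics: list[tuple[str, DoseMetricSpec, float]] = [
        (c.structure, c.metric, c.alpha_beta) for c in constraint_table
    ]
    if include_targets:
        metrics += [(s, DoseMetricSpec.parse(m), 10.0) for s, m in TARGET_METRICS]

    rows = []
    tests: list[PairedTestResult] = []
    for structure, spec, ab in metrics:
        pairs = []
        for b in paired:
            v0 = _metric_value(b, PLAN_NONCS, structure, spec, ab)
            v1 = _metric_value(b, PLAN_CSP, structure, spec, ab)
            if v0 is not None and v1 is not None:
                pairs.append((v0, v1))
        name = f"{structure} {spec}"
        if len(pairs) < 2:
            rows.append(
                {
                    "metric": name,
                    "n_pairs": len(pairs),
                    "median_diff_gy": np.nan,
                    "n_increased": 0,
                    "n_decreased": 0,
                    "statistic": np.nan,
                    "p_raw": np.nan,
                    "p_holm": np.nan,
                    "significant": False,
                    "evaluable": False,
                }
            )
            continue
        a, b_ = map(np.array, zip(*pairs))
        t = wilcoxon_paired(a, b_, metric=name)
        tests.append(t)
        rows.append(
            {
                "metric": name,
                "n_pairs": len(pairs),
                "median_diff_gy": float(np.median(t.differences)),
                "n_increased": t.n_increased,
                "n_decreased": t.n_decreased,
                "statistic": t.statistic,
                "p_raw": t.p_value,
                "p_holm": np.nan,
                "significant": False,
                "evaluable": True,
            }
        )
    df = pd.DataFrame(rows)
    evaluable = df["evaluable"].to_numpy()
    if evaluable.any():
        adj = holm_adjust(df.loc[evaluable, "p_raw"].to_numpy())
        df.loc[evaluable, "p_holm"] = adj
        df.loc[evaluable, "significant"] = adj <= alpha
    return df


def roc_table(
    predictors: pd.DataFrame,
    positive: np.ndarray | pd.Series,
    directions: dict[str, str],
) -> pd.DataFrame:
    """Table-3-style ROC summary, one row per predictor column.

    ``positive`` is a boolean vector aligned with the predictor rows;
    ``directions`` maps column name → direction.  Rows with NaN predictor
    values are dropped per predictor.
    """
    positive = np.asarray(positive, dtype=bool)
    rows = []
    for col, direction in directions.items():
        vals = predictors[col].to_numpy(dtype=float)
        ok = ~np.isnan(vals)
        pos, neg = vals[ok & positive], vals[ok & ~positive]
        if pos.size == 0 or neg.size == 0:
            continue
        r = roc(pos, neg, direction, predictor=col)
        rows.append(
            {
                "predictor": col,
                "direction": r.direction,
                "auc": r.auc,
                "p_value": r.p_value,
                "p_method": r.p_method,
                "threshold": r.threshold_tpr1 if r.threshold_reported else np.nan,
                "false_positives": r.false_positives if r.threshold_reported else np.nan,
                "false_positive_rate": (
                    r.false_positive_rate if r.threshold_reported else np.nan
                ),
                "threshold_reported": r.threshold_reported,
            }
        )
    return pd.DataFrame(rows)


__all__ = [
    "LARGER_IS_POSITIVE",
    "MAX_EXACT_ARRANGEMENTS",
    "PairedTestResult",
    "ROCResult",
    "SMALLER_IS_POSITIVE",
    "TARGET_METRICS",
    "holm_adjust",
    "mann_whitney",
    "plan_difference_table",
    "roc",
    "roc_table",
    "wilcoxon_paired",
]
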