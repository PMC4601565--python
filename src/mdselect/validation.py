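"""Statistical validation of before/after-selection metric vectors.

Given the same metric measured on k datasets under two conditions (all
features vs the selected subset), this module computes their Pearson
correlation with an Evans strength label, and a paired t-test of the
hypothesis that selection leaves performance unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

__all__ = [
    "ComparisonResult",
    "metric_correlation",
    "evans_category",
    "paired_t",
    "critical_value",
    "compare_metric_vectors",
    "validation_report",
]

#: Evans strength bins for |r|: lower bound (inclusive) -> label.
EVANS_BINS = (
    (0.80, "very strong"),
    (0.60, "strong"),
    (0.40, "moderate"),
    (0.20, "weak"),
    (0.00, "very weak"),
)

DEFAULT_ALPHAS = (0.05, 0.01)


@dataclass(frozen=True)
class ComparisonResult:
    """Correlation + paired-t comparison of two metric vectors."""

    correlation: float
    strength: str
    t_stat: float
    df: int
    critical_values: dict[float, float] = field(default_factory=dict)
    decisions: dict[float, str] = field(default_factory=dict)  # "accept"/"reject" H0
    degenerate: bool = False  # all paired differences were zero


def metric_correlation(a: np.ndarray, p: np.ndarray) -> float:
    """Sample Pearson correlation of two equal-length metric vectors (k >= 3).

    Computed from raw sums; errors on zero variance.
    """
    a = np.asarray(a, dtype=float)
    p = np.asarray(p, dtype=float)
    if a.shape != p.shape or a.ndim != 1:
        raise ValidationError("metric vectors must be 1-D with equal length")
    k = a.size
    if k < 3:
        raise ValidationError(f"need at least 3 paired metrics, got {k}")
    num = k * (a * p).sum() - a.sum() * p.sum()
    var_a = k * (a**2).sum() - a.sum() ** 2
    var_p = k * (p**2).sum() - p.sum() ** 2
    if var_a <= 0 or var_p <= 0:
        raise ValidationError("correlation undefined: a metric vector is constant")
    return float(num / np.sqrt(var_a * var_p))


def evans_category(r: float) -> str:
    """Bin |r| into very weak / weak / moderate / strong / very strong.

    Boundaries belong to the bin that starts there (0.80 -> very strong);
    the sign of r is ignored.
    """
    magnitude = abs(float(r))
    if magnitude > 1:
        raise ValidationError(f"|r| = {magnitude} exceeds 1")
    for lower, label in EVANS_BINS:
        if magnitude >= lower:
            return label
    return "very weak"  # unreachable


def critical_value(df: int, alpha: float) -> float:
    """Two-sided Student-t critical value."""
    if df < 1:
        raise ValidationError(f"df must be >= 1, got {df}")
    if not 0 < alpha < 1:
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    return float(stats.t.ppf(1 - alpha / 2, df))


def paired_t(
    a: np.ndarray,
    p: np.ndarray,
    alphas: tuple[float, ...] = DEFAULT_ALPHAS,
) -> ComparisonResult:
    """Paired t-test on d = a - p with df = k - 1.

    t = sum(d) / sqrt((k*sum(d^2) - sum(d)^2) / (k - 1)); H0 (no
    difference) is accepted at a level iff |t| <= the two-sided critical
    value.  If every difference is zero, t = 0 with ``degenerate=True``.
    The correlation/strength fields are filled when k >= 3 and both
    vectors vary, else NaN / "".
    """
    a = np.asarray(a, dtype=float)
    p = np.asarray(p, dtype=float)
    if a.shape != p.shape or a.ndim != 1:
        raise ValidationError("metric vectors must be 1-D with equal length")
    k = a.size
    if k < 2:
        raise ValidationError(f"need at least 2 paired metrics, got {k}")
    d = a - p
    ss = k * (d**2).sum() - d.sum() ** 2
    degenerate = bool(np.all(d == 0))
    if ss <= 0:
        # zero-variance differences: t is 0 for all-zero d, undefined for a
        # constant nonzero shift -- report +/-inf in that case
        t = 0.0 if degenerate else float(np.sign(d.sum()) * np.inf)
        degenerate = True
    else:
        t = float(d.sum() / np.sqrt(ss / (k - 1)))

    try:
        r = metric_correlation(a, p)
        strength = evans_category(r)
    except ValidationError:
        r, strength = float("nan"), ""

    df = k - 1
    crits = {alpha: critical_value(df, alpha) for alpha in alphas}
    decisions = {
        alpha: "accept" if abs(t) <= cv else "reject" for alpha, cv in crits.items()
    }
    return ComparisonResult(
        correlation=r,
        strength=strength,
        t_stat=t,
        df=df,
        critical_values=crits,
        decisions=decisions,
        degenerate=degenerate,
    )


def compare_metric_vectors(
    a: np.ndarray,
    p: np.ndarray,
    alphas: tuple[float, ...] = DEFAULT_ALPHAS,
) -> ComparisonResult:
    """Full comparison (alias of :func:`paired_t`, which also correlates)."""
    return paired_t(a, p, alphas=alphas)


def validation_report(
    metrics: pd.DataFrame,
    metric_columns: tuple[str, ...] = ("hamming_score", "exact_match"),
    baseline: str = "before_selection",
    treatment: str = "after_selection",
    alphas: tuple[float, ...] = DEFAULT_ALPHAS,
) -> pd.DataFrame:
    """Per (classifier, metric) comparison table from a long metric frame.

    ``metrics`` needs columns ``dataset``, ``classifier``, ``condition``
    plus the metric columns; each (classifier, metric) pair is compared
    across datasets between the two conditions.
    """
    required = {"dataset", "classifier", "condition"}
    if not required <= set(metrics.columns):
        raise ValidationError(f"metrics frame must have columns {sorted(required)}")
    rows = []
    for classifier, group in metrics.groupby("classifier", sort=False):
        wide = group.pivot(index="dataset", columns="condition")
        for metric in metric_columns:
            if metric not in group.columns:
                continue
            a = wide[(metric, baseline)].to_numpy(dtype=float)
            p = wide[(metric, treatment)].to_numpy(dtype=float)
            res = paired_t(a, p, alphas=alphas)
            row = {
                "classifier": classifier,
                "metric": metric,
                "correlation": res.correlation,
                "strength": res.strength,
                "t_stat": res.t_stat,
                "df": res.df,
            }
            for alpha in alphas:
                row[f"critical_{alpha}"] = res.critical_values[alpha]
                row[f"decision_{alpha}"] = res.decisions[alpha]
            rows.append(row)
    return pd.DataFrame(rows)
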