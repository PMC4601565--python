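"""Correlation rank-weight feature subset selection.

The pipeline: (1) an ``l x m`` Pearson correlation matrix between every
feature and every integer-encoded class variable; (2) per class, integer
rank weights ``l .. 1`` assigned in descending correlation order; (3) a
single overall weight per feature, the rank-weighted average of its
per-class correlations; (4) features sorted by overall weight and the top
``round(log2(l))`` kept.  The selected subset is shared by all class
variables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import MDDataset
from .errors import ValidationError

__all__ = [
    "CorrelationMatrix",
    "RankWeights",
    "OverallWeights",
    "SelectionResult",
    "correlation_matrix",
    "rank_weights",
    "overall_weights",
    "subset_size",
    "select",
    "selection_report",
]


@dataclass(frozen=True)
class CorrelationMatrix:
    """``l x m`` feature-class Pearson correlations.

    Entries involving a zero-variance column are 0 by convention.
    """

    values: np.ndarray
    n_used: int


@dataclass(frozen=True)
class RankWeights:
    """``l x m`` integer weights; each column is a permutation of 1..l."""

    values: np.ndarray


@dataclass(frozen=True)
class OverallWeights:
    """Length-l rank-weighted averages of per-class correlations."""

    values: np.ndarray


@dataclass(frozen=True)
class SelectionResult:
    ranking: np.ndarray  # feature indices, best first
    s: int
    selected: np.ndarray  # = ranking[:s]
    weights: OverallWeights


def correlation_matrix(data: MDDataset, absolute: bool = False) -> CorrelationMatrix:
    """Pearson correlation of every feature with every encoded class.

    Classes are integer-encoded by domain position (binary -> {0, 1}).
    Requires a dataset without missing values and n >= 3.  With
    ``absolute=True`` the magnitudes are returned (extension; off by
    default, which ranks strongly negative correlations last).
    """
    if data.has_missing():
        raise ValidationError("dataset has missing values; impute first")
    n = data.n
    if n < 3:
        raise ValidationError(f"correlation needs n >= 3, got {n}")
    x = data.features
    y = data.encoded_targets().astype(float)

    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    sx = np.sqrt((xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum(axis=0))
    cov = xc.T @ yc
    denom = np.outer(sx, sy)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, cov / np.where(denom > 0, denom, 1.0), 0.0)
    r = np.clip(r, -1.0, 1.0)
    if absolute:
        r = np.abs(r)
    return CorrelationMatrix(values=r, n_used=n)


def rank_weights(corr: CorrelationMatrix) -> RankWeights:
    """Per class, weight ``l`` for the largest correlation down to 1 for the
    smallest; ties give the larger weight to the lower feature index."""
    r = corr.values
    l, m = r.shape
    weights = np.empty((l, m), dtype=int)
    for i in range(m):
        # stable sort on index, then descending r: equal r keeps index order
        order = sorted(range(l), key=lambda j: (-r[j, i], j))
        for position, j in enumerate(order):
            weights[j, i] = l - position
    return RankWeights(values=weights)


def overall_weights(corr: CorrelationMatrix, weights: RankWeights) -> OverallWeights:
    """w_j = sum_i w_ji * r_ji / sum_i w_ji — a convex combination of the
    feature's per-class correlations."""
    r = corr.values
    w = weights.values
    if r.shape != w.shape:
        raise ValidationError("correlation and weight shapes differ")
    return OverallWeights(values=(w * r).sum(axis=1) / w.sum(axis=1))


def subset_size(l: int) -> int:  # noqa: E741 - domain convention
    """Selected-subset size ``round(log2(l))``, half rounded up, in [1, l]."""
    if l < 2:
        raise ValidationError(f"need at least 2 features, got {l}")
    s = math.floor(math.log2(l) + 0.5)
    return max(1, min(s, l))


def select(
    data: MDDataset,
    s: int | None = None,
    absolute: bool = False,
) -> SelectionResult:
    """Run the full pipeline and return the ranking plus the top-``s`` subset.

    ``s`` defaults to ``subset_size(l)``; pass an explicit value to
    override.  Final-ranking ties break by ascending feature index.
    """
    corr = correlation_matrix(data, absolute=absolute)
    ranks = rank_weights(corr)
    overall = overall_weights(corr, ranks)
    l = data.l
    if s is None:
        s = subset_size(l)
    if not 1 <= s <= l:
        raise ValidationError(f"subset size {s} outside [1, {l}]")
    ranking = np.array(sorted(range(l), key=lambda j: (-overall.values[j], j)))
    return SelectionResult(
        ranking=ranking,
        s=s,
        selected=ranking[:s].copy(),
        weights=overall,
    )


def selection_report(data: MDDataset, result: SelectionResult,
                     corr: CorrelationMatrix | None = None) -> pd.DataFrame:
    """Tabulate the ranking: one row per feature, best first, with overall
    weight, per-class correlations, rank position and selected flag."""
    if corr is None:
        corr = correlation_matrix(data)
    rows = []
    selected = set(result.selected.tolist())
    for position, j in enumerate(result.ranking, start=1):
        row = {
            "feature": data.feature_names[j],
            "rank": position,
            "overall_weight": result.weights.values[j],
            "selected": j in selected,
        }
        for i, cname in enumerate(data.class_names):
            row[f"r_{cname}"] = corr.values[j, i]
        rows.append(row)
    return pd.DataFrame(rows)
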