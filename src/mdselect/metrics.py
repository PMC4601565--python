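"""Evaluation metrics for multidimensional predictions.

Hamming metrics count cell-wise disagreement between an ``n x m`` true
class matrix and a prediction of the same shape, so they apply to class
variables of any cardinality; for binary multi-label data they reduce to
the standard definitions.  Exact match scores whole rows.  The complement
identities ``score + loss = 1`` hold exactly by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

__all__ = [
    "MetricSet",
    "hamming_loss",
    "hamming_score",
    "exact_match",
    "zero_one_loss",
    "example_prf",
    "compute_metrics",
]


@dataclass(frozen=True)
class MetricSet:
    hamming_score: float
    hamming_loss: float
    exact_match: float
    zero_one_loss: float
    precision: float | None = None
    recall: float | None = None
    f1: float | None = None

    def as_dict(self) -> dict[str, float]:
        out = {
            "hamming_score": self.hamming_score,
            "hamming_loss": self.hamming_loss,
            "exact_match": self.exact_match,
            "zero_one_loss": self.zero_one_loss,
        }
        if self.precision is not None:
            out.update(precision=self.precision, recall=self.recall, f1=self.f1)
        return out


def _check_shapes(true: np.ndarray, pred: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    true = np.asarray(true)
    pred = np.asarray(pred)
    if true.ndim != 2 or true.shape != pred.shape:
        raise ValidationError(
            f"shape mismatch: true {true.shape} vs pred {pred.shape}"
        )
    if true.size == 0:
        raise ValidationError("empty matrices")
    return true, pred


def hamming_loss(true: np.ndarray, pred: np.ndarray) -> float:
    """Fraction of (instance, class-variable) cells predicted wrongly."""
    true, pred = _check_shapes(true, pred)
    return float((true != pred).mean())


def hamming_score(true: np.ndarray, pred: np.ndarray) -> float:
    """Cell-wise accuracy; complement of :func:`hamming_loss`."""
    return 1.0 - hamming_loss(true, pred)


def exact_match(true: np.ndarray, pred: np.ndarray) -> float:
    """Fraction of instances whose full class vector is predicted exactly."""
    true, pred = _check_shapes(true, pred)
    return float((true == pred).all(axis=1).mean())


def zero_one_loss(true: np.ndarray, pred: np.ndarray) -> float:
    """Complement of :func:`exact_match`."""
    return 1.0 - exact_match(true, pred)


def example_prf(true: np.ndarray, pred: np.ndarray) -> tuple[float, float, float]:
    """Example-based precision/recall/F1 for binary label matrices.

    Per instance: precision = |T∩P| / |P|, recall = |T∩P| / |T|,
    F1 = 2|T∩P| / (|T| + |P|); an instance with both sets empty
    contributes 1 to all three, and an empty denominator otherwise
    contributes 0.  Averaged over instances.
    """
    true, pred = _check_shapes(true, pred)
    values = set(np.unique(true)) | set(np.unique(pred))
    if not values <= {0, 1}:
        raise ValidationError("example_prf requires binary (0/1) label matrices")
    t = true.astype(bool)
    p = pred.astype(bool)
    inter = (t & p).sum(axis=1).astype(float)
    n_true = t.sum(axis=1).astype(float)
    n_pred = p.sum(axis=1).astype(float)

    both_empty = (n_true == 0) & (n_pred == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        prec = np.where(n_pred > 0, inter / np.where(n_pred > 0, n_pred, 1), 0.0)
        rec = np.where(n_true > 0, inter / np.where(n_true > 0, n_true, 1), 0.0)
        f1 = np.where(
            n_true + n_pred > 0,
            2 * inter / np.where(n_true + n_pred > 0, n_true + n_pred, 1),
            0.0,
        )
    prec[both_empty] = rec[both_empty] = f1[both_empty] = 1.0
    return float(prec.mean()), float(rec.mean()), float(f1.mean())


def compute_metrics(true: np.ndarray, pred: np.ndarray,
                    with_prf: bool = False) -> MetricSet:
    """Bundle all metrics for one (classifier, dataset) run."""
    hl = hamming_loss(true, pred)
    em = exact_match(true, pred)
    prf = example_prf(true, pred) if with_prf else (None, None, None)
    return MetricSet(
        hamming_score=1.0 - hl,
        hamming_loss=hl,
        exact_match=em,
        zero_one_loss=1.0 - em,
        precision=prf[0],
        recall=prf[1],
        f1=prf[2],
    )
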