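"""Data model and I/O for multidimensional datasets.

An :class:`MDDataset` couples an ``n x l`` real feature matrix with an
``n x m`` class matrix, where each of the ``m`` class variables has its own
(small) domain of admissible values.  Readers are provided for the common
multi-label ARFF dialects (label count embedded in the relation name, or a
separate XML label list) and for plain CSV/TSV tables with declared target
columns, plus deterministic imputation and a synthetic generator with
planted feature-class structure.
"""

from __future__ import annotations

import math
import os
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ._arff import ArffAttribute, ArffFile, dump_arff, load_arff
from .errors import ConfigurationError, ValidationError

__all__ = [
    "MDDataset",
    "SyntheticSpec",
    "read_arff",
    "write_arff",
    "read_table",
    "impute_missing",
    "generate_synthetic",
]


@dataclass
class MDDataset:
    """A dataset with ``l`` features and ``m`` class variables.

    Parameters
    ----------
    features : ndarray of shape (n, l)
        Real-valued feature matrix.  Missing entries are NaN until
        :func:`impute_missing` is applied.
    targets : ndarray of shape (n, m), dtype object
        Class values; ``None`` marks a missing entry.
    feature_names, class_names : list of str
        Column labels.
    class_domains : list of list
        Per class variable, the ordered admissible values (cardinality >= 2
        unless the observed data is constant).
    feature_domains : list of (list of str or None)
        For integer-encoded nominal features, the original values in
        declaration order; ``None`` for natively numeric features.
    """

    features: np.ndarray
    targets: np.ndarray
    feature_names: list[str]
    class_names: list[str]
    class_domains: list[list]
    feature_domains: list[list[str] | None] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.targets = np.asarray(self.targets, dtype=object)
        if self.features.ndim != 2 or self.targets.ndim != 2:
            raise ValidationError("features and targets must be 2-D")
        if self.feature_domains is None:
            self.feature_domains = [None] * self.features.shape[1]
        n, l = self.features.shape
        if self.targets.shape[0] != n:
            raise ValidationError("feature and target row counts differ")
        m = self.targets.shape[1]
        if l < 2:
            raise ValidationError(f"need at least 2 features, got {l}")
        if m < 1:
            raise ValidationError("need at least 1 class variable")
        if n < 3:
            raise ValidationError(f"need at least 3 instances, got {n}")
        if len(self.feature_names) != l or len(self.class_names) != m:
            raise ValidationError("name lists do not match matrix shapes")
        if len(self.class_domains) != m or len(self.feature_domains) != l:
            raise ValidationError("domain lists do not match matrix shapes")
        for i, domain in enumerate(self.class_domains):
            allowed = set(domain)
            for value in self.targets[:, i]:
                if value is not None and value not in allowed:
                    raise ValidationError(
                        f"class {self.class_names[i]!r}: value {value!r} "
                        f"outside declared domain"
                    )

    @property
    def n(self) -> int:
        return self.features.shape[0]

    @property
    def l(self) -> int:  # noqa: E743 - domain convention
        return self.features.shape[1]

    @property
    def m(self) -> int:
        return self.targets.shape[1]

    def has_missing(self) -> bool:
        if np.isnan(self.features).any():
            return True
        return any(v is None for v in self.targets.flat)

    def encoded_targets(self) -> np.ndarray:
        """Integer-encode classes by domain position (binary -> {0, 1})."""
        if any(v is None for v in self.targets.flat):
            raise ValidationError("cannot encode targets with missing values")
        out = np.empty((self.n, self.m), dtype=int)
        for i, domain in enumerate(self.class_domains):
            index = {v: k for k, v in enumerate(domain)}
            out[:, i] = [index[v] for v in self.targets[:, i]]
        return out

    def subset_features(self, indices: Sequence[int]) -> "MDDataset":
        idx = list(indices)
        return MDDataset(
            features=self.features[:, idx].copy(),
            targets=self.targets.copy(),
            feature_names=[self.feature_names[j] for j in idx],
            class_names=list(self.class_names),
            class_domains=[list(d) for d in self.class_domains],
            feature_domains=[self.feature_domains[j] for j in idx],
        )

    def equals(self, other: "MDDataset") -> bool:
        return (
            np.array_equal(self.features, other.features, equal_nan=True)
            and self.targets.shape == other.targets.shape
            and all(a == b for a, b in zip(self.targets.flat, other.targets.flat))
            and self.feature_names == other.feature_names
            and self.class_names == other.class_names
            and self.class_domains == other.class_domains
            and self.feature_domains == other.feature_domains
        )


# ---------------------------------------------------------------------------
# ARFF


def _labels_from_relation(relation: str) -> int | None:
    import re

    m = re.search(r"-C\s+(-?\d+)", relation)
    return int(m.group(1)) if m else None


def _resolve_label_names(
    arff: ArffFile, label_spec: int | Sequence[str] | str | None
) -> list[str]:
    names = [a.name for a in arff.attributes]
    if label_spec is None:
        count = _labels_from_relation(arff.relation)
        if count is None:
            raise ConfigurationError(
                "no label specification given and none found in the relation name"
            )
        label_spec = count
    if isinstance(label_spec, str):
        if not os.path.exists(label_spec):
            raise ConfigurationError(f"label list file not found: {label_spec}")
        root = ET.parse(label_spec).getroot()
        labels = [
            el.attrib["name"]
            for el in root.iter()
            if el.tag.rsplit("}", 1)[-1] == "label" and "name" in el.attrib
        ]
        if not labels:
            raise ConfigurationError(f"no <label name=...> entries in {label_spec}")
        label_spec = labels
    if isinstance(label_spec, int):
        count = label_spec
        if count == 0 or abs(count) >= len(names):
            raise ConfigurationError(f"label count {count} out of range")
        # MEKA convention: positive count -> first attributes, negative -> last.
        return names[:count] if count > 0 else names[count:]
    labels = list(label_spec)
    unknown = [x for x in labels if x not in names]
    if unknown:
        raise ConfigurationError(f"label attributes not in ARFF header: {unknown}")
    return labels


def read_arff(path: str, label_spec: int | Sequence[str] | str | None = None) -> MDDataset:
    """Read a multi-label ARFF file.

    ``label_spec`` may be an integer count (positive: first attributes are
    classes, negative: last), an explicit list of attribute names, the path
    of an XML label-list file, or ``None`` to parse a ``-C m`` declaration
    from the relation name.
    """
    arff = load_arff(path)
    label_names = _resolve_label_names(arff, label_spec)
    label_set = set(label_names)

    feature_cols: list[int] = []
    class_cols: list[int] = []
    for k, attr in enumerate(arff.attributes):
        (class_cols if attr.name in label_set else feature_cols).append(k)
    # keep class columns in label_spec order
    by_name = {arff.attributes[k].name: k for k in class_cols}
    class_cols = [by_name[name] for name in label_names]

    n = len(arff.rows)
    features = np.full((n, len(feature_cols)), np.nan)
    feature_domains: list[list[str] | None] = []
    for out_j, k in enumerate(feature_cols):
        attr = arff.attributes[k]
        if attr.type_decl == "numeric":
            feature_domains.append(None)
            for r, row in enumerate(arff.rows):
                if row[k] is not None:
                    features[r, out_j] = float(row[k])
        else:
            domain = list(attr.domain or [])
            feature_domains.append(domain)
            code = {v: c for c, v in enumerate(domain)}
            for r, row in enumerate(arff.rows):
                if row[k] is not None:
                    features[r, out_j] = code[row[k]]

    targets = np.empty((n, len(class_cols)), dtype=object)
    class_domains: list[list] = []
    for out_i, k in enumerate(class_cols):
        attr = arff.attributes[k]
        column = [row[k] for row in arff.rows]
        targets[:, out_i] = column
        if attr.type_decl == "nominal":
            class_domains.append(list(attr.domain or []))
        else:
            observed = sorted({float(v) for v in column if v is not None})
            class_domains.append(observed)
            targets[:, out_i] = [None if v is None else float(v) for v in column]

    return MDDataset(
        features=features,
        targets=targets,
        feature_names=[arff.attributes[k].name for k in feature_cols],
        class_names=label_names,
        class_domains=class_domains,
        feature_domains=feature_domains,
    )


def write_arff(data: MDDataset, path: str, relation: str = "mddataset") -> None:
    """Write ``data`` with class attributes first and ``-C m`` in the relation.

    ``read_arff(path)`` on the result reproduces the dataset exactly.
    """
    attributes = [
        ArffAttribute(name, "nominal", [_format_value(v) for v in domain])
        for name, domain in zip(data.class_names, data.class_domains)
    ]
    for j, name in enumerate(data.feature_names):
        domain = data.feature_domains[j]
        if domain is None:
            attributes.append(ArffAttribute(name, "numeric"))
        else:
            attributes.append(ArffAttribute(name, "nominal", list(domain)))

    rows: list[list[str | None]] = []
    for r in range(data.n):
        row: list[str | None] = []
        for i in range(data.m):
            v = data.targets[r, i]
            row.append(None if v is None else _format_value(v))
        for j in range(data.l):
            x = data.features[r, j]
            if math.isnan(x):
                row.append(None)
            elif data.feature_domains[j] is not None:
                row.append(data.feature_domains[j][int(x)])
            else:
                row.append(repr(float(x)))
        rows.append(row)
    dump_arff(ArffFile(f"{relation} -C {data.m}", attributes, rows), path)


def _format_value(v: object) -> str:
    if isinstance(v, float):
        return repr(v)
    return str(v)


# ---------------------------------------------------------------------------
# Delimited tables


def read_table(
    path: str,
    target_columns: Sequence[str],
    sep: str | None = None,
) -> MDDataset:
    """Read a CSV/TSV file; ``target_columns`` become the class variables.

    Remaining columns are features.  Non-numeric feature columns are
    integer-encoded over their sorted distinct values; class domains are
    inferred from the observed values.
    """
    targets = list(target_columns)
    if not targets:
        raise ConfigurationError("at least one target column is required")
    if sep is None:
        sep = "\t" if os.path.splitext(path)[1].lower() in {".tsv", ".tab"} else ","
    frame = pd.read_csv(path, sep=sep)
    missing_cols = [c for c in targets if c not in frame.columns]
    if missing_cols:
        raise ConfigurationError(f"target columns not found: {missing_cols}")

    feature_names = [c for c in frame.columns if c not in set(targets)]
    n = len(frame)
    features = np.full((n, len(feature_names)), np.nan)
    feature_domains: list[list[str] | None] = []
    for j, name in enumerate(feature_names):
        col = frame[name]
        if pd.api.types.is_numeric_dtype(col):
            features[:, j] = col.to_numpy(dtype=float)
            feature_domains.append(None)
        else:
            observed = sorted({str(v) for v in col.dropna()})
            code = {v: k for k, v in enumerate(observed)}
            features[:, j] = [
                np.nan if pd.isna(v) else code[str(v)] for v in col
            ]
            feature_domains.append(observed)

    target_matrix = np.empty((n, len(targets)), dtype=object)
    class_domains: list[list] = []
    for i, name in enumerate(targets):
        col = frame[name]
        values = [None if pd.isna(v) else v for v in col]
        target_matrix[:, i] = values
        class_domains.append(sorted({v for v in values if v is not None}, key=str))

    return MDDataset(
        features=features,
        targets=target_matrix,
        feature_names=feature_names,
        class_names=targets,
        class_domains=class_domains,
        feature_domains=feature_domains,
    )


# ---------------------------------------------------------------------------
# Imputation


def impute_missing(data: MDDataset) -> MDDataset:
    """Fill feature gaps (mean for numeric, mode for nominal) and drop
    instances missing any class value.

    Idempotent; errors if a feature has no observed value at all.
    """
    keep = np.array(
        [all(v is not None for v in data.targets[r]) for r in range(data.n)]
    )
    features = data.features[keep].copy()
    targets = data.targets[keep].copy()
    if features.shape[0] < 3:
        raise ValidationError("fewer than 3 instances remain after dropping rows "
                              "with missing class values")

    for j in range(features.shape[1]):
        column = features[:, j]
        mask = np.isnan(column)
        if not mask.any():
            continue
        observed = column[~mask]
        if observed.size == 0:
            raise ValidationError(
                f"feature {data.feature_names[j]!r} has no observed values"
            )
        if data.feature_domains[j] is None:
            fill = observed.mean()
        else:  # nominal: most frequent code, smallest code on ties
            codes, counts = np.unique(observed, return_counts=True)
            fill = codes[np.argmax(counts)]
        column[mask] = fill

    return MDDataset(
        features=features,
        targets=targets,
        feature_names=list(data.feature_names),
        class_names=list(data.class_names),
        class_domains=[list(d) for d in data.class_domains],
        feature_domains=[None if d is None else list(d) for d in data.feature_domains],
    )


# ---------------------------------------------------------------------------
# Synthetic data


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a planted-structure synthetic dataset.

    ``informative`` maps a feature index to ``(class index, effect size)``.
    The planted feature is ``effect * z + noise`` where ``z`` is the
    unit-variance centred encoding of its balanced binary class, so its
    population correlation with the class is
    ``effect / sqrt(effect**2 + noise_sd**2)``.  Non-planted features are
    pure Gaussian noise.
    """

    n: int
    l: int  # noqa: E741 - domain convention
    m: int
    informative: dict[int, tuple[int, float]]
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 3 or self.l < 2 or self.m < 1:
            raise ValidationError("need n >= 3, l >= 2, m >= 1")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")
        for f, (c, effect) in self.informative.items():
            if not 0 <= f < self.l:
                raise ValidationError(f"informative feature index {f} out of range")
            if not 0 <= c < self.m:
                raise ValidationError(f"informative class index {c} out of range")
            if effect < 0:
                raise ValidationError("effect sizes must be non-negative")


def generate_synthetic(spec: SyntheticSpec) -> MDDataset:
    """Generate the dataset described by ``spec`` (deterministic per seed)."""
    rng = np.random.default_rng(spec.seed)
    labels = np.empty((spec.n, spec.m), dtype=int)
    half = spec.n // 2
    base = np.concatenate([np.zeros(half, dtype=int),
                           np.ones(spec.n - half, dtype=int)])
    for i in range(spec.m):
        labels[:, i] = rng.permutation(base)

    features = rng.normal(0.0, spec.noise_sd, size=(spec.n, spec.l))
    for f, (c, effect) in spec.informative.items():
        features[:, f] += effect * (2 * labels[:, c] - 1)

    targets = labels.astype(object)
    return MDDataset(
        features=features,
        targets=targets,
        feature_names=[f"f{j + 1}" for j in range(spec.l)],
        class_names=[f"c{i + 1}" for i in range(spec.m)],
        class_domains=[[0, 1] for _ in range(spec.m)],
        feature_domains=[None] * spec.l,
    )
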