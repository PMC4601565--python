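"""Bundled reference benchmark results.

A transcription of published evaluation metrics for four classifiers on
five multidimensional benchmark datasets, measured with all features
(``before_selection``) and with the correlation rank-weight subset
(``after_selection``).  These allow the statistical validation step to be
reproduced without the external datasets or any classifier runs.

Known erratum: the published after-selection row for (ibk, music) prints
hamming_score 0.74 with hamming_loss 0.252; the downstream correlation and
t statistics are consistent with 0.74, so the loss cell (which should read
0.26 to complement the score) is a typo in the source. The transcription
is faithful to the printed values.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_reference_metrics",
    "REFERENCE_FEATURE_COUNTS",
    "REFERENCE_DATASETS",
]

#: Post-load feature counts of the five benchmark datasets.
REFERENCE_FEATURE_COUNTS: dict[str, int] = {
    "thyroid": 28,
    "solar_flare": 10,
    "scene": 294,
    "music": 71,
    "yeast": 103,
}

REFERENCE_DATASETS = tuple(REFERENCE_FEATURE_COUNTS)


def load_reference_metrics() -> pd.DataFrame:
    """Long-format frame: dataset, classifier, condition, four metrics."""
    ref = resources.files("mdselect.data").joinpath("reference_metrics.tsv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")
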