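import math

import numpy as np
import pytest

from mdselect import MDDataset, SyntheticSpec, generate_synthetic


def pearson_rawsum(x, y):
    """Independent raw-sum Pearson oracle (kept free of package code)."""
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxx = sum(v * v for v in x)
    syy = sum(v * v for v in y)
    sxy = sum(a * b for a, b in zip(x, y))
    denom = math.sqrt(n * sxx - sx * sx) * math.sqrt(n * syy - sy * sy)
    return (n * sxy - sx * sy) / denom


@pytest.fixture
def tiny_dataset():
    """4 instances, 3 features, 2 binary class variables; no missing data."""
    features = np.array(
        [
            [1.0, 4.0, 5.0],
            [2.0, 3.0, 5.0],
            [3.0, 2.0, 5.0],
            [4.0, 1.0, 5.0],
        ]
    )
    targets = np.array(
        [[0, 1], [0, 1], [1, 0], [1, 0]], dtype=object
    )
    return MDDataset(
        features=features,
        targets=targets,
        feature_names=["f1", "f2", "f3"],
        class_names=["c1", "c2"],
        class_domains=[[0, 1], [0, 1]],
    )


@pytest.fixture
def planted_dataset():
    spec = SyntheticSpec(
        n=500,
        l=50,
        m=2,
        informative={j: (j % 2, 5.0) for j in range(6)},
        noise_sd=1.0,
        seed=7,
    )
    return generate_synthetic(spec)


ARFF_RELATION_DIALECT = """\
% toy multi-label fixture
@relation 'toy -C 2'

@attribute label_a {0,1}
@attribute label_b {yes,no}
@attribute f1 numeric
@attribute f2 real
@attribute colour {red,green,blue}

@data
0,yes,1.5,-2.0,red
1,no,2.5,0.0,green
0,yes,3.5,1.0,blue
1,no,4.5,2.5,red
0,no,5.5,4.0,green
"""

ARFF_LABEL_XML = """\
<?xml version="1.0" encoding="utf-8"?>
<labels xmlns="http://mulan.sourceforge.net/labels">
  <label name="label_a"/>
  <label name="label_b"/>
</labels>
"""


@pytest.fixture
def arff_fixture(tmp_path):
    path = tmp_path / "toy.arff"
    path.write_text(ARFF_RELATION_DIALECT)
    xml_path = tmp_path / "toy.xml"
    xml_path.write_text(ARFF_LABEL_XML)
    return path, xml_path
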