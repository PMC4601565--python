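# mdselect

Feature subset selection and evaluation for **multidimensional datasets** —
datasets where every instance carries several class variables (multi-label
data is the binary special case).

The selector is a filter method that produces a **single feature subset
shared by all class variables**:

1. compute the `l × m` Pearson correlation matrix between every feature and
   every (integer-encoded) class variable;
2. per class, assign integer rank weights `l … 1` in descending correlation
   order;
3. aggregate each feature's per-class correlations into one overall weight
   (a rank-weighted average);
4. sort by overall weight and keep the top `s = round(log2 l)` features.

Companion modules provide the multi-label evaluation metrics (Hamming
score/loss, exact match, zero-one loss, example-based P/R/F1), a
problem-transformation benchmark harness (one single-target classifier per
class variable, evaluated with all features vs the selected subset), and
statistical validation of the before/after metric vectors (Pearson
correlation with Evans strength labels, paired t-test against two-sided
Student-t critical values).

## Library quick start

```python
from mdselect import SyntheticSpec, generate_synthetic, select

spec = SyntheticSpec(n=500, l=50, m=2,
                     informative={j: (j % 2, 5.0) for j in range(6)},
                     noise_sd=1.0, seed=1)
data = generate_synthetic(spec)

result = select(data)          # s = round(log2(50)) = 6
print(result.selected)         # indices of the shared subset
```

Readers: `read_arff` (multi-label ARFF; label count in the relation name
`"... -C m"`, an explicit label list, or a Mulan-style XML label file) and
`read_table` (CSV/TSV with declared target columns). `impute_missing` fills
feature gaps (mean/mode) and drops instances with missing class values.

## CLI

```bash
mdselect simulate --n 500 --features 50 --classes 2 --informative 6 \
                  --effect 5 --seed 1 --out synthetic.csv
mdselect select synthetic.csv --targets c1,c2 --out selection.tsv
mdselect benchmark config.yaml --outdir out/   # metrics + validation TSVs
mdselect validate --out validation.tsv         # bundled reference metrics
```

`benchmark` takes a YAML config (`datasets`, `trainers`, `folds`, `seed`);
with three or more datasets it also writes the correlation/paired-t
validation report. `validate` replays any precomputed metric table
(columns `dataset`, `classifier`, `condition`, metric columns) through the
validation step; by default it uses the transcribed reference benchmark
bundled with the package. Every command writes a provenance JSON block
(config hash, seed, library versions) next to its outputs.

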