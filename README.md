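# priobench

A test bench for **variant pathogenicity prioritization methods**.

Clinical interpretation of exome and genome sequencing leans on methods
that score each genetic variant by how likely it is to be disease-causing
(CADD, fathmm-MKL, the dbNSFP score collection, ...).  Whenever such a
method is developed or retrained it has to be evaluated against current
labeled data — benign and pathogenic variants from archives such as
ClinVar or the VariSNP neutral benchmark — and compared with existing
methods.  Done by hand this means converting data into each method's input
format, driving each method's software stack, collecting scores, and
computing classifier statistics, over and over.

`priobench` automates that loop for anyone benchmarking prioritization
methods:

* **Input processing** — generic extractors for VCF- and CSV-based inputs
  (plus ClinVar-flavoured `CLNSIG` and VariSNP-flavoured specializations)
  transform labeled variants into a canonical table
  `(UID, RG, CHROM, POS, REF, ALT, TYPE, CLASS)` with
  `CHROM ∈ {1..22, X, Y, M}`, `TYPE ∈ {SNP, INDEL}` and
  `CLASS ∈ {benign, pathogenic}`, validated constraint-by-constraint with
  every violation reported at once.
* **Plugins** — each method is a directory with a declarative
  `manifest.yaml` (name, version, supported variation types, score cutoff
  and direction, reference genome, database versions) plus scoring logic:
  a Python script run in-process, or a container image driven through a
  file contract (serialize input → mount → run → parse `(UID, score)`
  output).  The bench checks manifest compatibility (variation types,
  reference genome with hg19↔GRCh37-style aliasing) *before* invoking
  anything and validates that every UID received exactly one finite score.
* **Performance reports** — truth labels are encoded benign→0,
  pathogenic→1 and scores thresholded at each method's cutoff (a score at
  the cutoff counts as pathogenic).  Supported metrics: sensitivity,
  specificity, precision, recall, NPV, accuracy, concordance (count and
  relative), Matthews correlation coefficient, and AUROC; summaries:
  confusion matrix, ROC curve, precision–recall curve.  AUROC is the
  trapezoidal area under the tie-grouped ROC sweep, which equals the
  Mann–Whitney pairwise probability P(pathogenic score > benign score).
  Reports serialize to deterministic, schema-versioned JSON; a series of
  reports (e.g. successive database releases) aggregates into a
  concordance trend table.
* **Fixtures** — a seeded generator produces synthetic labeled datasets
  (matching VCF/CSV/ClinVar renditions) and mock plugins with designed
  score behaviour (perfect/inverted oracles, exact false-negative /
  false-positive counts, two-Gaussian noisy scores with a closed-form
  expected AUROC), so the whole bench is testable offline.

## Worked example

Generate a 500 benign / 500 pathogenic synthetic SNP dataset and three
mock methods — one built to misclassify exactly 13 pathogenic and 13
benign variants, and two noisy scorers of different separations:

```python
from pathlib import Path
from priobench.fixtures import (DatasetSpec, MockPluginSpec, DesignedErrors,
                                Noisy, generate_dataset, materialize_mock_plugin)

root = Path("demo")
data, files = generate_dataset(DatasetSpec(500, 500, seed=1), root / "dataset")
for name, behaviour in [("designed-errors", DesignedErrors(fn=13, fp=13, seed=1)),
                        ("noisy-strong", Noisy(2.0, seed=2)),
                        ("noisy-weak", Noisy(1.0, seed=3))]:
    materialize_mock_plugin(MockPluginSpec(name, behaviour), data,
                            root / "plugins" / name)
```

then evaluate them:

```bash
priobench evaluate --input demo/dataset/dataset.csv --plugins demo/plugins \
    --metrics sensitivity,specificity,auroc,concordance_relative,mcc \
    --out demo/report.json --plots demo/plots
```

which prints

```
method               auroc  concordance_relative  mcc    sensitivity  specificity
designed-errors-1.0  0.974  0.974                 0.948  0.974        0.974
noisy-strong-1.0     0.914  0.839                 0.678  0.822        0.856
noisy-weak-1.0       0.751  0.678                 0.356  0.684        0.672
```

The designed-errors method lands exactly where its construction says it
must: 13/500 missed pathogenic variants and 13/500 false alarms give
sensitivity = specificity = 487/500 = 0.974.  The two noisy methods order
as their score separations dictate (AUROC 0.914 vs 0.751, against
closed-form expectations Φ(2/√2) ≈ 0.921 and Φ(1/√2) ≈ 0.760), and the
`--plots` directory holds one confusion-matrix and one ROC panel per
method.  `demo/report.json` contains the full-precision metrics, the
curves, and the manifest snapshot documenting what each number was
computed under; several such reports can be compared over time with
`priobench series report1.json report2.json ...`.

The same pipeline is available as a library call
(`priobench.run_pipeline(PipelineConfig(...))`), which is the natural
route when the selection predicate is a Python function or when methods
run as containers with a custom runner.

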