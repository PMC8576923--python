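# Methods

This note records the models, conventions and design choices behind
`priobench`, in the spirit of the methods documentation of statistical
packages: what is computed, under which assumptions, and where the
genuinely open choices were made.

## The evaluation model

A benchmark run evaluates prioritization methods as binary classifiers.
The truth is a labeled variant table — one row per variant with a unique
numeric identifier (UID), reference genome (RG), chromosome, 1-based
position, reference/alternative alleles over {A,C,G,T}, a variation type
(SNP when both alleles have length one, INDEL when the lengths differ),
and an expected class in {benign, pathogenic}.  Methods never see the
class column: they receive the variant data only and return one numeric
score per UID.  Scores are turned into predicted classes with the
method's own published cutoff, and predicted-vs-expected classes feed the
usual machinery (confusion matrix, ratio metrics, MCC, ROC/PR curves,
AUROC).

Equal-length multi-base substitutions (MNVs) do not fit the two-type
scheme and are rejected with a clear error (or dropped with a logged
count in skip mode) rather than silently typed.  Zero-length alleles are
likewise not accepted: every allele must be a non-empty ACGT string.

## Normalization conventions

* **Chromosomes** are normalized at extraction time: case-insensitive, a
  leading `chr` is stripped, `MT` maps to `M`; anything outside
  {1..22, X, Y, M} (alt contigs, out-of-range numbers) is an error.  The
  normalization is idempotent.
* **Reference genomes** are compared through a fixed alias table
  (hg19↔GRCh37, hg38↔GRCh38); unknown labels compare verbatim.
* **Alleles** are uppercased; lowercase input is accepted.
* **UIDs** are assigned consecutively from 0 in input order, making
  extraction deterministic and repeatable on the same file.
* **Positions** are 1-based (as in VCF); CSV inputs are read as 1-based.

Validation checks every constraint on every row and returns the complete
violation list (field, rule, offending row) instead of failing fast, so a
malformed input can be fixed in one pass.  The rule catalog splits
compound constraints (non-empty vs alphabet for each allele, integer vs
range for the position, value vs uniqueness for the UID), thirteen rules
in all; the TYPE↔allele-length consistency rule only fires on rows whose
alleles are otherwise valid, so each malformed fixture row triggers
exactly one rule.  Extraction itself normalizes structure and drops (or
refuses) unrepresentable records, but defers pure range violations such
as `POS < 1` to the validation stage — that keeps the pipeline's stage
order observable: invalid data fails at validation, before any
compatibility check or method invocation.

## Score interpretation and metrics

Classes are encoded benign→0, pathogenic→1.  For a method whose high
scores mean deleterious (`score_direction: higher`), a score **greater
than or equal to** the cutoff is called pathogenic.  The tie-goes-to-
pathogenic choice is deliberate: it is the clinically conservative
direction (fewer missed pathogenic variants), and it matches the ROC
sweep, which is anchored on "score ≥ threshold" — so the operating point
at any cutoff lies exactly on the method's ROC curve, including ties.
`score_direction: lower` is implemented by negating scores and cutoff and
reusing the same code path, so every property holds for both orientations
by construction.

The ROC sweep groups tied scores into a single step, uses the distinct
score values as thresholds, and anchors the curve at (0,0); the final
point is always (1,1).  AUROC is the trapezoidal area over this curve,
which equals the tie-corrected Mann–Whitney pairwise probability; both
implementations are kept (`auroc` and `auroc_mann_whitney`) and
cross-checked in the tests, alongside explicit O(n²) sweep oracles.  The
PR curve uses the same threshold grouping and reports (recall, precision)
per threshold without synthetic anchor points, so recall starts at its
lowest attained value.

Concordance is reported both as a count (tp + tn, the number of correctly
classified variants) and as a fraction of the dataset.  Ratio metrics
with a zero denominator (e.g. precision when nothing is predicted
pathogenic) return 0.0 with a logged warning rather than NaN; reports
stay numeric and the degenerate case is visible in the log.  Metrics are
stored at full precision; three-decimal rounding happens only in the
text-table rendering.

## Plugin contract

A plugin directory holds a `manifest.yaml` (schema enforced with
pydantic; a broken manifest aborts discovery, because a misconfigured
plugin tree is a setup bug, not data) and its scoring logic.  Discovery
is lexicographic by path, so plugin order — and therefore report column
order — is deterministic.  Selection is an arbitrary boolean function of
the manifest (the CLI accepts a restricted expression over manifest
fields, evaluated on a whitelisted AST with no calls, attributes or
subscripts).

Before anything runs, every selected manifest is checked against the
data: all variation types present must be supported and all
reference-genome labels must resolve to the manifest's genome.  Failures
enumerate plugin, dimension and observed-vs-supported values, and the run
stops before any method is invoked.

In-process plugins expose `process(variants) -> iterable[(uid, score)]`
and receive a copy of the variant table.  Container plugins declare a
file contract — input format and path, output format and path, read-only
bindings, command — and the bench serializes the variants, mounts the
paths, runs the command in a fresh container and parses the two-column
`uid,score` output.  The runtime sits behind a small runner interface:
the production implementation shells out to the `docker` CLI, and a stub
runner (used throughout the tests) executes a local script against the
same serialized files, so the whole contract is exercised without a
daemon.  UIDs are serialized as integers and must parse back as integers.

Plugins run concurrently under an explicit `jobs` bound using a thread
pool: in-process entry points are plain Python callables and container
entry points are subprocesses, so threads provide the concurrency cap
without pickling loaded plugin modules, and results are joined on UID —
the annotated table is independent of completion order by construction.
Each result set is validated (every UID exactly once, all scores finite)
before it becomes a score column named `<name>-<version>`.  A crashed
plugin fails the whole run with an error naming every failed plugin; a
benchmark with silently missing columns would be worse than a loud
failure.  An explicit `keep_going` mode instead drops the failed columns
and marks the report `partial`.

## Reports

A performance report carries, per method, the manifest snapshot the
numbers were computed under (name, version, cutoff and any override,
score direction, genome, database versions), the requested metrics, and
the requested summaries, plus dataset descriptors (size, class counts,
extractor, input digest) and a configuration echo.  JSON serialization is
schema-versioned, sorts keys, and deliberately excludes volatile run
facts (wall-clock timestamp, job count, output paths): identical inputs
and configuration produce byte-identical reports, which the tests check
directly.  The in-memory report object still records its creation time
for interactive use.  Cutoff overrides let a user re-evaluate a method at
different operating points; the override is recorded next to the
manifest's original cutoff, and the resulting operating points lie on the
method's ROC curve exactly.

`compile_release_series` generalizes trend analysis over any ordered
collection of labeled datasets (for example successive archive releases):
it requires the same method set in every report and emits a long-format
table of absolute and relative concordance per (release, method).
Fetching real archive releases is the user's task.

## Synthetic data and mock methods

The generator emulates the shape of a curated benchmark set — configured
class counts, a configurable INDEL fraction, one genome label — with
syntactic coordinates: chromosomes uniform over the catalog, positions
uniform in [1, 2.5×10⁸] (unique per site), random alleles.  No implemented
operation inspects sequence context, genome builds, or allele frequencies,
so this suffices for exercising the bench; it does **not** make the mock
scores biologically meaningful, and passing tests say nothing about how
any real method performs on real variants.  All draws come from a single
seeded generator and the written files are byte-stable per seed.  The
default benchmark scale used by the acceptance script, 500 benign + 500
pathogenic SNPs, mirrors the scale at which such comparisons are
typically demonstrated.

Mock methods exist to make downstream numbers checkable by construction:

* *designed-errors(fn, fp)* places exactly `fn` seeded-chosen pathogenic
  variants strictly on the benign side of the cutoff and `fp` benign ones
  on the pathogenic side (margin 0.5), fixing the confusion matrix —
  sensitivity must equal (P−fn)/P exactly.
* *noisy(separation s)* draws benign scores from N(0, 1) and pathogenic
  from N(s, 1) with the cutoff at the midpoint.  This is the simplest
  model with a closed-form expected AUROC, Φ(s/√2), which the acceptance
  script compares against the empirical value at n = 10,000 (the n at
  which the binomial-scale fluctuation of the AUROC estimate is well
  inside ±0.02).
* perfect/inverted oracles and constant scorers cover the boundary cases
  (all metrics 1; AUROC 0; degenerate one-point curves), and a crash-on
  behaviour plus container-stub variants (omitted UID, reversed output
  order) exercise the failure and join paths.

Mock scores are precomputed at materialization into a `scores.csv` inside
the plugin directory and merely read back at invocation, which makes
plugin output independent of invocation order and concurrency — the
property behind the byte-identical `jobs=1` vs `jobs=4` reports.

## Numerical choices and limitations

* Metric oracles in the test suite (element counting, explicit threshold
  sweeps, pairwise AUROC) share no code with the implementations; the
  agreement tolerance is 1e-12 where float division order can differ and
  exact where it cannot.
* Test and acceptance problem sizes (≤ 200 variants per oracle instance,
  1,000 random instances, 10,000-variant closed-form checks, 500/500
  pipeline datasets) were chosen so each check's statistical resolution
  comfortably exceeds the tolerance it asserts.
* Only binary labels are supported; multi-tier classifications (ACMG
  categories), structural variants, genotypes and sample columns are out
  of scope, as is coordinate liftover between genome builds — data must
  arrive on the genome the method supports.
* The VariSNP column layout is not standardized here beyond the
  documented `rs_id/chromosome/position/reference/alternative` export;
  other exports need an explicit column map through the generic CSV
  extractor.
* The docker runner mounts the output file read-write and everything else
  read-only, and does not manage image pulling, sandboxing or resource
  limits; those belong to the container runtime.
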