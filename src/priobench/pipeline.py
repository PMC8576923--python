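"""End-to-end benchmark orchestration and performance reporting.

:func:`run_pipeline` executes the stages in a fixed order — extract,
validate, strip labels, discover plugins, select, check compatibility,
invoke, validate scores, summarize — and returns a
:class:`PerformanceReport` holding, per method, the manifest metadata the
numbers were computed under, the requested metrics, and the requested
performance summaries (confusion matrix, ROC curve, PR curve).  Any stage
failure aborts the run with that stage's error, annotated with the stage
name.

Reports serialize to schema-versioned JSON with sorted keys and no
volatile fields, so identical inputs and configuration yield
byte-identical reports; display rounding (three decimals) happens only in
the text-table rendering.  :func:`compile_release_series` aggregates
reports over a labeled dataset series (e.g. successive database releases)
into a long-format concordance table for trend analysis.
"""

from __future__ import annotations

import ast
import hashlib
import json
import logging
import re
from contextlib import contextmanager
from dataclasses import dataclass, field as dataclass_field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Callable, Mapping, Sequence

import pandas as pd

from . import metrics as _metrics
from .core_data import (
    EvaluationData,
    strip_classification,
    validate_evaluation_data,
)
from .errors import (
    ConfigurationError,
    PriobenchError,
    SeriesError,
    ValidationFailedError,
)
from .extractors import get_extractor
from .metrics import (
    ConfusionMatrix,
    PrCurve,
    RocCurve,
    METRIC_NAMES,
    SUMMARY_NAMES,
    apply_cutoff,
    auroc,
    confusion_matrix,
    encode_classes,
    metric,
    pr_curve,
    roc_curve,
)
from .plugins import (
    ContainerRunner,
    Plugin,
    PluginManifest,
    check_compatibility,
    discover_plugins,
    run_plugins,
    select_plugins,
)

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1

DEFAULT_METRICS = METRIC_NAMES + ("auroc",)
DEFAULT_SUMMARIES = ("confusion_matrix", "roc_curve")


# --- selection expressions -------------------------------------------------

_ALLOWED_NODES = (
    ast.Expression, ast.BoolOp, ast.And, ast.Or, ast.UnaryOp, ast.Not,
    ast.USub, ast.Compare, ast.Eq, ast.NotEq, ast.Lt, ast.LtE, ast.Gt,
    ast.GtE, ast.In, ast.NotIn, ast.Name, ast.Load, ast.Constant,
    ast.List, ast.Tuple, ast.Set,
)


def compile_selection(expression: str) -> Callable[[PluginManifest], bool]:
    """Compile a restricted boolean expression over manifest fields.

    Names resolve to manifest fields (``name``, ``version``,
    ``supported_variation_types``, ``cutoff``, ``score_direction``,
    ``reference_genome``, ``databases``); only boolean logic, comparisons
    and membership tests are allowed — no calls, attributes or subscripts.
    Example: ``"'SNP' in supported_variation_types and cutoff >= 0.5"``.
    """
    try:
        tree = ast.parse(expression, mode="eval")
    except SyntaxError as exc:
        raise ConfigurationError(
            f"invalid selection expression {expression!r}: {exc}"
        ) from exc
    for node in ast.walk(tree):
        if not isinstance(node, _ALLOWED_NODES):
            raise ConfigurationError(
                f"selection expression {expression!r} uses disallowed "
                f"syntax ({type(node).__name__})"
            )
    code = compile(tree, "<selection>", "eval")

    def predicate(manifest: PluginManifest) -> bool:
        env = manifest.model_dump()
        env.pop("entry_point", None)
        try:
            return bool(eval(code, {"__builtins__": {}}, env))
        except NameError as exc:
            raise ConfigurationError(
                f"selection expression {expression!r}: {exc}"
            ) from exc

    return predicate


def _as_predicate(selection) -> Callable[[PluginManifest], bool]:
    if selection is None:
        return lambda manifest: True
    if callable(selection):
        return selection
    if isinstance(selection, str):
        return compile_selection(selection)
    raise ConfigurationError(
        f"selection must be a callable, an expression string or None, "
        f"got {type(selection).__name__}"
    )


# --- configuration ---------------------------------------------------------

@dataclass
class PipelineConfig:
    """Everything one benchmark run needs.

    ``selection`` is a callable over :class:`PluginManifest`, a restricted
    expression string, or None (all plugins).  ``cutoff_overrides`` maps a
    plugin name (or name-version column label) to a replacement cutoff.
    Execution-only knobs (``jobs``, ``keep_going``, ``workdir``) never
    enter the report, so they cannot change its bytes.
    """

    input: str | Path
    plugin_dir: str | Path
    extractor: str = "csv"
    extractor_options: dict[str, Any] = dataclass_field(default_factory=dict)
    selection: Callable[[PluginManifest], bool] | str | None = None
    metrics: Sequence[str] = DEFAULT_METRICS
    summaries: Sequence[str] = DEFAULT_SUMMARIES
    cutoff_overrides: dict[str, float] = dataclass_field(default_factory=dict)
    jobs: int = 1
    keep_going: bool = False
    workdir: str | Path | None = None
    report_label: str | None = None

    def validate(self) -> None:
        allowed_metrics = set(METRIC_NAMES) | {"auroc"}
        unknown = set(self.metrics) - allowed_metrics
        if unknown:
            raise ConfigurationError(
                f"unknown metric(s) {sorted(unknown)}; "
                f"supported: {sorted(allowed_metrics)}"
            )
        unknown = set(self.summaries) - set(SUMMARY_NAMES)
        if unknown:
            raise ConfigurationError(
                f"unknown summary(ies) {sorted(unknown)}; "
                f"supported: {sorted(SUMMARY_NAMES)}"
            )
        if self.jobs < 1:
            raise ConfigurationError("jobs must be >= 1")

    def echo(self) -> dict:
        """Reproducibility echo embedded in the report (no execution knobs)."""
        if self.selection is None:
            selection = "all"
        elif isinstance(self.selection, str):
            selection = self.selection
        else:
            selection = "<callable>"
        return {
            "input": str(self.input),
            "extractor": self.extractor,
            "extractor_options": dict(self.extractor_options),
            "selection": selection,
            "metrics": list(self.metrics),
            "summaries": list(self.summaries),
            "cutoff_overrides": dict(self.cutoff_overrides),
        }


# --- report model ----------------------------------------------------------

_SUMMARY_TYPES = {
    "confusion_matrix": ConfusionMatrix,
    "roc_curve": RocCurve,
    "pr_curve": PrCurve,
}


@dataclass
class PluginResult:
    """Metrics and summaries for one method, with its manifest snapshot."""

    name: str
    version: str
    cutoff: float
    cutoff_override: float | None
    score_direction: str
    reference_genome: str
    databases: dict[str, str]
    metrics: dict[str, float]
    summaries: dict[str, Any]

    @property
    def column_name(self) -> str:
        return f"{self.name}-{self.version}"

    @property
    def effective_cutoff(self) -> float:
        return self.cutoff if self.cutoff_override is None else self.cutoff_override

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "version": self.version,
            "cutoff": self.cutoff,
            "cutoff_override": self.cutoff_override,
            "score_direction": self.score_direction,
            "reference_genome": self.reference_genome,
            "databases": dict(self.databases),
            "metrics": {k: v for k, v in sorted(self.metrics.items())},
            "summaries": {
                k: v.to_dict() for k, v in sorted(self.summaries.items())
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PluginResult":
        return cls(
            name=d["name"], version=d["version"], cutoff=d["cutoff"],
            cutoff_override=d.get("cutoff_override"),
            score_direction=d["score_direction"],
            reference_genome=d["reference_genome"],
            databases=dict(d.get("databases", {})),
            metrics=dict(d["metrics"]),
            summaries={
                k: _SUMMARY_TYPES[k].from_dict(v)
                for k, v in d.get("summaries", {}).items()
            },
        )


@dataclass
class PerformanceReport:
    """Per-plugin performance plus the provenance to interpret it."""

    dataset: dict[str, Any]
    plugins: list[PluginResult]
    config: dict[str, Any]
    label: str | None = None
    partial: bool = False
    failed_plugins: list[str] = dataclass_field(default_factory=list)
    schema_version: int = REPORT_SCHEMA_VERSION
    created_at: str | None = None   # informational; not serialized

    def plugin(self, column_name: str) -> PluginResult:
        for result in self.plugins:
            if result.column_name == column_name or result.name == column_name:
                return result
        raise KeyError(column_name)

    def to_dict(self) -> dict:
        return {
            "schema_version": self.schema_version,
            "label": self.label,
            "dataset": dict(self.dataset),
            "config": dict(self.config),
            "partial": self.partial,
            "failed_plugins": list(self.failed_plugins),
            "plugins": [p.to_dict() for p in self.plugins],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PerformanceReport":
        return cls(
            dataset=dict(d["dataset"]),
            plugins=[PluginResult.from_dict(p) for p in d["plugins"]],
            config=dict(d.get("config", {})),
            label=d.get("label"),
            partial=bool(d.get("partial", False)),
            failed_plugins=list(d.get("failed_plugins", [])),
            schema_version=int(d.get("schema_version", REPORT_SCHEMA_VERSION)),
        )


# --- pipeline --------------------------------------------------------------

@contextmanager
def _stage(name: str):
    try:
        yield
    except PriobenchError as exc:
        exc.add_note(f"pipeline stage: {name}")
        logger.error("stage %s failed: %s", name, exc)
        raise


def _input_digest(path: str | Path) -> str:
    return "sha256:" + hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _plugin_result(
    plugin: Plugin,
    scores,
    y_true,
    config: PipelineConfig,
    cutoff_override: float | None,
) -> PluginResult:
    m = plugin.manifest
    effective = m.cutoff if cutoff_override is None else cutoff_override
    y_pred = apply_cutoff(scores, effective, m.score_direction)
    cm = confusion_matrix(y_true, y_pred)

    roc = None

    def get_roc():
        nonlocal roc
        if roc is None:
            roc = roc_curve(y_true, scores, m.score_direction)
        return roc

    metric_values: dict[str, float] = {}
    for name in config.metrics:
        if name == "auroc":
            metric_values[name] = auroc(get_roc())
        else:
            metric_values[name] = float(metric(cm, name))

    summaries: dict[str, Any] = {}
    for name in config.summaries:
        if name == "confusion_matrix":
            summaries[name] = cm
        elif name == "roc_curve":
            summaries[name] = get_roc()
        elif name == "pr_curve":
            summaries[name] = pr_curve(y_true, scores, m.score_direction)

    return PluginResult(
        name=m.name, version=m.version, cutoff=m.cutoff,
        cutoff_override=cutoff_override,
        score_direction=m.score_direction,
        reference_genome=m.reference_genome,
        databases=dict(m.databases),
        metrics=metric_values, summaries=summaries,
    )


def _override_for(plugin: Plugin, overrides: Mapping[str, float]) -> float | None:
    if plugin.column_name in overrides:
        return float(overrides[plugin.column_name])
    if plugin.manifest.name in overrides:
        return float(overrides[plugin.manifest.name])
    return None


def run_pipeline(
    config: PipelineConfig,
    *,
    runner: ContainerRunner | None = None,
) -> PerformanceReport:
    """Execute one full benchmark run and return its performance report."""
    with _stage("configuration"):
        config.validate()

    with _stage("extraction"):
        extractor = get_extractor(config.extractor)
        data: EvaluationData = extractor(config.input, **config.extractor_options)
        logger.info("extracted %d entries from %s", len(data), config.input)

    with _stage("validation"):
        validation = validate_evaluation_data(data)
        if not validation.ok:
            raise ValidationFailedError(validation)
        variant_data = strip_classification(data)
        logger.info("validated %d entries", len(data))

    with _stage("discovery"):
        plugins = discover_plugins(config.plugin_dir)
        logger.info("discovered %d plugin(s) under %s",
                    len(plugins), config.plugin_dir)

    with _stage("selection"):
        selected = select_plugins(plugins, _as_predicate(config.selection))
        logger.info("selected %d plugin(s): %s",
                    len(selected), [p.column_name for p in selected])
        known = {p.manifest.name for p in selected}
        known |= {p.column_name for p in selected}
        stray = set(config.cutoff_overrides) - known
        if stray:
            raise ConfigurationError(
                f"cutoff override(s) for unselected plugin(s): {sorted(stray)}"
            )

    with _stage("compatibility"):
        check_compatibility(selected, variant_data).raise_if_failed()

    with _stage("invocation"):
        annotated, failed = run_plugins(
            selected, variant_data, config.jobs,
            runner=runner, workdir=config.workdir,
            keep_going=config.keep_going,
        )
        logger.info("scored %d variants with %d plugin(s)%s",
                    len(annotated), len(selected) - len(failed),
                    f" ({len(failed)} failed)" if failed else "")

    with _stage("report"):
        y_true = encode_classes(list(data.table["CLASS"]))
        counts = data.class_counts()
        results = [
            _plugin_result(
                plugin, annotated[plugin.column_name].to_numpy(), y_true,
                config, _override_for(plugin, config.cutoff_overrides),
            )
            for plugin in selected
            if plugin.column_name not in failed
        ]
        label = config.report_label or Path(str(config.input)).stem
        return PerformanceReport(
            dataset={
                "n": int(len(data)),
                "n_benign": counts["benign"],
                "n_pathogenic": counts["pathogenic"],
                "extractor": config.extractor,
                "input": str(config.input),
                "input_digest": _input_digest(config.input),
            },
            plugins=results,
            config=config.echo(),
            label=label,
            partial=bool(failed),
            failed_plugins=list(failed),
            created_at=datetime.now(timezone.utc).isoformat(),
        )


# --- rendering -------------------------------------------------------------

def render_report(report: PerformanceReport, format: str = "json") -> str:
    """Serialize a report as stable JSON or a method-by-metric text table.

    JSON keys are sorted and volatile run facts (wall-clock time,
    execution knobs) are never included, so identical runs render to
    identical bytes.  The text table rounds to three decimals for display;
    full precision lives only in the JSON.
    """
    if format == "json":
        return json.dumps(report.to_dict(), sort_keys=True, indent=2,
                          allow_nan=False) + "\n"
    if format == "text-table":
        metric_names = sorted({m for p in report.plugins for m in p.metrics})
        header = ["method"] + metric_names
        rows = [
            [p.column_name] + [
                f"{p.metrics[m]:.3f}" if m in p.metrics else ""
                for m in metric_names
            ]
            for p in report.plugins
        ]
        widths = [max(len(r[i]) for r in [header] + rows)
                  for i in range(len(header))]
        lines = [
            "  ".join(cell.ljust(w) for cell, w in zip(r, widths)).rstrip()
            for r in [header] + rows
        ]
        return "\n".join(lines) + "\n"
    raise ConfigurationError(f"unknown report format {format!r}")


def parse_report(text: str) -> PerformanceReport:
    """Inverse of JSON :func:`render_report`."""
    return PerformanceReport.from_dict(json.loads(text))


def load_report(path: str | Path) -> PerformanceReport:
    return parse_report(Path(path).read_text())


# --- plotting --------------------------------------------------------------

def _slug(name: str) -> str:
    return re.sub(r"[^A-Za-z0-9._-]+", "-", name)


def plot_summaries(
    report: PerformanceReport,
    outdir: str | Path,
    summaries: Sequence[str] | None = None,
) -> list[Path]:
    """Write one panel per plugin and requested summary; return the files.

    Filenames are deterministic (``<method>_<summary>.png``).  A requested
    summary that a plugin's report does not contain is logged and skipped;
    plotting problems are never fatal to a pipeline run.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    requested = list(summaries) if summaries is not None else list(DEFAULT_SUMMARIES)
    written: list[Path] = []

    for result in report.plugins:
        for kind in requested:
            if kind not in result.summaries:
                logger.warning("plugin %s has no %s summary; skipping plot",
                               result.column_name, kind)
                continue
            path = outdir / f"{_slug(result.column_name)}_{kind}.png"
            fig, axis = plt.subplots(figsize=(4.5, 4))
            try:
                if kind == "confusion_matrix":
                    _plot_confusion(axis, result)
                elif kind == "roc_curve":
                    _plot_roc(axis, result)
                elif kind == "pr_curve":
                    _plot_pr(axis, result)
                fig.tight_layout()
                fig.savefig(path, dpi=100)
                written.append(path)
            except Exception as exc:  # plotting is best-effort by contract
                logger.warning("could not plot %s for %s: %s",
                               kind, result.column_name, exc)
            finally:
                plt.close(fig)
    return written


def _plot_confusion(axis, result: PluginResult) -> None:
    cm: ConfusionMatrix = result.summaries["confusion_matrix"]
    grid = [[cm.tn, cm.fp], [cm.fn, cm.tp]]
    axis.imshow(grid, cmap="Blues")
    for i in range(2):
        for j in range(2):
            axis.text(j, i, str(grid[i][j]), ha="center", va="center")
    axis.set_xticks([0, 1], ["benign", "pathogenic"])
    axis.set_yticks([0, 1], ["benign", "pathogenic"])
    axis.set_xlabel("predicted")
    axis.set_ylabel("expected")
    axis.set_title(result.column_name)


def _plot_roc(axis, result: PluginResult) -> None:
    roc: RocCurve = result.summaries["roc_curve"]
    axis.plot(roc.fpr, roc.tpr, drawstyle="steps-post")
    axis.plot([0, 1], [0, 1], linestyle="--", linewidth=0.8, color="grey")
    value = result.metrics.get("auroc", auroc(roc))
    axis.annotate(f"AUROC = {value:.6f}", xy=(0.45, 0.08),
                  xycoords="axes fraction")
    axis.set_xlabel("false-positive rate (1 - specificity)")
    axis.set_ylabel("true-positive rate (sensitivity)")
    axis.set_title(result.column_name)


def _plot_pr(axis, result: PluginResult) -> None:
    pr: PrCurve = result.summaries["pr_curve"]
    axis.plot(pr.recall, pr.precision, drawstyle="steps-post")
    axis.set_xlabel("recall")
    axis.set_ylabel("precision")
    axis.set_ylim(0, 1.05)
    axis.set_title(result.column_name)


# --- dataset series --------------------------------------------------------

def compile_release_series(
    reports: Sequence[PerformanceReport],
    labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Aggregate reports over a dataset series into a concordance table.

    Returns a long-format frame with one row per (release, method):
    columns ``release``, ``plugin``, ``n``, ``concordance_count``,
    ``concordance_relative``.  All reports must cover the same plugin set.
    """
    if not reports:
        raise SeriesError("need at least one report")
    if labels is not None and len(labels) != len(reports):
        raise SeriesError("labels must match reports one-to-one")

    plugin_sets = [tuple(sorted(p.column_name for p in r.plugins))
                   for r in reports]
    if len(set(plugin_sets)) != 1:
        raise SeriesError(
            f"plugin sets differ across reports: {sorted(set(plugin_sets))}"
        )

    rows = []
    for i, report in enumerate(reports):
        release = labels[i] if labels is not None else (report.label or str(i))
        n = int(report.dataset["n"])
        for result in report.plugins:
            count = result.metrics.get("concordance_count")
            if count is None and "confusion_matrix" in result.summaries:
                cm = result.summaries["confusion_matrix"]
                count = float(cm.tp + cm.tn)
            if count is None:
                raise SeriesError(
                    f"report {release!r} has neither a concordance_count "
                    f"metric nor a confusion_matrix summary for "
                    f"{result.column_name}"
                )
            relative = result.metrics.get("concordance_relative", count / n)
            rows.append({
                "release": release, "plugin": result.column_name, "n": n,
                "concordance_count": int(count),
                "concordance_relative": float(relative),
            })
    return pd.DataFrame(rows)
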