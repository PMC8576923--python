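"""Declarative plugin system for prioritization methods.

A plugin is a directory holding a ``manifest.yaml`` plus its integration
code.  The manifest declares everything the pipeline needs to know about a
method without running it: name, version, supported variation types,
score cutoff (and which side of the cutoff is pathogenic), reference
genome, the versions of backing databases, and an entry point.

Two entry-point modes exist:

* ``python`` — a script in the plugin directory exposing
  ``process(variants: pandas.DataFrame) -> iterable[(uid, score)]``,
  executed in the pipeline's own interpreter (convenient for methods under
  local development);
* ``container`` — an image reference plus a file contract: the pipeline
  serializes the variant data into the declared input format, mounts
  input/output paths and any static bindings, runs the declared command in
  a fresh container, and parses the declared output file into (uid, score)
  pairs.  The container runtime sits behind an injectable
  :class:`ContainerRunner`, so the whole serialize/mount/run/parse contract
  is testable with a stub and the real runner is only needed when actual
  images are evaluated.

Manifest schema (``manifest-version: 1``)::

    manifest-version: 1
    name: my-method
    version: "1.0"
    supported-variation-types: [SNP, INDEL]
    cutoff: 0.5
    score-direction: higher        # optional; higher|lower
    reference-genome: GRCh37
    databases: {training-set: "2021-01"}
    entry-point:
      mode: python
      file: score.py
    # -- or --
    entry-point:
      mode: container
      image: registry/method:1.0
      input-format: vcf            # vcf | csv
      input-path: /data/input.vcf
      output-format: csv          # two columns: uid,score
      output-path: /data/output.csv
      bindings: {resources/db.tsv: /db/db.tsv}
      command: score --in /data/input.vcf --out /data/output.csv
"""

from __future__ import annotations

import importlib.util
import logging
import math
import shlex
import shutil
import subprocess
import sys
import tempfile
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from typing import Annotated, Callable, Iterable, Literal, Sequence, Union

import pandas as pd
import yaml
from pydantic import (
    BaseModel,
    ConfigDict,
    Field,
    ValidationError,
    field_validator,
)

from .core_data import VariantData, resolve_genome
from .errors import (
    CompatibilityError,
    ContainerError,
    ManifestError,
    PluginCrashError,
    RuntimeUnavailableError,
    ScoreValidationError,
    SelectionError,
)
from .extractors import write_csv, write_vcf

logger = logging.getLogger(__name__)

MANIFEST_FILENAME = "manifest.yaml"


class PythonEntryPoint(BaseModel):
    model_config = ConfigDict(populate_by_name=True, extra="forbid")

    mode: Literal["python"]
    file: str


class ContainerEntryPoint(BaseModel):
    model_config = ConfigDict(populate_by_name=True, extra="forbid")

    mode: Literal["container"]
    image: str
    input_format: Literal["vcf", "csv"] = Field(alias="input-format")
    input_path: str = Field(alias="input-path")
    output_format: Literal["csv"] = Field(alias="output-format")
    output_path: str = Field(alias="output-path")
    bindings: dict[str, str] = Field(default_factory=dict)
    command: str | list[str]

    def command_argv(self) -> list[str]:
        if isinstance(self.command, str):
            return shlex.split(self.command)
        return list(self.command)


EntryPoint = Annotated[
    Union[PythonEntryPoint, ContainerEntryPoint], Field(discriminator="mode")
]


class PluginManifest(BaseModel):
    """Declarative method metadata parsed from ``manifest.yaml``."""

    model_config = ConfigDict(populate_by_name=True, extra="forbid")

    manifest_version: int = Field(alias="manifest-version", default=1)
    name: str = Field(min_length=1)
    version: str = "unversioned"
    supported_variation_types: list[Literal["SNP", "INDEL"]] = Field(
        alias="supported-variation-types", min_length=1
    )
    cutoff: float
    score_direction: Literal["higher", "lower"] = Field(
        alias="score-direction", default="higher"
    )
    reference_genome: str = Field(alias="reference-genome", min_length=1)
    databases: dict[str, str] = Field(default_factory=dict)
    entry_point: EntryPoint = Field(alias="entry-point")

    @field_validator("version", mode="before")
    @classmethod
    def _version_to_str(cls, v):
        return str(v)

    @field_validator("cutoff")
    @classmethod
    def _cutoff_finite(cls, v: float) -> float:
        if not math.isfinite(v):
            raise ValueError("cutoff must be a finite number")
        return v


@dataclass(frozen=True)
class Plugin:
    """A discovered plugin: validated manifest plus its root directory."""

    manifest: PluginManifest
    root: Path

    @property
    def name(self) -> str:
        return self.manifest.name

    @property
    def column_name(self) -> str:
        """Name of this plugin's score column in the annotated table."""
        return f"{self.manifest.name}-{self.manifest.version}"


@dataclass(frozen=True)
class ScoredVariant:
    """One (UID, score) pair returned by a plugin's processing logic."""

    uid: int
    score: float


def load_manifest(path: str | Path) -> PluginManifest:
    """Parse and schema-validate one manifest file."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except (OSError, yaml.YAMLError) as exc:
        raise ManifestError(f"{path}: cannot read manifest: {exc}") from exc
    if not isinstance(raw, dict):
        raise ManifestError(f"{path}: manifest must be a YAML mapping")
    try:
        return PluginManifest.model_validate(raw)
    except ValidationError as exc:
        problems = "; ".join(
            f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}"
            for err in exc.errors()
        )
        raise ManifestError(f"{path}: invalid manifest ({problems})") from exc


def discover_plugins(directory: str | Path) -> list[Plugin]:
    """Find plugins under ``directory`` by their manifest files.

    The directory itself and each immediate subdirectory containing a
    ``manifest.yaml`` yields one plugin, in lexicographic path order.  A
    broken manifest aborts discovery: a misconfigured plugin tree is a
    setup bug, not data to skip over.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise ManifestError(f"plugin directory {directory} does not exist")
    candidates = [directory] + sorted(
        p for p in directory.iterdir() if p.is_dir()
    )
    plugins = []
    for root in candidates:
        manifest_path = root / MANIFEST_FILENAME
        if manifest_path.is_file():
            plugins.append(Plugin(manifest=load_manifest(manifest_path), root=root))
    return plugins


def select_plugins(
    plugins: Sequence[Plugin], predicate: Callable[[PluginManifest], bool]
) -> list[Plugin]:
    """Order-preserving filter by a boolean function over the manifest."""
    selected = [p for p in plugins if predicate(p.manifest)]
    if not selected:
        raise SelectionError(
            f"selection matched none of the {len(plugins)} discovered plugin(s)"
        )
    return selected


# --- compatibility ---------------------------------------------------------

@dataclass(frozen=True)
class CompatibilityFailure:
    plugin: str
    dimension: Literal["variation_type", "reference_genome"]
    observed: tuple[str, ...]
    supported: tuple[str, ...]

    def __str__(self) -> str:
        return (f"{self.plugin}: {self.dimension} mismatch "
                f"(data has {list(self.observed)}, "
                f"plugin supports {list(self.supported)})")


@dataclass
class CompatibilityReport:
    failures: list[CompatibilityFailure] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.failures

    def raise_if_failed(self) -> None:
        if not self.ok:
            raise CompatibilityError(self.failures)


def check_compatibility(
    plugins: Sequence[Plugin], data: VariantData
) -> CompatibilityReport:
    """Compare each manifest's supported types and genome with the data.

    A plugin passes iff every variation type present in the data is
    supported and every reference-genome label in the data resolves (via
    the alias table) to the manifest's genome.
    """
    data_types = data.variation_types()
    data_genomes = data.reference_genomes()
    report = CompatibilityReport()
    for plugin in plugins:
        m = plugin.manifest
        unsupported = data_types - set(m.supported_variation_types)
        if unsupported:
            report.failures.append(CompatibilityFailure(
                plugin=plugin.column_name, dimension="variation_type",
                observed=tuple(sorted(data_types)),
                supported=tuple(m.supported_variation_types),
            ))
        plugin_genome = resolve_genome(m.reference_genome)
        if data_genomes - {plugin_genome}:
            report.failures.append(CompatibilityFailure(
                plugin=plugin.column_name, dimension="reference_genome",
                observed=tuple(sorted(data_genomes)),
                supported=(plugin_genome,),
            ))
    return report


# --- score validation ------------------------------------------------------

def validate_scores(
    data: VariantData, scores: Iterable[ScoredVariant], *,
    plugin: str | None = None,
) -> list[ScoredVariant]:
    """Ensure every UID got exactly one finite numerical score.

    Returns the scores unchanged on success; raises
    :class:`ScoreValidationError` listing missing, unknown, duplicated and
    non-finite entries separately.
    """
    scores = list(scores)
    expected = set(data.uids)
    seen: set[int] = set()
    duplicated: set[int] = set()
    non_finite: set[int] = set()
    for sv in scores:
        uid = int(sv.uid)
        if uid in seen:
            duplicated.add(uid)
        seen.add(uid)
        try:
            value = float(sv.score)
        except (TypeError, ValueError):
            value = float("nan")
        if not math.isfinite(value):
            non_finite.add(uid)
    missing = expected - seen
    unknown = seen - expected
    if missing or unknown or duplicated or non_finite:
        raise ScoreValidationError(
            missing=missing, unknown=unknown, duplicated=duplicated,
            non_finite=non_finite, plugin=plugin,
        )
    return scores


# --- invocation ------------------------------------------------------------

_module_counter = 0


def _load_script(path: Path):
    global _module_counter
    _module_counter += 1
    name = f"_priobench_plugin_{_module_counter}"
    spec = importlib.util.spec_from_file_location(name, path)
    if spec is None or spec.loader is None:
        raise ImportError(f"cannot load {path}")
    module = importlib.util.module_from_spec(spec)
    sys.modules[name] = module
    try:
        spec.loader.exec_module(module)
    finally:
        sys.modules.pop(name, None)
    return module


def _as_scored(result) -> list[ScoredVariant]:
    if isinstance(result, dict):
        result = result.items()
    return [ScoredVariant(uid=int(u), score=float(s)) for u, s in result]


def invoke_in_process(plugin: Plugin, data: VariantData) -> list[ScoredVariant]:
    """Load the plugin's Python entry point and run its ``process``.

    The script receives a copy of the variant table, so plugins cannot
    mutate pipeline state.  Any failure is wrapped in
    :class:`PluginCrashError` naming the plugin.
    """
    entry = plugin.manifest.entry_point
    if not isinstance(entry, PythonEntryPoint):
        raise PluginCrashError(
            f"plugin {plugin.name!r} has no python entry point"
        )
    script = plugin.root / entry.file
    try:
        module = _load_script(script)
        process = getattr(module, "process", None)
        if not callable(process):
            raise AttributeError(
                f"{script} does not define a callable 'process(variants)'"
            )
        result = process(data.table.copy(deep=True))
        return _as_scored(result)
    except Exception as exc:
        raise PluginCrashError(
            f"plugin {plugin.name!r} failed: {type(exc).__name__}: {exc}"
        ) from exc


@dataclass(frozen=True)
class ContainerJob:
    """Everything a container runner needs for one invocation."""

    image: str
    command: list[str]
    input_host: Path
    input_container: str
    output_host: Path
    output_container: str
    bindings: list[tuple[Path, str]]   # (host path, container path), read-only
    plugin_root: Path


class ContainerRunner:
    """Interface for executing one container job; see :class:`DockerCliRunner`."""

    def run(self, job: ContainerJob) -> None:  # pragma: no cover - interface
        raise NotImplementedError


class DockerCliRunner(ContainerRunner):
    """Run jobs through the ``docker`` command-line client.

    Input and binding paths are mounted read-only, the output file
    read-write; the container is removed after the run.
    """

    def __init__(self, executable: str = "docker") -> None:
        self.executable = executable

    def run(self, job: ContainerJob) -> None:
        if shutil.which(self.executable) is None:
            raise RuntimeUnavailableError(
                f"container runtime {self.executable!r} not found on PATH"
            )
        job.output_host.touch()
        argv = [self.executable, "run", "--rm",
                "-v", f"{job.input_host}:{job.input_container}:ro",
                "-v", f"{job.output_host}:{job.output_container}"]
        for host, container in job.bindings:
            argv += ["-v", f"{host}:{container}:ro"]
        argv.append(job.image)
        argv += job.command
        proc = subprocess.run(argv, capture_output=True, text=True)
        if proc.returncode != 0:
            raise ContainerError(
                f"image {job.image} exited with {proc.returncode}; "
                f"stderr: {proc.stderr.strip()[-2000:]}"
            )


def _serialize_input(data: VariantData, fmt: str, path: Path) -> None:
    if fmt == "vcf":
        write_vcf(data, path, style="plain")
    elif fmt == "csv":
        write_csv(data, path)
    else:  # unreachable: manifest schema restricts the vocabulary
        raise ContainerError(f"unsupported container input format {fmt!r}")


def _parse_scores_csv(path: Path) -> list[ScoredVariant]:
    frame = pd.read_csv(path)
    cols = [c.strip().lower() for c in frame.columns]
    if cols[:2] != ["uid", "score"]:
        raise ContainerError(
            f"{path}: expected a two-column uid,score file, got columns {cols}"
        )
    frame.columns = cols
    return [ScoredVariant(uid=int(r.uid), score=float(r.score))
            for r in frame.itertuples(index=False)]


def invoke_container(
    plugin: Plugin,
    data: VariantData,
    workdir: str | Path | None = None,
    runner: ContainerRunner | None = None,
) -> list[ScoredVariant]:
    """Execute a container-mode plugin through its file contract.

    Serializes the variant data into the manifest's input format, prepares
    the mount list (manifest bindings resolve relative to the plugin
    directory), hands the job to the runner, and parses the declared
    output file.
    """
    entry = plugin.manifest.entry_point
    if not isinstance(entry, ContainerEntryPoint):
        raise ContainerError(f"plugin {plugin.name!r} has no container entry point")
    runner = runner or DockerCliRunner()
    if workdir is None:
        workdir = Path(tempfile.mkdtemp(prefix=f"priobench-{plugin.name}-"))
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)

    input_host = workdir / f"input.{entry.input_format}"
    output_host = workdir / "output.csv"
    _serialize_input(data, entry.input_format, input_host)

    bindings = []
    for host, container in entry.bindings.items():
        host_path = Path(host)
        if not host_path.is_absolute():
            host_path = plugin.root / host_path
        bindings.append((host_path, container))

    job = ContainerJob(
        image=entry.image, command=entry.command_argv(),
        input_host=input_host, input_container=entry.input_path,
        output_host=output_host, output_container=entry.output_path,
        bindings=bindings, plugin_root=plugin.root,
    )
    runner.run(job)
    if not output_host.is_file() or output_host.stat().st_size == 0:
        raise ContainerError(
            f"plugin {plugin.name!r} produced no output file at {output_host}"
        )
    try:
        return _parse_scores_csv(output_host)
    except (pd.errors.ParserError, ValueError) as exc:
        raise ContainerError(
            f"plugin {plugin.name!r}: cannot parse output: {exc}"
        ) from exc


def _invoke(plugin: Plugin, data: VariantData,
            runner: ContainerRunner | None,
            workdir: Path | None) -> list[ScoredVariant]:
    if isinstance(plugin.manifest.entry_point, PythonEntryPoint):
        scores = invoke_in_process(plugin, data)
    else:
        sub = None if workdir is None else workdir / plugin.column_name
        scores = invoke_container(plugin, data, workdir=sub, runner=runner)
    return validate_scores(data, scores, plugin=plugin.column_name)


def run_plugins(
    plugins: Sequence[Plugin],
    data: VariantData,
    jobs: int = 1,
    *,
    runner: ContainerRunner | None = None,
    workdir: str | Path | None = None,
    keep_going: bool = False,
) -> tuple[pd.DataFrame, list[str]]:
    """Run plugins (up to ``jobs`` concurrently) and annotate the variants.

    Returns the variant table with one validated score column per plugin
    (named ``<name>-<version>``), joined on UID so the result is
    independent of completion order, plus the list of failed plugin column
    names (empty unless ``keep_going``).  Without ``keep_going`` the first
    plugin error propagates after all invocations finish, annotated with
    every failed plugin.
    """
    if jobs < 1:
        raise ValueError("jobs must be >= 1")
    if len(data) == 0:
        raise ValueError("cannot evaluate plugins on empty variant data")
    if not plugins:
        raise SelectionError("no plugins to run")
    workdir = None if workdir is None else Path(workdir)

    results: dict[str, list[ScoredVariant]] = {}
    errors: list[tuple[str, Exception]] = []
    with ThreadPoolExecutor(max_workers=jobs) as pool:
        futures = {
            pool.submit(_invoke, plugin, data, runner, workdir): plugin
            for plugin in plugins
        }
        for future, plugin in futures.items():
            try:
                results[plugin.column_name] = future.result()
            except Exception as exc:
                errors.append((plugin.column_name, exc))
                logger.error("plugin %s failed: %s", plugin.column_name, exc)

    failed = [name for name, _ in errors]
    if errors and not keep_going:
        first = errors[0][1]
        first.add_note(f"failed plugin(s): {', '.join(failed)}")
        raise first

    annotated = data.table.copy(deep=True)
    for plugin in plugins:
        column = plugin.column_name
        if column in results:
            lookup = {sv.uid: sv.score for sv in results[column]}
            annotated[column] = annotated["UID"].map(lookup).astype(float)
    return annotated, failed
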