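"""Synthetic evaluation datasets and mock prioritization plugins.

Everything the test bench needs to exercise itself offline is generated
here: seeded labeled variant datasets (written in the same VCF/CSV
dialects the extractors read, including a ClinVar-flavoured rendition) and
mock plugins with *designed* score behaviour, so downstream performance
numbers are fixed by construction and can be checked exactly.

Mock behaviours
---------------
``PerfectOracle``      every variant scored on the correct side of the cutoff
``InvertedOracle``     every variant scored on the wrong side
``Constant(c)``        the same score for every variant
``DesignedErrors``     exactly ``fn`` pathogenic variants scored on the
                       benign side and ``fp`` benign ones on the pathogenic
                       side (seeded choice) — the confusion matrix is fixed
                       by construction
``Noisy(separation)``  benign scores ~ N(0, 1), pathogenic ~ N(separation,
                       1), cutoff at the midpoint; the expected AUROC has
                       the closed form Phi(separation / sqrt(2))
``CrashOn(uid)``       raises when the given UID is in the input

Coordinates are syntactic — positions drawn uniformly in [1, 2.5e8] on a
uniformly chosen chromosome, alleles random — because no operation in the
bench inspects sequence context; see the methods note for what that does
and does not exercise.
"""

from __future__ import annotations

import importlib.util
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Union

import numpy as np
import yaml
from scipy.stats import norm

from .core_data import EvaluationData
from .errors import SpecError
from .extractors import write_csv, write_vcf
from .plugins import ContainerJob, ContainerRunner, Plugin, load_manifest

_CHROMOSOMES = [str(i) for i in range(1, 23)] + ["X", "Y", "M"]
_BASES = np.array(list("ACGT"))
_MAX_POS = 250_000_000


# --- behaviours ------------------------------------------------------------

@dataclass(frozen=True)
class PerfectOracle:
    pass


@dataclass(frozen=True)
class InvertedOracle:
    pass


@dataclass(frozen=True)
class Constant:
    value: float


@dataclass(frozen=True)
class DesignedErrors:
    fn: int
    fp: int
    seed: int = 0


@dataclass(frozen=True)
class Noisy:
    separation: float
    seed: int = 0


@dataclass(frozen=True)
class CrashOn:
    uid: int


Behaviour = Union[PerfectOracle, InvertedOracle, Constant, DesignedErrors,
                  Noisy, CrashOn]


def expected_noisy_auroc(separation: float) -> float:
    """Closed-form AUROC of the two-Gaussian noisy mock: Phi(s / sqrt(2))."""
    return float(norm.cdf(separation / np.sqrt(2.0)))


# --- dataset generation ----------------------------------------------------

#: Rule identifiers with a dedicated deliberately-malformed row, one per
#: schema rule (compound constraints are split, and UID uniqueness / TYPE
#: membership are included), giving exactly twelve catalog entries.
MALFORMED_CATALOG = (
    "uid_nonnegative_integer",
    "uid_unique",
    "rg_nonempty",
    "chrom_in_set",
    "pos_integer",
    "pos_min",
    "ref_nonempty",
    "ref_alphabet",
    "alt_nonempty",
    "alt_alphabet",
    "type_in_set",
    "class_in_set",
)

_MALFORMED_OVERRIDES: dict[str, dict] = {
    "uid_nonnegative_integer": {"UID": -1},
    "uid_unique": {},  # UID copied from the previous row at injection time
    "rg_nonempty": {"RG": ""},
    "chrom_in_set": {"CHROM": "25"},
    "pos_integer": {"POS": 10.5},
    "pos_min": {"POS": 0},
    "ref_nonempty": {"REF": "", "TYPE": "INDEL"},
    "ref_alphabet": {"REF": "N"},
    "alt_nonempty": {"ALT": "", "TYPE": "INDEL"},
    "alt_alphabet": {"ALT": "Z"},
    "type_in_set": {"TYPE": "MNV"},
    "class_in_set": {"CLASS": "vous"},
}

#: Field flagged by the validator for each catalog rule.
MALFORMED_FIELDS = {
    "uid_nonnegative_integer": "UID",
    "uid_unique": "UID",
    "rg_nonempty": "RG",
    "chrom_in_set": "CHROM",
    "pos_integer": "POS",
    "pos_min": "POS",
    "ref_nonempty": "REF",
    "ref_alphabet": "REF",
    "alt_nonempty": "ALT",
    "alt_alphabet": "ALT",
    "type_in_set": "TYPE",
    "class_in_set": "CLASS",
}


@dataclass(frozen=True)
class DatasetSpec:
    """Recipe for one synthetic labeled variant dataset."""

    n_benign: int
    n_pathogenic: int
    rg: str = "GRCh37"
    vtype_mix: float = 0.0          # fraction of INDELs
    seed: int = 0
    malformed_rows: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n_benign < 0 or self.n_pathogenic < 0:
            raise SpecError("class counts must be non-negative")
        if not 0.0 <= self.vtype_mix <= 1.0:
            raise SpecError("vtype_mix must be in [0, 1]")
        unknown = set(self.malformed_rows) - set(MALFORMED_CATALOG)
        if unknown:
            raise SpecError(f"unknown malformed-row rule(s): {sorted(unknown)}")
        if self.n_benign + self.n_pathogenic + len(self.malformed_rows) == 0:
            raise SpecError("dataset would be empty")


def _draw_alleles(rng: np.random.Generator, indel: bool) -> tuple[str, str]:
    base = str(rng.choice(_BASES))
    if not indel:
        alt = str(rng.choice([b for b in "ACGT" if b != base]))
        return base, alt
    extra = "".join(rng.choice(_BASES, size=int(rng.integers(1, 6))))
    if rng.random() < 0.5:
        return base, base + extra      # insertion
    return base + extra, base          # deletion


def generate_dataset(
    spec: DatasetSpec, outdir: str | Path | None = None
) -> tuple[EvaluationData, dict[str, Path]]:
    """Generate a seeded dataset; optionally write its file renditions.

    Returns the in-memory truth table and, when ``outdir`` is given, paths
    to byte-stable ``dataset.csv``, ``dataset.vcf`` and a ClinVar-flavoured
    ``dataset.clinvar.vcf`` (CLNSIG set from the class labels).  Deliberate
    violations from ``spec.malformed_rows`` are appended as extra rows,
    one per named rule.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_benign + spec.n_pathogenic
    classes = np.array(["benign"] * spec.n_benign
                       + ["pathogenic"] * spec.n_pathogenic)
    classes = rng.permutation(classes)

    rows = []
    sites: set[tuple[str, int]] = set()
    for uid in range(n):
        while True:
            chrom = str(rng.choice(_CHROMOSOMES))
            pos = int(rng.integers(1, _MAX_POS + 1))
            if (chrom, pos) not in sites:
                sites.add((chrom, pos))
                break
        indel = bool(rng.random() < spec.vtype_mix)
        ref, alt = _draw_alleles(rng, indel)
        rows.append({
            "UID": uid, "RG": spec.rg, "CHROM": chrom, "POS": pos,
            "REF": ref, "ALT": alt, "TYPE": "INDEL" if indel else "SNP",
            "CLASS": str(classes[uid]),
        })

    for offset, rule in enumerate(spec.malformed_rows):
        uid = n + offset
        row = {
            "UID": uid, "RG": spec.rg, "CHROM": "1", "POS": 1000 + uid,
            "REF": "A", "ALT": "G", "TYPE": "SNP", "CLASS": "benign",
        }
        row.update(_MALFORMED_OVERRIDES[rule])
        if rule == "uid_unique":
            # duplicate the first *valid* uid so only the uniqueness rule fires
            valid = [r["UID"] for r in rows
                     if isinstance(r["UID"], int) and r["UID"] >= 0]
            row["UID"] = valid[0] if valid else uid
        rows.append(row)

    import pandas as pd
    data = EvaluationData(pd.DataFrame(rows))

    files: dict[str, Path] = {}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        files["csv"] = write_csv(data, outdir / "dataset.csv")
        files["vcf"] = write_vcf(data, outdir / "dataset.vcf")
        files["clinvar_vcf"] = write_vcf(
            data, outdir / "dataset.clinvar.vcf", style="clinvar"
        )
    return data, files


# --- mock plugins ----------------------------------------------------------

@dataclass(frozen=True)
class MockPluginSpec:
    """Recipe for one mock prioritization plugin."""

    name: str
    behaviour: Behaviour
    supported_variation_types: tuple[str, ...] = ("SNP", "INDEL")
    rg: str = "GRCh37"
    cutoff: float | None = None     # None: midpoint for Noisy, else 0.5
    score_direction: Literal["higher", "lower"] = "higher"
    version: str = "1.0"
    databases: Mapping[str, str] = field(default_factory=dict)
    omit_uid: int | None = None     # container stub drops this uid's score
    reverse_output: bool = False    # container stub emits uids in reverse

    def resolved_cutoff(self) -> float:
        if self.cutoff is not None:
            return float(self.cutoff)
        if isinstance(self.behaviour, Noisy):
            mid = self.behaviour.separation / 2.0
            return mid if self.score_direction == "higher" else -mid
        return 0.5


def _side_score(cutoff: float, direction: str, pathogenic: bool,
                margin: float = 0.5) -> float:
    """A score `margin` inside the pathogenic (or benign) side of the cutoff."""
    sign = 1.0 if pathogenic else -1.0
    if direction == "lower":
        sign = -sign
    # ">= cutoff is pathogenic" under direction=higher, mirrored for lower;
    # the benign side sits strictly off the cutoff, never on the tie.
    return cutoff + sign * margin


def compute_mock_scores(
    spec: MockPluginSpec, truth: EvaluationData
) -> dict[int, float]:
    """The deterministic uid -> score map a mock plugin will return."""
    cutoff = spec.resolved_cutoff()
    direction = spec.score_direction
    entries = sorted(truth.entries(), key=lambda e: e.uid)
    pathogenic_uids = [e.uid for e in entries if e.cls == "pathogenic"]
    benign_uids = [e.uid for e in entries if e.cls == "benign"]
    b = spec.behaviour

    if isinstance(b, Constant):
        return {e.uid: float(b.value) for e in entries}
    if isinstance(b, CrashOn):
        return {e.uid: cutoff for e in entries}
    if isinstance(b, (PerfectOracle, InvertedOracle)):
        invert = isinstance(b, InvertedOracle)
        return {
            e.uid: _side_score(cutoff, direction,
                               (e.cls == "pathogenic") != invert)
            for e in entries
        }
    if isinstance(b, DesignedErrors):
        if b.fn > len(pathogenic_uids) or b.fp > len(benign_uids):
            raise SpecError(
                f"designed errors (fn={b.fn}, fp={b.fp}) exceed class counts "
                f"({len(pathogenic_uids)} pathogenic, {len(benign_uids)} benign)"
            )
        rng = np.random.default_rng(b.seed)
        wrong_fn = set(rng.choice(pathogenic_uids, size=b.fn, replace=False)
                       ) if b.fn else set()
        wrong_fp = set(rng.choice(benign_uids, size=b.fp, replace=False)
                       ) if b.fp else set()
        scores = {}
        for e in entries:
            pathogenic = e.cls == "pathogenic"
            wrong = e.uid in wrong_fn or e.uid in wrong_fp
            scores[e.uid] = _side_score(cutoff, direction,
                                        pathogenic != wrong)
        return scores
    if isinstance(b, Noisy):
        rng = np.random.default_rng(b.seed)
        means = np.array([
            b.separation if e.cls == "pathogenic" else 0.0 for e in entries
        ])
        z = rng.normal(means, 1.0)
        if direction == "lower":
            z = -z
        return {e.uid: float(s) for e, s in zip(entries, z)}
    raise SpecError(f"unknown behaviour {b!r}")


def _manifest_dict(spec: MockPluginSpec, entry_point: dict) -> dict:
    return {
        "manifest-version": 1,
        "name": spec.name,
        "version": spec.version,
        "supported-variation-types": list(spec.supported_variation_types),
        "cutoff": spec.resolved_cutoff(),
        "score-direction": spec.score_direction,
        "reference-genome": spec.rg,
        "databases": dict(spec.databases),
        "entry-point": entry_point,
    }


def _write_scores(scores: Mapping[int, float], path: Path) -> None:
    lines = ["uid,score"] + [f"{uid},{scores[uid]!r}" for uid in sorted(scores)]
    path.write_text("\n".join(lines) + "\n")


_SCRIPT_TEMPLATE = '''\
"""Auto-generated mock prioritization plugin (synthetic scores)."""
import csv
from pathlib import Path

HERE = Path(__file__).resolve().parent
CRASH_UID = {crash_uid!r}
OMIT_UID = {omit_uid!r}


def process(variants):
    (HERE / "invoked.marker").write_text("invoked")
    with open(HERE / "scores.csv", newline="") as fh:
        table = {{int(r["uid"]): float(r["score"]) for r in csv.DictReader(fh)}}
    uids = [int(u) for u in variants["UID"]]
    if CRASH_UID is not None and CRASH_UID in uids:
        raise RuntimeError(f"mock crash on uid {{CRASH_UID}}")
    return [(u, table[u]) for u in uids if u != OMIT_UID]
'''

_STUB_TEMPLATE = '''\
"""Auto-generated container stand-in: reads the serialized input file and
writes the (uid, score) output file, like the image's command would."""
import csv
from pathlib import Path

HERE = Path(__file__).resolve().parent
CRASH_UID = {crash_uid!r}
OMIT_UID = {omit_uid!r}
REVERSE = {reverse!r}


def run(input_path, output_path):
    (HERE / "invoked.marker").write_text("invoked")
    with open(HERE / "scores.csv", newline="") as fh:
        table = {{int(r["uid"]): float(r["score"]) for r in csv.DictReader(fh)}}
    with open(input_path, newline="") as fh:
        uids = [int(row["UID"]) for row in csv.DictReader(fh)]
    if CRASH_UID is not None and CRASH_UID in uids:
        raise RuntimeError(f"mock crash on uid {{CRASH_UID}}")
    if REVERSE:
        uids = list(reversed(uids))
    with open(output_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["uid", "score"])
        for uid in uids:
            if uid != OMIT_UID:
                writer.writerow([uid, repr(table[uid])])
'''


def materialize_mock_plugin(
    spec: MockPluginSpec, truth: EvaluationData, directory: str | Path
) -> Plugin:
    """Write a python-mode mock plugin (manifest + scoring script) to disk."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    _write_scores(compute_mock_scores(spec, truth), directory / "scores.csv")
    crash_uid = spec.behaviour.uid if isinstance(spec.behaviour, CrashOn) else None
    (directory / "score.py").write_text(
        _SCRIPT_TEMPLATE.format(crash_uid=crash_uid, omit_uid=spec.omit_uid)
    )
    manifest = _manifest_dict(spec, {"mode": "python", "file": "score.py"})
    (directory / "manifest.yaml").write_text(
        yaml.safe_dump(manifest, sort_keys=True)
    )
    return Plugin(manifest=load_manifest(directory / "manifest.yaml"),
                  root=directory)


def materialize_container_stub(
    spec: MockPluginSpec, truth: EvaluationData, directory: str | Path
) -> Plugin:
    """Write a container-mode mock plugin driven by :class:`StubContainerRunner`.

    The manifest declares the full container contract (image, CSV input and
    output paths, command); the stub runner substitutes for the runtime by
    executing the plugin's ``stub.py`` against the serialized input file,
    so the serialize -> mount -> run -> parse path is exercised end to end
    without a container daemon.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    _write_scores(compute_mock_scores(spec, truth), directory / "scores.csv")
    crash_uid = spec.behaviour.uid if isinstance(spec.behaviour, CrashOn) else None
    (directory / "stub.py").write_text(_STUB_TEMPLATE.format(
        crash_uid=crash_uid, omit_uid=spec.omit_uid, reverse=spec.reverse_output,
    ))
    manifest = _manifest_dict(spec, {
        "mode": "container",
        "image": f"priobench-stub/{spec.name}:{spec.version}",
        "input-format": "csv",
        "input-path": "/data/input.csv",
        "output-format": "csv",
        "output-path": "/data/output.csv",
        "command": "score --in /data/input.csv --out /data/output.csv",
    })
    (directory / "manifest.yaml").write_text(
        yaml.safe_dump(manifest, sort_keys=True)
    )
    return Plugin(manifest=load_manifest(directory / "manifest.yaml"),
                  root=directory)


class StubContainerRunner(ContainerRunner):
    """Container-runner stand-in executing the plugin's ``stub.py`` locally."""

    def run(self, job: ContainerJob) -> None:
        script = job.plugin_root / "stub.py"
        spec = importlib.util.spec_from_file_location(
            f"_priobench_stub_{job.plugin_root.name}", script
        )
        module = importlib.util.module_from_spec(spec)
        name = module.__name__
        sys.modules[name] = module
        try:
            spec.loader.exec_module(module)
            module.run(str(job.input_host), str(job.output_host))
        finally:
            sys.modules.pop(name, None)
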