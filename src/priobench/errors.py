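"""Exception hierarchy for the test bench.

Every failure mode the pipeline can surface has a distinct type so that
callers (and the CLI's exit-code mapping) can react per stage rather than
parsing messages.
"""

from __future__ import annotations


class PriobenchError(Exception):
    """Base class for all errors raised by this package."""


# --- core data -------------------------------------------------------------

class InvalidAllele(PriobenchError):
    """An allele string is empty or contains characters outside {A,C,G,T}."""


class UnsupportedVariationType(PriobenchError):
    """The (REF, ALT) pair describes a variation type outside {SNP, INDEL},
    e.g. a multi-nucleotide substitution of equal length > 1."""


class InvalidChromosome(PriobenchError):
    """A chromosome label cannot be normalized into {1..22, X, Y, M}."""


class ValidationFailedError(PriobenchError):
    """Evaluation data failed schema validation; carries the report."""

    def __init__(self, report) -> None:
        self.report = report
        lines = "; ".join(
            f"row {v.row} {v.field}: {v.message}" for v in report.violations[:10]
        )
        more = len(report.violations) - 10
        if more > 0:
            lines += f"; ... and {more} more"
        super().__init__(
            f"evaluation data failed validation with "
            f"{len(report.violations)} violation(s): {lines}"
        )


# --- extraction ------------------------------------------------------------

class ParseError(PriobenchError):
    """The input file could not be parsed (malformed VCF/CSV, missing
    mapped columns)."""


class ExtractionError(PriobenchError):
    """Extraction finished but produced no usable entries, or hit an
    unrecoverable record in strict mode."""


# --- plugins ---------------------------------------------------------------

class ManifestError(PriobenchError):
    """A plugin manifest is missing, unreadable, or schema-invalid."""


class SelectionError(PriobenchError):
    """The plugin selection predicate matched no plugins."""


class CompatibilityError(PriobenchError):
    """One or more selected plugins cannot handle the variant data
    (variation types or reference genome mismatch)."""

    def __init__(self, failures) -> None:
        self.failures = list(failures)
        detail = "; ".join(str(f) for f in self.failures)
        super().__init__(f"incompatible plugin(s): {detail}")


class PluginCrashError(PriobenchError):
    """A plugin's processing logic raised; wraps the original failure with
    the plugin name."""


class ContainerError(PriobenchError):
    """A containerized plugin run failed (non-zero exit or missing output)."""


class RuntimeUnavailableError(PriobenchError):
    """No container runtime is available on this host."""


class ScoreValidationError(PriobenchError):
    """A plugin's scores do not cover the variant UIDs exactly once each
    with finite numbers."""

    def __init__(self, *, missing=(), unknown=(), duplicated=(), non_finite=(),
                 plugin: str | None = None) -> None:
        self.missing = sorted(missing)
        self.unknown = sorted(unknown)
        self.duplicated = sorted(duplicated)
        self.non_finite = sorted(non_finite)
        self.plugin = plugin
        parts = []
        if self.missing:
            parts.append(f"missing uids: {self.missing}")
        if self.unknown:
            parts.append(f"unknown uids: {self.unknown}")
        if self.duplicated:
            parts.append(f"duplicated uids: {self.duplicated}")
        if self.non_finite:
            parts.append(f"non-finite scores for uids: {self.non_finite}")
        prefix = f"plugin {plugin!r}: " if plugin else ""
        super().__init__(prefix + "; ".join(parts))


# --- metrics ---------------------------------------------------------------

class UnknownMetric(PriobenchError):
    """Requested metric name is not in the supported vocabulary."""


class DegenerateLabels(PriobenchError):
    """The truth labels do not contain the classes a summary requires
    (e.g. a ROC curve over single-class labels)."""


# --- pipeline / reporting --------------------------------------------------

class ConfigurationError(PriobenchError):
    """The pipeline configuration is invalid (unknown metric names,
    cutoff override for an unselected plugin, ...)."""


class SeriesError(PriobenchError):
    """Reports in a series do not share the same plugin set."""


class SpecError(PriobenchError):
    """A synthetic dataset or mock plugin specification is inconsistent."""
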