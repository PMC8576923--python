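"""Canonical evaluation-data model and constraint validation.

The benchmark represents labeled variants as a flat table with one row per
variant and the columns UID, RG, CHROM, POS, REF, ALT, TYPE, CLASS:

========  =============================================================
UID       unique non-negative integer identifier, assigned in input order
RG        reference genome the variant was called against (e.g. GRCh37)
CHROM     chromosome, one of {1..22, X, Y, M} after normalization
POS       1-based position within the chromosome
REF/ALT   reference / alternative bases over the alphabet {A,C,G,T}
TYPE      variation type, SNP (both alleles length 1) or INDEL
CLASS     expected classification, ``benign`` or ``pathogenic``
========  =============================================================

``EvaluationData`` wraps that table; ``VariantData`` is the same table with
the CLASS column removed — it is what prioritization methods are allowed to
see.  Validation collects *all* constraint violations instead of failing on
the first, so a user can fix a malformed input file in one pass.
"""

from __future__ import annotations

import math
import numbers
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import pandas as pd

from .errors import InvalidAllele, InvalidChromosome, UnsupportedVariationType

EVALUATION_COLUMNS = ("UID", "RG", "CHROM", "POS", "REF", "ALT", "TYPE", "CLASS")
VARIANT_COLUMNS = EVALUATION_COLUMNS[:-1]

CHROMOSOMES = frozenset([str(i) for i in range(1, 23)] + ["X", "Y", "M"])
ALLELE_ALPHABET = frozenset("ACGT")
VARIATION_TYPES = ("SNP", "INDEL")
CLASSES = ("benign", "pathogenic")

#: Fixed alias table for reference-genome labels; comparisons between data
#: and plugin manifests go through :func:`resolve_genome` first.
GENOME_ALIASES = {
    "hg19": "GRCh37",
    "grch37": "GRCh37",
    "hg38": "GRCh38",
    "grch38": "GRCh38",
}

VariationType = Literal["SNP", "INDEL"]
Classification = Literal["benign", "pathogenic"]


def resolve_genome(label: str) -> str:
    """Map a reference-genome label onto its canonical assembly name.

    ``hg19``/``GRCh37`` and ``hg38``/``GRCh38`` are treated as the same
    assembly; unknown labels pass through unchanged (stripped).
    """
    raw = str(label).strip()
    return GENOME_ALIASES.get(raw.lower(), raw)


def normalize_chromosome(raw: str) -> str:
    """Normalize a chromosome spelling into the canonical {1..22, X, Y, M}.

    Case-insensitive; strips a leading ``chr`` prefix; accepts ``MT`` as an
    alias for ``M``.  Anything else (alt contigs, out-of-range numbers)
    raises :class:`InvalidChromosome`.
    """
    label = str(raw).strip()
    if not label:
        raise InvalidChromosome("empty chromosome label")
    if label.lower().startswith("chr"):
        label = label[3:]
    label = label.upper()
    if label == "MT":
        label = "M"
    if label not in CHROMOSOMES:
        raise InvalidChromosome(
            f"chromosome {raw!r} is not in {{1..22, X, Y, M}}"
        )
    return label


def _check_allele(allele: str, role: str) -> str:
    seq = str(allele).strip().upper()
    if not seq:
        raise InvalidAllele(f"{role} allele is empty")
    bad = set(seq) - ALLELE_ALPHABET
    if bad:
        raise InvalidAllele(
            f"{role} allele {allele!r} contains characters outside "
            f"{{A,C,G,T}}: {sorted(bad)}"
        )
    return seq


def infer_variation_type(ref: str, alt: str) -> VariationType:
    """Classify a (REF, ALT) pair as ``SNP`` or ``INDEL``.

    A SNP has both alleles of length 1; differing lengths make an INDEL.
    Equal lengths greater than one (multi-nucleotide substitutions) are not
    representable in the two-type scheme and raise
    :class:`UnsupportedVariationType`.
    """
    ref_seq = _check_allele(ref, "reference")
    alt_seq = _check_allele(alt, "alternative")
    if len(ref_seq) == 1 and len(alt_seq) == 1:
        return "SNP"
    if len(ref_seq) != len(alt_seq):
        return "INDEL"
    raise UnsupportedVariationType(
        f"equal-length substitution {ref_seq}>{alt_seq} is neither SNP nor INDEL"
    )


@dataclass(frozen=True)
class EvaluationEntry:
    """One labeled variant row."""

    uid: int
    rg: str
    chrom: str
    pos: int
    ref: str
    alt: str
    vtype: str
    cls: str

    def as_row(self) -> dict:
        return {
            "UID": self.uid, "RG": self.rg, "CHROM": self.chrom,
            "POS": self.pos, "REF": self.ref, "ALT": self.alt,
            "TYPE": self.vtype, "CLASS": self.cls,
        }


def _coerce_table(table: pd.DataFrame, columns: Sequence[str]) -> pd.DataFrame:
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise ValueError(f"table is missing required columns: {missing}")
    out = table.loc[:, list(columns)].reset_index(drop=True)
    # Best-effort integer dtypes; lossy casts (e.g. a fractional position)
    # are refused so validation still sees the malformed value.
    for col in ("UID", "POS"):
        try:
            numeric = pd.to_numeric(out[col])
            as_int = numeric.astype("int64")
            if bool((numeric == as_int).all()):
                out[col] = as_int
            else:
                out[col] = out[col].astype(object)
        except (ValueError, TypeError, OverflowError):
            out[col] = out[col].astype(object)
    return out


class EvaluationData:
    """Ordered collection of labeled variants backed by a pandas table."""

    columns = EVALUATION_COLUMNS

    def __init__(self, table: pd.DataFrame) -> None:
        self.table = _coerce_table(table, self.columns)

    @classmethod
    def from_entries(cls, entries: Iterable[EvaluationEntry]) -> "EvaluationData":
        rows = [e.as_row() for e in entries]
        if not rows:
            return cls(pd.DataFrame(columns=list(cls.columns)))
        return cls(pd.DataFrame(rows))

    def entries(self) -> list[EvaluationEntry]:
        return [
            EvaluationEntry(
                uid=int(r.UID), rg=r.RG, chrom=r.CHROM, pos=int(r.POS),
                ref=r.REF, alt=r.ALT, vtype=r.TYPE, cls=r.CLASS,
            )
            for r in self.table.itertuples(index=False)
        ]

    def __len__(self) -> int:
        return len(self.table)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EvaluationData):
            return NotImplemented
        return self.table.equals(other.table)

    def class_counts(self) -> dict[str, int]:
        counts = self.table["CLASS"].value_counts().to_dict()
        return {c: int(counts.get(c, 0)) for c in CLASSES}


class VariantData:
    """Evaluation data with the expected classification removed.

    This is the only view of the data a prioritization method receives, so
    a method cannot trivially echo the truth labels back.
    """

    columns = VARIANT_COLUMNS

    def __init__(self, table: pd.DataFrame) -> None:
        self.table = _coerce_table(table, self.columns)

    def __len__(self) -> int:
        return len(self.table)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, VariantData):
            return NotImplemented
        return self.table.equals(other.table)

    @property
    def uids(self) -> list[int]:
        return [int(u) for u in self.table["UID"]]

    def variation_types(self) -> set[str]:
        return set(self.table["TYPE"].unique())

    def reference_genomes(self) -> set[str]:
        return {resolve_genome(rg) for rg in self.table["RG"].unique()}


def strip_classification(data: EvaluationData) -> VariantData:
    """Drop the CLASS column, preserving row order and UIDs."""
    return VariantData(data.table.drop(columns=["CLASS"]))


# --- validation ------------------------------------------------------------

@dataclass(frozen=True)
class Violation:
    """One constraint violation: which row, which field, which rule."""

    row: int            # UID when the row's UID is itself valid, else row index
    field: str
    rule: str
    message: str


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def fields(self) -> list[str]:
        return [v.field for v in self.violations]


#: Rule identifiers checked by :func:`validate_evaluation_data`.  The first
#: twelve each have a dedicated malformed-fixture row in
#: :data:`priobench.fixtures.MALFORMED_CATALOG`; the TYPE/allele-length
#: consistency rule can only fire on rows whose other fields are valid.
VALIDATION_RULES = (
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
    "type_allele_consistency",
)


def _is_int(value) -> bool:
    if isinstance(value, bool):
        return False
    if isinstance(value, numbers.Integral):
        return True
    if isinstance(value, numbers.Real):
        return float(value).is_integer() and math.isfinite(float(value))
    return False


def _allele_ok(value) -> bool:
    return (
        isinstance(value, str)
        and len(value) > 0
        and set(value) <= ALLELE_ALPHABET
    )


def validate_evaluation_data(data: EvaluationData) -> ValidationReport:
    """Check every schema constraint on every row; collect all violations.

    Never raises for bad data: violations are returned as values so the
    caller can report them in one batch.  Pipeline runs treat a non-ok
    report as fatal.
    """
    report = ValidationReport()
    seen_uids: set[int] = set()

    for idx, row in enumerate(data.table.itertuples(index=False)):
        uid_ok = _is_int(row.UID) and int(row.UID) >= 0
        label = int(row.UID) if uid_ok else idx

        def flag(field_name: str, rule: str, message: str) -> None:
            report.violations.append(Violation(label, field_name, rule, message))

        if not uid_ok:
            flag("UID", "uid_nonnegative_integer",
                 f"UID must be a non-negative integer, got {row.UID!r}")
        else:
            uid = int(row.UID)
            if uid in seen_uids:
                flag("UID", "uid_unique", f"UID {uid} occurs more than once")
            seen_uids.add(uid)

        if not isinstance(row.RG, str) or not row.RG.strip():
            flag("RG", "rg_nonempty",
                 f"reference genome must be a non-empty string, got {row.RG!r}")

        if not isinstance(row.CHROM, str) or row.CHROM not in CHROMOSOMES:
            flag("CHROM", "chrom_in_set",
                 f"chromosome {row.CHROM!r} is not in {{1..22, X, Y, M}}")

        if not _is_int(row.POS):
            flag("POS", "pos_integer",
                 f"position must be an integer, got {row.POS!r}")
        elif int(row.POS) < 1:
            flag("POS", "pos_min",
                 f"position is 1-based and must be >= 1, got {int(row.POS)}")

        ref_ok = _allele_ok(row.REF)
        if not isinstance(row.REF, str) or len(row.REF) == 0:
            flag("REF", "ref_nonempty", "reference allele must be non-empty")
        elif not ref_ok:
            flag("REF", "ref_alphabet",
                 f"reference allele {row.REF!r} has characters outside {{A,C,G,T}}")

        alt_ok = _allele_ok(row.ALT)
        if not isinstance(row.ALT, str) or len(row.ALT) == 0:
            flag("ALT", "alt_nonempty", "alternative allele must be non-empty")
        elif not alt_ok:
            flag("ALT", "alt_alphabet",
                 f"alternative allele {row.ALT!r} has characters outside {{A,C,G,T}}")

        type_ok = row.TYPE in VARIATION_TYPES
        if not type_ok:
            flag("TYPE", "type_in_set",
                 f"variation type {row.TYPE!r} is not in {{SNP, INDEL}}")
        elif ref_ok and alt_ok:
            is_snp = len(row.REF) == 1 and len(row.ALT) == 1
            if (row.TYPE == "SNP") != is_snp:
                flag("TYPE", "type_allele_consistency",
                     f"TYPE={row.TYPE} inconsistent with allele lengths "
                     f"({len(row.REF)}, {len(row.ALT)})")

        if row.CLASS not in CLASSES:
            flag("CLASS", "class_in_set",
                 f"classification {row.CLASS!r} is not in {{benign, pathogenic}}")

    return report
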