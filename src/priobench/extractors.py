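"""Extract labeled evaluation data from VCF- and CSV-based input formats.

Two generic extractors (:func:`extract_from_vcf`, :func:`extract_from_csv`)
turn arbitrary VCF/CSV inputs into validated :class:`~priobench.core_data.
EvaluationData`; on top of them sit two database-flavoured specializations
for ClinVar-style VCFs (CLNSIG annotations) and VariSNP-style exports
(neutral benchmark variants, all labeled benign).

Extraction normalizes as it goes — chromosomes into {1..22, X, Y, M},
alleles uppercased, variation types inferred from allele lengths, UIDs
assigned consecutively from 0 in input order — so extracted data always
passes :func:`~priobench.core_data.validate_evaluation_data`.  Records that
cannot be represented (multi-nucleotide substitutions, symbolic or
non-ACGT alleles, off-catalog contigs) raise in ``strict`` mode and are
dropped with a logged count in ``skip`` mode; records whose raw class
annotation the :class:`ClassMapper` leaves unmapped are always skipped
with a logged count.

The module also provides the matching writers (:func:`write_csv`,
:func:`write_vcf`) so that datasets round-trip exactly; the synthetic-data
generator and the container input serialization reuse them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping

import pandas as pd
import pysam

from .core_data import (
    CLASSES,
    EvaluationData,
    EvaluationEntry,
    VariantData,
    infer_variation_type,
    normalize_chromosome,
)
from .errors import (
    ExtractionError,
    InvalidAllele,
    InvalidChromosome,
    ParseError,
    UnsupportedVariationType,
)

logger = logging.getLogger(__name__)

Mode = Literal["strict", "skip"]

#: Raw annotation vocabulary accepted by the default generic mapper.
DEFAULT_CLASS_MAP = {
    "benign": "benign",
    "pathogenic": "pathogenic",
    "Benign": "benign",
    "Pathogenic": "pathogenic",
}

CLINVAR_CLASS_MAP = {"Benign": "benign", "Pathogenic": "pathogenic"}
CLINVAR_LIKELY_MAP = {
    "Likely_benign": "benign",
    "Likely_pathogenic": "pathogenic",
    "Benign/Likely_benign": "benign",
    "Pathogenic/Likely_pathogenic": "pathogenic",
}


@dataclass(frozen=True)
class ClassMapper:
    """Total mapping from raw source annotations to {benign, pathogenic}.

    Annotations absent from the mapping resolve to ``None`` (unmapped) and
    the corresponding records never enter the evaluation data.
    """

    mapping: Mapping[str, str]

    def __post_init__(self) -> None:
        bad = {v for v in self.mapping.values() if v not in CLASSES}
        if bad:
            raise ValueError(f"class mapper targets outside {CLASSES}: {sorted(bad)}")

    def resolve(self, raw) -> str | None:
        if raw is None:
            return None
        if isinstance(raw, (tuple, list)):
            raw = ",".join(str(v) for v in raw)
        return self.mapping.get(str(raw).strip())


@dataclass(frozen=True)
class CsvColumnMap:
    """Assignment of source CSV columns to canonical fields.

    ``cls``/``constant_class`` and ``rg``/``constant_rg`` are mutually
    exclusive pairs: either name a source column or fix a constant for the
    whole file.  Positions are read as 1-based.
    """

    chrom: str
    pos: str
    ref: str
    alt: str
    cls: str | None = None
    rg: str | None = None
    constant_class: str | None = None
    constant_rg: str | None = None

    def __post_init__(self) -> None:
        if (self.cls is None) == (self.constant_class is None):
            raise ValueError("exactly one of cls / constant_class must be set")
        if (self.rg is None) == (self.constant_rg is None):
            raise ValueError("exactly one of rg / constant_rg must be set")
        if self.constant_class is not None and self.constant_class not in CLASSES:
            raise ValueError(f"constant_class must be in {CLASSES}")

    @classmethod
    def canonical(cls) -> "CsvColumnMap":
        """Column map for this package's own CSV dialect."""
        return cls(chrom="CHROM", pos="POS", ref="REF", alt="ALT",
                   cls="CLASS", rg="RG")

    def source_columns(self) -> list[str]:
        cols = [self.chrom, self.pos, self.ref, self.alt]
        if self.cls is not None:
            cols.append(self.cls)
        if self.rg is not None:
            cols.append(self.rg)
        return cols


@dataclass
class _Skips:
    """Per-reason counters for records dropped during extraction."""

    unmapped_class: int = 0
    unsupported: int = 0

    def log(self, source: str) -> None:
        if self.unmapped_class:
            logger.info("%s: skipped %d record(s) with unmapped class",
                        source, self.unmapped_class)
        if self.unsupported:
            logger.info("%s: skipped %d unrepresentable record(s)",
                        source, self.unsupported)


def _finish(entries: list[EvaluationEntry], path, skips: _Skips) -> EvaluationData:
    skips.log(str(path))
    if not entries:
        raise ExtractionError(f"no usable entries extracted from {path}")
    return EvaluationData.from_entries(entries)


def extract_from_vcf(
    path: str | Path,
    class_mapper: ClassMapper | None = None,
    rg: str | None = None,
    *,
    info_key: str = "CLASS",
    mode: Mode = "strict",
    pass_only: bool = False,
) -> EvaluationData:
    """Extract evaluation data from a VCF 4.x file (plain or gzip).

    One entry is produced per (record, ALT) pair, so multi-allelic records
    split into several entries sharing CHROM/POS.  The expected class comes
    from the INFO field ``info_key`` through ``class_mapper`` (default:
    benign/pathogenic spelled out, case as in :data:`DEFAULT_CLASS_MAP`).
    The reference-genome label is taken from ``rg`` or, when omitted, from
    a ``##reference=`` header line.
    """
    mapper = class_mapper or ClassMapper(DEFAULT_CLASS_MAP)
    try:
        vcf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise ParseError(f"cannot parse VCF {path}: {exc}") from exc

    with vcf:
        if rg is None:
            rg = _reference_from_header(vcf)
        if rg is None:
            raise ParseError(
                f"{path}: no reference genome given and no ##reference header line"
            )
        entries: list[EvaluationEntry] = []
        skips = _Skips()
        uid = 0
        try:
            for rec in vcf:
                if pass_only and "PASS" not in list(rec.filter):
                    skips.unsupported += 1
                    continue
                cls = mapper.resolve(rec.info.get(info_key))
                if cls is None:
                    skips.unmapped_class += 1
                    continue
                try:
                    chrom = normalize_chromosome(rec.chrom)
                except InvalidChromosome:
                    if mode == "strict":
                        raise ExtractionError(
                            f"{path}: contig {rec.chrom!r} not representable; "
                            f"use mode='skip' to drop such records"
                        ) from None
                    skips.unsupported += 1
                    continue
                for alt in rec.alts or ():
                    try:
                        vtype = infer_variation_type(rec.ref, alt)
                    except (InvalidAllele, UnsupportedVariationType) as exc:
                        if mode == "strict":
                            raise ExtractionError(
                                f"{path} at {rec.chrom}:{rec.pos}: {exc}"
                            ) from exc
                        skips.unsupported += 1
                        continue
                    entries.append(EvaluationEntry(
                        uid=uid, rg=rg, chrom=chrom, pos=int(rec.pos),
                        ref=str(rec.ref).upper(), alt=str(alt).upper(),
                        vtype=vtype, cls=cls,
                    ))
                    uid += 1
        except ValueError as exc:  # pysam parse failure mid-file
            raise ParseError(f"cannot parse VCF {path}: {exc}") from exc
    return _finish(entries, path, skips)


def _reference_from_header(vcf: pysam.VariantFile) -> str | None:
    for record in vcf.header.records:
        if record.key == "reference" and record.value:
            return str(record.value)
    return None


def extract_from_csv(
    path: str | Path,
    column_map: CsvColumnMap,
    class_mapper: ClassMapper | None = None,
    *,
    delimiter: str = ",",
    mode: Mode = "strict",
) -> EvaluationData:
    """Extract evaluation data from a delimited text file with a header row.

    One entry per row; the column map names the source columns for the
    canonical fields, and TYPE is always re-inferred from the alleles.
    """
    mapper = class_mapper or ClassMapper(DEFAULT_CLASS_MAP)
    try:
        frame = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ParseError(f"cannot parse CSV {path}: {exc}") from exc
    missing = [c for c in column_map.source_columns() if c not in frame.columns]
    if missing:
        raise ParseError(
            f"{path}: mapped column(s) {missing} not found; "
            f"file has {list(frame.columns)}"
        )

    entries: list[EvaluationEntry] = []
    skips = _Skips()
    uid = 0
    for idx, row in frame.iterrows():
        if column_map.constant_class is not None:
            cls = column_map.constant_class
        else:
            cls = mapper.resolve(row[column_map.cls])
            if cls is None:
                skips.unmapped_class += 1
                continue
        rg = (column_map.constant_rg if column_map.constant_rg is not None
              else str(row[column_map.rg]).strip())
        try:
            chrom = normalize_chromosome(row[column_map.chrom])
            # range violations (pos < 1) are deferred to schema validation
            pos = int(str(row[column_map.pos]).strip())
            vtype = infer_variation_type(row[column_map.ref], row[column_map.alt])
        except (InvalidChromosome, InvalidAllele, UnsupportedVariationType,
                ExtractionError, ValueError) as exc:
            if mode == "strict":
                raise ExtractionError(f"{path} row {idx}: {exc}") from exc
            skips.unsupported += 1
            continue
        entries.append(EvaluationEntry(
            uid=uid, rg=rg, chrom=chrom, pos=pos,
            ref=str(row[column_map.ref]).strip().upper(),
            alt=str(row[column_map.alt]).strip().upper(),
            vtype=vtype, cls=cls,
        ))
        uid += 1
    return _finish(entries, path, skips)


def extract_clinvar_vcf(
    path: str | Path,
    *,
    rg: str | None = None,
    include_likely: bool = False,
    mode: Mode = "strict",
) -> EvaluationData:
    """Extract a ClinVar-style VCF using its CLNSIG clinical significance.

    By default only the unambiguous assertions map — ``Benign`` -> benign
    and ``Pathogenic`` -> pathogenic; every other CLNSIG value (Likely_*,
    Uncertain_significance, Conflicting_*) is skipped.  With
    ``include_likely=True`` the ``Likely_``-qualified assertions join their
    parent class.
    """
    mapping = dict(CLINVAR_CLASS_MAP)
    if include_likely:
        mapping.update(CLINVAR_LIKELY_MAP)
    return extract_from_vcf(
        path, ClassMapper(mapping), rg=rg, info_key="CLNSIG", mode=mode,
    )


#: Column layout accepted for VariSNP-style exports.  The suite distributes
#: tab-separated text; this extractor expects a header with the columns
#: below (extra columns are ignored).  Every extracted variant is labeled
#: benign: VariSNP is a neutral benchmark set.
VARISNP_COLUMNS = CsvColumnMap(
    chrom="chromosome", pos="position", ref="reference", alt="alternative",
    constant_class="benign", constant_rg="GRCh37",
)


def extract_varisnp(
    path: str | Path,
    *,
    rg: str = "GRCh37",
    delimiter: str = "\t",
    mode: Mode = "strict",
) -> EvaluationData:
    """Extract a VariSNP-style neutral-variant export (all entries benign)."""
    column_map = CsvColumnMap(
        chrom=VARISNP_COLUMNS.chrom, pos=VARISNP_COLUMNS.pos,
        ref=VARISNP_COLUMNS.ref, alt=VARISNP_COLUMNS.alt,
        constant_class="benign", constant_rg=rg,
    )
    return extract_from_csv(path, column_map, delimiter=delimiter, mode=mode)


# --- writers ---------------------------------------------------------------

def write_csv(
    data: EvaluationData | VariantData, path: str | Path, *, delimiter: str = ","
) -> Path:
    """Write data in the package's canonical CSV dialect."""
    path = Path(path)
    data.table.to_csv(path, sep=delimiter, index=False)
    return path


def _vcf_header(rg: str | None, style: str) -> list[str]:
    lines = ["##fileformat=VCFv4.2"]
    if rg:
        lines.append(f"##reference={rg}")
    if style == "clinvar":
        lines.append(
            '##INFO=<ID=CLNSIG,Number=.,Type=String,'
            'Description="Clinical significance">'
        )
    elif style == "generic":
        lines.append(
            '##INFO=<ID=CLASS,Number=1,Type=String,'
            'Description="Expected classification">'
        )
    for chrom in [str(i) for i in range(1, 23)] + ["X", "Y", "M"]:
        lines.append(f"##contig=<ID={chrom}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    return lines


_CLINVAR_LABELS = {"benign": "Benign", "pathogenic": "Pathogenic"}


def write_vcf(
    data: EvaluationData | VariantData,
    path: str | Path,
    *,
    style: Literal["generic", "clinvar", "plain"] = "generic",
    merge_multiallelic: bool = False,
) -> Path:
    """Write data as an uncompressed VCF 4.2 file.

    ``generic`` carries the class as ``INFO/CLASS=benign|pathogenic``;
    ``clinvar`` as ``INFO/CLNSIG=Benign|Pathogenic``; ``plain`` writes no
    class (the dialect used for container inputs).  With
    ``merge_multiallelic`` consecutive rows sharing CHROM/POS/REF (and
    class) collapse into one record with a comma-separated ALT list —
    extraction splits them back in the same order.
    """
    path = Path(path)
    has_class = "CLASS" in data.table.columns and style != "plain"
    rgs = sorted(set(data.table["RG"])) if len(data.table) else []
    rg = rgs[0] if len(rgs) == 1 else None
    lines = _vcf_header(rg, style if has_class else "plain")

    def info_for(row) -> str:
        if not has_class:
            return "."
        if style == "clinvar":
            return f"CLNSIG={_CLINVAR_LABELS.get(row.CLASS, row.CLASS)}"
        return f"CLASS={row.CLASS}"

    rows = list(data.table.itertuples(index=False))
    i = 0
    while i < len(rows):
        row = rows[i]
        alts = [row.ALT]
        j = i + 1
        if merge_multiallelic:
            while j < len(rows):
                nxt = rows[j]
                same_site = (nxt.CHROM == row.CHROM and nxt.POS == row.POS
                             and nxt.REF == row.REF)
                same_class = (not has_class) or nxt.CLASS == row.CLASS
                if same_site and same_class and nxt.ALT not in alts:
                    alts.append(nxt.ALT)
                    j += 1
                else:
                    break
        lines.append("\t".join([
            str(row.CHROM), str(int(row.POS)), ".", str(row.REF),
            ",".join(alts), ".", ".", info_for(row),
        ]))
        i = j
    path.write_text("\n".join(lines) + "\n")
    return path


# --- registry --------------------------------------------------------------

def _vcf_named(path, *, class_map: Mapping[str, str] | None = None, **kw):
    mapper = ClassMapper(class_map) if class_map is not None else None
    return extract_from_vcf(path, mapper, **kw)


def _csv_named(path, *, column_map: Mapping[str, str] | None = None,
               class_map: Mapping[str, str] | None = None, **kw):
    cmap = (CsvColumnMap(**column_map) if column_map is not None
            else CsvColumnMap.canonical())
    mapper = ClassMapper(class_map) if class_map is not None else None
    return extract_from_csv(path, cmap, mapper, **kw)


#: Named extractors selectable from the CLI / pipeline configuration.
EXTRACTORS = {
    "vcf": _vcf_named,
    "csv": _csv_named,
    "clinvar": extract_clinvar_vcf,
    "varisnp": extract_varisnp,
}


def get_extractor(name: str):
    try:
        return EXTRACTORS[name]
    except KeyError:
        raise ParseError(
            f"unknown extractor {name!r}; available: {sorted(EXTRACTORS)}"
        ) from None
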