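"""Reading, quality filtering, normalization, and functional tallying of
annotated variant records for a single breed/sample.

Two input dialects are supported: plain or bgzipped VCF (per-site ``DP`` and
``MQ`` INFO fields expected, multi-allelic sites split into one record per
alternate allele) and the ANNOVAR ``exonic_variant_function`` tab-separated
table (line id, functional class, gene annotation, chrom, start, end, ref,
alt). Coordinates are 1-based inclusive throughout.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

REGION_CLASSES = {"exonic", "intronic", "intergenic", "other"}
FUNC_CLASSES = {
    "synonymous",
    "nonsynonymous",
    "stopgain",
    "stoploss",
    "unknown",
    "indel_frameshift",
    "indel_nonframeshift",
    "none",
}
SNP_FUNC_CLASSES = ("synonymous", "nonsynonymous", "stopgain", "stoploss", "unknown")

#: ANNOVAR exonic_variant_function class strings -> internal functional class.
ANNOVAR_CLASS_MAP = {
    "nonsynonymous SNV": "nonsynonymous",
    "synonymous SNV": "synonymous",
    "stopgain": "stopgain",
    "stoploss": "stoploss",
    "unknown": "unknown",
    "frameshift insertion": "indel_frameshift",
    "frameshift deletion": "indel_frameshift",
    "nonframeshift insertion": "indel_nonframeshift",
    "nonframeshift deletion": "indel_nonframeshift",
}

#: Gene-annotation placeholders treated as missing/invalid.
DEFAULT_INVALID_GENES = frozenset({"", "NA", "NONE", "-"})


def _infer_vtype(ref: str, alt: str) -> str:
    # ANNOVAR writes "-" for the absent allele of an indel.
    if ref == "-":
        return "INS"
    if alt == "-":
        return "DEL"
    if len(ref) == len(alt) == 1:
        return "SNP"
    return "INS" if len(alt) > len(ref) else "DEL"


@dataclass(frozen=True)
class VariantRecord:
    """One called variant: coordinates, alleles, quality, annotation.

    ``dp``/``mq`` are ``None`` when the source file did not provide them;
    such records are rejected (and counted) by :func:`apply_quality_filters`.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    rsid: str = ""
    dp: int | None = None
    mq: float | None = None
    region_class: str = "other"
    func_class: str = "none"
    gene: str = ""
    vtype: str = field(default="")

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        object.__setattr__(self, "ref", self.ref.upper())
        object.__setattr__(self, "alt", self.alt.upper())
        if self.region_class not in REGION_CLASSES:
            raise ValueError(f"unknown region_class {self.region_class!r}")
        if self.func_class not in FUNC_CLASSES:
            raise ValueError(f"unknown func_class {self.func_class!r}")
        if not self.vtype:
            object.__setattr__(self, "vtype", _infer_vtype(self.ref, self.alt))
        if self.vtype not in {"SNP", "INS", "DEL"}:
            raise ValueError(f"unknown vtype {self.vtype!r}")

    @property
    def key(self) -> str:
        """Positional identity key; rsid is a label, not identity."""
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


@dataclass
class ClassTally:
    """Counts of SNP functional classes; ``total`` always equals their sum."""

    counts: dict[str, int]
    total: int


@dataclass
class FilterReport:
    """Bookkeeping for one pass of :func:`apply_quality_filters`.

    A removed record is counted once, under the first failing check
    (missing fields, then low DP, then low MQ).
    """

    n_input: int = 0
    n_kept: int = 0
    n_removed: int = 0
    removed_missing_fields: int = 0
    removed_low_dp: int = 0
    removed_low_mq: int = 0
    dp_min: float = 4
    mq_min: float = 20

    def to_dict(self) -> dict:
        return dict(self.__dict__)


class VariantParseError(ValueError):
    """Malformed line in a variant table; message names the line number."""


def read_variant_table(path: str | Path, dialect: str) -> list[VariantRecord]:
    """Read one breed's variant table into :class:`VariantRecord` objects.

    ``dialect`` is ``"vcf"`` (DP/MQ pulled from INFO; multi-allelic sites
    split, one record per alternate allele) or ``"annovar_exonic"``
    (ANNOVAR exonic_variant_function table; all records exonic, functional
    class mapped through :data:`ANNOVAR_CLASS_MAP`, gene = first token
    before ``":"`` of the annotation string).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "vcf":
        return _read_vcf(path)
    if dialect == "annovar_exonic":
        return _read_annovar_exonic(path)
    raise ValueError(f"unknown dialect {dialect!r}; expected 'vcf' or 'annovar_exonic'")


def _read_vcf(path: Path) -> list[VariantRecord]:
    from cyvcf2 import VCF

    records: list[VariantRecord] = []
    for v in VCF(str(path)):
        dp = v.INFO.get("DP")
        mq = v.INFO.get("MQ")
        for alt in v.ALT:
            records.append(
                VariantRecord(
                    chrom=str(v.CHROM),
                    pos=int(v.POS),
                    ref=str(v.REF),
                    alt=str(alt),
                    rsid=v.ID or "",
                    dp=int(dp) if dp is not None else None,
                    mq=float(mq) if mq is not None else None,
                )
            )
    return records


def _parse_gene(annotation: str) -> str:
    # "OR10C1:XM_1:exon1:c.A5G:p.E2G" or a comma-joined list of such strings.
    first = annotation.split(",", 1)[0].strip()
    return first.split(":", 1)[0].strip()


def _read_annovar_exonic(path: Path) -> list[VariantRecord]:
    records: list[VariantRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise VariantParseError(
                    f"{path}:{lineno}: expected >= 8 tab-separated fields, got {len(fields)}"
                )
            _, func_str, gene_str, chrom, start, _end, ref, alt = fields[:8]
            func_class = ANNOVAR_CLASS_MAP.get(func_str.strip())
            if func_class is None:
                raise VariantParseError(
                    f"{path}:{lineno}: unrecognized functional class {func_str!r}"
                )
            try:
                pos = int(start)
            except ValueError as exc:
                raise VariantParseError(f"{path}:{lineno}: bad start {start!r}") from exc
            records.append(
                VariantRecord(
                    chrom=chrom,
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    gene=_parse_gene(gene_str),
                    region_class="exonic",
                    func_class=func_class,
                )
            )
    return records


def apply_quality_filters(
    records: Iterable[VariantRecord],
    dp_min: int = 4,
    mq_min: float = 20,
) -> tuple[list[VariantRecord], FilterReport]:
    """Retain records with ``dp > dp_min`` and ``mq > mq_min`` (both strict).

    Records missing DP or MQ are rejected with a logged warning and counted
    in the report. Order is preserved; the operation is idempotent.
    """
    report = FilterReport(dp_min=dp_min, mq_min=mq_min)
    kept: list[VariantRecord] = []
    for rec in records:
        report.n_input += 1
        if rec.dp is None or rec.mq is None:
            report.removed_missing_fields += 1
            logger.warning("record %s rejected: missing DP/MQ", rec.key)
        elif not rec.dp > dp_min:
            report.removed_low_dp += 1
        elif not rec.mq > mq_min:
            report.removed_low_mq += 1
        else:
            kept.append(rec)
            report.n_kept += 1
    report.n_removed = report.n_input - report.n_kept
    return kept, report


def normalize_and_dedupe(
    records: Sequence[VariantRecord],
    invalid_genes: frozenset[str] = DEFAULT_INVALID_GENES,
) -> list[VariantRecord]:
    """Drop records with missing/invalid gene annotation and collapse
    duplicates (identical chrom, pos, ref, alt), keeping the first occurrence.
    """
    seen: set[tuple[str, int, str, str]] = set()
    out: list[VariantRecord] = []
    for rec in records:
        if rec.gene.strip().upper() in invalid_genes:
            continue
        ident = (rec.chrom, rec.pos, rec.ref, rec.alt)
        if ident in seen:
            continue
        seen.add(ident)
        out.append(rec)
    return out


def tally_functional_classes(records: Iterable[VariantRecord]) -> ClassTally:
    """Tally SNP functional classes (synonymous/nonsynonymous/stop-gain/
    stop-loss/unknown). Raises on any non-SNP record."""
    counts = {c: 0 for c in SNP_FUNC_CLASSES}
    total = 0
    for rec in records:
        if rec.vtype != "SNP":
            raise ValueError(f"non-SNP record {rec.key} (vtype={rec.vtype}) in SNP tally")
        if rec.func_class not in counts:
            raise ValueError(f"record {rec.key} has non-SNP func_class {rec.func_class!r}")
        counts[rec.func_class] += 1
        total += 1
    return ClassTally(counts=counts, total=total)


TSV_COLUMNS = ("chrom", "pos", "rsid", "ref", "alt", "vtype", "region_class", "func_class", "gene")


def write_variant_tsv(records: Iterable[VariantRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(TSV_COLUMNS) + "\n")
        for r in records:
            fh.write(
                "\t".join(
                    [r.chrom, str(r.pos), r.rsid, r.ref, r.alt, r.vtype, r.region_class, r.func_class, r.gene]
                )
                + "\n"
            )


def read_variant_tsv(path: str | Path) -> list[VariantRecord]:
    records: list[VariantRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != TSV_COLUMNS:
            raise VariantParseError(f"{path}:1: unexpected header {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) != len(TSV_COLUMNS):
                raise VariantParseError(f"{path}:{lineno}: bad field count")
            records.append(
                VariantRecord(
                    chrom=f[0], pos=int(f[1]), rsid=f[2], ref=f[3], alt=f[4],
                    vtype=f[5], region_class=f[6], func_class=f[7], gene=f[8],
                )
            )
    return records


def write_filter_report(report: FilterReport, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)
        fh.write("\n")


def strip_quality(rec: VariantRecord) -> VariantRecord:
    """Copy of a record without DP/MQ (used when re-serializing filtered sets)."""
    return replace(rec, dp=None, mq=None)
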