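"""Missense/indel prioritization and length-normalized per-gene variant
densities (SNPs/kb, indels/kb).

Gene length is the genomic span ``end - start + 1`` of the gene's
coordinates (1-based inclusive); a gene listed several times contributes its
merged span (min start, max end). Densities are ``count / length_kb``, so
genes with variants but without coordinates cannot be scored — they are
excluded and reported separately rather than given an infinite density.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .variant_io import VariantRecord


@dataclass(frozen=True)
class GeneModel:
    """Genomic span of one gene, 1-based inclusive coordinates."""

    gene: str
    chrom: str
    start: int
    end: int
    ensembl_id: str = ""

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"{self.gene}: end {self.end} < start {self.start}")

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class DensityRecord:
    gene: str
    snp_count: int
    indel_count: int
    length_kb: float
    snp_density: float
    indel_density: float


def select_missense(records: Iterable[VariantRecord]) -> list[VariantRecord]:
    """Exonic nonsynonymous SNPs — the prioritized missense set."""
    return [
        r
        for r in records
        if r.vtype == "SNP" and r.region_class == "exonic" and r.func_class == "nonsynonymous"
    ]


def select_exonic_indels(records: Iterable[VariantRecord]) -> list[VariantRecord]:
    """All exonic indels, frameshift or not."""
    return [r for r in records if r.vtype in {"INS", "DEL"} and r.region_class == "exonic"]


def compute_gene_lengths(models: Iterable[GeneModel]) -> dict[str, float]:
    """Merged-span gene lengths in kilobases.

    Raises if the same gene symbol appears on two chromosomes.
    """
    spans: dict[str, tuple[str, int, int]] = {}
    for m in models:
        if m.gene in spans:
            chrom, lo, hi = spans[m.gene]
            if chrom != m.chrom:
                raise ValueError(
                    f"gene {m.gene} annotated on chromosomes {chrom} and {m.chrom}"
                )
            spans[m.gene] = (chrom, min(lo, m.start), max(hi, m.end))
        else:
            spans[m.gene] = (m.chrom, m.start, m.end)
    return {g: (hi - lo + 1) / 1000.0 for g, (_, lo, hi) in spans.items()}


def compute_density(
    snps: Iterable[VariantRecord],
    indels: Iterable[VariantRecord],
    lengths: Mapping[str, float],
) -> tuple[list[DensityRecord], set[str]]:
    """Per-gene variant counts and densities.

    Returns one :class:`DensityRecord` per gene present in either variant set
    and in ``lengths``, plus the set of genes carrying variants but lacking
    coordinates (excluded from densities).
    """
    snp_counts = Counter(r.gene for r in snps)
    indel_counts = Counter(r.gene for r in indels)
    genes = set(snp_counts) | set(indel_counts)
    missing = {g for g in genes if g not in lengths}
    out = []
    for gene in sorted(genes - missing):
        length_kb = lengths[gene]
        s, i = snp_counts.get(gene, 0), indel_counts.get(gene, 0)
        out.append(
            DensityRecord(
                gene=gene,
                snp_count=s,
                indel_count=i,
                length_kb=length_kb,
                snp_density=s / length_kb,
                indel_density=i / length_kb,
            )
        )
    return out, missing


def top_n(
    records: Sequence[DensityRecord], metric: str, n: int
) -> list[DensityRecord]:
    """Top ``n`` genes by ``metric`` (descending), ties broken by gene symbol."""
    if metric not in {"snp_density", "indel_density"}:
        raise ValueError(f"unknown metric {metric!r}")
    if n < 1:
        raise ValueError("n must be >= 1")
    ranked = sorted(records, key=lambda r: (-getattr(r, metric), r.gene))
    return ranked[:n]


def read_gene_models(path: str | Path, fmt: str | None = None) -> list[GeneModel]:
    """Load gene models from BED (0-based half-open, converted to 1-based
    inclusive on read) or TSV (``gene ensembl_id chrom start end``, 1-based).

    ``fmt`` defaults from the file suffix (``.bed`` -> bed, else tsv).
    """
    path = Path(path)
    if fmt is None:
        fmt = "bed" if path.suffix == ".bed" else "tsv"
    models: list[GeneModel] = []
    with open(path) as fh:
        if fmt == "bed":
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                f = line.split("\t")
                chrom, start0, end0, name = f[0], int(f[1]), int(f[2]), f[3]
                models.append(GeneModel(gene=name, chrom=chrom, start=start0 + 1, end=end0))
        elif fmt == "tsv":
            header = fh.readline().rstrip("\n").split("\t")
            idx = {c: i for i, c in enumerate(header)}
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                f = line.split("\t")
                models.append(
                    GeneModel(
                        gene=f[idx["gene"]],
                        ensembl_id=f[idx["ensembl_id"]] if "ensembl_id" in idx else "",
                        chrom=f[idx["chrom"]],
                        start=int(f[idx["start"]]),
                        end=int(f[idx["end"]]),
                    )
                )
        else:
            raise ValueError(f"unknown gene-model format {fmt!r}")
    return models


def write_density_tsv(records: Iterable[DensityRecord], path: str | Path) -> None:
    cols = ("gene", "snp_count", "indel_count", "length_kb", "snp_density", "indel_density")
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in records:
            fh.write(
                f"{r.gene}\t{r.snp_count}\t{r.indel_count}\t{r.length_kb:.6g}"
                f"\t{r.snp_density:.6g}\t{r.indel_density:.6g}\n"
            )
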