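"""Seeded synthetic inputs with the statistical structure the analysis
assumes, plus the packaged 46-SNP validation-panel table.

The generator emulates the study's two stages at desk scale:

* discovery — per-breed exonic variant tables over a common set of gene
  models, with a configurable fraction of variants shared by all breeds and
  the rest breed-exclusive, functional classes drawn from the discovery-
  stage class mix, and DP/MQ values that pass the default quality filters;
* validation — a diploid genotype matrix for 3 breeds x 18 animals over a
  46-SNP panel, each animal's genotype drawn under Hardy-Weinberg
  (Binomial(2, af) alternate alleles) from per-breed true allele
  frequencies, with uniform random missingness.

Every generator is deterministic under the config seed and keeps a truth
log so downstream modules can be checked against the generator's own
bookkeeping.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .density import GeneModel
from .validation import BREEDS, GenotypeMatrix
from .variant_io import VariantRecord

#: Discovery-stage SNP functional-class mix (synonymous, nonsynonymous,
#: stop-gain, stop-loss, unknown), matching the observed whole-genome
#: proportions for these breeds.
DEFAULT_CLASS_PROBS = (0.5954, 0.3982, 0.0058, 0.0004, 0.0002)
SNP_CLASSES = ("synonymous", "nonsynonymous", "stopgain", "stoploss", "unknown")
_BASES = np.array(["A", "C", "G", "T"])


@dataclass
class SimulationConfig:
    """All knobs of the synthetic generators; identical configs (including
    the seed) give byte-identical outputs."""

    seed: int = 0
    # discovery stage
    n_genes: int = 200
    gene_length_range_bp: tuple[int, int] = (1000, 5000)
    breeds: tuple[str, ...] = BREEDS
    n_variants_per_breed: int = 300
    shared_fraction: float = 0.4
    class_probs: tuple[float, ...] = DEFAULT_CLASS_PROBS
    indel_fraction: float = 0.024
    #: fraction of draws given DP/MQ below the default quality thresholds
    low_quality_fraction: float = 0.0
    # validation stage
    n_snps_panel: int = 46
    n_animals_per_breed: int = 18
    missing_rate: float = 0.02

    def __post_init__(self) -> None:
        if not math_isclose(sum(self.class_probs), 1.0):
            raise ValueError("class probabilities must sum to 1")
        if not 0 <= self.shared_fraction <= 1:
            raise ValueError("shared_fraction must lie in [0, 1]")
        if not 0 <= self.missing_rate <= 0.1:
            raise ValueError("missing_rate must lie in [0, 0.1]")


def math_isclose(a: float, b: float, tol: float = 1e-9) -> bool:
    return abs(a - b) <= tol


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def gen_gene_models(config: SimulationConfig) -> list[GeneModel]:
    """Non-overlapping gene spans on one chromosome, lengths uniform in the
    configured range, separated by random intergenic gaps."""
    if config.n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    lo, hi = config.gene_length_range_bp
    if not 1 <= lo <= hi:
        raise ValueError(f"infeasible gene length range {config.gene_length_range_bp}")
    rng = _rng(config, 1)
    lengths = rng.integers(lo, hi + 1, size=config.n_genes)
    gaps = rng.integers(100, 1001, size=config.n_genes)
    models = []
    cursor = 1
    for i, (length, gap) in enumerate(zip(lengths, gaps)):
        start = cursor + int(gap)
        end = start + int(length) - 1
        models.append(
            GeneModel(gene=f"G{i + 1:04d}", chrom="1", start=start, end=end,
                      ensembl_id=f"ENSOARG{i + 1:011d}")
        )
        cursor = end
    return models


def _draw_variant(
    rng: np.random.Generator,
    models: list[GeneModel],
    config: SimulationConfig,
    used_keys: set[tuple[str, int, str, str]],
) -> VariantRecord:
    while True:
        gene = models[int(rng.integers(len(models)))]
        pos = int(rng.integers(gene.start, gene.end + 1))
        if rng.random() < config.indel_fraction:
            base = str(rng.choice(_BASES))
            ins = str(rng.choice(_BASES))
            if rng.random() < 0.5:
                ref, alt = base, base + ins
            else:
                ref, alt = base + ins, base
            func = "indel_frameshift" if rng.random() < 0.5 else "indel_nonframeshift"
        else:
            ref_i = int(rng.integers(4))
            alt_i = (ref_i + 1 + int(rng.integers(3))) % 4
            ref, alt = str(_BASES[ref_i]), str(_BASES[alt_i])
            func = SNP_CLASSES[int(rng.choice(len(SNP_CLASSES), p=config.class_probs))]
        key = (gene.chrom, pos, ref, alt)
        if key in used_keys:
            continue
        used_keys.add(key)
        if rng.random() < config.low_quality_fraction:
            # fails DP and/or MQ thresholds
            dp, mq = int(rng.integers(0, 5)), float(rng.integers(0, 21))
        else:
            dp, mq = int(rng.integers(5, 61)), float(rng.integers(25, 61))
        return VariantRecord(
            chrom=gene.chrom,
            pos=pos,
            ref=ref,
            alt=alt,
            dp=dp,
            mq=mq,
            region_class="exonic",
            func_class=func,
            gene=gene.gene,
        )


def gen_variant_tables(
    config: SimulationConfig, models: list[GeneModel] | None = None
) -> tuple[dict[str, list[VariantRecord]], dict]:
    """Per-breed exonic variant tables plus a truth log.

    A ``shared_fraction`` of each breed's variants is common to all breeds
    (the three-way core); the remainder is breed-exclusive. The truth log
    records realized counts per comparison cell and per functional class.
    """
    if models is None:
        models = gen_gene_models(config)
    rng = _rng(config, 2)
    n_shared = round(config.shared_fraction * config.n_variants_per_breed)
    n_excl = config.n_variants_per_breed - n_shared
    used: set[tuple[str, int, str, str]] = set()
    shared = [_draw_variant(rng, models, config, used) for _ in range(n_shared)]
    tables: dict[str, list[VariantRecord]] = {}
    truth_cells = {"ABC": n_shared}
    class_counts: dict[str, dict[str, int]] = {}
    for breed in config.breeds:
        exclusive = [_draw_variant(rng, models, config, used) for _ in range(n_excl)]
        records = shared + exclusive
        tables[breed] = records
        truth_cells[f"{breed}_only"] = n_excl
        counts: dict[str, int] = {}
        for r in records:
            counts[r.func_class] = counts.get(r.func_class, 0) + 1
        class_counts[breed] = counts
    truth = {
        "cells": truth_cells,
        "class_counts": class_counts,
        "n_missense": {
            b: sum(1 for r in recs if r.vtype == "SNP" and r.func_class == "nonsynonymous")
            for b, recs in tables.items()
        },
        "n_exonic_indels": {
            b: sum(1 for r in recs if r.vtype in {"INS", "DEL"}) for b, recs in tables.items()
        },
        "n_pass_quality": {
            b: sum(1 for r in recs if r.dp > 4 and r.mq > 20) for b, recs in tables.items()
        },
    }
    return tables, truth


def panel_af_spec(
    config: SimulationConfig,
    n_specific_per_breed: int = 10,
    target_af: float = 0.65,
    other_af: float = 0.20,
    common_af_range: tuple[float, float] = (0.1, 0.9),
    null: bool = False,
) -> pd.DataFrame:
    """True per-breed allele frequencies for a synthetic validation panel.

    Mirrors the study panel's composition: ``n_specific_per_breed``
    breed-specific SNPs per breed (target breed at ``target_af``, the others
    at ``other_af`` — default gap 0.45) and the remainder of
    ``config.n_snps_panel`` as common SNPs with one shared frequency drawn
    uniformly from ``common_af_range``. With ``null=True`` every SNP gets
    equal frequencies in all breeds (the global null).
    """
    rng = _rng(config, 3)
    breeds = config.breeds
    n_common = config.n_snps_panel - n_specific_per_breed * len(breeds)
    if n_common < 0:
        raise ValueError("panel smaller than the requested breed-specific SNPs")
    rows = []
    i = 0
    for breed in breeds:
        for _ in range(n_specific_per_breed):
            i += 1
            if null:
                af = {b: float(rng.uniform(*common_af_range)) for b in breeds}
                af = dict.fromkeys(breeds, af[breeds[0]])
            else:
                af = {b: (target_af if b == breed else other_af) for b in breeds}
            rows.append({"snp_id": f"snp{i:03d}", "wgs_class": f"{breed}-specific",
                         "gene": f"G{i:04d}", "ref": "A", "alt": "G", **{f"af_{b}": af[b] for b in breeds}})
    for _ in range(n_common):
        i += 1
        shared_af = float(rng.uniform(*common_af_range))
        rows.append({"snp_id": f"snp{i:03d}", "wgs_class": "Common",
                     "gene": f"G{i:04d}", "ref": "A", "alt": "G",
                     **{f"af_{b}": shared_af for b in breeds}})
    return pd.DataFrame(rows)


def gen_genotypes(
    config: SimulationConfig, af_spec: pd.DataFrame | None = None, stream: int = 4
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Diploid genotype matrix under Hardy-Weinberg sampling.

    Each animal's genotype at a SNP carries Binomial(2, af_true) alternate
    alleles for its breed's true frequency; each call is masked missing
    independently with ``config.missing_rate``. Returns the matrix and the
    truth table (the allele-frequency spec used).
    """
    if af_spec is None:
        af_spec = panel_af_spec(config)
    for b in config.breeds:
        col = af_spec[f"af_{b}"]
        if ((col < 0) | (col > 1)).any():
            raise ValueError("true allele frequencies must lie in [0, 1]")
    rng = _rng(config, stream)
    samples = [
        (f"{breed}{i + 1:02d}", breed)
        for breed in config.breeds
        for i in range(config.n_animals_per_breed)
    ]
    calls: dict[str, list] = {}
    for _, snp in af_spec.iterrows():
        col = []
        ref, alt = snp["ref"], snp["alt"]
        for _sid, breed in samples:
            if rng.random() < config.missing_rate:
                col.append(None)
                continue
            n_alt = int(rng.binomial(2, float(snp[f"af_{breed}"])))
            col.append(tuple([alt] * n_alt + [ref] * (2 - n_alt)))
        calls[snp["snp_id"]] = col
    df = pd.DataFrame(calls, index=[s for s, _ in samples], dtype=object)
    matrix = GenotypeMatrix(samples=samples, snps=list(af_spec["snp_id"]), calls=df)
    return matrix, af_spec


def validation_panel_fixture() -> pd.DataFrame:
    """The packaged 46-SNP validation panel: per-breed allele frequencies,
    FDR-adjusted q-values, WGS-based classification, and the published
    pattern call for each SNP."""
    with resources.files("breedvar.data").joinpath("validation_panel.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype={"snp_id": str})
    return df


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_gene_models_tsv(models: list[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tensembl_id\tchrom\tstart\tend\n")
        for m in models:
            fh.write(f"{m.gene}\t{m.ensembl_id}\t{m.chrom}\t{m.start}\t{m.end}\n")


def write_genotype_tsv(matrix: GenotypeMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tbreed\t" + "\t".join(matrix.snps) + "\n")
        for sid, breed in matrix.samples:
            tokens = []
            for snp in matrix.snps:
                pair = matrix.calls.at[sid, snp]
                tokens.append("./." if pair is None else f"{pair[0]}/{pair[1]}")
            fh.write(f"{sid}\t{breed}\t" + "\t".join(tokens) + "\n")


_ANNOVAR_CLASS = {
    ("nonsynonymous", "SNP"): "nonsynonymous SNV",
    ("synonymous", "SNP"): "synonymous SNV",
    ("stopgain", "SNP"): "stopgain",
    ("stoploss", "SNP"): "stoploss",
    ("unknown", "SNP"): "unknown",
    ("indel_frameshift", "INS"): "frameshift insertion",
    ("indel_frameshift", "DEL"): "frameshift deletion",
    ("indel_nonframeshift", "INS"): "nonframeshift insertion",
    ("indel_nonframeshift", "DEL"): "nonframeshift deletion",
}


def write_annovar_exonic(records, path: str | Path) -> None:
    """Serialize exonic records in the ANNOVAR exonic_variant_function
    dialect that :func:`breedvar.variant_io.read_variant_table` consumes."""
    with open(path, "w") as fh:
        for i, r in enumerate(records, start=1):
            func = _ANNOVAR_CLASS[(r.func_class, r.vtype)]
            end = r.pos + max(len(r.ref), 1) - 1
            gene_str = f"{r.gene}:XM_{i:06d}:exon1:c.{r.ref}{i}{r.alt}"
            fh.write(
                f"line{i}\t{func}\t{gene_str}\t{r.chrom}\t{r.pos}\t{end}\t{r.ref}\t{r.alt}\n"
            )


def write_vcf(records, path: str | Path) -> None:
    """Minimal sorted single-sample VCF with per-site DP and MQ INFO fields."""
    recs = sorted(records, key=lambda r: (r.chrom, r.pos, r.ref, r.alt))
    contigs = sorted({r.chrom for r in recs})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##INFO=<ID=MQ,Number=1,Type=Float,Description="Mapping quality">\n')
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in recs:
            rsid = r.rsid or "."
            fh.write(
                f"{r.chrom}\t{r.pos}\t{rsid}\t{r.ref}\t{r.alt}\t.\t.\tDP={r.dp};MQ={r.mq:g}\n"
            )


def write_truth_log(truth: Mapping, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
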