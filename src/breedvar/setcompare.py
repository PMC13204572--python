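"""Shared/exclusive partitioning of variant and gene sets across breeds.

Variant identity is positional — ``(chrom, pos, ref, alt)`` with uppercased
alleles — never the rsID, which is carried only as a label. Pairwise and
three-way comparisons of 2-3 breeds produce disjoint cells that cover the
union of the inputs; the thirteen-list report bundles the 9 pairwise lists
(3 pairs x {shared, exclusive-to-first, exclusive-to-second}) with the 4
three-way lists (core plus one exclusive set per breed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Hashable, Iterable, Mapping

from .variant_io import VariantRecord

THREEWAY_CELLS = ("ABC", "AB", "AC", "BC", "A_only", "B_only", "C_only")


def make_key(record: VariantRecord) -> str:
    """Canonical positional identity key ``chrom:pos:REF:ALT``."""
    if not record.ref or not record.alt:
        raise ValueError("record has empty allele")
    return f"{record.chrom}:{record.pos}:{record.ref.upper()}:{record.alt.upper()}"


def variant_keys(records: Iterable[VariantRecord]) -> set[str]:
    return {make_key(r) for r in records}


def gene_set(records: Iterable[VariantRecord]) -> set[str]:
    """Upper-cased gene symbols carrying at least one variant."""
    return {r.gene.upper() for r in records if r.gene}


@dataclass
class PartitionResult:
    """Seven disjoint cells of a three-way set comparison."""

    labels: tuple[str, str, str]
    cells: dict[str, set[Hashable]]

    def sizes(self) -> dict[str, int]:
        return {name: len(s) for name, s in self.cells.items()}


def pairwise_partition(
    set_a: set[Hashable], set_b: set[Hashable]
) -> tuple[set[Hashable], set[Hashable], set[Hashable]]:
    """``(shared, only_a, only_b)`` = (A∩B, A\\B, B\\A)."""
    return set_a & set_b, set_a - set_b, set_b - set_a


def threeway_partition(
    set_a: set[Hashable],
    set_b: set[Hashable],
    set_c: set[Hashable],
    labels: tuple[str, str, str] = ("A", "B", "C"),
) -> PartitionResult:
    cells = {
        "ABC": set_a & set_b & set_c,
        "AB": (set_a & set_b) - set_c,
        "AC": (set_a & set_c) - set_b,
        "BC": (set_b & set_c) - set_a,
        "A_only": set_a - set_b - set_c,
        "B_only": set_b - set_a - set_c,
        "C_only": set_c - set_a - set_b,
    }
    return PartitionResult(labels=tuple(labels), cells=cells)


def thirteen_list_report(
    set_a: set[Hashable],
    set_b: set[Hashable],
    set_c: set[Hashable],
    labels: tuple[str, str, str] = ("A", "B", "C"),
) -> dict[str, set[Hashable]]:
    """The thirteen shared/exclusive lists from pairwise and three-way
    comparisons of three populations.

    Names: for each ordered pair XY — ``X-Y_shared``, ``X-Y_only_X``,
    ``X-Y_only_Y`` (9 lists); plus ``core`` (all three) and ``X_exclusive``
    per population (4 lists).
    """
    la, lb, lc = labels
    sets = dict(zip(labels, (set_a, set_b, set_c)))
    report: dict[str, set[Hashable]] = {}
    for x, y in ((la, lb), (la, lc), (lb, lc)):
        shared, only_x, only_y = pairwise_partition(sets[x], sets[y])
        report[f"{x}-{y}_shared"] = shared
        report[f"{x}-{y}_only_{x}"] = only_x
        report[f"{x}-{y}_only_{y}"] = only_y
    three = threeway_partition(set_a, set_b, set_c, labels)
    report["core"] = three.cells["ABC"]
    report[f"{la}_exclusive"] = three.cells["A_only"]
    report[f"{lb}_exclusive"] = three.cells["B_only"]
    report[f"{lc}_exclusive"] = three.cells["C_only"]
    assert len(report) == 13
    return report


def venn_counts(
    partition: PartitionResult,
    pairwise_sets: Mapping[str, set[Hashable]] | None = None,
) -> dict:
    """JSON-ready cell sizes: the 7 three-way cells plus pairwise margins."""
    la, lb, lc = partition.labels
    sets = {
        la: partition.cells["ABC"] | partition.cells["AB"] | partition.cells["AC"] | partition.cells["A_only"],
        lb: partition.cells["ABC"] | partition.cells["AB"] | partition.cells["BC"] | partition.cells["B_only"],
        lc: partition.cells["ABC"] | partition.cells["AC"] | partition.cells["BC"] | partition.cells["C_only"],
    }
    out = {"labels": list(partition.labels), "cells": partition.sizes(), "pairwise": {}}
    for x, y in ((la, lb), (la, lc), (lb, lc)):
        shared, only_x, only_y = pairwise_partition(sets[x], sets[y])
        out["pairwise"][f"{x}-{y}"] = {
            "shared": len(shared),
            f"only_{x}": len(only_x),
            f"only_{y}": len(only_y),
        }
    return out


def write_report(
    report: Mapping[str, set[Hashable]], out_dir: str | Path, prefix: str = ""
) -> None:
    """One sorted single-column TSV per list, plus a sizes JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sizes = {}
    for name, members in report.items():
        sizes[name] = len(members)
        fname = f"{prefix}{name}.tsv".replace("/", "_")
        with open(out_dir / fname, "w") as fh:
            for m in sorted(members, key=str):
                fh.write(f"{m}\n")
    with open(out_dir / f"{prefix}list_sizes.json", "w") as fh:
        json.dump(sizes, fh, indent=2, sort_keys=True)
        fh.write("\n")
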