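"""Shared and breed-exclusive variation across the three breeds.

Partitions the filtered variant sets (positional identity) and the derived
missense gene sets pairwise and three-way, writes the thirteen shared/
exclusive lists per level plus Venn-count JSONs, and cross-checks the
three-way SNP cells against the generator's truth log when present.
"""

import argparse
import json
import sys
from pathlib import Path

from breedvar import density, setcompare, variant_io

BREEDS = ("LES", "SER", "THR")


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--filtered-dir", type=Path, default=Path("results/filtered"))
    parser.add_argument("--truth", type=Path, default=Path("results/synthetic/truth.json"))
    parser.add_argument("--out-dir", type=Path, default=Path("results/overlap"))
    args = parser.parse_args()

    records = {
        b: variant_io.read_variant_tsv(args.filtered_dir / f"{b}.filtered.tsv") for b in BREEDS
    }
    levels = {
        "snp": {b: setcompare.variant_keys(r) for b, r in records.items()},
        "gene": {b: setcompare.gene_set(density.select_missense(r)) for b, r in records.items()},
    }
    for level, sets in levels.items():
        part = setcompare.threeway_partition(*(sets[b] for b in BREEDS), labels=BREEDS)
        report = setcompare.thirteen_list_report(*(sets[b] for b in BREEDS), labels=BREEDS)
        out = args.out_dir / level
        setcompare.write_report(report, out)
        with open(out / "venn_counts.json", "w") as fh:
            json.dump(setcompare.venn_counts(part), fh, indent=2)
        sizes = part.sizes()
        print(
            f"{level}-level: core {sizes['ABC']}, exclusives "
            + ", ".join(f"{b} {sizes[c]}" for b, c in zip(BREEDS, ("A_only", "B_only", "C_only")))
        )

    if args.truth.exists():
        truth = json.loads(args.truth.read_text())["cells"]
        sizes = setcompare.threeway_partition(*(levels["snp"][b] for b in BREEDS)).sizes()
        # truth counts are pre-QC; report the comparison rather than assert
        print(
            f"truth log (pre-QC): core {truth['ABC']}, exclusives "
            + ", ".join(str(truth[f"{b}_only"]) for b in BREEDS)
            + f" | observed post-QC core {sizes['ABC']}"
        )


if __name__ == "__main__":
    sys.exit(main())
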