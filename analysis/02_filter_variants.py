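"""Discovery-stage quality control per breed.

Reads each breed's VCF, applies the DP > 4 and MQ > 20 site filters, then
restricts the matching ANNOVAR exonic annotations to the passing sites,
drops records with missing/invalid gene annotations, collapses duplicate
entries, and writes the filtered annotated table plus a filter report.
Also tallies the SNP functional classes per breed.
"""

import argparse
import json
import sys
from pathlib import Path

from breedvar import setcompare, variant_io

BREEDS = ("LES", "SER", "THR")


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--in-dir", type=Path, default=Path("results/synthetic"))
    parser.add_argument("--out-dir", type=Path, default=Path("results/filtered"))
    parser.add_argument("--dp-min", type=int, default=4)
    parser.add_argument("--mq-min", type=float, default=20)
    args = parser.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    tallies = {}
    for breed in BREEDS:
        sites = variant_io.read_variant_table(args.in_dir / f"{breed}.vcf", "vcf")
        passing, report = variant_io.apply_quality_filters(sites, args.dp_min, args.mq_min)
        pass_keys = {setcompare.make_key(r) for r in passing}
        annotated = variant_io.read_variant_table(args.in_dir / f"{breed}.exonic", "annovar_exonic")
        annotated = [r for r in annotated if setcompare.make_key(r) in pass_keys]
        clean = variant_io.normalize_and_dedupe(annotated)
        variant_io.write_variant_tsv(clean, args.out_dir / f"{breed}.filtered.tsv")
        variant_io.write_filter_report(report, args.out_dir / f"{breed}.filter_report.json")
        snps = [r for r in clean if r.vtype == "SNP"]
        tallies[breed] = variant_io.tally_functional_classes(snps).counts
        print(
            f"{breed}: {report.n_input} sites, {report.n_kept} pass QC "
            f"({report.removed_low_dp} low DP, {report.removed_low_mq} low MQ); "
            f"{len(clean)} annotated records retained"
        )
    with open(args.out_dir / "functional_class_tallies.json", "w") as fh:
        json.dump(tallies, fh, indent=2)
    print(f"functional-class tallies -> {args.out_dir / 'functional_class_tallies.json'}")


if __name__ == "__main__":
    sys.exit(main())
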