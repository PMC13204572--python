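"""Per-gene variant density per breed.

Prioritizes missense SNPs and exonic indels from the filtered tables, maps
them onto the gene models, computes SNPs/kb and indels/kb over the genomic
span of each gene, and writes the full density table plus the top-20
rankings per metric for each breed.
"""

import argparse
import sys
from pathlib import Path

from breedvar import density, variant_io

BREEDS = ("LES", "SER", "THR")


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--filtered-dir", type=Path, default=Path("results/filtered"))
    parser.add_argument("--genes", type=Path, default=Path("results/synthetic/gene_models.tsv"))
    parser.add_argument("--out-dir", type=Path, default=Path("results/density"))
    parser.add_argument("--top", type=int, default=20)
    args = parser.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    lengths = density.compute_gene_lengths(density.read_gene_models(args.genes))
    for breed in BREEDS:
        records = variant_io.read_variant_tsv(args.filtered_dir / f"{breed}.filtered.tsv")
        snps = density.select_missense(records)
        indels = density.select_exonic_indels(records)
        dens, unmapped = density.compute_density(snps, indels, lengths)
        density.write_density_tsv(dens, args.out_dir / f"{breed}.density.tsv")
        for metric in ("snp_density", "indel_density"):
            top = density.top_n(dens, metric, args.top)
            density.write_density_tsv(top, args.out_dir / f"{breed}.top{args.top}.{metric}.tsv")
        lead = density.top_n(dens, "snp_density", 1)[0] if dens else None
        print(
            f"{breed}: {len(snps)} missense SNPs, {len(indels)} exonic indels over "
            f"{len(dens)} genes ({len(unmapped)} genes without coordinates); "
            + (f"densest gene {lead.gene} at {lead.snp_density:.2f} SNPs/kb" if lead else "")
        )


if __name__ == "__main__":
    sys.exit(main())
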