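# Methods

## Scope and data model

The package analyzes coding variation in three sheep breeds in two stages:
a discovery stage over per-breed annotated variant tables, and a validation
stage over a genotyped SNP panel. It deliberately begins *after* read
processing: alignment, variant calling, and functional annotation are
upstream tools' jobs, and the package consumes their output formats (VCF
with per-site DP/MQ, ANNOVAR-style exonic variant tables, BED/TSV gene
models, GMT gene sets, wide genotype TSVs).

Coordinates are 1-based inclusive everywhere internally (the VCF
convention); BED input is converted on read (start + 1). Variant identity
is positional — `(chrom, pos, ref, alt)` with upper-cased alleles — never
the rsID, which is carried as a label only. This matches how panels are
actually cross-referenced: rsIDs are frequently absent, and positional IDs
(e.g. `11:41098506`) must interoperate with them.

## Discovery stage

**Quality filtering.** Sites are retained when DP > 4 *and* MQ > 20, both
strict inequalities. Records missing either field are rejected and counted
(first failing check wins: missing fields, then DP, then MQ), so the filter
report's categories always sum to the number removed and the filter is
idempotent.

**Normalization.** Multi-allelic sites are split into one record per
alternate allele before anything else. Gene-annotation placeholders
(`""`, `NA`, `NONE`, `-`, case-insensitive) mark a record invalid and drop
it; duplicates (identical positional identity) collapse to the first
occurrence — deterministic and order-stable. Indel alleles are kept exactly
as written; no left-normalization is attempted, so the same physical indel
written two ways counts as two identities. This is a documented limitation.

**Prioritization.** Missense = exonic SNP with a nonsynonymous annotation.
SNPs with an `unknown` functional annotation are simply not missense and
are excluded at this step (no separate pre-filter removes them earlier);
whether such variants should be discarded before prioritization is
ambiguous in practice, but the end result here is the same set. All exonic
indels are retained regardless of frameshift status.

**Gene length and density.** A gene's length is the genomic span
`end − start + 1` of its coordinates, merged across multiple entries (min
start, max end; two chromosomes for one symbol is an error). Span-based
length — not summed exon length — is the choice because the coordinates
come from gene-level BioMart-style exports; densities are therefore
comparable within this package but not with transcript-resolved metrics.
Densities are `count / length_kb`. Genes carrying variants but lacking
coordinates are excluded and reported, never assigned infinite density.
Rankings sort by descending metric with ties broken lexicographically on
the gene symbol, for full determinism.

**Set comparison.** Pairwise partitions are plain set algebra; the
three-way partition produces the seven disjoint cells, and the thirteen-
list report bundles 9 pairwise lists with the 4 three-way lists. Gene-level
comparison uses upper-cased symbols after deduplication.

**Over-representation analysis.** The enrichment module is a generic
hypergeometric ORA with BH (default) or Bonferroni correction: p =
P(X ≥ k) for X ~ Hypergeometric(N, K, n) with the universe defaulting to
the union of the GMT's members. Query genes outside the universe are
dropped with a warning, mirroring how background-restricted services
behave. The upper tail is evaluated by `scipy.stats.hypergeom.sf`, which
works in log space internally. Proprietary multiple-testing schemes used
by enrichment web services are intentionally not imitated, so q-values
from this module are comparable only within a run, and no attempt is made
to reproduce database-versioned term lists.

## Validation stage

**QC.** Samples with call rate < 0.90 are dropped first, then SNPs with
call rate < 0.90 over the remaining samples. Allele frequencies are
computed per breed over non-missing calls only; a breed with no calls at a
SNP yields an undefined (reported missing) frequency.

**Exact test.** Allele counts per SNP form a 2 × c table (rows ref/alt,
columns breeds). The test enumerates every margin-consistent table, scores
it with the multivariate hypergeometric mass, and sums the masses of
tables with P(T) ≤ P(obs) · (1 + 1e−7). The relative tie tolerance guards
against floating-point misses of exactly tied tables (ties are common:
column permutations of the observed table often have identical
probability). Implementation notes:

* log-space throughout, with a precomputed log-factorial table grown on
  demand;
* the enumeration for a margin configuration is computed once, sorted, and
  cached with its running probability sums, so repeated tests (e.g. panel
  sweeps, simulations) cost one binary search each;
* allele-count tables, not genotype tables, are tested — the question is
  homogeneity of allele distributions across breeds.

The Pearson chi-square alternative (upper tail of the χ² distribution via
the regularized incomplete gamma function, df = (r−1)(c−1)) is available,
with the classical expected-count < 5 rule as an automatic chooser. The
pipeline default is `fisher-always`: with 36 alleles per breed and panel
allele frequencies regularly near 0 or 1, small expected counts are the
norm, and a single uniform method keeps the panel internally consistent.

**FDR.** BH step-up, implemented directly: sort ascending, rᵢ = p₍ᵢ₎·m/i,
q₍ᵢ₎ = min over j ≥ i of rⱼ, capped at 1, mapped back to input order. The
family is the whole panel passing QC (m = number of SNPs tested together);
a larger m may be passed when only part of a family is being adjusted.

**Pattern classification.** Per SNP, given its discovery-phase (WGS)
class, per-breed allele frequencies, and q:

* Common: `Shared` if q ≥ α, else `Inconsistent` (a significantly
  differentiated "common" SNP contradicts its classification; a
  deterministic rule is required even though the packaged panel contains
  no such case).
* Breed-specific: the target breed must hold the *strict* frequency
  maximum, else `Inconsistent`. With the maximum: q < α → `Significant`;
  otherwise margin = target AF − best other AF, and margin ≥ δ →
  `Consistent (NS)`, else `Inconsistent`.

Defaults are α = 0.05 and δ = 0.08. δ is a package choice: the packaged
panel's printed labels bound the implied threshold to the interval
(0.06, 0.09] — the largest margin labeled Inconsistent is 0.06 and the
smallest labeled Consistent (NS) is 0.09 — and 0.08 sits inside that
interval; it is configurable. The margin comparison carries a 1e−9
absolute tolerance so decimal frequencies that are not exactly
representable in binary (e.g. 0.48 − 0.40) compare as intended.
Classifying the packaged 46-row panel with these defaults reproduces the
printed pattern column exactly (18 Significant, 8 Consistent (NS), 16
Shared, 4 Inconsistent). The panel's source text elsewhere summarizes the
same table as 17 significant and five inconsistent loci; the table and its
labels are treated as authoritative here, and the discrepancy is surfaced
rather than resolved.

**Recomputation from published frequencies.** Allele counts are
reconstructed from frequencies rounded to two decimals via
alt = ⌊af · 2n + 0.5⌋ (round half-up) with n = 18 called animals per
breed, then tested and BH-adjusted (m = 46). Because the printed
frequencies are rounded, exact agreement with the published q-values is
not expected; on the packaged panel the recomputed q < 0.05 status agrees
with the printed Significant/non-Significant labels for 45 of 46 SNPs.

## Synthetic data

The generator emulates the study conditions, not the genome:

* **Gene models** — non-overlapping spans on one chromosome, lengths
  uniform in 1–5 kb, separated by 0.1–1 kb gaps. Real gene-length
  distributions are heavier-tailed; nothing downstream depends on that.
* **Variant tables** — 300 variants per breed with a 40% three-way-shared
  core and the remainder breed-exclusive (the scale of a desk-size
  pairwise/three-way comparison; whole-genome totals are ~60× larger but
  exercise identical code paths). Functional classes are drawn with
  probabilities (0.5954, 0.3982, 0.0058, 0.0004, 0.0002) over synonymous /
  nonsynonymous / stop-gain / stop-loss / unknown — the whole-genome class
  proportions observed for these breeds — plus a 2.4% indel fraction.
  DP/MQ are drawn to pass the default filters; an optional
  `low_quality_fraction` draws sub-threshold values for filter exercises.
  Only the three-way core and per-breed exclusives are populated (no
  two-breed-only cells): that is the structure the shared/exclusive truth
  log can specify exactly with one parameter.
* **Genotypes** — 46 SNPs × 18 animals/breed. Genotypes are Hardy–Weinberg
  draws, Binomial(2, af_true) alternate alleles per animal, no inbreeding
  coefficient, no LD between SNPs; missingness is uniform at 2% (observed
  call rates 90–100%, mostly above 95%). The default panel composition
  mirrors the study: 10 breed-specific SNPs per breed (target breed 0.65
  vs 0.20 elsewhere — a 0.45 gap) and 16 common SNPs with one shared
  frequency drawn uniformly from 0.1–0.9.

Because the generator omits LD, kinship, genotyping-error structure, and
realistic gene-length tails, passing tests demonstrate correctness of the
computations and calibration of the statistics under the stated sampling
model — not robustness to those real-data complications.

All generators derive independent RNG streams from the single config seed,
so identical configs give byte-identical outputs.

## Calibration

On synthetic cohorts at the validation shape (46 SNPs, 18 animals/breed,
200 seeded replicates): under the global null (equal true frequencies in
all breeds) the mean fraction of SNPs with q < 0.05 stays below 0.05, as
BH guarantees; under the designed 0.45 frequency gap, well over 70% of
truly breed-specific SNPs are recovered as Significant. Both checks run in
the test suite.

## Numerical choices, in one place

* strict inequalities for DP/MQ thresholds; first-failing-check accounting;
* exact-test tie tolerance P(obs)·(1 + 1e−7); log-factorial lookup table;
  per-margin enumeration cache (LRU, 16384 configurations);
* BH implemented by reverse running minimum; p-values outside (0, 1]
  rejected;
* classifier margin tolerance 1e−9; round-half-up count reconstruction;
* lexicographic tie-breaks in all rankings and sorted set serialization,
  so every output is deterministic.

## Known limitations

* No indel left-normalization; positional identity can split equivalent
  indels.
* Span-based gene lengths overstate the mutational target of genes with
  long introns; densities are comparable within, not across, conventions.
* The exact test enumerates margin-consistent tables, which is fast for
  2 × 3 allele tables at panel sample sizes but grows with margins and
  column count; very large tables should use the chi-square path.
* The ORA module is a generic hypergeometric test; it does not reproduce
  any specific enrichment service's corrected q-values or term databases.
* Whole-genome discovery counts (tens of thousands of missense SNPs per
  breed) require the original sequencing data and annotation databases;
  the package reproduces the *procedures* at desk scale and validates them
  property-by-property instead.
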