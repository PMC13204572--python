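"""Validation-phase statistics for a genotyped SNP panel.

Given diploid genotype calls for three breeds (or a table of already
published per-breed allele frequencies), this module provides:

* call-rate QC at >= 90% completeness, samples first, then SNPs;
* per-breed allele frequencies over non-missing calls;
* an exact two-sided test of homogeneity of allele distributions across
  breeds on the 2 x c allele-count table (rows ref/alt, one column per
  breed), by complete enumeration of margin-consistent tables: each table T
  has multivariate hypergeometric probability
  ``P(T) = (prod row-margins!)(prod col-margins!) / (N! prod cells!)`` and
  the p-value sums P(T) over tables no more probable than the observed one
  (with a small relative tie tolerance against floating-point misses);
* the Pearson chi-square alternative and an expected-count<5 chooser;
* Benjamini-Hochberg step-up FDR adjustment;
* the four-way pattern call per SNP — Significant / Consistent (NS) /
  Shared / Inconsistent — relating observed breed allele frequencies to the
  discovery-phase (WGS) classification of the SNP as breed-specific or
  common.

All computations on the exact test run in log space with a precomputed
log-factorial table; enumerations are cached per margin configuration.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2

BREEDS = ("LES", "SER", "THR")
MISSING_TOKEN = "./."

PATTERN_SIGNIFICANT = "Significant"
PATTERN_CONSISTENT_NS = "Consistent (NS)"
PATTERN_SHARED = "Shared"
PATTERN_INCONSISTENT = "Inconsistent"

#: Relative tie tolerance of the exact test: tables with
#: P(T) <= P(obs) * (1 + _TIE_REL) count toward the tail.
_TIE_REL = 1e-7
#: Absolute tolerance on the margin-vs-delta comparison in the classifier,
#: so frequency differences representable only approximately in binary
#: (e.g. 0.48 - 0.40) still compare as intended.
_MARGIN_EPS = 1e-9


# ---------------------------------------------------------------------------
# exact and asymptotic contingency tests
# ---------------------------------------------------------------------------

_logfact = gammaln(np.arange(1024, dtype=float) + 1.0)


def _lf(n: int) -> float:
    global _logfact
    if n >= _logfact.size:
        _logfact = gammaln(np.arange(max(n + 1, 2 * _logfact.size), dtype=float) + 1.0)
    return float(_logfact[n])


@lru_cache(maxsize=16384)
def _margin_enumeration(row0: int, row1: int, cols: tuple[int, ...]):
    """All 2xc tables with the given margins, summarized for tail sums.

    First rows are enumerated column by column with numpy; the last column
    is determined by the first-row margin. Returns the ascending-sorted
    log-probabilities and the running sum of the corresponding
    probabilities, so a p-value is one binary search plus one lookup.
    """
    global _logfact
    n_total = row0 + row1
    _lf(n_total)  # grow the table once
    c = len(cols)
    partial = np.zeros((1, 0), dtype=np.int64)
    for j in range(c - 1):
        vals = np.arange(min(row0, cols[j]) + 1, dtype=np.int64)
        partial = np.hstack(
            [
                np.repeat(partial, vals.size, axis=0),
                np.tile(vals, partial.shape[0])[:, None],
            ]
        )
        partial = partial[partial.sum(axis=1) <= row0]
    last = row0 - partial.sum(axis=1)
    ok = (last >= 0) & (last <= cols[-1])
    first_rows = np.hstack([partial[ok], last[ok][:, None]])
    cols_arr = np.asarray(cols, dtype=np.int64)
    second_rows = cols_arr[None, :] - first_rows
    const = _lf(row0) + _lf(row1) + sum(_lf(cj) for cj in cols) - _lf(n_total)
    logp = const - _logfact[first_rows].sum(axis=1) - _logfact[second_rows].sum(axis=1)
    logp_sorted = np.sort(logp)
    cum = np.cumsum(np.exp(logp_sorted))
    return logp_sorted, cum


def _validate_2xc(table) -> np.ndarray:
    t = np.asarray(table, dtype=np.int64)
    if t.ndim != 2 or t.shape[0] != 2:
        raise ValueError(f"expected a 2 x c table, got shape {t.shape}")
    if t.shape[1] < 2:
        raise ValueError("need at least 2 columns (populations)")
    if (t < 0).any():
        raise ValueError("negative cell count")
    if t.sum() < 1:
        raise ValueError("empty table")
    return t


def fisher_exact_2xc(table) -> float:
    """Exact two-sided p-value for a 2 x c contingency table.

    Enumerates every table sharing the observed margins and sums the
    multivariate hypergeometric probabilities of those no more probable
    than the observed table (relative tie tolerance 1e-7). Exact for any
    column count; intended for allele-count rows x breed columns.
    """
    t = _validate_2xc(table)
    row0, row1 = int(t[0].sum()), int(t[1].sum())
    cols = tuple(int(x) for x in t.sum(axis=0))
    logp_sorted, cum = _margin_enumeration(row0, row1, cols)
    n_total = row0 + row1
    const = _lf(row0) + _lf(row1) + sum(_lf(cj) for cj in cols) - _lf(n_total)
    logp_obs = const - sum(_lf(int(x)) for x in t.ravel())
    idx = int(np.searchsorted(logp_sorted, logp_obs + math.log1p(_TIE_REL), side="right"))
    p = float(cum[idx - 1])  # idx >= 1: the observed table is enumerated
    return min(max(p, 5e-324), 1.0)


def chisq_test(table) -> tuple[float, float]:
    """Pearson chi-square test of homogeneity; returns ``(statistic, p)``.

    ``p`` is the upper tail of the chi-squared distribution with
    ``(r-1)(c-1)`` degrees of freedom. Raises if any expected count is zero
    (caller should fall back to the exact test).
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2:
        raise ValueError("expected a 2-D table")
    if (t < 0).any():
        raise ValueError("negative cell count")
    n = t.sum()
    if n <= 0:
        raise ValueError("empty table")
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / n
    if (expected <= 0).any():
        raise ValueError("zero expected count; use the exact test")
    stat = float(((t - expected) ** 2 / expected).sum())
    df = (t.shape[0] - 1) * (t.shape[1] - 1)
    return stat, float(chi2.sf(stat, df))


def choose_test(table, mode: str = "auto") -> tuple[float, str]:
    """``(p, method)`` — exact test when any expected count is below 5
    (or always, in ``"fisher-always"`` mode), else chi-square."""
    t = _validate_2xc(table)
    if mode == "fisher-always":
        return fisher_exact_2xc(t), "fisher"
    if mode != "auto":
        raise ValueError(f"unknown mode {mode!r}")
    n = t.sum()
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / n
    if (expected < 5).any():
        return fisher_exact_2xc(t), "fisher"
    _, p = chisq_test(t)
    return p, "chisq"


def bh_adjust(pvalues: Sequence[float], m: int | None = None) -> list[float]:
    """Benjamini-Hochberg step-up q-values, in input order.

    ``m`` defaults to ``len(pvalues)``; a larger family size may be supplied
    when only part of the family is passed in.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return []
    if (p <= 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in (0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError("family size m cannot be smaller than the number of p-values")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, p.size + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q.tolist()


# ---------------------------------------------------------------------------
# genotype matrix, QC, allele frequencies
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Diploid calls for samples x SNPs with breed labels.

    ``calls`` is a pandas DataFrame (index: sample ids, columns: SNP ids)
    whose entries are ``(allele, allele)`` tuples or ``None`` for missing.
    """

    samples: list[tuple[str, str]]
    snps: list[str]
    calls: pd.DataFrame

    @property
    def sample_breeds(self) -> dict[str, str]:
        return dict(self.samples)

    def call_rate_by_sample(self) -> pd.Series:
        return self.calls.notna().mean(axis=1)

    def call_rate_by_snp(self) -> pd.Series:
        return self.calls.notna().mean(axis=0)


@dataclass
class AlleleFrequencyRecord:
    """Per-breed allele counts and alternate-allele frequency for one SNP.

    ``by_breed`` maps breed -> ``(n_called, ref_count, alt_count, af)``;
    ``af`` is ``None`` when no animal of that breed was called.
    """

    snp_id: str
    by_breed: dict[str, tuple[int, int, int, float | None]]


def load_genotypes(
    path: str | Path,
    breeds: Sequence[str] = BREEDS,
    ref_alt: Mapping[str, tuple[str, str]] | None = None,
) -> GenotypeMatrix:
    """Load a wide genotype TSV: ``sample_id  breed  <snp1> <snp2> ...``
    with tokens like ``A/G`` and ``./.`` for missing.

    When ``ref_alt`` is given, every called allele is validated against the
    SNP's declared ref/alt pair.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["sample_id", "breed"]:
        raise ValueError("genotype TSV must start with sample_id and breed columns")
    snp_ids = list(df.columns[2:])
    samples: list[tuple[str, str]] = []
    parsed: dict[str, list] = {s: [] for s in snp_ids}
    breed_set = set(breeds)
    for _, row in df.iterrows():
        breed = row["breed"]
        if breed not in breed_set:
            raise ValueError(f"unknown breed label {breed!r} for sample {row['sample_id']!r}")
        samples.append((row["sample_id"], breed))
        for snp in snp_ids:
            token = row[snp]
            if token == MISSING_TOKEN or (isinstance(token, float) and math.isnan(token)):
                parsed[snp].append(None)
                continue
            alleles = str(token).split("/")
            if len(alleles) != 2 or not all(alleles):
                raise ValueError(
                    f"sample {row['sample_id']!r}, SNP {snp!r}: bad genotype token {token!r}"
                )
            pair = (alleles[0].upper(), alleles[1].upper())
            if ref_alt is not None and snp in ref_alt:
                allowed = set(ref_alt[snp])
                if not set(pair) <= allowed:
                    raise ValueError(
                        f"sample {row['sample_id']!r}, SNP {snp!r}: allele outside "
                        f"declared ref/alt {ref_alt[snp]}"
                    )
            parsed[snp].append(pair)
    calls = pd.DataFrame(parsed, index=[s for s, _ in samples], columns=snp_ids, dtype=object)
    return GenotypeMatrix(samples=samples, snps=snp_ids, calls=calls)


def qc_call_rates(
    matrix: GenotypeMatrix, threshold: float = 0.90
) -> tuple[GenotypeMatrix, dict]:
    """Drop samples with call rate < threshold, then SNPs with call rate <
    threshold over the remaining samples. Returns the filtered matrix and a
    report of all rates and exclusions."""
    sample_rates = matrix.call_rate_by_sample()
    keep_samples = sample_rates[sample_rates >= threshold].index
    if len(keep_samples) == 0:
        raise ValueError("all samples fell below the call-rate threshold")
    calls = matrix.calls.loc[keep_samples]
    snp_rates = calls.notna().mean(axis=0)
    keep_snps = snp_rates[snp_rates >= threshold].index
    calls = calls[keep_snps]
    breeds = matrix.sample_breeds
    report = {
        "threshold": threshold,
        "sample_call_rates": sample_rates.round(6).to_dict(),
        "snp_call_rates": snp_rates.round(6).to_dict(),
        "excluded_samples": sorted(set(matrix.calls.index) - set(keep_samples)),
        "excluded_snps": sorted(set(matrix.snps) - set(keep_snps)),
    }
    filtered = GenotypeMatrix(
        samples=[(s, breeds[s]) for s in calls.index],
        snps=list(calls.columns),
        calls=calls,
    )
    return filtered, report


def allele_frequencies(
    matrix: GenotypeMatrix, ref_alt: Mapping[str, tuple[str, str]]
) -> list[AlleleFrequencyRecord]:
    """Per-SNP, per-breed allele counts over non-missing calls only."""
    breeds_of = matrix.sample_breeds
    out = []
    for snp in matrix.snps:
        ref, alt = ref_alt[snp]
        by_breed: dict[str, tuple[int, int, int, float | None]] = {}
        col = matrix.calls[snp]
        for breed in sorted({b for _, b in matrix.samples}):
            idx = [s for s, b in matrix.samples if b == breed]
            n_called = ref_count = alt_count = 0
            for s in idx:
                pair = col[s]
                if pair is None:
                    continue
                n_called += 1
                for a in pair:
                    if a == alt:
                        alt_count += 1
                    elif a == ref:
                        ref_count += 1
                    else:
                        raise ValueError(f"SNP {snp}: unexpected allele {a!r}")
            af = alt_count / (2 * n_called) if n_called else None
            by_breed[breed] = (n_called, ref_count, alt_count, af)
        out.append(AlleleFrequencyRecord(snp_id=snp, by_breed=by_breed))
    return out


# ---------------------------------------------------------------------------
# pattern classification
# ---------------------------------------------------------------------------


@dataclass
class ClassifierConfig:
    """Tunables of the pattern classifier.

    ``alpha`` — FDR significance level on q. ``delta`` — minimum allele-
    frequency margin of the target breed over the best other breed for a
    non-significant SNP to count as following the expected trend
    (Consistent (NS)) rather than Inconsistent. ``m`` — FDR family size;
    defaults to the number of SNPs tested together.
    """

    alpha: float = 0.05
    delta: float = 0.08
    m: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 <= self.delta < 1:
            raise ValueError("delta must be in [0, 1)")


@dataclass(frozen=True)
class PatternCall:
    snp_id: str
    wgs_class: str
    pattern: str
    margin: float | None


def classify_pattern(
    wgs_class: str,
    af_by_breed: Mapping[str, float],
    q: float,
    config: ClassifierConfig = ClassifierConfig(),
    snp_id: str = "",
) -> PatternCall:
    """Four-way pattern call for one SNP.

    Common SNPs: ``Shared`` when q >= alpha, else ``Inconsistent``.
    Breed-specific SNPs (``"LES-specific"`` etc.): the target breed must
    hold the strict allele-frequency maximum, else ``Inconsistent``;
    with the maximum, q < alpha gives ``Significant``, a margin of at least
    ``delta`` over the best other breed gives ``Consistent (NS)``, and
    anything smaller is ``Inconsistent``.
    """
    for breed, af in af_by_breed.items():
        if af is None or (isinstance(af, float) and math.isnan(af)):
            raise ValueError(f"missing allele frequency for breed {breed}")
    if wgs_class == "Common":
        pattern = PATTERN_SHARED if q >= config.alpha else PATTERN_INCONSISTENT
        return PatternCall(snp_id, wgs_class, pattern, None)
    target = wgs_class.removesuffix("-specific")
    if target == wgs_class or target not in af_by_breed:
        raise ValueError(f"unrecognized WGS classification {wgs_class!r}")
    target_af = af_by_breed[target]
    best_other = max(af for b, af in af_by_breed.items() if b != target)
    margin = target_af - best_other
    if not target_af > best_other:
        pattern = PATTERN_INCONSISTENT
    elif q < config.alpha:
        pattern = PATTERN_SIGNIFICANT
    elif margin >= config.delta - _MARGIN_EPS:
        pattern = PATTERN_CONSISTENT_NS
    else:
        pattern = PATTERN_INCONSISTENT
    return PatternCall(snp_id, wgs_class, pattern, margin)


def reconstruct_counts(af: float, n_called: int) -> tuple[int, int]:
    """``(ref_count, alt_count)`` from a (possibly rounded) allele frequency
    and the number of called diploid animals; alt rounds half-up."""
    if not 0 <= af <= 1:
        raise ValueError("af must lie in [0, 1]")
    if n_called < 1:
        raise ValueError("n_called must be >= 1")
    total = 2 * n_called
    alt = math.floor(af * total + 0.5)
    return total - alt, alt


# ---------------------------------------------------------------------------
# pipeline drivers
# ---------------------------------------------------------------------------


def _allele_count_table(
    by_breed: Mapping[str, tuple[int, int, int, float | None]],
    breeds: Sequence[str],
) -> np.ndarray:
    refs = [by_breed[b][1] for b in breeds]
    alts = [by_breed[b][2] for b in breeds]
    return np.asarray([refs, alts], dtype=np.int64)


def validate_genotypes(
    matrix: GenotypeMatrix,
    meta: pd.DataFrame,
    config: ClassifierConfig = ClassifierConfig(),
    mode: str = "fisher-always",
    qc_threshold: float = 0.90,
) -> pd.DataFrame:
    """Full validation pipeline from genotype calls.

    ``meta`` needs columns ``snp_id, gene, wgs_class, ref, alt``. Applies
    call-rate QC, computes per-breed allele frequencies, tests allele
    homogeneity per SNP (2 x breeds allele-count table), BH-adjusts across
    the panel, and classifies each SNP's pattern. Returns one row per SNP.
    """
    meta = meta.set_index("snp_id", drop=False)
    ref_alt = {s: (meta.loc[s, "ref"], meta.loc[s, "alt"]) for s in meta.index}
    filtered, _qc = qc_call_rates(matrix, qc_threshold)
    freqs = allele_frequencies(filtered, ref_alt)
    breeds = sorted({b for _, b in filtered.samples})
    rows = []
    pvals = []
    for fr in freqs:
        table = _allele_count_table(fr.by_breed, breeds)
        p, method = choose_test(table, mode=mode)
        pvals.append(p)
        rows.append((fr, method))
    qvals = bh_adjust(pvals, m=config.m)
    out = []
    for (fr, method), p, q in zip(rows, pvals, qvals):
        snp = fr.snp_id
        afs = {b: fr.by_breed[b][3] for b in breeds}
        call = classify_pattern(meta.loc[snp, "wgs_class"], afs, q, config, snp_id=snp)
        rec = {
            "snp_id": snp,
            "gene": meta.loc[snp, "gene"],
            "wgs_class": meta.loc[snp, "wgs_class"],
            **{f"af_{b}": afs[b] for b in breeds},
            "p": p,
            "q": q,
            "method": method,
            "pattern": call.pattern,
        }
        out.append(rec)
    return pd.DataFrame(out)


def recompute_from_frequencies(
    table: pd.DataFrame,
    n_per_breed: int = 18,
    breeds: Sequence[str] = BREEDS,
    mode: str = "fisher-always",
    m: int | None = None,
) -> pd.DataFrame:
    """Recompute p and q from published per-breed allele frequencies.

    ``table`` needs ``af_<breed>`` columns; allele counts are reconstructed
    with :func:`reconstruct_counts` at ``n_per_breed`` called animals per
    breed, tested, and BH-adjusted across all rows. Returns a copy with
    ``p_recomputed``/``q_recomputed``/``method`` columns.
    """
    out = table.copy()
    pvals, methods = [], []
    for _, row in out.iterrows():
        counts = [reconstruct_counts(float(row[f"af_{b}"]), n_per_breed) for b in breeds]
        t = np.asarray([[c[0] for c in counts], [c[1] for c in counts]], dtype=np.int64)
        p, method = choose_test(t, mode=mode)
        pvals.append(p)
        methods.append(method)
    out["p_recomputed"] = pvals
    out["q_recomputed"] = bh_adjust(pvals, m=m)
    out["method"] = methods
    return out


def classify_table(
    table: pd.DataFrame,
    config: ClassifierConfig = ClassifierConfig(),
    q_col: str = "q",
    breeds: Sequence[str] = BREEDS,
) -> list[PatternCall]:
    """Pattern calls for a frequency-mode table (one row per SNP, columns
    ``snp_id, wgs_class, af_<breed>..., <q_col>``)."""
    calls = []
    for _, row in table.iterrows():
        afs = {b: float(row[f"af_{b}"]) for b in breeds}
        calls.append(
            classify_pattern(row["wgs_class"], afs, float(row[q_col]), config, snp_id=row["snp_id"])
        )
    return calls


def pattern_summary(calls: Iterable[PatternCall]) -> dict[str, int]:
    counts = {
        PATTERN_SIGNIFICANT: 0,
        PATTERN_CONSISTENT_NS: 0,
        PATTERN_SHARED: 0,
        PATTERN_INCONSISTENT: 0,
    }
    for c in calls:
        counts[c.pattern] += 1
    return counts


def write_summary_json(summary: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(dict(summary), fh, indent=2)
        fh.write("\n")
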