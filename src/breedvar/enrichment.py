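"""Hypergeometric over-representation analysis (ORA) of a gene list against
user-supplied gene sets, with BH or Bonferroni correction.

This is a generic, self-contained ORA: the query is intersected with a
background universe, each gene set is tested with the upper-tail
hypergeometric probability P(X >= k), and q-values come from the chosen
multiple-testing correction over all tested sets. It deliberately makes no
attempt to mimic any web service's proprietary correction, so its q-values
are comparable only within a run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from scipy.stats import hypergeom

from .validation import bh_adjust

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene sets plus the background universe they live in."""

    sets: dict[str, tuple[str, frozenset[str]]]
    universe: frozenset[str]


@dataclass(frozen=True)
class EnrichmentRow:
    set_id: str
    name: str
    overlap_k: int
    set_size_K: int
    query_size_n: int
    universe_N: int
    p: float
    q: float


def read_gmt(path: str | Path, universe: Iterable[str] | None = None) -> GeneSetCollection:
    """Load a GMT file (set-id, description, tab-separated members).

    The universe defaults to the union of all members; an explicit universe
    restricts every set to it. Duplicate set-ids raise; empty sets are
    dropped with a warning.
    """
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: GMT line needs id and description")
            set_id, name, *members = fields
            if set_id in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set id {set_id!r}")
            genes = frozenset(m.strip().upper() for m in members if m.strip())
            if not genes:
                logger.warning("%s:%d: empty set %s dropped", path, lineno, set_id)
                continue
            sets[set_id] = (name, genes)
    if universe is not None:
        uni = frozenset(g.strip().upper() for g in universe)
        sets = {sid: (nm, genes & uni) for sid, (nm, genes) in sets.items()}
        sets = {sid: v for sid, v in sets.items() if v[1]}
    else:
        uni = frozenset().union(*(genes for _, genes in sets.values())) if sets else frozenset()
    if not uni:
        raise ValueError("empty gene universe")
    return GeneSetCollection(sets=sets, universe=uni)


def ora_test(query: set[str], gene_set: set[str], universe: set[str]) -> float:
    """Upper-tail hypergeometric over-representation p-value P(X >= k).

    X ~ Hypergeometric(N=|universe|, K=|set∩universe|, n=|query∩universe|),
    k = |query∩set∩universe|. Query genes outside the universe are dropped
    with a warning. Returns p in (0, 1].
    """
    if not universe:
        raise ValueError("empty universe")
    dropped = query - universe
    if dropped:
        logger.warning("%d query genes outside the universe dropped", len(dropped))
    query_in = query & universe
    n = len(query_in)
    if n == 0:
        raise ValueError("empty query after restriction to the universe")
    big_n = len(universe)
    big_k = len(gene_set & universe)
    k = len(query_in & gene_set)
    # sf(k-1) = P(X >= k); exactly 1.0 when k = 0
    p = float(hypergeom.sf(k - 1, big_n, big_k, n))
    return min(max(p, 5e-324), 1.0)


def enrich(
    query: Iterable[str],
    collection: GeneSetCollection,
    correction: str = "bh",
) -> list[EnrichmentRow]:
    """ORA over every set in the collection; one row per set, sorted by
    ascending p (ties by set id), with q from BH or Bonferroni over all
    tested sets."""
    if correction not in {"bh", "bonferroni"}:
        raise ValueError(f"unknown correction {correction!r}")
    q_genes = {g.strip().upper() for g in query}
    universe = set(collection.universe)
    query_in = q_genes & universe
    ids = sorted(collection.sets)
    pvals = []
    rows_raw = []
    for sid in ids:
        name, genes = collection.sets[sid]
        genes_in = genes & universe
        p = ora_test(q_genes, set(genes_in), universe)
        pvals.append(p)
        rows_raw.append(
            (sid, name, len(query_in & genes_in), len(genes_in), len(query_in), len(universe), p)
        )
    if correction == "bh":
        qvals = bh_adjust(pvals)
    else:
        m = len(pvals)
        qvals = [min(1.0, p * m) for p in pvals]
    rows = [
        EnrichmentRow(sid, name, k, K, n, N, p, q)
        for (sid, name, k, K, n, N, p), q in zip(rows_raw, qvals)
    ]
    rows.sort(key=lambda r: (r.p, r.set_id))
    return rows


def write_enrichment_tsv(rows: Sequence[EnrichmentRow], path: str | Path) -> None:
    cols = ("set_id", "name", "overlap_k", "set_size_K", "query_size_n", "universe_N", "p", "q")
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in rows:
            fh.write(
                f"{r.set_id}\t{r.name}\t{r.overlap_k}\t{r.set_size_K}\t{r.query_size_n}"
                f"\t{r.universe_N}\t{r.p:.6g}\t{r.q:.6g}\n"
            )
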