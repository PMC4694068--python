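"""Gene-set over-representation statistics (DAVID-style).

For a query list of L genes against a gene set ("term") annotating K of the
N genes in the background population, with k genes of the query in the set:

fold enrichment
    ``(k/L) / (K/N)`` — the term's rate in the query over its background
    rate, computed in exact rational arithmetic before the final float.
Fisher / hypergeometric p
    ``P(X ≥ k)`` for ``X ~ Hypergeometric(N, K, L)``, the one-sided
    over-representation tail, computed from log-gamma binomials in log space
    (no normal approximation at any size).
EASE p
    the same tail after removing one gene from the overlap,
    ``P(X ≥ k − 1)`` — a conservative variant that discounts single-gene
    overlaps entirely (k ≤ 1 scores 1.0).

:func:`enrich` tests a query against a whole collection, ranks terms by
p-value and attaches Benjamini–Hochberg adjusted p-values.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction
from math import exp, lgamma

import pandas as pd
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class GeneSet:
    """One named gene set: term id (e.g. a KEGG pathway id), label, genes."""

    term_id: str
    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.term_id!r} is empty")


@dataclass
class GeneSetCollection:
    """Gene sets plus the size N of the annotated background population.

    N is supplied, not recomputed from the union of sets: it plays the role
    of the annotation tool's "population total".
    """

    sets: list[GeneSet]
    population_total: int

    def __post_init__(self) -> None:
        if self.population_total < 1:
            raise ValueError("population_total must be a positive integer")
        ids = [s.term_id for s in self.sets]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate term_id in collection")
        for s in self.sets:
            if len(s.genes) > self.population_total:
                raise ValueError(
                    f"set {s.term_id!r} larger than the population total"
                )

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class QueryList:
    """Query gene symbols plus the mapped list total L.

    L is the number of query genes mappable to the annotation space; it may
    exceed the number of distinct symbols retained here but never be smaller
    than any overlap.
    """

    genes: set[str]
    mapped_total: int

    def __post_init__(self) -> None:
        if self.mapped_total < 1:
            raise ValueError("mapped_total (list total) must be >= 1")


def _check_counts(k: int, L: int, K: int, N: int, k_min: int) -> None:
    if not all(isinstance(v, (int,)) for v in (k, L, K, N)):
        raise ValueError("counts must be integers")
    if N < 1 or L < 1 or K < 1:
        raise ValueError("L, K, N must be positive")
    if L > N or K > N:
        raise ValueError("L and K cannot exceed the population total N")
    if k < k_min or k > min(L, K):
        raise ValueError(f"overlap k={k} outside [{k_min}, min(L, K)={min(L, K)}]")


def fold_enrichment(k: int, L: int, K: int, N: int) -> float:
    """Fold enrichment (k/L)/(K/N) in exact rational arithmetic.

    k = 0 is defined as 0.0 with a warning (an absent term is maximally
    depleted, not an error); other bound violations are hard errors.
    """
    _check_counts(k, L, K, N, k_min=0)
    if k == 0:
        warnings.warn(
            "fold enrichment of an empty overlap defined as 0",
            UserWarning,
            stacklevel=2,
        )
        return 0.0
    return float(Fraction(k * N, L * K))


def _log_binom(n: int, k: int) -> float:
    return lgamma(n + 1) - lgamma(k + 1) - lgamma(n - k + 1)


def hypergeom_logpmf(i: int, L: int, K: int, N: int) -> float:
    """log P(X = i) for X ~ Hypergeometric(N, K, L)."""
    return _log_binom(K, i) + _log_binom(N - K, L - i) - _log_binom(N, L)


def hypergeom_upper_tail(k: int, L: int, K: int, N: int) -> float:
    """P(X ≥ k) for X ~ Hypergeometric(N, K, L), summed in log space.

    X counts how many of L draws without replacement from a population of N
    (containing K marked items) are marked.  ``k <= 0`` returns 1.0 exactly.
    """
    _check_counts(max(k, 0), L, K, N, k_min=0)
    lo = max(k, L + K - N)  # support starts at max(0, L+K-N)
    hi = min(L, K)
    if k <= max(0, L + K - N):
        return 1.0
    logs = [hypergeom_logpmf(i, L, K, N) for i in range(lo, hi + 1)]
    return min(1.0, float(exp(logsumexp(logs))))


def ease_p(k: int, L: int, K: int, N: int) -> float:
    """EASE score: the hypergeometric upper tail at k − 1; 1.0 for k ≤ 1."""
    _check_counts(max(k, 0), L, K, N, k_min=0)
    if k <= 1:
        return 1.0
    return hypergeom_upper_tail(k - 1, L, K, N)


def enrich(
    query: QueryList,
    collection: GeneSetCollection,
    min_overlap: int = 2,
    p_mode: str = "ease",
) -> pd.DataFrame:
    """Test a query list against every set of a collection.

    Gene-symbol matching is case-insensitive.  One row is returned per term
    with overlap ``k >= min_overlap``, sorted by ascending p-value
    (``p_mode`` "ease", the default, or "fisher"); Benjamini–Hochberg
    adjusted p-values are computed over all tested terms.

    Columns: term_id, term_name, k, list_total, pop_hits, pop_total,
    percent (100·k/L), fold_enrichment, p_fisher, p_ease, p, p_adj,
    overlap_genes.
    """
    if p_mode not in ("ease", "fisher"):
        raise ValueError("p_mode must be 'ease' or 'fisher'")
    if len(collection) == 0:
        raise ValueError("empty gene-set collection")
    qnorm = {g.upper() for g in query.genes}
    if not qnorm:
        raise ValueError("query list is empty after mapping")
    L = query.mapped_total
    N = collection.population_total
    rows = []
    for gs in collection.sets:
        members = {g.upper() for g in gs.genes}
        overlap = sorted(qnorm & members)
        k = len(overlap)
        if k < min_overlap:
            continue
        K = len(members)
        rows.append(
            {
                "term_id": gs.term_id,
                "term_name": gs.name,
                "k": k,
                "list_total": L,
                "pop_hits": K,
                "pop_total": N,
                "percent": 100.0 * k / L,
                "fold_enrichment": fold_enrichment(k, L, K, N),
                "p_fisher": hypergeom_upper_tail(k, L, K, N),
                "p_ease": ease_p(k, L, K, N),
                "overlap_genes": ",".join(overlap),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=[
                "term_id", "term_name", "k", "list_total", "pop_hits",
                "pop_total", "percent", "fold_enrichment", "p_fisher",
                "p_ease", "p", "p_adj", "overlap_genes",
            ]
        )
    out = pd.DataFrame(rows)
    out["p"] = out["p_ease"] if p_mode == "ease" else out["p_fisher"]
    out["p_adj"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    out = out.sort_values(["p", "term_id"], kind="mergesort").reset_index(drop=True)
    return out[
        [
            "term_id", "term_name", "k", "list_total", "pop_hits", "pop_total",
            "percent", "fold_enrichment", "p_fisher", "p_ease", "p", "p_adj",
            "overlap_genes",
        ]
    ]
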