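"""Gene-set enrichment statistics: annotation charts, composition and Venn tests.

The annotation chart mirrors the DAVID functional-annotation chart: for every
annotation term that overlaps a query gene list, a one-sided hypergeometric
tail p-value is computed against a background gene universe, either as the
plain Fisher tail or as the EASE score (the conservative DAVID variant in
which the observed overlap is reduced by one before taking the tail).
P-values are adjusted across all tested terms (Benjamini–Hochberg by
default).

Composition tests (is one gene category over-contributed by a variant class?)
are one-sided Fisher exact tests on a 2x2 table, and Venn-overlap statistics
report the full region partition of several named gene lists together with
the hypergeometric significance of each list's overlap with a reference set.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Mapping, Sequence, Set, Tuple

import numpy as np
from scipy.stats import fisher_exact, hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AnnotationSet",
    "EnrichmentResult",
    "hypergeometric_tail",
    "ease_score",
    "annotation_chart",
    "composition_test",
    "venn_overlap",
]


@dataclass(frozen=True)
class AnnotationSet:
    """One annotation term (e.g. a GO category) and its member genes."""

    term_id: str
    term_name: str
    ontology: str  # "BP" | "CC" | "MF" (or any label for non-GO collections)
    genes: FrozenSet[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"annotation term {self.term_id} has no genes")
        object.__setattr__(self, "genes", frozenset(self.genes))


@dataclass(frozen=True)
class EnrichmentResult:
    """Enrichment of one term in one gene list against a background."""

    term_id: str
    term_name: str
    ontology: str
    k: int      # overlap between list and term
    K: int      # term size within the background
    n: int      # list size within the background
    n_background: int
    p_raw: float
    p_adj: float


def _check_counts(k: int, K: int, n: int, n_background: int) -> None:
    if min(k, K, n, n_background) < 0:
        raise ValueError("counts must be non-negative")
    if K > n_background or n > n_background:
        raise ValueError("term or list size exceeds the background size")
    if k > min(K, n):
        raise ValueError("overlap exceeds the smaller of term and list size")


def hypergeometric_tail(k: int, K: int, n: int, n_background: int) -> float:
    """Upper-tail P(X >= k) of Hypergeometric(N=n_background, K, n).

    The probability that drawing ``n`` genes without replacement from a
    background of ``n_background`` containing ``K`` term genes yields at
    least ``k`` term genes.  Computed exactly with integer combinatorics
    (a single rounding at the final division), so no underflow or
    cancellation occurs even for extreme tails.
    """
    _check_counts(k, K, n, n_background)
    if k == 0:
        return 1.0
    from fractions import Fraction
    from math import comb

    N = n_background
    numerator = sum(comb(K, x) * comb(N - K, n - x)
                    for x in range(k, min(K, n) + 1))
    return float(Fraction(numerator, comb(N, n)))


def ease_score(k: int, K: int, n: int, n_background: int) -> float:
    """DAVID's EASE score: hypergeometric tail with the overlap jackknifed to k-1."""
    _check_counts(k, K, n, n_background)
    if k <= 1:
        return 1.0
    return hypergeometric_tail(k - 1, K, n, n_background)


def annotation_chart(
    gene_list: Iterable[str],
    collection: Sequence[AnnotationSet],
    background: Iterable[str],
    method: str = "ease",
    adjust: str = "BH",
) -> List[EnrichmentResult]:
    """Functional annotation chart of a gene list against a term collection.

    Every term with at least one gene in common with the list is tested with
    the chosen method ("ease" or "fisher"); term gene sets are restricted to
    the background universe, and query genes outside the background are
    dropped with a warning.  Results are sorted by raw p-value (ties by term
    id); the adjustment ("BH", "bonferroni" or "none") spans all tested
    terms.
    """
    bg = set(background)
    if not bg:
        raise ValueError("background gene universe is empty")
    if method not in ("ease", "fisher"):
        raise ValueError(f"unknown method {method!r}")
    if adjust not in ("BH", "bonferroni", "none"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    query = set(gene_list)
    outside = query - bg
    if outside:
        warnings.warn(
            f"{len(outside)} query gene(s) outside the background were dropped",
            stacklevel=2,
        )
        query &= bg
    n, n_bg = len(query), len(bg)
    stat = ease_score if method == "ease" else hypergeometric_tail

    seen = set()
    rows = []
    for term in collection:
        if term.term_id in seen:
            raise ValueError(f"duplicate term id {term.term_id}")
        seen.add(term.term_id)
        term_genes = term.genes & bg
        k = len(query & term_genes)
        if k == 0:
            continue
        p = stat(k, len(term_genes), n, n_bg)
        rows.append((term, k, len(term_genes), p))

    if not rows:
        return []
    p_raw = np.array([r[3] for r in rows])
    if adjust == "BH":
        p_adj = multipletests(p_raw, method="fdr_bh")[1]
    elif adjust == "bonferroni":
        p_adj = np.minimum(p_raw * len(p_raw), 1.0)
    else:
        p_adj = p_raw
    results = [
        EnrichmentResult(
            term_id=term.term_id,
            term_name=term.term_name,
            ontology=term.ontology,
            k=k,
            K=K,
            n=n,
            n_background=n_bg,
            p_raw=float(p),
            p_adj=float(pa),
        )
        for (term, k, K, p), pa in zip(rows, p_adj)
    ]
    results.sort(key=lambda r: (r.p_raw, r.term_id))
    return results


def composition_test(table: Sequence[Sequence[int]]) -> float:
    """One-sided Fisher exact test that a category is enriched for a tag.

    ``table`` is 2x2: rows are {in-category, out-of-category}, columns are
    {tagged, untagged} gene counts.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2):
        raise ValueError("composition table must be 2x2")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    if t.sum() == 0:
        raise ValueError("composition table is all zero")
    return float(fisher_exact(t, alternative="greater")[1])


def venn_overlap(
    lists: Mapping[str, Iterable[str]],
    reference: Iterable[str],
    n_background: int,
) -> Tuple[Dict[FrozenSet[str], int], Dict[str, Tuple[int, float]]]:
    """Venn region counts of named gene lists, plus per-list overlap significance.

    Returns ``(regions, per_list)`` where ``regions`` maps each non-empty
    combination of list names to the number of genes in exactly those lists,
    and ``per_list`` maps each list name to its overlap with the reference
    set and the hypergeometric tail p-value of that overlap against a
    background universe of ``n_background`` genes.
    """
    sets = {name: set(genes) for name, genes in lists.items()}
    union = set().union(*sets.values()) if sets else set()
    ref = set(reference)
    if n_background < len(union | ref):
        raise ValueError("background smaller than the union of the inputs")
    names = sorted(sets)
    regions: Dict[FrozenSet[str], int] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*(sets[c] for c in combo))
            outside = set().union(*(sets[c] for c in names if c not in combo)) \
                if len(combo) < len(names) else set()
            regions[frozenset(combo)] = len(inside - outside)
    per_list: Dict[str, Tuple[int, float]] = {}
    for name in names:
        k = len(sets[name] & ref)
        p = hypergeometric_tail(k, len(ref), len(sets[name]), n_background)
        per_list[name] = (k, p)
    return regions, per_list
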