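"""Trait <-> biological-process association by overrepresentation.

For a trait with candidate-gene set of size ``n`` drawn from a genome of
``G`` genes, and a BP term annotated to ``K`` genes genome-wide of which
``a`` fall in the candidate set, overrepresentation is the one-sided Fisher
exact (upper hypergeometric tail) probability

    p = sum_{k=a}^{min(n,K)} C(K,k) C(G-K, n-k) / C(G, n).

Benjamini-Hochberg correction is applied once, pooled over all traits and
all tested terms.  A (trait, term) pair is *associated* when its adjusted
q-value passes the FDR threshold and the term occurs in at least the
required fraction of the trait's retained QTL regions.  Terms annotated to
too large a share of the genome (too "general" to discriminate) are removed
before testing, so they never enter the multiple-testing burden.
"""

from __future__ import annotations

from collections import Counter

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact as _scipy_fisher_exact
from scipy.stats import hypergeom

from .model import AnalysisParameters, FunctionAnnotation, GenomeGeneSet
from .regions import RegionGeneMap, TraitCandidateSet

__all__ = [
    "eligible_terms",
    "fisher_one_sided",
    "bh_adjust",
    "region_occurrence_fraction",
    "test_all",
    "associated_terms_by_trait",
]

ASSOCIATION_COLUMNS = [
    "trait",
    "term",
    "a",
    "n",
    "K",
    "G",
    "p_raw",
    "q_bh",
    "region_fraction",
    "associated",
]


def eligible_terms(
    annotation: FunctionAnnotation,
    genome: GenomeGeneSet,
    params: AnalysisParameters,
) -> set[str]:
    """Terms passing the generality filter: genome share below ``max_generality``.

    The comparison is strict (``count/G < max_generality``) by default; the
    inclusive variant is selected with ``params.generality_cmp = "le"``.
    """
    G = genome.size
    if G == 0:
        raise ValueError("gene universe is empty")
    out = set()
    for term, count in annotation.term_generality.items():
        share = count / G
        if share < params.max_generality or (
            params.generality_cmp == "le" and share <= params.max_generality
        ):
            out.add(term)
    if not out:
        raise ValueError(
            "no term passes the generality filter; review max_generality "
            f"(={params.max_generality}) against the annotation's term sizes"
        )
    return out


def _check_counts(a: int, n: int, K: int, G: int) -> None:
    if not (0 <= a <= min(n, K)):
        raise ValueError(f"invalid counts: a={a} outside [0, min(n={n}, K={K})]")
    if not (a <= n <= G and a <= K <= G):
        raise ValueError(f"invalid counts: need a<=n<=G and a<=K<=G, got {(a, n, K, G)}")
    if a < n + K - G:
        raise ValueError(
            f"impossible 2x2 table: a={a} < n+K-G={n + K - G} for {(a, n, K, G)}"
        )


def fisher_one_sided(a: int, n: int, K: int, G: int) -> float:
    """One-sided overrepresentation p-value of the 2x2 table.

    Upper tail of Hypergeometric(G, K, n) at ``a``, computed with the exact
    stable tail routine (no normal approximation).
    """
    _check_counts(a, n, K, G)
    return float(hypergeom.sf(a - 1, G, K, n))


def fisher_two_sided(a: int, n: int, K: int, G: int) -> float:
    """Two-sided Fisher exact p-value (optional sidedness variant)."""
    _check_counts(a, n, K, G)
    table = [[a, K - a], [n - a, G - K - (n - a)]]
    return float(_scipy_fisher_exact(table, alternative="two-sided")[1])


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, in the input order.

    ``q_(i) = min_{j >= i} p_(j) * m / j`` over the ascending sort; ties are
    kept stable.  Because the minimum always includes ``j = m``, the output
    is bounded by ``p_(m) <= 1`` without clipping.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-d vector of p-values")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0.0) | (p > 1.0)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranks = np.arange(1, m + 1, dtype=float)
    scaled = p[order] * m / ranks
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m, dtype=float)
    out[order] = q_sorted
    return out


def region_occurrence_fraction(
    trait_regions: list[str],
    term: str,
    region_map: RegionGeneMap,
    annotation: FunctionAnnotation,
) -> float:
    """Fraction of the trait's retained regions holding >=1 gene with *term*.

    Several annotated genes inside one region still count that region once.
    The caller passes the retained region ids; a trait with none must already
    have been dropped upstream.
    """
    if not trait_regions:
        raise ValueError("region-occurrence fraction undefined for zero regions")
    term_genes = annotation.term_to_genes.get(term, frozenset())
    hit = sum(
        1
        for region_id in trait_regions
        if any(g in term_genes for g in region_map.region_genes[region_id])
    )
    return hit / len(trait_regions)


def test_all(
    candidates: list[TraitCandidateSet],
    annotation: FunctionAnnotation,
    genome: GenomeGeneSet,
    region_map: RegionGeneMap,
    params: AnalysisParameters,
) -> pd.DataFrame:
    """Run every (trait, eligible term) overrepresentation test.

    By default only terms observed at least once in a trait's candidate set
    are tested (an ``a = 0`` row can never be enriched and would only inflate
    the multiple-testing burden); ``params.include_zero_count_tests`` adds
    them.  BH correction is applied jointly across all rows of the returned
    table — all traits and all terms pooled.

    Returns the association table with columns
    ``trait, term, a, n, K, G, p_raw, q_bh, region_fraction, associated``.
    """
    eligible = eligible_terms(annotation, genome, params)
    generality = annotation.term_generality
    G = genome.size
    fisher = fisher_one_sided if params.alternative == "greater" else fisher_two_sided

    rows: list[dict] = []
    for tcs in sorted(candidates, key=lambda c: c.trait):
        counts: Counter[str] = Counter()
        for gene in tcs.genes:
            counts.update(t for t in annotation.terms_of(gene) if t in eligible)
        # regions in which each term occurs at least once
        region_hits: Counter[str] = Counter()
        for region_id in tcs.region_ids:
            present: set[str] = set()
            for gene in region_map.region_genes[region_id]:
                present.update(t for t in annotation.terms_of(gene) if t in eligible)
            region_hits.update(present)

        terms = sorted(eligible) if params.include_zero_count_tests else sorted(counts)
        n = len(tcs.genes)
        for term in terms:
            a = counts.get(term, 0)
            K = generality[term]
            rows.append(
                {
                    "trait": tcs.trait,
                    "term": term,
                    "a": a,
                    "n": n,
                    "K": K,
                    "G": G,
                    "p_raw": fisher(a, n, K, G),
                    "region_fraction": region_hits.get(term, 0)
                    / tcs.n_regions_retained,
                }
            )

    table = pd.DataFrame(rows, columns=[c for c in ASSOCIATION_COLUMNS if c not in ("q_bh", "associated")])
    if table.empty:
        table["q_bh"] = pd.Series(dtype=float)
        table["associated"] = pd.Series(dtype=bool)
        return table[ASSOCIATION_COLUMNS]
    table["q_bh"] = bh_adjust(table["p_raw"].to_numpy())
    table["associated"] = (table["q_bh"] <= params.fdr_threshold) & (
        table["region_fraction"] >= params.min_region_fraction
    )
    return table[ASSOCIATION_COLUMNS]


def associated_terms_by_trait(association_table: pd.DataFrame) -> dict[str, set[str]]:
    """Per-trait set of associated BP terms from an association table."""
    hits = association_table[association_table["associated"]]
    out: dict[str, set[str]] = {}
    for trait, term in zip(hits["trait"], hits["term"]):
        out.setdefault(trait, set()).add(term)
    return out
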