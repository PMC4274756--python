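"""Candidate-gene prioritization from trait-BP associations.

A candidate gene is prioritized for a trait when it is annotated with at
least one BP term associated to that trait; it is emitted once per
(trait, region) in which it occurs, so a gene inside regions of several
traits can be prioritized for each independently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .enrichment import associated_terms_by_trait
from .model import FunctionAnnotation, QTLCompendium
from .regions import RegionGeneMap, TraitCandidateSet

__all__ = [
    "PrioritizedGene",
    "ReductionSummary",
    "prioritize",
    "single_annotated_gene_regions",
    "reduction_summary",
    "prioritized_to_frame",
]


@dataclass(frozen=True)
class PrioritizedGene:
    trait: str
    region_id: str
    gene_id: str
    supporting_terms: frozenset[str]

    def __post_init__(self) -> None:
        if not self.supporting_terms:
            raise ValueError("a prioritized gene needs >=1 supporting term")


@dataclass
class ReductionSummary:
    """How strongly prioritization shrinks the candidate lists."""

    per_trait: pd.DataFrame  # trait, n_candidates, n_prioritized, fraction
    per_region: pd.DataFrame  # trait, region_id, n_genes, n_selected
    mean_fraction: float
    sd_fraction: float
    mean_selected_per_region: float
    sd_selected_per_region: float


def prioritize(
    association_table: pd.DataFrame,
    region_map: RegionGeneMap,
    compendium: QTLCompendium,
    annotation: FunctionAnnotation,
) -> list[PrioritizedGene]:
    """Select genes annotated with >=1 associated term, per (trait, region).

    Traits without associated terms contribute nothing.  Only retained
    regions are scanned (excluded regions have no candidates by definition).
    """
    assoc = associated_terms_by_trait(association_table)
    out: list[PrioritizedGene] = []
    for trait in sorted(assoc):
        terms = assoc[trait]
        for region in compendium.regions_for(trait):
            if not region_map.retained[region.region_id]:
                continue
            for gene in region_map.region_genes[region.region_id]:
                support = annotation.terms_of(gene) & terms
                if support:
                    out.append(
                        PrioritizedGene(trait, region.region_id, gene, frozenset(support))
                    )
    return out


def single_annotated_gene_regions(
    prioritized: list[PrioritizedGene],
    term: str,
    annotation: FunctionAnnotation,
) -> list[tuple[str, str, str]]:
    """(trait, region, gene) triples where the gene is its region's only
    prioritized carrier of *term*.

    A single gene annotated with a trait-relevant process in a region is the
    region's prime candidate for that process.
    """
    if term not in annotation.term_to_genes:
        raise KeyError(f"unknown term {term!r}")
    carriers: dict[tuple[str, str], list[str]] = {}
    for p in prioritized:
        if term in p.supporting_terms:
            carriers.setdefault((p.trait, p.region_id), []).append(p.gene_id)
    return sorted(
        (trait, region_id, genes[0])
        for (trait, region_id), genes in carriers.items()
        if len(genes) == 1
    )


def reduction_summary(
    prioritized: list[PrioritizedGene],
    candidates: list[TraitCandidateSet],
    region_map: RegionGeneMap | None = None,
) -> ReductionSummary:
    """Per-trait and per-region reduction statistics.

    The trait-level prioritized set is the union over that trait's regions
    (deduplicated); the global mean +- sd of the prioritized fraction is
    unweighted over traits, with the sample (ddof=1) standard deviation.
    """
    by_trait: dict[str, set[str]] = {}
    by_region: dict[tuple[str, str], set[str]] = {}
    for p in prioritized:
        by_trait.setdefault(p.trait, set()).add(p.gene_id)
        by_region.setdefault((p.trait, p.region_id), set()).add(p.gene_id)

    trait_rows = []
    for tcs in sorted(candidates, key=lambda c: c.trait):
        n_cand = len(tcs.genes)
        n_prio = len(by_trait.get(tcs.trait, ()))
        trait_rows.append(
            {
                "trait": tcs.trait,
                "n_candidates": n_cand,
                "n_prioritized": n_prio,
                "fraction": n_prio / n_cand if n_cand else 0.0,
            }
        )
    per_trait = pd.DataFrame(
        trait_rows, columns=["trait", "n_candidates", "n_prioritized", "fraction"]
    )

    region_rows = []
    for tcs in sorted(candidates, key=lambda c: c.trait):
        for region_id in tcs.region_ids:
            n_genes = (
                len(region_map.region_genes[region_id]) if region_map is not None else np.nan
            )
            region_rows.append(
                {
                    "trait": tcs.trait,
                    "region_id": region_id,
                    "n_genes": n_genes,
                    "n_selected": len(by_region.get((tcs.trait, region_id), ())),
                }
            )
    per_region = pd.DataFrame(
        region_rows, columns=["trait", "region_id", "n_genes", "n_selected"]
    )

    fractions = per_trait["fraction"].to_numpy()
    selected = per_region["n_selected"].to_numpy()
    return ReductionSummary(
        per_trait=per_trait,
        per_region=per_region,
        mean_fraction=float(np.mean(fractions)) if fractions.size else 0.0,
        sd_fraction=float(np.std(fractions, ddof=1)) if fractions.size > 1 else 0.0,
        mean_selected_per_region=float(np.mean(selected)) if selected.size else 0.0,
        sd_selected_per_region=float(np.std(selected, ddof=1)) if selected.size > 1 else 0.0,
    )


def prioritized_to_frame(prioritized: list[PrioritizedGene]) -> pd.DataFrame:
    """Flatten to a TSV-ready table; supporting terms semicolon-joined, sorted."""
    rows = [
        {
            "trait": p.trait,
            "region_id": p.region_id,
            "gene_id": p.gene_id,
            "supporting_terms": ";".join(sorted(p.supporting_terms)),
        }
        for p in prioritized
    ]
    df = pd.DataFrame(rows, columns=["trait", "region_id", "gene_id", "supporting_terms"])
    return df.sort_values(["trait", "region_id", "gene_id"], kind="mergesort").reset_index(
        drop=True
    )
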