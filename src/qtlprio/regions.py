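"""Assigning genes to QTL regions and building per-trait candidate sets.

A gene belongs to a region when both lie on the same chromosome and their
closed intervals share at least one base (the inclusive reading; strict
containment is available as an option).  Regions holding more genes than the
size cutoff are excluded before anything downstream, including the
denominator of the region-occurrence fraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from intervaltree import IntervalTree

from .model import AnalysisParameters, GenomeGeneSet, QTLCompendium

logger = logging.getLogger(__name__)

__all__ = [
    "RegionGeneMap",
    "TraitCandidateSet",
    "assign_genes_to_regions",
    "filter_regions_by_size",
    "build_trait_candidate_sets",
]


@dataclass
class RegionGeneMap:
    """Per-region ordered gene membership plus the size-filter flag."""

    region_genes: dict[str, tuple[str, ...]]  # region_id -> genes, positional order
    retained: dict[str, bool]

    def genes_of(self, region_id: str) -> tuple[str, ...]:
        return self.region_genes[region_id]

    def retained_regions(self) -> list[str]:
        return [r for r, keep in self.retained.items() if keep]

    def to_frame(self, compendium: QTLCompendium) -> pd.DataFrame:
        rows = []
        for region_id, genes in self.region_genes.items():
            region = compendium[region_id]
            rows.append(
                {
                    "region_id": region_id,
                    "trait": region.trait,
                    "chrom": region.chrom,
                    "start": region.start,
                    "end": region.end,
                    "n_genes": len(genes),
                    "retained": self.retained[region_id],
                }
            )
        return pd.DataFrame(
            rows,
            columns=["region_id", "trait", "chrom", "start", "end", "n_genes", "retained"],
        )


@dataclass(frozen=True)
class TraitCandidateSet:
    """Union of genes over a trait's retained QTL regions."""

    trait: str
    genes: frozenset[str]
    n_regions_retained: int
    region_ids: tuple[str, ...]


def assign_genes_to_regions(
    genome: GenomeGeneSet,
    compendium: QTLCompendium,
    overlap_rule: str = "any",
) -> RegionGeneMap:
    """Map every QTL region to the genes it covers.

    ``overlap_rule="any"`` admits a gene overlapping the region by >=1 base;
    ``"contained"`` requires the whole gene span inside the region.  All
    regions start out retained; apply :func:`filter_regions_by_size` next.
    """
    if genome.size == 0:
        raise ValueError("gene universe is empty")
    if overlap_rule not in {"any", "contained"}:
        raise ValueError(f"unknown overlap rule {overlap_rule!r}")

    trees: dict[str, IntervalTree] = {}
    for chrom, genes in genome.by_chrom().items():
        # closed genomic interval [start, end] -> half-open tree key [start, end+1)
        trees[chrom] = IntervalTree.from_tuples(
            (g.start, g.end + 1, g.gene_id) for g in genes
        )

    gene_index = {g.gene_id: g for g in genome}
    region_genes: dict[str, tuple[str, ...]] = {}
    for region in compendium.regions:
        tree = trees.get(region.chrom)
        hits: list[str] = []
        if tree is not None:
            for iv in tree.overlap(region.start, region.end + 1):
                gene = gene_index[iv.data]
                if overlap_rule == "contained" and not (
                    region.start <= gene.start and gene.end <= region.end
                ):
                    continue
                hits.append(iv.data)
        hits.sort(key=lambda gid: (gene_index[gid].start, gene_index[gid].end, gid))
        region_genes[region.region_id] = tuple(hits)
    return RegionGeneMap(region_genes, {r: True for r in region_genes})


def filter_regions_by_size(
    region_map: RegionGeneMap, params: AnalysisParameters
) -> RegionGeneMap:
    """Flag regions with more than ``max_region_genes`` genes as excluded.

    A region with exactly the cutoff count is retained; only regions holding
    *more* genes are dropped.  Empty regions pass vacuously.
    """
    retained = {
        region_id: len(genes) <= params.max_region_genes
        for region_id, genes in region_map.region_genes.items()
    }
    n_excluded = sum(not keep for keep in retained.values())
    if n_excluded:
        logger.info(
            "size filter (> %d genes): excluded %d of %d regions",
            params.max_region_genes,
            n_excluded,
            len(retained),
        )
    return RegionGeneMap(dict(region_map.region_genes), retained)


def build_trait_candidate_sets(
    region_map: RegionGeneMap, compendium: QTLCompendium
) -> list[TraitCandidateSet]:
    """Union each trait's retained regions into its candidate gene set.

    A gene spanning several regions of one trait is counted once.  Traits
    whose every region failed the size filter are dropped (and logged): they
    have no candidate genes to test.
    """
    out: list[TraitCandidateSet] = []
    dropped: list[str] = []
    for trait in compendium.traits:
        kept = [
            r.region_id
            for r in compendium.regions_for(trait)
            if region_map.retained[r.region_id]
        ]
        if not kept:
            dropped.append(trait)
            continue
        genes = frozenset(
            g for region_id in kept for g in region_map.region_genes[region_id]
        )
        out.append(TraitCandidateSet(trait, genes, len(kept), tuple(kept)))
    if dropped:
        logger.info(
            "%d traits dropped (no region passed the size filter): %s",
            len(dropped),
            ", ".join(sorted(dropped)),
        )
    return out
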