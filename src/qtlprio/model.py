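"""Core domain types for QTL candidate-gene prioritization.

Coordinates are 1-based inclusive throughout (GFF3 convention); BED input
is converted on read.  Strand is stored for provenance but ignored by every
analysis step.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

__all__ = [
    "Gene",
    "GenomeGeneSet",
    "QTLRegion",
    "QTLCompendium",
    "FunctionAnnotation",
    "AnalysisParameters",
    "IdMapping",
]

_STRANDS = {"+", "-", "."}


@dataclass(frozen=True)
class Gene:
    """A gene model: identifier plus a closed genomic interval.

    ``start`` and ``end`` are 1-based and inclusive; ``strand`` is one of
    ``+``, ``-`` or ``.`` (unknown).
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.start < 1:
            raise ValueError(f"gene {self.gene_id}: start {self.start} < 1")
        if self.strand not in _STRANDS:
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


class GenomeGeneSet:
    """The gene universe: every identified gene of the genome build.

    This is the background population of the overrepresentation test, so it
    deliberately includes genes that carry no functional annotation.
    """

    def __init__(self, genes: Iterable[Gene]):
        self._genes: dict[str, Gene] = {}
        for g in genes:
            if g.gene_id in self._genes:
                raise ValueError(f"duplicate gene_id {g.gene_id!r}")
            self._genes[g.gene_id] = g

    @property
    def size(self) -> int:
        return len(self._genes)

    def __len__(self) -> int:
        return len(self._genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._genes

    def __getitem__(self, gene_id: str) -> Gene:
        return self._genes[gene_id]

    def __iter__(self):
        return iter(self._genes.values())

    @property
    def gene_ids(self) -> list[str]:
        return list(self._genes)

    def by_chrom(self) -> dict[str, list[Gene]]:
        """Genes grouped per chromosome, sorted by (start, end, gene_id)."""
        out: dict[str, list[Gene]] = {}
        for g in self._genes.values():
            out.setdefault(g.chrom, []).append(g)
        for genes in out.values():
            genes.sort(key=lambda g: (g.start, g.end, g.gene_id))
        return out

    def __repr__(self) -> str:
        return f"GenomeGeneSet({self.size} genes)"


@dataclass(frozen=True)
class QTLRegion:
    """One QTL interval linked to one trait (closed, 1-based)."""

    region_id: str
    trait: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"region {self.region_id}: start {self.start} > end {self.end}"
            )


class QTLCompendium:
    """A trait -> QTL interval compendium."""

    def __init__(self, regions: Iterable[QTLRegion]):
        self._regions: dict[str, QTLRegion] = {}
        self._by_trait: dict[str, list[QTLRegion]] = {}
        for r in regions:
            if r.region_id in self._regions:
                raise ValueError(f"duplicate region_id {r.region_id!r}")
            self._regions[r.region_id] = r
            self._by_trait.setdefault(r.trait, []).append(r)

    @property
    def regions(self) -> list[QTLRegion]:
        return list(self._regions.values())

    @property
    def traits(self) -> list[str]:
        return list(self._by_trait)

    def regions_for(self, trait: str) -> list[QTLRegion]:
        return list(self._by_trait.get(trait, []))

    def __getitem__(self, region_id: str) -> QTLRegion:
        return self._regions[region_id]

    def __len__(self) -> int:
        return len(self._regions)

    def __repr__(self) -> str:
        return f"QTLCompendium({len(self._regions)} regions, {len(self._by_trait)} traits)"


class FunctionAnnotation:
    """Bipartite gene <-> biological-process term map.

    The per-term genome-wide gene count ("generality") is maintained as an
    exact inverse of the gene->terms map, restricted to the gene universe the
    annotation was built against.
    """

    def __init__(self, gene_to_terms: Mapping[str, Iterable[str]]):
        self.gene_to_terms: dict[str, frozenset[str]] = {
            g: frozenset(ts) for g, ts in gene_to_terms.items() if ts
        }
        self.term_to_genes: dict[str, frozenset[str]] = {}
        inv: dict[str, set[str]] = {}
        for g, ts in self.gene_to_terms.items():
            for t in ts:
                inv.setdefault(t, set()).add(g)
        self.term_to_genes = {t: frozenset(gs) for t, gs in inv.items()}

    @classmethod
    def from_pairs(
        cls, pairs: Iterable[tuple[str, str]], universe: "GenomeGeneSet"
    ) -> tuple["FunctionAnnotation", int]:
        """Build from (gene_id, term_id) pairs restricted to *universe*.

        Returns the annotation and the number of discarded out-of-universe
        pairs.  Raises if nothing survives the restriction.
        """
        kept: dict[str, set[str]] = {}
        discarded = 0
        for gene_id, term_id in pairs:
            if gene_id in universe:
                kept.setdefault(gene_id, set()).add(term_id)
            else:
                discarded += 1
        if not kept:
            raise ValueError("no annotation pairs overlap the gene universe")
        return cls(kept), discarded

    @property
    def term_generality(self) -> dict[str, int]:
        return {t: len(gs) for t, gs in self.term_to_genes.items()}

    @property
    def n_pairs(self) -> int:
        return sum(len(ts) for ts in self.gene_to_terms.values())

    def terms_of(self, gene_id: str) -> frozenset[str]:
        return self.gene_to_terms.get(gene_id, frozenset())

    def __repr__(self) -> str:
        return (
            f"FunctionAnnotation({len(self.gene_to_terms)} genes, "
            f"{len(self.term_to_genes)} terms, {self.n_pairs} pairs)"
        )


@dataclass
class AnalysisParameters:
    """Tunable thresholds of the prioritization pipeline.

    Defaults are the published operating point of the method: FDR 0.1,
    term required in at least half of a trait's QTL regions, term annotated
    to less than 1% of the genome, QTL regions above 450 genes discarded.
    """

    fdr_threshold: float = 0.1
    min_region_fraction: float = 0.5
    max_generality: float = 0.01
    max_region_genes: int = 450
    permutation_iters: int = 1000
    rng_seed: int = 0
    # variants of deliberately-documented decisions
    generality_cmp: str = "lt"  # "lt" (strict, default) or "le"
    overlap_rule: str = "any"  # "any" (>=1 shared base) or "contained"
    alternative: str = "greater"  # Fisher sidedness; "two-sided" optional
    include_zero_count_tests: bool = False
    p_estimator: str = "count"  # "count" -> c/n ; "plus_one" -> (c+1)/(n+1)

    def __post_init__(self) -> None:
        if not 0.0 <= self.fdr_threshold <= 1.0:
            raise ValueError("fdr_threshold must be in [0, 1]")
        if not 0.0 <= self.min_region_fraction <= 1.0:
            raise ValueError("min_region_fraction must be in [0, 1]")
        if not 0.0 < self.max_generality <= 1.0:
            raise ValueError("max_generality must be in (0, 1]")
        if self.max_region_genes < 0:
            raise ValueError("max_region_genes must be >= 0")
        if self.permutation_iters < 1:
            raise ValueError("permutation_iters must be >= 1")
        if self.generality_cmp not in {"lt", "le"}:
            raise ValueError("generality_cmp must be 'lt' or 'le'")
        if self.overlap_rule not in {"any", "contained"}:
            raise ValueError("overlap_rule must be 'any' or 'contained'")
        if self.alternative not in {"greater", "two-sided"}:
            raise ValueError("alternative must be 'greater' or 'two-sided'")
        if self.p_estimator not in {"count", "plus_one"}:
            raise ValueError("p_estimator must be 'count' or 'plus_one'")


class IdMapping:
    """Exact-string identifier mapping between gene-id schemes (e.g. two
    annotation projects' locus identifiers for the same genome).

    Applied to externally sourced gene lists before any analysis; unmapped
    identifiers are reported, never silently dropped.
    """

    def __init__(self, pairs: Iterable[tuple[str, str]]):
        self._map: dict[str, str] = {}
        for ext, canon in pairs:
            self._map[ext] = canon

    def __len__(self) -> int:
        return len(self._map)

    def apply(self, ids: Iterable[str]) -> tuple[set[str], list[str]]:
        """Map *ids*; returns (mapped canonical ids, unmapped inputs)."""
        mapped: set[str] = set()
        unmapped: list[str] = []
        for i in ids:
            if i in self._map:
                mapped.add(self._map[i])
            else:
                unmapped.append(i)
        return mapped, unmapped
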