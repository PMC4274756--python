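"""Synthetic genomes, annotations and QTL compendia with planted signal.

The generator emulates the statistical structure the prioritization method
relies on: a tiled gene genome, background gene->BP annotations whose
per-term sizes follow a capped power law (mimicking the long-tailed size
distribution of real GO terms) and are independent of genomic position, and
traits whose QTL regions are seeded with causal genes all annotated with
one trait-specific causal BP term.  Because background annotations carry no
positional information, any positional enrichment the pipeline finds is
attributable solely to the planted signal — the generator doubles as a
clean oracle, exposing the full ground truth.

Everything is a pure function of the configuration (which embeds the seed):
two runs with the same config produce identical objects and, through
:func:`write_fixture`, byte-identical files.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .model import FunctionAnnotation, Gene, GenomeGeneSet, QTLCompendium, QTLRegion

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulationResult",
    "expected_generality",
    "simulate",
    "write_fixture",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of the synthetic benchmark.

    Defaults describe a small but structurally faithful instance: a
    1,000-gene genome, 50 background BP terms with rank-frequency exponent
    ``generality_exponent`` capped at ``generality_cap_fraction`` of the
    genome, and 5 traits x 4 QTL regions of ~30 genes each, every region
    carrying 2 planted causal genes (``f_regions = 1.0``).  With the default
    1% generality threshold the per-trait causal terms (4 x 2 = 8 carriers
    out of 1,000 genes) stay eligible, while the cap (5% of the genome)
    keeps the largest background terms ineligible on purpose.
    """

    n_chroms: int = 2
    genes_per_chrom: int = 500
    gene_length: int = 1_000
    intergenic_gap: int = 1_000
    # background annotation law
    n_terms: int = 50
    generality_exponent: float = 1.0
    generality_cap_fraction: float = 0.05
    terms_per_gene_mean: float = 1.0
    # traits and planted signal
    n_traits: int = 5
    regions_per_trait: int = 4
    region_gene_span: int = 30
    f_regions: float = 1.0
    n_causal_per_region: int = 2
    # auxiliary catalogs
    tf_fraction: float = 0.05
    tf_families: tuple[str, ...] = ("AP2", "MYB", "NAC", "WRKY")
    snp_fraction: float = 0.5
    reference_fraction: float = 0.5
    seed: int = 1

    def __post_init__(self) -> None:
        for name in (
            "n_chroms",
            "genes_per_chrom",
            "gene_length",
            "intergenic_gap",
            "n_terms",
            "n_traits",
            "regions_per_trait",
            "region_gene_span",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.f_regions <= 1.0:
            raise ValueError("f_regions must be in [0, 1]")
        if self.n_causal_per_region < 0:
            raise ValueError("n_causal_per_region must be >= 0")
        if self.region_gene_span > self.genes_per_chrom:
            raise ValueError("region_gene_span exceeds genes per chromosome")
        if self.n_causal_per_region > self.region_gene_span:
            raise ValueError("more causal genes per region than genes in a region")

    @property
    def n_genes(self) -> int:
        return self.n_chroms * self.genes_per_chrom


@dataclass
class GroundTruth:
    """What was planted: per trait, its causal term, genes and regions."""

    causal_term: dict[str, str] = field(default_factory=dict)
    causal_genes: dict[str, list[str]] = field(default_factory=dict)
    planted_regions: dict[str, list[str]] = field(default_factory=dict)

    def all_causal_genes(self) -> set[str]:
        return {g for genes in self.causal_genes.values() for g in genes}


@dataclass
class SimulationResult:
    config: SimulationConfig
    genome: GenomeGeneSet
    annotation: FunctionAnnotation
    compendium: QTLCompendium
    ground_truth: GroundTruth
    tf_catalog: dict[str, str]
    snp_hits: pd.DataFrame  # trait, chrom, pos
    reference_genes: set[str]


def expected_generality(config: SimulationConfig) -> dict[str, int]:
    """Expected genome-wide gene count per background term under the law.

    Rank ``r`` gets weight ``r**-exponent``; weights are scaled so the total
    expected number of annotation pairs is ``terms_per_gene_mean * n_genes``,
    then capped at ``generality_cap_fraction * n_genes`` (capping shrinks the
    realized mean slightly, which is documented behaviour).
    """
    ranks = np.arange(1, config.n_terms + 1, dtype=float)
    weights = ranks ** -config.generality_exponent
    total = config.terms_per_gene_mean * config.n_genes
    expected = total * weights / weights.sum()
    cap = config.generality_cap_fraction * config.n_genes
    expected = np.minimum(expected, cap)
    return {_bg_term(r): int(round(e)) for r, e in zip(range(1, config.n_terms + 1), expected)}


def _bg_term(rank: int) -> str:
    return f"BP:B{rank:03d}"


def _causal_term(trait_idx: int) -> str:
    return f"BP:C{trait_idx:02d}"


def simulate(config: SimulationConfig | None = None) -> SimulationResult:
    """Generate one synthetic instance; fully reproducible from the config."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)

    # --- genome: genes tiled deterministically along each chromosome
    step = config.gene_length + config.intergenic_gap
    genes: list[Gene] = []
    for c in range(1, config.n_chroms + 1):
        chrom = f"chr{c}"
        for i in range(config.genes_per_chrom):
            start = i * step + 1
            genes.append(
                Gene(f"g{c:02d}_{i:04d}", chrom, start, start + config.gene_length - 1, "+")
            )
    genome = GenomeGeneSet(genes)
    gene_ids = genome.gene_ids  # tiling order
    G = genome.size

    # --- background annotations: per-term counts from the capped power law,
    #     genes picked uniformly, independent of position
    gene_terms: dict[str, set[str]] = {g: set() for g in gene_ids}
    ranks = np.arange(1, config.n_terms + 1, dtype=float)
    weights = ranks ** -config.generality_exponent
    total = config.terms_per_gene_mean * G
    expected = np.minimum(total * weights / weights.sum(), config.generality_cap_fraction * G)
    for r, e in zip(range(1, config.n_terms + 1), expected):
        k = int(rng.binomial(G, min(e / G, 1.0)))
        for idx in rng.choice(G, size=k, replace=False):
            gene_terms[gene_ids[idx]].add(_bg_term(r))

    # --- traits, regions and planted signal
    by_chrom = genome.by_chrom()
    chrom_names = sorted(by_chrom)
    truth = GroundTruth()
    regions: list[QTLRegion] = []
    for t in range(1, config.n_traits + 1):
        trait = f"trait{t:02d}"
        term = _causal_term(t)
        trait_region_ids: list[str] = []
        trait_regions_genes: list[list[str]] = []
        for i in range(1, config.regions_per_trait + 1):
            chrom = chrom_names[rng.integers(len(chrom_names))]
            chrom_genes = by_chrom[chrom]
            first = int(rng.integers(len(chrom_genes) - config.region_gene_span + 1))
            span = chrom_genes[first : first + config.region_gene_span]
            region_id = f"{trait}#{i}"
            regions.append(
                QTLRegion(region_id, trait, chrom, span[0].start, span[-1].end)
            )
            trait_region_ids.append(region_id)
            trait_regions_genes.append([g.gene_id for g in span])

        n_planted_regions = int(round(config.f_regions * config.regions_per_trait))
        planted_idx = sorted(
            rng.choice(config.regions_per_trait, size=n_planted_regions, replace=False)
        )
        causal: list[str] = []
        planted_regions: list[str] = []
        if config.n_causal_per_region > 0:
            for ridx in planted_idx:
                members = trait_regions_genes[ridx]
                pick = rng.choice(len(members), size=config.n_causal_per_region, replace=False)
                for j in sorted(pick):
                    gene_terms[members[j]].add(term)
                    causal.append(members[j])
                planted_regions.append(trait_region_ids[ridx])
        if causal:
            truth.causal_term[trait] = term
            truth.causal_genes[trait] = sorted(set(causal))
            truth.planted_regions[trait] = planted_regions

    compendium = QTLCompendium(regions)
    annotation = FunctionAnnotation({g: ts for g, ts in gene_terms.items() if ts})

    # --- transcription-factor catalog: uniform random subset with families
    n_tf = int(round(config.tf_fraction * G))
    tf_idx = sorted(rng.choice(G, size=n_tf, replace=False))
    tf_catalog = {
        gene_ids[i]: config.tf_families[int(rng.integers(len(config.tf_families)))]
        for i in tf_idx
    }

    # --- SNP hits at midpoints of a random subset of planted genes
    snp_rows = []
    for trait in sorted(truth.causal_genes):
        planted = truth.causal_genes[trait]
        n_snp = max(1, int(round(config.snp_fraction * len(planted))))
        chosen = sorted(rng.choice(len(planted), size=n_snp, replace=False))
        for j in chosen:
            gene = genome[planted[j]]
            snp_rows.append(
                {"trait": trait, "chrom": gene.chrom, "pos": (gene.start + gene.end) // 2}
            )
    snp_hits = pd.DataFrame(snp_rows, columns=["trait", "chrom", "pos"])

    # --- reference (fine-mapped-like) genes: random subset of planted genes
    reference: set[str] = set()
    for trait in sorted(truth.causal_genes):
        planted = truth.causal_genes[trait]
        n_ref = max(1, int(round(config.reference_fraction * len(planted))))
        for j in sorted(rng.choice(len(planted), size=n_ref, replace=False)):
            reference.add(planted[j])

    return SimulationResult(
        config=config,
        genome=genome,
        annotation=annotation,
        compendium=compendium,
        ground_truth=truth,
        tf_catalog=tf_catalog,
        snp_hits=snp_hits,
        reference_genes=reference,
    )


def write_fixture(sim: SimulationResult, directory: str | os.PathLike) -> dict[str, str]:
    """Write a complete input fixture; returns the file map.

    Files: ``genes.gff3``, ``qtl_regions.tsv``, ``annotations.tsv``,
    ``tf_list.tsv``, ``snp_hits.tsv``, ``reference_genes.tsv`` and
    ``ground_truth.json``.  Re-reading them through the package's readers
    reproduces the in-memory objects.
    """
    directory = os.fspath(directory)
    os.makedirs(directory, exist_ok=True)
    paths = {name: os.path.join(directory, fname) for name, fname in [
        ("genes", "genes.gff3"),
        ("qtl", "qtl_regions.tsv"),
        ("annotations", "annotations.tsv"),
        ("tf", "tf_list.tsv"),
        ("snps", "snp_hits.tsv"),
        ("reference", "reference_genes.tsv"),
        ("ground_truth", "ground_truth.json"),
    ]}

    with open(paths["genes"], "w", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        for chrom in sorted(sim.genome.by_chrom()):
            for g in sim.genome.by_chrom()[chrom]:
                fh.write(
                    f"{g.chrom}\tqtlprio_sim\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
                )

    pd.DataFrame(
        [
            {
                "trait": r.trait,
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "region_id": r.region_id,
            }
            for r in sim.compendium.regions
        ]
    ).to_csv(paths["qtl"], sep="\t", index=False)

    pairs = [
        {"gene_id": g, "term_id": t}
        for g in sorted(sim.annotation.gene_to_terms)
        for t in sorted(sim.annotation.gene_to_terms[g])
    ]
    pd.DataFrame(pairs, columns=["gene_id", "term_id"]).to_csv(
        paths["annotations"], sep="\t", index=False
    )

    with open(paths["tf"], "w", encoding="utf-8") as fh:
        fh.write("gene_id\tfamily\n")
        for g in sorted(sim.tf_catalog):
            fh.write(f"{g}\t{sim.tf_catalog[g]}\n")

    sim.snp_hits.to_csv(paths["snps"], sep="\t", index=False)

    with open(paths["reference"], "w", encoding="utf-8") as fh:
        fh.write("gene_id\n")
        for g in sorted(sim.reference_genes):
            fh.write(f"{g}\n")

    with open(paths["ground_truth"], "w", encoding="utf-8") as fh:
        json.dump(
            {
                "config": asdict(sim.config),
                "causal_term": sim.ground_truth.causal_term,
                "causal_genes": sim.ground_truth.causal_genes,
                "planted_regions": sim.ground_truth.planted_regions,
            },
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")
    return paths
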