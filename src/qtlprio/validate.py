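"""Significance and comparison machinery for prioritization results.

Four independent checks mirror how a prioritization method is judged
against external evidence:

* resampling test of overlap with a reference (e.g. fine-mapped) gene set,
  drawing per-trait random gene sets of the same sizes from the QTL regions;
* a null run on annotations randomly reassigned to genes (bundle
  permutation, preserving both marginals of the gene x term incidence);
* overlap with GWAS hits through k-nearest-gene SNP neighborhoods;
* transcription-factor content profiling of the prioritized sets.

A parameter sweep re-runs the full pipeline over a grid of the three
thresholds and scores each point against the reference set.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .model import AnalysisParameters, FunctionAnnotation, GenomeGeneSet, QTLCompendium
from .prioritize import PrioritizedGene
from .regions import TraitCandidateSet

logger = logging.getLogger(__name__)

__all__ = [
    "PermutationResult",
    "TFProfile",
    "permutation_overlap_test",
    "randomize_annotations",
    "nearest_genes_to_snp",
    "gwas_overlap_test",
    "tf_profile",
    "parameter_sweep",
]


@dataclass(frozen=True)
class PermutationResult:
    """Outcome of a per-trait random-gene-set resampling test."""

    observed_overlap: int
    n_iter: int
    n_at_least: int  # iterations with random overlap >= observed
    p_empirical: float
    seed: int
    estimator: str = "count"

    def p_report(self) -> str:
        """Human-readable p; a zero count is reported as a bound."""
        if self.n_at_least == 0 and self.estimator == "count":
            return f"< {1.0 / self.n_iter:g}"
        return f"{self.p_empirical:g}"

    def to_dict(self) -> dict:
        return {
            "observed_overlap": self.observed_overlap,
            "n_iter": self.n_iter,
            "n_at_least": self.n_at_least,
            "p_empirical": self.p_empirical,
            "p_report": self.p_report(),
            "seed": self.seed,
            "estimator": self.estimator,
        }


def _overlap_p(n_at_least: int, n_iter: int, estimator: str) -> float:
    if estimator == "count":
        return n_at_least / n_iter
    if estimator == "plus_one":
        return (n_at_least + 1) / (n_iter + 1)
    raise ValueError(f"unknown estimator {estimator!r}")


def _null_overlap_draws(
    rng: np.random.Generator,
    sizes: list[tuple[int, int, int]],  # (n_candidates, n_reference_in_candidates, n_draw)
    n_iter: int,
) -> np.ndarray:
    """Null distribution of pooled overlap: per trait, draw ``n_draw`` genes
    without replacement from the candidates and count reference hits.

    The per-trait hit count of such a draw is exactly hypergeometric, so the
    draws are sampled as independent hypergeometric variates per trait and
    summed; this is distribution-identical to materializing the gene sets.
    """
    total = np.zeros(n_iter, dtype=np.int64)
    for n_cand, n_good, n_draw in sizes:
        if n_draw == 0 or n_good == 0:
            continue
        total += rng.hypergeometric(n_good, n_cand - n_good, n_draw, size=n_iter)
    return total


def permutation_overlap_test(
    prioritized_by_trait: dict[str, set[str]],
    candidates_by_trait: dict[str, set[str]],
    reference_genes: set[str],
    n_iter: int = 1000,
    seed: int = 0,
    estimator: str = "count",
) -> PermutationResult:
    """Is the prioritized/reference overlap larger than random selection?

    For every trait, a random gene set of the same size as that trait's
    prioritized set is drawn (without replacement) from that trait's
    candidate genes; the pooled reference overlap of the random sets,
    repeated ``n_iter`` times, gives the null.  The observed overlap is
    computed identically on the real prioritized sets, summed over traits.
    """
    sizes = []
    observed = 0
    for trait in sorted(candidates_by_trait):
        cand = candidates_by_trait[trait]
        prio = prioritized_by_trait.get(trait, set())
        if len(prio) > len(cand):
            raise ValueError(
                f"trait {trait!r}: prioritized size {len(prio)} exceeds "
                f"candidate size {len(cand)}"
            )
        if not prio <= cand:
            raise ValueError(f"trait {trait!r}: prioritized genes not in candidates")
        observed += len(prio & reference_genes)
        sizes.append((len(cand), len(cand & reference_genes), len(prio)))

    rng = np.random.default_rng(seed)
    null = _null_overlap_draws(rng, sizes, n_iter)
    n_at_least = int(np.count_nonzero(null >= observed))
    return PermutationResult(
        observed_overlap=observed,
        n_iter=n_iter,
        n_at_least=n_at_least,
        p_empirical=_overlap_p(n_at_least, n_iter, estimator),
        seed=seed,
        estimator=estimator,
    )


def randomize_annotations(
    annotation: FunctionAnnotation,
    seed: int,
    universe: GenomeGeneSet | None = None,
) -> FunctionAnnotation:
    """Randomly reassign whole per-gene term bundles to genes.

    Gene ``i`` receives gene ``pi(i)``'s full term set for a uniform random
    permutation ``pi``.  Both marginals of the gene x term incidence are
    preserved exactly: the multiset of per-gene bundle sizes and every
    per-term genome count.  When *universe* is given, bundles may land on
    previously unannotated genes (reassignment over the whole genome);
    otherwise the permutation runs over the annotated genes only.
    """
    if universe is not None:
        genes = sorted(universe.gene_ids)
    else:
        genes = sorted(annotation.gene_to_terms)
    bundles = [annotation.gene_to_terms.get(g, frozenset()) for g in genes]
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(genes))
    shuffled = {
        genes[i]: bundles[perm[i]] for i in range(len(genes)) if bundles[perm[i]]
    }
    return FunctionAnnotation(shuffled)


def nearest_genes_to_snp(
    genome: GenomeGeneSet, chrom: str, pos: int, k: int = 3
) -> list[str]:
    """The ``k`` genes closest to a SNP position, nearest first.

    Distance is 0 when the position falls inside a gene span, else the gap to
    the nearer span edge; ties break by (distance, gene_id).  A chromosome
    with fewer than ``k`` genes returns them all; an unknown chromosome
    returns an empty list with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    genes = genome.by_chrom().get(chrom)
    if not genes:
        logger.warning("no genes on chromosome %r; empty SNP neighborhood", chrom)
        return []
    scored = []
    for g in genes:
        if g.start <= pos <= g.end:
            d = 0
        else:
            d = min(abs(pos - g.start), abs(pos - g.end))
        scored.append((d, g.gene_id))
    scored.sort()
    return [gene_id for _, gene_id in scored[:k]]


def gwas_overlap_test(
    prioritized_by_trait: dict[str, set[str]],
    candidates_by_trait: dict[str, set[str]],
    snp_hits: pd.DataFrame,
    genome: GenomeGeneSet,
    n_iter: int = 1000,
    seed: int = 0,
    k: int = 3,
    estimator: str = "count",
) -> tuple[PermutationResult, pd.DataFrame]:
    """Overlap of prioritized genes with GWAS SNP neighborhoods.

    Per trait shared (by exact name) between the QTL analysis and the SNP
    table, the neighborhood is the union of the ``k`` nearest genes over the
    trait's SNPs; observed = |prioritized ∩ neighborhood| summed over shared
    traits.  The null re-draws per-trait random sets from the candidates,
    exactly as in :func:`permutation_overlap_test`.

    Returns the permutation result and a table of matched
    (trait, gene_id) pairs.
    """
    shared = sorted(set(candidates_by_trait) & set(snp_hits["trait"]))
    if not shared:
        raise ValueError("no traits shared between QTL compendium and SNP hits")

    sizes = []
    observed = 0
    matched_rows = []
    for trait in shared:
        hood: set[str] = set()
        for _, row in snp_hits[snp_hits["trait"] == trait].iterrows():
            hood.update(nearest_genes_to_snp(genome, str(row["chrom"]), int(row["pos"]), k))
        cand = candidates_by_trait[trait]
        prio = prioritized_by_trait.get(trait, set())
        if len(prio) > len(cand):
            raise ValueError(
                f"trait {trait!r}: prioritized size exceeds candidate size"
            )
        hits = prio & hood
        observed += len(hits)
        matched_rows.extend({"trait": trait, "gene_id": g} for g in sorted(hits))
        sizes.append((len(cand), len(cand & hood), len(prio)))

    rng = np.random.default_rng(seed)
    null = _null_overlap_draws(rng, sizes, n_iter)
    n_at_least = int(np.count_nonzero(null >= observed))
    result = PermutationResult(
        observed_overlap=observed,
        n_iter=n_iter,
        n_at_least=n_at_least,
        p_empirical=_overlap_p(n_at_least, n_iter, estimator),
        seed=seed,
        estimator=estimator,
    )
    matched = pd.DataFrame(matched_rows, columns=["trait", "gene_id"])
    return result, matched


@dataclass
class TFProfile:
    """Transcription-factor content of genome, candidates and prioritized sets."""

    pct_tf_genome: float
    pct_tf_candidates: float
    pct_tf_prioritized: float
    strata: dict[int, float]  # min #traits a gene is prioritized for -> % TF
    family_by_trait: pd.DataFrame  # traits x families, % of the trait's TFs


def _pct(tf_genes: set[str], genes: set[str]) -> float:
    return 100.0 * len(genes & tf_genes) / len(genes) if genes else 0.0


def tf_profile(
    prioritized: list[PrioritizedGene],
    candidates: list[TraitCandidateSet],
    genome: GenomeGeneSet,
    tf_catalog: dict[str, str],
    strata_ks: tuple[int, ...] = (1, 2, 4),
    min_tfs_per_trait: int = 10,
    family_share: float = 0.25,
) -> TFProfile:
    """Percentage of transcription factors at each stage of the funnel.

    ``strata`` reports the TF percentage among genes prioritized for at
    least ``k`` distinct traits.  ``family_by_trait`` keeps only traits with
    at least ``min_tfs_per_trait`` associated TFs of which some family
    exceeds ``family_share``, and only families exceeding that share for at
    least one kept trait; cells are the percentage of the trait's TFs in the
    family.  TFs without a family label never form a display family.
    """
    tf_genes = {g for g in tf_catalog if g in genome}
    genome_genes = set(genome.gene_ids)
    cand_union: set[str] = set()
    for tcs in candidates:
        cand_union |= tcs.genes

    gene_traits: dict[str, set[str]] = {}
    trait_genes: dict[str, set[str]] = {}
    for p in prioritized:
        gene_traits.setdefault(p.gene_id, set()).add(p.trait)
        trait_genes.setdefault(p.trait, set()).add(p.gene_id)
    prio_union = set(gene_traits)

    strata = {
        kk: _pct(tf_genes, {g for g, ts in gene_traits.items() if len(ts) >= kk})
        for kk in strata_ks
    }

    # family composition per trait
    fam_rows: dict[str, dict[str, float]] = {}
    for trait in sorted(trait_genes):
        tfs = sorted(trait_genes[trait] & tf_genes)
        if len(tfs) < min_tfs_per_trait:
            continue
        shares: dict[str, float] = {}
        for g in tfs:
            fam = tf_catalog.get(g, "")
            if fam:
                shares[fam] = shares.get(fam, 0.0) + 100.0 / len(tfs)
        if any(s > 100.0 * family_share for s in shares.values()):
            fam_rows[trait] = shares
    families = sorted(
        {
            fam
            for shares in fam_rows.values()
            for fam, s in shares.items()
            if s > 100.0 * family_share
        }
    )
    family_by_trait = pd.DataFrame(
        [
            {"trait": trait, **{f: shares.get(f, 0.0) for f in families}}
            for trait, shares in fam_rows.items()
        ],
        columns=["trait", *families],
    )

    return TFProfile(
        pct_tf_genome=_pct(tf_genes, genome_genes),
        pct_tf_candidates=_pct(tf_genes, cand_union),
        pct_tf_prioritized=_pct(tf_genes, prio_union),
        strata=strata,
        family_by_trait=family_by_trait,
    )


def parameter_sweep(
    genome: GenomeGeneSet,
    compendium: QTLCompendium,
    annotation: FunctionAnnotation,
    reference_genes: set[str],
    grid: dict[str, list],
    base_params: AnalysisParameters | None = None,
    n_iter: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Re-run the full pipeline over a threshold grid and score each point.

    *grid* maps :class:`AnalysisParameters` field names (typically
    ``fdr_threshold``, ``min_region_fraction``, ``max_generality``) to value
    lists; the cartesian product is evaluated.  Each row reports the number
    of associations, reference-gene recall among the attainable reference
    genes (those inside candidate sets), the mean prioritized fraction, and
    the resampling p-value against the reference set.
    """
    from .pipeline import run_prioritization  # deferred: pipeline uses this module

    if not grid:
        raise ValueError("empty parameter grid")
    base = base_params or AnalysisParameters()
    names = sorted(grid)
    rows = []
    for values in itertools.product(*(grid[name] for name in names)):
        params = replace(base, **dict(zip(names, values)))
        res = run_prioritization(genome, compendium, annotation, params)
        prio_by_trait = {
            t.trait: set() for t in res.candidates
        }
        for p in res.prioritized:
            prio_by_trait.setdefault(p.trait, set()).add(p.gene_id)
        cand_by_trait = {t.trait: set(t.genes) for t in res.candidates}
        perm = permutation_overlap_test(
            prio_by_trait, cand_by_trait, reference_genes, n_iter=n_iter, seed=seed,
            estimator=base.p_estimator,
        )
        attainable = reference_genes & set().union(*cand_by_trait.values()) if cand_by_trait else set()
        recovered = reference_genes & {p.gene_id for p in res.prioritized}
        rows.append(
            {
                **dict(zip(names, values)),
                "n_associations": int(res.associations["associated"].sum()),
                "recall": len(recovered) / len(attainable) if attainable else float("nan"),
                "prioritized_fraction": res.summary.mean_fraction,
                "permutation_p": perm.p_empirical,
                "observed_overlap": perm.observed_overlap,
            }
        )
    return pd.DataFrame(rows)
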