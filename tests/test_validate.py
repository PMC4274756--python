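"""Permutation tests, annotation randomization, SNP neighborhoods, TF profile."""

import numpy as np
import pandas as pd
import pytest

from qtlprio import (
    AnalysisParameters,
    Gene,
    GenomeGeneSet,
    gwas_overlap_test,
    nearest_genes_to_snp,
    parameter_sweep,
    permutation_overlap_test,
    randomize_annotations,
    run_prioritization,
    tf_profile,
)
from qtlprio.prioritize import PrioritizedGene
from qtlprio.regions import TraitCandidateSet


class TestPermutationOverlap:
    def test_disjoint_reference_ties_every_draw(self):
        res = permutation_overlap_test(
            {"A": {"g1"}}, {"A": {"g1", "g2"}}, {"zz"}, n_iter=100, seed=0
        )
        assert res.observed_overlap == 0 and res.p_empirical == 1.0

    def test_enumerable_case_matches_exact_probability(self):
        # candidates {g1..g4}, draw 2, reference {g1}: P(g1 in draw) = C(3,1)/C(4,2) = 0.5
        res = permutation_overlap_test(
            {"A": {"g1", "g2"}},
            {"A": {"g1", "g2", "g3", "g4"}},
            {"g1"},
            n_iter=10_000,
            seed=42,
        )
        assert res.observed_overlap == 1
        se = np.sqrt(0.5 * 0.5 / 10_000)
        assert abs(res.p_empirical - 0.5) <= 3 * se

    def test_seed_determinism(self):
        kwargs = dict(
            prioritized_by_trait={"A": {"g1", "g2"}},
            candidates_by_trait={"A": {"g1", "g2", "g3", "g4"}},
            reference_genes={"g1"},
            n_iter=500,
            seed=7,
        )
        assert permutation_overlap_test(**kwargs) == permutation_overlap_test(**kwargs)

    def test_oversized_prioritized_set_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            permutation_overlap_test({"A": {"g1", "g2"}}, {"A": {"g1"}}, set(), 10, 0)

    def test_zero_count_reported_as_bound(self):
        res = permutation_overlap_test(
            {"A": {"g1"}}, {"A": {"g1", "g2", "g3", "g4", "g5"}}, {"g1"},
            n_iter=1000, seed=3,
        )
        if res.n_at_least == 0:
            assert res.p_report() == "< 0.001"

    def test_plus_one_estimator(self):
        res = permutation_overlap_test(
            {"A": {"g1"}}, {"A": {"g1", "g2"}}, {"zz"}, n_iter=99, seed=0,
            estimator="plus_one",
        )
        assert res.p_empirical == pytest.approx((res.n_at_least + 1) / 100)


class TestRandomizeAnnotations:
    def test_both_marginals_preserved(self, default_sim):
        ann = default_sim.annotation
        rand = randomize_annotations(ann, seed=5)
        assert rand.term_generality == ann.term_generality
        sizes = sorted(len(t) for t in ann.gene_to_terms.values())
        assert sorted(len(t) for t in rand.gene_to_terms.values()) == sizes

    def test_marginals_preserved_over_full_universe(self, default_sim):
        rand = randomize_annotations(default_sim.annotation, seed=5, universe=default_sim.genome)
        assert rand.term_generality == default_sim.annotation.term_generality

    def test_deterministic_given_seed(self, default_sim):
        a = randomize_annotations(default_sim.annotation, seed=9)
        b = randomize_annotations(default_sim.annotation, seed=9)
        assert a.gene_to_terms == b.gene_to_terms

    def test_null_pipeline_rarely_associates(self, default_sim):
        """Randomized annotations should produce (near) zero associations."""
        res = run_prioritization(
            default_sim.genome,
            default_sim.compendium,
            default_sim.annotation,
            AnalysisParameters(rng_seed=1),
            null_run=True,
        )
        assert int(res.associations["associated"].sum()) <= 1


@pytest.fixture
def snp_genome():
    return GenomeGeneSet(
        [
            Gene("g1", "chr1", 100, 200),
            Gene("g2", "chr1", 300, 400),
            Gene("g3", "chr1", 900, 1000),
        ]
    )


class TestNearestGenes:
    def test_hand_computed_order(self, snp_genome):
        # SNP at 350: inside g2 (0), g1 at 150 from end=200 -> 150, g3 at 550
        assert nearest_genes_to_snp(snp_genome, "chr1", 350) == ["g2", "g1", "g3"]

    def test_snp_inside_gene_is_distance_zero(self, snp_genome):
        assert nearest_genes_to_snp(snp_genome, "chr1", 150, k=1) == ["g1"]

    def test_fewer_genes_than_k(self, snp_genome):
        assert len(nearest_genes_to_snp(snp_genome, "chr1", 350, k=5)) == 3

    def test_unknown_chromosome_empty(self, snp_genome):
        assert nearest_genes_to_snp(snp_genome, "chrX", 350) == []

    def test_tie_breaks_lexicographic(self):
        genome = GenomeGeneSet(
            [Gene("gB", "chr1", 100, 200), Gene("gA", "chr1", 400, 500)]
        )
        # SNP at 300: both 100 away
        assert nearest_genes_to_snp(genome, "chr1", 300, k=2) == ["gA", "gB"]

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_brute_force_sort(self, seed):
        rng = np.random.default_rng(seed)
        genes = []
        for i in range(40):
            s = int(rng.integers(1, 10_000))
            genes.append(Gene(f"g{i:02d}", "chr1", s, s + int(rng.integers(1, 500))))
        genome = GenomeGeneSet(genes)
        for pos in rng.integers(1, 11_000, size=20):
            pos = int(pos)
            def dist(g):
                if g.start <= pos <= g.end:
                    return 0
                return min(abs(pos - g.start), abs(pos - g.end))
            expected = [g.gene_id for g in sorted(genes, key=lambda g: (dist(g), g.gene_id))][:3]
            assert nearest_genes_to_snp(genome, "chr1", pos) == expected


class TestGWASOverlap:
    def test_no_shared_traits_is_an_error(self, snp_genome):
        snps = pd.DataFrame({"trait": ["X"], "chrom": ["chr1"], "pos": [350]})
        with pytest.raises(ValueError, match="shared"):
            gwas_overlap_test({"A": set()}, {"A": {"g1"}}, snps, snp_genome, 10, 0)

    def test_prioritized_gene_next_to_snp_counts(self, snp_genome):
        snps = pd.DataFrame({"trait": ["A"], "chrom": ["chr1"], "pos": [350]})
        res, matched = gwas_overlap_test(
            {"A": {"g2"}}, {"A": {"g1", "g2", "g3"}}, snps, snp_genome, 100, 0
        )
        assert res.observed_overlap >= 1
        assert ("A", "g2") in set(zip(matched["trait"], matched["gene_id"]))

    def test_planted_snps_hit_planted_genes(self, default_sim, default_run):
        prio = default_run.prioritized_by_trait()
        cand = default_run.candidates_by_trait()
        res, matched = gwas_overlap_test(
            prio, cand, default_sim.snp_hits, default_sim.genome, n_iter=200, seed=1
        )
        # SNPs sit at midpoints of planted genes; direct intersection oracle
        expected = 0
        for trait in sorted(set(default_sim.snp_hits["trait"])):
            hood = set()
            sub = default_sim.snp_hits[default_sim.snp_hits["trait"] == trait]
            for _, row in sub.iterrows():
                hood.update(
                    nearest_genes_to_snp(default_sim.genome, row["chrom"], int(row["pos"]))
                )
            expected += len(hood & prio.get(trait, set()))
        assert res.observed_overlap == expected
        assert res.observed_overlap >= len(set(default_sim.snp_hits["trait"]))


class TestTFProfile:
    def _mini(self):
        genome = GenomeGeneSet(
            Gene(f"g{i:03d}", "chr1", 10 * i + 1, 10 * i + 5) for i in range(100)
        )
        tf = {f"g{i:03d}": "MYB" for i in range(10)}
        return genome, tf

    def test_genome_percentage(self):
        genome, tf = self._mini()
        profile = tf_profile([], [], genome, tf)
        assert profile.pct_tf_genome == pytest.approx(10.0)

    def test_trait_below_tf_threshold_excluded(self):
        genome, tf = self._mini()
        prioritized = [
            PrioritizedGene("A", "r1", f"g{i:03d}", frozenset({"T"})) for i in range(9)
        ]
        cands = [TraitCandidateSet("A", frozenset(f"g{i:03d}" for i in range(20)), 1, ("r1",))]
        profile = tf_profile(prioritized, cands, genome, tf)
        assert profile.family_by_trait.empty

    def test_family_over_quarter_shown(self):
        genome, _ = self._mini()
        tf = {f"g{i:03d}": ("F" if i < 4 else "G") for i in range(12)}
        prioritized = [
            PrioritizedGene("A", "r1", f"g{i:03d}", frozenset({"T"})) for i in range(12)
        ]
        cands = [TraitCandidateSet("A", frozenset(f"g{i:03d}" for i in range(30)), 1, ("r1",))]
        profile = tf_profile(prioritized, cands, genome, tf)
        assert list(profile.family_by_trait["trait"]) == ["A"]
        assert profile.family_by_trait.iloc[0]["F"] == pytest.approx(100 * 4 / 12)

    def test_strata_on_planted_run(self, default_sim, default_run):
        profile = tf_profile(
            default_run.prioritized,
            default_run.candidates,
            default_sim.genome,
            default_sim.tf_catalog,
        )
        assert set(profile.strata) == {1, 2, 4}
        for v in profile.strata.values():
            assert 0.0 <= v <= 100.0
        assert 0.0 <= profile.pct_tf_prioritized <= 100.0


class TestParameterSweep:
    def test_single_point_matches_direct_run(self, default_sim, default_run):
        table = parameter_sweep(
            default_sim.genome,
            default_sim.compendium,
            default_sim.annotation,
            default_sim.reference_genes,
            {"fdr_threshold": [0.1]},
            n_iter=200,
            seed=1,
        )
        assert len(table) == 1
        row = table.iloc[0]
        assert row["n_associations"] == int(default_run.associations["associated"].sum())
        assert row["prioritized_fraction"] == pytest.approx(default_run.summary.mean_fraction)

    def test_grid_size(self, default_sim):
        table = parameter_sweep(
            default_sim.genome,
            default_sim.compendium,
            default_sim.annotation,
            default_sim.reference_genes,
            {"fdr_threshold": [0.05, 0.1], "min_region_fraction": [0.5]},
            n_iter=50,
            seed=1,
        )
        assert len(table) == 2

    def test_relaxing_generality_never_shrinks_prioritization(self, default_sim):
        table = parameter_sweep(
            default_sim.genome,
            default_sim.compendium,
            default_sim.annotation,
            default_sim.reference_genes,
            {"max_generality": [0.01, 0.05, 0.2]},
            n_iter=50,
            seed=1,
        )
        fracs = table.sort_values("max_generality")["prioritized_fraction"].to_numpy()
        assert np.all(np.diff(fracs) >= -1e-12)

    def test_empty_grid_rejected(self, default_sim):
        with pytest.raises(ValueError):
            parameter_sweep(
                default_sim.genome,
                default_sim.compendium,
                default_sim.annotation,
                set(),
                {},
            )
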