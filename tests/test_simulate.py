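"""Simulator contracts: determinism, truth bookkeeping, expected divergence."""

import numpy as np
import pytest

from allophylo import molevo
from allophylo._codon import STOP_CODONS, codon_indices, indices_to_seq
from allophylo.simulate import (
    SimulationScenario,
    evolve_cds,
    inject_introgression,
    random_cds,
    scramble_dataset_ids,
    simulate_ancestral_genome,
    simulate_clade,
    simulate_gene_families,
)

ZERO_TREE = "(((PA:0,PB:0):0,((t1:0,t2:0):0)merge:0):0,(o1:0,o2:0):0);"


class TestAncestralGenome:
    def test_counts_and_ordering(self):
        ann, cds = simulate_ancestral_genome(1, 10, 300, 42)
        assert ann.n_genes == 10
        assert [ann.genes[g].order for g in ann.chromosomes["anc_chr1"]] == list(range(10))

    def test_two_chromosomes(self):
        ann, _ = simulate_ancestral_genome(2, 5, 300, 7)
        assert ann.n_genes == 10
        assert all(len(v) == 5 for v in ann.chromosomes.values())

    def test_seed_determinism(self):
        a = simulate_ancestral_genome(2, 8, 120, 3)
        b = simulate_ancestral_genome(2, 8, 120, 3)
        assert a[1] == b[1]
        assert a[0].to_dataframe().equals(b[0].to_dataframe())

    def test_cds_are_valid_orfs(self):
        _, cds = simulate_ancestral_genome(1, 20, 90, 5)
        for seq in cds.values():
            assert seq.startswith("ATG")
            codons = {seq[i : i + 3] for i in range(0, len(seq), 3)}
            assert not codons & STOP_CODONS

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            simulate_ancestral_genome(0, 5, 300, 1)
        with pytest.raises(ValueError):
            simulate_ancestral_genome(1, 5, 301, 1)


class TestSequenceEvolution:
    def test_zero_length_is_identity(self, rng):
        idx = random_cds(50, rng)
        out, n = evolve_cds(idx, 0.0, 0.2, rng)
        assert np.array_equal(out, idx) and n == 0

    def test_expected_ks_recovered(self, rng):
        """A branch of expected Ks 0.2 over 500 genes: the NG86 estimate of
        the realized divergence should match within 3 standard errors."""
        est = []
        for _ in range(500):
            a = random_cds(100, rng)
            b, _ = evolve_cds(a, 0.2, 0.2, rng)
            est.append(molevo.estimate_ks_ka(a, b).ks)
        mean = float(np.mean(est))
        se = float(np.std(est, ddof=1) / np.sqrt(len(est)))
        assert abs(mean - 0.2) < 3 * se + 0.005  # small documented JC-mixture bias

    def test_never_creates_stops_or_moves_start(self, rng):
        for _ in range(20):
            a = random_cds(30, rng)
            b, _ = evolve_cds(a, 0.5, 0.3, rng)
            seq = indices_to_seq(b)
            assert seq.startswith("ATG")
            codon_indices(seq)  # raises on internal stops


class TestSimulateClade:
    def test_degenerate_scenario_identity(self):
        sc = SimulationScenario(
            n_chromosomes=1, genes_per_chromosome=12, tree=ZERO_TREE,
            loss_prob_dominant=0.0, loss_prob_recessive=0.0,
            inversions_per_branch=0.0, tandem_dups_per_branch=0.0, seed=2,
        )
        ds = simulate_clade(sc)
        _, anc_cds = simulate_ancestral_genome(1, 12, 300, 2)
        anc_by_locus = {k.split("_", 1)[1]: v for k, v in anc_cds.items()}
        for tip in ("t1", "t2"):
            # two homoeologs per ancestral gene, all identical to the ancestor
            per_locus = {}
            for g, seq in ds.cds[tip].items():
                per_locus.setdefault(ds.truth.ancestral_locus[g], []).append(seq)
            assert all(len(v) == 2 for v in per_locus.values())
            for locus, seqs in per_locus.items():
                assert seqs[0] == seqs[1] == anc_by_locus[locus]

    def test_total_recessive_loss(self):
        sc = SimulationScenario(
            n_chromosomes=1, genes_per_chromosome=15, tree=ZERO_TREE,
            loss_prob_dominant=0.0, loss_prob_recessive=1.0,
            inversions_per_branch=0.0, tandem_dups_per_branch=0.0, seed=2,
        )
        ds = simulate_clade(sc)
        for tip in ("t1", "t2"):
            subs = {ds.truth.subgenome_origin[g] for g in ds.cds[tip]}
            assert subs == {"A"}

    def test_bitwise_reproducibility(self):
        sc = SimulationScenario(n_chromosomes=1, genes_per_chromosome=30, seed=13)
        a = simulate_clade(sc)
        b = simulate_clade(SimulationScenario(n_chromosomes=1, genes_per_chromosome=30, seed=13))
        assert a.cds == b.cds
        for tip in a.annotations:
            assert a.annotations[tip].to_dataframe().equals(b.annotations[tip].to_dataframe())

    def test_every_gene_has_one_origin_and_lost_genes_absent(self, small_dataset):
        ds = small_dataset
        for tip in ds.truth.crown_tips:
            for g in ds.cds[tip]:
                assert ds.truth.subgenome_origin[g] in {"A", "B"}
            for key, fate in ds.truth.gene_fates[tip].items():
                sub, locus = key.split(":")
                present = any(
                    ds.truth.ancestral_locus[g] == locus
                    and ds.truth.subgenome_origin[g] == sub
                    for g in ds.cds[tip]
                )
                if fate == "lost":
                    assert not present

    def test_homoeolog_ks_exceeds_sister_ortholog_ks(self, small_dataset):
        """Parental divergence predates the crown, so within-tip homoeologous
        Ks must exceed between-sister-orthologs Ks."""
        ds = small_dataset
        an = ds.annotations
        by_locus = {}
        for g in ds.cds["t1"]:
            by_locus.setdefault(ds.truth.ancestral_locus[g], {})[
                ds.truth.subgenome_origin[g]
            ] = g
        homo = []
        for locus, copies in by_locus.items():
            if {"A", "B"} <= set(copies):
                homo.append(
                    molevo.estimate_ks_ka(
                        ds.cds["t1"][copies["A"]], ds.cds["t1"][copies["B"]]
                    ).ks
                )
        ortho = []
        t2_lookup = {
            (ds.truth.ancestral_locus[g], ds.truth.subgenome_origin[g]): g
            for g in ds.cds["t2"]
        }
        for locus, copies in by_locus.items():
            g2 = t2_lookup.get((locus, "A"))
            if "A" in copies and g2:
                ortho.append(molevo.estimate_ks_ka(ds.cds["t1"][copies["A"]], ds.cds["t2"][g2]).ks)
        assert np.median(homo) > np.median(ortho)

    def test_duplicate_tree_tips_rejected(self):
        tree = "(((PA:0,PB:0):0,((t1:0,t1:0):0)merge:0):0,o1:0);"
        with pytest.raises(ValueError, match="unique"):
            simulate_clade(
                SimulationScenario(n_chromosomes=1, genes_per_chromosome=5, tree=tree, seed=0)
            )

    def test_invalid_hybridization_rejected(self):
        with pytest.raises(ValueError, match="parents"):
            simulate_clade(
                SimulationScenario(
                    n_chromosomes=1, genes_per_chromosome=5,
                    hybridization=("nope", "PB", "merge"), seed=0,
                )
            )
        with pytest.raises(ValueError, match="merge"):
            simulate_clade(
                SimulationScenario(
                    n_chromosomes=1, genes_per_chromosome=5,
                    hybridization=("PA", "PB", "nope"), seed=0,
                )
            )


class TestIntrogression:
    def test_f_zero_is_identity(self, small_dataset):
        out = inject_introgression(small_dataset, "o1", "t1", 0.0, seed=1)
        assert out.cds == small_dataset.cds

    def test_f_one_replaces_every_matched_gene(self, small_dataset):
        ds = small_dataset
        out = inject_introgression(ds, "o1", "t1", 1.0, seed=1)
        donor_by_locus = {ds.truth.ancestral_locus[g]: g for g in ds.cds["o1"]}
        for g in out.cds["t1"]:
            src = donor_by_locus.get(ds.truth.ancestral_locus[g])
            if src is not None:
                assert out.cds["t1"][g] == ds.cds["o1"][src]

    def test_gene_order_and_content_invariant(self, small_dataset):
        out = inject_introgression(small_dataset, "o1", "t1", 0.5, seed=3)
        assert (
            out.annotations["t1"].to_dataframe().equals(
                small_dataset.annotations["t1"].to_dataframe()
            )
        )
        assert set(out.cds["t1"]) == set(small_dataset.cds["t1"])

    def test_invalid_arguments(self, small_dataset):
        with pytest.raises(ValueError):
            inject_introgression(small_dataset, "nope", "t1", 0.5, seed=1)
        with pytest.raises(ValueError):
            inject_introgression(small_dataset, "o1", "t1", 1.5, seed=1)


class TestScrambledIds:
    def test_truth_survives_relabeling(self, small_dataset):
        out = scramble_dataset_ids(small_dataset, seed=0)
        assert set(out.truth.id_map) == {
            g for t in small_dataset.cds for g in small_dataset.cds[t]
        }
        for tip in small_dataset.cds:
            for old, seq in small_dataset.cds[tip].items():
                assert out.cds[tip][out.truth.id_map[old]] == seq
        # opaque ids carry no structure
        assert all(v.startswith("g") and v[1:].isdigit() for v in out.truth.id_map.values())


class TestGeneFamilies:
    def test_shared_history_distance_structure(self):
        fams = simulate_gene_families(5, "shared", seed=1)
        for fam in fams:
            d_homo = molevo.estimate_ks_ka(fam["R1"], fam["R2"]).ks
            d_orth = molevo.estimate_ks_ka(fam["R1"], fam["S1"]).ks
            assert d_homo > d_orth

    def test_independent_history_distance_structure(self):
        fams = simulate_gene_families(5, "independent", seed=1)
        for fam in fams:
            d_copies = molevo.estimate_ks_ka(fam["R1"], fam["R2"]).ks
            d_species = molevo.estimate_ks_ka(fam["R1"], fam["S1"]).ks
            assert d_copies < d_species

    def test_copy_loss_keeps_at_least_one_per_species(self):
        fams = simulate_gene_families(40, "shared", copy_loss_prob=0.5, seed=2)
        for fam in fams:
            assert any(l.startswith("R") for l in fam)
            assert any(l.startswith("S") for l in fam)
            assert "O" in fam
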