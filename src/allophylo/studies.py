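"""Reproducible simulation studies exercising the whole pipeline.

Each function runs one self-contained study at fixed, documented conditions
(the methods note records the scenario sizes) and returns plain numbers:
recovery fractions, rate ratios, calibration rates. They are what the
acceptance machinery and the examples call; every study takes an explicit
seed and is deterministic given it.
"""

from __future__ import annotations

import dendropy
import numpy as np

from . import molevo, structphylo, subgenome, wgdtest
from .pipeline import CladeAnalysis
from .simulate import (
    SimulationScenario,
    inject_introgression,
    simulate_clade,
    simulate_gene_families,
)

#: crown topology of the default five-tip scenario, per subgenome clade
MIRROR_CROWN = "(((t1_X,t2_X),(t3_X,t4_X)),t5_X,(o1,o2));"


def _read(newick: str, tns=None) -> dendropy.Tree:
    return dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True, taxon_namespace=tns
    )


def slowdown_bounds() -> dict[str, float]:
    """Post-WGD slowdown ratios from the juglandoid/gamma Ks peak ranges.

    Peak ranges: juglandoid WGD 0.17-0.48, gamma triplication 1.70-2.01;
    ages 85 and ~120 Myr. Pairing the range minima gives the upper slowdown
    bound, the maxima the lower bound.
    """
    return {
        "upper": molevo.slowdown_ratio(0.17, 85e6, 1.70, 120e6),
        "lower": molevo.slowdown_ratio(0.48, 85e6, 2.01, 120e6),
    }


def cross_taxon_slowdowns() -> dict[str, float]:
    """Slowdown ratios for two other woody rosid WGDs (range midpoints).

    Salicoid WGD: Ks 0.45 at 62.5 Myr; Pomoideae WGD: Ks 0.33 at 49 Myr;
    both against the gamma triplication at Ks ~2.5 and ~120 Myr.
    """
    return {
        "salicoid": molevo.slowdown_ratio(0.45, 62.5e6, 2.5, 120e6),
        "pomoideae": molevo.slowdown_ratio(0.33, 49e6, 2.5, 120e6),
    }


# ------------------------------------------------------------------ trees


def _subgenome_units(ds, an, outgroup: str = "o1"):
    units = {}
    for tip in ds.truth.crown_tips:
        u, _ = an.subgenome_partition(tip, outgroup)
        units.update(u)
    for og in ds.truth.outgroups:
        units[og] = set(ds.cds[og])
    return units


def _synteny_tree(an, units, n_bootstrap: int = 0):
    g2u = {g: u for u, gs in units.items() for g in gs}
    clusters = an.clusters()
    filtered = [{g for g in c if g in g2u} for c in clusters]
    filtered = [c for c in filtered if len(c) >= 2]
    matrix = structphylo.build_matrix(filtered, g2u)
    res = structphylo.infer_binary_tree(matrix, n_bootstrap=n_bootstrap)
    return res.tree, matrix


def _restricted_rf(tree: dendropy.Tree, keep: list[str], reference_newick: str) -> int:
    sub = _read(tree.as_string(schema="newick"))
    sub.retain_taxa_with_labels(keep)
    tns = dendropy.TaxonNamespace()
    a = _read(sub.as_string(schema="newick"), tns)
    b = _read(reference_newick, tns)
    return structphylo.rf_distance(a, b)


def mirror_recovery(n_replicates: int = 20, seed: int = 0, genes_per_chromosome: int = 300):
    """Fraction of replicates whose synteny-cluster tree recovers the true
    organismal topology inside both the dominant and the recessive clade.

    Five allotetraploid tips plus two diploid outgroups, biased fractionation
    0.15/0.30, subgenomes assigned by outgroup-RBH counts over homoeologous
    chromosome pairs.
    """
    wins = 0
    details = []
    for rep in range(n_replicates):
        sc = SimulationScenario(
            n_chromosomes=2,
            genes_per_chromosome=genes_per_chromosome,
            seed=(seed + 7919 * rep) % 2**31,
        )
        ds = simulate_clade(sc)
        an = CladeAnalysis(ds.annotations, ds.cds)
        units = _subgenome_units(ds, an)
        tree, _ = _synteny_tree(an, units)
        rfs = {}
        for suffix in ("dom", "rec"):
            keep = [f"t{i}_{suffix}" for i in range(1, 6)] + ["o1", "o2"]
            rfs[suffix] = _restricted_rf(
                tree, keep, MIRROR_CROWN.replace("X", suffix)
            )
        details.append(rfs)
        wins += rfs["dom"] == 0 and rfs["rec"] == 0
    return wins / n_replicates, details


def introgression_contrast(
    n_replicates: int = 20,
    seed: int = 0,
    f: float = 0.3,
    genes_per_chromosome: int = 200,
):
    """The central structural-phylogenomics contrast under gene flow.

    A fraction ``f`` of one tip's genes receives outgroup (o1) sequence;
    gene order and presence/absence are untouched. Returns the fraction of
    replicates where (a) the synteny-cluster tree is identical with and
    without introgression (same fixed subgenome units) and (b) the mean-Ks
    neighbor-joining tree places the recipient away from its true sister.
    """
    invariant = misplaced = 0
    for rep in range(n_replicates):
        rep_seed = (seed + 104729 * rep) % 2**31
        sc = SimulationScenario(
            n_chromosomes=2, genes_per_chromosome=genes_per_chromosome, seed=rep_seed
        )
        ds = simulate_clade(sc)
        an0 = CladeAnalysis(ds.annotations, ds.cds)
        units = _subgenome_units(ds, an0)
        base_tree, _ = _synteny_tree(an0, units)

        ds2 = inject_introgression(ds, "o1", "t1", f, seed=rep_seed + 1)
        an2 = CladeAnalysis(ds2.annotations, ds2.cds)
        intro_tree, _ = _synteny_tree(an2, units)

        tns = dendropy.TaxonNamespace()
        a = _read(base_tree.as_string(schema="newick"), tns)
        b = _read(intro_tree.as_string(schema="newick"), tns)
        invariant += structphylo.rf_distance(a, b) == 0

        dist = an2.mean_ks_matrix(units)
        njt, _ = structphylo.nj_tree(dist)
        keep = [f"t{i}_dom" for i in range(1, 6)] + ["o1", "o2"]
        sub = _read(njt.as_string(schema="newick"))
        sub.retain_taxa_with_labels(keep)
        cherry_found = any(
            {lf.taxon.label for lf in node.leaf_iter()} == {"t1_dom", "t2_dom"}
            for node in sub.preorder_internal_node_iter()
        )
        misplaced += not cherry_found
    return invariant / n_replicates, misplaced / n_replicates


RATE_TREE = (
    "(((PA:0.08,PB:0.08):0.02,((tA:0.15,tB:0.15):0.02)merge:0.02):0.05,"
    "(o1:0.18,o2:0.18):0.02);"
)


def rate_recovery(seed: int = 0, scalar: float = 0.33, genes_per_chromosome: int = 400):
    """Branch-specific Ks ratio of a normal-rate tip over a slowed sister.

    One tip evolves at ``scalar`` times the clade rate; gene triplets
    (tip A ortholog, tip B ortholog, outgroup ortholog via RBH chains) are
    decomposed with the three-taxon relative-rate equations and the ratio of
    median branch-specific Ks values is returned along with the triplet
    count. With scalar 0.33 the expected ratio is ~3.
    """
    sc = SimulationScenario(
        n_chromosomes=2,
        genes_per_chromosome=genes_per_chromosome,
        tree=RATE_TREE,
        rate_scalars={"tA": scalar},
        seed=seed % 2**31,
    )
    ds = simulate_clade(sc)
    an = CladeAnalysis(ds.annotations, ds.cds)
    rbh_ao = dict(an.rbh("tA", "o1"))
    ks_slow, ks_normal = [], []
    for a, b in an.rbh("tA", "tB"):
        o = rbh_ao.get(a)
        if o is None:
            continue
        try:
            rr = molevo.relative_rate_decompose(
                an.ks(a, b).ks, an.ks(a, o).ks, an.ks(b, o).ks, tolerance=1.0
            )
        except ValueError:
            continue
        ks_slow.append(rr.ks_a)
        ks_normal.append(rr.ks_b)
    ratio = float(np.median(ks_normal) / np.median(ks_slow))
    return ratio, len(ks_slow)


def shared_wgd_calibration(
    seed: int = 0,
    n_shared: int = 300,
    n_independent: int = 100,
    support_threshold: float = 80.0,
):
    """Topology-test calibration on families with known WGD history.

    NJ gene trees (NG86 Ks distances, 100 codon-bootstrap replicates) are
    classified per family; returns the shared fraction among informative
    trees for shared-history families and the independent fraction for
    independent-history families, with the informative counts.
    """

    def run(history, n, offset):
        fams = simulate_gene_families(
            n, history, copy_loss_prob=0.15, seed=(seed + offset) % 2**31
        )
        verdicts = []
        for i, fam in enumerate(fams):
            focal = [l for l in fam if l.startswith("R")]
            other = [l for l in fam if l.startswith("S")]
            if len(focal) + len(other) < 3:
                continue
            tree = wgdtest.build_gene_tree(
                fam, "O", n_bootstrap=100, seed=(seed + offset + i + 1) % 2**31
            )
            verdicts.append(
                wgdtest.classify_family_topology(
                    tree, focal, other, "O", support_threshold, family_id=str(i)
                )
            )
        return wgdtest.tally_topologies(verdicts)

    shared_tally = run("shared", n_shared, offset=11)
    indep_tally = run("independent", n_independent, offset=500_011)
    return shared_tally, indep_tally


def wgd_contrast_calibration(n_replicates: int = 20, seed: int = 0):
    """Intergenomic ortholog/paralog block-median contrast on clades whose
    parental split predates speciation: fraction of 'shared' verdicts."""
    hits = 0
    for rep in range(n_replicates):
        sc = SimulationScenario(
            n_chromosomes=2, genes_per_chromosome=300, seed=(seed + 31 * rep) % 2**31
        )
        ds = simulate_clade(sc)
        an = CladeAnalysis(ds.annotations, ds.cds)
        summaries, _ = an.block_summaries("t1", "t2")
        medians = [s.median_ks for s in summaries]
        if len(medians) < 10:
            continue
        hits += wgdtest.ortholog_paralog_contrast(medians).verdict == "shared"
    return hits / n_replicates


SINGLE_TIP_TREE = (
    "(((PA:0.15,PB:0.15):0.02,((t1:0.05):0.03)merge:0.02):0.08,"
    "(o1:0.2,o2:0.2):0.05);"
)


def subgenome_assignment_accuracy(
    seed: int = 0, n_chromosomes: int = 16, genes_per_chromosome: int = 400
):
    """Fraction of homoeologous chromosome pairs whose low-loss (dominant)
    subgenome is identified correctly, at biased fractionation 0.15/0.30."""
    sc = SimulationScenario(
        n_chromosomes=n_chromosomes,
        genes_per_chromosome=genes_per_chromosome,
        tree=SINGLE_TIP_TREE,
        inversions_per_branch=1.0,
        tandem_dups_per_branch=1.0,
        seed=seed % 2**31,
    )
    ds = simulate_clade(sc)
    an = CladeAnalysis(ds.annotations, ds.cds)
    _, assignment = an.subgenome_partition("t1", "o1")
    correct = 0
    for p in assignment.pairs:
        subs = {
            ds.truth.subgenome_origin[g]
            for g in ds.annotations["t1"].chromosomes[p.dominant]
        }
        correct += subs == {"A"}
    return correct / len(assignment.pairs), len(assignment.pairs)


ZERO_LENGTH_TREE = "(((PA:0,PB:0):0,((t1:0):0)merge:0):0,(o1:0,o2:0):0);"


def fractionation_type_i(
    n_replicates: int = 100, seed: int = 0, loss: float = 0.2, alpha: float = 0.05
):
    """False-positive rate of the biased-fractionation test when both
    subgenomes lose genes at the same rate (non-overlapping windows)."""
    rejections = 0
    for rep in range(n_replicates):
        sc = SimulationScenario(
            n_chromosomes=1,
            genes_per_chromosome=600,
            tree=ZERO_LENGTH_TREE,
            loss_prob_dominant=loss,
            loss_prob_recessive=loss,
            inversions_per_branch=0.0,
            tandem_dups_per_branch=0.0,
            seed=(seed + 13 * rep) % 2**31,
        )
        ds = simulate_clade(sc)
        loc2genes: dict[str, set[str]] = {}
        for g in ds.cds["t1"]:
            loc2genes.setdefault(ds.truth.ancestral_locus[g], set()).add(g)
        ortho = {
            g: loc2genes.get(ds.truth.ancestral_locus[g], set())
            for g in ds.cds["o1"]
        }
        ann = ds.annotations["t1"]
        assignment = subgenome.SubgenomeAssignment(
            [
                subgenome.PairAssignment(
                    next(c for c in ann.chromosomes if "_A" in c),
                    next(c for c in ann.chromosomes if "_B" in c),
                    0, 0, False,
                )
            ]
        )
        prof = subgenome.fractionation_profile(
            ds.annotations["o1"], ortho, assignment, ann.chrom_of, window=30, step=30
        )
        if subgenome.biased_fractionation_test(prof).pvalue < alpha:
            rejections += 1
    return rejections / n_replicates


def quartet_type_i(
    n_replicates: int = 500, seed: int = 0, n_trees: int = 200, alpha: float = 0.05
):
    """False-positive rate of the quartet-concordance test when the two
    minor topologies are exactly exchangeable (the MSC null)."""
    rng = np.random.default_rng(seed % 2**31)
    rejections = 0
    for _ in range(n_replicates):
        counts = rng.multinomial(n_trees, [0.6, 0.2, 0.2])
        res = structphylo.quartet_concordance_test(
            counts={("a", "b", "c", "d"): tuple(counts)}, alpha=alpha
        )
        rejections += res[0].reject
    return rejections / n_replicates
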