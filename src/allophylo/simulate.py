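"""Synthetic allopolyploid clade simulator.

The generator emulates the history this package is built to analyse: two
diploid parental lineages diverge, merge into an allotetraploid, and the
polyploid clade then speciates under a known organismal tree while the two
subgenomes fractionate at different rates. Lineage-specific rate scalars,
within-chromosome inversions, tandem duplications and sequence-level
introgression (which leaves gene order untouched) are all available, and the
full truth — organismal tree, subgenome of origin, gene fates, introgressed
gene sets — is returned alongside the emitted annotations and CDS.

Sequence model
--------------
Branch lengths are expected synonymous substitutions per synonymous site
(Ks). Along a branch of length ``ks`` each gene receives
``Poisson(ks * S)`` synonymous substitution events (S = its NG86 synonymous
site count) placed uniformly over the gene's currently viable synonymous
single-nucleotide changes, plus ``Poisson(omega * ks * N)`` nonsynonymous
events placed likewise over nonsynonymous changes; changes through stop
codons never occur and the initial ATG is immutable. Expected pairwise NG86
Ks therefore equals path length (up to the small heterogeneity bias of the
Jukes–Cantor correction, see the methods note).

Hybridization semantics
-----------------------
The scenario tree contains two parent tips (default ``PA``, ``PB``) and an
internal node labelled ``merge``. The parent tips stand for the parental
gametes at the moment of merger: subgenome A of the allotetraploid *is* the
PA leaf genome and subgenome B the PB leaf genome, so the homoeologous
divergence at the merger equals the patristic distance between PA and PB.
The crown clade hangs from ``merge``; the branch leading into ``merge``
contributes no additional evolution. Leaves outside the crown and distinct
from the parents are emitted as unduplicated (diploid) outgroups.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np

from ._codon import (
    CODON_INDEX,
    CODONS,
    STOP_CODONS,
    codon_indices,
    indices_to_seq,
    mutation_opportunities,
    ng86_tables,
)
from .annotation import Gene, GenomeAnnotation

START = CODON_INDEX["ATG"]
_NONSTOP = [CODON_INDEX[c] for c in CODONS if c not in STOP_CODONS]

# The crown clade hangs from 'merge' through a short stem branch: the period
# between hybridization and the crown radiation, during which fractionation
# shared by the whole clade accumulates (the signal that marks each subgenome
# clade in presence/absence matrices).
DEFAULT_TREE = (
    "(((PA:0.15,PB:0.15):0.02,"
    "((((t1:0.01,t2:0.01):0.02,(t3:0.01,t4:0.01):0.02):0.02,t5:0.05):0.03)merge:0.02):0.08,"
    "(o1:0.2,o2:0.2):0.05);"
)


@dataclass
class SimulationScenario:
    """Parameters of one simulated allopolyploid clade."""

    n_chromosomes: int = 2
    genes_per_chromosome: int = 80
    codon_length: int = 300
    tree: str = DEFAULT_TREE
    hybridization: tuple[str, str, str] = ("PA", "PB", "merge")
    loss_prob_dominant: float = 0.15
    loss_prob_recessive: float = 0.30
    rate_scalars: dict[str, float] = field(default_factory=dict)
    inversions_per_branch: float = 0.5
    tandem_dups_per_branch: float = 0.5
    introgression_events: list[tuple[str, str, float]] = field(default_factory=list)
    omega: float = 0.2  # Ka/Ks of the nonsynonymous background
    seed: int = 0
    scramble_ids: bool = False

    def validate(self) -> None:
        if self.n_chromosomes < 1 or self.genes_per_chromosome < 1:
            raise ValueError("chromosome and gene counts must be >= 1")
        if self.codon_length % 3 != 0 or self.codon_length < 6:
            raise ValueError("codon_length must be a multiple of 3 and >= 6")
        for p in (self.loss_prob_dominant, self.loss_prob_recessive):
            if not 0.0 <= p <= 1.0:
                raise ValueError("loss probabilities must lie in [0, 1]")
        if (
            self.loss_prob_dominant > self.loss_prob_recessive
        ):
            raise ValueError(
                "biased fractionation requires loss_prob_dominant <= loss_prob_recessive"
            )
        for _, _, f in self.introgression_events:
            if not 0.0 <= f <= 1.0:
                raise ValueError("introgression fractions must lie in [0, 1]")
        for s in self.rate_scalars.values():
            if s <= 0:
                raise ValueError("rate scalars must be positive")


@dataclass
class SimulationTruth:
    true_tree: str  # newick over emitted taxa (crown tips + outgroups)
    crown_tips: list[str]
    outgroups: list[str]
    subgenome_origin: dict[str, str]  # emitted gene id -> 'A'/'B' ('' for outgroups)
    ancestral_locus: dict[str, str]  # emitted gene id -> 'c{chrom}g{index}'
    gene_fates: dict[str, dict[str, str]]  # tip -> '{sub}:{locus}' -> fate
    introgressed: dict[tuple[str, str], set[str]] = field(default_factory=dict)
    rate_scalars: dict[str, float] = field(default_factory=dict)
    realized_branch_ks: dict[str, float] = field(default_factory=dict)
    id_map: dict[str, str] = field(default_factory=dict)  # original -> emitted id


@dataclass
class SimulatedDataset:
    annotations: dict[str, GenomeAnnotation]
    cds: dict[str, dict[str, str]]
    truth: SimulationTruth


# --------------------------------------------------------------- sequences


def random_cds(n_codons: int, rng: np.random.Generator) -> np.ndarray:
    idx = rng.choice(_NONSTOP, size=n_codons)
    idx[0] = START
    return idx.astype(np.int16)


def evolve_cds(
    idx: np.ndarray, ks: float, omega: float, rng: np.random.Generator
) -> tuple[np.ndarray, int]:
    """Evolve a codon-index array by expected ``ks`` synonymous substitutions
    per synonymous site (and ``omega*ks`` nonsynonymous per nonsynonymous
    site). Returns (new array, number of synonymous events)."""
    if ks < 0:
        raise ValueError("branch length must be non-negative")
    idx = idx.copy()
    if ks == 0:
        return idx, 0
    S, N, _, _ = ng86_tables()
    syn_ops, non_ops = mutation_opportunities()
    s_total = float(S[idx[1:]].sum())  # position 0 (ATG) is frozen
    n_total = float(N[idx[1:]].sum())
    n_syn = rng.poisson(ks * s_total)
    n_non = rng.poisson(omega * ks * n_total)
    events = ["s"] * n_syn + ["n"] * n_non
    rng.shuffle(events)
    for kind in events:
        ops = syn_ops if kind == "s" else non_ops
        # uniform over all (codon, change) opportunities in the gene
        counts = np.fromiter((len(ops[c]) for c in idx[1:]), dtype=np.int64)
        total = int(counts.sum())
        if total == 0:
            continue
        r = int(rng.integers(total))
        codon_pos = 1 + int(np.searchsorted(np.cumsum(counts), r, side="right"))
        within = r - int(np.cumsum(counts)[codon_pos - 2]) if codon_pos > 1 else r
        _, _, new_idx = ops[idx[codon_pos]][within]
        idx[codon_pos] = new_idx
    return idx, n_syn


# ------------------------------------------------------ ancestral genome


def simulate_ancestral_genome(
    n_chromosomes: int, genes_per_chromosome: int, codon_length: int, seed: int
) -> tuple[GenomeAnnotation, dict[str, str]]:
    """Random ancestral genome: consecutively ordered genes with random CDS.

    Every CDS starts with ATG and contains no internal stop. Deterministic
    for a fixed seed.
    """
    if n_chromosomes < 1 or genes_per_chromosome < 1:
        raise ValueError("counts must be >= 1")
    if codon_length % 3 != 0:
        raise ValueError("codon_length must be a multiple of 3")
    rng = np.random.default_rng(seed)
    genes, cds = [], {}
    for ci in range(n_chromosomes):
        for gi in range(genes_per_chromosome):
            gid = f"anc_c{ci}g{gi:04d}"
            start = gi * 1000 + 1
            genes.append(Gene(gid, f"anc_chr{ci + 1}", start, start + codon_length - 1))
            cds[gid] = indices_to_seq(random_cds(codon_length // 3, rng))
    return GenomeAnnotation.from_genes("ancestor", genes), cds


# ------------------------------------------------------------ clade model


@dataclass
class _GeneState:
    locus: str  # 'c{ci}g{gi}' (+ '.t{k}' for tandem copies)
    sub: str  # '' before merge / outgroups; 'A'/'B' after merge
    idx: np.ndarray
    strand: str = "+"
    fate: str = "retained"


@dataclass
class _Chrom:
    index: int  # ancestral chromosome index
    genes: list[_GeneState] = field(default_factory=list)


def _copy_genome(genome: list[_Chrom]) -> list[_Chrom]:
    return [
        _Chrom(c.index, [replace(g, idx=g.idx.copy()) for g in c.genes]) for c in genome
    ]


class _CladeSimulator:
    def __init__(self, scenario: SimulationScenario):
        scenario.validate()
        self.sc = scenario
        self.rng = np.random.default_rng(scenario.seed)
        try:
            self.tree = dendropy.Tree.get(data=scenario.tree, schema="newick")
        except dendropy.utility.error.DataParseError as exc:
            if "Duplicate taxon" in str(exc) or "Multiple occurrences" in str(exc):
                raise ValueError("tree tips must be unique") from exc
            raise
        pa, pb, merge_label = scenario.hybridization
        labels = [lf.taxon.label for lf in self.tree.leaf_node_iter()]
        if len(labels) != len(set(labels)):
            raise ValueError("tree tips must be unique")
        taxa = set(labels)
        if pa not in taxa or pb not in taxa:
            raise ValueError(f"hybridization parents {pa!r}/{pb!r} not in tree")
        self.merge_node = None
        for nd in self.tree.preorder_node_iter():
            if nd.is_leaf():
                continue
            if (nd.label or "") == merge_label or (
                nd.taxon is not None and nd.taxon.label == merge_label
            ):
                self.merge_node = nd
        if self.merge_node is None:
            raise ValueError(f"merge node {merge_label!r} not found in tree")
        crown_leaves = {lf.taxon.label for lf in self.merge_node.leaf_iter()}
        if pa in crown_leaves or pb in crown_leaves:
            raise ValueError("impossible merge node: parents inside the crown clade")
        self.pa, self.pb = pa, pb
        self.crown_tips = sorted(crown_leaves)
        self.outgroups = sorted(taxa - crown_leaves - {pa, pb})
        self.tandem_counter = 0
        self.realized: dict[str, list[float]] = {}

    # -- branch operators ------------------------------------------------

    def _evolve_branch(self, genome: list[_Chrom], ks: float, label: str) -> None:
        ev = s_tot = 0.0
        S = ng86_tables()[0]
        for chrom in genome:
            for g in chrom.genes:
                g.idx, n_syn = evolve_cds(g.idx, ks, self.sc.omega, self.rng)
                ev += n_syn
                s_tot += float(S[g.idx[1:]].sum())
        if s_tot > 0:
            self.realized.setdefault(label, []).append(ev / s_tot)

    def _invert(self, genome: list[_Chrom]) -> None:
        n = self.rng.poisson(self.sc.inversions_per_branch)
        for _ in range(n):
            chrom = genome[int(self.rng.integers(len(genome)))]
            if len(chrom.genes) < 2:
                continue
            i, j = sorted(self.rng.choice(len(chrom.genes), size=2, replace=False))
            seg = chrom.genes[i : j + 1][::-1]
            for g in seg:
                g.strand = "-" if g.strand == "+" else "+"
            chrom.genes[i : j + 1] = seg

    def _tandem(self, genome: list[_Chrom]) -> None:
        n = self.rng.poisson(self.sc.tandem_dups_per_branch)
        for _ in range(n):
            chrom = genome[int(self.rng.integers(len(genome)))]
            if not chrom.genes:
                continue
            i = int(self.rng.integers(len(chrom.genes)))
            src = chrom.genes[i]
            self.tandem_counter += 1
            idx, _ = evolve_cds(src.idx, 0.01, self.sc.omega, self.rng)
            copy_state = _GeneState(
                locus=f"{src.locus}.t{self.tandem_counter}",
                sub=src.sub,
                idx=idx,
                strand=src.strand,
                fate="tandem-copy",
            )
            chrom.genes.insert(i + 1, copy_state)

    def _lose(self, genome: list[_Chrom], p_branch: dict[str, float], tip_fates) -> None:
        for chrom in genome:
            survivors = []
            for g in chrom.genes:
                p = p_branch.get(g.sub, 0.0)
                if p > 0 and self.rng.random() < p:
                    tip_fates[f"{g.sub}:{g.locus}"] = "lost"
                else:
                    survivors.append(g)
            chrom.genes = survivors

    # -- traversal -------------------------------------------------------

    def run(self) -> SimulatedDataset:
        sc = self.sc
        ann0, cds0 = simulate_ancestral_genome(
            sc.n_chromosomes, sc.genes_per_chromosome, sc.codon_length, sc.seed
        )
        genome0: list[_Chrom] = []
        for ci in range(sc.n_chromosomes):
            chrom = _Chrom(ci)
            for gi in range(sc.genes_per_chromosome):
                gid = f"anc_c{ci}g{gi:04d}"
                chrom.genes.append(
                    _GeneState(locus=f"c{ci}g{gi:04d}", sub="", idx=codon_indices(cds0[gid]))
                )
            genome0.append(chrom)

        leaf_genomes: dict[str, list[_Chrom]] = {}

        def walk_diploid(node, genome):
            for child in node.child_nodes():
                if child is self.merge_node:
                    continue  # the merge stem contributes no evolution
                sub = _copy_genome(genome)
                length = child.edge.length or 0.0
                label = child.taxon.label if child.is_leaf() else (child.label or "")
                scalar = sc.rate_scalars.get(label, 1.0) if child.is_leaf() else 1.0
                self._evolve_branch(sub, length * scalar, label or "internal")
                self._invert(sub)
                self._tandem(sub)
                if child.is_leaf():
                    leaf_genomes[child.taxon.label] = sub
                else:
                    walk_diploid(child, sub)

        walk_diploid(self.tree.seed_node, genome0)

        # merged allotetraploid: subgenome A = PA gamete, B = PB gamete
        merged: list[_Chrom] = []
        for src, tag in ((leaf_genomes[self.pa], "A"), (leaf_genomes[self.pb], "B")):
            for chrom in src:
                genes = [replace(g, idx=g.idx.copy(), sub=tag) for g in chrom.genes]
                merged.append(_Chrom(chrom.index, genes))

        # crown height for distributing loss along branches
        depths = {}

        def depth(node):
            if node is self.merge_node:
                return 0.0
            return depth(node.parent_node) + (node.edge.length or 0.0)

        for lf in self.merge_node.leaf_iter():
            depths[lf.taxon.label] = depth(lf)
        H = max(depths.values()) if depths else 0.0
        loss_total = {"A": sc.loss_prob_dominant, "B": sc.loss_prob_recessive}

        tip_genomes: dict[str, list[_Chrom]] = {}
        gene_fates: dict[str, dict[str, str]] = {}

        def branch_loss(sub: str, length: float, terminal: bool) -> float:
            p = loss_total[sub]
            if p >= 1.0:
                return 1.0 if terminal else 0.0
            if H <= 0:
                return p if terminal else 0.0
            return 1.0 - (1.0 - p) ** (length / H)

        def walk_crown(node, genome, fates):
            for child in node.child_nodes():
                sub = _copy_genome(genome)
                sub_fates = dict(fates)
                length = child.edge.length or 0.0
                terminal = child.is_leaf()
                label = child.taxon.label if terminal else (child.label or "crown-internal")
                scalar = sc.rate_scalars.get(label, 1.0) if terminal else 1.0
                self._evolve_branch(sub, length * scalar, label)
                self._invert(sub)
                self._tandem(sub)
                self._lose(
                    sub,
                    {s: branch_loss(s, length, terminal) for s in ("A", "B")},
                    sub_fates,
                )
                if terminal:
                    tip_genomes[label] = sub
                    gene_fates[label] = sub_fates
                else:
                    walk_crown(child, sub, sub_fates)

        walk_crown(self.merge_node, merged, {})

        return self._emit(tip_genomes, leaf_genomes, gene_fates)

    # -- emission --------------------------------------------------------

    def _emit(self, tip_genomes, leaf_genomes, gene_fates) -> SimulatedDataset:
        sc = self.sc
        annotations: dict[str, GenomeAnnotation] = {}
        cds: dict[str, dict[str, str]] = {}
        origin: dict[str, str] = {}
        locus_of: dict[str, str] = {}

        def emit(tip: str, genome: list[_Chrom], polyploid: bool):
            genes, seqs = [], {}
            for chrom in genome:
                sub = chrom.genes[0].sub if chrom.genes else "A"
                chrom_name = (
                    f"{tip}_{sub}{chrom.index + 1}" if polyploid else f"{tip}_{chrom.index + 1}"
                )
                for rank, g in enumerate(chrom.genes):
                    gid = f"{tip}_{(g.sub or 'D')}{chrom.index + 1}g{g.locus.split('g', 1)[1]}"
                    start = rank * 1000 + 1
                    genes.append(
                        Gene(gid, chrom_name, start, start + 3 * len(g.idx) - 1, g.strand)
                    )
                    seqs[gid] = indices_to_seq(g.idx)
                    origin[gid] = g.sub
                    locus_of[gid] = g.locus.split(".t")[0]
            annotations[tip] = GenomeAnnotation.from_genes(tip, genes)
            cds[tip] = seqs

        for tip in self.crown_tips:
            # record fates of retained genes too
            for chrom in tip_genomes[tip]:
                for g in chrom.genes:
                    gene_fates[tip].setdefault(f"{g.sub}:{g.locus}", g.fate)
            emit(tip, tip_genomes[tip], polyploid=True)
        for tip in self.outgroups:
            gene_fates[tip] = {
                f":{g.locus}": g.fate for chrom in leaf_genomes[tip] for g in chrom.genes
            }
            emit(tip, leaf_genomes[tip], polyploid=False)

        pruned = self.tree.clone(depth=1)
        pruned.prune_taxa_with_labels([self.pa, self.pb])
        pruned.suppress_unifurcations()
        true_tree = pruned.as_string(schema="newick").strip()

        truth = SimulationTruth(
            true_tree=true_tree,
            crown_tips=self.crown_tips,
            outgroups=self.outgroups,
            subgenome_origin=origin,
            ancestral_locus=locus_of,
            gene_fates=gene_fates,
            rate_scalars=dict(sc.rate_scalars),
            realized_branch_ks={
                k: float(np.sum(v)) for k, v in self.realized.items()
            },
        )
        ds = SimulatedDataset(annotations, cds, truth)
        for donor, recipient, f in sc.introgression_events:
            ds = inject_introgression(ds, donor, recipient, f, seed=int(self.rng.integers(2**31)))
        if sc.scramble_ids:
            ds = scramble_dataset_ids(ds, seed=sc.seed)
        return ds


def simulate_clade(scenario: SimulationScenario) -> SimulatedDataset:
    """Run the full clade simulation; bit-reproducible for a fixed seed."""
    return _CladeSimulator(scenario).run()


def inject_introgression(
    dataset: SimulatedDataset, donor: str, recipient: str, f: float, seed: int
) -> SimulatedDataset:
    """Replace a Bernoulli(f) subset of recipient CDS by the donor ortholog's CDS.

    Gene order, chromosome assignment and presence/absence are untouched: only
    sequences move, emulating homogenizing gene flow. Orthology is resolved by
    ancestral locus (same-subgenome copy preferred when the donor is
    polyploid). Returns a new dataset; the input is not modified.
    """
    if donor not in dataset.annotations or recipient not in dataset.annotations:
        raise ValueError(f"unknown tip: {donor!r} or {recipient!r}")
    if not 0.0 <= f <= 1.0:
        raise ValueError("introgression fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    new_cds = {t: dict(s) for t, s in dataset.cds.items()}
    truth = copy.deepcopy(dataset.truth)
    moved: set[str] = set()
    # donor lookup: (locus, sub) and locus -> gene id
    donor_by_locus_sub: dict[tuple[str, str], str] = {}
    donor_by_locus: dict[str, str] = {}
    for gid in dataset.cds[donor]:
        loc = truth.ancestral_locus[gid]
        donor_by_locus_sub[(loc, truth.subgenome_origin[gid])] = gid
        donor_by_locus.setdefault(loc, gid)
    for gid in sorted(dataset.cds[recipient]):
        if f == 0.0 or rng.random() >= f:
            continue
        loc = truth.ancestral_locus[gid]
        src = donor_by_locus_sub.get((loc, truth.subgenome_origin[gid])) or donor_by_locus.get(loc)
        if src is None:
            continue  # no surviving donor ortholog
        new_cds[recipient][gid] = dataset.cds[donor][src]
        moved.add(gid)
    truth.introgressed[(donor, recipient)] = moved
    return SimulatedDataset(dataset.annotations, new_cds, truth)


def scramble_dataset_ids(dataset: SimulatedDataset, seed: int) -> SimulatedDataset:
    """Replace truth-encoding gene ids by opaque ones (truth keeps the map).

    Downstream inference must never read histories out of identifiers; tests
    run pipelines in this mode to enforce it.
    """
    rng = np.random.default_rng(seed + 777)
    all_ids = sorted(i for t in dataset.cds for i in dataset.cds[t])
    perm = rng.permutation(len(all_ids))
    mapping = {old: f"g{perm[k]:06d}" for k, old in enumerate(all_ids)}
    anns = {}
    for tip, ann in dataset.annotations.items():
        genes = [
            Gene(mapping[g.id], g.chrom, g.start, g.end, g.strand)
            for chrom in sorted(ann.chromosomes)
            for g in (ann.genes[i] for i in ann.chromosomes[chrom])
        ]
        anns[tip] = GenomeAnnotation.from_genes(tip, genes)
    cds = {tip: {mapping[g]: s for g, s in seqs.items()} for tip, seqs in dataset.cds.items()}
    truth = copy.deepcopy(dataset.truth)
    truth.subgenome_origin = {mapping[g]: v for g, v in truth.subgenome_origin.items()}
    truth.ancestral_locus = {mapping[g]: v for g, v in truth.ancestral_locus.items()}
    truth.introgressed = {
        k: {mapping[g] for g in v} for k, v in truth.introgressed.items()
    }
    truth.id_map = mapping
    return SimulatedDataset(anns, cds, truth)


# ------------------------------------------------- gene-family generator


def simulate_gene_families(
    n_families: int,
    history: str = "shared",
    ks_wgd: float = 0.4,
    ks_speciation: float = 0.12,
    ks_outgroup: float = 0.8,
    codon_length: int = 300,
    omega: float = 0.2,
    copy_loss_prob: float = 0.0,
    seed: int = 0,
) -> list[dict[str, str]]:
    """Gene families under a shared- or independent-WGD history.

    ``shared``: duplication precedes the R/S speciation, giving true topology
    (O,((R1,S1),(R2,S2))). ``independent``: speciation first, then one
    autopolyploidy in each lineage, giving (O,((R1,R2),(S1,S2))). Labels are
    R1/R2 (focal species copies), S1/S2 (other species) and O (outgroup).
    In both histories the deeper split sits at ``ks_wgd`` and the shallower
    at ``ks_speciation`` (for ``independent`` the deep split is the
    speciation and the shallow ones are the two autopolyploidies). With
    ``copy_loss_prob`` each non-outgroup copy is independently dropped
    (keeping >=1 per species), producing 2+1 and 1+2 family types.
    """
    if history not in {"shared", "independent"}:
        raise ValueError("history must be 'shared' or 'independent'")
    rng = np.random.default_rng(seed)
    half_spec = ks_speciation / 2.0
    inner = (ks_wgd - ks_speciation) / 2.0
    if inner < 0:
        raise ValueError("need ks_wgd > ks_speciation")
    out: list[dict[str, str]] = []
    for _ in range(n_families):
        root = random_cds(codon_length // 3, rng)
        stem, _ = evolve_cds(root, (ks_outgroup - ks_wgd) / 2.0, omega, rng)
        o_seq, _ = evolve_cds(root, ks_outgroup / 2.0, omega, rng)
        fam = {"O": indices_to_seq(o_seq)}
        if history == "shared":
            # duplication at the stem, speciation within each copy
            for copy_tag in ("1", "2"):
                dup, _ = evolve_cds(stem, inner, omega, rng)
                for sp in ("R", "S"):
                    tipseq, _ = evolve_cds(dup, half_spec, omega, rng)
                    fam[f"{sp}{copy_tag}"] = indices_to_seq(tipseq)
        else:
            # speciation at the stem, one autopolyploidy per lineage
            for sp in ("R", "S"):
                lineage, _ = evolve_cds(stem, inner, omega, rng)
                for copy_tag in ("1", "2"):
                    tipseq, _ = evolve_cds(lineage, half_spec, omega, rng)
                    fam[f"{sp}{copy_tag}"] = indices_to_seq(tipseq)
        if copy_loss_prob > 0:
            for sp in ("R", "S"):
                keep = [t for t in ("1", "2") if rng.random() >= copy_loss_prob]
                if not keep:
                    keep = [rng.choice(["1", "2"])]
                for t in ("1", "2"):
                    if t not in keep:
                        del fam[f"{sp}{t}"]
        out.append(fam)
    return out
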