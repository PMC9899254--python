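"""Shared- vs independent-WGD tests.

Two complementary lines of evidence decide whether a polyploidy event
predates the divergence of two species:

* gene-family tree topologies: families with up to two copies per species
  and one outgroup copy are classified by whether the duplication-induced
  cherries mix the two species (shared WGD) or keep them separate
  (independent WGDs);
* the intergenomic Ks contrast: if the WGD is shared, homoeologous
  (paralogous) collinear blocks between the two genomes are older than
  orthologous blocks, so block-median Ks values split into two components.

Gene trees for simulated families are built in-repo: neighbor joining on
NG86 Ks distances with codon-column bootstrap support.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
from scipy import stats

from ._codon import codon_indices, ng86_tables
from .structphylo import UnrootedTree, _nj_adjacency

_JC_LIMIT = 0.75


def _ks_from_indices(ia: np.ndarray, ib: np.ndarray) -> float:
    """Fast NG86 Ks for codon-index arrays; raw proportion when saturated."""
    S, _, SD, _ = ng86_tables()
    s_sites = (S[ia].sum() + S[ib].sum()) / 2.0
    if s_sites <= 0:
        return 0.0
    ps = SD[ia, ib].sum() / s_sites
    if ps >= _JC_LIMIT:
        return float(ps)
    return float(-0.75 * np.log(1.0 - 4.0 * ps / 3.0))


def ks_distance_matrix(indexed: dict[str, np.ndarray], cols=None) -> np.ndarray:
    labels = sorted(indexed)
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ia, ib = indexed[labels[i]], indexed[labels[j]]
            if cols is not None:
                ia, ib = ia[cols], ib[cols]
            d[i, j] = d[j, i] = _ks_from_indices(ia, ib)
    return d


def _rooted_newick(topo: UnrootedTree, supports, outgroup: str) -> str:
    """Root the unrooted gene tree on the (single) outgroup leaf, writing
    bootstrap supports as internal-node labels."""
    o = topo.leaves.index(outgroup)
    (start,) = topo.adj[o]
    all_leaves = set(topo.leaves)

    def rec(node, parent):
        if node < len(topo.leaves):
            return topo.leaves[node]
        kids = [c for c in topo.adj[node] if c != parent]
        inner = ",".join(rec(c, node) for c in sorted(kids))
        side = frozenset(
            topo.leaves[i] for i in topo._side(parent, node) if i < len(topo.leaves)
        )
        norm = side if topo.leaves[0] in (all_leaves - side) else frozenset(all_leaves - side)
        sup = supports.get(norm)
        return f"({inner}){'' if sup is None else f'{sup:.0f}'}"

    return f"({outgroup},{rec(start, o)});"


def build_gene_tree(
    seqs: dict[str, str],
    outgroup: str,
    n_bootstrap: int = 100,
    seed: int = 0,
) -> dendropy.Tree:
    """NJ gene tree on NG86 Ks distances, rooted on the outgroup copy.

    Support values (percent of ``n_bootstrap`` codon-column resamples
    containing each split of the main tree) are written as internal node
    labels.
    """
    if outgroup not in seqs:
        raise ValueError(f"outgroup {outgroup!r} not among sequences")
    labels = sorted(seqs)
    indexed = {k: codon_indices(v) for k, v in seqs.items()}
    n_codons = len(next(iter(indexed.values())))
    topo, _ = _nj_adjacency(ks_distance_matrix(indexed), labels)
    supports: dict[frozenset[str], float] = {}
    if n_bootstrap > 0 and len(labels) >= 4:
        rng = np.random.default_rng(seed)
        counts = {s: 0 for s in topo.splits()}
        for _ in range(n_bootstrap):
            cols = rng.integers(n_codons, size=n_codons)
            btopo, _ = _nj_adjacency(ks_distance_matrix(indexed, cols), labels)
            for s in btopo.splits():
                if s in counts:
                    counts[s] += 1
        supports = {s: 100.0 * c / n_bootstrap for s, c in counts.items()}
    return dendropy.Tree.get(data=_rooted_newick(topo, supports, outgroup), schema="newick")


# ------------------------------------------------------------- topology


@dataclass
class TopologyVerdict:
    family_id: str
    verdict: str  # 'shared' | 'independent' | 'uninformative'
    family_type: int  # 1: 2+2 copies, 2: 2+1, 3: 1+2
    min_support: float | None  # on the decisive bipartition(s)


def classify_family_topology(
    tree: dendropy.Tree,
    focal_labels: set[str] | list[str],
    other_labels: set[str] | list[str],
    outgroup_label: str,
    support_threshold: float = 80.0,
    family_id: str = "",
) -> TopologyVerdict:
    """Classify one rooted gene-family tree as shared/independent WGD.

    With F = focal-species copies and T = other-species copies, the
    duplication is *shared* when every resolved cherry below the root mixes
    the species ((F,T) pairs) and *independent* when cherries are
    species-pure. Decisive-cherry support below ``support_threshold``,
    multifurcations, and shapes outside the six canonical topologies are
    uninformative. Missing support labels are treated as fully supported.
    """
    focal = set(focal_labels)
    other = set(other_labels)
    leaf_labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    if outgroup_label not in leaf_labels:
        raise ValueError("outgroup copy missing from tree")
    nf, nt = len(focal & leaf_labels), len(other & leaf_labels)
    if nf not in (1, 2) or nt not in (1, 2) or nf + nt < 3:
        raise ValueError(f"copy counts outside supported range: focal={nf}, other={nt}")
    family_type = 1 if (nf, nt) == (2, 2) else 2 if (nf, nt) == (2, 1) else 3

    work = tree.clone(depth=1)
    out_leaf = next(
        lf for lf in work.leaf_node_iter() if lf.taxon.label == outgroup_label
    )
    root_kids = work.seed_node.child_nodes()
    if out_leaf.parent_node is not work.seed_node or len(root_kids) != 2:
        work.reroot_at_edge(out_leaf.edge, update_bipartitions=False)
        root_kids = work.seed_node.child_nodes()
    ingroup_roots = [c for c in root_kids if c is not out_leaf]
    if len(ingroup_roots) != 1:
        return TopologyVerdict(family_id, "uninformative", family_type, None)
    ingroup = ingroup_roots[0]

    def cat(label: str) -> str:
        return "F" if label in focal else "T"

    def support_of(node) -> float | None:
        if node.label is None or node.label == "":
            return None
        try:
            return float(node.label)
        except ValueError:
            return None

    # collect resolved cherries (internal nodes with exactly two leaf children)
    verdict = None
    decisive_supports: list[float] = []

    def classify_cherry(node) -> str | None:
        kids = node.child_nodes()
        if len(kids) != 2 or not all(k.is_leaf() for k in kids):
            return None
        cats = sorted(cat(k.taxon.label) for k in kids)
        return "mixed" if cats == ["F", "T"] else "pure"

    kids = ingroup.child_nodes()
    if family_type == 1:
        if len(kids) != 2 or any(k.is_leaf() for k in kids):
            return TopologyVerdict(family_id, "uninformative", family_type, None)
        kinds = [classify_cherry(k) for k in kids]
        if None in kinds:
            return TopologyVerdict(family_id, "uninformative", family_type, None)
        for k in kids:
            s = support_of(k)
            if s is not None:
                decisive_supports.append(s)
        if kinds == ["mixed", "mixed"]:
            verdict = "shared"
        elif kinds == ["pure", "pure"]:
            verdict = "independent"
        else:
            verdict = "uninformative"
    else:
        # three ingroup leaves: shape (leaf, cherry)
        if len(kids) != 2:
            return TopologyVerdict(family_id, "uninformative", family_type, None)
        cherry = next((k for k in kids if not k.is_leaf()), None)
        if cherry is None or classify_cherry(cherry) is None:
            return TopologyVerdict(family_id, "uninformative", family_type, None)
        s = support_of(cherry)
        if s is not None:
            decisive_supports.append(s)
        kind = classify_cherry(cherry)
        verdict = "shared" if kind == "mixed" else "independent"

    min_sup = min(decisive_supports) if decisive_supports else None
    if min_sup is not None and min_sup < support_threshold:
        verdict = "uninformative"
    return TopologyVerdict(family_id, verdict, family_type, min_sup)


@dataclass
class TopologyTally:
    n_shared: int
    n_independent: int
    n_uninformative: int

    @property
    def n_informative(self) -> int:
        return self.n_shared + self.n_independent

    @property
    def shared_fraction(self) -> float | None:
        if self.n_informative == 0:
            return None
        return self.n_shared / self.n_informative

    @property
    def independent_fraction(self) -> float | None:
        if self.n_informative == 0:
            return None
        return self.n_independent / self.n_informative


def tally_topologies(verdicts: list[TopologyVerdict]) -> TopologyTally:
    if not verdicts:
        raise ValueError("no verdicts to tally")
    return TopologyTally(
        n_shared=sum(v.verdict == "shared" for v in verdicts),
        n_independent=sum(v.verdict == "independent" for v in verdicts),
        n_uninformative=sum(v.verdict == "uninformative" for v in verdicts),
    )


# -------------------------------------------------------- Ks contrast


@dataclass
class ContrastResult:
    lower_mean: float
    upper_mean: float
    assignment: np.ndarray  # 0 = lower (ortholog) component, 1 = upper (paralog)
    pvalue: float | None
    verdict: str  # 'shared' | 'inconclusive'


def _split_1d(values: np.ndarray) -> int:
    """Optimal two-component split of sorted 1-D values (min within-SSE)."""
    best_k, best_sse = 1, np.inf
    for k in range(1, len(values)):
        lo, hi = values[:k], values[k:]
        sse = ((lo - lo.mean()) ** 2).sum() + ((hi - hi.mean()) ** 2).sum()
        if sse < best_sse - 1e-15:
            best_sse, best_k = sse, k
    return best_k


def ortholog_paralog_contrast(
    block_medians, alpha: float = 0.05, min_blocks: int = 10
) -> ContrastResult:
    """Split intergenomic block-median Ks into ortholog vs paralog components.

    A shared WGD shows as a clear bimodality: the lower component collects
    orthologous blocks (divergence at speciation) and the upper component
    paralogous/homoeologous blocks (divergence at the parental split). A
    two-sided rank-sum test between the components backs the verdict.
    """
    x = np.asarray(list(block_medians), dtype=float)
    if x.size < min_blocks:
        raise ValueError(f"need >= {min_blocks} blocks, got {x.size}")
    order = np.argsort(x)
    xs = x[order]
    if np.ptp(xs) == 0:
        return ContrastResult(float(xs[0]), float(xs[0]), np.zeros(x.size, int), None, "inconclusive")
    k = _split_1d(xs)
    assign = np.zeros(x.size, dtype=int)
    assign[order[k:]] = 1
    lo, hi = xs[:k], xs[k:]
    if min(len(lo), len(hi)) < 3:
        return ContrastResult(float(lo.mean()), float(hi.mean()), assign, None, "inconclusive")
    p = float(stats.mannwhitneyu(lo, hi, alternative="two-sided").pvalue)
    verdict = "shared" if p < alpha and hi.mean() > lo.mean() else "inconclusive"
    return ContrastResult(float(lo.mean()), float(hi.mean()), assign, p, verdict)
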