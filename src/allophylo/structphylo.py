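"""Phylogenies from genome structure: synteny clusters, binary matrices,
parsimony / binary-Mk / neighbor-joining trees, and the quartet-concordance
test for gene-tree discord.

The presence/absence workflow mirrors the microsynteny approach: collinear
genes form a network, community detection yields synteny clusters, clusters
become binary characters over (sub)genomes, and a tree is inferred from the
matrix. Fitch parsimony with NNI hill-climbing (exhaustive for <=8 taxa) and
a simplified two-state Mk likelihood (estimated state frequencies, discrete
gamma rates, one shared branch length) are the in-repo tree criteria.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import dendropy
import networkx as nx
import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import gammaincinv
from statsmodels.stats.multitest import multipletests

# ------------------------------------------------------------- clustering


def cluster_synteny_network(
    network: nx.Graph, n_trials: int = 10, seed: int = 0
) -> list[set[str]]:
    """Partition the synteny network into clusters of collinear genes.

    Per connected component: cliques become single clusters outright; other
    components are split by seeded asynchronous label propagation, keeping
    the best-modularity partition over ``n_trials`` runs. Deterministic for a
    fixed seed. Clusters are returned sorted by their smallest member id.
    """
    if network.number_of_nodes() == 0:
        return []
    rng = np.random.default_rng(seed)
    clusters: list[set[str]] = []
    for comp in nx.connected_components(network):
        comp = sorted(comp)
        n = len(comp)
        sub = nx.Graph()
        sub.add_nodes_from(comp)
        sub.add_edges_from(
            sorted((min(u, v), max(u, v)) for u, v in network.subgraph(comp).edges())
        )
        if n <= 2 or sub.number_of_edges() == n * (n - 1) // 2:
            clusters.append(set(comp))
            continue
        best, best_q = None, -np.inf
        for _ in range(max(1, n_trials)):
            part = [
                set(c)
                for c in nx.community.asyn_lpa_communities(
                    sub, seed=int(rng.integers(2**31))
                )
            ]
            q = nx.community.modularity(sub, part)
            if q > best_q:
                best, best_q = part, q
        clusters.extend(best)
    return sorted(clusters, key=lambda c: min(c))


def build_matrix(
    clusters: list[set[str]] | list,
    gene_to_taxon: dict[str, str],
    taxa: list[str] | None = None,
) -> pd.DataFrame:
    """Binary taxa x cluster presence/absence matrix.

    ``clusters`` may be gene-id sets (synteny clusters) or objects with a
    ``genes`` attribute (orthogroups). Columns present in exactly one taxon
    are removed (uninformative for shared structure); all-zero rows are
    dropped. Column order is deterministic: by smallest member gene id.
    """
    col_sets = []
    for c in clusters:
        genes = c if isinstance(c, (set, frozenset, list, tuple)) else c.genes
        genes = sorted(genes)
        for g in genes:
            if g not in gene_to_taxon:
                raise KeyError(f"gene {g!r} not mapped to a taxon")
        col_sets.append((min(genes), sorted({gene_to_taxon[g] for g in genes})))
    col_sets.sort(key=lambda t: t[0])
    if taxa is None:
        taxa = sorted({t for _, ts in col_sets for t in ts})
    data = {}
    for key, ts in col_sets:
        if len(ts) <= 1:
            continue
        data[key] = [1 if t in ts else 0 for t in taxa]
    mat = pd.DataFrame(data, index=taxa, dtype=np.int8)
    mat = mat.loc[mat.sum(axis=1) > 0]
    return mat


# ------------------------------------------------------- tree containers


class UnrootedTree:
    """Lightweight unrooted binary tree over indexed leaves.

    Leaves are nodes 0..n-1 (labels in ``self.leaves``); internal nodes get
    higher ids. The adjacency map is the single source of truth.
    """

    def __init__(self, leaves: list[str]):
        self.leaves = list(leaves)
        self.adj: dict[int, set[int]] = {}
        self._next = len(leaves)

    def copy(self) -> "UnrootedTree":
        t = UnrootedTree(self.leaves)
        t.adj = {k: set(v) for k, v in self.adj.items()}
        t._next = self._next
        return t

    def new_node(self) -> int:
        nid = self._next
        self._next += 1
        self.adj[nid] = set()
        return nid

    def add_edge(self, u: int, v: int) -> None:
        self.adj.setdefault(u, set()).add(v)
        self.adj.setdefault(v, set()).add(u)

    def remove_edge(self, u: int, v: int) -> None:
        self.adj[u].discard(v)
        self.adj[v].discard(u)

    # -- construction ---------------------------------------------------

    @classmethod
    def star(cls, leaves: list[str]) -> "UnrootedTree":
        t = cls(leaves)
        hub = t.new_node()
        for i in range(len(leaves)):
            t.add_edge(i, hub)
        return t

    @classmethod
    def from_triple(cls, leaves: list[str]) -> "UnrootedTree":
        return cls.star(leaves[:3]) if len(leaves) == 3 else cls.star(leaves)

    def internal_edges(self) -> list[tuple[int, int]]:
        n = len(self.leaves)
        return sorted(
            (min(u, v), max(u, v))
            for u in self.adj
            for v in self.adj[u]
            if u >= n and v >= n and u < v
        )

    def splits(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions, each as the side not containing leaf 0."""
        out = set()
        for u, v in self.internal_edges():
            side = self._side(u, v)
            labels = frozenset(self.leaves[i] for i in side if i < len(self.leaves))
            if 1 < len(labels) < len(self.leaves) - 1:
                if self.leaves[0] in labels:
                    labels = frozenset(set(self.leaves) - labels)
                out.add(labels)
        return out

    def _side(self, u: int, v: int) -> set[int]:
        """Nodes on v's side of edge (u, v)."""
        seen = {u, v}
        stack = [v]
        while stack:
            x = stack.pop()
            for y in self.adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        return seen - {u}

    def to_newick(self, lengths: dict[tuple[int, int], float] | None = None) -> str:
        n = len(self.leaves)
        root = next(i for i in self.adj if i >= n)

        def blen(u, v):
            if lengths is None:
                return ""
            return f":{lengths[(min(u, v), max(u, v))]:.6g}"

        def rec(node, parent):
            children = [c for c in self.adj[node] if c != parent]
            if not children:
                return self.leaves[node]
            inner = ",".join(rec(c, node) + blen(c, node) for c in sorted(children))
            return f"({inner})"

        return rec(root, None) + ";"

    def to_dendropy(
        self, taxon_namespace=None, support: dict[frozenset[str], float] | None = None
    ) -> dendropy.Tree:
        tree = dendropy.Tree.get(
            data=self.to_newick(), schema="newick", taxon_namespace=taxon_namespace
        )
        if support:
            tree.encode_bipartitions()
            for node in tree.preorder_internal_node_iter():
                labels = frozenset(lf.taxon.label for lf in node.leaf_iter())
                if self.leaves[0] in labels:
                    labels = frozenset(set(self.leaves) - labels)
                if labels in support:
                    node.label = f"{support[labels]:.0f}"
        return tree


def _enumerate_topologies(leaves: list[str]):
    """All unrooted binary topologies (1*3*5*...*(2n-5) of them)."""
    n = len(leaves)
    base = UnrootedTree(leaves)
    hub = base.new_node()
    for i in range(3):
        base.add_edge(i, hub)

    def grow(tree: UnrootedTree, k: int):
        if k == n:
            yield tree
            return
        edges = sorted(
            (min(u, v), max(u, v)) for u in tree.adj for v in tree.adj[u] if u < v
        )
        for u, v in edges:
            t = tree.copy()
            t.remove_edge(u, v)
            mid = t.new_node()
            t.add_edge(u, mid)
            t.add_edge(v, mid)
            t.add_edge(k, mid)
            yield from grow(t, k + 1)

    if n == 3:
        yield base
    else:
        yield from grow(base, 3)


# --------------------------------------------------------------- parsimony


def _fitch_score(tree: UnrootedTree, states: np.ndarray) -> int:
    """Total Fitch parsimony length over all columns.

    ``states``: (n_leaves, n_cols) uint8 bitmasks (state 0 -> 1, state 1 -> 2).
    """
    n = len(tree.leaves)
    root_leaf = 0
    start = next(iter(tree.adj[root_leaf]))
    cost = np.zeros(states.shape[1], dtype=np.int64)

    def down(node, parent):
        if node < n:
            return states[node]
        acc = None
        for child in tree.adj[node]:
            if child == parent:
                continue
            s = down(child, node)
            if acc is None:
                acc = s
            else:
                inter = acc & s
                union = acc | s
                miss = inter == 0
                cost[miss] += 1
                acc = np.where(miss, union, inter)
        return acc

    acc = down(start, root_leaf)
    inter = acc & states[root_leaf]
    cost[inter == 0] += 1
    return int(cost.sum())


def _states_from_matrix(matrix: pd.DataFrame) -> np.ndarray:
    vals = matrix.to_numpy(dtype=np.int8)
    return np.where(vals == 0, 1, 2).astype(np.uint8)


def _nni_neighbours(tree: UnrootedTree):
    for u, v in tree.internal_edges():
        au = sorted(tree.adj[u] - {v})
        av = sorted(tree.adj[v] - {u})
        # two alternative arrangements per internal edge
        for b, c in ((au[1], av[0]), (au[1], av[1])):
            t = tree.copy()
            t.remove_edge(u, b)
            t.remove_edge(v, c)
            t.add_edge(u, c)
            t.add_edge(v, b)
            yield t


def _hill_climb(tree: UnrootedTree, score_fn) -> tuple[UnrootedTree, float]:
    best, best_s = tree, score_fn(tree)
    improved = True
    while improved:
        improved = False
        for cand in _nni_neighbours(best):
            s = score_fn(cand)
            if s < best_s:
                best, best_s = cand, s
                improved = True
                break
    return best, best_s


def _nj_adjacency(
    dist: np.ndarray, labels: list[str]
) -> tuple["UnrootedTree", dict[tuple[int, int], float]]:
    """Classic neighbor-joining. Returns (topology, edge length map)."""
    n = len(labels)
    tree = UnrootedTree(labels)
    lengths: dict[tuple[int, int], float] = {}

    def set_len(u, v, val):
        lengths[(min(u, v), max(u, v))] = float(val)

    if n == 2:
        hub = tree.new_node()
        tree.add_edge(0, hub)
        tree.add_edge(1, hub)
        set_len(0, hub, dist[0, 1] / 2)
        set_len(1, hub, dist[0, 1] / 2)
        return tree, lengths
    active = list(range(n))
    d = {(i, j): float(dist[i, j]) for i in range(n) for j in range(n) if i != j}
    node_ids = {i: i for i in range(n)}
    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[(i, j)] for j in active if j != i) for i in active}
        qbest, pair = None, None
        for i, j in itertools.combinations(active, 2):
            q = (m - 2) * d[(i, j)] - r[i] - r[j]
            if qbest is None or q < qbest - 1e-12:
                qbest, pair = q, (i, j)
        i, j = pair
        new = max(node_ids) + 1
        nid = tree.new_node()
        node_ids[new] = nid
        tree.add_edge(node_ids[i], nid)
        tree.add_edge(node_ids[j], nid)
        li = 0.5 * d[(i, j)] + (r[i] - r[j]) / (2.0 * (m - 2))
        set_len(node_ids[i], nid, li)
        set_len(node_ids[j], nid, d[(i, j)] - li)
        for k in active:
            if k in (i, j):
                continue
            d[(new, k)] = d[(k, new)] = 0.5 * (d[(i, k)] + d[(j, k)] - d[(i, j)])
        active = [k for k in active if k not in (i, j)] + [new]
    hub = tree.new_node()
    a, b, c = active
    for k in active:
        tree.add_edge(node_ids[k], hub)
    set_len(node_ids[a], hub, (d[(a, b)] + d[(a, c)] - d[(b, c)]) / 2)
    set_len(node_ids[b], hub, (d[(a, b)] + d[(b, c)] - d[(a, c)]) / 2)
    set_len(node_ids[c], hub, (d[(a, c)] + d[(b, c)] - d[(a, b)]) / 2)
    return tree, lengths


@dataclass
class TreeResult:
    tree: dendropy.Tree
    score: float
    method: str
    tie: bool = False
    support: dict[frozenset[str], float] = field(default_factory=dict)
    topology: "UnrootedTree | None" = None


def _search(matrix: pd.DataFrame, score_fn, exhaustive_max: int = 8):
    taxa = list(matrix.index)
    n = len(taxa)
    if n <= exhaustive_max:
        best, best_s, tie = None, None, False
        for topo in _enumerate_topologies(taxa):
            s = score_fn(topo)
            if best_s is None or s < best_s - 1e-12:
                best, best_s, tie = topo, s, False
            elif abs(s - best_s) <= 1e-12:
                tie = True
        return best, best_s, tie
    vals = matrix.to_numpy(dtype=float)
    ham = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ham[i, j] = ham[j, i] = float(np.mean(vals[i] != vals[j]))
    start, _ = _nj_adjacency(ham, taxa)
    best, best_s = _hill_climb(start, score_fn)
    return best, best_s, False


def infer_binary_tree(
    matrix: pd.DataFrame,
    method: str = "parsimony",
    seed: int = 0,
    n_bootstrap: int = 100,
) -> TreeResult:
    """Tree from a binary presence/absence matrix.

    ``parsimony``: Fitch length, exhaustive for <=8 taxa, NNI hill-climbing
    from an NJ (Hamming) start otherwise. ``mk_ml``: simplified two-state Mk
    likelihood (see :func:`mk_log_likelihood`). Support values come from
    ``n_bootstrap`` column resamples (majority-rule percentages mapped onto
    the best tree's splits).
    """
    if matrix.shape[0] < 4:
        raise ValueError("need >= 4 taxa")
    if matrix.shape[1] < 1:
        raise ValueError("need >= 1 column")
    if method not in {"parsimony", "mk_ml"}:
        raise ValueError(f"unknown method {method!r}")

    def make_score_fn(mat):
        if method == "parsimony":
            states = _states_from_matrix(mat)
            return lambda t: float(_fitch_score(t, states))
        vals = mat.to_numpy(dtype=np.int8)
        return lambda t: -mk_log_likelihood(t, vals)

    # the Mk criterion re-optimizes two parameters per topology; keep the
    # exhaustive sweep to sizes where that is affordable
    exhaustive_max = 8 if method == "parsimony" else 5
    best, best_s, tie = _search(matrix, make_score_fn(matrix), exhaustive_max)
    support: dict[frozenset[str], float] = {}
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        target = best.splits()
        counts = {s: 0 for s in target}
        for _ in range(n_bootstrap):
            cols = rng.integers(matrix.shape[1], size=matrix.shape[1])
            bmat = matrix.iloc[:, cols]
            btree, _, _ = _search(bmat, make_score_fn(bmat), exhaustive_max)
            for s in btree.splits():
                if s in counts:
                    counts[s] += 1
        support = {s: 100.0 * c / n_bootstrap for s, c in counts.items()}
    return TreeResult(
        tree=best.to_dendropy(support=support or None),
        score=best_s,
        method=method,
        tie=tie,
        support=support,
        topology=best,
    )


# ----------------------------------------------------------- Mk likelihood


def mk_log_likelihood(
    tree: UnrootedTree,
    data01: np.ndarray,
    n_rate_categories: int = 4,
) -> float:
    """Simplified binary-Mk log-likelihood of a topology.

    State frequencies are estimated from the observed 0/1 proportions,
    discrete-gamma rate heterogeneity uses category means at a profiled
    shape, and all branches share a single length; the shared length and the
    gamma shape are optimized numerically. A deliberate simplification of a
    full Mk+R+FO fit: adequate for ranking topologies on desk-scale matrices.
    """
    pi1 = float(np.clip(data01.mean(), 0.05, 0.95))
    pi = np.array([1 - pi1, pi1])
    n = data01.shape[0]

    def site_likelihoods(t_len, alpha):
        rates = _gamma_category_rates(alpha, n_rate_categories)
        total = np.zeros(data01.shape[1])
        for r in rates:
            total += _prune_binary(tree, data01, pi, t_len * r)
        return total / n_rate_categories

    def neg_ll(params):
        t_len, alpha = np.exp(params)
        lik = site_likelihoods(t_len, alpha)
        if np.any(lik <= 0):
            return 1e12
        return -float(np.log(lik).sum())

    res = optimize.minimize(
        neg_ll, x0=np.log([0.5, 1.0]), method="Nelder-Mead",
        options={"xatol": 1e-3, "fatol": 1e-6, "maxiter": 200},
    )
    return -float(res.fun)


def _gamma_category_rates(alpha: float, k: int) -> np.ndarray:
    # category medians of Gamma(alpha, 1/alpha), normalized to mean 1
    qs = (np.arange(k) + 0.5) / k
    rates = gammaincinv(alpha, qs) / alpha
    return rates / rates.mean()


def _prune_binary(tree: UnrootedTree, data01, pi, t_len) -> np.ndarray:
    """Felsenstein pruning for the 2-state stationary model, equal branches.

    Branch length is in expected substitutions per site; for the stationary
    binary chain P(t) = pi_j + (delta_ij - pi_j) exp(-t / (2 pi_0 pi_1)).
    """
    e = np.exp(-t_len / (2.0 * pi[0] * pi[1]))
    P = np.empty((2, 2))
    for i in range(2):
        for j in range(2):
            P[i, j] = pi[j] + (np.eye(2)[i, j] - pi[j]) * e
    n = len(tree.leaves)
    root_leaf = 0
    start = next(iter(tree.adj[root_leaf]))

    def down(node, parent):
        if node < n:
            L = np.zeros((data01.shape[1], 2))
            L[np.arange(data01.shape[1]), data01[node]] = 1.0
            return L @ P.T  # conditional at the parent end of the branch
        acc = np.ones((data01.shape[1], 2))
        for child in tree.adj[node]:
            if child == parent:
                continue
            acc *= down(child, node)
        return acc @ P.T

    # assemble at `start`, then connect the root leaf
    acc = np.ones((data01.shape[1], 2))
    for child in tree.adj[start]:
        if child == root_leaf:
            continue
        acc *= down(child, start)
    leafL = np.zeros((data01.shape[1], 2))
    leafL[np.arange(data01.shape[1]), data01[root_leaf]] = 1.0
    acc *= leafL @ P.T
    return acc @ pi


# ------------------------------------------------------------------- NJ


def nj_tree(distance: pd.DataFrame) -> tuple[dendropy.Tree, bool]:
    """Neighbor-joining tree from a symmetric zero-diagonal distance matrix.

    Returns (tree, clamped); ``clamped`` flags negative estimated branch
    lengths, which are clamped to zero in the emitted tree.
    """
    labels = list(distance.index)
    if len(labels) < 4:
        raise ValueError("need >= 4 taxa")
    d = distance.to_numpy(dtype=float)
    if not np.allclose(d, d.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-9):
        raise ValueError("distance matrix must have a zero diagonal")
    topo, lengths = _nj_adjacency(d, labels)
    clamped = any(v < 0 for v in lengths.values())
    lengths = {k: max(0.0, v) for k, v in lengths.items()}
    tree = dendropy.Tree.get(data=topo.to_newick(lengths), schema="newick")
    return tree, clamped


# ------------------------------------------------------------ RF distance


def _tree_splits(tree: dendropy.Tree) -> tuple[set[frozenset[str]], list[str]]:
    leaves = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    anchor = leaves[0]
    out = set()
    for node in tree.preorder_internal_node_iter():
        labels = frozenset(lf.taxon.label for lf in node.leaf_iter())
        side = labels if anchor not in labels else frozenset(set(leaves) - labels)
        if 1 < len(side) < len(leaves) - 1:
            out.add(side)
    return out, leaves


def rf_distance(tree_a: dendropy.Tree, tree_b: dendropy.Tree) -> int:
    """Robinson–Foulds distance: symmetric difference of non-trivial splits."""
    sa, la = _tree_splits(tree_a)
    sb, lb = _tree_splits(tree_b)
    if la != lb:
        raise ValueError("trees have different leaf sets")
    return len(sa ^ sb)


# ----------------------------------------------------------- quartet test


@dataclass
class QuartetResult:
    taxa: tuple[str, str, str, str]
    counts: tuple[int, int, int]  # (t0t1|t2t3, t0t2|t1t3, t0t3|t1t2)
    raw_p: float
    adj_p: float = float("nan")
    reject: bool = False


def quartet_topology(tree: dendropy.Tree, quartet: tuple[str, ...]) -> int | None:
    """Index of the resolved quartet topology induced by ``tree`` (or None)."""
    qset = set(quartet)
    t0 = quartet[0]
    for node in tree.preorder_internal_node_iter():
        labels = {lf.taxon.label for lf in node.leaf_iter()} & qset
        if len(labels) == 2:
            pairings = (
                {t0, quartet[1]}, {t0, quartet[2]}, {t0, quartet[3]},
            )
            other = qset - labels
            for idx, p in enumerate(pairings):
                if labels == p or other == p:
                    return idx
    return None


def quartet_concordance_test(
    gene_trees: list[dendropy.Tree] | None = None,
    counts: dict[tuple[str, ...], tuple[int, int, int]] | None = None,
    alpha: float = 0.05,
    min_informative: int = 10,
) -> list[QuartetResult]:
    """Test MSC concordance per species quartet, Holm–Bonferroni corrected.

    Under the multispecies coalescent the two minor quartet topologies are
    equally frequent; a two-sided exact binomial test on the two non-dominant
    counts flags quartets whose discord is too lopsided for incomplete
    lineage sorting alone (the signature of gene flow).
    """
    if counts is None:
        if not gene_trees:
            raise ValueError("provide gene_trees or counts")
        taxa = sorted(
            {lf.taxon.label for t in gene_trees for lf in t.leaf_node_iter()}
        )
        counts = {}
        for quartet in itertools.combinations(taxa, 4):
            tally = [0, 0, 0]
            for t in gene_trees:
                tree_taxa = {lf.taxon.label for lf in t.leaf_node_iter()}
                if not set(quartet) <= tree_taxa:
                    continue
                idx = quartet_topology(t, quartet)
                if idx is not None:
                    tally[idx] += 1
            counts[quartet] = tuple(tally)
    results = []
    for quartet in sorted(counts):
        tally = counts[quartet]
        total = sum(tally)
        if total < min_informative:
            continue
        minor = sorted(tally)[:2]
        if sum(minor) == 0:
            p = 1.0
        else:
            p = float(stats.binomtest(minor[0], sum(minor), 0.5).pvalue)
        results.append(QuartetResult(tuple(quartet), tuple(tally), p))
    if results:
        reject, adj, _, _ = multipletests(
            [r.raw_p for r in results], alpha=alpha, method="holm"
        )
        for r, rj, ap in zip(results, reject, adj):
            r.adj_p = float(ap)
            r.reject = bool(rj)
    return results


def holm_bonferroni(pvalues, alpha: float = 0.05) -> tuple[list[bool], list[float]]:
    """Holm–Bonferroni family-wise correction (wrapper, kept for re-use)."""
    reject, adj, _, _ = multipletests(list(pvalues), alpha=alpha, method="holm")
    return [bool(b) for b in reject], [float(a) for a in adj]


# ----------------------------------------------------------------- IO


def write_matrix(matrix: pd.DataFrame, path_phylip, path_csv=None) -> None:
    """Relaxed-PHYLIP (0/1 symbols) and optional CSV export."""
    with open(path_phylip, "w") as fh:
        fh.write(f"{matrix.shape[0]} {matrix.shape[1]}\n")
        for taxon, row in matrix.iterrows():
            fh.write(f"{taxon}  {''.join(str(int(v)) for v in row.to_numpy())}\n")
    if path_csv is not None:
        matrix.to_csv(path_csv)


def read_matrix_phylip(path) -> pd.DataFrame:
    lines = [ln for ln in open(path).read().splitlines() if ln.strip()]
    n, m = (int(x) for x in lines[0].split())
    taxa, rows = [], []
    for ln in lines[1 : n + 1]:
        name, chars = ln.split(None, 1)
        taxa.append(name)
        rows.append([int(c) for c in chars.strip()])
    return pd.DataFrame(rows, index=taxa, dtype=np.int8)
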