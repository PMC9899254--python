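"""Independent reference implementations used only by the test suite.

Each oracle is a deliberately separate transcription of the underlying
definition (different code structure, no shared helpers with the package) so
that agreement is evidence of correctness rather than duplication.
"""

from __future__ import annotations

import itertools
import math

# ------------------------------------------------------------ codon basics

_BASES = "TCAG"
_CODON_AA = {}


def _build_code():
    # standard genetic code written out as the classical 4x4x4 table
    aas = (
        "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
    )
    i = 0
    for b1 in _BASES:
        for b2 in _BASES:
            for b3 in _BASES:
                _CODON_AA[b1 + b2 + b3] = aas[i]
                i += 1


_build_code()


def _aa(codon: str) -> str:
    return _CODON_AA[codon]


def ng86_sites(codon: str) -> tuple[float, float]:
    """Synonymous/nonsynonymous site fractions of one codon (stops excluded
    from the viable-change denominator)."""
    syn = 0.0
    non = 0.0
    for pos in range(3):
        alts = [codon[:pos] + b + codon[pos + 1 :] for b in _BASES if b != codon[pos]]
        alts = [a for a in alts if _aa(a) != "*"]
        if not alts:
            continue
        s = sum(1 for a in alts if _aa(a) == _aa(codon)) / len(alts)
        syn += s
        non += 1 - s
    return syn, non


def ng86_pair_diffs(c1: str, c2: str) -> tuple[float, float]:
    """Pathway-averaged synonymous/nonsynonymous differences of a codon pair."""
    positions = [p for p in range(3) if c1[p] != c2[p]]
    if not positions:
        return 0.0, 0.0

    def walk(order, allow_stops):
        cur = c1
        sd = nd = 0
        for p in order:
            nxt = cur[:p] + c2[p] + cur[p + 1 :]
            if not allow_stops and _aa(nxt) == "*" and nxt != c2:
                return None
            if _aa(cur) == _aa(nxt):
                sd += 1
            else:
                nd += 1
            cur = nxt
        return sd, nd

    tallies = [t for t in (walk(o, False) for o in itertools.permutations(positions)) if t]
    if not tallies:
        tallies = [walk(o, True) for o in itertools.permutations(positions)]
    sd = sum(t[0] for t in tallies) / len(tallies)
    nd = sum(t[1] for t in tallies) / len(tallies)
    return sd, nd


def ng86_literal(seq1: str, seq2: str):
    """Full NG86 Ka/Ks of two aligned CDS; returns (ks, ka, S, N, sd, nd).

    Saturated proportions (>= 3/4) are returned uncorrected, mirroring the
    stated estimator convention.
    """
    assert len(seq1) == len(seq2) and len(seq1) % 3 == 0
    S = N = sd = nd = 0.0
    for i in range(0, len(seq1), 3):
        c1, c2 = seq1[i : i + 3], seq2[i : i + 3]
        s1, n1 = ng86_sites(c1)
        s2, n2 = ng86_sites(c2)
        S += (s1 + s2) / 2
        N += (n1 + n2) / 2
        d = ng86_pair_diffs(c1, c2)
        sd += d[0]
        nd += d[1]
    ps = sd / S if S else 0.0
    pn = nd / N if N else 0.0
    ks = ps if ps >= 0.75 else -0.75 * math.log(1 - 4 * ps / 3)
    ka = pn if pn >= 0.75 else -0.75 * math.log(1 - 4 * pn / 3)
    return ks, ka, S, N, sd, nd


_FOURFOLD_FAMILIES = {
    "CT", "GT", "TC", "CC", "AC", "GC", "CG", "GG",
}  # first-two-base prefixes whose third position is fourfold degenerate


def fourdtv_literal(seq1: str, seq2: str):
    """4DTv by explicit codon-table enumeration; None when no eligible site."""
    n = tv = 0
    for i in range(0, len(seq1), 3):
        c1, c2 = seq1[i : i + 3], seq2[i : i + 3]
        if c1[:2] != c2[:2] or c1[:2] not in _FOURFOLD_FAMILIES:
            continue
        n += 1
        pur = set("AG")
        if (c1[2] in pur) != (c2[2] in pur):
            tv += 1
    return tv / n if n else None


# --------------------------------------------------------------- chaining


def _valid_chain(chain, orientation, G) -> bool:
    for (a1, b1), (a2, b2) in zip(chain, chain[1:]):
        if a2 <= a1:
            return False
        if orientation == "+" and b2 <= b1:
            return False
        if orientation == "-" and b2 >= b1:
            return False
        if a2 - a1 - 1 > G or abs(b2 - b1) - 1 > G:
            return False
    return True


def best_chain_bruteforce(anchors, orientation, G):
    """Maximum-score chain by exhaustive subset enumeration (<=~15 anchors)."""
    pts = sorted(anchors)
    best = []
    for r in range(len(pts), 0, -1):
        for combo in itertools.combinations(pts, r):
            if _valid_chain(list(combo), orientation, G):
                return list(combo)
    return best


def peel_blocks_bruteforce(anchors, A, G):
    """Replicate greedy peeling per orientation with the brute-force chain
    finder; returns {orientation: [chain, ...]} with chains of score >= A."""
    out = {}
    for orientation in "+-":
        pool = sorted(anchors)
        chains = []
        while len(pool) >= A:
            chain = best_chain_bruteforce(pool, orientation, G)
            if len(chain) < A:
                break
            chains.append(chain)
            pool = [p for p in pool if p not in chain]
        out[orientation] = chains
    return out


# --------------------------------------------------------------- parsimony


def all_topologies(labels):
    """Unrooted binary topologies as edge sets (recursive leaf addition)."""
    labels = list(labels)

    def trees(k):
        if k == 3:
            yield {("n0", labels[0]), ("n0", labels[1]), ("n0", labels[2])}, 1
        else:
            for edges, nid in trees(k - 1):
                for u, v in sorted(edges):
                    mid = f"n{nid}"
                    rest = edges - {(u, v)}
                    yield rest | {(u, mid), (mid, v), (mid, labels[k - 1])}, nid + 1

    for edges, _ in trees(len(labels)):
        yield edges


def fitch_cost_edges(edges, char: dict[str, int]) -> int:
    """Fitch length of one binary character on an edge-list tree."""
    adj = {}
    for u, v in edges:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    root = next(n for n in adj if str(n).startswith("n"))
    cost = 0

    def rec(node, parent):
        nonlocal cost
        if node in char:
            return {char[node]}
        acc = None
        for child in adj[node]:
            if child == parent:
                continue
            s = rec(child, node)
            if acc is None:
                acc = s
            else:
                inter = acc & s
                if inter:
                    acc = inter
                else:
                    cost += 1
                    acc = acc | s
        return acc

    rec(root, None)
    return cost


def min_parsimony_bruteforce(matrix) -> int:
    """Exhaustive minimum Fitch length over all topologies (pandas matrix)."""
    labels = list(matrix.index)
    best = None
    for edges in all_topologies(labels):
        total = 0
        for col in matrix.columns:
            char = {t: int(matrix.loc[t, col]) for t in labels}
            total += fitch_cost_edges(edges, char)
        if best is None or total < best:
            best = total
    return best


# ---------------------------------------------------------- splits / RF


def splits_bruteforce(newick_tree) -> set[frozenset]:
    """All non-trivial bipartitions of a dendropy tree by leaf-set sweep,
    normalized to the side not containing the alphabetically first leaf."""
    leaves = sorted(lf.taxon.label for lf in newick_tree.leaf_node_iter())
    anchor = leaves[0]
    found = set()
    for node in newick_tree:
        if node.is_leaf() or node.parent_node is None:
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        side = below if anchor not in below else frozenset(set(leaves) - below)
        if 1 < len(side) < len(leaves) - 1:
            found.add(side)
    return found


# ------------------------------------------------------------------- Holm


def holm_by_hand(pvals, alpha=0.05):
    """Step-down Holm rejection decisions, computed literally."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    reject = [False] * m
    for step, idx in enumerate(order):
        if pvals[idx] <= alpha / (m - step):
            reject[idx] = True
        else:
            break
    return reject


# ---------------------------------------------------------------- 2-means


def two_means_threshold_bruteforce(values):
    """Optimal 1-D two-cluster split by trying every threshold."""
    xs = sorted(values)
    best = None
    for k in range(1, len(xs)):
        lo, hi = xs[:k], xs[k:]
        mlo = sum(lo) / len(lo)
        mhi = sum(hi) / len(hi)
        sse = sum((x - mlo) ** 2 for x in lo) + sum((x - mhi) ** 2 for x in hi)
        if best is None or sse < best[0]:
            best = (sse, k)
    return best[1]
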