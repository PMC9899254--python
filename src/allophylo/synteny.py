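"""Collinear-block detection by anchor chaining and the synteny network.

The chaining model follows the classical A/G parameterisation: a collinear
block is a chain of at least ``A`` anchor pairs, monotone in both genomes
(increasing/increasing for '+' orientation, increasing/decreasing for '-'),
with at most ``G`` intervening gene ranks between consecutive anchors on
either chromosome. Scoring is +1 per anchor with no gap penalty beyond the
hard cutoff; overlapping chains are resolved greedily by score, then by
leftmost start.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .homology import HitTable


@dataclass(frozen=True)
class AnchorPair:
    gene_a: str
    gene_b: str
    chrom_a: str
    chrom_b: str
    order_a: int  # 0-based gene rank along chrom_a
    order_b: int


@dataclass
class CollinearBlock:
    id: int
    chrom_a: str
    chrom_b: str
    orientation: str  # '+' or '-'
    anchors: list[AnchorPair]
    score: int = 0
    params: tuple[int, int] | None = None  # the (A, G) setting that produced it

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)


def anchors_from_hits(
    ann_a, ann_b, hits: HitTable, collapse_tandem: bool = True
) -> list[AnchorPair]:
    """Turn retained hits into candidate anchors with gene-rank coordinates.

    Tandem arrays (hit pairs adjacent on the same chromosome within one
    genome) are collapsed to their first member beforehand, the standard
    guard against arrays spawning spurious anchors.
    """
    anchors = set()
    for q, hs in hits.items():
        if q not in ann_a.genes:
            continue
        ga = ann_a.genes[q]
        for h in hs:
            if h.subject not in ann_b.genes:
                continue
            gb = ann_b.genes[h.subject]
            anchors.add(
                AnchorPair(q, h.subject, ga.chrom, gb.chrom, ga.order, gb.order)
            )
    anchors = sorted(anchors, key=lambda a: (a.chrom_a, a.chrom_b, a.order_a, a.order_b))
    if collapse_tandem:
        kept = []
        seen_runs: set[tuple] = set()
        by_target: dict[tuple, list[AnchorPair]] = {}
        for a in anchors:
            by_target.setdefault((a.chrom_a, a.chrom_b, a.gene_b), []).append(a)
        drop = set()
        for run in by_target.values():
            run.sort(key=lambda a: a.order_a)
            for prev, cur in zip(run, run[1:]):
                if cur.order_a - prev.order_a == 1:
                    drop.add(cur)
        by_query: dict[tuple, list[AnchorPair]] = {}
        for a in anchors:
            by_query.setdefault((a.chrom_a, a.chrom_b, a.gene_a), []).append(a)
        for run in by_query.values():
            run.sort(key=lambda a: a.order_b)
            for prev, cur in zip(run, run[1:]):
                if cur.order_b - prev.order_b == 1:
                    drop.add(cur)
        anchors = [a for a in anchors if a not in drop]
    return anchors


def _chain_once(anchors: list[AnchorPair], orientation: str, G: int):
    """Best chain (max anchors; ties resolved toward the leftmost-sorted
    predecessor) via vectorized DP over anchors sorted by (order_a, order_b).
    Returns (chain indices into ``anchors``, score)."""
    n = len(anchors)
    order = sorted(range(n), key=lambda i: (anchors[i].order_a, anchors[i].order_b))
    oa = np.array([anchors[i].order_a for i in order])
    ob = np.array([anchors[i].order_b for i in order])
    sign = 1 if orientation == "+" else -1
    dp = np.ones(n, dtype=np.int64)
    parent = np.full(n, -1, dtype=np.int64)
    for p in range(1, n):
        da = oa[p] - oa[:p]
        db = sign * (ob[p] - ob[:p])
        ok = (da > 0) & (db > 0) & (da - 1 <= G) & (np.abs(ob[p] - ob[:p]) - 1 <= G)
        if ok.any():
            cand = np.where(ok, dp[:p], 0)
            j = int(np.argmax(cand))
            if cand[j] + 1 > dp[p]:
                dp[p] = cand[j] + 1
                parent[p] = j
    best = int(np.argmax(dp))
    chain = []
    k = best
    while k != -1:
        chain.append(order[k])
        k = int(parent[k])
    return chain[::-1], int(dp[best])


def detect_collinear_blocks(
    anchors: list[AnchorPair], A: int = 5, G: int = 25
) -> list[CollinearBlock]:
    """Extract collinear blocks per chromosome pair and orientation.

    Chains are peeled greedily: the maximum-score chain is emitted and its
    anchors removed (per orientation), until the best remaining chain drops
    below ``A`` anchors. Blocks are returned in deterministic order:
    chromosome pair, then start rank, then orientation.
    """
    if A < 2:
        raise ValueError("A must be >= 2")
    if G < 0:
        raise ValueError("G must be >= 0")
    by_pair: dict[tuple[str, str], list[AnchorPair]] = {}
    for a in set(anchors):
        by_pair.setdefault((a.chrom_a, a.chrom_b), []).append(a)
    blocks: list[CollinearBlock] = []
    for (ca, cb) in sorted(by_pair):
        for orientation in "+-":
            pool = sorted(
                by_pair[(ca, cb)], key=lambda a: (a.order_a, a.order_b)
            )
            while len(pool) >= A:
                idx_chain, score = _chain_once(pool, orientation, G)
                if score < A:
                    break
                chain = [pool[i] for i in idx_chain]
                blocks.append(
                    CollinearBlock(-1, ca, cb, orientation, chain, score, (A, G))
                )
                used = set(idx_chain)
                pool = [a for i, a in enumerate(pool) if i not in used]
    blocks.sort(
        key=lambda b: (b.chrom_a, b.chrom_b, b.anchors[0].order_a, b.orientation)
    )
    for i, b in enumerate(blocks):
        b.id = i
    return blocks


def build_synteny_network(
    block_sets: list[list[CollinearBlock]] | list[CollinearBlock],
    params: tuple[int, int] | None = None,
    include_intra: bool = True,
) -> nx.Graph:
    """Assemble the gene-level synteny network from pairwise block sets.

    Nodes are genes participating in at least one block, edges are anchor
    pairs (deduplicated) annotated with a block id. All blocks must have
    been detected under one (A, G) setting: mixed settings are rejected.
    ``params`` is recorded in the graph metadata (inferred from the blocks
    when omitted).
    """
    if block_sets and isinstance(block_sets[0], CollinearBlock):
        block_sets = [block_sets]  # type: ignore[list-item]
    seen_params = {
        blk.params for blocks in block_sets for blk in blocks if blk.params is not None
    }
    if len(seen_params) > 1:
        raise ValueError(f"mixed chaining settings in one network: {sorted(seen_params)}")
    if params is None and seen_params:
        params = seen_params.pop()
    g = nx.Graph()
    g.graph["params"] = params
    g.graph["include_intra"] = include_intra
    for i, blocks in enumerate(block_sets):
        for blk in blocks:
            for a in blk.anchors:
                g.add_edge(a.gene_a, a.gene_b, block=(i, blk.id))
    return g


# ----------------------------------------------------------------- IO


def write_blocks_tsv(blocks: list[CollinearBlock], path) -> None:
    rows = []
    for b in blocks:
        for a in b.anchors:
            rows.append(
                (b.id, b.orientation, b.chrom_a, b.chrom_b, a.gene_a, a.gene_b,
                 a.order_a, a.order_b)
            )
    pd.DataFrame(
        rows,
        columns=["block", "orientation", "chrom_a", "chrom_b", "gene_a", "gene_b",
                 "order_a", "order_b"],
    ).to_csv(path, sep="\t", index=False)


def read_blocks_tsv(path) -> list[CollinearBlock]:
    df = pd.read_csv(path, sep="\t")
    blocks = []
    for bid, grp in df.groupby("block", sort=True):
        first = grp.iloc[0]
        anchors = [
            AnchorPair(r.gene_a, r.gene_b, r.chrom_a, r.chrom_b, int(r.order_a), int(r.order_b))
            for r in grp.itertuples(index=False)
        ]
        blocks.append(
            CollinearBlock(
                int(bid), first.chrom_a, first.chrom_b, first.orientation,
                anchors, len(anchors),
            )
        )
    return blocks
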