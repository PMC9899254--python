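"""Homology search, reciprocal best hits, orthogroups and duplicate modes.

The similarity stand-in is k-mer containment: score(q, s) = |shared distinct
k-mers| / min(|kmers(q)|, |kmers(s)|). It is a speed-oriented replacement for
an alignment search; precomputed tabular hits in the 12-column BLAST
outfmt-6 dialect are accepted as the authoritative path and flow through the
same :class:`HomologyHit` containers.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd


@dataclass
class HomologyHit:
    query: str
    subject: str
    score: float
    rank: int  # 1-based, dense per query


#: hits per query, each a rank-sorted list
HitTable = dict[str, list[HomologyHit]]


_BASE_CODE = bytes.maketrans(b"ACGT", bytes([0, 1, 2, 3]))
_KMER_CACHE: dict[tuple[str, int], "np.ndarray"] = {}


def _encode_kmers(seq: str, k: int) -> "np.ndarray":
    """Distinct k-mers of a sequence as sorted integer codes (base-4)."""
    key = (seq, k)
    cached = _KMER_CACHE.get(key)
    if cached is not None:
        return cached
    codes = np.frombuffer(seq.encode().translate(_BASE_CODE), dtype=np.uint8)
    if len(codes) < k:
        out = np.empty(0, dtype=np.int64)
    else:
        powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
        out = np.unique(np.lib.stride_tricks.sliding_window_view(codes, k) @ powers)
    if len(_KMER_CACHE) > 500_000:  # bound memory across long sessions
        _KMER_CACHE.clear()
    _KMER_CACHE[key] = out
    return out


def score_similarity(
    seqs_a: dict[str, str],
    seqs_b: dict[str, str],
    k: int = 8,
    top_n: int = 5,
    min_score: float = 0.05,
) -> HitTable:
    """Rank subjects of ``seqs_b`` for every query of ``seqs_a``.

    Ties are broken by subject id. Self-hits (identical ids, as arise in
    intra-genome searches) are never retained.
    """
    if k < 4:
        raise ValueError("k must be >= 4")
    if not seqs_a or not seqs_b:
        raise ValueError("empty sequence set")
    subjects = sorted(seqs_b)
    subj_kmers = [_encode_kmers(seqs_b[s], k) for s in subjects]
    subj_sizes = np.array([len(x) for x in subj_kmers])
    # inverted index: kmer code -> array of subject indices
    all_codes = np.concatenate(subj_kmers) if subj_kmers else np.empty(0, np.int64)
    owner = np.repeat(np.arange(len(subjects)), subj_sizes)
    sort = np.argsort(all_codes, kind="stable")
    all_codes, owner = all_codes[sort], owner[sort]
    out: HitTable = {}
    n_subj = len(subjects)
    for q in sorted(seqs_a):
        qk = _encode_kmers(seqs_a[q], k)
        if len(qk) == 0:
            continue
        lo = np.searchsorted(all_codes, qk, side="left")
        hi = np.searchsorted(all_codes, qk, side="right")
        spans = hi - lo
        total = int(spans.sum())
        if total:
            starts = lo[spans > 0]
            lens = spans[spans > 0]
            offs = np.concatenate(([0], np.cumsum(lens)[:-1]))
            gather = np.repeat(starts - offs, lens) + np.arange(total)
            counts = np.bincount(owner[gather], minlength=n_subj)
        else:
            counts = np.zeros(n_subj, dtype=np.int64)
        scores = counts / np.minimum(len(qk), np.maximum(subj_sizes, 1))
        cand = np.nonzero(scores >= min_score)[0]
        scored = sorted(
            ((-float(scores[i]), subjects[i]) for i in cand if subjects[i] != q)
        )
        hits = [
            HomologyHit(q, s, -neg, rank)
            for rank, (neg, s) in enumerate(scored[:top_n], start=1)
        ]
        if hits:
            out[q] = hits
    return out


def reciprocal_best_hits(hits_ab: HitTable, hits_ba: HitTable) -> list[tuple[str, str]]:
    """Pairs (a, b) where b is a's rank-1 subject and a is b's rank-1 subject."""
    best_ab = {q: hs[0].subject for q, hs in hits_ab.items() if hs}
    best_ba = {q: hs[0].subject for q, hs in hits_ba.items() if hs}
    pairs = [(a, b) for a, b in best_ab.items() if best_ba.get(b) == a]
    return sorted(pairs)


@dataclass
class Orthogroup:
    id: str
    members: dict[str, list[str]]  # genome -> gene ids

    @property
    def copy_counts(self) -> dict[str, int]:
        return {g: len(m) for g, m in self.members.items()}

    @property
    def genes(self) -> list[str]:
        return [g for m in self.members.values() for g in m]


def build_orthogroups(
    hit_tables: dict[tuple[str, str], HitTable],
    genomes: dict[str, list[str] | set[str] | dict],
) -> list[Orthogroup]:
    """Orthogroups as connected components of the mutual-hit graph.

    An edge joins two genes of different genomes when each lists the other
    among its retained (top-n) hits in both directions; genes without edges
    form singleton groups. This is a deliberate simplification of full gene-
    family inference: component membership, not tree-aware orthology.
    """
    if len(genomes) < 2:
        raise ValueError("need >= 2 genomes")
    gene_genome = {g: name for name, genes in genomes.items() for g in genes}
    listed: dict[tuple[str, str], set[str]] = {}
    for (ga, gb), table in hit_tables.items():
        for q, hs in table.items():
            listed[(q, gb)] = {h.subject for h in hs}
    graph = nx.Graph()
    graph.add_nodes_from(gene_genome)
    for (ga, gb), table in hit_tables.items():
        for q, hs in table.items():
            for h in hs:
                if q in listed.get((h.subject, ga), ()):  # mutual listing
                    graph.add_edge(q, h.subject)
    groups = []
    for i, comp in enumerate(
        sorted(nx.connected_components(graph), key=lambda c: min(c))
    ):
        members: dict[str, list[str]] = {}
        for g in sorted(comp):
            members.setdefault(gene_genome[g], []).append(g)
        groups.append(Orthogroup(id=f"OG{i:06d}", members=members))
    return groups


DUPLICATE_MODES = ("WGD", "TD", "PD", "TRD", "DSD")


def classify_duplicates(
    annotation,
    intra_hits: HitTable,
    blocks,
    ancestral_genes: set[str] | None = None,
    proximal_max: int = 10,
) -> dict[tuple[str, str], str]:
    """Label intra-genome duplicate pairs by mode.

    Precedence WGD > TD > PD > TRD > DSD: anchor pair inside a collinear
    block -> WGD; adjacent gene ranks on one chromosome -> TD; <=proximal_max
    intervening genes -> PD; exactly one gene at an ancestral (outgroup-
    syntenic) locus -> TRD (requires ``ancestral_genes``); remainder -> DSD.
    """
    anchor_pairs = set()
    for blk in blocks:
        for a in blk.anchors:
            anchor_pairs.add(frozenset((a.gene_a, a.gene_b)))
    labels: dict[tuple[str, str], str] = {}
    seen = set()
    for q, hs in intra_hits.items():
        for h in hs:
            key = frozenset((q, h.subject))
            if len(key) < 2 or key in seen:
                continue
            seen.add(key)
            a, b = sorted(key)
            ga, gb = annotation.genes[a], annotation.genes[b]
            if key in anchor_pairs:
                mode = "WGD"
            elif ga.chrom == gb.chrom and abs(ga.order - gb.order) == 1:
                mode = "TD"
            elif ga.chrom == gb.chrom and abs(ga.order - gb.order) - 1 <= proximal_max:
                mode = "PD"
            elif ancestral_genes is not None and (
                (a in ancestral_genes) != (b in ancestral_genes)
            ):
                mode = "TRD"
            else:
                mode = "DSD"
            labels[(a, b)] = mode
    return labels


# ----------------------------------------------------------------- IO

_OUTFMT6 = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def write_hits_tsv(hits: HitTable, path) -> None:
    """Write hits as a 12-column outfmt-6 style table (bitscore = score)."""
    rows = []
    for q in sorted(hits):
        for h in hits[q]:
            rows.append([h.query, h.subject, 0, 0, 0, 0, 0, 0, 0, 0, 0.0, h.score])
    pd.DataFrame(rows, columns=_OUTFMT6).to_csv(path, sep="\t", index=False, header=False)


def read_hits_tsv(path, top_n: int | None = None) -> HitTable:
    """Read an outfmt-6 dialect table (qseqid, sseqid, ..., bitscore used).

    Rows are re-ranked per query by descending bitscore, ties by subject id;
    self-hits are dropped.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=_OUTFMT6)
    out: HitTable = {}
    for q, grp in df.groupby("qseqid", sort=True):
        grp = grp[grp["sseqid"] != q]
        grp = grp.sort_values(["bitscore", "sseqid"], ascending=[False, True])
        if top_n is not None:
            grp = grp.head(top_n)
        out[str(q)] = [
            HomologyHit(str(q), str(r.sseqid), float(r.bitscore), i + 1)
            for i, r in enumerate(grp.itertuples(index=False))
        ]
    return out
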