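"""Codon tables and NG86 pairwise lookup tables.

Everything downstream of a coding sequence — synonymous/nonsynonymous site
counting, per-pair difference counting, fourfold-degenerate third positions —
is precomputed here as dense 64 and 64x64 numpy tables indexed by codon.
Codons are indexed base-4 with T=0, C=1, A=2, G=3 (the classical codon-table
ordering).

Conventions (shared by the estimator, the simulator and the test oracle):

* mutation paths passing through a stop codon are excluded from the NG86
  pathway average; if every path between two codons is blocked, all paths are
  used as a fallback (the situation is rare and the alternative would be to
  discard the codon pair);
* single-nucleotide changes that create a stop codon are excluded from the
  per-position site denominators, i.e. a position with one stop neighbour
  splits its one site between synonymous and nonsynonymous fractions computed
  over the two viable changes.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np
from Bio.Data import CodonTable

BASES = "TCAG"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
CODONS = [a + b + c for a in BASES for b in BASES for c in BASES]
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}

_standard = CodonTable.unambiguous_dna_by_id[1]
#: codon string -> amino acid, '*' for stop
AA = {c: _standard.forward_table.get(c, "*") for c in CODONS}
STOP_CODONS = frozenset(_standard.stop_codons)

# transversion lookup: purines A,G vs pyrimidines T,C
_PURINES = {"A", "G"}


def is_transversion(b1: str, b2: str) -> bool:
    return b1 != b2 and ((b1 in _PURINES) != (b2 in _PURINES))


def codon_indices(seq: str) -> np.ndarray:
    """Map a CDS string to an int array of codon indices.

    Raises ``ValueError`` on length not divisible by 3, non-ACGT characters,
    or internal stop codons (a single trailing stop is tolerated and dropped).
    """
    seq = seq.upper().replace("U", "T")
    if len(seq) % 3 != 0:
        raise ValueError(f"CDS length {len(seq)} is not a multiple of 3")
    if set(seq) - set("ACGT"):
        raise ValueError("CDS contains non-ACGT characters (gap-free input required)")
    idx = np.empty(len(seq) // 3, dtype=np.int16)
    for i in range(0, len(seq), 3):
        idx[i // 3] = CODON_INDEX[seq[i : i + 3]]
    stops = np.isin(idx, [CODON_INDEX[c] for c in STOP_CODONS])
    if stops.any():
        where = np.nonzero(stops)[0]
        if len(where) == 1 and where[0] == len(idx) - 1:
            idx = idx[:-1]
        else:
            raise ValueError("CDS contains internal stop codon(s)")
    return idx


def _neighbours(codon: str, pos: int):
    for b in BASES:
        if b != codon[pos]:
            yield codon[:pos] + b + codon[pos + 1 :]


def _site_fractions(codon: str) -> tuple[float, float]:
    """NG86 synonymous / nonsynonymous site counts for one codon."""
    s = 0.0
    n = 0.0
    for pos in range(3):
        syn = 0
        viable = 0
        for alt in _neighbours(codon, pos):
            if AA[alt] == "*":
                continue
            viable += 1
            if AA[alt] == AA[codon]:
                syn += 1
        if viable == 0:  # all changes at this position create stops
            continue
        s += syn / viable
        n += (viable - syn) / viable
    return s, n


def _path_steps(c1: str, c2: str, order: tuple[int, ...]):
    """Codon sequence along one substitution order; None if a stop is crossed."""
    path = [c1]
    cur = c1
    for pos in order:
        cur = cur[:pos] + c2[pos] + cur[pos + 1 :]
        if AA[cur] == "*" and cur != c2:
            return None
        path.append(cur)
    return path

def _pair_differences(c1: str, c2: str) -> tuple[float, float]:
    """NG86 synonymous / nonsynonymous difference counts, pathway-averaged."""
    diff_pos = tuple(p for p in range(3) if c1[p] != c2[p])
    if not diff_pos:
        return 0.0, 0.0
    orders = list(itertools.permutations(diff_pos))
    tallies = []
    for order in orders:
        path = _path_steps(c1, c2, order)
        if path is None:
            continue
        sd = nd = 0
        for a, b in zip(path[:-1], path[1:]):
            if AA[a] == AA[b]:
                sd += 1
            else:
                nd += 1
        tallies.append((sd, nd))
    if not tallies:  # every order crosses a stop: fall back to all orders
        for order in orders:
            cur = c1
            sd = nd = 0
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
                if AA[cur] == AA[nxt]:
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            tallies.append((sd, nd))
    sd = float(np.mean([t[0] for t in tallies]))
    nd = float(np.mean([t[1] for t in tallies]))
    return sd, nd


@lru_cache(maxsize=1)
def ng86_tables():
    """Dense NG86 tables: (S[64], N[64], SD[64,64], ND[64,64]).

    Stop-codon rows/columns are NaN; callers validate input beforehand.
    """
    S = np.full(64, np.nan)
    N = np.full(64, np.nan)
    SD = np.full((64, 64), np.nan)
    ND = np.full((64, 64), np.nan)
    for i, c in enumerate(CODONS):
        if AA[c] == "*":
            continue
        S[i], N[i] = _site_fractions(c)
    for i, c1 in enumerate(CODONS):
        if AA[c1] == "*":
            continue
        for j, c2 in enumerate(CODONS):
            if AA[c2] == "*":
                continue
            SD[i, j], ND[i, j] = _pair_differences(c1, c2)
    return S, N, SD, ND


@lru_cache(maxsize=1)
def fourfold_tables():
    """4DTv tables: (ELIGIBLE[64,64] bool, TRANSVERSION[64,64] bool).

    A codon pair contributes a fourfold-degenerate third-position site when
    both codons are fourfold degenerate at position 3 and agree at the first
    two positions; the transversion flag marks a purine/pyrimidine change at
    that position.
    """
    fourfold = np.zeros(64, dtype=bool)
    for i, c in enumerate(CODONS):
        if AA[c] == "*":
            continue
        fourfold[i] = all(AA[alt] == AA[c] for alt in _neighbours(c, 2))
    eligible = np.zeros((64, 64), dtype=bool)
    tv = np.zeros((64, 64), dtype=bool)
    for i, c1 in enumerate(CODONS):
        for j, c2 in enumerate(CODONS):
            if fourfold[i] and fourfold[j] and c1[:2] == c2[:2]:
                eligible[i, j] = True
                tv[i, j] = is_transversion(c1[2], c2[2])
    return eligible, tv


@lru_cache(maxsize=1)
def mutation_opportunities():
    """Per-codon lists of viable single-nucleotide changes.

    Returns (syn, nonsyn): each a list over codon index of a list of
    (position, new_base_char, new_codon_index) tuples; changes creating stop
    codons are excluded from both.
    """
    syn: list[list[tuple[int, str, int]]] = [[] for _ in range(64)]
    nonsyn: list[list[tuple[int, str, int]]] = [[] for _ in range(64)]
    for i, c in enumerate(CODONS):
        if AA[c] == "*":
            continue
        for pos in range(3):
            for alt in _neighbours(c, pos):
                if AA[alt] == "*":
                    continue
                entry = (pos, alt[pos], CODON_INDEX[alt])
                if AA[alt] == AA[c]:
                    syn[i].append(entry)
                else:
                    nonsyn[i].append(entry)
    return syn, nonsyn


def indices_to_seq(idx: np.ndarray) -> str:
    return "".join(CODONS[i] for i in idx)
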