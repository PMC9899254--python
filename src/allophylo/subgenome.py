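"""Dominant/recessive subgenome assignment and fractionation profiles.

After an allopolyploidy the two parental subgenomes lose duplicated genes at
unequal rates (biased fractionation). Units (homoeologous chromosomes, or
arbitrary gene-set partitions) are ranked by how many *ancestral genes* they
retain — genes with a reciprocal best hit to a designated unduplicated
outgroup genome; the richer unit of each homoeologous pair is 'dominant',
the other 'recessive'. Retention is then profiled in sliding gene windows
along the outgroup's chromosomes and the dominant > recessive bias is tested
with a paired one-sided rank test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class PairAssignment:
    dominant: str
    recessive: str
    dominant_count: int
    recessive_count: int
    tie: bool


@dataclass
class SubgenomeAssignment:
    pairs: list[PairAssignment]

    @property
    def labels(self) -> dict[str, str]:
        out = {}
        for p in self.pairs:
            out[p.dominant] = "dominant"
            out[p.recessive] = "recessive"
        return out

    @property
    def dominant_units(self) -> set[str]:
        return {p.dominant for p in self.pairs}

    @property
    def recessive_units(self) -> set[str]:
        return {p.recessive for p in self.pairs}

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (p.dominant, p.recessive, p.dominant_count, p.recessive_count, p.tie)
                for p in self.pairs
            ],
            columns=["dominant", "recessive", "dominant_count", "recessive_count", "tie"],
        )


def chromosome_units(annotation) -> dict[str, set[str]]:
    """Each chromosome as one assignable unit (chromosome mode)."""
    return {c: set(ids) for c, ids in annotation.chromosomes.items()}


def homoeolog_pairs_from_blocks(
    annotation, intra_blocks, min_coverage: float = 0.5
) -> list[tuple[str, str]]:
    """Pair homoeologous chromosomes from intra-genome collinear blocks.

    Two chromosomes are candidates when their mutual blocks cover at least
    ``min_coverage`` of the shorter chromosome's genes; candidates are
    matched greedily by descending coverage, each chromosome used once.
    """
    cover: dict[tuple[str, str], set[str]] = {}
    for blk in intra_blocks:
        if blk.chrom_a == blk.chrom_b:
            continue
        key = tuple(sorted((blk.chrom_a, blk.chrom_b)))
        bag = cover.setdefault(key, set())
        for a in blk.anchors:
            bag.add(a.gene_a)
            bag.add(a.gene_b)
    scored = []
    for (c1, c2), genes in cover.items():
        shorter = min(len(annotation.chromosomes[c1]), len(annotation.chromosomes[c2]))
        chrom_genes = set(annotation.chromosomes[c1]) | set(annotation.chromosomes[c2])
        frac = len(genes & chrom_genes) / 2 / shorter  # anchors span both chroms
        if frac >= min_coverage:
            scored.append((-frac, c1, c2))
    scored.sort()
    used: set[str] = set()
    pairs = []
    for _, c1, c2 in scored:
        if c1 in used or c2 in used:
            continue
        used.update((c1, c2))
        pairs.append((c1, c2))
    return sorted(pairs)


def assign_subgenomes(
    ancestral_genes: set[str] | list[tuple[str, str]],
    homoeolog_pairs: list[tuple[str, str]],
    units: dict[str, set[str]],
) -> SubgenomeAssignment:
    """Label each homoeologous unit pair dominant/recessive.

    ``ancestral_genes`` is either the set of genes with an outgroup RBH, or
    the raw RBH pair list (gene, outgroup_gene). The unit with strictly more
    ancestral genes is dominant; ties are flagged and broken
    lexicographically by unit id.
    """
    if ancestral_genes and isinstance(next(iter(ancestral_genes)), tuple):
        ancestral = {a for a, _ in ancestral_genes}
    else:
        ancestral = set(ancestral_genes)
    out = []
    for u1, u2 in homoeolog_pairs:
        for u in (u1, u2):
            if u not in units:
                raise KeyError(f"unit {u!r} not present in the unit map")
        c1 = len(units[u1] & ancestral)
        c2 = len(units[u2] & ancestral)
        tie = c1 == c2
        if c1 > c2 or (tie and u1 < u2):
            out.append(PairAssignment(u1, u2, c1, c2, tie))
        else:
            out.append(PairAssignment(u2, u1, c2, c1, tie))
    return SubgenomeAssignment(out)


def fractionation_profile(
    target_annotation,
    ortholog_map: dict[str, set[str]],
    assignment: SubgenomeAssignment,
    unit_of_gene,
    window: int = 100,
    step: int = 1,
) -> pd.DataFrame:
    """Retention rates per sliding gene window along the target genome.

    ``ortholog_map``: target (outgroup) gene -> syntenic ortholog gene ids in
    the polyploid; ``unit_of_gene(gene)`` maps a polyploid gene to its unit
    (e.g. chromosome). Rates per window: fraction of target genes retained in
    the dominant subgenome, the recessive subgenome, and in at least one
    ('both' in the sense of either copy surviving; a gene retained twice
    counts once). Columns: chrom, start, dominant, recessive, both.
    """
    dom, rec = assignment.dominant_units, assignment.recessive_units
    rows = []
    for chrom in sorted(target_annotation.chromosomes):
        genes = target_annotation.chromosomes[chrom]
        if window > len(genes):
            raise ValueError(
                f"window {window} exceeds chromosome {chrom} ({len(genes)} genes)"
            )
        in_dom = np.zeros(len(genes), dtype=bool)
        in_rec = np.zeros(len(genes), dtype=bool)
        for i, g in enumerate(genes):
            for o in ortholog_map.get(g, ()):
                u = unit_of_gene(o)
                if u in dom:
                    in_dom[i] = True
                elif u in rec:
                    in_rec[i] = True
        for start in range(0, len(genes) - window + 1, step):
            sl = slice(start, start + window)
            rows.append(
                (
                    chrom,
                    start,
                    float(in_dom[sl].mean()),
                    float(in_rec[sl].mean()),
                    float((in_dom[sl] | in_rec[sl]).mean()),
                )
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "dominant", "recessive", "both"])


@dataclass
class BiasTestResult:
    pvalue: float
    median_difference: float  # median over windows of (dominant - recessive)
    n_windows: int


def biased_fractionation_test(profile: pd.DataFrame, min_windows: int = 10) -> BiasTestResult:
    """Paired one-sided rank test of dominant > recessive retention.

    Windows are the pairing unit; feed non-overlapping windows (step=window)
    so they are approximately independent. Identical profiles give p = 1.
    """
    if len(profile) < min_windows:
        raise ValueError(f"need >= {min_windows} windows, got {len(profile)}")
    diff = (profile["dominant"] - profile["recessive"]).to_numpy(dtype=float)
    med = float(np.median(diff))
    if np.all(diff == 0):
        return BiasTestResult(1.0, 0.0, len(diff))
    res = stats.wilcoxon(diff, alternative="greater", zero_method="zsplit")
    return BiasTestResult(float(res.pvalue), med, len(diff))


def profile_to_bed(profile: pd.DataFrame, path, window: int) -> None:
    """Windows as BED-like intervals in gene-rank coordinates (0-based,
    half-open), with the three retention rates as extra columns."""
    with open(path, "w") as fh:
        for r in profile.itertuples(index=False):
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.start + window}\t{r.dominant:.4f}\t"
                f"{r.recessive:.4f}\t{r.both:.4f}\n"
            )
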