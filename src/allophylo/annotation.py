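"""Genome annotations: ordered gene models per chromosome.

The internal coordinate system is the *gene rank*: the 0-based position of a
gene along its chromosome when genes are sorted by start coordinate. All
synteny operations work in gene ranks; base-pair coordinates are only kept
for round-tripping GFF3/BED.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


@dataclass
class Gene:
    id: str
    chrom: str
    start: int  # 1-based inclusive, GFF convention
    end: int
    strand: str = "+"
    order: int = -1  # rank along chromosome, filled by GenomeAnnotation


@dataclass
class GenomeAnnotation:
    """Ordered gene models of one (sub)genome."""

    name: str
    genes: dict[str, Gene] = field(default_factory=dict)
    chromosomes: dict[str, list[str]] = field(default_factory=dict)

    @classmethod
    def from_genes(cls, name: str, genes: list[Gene]) -> "GenomeAnnotation":
        ann = cls(name=name)
        seen = set()
        for g in genes:
            if g.id in seen:
                raise ValueError(f"duplicate gene id {g.id!r}")
            seen.add(g.id)
        by_chrom: dict[str, list[Gene]] = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append(g)
        for chrom, gs in by_chrom.items():
            if any(a.start > b.start for a, b in zip(gs, gs[1:])):
                warnings.warn(f"unsorted genes on {chrom}; sorting by start")
                gs = sorted(gs, key=lambda g: (g.start, g.id))
            for rank, g in enumerate(gs):
                g.order = rank
                ann.genes[g.id] = g
            ann.chromosomes[chrom] = [g.id for g in gs]
        return ann

    def order_of(self, gene_id: str) -> int:
        return self.genes[gene_id].order

    def chrom_of(self, gene_id: str) -> str:
        return self.genes[gene_id].chrom

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            (g.chrom, g.start, g.end, g.id, g.strand, g.order)
            for chrom in sorted(self.chromosomes)
            for g in (self.genes[i] for i in self.chromosomes[chrom])
        ]
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene", "strand", "order"])

    # ------------------------------------------------------------------ IO

    def write_gff3(self, path: str | Path) -> None:
        df = self.to_dataframe()
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for row in df.itertuples(index=False):
                fh.write(
                    f"{row.chrom}\tallophylo\tgene\t{row.start}\t{row.end}\t.\t"
                    f"{row.strand}\t.\tID={row.gene}\n"
                )

    def write_bed(self, path: str | Path) -> None:
        df = self.to_dataframe()
        with open(path, "w") as fh:
            for row in df.itertuples(index=False):
                fh.write(f"{row.chrom}\t{row.start - 1}\t{row.end}\t{row.gene}\t0\t{row.strand}\n")


def load_annotation(path: str | Path, name: str | None = None) -> GenomeAnnotation:
    """Load a GFF3 (gene features) or BED-like annotation.

    GFF3 coordinates are 1-based inclusive; BED is 0-based half-open. Both are
    normalized to internal gene ranks. The dialect is sniffed from the first
    data line.
    """
    path = Path(path)
    name = name or path.stem
    lines = [
        ln.rstrip("\n")
        for ln in path.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    if not lines:
        raise ValueError(f"{path}: no records")
    ncol = len(lines[0].split("\t"))
    genes: list[Gene] = []
    if ncol >= 8:  # GFF3
        for ln in lines:
            f = ln.split("\t")
            if f[2].lower() not in {"gene", "mrna", "cds"} and f[2] != ".":
                continue
            if f[2].lower() != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            gid = attrs.get("ID") or attrs.get("Name")
            if gid is None:
                raise ValueError(f"{path}: gene feature without ID attribute")
            genes.append(Gene(gid, f[0], int(f[3]), int(f[4]), f[6] if f[6] in "+-" else "+"))
    elif ncol >= 4:  # BED-like: chrom start end name [score] [strand]
        for ln in lines:
            f = ln.split("\t")
            strand = f[5] if len(f) >= 6 and f[5] in "+-" else "+"
            genes.append(Gene(f[3], f[0], int(f[1]) + 1, int(f[2]), strand))
    else:
        raise ValueError(f"{path}: expected GFF3 (9 cols) or BED (>=4 cols), got {ncol}")
    return GenomeAnnotation.from_genes(name, genes)


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=k, description="") for k, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")
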