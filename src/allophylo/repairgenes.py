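"""Orthogroup copy-number asymmetry statistics.

The motivating pattern: a slowly evolving lineage retaining WGD duplicates
of DNA repair and recombination gene families at a higher rate than its
relatives, visible as a lopsided count of orthogroups where one species
keeps two copies while the other keeps at most one. Functional membership
(e.g. a repair-pathway gene list) is an input, never computed here.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats


def copy_number_table(
    orthogroups, species: list[str], gene_subset: set[str] | None = None
) -> pd.DataFrame:
    """Per-orthogroup copy counts for each species (zero counts explicit).

    With ``gene_subset`` the table is restricted to orthogroups intersecting
    the subset and counts only subset members; a subset gene not covered by
    any orthogroup is an error (it would silently vanish from the analysis).
    """
    if gene_subset is not None:
        covered = {g for og in orthogroups for g in og.genes}
        missing = set(gene_subset) - covered
        if missing:
            raise ValueError(
                f"{len(missing)} subset gene(s) not in any orthogroup, e.g. "
                f"{sorted(missing)[:3]}"
            )
    rows = {}
    for og in orthogroups:
        counts = {}
        for sp in species:
            members = og.members.get(sp, [])
            if gene_subset is not None:
                members = [g for g in members if g in gene_subset]
            counts[sp] = len(members)
        if gene_subset is not None and sum(counts.values()) == 0:
            continue
        rows[og.id] = counts
    return pd.DataFrame.from_dict(rows, orient="index", columns=species).fillna(0).astype(int)


@dataclass
class AsymmetryResult:
    focal: str
    other: str
    forward: int  # orthogroups with focal >= 2 (or == 2) copies and other <= 1
    reverse: int
    pvalue: float | None  # two-sided rank-sum on per-orthogroup counts
    strict_two: bool


def asymmetry_counts(
    table: pd.DataFrame, focal: str, other: str, strict_two: bool = False
) -> AsymmetryResult:
    """Duplicate-retention asymmetry between two species.

    ``strict_two`` switches the focal criterion from >=2 copies to exactly 2
    (the retained-homoeolog reading).
    """
    for sp in (focal, other):
        if sp not in table.columns:
            raise KeyError(f"species {sp!r} not in copy table")
    f = table[focal].to_numpy()
    o = table[other].to_numpy()
    has_two = (f == 2) if strict_two else (f >= 2)
    rev_two = (o == 2) if strict_two else (o >= 2)
    forward = int((has_two & (o <= 1)).sum())
    reverse = int((rev_two & (f <= 1)).sum())
    p = None
    if len(table) >= 3:
        p = float(stats.mannwhitneyu(f, o, alternative="two-sided").pvalue)
    return AsymmetryResult(focal, other, forward, reverse, p, strict_two)
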