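"""Molecular-evolution estimators.

Ka/Ks by Nei–Gojobori (1986) counting with Jukes–Cantor multiple-hit
correction, fourfold-degenerate third-codon transversion rates (4DTv),
per-collinear-block medians, kernel-density Ks-peak detection, substitution
rates r = Ks/t, three-taxon relative-rate decomposition, post-WGD slowdown
ratios, long-term effective population size Ne = theta/(4*mu*g) and rank-sum
distribution comparisons.

The NG86 estimator is the workhorse: sites are counted per codon as the
fraction of viable single-nucleotide changes that are synonymous (averaged
over the two sequences), observed differences are pathway-averaged, and the
proportions are corrected with d = -3/4 ln(1 - 4p/3). Inputs where the raw
synonymous proportion reaches 3/4 cannot be corrected and are returned with
``saturated=True`` carrying the raw proportion instead of being discarded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats

from ._codon import codon_indices, fourfold_tables, ng86_tables

JC_LIMIT = 0.75


def _jc(p: float) -> float:
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


@dataclass
class KsKaEstimate:
    ks: float
    ka: float
    fourdtv: float | None
    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float
    nonsyn_diffs: float
    saturated: bool = False

    @property
    def ka_ks(self) -> float | None:
        """Ka/Ks, or None when Ks = 0 (ratio undefined)."""
        if self.ks == 0:
            return None
        return self.ka / self.ks


def estimate_ks_ka(cds_a: str | np.ndarray, cds_b: str | np.ndarray) -> KsKaEstimate:
    """NG86 Ka/Ks between two pre-aligned, gap-free, equal-length CDS.

    Accepts raw strings or codon-index arrays (see
    :func:`allophylo._codon.codon_indices`) for repeated use.
    """
    ia = codon_indices(cds_a) if isinstance(cds_a, str) else np.asarray(cds_a)
    ib = codon_indices(cds_b) if isinstance(cds_b, str) else np.asarray(cds_b)
    if len(ia) != len(ib):
        raise ValueError(f"CDS lengths differ: {3 * len(ia)} vs {3 * len(ib)}")
    if len(ia) == 0:
        raise ValueError("empty CDS")
    S, N, SD, ND = ng86_tables()
    s_sites = float((S[ia].sum() + S[ib].sum()) / 2.0)
    n_sites = float((N[ia].sum() + N[ib].sum()) / 2.0)
    sd = float(SD[ia, ib].sum())
    nd = float(ND[ia, ib].sum())
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    saturated = ps >= JC_LIMIT or pn >= JC_LIMIT
    ks = ps if ps >= JC_LIMIT else _jc(ps)
    ka = pn if pn >= JC_LIMIT else _jc(pn)
    return KsKaEstimate(
        ks=ks,
        ka=ka,
        fourdtv=compute_4dtv(ia, ib),
        syn_sites=s_sites,
        nonsyn_sites=n_sites,
        syn_diffs=sd,
        nonsyn_diffs=nd,
        saturated=saturated,
    )


def compute_4dtv(cds_a: str | np.ndarray, cds_b: str | np.ndarray) -> float | None:
    """Raw transversion proportion at shared fourfold-degenerate third positions.

    Returns None when the pair has no eligible fourfold site.
    """
    ia = codon_indices(cds_a) if isinstance(cds_a, str) else np.asarray(cds_a)
    ib = codon_indices(cds_b) if isinstance(cds_b, str) else np.asarray(cds_b)
    if len(ia) != len(ib):
        raise ValueError("CDS lengths differ")
    eligible, tv = fourfold_tables()
    n = int(eligible[ia, ib].sum())
    if n == 0:
        return None
    return float(tv[ia, ib].sum()) / n


@dataclass
class BlockKsSummary:
    block_id: int
    median_ks: float
    median_4dtv: float | None
    n_pairs: int


def summarize_blocks(
    blocks,
    estimates: dict[tuple[str, str], KsKaEstimate],
    ks_max: float = 5.0,
    fourdtv_max: float = 1.0,
) -> tuple[list[BlockKsSummary], int]:
    """Per-block median Ks / 4DTv after the per-pair exclusion filters.

    Pairs with Ks = 0 or Ks > ks_max, or 4DTv = 0 or >= fourdtv_max, or a
    saturation flag, are excluded before the median (the 4DTv filter only
    applies to the 4DTv median). Blocks left with no surviving Ks values are
    dropped; the second return value counts them.
    """
    out: list[BlockKsSummary] = []
    dropped = 0
    for blk in blocks:
        ks_vals, tv_vals = [], []
        for a in blk.anchors:
            est = estimates.get((a.gene_a, a.gene_b)) or estimates.get((a.gene_b, a.gene_a))
            if est is None or est.saturated:
                continue
            if 0.0 < est.ks <= ks_max:
                ks_vals.append(est.ks)
            if est.fourdtv is not None and 0.0 < est.fourdtv < fourdtv_max:
                tv_vals.append(est.fourdtv)
        if not ks_vals:
            dropped += 1
            continue
        out.append(
            BlockKsSummary(
                block_id=blk.id,
                median_ks=float(np.median(ks_vals)),
                median_4dtv=float(np.median(tv_vals)) if tv_vals else None,
                n_pairs=len(ks_vals),
            )
        )
    return out, dropped


def detect_ks_peaks(
    values,
    bandwidth: float | None = None,
    min_prominence: float = 0.05,
    grid_size: int = 512,
) -> list[float]:
    """Local maxima of a Gaussian KDE over block-median Ks values.

    bandwidth defaults to Silverman's rule; peaks below ``min_prominence`` of
    the maximum density are discarded. Returned in ascending Ks order.
    """
    x = np.asarray(list(values), dtype=float)
    if x.size < 20:
        raise ValueError(f"need >=20 values for peak detection, got {x.size}")
    if np.ptp(x) == 0:  # degenerate: all values identical
        return [float(x[0])]
    kde = stats.gaussian_kde(x, bw_method="silverman" if bandwidth is None else bandwidth)
    lo, hi = x.min(), x.max()
    pad = 3 * float(np.std(x)) * (kde.factor if bandwidth is None else bandwidth)
    grid = np.linspace(lo - pad, hi + pad, grid_size)
    dens = kde(grid)
    idx, _ = signal.find_peaks(dens, prominence=min_prominence * dens.max())
    return [float(grid[i]) for i in idx]


@dataclass
class RateEstimate:
    r: float  # substitutions per synonymous site per year
    ks: float
    t_years: float


def substitution_rate(ks: float, t_years: float) -> RateEstimate:
    """Average substitution rate r = Ks / t (per synonymous site per year)."""
    if t_years <= 0:
        raise ValueError("divergence time must be positive")
    if ks < 0:
        raise ValueError("Ks must be non-negative")
    return RateEstimate(r=ks / t_years, ks=ks, t_years=t_years)


@dataclass
class RelativeRateResult:
    ks_a: float  # branch-specific Ks of lineage A since the A/B split
    ks_b: float
    ks_outgroup: float  # residual on the outgroup side of the split
    d_ab: float
    d_ao: float
    d_bo: float
    clamped: bool = False


def relative_rate_decompose(
    d_ab: float, d_ao: float, d_bo: float, tolerance: float = 1e-9
) -> RelativeRateResult:
    """Three-taxon relative-rate decomposition.

    ks_a = (d_AB + d_AO - d_BO)/2 and symmetrically for ks_b; the residual
    toward the outgroup is (d_AO + d_BO - d_AB)/2. Small negative branch
    estimates (within ``tolerance``) are clamped to 0; larger ones indicate
    inconsistent distances and raise.
    """
    if min(d_ab, d_ao, d_bo) < 0:
        raise ValueError("distances must be non-negative")
    ks_a = (d_ab + d_ao - d_bo) / 2.0
    ks_b = (d_ab + d_bo - d_ao) / 2.0
    ks_o = (d_ao + d_bo - d_ab) / 2.0
    clamped = False
    vals = []
    for v in (ks_a, ks_b, ks_o):
        if v < -tolerance:
            raise ValueError(f"inconsistent distances: branch estimate {v:.3g} < 0")
        if v < 0:
            v, clamped = 0.0, True
        vals.append(v)
    return RelativeRateResult(vals[0], vals[1], vals[2], d_ab, d_ao, d_bo, clamped)


def slowdown_ratio(
    ks_wgd: float, t_wgd_years: float, ks_older: float, t_older_years: float
) -> float:
    """Pre- vs post-WGD rate ratio from two Ks peaks and their ages.

    The older event (e.g. the core-eudicot gamma triplication) at
    (ks_older, t_older) brackets an earlier interval [t_older, t_wgd]; the
    ratio compares the per-year rate in that interval with the rate since the
    younger WGD: ((ks_older-ks_wgd)/(t_older-t_wgd)) / (ks_wgd/t_wgd).
    """
    if not (t_older_years > t_wgd_years > 0):
        raise ValueError("need t_older > t_wgd > 0")
    if not (ks_older > ks_wgd >= 0):
        raise ValueError("need ks_older > ks_wgd >= 0")
    if ks_wgd == 0:
        raise ValueError("ks_wgd must be positive for a finite ratio")
    older_rate = (ks_older - ks_wgd) / (t_older_years - t_wgd_years)
    recent_rate = ks_wgd / t_wgd_years
    return older_rate / recent_rate


@dataclass
class PopGenParams:
    theta: float
    mu_per_year: float
    g_years: float
    ne: float


def effective_population_size(theta: float, mu_per_year: float, g_years: float) -> PopGenParams:
    """Long-term Ne = theta / (4 * mu * g) from per-site heterozygosity."""
    if mu_per_year <= 0 or g_years <= 0:
        raise ValueError("mutation rate and generation time must be positive")
    if theta < 0:
        raise ValueError("theta must be non-negative")
    return PopGenParams(theta, mu_per_year, g_years, theta / (4.0 * mu_per_year * g_years))


@dataclass
class RankSumResult:
    statistic: float
    pvalue: float
    n_x: int
    n_y: int


def compare_distributions(
    x,
    y,
    ks_x=None,
    ks_y=None,
    ks_matching_tolerance: float | None = None,
) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) comparison of two samples.

    When ``ks_matching_tolerance`` is given the two samples are treated as
    paired observations (e.g. per-gene Ka/Ks in two species) and pairs are
    first restricted to those whose accompanying Ks values agree within the
    tolerance — the contrast is then made only between genes evolving at
    similar synonymous divergence.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if ks_matching_tolerance is not None:
        if ks_x is None or ks_y is None:
            raise ValueError("ks_x/ks_y required when a matching tolerance is given")
        ks_x = np.asarray(list(ks_x), dtype=float)
        ks_y = np.asarray(list(ks_y), dtype=float)
        keep = np.abs(ks_x - ks_y) <= ks_matching_tolerance
        x, y = x[keep], y[keep]
    if len(x) < 3 or len(y) < 3:
        raise ValueError("each sample needs n >= 3 after filtering")
    method = "exact" if max(len(x), len(y)) <= 25 else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return RankSumResult(float(res.statistic), float(res.pvalue), len(x), len(y))


def write_estimates_tsv(estimates: dict[tuple[str, str], KsKaEstimate], path) -> None:
    rows = [
        {
            "gene1": a,
            "gene2": b,
            "ka": e.ka,
            "ks": e.ks,
            "ka_ks": e.ka_ks if e.ka_ks is not None else float("nan"),
            "fourdtv": e.fourdtv if e.fourdtv is not None else float("nan"),
            "saturated": int(e.saturated),
        }
        for (a, b), e in estimates.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_estimates_tsv(path) -> dict[tuple[str, str], KsKaEstimate]:
    df = pd.read_csv(path, sep="\t")
    out = {}
    for row in df.itertuples(index=False):
        out[(row.gene1, row.gene2)] = KsKaEstimate(
            ks=row.ks,
            ka=row.ka,
            fourdtv=None if np.isnan(row.fourdtv) else row.fourdtv,
            syn_sites=float("nan"),
            nonsyn_sites=float("nan"),
            syn_diffs=float("nan"),
            nonsyn_diffs=float("nan"),
            saturated=bool(row.saturated),
        )
    return out
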