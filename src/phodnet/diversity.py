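"""Alpha diversity, niche breadth/overlap, phosphorus activation coefficient,
and temporal slope fitting.

Shannon entropy is reported in nats by default (``base`` is configurable).
Chao1 switches to the bias-corrected form whenever no doubletons are present,
avoiding division by zero. Niche metrics follow Levins (breadth: inverse
Simpson concentration of a taxon's share across samples) and Pianka (overlap:
normalized inner product of two taxa's share profiles).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from phodnet.core_io import OtuTable
from phodnet.errors import ValidationError


@dataclass(frozen=True)
class DiversityRecord:
    sample_id: str
    shannon: float
    chao1: float
    observed_richness: int


@dataclass
class NicheResult:
    """Levins breadth per taxon, Pianka overlap per pair, and community means."""

    breadth_per_taxon: dict[str, float]
    overlap_per_pair: dict[tuple[str, str], float]
    community_breadth: float
    community_overlap: float


@dataclass
class SlopeFit:
    group: str
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    per_replicate_slopes: list[float]


def shannon(counts: Sequence[float], base: float | None = None) -> float:
    """Shannon diversity H = −Σ p_i log p_i over nonzero proportions.

    Natural log by default; pass ``base`` for other units (e.g. 2 for bits).
    """
    x = np.asarray(counts, dtype=float)
    if np.any(x < 0):
        raise ValidationError("negative counts")
    total = x.sum()
    if total <= 0:
        raise ValidationError("all-zero count vector")
    p = x[x > 0] / total
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= math.log(base)
    return max(h, 0.0)


def chao1(counts: Sequence[float]) -> float:
    """Chao1 richness estimate S_obs + F1²/(2·F2).

    Uses the bias-corrected form S_obs + F1(F1−1)/2 when no doubletons exist.
    Counts must be integers (singleton/doubleton tallies are undefined
    otherwise).
    """
    x = np.asarray(counts, dtype=float)
    if np.any(x < 0):
        raise ValidationError("negative counts")
    if not np.allclose(x, np.round(x)):
        raise ValidationError("chao1 requires integer counts")
    x = np.round(x).astype(int)
    s_obs = int((x > 0).sum())
    f1 = int((x == 1).sum())
    f2 = int((x == 2).sum())
    if f2 > 0:
        return s_obs + f1 * f1 / (2.0 * f2)
    return s_obs + f1 * (f1 - 1) / 2.0


def observed_richness(counts: Sequence[float]) -> int:
    return int((np.asarray(counts) > 0).sum())


def diversity_records(table: OtuTable) -> list[DiversityRecord]:
    """Per-sample Shannon, Chao1 and observed richness for a count table."""
    return [
        DiversityRecord(
            s,
            shannon(table.counts[:, i]),
            chao1(table.counts[:, i]),
            observed_richness(table.counts[:, i]),
        )
        for i, s in enumerate(table.sample_ids)
    ]


def _taxon_shares(table: OtuTable) -> np.ndarray:
    """Row-normalize: each taxon's distribution of its total across samples."""
    totals = table.counts.sum(axis=1, keepdims=True)
    shares = np.zeros_like(table.counts)
    nz = totals[:, 0] > 0
    shares[nz] = table.counts[nz] / totals[nz]
    return shares


def levins_breadth(table: OtuTable) -> dict[str, float]:
    """Levins niche breadth B_j = 1 / Σ_i p_ij² with p_ij the share of taxon
    j's total found in sample i. B ∈ [1, n_samples]; absent taxa are excluded
    with a warning."""
    shares = _taxon_shares(table)
    out: dict[str, float] = {}
    absent = []
    for t, row in zip(table.taxon_ids, shares):
        ss = float((row**2).sum())
        if ss == 0:
            absent.append(t)
            continue
        out[t] = 1.0 / ss
    if absent:
        warnings.warn(f"excluded {len(absent)} absent taxa from niche breadth")
    return out


def pianka_overlap(rel_j: Sequence[float], rel_k: Sequence[float]) -> float:
    """Pianka niche overlap O = Σ p_ij p_ik / sqrt(Σ p_ij² Σ p_ik²) ∈ [0, 1]."""
    a = np.asarray(rel_j, dtype=float)
    b = np.asarray(rel_k, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("profiles must have equal length")
    na, nb = (a**2).sum(), (b**2).sum()
    if na == 0 or nb == 0:
        raise ValidationError("zero profile vector")
    return float(np.clip((a * b).sum() / math.sqrt(na * nb), 0.0, 1.0))


def niche_metrics(table: OtuTable, min_samples_present: int = 2) -> NicheResult:
    """Community niche summary.

    Community-level breadth and overlap are unweighted means over taxa (and
    taxon pairs) present in at least ``min_samples_present`` samples; rarer
    taxa give degenerate specialist values that would dominate the means.
    """
    shares = _taxon_shares(table)
    present = (table.counts > 0).sum(axis=1)
    breadth = levins_breadth(table)
    eligible = [
        (t, shares[i])
        for i, t in enumerate(table.taxon_ids)
        if present[i] >= min_samples_present
    ]
    overlap: dict[tuple[str, str], float] = {}
    for (tj, pj), (tk, pk) in combinations(eligible, 2):
        overlap[(tj, tk)] = pianka_overlap(pj, pk)
    community_breadth = (
        float(np.mean([breadth[t] for t, _ in eligible])) if eligible else float("nan")
    )
    community_overlap = (
        float(np.mean(list(overlap.values()))) if overlap else float("nan")
    )
    return NicheResult(breadth, overlap, community_breadth, community_overlap)


def pac(ap_mg_kg: float, tp_g_kg: float) -> float:
    """Phosphorus activation coefficient: available P over total P on a common
    unit scale, PAC = (AP/1000)/TP with AP in mg/kg and TP in g/kg."""
    if tp_g_kg <= 0:
        raise ValidationError("total phosphorus must be positive")
    if ap_mg_kg < 0:
        raise ValidationError("available phosphorus must be non-negative")
    return (ap_mg_kg / 1000.0) / tp_g_kg


def fit_temporal_slope(
    values: Mapping[int, Sequence[tuple[float, float]]] | Sequence[tuple[float, float]],
    group: str = "",
) -> SlopeFit:
    """OLS slope of an index against year.

    ``values`` is either a mapping replicate → [(year, value), ...] or a flat
    [(year, value), ...] sequence (treated as one replicate). The headline
    slope/r²/p come from a pooled OLS over all points; one OLS slope per
    replicate is additionally stored for slope comparison between groups.
    Requires at least 3 distinct years.
    """
    if isinstance(values, Mapping):
        per_rep = {k: list(v) for k, v in values.items()}
    else:
        per_rep = {1: list(values)}
    all_pts = [pt for pts in per_rep.values() for pt in pts]
    years = [y for y, _ in all_pts]
    if len(set(years)) < 3:
        raise ValidationError("need at least 3 distinct years to fit a slope")
    x = np.array([y for y, _ in all_pts], dtype=float)
    yv = np.array([v for _, v in all_pts], dtype=float)
    res = stats.linregress(x, yv)
    rep_slopes = []
    for pts in per_rep.values():
        if len({y for y, _ in pts}) >= 2:
            rx = np.array([y for y, _ in pts], dtype=float)
            ry = np.array([v for _, v in pts], dtype=float)
            rep_slopes.append(float(stats.linregress(rx, ry).slope))
    return SlopeFit(
        group=group,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        per_replicate_slopes=rep_slopes,
    )


def compare_slopes(a: SlopeFit, b: SlopeFit) -> tuple[float, float]:
    """Welch two-sample t-test on the two groups' per-replicate slopes.

    Returns (t statistic, two-sided p). The unit of replication is the field
    replicate: each replicate contributes one fitted slope.
    """
    sa, sb = a.per_replicate_slopes, b.per_replicate_slopes
    if len(sa) < 2 or len(sb) < 2:
        raise ValidationError("slope comparison needs >= 2 replicate slopes per group")
    if np.allclose(sa, sb) and np.var(sa) == 0 and np.var(sb) == 0:
        return 0.0, 1.0
    t, p = stats.ttest_ind(sa, sb, equal_var=False)
    return float(t), float(p)
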