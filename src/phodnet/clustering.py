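"""Fuzzy c-means clustering of taxon temporal trajectories.

Per treatment, each taxon's trajectory is its mean relative abundance per
year, z-scored across years so clustering groups shapes rather than
abundances. Standard fuzzy c-means (fuzzifier m, default 2) alternates
membership updates (inverse-distance ratios with exponent 2/(m−1)) and
centroid updates (membership^m-weighted means) until the objective change
falls below tolerance. A taxon counts as "temporally responsive" when it is
confidently assigned (max membership above a cutoff) to a cluster whose
centroid actually moves (range across years above an amplitude cutoff, in
standardized units).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from phodnet.core_io import OtuTable, SampleMetadata, relative_abundance
from phodnet.errors import ConvergenceError, ValidationError


@dataclass
class FuzzyClustering:
    taxon_ids: list[str]
    centroids: np.ndarray  # n_clusters × n_years, standardized units
    membership: np.ndarray  # n_taxa × n_clusters, rows sum to 1
    fuzzifier: float
    n_clusters: int
    seed: int
    objective_value: float

    def hard_assignment(self) -> np.ndarray:
        """Cluster index of each taxon's maximum membership."""
        return self.membership.argmax(axis=1)


def standardize_profiles(
    table: OtuTable, metadata: list[SampleMetadata], treatment: str
) -> tuple[np.ndarray, list[str], list[int]]:
    """Taxon × year matrix of z-scored yearly mean relative abundances.

    Returns (profiles, taxon_ids, years). Taxa with zero variance across
    years are dropped (their z-profile is undefined); requires at least
    3 years of samples for the treatment.
    """
    samples = [m for m in metadata if m.treatment == treatment]
    if not samples:
        raise ValidationError(f"no samples for treatment {treatment!r}")
    years = sorted({m.year for m in samples})
    if len(years) < 3:
        raise ValidationError(f"treatment {treatment!r} has fewer than 3 years")
    rel = relative_abundance(table)
    col = {s: i for i, s in enumerate(rel.sample_ids)}
    yearly = np.column_stack(
        [
            rel.counts[:, [col[m.sample_id] for m in samples if m.year == y]].mean(axis=1)
            for y in years
        ]
    )
    sd = yearly.std(axis=1, ddof=0)
    keep = sd > 0
    z = (yearly[keep] - yearly[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
    kept_ids = [t for t, k in zip(rel.taxon_ids, keep) if k]
    return z, kept_ids, years


def fuzzy_cmeans(
    profiles: np.ndarray,
    n_clusters: int,
    m: float = 2.0,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
    taxon_ids: list[str] | None = None,
) -> FuzzyClustering:
    """Fuzzy c-means with the standard alternating updates.

    The objective J = Σ_ij u_ij^m d_ij² is non-increasing across iterations;
    the run is deterministic given the seed (random initial memberships).
    A point coinciding exactly with a centroid receives crisp membership
    there. Raises :class:`ConvergenceError` when the data have fewer distinct
    profiles than requested clusters.
    """
    x = np.asarray(profiles, dtype=float)
    if x.ndim != 2:
        raise ValidationError("profiles must be a 2-D taxon × year matrix")
    n, _ = x.shape
    if not (1 <= n_clusters <= n):
        raise ValidationError("n_clusters must lie in [1, n_taxa]")
    if m <= 1:
        raise ValidationError("fuzzifier m must be > 1")
    n_distinct = np.unique(x, axis=0).shape[0]
    if n_clusters > n_distinct:
        raise ConvergenceError(
            f"{n_clusters} clusters requested but only {n_distinct} distinct profiles"
        )
    ids = taxon_ids if taxon_ids is not None else [f"T{i}" for i in range(n)]
    if n_clusters == 1:
        centroid = x.mean(axis=0, keepdims=True)
        d2 = ((x - centroid) ** 2).sum(axis=1)
        return FuzzyClustering(
            list(ids), centroid, np.ones((n, 1)), m, 1, seed, float(d2.sum())
        )

    rng = np.random.default_rng(seed)
    u = rng.random((n, n_clusters))
    u /= u.sum(axis=1, keepdims=True)
    prev_obj = np.inf
    obj = np.inf
    for _ in range(max_iter):
        w = u**m
        centroids = (w.T @ x) / w.sum(axis=0)[:, None]
        d2 = ((x[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        obj = float((w * d2).sum())
        # alternating minimization: J may not increase (small slack for fp noise)
        assert obj <= prev_obj + 1e-9 * max(1.0, abs(prev_obj))
        zero = d2 <= 1e-300
        any_zero = zero.any(axis=1)
        with np.errstate(divide="ignore"):
            inv = d2 ** (-1.0 / (m - 1.0))  # (1/d)^{2/(m-1)} applied to d²
        u_new = inv / inv.sum(axis=1, keepdims=True)
        if any_zero.any():
            u_new[any_zero] = 0.0
            u_new[any_zero] = zero[any_zero] / zero[any_zero].sum(axis=1, keepdims=True)
        if abs(prev_obj - obj) < tol:
            u = u_new
            break
        u = u_new
        prev_obj = obj
    return FuzzyClustering(
        list(ids), centroids, u, m, n_clusters, seed, obj
    )


def partition_coefficient(fc: FuzzyClustering) -> float:
    """Fuzzy partition coefficient (1/n) Σ u²; 1 = crisp, 1/c = maximally fuzzy."""
    return float((fc.membership**2).sum() / fc.membership.shape[0])


def count_responsive_otus(
    fc: FuzzyClustering,
    membership_min: float = 0.5,
    amplitude_min: float = 1.0,
) -> dict:
    """Count taxa whose temporal profile changes over years.

    A taxon is responsive iff its maximum membership is at least
    ``membership_min`` and the centroid of that cluster has range (max − min
    across years, standardized units) at least ``amplitude_min``. Returns the
    total plus a per-cluster breakdown and the parameters used.
    """
    ranges = fc.centroids.max(axis=1) - fc.centroids.min(axis=1)
    best = fc.hard_assignment()
    best_u = fc.membership.max(axis=1)
    responsive = (best_u >= membership_min) & (ranges[best] >= amplitude_min)
    per_cluster = {
        int(c): int(((best == c) & responsive).sum()) for c in range(fc.n_clusters)
    }
    return {
        "total": int(responsive.sum()),
        "per_cluster": per_cluster,
        "membership_min": membership_min,
        "amplitude_min": amplitude_min,
    }
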