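"""Network stability panel: natural connectivity, robustness under random taxon
removal, vulnerability, and community cohesion.

Natural connectivity is the spectral robustness measure
ln((1/N) Σ_i exp(λ_i)) over the eigenvalues λ_i of the unsigned, unweighted
adjacency matrix; it decreases monotonically under edge deletion. Robustness
is summarized as the trajectory of natural connectivity while random fractions
of taxa are removed. Vulnerability is the worst-case relative drop in global
efficiency caused by deleting a single node. Cohesion follows the
Herren–McMahon recipe: per-taxon connectedness is the mean null-corrected
pairwise correlation with other taxa (split by sign), and per-sample cohesion
weights connectedness by relative abundance; the |negative|:positive cohesion
ratio (NPC) indexes the dominance of negative associations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
from scipy.special import logsumexp

from phodnet.core_io import OtuTable, SignedNetwork, relative_abundance
from phodnet.errors import ValidationError


@dataclass
class RobustnessCurve:
    fractions_removed: list[float]
    mean_connectivity: list[float]
    sd_connectivity: list[float]
    n_repetitions: int
    seed: int
    auc: float  # trapezoid area under the mean curve over the fraction axis


@dataclass
class VulnerabilityResult:
    per_node: dict[str, float]
    network_vulnerability: float  # max over nodes; <= 1 always
    global_efficiency: float  # baseline E of the intact network


@dataclass
class CohesionResult:
    connectedness_pos: dict[str, float]
    connectedness_neg: dict[str, float]
    cohesion_pos: dict[str, float]  # per sample, >= 0
    cohesion_neg: dict[str, float]  # per sample, <= 0
    npc: dict[str, float]  # per sample, |C-|/C+; NaN when C+ == 0
    n_null: int
    seed: int


def _adjacency(net: SignedNetwork) -> np.ndarray:
    """Unsigned, unweighted 0/1 adjacency in node_ids order."""
    idx = {n: i for i, n in enumerate(net.node_ids)}
    a = np.zeros((net.n_nodes, net.n_nodes))
    for u, v, _, _ in net.edges:
        a[idx[u], idx[v]] = a[idx[v], idx[u]] = 1.0
    return a


def natural_connectivity(net: SignedNetwork) -> float:
    """ln of the mean exponentiated adjacency eigenvalue; 0 for edgeless graphs."""
    if net.n_nodes == 0:
        raise ValidationError("empty node set")
    if net.n_edges == 0:
        return 0.0
    lam = np.linalg.eigvalsh(_adjacency(net))
    return float(logsumexp(lam) - np.log(net.n_nodes))


def _natural_connectivity_adj(a: np.ndarray) -> float:
    if a.shape[0] == 0:
        raise ValidationError("empty node set")
    if not a.any():
        return 0.0
    lam = np.linalg.eigvalsh(a)
    return float(logsumexp(lam) - np.log(a.shape[0]))


def robustness_curve(
    net: SignedNetwork,
    fractions: Sequence[float] | None = None,
    n_reps: int = 100,
    seed: int = 0,
) -> RobustnessCurve:
    """Natural connectivity as taxa are removed uniformly at random.

    For each fraction f and repetition, ⌊fN⌋ nodes are removed (without
    replacement) and natural connectivity of the induced subgraph recorded.
    Each (fraction, repetition) cell uses a dedicated generator stream derived
    from the master seed, so curves are stable under re-ordering of the grid.
    Default grid: 0 to 0.8 in steps of 0.05.
    """
    if fractions is None:
        fractions = [round(0.05 * i, 2) for i in range(17)]  # 0.0 .. 0.8
    fractions = list(fractions)
    if any(f < 0 or f >= 1 for f in fractions):
        raise ValidationError("fractions must lie in [0, 1)")
    if sorted(fractions) != fractions:
        raise ValidationError("fractions must be sorted ascending")
    if n_reps < 1:
        raise ValidationError("n_reps must be >= 1")
    a = _adjacency(net)
    n = net.n_nodes
    means, sds = [], []
    for fi, f in enumerate(fractions):
        n_remove = int(np.floor(f * n))
        if n_remove == 0:
            nc = _natural_connectivity_adj(a)
            means.append(nc)
            sds.append(0.0)
            continue
        vals = np.empty(n_reps)
        for rep in range(n_reps):
            rng = np.random.default_rng([seed, fi, rep])
            keep = np.setdiff1d(
                np.arange(n), rng.choice(n, size=n_remove, replace=False)
            )
            vals[rep] = _natural_connectivity_adj(a[np.ix_(keep, keep)])
        means.append(float(vals.mean()))
        sds.append(float(vals.std(ddof=0)))
    auc = float(np.trapezoid(means, fractions)) if len(fractions) > 1 else 0.0
    return RobustnessCurve(fractions, means, sds, n_reps, seed, auc)


def global_efficiency(net: SignedNetwork) -> float:
    """E = (1/(N(N−1))) Σ_{i≠j} 1/d_ij on the unweighted graph; disconnected
    pairs contribute 0."""
    if net.n_nodes < 2:
        raise ValidationError("global efficiency needs at least 2 nodes")
    g = nx.Graph()
    g.add_nodes_from(net.node_ids)
    g.add_edges_from((a, b) for a, b, _, _ in net.edges)
    return float(nx.global_efficiency(g))


def vulnerability(net: SignedNetwork) -> VulnerabilityResult:
    """Per-node vulnerability V_i = (E − E_i)/E with E_i the global efficiency
    of the graph with node i deleted (normalized over the remaining N−1
    nodes); the network value is the maximum V_i and never exceeds 1."""
    if net.n_nodes < 3:
        raise ValidationError("vulnerability needs at least 3 nodes")
    g = nx.Graph()
    g.add_nodes_from(net.node_ids)
    g.add_edges_from((a, b) for a, b, _, _ in net.edges)
    e0 = float(nx.global_efficiency(g))
    if e0 == 0:
        raise ValidationError("baseline efficiency is zero")
    per_node: dict[str, float] = {}
    for node in net.node_ids:
        h = g.copy()
        h.remove_node(node)
        per_node[node] = (e0 - float(nx.global_efficiency(h))) / e0
    return VulnerabilityResult(per_node, max(per_node.values()), e0)


def cohesion(
    table: OtuTable,
    n_null: int = 200,
    seed: int = 0,
    method: str = "pearson",
) -> CohesionResult:
    """Herren–McMahon cohesion with a taxon-shuffle null model.

    Observed pairwise correlations between taxa are computed across samples on
    relative abundances. The null expectation per pair is the mean correlation
    over ``n_null`` randomizations in which each taxon's abundances are
    shuffled across samples independently. Corrected correlation = observed −
    null mean. Per-taxon connectedness is the mean of its positive (resp.
    negative) corrected correlations, and per-sample cohesion is the
    relative-abundance-weighted sum of connectedness:
    C⁺_i = Σ_j a_ij · conn⁺_j ≥ 0 and C⁻_i = Σ_j a_ij · conn⁻_j ≤ 0.
    NPC_i = |C⁻_i| / C⁺_i (NaN-flagged when C⁺_i = 0).

    ``method`` selects the pairwise correlation ("pearson" default, or
    "spearman"). Requires at least 5 samples; fewer than 10 null repetitions
    triggers a warning. Deterministic given the seed.
    """
    if table.n_samples < 5:
        raise ValidationError("cohesion needs at least 5 samples")
    if n_null < 1:
        raise ValidationError("n_null must be >= 1")
    if n_null < 10:
        warnings.warn("n_null < 10 gives a noisy null expectation")
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    rel = relative_abundance(table).counts
    n_taxa, n_samples = rel.shape
    if n_taxa < 2:
        zero = {t: 0.0 for t in table.taxon_ids}
        return CohesionResult(
            dict(zero), dict(zero),
            {s: 0.0 for s in table.sample_ids},
            {s: 0.0 for s in table.sample_ids},
            {s: float("nan") for s in table.sample_ids},
            n_null, seed,
        )

    obs = _pairwise_corr(rel, method)
    rng = np.random.default_rng(seed)
    null_sum = np.zeros_like(obs)
    for _ in range(n_null):
        shuffled = np.empty_like(rel)
        for j in range(n_taxa):
            shuffled[j] = rel[j, rng.permutation(n_samples)]
        null_sum += _pairwise_corr(shuffled, method)
    corrected = obs - null_sum / n_null
    np.fill_diagonal(corrected, np.nan)
    conn_pos, conn_neg, c_pos, c_neg, npc = cohesion_from_corrected(corrected, rel)
    return CohesionResult(
        dict(zip(table.taxon_ids, conn_pos.tolist())),
        dict(zip(table.taxon_ids, conn_neg.tolist())),
        dict(zip(table.sample_ids, c_pos.tolist())),
        dict(zip(table.sample_ids, c_neg.tolist())),
        dict(zip(table.sample_ids, npc.tolist())),
        n_null,
        seed,
    )


def cohesion_from_corrected(
    corrected: np.ndarray, rel: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Connectedness and per-sample cohesion from a null-corrected correlation
    matrix (diagonal ignored) and a taxon × sample relative-abundance matrix.

    Returns (conn_pos, conn_neg, c_pos, c_neg, npc). If every off-diagonal
    corrected correlation is positive, negative cohesion is identically zero
    and NPC is zero wherever positive cohesion is nonzero.
    """
    n_taxa = corrected.shape[0]
    conn_pos = np.zeros(n_taxa)
    conn_neg = np.zeros(n_taxa)
    mask = ~np.eye(n_taxa, dtype=bool)
    for j in range(n_taxa):
        row = corrected[j][mask[j]]
        pos = row[np.isfinite(row) & (row > 0)]
        neg = row[np.isfinite(row) & (row < 0)]
        conn_pos[j] = pos.mean() if pos.size else 0.0
        conn_neg[j] = neg.mean() if neg.size else 0.0
    c_pos = rel.T @ conn_pos  # per sample
    c_neg = rel.T @ conn_neg
    npc = np.where(c_pos > 0, np.abs(c_neg) / np.where(c_pos > 0, c_pos, 1.0), np.nan)
    return conn_pos, conn_neg, c_pos, c_neg, npc


def _pairwise_corr(rows: np.ndarray, method: str) -> np.ndarray:
    """Taxon × taxon correlation across samples; constant rows give NaN."""
    if method == "spearman":
        from scipy.stats import rankdata

        rows = np.apply_along_axis(rankdata, 1, rows)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(rows)
    return np.atleast_2d(c)
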