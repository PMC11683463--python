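"""Signed co-occurrence network inference and topological property panel.

Networks follow the common amplicon recipe: pairwise Spearman rank correlation
between taxa across samples, an edge kept only when the correlation is strong
(|r| above a threshold, default 0.8) and significant (p below a threshold,
default 0.01, uncorrected; Benjamini–Hochberg available by flag). Topology
metrics (mean degree, clustering, path length, density, modularity, the
negative:positive edge ratio NPE) are computed on the unsigned, unweighted
graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
from scipy import stats

from phodnet.core_io import OtuTable, SignedNetwork
from phodnet.errors import ValidationError


@dataclass
class CorrelationResult:
    """Pairwise Spearman matrix with two-sided p-values.

    ``r`` has unit diagonal; the diagonal of ``p`` is not meaningful and set
    to NaN. ``taxon_ids`` aligns rows/columns with taxa that survived the
    prevalence filter.
    """

    taxon_ids: list[str]
    r: np.ndarray
    p: np.ndarray
    n_samples: int


@dataclass
class TopologyRecord:
    n_nodes: int
    n_edges: int
    n_positive_edges: int
    n_negative_edges: int
    npe: float  # negative:positive edge ratio; inf if no positive edges
    avg_degree: float
    avg_clustering: float
    avg_path_length: float
    density: float
    modularity: float
    module_assignment: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["npe"] = None if np.isinf(self.npe) else self.npe
        d["npe_undefined"] = bool(np.isinf(self.npe))
        return d


def spearman_matrix(table: OtuTable, min_prevalence: float = 1 / 3) -> CorrelationResult:
    """Spearman rank correlation between all retained taxon pairs.

    Taxa present (count > 0) in fewer than ``min_prevalence`` of samples are
    dropped before correlating — correlations driven by shared zeros are
    spurious. Ties get average ranks; p-values use the t-distribution
    approximation with n−2 degrees of freedom. Requires at least 4 samples.
    """
    if table.n_samples < 4:
        raise ValidationError("Spearman correlation needs at least 4 samples")
    prevalence = (table.counts > 0).mean(axis=1)
    keep = prevalence >= min_prevalence
    if keep.sum() < 2:
        raise ValidationError("fewer than 2 taxa pass the prevalence filter")
    ids = [t for t, k in zip(table.taxon_ids, keep) if k]
    data = table.counts[keep]
    r, p = stats.spearmanr(data, axis=1)
    if np.ndim(r) == 0:  # scipy collapses the 2-variable case to a scalar
        r = np.array([[1.0, float(r)], [float(r), 1.0]])
        p = np.array([[np.nan, float(p)], [float(p), np.nan]])
    r = np.asarray(r, dtype=float)
    p = np.asarray(p, dtype=float)
    np.fill_diagonal(r, 1.0)
    np.fill_diagonal(p, np.nan)
    return CorrelationResult(ids, r, p, table.n_samples)


def threshold_network(
    corr: CorrelationResult,
    r_min: float = 0.8,
    p_max: float = 0.01,
    correction: str = "none",
) -> SignedNetwork:
    """Keep edges with |r| > r_min and (adjusted) p < p_max.

    ``correction="BH"`` applies Benjamini–Hochberg across the upper-triangle
    p-values before thresholding. Nodes left without any edge are dropped from
    the network (their count is recoverable from the correlation result).
    """
    if correction not in ("none", "BH"):
        raise ValueError(f"unknown correction {correction!r}")
    n = len(corr.taxon_ids)
    iu, ju = np.triu_indices(n, k=1)
    pvals = corr.p[iu, ju]
    if correction == "BH":
        pvals = _benjamini_hochberg(pvals)
    edges: list[tuple[str, str, float, int]] = []
    used: set[str] = set()
    for i, j, pv in zip(iu, ju, pvals):
        r = corr.r[i, j]
        if np.isnan(r) or np.isnan(pv):
            continue
        if abs(r) > r_min and pv < p_max:
            a, b = corr.taxon_ids[i], corr.taxon_ids[j]
            edges.append((a, b, float(np.clip(r, -1, 1)), 1 if r > 0 else -1))
            used.update((a, b))
    nodes = [t for t in corr.taxon_ids if t in used]
    return SignedNetwork(nodes, edges)


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.sum() == 0:
        return out
    q = stats.false_discovery_control(p[ok], method="bh")
    out[ok] = q
    return out


def topology_metrics(net: SignedNetwork) -> TopologyRecord:
    """Topological property panel on the unsigned, unweighted graph.

    Average path length is the mean shortest-path length over connected node
    pairs only, so it stays defined for fragmented networks. Modularity uses
    deterministic greedy agglomerative maximization (ties broken by node-id
    order via sorted insertion).
    """
    if net.n_nodes == 0:
        raise ValidationError("empty network")
    g = nx.Graph()
    g.add_nodes_from(sorted(net.node_ids))
    g.add_edges_from((a, b) for a, b, _, _ in net.edges)
    n = g.number_of_nodes()
    e = g.number_of_edges()
    n_pos = sum(1 for _, _, _, s in net.edges if s > 0)
    n_neg = len(net.edges) - n_pos
    npe = n_neg / n_pos if n_pos > 0 else (0.0 if n_neg == 0 else float("inf"))
    avg_k = 2.0 * e / n
    density = 2.0 * e / (n * (n - 1)) if n > 1 else 0.0
    avg_cc = nx.average_clustering(g) if n > 0 else 0.0
    # mean shortest-path length over connected (unordered) pairs only
    total, pairs = 0.0, 0
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        if len(comp) < 2:
            continue
        for _, dists in nx.all_pairs_shortest_path_length(sub):
            total += sum(dists.values())
            pairs += len(dists) - 1
    apl = total / pairs if pairs else float("nan")
    if e > 0:
        communities = nx.algorithms.community.greedy_modularity_communities(g)
        modularity = nx.algorithms.community.modularity(g, communities)
        assignment = {
            node: ci for ci, comm in enumerate(communities) for node in comm
        }
    else:
        modularity = 0.0
        assignment = {node: i for i, node in enumerate(sorted(g.nodes))}
    return TopologyRecord(
        n_nodes=n,
        n_edges=e,
        n_positive_edges=n_pos,
        n_negative_edges=n_neg,
        npe=npe,
        avg_degree=avg_k,
        avg_clustering=float(avg_cc),
        avg_path_length=float(apl),
        density=float(density),
        modularity=float(modularity),
        module_assignment=assignment,
    )


def topology_property_correlation(
    metrics: Mapping[str, Sequence[float]],
    properties: Mapping[str, Sequence[float]],
) -> dict[tuple[str, str], dict[str, float | bool]]:
    """Pearson correlations between group-level network metrics and soil
    properties (or any other named vectors).

    Each metric/property is a vector over matched groups (same order, same
    length). Pairs with fewer than 3 finite paired observations, or with a
    constant vector, are flagged undefined instead of raising.
    """
    out: dict[tuple[str, str], dict[str, float | bool]] = {}
    for mname, mvals in metrics.items():
        for pname, pvals in properties.items():
            x = np.asarray(mvals, dtype=float)
            y = np.asarray(pvals, dtype=float)
            if x.shape != y.shape:
                raise ValidationError(
                    f"length mismatch between {mname} and {pname}"
                )
            ok = np.isfinite(x) & np.isfinite(y)
            entry: dict[str, float | bool] = {}
            if ok.sum() < 3 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
                entry = {"r": float("nan"), "p": float("nan"), "undefined": True}
            else:
                r, p = stats.pearsonr(x[ok], y[ok])
                entry = {"r": float(r), "p": float(p), "undefined": False}
            out[(mname, pname)] = entry
    return out


def group_samples_by_period(
    metadata, periods: Sequence[Sequence[int]]
) -> dict[tuple[str, str], list[str]]:
    """Partition sample ids into treatment × year-period groups.

    ``periods`` is a list of year sets (e.g. [[0, 1], [4, 5], [6, 7]]); each
    group is labelled "<treatment>:<y0>-<y1>".
    """
    out: dict[tuple[str, str], list[str]] = {}
    for m in metadata:
        for years in periods:
            if m.year in years:
                label = f"{min(years)}-{max(years)}"
                out.setdefault((m.treatment, label), []).append(m.sample_id)
    return out
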