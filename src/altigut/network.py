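"""Signed co-occurrence networks per altitude stratum.

Edges are pairs of taxa whose across-sample Spearman correlation within
a stratum is strong (|rho| > 0.60) and significant after
Benjamini-Hochberg adjustment over all tested pairs in that stratum
(adjusted P < 0.01).  Nodes are taxa incident to at least one kept
edge.  Modularity is computed on absolute edge weights with a seeded
Louvain community detection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import networkx as nx
import numpy as np
from scipy import stats

from .io_meta import AbundanceTable
from .trends import bh_adjust

logger = logging.getLogger(__name__)

R_THRESHOLD = 0.60
P_THRESHOLD = 0.01


def spearman_matrix(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All pairwise Spearman correlations among rows of X (features x
    samples) with two-sided p-values from the t approximation."""
    n = X.shape[1]
    R = stats.rankdata(X, axis=1)
    Rc = R - R.mean(axis=1, keepdims=True)
    norms = np.sqrt((Rc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        C = (Rc @ Rc.T) / np.outer(norms, norms)
    C = np.clip(C, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = C * np.sqrt((n - 2) / (1.0 - C**2))
    P = 2.0 * stats.t.sf(np.abs(t), n - 2)
    P = np.where(np.abs(C) >= 1.0, 0.0, P)
    return C, P


def build_network(
    table,
    sample_subset=None,
    r_threshold: float = R_THRESHOLD,
    p_threshold: float = P_THRESHOLD,
    stratum: str | None = None,
) -> nx.Graph:
    """Build one signed co-occurrence network from an abundance table.

    Zero-variance features within the subset are dropped before
    correlation (their rho is undefined); the BH family is all tested
    pairs within this (stratum) subset.
    """
    data = table.data if isinstance(table, AbundanceTable) else table
    if sample_subset is not None:
        data = data.loc[:, list(sample_subset)]
    n_samples = data.shape[1]
    if n_samples < 5:
        raise ValueError(
            f"need at least 5 samples to build a network"
            + (f" (stratum {stratum})" if stratum else "")
        )
    X = data.to_numpy(dtype=float)
    keep = np.ptp(X, axis=1) > 0
    dropped = int((~keep).sum())
    if dropped:
        logger.info("dropped %d zero-variance features%s", dropped,
                    f" in {stratum}" if stratum else "")
    features = data.index[keep]
    X = X[keep]

    G = nx.Graph(stratum=stratum, n_samples=n_samples)
    if features.size >= 2:
        C, P = spearman_matrix(X)
        iu, ju = np.triu_indices(features.size, k=1)
        p_adj = bh_adjust(np.clip(P[iu, ju], np.finfo(float).tiny, 1.0))
        mask = (np.abs(C[iu, ju]) > r_threshold) & (p_adj < p_threshold)
        domains = None
        if isinstance(table, AbundanceTable) and table.domain_label is not None:
            domains = table.domain_label
        for a, b, padj in zip(iu[mask], ju[mask], p_adj[mask]):
            rho = float(C[a, b])
            u, v = features[a], features[b]
            G.add_edge(u, v, rho=rho, sign=1 if rho > 0 else -1,
                       weight=abs(rho), p_adj=float(padj))
        if domains is not None:
            nx.set_node_attributes(
                G, {node: str(domains.get(node, "")) for node in G.nodes}, "domain"
            )
    return G


def build_stratum_networks(
    table,
    sample_frame,
    r_threshold: float = R_THRESHOLD,
    p_threshold: float = P_THRESHOLD,
) -> dict[str, nx.Graph]:
    """One network per stratum present in the sample frame (>= 5 samples
    required in every present stratum)."""
    nets = {}
    for stratum, sub in sample_frame.groupby("stratum", sort=True):
        nets[stratum] = build_network(
            table, sample_subset=sub.index, r_threshold=r_threshold,
            p_threshold=p_threshold, stratum=stratum,
        )
    return nets


@dataclass
class TopologySummary:
    stratum: str | None
    n_nodes: int
    n_edges: int
    avg_degree: float
    modularity: float
    pct_positive: float
    pct_negative: float
    empty: bool = False

    def to_dict(self) -> dict:
        return asdict(self)


def topology(network: nx.Graph, seed: int = 0) -> TopologySummary:
    """Node/edge counts, average degree 2E/N, seeded Louvain modularity on
    absolute weights, and the percentage of positive edges."""
    stratum = network.graph.get("stratum")
    N, E = network.number_of_nodes(), network.number_of_edges()
    if N == 0:
        return TopologySummary(stratum, 0, 0, 0.0, 0.0, 0.0, 0.0, empty=True)
    avg_degree = 2.0 * E / N
    if E == 0:
        modularity = 0.0
        pct_pos = 0.0
    else:
        communities = nx.community.louvain_communities(network, weight="weight", seed=seed)
        modularity = float(nx.community.modularity(network, communities, weight="weight"))
        pct_pos = 100.0 * sum(1 for _, _, d in network.edges(data=True) if d.get("rho", d.get("weight", 1)) > 0) / E
    return TopologySummary(
        stratum=stratum,
        n_nodes=N,
        n_edges=E,
        avg_degree=avg_degree,
        modularity=modularity,
        pct_positive=pct_pos,
        pct_negative=100.0 - pct_pos,
        empty=False,
    )


def degree_distribution(network: nx.Graph) -> dict:
    """Degree per node; the degree sum equals 2E (handshake lemma)."""
    return dict(network.degree())
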