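"""Thresholded Spearman co-occurrence networks and their topology.

Pairwise Spearman rank correlations across samples are computed for every
pair of retained taxa (plus optional covariate nodes such as bacterivore
abundances), two-sided p-values are adjusted with the Benjamini-Hochberg
step-up over the strict upper triangle, and an undirected signed graph
keeps the pairs with |r| above the correlation threshold and adjusted p
below the significance threshold (defaults 0.7 and 0.01).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InputError, ParameterError
from .io import OtuTable

logger = logging.getLogger("rhizonet")


@dataclass
class CorrelationResult:
    """Symmetric Spearman correlation and p-value matrices over retained variables."""

    ids: list[str]
    r: np.ndarray
    p_raw: np.ndarray
    p_adj: np.ndarray
    kinds: dict[str, str]  # id -> "taxon" | "nematode"

    @property
    def n(self) -> int:
        return len(self.ids)


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment.

    Preserves input order, enforces monotonicity, caps at 1.  Accepts any
    array-like of values in [0, 1]; returns an array of the same shape.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise InputError("p-values must lie in [0, 1]")
    flat = p.ravel()
    adj = multipletests(flat, method="fdr_bh")[1]
    return adj.reshape(p.shape)


def filter_taxa(table: OtuTable, prevalence_min: float = 0.0,
                abundance_min: float = 0.0) -> OtuTable:
    """Drop taxa below a prevalence (fraction of samples present) or mean
    relative abundance cut-off.  ``abundance_min`` is a fraction, e.g. the
    dominant-taxon filter 0.001 keeps taxa above 0.1% mean relative abundance."""
    counts = table.counts
    keep = pd.Series(True, index=counts.index)
    if prevalence_min > 0:
        keep &= (counts > 0).mean(axis=1) >= prevalence_min
    if abundance_min > 0:
        rel = counts / counts.sum(axis=0)
        keep &= rel.mean(axis=1) >= abundance_min
    kept = counts.loc[keep]
    tax = table.taxonomy.loc[keep] if table.taxonomy is not None else None
    return OtuTable(kept, taxonomy=tax, is_relative=table.is_relative)


def spearman_matrix(table: OtuTable, prevalence_min: float = 0.0,
                    abundance_min: float = 0.0,
                    covariates: pd.DataFrame | None = None) -> CorrelationResult:
    """All-pairs Spearman correlations with BH-adjusted two-sided p-values.

    ``covariates`` (samples x variables, e.g. bacterivore genus densities)
    enter the same correlation matrix as the taxa, flagged kind
    "nematode".  Zero-variance variables are excluded with a warning.
    Requires at least 4 samples.
    """
    table = filter_taxa(table, prevalence_min, abundance_min)
    data = table.counts  # taxa x samples
    n_samples = data.shape[1]
    if n_samples < 4:
        raise InputError(f"need >= 4 samples for correlation, got {n_samples}")

    kinds = {str(t): "taxon" for t in data.index}
    mat = data
    if covariates is not None:
        cov = covariates.loc[data.columns].T  # variables x samples
        mat = pd.concat([data, cov])
        kinds.update({str(c): "nematode" for c in cov.index})

    variances = mat.var(axis=1)
    degenerate = variances[variances == 0].index.tolist()
    if degenerate:
        logger.warning("excluding %d zero-variance variables: %s", len(degenerate), degenerate[:5])
        mat = mat.drop(index=degenerate)
        for d in degenerate:
            kinds.pop(str(d), None)
    if mat.shape[0] < 2:
        raise InputError("fewer than 2 variables with nonzero variance")

    res = stats.spearmanr(mat.to_numpy(), axis=1)
    r = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    if r.ndim == 0:  # scipy collapses the 2-variable case to scalars
        r = np.array([[1.0, float(r)], [float(r), 1.0]])
        p = np.array([[0.0, float(p)], [float(p), 0.0]])
    np.fill_diagonal(r, 1.0)
    np.fill_diagonal(p, 0.0)

    iu = np.triu_indices(mat.shape[0], k=1)
    p_adj = np.zeros_like(p)
    p_adj[iu] = adjust_bh(p[iu])
    p_adj = p_adj + p_adj.T

    ids = [str(i) for i in mat.index]
    return CorrelationResult(ids=ids, r=r, p_raw=p, p_adj=p_adj, kinds=kinds)


def build_network(corr: CorrelationResult, r_threshold: float = 0.7,
                  p_threshold: float = 0.01, use_adjusted: bool = True,
                  keep_isolates: bool = False,
                  node_attrs: pd.DataFrame | None = None) -> nx.Graph:
    """Graph over variables with an edge wherever |r| > r_threshold and
    p < p_threshold (BH-adjusted p by default)."""
    for name, value in (("r_threshold", r_threshold), ("p_threshold", p_threshold)):
        if not 0 < value < 1:
            raise ParameterError(f"{name} must lie strictly between 0 and 1")
    p = corr.p_adj if use_adjusted else corr.p_raw
    g = nx.Graph()
    for i, node in enumerate(corr.ids):
        attrs = {"kind": corr.kinds.get(node, "taxon")}
        if node_attrs is not None and node in node_attrs.index:
            attrs.update(node_attrs.loc[node].to_dict())
        g.add_node(node, **attrs)
    n = corr.n
    for i in range(n):
        for j in range(i + 1, n):
            rij = corr.r[i, j]
            if abs(rij) > r_threshold and p[i, j] < p_threshold:
                g.add_edge(corr.ids[i], corr.ids[j], r=float(rij),
                           sign=1 if rij > 0 else -1)
    if not keep_isolates:
        g.remove_nodes_from(list(nx.isolates(g)))
    return g


@dataclass
class TopologyStats:
    """The topological summary reported for each co-occurrence network."""

    n_nodes: int
    n_edges: int
    n_positive: int
    n_negative: int
    neg_pos_ratio: float
    avg_path_length: float    # largest connected component, unweighted
    density: float
    diameter: int             # largest connected component
    avg_clustering: float
    avg_degree: float
    modularity: float | None = None

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def topology_summary(network: nx.Graph, partition: dict | None = None) -> TopologyStats:
    """Node/edge counts, sign ratio, path metrics (largest component) and
    density/clustering/mean degree; modularity if a partition is given."""
    if network.number_of_nodes() == 0:
        raise InputError("empty network")
    n = network.number_of_nodes()
    m = network.number_of_edges()
    pos = sum(1 for _, _, d in network.edges(data=True) if d.get("sign", 1) > 0)
    neg = m - pos
    if m:
        comp = max(nx.connected_components(network), key=len)
        sub = network.subgraph(comp)
        apl = nx.average_shortest_path_length(sub) if len(comp) > 1 else 0.0
        diam = nx.diameter(sub) if len(comp) > 1 else 0
    else:
        apl, diam = 0.0, 0
    modularity = None
    if partition is not None and m:
        communities: dict = {}
        for node, mod in partition.items():
            communities.setdefault(mod, set()).add(node)
        modularity = nx.community.modularity(network, communities.values())
    return TopologyStats(
        n_nodes=n,
        n_edges=m,
        n_positive=pos,
        n_negative=neg,
        neg_pos_ratio=neg / pos if pos else float("inf") if neg else 0.0,
        avg_path_length=apl,
        density=nx.density(network),
        diameter=diam,
        avg_clustering=nx.average_clustering(network) if n else 0.0,
        avg_degree=2 * m / n,
        modularity=modularity,
    )
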