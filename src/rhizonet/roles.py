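"""Module detection, within/among-module connectivity and node roles.

Nodes are classified by the within-module connectivity Z score and the
among-module connectivity (participation) P score.  Z standardises a
node's number of links inside its own module against the other members of
that module; P measures how evenly its links spread across modules:

    Z_i = (kappa_i - mean(kappa | module s_i)) / sd(kappa | module s_i)
    P_i = 1 - sum_t (kappa_it / k_i)^2

Role thresholds (strict inequalities): peripheral (Z < 2.5, P < 0.62),
module hub (Z > 2.5, P < 0.62), connector (Z < 2.5, P > 0.62), network hub
(Z > 2.5, P > 0.62).  Module hubs, connectors and network hubs together
form the potential keystone set.  Graphs are treated as unweighted and
unsigned throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .errors import DegenerateModuleError, InputError, ParameterError
from .io import OtuTable

logger = logging.getLogger("rhizonet")

Z_CUT_DEFAULT = 2.5
P_CUT_DEFAULT = 0.62

ROLE_PERIPHERAL = "peripheral"
ROLE_MODULE_HUB = "module hub"
ROLE_CONNECTOR = "connector"
ROLE_NETWORK_HUB = "network hub"
KEYSTONE_ROLES = frozenset({ROLE_MODULE_HUB, ROLE_CONNECTOR, ROLE_NETWORK_HUB})


@dataclass
class ModulePartition:
    """Node -> module-id mapping with per-module sizes and modularity."""

    membership: dict[str, int]
    sizes: dict[int, int]
    modularity: float

    def modules(self) -> dict[int, set]:
        out: dict[int, set] = {}
        for node, mod in self.membership.items():
            out.setdefault(mod, set()).add(node)
        return out


def detect_modules(network: nx.Graph, method: str = "louvain",
                   seed: int | None = None) -> ModulePartition:
    """Community detection on the unweighted, unsigned graph.

    ``method``: "louvain" (seeded Louvain modularity maximisation,
    default; a seed of None is pinned to 0 so results stay
    deterministic), "greedy" (agglomerative greedy modularity — fully
    deterministic but known to merge weakly linked module pairs), or
    "label-propagation".  Module ids are assigned by decreasing size with
    ties broken by smallest member id, so the labelling is stable.  A
    graph without edges yields singleton modules with a warning.
    """
    if network.number_of_nodes() == 0:
        raise InputError("empty network")
    g = nx.Graph()
    g.add_nodes_from(sorted(network.nodes(), key=str))
    g.add_edges_from(network.edges())
    if g.number_of_edges() == 0:
        logger.warning("network has no edges; every node becomes its own module")
        communities = [{n} for n in g.nodes()]
    elif method == "louvain":
        communities = [set(c) for c in
                       nx.community.louvain_communities(g, seed=0 if seed is None else seed)]
    elif method == "greedy":
        communities = [set(c) for c in nx.community.greedy_modularity_communities(g)]
    elif method == "label-propagation":
        communities = [set(c) for c in nx.community.asyn_lpa_communities(g, seed=seed)]
    else:
        raise ParameterError(f"unknown community detection method {method!r}")

    communities.sort(key=lambda c: (-len(c), min(str(n) for n in c)))
    membership = {node: i for i, comm in enumerate(communities) for node in comm}
    sizes = {i: len(comm) for i, comm in enumerate(communities)}
    if g.number_of_edges():
        q = nx.community.modularity(g, communities)
    else:
        q = 0.0
    return ModulePartition(membership=membership, sizes=sizes, modularity=q)


def zp_scores(network: nx.Graph, partition: ModulePartition | dict) -> pd.DataFrame:
    """Per-node degree, within-module degree, Z and P.

    Degenerate cases follow the documented conventions: Z = 0 when every
    member of a module has the same within-module degree (sd undefined),
    P = 0 for isolated nodes.
    """
    membership = partition.membership if isinstance(partition, ModulePartition) else partition
    missing = [n for n in network.nodes() if n not in membership]
    if missing:
        raise InputError(f"partition does not cover nodes: {missing[:5]}")

    nodes = list(network.nodes())
    within = {}
    per_module_links: dict = {}
    for node in nodes:
        own = membership[node]
        counts: dict[int, int] = {}
        for nb in network.neighbors(node):
            counts[membership[nb]] = counts.get(membership[nb], 0) + 1
        per_module_links[node] = counts
        within[node] = counts.get(own, 0)

    # moments of the within-module degree, per module
    module_members: dict[int, list] = {}
    for node in nodes:
        module_members.setdefault(membership[node], []).append(node)
    z = {}
    for mod, members in module_members.items():
        kappas = np.array([within[m] for m in members], dtype=float)
        mean, sd = kappas.mean(), kappas.std()  # population sd over module members
        if sd == 0:
            if len(members) > 1:
                logger.debug("module %s has constant within-degree; Z set to 0", mod)
            for m in members:
                z[m] = 0.0
        else:
            for m in members:
                z[m] = (within[m] - mean) / sd

    rows = []
    for node in nodes:
        k = network.degree(node)
        if k == 0:
            p_score = 0.0
        else:
            p_score = 1.0 - sum((c / k) ** 2 for c in per_module_links[node].values())
        rows.append(
            {
                "node": node,
                "module": membership[node],
                "degree": k,
                "within_module_degree": within[node],
                "Z": z[node],
                "P": p_score,
            }
        )
    return pd.DataFrame(rows).set_index("node")


def classify_roles(roles: pd.DataFrame, z_cut: float = Z_CUT_DEFAULT,
                   p_cut: float = P_CUT_DEFAULT) -> pd.DataFrame:
    """Fill the role column from (Z, P) with strict threshold inequalities.

    A node lying exactly on a threshold falls on the low side (printed
    tables can show boundary values like P = 0.62 through rounding; the
    classification always uses the unrounded scores).
    """
    out = roles.copy()
    high_z = out["Z"] > z_cut
    high_p = out["P"] > p_cut
    role = np.where(
        high_z & high_p, ROLE_NETWORK_HUB,
        np.where(high_z, ROLE_MODULE_HUB, np.where(high_p, ROLE_CONNECTOR, ROLE_PERIPHERAL)),
    )
    out["role"] = role
    out["keystone"] = out["role"].isin(KEYSTONE_ROLES)
    return out


def node_roles(network: nx.Graph, partition: ModulePartition | dict,
               z_cut: float = Z_CUT_DEFAULT, p_cut: float = P_CUT_DEFAULT) -> pd.DataFrame:
    """Convenience: zp_scores followed by classify_roles."""
    return classify_roles(zp_scores(network, partition), z_cut=z_cut, p_cut=p_cut)


@dataclass
class ModuleEigengene:
    """First principal component of a module's member-abundance matrix."""

    module_id: int | str
    eigengene: pd.Series          # per-sample values, unit norm
    variance_explained: float


def module_eigengene(table: OtuTable, partition: ModulePartition | dict,
                     module_id) -> ModuleEigengene:
    """Summarise a module by its eigengene.

    Member abundances are standardised per taxon (zero mean, unit
    variance across samples) before the singular value decomposition; the
    eigengene is the leading right-singular vector over samples, with its
    sign fixed so it correlates non-negatively with the mean standardised
    member profile.  Variance explained is the leading squared singular
    value over the total.
    """
    membership = partition.membership if isinstance(partition, ModulePartition) else partition
    members = [t for t in table.taxon_ids if membership.get(t) == module_id]
    if len(members) < 2:
        raise DegenerateModuleError(
            f"module {module_id!r} has {len(members)} member(s) in the table; need >= 2"
        )
    X = table.counts.loc[members].to_numpy(dtype=float)  # members x samples
    sd = X.std(axis=1, keepdims=True)
    constant = (sd == 0).ravel()
    if constant.any():
        logger.warning("dropping %d constant member profiles from module %s",
                       int(constant.sum()), module_id)
        X = X[~constant]
        members = [m for m, c in zip(members, constant) if not c]
        if len(members) < 2:
            raise DegenerateModuleError(f"module {module_id!r} degenerate after dropping constants")
        sd = X.std(axis=1, keepdims=True)
    Xs = (X - X.mean(axis=1, keepdims=True)) / sd

    _, s, vt = np.linalg.svd(Xs, full_matrices=False)
    eig = vt[0]
    mean_profile = Xs.mean(axis=0)
    if np.dot(eig, mean_profile) < 0:
        eig = -eig
    var_explained = float(s[0] ** 2 / np.sum(s**2))
    return ModuleEigengene(
        module_id=module_id,
        eigengene=pd.Series(eig, index=table.sample_ids, name=f"ME{module_id}"),
        variance_explained=var_explained,
    )


def eigengene_trait_correlation(eigengene: ModuleEigengene, trait,
                                method: str = "pearson") -> tuple[float, float]:
    """Correlate a module eigengene with a sample-level trait (e.g. enzyme
    activity).  ``method`` is "pearson" (default) or "spearman"."""
    from scipy import stats

    trait = pd.Series(trait).loc[eigengene.eigengene.index]
    if method == "pearson":
        r, p = stats.pearsonr(eigengene.eigengene, trait)
    elif method == "spearman":
        r, p = stats.spearmanr(eigengene.eigengene, trait)
    else:
        raise ParameterError(f"unknown correlation method {method!r}")
    return float(r), float(p)
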