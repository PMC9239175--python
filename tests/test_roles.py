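import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from rhizonet import (
    DegenerateModuleError,
    InputError,
    OtuTable,
    classify_roles,
    detect_modules,
    module_eigengene,
    node_roles,
    zp_scores,
)


def _two_cliques_bridge() -> nx.Graph:
    g = nx.Graph()
    g.add_edges_from(itertools.combinations(range(4), 2))
    g.add_edges_from(itertools.combinations(range(4, 8), 2))
    g.add_edge(0, 4)
    return g


def _best_two_partition_modularity(g: nx.Graph) -> float:
    """Exhaustive modularity maximum over all 2-partitions (oracle)."""
    nodes = list(g.nodes())
    best = -1.0
    for mask in range(1, 2 ** (len(nodes) - 1)):
        a = {nodes[i] for i in range(len(nodes)) if mask >> i & 1}
        b = set(nodes) - a
        if a and b:
            best = max(best, nx.community.modularity(g, [a, b]))
    return best


@pytest.mark.parametrize("method", ["louvain", "greedy"])
def test_two_cliques_split_into_two_modules(method):
    g = _two_cliques_bridge()
    part = detect_modules(g, method=method)
    assert len(part.sizes) == 2
    modules = part.modules()
    assert {frozenset(m) for m in modules.values()} == {
        frozenset(range(4)), frozenset(range(4, 8))}
    # exhaustive oracle confirms the clique split is the optimal 2-partition
    assert part.modularity == pytest.approx(_best_two_partition_modularity(g))


def test_complete_graph_is_single_module():
    part = detect_modules(nx.complete_graph(6))
    assert len(part.sizes) == 1


def test_edgeless_graph_gives_singletons():
    g = nx.empty_graph(4)
    part = detect_modules(g)
    assert len(part.sizes) == 4
    assert part.modularity == 0.0


def test_p_zero_when_all_links_internal():
    g = _two_cliques_bridge()
    g.remove_edge(0, 4)
    part = detect_modules(g)
    scores = zp_scores(g, part)
    assert (scores["P"] == 0).all()


def test_p_half_for_even_two_module_split():
    g = nx.Graph()
    # node x with k=4 split 2/2 across two K3 modules
    g.add_edges_from([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
    g.add_edges_from([("x", 0), ("x", 1), ("x", 3), ("x", 4)])
    membership = {0: 0, 1: 0, 2: 0, 3: 1, 4: 1, 5: 1, "x": 0}
    scores = zp_scores(g, membership)
    assert scores.loc["x", "P"] == pytest.approx(1 - (0.25 + 0.25))


def _zp_bruteforce(g, membership):
    """Independent double-loop recount of Z and P."""
    rows = {}
    mods = set(membership.values())
    for node in g.nodes():
        k = g.degree(node)
        kappa = {m: 0 for m in mods}
        for nb in g.neighbors(node):
            kappa[membership[nb]] += 1
        own = membership[node]
        members = [n for n in g.nodes() if membership[n] == own]
        own_counts = []
        for m in members:
            c = sum(1 for nb in g.neighbors(m) if membership[nb] == own)
            own_counts.append(c)
        mean = np.mean(own_counts)
        sd = np.std(own_counts)
        z = 0.0 if sd == 0 else (kappa[own] - mean) / sd
        p = 0.0 if k == 0 else 1 - sum((v / k) ** 2 for v in kappa.values())
        rows[node] = (z, p)
    return rows


def test_zp_scores_match_bruteforce_oracle():
    rng = np.random.default_rng(0)
    for trial in range(50):
        n = int(rng.integers(6, 13))
        g = nx.gnp_random_graph(n, 0.4, seed=int(rng.integers(2**31)))
        membership = {i: int(rng.integers(3)) for i in g.nodes()}
        scores = zp_scores(g, membership)
        oracle = _zp_bruteforce(g, membership)
        for node, (z, p) in oracle.items():
            assert scores.loc[node, "Z"] == pytest.approx(z, abs=1e-12)
            assert scores.loc[node, "P"] == pytest.approx(p, abs=1e-12)


def test_z_standardised_within_modules():
    """Z has zero mean and unit sd inside every module, by construction."""
    g = nx.gnp_random_graph(40, 0.2, seed=1)
    part = detect_modules(g)
    scores = zp_scores(g, part)
    for mod, grp in scores.groupby("module"):
        z = grp["Z"].to_numpy()
        if len(z) > 1 and z.std() > 0:
            assert abs(z.mean()) < 1e-9
            assert z.std() == pytest.approx(1.0, abs=1e-9)


def test_p_bounded_below_one():
    g = nx.gnp_random_graph(30, 0.3, seed=2)
    part = detect_modules(g)
    scores = zp_scores(g, part)
    assert (scores["P"] >= 0).all() and (scores["P"] < 1).all()


@pytest.mark.parametrize(
    "z,p,expected",
    [
        (2.78, 0.08, "module hub"),
        (0.48, 0.63, "connector"),
        (-0.20, 0.64, "connector"),
        (1.0, 0.5, "peripheral"),
        (3.0, 0.7, "network hub"),
        (2.5, 0.62, "peripheral"),  # boundary values fall on the low side
    ],
)
def test_role_classification_thresholds(z, p, expected):
    df = pd.DataFrame({"Z": [z], "P": [p]}, index=["node"])
    out = classify_roles(df)
    assert out.loc["node", "role"] == expected
    assert out.loc["node", "keystone"] == (expected != "peripheral")


def test_eigengene_rank_one_module():
    profile = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 6.0, 8.0, 7.0])
    counts = pd.DataFrame([profile * c for c in (1, 2, 3, 4, 5)],
                          index=[f"t{i}" for i in range(5)],
                          columns=[f"S{j}" for j in range(8)])
    table = OtuTable(counts)
    membership = {f"t{i}": 0 for i in range(5)}
    me = module_eigengene(table, membership, 0)
    assert me.variance_explained == pytest.approx(1.0)
    standardized = (profile - profile.mean()) / profile.std()
    cosine = np.dot(me.eigengene, standardized) / np.linalg.norm(standardized)
    assert abs(cosine) == pytest.approx(1.0, abs=1e-10)


def test_eigengene_sign_convention_positive_vs_mean_profile():
    rng = np.random.default_rng(3)
    for _ in range(50):
        counts = pd.DataFrame(rng.poisson(50, size=(4, 8)).astype(float),
                              index=[f"t{i}" for i in range(4)],
                              columns=[f"S{j}" for j in range(8)])
        table = OtuTable(counts)
        me = module_eigengene(table, {f"t{i}": 0 for i in range(4)}, 0)
        X = counts.to_numpy()
        Xs = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, keepdims=True)
        assert np.dot(me.eigengene, Xs.mean(axis=0)) >= -1e-12
        assert np.linalg.norm(me.eigengene) == pytest.approx(1.0)


def test_eigengene_matches_covariance_eigendecomposition():
    rng = np.random.default_rng(4)
    counts = pd.DataFrame(rng.poisson(80, size=(4, 8)).astype(float),
                          index=[f"t{i}" for i in range(4)],
                          columns=[f"S{j}" for j in range(8)])
    table = OtuTable(counts)
    me = module_eigengene(table, {f"t{i}": 0 for i in range(4)}, 0)
    X = counts.to_numpy()
    Xs = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, keepdims=True)
    evals, evecs = np.linalg.eigh(Xs.T @ Xs)  # 8x8 sample covariance oracle
    lead = evecs[:, -1]
    cosine = abs(np.dot(me.eigengene, lead))
    assert cosine >= 1 - 1e-10
    assert me.variance_explained == pytest.approx(evals[-1] / evals.sum())


def test_degenerate_module_raises():
    counts = pd.DataFrame([[1, 2, 3]], index=["t0"], columns=["a", "b", "c"])
    with pytest.raises(DegenerateModuleError):
        module_eigengene(OtuTable(counts), {"t0": 0}, 0)


def test_partition_must_cover_network():
    g = nx.path_graph(3)
    with pytest.raises(InputError):
        zp_scores(g, {0: 0, 1: 0})
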