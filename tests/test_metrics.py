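import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rhizonet import (
    InputError,
    OtuTable,
    ParameterError,
    anosim,
    bray_curtis,
    chao1,
    pcoa,
    predation_pressure,
    rarefy,
    shannon,
)


def _table(matrix, samples=None):
    matrix = np.asarray(matrix)
    samples = samples or [f"S{j}" for j in range(matrix.shape[1])]
    return OtuTable(pd.DataFrame(matrix, index=[f"t{i}" for i in range(matrix.shape[0])],
                                 columns=samples))


# ---------------------------------------------------------------------------
# rarefaction
# ---------------------------------------------------------------------------

def test_rarefy_full_depth_is_identity():
    table = _table([[10, 4], [5, 6], [5, 10]])
    out = rarefy(table, 20, seed=0)
    pd.testing.assert_frame_equal(out.counts, table.counts)


def test_rarefied_samples_sum_exactly_to_depth():
    rng = np.random.default_rng(0)
    table = _table(rng.poisson(40, size=(30, 6)))
    out = rarefy(table, 500, seed=1)
    assert (out.counts.sum(axis=0) == 500).all()


def test_rarefy_drops_shallow_samples():
    table = _table([[100, 3], [100, 3]])
    out = rarefy(table, 50, seed=0)
    assert out.sample_ids == ["S0"]


def test_rarefaction_mean_matches_hypergeometric_expectation():
    counts = np.array([50, 30, 20])
    table = _table(counts.reshape(3, 1))
    depth = 40
    draws = np.zeros(3)
    for seed in range(1000):
        draws += rarefy(table, depth, seed=seed).counts.iloc[:, 0].to_numpy()
    means = draws / 1000
    expected = depth * counts / counts.sum()
    assert np.allclose(means, expected, rtol=0.02)


def test_rarefy_invalid_depth():
    with pytest.raises(ParameterError):
        rarefy(_table([[5]]), 0)


# ---------------------------------------------------------------------------
# alpha diversity
# ---------------------------------------------------------------------------

def test_shannon_uniform_maximum():
    assert shannon([7] * 10) == pytest.approx(math.log(10))


def test_shannon_scale_invariant():
    assert shannon([1, 2, 3]) == pytest.approx(shannon([10, 20, 30]))


def test_shannon_all_zero_is_error():
    with pytest.raises(InputError):
        shannon([0, 0])


def test_chao1_no_singletons_equals_observed():
    assert chao1([5, 5, 5]) == 3


def test_chao1_formula_example():
    # S_obs=10, F1=4, F2=2 -> 10 + 16/4 = 14
    counts = [1, 1, 1, 1, 2, 2, 5, 5, 5, 5]
    assert chao1(counts) == pytest.approx(14.0)
    assert len(counts) == 10


def test_chao1_at_least_observed_richness():
    rng = np.random.default_rng(0)
    for _ in range(20):
        c = rng.poisson(2, size=50)
        if c.sum() == 0:
            continue
        assert chao1(c) >= (c > 0).sum()


# ---------------------------------------------------------------------------
# Bray-Curtis and PCoA
# ---------------------------------------------------------------------------

def test_bray_curtis_identical_samples_zero():
    table = _table([[3, 3], [4, 4], [1, 1]])
    d = bray_curtis(table)
    assert d.iloc[0, 1] == pytest.approx(0.0)


def test_bray_curtis_disjoint_samples_one():
    table = _table([[5, 0], [3, 0], [0, 2], [0, 7]])
    assert bray_curtis(table).iloc[0, 1] == pytest.approx(1.0)


def test_bray_curtis_worked_example():
    # a=(6,2,0), b=(2,2,4): 1 - 2*4/16 = 0.5
    table = _table([[6, 2], [2, 2], [0, 4]])
    assert bray_curtis(table).iloc[0, 1] == pytest.approx(0.5)


def test_bray_curtis_zero_total_sample_errors():
    with pytest.raises(InputError, match="S1"):
        bray_curtis(_table([[3, 0], [1, 0]]))


@settings(max_examples=30, deadline=None)
@given(st.lists(st.lists(st.integers(min_value=0, max_value=50), min_size=3, max_size=3),
                min_size=2, max_size=6))
def test_bray_curtis_bounds_and_symmetry(rows):
    mat = np.array(rows).T  # taxa x samples
    if (mat.sum(axis=0) == 0).any():
        return
    d = bray_curtis(_table(mat)).to_numpy()
    assert (d >= -1e-12).all() and (d <= 1 + 1e-12).all()
    assert np.allclose(d, d.T)
    assert np.allclose(np.diag(d), 0)


def test_pcoa_recovers_right_triangle():
    d = pd.DataFrame([[0, 3, 4], [3, 0, 5], [4, 5, 0]],
                     index=list("abc"), columns=list("abc"), dtype=float)
    res = pcoa(d, k=2)
    coords = res.coordinates.to_numpy()
    from scipy.spatial.distance import pdist, squareform

    recovered = squareform(pdist(coords))
    assert np.allclose(recovered, d.to_numpy(), atol=1e-9)
    assert res.eigenvalues[0] >= res.eigenvalues[1]


def test_pcoa_duplicate_samples_coincide():
    d = pd.DataFrame([[0, 0, 2], [0, 0, 2], [2, 2, 0]],
                     index=list("abc"), columns=list("abc"), dtype=float)
    res = pcoa(d, k=2)
    assert np.allclose(res.coordinates.loc["a"], res.coordinates.loc["b"], atol=1e-9)


def test_pcoa_k_too_large():
    d = pd.DataFrame(np.zeros((3, 3)), index=list("abc"), columns=list("abc"))
    with pytest.raises(ParameterError):
        pcoa(d, k=3)


def test_pcoa_reports_negative_eigenvalues():
    # non-Euclidean distances: violating the triangle inequality strongly
    d = pd.DataFrame([[0, 1, 1, 2.9], [1, 0, 1, 1], [1, 1, 0, 1], [2.9, 1, 1, 0]],
                     index=list("abcd"), columns=list("abcd"), dtype=float)
    res = pcoa(d, k=2)
    assert res.eigenvalues.min() < 0


# ---------------------------------------------------------------------------
# ANOSIM
# ---------------------------------------------------------------------------

def _clustered_distance(n_per_group=6, gap=10.0, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(0, 0.5, size=(n_per_group, 2))
    b = rng.normal(gap, 0.5, size=(n_per_group, 2))
    pts = np.vstack([a, b])
    from scipy.spatial.distance import pdist, squareform

    ids = [f"s{i}" for i in range(2 * n_per_group)]
    d = pd.DataFrame(squareform(pdist(pts)), index=ids, columns=ids)
    groups = ["A"] * n_per_group + ["B"] * n_per_group
    return d, groups


def test_anosim_separated_clusters_r_near_one():
    d, groups = _clustered_distance()
    r, p = anosim(d, groups, n_perm=199, seed=1)
    assert r > 0.9
    assert p <= 0.01


def test_anosim_r_bounded():
    rng = np.random.default_rng(2)
    from scipy.spatial.distance import pdist, squareform

    for trial in range(10):
        pts = rng.normal(size=(10, 3))
        ids = [f"s{i}" for i in range(10)]
        d = pd.DataFrame(squareform(pdist(pts)), index=ids, columns=ids)
        groups = rng.permutation(["A"] * 5 + ["B"] * 5)
        r, p = anosim(d, groups, n_perm=99, seed=trial)
        assert -1 <= r <= 1
        assert 0 < p <= 1


def test_anosim_matches_scikit_bio():
    skbio_stats = pytest.importorskip("skbio.stats.distance")
    d, groups = _clustered_distance(gap=2.0, seed=5)
    r, _ = anosim(d, groups, n_perm=99, seed=0)
    dm = skbio_stats.DistanceMatrix(d.to_numpy(), ids=list(d.index))
    expected = skbio_stats.anosim(dm, grouping=list(groups), permutations=0)
    assert r == pytest.approx(expected["test statistic"], abs=1e-12)


def test_anosim_reproducible_and_group_validation():
    d, groups = _clustered_distance(seed=3)
    assert anosim(d, groups, n_perm=99, seed=4) == anosim(d, groups, n_perm=99, seed=4)
    with pytest.raises(InputError):
        anosim(d, ["A"] + ["B"] * 11, n_perm=99)


def test_pcoa_matches_scikit_bio():
    skbio_ord = pytest.importorskip("skbio.stats.ordination")
    skbio_dist = pytest.importorskip("skbio.stats.distance")
    d, _ = _clustered_distance(gap=3.0, seed=7)
    res = pcoa(d, k=2)
    ref = skbio_ord.pcoa(skbio_dist.DistanceMatrix(d.to_numpy(), ids=list(d.index)))
    ours = np.sort(res.eigenvalues)[::-1][:2]
    theirs = np.sort(ref.eigvals.to_numpy())[::-1][:2]
    assert np.allclose(ours, theirs, rtol=1e-8)


# ---------------------------------------------------------------------------
# predation pressure
# ---------------------------------------------------------------------------

def test_predation_pressure_arithmetic(metadata_frame):
    meta = metadata_frame.copy()
    meta.loc["S01", "bacterivore_density"] = 50.0
    meta.loc["S01", "phoD_abundance"] = 1e7
    out = predation_pressure(meta)
    assert out.loc["S01", "pressure"] == pytest.approx(5e-6)


def test_predation_pressure_zero_density(metadata_frame):
    meta = metadata_frame.copy()
    meta.loc["S02", "bacterivore_density"] = 0.0
    out = predation_pressure(meta)
    assert out.loc["S02", "pressure"] == 0.0


def test_predation_pressure_homogeneity(metadata_frame):
    base = predation_pressure(metadata_frame)["pressure"]
    doubled = metadata_frame.copy()
    doubled["phoD_abundance"] *= 2
    assert np.allclose(predation_pressure(doubled)["pressure"], base / 2)


def test_predation_pressure_flags_zero_abundance(metadata_frame):
    meta = metadata_frame.copy()
    meta.loc["S03", "phoD_abundance"] = 0.0
    out = predation_pressure(meta)
    assert np.isnan(out.loc["S03", "pressure"])
    assert "undefined" in out.loc["S03", "note"]
    assert out.drop("S03")["pressure"].notna().all()
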