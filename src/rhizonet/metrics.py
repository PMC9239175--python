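"""Diversity, ordination, group separation and predation pressure.

Implements the community statistics of the study design: rarefaction to a
fixed depth, Shannon (natural log) and Chao1 alpha diversity, Bray-Curtis
distances, classical PCoA, the rank-based ANOSIM permutation test, and
the predation-pressure ratio (bacterivore density over phoD-gene
abundance).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from .errors import InputError, ParameterError, ValidationError
from .io import OtuTable

logger = logging.getLogger("rhizonet")


# ---------------------------------------------------------------------------
# Rarefaction and alpha diversity
# ---------------------------------------------------------------------------

def rarefy(table: OtuTable, depth: int, seed: int | None = None) -> OtuTable:
    """Subsample each sample to exactly ``depth`` reads without replacement.

    Samples whose total falls below ``depth`` are dropped with a warning.
    Requires integer counts.
    """
    if depth <= 0:
        raise ParameterError("rarefaction depth must be positive")
    counts = table.counts.to_numpy()
    if not np.allclose(counts, np.round(counts)):
        raise ValidationError("rarefaction requires integer counts")
    counts = counts.astype(np.int64)
    rng = np.random.default_rng(seed)

    totals = counts.sum(axis=0)
    keep = totals >= depth
    dropped = [s for s, k in zip(table.sample_ids, keep) if not k]
    if dropped:
        logger.warning("dropping %d samples below depth %d: %s", len(dropped), depth, dropped)
    if not keep.any():
        raise InputError(f"no sample reaches depth {depth}")

    out = np.zeros((counts.shape[0], int(keep.sum())), dtype=np.int64)
    for j_out, j in enumerate(np.flatnonzero(keep)):
        out[:, j_out] = rng.multivariate_hypergeometric(counts[:, j], depth)
    kept_samples = [s for s, k in zip(table.sample_ids, keep) if k]
    return OtuTable(pd.DataFrame(out, index=table.taxon_ids, columns=kept_samples),
                    taxonomy=table.taxonomy)


def shannon(counts) -> float:
    """Shannon diversity, natural log, from a count or proportion vector."""
    c = np.asarray(counts, dtype=float)
    if (c < 0).any():
        raise InputError("counts must be non-negative")
    total = c.sum()
    if total == 0:
        raise InputError("all-zero count vector")
    p = c[c > 0] / total
    return float(-(p * np.log(p)).sum())


def chao1(counts) -> float:
    """Chao1 richness: S_obs + F1^2/(2 F2), with the bias-corrected
    fallback S_obs + F1(F1-1)/(2(F2+1)) when no doubletons exist."""
    c = np.asarray(counts)
    if (c < 0).any():
        raise InputError("counts must be non-negative")
    if c.sum() == 0:
        raise InputError("all-zero count vector")
    s_obs = int((c > 0).sum())
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    if f2 > 0:
        return s_obs + f1**2 / (2 * f2)
    return s_obs + f1 * (f1 - 1) / (2 * (f2 + 1))


@dataclass
class DiversityRecord:
    sample_id: str
    shannon: float
    chao1: float
    observed_richness: int
    depth: int | None = None


def alpha_diversity(table: OtuTable, rarefaction_depth: int | None = None,
                    seed: int | None = None) -> pd.DataFrame:
    """Per-sample Shannon, Chao1 and observed richness, optionally after
    rarefaction to a fixed depth."""
    if rarefaction_depth is not None:
        table = rarefy(table, rarefaction_depth, seed=seed)
    rows = []
    for s in table.sample_ids:
        c = table.counts[s].to_numpy()
        rows.append(
            {
                "sample_id": s,
                "shannon": shannon(c),
                "chao1": chao1(c),
                "observed_richness": int((c > 0).sum()),
                "depth": rarefaction_depth,
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


# ---------------------------------------------------------------------------
# Beta diversity and ordination
# ---------------------------------------------------------------------------

def bray_curtis(table: OtuTable) -> pd.DataFrame:
    """Pairwise Bray-Curtis distances between samples,
    d(a,b) = 1 - 2 sum(min(a_i, b_i)) / (sum a + sum b)."""
    if table.shape[1] < 2:
        raise InputError("need >= 2 samples for a distance matrix")
    totals = table.counts.sum(axis=0)
    empty = totals.index[totals == 0].tolist()
    if empty:
        raise InputError(f"Bray-Curtis undefined for zero-total samples: {empty}")
    x = table.counts.to_numpy().T  # samples x taxa
    d = squareform(pdist(x, metric="braycurtis"))
    return pd.DataFrame(d, index=table.sample_ids, columns=table.sample_ids)


@dataclass
class PCoAResult:
    coordinates: pd.DataFrame     # samples x axes
    eigenvalues: np.ndarray       # all eigenvalues, descending (negatives included)
    proportion_explained: np.ndarray


def pcoa(dist: pd.DataFrame, k: int = 2) -> PCoAResult:
    """Classical (metric) multidimensional scaling.

    Double-centres the squared distance matrix and eigendecomposes it.
    Axes are ordered by eigenvalue; negative eigenvalues (non-Euclidean
    distances) are reported as-is, and their axes carry zero coordinates.
    """
    d = np.asarray(dist, dtype=float)
    n = d.shape[0]
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T):
        raise InputError("distance matrix must be square and symmetric")
    if k >= n:
        raise ParameterError(f"k must be < number of samples ({n})")
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    # numerical zeros (degenerate axes) are clipped so they do not leak
    # arbitrary eigenvector directions into the coordinates
    tol = np.abs(evals).max(initial=0.0) * n * np.finfo(float).eps
    evals = np.where(np.abs(evals) < tol, 0.0, evals)

    coords = np.zeros((n, k))
    for axis in range(k):
        if evals[axis] > 0:
            coords[:, axis] = evecs[:, axis] * np.sqrt(evals[axis])
    index = dist.index if isinstance(dist, pd.DataFrame) else pd.RangeIndex(n)
    positive = evals[evals > 0].sum()
    prop = np.where(evals > 0, evals / positive, 0.0) if positive > 0 else np.zeros(n)
    return PCoAResult(
        coordinates=pd.DataFrame(coords, index=index,
                                 columns=[f"PCo{i + 1}" for i in range(k)]),
        eigenvalues=evals,
        proportion_explained=prop,
    )


def anosim(dist: pd.DataFrame, grouping, n_perm: int = 999,
           seed: int | None = None) -> tuple[float, float]:
    """Analysis of similarities.

    R = (mean between-group rank - mean within-group rank) / (M/2) with
    M = n(n-1)/2, ranks taken over all pairwise distances (average ranks
    on ties).  p by random permutation of group labels, one-sided on R.
    """
    d = np.asarray(dist, dtype=float)
    n = d.shape[0]
    groups = np.asarray(pd.Series(grouping).loc[dist.index]
                        if isinstance(dist, pd.DataFrame) and isinstance(grouping, (pd.Series, dict))
                        else grouping)
    if len(groups) != n:
        raise InputError("grouping length must match the distance matrix")
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise InputError("ANOSIM needs >= 2 groups")
    if (counts < 2).any():
        small = labels[counts < 2].tolist()
        raise InputError(f"groups with fewer than 2 samples: {small}")

    iu = np.triu_indices(n, k=1)
    ranks = rankdata(d[iu])
    m = n * (n - 1) / 2

    def r_statistic(g: np.ndarray) -> float:
        within = g[iu[0]] == g[iu[1]]
        return (ranks[~within].mean() - ranks[within].mean()) / (m / 2)

    r_obs = r_statistic(groups)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if r_statistic(rng.permutation(groups)) >= r_obs:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return float(r_obs), float(p)


# ---------------------------------------------------------------------------
# Predation pressure
# ---------------------------------------------------------------------------

def predation_pressure(metadata: pd.DataFrame,
                       density_col: str = "bacterivore_density",
                       abundance_col: str = "phoD_abundance",
                       scale: float = 1.0) -> pd.DataFrame:
    """Bacterivore density over phoD abundance, per sample.

    Units: individuals per gene copy (pass ``scale=1e6`` for display in
    individuals per 10^6 copies).  Samples with zero or missing abundance
    get an error note and a NaN pressure; the rest proceed.
    """
    for col in (density_col, abundance_col):
        if col not in metadata.columns:
            raise InputError(f"metadata lacks column {col!r}")
    density = metadata[density_col].astype(float)
    abundance = metadata[abundance_col].astype(float)
    if (density.dropna() < 0).any():
        raise ValidationError("negative bacterivore densities")

    pressure = pd.Series(np.nan, index=metadata.index, dtype=float)
    note = pd.Series("", index=metadata.index, dtype=object)
    valid = abundance.notna() & (abundance > 0) & density.notna()
    pressure[valid] = density[valid] / abundance[valid] * scale
    note[~valid] = "undefined: zero or missing abundance"
    return pd.DataFrame(
        {
            "bacterivore_density": density,
            "phoD_abundance": abundance,
            "pressure": pressure,
            "note": note,
        }
    )


def group_summary(values: pd.Series, grouping: pd.Series) -> pd.DataFrame:
    """Group means +/- sd (the package's replacement for post-hoc letter displays)."""
    df = pd.DataFrame({"value": values, "group": grouping})
    return df.groupby("group")["value"].agg(["mean", "std", "count"])
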