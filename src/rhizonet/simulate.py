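"""Synthetic rhizosphere communities and pairwise competition assays.

The community generator plants the statistical structure the downstream
analysis is designed to detect: correlation modules, connector/hub
keystone taxa, compositional count noise, and nematode covariates tied to
keystone abundance.  Latent log-abundances follow a Gaussian copula whose
correlation matrix is assembled from factor loadings (hence positive
semi-definite by construction); counts are multinomial draws at a
per-sample sequencing depth, so rank (Spearman) correlations of the
counts track the latent correlations.

A geometric constraint worth knowing: a taxon cannot be correlated above
1/sqrt(k) with members of k mutually independent modules, so connector
keystones — which need |r| > 0.7 links into three modules — are only
possible when the factors of the modules they bridge are themselves
positively correlated.  The generator therefore groups modules into
disjoint triples with factor correlation ``module_factor_cor`` and
assigns each connector one triple.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .errors import GenerationError, ParameterError, ValidationError
from .io import OtuTable, TREATMENT_CODES

# ---------------------------------------------------------------------------
# Community generator
# ---------------------------------------------------------------------------

@dataclass
class CommunityConfig:
    """Parameters of the planted-community generator.

    Defaults mirror the emulated field study: 24 samples (8 factorial
    treatments x 3 replicate plots), six correlation modules, three
    connector keystones negatively associated with their linked members,
    and bacterivorous-nematode densities positively tied to keystone
    abundance.
    """

    n_samples: int = 24
    n_taxa: int = 300
    n_modules: int = 6
    module_size: int = 20
    rho_within: float = 0.9           # latent within-module correlation
    n_keystones: int = 3
    keystone_type: str = "connector"  # or "module hub"
    keystone_sign: int = -1           # keystones negatively associated with linked members
    keystone_modules_touched: int = 3
    keystone_loading_total: float = 0.99   # variance of keystone explained by factors
    module_factor_cor: float = 0.7    # factor correlation inside a connector triple
    log_abundance_sigma: float = 1.5  # scale of latent variation on the log scale
    baseline_mu_sd: float = 0.5       # spread of baseline log abundances across taxa
    planted_mu_offset: float = -0.7    # extra baseline abundance for module members
    keystone_mu_offset: float = 2.0   # keystones abundant enough that their downswings
                                      # are not censored by zero counts
    depth_mean: float = 30000.0       # mean sequencing depth per sample
    depth_cv: float = 0.1
    frac_nematode_added: float = 0.5
    nematode_effect: float = 0.8      # latent corr between keystones and bacterivore density
    exact_factor_scores: bool = True  # standardize factor scores so their sample
                                      # covariance equals the target exactly (the
                                      # mvrnorm(empirical=TRUE) convention); planted
                                      # signal then has no factor-level sampling wobble
    seed: int | None = None

    def validate(self) -> None:
        if self.n_modules < 1:
            raise ParameterError("n_modules must be >= 1")
        if self.module_size < 3:
            raise ParameterError("module sizes must be >= 3")
        if not 0 <= self.rho_within < 1:
            raise ParameterError("rho_within must lie in [0, 1)")
        if self.n_modules * self.module_size + self.n_keystones > self.n_taxa:
            raise ParameterError("n_taxa too small for the requested modules and keystones")
        if self.keystone_type not in ("connector", "module hub"):
            raise ParameterError(f"unknown keystone_type {self.keystone_type!r}")
        if self.keystone_sign not in (-1, 1):
            raise ParameterError("keystone_sign must be -1 or +1")
        if not 0 < self.keystone_loading_total < 1:
            raise ParameterError("keystone_loading_total must lie in (0, 1)")
        if not 0 <= self.module_factor_cor < 1:
            raise ParameterError("module_factor_cor must lie in [0, 1)")
        if not 0 <= self.frac_nematode_added <= 1:
            raise ParameterError("frac_nematode_added must lie in [0, 1]")
        if not -1 < self.nematode_effect < 1:
            raise ParameterError("nematode_effect must lie in (-1, 1)")


@dataclass
class GroundTruth:
    """What the generator planted, for scoring recovery."""

    module_of: dict[str, str]              # taxon -> "M1".. or "background"
    keystones: dict[str, str]              # taxon -> intended role
    keystone_modules: dict[str, list[str]] # taxon -> modules it bridges/anchors
    latent_correlation: np.ndarray         # taxa x taxa latent correlation
    taxon_ids: list[str]


def _factor_correlation(config: CommunityConfig) -> tuple[np.ndarray, list[list[int]]]:
    """Factor correlation matrix and the module triple assigned to each keystone."""
    m = config.n_modules
    F = np.eye(m)
    assignments: list[list[int]] = []
    if config.keystone_type == "module hub":
        for i in range(config.n_keystones):
            assignments.append([i % m])
        return F, assignments
    k = config.keystone_modules_touched
    n_groups = m // k
    if n_groups == 0:
        raise GenerationError(
            f"connector keystones need {k} modules per group but only {m} modules exist"
        )
    groups = [list(range(g * k, (g + 1) * k)) for g in range(n_groups)]
    for i in range(config.n_keystones):
        group = groups[i % n_groups]
        assignments.append(group)
        for a in group:
            for b in group:
                if a != b:
                    F[a, b] = config.module_factor_cor
    return F, assignments


def _assemble_loadings(config: CommunityConfig) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Build (loadings B, factor correlation F) and the ground-truth labels."""
    F, keystone_groups = _factor_correlation(config)
    n_planted = config.n_modules * config.module_size
    taxon_ids = [f"OTU{i + 1}" for i in range(config.n_taxa)]

    B = np.zeros((config.n_taxa, config.n_modules))
    module_of: dict[str, str] = {}
    idx = 0
    for mod in range(config.n_modules):
        label = f"M{mod + 1}"
        for _ in range(config.module_size):
            B[idx, mod] = np.sqrt(config.rho_within)
            module_of[taxon_ids[idx]] = label
            idx += 1

    keystones: dict[str, str] = {}
    keystone_modules: dict[str, list[str]] = {}
    for i in range(config.n_keystones):
        group = keystone_groups[i]
        tid = taxon_ids[idx]
        # spread the keystone's variance budget over its factor group;
        # Var(sum of loaded factors) accounts for the factor correlations
        c = F[np.ix_(group, group)].sum()
        lam = np.sqrt(config.keystone_loading_total / c)
        for g in group:
            B[idx, g] = config.keystone_sign * lam
        keystones[tid] = config.keystone_type
        keystone_modules[tid] = [f"M{g + 1}" for g in group]
        module_of[tid] = "keystone"
        idx += 1
    for j in range(idx, config.n_taxa):
        module_of[taxon_ids[j]] = "background"

    communalities = np.einsum("if,fg,ig->i", B, F, B)
    if (communalities > 1 + 1e-9).any():
        raise GenerationError(
            "assembled latent covariance is not positive semi-definite; "
            "reduce rho_within or keystone_loading_total"
        )
    Sigma = B @ F @ B.T
    np.fill_diagonal(Sigma, 1.0)
    truth = GroundTruth(
        module_of=module_of,
        keystones=keystones,
        keystone_modules=keystone_modules,
        latent_correlation=Sigma,
        taxon_ids=taxon_ids,
    )
    return B, F, truth


def _taxonomy_strings(truth: GroundTruth, rng: np.random.Generator) -> pd.Series:
    phyla = ["Alphaproteobacteria", "Betaproteobacteria", "Gammaproteobacteria", "Actinobacteria"]
    genera = ["Bradyrhizobium", "Aquabacterium", "Pseudolabrys", "Mitsuaria", "Pseudomonas", "Mesorhizobium"]
    rows = {}
    for tid in truth.taxon_ids:
        phylum = phyla[rng.integers(len(phyla))]
        genus = genera[rng.integers(len(genera))]
        rows[tid] = f"{phylum};{genus}"
    return pd.Series(rows, name="taxonomy")


def generate_community(config: CommunityConfig | None = None, seed: int | None = None
                       ) -> tuple[OtuTable, pd.DataFrame, GroundTruth]:
    """Draw one synthetic OTU table + metadata + ground truth.

    ``seed`` overrides ``config.seed`` when given.  Latent per-sample
    log-abundances come from the block-structured Gaussian copula;
    counts are multinomial at a lognormal per-sample depth (so column
    totals equal the drawn depths exactly); bacterivore density is a
    monotone function of the mean keystone latent abundance plus noise.
    """
    config = config or CommunityConfig()
    config.validate()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)

    B, F, truth = _assemble_loadings(config)
    n, p = config.n_samples, config.n_taxa

    # factors with correlation F (eigh handles the semi-definite boundary)
    evals, evecs = np.linalg.eigh(F)
    if evals.min() < -1e-9:
        raise GenerationError(
            "factor correlation matrix is not positive semi-definite; "
            "reduce module_factor_cor"
        )
    L = evecs @ np.diag(np.sqrt(np.clip(evals, 0, None)))

    communality = np.einsum("if,fg,ig->i", B, F, B)
    resid_sd = np.sqrt(np.clip(1.0 - communality, 0.0, None))
    keystone_rows = [i for i, t in enumerate(truth.taxon_ids) if t in truth.keystones]

    n_core = config.n_modules + len(keystone_rows)
    raw = rng.standard_normal((n, n_core))
    if config.exact_factor_scores and n > n_core + 1:
        # whiten so the sample covariance of the factor/keystone scores is
        # exactly the identity before colouring with chol(F (+) I)
        raw = raw - raw.mean(axis=0)
        s_evals, s_evecs = np.linalg.eigh(raw.T @ raw / n)
        raw = raw @ s_evecs @ np.diag(1.0 / np.sqrt(s_evals)) @ s_evecs.T
    factors = raw[:, : config.n_modules] @ L.T
    key_resid = raw[:, config.n_modules:]

    z = factors @ B.T + rng.standard_normal((n, p)) * resid_sd  # samples x taxa latents
    for col, i in enumerate(keystone_rows):  # keystone residuals come from the whitened block
        z[:, i] = factors @ B[i] + resid_sd[i] * key_resid[:, col]

    planted = np.array([truth.module_of[t] != "background" for t in truth.taxon_ids])
    keystone = np.array([t in truth.keystones for t in truth.taxon_ids])
    mu = rng.normal(0.0, config.baseline_mu_sd, size=p)
    mu[planted] += config.planted_mu_offset
    mu[keystone] += config.keystone_mu_offset - config.planted_mu_offset
    log_abund = mu + config.log_abundance_sigma * z
    probs = np.exp(log_abund - log_abund.max(axis=1, keepdims=True))
    probs /= probs.sum(axis=1, keepdims=True)

    depths = np.maximum(
        1, np.round(rng.lognormal(np.log(config.depth_mean), config.depth_cv, size=n))
    ).astype(np.int64)
    counts = np.empty((n, p), dtype=np.int64)
    for j in range(n):
        counts[j] = rng.multinomial(depths[j], probs[j])

    sample_ids = [f"S{j + 1:02d}" for j in range(n)]
    table = OtuTable(
        pd.DataFrame(counts.T, index=truth.taxon_ids, columns=sample_ids),
        taxonomy=_taxonomy_strings(truth, rng),
    )

    metadata = _metadata_frame(config, rng, z, truth, sample_ids)
    return table, metadata, truth


def _metadata_frame(config: CommunityConfig, rng: np.random.Generator, z: np.ndarray,
                    truth: GroundTruth, sample_ids: list[str]) -> pd.DataFrame:
    n = config.n_samples
    # factorial treatment layout: first half of codes lack added nematodes
    n_added = int(round(config.frac_nematode_added * n))
    without = [c for c in TREATMENT_CODES if not c.endswith("N")]
    with_n = [c for c in TREATMENT_CODES if c.endswith("N")]
    labels = []
    for j in range(n):
        pool = with_n if j < n_added else without
        labels.append(pool[j % len(pool)])
    added = np.array([t.endswith("N") for t in labels])

    key_idx = [truth.taxon_ids.index(t) for t in truth.keystones]
    if key_idx:
        key_latent = z[:, key_idx].mean(axis=1)
        key_latent = (key_latent - key_latent.mean()) / (key_latent.std() or 1.0)
        # keystones load negatively on the factors; bacterivore density rises
        # with keystone *abundance*, so follow the latent abundance directly
        signal = config.nematode_effect * key_latent
    else:
        signal = np.zeros(n)
    noise_sd = np.sqrt(1.0 - config.nematode_effect**2)
    density_latent = signal + noise_sd * rng.standard_normal(n)
    bacterivore = 150.0 * np.exp(0.4 * density_latent) * np.where(added, 1.9, 1.0)
    total = bacterivore / 0.412 * np.exp(0.1 * rng.standard_normal(n))
    phoD = 1.5e7 * np.exp(0.3 * rng.standard_normal(n)) * np.where(added, 1.6, 1.0)

    return pd.DataFrame(
        {
            "treatment": labels,
            "nematode_added": added,
            "bacterivore_density": bacterivore,
            "total_nematode_density": total,
            "phoD_abundance": phoD,
            "pH": rng.normal(6.8, 0.2, size=n),
            "SOC": rng.normal(12.0, 1.5, size=n),
            "TN": rng.normal(1.4, 0.2, size=n),
            "AN": rng.normal(95.0, 10.0, size=n),
            "AP": rng.normal(18.0, 3.0, size=n),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )


# ---------------------------------------------------------------------------
# Competition generator (two-species Lotka-Volterra with serial dilution)
# ---------------------------------------------------------------------------

@dataclass
class LVParams:
    """Two-species Lotka-Volterra competition parameters.

    dN1/dt = r1 N1 (1 - (N1 + a12 N2)/K1), symmetrically for N2.
    """

    r1: float = 0.6    # per-hour growth rates
    r2: float = 0.5
    K1: float = 1e9    # carrying capacities, CFU/mL
    K2: float = 1e9
    a12: float = 0.0   # effect of strain 2 on strain 1
    a21: float = 0.0

    def validate(self) -> None:
        if min(self.r1, self.r2) <= 0 or min(self.K1, self.K2) <= 0:
            raise ParameterError("growth rates and carrying capacities must be positive")
        if min(self.a12, self.a21) < 0:
            raise ParameterError("competition coefficients must be >= 0")


@dataclass
class CompetitionRecord:
    """Colony-count series for one pair, one initial-ratio treatment, one replicate."""

    pair_id: str
    focal: str
    competitor: str
    ratio_label: str                 # "1:1", "1:100" or "100:1"
    cycles: list[int]                # 0 = inoculum, then end of each growth cycle
    coculture: dict[str, list[float]]    # strain -> densities (CFU/mL)
    monoculture: dict[str, list[float]]  # matched monocultures, same initials
    replicate: int = 0


RATIO_LABELS = ("1:1", "1:100", "100:1")


def _initial_densities(ratio_label: str, base_density: float) -> tuple[float, float]:
    if ratio_label == "1:1":
        return base_density, base_density
    if ratio_label == "1:100":     # focal diluted 100-fold before mixing
        return base_density / 100.0, base_density
    if ratio_label == "100:1":     # competitor diluted 100-fold
        return base_density, base_density / 100.0
    raise ParameterError(f"unknown initial ratio {ratio_label!r}; use one of {RATIO_LABELS}")


def _lv_rhs(t, y, p: LVParams):
    n1, n2 = y
    return [
        p.r1 * n1 * (1.0 - (n1 + p.a12 * n2) / p.K1),
        p.r2 * n2 * (1.0 - (n2 + p.a21 * n1) / p.K2),
    ]


def _integrate_cycle(y0, params: LVParams, hours: float) -> np.ndarray:
    sol = solve_ivp(
        _lv_rhs, (0.0, hours), y0, args=(params,), method="LSODA",
        rtol=1e-10, atol=1e-6,
    )
    return np.clip(sol.y[:, -1], 0.0, None)


def simulate_dilution_course(params: LVParams, y0, n_cycles: int, dilution: float,
                             cycle_hours: float) -> np.ndarray:
    """Densities at the end of each growth cycle, (n_cycles+1) x 2, row 0 = inoculum."""
    out = np.empty((n_cycles + 1, 2))
    out[0] = y0
    y = np.asarray(y0, dtype=float)
    for c in range(1, n_cycles + 1):
        y = _integrate_cycle(y, params, cycle_hours)
        out[c] = y
        y = y * dilution
    return out


def generate_competition_records(
    lv_params: LVParams,
    initial_ratios: tuple[str, ...] = RATIO_LABELS,
    n_cycles: int = 4,
    dilution: float = 0.01,
    noise: float = 0.0,
    n_replicates: int = 1,
    base_density: float = 1e4,
    cycle_hours: float = 24.0,
    pair_id: str = "pair1",
    focal: str = "strain1",
    competitor: str = "strain2",
    seed: int | None = None,
) -> list[CompetitionRecord]:
    """Simulate serial growth-dilution competition assays.

    Within each cycle, densities follow two-species Lotka-Volterra
    dynamics integrated over ``cycle_hours``; both strains are then
    diluted by ``dilution`` into fresh medium.  Matched monocultures run
    the same model with the competitor's inoculum set to zero.  ``noise``
    is the sd of multiplicative lognormal observation noise on the
    reported colony counts.
    """
    lv_params.validate()
    if n_cycles < 1:
        raise ParameterError("n_cycles must be >= 1")
    if not 0 < dilution <= 1:
        raise ParameterError("dilution must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    records = []
    for rep in range(n_replicates):
        for label in initial_ratios:
            y0 = _initial_densities(label, base_density)
            co = simulate_dilution_course(lv_params, y0, n_cycles, dilution, cycle_hours)
            mono1 = simulate_dilution_course(lv_params, (y0[0], 0.0), n_cycles, dilution, cycle_hours)
            mono2 = simulate_dilution_course(lv_params, (0.0, y0[1]), n_cycles, dilution, cycle_hours)
            if noise > 0:
                co = co * rng.lognormal(0.0, noise, size=co.shape)
                mono1 = mono1 * rng.lognormal(0.0, noise, size=mono1.shape)
                mono2 = mono2 * rng.lognormal(0.0, noise, size=mono2.shape)
            records.append(
                CompetitionRecord(
                    pair_id=pair_id,
                    focal=focal,
                    competitor=competitor,
                    ratio_label=label,
                    cycles=list(range(n_cycles + 1)),
                    coculture={focal: co[:, 0].tolist(), competitor: co[:, 1].tolist()},
                    monoculture={focal: mono1[:, 0].tolist(), competitor: mono2[:, 1].tolist()},
                    replicate=rep,
                )
            )
    return records
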