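# rhizonet

Co-occurrence network analysis for microbiome OTU tables: thresholded
Spearman network construction, keystone-taxon identification by
within/among-module connectivity, natural-connectivity robustness under
node removal, the accompanying community statistics (diversity,
ordination, group separation, predation pressure), and analysis of
pairwise bacterial competition assays.

## Who this is for

Soil and rhizosphere microbial ecologists who profile a functional guild
(for example alkaline-phosphomonoesterase-producing bacteria via the
*phoD* marker gene) across replicated field treatments and want to ask:
which taxa hold the co-occurrence network together, how fragile is the
network to their loss, and do trophic covariates (such as bacterivorous
nematode densities) track those taxa?  The package also ships a synthetic
community generator with planted modules and keystones, so every stage of
the pipeline can be exercised and validated without sequencing data.

## The analysis chain

1. **Network construction.** All pairwise Spearman rank correlations
   between taxa (optionally plus nematode covariate nodes) are computed
   across samples; two-sided p-values are Benjamini–Hochberg adjusted over
   the upper triangle, and an undirected signed edge is kept where
   |r| > 0.7 and adjusted p < 0.01 (both thresholds configurable).
2. **Topology and modules.** Standard summary metrics (density, average
   path length on the largest component, diameter, clustering, mean
   degree, modularity) plus modularity-based community detection
   (seeded Louvain by default).
3. **Keystone roles.** Per node, the within-module connectivity
   Z = (κᵢ − mean κ) / sd κ (κ = links to the node's own module) and the
   among-module connectivity (participation) P = 1 − Σₜ (κᵢₜ/kᵢ)².
   Roles: peripheral (Z < 2.5, P < 0.62), module hub (Z > 2.5, P < 0.62),
   connector (Z < 2.5, P > 0.62), network hub (Z > 2.5, P > 0.62); module
   hubs, connectors and network hubs form the keystone set.  Each module is
   summarised by its eigengene (first principal component of the
   standardized member-abundance matrix).
4. **Robustness.** Natural connectivity
   λ̄ = ln((1/N) Σⱼ exp(λⱼ)) over the adjacency eigenvalues; an in-silico
   keystone-removal test compares the connectivity left after deleting the
   keystone set against a Monte-Carlo null of equal-sized random node sets.
5. **Community metrics.** Rarefaction to a fixed depth, Shannon (natural
   log) and Chao1 diversity, Bray–Curtis distances, classical PCoA,
   ANOSIM by label permutation, and predation pressure (bacterivore
   density / *phoD* gene abundance).
6. **Competition assays.** From monoculture/coculture colony counts:
   interaction index = observed coculture density / (sum of monoculture
   densities) — 1 is additive, < 1 antagonistic, > 1 facilitative — and
   qualitative outcome calls (exclusion, coexistence, founder control)
   from the final fractions of the 1:1, 1:100 and 100:1 initial-ratio
   treatments, including invasion from rare.  A two-species
   Lotka–Volterra serial growth-dilution simulator generates matched
   synthetic assays.

## Worked example

Run the full pipeline on a synthetic community (300 taxa, 6 planted
modules, 3 planted connector keystones, 150 samples):

```bash
rhizonet all --seed 1 --out demo --config <(echo '{"simulate": {"n_samples": 150},
  "robustness": {"n_null": 199}, "metrics": {"anosim_permutations": 199}}')
```

or in Python:

```python
from rhizonet import run_pipeline
summary = run_pipeline({"seed": 1, "simulate": {"n_samples": 150},
                        "robustness": {"n_null": 199},
                        "metrics": {"anosim_permutations": 199}}, "demo")
```

`demo/summary.json` then contains (abridged):

```json
{
  "network":    {"n_nodes": 123, "n_edges": 1315, "n_positive": 1143,
                 "n_negative": 172, "neg_pos_ratio": 0.1505,
                 "modularity": 0.7401},
  "roles":      {"n_modules": 6, "keystones": ["OTU121", "OTU122", "OTU123"]},
  "robustness": {"observed": 16.007, "null_mean": 18.892, "p_value": 0.005},
  "metrics":    {"shannon_mean": 4.432, "chao1_mean": 297.02,
                 "anosim_R": 0.010, "anosim_p": 0.145}
}
```

Reading this: the thresholded network keeps the 123 taxa with at least
one strong, significant correlation; detection finds the 6 planted
modules (modularity 0.74), and the three keystones the generator planted
(OTU121–123, negatively linked connectors) are exactly the nodes
classified as keystones.  Removing them drops natural connectivity to
16.0 against a random-removal null of 18.9 ± 0.3 (p = 0.005, 199 draws):
the planted connectors really do hold the network together.  The ANOSIM R
near 0 is expected here — the generator's treatment labels do not shift
overall composition, only the keystone-linked covariates.

Every artefact (OTU TSV, metadata TSV, GraphML network, roles TSV,
eigengenes, diversity, distance matrix, PCoA coordinates, robustness
curve) is written beside the summary, and a fixed seed makes the bundle
byte-identical across runs.

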