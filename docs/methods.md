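# Methods

## Scope and data model

The pipeline starts downstream of OTU calling: its root object is a taxa
× samples count (or relative-abundance) table with optional taxonomy
strings, paired with per-sample metadata (factorial treatment code,
nematode-addition flag, bacterivore density in individuals 100 g⁻¹ dry
soil, *phoD* gene copies g⁻¹ dry soil, soil covariates).  All analyses
operate on these two tables; raw reads, chimera removal and clustering
are out of scope.

## Correlation network

Spearman rank correlations (average ranks on ties) are computed for all
retained pairs; p-values use the large-sample t approximation, which is
standard practice at the 12-samples-per-group scale this design targets.
Zero-variance variables are excluded with a warning rather than an
error, since an all-zero taxon after filtering carries no information.
Benjamini–Hochberg adjustment is applied over the strict upper triangle
of each correlation matrix — i.e. within each network analysed, so when
"with" and "without" treatment subsets are analysed separately the
adjustment is stratified the same way.  Edges require |r| > 0.7 and
p < 0.01 on the adjusted p-value by default; whether the printed
significance gate of such studies refers to raw or adjusted p is often
ambiguous, so `use_adjusted` is an explicit flag rather than a silent
assumption.  Correlations may be computed on counts, relative abundances
or rarefied counts — rank correlation is invariant to per-sample
monotone rescaling, so this choice only matters through the
prevalence/abundance filters (`abundance_min=0.001` reproduces the
common "dominant OTU > 0.1%" filter; both filters default to off).
Covariate nodes (e.g. bacterivore genus densities) enter the same
matrix, flagged `kind="nematode"`; either a single pooled density or
per-genus columns can be supplied.

## Modules, Z/P roles, eigengenes

Community detection runs on the unweighted, unsigned graph.  The default
is seeded Louvain (a `seed=None` is pinned to 0, so results are
deterministic by default); greedy agglomerative modularity and label
propagation are available.  Greedy was rejected as the default after it
repeatedly merged weakly bridged module pairs whose separation was
modularity-optimal — a known coarseness artefact of agglomerative
merging.  Module ids are relabelled by decreasing size (ties by smallest
node id) so labellings are stable.

Within-module connectivity Z standardises a node's own-module degree
against all members of its module (population sd); among-module
connectivity P is the participation coefficient 1 − Σₜ(κᵢₜ/kᵢ)².
Degenerate cases follow explicit conventions: Z = 0 where a module's
within-degrees are constant (sd = 0), P = 0 for isolated nodes.  Role
thresholds are Z = 2.5 and P = 0.62 with strict inequalities; a node
sitting exactly on a threshold falls on the low side.  Printed tables in
the literature sometimes show a connector at P = 0.62 — that is display
rounding of an underlying value above the cut; classification here always
uses unrounded scores.  Signs of edges are ignored for both module
detection and Z/P, the convention of the role-classification literature.

Module eigengenes: member abundances are standardized per taxon (zero
mean, unit variance across samples) and decomposed by SVD; the eigengene
is the leading right-singular vector over samples (unit norm), sign-fixed
to correlate non-negatively with the mean standardized member profile;
variance explained is the leading squared singular value over the total.
Modules need ≥ 2 non-constant members.  Eigengene–trait correlation is
offered with Pearson (default) or Spearman.

## Natural connectivity and removal tests

Natural connectivity is ln((1/N) Σ exp(λⱼ)) over the adjacency
eigenvalues, computed with a log-sum-exp to avoid overflow.  After node
removal, N is the remaining node count, and isolates created by removal
stay in the spectrum (their zero eigenvalues legitimately dilute
connectivity).  The keystone-removal test draws `n_null` uniform random
node sets of the keystone set's size (from all nodes, keystones
included) and reports the one-sided empirical p-value
(1 + #{null ≤ observed})/(n_null + 1), which is never below
1/(n_null+1) and is reproducible under a fixed seed.  On graphs whose
connectivity takes few distinct values (near-clique modules) ties make
the test conservative; this is a property of the statistic, not a bug.
The default null size is 999 draws; calibration and power studies in the
test suite use 199 draws, which keeps the p-value resolution (0.005) far
below the 0.05 decision level at a fifth of the cost.

## Community metrics

Rarefaction subsamples each sample to an exact depth without replacement
(multivariate hypergeometric); shallow samples are dropped with a
warning.  Shannon uses the natural log — the convention is not universal,
so it is stated here.  Chao1 is S_obs + F₁²/(2F₂), falling back to the
bias-corrected S_obs + F₁(F₁−1)/(2(F₂+1)) when no doubletons exist.
Bray–Curtis, classical PCoA (double-centred squared distances;
eigenvalues reported including negative ones, never silently corrected;
numerically zero eigenvalues are clipped so degenerate axes carry zero
coordinates) and rank-based ANOSIM (R = (r̄_between − r̄_within)/(M/2),
M = n(n−1)/2; p by label permutation) are implemented directly with
explicit seeds, and are cross-checked against scikit-bio in the test
suite.  Plain PCoA stands in for constrained ordination, which is out of
scope.  Group comparisons are reported as means ± sd; post-hoc letter
displays are not reimplemented.  Predation pressure is bacterivore
density over *phoD* abundance (individuals per gene copy; a ×10⁶ display
scale is available); samples with zero or missing abundance yield
per-sample error notes, not a failed run.

## Synthetic community generator

The generator is the package's test bed: it emulates a 24-sample
(8 factorial treatments × 3 replicates) community with planted structure
and returns the ground truth alongside the data.

Latent log-abundances follow a Gaussian copula whose correlation matrix
is assembled from factor loadings — modules are blocks loading √ρ_in on
one factor each — so it is positive semi-definite by construction.
Counts are multinomial draws per sample at a lognormal depth
(mean 30,000, CV 0.1, matching typical rarefaction depths), so per-sample
totals equal the drawn depths exactly and taxa compete for reads
(compositional noise).  Bacterivore density is a monotone (exponential)
function of the mean keystone latent abundance plus noise, giving the
positive keystone–density rank correlation the analysis expects to find;
treatment labels with added nematodes get higher densities and *phoD*
abundances.

Connector keystones expose a geometric fact worth recording: a variable
cannot correlate above 1/√k with members of k mutually independent
modules, so connectors with |r| > 0.7 links into three modules are only
possible when the bridged modules' factors are positively correlated.
The generator therefore groups modules into disjoint triples with factor
correlation `module_factor_cor = 0.7` and loads each connector
negatively (keystone_sign = −1) across one triple with total factor
variance 0.99.  With ρ_in = 0.9 this puts the keystone–member latent
correlation near −0.84 and the realized count-level Spearman near −0.75,
comfortably above the edge threshold, while inter-module member
correlations (≈ 0.63 latent) stay safely below it.  Module-hub keystones
load on a single module instead.

Two further choices matter for realism-versus-detectability:

- **Compositional closure attenuates negative correlations.**  The shared
  read-count denominator co-varies with the module factors and biases all
  pairwise count correlations toward +1; negative keystone–member pairs
  lose ≈ 0.05–0.1 of |r| while positive member pairs lose much less.
  Keystones are therefore given a higher baseline abundance
  (`keystone_mu_offset = 2.0`) — so their downswings are not censored at
  zero counts — and planted members a slightly lower one
  (`planted_mu_offset = −0.7`), keeping the planted blocks a modest share
  of total reads.  This mirrors a genuine property of compositional
  sequencing data: negative associations are systematically harder to
  detect.
- **Exact factor scores.**  By default the factor and keystone-residual
  scores are standardized so their sample covariance equals the target
  exactly (the `mvrnorm(empirical=TRUE)` convention).  This removes
  factor-level sampling wobble from the planted signal: what remains
  random is per-taxon residual noise and the count layer.  Set
  `exact_factor_scores=False` for fully stochastic draws.

What the generator does **not** emulate: real phylogenetic correlation
structure, overdispersion beyond the copula (no per-count negative
binomial layer), unequal module sizes, sparse rare-biosphere tails, or
any direct dependence of composition on the treatment labels.  Passing
the recovery tests therefore shows the pipeline detects the planted
statistical structure under compositional count noise — not that any
particular real community satisfies these assumptions.

The competition generator integrates two-species Lotka–Volterra
competition (dN₁/dt = r₁N₁(1 − (N₁ + α₁₂N₂)/K₁), LSODA, rtol 1e-10)
within each growth cycle (24 h, r ≈ 0.5–0.6 h⁻¹, K = 10⁹ CFU/mL,
inoculum 10⁴ CFU/mL), then dilutes both strains 1:100 into fresh medium —
four cycles by default.  The three initial-fraction treatments mix the
strains 1:1, 1:100 and 100:1 (the rare strain diluted 100-fold before
mixing).  Matched monocultures run the same model with the competitor's
inoculum set to zero, so the additive-growth limit (α₁₂ = α₂₁ = 0)
reproduces the coculture trajectories exactly up to integrator error.
Observation noise is multiplicative lognormal on the reported counts.

## Competition analysis

The interaction index uses the sum of monoculture densities at the
matched time point as the expected density (the alternative of a mean is
deliberately not offered); indices are reported per cycle, with the
endpoint of each cycle as the observation time.  The additive band is
1 ± 0.05 by default — colony counting noise makes exact 1 unattainable —
and the extinction threshold for outcome calls is a final fraction of
0.01.  Outcome classification uses only final-cycle fractions plus the
invasion-from-rare criterion: focal exclusion requires a final fraction
> 1−ε from all three starts; founder control requires the 1:100 and
100:1 starts to finish on opposite boundaries; coexistence requires all
three finals interior with pairwise spread < 0.1.  Trajectories matching
none of these (dynamics unresolved at the last cycle) are labelled
`indeterminate` rather than forced into a category.  On simulated
serial-dilution assays with equal growth rates, these calls match the
analytic Lotka–Volterra regime map (coexistence when both α < 1,
exclusion under asymmetric α > 1, founder control when both α > 1) away
from the α = 1 boundaries; with unequal growth rates, few-cycle
trajectories can be dominated by growth-rate selection, which is why the
regime validation pins r₁ = r₂.

## Pipeline, seeds, problem sizes

`run_pipeline` chains simulate/load → network → roles → robustness →
metrics; any stage error is re-raised naming the stage.  A single config
seed is fanned out to child seeds (one per randomized stage) via
`numpy.random.SeedSequence.spawn`, so a fixed seed makes the entire
output bundle byte-identical; floats in JSON reports are rounded to 10
decimals to keep the files stable.

The statistical validation in the test suite uses deliberately moderate
problem sizes chosen for adequate power: planted-structure recovery runs
20 seeds at 150 samples × 300 taxa; permutation-test calibration runs
200 null datasets per test with 199 permutations/null draws each
(rejection at α = 0.05 is then an exact 5% event under exchangeability);
the regime validation draws 100 parameter sets integrated over 10
cycles.

## Known limitations

- Correlation networks are not compositionality-aware (no SparCC/
  SPIEC-EASI style inference); the generator quantifies, but the
  estimator does not correct, closure bias against negative edges.
- Path-based topology metrics are unweighted and restricted to the
  largest connected component.
- The removal test's Monte-Carlo null is a design choice; field studies
  often report post-hoc letters from unstated resampling schemes, and no
  claim of equivalence is made.  Replicate-level robustness comparisons
  (e.g. per-plot networks) are supported only via sample bootstrap
  outside the core pipeline.
- ANOSIM p-values are permutation-based and inherit the usual
  discreteness at small n.
- Lotka–Volterra parameters are never estimated from data; the simulator
  generates, the classifier reads.
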