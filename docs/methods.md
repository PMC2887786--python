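# Methods

This note records the statistical model, the conventions the
implementation fixes where the literature leaves choices open, what the
synthetic generator does and does not emulate, and the package's known
limitations.

## Indirect standardization

Expected counts are indirect: `E_i = Σ_s P_is ψ_s` over strata `s`
(age band × sex, optionally × income quintile), with reference rates
`ψ_s` either supplied externally or pooled from the study itself
("internal" standardization, which forces `Σ E_i = Σ Y_i` exactly — a
useful invariant the tests exploit). Direct standardization is out of
scope: with dissemination-area denominators the directly standardized
ratio is far too imprecise.

Intervals for `SIR = Y/E` are exact Poisson, via the gamma-quantile
construction: `low = Γ⁻¹(α/2; Y)/E` (0 when `Y = 0`),
`high = Γ⁻¹(1−α/2; Y+1)/E`. Counts at this scale are far too small for
normal approximations. Areas with `E = 0` and `Y = 0` (unpopulated) are
kept in outputs with an `excluded` flag and dropped from the screening
and smoothing stages; `E = 0` with `Y > 0` is rejected as impossible
under the model.

Cluster-level summaries (`aggregate_sir`) support two references:
the external rates as-is, or the complement of the subset (the subset's
expectation rescaled by the remainder's Y/E), which is the convention
for reporting a cluster's risk "relative to the remainder" of a study
region.

## Contiguity

First-order queen contiguity (any shared boundary point) is the default
neighbour definition on irregular administrative polygons; rook is
available by flag. The same graph feeds the Moran screen and the ICAR
prior. Islands are flagged, never dropped. Weight conventions differ by
consumer, matching the defaults of the tools practitioners use:
row-standardized weights for Moran's I, binary symmetric weights for
the ICAR prior. Distance-band and k-nearest-neighbour weights are
deliberately absent: with areas spanning orders of magnitude in
geographic size, contiguity is the defensible choice.

## Moran screen

`I = (n/S0) Σ_ij w_ij z_i z_j / Σ_i z_i²` on the SIR surface, areas with
`E = 0` masked before centring. Inference is by parametric bootstrap:
replicate counts `Y*_i ~ Poisson(E_i)` independently, statistic
recomputed on `Y*/E`, one-tailed
`p = (1 + #{I* ≥ I_obs})/(B + 1)` (the add-one Monte-Carlo convention,
so `p ∈ (0,1]` always). The Poisson/expected-count null conditions the
test on the population structure, which is how the screen "adjusts for
population density"; asymptotic-normal Moran inference is intentionally
not offered. A degenerate replicate (constant simulated surface) counts
as non-exceeding. Screening across outcomes is Bonferroni: flag iff
`p < α/m` **and** `I > 0` — the screen exists to find positive
aggregation worth smoothing, never negative autocorrelation.

## BYM smoothing

Model and priors as in the README. Implementation conventions:

- **Hyperpriors** Gamma(0.5, 0.0005) on both precisions — the
  long-standing disease-mapping default — configurable.
- **Identifiability**: α is flat; after every sweep `u` is re-centred
  (one sum-to-zero constraint per connected component) and the removed
  overall mean absorbed into α. Islands get `u_i = 0`; their risk is
  carried by `v_i` alone. The Gibbs update for `1/σ_u²` uses
  `(n_active − n_components)/2` degrees of freedom (the rank of the
  graph Laplacian) and the pairwise-difference quadratic form.
- **Sampler**: Metropolis-within-Gibbs. `v` updates are a single
  vectorized random-walk Metropolis block (conditionally independent
  given everything else). `u` updates are scheduled by a greedy proper
  colouring of the contiguity graph: same-colour areas have no common
  edge, hence update as one vectorized block; planar tessellations need
  only a handful of colours. α is random-walk Metropolis; precisions
  are conjugate Gamma draws. Proposal scales adapt toward 44%
  acceptance during burn-in only (diminishing-adaptation steps, frozen
  afterwards, so the post-burn-in chain is a fixed Markov kernel).
- **Label invariance**: computation is done in area-ID-sorted order and
  mapped back, so a consistent relabelling/permutation of the input
  yields bit-identical per-area results.
- **Initial values** are over-dispersed around the crude log-SIR of the
  pooled data, scaled by a configurable dispersion parameter, so the
  Gelman-Rubin diagnostic is meaningful.
- **Diagnostics**: classic potential-scale-reduction R̂ from
  between/within chain variances of the saved draws, monitored for α,
  both scale parameters, and every θ_i; the pipeline attaches a warning
  when any monitored R̂ ≥ 1.1 (a numeric stand-in for visual
  trace-plot checks). Degenerate chains yield NaN rather than an error.
- **fracspatial** is the variance-ratio form: per pooled draw,
  `Var_emp(u)/(Var_emp(u)+Var_emp(v))` across areas, summarised by mean
  and central 95% interval. A standard-deviation-ratio variant is a
  switch (`method="sd"`); the variance form is the default because it
  matches the generator's calibration target exactly.

Two MCMC presets exist: desk-scale defaults (2 chains × 20,000 kept
iterations, burn-in 5,000, thin 10) sized for simulation studies and CI,
and `replica_protocol()` (3 chains × 1,000,000 after 100,000 burn-in,
thin 200 — 15,000 saved draws) for registry-scale analyses. Sampler
correctness does not depend on the preset; the tests use whichever size
the check needs.

## Spatial scan

Circular (centroid-distance) windows: for every centre, zones are all
distance-ordered prefixes whose expected count stays within
`max_fraction` (default 0.5) of the total; duplicate member sets are
removed, distance ties break by area index. Expectations are rescaled so
`E_total = Y_total` (conditioning on the total), making the observed
statistic invariant to uniform rescaling of E. The zone score is the
Poisson log-likelihood ratio
`Y_z ln(Y_z/E_z) + (Y−Y_z) ln((Y−Y_z)/(E−E_z))` for high-rate zones,
zero otherwise; inference redistributes the observed total
multinomially with probabilities `E/E_total` (`p = (1 + #{max LLR* ≥
max LLR_obs})/(n_sim+1)`, floor 0.001 at 999 replicates). Elliptical
windows, space-time scans, and secondary-cluster reporting are out of
scope — window shape is orthogonal to the statistic.

## Synthetic study regions

The generator emulates the structure the analysis assumes, not any real
census geography:

- **Geometry**: Voronoi tessellation of uniform random points clipped to
  the unit square — irregular, contiguity-rich areas resembling
  dissemination areas (a deliberate choice over a lattice).
- **Populations**: area totals uniform on a configurable range (default
  400–700, the DA scale), split multinomially over age × sex cells by a
  fixed documented pyramid (0.25/0.27/0.28/0.13/0.07 over the five
  default bands, even sex split; geometric decline ratio 0.8 for
  non-default band lists). Fixed weights keep expected counts
  reproducible.
- **Income**: spatial moving-average field over the contiguity graph,
  rank-split into near-equal quintiles (remainder to the lower
  quintiles, ties by area ID — deterministic).
- **Risk surface**: `θ = exp(α + u + v)` with `u` drawn from the ICAR
  distribution by eigendecomposition of the graph Laplacian (null
  direction removed, sum-to-zero imposed, rescaled so the empirical SD
  equals σ_u exactly — the intrinsic prior fixes no scale, so the
  generator must); `v` iid normal. Optional planted multiplicative
  cluster over a graph-radius ball. Default calibration scenario
  σ_u = 0.3, σ_v = 0.1 gives a spatial variance fraction of 0.9.
- **Cases**: `Poisson(persons × stratum rate × area θ)` per stratum.
  Default reference rates double per age band from a base of 0.003
  cases/person/period, giving realistic small expected counts
  (E ≈ 5–10 per area at default populations); an income-gradient factor
  creates confounding scenarios in which income-stratified
  standardization demonstrably attenuates the SIR spread.

What the generator does **not** emulate: census suppression and
rounding, geocoding/postal-code allocation error, age-structure
heterogeneity between areas, migration, or temporal trends. Passing
tests therefore demonstrate the statistical machinery is correct and
calibrated under the model's own assumptions — not that any particular
real-world surface would be recovered.

## Problem sizes in the tests and acceptance script

Simulation checks run at sizes chosen to make each property sharply
testable while keeping the whole suite quick on a single core:
10×10 lattices with E = 10–20 per area for calibration runs (500 null
datasets for the bootstrap screen, 200 for the scan), one 100-area
recovery fit at 2 chains × 5,000 saved draws, 20 replicate fits for the
exceedance-sensitivity study at reduced chain lengths, and 50–100-area
Voronoi regions for end-to-end runs. These are the package's standard
simulation-study settings; all are parameters, not constants.

## Known limitations

- The ICAR generator eigendecomposes a dense Laplacian (O(n³)); fine to
  a few thousand areas, not for national-scale graphs.
- Single-site random-walk updates mix slowly when counts are very
  large and effects strongly coupled; the adaptive scales mitigate but
  a blocked or gradient-based sampler would scale better.
- The scan reports the single most-likely zone only.
- Exceedance probabilities are reported against the fixed threshold
  θ > 1; other thresholds require re-summarising the saved draws.
- Choropleth output is attribute assignment (class index, flags) plus a
  basic matplotlib rendering; publication cartography is out of scope.
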