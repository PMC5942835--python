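# Methods

## Problem setting and conventions

`popgrid` analyses population change between two time points on a raster
population grid. Cells are addressed by integer `(col, row)` indices; cell
centers sit at integer coordinates and the cell side is the distance unit.
The physical side length (500 m for a census mesh) is carried as metadata
only: every shape index the pipeline computes is a ratio that does not
depend on it. A cell is *populated* in a year iff it holds at least one
inhabitant; empty and water cells are simply absent rows.

An *inhabited cluster* is a connected component of populated cells under
the von Neumann adjacency (the four side-sharing neighbours; diagonal
contact does not connect). Clusters are identified at the baseline year
only. The dependent variable is the follow-up population **inside the
fixed baseline footprint**: later splits, merges and growth outside the
footprint are deliberately ignored, so the summed follow-up populations
over baseline footprints can be smaller than the grid's total follow-up
population. Clusters with fewer than 10 cells are dropped before modelling
(their geometry is dominated by the discreteness of the grid); the filter
threshold is a parameter (`min_cells`).

## Per-cluster features

For a cluster with cell set of size S and baseline population n:

* **Area** S (cells) and **Density** n/S (inhabitants per cell); both enter
  the regression in natural logs because their distributions are heavy
  tailed.
* **Roundness** = S / (π (d_max/2)²), d_max the longest Euclidean distance
  between member cell centers. Disc-like clusters approach ≈ 1.27 (the
  square grid's maximum packing of a circle), line-like clusters go to 0.
  d_max is found by brute force over all cell pairs up to 2000 cells and
  over convex-hull vertices beyond (both paths are tested to agree; the
  diameter is attained on the hull).
* **Irregularity** = 2 log L / log S, with L the perimeter: the number of
  unit cell edges adjacent to a non-member cell. Interior holes are counted
  in L — through the scaling relation S = L^(2/Irregularity) the index is a
  perimeter-based fractal-dimension proxy, which argues for the total
  exposed boundary. The ratio is independent of the logarithm base (natural
  logs are used internally).
* **CL** = E[distance between two uniformly random inhabitants] / √S
  = [Σ_{i<j} n_i n_j d_ij] / C(n,2) / √S. Same-cell pairs contribute
  distance 0 and are covered by the C(n,2) denominator. The √S division
  decorrelates CL from cluster size. CL is small when the population
  concentrates near the cluster centre; exact algebra (with a uniform
  remainder, the numerator is (m−1) Σ_j d_pj plus a placement-independent
  constant) shows the placement of a mass m minimizing CL is the cell with
  the smallest Euclidean distance sum — the test suite checks this on all
  4-cell shapes. Note this *geographical* centre need not coincide with the
  graph-closeness centre used for the region join (on an L-tetromino they
  differ), so "moving people to the closeness-central cell never increases
  CL" is not a theorem and is not asserted.
* **Heterogeneity** = sample coefficient of variation (SD with divisor
  S−1, divided by the mean) of per-cell counts. The sample convention is
  forced by the index's own worked example: 8 inhabitants on 4 cells reach
  CV = 1.00 only as (5,1,1,1) under the sample SD (the population SD caps
  at 0.866).
* **Gender** = female fraction of the cluster population.
* **Age** and **Tertiary** are region-level attributes (mean age,
  tertiary-industry worker fraction) joined at the cluster's representative
  cell: the member cell with the largest closeness centrality of the
  cluster-as-graph (cells as nodes, side-sharing cells adjacent). Closeness
  is (number of other nodes)/(total graph distance); any strictly monotone
  variant has the same argmax, which is all that is used. Tied cells are
  averaged, which can give a fractional coordinate; region containment
  therefore works on continuous cell footprints (rectangles extended by
  half a cell side), and a point on a shared edge goes to the
  lexicographically smallest region id. The region table is a local
  rectangle lookup; it replaces network geocoding services with the same
  contract (coordinate in, region out).

Degenerate clusters (single cell, or fewer than two inhabitants) yield
undefined markers that the feature-table builder turns into hard errors;
they cannot occur once the 10-cell filter has been applied.

## Regression models

With offset log n_c (coefficient fixed at 1) and log link,

    log μ_c = log n_c + β₀ + β₁ log S_c + β₂ log Density_c + Σ βᵢ X_ic .

The Poisson model assumes Var = μ. Overdispersion is tested with the
Dean–Lawless score statistic T = Σ[(y−μ̂)² − y] / √(2Σμ̂²), which is
N(0, 1) under the Poisson null; the test is one-sided (upper tail) because
the alternative of interest is Var > μ, and the default decision level is
0.001. The type-I calibration experiment in the acceptance suite runs the
test under an intercept-plus-offset null with moderate, non-dominated
means: the statistic's null normality is an asymptotic property that
requires no single cluster to dominate Σμ², and its finite-sample mean
shifts downward by roughly p/√(2N) when p regression parameters are
estimated — both are properties of the method, not of this implementation,
and the calibration is designed to check the implementation in the regime
the approximation targets.

The negative binomial (NB2) model has Var = μ + μ²/θ with a common
dispersion θ. Fitting alternates a fixed-θ GLM fit for β (statsmodels,
IRLS) with a bounded one-dimensional maximization of the exact NB
log-likelihood over log θ, until the log-likelihood changes by less than
1e-8 (at most 50 outer iterations) — the classic profile scheme. A θ
running past 1e6 means the data are Poisson-like; the fit is flagged and θ
reported at the cap. Reported standard errors for β are conditional on the
estimated θ (asymptotically β̂ and θ̂ are orthogonal); 95% intervals are
Wald, estimate ± 1.96 SE. AIC = 2k − 2ℓ counts θ as a parameter for the NB
family. Univariate fits use the same offset as the multivariate fit, one
covariate at a time.

## Model selection

Backward elimination starts from all nine main effects plus all 36
pairwise interactions. Interactions are products of the **mean-centered**
covariates (centering keeps the VIFs of product terms small), formed from
the transformed variables (log Area, log Density) since the model matrix
contains no raw Area or Density. At each step the term whose removal most
decreases the AIC is dropped; marginality is enforced (a main effect is
not removable while any of its interactions remains); elimination stops
when no removal decreases the AIC.

Candidate removals are scored with θ held at the current model's estimate
— one warm-started IRLS fit per candidate — and θ is re-profiled after
each accepted removal, with the profiled AIC recorded in the trace.
Because the profiled AIC is never larger than the fixed-θ AIC of the same
model, the recorded trace is non-increasing by construction. This is the
standard step-AIC economy (score cheaply, refit properly on acceptance)
and changes nothing asymptotically.

## Synthetic data

The generator produces grids with the statistical structure the analysis
assumes, with every default chosen to match the observed study scales:

| knob | default | rationale |
|---|---|---|
| n_clusters | 2000 | same order as the observed N = 2689 after filtering |
| area tail exponent | 1.5 (Pareto, min 10, cap 300) | heavy-tailed areas; the cap keeps desk-scale runs tractable |
| density | lognormal, log-mean 3.5, log-SD 0.98 | median ≈ 33 inhabitants/cell, matching observed density statistics |
| elongation | per-cluster U(0, 0.8) | spans compact blobs to near-lines, covering the observed Roundness range |
| concentration | 0.3 | exponential decay of expected counts with distance from the central cell |
| heterogeneity knob | 0.5 | lognormal cell-weight noise, giving observed-scale CV of cell counts |
| gender mean | 0.515 | national female fraction |
| regions | 8 vertical bands; age ~ N(44.6, 1.24), tertiary ~ N(0.653, 0.045) | prefecture-level resolution and scales |
| β | small mixed-sign effects on the observed covariate scales (`DEFAULT_BETA`) | known-truth recovery experiments under realistic effect sizes |
| θ | 5 | produces strong overdispersion at these μ while remaining far from the Poisson limit |

Shapes grow by stochastic Eden accretion from a seed cell; each growth
step extends the horizontal extremes with probability equal to the
cluster's elongation parameter (elongation 1 yields the exact 1×S line).
Baseline counts are 1 + multinomial over cells with distance-decay ×
lognormal-noise weights, so every member cell stays populated as the
cluster definition requires. Female counts are binomial per cell.
Follow-up counts are NB2 draws per cluster via the exact gamma–Poisson
mixture (λ ~ Gamma(θ, μ/θ), y ~ Poisson(λ)), scattered uniformly over the
cluster's cells. Clusters are shelf-packed with a 2-cell buffer, so the
clustering stage recovers exactly n_clusters components, and the stored
truth features are the ones the pipeline itself computes from the emitted
grid — the loop grid_io → clustering → morphology closes exactly, which
the test suite asserts through a full write/read round trip.

What the generator does **not** emulate: real geography (terrain, coasts,
transport), migration flows between clusters, spatial autocorrelation
between neighbouring clusters, and within-region variation of age and
tertiary share. Passing recovery tests therefore show that the estimation
machinery is correct under the model's own assumptions, not that the model
is adequate for any particular real data set.

## Problem sizes and numerical choices

The acceptance experiments use 500 replicates of N = 1000 for the
overdispersion calibration, 100 replicates of N = 2000 full grid pipelines
for coefficient coverage (≥ 90/100 CIs covering each generating
coefficient; θ̂ within 20% of truth in ≥ 90/100), and 50 replicates of
N = 2000 for retention of a planted log-Area × log-Density interaction
(coefficient 0.05) by backward AIC — sizes chosen to give tight binomial
error on the checked proportions while keeping the whole suite runnable on
a single CPU in minutes. The selection-consistency and calibration
experiments sample covariates directly at feature level (the grid stages
are exercised by the coverage experiment and their own oracle tests).

Other numerics: GLM IRLS capped at 200 iterations with non-convergence
raised as an error; θ profiling bounded on log θ ∈ [log 1e-4, log 1e7]
with xatol 1e-10; linear predictors clipped at ±30 inside the lean scoring
IRLS to avoid overflow far from the optimum; CSV region attributes are
parsed with exact round-trip float precision so that write/read cycles are
bit-stable; cluster ids are assigned by scan order of each component's
minimum (row, col) cell so that joins are reproducible across runs and
input permutations; all randomness flows from a single
`numpy.random.default_rng(seed)` per generated data set.

## Known limitations

* The perimeter convention (holes counted) and the planar-grid distance
  convention are choices; analyses of data whose source used different
  conventions will differ in the affected indices.
* NB standard errors conditional on θ̂ slightly understate the intercept's
  uncertainty at small N.
* The stepwise trace is a greedy path, not a global search; with many
  near-zero effects the final model retains a handful of noise terms, as
  expected for AIC at ~2 units per parameter.
* Follow-up clusters are never re-identified for the dependent variable (a
  diagnostic count is reported); cluster splits and merges are out of
  scope by design.
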