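# Methods

`symptomnet` implements the standard analysis chain of longitudinal
psychometric network studies of depression (PHQ-9) and anxiety (GAD-7)
items: regularized partial-correlation networks per assessment wave, node
centrality including bridge indices over the two symptom communities,
bootstrap stability, permutation-based network comparison between waves, a
network over per-participant change slopes, and simulation-based sample-size
planning. Because item-level cohort data of this kind are rarely shareable,
the package ships a synthetic cohort generator with known ground truth; all
statements below about what the tests establish are statements about data of
that form.

## Network model and estimation

Item scores are treated as noisy observations of a latent multivariate
Gaussian. The network is the Gaussian graphical model (GGM): nodes are
items, and an edge carries the partial correlation
`w_ij = -K_ij / sqrt(K_ii K_jj)` from the precision matrix `K`; a missing
edge means conditional independence given all other items.

`K` is estimated by the graphical lasso: maximize
`log det K - tr(R K) - lambda * sum_{i!=j} |K_ij|` over positive-definite
`K`, where `R` is the input correlation matrix. The solver is a block
coordinate-descent implementation (numba-compiled) whose penalty paths are
warm-started from the previous lambda; the unit tests pin it entrywise
against a generic proximal-gradient minimizer of the same objective and
against scikit-learn's solver. The path runs over 100 log-spaced penalties
from `lambda_max` (the largest absolute off-diagonal of `R`, above which the
solution is exactly diagonal) down to `0.01 * lambda_max`.

Model selection uses the extended BIC,
`EBIC = -2 l(K) + E log n + 4 E gamma log p`, with
`l(K) = (n/2)(log det K - tr(R K))` (the additive Gaussian constant is
omitted; it cancels in selection), `E` the number of nonzero
partial correlations (|w| >= 1e-8), and `gamma = 0.5` by default. Ties on
the grid resolve toward the sparser model. These defaults — gamma 0.5,
100-point grid, `lambda_min_ratio` 0.01 — are the conventions of the
estimation tooling standard in this literature and are all exposed in
`EstimatorConfig`.

The input correlation is Pearson by default. A two-step maximum-likelihood
polychoric estimator is provided for the latent-Gaussian reading of the
ordinal items (thresholds from marginal category proportions, then each
pairwise latent correlation by bounded 1-D likelihood maximization over the
bivariate-normal cell probabilities; boundary estimates are clamped at
±0.999 and flagged, and the matrix is repaired to the nearest
positive-semidefinite unit-diagonal matrix by eigenvalue clipping when
needed). Pearson is the default because it is deterministic, fast, and
robust to the near-empty top categories of low-prevalence symptoms; the
choice is surfaced in the config rather than hidden.

Missingness is handled by listwise deletion per wave only — each wave's
network uses that wave's complete cases, so `n` varies across waves. No
imputation is attempted.

## Centrality

Strength is `s_i = sum_j |w_ij|`, and the sum of strengths is exactly twice
the global strength (the absolute sum over unique edges) — this identity is
asserted on every estimated network in the tests. Bridge indices use the
fixed two-community partition (9 depression, 7 anxiety items):

* bridge strength: absolute sum of cross-community edge weights;
* bridge betweenness: number of shortest paths between cross-community node
  pairs passing through the node as an intermediate, with tied shortest
  paths counted fractionally (an integer-counting mode is available);
* bridge closeness: inverse mean shortest-path distance to the other
  community; a node unreachable from the entire other community gets 0 and
  is flagged.

Shortest paths use edge length `1/|w|`; negative edges enter via their
magnitude. Endpoints do not count as intermediates. These conventions are
fixed and documented here because published analyses rarely state them.
z-standardized columns (across the 16 nodes) are provided for plotting
parity; raw values are always retained.

## Stability

Edge accuracy: nonparametric bootstrap (row resampling, full re-estimation
per resample, default B = 1000), 2.5/97.5 percentile intervals per edge.
Case-drop stability: for drop proportions 0.05–0.75 in steps of 0.05, B
subsamples are re-estimated and the Spearman correlation between subsample
and full-sample centralities recorded. The CS coefficient is the largest
drop proportion at which at least 95% of subsamples stay correlated >= 0.7
with the full sample; values above 0.25 are conventionally read as
minimally stable. Estimator failures inside resamples (e.g. a constant
column after resampling) are dropped and counted, never silently ignored;
more than 10% failures aborts the report.

## Network comparison between waves

Two occasions of the same participants are compared on their common
complete cases with a paired permutation test. Statistics: `M`, the maximum
absolute edge-weight difference between the two estimated networks
(structure invariance), and `S`, the absolute difference in global strength.
The permutation scheme swaps each participant's pair of response vectors
between occasions independently with probability 1/2 — the
exchangeability-preserving choice for dependent samples — and re-estimates
both networks per permutation (default 1000). p-values use the add-one
estimator `(1 + #{null >= observed}) / (1 + n_perm)`, so they are never 0.
Edge-level differences reuse the same permutation draws, restricted to edges
nonzero in at least one observed network (bounded multiplicity), with
Holm correction across those edges. When all six wave pairs are compared,
a Bonferroni threshold of `alpha / 6` is applied across pairs. The paired
type-I error of the structure test is verified by simulation in the
acceptance tests (200 null replicates at n = 300 pairs).

## Change-trajectory network

For every participant observed at all four waves (n = 210 under the default
cohort), each item's OLS slope on the wave code (0,1,2,3) is computed in
closed form. The slopes, as continuous variables, then go through the same
Pearson + EBIC-glasso pipeline. Equally spaced integer time codes are used
although the real calendar gaps between treatment stages are unequal: the
slope *correlation* matrix — hence the network — is invariant to affine
re-coding of time (a property the tests assert), so only the nonlinearity
of true time, not the coding, is at stake. Items whose slope is constant
across all participants are dropped with a warning and returned as isolated
nodes.

## Sample-size planning

`recommend_sample_size` estimates, for each candidate n, the probability
q(n) that EBIC-glasso recovers at least a target fraction (default 0.6) of
the true edges, using a fresh sparse true model per replicate (default 100
replicates per candidate) — averaging over random structures at fixed
density rather than conditioning on one truth. An isotonic fit enforces
monotonicity of q(n) over a 10-point coarse grid (default 100–1000), the
smallest candidate crossing the assurance level (default 0.8) is bracketed,
and one refinement pass repeats the procedure on a finer grid. Observations
are multivariate Gaussian by default — the GGM's native observation model,
for which edge-recovery operating characteristics are defined;
`observations="ordinal"` pushes the draws through the questionnaire
thresholds instead, which attenuates correlations and raises every
recommendation (by roughly 40–70% under the default skewed thresholds).
Published planning tools in this area differ in unstated details of their
true-model and data conventions, so recommendations should be read as
order-of-magnitude guidance; with the defaults here, a 16-node network at
density 0.2 with sensitivity target 0.6 and assurance 0.8 lands in the
230–250 range.

## Synthetic cohort generator

The generator emulates a 4-wave ordinal item panel:

* **True network**: sparse random GGM with exactly
  `round(density * p(p-1)/2)` edges; precision off-diagonals uniform in
  [0.5, 1] with 90% positive partial correlations; diagonal set to 1.5x the
  row absolute sum and normalized (diagonally dominant, hence positive
  definite; uniform shrinkage as a bounded fallback). For the default
  cohort, 75% of the 24 edges are placed within the two communities,
  the rest are cross-community bridges.
* **Ordinal items**: latent Gaussian draws thresholded at latent quantiles
  0.55 / 0.80 / 0.93 into scores 0–3 — skewed toward 0 to mimic
  low-prevalence symptoms such as suicidal ideation.
* **Wave drift**: latent means shift by 0.08 SD per wave step — anxiety
  items downward, sadness and guilt upward — emulating the centrality shift
  described for treatment cohorts; magnitudes configurable.
* **Cohort shape**: baseline n 343 with per-wave complete-case targets
  (343, 269, 261, 212) and exactly 210 all-wave completers; ages
  N(30.68, 4.10). Participation patterns are mostly monotone dropout, plus
  the minimal number of intermittent patterns (2 under the defaults,
  present at T1/T3/T4) required to reconcile the final-wave count with the
  completer target. Dropout is age-dependent: participants are ranked by a
  Gumbel-perturbed age score (a Plackett–Luce draw; log-odds 0.1 per year
  by default) and the most dropout-prone receive the sparsest patterns, so
  dropouts are older on average while counts stay exact.

What the generator does **not** emulate: within-person correlation across
waves (waves are independent draws given the wave means, so there is no
true longitudinal dependence and the default cohort's slope network is
near-empty by construction), item-level missingness within an observed
wave, time-varying network structure, and the high internal-consistency
reliabilities of real questionnaires (a sparse GGM with moderate partials
yields alphas well below the 0.87–0.96 typical of PHQ-9/GAD-7). Passing
tests therefore establish correctness of the estimators and their operating
characteristics under a known latent-Gaussian truth, not fidelity of any
particular clinical finding.

## Numerical choices and degenerate inputs

* Glasso convergence: mean-absolute-change tolerance 1e-6 on the working
  covariance (scaled by the mean absolute off-diagonal of R), max 500
  sweeps; non-convergence raises rather than returning a stale fit.
* `lambda = 0` requires a positive-definite `R` and returns the exact
  inverse; `lambda >= lambda_max` returns the exact diagonal solution.
* Partial correlations below 1e-8 in magnitude are zeroed.
* Constant columns fail Pearson estimation loudly, naming the item; inside
  bootstrap/permutation loops such failures are counted and retried or
  dropped under the documented caps.
* The shared Fruchterman–Reingold layout is computed on the element-wise
  mean absolute weight matrix across waves, with initial positions drawn
  per sorted node label from the seed — deterministic and invariant to node
  input order; coordinates are rescaled to the unit square.
* Every stochastic stage takes an explicit seed; the pipeline manifest
  records seeds, sample sizes, and selected penalties per stage, and two
  runs with the same config produce byte-identical numeric outputs.

## Problem sizes used in the test suite

Unit tests run at small scale (p <= 8, B around 100, 10–50 permutation
draws) chosen to exercise the contracts; the acceptance-style checks use
the study-shaped scales: edge recovery at n = 2000 over 20 seeds, NCT
calibration over 200 null replicates of n = 300 pairs with 200 permutations
(on a 50-point penalty grid — type-I calibration of a permutation test does
not depend on the grid resolution), and the sample-size analysis at its
default 100 replicates per candidate. These sizes are the package's own
choices balancing Monte-Carlo error against desk-scale runtime.
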