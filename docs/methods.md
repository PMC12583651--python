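# Methods

This note documents the model, the estimation machinery, the synthetic-cohort
generator, and the numerical and design choices behind `copulanet`, in the
spirit of a statistical software methods appendix. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself compute.

## Model

### Gaussian graphical model

Latent variables $Z = (Z_1,\dots,Z_p)$ are multivariate normal with mean 0
and precision matrix $K$. The undirected graph $G$ over the $p$ variables has
an edge $(i,j)$ exactly when $k_{ij} \ne 0$, i.e. when $Z_i$ and $Z_j$ are
conditionally dependent given all other variables. The effect size attached
to an edge is the partial correlation
$\rho_{ij} = -k_{ij}/\sqrt{k_{ii} k_{jj}}$, the correlation between $i$ and
$j$ after the linear effect of every other variable is removed. Partial
correlations are invariant to rescaling of the latent columns, which is why
all reported quantities are scale-free (see "identifiability" below).

### Gaussian copula for mixed measurement types

Observed cohort variables are not jointly Gaussian: the design includes
binary (sex, *APOE4*), ordinal (five-level amyloid stage), integer-valued
(education years) and skewed continuous (regional volume, glucose uptake)
columns. Each observed column is modelled as a monotone nondecreasing
function of its latent column:

- **Continuous columns** are Gaussianized once, before sampling starts, by
  the rank-based semiparametric (nonparanormal) transform
  $\hat z_i = \Phi^{-1}\!\big(r_i/(n+1)\big)$ with average ranks for ties.
  The $r/(n+1)$ empirical CDF bounds the transform away from $\pm\infty$,
  which is the property the classical Winsorized estimator exists to provide;
  that variant (truncation at $\delta_n = 1/(4 n^{1/4}\sqrt{\pi \log n})$) is
  available behind the `winsorize` switch. Transformed columns are
  standardized to mean 0 / variance 1 once and then frozen. Age is treated as
  continuous although it is recorded in years.
- **Discrete columns** carry no margin-free transform. Under the extended
  rank likelihood, a discrete column's latent values are constrained only by
  the ordering of the observed values: the latent value of a row must exceed
  every latent value of rows with strictly smaller observed values and stay
  below those of rows with strictly larger ones; ties impose no mutual
  constraint. At every MCMC iteration each discrete latent entry is redrawn
  from the univariate normal conditional implied by $K$ — mean
  $-(1/k_{jj})\sum_{l \ne j} k_{jl} z_{il}$, variance $1/k_{jj}$ — truncated
  to those bounds. The conditional agrees with the Schur-complement
  conditional of $N(0, K^{-1})$ to numerical precision (tested at 1e-10).

The sweep is organized column-by-column in dictionary order; within a column
the observed levels are processed in ascending order with all rows of a level
drawn jointly (vectorized). Rows sharing a level are conditionally
independent and mutually unconstrained, so this equals a row-by-row scan in
distribution while being far cheaper in Python.

### Prior

- Graph: independent Bernoulli edges with inclusion probability 0.2 — a
  weakly-informative prior expressing that conditional dependence between any
  given pair is the exception, not the rule. Config-exposed.
- Precision matrix: G-Wishart$(\delta, D)$ restricted to $G$'s zero pattern,
  with $\delta = 3$, $D = I$. These hyperparameters are conventional software
  defaults, not study-reported values; both are config-exposed.

## Posterior computation

### G-Wishart sampling (direct sampler)

Draws from WG$(\delta, D, G)$ use the direct sampler: draw an unconstrained
Wishart variate with the same parameters, invert it, and complete the
resulting covariance to the graph by cyclic node-wise regression (iterative
proportional scaling); the inverse of the completed covariance is the
constrained draw, with exact zeros on non-edges. The completion loop is
numba-compiled (tolerance 1e-9 on the maximum entry change, at most 200
sweeps). A failed Cholesky after the final zeroing triggers a logged 1e-10
diagonal jitter and, failing that, a retry with fresh randomness (bounded
budget, then a hard numerical error). On the complete graph the sampler
reduces to an ordinary Wishart and its sample moments are checked against the
closed form; on the empty graph the diagonal entries are checked against
their Gamma margins.

### Trans-dimensional moves: double reversible jump with an exchange step

Each iteration proposes flipping one edge $(i,j)$ chosen uniformly from all
$p(p-1)/2$ pairs. Conditioning on every entry of $K$ except the pair
$(k_{ij}, k_{jj})$ — the pivot is the larger index $j$, fixed — the free
block integrates in closed form under the (unnormalized) G-Wishart density
with parameters $(\delta, D)$: substituting the Schur complement
$\gamma = k_{jj} - u^\top A^{-1} u$ (with $A$ the matrix without row/column
$j$ and $u$ the $j$-column) factorizes the block into a Gamma integral in
$\gamma$, common to both graphs, and a Gaussian integral in $k_{ij}$, present
only when the edge is. Their ratio — edge-present over edge-absent — is

$$R(K; \delta, D) = \sqrt{\frac{2\pi}{d_{jj}\,a}}\;
\exp\!\Big(\frac{(d_{jj} m + d_{ij})^2}{2\, d_{jj}\, a}\Big),
\qquad a = (A^{-1})_{ii},\; m = (A^{-1}u_0)_i,$$

where $u_0$ is the $j$-column with its $i$-entry zeroed. The posterior-side
ratio uses $(\delta + n,\, D + Z^\top Z)$ and the current chain state; the
intractable ratio of *prior* normalizing constants $I_G(\delta, D)$ is
cancelled by an exchange step: draw an auxiliary $\tilde K$ from the
G-Wishart prior under the *proposed* graph (exact, via the direct sampler)
and evaluate the same closed form on it at prior parameters. The acceptance
probability for adding an edge is

$$\alpha = \min\Big(1,\; \tfrac{\pi_e}{1-\pi_e}\cdot
\frac{R(K;\, \delta+n,\, D + Z^\top Z)}{R(\tilde K;\, \delta,\, D)}\Big),$$

and the reciprocal form for deletion. No normalizing constant is ever
evaluated. On acceptance the free block is redrawn from its exact conditional
(Gaussian $k_{ij}$, Gamma Schur complement); each iteration then refreshes
the whole of $K$ from its conditional posterior
WG$(\delta + n, D + Z^\top Z, G)$, which dominates mixing of the continuous
parameters.

A birth–death (continuous-time) variant would fit behind the same trace
contract via per-sample waiting-time weights; the trace and every summary are
weight-aware, but the discrete-time sampler with unit weights is the only
backend implemented.

### Exact oracle at small dimension

Every graph on at most three nodes is decomposable, so the G-Wishart
normalizing constant factorizes over cliques and separators into ordinary
Wishart constants, and the posterior over all $2^{p(p-1)/2}$ graphs is exact:
$P(G \mid Z) \propto P(G)\, I_G(\delta+n, D+Z^\top Z)/I_G(\delta, D)$. The
clique factorization is itself validated against direct numerical integration
of the two-node model in the tests. The chain is accepted only because it
reproduces this enumerated posterior within 0.03 per edge across fixtures
with $n \in \{0, 20, 50, 200\}$ — including $n=0$, where every edge
probability must return to the 0.2 prior.

### Convergence and determinism

`convergence_check` reports the first-half/second-half maximum edge-probability
drift, an edge-count trace summary, and (given a second chain) the
cross-chain maximum drift, flagging above 0.05 by default. All randomness
flows through one `numpy.random.Generator` seeded per run; traces, cohorts
and figure files are byte-reproducible given the seed (the trace container
writes fixed zip timestamps for this reason).

## Posterior summaries and reporting

- **Edge probability**: weight-normalized frequency of the edge across stored
  samples.
- **Model-averaged partial correlations**: means/SDs over all stored draws
  with absent-edge draws entered as exact zeros. The posterior of each pair
  is thus a spike-at-zero of mass $1 - P(\text{edge})$ plus a continuous
  part; interval probabilities include the spike iff the interval covers 0.
- **Thresholded network**: edges with inclusion probability at least 0.5 by
  default (the median-probability rule); rendered edge width is affine in
  probability over [cutoff, 1], blue/red encodes the partial correlation's
  sign.
- **Pearson baseline**: product-moment correlations on the *raw observed
  codings* with entries zeroed at two-sided $p > 0.05$ (no multiplicity
  correction — the baseline is deliberately naive). Raw rather than
  transformed values are used because that is the conventional naive
  comparator.
- **Sparsity report**: over unordered off-diagonal pairs — mean absolute
  value (computed before zeroing), fraction zeroed, fraction exceeding 0.25
  in absolute value.
- **Stratified refits** run the identical pipeline per diagnosis group and
  pooled; groups under a configurable minimum size (default 30) are skipped
  with a warning. The comparison reports the average absolute partial both
  over all pairs and over the thresholded matrix, because a stage-level
  "average partial correlation" admits either reading.

## Synthetic cohorts

The generator is first-class, tested code: the study's records are
access-restricted, so it stands in for the entire upstream
imaging/psychometrics pipeline.

- **Ground truth**: `make_true_model` builds a graph (Erdős–Rényi at a target
  density, or the fixed `ad_motif` wiring of hippocampus-volume–memory,
  PCC-volume–executive-function, APOE4–amyloid–cognition and age/sex hubs)
  and a unit-diagonal precision matrix whose off-diagonals are the negated
  target partial correlations, shrunk geometrically until the smallest
  eigenvalue clears 0.02. Edge magnitudes are drawn uniformly in
  [0.75, 1.25] x the target magnitude (default 0.2) with random signs, and
  the realized values are verified to stay within [0.5, 1.5] x target.
- **Latent draws**: rows of diagnosis group $g$ are
  $N(\mu_g,\, s_g^2 K^{-1})$. Default group mean shifts (in model-SD units)
  reproduce the qualitative stage gradients of the cohort table — memory and
  executive function declining CN > EMCI > LMCI > AD, amyloid accumulating,
  volumes and glucose uptake shrinking, the small age/education differences —
  and are configuration defaults, not estimates. Variance compression
  (defaults 1.0/0.85/0.75/0.65 when enabled) emulates the reduced
  within-group spread that makes stage-specific fits sparser.
- **Margins**: sex and *APOE4* are thresholded latent indicators; group
  prevalences (female 53/44/43/42%, pooled about 47%; carrier fractions
  rising with stage) are achieved by latent mean shifts against one global
  cut, keeping every margin a single monotone map per column — the property
  the copula layer relies on. The amyloid stage uses four global cuts at
  configured latent quantiles (defaults giving roughly 30/15/15/20/20%
  pooled occupancy). Education is rounded to whole years and clipped to
  [0, 25]; cognitive composites are affine maps hard-clipped to [−3, 3];
  volume and glucose use a strictly increasing convex exponential map
  (skew 0.35) so the nonparanormal step is genuinely exercised. A
  `gaussian_margins` switch turns all continuous maps affine for oracle
  tests.

What the generator does **not** emulate: measurement error structure,
longitudinal trajectories, missingness (the package is complete-case by
contract), site/scanner effects, or the amyloid staging algorithm itself.
Passing recovery tests therefore demonstrates fidelity of the copula +
sampler machinery under known monotone margins, not robustness to those
real-data complications.

## Benchmark configurations

Two deliberate choices in the study-scale benchmarks:

- **Parameter recovery** (AUC / MAE against truth) uses *zero* group mean
  shifts. With stage shifts on, the pooled latent data is a Gaussian mixture
  whose precision matrix is not the generator's $K$ — the shifts act as
  unmodelled confounding — so recovery against the true partial correlations
  is only well-posed on a homogeneous population. Mixed margins and the
  Table-1 group sizes (n = 1022) are kept. Chains use 40,000 iterations with
  10,000 burn-in; the production default is 120,000/20,000, and the reduced
  schedule was chosen as the benchmark problem size.
- **Stratified sparsification** uses stage shifts *and* variance compression
  on — the mechanism of interest — with 12,000-iteration chains per run; the
  check is categorical (each stage at least as sparse as pooled), not a
  tuned margin.

## Numerical choices and degenerate inputs

- SPD checks are Cholesky-based everywhere; only the sampler's completion
  step may apply a logged 1e-10 diagonal jitter.
- Truncated-normal draws use inverse-CDF sampling with the uniform clipped to
  [1e-12, 1 − 1e-12]; bounds in these models sit well inside the tractable
  range.
- A constant continuous column is a hard error (the rank transform is
  undefined); a constant *discrete* column is legal — its latent bounds are
  unbounded and the update reduces to unconstrained Gaussian draws.
- Empty diagnosis groups summarize as size 0 with NaN statistics; stratified
  fits skip undersized groups with a warning rather than failing.
- Edge indices are 0-based positions in the variable dictionary with
  $i < j$; column order is dictionary order regardless of file order.

## Known limitations

- Cost grows steeply with $p$ (graph moves and two G-Wishart completions per
  iteration) and linearly in $n$ through the per-iteration discrete
  resampling; the implementation is sized for tens of variables and cohorts
  of a few thousand.
- Partial correlations measure *linear* conditional association on the
  latent scale; monotone-but-nonlinear observed relationships are captured
  through the copula, but non-monotone ones are not.
- The graph is undirected: no causal ordering, no mediation effect sizes.
- Unordered categorical variables with more than two levels are out of
  scope; every variable in the design is binary, ordinal or continuous after
  coding.
- The diagonal of $K$ is not identified for discrete columns under the rank
  likelihood; all reported quantities (edge probabilities, partial
  correlations) are invariant to it, and the latent diagonals are left free.
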