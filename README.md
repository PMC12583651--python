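# copulanet

Bayesian Gaussian copula graphical models (GCGMs) for mixed-type cohort data,
built around an Alzheimer's-disease (AD) study design: estimate which variables
are *conditionally* dependent — and how strongly — among demographics (age,
sex, education), *APOE4* carriage, a five-level ordinal amyloid stage, two
cognitive composites (memory, executive function, each in [−3, 3]), and
region-specific gray-matter volume and glucose uptake for six brain regions
(hippocampus, caudate, putamen, thalamus, posterior cingulate cortex,
precuneus), with full posterior uncertainty.

## The model

Latent variables $Z_1,\dots,Z_p \sim N(0, \Sigma)$ with precision matrix
$K = \Sigma^{-1}$. The conditional-independence graph $G$ is the support of
$K$: $k_{ij} = 0 \iff Z_i \perp Z_j \mid Z_{\text{rest}}$, and the strength of
each dependence is the partial correlation

$$\rho_{ij} = -\,k_{ij}\,/\sqrt{k_{ii}\,k_{jj}}.$$

Observed variables attach to the latent scale through monotone margins
(a Gaussian copula): continuous columns are Gaussianized once with the
rank-based semiparametric (nonparanormal) transform
$\hat z_i = \Phi^{-1}(r_i/(n+1))$; discrete columns (sex, education, *APOE4*,
amyloid stage) are resampled at every MCMC iteration from truncated-normal
conditionals constrained only by the observed ordering (extended rank
likelihood). Age is treated as continuous.

Inference is fully Bayesian: $P(G, K \mid Z) \propto P(Z \mid K)\,P(K, G)$
with an independent-Bernoulli edge prior (inclusion probability 0.2) and a
G-Wishart(3, I) prior on $K$. A trans-dimensional MCMC chain makes one
single-edge double-reversible-jump move per iteration — with an exchange
(auxiliary prior draw) step so G-Wishart normalizing constants are never
evaluated — followed by a full conditional refresh
$K \sim \mathrm{WG}(\delta + n,\, D + Z^\top Z)$ via the direct sampler.
Edge-inclusion probabilities are sample frequencies of each edge;
partial-correlation posteriors are mixtures of a spike at zero (edge absent)
and a continuous part. For $p \le 3$ the exact posterior over all graphs is
available in closed form and gates the chain's correctness in the tests.

Because the study's records are access-restricted, the package ships a
first-class synthetic-cohort generator that emulates them: Table-1-style
group sizes (345 CN / 297 EMCI / 205 LMCI / 175 AD, n = 1022), group-wise
demographics and margins, disease-stage mean gradients and variance
compression — all driven by a known sparse precision matrix, so recovery can
be scored against ground truth.

## Worked example

```python
import numpy as np
from copulanet import (PriorSpec, default_config, generate_cohort, fit_cohort,
                       summarize_partials, threshold_network, interval_probability,
                       pearson_matrix, sparsity_report)

cfg = default_config(seed=7, structure="ad_motif", stage_effects=True)
cohort, truth = generate_cohort(cfg)
print(f"cohort: n={cohort.n}, p={cohort.p}, true edges={truth.graph.n_edges}")

trace = fit_cohort(cohort, PriorSpec(edge_prob=0.2),
                   iterations=20_000, burnin=5_000, thin=10, seed=7)
post = summarize_partials(trace, names=cohort.dictionary.names)

d = cohort.dictionary
i, j = d.index("mem"), d.index("v_hipp")
print(f"mem - v_hipp: P(edge) = {post.prob[i, j]:.2f}, "
      f"partial = {post.mean_partial[i, j]:.2f} (sd {post.sd_partial[i, j]:.2f})")
print(f"P(0.1 <= rho <= 0.3) = {interval_probability(post, i, j, 0.1, 0.3):.2f}")

network = threshold_network(post, cutoff=0.5)
print(f"network at 50% cutoff: {len(network)} edges")

_, pearson_rep = pearson_matrix(cohort)
zeroed = np.where(post.prob >= 0.5, post.mean_partial, 0.0)
partial_rep = sparsity_report(post.mean_partial, zeroed=zeroed)
print(f"avg |Pearson| = {pearson_rep.avg_abs:.2f}, "
      f"avg |partial| = {partial_rep.avg_abs:.2f}")
print(f"zeroed: Pearson {pearson_rep.frac_zero:.0%}, partial {partial_rep.frac_zero:.0%}")
```

prints

```
cohort: n=1022, p=19, true edges=27
mem - v_hipp: P(edge) = 1.00, partial = 0.28 (sd 0.02)
P(0.1 <= rho <= 0.3) = 0.81
network at 50% cutoff: 38 edges
avg |Pearson| = 0.11, avg |partial| = 0.04
zeroed: Pearson 37%, partial 78%
```

Reading the output: the memory–hippocampal-volume pair is conditionally
dependent with posterior probability 1 and a partial correlation of about
0.28 with posterior SD 0.02; the thresholded ("median probability") network
keeps pairs whose inclusion probability is at least 50%; and the partial
correlation matrix is markedly sparser and smaller in magnitude than the
naive Pearson baseline, because conditioning strips away the dependence that
confounders and mediators induce.

The same workflow is available from the shell:

```bash
copulanet simulate --seed 7 --out cohort.csv --truth truth.json
copulanet fit --cohort cohort.csv --iterations 20000 --burnin 5000 --seed 7 --out trace.npz
copulanet summarize --trace trace.npz --cohort cohort.csv --out-dir results/
copulanet all --seed 7 --out-dir results/   # full pipeline incl. figures
copulanet oracle                            # p=3 exact-vs-MCMC comparison
```

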