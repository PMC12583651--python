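import numpy as np
import pytest

from copulanet import (
    ConfigError,
    LatentMatrix,
    PriorSpec,
    edge_probabilities,
    interval_probability,
    mcmc_run,
    partial_from_precision,
    pearson_matrix,
    sparsity_report,
    summarize_partials,
    threshold_network,
)
from copulanet.sampler import MCMCTrace
from copulanet.graphs import all_pairs
from copulanet.summaries import fit_cohort


def _trace_from_arrays(p, adjacency, partials, weights=None):
    adjacency = np.asarray(adjacency, dtype=np.uint8)
    partials = np.asarray(partials, dtype=float)
    S = adjacency.shape[0]
    return MCMCTrace(
        p=p,
        pairs=all_pairs(p),
        adjacency=adjacency,
        partials=partials,
        weights=np.ones(S) if weights is None else np.asarray(weights, float),
        edge_counts=adjacency.sum(axis=1),
        iterations=S,
        burnin=0,
        thin=1,
        seed=0,
    )


def test_partial_from_precision_examples():
    K = np.array([[2.0, 1.0, 0.0], [1.0, 2.0, 1.0], [0.0, 1.0, 2.0]])
    rho = partial_from_precision(K)
    assert rho[0, 1] == pytest.approx(-0.5)
    assert rho[0, 2] == 0.0
    assert rho[1, 2] == pytest.approx(-0.5)
    assert np.all(np.diag(rho) == 0.0)
    K2 = np.array([[1.0, -0.5], [-0.5, 1.0]])
    assert partial_from_precision(K2)[0, 1] == pytest.approx(0.5)
    assert np.all(partial_from_precision(np.eye(4)) == 0.0)


def test_partial_equals_brute_force_conditional_correlation():
    """rho_ij = -k_ij/sqrt(k_ii k_jj) equals the conditional correlation of
    (i, j) given the rest, computed from Sigma = K^-1 by Schur complement."""
    rng = np.random.default_rng(0)
    for _ in range(20):
        p = int(rng.integers(3, 7))
        A = rng.normal(size=(p, p))
        K = A @ A.T + p * np.eye(p)
        sigma = np.linalg.inv(K)
        rho = partial_from_precision(K)
        for i in range(p):
            for j in range(i + 1, p):
                rest = [t for t in range(p) if t not in (i, j)]
                s11 = sigma[np.ix_([i, j], [i, j])]
                s12 = sigma[np.ix_([i, j], rest)]
                s22 = sigma[np.ix_(rest, rest)]
                cond = s11 - s12 @ np.linalg.solve(s22, s12.T)
                r = cond[0, 1] / np.sqrt(cond[0, 0] * cond[1, 1])
                assert abs(rho[i, j] - r) < 1e-10


def test_edge_probabilities_arithmetic():
    adj = np.zeros((10, 3), dtype=np.uint8)
    adj[:3, 0] = 1  # edge (0,1) in 3 of 10 samples
    adj[:, 2] = 1  # edge (1,2) always present
    trace = _trace_from_arrays(3, adj, np.zeros((10, 3)))
    mat = edge_probabilities(trace)
    assert mat[0, 1] == pytest.approx(0.3)
    assert mat[1, 2] == pytest.approx(1.0)
    # weighted: weights (2,1,1), edge in first sample only -> 0.5
    adj2 = np.array([[1], [0], [0]], dtype=np.uint8)
    t2 = _trace_from_arrays(2, adj2, np.zeros((3, 1)), weights=[2, 1, 1])
    assert edge_probabilities(t2)[0, 1] == pytest.approx(0.5)


def test_summarize_partials_spike_and_constants():
    # pair (0,1): absent always; pair (0,2): present always at 0.25; (1,2): half
    adj = np.zeros((8, 3), dtype=np.uint8)
    part = np.zeros((8, 3))
    adj[:, 1] = 1
    part[:, 1] = 0.25
    adj[:4, 2] = 1
    part[:4, 2] = 0.4
    post = summarize_partials(_trace_from_arrays(3, adj, part))
    assert post.mean_partial[0, 1] == 0.0 and post.sd_partial[0, 1] == 0.0
    assert post.spike_mass(0, 1) == 1.0
    assert post.mean_partial[0, 2] == pytest.approx(0.25)
    assert post.sd_partial[0, 2] == 0.0
    assert post.spike_mass(0, 2) == 0.0
    assert post.mean_partial[1, 2] == pytest.approx(0.2)
    # spike mass equals the fraction of exactly-zero draws
    assert post.spike_mass(1, 2) == pytest.approx(np.mean(part[:, 2] == 0.0))


def test_interval_probability_rules():
    adj = np.array([[1], [1], [0], [0]], dtype=np.uint8)
    part = np.array([[0.15], [0.3], [0.0], [0.0]])
    post = summarize_partials(_trace_from_arrays(2, adj, part))
    assert interval_probability(post, 0, 1, -1, 1) == 1.0
    assert interval_probability(post, 0, 1, 0.1, 0.2) == pytest.approx(0.25)
    # spike included iff 0 in [a, b]
    assert interval_probability(post, 0, 1, -0.05, 0.05) == pytest.approx(0.5)
    with pytest.raises(ConfigError):
        interval_probability(post, 0, 1, 0.5, 0.1)
    # additivity over a disjoint partition
    cuts = [-1, -0.2, 0.0999999, 0.24, 1]
    total = sum(
        interval_probability(post, 0, 1, a + (1e-12 if k else 0), b)
        for k, (a, b) in enumerate(zip(cuts[:-1], cuts[1:]))
    )
    assert total == pytest.approx(1.0)


def test_threshold_network_rules():
    adj = np.zeros((10, 3), dtype=np.uint8)
    part = np.zeros((10, 3))
    adj[:9, 0] = 1
    part[:9, 0] = -0.2  # prob 0.9, negative
    adj[:4, 1] = 1
    part[:4, 1] = 0.3  # prob 0.4: below cutoff
    post = summarize_partials(_trace_from_arrays(3, adj, part))
    net = threshold_network(post, cutoff=0.5)
    assert len(net) == 1
    edge = net[0]
    assert (edge.i, edge.j) == (0, 1) and edge.sign == -1
    assert edge.probability == pytest.approx(0.9)
    # monotone shrinkage over rising cutoffs
    sizes = [len(threshold_network(post, cutoff=c)) for c in (0.5, 0.7, 0.9, 0.95)]
    assert sizes == sorted(sizes, reverse=True)
    assert len(threshold_network(post, cutoff=0.95)) == 0
    with pytest.raises(ConfigError):
        threshold_network(post, cutoff=1.5)


def test_sparsity_report_arithmetic():
    rep = sparsity_report(np.zeros((4, 4)))
    assert (rep.avg_abs, rep.frac_zero, rep.frac_strong) == (0.0, 1.0, 0.0)
    m = np.zeros((4, 4))  # 6 pairs: 3 at +-0.3, 3 at 0
    m[0, 1] = m[1, 0] = 0.3
    m[0, 2] = m[2, 0] = -0.3
    m[1, 2] = m[2, 1] = 0.3
    rep = sparsity_report(m)
    assert rep.frac_zero == pytest.approx(0.5)
    assert rep.frac_strong == pytest.approx(0.5)
    assert rep.avg_abs == pytest.approx(0.15)
    assert rep.strong_cut == 0.25


def test_pearson_matrix_behaviour(small_cohort):
    cohort, _ = small_cohort
    mat, rep = pearson_matrix(cohort)
    assert np.all(np.diag(mat) == 1.0)
    assert 0 <= rep.frac_zero <= 1 and rep.frac_strong <= 1 - rep.frac_zero
    # duplicate columns stay perfectly correlated; independent noise is zeroed
    import pandas as pd
    from copulanet.data_model import CohortTable

    vals = cohort.values.copy()
    vals["g_prec"] = vals["v_prec"]
    dup = CohortTable(vals, cohort.diagnosis, cohort.dictionary)
    mat2, _ = pearson_matrix(dup)
    i, j = cohort.dictionary.index("v_prec"), cohort.dictionary.index("g_prec")
    assert mat2[i, j] == pytest.approx(1.0)


def test_pearson_recovers_known_correlation():
    rng = np.random.default_rng(4)
    n = 1000
    x = rng.normal(size=n)
    y = 0.6 * x + np.sqrt(1 - 0.36) * rng.normal(size=n)

    class _Cohort:
        dictionary = type("D", (), {"names": ["x", "y"]})()

        def to_numpy(self):
            return np.column_stack([x, y])

    mat, _ = pearson_matrix(_Cohort())
    assert mat[0, 1] == pytest.approx(0.6, abs=0.05)
    assert mat[0, 1] != 0.0


def test_pipeline_recovery_smoke(small_cohort):
    """A short chain on the small synthetic cohort finds no spurious dense
    structure and keeps probabilities in [0, 1]."""
    cohort, model = small_cohort
    trace = fit_cohort(cohort, PriorSpec(), iterations=3000, burnin=1000, thin=5, seed=1)
    post = summarize_partials(trace, names=cohort.dictionary.names)
    assert post.prob.min() >= 0 and post.prob.max() <= 1
    assert np.all(np.abs(post.mean_partial) < 1)
    # spike + continuous mass = 1 for every pair
    for i, j in [(0, 1), (2, 5), (10, 17)]:
        spike = post.spike_mass(i, j)
        cont = np.mean(post.draws(i, j) != 0.0)
        assert spike + cont == pytest.approx(1.0)
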