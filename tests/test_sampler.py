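import numpy as np
import pytest
from scipy import integrate

from copulanet import (
    ConfigError,
    Graph,
    LatentMatrix,
    NumericalError,
    PriorSpec,
    convergence_check,
    enumerate_posterior,
    gwishart_sample,
    log_posterior_unnormalized,
    mcmc_run,
)
from copulanet.sampler import (
    MCMCTrace,
    edge_probability_matrix,
    log_gwishart_norm,
)


def test_gwishart_complete_graph_wishart_moment():
    """On the complete graph the G-Wishart is an ordinary Wishart with
    E[K] = (df + p - 1) scale^-1."""
    rng = np.random.default_rng(0)
    p, df = 3, 3.0
    D = np.eye(p) + 0.3
    total = np.zeros((p, p))
    N = 10_000
    for _ in range(N):
        total += gwishart_sample(Graph.complete(p), df, D, rng)
    mean = total / N
    expected = (df + p - 1) * np.linalg.inv(D)
    assert np.max(np.abs(mean - expected) / np.abs(expected)) < 0.03


def test_gwishart_pattern_and_spd():
    rng = np.random.default_rng(1)
    g = Graph.from_edges(5, [(0, 1), (1, 2), (3, 4)])
    adj = g.adjacency()
    off = ~adj & ~np.eye(5, dtype=bool)
    for _ in range(50):
        K = gwishart_sample(g, 3.0, np.eye(5), rng)
        assert np.all(K[off] == 0.0)
        assert np.all(np.linalg.eigvalsh(K) > 0)
    # empty graph: diagonal draws
    K = gwishart_sample(Graph.empty(4), 3.0, np.eye(4), rng)
    assert np.all(K[~np.eye(4, dtype=bool)] == 0.0)
    with pytest.raises(NumericalError):
        gwishart_sample(Graph.empty(2), 3.0, np.array([[1.0, 2.0], [2.0, 1.0]]), rng)


def test_gwishart_empty_graph_gamma_margin():
    """Empty-graph diagonal entries follow Gamma(df/2, rate d_jj/2)."""
    rng = np.random.default_rng(2)
    df, djj = 3.0, 1.7
    draws = np.array([
        gwishart_sample(Graph.empty(2), df, np.diag([djj, 1.0]), rng)[0, 0]
        for _ in range(4000)
    ])
    assert abs(draws.mean() - df / djj) < 0.1
    assert abs(draws.var() - 2 * df / djj**2) < 0.3


def test_log_posterior_bernoulli_algebra(gaussian_latent_p3):
    Z = gaussian_latent_p3
    G = Graph.from_edges(3, [(0, 1), (1, 2)])
    rng = np.random.default_rng(3)
    K = gwishart_sample(G, 3.0, np.eye(3), rng)
    lp1 = log_posterior_unnormalized(G, K, Z, PriorSpec(edge_prob=0.2))
    lp2 = log_posterior_unnormalized(G, K, Z, PriorSpec(edge_prob=0.4))
    expected = 2 * np.log(0.4 / 0.2) + 1 * np.log(0.6 / 0.8)
    assert lp2 - lp1 == pytest.approx(expected, abs=1e-10)


def test_log_posterior_no_data_reduces_to_prior():
    G = Graph.from_edges(2, [(0, 1)])
    rng = np.random.default_rng(4)
    K = gwishart_sample(G, 3.0, np.eye(2), rng)
    prior = PriorSpec()
    lp = log_posterior_unnormalized(G, K, np.empty((0, 2)), prior)
    sign, logdet = np.linalg.slogdet(K)
    manual = (
        0.5 * (prior.gwishart_df - 2) * logdet
        - 0.5 * np.trace(K)
        + np.log(prior.edge_prob)
    )
    assert lp == pytest.approx(manual, abs=1e-10)


def test_p2_numerical_integration_matches_enumeration():
    """Integrating exp(log posterior) over K for both 2-node graphs reproduces
    the closed-form enumerated graph posterior."""
    rng = np.random.default_rng(5)
    Z = rng.multivariate_normal([0, 0], [[1, 0.6], [0.6, 1]], size=8)
    prior = PriorSpec()
    G1 = Graph.from_edges(2, [(0, 1)])
    G0 = Graph.empty(2)

    def mass_complete():
        def f(k12, k11, k22):
            if k11 * k22 - k12**2 <= 0:
                return 0.0
            K = np.array([[k11, k12], [k12, k22]])
            return np.exp(log_posterior_unnormalized(G1, K, Z, prior,
                                                     include_graph_constant=True))
        val, _ = integrate.tplquad(
            f, 0, 40, 0, 40,
            lambda k11, k22: -np.sqrt(k11 * k22), lambda k11, k22: np.sqrt(k11 * k22),
            epsabs=1e-10, epsrel=1e-8,
        )
        return val

    def mass_empty():
        def f(k11, k22):
            K = np.diag([k11, k22])
            return np.exp(log_posterior_unnormalized(G0, K, Z, prior,
                                                     include_graph_constant=True))
        val, _ = integrate.dblquad(f, 0, 40, 0, 40, epsabs=1e-10, epsrel=1e-8)
        return val

    m1, m0 = mass_complete(), mass_empty()
    numeric = m1 / (m0 + m1)
    exact = enumerate_posterior(Z, prior)[0, 1]
    assert numeric == pytest.approx(exact, abs=1e-4)


def test_enumerate_prior_recovery_and_symmetry():
    prior = PriorSpec(edge_prob=0.2)
    mat = enumerate_posterior(np.empty((0, 3)), prior)
    iu = np.triu_indices(3, 1)
    np.testing.assert_allclose(mat[iu], 0.2, atol=1e-12)
    # permutation equivariance
    rng = np.random.default_rng(6)
    Z = rng.normal(size=(40, 3))
    Z[:, 1] += 0.8 * Z[:, 0]
    m = enumerate_posterior((Z - Z.mean(0)) / Z.std(0), prior)
    perm = [2, 0, 1]
    Zp = Z[:, perm]
    mp = enumerate_posterior((Zp - Zp.mean(0)) / Zp.std(0), prior)
    np.testing.assert_allclose(mp, m[np.ix_(perm, perm)], atol=1e-10)
    with pytest.raises(ConfigError):
        enumerate_posterior(np.zeros((5, 4)), prior)


def test_enumerate_strong_signal_detects_edge():
    rng = np.random.default_rng(7)
    z1 = rng.normal(size=200)
    z2 = 0.8 * z1 + np.sqrt(1 - 0.64) * rng.normal(size=200)
    Z = np.column_stack([z1, z2])
    Z = (Z - Z.mean(0)) / Z.std(0)
    mat = enumerate_posterior(Z, PriorSpec())
    assert mat[0, 1] > 0.99


def test_mcmc_determinism_and_trace_io(tmp_path, gaussian_latent_p3):
    latent = LatentMatrix(gaussian_latent_p3, np.zeros(3, dtype=bool))
    kwargs = dict(iterations=2000, burnin=500, thin=5, seed=12)
    t1 = mcmc_run(latent, None, PriorSpec(), **kwargs)
    t2 = mcmc_run(latent, None, PriorSpec(), **kwargs)
    np.testing.assert_array_equal(t1.adjacency, t2.adjacency)
    np.testing.assert_array_equal(t1.partials, t2.partials)
    assert t1.n_samples == (2000 - 500) // 5
    path = tmp_path / "trace.npz"
    t1.save(path)
    loaded = MCMCTrace.load(path)
    np.testing.assert_array_equal(loaded.adjacency, t1.adjacency)
    np.testing.assert_allclose(loaded.partials, t1.partials)
    assert loaded.pairs == t1.pairs and loaded.seed == 12
    with pytest.raises(ConfigError):
        mcmc_run(latent, None, PriorSpec(), iterations=100, burnin=100)


def test_mcmc_samples_are_pattern_consistent(gaussian_latent_p3):
    """Stored partial correlations are nonzero exactly on stored edges, and the
    final precision matrix is SPD and pattern-consistent."""
    latent = LatentMatrix(gaussian_latent_p3, np.zeros(3, dtype=bool))
    trace = mcmc_run(latent, None, PriorSpec(), iterations=3000, burnin=500, thin=3, seed=8)
    absent = trace.adjacency == 0
    assert np.all(trace.partials[absent] == 0.0)
    assert np.all(trace.partials[~absent] != 0.0)
    assert np.all(np.abs(trace.partials) < 1)
    K = trace.last_precision
    assert np.all(np.linalg.eigvalsh(K) > 0)


def test_mcmc_detailed_balance_smoke(gaussian_latent_p3):
    """Starting from a full graph or an empty graph reaches the same edge
    probabilities (stationarity does not depend on the initial state)."""
    latent = LatentMatrix(gaussian_latent_p3, np.zeros(3, dtype=bool))
    prior = PriorSpec()
    a = mcmc_run(latent, None, prior, iterations=30_000, burnin=4000, thin=1,
                 seed=21, initial_graph=Graph.empty(3))
    b = mcmc_run(latent, None, prior, iterations=30_000, burnin=4000, thin=1,
                 seed=22, initial_graph=Graph.complete(3))
    diff = np.abs(edge_probability_matrix(a) - edge_probability_matrix(b))
    assert diff.max() < 0.05


def test_convergence_check():
    latent = LatentMatrix(np.random.default_rng(9).normal(size=(30, 3)), np.zeros(3, bool))
    t = mcmc_run(latent, None, PriorSpec(), iterations=20_000, burnin=2000, thin=1, seed=30)
    rep = convergence_check(t, t)
    assert rep.cross_chain_diff == 0.0
    assert rep.converged
    # a 10-sample trace is flagged
    short = mcmc_run(latent, None, PriorSpec(), iterations=40, burnin=20, thin=2, seed=31)
    rep2 = convergence_check(short)
    assert not rep2.converged


def test_decomposable_constant_additivity():
    """For a disconnected decomposable graph the log constant is the sum over
    components."""
    D = np.diag([1.2, 0.8, 1.5])
    g_single = Graph.from_edges(3, [(0, 1)])
    val = log_gwishart_norm(g_single, 3.0, D)
    # compare against directly assembled pieces: clique {0,1} plus singleton {2}
    from copulanet.sampler import _log_wishart_const
    pair = log_gwishart_norm(Graph.from_edges(2, [(0, 1)]), 3.0, D[:2, :2])
    manual = pair + _log_wishart_const(3.0, D[2:, 2:])
    assert val == pytest.approx(manual, abs=1e-12)
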