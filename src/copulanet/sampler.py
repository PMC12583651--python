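"""Trans-dimensional MCMC over graphs and G-Wishart precision matrices.

Target posterior: P(G, K | Z) proportional to P(Z | K) P(K | G) P(G), with an
independent-Bernoulli prior over edges (default inclusion probability 0.2)
and a G-Wishart(df, scale) prior on K restricted to G's zero pattern.

The sampler alternates three steps per iteration:

(a) a Gibbs sweep over discrete latent columns (copula layer);
(b) one single-edge trans-dimensional move, implemented as a double
    reversible jump with an exchange step: the single-edge conditional Bayes
    factor has closed form (a Gaussian x Gamma block integral), and the
    intractable ratio of G-Wishart prior normalizing constants is cancelled
    exactly by evaluating the same closed form on an auxiliary draw from the
    G-Wishart prior under the proposed graph — no normalizing constant is
    ever evaluated;
(c) a full refresh of K from its conditional posterior
    G-Wishart(df + n, scale + Z'Z) via the direct sampler (unconstrained
    Wishart draw followed by iterative-proportional-scaling completion to
    the graph's zero pattern).

For p <= 3 every graph is decomposable, so the posterior over all graphs has
a closed form via clique/separator factorization; ``enumerate_posterior``
computes it exactly and serves as the correctness oracle for the chain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from numba import njit
from scipy.special import gammaln, logsumexp, multigammaln

from .copula import LatentMatrix, resample_discrete_latents
from .data_model import CohortTable
from .errors import ConfigError, NumericalError, ValidationError
from .graphs import Graph, PrecisionMatrix, all_pairs, is_spd, partial_correlations

logger = logging.getLogger(__name__)

#: Diagonal jitter permitted inside the sampler's completion step.
_JITTER = 1e-10
_MAX_RETRIES = 25


@dataclass(frozen=True)
class PriorSpec:
    """Prior over (G, K): Bernoulli(edge_prob) edges, G-Wishart(df, scale) K."""

    edge_prob: float = 0.2
    gwishart_df: float = 3.0
    gwishart_scale: Optional[np.ndarray] = None  # default: identity

    def __post_init__(self) -> None:
        if not (0 < self.edge_prob < 1):
            raise ConfigError("edge_prob must lie in (0, 1)")
        if self.gwishart_df <= 2:
            raise ConfigError("gwishart_df must exceed 2")
        if self.gwishart_scale is not None and not is_spd(np.asarray(self.gwishart_scale)):
            raise ConfigError("gwishart_scale must be SPD")

    def scale_matrix(self, p: int) -> np.ndarray:
        if self.gwishart_scale is None:
            return np.eye(p)
        D = np.asarray(self.gwishart_scale, dtype=float)
        if D.shape != (p, p):
            raise ConfigError("gwishart_scale has wrong dimension")
        return D


# ---------------------------------------------------------------------------
# G-Wishart direct sampler
# ---------------------------------------------------------------------------


@njit(cache=True)
def _ips_complete(sigma: np.ndarray, adj: np.ndarray, tol: float, max_sweeps: int) -> np.ndarray:
    """Complete sigma to the covariance whose inverse has G's zero pattern.

    Cyclic regression updates (Hastie-Tibshirani-Friedman): for each node j,
    regress on its neighbours only; at the fixed point W matches sigma on the
    diagonal and on edges, while inv(W) vanishes on non-edges.
    """
    p = sigma.shape[0]
    W = sigma.copy()
    for _ in range(max_sweeps):
        diff = 0.0
        for j in range(p):
            nb = np.where(adj[j])[0]
            if nb.size == 0:
                for r in range(p):
                    if r != j:
                        d = abs(W[r, j])
                        if d > diff:
                            diff = d
                        W[r, j] = 0.0
                        W[j, r] = 0.0
            else:
                Wnn = W[nb][:, nb].copy()
                snj = sigma[nb, j].copy()
                beta = np.linalg.solve(Wnn, snj)
                wj = W[:, nb] @ beta
                for r in range(p):
                    if r != j:
                        d = abs(wj[r] - W[r, j])
                        if d > diff:
                            diff = d
                        W[r, j] = wj[r]
                        W[j, r] = wj[r]
        if diff < tol:
            break
    return W


def _wishart_draw(df_gw: float, scale_chol_inv: np.ndarray, rng) -> np.ndarray:
    """Draw K ~ Wishart with G-Wishart parameterization on the complete graph.

    Density proportional to |K|^((df-2)/2) exp(-tr(D K)/2); equals the
    standard Wishart with n = df + p - 1 degrees of freedom and scale D^-1.
    ``scale_chol_inv`` is L with L L' = D^-1 (Bartlett decomposition).
    """
    p = scale_chol_inv.shape[0]
    n = df_gw + p - 1
    A = np.zeros((p, p))
    for i in range(p):
        A[i, i] = np.sqrt(rng.chisquare(n - i))
    idx = np.tril_indices(p, -1)
    A[idx] = rng.standard_normal(len(idx[0]))
    L = scale_chol_inv @ A
    return L @ L.T


def gwishart_sample(
    graph: Graph,
    df: float,
    scale: np.ndarray,
    rng,
    tol: float = 1e-9,
    max_sweeps: int = 200,
) -> np.ndarray:
    """Exact draw from the G-Wishart(df, scale) restricted to ``graph``.

    Direct sampler: draw an unconstrained Wishart variate, invert, and
    complete its covariance to the graph by iterative proportional scaling;
    the inverse of the completion is the constrained draw. Non-edge entries
    are exact zeros; a failed positive-definiteness check retries with fresh
    randomness and a logged diagonal jitter.
    """
    D = np.asarray(scale, dtype=float)
    if not is_spd(D):
        raise NumericalError("G-Wishart scale must be SPD")
    Dinv = np.linalg.inv(D)
    chol = np.linalg.cholesky(Dinv)
    adj = graph.adjacency()
    off = ~adj & ~np.eye(graph.p, dtype=bool)
    for attempt in range(_MAX_RETRIES):
        Kfull = _wishart_draw(df, chol, rng)
        sigma = np.linalg.inv(Kfull)
        W = _ips_complete(sigma, adj, tol, max_sweeps)
        try:
            K = np.linalg.inv(W)
        except np.linalg.LinAlgError:
            continue
        K[off] = 0.0
        K = 0.5 * (K + K.T)
        if is_spd(K):
            return K
        K_j = K + _JITTER * np.eye(graph.p)
        if is_spd(K_j):
            logger.warning("gwishart_sample: applied %.0e diagonal jitter", _JITTER)
            return K_j
    raise NumericalError("gwishart_sample: SPD completion failed repeatedly")


# ---------------------------------------------------------------------------
# Closed-form pieces
# ---------------------------------------------------------------------------


def _log_wishart_const(df_gw: float, D_sub: np.ndarray) -> float:
    """log normalizing constant of the complete-graph G-Wishart on a clique."""
    D_sub = np.atleast_2d(D_sub)
    q = D_sub.shape[0]
    n = df_gw + q - 1
    sign, logdet = np.linalg.slogdet(D_sub)
    if sign <= 0:
        raise NumericalError("clique scale block is not positive definite")
    return 0.5 * n * q * np.log(2.0) - 0.5 * n * logdet + multigammaln(0.5 * n, q)


def _decomposable_cliques(graph: Graph) -> Tuple[list, list]:
    """Cliques and separators for p <= 3 graphs (all are decomposable)."""
    p, edges = graph.p, sorted(graph.edges)
    if p == 2:
        return ([[0, 1]], []) if edges else ([[0], [1]], [])
    if p != 3:
        raise ConfigError("exact enumeration supports p <= 3 only")
    m = len(edges)
    if m == 0:
        return [[0], [1], [2]], []
    if m == 1:
        (i, j) = edges[0]
        k = ({0, 1, 2} - {i, j}).pop()
        return [[i, j], [k]], []
    if m == 2:
        hub = (set(edges[0]) & set(edges[1])).pop()
        return [sorted(e) for e in edges], [[hub]]
    return [[0, 1, 2]], []


def log_gwishart_norm(graph: Graph, df: float, scale: np.ndarray) -> float:
    """Exact log G-Wishart normalizing constant for decomposable p <= 3 graphs."""
    cliques, seps = _decomposable_cliques(graph)
    D = np.asarray(scale, dtype=float)
    out = 0.0
    for c in cliques:
        out += _log_wishart_const(df, D[np.ix_(c, c)])
    for s in seps:
        out -= _log_wishart_const(df, D[np.ix_(s, s)])
    return out


def log_posterior_unnormalized(
    G: Graph,
    K: np.ndarray,
    Z: np.ndarray,
    prior: PriorSpec,
    include_graph_constant: bool = False,
) -> float:
    """log P(G, K | Z) up to graph-independent constants.

    Sum of the N(0, K^-1) log likelihood of Z, the unnormalized G-Wishart log
    density of K, and the Bernoulli edge log prior. With
    ``include_graph_constant`` the exact -log I_G(df, scale) is added (closed
    form, p <= 3 only), making graph-to-graph comparisons meaningful.
    """
    K = np.asarray(K, dtype=float)
    p = G.p
    adj = G.adjacency()
    off = ~adj & ~np.eye(p, dtype=bool)
    if np.any(np.abs(K[off]) > 1e-8):
        raise ValidationError("K has nonzero entries off the graph's pattern")
    if not is_spd(K):
        raise NumericalError("K must be SPD")
    Z = np.atleast_2d(np.asarray(Z, dtype=float)) if np.size(Z) else np.empty((0, p))
    n = Z.shape[0]
    sign, logdet = np.linalg.slogdet(K)
    S = Z.T @ Z if n else np.zeros((p, p))
    loglik = 0.5 * n * logdet - 0.5 * np.trace(S @ K)
    D = prior.scale_matrix(p)
    logprior_K = 0.5 * (prior.gwishart_df - 2.0) * logdet - 0.5 * np.trace(D @ K)
    m = G.n_edges
    m_max = p * (p - 1) // 2
    logprior_G = m * np.log(prior.edge_prob) + (m_max - m) * np.log(1 - prior.edge_prob)
    out = loglik + logprior_K + logprior_G
    if include_graph_constant:
        out -= log_gwishart_norm(G, prior.gwishart_df, D)
    return float(out)


# ---------------------------------------------------------------------------
# Exact enumeration oracle (p <= 3)
# ---------------------------------------------------------------------------


def enumerate_posterior(Z: np.ndarray, prior: PriorSpec, p: Optional[int] = None) -> np.ndarray:
    """Exact posterior edge-probability matrix for all-continuous data, p <= 3.

    Every graph on at most 3 nodes is decomposable, so
    P(G | Z) ~ P(G) * I_G(df + n, D + Z'Z) / I_G(df, D) in closed form; the
    edge probability is the posterior mass of graphs containing the edge.
    """
    Z = np.asarray(Z, dtype=float)
    if Z.ndim != 2:
        if p is None:
            raise ConfigError("p must be given when Z is empty")
        Z = np.empty((0, p))
    p = Z.shape[1] if p is None else p
    if p > 3 or p < 2:
        raise ConfigError("enumerate_posterior supports 2 <= p <= 3 (non-decomposable graphs appear at p=4)")
    n = Z.shape[0]
    D = prior.scale_matrix(p)
    Dstar = D + (Z.T @ Z if n else 0.0)
    pairs = all_pairs(p)
    graphs, logws = [], []
    for bits in range(2 ** len(pairs)):
        edges = [pairs[t] for t in range(len(pairs)) if (bits >> t) & 1]
        G = Graph.from_edges(p, edges)
        m = G.n_edges
        logw = (
            m * np.log(prior.edge_prob)
            + (len(pairs) - m) * np.log(1 - prior.edge_prob)
            + log_gwishart_norm(G, prior.gwishart_df + n, Dstar)
            - log_gwishart_norm(G, prior.gwishart_df, D)
        )
        graphs.append(G)
        logws.append(logw)
    logws = np.asarray(logws)
    probs = np.exp(logws - logsumexp(logws))
    mat = np.zeros((p, p))
    for G, w in zip(graphs, probs):
        for i, j in G.edges:
            mat[i, j] += w
            mat[j, i] += w
    return mat


# ---------------------------------------------------------------------------
# Single-edge conditional Bayes factor (the DRJ/exchange closed form)
# ---------------------------------------------------------------------------


def _log_block_ratio(K: np.ndarray, i: int, j: int, df_gw: float, D: np.ndarray) -> float:
    """log N1/N0: edge-present over edge-absent block integrals at edge (i,j).

    Conditioning on every entry of K except (k_ij, k_jj) and integrating the
    free block under |K|^((df-2)/2) exp(-tr(DK)/2) gives
    Gamma x Gaussian integrals whose ratio is
    sqrt(2 pi / (d_jj a)) * exp((d_jj m + d_ij)^2 / (2 d_jj a)),
    with a = (A^-1)_ii, m = (A^-1 u0)_i, A = K without row/column j and u0
    the j-column of K with its i-entry zeroed.
    """
    p = K.shape[0]
    idx = np.array([t for t in range(p) if t != j])
    A = K[np.ix_(idx, idx)]
    u0 = K[idx, j].copy()
    ipos = int(np.flatnonzero(idx == i)[0])
    u0[ipos] = 0.0
    e = np.zeros(p - 1)
    e[ipos] = 1.0
    try:
        y = np.linalg.solve(A, e)
    except np.linalg.LinAlgError as exc:
        raise NumericalError("singular conditioning block in edge move") from exc
    a = y[ipos]
    if a <= 0:
        raise NumericalError("conditioning block lost positive definiteness")
    m = float(y @ u0)
    djj = D[j, j]
    beta = djj * m + D[i, j]
    return 0.5 * np.log(2.0 * np.pi / (djj * a)) + beta**2 / (2.0 * djj * a)


def _set_edge_block(
    K: np.ndarray, i: int, j: int, present: bool, df_gw: float, D: np.ndarray, rng
) -> None:
    """Redraw (k_ij, k_jj) in place from their exact conditional given the rest."""
    p = K.shape[0]
    idx = np.array([t for t in range(p) if t != j])
    A = K[np.ix_(idx, idx)]
    u = K[idx, j].copy()
    ipos = int(np.flatnonzero(idx == i)[0])
    e = np.zeros(p - 1)
    e[ipos] = 1.0
    y = np.linalg.solve(A, e)
    a = y[ipos]
    djj = D[j, j]
    if present:
        u0 = u.copy()
        u0[ipos] = 0.0
        m = float(y @ u0)
        beta = djj * m + D[i, j]
        kij = rng.normal(-beta / (djj * a), np.sqrt(1.0 / (djj * a)))
        u[ipos] = kij
    else:
        u[ipos] = 0.0
    gamma = rng.gamma(shape=0.5 * df_gw, scale=2.0 / djj)
    quad = float(u @ np.linalg.solve(A, u))
    K[idx, j] = u
    K[j, idx] = u
    K[j, j] = gamma + quad
    K[i, j] = K[j, i] = u[ipos]


# ---------------------------------------------------------------------------
# MCMC
# ---------------------------------------------------------------------------


@dataclass
class MCMCTrace:
    """Thinned post-burn-in samples of (G, K), stored per variable pair.

    ``partials[s, t]`` is the partial correlation of pair ``pairs[t]`` in
    sample s, exactly zero when the edge is absent; ``adjacency`` stores the
    edge indicators. Weights are 1 for this discrete-time chain (a
    waiting-time-weighted continuous-time variant would store its holding
    times there).
    """

    p: int
    pairs: list
    adjacency: np.ndarray  # (S, n_pairs) uint8
    partials: np.ndarray  # (S, n_pairs) float
    weights: np.ndarray  # (S,)
    edge_counts: np.ndarray  # (S,)
    iterations: int
    burnin: int
    thin: int
    seed: int
    accept_rate: float = float("nan")
    last_precision: Optional[np.ndarray] = None

    @property
    def n_samples(self) -> int:
        return self.adjacency.shape[0]

    def save(self, path) -> None:
        """Write an npz container with fixed zip timestamps (byte-reproducible)."""
        import io
        import zipfile

        arrays = {
            "adjacency": self.adjacency,
            "partials": self.partials,
            "weights": self.weights,
            "edge_counts": self.edge_counts,
            "pairs": np.asarray(self.pairs),
            "meta": np.asarray([self.p, self.iterations, self.burnin, self.thin, self.seed]),
            "accept_rate": np.asarray([self.accept_rate]),
            "last_precision": self.last_precision
            if self.last_precision is not None
            else np.empty(0),
        }
        with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
            for name, arr in arrays.items():
                buf = io.BytesIO()
                np.lib.format.write_array(buf, np.ascontiguousarray(arr))
                info = zipfile.ZipInfo(name + ".npy", date_time=(1980, 1, 1, 0, 0, 0))
                info.compress_type = zipfile.ZIP_DEFLATED
                zf.writestr(info, buf.getvalue())

    @classmethod
    def load(cls, path) -> "MCMCTrace":
        data = np.load(path, allow_pickle=False)
        p, iterations, burnin, thin, seed = (int(v) for v in data["meta"])
        lp = data["last_precision"]
        return cls(
            p=p,
            pairs=[tuple(int(v) for v in pr) for pr in data["pairs"]],
            adjacency=data["adjacency"],
            partials=data["partials"],
            weights=data["weights"],
            edge_counts=data["edge_counts"],
            iterations=iterations,
            burnin=burnin,
            thin=thin,
            seed=seed,
            accept_rate=float(data["accept_rate"][0]),
            last_precision=lp if lp.size else None,
        )


def mcmc_run(
    Z0: LatentMatrix,
    observed: Optional[CohortTable],
    prior: PriorSpec,
    iterations: int = 120_000,
    burnin: int = 20_000,
    thin: int = 10,
    seed: int = 0,
    initial_graph: Optional[Graph] = None,
    initial_K: Optional[np.ndarray] = None,
) -> MCMCTrace:
    """Run the trans-dimensional chain targeting P(G, K | Z).

    ``observed`` may be None when every column is continuous (no per-iteration
    copula resampling). The chain is fully reproducible from ``seed``.
    """
    if iterations <= burnin:
        raise ConfigError("iterations must exceed burnin")
    if thin < 1:
        raise ConfigError("thin must be >= 1")
    latent = Z0.copy()
    p = latent.p
    n = latent.n
    has_discrete = bool(latent.discrete_mask.any())
    if has_discrete and observed is None:
        raise ConfigError("observed data required when discrete columns are present")
    rng = np.random.default_rng(seed)
    D = prior.scale_matrix(p)
    df = prior.gwishart_df
    df_post = df + n
    pairs = all_pairs(p)
    pair_pos = {e: t for t, e in enumerate(pairs)}
    log_odds_in = np.log(prior.edge_prob) - np.log(1 - prior.edge_prob)

    G = initial_graph if initial_graph is not None else Graph.empty(p)
    if initial_K is not None:
        K = np.asarray(initial_K, dtype=float).copy()
    else:
        K = gwishart_sample(G, df, D, rng)

    S = latent.values.T @ latent.values
    Dstar = D + S

    n_keep = (iterations - burnin) // thin
    adjacency = np.zeros((n_keep, len(pairs)), dtype=np.uint8)
    partials = np.zeros((n_keep, len(pairs)))
    edge_counts = np.zeros(n_keep, dtype=np.int64)
    kept = 0
    accepted = 0

    for it in range(iterations):
        # (a) copula resampling of discrete latent columns
        if has_discrete:
            resample_discrete_latents(latent, observed, K, rng)
            S = latent.values.T @ latent.values
            Dstar = D + S

        # (b) single-edge double-reversible-jump move with exchange step
        i, j = pairs[rng.integers(len(pairs))]
        adding = not G.has_edge(i, j)
        G_prop = G.flip(i, j)
        K_aux = gwishart_sample(G_prop, df, D, rng)
        log_r_post = _log_block_ratio(K, i, j, df_post, Dstar)
        log_r_prior = _log_block_ratio(K_aux, i, j, df, D)
        if adding:
            log_alpha = log_odds_in + log_r_post - log_r_prior
        else:
            log_alpha = -log_odds_in - log_r_post + log_r_prior
        if np.log(rng.uniform()) < log_alpha:
            G = G_prop
            _set_edge_block(K, i, j, present=adding, df_gw=df_post, D=Dstar, rng=rng)
            accepted += 1

        # (c) within-graph refresh from the conditional posterior
        K = gwishart_sample(G, df_post, Dstar, rng)

        if it >= burnin and (it - burnin) % thin == 0 and kept < n_keep:
            rho = partial_correlations(K)
            for e, t in pair_pos.items():
                if e in G.edges:
                    adjacency[kept, t] = 1
                    partials[kept, t] = rho[e[0], e[1]]
            edge_counts[kept] = G.n_edges
            kept += 1

    return MCMCTrace(
        p=p,
        pairs=pairs,
        adjacency=adjacency[:kept],
        partials=partials[:kept],
        weights=np.ones(kept),
        edge_counts=edge_counts[:kept],
        iterations=iterations,
        burnin=burnin,
        thin=thin,
        seed=seed,
        accept_rate=accepted / iterations,
        last_precision=K,
    )


# ---------------------------------------------------------------------------
# Convergence diagnostics
# ---------------------------------------------------------------------------


def edge_probability_matrix(trace: MCMCTrace) -> np.ndarray:
    """Weight-normalized edge-inclusion frequencies as a p x p matrix."""
    if trace.n_samples == 0:
        raise ValidationError("empty trace")
    w = trace.weights / trace.weights.sum()
    freq = np.clip(w @ trace.adjacency, 0.0, 1.0)
    mat = np.zeros((trace.p, trace.p))
    for (i, j), f in zip(trace.pairs, freq):
        mat[i, j] = mat[j, i] = f
    return mat


@dataclass
class ConvergenceReport:
    half_diff: float
    edge_count_mean: float
    edge_count_sd: float
    cross_chain_diff: Optional[float]
    threshold: float
    converged: bool


def convergence_check(
    trace: MCMCTrace, second_trace: Optional[MCMCTrace] = None, threshold: float = 0.05
) -> ConvergenceReport:
    """First-half vs second-half (and optional cross-chain) edge-probability drift."""
    if trace.n_samples == 0:
        raise ValidationError("empty trace")
    S = trace.n_samples
    half = S // 2
    if half == 0:
        return ConvergenceReport(np.inf, float(trace.edge_counts.mean()),
                                 float(trace.edge_counts.std()), None, threshold, False)
    p1 = trace.adjacency[:half].mean(axis=0)
    p2 = trace.adjacency[half:].mean(axis=0)
    half_diff = float(np.max(np.abs(p1 - p2))) if p1.size else 0.0
    cross = None
    if second_trace is not None:
        q1 = trace.adjacency.mean(axis=0)
        q2 = second_trace.adjacency.mean(axis=0)
        cross = float(np.max(np.abs(q1 - q2)))
    worst = max(half_diff, cross if cross is not None else 0.0)
    return ConvergenceReport(
        half_diff=half_diff,
        edge_count_mean=float(trace.edge_counts.mean()),
        edge_count_sd=float(trace.edge_counts.std()),
        cross_chain_diff=cross,
        threshold=threshold,
        converged=bool(worst < threshold),
    )
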