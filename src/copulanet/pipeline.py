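"""End-to-end orchestration, configuration, logging and figure rendering.

``run_pipeline`` chains simulate/load -> Gaussianize -> sample -> summarize ->
render and writes a manifest (config echo, seed, library versions, file
inventory, wall time) sufficient for byte-identical reruns of all seeded
computation.

Figure conventions: a network edge's width is affine in its inclusion
probability over [cutoff, 1]; blue encodes a positive and red a negative
model-averaged partial correlation. Heatmaps share a symmetric color scale
centered at zero, ordered by the variable dictionary. Density plots show the
continuous part of a pair's posterior plus a spike bar at zero whose height
is the posterior probability of conditional independence.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
import sys
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .data_model import CohortTable, VariableDictionary, load_cohort, merged_dictionary, split_dictionary, write_cohort
from .errors import ConfigError
from .graphs import all_pairs
from .sampler import MCMCTrace, PriorSpec, convergence_check
from .summaries import (
    DEFAULT_EDGE_CUTOFF,
    DEFAULT_PEARSON_ALPHA,
    DEFAULT_STRONG_CUT,
    EdgePosterior,
    NetworkEdge,
    fit_cohort,
    pearson_matrix,
    sparsity_report,
    stratified_run,
    summarize_partials,
    threshold_network,
)
from .synthetic import default_config, generate_cohort

logger = logging.getLogger(__name__)

plt.rcParams["svg.hashsalt"] = "copulanet"


@dataclass
class PipelineConfig:
    """Run-level settings mirrored completely by CLI flags."""

    mode: str = "merged"  # merged (19 variables) | split (31)
    cohort_path: Optional[str] = None  # when None, simulate
    simulate_structure: str = "ad_motif"
    simulate_stage_effects: bool = True
    simulate_variance_compression: bool = False
    prior_edge_prob: float = 0.2
    gwishart_df: float = 3.0
    iterations: int = 120_000
    burnin: int = 20_000
    thin: int = 10
    edge_cutoff: float = DEFAULT_EDGE_CUTOFF
    pearson_alpha: float = DEFAULT_PEARSON_ALPHA
    strong_cut: float = DEFAULT_STRONG_CUT
    stratify: bool = False
    stratify_iterations: int = 20_000
    stratify_burnin: int = 5_000
    out_dir: str = "results"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for name in ("edge_cutoff", "pearson_alpha", "strong_cut"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ConfigError(f"{name} must lie in (0, 1)")
        if self.mode not in ("merged", "split"):
            raise ConfigError("mode must be merged or split")
        if self.iterations <= self.burnin:
            raise ConfigError("iterations must exceed burnin")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def prior(self) -> PriorSpec:
        return PriorSpec(edge_prob=self.prior_edge_prob, gwishart_df=self.gwishart_df)

    def dictionary(self) -> VariableDictionary:
        return merged_dictionary() if self.mode == "merged" else split_dictionary()


def _setup_logging(config: PipelineConfig, out_dir: Path) -> None:
    handlers = [logging.StreamHandler(sys.stderr), logging.FileHandler(out_dir / "run.log")]
    logging.basicConfig(
        level=getattr(logging, config.log_level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def edges_table(posterior: EdgePosterior) -> pd.DataFrame:
    rows = []
    names = posterior.names or [str(k) for k in range(posterior.p)]
    for i, j in posterior.pairs:
        rows.append(
            {
                "i": i,
                "j": j,
                "name_i": names[i],
                "name_j": names[j],
                "prob": posterior.prob[i, j],
                "mean_partial": posterior.mean_partial[i, j],
                "sd_partial": posterior.sd_partial[i, j],
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis and return (and write) the run manifest."""
    t_start = time.time()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _setup_logging(config, out_dir)
    logger.info("pipeline start: seed=%d mode=%s", config.seed, config.mode)
    logger.info(
        "versions: python=%s numpy=%s pandas=%s copulanet=%s",
        platform.python_version(), np.__version__, pd.__version__, _pkg_version,
    )
    dictionary = config.dictionary()

    stage = "simulate/load"
    try:
        if config.cohort_path is None:
            if config.mode != "merged":
                raise ConfigError("the synthetic generator produces merged-mode cohorts")
            gen = default_config(
                seed=config.seed,
                structure=config.simulate_structure,
                stage_effects=config.simulate_stage_effects,
                variance_compression=config.simulate_variance_compression,
            )
            cohort, truth = generate_cohort(gen)
            write_cohort(cohort, out_dir / "cohort.csv")
            truth_payload = {
                "edges": sorted([list(e) for e in truth.graph.edges]),
                "partials": {
                    f"{i},{j}": float(truth.partials[i, j]) for i, j in truth.graph.edges
                },
            }
            (out_dir / "truth.json").write_text(json.dumps(truth_payload, indent=1))
        else:
            cohort = load_cohort(config.cohort_path, dictionary)
        logger.info("cohort: n=%d p=%d", cohort.n, cohort.p)

        stage = "fit"
        trace = fit_cohort(
            cohort,
            config.prior(),
            iterations=config.iterations,
            burnin=config.burnin,
            thin=config.thin,
            seed=config.seed,
        )
        trace.save(out_dir / "trace.npz")
        report = convergence_check(trace)
        logger.info(
            "fit done: accept=%.3f half-diff=%.4f converged=%s",
            trace.accept_rate, report.half_diff, report.converged,
        )

        stage = "summarize"
        posterior = summarize_partials(trace, names=dictionary.names)
        edges_df = edges_table(posterior)
        edges_df.to_csv(out_dir / "edges.csv", index=False)
        pearson, pearson_rep = pearson_matrix(cohort, alpha=config.pearson_alpha)
        pd.DataFrame(pearson, index=dictionary.names, columns=dictionary.names).to_csv(
            out_dir / "pearson.csv"
        )
        partial_zeroed = np.where(
            posterior.prob >= config.edge_cutoff, posterior.mean_partial, 0.0
        )
        partial_rep = sparsity_report(
            posterior.mean_partial, zeroed=partial_zeroed, strong_cut=config.strong_cut
        )
        sparsity = {
            "pearson": asdict(pearson_rep),
            "partial": asdict(partial_rep),
            "convergence": {
                "half_diff": report.half_diff,
                "converged": report.converged,
                "edge_count_mean": report.edge_count_mean,
            },
        }
        (out_dir / "sparsity.json").write_text(json.dumps(sparsity, indent=1))

        comparison_file = None
        if config.stratify:
            strat = stratified_run(
                cohort,
                config.prior(),
                iterations=config.stratify_iterations,
                burnin=config.stratify_burnin,
                thin=config.thin,
                seed=config.seed,
                cutoff=config.edge_cutoff,
            )
            strat.comparison.to_json(out_dir / "comparison.json", orient="index", indent=1)
            comparison_file = "comparison.json"

        stage = "render"
        network = threshold_network(posterior, cutoff=config.edge_cutoff)
        render_network(
            network, dictionary.names, out_dir / "network.svg",
            layout_seed=config.seed, cutoff=config.edge_cutoff,
        )
        for name, nodes in subnetwork_views(dictionary, network).items():
            sub = [e for e in network if e.i in nodes and e.j in nodes]
            render_network(
                sub, dictionary.names, out_dir / f"network_{name}.svg",
                layout_seed=config.seed, cutoff=config.edge_cutoff, node_subset=sorted(nodes),
            )
        render_heatmaps(
            pearson, partial_zeroed, dictionary.names,
            out_dir / "heatmap_pearson.svg", out_dir / "heatmap_partial.svg",
            titles=("Pearson correlation", "Partial correlation"),
        )
    except Exception:
        logger.exception("pipeline failed at stage %r", stage)
        raise

    skip = {"manifest.json", "run.log"}  # the log carries wall-clock timestamps
    files = sorted(f.name for f in out_dir.iterdir() if f.is_file() and f.name not in skip)
    manifest = {
        "config": asdict(config),
        "seed": config.seed,
        "n_variables": len(dictionary),
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "copulanet": _pkg_version,
        },
        "files": {name: _sha256(out_dir / name) for name in files},
        "wall_time_s": round(time.time() - t_start, 2),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    logger.info("pipeline done in %.1fs", manifest["wall_time_s"])
    return manifest


# ---------------------------------------------------------------------------
# Figure rendering
# ---------------------------------------------------------------------------

#: Named node-subset views of the thresholded network. Each view keeps the
#: listed role groups plus any node lying on a length-2 path between them
#: (the "indirect pathway" nodes).
_VIEW_ROLES = {
    "age_cognition": ({"age"}, {"mem", "ef"}),
    "sex_cognition": ({"sex"}, {"mem", "ef"}),
    "biomarkers_cognition": ("biomarker", {"mem", "ef"}),
    "demographics_biomarkers": ({"age", "sex", "edu"}, "biomarker"),
    "volume_glucose": ("volume", "glucose"),
}


def _role_nodes(dictionary: VariableDictionary, selector) -> set:
    if isinstance(selector, set):
        return {dictionary.index(n) for n in selector}
    if selector == "biomarker":
        return {k for k, s in enumerate(dictionary) if s.role in ("amyloid", "volume", "glucose")}
    return {k for k, s in enumerate(dictionary) if s.role == selector}


def subnetwork_views(dictionary: VariableDictionary, network: Sequence[NetworkEdge]) -> Dict[str, set]:
    adj: Dict[int, set] = {}
    for e in network:
        adj.setdefault(e.i, set()).add(e.j)
        adj.setdefault(e.j, set()).add(e.i)
    views = {}
    for name, (sel_a, sel_b) in _VIEW_ROLES.items():
        a = _role_nodes(dictionary, sel_a)
        b = _role_nodes(dictionary, sel_b)
        keep = a | b
        for node, nbrs in adj.items():
            if node not in keep and (nbrs & a) and (nbrs & b):
                keep.add(node)
        views[name] = keep
    return views


def _edge_width(probability: float, cutoff: float) -> float:
    """Affine width in [0.75, 4.5] over probabilities in [cutoff, 1]."""
    lo, hi = 0.75, 4.5
    t = (probability - cutoff) / (1.0 - cutoff)
    return lo + (hi - lo) * float(np.clip(t, 0.0, 1.0))


def render_network(
    network: Sequence[NetworkEdge],
    names: Sequence[str],
    path,
    layout_seed: int = 0,
    cutoff: float = DEFAULT_EDGE_CUTOFF,
    node_subset: Optional[Sequence[int]] = None,
) -> None:
    """Node-link diagram; width = probability, blue positive / red negative."""
    g = nx.Graph()
    nodes = list(node_subset) if node_subset is not None else list(range(len(names)))
    g.add_nodes_from(nodes)
    for e in network:
        g.add_edge(e.i, e.j, probability=e.probability, partial=e.mean_partial)
    pos = nx.spring_layout(g, seed=layout_seed)
    fig, ax = plt.subplots(figsize=(8, 8))
    widths = [_edge_width(d["probability"], cutoff) for _, _, d in g.edges(data=True)]
    colors = ["#2166ac" if d["partial"] >= 0 else "#b2182b" for _, _, d in g.edges(data=True)]
    nx.draw_networkx_edges(g, pos, ax=ax, width=widths, edge_color=colors)
    nx.draw_networkx_nodes(g, pos, ax=ax, node_color="#f0f0f0", edgecolors="#333333", node_size=900)
    nx.draw_networkx_labels(g, pos, labels={k: names[k] for k in g.nodes}, ax=ax, font_size=7)
    ax.set_axis_off()
    fig.savefig(path, metadata={"Date": None} if str(path).endswith(".svg") else None)
    plt.close(fig)


def render_heatmaps(
    pearson: np.ndarray,
    partial: np.ndarray,
    names: Sequence[str],
    path_pearson,
    path_partial,
    titles: Tuple[str, str] = ("", ""),
) -> None:
    """Two heatmaps on one shared symmetric color scale centered at zero."""
    import seaborn as sns

    vmax = float(max(np.abs(pearson).max(), np.abs(partial).max(), 1e-12))
    for mat, path, title in (
        (pearson, path_pearson, titles[0]),
        (partial, path_partial, titles[1]),
    ):
        fig, ax = plt.subplots(figsize=(9, 8))
        plot = np.array(mat, dtype=float).copy()
        np.fill_diagonal(plot, 0.0)
        sns.heatmap(
            pd.DataFrame(plot, index=list(names), columns=list(names)),
            cmap="RdBu", vmin=-vmax, vmax=vmax, center=0.0, square=True,
            cbar_kws={"shrink": 0.7}, ax=ax,
        )
        ax.set_title(title)
        fig.tight_layout()
        fig.savefig(path, metadata={"Date": None} if str(path).endswith(".svg") else None)
        plt.close(fig)


def render_density(posterior: EdgePosterior, i: int, j: int, path, bandwidth=None) -> None:
    """Posterior density of one pair: continuous part plus a spike bar at zero."""
    draws = posterior.draws(i, j)
    if draws.size == 0:
        raise ConfigError("pair has no stored draws")
    spike = posterior.spike_mass(i, j)
    nonzero = draws[draws != 0.0]
    mean = posterior.mean_partial[i, j]
    sd = posterior.sd_partial[i, j]
    fig, ax = plt.subplots(figsize=(6, 4))
    if nonzero.size > 1 and nonzero.std() > 0:
        from scipy.stats import gaussian_kde

        kde = gaussian_kde(nonzero, bw_method=bandwidth)
        grid = np.linspace(nonzero.min() - 0.05, nonzero.max() + 0.05, 400)
        # scale the continuous part by its posterior mass
        ax.fill_between(grid, kde(grid) * (1.0 - spike), color="#2166ac", alpha=0.5)
    if spike > 0:
        ax.bar([0.0], [spike], width=0.012, color="#333333", label=f"spike mass {spike:.2f}")
    names = posterior.names
    label = f"{names[i]} - {names[j]}" if names else f"{i} - {j}"
    ax.set_title(f"{label}: mean={mean:.3f}, sd={sd:.3f}, spike={spike:.3f}")
    ax.set_xlabel("partial correlation")
    ax.set_ylabel("density / probability")
    fig.tight_layout()
    fig.savefig(path, metadata={"Date": None} if str(path).endswith(".svg") else None)
    plt.close(fig)
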