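import numpy as np
import pytest
from scipy.stats import spearmanr

from copulanet import (
    ConfigError,
    GeneratorConfig,
    default_config,
    discretize,
    generate_cohort,
    make_true_model,
    merged_dictionary,
    partial_correlations,
    sample_latent,
)
from copulanet.synthetic import LatentCohort, MarginSpecs


def test_true_model_band_and_pattern():
    model = make_true_model(p=19, structure="random", target_magnitude=0.2, seed=3)
    K = model.precision.values
    adj = model.graph.adjacency()
    # recompute rho from K directly: band and zero pattern
    rho = partial_correlations(K)
    off = ~adj & ~np.eye(19, dtype=bool)
    assert np.all(rho[off] == 0)
    mags = np.abs(rho[adj])
    assert mags.min() >= 0.5 * 0.2 and mags.max() <= 1.5 * 0.2
    # inverse is a valid covariance
    sigma = model.covariance()
    assert np.all(np.linalg.eigvalsh(sigma) > 0)


def test_true_model_degenerate_densities():
    empty = make_true_model(p=5, edge_density=0.0, seed=0)
    assert empty.graph.n_edges == 0
    assert np.allclose(empty.precision.values, np.diag(np.diag(empty.precision.values)))
    full = make_true_model(p=3, edge_density=1.0, seed=0)
    assert full.graph.n_edges == 3
    assert np.all(partial_correlations(full.precision.values)[np.triu_indices(3, 1)] != 0)
    with pytest.raises(ConfigError):
        make_true_model(p=1)
    with pytest.raises(ConfigError):
        make_true_model(p=4, edge_density=1.5)


def test_ad_motif_wires_key_pathways():
    d = merged_dictionary()
    model = make_true_model(p=19, structure="ad_motif", seed=1, dictionary=d)
    g = model.graph
    assert g.has_edge(d.index("mem"), d.index("v_hipp"))
    assert g.has_edge(d.index("ef"), d.index("v_pcc"))
    assert g.has_edge(d.index("apoe4"), d.index("amyloid"))
    assert g.has_edge(d.index("amyloid"), d.index("mem"))


def test_sample_latent_moments():
    d = merged_dictionary()
    model = make_true_model(p=19, edge_density=0.0, seed=0)  # K = I
    cfg = GeneratorConfig(dictionary=d, model=model,
                          group_sizes={"CN": 10_000, "EMCI": 0, "LMCI": 0, "AD": 0})
    lat = sample_latent(model, cfg)
    n = lat.values.shape[0]
    assert np.all(np.abs(lat.values.mean(0)) < 4 / np.sqrt(n))
    assert np.all(np.abs(lat.values.var(0) - 1) < 0.1)


def test_group_variance_scaling():
    d = merged_dictionary()
    model = make_true_model(p=19, edge_density=0.2, seed=2)
    cfg = GeneratorConfig(
        dictionary=d, model=model,
        group_sizes={"CN": 4000, "EMCI": 0, "LMCI": 0, "AD": 4000},
        group_variance_scale={"AD": 0.5},
    )
    lat = sample_latent(model, cfg)
    cn = lat.values[lat.diagnosis == "CN"]
    ad = lat.values[lat.diagnosis == "AD"]
    ratio = ad.std(0) / cn.std(0)
    assert np.all(np.abs(ratio - 0.5) < 0.05)


def test_determinism_and_shapes():
    cfg = default_config(seed=9, structure="random")
    a, _ = generate_cohort(cfg)
    b, _ = generate_cohort(cfg)
    assert a.values.equals(b.values)
    assert a.n == 345 + 297 + 205 + 175
    assert a.p == 19
    assert list(a.diagnosis.unique()) == ["CN", "EMCI", "LMCI", "AD"]


def test_degenerate_group_sizes():
    d = merged_dictionary()
    model = make_true_model(p=19, edge_density=0.1, seed=4)
    cfg = GeneratorConfig(dictionary=d, model=model,
                          group_sizes={"CN": 5, "EMCI": 0, "LMCI": 0, "AD": 0})
    cohort, _ = generate_cohort(cfg)
    assert cohort.n == 5
    assert (cohort.diagnosis == "CN").all()


def test_margins_monotone_and_codings():
    cfg = default_config(seed=6, structure="random", stage_effects=False,
                         group_sizes={"CN": 10_000, "EMCI": 0, "LMCI": 0, "AD": 0})
    lat = sample_latent(cfg.model, cfg)
    cohort = discretize(lat, cfg)
    raw = cohort.to_numpy()
    # monotone: observed order never contradicts latent order, columnwise
    for j in range(cohort.p):
        order = np.argsort(lat.values[:, j], kind="stable")
        assert np.all(np.diff(raw[order, j]) >= 0)
    # sex cut near the configured pooled female fraction (53% here: CN margins)
    assert abs(raw[:, cohort.dictionary.index("sex")].mean() - 0.53) < 0.02
    # amyloid shows all five ordinal levels
    assert set(np.unique(raw[:, cohort.dictionary.index("amyloid")])) == {0, 1, 2, 3, 4}
    # cognitive composites respect the [-3, 3] bound
    assert np.all(np.abs(raw[:, cohort.dictionary.index("mem")]) <= 3)


def test_rank_preservation_through_margins():
    cfg = default_config(seed=8, structure="random", stage_effects=False,
                         group_sizes={"CN": 10_000, "EMCI": 0, "LMCI": 0, "AD": 0})
    lat = sample_latent(cfg.model, cfg)
    cohort = discretize(lat, cfg)
    d = cohort.dictionary
    for a, b in [("v_hipp", "g_hipp"), ("mem", "ef")]:
        i, j = d.index(a), d.index(b)
        r_obs = spearmanr(cohort.values[a], cohort.values[b]).statistic
        r_lat = spearmanr(lat.values[:, i], lat.values[:, j]).statistic
        assert abs(r_obs - r_lat) < 0.02


def test_bad_amyloid_cuts_rejected():
    d = merged_dictionary()
    model = make_true_model(p=19, edge_density=0.1, seed=4)
    with pytest.raises(ConfigError):
        GeneratorConfig(dictionary=d, model=model,
                        margins=MarginSpecs(amyloid_cum_frac=(0.5, 0.4, 0.6, 0.8)))
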