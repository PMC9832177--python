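import numpy as np
import pandas as pd
import pytest

from pmutual import network as nw
from pmutual import synthetic_data as sd


def _ggm_data(rng, K, n):
    Sigma = np.linalg.inv(K)
    return rng.multivariate_normal(np.zeros(len(K)), Sigma, n)


def _chain_precision(p, w=-0.3):
    K = np.eye(p)
    for i in range(p - 1):
        K[i, i + 1] = K[i + 1, i] = w
    return K


# ---------------------------------------------------------------------------
# centering
# ---------------------------------------------------------------------------

def test_centering_identities():
    panel, _ = sd.simulate(sd.DgpConfig(n_subjects=60, n_waves=4,
                                        attrition_hazard=0.15, seed=4))
    between, within, info = nw.center_within(panel)
    obs = within.observed_mask
    # per-subject mean of deviations is zero over observed waves
    sums = np.nansum(np.where(obs, within.values, 0.0), axis=1)
    np.testing.assert_allclose(sums, 0.0, atol=1e-10)
    # reconstruction is exact on observed cells
    recon = within.values + between.to_numpy()[:, None, :]
    keep = np.isin(panel.subject_ids, list(between.index))
    orig = panel.values[keep]
    np.testing.assert_allclose(recon[obs], orig[panel.observed_mask[keep]],
                               rtol=0, atol=1e-12)


def test_constant_subject_has_zero_deviations():
    vals = np.ones((3, 3, 2)) * np.array([1.0, 2.0, 3.0])[:, None, None]
    panel = sd.PanelDataset(["a", "b", "c"], [14, 15, 16], ["x", "y"], vals)
    _, within, _ = nw.center_within(panel)
    np.testing.assert_allclose(within.values, 0.0, atol=1e-12)


def test_single_wave_subjects_excluded():
    panel, _ = sd.simulate(sd.DgpConfig(n_subjects=30, n_waves=3, seed=2))
    panel.observed_mask[:5, 1:, :] = False
    panel.values[:5, 1:, :] = np.nan
    between, within, info = nw.center_within(panel)
    assert info["excluded_subjects"] == 5
    assert within.n_subjects == 25


# ---------------------------------------------------------------------------
# GGM estimation
# ---------------------------------------------------------------------------

def test_independent_variables_give_empty_network(rng):
    X = rng.standard_normal((1000, 6))
    net = nw.network_from_data(X)
    assert np.count_nonzero(net.weights) == 0


def test_chain_graph_recovered_exactly(rng):
    K = _chain_precision(8)
    X = _ggm_data(rng, K, 5000)
    net = nw.network_from_data(X)
    want = (np.abs(K) > 1e-9) & ~np.eye(8, dtype=bool)
    np.testing.assert_array_equal(net.weights != 0, want)


def test_partials_match_refit_precision(rng):
    K = _chain_precision(6)
    X = _ggm_data(rng, K, 3000)
    net = nw.network_from_data(X)
    Kf = net.precision
    d = np.sqrt(np.diag(Kf))
    want = -Kf / np.outer(d, d)
    np.fill_diagonal(want, 0.0)
    np.testing.assert_allclose(net.weights, want, atol=1e-10)


def test_node_order_permutation_invariance(rng):
    K = _chain_precision(5)
    X = _ggm_data(rng, K, 2000)
    names = [f"v{i}" for i in range(5)]
    net = nw.network_from_data(pd.DataFrame(X, columns=names))
    perm = [3, 1, 4, 0, 2]
    net_p = nw.network_from_data(
        pd.DataFrame(X[:, perm], columns=[names[i] for i in perm]))
    back = np.empty_like(net_p.weights)
    inv = np.argsort(perm)
    back = net_p.weights[np.ix_(inv, inv)]
    np.testing.assert_allclose(net.weights, back, atol=1e-10)
    s1 = nw.small_worldness(net)
    s2 = nw.small_worldness(net_p)
    assert s1["swi"] == pytest.approx(s2["swi"], abs=1e-12)


def test_non_pd_covariance_rejected():
    bad = np.ones((4, 4))
    with pytest.raises(ValueError, match="positive definite"):
        nw.estimate_ggm(bad, n=100)


def test_centering_makes_between_network_of_within_data_sparse(rng):
    cfg = sd.study_conditions("mutualism", n_subjects=5000, n_waves=6, seed=3)
    panel, _ = sd.simulate(cfg)
    _, within, _ = nw.center_within(panel)
    means = np.nanmean(within.values, axis=1)  # ~0 by construction
    assert np.nanmax(np.abs(means)) < 1e-10


# ---------------------------------------------------------------------------
# graph statistics
# ---------------------------------------------------------------------------

def _net_from_weights(W):
    return nw.GgmNetwork([f"v{i}" for i in range(len(W))], W, n=500,
                         ebic_gamma=0.5)


def test_expected_influence_is_signed_row_sum():
    W = np.zeros((3, 3))
    W[0, 1] = W[1, 0] = 0.5
    W[0, 2] = W[2, 0] = -0.2
    cent = nw.centrality(_net_from_weights(W))
    assert cent.loc["v0", "expected_influence"] == pytest.approx(0.3)


def test_three_node_path_betweenness():
    W = np.zeros((3, 3))
    W[0, 1] = W[1, 0] = 0.4
    W[1, 2] = W[2, 1] = 0.4
    cent = nw.centrality(_net_from_weights(W))
    assert cent.loc["v1", "betweenness"] == pytest.approx(1.0)
    assert cent.loc["v0", "betweenness"] == 0.0
    assert cent.loc["v2", "betweenness"] == 0.0


def test_isolate_gets_zero_closeness():
    W = np.zeros((3, 3))
    W[0, 1] = W[1, 0] = 0.4
    cent = nw.centrality(_net_from_weights(W))
    assert cent.loc["v2", "closeness"] == 0.0


def test_star_center_has_max_closeness(rng):
    W = np.zeros((5, 5))
    for j in range(1, 5):
        W[0, j] = W[j, 0] = 0.3
    cent = nw.centrality(_net_from_weights(W))
    assert cent["closeness"].idxmax() == "v0"


def test_complete_graph_swi_near_one():
    p = 8
    W = np.full((p, p), 0.2)
    np.fill_diagonal(W, 0.0)
    s = nw.small_worldness(_net_from_weights(W))
    assert 0.8 <= s["swi"] <= 1.2


def test_sparse_graph_swi_flagged():
    W = np.zeros((5, 5))
    W[0, 1] = W[1, 0] = 0.4
    s = nw.small_worldness(_net_from_weights(W))
    assert s["defined"] is False


def test_swi_cutoff_classification():
    # SWI just above 1 is small-world under the lenient cutoff, not strict
    p = 8
    W = np.full((p, p), 0.2)
    np.fill_diagonal(W, 0.0)
    s = nw.small_worldness(_net_from_weights(W))
    assert s["small_world"] == (s["swi"] > 1)
    assert s["strict"] == (s["swi"] >= 3)


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

def test_bootstrap_reproducible_and_ci_covers_strong_edge(rng):
    K = _chain_precision(5, w=-0.35)
    X = _ggm_data(rng, K, 1500)
    b1 = nw.bootstrap_edges(X, B=200, seed=9, n_alphas=8)
    b2 = nw.bootstrap_edges(X, B=200, seed=9, n_alphas=8)
    pd.testing.assert_frame_equal(b1["edge_ci"], b2["edge_ci"])
    ci = b1["edge_ci"].set_index("edge")
    lab = "v0--v1"
    assert ci.loc[lab, "lower"] > 0.0          # strong edge excludes zero
    assert ci.loc[lab, "lower"] <= ci.loc[lab, "estimate"] \
        <= ci.loc[lab, "upper"]
    assert b1["n_failures"] == 0


def test_case_drop_cs_poor_on_noise(rng):
    X = rng.standard_normal((400, 4))
    res = nw.case_drop_cs(X, B=200, drop_grid=(0.25, 0.5, 0.75), seed=5,
                          n_alphas=4)
    assert res.cs_coefficient <= 0.25
    assert res.label == "poor"


def test_case_drop_cs_excellent_on_strong_structure(rng):
    K = _chain_precision(5, w=-0.4)
    X = _ggm_data(rng, K, 6000)
    res = nw.case_drop_cs(X, B=200, drop_grid=(0.25, 0.5, 0.75), seed=5,
                          n_alphas=6)
    assert res.cs_coefficient >= 0.70
    assert res.label == "excellent"


def test_nct_identical_data_null(rng):
    X = rng.standard_normal((120, 4))
    res = nw.nct(X, X.copy(), n_perm=500, seed=3, n_alphas=2)
    assert res.m_statistic == 0.0
    assert res.s_statistic == 0.0
    assert res.m_p == 1.0
    assert res.s_p == 1.0


def test_nct_node_mismatch_raises(rng):
    a = pd.DataFrame(rng.standard_normal((50, 3)), columns=list("abc"))
    b = pd.DataFrame(rng.standard_normal((50, 3)), columns=list("abd"))
    with pytest.raises(ValueError, match="node sets"):
        nw.nct(a, b, n_perm=500)


def test_nct_detects_injected_edge(rng):
    p = 4
    K_null = np.eye(p)
    K_alt = np.eye(p)
    K_alt[0, 1] = K_alt[1, 0] = -0.4
    XA = _ggm_data(rng, K_null, 2000)
    XB = _ggm_data(rng, K_alt, 2000)
    res = nw.nct(XA, XB, n_perm=500, seed=7, n_alphas=4)
    assert res.m_p < 0.05
    edge = res.edge_tests.set_index("edge").loc["v0--v1"]
    assert edge["significant"]


def test_nct_reproducible(rng):
    XA = rng.standard_normal((150, 4))
    XB = rng.standard_normal((150, 4))
    r1 = nw.nct(XA, XB, n_perm=500, seed=11, n_alphas=2)
    r2 = nw.nct(XA, XB, n_perm=500, seed=11, n_alphas=2)
    assert r1.m_p == r2.m_p
    assert r1.s_p == r2.s_p
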