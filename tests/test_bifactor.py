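import numpy as np
import pytest

from pmutual import bifactor as bf
from pmutual import sem_core as sc
from pmutual import synthetic_data as sd


def _count_free_beta(spec):
    return sum(1 for c in spec.beta.reshape(-1) if isinstance(c, str))


def test_structural_path_counts():
    ar = bf.build_bifactor_spec([14, 15, 16, 17], variant="autoregressive")
    cl = bf.build_bifactor_spec([14, 15, 16, 17], variant="cross_lagged")
    assert _count_free_beta(ar) == 3 * 3
    assert _count_free_beta(cl) == 9 * 3


def test_identification_constraints():
    spec = bf.build_bifactor_spec([14, 15])
    li = {n: i for i, n in enumerate(spec.latent_vars)}
    for f in ("p", "INT", "EXT"):
        assert spec.psi[li[f"{f}@14"], li[f"{f}@14"]] == 1.0
        assert spec.psi[li[f"{f}@15"], li[f"{f}@15"]] == 1.0
    assert all(a == 0.0 for a in spec.alpha)


def test_single_wave_degenerates_to_cross_sectional():
    spec = bf.build_bifactor_spec([14])
    assert _count_free_beta(spec) == 0
    assert len(spec.latent_vars) == 3


def test_unassigned_indicator_raises():
    with pytest.raises(ValueError, match="unknown domain"):
        bf.build_bifactor_spec([14, 15], indicator_map={"GAD": "WHAT"})


# ---------------------------------------------------------------------------
# index formulas
# ---------------------------------------------------------------------------

def _toy_blocks():
    # 6 indicators, lambda_g = .6, lambda_s = .4, two 3-indicator subscales,
    # residuals chosen for unit total variances
    lam_g = np.full(6, 0.6)
    theta = np.full(6, 1 - 0.36 - 0.16)
    blocks = {"INT": (np.array([0, 1, 2]), np.full(3, 0.4)),
              "EXT": (np.array([3, 4, 5]), np.full(3, 0.4))}
    return lam_g, blocks, theta


def test_index_formula_oracle_to_1e10():
    lam_g, blocks, theta = _toy_blocks()
    out = bf.bifactor_indices_from_arrays(lam_g, blocks, theta, wave=14)
    # independent arithmetic
    ssq_g = 6 * 0.36
    ssq_s = 3 * 0.16
    var_total = 3.6 ** 2 + 2 * 1.2 ** 2 + 6 * 0.48
    ecv_g = ssq_g / (ssq_g + 2 * ssq_s)
    omega = (3.6 ** 2 + 2 * 1.2 ** 2) / var_total
    omega_h = 3.6 ** 2 / var_total
    g = out.factors["general"]
    assert g["ecv"] == pytest.approx(ecv_g, abs=1e-10)
    assert g["omega"] == pytest.approx(omega, abs=1e-10)
    assert g["omega_h"] == pytest.approx(omega_h, abs=1e-10)
    assert g["relative_omega"] == pytest.approx(omega_h / omega, abs=1e-10)
    l_std = 0.6  # unit total variances
    s = 6 * l_std ** 2 / (1 - l_std ** 2)
    assert g["h"] == pytest.approx(s / (1 + s), abs=1e-10)
    # subscale side
    var_sub = 1.8 ** 2 + 1.2 ** 2 + 3 * 0.48
    om_s = (1.8 ** 2 + 1.2 ** 2) / var_sub
    om_hs = 1.2 ** 2 / var_sub
    f = out.factors["INT"]
    assert f["omega"] == pytest.approx(om_s, abs=1e-10)
    assert f["omega_h"] == pytest.approx(om_hs, abs=1e-10)
    assert f["ecv"] == pytest.approx(ssq_s / (ssq_g + 2 * ssq_s), abs=1e-10)
    assert f["ecv_ss"] == pytest.approx(ssq_s / (3 * 0.36 + ssq_s), abs=1e-10)


def test_index_invariants():
    lam_g, blocks, theta = _toy_blocks()
    out = bf.bifactor_indices_from_arrays(lam_g, blocks, theta)
    ecvs = [d["ecv"] for d in out.factors.values()]
    assert sum(ecvs) == pytest.approx(1.0, abs=1e-10)
    for d in out.factors.values():
        for key in ("ecv", "ecv_ss", "omega", "omega_h", "relative_omega"):
            assert 0.0 <= d[key] <= 1.0
        assert d["omega_h"] <= d["omega"] + 1e-12


def test_pure_general_factor_limit():
    lam_g = np.full(6, 0.6)
    blocks = {"INT": (np.array([0, 1, 2]), np.zeros(3)),
              "EXT": (np.array([3, 4, 5]), np.zeros(3))}
    out = bf.bifactor_indices_from_arrays(lam_g, blocks, np.full(6, 0.64))
    assert out.factors["general"]["ecv"] == pytest.approx(1.0)
    assert out.factors["INT"]["omega_h"] == 0.0
    assert out.factors["EXT"]["omega_h"] == 0.0


def test_h_flagged_when_standardized_loading_reaches_one():
    lam_g = np.array([1.0, 0.6, 0.6, 0.6, 0.6, 0.6])
    blocks = {"INT": (np.array([0, 1, 2]), np.zeros(3)),
              "EXT": (np.array([3, 4, 5]), np.zeros(3))}
    theta = np.array([0.0, 0.5, 0.5, 0.5, 0.5, 0.5])
    out = bf.bifactor_indices_from_arrays(lam_g, blocks, theta)
    assert out.factors["general"]["h"] is None


def test_indicator_order_invariance(rng):
    cfg = sd.DgpConfig(dgp_kind="common_cause", n_subjects=1200, n_waves=2,
                       seed=4)
    panel, _ = sd.simulate(cfg)
    comp = sd.to_composites(panel)
    f1 = bf.fit_bifactor(comp, waves=[14], missing="listwise",
                         compute_se=False, indices=False)
    reordered = {v: bf.DEFAULT_INDICATOR_MAP[v]
                 for v in reversed(list(bf.DEFAULT_INDICATOR_MAP))}
    f2 = bf.fit_bifactor(comp, waves=[14], indicator_map=reordered,
                         missing="listwise", compute_se=False, indices=False)
    i1 = bf.compute_bifactor_indices(f1, 14).factors["general"]
    i2 = bf.compute_bifactor_indices(f2, 14).factors["general"]
    assert i1["ecv"] == pytest.approx(i2["ecv"], abs=2e-4)
    assert i1["omega_h"] == pytest.approx(i2["omega_h"], abs=2e-4)


def test_relative_omega_identity_on_fitted_model():
    cfg = sd.DgpConfig(dgp_kind="common_cause", n_subjects=1500, n_waves=3,
                       seed=7)
    panel, _ = sd.simulate(cfg)
    comp = sd.to_composites(panel)
    fit = bf.fit_bifactor(comp, missing="listwise", compute_se=False,
                          indices=False)
    for w in comp.waves:
        out = bf.compute_bifactor_indices(fit, w)
        g = out.factors["general"]
        assert g["relative_omega"] == pytest.approx(
            g["omega_h"] / g["omega"], abs=1e-10)


def test_crosslag_never_fits_worse_than_autoregressive():
    cfg = sd.DgpConfig(dgp_kind="common_cause", n_subjects=800, n_waves=3,
                       seed=9)
    panel, _ = sd.simulate(cfg)
    comp = sd.to_composites(panel)
    far = bf.fit_bifactor(comp, "autoregressive", missing="listwise",
                          compute_se=False, indices=False)
    fcl = bf.fit_bifactor(comp, "cross_lagged", missing="listwise",
                          compute_se=False, indices=False,
                          start=dict(far.estimates))
    assert fcl.loglik >= far.loglik - 1e-6


def test_endpoint_wald_statistic_and_direction():
    cfg = sd.DgpConfig(dgp_kind="common_cause", n_subjects=2000, n_waves=3,
                       seed=2)
    panel, _ = sd.simulate(cfg)
    comp = sd.to_composites(panel)
    fit = bf.fit_bifactor(comp, missing="listwise", compute_se=True,
                          indices=False)
    res, direction = bf.endpoint_loading_wald(fit, "ADHD")
    assert res.kind == "wald"
    assert res.df == 1
    assert res.statistic >= 0
    assert direction in (-1, 0, 1)


def test_ecv_recovery_on_common_cause_data():
    # generator-implied wave-1 ECV vs fitted per-wave ECV
    cfg = sd.DgpConfig(dgp_kind="common_cause", n_subjects=2000, n_waves=2,
                       seed=12)
    panel, truth = sd.simulate(cfg)
    comp = sd.to_composites(panel)
    fit = bf.fit_bifactor(comp, waves=[14], missing="listwise",
                          compute_se=False, indices=False)
    got = bf.compute_bifactor_indices(fit, 14).factors["general"]["ecv"]
    names = comp.variables
    lg, ls = [], []
    for v in names:
        if v == "SUB":
            lg.append(np.mean([truth["general_loadings"][s]
                               for s in ("FAU", "FMU", "FTU")]))
            ls.append(np.mean([truth["specific_loadings"][s]
                               for s in ("FAU", "FMU", "FTU")]))
        else:
            lg.append(truth["general_loadings"][v])
            ls.append(truth["specific_loadings"][v])
    lg, ls = np.array(lg), np.array(ls)
    want = np.sum(lg ** 2) / (np.sum(lg ** 2) + np.sum(ls ** 2))
    assert got == pytest.approx(want, abs=0.06)
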