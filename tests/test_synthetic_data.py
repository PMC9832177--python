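import numpy as np
import pytest
from scipy import stats

from pmutual import synthetic_data as sd
from pmutual.synthetic_data import DgpConfig, apply_attrition, simulate


def test_same_seed_is_bit_identical():
    cfg = dict(dgp_kind="mutualism", n_subjects=200, n_waves=4, seed=11,
               attrition_hazard=0.1)
    a, ta = simulate(DgpConfig(**cfg))
    b, tb = simulate(DgpConfig(**cfg))
    np.testing.assert_array_equal(a.values, b.values)
    np.testing.assert_array_equal(a.observed_mask, b.observed_mask)
    assert ta == tb


def test_common_cause_wave1_matches_implied_moments():
    cfg = DgpConfig(dgp_kind="common_cause", n_subjects=50000, n_waves=2,
                    seed=3)
    panel, truth = simulate(cfg)
    lg = np.array([truth["general_loadings"][v] for v in panel.variables])
    ls = np.array([truth["specific_loadings"][v] for v in panel.variables])
    th = np.array([truth["residual_var"][v] for v in panel.variables])
    doms = [sd.DOMAIN_OF[v] for v in panel.variables]
    same_dom = np.equal.outer(doms, doms)
    implied = np.outer(lg, lg) + np.outer(ls, ls) * same_dom
    np.fill_diagonal(implied, lg ** 2 + ls ** 2 + th)
    S = np.cov(panel.wave_matrix(14).T, bias=True)
    assert np.max(np.abs(S - implied)) < 0.02


def test_decoupled_var_has_no_lag1_cross_domain_correlation():
    v = len(sd.DEFAULT_VARIABLES)
    cfg = DgpConfig(dgp_kind="mutualism", n_subjects=50000, n_waves=3,
                    coupling_start=0.0, coupling_end=0.0,
                    within_domain_coupling=0.0,
                    baseline_cov=np.eye(v), innovation_cov=np.eye(v), seed=9)
    panel, _ = simulate(cfg)
    X0 = panel.wave_matrix(14)
    X1 = panel.wave_matrix(15)
    doms = [sd.DOMAIN_OF[x] for x in panel.variables]
    worst = 0.0
    for i in range(v):
        for j in range(v):
            if doms[i] != doms[j]:
                r = np.corrcoef(X1[:, i], X0[:, j])[0, 1]
                worst = max(worst, abs(r))
    assert worst < 0.02


def test_mutualism_cross_domain_correlation_nondecreasing():
    # zero cross-domain baseline so the rising coupling is the only
    # cross-domain source (the invariant's premise)
    v = len(sd.DEFAULT_VARIABLES)
    doms = [sd.DOMAIN_OF[x] for x in sd.DEFAULT_VARIABLES]
    base = np.eye(v)
    for i in range(v):
        for j in range(i + 1, v):
            if doms[i] == doms[j]:
                base[i, j] = base[j, i] = 0.3
    cfg = DgpConfig(dgp_kind="mutualism", n_subjects=20000, n_waves=8,
                    baseline_cov=base, seed=2)
    panel, _ = simulate(cfg)
    doms = [sd.DOMAIN_OF[x] for x in panel.variables]

    def mean_cross_r(wave):
        S = np.corrcoef(panel.wave_matrix(wave).T)
        vals = [abs(S[i, j]) for i in range(len(doms))
                for j in range(i + 1, len(doms)) if doms[i] != doms[j]]
        return float(np.mean(vals))

    rs = [mean_cross_r(w) for w in (14, 17, 21)]
    assert rs[0] <= rs[1] + 0.01 <= rs[2] + 0.02
    assert rs[2] > rs[0]


def test_differentiation_cross_domain_correlation_decreasing():
    cfg = sd.study_conditions("differentiation", n_subjects=20000, n_waves=8,
                              seed=2)
    panel, _ = simulate(cfg)
    doms = [sd.DOMAIN_OF[x] for x in panel.variables]

    def mean_cross_r(wave):
        S = np.corrcoef(panel.wave_matrix(wave).T)
        vals = [abs(S[i, j]) for i in range(len(doms))
                for j in range(i + 1, len(doms)) if doms[i] != doms[j]]
        return float(np.mean(vals))

    assert mean_cross_r(21) < mean_cross_r(14)


def test_explosive_var_rejected_at_config_time():
    with pytest.raises(ValueError, match="explosive"):
        DgpConfig(dgp_kind="mutualism", coupling_start=0.0, coupling_end=0.5,
                  n_subjects=10, n_waves=3)


def test_schedule_direction_constraints():
    with pytest.raises(ValueError, match="mutualism"):
        DgpConfig(dgp_kind="mutualism", coupling_start=0.2, coupling_end=0.1)
    with pytest.raises(ValueError, match="differentiation"):
        DgpConfig(dgp_kind="differentiation", coupling_start=0.0,
                  coupling_end=0.1)


# ---------------------------------------------------------------------------
# attrition
# ---------------------------------------------------------------------------

def test_attrition_trivial_limits():
    panel, _ = simulate(DgpConfig(n_subjects=50, n_waves=4, seed=1))
    same = apply_attrition(panel, [0, 0, 0], seed=4)
    np.testing.assert_array_equal(same.observed_mask, panel.observed_mask)
    gone = apply_attrition(panel, [1, 0, 0], seed=4)
    assert gone.observed_mask[:, 0, :].all()
    assert not gone.observed_mask[:, 1:, :].any()


def test_attrition_survival_matches_closed_form():
    panel, _ = simulate(DgpConfig(n_subjects=10000, n_waves=8, seed=7))
    out = apply_attrition(panel, [0.13] * 7, seed=7)
    frac = out.observed_mask[:, -1, 0].mean()
    assert frac == pytest.approx(0.87 ** 7, abs=0.03)


def test_attrition_is_monotone():
    panel, _ = simulate(DgpConfig(n_subjects=500, n_waves=5, seed=3))
    out = apply_attrition(panel, [0.3] * 4, seed=3)
    alive = out.observed_mask[:, :, 0]
    # once missing, missing ever after
    assert not np.any(~alive[:, :-1] & alive[:, 1:])


def test_mar_attrition_targets_high_scorers():
    panel, _ = simulate(DgpConfig(n_subjects=20000, n_waves=3, seed=5))
    out = apply_attrition(panel, [0.3, 0.0], mar_on="ADHD", mar_slope=1.5,
                          seed=5)
    x = panel.values[:, 0, panel.var_index("ADHD")]
    dropped = ~out.observed_mask[:, 1, 0]
    assert x[dropped].mean() > x[~dropped].mean() + 0.2
    # marginal rate still matches the hazard
    assert dropped.mean() == pytest.approx(0.3, abs=0.02)


def test_mcar_attrition_leaves_covariance_unbiased():
    cfg = DgpConfig(dgp_kind="common_cause", n_subjects=20000, n_waves=3,
                    seed=6)
    panel, _ = simulate(cfg)
    out = apply_attrition(panel, [0.2, 0.2], seed=6)
    X_full = panel.wave_matrix(15)
    obs = out.observed_mask[:, 1, 0]
    S_full = np.cov(X_full.T, bias=True)
    S_cc = np.cov(X_full[obs].T, bias=True)
    assert np.max(np.abs(S_full - S_cc)) < 0.06


# ---------------------------------------------------------------------------
# discretization
# ---------------------------------------------------------------------------

def test_likert_binning_rules():
    panel, _ = simulate(DgpConfig(n_subjects=200, n_waves=2, seed=1))
    one_cat = sd.discretize_to_likert(panel, {"*": [np.inf]})
    assert np.all(one_cat.values[one_cat.observed_mask] == 0)
    binned = sd.discretize_to_likert(panel, {"*": [-0.5, 0.5]})
    low = panel.values < -0.5
    assert np.all(binned.values[low & panel.observed_mask] == 0)
    with pytest.raises(ValueError, match="strictly increasing"):
        sd.discretize_to_likert(panel, {"*": [1.0, 0.0]})


def test_likert_preserves_rank_order():
    panel, _ = simulate(DgpConfig(n_subjects=5000, n_waves=2, seed=8))
    thresholds = list(np.linspace(-2, 2, 7))     # 8 categories
    binned = sd.discretize_to_likert(panel, {"*": thresholds})
    x = panel.values[:, 0, 0]
    y = binned.values[:, 0, 0]
    rho = stats.spearmanr(x, y).statistic
    assert rho > 0.95


# ---------------------------------------------------------------------------
# substance-use collapse and the RI-CLPM generator
# ---------------------------------------------------------------------------

def test_to_composites_substance_mean():
    panel, _ = simulate(DgpConfig(n_subjects=100, n_waves=2, seed=2))
    comp = sd.to_composites(panel)
    assert comp.variables[-1] == "SUB"
    i = [panel.var_index(s) for s in ("FAU", "FMU", "FTU")]
    np.testing.assert_allclose(comp.values[:, :, -1],
                               panel.values[:, :, i].mean(axis=2))


def test_riclpm_generator_moments():
    panel, truth = sd.simulate_riclpm(50000, 4, ar=(0.3, 0.3),
                                      cross=(0.0, 0.0), ri_var=(4, 9),
                                      ri_corr=0.5, seed=3)
    # between-person variance shows up in every wave's variance
    per_subject_mean = np.nanmean(panel.values, axis=1)
    r = np.corrcoef(per_subject_mean.T)[0, 1]
    assert r == pytest.approx(0.5, abs=0.06)
    v_int = per_subject_mean[:, 0].var()
    assert v_int > 3.0  # dominated by the RI variance of 4
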