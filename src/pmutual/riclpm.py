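"""Random-intercept cross-lagged panel models for INT and EXT series.

The RI-CLPM separates stable between-person differences (random-intercept
latents with unit loadings on every wave of a series) from within-person
lagged dynamics among the per-wave deviations.  The model family spans a
nesting lattice over which cross-lags are freed:

    baseline (none)  <  int_to_ext / ext_to_int (one direction)  <
    bidirectional ("mutualism")

plus the traditional CLPM, obtained from the bidirectional model by fixing
the random-intercept variances and covariance to zero — a boundary
restriction tested with the chi-bar-square machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import sem_core
from .panel import PanelDataset
from .sem_core import SemFit, SemSpec, TestResult, _pattern

__all__ = ["VARIANTS", "build_riclpm_spec", "build_clpm_spec", "fit_riclpm",
           "compare_family", "RiclpmEstimates", "extract_estimates"]

VARIANTS = ("baseline", "int_to_ext", "ext_to_int", "bidirectional", "clpm")


def build_riclpm_spec(waves, variant: str = "bidirectional",
                      series=("INT", "EXT")) -> SemSpec:
    """RI-CLPM pattern over the given wave labels (needs W >= 3).

    Observed variables are ``INT@w`` / ``EXT@w`` composites.  Grand means
    are free per-wave intercepts; wave-1 deviations are exogenous with free
    variance/covariance; lag-1 autoregressions are always free and
    cross-lags follow the variant; within-time deviation (residual)
    covariances are free at every wave.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    waves = [int(w) for w in waves]
    W = len(waves)
    if W < 3:
        raise ValueError("RI-CLPM identification needs at least 3 waves")
    a_name, b_name = series

    obs = [f"{s}@{w}" for w in waves for s in series]
    lats = ["RI_INT", "RI_EXT"] + [f"d{s}@{w}" for w in waves for s in series]
    p, m = len(obs), len(lats)
    lam = _pattern((p, m))
    beta = _pattern((m, m))
    psi = _pattern((m, m))
    theta = _pattern((p, p))
    nu = _pattern((p,))
    alpha = _pattern((m,))
    li = {n: i for i, n in enumerate(lats)}

    clpm = variant == "clpm"
    psi[li["RI_INT"], li["RI_INT"]] = 0.0 if clpm else "s2_ri_int"
    psi[li["RI_EXT"], li["RI_EXT"]] = 0.0 if clpm else "s2_ri_ext"
    psi[li["RI_INT"], li["RI_EXT"]] = 0.0 if clpm else "cov_ri"
    psi[li["RI_EXT"], li["RI_INT"]] = psi[li["RI_INT"], li["RI_EXT"]]

    cross_ie = variant in ("int_to_ext", "bidirectional", "clpm")
    cross_ei = variant in ("ext_to_int", "bidirectional", "clpm")
    for wi, w in enumerate(waves):
        for si, s in enumerate(series):
            r = wi * 2 + si
            lam[r, li[f"RI_{s}"]] = 1.0
            lam[r, li[f"d{s}@{w}"]] = 1.0
            nu[r] = f"nu_{s}@{w}"
        dint, dext = li[f"d{a_name}@{w}"], li[f"d{b_name}@{w}"]
        psi[dint, dint] = f"v_dint@{w}"
        psi[dext, dext] = f"v_dext@{w}"
        psi[dint, dext] = psi[dext, dint] = f"c_d@{w}"
        if wi > 0:
            wp = waves[wi - 1]
            beta[dint, li[f"d{a_name}@{wp}"]] = f"a_int@{w}"
            beta[dext, li[f"d{b_name}@{wp}"]] = f"a_ext@{w}"
            if cross_ie:
                beta[dext, li[f"d{a_name}@{wp}"]] = f"c_ie@{w}"
            if cross_ei:
                beta[dint, li[f"d{b_name}@{wp}"]] = f"c_ei@{w}"
    spec = SemSpec(obs, lats, lam, beta, psi, theta, nu, alpha,
                   bounds={"s2_ri_int": (1e-6, None),
                           "s2_ri_ext": (1e-6, None)} if not clpm else {},
                   start={} if clpm else {"s2_ri_int": 1.0, "s2_ri_ext": 1.0})
    spec.meta = {"waves": waves, "variant": variant, "series": list(series)}
    return spec


def build_clpm_spec(waves, series=("INT", "EXT")) -> SemSpec:
    """Traditional cross-lagged panel model, specified without RI latents.

    Built independently of :func:`build_riclpm_spec` (no random-intercept
    factors at all) as a cross-check: its ML estimates must coincide with
    the ``clpm`` variant, whose RI latents are present but pinned to zero
    variance.
    """
    waves = [int(w) for w in waves]
    a_name, b_name = series
    obs = [f"{s}@{w}" for w in waves for s in series]
    lats = [f"e{s}@{w}" for w in waves for s in series]
    p = len(obs)
    m = len(lats)
    lam = _pattern((p, m))
    beta = _pattern((m, m))
    psi = _pattern((m, m))
    theta = _pattern((p, p))
    nu = _pattern((p,))
    alpha = _pattern((m,))
    li = {n: i for i, n in enumerate(lats)}
    for wi, w in enumerate(waves):
        for si, s in enumerate(series):
            r = wi * 2 + si
            lam[r, li[f"e{s}@{w}"]] = 1.0
            nu[r] = f"nu_{s}@{w}"
        ei, ee = li[f"e{a_name}@{w}"], li[f"e{b_name}@{w}"]
        psi[ei, ei] = f"v_dint@{w}"
        psi[ee, ee] = f"v_dext@{w}"
        psi[ei, ee] = psi[ee, ei] = f"c_d@{w}"
        if wi > 0:
            wp = waves[wi - 1]
            beta[ei, li[f"e{a_name}@{wp}"]] = f"a_int@{w}"
            beta[ee, li[f"e{b_name}@{wp}"]] = f"a_ext@{w}"
            beta[ee, li[f"e{a_name}@{wp}"]] = f"c_ie@{w}"
            beta[ei, li[f"e{b_name}@{wp}"]] = f"c_ei@{w}"
    spec = SemSpec(obs, lats, lam, beta, psi, theta, nu, alpha)
    spec.meta = {"waves": waves, "variant": "clpm_plain", "series": list(series)}
    return spec


def _frame(panel: PanelDataset, series) -> pd.DataFrame:
    X, cols = panel.wide_matrix(variables=list(series))
    return pd.DataFrame(X, columns=cols)


def fit_riclpm(panel: PanelDataset, variant: str = "bidirectional",
               series=("INT", "EXT"), missing: str = "fiml",
               compute_se: bool = True, indices: bool = True) -> SemFit:
    spec = build_riclpm_spec(panel.waves, variant, series)
    fit = sem_core.fit_ml(spec, _frame(panel, series), missing=missing,
                          compute_se=compute_se, indices=indices)
    return fit


def compare_family(panel: PanelDataset, series=("INT", "EXT"),
                   missing: str = "fiml", boundary_draws: int = 200,
                   compute_se: bool = False, seed: int = 0) -> dict:
    """Fit the four RI-CLPM variants (+ CLPM), compare, pick a winner.

    Returns a dict with the per-model fit table, the pairwise LRTs along
    the nesting lattice, the chi-bar-square test of the CLPM boundary
    restriction, and ``best`` (lowest AIC among converged members, with a
    note on LRT concordance).  Non-converged members stay in the table but
    drop out of the comparisons.
    """
    fits: dict[str, SemFit] = {}
    for variant in VARIANTS:
        try:
            fits[variant] = fit_riclpm(panel, variant, series, missing,
                                       compute_se=compute_se and
                                       variant == "bidirectional")
        except Exception as e:  # isolate failures per family member
            import warnings
            fits[variant] = None
            warnings.warn(f"riclpm variant {variant} failed: {e}")

    rows = []
    for variant, fit in fits.items():
        if fit is None:
            rows.append({"model": variant, "converged": False})
            continue
        rows.append({"model": variant, "chi_square": fit.chi_square,
                     "df": fit.df, "cfi": fit.cfi, "tli": fit.tli,
                     "rmsea": fit.rmsea, "aic": fit.aic,
                     "loglik": fit.loglik, "n_params": fit.n_params,
                     "converged": fit.converged})
    table = pd.DataFrame(rows)

    lattice = [("baseline", "int_to_ext"), ("baseline", "ext_to_int"),
               ("int_to_ext", "bidirectional"), ("ext_to_int", "bidirectional"),
               ("baseline", "bidirectional")]
    tests = {}
    for r, f in lattice:
        if fits.get(r) is not None and fits.get(f) is not None \
                and fits[r].converged and fits[f].converged:
            tests[f"{r}_vs_{f}"] = sem_core.lrt(fits[r], fits[f])

    chibar = None
    if boundary_draws > 0 and fits.get("clpm") is not None \
            and fits.get("bidirectional") is not None \
            and fits["clpm"].converged and fits["bidirectional"].converged:
        chibar = sem_core.boundary_lrt(fits["clpm"], fits["bidirectional"],
                                       n_draws=boundary_draws, seed=seed)

    ranked = [v for v in ("baseline", "int_to_ext", "ext_to_int",
                          "bidirectional")
              if fits.get(v) is not None and fits[v].converged]
    best = min(ranked, key=lambda v: fits[v].aic) if ranked else None
    concordant = None
    if best == "bidirectional" and "baseline_vs_bidirectional" in tests:
        concordant = tests["baseline_vs_bidirectional"].p < 0.05
    return {"fits": fits, "table": table, "tests": tests,
            "chibar": chibar, "best": best, "lrt_concordant": concordant}


# ---------------------------------------------------------------------------
# parameter extraction
# ---------------------------------------------------------------------------

@dataclass
class RiclpmEstimates:
    """Between-person variances/correlation and within-person dynamics."""
    ri_var: dict
    ri_var_se: dict
    ri_corr: float | None
    transitions: pd.DataFrame       # per transition: ar/cross raw + std
    within_time_corr: dict          # wave -> residual correlation
    extra: dict = field(default_factory=dict)


def extract_estimates(fit: SemFit) -> RiclpmEstimates:
    """Table-shaped record of a converged RI-CLPM (or CLPM) fit."""
    if not fit.converged:
        raise ValueError("extract_estimates needs a converged fit")
    meta = fit.spec.meta
    waves = meta["waves"]
    est, se, std = fit.estimates, fit.se, fit.standardized

    ri_var = {"INT": est.get("s2_ri_int", 0.0), "EXT": est.get("s2_ri_ext", 0.0)}
    ri_se = {"INT": se.get("s2_ri_int"), "EXT": se.get("s2_ri_ext")}
    if ri_var["INT"] > 0 and ri_var["EXT"] > 0 and "cov_ri" in est:
        ri_corr = est["cov_ri"] / np.sqrt(ri_var["INT"] * ri_var["EXT"])
    else:
        ri_corr = None

    rows = []
    for w0, w1 in zip(waves, waves[1:]):
        row = {"from_wave": w0, "to_wave": w1}
        for key, name in (("a_int", "ar_int"), ("a_ext", "ar_ext"),
                          ("c_ie", "cross_int_to_ext"),
                          ("c_ei", "cross_ext_to_int")):
            lab = f"{key}@{w1}"
            if lab in est:
                row[name] = est[lab]
                row[name + "_std"] = std.get(lab)
                row[name + "_se"] = se.get(lab)
        rows.append(row)
    trans = pd.DataFrame(rows)

    wt = {}
    for w in waves:
        c = est.get(f"c_d@{w}")
        vi, ve = est.get(f"v_dint@{w}"), est.get(f"v_dext@{w}")
        if c is not None and vi and ve:
            wt[w] = float(c / np.sqrt(vi * ve))
    return RiclpmEstimates(ri_var=ri_var, ri_var_se=ri_se,
                           ri_corr=None if ri_corr is None else float(ri_corr),
                           transitions=trans, within_time_corr=wt)
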