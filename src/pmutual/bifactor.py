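"""Longitudinal bifactor models of general (p) and domain-specific severity.

Every composite loads on a wave-specific general factor ``p`` and on its
domain factor (internalizing or externalizing); the three factors are
mutually orthogonal within wave.  Two structural variants connect waves:
autoregressive-only (each factor predicts itself one wave ahead) and
cross-lagged (all six additional lag-1 paths among p, INT, EXT).  The scale
is set by fixing wave-1 factor variances, and the residual variances of
endogenous factors, to 1 — the standardized-latent identification that
leaves every loading free per wave, which is what the endpoint equality
tests require.

Factor strength and model-based reliability are summarized per wave by the
bifactor index set: explained common variance (ECV, globally and relative
to each subscale), omega total / subscale, omega hierarchical (general and
specific), relative omega, and Hancock-Mueller H.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import sem_core
from .panel import PanelDataset
from .sem_core import SemFit, SemSpec, TestResult, _pattern

__all__ = ["DEFAULT_INDICATOR_MAP", "build_bifactor_spec", "fit_bifactor",
           "BifactorIndexSet", "compute_bifactor_indices",
           "bifactor_indices_from_arrays", "endpoint_loading_wald",
           "index_table"]

DEFAULT_INDICATOR_MAP = {"GAD": "INT", "MDD": "INT", "ADHD": "EXT",
                         "CDASPD": "EXT", "ODD": "EXT", "SUB": "EXT"}


def build_bifactor_spec(waves, indicator_map: dict | None = None,
                        variant: str = "autoregressive",
                        residual_autocorr: bool = False) -> SemSpec:
    """Bifactor specification over the given wave (age) labels.

    ``indicator_map`` assigns each composite to "INT" or "EXT"; every
    composite also loads on the general factor.  ``variant`` is
    ``"autoregressive"`` (3 lag-1 paths per transition) or
    ``"cross_lagged"`` (all 9).  ``residual_autocorr`` optionally frees
    lag-1 residual covariances of the same indicator.
    """
    imap = dict(DEFAULT_INDICATOR_MAP if indicator_map is None else indicator_map)
    if variant not in ("autoregressive", "cross_lagged"):
        raise ValueError(f"unknown variant {variant!r}")
    # a 2-indicator specific factor only identifies the product of its two
    # loadings cross-sectionally; constrain them equal (tau-equivalent
    # specific factor), the standard remedy
    dom_counts = {}
    for v, d in imap.items():
        dom_counts[d] = dom_counts.get(d, 0) + 1
    tau_equal = {d for d, c in dom_counts.items() if c == 2}
    domains = []
    for v, d in imap.items():
        if d not in ("INT", "EXT"):
            raise ValueError(f"indicator {v!r} assigned to unknown domain {d!r}")
        if d not in domains:
            domains.append(d)
    indicators = list(imap)
    waves = [int(w) for w in waves]
    factors = ["p"] + domains

    obs = [f"{v}@{w}" for w in waves for v in indicators]
    lats = [f"{f}@{w}" for w in waves for f in factors]
    p, m = len(obs), len(lats)
    lam = _pattern((p, m))
    beta = _pattern((m, m))
    psi = _pattern((m, m))
    theta = _pattern((p, p))
    nu = _pattern((p,))
    alpha = _pattern((m,))

    li = {name: i for i, name in enumerate(lats)}
    inv_load = {}
    inv_int = {}
    for wi, w in enumerate(waves):
        for vi, v in enumerate(indicators):
            r = wi * len(indicators) + vi
            gl = f"lg_{v}@{w}"
            sl = f"ls_{imap[v]}@{w}" if imap[v] in tau_equal else f"ls_{v}@{w}"
            lam[r, li[f"p@{w}"]] = gl
            lam[r, li[f"{imap[v]}@{w}"]] = sl
            theta[r, r] = f"th_{v}@{w}"
            nu[r] = f"nu_{v}@{w}"
            inv_load.setdefault(f"g_{v}", []).append(gl)
            s_group = inv_load.setdefault(
                f"s_{imap[v] if imap[v] in tau_equal else v}", [])
            if sl not in s_group:
                s_group.append(sl)
            inv_int.setdefault(v, []).append(f"nu_{v}@{w}")
            if residual_autocorr and wi > 0:
                r0 = (wi - 1) * len(indicators) + vi
                theta[r, r0] = theta[r0, r] = f"thc_{v}@{w}"
        for f in factors:
            # exogenous variances and endogenous residual variances fixed to 1
            psi[li[f"{f}@{w}"], li[f"{f}@{w}"]] = 1.0
        if wi > 0:
            wp = waves[wi - 1]
            for f in factors:
                beta[li[f"{f}@{w}"], li[f"{f}@{wp}"]] = f"b_{f}_{f}@{w}"
            if variant == "cross_lagged":
                for f_to in factors:
                    for f_from in factors:
                        if f_to != f_from:
                            beta[li[f"{f_to}@{w}"], li[f"{f_from}@{wp}"]] = \
                                f"b_{f_to}_{f_from}@{w}"
    spec = SemSpec(obs, lats, lam, beta, psi, theta, nu, alpha,
                   invariance={"loadings": inv_load, "intercepts": inv_int})
    spec.meta = {"waves": waves, "indicators": indicators, "map": imap,
                 "variant": variant, "domains": domains,
                 "tau_equal": sorted(tau_equal)}
    return spec


def specific_loading_label(meta: dict, indicator: str, wave: int) -> str:
    dom = meta["map"][indicator]
    if dom in meta.get("tau_equal", ()):
        return f"ls_{dom}@{wave}"
    return f"ls_{indicator}@{wave}"


def fit_bifactor(panel: PanelDataset, variant: str = "autoregressive",
                 waves=None, indicator_map: dict | None = None,
                 missing: str = "fiml", compute_se: bool = True,
                 indices: bool = True, start: dict | None = None) -> SemFit:
    """Build and fit a bifactor variant on the composite panel.

    ``start`` warm-starts shared parameters (e.g. the cross-lagged variant
    from a fitted autoregressive one, which stabilizes the harder fit).
    """
    waves = list(panel.waves) if waves is None else [int(w) for w in waves]
    imap = dict(DEFAULT_INDICATOR_MAP if indicator_map is None else indicator_map)
    spec = build_bifactor_spec(waves, imap, variant)
    X, cols = panel.wide_matrix(variables=list(imap), waves=waves)
    df = pd.DataFrame(X, columns=cols)
    starts = _pc_starts(df, spec.meta)
    if start:
        starts.update(start)
    fit = sem_core.fit_ml(spec, df, missing=missing, compute_se=compute_se,
                          indices=indices, start=starts)
    return fit


def _pc_starts(df: pd.DataFrame, meta: dict) -> dict:
    """First-principal-component starting values per wave (cuts the
    quasi-Newton iteration count on the large longitudinal models)."""
    starts = {}
    indicators = meta["indicators"]
    for w in meta["waves"]:
        sub = df[[f"{v}@{w}" for v in indicators]].dropna()
        if len(sub) < 10:
            continue
        S = np.cov(sub.to_numpy().T)
        evals, evecs = np.linalg.eigh(S)
        pc = evecs[:, -1] * np.sqrt(max(evals[-1], 1e-6))
        if pc.sum() < 0:
            pc = -pc
        for i, v in enumerate(indicators):
            lam_g = float(np.clip(pc[i], 0.05, 2.0))
            starts[f"lg_{v}@{w}"] = lam_g
            starts[specific_loading_label(meta, v, w)] = 0.3
            starts[f"th_{v}@{w}"] = float(
                np.clip(S[i, i] - lam_g ** 2 - 0.09, 0.10, None))
            starts[f"nu_{v}@{w}"] = float(sub.iloc[:, i].mean())
        for f in ["p"] + meta["domains"]:
            lab = f"b_{f}_{f}@{w}"
            starts[lab] = 0.3
    return starts


# ---------------------------------------------------------------------------
# bifactor strength / reliability indices
# ---------------------------------------------------------------------------

@dataclass
class BifactorIndexSet:
    """Per-wave factor strength and reliability summary.

    ``factors`` maps "general" and each specific-factor name to a dict with
    keys ``ecv`` (global, summing to 1 across factors), ``ecv_ss``
    (subscale-relative), ``omega`` (omega total for the general row, omega
    subscale for specific rows), ``omega_h`` (omega hierarchical /
    hierarchical-subscale), ``relative_omega`` and ``h`` (None when a
    standardized loading reaches 1).
    """
    wave: int
    factors: dict = field(default_factory=dict)

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for f, d in self.factors.items():
            rows.append({"wave": self.wave, "factor": f, **d})
        return pd.DataFrame(rows)


def bifactor_indices_from_arrays(lam_g, lam_s_blocks: dict, theta,
                                 wave: int = 0) -> BifactorIndexSet:
    """Index set from loadings on standardized factors and residual variances.

    ``lam_g``: general-factor loadings for all indicators (in order);
    ``lam_s_blocks``: specific-factor name -> (indicator index array,
    loadings); ``theta``: residual variances, same order as ``lam_g``.
    """
    lam_g = np.asarray(lam_g, float)
    theta = np.asarray(theta, float)
    p = len(lam_g)
    ssq_g = float(np.sum(lam_g ** 2))
    ssq_s = {f: float(np.sum(np.asarray(l) ** 2))
             for f, (idx, l) in lam_s_blocks.items()}
    common = ssq_g + sum(ssq_s.values())
    var_total = float(np.sum(lam_g) ** 2
                      + sum(np.sum(np.asarray(l)) ** 2
                            for _, (i, l) in lam_s_blocks.items())
                      + np.sum(theta))
    omega = (np.sum(lam_g) ** 2
             + sum(np.sum(np.asarray(l)) ** 2
                   for _, (i, l) in lam_s_blocks.items())) / var_total
    omega_h = np.sum(lam_g) ** 2 / var_total

    # indicator total variances implied by the (orthogonal-factor) model
    var_ind = lam_g ** 2 + theta
    for f, (idx, l) in lam_s_blocks.items():
        var_ind[np.asarray(idx, int)] += np.asarray(l, float) ** 2

    def h_index(loadings, idx):
        l_std = np.asarray(loadings, float) / np.sqrt(var_ind[np.asarray(idx, int)])
        if np.any(np.abs(l_std) >= 1):
            return None
        s = np.sum(l_std ** 2 / (1 - l_std ** 2))
        return float(s / (1 + s))

    factors = {"general": {
        "ecv": ssq_g / common,
        "ecv_ss": ssq_g / common,
        "omega": float(omega),
        "omega_h": float(omega_h),
        "relative_omega": float(omega_h / omega),
        "h": h_index(lam_g, np.arange(p)),
    }}
    for f, (idx, l) in lam_s_blocks.items():
        idx = np.asarray(idx, int)
        l = np.asarray(l, float)
        sub_g = lam_g[idx]
        sub_th = theta[idx]
        var_sub = float(np.sum(sub_g) ** 2 + np.sum(l) ** 2 + np.sum(sub_th))
        omega_s = (np.sum(sub_g) ** 2 + np.sum(l) ** 2) / var_sub
        omega_hs = np.sum(l) ** 2 / var_sub
        factors[f] = {
            "ecv": ssq_s[f] / common,
            "ecv_ss": ssq_s[f] / (float(np.sum(sub_g ** 2)) + ssq_s[f]),
            "omega": float(omega_s),
            "omega_h": float(omega_hs),
            "relative_omega": float(omega_hs / omega_s),
            "h": h_index(l, idx),
        }
    return BifactorIndexSet(wave=wave, factors=factors)


def compute_bifactor_indices(fit: SemFit, wave: int) -> BifactorIndexSet:
    """Index set at one wave of a fitted bifactor model.

    Loadings are rescaled to standardized factors using the model-implied
    factor variances (endogenous factors do not have unit variance under
    the AR structure), so indices are comparable across waves.
    """
    if not fit.converged:
        raise ValueError("indices require a converged fit")
    meta = getattr(fit.spec, "meta", None)
    if meta is None:
        raise ValueError("fit does not carry bifactor metadata")
    wave = int(wave)
    indicators = meta["indicators"]
    imap = meta["map"]
    lat_names = list(fit.spec.latent_vars)
    sd_p = np.sqrt(fit.implied_latent_cov[
        lat_names.index(f"p@{wave}"), lat_names.index(f"p@{wave}")])
    lam_g = np.array([fit.estimates[f"lg_{v}@{wave}"] for v in indicators]) * sd_p
    theta = np.array([fit.estimates[f"th_{v}@{wave}"] for v in indicators])
    blocks = {}
    for dom in meta["domains"]:
        idx = [i for i, v in enumerate(indicators) if imap[v] == dom]
        sd_d = np.sqrt(fit.implied_latent_cov[
            lat_names.index(f"{dom}@{wave}"), lat_names.index(f"{dom}@{wave}")])
        lam = np.array([fit.estimates[
            specific_loading_label(meta, indicators[i], wave)]
            for i in idx]) * sd_d
        blocks[dom] = (np.array(idx), lam)
    # orient each factor positively (sign indeterminacy of the latent)
    if lam_g.sum() < 0:
        lam_g = -lam_g
    blocks = {f: (i, -l if l.sum() < 0 else l) for f, (i, l) in blocks.items()}
    return bifactor_indices_from_arrays(lam_g, blocks, theta, wave=wave)


def index_table(fit: SemFit, waves=None) -> pd.DataFrame:
    """One row per wave x factor, mirroring the published index layout."""
    meta = fit.spec.meta
    waves = meta["waves"] if waves is None else waves
    return pd.concat([compute_bifactor_indices(fit, w).as_frame()
                      for w in waves], ignore_index=True)


def endpoint_loading_wald(fit: SemFit, indicator: str, factor: str = "p",
                          waves=None) -> tuple[TestResult, int]:
    """Wald test of equal first/last-wave loadings on a factor, plus direction.

    The single-df Wald statistic tests equality of the raw loading
    parameters (the constrained quantity).  The reported direction is the
    sign of the change in the *standardized* loading: later-wave factors do
    not have unit variance under the autoregressive identification, so the
    standardized loading is the scale-comparable quantity a loading table
    would be read from.
    """
    meta = fit.spec.meta
    all_waves = meta["waves"]
    w0, w1 = (all_waves[0], all_waves[-1]) if waves is None else waves
    prefix = "lg" if factor == "p" else "ls"
    a, b = f"{prefix}_{indicator}@{w0}", f"{prefix}_{indicator}@{w1}"
    if a not in fit.estimates or b not in fit.estimates:
        raise ValueError(f"loadings {a}/{b} not in fit")
    wald_res = sem_core.wald(fit, [(a, b)])
    direction = int(np.sign(fit.standardized[b] - fit.standardized[a]))
    return wald_res, direction
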