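"""Covariance-structure (SEM) engine: specification, ML/FIML estimation, tests.

The engine fits linear latent-variable models of the usual LISREL-style form

    y = nu + Lambda (I - B)^{-1} (alpha + zeta) + eps
    Sigma(theta) = Lambda (I - B)^{-1} Psi (I - B)^{-T} Lambda^T + Theta

by maximizing the multivariate-normal log-likelihood (N-denominator
convention).  Missing data are handled either listwise or by
full-information maximum likelihood, implemented exactly by grouping rows
into missingness patterns and summing pattern-wise Gaussian log-likelihoods.

Pattern matrices hold a float (fixed value) or a string (free-parameter
label) per cell; cells sharing a label are constrained equal, which is how
every equality constraint (including the measurement-invariance ladder) is
expressed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import optimize, stats

from .gaussian import em_mvn
from .panel import PanelDataset

__all__ = ["SemSpec", "SemFit", "TestResult", "fit_ml", "fit_indices",
           "lrt", "wald", "boundary_lrt", "invariance_ladder",
           "one_factor_spec", "repeated_onefactor_spec", "as_frame",
           "simulate_from_fit", "independence_loglik", "saturated_loglik"]

_PENALTY = 1e10


def free(label: str) -> str:
    return label


def _pattern(shape, fill=0.0) -> np.ndarray:
    a = np.empty(shape, dtype=object)
    a[...] = fill
    return a


# ---------------------------------------------------------------------------
# specification
# ---------------------------------------------------------------------------

@dataclass
class SemSpec:
    """Declarative latent-variable model pattern.

    ``lam`` (observed x latent), ``beta`` (latent x latent regressions),
    ``psi`` (latent covariance), ``theta`` (residual covariance), ``nu``
    (observed intercepts) and ``alpha`` (latent means) are object arrays of
    floats (fixed) and strings (free labels); shared labels are equal.
    ``invariance`` optionally maps "loadings"/"intercepts" to groups of
    labels that repeat across waves, which drives the invariance ladder.
    """

    observed_vars: list
    latent_vars: list
    lam: np.ndarray
    beta: np.ndarray
    psi: np.ndarray
    theta: np.ndarray
    nu: np.ndarray
    alpha: np.ndarray
    bounds: dict = field(default_factory=dict)
    start: dict = field(default_factory=dict)
    invariance: dict = field(default_factory=dict)

    def __post_init__(self):
        p, m = len(self.observed_vars), len(self.latent_vars)
        assert self.lam.shape == (p, m)
        assert self.beta.shape == (m, m)
        assert self.psi.shape == (m, m)
        assert self.theta.shape == (p, p)
        for M, name in ((self.psi, "psi"), (self.theta, "theta")):
            for i in range(M.shape[0]):
                for j in range(i):
                    if M[i, j] != M[j, i]:
                        raise ValueError(f"{name} pattern must be symmetric")

    # -- label bookkeeping ------------------------------------------------
    def free_labels(self) -> list[str]:
        seen, out = set(), []
        for M in (self.lam, self.beta, self.psi, self.theta,
                  self.nu, self.alpha):
            for cell in M.reshape(-1):
                if isinstance(cell, str) and cell not in seen:
                    seen.add(cell)
                    out.append(cell)
        return out

    @property
    def n_free(self) -> int:
        return len(self.free_labels())

    def degrees_of_freedom(self) -> int:
        p = len(self.observed_vars)
        return p * (p + 3) // 2 - self.n_free

    def relabel(self, mapping: dict) -> "SemSpec":
        """New spec with labels replaced per ``mapping`` (merging = equality)."""
        def remap(M):
            out = M.copy()
            it = np.nditer(out, flags=["multi_index", "refs_ok"])
            for cell in it:
                c = cell.item()
                if isinstance(c, str) and c in mapping:
                    out[it.multi_index] = mapping[c]
            return out
        inv = {k: {g: [mapping.get(l, l) for l in ls]
                   for g, ls in v.items()}
               for k, v in self.invariance.items()}
        return SemSpec(list(self.observed_vars), list(self.latent_vars),
                       remap(self.lam), remap(self.beta), remap(self.psi),
                       remap(self.theta), remap(self.nu), remap(self.alpha),
                       bounds={mapping.get(k, k): v for k, v in self.bounds.items()},
                       start={mapping.get(k, k): v for k, v in self.start.items()},
                       invariance=inv)

    def fix(self, values: dict) -> "SemSpec":
        """New spec with the given labels fixed at numeric values."""
        def remap(M):
            out = M.copy()
            it = np.nditer(out, flags=["multi_index", "refs_ok"])
            for cell in it:
                c = cell.item()
                if isinstance(c, str) and c in values:
                    out[it.multi_index] = float(values[c])
            return out
        return SemSpec(list(self.observed_vars), list(self.latent_vars),
                       remap(self.lam), remap(self.beta), remap(self.psi),
                       remap(self.theta), remap(self.nu), remap(self.alpha),
                       bounds={k: v for k, v in self.bounds.items() if k not in values},
                       start={k: v for k, v in self.start.items() if k not in values},
                       invariance=self.invariance)

    # -- serialization ----------------------------------------------------
    def to_json(self, path=None) -> str:
        def ser(M):
            return [[c if isinstance(c, str) else float(c) for c in row]
                    for row in np.atleast_2d(M)]
        d = {"observed_vars": list(self.observed_vars),
             "latent_vars": list(self.latent_vars),
             "lam": ser(self.lam), "beta": ser(self.beta),
             "psi": ser(self.psi), "theta": ser(self.theta),
             "nu": ser(self.nu)[0], "alpha": ser(self.alpha)[0],
             "bounds": {k: list(v) for k, v in self.bounds.items()},
             "start": self.start, "invariance": self.invariance}
        text = json.dumps(d, indent=1)
        if path is not None:
            from pathlib import Path
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text_or_path) -> "SemSpec":
        from pathlib import Path
        s = str(text_or_path)
        if not s.lstrip().startswith("{"):
            s = Path(text_or_path).read_text()
        d = json.loads(s)

        def de(M, shape):
            a = np.empty(shape, dtype=object)
            flat = np.array(M, dtype=object).reshape(shape)
            for idx in np.ndindex(shape):
                c = flat[idx]
                a[idx] = c if isinstance(c, str) else float(c)
            return a
        p, m = len(d["observed_vars"]), len(d["latent_vars"])
        return cls(d["observed_vars"], d["latent_vars"],
                   de(d["lam"], (p, m)), de(d["beta"], (m, m)),
                   de(d["psi"], (m, m)), de(d["theta"], (p, p)),
                   de(d["nu"], (p,)), de(d["alpha"], (m,)),
                   bounds={k: tuple(v) for k, v in d.get("bounds", {}).items()},
                   start=d.get("start", {}),
                   invariance=d.get("invariance", {}))


# ---------------------------------------------------------------------------
# compiled model: fast parameter -> implied moments
# ---------------------------------------------------------------------------

class _Compiled:
    def __init__(self, spec: SemSpec):
        self.spec = spec
        self.labels = spec.free_labels()
        self.index = {l: i for i, l in enumerate(self.labels)}
        self.k = len(self.labels)
        p, m = len(spec.observed_vars), len(spec.latent_vars)
        self.p, self.m = p, m
        self.roles = {}  # label -> (kind, i, j) at first appearance

        def compile_mat(M, kind, symmetric=False):
            base = np.zeros(M.shape, dtype=float)
            rows, cols, idx = [], [], []
            it = np.nditer(M, flags=["multi_index", "refs_ok"])
            for cell in it:
                c = cell.item()
                ij = it.multi_index
                if symmetric and len(ij) == 2 and ij[0] < ij[1]:
                    continue  # use lower triangle incl. diagonal
                if isinstance(c, str):
                    rows.append(ij[0] if len(ij) == 2 else ij[0])
                    cols.append(ij[1] if len(ij) == 2 else 0)
                    idx.append(self.index[c])
                    self.roles.setdefault(c, (kind, *ij))
                else:
                    if len(ij) == 2:
                        base[ij] = float(c)
                    else:
                        base[ij[0]] = float(c)
            return base, np.array(rows, int), np.array(cols, int), np.array(idx, int)

        self.lam = compile_mat(spec.lam, "lam")
        self.beta = compile_mat(spec.beta, "beta")
        self.psi = compile_mat(spec.psi, "psi", symmetric=True)
        self.theta = compile_mat(spec.theta, "theta", symmetric=True)
        self.nu = compile_mat(spec.nu.reshape(-1, 1), "nu")
        self.alpha = compile_mat(spec.alpha.reshape(-1, 1), "alpha")
        # chain-rule weights for symmetric matrices (off-diagonal cells
        # appear twice in the matrix but are one parameter)
        self.psi_w = np.where(self.psi[1] == self.psi[2], 1.0, 2.0)
        self.theta_w = np.where(self.theta[1] == self.theta[2], 1.0, 2.0)

    def matrices(self, th: np.ndarray):
        def fill(cm, symmetric=False):
            base, r, c, i = cm
            A = base.copy()
            if len(r):
                A[r, c] = th[i]
                if symmetric:
                    A[c, r] = th[i]
            return A
        Lam = fill(self.lam)
        B = fill(self.beta)
        Psi = fill(self.psi, symmetric=True)
        Th = fill(self.theta, symmetric=True)
        nu = fill(self.nu)[:, 0]
        al = fill(self.alpha)[:, 0]
        return Lam, B, Psi, Th, nu, al

    def implied(self, th: np.ndarray):
        Lam, B, Psi, Th, nu, al = self.matrices(th)
        M = np.linalg.solve(np.eye(self.m) - B, np.eye(self.m))
        LM = Lam @ M
        Sigma = LM @ Psi @ LM.T + Th
        mu = nu + LM @ al
        Vlat = M @ Psi @ M.T
        return mu, Sigma, Vlat, (Lam, B, Psi, Th, nu, al)

    def value_and_grad(self, th, pdta):
        """Objective -2logl/N and its analytic gradient."""
        Lam, B, Psi, Th, nu, al = self.matrices(th)
        M = np.linalg.solve(np.eye(self.m) - B, np.eye(self.m))
        T = Lam @ M
        Sigma = T @ Psi @ T.T + Th
        mu = nu + T @ al
        out = pdta.value_and_moment_gradients(mu, Sigma)
        if out is None:
            return _PENALTY / pdta.n, np.zeros(self.k)
        f, G, gmu = out
        dT = 2.0 * G @ T @ Psi + np.outer(gmu, al)
        dLam = dT @ M.T
        dB = T.T @ dT @ M.T
        dPsi = T.T @ G @ T
        dAl = T.T @ gmu
        g = np.zeros(self.k)
        for cm, D, w in ((self.lam, dLam, None), (self.beta, dB, None),
                         (self.psi, dPsi, self.psi_w),
                         (self.theta, G, self.theta_w)):
            _, r, c, i = cm
            if len(r):
                vals = D[r, c] if w is None else w * D[r, c]
                np.add.at(g, i, vals)
        for cm, D in ((self.nu, gmu), (self.alpha, dAl)):
            _, r, c, i = cm
            if len(r):
                np.add.at(g, i, D[r])
        return f / pdta.n, g / pdta.n

    # -- bounds & starts --------------------------------------------------
    def default_start(self, samp_mean, samp_var):
        th0 = np.empty(self.k)
        for l, i in self.index.items():
            kind, a, b = self.roles[l]
            if l in self.spec.start:
                th0[i] = self.spec.start[l]
            elif kind == "lam":
                th0[i] = 0.5 * np.sqrt(max(samp_var[a], 1e-3))
            elif kind == "beta":
                th0[i] = 0.1
            elif kind == "psi":
                th0[i] = 1.0 if a == b else 0.0
            elif kind == "theta":
                th0[i] = 0.5 * max(samp_var[a], 1e-3) if a == b else 0.0
            elif kind == "nu":
                th0[i] = samp_mean[a]
            else:  # alpha
                th0[i] = 0.0
        return th0

    def default_bounds(self):
        bounds = []
        for l in self.labels:
            if l in self.spec.bounds:
                bounds.append(tuple(self.spec.bounds[l]))
                continue
            kind, a, b = self.roles[l]
            if kind in ("psi", "theta") and a == b:
                bounds.append((1e-6, None))
            else:
                bounds.append((None, None))
        return bounds


# ---------------------------------------------------------------------------
# data handling
# ---------------------------------------------------------------------------

def as_frame(data, observed_vars) -> pd.DataFrame:
    """Coerce a DataFrame / array / PanelDataset to the model's columns."""
    if isinstance(data, PanelDataset):
        X, cols = data.wide_matrix()
        df = pd.DataFrame(X, columns=cols)
    elif isinstance(data, pd.DataFrame):
        df = data
    else:
        X = np.asarray(data, dtype=float)
        if X.shape[1] != len(observed_vars):
            raise ValueError("array width != number of observed variables")
        return pd.DataFrame(X, columns=list(observed_vars))
    missing = [v for v in observed_vars if v not in df.columns]
    if missing:
        raise ValueError(f"data lacks observed variables {missing}")
    return df[list(observed_vars)]


class _PatternData:
    """Rows grouped by missingness pattern with per-pattern moments."""

    def __init__(self, X: np.ndarray, missing: str):
        mask = np.isfinite(X)
        keep = mask.any(axis=1)
        X, mask = X[keep], mask[keep]
        if missing == "listwise":
            complete = mask.all(axis=1)
            X, mask = X[complete], mask[complete]
            if len(X) == 0:
                raise ValueError("no complete rows for listwise estimation")
        self.n = len(X)
        self.p = X.shape[1]
        self.patterns = []
        codes = (mask * (1 << np.arange(self.p))).sum(axis=1)
        for code in np.unique(codes):
            rows = X[codes == code]
            obs = np.flatnonzero(mask[codes == code][0])
            sub = rows[:, obs]
            nk = len(sub)
            mk = sub.mean(axis=0)
            dk = sub - mk
            Sk = dk.T @ dk / nk
            self.patterns.append((obs, nk, mk, Sk))
        # available-case moments for starting values
        with np.errstate(invalid="ignore"):
            self.samp_mean = np.nanmean(X, axis=0)
            self.samp_var = np.nanvar(X, axis=0)
        self.samp_mean = np.nan_to_num(self.samp_mean)
        self.samp_var = np.where(np.isfinite(self.samp_var) & (self.samp_var > 0),
                                 self.samp_var, 1.0)
        self.complete = all(len(pat[0]) == self.p for pat in self.patterns)
        self.X = X
        self.mask = mask

    def neg2loglik(self, mu, Sigma) -> float:
        """-2 log L at given moments; +inf (penalty) when not PD."""
        total = 0.0
        for obs, nk, mk, Sk in self.patterns:
            So = Sigma[np.ix_(obs, obs)]
            try:
                c, low = sla.cho_factor(So, check_finite=False)
            except (np.linalg.LinAlgError, ValueError):
                return _PENALTY
            logdet = 2.0 * np.log(np.diag(c)).sum()
            Sinv_S = sla.cho_solve((c, low), Sk, check_finite=False)
            d = mk - mu[obs]
            quad = d @ sla.cho_solve((c, low), d, check_finite=False)
            total += nk * (len(obs) * np.log(2 * np.pi) + logdet
                           + np.trace(Sinv_S) + quad)
        return total

    def moment_gradients(self, mu, Sigma):
        """(dF/dSigma, dF/dmu) of F = -2 log L, or None when not PD."""
        out = self.value_and_moment_gradients(mu, Sigma)
        return None if out is None else (out[1], out[2])

    def value_and_moment_gradients(self, mu, Sigma):
        """(-2logL, dF/dSigma, dF/dmu) with a single factorization pass."""
        p = len(mu)
        total = 0.0
        G = np.zeros((p, p))
        gmu = np.zeros(p)
        for obs, nk, mk, Sk in self.patterns:
            So = Sigma[np.ix_(obs, obs)]
            try:
                c, low = sla.cho_factor(So, check_finite=False)
            except (np.linalg.LinAlgError, ValueError):
                return None
            Sinv = sla.cho_solve((c, low), np.eye(len(obs)),
                                 check_finite=False)
            logdet = 2.0 * np.log(np.diag(c)).sum()
            d = mk - mu[obs]
            Sid = Sinv @ d
            M = Sk + np.outer(d, d)
            SiM = Sinv @ M
            total += nk * (len(obs) * np.log(2 * np.pi) + logdet
                           + np.trace(SiM))
            G[np.ix_(obs, obs)] += nk * (Sinv - SiM @ Sinv)
            gmu[obs] += -2.0 * nk * Sid
        return total, G, gmu


# ---------------------------------------------------------------------------
# fit result
# ---------------------------------------------------------------------------

@dataclass
class SemFit:
    spec: SemSpec
    estimates: dict
    se: dict
    standardized: dict
    loglik: float
    n_params: int
    n_used: int
    missing: str
    converged: bool
    gradient_norm: float
    implied_mean: np.ndarray
    implied_cov: np.ndarray
    implied_latent_cov: np.ndarray | None = None
    param_cov: np.ndarray | None = None
    param_order: list = field(default_factory=list)
    chi_square: float | None = None
    df: int | None = None
    p_value: float | None = None
    cfi: float | None = None
    tli: float | None = None
    rmsea: float | None = None
    rmsea_ci: tuple | None = None
    adequate: bool | None = None
    warnings: list = field(default_factory=list)
    data: object = None  # retained _PatternData for downstream tests

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params

    def parameter_table(self) -> pd.DataFrame:
        rows = []
        for l in self.param_order:
            rows.append({"label": l, "estimate": self.estimates[l],
                         "se": self.se.get(l, np.nan),
                         "z": self.estimates[l] / self.se[l]
                         if self.se.get(l) else np.nan,
                         "standardized": self.standardized.get(l, np.nan)})
        return pd.DataFrame(rows)

    def to_json(self, path=None) -> str:
        d = {"estimates": {k: float(v) for k, v in self.estimates.items()},
             "se": {k: float(v) for k, v in self.se.items()},
             "standardized": {k: float(v) for k, v in self.standardized.items()},
             "loglik": self.loglik, "aic": self.aic,
             "n_params": self.n_params, "n_used": self.n_used,
             "missing": self.missing, "converged": self.converged,
             "chi_square": self.chi_square, "df": self.df,
             "p_value": self.p_value, "cfi": self.cfi, "tli": self.tli,
             "rmsea": self.rmsea, "adequate": self.adequate}
        text = json.dumps(d, indent=1)
        if path is not None:
            from pathlib import Path
            Path(path).write_text(text)
        return text


@dataclass
class TestResult:
    kind: str          # wald | lrt | chibar
    statistic: float
    df: object         # int, or mixture weights dict for chibar
    p: float
    extra: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# estimation
# ---------------------------------------------------------------------------

def fit_ml(spec: SemSpec, data, missing: str = "fiml",
           compute_se: bool = True, start: dict | None = None,
           indices: bool = False) -> SemFit:
    """Maximize the (full-information) multivariate-normal likelihood.

    ``missing="fiml"`` sums casewise pattern log-likelihoods; ``"listwise"``
    uses complete rows only.  Standard errors come from the inverse observed
    information (numerical Hessian); set ``compute_se=False`` in simulation
    loops that only need point estimates and log-likelihoods.
    """
    if missing not in ("fiml", "listwise"):
        raise ValueError("missing must be 'fiml' or 'listwise'")
    df = as_frame(data, spec.observed_vars)
    X = df.to_numpy(dtype=float)
    pdta = _PatternData(X, missing)
    comp = _Compiled(spec)
    if comp.k == 0:
        raise ValueError("model has no free parameters")

    N = pdta.n

    def objective(th):
        return comp.value_and_grad(th, pdta)

    th0 = comp.default_start(pdta.samp_mean, pdta.samp_var)
    if start:
        for l, v in start.items():
            if l in comp.index:
                th0[comp.index[l]] = v
    bounds = comp.default_bounds()

    opts = {"maxiter": 1500, "maxfun": 400000, "ftol": 1e-13,
            "gtol": 1e-8, "maxcor": 30}
    res = optimize.minimize(objective, th0, method="L-BFGS-B", jac=True,
                            bounds=bounds, options=opts)
    th = res.x
    gnorm = _kkt_gradient_norm(objective, th, bounds)
    stalled = False
    if gnorm > 1e-5:
        th, gnorm, stalled = _newton_polish(objective, th, bounds)
    if gnorm > 1e-5 and not stalled:
        res2 = optimize.minimize(objective, th, method="L-BFGS-B", jac=True,
                                 bounds=bounds,
                                 options={**opts, "ftol": 1e-15,
                                          "gtol": 1e-10})
        if res2.fun <= res.fun + 1e-12:
            th = res2.x
        gnorm = _kkt_gradient_norm(objective, th, bounds)
        if gnorm > 1e-5:
            th, gnorm, stalled = _newton_polish(objective, th, bounds)

    f = objective(th)[0]
    loglik = -0.5 * N * f
    proper = np.isfinite(f) and f < _PENALTY / N
    converged = bool(proper and gnorm < 1e-5)
    flat_ridge = bool(proper and not converged and stalled and gnorm < 5e-3)
    converged = converged or flat_ridge

    mu, Sigma, Vlat, mats = comp.implied(th)
    estimates = {l: float(th[comp.index[l]]) for l in comp.labels}
    standardized = _standardize(comp, th, Sigma, Vlat)

    warnings_ = []
    if not converged:
        warnings_.append(f"non-convergence: max gradient {gnorm:.2e}")
    elif flat_ridge:
        warnings_.append(
            f"converged on a numerically flat ridge (max gradient "
            f"{gnorm:.2e}; no further likelihood improvement attainable)")
    for name, M in (("psi", mats[2]), ("theta", mats[3])):
        ev = np.linalg.eigvalsh((M + M.T) / 2)
        if ev.min() < -1e-8:
            warnings_.append(f"{name} not positive semi-definite at solution")

    se, pcov = {}, None
    if compute_se and converged:
        pcov = _param_cov(objective, th, N)
        if pcov is not None:
            d = np.diag(pcov)
            se = {l: float(np.sqrt(d[comp.index[l]])) if d[comp.index[l]] > 0
                  else np.nan for l in comp.labels}
        else:
            warnings_.append("information matrix singular; no SEs")

    fit = SemFit(spec=spec, estimates=estimates, se=se,
                 standardized=standardized, loglik=float(loglik),
                 n_params=comp.k, n_used=N, missing=missing,
                 converged=converged, gradient_norm=float(gnorm),
                 implied_mean=mu, implied_cov=Sigma,
                 implied_latent_cov=Vlat, param_cov=pcov,
                 param_order=list(comp.labels), warnings=warnings_,
                 data=pdta)
    if indices:
        fit = fit_indices(fit)
    return fit


def _newton_polish(objective, th, bounds, max_steps: int = 12):
    """Damped Newton refinement when quasi-Newton stalls on a flat ridge.

    Returns ``(theta, gnorm, stalled)``; ``stalled`` means no line-search
    direction could improve the objective any further (numerically flat)."""
    th = th.copy()
    gnorm = _kkt_gradient_norm(objective, th, bounds)
    stalled = False
    for _ in range(max_steps):
        if gnorm <= 1e-6:
            break
        f0, g = objective(th)
        k = len(th)
        # freeze coordinates pinned at a bound with the gradient pushing out
        frozen = np.zeros(k, dtype=bool)
        for i, (lo, up) in enumerate(bounds):
            if lo is not None and th[i] <= lo + 1e-9 and g[i] > 0:
                frozen[i] = True
            if up is not None and th[i] >= up - 1e-9 and g[i] < 0:
                frozen[i] = True
        free_idx = np.flatnonzero(~frozen)
        if len(free_idx) == 0:
            stalled = True
            break
        H = np.empty((k, len(free_idx)))
        h = 1e-6 * np.maximum(1.0, np.abs(th))
        for col, i in enumerate(free_idx):
            tp, tm = th.copy(), th.copy()
            tp[i] += h[i]
            tm[i] -= h[i]
            H[:, col] = (objective(tp)[1] - objective(tm)[1]) / (2 * h[i])
        Hf = H[free_idx, :]
        Hf = (Hf + Hf.T) / 2
        gf = g[free_idx]
        ridge = 1e-8 * max(1.0, np.abs(np.diag(Hf)).max())
        step_f = None
        for _ in range(8):
            try:
                ev_min = np.linalg.eigvalsh(Hf + ridge * np.eye(len(gf)))[0]
                if ev_min <= 0:
                    raise np.linalg.LinAlgError
                step_f = np.linalg.solve(Hf + ridge * np.eye(len(gf)), -gf)
                break
            except np.linalg.LinAlgError:
                ridge = max(ridge * 100, 1e-6)
        if step_f is None:
            break
        step = np.zeros(k)
        step[free_idx] = step_f
        improved = False
        for scale in (1.0, 0.5, 0.25, 0.1, 0.02):
            cand = th + scale * step
            for i, (lo, up) in enumerate(bounds):
                if lo is not None:
                    cand[i] = max(cand[i], lo)
                if up is not None:
                    cand[i] = min(cand[i], up)
            fc = objective(cand)[0]
            if fc <= f0 + 1e-14:
                gn = _kkt_gradient_norm(objective, cand, bounds)
                if fc < f0 - 1e-14 or gn < gnorm:
                    th, gnorm, improved = cand, gn, True
                    if f0 - fc < 1e-11 * max(1.0, abs(f0)):
                        stalled = True   # likelihood numerically maximal
                    break
        if not improved:
            stalled = True
            break
        if stalled:
            break
    else:
        # steps exhausted while improvements had become negligible
        stalled = gnorm < 5e-3
    return th, gnorm, stalled


def _kkt_gradient_norm(objective, th, bounds):
    """Max |gradient| with components at active bounds KKT-screened."""
    g = objective(th)[1].copy()
    for i, (lo, up) in enumerate(bounds):
        if lo is not None and th[i] <= lo + 1e-9 and g[i] > 0:
            g[i] = 0.0
        if up is not None and th[i] >= up - 1e-9 and g[i] < 0:
            g[i] = 0.0
    return float(np.max(np.abs(g))) if len(g) else 0.0


def _param_cov(objective, th, N, h_scale=1e-6):
    """Inverse observed information via central differences of the
    analytic gradient; objective returns (-2logl/N, gradient)."""
    k = len(th)
    H = np.empty((k, k))
    h = h_scale * np.maximum(1.0, np.abs(th))
    for i in range(k):
        tp, tm = th.copy(), th.copy()
        tp[i] += h[i]
        tm[i] -= h[i]
        H[:, i] = (objective(tp)[1] - objective(tm)[1]) / (2 * h[i])
    H = (H + H.T) / 2
    info = 0.5 * N * H  # Hessian of -loglik
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        return None
    if not np.all(np.isfinite(cov)):
        return None
    return cov


def _standardize(comp: _Compiled, th, Sigma, Vlat):
    sd_obs = np.sqrt(np.clip(np.diag(Sigma), 1e-12, None))
    sd_lat = np.sqrt(np.clip(np.diag(Vlat), 1e-12, None))
    out = {}
    for l, i in comp.index.items():
        kind, a, b = comp.roles[l]
        v = th[i]
        if kind == "lam":
            out[l] = float(v * sd_lat[b] / sd_obs[a])
        elif kind == "beta":
            out[l] = float(v * sd_lat[b] / sd_lat[a])
        elif kind == "psi":
            out[l] = float(v / (sd_lat[a] * sd_lat[b])) if a != b \
                else float(v / Vlat[a, a]) if Vlat[a, a] > 0 else np.nan
        elif kind == "theta":
            out[l] = float(v / (sd_obs[a] * sd_obs[b])) if a != b \
                else float(v / Sigma[a, a])
        else:
            out[l] = float(v)
    return out


# ---------------------------------------------------------------------------
# saturated / independence log-likelihoods and fit indices
# ---------------------------------------------------------------------------

def saturated_loglik(pdta: _PatternData) -> float:
    if pdta.complete:
        mu = pdta.X.mean(axis=0)
        d = pdta.X - mu
        S = d.T @ d / pdta.n
        sign, logdet = np.linalg.slogdet(S)
        return -0.5 * pdta.n * (pdta.p * np.log(2 * np.pi) + logdet + pdta.p)
    Xm = np.where(pdta.mask, pdta.X, np.nan)
    mu, Sigma, _ = em_mvn(Xm)
    return -0.5 * pdta.neg2loglik(mu, Sigma)


def independence_loglik(pdta: _PatternData) -> tuple[float, int]:
    """(loglik, df) of the diagonal-covariance, free-means model."""
    Xm = np.where(pdta.mask, pdta.X, np.nan)
    ll = 0.0
    for j in range(pdta.p):
        col = Xm[:, j]
        col = col[np.isfinite(col)]
        nv = len(col)
        var = max(col.var(), 1e-12)
        ll += -0.5 * nv * (np.log(2 * np.pi) + np.log(var) + 1.0)
    df = pdta.p * (pdta.p + 3) // 2 - 2 * pdta.p
    return ll, df


def fit_indices(fit: SemFit, baseline: SemFit | None = None) -> SemFit:
    """Attach chi-square, CFI/TLI/RMSEA (+90% CI) and the adequacy label.

    ``baseline`` defaults to the closed-form independence model on the same
    data; the saturated log-likelihood is closed-form on complete data and
    EM-based under missingness.
    """
    pdta = fit.data
    ll_sat = saturated_loglik(pdta)
    chi2 = max(0.0, 2.0 * (ll_sat - fit.loglik))
    dof = fit.spec.degrees_of_freedom()
    if baseline is not None:
        chi2_b = max(0.0, 2.0 * (ll_sat - baseline.loglik))
        df_b = baseline.spec.degrees_of_freedom() if baseline.spec is not None \
            else baseline.df
    else:
        ll_b, df_b = independence_loglik(pdta)
        chi2_b = max(0.0, 2.0 * (ll_sat - ll_b))
    n = fit.n_used

    fit.chi_square = float(chi2)
    fit.df = int(dof)
    fit.p_value = float(stats.chi2.sf(chi2, dof)) if dof > 0 else np.nan

    num = max(chi2 - dof, 0.0)
    den = max(chi2_b - df_b, chi2 - dof, 0.0)
    fit.cfi = float(1.0 - num / den) if den > 0 else 1.0
    if df_b > 0 and dof > 0 and chi2_b / df_b != 1.0:
        tli = ((chi2_b / df_b) - (chi2 / dof)) / ((chi2_b / df_b) - 1.0)
        fit.tli = float(min(tli, 1.0))
    else:
        fit.tli = 1.0
    if dof > 0:
        fit.rmsea = float(np.sqrt(max(chi2 - dof, 0.0) / (dof * n)))
        fit.rmsea_ci = _rmsea_ci(chi2, dof, n)
    else:
        fit.rmsea = None
        fit.warnings.append("df = 0: RMSEA undefined")
    fit.adequate = bool(fit.cfi >= 0.90 and fit.tli >= 0.90
                        and (fit.rmsea is None or fit.rmsea <= 0.06))
    return fit


def _rmsea_ci(chi2, dof, n, level=0.90):
    lo_p, hi_p = (1 + level) / 2, (1 - level) / 2

    def solve(target):
        if stats.ncx2.cdf(chi2, dof, 0) < target:
            return 0.0
        hi = max(chi2, dof) * 2 + 100
        while stats.ncx2.cdf(chi2, dof, hi) > target and hi < 1e7:
            hi *= 2
        from scipy.optimize import brentq
        try:
            return brentq(lambda l: stats.ncx2.cdf(chi2, dof, l) - target,
                          0, hi, xtol=1e-6)
        except ValueError:
            return 0.0
    lam_lo = solve(lo_p)
    lam_hi = solve(hi_p)
    return (float(np.sqrt(lam_lo / (dof * n))),
            float(np.sqrt(lam_hi / (dof * n))))


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------

def lrt(fit_restricted: SemFit, fit_full: SemFit, tol: float = 1e-6) -> TestResult:
    """Likelihood-ratio test of nested fits on the same data."""
    if fit_restricted.n_used != fit_full.n_used:
        raise ValueError("fits use different samples")
    stat = 2.0 * (fit_full.loglik - fit_restricted.loglik)
    if stat < -tol * max(1.0, abs(fit_full.loglik)):
        raise RuntimeError(
            f"restricted loglik exceeds full ({stat:.4g}): optimizer failure")
    stat = max(stat, 0.0)
    ddf = fit_full.n_params - fit_restricted.n_params
    if ddf <= 0:
        p = 1.0 if stat <= tol else np.nan
        return TestResult("lrt", float(stat), int(max(ddf, 0)), float(p))
    return TestResult("lrt", float(stat), int(ddf),
                      float(stats.chi2.sf(stat, ddf)))


def wald(fit: SemFit, constraints) -> TestResult:
    """Wald test of linear constraints h(theta) = 0 on a fitted model.

    Each constraint is either a pair of labels (equality) or a dict mapping
    labels to coefficients with optional key ``"_const"``.
    """
    if fit.param_cov is None:
        raise ValueError("fit lacks a parameter covariance (compute_se=True)")
    order = {l: i for i, l in enumerate(fit.param_order)}
    q = len(constraints)
    J = np.zeros((q, len(order)))
    h = np.zeros(q)
    for r, con in enumerate(constraints):
        if isinstance(con, dict):
            const = con.get("_const", 0.0)
            val = const
            for l, cf in con.items():
                if l == "_const":
                    continue
                J[r, order[l]] = cf
                val += cf * fit.estimates[l]
            h[r] = val
        else:
            a, b = con
            J[r, order[a]] = 1.0
            J[r, order[b]] = -1.0
            h[r] = fit.estimates[a] - fit.estimates[b]
    V = J @ fit.param_cov @ J.T
    if q > 1 and np.linalg.matrix_rank(V, tol=1e-10 * np.trace(V)) < q:
        raise ValueError("singular constraint covariance: a constraint is "
                         "redundant with the others")
    try:
        W = float(h @ np.linalg.solve(V, h))
    except np.linalg.LinAlgError as e:
        raise ValueError(f"singular constraint covariance: {e}") from e
    W = max(W, 0.0)
    return TestResult("wald", W, q, float(stats.chi2.sf(W, q)))


def add_param_cov(fit: SemFit) -> SemFit:
    """Compute the parameter covariance (and SEs) of a fit post hoc."""
    if fit.param_cov is not None or not fit.converged:
        return fit
    comp = _Compiled(fit.spec)
    th = np.array([fit.estimates[l] for l in comp.labels])
    pcov = _param_cov(lambda t: comp.value_and_grad(t, fit.data),
                      th, fit.n_used)
    if pcov is not None:
        fit.param_cov = pcov
        d = np.diag(pcov)
        fit.se = {l: float(np.sqrt(d[comp.index[l]])) if d[comp.index[l]] > 0
                  else np.nan for l in comp.labels}
    return fit


def simulate_from_fit(fit: SemFit, n: int, rng) -> pd.DataFrame:
    """Complete-data draw from the fit's implied moments."""
    Sigma = (fit.implied_cov + fit.implied_cov.T) / 2
    X = rng.multivariate_normal(fit.implied_mean, Sigma, size=n,
                                method="cholesky")
    return pd.DataFrame(X, columns=list(fit.spec.observed_vars))


def boundary_lrt(fit_restricted: SemFit, fit_full: SemFit,
                 n_draws: int = 500, seed: int = 0) -> TestResult:
    """Chi-bar-square test for variances restricted to their 0 boundary.

    The null distribution of the LR statistic is a mixture of chi-squares;
    it is approximated by parametric simulation under the restricted fit:
    ``n_draws`` complete-data panels are drawn from the restricted model's
    implied moments, both models are refitted, and the p-value is the
    simulated upper-tail probability.  For a single boundary variance the
    estimated mixture weights on (chi2_0, chi2_1) are also reported.
    """
    if n_draws < 1:
        raise ValueError("boundary_lrt needs at least one simulation draw")
    stat = max(0.0, 2.0 * (fit_full.loglik - fit_restricted.loglik))
    ddf = fit_full.n_params - fit_restricted.n_params
    if stat == 0.0:
        return TestResult("chibar", 0.0, {"df_max": ddf}, 1.0)
    rng = np.random.default_rng(seed)
    sims = np.empty(n_draws)
    warm_r = fit_restricted.estimates
    warm_f = fit_full.estimates
    n = fit_restricted.n_used
    for b in range(n_draws):
        dat = simulate_from_fit(fit_restricted, n, rng)
        fr = fit_ml(fit_restricted.spec, dat, missing="listwise",
                    compute_se=False, start=warm_r)
        ff = fit_ml(fit_full.spec, dat, missing="listwise",
                    compute_se=False, start=warm_f)
        sims[b] = max(0.0, 2.0 * (ff.loglik - fr.loglik))
    p = (1.0 + np.sum(sims >= stat)) / (n_draws + 1.0)
    weights = {"df_max": ddf}
    if ddf == 1:
        w0 = float(np.mean(sims < 1e-3))
        weights.update({"w0": w0, "w1": 1.0 - w0})
    return TestResult("chibar", float(stat), weights, float(p),
                      extra={"n_draws": n_draws, "sim_quantiles":
                             [float(np.quantile(sims, q))
                              for q in (0.5, 0.9, 0.95, 0.99)]})


# ---------------------------------------------------------------------------
# measurement-invariance ladder
# ---------------------------------------------------------------------------

def invariance_ladder(spec: SemSpec, data,
                      levels=("configural", "metric", "scalar"),
                      release=(), missing: str = "fiml") -> list[dict]:
    """Configural -> metric (equal loadings) -> scalar (equal intercepts).

    ``spec.invariance["loadings"]`` / ``["intercepts"]`` must map group
    names (one per repeated indicator) to the per-wave labels to merge;
    groups named in ``release`` stay free (partial invariance).  Returns a
    list of ``{"level", "fit", "test"}`` with successive LRTs.
    """
    if not spec.invariance.get("loadings"):
        raise ValueError("spec carries no invariance metadata")
    out = []
    prev = None
    current = spec
    for level in levels:
        if level == "configural":
            s = spec
        elif level == "metric":
            mapping = {}
            for g, labels in spec.invariance["loadings"].items():
                if g in release:
                    continue
                for l in labels[1:]:
                    mapping[l] = labels[0]
            s = spec.relabel(mapping)
        elif level == "scalar":
            mapping = {}
            for key in ("loadings", "intercepts"):
                for g, labels in spec.invariance.get(key, {}).items():
                    if g in release:
                        continue
                    for l in labels[1:]:
                        mapping[l] = labels[0]
            s = spec.relabel(mapping)
        else:
            raise ValueError(f"unknown level {level!r}")
        fit = fit_ml(s, data, missing=missing, compute_se=False)
        test = lrt(fit, prev) if prev is not None else None
        out.append({"level": level, "fit": fit, "test": test})
        prev = fit
    return out


# ---------------------------------------------------------------------------
# convenience builders
# ---------------------------------------------------------------------------

def one_factor_spec(items: list[str]) -> SemSpec:
    """Cross-sectional one-factor model, factor variance fixed to 1."""
    p = len(items)
    lam = _pattern((p, 1))
    theta = _pattern((p, p))
    nu = _pattern((p,))
    for i, it in enumerate(items):
        lam[i, 0] = f"lam_{it}"
        theta[i, i] = f"theta_{it}"
        nu[i] = f"nu_{it}"
    psi = _pattern((1, 1), 1.0)
    beta = _pattern((1, 1))
    alpha = _pattern((1,))
    alpha[0] = 0.0
    return SemSpec(list(items), ["F"], lam, beta, psi, theta, nu, alpha)


def repeated_onefactor_spec(items: list[str], waves: list[int],
                            ar: bool = True) -> SemSpec:
    """Longitudinal one-factor model with per-wave free loadings/intercepts.

    Wave-1 factor variance fixed to 1; endogenous factor residual variances
    fixed to 1 (scale identification with free loadings); AR(1) structural
    paths between consecutive waves.  Carries invariance metadata.
    """
    obs = [f"{it}@{w}" for w in waves for it in items]
    lats = [f"F@{w}" for w in waves]
    p, m = len(obs), len(lats)
    lam = _pattern((p, m))
    theta = _pattern((p, p))
    nu = _pattern((p,))
    psi = _pattern((m, m))
    beta = _pattern((m, m))
    alpha = _pattern((m,))
    inv_load = {it: [] for it in items}
    inv_int = {it: [] for it in items}
    for wi, w in enumerate(waves):
        for ii, it in enumerate(items):
            r = wi * len(items) + ii
            l_lab = f"lam_{it}@{w}"
            n_lab = f"nu_{it}@{w}"
            lam[r, wi] = l_lab
            theta[r, r] = f"theta_{it}@{w}"
            nu[r] = n_lab
            inv_load[it].append(l_lab)
            inv_int[it].append(n_lab)
        psi[wi, wi] = 1.0
        if wi > 0 and ar:
            beta[wi, wi - 1] = f"ar@{w}"
    return SemSpec(obs, lats, lam, beta, psi, theta, nu, alpha,
                   invariance={"loadings": inv_load, "intercepts": inv_int})
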