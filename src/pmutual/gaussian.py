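"""EM estimation of a Gaussian mean and covariance under arbitrary missingness.

This is the maximum-likelihood (full-information) estimator of the
unstructured multivariate-normal model, used both as the saturated model
for SEM fit indices and as the input stage for network estimation on
incomplete panels.  On complete data it returns the sample moments
(N-denominator) exactly, in a single iteration.
"""

from __future__ import annotations

import numpy as np
from scipy import linalg as sla

__all__ = ["em_mvn"]


def em_mvn(X, max_iter: int = 500, tol: float = 1e-9):
    """ML mean/covariance of rows with NaN holes via EM.

    Parameters
    ----------
    X : (n, p) array with NaN marking missing entries; rows with no
        observed entry are dropped.

    Returns
    -------
    mean : (p,) ndarray
    cov : (p, p) ndarray (N-denominator MLE)
    info : dict with ``n_used``, ``n_iter``, ``converged``

    Raises
    ------
    RuntimeError if EM has not converged after ``max_iter`` sweeps (the
    trace of parameter changes is attached to the exception).
    """
    X = np.asarray(X, dtype=float)
    mask = np.isfinite(X)
    keep = mask.any(axis=1)
    X, mask = X[keep], mask[keep]
    n, p = X.shape
    if n == 0:
        raise ValueError("no rows with observed data")
    frac = mask.mean(axis=0)
    if np.any(frac < 0.10):
        raise ValueError("a variable is observed in fewer than 10% of rows")

    # group rows by pattern once
    codes = (mask * (1 << np.arange(p))).sum(axis=1)
    groups = []
    for code in np.unique(codes):
        rows = np.flatnonzero(codes == code)
        obs = np.flatnonzero(mask[rows[0]])
        groups.append((rows, obs))

    if all(len(obs) == p for _, obs in groups):
        mu = X.mean(axis=0)
        d = X - mu
        return mu, d.T @ d / n, {"n_used": n, "n_iter": 0, "converged": True}

    col_mean = np.array([X[mask[:, j], j].mean() if mask[:, j].any() else 0.0
                         for j in range(p)])
    col_var = np.array([X[mask[:, j], j].var() if mask[:, j].sum() > 1 else 1.0
                        for j in range(p)])
    mu = col_mean.copy()
    Sigma = np.diag(np.maximum(col_var, 1e-6))
    trace = []
    for it in range(max_iter):
        s1 = np.zeros(p)
        s2 = np.zeros((p, p))
        for rows, obs in groups:
            mis = np.setdiff1d(np.arange(p), obs, assume_unique=False)
            Y = X[np.ix_(rows, obs)]
            if len(mis) == 0:
                s1 += Y.sum(axis=0)
                s2 += Y.T @ Y
                continue
            Soo = Sigma[np.ix_(obs, obs)]
            Smo = Sigma[np.ix_(mis, obs)]
            c, low = sla.cho_factor(Soo + 1e-12 * np.eye(len(obs)),
                                    check_finite=False)
            W = sla.cho_solve((c, low), Smo.T, check_finite=False).T  # mis x obs
            resid = Y - mu[obs]
            Em = mu[mis] + resid @ W.T                              # rows x mis
            Cm = Sigma[np.ix_(mis, mis)] - W @ Smo.T
            full = np.zeros((len(rows), p))
            full[:, obs] = Y
            full[:, mis] = Em
            s1 += full.sum(axis=0)
            s2 += full.T @ full
            s2[np.ix_(mis, mis)] += len(rows) * Cm
        mu_new = s1 / n
        Sigma_new = s2 / n - np.outer(mu_new, mu_new)
        Sigma_new = (Sigma_new + Sigma_new.T) / 2
        delta = max(np.max(np.abs(mu_new - mu)),
                    np.max(np.abs(Sigma_new - Sigma)))
        mu, Sigma = mu_new, Sigma_new
        trace.append(float(delta))
        if delta < tol:
            return mu, Sigma, {"n_used": n, "n_iter": it + 1, "converged": True}
    raise RuntimeError(f"EM did not converge in {max_iter} iterations; "
                       f"last deltas {trace[-5:]}")
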