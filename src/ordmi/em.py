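"""EM algorithm for the multivariate normal mean and covariance under
arbitrary (nonmonotone) missingness, and conditional-mean completion.

The E-step groups cases by missingness pattern and, for each pattern,
computes the conditional expectations E[x_mis | x_obs; mu, Sigma] and the
conditional covariance of the missing block via the usual conditional-normal
regression; the M-step updates mean and covariance with the maximum
likelihood divisor n. The observed-data log-likelihood is tracked per
iteration and is monotone non-decreasing, the standard EM guarantee.

`EMImputer` is an sklearn-style transformer: ``fit`` estimates (mu, Sigma)
from a numeric array/DataFrame with NaN as missing, ``transform`` replaces
every missing cell by its conditional mean given the observed cells of its
case — the single "EM-completed" dataset used for model development.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg


@dataclass
class MVNParams:
    """Mean vector and covariance matrix of a d-variate normal."""

    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float).ravel()
        self.cov = np.asarray(self.cov, dtype=float)
        d = self.mean.shape[0]
        if self.cov.shape != (d, d):
            raise ValueError(f"cov shape {self.cov.shape} does not match d={d}")
        if not np.allclose(self.cov, self.cov.T, atol=1e-8):
            raise ValueError("cov must be symmetric")

    @property
    def d(self) -> int:
        return self.mean.shape[0]


@dataclass
class EMResult:
    params: MVNParams
    n_iterations: int
    converged: bool
    loglik_trace: list[float] = field(default_factory=list)


class EMError(ValueError):
    pass


def _as_array(X) -> tuple[np.ndarray, list[str] | None, object]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns), X.index
    return np.asarray(X, dtype=float), None, None


def _check_columns(X: np.ndarray, columns) -> None:
    all_missing = np.isnan(X).all(axis=0)
    if all_missing.any():
        idx = np.flatnonzero(all_missing)
        names = [columns[i] for i in idx] if columns else list(idx)
        raise EMError(f"column(s) entirely missing: {names}")


def _psd_repair(S: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    S = (S + S.T) / 2.0
    w, V = np.linalg.eigh(S)
    floor = max(eps, eps * float(w.max(initial=1.0)))
    if w.min(initial=0.0) < floor:
        S = (V * np.maximum(w, floor)) @ V.T
        S = (S + S.T) / 2.0
    return S


def _initial_params(X: np.ndarray) -> MVNParams:
    """Complete-case moments when enough complete cases exist, else
    available-case moments with a PSD repair."""
    n, d = X.shape
    complete = ~np.isnan(X).any(axis=1)
    if complete.sum() >= d + 1:
        Xc = X[complete]
        mean = Xc.mean(axis=0)
        cov = np.cov(Xc, rowvar=False, bias=True)
    else:
        mean = np.nanmean(X, axis=0)
        obs = ~np.isnan(X)
        Xz = np.where(obs, X - mean, 0.0)
        counts = obs.T.astype(float) @ obs.astype(float)
        cov = (Xz.T @ Xz) / np.maximum(counts, 1.0)
    cov = _psd_repair(np.atleast_2d(cov))
    return MVNParams(mean, cov)


def _patterns(mask: np.ndarray):
    """Group row indices by missingness pattern (rows of a boolean mask)."""
    order = np.lexsort(mask.T[::-1])
    sorted_mask = mask[order]
    change = np.any(sorted_mask[1:] != sorted_mask[:-1], axis=1)
    starts = np.concatenate([[0], np.flatnonzero(change) + 1, [len(mask)]])
    for a, b in zip(starts[:-1], starts[1:]):
        yield sorted_mask[a], order[a:b]


def _solve_obs_block(S_oo: np.ndarray, ridge_scale: float):
    """Cholesky factor of the observed-block covariance, ridge-stabilized
    when numerically singular."""
    try:
        return linalg.cho_factor(S_oo, lower=True), S_oo
    except linalg.LinAlgError:
        warnings.warn("singular observed-block covariance; ridge-stabilized",
                      RuntimeWarning, stacklevel=3)
        S = S_oo + ridge_scale * np.eye(len(S_oo))
        return linalg.cho_factor(S, lower=True), S


def _e_step(X: np.ndarray, mask: np.ndarray, params: MVNParams):
    """Expected sufficient statistics T1 = sum E[x], T2 = sum E[x x'],
    plus the observed-data log-likelihood."""
    n, d = X.shape
    mu, S = params.mean, params.cov
    ridge = 1e-10 * max(float(np.trace(S)) / d, 1.0)
    T1 = np.zeros(d)
    T2 = np.zeros((d, d))
    loglik = 0.0
    for pat, rows in _patterns(mask):
        m = pat
        o = ~pat
        Xr = X[rows]
        k = len(rows)
        if not m.any():
            T1 += Xr.sum(axis=0)
            T2 += Xr.T @ Xr
            dev = Xr - mu
            cho, S_used = _solve_obs_block(S, ridge)
            sol = linalg.cho_solve(cho, dev.T)
            logdet = 2.0 * np.log(np.diag(cho[0])).sum()
            loglik += -0.5 * (k * (d * np.log(2 * np.pi) + logdet)
                              + float(np.sum(dev.T * sol)))
            continue
        if not o.any():
            # no observed cells: expectation is the marginal mean/cov
            T1 += k * mu
            T2 += k * (S + np.outer(mu, mu))
            continue
        S_oo = S[np.ix_(o, o)]
        S_mo = S[np.ix_(m, o)]
        S_mm = S[np.ix_(m, m)]
        cho, S_oo_used = _solve_obs_block(S_oo, ridge)
        dev_o = Xr[:, o] - mu[o]                     # k x no
        sol = linalg.cho_solve(cho, dev_o.T)         # no x k
        Emis = mu[m] + (S_mo @ sol).T                # k x nm
        Cmm = S_mm - S_mo @ linalg.cho_solve(cho, S_mo.T)
        Xfill = Xr.copy()
        Xfill[:, m] = Emis
        T1 += Xfill.sum(axis=0)
        T2 += Xfill.T @ Xfill
        T2[np.ix_(m, m)] += k * Cmm
        no = int(o.sum())
        logdet = 2.0 * np.log(np.diag(cho[0])).sum()
        loglik += -0.5 * (k * (no * np.log(2 * np.pi) + logdet)
                          + float(np.sum(dev_o.T * sol)))
    return T1, T2, loglik


def em_fit(X, tol: float = 1e-6, max_iter: int = 500) -> EMResult:
    """ML estimation of (mean, cov) by EM.

    Parameters
    ----------
    X : array or DataFrame, shape (n, d)
        Numeric data with NaN marking missing cells.
    tol : float
        Convergence: max absolute change over all means, variances and
        covariances below ``tol``.
    max_iter : int
        Iteration cap; the result's ``converged`` flag records whether the
        tolerance was reached.
    """
    arr, columns, _ = _as_array(X)
    n, d = arr.shape
    if n < d + 1:
        raise EMError(f"need at least d+1={d + 1} cases, got {n}")
    _check_columns(arr, columns)
    mask = np.isnan(arr)
    params = _initial_params(arr)
    trace: list[float] = []
    converged = False
    it = 0
    if not mask.any():
        # complete data: a single M-step lands on the ML estimates
        mean = arr.mean(axis=0)
        cov = _psd_repair(np.cov(arr, rowvar=False, bias=True))
        params = MVNParams(mean, cov)
        _, _, ll = _e_step(arr, mask, params)
        return EMResult(params, 1, True, [ll])
    for it in range(1, max_iter + 1):
        T1, T2, ll = _e_step(arr, mask, params)
        trace.append(ll)
        mean = T1 / n
        cov = T2 / n - np.outer(mean, mean)
        cov = _psd_repair(cov)
        delta = max(
            float(np.max(np.abs(mean - params.mean))),
            float(np.max(np.abs(cov - params.cov))),
        )
        params = MVNParams(mean, cov)
        if delta < tol:
            converged = True
            break
    return EMResult(params, it, converged, trace)


def em_complete(X, params: MVNParams):
    """Replace each missing cell by its conditional mean under ``params``.

    Observed cells are unchanged; the output has no missing cells. A case
    with every cell missing is filled with the mean vector.
    """
    arr, columns, index = _as_array(X)
    if arr.shape[1] != params.d:
        raise EMError(f"params dimension {params.d} != table width {arr.shape[1]}")
    mask = np.isnan(arr)
    out = arr.copy()
    mu, S = params.mean, params.cov
    ridge = 1e-10 * max(float(np.trace(S)) / params.d, 1.0)
    for pat, rows in _patterns(mask):
        m, o = pat, ~pat
        if not m.any():
            continue
        if not o.any():
            out[np.ix_(rows, np.flatnonzero(m))] = mu[m]
            continue
        cho, _ = _solve_obs_block(S[np.ix_(o, o)], ridge)
        dev_o = arr[np.ix_(rows, np.flatnonzero(o))] - mu[o]
        fill = mu[m] + (S[np.ix_(m, o)] @ linalg.cho_solve(cho, dev_o.T)).T
        out[np.ix_(rows, np.flatnonzero(m))] = fill
    if columns is not None:
        return pd.DataFrame(out, columns=columns, index=index)
    return out


class EMImputer:
    """sklearn-style transformer: EM-estimated conditional-mean completion.

    Parameters
    ----------
    tol : float, default 1e-6
        EM convergence tolerance (max absolute parameter change).
    max_iter : int, default 500
        Maximum EM iterations.

    Attributes
    ----------
    mean_ : ndarray of shape (d,)
        ML mean estimate.
    covariance_ : ndarray of shape (d, d)
        ML covariance estimate.
    n_iter_ : int
        EM iterations run.
    converged_ : bool
    loglik_trace_ : list of float
        Observed-data log-likelihood per iteration (non-decreasing).
    """

    def __init__(self, tol: float = 1e-6, max_iter: int = 500):
        self.tol = tol
        self.max_iter = max_iter

    def get_params(self, deep: bool = True) -> dict:
        return {"tol": self.tol, "max_iter": self.max_iter}

    def set_params(self, **params) -> "EMImputer":
        for k, v in params.items():
            if k not in ("tol", "max_iter"):
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y=None) -> "EMImputer":
        res = em_fit(X, tol=self.tol, max_iter=self.max_iter)
        self.mean_ = res.params.mean
        self.covariance_ = res.params.cov
        self.n_iter_ = res.n_iterations
        self.converged_ = res.converged
        self.loglik_trace_ = res.loglik_trace
        return self

    def transform(self, X):
        if not hasattr(self, "mean_"):
            raise RuntimeError("EMImputer is not fitted")
        return em_complete(X, MVNParams(self.mean_, self.covariance_))

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(X)
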