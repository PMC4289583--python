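"""Multivariate-normal multiple imputation by data augmentation (DA).

DA is a two-step Markov chain on (missing data, parameters): the I-step
draws every missing cell from its conditional normal given the case's
observed cells and the current (mu, Sigma); the P-step draws new parameters
from the complete-data posterior under the noninformative Jeffreys prior
(inverse-Wishart for Sigma, normal for mu given Sigma). The chain starts at
the EM maximum-likelihood estimates, runs N = m*k iterations, and the
completed dataset at the end of every k-th cycle is saved — k defaulting to
the EM iteration count, since DA nearly always converges in fewer cycles
than EM.

Categorical variables enter as reference-omitted dummy codes (see
:mod:`ordmi.coding`); after the chain, sensible rounding maps the saved
numeric datasets back to legal category labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .coding import CodingMap, InteractionTerm, code_for_mvni, sensible_round
from .em import EMError, MVNParams, _patterns, _psd_repair, em_fit
from .table import MaskedTable

DEFAULT_M = 20        # recommended imputation count at the study's missing fraction
MIN_CYCLE_LEN = 10    # floor for the DA cycle length k


@dataclass
class DAConfig:
    """Settings for one DA run.

    ``k=None`` defers to the EM iteration count (floored at 10); the chain
    then runs N = m*k iterations total.
    """

    m: int = DEFAULT_M
    k: int | None = None
    seed: int | None = None
    ridge: float = 0.0          # optional ridge eps added to the posterior scale
    em_tol: float = 1e-6
    em_max_iter: int = 500

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError("m must be >= 2")
        if self.k is not None and self.k < 1:
            raise ValueError("k must be >= 1")


@dataclass
class ImputedStack:
    """m completed tables plus provenance."""

    datasets: list[MaskedTable]
    method: str                      # "mvni" | "fcs"
    coding: CodingMap | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(not d.is_complete() for d in self.datasets):
            raise ValueError("imputed datasets must have no missing cells")

    @property
    def m(self) -> int:
        return len(self.datasets)

    def __iter__(self):
        return iter(self.datasets)


def i_step(X, params: MVNParams, rng: np.random.Generator):
    """Draw missing cells from their conditional normal given observed cells."""
    if isinstance(X, pd.DataFrame):
        arr = X.to_numpy(dtype=float)
        wrap = lambda a: pd.DataFrame(a, columns=X.columns, index=X.index)
    else:
        arr = np.asarray(X, dtype=float)
        wrap = lambda a: a
    mask = np.isnan(arr)
    out = arr.copy()
    if not mask.any():
        return wrap(out)
    mu, S = params.mean, params.cov
    d = params.d
    ridge = 1e-10 * max(float(np.trace(S)) / d, 1.0)
    for pat, rows in _patterns(mask):
        m, o = pat, ~pat
        if not m.any():
            continue
        k = len(rows)
        nm = int(m.sum())
        if not o.any():
            C = S
            cond_mean = np.tile(mu, (k, 1))
        else:
            S_oo = S[np.ix_(o, o)]
            S_mo = S[np.ix_(m, o)]
            try:
                cho = linalg.cho_factor(S_oo, lower=True)
            except linalg.LinAlgError:
                warnings.warn("non-PSD observed block in I-step; ridge repair",
                              RuntimeWarning, stacklevel=2)
                cho = linalg.cho_factor(S_oo + ridge * np.eye(len(S_oo)),
                                        lower=True)
            dev_o = arr[np.ix_(rows, np.flatnonzero(o))] - mu[o]
            cond_mean = mu[m] + (S_mo @ linalg.cho_solve(cho, dev_o.T)).T
            C = S[np.ix_(m, m)] - S_mo @ linalg.cho_solve(cho, S_mo.T)
        C = (C + C.T) / 2.0
        try:
            L = np.linalg.cholesky(C)
        except np.linalg.LinAlgError:
            w, V = np.linalg.eigh(C)
            w = np.clip(w, 0.0, None)
            if w.max(initial=0.0) > 0 and w.min(initial=0.0) < 0:
                warnings.warn("non-PSD conditional covariance; ridge repair",
                              RuntimeWarning, stacklevel=2)
            L = V * np.sqrt(w)
        draws = cond_mean + rng.standard_normal((k, nm)) @ L.T
        out[np.ix_(rows, np.flatnonzero(m))] = draws
    return wrap(out)


def p_step(completed, rng: np.random.Generator, ridge: float = 0.0) -> MVNParams:
    """Posterior draw of (mu, Sigma) from a completed table (Jeffreys prior).

    Sigma ~ InvWishart(n-1, S) with S the centered cross-product matrix;
    mu | Sigma ~ N(xbar, Sigma/n).
    """
    arr = completed.to_numpy(dtype=float) if isinstance(completed, pd.DataFrame) \
        else np.asarray(completed, dtype=float)
    if np.isnan(arr).any():
        raise ValueError("p_step needs a completed (no-missing) table")
    n, d = arr.shape
    if n <= d:
        raise EMError(
            f"posterior draw needs n > d (n={n}, d={d}); consider a ridge prior"
        )
    xbar = arr.mean(axis=0)
    dev = arr - xbar
    S = dev.T @ dev
    if ridge > 0.0:
        S = S + ridge * np.diag(np.diag(S))
    S = _psd_repair(S, eps=1e-12)
    cov = stats.invwishart.rvs(df=n - 1, scale=S, random_state=rng)
    cov = np.atleast_2d(cov)
    cov = (cov + cov.T) / 2.0
    L = np.linalg.cholesky(_psd_repair(cov, eps=1e-12))
    mean = xbar + (L @ rng.standard_normal(d)) / np.sqrt(n)
    return MVNParams(mean, cov)


def impute_mvni(t: MaskedTable, interactions: list[InteractionTerm] = (),
                cfg: DAConfig | None = None) -> ImputedStack:
    """Full MVNI pipeline: code -> EM start values -> DA chain -> round -> decode.

    Runs the DA chain for N = m*k iterations, saving the completed dataset at
    the end of every k-th cycle; each saved numeric dataset is sensibly
    rounded back to category labels.
    """
    cfg = cfg or DAConfig()
    interactions = list(interactions)
    rng = np.random.default_rng(cfg.seed)
    numeric, cmap = code_for_mvni(t, interactions)
    em = em_fit(numeric, tol=cfg.em_tol, max_iter=cfg.em_max_iter)
    k = cfg.k if cfg.k is not None else max(em.n_iterations, MIN_CYCLE_LEN)
    params = em.params
    saved: list[MaskedTable] = []
    arr = numeric
    n_iter = cfg.m * k
    for it in range(1, n_iter + 1):
        completed = i_step(arr, params, rng)
        if it % k == 0:
            saved.append(sensible_round(completed, cmap, t.schema, interactions))
        params = p_step(completed, rng, ridge=cfg.ridge)
    prov = {
        "method": "mvni", "m": cfg.m, "k": k, "n_iterations": n_iter,
        "seed": cfg.seed, "em_iterations": em.n_iterations,
        "em_converged": em.converged,
    }
    return ImputedStack(saved, "mvni", cmap, prov)


class MVNImputer:
    """sklearn-style front end to :func:`impute_mvni`.

    ``fit`` runs the coding + EM stage on a :class:`MaskedTable`;
    ``transform`` runs the DA chain and returns an :class:`ImputedStack`.

    Attributes (after fit): ``em_result_``, ``coding_map_``, ``k_``.
    """

    def __init__(self, m: int = DEFAULT_M, k: int | None = None,
                 seed: int | None = None, interactions: tuple = (),
                 ridge: float = 0.0):
        self.m = m
        self.k = k
        self.seed = seed
        self.interactions = interactions
        self.ridge = ridge

    def get_params(self, deep: bool = True) -> dict:
        return {"m": self.m, "k": self.k, "seed": self.seed,
                "interactions": self.interactions, "ridge": self.ridge}

    def set_params(self, **params) -> "MVNImputer":
        for key, v in params.items():
            if key not in self.get_params():
                raise ValueError(f"invalid parameter {key!r}")
            setattr(self, key, v)
        return self

    def _config(self) -> DAConfig:
        return DAConfig(m=self.m, k=self.k, seed=self.seed, ridge=self.ridge)

    def fit(self, t: MaskedTable, y=None) -> "MVNImputer":
        numeric, cmap = code_for_mvni(t, list(self.interactions))
        self.em_result_ = em_fit(numeric)
        self.coding_map_ = cmap
        self.k_ = self.k if self.k is not None else max(
            self.em_result_.n_iterations, MIN_CYCLE_LEN)
        return self

    def transform(self, t: MaskedTable) -> ImputedStack:
        if not hasattr(self, "k_"):
            raise RuntimeError("MVNImputer is not fitted")
        cfg = DAConfig(m=self.m, k=self.k_, seed=self.seed, ridge=self.ridge)
        return impute_mvni(t, list(self.interactions), cfg)

    def fit_transform(self, t: MaskedTable, y=None) -> ImputedStack:
        return self.fit(t).transform(t)
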