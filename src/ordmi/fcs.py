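"""Fully conditional specification (chained equations) multiple imputation.

Each incomplete variable gets a conditional model of its own type regressed
on all other variables: linear regression for continuous targets, binary or
multinomial logistic regression for categorical targets. A sweep starts
from "place holder" fills (random draws from the observed marginal of each
variable), then cycles through the incomplete variables in order of
ascending missing count: reset the variable's originally-missing cells,
refit its conditional model on the observed cells, draw model parameters
from their approximate posterior (asymptotic normal for coefficients; the
linear-model residual variance from its scaled inverse chi-square), and
draw imputations from the resulting predictive distribution. Ten sweeps per
dataset is the default — the point at which the conditional-model
parameters have typically stabilized — and the whole process is repeated
independently for each of the m datasets.

The parameter draws are what make the imputations "proper": without them
the between-imputation variance component of Rubin's rules would be
understated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coding import InteractionTerm, code_for_fcs
from .mvni import ImputedStack
from .schema import Schema
from .table import MaskedTable

DEFAULT_N_ITER = 10
_MAX_ABS_COEF = 25.0   # separation guard on logistic coefficients


@dataclass
class FCSConfig:
    """Settings for one chained-equations run."""

    m: int = 20
    n_iter: int = DEFAULT_N_ITER
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError("m must be >= 2")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")


def init_fill(t: MaskedTable, rng: np.random.Generator) -> MaskedTable:
    """Place-holder fill: draws from each variable's observed marginal."""
    data = t.data.copy()
    for spec in t.schema:
        col = data[spec.name]
        miss = col.isna()
        if not miss.any():
            continue
        obs = col[~miss]
        if len(obs) == 0:
            raise ValueError(f"variable {spec.name!r} is fully missing")
        nmiss = int(miss.sum())
        if spec.is_categorical:
            cats, counts = np.unique(obs.astype(str).to_numpy(), return_counts=True)
            draws = rng.choice(cats, size=nmiss, p=counts / counts.sum())
            data.loc[miss, spec.name] = draws
        else:
            mu = float(obs.mean())
            sd = float(obs.std(ddof=1)) if len(obs) > 1 else 0.0
            if not np.isfinite(sd):
                sd = 0.0
            data.loc[miss, spec.name] = rng.normal(mu, sd, size=nmiss)
    return MaskedTable(t.schema, data)


def _design(schema: Schema, data: pd.DataFrame, exclude: str,
            also_exclude: set[str] = frozenset()) -> np.ndarray:
    """Intercept + all variables except ``exclude``; categoricals dummy-coded.

    ``also_exclude`` drops a variable's deterministic relatives (a derived
    interaction from its own factor's model and vice versa), which would
    otherwise guarantee perfect separation.
    """
    cols = [np.ones(len(data))]
    for spec in schema:
        if spec.name == exclude or spec.name in also_exclude:
            continue
        col = data[spec.name]
        if spec.is_categorical:
            for c in spec.categories:
                if c == spec.reference:
                    continue
                cols.append((col.astype(object) == c).astype(float).to_numpy())
        else:
            cols.append(col.to_numpy(dtype=float))
    return np.column_stack(cols)


def _draw_linear(y: np.ndarray, X: np.ndarray, Xmis: np.ndarray,
                 rng: np.random.Generator) -> np.ndarray:
    """Bayesian linear regression predictive draws (noninformative prior)."""
    n, p = X.shape
    if n <= p:
        raise np.linalg.LinAlgError("too few observed cases for linear model")
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df = n - rank
    rss = float(resid @ resid)
    sigma2 = rss / max(rng.chisquare(df), 1e-12) if rss > 0 else 0.0
    XtX_inv = np.linalg.pinv(X.T @ X)
    L = np.linalg.cholesky(
        (XtX_inv + XtX_inv.T) / 2.0 + 1e-12 * np.eye(p)
    )
    beta_draw = beta + np.sqrt(sigma2) * (L @ rng.standard_normal(p))
    mean = Xmis @ beta_draw
    return mean + np.sqrt(sigma2) * rng.standard_normal(len(Xmis))


def _draw_from_normal_posterior(params: np.ndarray, cov: np.ndarray,
                                rng: np.random.Generator) -> np.ndarray:
    cov = (cov + cov.T) / 2.0
    p = len(params)
    try:
        L = np.linalg.cholesky(cov + 1e-12 * np.eye(p))
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(cov)
        L = V * np.sqrt(np.clip(w, 0.0, None))
    return params + L @ rng.standard_normal(p)


def _draw_logistic(y_cat: np.ndarray, categories: list[str], X: np.ndarray,
                   Xmis: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Binary / multinomial logistic predictive draws; raises on failure so
    the caller can fall back to marginal draws."""
    import statsmodels.api as sm

    levels = [c for c in categories if c in set(y_cat)]
    if len(levels) < 2:
        # observed cells all one category: degenerate, predict that category
        return np.full(len(Xmis), levels[0] if levels else categories[0],
                       dtype=object)
    codes = np.array([levels.index(v) for v in y_cat])

    def _fit(model):
        # Newton is fast and surfaces separation; BFGS is the fallback
        try:
            res = model.fit(method="newton", maxiter=100, disp=False)
            if res.mle_retvals.get("converged", False):
                return res
        except Exception:
            pass
        res = model.fit(method="bfgs", maxiter=500, disp=False)
        if not res.mle_retvals.get("converged", False):
            raise np.linalg.LinAlgError("logistic fit did not converge")
        return res

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if len(levels) == 2:
            res = _fit(sm.Logit(codes, X))
            params = np.asarray(res.params, dtype=float)
            if np.max(np.abs(params)) > _MAX_ABS_COEF:
                raise np.linalg.LinAlgError("separation suspected")
            draw = _draw_from_normal_posterior(params, np.asarray(res.cov_params()),
                                               rng)
            p1 = 1.0 / (1.0 + np.exp(-(Xmis @ draw)))
            picks = (rng.random(len(Xmis)) < p1).astype(int)
        else:
            res = _fit(sm.MNLogit(codes, X))
            params = np.asarray(res.params, dtype=float)       # (p, J-1)
            if np.max(np.abs(params)) > _MAX_ABS_COEF:
                raise np.linalg.LinAlgError("separation suspected")
            flat = params.ravel(order="F")                     # equation-stacked
            draw = _draw_from_normal_posterior(
                flat, np.asarray(res.cov_params()), rng
            ).reshape(params.shape, order="F")
            eta = Xmis @ draw                                  # (nmis, J-1)
            expeta = np.exp(np.column_stack([np.zeros(len(Xmis)), eta]))
            probs = expeta / expeta.sum(axis=1, keepdims=True)
            u = rng.random(len(Xmis))
            picks = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
    return np.array([levels[j] for j in picks], dtype=object)


def fcs_iteration(current: MaskedTable, original_mask: pd.DataFrame,
                  rng: np.random.Generator, log: list | None = None,
                  exclusions: dict[str, set[str]] | None = None) -> MaskedTable:
    """One chained-equations sweep over the incomplete variables.

    ``exclusions`` maps a variable to predictors left out of its conditional
    model (its deterministic relatives from interaction coding).
    """
    if not current.is_complete():
        raise ValueError("fcs_iteration expects a completed (place-held) table")
    exclusions = exclusions or {}
    data = current.data.copy()
    schema = current.schema
    counts = original_mask.sum(axis=0)
    visit = [n for n in counts.sort_values(kind="stable").index if counts[n] > 0]
    for name in visit:
        spec = schema[name]
        miss = original_mask[name].to_numpy()
        obs = ~miss
        X = _design(schema, data, exclude=name,
                    also_exclude=exclusions.get(name, set()))
        Xobs, Xmis = X[obs], X[miss]
        if spec.is_categorical:
            y_cat = data.loc[obs, name].astype(str).to_numpy()
            try:
                draws = _draw_logistic(y_cat, list(spec.categories), Xobs, Xmis, rng)
            except Exception as exc:  # separation / non-convergence
                if log is not None:
                    log.append(f"{name}: logistic fallback ({exc})")
                cats, counts_ = np.unique(y_cat, return_counts=True)
                draws = rng.choice(cats, size=int(miss.sum()),
                                   p=counts_ / counts_.sum())
            data.loc[miss, name] = draws
        else:
            y = data.loc[obs, name].to_numpy(dtype=float)
            try:
                draws = _draw_linear(y, Xobs, Xmis, rng)
            except np.linalg.LinAlgError as exc:
                if log is not None:
                    log.append(f"{name}: linear fallback ({exc})")
                mu = float(np.mean(y))
                sd = float(np.std(y, ddof=1)) if len(y) > 1 else 0.0
                if not np.isfinite(sd):
                    sd = 0.0
                draws = rng.normal(mu, sd, size=int(miss.sum()))
            data.loc[miss, name] = draws
    return MaskedTable(schema, data)


def impute_fcs(t: MaskedTable, interactions: list[InteractionTerm] = (),
               cfg: FCSConfig | None = None) -> ImputedStack:
    """Full FCS pipeline: code interactions -> m independent chains -> stack."""
    cfg = cfg or FCSConfig()
    interactions = list(interactions)
    coded, cmap = code_for_fcs(t, interactions)
    mask = coded.mask
    # a derived interaction is a deterministic function of its factors:
    # keep each out of the other's conditional model
    exclusions: dict[str, set[str]] = {}
    for b in cmap.blocks:
        if not b.is_interaction:
            continue
        for f in b.factors:
            exclusions.setdefault(f, set()).update(b.columns)
            for col in b.columns:
                exclusions.setdefault(col, set()).update(b.factors)
    streams = np.random.SeedSequence(cfg.seed).spawn(cfg.m)
    datasets: list[MaskedTable] = []
    logs: list[list[str]] = []
    for ss in streams:
        rng = np.random.default_rng(ss)
        log: list[str] = []
        cur = init_fill(coded, rng)
        for _ in range(cfg.n_iter):
            cur = fcs_iteration(cur, mask, rng, log, exclusions)
        datasets.append(cur)
        logs.append(log)
    prov = {"method": "fcs", "m": cfg.m, "n_iter": cfg.n_iter,
            "seed": cfg.seed, "fallback_log": logs}
    return ImputedStack(datasets, "fcs", cmap, prov)


class FCSImputer:
    """sklearn-style front end to :func:`impute_fcs`."""

    def __init__(self, m: int = 20, n_iter: int = DEFAULT_N_ITER,
                 seed: int | None = None, interactions: tuple = ()):
        self.m = m
        self.n_iter = n_iter
        self.seed = seed
        self.interactions = interactions

    def get_params(self, deep: bool = True) -> dict:
        return {"m": self.m, "n_iter": self.n_iter, "seed": self.seed,
                "interactions": self.interactions}

    def set_params(self, **params) -> "FCSImputer":
        for key, v in params.items():
            if key not in self.get_params():
                raise ValueError(f"invalid parameter {key!r}")
            setattr(self, key, v)
        return self

    def fit(self, t: MaskedTable, y=None) -> "FCSImputer":
        coded, cmap = code_for_fcs(t, list(self.interactions))
        self.coding_map_ = cmap
        self.missing_counts_ = coded.mask.sum(axis=0)
        return self

    def transform(self, t: MaskedTable) -> ImputedStack:
        if not hasattr(self, "coding_map_"):
            raise RuntimeError("FCSImputer is not fitted")
        cfg = FCSConfig(m=self.m, n_iter=self.n_iter, seed=self.seed)
        return impute_fcs(t, list(self.interactions), cfg)

    def fit_transform(self, t: MaskedTable, y=None) -> ImputedStack:
        return self.fit(t).transform(t)
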