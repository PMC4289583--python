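"""Proportional-odds (cumulative logit) regression and likelihood-ratio tests.

The model for an ordinal outcome with levels 1..J is

    logit P(Y <= j | x) = theta_j - x' beta,   j = 1..J-1,

with strictly increasing thresholds theta and one coefficient vector beta
shared across thresholds. Fitting is maximum likelihood by L-BFGS-B on the
negative log-likelihood with analytic gradients, the threshold ordering
enforced through the reparameterization theta_j = a + sum_{l<=j} exp(d_l);
standard errors come from the inverse observed information (numerically
differentiated analytic score at the optimum). The design matrix uses
reference-omitted dummy coding, and interaction terms contribute one
product column per combination
of non-reference categories (so a k1 x k2 interaction adds
(k1-1)(k2-1) columns on top of the mains). When a completed table carries
an imputed joint interaction variable (transform-then-impute), the product
columns are read off that variable rather than recomputed from the factors.

Likelihood-ratio tests of nested fits drive the stepwise model development:
the test of a term compares the fit with and without the term's full dummy
block, which handles multi-column terms coherently.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .coding import InteractionTerm, _product_values
from .schema import SchemaError
from .table import MaskedTable

_SEPARATION_BOUND = 15.0


@dataclass
class ModelTerms:
    """Main effects and interaction terms of an analysis model."""

    main_effects: list[str] = field(default_factory=list)
    interactions: list[InteractionTerm] = field(default_factory=list)

    def copy(self) -> "ModelTerms":
        return ModelTerms(list(self.main_effects), list(self.interactions))

    @property
    def term_names(self) -> list[str]:
        return list(self.main_effects) + [t.name for t in self.interactions]

    def without(self, term_name: str) -> "ModelTerms":
        out = self.copy()
        if term_name in out.main_effects:
            out.main_effects.remove(term_name)
        else:
            out.interactions = [t for t in out.interactions if t.name != term_name]
        return out

    def with_interaction(self, term: InteractionTerm) -> "ModelTerms":
        out = self.copy()
        out.interactions.append(term)
        return out


@dataclass
class OrdinalFit:
    """A fitted proportional-odds model."""

    params: pd.Series            # per design-column estimate (EST)
    se: pd.Series                # per design-column standard error (SE)
    vcov: pd.DataFrame
    thresholds: np.ndarray       # J-1 strictly increasing cutpoints
    llf: float
    converged: bool
    n: int
    terms: ModelTerms
    term_columns: dict[str, list[str]] = field(default_factory=dict)
    flagged: bool = False        # non-convergence or suspected separation

    @property
    def p_values(self) -> pd.Series:
        """Wald per-coefficient two-sided p-values (normal reference)."""
        with np.errstate(divide="ignore", invalid="ignore"):
            z = self.params / self.se
        return pd.Series(2 * stats.norm.sf(np.abs(z)), index=self.params.index)

    def to_records(self) -> list[dict]:
        pv = self.p_values
        return [
            {"column": c, "EST": float(self.params[c]), "SE": float(self.se[c]),
             "p": float(pv[c])}
            for c in self.params.index
        ]


def _interaction_design(t: MaskedTable, term: InteractionTerm) -> pd.DataFrame:
    """Product columns for one interaction on a completed table.

    Prefers the table's imputed joint variable (transform-then-impute);
    falls back to products of the factor columns.
    """
    schema = t.schema
    if term.is_all_categorical(schema):
        non_ref = [
            [c for c in schema[f].categories if c != schema[f].reference]
            for f in term.factors
        ]
        names = {
            combo: ":".join(f"{f}={c}" for f, c in zip(term.factors, combo))
            for combo in itertools.product(*non_ref)
        }
        if term.name in schema:
            # labels of the derived joint variable are in row-major factor order
            spec = schema[term.name]
            combos = list(itertools.product(*(schema[f].categories
                                              for f in term.factors)))
            if len(spec.categories) != len(combos):
                raise SchemaError(
                    f"derived variable {term.name!r} does not match its factors"
                )
            lab_of = dict(zip(combos, spec.categories))
            joint = t.data[term.name].astype(object)
            cols = {
                names[combo]: (joint == lab_of[combo]).astype(float).to_numpy()
                for combo in names
            }
        else:
            cols = {}
            for combo in names:
                ind = np.ones(t.n_cases)
                for f, c in zip(term.factors, combo):
                    ind = ind * (t.data[f].astype(object) == c).astype(float).to_numpy()
                cols[names[combo]] = ind
        return pd.DataFrame(cols, index=t.data.index)
    # continuous-involving: derived product columns if carried, else recompute
    prods = _product_values(term, schema, t.data) if term.name not in schema else None
    if prods is None:
        prods = _product_values(term, schema, t.data)
    carried = [c for c in prods.columns if c in t.data.columns]
    if carried and len(carried) == len(prods.columns):
        return t.data[carried].astype(float)
    return prods


def build_design(t: MaskedTable, terms: ModelTerms
                 ) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Design matrix (no intercept) and the term -> columns bookkeeping."""
    schema = t.schema
    pieces: list[pd.DataFrame] = []
    term_cols: dict[str, list[str]] = {}
    for name in terms.main_effects:
        spec = schema[name]
        if spec.role == "outcome":
            raise SchemaError("outcome cannot be a main effect")
        if spec.is_categorical:
            cols = {
                f"{name}={c}": (t.data[name].astype(object) == c).astype(float)
                for c in spec.categories if c != spec.reference
            }
            df = pd.DataFrame(cols, index=t.data.index)
        else:
            df = t.data[[name]].astype(float)
        pieces.append(df)
        term_cols[name] = list(df.columns)
    for term in terms.interactions:
        df = _interaction_design(t, term)
        pieces.append(df)
        term_cols[term.name] = list(df.columns)
    if pieces:
        X = pd.concat(pieces, axis=1)
    else:
        X = pd.DataFrame(index=t.data.index)
    return X, term_cols


# ---------------------------------------------------------------------------
# proportional-odds maximum likelihood


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _unpack(params: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """(beta, thresholds) from the working parameter vector.

    Thresholds are theta_1 = a and theta_j = a + sum_{l<j} exp(d_l), which
    keeps them strictly increasing for any real working values.
    """
    beta = params[:k]
    a = params[k]
    gaps = np.exp(params[k + 1:])
    theta = a + np.concatenate([[0.0], np.cumsum(gaps)])
    return beta, theta


def _nll_grad(params: np.ndarray, X: np.ndarray, y: np.ndarray,
              n_levels: int) -> tuple[float, np.ndarray]:
    """Negative log-likelihood and its gradient in the working parameters."""
    n, k = X.shape
    beta, theta = _unpack(params, k)
    eta = X @ beta
    J1 = n_levels - 1
    upper_idx = y          # theta index for the upper bound, J1 means +inf
    lower_idx = y - 1      # theta index for the lower bound, -1 means -inf
    Fb = np.ones(n)
    fb = np.zeros(n)
    has_up = upper_idx < J1
    zb = theta[np.minimum(upper_idx, J1 - 1)] - eta
    Fb[has_up] = _sigmoid(zb[has_up])
    fb[has_up] = Fb[has_up] * (1.0 - Fb[has_up])
    Fa = np.zeros(n)
    fa = np.zeros(n)
    has_lo = lower_idx >= 0
    za = theta[np.maximum(lower_idx, 0)] - eta
    Fa[has_lo] = _sigmoid(za[has_lo])
    fa[has_lo] = Fa[has_lo] * (1.0 - Fa[has_lo])
    P = np.clip(Fb - Fa, 1e-300, None)
    nll = -float(np.sum(np.log(P)))
    # d ll / d eta and d ll / d theta_j
    dl_deta = -(fb - fa) / P
    grad_beta = -(X.T @ dl_deta)
    dl_dtheta = np.zeros(J1)
    wb = fb / P
    wa = fa / P
    np.add.at(dl_dtheta, np.minimum(upper_idx, J1 - 1), np.where(has_up, wb, 0.0))
    np.add.at(dl_dtheta, np.maximum(lower_idx, 0), -np.where(has_lo, wa, 0.0))
    # chain rule to (a, d): theta_j = a + sum_{l<j} exp(d_l)
    grad_a = -float(dl_dtheta.sum())
    grad_d = np.array([
        -np.sum(dl_dtheta[l:]) * np.exp(params[k + l])
        for l in range(1, J1)
    ]) if J1 > 1 else np.empty(0)
    # grad_d index l corresponds to gap l (theta_{l+1} onward)
    return nll, np.concatenate([grad_beta, [grad_a], grad_d])


def _score_unconstrained(beta: np.ndarray, theta: np.ndarray, X: np.ndarray,
                         y: np.ndarray, n_levels: int) -> np.ndarray:
    """Score of the log-likelihood in the natural (beta, theta) coordinates."""
    n, k = X.shape
    J1 = n_levels - 1
    eta = X @ beta
    Fb = np.ones(n); fb = np.zeros(n)
    has_up = y < J1
    zb = theta[np.minimum(y, J1 - 1)] - eta
    Fb[has_up] = _sigmoid(zb[has_up]); fb[has_up] = Fb[has_up] * (1 - Fb[has_up])
    Fa = np.zeros(n); fa = np.zeros(n)
    has_lo = y - 1 >= 0
    za = theta[np.maximum(y - 1, 0)] - eta
    Fa[has_lo] = _sigmoid(za[has_lo]); fa[has_lo] = Fa[has_lo] * (1 - Fa[has_lo])
    P = np.clip(Fb - Fa, 1e-300, None)
    dl_deta = -(fb - fa) / P
    g_beta = X.T @ dl_deta
    g_theta = np.zeros(J1)
    np.add.at(g_theta, np.minimum(y, J1 - 1), np.where(has_up, fb / P, 0.0))
    np.add.at(g_theta, np.maximum(y - 1, 0), -np.where(has_lo, fa / P, 0.0))
    return np.concatenate([g_beta, g_theta])


def _observed_information(beta: np.ndarray, theta: np.ndarray, X: np.ndarray,
                          y: np.ndarray, n_levels: int) -> np.ndarray:
    """Numerical derivative of the analytic score: the observed information."""
    p0 = np.concatenate([beta, theta])
    k = len(beta)
    m = len(p0)
    info = np.empty((m, m))
    h = 1e-5 * np.maximum(np.abs(p0), 1.0)
    for j in range(m):
        hi = p0.copy(); hi[j] += h[j]
        lo = p0.copy(); lo[j] -= h[j]
        s_hi = _score_unconstrained(hi[:k], hi[k:], X, y, n_levels)
        s_lo = _score_unconstrained(lo[:k], lo[k:], X, y, n_levels)
        info[:, j] = -(s_hi - s_lo) / (2.0 * h[j])
    return (info + info.T) / 2.0


def _fit_mle(X: np.ndarray, y: np.ndarray, n_levels: int,
             tol: float = 1e-8):
    """L-BFGS-B fit; returns (beta, theta, llf, vcov, converged)."""
    from scipy import optimize

    n, k = X.shape
    counts = np.bincount(y, minlength=n_levels).astype(float)
    props = np.clip(counts / counts.sum(), 1e-6, None)
    cum = np.clip(np.cumsum(props)[:-1], 1e-6, 1 - 1e-6)
    theta0 = np.log(cum / (1 - cum))
    gaps0 = np.clip(np.diff(theta0), 1e-3, None)
    x0 = np.concatenate([np.zeros(k), [theta0[0]], np.log(gaps0)])
    res = optimize.minimize(
        _nll_grad, x0, args=(X, y, n_levels), jac=True, method="L-BFGS-B",
        options={"maxiter": 500, "ftol": tol, "gtol": 1e-7},
    )
    beta, theta = _unpack(res.x, k)
    info = _observed_information(beta, theta, X, y, n_levels)
    try:
        vcov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        vcov = np.linalg.pinv(info)
    return beta, theta, -float(res.fun), vcov, bool(res.success)


def _intercept_only_fit(y_codes: np.ndarray, n_levels: int,
                        terms: ModelTerms, n: int) -> OrdinalFit:
    """Closed-form MLE with no covariates: thresholds are the cumulative logits."""
    counts = np.bincount(y_codes, minlength=n_levels).astype(float)
    props = counts / counts.sum()
    cum = np.cumsum(props)[:-1]
    thresholds = np.log(cum / (1 - cum))
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = float(np.sum(counts[counts > 0] * np.log(props[counts > 0])))
    empty = pd.Series(dtype=float)
    return OrdinalFit(empty, empty.copy(), pd.DataFrame(), thresholds, ll,
                      True, n, terms, {})


def fit_ordinal(t: MaskedTable, terms: ModelTerms) -> OrdinalFit:
    """ML fit of the proportional-odds model on a complete table."""
    schema = t.schema
    out_spec = schema.outcome
    if out_spec.n_categories < 3:
        raise SchemaError("ordinal regression needs an outcome with >= 3 levels")
    y_raw = t.data[out_spec.name]
    if y_raw.isna().any():
        raise SchemaError("outcome has missing cells")
    codes = np.array([out_spec.categories.index(v) for v in y_raw.astype(str)])
    X, term_cols = build_design(t, terms)
    if X.isna().to_numpy().any():
        raise SchemaError("design matrix has missing cells; complete the data first")
    # drop constant columns (absent categories) so the likelihood is identified
    keep = [c for c in X.columns if X[c].nunique() > 1]
    dropped = [c for c in X.columns if c not in keep]
    X = X[keep]
    term_cols = {k: [c for c in v if c in keep] for k, v in term_cols.items()}
    n = len(X)
    if X.shape[1] == 0:
        return _intercept_only_fit(codes, out_spec.n_categories, terms, n)
    k = X.shape[1]
    Xa = X.to_numpy(dtype=float)
    b, theta, llf, vcov_full, converged = _fit_mle(Xa, codes,
                                                   out_spec.n_categories)
    beta = pd.Series(b, index=X.columns)
    cov = vcov_full[:k, :k]
    se = pd.Series(np.sqrt(np.clip(np.diag(cov), 0.0, None)), index=X.columns)
    scale = X.std(ddof=0).replace(0.0, 1.0)
    flagged = (not converged) or bool(
        np.any(np.abs(beta.to_numpy() * scale.to_numpy()) > _SEPARATION_BOUND)
    )
    fit = OrdinalFit(beta, se, pd.DataFrame(cov, index=X.columns, columns=X.columns),
                     theta, llf, converged, n, terms, term_cols, flagged)
    fit.dropped_columns = dropped
    return fit


def lr_test(full: OrdinalFit, reduced: OrdinalFit) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested proportional-odds fits.

    Returns (statistic, df, p) with statistic = 2(llf_full - llf_reduced)
    and df the difference in design columns.
    """
    if full.n != reduced.n:
        raise ValueError("LR test requires fits on the same cases")
    full_cols = set(full.params.index)
    red_cols = set(reduced.params.index)
    if not red_cols <= full_cols:
        raise ValueError("reduced model is not nested in the full model")
    df = len(full_cols) - len(red_cols)
    stat = 2.0 * (full.llf - reduced.llf)
    if df == 0:
        return max(stat, 0.0), 0, 1.0
    stat = max(stat, 0.0)
    return stat, df, float(stats.chi2.sf(stat, df))


class OrdinalRegression:
    """sklearn-style proportional-odds classifier.

    Parameters: none beyond the link (logit, fixed). ``fit(X, y)`` takes a
    numeric design (array or DataFrame, no intercept) and an ordinal target
    given as integer codes 0..J-1.

    Attributes: ``coef_``, ``se_``, ``thresholds_``, ``llf_``, ``vcov_``,
    ``n_iter_`` (unused, kept for API symmetry), ``converged_``.
    """

    def __init__(self):
        pass

    def get_params(self, deep: bool = True) -> dict:
        return {}

    def set_params(self, **params) -> "OrdinalRegression":
        if params:
            raise ValueError(f"invalid parameters {sorted(params)}")
        return self

    def fit(self, X, y) -> "OrdinalRegression":
        Xdf = pd.DataFrame(X)
        y = np.asarray(y)
        if len(Xdf) != len(y):
            raise ValueError("X and y length mismatch")
        if Xdf.isna().to_numpy().any() or np.any(pd.isna(y)):
            raise ValueError("X and y must be complete")
        levels = np.unique(y)
        if len(levels) < 3:
            raise ValueError("ordinal target needs >= 3 observed levels")
        codes = np.searchsorted(levels, y)
        k = Xdf.shape[1]
        b, theta, llf, vcov_full, converged = _fit_mle(
            Xdf.to_numpy(dtype=float), codes, len(levels))
        self.classes_ = levels
        self.coef_ = b
        cov = vcov_full[:k, :k]
        self.se_ = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        self.vcov_ = cov
        self.thresholds_ = theta
        self.llf_ = llf
        self.converged_ = converged
        return self

    def predict_proba(self, X) -> np.ndarray:
        eta = np.asarray(pd.DataFrame(X), dtype=float) @ self.coef_
        cum = 1.0 / (1.0 + np.exp(-(self.thresholds_[None, :] - eta[:, None])))
        cum = np.column_stack([np.zeros(len(cum)), cum, np.ones(len(cum))])
        return np.diff(cum, axis=1)

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]
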