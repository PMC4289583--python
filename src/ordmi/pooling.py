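"""Rubin's rules for combining per-imputation fits, and post-imputation
diagnostics: observed-vs-imputed Kolmogorov-Smirnov comparisons, the
degrees-of-freedom stability reading, and the recommended number of
imputations as a function of the missing-information fraction.

Rubin's rules for m estimates Q_1..Q_m with squared standard errors U_i:

    Qbar = mean(Q_i)
    W    = mean(U_i)                     (within-imputation variance)
    B    = var(Q_i, ddof=1)              (between-imputation variance)
    T    = W + (1 + 1/m) B               (total variance)
    df   = (m - 1) (1 + W / ((1 + 1/m) B))^2

Inference is t-based on df; when B = 0 the df is infinite and inference is
normal. The df doubles as a diagnostic: a df large relative to m means the
between-imputation component is small — the pooled estimates have
stabilized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .mvni import ImputedStack
from .ordinal import OrdinalFit
from .table import MaskedTable


@dataclass
class PooledResult:
    """Per-coefficient Rubin-pooled estimates and inference."""

    table: pd.DataFrame   # columns: estimate, se, W, B, T, df, t, p, ci_low, ci_high
    m: int
    thresholds: np.ndarray | None = None

    def __getitem__(self, coef: str) -> pd.Series:
        return self.table.loc[coef]

    @property
    def coefficients(self) -> pd.Series:
        return self.table["estimate"]


def rubin_pool(fits: list[OrdinalFit], conf_level: float = 0.95) -> PooledResult:
    """Combine m proportional-odds fits on identical terms."""
    m = len(fits)
    if m < 2:
        raise ValueError("Rubin pooling needs m >= 2 fits "
                         "(between-imputation variance is undefined at m = 1)")
    cols = list(fits[0].params.index)
    for f in fits[1:]:
        if list(f.params.index) != cols:
            raise ValueError("fits have mismatched coefficient sets")
    est = np.vstack([f.params.to_numpy(dtype=float) for f in fits])
    ses = np.vstack([f.se.to_numpy(dtype=float) for f in fits])
    qbar = est.mean(axis=0)
    W = (ses ** 2).mean(axis=0)
    B = est.var(axis=0, ddof=1)
    T = W + (1.0 + 1.0 / m) * B
    with np.errstate(divide="ignore", invalid="ignore"):
        df = (m - 1) * (1.0 + W / ((1.0 + 1.0 / m) * B)) ** 2
    df = np.where(B <= 0.0, np.inf, df)
    se = np.sqrt(T)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, qbar / se, np.where(qbar == 0, 0.0, np.inf))
    p = np.empty_like(tstat)
    crit = np.empty_like(tstat)
    alpha = 1.0 - conf_level
    finite = np.isfinite(df)
    p[finite] = 2.0 * stats.t.sf(np.abs(tstat[finite]), df[finite])
    p[~finite] = 2.0 * stats.norm.sf(np.abs(tstat[~finite]))
    crit[finite] = stats.t.ppf(1.0 - alpha / 2.0, df[finite])
    crit[~finite] = stats.norm.ppf(1.0 - alpha / 2.0)
    table = pd.DataFrame(
        {"estimate": qbar, "se": se, "W": W, "B": B, "T": T, "df": df,
         "t": tstat, "p": p,
         "ci_low": qbar - crit * se, "ci_high": qbar + crit * se},
        index=cols,
    )
    thr = np.vstack([f.thresholds for f in fits]).mean(axis=0) \
        if all(len(f.thresholds) for f in fits) else None
    return PooledResult(table, m, thr)


@dataclass
class KSReport:
    """Two-sample KS comparisons of observed vs imputed cell distributions."""

    rows: list[dict] = field(default_factory=list)
    min_missing_pct: float = 8.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    @property
    def any_significant(self) -> bool:
        return any(r.get("p", 1.0) < 0.05 for r in self.rows if not r["skipped"])


def _numeric_codes(spec, values: pd.Series) -> np.ndarray:
    """Schema-order numeric coding for KS on categorical variables."""
    if spec.is_categorical:
        lookup = {c: i for i, c in enumerate(spec.categories)}
        return np.array([lookup[v] for v in values.astype(str)], dtype=float)
    return values.to_numpy(dtype=float)


def ks_compare(t: MaskedTable, stack: ImputedStack,
               min_missing_pct: float = 8.0) -> KSReport:
    """KS-test observed vs pooled imputed values for heavily missing variables.

    Every variable of the source table whose missing percentage exceeds
    ``min_missing_pct`` is compared: its observed cells against the pooled
    imputed cells across the m datasets.
    """
    report = KSReport(min_missing_pct=min_missing_pct)
    mask = t.mask
    for spec in t.schema:
        pct = 100.0 * float(mask[spec.name].mean())
        if pct <= min_missing_pct:
            continue
        observed = _numeric_codes(spec, t.data.loc[~mask[spec.name], spec.name])
        imputed_parts = [
            _numeric_codes(spec, d.data.loc[mask[spec.name].to_numpy(), spec.name])
            for d in stack
        ]
        imputed = np.concatenate(imputed_parts) if imputed_parts else np.array([])
        row = {"variable": spec.name, "pct_missing": pct,
               "n_observed": int(len(observed)), "n_imputed": int(len(imputed))}
        if len(imputed) < 2 or len(observed) < 2:
            row.update({"skipped": True, "D": np.nan, "p": np.nan})
        else:
            res = stats.ks_2samp(observed, imputed, method="asymp")
            row.update({"skipped": False, "D": float(res.statistic),
                        "p": float(res.pvalue)})
        report.rows.append(row)
    return report


def df_stability(pooled: PooledResult, m: int | None = None,
                 c: float = 3.0) -> pd.Series:
    """Flag coefficients whose Rubin df is large relative to m (df >= c*m).

    A large df means the within/between variance ratio is high — the pooled
    estimates have stabilized and can be trusted.
    """
    m = pooled.m if m is None else m
    df = pooled.table["df"]
    return (df >= c * m) | ~np.isfinite(df)


class RecommendedM(int):
    """An imputation count; ``open_ended`` marks the '>100' top band."""

    def __new__(cls, value: int, open_ended: bool = False):
        obj = super().__new__(cls, value)
        obj.open_ended = open_ended
        return obj


#: upper band edges and the recommended m for each (step-function lookup)
M_BANDS = ((0.1, 20), (0.3, 20), (0.5, 40), (0.7, 100))


def recommended_m(missing_fraction: float) -> RecommendedM:
    """Recommended number of imputations for a missing-information fraction.

    Step-function lookup over the published bands: up to 0.1 -> 20, up to
    0.3 -> 20, up to 0.5 -> 40, up to 0.7 -> 100, beyond 0.7 -> more than
    100 (returned as 100 with ``open_ended=True``).
    """
    f = float(missing_fraction)
    if not (0.0 <= f < 1.0):
        raise ValueError(f"missing fraction must be in [0, 1), got {f}")
    for edge, m in M_BANDS:
        if f <= edge:
            return RecommendedM(m)
    return RecommendedM(100, open_ended=True)
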