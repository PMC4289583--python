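"""Missingness summaries and MAR-plausibility screening.

`summarize_missingness` gives the cell-, case- and variable-level
missingness percentages and classifies the pattern (none / monotone /
nonmonotone). `screen_mar` runs, for every incomplete variable, chi-square
tests of (a) the variable's observed values against each other variable and
(b) an indicator of its missingness against each other variable — evidence
that missingness depends on observed data, which makes the
missing-at-random assumption plausible and tells the analyst which
variables the imputation model should carry. Continuous partners are
quartile-binned so a single test family covers all pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .table import MaskedTable


@dataclass
class MissingnessSummary:
    n_cases: int
    n_vars: int
    n_missing_cells: int
    overall_pct: float
    per_variable_pct: pd.Series
    n_incomplete_cases: int
    pct_incomplete_cases: float
    n_vars_with_missing: int
    pct_vars_with_missing: float
    pattern: str   # none | monotone | nonmonotone

    def to_dict(self) -> dict:
        return {
            "n_cases": self.n_cases, "n_vars": self.n_vars,
            "n_missing_cells": self.n_missing_cells,
            "overall_pct": self.overall_pct,
            "per_variable_pct": {k: float(v)
                                 for k, v in self.per_variable_pct.items()},
            "n_incomplete_cases": self.n_incomplete_cases,
            "pct_incomplete_cases": self.pct_incomplete_cases,
            "n_vars_with_missing": self.n_vars_with_missing,
            "pct_vars_with_missing": self.pct_vars_with_missing,
            "pattern": self.pattern,
        }


def _pattern(mask: np.ndarray) -> str:
    """Classify the missingness pattern of a boolean mask (True = missing).

    Monotone means the columns can be ordered so that a case missing on one
    column is missing on every later column — i.e. the per-column missing
    sets are nested. Ordering columns by ascending missing count, the mask
    is monotone iff each column's missing set is contained in the next.
    """
    if not mask.any():
        return "none"
    counts = mask.sum(axis=0)
    order = np.argsort(counts, kind="stable")
    cols = [mask[:, j] for j in order if counts[j] > 0]
    for a, b in zip(cols[:-1], cols[1:]):
        if np.any(a & ~b):
            return "nonmonotone"
    return "monotone"


def summarize_missingness(t: MaskedTable) -> MissingnessSummary:
    """Exact counts and percentages of missingness; pattern classification."""
    if t.n_cases == 0:
        raise ValueError("empty table")
    mask = t.mask.to_numpy()
    n, d = mask.shape
    n_missing = int(mask.sum())
    per_var = pd.Series(100.0 * mask.mean(axis=0), index=t.schema.names)
    n_inc = int(mask.any(axis=1).sum())
    n_vars_missing = int((mask.any(axis=0)).sum())
    return MissingnessSummary(
        n_cases=n, n_vars=d, n_missing_cells=n_missing,
        overall_pct=100.0 * n_missing / (n * d),
        per_variable_pct=per_var,
        n_incomplete_cases=n_inc,
        pct_incomplete_cases=100.0 * n_inc / n,
        n_vars_with_missing=n_vars_missing,
        pct_vars_with_missing=100.0 * n_vars_missing / d,
        pattern=_pattern(mask),
    )


@dataclass
class MarScreenResult:
    """Chi-square screening of incomplete variables and their missingness."""

    rows: list[dict] = field(default_factory=list)
    alpha: float = 0.05
    #: per incomplete variable: is its *missingness* associated with the outcome?
    missingness_related_to_outcome: dict[str, bool] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def screened_variables(self) -> list[str]:
        return sorted({r["variable"] for r in self.rows})


def _binned(values: pd.Series, is_categorical: bool) -> pd.Series:
    """Quartile-bin continuous values; pass categorical labels through."""
    if is_categorical:
        return values.astype(str)
    try:
        return pd.qcut(values.astype(float), 4, duplicates="drop").astype(str)
    except ValueError:
        return values.astype(float).round(12).astype(str)


def _chi2_row(x: pd.Series, y: pd.Series) -> dict:
    tab = pd.crosstab(x, y)
    tab = tab.loc[(tab.sum(axis=1) > 0), (tab.sum(axis=0) > 0)]
    if tab.shape[0] < 2 or tab.shape[1] < 2:
        return {"p": np.nan, "stat": np.nan, "df": 0, "valid": False,
                "skipped": True, "note": "degenerate table"}
    res = stats.chi2_contingency(tab.to_numpy())
    exp = res.expected_freq
    low_exp = float((exp < 5).mean())
    valid = low_exp <= 0.20
    return {"p": float(res.pvalue), "stat": float(res.statistic),
            "df": int(res.dof), "valid": valid, "skipped": False,
            "note": "" if valid else f"{100 * low_exp:.0f}% of expected counts < 5"}


def screen_mar(t: MaskedTable, alpha: float = 0.05) -> MarScreenResult:
    """Chi-square screening of every incomplete variable.

    For each variable V with missing cells, and each other variable W:

    * ``kind="value"`` — observed V vs observed W on complete pairs
      (is V related to W?);
    * ``kind="missingness"`` — indicator(V missing) vs observed W
      (is V's missingness related to W?).

    Tests whose expected cell counts are too small are flagged invalid
    rather than silently dropped. Completely observed variables are not
    screened (they appear only as partners).
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    if t.n_vars < 2:
        raise ValueError("screening needs at least 2 variables")
    mask = t.mask
    result = MarScreenResult(alpha=alpha)
    outcome = t.schema.outcome.name
    incomplete = [s for s in t.schema if mask[s.name].any()]
    for spec in incomplete:
        v_missing = mask[spec.name]
        for other in t.schema:
            if other.name == spec.name:
                continue
            w_obs = ~mask[other.name]
            # value association on complete pairs
            both = w_obs & ~v_missing
            if both.sum() > 0:
                row = _chi2_row(
                    _binned(t.data.loc[both, spec.name], spec.is_categorical),
                    _binned(t.data.loc[both, other.name], other.is_categorical),
                )
            else:
                row = {"p": np.nan, "stat": np.nan, "df": 0, "valid": False,
                       "skipped": True, "note": "no complete pairs"}
            row.update({"variable": spec.name, "partner": other.name,
                        "kind": "value"})
            result.rows.append(row)
            # missingness association against observed partner values
            sub = w_obs
            row = _chi2_row(
                v_missing[sub].map({True: "missing", False: "observed"}),
                _binned(t.data.loc[sub, other.name], other.is_categorical),
            )
            row.update({"variable": spec.name, "partner": other.name,
                        "kind": "missingness"})
            result.rows.append(row)
            if other.name == outcome:
                result.missingness_related_to_outcome[spec.name] = (
                    not row["skipped"] and row["p"] < alpha
                )
    return result
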