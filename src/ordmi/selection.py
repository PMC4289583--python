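"""Three-stage model development and its two combinations with multiple
imputation.

The development process: (1) all schema predictors enter as main effects;
(2) candidate two-way interactions are added one at a time, each step
adding the candidate whose likelihood-ratio test against the current model
is most significant, while it clears the entry threshold (default 0.05);
(3) backward elimination removes, one at a time, the term with the least
significant LR test while it exceeds the stopping threshold (default 0.10).
Main effects that parent a retained interaction are never removable
(model hierarchy).

Strategy 1 runs all three stages on the single EM-completed dataset, feeds
the identified interactions into the imputation model, imputes m datasets,
fits each, and pools with Rubin's rules. Strategy 2 stops the single-set
development after stage 2, imputes, then applies backward elimination to
each imputed dataset separately; terms retained in at least a fraction tau
(default 50%) of the datasets make the final model, which is refit on every
dataset and pooled. When nothing meets the tally criterion the threshold is
relaxed in steps of 0.1 down to a floor of 0.2.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

from .coding import InteractionTerm, code_for_mvni, sensible_round
from .em import EMResult, em_complete, em_fit
from .fcs import FCSConfig, impute_fcs
from .mvni import DAConfig, ImputedStack, impute_mvni
from .ordinal import ModelTerms, OrdinalFit, fit_ordinal, lr_test
from .pooling import PooledResult, rubin_pool
from .table import MaskedTable

ALPHA_IN = 0.05
ALPHA_OUT = 0.10
TAU = 0.5
TAU_FLOOR = 0.2


@dataclass
class Step:
    action: str          # "add" | "remove"
    term: str
    statistic: float
    df: int
    p: float


@dataclass
class DevelopmentTrace:
    steps: list[Step] = field(default_factory=list)
    final: ModelTerms | None = None
    skipped: list[str] = field(default_factory=list)

    def to_dicts(self) -> list[dict]:
        return [s.__dict__ for s in self.steps]


@dataclass
class SelectionTally:
    """Per-term retention counts across the m per-dataset eliminations."""

    counts: dict[str, int]
    m: int
    tau: float
    tau_used: float
    selected: list[str]

    def fraction(self, term: str) -> float:
        return self.counts.get(term, 0) / self.m


def default_candidates(schema, mains: list[str]) -> list[InteractionTerm]:
    """All two-way interactions among the main effects."""
    return [InteractionTerm((a, b)) for a, b in itertools.combinations(mains, 2)]


def _safe_fit(t: MaskedTable, terms: ModelTerms) -> OrdinalFit | None:
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_ordinal(t, terms)
        return None if fit.flagged else fit
    except Exception:
        return None


def forward_interactions(t: MaskedTable, mains, candidates=None,
                         alpha_in: float = ALPHA_IN) -> DevelopmentTrace:
    """Stepwise forward selection of interaction terms on a complete table.

    At each round every remaining candidate is tested (LR against the
    current model); the candidate with the smallest p enters if
    p < ``alpha_in``. Ties break by larger LR statistic, then by term name.
    """
    if isinstance(mains, ModelTerms):
        current = mains.copy()
    else:
        current = ModelTerms(list(mains), [])
    if candidates is None:
        candidates = default_candidates(t.schema, current.main_effects)
    remaining = list(candidates)
    trace = DevelopmentTrace()
    base = _safe_fit(t, current)
    if base is None:
        raise RuntimeError("base model (main effects) failed to fit")
    while remaining:
        results = []
        for cand in remaining:
            fit = _safe_fit(t, current.with_interaction(cand))
            if fit is None:
                trace.skipped.append(cand.name)
                continue
            stat, df, p = lr_test(fit, base)
            if df == 0:
                continue
            results.append((p, -stat, cand.name, cand, fit, stat, df))
        if not results:
            break
        results.sort(key=lambda r: (r[0], r[1], r[2]))
        p, _, name, cand, fit, stat, df = results[0]
        if p >= alpha_in:
            break
        current = current.with_interaction(cand)
        base = fit
        remaining = [c for c in remaining if c.name != name]
        trace.steps.append(Step("add", name, stat, df, p))
    trace.final = current
    return trace


def _removable(terms: ModelTerms) -> list[str]:
    parents = {f for t in terms.interactions for f in t.factors}
    names = [t.name for t in terms.interactions]
    names += [m for m in terms.main_effects if m not in parents]
    return names


def backward_eliminate(t: MaskedTable, terms: ModelTerms,
                       alpha_out: float = ALPHA_OUT) -> DevelopmentTrace:
    """Backward elimination on a complete table, honouring model hierarchy."""
    current = terms.copy()
    trace = DevelopmentTrace()
    full = _safe_fit(t, current)
    if full is None:
        raise RuntimeError("full model failed to fit")
    while True:
        worst = None
        for name in _removable(current):
            reduced_terms = current.without(name)
            fit = _safe_fit(t, reduced_terms)
            if fit is None:
                trace.skipped.append(name)
                continue
            stat, df, p = lr_test(full, fit)
            if df == 0:
                continue
            key = (-p, stat, name)
            if worst is None or key < worst[0]:
                worst = (key, name, reduced_terms, fit, stat, df, p)
        if worst is None:
            break
        _, name, reduced_terms, fit, stat, df, p = worst
        if p <= alpha_out:
            break
        current = reduced_terms
        full = fit
        trace.steps.append(Step("remove", name, stat, df, p))
    trace.final = current
    return trace


# ---------------------------------------------------------------------------
# strategies


def em_completed_dataset(t: MaskedTable, tol: float = 1e-6,
                         max_iter: int = 500) -> tuple[MaskedTable, EMResult]:
    """The single EM-completed dataset used for model development."""
    numeric, cmap = code_for_mvni(t, [])
    em = em_fit(numeric, tol=tol, max_iter=max_iter)
    completed = em_complete(numeric, em.params)
    return sensible_round(completed, cmap, t.schema, []), em


def _impute(t: MaskedTable, interactions, method: str, m: int,
            seed) -> ImputedStack:
    if method == "mvni":
        return impute_mvni(t, interactions, DAConfig(m=m, seed=seed))
    if method == "fcs":
        return impute_fcs(t, interactions, FCSConfig(m=m, seed=seed))
    raise ValueError(f"unknown imputation method {method!r}")


@dataclass
class StrategyResult:
    terms: ModelTerms
    stack: ImputedStack
    pooled: PooledResult
    forward_trace: DevelopmentTrace
    backward_trace: DevelopmentTrace | None = None
    tally: SelectionTally | None = None
    em_result: EMResult | None = None


def strategy1(t: MaskedTable, method: str = "mvni", m: int = 20,
              seed=None, candidates=None, alpha_in: float = ALPHA_IN,
              alpha_out: float = ALPHA_OUT) -> StrategyResult:
    """Full development on the EM-completed set, then impute, fit and pool."""
    t.validate(require_complete_outcome=True)
    t0, em = em_completed_dataset(t)
    mains = [v.name for v in t.schema.predictors]
    fwd = forward_interactions(t0, mains, candidates, alpha_in)
    bwd = backward_eliminate(t0, fwd.final, alpha_out)
    final = bwd.final
    stack = _impute(t, final.interactions, method, m, seed)
    fits = [fit_ordinal(d, final) for d in stack]
    pooled = rubin_pool(fits)
    return StrategyResult(final, stack, pooled, fwd, bwd, em_result=em)


def strategy2(t: MaskedTable, method: str = "mvni", m: int = 20,
              seed=None, candidates=None, alpha_in: float = ALPHA_IN,
              alpha_out: float = ALPHA_OUT, tau: float = TAU) -> StrategyResult:
    """Stages 1-2 on the EM set; per-imputation backward elimination; tally."""
    if not (0.0 < tau <= 1.0):
        raise ValueError("tau must be in (0, 1]")
    t.validate(require_complete_outcome=True)
    t0, em = em_completed_dataset(t)
    mains = [v.name for v in t.schema.predictors]
    fwd = forward_interactions(t0, mains, candidates, alpha_in)
    stage2 = fwd.final
    stack = _impute(t, stage2.interactions, method, m, seed)
    counts: dict[str, int] = {name: 0 for name in stage2.term_names}
    for d in stack:
        bwd = backward_eliminate(d, stage2, alpha_out)
        for name in bwd.final.term_names:
            counts[name] = counts.get(name, 0) + 1
    m_eff = stack.m
    tau_used = tau
    selected: list[str] = []
    while True:
        selected = [n for n in stage2.term_names
                    if counts.get(n, 0) / m_eff >= tau_used]
        if selected or tau_used <= TAU_FLOOR:
            break
        tau_used = round(tau_used - 0.1, 10)
        warnings.warn(
            f"no term met the {tau_used + 0.1:.0%} tally; relaxing to "
            f"{tau_used:.0%}", RuntimeWarning, stacklevel=2)
    sel_set = set(selected)
    final_inter = [it for it in stage2.interactions if it.name in sel_set]
    # hierarchy: parents of selected interactions stay in the model
    parents = {f for it in final_inter for f in it.factors}
    final_mains = [n for n in stage2.main_effects
                   if n in sel_set or n in parents]
    final = ModelTerms(final_mains, final_inter)
    tally = SelectionTally(counts, m_eff, tau, tau_used, selected)
    fits = [fit_ordinal(d, final) for d in stack]
    pooled = rubin_pool(fits)
    return StrategyResult(final, stack, pooled, fwd, None, tally, em)


def complete_case_analysis(t: MaskedTable, terms: ModelTerms,
                           alpha_out: float = ALPHA_OUT,
                           eliminate: bool = True):
    """Fit (optionally after backward elimination) on the complete cases only."""
    keep = ~t.mask.any(axis=1)
    cc = MaskedTable(t.schema, t.data.loc[keep].reset_index(drop=True))
    if eliminate:
        bwd = backward_eliminate(cc, terms, alpha_out)
        return fit_ordinal(cc, bwd.final), bwd
    return fit_ordinal(cc, terms), None
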