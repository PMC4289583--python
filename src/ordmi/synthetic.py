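"""Synthetic data with the study's structure: a mostly categorical
case-by-variable table, a 3-level ordinal outcome generated from a known
proportional-odds model, and controllable MCAR/MAR/MNAR missingness with
per-variable target rates.

The default design mirrors the asthma-severity questionnaire data the
package is built around: 382 cases, 21 categorical predictors and one
continuous (age), fully observed age/gender/area and outcome, per-variable
missingness from 0 to 19.4%, and a nonmonotone realized pattern (each
variable's mask is drawn independently). Predictor dependence is induced
through a Gaussian copula over latent scores thresholded to categories, so
pairwise association is controllable without a bespoke categorical model.
Two interactions carry true nonzero coefficients, giving the
forward-selection stage a known answer.

Under MAR, each incomplete variable's missingness probability is a logistic
function of fully observed variables; the intercept is calibrated (on the
realized sample) so the expected missing rate hits the target. MNAR adds
the cell's own (standardized) value to that score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .schema import Schema, SchemaError, VariableSpec
from .table import MaskedTable


@dataclass
class SimulationDesign:
    """Everything needed to generate and then ampute one synthetic dataset."""

    n: int
    schema: Schema
    #: categorical: category probabilities (schema order); continuous: (loc, scale)
    marginals: dict[str, tuple]
    #: proportional-odds coefficients keyed by design column, e.g.
    #: "fear=yes", "age", "fear=yes:breakfast=daily"
    true_coefficients: dict[str, float]
    thresholds: tuple[float, ...]
    #: per-variable target missing rate in [0, 1)
    missing_rates: dict[str, float] = field(default_factory=dict)
    #: MAR dependence map: variable -> {driver variable: logistic weight}
    mar_drivers: dict[str, dict[str, float]] = field(default_factory=dict)
    mechanism: str = "MAR"           # MCAR | MAR | MNAR
    mnar_weight: float = 1.0
    copula_corr: float = 0.15

    def __post_init__(self) -> None:
        if self.mechanism not in ("MCAR", "MAR", "MNAR"):
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        thr = np.asarray(self.thresholds, dtype=float)
        if np.any(np.diff(thr) <= 0):
            raise ValueError("thresholds must be strictly increasing")
        out = self.schema.outcome
        if len(thr) != out.n_categories - 1:
            raise ValueError("need J-1 thresholds for a J-level outcome")
        for name, rate in self.missing_rates.items():
            if not (0.0 <= rate < 1.0):
                raise ValueError(f"{name}: rate must be in [0, 1)")
            if self.schema[name].role == "outcome" and rate > 0:
                raise ValueError("the outcome is never amputed")
        if self.mechanism == "MAR":
            for name, drivers in self.mar_drivers.items():
                for drv in drivers:
                    if self.missing_rates.get(drv, 0.0) > 0:
                        raise SchemaError(
                            f"MAR driver {drv!r} of {name!r} is itself incomplete"
                        )

    @property
    def protected(self) -> list[str]:
        """Variables never amputed: the outcome and everything with rate 0."""
        return [v.name for v in self.schema
                if v.role == "outcome" or self.missing_rates.get(v.name, 0.0) == 0.0]


def _standardized(design: SimulationDesign, data: pd.DataFrame,
                  name: str) -> np.ndarray:
    """Numeric z-score-ish coding of one column, for logistic missingness scores."""
    spec = design.schema[name]
    if spec.is_categorical:
        codes = np.array([spec.categories.index(v)
                          for v in data[name].astype(str)], dtype=float)
    else:
        codes = data[name].to_numpy(dtype=float)
    sd = codes.std()
    return (codes - codes.mean()) / (sd if sd > 0 else 1.0)


def _column_term(design: SimulationDesign, data: pd.DataFrame,
                 key: str) -> np.ndarray:
    """Evaluate one true-coefficient design column on generated data."""
    vals = np.ones(len(data))
    for piece in key.split(":"):
        if "=" in piece:
            var, cat = piece.split("=", 1)
            spec = design.schema[var]
            if cat not in spec.categories:
                raise SchemaError(f"coefficient key {key!r}: {cat!r} not a "
                                  f"category of {var!r}")
            vals = vals * (data[var].astype(str) == cat).to_numpy(dtype=float)
        else:
            loc, scale = design.marginals[piece]
            vals = vals * (data[piece].to_numpy(dtype=float) - loc) / scale
    return vals


def generate_complete(design: SimulationDesign,
                      rng: np.random.Generator | int | None = None) -> MaskedTable:
    """Draw one complete dataset from the design's generating model."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) \
        else rng
    preds = [v for v in design.schema if v.role != "outcome"]
    d = len(preds)
    rho = design.copula_corr
    # equicorrelated Gaussian copula: z = sqrt(rho)*common + sqrt(1-rho)*own
    common = rng.standard_normal(design.n)
    z = (np.sqrt(rho) * common[:, None]
         + np.sqrt(1.0 - rho) * rng.standard_normal((design.n, d)))
    data: dict[str, object] = {}
    for j, spec in enumerate(preds):
        marg = design.marginals[spec.name]
        if spec.is_categorical:
            probs = np.asarray(marg, dtype=float)
            if len(probs) != spec.n_categories or not np.isclose(probs.sum(), 1.0):
                raise ValueError(f"{spec.name}: bad marginal probabilities")
            cuts = stats.norm.ppf(np.cumsum(probs)[:-1])
            idx = np.searchsorted(cuts, z[:, j], side="left")
            data[spec.name] = np.array(spec.categories, dtype=object)[idx]
        else:
            loc, scale = marg
            data[spec.name] = loc + scale * z[:, j]
    df = pd.DataFrame(data)
    lp = np.zeros(design.n)
    for key, coef in design.true_coefficients.items():
        lp += coef * _column_term(design, df, key)
    ystar = lp + rng.logistic(size=design.n)
    levels = np.sum(ystar[:, None] > np.asarray(design.thresholds)[None, :], axis=1)
    out_spec = design.schema.outcome
    df[out_spec.name] = np.array(out_spec.categories, dtype=object)[levels]
    return MaskedTable(design.schema, df)


def _calibrate_intercept(score: np.ndarray, rate: float) -> float:
    """Intercept b0 such that mean(sigmoid(b0 + score)) equals the target."""
    def gap(b0):
        return float(np.mean(1.0 / (1.0 + np.exp(-(b0 + score))))) - rate

    lo, hi = -40.0, 40.0
    lo_rate, hi_rate = gap(lo) + rate, gap(hi) + rate
    if not (lo_rate <= rate <= hi_rate):
        raise ValueError(
            f"target rate {rate} unreachable; achievable range "
            f"[{lo_rate:.4f}, {hi_rate:.4f}] under this dependence map"
        )
    return float(optimize.brentq(gap, lo, hi))


def ampute(t: MaskedTable, design: SimulationDesign,
           rng: np.random.Generator | int | None = None) -> MaskedTable:
    """Delete cells per the design's mechanism and per-variable target rates.

    Per-variable masks are drawn independently, so the realized pattern is
    nonmonotone by construction. Protected variables (rate 0, and always
    the outcome) are untouched.
    """
    if not t.is_complete():
        raise ValueError("ampute expects a complete table")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) \
        else rng
    data = t.data.copy()
    protected = set(design.protected)
    for spec in t.schema:
        rate = design.missing_rates.get(spec.name, 0.0)
        if rate == 0.0 or spec.name in protected:
            continue
        if design.mechanism == "MCAR":
            mask = rng.random(t.n_cases) < rate
        else:
            drivers = design.mar_drivers.get(spec.name, {})
            score = np.zeros(t.n_cases)
            for drv, w in drivers.items():
                score += w * _standardized(design, t.data, drv)
            if design.mechanism == "MNAR":
                score += design.mnar_weight * _standardized(design, t.data,
                                                            spec.name)
            b0 = _calibrate_intercept(score, rate)
            mask = rng.random(t.n_cases) < 1.0 / (1.0 + np.exp(-(b0 + score)))
        data.loc[mask, spec.name] = np.nan
    return MaskedTable(t.schema, data)


# ---------------------------------------------------------------------------
# the default design: the study's structure


def default_schema() -> Schema:
    """22 variables: 1 continuous, 21 categorical, 3-level ordinal outcome."""
    b = lambda name: VariableSpec(name, "binary", ("no", "yes"), "no")
    return Schema([
        VariableSpec("gender", "binary", ("male", "female"), "male"),
        b("neonatal_care"),
        VariableSpec("birth_weight", "nominal",
                     ("up to 2.5 kg", "over 2.5 kg", "don't know"),
                     "over 2.5 kg"),
        b("fear"),
        b("smoked_pregnant"),
        b("smokers_home"),
        b("smoke_vehicle"),
        VariableSpec("exercise", "ordinal",
                     ("up to once a week", "2-4 times a week",
                      "over 4 times a week"), "over 4 times a week"),
        VariableSpec("tv", "ordinal",
                     ("up to an hour", "1-3 hours", "over 3 hours"),
                     "over 3 hours"),
        VariableSpec("people_home", "ordinal", ("1-4", "5-7", "8 plus"), "8 plus"),
        VariableSpec("income", "ordinal",
                     ("up to R1000", "R1001-R4500", "R4501-R10000",
                      "R10001 plus"), "R10001 plus"),
        VariableSpec("food", "binary", ("enough", "not always enough"), "enough"),
        VariableSpec("perceived_weight", "nominal",
                     ("overweight", "underweight", "correct weight"),
                     "correct weight"),
        b("work_wear"),
        b("pets"),
        VariableSpec("area", "binary", ("North Durban", "South Durban"),
                     "North Durban"),
        VariableSpec("breakfast", "binary", ("daily", "not daily"), "daily"),
        b("violence"),
        b("weapons"),
        VariableSpec("stove", "nominal", ("paraffin", "gas", "electric", "none"),
                     "none"),
        VariableSpec("age", "continuous"),
        VariableSpec("severity", "ordinal",
                     ("none/mild intermittent", "mild persistent",
                      "moderate/severe"),
                     role="outcome"),
    ])


#: per-variable target missing rates matching the study's Table of variables
DEFAULT_MISSING_RATES = {
    "gender": 0.0, "neonatal_care": 0.037, "birth_weight": 0.010,
    "fear": 0.065, "smoked_pregnant": 0.050, "smokers_home": 0.003,
    "smoke_vehicle": 0.076, "exercise": 0.063, "tv": 0.065,
    "people_home": 0.092, "income": 0.194, "food": 0.084,
    "perceived_weight": 0.068, "work_wear": 0.037, "pets": 0.010,
    "area": 0.0, "breakfast": 0.065, "violence": 0.073, "weapons": 0.073,
    "stove": 0.099, "age": 0.0, "severity": 0.0,
}


def default_design(n: int = 382, mechanism: str = "MAR",
                   missing_rates: dict | None = None) -> SimulationDesign:
    """The package's reference simulation: study-scale data, two true
    interactions, MAR missingness driven by the fully observed variables."""
    schema = default_schema()
    marginals = {
        "gender": (0.52, 0.48),
        "neonatal_care": (0.80, 0.20),
        "birth_weight": (0.15, 0.75, 0.10),
        "fear": (0.60, 0.40),
        "smoked_pregnant": (0.90, 0.10),
        "smokers_home": (0.55, 0.45),
        "smoke_vehicle": (0.75, 0.25),
        "exercise": (0.35, 0.40, 0.25),
        "tv": (0.25, 0.45, 0.30),
        "people_home": (0.40, 0.40, 0.20),
        "income": (0.30, 0.35, 0.20, 0.15),
        "food": (0.70, 0.30),
        "perceived_weight": (0.15, 0.20, 0.65),
        "work_wear": (0.85, 0.15),
        "pets": (0.50, 0.50),
        "area": (0.45, 0.55),
        "breakfast": (0.70, 0.30),
        "violence": (0.75, 0.25),
        "weapons": (0.85, 0.15),
        "stove": (0.10, 0.15, 0.70, 0.05),
        "age": (10.0, 1.8),
    }
    true_coefficients = {
        "fear=yes": 0.8,
        "smokers_home=yes": 0.7,
        "area=South Durban": 0.9,
        "age": 0.35,
        # the two interactions forward selection should find
        "fear=yes:breakfast=not daily": 1.4,
        "gender=female:smoke_vehicle=yes": 1.5,
    }
    mar_drivers = {
        "neonatal_care": {"age": 0.8},
        "birth_weight": {"age": 0.6},
        "fear": {"area": 0.9},
        "smoked_pregnant": {"gender": 0.5, "age": 0.4},
        "smokers_home": {"area": 0.6},
        "smoke_vehicle": {"area": 0.8, "age": 0.3},
        "exercise": {"gender": 0.7},
        "tv": {"age": 0.8},
        "people_home": {"area": 0.7},
        "income": {"area": 1.0, "age": 0.3},
        "food": {"severity": 0.8},      # missingness related to the outcome
        "perceived_weight": {"gender": 0.8},
        "work_wear": {"age": 0.5},
        "pets": {"area": 0.5},
        "breakfast": {"age": 0.7},
        "violence": {"area": 0.8},
        "weapons": {"area": 0.8},
        "stove": {"area": 0.9, "age": 0.3},
    }
    return SimulationDesign(
        n=n, schema=schema, marginals=marginals,
        true_coefficients=true_coefficients,
        thresholds=(-0.4, 1.6),
        missing_rates=dict(missing_rates if missing_rates is not None
                           else DEFAULT_MISSING_RATES),
        mar_drivers=mar_drivers, mechanism=mechanism,
    )


def compact_design(n: int = 500, mechanism: str = "MAR",
                   missing_scale: float = 1.0) -> SimulationDesign:
    """A reduced design for simulation studies: 6 categorical predictors plus
    age, the same two true interactions as the default design, and MAR
    missingness driven by the fully observed gender/area/age.

    ``missing_scale`` multiplies every per-variable missing rate, so a single
    knob moves the study between light and heavy missingness.
    """
    b = lambda name: VariableSpec(name, "binary", ("no", "yes"), "no")
    schema = Schema([
        VariableSpec("gender", "binary", ("male", "female"), "male"),
        b("fear"),
        b("smokers_home"),
        b("smoke_vehicle"),
        VariableSpec("area", "binary", ("North Durban", "South Durban"),
                     "North Durban"),
        VariableSpec("breakfast", "binary", ("daily", "not daily"), "daily"),
        VariableSpec("age", "continuous"),
        VariableSpec("severity", "ordinal",
                     ("none/mild intermittent", "mild persistent",
                      "moderate/severe"),
                     role="outcome"),
    ])
    marginals = {
        "gender": (0.52, 0.48), "fear": (0.60, 0.40),
        "smokers_home": (0.55, 0.45), "smoke_vehicle": (0.70, 0.30),
        "area": (0.45, 0.55), "breakfast": (0.65, 0.35), "age": (10.0, 1.8),
    }
    true_coefficients = {
        "fear=yes": 0.8, "smokers_home=yes": 0.7, "area=South Durban": 0.9,
        "age": 0.35,
        "fear=yes:breakfast=not daily": 1.6,
        "gender=female:smoke_vehicle=yes": 1.7,
    }
    rates = {"fear": 0.15, "smokers_home": 0.10, "smoke_vehicle": 0.20,
             "breakfast": 0.15}
    mar_drivers = {
        "fear": {"area": 0.9, "age": 0.4},
        "smokers_home": {"gender": 0.7},
        "smoke_vehicle": {"area": 0.8, "age": 0.4},
        "breakfast": {"age": 0.8, "gender": 0.4},
    }
    return SimulationDesign(
        n=n, schema=schema, marginals=marginals,
        true_coefficients=true_coefficients, thresholds=(-0.4, 1.6),
        missing_rates={k: min(v * missing_scale, 0.95) for k, v in rates.items()},
        mar_drivers=mar_drivers, mechanism=mechanism,
    )


def simulate(design: SimulationDesign | None = None,
             seed: int | None = None) -> MaskedTable:
    """Generate-then-ampute convenience wrapper."""
    design = design or default_design()
    rng = np.random.default_rng(seed)
    return ampute(generate_complete(design, rng), design, rng)
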