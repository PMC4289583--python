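"""Dummy coding for imputation models, transform-then-impute interactions,
and sensible rounding of imputed indicator columns.

Two coding modes feed the two imputation engines:

* **MVNI mode** — every k-category variable becomes k-1 indicator columns
  (reference omitted); an interaction between categorical factors with p
  joint categories becomes p-1 indicators over the joint categories.
  Interactions involving a continuous factor become product columns
  (indicator x value). The result is a fully numeric grid suitable for a
  multivariate-normal model.
* **FCS mode** — source variables stay as they are; each all-categorical
  interaction becomes a single nominal variable whose categories are the
  joint categories, integer-labelled in row-major factor order (so for
  gender x smoking: male/yes=1, male/no=2, female/yes=3, female/no=4).

In both modes a derived interaction cell is missing iff any factor cell is
missing, so the interaction is imputed as a variable in its own right
(transform-then-impute) rather than recomputed from imputed components.

After MVNI imputation the continuous imputations on indicator columns are
mapped back to legal categories by *sensible rounding*: a single indicator
is thresholded at 0.5 (ties round to "present"), a multi-indicator block
takes the category with the largest indicator, falling back to the
reference when every indicator is below 0.5.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .schema import Schema, SchemaError, VariableSpec
from .table import MaskedTable

#: joiner for joint-category labels; factor category labels must not contain it
JOINER = "&"


@dataclass(frozen=True)
class InteractionTerm:
    """An interaction between two or more named variables."""

    factors: tuple[str, ...]

    def __post_init__(self) -> None:
        facs = tuple(str(f) for f in self.factors)
        object.__setattr__(self, "factors", facs)
        if len(facs) < 2:
            raise ValueError("an interaction needs at least 2 factors")
        if len(set(facs)) != len(facs):
            raise ValueError(f"interaction factors must be distinct: {facs}")

    @property
    def name(self) -> str:
        return ":".join(self.factors)

    def validate(self, schema: Schema) -> None:
        for f in self.factors:
            spec = schema[f]
            if spec.role == "outcome":
                raise SchemaError(
                    f"interaction {self.name!r} references the outcome {f!r}; "
                    "the outcome enters the imputation model as a main column only"
                )
            if spec.is_categorical and any(JOINER in c for c in spec.categories):
                raise SchemaError(
                    f"category labels of {f!r} may not contain {JOINER!r}"
                )

    def is_all_categorical(self, schema: Schema) -> bool:
        return all(schema[f].is_categorical for f in self.factors)

    def n_joint_categories(self, schema: Schema) -> int:
        """p = product of the categorical factors' category counts."""
        p = 1
        for f in self.factors:
            spec = schema[f]
            if spec.is_categorical:
                p *= spec.n_categories
        return p

    def joint_combos(self, schema: Schema) -> list[tuple[str, ...]]:
        """Joint categories in row-major factor order (all-categorical terms)."""
        if not self.is_all_categorical(schema):
            raise SchemaError(f"{self.name}: joint categories need categorical factors")
        return list(itertools.product(*(schema[f].categories for f in self.factors)))

    def reference_combo(self, schema: Schema) -> tuple[str, ...]:
        return tuple(schema[f].reference for f in self.factors)


@dataclass
class CodedBlock:
    """How one source variable or interaction maps to coded columns."""

    source: str
    kind: str                      # "continuous" | "indicators" | "joint_nominal" | "products"
    columns: list[str]
    categories: list[str] = field(default_factory=list)   # full list incl. reference
    reference: str = ""
    is_interaction: bool = False
    factors: tuple[str, ...] = ()
    combos: list[tuple[str, ...]] = field(default_factory=list)  # aligned w/ categories

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["factors"] = list(self.factors)
        d["combos"] = [list(c) for c in self.combos]
        return d


@dataclass
class CodingMap:
    """Invertible record of a coding pass; serializable for provenance."""

    mode: str                      # "mvni" | "fcs"
    blocks: list[CodedBlock]

    def block(self, source: str) -> CodedBlock:
        for b in self.blocks:
            if b.source == source:
                return b
        raise KeyError(source)

    @property
    def columns(self) -> list[str]:
        return [c for b in self.blocks for c in b.columns]

    def to_json(self) -> str:
        return json.dumps(
            {"mode": self.mode, "blocks": [b.to_dict() for b in self.blocks]}, indent=2
        )

    @classmethod
    def from_json(cls, s: str) -> "CodingMap":
        payload = json.loads(s)
        blocks = []
        for d in payload["blocks"]:
            d = dict(d)
            d["factors"] = tuple(d.get("factors", ()))
            d["combos"] = [tuple(c) for c in d.get("combos", [])]
            blocks.append(CodedBlock(**d))
        return cls(payload["mode"], blocks)


# ---------------------------------------------------------------------------
# helpers


def _indicator_columns(spec: VariableSpec) -> tuple[list[str], list[str]]:
    """Non-reference categories and their indicator column names."""
    cats = [c for c in spec.categories if c != spec.reference]
    return cats, [f"{spec.name}={c}" for c in cats]


def _joint_labels(term: InteractionTerm, schema: Schema, mode: str):
    combos = term.joint_combos(schema)
    if mode == "mvni":
        labels = [JOINER.join(c) for c in combos]
    else:  # fcs: integer labels in row-major factor order
        labels = [str(i + 1) for i in range(len(combos))]
    ref_combo = term.reference_combo(schema)
    ref_label = labels[combos.index(ref_combo)]
    return combos, labels, ref_label


def derived_specs(schema: Schema, interactions: list[InteractionTerm],
                  mode: str) -> list[VariableSpec]:
    """Variable specs for the derived interaction columns a coding pass adds."""
    out: list[VariableSpec] = []
    for term in interactions:
        term.validate(schema)
        if term.is_all_categorical(schema):
            _, labels, ref = _joint_labels(term, schema, mode)
            out.append(
                VariableSpec(term.name, "nominal", tuple(labels), ref, "auxiliary")
            )
        else:
            for col in _product_columns(term, schema):
                out.append(VariableSpec(col, "continuous", role="auxiliary"))
    return out


def extended_schema(schema: Schema, interactions: list[InteractionTerm],
                    mode: str) -> Schema:
    return schema.extended(derived_specs(schema, interactions, mode))


def _product_columns(term: InteractionTerm, schema: Schema) -> list[str]:
    """Column names for a continuous-involving interaction (product terms)."""
    pieces: list[list[str]] = []
    for f in term.factors:
        spec = schema[f]
        if spec.is_categorical:
            cats, _ = _indicator_columns(spec)
            pieces.append([f"{f}={c}" for c in cats])
        else:
            pieces.append([f])
    return [":".join(p) for p in itertools.product(*pieces)]


def _product_values(term: InteractionTerm, schema: Schema,
                    data: pd.DataFrame) -> pd.DataFrame:
    """Numeric product columns for a continuous-involving interaction."""
    any_missing = data[list(term.factors)].isna().any(axis=1).to_numpy()
    piece_vals: list[list[np.ndarray]] = []
    piece_names: list[list[str]] = []
    for f in term.factors:
        spec = schema[f]
        col = data[f]
        if spec.is_categorical:
            cats, _ = _indicator_columns(spec)
            piece_vals.append(
                [(col.astype(object) == c).astype(float).to_numpy() for c in cats]
            )
            piece_names.append([f"{f}={c}" for c in cats])
        else:
            piece_vals.append([col.to_numpy(dtype=float)])
            piece_names.append([f])
    out = {}
    for vals, names in zip(
        itertools.product(*piece_vals), itertools.product(*piece_names)
    ):
        prod = np.prod(np.column_stack(vals), axis=1)
        prod[any_missing] = np.nan
        out[":".join(names)] = prod
    return pd.DataFrame(out, index=data.index)


# ---------------------------------------------------------------------------
# MVNI coding


def code_for_mvni(t: MaskedTable, interactions: list[InteractionTerm] = ()
                  ) -> tuple[pd.DataFrame, CodingMap]:
    """Code a mixed-type table into the fully numeric grid MVNI imputes.

    Returns the numeric table (NaN = missing) and the invertible CodingMap.
    """
    interactions = list(interactions)
    blocks: list[CodedBlock] = []
    cols: dict[str, np.ndarray] = {}
    data = t.data
    for spec in t.schema:
        if not spec.is_categorical:
            cols[spec.name] = data[spec.name].to_numpy(dtype=float)
            blocks.append(CodedBlock(spec.name, "continuous", [spec.name]))
            continue
        cats, names = _indicator_columns(spec)
        missing = data[spec.name].isna().to_numpy()
        for c, nm in zip(cats, names):
            v = (data[spec.name].astype(object) == c).astype(float).to_numpy()
            v[missing] = np.nan
            cols[nm] = v
        blocks.append(
            CodedBlock(spec.name, "indicators", names,
                       list(spec.categories), spec.reference)
        )
    for term in interactions:
        term.validate(t.schema)
        if term.is_all_categorical(t.schema):
            combos, labels, ref = _joint_labels(term, t.schema, "mvni")
            missing = data[list(term.factors)].isna().any(axis=1).to_numpy()
            # NaN factor cells become the label "nan", which matches no joint
            # category; those rows are forced missing below anyway
            joint = pd.Series(
                [JOINER.join(map(str, c)) for c in zip(
                    *(data[f].astype(object) for f in term.factors))],
                index=data.index,
            )
            names = [f"{term.name}={lab}" for lab in labels if lab != ref]
            for lab, nm in zip([l for l in labels if l != ref], names):
                v = (joint == lab).astype(float).to_numpy()
                v[missing] = np.nan
                cols[nm] = v
            blocks.append(
                CodedBlock(term.name, "indicators", names, labels, ref,
                           is_interaction=True, factors=term.factors,
                           combos=combos)
            )
        else:
            prods = _product_values(term, t.schema, data)
            for nm in prods.columns:
                cols[nm] = prods[nm].to_numpy()
            blocks.append(
                CodedBlock(term.name, "products", list(prods.columns),
                           is_interaction=True, factors=term.factors)
            )
    return pd.DataFrame(cols, index=data.index), CodingMap("mvni", blocks)


def sensible_round(numeric: pd.DataFrame, cmap: CodingMap, schema: Schema,
                   interactions: list[InteractionTerm] = ()) -> MaskedTable:
    """Map a completed numeric MVNI table back to legal category labels.

    Originally observed cells are exact 0/1 indicators and decode to their
    original category; only imputed cells are rounded. The output schema is
    the input schema extended with the derived interaction variables.
    """
    if cmap.mode != "mvni":
        raise ValueError("sensible_round applies to MVNI-coded tables")
    ext = extended_schema(schema, list(interactions), "mvni")
    out: dict[str, object] = {}
    for b in cmap.blocks:
        missing_cols = [c for c in b.columns if c not in numeric.columns]
        if missing_cols:
            raise SchemaError(
                f"block {b.source!r} lacks coded columns {missing_cols}"
            )
        if b.kind in ("continuous", "products"):
            for c in b.columns:
                out[c] = numeric[c].to_numpy(dtype=float)
            continue
        block_vals = numeric[b.columns].to_numpy(dtype=float)
        if np.isnan(block_vals).any():
            raise ValueError(f"block {b.source!r} still has missing cells")
        non_ref = [c for c in b.categories if c != b.reference]
        # argmax over indicators; ties -> lowest category index; all < 0.5 -> reference
        best = np.argmax(block_vals, axis=1)
        best_val = block_vals[np.arange(len(block_vals)), best]
        labels = np.array([non_ref[j] for j in best], dtype=object)
        labels[best_val < 0.5] = b.reference
        out[b.source] = labels
    df = pd.DataFrame(out, index=numeric.index)
    return MaskedTable(ext, df)


# ---------------------------------------------------------------------------
# FCS coding


def code_for_fcs(t: MaskedTable, interactions: list[InteractionTerm] = ()
                 ) -> tuple[MaskedTable, CodingMap]:
    """Append interaction variables for chained-equations imputation.

    Source variables are retained unchanged; all-categorical interactions
    become one nominal variable over the integer-labelled joint categories,
    continuous-involving interactions become numeric product columns.
    """
    interactions = list(interactions)
    blocks: list[CodedBlock] = []
    data = t.data.copy()
    for spec in t.schema:
        kind = "continuous" if not spec.is_categorical else "joint_nominal"
        blocks.append(
            CodedBlock(spec.name, kind if spec.is_categorical else "continuous",
                       [spec.name], list(spec.categories), spec.reference or "")
        )
    for term in interactions:
        term.validate(t.schema)
        if term.is_all_categorical(t.schema):
            combos, labels, ref = _joint_labels(term, t.schema, "fcs")
            lookup = {c: lab for c, lab in zip(combos, labels)}
            missing = data[list(term.factors)].isna().any(axis=1).to_numpy()
            vals = np.array(
                [lookup.get(c, np.nan) for c in zip(
                    *(data[f].astype(object) for f in term.factors))],
                dtype=object,
            )
            vals[missing] = np.nan
            data[term.name] = vals
            blocks.append(
                CodedBlock(term.name, "joint_nominal", [term.name], labels, ref,
                           is_interaction=True, factors=term.factors,
                           combos=combos)
            )
        else:
            prods = _product_values(term, t.schema, data)
            for nm in prods.columns:
                data[nm] = prods[nm]
            blocks.append(
                CodedBlock(term.name, "products", list(prods.columns),
                           is_interaction=True, factors=term.factors)
            )
    ext = extended_schema(t.schema, interactions, "fcs")
    return MaskedTable(ext, data), CodingMap("fcs", blocks)


def decode_joint(cmap: CodingMap, source: str, label: str) -> tuple[str, ...]:
    """Recover the factor categories behind one joint-category label."""
    b = cmap.block(source)
    if not b.is_interaction:
        raise KeyError(f"{source!r} is not an interaction block")
    return b.combos[b.categories.index(str(label))]
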