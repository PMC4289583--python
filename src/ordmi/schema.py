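"""Variable metadata: typed schema for mixed-type tabular data.

A :class:`Schema` is an ordered collection of :class:`VariableSpec` entries
describing each column of a case-by-variable table: its measurement kind
(continuous, binary, nominal or ordinal), the admissible category labels,
the reference level used when dummy coding, and its role in the analysis
(predictor, outcome or auxiliary). Category labels stay strings throughout;
numeric codes are assigned only at coding time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import yaml

KINDS = ("continuous", "binary", "nominal", "ordinal")
ROLES = ("predictor", "outcome", "auxiliary")


class SchemaError(ValueError):
    """Raised when a schema or a value violates its declared metadata."""


@dataclass(frozen=True)
class VariableSpec:
    """Metadata for one variable.

    Parameters
    ----------
    name : str
        Column name, unique within a schema.
    kind : {"continuous", "binary", "nominal", "ordinal"}
        Measurement scale. ``binary`` requires exactly two categories,
        ``ordinal`` at least two *ordered* categories.
    categories : tuple of str
        Ordered category labels; empty for continuous variables.
    reference : str, optional
        Reference level for dummy coding (categorical only). Defaults to
        the first category.
    role : {"predictor", "outcome", "auxiliary"}
    """

    name: str
    kind: str
    categories: tuple[str, ...] = ()
    reference: str | None = None
    role: str = "predictor"

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise SchemaError(f"{self.name}: unknown kind {self.kind!r}")
        if self.role not in ROLES:
            raise SchemaError(f"{self.name}: unknown role {self.role!r}")
        cats = tuple(str(c) for c in self.categories)
        object.__setattr__(self, "categories", cats)
        if self.kind == "continuous":
            if cats:
                raise SchemaError(f"{self.name}: continuous variable has categories")
            if self.reference is not None:
                raise SchemaError(f"{self.name}: continuous variable has a reference")
            return
        if self.kind == "binary" and len(cats) != 2:
            raise SchemaError(f"{self.name}: binary variable needs exactly 2 categories")
        if len(cats) < 2:
            raise SchemaError(f"{self.name}: categorical variable needs >= 2 categories")
        if len(set(cats)) != len(cats):
            raise SchemaError(f"{self.name}: duplicate categories")
        if self.reference is None:
            object.__setattr__(self, "reference", cats[0])
        elif self.reference not in cats:
            raise SchemaError(
                f"{self.name}: reference {self.reference!r} not among categories"
            )

    @property
    def is_categorical(self) -> bool:
        return self.kind != "continuous"

    @property
    def n_categories(self) -> int:
        return len(self.categories)

    def to_dict(self) -> dict:
        d = {"name": self.name, "kind": self.kind, "role": self.role}
        if self.is_categorical:
            d["categories"] = list(self.categories)
            d["reference"] = self.reference
        return d


@dataclass
class Schema:
    """Ordered list of variable specs with unique names and one outcome."""

    variables: list[VariableSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate variable names in schema")
        n_out = sum(v.role == "outcome" for v in self.variables)
        if self.variables and n_out != 1:
            raise SchemaError(f"schema must declare exactly one outcome, found {n_out}")
        self._by_name = {v.name: v for v in self.variables}

    def __iter__(self):
        return iter(self.variables)

    def __len__(self) -> int:
        return len(self.variables)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> VariableSpec:
        try:
            return self._by_name[name]
        except KeyError:
            raise SchemaError(f"no variable named {name!r} in schema") from None

    @property
    def names(self) -> list[str]:
        return [v.name for v in self.variables]

    @property
    def outcome(self) -> VariableSpec:
        for v in self.variables:
            if v.role == "outcome":
                return v
        raise SchemaError("schema has no outcome variable")

    @property
    def predictors(self) -> list[VariableSpec]:
        return [v for v in self.variables if v.role == "predictor"]

    def extended(self, extra: list[VariableSpec]) -> "Schema":
        """A new schema with derived variables appended (e.g. interaction columns)."""
        return Schema(self.variables + list(extra))

    # ---- serialization -------------------------------------------------

    def to_dicts(self) -> list[dict]:
        return [v.to_dict() for v in self.variables]

    @classmethod
    def from_dicts(cls, dicts: list[dict]) -> "Schema":
        specs = []
        for d in dicts:
            specs.append(
                VariableSpec(
                    name=str(d["name"]),
                    kind=str(d["kind"]),
                    categories=tuple(str(c) for c in d.get("categories", ()) or ()),
                    reference=(None if d.get("reference") is None else str(d["reference"])),
                    role=str(d.get("role", "predictor")),
                )
            )
        return cls(specs)

    def save(self, path) -> None:
        path = str(path)
        payload = {"variables": self.to_dicts()}
        with open(path, "w") as fh:
            if path.endswith(".json"):
                json.dump(payload, fh, indent=2)
            else:
                yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "Schema":
        path = str(path)
        with open(path) as fh:
            payload = json.load(fh) if path.endswith(".json") else yaml.safe_load(fh)
        if isinstance(payload, dict):
            payload = payload["variables"]
        return cls.from_dicts(payload)
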