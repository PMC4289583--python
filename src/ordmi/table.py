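"""MaskedTable: the universal data carrier (values + missingness mask) and CSV I/O.

Missing cells are held as NaN inside a pandas DataFrame; the boolean mask is
derived from it, so values and mask can never disagree in shape. Continuous
columns are float64; categorical columns are object dtype holding the string
labels declared in the schema.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .schema import Schema, SchemaError

#: cell contents interpreted as missing when reading CSV
DEFAULT_NA_VALUES = ("", "NA", ".")


@dataclass
class MaskedTable:
    """A case-by-variable table tied to a :class:`~ordmi.schema.Schema`.

    ``data`` holds one column per schema variable, in schema order; missing
    cells are NaN. ``mask`` (derived) is True where a cell is missing.
    """

    schema: Schema
    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing_cols = [n for n in self.schema.names if n not in self.data.columns]
        if missing_cols:
            raise SchemaError(f"data lacks schema columns: {missing_cols}")
        self.data = self.data.loc[:, self.schema.names].reset_index(drop=True)
        for spec in self.schema:
            col = self.data[spec.name]
            if spec.is_categorical:
                vals = col.astype(object).where(col.notna(), np.nan)
                self.data[spec.name] = vals
            else:
                self.data[spec.name] = pd.to_numeric(col, errors="raise").astype(float)

    # ---- basic properties ---------------------------------------------

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean grid, True = missing."""
        return self.data.isna()

    @property
    def n_cases(self) -> int:
        return len(self.data)

    @property
    def n_vars(self) -> int:
        return len(self.schema)

    def copy(self) -> "MaskedTable":
        return MaskedTable(self.schema, self.data.copy())

    def is_complete(self) -> bool:
        return not bool(self.mask.to_numpy().any())

    # ---- validation ----------------------------------------------------

    def validate(self, require_complete_outcome: bool = False) -> None:
        """Check every observed categorical cell against its declared categories."""
        for spec in self.schema:
            if not spec.is_categorical:
                continue
            col = self.data[spec.name]
            observed = col[col.notna()]
            bad = ~observed.astype(str).isin(spec.categories)
            if bad.any():
                row = observed.index[bad.to_numpy()][0]
                raise SchemaError(
                    f"column {spec.name!r}, row {row}: value "
                    f"{observed.loc[row]!r} not in categories {list(spec.categories)}"
                )
        if require_complete_outcome:
            out = self.schema.outcome.name
            if self.data[out].isna().any():
                rows = list(self.data.index[self.data[out].isna()][:5])
                raise SchemaError(
                    f"outcome column {out!r} has missing cells (rows {rows}); "
                    "analysis requires a fully observed outcome"
                )


def read_table(path, schema_path=None, schema: Schema | None = None,
               na_values=DEFAULT_NA_VALUES) -> MaskedTable:
    """Read a CSV into a MaskedTable, validating against the schema.

    Parameters
    ----------
    path : path-like
        CSV file with a header row whose names match the schema.
    schema_path : path-like, optional
        YAML/JSON schema config; alternatively pass ``schema`` directly.
    na_values : sequence of str
        Cell contents treated as missing (default: empty string, "NA", ".").
    """
    if schema is None:
        if schema_path is None:
            raise ValueError("provide schema or schema_path")
        schema = Schema.load(schema_path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False, skipinitialspace=False)
    na_set = set(na_values)
    data = {}
    for spec in schema:
        if spec.name not in raw.columns:
            raise SchemaError(f"CSV lacks column {spec.name!r}")
        col = raw[spec.name].map(lambda v: np.nan if v in na_set else v)
        data[spec.name] = col
    t = MaskedTable(schema, pd.DataFrame(data))
    t.validate()
    return t


def write_table(t: MaskedTable, path, na_rep: str = "") -> None:
    """Write a MaskedTable to CSV; missing cells become ``na_rep``.

    Column order is the schema order, so write/read round-trips are
    deterministic and lossless for values and mask.
    """
    out = t.data.copy()
    for spec in t.schema:
        if not spec.is_categorical:
            # plain repr keeps full precision; ints print without trailing .0
            out[spec.name] = out[spec.name].map(
                lambda v: "" if pd.isna(v) else repr(float(v))
            )
    out.to_csv(path, index=False, na_rep=na_rep)


def write_stack(datasets: list[MaskedTable], path) -> None:
    """Write m completed tables as one stacked CSV with a leading .imp index (1..m)."""
    frames = []
    for i, t in enumerate(datasets, start=1):
        df = t.data.copy()
        df.insert(0, ".imp", i)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, na_rep="")
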