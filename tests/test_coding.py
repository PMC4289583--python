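"""Dummy/interaction coding and sensible rounding: the worked 2x2 example,
column counts by enumeration, missingness propagation, and decode identity."""

import numpy as np
import pandas as pd
import pytest

from ordmi import (InteractionTerm, MaskedTable, Schema, SchemaError,
                   VariableSpec, code_for_fcs, code_for_mvni, sensible_round)
from ordmi.coding import CodingMap, decode_joint


@pytest.fixture
def study_schema():
    return Schema([
        VariableSpec("gender", "binary", ("male", "female"), "female"),
        VariableSpec("smoking", "binary", ("yes", "no"), "no"),
        VariableSpec("income", "nominal", ("i1", "i2", "i3", "i4"), "i4"),
        VariableSpec("breakfast", "binary", ("daily", "not daily"), "daily"),
        VariableSpec("age", "continuous"),
        VariableSpec("sev", "ordinal", ("1", "2", "3"), role="outcome"),
    ])


@pytest.fixture
def study_table(study_schema):
    df = pd.DataFrame({
        "gender": ["male", "female", "male", np.nan],
        "smoking": ["yes", "no", np.nan, "yes"],
        "income": ["i1", "i2", "i3", "i4"],
        "breakfast": ["daily", "not daily", "daily", "not daily"],
        "age": [10.0, 11.0, 9.0, 12.0],
        "sev": ["1", "2", "3", "1"],
    })
    return MaskedTable(study_schema, df)


class TestMvniCoding:
    def test_two_by_two_interaction_gives_three_indicators(self, study_table):
        term = InteractionTerm(("gender", "smoking"))
        _, cmap = code_for_mvni(study_table, [term])
        assert len(cmap.block("gender:smoking").columns) == 3

    def test_binary_variable_gives_one_indicator(self, study_table):
        numeric, cmap = code_for_mvni(study_table, [])
        assert cmap.block("gender").columns == ["gender=male"]

    def test_four_by_two_interaction_gives_seven_indicators(self, study_table):
        term = InteractionTerm(("income", "breakfast"))
        _, cmap = code_for_mvni(study_table, [term])
        # p = 4*2 joint categories, reference omitted
        assert len(cmap.block("income:breakfast").columns) == 7

    def test_missing_factor_propagates_to_all_interaction_columns(
            self, study_table):
        term = InteractionTerm(("gender", "smoking"))
        numeric, cmap = code_for_mvni(study_table, [term])
        cols = cmap.block("gender:smoking").columns
        # rows 2 and 3 have a missing factor
        assert numeric.loc[2, cols].isna().all()
        assert numeric.loc[3, cols].isna().all()
        assert numeric.loc[0, cols].notna().all()

    def test_outcome_in_interaction_rejected(self, study_table):
        with pytest.raises(SchemaError, match="outcome"):
            code_for_mvni(study_table, [InteractionTerm(("gender", "sev"))])

    def test_continuous_passthrough(self, study_table):
        numeric, _ = code_for_mvni(study_table, [])
        assert np.allclose(numeric["age"],
                           study_table.data["age"].to_numpy(dtype=float))

    def test_categorical_by_continuous_product_columns(self, study_table):
        term = InteractionTerm(("income", "age"))
        numeric, cmap = code_for_mvni(study_table, [term])
        cols = cmap.block("income:age").columns
        assert len(cols) == 3  # (4-1) indicator x value products
        assert numeric.loc[0, "income=i1:age"] == pytest.approx(10.0)
        assert numeric.loc[1, "income=i1:age"] == pytest.approx(0.0)


class TestFcsCoding:
    def test_joint_nominal_integer_labels_row_major(self, study_schema):
        df = pd.DataFrame({
            "gender": ["male", "male", "female", "female"],
            "smoking": ["yes", "no", "yes", "no"],
            "income": ["i1"] * 4, "breakfast": ["daily"] * 4,
            "age": [10.0] * 4, "sev": ["1", "2", "3", "1"],
        })
        t = MaskedTable(study_schema, df)
        coded, cmap = code_for_fcs(t, [InteractionTerm(("gender", "smoking"))])
        # male/yes = 1, male/no = 2, female/yes = 3, female/no = 4
        assert list(coded.data["gender:smoking"]) == ["1", "2", "3", "4"]
        assert decode_joint(cmap, "gender:smoking", "3") == ("female", "yes")

    def test_missingness_propagation_and_source_retention(self, study_table):
        coded, _ = code_for_fcs(study_table,
                                [InteractionTerm(("gender", "smoking"))])
        derived = coded.data["gender:smoking"]
        assert derived.isna().tolist() == [False, False, True, True]
        for name in study_table.schema.names:
            assert coded.data[name].fillna("<NA>").astype(str).equals(
                study_table.data[name].fillna("<NA>").astype(str))

    def test_decode_recovers_both_factors_on_observed_cells(self, study_table):
        coded, cmap = code_for_fcs(study_table,
                                   [InteractionTerm(("gender", "smoking"))])
        for i in (0, 1):
            combo = decode_joint(cmap, "gender:smoking",
                                 coded.data.loc[i, "gender:smoking"])
            assert combo == (study_table.data.loc[i, "gender"],
                             study_table.data.loc[i, "smoking"])

    def test_coding_map_json_round_trip(self, study_table):
        _, cmap = code_for_fcs(study_table,
                               [InteractionTerm(("gender", "smoking"))])
        back = CodingMap.from_json(cmap.to_json())
        assert back.mode == cmap.mode
        assert back.block("gender:smoking").combos == \
            cmap.block("gender:smoking").combos


class TestSensibleRound:
    def test_code_decode_identity_on_complete_table(self, study_schema):
        df = pd.DataFrame({
            "gender": ["male", "female"], "smoking": ["yes", "no"],
            "income": ["i1", "i3"], "breakfast": ["daily", "not daily"],
            "age": [10.0, 11.0], "sev": ["1", "3"],
        })
        t = MaskedTable(study_schema, df)
        term = InteractionTerm(("gender", "smoking"))
        numeric, cmap = code_for_mvni(t, [term])
        rounded = sensible_round(numeric, cmap, study_schema, [term])
        for name in study_schema.names:
            assert list(rounded.data[name].astype(str)) == \
                list(df[name].astype(str))

    def test_single_indicator_thresholded_at_half(self, study_schema,
                                                  study_table):
        numeric, cmap = code_for_mvni(study_table, [])
        numeric = numeric.fillna(0.0)
        numeric.loc[0, "gender=male"] = 0.7
        rounded = sensible_round(numeric, cmap, study_schema)
        assert rounded.data.loc[0, "gender"] == "male"
        numeric.loc[0, "gender=male"] = 0.5   # tie rounds to "present"
        assert sensible_round(numeric, cmap,
                              study_schema).data.loc[0, "gender"] == "male"

    def test_multi_indicator_block_argmax_and_fallback(self, study_schema,
                                                       study_table):
        numeric, cmap = code_for_mvni(study_table, [])
        numeric = numeric.fillna(0.0)
        block = cmap.block("income").columns       # i1, i2, i3 (ref i4)
        numeric.loc[0, block] = [0.2, 0.9, 0.3]
        numeric.loc[1, block] = [0.1, 0.2, 0.3]    # all < 0.5 -> reference
        rounded = sensible_round(numeric, cmap, study_schema)
        assert rounded.data.loc[0, "income"] == "i2"
        assert rounded.data.loc[1, "income"] == "i4"

    def test_observed_cells_never_altered_and_all_legal(self, study_schema,
                                                        rng):
        n = 50
        df = pd.DataFrame({
            "gender": rng.choice(["male", "female"], n),
            "smoking": rng.choice(["yes", "no"], n),
            "income": rng.choice(["i1", "i2", "i3", "i4"], n),
            "breakfast": rng.choice(["daily", "not daily"], n),
            "age": rng.normal(10, 2, n),
            "sev": rng.choice(["1", "2", "3"], n),
        })
        t = MaskedTable(study_schema, df)
        numeric, cmap = code_for_mvni(t, [])
        # perturb as an imputer would: replace a random subset with noise
        noisy = numeric.copy()
        jitter_rows = rng.choice(n, 10, replace=False)
        for c in [c_ for c_ in noisy.columns if "=" in c_]:
            noisy.loc[jitter_rows, c] = rng.normal(0.4, 0.5, len(jitter_rows))
        rounded = sensible_round(noisy, cmap, study_schema)
        rounded.validate()
        untouched = [i for i in range(n) if i not in set(jitter_rows)]
        for name in study_schema.names:
            assert list(rounded.data.loc[untouched, name].astype(str)) == \
                list(df.loc[untouched, name].astype(str))

    def test_missing_block_column_is_structural_error(self, study_table,
                                                      study_schema):
        numeric, cmap = code_for_mvni(study_table, [])
        with pytest.raises(SchemaError, match="lacks coded columns"):
            sensible_round(numeric.drop(columns=["income=i1"]).fillna(0.0),
                           cmap, study_schema)
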