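import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from bymlogit import (
    CovariateSchema,
    MultilevelDataset,
    dichotomize_bmi,
    encode_design,
    read_individuals,
    write_individuals,
)
from bymlogit.data_model import DegenerateDesignError, RecordError, SchemaError


class TestBmiDichotomization:
    @pytest.mark.parametrize(
        "height, weight, expected",
        [
            (1.75, 76.6, 1),  # BMI 25.01
            (1.75, 76.5, 0),  # BMI 24.98
            (2.0, 100.0, 1),  # BMI exactly 25.0: the cut is inclusive
        ],
    )
    def test_threshold(self, height, weight, expected):
        assert dichotomize_bmi(height, weight) == expected

    @pytest.mark.parametrize("height, weight", [(0.0, 70.0), (1.7, -1.0)])
    def test_nonpositive_inputs_rejected(self, height, weight):
        with pytest.raises(ValueError):
            dichotomize_bmi(height, weight)


class TestReadWrite:
    def test_three_row_roundtrip(self, tmp_path, small_schema):
        df = pd.DataFrame(
            {
                "area_id": ["A1", "A1", "A2"],
                "outcome": [0, 1, 0],
                "smoke": ["never", "current", "former"],
                "mvpa": ["no", "yes", "no"],
            }
        )
        path = tmp_path / "ind.csv"
        df.to_csv(path, index=False)
        ds = read_individuals(path, small_schema)
        assert ds.n_records == 3
        assert ds.areas == ["A1", "A2"]
        assert list(ds.area_sizes()) == [2, 1]

    def test_unknown_label_names_row_and_column(self, tmp_path, small_schema):
        df = pd.DataFrame(
            {
                "area_id": ["A1", "A2"],
                "outcome": [0, 1],
                "smoke": ["never", "maybe"],
                "mvpa": ["no", "yes"],
            }
        )
        path = tmp_path / "bad.csv"
        df.to_csv(path, index=False)
        with pytest.raises(RecordError, match=r"row 1.*smoke"):
            read_individuals(path, small_schema)

    def test_missing_column_is_schema_error(self, tmp_path, small_schema):
        pd.DataFrame({"area_id": ["A1"], "outcome": [1]}).to_csv(
            tmp_path / "m.csv", index=False
        )
        with pytest.raises(SchemaError):
            read_individuals(tmp_path / "m.csv", small_schema)

    def test_write_read_identity_on_generated_fixture(self, tmp_path, rng, small_schema):
        n = 200
        df = pd.DataFrame(
            {
                "area_id": rng.choice(["A1", "A2", "A3"], n),
                "outcome": rng.integers(0, 2, n),
                "smoke": rng.choice(["never", "former", "current"], n),
                "mvpa": rng.choice(["no", "yes"], n),
            }
        )
        ds = MultilevelDataset(individuals=df, schema=small_schema)
        path = tmp_path / "rt.csv"
        write_individuals(ds, path)
        back = read_individuals(path, small_schema)
        pd.testing.assert_frame_equal(
            back.individuals, ds.individuals, check_dtype=False
        )
        assert back.areas == ds.areas

    def test_missing_values_dropped_with_warning(self, tmp_path, small_schema, caplog):
        df = pd.DataFrame(
            {
                "area_id": ["A1", "A2", "A3"],
                "outcome": [0, 1, 0],
                "smoke": ["never", None, "current"],
                "mvpa": ["no", "yes", "yes"],
            }
        )
        path = tmp_path / "na.csv"
        df.to_csv(path, index=False)
        with caplog.at_level("WARNING"):
            ds = read_individuals(path, small_schema)
        assert ds.n_records == 2
        assert any("dropping" in r.message for r in caplog.records)


class TestEncodeDesign:
    def test_three_level_covariate_gives_two_columns(self, small_dataset):
        design = encode_design(small_dataset, individual_covariates=["smoke"])
        assert design.X.shape == (small_dataset.n_records, 2)
        assert design.x_names == ["smoke[former]", "smoke[current]"]
        ref_rows = small_dataset.individuals["smoke"] == "never"
        assert np.all(design.X[ref_rows.to_numpy()] == 0)

    def test_column_count_is_sum_of_levels_minus_one(self, small_dataset):
        design = encode_design(small_dataset, individual_covariates=["smoke", "mvpa"])
        assert design.X.shape[1] == (3 - 1) + (2 - 1)
        assert set(np.unique(design.X)) <= {0.0, 1.0}

    def test_tertile_reference_t1_orientation(self, small_schema, rng):
        n = 30
        areas = [f"A{i}" for i in range(6)]
        df = pd.DataFrame(
            {
                "area_id": rng.choice(areas, n),
                "outcome": rng.integers(0, 2, n),
                "smoke": rng.choice(["never", "former", "current"], n),
                "mvpa": rng.choice(["no", "yes"], n),
            }
        )
        area_cov = pd.DataFrame(
            {"dist_pa_tertile": ["T1", "T2", "T3", "T1", "T2", "T3"]},
            index=pd.Index(areas, name="area_id"),
        )
        ds = MultilevelDataset(
            individuals=df, schema=small_schema, area_covariates=area_cov
        )
        design = encode_design(ds, area_covariates=["dist_pa_tertile"])
        # reference T1 dropped: columns are the T2 and T3 contrasts
        assert design.w_names == ["dist_pa_tertile[T2]", "dist_pa_tertile[T3]"]

    def test_w_constant_within_area(self, small_schema, rng):
        n = 40
        areas = ["A0", "A1", "A2"]
        df = pd.DataFrame(
            {
                "area_id": rng.choice(areas, n),
                "outcome": rng.integers(0, 2, n),
                "smoke": rng.choice(["never", "former", "current"], n),
                "mvpa": rng.choice(["no", "yes"], n),
            }
        )
        area_cov = pd.DataFrame(
            {"t": ["T1", "T2", "T3"]}, index=pd.Index(areas, name="area_id")
        )
        ds = MultilevelDataset(
            individuals=df, schema=small_schema, area_covariates=area_cov
        )
        design = encode_design(ds, area_covariates=["t"])
        for a in range(3):
            rows = design.W[design.area_index == a]
            assert np.all(rows == rows[0])

    def test_decode_recovers_category(self, small_dataset):
        """Dummy columns must invert back to the original labels row by row."""
        design = encode_design(small_dataset, individual_covariates=["smoke"])
        levels = ["never", "former", "current"]
        decoded = []
        for row in design.X:
            if row.sum() == 0:
                decoded.append("never")
            else:
                decoded.append(levels[1 + int(np.argmax(row))])
        assert decoded == list(small_dataset.individuals["smoke"])

    def test_single_observed_level_is_degenerate(self, small_schema):
        df = pd.DataFrame(
            {
                "area_id": ["A1"] * 4,
                "outcome": [0, 1, 0, 1],
                "smoke": ["never"] * 4,
                "mvpa": ["no", "yes", "no", "yes"],
            }
        )
        ds = MultilevelDataset(individuals=df, schema=small_schema)
        with pytest.raises(DegenerateDesignError):
            encode_design(ds, individual_covariates=["smoke"])


@given(
    labels=st.lists(st.sampled_from(["a", "b", "c"]), min_size=3, max_size=40).filter(
        lambda ls: len(set(ls)) >= 2
    )
)
@settings(max_examples=25, deadline=None, derandomize=True)
def test_dummy_coding_row_sums(labels):
    """Each row has at most one indicator set; reference rows have none."""
    schema = CovariateSchema(levels={"c": ["a", "b", "c"]})
    df = pd.DataFrame(
        {"area_id": ["A1"] * len(labels), "outcome": [0, 1] * (len(labels) // 2) + [0] * (len(labels) % 2), "c": labels}
    )
    ds = MultilevelDataset(individuals=df, schema=schema)
    design = encode_design(ds, individual_covariates=["c"])
    sums = design.X.sum(axis=1)
    is_ref = (df["c"] == "a").to_numpy()
    assert np.all(sums[is_ref] == 0)
    assert np.all(sums[~is_ref] == 1)


def test_invalid_outcome_rejected(small_schema):
    df = pd.DataFrame(
        {"area_id": ["A1"], "outcome": [2], "smoke": ["never"], "mvpa": ["no"]}
    )
    with pytest.raises(RecordError):
        MultilevelDataset(individuals=df, schema=small_schema)
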