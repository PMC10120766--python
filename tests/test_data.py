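"""Loading, validation, derived covariates and data-adequacy warnings."""

import numpy as np
import pandas as pd
import pytest

from trajmix import (
    ConfigurationError,
    DataError,
    ModelSpec,
    derive_centered_covariate,
    emit_data_warnings,
    from_frame,
    load_long_data,
)

from conftest import make_long


@pytest.fixture
def demo_csv(tmp_path):
    path = tmp_path / "demo.csv"
    path.write_text(
        "ID,time,cognition,ageDeath\n"
        "1000,-10.00,0.45,91\n"
        "1000,-9.08,0.27,91\n"
        "1001,-5.00,,88\n"          # missing outcome -> dropped
        "1001,-4.00,0.10,88\n"
        "1002,-3.00,0.20,90\n"
    )
    return path


class TestLoading:
    def test_parses_table_row(self, demo_csv):
        data = load_long_data(demo_csv, "ID", "cognition", "time")
        row = data.df.iloc[0]
        assert row["time"] == -10.0 and row["cognition"] == 0.45
        assert data.n_subjects == 3

    def test_drop_accounting(self, demo_csv):
        data = load_long_data(demo_csv, "ID", "cognition", "time")
        assert data.n_dropped + data.n_obs == 5

    def test_empty_file_is_data_error(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        with pytest.raises(DataError):
            load_long_data(path, "ID", "y", "t")

    def test_all_missing_outcomes_is_data_error(self, tmp_path):
        path = tmp_path / "na.csv"
        path.write_text("ID,y,t\n1,,0\n2,,1\n")
        with pytest.raises(DataError):
            load_long_data(path, "ID", "y", "t")

    def test_misspelled_column_names_the_request(self, demo_csv):
        with pytest.raises(ConfigurationError, match="cognitionn"):
            load_long_data(demo_csv, "ID", "cognitionn", "time")

    def test_missing_file(self, tmp_path):
        with pytest.raises(ConfigurationError):
            load_long_data(tmp_path / "nope.csv", "ID", "y", "t")

    def test_round_trip(self, demo_csv, tmp_path):
        data = load_long_data(demo_csv, "ID", "cognition", "time")
        out = tmp_path / "out.csv"
        data.to_csv(out)
        again = load_long_data(out, "ID", "cognition", "time")
        pd.testing.assert_frame_equal(data.df, again.df)

    def test_duplicate_subject_time_flagged_not_dropped(self):
        data = make_long([(1, -1.0, 0.1), (1, -1.0, 0.2), (1, 0.0, 0.3)])
        assert data.n_duplicates == 2 and data.n_obs == 3


class TestDerivedCovariate:
    def test_centering(self):
        data = make_long([(1, -1.0, 0.1)], covs={"ageDeath": {1: 91}})
        out = derive_centered_covariate(data, "ageDeath", 90, "ageDeath90")
        assert out.df["ageDeath90"].iloc[0] == 1

    @pytest.mark.parametrize("age,center,expect", [(91, 0, 91), (90, 90, 0)])
    def test_identity_and_zero(self, age, center, expect):
        data = make_long([(1, -1.0, 0.1)], covs={"a": {1: age}})
        out = derive_centered_covariate(data, "a", center, "b")
        assert out.df["b"].iloc[0] == expect

    def test_non_numeric_source(self):
        data = make_long([(1, -1.0, 0.1)])
        data.df["lab"] = "x"
        with pytest.raises(DataError):
            derive_centered_covariate(data, "lab", 0, "bad")


class TestWarnings:
    def _data(self, n_subjects, covs=0):
        rows = [(i, -float(j), 0.1 * j) for i in range(n_subjects) for j in range(5)]
        mapping = {name: {i: 0.5 for i in range(n_subjects)}
                   for name in (f"c{k}" for k in range(covs))}
        return make_long(rows, covs=mapping or None)

    def test_small_sample_warning(self):
        warnings = emit_data_warnings(self._data(30))
        assert any("small sample" in w for w in warnings)

    def test_nominal_case_no_warnings(self):
        spec = ModelSpec(model_id=2, predictors=(("c0",),) * 4)
        warnings = emit_data_warnings(self._data(1200, covs=1), spec)
        assert warnings == []

    def test_covariate_count_warning(self):
        names = tuple(f"c{k}" for k in range(8))
        spec = ModelSpec(model_id=2, predictors=(names,) * 4)
        warnings = emit_data_warnings(self._data(100, covs=8), spec)
        assert any("fixed effects" in w for w in warnings)

    def test_never_raises_without_spec(self):
        assert isinstance(emit_data_warnings(self._data(5)), list)


class TestCovariateTable:
    def test_time_varying_covariate_rejected(self):
        df = pd.DataFrame({
            "ID": [1, 1], "t": [-1.0, 0.0], "y": [0.1, 0.2], "x": [1.0, 2.0],
        })
        data = from_frame(df, "ID", "y", "t")
        with pytest.raises(DataError, match="time-varying"):
            data.covariate_table(["x"])

    def test_missing_covariate_column(self):
        data = make_long([(1, 0.0, 0.1)])
        with pytest.raises(ConfigurationError):
            data.covariate_table(["nope"])
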