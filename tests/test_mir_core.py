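"""MIR arithmetic, dataset container, replication convention, IO."""

import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirharmonic.mir_core import (
    EmptyDatasetError,
    InvalidMeasurementError,
    MIRDataset,
    MIRRecord,
    compute_mir,
    dataset_from_arrays,
    monthly_means,
    read_mir_table,
    replicate_two_periods,
    write_monthly_means,
)


class TestComputeMir:
    @pytest.mark.parametrize(
        "mi, pi, expected",
        [(3.2, 3.2, 100.0), (0.0, 3.2, 0.0), (5.5, 11.0, 50.0), (12.0, 10.0, 120.0)],
    )
    def test_examples(self, mi, pi, expected):
        assert compute_mir(mi, pi) == pytest.approx(expected)

    @pytest.mark.parametrize("mi, pi", [(1.0, 0.0), (1.0, -2.0), (-0.1, 1.0)])
    def test_invalid_measurements(self, mi, pi):
        with pytest.raises(InvalidMeasurementError):
            compute_mir(mi, pi)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        mi=st.floats(0.0, 1e3),
        pi=st.floats(1e-3, 1e3),
        k=st.floats(1e-3, 1e3),
    )
    def test_scale_invariance(self, mi, pi, k):
        assert compute_mir(k * mi, k * pi) == pytest.approx(
            compute_mir(mi, pi), rel=1e-9, abs=1e-9
        )


class TestRecordValidation:
    @pytest.mark.parametrize("month", [0, 13, -1])
    def test_month_out_of_range(self, month):
        with pytest.raises(ValueError, match="month"):
            MIRRecord("a", month, 2010, 50.0)

    @pytest.mark.parametrize("mir", [0.0, -5.0, float("nan")])
    def test_nonpositive_mir_rejected(self, mir):
        with pytest.raises(ValueError, match="mir"):
            MIRRecord("a", 6, 2010, mir)


class TestReplication:
    def test_single_record_gets_mirror_at_t_plus_period(self):
        d = dataset_from_arrays([3], [40.0])
        r = replicate_two_periods(d)
        assert sorted(r.times) == [3.0, 15.0]
        assert len(r) == 2

    def test_doubles_count_and_preserves_mir_multiset(self, clean_dataset):
        r = replicate_two_periods(clean_dataset)
        assert len(r) == 2 * clean_dataset.n_original
        orig = sorted(clean_dataset.mir)
        assert sorted(r.mir) == pytest.approx(sorted(orig + orig))
        # original untouched
        assert not clean_dataset.is_replicated
        assert len(clean_dataset) == clean_dataset.n_original

    def test_composition_spans_four_periods(self):
        d = dataset_from_arrays([3, 7], [40.0, 60.0])
        r2 = replicate_two_periods(replicate_two_periods(d))
        assert len(r2) == 8
        assert max(r2.times) > 3 * d.period_unit

    def test_empty_dataset_rejected(self):
        with pytest.raises(EmptyDatasetError):
            replicate_two_periods(MIRDataset(()))


class TestMonthlyMeans:
    def test_two_point_mean(self):
        d = dataset_from_arrays([1, 1], [40.0, 60.0])
        assert monthly_means(d) == [(1, 50.0, 2)]

    def test_single_record(self):
        d = dataset_from_arrays([7], [80.0])
        assert monthly_means(d) == [(7, 80.0, 1)]

    def test_counts_sum_to_n_and_constant_case(self, rng):
        months = rng.integers(1, 13, size=120)
        d = dataset_from_arrays(months, np.full(120, 55.0))
        mm = monthly_means(d)
        assert sum(c for _, _, c in mm) == 120
        assert all(mean == pytest.approx(55.0) for _, mean, _ in mm)
        # months absent from the data are omitted
        assert {m for m, _, _ in mm} == set(np.unique(months))


class TestIO:
    def _frame(self):
        return pd.DataFrame(
            {
                "Sample_ID": ["a1", "a2", "a3"],
                "MONTH": [1, 6, 12],
                "Year": [2010, 2010, 2011],
                "MIR": [12.5, 80.0, 45.0],
                "Age": [7, 9, 11],
            }
        )

    def test_csv_roundtrip_case_insensitive(self, tmp_path):
        p = tmp_path / "mir.csv"
        self._frame().to_csv(p, index=False)
        d = read_mir_table(p, species_label="test sp.")
        assert d.n_original == 3
        assert d.records[1].mir == 80.0
        assert d.records[1].age == 9
        assert d.species_label == "test sp."

    def test_xlsx_roundtrip(self, tmp_path):
        p = tmp_path / "mir.xlsx"
        self._frame().to_excel(p, index=False)
        d = read_mir_table(p)
        assert d.n_original == 3
        assert [r.month for r in d.records] == [1, 6, 12]

    def test_column_mapping(self, tmp_path):
        df = self._frame().rename(columns={"MIR": "MIR %"})
        p = tmp_path / "mir.csv"
        df.to_csv(p, index=False)
        d = read_mir_table(p, column_map={"mir": "MIR %"})
        assert d.n_original == 3

    def test_missing_column_names_offender(self, tmp_path):
        p = tmp_path / "bad.csv"
        self._frame().drop(columns=["MIR"]).to_csv(p, index=False)
        with pytest.raises(KeyError, match="mir"):
            read_mir_table(p)

    def test_zero_mir_dropped_with_warning(self, tmp_path, caplog):
        df = self._frame()
        df.loc[1, "MIR"] = 0.0
        p = tmp_path / "mir.csv"
        df.to_csv(p, index=False)
        with caplog.at_level(logging.WARNING):
            d = read_mir_table(p)
        assert d.n_original == 2
        assert "excluded 1" in caplog.text

    def test_monthly_means_writer(self, tmp_path):
        d = dataset_from_arrays([1, 1, 2], [40.0, 60.0, 30.0])
        out = tmp_path / "means.csv"
        write_monthly_means(d, out)
        back = pd.read_csv(out)
        assert list(back.columns) == ["month", "mean_mir", "n"]
        assert back["mean_mir"].tolist() == [50.0, 30.0]

    def test_metadata_json(self, clean_dataset):
        import json

        meta = json.loads(clean_dataset.metadata_json())
        assert meta["n_records"] == 300
        assert meta["replicated"] is False
        assert meta["period_unit"] == 12.0
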