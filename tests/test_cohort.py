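"""Patient records, endpoint derivation, biomarker summaries, file round trips."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import emaxrisk as er
from emaxrisk.cohort import rows_to_frame
from emaxrisk.params import ParameterError


def _record(series, death=None, transplant=None, followup=2000.0, **extra):
    return er.PatientRecord(id="p1", nt_probnp_series=tuple(series),
                            last_followup_time=followup, death_time=death,
                            transplant_time=transplant, **extra)


class TestDeriveEndpoint:
    @pytest.mark.parametrize("death, transplant, horizon, expected", [
        (100.0, None, 730.0, 1),
        (None, 800.0, 730.0, 0),
        (None, None, 1825.0, 0),
        (900.0, 400.0, 730.0, 1),   # earlier of the two applies
    ])
    def test_composite_rule(self, death, transplant, horizon, expected):
        rec = _record([(0.0, 500.0)], death=death, transplant=transplant)
        assert er.derive_endpoint(rec, horizon) == expected

    def test_negative_horizon_rejected(self):
        with pytest.raises(ParameterError):
            er.derive_endpoint(_record([(0.0, 500.0)]), -10.0)

    @given(event_day=st.floats(0.0, 3000.0),
           h1=st.floats(1.0, 3000.0), h2=st.floats(1.0, 3000.0))
    def test_monotone_in_horizon(self, event_day, h1, h2):
        rec = _record([(0.0, 500.0)], death=event_day, followup=3000.0)
        lo, hi = sorted((h1, h2))
        assert er.derive_endpoint(rec, hi) >= er.derive_endpoint(rec, lo)


class TestSummarizeBiomarker:
    def test_single_measurement_either_mode(self):
        rec = _record([(0.0, 500.0)])
        assert er.summarize_biomarker(rec, "enrollment", 730.0) == 500.0
        assert er.summarize_biomarker(rec, "median_followup", 730.0) == 500.0

    def test_median_of_three_in_window(self):
        rec = _record([(10.0, 100.0), (200.0, 400.0), (400.0, 200.0)])
        assert er.summarize_biomarker(rec, "median_followup", 730.0) == 200.0

    def test_window_filter_then_median(self):
        rec = _record([(10.0, 100.0), (900.0, 9000.0)])
        # only the day-10 value falls inside the 730-day horizon
        assert er.summarize_biomarker(rec, "median_followup", 730.0) == 100.0

    def test_enrollment_mode_uses_nearest_within_window(self):
        rec = _record([(25.0, 300.0), (5.0, 800.0), (400.0, 50.0)])
        assert er.summarize_biomarker(rec, "enrollment", 730.0) == 800.0

    def test_no_eligible_measurement_raises(self):
        rec = _record([(500.0, 300.0)])
        with pytest.raises(er.MissingDataError):
            er.summarize_biomarker(rec, "enrollment", 730.0)

    def test_order_invariance_of_median(self):
        series = [(10.0, 100.0), (200.0, 400.0), (400.0, 200.0)]
        forward = er.summarize_biomarker(_record(series), "median_followup", 730.0)
        backward = er.summarize_biomarker(_record(series[::-1]), "median_followup", 730.0)
        assert forward == backward

    def test_excluded_patients_counted_not_fatal(self):
        records = [
            _record([(0.0, 500.0)], death=100.0),
            _record([(600.0, 300.0)]),  # nothing near enrollment
        ]
        rows = er.derive_analysis_rows(records, mode="enrollment", horizon=730.0)
        assert len(rows) == 1
        assert rows[0].event == 1


class TestBaselineTable:
    def test_median_iqr_convention(self):
        records = [_record([(0.0, v)], **{"age_years": v}) for v in (1, 2, 3, 4, 5)]
        rows = [er.AnalysisRow(nt_probnp=float(v), event=0) for v in (1, 2, 3, 4, 5)]
        table = er.baseline_table(records, rows, horizon=730.0)
        age = table[table.characteristic.str.startswith("Age")]["value"].item()
        assert age == "3 (2, 4)"

    def test_death_count_percentage_convention(self):
        records = []
        for i in range(109):
            records.append(_record([(0.0, 500.0)], death=100.0 if i < 8 else None))
        rows = [er.AnalysisRow(nt_probnp=500.0, event=int(i < 8)) for i in range(109)]
        table = er.baseline_table(records, rows, horizon=730.0)
        death = table[table.characteristic.str.startswith("Death")]["value"].item()
        assert death == "8 (7)"

    def test_missing_optional_field_reported(self):
        records = [_record([(0.0, 500.0)]) for _ in range(5)]
        rows = [er.AnalysisRow(nt_probnp=500.0, event=0)] * 5
        table = er.baseline_table(records, rows, horizon=730.0)
        male = table[table.characteristic.str.startswith("Male")]["value"].item()
        assert "missing" in male and "(100)" in male

    def test_event_counts_equal_derive_endpoint_sum(self):
        cohort = er.generate_cohort(er.preset_configs()["explorys_child"].with_seed(3))
        table = er.baseline_table(list(cohort.records), list(cohort.analysis_rows),
                                  horizon=730.0)
        comp = table[table.characteristic.str.startswith("Composite")]["value"].item()
        expected = sum(er.derive_endpoint(r, 730.0) for r in cohort.records)
        assert comp.startswith(f"{expected} (")


class TestRecordValidation:
    def test_measurement_outside_followup_rejected(self):
        with pytest.raises(ParameterError):
            _record([(2500.0, 100.0)], followup=2000.0)

    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(ParameterError):
            _record([(0.0, -5.0)])


class TestFileIO:
    def test_wide_round_trip_is_exact(self, tmp_path):
        cohort = er.generate_cohort(er.preset_configs()["explorys_child"].with_seed(8))
        path = tmp_path / "cohort.csv"
        er.write_cohort(path, list(cohort.analysis_rows))
        rows, diagnostics = er.read_cohort(path)
        assert diagnostics == []
        assert tuple(rows) == cohort.analysis_rows
        # writer/reader are mutually inverse at the byte level too
        er.write_cohort(tmp_path / "again.csv", rows)
        assert (tmp_path / "again.csv").read_bytes() == path.read_bytes()

    def test_long_round_trip_preserves_series_and_outcomes(self, tmp_path):
        cohort = er.generate_cohort(er.preset_configs()["explorys_child"].with_seed(8))
        path = tmp_path / "long.csv"
        er.write_cohort(path, list(cohort.records))
        records, diagnostics = er.read_cohort(path)
        assert diagnostics == []
        assert len(records) == len(cohort.records)
        for got, want in zip(records, cohort.records):
            assert got.nt_probnp_series == want.nt_probnp_series
            assert got.death_time == want.death_time
            assert got.transplant_time == want.transplant_time

    def test_well_formed_file_no_diagnostics(self, tmp_path):
        path = tmp_path / "ok.csv"
        path.write_text("id,ntprobnp_pgml,event\na,100,0\nb,2500,1\nc,40,0\n")
        rows, diagnostics = er.read_cohort(path)
        assert len(rows) == 3 and diagnostics == []

    def test_negative_concentration_row_rejected_with_line_number(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("id,ntprobnp_pgml,event\na,100,0\nb,-5,1\nc,40,1\n")
        rows, diagnostics = er.read_cohort(path)
        assert len(rows) == 2
        assert len(diagnostics) == 1
        assert "line 2" in diagnostics[0] and "ntprobnp" in diagnostics[0]

    def test_missing_required_columns_fails(self, tmp_path):
        path = tmp_path / "wrong.csv"
        path.write_text("foo,bar\n1,2\n")
        with pytest.raises(er.CohortReadError):
            er.read_cohort(path)

    def test_schema_renames_columns(self, tmp_path):
        path = tmp_path / "renamed.csv"
        path.write_text("pid,bnp,outcome\na,100,0\nb,900,1\n")
        rows, _ = er.read_cohort(
            path, schema={"id": "pid", "ntprobnp_pgml": "bnp", "event": "outcome"})
        assert [r.nt_probnp for r in rows] == [100.0, 900.0]

    def test_tab_delimiter_detected(self, tmp_path):
        path = tmp_path / "tabs.tsv"
        path.write_text("id\tntprobnp_pgml\tevent\na\t100\t0\nb\t900\t1\n")
        rows, _ = er.read_cohort(path)
        assert len(rows) == 2
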