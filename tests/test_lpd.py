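"""Tests for LPD-dialect parsing and the extirpation selection criteria."""

import numpy as np
import pytest

from extvortex import lpd
from extvortex.lpd import (
    COUNTRY_AGGREGATE,
    GAP_GT_1YR,
    INTERIOR_ZERO,
    PREFIX_OBS_LT_5,
    SPAN_LT_10,
    TERMINAL_ZEROS_LE_1,
    LpdParseError,
    LpdValidationError,
    apply_selection_criteria,
    derive_yte,
    parse_lpd_table,
    scale_abundance,
    write_lpd_table,
)

from conftest import make_series


class TestParsing:
    def test_blank_and_na_cells_become_missing_years(self, tmp_path):
        csv = tmp_path / "t.csv"
        csv.write_text(
            "ID,Binomial,Class,Country_aggregate,Units,2000,2001,2002,2003,2004\n"
            "p1,Aquila exempli,Aves,0,count,5,,3,0,0\n"
        )
        (series,) = parse_lpd_table(csv)
        assert series.observations == {2000: 5.0, 2002: 3.0, 2003: 0.0, 2004: 0.0}
        assert 2001 not in series.observations

    def test_row_without_observations_is_rejected(self, tmp_path):
        csv = tmp_path / "t.csv"
        csv.write_text(
            "ID,Binomial,2000,2001\n"
            "p1,Aquila exempli,,\n"
        )
        with pytest.raises(LpdValidationError, match="no observations"):
            parse_lpd_table(csv)

    def test_negative_abundance_names_the_row(self, tmp_path):
        csv = tmp_path / "t.csv"
        csv.write_text("ID,Binomial,2000,2001\np9,Aquila exempli,5,-1\n")
        with pytest.raises(LpdValidationError, match="p9"):
            parse_lpd_table(csv)

    def test_header_without_year_columns_is_a_parse_error(self, tmp_path):
        csv = tmp_path / "t.csv"
        csv.write_text("ID,Binomial,alpha,beta\np1,x,1,2\n")
        with pytest.raises(LpdParseError, match="year columns"):
            parse_lpd_table(csv)

    def test_three_row_fixture_round_trips(self, tmp_path):
        rows = [
            make_series([10, 9, None, 7, 0, 0], series_id="a", species="Sp a"),
            make_series([4, 4, 4, 2, 1, 0], series_id="b", species="Sp b",
                        is_country_aggregate=True),
            make_series([0.5, 0.25, 0.125, None, None, 0], series_id="c", species="Sp c"),
        ]
        path = tmp_path / "wide.csv"
        write_lpd_table(rows, path)
        back = parse_lpd_table(path)
        assert len(back) == 3
        for orig, rt in zip(rows, back):
            assert rt.series_id == orig.series_id
            assert rt.species_binomial == orig.species_binomial
            assert rt.is_country_aggregate == orig.is_country_aggregate
            assert rt.observations == orig.observations
        # writing again is bit-identical
        path2 = tmp_path / "wide2.csv"
        write_lpd_table(back, path2)
        assert path.read_bytes() == path2.read_bytes()


class TestSelectionCriteria:
    def test_clean_extirpation_series_is_accepted(self, accepted_series):
        report = apply_selection_criteria(accepted_series)
        assert report.accepted and report.failed_criteria == []

    @pytest.mark.parametrize(
        "values, expected",
        [
            ([3, 2, 1, 0, 5, 2, 1, 0, 0], INTERIOR_ZERO),
            ([9, 8, 7, 6, 5, 4, 3, 2, 1, 2, 0], TERMINAL_ZEROS_LE_1),
            # last nonzero 2005, first zero 2007 (2006 missing)
            ([9, 8, 7, 6, 5, 4, None, 0, 0], GAP_GT_1YR),
            ([9, 8, 7, 6, 5, 4, 3, 0, 0], SPAN_LT_10),
            ([9, None, None, None, None, None, None, 5, 4, 3, 0, 0], PREFIX_OBS_LT_5),
        ],
    )
    def test_each_violation_is_reported(self, values, expected):
        report = apply_selection_criteria(make_series(values))
        assert not report.accepted
        assert expected in report.failed_criteria

    def test_country_aggregates_are_excluded(self, accepted_series):
        agg = make_series(accepted_series.values, is_country_aggregate=True)
        report = apply_selection_criteria(agg)
        assert report.failed_criteria == [COUNTRY_AGGREGATE]

    def test_all_failures_reported_not_just_first(self):
        report = apply_selection_criteria(
            make_series([5, 4, 3, 0, 0], is_country_aggregate=True)
        )
        assert set(report.failed_criteria) >= {COUNTRY_AGGREGATE, PREFIX_OBS_LT_5,
                                               SPAN_LT_10}

    def test_filter_is_idempotent_on_accepted_series(self, accepted_series):
        fs = derive_yte(accepted_series)
        again = apply_selection_criteria(fs.base)
        assert again.accepted


class TestYearsToExtinction:
    def test_yte_counts_backward_from_first_zero(self):
        s = make_series([9, 8, 7, 6, 5, 4, 3, 2.5, 0, 0], start_year=2000)
        # extend to satisfy span: 2000..2010 with zero run at 2008
        s = make_series([9, 8, 7, 6, 5, 4, 3, 2.5, 2, 1.5, 1, 0, 0], start_year=2000)
        fs = derive_yte(s)
        assert fs.extinction_year == 2011
        assert fs.yte[2000] == 11
        assert fs.yte[2010] == 1
        assert fs.yte[2011] == 0
        assert fs.yte[2012] == -1  # post-extinction zero flagged out of analysis
        assert 2012 not in fs.analysis_years

    def test_extinction_year_is_first_of_terminal_run(self, accepted_series):
        fs = derive_yte(accepted_series)
        assert fs.extinction_year == 2010
        assert fs.span_years == 10

    def test_missing_years_stay_missing(self):
        s = make_series([9, 8, 7, None, 5, 4, 3, 2, 2, 1, 1, 0, 0])
        fs = derive_yte(s)
        assert 2003 not in fs.yte

    def test_rejected_series_is_a_contract_violation(self):
        with pytest.raises(ValueError, match="rejected"):
            derive_yte(make_series([5, 4, 3, 0, 0]))

    def test_yte_bijection_over_analysis_years(self, small_study):
        for series in small_study.series:
            fs = derive_yte(series)
            ytes = [fs.yte[y] for y in fs.analysis_years]
            assert len(set(ytes)) == len(ytes)
            assert all(0 <= v <= fs.span_years for v in ytes)


class TestScaling:
    @pytest.mark.parametrize(
        "prefix, values, expected",
        [
            ([60, 55, 50, 45, 40, 35, 30, 25, 20], [100, 50, 0, 0],
             [1.0, 0.5, 0.0, 0.0]),
            ([4, 4, 3, 3, 2, 2, 1, 1, 1], [5, 5, 0, 0],
             [1.0, 1.0, 0.0, 0.0]),
        ],
    )
    def test_divide_by_maximum(self, prefix, values, expected):
        fs = scale_abundance(derive_yte(make_series(prefix + values)))
        years = sorted(fs.scaled_abundance)
        scaled_tail = [fs.scaled_abundance[y] for y in years[-len(values):]]
        np.testing.assert_allclose(scaled_tail, expected)

    def test_scaled_values_span_zero_to_one(self, accepted_series):
        fs = scale_abundance(derive_yte(accepted_series))
        vals = list(fs.scaled_abundance.values())
        assert max(vals) == 1.0 and min(vals) == 0.0

    def test_missing_years_not_imputed(self):
        s = make_series([9, 8, 7, None, 5, 4, 3, 2, 2, 1, 1, 0, 0])
        fs = scale_abundance(derive_yte(s))
        assert 2003 not in fs.scaled_abundance

    def test_invariant_to_positive_rescaling(self, accepted_series, rng):
        base = scale_abundance(derive_yte(accepted_series))
        for factor in rng.uniform(0.01, 500.0, size=5):
            scaled = make_series(
                [v * factor for v in accepted_series.values]
            )
            fs = scale_abundance(derive_yte(scaled))
            np.testing.assert_allclose(
                list(fs.scaled_abundance.values()),
                list(base.scaled_abundance.values()),
                rtol=1e-12,
            )

    def test_all_zero_series_is_degenerate(self):
        s = make_series([5, 4, 3, 2, 1, 1, 1, 1, 1, 1, 0, 0])
        fs = derive_yte(s)
        fs.base.observations = {y: 0.0 for y in fs.base.observations}
        with pytest.raises(ValueError, match="degenerate"):
            scale_abundance(fs)


def test_every_synthetic_series_passes_all_criteria(small_study):
    for series in small_study.series:
        report = apply_selection_criteria(series)
        assert report.accepted, (series.series_id, report.failed_criteria)
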