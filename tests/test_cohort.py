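import numpy as np
import pandas as pd
import pytest

import bioage as ba
from bioage.cohort import ColumnConfigError, EmptyCohortError

from conftest import make_cohort

CSV = """id,ca,bm_a,bm_b,bm_c,years,died
a,45,1.2,3.4,5.6,10,0
b,52,2.3,4.5,6.7,8,1
c,61,3.4,5.6,7.8,12,0
d,38,4.5,6.7,8.9,15,1
e,70,5.6,7.8,9.1,20,0
"""


@pytest.fixture
def toy_csv(tmp_path):
    p = tmp_path / "toy.csv"
    p.write_text(CSV)
    return p


@pytest.fixture
def toy_config():
    return ba.ColumnConfig(
        age="ca", duration="years", event="died", markers=["bm_a", "bm_b", "bm_c"], subject_id="id"
    )


def test_read_parses_rows_and_markers(toy_csv, toy_config):
    cohort = ba.read_cohort(toy_csv, toy_config)
    assert cohort.n == 5 and cohort.n_markers == 3
    # file order preserved, no filtering applied
    assert list(cohort.subject_id) == ["a", "b", "c", "d", "e"]
    assert cohort.age[0] == 45 and cohort.dead[1] == 1


def test_missing_mapped_column_names_the_role(toy_csv):
    config = ba.ColumnConfig(age="agecol", duration="years", event="died", markers=["bm_a"])
    with pytest.raises(ColumnConfigError, match="agecol"):
        ba.read_cohort(toy_csv, config)


def test_unparseable_cell_reports_row(tmp_path, toy_config):
    p = tmp_path / "bad.csv"
    p.write_text(CSV.replace("2.3", "oops"))
    with pytest.raises(ba.cohort.CohortParseError, match="bm_a") as exc:
        ba.read_cohort(p, toy_config)
    assert exc.value.rows == [1]


def test_write_read_round_trip(tmp_path, toy_csv, toy_config):
    cohort = ba.read_cohort(toy_csv, toy_config)
    out = tmp_path / "round.csv"
    ba.write_cohort(cohort, out)
    cfg2 = ba.ColumnConfig(
        age="age",
        duration="duration",
        event="dead",
        cause_flag="excluded_cause",
        markers=cohort.markers,
        subject_id="subject_id",
    )
    back = ba.read_cohort(out, cfg2)
    np.testing.assert_allclose(back.marker_matrix, cohort.marker_matrix, atol=1e-12)
    np.testing.assert_allclose(back.age, cohort.age, atol=1e-12)


def test_stata_round_trip(tmp_path, toy_csv, toy_config):
    cohort = ba.read_cohort(toy_csv, toy_config)
    p = tmp_path / "toy.dta"
    cohort.data.to_stata(p, write_index=False)
    back = ba.read_cohort(
        p,
        ba.ColumnConfig(
            age="age",
            duration="duration",
            event="dead",
            markers=cohort.markers,
            subject_id="subject_id",
        ),
    )
    np.testing.assert_allclose(back.marker_matrix, cohort.marker_matrix, rtol=1e-6)


def test_log_transform_on_read(tmp_path, toy_csv):
    cfg = ba.ColumnConfig(
        age="ca", duration="years", event="died", markers=["bm_a"], log_markers=["bm_a"]
    )
    cohort = ba.read_cohort(toy_csv, cfg)
    assert cohort.marker_matrix[0, 0] == pytest.approx(np.log(1.2))


def test_config_rejects_empty_markers_and_duplicates():
    with pytest.raises(ColumnConfigError):
        ba.ColumnConfig(age="a", duration="d", event="e", markers=[])
    with pytest.raises(ColumnConfigError):
        ba.ColumnConfig(age="a", duration="a", event="e", markers=["m"])


class TestEligibilityFilters:
    def _cohort(self):
        # hand-tallied 6-row toy: one under-age, one missing marker,
        # one excluded-cause death, three clean (one ordinary death)
        return make_cohort(
            age=[29, 45, 50, 55, 60, 65],
            markers={"m1": [1, 2, np.nan, 4, 5, 6], "m2": [1, 2, 3, 4, 5, 6]},
            duration=[5, 10, 10, 7, 8, 9],
            dead=[0, 0, 1, 1, 1, 0],
            excluded=[0, 0, 0, 1, 0, 0],
        )

    def test_age_window_drop_counted(self):
        out, rep = ba.apply_eligibility_filters(self._cohort(), 30, 75)
        assert rep.dropped_age == 1 and 29 not in out.age

    def test_incomplete_marker_drop_counted(self):
        out, rep = ba.apply_eligibility_filters(self._cohort(), 30, 75)
        assert rep.dropped_incomplete == 1
        assert not np.isnan(out.marker_matrix).any()

    def test_excluded_cause_death_censored_not_deleted(self):
        out, rep = ba.apply_eligibility_filters(self._cohort(), 30, 75)
        # survivor tally: of 4 retained subjects, the excluded-cause death
        # at age 55 is kept but recoded censored -> exactly 1 death remains
        assert out.n == 4
        assert rep.recoded_censored == 1
        assert out.dead.sum() == 1
        row = out.data[out.data["age"] == 55].iloc[0]
        assert row["dead"] == 0 and row["duration"] == 7

    def test_excluded_cause_drop_mode(self):
        out, rep = ba.apply_eligibility_filters(self._cohort(), 30, 75, "drop")
        assert out.n == 3 and rep.dropped_excluded_cause == 1

    def test_drop_counts_sum_to_n_difference(self):
        _, rep = ba.apply_eligibility_filters(self._cohort(), 30, 75, "drop")
        total = rep.dropped_age + rep.dropped_incomplete + rep.dropped_excluded_cause
        assert total == rep.n_in - rep.n_out

    def test_filtering_is_idempotent(self):
        once, _ = ba.apply_eligibility_filters(self._cohort(), 30, 75)
        twice, rep2 = ba.apply_eligibility_filters(once, 30, 75)
        pd.testing.assert_frame_equal(once.data, twice.data)
        assert rep2.n_in == rep2.n_out

    def test_empty_result_raises(self):
        with pytest.raises(EmptyCohortError):
            ba.apply_eligibility_filters(self._cohort(), 90, 99)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            ba.apply_eligibility_filters(self._cohort(), 75, 30)


def test_negative_duration_rejected():
    with pytest.raises(ba.cohort.CohortError):
        make_cohort(age=[50], markers={"m": [1.0]}, duration=[-1.0])
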