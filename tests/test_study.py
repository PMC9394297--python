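"""Study-table domain types, validation, and CSV round-tripping."""

import pytest

import isobolab as ib
from isobolab.errors import ValidationError

from conftest import make_timecourse


class TestDomainInvariants:
    def test_dose_spec_rejects_negative_dose(self):
        with pytest.raises(ValidationError):
            ib.DoseSpec("IBU", -1.0, ib.DoseUnit.MG_PER_KG, ib.Route.SYSTEMIC)

    def test_vehicle_control_must_be_drug_free(self):
        dose = ib.DoseSpec("IBU", 1.0, ib.DoseUnit.MG_PER_KG, ib.Route.SYSTEMIC)
        with pytest.raises(ValidationError):
            ib.TreatmentArm("control", (dose,), ib.ArmRole.VEHICLE_CONTROL, 6)

    def test_combination_needs_two_drugs(self):
        dose = ib.DoseSpec("IBU", 1.0, ib.DoseUnit.MG_PER_KG, ib.Route.SYSTEMIC)
        with pytest.raises(ValidationError):
            ib.TreatmentArm("comb", (dose,), ib.ArmRole.COMBINATION, 6)

    def test_timecourse_times_strictly_increasing(self):
        with pytest.raises(ValidationError):
            ib.TimeCourse("s1", "a", ((5, 1), (5, 2)))

    def test_timecourse_rejects_negative_count(self):
        with pytest.raises(ValidationError):
            ib.TimeCourse("s1", "a", ((5, 1), (10, -2)))

    def test_study_requires_exactly_one_control(self, tiny_study):
        arms = [a for a in tiny_study.arms.values() if a.role is not ib.ArmRole.VEHICLE_CONTROL]
        with pytest.raises(ValidationError, match="vehicle_control"):
            ib.study_from_records(arms, [tc for tc in tiny_study.timecourses if tc.arm != "control"])

    def test_study_rejects_unknown_arm_reference(self, tiny_study):
        stray = make_timecourse("x1", "ghost", [0] * 12)
        with pytest.raises(ValidationError, match="ghost"):
            ib.study_from_records(tiny_study.arms.values(), list(tiny_study.timecourses) + [stray])


class TestRoundTrip:
    def test_fixture_loads_with_all_timecourses(self, tiny_study, tmp_path):
        ib.write_study(tiny_study, tmp_path / "tc.csv", tmp_path / "arms.csv")
        back = ib.read_study(tmp_path / "tc.csv", tmp_path / "arms.csv")
        assert len(back.timecourses) == 4

    def test_read_write_identity(self, tiny_study, tmp_path):
        """read(write(study)) == study field-wise, twice over."""
        ib.write_study(tiny_study, tmp_path / "tc.csv", tmp_path / "arms.csv")
        once = ib.read_study(tmp_path / "tc.csv", tmp_path / "arms.csv")
        assert once == tiny_study
        ib.write_study(once, tmp_path / "tc2.csv", tmp_path / "arms2.csv")
        twice = ib.read_study(tmp_path / "tc2.csv", tmp_path / "arms2.csv")
        assert twice == once

    def test_round_trip_preserves_combination_arms(self, tmp_path):
        sim = ib.simulate_study(
            ib.default_paper_config(n_per_arm=2), ib.default_paper_design(2)
        )
        ib.write_study(sim.study, tmp_path / "tc.csv", tmp_path / "arms.csv")
        back = ib.read_study(tmp_path / "tc.csv", tmp_path / "arms.csv")
        assert back == sim.study

    def test_write_refuses_empty_study(self, tiny_study, tmp_path):
        tiny_study.timecourses.clear()
        with pytest.raises(ValidationError, match="no timecourses"):
            ib.write_study(tiny_study, tmp_path / "tc.csv", tmp_path / "arms.csv")

    def test_written_headers_match_schema(self, tiny_study, tmp_path):
        ib.write_study(tiny_study, tmp_path / "tc.csv", tmp_path / "arms.csv")
        assert (tmp_path / "tc.csv").read_text().splitlines()[0] == "subject,arm,time_min,count"
        header = (tmp_path / "arms.csv").read_text().splitlines()[0]
        assert header.startswith("arm,role,n,drug1,dose1,unit1,route1")


class TestFileValidation:
    @pytest.fixture
    def csv_pair(self, tiny_study, tmp_path):
        tc, arms = tmp_path / "tc.csv", tmp_path / "arms.csv"
        ib.write_study(tiny_study, tc, arms)
        return tc, arms

    def test_missing_column_is_named(self, csv_pair, tmp_path):
        tc, arms = csv_pair
        lines = tc.read_text().splitlines()
        lines[0] = "subject,arm,time_min"
        bad = tmp_path / "bad.csv"
        bad.write_text("\n".join(",".join(l.split(",")[:3]) for l in lines))
        with pytest.raises(ValidationError, match="count"):
            ib.read_study(bad, arms)

    def test_missing_file(self, csv_pair, tmp_path):
        with pytest.raises(ValidationError, match="does not exist"):
            ib.read_study(tmp_path / "nope.csv", csv_pair[1])

    @pytest.mark.parametrize(
        "column,value,message",
        [
            ("count", "-3", "negative count"),
            ("count", "2.5", "non-integer count"),
            ("arm", "ghost", "ghost"),
            ("time_min", "not-a-time", "time_min"),
        ],
    )
    def test_corrupted_timecourse_cell_names_row(
        self, csv_pair, tmp_path, column, value, message
    ):
        """Every single-cell corruption is rejected with row context."""
        tc, arms = csv_pair
        lines = tc.read_text().splitlines()
        cols = lines[0].split(",")
        cells = lines[5].split(",")
        cells[cols.index(column)] = value
        lines[5] = ",".join(cells)
        bad = tmp_path / "corrupt.csv"
        bad.write_text("\n".join(lines))
        with pytest.raises(ValidationError, match=message) as err:
            ib.read_study(bad, arms)
        assert "row 6" in str(err.value)

    def test_duplicate_subject_time_rejected(self, csv_pair, tmp_path):
        tc, arms = csv_pair
        lines = tc.read_text().splitlines()
        lines.append(lines[1])
        bad = tmp_path / "dup.csv"
        bad.write_text("\n".join(lines))
        with pytest.raises(ValidationError, match="duplicate"):
            ib.read_study(bad, arms)

    @pytest.mark.parametrize(
        "column,value",
        [("role", "not_a_role"), ("n", "0"), ("dose1", "-4"), ("unit1", "furlongs")],
    )
    def test_corrupted_arm_cell_rejected(self, csv_pair, tmp_path, column, value):
        tc, arms = csv_pair
        lines = arms.read_text().splitlines()
        cols = lines[0].split(",")
        cells = lines[2].split(",")  # the dosed arm's row
        cells[cols.index(column)] = value
        lines[2] = ",".join(cells)
        bad = tmp_path / "corrupt_arms.csv"
        bad.write_text("\n".join(lines))
        with pytest.raises(ValidationError):
            ib.read_study(tc, bad)

    def test_study_without_control_arm_rejected(self, csv_pair, tmp_path):
        tc, arms = csv_pair
        lines = arms.read_text().splitlines()
        lines[1] = lines[1].replace("vehicle_control", "monotherapy")
        bad = tmp_path / "noctl.csv"
        bad.write_text("\n".join(lines))
        with pytest.raises(ValidationError, match="vehicle_control"):
            ib.read_study(tc, bad)
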