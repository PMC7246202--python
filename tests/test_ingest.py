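"""Study-table parsing, CO2 category binning and arm resolution."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oameta.ingest import (
    AMBIENT_MARKER,
    DEFAULT_CATEGORIES,
    RowValidationError,
    SchemaError,
    StudyRecord,
    TreatmentArm,
    assign_co2_category,
    identify_ambient,
    parse_study_table,
    select_arm_for_category,
    write_study_table,
)

HEADER = (
    "study_id,experiment_id,species,group,trophic_level,response_name,"
    "direction,community_flag,duration_days,costressors_ambient,is_control,"
    "co2_uatm,mean,se,n,q1,median,q3\n"
)


def _write(tmp_path, body):
    path = tmp_path / "table.csv"
    path.write_text(HEADER + body)
    return path


class TestParse:
    def test_three_rows_one_record(self, tmp_path):
        body = (
            "s1,e1,sp,phytoplankton,autotroph,chlorophyll_a,higher_is_better,"
            "single_species,14,true,true,400,100,5,6,,,\n"
            "s1,e1,sp,phytoplankton,autotroph,chlorophyll_a,higher_is_better,"
            "single_species,14,true,false,900,80,5,6,,,\n"
            "s1,e1,sp,phytoplankton,autotroph,chlorophyll_a,higher_is_better,"
            "single_species,14,true,false,1250,70,5,6,,,\n"
        )
        records = parse_study_table(_write(tmp_path, body))
        assert len(records) == 1
        assert len(records[0].arms) == 3
        assert records[0].arms[0].is_control

    def test_quartile_branch(self, tmp_path):
        body = (
            "s1,e1,sp,invertebrate,heterotroph,shell_state,higher_is_worse,"
            "single_species,20,true,true,400,,,8,90,100,112\n"
            "s1,e1,sp,invertebrate,heterotroph,shell_state,higher_is_worse,"
            "single_species,20,true,false,1800,,,8,60,72,85\n"
        )
        (rec,) = parse_study_table(_write(tmp_path, body))
        arm = rec.arms[0]
        assert arm.mean is None and arm.has_quartiles
        assert (arm.q1, arm.median, arm.q3) == (90.0, 100.0, 112.0)

    def test_non_numeric_n_names_row(self, tmp_path):
        body = (
            "s1,e1,sp,fish,heterotroph,survival,higher_is_better,"
            "single_species,10,true,true,400,1,0.1,three,,,\n"
            "s1,e1,sp,fish,heterotroph,survival,higher_is_better,"
            "single_species,10,true,false,900,0.8,0.1,6,,,\n"
        )
        with pytest.raises(RowValidationError, match="row 2.*'n'"):
            parse_study_table(_write(tmp_path, body))

    def test_missing_column_is_schema_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("study_id,mean\ns1,3\n")
        with pytest.raises(SchemaError, match="required column"):
            parse_study_table(path)

    def test_schema_config_renames_columns(self, tmp_path):
        path = tmp_path / "renamed.csv"
        path.write_text(
            HEADER.replace("co2_uatm", "pCO2")
            + "s1,e1,sp,bacteria,prokaryote,abundance,higher_is_better,"
            "community,7,true,true,390,10,1,3,,,\n"
            "s1,e1,sp,bacteria,prokaryote,abundance,higher_is_better,"
            "community,7,true,false,950,14,1,3,,,\n"
        )
        records = parse_study_table(path, schema_config={"co2_uatm": "pCO2"})
        assert records[0].arms[1].co2_uatm == 950.0

    def test_group_trophic_mismatch_rejected(self, tmp_path):
        body = (
            "s1,e1,sp,fish,autotroph,survival,higher_is_better,"
            "single_species,10,true,true,400,1,0.1,3,,,\n"
            "s1,e1,sp,fish,autotroph,survival,higher_is_better,"
            "single_species,10,true,false,900,1,0.1,3,,,\n"
        )
        with pytest.raises(RowValidationError, match="inconsistent"):
            parse_study_table(_write(tmp_path, body))


def test_round_trip_preserves_fields(tmp_path, simple_record):
    write_study_table([simple_record], tmp_path / "rt.csv")
    (back,) = parse_study_table(tmp_path / "rt.csv")
    assert back == simple_record
    # And a second write is byte-identical.
    write_study_table([back], tmp_path / "rt2.csv")
    assert (tmp_path / "rt.csv").read_bytes() == (tmp_path / "rt2.csv").read_bytes()


class TestCategoryAssignment:
    @pytest.mark.parametrize(
        "co2,expected",
        [
            (900.0, "c801_1000"),
            (2500.0, "gt2000"),
            (400.0, AMBIENT_MARKER),
            (650.0, "c500_800"),
            (1000.0, "c801_1000"),  # boundary is half-open: (800, 1000]
            (1000.5, "c1001_1500"),
            (180.0, "preindustrial"),
            (2000.0, "c1501_2000"),
        ],
    )
    def test_examples(self, co2, expected):
        assert assign_co2_category(co2, 400.0) == expected

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            assign_co2_category(0.0, 400.0)

    @given(co2=st.floats(min_value=1.0, max_value=5000.0))
    @settings(max_examples=300, deadline=None)
    def test_partition(self, co2):
        """Every positive level maps to exactly one marker/category."""
        label = assign_co2_category(co2, 400.0)
        assert label in {AMBIENT_MARKER} | {c.label for c in DEFAULT_CATEGORIES}


def _arm(co2, control=False):
    return TreatmentArm(co2_uatm=co2, mean=1.0, se=0.1, n=3, is_control=control)


class TestArmSelection:
    def test_highest_wins_in_elevated_category(self):
        arms = [_arm(850.0), _arm(950.0)]
        assert select_arm_for_category(arms, "c801_1000").co2_uatm == 950.0

    def test_lowest_wins_in_preindustrial(self):
        arms = [_arm(180.0), _arm(280.0)]
        assert select_arm_for_category(arms, "preindustrial").co2_uatm == 180.0

    def test_single_arm(self):
        arms = [_arm(700.0)]
        assert select_arm_for_category(arms, "c500_800") is arms[0]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_arm_for_category([], "c500_800")

    @given(st.permutations([650.0, 700.0, 750.0, 799.0]))
    @settings(max_examples=24, deadline=None)
    def test_order_independent(self, levels):
        arms = [_arm(c) for c in levels]
        assert select_arm_for_category(arms, "c500_800").co2_uatm == 799.0


class TestIdentifyAmbient:
    def test_flagged_control_wins(self):
        arms = [_arm(390.0, control=True), _arm(380.0)]
        assert identify_ambient(arms).co2_uatm == 390.0

    def test_closest_to_reference(self):
        arms = [_arm(410.0), _arm(750.0), _arm(1100.0)]
        assert identify_ambient(arms, 400.0).co2_uatm == 410.0

    def test_tie_breaks_toward_lower_co2(self):
        arms = [_arm(430.0), _arm(370.0)]
        assert identify_ambient(arms, 400.0).co2_uatm == 370.0


class TestArmValidation:
    def test_both_summaries_rejected(self):
        with pytest.raises(ValueError, match="exactly one"):
            TreatmentArm(co2_uatm=400, mean=1.0, se=0.1, n=3, q1=1, median=2, q3=3)

    def test_neither_summary_rejected(self):
        with pytest.raises(ValueError, match="exactly one"):
            TreatmentArm(co2_uatm=400, n=3)

    def test_ph_without_aux_rejected(self):
        with pytest.raises(ValueError, match="auxiliary"):
            TreatmentArm(ph=8.0, mean=1.0, se=0.1, n=3)

    def test_two_controls_rejected(self, simple_record):
        arms = [
            TreatmentArm(co2_uatm=400, mean=1, se=0.1, n=3, is_control=True),
            TreatmentArm(co2_uatm=900, mean=1, se=0.1, n=3, is_control=True),
        ]
        with pytest.raises(ValueError, match="control"):
            StudyRecord(**{**simple_record.model_dump(exclude={"arms"}), "arms": arms})
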