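"""Table reading, joining, unit conversion and two-stage deduplication."""

from datetime import date

import pytest
from hypothesis import given, settings, strategies as st

from faersig.ingest import (
    deduplicate,
    filter_primary_suspect,
    parse_faers_date,
    read_quarter,
)
from faersig.synth import SyntheticConfig, generate

from conftest import make_report, write_quarter


class TestReadQuarter:
    def test_empty_demo_yields_empty_collection(self, quarter_writer):
        paths = quarter_writer(demo_rows=[], drug_rows=[], reac_rows=[])
        result = read_quarter(**paths)
        assert result.reports == []
        assert result.log.count() == 0

    def test_missing_file_is_fatal(self, tmp_path):
        paths = write_quarter(tmp_path, demo_rows=[], drug_rows=[], reac_rows=[])
        paths["reac_path"].unlink()
        with pytest.raises(FileNotFoundError):
            read_quarter(**paths)

    def test_orphan_drug_row_logged_not_joined(self, quarter_writer):
        paths = quarter_writer(
            demo_rows=[{"primaryid": "1", "caseid": "1", "fda_dt": "20200101"}],
            drug_rows=[
                {"primaryid": "1", "drug_seq": "1", "role_cod": "PS", "drugname": "X"},
                {"primaryid": "99", "drug_seq": "1", "role_cod": "PS", "drugname": "Y"},
            ],
            reac_rows=[{"primaryid": "1", "pt": "Osteoporosis"}],
        )
        result = read_quarter(**paths)
        assert len(result.reports) == 1
        assert result.log.count("orphan") == 1

    def test_demo_without_reaction_excluded_and_counted(self, quarter_writer):
        paths = quarter_writer(
            demo_rows=[
                {"primaryid": "1", "caseid": "1", "fda_dt": "20200101"},
                {"primaryid": "2", "caseid": "2", "fda_dt": "20200101"},
            ],
            drug_rows=[
                {"primaryid": "1", "drug_seq": "1", "role_cod": "PS", "drugname": "X"},
                {"primaryid": "2", "drug_seq": "1", "role_cod": "PS", "drugname": "X"},
            ],
            reac_rows=[{"primaryid": "1", "pt": "Osteoporosis"}],
        )
        result = read_quarter(**paths)
        assert [r.primary_id for r in result.reports] == ["1"]
        assert result.log.count("no joinable REAC") == 1

    def test_age_and_weight_unit_conversion(self, quarter_writer):
        paths = quarter_writer(
            demo_rows=[
                {"primaryid": "1", "caseid": "1", "fda_dt": "20200101",
                 "age": "600", "age_cod": "MON", "wt": "154.324", "wt_cod": "LBS"},
                {"primaryid": "2", "caseid": "2", "fda_dt": "20200101",
                 "age": "6", "age_cod": "DEC"},
                {"primaryid": "3", "caseid": "3", "fda_dt": "20200101",
                 "age": "44", "age_cod": "XYZ"},
            ],
            drug_rows=[
                {"primaryid": p, "drug_seq": "1", "role_cod": "PS", "drugname": "X"}
                for p in "123"
            ],
            reac_rows=[{"primaryid": p, "pt": "Osteoporosis"} for p in "123"],
        )
        result = read_quarter(**paths)
        by_pid = {r.primary_id: r for r in result.reports}
        assert by_pid["1"].age_years == pytest.approx(50.0)
        assert by_pid["1"].weight_kg == pytest.approx(70.0, abs=0.01)
        assert by_pid["2"].age_years == pytest.approx(60.0)
        assert by_pid["3"].age_years is None  # unknown unit -> missing
        assert result.log.count("unknown age unit") == 1

    def test_partial_dates_completed_to_first(self):
        assert parse_faers_date("202006") == (date(2020, 6, 1), True)
        assert parse_faers_date("2020") == (date(2020, 1, 1), True)
        assert parse_faers_date("20200615") == (date(2020, 6, 15), False)
        assert parse_faers_date("") == (None, False)
        assert parse_faers_date("20201345") == (None, False)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_round_trip_of_generator_output(self, tmp_path, seed):
        """Written files read back field-for-field equal to in-memory truth."""
        config = SyntheticConfig(n_reports=300, seed=seed)
        dataset = generate(config)
        paths = dataset.write(tmp_path / f"q{seed}")
        result = read_quarter(
            paths["demo"], paths["drug"], paths["reac"], paths["ther"], paths["outc"]
        )
        truth = {r.primary_id: r for r in dataset.to_reports()}
        assert len(result.reports) == len(truth)
        assert result.log.count() == 0
        for report in result.reports:
            assert report == truth[report.primary_id]


class TestDeduplicate:
    def test_all_distinct_input_unchanged(self):
        reports = [make_report(pid=str(i), age=20.0 + i) for i in range(5)]
        assert deduplicate(reports) == sorted(reports, key=lambda r: int(r.primary_id))

    def test_case_version_rule_keeps_greatest_primaryid(self):
        older = make_report(pid="100", case_id="C1")
        newer = make_report(pid="200", case_id="C1", age=60.0)
        assert deduplicate([older, newer]) == [newer]
        assert deduplicate([newer, older]) == [newer]

    def test_six_field_rule_keeps_latest_receipt(self):
        early = make_report(pid="1", case_id="A", receipt=date(2020, 1, 1))
        late = make_report(pid="2", case_id="B", receipt=date(2021, 1, 1))
        assert deduplicate([early, late]) == [late]

    def test_missing_fields_act_as_shared_sentinel(self):
        r1 = make_report(pid="1", case_id="A", event=None, age=None,
                         receipt=date(2020, 1, 1))
        r2 = make_report(pid="2", case_id="B", event=None, age=None,
                         receipt=date(2020, 2, 1))
        assert deduplicate([r1, r2]) == [r2]

    def test_differing_reaction_sets_not_collapsed(self):
        r1 = make_report(pid="1", case_id="A", reactions={"osteoporosis"})
        r2 = make_report(pid="2", case_id="B", reactions={"bone loss"})
        assert len(deduplicate([r1, r2])) == 2

    def test_idempotent_and_never_increasing_on_generated_data(self):
        config = SyntheticConfig(
            n_reports=800, seed=9, duplicate_rate=0.1, six_field_dup_rate=0.05
        )
        reports = generate(config).to_reports()
        once = deduplicate(reports)
        assert len(once) <= len(reports)
        assert deduplicate(once) == once
        # survivors are unaltered members of the input
        originals = {r.primary_id: r for r in reports}
        assert all(originals[r.primary_id] == r for r in once)


_report_strategy = st.builds(
    make_report,
    pid=st.integers(1, 40).map(str),
    case_id=st.integers(1, 20).map(str),
    receipt=st.one_of(st.none(), st.dates(date(2015, 1, 1), date(2024, 1, 1))),
    event=st.one_of(st.none(), st.dates(date(2010, 1, 1), date(2023, 1, 1))),
    sex=st.sampled_from(["male", "female", "unknown"]),
    age=st.one_of(st.none(), st.integers(1, 90).map(float)),
    reactions=st.sets(
        st.sampled_from(["osteoporosis", "bone loss", "headache"]), min_size=1
    ),
)


class TestDeduplicateProperties:
    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.lists(_report_strategy, max_size=25))
    def test_idempotent_never_increasing_fields_unaltered(self, reports):
        once = deduplicate(reports)
        assert len(once) <= len(reports)
        assert deduplicate(once) == once
        for survivor in once:
            assert survivor in reports  # survivors are unaltered input records


class TestFilterPrimarySuspect:
    def test_secondary_suspect_only_is_excluded(self):
        r = make_report(drugs=(("ADEFOVIR", "SS", None),))
        assert filter_primary_suspect([r], "adefovir") == []

    def test_role_rule_on_small_fixture(self):
        reports = [
            make_report(pid="1", drugs=(("DRUG X", "PS", None),)),
            make_report(pid="2", drugs=(("DRUG X", "PS", None), ("OTHER", "C", None))),
            make_report(pid="3", drugs=(("DRUG X", "C", None),)),
            make_report(pid="4", drugs=(("OTHER", "PS", None),)),
            make_report(pid="5", drugs=(("ANOTHER", "I", None),)),
        ]
        hits = filter_primary_suspect(reports, "  drug   x ")
        assert [r.primary_id for r in hits] == ["1", "2"]

    def test_unknown_drug_returns_empty_with_warning(self):
        reports = [make_report()]
        with pytest.warns(UserWarning, match="does not appear"):
            assert filter_primary_suspect(reports, "NOSUCHDRUG") == []

    def test_empty_input(self):
        with pytest.warns(UserWarning):
            assert filter_primary_suspect([], "ADEFOVIR") == []
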