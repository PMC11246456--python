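"""Deduplication, suspect-drug selection, exclusions and summaries."""

import itertools
import random

import pytest
from hypothesis import given
from hypothesis import strategies as st

from pvsignal.cohort import (
    age_band,
    age_in_years,
    apply_exclusions,
    deduplicate,
    proportion_pct,
    restrict_to_soc,
    select_drug_cases,
    summarize_cohort,
    weight_in_kg,
)

from conftest import make_case


def drug_case(caseid, primaryid, fda_dt="20200101", drugname="VIMPAT",
              prod_ai="LACOSAMIDE", role="PS", **kw):
    return make_case(
        primaryid=primaryid, caseid=caseid, fda_dt=fda_dt,
        drugs=[(1, role, drugname, prod_ai)], **kw,
    )


class TestDeduplicate:
    def test_latest_fda_dt_survives(self):
        old = make_case(caseid="X", primaryid="11", fda_dt="20200101")
        new = make_case(caseid="X", primaryid="10", fda_dt="20210101")
        assert deduplicate([old, new]) == [new]

    def test_equal_dates_higher_primaryid_survives(self):
        a = make_case(caseid="X", primaryid="1001", fda_dt="20200101")
        b = make_case(caseid="X", primaryid="1002", fda_dt="20200101")
        assert deduplicate([a, b])[0].primaryid == "1002"

    def test_numeric_not_lexicographic_tiebreak(self):
        a = make_case(caseid="X", primaryid="900", fda_dt="20200101")
        b = make_case(caseid="X", primaryid="1002", fda_dt="20200101")
        assert deduplicate([a, b])[0].primaryid == "1002"

    def test_matches_bruteforce_groupby_oracle(self):
        rng = random.Random(5)
        cases = []
        for cid in range(5):
            for version in range(3):
                cases.append(
                    make_case(
                        caseid=f"C{cid}",
                        primaryid=str(1000 + cid * 10 + version),
                        fda_dt=f"202{rng.randint(0, 2)}0{rng.randint(1, 9)}15",
                    )
                )
        rng.shuffle(cases)
        result = deduplicate(cases)
        assert len(result) == 5
        # oracle: group by caseid, max by (fda_dt, int(primaryid))
        expected = {}
        for caseid, group in itertools.groupby(
            sorted(cases, key=lambda c: c.caseid), key=lambda c: c.caseid
        ):
            expected[caseid] = max(
                group, key=lambda c: (c.demo.fda_dt.sort_key(), int(c.primaryid))
            )
        assert {c.caseid: c.primaryid for c in result} == {
            k: v.primaryid for k, v in expected.items()
        }

    def test_idempotent(self):
        cases = [
            make_case(caseid=f"C{i % 3}", primaryid=str(100 + i),
                      fda_dt=f"2020010{1 + i % 5}")
            for i in range(9)
        ]
        once = deduplicate(cases)
        assert deduplicate(once) == once


class TestSelectDrugCases:
    def test_trade_name_primary_suspect_selected(self, lacosamide_config):
        case = drug_case("1", "11", drugname="VIMPAT", prod_ai="")
        assert select_drug_cases([case], lacosamide_config) == [case]

    def test_concomitant_role_rejected(self, lacosamide_config):
        case = drug_case("1", "11", drugname="", prod_ai="LACOSAMIDE", role="C")
        assert select_drug_cases([case], lacosamide_config) == []

    def test_substring_case_insensitive_match(self, lacosamide_config):
        case = drug_case("1", "11", drugname="lacosamide 50mg tab", prod_ai="")
        assert select_drug_cases([case], lacosamide_config) == [case]

    def test_unrelated_drug_rejected_and_size_bounded(self, lacosamide_config):
        cases = [
            drug_case("1", "11"),
            drug_case("2", "21", drugname="METFORMIN", prod_ai="METFORMIN"),
        ]
        selected = select_drug_cases(cases, lacosamide_config)
        assert [c.caseid for c in selected] == ["1"]
        assert len(selected) <= len(cases)


class TestApplyExclusions:
    def test_excluded_pt_removed_case_kept(self, lacosamide_config):
        case = drug_case("1", "11", pts=["Off label use", "Bradycardia"])
        (kept,) = apply_exclusions([case], lacosamide_config)
        assert kept.pts == ["Bradycardia"]

    def test_case_dropped_when_all_pts_excluded(self, lacosamide_config):
        case = drug_case("1", "11", pts=["Off label use", "Seizure"])
        assert apply_exclusions([case], lacosamide_config) == []

    def test_event_before_start_dropped(self, lacosamide_config):
        case = drug_case(
            "1", "11", pts=["Bradycardia"], event_dt="20200101",
            therapies=[(1, "20200301", None)],
        )
        assert apply_exclusions([case], lacosamide_config) == []

    def test_missing_event_date_retained(self, lacosamide_config):
        case = drug_case(
            "1", "11", pts=["Bradycardia"], event_dt=None,
            therapies=[(1, "20200301", None)],
        )
        assert len(apply_exclusions([case], lacosamide_config)) == 1

    def test_partial_event_date_is_not_date_error_evidence(self, lacosamide_config):
        case = drug_case(
            "1", "11", pts=["Bradycardia"], event_dt="202001",
            therapies=[(1, "20200301", None)],
        )
        assert len(apply_exclusions([case], lacosamide_config)) == 1


class TestRestrictToSoc:
    def test_single_cardiac_pt_counts_one_event(self, lacosamide_config):
        case = drug_case("1", "11", pts=["Bradycardia", "Nausea"])
        kept, events = restrict_to_soc([case], lacosamide_config)
        assert kept == [case] and events == 1

    def test_multi_cardiac_pts_double_counted(self, lacosamide_config):
        case = drug_case(
            "1", "11",
            pts=["Bradycardia", "Cardiac arrest", "Atrial fibrillation"],
        )
        kept, events = restrict_to_soc([case], lacosamide_config)
        assert len(kept) == 1 and events == 3

    def test_no_cardiac_pt_excluded(self, lacosamide_config):
        case = drug_case("1", "11", pts=["Nausea"])
        kept, events = restrict_to_soc([case], lacosamide_config)
        assert kept == [] and events == 0

    def test_unmapped_pt_not_tallied(self, lacosamide_config):
        case = drug_case("1", "11", pts=["Bradycardia", "Mystery reaction"])
        kept, events = restrict_to_soc([case], lacosamide_config)
        assert len(kept) == 1 and events == 1


class TestUnits:
    @pytest.mark.parametrize(
        "age,cod,years",
        [
            (24, "MON", 2.0),
            (6, "DEC", 60.0),
            (730.5, "DY", 2.0),
            (52.18, "WK", 1.0),
            (8766, "HR", 1.0),
            (45, "YR", 45.0),
        ],
    )
    def test_age_conversion(self, age, cod, years):
        assert age_in_years(age, cod) == pytest.approx(years)

    def test_weight_conversion(self):
        assert weight_in_kg(70, "KG") == 70
        assert weight_in_kg(100, "LBS") == pytest.approx(45.36)
        assert weight_in_kg(70, "STONES") is None


class TestSummarize:
    def test_age_bands_and_median(self):
        cases = [make_case(caseid=str(i), primaryid=f"{i}1", age=a)
                 for i, a in enumerate([10.0, 30.0, 70.0])]
        s = summarize_cohort(cases)
        assert s.age_bands == {"<18": 1, "18-64": 1, ">64": 1}
        assert s.age_median_iqr[0] == 30.0

    def test_female_share_percentage(self):
        # 388 female of 734 with known sex -> 52.86%
        assert proportion_pct(388, 734) == pytest.approx(52.86, abs=0.005)

    def test_infant_months_fall_in_youngest_band(self):
        assert age_band(age_in_years(24, "MON")) == "<18"

    def test_band_counts_partition_available_denominators(self):
        rng = random.Random(9)
        cases = []
        for i in range(60):
            cases.append(
                make_case(
                    caseid=str(i), primaryid=f"{i}1",
                    age=rng.choice([None, float(rng.randint(1, 90))]),
                    wt=rng.choice([None, float(rng.randint(30, 130))]),
                    sex=rng.choice(["F", "M", ""]),
                )
            )
        s = summarize_cohort(cases)
        assert sum(s.age_bands.values()) == s.age_available
        assert sum(s.weight_bands.values()) == s.weight_available
        assert sum(s.sex_counts.values()) == s.sex_available


@given(
    st.lists(
        st.tuples(st.integers(0, 4), st.integers(0, 2), st.integers(1, 28)),
        min_size=1,
        max_size=30,
    )
)
def test_dedup_one_survivor_per_caseid_property(spec):
    """Every caseid keeps exactly one version, whatever the input order."""
    cases = [
        make_case(
            caseid=f"C{cid}",
            primaryid=str(1000 + i),
            fda_dt=f"202{vdate % 3}01{day:02d}",
        )
        for i, (cid, vdate, day) in enumerate(spec)
    ]
    result = deduplicate(cases)
    assert sorted({c.caseid for c in cases}) == [c.caseid for c in result]
    assert deduplicate(result) == result
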