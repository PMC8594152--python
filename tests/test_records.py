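"""Cleaning rules: worst diagnosis, grades, dates, ages, transitions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from liabped import clean_records, transition_counts, compute_age, Pedigree


def ped_of(animals, birth="2010-01-01"):
    return Pedigree(
        pd.DataFrame(
            {
                "id": animals,
                "sire": [None] * len(animals),
                "dam": [None] * len(animals),
                "sex": ["female"] * len(animals),
                "birth_date": [birth] * len(animals),
            }
        )
    )


def recs(rows):
    df = pd.DataFrame(rows, columns=["animal", "exam_date", "diagnosis", "grade"])
    df["exam_date"] = pd.to_datetime(df["exam_date"])
    return df


class TestDeduplicate:
    def test_once_affected_stays_affected(self):
        r = recs(
            [
                ("d1", "2012-01-01", "unaffected", "none"),
                ("d1", "2013-01-01", "affected", "none"),
                ("d1", "2014-01-01", "unaffected", "none"),
            ]
        )
        clean, _ = clean_records(r, ped_of(["d1"]))
        assert clean["final_diagnosis"].iloc[0] == "affected"
        assert clean["y"].iloc[0] == 1

    def test_worst_grade_kept(self):
        r = recs(
            [
                ("d1", "2012-01-01", "affected", "mild"),
                ("d1", "2013-01-01", "affected", "moderate"),
            ]
        )
        clean, _ = clean_records(r, ped_of(["d1"]))
        assert clean["final_grade"].iloc[0] == "moderate"

    def test_ungraded_ranks_below_mild(self):
        r = recs(
            [
                ("d1", "2012-01-01", "affected", "none"),
                ("d1", "2013-01-01", "affected", "mild"),
            ]
        )
        clean, _ = clean_records(r, ped_of(["d1"]))
        assert clean["final_grade"].iloc[0] == "mild"

    def test_missing_birth_date_drops_animal(self):
        ped = Pedigree(
            pd.DataFrame(
                {"id": ["d1"], "sire": [None], "dam": [None], "sex": ["male"],
                 "birth_date": [None]}
            )
        )
        r = recs([("d1", "2012-01-01", "unaffected", "none")])
        clean, rep = clean_records(r, ped)
        assert len(clean) == 0
        assert rep.n_removed_missing_birth_date == 1

    def test_undated_records_dropped_animal_kept_if_dated_remains(self):
        r = recs(
            [
                ("d1", None, "affected", "mild"),
                ("d1", "2013-01-01", "unaffected", "none"),
                ("d2", None, "unaffected", "none"),
            ]
        )
        clean, rep = clean_records(r, ped_of(["d1", "d2"]))
        assert list(clean["animal"]) == ["d1"]
        # the undated affected exam cannot be used: d1 ends unaffected
        assert clean["y"].iloc[0] == 0
        assert rep.n_removed_missing_exam_date == 1

    def test_grade_on_unaffected_rejected_with_warning(self):
        r = recs(
            [
                ("d1", "2012-01-01", "unaffected", "mild"),
                ("d1", "2013-01-01", "unaffected", "none"),
            ]
        )
        with pytest.warns(UserWarning, match="grade"):
            clean, rep = clean_records(r, ped_of(["d1"]))
        assert rep.n_rejected_grade_on_unaffected == 1
        assert clean["y"].iloc[0] == 0

    def test_exam_date_anchored_at_first_affected(self):
        r = recs(
            [
                ("d1", "2012-01-01", "unaffected", "none"),
                ("d1", "2014-06-01", "affected", "mild"),
                ("d1", "2015-01-01", "affected", "severe"),
            ]
        )
        clean, _ = clean_records(r, ped_of(["d1"]))
        assert clean["exam_date"].iloc[0] == pd.Timestamp("2014-06-01")
        assert clean["final_grade"].iloc[0] == "severe"

    def test_idempotent_on_own_output(self, small_population):
        clean1, _ = clean_records(
            small_population.records, small_population.pedigree
        )
        again = pd.DataFrame(
            {
                "animal": clean1["animal"],
                "exam_date": clean1["exam_date"],
                "diagnosis": clean1["final_diagnosis"],
                "grade": clean1["final_grade"].where(clean1["y"] == 1, "none"),
            }
        )
        clean2, rep2 = clean_records(again, small_population.pedigree)
        merged = clean1.merge(clean2, on="animal", suffixes=("_1", "_2"))
        assert len(merged) == len(clean1)
        assert (merged["final_diagnosis_1"] == merged["final_diagnosis_2"]).all()
        assert (merged["exam_date_1"] == merged["exam_date_2"]).all()
        assert rep2.n_raw == rep2.n_final

    def test_partition_counts(self, small_population):
        clean, rep = clean_records(small_population.records, small_population.pedigree)
        assert rep.n_final == len(clean)
        assert rep.n_final == (
            rep.n_unique
            - rep.n_removed_missing_exam_date
            - rep.n_removed_missing_birth_date
        )

    @given(st.lists(st.booleans(), min_size=1, max_size=6))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_affected_iff_any_affected_exam(self, flags):
        rows = [
            (
                "d1",
                f"201{k}-01-01",
                "affected" if f else "unaffected",
                "none",
            )
            for k, f in enumerate(flags)
        ]
        clean, _ = clean_records(recs(rows), ped_of(["d1"], birth="2009-06-01"))
        assert clean["y"].iloc[0] == int(any(flags))


class TestTransitions:
    def test_single_exams_no_transitions(self):
        r = recs([("a", "2012-01-01", "affected", "none"),
                  ("b", "2012-01-01", "unaffected", "none")])
        assert transition_counts(r) == (0, 0)

    def test_unaffected_to_affected(self):
        r = recs([("a", "2012-01-01", "unaffected", "none"),
                  ("a", "2013-01-01", "affected", "none")])
        assert transition_counts(r) == (1, 0)

    def test_affected_to_unaffected_uses_first_and_last(self):
        r = recs(
            [
                ("a", "2012-01-01", "affected", "none"),
                ("a", "2013-01-01", "unaffected", "none"),
                ("a", "2014-01-01", "unaffected", "none"),
            ]
        )
        assert transition_counts(r) == (0, 1)


class TestAge:
    def test_same_day(self):
        assert compute_age("2010-01-01", "2010-01-01") == (0, 0.0)

    def test_730_days(self):
        yrs, cont = compute_age("2010-01-01", "2012-01-01")
        assert yrs == 1
        assert cont == pytest.approx(730 / 365.25, abs=1e-9)

    def test_400_days(self):
        yrs, cont = compute_age("2010-01-01", "2011-02-05")
        assert yrs == 1
        assert cont == pytest.approx(400 / 365.25, abs=1e-3)

    def test_exam_before_birth_errors(self):
        with pytest.raises(ValueError, match="precedes"):
            compute_age("2012-01-01", "2010-01-01")
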