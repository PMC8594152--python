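"""Examination-record cleaning.

Raw eye-screening data hold one row per examination; an animal may be
examined many times, with occasionally conflicting diagnoses.  Cleaning
reduces them to one row per animal under the screening scheme's rules:

* once affected = affected — any affected examination makes the final
  diagnosis "affected", the "worst" of conflicting results;
* the final grade is the worst grade ever recorded (mild < moderate <
  severe; affected-but-ungraded ranks below mild);
* undated examinations cannot be ordered and are discarded; an animal is
  dropped (and counted) only if no dated examination remains, or if its
  birth date is missing;
* age at diagnosis is anchored at the first affected examination for
  affected animals, at the first examination otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .pedigree import Pedigree

__all__ = [
    "CleaningReport",
    "clean_records",
    "transition_counts",
    "compute_age",
    "read_records",
]

GRADE_ORDER = {"none": 0, "mild": 1, "moderate": 2, "severe": 3}
GRADE_NAMES = {v: k for k, v in GRADE_ORDER.items()}

DAYS_PER_YEAR = 365.25


@dataclass
class CleaningReport:
    """Bookkeeping for the raw-records -> analysis-set reduction."""

    n_raw: int
    n_unique: int
    n_removed_missing_exam_date: int
    n_removed_missing_birth_date: int
    n_final: int
    n_unaffected_to_affected: int
    n_affected_to_unaffected: int
    n_rejected_grade_on_unaffected: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


def read_records(path, sep: str = ",") -> pd.DataFrame:
    """Read an examination file: columns animal, examdate, diagnosis[, grade]."""
    df = pd.read_csv(path, sep=sep, dtype=str)
    need = {"animal", "examdate", "diagnosis"}
    if not need.issubset(df.columns):
        raise ValueError(f"records file needs columns {sorted(need)}")
    out = pd.DataFrame(
        {
            "animal": df["animal"].astype(str).str.strip(),
            "exam_date": pd.to_datetime(df["examdate"], errors="coerce"),
            "diagnosis": df["diagnosis"].astype(str).str.strip().str.lower(),
            "grade": (
                df["grade"].fillna("none").astype(str).str.strip().str.lower()
                if "grade" in df.columns
                else "none"
            ),
        }
    )
    bad = ~out["diagnosis"].isin(["affected", "unaffected"])
    if bad.any():
        raise ValueError(
            f"unrecognised diagnosis value(s): {sorted(out['diagnosis'][bad].unique())}"
        )
    out.loc[out["grade"].isin(["", "nan", "na"]), "grade"] = "none"
    badg = ~out["grade"].isin(GRADE_ORDER)
    if badg.any():
        raise ValueError(
            f"unrecognised grade value(s): {sorted(out['grade'][badg].unique())}"
        )
    return out


def compute_age(birth: pd.Timestamp, exam: pd.Timestamp) -> tuple[int, float]:
    """(integer years, continuous years) between birth and examination.

    Continuous age is days / 365.25; integer age is its floor.
    """
    birth = pd.Timestamp(birth)
    exam = pd.Timestamp(exam)
    if exam < birth:
        raise ValueError(f"examination date {exam.date()} precedes birth {birth.date()}")
    cont = (exam - birth).days / DAYS_PER_YEAR
    return int(np.floor(cont)), float(cont)


def transition_counts(records: pd.DataFrame) -> tuple[int, int]:
    """First-vs-last diagnosis changes among animals examined >= 2 times.

    Returns (unaffected->affected, affected->unaffected) counts over dated
    examinations only.
    """
    dated = records.dropna(subset=["exam_date"])
    n01 = n10 = 0
    for _, grp in dated.groupby("animal", sort=False):
        if len(grp) < 2:
            continue
        grp = grp.sort_values("exam_date", kind="stable")
        first, last = grp["diagnosis"].iloc[0], grp["diagnosis"].iloc[-1]
        if first == "unaffected" and last == "affected":
            n01 += 1
        elif first == "affected" and last == "unaffected":
            n10 += 1
    return n01, n10


def clean_records(
    records: pd.DataFrame,
    pedigree: Pedigree | pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, CleaningReport]:
    """Reduce raw examinations to a one-row-per-animal analysis set.

    Parameters
    ----------
    records : DataFrame
        Columns ``animal``, ``exam_date``, ``diagnosis`` ({affected,
        unaffected}), ``grade`` ({none, mild, moderate, severe}).
    pedigree : Pedigree or DataFrame, optional
        Source of birth dates and sex (columns ``id``/``birth_date``/``sex``
        or a :class:`Pedigree`).  Without it, animals have no birth date and
        are all removed — pass it.

    Returns
    -------
    (clean, report)
        ``clean`` has one row per retained animal: ``animal``, ``y`` (0/1),
        ``final_diagnosis``, ``final_grade``, ``sex``, ``age_years``,
        ``age_continuous``, ``diagnosis_year``, ``exam_date``,
        ``birth_date``.  ``report`` is a :class:`CleaningReport`.
    """
    if records.empty:
        raise ValueError("no examination records supplied")
    rec = records.copy()
    n_raw = len(rec)

    n_bad_grade = int(((rec["diagnosis"] == "unaffected") & (rec["grade"] != "none")).sum())
    if n_bad_grade:
        warnings.warn(
            f"{n_bad_grade} record(s) carry a grade on an 'unaffected' diagnosis; rejected",
            stacklevel=2,
        )
        rec = rec[~((rec["diagnosis"] == "unaffected") & (rec["grade"] != "none"))]

    n_unique = rec["animal"].nunique()
    n01, n10 = transition_counts(rec)

    # undated records cannot be ordered: discard them, drop the animal only
    # if nothing dated remains
    dated = rec.dropna(subset=["exam_date"])
    animals_all = set(rec["animal"])
    animals_dated = set(dated["animal"])
    n_removed_exam = len(animals_all - animals_dated)

    if pedigree is None:
        meta = pd.DataFrame(columns=["animal", "birth_date", "sex"])
    elif isinstance(pedigree, Pedigree):
        meta = pedigree.table.rename(columns={"id": "animal"})[
            ["animal", "birth_date", "sex"]
        ]
    else:
        meta = pedigree.rename(columns={"id": "animal"})[["animal", "birth_date", "sex"]]
        meta = meta.assign(birth_date=pd.to_datetime(meta["birth_date"], errors="coerce"))

    rows = []
    n_removed_birth = 0
    for animal, grp in dated.groupby("animal", sort=False):
        grp = grp.sort_values("exam_date", kind="stable")
        affected = (grp["diagnosis"] == "affected").any()
        if affected:
            aff = grp[grp["diagnosis"] == "affected"]
            exam_date = aff["exam_date"].iloc[0]
            grade = GRADE_NAMES[max(GRADE_ORDER[g] for g in aff["grade"])]
        else:
            exam_date = grp["exam_date"].iloc[0]
            grade = "none"
        m = meta[meta["animal"] == animal]
        birth = m["birth_date"].iloc[0] if len(m) else pd.NaT
        sex = m["sex"].iloc[0] if len(m) else "unknown"
        if pd.isna(birth):
            n_removed_birth += 1
            continue
        age_years, age_cont = compute_age(birth, exam_date)
        rows.append(
            {
                "animal": animal,
                "final_diagnosis": "affected" if affected else "unaffected",
                "y": int(affected),
                "final_grade": grade,
                "sex": sex,
                "age_years": age_years,
                "age_continuous": age_cont,
                "diagnosis_year": int(exam_date.year),
                "exam_date": exam_date,
                "birth_date": birth,
            }
        )

    clean = pd.DataFrame(rows).reset_index(drop=True)
    report = CleaningReport(
        n_raw=n_raw,
        n_unique=n_unique,
        n_removed_missing_exam_date=n_removed_exam,
        n_removed_missing_birth_date=n_removed_birth,
        n_final=len(clean),
        n_unaffected_to_affected=n01,
        n_affected_to_unaffected=n10,
        n_rejected_grade_on_unaffected=n_bad_grade,
    )
    return clean, report
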