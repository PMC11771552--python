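"""Cohort construction from OMOP-style CSV tables.

Reads the five raw tables, identifies breast-cancer patients by diagnosis-code
prefix, fixes each patient's index date at the earliest qualifying diagnosis,
and assembles a :class:`PatientTimeline` with all events re-expressed as day
offsets relative to the index date.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import CohortConfig
from .simulate import RawCohortTables, TABLE_NAMES

logger = logging.getLogger(__name__)

__all__ = ["PatientTimeline", "extract_cohort", "read_tables"]

_EXPECTED_COLUMNS = {
    "persons": ["person_id", "birth_date", "race", "ethnicity"],
    "conditions": ["person_id", "vocabulary", "code", "date"],
    "drug_exposures": ["person_id", "drug", "start_date", "end_date"],
    "surveys": ["person_id", "question", "answer"],
    "measurements": ["person_id", "pain_score", "date"],
}
_DATE_COLUMNS = {
    "persons": ["birth_date"],
    "conditions": ["date"],
    "drug_exposures": ["start_date", "end_date"],
    "surveys": [],
    "measurements": ["date"],
}


@dataclass
class PatientTimeline:
    """One patient's history anchored at the breast-cancer index date.

    ``pre_index_codes`` are (vocabulary, code, days_until_diagnosis) with
    days_until_diagnosis >= 0, sorted by *decreasing* offset so the list reads
    chronologically toward the diagnosis; events dated exactly on the index
    day sit at offset 0 at the end.  ``post_index_codes`` are
    (vocabulary, code, days_after_diagnosis) with strictly positive offsets.
    Pain scores carry a signed day offset and a pre/post flag (index-day
    scores count as pre: they were known at diagnosis).
    """

    patient_id: int
    age_at_diagnosis: float
    race: str
    ethnicity: str
    index_date: dt.date
    pre_index_codes: list[tuple[str, str, int]] = field(default_factory=list)
    post_index_codes: list[tuple[str, str, int]] = field(default_factory=list)
    drug_intervals: list[tuple[str, int, int]] = field(default_factory=list)
    pain_scores: list[tuple[float, int, str]] = field(default_factory=list)
    survey_answers: list[tuple[str, str]] = field(default_factory=list)


def _validate_dates(df: pd.DataFrame, name: str) -> None:
    for col in _DATE_COLUMNS[name]:
        parsed = pd.to_datetime(df[col], format="%Y-%m-%d", errors="coerce")
        bad = df.index[parsed.isna() & df[col].notna()]
        if len(bad):
            # +2: header line plus 1-based numbering
            lines = ", ".join(str(i + 2) for i in bad[:10])
            raise ValueError(
                f"{name}.csv: unparseable {col} at line(s) {lines}"
                + (" ..." if len(bad) > 10 else "")
            )


def read_tables(directory: str | Path) -> RawCohortTables:
    """Read and validate the five cohort CSVs from ``directory``."""
    directory = Path(directory)
    frames = {}
    for name in TABLE_NAMES:
        path = directory / f"{name}.csv"
        if not path.exists():
            raise FileNotFoundError(f"missing table file: {path}")
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        missing = [c for c in _EXPECTED_COLUMNS[name] if c not in df.columns]
        if missing:
            raise ValueError(f"{name}.csv: missing column(s) {missing}")
        df["person_id"] = df["person_id"].astype(int)
        _validate_dates(df, name)
        frames[name] = df
    frames["measurements"]["pain_score"] = frames["measurements"]["pain_score"].astype(float)
    tables = RawCohortTables(**frames)
    tables.validate()
    return tables


def _days(a: np.ndarray, b: np.ndarray | np.datetime64) -> np.ndarray:
    return ((a - b) / np.timedelta64(1, "D")).astype(int)


def extract_cohort(
    tables: RawCohortTables, config: CohortConfig | None = None
) -> list[PatientTimeline]:
    """Assemble one timeline per patient with a qualifying breast-cancer code.

    The index date is the earliest condition matching any configured prefix;
    age at diagnosis is computed in fractional years from the birth date.
    Patients with a qualifying code but no parseable birth date are excluded
    with a logged warning.
    """
    config = config or CohortConfig()
    cond = tables.conditions
    codes = cond["code"].astype(str)
    match = np.zeros(len(cond), dtype=bool)
    for vocab, prefixes in config.breast_cancer_prefixes.items():
        in_vocab = (cond["vocabulary"] == vocab).to_numpy()
        for prefix in prefixes:
            match |= in_vocab & codes.str.startswith(prefix).to_numpy()

    cond_dates = pd.to_datetime(cond["date"]).to_numpy()
    index_dates = (
        pd.Series(cond_dates[match], index=cond["person_id"][match]).groupby(level=0).min()
    )

    persons = tables.persons.set_index("person_id")
    birth = pd.to_datetime(persons["birth_date"], errors="coerce")

    timelines: dict[int, PatientTimeline] = {}
    for pid, idx_date in index_dates.items():
        if pid not in persons.index or pd.isna(birth.loc[pid]):
            logger.warning("patient %s: qualifying code but no birth date; excluded", pid)
            continue
        age = (idx_date - birth.loc[pid].to_numpy()) / np.timedelta64(1, "D") / 365.25
        timelines[pid] = PatientTimeline(
            patient_id=int(pid),
            age_at_diagnosis=float(age),
            race=str(persons.loc[pid, "race"]),
            ethnicity=str(persons.loc[pid, "ethnicity"]),
            index_date=pd.Timestamp(idx_date).date(),
        )

    index_of = {pid: idx for pid, idx in index_dates.items() if pid in timelines}

    # condition events -> pre/post day offsets
    pids = cond["person_id"].to_numpy()
    in_cohort = np.isin(pids, list(index_of)) if index_of else np.zeros(len(cond), bool)
    for row_pid, vocab, code, date in zip(
        pids[in_cohort],
        cond["vocabulary"].to_numpy()[in_cohort],
        codes.to_numpy()[in_cohort],
        cond_dates[in_cohort],
    ):
        offset = int((date - index_of[row_pid]) / np.timedelta64(1, "D"))
        tl = timelines[row_pid]
        if offset <= 0:
            tl.pre_index_codes.append((vocab, code, -offset))
        else:
            tl.post_index_codes.append((vocab, code, offset))
    for tl in timelines.values():
        tl.pre_index_codes.sort(key=lambda e: (-e[2], e[0], e[1]))
        tl.post_index_codes.sort(key=lambda e: (e[2], e[0], e[1]))

    drugs = tables.drug_exposures
    if len(drugs):
        starts = pd.to_datetime(drugs["start_date"]).to_numpy()
        ends = pd.to_datetime(drugs["end_date"]).to_numpy()
        for pid, name, s, e in zip(
            drugs["person_id"].to_numpy(), drugs["drug"].to_numpy(), starts, ends
        ):
            if pid in timelines:
                anchor = index_of[pid]
                timelines[pid].drug_intervals.append(
                    (
                        str(name),
                        int((s - anchor) / np.timedelta64(1, "D")),
                        int((e - anchor) / np.timedelta64(1, "D")),
                    )
                )
        for tl in timelines.values():
            tl.drug_intervals.sort(key=lambda iv: (iv[1], iv[2], iv[0]))

    meas = tables.measurements
    if len(meas):
        mdates = pd.to_datetime(meas["date"]).to_numpy()
        for pid, score, date in zip(
            meas["person_id"].to_numpy(), meas["pain_score"].to_numpy(), mdates
        ):
            if pid in timelines:
                offset = int((date - index_of[pid]) / np.timedelta64(1, "D"))
                timelines[pid].pain_scores.append(
                    (float(score), offset, "post" if offset > 0 else "pre")
                )
        for tl in timelines.values():
            tl.pain_scores.sort(key=lambda s: s[1])

    for pid, question, answer in tables.surveys.itertuples(index=False):
        if pid in timelines:
            timelines[pid].survey_answers.append((str(question), str(answer)))

    return [timelines[pid] for pid in sorted(timelines)]
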