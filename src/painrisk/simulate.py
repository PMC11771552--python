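"""Synthetic OMOP-style cohort generator with a planted, recoverable risk signal.

The generator emulates the statistical shape of a breast-cancer EHR cohort:
each patient carries one index breast-cancer diagnosis, a pre-index sequence
of dated diagnosis codes (length ~ Poisson with mean 109), demographics drawn
from a reference breast-cancer cohort profile (mean age 57.8 +/- 10.4, majority
White and non-Hispanic), 81 survey question-answer items, opioid exposure
intervals and 0-10 pain-intensity scores.

The chronic-pain outcome is generated by a *logistic model on latent
indicators* — planted diagnosis codes, planted survey answers and age — never
by the classifier's own functional form, so downstream signal recovery is a
fair test.  Outcome-positive patients then receive post-index evidence
matching the computable-phenotype branches (pain codes, qualifying opioid
chains, or rising pain scores); negatives may receive sub-threshold opioid
exposures as near-boundary noise.

All dates are emitted as absolute ISO-8601 strings relative to a per-patient
index date, forcing the cohort reader to recompute day offsets itself.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import (
    ETHNICITY_CATEGORIES,
    PAIN_MEDICATIONS,
    RACE_CATEGORIES,
    ConfigError,
    SimConfig,
)

__all__ = [
    "RawCohortTables",
    "TABLE_NAMES",
    "calibrate_baseline_logit",
    "generate_cohort",
    "planted_risk",
    "synthetic_code",
    "write_tables",
]

TABLE_NAMES = ("persons", "conditions", "drug_exposures", "surveys", "measurements")

_RACE_PROBS = (0.882, 0.075, 0.021, 0.011, 0.011)
_ETHNICITY_PROBS = (0.98, 0.02)
_AGE_MEAN, _AGE_SD, _AGE_MIN, _AGE_MAX = 57.8, 10.4, 23.9, 86.8

# ICD-10-CM letters that can never collide with the cohort prefix (C50) or the
# chronic-pain prefix (G89)
_ICD10_LETTERS = "DEFHJKLMN"


def synthetic_code(j: int) -> tuple[str, str]:
    """Deterministic (vocabulary, code) for synthetic-vocabulary index ``j``.

    Codes rotate over ICD9CM / ICD10CM / SNOMED families and are constructed
    so that none matches the breast-cancer prefixes (170, C50), the
    chronic-pain prefixes (G89, 338.2) or the chronic-pain SNOMED code.
    """
    family, k = j % 3, j // 3
    if family == 0:
        return "ICD9CM", f"{400 + k}.0"
    if family == 1:
        letter = _ICD10_LETTERS[k % len(_ICD10_LETTERS)]
        return "ICD10CM", f"{letter}{k // len(_ICD10_LETTERS):02d}.{k % 10}"
    return "SNOMED", str(10000000 + k)


@dataclass
class RawCohortTables:
    """The five OMOP-style tables, plus optional generator ground truth.

    ``truth`` (person_id, positive, branch) records which phenotype branch the
    generator planted for each patient; it exists for validation only and is
    not part of the five-table interface.
    """

    persons: pd.DataFrame
    conditions: pd.DataFrame
    drug_exposures: pd.DataFrame
    surveys: pd.DataFrame
    measurements: pd.DataFrame
    truth: pd.DataFrame | None = field(default=None, compare=False)

    def validate(self) -> None:
        ids = set(self.persons["person_id"])
        for name in ("conditions", "drug_exposures", "surveys", "measurements"):
            table = getattr(self, name)
            orphan = set(table["person_id"]) - ids
            if orphan:
                raise ValueError(f"{name}: person ids not in persons: {sorted(orphan)[:5]}")
        starts = pd.to_datetime(self.drug_exposures["start_date"])
        ends = pd.to_datetime(self.drug_exposures["end_date"])
        if (ends < starts).any():
            bad = int((ends < starts).sum())
            raise ValueError(f"drug_exposures: {bad} rows with end_date < start_date")


def _latent_logit_samples(cfg: SimConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    """Sample the latent risk score (without intercept) for ``n`` patients."""
    s = np.zeros(n)
    for pc in cfg.risk_codes:
        s += pc.effect * (rng.random(n) < pc.carrier_rate)
    for si in cfg.risk_survey_items:
        s += si.effect * (rng.random(n) < si.carrier_rate)
    ages = np.clip(rng.normal(_AGE_MEAN, _AGE_SD, n), _AGE_MIN, _AGE_MAX)
    s += cfg.age_effect * (ages - 55.0) / 10.0
    return s


def calibrate_baseline_logit(cfg: SimConfig, n_mc: int = 200_000) -> float:
    """Solve for the intercept giving the configured marginal prevalence.

    Bisects ``E[sigmoid(b + S)] = target_prevalence`` over a fixed-seed
    Monte-Carlo sample of the latent score S; deterministic for a given
    effect configuration.
    """
    rng = np.random.default_rng(np.random.SeedSequence(20240726))
    s = _latent_logit_samples(cfg, rng, n_mc)
    lo, hi = -20.0, 20.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if np.mean(1.0 / (1.0 + np.exp(-(mid + s)))) < cfg.target_prevalence:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def planted_risk(code_carriers, survey_carriers, age, cfg: SimConfig):
    """Outcome probability under the planted logistic model.

    sigmoid(baseline_logit + sum of carried code effects + sum of carried
    survey effects + age_effect * (age - 55)/10).  Accepts scalars or arrays;
    carrier arguments index ``cfg.risk_codes`` / ``cfg.risk_survey_items``.
    """
    code_carriers = np.atleast_2d(np.asarray(code_carriers, dtype=float))
    survey_carriers = np.atleast_2d(np.asarray(survey_carriers, dtype=float))
    age = np.asarray(age, dtype=float)
    code_fx = np.array([pc.effect for pc in cfg.risk_codes])
    survey_fx = np.array([si.effect for si in cfg.risk_survey_items])
    logit = (
        cfg.baseline_logit
        + (code_carriers * code_fx).sum(axis=-1)
        + (survey_carriers * survey_fx).sum(axis=-1)
        + cfg.age_effect * (age - 55.0) / 10.0
    )
    p = 1.0 / (1.0 + np.exp(-logit))
    return float(p[0]) if p.size == 1 else p


def _iso(d: dt.date) -> str:
    return d.isoformat()


def generate_cohort(cfg: SimConfig) -> RawCohortTables:
    """Generate a full synthetic cohort; byte-deterministic given config+seed."""
    if cfg.n_patients < 1:
        raise ConfigError("n_patients must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))

    risk_set = {(pc.vocabulary, pc.code) for pc in cfg.risk_codes}
    background = [
        synthetic_code(j)
        for j in range(cfg.code_vocab_size)
        if synthetic_code(j) not in risk_set
    ]
    planted_by_question = {si.question: si for si in cfg.risk_survey_items}
    questions = [f"SQ{k:03d}" for k in range(1, cfg.n_survey_questions + 1)]
    answers = [f"A{a}" for a in range(1, cfg.n_survey_answers + 1)]

    persons, conditions, drugs, surveys, measurements, truth = [], [], [], [], [], []

    for i in range(cfg.n_patients):
        pid = i + 1
        age = float(np.clip(rng.normal(_AGE_MEAN, _AGE_SD), _AGE_MIN, _AGE_MAX))
        race = RACE_CATEGORIES[rng.choice(len(RACE_CATEGORIES), p=_RACE_PROBS)]
        ethnicity = ETHNICITY_CATEGORIES[rng.choice(2, p=_ETHNICITY_PROBS)]
        index_date = dt.date(2015, 6, 1) + dt.timedelta(days=int(rng.integers(-1200, 1201)))
        birth_date = index_date - dt.timedelta(days=int(round(age * 365.25)))
        persons.append((pid, _iso(birth_date), race, ethnicity))

        # index breast-cancer condition
        conditions.append((pid, "ICD10CM", "C50.911", _iso(index_date)))

        # planted risk-code carriage
        code_carried = rng.random(len(cfg.risk_codes)) < np.array(
            [pc.carrier_rate for pc in cfg.risk_codes]
        )
        # carried chronic-condition codes recur across visits, as they do in
        # real billing data
        events: list[tuple[str, str]] = []
        for pc, c in zip(cfg.risk_codes, code_carried):
            if c:
                events.extend([(pc.vocabulary, pc.code)] * int(rng.integers(3, 9)))
        n_total = int(rng.poisson(cfg.mean_seq_len))
        n_fill = max(n_total - len(events), 0)
        if n_fill and background:
            for j in rng.integers(0, len(background), n_fill):
                events.append(background[j])
        # codes arrive in visit clusters: several codes share each visit day
        n_visits = max(1, int(rng.poisson(max(len(events), 1) / 6)))
        visit_days = rng.integers(1, 2001, n_visits)
        days_until = visit_days[rng.integers(0, n_visits, len(events))]
        for (vocab, code), d in zip(events, days_until):
            conditions.append((pid, vocab, code, _iso(index_date - dt.timedelta(days=int(d)))))

        # surveys: planted answers for carriers, uniform otherwise
        survey_carried = []
        for q in questions:
            si = planted_by_question.get(q)
            if si is not None:
                carried = bool(rng.random() < si.carrier_rate)
                survey_carried.append(carried)
                if carried:
                    ans = si.answer
                else:
                    others = [a for a in answers if a != si.answer]
                    ans = others[rng.integers(0, len(others))]
            else:
                ans = answers[rng.integers(0, len(answers))]
            surveys.append((pid, q, ans))

        # outcome from the planted logistic model
        p = planted_risk(
            code_carried.astype(float), np.array(survey_carried, dtype=float), age, cfg
        )
        positive = bool(rng.random() < p)

        if positive:
            has_code = rng.random() < cfg.pain_code_rate
            has_med = rng.random() < cfg.med_persistence
            has_exac = rng.random() < cfg.exacerbation_rate
            if not (has_code or has_med or has_exac):
                has_code = True
            if has_code:
                kind = rng.integers(0, 3)
                if kind == 0:
                    vocab, code = "ICD10CM", f"G89.{[0, 1, 2, 3, 4][rng.integers(0, 5)]}"
                elif kind == 1:
                    vocab, code = "ICD9CM", f"338.2{rng.integers(0, 10)}"
                else:
                    vocab, code = "SNOMED", "82423001"
                d = int(rng.integers(7, 1001))
                conditions.append((pid, vocab, code, _iso(index_date + dt.timedelta(days=d))))
            if has_med:
                # qualifying chain: disjoint intervals, gaps <= 90, union > 90 days
                drug = PAIN_MEDICATIONS[rng.integers(0, len(PAIN_MEDICATIONS))]
                label = f"{drug} 5 MG Oral Tablet"
                start = int(rng.integers(5, 201))
                covered = 0
                while covered <= 90:
                    length = int(rng.integers(25, 46))  # covered days = length + 1
                    end = start + length
                    drugs.append(
                        (
                            pid,
                            label,
                            _iso(index_date + dt.timedelta(days=start)),
                            _iso(index_date + dt.timedelta(days=end)),
                        )
                    )
                    covered += length + 1
                    start = end + int(rng.integers(5, 61))  # gap <= 90
            if has_exac:
                base = int(rng.integers(0, 7))
                measurements.append(
                    (pid, base, _iso(index_date - dt.timedelta(days=int(rng.integers(30, 401)))))
                )
                post = int(rng.integers(base + 1, min(base + 5, 11)))
                measurements.append(
                    (pid, post, _iso(index_date + dt.timedelta(days=int(rng.integers(7, 1001)))))
                )
            branch = "code" if has_code else ("medication" if has_med else "exacerbation")
        else:
            branch = "none"
            if rng.random() < cfg.negative_opioid_rate:
                # sub-threshold exposure: every chain covers <= 90 days
                drug = PAIN_MEDICATIONS[rng.integers(0, len(PAIN_MEDICATIONS))]
                label = f"{drug} 5 MG Oral Tablet"
                if rng.random() < 0.5:
                    start = int(rng.integers(0, 400))
                    end = start + int(rng.integers(4, 80))  # covered <= 80 days
                    drugs.append(
                        (
                            pid,
                            label,
                            _iso(index_date + dt.timedelta(days=start)),
                            _iso(index_date + dt.timedelta(days=end)),
                        )
                    )
                else:
                    # two short chains separated by a gap > 90 days
                    start = int(rng.integers(0, 200))
                    for _ in range(2):
                        end = start + int(rng.integers(4, 40))
                        drugs.append(
                            (
                                pid,
                                label,
                                _iso(index_date + dt.timedelta(days=start)),
                                _iso(index_date + dt.timedelta(days=end)),
                            )
                        )
                        start = end + int(rng.integers(100, 200))
            if rng.random() < 0.3:
                # non-rising pain scores
                base = int(rng.integers(2, 9))
                measurements.append(
                    (pid, base, _iso(index_date - dt.timedelta(days=int(rng.integers(30, 401)))))
                )
                measurements.append(
                    (
                        pid,
                        int(rng.integers(0, base + 1)),
                        _iso(index_date + dt.timedelta(days=int(rng.integers(7, 1001)))),
                    )
                )
        truth.append((pid, positive, branch))

    tables = RawCohortTables(
        persons=pd.DataFrame(persons, columns=["person_id", "birth_date", "race", "ethnicity"]),
        conditions=pd.DataFrame(conditions, columns=["person_id", "vocabulary", "code", "date"]),
        drug_exposures=pd.DataFrame(
            drugs, columns=["person_id", "drug", "start_date", "end_date"]
        ),
        surveys=pd.DataFrame(surveys, columns=["person_id", "question", "answer"]),
        measurements=pd.DataFrame(measurements, columns=["person_id", "pain_score", "date"]),
        truth=pd.DataFrame(truth, columns=["person_id", "positive", "branch"]),
    )
    tables.validate()
    return tables


def write_tables(tables: RawCohortTables, directory: str | Path) -> dict[str, int]:
    """Write one CSV per table plus a key=value manifest of row counts."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, int] = {}
    for name in TABLE_NAMES:
        df: pd.DataFrame = getattr(tables, name)
        df.to_csv(directory / f"{name}.csv", index=False, lineterminator="\n")
        manifest[name] = len(df)
    if tables.truth is not None:
        tables.truth.to_csv(directory / "truth.csv", index=False, lineterminator="\n")
        manifest["truth"] = len(tables.truth)
    with open(directory / "manifest.txt", "w", encoding="utf-8") as fh:
        for key, value in manifest.items():
            fh.write(f"{key}={value}\n")
    return manifest
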