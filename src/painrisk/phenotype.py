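"""Computable chronic-pain phenotype over a 3-year post-diagnosis horizon.

A patient is labeled chronic-pain positive if any of three rules fires within
``followup_days`` (default 1095 = 3 years) after the breast-cancer index date:

* **code** — any post-index diagnosis code matching a chronic-pain rule:
  ICD-10-CM prefix ``G89``, ICD-9-CM prefix ``338.2``, or SNOMED code exactly
  ``82423001``;
* **medication** — a qualifying chain of pain-medication exposures: exposures
  sorted by start form maximal runs in which each gap (next start minus
  previous end) is at most 90 days, and some run covers strictly more than 90
  distinct days;
* **exacerbation** — pain-intensity scores exist both before and after the
  index date and the post-index maximum strictly exceeds the latest pre-index
  score (the pre-diagnosis baseline).

Positivity is a pure OR of the three rules; the reported branch is the first
true rule in the order code -> medication -> exacerbation.

Day-count conventions: "3 months" is 90 days and "3 years" is 1095 days; an
exposure interval (start, end) covers ``end - start + 1`` distinct days; the
duration rule is strict (> 90 covered days) while the gap rule is non-strict
(<= 90 days), reading "exceeding" strictly and "within" inclusively.  Only
post-index exposure days (offset >= 0) count toward a chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .cohort import PatientTimeline
from .config import CohortConfig

__all__ = [
    "ChronicPainLabel",
    "derive_label",
    "label_by_codes",
    "label_by_exacerbation",
    "label_by_medication",
    "label_cohort",
    "oracle_medication_label",
]


@dataclass
class ChronicPainLabel:
    positive: bool
    branch: str  # "code" | "medication" | "exacerbation" | "none"
    evidence: list = field(default_factory=list)

    def __post_init__(self):
        assert self.positive == (self.branch != "none")


def _matching_pain_codes(timeline: PatientTimeline, config: CohortConfig):
    hits = []
    for vocab, code, day in timeline.post_index_codes:
        if day > config.followup_days:
            continue
        if any(code.startswith(p) for p in config.pain_code_prefixes.get(vocab, ())):
            hits.append((vocab, code, day))
        elif code in config.pain_code_exact.get(vocab, ()):
            hits.append((vocab, code, day))
    return hits


def label_by_codes(timeline: PatientTimeline, config: CohortConfig | None = None) -> bool:
    """Code rule: any qualifying chronic-pain code within the follow-up window."""
    config = config or CohortConfig()
    return bool(_matching_pain_codes(timeline, config))


def _qualifying_intervals(timeline: PatientTimeline, config: CohortConfig):
    """Post-index pain-medication intervals clipped to the follow-up window.

    Drug matching is a case-insensitive substring test against the configured
    ingredient list, since exposure records usually carry brand/strength text.
    """
    meds = [m.lower() for m in config.pain_medications]
    out = []
    for name, start, end in timeline.drug_intervals:
        if end < start:
            raise ValueError(
                f"patient {timeline.patient_id}: exposure end {end} before start {start}"
            )
        if start < 0:  # only exposures begun after the diagnosis count
            continue
        lowered = name.lower()
        if not any(m in lowered for m in meds):
            continue
        end = min(end, config.followup_days)
        if start <= config.followup_days and end >= start:
            out.append((start, end))
    return sorted(out)


def label_by_medication(timeline: PatientTimeline, config: CohortConfig | None = None) -> bool:
    """Medication rule via interval arithmetic.

    Exposures are merged into chains: consecutive (sorted by start) exposures
    belong to one chain while the gap between the running chain end and the
    next start is <= ``medication_gap_days``.  Within a chain the union of
    covered days is accumulated with overlap correction; the rule fires if any
    single chain covers more than ``medication_duration_days`` distinct days.
    """
    config = config or CohortConfig()
    intervals = _qualifying_intervals(timeline, config)
    if not intervals:
        return False
    gap, need = config.medication_gap_days, config.medication_duration_days
    chain_end = None
    covered = 0
    for start, end in intervals:
        if chain_end is None or start - chain_end > gap:
            # new chain
            covered = end - start + 1
            chain_end = end
        else:
            if end > chain_end:
                covered += end - max(chain_end + 1, start) + 1
                chain_end = end
            # fully nested interval adds no new days
        if covered > need:
            return True
    return False


def oracle_medication_label(
    timeline: PatientTimeline, config: CohortConfig | None = None
) -> bool:
    """Brute-force day-expansion check of the medication rule.

    Expands every qualifying exposure into its set of integer days, splits the
    sorted day set into maximal runs with inter-day gaps <= the configured gap,
    and reports whether any run contains more than the required number of
    distinct days.  Kept deliberately independent of the interval-arithmetic
    path in :func:`label_by_medication`.
    """
    config = config or CohortConfig()
    days: set[int] = set()
    for start, end in _qualifying_intervals(timeline, config):
        days.update(range(start, end + 1))
    if not days:
        return False
    ordered = sorted(days)
    run = 1
    best = 1
    for prev, cur in zip(ordered, ordered[1:]):
        if cur - prev <= config.medication_gap_days:
            run += 1
        else:
            run = 1
        best = max(best, run)
    return best > config.medication_duration_days


def label_by_exacerbation(
    timeline: PatientTimeline, config: CohortConfig | None = None
) -> bool:
    """Exacerbation rule: post-index maximum strictly above the latest pre-index score."""
    config = config or CohortConfig()
    pre = [(day, score) for score, day, flag in timeline.pain_scores if flag == "pre"]
    post = [
        score
        for score, day, flag in timeline.pain_scores
        if flag == "post" and day <= config.followup_days
    ]
    if not pre or not post:
        return False
    baseline = max(pre)[1]  # score at the latest pre-index day
    return max(post) > baseline


def derive_label(
    timeline: PatientTimeline, config: CohortConfig | None = None
) -> ChronicPainLabel:
    """Combine the three rules; branch reports the first firing rule."""
    config = config or CohortConfig()
    if label_by_codes(timeline, config):
        return ChronicPainLabel(True, "code", _matching_pain_codes(timeline, config))
    if label_by_medication(timeline, config):
        evidence = _qualifying_intervals(timeline, config)
        return ChronicPainLabel(True, "medication", evidence)
    if label_by_exacerbation(timeline, config):
        return ChronicPainLabel(True, "exacerbation", list(timeline.pain_scores))
    return ChronicPainLabel(False, "none")


def label_cohort(
    timelines: list[PatientTimeline], config: CohortConfig | None = None
) -> pd.DataFrame:
    """Label every timeline; returns (patient_id, positive, branch) rows."""
    config = config or CohortConfig()
    rows = []
    for tl in timelines:
        lab = derive_label(tl, config)
        rows.append((tl.patient_id, lab.positive, lab.branch))
    return pd.DataFrame(rows, columns=["patient_id", "positive", "branch"])
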