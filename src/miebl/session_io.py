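"""Trial-level session records: reading, aggregation, synthetic fixtures.

A trial-record CSV has one row per discrete trial with the header
``student_id,skill_id,session_id,trial_index,outcome`` (outcome 1 = correct,
0 = incorrect).  Records aggregate to the (n, x) counts the posterior engine
consumes, either per session or pooled across sessions -- practitioners
differ on whether a criterion applies within one session or across several,
so both scopes are first-class.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .posterior import TrialCount

__all__ = [
    "TrialRecord",
    "AggregationPolicy",
    "read_trials",
    "write_trials",
    "aggregate",
    "generate_fixture",
    "CSV_COLUMNS",
]

CSV_COLUMNS = ("student_id", "skill_id", "session_id", "trial_index", "outcome")


@dataclass(frozen=True)
class TrialRecord:
    """One discrete trial: who, which skill, which session, and the outcome."""

    student_id: str
    skill_id: str
    session_id: str
    trial_index: int
    outcome: int

    def __post_init__(self) -> None:
        if self.outcome not in (0, 1):
            raise ValueError(f"outcome must be 0 or 1, got {self.outcome}")
        if self.trial_index < 1:
            raise ValueError(f"trial_index must be >= 1, got {self.trial_index}")

    @property
    def key(self) -> tuple:
        return (self.student_id, self.skill_id, self.session_id, self.trial_index)


@dataclass(frozen=True)
class AggregationPolicy:
    """How to roll trials up into counts.

    ``scope="per_session"`` yields one TrialCount per (student, skill,
    session); ``"pooled"`` sums across sessions per (student, skill).
    ``sessions`` optionally restricts to a subset of session ids first.
    """

    scope: str = "pooled"
    sessions: Optional[frozenset] = None

    def __post_init__(self) -> None:
        if self.scope not in ("per_session", "pooled"):
            raise ValueError(
                f"scope must be 'per_session' or 'pooled', got {self.scope!r}"
            )


class TrialDataError(ValueError):
    """Malformed or empty trial-record input."""


def read_trials(path: str) -> list[TrialRecord]:
    """Read and validate a trial-record CSV.

    Rejects missing columns, non-binary outcomes, unparseable rows and
    duplicate (student, skill, session, trial_index) keys, naming the
    offending data row number (header = row 1).
    """
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise TrialDataError(f"{path}: empty file, no header row")
        missing = [c for c in CSV_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise TrialDataError(
                f"{path}: missing required column(s) {', '.join(missing)}; "
                f"expected header {','.join(CSV_COLUMNS)}"
            )
        records: list[TrialRecord] = []
        seen: set[tuple] = set()
        for rownum, row in enumerate(reader, start=2):
            try:
                rec = TrialRecord(
                    student_id=row["student_id"],
                    skill_id=row["skill_id"],
                    session_id=row["session_id"],
                    trial_index=int(row["trial_index"]),
                    outcome=int(row["outcome"]),
                )
            except (TypeError, ValueError) as exc:
                raise TrialDataError(f"{path}: row {rownum}: {exc}") from exc
            if rec.key in seen:
                raise TrialDataError(
                    f"{path}: row {rownum}: duplicate trial key {rec.key}"
                )
            seen.add(rec.key)
            records.append(rec)
    if not records:
        raise TrialDataError(f"{path}: no records (header only)")
    return records


def write_trials(records: Iterable[TrialRecord], path: str) -> None:
    """Write records as RFC-4180 CSV with the canonical header."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for r in records:
            writer.writerow(
                [r.student_id, r.skill_id, r.session_id, r.trial_index, r.outcome]
            )


def aggregate(
    records: Sequence[TrialRecord], policy: AggregationPolicy = AggregationPolicy()
) -> dict[tuple, TrialCount]:
    """Roll trial records up into (n, x) counts per the policy.

    Keys are (student, skill, session) in per-session scope and
    (student, skill) when pooled.  Totals conserve record counts.
    """
    if not records:
        raise TrialDataError("no trial records to aggregate")
    if policy.sessions is not None:
        records = [r for r in records if r.session_id in policy.sessions]
        if not records:
            raise TrialDataError(
                f"no records remain after filtering to sessions "
                f"{sorted(policy.sessions)}"
            )
    counts: dict[tuple, list[int]] = {}
    for r in records:
        if policy.scope == "per_session":
            key = (r.student_id, r.skill_id, r.session_id)
        else:
            key = (r.student_id, r.skill_id)
        acc = counts.setdefault(key, [0, 0])
        acc[0] += 1
        acc[1] += r.outcome
    return {k: TrialCount(n=n, x=x) for k, (n, x) in counts.items()}


def generate_fixture(
    true_p: float,
    n_sessions: int,
    trials_per_session: int,
    seed: int,
    student_id: str = "S1",
    skill_id: str = "K1",
) -> list[TrialRecord]:
    """Synthetic trial records for a student with known true mastery.

    Outcomes are independent Bernoulli(true_p) draws -- the model's own
    independence assumption -- deterministic for a given seed.
    """
    if not 0.0 <= true_p <= 1.0:
        raise ValueError(f"true_p must be in [0, 1], got {true_p}")
    if n_sessions < 1 or trials_per_session < 1:
        raise ValueError("n_sessions and trials_per_session must be >= 1")
    rng = np.random.default_rng(seed)
    outcomes = rng.random((n_sessions, trials_per_session)) < true_p
    return [
        TrialRecord(
            student_id=student_id,
            skill_id=skill_id,
            session_id=f"sess{s + 1}",
            trial_index=t + 1,
            outcome=int(outcomes[s, t]),
        )
        for s in range(n_sessions)
        for t in range(trials_per_session)
    ]
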