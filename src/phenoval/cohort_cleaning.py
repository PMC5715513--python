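"""Study-cohort construction from a raw hospital registry extract.

Two exclusion rules are applied, each with a full audit trail:

1. **duplicate_patient** — a ``patient_id`` registered more than once; the
   row with the earliest ``registration_date`` survives (ties broken by file
   order), every other row is excluded.
2. **death_before_birth** — an input mistake where the recorded death date
   precedes the birth date.

A row hit by both rules is logged once, as ``duplicate_patient``: reasons are
disjoint, so retained + excluded always reconstructs the input exactly.
Cleaning never fails; it logs.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

REASON_DUPLICATE = "duplicate_patient"
REASON_DEATH_BEFORE_BIRTH = "death_before_birth"
REASONS = (REASON_DUPLICATE, REASON_DEATH_BEFORE_BIRTH)


@dataclass
class ExclusionLog:
    """One entry per excluded registry row: (patient_id, reason, detail)."""

    entries: list[tuple[str, str, str]] = field(default_factory=list)

    def add(self, patient_id: str, reason: str, detail: str) -> None:
        assert reason in REASONS
        self.entries.append((patient_id, reason, detail))

    def __len__(self) -> int:
        return len(self.entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries,
                            columns=["patient_id", "reason", "detail"])


@dataclass
class CleanResult:
    retained: pd.DataFrame
    log: ExclusionLog


def clean_registry(patients: pd.DataFrame) -> CleanResult:
    """Apply both exclusion rules to a schema-valid patient table.

    Returns retained rows (unique patient_id, no death-before-birth) plus the
    exclusion log; ``len(retained) + len(log) == len(patients)`` always.
    """
    df = patients.reset_index(drop=True)
    log = ExclusionLog()
    if len(df) == 0:
        return CleanResult(df, log)

    dead_before_born = (
        df["death_date"].notna() & (df["death_date"] < df["birth_date"])
    )

    # Survivor per patient_id: earliest registration_date; ties prefer a row
    # with consistent dates, then file order (keeps the retained count
    # invariant under row permutation).
    order = df[["patient_id", "registration_date"]].copy()
    order["_invalid"] = dead_before_born.to_numpy()
    order["_row"] = order.index
    survivors = (
        order.sort_values(["registration_date", "_invalid", "_row"], kind="stable")
        .drop_duplicates("patient_id", keep="first")["_row"]
    )
    is_survivor = df.index.isin(survivors)

    keep = is_survivor & ~dead_before_born
    for row in df.index[~keep]:
        pid = df.at[row, "patient_id"]
        if not is_survivor[row]:
            log.add(pid, REASON_DUPLICATE,
                    f"row {row}: patient_id registered more than once")
        else:
            log.add(
                pid, REASON_DEATH_BEFORE_BIRTH,
                f"row {row}: death {df.at[row, 'death_date'].date()} precedes "
                f"birth {df.at[row, 'birth_date'].date()}",
            )

    retained = df.loc[keep].reset_index(drop=True)
    return CleanResult(retained, log)


def exclusion_summary(log: ExclusionLog) -> dict[str, int]:
    """Counts by exclusion reason; every reason present, zeros included."""
    counts = Counter(reason for _, reason, _ in log.entries)
    return {reason: counts.get(reason, 0) for reason in REASONS}
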