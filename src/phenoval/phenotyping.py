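"""Same-day code deduplication and imaging-linkage arm classification.

The phenotyping algorithm has two stages.

**Deduplication.**  In routine care, several departments may register the
identical diagnosis code for the same patient on the same day.  A duplicate
is therefore defined as two or more records sharing (patient, code,
registration day); within a duplicate group the survivor is the record with
the highest code position (primary > secondary > other), ties broken by file
order.  "Definite" and "suspected" codes are deduplicated independently.

**Arm classification.**  Each deduplicated record is tested against a set of
algorithm arms combining a certainty requirement with an imaging-linkage
requirement: no imaging required, any brain imaging order for the patient, or
an imaging order within W days of the code's registration date.  Windows are
two-sided by default (|offset| <= W); one-sided variants are available per
arm.  The five shipped arms are

==================  ==========  =====================
name                certainty   imaging
==================  ==========  =====================
definite            definite    not required
definite_any        definite    any order
definite_w30        definite    within 30 days
definite_w1         definite    within 1 day
suspected_any       suspected   any order
==================  ==========  =====================

Arms overlap by construction and obey the nesting
``within 1 ⊆ within 30 ⊆ any ⊆ certainty alone``.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .errors import UnknownArmError

POSITION_RANK = {"primary": 0, "secondary": 1, "other": 2}

TWO_SIDED = "two_sided"
AFTER_ONLY = "after_only"
BEFORE_ONLY = "before_only"

IMAGING_NOT_REQUIRED = "not_required"
IMAGING_ANY = "any"


@dataclass(frozen=True)
class ArmSpec:
    """One algorithm arm: certainty plus an imaging-linkage requirement.

    ``imaging`` is ``"not_required"``, ``"any"``, or a whole-day window
    half-width W >= 0; ``window_direction`` applies only to windowed arms.
    """

    name: str
    certainty_required: str
    imaging: str | int = IMAGING_NOT_REQUIRED
    window_direction: str = TWO_SIDED

    def __post_init__(self):
        if self.certainty_required not in ("definite", "suspected"):
            raise ValueError(f"{self.name}: bad certainty {self.certainty_required!r}")
        if isinstance(self.imaging, int):
            if self.imaging < 0:
                raise ValueError(f"{self.name}: window must be >= 0 days")
        elif self.imaging not in (IMAGING_NOT_REQUIRED, IMAGING_ANY):
            raise ValueError(f"{self.name}: bad imaging rule {self.imaging!r}")
        if self.window_direction not in (TWO_SIDED, AFTER_ONLY, BEFORE_ONLY):
            raise ValueError(f"{self.name}: bad direction {self.window_direction!r}")


def default_arms() -> list[ArmSpec]:
    """The five shipped arms, loaded from ``data/arms.yaml``."""
    text = resources.files("phenoval.data").joinpath("arms.yaml").read_text()
    return load_arms_config(yaml.safe_load(text))


def load_arms_config(raw: list[dict]) -> list[ArmSpec]:
    arms = []
    for item in raw:
        imaging = item.get("imaging", IMAGING_NOT_REQUIRED)
        if isinstance(imaging, str) and imaging.isdigit():
            imaging = int(imaging)
        arms.append(ArmSpec(
            name=item["name"],
            certainty_required=item["certainty"],
            imaging=imaging,
            window_direction=item.get("window_direction", TWO_SIDED),
        ))
    return arms


def dedup_diagnoses(records: pd.DataFrame) -> pd.DataFrame:
    """Collapse same-day duplicate registrations of the same code.

    Output is unique on (patient_id, code, registration_date, certainty);
    the survivor of each group carries the highest position rank, with file
    order breaking ties.  Idempotent, never increases the row count.
    """
    if len(records) == 0:
        return records.reset_index(drop=True)
    df = records.reset_index(drop=True)
    rank = df["position"].map(POSITION_RANK)
    key = df.assign(_rank=rank, _row=df.index)
    survivors = (
        key.sort_values(["_rank", "_row"], kind="stable")
        .drop_duplicates(["patient_id", "code", "registration_date", "certainty"],
                         keep="first")["_row"]
        .sort_values()
    )
    return df.loc[survivors].reset_index(drop=True)


def _offset_features(records: pd.DataFrame,
                     procedures: pd.DataFrame) -> pd.DataFrame:
    """Per record: nearest signed imaging offset and one-sided extremes.

    Offsets are ``order_date - registration_date`` in whole days over all of
    the patient's imaging orders.  ``nearest_offset`` minimizes |offset| with
    ties resolved toward the non-negative value; ``nearest_after`` /
    ``nearest_before`` are the smallest-magnitude offsets at or after /
    at or before the code date (NaN when none exist).
    """
    base = pd.DataFrame(index=records.index)
    base["has_imaging"] = False
    base["nearest_offset"] = np.nan
    base["nearest_after"] = np.nan
    base["nearest_before"] = np.nan
    if len(records) == 0 or len(procedures) == 0:
        return base

    left = records[["patient_id", "registration_date"]].reset_index(names="_rec")
    merged = left.merge(procedures[["patient_id", "order_date"]], on="patient_id")
    if len(merged) == 0:
        return base
    merged["offset"] = (
        (merged["order_date"] - merged["registration_date"]).dt.days
    )

    # tie toward non-negative: sort by (|offset|, offset < 0)
    merged["_abs"] = merged["offset"].abs()
    merged["_neg"] = merged["offset"] < 0
    nearest = (
        merged.sort_values(["_abs", "_neg"], kind="stable")
        .drop_duplicates("_rec")
        .set_index("_rec")["offset"]
    )
    after = merged.loc[merged["offset"] >= 0].groupby("_rec")["offset"].min()
    before = merged.loc[merged["offset"] <= 0].groupby("_rec")["offset"].max()

    base.loc[nearest.index, "has_imaging"] = True
    base["nearest_offset"] = nearest.reindex(base.index)
    base["nearest_after"] = after.reindex(base.index)
    base["nearest_before"] = before.reindex(base.index)
    return base


def nearest_imaging_offset(record: pd.Series,
                           procedures: pd.DataFrame) -> int | None:
    """Signed day offset of the patient's imaging order nearest the code date.

    Smallest absolute offset wins; a +d / -d tie resolves to +d.  ``None``
    when the patient has no imaging order.
    """
    rec = pd.DataFrame({
        "patient_id": [record["patient_id"]],
        "registration_date": [pd.Timestamp(record["registration_date"])],
    })
    feats = _offset_features(rec,
                             procedures[procedures["patient_id"]
                                        == record["patient_id"]])
    value = feats.at[0, "nearest_offset"]
    return None if pd.isna(value) else int(value)


def _arm_mask(spec: ArmSpec, records: pd.DataFrame,
              feats: pd.DataFrame) -> pd.Series:
    mask = records["certainty"] == spec.certainty_required
    if spec.imaging == IMAGING_NOT_REQUIRED:
        return mask
    if spec.imaging == IMAGING_ANY:
        return mask & feats["has_imaging"]
    w = int(spec.imaging)
    if spec.window_direction == TWO_SIDED:
        ok = feats["nearest_offset"].abs() <= w
    elif spec.window_direction == AFTER_ONLY:
        ok = feats["nearest_after"] <= w
    else:
        ok = feats["nearest_before"] >= -w
    return mask & ok.fillna(False)


def classify_arms(deduped_records: pd.DataFrame, procedures: pd.DataFrame,
                  arm_specs: list[ArmSpec] | None = None) -> pd.DataFrame:
    """Assign each deduplicated record to every arm whose rule it satisfies.

    Returns one row per record with identifying fields, the nearest signed
    imaging offset (NaN when the patient has no imaging), and one boolean
    column per arm name.
    """
    if arm_specs is None:
        arm_specs = default_arms()
    names = [a.name for a in arm_specs]
    if len(set(names)) != len(names):
        raise UnknownArmError("duplicate arm names", sorted(set(names)))

    records = deduped_records.reset_index(drop=True)
    feats = _offset_features(records, procedures)
    out = records[["record_id", "patient_id", "code", "registration_date",
                   "certainty", "position"]].copy()
    out["nearest_offset"] = feats["nearest_offset"]
    for spec in arm_specs:
        out[spec.name] = _arm_mask(spec, records, feats).to_numpy()
    return out


def arm_records(assignments: pd.DataFrame, arm: str) -> pd.DataFrame:
    """Records belonging to one arm of a classify_arms output."""
    if arm not in assignments.columns:
        known = [c for c in assignments.columns
                 if assignments[c].dtype == bool]
        raise UnknownArmError(arm, known)
    return assignments.loc[assignments[arm]].reset_index(drop=True)


def arm_counts(assignments: pd.DataFrame,
               arm_specs: list[ArmSpec] | None = None) -> dict[str, int]:
    """Record count per arm, in arm order."""
    if arm_specs is None:
        arm_specs = default_arms()
    counts = {}
    for spec in arm_specs:
        if spec.name not in assignments.columns:
            raise UnknownArmError(spec.name, list(assignments.columns))
        counts[spec.name] = int(assignments[spec.name].sum())
    return counts
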