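"""Synthetic hospital-EMR generator with latent chart-review truth.

Stands in for the hospital database and the manual chart review: emits the
three EMR tables plus a truth table giving, for every stroke-code record, the
latent acute-cerebrovascular-disease status and — for false positives — the
coding mechanism behind it.

Two modes:

* :func:`generate_cohort` — stochastic cohort of ~25,827 cancer patients.
  Each stroke-code record traces to exactly one mechanism:

  - **true_event** — genuine acute CVD; definite code with brain imaging at
    the code date (offset 0 or +/-1 day).
  - **history_of_stroke** — old stroke carried forward as a definite code;
    no imaging, or imaging far from the code date (beyond +/-30 days).
  - **stroke_mimic** — another condition coded as stroke; near-date imaging
    (the imaging is exactly why the code was entered), truth negative.
  - **blood_or_imaging_tests** — a definite code entered only to order
    tests; no brain imaging.
  - **ruleout_suspected** — a "suspected" rule-out code with imaging at the
    code date; truth positive only for a small fraction.

  Default mechanism rates are calibrated so the five algorithm arms have
  expected PPVs of roughly 22 / 51 / 84 / 90 / 7 percent (derivation in
  docs/methods.md).

* :func:`generate_fixture` — deterministic bundle realizing exact pipeline
  counts (registry rows, duplicates, invalid dates, distinct/total code
  records, nested imaging-arm sizes), for worked-example tests.

One master seed drives ordered sub-streams per table, so adding a mechanism
never perturbs unrelated draws.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .emr_tables import EmrBundle
from .errors import InfeasibleFixtureError, MissingLabelError
from .validation_study import TRUTH_NEGATIVE, TRUTH_POSITIVE

STUDY_START = pd.Timestamp("2007-01-01")
STUDY_END = pd.Timestamp("2015-12-31")
_SPAN_DAYS = (STUDY_END - STUDY_START).days

STROKE_CODES = ["I639", "I633", "I619", "I609", "G459", "G458"]
_STROKE_CODE_W = np.array([0.50, 0.15, 0.15, 0.08, 0.07, 0.05])

MIMIC_SUBTYPES = [
    "disturbance_of_consciousness", "brain_tumor",
    "cervical_spondylotic_myelopathy", "syncope", "seizure",
    "dementia", "vestibular_dysfunction", "sudden_severe_headache",
    "ophthalmic_disorder", "acute_mononeuropathy",
    "toxic_metabolic_symptoms", "functional_symptoms",
]
_MIMIC_W = np.array([10, 9, 7, 7, 5, 4, 4, 4, 3, 2, 1, 1], dtype=float)
_MIMIC_W /= _MIMIC_W.sum()

_COMORBIDITY_CODES = {
    "hypertension": "I10",
    "diabetes": "E119",
    "dyslipidemia": "E785",
    "atrial_fibrillation": "I48",
    "brain_metastases": "C793",
}

_CANCER_TYPE_WEIGHTS = {
    "breast": 0.113, "uterus": 0.091, "colorectal": 0.081, "gastric": 0.079,
    "lung": 0.065, "brain": 0.063, "prostate": 0.063, "esophageal": 0.054,
    "hepatic": 0.043, "oropharyngeal": 0.040, "other": 0.308,
}
_STAGE_WEIGHTS = {
    "0": 0.061, "I": 0.312, "II": 0.158, "III": 0.115, "IV": 0.155,
    "unknown": 0.199,
}


class OffsetModel(BaseModel):
    """Distribution of signed imaging-order offsets for one mechanism.

    With probability ``p_none`` the patient has no brain imaging; otherwise a
    range is drawn by weight and the day offset uniformly within it
    (inclusive bounds).
    """

    p_none: float = Field(ge=0.0, le=1.0)
    ranges: list[tuple[int, int, float]] = Field(default_factory=list)

    @model_validator(mode="after")
    def _check(self):
        if self.p_none < 1.0 and not self.ranges:
            raise ValueError("offset ranges required when p_none < 1")
        for low, high, weight in self.ranges:
            if low > high or weight <= 0:
                raise ValueError(f"bad offset range ({low}, {high}, {weight})")
        return self

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """n offsets as floats, NaN meaning no imaging."""
        out = np.full(n, np.nan)
        has = rng.random(n) >= self.p_none
        k = int(has.sum())
        if k and self.ranges:
            weights = np.array([w for _, _, w in self.ranges], dtype=float)
            weights /= weights.sum()
            which = rng.choice(len(self.ranges), size=k, p=weights)
            lows = np.array([r[0] for r in self.ranges])
            highs = np.array([r[1] for r in self.ranges])
            out[has] = rng.integers(lows[which], highs[which] + 1)
        return out


def _default_offset_models() -> dict[str, OffsetModel]:
    return {
        "true_event": OffsetModel(p_none=0.0, ranges=[(-1, 1, 1.0)]),
        "history_of_stroke": OffsetModel(
            p_none=0.6, ranges=[(-365, -31, 0.5), (31, 365, 0.5)]),
        "stroke_mimic": OffsetModel(
            p_none=0.0, ranges=[(-1, 1, 0.58333), (2, 30, 0.41667)]),
        "blood_or_imaging_tests": OffsetModel(p_none=1.0),
        "ruleout_suspected": OffsetModel(p_none=0.0, ranges=[(-1, 1, 1.0)]),
    }


class SyntheticConfig(BaseModel):
    """Parameters of the stochastic EMR generator.

    Mechanism rates are per patient over the whole study window; the
    defaults are calibrated so the shipped arms reproduce the expected PPV
    gradient (see module docstring).
    """

    n_patients: int = Field(default=25827, ge=1)
    duplicate_patient_count: int = Field(default=2083, ge=0)
    invalid_date_count: int = Field(default=22, ge=0)
    female_fraction: float = Field(default=0.495, ge=0.0, le=1.0)
    age_mean: float = Field(default=61.6, gt=0)
    age_sd: float = Field(default=15.7, ge=0)
    cancer_type_weights: dict[str, float] = Field(
        default_factory=lambda: dict(_CANCER_TYPE_WEIGHTS))
    stage_weights: dict[str, float] = Field(
        default_factory=lambda: dict(_STAGE_WEIGHTS))
    # mechanism rates, per patient over the study window
    true_event_rate: float = Field(default=0.007769, ge=0.0, le=1.0)
    history_coding_rate: float = Field(default=0.014962, ge=0.0, le=1.0)
    mimic_rate: float = Field(default=0.001480, ge=0.0, le=1.0)
    testonly_coding_rate: float = Field(default=0.011103, ge=0.0, le=1.0)
    ruleout_suspected_rate: float = Field(default=0.008828, ge=0.0, le=1.0)
    ruleout_true_fraction: float = Field(default=0.07, ge=0.0, le=1.0)
    imaging_offset_model: dict[str, OffsetModel] = Field(
        default_factory=_default_offset_models)
    same_day_duplication_prob: float = Field(default=0.54, ge=0.0, lt=1.0)
    primary_position_fraction: float = Field(default=0.07, ge=0.0, le=1.0)
    background_imaging_rate: float = Field(default=0.13, ge=0.0, le=1.0)
    comorbidity_rates: dict[str, float] = Field(default_factory=lambda: {
        "hypertension": 0.203, "diabetes": 0.175, "dyslipidemia": 0.127,
        "atrial_fibrillation": 0.033, "brain_metastases": 0.018,
    })
    seed: int

    @model_validator(mode="after")
    def _check(self):
        for name in ("true_event", "history_of_stroke", "stroke_mimic",
                     "blood_or_imaging_tests", "ruleout_suspected"):
            if name not in self.imaging_offset_model:
                raise ValueError(f"imaging_offset_model missing {name!r}")
        for cond, rate in self.comorbidity_rates.items():
            if cond not in _COMORBIDITY_CODES:
                raise ValueError(f"unknown comorbidity {cond!r}")
            if not 0 <= rate <= 1:
                raise ValueError(f"comorbidity_rates[{cond!r}] outside [0, 1]")
        return self


_MECHANISMS = [
    # (name, rate attribute, certainty, truth category when negative)
    ("true_event", "true_event_rate", "definite", None),
    ("history_of_stroke", "history_coding_rate", "definite",
     "history_of_stroke"),
    ("stroke_mimic", "mimic_rate", "definite", "stroke_mimic"),
    ("blood_or_imaging_tests", "testonly_coding_rate", "definite",
     "blood_or_imaging_tests"),
    ("ruleout_suspected", "ruleout_suspected_rate", "suspected", None),
]


def _substreams(seed: int, names: list[str]) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: np.random.default_rng(child)
            for name, child in zip(names, children)}


def _random_dates(n: int, rng: np.random.Generator) -> pd.Series:
    days = rng.integers(0, _SPAN_DAYS + 1, size=n)
    return STUDY_START + pd.to_timedelta(days, unit="D")


def _draw_positions(n: int, p_primary: float,
                    rng: np.random.Generator) -> np.ndarray:
    rest = 1.0 - p_primary
    return rng.choice(["primary", "secondary", "other"], size=n,
                      p=[p_primary, rest * 0.65, rest * 0.35])


def generate_cohort(config: SyntheticConfig) -> tuple[EmrBundle, pd.DataFrame]:
    """Simulate the registry, diagnoses and imaging orders plus latent truth.

    Returns the bundle (pre-cleaning: duplicate registry rows and
    death-before-birth mistakes included) and the truth table covering every
    stroke-code record (columns record_id, truth, category, mimic_subtype,
    mechanism).
    """
    rngs = _substreams(config.seed, [
        "patients", "events", "imaging", "duplication", "comorbidity",
        "background", "injection",
    ])

    # --- patient registry -------------------------------------------------
    rng = rngs["patients"]
    n = config.n_patients
    ids = np.array([f"S{i:06d}" for i in range(n)])
    registration = _random_dates(n, rng)
    ages = np.clip(rng.normal(config.age_mean, config.age_sd, size=n), 18, 100)
    birth = registration - pd.to_timedelta(np.round(ages * 365.25), unit="D")
    dies = rng.random(n) < 0.25
    death_offset = rng.integers(30, 3000, size=n)
    death = pd.Series(pd.NaT, index=range(n))
    death[dies] = registration[dies] + pd.to_timedelta(
        death_offset[dies], unit="D")
    sex = np.where(rng.random(n) < config.female_fraction, "female", "male")
    type_names = list(config.cancer_type_weights)
    type_w = np.array(list(config.cancer_type_weights.values()), dtype=float)
    stage_names = list(config.stage_weights)
    stage_w = np.array(list(config.stage_weights.values()), dtype=float)
    patients = pd.DataFrame({
        "patient_id": ids,
        "birth_date": birth,
        "death_date": pd.to_datetime(death),
        "sex": sex,
        "cancer_type": rng.choice(type_names, size=n, p=type_w / type_w.sum()),
        "cancer_stage": rng.choice(stage_names, size=n,
                                   p=stage_w / stage_w.sum()),
        "registration_date": registration,
    })

    # --- stroke-code events, one mechanism each ---------------------------
    rng = rngs["events"]
    event_frames = []
    for mech, rate_attr, certainty, neg_category in _MECHANISMS:
        hit = rng.random(n) < getattr(config, rate_attr)
        k = int(hit.sum())
        if k == 0:
            continue
        if mech == "ruleout_suspected":
            positive = rng.random(k) < config.ruleout_true_fraction
        elif mech == "true_event":
            positive = np.ones(k, dtype=bool)
        else:
            positive = np.zeros(k, dtype=bool)
        subtype = np.where(
            (~positive) & (mech == "stroke_mimic"),
            rng.choice(MIMIC_SUBTYPES, size=k, p=_MIMIC_W), "")
        reg = registration[hit]
        gap = rng.integers(0, np.maximum((STUDY_END - reg).days, 0) + 1)
        event_frames.append(pd.DataFrame({
            "patient_id": ids[hit],
            "code": rng.choice(STROKE_CODES, size=k,
                               p=_STROKE_CODE_W / _STROKE_CODE_W.sum()),
            "registration_date": reg + pd.to_timedelta(gap, unit="D"),
            "certainty": certainty,
            "position": _draw_positions(
                k, config.primary_position_fraction, rng),
            "mechanism": mech,
            "truth": np.where(positive, TRUTH_POSITIVE, TRUTH_NEGATIVE),
            "category": np.where(positive, "",
                                 neg_category or "stroke_mimic"),
            "mimic_subtype": subtype,
        }))
    events = (pd.concat(event_frames, ignore_index=True) if event_frames
              else pd.DataFrame(columns=[
                  "patient_id", "code", "registration_date", "certainty",
                  "position", "mechanism", "truth", "category",
                  "mimic_subtype"]))

    # ruleout codes that are truly positive get no mechanism category
    neg_ruleout = ((events["mechanism"] == "ruleout_suspected")
                   & (events["truth"] == TRUTH_NEGATIVE))
    events.loc[neg_ruleout, "category"] = "blood_or_imaging_tests"

    # --- imaging orders linked to events -----------------------------------
    rng = rngs["imaging"]
    order_rows = []
    for mech, model in config.imaging_offset_model.items():
        part = events.loc[events["mechanism"] == mech]
        if len(part) == 0:
            continue
        offsets = model.sample(len(part), rng)
        has = ~np.isnan(offsets)
        order_rows.append(pd.DataFrame({
            "patient_id": part.loc[has, "patient_id"].to_numpy(),
            "modality": rng.choice(["MRI", "CT"], size=int(has.sum()),
                                   p=[0.6, 0.4]),
            "order_date": part.loc[has, "registration_date"].to_numpy()
            + pd.to_timedelta(offsets[has], unit="D"),
        }))

    # background imaging for patients without stroke codes
    rng = rngs["background"]
    coded = set(events["patient_id"])
    uncoded = ~pd.Series(ids).isin(coded).to_numpy()
    bg = (rng.random(n) < config.background_imaging_rate) & uncoded
    k = int(bg.sum())
    if k:
        order_rows.append(pd.DataFrame({
            "patient_id": ids[bg],
            "modality": rng.choice(["MRI", "CT"], size=k, p=[0.5, 0.5]),
            "order_date": _random_dates(k, rng),
        }))
    procedures = (pd.concat(order_rows, ignore_index=True) if order_rows
                  else pd.DataFrame(columns=["patient_id", "modality",
                                             "order_date"]))
    procedures = procedures.sort_values(
        ["patient_id", "order_date"], kind="stable").reset_index(drop=True)
    procedures.insert(0, "record_id",
                      [f"P{i:07d}" for i in range(len(procedures))])

    # --- same-day duplicate registrations ----------------------------------
    rng = rngs["duplication"]
    p = config.same_day_duplication_prob
    extras = (rng.geometric(1.0 - p, size=len(events)) - 1 if p > 0
              else np.zeros(len(events), dtype=int))
    dup_idx = np.repeat(events.index.to_numpy(), extras)
    duplicates = events.loc[dup_idx].copy()
    duplicates["position"] = "other"  # second-department re-registration
    diagnoses = pd.concat([events, duplicates], ignore_index=True)
    diagnoses["department"] = "neurology"
    diagnoses.loc[len(events):, "department"] = "other_department"

    # --- comorbidity codes --------------------------------------------------
    rng = rngs["comorbidity"]
    com_rows = []
    for cond, rate in config.comorbidity_rates.items():
        hit = rng.random(n) < rate
        k = int(hit.sum())
        if k == 0:
            continue
        com_rows.append(pd.DataFrame({
            "patient_id": ids[hit],
            "code": _COMORBIDITY_CODES[cond],
            "registration_date": _random_dates(k, rng),
            "certainty": "definite",
            "position": "other",
            "mechanism": "",
            "truth": "",
            "category": "",
            "mimic_subtype": "",
            "department": "internal_medicine",
        }))
    if com_rows:
        diagnoses = pd.concat([diagnoses] + com_rows, ignore_index=True)

    diagnoses.insert(0, "record_id",
                     [f"D{i:07d}" for i in range(len(diagnoses))])
    truth = diagnoses.loc[diagnoses["mechanism"] != "",
                          ["record_id", "truth", "category",
                           "mimic_subtype", "mechanism"]].reset_index(drop=True)
    diagnoses = diagnoses[["record_id", "patient_id", "code",
                           "registration_date", "certainty", "position",
                           "department"]]

    # --- registry-noise injection: duplicate rows and date mistakes --------
    rng = rngs["injection"]
    if config.duplicate_patient_count > 0:
        pick = rng.choice(n, size=config.duplicate_patient_count,
                          replace=config.duplicate_patient_count > n)
        dup_rows = patients.iloc[pick].copy()
        dup_rows["registration_date"] = (
            dup_rows["registration_date"] + pd.Timedelta(days=1))
        patients = pd.concat([patients, dup_rows], ignore_index=True)
    if config.invalid_date_count > 0:
        m = config.invalid_date_count
        reg = _random_dates(m, rng)
        bad = pd.DataFrame({
            "patient_id": [f"X{i:06d}" for i in range(m)],
            "birth_date": reg - pd.Timedelta(days=365 * 40),
            "death_date": reg - pd.Timedelta(days=365 * 41),
            "sex": rng.choice(["male", "female"], size=m),
            "cancer_type": "other",
            "cancer_stage": "unknown",
            "registration_date": reg,
        })
        patients = pd.concat([patients, bad], ignore_index=True)

    bundle = EmrBundle(patients, diagnoses, procedures)
    return bundle, truth


class FixtureSpec(BaseModel):
    """Exact pipeline counts a deterministic fixture bundle must realize."""

    registry_rows: int = 27932
    duplicate_rows: int = 2083
    invalid_rows: int = 22
    distinct_definite: int = 912
    total_definite: int = 1991
    distinct_suspected: int = 228
    total_suspected: int = 663
    imaging_any: int = 438
    imaging_w30: int = 239
    imaging_w1: int = 212
    imaging_orders_total: Optional[int] = 4544
    seed: int = 0

    @model_validator(mode="after")
    def _check(self):
        if not (0 <= self.imaging_w1 <= self.imaging_w30
                <= self.imaging_any <= self.distinct_definite):
            raise InfeasibleFixtureError(
                "imaging counts must nest: w1 <= w30 <= any <= distinct "
                f"definite; got {self.imaging_w1}/{self.imaging_w30}/"
                f"{self.imaging_any}/{self.distinct_definite}")
        if (self.total_definite < self.distinct_definite
                or self.total_suspected < self.distinct_suspected):
            raise InfeasibleFixtureError("totals must be >= distinct events")
        retained = self.registry_rows - self.duplicate_rows - self.invalid_rows
        if retained < self.distinct_definite + self.distinct_suspected:
            raise InfeasibleFixtureError(
                f"only {retained} retained patients for "
                f"{self.distinct_definite + self.distinct_suspected} events")
        if self.duplicate_rows > retained:
            raise InfeasibleFixtureError(
                "more duplicate rows than patients to duplicate")
        linked = self.imaging_any + self.distinct_suspected
        if (self.imaging_orders_total is not None
                and self.imaging_orders_total < linked):
            raise InfeasibleFixtureError(
                f"imaging_orders_total {self.imaging_orders_total} below the "
                f"{linked} orders implied by the arm counts")
        return self


# deterministic offset cycles per imaging band of the fixture
_W1_OFFSETS = [0, 1, -1]
_W30_OFFSETS = [7, 15, 30, -10, -25]
_FAR_OFFSETS = [45, -60, 120, 300]

# full-arm truth fractions the fixture labels approximate
_FIXTURE_PPV = {"w1": 0.90, "w30": 0.84, "any": 0.51, "suspected": 0.07}


def _fixture_truth_flags(spec: FixtureSpec) -> np.ndarray:
    """Acute/non-acute flag per definite event index (imaging-band order)."""
    acute_w1 = round(_FIXTURE_PPV["w1"] * spec.imaging_w1)
    acute_w30 = max(acute_w1, round(_FIXTURE_PPV["w30"] * spec.imaging_w30))
    acute_any = max(acute_w30, round(_FIXTURE_PPV["any"] * spec.imaging_any))
    flags = np.zeros(spec.distinct_definite, dtype=bool)
    flags[:acute_w1] = True
    flags[spec.imaging_w1:spec.imaging_w1 + (acute_w30 - acute_w1)] = True
    flags[spec.imaging_w30:spec.imaging_w30 + (acute_any - acute_w30)] = True
    return flags


def generate_fixture(spec: FixtureSpec) -> tuple[EmrBundle, pd.DataFrame]:
    """Deterministic bundle whose pipeline counts equal the requested counts.

    Definite events occupy one patient each, ordered so the first
    ``imaging_w1`` have imaging within one day, the next up to ``imaging_w30``
    within 30 days, the next up to ``imaging_any`` beyond 30 days, and the
    rest none; suspected events all carry same-day imaging.  Truth labels are
    deterministic and approximate the observed full-arm PPV gradient.
    """
    rng = np.random.default_rng(spec.seed)
    retained = spec.registry_rows - spec.duplicate_rows - spec.invalid_rows

    ids = np.array([f"F{i:06d}" for i in range(retained)])
    registration = _random_dates(retained, rng)
    birth = registration - pd.to_timedelta(
        np.round(np.clip(rng.normal(61.6, 15.7, retained), 18, 100) * 365.25),
        unit="D")
    patients = pd.DataFrame({
        "patient_id": ids,
        "birth_date": birth,
        "death_date": pd.NaT,
        "sex": rng.choice(["female", "male"], size=retained),
        "cancer_type": "other",
        "cancer_stage": "unknown",
        "registration_date": registration,
    })
    patients["death_date"] = pd.to_datetime(patients["death_date"])

    # registry noise: later re-registrations of existing ids + date mistakes
    dup_rows = patients.iloc[:spec.duplicate_rows].copy()
    dup_rows["registration_date"] += pd.Timedelta(days=7)
    reg_bad = _random_dates(spec.invalid_rows, rng)
    bad_rows = pd.DataFrame({
        "patient_id": [f"X{i:06d}" for i in range(spec.invalid_rows)],
        "birth_date": reg_bad - pd.Timedelta(days=365 * 40),
        "death_date": reg_bad - pd.Timedelta(days=365 * 41),
        "sex": "male",
        "cancer_type": "other",
        "cancer_stage": "unknown",
        "registration_date": reg_bad,
    })
    registry = pd.concat([patients, dup_rows, bad_rows], ignore_index=True)

    # --- definite events, one per patient, imaging-band ordered ------------
    nd = spec.distinct_definite
    event_patients = ids[:nd]
    event_dates = registration[:nd] + pd.Timedelta(days=60)
    codes = np.array([STROKE_CODES[i % len(STROKE_CODES)] for i in range(nd)])
    positions = np.where(np.arange(nd) % 14 == 0, "primary", "secondary")
    truth_flags = _fixture_truth_flags(spec)

    offsets = np.full(nd, np.nan)
    for i in range(spec.imaging_w1):
        offsets[i] = _W1_OFFSETS[i % len(_W1_OFFSETS)]
    for j, i in enumerate(range(spec.imaging_w1, spec.imaging_w30)):
        offsets[i] = _W30_OFFSETS[j % len(_W30_OFFSETS)]
    for j, i in enumerate(range(spec.imaging_w30, spec.imaging_any)):
        offsets[i] = _FAR_OFFSETS[j % len(_FAR_OFFSETS)]

    categories = np.full(nd, "", dtype=object)
    subtypes = np.full(nd, "", dtype=object)
    mechanisms = np.full(nd, "true_event", dtype=object)
    neg = ~truth_flags
    near = ~np.isnan(offsets) & (np.abs(offsets) <= 30)
    far = ~np.isnan(offsets) & (np.abs(offsets) > 30)
    none = np.isnan(offsets)
    categories[neg & near] = "stroke_mimic"
    mechanisms[neg & near] = "stroke_mimic"
    categories[neg & far] = "history_of_stroke"
    mechanisms[neg & far] = "history_of_stroke"
    none_idx = np.flatnonzero(neg & none)
    for j, i in enumerate(none_idx):  # alternate the imaging-free mechanisms
        cat = ("history_of_stroke" if j % 2 == 0
               else "blood_or_imaging_tests")
        categories[i] = cat
        mechanisms[i] = cat
    mimic_idx = np.flatnonzero(categories == "stroke_mimic")
    for j, i in enumerate(mimic_idx):
        subtypes[i] = MIMIC_SUBTYPES[j % len(MIMIC_SUBTYPES)]

    definite = pd.DataFrame({
        "patient_id": event_patients,
        "code": codes,
        "registration_date": event_dates,
        "certainty": "definite",
        "position": positions,
        "truth": np.where(truth_flags, TRUTH_POSITIVE, TRUTH_NEGATIVE),
        "category": categories,
        "mimic_subtype": subtypes,
        "mechanism": mechanisms,
    })

    # --- suspected events: disjoint patients, all with same-day imaging ----
    ns = spec.distinct_suspected
    s_patients = ids[nd:nd + ns]
    s_dates = registration[nd:nd + ns] + pd.Timedelta(days=45)
    n_pos = round(_FIXTURE_PPV["suspected"] * ns)
    s_truth = np.arange(ns) < n_pos
    s_cat = np.where(s_truth, "",
                     np.where(np.arange(ns) % 2 == 0, "stroke_mimic",
                              "blood_or_imaging_tests"))
    s_sub = np.where(s_cat == "stroke_mimic",
                     [MIMIC_SUBTYPES[i % len(MIMIC_SUBTYPES)]
                      for i in range(ns)], "")
    suspected = pd.DataFrame({
        "patient_id": s_patients,
        "code": [STROKE_CODES[i % len(STROKE_CODES)] for i in range(ns)],
        "registration_date": s_dates,
        "certainty": "suspected",
        "position": np.where(np.arange(ns) % 14 == 0, "primary", "secondary"),
        "truth": np.where(s_truth, TRUTH_POSITIVE, TRUTH_NEGATIVE),
        "category": s_cat,
        "mimic_subtype": s_sub,
        "mechanism": np.where(s_truth, "true_event", "ruleout_suspected"),
    })

    def _expand(base: pd.DataFrame, total: int) -> pd.DataFrame:
        extra = total - len(base)
        pick = np.arange(extra) % len(base)
        dup = base.iloc[pick].copy()
        dup["position"] = "other"
        return pd.concat([base, dup], ignore_index=True)

    diagnoses = pd.concat([
        _expand(definite, spec.total_definite),
        _expand(suspected, spec.total_suspected),
    ], ignore_index=True)
    diagnoses["department"] = "neurology"
    diagnoses.insert(0, "record_id",
                     [f"DF{i:06d}" for i in range(len(diagnoses))])
    truth = diagnoses[["record_id", "truth", "category", "mimic_subtype",
                       "mechanism"]].copy()
    diagnoses = diagnoses[["record_id", "patient_id", "code",
                           "registration_date", "certainty", "position",
                           "department"]]

    # --- imaging orders -----------------------------------------------------
    has_img = ~np.isnan(offsets)
    order_frames = [
        pd.DataFrame({
            "patient_id": event_patients[has_img],
            "modality": "MRI",
            "order_date": event_dates[has_img]
            + pd.to_timedelta(offsets[has_img], unit="D"),
        }),
        pd.DataFrame({
            "patient_id": s_patients,
            "modality": "CT",
            "order_date": s_dates,
        }),
    ]
    linked = int(has_img.sum()) + ns
    if spec.imaging_orders_total is not None:
        pad = spec.imaging_orders_total - linked
        pad_patients = ids[nd + ns:nd + ns + pad]
        if pad > len(pad_patients):
            raise InfeasibleFixtureError(
                "not enough stroke-free patients for padding imaging orders")
        order_frames.append(pd.DataFrame({
            "patient_id": pad_patients,
            "modality": "CT",
            "order_date": registration[nd + ns:nd + ns + pad]
            + pd.Timedelta(days=10),
        }))
    procedures = pd.concat(order_frames, ignore_index=True)
    procedures.insert(0, "record_id",
                      [f"PF{i:06d}" for i in range(len(procedures))])

    return EmrBundle(registry, diagnoses, procedures), truth


def load_scenario(path: str | None = None, *,
                  seed: int | None = None, **overrides) -> SyntheticConfig:
    """Read a SyntheticConfig from YAML; default is the calibrated scenario."""
    import yaml
    from importlib import resources

    if path is None:
        text = resources.files("phenoval.data").joinpath(
            "scenario_calibrated.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text) or {}
    raw.update(overrides)
    if seed is not None:
        raw["seed"] = seed
    return SyntheticConfig(**raw)


def load_fixture_spec(path: str | None = None, **overrides) -> FixtureSpec:
    """Read a FixtureSpec from YAML; default is the shipped flow-count file."""
    import yaml
    from importlib import resources

    if path is None:
        text = resources.files("phenoval.data").joinpath(
            "fixture_flow_counts.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text) or {}
    raw.update(overrides)
    return FixtureSpec(**raw)


def auto_label(sample: pd.DataFrame, truth_table: pd.DataFrame,
               noise: float = 0.0,
               seed: int | None = None) -> pd.DataFrame:
    """Label a review sample from the latent truth (a simulated reviewer).

    With ``noise`` > 0 each label flips independently with that probability:
    a flipped positive becomes a stroke mimic, a flipped negative becomes
    positive.  Raises when a sampled record is missing from the truth table.
    """
    merged = sample[["record_id"]].merge(truth_table, on="record_id",
                                         how="left")
    missing = merged.loc[merged["truth"].isna(), "record_id"].tolist()
    if missing:
        raise MissingLabelError(missing)
    labels = merged[["record_id", "truth", "category", "mimic_subtype"]].copy()
    if noise > 0:
        rng = np.random.default_rng(seed)
        flip = rng.random(len(labels)) < noise
        was_pos = labels["truth"] == TRUTH_POSITIVE
        labels.loc[flip & was_pos, "truth"] = TRUTH_NEGATIVE
        labels.loc[flip & was_pos, "category"] = "stroke_mimic"
        labels.loc[flip & was_pos, "mimic_subtype"] = "functional_symptoms"
        labels.loc[flip & ~was_pos, "truth"] = TRUTH_POSITIVE
        labels.loc[flip & ~was_pos, ["category", "mimic_subtype"]] = ""
    return labels
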