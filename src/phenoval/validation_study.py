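"""Chart-review sampling, PPV estimation, and report rendering.

For each algorithm arm a fixed-size review sample (default 100 records) is
drawn uniformly without replacement; an external label table — from a human
chart reviewer or the synthetic truth oracle — marks each sampled record as
acute cerebrovascular disease or not.  Positive predictive value (PPV) is the
fraction confirmed, reported overall and stratified by code position
(primary vs secondary-or-others), with exact Clopper–Pearson 95% intervals
(Wilson optionally).  Percentages round to the nearest integer, ties away
from zero.  A breakdown of the false positives tallies the three coding
mechanisms behind them: history of stroke, stroke mimics, and codes entered
only to order blood/imaging tests.
"""

from __future__ import annotations

import math
import os
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .errors import EmptyArmError, MissingLabelError, OverlappingStrataError

TRUTH_POSITIVE = "acute_cvd"
TRUTH_NEGATIVE = "not_acute_cvd"
NONDISEASE_CATEGORIES = (
    "history_of_stroke", "stroke_mimic", "blood_or_imaging_tests",
)

STRATUM_ALL = "all"
STRATUM_PRIMARY = "primary"
STRATUM_SECONDARY = "secondary_or_others"


def round_half_away(x: float) -> int:
    """Nearest-integer rounding with ties away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class ReviewDesign:
    """How many records to review per arm and with what random stream."""

    sample_size: int = 100
    seed: int = 0
    stratify_by_position: bool = False

    def __post_init__(self):
        if self.sample_size < 1:
            raise ValueError("sample_size must be >= 1")


@dataclass
class PpvEstimate:
    """A binomial proportion with its exact confidence interval."""

    stratum: str
    n_sampled: int
    n_positive: int
    ppv: float = field(init=False)
    ci_low: float = field(init=False)
    ci_high: float = field(init=False)
    ci_method: str = "beta"  # statsmodels name for Clopper-Pearson

    def __post_init__(self):
        if not 0 <= self.n_positive <= self.n_sampled:
            raise ValueError("need 0 <= n_positive <= n_sampled")
        self.ppv = self.n_positive / self.n_sampled
        low, high = proportion_confint(self.n_positive, self.n_sampled,
                                       alpha=0.05, method=self.ci_method)
        self.ci_low, self.ci_high = float(low), float(high)

    @property
    def report_percent(self) -> int:
        return round_half_away(100.0 * self.n_positive / self.n_sampled)


def draw_review_sample(arm_records: pd.DataFrame,
                       design: ReviewDesign) -> pd.DataFrame:
    """Uniform sample without replacement of min(sample_size, arm size) rows.

    Deterministic given the design seed; warns when the arm is smaller than
    the requested sample and every record is returned instead.
    """
    n = len(arm_records)
    if n == 0:
        raise EmptyArmError("(empty)")
    k = min(design.sample_size, n)
    if k < design.sample_size:
        warnings.warn(
            f"arm has only {n} records; reviewing all of them instead of "
            f"{design.sample_size}", stacklevel=2)
    rng = np.random.default_rng(design.seed)
    idx = rng.choice(n, size=k, replace=False)
    return arm_records.iloc[idx].reset_index(drop=True)


def _stratum_mask(sample: pd.DataFrame, stratum: str) -> pd.Series:
    if stratum == STRATUM_ALL:
        return pd.Series(True, index=sample.index)
    if stratum == STRATUM_PRIMARY:
        return sample["position"] == "primary"
    if stratum == STRATUM_SECONDARY:
        return sample["position"] != "primary"
    raise ValueError(f"unknown stratum {stratum!r}")


def estimate_ppv(sample: pd.DataFrame, labels: pd.DataFrame,
                 stratum: str = STRATUM_ALL,
                 ci_method: str = "beta") -> PpvEstimate:
    """PPV of a reviewed sample within one position stratum.

    ``labels`` must cover every sampled record (columns record_id, truth);
    missing labels raise with the offending ids listed.
    """
    part = sample.loc[_stratum_mask(sample, stratum)]
    merged = part.merge(labels[["record_id", "truth"]], on="record_id",
                        how="left", validate="one_to_one")
    missing = merged.loc[merged["truth"].isna(), "record_id"].tolist()
    if missing:
        raise MissingLabelError(missing)
    n_pos = int((merged["truth"] == TRUTH_POSITIVE).sum())
    return PpvEstimate(stratum, len(merged), n_pos, ci_method=ci_method)


def pooled_ppv(stratum_estimates: list[PpvEstimate],
               ci_method: str = "beta") -> PpvEstimate:
    """Pool disjoint, exhaustive strata by summing numerators/denominators.

    Exact integer arithmetic before any rounding, so the pooled PPV equals
    the sample-size-weighted mean of the stratum PPVs.
    """
    strata = [e.stratum for e in stratum_estimates]
    if len(set(strata)) != len(strata) or STRATUM_ALL in strata:
        raise OverlappingStrataError(strata)
    if len(stratum_estimates) == 1:
        only = stratum_estimates[0]
        return PpvEstimate(STRATUM_ALL, only.n_sampled, only.n_positive,
                           ci_method=ci_method)
    n = sum(e.n_sampled for e in stratum_estimates)
    pos = sum(e.n_positive for e in stratum_estimates)
    return PpvEstimate(STRATUM_ALL, n, pos, ci_method=ci_method)


@dataclass
class NonDiseaseTally:
    """Counts of false-positive mechanisms among reviewed records."""

    history_of_stroke: int
    stroke_mimic: int
    blood_or_imaging_tests: int
    mimic_subtypes: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return (self.history_of_stroke + self.stroke_mimic
                + self.blood_or_imaging_tests)

    def as_dict(self) -> dict[str, int]:
        return {
            "history_of_stroke": self.history_of_stroke,
            "stroke_mimic": self.stroke_mimic,
            "blood_or_imaging_tests": self.blood_or_imaging_tests,
        }


def tally_nondisease(labels: pd.DataFrame) -> NonDiseaseTally:
    """Break down the non-disease labels of one arm's review.

    ``labels`` carries truth, category, and (for mimics) mimic_subtype; the
    tally total equals the number of sampled records not confirmed positive.
    """
    neg = labels.loc[labels["truth"] == TRUTH_NEGATIVE]
    counts = Counter(neg["category"])
    unknown = set(counts) - set(NONDISEASE_CATEGORIES)
    if unknown:
        raise ValueError(f"unknown non-disease categories: {sorted(unknown)}")
    subtypes: Counter = Counter()
    if "mimic_subtype" in neg.columns:
        mimics = neg.loc[neg["category"] == "stroke_mimic", "mimic_subtype"]
        subtypes = Counter(s for s in mimics if isinstance(s, str) and s)
    return NonDiseaseTally(
        history_of_stroke=counts.get("history_of_stroke", 0),
        stroke_mimic=counts.get("stroke_mimic", 0),
        blood_or_imaging_tests=counts.get("blood_or_imaging_tests", 0),
        mimic_subtypes=dict(sorted(subtypes.items())),
    )


def _markdown_table(header: list[str], rows: list[list]) -> str:
    lines = ["| " + " | ".join(str(c) for c in header) + " |",
             "|" + "|".join([" --- "] * len(header)) + "|"]
    for row in rows:
        lines.append("| " + " | ".join(str(c) for c in row) + " |")
    return "\n".join(lines)


def render_report(arm_results: dict[str, dict], out_dir: str | os.PathLike,
                  *, seed: int | None = None,
                  config_note: str = "") -> dict[str, str]:
    """Write the validation report as CSV + markdown.

    ``arm_results`` maps arm name to a dict with keys ``n_records`` (arm
    size) and optionally ``estimates`` (list of PpvEstimate per stratum) and
    ``tally`` (NonDiseaseTally).  Identical inputs produce identical files.
    """
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for arm, res in arm_results.items():
        ests = res.get("estimates") or []
        if not ests:
            rows.append({"arm": arm, "n_records": res.get("n_records", ""),
                         "stratum": "", "n_sampled": "", "n_positive": "",
                         "ppv_percent": "", "ci_low": "", "ci_high": ""})
        for est in ests:
            rows.append({
                "arm": arm, "n_records": res.get("n_records", ""),
                "stratum": est.stratum, "n_sampled": est.n_sampled,
                "n_positive": est.n_positive,
                "ppv_percent": est.report_percent,
                "ci_low": round(est.ci_low, 4), "ci_high": round(est.ci_high, 4),
            })
    table = pd.DataFrame(rows)
    csv_path = os.path.join(out_dir, "ppv_report.csv")
    table.to_csv(csv_path, index=False)

    md_lines = ["# Diagnostic-code validation report", ""]
    if seed is not None:
        md_lines.append(f"Seed: {seed}")
    if config_note:
        md_lines.append(f"Config: {config_note}")
    md_lines += ["", "## PPV by arm and code position", "",
                 _markdown_table(list(table.columns),
                                 table.fillna("").values.tolist()), ""]

    breakdown_rows = []
    for arm, res in arm_results.items():
        tally = res.get("tally")
        if tally is None:
            continue
        for category, count in tally.as_dict().items():
            breakdown_rows.append({"arm": arm, "category": category,
                                   "subtype": "", "count": count})
        for subtype, count in tally.mimic_subtypes.items():
            breakdown_rows.append({"arm": arm, "category": "stroke_mimic",
                                   "subtype": subtype, "count": count})
    paths = {"csv": csv_path}
    if breakdown_rows:
        bd = pd.DataFrame(breakdown_rows)
        bd_path = os.path.join(out_dir, "nondisease_breakdown.csv")
        bd.to_csv(bd_path, index=False)
        paths["breakdown_csv"] = bd_path
        md_lines += ["## Breakdown of non-disease records", "",
                     _markdown_table(list(bd.columns), bd.values.tolist()), ""]

    md_path = os.path.join(out_dir, "report.md")
    with open(md_path, "w") as fh:
        fh.write("\n".join(md_lines))
    paths["markdown"] = md_path
    return paths
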