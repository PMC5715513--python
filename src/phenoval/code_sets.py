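"""ICD-10 code normalization, code-set membership, and cohort prevalence.

A :class:`CodeSet` names a condition via three matching rules, mirroring how
code lists are published in validation studies:

* exact normalized codes (e.g. ``G458``, ``G459`` — deliberately not the
  whole G45 category),
* 3-character category prefixes (e.g. ``I63`` matches ``I63``, ``I639`` ...),
* inclusive category ranges (block notation such as I10–I15 for
  hypertension: any code whose first three characters fall in the range).

Codes are stored dot-free and uppercase (``"I63.9"`` → ``"I639"``), the form
used in Japanese EMR extracts.  The default sets shipped in
``data/code_sets.yaml`` cover acute stroke (I60, I61, I63, G458, G459) and
the stroke-related covariates: hypertension I10–I15, diabetes mellitus
E10–E14, dyslipidemia E78, atrial fibrillation I48, and brain metastases
C793.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd
import yaml

from .errors import CodePatternError

_CODE_RE = re.compile(r"^[A-Z][0-9]{2}[0-9A-Z]*$")
_CATEGORY_RE = re.compile(r"^[A-Z][0-9]{2}$")


def normalize_code(raw: object) -> str:
    """Normalize an ICD-10 code: strip, uppercase, remove the dot.

    Raises :class:`CodePatternError` for empty strings or anything that does
    not reduce to letter + two digits (+ optional subdivision characters).
    """
    if raw is None or not str(raw).strip():
        raise CodePatternError(raw)
    code = str(raw).strip().upper().replace(".", "")
    if not _CODE_RE.match(code):
        raise CodePatternError(raw)
    return code


@dataclass(frozen=True)
class CodeSet:
    """A named ICD-10 code collection with exact / prefix / range members."""

    name: str
    exact_codes: frozenset[str] = frozenset()
    category_prefixes: frozenset[str] = frozenset()
    category_ranges: tuple[tuple[str, str], ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "exact_codes",
                           frozenset(normalize_code(c) for c in self.exact_codes))
        for cat in self.category_prefixes:
            if not _CATEGORY_RE.match(cat):
                raise CodePatternError(cat)
        object.__setattr__(self, "category_prefixes",
                           frozenset(self.category_prefixes))
        ranges = []
        for start, end in self.category_ranges:
            if not (_CATEGORY_RE.match(start) and _CATEGORY_RE.match(end)):
                raise CodePatternError((start, end))
            if start[0] != end[0] or start > end:
                raise ValueError(
                    f"{self.name}: range {start}–{end} must stay within one "
                    "letter with start <= end"
                )
            ranges.append((start, end))
        object.__setattr__(self, "category_ranges", tuple(ranges))


def match_code(code: str, code_set: CodeSet) -> bool:
    """True iff a normalized code belongs to the set under any of its rules."""
    if code in code_set.exact_codes:
        return True
    category = code[:3]
    if category in code_set.category_prefixes:
        return True
    return any(start <= category <= end for start, end in code_set.category_ranges)


def extract_codes(diagnoses: pd.DataFrame, code_set: CodeSet) -> pd.DataFrame:
    """Subset diagnosis records whose code matches the set, order preserved."""
    mask = diagnoses["code"].map(lambda c: match_code(c, code_set))
    return diagnoses.loc[mask].reset_index(drop=True)


@dataclass
class Prevalence:
    """Distinct carriers of a code set in a cleaned cohort."""

    code_set: str
    carriers: int
    n_patients: int
    proportion: float = field(init=False)

    def __post_init__(self):
        self.proportion = self.carriers / self.n_patients

    @property
    def percent(self) -> float:
        """Percent rounded to one decimal, the reporting convention."""
        return round(100.0 * self.proportion, 1)


def prevalence(clean_patients: pd.DataFrame, diagnoses: pd.DataFrame,
               code_set: CodeSet) -> Prevalence:
    """Fraction of cohort patients carrying >= 1 matching code.

    A patient counts once no matter how many matching records they have;
    diagnosis rows whose patient is outside the cleaned cohort are ignored.
    """
    if len(clean_patients) == 0:
        raise ValueError("prevalence undefined on an empty patient table")
    matched = extract_codes(diagnoses, code_set)
    cohort_ids = set(clean_patients["patient_id"])
    carriers = {p for p in matched["patient_id"] if p in cohort_ids}
    return Prevalence(code_set.name, len(carriers), len(clean_patients))


def _set_from_dict(name: str, spec: dict) -> CodeSet:
    ranges = tuple(
        tuple(r.replace("-", "–").split("–")) if isinstance(r, str) else tuple(r)
        for r in spec.get("category_ranges", [])
    )
    return CodeSet(
        name=name,
        exact_codes=frozenset(spec.get("exact_codes", [])),
        category_prefixes=frozenset(spec.get("category_prefixes", [])),
        category_ranges=ranges,
    )


def load_code_sets(path: str | None = None) -> dict[str, CodeSet]:
    """Load named code sets from YAML; defaults to the shipped definitions."""
    if path is None:
        text = resources.files("phenoval.data").joinpath("code_sets.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    return {name: _set_from_dict(name, spec) for name, spec in raw.items()}


def default_code_sets() -> dict[str, CodeSet]:
    return load_code_sets()
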