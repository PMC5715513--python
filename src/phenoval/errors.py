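"""Exception types raised across the package.

Every schema violation carries enough context (table, row number, offending
value) to locate the bad record in the source CSV.
"""

from __future__ import annotations


class PhenovalError(Exception):
    """Base class for all package errors."""


class SchemaError(PhenovalError):
    """A table violates its documented schema."""


class MissingColumnError(SchemaError):
    def __init__(self, table: str, columns: list[str]):
        self.table = table
        self.columns = columns
        super().__init__(f"{table}: missing required column(s) {columns}")


class DateParseError(SchemaError):
    def __init__(self, table: str, row: int, column: str, value: object):
        self.table, self.row, self.column, self.value = table, row, column, value
        super().__init__(
            f"{table} row {row}: cannot parse {column}={value!r} as an ISO-8601 date"
        )


class EnumValueError(SchemaError):
    def __init__(self, table: str, row: int, column: str, value: object, allowed: tuple):
        self.table, self.row, self.column, self.value = table, row, column, value
        super().__init__(
            f"{table} row {row}: {column}={value!r} not one of {sorted(allowed)}"
        )


class ReferentialIntegrityError(SchemaError):
    def __init__(self, table: str, orphan_ids: list[str]):
        self.table = table
        self.orphan_ids = orphan_ids
        shown = orphan_ids[:5]
        super().__init__(
            f"{table}: {len(orphan_ids)} patient_id value(s) absent from the "
            f"patient table, e.g. {shown}"
        )


class CodePatternError(PhenovalError):
    """An ICD-10 code does not match the letter + digits pattern."""

    def __init__(self, raw: object):
        self.raw = raw
        super().__init__(f"not a valid ICD-10 code: {raw!r}")


class UnknownArmError(PhenovalError):
    def __init__(self, name: str, known: list[str]):
        super().__init__(f"unknown arm {name!r}; shipped arms: {known}")


class EmptyArmError(PhenovalError):
    def __init__(self, arm: str):
        super().__init__(f"arm {arm!r} contains no records; nothing to sample")


class MissingLabelError(PhenovalError):
    def __init__(self, record_ids: list[str]):
        self.record_ids = record_ids
        shown = record_ids[:10]
        super().__init__(
            f"{len(record_ids)} sampled record(s) have no review label: {shown}"
        )


class OverlappingStrataError(PhenovalError):
    def __init__(self, strata: list[str]):
        super().__init__(f"strata must be disjoint; got repeated labels in {strata}")


class InfeasibleFixtureError(PhenovalError):
    """Requested exact counts cannot be realized (e.g. broken nesting)."""


class ConfigError(PhenovalError):
    """A generator configuration field is invalid."""
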