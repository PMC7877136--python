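"""Data model and file I/O for the two instruments.

The package works with two paired record types:

* :class:`AssessmentRecord` — one home-care assessment, a mapping from
  interRAI-style item identifiers (``"J6a"``, ``"M2"``, ...) to coded
  values, validated against a :class:`CodingDictionary`;
* :class:`ComidChecklist` — the 30-item binary reference checklist of
  multidimensional care complexity (6 domains x 5 items).

Both read from / write to RFC-4180 CSV (header row of item ids) and JSON
(array of flat objects).  Empty cells and configurable missing tokens map
to the :data:`MISSING` sentinel; an item's declared "uncertain" code maps
to :data:`UNCERTAIN`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import pandas as pd
import yaml

from ._sentinels import MISSING, UNCERTAIN, Sentinel
from .errors import CodeValidationError, InstrumentFormatError, SchemaError

Code = Union[int, Sentinel]

#: Default tokens read as MISSING in files (besides genuinely empty cells).
DEFAULT_MISSING_TOKENS = ("", "NA")

#: The 30 checklist item ids: 6 complexity domains x 5 items each.
COMID_DOMAINS = ("1", "2", "3", "4", "5", "6")
COMID_ITEMS = tuple(f"{d}{s}" for d in COMID_DOMAINS for s in "abcde")

#: The four items tied to the care-provider / care-system dimension that
#: have no assessment-derived counterpart; the 26-item restriction of the
#: checklist excludes them.
COMID26_EXCLUDED = frozenset({"6b", "6c", "6d", "6e"})
COMID26_ITEMS = tuple(i for i in COMID_ITEMS if i not in COMID26_EXCLUDED)

#: Medication-slot items counted when no precomputed medication_count is given.
MEDICATION_SLOT_ITEMS = tuple(f"M{i}f" for i in range(1, 10))


@dataclass(frozen=True)
class ItemValue:
    """A single coded observation: a numeric code, MISSING or UNCERTAIN."""

    item_id: str
    code: Code

    def is_missing(self) -> bool:
        return self.code is MISSING

    def is_uncertain(self) -> bool:
        return self.code is UNCERTAIN


@dataclass(frozen=True)
class ItemSpec:
    """Coding declaration for one item."""

    item_id: str
    section: str
    label: str
    max_code: int
    positive: object = "nonzero"  # "nonzero" | "zero" | {"min": k}
    uncertain_code: int | None = None
    freetext: bool = False
    measurement: bool = False

    def legal(self, code: int) -> bool:
        if self.uncertain_code is not None and code == self.uncertain_code:
            return True
        return 0 <= code <= self.max_code

    def is_positive(self, code: int) -> bool:
        """Does this numeric code count as 'problem present'?"""
        if self.positive == "nonzero":
            return code > 0
        if self.positive == "zero":
            return code == 0
        if isinstance(self.positive, Mapping) and "min" in self.positive:
            return code >= int(self.positive["min"])
        raise ValueError(f"bad positivity spec for {self.item_id}: {self.positive!r}")

    def positive_code(self) -> int:
        """Canonical code realizing positivity (used by witness construction)."""
        if self.positive == "nonzero":
            return 1
        if self.positive == "zero":
            return 0
        return int(self.positive["min"])

    def negative_code(self) -> int:
        """Canonical code realizing non-positivity."""
        return 1 if self.positive == "zero" else 0


class CodingDictionary:
    """Per-item coding declarations plus the 19 MDS section letters A-S.

    Loadable from the shipped YAML config (:meth:`default`) or any
    compatible file, so thresholds and code ranges stay auditable and
    adjustable without code changes.
    """

    def __init__(self, sections: Mapping[str, str], items: Mapping[str, ItemSpec]):
        self.sections = dict(sections)
        self.items = dict(items)
        for spec in self.items.values():
            if spec.section not in self.sections:
                raise SchemaError(
                    f"item {spec.item_id} declares unknown section {spec.section!r}"
                )

    # -- construction ------------------------------------------------------
    @classmethod
    def from_mapping(cls, raw: Mapping) -> "CodingDictionary":
        items = {}
        for item_id, decl in raw["items"].items():
            positive = decl.get("positive", "nonzero")
            items[item_id] = ItemSpec(
                item_id=item_id,
                section=decl["section"],
                label=decl["label"],
                max_code=int(decl["max"]),
                positive=positive,
                uncertain_code=decl.get("uncertain"),
                freetext=bool(decl.get("freetext", False)),
                measurement=bool(decl.get("measurement", False)),
            )
        return cls(raw["sections"], items)

    @classmethod
    def from_file(cls, path: str | Path) -> "CodingDictionary":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_mapping(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "CodingDictionary":
        return _default_dictionary()

    # -- queries -----------------------------------------------------------
    def __contains__(self, item_id: str) -> bool:
        return item_id in self.items

    def spec(self, item_id: str) -> ItemSpec:
        try:
            return self.items[item_id]
        except KeyError:
            raise SchemaError(f"unknown item id {item_id!r}") from None

    def is_positive(self, item_id: str, code: Code) -> Union[bool, Sentinel]:
        """Positivity of a coded value; sentinels pass through."""
        if isinstance(code, Sentinel):
            return code
        return self.spec(item_id).is_positive(code)

    def parse_cell(self, item_id: str, raw, subject_id: str,
                   missing_tokens: Sequence[str] = DEFAULT_MISSING_TOKENS) -> Code:
        """Convert one file cell into a code or sentinel, validating range."""
        spec = self.spec(item_id)
        if raw is None:
            return MISSING
        if isinstance(raw, float) and pd.isna(raw):
            return MISSING
        if isinstance(raw, str):
            token = raw.strip()
            if token in missing_tokens:
                return MISSING
            try:
                code = int(token)
            except ValueError:
                if spec.freetext:
                    return 1  # any response counts as "populated"
                raise CodeValidationError(
                    f"subject {subject_id!r}, item {item_id}: "
                    f"non-numeric value {raw!r}"
                ) from None
        else:
            code = int(raw)
        if spec.uncertain_code is not None and code == spec.uncertain_code:
            return UNCERTAIN
        if spec.freetext and code not in (0, 1):
            code = 1
        if not spec.legal(code):
            raise CodeValidationError(
                f"subject {subject_id!r}, item {item_id}: code {code} outside "
                f"the legal range 0..{spec.max_code}"
            )
        return code


@lru_cache(maxsize=1)
def _default_dictionary() -> CodingDictionary:
    ref = resources.files("interrai_ci.data") / "coding_dictionary.yaml"
    return CodingDictionary.from_mapping(yaml.safe_load(ref.read_text(encoding="utf-8")))


@dataclass
class AssessmentRecord:
    """One assessment: subject id, item codes and the medication count.

    ``medication_count`` is the number of regularly-taken substances.  It
    may be supplied precomputed or, when absent, is counted from populated
    medication-slot items (``M1f`` ... ``M9f``) at read time.
    """

    subject_id: str
    items: dict[str, Code] = field(default_factory=dict)
    medication_count: Code = MISSING

    def get(self, item_id: str) -> Code:
        """Code for an item; an unrecorded item is MISSING."""
        return self.items.get(item_id, MISSING)

    def with_items(self, updates: Mapping[str, Code]) -> "AssessmentRecord":
        merged = dict(self.items)
        merged.update(updates)
        return AssessmentRecord(self.subject_id, merged, self.medication_count)


@dataclass
class ComidChecklist:
    """The 30 binary answers of the reference complexity checklist."""

    subject_id: str
    answers: dict[str, Code] = field(default_factory=dict)

    def __post_init__(self) -> None:
        extra = set(self.answers) - set(COMID_ITEMS)
        if extra:
            raise SchemaError(f"unknown checklist item ids: {sorted(extra)}")
        for item in COMID_ITEMS:
            self.answers.setdefault(item, MISSING)
        for item, value in self.answers.items():
            if value is not MISSING and value not in (0, 1):
                raise CodeValidationError(
                    f"subject {self.subject_id!r}, checklist item {item}: "
                    f"value {value!r} is not binary"
                )


def comid_total(checklist: ComidChecklist, variant: str = "comid30") -> Code:
    """Total checklist score: sum of "yes" answers over the variant's items.

    ``comid30`` sums all 30 items (range 0-30); ``comid26`` restricts to
    the 26 items with assessment-derived counterparts (range 0-26).
    Returns MISSING if any item in the variant's set is MISSING
    (list-wise handling at score level).
    """
    if variant == "comid30":
        item_set: Iterable[str] = COMID_ITEMS
    elif variant == "comid26":
        item_set = COMID26_ITEMS
    else:
        raise ValueError(f"unknown variant {variant!r}")
    total = 0
    for item in item_set:
        value = checklist.answers.get(item, MISSING)
        if value is MISSING:
            return MISSING
        total += value
    return total


# ---------------------------------------------------------------------------
# File readers / writers
# ---------------------------------------------------------------------------

_RESERVED_ASSESSMENT_COLUMNS = ("subject_id", "medication_count")


def _load_rows(path: str | Path, fmt: str) -> list[dict]:
    path = Path(path)
    if fmt == "csv":
        try:
            frame = pd.read_csv(path, dtype=str, keep_default_na=False)
        except Exception as exc:  # pragma: no cover - pandas error text varies
            raise InstrumentFormatError(f"cannot parse {path} as CSV: {exc}") from exc
        return frame.to_dict(orient="records")
    if fmt == "json":
        try:
            with open(path, "r", encoding="utf-8") as fh:
                data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise InstrumentFormatError(f"cannot parse {path} as JSON: {exc}") from exc
        if not isinstance(data, list):
            raise InstrumentFormatError(f"{path}: expected a JSON array of objects")
        return data
    raise ValueError(f"unknown format {fmt!r} (expected 'csv' or 'json')")


def read_assessments(path: str | Path, fmt: str = "csv",
                     dictionary: CodingDictionary | None = None,
                     missing_tokens: Sequence[str] = DEFAULT_MISSING_TOKENS,
                     ) -> list[AssessmentRecord]:
    """Read assessment records from CSV or JSON.

    Columns/keys must be item ids from the coding dictionary or the
    reserved names ``subject_id`` and ``medication_count``.  Unknown
    columns raise :class:`SchemaError` naming the column; out-of-range
    codes raise :class:`CodeValidationError` naming subject and item.
    """
    dictionary = dictionary or CodingDictionary.default()
    rows = _load_rows(path, fmt)
    records = []
    for i, row in enumerate(rows):
        unknown = [k for k in row
                   if k not in _RESERVED_ASSESSMENT_COLUMNS and k not in dictionary]
        if unknown:
            raise SchemaError(f"unknown item column(s): {', '.join(sorted(unknown))}")
        subject_id = str(row.get("subject_id", f"row{i}"))
        items: dict[str, Code] = {}
        for item_id, raw in row.items():
            if item_id in _RESERVED_ASSESSMENT_COLUMNS:
                continue
            items[item_id] = dictionary.parse_cell(item_id, raw, subject_id,
                                                   missing_tokens)
        med = _parse_medication_count(row, items, subject_id, missing_tokens)
        records.append(AssessmentRecord(subject_id, items, med))
    return records


def _parse_medication_count(row, items, subject_id, missing_tokens) -> Code:
    # a present medication_count column is authoritative (empty -> MISSING);
    # counting populated medication slots is the fallback when absent
    if "medication_count" in row:
        raw = row["medication_count"]
        token = raw.strip() if isinstance(raw, str) else raw
        if token is None or token in missing_tokens or (
                isinstance(token, float) and pd.isna(token)):
            return MISSING
        try:
            count = int(token)
        except (TypeError, ValueError):
            raise CodeValidationError(
                f"subject {subject_id!r}: medication_count {raw!r} is not an integer"
            ) from None
        if count < 0:
            raise CodeValidationError(
                f"subject {subject_id!r}: medication_count must be >= 0")
        return count
    slots = [items[s] for s in MEDICATION_SLOT_ITEMS if s in items]
    if not slots:
        return MISSING
    if any(v is MISSING for v in slots):
        # a populated slot is still countable; unpopulated slots read as 0
        known = sum(1 for v in slots if v not in (MISSING, UNCERTAIN) and v > 0)
        return known if known >= 5 else MISSING
    return sum(1 for v in slots if not isinstance(v, Sentinel) and v > 0)


def write_assessments(records: Sequence[AssessmentRecord], path: str | Path,
                      fmt: str = "csv",
                      dictionary: CodingDictionary | None = None) -> None:
    """Write records so that a read round-trip preserves codes and sentinels."""
    dictionary = dictionary or CodingDictionary.default()
    item_ids = sorted({i for r in records for i in r.items})

    def cell(record: AssessmentRecord, item_id: str):
        code = record.items.get(item_id, MISSING)
        if code is MISSING:
            return None
        if code is UNCERTAIN:
            return dictionary.spec(item_id).uncertain_code
        return code

    rows = []
    for r in records:
        row: dict = {"subject_id": r.subject_id}
        for item_id in item_ids:
            row[item_id] = cell(r, item_id)
        row["medication_count"] = None if r.medication_count is MISSING else r.medication_count
        rows.append(row)
    _dump_rows(rows, path, fmt)


def read_comid(path: str | Path, fmt: str = "csv",
               missing_tokens: Sequence[str] = DEFAULT_MISSING_TOKENS,
               ) -> list[ComidChecklist]:
    """Read 30-item checklists; values must be 0, 1 or a missing token."""
    rows = _load_rows(path, fmt)
    checklists = []
    for i, row in enumerate(rows):
        keys = {k for k in row if k != "subject_id"}
        absent = [c for c in COMID_ITEMS if c not in keys]
        if absent:
            raise SchemaError(f"checklist column(s) absent: {', '.join(absent)}")
        unknown = keys - set(COMID_ITEMS)
        if unknown:
            raise SchemaError(f"unknown checklist column(s): {', '.join(sorted(unknown))}")
        subject_id = str(row.get("subject_id", f"row{i}"))
        answers: dict[str, Code] = {}
        for item in COMID_ITEMS:
            raw = row[item]
            token = raw.strip() if isinstance(raw, str) else raw
            if token is None or token in missing_tokens or (
                    isinstance(token, float) and pd.isna(token)):
                answers[item] = MISSING
                continue
            try:
                value = int(token)
            except (TypeError, ValueError):
                value = -1
            if value not in (0, 1):
                raise CodeValidationError(
                    f"subject {subject_id!r}, checklist item {item}: "
                    f"value {raw!r} is not binary")
            answers[item] = value
        checklists.append(ComidChecklist(subject_id, answers))
    return checklists


def write_comid(checklists: Sequence[ComidChecklist], path: str | Path,
                fmt: str = "csv") -> None:
    rows = []
    for c in checklists:
        row: dict = {"subject_id": c.subject_id}
        for item in COMID_ITEMS:
            v = c.answers.get(item, MISSING)
            row[item] = None if v is MISSING else v
        rows.append(row)
    _dump_rows(rows, path, fmt)


def _dump_rows(rows: list[dict], path: str | Path, fmt: str) -> None:
    path = Path(path)
    if fmt == "csv":
        frame = pd.DataFrame(rows)
        # pandas would render None as "" already, but ints in columns with
        # None become floats; coerce to nullable Int64 where possible
        for col in frame.columns:
            if col == "subject_id":
                continue
            frame[col] = pd.array(frame[col], dtype="Int64")
        frame.to_csv(path, index=False)
    elif fmt == "json":
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(rows, fh, indent=1)
    else:
        raise ValueError(f"unknown format {fmt!r}")
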