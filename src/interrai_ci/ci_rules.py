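"""The 26-rule Complexity Index derivation engine.

Each of the 26 binary index variables mirrors one reference-checklist item
(ids ``1a`` ... ``6a``) and is computed from a disjoint set of assessment
items by a declarative predicate.  Predicates are evaluated in Kleene
three-valued logic over item *positivity* (declared per item in the coding
dictionary), so a variable is ``1`` when the predicate demonstrably holds,
``0`` when it demonstrably fails, and ``MISSING`` when some value needed
to decide is absent.

The total score is the unweighted sum of the 26 binaries (range 0-26).
Four checklist items tied to the care-provider / care-system dimension
have no assessment counterpart and are never derived; see
:func:`non_derivable_items`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence, Union

import yaml

from ._sentinels import MISSING, UNCERTAIN, Sentinel
from .errors import CodeValidationError, SchemaError, UnknownRuleError
from .instruments import (AssessmentRecord, CodingDictionary,
                          COMID26_EXCLUDED, COMID_ITEMS)

TriBool = Union[int, Sentinel]  # 0, 1 or MISSING

#: The 13 disease sources of rule 1a, besides the BMI-derived condition
#: and the "other diagnoses" bonus.
CONDITION_ITEMS = ("I1c", "I1d", "I1f", "I1h", "I1j", "I1k", "I1l", "I1m",
                   "I1t", "I1u", "J3u", "J4")

#: Default BMI band counted as one chronic condition (under/over-nutrition).
BMI_LOW = 18.5
BMI_HIGH = 30.0


def non_derivable_items() -> frozenset[str]:
    """Checklist items with no assessment-derived counterpart: {6b,6c,6d,6e}."""
    return COMID26_EXCLUDED


@dataclass(frozen=True)
class CiRuleSpec:
    """One derivation rule: id, item set, predicate, uncertainty handling."""

    rule_id: str
    comid_label: str
    description: str
    required_items: frozenset[str]
    predicate: Mapping
    uncertainty_positive: bool = False


@dataclass
class CiResult:
    """The 26 derived binaries and the total score for one subject."""

    subject_id: str
    variables: dict[str, TriBool]
    total: TriBool
    n_missing: int = 0
    policy: str = "strict"


@dataclass(frozen=True)
class DerivedQuantities:
    """Quantities computed from raw items before thresholding."""

    bmi: Union[float, Sentinel]
    condition_count: TriBool
    medication_count: TriBool
    provider_count: TriBool


class RuleCatalogue:
    """The shipped rule set plus the numeric thresholds that parametrise it.

    The catalogue is loaded from a human-readable YAML config mirroring the
    published correspondence table row for row, and is validated on load:
    exactly 26 rules, ids + the non-derivable items = the 30 checklist ids,
    and no assessment item referenced by two rules.
    """

    def __init__(self, rules: Sequence[CiRuleSpec],
                 dictionary: CodingDictionary | None = None,
                 bmi_low: float = BMI_LOW, bmi_high: float = BMI_HIGH):
        self.rules = {r.rule_id: r for r in rules}
        self.dictionary = dictionary or CodingDictionary.default()
        self.bmi_low = bmi_low
        self.bmi_high = bmi_high
        self._validate()

    def _validate(self) -> None:
        ids = set(self.rules)
        if len(self.rules) != 26:
            raise SchemaError(f"catalogue must have exactly 26 rules, got {len(self.rules)}")
        if ids | non_derivable_items() != set(COMID_ITEMS):
            raise SchemaError("rule ids plus the 4 non-derivable items must "
                              "cover the 30 checklist ids exactly")
        seen: dict[str, str] = {}
        for rule in self.rules.values():
            for item in rule.required_items:
                if item in seen:
                    raise SchemaError(
                        f"item {item} referenced by rules {seen[item]} and {rule.rule_id}; "
                        "each assessment item may be used only once")
                seen[item] = rule.rule_id
            for item in rule.required_items:
                self.dictionary.spec(item)  # raises SchemaError if undeclared

    @classmethod
    def from_file(cls, path: str | Path, **kwargs) -> "RuleCatalogue":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_mapping(yaml.safe_load(fh), **kwargs)

    @classmethod
    def from_mapping(cls, raw: Mapping, **kwargs) -> "RuleCatalogue":
        rules = [
            CiRuleSpec(
                rule_id=str(entry["rule_id"]),
                comid_label=entry.get("comid_label", ""),
                description=entry.get("description", ""),
                required_items=frozenset(entry["items"]),
                predicate=entry["predicate"],
                uncertainty_positive=bool(entry.get("uncertainty_positive", False)),
            )
            for entry in raw["rules"]
        ]
        return cls(rules, **kwargs)

    @classmethod
    def default(cls) -> "RuleCatalogue":
        return _default_catalogue()

    # ------------------------------------------------------------------
    def rule(self, rule_id: str) -> CiRuleSpec:
        try:
            return self.rules[rule_id]
        except KeyError:
            raise UnknownRuleError(rule_id) from None

    def rule_ids(self) -> tuple[str, ...]:
        return tuple(sorted(self.rules))

    # -- derived quantities --------------------------------------------
    def bmi(self, record: AssessmentRecord) -> Union[float, Sentinel]:
        height = record.get("K1a")
        weight = record.get("K1b")
        if height is MISSING or weight is MISSING:
            return MISSING
        if height <= 0 or weight <= 0:
            raise CodeValidationError(
                f"subject {record.subject_id!r}: nonpositive height/weight")
        return float(weight) / (float(height) / 100.0) ** 2

    def _bmi_condition(self, record: AssessmentRecord) -> TriBool:
        bmi = self.bmi(record)
        if bmi is MISSING:
            return MISSING
        return int(bmi < self.bmi_low or bmi >= self.bmi_high)

    def count_chronic_conditions(self, record: AssessmentRecord) -> TriBool:
        """Number of chronic conditions for rule 1a.

        Counts positives among the 13 disease sources (12 checklist slots
        + falls item + the BMI band) plus one for any response in the
        "other diagnoses" field.  An empty "other diagnoses" field counts
        as zero, not MISSING: no response means nothing to count.  With
        MISSING sources the count is returned once the known positives
        already decide the "more than 2" threshold, otherwise MISSING.
        """
        sources: list[TriBool] = []
        for item in CONDITION_ITEMS:
            pos = self.dictionary.is_positive(item, record.get(item))
            sources.append(MISSING if isinstance(pos, Sentinel) else int(pos))
        sources.append(self._bmi_condition(record))
        i2 = record.get("I2")
        i2_pos = 0 if i2 is MISSING else int(bool(self.dictionary.is_positive("I2", i2) is True))
        known = sum(v for v in sources if not isinstance(v, Sentinel)) + i2_pos
        any_missing = any(isinstance(v, Sentinel) for v in sources)
        if not any_missing or known > 2:
            return known
        return MISSING

    def provider_count(self, record: AssessmentRecord) -> TriBool:
        """Known count of positive provider sources (rule 6a); MISSING only
        when the unknowns could change the >=3 decision."""
        spec = self.rule("6a").predicate["count_ge"]
        positives = missing = 0
        for item in spec["items"]:
            pos = self.dictionary.is_positive(item, record.get(item))
            if isinstance(pos, Sentinel):
                missing += 1
            elif pos:
                positives += 1
        if missing == 0 or positives >= int(spec["n"]):
            return positives
        return MISSING

    def derived_quantities(self, record: AssessmentRecord) -> DerivedQuantities:
        return DerivedQuantities(
            bmi=self.bmi(record),
            condition_count=self.count_chronic_conditions(record),
            medication_count=record.medication_count,
            provider_count=self.provider_count(record),
        )

    # -- predicate evaluation ------------------------------------------
    def evaluate_rule(self, rule: Union[str, CiRuleSpec],
                      record: AssessmentRecord) -> TriBool:
        """Evaluate one rule to 1, 0 or MISSING (three-valued logic)."""
        if isinstance(rule, str):
            rule = self.rule(rule)
        return self._eval(rule.predicate, record, rule.uncertainty_positive)

    def _eval(self, node: Mapping, record: AssessmentRecord,
              uncertainty_positive: bool) -> TriBool:
        if "item" in node:
            code = record.get(node["item"])
            if code is UNCERTAIN:
                return 1 if uncertainty_positive else MISSING
            pos = self.dictionary.is_positive(node["item"], code)
            return MISSING if isinstance(pos, Sentinel) else int(pos)
        if "any" in node:
            branches = [self._eval(b, record, uncertainty_positive) for b in node["any"]]
            if any(b == 1 for b in branches if not isinstance(b, Sentinel)):
                return 1
            if all(not isinstance(b, Sentinel) for b in branches):
                return 0
            return MISSING
        if "all" in node:
            branches = [self._eval(b, record, uncertainty_positive) for b in node["all"]]
            if any(b == 0 for b in branches if not isinstance(b, Sentinel)):
                return 0
            if all(not isinstance(b, Sentinel) for b in branches):
                return 1
            return MISSING
        if "count_ge" in node:
            spec = node["count_ge"]
            n = int(spec["n"])
            positives = missing = 0
            for item in spec["items"]:
                code = record.get(item)
                if code is UNCERTAIN:
                    if uncertainty_positive:
                        positives += 1
                    else:
                        missing += 1
                    continue
                pos = self.dictionary.is_positive(item, code)
                if isinstance(pos, Sentinel):
                    missing += 1
                elif pos:
                    positives += 1
            if positives >= n:
                return 1
            if positives + missing < n:
                return 0
            return MISSING
        if "quantity" in node:
            spec = node["quantity"]
            value = self._quantity(spec["name"], record)
            if isinstance(value, Sentinel):
                return MISSING
            if "ge" in spec:
                return int(value >= spec["ge"])
            if "gt" in spec:
                return int(value > spec["gt"])
            raise SchemaError(f"quantity node needs ge/gt: {spec!r}")
        raise SchemaError(f"unknown predicate node: {node!r}")

    def _quantity(self, name: str, record: AssessmentRecord):
        if name == "condition_count":
            return self.count_chronic_conditions(record)
        if name == "medication_count":
            return record.medication_count
        if name == "provider_count":
            return self.provider_count(record)
        raise SchemaError(f"unknown derived quantity {name!r}")

    # -- scoring --------------------------------------------------------
    def derive_ci(self, record: AssessmentRecord,
                  policy: str = "strict") -> CiResult:
        """Evaluate all 26 rules and total them.

        ``strict`` (default, matching list-wise deletion downstream): the
        total is MISSING whenever any variable is MISSING.  ``per_rule``:
        the total sums the decided variables and ``n_missing`` reports how
        many were undecidable.
        """
        if policy not in ("strict", "per_rule"):
            raise ValueError(f"unknown policy {policy!r}")
        variables = {rid: self.evaluate_rule(rid, record)
                     for rid in self.rule_ids()}
        n_missing = sum(1 for v in variables.values() if isinstance(v, Sentinel))
        if n_missing and policy == "strict":
            total: TriBool = MISSING
        else:
            total = sum(v for v in variables.values() if not isinstance(v, Sentinel))
        return CiResult(record.subject_id, variables, total, n_missing, policy)


@lru_cache(maxsize=1)
def _default_catalogue() -> RuleCatalogue:
    ref = resources.files("interrai_ci.data") / "ci_rules.yaml"
    return RuleCatalogue.from_mapping(yaml.safe_load(ref.read_text(encoding="utf-8")))


# Convenience module-level wrappers over the default catalogue -------------

def evaluate_rule(rule_id: str, record: AssessmentRecord) -> TriBool:
    return RuleCatalogue.default().evaluate_rule(rule_id, record)


def derive_ci(record: AssessmentRecord, policy: str = "strict") -> CiResult:
    return RuleCatalogue.default().derive_ci(record, policy)


def count_chronic_conditions(record: AssessmentRecord) -> TriBool:
    return RuleCatalogue.default().count_chronic_conditions(record)
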