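"""Synthetic paired assessment + checklist datasets.

No clinical dataset accompanies the index, so every statistic in the
package is exercised on synthetic records.  The generator draws, per
subject and per rule, a latent binary truth (the value the index variable
*should* take), realises that truth in raw assessment item codes through
deterministic witness settings, and produces the paired checklist answer
as a noisy copy of the truth (equal with a per-rule agreement
probability).  The four checklist items with no derived counterpart are
drawn independently.  Missingness is injected item-wise.

Defaults emulate the index's derivation-study conditions: 216 subjects,
per-variable prevalences equal to the published derived-yes fractions and
agreement probabilities read off the published 2x2 marginals; see
:mod:`interrai_ci.reference`.

Because no assessment item is shared between rules, positive witness item
settings for different rules merge without interference — the basis both
for :func:`witness_record` and for the generator's realisation step.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from ._sentinels import MISSING, Sentinel
from .ci_rules import RuleCatalogue, non_derivable_items
from .errors import UnknownRuleError
from .instruments import (AssessmentRecord, CodingDictionary, ComidChecklist,
                          COMID_ITEMS, write_assessments, write_comid)
from .reference import (reference_agreement, reference_comid_prevalence,
                        reference_prevalence)

#: Item settings (beyond the all-negative baseline) that make each rule fire.
#: Values name the *canonical positive code* of the coding dictionary unless
#: given as an explicit integer.
_POSITIVE_SETTINGS: dict[str, tuple[str, ...]] = {
    "1a": ("I1c", "I1d", "I1f"),      # three diseases > 2
    "1b": ("J6a",),
    "1c": ("M2",),
    "1d": (),                          # via medication_count = 5
    "1e": ("C2a", "C1"),
    "2a": ("Q4",),
    "2b": ("P2a",),
    "2c": ("D2",),
    "2d": ("A13a", "F3"),
    "2e": ("Q1a",),
    "3a": ("I1p",),
    "3b": ("J3g",),
    "3c": ("J9a",),
    "3d": ("I1n",),
    "3e": ("C3c",),
    "4a": ("E1e",),
    "4b": ("F1d", "E1b"),
    "4c": ("E1d",),
    "4d": ("E3b",),
    "4e": ("E3f",),
    "5a": ("J7b",),
    "5b": ("G6",),
    "5c": ("F5",),
    "5d": ("C5",),
    "5e": ("J7a",),
    "6a": ("N3aA", "N3bA", "N3cA"),   # three providers
}

#: Healthy-adult anthropometrics for the baseline record (BMI 22.5,
#: inside the unproblematic band).
_BASE_HEIGHT_CM = 170
_BASE_WEIGHT_KG = 65

_MEDS_IF_POLYPHARMACY = 5   # at the "five or more" threshold
_MEDS_OTHERWISE = 2


def base_negative_record(subject_id: str = "base",
                         dictionary: CodingDictionary | None = None,
                         ) -> AssessmentRecord:
    """A fully observed record on which every rule evaluates to 0."""
    dictionary = dictionary or CodingDictionary.default()
    items: dict = {}
    for item_id, spec in dictionary.items.items():
        if spec.measurement:
            continue
        items[item_id] = spec.negative_code()
    items["K1a"] = _BASE_HEIGHT_CM
    items["K1b"] = _BASE_WEIGHT_KG
    return AssessmentRecord(subject_id, items, medication_count=_MEDS_OTHERWISE)


def witness_record(rule_id: str, polarity: int = 1,
                   subject_id: str | None = None,
                   catalogue: RuleCatalogue | None = None) -> AssessmentRecord:
    """Deterministic record on which ``rule_id`` evaluates to ``polarity``
    and every other rule evaluates to 0."""
    catalogue = catalogue or RuleCatalogue.default()
    if rule_id not in catalogue.rules:
        raise UnknownRuleError(rule_id)
    if polarity not in (0, 1):
        raise ValueError("polarity must be 0 or 1")
    subject_id = subject_id or f"witness_{rule_id}_{polarity}"
    record = base_negative_record(subject_id, catalogue.dictionary)
    if polarity == 1:
        record = _apply_positive(record, rule_id, catalogue.dictionary)
    return record


def merged_positive_witness(subject_id: str = "witness_all_positive",
                            catalogue: RuleCatalogue | None = None,
                            ) -> AssessmentRecord:
    """All 26 positive witnesses merged into one record (items are
    disjoint across rules, so the merge is well-defined); scores 26."""
    catalogue = catalogue or RuleCatalogue.default()
    record = base_negative_record(subject_id, catalogue.dictionary)
    for rule_id in catalogue.rule_ids():
        record = _apply_positive(record, rule_id, catalogue.dictionary)
    return record


def _apply_positive(record: AssessmentRecord, rule_id: str,
                    dictionary: CodingDictionary) -> AssessmentRecord:
    updates = {item: dictionary.spec(item).positive_code()
               for item in _POSITIVE_SETTINGS[rule_id]}
    record = record.with_items(updates)
    if rule_id == "1d":
        record.medication_count = _MEDS_IF_POLYPHARMACY
    return record


# ---------------------------------------------------------------------------
# Randomised paired datasets
# ---------------------------------------------------------------------------

def _default_prevalence() -> dict[str, float]:
    return {rid: reference_prevalence(rid)
            for rid in RuleCatalogue.default().rule_ids()}


def _default_agreement() -> dict[str, float]:
    return {rid: reference_agreement(rid)
            for rid in RuleCatalogue.default().rule_ids()}


def _default_comid_extra() -> dict[str, float]:
    return {item: reference_comid_prevalence(item)
            for item in sorted(non_derivable_items())}


@dataclass
class SyntheticConfig:
    """Parameters of the paired-dataset generator.

    Defaults are the derivation-study conditions (216 subjects, published
    per-variable prevalences and implied agreement probabilities, no
    missingness).  ``latent_correlation`` adds a shared one-factor
    dependence across the 26 latent truths (tetrachoric-style Gaussian
    factor), producing the positive inter-item correlation needed for a
    nonzero internal-consistency target; 0 keeps truths independent.
    """

    n_subjects: int = 216
    prevalence: dict[str, float] = field(default_factory=_default_prevalence)
    agreement: dict[str, float] = field(default_factory=_default_agreement)
    comid_extra_prevalence: dict[str, float] = field(default_factory=_default_comid_extra)
    missing_rate: float = 0.0
    latent_correlation: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if self.n_subjects < 1:
            problems.append("n_subjects must be >= 1")
        for name, mapping in (("prevalence", self.prevalence),
                              ("agreement", self.agreement),
                              ("comid_extra_prevalence", self.comid_extra_prevalence)):
            for key, p in mapping.items():
                if not 0.0 <= p <= 1.0:
                    problems.append(f"{name}[{key}] = {p} outside [0, 1]")
        if not 0.0 <= self.missing_rate <= 1.0:
            problems.append(f"missing_rate {self.missing_rate} outside [0, 1]")
        if not 0.0 <= self.latent_correlation < 1.0:
            problems.append(f"latent_correlation {self.latent_correlation} outside [0, 1)")
        if problems:
            raise ValueError("; ".join(problems))

    @classmethod
    def from_mapping(cls, raw: Mapping) -> "SyntheticConfig":
        cfg = cls()
        known = set(cfg.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        updates = dict(raw)
        for key in ("prevalence", "agreement", "comid_extra_prevalence"):
            if key in updates:
                merged = dict(getattr(cfg, key))
                value = updates[key]
                if isinstance(value, Mapping):
                    merged.update(value)
                else:  # scalar: apply uniformly
                    merged = {k: float(value) for k in merged}
                updates[key] = merged
        cfg = replace(cfg, **updates)
        cfg.validate()
        return cfg


def generate_paired_dataset(config: SyntheticConfig,
                            catalogue: RuleCatalogue | None = None,
                            ) -> tuple[list[AssessmentRecord],
                                       list[ComidChecklist],
                                       pd.DataFrame]:
    """Generate paired assessments and checklists plus the latent truth.

    Per subject and rule, truth ~ Bernoulli(prevalence) (optionally
    sharing a Gaussian severity factor), realised through the rule's
    witness item settings; the paired checklist answer equals the truth
    with the configured agreement probability.  The four non-derivable
    checklist items are drawn independently.  With ``missing_rate`` 0 the
    index scorer recovers the latent truth exactly.
    """
    config.validate()
    catalogue = catalogue or RuleCatalogue.default()
    rng = np.random.default_rng(config.seed)
    rule_ids = catalogue.rule_ids()
    extra_items = sorted(non_derivable_items())

    assessments: list[AssessmentRecord] = []
    checklists: list[ComidChecklist] = []
    truth_rows = []
    r = config.latent_correlation
    for i in range(config.n_subjects):
        subject_id = f"S{i + 1:05d}"
        if r > 0:
            z = rng.standard_normal()
            e = rng.standard_normal(len(rule_ids))
            latent = np.sqrt(r) * z + np.sqrt(1.0 - r) * e
            truth = {rid: int(latent[j] < norm.ppf(config.prevalence.get(rid, 0.0)))
                     for j, rid in enumerate(rule_ids)}
        else:
            draws = rng.random(len(rule_ids))
            truth = {rid: int(draws[j] < config.prevalence.get(rid, 0.0))
                     for j, rid in enumerate(rule_ids)}

        record = base_negative_record(subject_id, catalogue.dictionary)
        for rid in rule_ids:
            if truth[rid]:
                record = _apply_positive(record, rid, catalogue.dictionary)

        answers: dict = {}
        for rid in rule_ids:
            agree = rng.random() < config.agreement.get(rid, 1.0)
            answers[rid] = truth[rid] if agree else 1 - truth[rid]
        for item in extra_items:
            answers[item] = int(rng.random() < config.comid_extra_prevalence.get(item, 0.0))

        assessments.append(record)
        checklists.append(ComidChecklist(subject_id, answers))
        truth_rows.append({"subject_id": subject_id, **truth})

    if config.missing_rate > 0:
        assessments, checklists = inject_missing(
            assessments, checklists, config.missing_rate, rng=rng)

    truth = pd.DataFrame(truth_rows)
    return assessments, checklists, truth


def inject_missing(assessments: Sequence[AssessmentRecord],
                   checklists: Sequence[ComidChecklist],
                   rate: float, seed: int | None = None,
                   rng: np.random.Generator | None = None,
                   ) -> tuple[list[AssessmentRecord], list[ComidChecklist]]:
    """Replace each stored value independently by MISSING with probability
    ``rate``; reproducible under ``seed`` (or an explicit generator)."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    out_assessments = []
    for record in assessments:
        items = {item: (MISSING if rate > 0 and rng.random() < rate else code)
                 for item, code in record.items.items()}
        med = record.medication_count
        if not isinstance(med, Sentinel) and rate > 0 and rng.random() < rate:
            med = MISSING
        out_assessments.append(AssessmentRecord(record.subject_id, items, med))
    out_checklists = []
    for checklist in checklists:
        answers = {item: (MISSING if rate > 0 and rng.random() < rate else value)
                   for item, value in checklist.answers.items()}
        out_checklists.append(ComidChecklist(checklist.subject_id, answers))
    return out_assessments, out_checklists


def write_dataset(assessments: Sequence[AssessmentRecord],
                  checklists: Sequence[ComidChecklist],
                  truth: pd.DataFrame, out_dir: str | Path,
                  fmt: str = "csv") -> dict[str, Path]:
    """Write the three dataset files into ``out_dir``; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ext = "csv" if fmt == "csv" else "json"
    paths = {
        "assessments": out_dir / f"assessments.{ext}",
        "comid": out_dir / f"comid.{ext}",
        "truth": out_dir / "truth.csv",
    }
    write_assessments(assessments, paths["assessments"], fmt)
    write_comid(checklists, paths["comid"], fmt)
    truth.to_csv(paths["truth"], index=False)
    return paths
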