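# interrai-ci

Derivation and validation of a **Complexity Index (CI)** for home-care
nursing from interRAI-HC comprehensive geriatric assessments.

Home-care nurses routinely assess patients with the interRAI-HC minimum
data set, which covers 19 health domains (sections A–S) but offers no
indicator of how *complex* a care situation is. Multidimensional
complexity — the accumulation of medical, social, mental, behavioural,
instability and care-system factors — is operationalised in practice by
a dedicated 30-item binary nursing checklist (COMID, 6 domains × 5
items, total score 0–30). This package implements the published
correspondence between the two instruments: 26 of the 30 checklist items
can be mirrored by combinations of assessment items, giving a binary
variable per item and an unweighted total,

```
CI = Σᵢ xᵢ ,   xᵢ ∈ {0, 1},  i = 1a … 6a,   0 ≤ CI ≤ 26,
```

computable from a routine assessment with no extra data collection. The
four checklist items tied to the care-provider/care-system dimension
(6b–6e) have no assessment counterpart and are excluded; the reference
total restricted to the 26 mirrored items is called COMID-26.

The package provides:

* **instruments** — typed records for assessments and checklists, a
  shipped YAML coding dictionary (legal ranges, positivity direction,
  explicit "uncertain" codes), CSV/JSON readers and writers, and
  checklist scoring (COMID-30 / COMID-26);
* **ci_rules** — the 26 derivation rules as a declarative, auditable
  YAML catalogue (each assessment item used by at most one rule),
  evaluated in three-valued logic so missing data propagate honestly;
  derived quantities (BMI band, chronic-condition count, medication
  count, provider count) and the 0–26 total under a strict or per-rule
  missing policy;
* **psychometrics** — the validation battery: per-variable 2×2 tables
  and phi coefficients with chi-square p-values (φ = (ad−bc)/√((a+b)(c+d)(a+c)(b+d)),
  χ² = nφ²), Bonferroni-adjusted significance (0.05/26 = .0019),
  Cronbach's alpha, Spearman's rank correlation between the two totals,
  and list-wise / pairwise deletion;
* **synthetic_data** — a seeded generator of paired datasets with
  controllable per-variable prevalence, index↔checklist agreement,
  missingness and an optional shared severity factor, plus deterministic
  per-rule witness records;
* a thin CLI: `interrai-ci simulate | derive | validate`.

## Worked example

```python
from interrai_ci import derive_ci
from interrai_ci.synthetic_data import base_negative_record

case = base_negative_record("case-042").with_items(
    {"J6a": 2, "A13a": 1, "F1b": 0, "F1c": 0, "I1n": 1})
case.medication_count = 6
result = derive_ci(case)
print(result.total, [r for r, v in result.variables.items() if v == 1])
```

prints

```
4 ['1b', '1d', '2d', '3d']
```

— the case scores 4 of 26 complexity factors: chronic pain (1b, any
pain on J6a), polymedication (1d, ≥ 5 substances), social isolation
(2d, lives alone with no recent contact) and anxiety (3d, diagnosis).
Running `python examples/validate_against_checklist.py` generates 216
paired synthetic records with a shared severity factor and prints the
full validation table; with that seed the index total correlates with
the 26-item checklist total at Spearman ρ = 0.831, every calculable phi
clears the .0019 threshold, and the variable with prevalence 0 (4e)
is reported as not calculable — the degenerate zero-margin outcome the
battery must handle.

The other examples (`examples/derive_index.py`,
`examples/simulate_and_inspect.py`) show scoring extremes (0 and 26)
and exact recovery of the generator's latent truth from written files.

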