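"""Derive the Complexity Index for a few assessment records.

Builds three records in memory — an all-negative baseline, a maximally
complex merged witness, and a hand-written case — scores each with the
26-rule engine and prints the per-variable values and totals.
"""

from interrai_ci import RuleCatalogue, derive_ci
from interrai_ci.synthetic_data import base_negative_record, merged_positive_witness

catalogue = RuleCatalogue.default()

baseline = base_negative_record("uncomplicated")
maximal = merged_positive_witness("maximal")

# a realistic mid-complexity case: chronic pain, 6 medications, lives alone
# with no recent social contact, and an anxiety diagnosis
case = base_negative_record("case-042").with_items(
    {"J6a": 2, "A13a": 1, "F1b": 0, "F1c": 0, "I1n": 1})
case.medication_count = 6

for record in (baseline, case, maximal):
    result = derive_ci(record)
    positives = [rid for rid, v in result.variables.items() if v == 1]
    print(f"{record.subject_id:>14}: total {result.total:>2}/26  "
          f"positive variables: {', '.join(positives) or 'none'}")

print()
print("The total counts how many of the 26 binary complexity factors are")
print("present; 0 is an uncomplicated situation, 26 the theoretical maximum.")
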