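"""Reference statistics from the index's derivation study (N = 216).

The study that introduced the 26-variable index reported, for every
variable, the yes/no marginals of the derived value and of its checklist
counterpart together with the phi coefficient between them (two decimals;
one variable, 4e, had zero derived "yes" answers and its phi could not be
calculated).  Those published marginals are transcribed here and serve
two purposes:

* a consistency suite — for each variable, brute force over the one free
  cell of the 2x2 joint table that the marginals leave undetermined and
  check that at least one integer table reproduces the printed phi;
* realistic defaults for the synthetic-data generator — the per-variable
  prevalence is the published derived-yes fraction, and the index/checklist
  agreement probability is read off the feasible joint table whose phi is
  closest to the printed value.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from ._sentinels import Sentinel
from .psychometrics import TwoByTwoTable, phi_coefficient

#: Analysis sample size of the derivation study.
N_REFERENCE = 216


@dataclass(frozen=True)
class ReferenceRow:
    """Published marginals and phi for one variable (phi None if not calculated)."""

    comid_no: int
    comid_yes: int
    ci_no: int
    ci_yes: int
    phi: float | None


#: Per-variable published marginals: checklist no/yes, index no/yes, phi.
REFERENCE_MARGINALS: dict[str, ReferenceRow] = {
    "1a": ReferenceRow(110, 106, 140, 76, 0.52),
    "1b": ReferenceRow(73, 143, 61, 155, 0.84),
    "1c": ReferenceRow(162, 54, 159, 57, 0.89),
    "1d": ReferenceRow(131, 85, 126, 90, 0.82),
    "1e": ReferenceRow(197, 19, 168, 48, 0.38),
    "2a": ReferenceRow(204, 12, 193, 23, 0.64),
    "2b": ReferenceRow(195, 21, 167, 49, 0.38),
    "2c": ReferenceRow(208, 8, 197, 19, 0.29),
    "2d": ReferenceRow(191, 25, 186, 30, 0.32),
    "2e": ReferenceRow(193, 23, 195, 21, 0.44),
    "3a": ReferenceRow(198, 18, 167, 49, 0.48),
    "3b": ReferenceRow(212, 4, 208, 8, 0.34),
    "3c": ReferenceRow(202, 14, 197, 19, 0.52),
    "3d": ReferenceRow(200, 16, 155, 61, 0.37),
    "3e": ReferenceRow(209, 7, 210, 6, 0.45),
    "4a": ReferenceRow(206, 10, 190, 26, -0.01),
    "4b": ReferenceRow(214, 2, 211, 5, 0.31),
    "4c": ReferenceRow(193, 23, 174, 42, 0.29),
    "4d": ReferenceRow(214, 2, 212, 4, 0.35),
    "4e": ReferenceRow(214, 2, 216, 0, None),
    "5a": ReferenceRow(179, 37, 199, 17, 0.28),
    "5b": ReferenceRow(201, 15, 184, 32, 0.40),
    "5c": ReferenceRow(194, 22, 149, 67, 0.20),
    "5d": ReferenceRow(210, 6, 205, 11, 0.35),
    "5e": ReferenceRow(180, 36, 186, 30, 0.47),
    "6a": ReferenceRow(205, 11, 190, 26, 0.37),
}

#: Published yes-counts for the four checklist items with no derived
#: counterpart (care-provider / care-system dimension).
ORIGINAL_ITEM_MARGINALS: dict[str, tuple[int, int]] = {
    "6b": (214, 2),
    "6c": (216, 0),
    "6d": (214, 2),
    "6e": (209, 7),
}


def feasible_tables(row: ReferenceRow, n: int = N_REFERENCE) -> list[TwoByTwoTable]:
    """All integer 2x2 tables consistent with the published marginals.

    With both marginals fixed, a single cell (both-yes count ``a``) is
    free; it ranges over max(0, ci_yes + comid_yes - n) .. min(ci_yes,
    comid_yes).  Rows are the derived value, columns the checklist answer.
    """
    lo = max(0, row.ci_yes + row.comid_yes - n)
    hi = min(row.ci_yes, row.comid_yes)
    tables = []
    for a in range(lo, hi + 1):
        b = row.ci_yes - a
        c = row.comid_yes - a
        d = n - a - b - c
        tables.append(TwoByTwoTable(a, b, c, d))
    return tables


def tables_matching_phi(row: ReferenceRow, n: int = N_REFERENCE,
                        decimals: int = 2) -> list[TwoByTwoTable]:
    """Feasible tables whose phi rounds to the printed coefficient."""
    if row.phi is None:
        raise ValueError("row has no printed phi (not calculated)")
    matches = []
    for table in feasible_tables(row, n):
        phi = phi_coefficient(table).phi
        if not isinstance(phi, Sentinel) and round(phi, decimals) == row.phi:
            matches.append(table)
    return matches


@lru_cache(maxsize=None)
def reference_agreement(rule_id: str, n: int = N_REFERENCE) -> float:
    """Index/checklist agreement probability implied by the published row.

    Picks, among the feasible joint tables, the one whose phi is closest
    to the printed value (for 4e, the zero-derived-yes margin fixes the
    table completely) and returns its observed agreement (a + d) / n.
    """
    row = REFERENCE_MARGINALS[rule_id]
    if row.phi is None:
        best = feasible_tables(row, n)[0]
    else:
        def dist(table: TwoByTwoTable) -> float:
            phi = phi_coefficient(table).phi
            return abs(phi - row.phi) if not isinstance(phi, Sentinel) else float("inf")

        best = min(feasible_tables(row, n), key=dist)
    return (best.a + best.d) / n


def reference_prevalence(rule_id: str, n: int = N_REFERENCE) -> float:
    """Published prevalence of the derived variable (yes fraction)."""
    return REFERENCE_MARGINALS[rule_id].ci_yes / n


def reference_comid_prevalence(item_id: str, n: int = N_REFERENCE) -> float:
    """Published checklist yes-fraction for a non-derivable item."""
    no, yes = ORIGINAL_ITEM_MARGINALS[item_id]
    return yes / n
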