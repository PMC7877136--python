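"""Validation statistics for the derived index against its reference checklist.

For each of the 26 derived variables the battery crosses the binary index
value with the matching checklist answer in a 2x2 table and reports the
phi coefficient with its chi-square p-value, flagged against a
Bonferroni-adjusted threshold (family-wise alpha divided by the number of
variables, 0.05/26 = .0019 by default).  Internal consistency of the
index and of both checklist variants is summarised with Cronbach's alpha,
and the two total scores are compared with Spearman's rank correlation.

Missing data are handled by list-wise deletion by default (drop any
record with a hole on any analysis variable); pairwise deletion (use all
records complete for each individual analysis) is available for
sensitivity checks.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from ._sentinels import MISSING, NOT_CALCULABLE, Sentinel
from .ci_rules import RuleCatalogue
from .errors import EmptyAnalysisError
from .instruments import (AssessmentRecord, ComidChecklist, COMID26_ITEMS,
                          COMID_ITEMS)

Real = Union[float, Sentinel]


@dataclass(frozen=True)
class TwoByTwoTable:
    """Counts of a 2x2 cross-classification.

    ``a`` both positive, ``b`` row-positive only, ``c`` column-positive
    only, ``d`` both negative.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for cell in (self.a, self.b, self.c, self.d):
            if cell < 0 or int(cell) != cell:
                raise ValueError("cells must be non-negative integers")
        if self.n < 1:
            raise ValueError("table must contain at least one observation")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def marginals(self) -> tuple[int, int, int, int]:
        """(row-positive, row-negative, col-positive, col-negative) sums."""
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)

    def transpose(self) -> "TwoByTwoTable":
        return TwoByTwoTable(self.a, self.c, self.b, self.d)


@dataclass(frozen=True)
class PhiResult:
    """Phi coefficient, its p-value and the significance flag."""

    phi: Real
    p_value: Real
    significant_at: bool = False

    @property
    def calculable(self) -> bool:
        return not isinstance(self.phi, Sentinel)


def crosstab(x: Sequence[int], y: Sequence[int]) -> TwoByTwoTable:
    """Cross-tabulate two equal-length binary vectors."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d vectors")
    if not (np.isin(x, (0, 1)).all() and np.isin(y, (0, 1)).all()):
        raise ValueError("values must be binary 0/1")
    a = int(np.sum((x == 1) & (y == 1)))
    b = int(np.sum((x == 1) & (y == 0)))
    c = int(np.sum((x == 0) & (y == 1)))
    d = int(np.sum((x == 0) & (y == 0)))
    return TwoByTwoTable(a, b, c, d)


def phi_coefficient(table: TwoByTwoTable, threshold: float | None = None,
                    method: str = "chi2") -> PhiResult:
    """Phi = (ad - bc) / sqrt of the marginal product, with a p-value.

    The default p-value is the upper tail of the 1-df chi-square at
    ``n * phi**2`` (no continuity correction), the canonical companion of
    phi; ``chi2_corrected`` applies the Yates correction and ``fisher``
    uses the exact test.  A table with any zero marginal has no defined
    phi and yields NOT_CALCULABLE rather than an error — this is the
    degenerate "Not calculated" outcome a constant variable produces.
    """
    r1, r0, c1, c0 = table.marginals
    if 0 in (r1, r0, c1, c0):
        return PhiResult(NOT_CALCULABLE, NOT_CALCULABLE, False)
    phi = (table.a * table.d - table.b * table.c) / math.sqrt(
        float(r1) * r0 * c1 * c0)
    if method == "chi2":
        chi2 = table.n * phi * phi
        p = float(stats.chi2.sf(chi2, df=1))
    elif method == "chi2_corrected":
        obs = np.array([[table.a, table.b], [table.c, table.d]])
        _, p, _, _ = stats.chi2_contingency(obs, correction=True)
        p = float(p)
    elif method == "fisher":
        _, p = stats.fisher_exact([[table.a, table.b], [table.c, table.d]])
        p = float(p)
    else:
        raise ValueError(f"unknown p-value method {method!r}")
    significant = threshold is not None and p < threshold
    return PhiResult(phi, p, significant)


def bonferroni_threshold(alpha: float = 0.05, m: int = 26) -> float:
    """Per-test threshold alpha/m controlling the family-wise error rate."""
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    if m < 1:
        raise ValueError("m must be a positive integer")
    return alpha / m


def cronbach_alpha(items, ddof: int = 1) -> Real:
    """Cronbach's alpha: k/(k-1) * (1 - sum of item variances / score variance).

    ``items`` is an n-subjects x k-items matrix (array or DataFrame) of
    item scores; rows with any missing value (NaN) are dropped first
    (list-wise).  Variances use the sample convention (``ddof=1``) by
    default; pass ``ddof=0`` for the population convention — at a couple
    hundred subjects the two differ only in the third decimal.
    Returns NOT_CALCULABLE when the total-score variance is zero.
    """
    matrix = np.asarray(pd.DataFrame(items), dtype=float)
    matrix = matrix[~np.isnan(matrix).any(axis=1)]
    n, k = matrix.shape
    if k < 2:
        raise ValueError("need at least 2 item columns")
    if n < 2:
        raise ValueError("need at least 2 complete rows")
    item_var = matrix.var(axis=0, ddof=ddof).sum()
    total_var = matrix.sum(axis=1).var(ddof=ddof)
    if total_var == 0:
        return NOT_CALCULABLE
    return (k / (k - 1)) * (1.0 - item_var / total_var)


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> Real:
    """Spearman rank correlation: Pearson correlation of mid-ranks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need equal-length vectors of length >= 3")
    import warnings
    with warnings.catch_warnings():
        # a constant vector yields NaN; we report NOT_CALCULABLE instead
        warnings.simplefilter("ignore", stats.ConstantInputWarning)
        rho = stats.spearmanr(x, y).statistic
    if np.isnan(rho):
        return NOT_CALCULABLE
    return float(rho)


# ---------------------------------------------------------------------------
# Deletion policies
# ---------------------------------------------------------------------------

@dataclass
class ListwiseResult:
    """Rows complete on every analysis column, with the exclusion tally."""

    data: pd.DataFrame
    n_excluded: int
    excluded_fraction: float


class PairwiseSelector:
    """Per-analysis subsets: each analysis keeps rows complete on *its* columns."""

    def __init__(self, data: pd.DataFrame):
        self._data = data

    def subset(self, columns: Sequence[str]) -> pd.DataFrame:
        return self._data.dropna(subset=list(columns))


def apply_deletion(dataset: pd.DataFrame, columns: Sequence[str],
                   policy: str = "listwise"):
    """List-wise or pairwise missing-data handling over ``columns``.

    List-wise returns a :class:`ListwiseResult`; an empty retained set
    raises :class:`EmptyAnalysisError` so degeneracy is never silent.
    Pairwise returns a :class:`PairwiseSelector` over the full dataset.
    """
    missing_cols = [c for c in columns if c not in dataset.columns]
    if missing_cols:
        raise KeyError(f"columns absent from dataset: {missing_cols}")
    if policy == "listwise":
        kept = dataset.dropna(subset=list(columns))
        n_excluded = len(dataset) - len(kept)
        if kept.empty:
            raise EmptyAnalysisError(
                "list-wise deletion removed every record")
        return ListwiseResult(kept, n_excluded, n_excluded / len(dataset))
    if policy == "pairwise":
        return PairwiseSelector(dataset)
    raise ValueError(f"unknown deletion policy {policy!r}")


# ---------------------------------------------------------------------------
# Full validation report
# ---------------------------------------------------------------------------

@dataclass
class VariableResult:
    """One per-variable row of the report: marginals + phi test."""

    rule_id: str
    label: str
    comid_no: int
    comid_yes: int
    ci_no: int
    ci_yes: int
    phi: PhiResult
    n: int


@dataclass
class ValidationReport:
    variables: list[VariableResult]
    cronbach_alpha_ci: Real
    cronbach_alpha_comid26: Real
    cronbach_alpha_comid30: Real
    spearman_rho: Real
    n_analyzed: int
    n_excluded: int
    deletion_policy: str
    threshold: float
    unpaired_subjects: list[str] = field(default_factory=list)
    descriptives: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Per-variable block shaped like the published comparison table."""
        rows = []
        for v in self.variables:
            calc = v.phi.calculable
            rows.append({
                "variable": v.rule_id,
                "label": v.label,
                "comid_no": v.comid_no,
                "comid_yes": v.comid_yes,
                "ci_no": v.ci_no,
                "ci_yes": v.ci_yes,
                "phi": round(v.phi.phi, 2) if calc else None,
                "p_value": v.phi.p_value if calc else None,
                "significant": v.phi.significant_at if calc else None,
                "n": v.n,
            })
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        def scalar(v):
            if isinstance(v, Sentinel):
                return None
            if isinstance(v, float) and math.isnan(v):
                return None
            return v

        records = [{k: scalar(v) for k, v in row.items()}
                   for row in self.to_frame().to_dict(orient="records")]
        return {
            "variables": records,
            "cronbach_alpha_ci": scalar(self.cronbach_alpha_ci),
            "cronbach_alpha_comid26": scalar(self.cronbach_alpha_comid26),
            "cronbach_alpha_comid30": scalar(self.cronbach_alpha_comid30),
            "spearman_rho": scalar(self.spearman_rho),
            "n_analyzed": self.n_analyzed,
            "n_excluded": self.n_excluded,
            "deletion_policy": self.deletion_policy,
            "threshold": self.threshold,
            "unpaired_subjects": self.unpaired_subjects,
            "descriptives": self.descriptives,
        }

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def write_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def paired_frame(assessments: Sequence[AssessmentRecord],
                 checklists: Sequence[ComidChecklist],
                 catalogue: RuleCatalogue | None = None,
                 ) -> tuple[pd.DataFrame, list[str]]:
    """Derive the index and align it with the checklists by subject id.

    Returns a DataFrame with columns ``ci_<rule>`` (26) and
    ``comid_<item>`` (30), NaN marking MISSING, plus the list of subject
    ids present on only one side.
    """
    catalogue = catalogue or RuleCatalogue.default()
    comid_by_subject = {c.subject_id: c for c in checklists}
    rows = []
    paired_ids = set()
    for record in assessments:
        checklist = comid_by_subject.get(record.subject_id)
        if checklist is None:
            continue
        paired_ids.add(record.subject_id)
        result = catalogue.derive_ci(record, policy="per_rule")
        row: dict = {"subject_id": record.subject_id}
        for rid, value in result.variables.items():
            row[f"ci_{rid}"] = np.nan if isinstance(value, Sentinel) else value
        for item in COMID_ITEMS:
            value = checklist.answers.get(item, MISSING)
            row[f"comid_{item}"] = np.nan if isinstance(value, Sentinel) else value
        rows.append(row)
    unpaired = sorted(
        ({r.subject_id for r in assessments} | set(comid_by_subject))
        - paired_ids)
    frame = pd.DataFrame(rows)
    return frame, unpaired


def validation_report(assessments: Sequence[AssessmentRecord],
                      checklists: Sequence[ComidChecklist],
                      catalogue: RuleCatalogue | None = None,
                      alpha: float = 0.05,
                      n_tests: int = 26,
                      deletion: str = "listwise",
                      phi_method: str = "chi2",
                      alpha_ddof: int = 1) -> ValidationReport:
    """Run the full validation battery on paired records.

    Derives the 26 index variables per subject, crosses each with its
    checklist counterpart (phi + Bonferroni-adjusted significance),
    computes Cronbach's alpha for the index and both checklist variants,
    and Spearman's rho between the index total and the 26-item checklist
    total, all under the requested deletion policy.
    """
    catalogue = catalogue or RuleCatalogue.default()
    frame, unpaired = paired_frame(assessments, checklists, catalogue)
    if frame.empty:
        raise EmptyAnalysisError("no paired subjects to analyse")
    threshold = bonferroni_threshold(alpha, n_tests)

    ci_cols = [f"ci_{rid}" for rid in catalogue.rule_ids()]
    comid30_cols = [f"comid_{i}" for i in COMID_ITEMS]
    comid26_cols = [f"comid_{i}" for i in COMID26_ITEMS]
    analysis_cols = ci_cols + comid30_cols

    if deletion == "listwise":
        result = apply_deletion(frame, analysis_cols, "listwise")
        analysis, n_excluded = result.data, result.n_excluded

        def pair_subset(cols):
            return analysis
    elif deletion == "pairwise":
        selector = apply_deletion(frame, analysis_cols, "pairwise")
        analysis, n_excluded = frame, 0
        pair_subset = selector.subset
    else:
        raise ValueError(f"unknown deletion policy {deletion!r}")

    variables = []
    for rid in catalogue.rule_ids():
        cols = [f"ci_{rid}", f"comid_{rid}"]
        sub = pair_subset(cols).dropna(subset=cols)
        ci = sub[cols[0]].astype(int).to_numpy()
        comid = sub[cols[1]].astype(int).to_numpy()
        if len(sub):
            table = crosstab(ci, comid)
            phi = phi_coefficient(table, threshold, method=phi_method)
        else:
            phi = PhiResult(NOT_CALCULABLE, NOT_CALCULABLE, False)
        variables.append(VariableResult(
            rule_id=rid,
            label=catalogue.rule(rid).comid_label,
            comid_no=int(np.sum(comid == 0)),
            comid_yes=int(np.sum(comid == 1)),
            ci_no=int(np.sum(ci == 0)),
            ci_yes=int(np.sum(ci == 1)),
            phi=phi,
            n=len(sub),
        ))

    def safe_alpha(cols):
        sub = pair_subset(cols).dropna(subset=cols)
        if len(sub) < 2:
            return NOT_CALCULABLE
        return cronbach_alpha(sub[cols], ddof=alpha_ddof)

    alpha_ci = safe_alpha(ci_cols)
    alpha_c26 = safe_alpha(comid26_cols)
    alpha_c30 = safe_alpha(comid30_cols)

    score_cols = ci_cols + comid26_cols
    score_sub = pair_subset(score_cols).dropna(subset=score_cols)
    ci_total = score_sub[ci_cols].sum(axis=1)
    comid26_total = score_sub[comid26_cols].sum(axis=1)
    if len(score_sub) >= 3:
        rho = spearman_rho(ci_total, comid26_total)
    else:
        rho = NOT_CALCULABLE

    descriptives = {}
    if len(score_sub):
        descriptives = {
            "ci_total": _describe(ci_total),
            "comid26_total": _describe(comid26_total),
        }

    return ValidationReport(
        variables=variables,
        cronbach_alpha_ci=alpha_ci,
        cronbach_alpha_comid26=alpha_c26,
        cronbach_alpha_comid30=alpha_c30,
        spearman_rho=rho,
        n_analyzed=len(analysis),
        n_excluded=n_excluded,
        deletion_policy=deletion,
        threshold=threshold,
        unpaired_subjects=unpaired,
        descriptives=descriptives,
    )


def _describe(series: pd.Series) -> dict:
    return {
        "mean": float(series.mean()),
        "sd": float(series.std(ddof=1)) if len(series) > 1 else 0.0,
        "min": float(series.min()),
        "max": float(series.max()),
        "n": int(len(series)),
    }
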