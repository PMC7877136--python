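"""Association and reliability statistics: phi, Bonferroni control,
Cronbach's alpha, Spearman's rho, deletion policies and the full report."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from interrai_ci import (NOT_CALCULABLE, RuleCatalogue, SyntheticConfig,
                         TwoByTwoTable, apply_deletion, bonferroni_threshold,
                         cronbach_alpha, crosstab, generate_paired_dataset,
                         phi_coefficient, spearman_rho, validation_report)
from interrai_ci.errors import EmptyAnalysisError
from interrai_ci.psychometrics import PairwiseSelector


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def phi_oracle(table: TwoByTwoTable) -> float:
    """sign(ad - bc) * sqrt(chi2 / n) with chi2 from the generic
    contingency-table routine (no continuity correction)."""
    obs = np.array([[table.a, table.b], [table.c, table.d]])
    chi2 = stats.chi2_contingency(obs, correction=False).statistic
    return math.copysign(math.sqrt(chi2 / table.n),
                         table.a * table.d - table.b * table.c)


def spearman_oracle(x, y) -> float:
    """Explicit mid-rank table, then the Pearson formula."""
    def midranks(v):
        v = list(v)
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                ranks[order[k]] = avg
            i = j + 1
        return ranks

    rx, ry = midranks(x), midranks(y)
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
    return num / den


def alpha_oracle(matrix, ddof=1) -> float:
    """Direct variance formula, computed cell by cell."""
    matrix = [list(map(float, row)) for row in matrix]
    n, k = len(matrix), len(matrix[0])

    def var(values):
        m = sum(values) / len(values)
        return sum((v - m) ** 2 for v in values) / (len(values) - ddof)

    item_vars = sum(var([row[j] for row in matrix]) for j in range(k))
    total_var = var([sum(row) for row in matrix])
    return k / (k - 1) * (1 - item_vars / total_var)


def random_nonzero_margin_tables(n_tables, seed, max_cell=60):
    rng = np.random.default_rng(seed)
    tables = []
    while len(tables) < n_tables:
        a, b, c, d = rng.integers(0, max_cell + 1, size=4)
        t = TwoByTwoTable(int(a), int(b), int(c), int(d))
        if 0 not in t.marginals:
            tables.append(t)
    return tables


# ---------------------------------------------------------------------------
# Crosstab and phi
# ---------------------------------------------------------------------------

class TestCrosstab:
    @pytest.mark.parametrize("x, y, cells", [
        ((1, 1, 0, 0), (1, 0, 1, 0), (1, 1, 1, 1)),
        ((1, 0), (1, 0), (1, 0, 0, 1)),
        ((1, 1), (0, 0), (0, 2, 0, 0)),
    ])
    def test_cell_counts(self, x, y, cells):
        t = crosstab(x, y)
        assert (t.a, t.b, t.c, t.d) == cells
        assert t.n == len(x)

    def test_rejects_nonbinary_and_mismatch(self):
        with pytest.raises(ValueError):
            crosstab((1, 2), (0, 1))
        with pytest.raises(ValueError):
            crosstab((1, 0, 1), (0, 1))


class TestPhiCoefficient:
    def test_perfect_agreement(self):
        assert phi_coefficient(TwoByTwoTable(10, 0, 0, 10)).phi == pytest.approx(1.0)

    def test_independence(self):
        result = phi_coefficient(TwoByTwoTable(5, 5, 5, 5))
        assert result.phi == pytest.approx(0.0)
        assert result.p_value == pytest.approx(1.0)

    def test_worked_example(self):
        result = phi_coefficient(TwoByTwoTable(50, 10, 5, 35))
        assert result.phi == pytest.approx(0.698, abs=5e-4)
        assert result.phi == pytest.approx(phi_oracle(TwoByTwoTable(50, 10, 5, 35)),
                                           abs=1e-12)

    def test_zero_marginal_not_calculable(self):
        result = phi_coefficient(TwoByTwoTable(0, 0, 26, 190))
        assert result.phi is NOT_CALCULABLE
        assert result.p_value is NOT_CALCULABLE
        assert not result.significant_at

    def test_chi_square_equivalence_on_random_tables(self):
        """phi == sign(ad-bc) * sqrt(chi2/n) to 1e-12 on 1,000 random
        tables with nonzero marginals."""
        for table in random_nonzero_margin_tables(1000, seed=123):
            assert phi_coefficient(table).phi == pytest.approx(
                phi_oracle(table), abs=1e-12)

    def test_symmetry_and_double_swap_invariance(self):
        for table in random_nonzero_margin_tables(50, seed=7):
            phi = phi_coefficient(table).phi
            assert phi_coefficient(table.transpose()).phi == pytest.approx(phi)
            swapped = TwoByTwoTable(table.d, table.c, table.b, table.a)
            assert phi_coefficient(swapped).phi == pytest.approx(phi)

    def test_alternative_p_value_methods(self):
        table = TwoByTwoTable(30, 10, 8, 40)
        default = phi_coefficient(table).p_value
        corrected = phi_coefficient(table, method="chi2_corrected").p_value
        fisher = phi_coefficient(table, method="fisher").p_value
        assert default < corrected  # Yates correction is conservative
        assert 0 < fisher < 1

    def test_significance_uses_strict_inequality(self):
        table = TwoByTwoTable(5, 5, 5, 5)  # p = 1.0
        assert not phi_coefficient(table, threshold=1.0).significant_at


class TestBonferroni:
    def test_study_threshold(self):
        assert round(bonferroni_threshold(0.05, 26), 4) == 0.0019

    def test_identity_and_division(self):
        assert bonferroni_threshold(0.05, 1) == 0.05
        assert bonferroni_threshold(0.01, 5) == pytest.approx(0.002)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)
        with pytest.raises(ValueError):
            bonferroni_threshold(0.0, 26)


# ---------------------------------------------------------------------------
# Reliability and correlation
# ---------------------------------------------------------------------------

class TestCronbachAlpha:
    def test_identical_columns_give_one(self):
        col = [1, 0, 1, 1, 0, 1]
        matrix = np.column_stack([col, col, col])
        assert cronbach_alpha(matrix) == pytest.approx(1.0)

    def test_worked_matrix_matches_oracle(self):
        matrix = [(1, 1, 1), (1, 1, 0), (0, 0, 0), (1, 0, 0)]
        assert alpha_oracle(matrix) == pytest.approx(0.75)
        assert cronbach_alpha(np.array(matrix)) == pytest.approx(0.75)

    def test_independent_items_give_near_zero(self):
        rng = np.random.default_rng(11)
        matrix = (rng.random((5000, 26)) < 0.2).astype(float)
        assert abs(cronbach_alpha(matrix)) < 0.05

    def test_matches_pingouin_on_random_matrix(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(4)
        frame = pd.DataFrame((rng.random((80, 6)) < 0.4).astype(float))
        expected = pingouin.cronbach_alpha(data=frame)[0]
        assert cronbach_alpha(frame) == pytest.approx(expected, abs=1e-10)

    def test_population_convention_available(self):
        matrix = [(1, 1, 1), (1, 1, 0), (0, 0, 0), (1, 0, 0)]
        assert cronbach_alpha(np.array(matrix), ddof=0) == pytest.approx(
            alpha_oracle(matrix, ddof=0))

    def test_zero_total_variance_not_calculable(self):
        matrix = np.array([(1, 0), (0, 1), (1, 0)])
        assert cronbach_alpha(matrix) is NOT_CALCULABLE

    def test_alpha_never_exceeds_one(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            matrix = (rng.random((40, 5)) < rng.uniform(0.2, 0.8)).astype(float)
            value = cronbach_alpha(matrix)
            if value is not NOT_CALCULABLE:
                assert value <= 1.0


class TestSpearman:
    def test_monotone_identity_and_reversal(self):
        x = [3.0, 1.0, 4.0, 1.5, 9.0]
        assert spearman_rho(x, x) == pytest.approx(1.0)
        assert spearman_rho(x, [-v for v in x]) == pytest.approx(-1.0)

    def test_tied_ranks_match_brute_force(self):
        x, y = (1, 2, 2, 4), (1, 3, 2, 4)
        expected = spearman_oracle(x, y)
        assert expected == pytest.approx(0.94868, abs=1e-5)
        assert spearman_rho(x, y) == pytest.approx(expected, abs=1e-12)

    def test_random_vectors_match_brute_force(self):
        rng = np.random.default_rng(21)
        for _ in range(25):
            x = rng.integers(0, 8, size=30)
            y = rng.integers(0, 8, size=30)
            if len(set(x)) < 2 or len(set(y)) < 2:
                continue
            assert spearman_rho(x, y) == pytest.approx(
                spearman_oracle(x, y), abs=1e-12)

    def test_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        x = rng.integers(0, 27, size=60)
        y = rng.integers(0, 27, size=60)
        rho = spearman_rho(x, y)
        assert spearman_rho(np.exp(x / 5.0), y) == pytest.approx(rho, abs=1e-12)
        assert spearman_rho(x, 3 * y + 7) == pytest.approx(rho, abs=1e-12)

    def test_constant_vector_not_calculable(self):
        assert spearman_rho([1, 1, 1, 1], [1, 2, 3, 4]) is NOT_CALCULABLE


# ---------------------------------------------------------------------------
# Deletion policies
# ---------------------------------------------------------------------------

class TestDeletion:
    def _frame(self, n_rows, n_missing):
        frame = pd.DataFrame({"x": [1.0] * n_rows, "y": [0.0] * n_rows})
        frame.loc[: n_missing - 1, "x"] = np.nan
        return frame

    def test_listwise_retains_complete_rows(self):
        result = apply_deletion(self._frame(10, 2), ["x", "y"], "listwise")
        assert len(result.data) == 8
        assert result.n_excluded == 2

    def test_study_exclusion_fraction(self):
        """15 incomplete records out of 231 is a 6.5% exclusion."""
        result = apply_deletion(self._frame(231, 15), ["x", "y"], "listwise")
        assert result.n_excluded == 15
        assert round(100 * result.excluded_fraction, 1) == 6.5

    def test_pairwise_keeps_full_n_for_complete_pair(self):
        frame = self._frame(10, 4)
        selector = apply_deletion(frame, ["x", "y"], "pairwise")
        assert isinstance(selector, PairwiseSelector)
        assert len(selector.subset(["y"])) == 10
        assert len(selector.subset(["x"])) == 6

    def test_empty_listwise_result_signalled(self):
        with pytest.raises(EmptyAnalysisError):
            apply_deletion(self._frame(3, 3), ["x"], "listwise")


# ---------------------------------------------------------------------------
# Full report
# ---------------------------------------------------------------------------

class TestValidationReport:
    def test_perfect_agreement_gives_unit_statistics(self, perfect_pair):
        assessments, checklists, _ = perfect_pair
        report = validation_report(assessments, checklists)
        assert report.threshold == pytest.approx(0.05 / 26)
        assert report.spearman_rho == pytest.approx(1.0)
        for variable in report.variables:
            if variable.phi.calculable:
                assert variable.phi.phi == pytest.approx(1.0)
            else:
                # a constant variable has no defined phi but the report completes
                assert variable.ci_yes == 0 or variable.ci_no == 0

    def test_independent_pairs_rarely_significant(self):
        """Under independence the Bonferroni-adjusted threshold keeps the
        association weak and admits at most a stray flag (two or more
        simultaneous flags have probability ~0.1% in one dataset; the
        replicate-level guarantee is checked in the acceptance suite)."""
        config = SyntheticConfig(
            n_subjects=216,
            prevalence={r: 0.3 for r in RuleCatalogue.default().rule_ids()},
            agreement={r: 0.5 for r in RuleCatalogue.default().rule_ids()},
            seed=13,
        )
        assessments, checklists, _ = generate_paired_dataset(config)
        report = validation_report(assessments, checklists)
        flagged = [v.rule_id for v in report.variables
                   if v.phi.calculable and v.phi.significant_at]
        assert len(flagged) <= 1
        phis = [abs(v.phi.phi) for v in report.variables if v.phi.calculable]
        assert sum(phis) / len(phis) < 0.1

    def test_constant_zero_variable_not_calculated(self, perfect_pair):
        assessments, checklists, truth = perfect_pair
        # default prevalence for 4e is 0, so its derived column is constant
        assert truth["4e"].sum() == 0
        report = validation_report(assessments, checklists)
        by_rule = {v.rule_id: v for v in report.variables}
        assert not by_rule["4e"].phi.calculable
        assert by_rule["4e"].ci_yes == 0

    def test_report_serialization_shape(self, perfect_pair, tmp_path):
        assessments, checklists, _ = perfect_pair
        report = validation_report(assessments, checklists)
        frame = report.to_frame()
        assert list(frame["variable"]) == sorted(frame["variable"])
        assert len(frame) == 26
        assert {"comid_no", "comid_yes", "ci_no", "ci_yes", "phi", "p_value"} <= set(frame.columns)
        report.write_csv(tmp_path / "report.csv")
        report.write_json(tmp_path / "report.json")
        assert (tmp_path / "report.csv").exists()
        back = pd.read_csv(tmp_path / "report.csv")
        assert len(back) == 26

    def test_unpaired_subjects_reported(self, perfect_pair):
        assessments, checklists, _ = perfect_pair
        report = validation_report(assessments[:-5], checklists)
        assert len(report.unpaired_subjects) == 5
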