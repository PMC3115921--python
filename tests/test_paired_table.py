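import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from scipy import stats

from pairback import (
    EffectWithCI,
    PairedTable,
    marginals_of,
    mcnemar_p,
    mcnemar_z,
    nnt,
    odds_ratio,
    rd_variance_general,
    rd_variance_null,
    risk_difference,
    risk_ratio,
)
from pairback.exceptions import DegenerateInputError, DomainError, SparseDataWarning

from conftest import tables_strategy


def multinomial_var_rd(table: PairedTable) -> float:
    """Exact Var((C - B)/n) under Multinomial(n, cells/n), by enumeration.

    Independent oracle for the plug-in risk-difference variance: enumerate
    every possible outcome of n pairs at the table's own cell frequencies.
    """
    n = table.n
    probs = np.array(table.cells, dtype=float) / n
    mean = 0.0
    mean_sq = 0.0
    for cells in itertools.product(range(n + 1), repeat=3):
        if sum(cells) > n:
            continue
        a, b, c = cells
        d = n - a - b - c
        pmf = stats.multinomial.pmf((a, b, c, d), n, probs)
        delta = (c - b) / n
        mean += pmf * delta
        mean_sq += pmf * delta**2
    return mean_sq - mean**2


def delta_method_var_log_rr(table: PairedTable) -> float:
    """Delta-method Var(ln theta_hat) from the multinomial covariance."""
    n = table.n
    p = np.array(table.cells, dtype=float) / n
    b, c, d = table.b, table.c, table.d
    grad = np.array([0.0, 1 / (b + d), -1 / (c + d), 1 / (b + d) - 1 / (c + d)])
    cov = n * (np.diag(p) - np.outer(p, p))
    return float(grad @ cov @ grad)


class TestTableType:
    def test_cells_must_be_counts(self):
        with pytest.raises(DomainError):
            PairedTable(1, -1, 2, 3)
        with pytest.raises(DomainError):
            PairedTable(1.5, 0, 2, 3)
        with pytest.raises(DomainError):
            PairedTable(0, 0, 0, 0)

    def test_marginals(self, mortality_table):
        m = marginals_of(mortality_table)
        assert m.p1_hat == pytest.approx(0.7)
        assert m.p2_hat == pytest.approx(0.5)
        assert m.n == 60

    def test_marginals_all_concordant_negative(self):
        m = marginals_of(PairedTable(9, 0, 0, 0))
        assert (m.p1_hat, m.p2_hat) == (0.0, 0.0)

    def test_marginals_of_case_control_example(self):
        m = marginals_of(PairedTable(25, 30, 15, 10))
        assert m.p1_hat == pytest.approx(0.3125)
        assert m.p2_hat == pytest.approx(0.5)


class TestVariances:
    def test_general_se_matches_published(self, mortality_table):
        assert math.sqrt(rd_variance_general(mortality_table)) == pytest.approx(
            0.084, abs=5e-4
        )

    def test_null_se_matches_published(self, mortality_table):
        # printed as s0 = 0.2/2.27 = 0.088
        assert math.sqrt(rd_variance_null(mortality_table)) == pytest.approx(
            0.088, abs=5e-4
        )

    def test_no_discordant_pairs(self):
        assert rd_variance_general(PairedTable(3, 0, 0, 3)) == 0.0
        with pytest.raises(DegenerateInputError):
            rd_variance_null(PairedTable(3, 0, 0, 3))

    def test_null_direct_arithmetic(self):
        assert rd_variance_null(PairedTable(0, 1, 1, 0)) == pytest.approx(0.5)

    @given(tables_strategy)
    def test_general_null_relationship(self, table):
        """v_general = v_null - delta^2 / n, exactly, for every table."""
        delta = (table.c - table.b) / table.n
        assert rd_variance_general(table) == pytest.approx(
            rd_variance_null(table) - delta**2 / table.n, rel=1e-12
        )

    @pytest.mark.parametrize(
        "table",
        [
            PairedTable(1, 2, 3, 0),
            PairedTable(0, 1, 4, 1),
            PairedTable(2, 1, 2, 1),
            PairedTable(0, 3, 1, 1),
        ],
    )
    def test_enumeration_oracle_rd(self, table):
        """Plug-in variance equals the exact multinomial variance at the
        table's own cell frequencies (full enumeration, n <= 6)."""
        assert rd_variance_general(table) == pytest.approx(
            multinomial_var_rd(table), rel=1e-10
        )

    @pytest.mark.parametrize(
        "table", [PairedTable(1, 2, 3, 0), PairedTable(1, 1, 2, 2)]
    )
    def test_delta_method_oracle_log_rr(self, table):
        se = risk_ratio(table).se
        assert se**2 == pytest.approx(delta_method_var_log_rr(table), rel=1e-10)


class TestMcNemar:
    def test_published_statistic(self, mortality_table):
        assert mcnemar_z(mortality_table) == pytest.approx(2.268, abs=5e-4)
        assert mcnemar_p(mortality_table) == pytest.approx(0.023, abs=5e-4)

    def test_symmetric_table(self):
        t = PairedTable(1, 7, 7, 1)
        assert mcnemar_z(t) == 0.0
        assert mcnemar_p(t) == 1.0

    def test_one_sided_discordance(self):
        assert mcnemar_z(PairedTable(0, 0, 5, 0)) == pytest.approx(math.sqrt(5))

    def test_undefined_without_discordant_pairs(self):
        with pytest.raises(DegenerateInputError):
            mcnemar_z(PairedTable(2, 0, 0, 2))

    @given(tables_strategy)
    def test_null_variance_identity(self, table):
        """T * s0 = |risk difference| for every table with discordant pairs."""
        delta = abs(table.c - table.b) / table.n
        assert mcnemar_z(table) * math.sqrt(rd_variance_null(table)) == pytest.approx(
            delta, rel=1e-12
        )


class TestRiskDifference:
    def test_published_ci(self, mortality_table):
        eff = risk_difference(mortality_table)
        assert eff.estimate == pytest.approx(0.2)
        assert eff.ci_low == pytest.approx(0.035, abs=5e-4)
        assert eff.ci_high == pytest.approx(0.37, abs=5e-3)

    def test_truncated_to_parameter_space(self):
        eff = risk_difference(PairedTable(0, 0, 3, 1))
        assert eff.ci_high <= 1.0

    def test_symmetric_table_zero_estimate(self):
        with pytest.warns(SparseDataWarning):
            assert risk_difference(PairedTable(5, 4, 4, 5)).estimate == 0.0

    def test_coverage_of_true_delta(self, rng):
        """Wald CI covers the true risk difference near nominally at n=500."""
        probs = (0.35, 0.1, 0.25, 0.3)
        true_delta = (probs[2] + probs[3]) - (probs[1] + probs[3])
        reps = 2000
        draws = rng.multinomial(500, probs, size=reps)
        hits = 0
        for a, b, c, d in draws:
            eff = risk_difference(PairedTable(int(a), int(b), int(c), int(d)))
            hits += eff.ci_low <= true_delta <= eff.ci_high
        # nominal 0.95 within ~4 Monte-Carlo SEs (SE ~ 0.0049 at 2000 reps)
        assert hits / reps == pytest.approx(0.95, abs=0.02)


class TestRiskRatio:
    def test_published_ci(self, mortality_table):
        eff = risk_ratio(mortality_table)
        assert eff.estimate == pytest.approx(30 / 42)
        assert eff.se == pytest.approx(0.15, abs=5e-3)
        assert eff.ci_low == pytest.approx(0.53, abs=5e-3)
        assert eff.ci_high == pytest.approx(0.95, abs=1e-2)

    def test_equal_discordant_cells_give_unity(self):
        with pytest.warns(SparseDataWarning):
            assert risk_ratio(PairedTable(5, 4, 4, 5)).estimate == 1.0

    def test_zero_margin_rejected(self):
        with pytest.raises(DegenerateInputError, match="c \\+ d"):
            risk_ratio(PairedTable(50, 3, 0, 0))


class TestOddsRatio:
    def test_published_ci(self):
        eff = odds_ratio(PairedTable(25, 30, 15, 10))
        assert eff.estimate == pytest.approx(2.0)
        assert eff.se == pytest.approx(0.32, abs=5e-3)
        assert eff.ci_low == pytest.approx(1.1, abs=5e-2)
        assert eff.ci_high == pytest.approx(3.7, abs=5e-2)

    def test_minimal_discordance_se(self):
        with pytest.warns(SparseDataWarning):
            eff = odds_ratio(PairedTable(0, 1, 1, 0))
        assert eff.se == pytest.approx(math.sqrt(2))

    def test_needs_both_discordant_cells(self):
        with pytest.raises(DegenerateInputError):
            odds_ratio(PairedTable(10, 0, 5, 10))

    @given(tables_strategy)
    def test_log_ci_symmetric_about_estimate(self, table):
        eff = odds_ratio(table)
        assert math.log(eff.ci_low) + math.log(eff.ci_high) == pytest.approx(
            2 * math.log(eff.estimate), abs=1e-9
        )


class TestNNT:
    def test_published_values(self, mortality_table):
        eff = nnt(risk_difference(mortality_table))
        assert eff.estimate == pytest.approx(5.0)
        assert round(eff.ci_low) == 3
        assert round(eff.ci_high) == 29

    def test_total_effect(self):
        rd = EffectWithCI("risk_difference", 1.0, 0.01, 0.9, 1.0, 0.95)
        assert nnt(rd).estimate == 1.0

    def test_reciprocal_limits(self):
        rd = EffectWithCI("risk_difference", 0.5, 0.1, 0.25, 0.75, 0.95)
        eff = nnt(rd)
        assert eff.ci_low == pytest.approx(1 / 0.75)
        assert eff.ci_high == pytest.approx(4.0)

    def test_undefined_when_ci_spans_zero(self):
        rd = EffectWithCI("risk_difference", 0.1, 0.2, -0.1, 0.3, 0.95)
        with pytest.raises(DegenerateInputError, match="spans 0"):
            nnt(rd)

    def test_requires_risk_difference(self):
        rr = EffectWithCI("risk_ratio", 2.0, 0.1, 1.5, 2.5, 0.95, scale="log")
        with pytest.raises(DomainError):
            nnt(rr)


class TestDiagnostics:
    def test_small_study_warns(self):
        with pytest.warns(SparseDataWarning, match="<= 50 pairs"):
            risk_difference(PairedTable(10, 8, 12, 10))

    def test_sparse_discordance_warns(self):
        with pytest.warns(SparseDataWarning, match="discordant"):
            risk_difference(PairedTable(100, 2, 4, 100))

    def test_large_balanced_table_silent(self, recwarn):
        risk_difference(PairedTable(30, 20, 35, 30))
        assert not [w for w in recwarn if issubclass(w.category, SparseDataWarning)]

    @given(tables_strategy)
    def test_estimate_inside_ci(self, table):
        for eff in (risk_difference(table), risk_ratio(table), odds_ratio(table)):
            assert eff.ci_low <= eff.estimate <= eff.ci_high
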