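import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pasmatch.biostats import (
    PowerSpec,
    correlation_r2,
    ddct_fold_change,
    fisher_exact_2x2,
    fit_ic50,
    four_pl,
    min_n_for_power,
    power,
    power_one_way_anova,
    power_two_sample_t,
)
from pasmatch.errors import UndefinedStatisticError, ValidationError
from pasmatch.io import ContingencyTable2x2


class TestFisherExact:
    def test_stage_contingency_gives_p_one(self):
        # stage I: 4 vs 5; stage II+: 5 vs 5 (with vs without endometriosis)
        assert fisher_exact_2x2(ContingencyTable2x2(4, 5, 5, 5)) == pytest.approx(1.0)

    def test_fully_symmetric_table(self):
        assert fisher_exact_2x2(ContingencyTable2x2(1, 1, 1, 1)) == pytest.approx(1.0)

    def test_enumerated_cross_table(self):
        # [[3,1],[1,3]]: sum of hypergeometric probabilities <= observed = 34/70
        assert fisher_exact_2x2(ContingencyTable2x2(3, 1, 1, 3)) == pytest.approx(34 / 70, rel=1e-7)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.tuples(*[st.integers(0, 12)] * 4).filter(lambda t: sum(t) > 0))
    def test_invariant_under_row_column_swap_and_transpose(self, cells):
        a, b, c, d = cells
        base = fisher_exact_2x2(ContingencyTable2x2(a, b, c, d))
        assert fisher_exact_2x2(ContingencyTable2x2(c, d, a, b)) == pytest.approx(base, rel=1e-9)
        assert fisher_exact_2x2(ContingencyTable2x2(b, a, d, c)) == pytest.approx(base, rel=1e-9)
        assert fisher_exact_2x2(ContingencyTable2x2(a, c, b, d)) == pytest.approx(base, rel=1e-9)


class TestPowerT:
    def test_null_effect_power_equals_alpha(self):
        assert power_two_sample_t(0.0, 10, alpha=0.05) == pytest.approx(0.05, abs=1e-9)

    def test_huge_effect_tiny_groups_exceeds_95(self):
        assert power_two_sample_t(9.6, 2, alpha=0.05) >= 0.95

    def test_monotone_in_effect_and_n(self):
        powers_d = [power_two_sample_t(d, 5) for d in (0.0, 0.5, 1.0, 2.0, 4.0)]
        assert all(b >= a for a, b in zip(powers_d, powers_d[1:]))
        powers_n = [power_two_sample_t(0.8, n) for n in (2, 4, 8, 16, 32)]
        assert all(b >= a for a, b in zip(powers_n, powers_n[1:]))

    def test_one_sided_exceeds_two_sided(self):
        assert power_two_sample_t(1.0, 6, sides=1) > power_two_sample_t(1.0, 6, sides=2)

    def test_spec_dispatch(self):
        spec = PowerSpec(test="two_sample_t", effect_size=9.6, n_per_group=2)
        assert power(spec) == pytest.approx(power_two_sample_t(9.6, 2))


class TestPowerAnova:
    def test_null_effect_power_equals_alpha(self):
        assert power_one_way_anova(0.0, 3, 24, alpha=0.05) == pytest.approx(0.05, abs=1e-9)

    def test_study_design_exceeds_80(self):
        assert power_one_way_anova(0.7, 3, 24, alpha=0.05) >= 0.80

    def test_monotone_in_effect_and_n(self):
        powers_f = [power_one_way_anova(f, 3, 24) for f in (0.0, 0.2, 0.4, 0.7, 1.0)]
        assert all(b >= a for a, b in zip(powers_f, powers_f[1:]))
        powers_n = [power_one_way_anova(0.5, 3, n) for n in (9, 12, 24, 48)]
        assert all(b >= a for a, b in zip(powers_n, powers_n[1:]))

    def test_minimal_n_consistent_with_power(self):
        n_min = min_n_for_power(0.7, 3, target_power=0.80)
        assert power_one_way_anova(0.7, 3, n_min) >= 0.80
        assert power_one_way_anova(0.7, 3, n_min - 1) < 0.80
        assert n_min <= 24


class TestDdct:
    def test_zero_ddct_is_unity(self):
        assert ddct_fold_change(20.0, 18.0, 22.0, 20.0) == pytest.approx(1.0)

    def test_worked_arithmetic(self):
        # treated dCt = 20-15 = 5; control dCt = 24-16 = 8; ddCt = -3 -> 2^3 = 8
        assert ddct_fold_change(20.0, 15.0, 24.0, 16.0) == pytest.approx(8.0)

    def test_positive_unit_ddct_halves_expression(self):
        assert ddct_fold_change(21.0, 20.0, 20.0, 20.0) == pytest.approx(0.5)

    def test_nonfinite_ct_rejected(self):
        with pytest.raises(ValidationError):
            ddct_fold_change(math.inf, 20.0, 20.0, 20.0)


class TestIC50:
    doses = np.array([5, 10, 20, 35, 50, 75, 100, 130, 165, 200], dtype=float)

    def test_noiseless_recovery_within_one_percent(self):
        y = four_pl(self.doses, 0.05, 1.0, 50.0, 1.3)
        fit = fit_ic50(self.doses, y)
        assert fit.ic50 == pytest.approx(50.0, rel=0.01)
        assert fit.r_squared > 0.999

    def test_noisy_recovery_median_within_ten_percent(self):
        # a full-span response (both plateaus inside the dose range) in
        # triplicate with 5% absolute noise: median error across seeds <= 10%
        errors = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            d3 = np.repeat(self.doses, 3)
            y = four_pl(d3, 0.05, 1.0, 50.0, 2.0) + rng.normal(0, 0.05, size=d3.size)
            fit = fit_ic50(d3, y)
            errors.append(abs(fit.ic50 - 50.0) / 50.0)
        assert np.median(errors) <= 0.10

    def test_scale_equivariance(self):
        y = four_pl(self.doses, 0.0, 1.0, 40.0, 1.5)
        base = fit_ic50(self.doses, y)
        scaled = fit_ic50(self.doses * 3.0, y)
        assert scaled.ic50 == pytest.approx(3.0 * base.ic50, rel=1e-3)

    def test_flat_response_is_undefined_with_warning(self):
        with pytest.warns(UserWarning, match="flat"):
            fit = fit_ic50(self.doses, np.ones_like(self.doses))
        assert not fit.defined

    def test_increasing_viability_is_undefined_with_warning(self):
        y = np.linspace(0.2, 1.0, self.doses.size)
        with pytest.warns(UserWarning, match="increases"):
            fit = fit_ic50(self.doses, y)
        assert not fit.defined

    def test_too_few_doses_rejected(self):
        with pytest.raises(ValidationError):
            fit_ic50([1.0, 2.0, 4.0], [1.0, 0.6, 0.2])


class TestCorrelationR2:
    def test_exact_linearity(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert correlation_r2(x, 2 * x + 1) == pytest.approx(1.0)

    def test_orthogonal_deviations(self):
        x = np.array([-1.0, 0.0, 1.0])
        y = np.array([1.0, -2.0, 1.0])  # quadratic pattern, zero linear component
        assert correlation_r2(x, y) == pytest.approx(0.0, abs=1e-12)

    def test_square_of_pearson_example(self):
        assert correlation_r2([1.0, 2.0, 3.0], [1.0, 2.0, 4.0]) == pytest.approx(
            (3.0 / np.sqrt(2.0 * 14.0 / 3.0)) ** 2, abs=1e-12
        )

    def test_constant_input_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            correlation_r2([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
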