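from dataclasses import replace

import pytest

from donorpanel import (
    InvalidInputError,
    PanelParams,
    annual_screened,
    default_panel_params,
    maintenance_rate,
    panel_after_years,
    required_fraction,
    years_to_target,
)


@pytest.fixture
def genotype_params():
    return default_panel_params("genotype")


@pytest.fixture
def phenotype_params():
    return default_panel_params("phenotype")


class TestAnnualScreened:
    @pytest.mark.parametrize(
        "weekly,fraction,expected",
        [(13_500, 0.01, 7_039), (13_500, 0.05, 35_196), (10_000, 0.0, 0)],
    )
    def test_published_anchors(self, weekly, fraction, expected):
        assert annual_screened(weekly, fraction) == expected

    def test_negative_inputs_rejected(self):
        with pytest.raises(InvalidInputError):
            annual_screened(-1, 0.05)


class TestPanelAfterYears:
    def test_zero_horizon_returns_D0(self, genotype_params):
        assert panel_after_years(genotype_params, 0) == genotype_params.D0

    def test_closed_form_equals_recursion(self, phenotype_params):
        params = replace(phenotype_params, screening_fraction=0.07)
        D = params.D0
        for y in range(1, 51):
            D = (1 - params.m) * D + params.M
            assert panel_after_years(params, y) == pytest.approx(D, rel=1e-6)

    def test_zero_attrition_is_linear(self):
        params = PanelParams(
            panel_size=100_000, weekly_returning=1000,
            screening_fraction=0.1, D0=500, m=0.0,
        )
        q = params.q
        assert panel_after_years(params, 7) == pytest.approx(500 + 7 * q)

    def test_monotone_convergence_to_steady_state(self, genotype_params):
        params = replace(genotype_params, screening_fraction=0.05)
        steady = params.steady_state
        values = [panel_after_years(params, y) for y in range(0, 60)]
        assert all(b > a for a, b in zip(values, values[1:]))
        assert all(v < steady for v in values)
        assert values[35] > 0.99 * steady


class TestYearsToTarget:
    def test_genotype_five_percent_reaches_in_12_years(self, genotype_params):
        res = years_to_target(
            replace(genotype_params, screening_fraction=0.05), 205_000
        )
        assert res.years == 12
        assert round(res.D_y) == pytest.approx(207_381, abs=3)

    def test_genotype_low_fractions_never_attain(self, genotype_params):
        for fraction in (0.01, 0.04):
            res = years_to_target(
                replace(genotype_params, screening_fraction=fraction), 205_000
            )
            assert res.years is None
            assert res.steady_state < 205_000

    def test_phenotype_nine_percent_three_years(self, phenotype_params):
        res = years_to_target(
            replace(phenotype_params, screening_fraction=0.09), 188_000
        )
        assert res.years == 3
        assert round(res.D_y) == pytest.approx(198_862, abs=3)

    def test_target_already_met(self, genotype_params):
        res = years_to_target(genotype_params, 5_000)
        assert res.years == 0 and res.D_y == genotype_params.D0

    def test_trajectory_increasing_below_steady_state(self, phenotype_params):
        res = years_to_target(
            replace(phenotype_params, screening_fraction=0.06), 188_000
        )
        assert all(b > a for a, b in zip(res.trajectory, res.trajectory[1:]))
        assert res.trajectory[-1] == res.D_y

    def test_years_non_increasing_in_fraction(self, genotype_params):
        years = []
        for fraction in (0.05, 0.07, 0.09, 0.11):
            res = years_to_target(
                replace(genotype_params, screening_fraction=fraction), 205_000
            )
            years.append(res.years)
        assert all(b <= a for a, b in zip(years, years[1:]))


class TestRequiredFraction:
    def test_genotype_three_year_deadline_needs_12_percent(self, genotype_params):
        fraction, res = required_fraction(genotype_params, 205_000, deadline_years=3)
        assert fraction == pytest.approx(0.12)
        assert res.years == 3

    def test_phenotype_three_year_deadline_needs_9_percent(self, phenotype_params):
        fraction, res = required_fraction(phenotype_params, 188_000, deadline_years=3)
        assert fraction == pytest.approx(0.09)

    def test_no_deadline_finds_smallest_finite_fraction(self, genotype_params):
        fraction, res = required_fraction(genotype_params, 205_000)
        assert fraction == pytest.approx(0.05)
        assert res.years == 12

    def test_unattainable_returns_none(self):
        params = PanelParams(
            panel_size=1000, weekly_returning=10,
            screening_fraction=0.0, D0=0, m=0.5,
        )
        assert required_fraction(params, 10_000_000, deadline_years=5) is None


class TestMaintenanceRate:
    def test_genotype_and_phenotype_rates(self):
        assert round(maintenance_rate(205_000, 0.13), -2) == 28_500
        assert round(maintenance_rate(188_000, 0.13), -1) == 26_140

    def test_zero_attrition_needs_no_replacement(self):
        assert maintenance_rate(1_000_000, 0.0) == 0.0

    def test_fixed_point_of_projection(self):
        # screening at the maintenance rate holds the panel exactly steady
        target, m = 205_000, 0.13
        q = maintenance_rate(target, m)
        weekly = q / (0.13 * 365 / 7)  # arbitrary decomposition giving this q
        params = PanelParams(
            panel_size=542_891, weekly_returning=weekly,
            screening_fraction=0.13, D0=target, m=m, round_q=False,
        )
        for y in (1, 5, 25):
            assert panel_after_years(params, y) == pytest.approx(target, rel=1e-6)
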