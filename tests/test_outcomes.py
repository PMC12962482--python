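"""Life-expectancy, discounting, unrelated-cost, and regimen arithmetic."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ipn_cea.outcomes import (
    DEFAULT_REGIMENS,
    MEDICARE_MARKUP,
    Payoff,
    RegimenLine,
    deale_life_expectancy,
    discount_life_years,
    invert_discount,
    regimen_cost,
    unrelated_annual_cost,
)


class TestDeale:
    @pytest.mark.parametrize(
        "s5,background,expected",
        [
            (1.0, 22.7, 22.7),                     # no excess mortality
            (math.exp(-0.5), 25.0, 1 / (0.04 + 0.10)),
            (0.25, 22.7, 3.1122),                  # 1/(1/22.7 + ln4/5)
        ],
    )
    def test_closed_form(self, s5, background, expected):
        assert deale_life_expectancy(s5, background) == pytest.approx(
            expected, abs=1e-4
        )

    @pytest.mark.parametrize("s5", [0.0, -0.1, 1.1])
    def test_survival_domain(self, s5):
        with pytest.raises(ValueError):
            deale_life_expectancy(s5, 20.0)

    @given(st.floats(0.01, 0.999), st.floats(1.0, 60.0))
    def test_harmonic_bound(self, s5, background):
        le = deale_life_expectancy(s5, background)
        assert le <= min(background, 5.0 / -math.log(s5)) + 1e-12


class TestDiscounting:
    def test_zero_rate_is_identity(self):
        assert discount_life_years(12.3, 0.0) == 12.3
        assert invert_discount(12.3, 0.0) == 12.3

    def test_benign_payoff_consistent_with_background_horizon(self):
        # 22.66 undiscounted years at 3% continuous discounting gives the
        # packaged benign life-year payoff of 16.44
        assert discount_life_years(22.66, 0.03) == pytest.approx(16.44, abs=0.01)
        assert invert_discount(16.44, 0.03) == pytest.approx(22.66, abs=0.02)

    def test_zero_years(self):
        assert discount_life_years(0.0, 0.03) == 0.0

    def test_unbounded_horizon_rejected(self):
        with pytest.raises(ValueError, match="unbounded"):
            invert_discount(34.0, 0.03)

    @given(st.floats(0.0, 40.0),
           st.one_of(st.just(0.0), st.floats(1e-3, 0.2)))
    def test_round_trip(self, years, rate):
        discounted = discount_life_years(years, rate)
        assert invert_discount(discounted, rate) == pytest.approx(years, abs=1e-9)

    @given(st.floats(0.1, 40.0), st.floats(0.001, 0.2))
    def test_monotone_in_years_and_rate(self, years, rate):
        assert discount_life_years(years + 0.1, rate) > discount_life_years(
            years, rate
        )
        assert discount_life_years(years, rate + 0.01) < discount_life_years(
            years, rate
        )


class TestUnrelatedAnnualCost:
    def test_zero_survival_costs_nothing(self):
        assert unrelated_annual_cost(0.0, 60, 0.03, 9056, 12961, 65) == 0.0

    def test_single_full_year(self):
        one_year = discount_life_years(1.0, 0.03)
        assert unrelated_annual_cost(one_year, 60, 0.03, 9056, 12961, 65) == (
            pytest.approx(9056 / 1.03, abs=1e-6)
        )

    @pytest.mark.parametrize("undiscounted", [5.0, 10.0, 22.0])
    def test_matches_annuity_oracle_at_integer_horizons(self, undiscounted):
        # independent oracle: closed-form annuity factors split at the age
        # crossover (base age 60, so survival years 1-5 bill the young rate)
        dly = discount_life_years(undiscounted, 0.03)
        t = np.arange(1, int(undiscounted) + 1)
        factors = 1.03 ** -t.astype(float)
        expected = (9056 * factors[t <= 5]).sum() + (12961 * factors[t > 5]).sum()
        got = unrelated_annual_cost(dly, 60, 0.03, 9056, 12961, 65)
        assert got == pytest.approx(expected, abs=1e-6)

    def test_partial_final_year_prorated(self):
        dly = discount_life_years(1.5, 0.03)
        expected = 9056 / 1.03 + 0.5 * 9056 / 1.03**2
        assert unrelated_annual_cost(dly, 60, 0.03, 9056, 12961, 65) == (
            pytest.approx(expected, abs=1e-6)
        )

    def test_benign_base_case_magnitude(self):
        # 16.44 discounted LY -> ~22.66-year horizon: 5 years young rate,
        # 17 full + 1 partial old-rate years; brute-force year-by-year sum
        horizon = invert_discount(16.44, 0.03)
        total = 0.0
        t = 1
        remaining = horizon
        while remaining > 0:
            frac = min(1.0, remaining)
            rate = 9056 if 60 + t <= 65 else 12961
            total += frac * rate / 1.03**t
            remaining -= frac
            t += 1
        got = unrelated_annual_cost(16.44, 60, 0.03, 9056, 12961, 65)
        assert got == pytest.approx(total, abs=1e-6)

    @given(st.floats(0.0, 25.0))
    def test_monotone_in_survival(self, dly):
        a = unrelated_annual_cost(dly, 60, 0.03, 9056, 12961, 65)
        b = unrelated_annual_cost(min(dly + 0.5, 25.5), 60, 0.03, 9056, 12961, 65)
        assert b >= a


class TestRegimens:
    def test_zero_prices_cost_nothing(self):
        lines = [RegimenLine("drug", "flat-mg", 100, 3, 0.0)]
        assert regimen_cost(lines) == 0.0

    def test_markup_applied_per_administration(self):
        lines = [
            RegimenLine("a", "flat-mg", 10, 1, 100.0),
            RegimenLine("b", "flat-mg", 10, 1, 100.0),
        ]
        assert regimen_cost(lines, markup=0.043) == pytest.approx(208.60)

    def test_pembrolizumab_unit_price_inverts_published_total(self):
        pembro = next(
            l for l in DEFAULT_REGIMENS["stage_ii_iiia"] if l.agent == "pembrolizumab"
        )
        assert pembro.n_infusions == 17
        assert pembro.unit_price == pytest.approx(188418 / (17 * 1.043), rel=1e-9)
        assert regimen_cost([pembro]) == pytest.approx(188418.0, rel=1e-9)

    @pytest.mark.parametrize(
        "regimen,total",
        [("unresectable_iii", 185452.0), ("stage_iv_pdl1_low", 420088.0)],
    )
    def test_packaged_regimen_totals(self, regimen, total):
        assert regimen_cost(DEFAULT_REGIMENS[regimen]) == pytest.approx(
            total, rel=1e-9
        )

    def test_dose_calculation_by_spec(self):
        per_m2 = RegimenLine("pemetrexed", "per-m2", 500, 4, 1.0)
        per_kg = RegimenLine("durvalumab", "per-kg", 10, 26, 1.0)
        assert per_m2.administered_dose(2.0, 90.7) == 1000.0
        assert per_kg.administered_dose(2.0, 90.7) == 907.0

    def test_unknown_dose_spec_rejected(self):
        with pytest.raises(ValueError, match="dose spec"):
            RegimenLine("x", "per-furlong", 1, 1, 1.0)


class TestPayoffAndPackagedCosts:
    def test_negative_payoff_rejected(self):
        with pytest.raises(ValueError):
            Payoff(-1.0, 0.0)

    def test_surveillance_cost_ratio_four_cts_to_one(self, params):
        # stable nodules get four surveillance CTs, growing nodules one
        assert params["cost_surveillance_stable"] == (
            4 * params["cost_surveillance_growth"]
        )

    def test_markup_constant(self):
        assert MEDICARE_MARKUP == 0.043
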