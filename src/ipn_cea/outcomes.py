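"""Terminal payoffs: discounted life years and payer-perspective costs.

Life-year payoffs come from the declining exponential approximation of
life expectancy (DEALE): a constant disease-specific mortality rate
derived from 5-year survival is added to the background rate (reciprocal
of background life expectancy), and the reciprocal of the sum is the
expected survival.  Survival is discounted continuously; the packaged
life-year values are already-discounted terminal payoffs, and the
functions here document and cross-check them.

Costs are one-time procedure/treatment amounts plus unrelated annual
medical costs accrued discretely at the end of each survival year, at an
age-dependent rate (the bracket boundary falls at age 65 for a 60-year-old
base case).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "Payoff",
    "RegimenLine",
    "deale_life_expectancy",
    "discount_life_years",
    "invert_discount",
    "unrelated_annual_cost",
    "regimen_cost",
    "terminal_cost",
    "DEFAULT_REGIMENS",
    "MEDICARE_MARKUP",
    "BASE_CASE_BSA_M2",
    "BASE_CASE_WEIGHT_KG",
]

MEDICARE_MARKUP = 0.043           # standard drug reimbursement uplift
BASE_CASE_BSA_M2 = 2.0            # average US male, 200 lb / 70 in
BASE_CASE_WEIGHT_KG = 90.7


@dataclass(frozen=True)
class Payoff:
    """Terminal-node value: total cost (2021 USD) and discounted life years.

    Operative-death terminals carry effect exactly 0.
    """

    cost: float
    effect: float

    def __post_init__(self) -> None:
        if self.cost < 0 or self.effect < 0:
            raise ValueError(f"payoff components must be nonnegative: {self}")


def deale_life_expectancy(five_year_survival: float,
                          background_life_expectancy: float) -> float:
    """Life expectancy under constant disease + background mortality rates.

    The disease rate is ``-ln(S5)/5``; the background rate is the
    reciprocal of background life expectancy; expectancy is the reciprocal
    of their sum.
    """
    if not 0.0 < five_year_survival <= 1.0:
        raise ValueError(
            f"five-year survival must be in (0, 1], got {five_year_survival}"
        )
    if background_life_expectancy <= 0:
        raise ValueError("background life expectancy must be positive")
    mu_disease = -math.log(five_year_survival) / 5.0
    mu_background = 1.0 / background_life_expectancy
    return 1.0 / (mu_background + mu_disease)


def discount_life_years(undiscounted: float, rate: float) -> float:
    """Continuous-time discounted value of ``undiscounted`` years of life."""
    if undiscounted < 0 or rate < 0:
        raise ValueError("life years and discount rate must be nonnegative")
    if rate == 0:
        return undiscounted
    return (1.0 - math.exp(-rate * undiscounted)) / rate


def invert_discount(discounted: float, rate: float) -> float:
    """Exact inverse of :func:`discount_life_years`.

    Recovers the undiscounted survival horizon from a discounted payoff;
    needed to accrue annual costs over calendar years of survival.
    """
    if discounted < 0 or rate < 0:
        raise ValueError("inputs must be nonnegative")
    if rate == 0:
        return discounted
    if discounted >= 1.0 / rate:
        raise ValueError(
            f"discounted life years {discounted} >= 1/rate = {1.0 / rate:.4f}: "
            "horizon unbounded"
        )
    return -math.log(1.0 - rate * discounted) / rate


def unrelated_annual_cost(discounted_life_years: float, base_age: float,
                          rate: float, cost_young: float, cost_old: float,
                          crossover_age: float) -> float:
    """Discounted unrelated medical costs over the survival horizon.

    The undiscounted horizon ``L`` is recovered from the discounted payoff;
    costs accrue at the end of each survival year ``t = 1..ceil(L)`` (the
    final partial year prorated), discounted discretely by ``(1+rate)^-t``,
    at the under-65 rate while attained age stays at or below the crossover
    and the over-65 rate afterwards.
    """
    if min(discounted_life_years, base_age, rate, cost_young, cost_old) < 0:
        raise ValueError("all inputs must be nonnegative")
    if crossover_age < base_age:
        raise ValueError("crossover age must not precede base age")
    horizon = invert_discount(discounted_life_years, rate)
    if horizon == 0:
        return 0.0
    n_full = math.floor(horizon)
    fraction = horizon - n_full
    total = 0.0
    for t in range(1, n_full + 1):
        annual = cost_young if base_age + t <= crossover_age else cost_old
        total += annual / (1.0 + rate) ** t
    if fraction > 0:
        t = n_full + 1
        annual = cost_young if base_age + t <= crossover_age else cost_old
        total += fraction * annual / (1.0 + rate) ** t
    return total


def terminal_cost(params, life_years: float, treatment_cost: float = 0.0) -> float:
    """One-time treatment cost plus survival-dependent unrelated costs."""
    return treatment_cost + unrelated_annual_cost(
        life_years,
        params["base_age"],
        params["discount_rate"],
        params["cost_unrelated_under_65"],
        params["cost_unrelated_over_65"],
        params["crossover_age"],
    )


# ---------------------------------------------------------------------------
# Anticancer regimen costing


@dataclass(frozen=True)
class RegimenLine:
    """One agent of a treatment regimen.

    ``dose_spec`` is one of ``per-m2``, ``flat-mg``, ``per-kg``, or
    ``auc`` (Calvert-dosed carboplatin, priced per administration since
    renal function is not an input).  ``unit_price`` is USD per
    administered dose before the reimbursement markup.
    """

    agent: str
    dose_spec: str
    dose_value: float
    n_infusions: int
    unit_price: float

    def __post_init__(self) -> None:
        if self.dose_spec not in ("per-m2", "flat-mg", "per-kg", "auc"):
            raise ValueError(f"unknown dose spec: {self.dose_spec}")
        if self.n_infusions < 1:
            raise ValueError("n_infusions must be >= 1")
        if self.unit_price < 0:
            raise ValueError("unit price must be nonnegative")

    def administered_dose(self, body_surface_area: float, weight_kg: float) -> float:
        """Administered amount (mg, or AUC units for carboplatin)."""
        if self.dose_spec == "per-m2":
            return self.dose_value * body_surface_area
        if self.dose_spec == "per-kg":
            return self.dose_value * weight_kg
        return self.dose_value


def regimen_cost(lines, markup: float = MEDICARE_MARKUP,
                 body_surface_area: float = BASE_CASE_BSA_M2,
                 weight_kg: float = BASE_CASE_WEIGHT_KG) -> float:
    """Total regimen cost: sum of infusions x unit price, marked up.

    Dosing inputs determine the administered amount per infusion (exposed
    through :meth:`RegimenLine.administered_dose` for audit); the billed
    amount per administration is ``unit_price``.
    """
    if markup < 0:
        raise ValueError("markup must be nonnegative")
    if body_surface_area <= 0 or weight_kg <= 0:
        raise ValueError("dosing inputs must be positive")
    total = 0.0
    for line in lines:
        line.administered_dose(body_surface_area, weight_kg)  # validates spec
        total += line.n_infusions * line.unit_price * (1.0 + markup)
    return total


def _line(agent, dose_spec, dose_value, n_infusions, published_total):
    # unit prices back-derived from published regimen totals (which include
    # the markup): price = total / (n * (1 + markup))
    price = published_total / (n_infusions * (1.0 + MEDICARE_MARKUP))
    return RegimenLine(agent, dose_spec, dose_value, n_infusions, price)


#: Standard adjuvant/definitive regimens by stage (adenocarcinoma, no
#: targetable mutation), priced at average sales price + Medicare markup.
DEFAULT_REGIMENS: dict[str, tuple[RegimenLine, ...]] = {
    "stage_i": (),
    "stage_ii_iiia": (
        _line("cisplatin", "per-m2", 75.0, 4, 101.0),
        _line("pemetrexed", "per-m2", 500.0, 4, 8617.0),
        _line("pembrolizumab", "flat-mg", 200.0, 17, 188418.0),
    ),
    "unresectable_iii": (
        _line("carboplatin", "auc", 2.0, 6, 71.0),
        _line("paclitaxel", "per-m2", 45.0, 6, 92.0),
        _line("durvalumab", "per-kg", 10.0, 26, 185289.0),
    ),
    "stage_iv_pdl1_high": (
        _line("pembrolizumab", "flat-mg", 200.0, 35, 387919.0),
    ),
    "stage_iv_pdl1_low": (
        _line("carboplatin", "auc", 5.0, 4, 119.0),
        _line("pemetrexed", "per-m2", 500.0, 35, 32050.0),
        _line("pembrolizumab", "flat-mg", 200.0, 35, 387919.0),
    ),
}
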