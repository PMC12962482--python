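"""Incremental cost-effectiveness arithmetic and decision rules."""

from __future__ import annotations

from dataclasses import dataclass

from .tree import StrategyResult

__all__ = ["CEAResult", "icer", "net_monetary_benefit"]


@dataclass(frozen=True)
class CEAResult:
    """Incremental comparison of a comparator against a reference strategy.

    ``icer`` is the cost per life year gained and is populated only when
    the effect difference is nonzero; ``dominance`` flags the quadrants
    where a ratio is not a decision quantity: ``dominant`` (cheaper and
    more effective), ``dominated`` (costlier and less effective), or
    ``dominated (no gain)`` (costlier with zero gain).
    """

    reference: str
    comparator: str
    delta_cost: float
    delta_effect: float
    icer: float | None
    dominance: str | None


def icer(reference: StrategyResult, comparator: StrategyResult) -> CEAResult:
    """Incremental cost, effect, and their ratio (comparator − reference)."""
    d_cost = comparator.cost - reference.cost
    d_effect = comparator.effect - reference.effect
    dominance = None
    ratio: float | None = None
    if d_effect == 0.0:
        if d_cost > 0.0:
            dominance = "dominated (no gain)"
        elif d_cost < 0.0:
            dominance = "dominant"
    else:
        ratio = d_cost / d_effect
        if d_cost < 0.0 and d_effect > 0.0:
            dominance = "dominant"
        elif d_cost > 0.0 and d_effect < 0.0:
            dominance = "dominated"
    return CEAResult(reference.strategy, comparator.strategy,
                     d_cost, d_effect, ratio, dominance)


def net_monetary_benefit(result: StrategyResult, wtp: float) -> float:
    """``wtp × effect − cost``; higher is preferred at that threshold."""
    if wtp < 0:
        raise ValueError("willingness to pay must be nonnegative")
    return wtp * result.effect - result.cost
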