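"""Deterministic sensitivity analyses: one-way, tornado, threshold, two-way.

All analyses rebuild and roll back the full tree at each evaluated point;
multinomial complements renormalize proportionally when one component is
varied.  The comparator throughout is the AI-assisted strategy against the
clinician-alone reference.  For threshold logic, points where the AI
strategy yields no life-year gain at extra cost are scored as an infinite
cost-per-life-year ratio, which keeps bisection monotone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .cea import CEAResult, icer
from .parameters import SPECS_BY_NAME, ParameterError, ParameterSet
from .tree import build_model, rollback

__all__ = [
    "OneWayCurve",
    "TornadoEntry",
    "ThresholdResult",
    "evaluate",
    "icer_value",
    "one_way",
    "tornado",
    "threshold",
    "two_way",
    "DERIVED_PARAMETERS",
]

# Reparameterizations of packaged inputs, usable anywhere a parameter name
# is accepted.  PET specificity in benign disease is 1 - benign PET avidity.
DERIVED_PARAMETERS = {
    "pet_specificity": ("pet_avid_benign", lambda x: 1.0 - x),
}


def set_parameter(params: ParameterSet, name: str, value: float) -> ParameterSet:
    """`with_value` plus support for derived parameter names."""
    if name in DERIVED_PARAMETERS:
        target, transform = DERIVED_PARAMETERS[name]
        return params.with_value(target, transform(value))
    return params.with_value(name, value)


def evaluate(params: ParameterSet) -> CEAResult:
    """Base comparison at one parameter set: AI-assisted vs clinician."""
    results = rollback(build_model(params))
    return icer(results["clinician"], results["ai_assisted"])


def icer_value(result: CEAResult) -> float:
    """Scalar ICER with signed-infinity conventions for threshold search.

    No gain at extra cost -> +inf (never cost-effective); dominant
    (cheaper, no effect loss) -> -inf (always cost-effective).
    """
    if result.delta_effect <= 0.0:
        return math.inf if result.delta_cost >= 0.0 else -math.inf
    return result.delta_cost / result.delta_effect


@dataclass(frozen=True)
class OneWayCurve:
    parameter: str
    grid: tuple[float, ...]
    results: tuple[CEAResult, ...]

    @property
    def icers(self) -> tuple[float, ...]:
        return tuple(icer_value(r) for r in self.results)


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    low: float
    high: float
    icer_low: float
    icer_high: float

    @property
    def span(self) -> float:
        return abs(self.icer_high - self.icer_low)

    @property
    def rankable(self) -> bool:
        """Whether the entry can be drawn as an ICER bar.

        A bound that drives the comparison out of the positive-gain
        quadrant (no life-year gain at extra cost) has no ICER — the point
        is dominated — so the parameter has no well-defined ICER range.
        """
        return math.isfinite(self.icer_low) and math.isfinite(self.icer_high)


@dataclass(frozen=True)
class ThresholdResult:
    parameter: str
    wtp: float
    value: float | None
    crossed: bool


def _check_name(name: str) -> None:
    if name not in SPECS_BY_NAME and name not in DERIVED_PARAMETERS:
        raise ParameterError(f"unknown parameter: {name}")


def one_way(params: ParameterSet, name: str, low: float, high: float,
            steps: int = 21, include_base: bool = True) -> OneWayCurve:
    """Rebuild and roll back the model over a grid of one parameter.

    The base value is spliced into the grid (so the curve always contains
    the exact base-case point) unless ``include_base`` is false.
    """
    _check_name(name)
    if low > high:
        raise ParameterError(f"one_way: low {low} > high {high}")
    if steps < 1:
        raise ParameterError("one_way: steps must be >= 1")
    if low == high:
        grid = [low]
    else:
        grid = list(np.linspace(low, high, steps))
    if include_base and name in SPECS_BY_NAME:
        base = params[name]
        if low <= base <= high and base not in grid:
            grid = sorted(grid + [base])
    results = tuple(evaluate(set_parameter(params, name, v)) for v in grid)
    return OneWayCurve(name, tuple(grid), results)


def tornado(params: ParameterSet, names=None) -> list[TornadoEntry]:
    """ICER at both DSA bounds per parameter, sorted by descending span.

    Entries whose range drives the comparison into dominance at either
    bound (infinite endpoint, no drawable ICER bar) are flagged via
    :attr:`TornadoEntry.rankable` and listed after the rankable bars.
    """
    if names is None:
        names = [s.name for s in SPECS_BY_NAME.values() if s.has_range]
    entries = []
    for name in names:
        _check_name(name)
        spec = SPECS_BY_NAME.get(name)
        if spec is None or spec.low is None or spec.high is None:
            raise ParameterError(f"{name} has no declared sensitivity range")
        lo = icer_value(evaluate(set_parameter(params, name, spec.low)))
        hi = icer_value(evaluate(set_parameter(params, name, spec.high)))
        entries.append(TornadoEntry(name, spec.low, spec.high, lo, hi))
    entries.sort(
        key=lambda e: (not e.rankable, -e.span if e.rankable else 0.0)
    )
    return entries


def threshold(params: ParameterSet, name: str, wtp: float,
              bracket: tuple[float, float], tol: float = 1e-4) -> ThresholdResult:
    """Bisection for the parameter value where the ICER crosses the WTP.

    Requires the sign of ``ICER − wtp`` to differ at the bracket ends
    (dominance scored as ±inf); returns a no-crossing result otherwise.
    """
    _check_name(name)
    lo, hi = bracket

    def excess(x: float) -> float:
        return icer_value(evaluate(set_parameter(params, name, x))) - wtp

    f_lo, f_hi = excess(lo), excess(hi)
    if f_lo == 0.0:
        return ThresholdResult(name, wtp, lo, True)
    if f_hi == 0.0:
        return ThresholdResult(name, wtp, hi, True)
    if (f_lo > 0) == (f_hi > 0):
        return ThresholdResult(name, wtp, None, False)
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        f_mid = excess(mid)
        if f_mid == 0.0:
            return ThresholdResult(name, wtp, mid, True)
        if (f_mid > 0) == (f_lo > 0):
            lo, f_lo = mid, f_mid
        else:
            hi, f_hi = mid, f_mid
    return ThresholdResult(name, wtp, 0.5 * (lo + hi), True)


def two_way(params: ParameterSet, name1: str, grid1, name2: str, grid2):
    """Full-factorial CEAResult grid over two parameters.

    Returns a list of rows (one per ``grid1`` value) of CEAResults, row
    index varying ``name1`` and column index ``name2``.
    """
    _check_name(name1)
    _check_name(name2)
    matrix = []
    for v1 in grid1:
        p1 = set_parameter(params, name1, v1)
        matrix.append([evaluate(set_parameter(p1, name2, v2)) for v2 in grid2])
    return matrix
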