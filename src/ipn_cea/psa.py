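"""Probabilistic sensitivity analysis: second-order Monte Carlo + CEAC.

Distributions are moment-fit from the deterministic inputs: every
distribution's mean is the base-case value and its standard deviation is
half the deterministic sensitivity range, so the whole range lies within
two standard deviations.  Probabilities get beta distributions, costs get
gamma distributions, and multinomial rows (stage distributions, risk
stratification rows, biopsy outcome partitions) are drawn jointly from a
Dirichlet whose concentration is solved so the anchor component's
beta marginal has the target standard deviation.  Parameters flagged
``fixed`` (life-year payoffs, structural settings, clinical-decision
knobs) are held at base.

Each draw rebuilds and rolls back the full tree; cost-effectiveness
acceptability curves score draws by net monetary benefit on a
willingness-to-pay grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cea import net_monetary_benefit
from .parameters import GROUPS, PARAMETER_SPECS, ParameterError, ParameterSet
from .tree import StrategyResult, build_model, rollback

__all__ = [
    "FittedDistribution",
    "PSASample",
    "CEACCurve",
    "fit_beta",
    "fit_gamma",
    "fit_dirichlet",
    "build_distributions",
    "run_psa",
    "ceac",
    "ceac_crossing",
    "default_wtp_grid",
]


@dataclass(frozen=True)
class FittedDistribution:
    """Moment-fit sampling distribution (beta, gamma, or dirichlet)."""

    family: str
    params: tuple[float, ...]

    def sample(self, rng: np.random.Generator):
        if self.family == "beta":
            a, b = self.params
            return float(rng.beta(a, b))
        if self.family == "gamma":
            shape, rate = self.params
            return float(rng.gamma(shape, 1.0 / rate))
        if self.family == "dirichlet":
            return rng.dirichlet(np.asarray(self.params))
        raise ParameterError(f"unknown family: {self.family}")


def fit_beta(mean: float, sd: float) -> FittedDistribution:
    """Beta(α, β) with the given mean and standard deviation."""
    if not 0.0 < mean < 1.0:
        raise ParameterError(f"beta mean must be in (0, 1), got {mean}")
    if sd <= 0:
        raise ParameterError("beta sd must be positive")
    if sd * sd >= mean * (1.0 - mean):
        raise ParameterError(
            f"infeasible beta moments: sd^2 = {sd * sd:.6g} >= "
            f"mean(1-mean) = {mean * (1 - mean):.6g}"
        )
    nu = mean * (1.0 - mean) / (sd * sd) - 1.0
    return FittedDistribution("beta", (mean * nu, (1.0 - mean) * nu))


def fit_gamma(mean: float, sd: float) -> FittedDistribution:
    """Gamma(shape, rate) with the given mean and standard deviation."""
    if mean <= 0 or sd <= 0:
        raise ParameterError("gamma moments must be positive")
    shape = mean * mean / (sd * sd)
    rate = mean / (sd * sd)
    return FittedDistribution("gamma", (shape, rate))


def fit_dirichlet(means, anchor_sd: float, anchor_index: int = 0) -> FittedDistribution:
    """Dirichlet with given component means, moment-matched on one marginal.

    The concentration total ``c`` solves the anchor component's beta
    marginal (Beta(m·c, (1−m)·c)) for the target standard deviation; all
    concentrations are then ``meanᵢ·c``.
    """
    means = [float(m) for m in means]
    if abs(sum(means) - 1.0) > 1e-9:
        raise ParameterError(f"dirichlet means sum to {sum(means)}, not 1")
    m = means[anchor_index]
    if not 0.0 < m < 1.0:
        raise ParameterError("anchor mean must be in (0, 1)")
    if anchor_sd <= 0 or anchor_sd * anchor_sd >= m * (1.0 - m):
        raise ParameterError("infeasible anchor moments for dirichlet fit")
    c = m * (1.0 - m) / (anchor_sd * anchor_sd) - 1.0
    alphas = tuple(mi * c for mi in means)
    if any(a <= 0 for a in alphas):
        raise ParameterError("dirichlet concentrations must be positive")
    return FittedDistribution("dirichlet", alphas)


def _half_range(spec) -> float:
    return 0.5 * (spec.high - spec.low)


def build_distributions(params: ParameterSet) -> dict[str, FittedDistribution]:
    """Fit every sampled parameter/group; keys are names or group names."""
    dists: dict[str, FittedDistribution] = {}
    by_name = {s.name: s for s in PARAMETER_SPECS}
    for spec in PARAMETER_SPECS:
        if spec.group is not None or spec.psa_family == "fixed":
            continue
        base = params[spec.name]
        sd = _half_range(spec)
        if spec.psa_family == "beta":
            dists[spec.name] = fit_beta(base, sd)
        elif spec.psa_family == "gamma":
            dists[spec.name] = fit_gamma(base, sd)
        else:
            raise ParameterError(
                f"{spec.name}: unsupported PSA family {spec.psa_family}"
            )
    for group, members in GROUPS.items():
        anchor = by_name[members[0]]
        if not anchor.has_range:
            raise ParameterError(f"group {group}: anchor has no range")
        means = [params[m] for m in members]
        dists[group] = fit_dirichlet(means, _half_range(anchor), 0)
    return dists


@dataclass(frozen=True)
class PSASample:
    """One Monte Carlo draw: sampled inputs and both strategies' results."""

    index: int
    params: ParameterSet
    results: dict[str, StrategyResult]
    seed: int


def sample_parameter_set(params: ParameterSet,
                         dists: dict[str, FittedDistribution],
                         rng: np.random.Generator) -> ParameterSet:
    """One joint draw (independent across parameters/groups)."""
    values = dict(params.values)
    # deterministic iteration order => reproducible streams
    for spec in PARAMETER_SPECS:
        if spec.group is None and spec.name in dists:
            values[spec.name] = dists[spec.name].sample(rng)
    for group, members in GROUPS.items():
        row = dists[group].sample(rng)
        for m, v in zip(members, row):
            values[m] = float(v)
    return ParameterSet(values, seed=params.seed)


def run_psa(params: ParameterSet, n_draws: int, seed: int) -> list[PSASample]:
    """Second-order Monte Carlo: sample, rebuild, roll back, repeat."""
    if n_draws < 0:
        raise ParameterError("n_draws must be nonnegative")
    dists = build_distributions(params)  # fit failures surface before sampling
    rng = np.random.default_rng(seed)
    samples = []
    for i in range(n_draws):
        drawn = sample_parameter_set(params, dists, rng)
        samples.append(PSASample(i, drawn, rollback(build_model(drawn)), seed))
    return samples


@dataclass(frozen=True)
class CEACCurve:
    """Acceptability fraction per strategy over a willingness-to-pay grid."""

    wtp: tuple[float, ...]
    ai_fraction: tuple[float, ...]

    @property
    def clinician_fraction(self) -> tuple[float, ...]:
        return tuple(1.0 - f for f in self.ai_fraction)


def default_wtp_grid(wtp_max: float = 200_000.0, step: float = 1_000.0):
    return tuple(np.arange(0.0, wtp_max + 0.5 * step, step))


def ceac(samples: list[PSASample], wtp_grid) -> CEACCurve:
    """Fraction of draws preferring AI at each threshold (ties split evenly)."""
    if not samples:
        raise ParameterError("CEAC requires at least one PSA sample")
    fractions = []
    for wtp in wtp_grid:
        score = 0.0
        for s in samples:
            nmb_ai = net_monetary_benefit(s.results["ai_assisted"], wtp)
            nmb_cl = net_monetary_benefit(s.results["clinician"], wtp)
            if nmb_ai > nmb_cl:
                score += 1.0
            elif nmb_ai == nmb_cl:
                score += 0.5
        fractions.append(score / len(samples))
    return CEACCurve(tuple(float(w) for w in wtp_grid), tuple(fractions))


def ceac_crossing(curve: CEACCurve) -> float | None:
    """WTP at the AI fraction's first upward crossing of 0.5 (interpolated)."""
    for (w0, f0), (w1, f1) in zip(
        zip(curve.wtp, curve.ai_fraction),
        zip(curve.wtp[1:], curve.ai_fraction[1:]),
    ):
        if f0 < 0.5 <= f1:
            if f1 == f0:
                return w1
            return w0 + (0.5 - f0) * (w1 - w0) / (f1 - f0)
        if f0 == 0.5:
            return w0
    return None
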