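"""Model inputs: base-case values, deterministic-sensitivity ranges, PSA families.

Every input of the decision model lives here as a :class:`ParameterSpec` —
its base-case value, the range explored in deterministic sensitivity
analysis (DSA), and the distribution family used in probabilistic
sensitivity analysis (PSA).  Multinomial blocks (risk-stratification rows,
stage distributions, biopsy outcome partitions) are registered as *groups*:
varying one component proportionally renormalizes its complements so every
row keeps summing to one.

The packaged defaults describe the reference scenario: a 1.1 cm
incidentally discovered indeterminate pulmonary nodule in a 60-year-old
operative candidate, evaluated in a clinic population with 65% malignancy
prevalence, costs in 2021 USD from the payer perspective.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import yaml

__all__ = [
    "ParameterSpec",
    "ParameterSet",
    "ParameterError",
    "STRATEGIES",
    "TRUTHS",
    "RISK_CLASSES",
    "PARAMETER_SPECS",
    "GROUPS",
    "default_parameters",
    "load_parameters",
    "serialize",
    "renormalize_complement",
]

STRATEGIES = ("clinician", "ai_assisted")
TRUTHS = ("malignant", "benign")
RISK_CLASSES = ("high", "intermediate", "low")


class ParameterError(ValueError):
    """Raised for invalid, unknown, or out-of-range model inputs."""


@dataclass(frozen=True)
class ParameterSpec:
    """One model input: base value, DSA range, and PSA family.

    ``psa_family`` is one of ``beta`` (probabilities), ``gamma`` (costs),
    ``dirichlet-component`` (member of a jointly-sampled multinomial row),
    or ``fixed`` (held at base in PSA).  Components whose DSA range is
    induced by their complements carry ``low = high = None``.
    """

    name: str
    base: float
    low: float | None
    high: float | None
    psa_family: str
    group: str | None = None
    source: str = ""

    def __post_init__(self) -> None:
        if self.low is not None and self.high is not None:
            if not (self.low <= self.base <= self.high):
                raise ParameterError(
                    f"{self.name}: base {self.base} outside range "
                    f"[{self.low}, {self.high}]"
                )

    @property
    def has_range(self) -> bool:
        return self.low is not None and self.high is not None and self.low < self.high


def _p(name, base, low, high, family, group=None, source=""):
    return ParameterSpec(name, base, low, high, family, group, source)


# Table-derived inputs.  Probabilities are unitless, costs are 2021 USD,
# life years are discounted at the structural discount rate.
PARAMETER_SPECS: tuple[ParameterSpec, ...] = (
    # -- probabilities ----------------------------------------------------
    _p("malignancy_prevalence", 0.65, 0.01, 0.80, "beta",
       source="nodule-clinic prevalence"),
    _p("lobectomy_mortality", 0.022, 0.01, 0.03, "beta", source="STS database"),
    _p("wedge_mortality", 0.0083, 0.005, 0.015, "beta", source="STS database"),
    _p("benign_growth", 0.1, 0.08, 0.12, "beta",
       source="benign nodule growth on surveillance"),
    _p("pet_avid_malignant", 0.89, 0.85, 0.92, "beta", source="PET meta-analysis"),
    _p("pet_avid_benign", 0.23, 0.19, 0.51, "beta", source="PET meta-analysis"),
    _p("biopsy_diagnostic_benign", 0.56, 0.45, 0.67, "dirichlet-component",
       group="biopsy_benign", source="non-surgical biopsy registry"),
    _p("biopsy_nondiagnostic_benign", 0.44, None, None, "dirichlet-component",
       group="biopsy_benign", source="complement"),
    _p("biopsy_diagnostic_malignant", 0.92, 0.74, 1.0, "dirichlet-component",
       group="biopsy_malignant", source="non-surgical biopsy registry"),
    _p("biopsy_false_negative_malignant", 0.037, 0.03, 0.044, "dirichlet-component",
       group="biopsy_malignant", source="non-surgical biopsy registry"),
    _p("biopsy_nondiagnostic_malignant", 0.043, None, None, "dirichlet-component",
       group="biopsy_malignant", source="complement"),
    _p("progression_unresectable", 0.04, 0.02, 0.06, "beta",
       source="delayed-resection outcomes model"),
    _p("unresectable_iii", 0.5, 0.2, 0.8, "dirichlet-component",
       group="unresectable_split", source="delayed-resection outcomes model"),
    _p("unresectable_iv", 0.5, None, None, "dirichlet-component",
       group="unresectable_split", source="complement"),
    # clinical-decision knobs: no literature base value, varied 0-1 in DSA
    _p("p_intermediate_pet", 0.5, 0.0, 1.0, "fixed",
       source="clinician/patient preference"),
    _p("p_surgical_biopsy", 0.5, 0.0, 1.0, "fixed",
       source="practice variation after non-diagnostic biopsy"),
    # -- stage distributions ---------------------------------------------
    _p("stage_immediate_i", 0.75, 0.60, 0.82, "dirichlet-component",
       group="stage_immediate", source="resection stage distribution"),
    _p("stage_immediate_ii", 0.17, 0.14, 0.20, "dirichlet-component",
       group="stage_immediate"),
    _p("stage_immediate_iii", 0.08, None, None, "dirichlet-component",
       group="stage_immediate", source="complement"),
    _p("stage_delayed_i", 0.72, 0.58, 0.75, "dirichlet-component",
       group="stage_delayed", source="delayed-resection stage distribution"),
    _p("stage_delayed_ii", 0.19, 0.15, 0.23, "dirichlet-component",
       group="stage_delayed"),
    _p("stage_delayed_iii", 0.09, None, None, "dirichlet-component",
       group="stage_delayed", source="complement"),
    # -- risk stratification (12-reader study frequencies) ----------------
    _p("strat_clinician_malignant_high", 0.47, 0.20, 0.58, "dirichlet-component",
       group="strat_clinician_malignant", source="12-reader study"),
    _p("strat_clinician_malignant_intermediate", 0.43, None, None,
       "dirichlet-component", group="strat_clinician_malignant",
       source="complement"),
    _p("strat_clinician_malignant_low", 0.10, 0.01, 0.27, "dirichlet-component",
       group="strat_clinician_malignant", source="12-reader study"),
    _p("strat_clinician_benign_high", 0.11, 0.02, 0.50, "dirichlet-component",
       group="strat_clinician_benign", source="12-reader study"),
    _p("strat_clinician_benign_intermediate", 0.39, None, None,
       "dirichlet-component", group="strat_clinician_benign",
       source="complement"),
    _p("strat_clinician_benign_low", 0.50, 0.18, 0.71, "dirichlet-component",
       group="strat_clinician_benign", source="12-reader study"),
    _p("strat_ai_assisted_malignant_high", 0.60, 0.45, 0.75, "dirichlet-component",
       group="strat_ai_assisted_malignant", source="12-reader study"),
    _p("strat_ai_assisted_malignant_intermediate", 0.35, None, None,
       "dirichlet-component", group="strat_ai_assisted_malignant",
       source="complement"),
    _p("strat_ai_assisted_malignant_low", 0.05, 0.02, 0.08, "dirichlet-component",
       group="strat_ai_assisted_malignant", source="12-reader study"),
    _p("strat_ai_assisted_benign_high", 0.09, 0.04, 0.15, "dirichlet-component",
       group="strat_ai_assisted_benign", source="12-reader study"),
    _p("strat_ai_assisted_benign_intermediate", 0.37, None, None,
       "dirichlet-component", group="strat_ai_assisted_benign",
       source="complement"),
    _p("strat_ai_assisted_benign_low", 0.54, 0.36, 0.73, "dirichlet-component",
       group="strat_ai_assisted_benign", source="12-reader study"),
    # -- life years (discounted terminal payoffs; fixed in PSA) -----------
    _p("ly_benign", 16.44, 13.15, 19.73, "fixed", source="NVSS life tables, DEALE"),
    _p("ly_stage_i", 16.32, 13.06, 16.44, "fixed", source="IASLC, DEALE"),
    _p("ly_stage_ii", 8.42, 6.74, 10.1, "fixed", source="IASLC, DEALE"),
    _p("ly_stage_iii_resectable", 5.04, 4.03, 6.05, "fixed", source="IASLC, DEALE"),
    _p("ly_stage_iii_unresectable", 3.84, 3.07, 4.61, "fixed",
       source="IASLC, DEALE"),
    _p("ly_stage_iv", 3.34, 2.67, 3.84, "fixed", source="IASLC, DEALE"),
    # -- one-time costs (2021 USD) ----------------------------------------
    _p("cost_biopsy", 2550.0, 2040.0, 3060.0, "gamma",
       source="CPT 31628, 32408; DRG 200, 201"),
    _p("cost_pet", 1480.0, 1184.0, 1776.0, "gamma", source="APC 5594"),
    _p("cost_surveillance_growth", 163.0, 130.0, 196.0, "gamma",
       source="CPT 71250 (one CT)"),
    _p("cost_surveillance_stable", 652.0, 326.0, 815.0, "gamma",
       source="CPT 71250 (four CTs)"),
    _p("cost_ai", 650.0, 100.0, 1200.0, "gamma", source="CPT 0721T"),
    _p("cost_wedge", 8821.0, 7057.0, 10585.0, "gamma", source="DRG 166, 168"),
    _p("cost_lobectomy", 12944.0, 10355.0, 15533.0, "gamma",
       source="DRG 163, 165"),
    _p("cost_adjuvant", 200446.0, 160357.0, 240535.0, "gamma",
       source="regimen table, stage II-IIIA"),
    _p("cost_unresectable_iii_chemo", 193426.0, 154741.0, 232111.0, "gamma",
       source="regimen table, unresectable III"),
    _p("cost_stage_iv_chemo", 421376.0, 337101.0, 505651.0, "gamma",
       source="regimen table, stage IV"),
    _p("cost_stage_iii_xrt", 166933.0, 133546.0, 200320.0, "gamma",
       source="IMRT CPT bundle"),
    _p("cost_unrelated_under_65", 9056.0, 7245.0, 10867.0, "gamma",
       source="MEPS annual medical cost, age < 65"),
    _p("cost_unrelated_over_65", 12961.0, 10369.0, 15553.0, "gamma",
       source="MEPS annual medical cost, age > 65"),
    # -- structural settings (never sampled) -------------------------------
    _p("discount_rate", 0.03, 0.03, 0.03, "fixed", source="annual discount rate"),
    _p("base_age", 60.0, 60.0, 60.0, "fixed"),
    _p("crossover_age", 65.0, 65.0, 65.0, "fixed",
       source="unrelated-cost age bracket boundary"),
    _p("wtp", 100000.0, 100000.0, 100000.0, "fixed",
       source="willingness-to-pay per life year gained"),
    _p("psa_draws", 400.0, 400.0, 400.0, "fixed"),
)

SPECS_BY_NAME: dict[str, ParameterSpec] = {s.name: s for s in PARAMETER_SPECS}

# Multinomial groups, in component order (first component is the PSA anchor).
GROUPS: dict[str, tuple[str, ...]] = {}
for _spec in PARAMETER_SPECS:
    if _spec.group is not None:
        GROUPS.setdefault(_spec.group, ())
        GROUPS[_spec.group] = GROUPS[_spec.group] + (_spec.name,)

_PROBABILITY_PREFIXES = ("strat_", "stage_", "biopsy_", "pet_avid", "p_")
_PROBABILITY_NAMES = frozenset(
    s.name
    for s in PARAMETER_SPECS
    if s.name.startswith(_PROBABILITY_PREFIXES)
    or s.name in (
        "malignancy_prevalence", "lobectomy_mortality", "wedge_mortality",
        "benign_growth", "progression_unresectable", "unresectable_iii",
        "unresectable_iv", "discount_rate",
    )
)


def renormalize_complement(values, varied_index, new_value):
    """Set one component of a probability vector, rescaling the rest.

    The remaining components keep their relative proportions and are scaled
    so the vector sums to one again.  Fails when the complement carries no
    mass to redistribute while ``new_value`` < 1.
    """
    values = [float(v) for v in values]
    if not 0.0 <= new_value <= 1.0:
        raise ParameterError(f"new value {new_value} outside [0, 1]")
    if abs(sum(values) - 1.0) > 1e-9:
        raise ParameterError(f"input vector sums to {sum(values)}, not 1")
    rest = [v for i, v in enumerate(values) if i != varied_index]
    rest_sum = sum(rest)
    remaining = 1.0 - new_value
    if rest_sum <= 0.0:
        if remaining > 1e-12:
            raise ParameterError(
                "cannot redistribute: complement components are all zero"
            )
        scale = 0.0
    else:
        scale = remaining / rest_sum
    out = []
    for i, v in enumerate(values):
        out.append(new_value if i == varied_index else v * scale)
    return out


class ParameterSet:
    """Validated, immutable-by-convention collection of model inputs.

    Construct via :func:`default_parameters` or :func:`load_parameters`;
    derive perturbed sets with :meth:`with_value` (which renormalizes
    multinomial complements) rather than mutating ``values``.
    """

    def __init__(self, values: Mapping[str, float], seed: int | None = None,
                 validate: bool = True):
        unknown = set(values) - set(SPECS_BY_NAME)
        if unknown:
            raise ParameterError(f"unknown parameter(s): {sorted(unknown)}")
        missing = set(SPECS_BY_NAME) - set(values)
        if missing:
            raise ParameterError(f"missing parameter(s): {sorted(missing)}")
        self.values: dict[str, float] = {k: float(values[k]) for k in SPECS_BY_NAME}
        self.seed = seed
        if validate:
            self.validate()

    # -- access -----------------------------------------------------------
    def __getitem__(self, name: str) -> float:
        try:
            return self.values[name]
        except KeyError:
            raise ParameterError(f"unknown parameter: {name}") from None

    get = __getitem__

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, ParameterSet)
            and self.values == other.values
            and self.seed == other.seed
        )

    def __repr__(self) -> str:
        return f"ParameterSet({len(self.values)} parameters, seed={self.seed})"

    def strat_row(self, strategy: str, truth: str) -> tuple[float, float, float]:
        """(high, intermediate, low) assignment probabilities."""
        if strategy not in STRATEGIES:
            raise ParameterError(f"unknown strategy: {strategy}")
        if truth not in TRUTHS:
            raise ParameterError(f"unknown truth state: {truth}")
        return tuple(
            self.values[f"strat_{strategy}_{truth}_{c}"] for c in RISK_CLASSES
        )

    def stratification_matrix(self) -> dict[tuple[str, str], tuple[float, ...]]:
        return {
            (s, t): self.strat_row(s, t) for s in STRATEGIES for t in TRUTHS
        }

    def stage_distribution(self, context: str) -> tuple[float, float, float]:
        """Stage I/II/III weights for ``immediate`` or ``delayed`` resection."""
        if context not in ("immediate", "delayed"):
            raise ParameterError(f"unknown resection context: {context}")
        return tuple(self.values[f"stage_{context}_{s}"] for s in ("i", "ii", "iii"))

    # -- derivation -------------------------------------------------------
    def with_value(self, name: str, value: float) -> "ParameterSet":
        """New set with ``name`` set to ``value``.

        Multinomial group members trigger proportional renormalization of
        their complements; all other parameters are set directly.
        """
        spec = SPECS_BY_NAME.get(name)
        if spec is None:
            raise ParameterError(f"unknown parameter: {name}")
        new = dict(self.values)
        if spec.group is not None:
            members = GROUPS[spec.group]
            idx = members.index(name)
            row = [self.values[m] for m in members]
            row = renormalize_complement(row, idx, value)
            for m, v in zip(members, row):
                new[m] = v
        else:
            new[name] = float(value)
        return ParameterSet(new, seed=self.seed)

    def with_stratification(
        self, strategy: str, rows: Mapping[str, Iterable[float]]
    ) -> "ParameterSet":
        """Replace whole stratification rows, e.g. from a reader study."""
        new = dict(self.values)
        for truth, row in rows.items():
            row = [float(v) for v in row]
            if truth not in TRUTHS:
                raise ParameterError(f"unknown truth state: {truth}")
            if len(row) != 3 or abs(sum(row) - 1.0) > 1e-9:
                raise ParameterError(
                    f"stratification row for {strategy}/{truth} must have 3 "
                    f"entries summing to 1, got {row}"
                )
            for c, v in zip(RISK_CLASSES, row):
                new[f"strat_{strategy}_{truth}_{c}"] = v
        return ParameterSet(new, seed=self.seed)

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        for name, v in self.values.items():
            if name in _PROBABILITY_NAMES:
                if not 0.0 <= v <= 1.0:
                    raise ParameterError(f"{name} = {v} outside [0, 1]")
            elif v < 0.0:
                raise ParameterError(f"{name} = {v} must be nonnegative")
        for group, members in GROUPS.items():
            total = sum(self.values[m] for m in members)
            if abs(total - 1.0) > 1e-9:
                raise ParameterError(
                    f"group {group} sums to {total:.12f}, expected 1"
                )

    # -- serialization ----------------------------------------------------
    def to_config(self) -> dict:
        """Nested config document (round-trips through load_parameters)."""
        cfg: dict = {
            "probabilities": {}, "stratification": {}, "stage_distributions": {},
            "life_years": {}, "costs": {}, "structure": {},
        }
        for s in STRATEGIES:
            cfg["stratification"][s] = {
                t: dict(zip(RISK_CLASSES, self.strat_row(s, t))) for t in TRUTHS
            }
        for ctx in ("immediate", "delayed"):
            cfg["stage_distributions"][ctx] = dict(
                zip(("i", "ii", "iii"), self.stage_distribution(ctx))
            )
        for name, v in self.values.items():
            if name.startswith(("strat_", "stage_")):
                continue
            if name.startswith("ly_"):
                cfg["life_years"][name[3:]] = v
            elif name.startswith("cost_"):
                cfg["costs"][name[5:]] = v
            elif name in _STRUCTURE_NAMES:
                cfg["structure"][name] = v
            else:
                cfg["probabilities"][name] = v
        if self.seed is not None:
            cfg["structure"]["seed"] = self.seed
        return cfg

    def digest(self) -> str:
        """Stable sha256 over the config document (for run manifests)."""
        payload = json.dumps(self.to_config(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()


_STRUCTURE_NAMES = ("discount_rate", "base_age", "crossover_age", "wtp",
                    "psa_draws")


def default_parameters() -> ParameterSet:
    """The packaged base case."""
    return ParameterSet({s.name: s.base for s in PARAMETER_SPECS})


def _flatten_config(cfg: Mapping) -> tuple[dict[str, float], int | None]:
    """Sectioned (or flat) config -> flat overrides; rejects unknown keys."""
    flat: dict[str, float] = {}
    seed: int | None = None

    def put(name: str, value, where: str) -> None:
        if name not in SPECS_BY_NAME:
            raise ParameterError(f"unknown key '{name}' in {where}")
        if not isinstance(value, (int, float)) or isinstance(value, bool):
            raise ParameterError(f"{where}/{name}: expected a number, got {value!r}")
        flat[name] = float(value)

    for key, section in cfg.items():
        if key == "probabilities":
            for k, v in section.items():
                put(k, v, "probabilities")
        elif key == "stratification":
            for strategy, truths in section.items():
                if strategy not in STRATEGIES:
                    raise ParameterError(f"unknown strategy '{strategy}'")
                for truth, row in truths.items():
                    if truth not in TRUTHS:
                        raise ParameterError(f"unknown truth state '{truth}'")
                    for cls, v in row.items():
                        if cls not in RISK_CLASSES:
                            raise ParameterError(f"unknown risk class '{cls}'")
                        put(f"strat_{strategy}_{truth}_{cls}", v, "stratification")
        elif key == "stage_distributions":
            for ctx, dist in section.items():
                if ctx not in ("immediate", "delayed"):
                    raise ParameterError(f"unknown resection context '{ctx}'")
                for stage, v in dist.items():
                    if stage not in ("i", "ii", "iii"):
                        raise ParameterError(f"unknown stage '{stage}'")
                    put(f"stage_{ctx}_{stage}", v, "stage_distributions")
        elif key == "life_years":
            for k, v in section.items():
                put(f"ly_{k}", v, "life_years")
        elif key == "costs":
            for k, v in section.items():
                put(f"cost_{k}", v, "costs")
        elif key == "structure":
            for k, v in section.items():
                if k == "seed":
                    if v is not None and (not isinstance(v, int) or isinstance(v, bool)):
                        raise ParameterError("structure/seed must be an integer")
                    seed = v
                else:
                    put(k, v, "structure")
        elif key in SPECS_BY_NAME:
            put(key, cfg[key], "top level")
        else:
            raise ParameterError(f"unknown config key '{key}'")
    return flat, seed


def load_parameters(source=None) -> ParameterSet:
    """Load a config document, falling back to packaged defaults.

    ``source`` may be None (pure defaults), a mapping, or a path to a
    JSON/YAML file.  Unknown keys are rejected with the offending key named.
    Overriding a single member of a multinomial group renormalizes its
    complements; overriding a whole row uses the row as given.
    """
    if source is None:
        return default_parameters()
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
        doc = yaml.safe_load(text)  # YAML superset handles JSON too
        if doc is None:
            doc = {}
        if not isinstance(doc, Mapping):
            raise ParameterError("config document must be a mapping")
        return load_parameters(doc)
    if not isinstance(source, Mapping):
        raise ParameterError(f"cannot load parameters from {type(source)!r}")

    flat, seed = _flatten_config(source)
    values = {s.name: s.base for s in PARAMETER_SPECS}

    # whole groups given explicitly are taken verbatim; partial overrides
    # renormalize the untouched complements
    handled: set[str] = set()
    for group, members in GROUPS.items():
        given = [m for m in members if m in flat]
        if not given:
            continue
        if len(given) == len(members):
            for m in members:
                values[m] = flat[m]
        else:
            row = [values[m] for m in members]
            for m in given:
                row = renormalize_complement(row, members.index(m), flat[m])
            for m, v in zip(members, row):
                values[m] = v
        handled.update(members)
    for name, v in flat.items():
        if name not in handled:
            values[name] = v
    return ParameterSet(values, seed=seed)


def serialize(params: ParameterSet, path=None, fmt: str | None = None):
    """Write (or return) the config document for a ParameterSet."""
    cfg = params.to_config()
    if path is None:
        return cfg
    path = Path(path)
    fmt = fmt or ("json" if path.suffix == ".json" else "yaml")
    if fmt == "json":
        path.write_text(json.dumps(cfg, indent=2, sort_keys=True))
    else:
        path.write_text(yaml.safe_dump(cfg, sort_keys=True))
    return cfg
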