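"""Decision tree over guideline-based nodule workup, with rollback.

The tree compares two strategies for the initial risk stratification of an
indeterminate pulmonary nodule — clinician alone versus clinician with AI
assistance — and then follows identical guideline-based management:

* high risk      -> diagnostic wedge resection with frozen section;
                    malignant nodules continue to lobectomy in the same
                    operation (immediate stage distribution)
* intermediate   -> PET or non-surgical biopsy (clinical-decision split);
                    PET-avid nodules go to surgical biopsy (wedge), non-avid
                    nodules to surveillance; biopsies are diagnostic,
                    falsely negative, or non-diagnostic, the latter routed
                    to surgical biopsy or surveillance
* low risk       -> CT surveillance; all malignant nodules eventually grow
                    and progress to lobectomy with a delayed (shifted) stage
                    distribution, or become unresectable

Chance nodes carry branch probabilities; one-time costs accrue on the node
where they are incurred; terminals carry the stage-specific treatment cost,
unrelated annual medical costs over survival, and discounted life years.
Operative deaths score zero life years.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .outcomes import Payoff, terminal_cost
from .parameters import ParameterSet, STRATEGIES

__all__ = [
    "Node",
    "StrategyResult",
    "PathRecord",
    "TreeError",
    "build_model",
    "rollback",
    "enumerate_paths",
    "export_tree",
]

_PROB_TOL = 1e-9


class TreeError(ValueError):
    """Structural defect in a decision tree."""


@dataclass
class Node:
    """Decision, chance, or terminal node.

    ``branches`` holds ``(probability, child)`` pairs for chance nodes and
    ``(choice_label, child)`` pairs for decision nodes.  ``cost`` is the
    one-time cost accrued when a path passes through this node.
    """

    kind: str
    label: str
    branches: list = field(default_factory=list)
    payoff: Payoff | None = None
    cost: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("decision", "chance", "terminal"):
            raise TreeError(f"unknown node kind: {self.kind}")
        if self.kind == "terminal":
            if self.branches:
                raise TreeError(f"terminal node {self.label} has branches")
            if self.payoff is None:
                raise TreeError(f"terminal node {self.label} lacks a payoff")
        if self.cost < 0:
            raise TreeError(f"negative accrued cost at {self.label}")


@dataclass(frozen=True)
class StrategyResult:
    """Expected discounted cost and life years for one strategy."""

    strategy: str
    cost: float
    effect: float


@dataclass(frozen=True)
class PathRecord:
    """One root-to-terminal path: labels, probability, cost, effect."""

    strategy: str
    labels: tuple[str, ...]
    probability: float
    cost: float
    effect: float


# ---------------------------------------------------------------------------
# construction


def _require(params: ParameterSet, name: str) -> float:
    try:
        return params[name]
    except Exception as exc:  # surface the missing key by name
        raise TreeError(f"missing model parameter: {name}") from exc


def _death(label: str) -> Node:
    # procedure costs were accrued on the way in; life years are zero
    return Node("terminal", label, payoff=Payoff(0.0, 0.0))


def _benign_terminal(p: ParameterSet, label: str, extra_cost: float = 0.0) -> Node:
    ly = _require(p, "ly_benign")
    return Node("terminal", label, payoff=Payoff(terminal_cost(p, ly), ly),
                cost=extra_cost)


_STAGE_PAYOFFS = {
    # resected disease: (life-year key, treatment-cost key or None)
    "i": ("ly_stage_i", None),
    "ii": ("ly_stage_ii", "cost_adjuvant"),
    "iii": ("ly_stage_iii_resectable", "cost_adjuvant"),
}


def _stage_terminal(p: ParameterSet, stage: str, context: str) -> Node:
    ly_key, cost_key = _STAGE_PAYOFFS[stage]
    ly = _require(p, ly_key)
    treatment = _require(p, cost_key) if cost_key else 0.0
    return Node(
        "terminal", f"stage_{stage}_{context}",
        payoff=Payoff(terminal_cost(p, ly, treatment), ly),
    )


def _stage_chance(p: ParameterSet, context: str) -> Node:
    weights = p.stage_distribution(context)
    return Node("chance", f"pathologic_stage_{context}", [
        (weights[0], _stage_terminal(p, "i", context)),
        (weights[1], _stage_terminal(p, "ii", context)),
        (weights[2], _stage_terminal(p, "iii", context)),
    ])


def _lobectomy(p: ParameterSet, context: str) -> Node:
    """Definitive lobectomy; operative death or stage-specific outcome."""
    mort = _require(p, "lobectomy_mortality")
    return Node("chance", f"lobectomy_{context}", [
        (mort, _death("lobectomy_death")),
        (1.0 - mort, _stage_chance(p, context)),
    ], cost=_require(p, "cost_lobectomy"))


def _wedge(p: ParameterSet, truth: str, context: str = "immediate") -> Node:
    """Diagnostic wedge resection with frozen-section analysis.

    Benign nodules are operatively complete after the wedge and bill the
    wedge DRG.  Malignant nodules continue to lobectomy in the same
    operation: one anesthetic, one inpatient admission, so the stay is
    reimbursed under the lobectomy DRG alone and carries lobectomy
    mortality (the dominant operative risk).
    """
    if truth == "benign":
        mort = _require(p, "wedge_mortality")
        return Node("chance", "wedge_resection", [
            (mort, _death("wedge_death")),
            (1.0 - mort, _benign_terminal(p, "benign_wedge_confirmed")),
        ], cost=_require(p, "cost_wedge"))
    mort = _require(p, "lobectomy_mortality")
    return Node("chance", "wedge_then_lobectomy", [
        (mort, _death("lobectomy_death")),
        (1.0 - mort, _stage_chance(p, context)),
    ], cost=_require(p, "cost_lobectomy"))


def _unresectable(p: ParameterSet) -> Node:
    ly3 = _require(p, "ly_stage_iii_unresectable")
    ly4 = _require(p, "ly_stage_iv")
    chemo3 = _require(p, "cost_unresectable_iii_chemo")
    xrt = _require(p, "cost_stage_iii_xrt")
    chemo4 = _require(p, "cost_stage_iv_chemo")
    return Node("chance", "unresectable_stage", [
        (_require(p, "unresectable_iii"),
         Node("terminal", "stage_iii_unresectable",
              payoff=Payoff(terminal_cost(p, ly3, chemo3 + xrt), ly3))),
        (_require(p, "unresectable_iv"),
         Node("terminal", "stage_iv",
              payoff=Payoff(terminal_cost(p, ly4, chemo4), ly4))),
    ])


def _surveillance(p: ParameterSet, truth: str) -> Node:
    """CT surveillance; malignant nodules all eventually grow."""
    if truth == "benign":
        growth = _require(p, "benign_growth")
        grown = _wedge(p, "benign")
        grown.cost += _require(p, "cost_surveillance_growth")
        return Node("chance", "surveillance_benign", [
            (growth, grown),
            (1.0 - growth,
             _benign_terminal(p, "benign_stable",
                              extra_cost=_require(p, "cost_surveillance_stable"))),
        ])
    prog = _require(p, "progression_unresectable")
    return Node("chance", "surveillance_malignant", [
        (prog, _unresectable(p)),
        (1.0 - prog, _lobectomy(p, "delayed")),
    ], cost=_require(p, "cost_surveillance_growth"))


def _biopsy(p: ParameterSet, truth: str) -> Node:
    """Non-surgical biopsy with truth-conditional diagnostic yield."""
    p_surg = _require(p, "p_surgical_biopsy")
    if truth == "malignant":
        nondx = Node("chance", "post_nondiagnostic", [
            (p_surg, _wedge(p, "malignant")),
            (1.0 - p_surg, _surveillance(p, "malignant")),
        ])
        return Node("chance", "biopsy_malignant", [
            (_require(p, "biopsy_diagnostic_malignant"), _lobectomy(p, "immediate")),
            (_require(p, "biopsy_false_negative_malignant"),
             _surveillance(p, "malignant")),
            (_require(p, "biopsy_nondiagnostic_malignant"), nondx),
        ], cost=_require(p, "cost_biopsy"))
    nondx = Node("chance", "post_nondiagnostic", [
        (p_surg, _wedge(p, "benign")),
        (1.0 - p_surg, _surveillance(p, "benign")),
    ])
    return Node("chance", "biopsy_benign", [
        (_require(p, "biopsy_diagnostic_benign"),
         _benign_terminal(p, "benign_biopsy_confirmed")),
        (_require(p, "biopsy_nondiagnostic_benign"), nondx),
    ], cost=_require(p, "cost_biopsy"))


def _pet(p: ParameterSet, truth: str) -> Node:
    avid = _require(p, f"pet_avid_{truth}")
    return Node("chance", f"pet_{truth}", [
        (avid, _wedge(p, truth)),
        (1.0 - avid, _surveillance(p, truth)),
    ], cost=_require(p, "cost_pet"))


def _intermediate(p: ParameterSet, truth: str) -> Node:
    p_pet = _require(p, "p_intermediate_pet")
    return Node("chance", "intermediate_workup", [
        (p_pet, _pet(p, truth)),
        (1.0 - p_pet, _biopsy(p, truth)),
    ])


def _risk_class_node(p: ParameterSet, strategy: str, truth: str) -> Node:
    high, intermediate, low = p.strat_row(strategy, truth)
    return Node("chance", f"risk_class_{truth}", [
        (high, _wedge(p, truth)),
        (intermediate, _intermediate(p, truth)),
        (low, _surveillance(p, truth)),
    ])


def build_model(params: ParameterSet) -> Node:
    """Full two-strategy tree for the packaged (or perturbed) parameters.

    The AI arm accrues the AI-assistance fee once at its root; everything
    downstream differs between arms only through the stratification rows.
    """
    prevalence = _require(params, "malignancy_prevalence")
    arms = []
    for strategy in STRATEGIES:
        arm = Node("chance", f"{strategy}_truth", [
            (prevalence, _risk_class_node(params, strategy, "malignant")),
            (1.0 - prevalence, _risk_class_node(params, strategy, "benign")),
        ], cost=_require(params, "cost_ai") if strategy == "ai_assisted" else 0.0)
        arms.append((strategy, arm))
    return Node("decision", "stratification_strategy", arms)


# ---------------------------------------------------------------------------
# evaluation


def _expected_value(node: Node) -> tuple[float, float]:
    if node.kind == "terminal":
        return node.cost + node.payoff.cost, node.payoff.effect
    if node.kind == "decision":
        raise TreeError("decision nodes below the root are not supported")
    total_p = sum(prob for prob, _ in node.branches)
    if abs(total_p - 1.0) > _PROB_TOL:
        raise TreeError(
            f"chance node {node.label}: branch probabilities sum to {total_p!r}"
        )
    cost = node.cost
    effect = 0.0
    for prob, child in node.branches:
        if prob < -_PROB_TOL:
            raise TreeError(f"negative branch probability at {node.label}")
        c, e = _expected_value(child)
        cost += prob * c
        effect += prob * e
    return cost, effect


def rollback(root: Node) -> dict[str, StrategyResult]:
    """Expected cost/effect per strategy by bottom-up expectation."""
    if root.kind == "decision":
        out = {}
        for label, child in root.branches:
            cost, effect = _expected_value(child)
            cost += root.cost
            out[label] = StrategyResult(label, cost, effect)
        return out
    cost, effect = _expected_value(root)
    return {root.label: StrategyResult(root.label, cost, effect)}


def enumerate_paths(root: Node) -> list[PathRecord]:
    """Every root-to-terminal path with probability and accumulated cost.

    An independent audit surface: the probability-weighted sums over paths
    must reproduce :func:`rollback` exactly.
    """
    records: list[PathRecord] = []

    def walk(node, strategy, labels, prob, cost):
        labels = labels + (node.label,)
        cost += node.cost
        if node.kind == "terminal":
            records.append(PathRecord(strategy, labels, prob,
                                      cost + node.payoff.cost,
                                      node.payoff.effect))
            return
        if node.kind == "decision":
            for choice, child in node.branches:
                walk(child, choice, labels, prob, cost)
            return
        total_p = sum(p for p, _ in node.branches)
        if abs(total_p - 1.0) > _PROB_TOL:
            raise TreeError(
                f"chance node {node.label}: branch probabilities sum to {total_p!r}"
            )
        for p, child in node.branches:
            walk(child, strategy, labels, prob * p, cost)

    walk(root, root.label, (), 1.0, 0.0)
    return records


def export_tree(node: Node) -> dict:
    """Nested JSON-serializable view of the tree for audit."""
    out: dict = {"kind": node.kind, "label": node.label}
    if node.cost:
        out["cost"] = node.cost
    if node.kind == "terminal":
        out["payoff"] = {"cost": node.payoff.cost, "effect": node.payoff.effect}
    else:
        key = "choice" if node.kind == "decision" else "probability"
        out["branches"] = [
            {key: tag, "node": export_tree(child)} for tag, child in node.branches
        ]
    return out
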