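"""Tree structure, rollback, and the path-enumeration oracle."""

import random

import pytest

from ipn_cea.outcomes import Payoff
from ipn_cea.tree import (
    Node,
    TreeError,
    build_model,
    enumerate_paths,
    export_tree,
    rollback,
)

# fixed once at construction; a structural change to the tree must be
# deliberate enough to update this constant
EXPECTED_PATHS_PER_STRATEGY = 56


def _walk(node):
    yield node
    for _, child in node.branches:
        yield from _walk(child)


class TestStructure:
    def test_root_offers_both_strategies(self, params):
        root = build_model(params)
        assert root.kind == "decision"
        assert [label for label, _ in root.branches] == ["clinician", "ai_assisted"]

    def test_every_chance_node_is_normalized(self, params):
        for node in _walk(build_model(params)):
            if node.kind == "chance":
                total = sum(p for p, _ in node.branches)
                assert total == pytest.approx(1.0, abs=1e-9)

    def test_ai_fee_accrued_once_on_every_ai_path(self, params):
        # pair paths by label sequence below the strategy arm: identical
        # trees, so the cost difference is exactly the per-patient fee
        paths = enumerate_paths(build_model(params))
        by_strategy = {}
        for record in paths:
            by_strategy.setdefault(record.strategy, {})[record.labels[2:]] = record
        clin, ai = by_strategy["clinician"], by_strategy["ai_assisted"]
        assert set(clin) == set(ai)
        for key in clin:
            assert ai[key].cost - clin[key].cost == pytest.approx(650.0, abs=1e-9)

    def test_path_count_regression(self, params):
        paths = enumerate_paths(build_model(params))
        per_strategy = {}
        for r in paths:
            per_strategy[r.strategy] = per_strategy.get(r.strategy, 0) + 1
        assert per_strategy == {
            "clinician": EXPECTED_PATHS_PER_STRATEGY,
            "ai_assisted": EXPECTED_PATHS_PER_STRATEGY,
        }

    def test_missing_parameter_named(self, params):
        from ipn_cea.parameters import ParameterSet

        broken = ParameterSet.__new__(ParameterSet)  # bypass completeness check
        broken.values = {k: v for k, v in params.values.items() if k != "cost_pet"}
        broken.seed = None
        with pytest.raises(TreeError, match="cost_pet"):
            build_model(broken)

    def test_export_round_structure(self, params):
        exported = export_tree(build_model(params))
        assert exported["kind"] == "decision"
        assert len(exported["branches"]) == 2


class TestRollback:
    def test_single_terminal_identity(self):
        node = Node("terminal", "t", payoff=Payoff(10.0, 2.0))
        result = rollback(node)["t"]
        assert (result.cost, result.effect) == (10.0, 2.0)

    def test_two_branch_expectation(self):
        node = Node("chance", "c", [
            (0.5, Node("terminal", "a", payoff=Payoff(0.0, 4.0))),
            (0.5, Node("terminal", "b", payoff=Payoff(100.0, 2.0))),
        ])
        result = rollback(node)["c"]
        assert (result.cost, result.effect) == (50.0, 3.0)

    def test_probability_sum_violation_raises(self):
        node = Node("chance", "c", [
            (0.5, Node("terminal", "a", payoff=Payoff(0.0, 1.0))),
            (0.4, Node("terminal", "b", payoff=Payoff(0.0, 1.0))),
        ])
        with pytest.raises(TreeError, match="sum"):
            rollback(node)

    def test_effect_bounded_by_benign_payoff(self, params):
        for result in rollback(build_model(params)).values():
            assert result.effect <= params["ly_benign"]
            assert result.cost >= 0

    def test_prevalence_zero_reaches_only_benign_terminals(self, params):
        p0 = params.with_value("malignancy_prevalence", 0.0)
        for record in enumerate_paths(build_model(p0)):
            if record.probability > 0:
                assert record.labels[-1].startswith(("benign", "wedge_death"))

    def test_prevalence_one_starves_benign_terminals(self, params):
        p1 = params.with_value("malignancy_prevalence", 1.0)
        for record in enumerate_paths(build_model(p1)):
            if record.labels[-1].startswith("benign"):
                assert record.probability == 0.0

    def test_benign_only_favorable_extremes_hit_payoff_ceiling(self, params):
        ideal = params.with_value("malignancy_prevalence", 0.0).with_value(
            "wedge_mortality", 0.0
        )
        for result in rollback(build_model(ideal)).values():
            assert result.effect == pytest.approx(params["ly_benign"], abs=1e-12)

    def test_effect_monotone_nonincreasing_in_prevalence(self, params):
        effects = []
        for prevalence in [0.0, 0.2, 0.4, 0.6, 0.8, 1.0]:
            results = rollback(
                build_model(params.with_value("malignancy_prevalence", prevalence))
            )
            effects.append(results["clinician"].effect)
        assert effects == sorted(effects, reverse=True)


def _random_tree(rng, depth=0):
    if depth >= 4 or rng.random() < 0.35:
        return Node("terminal", f"t{rng.randrange(1_000_000)}",
                    payoff=Payoff(rng.uniform(0, 1e5), rng.uniform(0, 16)),
                    cost=rng.uniform(0, 500))
    n = rng.randint(2, 4)
    raw = [rng.random() + 1e-3 for _ in range(n)]
    total = sum(raw)
    return Node("chance", f"c{depth}", [
        (w / total, _random_tree(rng, depth + 1)) for w in raw
    ], cost=rng.uniform(0, 1000))


class TestPathOracle:
    def test_rollback_matches_path_sums_on_full_model(self, params):
        root = build_model(params)
        results = rollback(root)
        paths = enumerate_paths(root)
        for strategy, result in results.items():
            mine = [r for r in paths if r.strategy == strategy]
            assert sum(r.probability for r in mine) == pytest.approx(1.0, abs=1e-9)
            cost = sum(r.probability * r.cost for r in mine)
            effect = sum(r.probability * r.effect for r in mine)
            assert cost == pytest.approx(result.cost, abs=1e-9 * max(1, result.cost))
            assert effect == pytest.approx(result.effect, abs=1e-9)

    def test_rollback_matches_path_sums_on_random_trees(self):
        rng = random.Random(20210715)
        for _ in range(100):
            root = _random_tree(rng)
            result = list(rollback(root).values())[0]
            paths = enumerate_paths(root)
            cost = sum(r.probability * r.cost for r in paths)
            effect = sum(r.probability * r.effect for r in paths)
            assert cost == pytest.approx(result.cost, rel=1e-9, abs=1e-9)
            assert effect == pytest.approx(result.effect, rel=1e-9, abs=1e-9)

    def test_single_terminal_single_record(self):
        records = enumerate_paths(Node("terminal", "t", payoff=Payoff(1.0, 1.0)))
        assert len(records) == 1 and records[0].probability == 1.0


class TestStrategyContrast:
    def test_identical_matrices_leave_only_the_fee(self, params):
        rows = {
            "malignant": params.strat_row("clinician", "malignant"),
            "benign": params.strat_row("clinician", "benign"),
        }
        same = params.with_stratification("ai_assisted", rows)
        results = rollback(build_model(same))
        delta_cost = results["ai_assisted"].cost - results["clinician"].cost
        delta_effect = results["ai_assisted"].effect - results["clinician"].effect
        assert delta_effect == 0.0
        assert delta_cost == pytest.approx(650.0, abs=1e-9)
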