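"""Deterministic base-case pipeline tying schedules, the Markov engine
and the outcome measures together.

Two evaluation routes coexist and are both exposed:

* ``reference`` — the published base-case (cost, QALY) pairs, used for
  table reproduction, savings and frontier analysis.  Available for all
  strategies.
* ``model`` — schedule cost plus Markov-simulated effectiveness under
  the current parameter set.  Available for schedule-backed strategies
  (CEUS, Fukuoka).  Absolute simulated QALY levels are on the model's
  own scale (cycle-length calibration differs from the published one;
  see docs/methods.md) and are reported alongside, never mixed into the
  reference arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass

from .markov import LifeTable, simulate_strategy
from .outcomes import CEResult
from .parameters import SCENARIOS, ParamSet, ScenarioSpec
from .reference import SCHEDULE_BACKED, reference_row, strategies_for
from .schedules import StrategySchedule, build_schedule, schedule_cost


def _scenario(scenario: ScenarioSpec | str) -> ScenarioSpec:
    if isinstance(scenario, ScenarioSpec):
        return scenario
    try:
        return SCENARIOS[scenario]
    except KeyError:
        raise KeyError(
            f"unknown scenario {scenario!r}; known: {sorted(SCENARIOS)}"
        ) from None


def reference_results(
    scenario: ScenarioSpec | str, wtp: float = 30000.0
) -> list[CEResult]:
    """Published base-case CEResults for every strategy in a scenario,
    with incremental NHB computed against the CEUS strategy."""
    spec = _scenario(scenario)
    results = []
    for strategy_id in strategies_for(spec.scenario_id):
        row = reference_row(spec.scenario_id, strategy_id)
        results.append(
            CEResult(
                strategy_id=strategy_id,
                scenario_id=spec.scenario_id,
                cost=row.cost,
                effectiveness=row.effectiveness,
                wtp=wtp,
            )
        )
    ceus = next(r for r in results if r.strategy_id == "ceus")
    for r in results:
        if r is not ceus:
            r.inhb_vs_reference = ceus.nhb - r.nhb
    return results


@dataclass
class ModelResult:
    """Model-route outcome for one schedule-backed strategy."""

    strategy_id: str
    scenario_id: str
    schedule: StrategySchedule
    schedule_cost: float  # EUR per surviving patient (calendar cost)
    cohort_cost: float  # EUR per patient, alive-fraction weighted
    effectiveness: float  # simulated QALYs per patient


def model_result(
    strategy_id: str,
    scenario: ScenarioSpec | str,
    params: ParamSet,
    life_table: LifeTable,
) -> ModelResult:
    """Run the full deterministic pipeline for a schedule-backed strategy."""
    spec = _scenario(scenario)
    schedule = build_schedule(strategy_id, spec, params)
    cost, qaly, _trace = simulate_strategy(params, schedule, life_table)
    return ModelResult(
        strategy_id=strategy_id,
        scenario_id=spec.scenario_id,
        schedule=schedule,
        schedule_cost=schedule_cost(schedule, params, params.discount_rate),
        cohort_cost=cost,
        effectiveness=qaly,
    )


def model_results(
    scenario: ScenarioSpec | str, params: ParamSet, life_table: LifeTable
) -> list[ModelResult]:
    """Model-route results for every schedule-backed strategy of a scenario."""
    spec = _scenario(scenario)
    return [
        model_result(s, spec, params, life_table)
        for s in strategies_for(spec.scenario_id)
        if s in SCHEDULE_BACKED
    ]
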