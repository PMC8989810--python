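"""Three-state Markov cohort engine: Asymptomatic, Symptomatic, Dead.

The natural history of an asymptomatic pancreatic cystic neoplasm under
surveillance is modelled with three health states.  Each 1-year cycle a
patient may become symptomatic or die; Dead is absorbing.  Competing
risks combine multiplicatively — the probability of transitioning while
surviving background mortality is p * (1 - qx) — which keeps every row
stochastic for any parameter values.

Costs are booked for the fraction of the cohort alive at cycle start
(matching the exam-calendar convention in ``schedules``); utilities are
weighted by start-of-cycle occupancy, decline with age, and drop on
symptom onset.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass
from enum import IntEnum
from typing import Iterable, Mapping, Sequence

import numpy as np

from .parameters import ParamSet
from .schedules import StrategySchedule, cycle_costs

logger = logging.getLogger(__name__)


class HealthState(IntEnum):
    ASYMPTOMATIC = 0
    SYMPTOMATIC = 1
    DEAD = 2


STATE_NAMES = tuple(s.name.lower() for s in HealthState)


class LifeTable:
    """Age-specific annual probability of death qx, for integer ages."""

    def __init__(self, qx_by_age: Mapping[int, float]):
        self._qx = {int(a): float(q) for a, q in qx_by_age.items()}
        for age, q in self._qx.items():
            if not (0.0 <= q <= 1.0):
                raise ValueError(f"qx({age}) = {q!r} outside [0, 1]")

    def qx(self, age: float) -> float:
        key = int(math.floor(age))
        try:
            return self._qx[key]
        except KeyError:
            raise KeyError(
                f"life table does not cover age {age} (integer age {key}); "
                f"covered range {min(self._qx)}..{max(self._qx)}"
            ) from None

    @property
    def ages(self) -> list[int]:
        return sorted(self._qx)

    def covers(self, age_lo: float, age_hi: float) -> bool:
        return all(
            int(math.floor(a)) in self._qx
            for a in range(int(math.floor(age_lo)), int(math.floor(age_hi)) + 1)
        )

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        """Read a 2-column (age, qx) CSV."""
        qx: dict[int, float] = {}
        with open(path, newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                qx[int(row["age"])] = float(row["qx"])
        return cls(qx)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["age", "qx"])
            for age in self.ages:
                writer.writerow([age, repr(self._qx[age])])


@dataclass
class TransitionMatrix:
    """One cycle's 3x3 row-stochastic transition matrix."""

    matrix: np.ndarray
    cycle_index: int = 0
    age: float = 0.0

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError(f"transition matrix must be 3x3, got {m.shape}")
        if (m < -1e-15).any() or (m > 1 + 1e-15).any():
            raise ValueError("transition probabilities outside [0, 1]")
        rows = m.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-12):
            raise ValueError(f"rows must sum to 1, got {rows}")
        if not np.allclose(m[HealthState.DEAD], [0.0, 0.0, 1.0], atol=1e-15):
            raise ValueError("Dead must be absorbing: row (0, 0, 1)")
        self.matrix = m


def build_transition_matrix(
    params: ParamSet,
    age: float,
    life_table: LifeTable,
    strategy_is_invasive: bool = False,
    cycle_index: int = 0,
) -> TransitionMatrix:
    """Transition matrix at a given age.

    Asymptomatic -> Dead is background mortality qx (plus the EUS-FNA
    procedural mortality when the strategy's cycle is invasive);
    Asymptomatic -> Symptomatic is p_symptomatic_annual among survivors.
    Symptomatic patients face background mortality plus an optional excess
    hazard p_death_malignant_untreated * frac_malignant_among_symptomatic
    (zero in the base case: the modelled population has no risk of
    malignant progression).
    """
    qx = life_table.qx(age)
    q_asym = qx
    if strategy_is_invasive:
        q_asym = min(1.0, qx + params.p_death_eusfna)
    a2d = q_asym
    a2s = params.p_symptomatic_annual * (1.0 - q_asym)
    a2a = 1.0 - a2d - a2s

    p_excess = 0.0
    if params.include_malignant_branch:
        p_excess = (
            params.p_death_malignant_untreated
            * params.frac_malignant_among_symptomatic
        )
    s2d = 1.0 - (1.0 - qx) * (1.0 - p_excess)
    s2s = 1.0 - s2d

    m = np.array(
        [
            [a2a, a2s, a2d],
            [0.0, s2s, s2d],
            [0.0, 0.0, 1.0],
        ]
    )
    return TransitionMatrix(m, cycle_index=cycle_index, age=age)


def build_cycle_matrices(
    params: ParamSet,
    life_table: LifeTable,
    schedule: StrategySchedule | None = None,
) -> list[TransitionMatrix]:
    """One transition matrix per cycle, ageing the cohort each year."""
    matrices = []
    for t in range(1, params.n_cycles + 1):
        invasive = schedule.contains_eus(t) if schedule is not None else False
        matrices.append(
            build_transition_matrix(
                params,
                age=params.base_age + (t - 1),
                life_table=life_table,
                strategy_is_invasive=invasive,
                cycle_index=t,
            )
        )
    return matrices


@dataclass
class CohortTrace:
    """State occupancy (persons) from cycle 0 through n_cycles."""

    occupancy: np.ndarray  # (n_cycles + 1, 3)

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    @property
    def cohort_size(self) -> float:
        return float(self.occupancy[0].sum())

    def alive_fraction_at_start(self, cycle: int) -> float:
        """Fraction of the cohort alive at the start of 1-based cycle t."""
        occ = self.occupancy[cycle - 1]
        return float((occ.sum() - occ[HealthState.DEAD]) / self.cohort_size)

    def to_csv(self, path, base_age: float | None = None) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            header = ["cycle"] + (["age"] if base_age is not None else [])
            writer.writerow(header + list(STATE_NAMES))
            for t, row in enumerate(self.occupancy):
                out: list = [t]
                if base_age is not None:
                    out.append(base_age + t)
                writer.writerow(out + [repr(float(x)) for x in row])


def run_cohort(
    initial: Sequence[float], matrices: Iterable[TransitionMatrix]
) -> CohortTrace:
    """Propagate the cohort: occupancy[t] = occupancy[t-1] @ M_t."""
    occ0 = np.asarray(initial, dtype=float)
    if occ0.shape != (3,):
        raise ValueError(f"initial occupancy must have 3 states, got {occ0.shape}")
    if (occ0 < 0).any():
        raise ValueError("initial occupancy must be non-negative")
    rows = [occ0]
    for tm in matrices:
        rows.append(rows[-1] @ tm.matrix)
    return CohortTrace(np.vstack(rows))


def accumulate_outcomes(
    trace: CohortTrace,
    schedule: StrategySchedule,
    params: ParamSet,
    discount_rate: float | None = None,
) -> tuple[float, float]:
    """Per-patient mean (total cost EUR, total QALYs) over the horizon.

    Cycle t utilities: asymptomatic patients get
    u_surv - u_aging_decrement_annual * (t - 1), where u_surv is the
    invasive-surveillance utility (0.73) in cycles containing an EUS and
    the non-invasive one (0.78) otherwise; symptomatic patients lose a
    further u_symptom_decrement; the dead contribute 0.  Negative
    utilities are clamped at 0 with a logged warning.  Costs are booked
    for the alive fraction at cycle start.  Both streams are discounted
    by (1 + r)^-(t-1); the optional half-cycle correction averages
    start- and end-of-cycle occupancy for the utility weights.
    """
    if discount_rate is None:
        discount_rate = params.discount_rate
    if discount_rate < 0:
        raise ValueError(f"discount rate must be >= 0, got {discount_rate}")
    if trace.n_cycles != schedule.n_cycles:
        raise ValueError(
            f"trace has {trace.n_cycles} cycles but schedule has "
            f"{schedule.n_cycles}"
        )
    n = trace.cohort_size
    costs_per_cycle = cycle_costs(schedule, params)
    total_cost = 0.0
    total_qaly = 0.0
    for t in range(1, trace.n_cycles + 1):
        disc = (1.0 + discount_rate) ** -(t - 1)
        u_surv = (
            params.u_invasive_surv
            if schedule.contains_eus(t)
            else params.u_noninvasive_surv
        )
        u_asym = u_surv - params.u_aging_decrement_annual * (t - 1)
        u_sym = u_asym - params.u_symptom_decrement
        if u_asym < 0 or u_sym < 0:
            logger.warning(
                "cycle %d: utility decrements drive utility below 0; clamping",
                t,
            )
            u_asym = max(0.0, u_asym)
            u_sym = max(0.0, u_sym)
        occ = trace.occupancy[t - 1]
        if params.half_cycle_correction:
            occ = 0.5 * (trace.occupancy[t - 1] + trace.occupancy[t])
        total_qaly += disc * (
            occ[HealthState.ASYMPTOMATIC] * u_asym
            + occ[HealthState.SYMPTOMATIC] * u_sym
        )
        total_cost += disc * trace.alive_fraction_at_start(t) * costs_per_cycle[t - 1]
    return total_cost, total_qaly / n


def simulate_strategy(
    params: ParamSet,
    schedule: StrategySchedule,
    life_table: LifeTable,
    initial: Sequence[float] | None = None,
) -> tuple[float, float, CohortTrace]:
    """Full deterministic run: matrices -> trace -> (cost, QALY, trace)."""
    if initial is None:
        initial = [float(params.cohort_size), 0.0, 0.0]
    matrices = build_cycle_matrices(params, life_table, schedule)
    trace = run_cohort(initial, matrices)
    cost, qaly = accumulate_outcomes(trace, schedule, params)
    return cost, qaly, trace
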