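"""Probabilistic and deterministic sensitivity analysis.

Second-order Monte-Carlo PSA draws every model parameter from its
assigned distribution — gamma for costs (mean-preserving, parameterized
by shape 1/cv^2 and scale mean*cv^2), normal for probabilities,
proportions and utilities (sd = prob_sd_frac * value, truncated to
[0, 1] by rejection), uniform for imaging sensitivity/specificity over
their published intervals — and re-evaluates the full deterministic
pipeline per draw.  Comparator strategies without a derivable exam
calendar draw their cost by gamma around the published total and their
effectiveness by a normal around the published QALY rescaled to the
model's effectiveness scale (see docs/methods.md).

From the per-draw (cost, QALY) pairs the module builds
cost-effectiveness acceptability curves (probability each strategy has
the highest net monetary benefit as willingness-to-pay varies) and
within-budget fractions, and runs one-way (tornado) deterministic
sensitivity analysis over stated parameter ranges.

Randomness uses one named stream per (seed, parameter), so adding a
parameter never perturbs another parameter's draws.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .markov import LifeTable, simulate_strategy
from .outcomes import net_health_benefit
from .parameters import (
    COST_FIELDS,
    MODALITIES,
    PROBABILITY_FIELDS,
    UTILITY_FIELDS,
    ParamSet,
    ScenarioSpec,
)
from .pipeline import _scenario
from .reference import SCHEDULE_BACKED, reference_row, strategies_for
from .schedules import build_schedule, schedule_cost
from .synthetic import make_life_table

logger = logging.getLogger(__name__)

DEFAULT_WTP_GRID: tuple[float, ...] = tuple(float(w) for w in range(0, 65000, 5000))


@dataclass
class PSAConfig:
    n_draws: int = 1000
    seed: int = 0
    cost_cv: float = 0.20  # gamma coefficient of variation for costs
    prob_sd_frac: float = 0.10  # normal sd as a fraction of the base value
    wtp_grid: tuple[float, ...] = DEFAULT_WTP_GRID

    def __post_init__(self) -> None:
        if self.n_draws < 1:
            raise ValueError(f"n_draws must be >= 1, got {self.n_draws}")
        if self.cost_cv < 0 or self.prob_sd_frac < 0:
            raise ValueError("distribution spreads must be >= 0")
        grid = tuple(float(w) for w in self.wtp_grid)
        if any(b <= a for a, b in zip(grid, grid[1:])):
            raise ValueError("wtp_grid must be strictly increasing")
        self.wtp_grid = grid


def _stream(seed: int, name: str) -> np.random.Generator:
    """Independent generator keyed by (seed, parameter name)."""
    digest = hashlib.sha256(name.encode("utf-8")).digest()
    key = int.from_bytes(digest[:4], "big") % (2**31)
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), key]))


def _draw_gamma(seed: int, name: str, mean: float, cv: float, n: int) -> np.ndarray:
    if not np.isfinite(mean):
        raise ValueError(f"{name}: non-finite base value {mean!r}")
    if cv == 0 or mean == 0:
        return np.full(n, mean)
    shape = 1.0 / cv**2
    scale = mean * cv**2
    return _stream(seed, name).gamma(shape, scale, size=n)


def _draw_truncated_normal(
    seed: int, name: str, mean: float, sd: float, n: int
) -> tuple[np.ndarray, int]:
    """Normal truncated to [0, 1] by rejection; returns (draws, n_rejected)."""
    if not np.isfinite(mean):
        raise ValueError(f"{name}: non-finite base value {mean!r}")
    if sd == 0:
        return np.full(n, mean), 0
    rng = _stream(seed, name)
    out = rng.normal(mean, sd, size=n)
    rejected = 0
    bad = (out < 0) | (out > 1)
    while bad.any():
        rejected += int(bad.sum())
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < 0) | (out > 1)
    return out, rejected


# Fields drawn as complements of another field, keeping sum invariants.
_COMPLEMENT_OF = {
    "frac_invasive_given_malignant": "frac_cis_given_malignant",
    "p_body_tail": "p_head_neck",
}


def sample_params(base: ParamSet, config: PSAConfig) -> list[ParamSet]:
    """Draw ``config.n_draws`` parameter sets around ``base``.

    Identical (base, config) always yields identical draws.  Complement
    pairs (CIS/invasive split, head-neck/body-tail location) are drawn
    jointly so every draw satisfies the sum invariants; mucinous +
    non-mucinous draws exceeding 1 are rejected and redrawn.
    """
    n = config.n_draws
    seed = config.seed
    columns: dict[str, np.ndarray] = {}
    total_rejected = 0

    for name in COST_FIELDS:
        columns[name] = _draw_gamma(
            seed, f"cost:{name}", getattr(base, name), config.cost_cv, n
        )
    for name in PROBABILITY_FIELDS + UTILITY_FIELDS:
        if name in _COMPLEMENT_OF:
            continue
        mean = getattr(base, name)
        draws, rejected = _draw_truncated_normal(
            seed, f"prob:{name}", mean, config.prob_sd_frac * mean, n
        )
        columns[name] = draws
        total_rejected += rejected
    for name, partner in _COMPLEMENT_OF.items():
        columns[name] = 1.0 - columns[partner]

    # Joint constraint: mucinous + non-mucinous <= 1 (pairwise rejection).
    bad = columns["prop_mucinous"] + columns["prop_nonmucinous"] > 1.0
    guard = 0
    while bad.any() and guard < 1000:
        total_rejected += int(bad.sum())
        for name in ("prop_mucinous", "prop_nonmucinous"):
            mean = getattr(base, name)
            redraw, rej = _draw_truncated_normal(
                _stream(seed, f"redraw:{name}:{guard}").integers(2**31),
                f"prob:{name}",
                mean,
                config.prob_sd_frac * mean,
                int(bad.sum()),
            )
            columns[name][bad] = redraw
            total_rejected += rej
        bad = columns["prop_mucinous"] + columns["prop_nonmucinous"] > 1.0
        guard += 1

    sens: dict[str, np.ndarray] = {}
    spec: dict[str, np.ndarray] = {}
    for m in MODALITIES:
        lo, hi = base.sens_range[m]
        sens[m] = _stream(seed, f"sens:{m}").uniform(lo, hi, size=n)
        lo, hi = base.spec_range[m]
        spec[m] = _stream(seed, f"spec:{m}").uniform(lo, hi, size=n)

    if total_rejected:
        logger.info("PSA sampling rejected and redrew %d values", total_rejected)

    draws = []
    for i in range(n):
        changes = {name: float(col[i]) for name, col in columns.items()}
        changes["sens_range"] = {m: (float(sens[m][i]),) * 2 for m in MODALITIES}
        changes["spec_range"] = {m: (float(spec[m][i]),) * 2 for m in MODALITIES}
        draws.append(base.replace(**changes))
    return draws


@dataclass
class PSAResult:
    """Per-draw, per-strategy (cost, effectiveness) pairs."""

    scenario_id: str
    strategy_ids: list[str]
    costs: np.ndarray  # (n_draws, n_strategies) EUR
    effs: np.ndarray  # (n_draws, n_strategies) QALY
    draws: list[ParamSet] = field(repr=False, default_factory=list)
    config: PSAConfig | None = None

    @property
    def n_draws(self) -> int:
        return self.costs.shape[0]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for j, s in enumerate(self.strategy_ids):
            for i in range(self.n_draws):
                rows.append(
                    {
                        "draw": i,
                        "strategy_id": s,
                        "cost": self.costs[i, j],
                        "effectiveness": self.effs[i, j],
                    }
                )
        return pd.DataFrame(rows)


def run_psa(
    scenario: ScenarioSpec | str,
    strategies: list[str] | None = None,
    config: PSAConfig | None = None,
    base_params: ParamSet | None = None,
    life_table: LifeTable | None = None,
) -> PSAResult:
    """Second-order Monte-Carlo PSA for one scenario.

    Schedule-backed strategies re-run the full deterministic pipeline at
    every drawn parameter set.  Fixed-cost comparators draw cost ~ gamma
    around their published total and effectiveness ~ normal around the
    published QALY rescaled into the model's effectiveness scale (via
    the CEUS published/simulated ratio), sd = prob_sd_frac * mean,
    truncated at 0.
    """
    spec = _scenario(scenario)
    config = config or PSAConfig()
    base = base_params or ParamSet()
    lt = life_table or make_life_table()
    strategy_ids = strategies or strategies_for(spec.scenario_id)

    draws = sample_params(base, config)
    n = config.n_draws
    costs = np.empty((n, len(strategy_ids)))
    effs = np.empty((n, len(strategy_ids)))

    # Model-scale calibration for comparators without a calendar.
    ceus_ref = reference_row(spec.scenario_id, "ceus")
    _, base_eff_ceus, _ = simulate_strategy(
        base, build_schedule("ceus", spec, base), lt
    )
    eff_scale = base_eff_ceus / ceus_ref.effectiveness

    for j, strategy_id in enumerate(strategy_ids):
        if strategy_id in SCHEDULE_BACKED:
            schedule = build_schedule(strategy_id, spec, base)
            for i, p in enumerate(draws):
                costs[i, j] = schedule_cost(schedule, p, p.discount_rate)
                _, effs[i, j], _ = simulate_strategy(p, schedule, lt)
        else:
            ref = reference_row(spec.scenario_id, strategy_id)
            costs[:, j] = _draw_gamma(
                config.seed, f"fixed_cost:{strategy_id}", ref.cost, config.cost_cv, n
            )
            mean_eff = ref.effectiveness * eff_scale
            sd = config.prob_sd_frac * mean_eff
            if sd == 0:
                effs[:, j] = mean_eff
            else:
                rng = _stream(config.seed, f"fixed_eff:{strategy_id}")
                e = rng.normal(mean_eff, sd, size=n)
                bad = e < 0
                while bad.any():
                    e[bad] = rng.normal(mean_eff, sd, size=int(bad.sum()))
                    bad = e < 0
                effs[:, j] = e

    return PSAResult(
        scenario_id=spec.scenario_id,
        strategy_ids=list(strategy_ids),
        costs=costs,
        effs=effs,
        draws=draws,
        config=config,
    )


@dataclass
class CEACCurve:
    """Acceptability curve plus within-budget fractions at the threshold."""

    strategy_ids: list[str]
    wtp_grid: tuple[float, ...]
    prob_optimal: np.ndarray  # (len(wtp_grid), n_strategies), rows sum to 1
    within_budget: dict[str, float]  # fraction of draws with ACER <= threshold
    within_budget_nmb: dict[str, float]  # alternative: fraction with NMB > 0
    budget_wtp: float = 30000.0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, wtp in enumerate(self.wtp_grid):
            for j, s in enumerate(self.strategy_ids):
                rows.append(
                    {
                        "wtp": wtp,
                        "strategy_id": s,
                        "probability_optimal": self.prob_optimal[i, j],
                    }
                )
        return pd.DataFrame(rows)


def ceac(
    psa: PSAResult,
    wtp_grid: tuple[float, ...] | None = None,
    budget_wtp: float = 30000.0,
) -> CEACCurve:
    """Probability each strategy is optimal (highest NMB) per WTP value.

    Ties for the per-draw maximum split their probability mass equally,
    so probabilities sum to exactly 1 at every WTP.  The within-budget
    fraction is the share of draws with ACER <= budget_wtp (the
    alternative NMB > 0 definition is reported alongside).
    """
    if psa.n_draws < 1:
        raise ValueError("PSA result is empty")
    if wtp_grid is None:
        grid = psa.config.wtp_grid if psa.config else ()
    else:
        grid = tuple(wtp_grid)
    if not grid:
        raise ValueError("empty willingness-to-pay grid")
    prob = np.zeros((len(grid), len(psa.strategy_ids)))
    for i, wtp in enumerate(grid):
        nmb = wtp * psa.effs - psa.costs
        best = nmb.max(axis=1, keepdims=True)
        winners = nmb >= best - 1e-12
        weights = winners / winners.sum(axis=1, keepdims=True)
        prob[i] = weights.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        acer_draws = np.where(psa.effs > 0, psa.costs / psa.effs, np.inf)
    nmb_budget = budget_wtp * psa.effs - psa.costs
    within = {
        s: float((acer_draws[:, j] <= budget_wtp).mean())
        for j, s in enumerate(psa.strategy_ids)
    }
    within_nmb = {
        s: float((nmb_budget[:, j] > 0).mean())
        for j, s in enumerate(psa.strategy_ids)
    }
    return CEACCurve(
        strategy_ids=list(psa.strategy_ids),
        wtp_grid=tuple(float(w) for w in grid),
        prob_optimal=prob,
        within_budget=within,
        within_budget_nmb=within_nmb,
        budget_wtp=budget_wtp,
    )


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    low: float
    high: float
    nhb_at_low: float
    nhb_at_high: float

    @property
    def bar_width(self) -> float:
        return abs(self.nhb_at_high - self.nhb_at_low)


def default_tornado_ranges(params: ParamSet) -> dict[str, tuple[float, float]]:
    """One-way ranges: costs +/-20%, probabilities and utilities +/-10%
    (clipped to [0, 1]), for the parameters the base-case model uses."""
    ranges: dict[str, tuple[float, float]] = {}
    for name in COST_FIELDS:
        v = getattr(params, name)
        ranges[name] = (0.8 * v, 1.2 * v)
    for name in (
        "p_symptomatic_annual",
        "p_death_eusfna",
        "u_noninvasive_surv",
        "u_invasive_surv",
        "u_aging_decrement_annual",
        "u_symptom_decrement",
    ):
        v = getattr(params, name)
        ranges[name] = (max(0.0, 0.9 * v), min(1.0, 1.1 * v))
    return ranges


def tornado(
    base: ParamSet,
    ranges: dict[str, tuple[float, float]],
    scenario: ScenarioSpec | str,
    strategy_id: str = "ceus",
    life_table: LifeTable | None = None,
) -> list[TornadoEntry]:
    """One-way deterministic sensitivity of NHB for one strategy.

    Each parameter is set to its low then high value with all others at
    base; the strategy's net health benefit (at the base WTP) is
    recomputed through the full pipeline.  Entries are sorted by
    descending bar width, ties broken alphabetically.
    """
    if strategy_id not in SCHEDULE_BACKED:
        raise ValueError(
            f"tornado analysis needs a schedule-backed strategy; "
            f"{strategy_id!r} is a fixed-cost comparator"
        )
    spec = _scenario(scenario)
    lt = life_table or make_life_table()
    schedule = build_schedule(strategy_id, spec, base)

    def nhb_at(p: ParamSet) -> float:
        cost = schedule_cost(schedule, p, p.discount_rate)
        _, eff, _ = simulate_strategy(p, schedule, lt)
        return net_health_benefit(cost, eff, base.wtp)

    entries = []
    for name in sorted(ranges):
        lo, hi = ranges[name]
        base_value = getattr(base, name)
        if not (lo <= base_value <= hi):
            raise ValueError(
                f"range ({lo}, {hi}) for {name!r} excludes base value {base_value}"
            )
        entries.append(
            TornadoEntry(
                parameter=name,
                low=lo,
                high=hi,
                nhb_at_low=nhb_at(base.replace(**{name: lo})),
                nhb_at_high=nhb_at(base.replace(**{name: hi})),
            )
        )
    entries.sort(key=lambda e: (-e.bar_width, e.parameter))
    return entries


def tornado_to_frame(entries: list[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parameter": e.parameter,
                "low": e.low,
                "high": e.high,
                "nhb_low": e.nhb_at_low,
                "nhb_high": e.nhb_at_high,
                "width": e.bar_width,
            }
            for e in entries
        ]
    )
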