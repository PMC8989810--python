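"""Cost-effectiveness summary measures.

Given per-strategy (cost, effectiveness) pairs this module computes the
average cost-effectiveness ratio (ACER = C/E), pairwise incremental
ratios with dominance verdicts, net health benefit (NHB = E - C/lambda,
in QALYs) and its monetary twin (NMB = lambda * NHB, in EUR), savings of
the CEUS strategy against each guideline comparator, cross-scenario
means, and the efficiency frontier with strict and extended dominance.

The published tables print the net-benefit column in QALY units (it is
NHB, not monetary NMB) and truncate toward zero at the printed precision;
:func:`truncate` reproduces that rendering convention, while every
internal computation is carried at full double precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_DOWN, Decimal
from typing import Iterable, Sequence


def truncate(x: float, ndigits: int = 2) -> float:
    """Truncate toward zero at ``ndigits`` decimals (12.4888 -> 12.48).

    Binary float noise is removed first (round at 9 decimals) so that a
    decimal-exact difference such as 2196.10 - 1301.44 truncates to
    894.66 rather than 894.65.
    """
    d = Decimal(repr(float(x))).quantize(Decimal("1e-9"))
    return float(d.quantize(Decimal(1).scaleb(-ndigits), rounding=ROUND_DOWN))


@dataclass
class CEResult:
    """Cost-effectiveness summary for one strategy in one scenario."""

    strategy_id: str
    scenario_id: str
    cost: float  # EUR per patient
    effectiveness: float  # QALYs per patient
    acer: float = field(init=False)
    nhb: float = field(init=False)  # QALY units, at self.wtp
    nmb_money: float = field(init=False)  # EUR
    wtp: float = 30000.0
    inhb_vs_reference: float | None = None
    dominated: bool = False

    def __post_init__(self) -> None:
        self.acer = acer(self.cost, self.effectiveness) if self.effectiveness > 0 else math.nan
        self.nhb = net_health_benefit(self.cost, self.effectiveness, self.wtp)
        self.nmb_money = self.wtp * self.nhb


def net_health_benefit(cost: float, effectiveness: float, wtp: float) -> float:
    """NHB = E - C / lambda (QALY units)."""
    if wtp <= 0:
        raise ValueError(f"willingness-to-pay must be > 0, got {wtp}")
    return effectiveness - cost / wtp


def net_monetary_benefit(cost: float, effectiveness: float, wtp: float) -> float:
    """NMB = lambda * E - C (EUR); equals wtp * NHB exactly."""
    return wtp * net_health_benefit(cost, effectiveness, wtp)


def acer(cost: float, effectiveness: float) -> float:
    """Average cost-effectiveness ratio C/E (EUR per QALY)."""
    if effectiveness <= 0:
        raise ValueError(
            f"ACER requires effectiveness > 0, got {effectiveness}"
        )
    return cost / effectiveness


def icer_pairwise(a: "CEResult", b: "CEResult") -> float | str:
    """Incremental ratio of a vs b, or a dominance verdict for a.

    Returns (cost_a - cost_b) / (eff_a - eff_b) when neither strategy
    dominates; the string ``"dominant"`` when a is at least as cheap and
    at least as effective (one strictly), ``"dominated"`` for the
    reverse, and ``"equivalent"`` for identical pairs.
    """
    if a.scenario_id != b.scenario_id:
        raise ValueError(
            f"cannot compare strategies across scenarios "
            f"({a.scenario_id!r} vs {b.scenario_id!r})"
        )
    dc = a.cost - b.cost
    de = a.effectiveness - b.effectiveness
    if dc == 0 and de == 0:
        return "equivalent"
    if dc <= 0 and de >= 0:
        return "dominant"
    if dc >= 0 and de <= 0:
        return "dominated"
    return dc / de


@dataclass(frozen=True)
class SavingsEntry:
    """Saving of the CEUS strategy against one guideline comparator."""

    scenario_id: str
    comparator_id: str
    saving_eur: float
    saving_pct: float  # 100 * saving_eur / comparator cost


def savings(
    comparator_cost: float,
    ceus_cost: float,
    scenario_id: str = "",
    comparator_id: str = "",
) -> SavingsEntry:
    """Absolute and percentage saving of CEUS vs a comparator strategy."""
    if comparator_cost <= 0:
        raise ValueError(
            f"comparator cost must be > 0, got {comparator_cost}"
        )
    saving = comparator_cost - ceus_cost
    return SavingsEntry(
        scenario_id=scenario_id,
        comparator_id=comparator_id,
        saving_eur=saving,
        saving_pct=100.0 * saving / comparator_cost,
    )


def scenario_means(results: Sequence["CEResult"]) -> tuple[float, float, float]:
    """Arithmetic means of (cost, effectiveness, ACER) for one strategy family."""
    if not results:
        raise ValueError("scenario_means requires at least one result")
    n = len(results)
    return (
        sum(r.cost for r in results) / n,
        sum(r.effectiveness for r in results) / n,
        sum(r.acer for r in results) / n,
    )


def _strictly_dominated(r: "CEResult", others: Iterable["CEResult"]) -> bool:
    for o in others:
        if o is r:
            continue
        if (
            o.cost <= r.cost
            and o.effectiveness >= r.effectiveness
            and (o.cost < r.cost or o.effectiveness > r.effectiveness)
        ):
            return True
    return False


def frontier(results: Sequence["CEResult"]) -> list["CEResult"]:
    """Efficiency frontier: strict then extended dominance removed.

    Returns the non-dominated strategies sorted by increasing
    effectiveness and sets ``dominated`` flags on every input.  A
    strategy is extendedly dominated when a convex blend of two frontier
    neighbours delivers at least its effectiveness at lower cost, i.e.
    when incremental ratios along the effectiveness-sorted frontier fail
    to increase.
    """
    if not results:
        raise ValueError("frontier requires at least one result")
    for r in results:
        r.dominated = _strictly_dominated(r, results)
    candidates = sorted(
        (r for r in results if not r.dominated),
        key=lambda r: (r.effectiveness, r.cost, r.strategy_id),
    )
    # Extended dominance: repeatedly drop interior points with a
    # non-increasing incremental ratio sequence.
    changed = True
    while changed and len(candidates) > 2:
        changed = False
        for i in range(1, len(candidates) - 1):
            lo, mid, hi = candidates[i - 1], candidates[i], candidates[i + 1]

            def _ratio(p: "CEResult", q: "CEResult") -> float:
                de = q.effectiveness - p.effectiveness
                return (q.cost - p.cost) / de if de > 0 else math.inf

            if _ratio(lo, mid) >= _ratio(mid, hi):
                mid.dominated = True
                del candidates[i]
                changed = True
                break
    return candidates
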