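"""Published base-case cost-effectiveness results per scenario and strategy.

The comparator guideline strategies (Italian consensus, European/ACG) have
no exam calendar that can be reconstructed from the per-exam unit costs:
their published totals admit no small integer decomposition and partly rest
on plain ultrasound, which has no listed cost.  They are therefore carried
as fixed (cost, QALY) strategies with honest provenance, while the CEUS and
Fukuoka strategies are backed by explicit schedules (see ``schedules``).

All monetary values are EUR per patient over the 10-year horizon;
effectiveness is QALYs per patient.
"""

from __future__ import annotations

from dataclasses import dataclass

STRATEGY_LABELS: dict[str, str] = {
    "ceus": "CEUS follow-up",
    "fukuoka": "Consensus Fukuoka guidelines",
    "italian": "Italian consensus guidelines",
    "european_acg": "European evidence-based / ACG guidelines",
}

#: Strategy ids with an explicit exam calendar (full pipeline support).
SCHEDULE_BACKED: frozenset[str] = frozenset({"ceus", "fukuoka"})


@dataclass(frozen=True)
class ReferenceCEA:
    """One published base-case row: per-patient cost and effectiveness."""

    scenario_id: str
    strategy_id: str
    cost: float
    effectiveness: float
    icer_printed: float  # published average ratio; see docs on its provenance


#: Published base-case table, keyed by (scenario_id, strategy_id).
REFERENCE_CEA: dict[tuple[str, str], ReferenceCEA] = {
    (r.scenario_id, r.strategy_id): r
    for r in (
        ReferenceCEA("bd_lt1cm", "fukuoka", 1537.27, 12.54, 121.63),
        ReferenceCEA("bd_lt1cm", "italian", 828.22, 13.37, 61.04),
        ReferenceCEA("bd_lt1cm", "ceus", 705.00, 13.57, 51.06),
        ReferenceCEA("bd_1_2cm", "fukuoka", 1756.88, 11.32, 154.14),
        ReferenceCEA("bd_1_2cm", "italian", 1663.95, 11.46, 144.15),
        ReferenceCEA("bd_1_2cm", "ceus", 1480.50, 11.59, 126.70),
        ReferenceCEA("bd_2_3cm", "fukuoka", 8268.44, 10.53, 784.09),
        ReferenceCEA("bd_2_3cm", "italian", 4392.20, 10.59, 413.62),
        ReferenceCEA("bd_2_3cm", "ceus", 2751.99, 10.63, 257.76),
        ReferenceCEA("mcn_3_4cm", "european_acg", 8847.10, 9.20, 960.34),
        ReferenceCEA("mcn_3_4cm", "ceus", 3684.71, 9.70, 378.62),
        ReferenceCEA("scn_lt4cm", "european_acg", 2196.10, 12.59, 173.48),
        ReferenceCEA("scn_lt4cm", "italian", 1662.40, 13.40, 124.06),
        ReferenceCEA("scn_lt4cm", "ceus", 1301.44, 13.46, 95.79),
    )
}


def strategies_for(scenario_id: str) -> list[str]:
    """Strategy ids with a published base-case row for this scenario."""
    ids = [s for (sc, s) in REFERENCE_CEA if sc == scenario_id]
    if not ids:
        raise KeyError(f"unknown scenario_id {scenario_id!r}")
    order = ["ceus", "fukuoka", "italian", "european_acg"]
    return sorted(ids, key=order.index)


def reference_row(scenario_id: str, strategy_id: str) -> ReferenceCEA:
    try:
        return REFERENCE_CEA[(scenario_id, strategy_id)]
    except KeyError:
        raise KeyError(
            f"no published base-case row for strategy {strategy_id!r} "
            f"in scenario {scenario_id!r}"
        ) from None
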