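"""Model parameter registry for the pancreatic-cyst surveillance model.

Every tunable quantity of the decision model lives in :class:`ParamSet`:
transition probabilities, branch proportions, per-exam costs (EUR), health
utilities, imaging sensitivity/specificity ranges, and run settings
(cohort size, base age, willingness-to-pay threshold, discount rate).
Defaults are the published base-case estimates for a 60-year-old cohort
under surveillance for an asymptomatic pancreatic cystic neoplasm (PCN).

Validation is data-first: :func:`validate_params` returns a list of
:class:`Violation` records rather than raising, so a config checker can
report every problem at once.
"""

from __future__ import annotations

import dataclasses
import io
import os
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping

import yaml

MODALITIES: tuple[str, ...] = ("CEUS", "CT", "MRI", "EUS")

#: Published sensitivity / specificity ranges per imaging modality,
#: stored as proportion intervals (the source prints percents).
DEFAULT_SENS_RANGE: dict[str, tuple[float, float]] = {
    "CEUS": (0.79, 0.94),
    "CT": (0.57, 0.69),
    "MRI": (0.75, 0.82),
    "EUS": (0.78, 0.83),
}
DEFAULT_SPEC_RANGE: dict[str, tuple[float, float]] = {
    "CEUS": (0.76, 0.99),
    "CT": (0.63, 0.83),
    "MRI": (0.94, 0.96),
    "EUS": (0.91, 0.95),
}

# Field groups used by validation and by the probabilistic sensitivity
# analysis (costs draw gamma; probability-scale fields draw normal).
COST_FIELDS: tuple[str, ...] = ("cost_ct", "cost_mri", "cost_eus", "cost_ceus")
PROBABILITY_FIELDS: tuple[str, ...] = (
    "p_correct_dx",
    "p_benign_cyst",
    "p_malignant_cyst",
    "p_head_neck",
    "p_body_tail",
    "prop_mucinous",
    "prop_nonmucinous",
    "p_symptomatic_annual",
    "p_benign_growth_annual",
    "p_death_eusfna",
    "p_death_malignant_untreated",
    "frac_malignant_bd_ipmn",
    "frac_cis_given_malignant",
    "frac_invasive_given_malignant",
    "frac_malignant_among_symptomatic",
)
UTILITY_FIELDS: tuple[str, ...] = (
    "u_base",
    "u_aging_decrement_annual",
    "u_symptom_decrement",
    "u_invasive_surv",
    "u_noninvasive_surv",
    "u_malignant",
)


@dataclass
class ParamSet:
    """Full parameter set of the surveillance cost-effectiveness model.

    Probabilities, proportions and utilities are on the [0, 1] scale;
    costs are EUR per examination; ``wtp`` is EUR per QALY.
    """

    # Run structure
    n_cycles: int = 10
    cohort_size: int = 1000
    base_age: float = 60.0
    discount_rate: float = 0.0
    wtp: float = 30000.0

    # Diagnostic / natural-history probabilities and proportions
    p_correct_dx: float = 0.85
    p_benign_cyst: float = 0.10
    p_malignant_cyst: float = 0.05
    p_head_neck: float = 0.50
    p_body_tail: float = 0.50
    prop_mucinous: float = 0.65
    prop_nonmucinous: float = 0.30
    p_symptomatic_annual: float = 0.02
    p_benign_growth_annual: float = 0.05
    p_death_eusfna: float = 0.0001
    p_death_malignant_untreated: float = 0.6
    frac_malignant_bd_ipmn: float = 0.15
    frac_cis_given_malignant: float = 0.59
    frac_invasive_given_malignant: float = 0.41

    # Per-exam costs, EUR
    cost_ct: float = 106.23
    cost_mri: float = 219.61
    cost_eus: float = 739.00
    cost_ceus: float = 70.50

    # Health utilities
    u_base: float = 0.80
    u_aging_decrement_annual: float = 0.01
    u_symptom_decrement: float = 0.03
    u_invasive_surv: float = 0.73
    u_noninvasive_surv: float = 0.78
    u_malignant: float = 0.68

    # Imaging performance intervals (proportions)
    sens_range: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SENS_RANGE)
    )
    spec_range: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SPEC_RANGE)
    )

    # Structural switches. The modelled population has no worrisome
    # features, so the malignant-branch and misdiagnosis pathways are
    # off in the base case; the base-case printed costs are reproduced
    # without them.
    include_malignant_branch: bool = False
    include_misdiagnosis: bool = False
    frac_malignant_among_symptomatic: float = 0.0
    half_cycle_correction: bool = False

    def unit_cost(self, modality: str) -> float:
        """EUR cost of a single examination of the given modality."""
        try:
            return {
                "CEUS": self.cost_ceus,
                "CT": self.cost_ct,
                "MRI": self.cost_mri,
                "EUS": self.cost_eus,
            }[modality]
        except KeyError:
            raise KeyError(f"unknown imaging modality {modality!r}") from None

    def replace(self, **changes: Any) -> "ParamSet":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class ScenarioSpec:
    """One cyst-type x size-class scenario (separate model per scenario)."""

    scenario_id: str
    cyst_type: str  # BD-IPMN / MCN / SCN
    size_class: str
    female_ratio: float
    base_age: float = 60.0


#: The five scenarios analysed: BD-IPMN by size, MCN 3-4 cm, SCN < 4 cm.
#: Gender ratios: BD-IPMN 1:1, MCN 9:1 and SCN 4:1 (female:male).
SCENARIOS: dict[str, ScenarioSpec] = {
    s.scenario_id: s
    for s in (
        ScenarioSpec("bd_lt1cm", "BD-IPMN", "< 1 cm", 0.5),
        ScenarioSpec("bd_1_2cm", "BD-IPMN", "1-2 cm", 0.5),
        ScenarioSpec("bd_2_3cm", "BD-IPMN", "2-3 cm", 0.5),
        ScenarioSpec("mcn_3_4cm", "MCN", "3-4 cm", 0.9),
        ScenarioSpec("scn_lt4cm", "SCN", "< 4 cm", 0.8),
    )
}


@dataclass(frozen=True)
class Violation:
    """A single validation failure: which field, and which rule it broke."""

    field: str
    rule: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.field}: {self.rule}"


class ConfigError(ValueError):
    """Raised for malformed or out-of-range configuration documents."""


def _check_unit(violations: list[Violation], name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        violations.append(Violation(name, f"value {value!r} outside [0, 1]"))


def validate_params(params: ParamSet) -> list[Violation]:
    """Check every model invariant; return violations (empty list = valid)."""
    v: list[Violation] = []
    for name in PROBABILITY_FIELDS + UTILITY_FIELDS + ("discount_rate",):
        _check_unit(v, name, getattr(params, name))
    for name in COST_FIELDS + ("wtp",):
        if getattr(params, name) < 0:
            v.append(Violation(name, f"negative cost {getattr(params, name)!r}"))
    if params.n_cycles < 1:
        v.append(Violation("n_cycles", f"must be >= 1, got {params.n_cycles}"))
    if params.cohort_size < 1:
        v.append(Violation("cohort_size", f"must be >= 1, got {params.cohort_size}"))
    s = params.frac_cis_given_malignant + params.frac_invasive_given_malignant
    if abs(s - 1.0) > 1e-9:
        v.append(
            Violation(
                "frac_cis_given_malignant",
                f"CIS + invasive fractions sum to {s!r}, expected 1",
            )
        )
    if params.prop_mucinous + params.prop_nonmucinous > 1.0 + 1e-12:
        v.append(
            Violation("prop_mucinous", "mucinous + non-mucinous proportions exceed 1")
        )
    for attr in ("sens_range", "spec_range"):
        ranges = getattr(params, attr)
        for modality, (lo, hi) in ranges.items():
            if modality not in MODALITIES:
                v.append(Violation(attr, f"unknown modality {modality!r}"))
                continue
            if not (0.0 <= lo <= hi <= 1.0):
                v.append(
                    Violation(
                        f"{attr}[{modality}]",
                        f"interval ({lo!r}, {hi!r}) must satisfy 0 <= lo <= hi <= 1",
                    )
                )
    return v


_FIELD_NAMES = {f.name for f in dataclasses.fields(ParamSet)}
_INT_FIELDS = {"n_cycles", "cohort_size"}
_BOOL_FIELDS = {
    "include_malignant_branch",
    "include_misdiagnosis",
    "half_cycle_correction",
}


def _coerce_field(key: str, value: Any) -> Any:
    if key in ("sens_range", "spec_range"):
        if not isinstance(value, Mapping):
            raise ConfigError(f"{key}: expected a modality -> [lo, hi] mapping")
        out: dict[str, tuple[float, float]] = {}
        for modality, pair in value.items():
            try:
                lo, hi = pair
            except (TypeError, ValueError):
                raise ConfigError(
                    f"{key}[{modality}]: expected a two-element [lo, hi] interval"
                ) from None
            out[str(modality)] = (float(lo), float(hi))
        return out
    if key in _BOOL_FIELDS:
        if not isinstance(value, bool):
            raise ConfigError(f"{key}: expected a boolean, got {value!r}")
        return value
    if key in _INT_FIELDS:
        if isinstance(value, bool) or int(value) != value:
            raise ConfigError(f"{key}: expected an integer, got {value!r}")
        return int(value)
    try:
        return float(value)
    except (TypeError, ValueError):
        raise ConfigError(f"{key}: expected a number, got {value!r}") from None


def _parse_scenarios(block: Any) -> list[ScenarioSpec]:
    if not isinstance(block, list):
        raise ConfigError("scenarios: expected a list of scenario mappings")
    specs = []
    seen: set[str] = set()
    for entry in block:
        if isinstance(entry, str):
            if entry not in SCENARIOS:
                raise ConfigError(
                    f"scenarios: unknown scenario_id {entry!r}; "
                    f"known ids: {sorted(SCENARIOS)}"
                )
            spec = SCENARIOS[entry]
        elif isinstance(entry, Mapping):
            try:
                spec = ScenarioSpec(
                    scenario_id=str(entry["scenario_id"]),
                    cyst_type=str(entry["cyst_type"]),
                    size_class=str(entry["size_class"]),
                    female_ratio=float(entry["female_ratio"]),
                    base_age=float(entry.get("base_age", 60.0)),
                )
            except KeyError as exc:
                raise ConfigError(f"scenarios: missing key {exc.args[0]!r}") from None
        else:
            raise ConfigError(f"scenarios: cannot parse entry {entry!r}")
        if not (0.0 <= spec.female_ratio <= 1.0):
            raise ConfigError(
                f"scenarios[{spec.scenario_id}]: female_ratio outside [0, 1]"
            )
        if spec.scenario_id in seen:
            raise ConfigError(f"scenarios: duplicate scenario_id {spec.scenario_id!r}")
        seen.add(spec.scenario_id)
        specs.append(spec)
    return specs


def load_config(source: Any) -> tuple[ParamSet, list[ScenarioSpec]]:
    """Parse a YAML/JSON config into a validated (ParamSet, scenarios) pair.

    ``source`` may be a mapping, a path to a file, a YAML/JSON string, or a
    file-like object.  Keys are exactly the :class:`ParamSet` field names
    plus an optional ``scenarios:`` block; unknown keys are rejected.
    Omitted fields take the base-case defaults.  An empty document yields
    the default parameter set and the five standard scenarios.
    """
    if isinstance(source, Mapping):
        doc: Any = dict(source)
    else:
        if isinstance(source, (str, os.PathLike)) and os.path.exists(str(source)):
            with open(source, "r", encoding="utf-8") as fh:
                text = fh.read()
        elif isinstance(source, io.IOBase) or hasattr(source, "read"):
            text = source.read()
        else:
            text = str(source)
        try:
            doc = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse config document: {exc}") from exc
    if doc is None:
        doc = {}
    if not isinstance(doc, Mapping):
        raise ConfigError(f"config root must be a mapping, got {type(doc).__name__}")

    scenarios = list(SCENARIOS.values())
    overrides: dict[str, Any] = {}
    for key, value in doc.items():
        if key == "scenarios":
            scenarios = _parse_scenarios(value)
            continue
        if key not in _FIELD_NAMES:
            raise ConfigError(f"unknown configuration key {key!r}")
        overrides[key] = _coerce_field(key, value)

    params = ParamSet(**overrides)
    violations = validate_params(params)
    if violations:
        raise ConfigError(
            "invalid parameter values: " + "; ".join(str(v) for v in violations)
        )
    return params, scenarios


def load_params(source: Any) -> ParamSet:
    """Parse a config document (see :func:`load_config`) into a ParamSet."""
    return load_config(source)[0]


def serialize_params(
    params: ParamSet, scenarios: Iterable[ScenarioSpec] | None = None
) -> str:
    """Render a ParamSet (and optional scenarios block) as YAML.

    Round-trip safe: ``load_params(serialize_params(p)) == p``.
    """
    doc: dict[str, Any] = {}
    for f in dataclasses.fields(ParamSet):
        value = getattr(params, f.name)
        if f.name in ("sens_range", "spec_range"):
            value = {m: [lo, hi] for m, (lo, hi) in value.items()}
        doc[f.name] = value
    if scenarios is not None:
        doc["scenarios"] = [dataclasses.asdict(s) for s in scenarios]
    return yaml.safe_dump(doc, sort_keys=True, default_flow_style=False)
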