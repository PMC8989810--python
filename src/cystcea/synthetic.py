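"""Synthetic inputs: life table, patient cohort, and bundled fixtures.

The analysis needs an age-specific all-cause mortality table and a
1000-patient cohort with the stated scenario and gender mix.  No public
table accompanies the model, so a Gompertz-Makeham stand-in with
documented coefficients is generated here (and any user-supplied
(age, qx) CSV is accepted by :class:`~cystcea.markov.LifeTable`).  The
hazard is mu(age) = lambda + alpha * exp(beta * age), giving an annual
death probability qx = 1 - exp(-mu); the default coefficients yield
qx(60) ~ 0.0065, in the range of recent European all-cause mortality at
that age.

Cohorts are fixed at age 60 by default (the base case), with sex drawn
Bernoulli at the scenario's female ratio (BD-IPMN 1:1, MCN 9:1, SCN 4:1
female:male) and, for branch-duct IPMN scenarios, a 15% malignant-branch
flag.
"""

from __future__ import annotations

import hashlib
import json
import math
import os
from typing import Sequence

import numpy as np
import pandas as pd

from .markov import LifeTable
from .parameters import (
    SCENARIOS,
    ParamSet,
    ScenarioSpec,
    serialize_params,
)
from .reference import REFERENCE_CEA

#: Default Gompertz-Makeham hazard coefficients (per year).
GM_DEFAULTS = {"lam": 0.0005, "alpha": 2e-5, "beta": 0.095}


def make_life_table(
    model: str = "gompertz_makeham",
    params: dict | None = None,
    age_range: tuple[int, int] = (40, 110),
) -> LifeTable:
    """Build a synthetic life table.

    ``model`` is ``"gompertz_makeham"`` (qx = 1 - exp(-(lam + alpha *
    exp(beta * age))), monotone increasing for beta > 0) or ``"flat"``
    (constant qx = params["q"]).  The final age is capped at qx = 1 so
    the table closes out.
    """
    lo, hi = age_range
    if hi < lo:
        raise ValueError(f"empty age range {age_range}")
    qx: dict[int, float] = {}
    if model == "gompertz_makeham":
        p = dict(GM_DEFAULTS, **(params or {}))
        for age in range(lo, hi + 1):
            hazard = p["lam"] + p["alpha"] * math.exp(p["beta"] * age)
            q = 1.0 - math.exp(-hazard)
            if not (0.0 <= q <= 1.0):
                raise ValueError(f"qx out of [0, 1] at age {age}: {q}")
            qx[age] = q
    elif model == "flat":
        q = float((params or {}).get("q", 0.0))
        if not (0.0 <= q <= 1.0):
            raise ValueError(f"flat qx {q} outside [0, 1]")
        qx = {age: q for age in range(lo, hi + 1)}
    else:
        raise ValueError(f"unknown life-table model {model!r}")
    qx[hi] = 1.0  # close the table
    return LifeTable(qx)


def make_cohort(
    spec: ScenarioSpec, params: ParamSet, seed: int = 0
) -> pd.DataFrame:
    """Simulate a patient cohort for one scenario.

    Columns: id, age, sex (F/M), scenario_id, true_lesion
    (benign/malignant).  Sex ~ Bernoulli(female_ratio); the
    malignant-branch fraction applies to BD-IPMN scenarios only.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5EED]))
    n = params.cohort_size
    female = rng.random(n) < spec.female_ratio
    p_malignant = (
        params.frac_malignant_bd_ipmn if spec.cyst_type == "BD-IPMN" else 0.0
    )
    malignant = rng.random(n) < p_malignant
    return pd.DataFrame(
        {
            "id": np.arange(1, n + 1),
            "age": np.full(n, spec.base_age),
            "sex": np.where(female, "F", "M"),
            "scenario_id": spec.scenario_id,
            "true_lesion": np.where(malignant, "malignant", "benign"),
        }
    )


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_fixtures(
    output_dir: str,
    params: ParamSet | None = None,
    scenarios: Sequence[ScenarioSpec] | None = None,
    seed: int = 0,
) -> dict[str, str]:
    """Write every input fixture the pipeline needs; return a manifest.

    Files: life_table.csv, cohort_<scenario>.csv per scenario,
    default_config.yaml, published_reference.csv (published base-case
    values with provenance notes).  The manifest maps file name to
    sha256 and is also written as manifest.json.  Deterministic for a
    given seed.
    """
    params = params or ParamSet()
    scenarios = list(scenarios or SCENARIOS.values())
    os.makedirs(output_dir, exist_ok=True)
    written: list[str] = []

    lt_path = os.path.join(output_dir, "life_table.csv")
    make_life_table().to_csv(lt_path)
    written.append("life_table.csv")

    for spec in scenarios:
        name = f"cohort_{spec.scenario_id}.csv"
        make_cohort(spec, params, seed=seed).to_csv(
            os.path.join(output_dir, name), index=False
        )
        written.append(name)

    cfg_path = os.path.join(output_dir, "default_config.yaml")
    with open(cfg_path, "w", encoding="utf-8") as fh:
        fh.write(serialize_params(params, scenarios))
    written.append("default_config.yaml")

    ref_path = os.path.join(output_dir, "published_reference.csv")
    ref = pd.DataFrame(
        [
            {
                "scenario_id": r.scenario_id,
                "strategy_id": r.strategy_id,
                "cost": r.cost,
                "effectiveness": r.effectiveness,
                "icer_printed": r.icer_printed,
                "provenance": "published base-case table",
            }
            for r in REFERENCE_CEA.values()
        ]
    )
    ref.to_csv(ref_path, index=False)
    written.append("published_reference.csv")

    manifest = {name: _sha256(os.path.join(output_dir, name)) for name in written}
    with open(os.path.join(output_dir, "manifest.json"), "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
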