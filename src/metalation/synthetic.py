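"""Synthetic qPCR tables with known ground-truth metal availabilities.

The generator runs the calibration pipeline *forwards*: a chosen buffered
concentration per (condition, sensor) is mapped through the sensor's
thermodynamic response to an occupancy, the occupancy back through the
linear 0.01/0.99 calibration to a fold change, the fold change to a ddCq,
and the ddCq to per-replicate quantification cycles with optional Gaussian
noise.  Two boundary pseudo-conditions are emitted whose fold changes are 1
and fold_change_max by construction, so a calibration run on the generated
table has genuine anchors.  Reference-gene rows (one set per condition) can
carry a configurable Cq drift to exercise the reference-shift QC rule.

The result is a table a qPCR instrument could plausibly have produced plus
a truth sidecar, enabling end-to-end parameter-recovery tests with no
external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .qpcr import BoundarySet
from .sensors import SensorClass, SensorParams, sensor_theta

__all__ = ["SyntheticScenario", "generate_synthetic_qpcr", "scenario_boundaries"]

#: Default scenario dimensions: biological triplicates with instrument-level
#: Cq scatter of 0.1 cycles, reference gene near Cq 15 and regulated genes
#: near Cq 22 at minimum expression, clean no-template controls at Cq 40.
DEFAULT_REPLICATES = 3
DEFAULT_NOISE_SD = 0.1


@dataclass(frozen=True)
class SyntheticScenario:
    """Ground truth and nuisance parameters for one simulated experiment.

    ``truth`` maps condition -> sensor name -> buffered metal concentration
    (M); every truth must lie within the sensor's responsive window so the
    forward map stays inside the 0.01-0.99 calibration range.
    ``fold_change_max`` fixes the dynamic range of each gene's expression
    (the fold change emitted for the max-expression boundary condition).
    ``ref_drift`` adds cycles to the reference gene in chosen conditions to
    exercise QC; ``mrt_offsets`` likewise perturbs minus-RT controls.
    """

    truth: Mapping[str, Mapping[str, float]]
    fold_change_max: Mapping[str, float]
    n_replicates: int = DEFAULT_REPLICATES
    cq_noise_sd: float = DEFAULT_NOISE_SD
    reference_cq: float = 15.0
    base_cq: float = 22.0
    control_cq: float = 40.0
    ref_drift: Mapping[str, float] = field(default_factory=dict)
    mrt_offsets: Mapping[str, float] = field(default_factory=dict)
    min_condition: str = "boundary_min"
    max_condition: str = "boundary_max"

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.cq_noise_sd < 0:
            raise ValueError("cq_noise_sd must be >= 0")
        for sensor, fc in self.fold_change_max.items():
            if not fc > 1:
                raise ValueError(f"fold_change_max for {sensor} must exceed 1, got {fc}")


def _theta_to_fold_change(theta: float, fc_max: float, cls: SensorClass) -> float:
    """Invert the linear 0.01/0.99 calibration: occupancy -> fold change."""
    if cls is SensorClass.ACTIVATOR:
        frac = (theta - 0.01) / 0.98
    else:
        frac = (0.99 - theta) / 0.98
    return 1.0 + frac * (fc_max - 1.0)


def generate_synthetic_qpcr(
    scenario: SyntheticScenario,
    sensors: dict[str, SensorParams],
    seed: int,
    abundance_mode: str = "interpolate",
) -> tuple[pd.DataFrame, dict]:
    """Fabricate a Cq table (gene, condition, replicate, cq, ntc_cq, mrt_cq).

    Deterministic for a fixed seed.  Raises if a truth concentration maps
    outside a sensor's calibrated occupancy window, naming the sensor and
    condition, since such a truth could never be recovered.
    """
    rng = np.random.default_rng(seed)
    sensor_names = sorted(
        {s for cond in scenario.truth.values() for s in cond}
    )
    for name in sensor_names:
        if name not in sensors:
            raise KeyError(f"scenario references unknown sensor {name!r}")
        if name not in scenario.fold_change_max:
            raise KeyError(f"scenario missing fold_change_max for sensor {name!r}")

    # forward map: truth concentration -> theta -> fold change, per condition
    fold_changes: dict[str, dict[str, float]] = {name: {} for name in sensor_names}
    for name in sensor_names:
        params = sensors[name]
        cls = params.sensor_class
        fc_max = scenario.fold_change_max[name]
        fold_changes[name][scenario.min_condition] = 1.0
        fold_changes[name][scenario.max_condition] = fc_max
        for condition in sorted(scenario.truth):
            conc = scenario.truth[condition].get(name)
            if conc is None:
                continue
            theta = sensor_theta(params, conc, abundance_mode)
            if not (0.01 <= theta <= 0.99):
                raise ValueError(
                    f"truth {conc:g} M for sensor {name} in condition "
                    f"{condition!r} maps to occupancy {theta:.4f}, outside the "
                    "calibrated window [0.01, 0.99]"
                )
            fold_changes[name][condition] = _theta_to_fold_change(theta, fc_max, cls)

    conditions = [scenario.min_condition, scenario.max_condition] + sorted(scenario.truth)
    rows: list[dict] = []
    for condition in conditions:
        drift = scenario.ref_drift.get(condition, 0.0)
        mrt_off = scenario.mrt_offsets.get(condition, 0.0)
        for rep in range(1, scenario.n_replicates + 1):
            noise = rng.normal(0.0, scenario.cq_noise_sd) if scenario.cq_noise_sd else 0.0
            ref_cq = scenario.reference_cq + drift + noise
            rows.append(
                {
                    "gene": "rpoD",
                    "condition": condition,
                    "replicate": rep,
                    "cq": ref_cq,
                    "ntc_cq": scenario.control_cq,
                    "mrt_cq": scenario.control_cq + mrt_off,
                }
            )
        for name in sensor_names:
            fc = fold_changes[name].get(condition)
            if fc is None:
                continue
            gene = sensors[name].gene or name
            for rep in range(1, scenario.n_replicates + 1):
                noise = rng.normal(0.0, scenario.cq_noise_sd) if scenario.cq_noise_sd else 0.0
                cq = scenario.base_cq - math.log2(fc) + scenario.ref_drift.get(condition, 0.0) + noise
                rows.append(
                    {
                        "gene": gene,
                        "condition": condition,
                        "replicate": rep,
                        "cq": cq,
                        "ntc_cq": scenario.control_cq,
                        "mrt_cq": np.nan,
                    }
                )
    table = pd.DataFrame(rows)
    truth_sidecar = {
        "seed": int(seed),
        "noise_sd": scenario.cq_noise_sd,
        "n_replicates": scenario.n_replicates,
        "min_condition": scenario.min_condition,
        "max_condition": scenario.max_condition,
        "truth_concentrations_M": {
            cond: dict(per_sensor) for cond, per_sensor in scenario.truth.items()
        },
        "fold_change_max": dict(scenario.fold_change_max),
    }
    return table, truth_sidecar


def scenario_boundaries(
    scenario: SyntheticScenario, sensors: dict[str, SensorParams]
) -> list[BoundarySet]:
    """Boundary declarations matching the generator's pseudo-conditions."""
    names = sorted({s for cond in scenario.truth.values() for s in cond})
    return [
        BoundarySet(
            sensor=name,
            min_condition=scenario.min_condition,
            max_condition=scenario.max_condition,
        )
        for name in names
    ]
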