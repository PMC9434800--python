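"""From qPCR quantification cycles to buffered metal availabilities.

The ladder has five rungs:

1. :func:`qc_filter` -- reject samples whose no-template / minus-RT control
   amplifies too close to the cDNA sample, and whole conditions whose
   reference-gene Cq shifts by more than 2 cycles from the control
   condition (unless a second reference gene passes the same test).
2. :func:`fold_change` -- relative quantification by the 2^-ddCq method
   against a reference gene, with the minimum-expression condition of each
   regulated gene as baseline (fold change 1).
3. :func:`fractional_response` -- linear calibration of fold change onto
   normalized sensor-DNA occupancy between 0.01 and 0.99:

       theta_D  = 0.99 - 0.98 * (fc_obs - 1)/(fc_max - 1)   (repressors)
       theta_DM = 0.01 + 0.98 * (fc_obs - 1)/(fc_max - 1)   (activators)

   Minimum transcript abundance anchors maximum repressor-DNA occupancy
   (theta_D = 0.99) and minimum activator occupancy (theta_DM = 0.01);
   maximum abundance anchors the opposite end.  Outside that window gene
   expression no longer tracks availability, so out-of-window fold changes
   are clamped (with a warning), never extrapolated.
4. :func:`calibrate_availability` -- invert the sensor's thermodynamic
   response curve per biological replicate, then average the replicate
   *concentrations* (not the thetas) and report their SD.  Boundary
   conditions are anchored exactly at 0.01/0.99 and carry no SD.
5. :func:`zinc_midpoint` -- the zinc pool is bracketed by two sensors (Zur
   and ZntR); their single-number summary is the log-scale (geometric)
   midpoint of the two means.

:func:`run_calibration` chains the rungs over a whole Cq table.
"""

from __future__ import annotations

import json
import logging
import math
import statistics
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .chem import DEFAULT_CONSTANTS, Metal, ThermoConstants, concentration_to_free_energy
from .sensors import (
    ResponseRangeError,
    SensorClass,
    SensorParams,
    invert_response,
)

logger = logging.getLogger(__name__)

__all__ = [
    "REQUIRED_COLUMNS",
    "Exclusion",
    "ExclusionReport",
    "FoldChange",
    "FractionalResponse",
    "BoundarySet",
    "AvailabilityEstimate",
    "qc_filter",
    "fold_change",
    "fractional_response",
    "calibrate_availability",
    "zinc_midpoint",
    "run_calibration",
    "estimates_to_frame",
]

REQUIRED_COLUMNS = ("gene", "condition", "replicate", "cq")


@dataclass(frozen=True)
class Exclusion:
    rule: str  # "ref-shift" | "no-reference" | "control-margin-ntc" | "control-margin-rt"
    level: str  # "condition" | "sample"
    condition: str
    gene: Optional[str] = None
    replicate: Optional[object] = None
    detail: str = ""


@dataclass
class ExclusionReport:
    """Machine-readable record of every QC rejection and rescue."""

    exclusions: list[Exclusion] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    def add(self, exclusion: Exclusion) -> None:
        self.exclusions.append(exclusion)
        logger.warning(
            "QC exclusion [%s/%s] condition=%s gene=%s replicate=%s: %s",
            exclusion.rule,
            exclusion.level,
            exclusion.condition,
            exclusion.gene,
            exclusion.replicate,
            exclusion.detail,
        )

    def excluded_conditions(self) -> set[str]:
        return {e.condition for e in self.exclusions if e.level == "condition"}

    def to_json(self) -> str:
        return json.dumps(
            {
                "exclusions": [vars(e) for e in self.exclusions],
                "notes": self.notes,
            },
            indent=2,
            default=str,
        )


def _check_columns(records: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"Cq table missing required column(s): {', '.join(missing)}")


def qc_filter(
    records: pd.DataFrame,
    control_condition: str,
    reference_gene: str = "rpoD",
    second_reference: Optional[str] = "gyrA",
    shift_threshold: float = 2.0,
    control_margin: int = 10,
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Apply the two sample-rejection rules; return retained rows + report.

    Sample rule: a row is rejected when its no-template-control or
    minus-RT-control Cq, rounded to the nearest integer, is fewer than
    ``control_margin`` cycles above the sample Cq (the control reaction
    amplified something).

    Condition rule: a condition is dropped when its mean reference-gene Cq
    differs from the control condition's mean by more than
    ``shift_threshold`` cycles, unless a second reference gene is present
    and passes the same test (the condition is then rescued, with a note).
    Conditions lacking reference-gene rows are dropped with rule
    ``no-reference``.
    """
    _check_columns(records)
    report = ExclusionReport()
    df = records.copy()

    def control_ok(row, col: str, rule: str) -> bool:
        val = row.get(col)
        if val is None or (isinstance(val, float) and math.isnan(val)):
            return True
        margin = round(float(val) - float(row["cq"]))
        if margin < control_margin:
            report.add(
                Exclusion(
                    rule=rule,
                    level="sample",
                    condition=row["condition"],
                    gene=row["gene"],
                    replicate=row["replicate"],
                    detail=f"control Cq {val} only {margin} cycles above sample Cq {row['cq']}",
                )
            )
            return False
        return True

    keep = df.apply(
        lambda row: control_ok(row, "ntc_cq", "control-margin-ntc")
        and control_ok(row, "mrt_cq", "control-margin-rt"),
        axis=1,
    )
    df = df[keep] if len(df) else df

    ref = df[df["gene"] == reference_gene]
    control_ref = ref[ref["condition"] == control_condition]
    if control_ref.empty:
        raise ValueError(
            f"no {reference_gene} rows for control condition {control_condition!r}"
        )
    control_mean = control_ref["cq"].mean()

    ref2 = df[df["gene"] == second_reference] if second_reference else df.iloc[0:0]
    control2_mean = (
        ref2[ref2["condition"] == control_condition]["cq"].mean()
        if not ref2.empty
        else math.nan
    )

    dropped: set[str] = set()
    for condition in sorted(df["condition"].unique()):
        cond_ref = ref[ref["condition"] == condition]
        if cond_ref.empty:
            report.add(
                Exclusion(
                    rule="no-reference",
                    level="condition",
                    condition=condition,
                    gene=reference_gene,
                    detail=f"no {reference_gene} measurements for this condition",
                )
            )
            dropped.add(condition)
            continue
        shift = abs(cond_ref["cq"].mean() - control_mean)
        if shift <= shift_threshold:
            continue
        cond2 = ref2[ref2["condition"] == condition] if not ref2.empty else ref2
        if not cond2.empty and not math.isnan(control2_mean):
            shift2 = abs(cond2["cq"].mean() - control2_mean)
            if shift2 <= shift_threshold:
                report.notes.append(
                    f"condition {condition!r}: {reference_gene} shifted {shift:.2f} "
                    f"cycles but rescued by {second_reference} (shift {shift2:.2f})"
                )
                continue
        report.add(
            Exclusion(
                rule="ref-shift",
                level="condition",
                condition=condition,
                gene=reference_gene,
                detail=f"mean {reference_gene} Cq shifted {shift:.2f} > {shift_threshold} "
                f"cycles from control {control_condition!r}",
            )
        )
        dropped.add(condition)
    if dropped:
        df = df[~df["condition"].isin(dropped)]
    return df.reset_index(drop=True), report


@dataclass(frozen=True)
class FoldChange:
    """2^-ddCq fold change of one gene in one condition vs its baseline."""

    gene: str
    condition: str
    baseline_condition: str
    fold_change: float
    per_replicate: tuple[float, ...]


def _delta_cq(records: pd.DataFrame, gene: str, condition: str, reference_gene: str) -> pd.Series:
    """Per-replicate Cq(gene) - Cq(reference), matched on replicate id."""
    sub = records[records["condition"] == condition]
    gene_cq = sub[sub["gene"] == gene].groupby("replicate")["cq"].mean()
    ref_cq = sub[sub["gene"] == reference_gene].groupby("replicate")["cq"].mean()
    d = (gene_cq - ref_cq).dropna()
    if d.empty:
        raise ValueError(
            f"no paired {gene}/{reference_gene} replicates in condition {condition!r}"
        )
    return d


def fold_change(
    records: pd.DataFrame,
    gene: str,
    condition: str,
    baseline_condition: str,
    reference_gene: str = "rpoD",
) -> FoldChange:
    """Relative abundance of ``gene`` vs the baseline (minimum-expression)
    condition by the 2^-ddCq method.

    ddCq = mean dCq(condition) - mean dCq(baseline); per-replicate fold
    changes (against the baseline *mean*) are retained for SD propagation
    through the downstream inversion.
    """
    _check_columns(records)
    d_cond = _delta_cq(records, gene, condition, reference_gene)
    d_base = _delta_cq(records, gene, baseline_condition, reference_gene)
    ddcq = d_cond.mean() - d_base.mean()
    per_rep = tuple(2.0 ** -(d - d_base.mean()) for d in d_cond)
    return FoldChange(
        gene=gene,
        condition=condition,
        baseline_condition=baseline_condition,
        fold_change=2.0 ** -ddcq,
        per_replicate=per_rep,
    )


@dataclass(frozen=True)
class FractionalResponse:
    """Calibrated sensor occupancy theta in [0.01, 0.99] for one condition."""

    sensor: str
    condition: str
    theta: float
    readout: str  # "theta_D" or "theta_DM"
    fold_change_max: float
    clamped: bool = False


def fractional_response(
    fc_obs: float,
    fc_max: float,
    sensor_class: SensorClass,
) -> tuple[float, bool]:
    """Map an observed fold change onto occupancy within [0.01, 0.99].

    Returns ``(theta, clamped)``; ``clamped`` flags observed fold changes
    outside [1, fc_max], which are pinned to the nearest anchor because
    expression is insensitive to availability beyond the window.
    """
    if not (fc_max > 1.0):
        raise ValueError(f"fold_change_max must exceed 1, got {fc_max}")
    clamped = False
    if fc_obs < 1.0 or fc_obs > fc_max:
        logger.warning(
            "fold change %.4g outside calibration window [1, %.4g]; clamping", fc_obs, fc_max
        )
        fc_obs = min(max(fc_obs, 1.0), fc_max)
        clamped = True
    frac = (fc_obs - 1.0) / (fc_max - 1.0)
    if sensor_class is SensorClass.ACTIVATOR:
        theta = 0.01 + 0.98 * frac
    else:
        theta = 0.99 - 0.98 * frac
    return theta, clamped


@dataclass(frozen=True)
class BoundarySet:
    """Calibration anchors for one sensor (optionally one growth regime).

    ``min_condition`` shows minimum transcript abundance (theta_D anchored
    at 0.99, theta_DM at 0.01); ``max_condition`` the maximum.  When a
    sensor needs regime-specific anchors (nickel sensing differs between
    aerobic and anaerobic growth), ship one BoundarySet per regime and list
    which conditions each governs in ``conditions``.
    """

    sensor: str
    min_condition: str
    max_condition: str
    conditions: Optional[tuple[str, ...]] = None
    regime: str = ""

    def governs(self, condition: str) -> bool:
        if self.conditions is None:
            return True
        return condition in self.conditions or condition in (
            self.min_condition,
            self.max_condition,
        )


@dataclass(frozen=True)
class AvailabilityEstimate:
    """Buffered metal concentration inferred for one condition.

    Boundary-defining conditions carry ``sd=None`` (the anchor is assigned,
    not replicated).  ``free_energy`` is RT ln of the mean concentration.
    """

    metal: Metal
    condition: str
    concentration: float
    sd: Optional[float]
    free_energy: float
    sensors: tuple[str, ...]
    n_replicates: int = 0
    boundary: bool = False

    def __post_init__(self) -> None:
        if not (self.concentration > 0 and math.isfinite(self.concentration)):
            raise ValueError(f"estimated concentration must be positive, got {self.concentration}")
        if self.sd is not None and self.sd < 0:
            raise ValueError("SD must be non-negative when present")


def calibrate_availability(
    replicate_thetas: Sequence[float],
    params: SensorParams,
    condition: str,
    boundary: bool = False,
    constants: ThermoConstants = DEFAULT_CONSTANTS,
    abundance_mode: str = "interpolate",
) -> AvailabilityEstimate:
    """Invert each replicate's occupancy and aggregate the concentrations.

    Replicates are inverted individually and the resulting concentrations
    averaged (their SD reported), rather than averaging theta first: the
    replicate scatter of interest is in concentration space.  Out-of-range
    replicates are skipped with a warning; the estimate uses the remainder.
    Boundary conditions report no SD.
    """
    concentrations: list[float] = []
    for i, theta in enumerate(replicate_thetas, start=1):
        try:
            concentrations.append(
                invert_response(params, theta, abundance_mode=abundance_mode)
            )
        except ResponseRangeError as exc:
            logger.warning(
                "%s %s replicate %d: %s; replicate dropped", params.name, condition, i, exc
            )
    if not concentrations:
        raise ResponseRangeError(
            params.name, float("nan"), *(0.0, 1.0)
        )
    mean = sum(concentrations) / len(concentrations)
    if boundary or len(concentrations) < 2:
        sd = None if boundary else 0.0
    else:
        sd = statistics.stdev(concentrations)
    return AvailabilityEstimate(
        metal=params.metal,
        condition=condition,
        concentration=mean,
        sd=sd,
        free_energy=concentration_to_free_energy(mean, constants),
        sensors=(params.name,),
        n_replicates=len(concentrations),
        boundary=boundary,
    )


def zinc_midpoint(
    zur_estimate: AvailabilityEstimate,
    zntr_estimate: AvailabilityEstimate,
    constants: ThermoConstants = DEFAULT_CONSTANTS,
) -> AvailabilityEstimate:
    """Geometric-mean (log-scale midpoint) zinc availability from Zur + ZntR."""
    for est in (zur_estimate, zntr_estimate):
        if est.metal is not Metal.ZN:
            raise ValueError(f"zinc midpoint requires Zn2+ estimates, got {est.metal.value}")
    if zur_estimate.condition != zntr_estimate.condition:
        raise ValueError(
            "zinc midpoint requires estimates from the same condition, got "
            f"{zur_estimate.condition!r} and {zntr_estimate.condition!r}"
        )
    mid = math.sqrt(zur_estimate.concentration * zntr_estimate.concentration)
    return AvailabilityEstimate(
        metal=Metal.ZN,
        condition=zur_estimate.condition,
        concentration=mid,
        sd=None,
        free_energy=concentration_to_free_energy(mid, constants),
        sensors=zur_estimate.sensors + zntr_estimate.sensors,
        n_replicates=min(zur_estimate.n_replicates, zntr_estimate.n_replicates),
        boundary=zur_estimate.boundary or zntr_estimate.boundary,
    )


def run_calibration(
    records: pd.DataFrame,
    sensors: dict[str, SensorParams],
    boundaries: Iterable[BoundarySet],
    control_condition: str,
    reference_gene: str = "rpoD",
    second_reference: Optional[str] = "gyrA",
    conditions: Optional[Sequence[str]] = None,
    constants: ThermoConstants = DEFAULT_CONSTANTS,
    abundance_mode: str = "interpolate",
) -> tuple[list[AvailabilityEstimate], ExclusionReport]:
    """Full pipeline: QC -> fold changes -> theta -> inversion -> midpoint.

    For every boundary set, the governed conditions (default: all QC-passed
    conditions with data for the sensor's gene) are calibrated against that
    set's anchors.  When both zinc sensors yield an estimate for a
    condition, a combined ``Zur+ZntR`` midpoint estimate is appended.
    """
    passed, report = qc_filter(
        records,
        control_condition=control_condition,
        reference_gene=reference_gene,
        second_reference=second_reference,
    )
    estimates: list[AvailabilityEstimate] = []
    for bset in boundaries:
        params = sensors[bset.sensor]
        gene = params.gene
        if gene is None:
            raise ValueError(f"sensor {params.name} has no associated gene")
        if bset.min_condition in report.excluded_conditions() or bset.max_condition in report.excluded_conditions():
            report.notes.append(
                f"boundary set for {bset.sensor} skipped: an anchor condition was excluded by QC"
            )
            continue
        fc_max = fold_change(
            passed, gene, bset.max_condition, bset.min_condition, reference_gene
        ).fold_change
        gene_conditions = sorted(
            passed[passed["gene"] == gene]["condition"].unique()
        )
        for condition in gene_conditions:
            if conditions is not None and condition not in conditions:
                continue
            if not bset.governs(condition):
                continue
            is_boundary = condition in (bset.min_condition, bset.max_condition)
            if is_boundary:
                anchor_fc = 1.0 if condition == bset.min_condition else fc_max
                theta, _ = fractional_response(anchor_fc, fc_max, params.sensor_class)
                thetas = [theta]
            else:
                fc = fold_change(passed, gene, condition, bset.min_condition, reference_gene)
                thetas = [
                    fractional_response(f, fc_max, params.sensor_class)[0]
                    for f in fc.per_replicate
                ]
            estimates.append(
                calibrate_availability(
                    thetas,
                    params,
                    condition,
                    boundary=is_boundary,
                    constants=constants,
                    abundance_mode=abundance_mode,
                )
            )
    zn = [e for e in estimates if e.metal is Metal.ZN]
    by_condition: dict[str, dict[str, AvailabilityEstimate]] = {}
    for e in zn:
        by_condition.setdefault(e.condition, {})[e.sensors[0]] = e
    for condition, pair in sorted(by_condition.items()):
        if "Zur" in pair and "ZntR" in pair:
            estimates.append(zinc_midpoint(pair["Zur"], pair["ZntR"], constants))
    return estimates, report


def estimates_to_frame(estimates: Sequence[AvailabilityEstimate]) -> pd.DataFrame:
    """Availability table: one row per (metal, sensor(s), condition)."""
    return pd.DataFrame(
        {
            "metal": [e.metal.value for e in estimates],
            "sensor": ["+".join(e.sensors) for e in estimates],
            "condition": [e.condition for e in estimates],
            "concentration_M": [e.concentration for e in estimates],
            "sd_M": [e.sd for e in estimates],
            "delta_g_kj_mol": [e.free_energy for e in estimates],
            "n_replicates": [e.n_replicates for e in estimates],
            "boundary": [e.boundary for e in estimates],
        }
    )
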