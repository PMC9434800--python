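"""Thermodynamic model of DNA-binding metal sensors.

A metalloregulator is modelled as five species at equilibrium with a fixed
(buffered) free metal concentration ``[M]``:

    P    apo sensor                 P + M  <-> PM    K_metal
    PM   metal-bound sensor         P + D  <-> PD    K_DNA_apo
    D    free operator DNA          PM + D <-> PMD   K_DNA_holo
    PD   apo-sensor-bound operator
    PMD  holo-sensor-bound operator

All equilibrium constants are dissociation constants (molar).  The buffered
pool is treated as an infinite reservoir: ``[M]`` is an input, not depleted.
Metal binding to DNA-bound sensor is implied by thermodynamic cycle closure
(K_metal * K_DNA_holo / K_DNA_apo), not an independent constant.

Sensor and operator totals come from molecules-per-cell divided by
(Avogadro * cell volume).  Under both mass balances the system reduces to a
single quadratic in free operator, solved in closed form with a
cancellation-safe root; the brute-force invariant checks live in the tests.

The regulatory readout is the normalized operator occupancy by the
*repressing* species (theta_D = PD/D_total for de-repressors, PMD/D_total
for co-repressors) or by the metalated activator (theta_DM = PMD/D_total).
Readouts are monotone in ``[M]``, which makes the response invertible:
:func:`invert_response` maps an occupancy back to the buffered metal
concentration by root-finding on log10[M].
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional

import numpy as np
import yaml
from scipy.constants import Avogadro
from scipy.optimize import brentq

from .chem import Metal

__all__ = [
    "SensorClass",
    "SensorParams",
    "SpeciesState",
    "ResponseCurve",
    "ResponseRangeError",
    "solve_equilibrium",
    "response_occupancy",
    "sensor_theta",
    "attainable_range",
    "invert_response",
    "build_response_curve",
    "load_sensor_set",
    "DEFAULT_BRACKET",
]

#: Bisection bracket on buffered free metal (molar): spans every availability
#: a bacterial cytosol plausibly buffers, femtomolar-to-centimolar with margin.
DEFAULT_BRACKET = (1e-25, 1e-1)


class SensorClass(enum.Enum):
    """Regulatory logic of a sensor.

    * ``CO_REPRESSOR`` -- holo sensor represses (MntR, Fur, Zur, NikR);
      readout theta_D rises with metal.
    * ``DE_REPRESSOR`` -- apo sensor represses (RcnR); readout theta_D
      falls with metal.
    * ``ACTIVATOR`` -- holo sensor activates (ZntR, CueR); readout theta_DM
      rises with metal.
    """

    CO_REPRESSOR = "co-repressor"
    DE_REPRESSOR = "de-repressor"
    ACTIVATOR = "activator"

    @property
    def readout(self) -> str:
        return "theta_DM" if self is SensorClass.ACTIVATOR else "theta_D"

    @property
    def increasing(self) -> bool:
        """True if the readout rises with metal availability."""
        return self is not SensorClass.DE_REPRESSOR


class ResponseRangeError(ValueError):
    """Target occupancy outside the sensor's attainable response range."""

    def __init__(self, sensor: str, target: float, lo: float, hi: float):
        self.attainable = (lo, hi)
        super().__init__(
            f"theta={target:g} is outside the attainable occupancy range "
            f"[{lo:.6g}, {hi:.6g}] of sensor {sensor}"
        )


class ConvergenceError(RuntimeError):
    """Equilibrium or inversion failed to converge for a parameter set."""


@dataclass(frozen=True)
class SensorParams:
    """Thermodynamic constants of one metalloregulator.

    Parameters
    ----------
    name : sensor protein name (e.g. ``NikR``).
    metal : cognate :class:`~metalation.chem.Metal`.
    sensor_class : regulatory logic.
    k_metal : dissociation constant of the tightest allosteric metal site (M).
    k_dna_apo, k_dna_holo : operator dissociation constants of the apo and
        metalated sensor (M).  Metal must tighten DNA binding for
        co-repressors/activators and weaken it for de-repressors.
    abundance_low, abundance_high : sensor molecules per cell at low and
        elevated cognate metal.
    n_targets : operator sites per cell (>= 1).
    cell_volume : litres; default 1 fL, a typical bacterial cytosol.
    gene : regulated transcript used as the qPCR proxy (optional).
    """

    name: str
    metal: Metal
    sensor_class: SensorClass
    k_metal: float
    k_dna_apo: float
    k_dna_holo: float
    abundance_low: float
    abundance_high: float
    n_targets: int
    cell_volume: float = 1.0e-15
    gene: Optional[str] = None

    def __post_init__(self) -> None:
        for attr in ("k_metal", "k_dna_apo", "k_dna_holo", "cell_volume"):
            v = getattr(self, attr)
            if not (v > 0 and math.isfinite(v)):
                raise ValueError(f"{self.name}: {attr} must be positive, got {v}")
        if self.abundance_low <= 0 or self.abundance_high <= 0:
            raise ValueError(f"{self.name}: sensor abundances must be positive")
        if self.abundance_low > self.abundance_high:
            raise ValueError(
                f"{self.name}: abundance_low ({self.abundance_low}) exceeds "
                f"abundance_high ({self.abundance_high})"
            )
        if not (isinstance(self.n_targets, int) and self.n_targets >= 1):
            raise ValueError(f"{self.name}: n_targets must be an integer >= 1")
        if self.sensor_class is SensorClass.DE_REPRESSOR:
            if not self.k_dna_apo < self.k_dna_holo:
                raise ValueError(
                    f"{self.name}: de-repressor requires k_dna_apo < k_dna_holo"
                )
        else:
            if not self.k_dna_holo < self.k_dna_apo:
                raise ValueError(
                    f"{self.name}: {self.sensor_class.value} requires "
                    "k_dna_holo < k_dna_apo (metal tightens DNA binding)"
                )

    def molecules_to_molar(self, n: float) -> float:
        return n / (Avogadro * self.cell_volume)

    @property
    def operator_total(self) -> float:
        """Total operator concentration (M)."""
        return self.molecules_to_molar(self.n_targets)

    def sensor_total(self, free_metal: float, abundance_mode: str = "interpolate") -> float:
        """Total sensor concentration (M) at a given buffered metal level.

        ``abundance_mode`` blends the low- and high-metal abundances:
        ``interpolate`` (default) weights them by the sensor's fractional
        metal saturation [M]/([M]+K_metal) -- the apo/holo partition of free
        sensor, which is independent of the DNA equilibria; ``low``,
        ``high`` and ``mean`` use the respective fixed values.
        """
        lo, hi = self.abundance_low, self.abundance_high
        if abundance_mode == "low":
            n = lo
        elif abundance_mode == "high":
            n = hi
        elif abundance_mode == "mean":
            n = 0.5 * (lo + hi)
        elif abundance_mode == "interpolate":
            sat = free_metal / (free_metal + self.k_metal)
            n = lo + (hi - lo) * sat
        else:
            raise ValueError(f"unknown abundance_mode {abundance_mode!r}")
        return self.molecules_to_molar(n)


@dataclass(frozen=True)
class SpeciesState:
    """Solved equilibrium concentrations (M) of the five sensor species."""

    p: float
    pm: float
    d: float
    pd: float
    pmd: float
    free_metal: float
    sensor_total: float
    operator_total: float

    def mass_balance_errors(self) -> tuple[float, float]:
        """Relative sensor- and operator-balance residuals."""
        s = (self.p + self.pm + self.pd + self.pmd - self.sensor_total) / self.sensor_total
        o = (self.d + self.pd + self.pmd - self.operator_total) / self.operator_total
        return abs(s), abs(o)

    def equilibrium_ratios(self) -> dict[str, float]:
        """Reconstructed dissociation constants (NaN where undefined at [M]=0)."""
        with np.errstate(divide="ignore", invalid="ignore"):
            return {
                "k_metal": self.p * self.free_metal / self.pm if self.pm else math.nan,
                "k_dna_apo": self.p * self.d / self.pd if self.pd else math.nan,
                "k_dna_holo": self.pm * self.d / self.pmd if self.pmd else math.nan,
            }


def solve_equilibrium(
    params: SensorParams,
    free_metal: float,
    abundance_mode: str = "interpolate",
) -> SpeciesState:
    """Solve the coupled sensor/operator equilibria at fixed buffered [M].

    Substituting the three equilibrium relations into the two mass balances
    gives ``P = P_tot / (a + b*D)`` with ``a = 1 + M/K_metal`` and
    ``b = 1/K_dna_apo + M/(K_metal*K_dna_holo)``, and a single quadratic

        b*D^2 + (a + b*(P_tot - D_tot))*D - a*D_tot = 0

    whose unique non-negative root is taken (rearranged to avoid
    catastrophic cancellation when the linear coefficient dominates).
    """
    if not (free_metal >= 0 and math.isfinite(free_metal)):
        raise ValueError(f"free_metal must be a finite non-negative molar value, got {free_metal}")
    m = float(free_metal)
    p_tot = params.sensor_total(m, abundance_mode)
    d_tot = params.operator_total

    a = 1.0 + m / params.k_metal
    b = 1.0 / params.k_dna_apo + m / (params.k_metal * params.k_dna_holo)
    lin = a + b * (p_tot - d_tot)
    # roots of b*D^2 + lin*D - a*d_tot = 0
    disc = lin * lin + 4.0 * b * a * d_tot
    sq = math.sqrt(disc)
    if lin >= 0:
        d = 2.0 * a * d_tot / (lin + sq)
    else:
        d = (sq - lin) / (2.0 * b)
    p = p_tot / (a + b * d)
    pm = p * m / params.k_metal
    pd = p * d / params.k_dna_apo
    pmd = pm * d / params.k_dna_holo

    state = SpeciesState(p, pm, d, pd, pmd, m, p_tot, d_tot)
    s_err, o_err = state.mass_balance_errors()
    if not (s_err < 1e-8 and o_err < 1e-8):
        raise ConvergenceError(
            f"equilibrium solution for {params.name} at [M]={m:g} violates mass "
            f"balance (sensor {s_err:.2e}, operator {o_err:.2e})"
        )
    return state


def response_occupancy(state: SpeciesState, sensor_class: SensorClass) -> float:
    """Normalized operator occupancy by the regulating species, in [0, 1]."""
    if sensor_class is SensorClass.DE_REPRESSOR:
        bound = state.pd
    else:  # co-repressor theta_D and activator theta_DM are both PMD-based
        bound = state.pmd
    return min(1.0, max(0.0, bound / state.operator_total))


def sensor_theta(
    params: SensorParams,
    free_metal: float,
    abundance_mode: str = "interpolate",
) -> float:
    """Forward response: buffered [M] -> occupancy readout."""
    state = solve_equilibrium(params, free_metal, abundance_mode)
    return response_occupancy(state, params.sensor_class)


def attainable_range(
    params: SensorParams,
    bracket: tuple[float, float] = DEFAULT_BRACKET,
    abundance_mode: str = "interpolate",
) -> tuple[float, float]:
    """Occupancy interval reachable within the metal bracket (lo <= hi)."""
    t0 = sensor_theta(params, bracket[0], abundance_mode)
    t1 = sensor_theta(params, bracket[1], abundance_mode)
    return (min(t0, t1), max(t0, t1))


def invert_response(
    params: SensorParams,
    theta_target: float,
    bracket: tuple[float, float] = DEFAULT_BRACKET,
    abundance_mode: str = "interpolate",
    rtol: float = 1e-6,
) -> float:
    """Buffered metal concentration (M) at which the readout equals the target.

    Root-finds on log10[M] over ``bracket``; the readout's monotonicity in
    [M] (direction set by the sensor class) makes the root unique.  Targets
    outside the attainable occupancy interval raise
    :class:`ResponseRangeError` reporting that interval.
    """
    if not (0.0 < theta_target < 1.0):
        raise ResponseRangeError(params.name, theta_target, *attainable_range(params, bracket, abundance_mode))
    lo, hi = attainable_range(params, bracket, abundance_mode)
    if not (lo <= theta_target <= hi):
        raise ResponseRangeError(params.name, theta_target, lo, hi)

    def f(log_m: float) -> float:
        return sensor_theta(params, 10.0 ** log_m, abundance_mode) - theta_target

    try:
        root = brentq(
            f,
            math.log10(bracket[0]),
            math.log10(bracket[1]),
            xtol=rtol / math.log(10.0),
            maxiter=200,
        )
    except Exception as exc:  # pragma: no cover - bracketing guarded above
        raise ConvergenceError(
            f"inversion failed for {params.name} at theta={theta_target}: {exc}"
        ) from exc
    return 10.0 ** root


@dataclass
class ResponseCurve:
    """A sensor's occupancy readout over a log-spaced metal grid.

    ``boundaries`` maps the two calibration anchors (occupancy 0.01 and
    0.99) to buffered concentrations; ``midpoint`` is their log-scale
    midpoint, the conventional single-number summary of the dynamic range.
    """

    sensor: str
    readout: str
    concentrations: np.ndarray
    theta: np.ndarray
    boundaries: dict[float, float] = field(default_factory=dict)
    midpoint: Optional[float] = None
    warnings: list[str] = field(default_factory=list)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"concentration_M": self.concentrations, self.readout: self.theta}
        )


def build_response_curve(
    params: SensorParams,
    n_points: int = 200,
    bracket: tuple[float, float] = DEFAULT_BRACKET,
    abundance_mode: str = "interpolate",
    anchors: tuple[float, float] = (0.01, 0.99),
) -> ResponseCurve:
    """Tabulate the response over ``bracket`` and locate the anchor points.

    The anchors (defaults 0.01/0.99) delimit the dynamic range within which
    transcript fold changes track metal availability; the reported midpoint
    is ``10**((log10 b1 + log10 b2)/2)``.  A bracket too narrow to contain
    an anchor is recorded as a warning in the curve metadata rather than an
    error, so partial curves remain plottable.
    """
    grid = np.logspace(math.log10(bracket[0]), math.log10(bracket[1]), n_points)
    theta = np.array([sensor_theta(params, c, abundance_mode) for c in grid])
    curve = ResponseCurve(
        sensor=params.name,
        readout=params.sensor_class.readout,
        concentrations=grid,
        theta=theta,
    )
    logs = []
    for anchor in anchors:
        try:
            c = invert_response(params, anchor, bracket, abundance_mode)
        except ResponseRangeError as exc:
            curve.warnings.append(
                f"anchor theta={anchor} unattainable within bracket "
                f"[{bracket[0]:g}, {bracket[1]:g}] M: {exc}"
            )
            continue
        curve.boundaries[anchor] = c
        logs.append(math.log10(c))
    if len(logs) == 2:
        curve.midpoint = 10.0 ** (0.5 * (logs[0] + logs[1]))
    return curve


def _params_from_record(name: str, rec: dict, default_volume: float) -> SensorParams:
    return SensorParams(
        name=name,
        metal=Metal.parse(rec["metal"]),
        sensor_class=SensorClass(rec["class"]),
        k_metal=float(rec["k_metal"]),
        k_dna_apo=float(rec["k_dna_apo"]),
        k_dna_holo=float(rec["k_dna_holo"]),
        abundance_low=float(rec["abundance_low"]),
        abundance_high=float(rec["abundance_high"]),
        n_targets=int(rec["n_targets"]),
        cell_volume=float(rec.get("cell_volume", default_volume)),
        gene=rec.get("gene"),
    )


def load_sensor_set(path=None) -> dict[str, SensorParams]:
    """Load sensor parameter sets from YAML.

    With no path, loads the packaged *synthetic* placeholder set (see its
    ``provenance`` field): internally consistent, plausible constants for
    the seven sensors, intended for simulation and testing, not as measured
    values for any organism.
    """
    if path is None:
        text = (
            resources.files("metalation").joinpath("data/sensors_synthetic.yaml").read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    doc = yaml.safe_load(text)
    default_volume = float(doc.get("cell_volume", 1.0e-15))
    return {
        name: _params_from_record(name, rec, default_volume)
        for name, rec in doc["sensors"].items()
    }
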