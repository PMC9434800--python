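"""Competitive metalation calculators.

Given a condition's buffered metal availabilities and a molecule's metal
dissociation constants, predict the fractional occupancy of a single 1:1
metal site under inter-metal competition, capping total occupancy at a
stoichiometry of 1.  For enabled metals *i* with ratio
``r_i = [M_i]/K_D,i``, the site behaves as a binding polynomial:

    theta_i = r_i / (1 + sum_j r_j)

The "1 +" term is the unmetalated site; competition from the intracellular
buffer is implicit in the fixed buffered free concentrations.  The identical
result in free-energy form, with ddG_i = RT ln K_D,i - RT ln [M_i],

    theta_i = exp(-ddG_i/RT) / (1 + sum_j exp(-ddG_j/RT))

is exposed separately so the two routes can be cross-checked.  The metal
with the most negative ddG (largest favourable gradient from the available
pool to the molecule) dominates.

The module assumes the molecule does not deplete the buffered pools and a
preformed 1:1 site; multi-molecule assemblies with beta (M^-2) affinities
are out of scope.
"""

from __future__ import annotations

import csv
import io
import json
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping, Optional, Sequence

import yaml

from .chem import (
    DEFAULT_CONSTANTS,
    Metal,
    ThermoConstants,
    concentration_to_free_energy,
    kd_to_free_energy,
)

__all__ = [
    "AvailabilityPreset",
    "ProteinAffinitySet",
    "MetalOccupancy",
    "MetalationResult",
    "load_preset",
    "available_presets",
    "load_affinity_set",
    "compute_occupancy",
    "occupancy_from_ratios",
    "occupancy_from_free_energies",
    "whatif_availability",
    "render_report",
]


@dataclass(frozen=True)
class AvailabilityPreset:
    """Per-condition buffered metal concentrations (M) with optional SDs.

    ``boundary`` marks metals whose value anchored a calibration boundary
    (no SD by construction).  ``free_energy`` returns RT ln[M] per metal.
    """

    name: str
    concentrations: dict[Metal, float]
    sd: dict[Metal, float] = field(default_factory=dict)
    boundary: frozenset = frozenset()
    provenance: str = ""

    def __post_init__(self) -> None:
        for metal, c in self.concentrations.items():
            if not (c > 0 and math.isfinite(c)):
                raise ValueError(f"{self.name}: {metal.value} concentration must be positive, got {c}")
        for metal, s in self.sd.items():
            if s < 0:
                raise ValueError(f"{self.name}: {metal.value} SD must be non-negative")

    def free_energy(self, metal: Metal, constants: ThermoConstants = DEFAULT_CONSTANTS) -> float:
        return concentration_to_free_energy(self.concentrations[metal], constants)


def _load_preset_doc() -> dict:
    text = resources.files("metalation").joinpath("data/presets.yaml").read_text()
    return yaml.safe_load(text)


def available_presets() -> list[str]:
    """Names of the packaged condition presets (aerobic, anaerobic, h2o2)."""
    return sorted(_load_preset_doc()["presets"])


def load_preset(name: str, zinc: str = "midpoint") -> AvailabilityPreset:
    """Load a packaged availability preset.

    Two zinc sensors bracket the zinc pool; ``zinc`` selects which estimate
    the preset carries: ``"midpoint"`` (default; the log-scale midpoint of
    the two sensor means), ``"zur"`` or ``"zntr"``.
    """
    doc = _load_preset_doc()
    try:
        raw = doc["presets"][name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(sorted(doc['presets']))}"
        ) from None
    conc: dict[Metal, float] = {}
    sd: dict[Metal, float] = {}
    boundary = set()
    for sym, entry in raw.items():
        metal = Metal.parse(sym)
        if metal is Metal.ZN:
            if zinc not in entry:
                raise KeyError(f"zinc variant {zinc!r} not in preset {name!r}")
            entry = entry[zinc]
        conc[metal] = float(entry["concentration"])
        if "sd" in entry:
            sd[metal] = float(entry["sd"])
        if entry.get("boundary"):
            boundary.add(metal)
    return AvailabilityPreset(
        name=name,
        concentrations=conc,
        sd=sd,
        boundary=frozenset(boundary),
        provenance=doc.get("provenance", ""),
    )


@dataclass(frozen=True)
class ProteinAffinitySet:
    """A molecule's metal dissociation constants with per-metal toggles.

    Disabled metals need no K_D (simulations for proteins where some
    affinities are unknown); enabled metals must carry a positive K_D.
    """

    name: str
    kd: dict[Metal, float]
    enabled: frozenset = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.enabled is None:
            object.__setattr__(self, "enabled", frozenset(self.kd))
        for metal in self.enabled:
            if metal not in self.kd:
                raise ValueError(f"{self.name}: enabled metal {metal.value} has no K_D")
            v = self.kd[metal]
            if not (v > 0 and math.isfinite(v)):
                raise ValueError(f"{self.name}: K_D for {metal.value} must be positive, got {v}")

    def exclude(self, *metals: Metal) -> "ProteinAffinitySet":
        return replace(self, enabled=self.enabled - set(metals))


def load_affinity_set(path, name: Optional[str] = None) -> ProteinAffinitySet:
    """Read an affinity table (TSV/CSV: metal, kd_molar, enabled; or YAML)."""
    import pathlib

    path = pathlib.Path(path)
    if path.suffix in {".yaml", ".yml"}:
        doc = yaml.safe_load(path.read_text())
        kd = {Metal.parse(k): float(v) for k, v in doc["kd"].items()}
        enabled = frozenset(Metal.parse(m) for m in doc.get("enabled", doc["kd"]))
        return ProteinAffinitySet(name or doc.get("name", path.stem), kd, enabled)
    delim = "\t" if path.suffix in {".tsv", ".txt"} else ","
    kd: dict[Metal, float] = {}
    enabled = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        if reader.fieldnames is None or "metal" not in reader.fieldnames:
            raise ValueError(f"{path}: expected columns metal, kd_molar, enabled")
        for i, row in enumerate(reader, start=2):
            metal = Metal.parse(row["metal"])
            on = str(row.get("enabled", "true")).strip().lower() in {"1", "true", "yes", "on"}
            raw_kd = (row.get("kd_molar") or "").strip()
            if raw_kd:
                kd[metal] = float(raw_kd)
            elif on:
                raise ValueError(f"{path}:{i}: enabled metal {metal.value} missing kd_molar")
            if on:
                enabled.add(metal)
    return ProteinAffinitySet(name or path.stem, kd, frozenset(enabled))


def packaged_affinity_set(name: str) -> ProteinAffinitySet:
    """Load one of the shipped example affinity sets (``hypb``, ``soda``)."""
    ref = resources.files("metalation").joinpath(f"data/affinities/{name.lower()}.tsv")
    with resources.as_file(ref) as p:
        return load_affinity_set(p, name=name)


@dataclass(frozen=True)
class MetalOccupancy:
    """One metal's row of a metalation prediction."""

    metal: Metal
    kd: float
    available: float
    dg_protein: float  # RT ln K_D, kJ/mol
    dg_available: float  # RT ln [M], kJ/mol
    ddg: float  # dg_protein - dg_available; negative favours metalation
    occupancy: float  # fraction in [0, 1)


@dataclass(frozen=True)
class MetalationResult:
    """Competitive occupancy of a 1:1 site, total capped below 1."""

    molecule: str
    condition: str
    rows: tuple[MetalOccupancy, ...]

    @property
    def total_occupancy(self) -> float:
        return sum(r.occupancy for r in self.rows)

    def occupancy(self, metal: Metal) -> float:
        for r in self.rows:
            if r.metal is metal:
                return r.occupancy
        raise KeyError(f"{metal.value} not in result for {self.molecule}")

    def percent(self, metal: Metal) -> float:
        return 100.0 * self.occupancy(metal)


def occupancy_from_ratios(ratios: Mapping[Metal, float]) -> dict[Metal, float]:
    """Site occupancies from availability/K_D ratios: r_i / (1 + sum r)."""
    denom = 1.0 + sum(ratios.values())
    return {m: r / denom for m, r in ratios.items()}


def occupancy_from_free_energies(
    ddg: Mapping[Metal, float], constants: ThermoConstants = DEFAULT_CONSTANTS
) -> dict[Metal, float]:
    """Occupancies from free-energy gradients: Boltzmann-weighted site states."""
    weights = {m: math.exp(-g / constants.RT) for m, g in ddg.items()}
    denom = 1.0 + sum(weights.values())
    return {m: w / denom for m, w in weights.items()}


def compute_occupancy(
    preset: AvailabilityPreset,
    affinities: ProteinAffinitySet,
    constants: ThermoConstants = DEFAULT_CONSTANTS,
) -> MetalationResult:
    """Predict percentage metal occupancies of a molecule under a condition.

    Enabled metals compete for one site; each needs a K_D and a preset
    concentration.  Rows are returned in the canonical metal order.
    """
    ratios: dict[Metal, float] = {}
    for metal in affinities.enabled:
        if metal not in preset.concentrations:
            raise ValueError(
                f"preset {preset.name!r} has no availability for enabled metal {metal.value}"
            )
        ratios[metal] = preset.concentrations[metal] / affinities.kd[metal]
    theta = occupancy_from_ratios(ratios)
    rows = tuple(
        MetalOccupancy(
            metal=m,
            kd=affinities.kd[m],
            available=preset.concentrations[m],
            dg_protein=kd_to_free_energy(affinities.kd[m], constants),
            dg_available=preset.free_energy(m, constants),
            ddg=kd_to_free_energy(affinities.kd[m], constants) - preset.free_energy(m, constants),
            occupancy=theta[m],
        )
        for m in Metal
        if m in theta
    )
    return MetalationResult(molecule=affinities.name, condition=preset.name, rows=rows)


def whatif_availability(
    base: AvailabilityPreset, overrides: Mapping[Metal, float]
) -> AvailabilityPreset:
    """Return a custom preset with overridden concentrations.

    Derived free energies follow automatically; overridden metals lose any
    SD/boundary annotation since they no longer come from the calibration.
    """
    for metal, c in overrides.items():
        if not (c > 0 and math.isfinite(c)):
            raise ValueError(f"override for {metal.value} must be positive, got {c}")
    if not overrides:
        return base
    conc = dict(base.concentrations)
    conc.update(overrides)
    sd = {m: s for m, s in base.sd.items() if m not in overrides}
    boundary = frozenset(m for m in base.boundary if m not in overrides)
    return AvailabilityPreset(
        name="custom",
        concentrations=conc,
        sd=sd,
        boundary=boundary,
        provenance=f"custom overrides on {base.name}",
    )


def render_report(result: MetalationResult, fmt: str = "text") -> str:
    """Render a result as ``text``, ``tsv`` or ``json``.

    All formats carry identical numbers: per-metal K_D, dG of the protein
    complex, dG of the available pool, ddG, percent occupancy (one decimal),
    and the total.
    """
    records = [
        {
            "metal": r.metal.value,
            "kd_molar": r.kd,
            "available_molar": r.available,
            "dg_protein_kj_mol": round(r.dg_protein, 2),
            "dg_available_kj_mol": round(r.dg_available, 2),
            "ddg_kj_mol": round(r.ddg, 2),
            "occupancy_percent": round(100.0 * r.occupancy, 1),
        }
        for r in result.rows
    ]
    total = round(100.0 * result.total_occupancy, 1)
    if fmt == "json":
        return json.dumps(
            {
                "molecule": result.molecule,
                "condition": result.condition,
                "metals": records,
                "total_occupancy_percent": total,
            },
            indent=2,
        )
    header = [
        "metal",
        "kd_molar",
        "available_molar",
        "dg_protein_kj_mol",
        "dg_available_kj_mol",
        "ddg_kj_mol",
        "occupancy_percent",
    ]
    if fmt == "tsv":
        buf = io.StringIO()
        writer = csv.writer(buf, delimiter="\t", lineterminator="\n")
        writer.writerow(header)
        for rec in records:
            writer.writerow([rec[h] for h in header])
        writer.writerow(["total", "", "", "", "", "", total])
        return buf.getvalue()
    if fmt == "text":
        lines = [
            f"Metalation of {result.molecule} ({result.condition} availabilities)",
            f"{'metal':<6} {'K_D (M)':>10} {'[M] (M)':>10} {'dG_prot':>9} "
            f"{'dG_avail':>9} {'ddG':>8} {'occ %':>7}",
        ]
        for rec in records:
            lines.append(
                f"{rec['metal']:<6} {rec['kd_molar']:>10.2e} {rec['available_molar']:>10.2e} "
                f"{rec['dg_protein_kj_mol']:>9.2f} {rec['dg_available_kj_mol']:>9.2f} "
                f"{rec['ddg_kj_mol']:>8.2f} {rec['occupancy_percent']:>7.1f}"
            )
        lines.append(f"{'total':<6} {'':>10} {'':>10} {'':>9} {'':>9} {'':>8} {total:>7.1f}")
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown report format {fmt!r}; use text, tsv or json")
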