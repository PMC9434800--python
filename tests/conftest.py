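"""Shared fixtures: packaged sensor sets, randomized sensor parameters and
an independent brute-force equilibrium oracle.

The oracle solves the same five-species mass-balance system as the
production solver but by nested interval bisection on the free-species
concentrations (outer loop on free operator, inner loop on free sensor),
writing each equilibrium relation out directly.  It shares no algebra with
the closed-form quadratic route it checks.
"""

from __future__ import annotations

import numpy as np
import pytest

from metalation.chem import Metal
from metalation.sensors import SensorClass, SensorParams, load_sensor_set


@pytest.fixture(scope="session")
def sensor_set() -> dict[str, SensorParams]:
    return load_sensor_set()


def oracle_solve(
    p_tot: float,
    d_tot: float,
    m: float,
    k_metal: float,
    k_dna_apo: float,
    k_dna_holo: float,
    iters: int = 80,
) -> dict[str, float]:
    """Brute-force equilibrium: nested bisection on (free operator, free sensor)."""

    def species(p: float, d: float) -> tuple[float, float, float]:
        pm = p * m / k_metal
        pd = p * d / k_dna_apo
        pmd = pm * d / k_dna_holo
        return pm, pd, pmd

    def solve_p(d: float) -> float:
        lo, hi = 0.0, p_tot
        for _ in range(iters):
            mid = 0.5 * (lo + hi)
            pm, pd, pmd = species(mid, d)
            if mid + pm + pd + pmd > p_tot:
                hi = mid
            else:
                lo = mid
        return 0.5 * (lo + hi)

    lo, hi = 0.0, d_tot
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        p = solve_p(mid)
        pm, pd, pmd = species(p, mid)
        if mid + pd + pmd > d_tot:
            hi = mid
        else:
            lo = mid
    d = 0.5 * (lo + hi)
    p = solve_p(d)
    pm, pd, pmd = species(p, d)
    return {"p": p, "pm": pm, "d": d, "pd": pd, "pmd": pmd}


def random_sensor_params(rng: np.random.Generator, sensor_class: SensorClass | None = None) -> SensorParams:
    """Draw a physically valid random parameter set for property tests.

    De-repressors get equal low/high abundances: their expression is not
    induced by the cognate metal, and equal abundances keep the readout
    monotone under abundance interpolation.
    """
    cls = sensor_class or rng.choice(list(SensorClass))
    k_metal = 10.0 ** rng.uniform(-16, -5)
    if cls is SensorClass.DE_REPRESSOR:
        k_dna_apo = 10.0 ** rng.uniform(-11, -9)
        k_dna_holo = k_dna_apo * 10.0 ** rng.uniform(1.5, 4.0)
        lo = hi = float(rng.integers(50, 400))
    else:
        k_dna_apo = 10.0 ** rng.uniform(-7, -5)
        k_dna_holo = k_dna_apo * 10.0 ** -rng.uniform(1.5, 4.0)
        lo = float(rng.integers(30, 300))
        hi = lo * rng.uniform(1.0, 3.0)
    return SensorParams(
        name=f"rand-{cls.value}",
        metal=Metal.ZN,
        sensor_class=cls,
        k_metal=k_metal,
        k_dna_apo=k_dna_apo,
        k_dna_holo=k_dna_holo,
        abundance_low=lo,
        abundance_high=hi,
        n_targets=int(rng.integers(1, 4)),
    )
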