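"""Synthetic dielectric sweeps with known ground truth, plus a ready fixture.

The generator emulates the structure the analysis assumes: temperature
sweeps 30-55 C in 5 C steps, replicate runs, and a monotone natural
frequency versus temperature whose forward permittivity increases with
temperature.  Noise is multiplicative on eps_r (measurement spread scales
with magnitude in this kind of data; an additive mode is available), with
a hard floor just above 1 and a clip counter so that the guard is never
silent.

``literature_fixture`` emits the measured insulin/papain/ZnO permittivity
series and species constants reported in the literature for this system,
as a ready-made (records, registry) pair for end-to-end runs and tests.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .config import Registry
from .dataset_io import DielectricRecord
from .mixtures import SampleComponent, SampleComposition
from .oscillator_core import (
    FieldConfig,
    MolecularSpecies,
    OscillatorEnsemble,
    forward_permittivity,
)

__all__ = [
    "SyntheticTruth",
    "linear_omega0_map",
    "generate_measurements",
    "literature_fixture",
]

logger = logging.getLogger(__name__)

EPS_FLOOR = 1.0 + 1e-6


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth for one synthetic sample.

    ``omega0_true`` maps temperature (C) to the natural angular frequency
    (rad/s); it must be strictly monotone in temperature (unfolding drives
    the frequency one way).  ``noise_sd`` is the multiplicative relative
    noise on eps_r; ``n_runs`` the replicate count (two, matching the
    repeatability protocol the analysis expects, unless overridden).
    """

    gamma_true: float
    omega0_true: Mapping[float, float]
    noise_sd: float = 0.0
    n_runs: int = 2
    sample_id: str = "synthetic"
    additive_noise: bool = False

    def __post_init__(self) -> None:
        if not self.gamma_true > 0:
            raise ValueError("gamma_true must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        temps = sorted(self.omega0_true)
        if len(temps) == 0:
            raise ValueError("omega0_true must not be empty")
        vals = [self.omega0_true[t] for t in temps]
        if any(not v > 0 for v in vals):
            raise ValueError("omega0_true values must be > 0")
        diffs = [b - a for a, b in zip(vals, vals[1:])]
        if diffs and not (all(d > 0 for d in diffs) or all(d < 0 for d in diffs)):
            raise ValueError("omega0_true must be strictly monotone in temperature")


def linear_omega0_map(
    omega0_start: float,
    omega0_end: float,
    temperatures=(30.0, 35.0, 40.0, 45.0, 50.0, 55.0),
) -> dict[float, float]:
    """Linear-in-temperature natural-frequency map over the given sweep."""
    temps = list(temperatures)
    t0, t1 = temps[0], temps[-1]
    return {
        t: omega0_start + (omega0_end - omega0_start) * (t - t0) / (t1 - t0)
        for t in temps
    }


def generate_measurements(
    truth: SyntheticTruth,
    ens: OscillatorEnsemble,
    fieldcfg: FieldConfig,
    seed: int,
) -> tuple[list[DielectricRecord], int]:
    """Generate a replicate dielectric table from ground truth.

    eps_r(T, run) = forward(omega0_true(T)) * (1 + eta),
    eta ~ Normal(0, noise_sd) (or + eta * forward-scale when additive),
    clipped below at 1 + 1e-6.  Deterministic per seed.  Returns the
    records and the number of clipped draws (always 0 at zero noise).
    """
    rng = np.random.default_rng(seed)
    records: list[DielectricRecord] = []
    clipped = 0
    for temp in sorted(truth.omega0_true):
        eps_exact = float(forward_permittivity(ens, fieldcfg, truth.omega0_true[temp]))
        for run in range(1, truth.n_runs + 1):
            eta = rng.normal(0.0, truth.noise_sd)
            val = eps_exact + eta if truth.additive_noise else eps_exact * (1.0 + eta)
            if val < EPS_FLOOR:
                val = EPS_FLOOR
                clipped += 1
            records.append(
                DielectricRecord(
                    sample_id=truth.sample_id,
                    temperature_C=temp,
                    epsilon_r=val,
                    run=run,
                )
            )
    if clipped:
        logger.warning(
            "%s: clipped %d permittivity draws at the %.6f floor",
            truth.sample_id, clipped, EPS_FLOOR,
        )
    return records, clipped


# -- measured values and constants for the insulin / papain / ZnO system --

_HOLDER_UL = 250.0  # sample-holder capacity, microlitres

_INSULIN_CONC = 6.9e-3    # kg/L (6.9 mg/ml)
_PAPAIN_CONCS = {"P1": 10.0e-3, "P2": 5.0e-3, "P3": 2.5e-3}
_ZNO_CONC = 3.45e-3

_PROSE_VALUES: tuple[tuple[str, float, float], ...] = (
    ("I", 30.0, 68.0),
    ("I", 55.0, 370.0),
    ("P1", 30.0, 27.0),
    ("P1", 55.0, 31.0),
    ("P2", 30.0, 24.0),
    ("P3", 30.0, 22.0),
    ("IZnO_S", 30.0, 40.0),
    ("IZnO_S", 55.0, 167.0),
    ("IZnO_T", 30.0, 95.0),
    ("IZnO_T", 55.0, 351.0),
)


def literature_fixture() -> tuple[list[DielectricRecord], Registry]:
    """Measured permittivity series and species registry for the
    insulin / papain / ZnO corona system.

    Species constants (literature values): insulin Q = 74.805e-10 C,
    M = 9.52e-18 kg, dipole 369 D; papain Q = 4.01e-8 C, M = 3.88e-17 kg,
    dipole 150 D; ZnO particles inert.  Samples: pure insulin at 6.9 mg/ml,
    papain at three dilutions (10 / 5 / 2.5 mg/ml), and 2:1 insulin:ZnO
    mixtures, all in a 250 uL holder.  Insulin is the comparison reference.
    """
    species = {
        "insulin": MolecularSpecies(
            name="insulin",
            charge_Q=74.805e-10,
            mass_M=9.52e-18,
            dipole_lit=369.0,
        ),
        "papain": MolecularSpecies(
            name="papain",
            charge_Q=4.01e-8,
            mass_M=3.88e-17,
            dipole_lit=150.0,
        ),
        "zno_s": MolecularSpecies(name="zno_s", inert=True),
        "zno_t": MolecularSpecies(name="zno_t", inert=True),
    }

    def ul(v: float) -> float:
        return v * 1e-6

    samples = {
        "I": SampleComposition(
            sample_id="I",
            components=(
                SampleComponent("insulin", ul(_HOLDER_UL), _INSULIN_CONC),
            ),
            is_reference=True,
        ),
    }
    for pid, conc in _PAPAIN_CONCS.items():
        samples[pid] = SampleComposition(
            sample_id=pid,
            components=(SampleComponent("papain", ul(_HOLDER_UL), conc),),
        )
    for sid, zno in (("IZnO_S", "zno_s"), ("IZnO_T", "zno_t")):
        samples[sid] = SampleComposition(
            sample_id=sid,
            components=(
                SampleComponent("insulin", ul(_HOLDER_UL * 2.0 / 3.0), _INSULIN_CONC),
                SampleComponent(zno, ul(_HOLDER_UL / 3.0), _ZNO_CONC),
            ),
        )

    registry = Registry(species=species, samples=samples, field=FieldConfig())
    records = [
        DielectricRecord(sample_id=sid, temperature_C=t, epsilon_r=eps, run=1)
        for sid, t, eps in _PROSE_VALUES
    ]
    return records, registry
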