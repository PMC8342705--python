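"""Pumped-frequency power-absorption scan: simulation and peak detection.

A vector signal generator pumps a grid of frequencies into the sample at
fixed power; when the pump matches the natural frequency of the molecular
oscillator, power is absorbed resonantly.  The absorption lineshape is the
Lorentzian consistent with the driven-damped oscillator of this package::

    A(w) = P_pump * (gamma w)^2 / ( (w0^2 - w^2)^2 + (gamma w)^2 )

which equals the pump power exactly on resonance.  Additive Gaussian noise
models receiver fluctuation; resonance detection refines the grid argmax
with three-point parabolic interpolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NoPeakError",
    "AbsorptionScan",
    "dbm_to_watts",
    "simulate_absorption",
    "find_resonance",
]

TWO_PI = 2.0 * np.pi


class NoPeakError(RuntimeError):
    """Scan has no interior absorption maximum (flat or monotone)."""


@dataclass(frozen=True, eq=False)
class AbsorptionScan:
    """One absorption scan: frequency grid (Hz) and absorbed power (W)."""

    pump_frequencies: np.ndarray
    absorbed_power: np.ndarray
    pump_power: float
    noise_sd: float

    def __post_init__(self) -> None:
        f = np.asarray(self.pump_frequencies, dtype=float)
        p = np.asarray(self.absorbed_power, dtype=float)
        if f.ndim != 1 or f.size != p.size:
            raise ValueError("grid and power arrays must be 1-D and equal length")
        if not np.all(np.diff(f) > 0):
            raise ValueError("pump-frequency grid must be strictly increasing")
        if np.any(p > self.pump_power * (1 + 1e-12)):
            raise ValueError("absorbed power exceeds pump power")
        object.__setattr__(self, "pump_frequencies", f)
        object.__setattr__(self, "absorbed_power", p)


def dbm_to_watts(p_dbm):
    """Convert dBm to watts: ``10^(p/10)`` milliwatts (standard conversion).

    Note that -50 dBm is 10 nW.  Claims equating -50 dBm with tens of
    microwatts stem from a unit slip, not an alternative convention, so no
    as-printed variant exists here.
    """
    return 1e-3 * np.power(10.0, np.asarray(p_dbm, dtype=float) / 10.0)


def simulate_absorption(
    omega0_true: float,
    gamma: float,
    grid_hz,
    pump_power_w: float,
    noise_sd_w: float = 0.0,
    seed: int | None = None,
) -> AbsorptionScan:
    """Simulate one absorption scan over a cyclic-frequency grid.

    ``omega0_true`` and ``gamma`` are angular (rad/s); ``grid_hz`` is the
    cyclic pump grid.  Noise is additive Gaussian with the given seed
    (deterministic per seed); the result is clipped to ``[0, pump_power]``
    to honour energy conservation pointwise.  A grid that does not span the
    true resonance triggers a warning diagnostic.
    """
    grid = np.asarray(grid_hz, dtype=float)
    if not np.all(np.diff(grid) > 0):
        raise ValueError("grid must be strictly increasing")
    if noise_sd_w < 0:
        raise ValueError("noise_sd_w must be >= 0")
    f0_true = omega0_true / TWO_PI
    if not grid[0] <= f0_true <= grid[-1]:
        warnings.warn(
            f"grid [{grid[0]:.4g}, {grid[-1]:.4g}] Hz does not span the true "
            f"resonance {f0_true:.4g} Hz",
            stacklevel=2,
        )
    w = TWO_PI * grid
    x = omega0_true ** 2 - w ** 2
    gw = gamma * w
    absorbed = pump_power_w * gw ** 2 / (x ** 2 + gw ** 2)
    rng = np.random.default_rng(seed)
    absorbed = absorbed + rng.normal(0.0, noise_sd_w, size=grid.size)
    absorbed = np.clip(absorbed, 0.0, pump_power_w)
    return AbsorptionScan(
        pump_frequencies=grid,
        absorbed_power=absorbed,
        pump_power=pump_power_w,
        noise_sd=noise_sd_w,
    )


def find_resonance(scan: AbsorptionScan) -> float:
    """Resonance frequency (Hz) from the absorption maximum.

    The grid argmax is refined by three-point parabolic interpolation.
    A flat scan, or one whose maximum sits on the grid boundary (e.g. a
    monotone ramp), raises :class:`NoPeakError`.
    """
    f = scan.pump_frequencies
    y = scan.absorbed_power
    if f.size < 3:
        raise NoPeakError("at least 3 grid points required")
    if np.ptp(y) == 0:
        raise NoPeakError("flat scan: no absorption peak")
    i = int(np.argmax(y))
    if i == 0 or i == f.size - 1:
        raise NoPeakError("maximum on grid boundary: no interior peak")
    denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
    if denom == 0:
        return float(f[i])
    delta = 0.5 * (y[i - 1] - y[i + 1]) / denom
    step = 0.5 * (f[i + 1] - f[i - 1])
    return float(f[i] + delta * step)
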