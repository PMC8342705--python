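"""Lorentz (driven-damped harmonic) oscillator model of polar molecules.

A suspension of ``N`` identical molecules, each carrying an effective bound
charge ``Q`` (mass ``M``), driven by a microwave field ``E0 e^{-i w t}``,
responds with a bound-charge displacement that fixes the sample's relative
permittivity:

    eps_r = 1 + S (w0^2 - w^2) / ( eps0 [ (w0^2 - w^2)^2 + (gamma w)^2 ] )

with oscillator strength ``S = N Q^2 / M``, natural angular frequency ``w0``
and damping constant ``gamma`` (the drag of the buffer on the molecule).
The module provides:

* the forward permittivity map above,
* its exact inversion for ``w0`` -- a quadratic in the detuning
  ``x = w0^2 - w^2``:  ``x^2 - B x + (gamma w)^2 = 0`` with
  ``B = S / (eps0 (eps_r - 1))``,
* the complex polarization response and the polarization current density
  (its time derivative),
* calibration of ``gamma`` against a literature dipole moment.

Conventions
-----------
All frequencies handled internally are *angular* (rad/s); user-facing
cyclic frequencies (Hz, MHz) are always labelled as such.  Inversion roots
are returned as :class:`NaturalFrequencyRoot` objects that carry the
detuning ``x`` exactly as produced by the quadratic formula: recomputing
``x`` from ``w0`` loses precision catastrophically when ``x << w^2``, so
:func:`forward_permittivity` prefers the stored detuning when handed a root
object.

When the quadratic has no real root (``B^2 < 4 (gamma w)^2``) the conjugate
complex pair is returned, flagged -- never silently dropped and never
replaced by magnitudes.  Note that either complex root still satisfies the
quadratic identity, so substituting it back into the forward map reproduces
``eps_r`` exactly (the complex parts cancel); downstream per-molecule
magnitudes computed from a complex root use moduli and carry a diagnostic.
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "VACUUM_PERMITTIVITY",
    "DEBYE_IN_SI",
    "DegenerateInputError",
    "MolecularSpecies",
    "FieldConfig",
    "OscillatorEnsemble",
    "NaturalFrequencyRoot",
    "OscillatorSolution",
    "PolarizationResponse",
    "CalibrationResult",
    "debye_to_si",
    "forward_permittivity",
    "invert_natural_frequency",
    "polarization",
    "polarization_current",
    "calibrate_damping",
]

#: vacuum permittivity, F/m (2018 CODATA)
VACUUM_PERMITTIVITY = 8.8541878128e-12

#: one debye in SI units, C*m
DEBYE_IN_SI = 3.33564e-30


class DegenerateInputError(ValueError):
    """Raised when eps_r <= 1: the inversion quadratic is undefined there."""


@dataclass(frozen=True)
class MolecularSpecies:
    """Per-molecule physical parameters of one molecular species.

    Parameters
    ----------
    name:
        Species label used in registries and sample compositions.
    charge_Q:
        Effective bound charge per molecule, coulomb.
    mass_M:
        Mass per molecule, kg.
    dipole_lit:
        Literature reference dipole moment, debye (calibration target for
        the damping constant).  ``None`` when no calibration is intended.
    gamma:
        Damping constant, 1/s.  ``None`` until calibrated.
    inert:
        Inert particles (e.g. ZnO, with near-zero net charge and a mass far
        above the proteins') contribute neither oscillator strength nor
        damping; their charge/mass may be omitted.
    """

    name: str
    charge_Q: float | None = None
    mass_M: float | None = None
    dipole_lit: float | None = None
    gamma: float | None = None
    inert: bool = False

    def __post_init__(self) -> None:
        if not self.inert:
            if self.charge_Q is None or not self.charge_Q > 0:
                raise ValueError(f"{self.name}: charge_Q must be > 0")
            if self.mass_M is None or not self.mass_M > 0:
                raise ValueError(f"{self.name}: mass_M must be > 0")
        if self.dipole_lit is not None and not self.dipole_lit > 0:
            raise ValueError(f"{self.name}: dipole_lit must be > 0")
        if self.gamma is not None and not self.gamma > 0:
            raise ValueError(f"{self.name}: gamma must be > 0")


@dataclass(frozen=True)
class FieldConfig:
    """Driving-field configuration of the microwave probe.

    ``drive_frequency_hz`` is cyclic (Hz); the angular frequency is exposed
    as :attr:`drive_omega`.  ``eval_time_t`` is the instant at which
    time-dependent responses are reported (default 1 us, the order of
    protein relaxation times).
    """

    drive_frequency_hz: float = 6.41e9
    field_amplitude_E0: float = 4.9
    eval_time_t: float = 1e-6

    def __post_init__(self) -> None:
        if not self.drive_frequency_hz > 0:
            raise ValueError("drive_frequency_hz must be > 0")
        if not self.field_amplitude_E0 > 0:
            raise ValueError("field_amplitude_E0 must be > 0")
        if not self.eval_time_t >= 0:
            raise ValueError("eval_time_t must be >= 0")

    @property
    def drive_omega(self) -> float:
        """Angular driving frequency, rad/s."""
        return 2.0 * math.pi * self.drive_frequency_hz


@dataclass(frozen=True)
class OscillatorEnsemble:
    """Aggregate oscillator parameters of one sample.

    ``strength_NQ2_over_M`` is ``N Q^2 / M`` for a pure sample, or the sum
    over (non-inert) components for a mixture; ``gamma_eff`` the effective
    (volume-weighted) damping constant.
    """

    n_molecules_N: float
    strength_NQ2_over_M: float
    gamma_eff: float

    def __post_init__(self) -> None:
        if not self.n_molecules_N > 0:
            raise ValueError("n_molecules_N must be > 0")
        if not self.strength_NQ2_over_M > 0:
            raise ValueError("strength_NQ2_over_M must be > 0")
        if not self.gamma_eff > 0:
            raise ValueError("gamma_eff must be > 0")


@dataclass(frozen=True)
class NaturalFrequencyRoot:
    """One root of the natural-frequency inversion.

    ``detuning`` is ``w0^2 - w^2`` exactly as produced by the quadratic
    (kept to avoid cancellation when re-substituting into the forward map).
    ``kind`` is ``"real"``, ``"complex"`` (conjugate pair, no real root) or
    ``"negative"`` (negative real ``w0^2``; only reachable in the
    as-printed audit mode).
    """

    omega0: complex
    omega0_sq: complex
    detuning: complex
    kind: str

    @property
    def is_real(self) -> bool:
        return self.kind == "real"

    @property
    def f0_hz(self) -> complex:
        """Cyclic natural frequency, Hz (complex if the root is not real)."""
        return self.omega0 / (2.0 * math.pi)


@dataclass(frozen=True)
class OscillatorSolution:
    """Inversion output at one (sample, temperature) condition."""

    epsilon_r_in: float
    mode: str
    roots: tuple[NaturalFrequencyRoot, ...]
    selected: NaturalFrequencyRoot
    dipole_per_molecule: float
    jp_amplitude: float
    diagnostics: tuple[str, ...]

    @property
    def f0_hz(self) -> complex:
        return self.selected.f0_hz

    @property
    def selected_root(self) -> complex:
        return self.selected.omega0


@dataclass(frozen=True)
class PolarizationResponse:
    """Complex polarization response and the per-molecule dipole amplitude."""

    value: complex
    dipole_per_molecule: float


@dataclass(frozen=True)
class CalibrationResult:
    """Damping-constant calibration outcome.

    ``converged`` is False when the literature dipole target lies outside
    the range achievable with real inversion roots; ``gamma`` is then the
    nearest-achievable value and ``message`` says so.
    """

    gamma: float
    dipole_achieved: float
    dipole_target: float
    converged: bool
    message: str = ""


def debye_to_si(d):
    """Convert a dipole moment from debye to C*m (1 D = 3.33564e-30 C*m)."""
    return np.multiply(d, DEBYE_IN_SI) if isinstance(d, np.ndarray) else d * DEBYE_IN_SI


OmegaLike = Union[float, complex, np.ndarray, NaturalFrequencyRoot]


def _detuning_of(omega0: OmegaLike, w: float):
    if isinstance(omega0, NaturalFrequencyRoot):
        x = omega0.detuning
        return x.real if omega0.is_real else x
    if isinstance(omega0, np.ndarray):
        return omega0 * omega0 - w * w
    return omega0 * omega0 - w * w


def forward_permittivity(ens: OscillatorEnsemble, field: FieldConfig, omega0: OmegaLike):
    """Relative permittivity of the ensemble at natural frequency ``omega0``.

    ``omega0`` may be a scalar (real or complex), an ndarray, or a
    :class:`NaturalFrequencyRoot` -- the latter evaluates via the stored
    detuning and is the numerically exact way to round-trip an inversion.
    Exact evaluation; no fitting.
    """
    w = field.drive_omega
    x = _detuning_of(omega0, w)
    gw2 = (ens.gamma_eff * w) ** 2
    val = 1.0 + ens.strength_NQ2_over_M * x / (VACUUM_PERMITTIVITY * (x * x + gw2))
    if not np.all(np.isfinite(np.atleast_1d(val))):
        raise FloatingPointError(
            "forward permittivity overflowed: parameter magnitudes invalid"
        )
    return val


def _root_from_detuning(x, w: float) -> NaturalFrequencyRoot:
    """Build a root from a quadratic detuning solution (real x > 0 or complex)."""
    if isinstance(x, complex):
        w0sq = x + w * w
        return NaturalFrequencyRoot(
            omega0=cmath.sqrt(w0sq), omega0_sq=w0sq, detuning=x, kind="complex"
        )
    w0sq = x + w * w
    return NaturalFrequencyRoot(
        omega0=complex(math.sqrt(w0sq), 0.0),
        omega0_sq=complex(w0sq, 0.0),
        detuning=complex(x, 0.0),
        kind="real",
    )


def _root_from_omega0_sq(z: complex, w: float) -> NaturalFrequencyRoot:
    """Build a root from an as-printed ``w0^2`` value (may be negative/complex)."""
    if z.imag == 0.0:
        if z.real >= 0.0:
            return NaturalFrequencyRoot(
                omega0=complex(math.sqrt(z.real), 0.0),
                omega0_sq=z,
                detuning=z - w * w,
                kind="real",
            )
        return NaturalFrequencyRoot(
            omega0=cmath.sqrt(z), omega0_sq=z, detuning=z - w * w, kind="negative"
        )
    return NaturalFrequencyRoot(
        omega0=cmath.sqrt(z), omega0_sq=z, detuning=z - w * w, kind="complex"
    )


def _response_magnitudes(
    ens: OscillatorEnsemble, field: FieldConfig, root: NaturalFrequencyRoot
) -> tuple[float, float]:
    """Per-molecule dipole amplitude and instantaneous J_P at the eval time.

    For a complex root the moduli of the detuning and of the resonance
    denominator are used (flagged by the caller); for a real root this is
    the exact real formula.
    """
    w = field.drive_omega
    g = ens.gamma_eff
    s = ens.strength_NQ2_over_M
    e0 = field.field_amplitude_E0
    if root.is_real:
        x = root.detuning.real
        denom = x * x + (g * w) ** 2
    else:
        x = abs(root.detuning)
        denom = abs(root.detuning * root.detuning + (g * w) ** 2)
    dipole = (s / ens.n_molecules_N) * e0 / math.sqrt(denom)
    t = field.eval_time_t
    jp = (
        s * e0 * w / (VACUUM_PERMITTIVITY * denom)
        * (g * w * math.cos(w * t) - x * math.sin(w * t))
    )
    return dipole, jp


def invert_natural_frequency(
    ens: OscillatorEnsemble,
    field: FieldConfig,
    epsilon_r: float,
    mode: str = "consistent",
) -> OscillatorSolution:
    """Invert the forward permittivity map for the natural frequency.

    In ``consistent`` mode the forward map is solved exactly as a quadratic
    in the detuning ``x = w0^2 - w^2``::

        x = [ B +/- sqrt(B^2 - 4 (gamma w)^2) ] / 2,
        B = S / (eps0 (eps_r - 1))

    Both roots are returned; complex pairs are flagged, not dropped.  The
    selected root is the *smaller real* root by default (both branches are
    physically admissible; the smaller one is the gentler oscillator).  In
    ``as_printed`` mode the historically typeset discriminant
    ``(B + 2 w^2)^2 - 4 (B + 2 w^2)(w^4 + gamma^2 w^2 + B w^2)`` is
    evaluated verbatim for audit; its roots do not round-trip through the
    forward map and are flagged as such.

    Raises
    ------
    DegenerateInputError
        If ``epsilon_r <= 1`` (the quadratic coefficient ``B`` diverges;
        at eps_r == 1 the forward map forces ``w0 == w`` only).
    """
    if not math.isfinite(epsilon_r):
        raise ValueError("epsilon_r must be finite")
    if epsilon_r <= 1.0:
        raise DegenerateInputError(
            f"epsilon_r={epsilon_r} <= 1: inversion undefined (B divergent)"
        )
    w = field.drive_omega
    g = ens.gamma_eff
    s = ens.strength_NQ2_over_M
    b = s / (VACUUM_PERMITTIVITY * (epsilon_r - 1.0))
    gw = g * w
    diagnostics: list[str] = []

    if mode == "consistent":
        disc = b * b - 4.0 * gw * gw
        if disc >= 0.0:
            sq = math.sqrt(disc)
            x_hi = 0.5 * (b + sq)
            x_lo = (gw * gw) / x_hi  # product of roots = (gamma w)^2
            roots = (_root_from_detuning(x_lo, w), _root_from_detuning(x_hi, w))
        else:
            sq = math.sqrt(-disc)
            roots = (
                _root_from_detuning(complex(0.5 * b, 0.5 * sq), w),
                _root_from_detuning(complex(0.5 * b, -0.5 * sq), w),
            )
            diagnostics.append(
                "no real natural-frequency root: B^2 < 4(gamma*omega)^2; "
                "conjugate complex pair reported"
            )
    elif mode == "as_printed":
        a = b + 2.0 * w * w
        disc_p = a * a - 4.0 * a * (w ** 4 + gw * gw + b * w * w)
        sq = cmath.sqrt(complex(disc_p, 0.0))
        roots = (
            _root_from_omega0_sq(0.5 * (a - sq), w),
            _root_from_omega0_sq(0.5 * (a + sq), w),
        )
        diagnostics.append(
            "as-printed discriminant: roots do not round-trip through the "
            "forward permittivity"
        )
    else:
        raise ValueError(f"unknown inversion mode {mode!r}")

    real_roots = [r for r in roots if r.is_real]
    if real_roots:
        selected = min(real_roots, key=lambda r: r.omega0.real)
    else:
        selected = next(
            (r for r in roots if r.detuning.imag >= 0 or r.kind == "negative"),
            roots[0],
        )
        diagnostics.append(
            "selected root is not real; per-molecule magnitudes below use "
            "moduli (magnitude convention)"
        )

    dipole, jp = _response_magnitudes(ens, field, selected)
    return OscillatorSolution(
        epsilon_r_in=epsilon_r,
        mode=mode,
        roots=roots,
        selected=selected,
        dipole_per_molecule=dipole,
        jp_amplitude=jp,
        diagnostics=tuple(diagnostics),
    )


def polarization(
    ens: OscillatorEnsemble, field: FieldConfig, omega0: OmegaLike, t: float
) -> PolarizationResponse:
    """Complex polarization response at time ``t``.

    Returns the bracketed complex amplitude times the phase factor
    ``e^{-i w t}``; the bracketed amplitude is
    ``S E0 (x + i gamma w) / (eps0 (x^2 + (gamma w)^2))`` with detuning
    ``x = w0^2 - w^2``.  ``dipole_per_molecule`` is the displacement
    amplitude times the per-molecule charge,
    ``(Q^2/M) E0 / sqrt(x^2 + (gamma w)^2)`` -- the quantity the damping
    calibration matches against the literature dipole moment.
    """
    w = field.drive_omega
    g = ens.gamma_eff
    s = ens.strength_NQ2_over_M
    e0 = field.field_amplitude_E0
    x = _detuning_of(omega0, w)
    denom = x * x + (g * w) ** 2
    amp = s * e0 * (x + 1j * g * w) / (VACUUM_PERMITTIVITY * denom)
    value = amp * cmath.exp(-1j * w * t)
    dipole = (s / ens.n_molecules_N) * e0 / math.sqrt(abs(denom))
    return PolarizationResponse(value=value, dipole_per_molecule=dipole)


def polarization_current(
    ens: OscillatorEnsemble,
    field: FieldConfig,
    omega0: OmegaLike,
    t,
    mode: str = "derivative_consistent",
):
    """Polarization current density at time ``t`` (A/m^2; ``t`` may be an array).

    ``derivative_consistent`` (default) is the analytic time derivative of
    the real part of :func:`polarization` -- ``J = dP/dt`` is the defining
    physical relation::

        J(t) = S E0 w / (eps0 (x^2 + (gamma w)^2))
               * ( gamma w cos(w t) - x sin(w t) )

    ``as_printed`` evaluates the historically typeset form verbatim (an
    extra detuning prefactor and no vacuum-permittivity factor), for audit.
    """
    w = field.drive_omega
    g = ens.gamma_eff
    s = ens.strength_NQ2_over_M
    e0 = field.field_amplitude_E0
    x = _detuning_of(omega0, w)
    if isinstance(x, complex):
        raise TypeError(
            "polarization_current requires a real natural frequency; use the "
            "flagged magnitudes on OscillatorSolution for complex roots"
        )
    t = np.asarray(t, dtype=float) if not np.isscalar(t) else t
    denom = x * x + (g * w) ** 2
    if mode == "derivative_consistent":
        return s * e0 * w / (VACUUM_PERMITTIVITY * denom) * (
            g * w * np.cos(w * t) - x * np.sin(w * t)
        )
    if mode == "as_printed":
        return (s * e0 * x / denom) * (
            g * w * w * np.cos(w * t) - x * w * np.sin(w * t)
        )
    raise ValueError(f"unknown polarization-current mode {mode!r}")


def _dipole_at_gamma(
    qsq_over_m: float, e0: float, b: float, w: float, gamma: float
) -> float:
    """Per-molecule dipole with the smaller real inversion root at ``gamma``.

    Uses the root identities x_lo * x_hi = (gamma w)^2 and
    x^2 + (gamma w)^2 = B x to stay stable near the real-root boundary.
    """
    gw = gamma * w
    disc = b * b - 4.0 * gw * gw
    if disc < 0.0:
        raise ValueError("gamma beyond the real-root boundary")
    x_hi = 0.5 * (b + math.sqrt(disc))
    x_lo = (gw * gw) / x_hi
    return qsq_over_m * e0 / math.sqrt(b * x_lo)


def calibrate_damping(
    species: MolecularSpecies,
    ens: OscillatorEnsemble,
    field: FieldConfig,
    epsilon_r_ref: float,
    gamma_bounds: tuple[float, float] = (1e-3, 1e15),
    rel_tol: float = 1e-8,
) -> CalibrationResult:
    """Calibrate the damping constant against the literature dipole moment.

    Finds ``gamma* > 0`` such that, with the natural frequency re-solved
    from the inversion at ``gamma*`` (smaller real root), the per-molecule
    dipole amplitude ``(Q^2/M) E0 / sqrt(x^2 + (gamma w)^2)`` equals
    ``debye_to_si(species.dipole_lit)``.  The dipole is strictly decreasing
    in ``gamma`` on the real-root domain, so a bracketed Brent search on
    ``log10 gamma`` is used.  If no bracket exists within ``gamma_bounds``
    (intersected with the real-root domain ``gamma < B / (2 w)``), the
    nearest-achievable dipole is returned with ``converged=False`` and a
    no-solution diagnostic -- never silently clipped.
    """
    if species.dipole_lit is None or not species.dipole_lit > 0:
        raise ValueError(f"{species.name}: no literature dipole to calibrate against")
    if epsilon_r_ref <= 1.0:
        raise DegenerateInputError(
            f"epsilon_r_ref={epsilon_r_ref} <= 1: calibration undefined"
        )
    target = debye_to_si(species.dipole_lit)
    w = field.drive_omega
    e0 = field.field_amplitude_E0
    s = ens.strength_NQ2_over_M
    b = s / (VACUUM_PERMITTIVITY * (epsilon_r_ref - 1.0))
    qsq_over_m = species.charge_Q ** 2 / species.mass_M
    gamma_real_max = b / (2.0 * w)

    lo = gamma_bounds[0]
    hi = min(gamma_bounds[1], gamma_real_max * (1.0 - 1e-12))
    if hi <= lo:
        d_lo = qsq_over_m * e0 / math.sqrt(b * gamma_real_max * w)  # boundary scale
        return CalibrationResult(
            gamma=lo,
            dipole_achieved=d_lo,
            dipole_target=target,
            converged=False,
            message=(
                "real-root domain does not intersect the search bounds; "
                "returning the lower bound"
            ),
        )

    def dipole(gamma: float) -> float:
        return _dipole_at_gamma(qsq_over_m, e0, b, w, gamma)

    d_lo = dipole(lo)  # largest achievable dipole (gamma small)
    d_hi = dipole(hi)  # smallest achievable dipole (gamma at the boundary)

    if d_hi <= target <= d_lo:
        lg = brentq(
            lambda lg_: dipole(10.0 ** lg_) - target,
            math.log10(lo),
            math.log10(hi),
            xtol=1e-13,
            rtol=8.9e-16,
        )
        gamma_star = 10.0 ** lg
        achieved = dipole(gamma_star)
        ok = abs(achieved - target) <= rel_tol * target
        return CalibrationResult(
            gamma=gamma_star,
            dipole_achieved=achieved,
            dipole_target=target,
            converged=ok,
            message="" if ok else "bracketed search did not reach rel_tol",
        )

    # no bracket: the literature dipole is outside the achievable range
    if target < d_hi:
        gamma_star, achieved = hi, d_hi
        side = "below"
    else:
        gamma_star, achieved = lo, d_lo
        side = "above"
    return CalibrationResult(
        gamma=gamma_star,
        dipole_achieved=achieved,
        dipole_target=target,
        converged=False,
        message=(
            f"no solution: target dipole {target:.4g} C*m lies {side} the "
            f"achievable range [{d_hi:.4g}, {d_lo:.4g}] C*m; returning the "
            "nearest-achievable damping constant"
        ),
    )
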