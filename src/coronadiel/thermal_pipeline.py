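"""Per-sample, per-temperature model inversion and relative-change summaries.

``run_sweep`` orchestrates the full analysis of a dielectric temperature
sweep: replicate averaging, one damping-constant calibration per pure
protein species at its coolest measured temperature (held fixed across the
sweep unless ``recalibrate_per_temperature`` is set), mixture rules for
composite samples, exact inversion of the permittivity for the natural
frequency at every (sample, temperature), and evaluation of the
polarization response and current density at the configured instant.

``radar_summary`` condenses a sweep plus auxiliary tables (zeta potential,
DSC enthalpy) into per-sample relative changes versus a reference sample,
``|x - x_ref| / |x_ref|``, at a declared comparison temperature (default
30 C).  Rows whose selected natural-frequency root is not real are excluded
from the frequency entry (reported ``None`` with a note) rather than
silently converted to magnitudes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import asdict, dataclass
from typing import Mapping, Sequence

from .config import Registry
from .dataset_io import AuxiliaryRecord, DielectricRecord, average_runs
from .mixtures import build_ensemble
from .oscillator_core import (
    CalibrationResult,
    FieldConfig,
    calibrate_damping,
    forward_permittivity,
    invert_natural_frequency,
)

__all__ = [
    "PipelineError",
    "RadarError",
    "RootSummary",
    "SweepResult",
    "RadarSummary",
    "calibrate_registry",
    "run_sweep",
    "radar_summary",
    "sweep_to_dicts",
    "sweep_from_dicts",
]

logger = logging.getLogger(__name__)

RADAR_QUANTITIES = ("epsilon_r", "dipole", "jp", "f0", "zeta", "enthalpy")


class PipelineError(RuntimeError):
    """Unrecoverable sweep-orchestration failure (unknown sample, no gamma)."""


class RadarError(ValueError):
    """Missing reference sample or zero-valued reference quantity."""


@dataclass(frozen=True)
class RootSummary:
    """One natural-frequency root in cyclic MHz (complex part kept explicit)."""

    f0_mhz_re: float
    f0_mhz_im: float
    is_real: bool


@dataclass(frozen=True)
class SweepResult:
    """Inversion outcome at one (sample, temperature).

    ``f0_mhz`` is the selected root in MHz when real, ``None`` otherwise
    (the full flagged pair is in ``f0_mhz_all_roots``).
    ``epsilon_r_roundtrip`` is the forward permittivity re-evaluated at the
    selected root -- the invert-then-forward consistency check.
    """

    sample_id: str
    temperature_C: float
    epsilon_r_mean: float
    epsilon_r_spread: float
    f0_mhz: float | None
    f0_mhz_all_roots: tuple[RootSummary, ...]
    dipole_per_molecule: float
    jp_amplitude: float
    epsilon_r_roundtrip: float
    diagnostics: tuple[str, ...]


@dataclass(frozen=True)
class RadarSummary:
    """Relative changes of one sample versus the reference, per quantity."""

    sample_id: str
    changes: Mapping[str, float | None]
    notes: tuple[str, ...]


def _pure_protein_samples(registry: Registry, species_name: str):
    return [
        s
        for s in registry.samples.values()
        if s.is_pure(species_name)
    ]


def calibrate_registry(
    registry: Registry,
    measurements: Sequence[DielectricRecord],
    field: FieldConfig | None = None,
) -> dict[str, CalibrationResult]:
    """Calibrate the damping constant of every species that needs one.

    For each non-inert species without a preset ``gamma`` but with a
    literature dipole moment, the calibration runs against the pure sample
    of that species with the largest molecule count, at the coolest
    measured temperature with ``eps_r > 1``.
    """
    field = field or registry.field
    by_sample: dict[str, dict[float, float]] = {}
    for agg in average_runs(list(measurements)):
        by_sample.setdefault(agg.sample_id, {})[float(agg.key)] = agg.mean

    results: dict[str, CalibrationResult] = {}
    for name, sp in registry.species.items():
        if sp.inert or sp.gamma is not None or sp.dipole_lit is None:
            continue
        candidates = [
            s for s in _pure_protein_samples(registry, name) if s.sample_id in by_sample
        ]
        if not candidates:
            continue
        # largest total dissolved mass <=> largest N for a single species
        cand = max(
            candidates,
            key=lambda s: sum(c.conc_kg_per_L * c.volume_L for c in s.components),
        )
        temps = sorted(t for t, e in by_sample[cand.sample_id].items() if e > 1.0)
        if not temps:
            continue
        eps_ref = by_sample[cand.sample_id][temps[0]]
        ens0 = build_ensemble(cand, registry.species, gamma_overrides={name: 1.0})
        res = calibrate_damping(sp, ens0, field, eps_ref)
        if not res.converged:
            logger.warning("calibration of %s: %s", name, res.message)
        results[name] = res
    return results


def run_sweep(
    registry: Registry,
    measurements: Sequence[DielectricRecord],
    field: FieldConfig | None = None,
    mode: str = "consistent",
    recalibrate_per_temperature: bool = False,
) -> list[SweepResult]:
    """Run the full inversion pipeline over a measurement table.

    Deterministic given inputs; results are sorted by (sample,
    temperature), so the output is independent of input-row order.  Rows
    with mean ``eps_r <= 1`` are skipped with a logged diagnostic, never
    silently.
    """
    field = field or registry.field
    aggs = average_runs(list(measurements))
    unknown = sorted({a.sample_id for a in aggs} - set(registry.samples))
    if unknown:
        raise PipelineError(f"samples without a registry entry: {unknown}")

    calib = calibrate_registry(registry, measurements, field)
    gammas: dict[str, float] = {
        name: sp.gamma for name, sp in registry.species.items() if sp.gamma is not None
    }
    gammas.update({name: res.gamma for name, res in calib.items()})

    results: list[SweepResult] = []
    for agg in aggs:
        sid, temp, eps = agg.sample_id, float(agg.key), agg.mean
        sample = registry.samples[sid]
        if eps <= 1.0:
            logger.warning(
                "skipping %s at %.1f C: mean eps_r=%.4g <= 1 (inversion undefined)",
                sid, temp, eps,
            )
            continue
        sample_gammas = dict(gammas)
        notes: list[str] = []
        if recalibrate_per_temperature:
            for comp in sample.components:
                sp = registry.species[comp.species]
                if sp.inert or sp.dipole_lit is None or not sample.is_pure(sp.name):
                    continue
                ens0 = build_ensemble(
                    sample, registry.species, gamma_overrides={sp.name: 1.0}
                )
                res = calibrate_damping(sp, ens0, field, eps)
                sample_gammas[sp.name] = res.gamma
                if res.message:
                    notes.append(f"recalibration[{sp.name}]: {res.message}")
        for comp in sample.components:
            sp = registry.species[comp.species]
            if not sp.inert and sp.name in calib and calib[sp.name].message:
                notes.append(f"calibration[{sp.name}]: {calib[sp.name].message}")
        try:
            ens = build_ensemble(sample, registry.species, gamma_overrides=sample_gammas)
        except ValueError as exc:
            raise PipelineError(str(exc)) from exc
        sol = invert_natural_frequency(ens, field, eps, mode=mode)
        recovered = forward_permittivity(ens, field, sol.selected)
        if isinstance(recovered, complex):
            notes.append(
                f"round-trip imaginary residue {abs(recovered.imag):.3g}"
            )
            recovered = recovered.real
        root_summaries = tuple(
            RootSummary(
                f0_mhz_re=r.f0_hz.real / 1e6,
                f0_mhz_im=r.f0_hz.imag / 1e6,
                is_real=r.is_real,
            )
            for r in sol.roots
        )
        f0_mhz = sol.selected.f0_hz.real / 1e6 if sol.selected.is_real else None
        results.append(
            SweepResult(
                sample_id=sid,
                temperature_C=temp,
                epsilon_r_mean=eps,
                epsilon_r_spread=agg.spread,
                f0_mhz=f0_mhz,
                f0_mhz_all_roots=root_summaries,
                dipole_per_molecule=sol.dipole_per_molecule,
                jp_amplitude=sol.jp_amplitude,
                epsilon_r_roundtrip=float(recovered),
                diagnostics=tuple(sol.diagnostics) + tuple(notes),
            )
        )
    results.sort(key=lambda r: (r.sample_id, r.temperature_C))
    return results


def _aux_means(aux: Sequence[AuxiliaryRecord]) -> dict[tuple[str, str], float]:
    return {
        (a.sample_id, str(a.key)): a.mean for a in average_runs(list(aux))
    }


def radar_summary(
    results: Sequence[SweepResult],
    aux: Sequence[AuxiliaryRecord],
    reference_id: str,
    temperature_C: float = 30.0,
) -> list[RadarSummary]:
    """Relative change of each sample versus the reference, per quantity.

    Quantities: ``epsilon_r``, ``dipole``, ``jp``, ``f0`` from the sweep at
    the comparison temperature; ``zeta`` and ``enthalpy`` from auxiliary
    aggregates.  A missing reference sample or a zero-valued reference
    quantity raises :class:`RadarError` (never silently yields infinity).
    """
    rows = {
        r.sample_id: r
        for r in results
        if math.isclose(r.temperature_C, temperature_C, abs_tol=1e-9)
    }
    if reference_id not in rows:
        raise RadarError(
            f"reference sample {reference_id!r} has no sweep row at "
            f"{temperature_C} C"
        )
    aux_means = _aux_means(aux)

    def quantities_of(sid: str) -> dict[str, float | None]:
        row = rows[sid]
        return {
            "epsilon_r": row.epsilon_r_mean,
            "dipole": row.dipole_per_molecule,
            "jp": abs(row.jp_amplitude),
            "f0": row.f0_mhz,
            "zeta": aux_means.get((sid, "zeta_mV")),
            "enthalpy": aux_means.get((sid, "enthalpy_J_per_g_degC")),
        }

    ref = quantities_of(reference_id)
    out: list[RadarSummary] = []
    for sid in sorted(rows):
        vals = quantities_of(sid)
        changes: dict[str, float | None] = {}
        notes: list[str] = []
        for q in RADAR_QUANTITIES:
            v, vr = vals[q], ref[q]
            if vr is None or v is None:
                changes[q] = None
                if q == "f0" and v is None and sid in rows:
                    notes.append(
                        f"{q}: no real natural-frequency root; excluded"
                    )
                continue
            if vr == 0:
                raise RadarError(
                    f"reference quantity {q!r} is zero; relative change undefined"
                )
            changes[q] = abs(v - vr) / abs(vr)
        out.append(RadarSummary(sample_id=sid, changes=changes, notes=tuple(notes)))
    return out


def sweep_to_dicts(results: Sequence[SweepResult]) -> list[dict]:
    """JSON-serializable form of sweep results."""
    return [asdict(r) for r in results]


def sweep_from_dicts(rows: Sequence[Mapping]) -> list[SweepResult]:
    """Rebuild :class:`SweepResult` objects from their dict form."""
    out = []
    for row in rows:
        roots = tuple(RootSummary(**r) for r in row["f0_mhz_all_roots"])
        d = dict(row)
        d["f0_mhz_all_roots"] = roots
        d["diagnostics"] = tuple(d.get("diagnostics", ()))
        out.append(SweepResult(**d))
    return out
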