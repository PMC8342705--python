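"""Mixture rules and molecule-count estimation for pure and mixed samples.

A sample is a list of components, each a (species, contributed volume,
pre-mix mass concentration) triple.  Mixing conserves component mass, so
the molecule count of each component is computed from its own concentration
and its own contributed volume.  The effective damping constant of a
mixture is the volume-weighted arithmetic mean of the component damping
constants, and the aggregate oscillator strength is additive:

    gamma_mix = sum_i gamma_i V_i / sum_i V_i
    S_mix     = sum_i N_i Q_i^2 / M_i

Both rules generalize the binary forms to any number of components (needed
for ternary protein + enzyme + particle samples).  Species flagged ``inert``
(near-zero net charge, much higher mass -- e.g. ZnO micro/nanoparticles)
are excluded from both sums by default; including them in the damping
average is available as a policy switch.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .oscillator_core import MolecularSpecies, OscillatorEnsemble

__all__ = [
    "SampleComponent",
    "SampleComposition",
    "estimate_molecule_count",
    "mixed_damping",
    "mixed_strength",
    "build_ensemble",
]


@dataclass(frozen=True)
class SampleComponent:
    """One component of a sample: species name, volume (L), concentration (kg/L)."""

    species: str
    volume_L: float
    conc_kg_per_L: float

    def __post_init__(self) -> None:
        if not self.volume_L > 0:
            raise ValueError(f"{self.species}: volume_L must be > 0")
        if not self.conc_kg_per_L > 0:
            raise ValueError(f"{self.species}: conc_kg_per_L must be > 0")


@dataclass(frozen=True)
class SampleComposition:
    """A pure or mixed sample; ``is_reference`` marks the comparison baseline."""

    sample_id: str
    components: tuple[SampleComponent, ...]
    is_reference: bool = False

    def __post_init__(self) -> None:
        if len(self.components) == 0:
            raise ValueError(f"{self.sample_id}: at least one component required")

    @property
    def total_volume_L(self) -> float:
        return sum(c.volume_L for c in self.components)

    def is_pure(self, species_name: str) -> bool:
        """True when every component is of the given species."""
        return all(c.species == species_name for c in self.components)


def estimate_molecule_count(
    concentration_kg_per_L: float, volume_L: float, mass_M_kg: float
) -> float:
    """Number of molecules N = concentration * volume / molecular mass.

    Real-valued (not rounded); all arguments must be positive.
    """
    if not mass_M_kg > 0:
        raise ValueError("mass_M_kg must be > 0")
    if not concentration_kg_per_L > 0 or not volume_L > 0:
        raise ValueError("concentration and volume must be > 0")
    return concentration_kg_per_L * volume_L / mass_M_kg


def mixed_damping(components: Sequence[tuple[float, float]]) -> float:
    """Volume-weighted mean damping constant of (gamma_i, V_i) components."""
    if len(components) == 0:
        raise ValueError("mixed_damping requires at least one component")
    for gamma, vol in components:
        if not gamma > 0 or not vol > 0:
            raise ValueError("all gamma_i and V_i must be > 0")
    v_total = sum(v for _, v in components)
    return sum(g * v for g, v in components) / v_total


def mixed_strength(components: Sequence[tuple[float, float, float]]) -> float:
    """Additive aggregate oscillator strength sum_i N_i Q_i^2 / M_i."""
    total = 0.0
    for n, q, m in components:
        if not n > 0 or not q > 0 or not m > 0:
            raise ValueError("all N_i, Q_i, M_i must be > 0")
        total += n * q * q / m
    return total


def build_ensemble(
    sample: SampleComposition,
    species: Mapping[str, MolecularSpecies],
    gamma_overrides: Mapping[str, float] | None = None,
    include_inert_in_damping: bool = False,
) -> OscillatorEnsemble:
    """Aggregate oscillator parameters of a sample under the mixing rules.

    Per-component molecule counts use pre-mix concentration and contributed
    volume (mass conservation).  Inert species contribute zero strength and
    are, by default, excluded from the damping average as well (numerator
    *and* denominator); set ``include_inert_in_damping=True`` to weight
    them in -- inert species then need a damping constant of their own.

    ``gamma_overrides`` maps species names to calibrated damping constants,
    taking precedence over any ``gamma`` stored on the species.
    """
    overrides = gamma_overrides or {}
    strength_terms: list[tuple[float, float, float]] = []
    damping_terms: list[tuple[float, float]] = []
    n_total = 0.0
    for comp in sample.components:
        try:
            sp = species[comp.species]
        except KeyError:
            raise KeyError(
                f"{sample.sample_id}: unknown species {comp.species!r}"
            ) from None
        if sp.inert and not include_inert_in_damping:
            continue
        gamma = overrides.get(sp.name, sp.gamma)
        if not sp.inert:
            n_i = estimate_molecule_count(comp.conc_kg_per_L, comp.volume_L, sp.mass_M)
            strength_terms.append((n_i, sp.charge_Q, sp.mass_M))
            n_total += n_i
        if gamma is None:
            raise ValueError(
                f"{sample.sample_id}: species {sp.name!r} has no damping "
                "constant (calibrate first or set gamma)"
            )
        damping_terms.append((gamma, comp.volume_L))
    if not strength_terms:
        raise ValueError(
            f"{sample.sample_id}: no polarizable (non-inert) component"
        )
    return OscillatorEnsemble(
        n_molecules_N=n_total,
        strength_NQ2_over_M=mixed_strength(strength_terms),
        gamma_eff=mixed_damping(damping_terms),
    )
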