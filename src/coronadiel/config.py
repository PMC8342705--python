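"""Structured registry configuration: species, samples, driving field.

YAML schema (units chosen to match how such experiments are reported;
converted to SI on load)::

    field:
      frequency_GHz: 6.41
      E0_V_per_m: 4.9
      t_us: 1.0
    species:
      insulin: {charge_Q_C: 7.4805e-9, mass_M_kg: 9.52e-18,
                dipole_lit_debye: 369.0}
      zno_t:   {inert: true}
    samples:
      I:
        reference: true
        components:
          - {species: insulin, volume_uL: 250.0, concentration_mg_per_mL: 6.9}
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import yaml

from .mixtures import SampleComponent, SampleComposition
from .oscillator_core import FieldConfig, MolecularSpecies

__all__ = ["Registry", "load_registry", "registry_to_dict", "write_registry"]


@dataclass(frozen=True)
class Registry:
    """Species parameters, sample compositions and field configuration."""

    species: Mapping[str, MolecularSpecies]
    samples: Mapping[str, SampleComposition]
    field: FieldConfig

    def reference_sample(self) -> SampleComposition | None:
        for s in self.samples.values():
            if s.is_reference:
                return s
        return None


def _species_from_dict(name: str, d: Mapping) -> MolecularSpecies:
    return MolecularSpecies(
        name=name,
        charge_Q=d.get("charge_Q_C"),
        mass_M=d.get("mass_M_kg"),
        dipole_lit=d.get("dipole_lit_debye"),
        gamma=d.get("gamma_per_s"),
        inert=bool(d.get("inert", False)),
    )


def _sample_from_dict(sample_id: str, d: Mapping) -> SampleComposition:
    comps = tuple(
        SampleComponent(
            species=c["species"],
            volume_L=float(c["volume_uL"]) * 1e-6,
            conc_kg_per_L=float(c["concentration_mg_per_mL"]) * 1e-3,
        )
        for c in d.get("components", ())
    )
    return SampleComposition(
        sample_id=sample_id,
        components=comps,
        is_reference=bool(d.get("reference", False)),
    )


def load_registry(path) -> Registry:
    """Load a registry config from YAML, converting units to SI."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    fd = raw.get("field", {})
    field = FieldConfig(
        drive_frequency_hz=float(fd.get("frequency_GHz", 6.41)) * 1e9,
        field_amplitude_E0=float(fd.get("E0_V_per_m", 4.9)),
        eval_time_t=float(fd.get("t_us", 1.0)) * 1e-6,
    )
    species = {
        name: _species_from_dict(name, d or {})
        for name, d in (raw.get("species") or {}).items()
    }
    samples = {
        sid: _sample_from_dict(sid, d or {})
        for sid, d in (raw.get("samples") or {}).items()
    }
    return Registry(species=species, samples=samples, field=field)


def registry_to_dict(reg: Registry) -> dict:
    """Serialize a registry back to the YAML-facing dict form."""
    out: dict = {
        "field": {
            "frequency_GHz": reg.field.drive_frequency_hz / 1e9,
            "E0_V_per_m": reg.field.field_amplitude_E0,
            "t_us": reg.field.eval_time_t * 1e6,
        },
        "species": {},
        "samples": {},
    }
    for name, sp in reg.species.items():
        d: dict = {}
        if sp.charge_Q is not None:
            d["charge_Q_C"] = sp.charge_Q
        if sp.mass_M is not None:
            d["mass_M_kg"] = sp.mass_M
        if sp.dipole_lit is not None:
            d["dipole_lit_debye"] = sp.dipole_lit
        if sp.gamma is not None:
            d["gamma_per_s"] = sp.gamma
        if sp.inert:
            d["inert"] = True
        out["species"][name] = d
    for sid, sample in reg.samples.items():
        out["samples"][sid] = {
            "reference": sample.is_reference,
            "components": [
                {
                    "species": c.species,
                    "volume_uL": c.volume_L * 1e6,
                    "concentration_mg_per_mL": c.conc_kg_per_L * 1e3,
                }
                for c in sample.components
            ],
        }
    return out


def write_registry(reg: Registry, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(registry_to_dict(reg), fh, sort_keys=True)
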