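"""Measurement-table I/O and replicate-run aggregation.

Canonical CSV schemas (comma-separated, UTF-8, ``.`` decimal separator,
header required; the Unicode minus sign is normalized to ASCII on read):

* ``measurements.csv`` -- columns ``sample_id,temperature_C,epsilon_r,run``
* ``aux.csv``          -- columns ``sample_id,quantity,value,run`` with
  ``quantity`` one of ``zeta_mV`` (electrokinetic potential, mV) or
  ``enthalpy_J_per_g_degC`` (unfolding enthalpy from DSC).

Replicate aggregation reports the arithmetic mean per group with a spread
convention matching how such tables are published: half the max-min range
for two runs (error bars between a pair of runs), the sample standard
deviation for three or more.  ``printed_mean`` renders a mean at a table's
printed precision, truncating toward zero -- the convention the source
tables for this kind of data follow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, Union

import pandas as pd

__all__ = [
    "MEASUREMENT_COLUMNS",
    "AUX_COLUMNS",
    "AUX_QUANTITIES",
    "TableFormatError",
    "DielectricRecord",
    "AuxiliaryRecord",
    "RunAggregate",
    "read_measurements",
    "write_measurements",
    "read_aux",
    "write_aux",
    "average_runs",
    "printed_mean",
]

MEASUREMENT_COLUMNS = ("sample_id", "temperature_C", "epsilon_r", "run")
AUX_COLUMNS = ("sample_id", "quantity", "value", "run")
AUX_QUANTITIES = ("zeta_mV", "enthalpy_J_per_g_degC")


class TableFormatError(ValueError):
    """Malformed table: missing columns, bad cells or duplicate keys."""


@dataclass(frozen=True)
class DielectricRecord:
    """One dielectric measurement: sample, temperature (C), eps_r, run index."""

    sample_id: str
    temperature_C: float
    epsilon_r: float
    run: int

    def __post_init__(self) -> None:
        if not self.epsilon_r > 0:
            raise ValueError(f"{self.sample_id}: epsilon_r must be > 0")
        if self.run < 1:
            raise ValueError(f"{self.sample_id}: run index must be >= 1")


@dataclass(frozen=True)
class AuxiliaryRecord:
    """One auxiliary measurement (zeta potential or DSC enthalpy)."""

    sample_id: str
    quantity: str
    value: float
    run: int

    def __post_init__(self) -> None:
        if self.quantity not in AUX_QUANTITIES:
            raise ValueError(
                f"{self.sample_id}: quantity must be one of {AUX_QUANTITIES}"
            )
        if self.run < 1:
            raise ValueError(f"{self.sample_id}: run index must be >= 1")


@dataclass(frozen=True)
class RunAggregate:
    """Per-group replicate aggregate.

    ``key`` is the temperature (dielectric records) or the quantity name
    (auxiliary records); ``spread`` is half-range for <=2 runs, sample
    standard deviation for >=3.
    """

    sample_id: str
    key: Union[float, str]
    mean: float
    spread: float
    n_runs: int


def _normalize_cell(cell: str) -> str:
    # Unicode minus (U+2212) appears in published tables; map it to ASCII.
    return cell.replace("−", "-").strip()


def _read_table(path, columns) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing columns {missing}")
    return df


def read_measurements(
    path, temperature_range: tuple[float, float] = (0.0, 100.0)
) -> list[DielectricRecord]:
    """Read and validate a dielectric-measurement table.

    Malformed rows (non-numeric cells, non-positive eps_r, temperature
    outside the declared instrument range, bad run index) and duplicate
    (sample, temperature, run) keys raise :class:`TableFormatError` with
    the offending line numbers.  An empty data section yields ``[]``.
    """
    df = _read_table(path, MEASUREMENT_COLUMNS)
    records: list[DielectricRecord] = []
    bad: list[str] = []
    seen: dict[tuple, int] = {}
    lo, hi = temperature_range
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        try:
            sid = _normalize_cell(str(row["sample_id"]))
            temp = float(_normalize_cell(row["temperature_C"]))
            eps = float(_normalize_cell(row["epsilon_r"]))
            run = int(_normalize_cell(row["run"]))
            if not lo <= temp <= hi:
                raise ValueError(f"temperature {temp} outside [{lo}, {hi}] C")
            rec = DielectricRecord(sid, temp, eps, run)
        except (ValueError, TypeError) as exc:
            bad.append(f"line {line}: {exc}")
            continue
        key = (rec.sample_id, rec.temperature_C, rec.run)
        if key in seen:
            bad.append(
                f"line {line}: duplicate key {key} (first seen line {seen[key]})"
            )
            continue
        seen[key] = line
        records.append(rec)
    if bad:
        raise TableFormatError(f"{path}: rejected rows:\n  " + "\n  ".join(bad))
    return records


def read_aux(path) -> list[AuxiliaryRecord]:
    """Read and validate an auxiliary table (zeta potential / enthalpy)."""
    df = _read_table(path, AUX_COLUMNS)
    records: list[AuxiliaryRecord] = []
    bad: list[str] = []
    seen: dict[tuple, int] = {}
    for idx, row in df.iterrows():
        line = idx + 2
        try:
            rec = AuxiliaryRecord(
                _normalize_cell(str(row["sample_id"])),
                _normalize_cell(str(row["quantity"])),
                float(_normalize_cell(row["value"])),
                int(_normalize_cell(row["run"])),
            )
        except (ValueError, TypeError) as exc:
            bad.append(f"line {line}: {exc}")
            continue
        key = (rec.sample_id, rec.quantity, rec.run)
        if key in seen:
            bad.append(
                f"line {line}: duplicate key {key} (first seen line {seen[key]})"
            )
            continue
        seen[key] = line
        records.append(rec)
    if bad:
        raise TableFormatError(f"{path}: rejected rows:\n  " + "\n  ".join(bad))
    return records


def write_measurements(records: Iterable[DielectricRecord], path) -> None:
    df = pd.DataFrame(
        [(r.sample_id, r.temperature_C, r.epsilon_r, r.run) for r in records],
        columns=list(MEASUREMENT_COLUMNS),
    )
    df.to_csv(path, index=False)


def write_aux(records: Iterable[AuxiliaryRecord], path) -> None:
    df = pd.DataFrame(
        [(r.sample_id, r.quantity, r.value, r.run) for r in records],
        columns=list(AUX_COLUMNS),
    )
    df.to_csv(path, index=False)


def _spread(values: Sequence[float]) -> float:
    n = len(values)
    if n <= 1:
        return 0.0
    if n == 2:
        return 0.5 * (max(values) - min(values))
    mean = sum(values) / n
    return math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1))


def average_runs(
    records: Sequence[Union[DielectricRecord, AuxiliaryRecord]],
) -> list[RunAggregate]:
    """Aggregate replicate runs per (sample, temperature) or (sample, quantity).

    Permutation-invariant; groups are returned sorted by (sample_id, key).
    """
    groups: dict[tuple, list[float]] = {}
    for rec in records:
        if isinstance(rec, DielectricRecord):
            key = (rec.sample_id, rec.temperature_C)
            groups.setdefault(key, []).append(rec.epsilon_r)
        elif isinstance(rec, AuxiliaryRecord):
            key = (rec.sample_id, rec.quantity)
            groups.setdefault(key, []).append(rec.value)
        else:
            raise TypeError(f"unsupported record type {type(rec).__name__}")
    out = []
    for (sid, key), vals in groups.items():
        vals.sort()  # fixed reduction order: exact permutation invariance
        out.append(
            RunAggregate(
                sample_id=sid,
                key=key,
                mean=sum(vals) / len(vals),
                spread=_spread(vals),
                n_runs=len(vals),
            )
        )
    out.sort(key=lambda a: (a.sample_id, str(a.key)))
    return out


def printed_mean(value: float, decimals: int) -> float:
    """Render a mean at a table's printed precision (truncation toward zero).

    Values that are already exact at the requested precision (up to fp
    representation noise) pass through unchanged; otherwise the extra
    digits are dropped, matching the truncating convention of the published
    replicate tables this module reproduces.
    """
    scale = 10.0 ** decimals
    scaled = value * scale
    nearest = round(scaled)
    if abs(scaled - nearest) <= 1e-9 * max(1.0, abs(scaled)):
        return nearest / scale
    return math.trunc(scaled) / scale
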