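"""Minimal chart exports: radar of relative changes, frequency-sweep lines."""

from __future__ import annotations

import math
from typing import Sequence

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt  # noqa: E402

from .thermal_pipeline import RADAR_QUANTITIES, RadarSummary, SweepResult  # noqa: E402

__all__ = ["plot_radar", "plot_sweep"]

_LABELS = {
    "epsilon_r": r"$\varepsilon_r$",
    "dipole": "P",
    "jp": r"$J_P$",
    "f0": r"$\omega_0$",
    "zeta": r"$\zeta$",
    "enthalpy": "H",
}


def plot_radar(summaries: Sequence[RadarSummary], path) -> None:
    """Radar chart of per-sample relative changes versus the reference."""
    quantities = list(RADAR_QUANTITIES)
    angles = [2 * math.pi * i / len(quantities) for i in range(len(quantities))]
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(6, 6))
    for summ in summaries:
        vals = [summ.changes.get(q) for q in quantities]
        pts = [(a, v) for a, v in zip(angles, vals) if v is not None]
        if not pts:
            continue
        aa = [p[0] for p in pts] + [pts[0][0]]
        vv = [p[1] for p in pts] + [pts[0][1]]
        ax.plot(aa, vv, marker="o", label=summ.sample_id)
    ax.set_xticks(angles)
    ax.set_xticklabels([_LABELS[q] for q in quantities])
    ax.set_title("Relative change vs reference")
    ax.legend(loc="upper right", bbox_to_anchor=(1.3, 1.1), fontsize="small")
    fig.savefig(path, bbox_inches="tight", dpi=120)
    plt.close(fig)


def plot_sweep(results: Sequence[SweepResult], path) -> None:
    """Natural frequency (real roots only) versus temperature, per sample."""
    by_sample: dict[str, list[SweepResult]] = {}
    for r in results:
        by_sample.setdefault(r.sample_id, []).append(r)
    fig, ax = plt.subplots(figsize=(7, 5))
    for sid, rows in sorted(by_sample.items()):
        pts = [(r.temperature_C, r.f0_mhz) for r in rows if r.f0_mhz is not None]
        if not pts:
            continue
        pts.sort()
        ax.plot([p[0] for p in pts], [p[1] for p in pts], marker="o", label=sid)
    ax.set_xlabel("temperature (C)")
    ax.set_ylabel("natural frequency (MHz, cyclic)")
    ax.legend(fontsize="small")
    fig.savefig(path, bbox_inches="tight", dpi=120)
    plt.close(fig)
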