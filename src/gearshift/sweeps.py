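"""Force-ratio sweeps and preset parameterizations as tidy tables.

A sweep evaluates a mosaic system on a grid of force ratios and returns one
row per grid point: total and per-pathway fluxes (normalized by L*dGc by
default), the leak flux, fractional per-pathway ATP fluxes, the flux-ratio
stoichiometry n(X), the efficiency eta = n*X, and a reverse-operation flag
for force ratios beyond catabolic reversal.  Rows at the singular point
X = 1/nu carry empty n/eta cells.

Four named presets bundle the standard parameterizations used throughout
this package's worked examples: a two-gear mosaic system (``fig1``), three
fixed-Z pathways at equal coupling with their sum and the variomatic
envelope (``fig2``), the dual-pathway capacity-split family (``fig3``), and
four integer gears with the discrete switching schedule (``fig4``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import TransducerSystem, total_fluxes
from .gears import GearSet, GearSchedule, best_discrete_gear, gear_switch_points
from .phenomenological import (
    PhenomenologicalParams,
    phenomenological_flux_ratio,
    phenomenological_fluxes,
)
from .gears import variomatic_flux

__all__ = ["SweepGrid", "sweep", "FigurePreset", "figure_preset", "figure_tables"]

PRESET_NAMES = ("fig1", "fig2", "fig3", "fig4")


@dataclass(frozen=True)
class SweepGrid:
    """Uniform force-ratio grid [x_start, x_stop] with the given step."""

    x_start: float = 0.0
    x_stop: float = 1.0
    step: float = 0.01

    def __post_init__(self) -> None:
        if not self.x_start < self.x_stop:
            raise ValueError(
                f"x_start must be < x_stop, got [{self.x_start}, {self.x_stop}]"
            )
        if not self.step > 0:
            raise ValueError(f"step must be > 0, got {self.step}")
        if self.x_start < 0:
            raise ValueError(f"x_start must be >= 0, got {self.x_start}")

    def points(self) -> np.ndarray:
        n = int(round((self.x_stop - self.x_start) / self.step))
        pts = self.x_start + self.step * np.arange(n + 1)
        return pts[pts <= self.x_stop + 1e-12 * max(1.0, self.x_stop)]


def sweep(
    system: TransducerSystem, grid: SweepGrid | None = None, normalized: bool = True
) -> pd.DataFrame:
    """Evaluate a system over a force-ratio grid.

    Returns a DataFrame with columns ``X, Jc_total, Jp_total, Jc_1.., Jp_1..,
    Jp_leak, n, eta, reverse_flag, frac_Jp_1..``; fluxes are divided by
    L*dGc when ``normalized`` (the default).  Fractions are per-pathway ATP
    flux over the total; wherever the total is nonzero they sum to
    ``1 + Jp_leak/Jp_total`` (the leak correction).
    """
    if grid is None:
        grid = SweepGrid()
    scale = system.capacity * system.gibbs_catabolic if normalized else 1.0
    k = len(system.pathways)
    rows = []
    for x in grid.points():
        st = total_fluxes(system, float(x))
        row: dict[str, object] = {
            "X": float(x),
            "Jc_total": st.jc_total / scale,
            "Jp_total": st.jp_total / scale,
        }
        for i in range(k):
            row[f"Jc_{i + 1}"] = st.jc_per_pathway[i] / scale
        for i in range(k):
            row[f"Jp_{i + 1}"] = st.jp_per_pathway[i] / scale
        row["Jp_leak"] = st.jp_leak / scale
        row["n"] = st.flux_ratio_stoichiometry
        row["eta"] = st.efficiency
        row["reverse_flag"] = st.reverse_operation
        for i in range(k):
            if st.jp_total != 0.0:
                row[f"frac_Jp_{i + 1}"] = st.jp_per_pathway[i] / st.jp_total
            else:
                row[f"frac_Jp_{i + 1}"] = None
        rows.append(row)
    df = pd.DataFrame(rows)
    return df.astype({"n": float, "eta": float}, errors="ignore")


@dataclass(frozen=True)
class FigurePreset:
    """Bundle of systems/parameters and a grid for one named preset."""

    name: str
    grid: SweepGrid
    systems: tuple[TransducerSystem, ...] = ()
    phenomenological: tuple[PhenomenologicalParams, ...] = ()
    gears: GearSet | None = None
    schedule: GearSchedule | None = None
    labels: tuple[str, ...] = field(default=())


def figure_preset(name: str) -> FigurePreset:
    """Return the parameter bundle for one of the named presets.

    - ``fig1``: two-pathway mosaic system, phi=0.2, n1=1, n2=2, L=dGc=1,
      no leak; grid 0..1 (covers both the stall at 0.75 and the catabolic
      reversal at 0.83).
    - ``fig2``: three phenomenological pathways, q=0.9, Z in {0.5, 1, 2},
      unit capacity each; their sum and the variomatic envelope.
    - ``fig3``: dual-pathway family n1=1, n2=3 at capacity splits
      phi in {1, 0.375, 0.25, 0}.
    - ``fig4``: four discrete gears n = 1..4, each a single fully coupled
      unit-capacity pathway, plus the optimal switching schedule.
    """
    grid = SweepGrid(0.0, 1.0, 0.01)
    if name == "fig1":
        return FigurePreset(
            name=name,
            grid=grid,
            systems=(TransducerSystem.two_pathway(phi=0.2, n1=1.0, n2=2.0),),
            labels=("phi=0.2",),
        )
    if name == "fig2":
        zs = (0.5, 1.0, 2.0)
        return FigurePreset(
            name=name,
            grid=grid,
            phenomenological=tuple(
                PhenomenologicalParams(stoichiometry_Z=z, coupling_q=0.9) for z in zs
            ),
            labels=tuple(f"Z={z:g}" for z in zs),
        )
    if name == "fig3":
        phis = (1.0, 0.375, 0.25, 0.0)
        return FigurePreset(
            name=name,
            grid=grid,
            systems=tuple(
                TransducerSystem.two_pathway(phi=phi, n1=1.0, n2=3.0) for phi in phis
            ),
            labels=tuple(f"phi={phi:g}" for phi in phis),
        )
    if name == "fig4":
        gears = GearSet((1.0, 2.0, 3.0, 4.0))
        return FigurePreset(
            name=name,
            grid=grid,
            gears=gears,
            schedule=gear_switch_points(gears, x_max=1.0),
            labels=tuple(f"n={g:g}" for g in gears.gears),
        )
    raise ValueError(f"unknown preset {name!r}; expected one of {PRESET_NAMES}")


def figure_tables(name: str, normalized: bool = True) -> dict[str, pd.DataFrame]:
    """Compute the tables behind a named preset.

    Returns a dict of DataFrames keyed by table name; every preset includes
    a ``"curves"`` table with one row per grid point.
    """
    preset = figure_preset(name)
    xs = preset.grid.points()
    if name == "fig1":
        return {"curves": sweep(preset.systems[0], preset.grid, normalized=normalized)}
    if name == "fig2":
        rows = []
        for x in xs:
            x = float(x)
            row: dict[str, object] = {"X": x}
            total = 0.0
            for p, lab in zip(preset.phenomenological, preset.labels):
                _, jp = phenomenological_fluxes(p, 1.0, x)
                jp /= p.capacity  # normalized by L*dGc, dGc = 1
                row[f"Jp[{lab}]"] = jp
                row[f"n[{lab}]"] = phenomenological_flux_ratio(p, x)
                total += jp
            row["Jp_sum"] = total
            row["Jp_variomatic"] = (
                variomatic_flux(0.9, x) if x > 0 else None
            )
            rows.append(row)
        return {"curves": pd.DataFrame(rows)}
    if name == "fig3":
        tables = {"curves": None}
        rows = []
        for x in xs:
            x = float(x)
            row = {"X": x}
            for s, lab in zip(preset.systems, preset.labels):
                st = total_fluxes(s, x)
                row[f"Jp[{lab}]"] = st.jp_total / (s.capacity * s.gibbs_catabolic)
            rows.append(row)
        tables["curves"] = pd.DataFrame(rows)
        tables.update(
            {
                f"fractions[{lab}]": sweep(s, preset.grid, normalized=normalized)
                for s, lab in zip(preset.systems, preset.labels)
            }
        )
        return tables
    if name == "fig4":
        assert preset.gears is not None and preset.schedule is not None
        rows = []
        for x in xs:
            x = float(x)
            row = {"X": x}
            total = 0.0
            for g, lab in zip(preset.gears.gears, preset.labels):
                f = g * (1.0 - g * x)
                row[f"Jp[{lab}]"] = f
                total += f
            row["Jp_sum"] = total
            gear, flux = best_discrete_gear(preset.gears, x)
            row["best_gear"] = gear
            row["Jp_best_gear"] = flux
            rows.append(row)
        schedule_df = pd.DataFrame(
            [
                {"interval_start": a, "interval_end": b, "gear": g}
                for a, b, g in preset.schedule.intervals()
            ]
        )
        return {"curves": pd.DataFrame(rows), "schedule": schedule_df}
    raise ValueError(f"unknown preset {name!r}; expected one of {PRESET_NAMES}")
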