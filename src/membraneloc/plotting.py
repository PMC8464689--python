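"""Matplotlib figures for the three analysis tracks."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .density import DensityProfile
from .dsc import PhaseDiagram, Thermogram


def plot_thermogram(tg: Thermogram, peaks=(), ax=None):
    """Cp vs T with detected transition markers."""
    if ax is None:
        _, ax = plt.subplots()
    ax.plot(tg.T, tg.Cp, lw=1)
    for p in peaks:
        ax.axvline(p.Tm, ls="--", lw=0.7, color="0.4")
        ax.annotate(p.kind, (p.Tm, p.height), fontsize=8, rotation=90)
    ax.set_xlabel("temperature (°C)")
    ax.set_ylabel("excess Cp (kcal mol$^{-1}$ °C$^{-1}$)")
    return ax


def plot_phase_diagram(diagram: PhaseDiagram, ax=None):
    """Solidus/fluidus lines vs drug:lipid molar ratio with error bars."""
    if ax is None:
        _, ax = plt.subplots()
    t = diagram.table
    ax.errorbar(t["ratio"], t["solidus_C"], yerr=t["solidus_sd"], marker="s",
                label="solidus (onset)")
    ax.errorbar(t["ratio"], t["fluidus_C"], yerr=t["fluidus_sd"], marker="o",
                label="fluidus (completion)")
    ax.set_xlabel("drug:lipid molar ratio")
    ax.set_ylabel("temperature (°C)")
    ax.legend()
    return ax


def plot_density_profiles(profiles: list[DensityProfile], ax=None):
    """Overlay z-axis mass-density profiles of several selections."""
    if ax is None:
        _, ax = plt.subplots()
    for p in profiles:
        ax.plot(p.z, p.density, label=p.selection, lw=1)
    ax.set_xlabel("z (nm, midplane at 0)")
    ax.set_ylabel("mass density (kg m$^{-3}$)")
    ax.legend(fontsize=8)
    return ax
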