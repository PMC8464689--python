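"""Differential scanning calorimetry (DSC) transition analysis.

Extracts gel → liquid-crystalline transition parameters from excess
heat-capacity thermograms of phospholipid/drug mixtures and assembles a
partial phase diagram for the lipid component.

Conventions
-----------
* Temperatures are in degrees Celsius throughout the public interface.
* Heat capacity is the excess Cp in kcal mol⁻¹ °C⁻¹ after buffer/baseline
  subtraction; transition enthalpies integrate to kcal/mol.
* The transition temperature Tm is the peak maximum; onset and completion
  temperatures are the outermost temperatures at which the
  baseline-subtracted trace equals 5% of the peak height (the "5% rule").
  Onset temperatures across compositions trace the solidus line of the
  partial phase diagram, completion temperatures the fluidus line.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

__all__ = [
    "Thermogram",
    "TransitionPeak",
    "PhaseDiagram",
    "ImmiscibilityAssessment",
    "subtract_baseline",
    "detect_peaks",
    "transition_bounds",
    "transition_enthalpy",
    "analyze_thermogram",
    "build_phase_diagram",
    "assess_fluid_immiscibility",
]

MAIN = "main"
PRE = "pre-transition"
OTHER = "other"


@dataclass(frozen=True)
class Thermogram:
    """A single scan: excess heat capacity versus temperature.

    Parameters
    ----------
    T : array of temperatures, °C, strictly increasing.
    Cp : array of excess heat capacity, kcal mol⁻¹ °C⁻¹, same length as T.
    meta : free-form metadata (lipid:drug molar ratio, scan id, ground truth
        of synthetic scans, ...).
    """

    T: np.ndarray
    Cp: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        T = np.asarray(self.T, dtype=float)
        Cp = np.asarray(self.Cp, dtype=float)
        if T.ndim != 1 or Cp.ndim != 1 or len(T) != len(Cp):
            raise ValueError("T and Cp must be 1-D arrays of equal length")
        if len(T) >= 2 and not np.all(np.diff(T) > 0):
            raise ValueError("temperature grid must be strictly increasing")
        if not (np.all(np.isfinite(T)) and np.all(np.isfinite(Cp))):
            raise ValueError("thermogram contains non-finite values")
        object.__setattr__(self, "T", T)
        object.__setattr__(self, "Cp", Cp)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"temperature_C": self.T, "cp_kcal_per_mol_C": self.Cp}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, meta: dict | None = None) -> "Thermogram":
        df = pd.read_csv(path)
        missing = {"temperature_C", "cp_kcal_per_mol_C"} - set(df.columns)
        if missing:
            raise ValueError(f"thermogram CSV missing columns: {sorted(missing)}")
        return cls(
            df["temperature_C"].to_numpy(),
            df["cp_kcal_per_mol_C"].to_numpy(),
            dict(meta or {}),
        )


@dataclass
class TransitionPeak:
    """Parameters of one detected transition.

    ``height`` is the baseline-subtracted Cp at the peak maximum; ``T_onset``
    and ``T_end`` are the 5%-of-height crossings; ``dH`` the integrated
    calorimetric enthalpy.  ``index`` is the grid index of the discrete
    maximum (used internally to anchor outward searches).
    """

    Tm: float
    height: float
    kind: str = MAIN
    dH: float = np.nan
    T_onset: float = np.nan
    T_end: float = np.nan
    index: int = -1


@dataclass(frozen=True)
class PhaseDiagram:
    """Partial phase diagram: solidus/fluidus temperature vs. composition.

    ``table`` has one row per drug:lipid molar ratio with columns
    ``ratio, solidus_C, solidus_sd, fluidus_C, fluidus_sd``, sorted by ratio.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = {"ratio", "solidus_C", "solidus_sd", "fluidus_C", "fluidus_sd"}
        if missing := required - set(t.columns):
            raise ValueError(f"phase diagram missing columns: {sorted(missing)}")
        if (t["ratio"] < 0).any():
            raise ValueError("molar ratios must be non-negative")
        if t["ratio"].duplicated().any():
            raise ValueError("duplicate molar ratios in phase diagram")
        bad = t[t["solidus_C"] > t["fluidus_C"]]
        if len(bad):
            raise ValueError(
                "solidus above fluidus at ratios "
                f"{bad['ratio'].tolist()} — inconsistent analysis"
            )

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class ImmiscibilityAssessment:
    fluid_immiscibility: bool
    fluidus_slope: float  # °C per unit drug:lipid molar ratio
    solidus_slope: float


# ---------------------------------------------------------------------------
# baseline


def _default_flanks(T: np.ndarray) -> tuple[tuple[float, float], tuple[float, float]]:
    span = T[-1] - T[0]
    return (T[0], T[0] + 0.1 * span), (T[-1] - 0.1 * span, T[-1])


def subtract_baseline(
    tg: Thermogram,
    flank_windows: tuple[tuple[float, float], tuple[float, float]] | None = None,
) -> tuple[Thermogram, tuple[float, float]]:
    """Subtract a straight baseline fitted through two peak-free flank windows.

    The line passes through the mean (T, Cp) point of each window; windows
    default to the first and last 10% of the temperature range.  Returns the
    subtracted thermogram and the baseline ``(slope, intercept)``.

    Raises ``ValueError`` if a window lies outside the grid, the windows
    overlap, a window holds fewer than 5 grid points, or a window contains
    the transition peak.
    """
    T, Cp = tg.T, tg.Cp
    if flank_windows is None:
        flank_windows = _default_flanks(T)
    (lo1, hi1), (lo2, hi2) = (sorted(w) for w in flank_windows)
    if (lo1, hi1) > (lo2, hi2):
        (lo1, hi1), (lo2, hi2) = (lo2, hi2), (lo1, hi1)
    if lo1 < T[0] - 1e-9 or hi2 > T[-1] + 1e-9:
        raise ValueError("flank window outside the temperature grid")
    if hi1 > lo2:
        raise ValueError("flank windows overlap")
    m1 = (T >= lo1) & (T <= hi1)
    m2 = (T >= lo2) & (T <= hi2)
    if m1.sum() < 5 or m2.sum() < 5:
        raise ValueError("each flank window must contain at least 5 grid points")

    t1, c1 = T[m1].mean(), Cp[m1].mean()
    t2, c2 = T[m2].mean(), Cp[m2].mean()
    slope = (c2 - c1) / (t2 - t1)
    intercept = c1 - slope * t1
    resid = Cp - (slope * T + intercept)

    # A window containing the transition peak invalidates the fit: the
    # global residual maximum may not fall inside a window unless the trace
    # is featureless (residuals comparable to the quieter window's scatter).
    imax = int(np.argmax(resid))
    quiet_sd = max(min(resid[m1].std(), resid[m2].std()), 1e-12)
    if resid[imax] > 10 * quiet_sd and (m1[imax] or m2[imax]):
        raise ValueError("flank window contains the transition peak")

    out = Thermogram(T, resid, dict(tg.meta))
    return out, (slope, intercept)


# ---------------------------------------------------------------------------
# peak detection


def _refine_maximum(T: np.ndarray, Cp: np.ndarray, i: int) -> tuple[float, float]:
    """Sub-grid peak position by 3-point parabolic interpolation.

    The reported height stays the measured grid maximum: fitting a parabola
    through the apex of a sharp, possibly asymmetric transition overshoots
    the true maximum and would inflate the 5% threshold.
    """
    if i == 0 or i == len(T) - 1:
        return float(T[i]), float(Cp[i])
    y0, y1, y2 = Cp[i - 1], Cp[i], Cp[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom >= 0:  # not locally concave; keep the grid point
        return float(T[i]), float(y1)
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    return float(T[i] + delta * (T[i + 1] - T[i])), float(y1)


def detect_peaks(
    tg: Thermogram,
    min_prominence: float = 0.05,
    min_separation_C: float = 1.0,
    pre_height_frac: float = 0.5,
    pre_min_gap_C: float = 3.0,
) -> list[TransitionPeak]:
    """Locate transition peaks in a baseline-subtracted thermogram.

    Local maxima with prominence ≥ ``min_prominence`` and mutual separation
    ≥ ``min_separation_C`` are kept.  The tallest peak is the main
    transition (ties broken toward higher temperature).  A single smaller
    peak at lower temperature is labelled the pre-transition (gel → ripple)
    when its height is below ``pre_height_frac`` of the main height and it
    lies at least ``pre_min_gap_C`` below the main Tm; an exactly
    equal-height lower-temperature peak is likewise labelled pre-transition.
    Returns an empty list when nothing exceeds the threshold.
    """
    T, Cp = tg.T, tg.Cp
    if len(T) < 3:
        return []
    step = float(np.median(np.diff(T)))
    distance = max(1, int(round(min_separation_C / step)))
    idx, _ = find_peaks(Cp, prominence=min_prominence, distance=distance)
    if len(idx) == 0:
        return []

    peaks = []
    for i in idx:
        Tm, h = _refine_maximum(T, Cp, int(i))
        peaks.append(TransitionPeak(Tm=Tm, height=h, kind=OTHER, index=int(i)))

    # main: tallest, ties toward higher temperature
    main = max(peaks, key=lambda p: (p.height, p.Tm))
    main.kind = MAIN
    pre_candidates = [
        p
        for p in peaks
        if p is not main
        and p.Tm < main.Tm
        and (
            (p.height < pre_height_frac * main.height and p.Tm <= main.Tm - pre_min_gap_C)
            or np.isclose(p.height, main.height, rtol=1e-9)
        )
    ]
    if pre_candidates:
        max(pre_candidates, key=lambda p: p.height).kind = PRE
    return sorted(peaks, key=lambda p: p.Tm)


# ---------------------------------------------------------------------------
# 5% bounds and enthalpy


def _cross_outward(
    T: np.ndarray, Cp: np.ndarray, start: int, thr: float, direction: int
) -> float:
    """First sub-threshold crossing moving outward from ``start``.

    Walks in ``direction`` (−1 low side, +1 high side) until Cp drops below
    ``thr`` and linearly interpolates the crossing temperature between the
    bracketing grid points.
    """
    i = start
    last = len(T) - 1
    while 0 <= i <= last:
        if Cp[i] < thr:
            j = i - direction  # inner neighbour, Cp[j] >= thr
            frac = (thr - Cp[j]) / (Cp[i] - Cp[j])
            return float(T[j] + frac * (T[i] - T[j]))
        i += direction
    side = "low" if direction < 0 else "high"
    raise ValueError(
        f"trace never falls below {thr:.6g} on the {side}-temperature side"
    )


def transition_bounds(
    tg: Thermogram, peak: TransitionPeak, fraction: float = 0.05
) -> tuple[float, float]:
    """Onset/end temperatures at ``fraction`` of peak height (the 5% rule).

    Moves outward from the peak maximum and takes the first crossing below
    ``fraction × height`` on each side, linearly interpolated; shoulders on
    a flank therefore stay inside the transition envelope.
    """
    if not peak.height > 0:
        raise ValueError("peak height must be positive")
    thr = fraction * peak.height
    i0 = peak.index if peak.index >= 0 else int(np.argmin(np.abs(tg.T - peak.Tm)))
    T_onset = _cross_outward(tg.T, tg.Cp, i0, thr, -1)
    T_end = _cross_outward(tg.T, tg.Cp, i0, thr, +1)
    return T_onset, T_end


def transition_enthalpy(
    tg: Thermogram,
    peak: TransitionPeak,
    search_window: tuple[float, float] | None = None,
) -> float:
    """Calorimetric enthalpy (kcal/mol) of one transition.

    Trapezoid integral of the baseline-subtracted trace over
    ``[T_onset, T_end]`` extended outward to the nearest baseline (zero)
    crossings; the extension never leaves ``search_window`` (used by
    :func:`analyze_thermogram` to stop at the minimum between neighbouring
    peaks) or the grid.  A negative integral is reported as 0 with a warning.
    """
    if not (np.isfinite(peak.T_onset) and np.isfinite(peak.T_end)):
        raise ValueError("peak bounds are unset; call transition_bounds first")
    T, Cp = tg.T, tg.Cp
    w_lo, w_hi = search_window if search_window is not None else (T[0], T[-1])

    def extend(i: int, direction: int) -> tuple[int, float | None]:
        """Outermost positive index and interpolated zero crossing, if any."""
        while True:
            j = i + direction
            if not (0 <= j < len(T)) or not (w_lo <= T[j] <= w_hi):
                return i, None
            if Cp[j] <= 0:
                if Cp[i] > 0:
                    frac = Cp[i] / (Cp[i] - Cp[j])
                    return i, float(T[i] + frac * (T[j] - T[i]))
                return i, float(T[i])
            i = j

    i_on = int(np.searchsorted(T, peak.T_onset))
    i_end = int(np.searchsorted(T, peak.T_end, side="right")) - 1
    lo, z_lo = extend(i_on, -1)
    hi, z_hi = extend(i_end, +1)

    area = float(np.trapezoid(Cp[lo : hi + 1], T[lo : hi + 1]))
    if z_lo is not None:  # triangle from the zero crossing to the first point
        area += 0.5 * Cp[lo] * (T[lo] - z_lo)
    if z_hi is not None:
        area += 0.5 * Cp[hi] * (z_hi - T[hi])
    if area < 0:
        warnings.warn("negative transition integral reported as 0", stacklevel=2)
        return 0.0
    return area


def analyze_thermogram(
    tg: Thermogram,
    fraction: float = 0.05,
    min_prominence: float = 0.05,
    min_separation_C: float = 1.0,
    flank_windows: tuple[tuple[float, float], tuple[float, float]] | None = None,
    baseline_subtracted: bool = False,
) -> list[TransitionPeak]:
    """Full single-scan analysis: baseline, peaks, 5% bounds, enthalpies.

    Returns the detected peaks (sorted by temperature) with ``T_onset``,
    ``T_end`` and ``dH`` filled in.  Enthalpy integration for each peak is
    confined between the Cp minima separating it from its neighbours, so
    overlapping transitions are not double counted.  An empty or featureless
    trace yields an empty list.
    """
    if not baseline_subtracted:
        tg, _ = subtract_baseline(tg, flank_windows)
    peaks = detect_peaks(tg, min_prominence, min_separation_C)
    if not peaks:
        return []

    # integration windows bounded by inter-peak Cp minima
    cuts = [tg.T[0]]
    for a, b in zip(peaks, peaks[1:]):
        seg = slice(a.index, b.index + 1)
        cuts.append(float(tg.T[a.index + int(np.argmin(tg.Cp[seg]))]))
    cuts.append(tg.T[-1])

    for p, w_lo, w_hi in zip(peaks, cuts, cuts[1:]):
        p.T_onset, p.T_end = transition_bounds(tg, p, fraction)
        p.dH = transition_enthalpy(tg, p, search_window=(w_lo, w_hi))
    return peaks


# ---------------------------------------------------------------------------
# phase diagram


def _main_peak(entry) -> list[TransitionPeak]:
    peaks = [entry] if isinstance(entry, TransitionPeak) else list(entry)
    mains = [p for p in peaks if p.kind == MAIN]
    if not mains:
        raise ValueError("no main transition among the supplied peaks")
    return mains


def build_phase_diagram(
    analyses: Mapping[float, TransitionPeak | Sequence[TransitionPeak]],
) -> PhaseDiagram:
    """Assemble solidus/fluidus lines from per-composition main transitions.

    ``analyses`` maps the drug:lipid molar ratio to the main
    :class:`TransitionPeak` of that composition, or to a sequence of
    replicate peaks (replicates yield the mean ± sd; a single scan reports
    sd 0).  Requires at least two ratios including the pure lipid (ratio 0).
    """
    if len(analyses) < 2:
        raise ValueError("phase diagram needs at least 2 compositions")
    if not any(np.isclose(r, 0.0) for r in analyses):
        raise ValueError("phase diagram requires the pure-lipid composition (ratio 0)")
    rows = []
    for ratio in sorted(analyses):
        mains = _main_peak(analyses[ratio])
        onsets = np.array([p.T_onset for p in mains])
        ends = np.array([p.T_end for p in mains])
        if not (np.all(np.isfinite(onsets)) and np.all(np.isfinite(ends))):
            raise ValueError(f"unset transition bounds at ratio {ratio}")
        rows.append(
            {
                "ratio": float(ratio),
                "solidus_C": onsets.mean(),
                "solidus_sd": onsets.std(ddof=1) if len(onsets) > 1 else 0.0,
                "fluidus_C": ends.mean(),
                "fluidus_sd": ends.std(ddof=1) if len(ends) > 1 else 0.0,
            }
        )
    return PhaseDiagram(pd.DataFrame(rows))


def assess_fluid_immiscibility(
    diagram: PhaseDiagram, slope_tol: float = 2.0
) -> ImmiscibilityAssessment:
    """Flag fluid–fluid immiscibility from the phase-diagram line slopes.

    Fits least-squares lines to fluidus and solidus temperature versus
    drug:lipid ratio.  A fluidus line flat within ``slope_tol``
    (°C per unit ratio) combined with a solidus falling faster than
    ``slope_tol`` indicates a composition-independent completion
    temperature, i.e. coexisting fluid phases (drug-rich aggregates).
    """
    t = diagram.table
    if len(t) < 3:
        raise ValueError("immiscibility assessment needs at least 3 compositions")
    x = t["ratio"].to_numpy()
    fl = float(np.polyfit(x, t["fluidus_C"].to_numpy(), 1)[0])
    so = float(np.polyfit(x, t["solidus_C"].to_numpy(), 1)[0])
    return ImmiscibilityAssessment(
        fluid_immiscibility=(abs(fl) <= slope_tol and so < -slope_tol),
        fluidus_slope=fl,
        solidus_slope=so,
    )
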