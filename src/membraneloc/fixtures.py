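"""Reference study conditions: the DMPC/clotrimazole and POPC/clotrimazole systems.

This module pins the default parameterization of the synthetic generators
to the measured values of the reference study: DSC main-transition
temperatures and enthalpies per DMPC:clotrimazole molar ratio, the 5%
onset/completion (solidus/fluidus) temperatures, the NOESY mixing time and
the planted drug-proton depths, and the bilayer composition.  Analysis
stages run against these fixtures must recover the pinned numbers, which
is the package's primary validation path.

Values not individually measured (intermediate-ratio temperatures, the
constant fluidus level, peak widths) are interpolated or chosen once as
physically plausible; see the methods note.
"""

from __future__ import annotations

from .noesy import DEFAULT_LADDER
from .synthetic import (
    BilayerCompositionSpec,
    PlantedDepthModel,
    ThermogramSpec,
    TransitionSpec,
    default_composition,
)

__all__ = [
    "DSC_SERIES",
    "MIXING_TIME_S",
    "dsc_thermogram_spec",
    "noesy_depth_model",
    "POPC_SHIFTS_PURE_PPM",
    "POPC_SHIFTS_WITH_DRUG_PPM",
    "bilayer_spec",
]

#: Per-composition main-transition parameters, keyed by the
#: clotrimazole:DMPC molar ratio.  Tm (peak maximum), dH (calorimetric
#: enthalpy, kcal/mol), onset/end (5% peak-height crossings = solidus and
#: fluidus points).  The pure-lipid scan also carries the gel → ripple
#: pre-transition (Tm, dH); it vanishes at all drug-containing ratios.
DSC_SERIES: dict[float, dict] = {
    0.0: dict(Tm=23.7, dH=6.626, onset=22.6, end=24.6, pre=(12.5, 1.0)),
    0.02: dict(Tm=22.1, dH=6.548, onset=20.9, end=24.6, pre=None),
    0.05: dict(Tm=21.8, dH=6.386, onset=20.4, end=24.6, pre=None),
    0.1: dict(Tm=21.4, dH=6.316, onset=19.8, end=24.6, pre=None),
    0.2: dict(Tm=20.5, dH=6.342, onset=18.5, end=24.6, pre=None),
    0.5: dict(Tm=17.8, dH=6.348, onset=14.4, end=24.6, pre=None),
}

#: NOESY mixing time, seconds.
MIXING_TIME_S = 0.3

#: van't Hoff enthalpy (kcal/mol, both sides) of the narrow pre-transition.
PRE_TRANSITION_DHVH = 800.0

#: Peak-free baseline flank windows for these scans (°C).  The default
#: first/last-10% windows would clip the pre-transition and the broad
#: low-temperature flank of the high-drug scans, violating the requirement
#: that flank windows contain no peak.
DSC_FLANK_WINDOWS = ((10.0, 10.5), (37.0, 40.0))


def dsc_thermogram_spec(
    ratio: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    baseline: tuple[float, float] = (0.0, 0.0),
) -> ThermogramSpec:
    """Generator spec for the scan at one clotrimazole:DMPC molar ratio.

    The main transition is specified in crossings mode (its 5% onset/end
    are calibration targets); the pure-lipid pre-transition uses a fixed
    narrow van't Hoff width.  Scans run 10–40 °C as in the reference
    protocol, on a 0.01 °C grid.
    """
    if ratio not in DSC_SERIES:
        raise KeyError(
            f"no reference parameters for ratio {ratio}; "
            f"known ratios: {sorted(DSC_SERIES)}"
        )
    p = DSC_SERIES[ratio]
    transitions = []
    if p["pre"] is not None:
        pre_Tm, pre_dH = p["pre"]
        transitions.append(
            TransitionSpec(
                Tm=pre_Tm,
                dH_cal=pre_dH,
                dHvH_low=PRE_TRANSITION_DHVH,
                dHvH_high=PRE_TRANSITION_DHVH,
                kind="pre-transition",
            )
        )
    transitions.append(
        TransitionSpec(
            Tm=p["Tm"], dH_cal=p["dH"], T_onset=p["onset"], T_end=p["end"], kind="main"
        )
    )
    slope, intercept = baseline
    return ThermogramSpec(
        transitions=tuple(transitions),
        T_start=10.0,
        T_stop=40.0,
        T_step=0.01,
        baseline_slope=slope,
        baseline_intercept=intercept,
        noise_sd=noise_sd,
        seed=seed,
        meta={"ratio": ratio},
    )


def noesy_depth_model(noise_cv: float = 0.0, seed: int = 0) -> PlantedDepthModel:
    """Planted depths of the seven drug proton groups (A–G).

    Depths are on the lipid-ladder axis (C2 at 3, C3 at 4).  The imidazole
    protons C and A sit closest to C2 (most polar position); B, F and G
    (chlorophenyl/phenyl) and the grouped aromatic protons D and E sit
    closer to C3 — the ordering inferred from the measured rates.
    """
    return PlantedDepthModel(
        drug_depths={
            "C": 2.90,
            "A": 3.10,
            "D": 3.55,
            "E": 3.65,
            "B": 3.75,
            "F": 3.85,
            "G": 3.95,
        },
        ladder=DEFAULT_LADDER,
        sigma0=0.2,
        lam=1.0,
        noise_cv=noise_cv,
        seed=seed,
    )


#: 1H chemical shifts (ppm) of the POPC proton groups in pure vesicles and
#: with incorporated drug.  Pure-lipid values are textbook POPC positions;
#: the drug-induced upfield displacement is largest for C2 and C3,
#: mirroring the ring-current effect of the nearby aromatic rings.
POPC_SHIFTS_PURE_PPM: dict[str, float] = {
    "N(CH3)3": 3.23,
    "CH2-N": 3.65,
    "CH2-O": 4.05,
    "C2": 2.35,
    "C3": 1.57,
    "CH2": 1.26,
    "CH=CH": 5.32,
    "CH3": 0.88,
}

_UPFIELD_DELTA_PPM: dict[str, float] = {
    "N(CH3)3": 0.006,
    "CH2-N": 0.008,
    "CH2-O": 0.010,
    "C2": 0.030,
    "C3": 0.027,
    "CH2": 0.015,
    "CH=CH": 0.012,
    "CH3": 0.005,
}

POPC_SHIFTS_WITH_DRUG_PPM: dict[str, float] = {
    g: POPC_SHIFTS_PURE_PPM[g] - _UPFIELD_DELTA_PPM[g] for g in POPC_SHIFTS_PURE_PPM
}


def bilayer_spec(n_frames: int = 200, seed: int = 0) -> BilayerCompositionSpec:
    """The reference bilayer: 64 POPC + 13 drug + 2500 waters per leaflet."""
    return default_composition(n_frames=n_frames, seed=seed)
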