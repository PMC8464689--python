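"""Synthetic data generators with known ground truth.

Three generators emulate the three experimental tracks so every analysis
stage can be validated without instrument data:

* DSC thermograms: sums of two-state van't Hoff excess heat-capacity peaks
  on a linear baseline, optionally calibrated so the 5% peak-height
  crossings land on requested onset/completion temperatures.
* NOESY volume tables: cross-relaxation rates planted by an exponential
  distance kernel between drug-proton depths and a lipid group ladder,
  inverted into cross/diagonal volumes at a given mixing time.
* Bilayer coordinate frames: Gaussian z placement of united-atom groups in
  the two leaflets of an orthorhombic box (64 lipids + 13 drug molecules +
  2500 waters per leaflet by default).

All randomness is driven by one integer seed per generator call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .density import BilayerSnapshot
from .dsc import Thermogram
from .noesy import (
    DEFAULT_LADDER,
    CrossRelaxationMatrix,
    LipidGroupLadder,
    NOESYPeakTable,
)

__all__ = [
    "R_KCAL",
    "TransitionSpec",
    "ThermogramSpec",
    "CalibrationError",
    "vant_hoff_cp",
    "simulate_thermogram",
    "PlantedDepthModel",
    "simulate_noesy_table",
    "GroupPlacement",
    "BilayerCompositionSpec",
    "default_composition",
    "default_group_map",
    "simulate_bilayer_frames",
]

R_KCAL = 1.987204259e-3  # gas constant, kcal mol⁻¹ K⁻¹
_C_TO_K = 273.15


class CalibrationError(RuntimeError):
    """Raised when no positive van't Hoff enthalpy meets a crossing target."""


@dataclass(frozen=True)
class TransitionSpec:
    """One simulated transition.

    Shape is given either directly as one-sided van't Hoff enthalpies
    ``(dHvH_low, dHvH_high)`` — larger values give sharper flanks — or as
    target 5% peak-height crossings ``(T_onset, T_end)`` to which the
    one-sided enthalpies are calibrated numerically.
    """

    Tm: float  # °C
    dH_cal: float  # kcal/mol, calorimetric area of the peak
    dHvH_low: float | None = None  # kcal/mol
    dHvH_high: float | None = None
    T_onset: float | None = None  # °C, 5% crossing targets
    T_end: float | None = None
    kind: str = "main"

    def __post_init__(self) -> None:
        if not self.dH_cal > 0:
            raise ValueError("calorimetric enthalpy must be positive")
        vh = (self.dHvH_low, self.dHvH_high)
        cr = (self.T_onset, self.T_end)
        if all(v is not None for v in vh) and all(c is None for c in cr):
            if min(vh) <= 0:
                raise ValueError("van't Hoff enthalpies must be positive")
        elif all(c is not None for c in cr) and all(v is None for v in vh):
            if not self.T_onset < self.Tm < self.T_end:
                raise ValueError("crossing targets must bracket Tm")
        else:
            raise ValueError(
                "specify either (dHvH_low, dHvH_high) or (T_onset, T_end)"
            )

    @property
    def crossings_mode(self) -> bool:
        return self.T_onset is not None


@dataclass(frozen=True)
class ThermogramSpec:
    """A full synthetic scan: transitions + linear baseline + noise + grid."""

    transitions: tuple[TransitionSpec, ...]
    T_start: float = 10.0
    T_stop: float = 40.0
    T_step: float = 0.01
    baseline_slope: float = 0.0
    baseline_intercept: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.T_step > 0 or not self.T_stop > self.T_start:
            raise ValueError("temperature grid must be strictly increasing")
        if self.noise_sd < 0:
            raise ValueError("noise amplitude must be non-negative")
        for tr in self.transitions:
            if not self.T_start < tr.Tm < self.T_stop:
                raise ValueError(
                    f"transition Tm {tr.Tm} °C lies outside the grid "
                    f"[{self.T_start}, {self.T_stop}]"
                )

    def grid(self) -> np.ndarray:
        n = int(round((self.T_stop - self.T_start) / self.T_step))
        return self.T_start + self.T_step * np.arange(n + 1)


def vant_hoff_cp(
    T: np.ndarray, Tm: float, dH_cal: float, dHvH_low: float, dHvH_high: float
) -> np.ndarray:
    """Two-state excess heat capacity with one-sided van't Hoff enthalpies.

    Cp(T) = dH_cal · dHvH · K / (R · T_K² · (1 + K)²) with
    K = exp(−(dHvH/R)(1/T_K − 1/Tm_K)); dHvH_low applies below Tm and
    dHvH_high at and above it, which permits the low-side-broadened peaks
    seen for drug-containing bilayers while keeping the calorimetric area
    exactly dH_cal (each side contributes dH_cal/2).
    """
    T = np.asarray(T, dtype=float)
    TK = T + _C_TO_K
    TmK = Tm + _C_TO_K
    dHvH = np.where(T < Tm, dHvH_low, dHvH_high)
    lnK = -(dHvH / R_KCAL) * (1.0 / TK - 1.0 / TmK)
    # K/(1+K)² = sech²(lnK/2)/4, stable for arbitrarily sharp transitions
    e = np.exp(-np.abs(lnK))
    sech2 = 4.0 * e / (1.0 + e) ** 2
    return dH_cal * dHvH * sech2 / (4.0 * R_KCAL * TK**2)


def _side_cp(T: float, Tm: float, dH_cal: float, dHvH: float) -> float:
    return float(vant_hoff_cp(np.array([T]), Tm, dH_cal, dHvH, dHvH)[0])


def _peak_height(Tm: float, dH_cal: float, dHvH_low: float, dHvH_high: float) -> float:
    # K = 1 at Tm on either branch
    TmK = Tm + _C_TO_K
    return dH_cal * max(dHvH_low, dHvH_high) / (4.0 * R_KCAL * TmK**2)


def _crossing(
    Tm: float, dH_cal: float, dHvH: float, threshold: float, side: int
) -> float | None:
    """Temperature where the one-sided curve crosses ``threshold``.

    ``side`` −1 searches below Tm, +1 above.  Returns None when the flank
    maximum itself is below the threshold (crossing unreachable).
    """
    far = Tm - 200.0 if side < 0 else Tm + 200.0
    near = Tm - 1e-9 if side < 0 else Tm + 1e-9

    def f(T: float) -> float:
        return _side_cp(T, Tm, dH_cal, dHvH) - threshold

    if f(near) <= 0:  # flank maximum already below threshold
        return None
    lo, hi = (far, near) if side < 0 else (near, far)
    return float(brentq(f, lo, hi, xtol=1e-9))


def _calibrate_crossings(
    tr: TransitionSpec, fraction: float = 0.05, tol_C: float = 1e-3
) -> tuple[float, float]:
    """Find one-sided van't Hoff enthalpies hitting the 5% crossing targets.

    Each side is solved by bisection (brentq) of the crossing temperature
    against its target; because the 5% threshold depends on the overall
    peak height — set by the larger of the two enthalpies — the two
    one-sided solves are alternated until both crossings are within
    ``tol_C`` of their targets.
    """
    assert tr.crossings_mode

    def solve_side(side: int, other_dHvH: float) -> float:
        target = tr.T_onset if side < 0 else tr.T_end

        def mismatch(log_dHvH: float) -> float:
            dHvH = math.exp(log_dHvH)
            thr = fraction * _peak_height(
                tr.Tm, tr.dH_cal, *((dHvH, other_dHvH) if side < 0 else (other_dHvH, dHvH))
            )
            Tc = _crossing(tr.Tm, tr.dH_cal, dHvH, thr, side)
            if Tc is None:  # flank everywhere below threshold → crossing at ∓∞
                return 1e6 * side
            return Tc - target

        # The crossing temperature is monotone in the enthalpy only on the
        # sharp (large-enthalpy) branch, so bracket the root scanning down
        # from the sharp end and take the first sign change.
        logs = np.log(np.logspace(-3, 6, 64))[::-1]
        f_prev = mismatch(logs[0])
        for lg, lg_prev in zip(logs[1:], logs):
            f = mismatch(lg)
            if f == 0.0:
                return math.exp(lg)
            if f * f_prev < 0:
                return math.exp(brentq(mismatch, lg, lg_prev, xtol=1e-12))
            f_prev = f
        raise CalibrationError(
            f"{tr.kind} transition at Tm={tr.Tm} °C: 5% crossing target "
            f"{target} °C unreachable with positive van't Hoff enthalpy"
        )

    # initial symmetric guess from the onset side assuming it sets the height
    dH_low = dH_high = solve_side(-1, other_dHvH=1.0)
    for _ in range(60):
        dH_low = solve_side(-1, dH_high)
        dH_high = solve_side(+1, dH_low)
        thr = fraction * _peak_height(tr.Tm, tr.dH_cal, dH_low, dH_high)
        c_lo = _crossing(tr.Tm, tr.dH_cal, dH_low, thr, -1)
        c_hi = _crossing(tr.Tm, tr.dH_cal, dH_high, thr, +1)
        if (
            c_lo is not None
            and c_hi is not None
            and abs(c_lo - tr.T_onset) < tol_C
            and abs(c_hi - tr.T_end) < tol_C
        ):
            return dH_low, dH_high
    raise CalibrationError(
        f"{tr.kind} transition at Tm={tr.Tm} °C: crossing calibration did not converge"
    )


def resolve_widths(tr: TransitionSpec, fraction: float = 0.05) -> tuple[float, float]:
    """One-sided van't Hoff enthalpies of a transition, calibrating if needed."""
    if tr.crossings_mode:
        return _calibrate_crossings(tr, fraction)
    return tr.dHvH_low, tr.dHvH_high


def simulate_thermogram(spec: ThermogramSpec) -> Thermogram:
    """Render a synthetic thermogram; ground truth is stored in ``meta``.

    With ``noise_sd = 0`` the output is deterministic.  Crossings-mode
    transitions are calibrated so the noise-free 5% peak-height crossings
    land within 0.01 °C of the targets; an unreachable target raises
    :class:`CalibrationError` naming the transition.
    """
    T = spec.grid()
    Cp = spec.baseline_intercept + spec.baseline_slope * T
    truth = []
    for tr in spec.transitions:
        dH_low, dH_high = resolve_widths(tr)
        Cp = Cp + vant_hoff_cp(T, tr.Tm, tr.dH_cal, dH_low, dH_high)
        truth.append(
            {
                "kind": tr.kind,
                "Tm": tr.Tm,
                "dH_cal": tr.dH_cal,
                "dHvH_low": dH_low,
                "dHvH_high": dH_high,
                "T_onset": tr.T_onset,
                "T_end": tr.T_end,
            }
        )
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        Cp = Cp + rng.normal(0.0, spec.noise_sd, size=T.shape)
    meta = dict(spec.meta)
    meta["truth"] = truth
    meta["baseline"] = (spec.baseline_slope, spec.baseline_intercept)
    return Thermogram(T, Cp, meta)


# ---------------------------------------------------------------------------
# NOESY generator


@dataclass(frozen=True)
class PlantedDepthModel:
    """Ground-truth spatial model behind a synthetic NOESY table.

    Drug proton groups sit at planted depths on the same arbitrary-unit
    axis as the lipid ladder; true rates follow an exponential proximity
    kernel sigma_ij = sigma0 · exp(−|z_i − z_j| / lam).  ``noise_cv`` is
    the coefficient of variation of multiplicative log-normal noise applied
    to the emitted cross volumes.
    """

    drug_depths: dict[str, float]
    ladder: LipidGroupLadder = DEFAULT_LADDER
    sigma0: float = 0.2  # s⁻¹, rate at zero separation
    lam: float = 1.0  # decay length, ladder units
    noise_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.sigma0 > 0 or not self.lam > 0:
            raise ValueError("sigma0 and lambda must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if not all(np.isfinite(list(self.drug_depths.values()))):
            raise ValueError("planted depths must be finite")

    def true_rates(self) -> CrossRelaxationMatrix:
        z_l = np.array(self.ladder.depths)
        rows = {
            g: self.sigma0 * np.exp(-np.abs(z - z_l) / self.lam)
            for g, z in self.drug_depths.items()
        }
        return CrossRelaxationMatrix(
            sigma=pd.DataFrame.from_dict(rows, orient="index", columns=self.ladder.labels)
        )


def simulate_noesy_table(
    model: PlantedDepthModel, tm: float = 0.3
) -> tuple[NOESYPeakTable, CrossRelaxationMatrix]:
    """Emit a NOESY volume table consistent with the planted depths.

    Volumes follow the initial-rate relation A_ij = sigma_ij · tm · A_jj
    with fixed positive lipid diagonals; the planted rate matrix is
    returned alongside for ground-truth checks.
    """
    if not tm > 0:
        raise ValueError("mixing time must be positive")
    truth = model.true_rates()
    labels = list(model.ladder.labels)
    # fixed, deterministic diagonals of order unity, distinct per resonance
    diag = pd.Series(
        {g: 0.8 + 0.05 * i for i, g in enumerate(labels)}, name="A_diag"
    )
    cross = truth.sigma.mul(diag, axis="columns") * tm
    if model.noise_cv > 0:
        rng = np.random.default_rng(model.seed)
        s = math.sqrt(math.log(1.0 + model.noise_cv**2))
        factors = rng.lognormal(mean=-0.5 * s * s, sigma=s, size=cross.shape)
        cross = cross * factors
    table = NOESYPeakTable(cross=cross, diag=diag, tm=tm)
    return table, truth


# ---------------------------------------------------------------------------
# bilayer frames generator


@dataclass(frozen=True)
class GroupPlacement:
    """Depth distribution of one united-atom group within one molecule type."""

    molecule: str  # "lipid" | "drug" | "water"
    name_prefix: str  # GRO atom names are prefix + running number
    group: str  # density-selection label
    count_per_molecule: int
    mass: float  # amu
    mean_abs_z: float  # nm from the midplane
    sd: float  # nm

    def __post_init__(self) -> None:
        if self.count_per_molecule <= 0:
            raise ValueError("group atom count must be positive")
        if self.sd < 0 or self.mass <= 0:
            raise ValueError("sd must be non-negative and mass positive")


@dataclass(frozen=True)
class BilayerCompositionSpec:
    """Molecule counts per leaflet, group placements, box and frame count."""

    lipids_per_leaflet: int = 64
    drugs_per_leaflet: int = 13
    waters_per_leaflet: int = 2500
    placements: tuple[GroupPlacement, ...] = ()
    box: tuple[float, float, float] = (6.4, 6.4, 7.0)
    n_frames: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.lipids_per_leaflet, self.drugs_per_leaflet, self.waters_per_leaflet) <= 0:
            raise ValueError("molecule counts must be positive")
        if min(self.box) <= 0:
            raise ValueError("box lengths must be positive")
        if self.n_frames <= 0:
            raise ValueError("n_frames must be positive")
        if not self.placements:
            object.__setattr__(self, "placements", _DEFAULT_PLACEMENTS)


# United-atom placement of a POPC/clotrimazole/water system.  Depths are
# nominal distances from the bilayer midplane typical of a fluid PC
# bilayer (P–P distance ≈ 3.9 nm); the drug depths encode the
# experimentally inferred location: its nitrogens at carbonyl level, the
# molecule and its chlorine centred near the C3 acyl carbon.
_DEFAULT_PLACEMENTS: tuple[GroupPlacement, ...] = (
    GroupPlacement("lipid", "P", "phosphate", 1, 30.974, 1.95, 0.25),
    GroupPlacement("lipid", "CO", "carbonyl", 2, 28.010, 1.45, 0.22),
    GroupPlacement("lipid", "C2", "C2", 2, 14.027, 1.35, 0.22),
    GroupPlacement("lipid", "C3", "C3", 2, 14.027, 1.25, 0.22),
    GroupPlacement("lipid", "C9", "double_bond", 2, 13.019, 0.90, 0.25),
    GroupPlacement("lipid", "CM", "CH2", 20, 14.027, 0.80, 0.35),
    GroupPlacement("lipid", "CT", "terminal_CH3", 2, 15.035, 0.25, 0.20),
    GroupPlacement("drug", "NI", "drug_N", 2, 14.007, 1.45, 0.30),
    GroupPlacement("drug", "CLA", "drug_Cl", 1, 35.453, 1.30, 0.30),
    GroupPlacement("drug", "CD", "drug_C", 22, 13.019, 1.25, 0.30),
    GroupPlacement("water", "MW", "water", 1, 18.0153, 2.80, 0.35),
)


def default_composition(**overrides) -> BilayerCompositionSpec:
    """The reference synthetic system: 64 lipids, 13 drugs, 2500 waters per leaflet."""
    return BilayerCompositionSpec(**overrides)


def default_group_map(spec: BilayerCompositionSpec | None = None) -> dict[str, str]:
    """Atom-name → group-label map matching the generator's naming scheme."""
    spec = spec or default_composition()
    out: dict[str, str] = {}
    for p in spec.placements:
        for k in range(p.count_per_molecule):
            name = p.name_prefix if p.count_per_molecule == 1 else f"{p.name_prefix}{k + 1}"
            out[name] = p.group
    return out


def simulate_bilayer_frames(spec: BilayerCompositionSpec) -> list[BilayerSnapshot]:
    """Generate independent bilayer frames with Gaussian z placement.

    Each atom's z is drawn from a Gaussian at ± its group's mean |z|
    (sign set by the leaflet, midplane at the box centre); x and y are
    uniform in the box.  Atoms outside the box are wrapped, never dropped.
    Frames are independent given the seed and bit-reproducible for a fixed
    seed.  Drug-group density in the emitted frames therefore matches the
    experimentally inferred location by construction.
    """
    rng = np.random.default_rng(spec.seed)
    lx, ly, lz = spec.box
    counts = {
        "lipid": spec.lipids_per_leaflet,
        "drug": spec.drugs_per_leaflet,
        "water": spec.waters_per_leaflet,
    }

    # static atom table (names, groups, masses, molecule ids, leaflet signs)
    names, groups, masses, mol_ids, signs, mean_z, sd_z = [], [], [], [], [], [], []
    mol_id = 0
    for leaflet_sign in (+1, -1):
        for molecule in ("lipid", "drug", "water"):
            placements = [p for p in spec.placements if p.molecule == molecule]
            for _ in range(counts[molecule]):
                mol_id += 1
                for p in placements:
                    for k in range(p.count_per_molecule):
                        name = (
                            p.name_prefix
                            if p.count_per_molecule == 1
                            else f"{p.name_prefix}{k + 1}"
                        )
                        names.append(name)
                        groups.append(p.group)
                        masses.append(p.mass)
                        mol_ids.append(mol_id)
                        signs.append(leaflet_sign)
                        mean_z.append(p.mean_abs_z)
                        sd_z.append(p.sd)

    names = np.array(names)
    groups = np.array(groups)
    masses = np.array(masses, dtype=float)
    mol_ids = np.array(mol_ids, dtype=int)
    signs = np.array(signs, dtype=float)
    mean_z = np.array(mean_z, dtype=float)
    sd_z = np.array(sd_z, dtype=float)
    n = len(names)

    frames = []
    for _ in range(spec.n_frames):
        xy = rng.uniform(0.0, [lx, ly], size=(n, 2))
        z = lz / 2 + signs * rng.normal(mean_z, sd_z)
        z %= lz  # wrap into the primary box
        xyz = np.column_stack([xy, z])
        frames.append(
            BilayerSnapshot(
                names=names,
                mol_ids=mol_ids,
                groups=groups,
                masses=masses,
                xyz=xyz,
                box=spec.box,
            )
        )
    return frames
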