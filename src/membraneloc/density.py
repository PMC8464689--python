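"""Mass-density profiles along the bilayer normal (z-axis).

Bins the masses of a chosen atom selection along z for every trajectory
frame, after recentring each frame so that the bilayer midplane sits at
z = 0, and averages over frames.  Peak positions and widths of the
resulting profiles locate molecular groups along the membrane normal:
phosphate outermost, carbonyls below it, then the first acyl carbons, the
oleoyl double bond, and the terminal methyls at the centre.

Units: nm and amu in, kg m⁻³ out.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .gro import RawFrame, mass_of, read_gro

__all__ = [
    "BilayerSnapshot",
    "DensityProfile",
    "ProfileStatistics",
    "load_gro",
    "density_profile",
    "symmetrize",
    "profile_statistics",
    "compare_profiles",
]

AMU_PER_KG_M3 = 1.66053906660  # amu/nm³ → kg/m³ (1.66e-27 kg / 1e-27 m³)


@dataclass(frozen=True)
class BilayerSnapshot:
    """Labelled point masses of one bilayer frame in an orthorhombic box."""

    names: np.ndarray
    mol_ids: np.ndarray
    groups: np.ndarray  # group label per atom (e.g. "phosphate", "drug_N")
    masses: np.ndarray  # amu
    xyz: np.ndarray  # (n, 3) nm
    box: tuple[float, float, float]  # nm

    def __post_init__(self) -> None:
        n = len(self.names)
        if not (
            len(self.mol_ids) == len(self.groups) == len(self.masses) == n
            and self.xyz.shape == (n, 3)
        ):
            raise ValueError("snapshot arrays have inconsistent lengths")
        if np.any(self.masses <= 0):
            raise ValueError("atom masses must be positive")
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("coordinates must be finite")
        if min(self.box) <= 0:
            raise ValueError("box lengths must be positive")


@dataclass(frozen=True)
class DensityProfile:
    """Frame-averaged mass density per z bin for one selection.

    ``z`` holds bin centres (nm, midplane at 0), ``density`` the mass
    density (kg m⁻³).  ``bin_width`` is the realized width (the requested
    width rounded so bins tile the box exactly) and ``box_area`` the x–y
    cross-section used for the bin volume.
    """

    z: np.ndarray
    density: np.ndarray
    selection: str
    n_frames: int
    bin_width: float
    box_area: float

    def __post_init__(self) -> None:
        if np.any(self.density < 0):
            raise ValueError("densities must be non-negative")

    @property
    def total_mass_amu(self) -> float:
        """Mean selection mass per frame implied by the profile."""
        return float(
            self.density.sum() * self.bin_width * self.box_area / AMU_PER_KG_M3
        )

    def to_tsv(self, path) -> None:
        pd.DataFrame({"z_nm": self.z, "density_kg_m3": self.density}).to_csv(
            path, sep="\t", index=False
        )


@dataclass(frozen=True)
class ProfileStatistics:
    peak_z: float  # bin centre of the maximum (ties → smaller |z|)
    mean_abs_z: float  # mass-weighted mean distance from the midplane
    fwhm: float  # full width at half maximum of the main peak


# ---------------------------------------------------------------------------
# loading


def load_gro(path, group_map: Mapping[str, str]) -> list[BilayerSnapshot]:
    """Read GRO frames and attach group labels and masses.

    ``group_map`` maps exact atom names to group labels; any atom name not
    in the map aborts with the full list of unmapped names.  Masses come
    from the built-in element/united-atom table keyed by atom name.
    """
    snapshots = []
    for fr in read_gro(path):
        unmapped = sorted({n for n in fr.names if n not in group_map})
        if unmapped:
            raise ValueError(f"atom names missing from group map: {unmapped}")
        groups = np.array([group_map[n] for n in fr.names])
        masses = np.array([mass_of(n) for n in fr.names])
        snapshots.append(
            BilayerSnapshot(
                names=fr.names,
                mol_ids=fr.resids,
                groups=groups,
                masses=masses,
                xyz=fr.xyz,
                box=fr.box,
            )
        )
    return snapshots


def snapshot_to_raw(snap: BilayerSnapshot, resname_map: Mapping[str, str] | None = None) -> RawFrame:
    """Convert a snapshot to a raw GRO frame (resname from the group label)."""
    resnames = np.array(
        [
            (resname_map or {}).get(g, g[:5].upper() or "MOL")
            for g in snap.groups
        ]
    )
    return RawFrame(
        names=snap.names,
        resids=snap.mol_ids,
        resnames=resnames,
        xyz=snap.xyz,
        box=snap.box,
    )


# ---------------------------------------------------------------------------
# profiles


def _select(snap: BilayerSnapshot, selection) -> np.ndarray:
    if callable(selection):
        return np.asarray(selection(snap), dtype=bool)
    if isinstance(selection, str):
        wanted = {selection} if selection != "all" else set(snap.groups)
    else:
        wanted = set(selection)
    return np.isin(snap.groups, list(wanted))


def _center_z(snap: BilayerSnapshot, centering: str) -> np.ndarray:
    """Frame z coordinates shifted so the chosen reference COM is 0."""
    z = snap.xyz[:, 2]
    if centering == "phosphate":
        ref = snap.groups == "phosphate"
        if not ref.any():
            raise ValueError("no phosphate-group atoms to centre on")
    elif centering == "lipid":
        ref = np.isin(
            snap.groups,
            [g for g in np.unique(snap.groups) if not g.startswith(("drug", "water"))],
        )
    elif centering == "none":
        return z.copy()
    else:
        raise ValueError(f"unknown centering convention {centering!r}")
    zc = float(np.average(z[ref], weights=snap.masses[ref]))
    return z - zc


def density_profile(
    frames: Sequence[BilayerSnapshot],
    selection: str | Sequence[str] | Callable,
    bin_width: float = 0.1,
    centering: str = "phosphate",
) -> DensityProfile:
    """z-axis mass density of ``selection``, averaged over frames.

    Each frame is recentred (default: centre of mass of the
    phosphorus-group atoms defines z = 0, placing the midplane at the
    origin for a symmetric bilayer), atoms are wrapped into
    [−Lz/2, Lz/2) and binned into half-open bins of ~``bin_width`` whose
    count is chosen so they tile the box exactly.  Bin masses are divided
    by the bin volume (width × box x–y area) and averaged over frames.
    """
    if len(frames) == 0:
        raise ValueError("at least one frame is required")
    if not bin_width > 0:
        raise ValueError("bin width must be positive")
    lx, ly, lz = frames[0].box
    n_bins = max(1, int(round(lz / bin_width)))
    edges = np.linspace(-lz / 2, lz / 2, n_bins + 1)
    width = lz / n_bins
    area = lx * ly

    acc = np.zeros(n_bins)
    label = selection if isinstance(selection, str) else ",".join(selection) if not callable(selection) else getattr(selection, "__name__", "custom")
    any_selected = False
    for snap in frames:
        if snap.box != frames[0].box:
            raise ValueError("all frames must share the same box")
        mask = _select(snap, selection)
        if mask.any():
            any_selected = True
        z = _center_z(snap, centering)[mask]
        z = (z + lz / 2) % lz - lz / 2  # wrap, never drop
        hist, _ = np.histogram(z, bins=edges, weights=snap.masses[mask])
        acc += hist
    if not any_selected:
        raise ValueError(f"selection {label!r} matches no atoms")

    density = acc / len(frames) / (width * area) * AMU_PER_KG_M3
    centers = 0.5 * (edges[:-1] + edges[1:])
    return DensityProfile(
        z=centers,
        density=density,
        selection=label,
        n_frames=len(frames),
        bin_width=width,
        box_area=area,
    )


def symmetrize(p: DensityProfile) -> DensityProfile:
    """Average the two leaflets: rho_sym(z) = (rho(z) + rho(−z)) / 2."""
    return DensityProfile(
        z=p.z,
        density=0.5 * (p.density + p.density[::-1]),
        selection=p.selection,
        n_frames=p.n_frames,
        bin_width=p.bin_width,
        box_area=p.box_area,
    )


def profile_statistics(p: DensityProfile) -> ProfileStatistics:
    """Peak position, mass-weighted mean |z| and FWHM of a profile.

    The peak is the bin centre of the global maximum, ties resolved toward
    smaller |z|; the FWHM brackets that peak by linear interpolation at
    half maximum (walking outward until the profile drops below half).
    """
    rho = p.density
    if len(rho) == 0 or not rho.max() > 0:
        raise ValueError("profile is empty or all zero")
    top = rho.max()
    candidates = np.flatnonzero(rho == top)
    i = int(candidates[np.argmin(np.abs(p.z[candidates]))])
    half = top / 2

    def half_cross(direction: int) -> float:
        j = i
        while 0 <= j + direction < len(rho):
            k = j + direction
            if rho[k] < half:
                frac = (rho[j] - half) / (rho[j] - rho[k])
                return float(p.z[j] + frac * (p.z[k] - p.z[j]))
            j = k
        return float(p.z[j])  # never drops below half: clip at the edge

    fwhm = half_cross(+1) - half_cross(-1)
    mean_abs_z = float(np.average(np.abs(p.z), weights=rho))
    return ProfileStatistics(peak_z=float(p.z[i]), mean_abs_z=mean_abs_z, fwhm=fwhm)


def compare_profiles(a: DensityProfile, b: DensityProfile) -> float:
    """Signed peak offset peak|z|(a) − peak|z|(b) of leaflet-symmetrized profiles."""
    if len(a.z) != len(b.z) or not np.allclose(a.z, b.z):
        raise ValueError("profiles use different binning")
    pa = profile_statistics(symmetrize(a))
    pb = profile_statistics(symmetrize(b))
    return abs(pa.peak_z) - abs(pb.peak_z)
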