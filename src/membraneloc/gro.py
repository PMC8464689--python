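"""Fixed-column GRO coordinate file reading and writing.

Supports the plain fixed-column dialect (nm units, %8.3f coordinates) with
an orthorhombic box line; multi-frame files are accepted as concatenated
title/count/atoms/box blocks.  Only the three diagonal box components may
be non-zero — triclinic boxes are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["RawFrame", "read_gro", "write_gro", "mass_of"]


@dataclass(frozen=True)
class RawFrame:
    """One GRO frame before group mapping: names, residues, coordinates."""

    names: np.ndarray  # atom names, str
    resids: np.ndarray  # residue numbers, int
    resnames: np.ndarray  # residue names, str
    xyz: np.ndarray  # (n, 3) nm
    box: tuple[float, float, float]  # nm


# united-atom / element masses (amu) by longest-prefix match on the atom
# name; united entries cover the synthetic bilayer naming scheme (CO
# carbonyl, CT terminal CH3, CM bulk CH2, C2/C3 acyl CH2, C9/CD sp2 CH,
# NI imidazole N, MW one-site water).
_MASS_PREFIXES: tuple[tuple[str, float], ...] = (
    ("CLA", 35.453),
    ("CL", 35.453),
    ("CO", 28.010),
    ("CT", 15.035),
    ("CM", 14.027),
    ("C2", 14.027),
    ("C3", 14.027),
    ("C9", 13.019),
    ("CD", 13.019),
    ("CH3", 15.035),
    ("CH2", 14.027),
    ("CH1", 13.019),
    ("CH", 13.019),
    ("NI", 14.007),
    ("MW", 18.0153),
    ("OW", 15.999),
    ("HW", 1.008),
    ("P", 30.974),
    ("N", 14.007),
    ("O", 15.999),
    ("S", 32.06),
    ("C", 12.011),
    ("H", 1.008),
)


def mass_of(name: str) -> float:
    """Atomic/united-atom mass for a GRO atom name (longest prefix match)."""
    key = name.strip().upper()
    for prefix, mass in _MASS_PREFIXES:
        if key.startswith(prefix):
            return mass
    raise KeyError(name.strip())


def _parse_box(line: str, lineno: int) -> tuple[float, float, float]:
    try:
        parts = [float(tok) for tok in line.split()]
    except ValueError:
        raise ValueError(f"line {lineno}: malformed box line {line!r}") from None
    if len(parts) == 3:
        lx, ly, lz = parts
    elif len(parts) == 9:
        lx, ly, lz = parts[:3]
        if any(abs(v) > 1e-12 for v in parts[3:]):
            raise ValueError(
                f"line {lineno}: triclinic box not supported (off-diagonal "
                "components must be zero)"
            )
    else:
        raise ValueError(f"line {lineno}: box line must have 3 or 9 components")
    if min(lx, ly, lz) <= 0:
        raise ValueError(f"line {lineno}: box lengths must be positive")
    return lx, ly, lz


def read_gro(path) -> list[RawFrame]:
    """Read all frames of a (possibly concatenated multi-frame) GRO file."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    frames: list[RawFrame] = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():  # trailing blank lines
            i += 1
            continue
        if i + 1 >= len(lines):
            raise ValueError(f"line {i + 1}: truncated frame header")
        try:
            n_atoms = int(lines[i + 1].strip())
        except ValueError:
            raise ValueError(
                f"line {i + 2}: expected atom count, got {lines[i + 1]!r}"
            ) from None
        first = i + 2
        if first + n_atoms + 1 > len(lines):
            raise ValueError(
                f"line {len(lines)}: truncated frame (expected {n_atoms} atoms + box)"
            )
        names, resids, resnames, xyz = [], [], [], []
        for k in range(n_atoms):
            ln = lines[first + k]
            lineno = first + k + 1
            if len(ln) < 44:
                raise ValueError(f"line {lineno}: atom line too short ({len(ln)} chars)")
            try:
                resids.append(int(ln[0:5]))
                resnames.append(ln[5:10].strip())
                names.append(ln[10:15].strip())
                xyz.append((float(ln[20:28]), float(ln[28:36]), float(ln[36:44])))
            except ValueError:
                raise ValueError(f"line {lineno}: malformed atom line {ln!r}") from None
        box = _parse_box(lines[first + n_atoms], first + n_atoms + 1)
        frames.append(
            RawFrame(
                names=np.array(names),
                resids=np.array(resids, dtype=int),
                resnames=np.array(resnames),
                xyz=np.array(xyz, dtype=float),
                box=box,
            )
        )
        i = first + n_atoms + 1
    if not frames:
        raise ValueError("no frames found in GRO file")
    return frames


def write_gro(path, frames, title: str = "synthetic bilayer") -> None:
    """Write frames (RawFrame or compatible) as a concatenated GRO file."""
    if isinstance(frames, RawFrame):
        frames = [frames]
    with open(path, "w") as fh:
        for t, fr in enumerate(frames):
            fh.write(f"{title} frame {t}\n{len(fr.names):5d}\n")
            for k in range(len(fr.names)):
                fh.write(
                    f"{int(fr.resids[k]) % 100000:5d}"
                    f"{str(fr.resnames[k])[:5]:<5s}"
                    f"{str(fr.names[k])[:5]:>5s}"
                    f"{(k + 1) % 100000:5d}"
                    f"{fr.xyz[k, 0]:8.3f}{fr.xyz[k, 1]:8.3f}{fr.xyz[k, 2]:8.3f}\n"
                )
            fh.write(f"{fr.box[0]:10.5f}{fr.box[1]:10.5f}{fr.box[2]:10.5f}\n")
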