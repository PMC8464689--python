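"""NOESY cross-relaxation analysis and drug depth ranking in bilayers.

Cross-peak volumes from a 2D NOESY MAS-NMR spectrum of drug-containing
phospholipid vesicles report through-space proximity between drug protons
and lipid proton groups.  In the initial-rate regime the cross-relaxation
rate between drug resonance i and lipid resonance j is

    sigma_ij = A_ij / (A_jj * t_m)

with A_ij the cross-peak volume, A_jj the diagonal volume of the lipid
resonance and t_m the mixing time.  Normalizing each drug proton's rates
over an ordered ladder of lipid groups (headgroup → terminal methyl) gives
a proximity profile along the bilayer normal, whose weighted mean ranks the
drug protons by insertion depth.  Ring-current-induced chemical-shift
differences (pure lipid minus drug-containing sample) provide an
independent proximity read-out for the aromatic drug moieties.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NOESYPeakTable",
    "CrossRelaxationMatrix",
    "LipidGroupLadder",
    "ShiftTable",
    "LocalizationProfile",
    "DEFAULT_LADDER",
    "cross_relaxation_rate",
    "rate_matrix",
    "shift_changes",
    "localization_profile",
]


@dataclass(frozen=True)
class NOESYPeakTable:
    """Cross- and diagonal-peak volumes at one mixing time.

    ``cross`` is indexed by drug proton group (rows) × lipid proton group
    (columns); NaN marks a cross-peak that could not be observed (absent,
    not zero).  ``diag`` holds the diagonal volume of every referenced
    lipid resonance.  ``tm`` is the mixing time in seconds.
    """

    cross: pd.DataFrame
    diag: pd.Series
    tm: float

    def __post_init__(self) -> None:
        if not self.tm > 0:
            raise ValueError("mixing time must be positive")
        vals = self.cross.to_numpy(dtype=float)
        if np.any(np.isinf(vals)):
            raise ValueError("cross volumes must be finite")
        if np.nanmin(vals, initial=0.0) < 0:
            raise ValueError("cross volumes must be non-negative")
        if not np.all(np.isfinite(self.diag.to_numpy(dtype=float))):
            raise ValueError("diagonal volumes must be finite")
        if (self.diag <= 0).any():
            raise ValueError("diagonal volumes must be positive")
        missing = set(self.cross.columns) - set(self.diag.index)
        if missing:
            raise ValueError(f"no diagonal volume for lipid groups: {sorted(missing)}")

    def to_tsv(self, cross_path, diag_path) -> None:
        long = (
            self.cross.rename_axis("drug_group")
            .reset_index()
            .melt("drug_group", var_name="lipid_group", value_name="A_cross")
            .dropna(subset=["A_cross"])
        )
        long.to_csv(cross_path, sep="\t", index=False)
        self.diag.rename_axis("group").rename("A_diag").reset_index().to_csv(
            diag_path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, cross_path, diag_path, tm: float) -> "NOESYPeakTable":
        long = pd.read_csv(cross_path, sep="\t")
        diag = pd.read_csv(diag_path, sep="\t").set_index("group")["A_diag"]
        cross = long.pivot(
            index="drug_group", columns="lipid_group", values="A_cross"
        )
        return cls(cross=cross, diag=diag, tm=tm)


@dataclass(frozen=True)
class CrossRelaxationMatrix:
    """Cross-relaxation rates sigma_ij (s⁻¹), drug rows × lipid columns.

    NaN marks an absent cross-peak.  ``sd`` (optional) carries per-cell
    standard deviations over replicate determinations.
    """

    sigma: pd.DataFrame
    sd: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        vals = self.sigma.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise ValueError("cross-relaxation rates must be non-negative")
        if self.sd is not None and not self.sd.shape == self.sigma.shape:
            raise ValueError("sd shape must match the rate matrix")

    def to_tsv(self, path) -> None:
        self.sigma.rename_axis("drug_group").to_csv(path, sep="\t")


@dataclass(frozen=True)
class LipidGroupLadder:
    """Ordered lipid proton groups with nominal depth coordinates.

    Depth is an arbitrary-unit coordinate increasing from the most polar
    group (0) toward the bilayer centre; the default ladder spaces the
    groups equally because only the ordering is experimentally anchored.
    """

    labels: tuple[str, ...]
    depths: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.depths):
            raise ValueError("labels and depths differ in length")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("ladder labels must be unique")
        if not np.all(np.diff(self.depths) > 0):
            raise ValueError("ladder depths must be strictly increasing")

    def depth_of(self, label: str) -> float:
        return self.depths[self.labels.index(label)]


DEFAULT_LADDER = LipidGroupLadder(
    labels=("N(CH3)3", "CH2-N", "CH2-O", "C2", "C3", "CH2", "CH=CH", "CH3"),
    depths=(0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0),
)


@dataclass(frozen=True)
class ShiftTable:
    """Chemical shifts of the pure lipid vs. the drug-containing sample.

    ``d_delta = delta_pure − delta_drug`` (ppm); an upfield movement of the
    drug-containing sample gives a positive difference.
    """

    table: pd.DataFrame  # columns: delta_pure_ppm, delta_drug_ppm, d_delta_ppm

    def to_tsv(self, path) -> None:
        self.table.rename_axis("group").to_csv(path, sep="\t")


@dataclass(frozen=True)
class LocalizationProfile:
    """Per-drug-proton proximity profiles over the lipid ladder.

    ``profiles``: rows are drug groups, columns the ladder groups; each row
    is normalized to sum 1 over its observed cells.  ``summary`` reports the
    argmax lipid group and the depth-weighted profile mean per drug proton.
    ``uninformative`` lists drug groups with no usable cross-peaks.
    """

    profiles: pd.DataFrame
    summary: pd.DataFrame  # columns: argmax_lipid_group, weighted_depth
    uninformative: tuple[str, ...] = field(default=())

    def to_tsv(self, path) -> None:
        self.summary.rename_axis("drug_group").to_csv(path, sep="\t")


# ---------------------------------------------------------------------------


def cross_relaxation_rate(A_cross: float, A_diag: float, tm: float) -> float:
    """sigma = A_cross / (A_diag * tm), the initial-rate NOESY estimate."""
    if not A_diag > 0:
        raise ValueError("diagonal volume must be positive")
    if not tm > 0:
        raise ValueError("mixing time must be positive")
    return A_cross / (A_diag * tm)


def rate_matrix(table: NOESYPeakTable) -> CrossRelaxationMatrix:
    """Apply the initial-rate estimate cell-wise to a NOESY volume table.

    Each cross volume is normalized by the diagonal of its lipid (column)
    resonance and the mixing time.  Absent cross-peaks propagate as NaN.
    """
    diag = table.diag.reindex(table.cross.columns)
    sigma = table.cross.div(diag * table.tm, axis="columns")
    return CrossRelaxationMatrix(sigma=sigma)


def shift_changes(
    pure: Mapping[str, float] | pd.Series, with_drug: Mapping[str, float] | pd.Series
) -> ShiftTable:
    """Chemical-shift differences delta_pure − delta_drug per lipid group."""
    pure = pd.Series(dict(pure), dtype=float)
    drug = pd.Series(dict(with_drug), dtype=float)
    only_pure = set(pure.index) - set(drug.index)
    only_drug = set(drug.index) - set(pure.index)
    if only_pure or only_drug:
        raise ValueError(
            "shift tables cover different groups: "
            f"only in pure: {sorted(only_pure)}; only with drug: {sorted(only_drug)}"
        )
    drug = drug.reindex(pure.index)
    return ShiftTable(
        pd.DataFrame(
            {
                "delta_pure_ppm": pure,
                "delta_drug_ppm": drug,
                "d_delta_ppm": pure - drug,
            }
        )
    )


def localization_profile(
    m: CrossRelaxationMatrix, ladder: LipidGroupLadder = DEFAULT_LADDER
) -> LocalizationProfile:
    """Depth-rank drug protons from their normalized rate profiles.

    Each drug row is normalized to sum 1 over its observed (non-NaN) ladder
    columns; the weighted mean depth is the profile-weighted average of the
    ladder's nominal depths, and the argmax is the lipid group with the
    largest share (ties broken toward the more polar, i.e. shallower,
    group).  Rows with no positive observed rate are flagged uninformative
    and excluded from the depth ranking.
    """
    extra = set(m.sigma.columns) - set(ladder.labels)
    if extra:
        raise ValueError(f"rate-matrix columns not on the ladder: {sorted(extra)}")
    cols = [g for g in ladder.labels if g in m.sigma.columns]
    depths = np.array([ladder.depth_of(g) for g in cols])
    sig = m.sigma[cols]

    profiles, rows, dead = {}, [], []
    for drug_group, row in sig.iterrows():
        total = row.sum(skipna=True)
        if not total > 0:
            dead.append(str(drug_group))
            continue
        p = row / total
        profiles[drug_group] = p
        w = p.to_numpy(dtype=float)
        w_clean = np.nan_to_num(w)
        argmax = cols[int(np.argmax(w_clean))]  # first max → more polar on ties
        rows.append(
            {
                "drug_group": drug_group,
                "argmax_lipid_group": argmax,
                "weighted_depth": float(np.nansum(w * depths)),
            }
        )
    if not rows:
        raise ValueError("no drug group has informative cross-peaks")
    return LocalizationProfile(
        profiles=pd.DataFrame(profiles).T.reindex(columns=cols),
        summary=pd.DataFrame(rows).set_index("drug_group"),
        uninformative=tuple(dead),
    )
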