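# Methods

This note documents the models behind `membraneloc`, the parameters that
matter, and what the synthetic generators do and do not emulate.

## DSC track

### Thermogram model

Synthetic scans are sums of two-state van't Hoff excess heat-capacity
peaks on a linear baseline:

    Cp(T) = ΔH_cal · ΔH_vH · K / (4 R T_K²) · sech²(ln K / 2),
    ln K  = −(ΔH_vH / R)(1/T_K − 1/Tm_K)

with the gas constant R in kcal mol⁻¹ K⁻¹ and temperatures converted to
kelvin only inside this expression.  `ΔH_cal` (kcal/mol) is the
calorimetric area; `ΔH_vH` controls sharpness.  A separate `ΔH_vH` below
and above `Tm` permits the low-side-broadened peaks of drug-containing
mixtures; each side then integrates to exactly `ΔH_cal/2`.  The price of
the piecewise form is a step discontinuity in `Cp` at `Tm` when the two
enthalpies differ; on the default 0.01 °C grid it contributes < 0.1% to
the trapezoid area and shifts the discrete maximum by at most ~0.015 °C,
both well inside the analysis tolerances (0.05 °C, 1%).

Instead of widths, a transition can be specified by target onset and
completion temperatures.  The generator then calibrates each one-sided
`ΔH_vH` so that the noise-free crossings of 5% of peak height land on the
targets within 0.01 °C.  Each side is solved with Brent's method; because
the 5% threshold is set by the overall peak height — i.e. by the larger
of the two enthalpies — the two one-sided solves are alternated to a
fixed point (converges in 2–3 rounds).  The crossing temperature is
monotone in the enthalpy only on the sharp branch; the solver brackets
from the sharp end so that an unreachable target (threshold above the
entire flank) raises a calibration error naming the transition rather
than returning the spurious inner root.

### Analysis

* **Baseline**: a straight line through the mean points of two operator-
  chosen flank windows (default: first and last 10% of the grid), which
  must be peak-free — a window containing the global residual maximum is
  rejected.  The pinned reference conditions use windows (10–10.5 °C,
  37–40 °C) because the pre-transition at 12.5 °C sits inside the default
  low window.
* **Peak detection**: `scipy.signal.find_peaks` with a prominence floor
  (default 0.05 kcal mol⁻¹ °C⁻¹) and 1 °C minimum separation.  The
  position is refined by a three-point parabola; the reported height is
  the measured grid maximum, because an apex parabola overestimates the
  height of sharp asymmetric peaks by 1–2% and would inflate the 5%
  threshold (shifting the recovered onset by ~0.07 °C).  The tallest peak
  is the main transition; a lower-temperature peak below 50% of the main
  height and ≥ 3 °C away is the pre-transition, and an exactly
  equal-height lower peak also resolves to pre-transition so the
  labelling is deterministic.
* **5% rule**: onset/end are the first crossings of 5% of peak height
  walking outward from the maximum, linearly interpolated — first
  crossing, so flank shoulders (seen at high drug content) stay inside
  the transition envelope.
* **Enthalpy**: trapezoid integral over [onset, end] extended outward to
  the nearest baseline crossing.  On noise-free multi-peak traces the
  trace never crosses zero, so the full analysis bounds each peak's
  extension at the Cp minima separating neighbouring peaks; otherwise
  the main-transition integral would swallow the pre-transition.
* **Phase diagram**: solidus = onset, fluidus = completion of the main
  transition per composition; sd over replicate scans where given, else
  0.  Fluid immiscibility is flagged when the least-squares fluidus
  slope is flat within `slope_tol` (default 2 °C per unit drug:lipid
  molar ratio) while the solidus falls faster than that.

### Reference conditions

The pinned series (ratio = clotrimazole:DMPC, °C, kcal/mol):

| ratio | Tm   | ΔH    | onset | end  | pre-transition |
|-------|------|-------|-------|------|----------------|
| 0     | 23.7 | 6.626 | 22.6  | 24.6 | 12.5 °C, 1.0   |
| 0.02  | 22.1 | 6.548 | 20.9  | 24.6 | —              |
| 0.05  | 21.8 | 6.386 | 20.4  | 24.6 | —              |
| 0.1   | 21.4 | 6.316 | 19.8  | 24.6 | —              |
| 0.2   | 20.5 | 6.342 | 18.5  | 24.6 | —              |
| 0.5   | 17.8 | 6.348 | 14.4  | 24.6 | —              |

Anchored values are the measured ones; the intermediate-ratio
temperatures are monotone interpolations chosen once (the measurements
report only the endpoints and the 50:1 step), and the constant fluidus
level of 24.6 °C encodes the observed composition-independent completion
temperature.  The pre-transition width (van't Hoff enthalpy
800 kcal/mol) and the ~1 kcal/mol pre-transition enthalpy are typical
DMPC values; measured widths are not available, so widths are free
generator parameters throughout.  Scans run 10–40 °C on a 0.01 °C grid
(3001 points).

## NOESY track

The initial-rate estimate of the cross-relaxation rate between drug
proton i and lipid proton group j is `σ_ij = A_ij / (A_jj · t_m)` with
cross volume `A_ij`, diagonal volume `A_jj` and mixing time `t_m`
(default 0.3 s).  The diagonal is resolved as the **lipid (column)
resonance**: cross-peaks are normalized per lipid resonance so that rows
are comparable across drug protons.  Unobserved cross-peaks are treated
as *absent* (NaN), not zero — in crowded spectra a missing peak is not
evidence of zero intensity — and are excluded from profile
normalization.

Depth ranking: each drug row of the rate matrix is normalized to sum 1
over the observed columns of an ordered lipid ladder — by default
N(CH3)3, CH2-N, CH2-O, C2, C3, bulk CH2, CH=CH, terminal CH3 at equally
spaced nominal depths 0–7 (the experimental ordering is known but no
numeric depths are; the units are therefore arbitrary).  The weighted
mean depth ranks the drug protons; the argmax group resolves ties toward
the more polar group.

The generator plants drug-proton depths on the ladder axis and emits
volumes via `A_ij = σ_ij · t_m · A_jj` with fixed order-unity diagonals
and rates from an exponential kernel
`σ_ij = σ₀ · exp(−|z_i − z_j|/λ)` (σ₀ = 0.2 s⁻¹, λ = 1 ladder unit).
The kernel is a monotone distance proxy, *not* r⁻⁶ spin physics: it
suffices for ordering-recovery tests but carries no spin-diffusion or
correlation-time information.  Planted depths put the imidazole protons
C and A nearest C2 and the phenyl/chlorophenyl protons (D, E, B, F, G)
nearer C3, the experimentally inferred arrangement; multiplicative
log-normal noise with a chosen coefficient of variation models volume
integration error.  Reference chemical shifts use textbook POPC
positions with planted upfield displacements largest at C2/C3.

## Density track

Mass-density profiles bin atom masses along z in half-open bins
(default 0.1 nm, adjusted so bins tile the box exactly), divide by bin
volume (width × box x–y area, amu/nm³ → kg/m³ via 1.66053906660) and
average over frames.  Each frame is first recentred so the centre of
mass of the phosphorus-group atoms defines z = 0 (whole-lipid COM and
no centering are selectable); atoms are wrapped into the primary box,
never dropped, which makes the per-selection mass exactly conserved —
an invariant the tests check to 10⁻⁹ relative.  Only orthorhombic boxes
are supported (sufficient for planar bilayers).  Peak statistics report
the bin centre of the maximum (ties toward smaller |z|), the
mass-weighted mean |z|, and the FWHM of the main peak by linear
interpolation; profile comparisons use |peak z| of leaflet-symmetrized
profiles.

The frame generator places each united-atom group at ± its nominal
mean |z| with Gaussian spread, x–y uniform — 64 POPC, 13 clotrimazole
and 2500 one-site waters per leaflet in a 6.4 × 6.4 × 7.0 nm box.
Nominal depths are typical fluid-PC values (P at 1.95 nm, carbonyls
1.45, C2 1.35, C3 1.25, double bond 0.90, terminal CH3 0.25 nm); the
drug placement encodes the inferred location (nitrogens at carbonyl
level 1.45 nm; chlorine 1.30 nm; ring carbons 1.25 nm).  Frames are
independent draws — there is no molecular connectivity, no dynamics,
no force field, and no water structure — so the generator validates the
*analysis* (binning, centering, statistics, file I/O), not membrane
physics.  Default profile runs use 200 frames (~10⁴–10⁵ samples per
selection), enough to pin every landmark's peak bin at 0.1 nm
resolution.

## What passing tests show — and do not show

Recovery tests demonstrate that the analysis stages are correct
inverses of the stated forward models at realistic signal-to-noise, and
the oracle tests (dense-scan crossings, refined Riemann sums, per-atom
histogram loops, independent GRO parsing) show the numerics are exact
to their tolerances.  They do not validate the forward models against
real instruments: real thermograms have scan-rate and response
distortions, real NOESY volumes include spin diffusion, and real
bilayers have correlated, connected molecules.  Degenerate inputs are
handled explicitly: featureless traces yield empty peak lists (not
errors), negative enthalpy integrals report 0 with a warning,
uninformative (all-zero) NOESY rows are flagged and excluded, and
all-zero density profiles are rejected.

## Problem sizes

Default problem sizes — 3001-point thermograms, a 7 × 8 rate matrix,
100-replicate noise studies, 200-frame density runs of ~9600 atoms —
were chosen so every quantity's Monte-Carlo or discretization error is
at least an order of magnitude below its test tolerance; the full suite
and the acceptance script each run in well under a minute.
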