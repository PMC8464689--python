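# membraneloc

Where does a small amphipathic drug sit inside a phospholipid bilayer, and
what does it do to the membrane's phase behaviour?  `membraneloc` answers
both questions for the azole antifungal clotrimazole in phosphatidylcholine
model membranes, as a tested, fully synthetic-data-driven pipeline with
three tracks:

1. **DSC** — analyse excess heat-capacity thermograms of
   DMPC/clotrimazole multilamellar vesicles: transition temperature
   `Tm` (peak maximum), calorimetric enthalpy `ΔH` (trapezoid integral),
   onset/completion temperatures by the **5% peak-height rule**, and a
   partial phase diagram whose onset temperatures trace the *solidus* and
   completion temperatures the *fluidus* line.  A composition-independent
   fluidus over a falling solidus flags **fluid immiscibility**
   (drug-rich fluid domains).
2. **NOESY** — convert 2D NOESY MAS-NMR peak volumes into
   cross-relaxation rates, `σ_ij = A_ij / (A_jj · t_m)`, and rank the
   drug's proton groups along an ordered ladder of POPC proton groups
   (headgroup → terminal methyl) to localize the drug's insertion depth;
   ring-current chemical-shift differences give an independent read-out.
3. **Density** — z-axis mass-density profiles of atom selections in
   bilayer coordinate frames (GRO format), comparing peak positions of
   drug atoms against lipid landmark groups (phosphate, carbonyl, C2/C3,
   double bond, terminal methyls).

Each track is fed by a synthetic generator with known ground truth
(van't Hoff heat-capacity peaks, an exponential depth-proximity kernel,
Gaussian z placement of united atoms), so the entire pipeline runs and is
validated without any instrument data.  Intended users: membrane
biophysicists analysing DSC/NOESY data for drug–membrane interactions, and
developers who need a reference implementation of these analyses.

## Worked example

Run the full pipeline on the built-in reference conditions
(DMPC:clotrimazole ratios 0–0.5, POPC ladder, 64 lipids + 13 drugs +
2500 waters per leaflet):

```
membraneloc run --out-dir out --seed 0
cat out/summary.json
```

The DSC section of the summary reads (temperatures in °C, enthalpies in
kcal/mol):

```
"dsc": {
  "0.0":  {"T_onset_C": 22.6,   "main_Tm_C": 23.705, "dH_kcal_mol": 6.6352, "pre_Tm_C": 12.499, ...},
  "0.02": {"T_onset_C": 20.9,   "main_Tm_C": 22.085, "dH_kcal_mol": 6.5292, ...},
  "0.5":  {"T_onset_C": 14.403, "main_Tm_C": 17.785, "dH_kcal_mol": 6.3322, ...}
},
"phase_diagram": {
  "fluid_immiscibility": true,
  "fluidus_slope_C_per_ratio": -0.0133,
  "solidus_slope_C_per_ratio": -14.6416
}
```

Reading: the gel → liquid-crystalline transition of pure DMPC peaks at
23.7 °C with a small gel → ripple pre-transition near 12.5 °C; adding
clotrimazole abolishes the pre-transition and depresses the peak to
17.8 °C at the 2:1 ratio while `ΔH` stays near 6.3–6.6 kcal/mol.  The
onset (solidus) falls from 22.6 to 14.4 °C but the completion (fluidus)
stays flat — the fluid-immiscibility signature.  The NOESY section ranks
every drug proton's largest cross-relaxation rate at the C2/C3 acyl
carbons, with the imidazole protons (C, A) shallowest; the density section
puts the drug's nitrogen peak at the carbonyl level (|z| ≈ 1.45 nm) and
the whole molecule at C3 (|z| ≈ 1.25 nm) with its chlorine within one
bin of that, between the carbonyls and the oleoyl double bond.

Single stages work on plain CSV/TSV/GRO files, e.g.:

```
membraneloc dsc analyze scan.csv --fraction 0.05
membraneloc noesy localize cross.tsv diag.tsv --mixing-time-s 0.3
membraneloc density profile system.gro --selection drug_N --bin-width 0.1
```

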