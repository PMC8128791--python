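# bctopt

Dose and image-quality optimization toolkit for dedicated spiral breast CT
(B-CT). B-CT scans the pendant breast without compression at a fixed 60 kV,
so the only free exposure parameter is the tube current, which must be set
*before* the scan (the scanner takes no scout views). `bctopt` is for medical
physicists and imaging scientists who want to reproduce, extend or re-analyse
the protocol-optimization chain behind current-selection guidance: which of
the scanner's ten currents (6–125 mA) delivers diagnostic image quality at an
average breast dose comparable to mammography, as a function of breast volume
and glandular density.

## What it computes

- **Tissue surrogates and phantoms.** Agar/oil emulsion recipes keyed by
  glandular fraction *g* (agar solution ≈ fibroglandular tissue, plant oil ≈
  fat; ACR density categories map to the band midpoints 12.5/37.5/62.5/87.5%),
  their bulk density/elemental composition, and voxelized pendant-breast
  phantoms matched to the three study volumes (248, 358, 1067 cm³).
- **Monte Carlo dosimetry.** Woodcock (delta) tracking of a filtered 60-kVp
  spectrum along the scanner's helix (31.53-mm collimation, pitch 1.05, 2-s
  rotation, 2000 projections/rotation), with photoelectric absorption and
  Klein–Nishina scattering under the kerma approximation; per-voxel absorbed
  dose in mGy, volume-averaged dose, surface doses, and radial dose profiles.
- **Image quality.** ROI statistics for the HR (0.15-mm) and STD (0.3-mm)
  reconstructions from a parametric noise model, the signal-to-noise ratio

  SNR = (μ_mixture − μ_air) / σ_air,  σ_SNR = √(σ²_mixture + σ²_air) / σ_air,

  and the logarithmic regression SNR = a + b·ln(I) that captures SNR
  saturation above ~64 mA.
- **Dose model and optimizer.** The linear dose law

  dose = F(V, g) · I,  F(V, g) = α·e^(−βV)·(1 + γ·g)  [mGy/mA],

  fitted per phantom/filling from the simulations, plus the constrained
  recommendation: the smallest current ≥ 25 mA with SNR_HR ≥ 35 and
  SNR_STD ≥ 100, flagged when the implied dose exceeds 6.5 mGy (7 mGy
  allowance for the small breast).

## Worked example

```python
from bctopt import (build_phantom, build_protocol, generate_spectrum,
                    make_recipe, material_for_mixture, simulate_dose,
                    select_current, OptimizationConstraints)

recipe = make_recipe(0.375)           # ACR category 2 filling
filling = material_for_mixture(recipe)
phantom = build_phantom("medium", filling=filling, voxel_spacing_mm=2.0)
protocol = build_protocol(tube_current_ma=25.0, scan_length_mm=80.0)
dose = simulate_dose(phantom, protocol, generate_spectrum(),
                     n_histories=200_000, seed=42)
print(recipe.agar_solution_volume_ml, recipe.oil_volume_ml)   # 356 594
print(f"{dose.average_dose_mgy:.2f} +/- {dose.average_dose_se_mgy:.2f} mGy")
```

prints `356 594` (the printed recipe for the 37.5% filling: 356 ml agar
solution, 594 ml oil per litre) and `6.68 +/- 0.04 mGy` — the average
absorbed dose in the 358-cm³ breast at 25 mA, i.e. a dose factor of
0.267 mGy/mA for this filling. Feeding that factor and an SNR table into
`select_current` yields `25 mA (6.68 mGy)*`, the asterisk marking a dose
above the 6.5-mGy base limit.

The same steps are available from the shell:

```
bctopt make-phantom --size medium --glandularity 0.375 --out phantom.nii.gz
bctopt simulate-dose --phantom phantom.nii.gz --current 25 --scan-length 80 \
       --histories 200000 --seed 42 --out dose.nii.gz
bctopt run-study --preset desk --out study_out/
```

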