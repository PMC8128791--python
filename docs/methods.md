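# Methods

This note records the models behind `bctopt`, the calibrations they need,
and what the synthetic pipeline can and cannot say about real scanner data.

## Materials and phantoms

The breast is modelled as a homogeneous agar/oil emulsion. A batch of
volume *B* ml contains 50·*B*/1000 ml of lecithin emulsifier solution
(treated as water), with the remainder split by glandular fraction *g*
between 1.5% agar solution (water + 1.5% carbohydrate, ρ = 1.004 g/cm³)
and plant oil (triolein C₅₇H₁₀₄O₆, ρ = 0.92 g/cm³), each rounded to whole
ml. Bulk density is the volume-fraction mean; elemental fractions are
mass-weighted. ACR density categories 1–4 map to the band midpoints
g = 0.125, 0.375, 0.625, 0.875.

The scanned phantoms are pendant-breast solids of revolution: a
half-ellipsoid of length `aspect × radius` (default aspect 1.4) capped with
a paraboloid tip over the last 15% of its length. The original study used
patient-derived printed shells that are not distributed; only volume and
rough geometry drive the volume-averaged dose, so a parametric shape scaled
to the measured filling volumes (248/358/1067 cm³) stands in for them. The
rasterized radius is bisected until the voxelized volume matches the target
to 0.5%, so the discrete volume honours the target at any spacing; phantoms
wider than the 200-mm field of measurement are rejected. Axis convention
throughout: arrays are (z, y, x), z is the scanner axis, chest wall at
z = 0, nipple at largest z. Default voxel spacing is 2 mm (desk scale);
finer grids are a constructor argument.

## Beam model and cross sections

The tube spectrum is Kramers' thick-target bremsstrahlung,
N(E) ∝ (kVp/E − 1) on a 1-keV grid, filtered through 0.3 mm Be + 1.5 mm Al.
The scanner's actual filter thicknesses are not public; these defaults are
typical for dedicated breast CT, they give a mean energy of 31.9 keV at
60 kVp, and the absolute dose scale is re-anchored downstream, so the
spectrum's job is to set the *shape* of the depth-dose behaviour. Tungsten
K lines (69.5-keV edge) cannot be excited at 60 kVp, so the model is pure
bremsstrahlung; the anode angle (10°) is carried as metadata, with heel
effect out of scope.

Photon interaction coefficients use the mixture rule over elemental
tables. Totals for H, C, N, O, Al are the standard NIST grid values
(10–80 keV, coherent included; log-log interpolated, and extrapolated in
the photoelectric power-law regime below 10 keV for the transport cutoff
region). The photoelectric component comes from Cromer–Liberman f″
(via `gemmi`), incoherent scattering from the free-electron Klein–Nishina
cross section, and the coherent part is the clipped remainder
total − PE − KN. Elements without a packaged total (Be, Ar) use PE + KN.
This reproduces μ_water(60 keV) = 0.2054 cm⁻¹ (reference 0.206, −0.3%).
Mass energy absorption is kerma-based: PE deposits the full photon energy,
incoherent deposits the Klein–Nishina mean transferred fraction.

## Monte Carlo transport

Photons are emitted uniformly along the helix (z extent = scan length plus
half a collimation on both ends; pitch × collimation = 33.11 mm advance per
rotation) toward points drawn uniformly on the collimation window at the
isocenter plane (±100 mm fan, ±15.77 mm in z). Woodcock (delta) tracking
with a per-energy majorant steps photons through the voxel grid; real
interactions are photoelectric (local absorption) or Klein–Nishina
scattering (energy transfer deposited locally, direction rotated by the
sampled angle). Coherent scattering is available behind a flag
(`include_coherent`), sampling a Thomson angular distribution without an
atomic form factor — a deliberately crude model, off by default. Photons
below 5 keV deposit their remainder and stop. Electron transport is
omitted (kerma ≈ dose: sub-mm electron ranges versus 2-mm voxels at
≤ 60 keV). Scatter from outside the grid bounding box is neglected.

Tallies are energy per voxel, restricted to the phantom mask. Per-voxel
statistical uncertainty uses a 10-batch estimate; the volume-average dose
additionally carries a standard error from the per-history deposit
variance, which is the statistically stable quantity used for the 1/√N
convergence check. All randomness flows from one `numpy` PCG64 generator
per run, so equal seeds give bitwise-identical maps.

**Absolute dose.** The photon fluence per mAs of the real tube is not
published. A single calibration constant (photons per mAs) is fixed so the
simulated dose factor of the anchor cell — medium phantom (358 cm³),
g = 0.125, 25 mA, 80-mm scan — equals the published lookup value
0.24 mGy/mA; every other cell is then a prediction. `run_study` performs
this calibration at runtime by default; a packaged constant
(2.548 × 10¹⁰ photons/mAs, from a 4 × 10⁵-history run of the same anchor)
serves standalone `simulate_dose` calls. Doses scale as current ×
acquisition time, with the scanner's acquisition times (7/9.5/12 s for
80/120/160 mm) treated as lookup constants: the printed values are not
exactly reproduced by the helix geometry (which gives ≈ 6.7/9.2/11.6 s
with one-collimation overscan), so the trajectory is geometric and the
mAs bookkeeping follows the scanner's reported times.

Problem sizes: the default desk scale is 2 × 10⁵ histories on 2-mm voxels
(seconds per cell); the study-scale 10⁶ histories is a configuration
change. Statistical uncertainty of the volume-average dose at desk scale
is ≈ 0.3–1%, far below the 16–30% spans of the volume and glandularity
effects being resolved.

## Image-quality model

No image reconstruction is performed. ROI statistics are drawn from the
parametric model: the mixture mean is the spectrum-weighted Hounsfield
value of the filling, air is −1000 HU, and the air noise follows quantum
statistics, σ_air = σ_ref·√(I_ref/I)/√(relative voxel volume). The STD
voxel is taken 8× the HR voxel (doubled in-plane and slice), which matches
the √8 ≈ 100/35 ratio of the two clinical SNR thresholds; a slice-only
ratio of 2 is a configuration change. Mixture-ROI noise is inflated
linearly with signal (coupling 0.3) to mirror the measured noise-vs-signal
behaviour. σ_ref defaults to 19.0 HU at 25 mA in HR: with the g = 0.125
filling's ≈ 700 HU contrast this puts SNR_HR(25 mA) ≈ 36.7 ≈ 35 — at, and
just clearing, both clinical thresholds at the 25-mA operating point, which
is where the published recommendations place that filling. The absolute
SNR scale is therefore a model choice (the study's SNR appendix is not
available), and only relative SNR behaviour (current scaling, mode ratio,
density ordering) is meaningful. ROI sizes follow the study policy
(> 1000/500/200 mm² mixture ROIs for large/medium/small, 150–200 mm² air),
placed deterministically; ring artifacts and artifact avoidance are not
modelled. At 25/32/40 mA the SNR is averaged over three slices with the
error-propagated spread recorded, as in the measurement protocol.

## Dose model and optimizer

Dose factors F = dose/I are slopes of least-squares lines through the
origin (exact here, because dose is linear in mAs by construction). The
surface F(V, g) = α·e^(−βV)·(1 + γ·g) is fitted by Levenberg–Marquardt
from the fixed start (0.3, 5 × 10⁻⁴, 0.4); on noiseless synthetic grids
the parameters are recovered to 10⁻⁶.

The optimizer enumerates the allowed currents at or above the 25-mA floor
and returns the smallest one meeting SNR_HR ≥ 35 and SNR_STD ≥ 100. Dose
limits never change the choice: they set flags. `exceeds_base_limit`
marks doses above 6.5 mGy (the table asterisk); `feasible` is false when
the chosen dose exceeds the applicable limit (6.5 mGy, relaxed to 7 mGy
for the small phantom — whose densest fillings still exceed it, as in the
published table, and are reported flagged rather than dropped). If no
current satisfies the SNR thresholds, the current with the best worst-case
SNR margin is reported with `feasible=False`. The SNR thresholds
themselves are configurable constants: they are stated operating points,
not derived quantities.

## What passing tests do and do not show

The synthetic generator reproduces the study *conditions* — volumes,
fillings, protocol grid, noise scaling — not the study's raw data. Tests
and the acceptance run therefore establish: the printed recipe and
protocol constants round-trip exactly; transport agrees with the
closed-form attenuation oracle and obeys energy conservation, 1/√N error
scaling and seed determinism; the simulated dose factors reproduce the
published qualitative pattern (increasing in glandularity, decreasing in
volume; periphery hotter than centre; large-breast centre and average dose
lower); and the optimizer equals exhaustive search and reproduces the
published flag logic on the published inputs. They do not certify absolute
agreement with the commercial Monte Carlo (unpublished fluence and
filtration) or with the measured SNR tables (unavailable): beyond the
anchored cell, simulated factors deviate from the published lookup by
roughly 5–15%, with a somewhat steeper glandularity slope (the model
spectrum is likely softer than the real tube's), and the recommendation
table consequently selects 25 mA in some cells where the published table
lists 32 mA.

## Known limitations

- Homogeneous fillings only; no lesions, microcalcifications or skin.
- Average dose over the volume, not mean glandular dose (conservative:
  central dose is below surface dose).
- No detector model, no projections, no reconstruction; SNR is parametric.
- Coherent scattering crude and off by default; no Doppler broadening or
  binding corrections to Klein–Nishina; no electron transport.
- Single-material phantom interior; the printed shell wall is ignored.
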