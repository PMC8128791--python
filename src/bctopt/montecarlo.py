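"""Spiral-trajectory Monte Carlo photon transport on voxel breast phantoms.

The engine models the dedicated spiral breast-CT acquisition: a 60-kVp
point source on a helix around the pendant breast, collimated to the
31.53-mm beam and the 200-mm field of measurement, with Woodcock (delta)
tracking through the voxel grid.  Interactions are photoelectric
absorption and incoherent (Klein-Nishina) scattering, with optional
coherent scattering; all energy transferred to electrons is deposited at
the interaction site (kerma approximation — electron ranges at these
energies are well below the voxel size).  Photons are terminated below a
5-keV cutoff, depositing the remainder locally.

Absolute dose uses a single fluence calibration constant (photons per
mAs entering the field), anchored so that the simulated dose factor of
the medium phantom with the least-dense filling matches the published
0.24 mGy/mA lookup value; all other cells are predictions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .materials import VoxelPhantom, MaterialProperties, WATER
from .physics import AttenuationModel, XraySpectrum, generate_spectrum, KEV_TO_JOULE

# ---------------------------------------------------------------------------
# scan protocol
# ---------------------------------------------------------------------------

ALLOWED_CURRENTS_MA = (6.0, 12.5, 25.0, 32.0, 40.0, 50.0, 64.0, 80.0, 100.0, 125.0)
ALLOWED_SCAN_LENGTHS_MM = (80.0, 120.0, 160.0)

#: scanner-reported total acquisition time per scan length (lookup constants;
#: the helix geometry itself is computed from pitch and collimation)
ACQUISITION_TIME_S = {80.0: 7.0, 120.0: 9.5, 160.0: 12.0}

ENERGY_CUTOFF_KEV = 5.0

#: packaged fluence anchor (photons per mAs reaching the field); recompute
#: with :func:`calibrate_photons_per_mas` for other spectra or geometries
DEFAULT_PHOTONS_PER_MAS = 2.5482314309146267e10


@dataclass(frozen=True)
class ScanProtocol:
    tube_current_ma: float
    scan_length_mm: float
    kvp: float = 60.0
    rotation_time_s: float = 2.0
    projections_per_rotation: int = 2000
    collimation_mm: float = 31.53
    pitch: float = 1.05
    source_to_isocenter_mm: float = 570.0
    fan_coverage_diameter_mm: float = 200.0

    @property
    def acquisition_time_s(self) -> float:
        return ACQUISITION_TIME_S[self.scan_length_mm]

    @property
    def mas(self) -> float:
        return self.tube_current_ma * self.acquisition_time_s

    @property
    def z_advance_per_rotation_mm(self) -> float:
        return self.pitch * self.collimation_mm

    @property
    def n_rotations(self) -> float:
        """Continuous rotation count covering the scan length plus a
        half-collimation overscan at both ends."""
        return ((self.scan_length_mm + self.collimation_mm)
                / self.z_advance_per_rotation_mm)


def build_protocol(tube_current_ma: float, scan_length_mm: float,
                   **overrides) -> ScanProtocol:
    """Validated protocol with the fixed study constants."""
    if float(tube_current_ma) not in ALLOWED_CURRENTS_MA:
        raise ValueError(
            f"tube current {tube_current_ma} mA not available; "
            f"allowed: {ALLOWED_CURRENTS_MA}")
    if float(scan_length_mm) not in ALLOWED_SCAN_LENGTHS_MM:
        raise ValueError(
            f"scan length {scan_length_mm} mm not available; "
            f"allowed: {ALLOWED_SCAN_LENGTHS_MM}")
    return ScanProtocol(float(tube_current_ma), float(scan_length_mm), **overrides)


def spiral_trajectory(protocol: ScanProtocol, z_center_mm: float = 0.0) -> dict:
    """Discrete helix: one entry per projection.

    Returns arrays ``angle_rad``, ``source_mm`` (N, 3 as x/y/z),
    ``beam_axis`` (unit vectors toward the rotation axis) and the
    collimated cone bounds at isocenter (``cone_half_z_mm``,
    ``fan_half_width_mm``).  The source starts half a scan-plus-collimation
    extent below ``z_center_mm`` and ends symmetrically above it.
    """
    n_steps = max(int(round(protocol.n_rotations
                            * protocol.projections_per_rotation)), 1)
    t = np.arange(n_steps + 1) / n_steps
    angle = 2.0 * np.pi * protocol.n_rotations * t
    half = 0.5 * (protocol.scan_length_mm + protocol.collimation_mm)
    z = z_center_mm - half + t * 2.0 * half
    r = protocol.source_to_isocenter_mm
    src = np.stack([r * np.cos(angle), r * np.sin(angle), z], axis=1)
    axis = np.stack([-np.cos(angle), -np.sin(angle), np.zeros_like(angle)], axis=1)
    return dict(angle_rad=angle, source_mm=src, beam_axis=axis,
                cone_half_z_mm=protocol.collimation_mm / 2.0,
                fan_half_width_mm=protocol.fan_coverage_diameter_mm / 2.0)


# ---------------------------------------------------------------------------
# dose map container
# ---------------------------------------------------------------------------

@dataclass
class DoseMap:
    """Per-voxel absorbed dose on the phantom grid (mGy)."""

    dose_mgy: np.ndarray
    uncertainty_mgy: np.ndarray
    n_histories: int
    seed: int
    protocol: ScanProtocol
    normalization: str                      # "absolute-mGy" | "per-history"
    photons_per_mas: float
    total_emitted_kev: float
    total_deposited_kev: float              # inside the phantom mask
    average_dose_mgy: float
    average_dose_se_mgy: float

    @property
    def grid_shape(self):
        return self.dose_mgy.shape


# ---------------------------------------------------------------------------
# transport kernel
# ---------------------------------------------------------------------------

def _material_tables(phantom: VoxelPhantom, kvp: float, step_kev: float = 0.25):
    """Stacked linear-attenuation tables per material id on a fine grid."""
    ids = sorted(phantom.material_table)
    assert ids[0] == 0, "material id 0 (air) must be present"
    e = np.arange(ENERGY_CUTOFF_KEV, kvp + step_kev, step_kev)
    n = len(e)
    mu_pe = np.zeros((len(ids), n))
    mu_incoh = np.zeros((len(ids), n))
    mu_coh = np.zeros((len(ids), n))
    for k, mid in enumerate(ids):
        am = AttenuationModel(phantom.material_table[mid],
                              e_min=ENERGY_CUTOFF_KEV, e_max=70.0, step=0.5)
        mu_pe[k] = np.interp(e, am.energies, am.mu_pe)
        mu_incoh[k] = np.interp(e, am.energies, am.mu_incoh)
        mu_coh[k] = np.interp(e, am.energies, am.mu_coh)
    return e, mu_pe, mu_incoh, mu_coh


def _sample_compton(rng: np.random.Generator, energy_kev: np.ndarray):
    """Sample the scattered-to-incident energy ratio eps = E'/E from the
    Klein-Nishina differential cross section by rejection, and the polar
    scattering cosine it implies."""
    a = energy_kev / 510.99895
    eps_min = 1.0 / (1.0 + 2.0 * a)
    eps = np.empty_like(energy_kev)
    todo = np.arange(len(energy_kev))
    fmax = np.maximum(2.0, eps_min + 1.0 / eps_min)
    while todo.size:
        u = rng.random(todo.size)
        e_try = eps_min[todo] + u * (1.0 - eps_min[todo])
        cos_t = 1.0 - (1.0 / e_try - 1.0) / a[todo]
        f = e_try + 1.0 / e_try - (1.0 - cos_t ** 2)
        acc = rng.random(todo.size) * fmax[todo] < f
        eps[todo[acc]] = e_try[acc]
        todo = todo[~acc]
    cos_t = 1.0 - (1.0 / eps - 1.0) / a
    return eps, np.clip(cos_t, -1.0, 1.0)


def _sample_thomson_cosine(rng: np.random.Generator, n: int) -> np.ndarray:
    """cos(theta) from the Thomson distribution (1 + cos^2), used for the
    optional coherent channel (no atomic form factor — crude model)."""
    out = np.empty(n)
    todo = np.arange(n)
    while todo.size:
        c = rng.uniform(-1.0, 1.0, todo.size)
        acc = rng.random(todo.size) * 2.0 < 1.0 + c ** 2
        out[todo[acc]] = c[acc]
        todo = todo[~acc]
    return out


def _rotate(dirs: np.ndarray, cos_t: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Rotate unit vectors by polar angle acos(cos_t) and azimuth phi."""
    d = dirs
    helper = np.zeros_like(d)
    use_z = np.abs(d[:, 2]) < 0.99
    helper[use_z, 2] = 1.0
    helper[~use_z, 0] = 1.0
    e1 = np.cross(d, helper)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(d, e1)
    sin_t = np.sqrt(np.clip(1.0 - cos_t ** 2, 0.0, None))
    out = (cos_t[:, None] * d
           + sin_t[:, None] * (np.cos(phi)[:, None] * e1 + np.sin(phi)[:, None] * e2))
    return out / np.linalg.norm(out, axis=1, keepdims=True)


def _enter_box(pos, dirs, lo, hi):
    """Advance rays to their entry into the axis-aligned box; returns the
    advanced positions and a mask of rays that hit the box."""
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = (lo[None, :] - pos) / dirs
        t2 = (hi[None, :] - pos) / dirs
    tmin = np.nanmax(np.minimum(t1, t2), axis=1)
    tmax = np.nanmin(np.maximum(t1, t2), axis=1)
    hit = (tmax > np.maximum(tmin, 0.0))
    t0 = np.maximum(tmin, 0.0) + 1e-6
    return pos + t0[:, None] * dirs, hit


def _trace(rng, pos, dirs, energy, pid, labels_flat, shape, origin, spacing,
           e_grid, mu_pe, mu_incoh, mu_coh, *, include_coherent, primary_only,
           edep_batches, hist_edep, n_batches, max_steps=100000):
    """Woodcock transport of one photon batch; deposits energy in place."""
    nz, ny, nx = shape
    e_lo, e_step = e_grid[0], e_grid[1] - e_grid[0]
    n_e = len(e_grid)
    mu_used = mu_pe + mu_incoh + (mu_coh if include_coherent else 0.0)
    mu_maj = mu_used.max(axis=0)
    lo = origin
    hi = origin + spacing * np.array([nx, ny, nz], dtype=float)

    pos, hit = _enter_box(pos, dirs, lo, hi)
    pos, dirs, energy, pid = pos[hit], dirs[hit], energy[hit], pid[hit]

    def deposit(pids, flats, labs, amounts):
        inmask = labs > 0
        if np.any(inmask):
            np.add.at(edep_batches,
                      (pids[inmask] % n_batches, flats[inmask]), amounts[inmask])
            np.add.at(hist_edep, pids[inmask], amounts[inmask])

    for _ in range(max_steps):
        if energy.size == 0:
            return
        eidx = np.clip(((energy - e_lo) / e_step).astype(np.int64), 0, n_e - 1)
        # mu tables are per cm; positions are in mm
        step = rng.exponential(1.0, energy.size) / mu_maj[eidx] * 10.0
        pos = pos + step[:, None] * dirs

        iv = np.floor((pos - lo[None, :]) / spacing).astype(np.int64)
        inside = ((iv[:, 0] >= 0) & (iv[:, 0] < nx)
                  & (iv[:, 1] >= 0) & (iv[:, 1] < ny)
                  & (iv[:, 2] >= 0) & (iv[:, 2] < nz))
        pos, dirs, energy, pid, iv, eidx = (
            pos[inside], dirs[inside], energy[inside], pid[inside],
            iv[inside], eidx[inside])
        if energy.size == 0:
            return

        flat = (iv[:, 2] * ny + iv[:, 1]) * nx + iv[:, 0]
        lab = labels_flat[flat]
        mu_here = mu_used[lab, eidx]
        real = rng.random(energy.size) * mu_maj[eidx] < mu_here
        if np.any(real):
            r_pid, r_flat, r_lab, r_e = pid[real], flat[real], lab[real], energy[real]
            r_eidx = eidx[real]
            u = rng.random(r_e.size) * mu_here[real]
            is_pe = u < mu_pe[r_lab, r_eidx]
            if primary_only:
                is_pe = np.ones_like(is_pe)
            is_coh = (~is_pe) & (u >= mu_pe[r_lab, r_eidx] + mu_incoh[r_lab, r_eidx])
            is_sc = ~is_pe & ~is_coh

            deposit(r_pid[is_pe], r_flat[is_pe], r_lab[is_pe], r_e[is_pe])

            survive = np.ones(energy.size, dtype=bool)
            real_idx = np.flatnonzero(real)
            survive[real_idx[is_pe]] = False

            if np.any(is_sc):
                sc = real_idx[is_sc]
                eps, cos_t = _sample_compton(rng, energy[sc])
                transfer = energy[sc] * (1.0 - eps)
                deposit(pid[sc], flat[sc], lab[sc], transfer)
                energy[sc] *= eps
                phi = rng.uniform(0.0, 2.0 * np.pi, sc.size)
                dirs[sc] = _rotate(dirs[sc], cos_t, phi)
                low = energy[sc] < ENERGY_CUTOFF_KEV
                if np.any(low):
                    deposit(pid[sc][low], flat[sc][low], lab[sc][low],
                            energy[sc][low])
                    survive[sc[low]] = False
            if np.any(is_coh):
                ch = real_idx[is_coh]
                cos_t = _sample_thomson_cosine(rng, ch.size)
                phi = rng.uniform(0.0, 2.0 * np.pi, ch.size)
                dirs[ch] = _rotate(dirs[ch], cos_t, phi)

            pos, dirs, energy, pid = (pos[survive], dirs[survive],
                                      energy[survive], pid[survive])
    raise RuntimeError("transport did not terminate within max_steps")


# ---------------------------------------------------------------------------
# source sampling and the public simulation entry point
# ---------------------------------------------------------------------------

def _sample_spectrum(rng, spectrum: XraySpectrum, n: int) -> np.ndarray:
    keep = (spectrum.energies_kev >= ENERGY_CUTOFF_KEV) & (spectrum.relative_fluence > 0)
    e = spectrum.energies_kev[keep]
    w = spectrum.relative_fluence[keep]
    cdf = np.cumsum(w) / w.sum()
    pick = np.searchsorted(cdf, rng.random(n))
    # uniform within the 1-keV bin centred on the grid value
    return e[pick] - 0.5 + rng.random(n)


def _sample_source(rng, protocol: ScanProtocol, z_center: float, n: int):
    """Emission points uniformly along the helix; directions toward a point
    drawn uniformly on the collimation window at the isocenter plane."""
    t = rng.random(n)
    angle = 2.0 * np.pi * protocol.n_rotations * t
    half = 0.5 * (protocol.scan_length_mm + protocol.collimation_mm)
    z_s = z_center - half + 2.0 * half * t
    r = protocol.source_to_isocenter_mm
    src = np.stack([r * np.cos(angle), r * np.sin(angle), z_s], axis=1)
    lat = np.stack([-np.sin(angle), np.cos(angle), np.zeros_like(angle)], axis=1)
    u = rng.uniform(-0.5, 0.5, n) * protocol.fan_coverage_diameter_mm
    v = rng.uniform(-0.5, 0.5, n) * protocol.collimation_mm
    target = u[:, None] * lat
    target[:, 2] += z_s + v
    d = target - src
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    return src, d


def simulate_dose(phantom: VoxelPhantom, protocol: ScanProtocol,
                  spectrum: XraySpectrum | None = None,
                  n_histories: int = 200_000, seed: int = 0, *,
                  photons_per_mas: float | None = DEFAULT_PHOTONS_PER_MAS,
                  include_coherent: bool = False,
                  n_batches: int = 10,
                  chunk: int = 200_000) -> DoseMap:
    """Monte Carlo absorbed-dose map for one scan.

    ``photons_per_mas`` converts the per-history tally to absolute mGy via
    the protocol's mAs (current x acquisition time); pass ``None`` for a
    per-history normalization.  Bitwise reproducible for a fixed seed.
    """
    if spectrum is None:
        spectrum = generate_spectrum(kvp=protocol.kvp)
    shape = phantom.grid_shape
    nvox = int(np.prod(shape))
    labels_flat = np.ascontiguousarray(phantom.label_grid).reshape(-1)
    e_grid, mu_pe, mu_incoh, mu_coh = _material_tables(phantom, protocol.kvp)

    edep_batches = np.zeros((n_batches, nvox))
    hist_edep = np.zeros(max(n_histories, 1))
    total_emitted = 0.0
    z_center = shape[0] * phantom.voxel_spacing_mm / 2.0

    rng = np.random.default_rng(seed)
    if n_histories == 0:
        warnings.warn("simulate_dose called with zero histories; "
                      "returning an all-zero dose map")
    done = 0
    while done < n_histories:
        n = min(chunk, n_histories - done)
        energy = _sample_spectrum(rng, spectrum, n)
        total_emitted += float(energy.sum())
        src, dirs = _sample_source(rng, protocol, z_center, n)
        pid = np.arange(done, done + n)
        _trace(rng, src, dirs, energy, pid, labels_flat, shape,
               phantom.origin_mm, phantom.voxel_spacing_mm,
               e_grid, mu_pe, mu_incoh, mu_coh,
               include_coherent=include_coherent, primary_only=False,
               edep_batches=edep_batches, hist_edep=hist_edep,
               n_batches=n_batches)
        done += n

    edep = edep_batches.sum(axis=0).reshape(shape)
    if photons_per_mas is None:
        scale = 1.0 / max(n_histories, 1)
        norm = "per-history"
        photons_per_mas = float("nan")
    else:
        scale = photons_per_mas * protocol.mas / max(n_histories, 1)
        norm = "absolute-mGy"

    mass_kg = phantom.density_grid() * phantom.voxel_volume_cm3 * 1e-3
    dose = np.zeros(shape)
    mask = phantom.mask
    dose[mask] = edep[mask] * KEV_TO_JOULE / mass_kg[mask] * 1e3 * scale

    # batch estimate of the per-voxel statistical uncertainty
    unc = np.zeros(shape)
    if n_histories > 0:
        bd = edep_batches.reshape(n_batches, *shape) * n_batches
        se = bd.std(axis=0, ddof=1) / np.sqrt(n_batches)
        unc[mask] = se[mask] * KEV_TO_JOULE / mass_kg[mask] * 1e3 * scale

    mask_mass = mass_kg[mask].sum()
    avg = float(edep[mask].sum() * KEV_TO_JOULE / mask_mass * 1e3 * scale)
    if n_histories > 1:
        se_hist = hist_edep.std(ddof=1) * np.sqrt(n_histories)
        avg_se = float(se_hist * KEV_TO_JOULE / mask_mass * 1e3 * scale)
    else:
        avg_se = float("nan")

    return DoseMap(dose, unc, n_histories, seed, protocol, norm,
                   photons_per_mas, total_emitted, float(edep[mask].sum()),
                   avg, avg_se)


def calibrate_photons_per_mas(spectrum: XraySpectrum | None = None,
                              target_factor_mgy_per_ma: float = 0.24,
                              n_histories: int = 200_000, seed: int = 20,
                              voxel_spacing_mm: float = 2.0) -> float:
    """Fluence anchor: photons/mAs chosen so the simulated dose factor for
    the medium phantom (358 cm^3) with the 12.5%-glandularity filling at
    25 mA equals the published lookup value (0.24 mGy/mA by default)."""
    from .materials import build_phantom, material_for_mixture, make_recipe

    phantom = build_phantom("medium",
                            filling=material_for_mixture(make_recipe(0.125)),
                            voxel_spacing_mm=voxel_spacing_mm)
    protocol = build_protocol(25.0, 80.0)
    dm = simulate_dose(phantom, protocol, spectrum, n_histories, seed,
                       photons_per_mas=1.0)
    return target_factor_mgy_per_ma * protocol.tube_current_ma / (
        dm.average_dose_mgy)


# ---------------------------------------------------------------------------
# dose-map analysis
# ---------------------------------------------------------------------------

def average_dose(dose_map: DoseMap, phantom: VoxelPhantom) -> float:
    """Mass-weighted mean dose over the phantom volume (mGy)."""
    mask = phantom.mask
    if not np.any(mask):
        raise ValueError("phantom mask is empty")
    w = phantom.density_grid()[mask]
    return float((dose_map.dose_mgy[mask] * w).sum() / w.sum())


@dataclass
class SurfaceDoseSample:
    position_mm: tuple
    simulated_mgy: float
    measured_mgy: float | None = None

    @property
    def percent_difference(self) -> float | None:
        if self.measured_mgy is None:
            return None
        return percent_difference(self.measured_mgy, self.simulated_mgy)


def percent_difference(measured_mgy: float, simulated_mgy: float) -> float:
    """(simulated - measured) / measured x 100."""
    if measured_mgy <= 0:
        raise ValueError("measured dose must be positive")
    return (simulated_mgy - measured_mgy) / measured_mgy * 100.0


def _boundary_mask(mask: np.ndarray) -> np.ndarray:
    from scipy import ndimage

    return mask & ~ndimage.binary_erosion(mask)


def surface_dose(dose_map: DoseMap, phantom: VoxelPhantom,
                 positions_mm: Sequence[Sequence[float]],
                 measured_mgy: Sequence[float] | None = None,
                 patch_halfwidth: int = 1) -> list[SurfaceDoseSample]:
    """Mean dose over a small surface patch (default 3x3x3 boundary
    neighbourhood) at each requested surface position (x, y, z in mm)."""
    boundary = _boundary_mask(phantom.mask)
    bidx = np.argwhere(boundary)  # (z, y, x)
    bpos = (bidx[:, ::-1] + 0.5) * phantom.voxel_spacing_mm + phantom.origin_mm
    out = []
    for i, p in enumerate(np.atleast_2d(np.asarray(positions_mm, dtype=float))):
        d2 = ((bpos - p) ** 2).sum(axis=1)
        j = int(np.argmin(d2))
        if np.sqrt(d2[j]) > 2.0 * phantom.voxel_spacing_mm:
            raise ValueError(f"position {tuple(p)} is not near the phantom surface")
        zc, yc, xc = bidx[j]
        h = patch_halfwidth
        sl = (slice(max(zc - h, 0), zc + h + 1),
              slice(max(yc - h, 0), yc + h + 1),
              slice(max(xc - h, 0), xc + h + 1))
        patch_mask = phantom.mask[sl]
        sim = float(dose_map.dose_mgy[sl][patch_mask].mean())
        meas = None if measured_mgy is None else float(measured_mgy[i])
        out.append(SurfaceDoseSample(tuple(p), sim, meas))
    return out


def radial_dose_profile(dose_map: DoseMap, phantom: VoxelPhantom,
                        z_index: int | None = None,
                        n_bins: int = 12):
    """Azimuthally averaged dose versus radius from the slice centroid.

    Returns ``(radius_mm, dose_mgy)`` arrays over the phantom voxels of the
    chosen transaxial slice.  The default is the mask's z-centroid slice:
    there the lateral rim is true surface, whereas the chest-wall face
    slice sees the beam head-on and has no periphery/centre contrast.
    """
    mask = phantom.mask
    if z_index is None:
        zs = np.nonzero(mask.any(axis=(1, 2)))[0]
        weights = mask.sum(axis=(1, 2))[zs]
        z_index = int(round((zs * weights).sum() / weights.sum()))
    sl_mask = mask[z_index]
    if not np.any(sl_mask):
        raise ValueError(f"slice {z_index} does not intersect the phantom")
    yy, xx = np.nonzero(sl_mask)
    cy, cx = yy.mean(), xx.mean()
    r = np.hypot(yy - cy, xx - cx) * phantom.voxel_spacing_mm
    d = dose_map.dose_mgy[z_index][sl_mask]
    edges = np.linspace(0.0, r.max() + 1e-9, n_bins + 1)
    which = np.digitize(r, edges) - 1
    radius = 0.5 * (edges[:-1] + edges[1:])
    prof = np.array([d[which == b].mean() if np.any(which == b) else np.nan
                     for b in range(n_bins)])
    return radius, prof


# ---------------------------------------------------------------------------
# analytic oracle helper
# ---------------------------------------------------------------------------

def slab_transmission(material: MaterialProperties, thickness_cm: float,
                      energy_kev: float, n_histories: int = 50_000,
                      seed: int = 0, include_coherent: bool = False):
    """Fraction of a monoenergetic pencil beam traversing a homogeneous
    slab without any real interaction, using the same Woodcock kernel as
    :func:`simulate_dose` in primary-only mode.

    Returns ``(fraction, standard_error)``; for an attenuation coefficient
    mu (photoelectric + incoherent by default) the expectation is
    ``exp(-mu * thickness)``.
    """
    spacing = 2.0
    nz = max(int(np.ceil(thickness_cm * 10.0 / spacing)), 1)
    spacing = thickness_cm * 10.0 / nz
    grid = np.ones((nz, 3, 3), dtype=np.int8)
    phantom = VoxelPhantom(grid, spacing, {0: material, 1: material})
    # label 0 never occurs inside; keep the air slot for the table contract
    from .materials import AIR
    phantom.material_table[0] = AIR

    e_grid, mu_pe, mu_incoh, mu_coh = _material_tables(phantom, 70.0 - 1e-9)
    labels_flat = grid.reshape(-1)
    edep = np.zeros((1, labels_flat.size))
    hist = np.zeros(n_histories)
    rng = np.random.default_rng(seed)
    pos = np.tile(phantom.origin_mm + np.array(
        [1.5 * spacing, 1.5 * spacing, -1.0]), (n_histories, 1))
    dirs = np.tile([0.0, 0.0, 1.0], (n_histories, 1))
    energy = np.full(n_histories, float(energy_kev))
    _trace(rng, pos, dirs, energy, np.arange(n_histories), labels_flat,
           grid.shape, phantom.origin_mm, spacing, e_grid, mu_pe, mu_incoh,
           mu_coh, include_coherent=include_coherent, primary_only=True,
           edep_batches=edep, hist_edep=hist, n_batches=1)
    transmitted = float((hist == 0.0).sum()) / n_histories
    se = np.sqrt(max(transmitted * (1.0 - transmitted), 1e-12) / n_histories)
    return transmitted, se
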