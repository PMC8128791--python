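"""X-ray beam physics for the 60-kVp spiral breast-CT energy range.

Provides a filtered tungsten-tube bremsstrahlung spectrum and
energy-dependent photon interaction coefficients (photoelectric,
incoherent, coherent, total and energy absorption) for arbitrary
elemental mixtures on a 1-keV grid.

Data sources
------------
Total mass attenuation coefficients for H, C, N, O and Al are packaged
from the standard NIST (Hubbell & Seltzer) tabulation, 10-80 keV, with
coherent scattering included.  Photoelectric cross sections come from
the Cromer-Liberman anomalous-scattering f'' values provided by
``gemmi``; incoherent scattering uses the analytic free-electron
Klein-Nishina cross section.  The coherent component is obtained as the
(clipped) remainder ``total - photoelectric - incoherent``; for elements
without a packaged total (Be, Ar) the total is reconstructed as
``photoelectric + Klein-Nishina`` and the coherent part is zero.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np

try:
    import gemmi
except ImportError as _e:  # pragma: no cover
    gemmi = None

# ---------------------------------------------------------------------------
# constants
# ---------------------------------------------------------------------------

ELECTRON_REST_KEV = 510.99895
CLASSICAL_ELECTRON_RADIUS_CM = 2.8179403262e-13
AVOGADRO = 6.02214076e23
HC_KEV_ANGSTROM = 12.398419843320026
KEV_TO_JOULE = 1.602176634e-16

#: public validity range of the attenuation model (keV)
ENERGY_MIN_KEV = 10.0
ENERGY_MAX_KEV = 70.0

#: internal tabulation grid (extends below 10 keV by log-log extrapolation
#: so that the Monte Carlo engine can follow photons down to its 5-keV cutoff)
_TAB_GRID_KEV = np.array([10.0, 15.0, 20.0, 30.0, 40.0, 50.0, 60.0, 80.0])

# NIST mass attenuation coefficients mu/rho (cm^2/g), coherent included,
# on _TAB_GRID_KEV.  Z and standard atomic weight per element.
_ELEMENTS: dict[str, dict] = {
    "H": dict(Z=1, A=1.008,
              mu=[0.3854, 0.3764, 0.3695, 0.3570, 0.3458, 0.3355, 0.3260, 0.3091]),
    "C": dict(Z=6, A=12.011,
              mu=[2.373, 0.8071, 0.4420, 0.2562, 0.2076, 0.1871, 0.1753, 0.1610]),
    "N": dict(Z=7, A=14.007,
              mu=[3.879, 1.236, 0.6178, 0.3066, 0.2288, 0.1980, 0.1817, 0.1639]),
    "O": dict(Z=8, A=15.999,
              mu=[5.952, 1.836, 0.8651, 0.3779, 0.2585, 0.2132, 0.1907, 0.1678]),
    "Al": dict(Z=13, A=26.982,
               mu=[26.23, 7.955, 3.441, 1.128, 0.5685, 0.3681, 0.2778, 0.2018]),
    # no packaged NIST total: reconstructed from Cromer-Liberman + Klein-Nishina
    "Be": dict(Z=4, A=9.0122, mu=None),
    "Ar": dict(Z=18, A=39.948, mu=None),
}

#: filter material densities (g/cm^3)
FILTER_DENSITY = {"Al": 2.699, "Be": 1.848}


# ---------------------------------------------------------------------------
# elemental cross sections
# ---------------------------------------------------------------------------

def klein_nishina_total_cm2(energy_kev: np.ndarray | float) -> np.ndarray | float:
    """Total Klein-Nishina cross section per electron (cm^2)."""
    a = np.asarray(energy_kev, dtype=float) / ELECTRON_REST_KEV
    r2 = CLASSICAL_ELECTRON_RADIUS_CM ** 2
    ln_t = np.log1p(2.0 * a)
    sig = 2.0 * np.pi * r2 * (
        (1.0 + a) / a ** 2 * (2.0 * (1.0 + a) / (1.0 + 2.0 * a) - ln_t / a)
        + ln_t / (2.0 * a)
        - (1.0 + 3.0 * a) / (1.0 + 2.0 * a) ** 2
    )
    return sig


def klein_nishina_transfer_fraction(energy_kev: np.ndarray | float) -> np.ndarray:
    """Mean fraction of photon energy transferred to the electron per
    incoherent scatter, from numeric integration of the Klein-Nishina
    differential cross section."""
    e = np.atleast_1d(np.asarray(energy_kev, dtype=float))
    a = e / ELECTRON_REST_KEV
    mu = np.linspace(-1.0, 1.0, 2001)  # cos(theta)
    out = np.empty_like(e)
    for i, ai in enumerate(a):
        eps = 1.0 / (1.0 + ai * (1.0 - mu))          # E'/E
        dsig = eps ** 2 * (eps + 1.0 / eps - (1.0 - mu ** 2))
        out[i] = np.trapezoid(dsig * (1.0 - eps), mu) / np.trapezoid(dsig, mu)
    return out if np.ndim(energy_kev) else float(out[0])


@lru_cache(maxsize=None)
def _element_tables(symbol: str) -> dict:
    """Per-element mu/rho component tables (cm^2/g) on _TAB_GRID_KEV."""
    if symbol not in _ELEMENTS:
        raise ValueError(f"element {symbol!r} not in the packaged table "
                         f"(available: {sorted(_ELEMENTS)})")
    info = _ELEMENTS[symbol]
    Z, A = info["Z"], info["A"]
    e = _TAB_GRID_KEV
    # photoelectric from Cromer-Liberman f'' : sigma = 2 r_e lambda f''
    lam_cm = HC_KEV_ANGSTROM / e * 1e-8
    if gemmi is None:  # pragma: no cover
        raise RuntimeError("gemmi is required for photoelectric cross sections")
    fpp = np.array([gemmi.cromer_liberman(z=Z, energy=ek * 1000.0)[1] for ek in e])
    pe = 2.0 * CLASSICAL_ELECTRON_RADIUS_CM * lam_cm * fpp * AVOGADRO / A
    incoh = Z * klein_nishina_total_cm2(e) * AVOGADRO / A
    if info["mu"] is not None:
        total = np.asarray(info["mu"], dtype=float)
        coh = np.clip(total - pe - incoh, 0.0, None)
    else:
        coh = np.zeros_like(e)
        total = pe + incoh
    return dict(total=total, pe=pe, incoh=incoh, coh=coh)


def _loglog_interp(energy_kev: np.ndarray, table: np.ndarray) -> np.ndarray:
    """Log-log interpolation on _TAB_GRID_KEV with extrapolation below
    10 keV (photoelectric power-law regime); zeros handled by flooring."""
    e = np.atleast_1d(np.asarray(energy_kev, dtype=float))
    y = np.clip(table, 1e-12, None)
    lo = np.log(_TAB_GRID_KEV)
    ly = np.log(y)
    le = np.log(np.clip(e, 1e-6, None))
    # linear extrapolation in log-log below the grid
    slope0 = (ly[1] - ly[0]) / (lo[1] - lo[0])
    out = np.interp(le, lo, ly)
    below = le < lo[0]
    out[below] = ly[0] + slope0 * (le[below] - lo[0])
    return np.exp(out)


# ---------------------------------------------------------------------------
# material-level coefficients
# ---------------------------------------------------------------------------

def _fractions(material) -> dict[str, float]:
    fr = dict(material.elemental_mass_fractions)
    s = sum(fr.values())
    if s > 0 and abs(s - 1.0) > 1e-6:
        raise ValueError(f"elemental mass fractions of {material.name!r} "
                         f"sum to {s:.6f}, expected 1")
    return fr


def mass_attenuation(material, energy_kev, component: str = "total") -> np.ndarray:
    """Mixture-rule mass coefficient (cm^2/g): sum_i w_i (mu/rho)_i(E).

    ``component`` is one of ``total``, ``pe``, ``incoh``, ``coh``.
    """
    e = np.atleast_1d(np.asarray(energy_kev, dtype=float))
    out = np.zeros_like(e)
    for sym, w in _fractions(material).items():
        out += w * _loglog_interp(e, _element_tables(sym)[component])
    return out if np.ndim(energy_kev) else float(out[0])


def mass_energy_absorption(material, energy_kev) -> np.ndarray:
    """Kerma-based mass energy-absorption coefficient (cm^2/g):
    photoelectric deposits the full photon energy, incoherent scattering
    the Klein-Nishina mean transferred fraction, coherent nothing."""
    e = np.atleast_1d(np.asarray(energy_kev, dtype=float))
    pe = mass_attenuation(material, e, "pe")
    incoh = mass_attenuation(material, e, "incoh")
    out = pe + incoh * klein_nishina_transfer_fraction(e)
    return out if np.ndim(energy_kev) else float(out[0])


def linear_attenuation(material, energy_kev) -> np.ndarray | float:
    """Total linear attenuation coefficient mu (1/cm), coherent included.

    Valid for 10-70 keV; energies outside raise ``ValueError``.
    """
    e = np.asarray(energy_kev, dtype=float)
    if np.any(e < ENERGY_MIN_KEV) or np.any(e > ENERGY_MAX_KEV):
        raise ValueError(
            f"energy out of tabulated range [{ENERGY_MIN_KEV}, {ENERGY_MAX_KEV}] keV")
    return material.mass_density * mass_attenuation(material, energy_kev, "total")


class AttenuationModel:
    """Precomputed interaction coefficients for one material on a 1-keV grid.

    Attributes are arrays aligned with ``energies`` (keV): ``mu_total``,
    ``mu_pe``, ``mu_incoh``, ``mu_coh`` (linear, 1/cm) and ``mu_en_rho``
    (mass energy absorption, cm^2/g).
    """

    def __init__(self, material, e_min: float = 5.0, e_max: float = ENERGY_MAX_KEV,
                 step: float = 1.0):
        self.material = material
        self.energies = np.arange(e_min, e_max + 0.5 * step, step)
        rho = material.mass_density
        self.mu_pe = rho * mass_attenuation(material, self.energies, "pe")
        self.mu_incoh = rho * mass_attenuation(material, self.energies, "incoh")
        self.mu_coh = rho * mass_attenuation(material, self.energies, "coh")
        self.mu_total = rho * mass_attenuation(material, self.energies, "total")
        self.mu_en_rho = mass_energy_absorption(material, self.energies)

    def mu(self, energy_kev, include_coherent: bool = True):
        tab = self.mu_total if include_coherent else self.mu_pe + self.mu_incoh
        return np.interp(energy_kev, self.energies, tab)


# ---------------------------------------------------------------------------
# tube spectrum
# ---------------------------------------------------------------------------

@dataclass
class XraySpectrum:
    """Filtered tube spectrum on a 1-keV grid from 1 keV to the kVp.

    ``relative_fluence`` are photon-number weights per bin (not energy
    fluence); they are kept unnormalized and normalized on demand.
    """

    energies_kev: np.ndarray
    relative_fluence: np.ndarray
    kvp: float
    anode_angle_deg: float = 10.0
    filtration: tuple = (("Be", 0.3), ("Al", 1.5))

    def normalized(self) -> "XraySpectrum":
        s = self.relative_fluence.sum()
        if s <= 0:
            raise ValueError("spectrum has no fluence")
        return XraySpectrum(self.energies_kev, self.relative_fluence / s,
                            self.kvp, self.anode_angle_deg, self.filtration)

    @property
    def mean_energy_kev(self) -> float:
        w = self.relative_fluence
        return float((self.energies_kev * w).sum() / w.sum())

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            wr = csv.writer(fh)
            wr.writerow(["energy_kev", "relative_fluence"])
            for e, f in zip(self.energies_kev, self.relative_fluence):
                wr.writerow([f"{e:g}", f"{f:.8e}"])

    @classmethod
    def from_csv(cls, path, kvp: float | None = None) -> "XraySpectrum":
        data = np.loadtxt(path, delimiter=",", skiprows=1)
        e, f = data[:, 0], data[:, 1]
        return cls(e, f, kvp=float(kvp if kvp is not None else e[f > 0].max()))


def _filter_transmission(energies: np.ndarray, filtration) -> np.ndarray:
    t = np.ones_like(energies)
    for sym, thick_mm in filtration:
        tab = _element_tables(sym)["total"]
        mu = FILTER_DENSITY[sym] * _loglog_interp(energies, tab)  # 1/cm
        t *= np.exp(-mu * thick_mm * 0.1)
    return t


def generate_spectrum(kvp: float = 60.0, anode_angle_deg: float = 10.0,
                      filtration=(("Be", 0.3), ("Al", 1.5))) -> XraySpectrum:
    """Semi-empirical filtered bremsstrahlung spectrum.

    Kramers' thick-target law ``N(E) dE ∝ (kVp/E - 1)`` attenuated by the
    inherent beryllium and added aluminum filtration.  At 60 kVp the
    tungsten K lines (69.5-keV edge) cannot be excited, so no
    characteristic lines are added; the model is pure bremsstrahlung
    (documented behaviour).  Deterministic for fixed inputs.

    The anode angle is carried as metadata; heel-effect azimuthal
    variation is out of scope for this model.
    """
    if not (40.0 <= kvp <= 70.0):
        raise ValueError(f"kvp {kvp} outside supported range [40, 70] kV")
    energies = np.arange(1.0, np.floor(kvp) + 1.0)
    fluence = np.clip(kvp / energies - 1.0, 0.0, None)
    fluence *= _filter_transmission(energies, filtration)
    # below the 5-keV transport cutoff the filtered fluence is numerically
    # negligible; zero it explicitly so samplers never draw there
    fluence[energies < 5.0] = 0.0
    return XraySpectrum(energies, fluence, float(kvp), anode_angle_deg,
                        tuple((s, float(t)) for s, t in filtration))


def hounsfield_value(material, spectrum: XraySpectrum, water=None) -> float:
    """Effective Hounsfield value: fluence-weighted linear attenuation
    relative to water, HU = 1000 (mu_eff - mu_water) / mu_water."""
    if water is None:
        from .materials import WATER
        water = WATER
    sp = spectrum.normalized()
    keep = (sp.energies_kev >= ENERGY_MIN_KEV) & (sp.relative_fluence > 0)
    e, w = sp.energies_kev[keep], sp.relative_fluence[keep]
    mu_m = float((linear_attenuation(material, e) * w).sum() / w.sum())
    mu_w = float((linear_attenuation(water, e) * w).sum() / w.sum())
    return 1000.0 * (mu_m - mu_w) / mu_w
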