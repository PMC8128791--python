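"""Breast-equivalent mixture recipes, material physics and voxel phantoms.

The study conditions are agar/oil emulsions standing in for fibroglandular
(agar solution) and fatty (plant oil) breast tissue, poured into pendant
breast shells of three sizes (248, 358 and 1067 cm^3).  This module turns a
glandular fraction into a mixture recipe, a recipe into bulk material
properties (density, elemental composition, attenuation), and a target
volume into a labelled voxel phantom ready for Monte Carlo transport.

Coordinate convention (used package-wide): 0-based indices, array axis
order (z, y, x) with z the scanner longitudinal axis; the breast hangs
pendant with the chest wall at z = 0 and the nipple at the largest z.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import physics

# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MixtureRecipe:
    """Volumes (ml) of the three emulsion components for one batch."""

    glandularity: float
    agar_solution_volume_ml: float
    oil_volume_ml: float
    lecithin_solution_volume_ml: float
    batch_volume_ml: float = 1000.0

    def __post_init__(self):
        total = (self.agar_solution_volume_ml + self.oil_volume_ml
                 + self.lecithin_solution_volume_ml)
        if abs(total - self.batch_volume_ml) > 1.0:
            raise ValueError(
                f"component volumes sum to {total} ml, batch is "
                f"{self.batch_volume_ml} ml (>1 ml rounding slack)")


@dataclass(frozen=True)
class MaterialProperties:
    """Bulk material: density and elemental mass fractions.

    Attenuation and energy-absorption coefficients are derived on demand
    through :mod:`bctopt.physics` (mixture rule over packaged elemental
    tables)."""

    name: str
    mass_density: float  # g/cm^3
    elemental_mass_fractions: dict

    def __post_init__(self):
        s = sum(self.elemental_mass_fractions.values())
        if abs(s - 1.0) > 1e-6:
            raise ValueError(f"mass fractions of {self.name!r} sum to {s}")

    def linear_attenuation(self, energy_kev):
        """Total linear attenuation mu(E) in 1/cm."""
        return physics.linear_attenuation(self, energy_kev)

    def mass_energy_absorption(self, energy_kev):
        """Mass energy-absorption coefficient mu_en/rho(E) in cm^2/g."""
        return physics.mass_energy_absorption(self, energy_kev)


# Component definitions.  Compositions are standard: water (H/O), a 1.5%
# carbohydrate (C6H10O5) solution for the agar gel, triolein (C57H104O6)
# for plant oil; the lecithin emulsifier solution is treated as water.
WATER = MaterialProperties("water", 0.998, {"H": 0.1119, "O": 0.8881})

_CARB = {"C": 0.4444, "H": 0.0622, "O": 0.4934}  # (C6H10O5)_n
AGAR_SOLUTION = MaterialProperties(
    "agar_solution_1.5pct", 1.004,
    {
        "H": round(0.985 * 0.1119 + 0.015 * _CARB["H"], 6),
        "C": round(0.015 * _CARB["C"], 6),
        "O": round(1.0 - (0.985 * 0.1119 + 0.015 * _CARB["H"])
                   - 0.015 * _CARB["C"], 6),
    },
)
PLANT_OIL = MaterialProperties(
    "plant_oil", 0.920, {"C": 0.7732, "H": 0.1184, "O": 0.1084})
LECITHIN_SOLUTION = MaterialProperties(
    "lecithin_solution", 1.000, {"H": 0.1119, "O": 0.8881})
AIR = MaterialProperties(
    "air", 1.205e-3, {"N": 0.755, "O": 0.232, "Ar": 0.013})


# ---------------------------------------------------------------------------
# recipes
# ---------------------------------------------------------------------------

#: ACR 4th-edition density bands; the study fillings sit at each band midpoint
ACR_GLANDULARITY = {1: 0.125, 2: 0.375, 3: 0.625, 4: 0.875}

LECITHIN_ML_PER_LITER = 50.0


def acr_to_glandularity(category: int) -> float:
    """Glandular fraction for an ACR density category (band midpoint)."""
    try:
        c = float(category)
    except (TypeError, ValueError):
        raise ValueError(f"ACR category must be 1-4, got {category!r}") from None
    if not c.is_integer() or int(c) not in ACR_GLANDULARITY:
        raise ValueError(f"ACR category must be 1-4, got {category!r}")
    return ACR_GLANDULARITY[int(c)]


def make_recipe(glandularity: float, batch_volume_ml: float = 1000.0) -> MixtureRecipe:
    """Emulsion recipe for a given glandular (agar) fraction.

    The emulsifier is fixed at 50 ml lecithin solution per litre of batch;
    the remainder is split between agar solution (glandular surrogate) and
    plant oil (fat surrogate) by the glandular fraction, rounded to whole ml.
    """
    if not 0.0 <= glandularity <= 1.0:
        raise ValueError(f"glandularity must be in [0, 1], got {glandularity}")
    if batch_volume_ml <= 0:
        raise ValueError(f"batch volume must be positive, got {batch_volume_ml}")
    lecithin = LECITHIN_ML_PER_LITER * batch_volume_ml / 1000.0
    rest = batch_volume_ml - lecithin
    agar = round(glandularity * rest)
    oil = round((1.0 - glandularity) * rest)
    return MixtureRecipe(glandularity, agar, oil, lecithin, batch_volume_ml)


def material_for_mixture(recipe: MixtureRecipe) -> MaterialProperties:
    """Bulk properties of the emulsion: volume-fraction weighted density,
    mass-weighted elemental fractions of the components."""
    comps = [
        (AGAR_SOLUTION, recipe.agar_solution_volume_ml),
        (PLANT_OIL, recipe.oil_volume_ml),
        (LECITHIN_SOLUTION, recipe.lecithin_solution_volume_ml),
    ]
    vtot = sum(v for _, v in comps)
    density = sum(m.mass_density * v for m, v in comps) / vtot
    masses = [(m, m.mass_density * v) for m, v in comps]
    mtot = sum(w for _, w in masses)
    fractions: dict[str, float] = {}
    for m, w in masses:
        for el, f in m.elemental_mass_fractions.items():
            fractions[el] = fractions.get(el, 0.0) + f * w / mtot
    # renormalize away float round-off
    s = sum(fractions.values())
    fractions = {el: f / s for el, f in fractions.items()}
    return MaterialProperties(
        f"mixture_g{recipe.glandularity:g}", density, fractions)


# ---------------------------------------------------------------------------
# voxel phantom
# ---------------------------------------------------------------------------

#: measured filling volumes (cm^3) of the three printed breast shells
PHANTOM_VOLUMES_CM3 = {"small": 248.0, "medium": 358.0, "large": 1067.0}

FIELD_DIAMETER_MM = 200.0


@dataclass
class VoxelPhantom:
    """Labelled voxel grid; label 0 is air, other ids index material_table."""

    label_grid: np.ndarray          # (z, y, x) int8
    voxel_spacing_mm: float
    material_table: dict            # id -> MaterialProperties
    origin_mm: np.ndarray = None    # physical (x, y, z) of voxel (0,0,0) corner

    def __post_init__(self):
        if self.origin_mm is None:
            nz, ny, nx = self.label_grid.shape
            d = self.voxel_spacing_mm
            # rotation axis through the grid centre in x/y, chest wall at z=0
            self.origin_mm = np.array([-nx * d / 2.0, -ny * d / 2.0, 0.0])
        self.origin_mm = np.asarray(self.origin_mm, dtype=float)

    @property
    def grid_shape(self):
        return self.label_grid.shape

    @property
    def mask(self) -> np.ndarray:
        return self.label_grid > 0

    @property
    def voxel_volume_cm3(self) -> float:
        return (self.voxel_spacing_mm / 10.0) ** 3

    @property
    def physical_volume_cm3(self) -> float:
        return float(np.count_nonzero(self.label_grid)) * self.voxel_volume_cm3

    def density_grid(self) -> np.ndarray:
        """Per-voxel mass density (g/cm^3), air outside the mask."""
        rho = np.full(self.label_grid.shape, AIR.mass_density)
        for mid, mat in self.material_table.items():
            if mid != 0:
                rho[self.label_grid == mid] = mat.mass_density
        return rho


def _pendant_profile(zfrac: np.ndarray, tip_start: float = 0.85) -> np.ndarray:
    """Radius profile r(z)/R of the pendant breast solid of revolution:
    half-ellipsoid body capped with a paraboloid tip, continuous at the
    junction.  ``zfrac`` runs 0 (chest wall) to 1 (nipple)."""
    z = np.clip(zfrac, 0.0, 1.0)
    r = np.sqrt(np.clip(1.0 - z ** 2, 0.0, None))
    r_j = np.sqrt(1.0 - tip_start ** 2)
    tip = z > tip_start
    r_tip = r_j * np.sqrt(np.clip((1.0 - z) / (1.0 - tip_start), 0.0, None))
    return np.where(tip, r_tip, r)


def _rasterize(target_radius_mm: float, aspect: float, spacing: float,
               tip_start: float):
    length = aspect * target_radius_mm
    nz = int(np.ceil(length / spacing)) + 2
    nxy = int(np.ceil(2 * target_radius_mm / spacing)) + 3
    d = spacing
    zc = (np.arange(nz) + 0.5) * d
    xc = (np.arange(nxy) + 0.5) * d - nxy * d / 2.0
    Z = zc[:, None, None]
    Y = xc[None, :, None]
    X = xc[None, None, :]
    rprof = _pendant_profile(Z / length, tip_start) * target_radius_mm
    inside = (X ** 2 + Y ** 2) <= rprof ** 2
    return inside.astype(np.int8)


def build_phantom(size_label: str | None = None, *,
                  target_volume_cm3: float | None = None,
                  filling: MaterialProperties | None = None,
                  voxel_spacing_mm: float = 2.0,
                  aspect: float = 1.4,
                  tip_start: float = 0.85,
                  volume_tolerance: float = 0.005) -> VoxelPhantom:
    """Rasterize a pendant-breast solid matched to a target volume.

    The solid of revolution (half-ellipsoid with a paraboloid tip, length =
    ``aspect`` x radius) is scaled by bisection on its radius until the
    rasterized volume is within ``volume_tolerance`` of the target, so the
    discrete volume honours the measured filling volume at any spacing.
    """
    if size_label is not None:
        if size_label not in PHANTOM_VOLUMES_CM3:
            raise ValueError(f"unknown size label {size_label!r}; "
                             f"use one of {sorted(PHANTOM_VOLUMES_CM3)}")
        target_volume_cm3 = PHANTOM_VOLUMES_CM3[size_label]
    if target_volume_cm3 is None or target_volume_cm3 <= 0:
        raise ValueError("target volume must be positive")
    if voxel_spacing_mm <= 0:
        raise ValueError("voxel spacing must be positive")
    if filling is None:
        filling = material_for_mixture(make_recipe(0.375))

    # analytic volume of the profile solid: V = c * R^3 with
    # c = aspect * pi * integral r(z)^2 dz (numeric, shape-dependent)
    zf = np.linspace(0.0, 1.0, 4001)
    shape_integral = np.trapezoid(_pendant_profile(zf, tip_start) ** 2, zf)
    c = np.pi * aspect * shape_integral
    r0 = (target_volume_cm3 * 1000.0 / c) ** (1.0 / 3.0)  # mm

    lo, hi = 0.9 * r0, 1.1 * r0
    best = None
    for _ in range(40):
        r = 0.5 * (lo + hi)
        grid = _rasterize(r, aspect, voxel_spacing_mm, tip_start)
        vol = grid.sum() * (voxel_spacing_mm / 10.0) ** 3
        best = (grid, vol, r)
        err = (vol - target_volume_cm3) / target_volume_cm3
        if abs(err) <= volume_tolerance:
            break
        if vol < target_volume_cm3:
            lo = r
        else:
            hi = r
    grid, vol, r = best
    if 2.0 * r > FIELD_DIAMETER_MM:
        raise ValueError(
            f"phantom diameter {2 * r:.1f} mm exceeds the "
            f"{FIELD_DIAMETER_MM:.0f}-mm field of measurement")
    return VoxelPhantom(grid, voxel_spacing_mm, {0: AIR, 1: filling})


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def save_phantom(phantom: VoxelPhantom, path) -> None:
    """Write the label image as NIfTI plus a JSON sidecar holding the
    material table and spacing."""
    import nibabel as nib

    path = Path(path)
    affine = np.diag([phantom.voxel_spacing_mm] * 3 + [1.0])
    # NIfTI stores (x, y, z); transpose from the package's (z, y, x)
    img = nib.Nifti1Image(np.ascontiguousarray(
        phantom.label_grid.transpose(2, 1, 0)).astype(np.int16), affine)
    nib.save(img, str(path))
    sidecar = {
        "voxel_spacing_mm": phantom.voxel_spacing_mm,
        "origin_mm": list(phantom.origin_mm),
        "axis_order": "zyx",
        "materials": {
            str(mid): {
                "name": m.name,
                "mass_density": m.mass_density,
                "elemental_mass_fractions": m.elemental_mass_fractions,
            }
            for mid, m in phantom.material_table.items()
        },
    }
    path.with_suffix("").with_suffix(".json").write_text(
        json.dumps(sidecar, indent=2))


def load_phantom(path) -> VoxelPhantom:
    import nibabel as nib

    path = Path(path)
    img = nib.load(str(path))
    labels = np.asarray(img.dataobj).astype(np.int8).transpose(2, 1, 0)
    sidecar = json.loads(path.with_suffix("").with_suffix(".json").read_text())
    table = {
        int(mid): MaterialProperties(
            rec["name"], rec["mass_density"], rec["elemental_mass_fractions"])
        for mid, rec in sidecar["materials"].items()
    }
    return VoxelPhantom(labels, float(sidecar["voxel_spacing_mm"]), table,
                        np.asarray(sidecar["origin_mm"]))


def recipe_table(glandularities=(0.125, 0.375, 0.625, 0.875)):
    """Recipe rows as a DataFrame (columns: glandularity, agar_ml, oil_ml,
    lecithin_ml) for CSV export."""
    import pandas as pd

    rows = []
    for g in glandularities:
        r = make_recipe(g)
        rows.append(dict(glandularity=g, agar_ml=r.agar_solution_volume_ml,
                         oil_ml=r.oil_volume_ml,
                         lecithin_ml=r.lecithin_solution_volume_ml))
    return pd.DataFrame(rows)
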