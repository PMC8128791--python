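"""Dose-factor model and constrained tube-current recommendation.

The average absorbed dose is linear in the tube current,
``dose = F(V, g) * I``, with the dose factor F depending exponentially on
breast volume and linearly on glandularity,
``F(V, g) = alpha * exp(-beta * V) * (1 + gamma * g)``.

The optimizer picks, per phantom and filling, the smallest allowed tube
current (at or above the 25-mA clinical floor) whose SNR meets the
clinical thresholds (>= 35 in HR, >= 100 in STD); dose limits flag but
never silently drop a recommendation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .montecarlo import ALLOWED_CURRENTS_MA

# ---------------------------------------------------------------------------
# dose-factor calibration
# ---------------------------------------------------------------------------


def fit_dose_factor(currents_ma, average_doses_mgy) -> float:
    """Dose factor F (mGy/mA): slope of the least-squares line through the
    origin fitted to average dose versus tube current."""
    x = np.asarray(currents_ma, dtype=float)
    y = np.asarray(average_doses_mgy, dtype=float)
    if x.shape != y.shape:
        raise ValueError("currents and doses must have the same length")
    if x.size < 2:
        raise ValueError("need at least 2 points")
    if np.any(x <= 0):
        raise ValueError("currents must be positive")
    return float((x * y).sum() / (x * x).sum())


def predict_dose(factor_mgy_per_ma: float, current_ma: float) -> float:
    """Average absorbed dose implied by a dose factor and a current."""
    return factor_mgy_per_ma * current_ma


@dataclass
class DoseFactorTable:
    """F(volume, glandularity) lookup; glandularity as a fraction."""

    volumes_cm3: tuple
    glandularities: tuple
    factors: np.ndarray          # shape (n_glandularities, n_volumes)
    rounding_decimals: int = 2

    def as_frame(self, rounded: bool = True) -> pd.DataFrame:
        f = self.factors
        if rounded:
            f = np.round(f, self.rounding_decimals)
        return pd.DataFrame(f,
                            index=pd.Index(self.glandularities, name="glandularity"),
                            columns=pd.Index(self.volumes_cm3, name="volume_cm3"))

    def lookup(self, volume_cm3: float, glandularity: float) -> float:
        i = self.glandularities.index(glandularity)
        j = self.volumes_cm3.index(volume_cm3)
        return float(self.factors[i, j])


@dataclass
class FactorSurfaceModel:
    """Parameters of F(V, g) = alpha * exp(-beta V) * (1 + gamma g)."""

    alpha: float
    beta: float
    gamma: float
    residual_rms: float = float("nan")

    def predict(self, volume_cm3, glandularity):
        v = np.asarray(volume_cm3, dtype=float)
        g = np.asarray(glandularity, dtype=float)
        return self.alpha * np.exp(-self.beta * v) * (1.0 + self.gamma * g)


def fit_factor_surface(table: DoseFactorTable,
                       p0=(0.3, 5e-4, 0.4)) -> FactorSurfaceModel:
    """Nonlinear least squares for the exponential-in-volume,
    linear-in-glandularity factor surface; deterministic for a fixed
    initialization."""
    if len(table.volumes_cm3) < 2 or len(table.glandularities) < 2:
        raise ValueError("need at least 2 volumes and 2 glandularities")
    G, V = np.meshgrid(table.glandularities, table.volumes_cm3, indexing="ij")
    x = np.stack([V.ravel(), G.ravel()])
    y = table.factors.ravel()

    def model(x, alpha, beta, gamma):
        v, g = x
        return alpha * np.exp(-beta * v) * (1.0 + gamma * g)

    try:
        popt, _ = curve_fit(model, x, y, p0=p0, maxfev=20000)
    except RuntimeError as e:
        resid = y - model(x, *p0)
        raise RuntimeError(
            f"factor-surface fit did not converge (initial residual rms "
            f"{np.sqrt(np.mean(resid**2)):.3g}): {e}") from e
    resid = y - model(x, *popt)
    return FactorSurfaceModel(*map(float, popt),
                              residual_rms=float(np.sqrt(np.mean(resid ** 2))))


# ---------------------------------------------------------------------------
# constrained current selection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OptimizationConstraints:
    snr_hr_min: float = 35.0
    snr_std_min: float = 100.0
    dose_limit_mgy: float = 6.5
    base_dose_limit_mgy: float = 6.5   # the flag threshold (printed asterisk)
    current_min_ma: float = 25.0
    allowed_currents_ma: tuple = ALLOWED_CURRENTS_MA


@dataclass
class Recommendation:
    phantom: str
    glandularity: float
    chosen_current_ma: float
    predicted_dose_mgy: float
    exceeds_base_limit: bool
    feasible: bool

    def render(self) -> str:
        flag = "*" if self.exceeds_base_limit else ""
        return f"{self.chosen_current_ma:g} mA ({self.predicted_dose_mgy:.2f} mGy){flag}"


def select_current(snr_curves: dict, factor_mgy_per_ma: float,
                   constraints: OptimizationConstraints = OptimizationConstraints(),
                   phantom: str = "", glandularity: float = float("nan")
                   ) -> Recommendation:
    """Smallest allowed current meeting both SNR thresholds.

    ``snr_curves`` maps mode name ("HR"/"STD") to a mapping of tube current
    (mA) to SNR; the curves must cover every allowed current at or above the
    floor.  The dose limit never changes the chosen current: it sets the
    ``feasible`` flag, and doses above the base limit are flagged (the
    printed asterisk).  If no current satisfies the SNR thresholds the
    current with the best worst-case SNR margin is reported with
    ``feasible=False``.
    """
    for mode in ("HR", "STD"):
        if mode not in snr_curves or not snr_curves[mode]:
            raise ValueError(f"missing SNR curve for mode {mode!r}")
    candidates = sorted(c for c in constraints.allowed_currents_ma
                        if c >= constraints.current_min_ma)
    if not candidates:
        raise ValueError("no allowed current at or above the minimum")
    for c in candidates:
        for mode in ("HR", "STD"):
            if c not in snr_curves[mode]:
                raise ValueError(f"SNR curve for {mode} does not cover {c} mA")

    ok = [c for c in candidates
          if snr_curves["HR"][c] >= constraints.snr_hr_min
          and snr_curves["STD"][c] >= constraints.snr_std_min]
    if ok:
        chosen = ok[0]
        dose = predict_dose(factor_mgy_per_ma, chosen)
        feasible = dose <= constraints.dose_limit_mgy
    else:
        margins = {
            c: min(snr_curves["HR"][c] / constraints.snr_hr_min,
                   snr_curves["STD"][c] / constraints.snr_std_min)
            for c in candidates
        }
        best = max(margins.values())
        chosen = min(c for c, m in margins.items() if m == best)
        dose = predict_dose(factor_mgy_per_ma, chosen)
        feasible = False
    return Recommendation(phantom, glandularity, float(chosen), float(dose),
                          bool(dose > constraints.base_dose_limit_mgy),
                          bool(feasible))


def build_recommendation_table(snr_data: pd.DataFrame,
                               factor_table: DoseFactorTable,
                               constraints: OptimizationConstraints = OptimizationConstraints(),
                               small_dose_limit_mgy: float = 7.0,
                               phantom_volumes: dict | None = None) -> pd.DataFrame:
    """One recommendation per (phantom, glandularity).

    ``snr_data`` columns: phantom, glandularity, mode, current_ma, snr —
    also the ingestion format for user-measured SNR tables.  The small
    phantom uses the relaxed dose limit (7 mGy by default), mirroring the
    study's handling; the base 6.5-mGy flag threshold is unchanged.
    """
    if phantom_volumes is None:
        from .materials import PHANTOM_VOLUMES_CM3
        phantom_volumes = PHANTOM_VOLUMES_CM3
    rows = []
    for (phantom, g), grp in snr_data.groupby(["phantom", "glandularity"]):
        curves = {
            mode: dict(zip(sub["current_ma"], sub["snr"]))
            for mode, sub in grp.groupby("mode")
        }
        cons = constraints
        if phantom == "small":
            cons = replace(constraints, dose_limit_mgy=small_dose_limit_mgy)
        f = factor_table.lookup(phantom_volumes[phantom], g)
        rec = select_current(curves, f, cons, phantom=phantom, glandularity=g)
        rows.append(dict(phantom=phantom, glandularity=g,
                         current_ma=rec.chosen_current_ma,
                         dose_mgy=rec.predicted_dose_mgy,
                         exceeds_base_limit=rec.exceeds_base_limit,
                         feasible=rec.feasible, rendered=rec.render()))
    order = {"large": 0, "medium": 1, "small": 2}
    return (pd.DataFrame(rows)
            .sort_values(["phantom", "glandularity"],
                         key=lambda s: s.map(order) if s.name == "phantom" else -s)
            .reset_index(drop=True))
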