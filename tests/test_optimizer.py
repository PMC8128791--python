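import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bctopt import (
    ALLOWED_CURRENTS_MA, DoseFactorTable, OptimizationConstraints,
    build_recommendation_table, fit_dose_factor, fit_factor_surface,
    predict_dose, select_current,
)
from bctopt import reference

CURRENTS = np.array(ALLOWED_CURRENTS_MA)


class TestDoseFactorFit:
    def test_exact_linear_data(self):
        assert fit_dose_factor(CURRENTS, 0.24 * CURRENTS) == pytest.approx(0.24)

    def test_all_zero_doses(self):
        assert fit_dose_factor(CURRENTS, np.zeros_like(CURRENTS)) == 0.0

    def test_noisy_recovery_within_three_standard_errors(self):
        rng = np.random.default_rng(0)
        noise = rng.normal(0.0, 0.05, CURRENTS.size)
        f = fit_dose_factor(CURRENTS, 0.24 * CURRENTS + noise)
        se = 0.05 / np.sqrt((CURRENTS ** 2).sum())
        assert abs(f - 0.24) < 3.0 * se

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            fit_dose_factor([25.0, 32.0], [6.0])

    @pytest.mark.parametrize("f,i,expected", [(0.24, 25.0, 6.0), (0.19, 32.0, 6.08),
                                              (0.3, 0.0, 0.0)])
    def test_predict_dose(self, f, i, expected):
        assert predict_dose(f, i) == pytest.approx(expected)


class TestFactorSurface:
    def test_noiseless_parameter_recovery(self):
        alpha, beta, gamma = 0.3, 5e-4, 0.4
        vols = (248.0, 358.0, 1067.0)
        glands = (0.125, 0.375, 0.625, 0.875)
        G, V = np.meshgrid(glands, vols, indexing="ij")
        table = DoseFactorTable(vols, glands,
                                alpha * np.exp(-beta * V) * (1 + gamma * G))
        fit = fit_factor_surface(table)
        assert fit.alpha == pytest.approx(alpha, abs=1e-6)
        assert fit.beta == pytest.approx(beta, abs=1e-6)
        assert fit.gamma == pytest.approx(gamma, abs=1e-6)

    def test_fit_on_published_lookup_is_monotone(self):
        table = DoseFactorTable(
            reference.DOSE_FACTOR_VOLUMES_CM3,
            reference.DOSE_FACTOR_GLANDULARITIES,
            reference.DOSE_FACTOR_MGY_PER_MA.to_numpy())
        fit = fit_factor_surface(table)
        assert fit.beta > 0 and fit.gamma > 0
        v = np.linspace(200.0, 1100.0, 10)
        assert np.all(np.diff(fit.predict(v, 0.5)) < 0)
        g = np.linspace(0.0, 1.0, 10)
        assert np.all(np.diff(fit.predict(500.0, g)) > 0)

    def test_single_volume_underdetermined(self):
        table = DoseFactorTable((358.0,), (0.125, 0.875),
                                np.array([[0.24], [0.27]]))
        with pytest.raises(ValueError):
            fit_factor_surface(table)


def flat_curves(hr, std):
    """SNR curves constant over the allowed currents."""
    return {"HR": {c: hr for c in ALLOWED_CURRENTS_MA},
            "STD": {c: std for c in ALLOWED_CURRENTS_MA}}


def curve_from_pairs(pairs):
    return {c: s for c, s in pairs}


class TestSelectCurrent:
    def test_medium_phantom_operating_point(self):
        rec = select_current(flat_curves(40.0, 110.0), 0.2396)
        assert rec.chosen_current_ma == 25.0
        assert rec.predicted_dose_mgy == pytest.approx(5.99, abs=0.01)
        assert not rec.exceeds_base_limit and rec.feasible

    def test_large_phantom_needs_32_ma(self):
        hr = {c: (33.0 if c < 32.0 else 37.0) for c in ALLOWED_CURRENTS_MA}
        std = {c: (95.0 if c < 32.0 else 104.0) for c in ALLOWED_CURRENTS_MA}
        rec = select_current({"HR": hr, "STD": std}, 0.2025)
        assert rec.chosen_current_ma == 32.0
        assert rec.predicted_dose_mgy == pytest.approx(6.48, abs=0.01)

    def test_small_phantom_flagged_above_base_limit(self):
        cons = OptimizationConstraints(dose_limit_mgy=7.0)
        rec = select_current(flat_curves(40.0, 110.0), 0.2912, cons)
        assert rec.chosen_current_ma == 25.0
        assert rec.predicted_dose_mgy == pytest.approx(7.28, abs=0.01)
        assert rec.exceeds_base_limit
        assert not rec.feasible  # 7.28 exceeds even the relaxed 7-mGy limit

    def test_infeasible_snr_reports_best_margin(self):
        rec = select_current(flat_curves(20.0, 50.0), 0.2)
        assert not rec.feasible
        assert rec.chosen_current_ma in ALLOWED_CURRENTS_MA

    def test_incomplete_curves_rejected(self):
        with pytest.raises(ValueError):
            select_current({"HR": {25.0: 40.0}, "STD": {25.0: 110.0}}, 0.2)

    @settings(derandomize=True, max_examples=150)
    @given(st.data())
    def test_matches_exhaustive_search(self, data):
        """Optimality oracle: the selection equals brute force over the
        allowed current grid for arbitrary monotone SNR curves."""
        base_hr = data.draw(st.floats(10.0, 60.0))
        base_std = data.draw(st.floats(40.0, 160.0))
        slope_hr = data.draw(st.floats(0.0, 20.0))
        slope_std = data.draw(st.floats(0.0, 60.0))
        f = data.draw(st.floats(0.05, 0.5))
        curves = {
            "HR": {c: base_hr + slope_hr * np.log(c / 25.0) for c in ALLOWED_CURRENTS_MA},
            "STD": {c: base_std + slope_std * np.log(c / 25.0) for c in ALLOWED_CURRENTS_MA},
        }
        cons = OptimizationConstraints()
        rec = select_current(curves, f, cons)
        ok = [c for c in sorted(ALLOWED_CURRENTS_MA)
              if c >= cons.current_min_ma
              and curves["HR"][c] >= cons.snr_hr_min
              and curves["STD"][c] >= cons.snr_std_min]
        if ok:
            assert rec.chosen_current_ma == ok[0]
            assert rec.feasible == (f * ok[0] <= cons.dose_limit_mgy)
        else:
            assert not rec.feasible
        assert rec.exceeds_base_limit == (rec.predicted_dose_mgy > 6.5)

    @pytest.mark.parametrize("limits", [(5.0, 6.5, 8.0)])
    def test_monotone_in_dose_limit_and_thresholds(self, limits):
        curves = {
            "HR": {c: 30.0 + 8.0 * np.log(c / 25.0 + 1.0) for c in ALLOWED_CURRENTS_MA},
            "STD": {c: 90.0 + 25.0 * np.log(c / 25.0 + 1.0) for c in ALLOWED_CURRENTS_MA},
        }
        chosen_by_limit = [
            select_current(curves, 0.25,
                           OptimizationConstraints(dose_limit_mgy=d)).chosen_current_ma
            for d in limits]
        assert np.all(np.diff(chosen_by_limit) <= 0)
        chosen_by_thresh = [
            select_current(curves, 0.25,
                           OptimizationConstraints(snr_hr_min=t)).chosen_current_ma
            for t in (30.0, 35.0, 40.0)]
        assert np.all(np.diff(chosen_by_thresh) >= 0)


class TestPublishedRoundTrip:
    def test_quotients_reproduce_factor_lookup(self):
        """Dose/current from the published recommendations, rounded to two
        decimals, matches the published factor lookup (one printed cell —
        small phantom, 37.5% — deviates by a single rounding step)."""
        lut = reference.DOSE_FACTOR_MGY_PER_MA
        vol = {"small": 248.0, "medium": 358.0, "large": 1067.0}
        for _, row in reference.RECOMMENDATIONS.iterrows():
            q = round(row.dose_mgy / row.current_ma, 2)
            assert q == pytest.approx(
                lut.loc[row.glandularity, vol[row.phantom]], abs=0.0101)

    def test_unique_large_25ma_cell_exact(self):
        row = reference.RECOMMENDATIONS.query(
            "phantom == 'large' and current_ma == 25.0").iloc[0]
        assert round(row.dose_mgy / 25.0, 2) == 0.21
        assert reference.DOSE_FACTOR_MGY_PER_MA.loc[row.glandularity, 1067.0] == 0.21

    def test_flag_logic_on_printed_inputs(self):
        """Feeding the optimizer the published factors with SNR curves that
        first satisfy both thresholds at each published current reproduces
        the printed recommendation, dose and asterisk flags."""
        vol = {"small": 248.0, "medium": 358.0, "large": 1067.0}
        for _, row in reference.RECOMMENDATIONS.iterrows():
            f = row.dose_mgy / row.current_ma  # unrounded printed factor
            hr = {c: (36.0 if c >= row.current_ma else 34.0)
                  for c in ALLOWED_CURRENTS_MA}
            std = {c: (102.0 if c >= row.current_ma else 98.0)
                   for c in ALLOWED_CURRENTS_MA}
            cons = OptimizationConstraints(
                dose_limit_mgy=7.0 if row.phantom == "small" else 6.5)
            rec = select_current({"HR": hr, "STD": std}, f, cons,
                                 phantom=row.phantom, glandularity=row.glandularity)
            assert rec.chosen_current_ma == row.current_ma
            assert rec.predicted_dose_mgy == pytest.approx(row.dose_mgy, abs=0.005)
            assert rec.exceeds_base_limit == row.flagged


class TestRecommendationTable:
    def test_one_row_per_cell_with_rendered_flags(self):
        import pandas as pd

        snr_rows = []
        for p in ("small", "medium", "large"):
            for g in (0.125, 0.875):
                for mode, val in (("HR", 40.0), ("STD", 110.0)):
                    for c in ALLOWED_CURRENTS_MA:
                        snr_rows.append(dict(phantom=p, glandularity=g,
                                             mode=mode, current_ma=c, snr=val))
        table = DoseFactorTable((248.0, 358.0, 1067.0), (0.125, 0.875),
                                np.array([[0.29, 0.27, 0.21],
                                          [0.25, 0.24, 0.19]])[::-1])
        recs = build_recommendation_table(pd.DataFrame(snr_rows), table)
        assert len(recs) == 6
        flagged = recs.query("phantom == 'small' and glandularity == 0.875")
        assert bool(flagged.exceeds_base_limit.iloc[0])
        assert flagged.rendered.str.endswith("*").iloc[0]
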