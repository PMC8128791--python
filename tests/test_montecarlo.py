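import numpy as np
import pytest

from bctopt import (
    ACQUISITION_TIME_S, WATER, average_dose, build_phantom, build_protocol,
    percent_difference, radial_dose_profile, simulate_dose, slab_transmission,
    spiral_trajectory, surface_dose,
)
from bctopt.montecarlo import DoseMap
from bctopt.physics import mass_attenuation


class TestProtocol:
    @pytest.mark.parametrize("length,time", [(80.0, 7.0), (120.0, 9.5), (160.0, 12.0)])
    def test_acquisition_time_lookup(self, length, time):
        assert build_protocol(25.0, length).acquisition_time_s == time

    @pytest.mark.parametrize("current,length", [(30.0, 80.0), (25.0, 140.0)])
    def test_disallowed_settings_rejected(self, current, length):
        with pytest.raises(ValueError, match="allowed"):
            build_protocol(current, length)

    def test_pitch_advance_per_rotation(self):
        p = build_protocol(25.0, 80.0)
        assert p.z_advance_per_rotation_mm == pytest.approx(33.11, abs=0.01)

    def test_rotation_count_geometry(self):
        p = build_protocol(25.0, 120.0)
        assert p.n_rotations == pytest.approx((120.0 + 31.53) / (1.05 * 31.53))

    def test_trajectory_symmetric_about_scan_center(self):
        traj = spiral_trajectory(build_protocol(25.0, 80.0), z_center_mm=40.0)
        z = traj["source_mm"][:, 2]
        assert z[0] + z[-1] == pytest.approx(2 * 40.0, abs=1e-6)
        one_rot = np.searchsorted(traj["angle_rad"], 2 * np.pi)
        assert z[one_rot] - z[0] == pytest.approx(33.11, abs=0.05)


class TestTransportContracts:
    def test_zero_histories_warns_and_returns_zero_map(self, small_phantom, spectrum):
        with pytest.warns(UserWarning, match="zero histories"):
            dm = simulate_dose(small_phantom, build_protocol(25.0, 80.0),
                               spectrum, n_histories=0, seed=1)
        assert not dm.dose_mgy.any()

    def test_seed_determinism_bitwise(self, small_phantom, spectrum):
        proto = build_protocol(25.0, 80.0)
        a = simulate_dose(small_phantom, proto, spectrum, 8000, seed=42)
        b = simulate_dose(small_phantom, proto, spectrum, 8000, seed=42)
        c = simulate_dose(small_phantom, proto, spectrum, 8000, seed=43)
        assert np.array_equal(a.dose_mgy, b.dose_mgy)
        assert not np.array_equal(a.dose_mgy, c.dose_mgy)

    def test_dose_scales_exactly_with_current(self, small_phantom, spectrum):
        """Per-mAs normalization: doubling the current doubles every voxel."""
        a = simulate_dose(small_phantom, build_protocol(25.0, 80.0), spectrum,
                          8000, seed=5)
        b = simulate_dose(small_phantom, build_protocol(50.0, 80.0), spectrum,
                          8000, seed=5)
        assert np.allclose(b.dose_mgy, 2.0 * a.dose_mgy, rtol=1e-14, atol=0.0)

    def test_energy_conservation(self, small_dose_map):
        assert 0 < small_dose_map.total_deposited_kev <= small_dose_map.total_emitted_kev

    def test_dose_zero_outside_mask(self, small_dose_map, small_phantom):
        assert not small_dose_map.dose_mgy[~small_phantom.mask].any()
        assert np.all(small_dose_map.dose_mgy >= 0)

    def test_standard_error_scales_inverse_sqrt_n(self, small_phantom, spectrum):
        proto = build_protocol(25.0, 80.0)
        small = simulate_dose(small_phantom, proto, spectrum, 15_000, seed=9)
        big = simulate_dose(small_phantom, proto, spectrum, 60_000, seed=10)
        rel_small = small.average_dose_se_mgy / small.average_dose_mgy
        rel_big = big.average_dose_se_mgy / big.average_dose_mgy
        assert rel_small / rel_big == pytest.approx(2.0, rel=0.2)


class TestBeerLambertOracle:
    @pytest.mark.parametrize("energy,thickness", [(25.0, 3.0), (40.0, 4.0)])
    def test_primary_transmission_matches_closed_form(self, energy, thickness):
        frac, se = slab_transmission(WATER, thickness, energy,
                                     n_histories=40_000, seed=3)
        mu = WATER.mass_density * (mass_attenuation(WATER, energy, "pe")
                                   + mass_attenuation(WATER, energy, "incoh"))
        assert abs(frac - np.exp(-mu * thickness)) < 3.0 * se + 1e-9


class TestDoseMapAnalysis:
    def test_average_dose_of_uniform_map(self, small_phantom):
        d = np.where(small_phantom.mask, 2.5, 0.0)
        dm = DoseMap(d, np.zeros_like(d), 1, 0, build_protocol(25.0, 80.0),
                     "absolute-mGy", 1.0, 1.0, 1.0, 2.5, 0.0)
        assert average_dose(dm, small_phantom) == pytest.approx(2.5)

    def test_average_dose_empty_mask_raises(self, small_phantom, small_dose_map):
        import copy

        empty = copy.copy(small_phantom)
        empty.label_grid = np.zeros_like(small_phantom.label_grid)
        with pytest.raises(ValueError, match="empty"):
            average_dose(small_dose_map, empty)

    def test_periphery_receives_more_dose_than_center(self, small_dose_map,
                                                      small_phantom):
        radius, prof = radial_dose_profile(small_dose_map, small_phantom)
        valid = ~np.isnan(prof)
        r, p = radius[valid], prof[valid]
        inner = p[r <= r.max() * 0.2].mean()
        outer = p[r >= r.max() * 0.8].mean()
        assert outer > inner

    def test_uniform_map_gives_flat_profile(self, small_phantom):
        d = np.where(small_phantom.mask, 1.0, 0.0)
        dm = DoseMap(d, np.zeros_like(d), 1, 0, build_protocol(25.0, 80.0),
                     "absolute-mGy", 1.0, 1.0, 1.0, 1.0, 0.0)
        _, prof = radial_dose_profile(dm, small_phantom)
        assert np.nanstd(prof) == pytest.approx(0.0, abs=1e-12)

    def test_surface_dose_patch(self, small_dose_map, small_phantom):
        mask = small_phantom.mask
        z = int(np.argmax(mask.sum(axis=(1, 2))))
        yy, xx = np.nonzero(mask[z])
        d = small_phantom.voxel_spacing_mm
        pos = ((xx.max() + 0.5) * d + small_phantom.origin_mm[0],
               (yy[xx.argmax()] + 0.5) * d + small_phantom.origin_mm[1],
               (z + 0.5) * d)
        samples = surface_dose(small_dose_map, small_phantom, [pos],
                               measured_mgy=[1.0])
        assert samples[0].simulated_mgy > 0
        assert samples[0].percent_difference is not None

    def test_surface_dose_rejects_interior_position(self, small_dose_map,
                                                    small_phantom):
        with pytest.raises(ValueError, match="surface"):
            surface_dose(small_dose_map, small_phantom, [(0.0, 0.0, 1000.0)])


class TestPercentDifference:
    @pytest.mark.parametrize("measured,simulated,expected", [
        (10.0, 8.6, -14.0),     # printed -13.7 comes from unrounded doses
        (6.8, 8.0, 17.6),       # printed 18.1
        (7.2, 6.7, -6.9),       # printed -7.7
        (5.0, 5.0, 0.0),
    ])
    def test_arithmetic_on_printed_doses(self, measured, simulated, expected):
        assert percent_difference(measured, simulated) == pytest.approx(
            expected, abs=0.05)

    def test_requires_positive_measurement(self):
        with pytest.raises(ValueError):
            percent_difference(0.0, 1.0)
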