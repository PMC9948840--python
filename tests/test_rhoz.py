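"""Look-up-table inversion of paired HU into Z_eff and effective density."""

import numpy as np
import pytest

from deqct import (
    MaterialSpec,
    VOIMeasurement,
    calibrate_density,
    estimate_rho_e,
    estimate_rhoz,
    estimate_zeff,
    forward_hu,
    hu_to_mu_eff_star,
    predict_mu_m_star,
)
from deqct.materials import derive


class TestHuToAttenuation:
    @pytest.mark.parametrize("hu,expected", [(0.0, 1.0), (-1000.0, 0.0), (250.0, 1.25)])
    def test_values(self, hu, expected):
        assert hu_to_mu_eff_star(hu) == pytest.approx(expected)

    def test_below_air_rejected(self):
        with pytest.raises(ValueError):
            hu_to_mu_eff_star(-1001.0)


class TestLookupTable:
    def test_thirty_rows(self, lut):
        assert len(lut.z) == 30
        assert np.all(np.isfinite(lut.f_of_z))
        assert np.all(lut.f_of_z > 0)

    def test_row_at_z20_matches_hand_evaluation(self, lut, beam):
        zn = (20.0 / beam.water_zeff) ** beam.n
        mu_low = predict_mu_m_star(zn, beam.alpha_low)
        mu_high = predict_mu_m_star(zn, beam.alpha_high)
        i = 19
        assert lut.mu_m_star_low[i] == pytest.approx(mu_low, rel=1e-12)
        assert lut.f_of_z[i] == pytest.approx(mu_low / mu_high, rel=1e-12)

    def test_f_strictly_monotone_from_carbon_up(self, lut):
        seg = lut.f_of_z[5:]  # Z >= 6
        assert np.all(np.diff(seg) > 0)

    def test_water_ratio_interpolates_to_water_zeff(self, lut, beam):
        z = lut.zeff_from_ratio(1.0)
        # limited by piecewise-linear interpolation between integer Z
        assert z == pytest.approx(beam.water_zeff, rel=5e-3)

    def test_serialization_carries_beam_provenance(self, lut, tmp_path):
        path = tmp_path / "lut.tsv"
        lut.save(path)
        text = path.read_text()
        assert text.startswith("# beam:")
        assert f"n={lut.beam.n:g}" in text


class TestZeffEstimation:
    def test_water_voi(self, lut, beam):
        z = estimate_zeff(VOIMeasurement("water", 0.0, 0.0), lut)
        assert z == pytest.approx(beam.water_zeff, rel=5e-3)

    def test_out_of_range_raises_with_interval(self, lut):
        with pytest.raises(ValueError, match="invertible interval"):
            estimate_zeff(VOIMeasurement("bad", -999.0, 3000.0), lut)

    def test_clamp_pins_to_range(self, lut):
        z = estimate_zeff(VOIMeasurement("bad", -999.0, 3000.0), lut, clamp=True)
        lo, hi = lut.invertible_z
        assert z in (pytest.approx(lo), pytest.approx(hi))

    def test_scale_invariance(self, lut):
        base = VOIMeasurement("a", 200.0, 120.0)
        mu_l, mu_h = hu_to_mu_eff_star(200.0), hu_to_mu_eff_star(120.0)
        scaled = VOIMeasurement(
            "b", 1000.0 * (1.7 * mu_l - 1.0), 1000.0 * (1.7 * mu_h - 1.0)
        )
        assert estimate_zeff(base, lut) == pytest.approx(
            estimate_zeff(scaled, lut), rel=1e-12
        )


class TestRhoEEstimation:
    def test_water_voi_is_unity(self, lut, beam):
        voi = VOIMeasurement("water", 0.0, 0.0)
        z = estimate_zeff(voi, lut)
        assert estimate_rho_e(voi, z, lut) == pytest.approx(1.0, abs=5e-3)

    def test_homogeneity(self, lut):
        voi = VOIMeasurement("a", 300.0, 180.0)
        z = estimate_zeff(voi, lut)
        rho = estimate_rho_e(voi, z, lut)
        mu_l, mu_h = hu_to_mu_eff_star(300.0), hu_to_mu_eff_star(180.0)
        doubled = VOIMeasurement(
            "b", 1000.0 * (2 * mu_l - 1.0), 1000.0 * (2 * mu_h - 1.0)
        )
        z2 = estimate_zeff(doubled, lut)
        assert estimate_rho_e(doubled, z2, lut) == pytest.approx(2 * rho, rel=1e-9)


class TestRoundTrip:
    @pytest.mark.parametrize("w_ca,density", [
        (0.00, 0.95), (0.05, 1.05), (0.15, 1.2), (0.30, 1.5), (0.55, 2.2),
    ])
    def test_forward_inverse_recovery(self, lut, beam, w_ca, density):
        """Noise-free Z_eff/rho_e* recovery to < 0.5% over Z_eff ~ 6.3-16."""
        mat = MaterialSpec("m", {"H": 0.10 * (1 - w_ca), "O": 0.90 * (1 - w_ca),
                                 "Ca": w_ca}, density)
        d = derive(mat, beam.n)
        hu = forward_hu({mat: 1.0}, beam)
        voi = VOIMeasurement("m", *hu)
        z = estimate_zeff(voi, lut)
        rho = estimate_rho_e(voi, z, lut)
        assert abs(z / d.z_eff - 1.0) < 5e-3
        assert abs(rho / d.rho_e_star - 1.0) < 5e-3


class TestDensityCalibration:
    def test_exact_identity_line(self):
        cal = calibrate_density([(0.9, 0.9), (1.0, 1.0), (1.3, 1.3)])
        assert cal.slope == pytest.approx(1.0, abs=1e-12)
        assert cal.intercept == pytest.approx(0.0, abs=1e-12)
        assert cal(1.1) == pytest.approx(1.1)

    def test_noisy_line_recovery_within_se(self):
        rng = np.random.default_rng(7)
        slope_true, intercept_true = 1.07, -0.05
        x = np.linspace(0.9, 1.7, 7)
        y = slope_true * x + intercept_true + rng.normal(0, 0.004, x.size)
        cal = calibrate_density(list(zip(x, y)))
        assert cal.slope == pytest.approx(slope_true, abs=3 * cal.slope_se)

    def test_degenerate_points_rejected(self):
        with pytest.raises(ValueError):
            calibrate_density([(1.0, 1.0), (1.0, 2.0)])
        with pytest.raises(ValueError):
            calibrate_density([(1.0, 1.0)])

    def test_full_estimate_with_density(self, lut):
        cal = calibrate_density([(0.9, 0.9), (1.0, 1.0), (1.3, 1.3)])
        res = estimate_rhoz(VOIMeasurement("water", 0.0, 0.0), lut, cal)
        assert res.rho_eff == pytest.approx(1.0, abs=5e-3)
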