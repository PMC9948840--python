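"""Volume-fraction decomposition: exact solves, fallback, BMD."""

import numpy as np
import pytest

from deqct import (
    BasisMaterial,
    CCurve,
    HYDROXYAPATITE,
    MaterialSpec,
    VOIMeasurement,
    basis_attenuation,
    basis_from_series,
    basis_from_vial,
    beam_hardening_factor,
    bmd,
    decompose,
    forward_hu,
    mass_fractions_from_volume,
    predict_mu_m_star,
    spongiosa_basis,
)
from deqct.decomposition import calibrate_c_curve
from deqct.materials import derive

WATER = MaterialSpec.from_formula("water", "H2O", 1.0)


@pytest.fixture(scope="module")
def basis3(beam):
    return [basis_attenuation(m, beam) for m in spongiosa_basis().values()]


class TestBasisAttenuation:
    def test_water_is_unity_at_both_beams(self, beam):
        b = basis_attenuation(WATER, beam)
        assert b.mu_star_low == pytest.approx(1.0, abs=1e-12)
        assert b.mu_star_high == pytest.approx(1.0, abs=1e-12)

    def test_water_equivalent_scales_with_electron_density(self, beam):
        b = basis_attenuation(MaterialSpec.from_formula("heavy", "H2O", 2.0), beam)
        assert b.mu_star_low == pytest.approx(2.0, rel=1e-12)
        assert b.mu_star_high == pytest.approx(2.0, rel=1e-12)

    def test_hydroxyapatite_two_step_hand_evaluation(self, beam):
        d = derive(HYDROXYAPATITE, beam.n)
        expected_low = predict_mu_m_star(d.z_eff_star_n, beam.alpha_low) * d.rho_e_star
        b = basis_attenuation(HYDROXYAPATITE, beam)
        assert b.mu_star_low == pytest.approx(expected_low, rel=1e-12)
        assert b.source == "computed"


class TestMeasuredBasis:
    def test_zero_hu_vial_is_water_like(self):
        b = basis_from_vial(VOIMeasurement("v", 0.0, 0.0), "agar", 1.0)
        assert (b.mu_star_low, b.mu_star_high) == (1.0, 1.0)
        assert b.source == "measured"

    def test_series_extrapolates_generating_line(self):
        # HU exactly linear in concentration at both beams
        slopes, intercepts = (1.2, 0.8), (10.0, 5.0)
        conc = [100.0, 200.0, 300.0]
        vials = [
            VOIMeasurement(
                f"v{c}", slopes[0] * c + intercepts[0], slopes[1] * c + intercepts[1]
            )
            for c in conc
        ]
        pure, base = basis_from_series(vials, conc, "ha", 3000.0)
        assert pure.mu_star_low == pytest.approx(
            (slopes[0] * 3000.0 + intercepts[0]) / 1000.0 + 1.0, rel=1e-9
        )
        assert base.mu_star_low == pytest.approx(intercepts[0] / 1000.0 + 1.0, rel=1e-9)

    def test_noisy_series_recovery(self):
        rng = np.random.default_rng(11)
        conc = np.array([100.0, 150.0, 200.0, 250.0, 300.0])
        hu80 = 1.25 * conc + 12.0 + rng.normal(0, 1.0, conc.size)
        hu130 = 0.85 * conc + 6.0 + rng.normal(0, 1.0, conc.size)
        vials = [VOIMeasurement(f"v{i}", a, b) for i, (a, b) in enumerate(zip(hu80, hu130))]
        pure, _ = basis_from_series(vials, list(conc), "ha", 3000.0)
        assert pure.mu_star_low == pytest.approx(1.25 * 3.0 + 0.012 + 1.0, rel=0.01)

    def test_degenerate_series_rejected(self):
        vials = [VOIMeasurement("a", 0, 0), VOIMeasurement("b", 1, 1)]
        with pytest.raises(ValueError):
            basis_from_series(vials, [100.0, 100.0], "ha")


class TestBeamHardeningFactor:
    def test_unity_below_threshold(self):
        assert beam_hardening_factor(7.5) == 1.0
        assert beam_hardening_factor(7.5, CCurve([11, 15], [1.05, 1.2])) == 1.0

    def test_identity_default_above_threshold(self):
        assert beam_hardening_factor(12.0) == 1.0

    def test_configured_curve(self):
        curve = CCurve([10.0, 20.0], [1.0, 1.1])  # C(Z) = 1 + 0.01 (Z - 10)
        assert beam_hardening_factor(12.0, curve) == pytest.approx(1.02)

    def test_malformed_curve_rejected(self):
        with pytest.raises(ValueError):
            CCurve([10.0, 10.0], [1.0, 1.1])
        with pytest.raises(ValueError):
            CCurve([10.0, 12.0], [1.0, -0.5])

    def test_calibrated_curve_recovers_known_factor(self, beam, basis3):
        c_true = 1.03
        mats = list(spongiosa_basis().values())
        vf = {"hydroxyapatite": 0.3, "water_phema": 0.7}
        mixture = [(mats[0], 0.3), (mats[2], 0.7)]
        hu = forward_hu(mixture, beam, c_factor=c_true)
        curve = calibrate_c_curve(
            [(VOIMeasurement("ref", *hu), vf, 12.5)], basis3
        )
        assert curve(12.5) == pytest.approx(c_true, rel=1e-9)


class TestDecompose:
    def test_pure_member_gives_unit_vector(self, beam, basis3):
        mats = list(spongiosa_basis().values())
        hu = forward_hu({mats[1]: 1.0}, beam)
        res = decompose(VOIMeasurement("oil", *hu), basis3)
        assert res.volume_fractions["peanut_oil"] == pytest.approx(1.0, abs=1e-9)
        assert res.bmd_mg_cm3 == pytest.approx(0.0, abs=1e-6)

    def test_simplex_round_trip_200_mixtures(self, beam, basis3):
        """decompose(forward(vf)) == vf to 1e-9 for random simplex points."""
        rng = np.random.default_rng(3)
        mats = list(spongiosa_basis().values())
        vf = rng.dirichlet(np.ones(3), size=200)
        worst = 0.0
        for k in range(200):
            hu = forward_hu(list(zip(mats, vf[k])), beam)
            res = decompose(VOIMeasurement(f"m{k}", *hu), basis3)
            got = np.array([res.volume_fractions[m.name] for m in mats])
            worst = max(worst, float(np.abs(got - vf[k]).max()))
        assert worst < 1e-9

    def test_closure_is_exact(self, beam, basis3):
        res = decompose(VOIMeasurement("v", 180.0, 120.0), basis3)
        assert sum(res.volume_fractions.values()) == pytest.approx(1.0, abs=1e-12)

    @staticmethod
    def _head_like_hu(beam):
        """A high-mineral, fat-free VOI whose high-kVp reading carries a few
        HU of residual beam-hardening error — enough to push the exact
        solution outside the simplex (the fat fraction goes negative)."""
        mats = list(spongiosa_basis().values())
        hu = forward_hu([(mats[0], 0.22), (mats[2], 0.78)], beam)
        return hu[0], hu[1] + 5.0

    def test_fallback_on_no_fat_high_mineral_mixture(self, beam, basis3):
        hu = self._head_like_hu(beam)
        res3 = decompose(VOIMeasurement("head", *hu), basis3)
        assert res3.fallback == ("peanut_oil",)
        assert res3.volume_fractions["peanut_oil"] == 0.0
        res2 = decompose(
            VOIMeasurement("head", *hu),
            [b for b in basis3 if b.name != "peanut_oil"],
        )
        for name in ("hydroxyapatite", "water_phema"):
            assert res3.volume_fractions[name] == pytest.approx(
                res2.volume_fractions[name], abs=1e-12
            )

    def test_fallback_is_idempotent(self, beam, basis3):
        hu = self._head_like_hu(beam)
        res = decompose(VOIMeasurement("head", *hu), basis3)
        reduced = [b for b in basis3 if b.name not in res.fallback]
        again = decompose(VOIMeasurement("head", *hu), reduced)
        for name, value in again.volume_fractions.items():
            assert res.volume_fractions[name] == pytest.approx(value, abs=1e-12)

    def test_two_material_equals_three_with_member_pinned(self, beam, basis3):
        mats = list(spongiosa_basis().values())
        hu = forward_hu([(mats[0], 0.1), (mats[2], 0.9)], beam)
        res2 = decompose(VOIMeasurement("v", *hu),
                         [basis3[0], basis3[2]])
        res3 = decompose(VOIMeasurement("v", *hu), basis3)
        assert res3.volume_fractions["peanut_oil"] == pytest.approx(0.0, abs=1e-9)
        assert res2.volume_fractions["hydroxyapatite"] == pytest.approx(
            res3.volume_fractions["hydroxyapatite"], abs=1e-9
        )

    def test_singular_basis_rejected(self):
        # two members indistinguishable at both beams: the closure-constrained
        # system is singular
        a = BasisMaterial("a", 1.2, 1.1, 1.0)
        b = BasisMaterial("b", 1.2, 1.1, 2.0)
        c = BasisMaterial("c", 0.9, 0.95, 0.9)
        with pytest.raises(np.linalg.LinAlgError):
            decompose(VOIMeasurement("v", 100.0, 80.0), [a, b, c])

    def test_conditioning_warning_near_collinear(self, beam, basis3):
        """Fat and water surrogates are nearly collinear in attenuation space;
        noise amplification shows up as a large condition number."""
        res = decompose(VOIMeasurement("v", 180.0, 120.0), basis3)
        assert res.condition_number > 100.0

    def test_noise_amplification_grows_with_collinearity(self, beam, basis3):
        rng = np.random.default_rng(5)
        mats = list(spongiosa_basis().values())
        vf_true = np.array([0.14, 0.41, 0.45])
        hu = np.array(forward_hu(list(zip(mats, vf_true)), beam))
        well = [basis3[0], basis_attenuation(WATER, beam),
                BasisMaterial("air", 1e-3, 1e-3, 1e-3)]

        def spread(basis):
            errs = []
            for _ in range(40):
                noisy = hu + rng.normal(0, 5.0, 2)
                res = decompose(VOIMeasurement("v", *noisy), basis)
                errs.append(res.volume_fractions[basis[0].name])
            return np.std(errs)

        assert spread(basis3) > spread(well)


class TestMassFractions:
    def test_single_material_identity(self):
        mf, resid = mass_fractions_from_volume({"x": 1.0}, {"x": 1.7}, 1.7)
        assert mf["x"] == pytest.approx(1.0)
        assert resid == pytest.approx(0.0, abs=1e-12)

    def test_half_half_mixture(self):
        mf, _ = mass_fractions_from_volume(
            {"a": 0.5, "b": 0.5}, {"a": 1.0, "b": 3.0}, 2.0
        )
        assert mf == {"a": pytest.approx(0.25), "b": pytest.approx(0.75)}

    def test_round_trip_is_identity(self):
        vf = {"a": 0.3, "b": 0.7}
        rho = {"a": 1.2, "b": 0.9}
        rho_eff = sum(vf[k] * rho[k] for k in vf)
        mf, resid = mass_fractions_from_volume(vf, rho, rho_eff)
        back = {k: mf[k] * rho_eff / rho[k] for k in mf}
        assert back["a"] == pytest.approx(vf["a"], rel=1e-12)
        assert resid < 1e-12

    def test_zero_density_rejected(self):
        with pytest.raises(ValueError):
            mass_fractions_from_volume({"a": 1.0}, {"a": 0.0}, 1.0)


class TestBmd:
    @pytest.mark.parametrize("vf,expected", [(0.0, 0.0), (1 / 60, 50.0), (0.22, 660.0)])
    def test_values(self, vf, expected):
        assert bmd(vf) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bmd(1.2)

    def test_configurable_mineral_density(self):
        assert bmd(0.5, mineral_density_mg_cm3=2000.0) == pytest.approx(1000.0)
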