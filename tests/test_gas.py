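import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dielpond import (
    ChamberSeries,
    DomainError,
    GasSample,
    ValidationError,
    chamber_flux,
    dissolved_gas_result,
    equilibrium_solubility,
    headspace_to_dissolved,
    partition_to_headspace,
    saturation_percent,
)
from dielpond.gas import R_L_ATM

GASES = ("CO2", "CH4", "N2O")


class TestSolubility:
    @pytest.mark.parametrize("gas", GASES)
    def test_decreases_with_temperature(self, gas):
        assert equilibrium_solubility(gas, 5, 0) > equilibrium_solubility(gas, 25, 0)

    @pytest.mark.parametrize("gas", GASES)
    def test_salting_out(self, gas):
        assert equilibrium_solubility(gas, 20, 0) > equilibrium_solubility(gas, 20, 35)

    @pytest.mark.parametrize(
        "gas,coeffs,bunsen",
        [
            ("CO2", ((-58.0931, 90.5069, 22.2940), (0.027766, -0.025888, 0.0050578)), False),
            ("N2O", ((-62.7062, 97.3066, 24.1406), (-0.058420, 0.033193, -0.0051313)), False),
            ("CH4", ((-68.8862, 101.4956, 28.7314), (-0.076146, 0.043970, -0.0068672)), True),
        ],
    )
    def test_matches_independent_polynomial_evaluation(self, gas, coeffs, bunsen):
        # re-evaluate the published coefficient fit from scratch and compare
        # to 4 significant figures at 20 degC, S = 0
        (a1, a2, a3), (b1, b2, b3) = coeffs
        t = (20.0 + 273.15) / 100.0
        expected = np.exp(a1 + a2 / t + a3 * np.log(t) + 0.0 * (b1 + b2 * t + b3 * t * t))
        if bunsen:
            expected /= 22.414
        assert equilibrium_solubility(gas, 20.0, 0.0) == pytest.approx(
            expected, rel=1e-4
        )

    def test_unsupported_gas(self):
        with pytest.raises(DomainError):
            equilibrium_solubility("O2", 20, 0)

    def test_out_of_range_warns(self):
        with pytest.warns(UserWarning):
            equilibrium_solubility("CO2", 50, 0)


def sample(ppm, gas="CH4", temp=10.0, sal=1.0, vial=20.0, hs=5.0, p=0.64):
    return GasSample(gas, ppm, vial, hs, temp, sal, p)


class TestHeadspace:
    def test_zero_headspace_means_zero_dissolved(self):
        assert headspace_to_dissolved(sample(0.0)).concentration == 0.0

    def test_linearity_in_measured_mole_fraction(self):
        c1 = headspace_to_dissolved(sample(100.0)).concentration_mol_l
        c2 = headspace_to_dissolved(sample(200.0)).concentration_mol_l
        assert c2 == pytest.approx(2 * c1, rel=1e-12)

    @pytest.mark.parametrize("gas", GASES)
    @pytest.mark.parametrize("temp", [0.0, 10.0, 20.0, 30.0])
    def test_round_trip_is_identity(self, gas, temp):
        c0 = 50e-9 if gas != "CO2" else 20e-6
        ppm = partition_to_headspace(c0, gas, temp, 5.0, 20.0, 5.0, 0.64)
        s = sample(ppm, gas=gas, temp=temp, sal=5.0)
        assert headspace_to_dissolved(s).concentration_mol_l == pytest.approx(
            c0, rel=1e-9
        )

    @given(
        c0=st.floats(1e-10, 1e-4),
        temp=st.floats(0.0, 35.0),
        sal=st.floats(0.0, 40.0),
        hs_frac=st.floats(0.05, 0.95),
    )
    @settings(deadline=None, derandomize=True, max_examples=100)
    def test_round_trip_property(self, c0, temp, sal, hs_frac):
        vial = 20.0
        ppm = partition_to_headspace(c0, "N2O", temp, sal, vial, vial * hs_frac, 0.64)
        s = GasSample("N2O", ppm, vial, vial * hs_frac, temp, sal, 0.64)
        assert headspace_to_dissolved(s).concentration_mol_l == pytest.approx(
            c0, rel=1e-6
        )

    def test_volume_invariant_enforced(self):
        with pytest.raises(ValidationError):
            GasSample("CH4", 10, 20, 25, 10, 1)


class TestSaturation:
    def test_equilibrium_and_double(self):
        # use the function's own equilibrium concentration so 100% is exact
        _, c_eq, _ = saturation_percent(1e-9, "CH4", 10, 1, 1.9, 0.64)
        pct, _, status = saturation_percent(c_eq, "CH4", 10, 1, 1.9, 0.64)
        assert pct == pytest.approx(100.0)
        assert status == "equilibrium"
        pct2, _, status2 = saturation_percent(2 * c_eq, "CH4", 10, 1, 1.9, 0.64)
        assert pct2 == pytest.approx(200.0)
        assert status2 == "supersaturated"

    def test_scale_invariance(self):
        pct1, _, _ = saturation_percent(5e-9, "N2O", 10, 1, 0.335, 0.64)
        pct2, _, _ = saturation_percent(5e-9 * 3, "N2O", 10, 1, 0.335 * 3, 0.64)
        assert pct1 == pytest.approx(pct2, rel=1e-12)

    def test_vial_result_carries_status(self):
        ppm = partition_to_headspace(163.1e-9, "CH4", 10, 1, 20, 5, 0.64)
        r = dissolved_gas_result(sample(ppm))
        assert r.status == "supersaturated"
        assert r.unit == "nM"
        assert r.concentration == pytest.approx(163.1, rel=1e-6)


def series(y, t=None, gas="CH4", vol=20.0, area=0.25, temp=15.0, p=0.65):
    t = np.array([0, 20, 40, 60, 80.0]) if t is None else np.asarray(t, float)
    return ChamberSeries(gas, t, np.asarray(y, float), vol, area, temp, p)


class TestChamberFlux:
    def test_exact_linear_series_matches_closed_form(self):
        t = np.array([0, 20, 40, 60, 80.0])
        est = chamber_flux(series(1.9 + 1.0 * t, t))
        # hand conversion: slope[ppm/min] * 1e-6 * P/(R T) * V/A * 60 * 1e6
        expected = 1.0 * 1e-6 * 0.65 / (R_L_ATM * (273.15 + 15)) * 20 / 0.25 * 60 * 1e6
        assert est.flux == pytest.approx(expected, rel=1e-9)
        assert est.classification == "accumulation"
        assert est.r_squared == pytest.approx(1.0)

    def test_constant_series_is_no_trend(self):
        est = chamber_flux(series(np.full(5, 1.9)))
        assert est.flux == 0.0
        assert est.classification == "no-trend"

    def test_odd_symmetry(self):
        t = np.array([0, 20, 40, 60, 80.0])
        y = 400 + 0.3 * t + np.sin(t / 7)  # deterministic wiggle
        up = chamber_flux(series(y, t))
        down = chamber_flux(series(-y, t))
        assert down.flux == pytest.approx(-up.flux, rel=1e-12)

    def test_noisy_ensemble_recovers_true_slope(self):
        t = np.array([0, 20, 40, 60, 80.0])
        truth = chamber_flux(series(1.9 + 0.006 * t, t)).flux
        rng = np.random.default_rng(11)
        fluxes = np.array(
            [
                chamber_flux(series(1.9 + 0.006 * t + rng.normal(0, 0.01, 5), t)).flux
                for _ in range(500)
            ]
        )
        se = fluxes.std(ddof=1) / np.sqrt(fluxes.size)
        assert abs(fluxes.mean() - truth) < 2 * se

    def test_too_few_points_and_duplicate_times_rejected(self):
        with pytest.raises(ValidationError):
            series([1, 2], t=[0, 20])
        with pytest.raises(ValidationError):
            series([1, 2, 3], t=[0, 20, 20])
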