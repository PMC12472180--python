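import dataclasses

import numpy as np
import pandas as pd
import pytest

from dielpond import ValidationError, fit_kd, headspace_to_dissolved
from dielpond.gas import GasSample, chamber_flux
from dielpond.io import (
    validate_chamber,
    validate_gas_samples,
    validate_incubations,
    validate_pam,
    validate_profiles,
)
from dielpond.synth import (
    SyntheticTruth,
    gen_forcing,
    gen_gas_field,
    gen_incubation,
    gen_pam_trace,
    make_bundle,
)

from conftest import zero_noise_truth


class TestForcing:
    def test_default_peak_par_in_observed_range(self, default_bundle):
        assert 1000 <= default_bundle.forcing["par"].max() <= 1150

    def test_radiation_zero_at_night_and_boundaries(self):
        truth = zero_noise_truth()
        f = gen_forcing(truth)
        night = f[(f["time_h"] < 7.0) | (f["time_h"] > 19.0)]
        assert (night[["par", "uva", "uvb"]] == 0).all().all()
        at_sunrise = f.loc[(f["time_h"] - 7.0).abs().idxmin()]
        assert at_sunrise["par"] == pytest.approx(0.0, abs=1e-9)

    def test_noiseless_peaks_hit_configured_values(self):
        f = gen_forcing(zero_noise_truth())
        assert f["uvb"].max() == pytest.approx(58.0)
        assert f["uva"].max() == pytest.approx(165.0)
        assert f["par"].max() == pytest.approx(1100.0)

    def test_temperature_and_wind_ranges(self):
        f = gen_forcing(zero_noise_truth())
        assert f["air_temp_c"].min() == pytest.approx(-5.0, abs=0.1)
        assert f["air_temp_c"].max() == pytest.approx(18.0, abs=0.1)
        assert f["wind_ms"].iloc[0] == pytest.approx(1.0)
        assert f["wind_ms"].iloc[-1] == pytest.approx(6.0)

    def test_invalid_time_bounds_rejected(self):
        truth = SyntheticTruth(seed=0)
        bad = dataclasses.replace(
            truth, forcing=dataclasses.replace(truth.forcing, sunrise_h=20, sunset_h=6)
        )
        with pytest.raises(ValidationError):
            gen_forcing(bad)


class TestPamTrace:
    def test_zero_coupling_zero_noise_is_flat(self):
        truth = zero_noise_truth()
        truth = dataclasses.replace(
            truth, photo=dataclasses.replace(truth.photo, coupling=0.0)
        )
        trace = gen_pam_trace(truth, gen_forcing(truth))
        y = (trace["fm_prime"] - trace["f"]) / trace["fm_prime"]
        assert np.allclose(y, truth.photo.yield_baseline)

    def test_min_yield_at_max_par_for_zero_noise(self):
        truth = zero_noise_truth()
        trace = gen_pam_trace(truth, gen_forcing(truth))
        y = (trace["fm_prime"] - trace["f"]) / trace["fm_prime"]
        assert int(np.argmin(y.values)) == int(np.argmax(trace["e_par"].values))

    def test_bad_depression_rejected(self):
        truth = SyntheticTruth(seed=0)
        bad = dataclasses.replace(
            truth, photo=dataclasses.replace(truth.photo, midday_depression=1.2)
        )
        with pytest.raises(Exception):
            gen_pam_trace(bad, gen_forcing(truth))


class TestGasField:
    def test_zero_noise_round_trip_recovers_dissolved_field(self):
        truth = zero_noise_truth()
        vials, _, gas_truth = gen_gas_field(truth)
        truth_lookup = {
            (row["gas"], row["time_h"]): row["dissolved_mol_l"]
            for _, row in gas_truth.iterrows()
        }
        for _, row in vials.iterrows():
            s = GasSample(
                row["gas"], row["headspace_ppm"], row["vial_volume_ml"],
                row["headspace_volume_ml"], row["temp_c"], row["salinity"],
                row["pressure_atm"],
            )
            c = headspace_to_dissolved(s).concentration_mol_l
            h, m = row["timestamp"].split(":")
            key = (row["gas"], float(h) + float(m) / 60.0)
            assert c == pytest.approx(truth_lookup[key], rel=1e-6)

    def test_zero_slope_chamber_is_no_trend(self):
        truth = zero_noise_truth()
        _, chambers, _ = gen_gas_field(truth)
        assert chamber_flux(chambers["N2O"]).classification == "no-trend"

    def test_negative_mean_rejected(self):
        truth = SyntheticTruth(seed=0)
        bad = dataclasses.replace(
            truth,
            gas=dataclasses.replace(truth.gas, mean_mol_l={"CO2": -1e-6}),
        )
        with pytest.raises(Exception):
            gen_gas_field(bad)


class TestIncubation:
    def test_zero_rates_zero_noise_endpoints_equal_initial(self):
        truth = zero_noise_truth()
        inc = dataclasses.replace(
            truth.incubation,
            morning=dataclasses.replace(
                truth.incubation.morning, control_rate=0, r_aob=0, r_aoa=0, r_other=0
            ),
        )
        exp = gen_incubation(dataclasses.replace(truth, incubation=inc), "morning")
        for reps in exp.treatments.values():
            for i0, f1 in reps:
                assert f1 == pytest.approx(i0)

    def test_morning_rates_positive_and_above_afternoon(self):
        truth = zero_noise_truth()
        m = gen_incubation(truth, "morning")
        a = gen_incubation(truth, "afternoon")
        for label in m.treatments:
            rm = np.mean([(f - i) / m.duration_h for i, f in m.treatments[label]])
            ra = np.mean([(f - i) / a.duration_h for i, f in a.treatments[label]])
            assert rm > 0
            assert rm > ra

    def test_invalid_session_rejected(self):
        with pytest.raises(ValidationError):
            gen_incubation(SyntheticTruth(seed=0), "midnight")

    def test_efficacy_out_of_range_rejected(self):
        truth = SyntheticTruth(seed=0)
        bad = dataclasses.replace(
            truth, incubation=dataclasses.replace(truth.incubation, e_azide=1.5)
        )
        with pytest.raises(ValidationError):
            gen_incubation(bad, "morning")

    def test_partial_atu_cross_inhibition_shrinks_aoa_signal(self):
        from dielpond import partition_nitrification, treatment_rates

        truth = zero_noise_truth()
        leaky = dataclasses.replace(
            truth, incubation=dataclasses.replace(truth.incubation, e_atu_aoa=0.3)
        )
        p = partition_nitrification(
            treatment_rates(gen_incubation(leaky, "morning"))
        )
        assert p.r_aoa == pytest.approx(0.7 * truth.incubation.morning.r_aoa)


class TestBundle:
    def test_same_seed_bit_identical(self):
        b1, b2 = make_bundle(seed=33), make_bundle(seed=33)
        pd.testing.assert_frame_equal(b1.forcing, b2.forcing)
        pd.testing.assert_frame_equal(b1.pam, b2.pam)
        pd.testing.assert_frame_equal(b1.vials, b2.vials)
        for gas in b1.chambers:
            np.testing.assert_array_equal(
                b1.chambers[gas].mole_fraction_ppm, b2.chambers[gas].mole_fraction_ppm
            )
        assert b1.incubations["morning"].treatments == b2.incubations["morning"].treatments

    def test_different_seeds_differ(self):
        b1, b2 = make_bundle(seed=1), make_bundle(seed=2)
        assert not b1.pam["f"].equals(b2.pam["f"])

    def test_written_tables_pass_validators_with_zero_flags(self, tmp_path):
        make_bundle(seed=0, truth=zero_noise_truth()).write(tmp_path)
        assert validate_profiles(pd.read_csv(tmp_path / "profiles.csv")) == []
        assert validate_pam(pd.read_csv(tmp_path / "pam.csv")) == []
        assert validate_gas_samples(pd.read_csv(tmp_path / "gas_vials.csv")) == []
        assert validate_chamber(pd.read_csv(tmp_path / "chamber.csv")) == []
        assert validate_incubations(pd.read_csv(tmp_path / "incubations.csv")) == []

    def test_profiles_encode_true_kd(self, quiet_bundle):
        for p in quiet_bundle.profiles:
            assert fit_kd(p).kd == pytest.approx(quiet_bundle.truth.kd_true, abs=1e-9)
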