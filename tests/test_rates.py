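import dataclasses

import numpy as np
import pytest

from dielpond import (
    DomainError,
    IncubationExperiment,
    MissingTreatmentError,
    ValidationError,
    endpoint_rate,
    partition_nitrification,
    session_contrast,
    treatment_rates,
)
from dielpond.rates import CONTROL, TreatmentRate, TreatmentRates
from dielpond.synth import SyntheticTruth, gen_incubation

from conftest import zero_noise_truth


class TestEndpointRate:
    @pytest.mark.parametrize(
        "i,f,d,expected", [(1.0, 2.0, 5, 0.2), (1.5, 1.5, 6, 0.0), (2.0, 1.0, 5, -0.2)]
    )
    def test_arithmetic(self, i, f, d, expected):
        assert endpoint_rate(i, f, d) == pytest.approx(expected)

    def test_antisymmetric_under_endpoint_swap(self):
        assert endpoint_rate(0.3, 1.1, 5.5) == pytest.approx(
            -endpoint_rate(1.1, 0.3, 5.5)
        )

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(DomainError):
            endpoint_rate(1, 2, 0)


def experiment(treatments, duration=5.0, session="morning"):
    return IncubationExperiment(session, "nitrite", duration, treatments)


class TestTreatmentRates:
    def test_identical_duplicates_have_zero_spread(self):
        tr = treatment_rates(experiment({CONTROL: [(1.0, 2.0), (1.0, 2.0)]}))
        assert tr.rates[CONTROL].rate == pytest.approx(0.2)
        assert tr.rates[CONTROL].spread == 0.0
        assert tr.rates[CONTROL].spread_kind == "half-range"

    def test_duplicate_half_range(self):
        tr = treatment_rates(experiment({CONTROL: [(0.0, 1.0), (0.0, 2.0)]}))
        assert tr.rates[CONTROL].rate == pytest.approx(0.3)
        assert tr.rates[CONTROL].spread == pytest.approx(0.1)

    def test_triplicates_use_sd(self):
        tr = treatment_rates(experiment({CONTROL: [(0, 1.0), (0, 1.5), (0, 2.0)]}))
        assert tr.rates[CONTROL].spread_kind == "sd"
        assert tr.rates[CONTROL].spread == pytest.approx(np.std([0.2, 0.3, 0.4], ddof=1))

    def test_missing_control_rejected(self):
        with pytest.raises(ValidationError):
            experiment({"AZIDE": [(0.0, 1.0)]})

    def test_simulation_recovery_within_replicate_error(self):
        truth = SyntheticTruth(seed=42)
        exp = gen_incubation(truth, "morning")
        tr = treatment_rates(exp)
        inc = truth.incubation
        sigma_rate = inc.noise_sigma_um / inc.duration_h
        expected_control = inc.morning.control_rate
        assert abs(tr.rates[CONTROL].rate - expected_control) < 3 * sigma_rate / np.sqrt(
            inc.n_replicates
        )


def rates_from(values, spread=0.0, n=2):
    return TreatmentRates(
        "morning",
        "nitrite",
        5.0,
        {k: TreatmentRate(v, spread, n, "half-range") for k, v in values.items()},
    )


class TestPartition:
    def test_null_case_all_equal_to_control(self):
        tr = rates_from({CONTROL: 0.1, "AZIDE": 0.1, "AZIDE_GC7": 0.1, "AZIDE_ATU": 0.1})
        p = partition_nitrification(tr)
        assert (p.r_aob, p.r_aoa, p.r_other) == (0.0, 0.0, 0.0)

    def test_worked_difference_example(self):
        tr = rates_from(
            {CONTROL: 0.1, "AZIDE_GC7": 0.5, "AZIDE_ATU": 0.3, "AZIDE": 0.05}
        )
        p = partition_nitrification(tr)
        assert p.r_aob == pytest.approx(0.4)
        assert p.r_aoa == pytest.approx(0.2)
        assert p.r_other == pytest.approx(-0.05)

    def test_linearity_under_common_scaling(self):
        base = {CONTROL: 0.1, "AZIDE_GC7": 0.5, "AZIDE_ATU": 0.3, "AZIDE": 0.05}
        p1 = partition_nitrification(rates_from(base))
        p3 = partition_nitrification(rates_from({k: 3 * v for k, v in base.items()}))
        for comp in ("r_aob", "r_aoa", "r_other"):
            assert getattr(p3, comp) == pytest.approx(3 * getattr(p1, comp))

    def test_missing_treatment_error_names_label(self):
        tr = rates_from({CONTROL: 0.1, "AZIDE": 0.05, "AZIDE_GC7": 0.5})
        with pytest.raises(MissingTreatmentError, match="AZIDE_ATU"):
            partition_nitrification(tr)

    def test_quadrature_uncertainty(self):
        tr = rates_from(
            {CONTROL: 0.1, "AZIDE_GC7": 0.5, "AZIDE_ATU": 0.3, "AZIDE": 0.05},
            spread=0.03,
        )
        p = partition_nitrification(tr)
        assert p.se["r_aob"] == pytest.approx(np.hypot(0.03, 0.03))
        assert p.u95["r_aob"] > p.se["r_aob"]  # expanded > 1 SE always

    def test_ideal_zero_noise_round_trip_is_exact(self):
        truth = zero_noise_truth()
        for session in ("morning", "afternoon"):
            exp = gen_incubation(truth, session)
            p = partition_nitrification(treatment_rates(exp))
            st = getattr(truth.incubation, session)
            assert p.r_aob == pytest.approx(st.r_aob, abs=1e-12)
            assert p.r_aoa == pytest.approx(st.r_aoa, abs=1e-12)
            assert p.r_other == pytest.approx(st.r_other, abs=1e-12)

    @pytest.mark.parametrize("n_reps", [2, 10, 50])
    def test_bias_shrinks_with_replication(self, n_reps):
        truth = SyntheticTruth(seed=0)
        truth = dataclasses.replace(
            truth, incubation=dataclasses.replace(truth.incubation, n_replicates=n_reps)
        )
        errs = []
        for i in range(200):
            t = dataclasses.replace(truth, seed=5000 + i)
            p = partition_nitrification(treatment_rates(gen_incubation(t, "morning")))
            errs.append(p.r_aob - truth.incubation.morning.r_aob)
        errs = np.array(errs)
        # unbiased at every n; the Monte-Carlo bound tightens as n grows
        sigma_rate = truth.incubation.noise_sigma_um / truth.incubation.duration_h
        se_mean = sigma_rate * np.sqrt(2.0 / n_reps) / np.sqrt(len(errs))
        assert abs(errs.mean()) < 3 * se_mean


class TestSessionContrast:
    def test_morning_minus_afternoon(self):
        truth = zero_noise_truth()
        pm = partition_nitrification(treatment_rates(gen_incubation(truth, "morning")))
        pa = partition_nitrification(treatment_rates(gen_incubation(truth, "afternoon")))
        table = session_contrast(pm, pa).set_index("quantity")
        m, a = truth.incubation.morning, truth.incubation.afternoon
        assert table.loc["r_aoa", "difference"] == pytest.approx(m.r_aoa - a.r_aoa)
        assert bool(table.loc["r_aob", "morning_higher"])
        assert bool(table.loc["r_aoa", "morning_higher"])

    def test_identical_sessions_all_zero(self):
        truth = zero_noise_truth()
        p = partition_nitrification(treatment_rates(gen_incubation(truth, "morning")))
        table = session_contrast(p, p)
        assert (table["difference"] == 0).all()

    def test_absent_session_rejected(self):
        truth = zero_noise_truth()
        p = partition_nitrification(treatment_rates(gen_incubation(truth, "morning")))
        with pytest.raises(ValidationError):
            session_contrast(p, None)

    def test_contrast_detected_in_most_seeded_simulations(self):
        truth = SyntheticTruth(seed=0)
        detected = 0
        n = 200
        for i in range(n):
            t = dataclasses.replace(truth, seed=20_000 + i)
            pm = partition_nitrification(treatment_rates(gen_incubation(t, "morning")))
            pa = partition_nitrification(treatment_rates(gen_incubation(t, "afternoon")))
            tab = session_contrast(pm, pa)
            detected += bool(
                tab.set_index("quantity").loc[["r_aob", "r_aoa"], "morning_higher"].all()
            )
        assert detected / n >= 0.95
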