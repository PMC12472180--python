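import dataclasses

import pytest

from dielpond.synth import (
    ForcingTruth,
    GasTruth,
    IncubationTruth,
    PhotoTruth,
    SyntheticTruth,
    make_bundle,
)


def zero_noise_truth(seed: int = 0) -> SyntheticTruth:
    """A truth object with every stochastic term switched off."""
    base = SyntheticTruth(seed=seed)
    return dataclasses.replace(
        base,
        profile_noise_sigma=0.0,
        forcing=dataclasses.replace(base.forcing, noise_sigma=0.0),
        photo=dataclasses.replace(base.photo, noise_sigma=0.0),
        gas=dataclasses.replace(
            base.gas,
            noise_rel=0.0,
            chamber_noise_ppm={"CO2": 0.0, "CH4": 0.0, "N2O": 0.0},
        ),
        incubation=dataclasses.replace(base.incubation, noise_sigma_um=0.0),
    )


@pytest.fixture(scope="session")
def default_bundle():
    return make_bundle(seed=0)


@pytest.fixture(scope="session")
def quiet_bundle():
    """Bundle generated with all noise terms at zero."""
    return make_bundle(seed=0, truth=zero_noise_truth())
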