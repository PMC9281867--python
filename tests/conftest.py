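import numpy as np
import pytest

from thrombosim import (
    DonorConcentrationProfile,
    ModelConfig,
    panel_to_profile,
    profile_to_panel,
)

#: Reference-plasma initial conditions (100 % of every factor, 5 pM TF).
REFERENCE_CONCENTRATIONS = dict(
    TF=5e-12,
    FII=1.4e-6,
    FV=2.0e-8,
    FVII=1.0e-8,
    FVIIa=1.0e-10,
    FVIII=7.0e-10,
    FIX=9.0e-8,
    FX=1.6e-7,
    TFPI=2.5e-9,
    AT=3.4e-6,
)


@pytest.fixture(scope="session")
def model() -> ModelConfig:
    return ModelConfig.default()


@pytest.fixture(scope="session")
def reference_profile() -> DonorConcentrationProfile:
    return DonorConcentrationProfile(dict(REFERENCE_CONCENTRATIONS))


@pytest.fixture(scope="session")
def reference_panel(model, reference_profile):
    return profile_to_panel(reference_profile, model.reference, donor_id="ref")


def random_profile(rng: np.random.Generator, model: ModelConfig):
    """A physiologically-spread random donor: each factor at 50-150 % of
    reference, TF uniform on 1-20 pM."""
    ref = REFERENCE_CONCENTRATIONS
    conc = {k: v * rng.uniform(0.5, 1.5) for k, v in ref.items() if k not in ("TF", "FVIIa")}
    conc["TF"] = rng.uniform(1e-12, 2e-11)
    conc["FVIIa"] = model.reference.fviia_fraction * conc["FVII"]
    return DonorConcentrationProfile(conc)


@pytest.fixture(scope="session")
def random_profiles(model):
    rng = np.random.default_rng(20210)
    return [random_profile(rng, model) for _ in range(50)]
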