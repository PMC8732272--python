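import datetime as dt

import pytest

from tracerlake.data_model import (
    Basis,
    CompartmentSample,
    Compartment,
    Dataset,
    FishObservation,
    IsotopeChannel,
    Species,
    StudyCalendar,
    Units,
)
from tracerlake.synthetic_ecosystem import default_config, simulate


@pytest.fixture(scope="session")
def calendar():
    return StudyCalendar()


@pytest.fixture(scope="session")
def sim_result():
    """One default simulation shared across the session (seed 1)."""
    return simulate(default_config(), seed=1)


@pytest.fixture(scope="session")
def noiseless_sim():
    return simulate(default_config(obs_noise_cv=0.0), seed=1)


def make_sample(
    value: float,
    month: int = 6,
    year: int = 2005,
    compartment: Compartment = Compartment.ZOOPLANKTON,
    channel: IsotopeChannel = IsotopeChannel.AMBIENT,
    basis: Basis = Basis.WET,
    **extra,
) -> CompartmentSample:
    units = Units.NG_PER_L if compartment is Compartment.WATER else Units.NG_PER_G
    if compartment is Compartment.SEDIMENT:
        basis = Basis.DRY
    conc = {channel: value}
    conc.update(extra.pop("conc", {}))
    return CompartmentSample(
        compartment=compartment,
        date=dt.date(year, month, 15),
        conc=conc,
        basis=basis,
        units=units,
        **extra,
    )


def make_fish(
    species: Species = Species.NORTHERN_PIKE,
    year: int = 2007,
    fl: float = 450.0,
    mass: float = 500.0,
    dwp: float = 0.2,
    conc_dw: dict | None = None,
    **extra,
) -> FishObservation:
    return FishObservation(
        species=species,
        date=dt.date(year, 9, 15),
        fork_length_mm=fl,
        mass_g=mass,
        dw_proportion=dwp,
        conc_dw=conc_dw or {IsotopeChannel.AMBIENT: 100.0, IsotopeChannel.LAKE_SPIKE: 50.0},
        **extra,
    )


@pytest.fixture
def tiny_dataset():
    samples = [
        make_sample(1.0, month=5, compartment=Compartment.WATER),
        make_sample(2.5, month=8, compartment=Compartment.SEDIMENT, basis=Basis.DRY),
        make_sample(4.0, month=6),
    ]
    fish = [make_fish(), make_fish(species=Species.YELLOW_PERCH, fl=120.0, mass=30.0)]
    return Dataset(samples=samples, fish=fish)
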