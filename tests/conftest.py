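import numpy as np
import pytest

from phenoranges.records import (
    DispersionKind,
    MeasurementRecord,
    Sex,
    StrainClass,
)


def _record(i: int, **overrides) -> MeasurementRecord:
    base = dict(
        record_id=f"r{i:03d}",
        study_id=f"study{i:03d}",
        phenotype="systolic blood pressure",
        strain="BN",
        strain_class=StrainClass.inbred,
        sex=Sex.male,
        age_low_days=80,
        age_high_days=90,
        method="tail cuff",
        condition="naive control",
        n_animals=10,
        mean_value=120.0 + i,
        dispersion_value=8.0,
        dispersion_kind=DispersionKind.SD,
        units="mmHg",
    )
    base.update(overrides)
    return MeasurementRecord(**base)


@pytest.fixture
def record_factory():
    return _record


@pytest.fixture
def six_records(record_factory):
    """2 strains x male/female, 6 records, one stratum axis configuration."""
    return [
        record_factory(0, strain="BN", sex=Sex.male),
        record_factory(1, strain="BN", sex=Sex.male),
        record_factory(2, strain="BN", sex=Sex.female),
        record_factory(3, strain="SHR", sex=Sex.male),
        record_factory(4, strain="SHR", sex=Sex.female),
        record_factory(5, strain="SHR", sex=Sex.female),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
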