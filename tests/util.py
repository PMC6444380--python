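"""Shared test helpers."""

from __future__ import annotations

import numpy as np

from phenoranges.stratify import MetaInput, StratumKey


def make_input(
    y,
    var,
    n=None,
    sd_animals=None,
    key: StratumKey | None = None,
    study_ids=None,
) -> MetaInput:
    """Build a MetaInput directly from study-level vectors."""
    y = np.asarray(y, dtype=float)
    var = np.asarray(var, dtype=float)
    k = len(y)
    if n is None:
        n = np.full(k, 10)
    if sd_animals is None:
        sd_animals = np.sqrt(var * np.asarray(n))
    if study_ids is None:
        study_ids = tuple(f"s{i}" for i in range(k))
    return MetaInput(
        key=key or StratumKey("phenotype", "STRAIN"),
        study_ids=tuple(study_ids),
        record_ids=tuple(f"r{i}" for i in range(k)),
        y=y,
        var=var,
        n=np.asarray(n, dtype=int),
        sd_animals=np.asarray(sd_animals, dtype=float),
        units="mmHg",
    )


def random_input(rng: np.random.Generator, k: int | None = None) -> MetaInput:
    """A random stratum with k in 2..12 and positive variances."""
    if k is None:
        k = int(rng.integers(2, 13))
    y = rng.normal(50, 20, size=k)
    var = rng.uniform(0.1, 9.0, size=k)
    return make_input(y, var)
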