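"""Synthetic study-level phenotype panels with known ground truth.

The generator follows the additive two-level model behind the pipeline: for
each stratum with true mean ``mu``, between-study SD ``tau`` and animal-level
SD ``sigma``, study i of size ``n_i`` observes

    theta_i ~ Normal(mu, tau^2)          (study-level true value)
    y_i     ~ Normal(theta_i, sigma^2/n_i)  (reported study mean)

Records report the animal-level SD as the true ``sigma`` by default, so
within-study variances are exact and estimator checks are sharp; a
sampled-SD mode draws the SD from its chi-square sampling distribution for
realism.  One-sided small-study censoring emulates publication bias
(suppressing unimpressive small studies) and outlier injection shifts chosen
study means by a multiple of sigma.  Everything is reproducible from a seed,
and a truth table joins 1:1 to the emitted records by record id.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, model_validator

from .errors import PhenorangesError
from .records import (
    DispersionKind,
    MeasurementRecord,
    Sex,
    StrainClass,
    stable_record_id,
)

TRUTH_COLUMNS = ["record_id", "strain", "theta", "censored", "outlier"]


class SimScenario(BaseModel):
    """Ground truth for one simulated stratum (strain x sex x age bin)."""

    model_config = ConfigDict(frozen=True)

    strain: str
    phenotype: str = "systolic blood pressure"
    sex: Sex = Sex.male
    age_low_days: int = 70
    age_high_days: int = 99
    method: str = "tail cuff"
    condition: str = "naive control"
    units: str = "mmHg"
    strain_class: StrainClass = StrainClass.inbred
    parent_strain: Optional[str] = None
    mu: float
    tau: float = 0.0
    sigma: float = 1.0
    k: int = 6
    n_low: int = 5
    n_high: int = 30
    sampled_sd: bool = False

    @model_validator(mode="after")
    def _check(self) -> "SimScenario":
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not (1 <= self.n_low <= self.n_high):
            raise ValueError("need 1 <= n_low <= n_high")
        return self


@dataclass(frozen=True)
class CensorRule:
    """One-sided small-study suppression.

    Studies on ``side`` of the value threshold (given directly or as a
    quantile of the panel's values) are dropped, but only among studies with
    ``n_animals <= max_n`` (``None`` = all studies are censorable).
    """

    side: str = "low"  # "low" | "high"
    threshold: Optional[float] = None
    quantile: Optional[float] = None
    max_n: Optional[int] = None

    def __post_init__(self) -> None:
        if self.side not in ("low", "high"):
            raise PhenorangesError("censor side must be 'low' or 'high'")
        if (self.threshold is None) == (self.quantile is None):
            raise PhenorangesError("give exactly one of threshold / quantile")


def simulate_stratum(
    scenario: SimScenario, seed: int | np.random.Generator
) -> tuple[list[MeasurementRecord], pd.DataFrame]:
    """Draw one stratum of study-level records plus its truth table."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sc = scenario
    n_i = rng.integers(sc.n_low, sc.n_high + 1, size=sc.k)
    theta = sc.mu + sc.tau * rng.standard_normal(sc.k)
    y = theta + sc.sigma / np.sqrt(n_i) * rng.standard_normal(sc.k)
    if sc.sampled_sd:
        dfree = np.maximum(n_i - 1, 1)
        sd = sc.sigma * np.sqrt(rng.chisquare(dfree) / dfree)
    else:
        sd = np.full(sc.k, sc.sigma)
    records: list[MeasurementRecord] = []
    truth_rows = []
    tag = (sc.strain, sc.sex.value, sc.age_low_days, sc.age_high_days, sc.phenotype)
    seed_tag = str(rng.bit_generator.seed_seq)
    for i in range(sc.k):
        rid = stable_record_id(*tag, i, seed_tag)
        records.append(
            MeasurementRecord(
                record_id=rid,
                study_id=f"{sc.strain}-{sc.sex.value}-study{i:03d}",
                phenotype=sc.phenotype,
                strain=sc.strain,
                parent_strain=sc.parent_strain,
                strain_class=sc.strain_class,
                sex=sc.sex,
                age_low_days=sc.age_low_days,
                age_high_days=sc.age_high_days,
                method=sc.method,
                condition=sc.condition,
                n_animals=int(n_i[i]),
                mean_value=float(y[i]),
                dispersion_value=float(sd[i]),
                dispersion_kind=DispersionKind.SD,
                units=sc.units,
            )
        )
        truth_rows.append(
            {
                "record_id": rid,
                "strain": sc.strain,
                "theta": float(theta[i]),
                "censored": False,
                "outlier": False,
            }
        )
    return records, pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)


def apply_censoring(
    records: Sequence[MeasurementRecord],
    truth: pd.DataFrame,
    rule: CensorRule,
) -> tuple[list[MeasurementRecord], pd.DataFrame]:
    """Drop records per the censor rule; surviving records are untouched.

    The truth table keeps every row, with ``censored`` marking the dropped
    records.  Raises if the rule would remove every record.
    """
    values = np.array([r.mean_value for r in records])
    if rule.threshold is not None:
        thr = rule.threshold
    else:
        thr = float(np.quantile(values, rule.quantile))
    survivors: list[MeasurementRecord] = []
    censored_ids: set[str] = set()
    for r in records:
        small = rule.max_n is None or r.n_animals <= rule.max_n
        suppressed = small and (
            r.mean_value < thr if rule.side == "low" else r.mean_value > thr
        )
        if suppressed:
            censored_ids.add(r.record_id)
        else:
            survivors.append(r)
    if not survivors:
        raise PhenorangesError("censor rule removed every record")
    truth = truth.copy()
    truth["censored"] = truth["censored"] | truth["record_id"].isin(censored_ids)
    return survivors, truth


def inject_outlier(
    records: Sequence[MeasurementRecord],
    truth: pd.DataFrame,
    count: int,
    offset_sigmas: float,
    seed: int | np.random.Generator = 0,
) -> tuple[list[MeasurementRecord], pd.DataFrame]:
    """Shift ``count`` randomly chosen study means by ``offset_sigmas`` times
    the record's animal-level SD; the truth table marks the shifted studies."""
    if count > len(records):
        raise PhenorangesError(f"cannot inject {count} outliers into {len(records)} records")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chosen = set(rng.choice(len(records), size=count, replace=False).tolist())
    out: list[MeasurementRecord] = []
    shifted_ids: set[str] = set()
    for i, r in enumerate(records):
        if i in chosen and offset_sigmas != 0:
            sigma = r.dispersion_value if r.dispersion_kind is DispersionKind.SD else (
                r.dispersion_value * math.sqrt(r.n_animals)
            )
            out.append(r.model_copy(update={"mean_value": r.mean_value + offset_sigmas * sigma}))
            shifted_ids.add(r.record_id)
        else:
            out.append(r)
            if i in chosen:  # offset 0: marked but unchanged
                shifted_ids.add(r.record_id)
    truth = truth.copy()
    truth["outlier"] = truth["outlier"] | truth["record_id"].isin(shifted_ids)
    return out, truth


def simulate_panel(
    scenarios: Sequence[SimScenario], seed: int
) -> tuple[list[MeasurementRecord], pd.DataFrame]:
    """Simulate a multi-stratum panel; each scenario gets an independent
    child stream of the seed so panels are reproducible."""
    if not scenarios:
        raise PhenorangesError("empty scenario list")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(scenarios))
    records: list[MeasurementRecord] = []
    truths: list[pd.DataFrame] = []
    for sc, child in zip(scenarios, children):
        recs, truth = simulate_stratum(sc, np.random.default_rng(child))
        records.extend(recs)
        truths.append(truth)
    return records, pd.concat(truths, ignore_index=True)


# ---------------------------------------------------------------------------
# Reference panel: normal vs hypertensive-like strains
# ---------------------------------------------------------------------------

#: Inbred strains commonly used as blood-pressure controls.
NORMAL_STRAINS = (
    "ACI", "BN", "BUF", "DA", "F344", "GK", "LE",
    "LEW", "LN", "M520", "MNS", "MR", "MWF", "WKY",
)
#: Hypertensive-like strains expected to fall outside the control range.
SHIFTED_STRAINS = ("GH", "LH", "MHS", "SHR", "SHRSP")
#: Long-established founder control strains for blood pressure.
DEFAULT_FOUNDERS = ("BN", "WKY")


@dataclass
class PanelSpec:
    scenarios: list[SimScenario]
    founders: tuple[str, ...]
    expected_labels: dict[str, str]  # strain -> "normal" | "abnormal"


def default_panel(
    tau: float = 4.0,
    sigma: float = 9.0,
    k: int = 6,
    shift: Optional[float] = None,
    normal_strains: Sequence[str] = NORMAL_STRAINS,
    shifted_strains: Sequence[str] = SHIFTED_STRAINS,
) -> PanelSpec:
    """Systolic-blood-pressure-like panel: 14 normotensive strains spread
    around 120 mmHg plus 5 strains shifted upward by at least four total SDs,
    mirroring a normal-vs-hypertensive strain split.
    """
    total_sd = math.sqrt(tau * tau + sigma * sigma)
    if shift is None:
        shift = 4.5 * total_sd
    scenarios = []
    # Deterministic spread of normal means over ~[112, 130] mmHg so that all
    # normal ranges (+/- ~1 total SD) mutually overlap.
    high_normal = 130.0
    for i, strain in enumerate(normal_strains):
        mu = 112.0 + (high_normal - 112.0) * i / max(len(normal_strains) - 1, 1)
        scenarios.append(
            SimScenario(strain=strain, mu=mu, tau=tau, sigma=sigma, k=k)
        )
    # Shift is measured from the highest normal mean so every shifted strain
    # clears the whole normal band by at least the requested margin.
    base_high = high_normal + shift
    for j, strain in enumerate(shifted_strains):
        mu = base_high + 4.0 * j
        scenarios.append(
            SimScenario(strain=strain, mu=mu, tau=tau, sigma=sigma, k=k)
        )
    labels = {s: "normal" for s in normal_strains}
    labels.update({s: "abnormal" for s in shifted_strains})
    return PanelSpec(
        scenarios=scenarios,
        founders=DEFAULT_FOUNDERS,
        expected_labels=labels,
    )


def load_scenarios(path: str | Path) -> list[SimScenario]:
    """Read a scenario YAML file: a list of scenario mappings."""
    with Path(path).open() as fh:
        raw = yaml.safe_load(fh)
    if not raw:
        raise PhenorangesError(f"{path}: empty scenario file")
    return [SimScenario(**item) for item in raw]


def write_truth(truth: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    truth.to_csv(path, sep="\t", index=False)
    return path
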