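"""Partition harmonized records into meta-analysis strata.

A stratum is the unit of one meta-analysis: records sharing phenotype,
strain (or parent strain group), sex group, age bin, measurement method and
experimental condition.  Any of the sex/age/method/condition axes can instead
be pooled ("all"), which coarsens the partition; phenotype and strain are
always stratified.

Age is carried as a [low, high] day interval and binned by its midpoint.  The
default bins are age1 (<70 days), age2 (70-99) and age3 (100+), the young /
adult / old split used for cardiovascular phenotypes; body-weight-like
phenotypes may override the scheme (e.g. a 20-79 / 80-99 young-adult split).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, field_serializer, field_validator

from .errors import UnitMismatchError
from .records import MeasurementRecord, StrainClass, harmonize_dispersion


@dataclass(frozen=True)
class AgeBin:
    """Inclusive day interval; ``high=None`` means open-ended."""

    label: str
    low: int
    high: Optional[int] = None

    def contains(self, day: int) -> bool:
        return day >= self.low and (self.high is None or day <= self.high)


@dataclass(frozen=True)
class AgeBinScheme:
    bins: tuple[AgeBin, ...]

    def __post_init__(self) -> None:
        prev_high = -1
        for b in self.bins:
            if b.low <= prev_high:
                raise ValueError("age bins must be sorted and non-overlapping")
            if b.high is not None and b.high < b.low:
                raise ValueError(f"bin {b.label!r} has high < low")
            prev_high = b.high if b.high is not None else np.iinfo(np.int64).max

    def assign(self, day: int) -> Optional[str]:
        for b in self.bins:
            if b.contains(day):
                return b.label
        return None


DEFAULT_AGE_SCHEME = AgeBinScheme(
    (AgeBin("age1", 0, 69), AgeBin("age2", 70, 99), AgeBin("age3", 100, None))
)


def assign_age_bin(record: MeasurementRecord, scheme: AgeBinScheme = DEFAULT_AGE_SCHEME) -> Optional[str]:
    """Bin a record by its age-interval midpoint; ``None`` if outside all bins."""
    return scheme.assign(record.age_midpoint)


def _crosses_bin_edge(record: MeasurementRecord, scheme: AgeBinScheme) -> bool:
    return scheme.assign(record.age_low_days) != scheme.assign(record.age_high_days)


@dataclass(frozen=True, order=True)
class StratumKey:
    phenotype: str
    strain_or_group: str
    sex_group: str = "all"
    age_bin: str = "all"
    method: str = "all"
    condition: str = "all"

    def label(self) -> str:
        parts = [self.phenotype, self.strain_or_group, self.sex_group, self.age_bin]
        if self.method != "all":
            parts.append(self.method)
        if self.condition != "all":
            parts.append(self.condition)
        return " | ".join(parts)


@dataclass
class MetaInput:
    """A homogeneous stack of study-level observations feeding one meta-analysis.

    ``y`` are study means, ``var`` the variances of those means (s_i^2), ``n``
    the animals per study and ``sd_animals`` the animal-level SDs.
    """

    key: StratumKey
    study_ids: tuple[str, ...]
    record_ids: tuple[str, ...]
    y: np.ndarray
    var: np.ndarray
    n: np.ndarray
    sd_animals: np.ndarray
    units: str

    @property
    def k(self) -> int:
        return len(self.y)

    def drop(self, index: int) -> "MetaInput":
        """Copy with study ``index`` removed (leave-one-out helper)."""
        keep = [i for i in range(self.k) if i != index]
        return self.subset(keep)

    def subset(self, indices: Sequence[int]) -> "MetaInput":
        idx = list(indices)
        return MetaInput(
            key=self.key,
            study_ids=tuple(self.study_ids[i] for i in idx),
            record_ids=tuple(self.record_ids[i] for i in idx),
            y=self.y[idx].copy(),
            var=self.var[idx].copy(),
            n=self.n[idx].copy(),
            sd_animals=self.sd_animals[idx].copy(),
            units=self.units,
        )


def meta_input_from_records(
    key: StratumKey, records: Sequence[MeasurementRecord]
) -> MetaInput:
    units = {r.units_key for r in records}
    if len(units) > 1:
        raise UnitMismatchError(
            f"stratum '{key.label()}' mixes units: {sorted(units)}"
        )
    harm = [harmonize_dispersion(r) for r in records]
    return MetaInput(
        key=key,
        study_ids=tuple(r.study_id for r in records),
        record_ids=tuple(r.record_id for r in records),
        y=np.array([r.mean_value for r in records], dtype=float),
        var=np.array([h.var_of_mean for h in harm], dtype=float),
        n=np.array([r.n_animals for r in records], dtype=int),
        sd_animals=np.array([h.sd_animals for h in harm], dtype=float),
        units=records[0].units.strip(),
    )


class StratifyConfig(BaseModel):
    """Which axes to stratify vs pool, plus record filters."""

    model_config = ConfigDict(arbitrary_types_allowed=True)

    grouping: Literal["substrain", "parent"] = "substrain"
    stratify_sex: bool = True
    stratify_age: bool = True
    stratify_method: bool = False
    stratify_condition: bool = False
    age_scheme: AgeBinScheme = DEFAULT_AGE_SCHEME
    drop_cross_bin: bool = False
    condition_whitelist: Optional[list[str]] = None
    strain_class_whitelist: Optional[list[StrainClass]] = None

    @field_validator("age_scheme", mode="before")
    @classmethod
    def _coerce_scheme(cls, v):
        """Accept an AgeBinScheme or a YAML-style list of [label, low, high]."""
        if isinstance(v, AgeBinScheme):
            return v
        return AgeBinScheme(
            tuple(
                AgeBin(str(item[0]), int(item[1]), None if item[2] is None else int(item[2]))
                for item in v
            )
        )

    @field_serializer("age_scheme")
    def _dump_scheme(self, scheme: AgeBinScheme, _info):
        return [[b.label, b.low, b.high] for b in scheme.bins]


@dataclass
class StrataResult:
    strata: dict[StratumKey, MetaInput]
    skipped: list[tuple[str, str]] = field(default_factory=list)  # (record_id, reason)

    def __iter__(self):
        return iter(self.strata.items())


def build_strata(
    records: Iterable[MeasurementRecord], config: StratifyConfig = StratifyConfig()
) -> StrataResult:
    """Assign each filtered record to exactly one stratum.

    Records whose age midpoint falls outside the configured bins (or whose age
    interval crosses a bin edge, when ``drop_cross_bin``) are skipped with a
    reason rather than silently lost, so record counts are conserved.
    """
    groups: dict[StratumKey, list[MeasurementRecord]] = {}
    skipped: list[tuple[str, str]] = []
    for r in records:
        if config.condition_whitelist is not None and r.condition not in config.condition_whitelist:
            skipped.append((r.record_id, f"condition {r.condition!r} filtered"))
            continue
        if config.strain_class_whitelist is not None and r.strain_class not in config.strain_class_whitelist:
            skipped.append((r.record_id, f"strain_class {r.strain_class} filtered"))
            continue
        if config.grouping == "parent":
            strain = r.parent_strain or r.strain
        else:
            strain = r.strain
        age_bin = "all"
        if config.stratify_age:
            if config.drop_cross_bin and _crosses_bin_edge(r, config.age_scheme):
                skipped.append((r.record_id, "age interval crosses a bin edge"))
                continue
            label = assign_age_bin(r, config.age_scheme)
            if label is None:
                skipped.append((r.record_id, "age midpoint outside all bins"))
                continue
            age_bin = label
        key = StratumKey(
            phenotype=r.phenotype,
            strain_or_group=strain,
            sex_group=r.sex.value if config.stratify_sex else "all",
            age_bin=age_bin,
            method=r.method if config.stratify_method else "all",
            condition=r.condition if config.stratify_condition else "all",
        )
        groups.setdefault(key, []).append(r)
    strata = {key: meta_input_from_records(key, recs) for key, recs in groups.items()}
    return StrataResult(strata=strata, skipped=skipped)


def study_range(m: MetaInput) -> float:
    """Spread of study means: max(y_i) - min(y_i).

    With few experiments this range can be falsely small, masking
    heterogeneity — one motivation for the minimum-experiments rule.
    """
    return float(np.max(m.y) - np.min(m.y))


def stratum_manifest(result: StrataResult) -> pd.DataFrame:
    """Summary table of the built strata (one row per stratum)."""
    rows = []
    for key, m in sorted(result.strata.items()):
        rows.append(
            {
                "phenotype": key.phenotype,
                "strain_or_group": key.strain_or_group,
                "sex_group": key.sex_group,
                "age_bin": key.age_bin,
                "method": key.method,
                "condition": key.condition,
                "k": m.k,
                "total_animals": int(m.n.sum()),
                "units": m.units,
                "study_range": study_range(m),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "phenotype", "strain_or_group", "sex_group", "age_bin",
            "method", "condition", "k", "total_animals", "units", "study_range",
        ],
    )
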