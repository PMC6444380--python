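"""Reading, validating and harmonizing study-level phenotype measurement records.

A record is one measurement *group* from one experiment: a strain, sex and age
range, a measurement method and experimental condition, the number of animals,
the group mean and a dispersion given either as an animal-level standard
deviation (SD) or as a standard error of the mean (SEM).  Files are delimited
text (TSV/CSV) with a header; a configurable column map lets PhenoMiner-style
exports and synthetic fixtures share one parser.
"""

from __future__ import annotations

import csv
import hashlib
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from pydantic import BaseModel, ConfigDict, field_validator, model_validator

from .errors import NoRecordsError, SchemaError, StrainTableError


class Sex(str, Enum):
    male = "male"
    female = "female"
    both = "both"
    unspecified = "unspecified"


class StrainClass(str, Enum):
    inbred = "inbred"
    outbred = "outbred"
    congenic = "congenic"
    consomic = "consomic"
    mutant = "mutant"
    transgenic = "transgenic"


class DispersionKind(str, Enum):
    SD = "SD"
    SEM = "SEM"


class MeasurementRecord(BaseModel):
    """One study-level phenotype measurement group."""

    model_config = ConfigDict(frozen=True)

    record_id: str
    study_id: str
    phenotype: str
    strain: str
    parent_strain: Optional[str] = None
    strain_class: Optional[StrainClass] = None
    sex: Sex = Sex.unspecified
    age_low_days: int
    age_high_days: int
    method: str = "unspecified"
    condition: str = "unspecified"
    n_animals: int
    mean_value: float
    dispersion_value: float
    dispersion_kind: DispersionKind
    units: str

    @field_validator("n_animals")
    @classmethod
    def _positive_n(cls, v: int) -> int:
        if v < 1:
            raise ValueError("n_animals must be >= 1")
        return v

    @field_validator("dispersion_value")
    @classmethod
    def _nonneg_dispersion(cls, v: float) -> float:
        if v < 0:
            raise ValueError("dispersion_value must be >= 0")
        return v

    @field_validator("age_low_days", "age_high_days")
    @classmethod
    def _nonneg_age(cls, v: int) -> int:
        if v < 0:
            raise ValueError("age must be >= 0 days")
        return v

    @field_validator("units")
    @classmethod
    def _nonempty_units(cls, v: str) -> str:
        if not v.strip():
            raise ValueError("units must be non-empty")
        return v

    @model_validator(mode="after")
    def _age_order(self) -> "MeasurementRecord":
        if self.age_low_days > self.age_high_days:
            raise ValueError("age_low_days must be <= age_high_days")
        return self

    @property
    def units_key(self) -> str:
        """Units normalized for comparison: trimmed and case-folded only."""
        return self.units.strip().casefold()

    @property
    def age_midpoint(self) -> int:
        return (self.age_low_days + self.age_high_days) // 2


#: Canonical field names, in file order.  ``parent_strain`` and
#: ``strain_class`` are optional columns.
CANONICAL_FIELDS: tuple[str, ...] = (
    "record_id",
    "study_id",
    "phenotype",
    "strain",
    "parent_strain",
    "strain_class",
    "sex",
    "age_low_days",
    "age_high_days",
    "method",
    "condition",
    "n_animals",
    "mean_value",
    "dispersion_value",
    "dispersion_kind",
    "units",
)

REQUIRED_FIELDS: tuple[str, ...] = tuple(
    f for f in CANONICAL_FIELDS if f not in ("parent_strain", "strain_class")
)


@dataclass(frozen=True)
class ColumnMap:
    """Maps canonical field names to the column names used in a file."""

    columns: Mapping[str, str] = field(default_factory=dict)

    def column_for(self, canonical: str) -> str:
        return self.columns.get(canonical, canonical)

    def validate_header(self, header: Sequence[str]) -> None:
        missing = [
            self.column_for(f) for f in REQUIRED_FIELDS if self.column_for(f) not in header
        ]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")


@dataclass(frozen=True)
class RejectedRow:
    row_number: int
    record_id: str
    reason: str


@dataclass
class ParseReport:
    """Outcome of parsing one file: valid records plus a reject report."""

    records: list[MeasurementRecord]
    rejects: list[RejectedRow]


_INT_FIELDS = ("age_low_days", "age_high_days", "n_animals")
_FLOAT_FIELDS = ("mean_value", "dispersion_value")


def _record_from_row(row: Mapping[str, str], cmap: ColumnMap) -> MeasurementRecord:
    kwargs: dict = {}
    for canonical in CANONICAL_FIELDS:
        raw = row.get(cmap.column_for(canonical))
        if raw is None or raw == "":
            if canonical in ("parent_strain", "strain_class"):
                continue
            raise ValueError(f"field '{canonical}': missing value")
        raw = raw.strip()
        if canonical in _INT_FIELDS:
            try:
                kwargs[canonical] = int(raw)
            except ValueError:
                raise ValueError(f"field '{canonical}': unparseable integer {raw!r}")
        elif canonical in _FLOAT_FIELDS:
            try:
                value = float(raw)
            except ValueError:
                raise ValueError(f"field '{canonical}': unparseable number {raw!r}")
            if not math.isfinite(value):
                raise ValueError(f"field '{canonical}': non-finite value {raw!r}")
            kwargs[canonical] = value
        else:
            kwargs[canonical] = raw
    return MeasurementRecord(**kwargs)


def _delimiter_for(path: Path, delimiter: Optional[str]) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","


def parse_records(
    path: str | Path,
    column_map: Optional[ColumnMap] = None,
    delimiter: Optional[str] = None,
) -> ParseReport:
    """Parse a delimited file of measurement records.

    Every row either yields a valid :class:`MeasurementRecord` or is listed in
    the reject report with its row number, record id and reason.  Row order is
    preserved.

    Raises
    ------
    SchemaError
        If a required column is absent from the header.
    NoRecordsError
        If the file has no data rows.
    """
    path = Path(path)
    cmap = column_map or ColumnMap()
    sep = _delimiter_for(path, delimiter)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter=sep)
        if reader.fieldnames is None:
            raise NoRecordsError(f"{path}: no records (empty file)")
        cmap.validate_header(reader.fieldnames)
        records: list[MeasurementRecord] = []
        rejects: list[RejectedRow] = []
        n_rows = 0
        for i, row in enumerate(reader):
            n_rows += 1
            row_number = i + 2  # 1-based, after the header
            rid = (row.get(cmap.column_for("record_id")) or f"row{row_number}").strip()
            try:
                records.append(_record_from_row(row, cmap))
            except (ValueError, TypeError) as exc:
                rejects.append(RejectedRow(row_number, rid, _clean_reason(exc)))
    if n_rows == 0:
        raise NoRecordsError(f"{path}: no records (header only)")
    return ParseReport(records=records, rejects=rejects)


def _clean_reason(exc: Exception) -> str:
    # pydantic ValidationError messages are multi-line; keep the informative part
    lines = [ln.strip() for ln in str(exc).splitlines() if ln.strip()]
    return "; ".join(lines[:4])


def write_records(
    records: Iterable[MeasurementRecord], path: str | Path, delimiter: Optional[str] = None
) -> Path:
    """Write records in the canonical column order; round-trips with
    :func:`parse_records`."""
    path = Path(path)
    sep = _delimiter_for(path, delimiter)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter=sep, lineterminator="\n")
        writer.writerow(CANONICAL_FIELDS)
        for r in records:
            writer.writerow(
                [
                    r.record_id,
                    r.study_id,
                    r.phenotype,
                    r.strain,
                    r.parent_strain or "",
                    r.strain_class.value if r.strain_class else "",
                    r.sex.value,
                    r.age_low_days,
                    r.age_high_days,
                    r.method,
                    r.condition,
                    r.n_animals,
                    repr(r.mean_value),
                    repr(r.dispersion_value),
                    r.dispersion_kind.value,
                    r.units,
                ]
            )
    return path


def write_rejects(rejects: Iterable[RejectedRow], path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["row_number", "record_id", "reason"])
        for rej in rejects:
            writer.writerow([rej.row_number, rej.record_id, rej.reason])
    return path


# ---------------------------------------------------------------------------
# Dispersion harmonization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HarmonizedDispersion:
    """Animal-level SD and variance of the study mean for one record."""

    sd_animals: float
    var_of_mean: float
    flags: frozenset[str] = frozenset()


def harmonize_dispersion(record: MeasurementRecord) -> HarmonizedDispersion:
    """Convert a record's dispersion to (animal-level SD, variance of the mean).

    All pooling weights downstream use the variance of the *study mean*:
    ``SD^2 / n`` when the record reports an SD, ``SEM^2`` when it reports a
    SEM.  The two parameterizations are exact transforms of each other
    (``SD = SEM * sqrt(n)``).

    Degenerate inputs are flagged rather than rejected: a zero dispersion
    yields a zero variance with flag ``zero-variance``; a single-animal SEM of
    zero additionally carries ``uninformative-variance``.
    """
    n = record.n_animals
    d = record.dispersion_value
    if record.dispersion_kind is DispersionKind.SD:
        sd_animals = d
        var_of_mean = d * d / n
    else:
        sd_animals = d * math.sqrt(n)
        var_of_mean = d * d
    flags: set[str] = set()
    if var_of_mean == 0.0:
        flags.add("zero-variance")
        if n == 1 and record.dispersion_kind is DispersionKind.SEM:
            flags.add("uninformative-variance")
    return HarmonizedDispersion(sd_animals, var_of_mean, frozenset(flags))


# ---------------------------------------------------------------------------
# Strain grouping
# ---------------------------------------------------------------------------

class StrainGroupTable:
    """Flat two-level mapping parent strain -> set of substrain symbols.

    Mirrors the rat strain nomenclature in which e.g. strain group ``ACI``
    collects the substrains ``ACI/Eur``, ``ACI/Kun``, ``ACI/N``, ... bred in
    separate facilities.  Each substrain belongs to exactly one parent and a
    parent may not itself be listed as a substrain.
    """

    def __init__(self, mapping: Mapping[str, Iterable[str]]):
        groups: dict[str, frozenset[str]] = {}
        seen: dict[str, str] = {}
        for parent, subs in mapping.items():
            subs = frozenset(subs)
            for sub in subs:
                if sub in seen and seen[sub] != parent:
                    raise StrainTableError(
                        f"substrain {sub!r} listed under both {seen[sub]!r} and {parent!r}"
                    )
                seen[sub] = parent
            groups[parent] = subs
        for parent in groups:
            if parent in seen and seen[parent] != parent:
                raise StrainTableError(
                    f"parent {parent!r} is also a substrain of {seen[parent]!r}"
                )
        self._groups = groups
        self._parent_of = seen

    @classmethod
    def from_tsv(cls, path: str | Path) -> "StrainGroupTable":
        """Load a two-column (substrain, parent) TSV, header optional."""
        mapping: dict[str, set[str]] = {}
        with Path(path).open(newline="") as fh:
            for row in csv.reader(fh, delimiter="\t"):
                if not row or row[0].startswith("#"):
                    continue
                if row[0].strip().casefold() in ("substrain", "strain"):
                    continue
                if len(row) < 2:
                    raise StrainTableError(f"strain table row needs 2 columns: {row!r}")
                sub, parent = row[0].strip(), row[1].strip()
                mapping.setdefault(parent, set()).add(sub)
        return cls(mapping)

    def parent_of(self, strain: str) -> Optional[str]:
        return self._parent_of.get(strain)

    def __contains__(self, strain: str) -> bool:
        return strain in self._parent_of

    @property
    def parents(self) -> frozenset[str]:
        return frozenset(self._groups)


def expand_strain_groups(
    records: Iterable[MeasurementRecord], table: StrainGroupTable
) -> list[MeasurementRecord]:
    """Fill ``parent_strain`` from the grouping table.

    Strains absent from the table are their own parent, so grouping at the
    parent level is total.
    """
    out = []
    for r in records:
        parent = table.parent_of(r.strain) or r.strain
        out.append(r.model_copy(update={"parent_strain": parent}))
    return out


def stable_record_id(*parts: object) -> str:
    """Deterministic short id from arbitrary parts (used by the simulator)."""
    digest = hashlib.md5("|".join(str(p) for p in parts).encode()).hexdigest()
    return f"R{digest[:10]}"
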