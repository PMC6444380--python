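"""Expected ranges, the control-strain-group range, strain classification,
expert comparison, and forest/funnel rendering.

An *expected range* summarizes a strain's typical values for one phenotype as
the pooled meta-analysis mean plus/minus one standard deviation.  The SD used
is ``sqrt(tau2_hat + pooled animal-level variance)`` — the between-study
variance (zero under the fixed-effect model) plus the inverse-variance-
weighted mean of the studies' animal-level variances — so ranges widen under
true heterogeneity and reduce to the familiar animal-level SD when the
studies are homogeneous.

The *control expected range* for a phenotype is built iteratively: start from
designated founder control strains (e.g. BN and WKY for blood pressure), take
the lowest low and highest high of their expected ranges, then admit every
other strain whose expected range intersects the current interval, widening
the interval as strains are admitted.  Strains are finally classified as
within / overlapping / outside the control range; within and overlapping both
count as "normal" when comparing with expert strain labels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel

from .bias import EggerResult
from .errors import (
    KeyMismatchError,
    MissingRangeError,
    PhenotypeMismatchError,
)
from .meta import LOW_CONFIDENCE, MetaResult, effective_variances
from .stratify import MetaInput, StratumKey

NORMAL = "normal"
ABNORMAL = "abnormal"


class RangeConfig(BaseModel):
    """Options for expected-range construction."""

    sd_source: Literal["animal", "pooled_se"] = "animal"
    min_overlap_frac: float = 0.0
    control_mode: Literal["single-pass", "fixed-point"] = "single-pass"


@dataclass(frozen=True)
class ExpectedRange:
    key: StratumKey
    center: float
    sd_used: float
    low: float
    high: float
    k: int
    confidence: str
    flags: frozenset[str] = frozenset()

    @property
    def width(self) -> float:
        return self.high - self.low


def expected_range(
    result: MetaResult, m: MetaInput, config: Optional[RangeConfig] = None
) -> ExpectedRange:
    """Expected range = pooled mean +/- one standard deviation.

    By default the SD combines estimated between-study variance with the
    pooled animal-level variance; ``sd_source="pooled_se"`` instead uses the
    SE of the pooled mean (a much narrower "uncertainty of the mean" band)
    and flags the range accordingly.
    """
    cfg = config or RangeConfig()
    flags: set[str] = set()
    center = result.pooled.mean
    if cfg.sd_source == "pooled_se":
        sd_used = result.pooled.se
        flags.add("sd-from-pooled-se")
    else:
        sd_animals2 = np.asarray(m.sd_animals, dtype=float) ** 2
        valid = np.isfinite(sd_animals2)
        if not valid.any():
            raise MissingRangeError(
                f"stratum '{m.key.label()}': no animal-level dispersions available"
            )
        var_eff, _ = effective_variances(m)
        w = 1.0 / var_eff
        pooled_within = float(np.sum(w[valid] * sd_animals2[valid]) / np.sum(w[valid]))
        tau2 = 0.0
        if result.het is not None and result.pooled.model == "random":
            tau2 = result.het.tau2
        sd_used = math.sqrt(tau2 + pooled_within)
    if sd_used == 0:
        flags.add("zero-width")
    return ExpectedRange(
        key=result.key,
        center=center,
        sd_used=sd_used,
        low=center - sd_used,
        high=center + sd_used,
        k=result.k,
        confidence=result.confidence,
        flags=frozenset(flags),
    )


# ---------------------------------------------------------------------------
# Control-strain-group range
# ---------------------------------------------------------------------------

@dataclass
class ControlRange:
    phenotype: str
    founders: tuple[str, ...]
    included: tuple[str, ...]  # founders plus admitted strains
    low: float
    high: float
    iteration_log: list[tuple[str, str, tuple[float, float]]] = field(default_factory=list)


def _intersects(low1: float, high1: float, low2: float, high2: float, min_frac: float) -> bool:
    overlap = min(high1, high2) - max(low1, low2)
    if min_frac <= 0:
        return overlap >= 0  # touching endpoints count as contact
    width = high2 - low2
    if width == 0:
        return overlap >= 0
    return overlap / width > min_frac


def build_control_range(
    founders: Sequence[str],
    ranges: Mapping[str, ExpectedRange],
    veto: Sequence[str] = (),
    mode: Optional[Literal["single-pass", "fixed-point"]] = None,
    config: Optional[RangeConfig] = None,
    candidate_order: Optional[Sequence[str]] = None,
) -> ControlRange:
    """Iteratively build the phenotype-level control ("normal") range.

    (i) the ``founders`` are taken as given control strains; (ii) the initial
    interval spans the lowest low and highest high of their expected ranges;
    (iii) every other non-vetoed strain whose expected range intersects the
    current interval is admitted; (iv) the interval is updated to the min/max
    over all admitted strains.  ``single-pass`` examines each candidate once
    in sorted-symbol order; ``fixed-point`` repeats passes until no further
    strain is admitted.  Every decision is recorded in the iteration log and
    the interval only ever widens.  ``candidate_order`` overrides the default
    sorted order (the fixed-point result does not depend on it).
    """
    cfg = config or RangeConfig()
    mode = mode or cfg.control_mode
    if not founders:
        raise MissingRangeError("control range needs at least one founder strain")
    missing = [f for f in founders if f not in ranges]
    if missing:
        raise MissingRangeError(f"founder strain(s) without an expected range: {missing}")
    phenotypes = {ranges[f].key.phenotype for f in founders}
    if len(phenotypes) > 1:
        raise PhenotypeMismatchError(f"founder ranges mix phenotypes: {sorted(phenotypes)}")
    phenotype = phenotypes.pop()

    log: list[tuple[str, str, tuple[float, float]]] = []
    low = min(ranges[f].low for f in founders)
    high = max(ranges[f].high for f in founders)
    for f in sorted(founders):
        log.append((f, "founder", (low, high)))
    included = set(founders)
    vetoed = set(veto)

    if candidate_order is None:
        candidates = sorted(set(ranges) - included)
    else:
        candidates = [s for s in candidate_order if s not in included]
    changed = True
    first_pass = True
    while changed:
        changed = False
        for strain in candidates:
            if strain in included:
                continue
            if strain in vetoed:
                if first_pass:
                    log.append((strain, "vetoed", (low, high)))
                continue
            er = ranges[strain]
            if er.key.phenotype != phenotype:
                raise PhenotypeMismatchError(
                    f"strain {strain!r} range is for {er.key.phenotype!r}, not {phenotype!r}"
                )
            if _intersects(low, high, er.low, er.high, cfg.min_overlap_frac):
                included.add(strain)
                low = min(low, er.low)
                high = max(high, er.high)
                log.append((strain, "included", (low, high)))
                changed = True
            elif first_pass:
                log.append((strain, "excluded", (low, high)))
        if mode == "single-pass":
            break
        first_pass = False
    return ControlRange(
        phenotype=phenotype,
        founders=tuple(sorted(founders)),
        included=tuple(sorted(included)),
        low=low,
        high=high,
        iteration_log=log,
    )


# ---------------------------------------------------------------------------
# Classification against the control range
# ---------------------------------------------------------------------------

WITHIN = "within"
OVERLAPPING = "overlapping"
OUTSIDE = "outside"


@dataclass(frozen=True)
class StrainClassification:
    strain: str
    status: str  # within | overlapping | outside
    strain_low: float
    strain_high: float
    control_low: float
    control_high: float


def classify_strain(strain_range: ExpectedRange, control: ControlRange) -> StrainClassification:
    """Interval relation of a strain's expected range to the control range.

    ``within``: contained; ``outside``: disjoint; ``overlapping`` otherwise.
    Exactly one status holds for any pair of closed intervals.
    """
    if strain_range.key.phenotype != control.phenotype:
        raise PhenotypeMismatchError(
            f"cannot classify {strain_range.key.phenotype!r} range against "
            f"{control.phenotype!r} control range"
        )
    lo, hi = strain_range.low, strain_range.high
    if lo >= control.low and hi <= control.high:
        status = WITHIN
    elif hi < control.low or lo > control.high:
        status = OUTSIDE
    else:
        status = OVERLAPPING
    return StrainClassification(
        strain=strain_range.key.strain_or_group,
        status=status,
        strain_low=lo,
        strain_high=hi,
        control_low=control.low,
        control_high=control.high,
    )


def labels_from_classifications(
    classifications: Iterable[StrainClassification],
) -> dict[str, str]:
    """Tool labels: within/overlapping count as normal, outside as abnormal."""
    return {
        c.strain: (NORMAL if c.status in (WITHIN, OVERLAPPING) else ABNORMAL)
        for c in classifications
    }


@dataclass
class AgreementReport:
    percent: float
    n: int
    disagreements: list[tuple[str, str, str]]  # (key, tool label, expert label)


def compare_with_expert(
    tool_labels: Mapping[str, str], expert_labels: Mapping[str, str]
) -> AgreementReport:
    """Percentage agreement between tool and expert normal/abnormal labels."""
    missing_expert = sorted(set(tool_labels) - set(expert_labels))
    missing_tool = sorted(set(expert_labels) - set(tool_labels))
    if missing_expert or missing_tool:
        raise KeyMismatchError(
            f"label key mismatch; missing from expert: {missing_expert}; "
            f"missing from tool: {missing_tool}"
        )
    if not tool_labels:
        raise KeyMismatchError("no keys to compare")
    disagreements = [
        (k, tool_labels[k], expert_labels[k])
        for k in sorted(tool_labels)
        if tool_labels[k] != expert_labels[k]
    ]
    n = len(tool_labels)
    percent = 100.0 * (n - len(disagreements)) / n
    return AgreementReport(percent=percent, n=n, disagreements=disagreements)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

_SEX_MARKERS = {"male": "s", "female": "o", "both": "D", "unspecified": "v", "all": "s"}


def forest_table(
    rows: Sequence[tuple[MetaResult, ExpectedRange]]
) -> pd.DataFrame:
    """Numeric geometry of the forest plot, one row per stratum."""
    data = []
    for res, er in rows:
        data.append(
            {
                "label": res.key.label(),
                "strain_or_group": res.key.strain_or_group,
                "sex_group": res.key.sex_group,
                "age_bin": res.key.age_bin,
                "center": er.center,
                "low": er.low,
                "high": er.high,
                "extent": er.width,
                "k": res.k,
                "confidence": res.confidence,
                "shape": _SEX_MARKERS.get(res.key.sex_group, "s"),
            }
        )
    return pd.DataFrame(
        data,
        columns=[
            "label", "strain_or_group", "sex_group", "age_bin",
            "center", "low", "high", "extent", "k", "confidence", "shape",
        ],
    )


def render_forest(
    rows: Sequence[tuple[MetaResult, ExpectedRange]],
    path: Optional[str] = None,
    sex_shapes: bool = False,
    title: str = "Expected ranges",
    control: Optional[ControlRange] = None,
) -> tuple[pd.DataFrame, Optional[str]]:
    """Forest plot of expected ranges: box center at the pooled mean, box
    extent +/- one SD, color encoding the number of experiments, legend
    noting confidence (k < 4 -> low_confidence).

    Always returns the plot-data table; the image is written only when
    ``path`` is given (suffix selects SVG/PNG).
    """
    table = forest_table(rows)
    if path is None:
        return table, None
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, max(2.5, 0.4 * len(table) + 1.5)))
    if len(table):
        kmax = max(int(table["k"].max()), 1)
        cmap = plt.get_cmap("viridis")
        for ypos, row in enumerate(table.itertuples()):
            color = cmap(min(row.k / max(kmax, 4), 1.0))
            ax.plot([row.low, row.high], [ypos, ypos], color=color, lw=4, solid_capstyle="butt")
            marker = row.shape if sex_shapes else "s"
            ax.plot(
                [row.center], [ypos], marker=marker, color=color,
                markeredgecolor="black", markersize=7,
            )
        labels = [
            f"{row.label} ({row.confidence})" if row.confidence == LOW_CONFIDENCE else row.label
            for row in table.itertuples()
        ]
        ax.set_yticks(range(len(table)))
        ax.set_yticklabels(labels, fontsize=7)
        ax.invert_yaxis()
        sm_ = plt.cm.ScalarMappable(cmap=cmap, norm=matplotlib.colors.Normalize(1, kmax))
        fig.colorbar(sm_, ax=ax, label="experiments (k)")
    if control is not None:
        ax.axvline(control.low, ls=":", color="grey")
        ax.axvline(control.high, ls=":", color="grey")
    ax.set_xlabel("measurement value")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return table, path


def funnel_table(m: MetaInput, egger: EggerResult) -> pd.DataFrame:
    var_eff, _ = effective_variances(m)
    s = np.sqrt(var_eff)
    return pd.DataFrame(
        {
            "study_id": list(m.study_ids),
            "standardized_effect": m.y / s,
            "precision": 1.0 / s,
            "n_animals": m.n,
        }
    )


def render_funnel(
    m: MetaInput,
    egger: EggerResult,
    path: Optional[str] = None,
    title: str = "Funnel diagnostics",
) -> tuple[pd.DataFrame, Optional[str]]:
    """Scatter of standardized effect vs precision with the Egger line.

    The regression overlay (and intercept annotation) appears only when the
    Egger result is evaluable (k >= 3).
    """
    table = funnel_table(m, egger)
    if path is None:
        return table, None
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(table["precision"], table["standardized_effect"], s=20 + 2 * table["n_animals"])
    if egger.evaluable and math.isfinite(egger.intercept):
        xs = np.linspace(0, float(table["precision"].max()) * 1.05, 50)
        ax.plot(xs, egger.intercept + egger.slope * xs, "r-", lw=1)
        ax.annotate(
            f"intercept = {egger.intercept:.3g}",
            xy=(0, egger.intercept),
            xytext=(5, 5),
            textcoords="offset points",
            fontsize=8,
        )
    ax.set_xlabel("precision (1/SD)")
    ax.set_ylabel("standardized effect (value/SD)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return table, path
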