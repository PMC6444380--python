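"""Publication-bias diagnostics and leave-one-out sensitivity analysis.

Publication bias arises because small studies with unremarkable findings are
less likely to be published; on a funnel plot (effect vs precision) this shows
up as asymmetry.  The Egger screen regresses the standardized effect
``y_i / s_i`` on the precision ``1 / s_i`` by ordinary least squares; an
unbiased, homogeneous set of studies regresses through the origin, so a
nonzero intercept signals asymmetry.  The dimensionless asymmetry score is

    Asy = intercept / average value of the measurements,

with the unweighted arithmetic mean in the denominator so that Asy is
invariant under unit rescaling.  Because the Egger test has a relatively high
false-positive rate, |Asy| above the threshold (default 1.5) only *flags* a
stratum as bias-suspect — it never excludes data automatically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import CollinearityError
from .stratify import MetaInput

if TYPE_CHECKING:  # pragma: no cover
    from .meta import MetaConfig, MetaResult

__all__ = [
    "EggerResult",
    "egger_regression",
    "funnel_data",
    "quadrant",
    "asy_vs_k_profile",
    "LeaveOneOutSeries",
    "leave_one_out",
    "CollinearityError",
]


@dataclass(frozen=True)
class EggerResult:
    intercept: float
    slope: float
    intercept_se: float
    asymmetry_score: float  # NaN when mean(y) == 0
    evaluable: bool
    note: str = ""


def egger_regression(m: MetaInput, floor_factor: float = 1e-3) -> EggerResult:
    """Egger funnel-asymmetry regression of y/s on 1/s.

    Needs at least three studies for a residual degree of freedom; with fewer
    the result is returned not-evaluable rather than raising, so the workflow
    degrades gracefully.  All precisions identical leaves the design matrix
    collinear and raises :class:`CollinearityError`.
    """
    if m.k < 3:
        return EggerResult(
            math.nan, math.nan, math.nan, math.nan,
            evaluable=False, note="fewer than 3 studies",
        )
    from .meta import effective_variances  # local import avoids a cycle

    var, _ = effective_variances(m, floor_factor)
    s = np.sqrt(var)
    precision = 1.0 / s
    if np.ptp(precision) == 0:
        raise CollinearityError("all study precisions identical; Egger regression undefined")
    design = sm.add_constant(precision)
    fit = sm.OLS(m.y / s, design).fit()
    intercept, slope = float(fit.params[0]), float(fit.params[1])
    intercept_se = float(fit.bse[0])
    ybar = float(np.mean(m.y))
    if ybar == 0:
        asy, note = math.nan, "average value is zero; Asy undefined"
    else:
        asy, note = intercept / ybar, ""
    return EggerResult(intercept, slope, intercept_se, asy, evaluable=True, note=note)


def funnel_data(m: MetaInput) -> pd.DataFrame:
    """Per-study funnel-plot coordinates (value, precision, sample size)."""
    s = np.sqrt(m.var, where=m.var > 0, out=np.full(m.k, np.nan))
    with np.errstate(divide="ignore"):
        precision = np.where(s > 0, 1.0 / s, np.inf)
    return pd.DataFrame(
        {
            "study_id": list(m.study_ids),
            "y": m.y,
            "precision": precision,
            "n_animals": m.n,
        }
    )


def quadrant(
    asymmetry_score: float,
    i2: float,
    asy_threshold: float = 1.5,
    i2_threshold: float = 0.85,
) -> str:
    """Place a stratum in the (|Asy|, I^2) quadrant diagram.

    Q1: high asymmetry & high heterogeneity (publication bias or extreme
    outliers); Q2: high asymmetry & low heterogeneity (true publication bias
    suspected); Q3: low & low (fixed-effect model); Q4: low asymmetry & high
    heterogeneity (random-effect model).  "High" is strictly above threshold.
    """
    high_asy = abs(asymmetry_score) > asy_threshold
    high_i2 = i2 > i2_threshold
    if high_asy:
        return "Q1" if high_i2 else "Q2"
    return "Q4" if high_i2 else "Q3"


def asy_vs_k_profile(results: Iterable["MetaResult"]) -> pd.DataFrame:
    """Summaries of |Asy| grouped by number of experiments k.

    Used to check that asymmetry settles down with enough experiments, the
    diagnostic behind the minimum-experiments (k >= 4) confidence rule.
    Results whose Asy is not evaluable are ignored; the table is empty when
    none remain.
    """
    rows = [
        {"k": r.k, "abs_asy": abs(r.asymmetry_score)}
        for r in results
        if math.isfinite(r.asymmetry_score)
    ]
    if not rows:
        return pd.DataFrame(columns=["k", "n_results", "median_abs_asy", "iqr_abs_asy", "max_abs_asy"])
    df = pd.DataFrame(rows)
    grouped = df.groupby("k")["abs_asy"]
    out = pd.DataFrame(
        {
            "n_results": grouped.size(),
            "median_abs_asy": grouped.median(),
            "iqr_abs_asy": grouped.quantile(0.75) - grouped.quantile(0.25),
            "max_abs_asy": grouped.max(),
        }
    ).reset_index()
    return out


@dataclass
class LeaveOneOutSeries:
    """One sub-analysis per omitted study, with influence scores and flags."""

    study_ids: tuple[str, ...]
    results: list["MetaResult"]  # results[i] omits study i
    influence: np.ndarray
    flagged: tuple[str, ...]
    flagged_indices: tuple[int, ...]
    evaluable: bool = True
    note: str = ""
    full_result: Optional["MetaResult"] = None


def leave_one_out(m: MetaInput, config: Optional["MetaConfig"] = None) -> LeaveOneOutSeries:
    """Exclusion-sensitivity series: repeat the meta-analysis omitting one
    study at a time.

    The influence of study i is the shift of the pooled mean when it is
    omitted, in units of the full-analysis pooled SE.  A study is flagged as a
    potential outlier when its influence strictly exceeds the configured
    threshold, or when omitting it moves I^2 across the model-choice
    threshold (so the fixed/random decision hinges on that single study).
    Flags are advisory: exclusion remains the analyst's call.
    """
    from .meta import MetaConfig, run_meta

    cfg = config or MetaConfig()
    if m.k < 3:
        return LeaveOneOutSeries(
            study_ids=m.study_ids,
            results=[],
            influence=np.array([]),
            flagged=(),
            flagged_indices=(),
            evaluable=False,
            note="insufficient-for-sensitivity (k < 3)",
        )
    full = run_meta(m, cfg)
    full_i2 = full.het.i2 if full.het is not None else math.nan
    results = []
    influence = np.empty(m.k)
    flagged_idx: list[int] = []
    for i in range(m.k):
        sub = run_meta(m.drop(i), cfg)
        results.append(sub)
        influence[i] = abs(sub.pooled.mean - full.pooled.mean) / full.pooled.se
        crosses = (
            sub.het is not None
            and math.isfinite(full_i2)
            and (full_i2 > cfg.i2_threshold) != (sub.het.i2 > cfg.i2_threshold)
        )
        if influence[i] > cfg.influence_threshold or crosses:
            flagged_idx.append(i)
    return LeaveOneOutSeries(
        study_ids=m.study_ids,
        results=results,
        influence=influence,
        flagged=tuple(m.study_ids[i] for i in flagged_idx),
        flagged_indices=tuple(flagged_idx),
        full_result=full,
    )


def loo_table(series: LeaveOneOutSeries) -> pd.DataFrame:
    """Flat table of the leave-one-out series for reporting."""
    rows = []
    for i, res in enumerate(series.results):
        rows.append(
            {
                "omitted_study": series.study_ids[i],
                "mean_without": res.pooled.mean,
                "se_without": res.pooled.se,
                "i2_without": res.het.i2 if res.het else math.nan,
                "model_without": res.pooled.model,
                "influence": series.influence[i],
                "flagged": i in series.flagged_indices,
            }
        )
    return pd.DataFrame(rows)
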