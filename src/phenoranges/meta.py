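"""Heterogeneity statistics and pooled estimation for one stratum.

The model: the observed study mean ``y_i = theta_i + e_i``, where ``e_i`` has
variance ``s_i^2`` (the variance of the study mean) and, under the
random-effect model, ``theta_i ~ N(mu, tau^2)`` with between-study variance
``tau^2`` estimated by the non-iterative DerSimonian-Laird moment estimator.

Fixed-effect pooling weights studies by inverse variance ``w_i = 1/s_i^2``;
random-effect pooling by ``w*_i = 1/(tau^2 + s_i^2)``.  In both cases the
pooled mean is ``sum(w y) / sum(w)`` with variance ``1/sum(w)`` and standard
error ``1/sqrt(sum(w))``.

Model choice follows a heterogeneity decision rule: Cochran's
``Q = sum w_i (y_i - m_w)^2`` on ``k-1`` degrees of freedom gives
``I^2 = max(0, (Q - df)/Q)``, the fraction of total variation attributable to
between-study heterogeneity; strata with ``I^2`` strictly above the threshold
(default 0.85) are pooled with the random-effect model, all others with the
fixed-effect model.  Confidence is a binary label driven by the number of
experiments: fewer than ``min_experiments`` (default 4) studies mark the
result ``low_confidence``, since funnel asymmetry only stabilizes from about
four experiments upward and small strata can show falsely small study ranges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from pydantic import BaseModel

from . import bias
from .errors import DegenerateInputError, InsufficientStudiesError
from .stratify import MetaInput, StratumKey

CONFIDENT = "confident"
LOW_CONFIDENCE = "low_confidence"


class MetaConfig(BaseModel):
    """Tunable thresholds of the meta-analysis decision tree."""

    min_experiments: int = 4
    i2_threshold: float = 0.85
    asy_threshold: float = 1.5
    influence_threshold: float = 1.0
    variance_floor_factor: float = 1e-3
    ci_z: float = 1.96


@dataclass(frozen=True)
class HeterogeneityStats:
    Q: float
    df: int
    i2: float
    tau2: float


@dataclass(frozen=True)
class PooledEstimate:
    model: str  # "fixed" | "random"
    mean: float
    se: float
    ci95: tuple[float, float]


@dataclass
class MetaResult:
    """Everything the workflow computed for one stratum."""

    key: StratumKey
    k: int
    pooled: PooledEstimate
    het: Optional[HeterogeneityStats]
    confidence: str
    asymmetry_score: float  # NaN when not evaluable
    quadrant: Optional[str]
    egger: Optional["bias.EggerResult"]
    flags: set[str] = field(default_factory=set)


def effective_variances(m: MetaInput, floor_factor: float = 1e-3) -> tuple[np.ndarray, bool]:
    """Replace zero within-study variances by a small positive floor.

    Zero-SD records occur in curated data and must not produce infinite
    weights; the floor is the smallest positive variance in the stratum times
    ``floor_factor``.  Returns (variances, whether flooring was applied).

    Raises :class:`DegenerateInputError` when every variance is zero.
    """
    var = np.asarray(m.var, dtype=float)
    if np.all(var == 0):
        raise DegenerateInputError(
            f"stratum '{m.key.label()}': all within-study variances are zero"
        )
    if np.any(var == 0):
        floor = var[var > 0].min() * floor_factor
        return np.where(var == 0, floor, var), True
    return var, False


def fixed_effect(m: MetaInput, floor_factor: float = 1e-3, ci_z: float = 1.96) -> PooledEstimate:
    """Inverse-variance fixed-effect pool: one true effect, weights 1/s_i^2."""
    var, _ = effective_variances(m, floor_factor)
    w = 1.0 / var
    mean = float(np.sum(w * m.y) / np.sum(w))
    se = float(1.0 / math.sqrt(np.sum(w)))
    return PooledEstimate("fixed", mean, se, (mean - ci_z * se, mean + ci_z * se))


def cochran_q(m: MetaInput, floor_factor: float = 1e-3) -> tuple[float, int]:
    """Cochran's Q (weighted squared deviation from the fixed-effect mean)."""
    var, _ = effective_variances(m, floor_factor)
    w = 1.0 / var
    mw = np.sum(w * m.y) / np.sum(w)
    q = float(np.sum(w * (m.y - mw) ** 2))
    return q, m.k - 1


def i_squared(Q: float, df: int) -> float:
    """I^2 = max(0, (Q - df)/Q): heterogeneity as a fraction in [0, 1)."""
    if Q <= 0:
        return 0.0
    return max(0.0, (Q - df) / Q)


def dl_tau2(m: MetaInput, floor_factor: float = 1e-3) -> float:
    """DerSimonian-Laird moment estimator of the between-study variance.

    ``tau^2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w))`` with
    fixed-effect weights; clamped at zero.
    """
    if m.k < 2:
        raise InsufficientStudiesError("DerSimonian-Laird tau^2 needs k >= 2")
    var, _ = effective_variances(m, floor_factor)
    w = 1.0 / var
    q, df = cochran_q(m, floor_factor)
    denom = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    if denom <= 0:
        raise DegenerateInputError("tau^2 denominator vanished (single effective study)")
    return max(0.0, (q - df) / denom)


def random_effect(
    m: MetaInput, tau2: float, floor_factor: float = 1e-3, ci_z: float = 1.96
) -> PooledEstimate:
    """Random-effect pool with weights 1/(tau^2 + s_i^2).

    With ``tau2 = 0`` this reproduces :func:`fixed_effect` exactly.
    """
    var, _ = effective_variances(m, floor_factor)
    w = 1.0 / (tau2 + var)
    mean = float(np.sum(w * m.y) / np.sum(w))
    se = float(1.0 / math.sqrt(np.sum(w)))
    return PooledEstimate("random", mean, se, (mean - ci_z * se, mean + ci_z * se))


def select_model(i2: float, threshold: float = 0.85) -> str:
    """Random-effect model iff I^2 strictly exceeds the threshold.

    The boundary value routes to the fixed-effect model: the threshold is read
    as the highest I^2 still eligible for fixed-effect pooling.
    """
    return "random" if i2 > threshold else "fixed"


def run_meta(m: MetaInput, config: Optional[MetaConfig] = None) -> MetaResult:
    """Run the full per-stratum workflow and keep every intermediate statistic.

    Steps: Egger funnel asymmetry (when evaluable), the minimum-experiments
    confidence rule, Q / I^2 / DL tau^2, model selection by the I^2 threshold,
    pooling under the selected model, and quadrant assignment of
    (|Asy|, I^2).  Single-study strata are pooled trivially and flagged
    ``het-undefined`` rather than dropped.
    """
    cfg = config or MetaConfig()
    flags: set[str] = set()
    ff = cfg.variance_floor_factor

    _, floored = effective_variances(m, ff)
    if floored:
        flags.add("zero-variance-floored")

    # Publication-bias screen
    try:
        egger: Optional[bias.EggerResult] = bias.egger_regression(m, floor_factor=ff)
    except bias.CollinearityError:
        egger = None
        flags.add("egger-collinear")
    asy = float("nan")
    if egger is not None and egger.evaluable:
        asy = egger.asymmetry_score
        if math.isnan(asy):
            flags.add("asy-undefined")
    elif egger is not None:
        flags.add("insufficient-for-egger")
    if math.isfinite(asy) and abs(asy) > cfg.asy_threshold:
        flags.add("bias-suspect")

    # Heterogeneity and pooling
    if m.k == 1:
        het: Optional[HeterogeneityStats] = None
        flags.add("het-undefined")
        pooled = fixed_effect(m, ff, cfg.ci_z)
    else:
        q, df = cochran_q(m, ff)
        i2 = i_squared(q, df)
        tau2 = dl_tau2(m, ff)
        het = HeterogeneityStats(Q=q, df=df, i2=i2, tau2=tau2)
        model = select_model(i2, cfg.i2_threshold)
        if model == "random":
            pooled = random_effect(m, tau2, ff, cfg.ci_z)
        else:
            pooled = fixed_effect(m, ff, cfg.ci_z)

    confidence = CONFIDENT if m.k >= cfg.min_experiments else LOW_CONFIDENCE
    if confidence == LOW_CONFIDENCE:
        flags.add("insufficient-data")

    quad = None
    if math.isfinite(asy) and het is not None:
        quad = bias.quadrant(asy, het.i2, cfg.asy_threshold, cfg.i2_threshold)

    return MetaResult(
        key=m.key,
        k=m.k,
        pooled=pooled,
        het=het,
        confidence=confidence,
        asymmetry_score=asy,
        quadrant=quad,
        egger=egger,
        flags=flags,
    )
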