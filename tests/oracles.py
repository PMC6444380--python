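"""Independent naive-loop oracles for the pooled statistics.

Pure-Python reference implementations written from the defining formulas,
kept free of numpy vectorization and of any code path in the package under
test.
"""

from __future__ import annotations

import math


def fe_mean_se(y, var):
    sw = sum(1.0 / v for v in var)
    swy = sum(yi / v for yi, v in zip(y, var))
    return swy / sw, 1.0 / math.sqrt(sw)


def cochran_q(y, var):
    mean, _ = fe_mean_se(y, var)
    return sum((yi - mean) ** 2 / v for yi, v in zip(y, var))


def i_squared(q, df):
    if q <= 0:
        return 0.0
    return max(0.0, (q - df) / q)


def dl_tau2(y, var):
    k = len(y)
    q = cochran_q(y, var)
    sw = sum(1.0 / v for v in var)
    sw2 = sum(1.0 / v**2 for v in var)
    denom = sw - sw2 / sw
    return max(0.0, (q - (k - 1)) / denom)


def re_mean_se(y, var, tau2):
    w = [1.0 / (tau2 + v) for v in var]
    mean = sum(wi * yi for wi, yi in zip(w, y)) / sum(w)
    return mean, 1.0 / math.sqrt(sum(w))


def egger_normal_equations(y, s):
    """OLS of y/s on 1/s via the closed-form normal equations.

    Returns (intercept, slope, intercept_se); the SE uses the unbiased
    residual variance on k-2 degrees of freedom.
    """
    k = len(y)
    xs = [1.0 / si for si in s]
    ys = [yi / si for yi, si in zip(y, s)]
    xbar = sum(xs) / k
    ybar = sum(ys) / k
    sxx = sum((x - xbar) ** 2 for x in xs)
    sxy = sum((x - xbar) * (yv - ybar) for x, yv in zip(xs, ys))
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    residuals = [yv - intercept - slope * x for x, yv in zip(xs, ys)]
    sigma2 = sum(r * r for r in residuals) / (k - 2) if k > 2 else 0.0
    se_intercept = math.sqrt(sigma2 * (1.0 / k + xbar**2 / sxx))
    return intercept, slope, se_intercept
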