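"""Brute-force statistical oracles, independent of the package internals.

Everything here is computed from first-principles sums and the textbook
normal-equations / t-statistic formulas, so the package's regression and
test code can be checked against an implementation that shares nothing
with it but the t distribution function itself.
"""

import math

from scipy.stats import t as t_dist


def ols_oracle(x, y):
    """Simple linear regression y = a + b*x by explicit normal equations.

    Returns (slope, intercept, r_squared, residual_sd, p_two_sided) where
    the p-value is the two-sided t-test of slope = 0 on n-2 df.
    """
    n = len(x)
    sx = sum(x)
    sy = sum(y)
    sxx = sum(xi * xi for xi in x)
    sxy = sum(xi * yi for xi, yi in zip(x, y))
    denom = n * sxx - sx * sx
    slope = (n * sxy - sx * sy) / denom
    intercept = (sy - slope * sx) / n
    resid = [yi - (intercept + slope * xi) for xi, yi in zip(x, y)]
    sse = sum(r * r for r in resid)
    ybar = sy / n
    sst = sum((yi - ybar) ** 2 for yi in y)
    r_squared = 1.0 if sst == 0 else 1.0 - sse / sst
    if n > 2:
        residual_sd = math.sqrt(sse / (n - 2))
        sxx_c = sxx - sx * sx / n
        se_slope = residual_sd / math.sqrt(sxx_c)
        if se_slope == 0:
            p = 1.0 if slope == 0 else 0.0
        else:
            tstat = slope / se_slope
            p = 2.0 * t_dist.sf(abs(tstat), n - 2)
    else:
        residual_sd = 0.0
        p = float("nan")
    return slope, intercept, r_squared, residual_sd, p


def paired_t_oracle(x, y):
    """Textbook two-sided paired t-test. Returns (t, p, mean_difference)."""
    n = len(x)
    d = [xi - yi for xi, yi in zip(x, y)]
    dbar = sum(d) / n
    var = sum((di - dbar) ** 2 for di in d) / (n - 1)
    sd = math.sqrt(var)
    tstat = dbar / (sd / math.sqrt(n))
    p = 2.0 * t_dist.sf(abs(tstat), n - 1)
    return tstat, p, dbar
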