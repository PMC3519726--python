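"""Bland-Altman agreement analysis with regression-based limits.

Two %ID/g measurements of the same specimen (gamma and fluorescence halves)
are compared through their paired difference d = gamma - IR plotted against
their average a. The bias line is the overall mean difference unless OLS of
d on log(a) finds the bias to depend on magnitude (two-sided slope test at
alpha). The spread is modelled by regressing the absolute residuals around
the chosen bias line on log(a); since the mean absolute value of a centred
Gaussian is sigma * sqrt(2/pi), the fitted mean absolute residual is scaled
by sqrt(pi/2) to a standard deviation, and the 95% limits of agreement are
bias_line(a) -/+ 1.96 * sqrt(pi/2) * m(a). With a significant slope the
limits widen log-linearly with the average — the heteroscedastic picture
typical when disagreement grows with uptake.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .biodistribution import UptakeRecord
from .core import (
    DomainError,
    EstimationError,
    RegressionError,
    StudyConfig,
    logger,
)

HALF_NORMAL_SCALE = math.sqrt(math.pi / 2.0)

CONSTANT = "constant"
LOG_LINEAR = "log_linear"


@dataclass(frozen=True)
class PairedSample:
    """One specimen measured by both modalities."""

    sample_id: str
    x_gamma: float
    x_ir: float

    @property
    def difference(self) -> float:
        return self.x_gamma - self.x_ir

    @property
    def average(self) -> float:
        return 0.5 * (self.x_gamma + self.x_ir)


@dataclass(frozen=True)
class AgreementResult:
    """Everything needed to draw the Bland-Altman plot and its limits."""

    n: int
    n_excluded: int
    bias: float  # mean paired difference (gamma - IR)
    magnitude_slope: float
    magnitude_intercept: float
    magnitude_p: float
    bias_line: str  # "constant" | "log_linear"
    variation_gamma0: float
    variation_gamma1: float
    variation_p: float
    mean_abs_residual: float
    limits_model: str  # "constant" | "log_linear"
    z: float
    log_base: str
    alpha: float

    def to_dict(self) -> dict:
        import dataclasses

        return dataclasses.asdict(self)


def _log(a: np.ndarray | float, base: str):
    return np.log(a) if base == "natural" else np.log10(a)


def _slope_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """OLS slope/intercept with a two-sided slope p-value.

    Degenerate cases are resolved before the library fit: a constant
    response carries no evidence of trend (slope 0, p = 1); a constant
    regressor leaves the slope unidentified.
    """
    if np.ptp(x) == 0:
        raise RegressionError("zero variance in the regressor")
    if np.ptp(y) == 0:
        return 0.0, float(y[0]), 1.0
    res = stats.linregress(x, y)
    p = float(res.pvalue)
    if math.isnan(p):  # perfectly collinear fit: zero residual, nonzero slope
        p = 0.0
    return float(res.slope), float(res.intercept), p


def make_pairs(
    ir_records: Sequence[UptakeRecord], gamma_records: Sequence[UptakeRecord]
) -> list[PairedSample]:
    """Join two uptake record sets on sample_id into paired samples."""
    ir = {r.sample_id: r.percent_id_per_g for r in ir_records}
    gm = {r.sample_id: r.percent_id_per_g for r in gamma_records}
    shared = sorted(set(ir) & set(gm))
    unmatched = (set(ir) | set(gm)) - set(shared)
    if unmatched:
        logger.warning(
            "%d sample(s) present in only one modality; dropped", len(unmatched)
        )
    return [PairedSample(s, x_gamma=gm[s], x_ir=ir[s]) for s in shared]


def bland_altman(
    pairs: Sequence[PairedSample], cfg: StudyConfig | None = None
) -> AgreementResult:
    """Fit the full regression-based Bland-Altman model.

    Steps: (1) bias = mean paired difference over all usable pairs;
    (2) magnitude check — OLS of d on log(a); the bias line becomes
    log-linear only if the slope is significant at ``cfg.alpha``;
    (3) variation check — OLS of |residual around the bias line| on log(a);
    (4) the limits model is log-linear exactly when that slope is
    significant. Pairs with nonpositive average cannot be log-transformed
    and are excluded with a warning.
    """
    cfg = cfg or StudyConfig()
    usable = [p for p in pairs if p.average > 0]
    n_excluded = len(pairs) - len(usable)
    if n_excluded:
        logger.warning(
            "%d pair(s) with nonpositive average excluded from the "
            "agreement analysis",
            n_excluded,
        )
    if len(usable) < 3:
        raise EstimationError(
            f"Bland-Altman analysis needs >= 3 usable pairs, got {len(usable)}"
        )
    a = np.asarray([p.average for p in usable])
    d = np.asarray([p.difference for p in usable])
    log_a = _log(a, cfg.log_base)

    bias = float(d.mean())
    mag_slope, mag_intercept, mag_p = _slope_test(log_a, d)
    bias_line = LOG_LINEAR if mag_p < cfg.alpha else CONSTANT

    if bias_line == LOG_LINEAR:
        fitted = mag_intercept + mag_slope * log_a
    else:
        fitted = np.full_like(d, bias)
    abs_resid = np.abs(d - fitted)

    var_g1, var_g0, var_p = _slope_test(log_a, abs_resid)
    limits_model = LOG_LINEAR if var_p < cfg.alpha else CONSTANT

    return AgreementResult(
        n=len(usable),
        n_excluded=n_excluded,
        bias=bias,
        magnitude_slope=mag_slope,
        magnitude_intercept=mag_intercept,
        magnitude_p=mag_p,
        bias_line=bias_line,
        variation_gamma0=var_g0,
        variation_gamma1=var_g1,
        variation_p=var_p,
        mean_abs_residual=float(abs_resid.mean()),
        limits_model=limits_model,
        z=cfg.z_95,
        log_base=cfg.log_base,
        alpha=cfg.alpha,
    )


def bias_line_at(result: AgreementResult, a: float | np.ndarray):
    """Value of the line of best agreement at average a."""
    if result.bias_line == LOG_LINEAR:
        return result.magnitude_intercept + result.magnitude_slope * _log(
            a, result.log_base
        )
    return result.bias if np.isscalar(a) else np.full(np.shape(a), result.bias)


def limits_at(
    result: AgreementResult, a: float
) -> tuple[float, float]:
    """95% limits of agreement at average a.

    The predicted mean absolute residual m(a) (log-linear or constant) is
    scaled by sqrt(pi/2) to a standard deviation and multiplied by z; a
    negative m(a) extrapolation clamps the half-width at zero.
    """
    if np.any(np.asarray(a) <= 0):
        raise DomainError("average must be > 0")
    if result.limits_model == LOG_LINEAR:
        m = result.variation_gamma0 + result.variation_gamma1 * _log(
            a, result.log_base
        )
    else:
        m = result.mean_abs_residual
    m = np.maximum(m, 0.0)
    half_width = result.z * HALF_NORMAL_SCALE * m
    center = bias_line_at(result, a)
    lower, upper = center - half_width, center + half_width
    if np.isscalar(a):
        return float(lower), float(upper)
    return lower, upper


def plot_data(
    result: AgreementResult,
    pairs: Sequence[PairedSample],
    n_grid: int = 200,
) -> pd.DataFrame:
    """Tabulate the Bland-Altman plot: scatter points and fitted lines.

    Returns one table with a ``kind`` column: ``point`` rows carry each
    pair's (average, difference); ``grid`` rows carry the bias line and
    the 95% limits on a log-spaced grid spanning the observed averages, so
    any plotting front-end can reproduce the plot's geometry.
    """
    usable = [p for p in pairs if p.average > 0]
    rows = [
        {
            "kind": "point",
            "sample_id": p.sample_id,
            "average": p.average,
            "difference": p.difference,
            "bias_line": np.nan,
            "lower": np.nan,
            "upper": np.nan,
        }
        for p in usable
    ]
    a_vals = np.asarray([p.average for p in usable])
    grid = np.geomspace(a_vals.min(), a_vals.max(), n_grid)
    lower, upper = limits_at(result, grid)
    center = bias_line_at(result, grid)
    for a, c, lo, hi in zip(grid, np.broadcast_to(center, grid.shape), lower, upper):
        rows.append(
            {
                "kind": "grid",
                "sample_id": "",
                "average": float(a),
                "difference": np.nan,
                "bias_line": float(c),
                "lower": float(lo),
                "upper": float(hi),
            }
        )
    return pd.DataFrame(rows)
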