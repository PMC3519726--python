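"""Linear-dynamic-range selection and calibration-curve inverse prediction.

Fluorescence intensity of a concentrated lysate is depressed by
concentration quenching and, above the scanner ceiling, truncated outright;
using such wells directly underestimates the probe content. Each sample is
therefore read as a 1:2 dilution series, saturated wells are discarded, and
the linear range is delimited by walking from the most dilute well toward
the most concentrated one while each successive intensity ratio stays within
``step_factor * (1 +/- linearity_tolerance)``. Concentration is then read
off an ordinary-least-squares calibration line fitted to a dilution series
of the injected probe itself (classical calibration: intensity on
concentration, inverted).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    DilutionSeries,
    FitError,
    LinearRangeError,
    StudyConfig,
    ValidationError,
    logger,
)

# Exclusion reasons for LinearRange.excluded_indices
SATURATED = "saturated"
NONLINEAR_HIGH = "nonlinear_high"
BELOW_LOD = "below_lod"
GAP = "gap"


@dataclass(frozen=True)
class LinearRange:
    """Outcome of linear-range selection for one dilution series."""

    sample_id: str
    retained_indices: tuple[int, ...]
    excluded_indices: dict[int, str]

    @property
    def n_retained(self) -> int:
        return len(self.retained_indices)


@dataclass(frozen=True)
class CalibrationCurve:
    """OLS line intensity = slope * C + intercept, with diagnostics.

    ``lod_intensity`` is the IUPAC-style 3-sigma limit of detection on the
    intensity scale: intercept + 3 * residual SD.
    """

    slope: float
    intercept: float
    r_squared: float
    residual_sd: float
    lod_intensity: float
    fit_range: tuple[float, float]
    n_points: int


class InversionResult(NamedTuple):
    concentration_ug_per_mL: float
    below_lod: bool
    clamped: bool


@dataclass(frozen=True)
class ConcentrationEstimate:
    """Back-calculated lysate concentration for one sample."""

    sample_id: str
    lysate_concentration_ug_per_mL: float
    n_wells_used: int
    per_well_estimates: tuple[tuple[int, float], ...]
    cv: float
    flags: frozenset[str] = frozenset()


# ---------------------------------------------------------------------------
# Saturation and linear range
# ---------------------------------------------------------------------------


def flag_saturation(series: DilutionSeries, ceiling: float) -> DilutionSeries:
    """Return a copy with ``saturated = True`` on wells at/above the ceiling.

    Idempotent; wells already flagged stay flagged.
    """
    import dataclasses

    if ceiling <= 0:
        raise ValidationError("ceiling must be > 0")
    wells = tuple(
        dataclasses.replace(w, saturated=True)
        if w.intensity >= ceiling
        else w
        for w in series.wells
    )
    return dataclasses.replace(series, wells=wells)


def select_linear_range(series: DilutionSeries, cfg: StudyConfig) -> LinearRange:
    """Delimit the linear dynamic range of one dilution series.

    Saturated wells are excluded first (any well more concentrated than a
    saturated well is excluded too, as the series is broken there). Then,
    walking from the most dilute surviving well toward the most concentrated
    one, wells are retained while each successive intensity ratio lies
    within ``step_factor**gap * (1 +/- linearity_tolerance)``; the first
    violating well and everything more concentrated are excluded as
    ``nonlinear_high`` — the onset of quenching seen from above.

    Raises
    ------
    LinearRangeError
        If fewer than ``cfg.min_linear_wells`` wells survive; quantifying
        from such a series would underestimate the probe content.
    """
    excluded: dict[int, str] = {}
    sat_indices = [w.dilution_index for w in series.wells if w.saturated]
    deepest_sat = max(sat_indices) if sat_indices else -1
    candidates = []
    for w in series.wells:
        if w.saturated:
            excluded[w.dilution_index] = SATURATED
        elif w.dilution_index < deepest_sat:
            # unsaturated well on the concentrated side of a saturated one
            excluded[w.dilution_index] = GAP
        else:
            candidates.append(w)

    tol = cfg.linearity_tolerance
    step = series.step_factor
    retained: list[int] = []
    if candidates:
        # walk from the most dilute candidate toward the most concentrated
        ordered = list(reversed(candidates))  # descending dilution_index
        retained.append(ordered[0].dilution_index)
        for prev, cur in zip(ordered, ordered[1:]):
            gap = prev.dilution_index - cur.dilution_index
            expected = step**gap
            ok = (
                prev.intensity > 0
                and expected * (1 - tol)
                <= cur.intensity / prev.intensity
                <= expected * (1 + tol)
            )
            if not ok:
                # cur and everything more concentrated fail
                cut = cur.dilution_index
                for w in candidates:
                    if w.dilution_index <= cut:
                        excluded[w.dilution_index] = NONLINEAR_HIGH
                break
            retained.append(cur.dilution_index)

    retained_sorted = tuple(sorted(retained))
    if len(retained_sorted) < cfg.min_linear_wells:
        raise LinearRangeError(
            f"sample {series.sample_id}: only {len(retained_sorted)} well(s) "
            f"in the linear range (need >= {cfg.min_linear_wells}); "
            "quantification would underestimate the signal"
        )
    return LinearRange(
        sample_id=series.sample_id,
        retained_indices=retained_sorted,
        excluded_indices=excluded,
    )


# ---------------------------------------------------------------------------
# Calibration fit and inversion
# ---------------------------------------------------------------------------


def fit_calibration(
    standards: Sequence[tuple[float, float]],
    cfg: StudyConfig | None = None,
) -> CalibrationCurve:
    """Fit the calibration line intensity = slope * C + intercept by OLS.

    ``standards`` are (concentration in ug/mL, intensity) pairs from the
    injected-probe dilution series, already restricted to unsaturated wells
    within their own linear range.
    """
    if len(standards) < 2:
        raise FitError("calibration needs >= 2 points")
    conc = np.asarray([c for c, _ in standards], dtype=float)
    inten = np.asarray([i for _, i in standards], dtype=float)
    if len(np.unique(conc)) < 2:
        raise FitError("calibration needs >= 2 distinct concentrations")

    res = stats.linregress(conc, inten)
    slope, intercept = float(res.slope), float(res.intercept)
    if slope <= 0:
        raise FitError(f"calibration slope {slope:.4g} <= 0: unusable standards")
    n = len(conc)
    resid = inten - (slope * conc + intercept)
    sse = float(np.sum(resid**2))
    if n > 2:
        residual_sd = math.sqrt(sse / (n - 2))
    else:
        residual_sd = 0.0
    sst = float(np.sum((inten - inten.mean()) ** 2))
    r_squared = 1.0 if sst == 0 else max(0.0, 1.0 - sse / sst)
    return CalibrationCurve(
        slope=slope,
        intercept=intercept,
        r_squared=r_squared,
        residual_sd=residual_sd,
        lod_intensity=intercept + 3.0 * residual_sd,
        fit_range=(float(conc.min()), float(conc.max())),
        n_points=n,
    )


def prepare_standards(
    standards: pd.DataFrame, cfg: StudyConfig
) -> list[tuple[float, float]]:
    """Reduce a standards table to fit-ready (concentration, intensity) pairs.

    Each standard series is saturation-flagged and linear-range-selected
    exactly like a sample series, so quenched/saturated top standards never
    bend the calibration line.
    """
    from .core import WellMeasurement, group_series

    pairs: list[tuple[float, float]] = []
    for sid, grp in standards.groupby("sample_id"):
        grp = grp.sort_values("dilution_index")
        # synthesize a well per row; plate coordinates are irrelevant here
        wells = [
            WellMeasurement(
                plate_id="standards",
                row="A",
                col=1 + (int(r.dilution_index) % 12),
                sample_id=str(sid),
                dilution_index=int(r.dilution_index),
                intensity=float(r.intensity),
            )
            for r in grp.itertuples(index=False)
        ]
        (series,) = group_series(wells, step_factor=cfg.step_factor)
        series = flag_saturation(series, cfg.detector_ceiling)
        rng = select_linear_range(series, cfg)
        keep = set(rng.retained_indices)
        for r in grp.itertuples(index=False):
            if int(r.dilution_index) in keep:
                pairs.append(
                    (float(r.known_concentration_ug_per_mL), float(r.intensity))
                )
    return pairs


def invert_calibration(curve: CalibrationCurve, intensity: float) -> InversionResult:
    """Inverse prediction C = (intensity - intercept) / slope.

    Never raises on a dim well: readings below the LOD are flagged, and
    readings below the intercept are clamped to zero concentration.
    """
    if intensity < 0:
        raise ValidationError("intensity must be >= 0")
    c = (intensity - curve.intercept) / curve.slope
    clamped = c < 0
    return InversionResult(
        concentration_ug_per_mL=0.0 if clamped else c,
        below_lod=intensity < curve.lod_intensity,
        clamped=clamped,
    )


def estimate_lysate_concentration(
    series: DilutionSeries,
    linear_range: LinearRange,
    curve: CalibrationCurve,
    predilution: float = 1.0,
) -> ConcentrationEstimate:
    """Back-calculate the undiluted lysate concentration of one sample.

    Every retained well k gives an independent estimate
    ``invert(I_k) * step_factor**k * predilution``; the sample estimate is
    their unweighted mean, excluding wells flagged below the LOD (dim wells
    lose averaging rights but do not shorten the linear range). If every
    retained well is below the LOD the estimate is 0 with a ``below_lod``
    flag.
    """
    if linear_range.sample_id != series.sample_id:
        raise ValidationError("linear range does not belong to this series")
    if not linear_range.retained_indices:
        raise LinearRangeError(f"sample {series.sample_id}: empty retained set")
    by_index = {w.dilution_index: w for w in series.wells}
    per_well: list[tuple[int, float]] = []
    used: list[float] = []
    flags: set[str] = set()
    for k in linear_range.retained_indices:
        w = by_index[k]
        inv = invert_calibration(curve, w.intensity)
        lysate = inv.concentration_ug_per_mL * series.step_factor**k * predilution
        per_well.append((k, lysate))
        if inv.clamped:
            flags.add("clamped")
        if inv.below_lod:
            continue
        used.append(lysate)

    if not used:
        flags.add("below_lod")
        estimate, cv, n_used = 0.0, 0.0, 0
    else:
        arr = np.asarray(used)
        estimate = float(arr.mean())
        n_used = len(used)
        if n_used > 1 and estimate > 0:
            cv = float(arr.std(ddof=1) / estimate)
        else:
            cv = 0.0
    return ConcentrationEstimate(
        sample_id=series.sample_id,
        lysate_concentration_ug_per_mL=estimate,
        n_wells_used=n_used,
        per_well_estimates=tuple(per_well),
        cv=cv,
        flags=frozenset(flags),
    )


def estimates_to_frame(estimates: Sequence[ConcentrationEstimate]) -> pd.DataFrame:
    """Per-sample concentration table (the `quantify` concentration output)."""
    return pd.DataFrame(
        {
            "sample_id": [e.sample_id for e in estimates],
            "lysate_concentration_ug_per_mL": [
                e.lysate_concentration_ug_per_mL for e in estimates
            ],
            "n_wells_used": [e.n_wells_used for e in estimates],
            "cv": [e.cv for e in estimates],
            "flags": [";".join(sorted(e.flags)) for e in estimates],
        }
    )
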