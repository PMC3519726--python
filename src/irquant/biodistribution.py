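"""Percent-injected-dose-per-gram conversion, summaries, and comparisons.

Both modalities report the standard biodistribution unit %ID/g — the
percentage of the injected probe dose recovered per gram of tissue. For the
fluorescence arm, probe amount = lysate concentration x lysate volume; for
the gamma arm, the fraction of injected dose is counts relative to an
injected-dose counting standard, with both readings decay-corrected to
injection time using the radionuclide half-life.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .calibration import (
    ConcentrationEstimate,
    estimate_lysate_concentration,
    fit_calibration,
    flag_saturation,
    prepare_standards,
    select_linear_range,
)
from .core import (
    DomainError,
    GammaMeasurement,
    LinearRangeError,
    StudyConfig,
    TissueSample,
    ValidationError,
    WellMeasurement,
    group_series,
    logger,
    subtract_blank,
)


@dataclass(frozen=True)
class UptakeRecord:
    """%ID/g of one tissue half under one modality."""

    sample_id: str
    mouse_id: str
    organ: str
    modality: str
    percent_id_per_g: float
    half_weight_g: float
    flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.percent_id_per_g < 0:
            raise ValidationError("percent_id_per_g must be >= 0")


@dataclass(frozen=True)
class OrganSummary:
    organ: str
    modality: str
    n: int
    mean: float
    sem: float | None  # None when n == 1 (SEM undefined)


@dataclass(frozen=True)
class OrganComparison:
    organ: str
    n_pairs: int
    mean_difference: float  # gamma - IR
    p_value: float
    significance_mark: str  # "ns", "**" or "***"


# ---------------------------------------------------------------------------
# %ID/g arithmetic
# ---------------------------------------------------------------------------


def ir_percent_id_per_g(
    lysate_concentration_ug_per_mL: float,
    lysate_volume_mL: float,
    injected_dose_ug: float,
    half_weight_g: float,
) -> float:
    """%ID/g from the fluorescence arm.

    Probe amount in the tissue half is concentration x homogenate volume;
    expressed as a percentage of the injected dose and normalised by the
    half's weight.
    """
    if injected_dose_ug <= 0 or half_weight_g <= 0:
        raise DomainError("injected dose and half weight must be > 0")
    if lysate_concentration_ug_per_mL < 0 or lysate_volume_mL < 0:
        raise DomainError("concentration and volume must be >= 0")
    amount_ug = lysate_concentration_ug_per_mL * lysate_volume_mL
    return (amount_ug / injected_dose_ug) * 100.0 / half_weight_g


def decay_correction_factor(elapsed_h: float, halflife_h: float) -> float:
    """Factor 2**(elapsed/halflife) restoring counts to injection time."""
    if elapsed_h < 0:
        raise DomainError("elapsed time must be >= 0")
    if halflife_h <= 0:
        raise DomainError("half-life must be > 0")
    return 2.0 ** (elapsed_h / halflife_h)


def gamma_percent_id_per_g(
    meas: GammaMeasurement, half_weight_g: float, cfg: StudyConfig
) -> float:
    """%ID/g from the gamma arm.

    Sample and standard counts are each decay-corrected to injection time
    with their own elapsed times (so a simultaneously counted standard and
    an injection-time-referenced standard are both expressible), then the
    corrected count ratio is the fraction of injected dose.
    """
    if half_weight_g <= 0:
        raise DomainError("half weight must be > 0")
    if meas.standard_counts_per_minute <= 0:
        raise DomainError("standard counts per minute must be > 0")
    corr_sample = meas.counts_per_minute * decay_correction_factor(
        meas.count_time_h, cfg.halflife_h
    )
    corr_std = meas.standard_counts_per_minute * decay_correction_factor(
        meas.standard_time_h, cfg.halflife_h
    )
    return (corr_sample / corr_std) * 100.0 / half_weight_g


# ---------------------------------------------------------------------------
# Study-level pipelines
# ---------------------------------------------------------------------------


def ir_uptake_from_plates(
    wells: Sequence[WellMeasurement],
    manifest: Sequence[TissueSample],
    standards: pd.DataFrame,
    cfg: StudyConfig,
) -> tuple[list[UptakeRecord], list[ConcentrationEstimate]]:
    """Full fluorescence arm: plates + standards + manifest -> %ID/g.

    Fits the calibration curve on the linear range of the standard series,
    then per sample: saturation flagging, linear-range selection, inverse
    prediction, %ID/g. Samples whose series has too few linear wells are
    skipped with a logged warning (the study run never aborts on one bad
    series).
    """
    if cfg.blank_sample_id is not None:
        wells = subtract_blank(wells, cfg.blank_sample_id)
    curve = fit_calibration(prepare_standards(standards, cfg), cfg)
    by_sample = {
        s.sample_id: s for s in manifest if s.modality == "IR"
    }
    records: list[UptakeRecord] = []
    estimates: list[ConcentrationEstimate] = []
    for series in group_series(wells, step_factor=cfg.step_factor):
        sample = by_sample.get(series.sample_id)
        if sample is None:
            logger.warning(
                "plate sample %s has no IR manifest entry; skipped",
                series.sample_id,
            )
            continue
        series = flag_saturation(series, cfg.detector_ceiling)
        try:
            rng = select_linear_range(series, cfg)
        except LinearRangeError as err:
            logger.warning("%s; sample skipped", err)
            continue
        est = estimate_lysate_concentration(
            series, rng, curve, predilution=sample.predilution
        )
        estimates.append(est)
        records.append(
            UptakeRecord(
                sample_id=sample.sample_id,
                mouse_id=sample.mouse_id,
                organ=sample.organ,
                modality="IR",
                percent_id_per_g=ir_percent_id_per_g(
                    est.lysate_concentration_ug_per_mL,
                    sample.lysate_volume_mL,
                    cfg.injected_dose_ug,
                    sample.half_weight_g,
                ),
                half_weight_g=sample.half_weight_g,
                flags=est.flags,
            )
        )
    return records, estimates


def gamma_uptake(
    measurements: Sequence[GammaMeasurement],
    manifest: Sequence[TissueSample],
    cfg: StudyConfig,
) -> list[UptakeRecord]:
    """Reference arm: gamma counts + manifest -> %ID/g records."""
    by_sample = {s.sample_id: s for s in manifest if s.modality == "gamma"}
    records: list[UptakeRecord] = []
    for meas in measurements:
        sample = by_sample.get(meas.sample_id)
        if sample is None:
            logger.warning(
                "gamma sample %s has no manifest entry; skipped", meas.sample_id
            )
            continue
        records.append(
            UptakeRecord(
                sample_id=sample.sample_id,
                mouse_id=sample.mouse_id,
                organ=sample.organ,
                modality="gamma",
                percent_id_per_g=gamma_percent_id_per_g(
                    meas, sample.half_weight_g, cfg
                ),
                half_weight_g=sample.half_weight_g,
            )
        )
    return records


# ---------------------------------------------------------------------------
# Summaries and comparisons
# ---------------------------------------------------------------------------


def summarize(records: Sequence[UptakeRecord]) -> list[OrganSummary]:
    """Per-(organ, modality) mean +/- SEM, sample (n-1) SD."""
    if not records:
        raise ValidationError("no uptake records to summarize")
    groups: dict[tuple[str, str], list[float]] = {}
    for r in records:
        groups.setdefault((r.organ, r.modality), []).append(r.percent_id_per_g)
    out = []
    for (organ, modality) in sorted(groups):
        vals = np.asarray(groups[(organ, modality)])
        n = len(vals)
        sem = float(vals.std(ddof=1) / math.sqrt(n)) if n > 1 else None
        out.append(
            OrganSummary(
                organ=organ, modality=modality, n=n, mean=float(vals.mean()), sem=sem
            )
        )
    return out


def _mark(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    return "ns"


def compare_methods(
    records: Sequence[UptakeRecord], cfg: StudyConfig | None = None
) -> list[OrganComparison]:
    """Per-organ two-sided test of gamma vs IR %ID/g.

    The two halves of one specimen are natural pairs, so the default is a
    paired t-test on per-sample (gamma - IR) differences; a Welch unpaired
    fallback is available via ``cfg.comparison_test``. Significance marks
    follow the p < 0.01 / p < 0.001 tiers; identical measurements give
    p = 1 by convention. Organs with fewer than two pairs are skipped with
    a warning.
    """
    cfg = cfg or StudyConfig()
    by_organ: dict[str, dict[str, dict[str, float]]] = {}
    for r in records:
        by_organ.setdefault(r.organ, {}).setdefault(r.modality, {})[
            r.sample_id
        ] = r.percent_id_per_g

    results: list[OrganComparison] = []
    for organ in sorted(by_organ):
        ir = by_organ[organ].get("IR", {})
        gm = by_organ[organ].get("gamma", {})
        shared = sorted(set(ir) & set(gm))
        if len(shared) < 2:
            logger.warning(
                "organ %s: %d paired sample(s); comparison skipped",
                organ,
                len(shared),
            )
            continue
        x_gamma = np.asarray([gm[s] for s in shared])
        x_ir = np.asarray([ir[s] for s in shared])
        d = x_gamma - x_ir
        if np.all(d == 0):
            p = 1.0
        elif cfg.comparison_test == "welch":
            p = float(stats.ttest_ind(x_gamma, x_ir, equal_var=False).pvalue)
        elif d.std(ddof=1) == 0:
            p = 0.0  # constant nonzero shift: infinite t statistic
        else:
            p = float(stats.ttest_rel(x_gamma, x_ir).pvalue)
        results.append(
            OrganComparison(
                organ=organ,
                n_pairs=len(shared),
                mean_difference=float(d.mean()),
                p_value=p,
                significance_mark=_mark(p),
            )
        )
    if cfg.p_adjust != "none" and results:
        from statsmodels.stats.multitest import multipletests

        method = {"bonferroni": "bonferroni", "bh": "fdr_bh"}[cfg.p_adjust]
        adj = multipletests([r.p_value for r in results], method=method)[1]
        results = [
            dataclasses.replace(r, p_value=float(p), significance_mark=_mark(p))
            for r, p in zip(results, adj)
        ]
    return results


def tumor_to_normal_ratio(
    tumor_roi_mean: float, background_roi_mean: float
) -> float:
    """Tumor-to-normal signal ratio from imaging region-of-interest means."""
    if background_roi_mean <= 0:
        raise DomainError("background ROI mean must be > 0")
    return tumor_roi_mean / background_roi_mean


def tn_summary(roi: pd.DataFrame) -> tuple[float, float, int]:
    """Study-level T/N ratio: mean +/- SD ((n-1) SD) over mice."""
    ratios = np.asarray(
        [
            tumor_to_normal_ratio(t, b)
            for t, b in zip(roi["tumor_roi_mean"], roi["background_roi_mean"])
        ]
    )
    n = len(ratios)
    sd = float(ratios.std(ddof=1)) if n > 1 else 0.0
    return float(ratios.mean()), sd, n


# ---------------------------------------------------------------------------
# Tabular output
# ---------------------------------------------------------------------------


def uptake_to_frame(records: Sequence[UptakeRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "mouse_id": [r.mouse_id for r in records],
            "organ": [r.organ for r in records],
            "modality": [r.modality for r in records],
            "percent_id_per_g": [r.percent_id_per_g for r in records],
            "half_weight_g": [r.half_weight_g for r in records],
            "flags": [";".join(sorted(r.flags)) for r in records],
        }
    )


def uptake_from_frame(df: pd.DataFrame) -> list[UptakeRecord]:
    required = [
        "sample_id",
        "mouse_id",
        "organ",
        "modality",
        "percent_id_per_g",
        "half_weight_g",
    ]
    from .core import FormatError

    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"uptake table: missing column(s): {', '.join(missing)}")
    out = []
    for rec in df.itertuples(index=False):
        flags = (
            frozenset(str(rec.flags).split(";"))
            if "flags" in df.columns and isinstance(rec.flags, str) and rec.flags
            else frozenset()
        )
        out.append(
            UptakeRecord(
                sample_id=str(rec.sample_id),
                mouse_id=str(rec.mouse_id),
                organ=str(rec.organ),
                modality=str(rec.modality),
                percent_id_per_g=float(rec.percent_id_per_g),
                half_weight_g=float(rec.half_weight_g),
                flags=flags,
            )
        )
    return out


def summaries_to_frame(summaries: Sequence[OrganSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "organ": [s.organ for s in summaries],
            "modality": [s.modality for s in summaries],
            "n": [s.n for s in summaries],
            "mean": [s.mean for s in summaries],
            "sem": [s.sem for s in summaries],
        }
    )


def comparisons_to_frame(comparisons: Sequence[OrganComparison]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "organ": [c.organ for c in comparisons],
            "n_pairs": [c.n_pairs for c in comparisons],
            "mean_difference": [c.mean_difference for c in comparisons],
            "p_value": [c.p_value for c in comparisons],
            "mark": [c.significance_mark for c in comparisons],
        }
    )
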