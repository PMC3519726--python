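"""Core data model and CSV/JSON interfaces.

Domain objects for a dual-label (near-infrared fluorescence + gamma
counting) biodistribution study: 96-well plate measurements of serially
diluted tissue lysates, the tissue manifest, gamma-well-counter readings,
and the study configuration. All file interfaces are plain long-format CSV
(one row per well / sample / measurement) so arbitrary plate layouts are
representable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger("irquant")

PLATE_ROWS = tuple("ABCDEFGH")
PLATE_COLS = tuple(range(1, 13))

#: Advisory organ vocabulary (warnings only; users may extend the panel).
KNOWN_ORGANS = frozenset(
    {
        "blood",
        "tumor",
        "liver",
        "spleen",
        "kidney",
        "lung",
        "heart",
        "sternum",
        "muscle",
        "skin",
        "stomach",
        "intestines",
    }
)

MODALITIES = ("IR", "gamma")


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------


class IrquantError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(IrquantError):
    """A file does not have the documented structure (e.g. missing column)."""


class ValidationError(IrquantError):
    """A record violates a domain invariant."""


class LinearRangeError(IrquantError):
    """Too few wells survive linear-range selection for a sample."""


class FitError(IrquantError):
    """The calibration fit is impossible or unusable (e.g. slope <= 0)."""


class DomainError(IrquantError):
    """A scalar argument is outside its mathematical domain."""


class EstimationError(IrquantError):
    """An estimation step cannot proceed (e.g. too few paired samples)."""


class RegressionError(EstimationError):
    """A regression is degenerate (e.g. zero variance in the regressor)."""


# ---------------------------------------------------------------------------
# Study configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StudyConfig:
    """All analysis constants, with study-level defaults.

    Parameters
    ----------
    injected_dose_ug
        Injected probe dose in micrograms (default 106, a 120 uL injection
        of the antibody probe).
    detector_ceiling
        Maximum reportable scanner intensity; wells at or above it carry no
        quantitative information (default 65535, a 16-bit readout).
    linearity_tolerance
        Relative tolerance on the successive 1:2 intensity ratio used to
        delimit the linear dynamic range.
    min_linear_wells
        Minimum number of wells that must survive linear-range selection.
    log_base
        Base of the log transform used in the agreement analysis
        ("natural" or "base10"); the limits of agreement are invariant to
        this choice.
    alpha
        Two-sided significance cutoff (default 0.05).
    halflife_h
        Radionuclide half-life in hours (default 78.4, for 89Zr).
    z_95
        Normal quantile used for the 95% limits of agreement.
    step_factor
        Dilution step between successive wells (default 2 for 1:2 series).
    comparison_test
        Per-organ between-modality test: "paired" (two-sided paired t) or
        "welch" (unpaired Welch fallback).
    p_adjust
        Multiple-testing correction across organs: "none" (default,
        matching per-organ reporting), "bonferroni" or "bh".
    blank_sample_id
        Optional sample id whose mean per-plate intensity is subtracted
        from every well on the same plate before analysis (off by default).
    """

    injected_dose_ug: float = 106.0
    detector_ceiling: float = 65535.0
    linearity_tolerance: float = 0.15
    min_linear_wells: int = 3
    log_base: str = "natural"
    alpha: float = 0.05
    halflife_h: float = 78.4
    z_95: float = 1.96
    step_factor: float = 2.0
    comparison_test: str = "paired"
    p_adjust: str = "none"
    blank_sample_id: str | None = None

    def __post_init__(self) -> None:
        if self.injected_dose_ug <= 0:
            raise ValidationError("injected_dose_ug must be > 0")
        if self.detector_ceiling <= 0:
            raise ValidationError("detector_ceiling must be > 0")
        if not 0 < self.linearity_tolerance < 1:
            raise ValidationError("linearity_tolerance must be in (0, 1)")
        if self.min_linear_wells < 2:
            raise ValidationError("min_linear_wells must be >= 2")
        if self.log_base not in ("natural", "base10"):
            raise ValidationError("log_base must be 'natural' or 'base10'")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")
        if self.halflife_h <= 0:
            raise ValidationError("halflife_h must be > 0")
        if self.z_95 <= 0:
            raise ValidationError("z_95 must be > 0")
        if self.step_factor <= 1:
            raise ValidationError("step_factor must be > 1")
        if self.comparison_test not in ("paired", "welch"):
            raise ValidationError("comparison_test must be 'paired' or 'welch'")
        if self.p_adjust not in ("none", "bonferroni", "bh"):
            raise ValidationError("p_adjust must be 'none', 'bonferroni' or 'bh'")

    @classmethod
    def from_json(cls, path: str | Path) -> "StudyConfig":
        """Load a configuration from a JSON file; all keys optional."""
        with open(path) as fh:
            raw = json.load(fh)
        if not isinstance(raw, dict):
            raise FormatError(f"config file {path} must hold a JSON object")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise FormatError(
                f"unknown config key(s): {', '.join(sorted(unknown))}"
            )
        return cls(**raw)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


# ---------------------------------------------------------------------------
# Domain records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WellMeasurement:
    """One well of a 96-well plate: a sample at one dilution step."""

    plate_id: str
    row: str
    col: int
    sample_id: str
    dilution_index: int
    intensity: float
    saturated: bool = False

    def __post_init__(self) -> None:
        if self.row not in PLATE_ROWS:
            raise ValidationError(f"row must be A-H, got {self.row!r}")
        if self.col not in PLATE_COLS:
            raise ValidationError(f"col must be 1-12, got {self.col!r}")
        if self.dilution_index < 0:
            raise ValidationError("dilution_index must be >= 0")
        if self.intensity < 0:
            raise ValidationError(
                f"negative intensity {self.intensity} in well "
                f"{self.plate_id}/{self.row}{self.col}"
            )


@dataclass(frozen=True)
class DilutionSeries:
    """Ordered 1:2 (by default) dilution series of one sample.

    ``dilution_index`` 0 is the undiluted lysate; the concentration in well
    k is ``lysate concentration / step_factor**k``.
    """

    sample_id: str
    wells: tuple[WellMeasurement, ...]
    step_factor: float = 2.0

    def __post_init__(self) -> None:
        if not self.wells:
            raise ValidationError(f"series {self.sample_id}: no wells")
        if self.step_factor <= 1:
            raise ValidationError("step_factor must be > 1")
        idx = [w.dilution_index for w in self.wells]
        if any(w.sample_id != self.sample_id for w in self.wells):
            raise ValidationError(
                f"series {self.sample_id}: wells with foreign sample_id"
            )
        if len(set(idx)) != len(idx):
            raise ValidationError(
                f"series {self.sample_id}: duplicate dilution_index"
            )
        if idx != sorted(idx):
            raise ValidationError(
                f"series {self.sample_id}: wells not sorted by dilution_index"
            )

    @property
    def indices(self) -> tuple[int, ...]:
        return tuple(w.dilution_index for w in self.wells)

    @property
    def intensities(self) -> tuple[float, ...]:
        return tuple(w.intensity for w in self.wells)


@dataclass(frozen=True)
class TissueSample:
    """One tissue half (identity, weight, lysate volume, modality)."""

    sample_id: str
    mouse_id: str
    organ: str
    half_weight_g: float
    lysate_volume_mL: float
    modality: str
    predilution: float = 1.0

    def __post_init__(self) -> None:
        if self.half_weight_g <= 0:
            raise ValidationError(
                f"sample {self.sample_id}: half_weight_g must be > 0"
            )
        if self.lysate_volume_mL <= 0:
            raise ValidationError(
                f"sample {self.sample_id}: lysate_volume_mL must be > 0"
            )
        if self.modality not in MODALITIES:
            raise ValidationError(
                f"sample {self.sample_id}: modality must be one of {MODALITIES}"
            )
        if self.predilution <= 0:
            raise ValidationError(
                f"sample {self.sample_id}: predilution must be > 0"
            )
        if self.organ not in KNOWN_ORGANS:
            logger.warning(
                "sample %s: organ %r is not in the standard panel "
                "(accepted as-is)",
                self.sample_id,
                self.organ,
            )


@dataclass(frozen=True)
class GammaMeasurement:
    """One gamma-well-counter reading with its injected-dose standard."""

    sample_id: str
    counts_per_minute: float
    count_time_h: float
    standard_counts_per_minute: float
    standard_time_h: float

    def __post_init__(self) -> None:
        if self.counts_per_minute < 0:
            raise ValidationError(
                f"sample {self.sample_id}: counts_per_minute must be >= 0"
            )
        if self.count_time_h < 0 or self.standard_time_h < 0:
            raise ValidationError(
                f"sample {self.sample_id}: count times must be >= 0"
            )
        if self.standard_counts_per_minute <= 0:
            raise ValidationError(
                f"sample {self.sample_id}: standard_counts_per_minute must be > 0"
            )


# ---------------------------------------------------------------------------
# CSV readers / writers
# ---------------------------------------------------------------------------

PLATE_COLUMNS = ["plate_id", "row", "col", "sample_id", "dilution_index", "intensity"]
MANIFEST_COLUMNS = [
    "sample_id",
    "mouse_id",
    "organ",
    "half_weight_g",
    "lysate_volume_mL",
    "modality",
]
GAMMA_COLUMNS = [
    "sample_id",
    "counts_per_minute",
    "count_time_h",
    "standard_counts_per_minute",
    "standard_time_h",
]
STANDARDS_COLUMNS = [
    "sample_id",
    "dilution_index",
    "known_concentration_ug_per_mL",
    "intensity",
]
ROI_COLUMNS = ["mouse_id", "tumor_roi_mean", "background_roi_mean"]


def _read_csv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"file not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )
    return df


def wells_from_frame(df: pd.DataFrame) -> list[WellMeasurement]:
    """Validate a long-format plate table into well records."""
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"plate table: missing column(s): {', '.join(missing)}")
    has_sat = "saturated" in df.columns
    wells: list[WellMeasurement] = []
    seen: set[tuple[str, str, int]] = set()
    for rec in df.itertuples(index=False):
        key = (str(rec.plate_id), str(rec.row), int(rec.col))
        if key in seen:
            raise ValidationError(
                f"duplicate well {key[1]}{key[2]} on plate {key[0]}"
            )
        seen.add(key)
        wells.append(
            WellMeasurement(
                plate_id=str(rec.plate_id),
                row=str(rec.row),
                col=int(rec.col),
                sample_id=str(rec.sample_id),
                dilution_index=int(rec.dilution_index),
                intensity=float(rec.intensity),
                saturated=bool(rec.saturated) if has_sat else False,
            )
        )
    return wells


def read_plate_csv(path: str | Path) -> list[WellMeasurement]:
    """Read a long-format plate CSV (one row per well).

    The optional ``saturated`` column is honoured when present; otherwise
    saturation is left unset here and flagged downstream against the
    detector ceiling.
    """
    return wells_from_frame(_read_csv(path, PLATE_COLUMNS))


def write_plate_csv(path: str | Path, wells: Iterable[WellMeasurement]) -> None:
    df = pd.DataFrame([dataclasses.asdict(w) for w in wells])
    df.to_csv(path, index=False)


def manifest_from_frame(df: pd.DataFrame) -> list[TissueSample]:
    """Validate a manifest table into tissue-half records."""
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(
            f"manifest table: missing column(s): {', '.join(missing)}"
        )
    has_pre = "predilution" in df.columns
    samples: list[TissueSample] = []
    seen: set[tuple[str, str]] = set()
    for rec in df.itertuples(index=False):
        key = (str(rec.sample_id), str(rec.modality))
        if key in seen:
            raise ValidationError(
                f"duplicate manifest entry for sample {key[0]} / {key[1]}"
            )
        seen.add(key)
        samples.append(
            TissueSample(
                sample_id=str(rec.sample_id),
                mouse_id=str(rec.mouse_id),
                organ=str(rec.organ),
                half_weight_g=float(rec.half_weight_g),
                lysate_volume_mL=float(rec.lysate_volume_mL),
                modality=str(rec.modality),
                predilution=float(rec.predilution) if has_pre else 1.0,
            )
        )
    return samples


def read_manifest_csv(path: str | Path) -> list[TissueSample]:
    """Read the tissue manifest (one row per tissue half).

    An optional ``predilution`` column gives a per-sample factor applied
    before the lysate was loaded into well 0 (default 1 = neat lysate).
    """
    return manifest_from_frame(_read_csv(path, MANIFEST_COLUMNS))


def write_manifest_csv(path: str | Path, samples: Iterable[TissueSample]) -> None:
    df = pd.DataFrame([dataclasses.asdict(s) for s in samples])
    df.to_csv(path, index=False)


def gamma_from_frame(df: pd.DataFrame) -> list[GammaMeasurement]:
    """Validate a gamma-counter table into measurement records."""
    missing = [c for c in GAMMA_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"gamma table: missing column(s): {', '.join(missing)}")
    out: list[GammaMeasurement] = []
    seen: set[str] = set()
    for rec in df.itertuples(index=False):
        sid = str(rec.sample_id)
        if sid in seen:
            raise ValidationError(f"duplicate gamma measurement for {sid}")
        seen.add(sid)
        out.append(
            GammaMeasurement(
                sample_id=sid,
                counts_per_minute=float(rec.counts_per_minute),
                count_time_h=float(rec.count_time_h),
                standard_counts_per_minute=float(rec.standard_counts_per_minute),
                standard_time_h=float(rec.standard_time_h),
            )
        )
    return out


def read_gamma_csv(path: str | Path) -> list[GammaMeasurement]:
    return gamma_from_frame(_read_csv(path, GAMMA_COLUMNS))


def write_gamma_csv(path: str | Path, meas: Iterable[GammaMeasurement]) -> None:
    df = pd.DataFrame([dataclasses.asdict(m) for m in meas])
    df.to_csv(path, index=False)


def read_standards_csv(path: str | Path) -> pd.DataFrame:
    """Read the standard (injected probe) dilution series.

    Columns: sample_id, dilution_index, known_concentration_ug_per_mL,
    intensity. Returns a validated DataFrame.
    """
    df = _read_csv(path, STANDARDS_COLUMNS)
    if (df["known_concentration_ug_per_mL"] < 0).any():
        raise ValidationError("standards: negative known concentration")
    if (df["intensity"] < 0).any():
        raise ValidationError("standards: negative intensity")
    if df.duplicated(subset=["sample_id", "dilution_index"]).any():
        raise ValidationError("standards: duplicate (sample_id, dilution_index)")
    return df.copy()


def read_roi_csv(path: str | Path) -> pd.DataFrame:
    """Read per-mouse region-of-interest mean intensities (tumor, background)."""
    df = _read_csv(path, ROI_COLUMNS)
    if (df["background_roi_mean"] <= 0).any():
        raise ValidationError("ROI table: background_roi_mean must be > 0")
    return df.copy()


# ---------------------------------------------------------------------------
# Grouping
# ---------------------------------------------------------------------------


def group_series(
    wells: Sequence[WellMeasurement], step_factor: float = 2.0
) -> list[DilutionSeries]:
    """Partition validated wells into per-sample dilution series.

    Every input well appears in exactly one output series; wells are sorted
    by dilution_index. Gaps in the index sequence are permitted but logged.
    """
    by_sample: dict[str, list[WellMeasurement]] = {}
    for w in wells:
        by_sample.setdefault(w.sample_id, []).append(w)
    out: list[DilutionSeries] = []
    for sid in sorted(by_sample):
        group = sorted(by_sample[sid], key=lambda w: w.dilution_index)
        idx = [w.dilution_index for w in group]
        if len(set(idx)) != len(idx):
            dup = sorted({i for i in idx if idx.count(i) > 1})
            raise ValidationError(
                f"sample {sid}: duplicate dilution_index {dup}"
            )
        expected = set(range(idx[0], idx[-1] + 1))
        gaps = sorted(expected - set(idx))
        if gaps:
            logger.warning(
                "sample %s: gap(s) in dilution_index at %s", sid, gaps
            )
        out.append(DilutionSeries(sample_id=sid, wells=tuple(group), step_factor=step_factor))
    return out


def check_cross_references(
    wells: Sequence[WellMeasurement], manifest: Sequence[TissueSample]
) -> list[str]:
    """Return plate sample ids absent from the IR manifest (also logged)."""
    manifest_ids = {s.sample_id for s in manifest if s.modality == "IR"}
    missing = sorted({w.sample_id for w in wells} - manifest_ids)
    for sid in missing:
        logger.warning("plate sample %s has no IR manifest entry", sid)
    return missing


def subtract_blank(
    wells: Sequence[WellMeasurement], blank_sample_id: str
) -> list[WellMeasurement]:
    """Per-plate blank subtraction (optional; clamps at zero).

    The mean intensity of the blank sample's wells on each plate is
    subtracted from every other well on that plate. Blank wells themselves
    are dropped from the result.
    """
    import numpy as np

    blank_mean: dict[str, float] = {}
    for plate in {w.plate_id for w in wells}:
        blanks = [
            w.intensity
            for w in wells
            if w.plate_id == plate and w.sample_id == blank_sample_id
        ]
        blank_mean[plate] = float(np.mean(blanks)) if blanks else 0.0
    out = []
    for w in wells:
        if w.sample_id == blank_sample_id:
            continue
        out.append(
            dataclasses.replace(
                w, intensity=max(0.0, w.intensity - blank_mean[w.plate_id])
            )
        )
    return out
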