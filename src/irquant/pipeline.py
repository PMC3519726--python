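"""Convenience orchestration over the whole quantification workflow."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .agreement import AgreementResult, PairedSample, bland_altman, make_pairs
from .biodistribution import (
    OrganComparison,
    OrganSummary,
    UptakeRecord,
    compare_methods,
    gamma_uptake,
    ir_uptake_from_plates,
    summarize,
)
from .core import (
    StudyConfig,
    gamma_from_frame,
    manifest_from_frame,
    wells_from_frame,
)
from .synthetic import SimulatedStudy


@dataclass(frozen=True)
class StudyAnalysis:
    """Everything the quantify + summarize + agree workflow produces."""

    ir_records: list[UptakeRecord]
    gamma_records: list[UptakeRecord]
    summaries: list[OrganSummary]
    comparisons: list[OrganComparison]
    pairs: list[PairedSample]
    agreement: AgreementResult


def analyze_tables(
    plate: pd.DataFrame,
    manifest: pd.DataFrame,
    standards: pd.DataFrame,
    gamma: pd.DataFrame,
    cfg: StudyConfig | None = None,
) -> StudyAnalysis:
    """Run quantify, summarize and agree on in-memory study tables."""
    cfg = cfg or StudyConfig()
    wells = wells_from_frame(plate)
    samples = manifest_from_frame(manifest)
    ir_records, _ = ir_uptake_from_plates(wells, samples, standards, cfg)
    gamma_records = gamma_uptake(gamma_from_frame(gamma), samples, cfg)
    pairs = make_pairs(ir_records, gamma_records)
    return StudyAnalysis(
        ir_records=ir_records,
        gamma_records=gamma_records,
        summaries=summarize(ir_records + gamma_records),
        comparisons=compare_methods(ir_records + gamma_records, cfg),
        pairs=pairs,
        agreement=bland_altman(pairs, cfg),
    )


def analyze_simulated_study(
    study: SimulatedStudy, cfg: StudyConfig | None = None
) -> StudyAnalysis:
    """Run the full workflow on a synthetic study's tables."""
    cfg = cfg or StudyConfig(detector_ceiling=study.params.detector_ceiling)
    return analyze_tables(
        study.plate, study.manifest, study.standards, study.gamma, cfg
    )
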