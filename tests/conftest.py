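import pytest

from irquant import DilutionSeries, StudyConfig, WellMeasurement


@pytest.fixture
def cfg() -> StudyConfig:
    return StudyConfig()


def make_series(
    intensities,
    sample_id="s1",
    step_factor=2.0,
    plate_id="P1",
    col=1,
    saturated=None,
):
    """Build a dilution series from a top-to-bottom intensity list."""
    saturated = saturated or [False] * len(intensities)
    wells = tuple(
        WellMeasurement(
            plate_id=plate_id,
            row="ABCDEFGH"[k % 8],
            col=col + k // 8,
            sample_id=sample_id,
            dilution_index=k,
            intensity=float(i),
            saturated=bool(s),
        )
        for k, (i, s) in enumerate(zip(intensities, saturated))
    )
    return DilutionSeries(sample_id=sample_id, wells=wells, step_factor=step_factor)
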