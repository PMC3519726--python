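"""Saturation flagging, linear-range selection, calibration, inversion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import irquant as iq
from conftest import make_series
from _oracles import ols_oracle


# ---------------------------------------------------------------------------
# flag_saturation
# ---------------------------------------------------------------------------


def test_flag_saturation_marks_ceiling_wells():
    series = make_series([4095, 2000])
    flagged = iq.flag_saturation(series, ceiling=4095)
    assert [w.saturated for w in flagged.wells] == [True, False]


def test_flag_saturation_below_ceiling_no_flags():
    flagged = iq.flag_saturation(make_series([100, 50, 25]), ceiling=4095)
    assert not any(w.saturated for w in flagged.wells)


def test_flag_saturation_idempotent():
    series = make_series([5000, 4095, 100])
    once = iq.flag_saturation(series, ceiling=4095)
    twice = iq.flag_saturation(once, ceiling=4095)
    assert once == twice


# ---------------------------------------------------------------------------
# select_linear_range
# ---------------------------------------------------------------------------


def test_exact_doubling_series_fully_retained(cfg):
    series = make_series([800, 400, 200, 100, 50])
    rng = iq.select_linear_range(iq.flag_saturation(series, cfg.detector_ceiling), cfg)
    assert rng.retained_indices == (0, 1, 2, 3, 4)
    assert rng.excluded_indices == {}


def test_saturated_then_linear_series(cfg):
    # hand-evaluated walk: indices 0,1 saturated at 4095; ratios from the
    # dilute end 830/415, 1650/830, 3200/1650 all inside 2*(1 +/- 0.15)
    series = make_series([4095, 4095, 3200, 1650, 830, 415])
    series = iq.flag_saturation(series, ceiling=4095)
    rng = iq.select_linear_range(series, cfg)
    assert rng.retained_indices == (2, 3, 4, 5)
    assert rng.excluded_indices == {0: "saturated", 1: "saturated"}


def test_quench_bend_cut_as_nonlinear_high(cfg):
    # top ratio 1500/1000 = 1.5 < 1.7 violates; the rest double exactly
    series = make_series([1500, 1000, 500, 250, 125])
    rng = iq.select_linear_range(series, cfg)
    assert rng.retained_indices == (1, 2, 3, 4)
    assert rng.excluded_indices == {0: "nonlinear_high"}


def test_all_saturated_raises_linear_range_error(cfg):
    series = iq.flag_saturation(make_series([4095] * 6), ceiling=4095)
    with pytest.raises(iq.LinearRangeError, match="s1"):
        iq.select_linear_range(series, cfg)


def test_min_linear_wells_enforced(cfg):
    series = make_series([900, 400, 100])  # 400/100 = 4, violates at once
    with pytest.raises(iq.LinearRangeError):
        iq.select_linear_range(series, cfg)


@settings(max_examples=60, deadline=None)
@given(
    noise=st.lists(st.floats(0.9, 1.1), min_size=4, max_size=8),
    ceiling_lo=st.floats(500, 2000),
    ceiling_boost=st.floats(1, 3000),
)
def test_raising_ceiling_never_shrinks_retained_set(noise, ceiling_lo, ceiling_boost):
    intensities = [3200 / 2**k * f for k, f in enumerate(noise)]
    cfg = iq.StudyConfig(min_linear_wells=2)
    series = make_series(intensities)

    def retained(ceiling):
        try:
            flagged = iq.flag_saturation(series, ceiling)
            return set(iq.select_linear_range(flagged, cfg).retained_indices)
        except iq.LinearRangeError:
            return set()

    assert retained(ceiling_lo) <= retained(ceiling_lo + ceiling_boost)


@settings(max_examples=60, deadline=None)
@given(
    noise=st.lists(st.floats(0.9, 1.1), min_size=4, max_size=8),
    tol_small=st.floats(0.02, 0.15),
    tol_extra=st.floats(0.0, 0.5),
)
def test_tightening_tolerance_never_grows_retained_set(noise, tol_small, tol_extra):
    intensities = [3200 / 2**k * f for k, f in enumerate(noise)]
    series = make_series(intensities)

    def retained(tol):
        cfg = iq.StudyConfig(min_linear_wells=2, linearity_tolerance=min(tol, 0.99))
        try:
            return set(iq.select_linear_range(series, cfg).retained_indices)
        except iq.LinearRangeError:
            return set()

    assert retained(tol_small) <= retained(tol_small + tol_extra)


# ---------------------------------------------------------------------------
# fit_calibration / invert_calibration
# ---------------------------------------------------------------------------


def test_fit_exact_line():
    pts = [(8, 8050), (4, 4050), (2, 2050), (1, 1050), (0.5, 550)]
    curve = iq.fit_calibration(pts)
    assert curve.slope == pytest.approx(1000.0)
    assert curve.intercept == pytest.approx(50.0)
    assert curve.r_squared == pytest.approx(1.0)
    assert curve.lod_intensity == pytest.approx(curve.intercept)


def test_fit_two_points():
    curve = iq.fit_calibration([(1, 100), (2, 200)])
    assert curve.slope == pytest.approx(100.0)
    assert curve.intercept == pytest.approx(0.0, abs=1e-12)
    assert curve.residual_sd == 0.0


def test_fit_matches_normal_equations_oracle():
    rng = np.random.default_rng(42)
    for _ in range(20):
        conc = rng.uniform(0.1, 10, size=6)
        inten = 900 * conc + 30 + rng.normal(0, 20, size=6)
        curve = iq.fit_calibration(list(zip(conc, inten)))
        slope, intercept, r2, resid_sd, _ = ols_oracle(conc, inten)
        assert curve.slope == pytest.approx(slope, rel=1e-10)
        assert curve.intercept == pytest.approx(intercept, rel=1e-10)
        assert curve.r_squared == pytest.approx(r2, rel=1e-10)
        assert curve.residual_sd == pytest.approx(resid_sd, rel=1e-10)


def test_fit_rejects_degenerate_standards():
    with pytest.raises(iq.FitError):
        iq.fit_calibration([(1, 100)])
    with pytest.raises(iq.FitError, match="slope"):
        iq.fit_calibration([(1, 200), (2, 100), (3, 10)])


def test_inversion_examples():
    curve = iq.fit_calibration([(8, 8050), (4, 4050), (2, 2050), (1, 1050), (0.5, 550)])
    assert iq.invert_calibration(curve, 1050).concentration_ug_per_mL == pytest.approx(1.0)
    at_intercept = iq.invert_calibration(curve, 50)
    assert at_intercept.concentration_ug_per_mL == pytest.approx(0.0, abs=1e-12)
    below = iq.invert_calibration(curve, 40)
    assert below.concentration_ug_per_mL == 0.0
    assert below.clamped


def test_inversion_flags_below_lod():
    rng = np.random.default_rng(0)
    conc = np.linspace(0.5, 8, 8)
    inten = 1000 * conc + 50 + rng.normal(0, 40, size=8)
    curve = iq.fit_calibration(list(zip(conc, inten)))
    assert curve.lod_intensity > curve.intercept
    assert iq.invert_calibration(curve, curve.lod_intensity * 0.9).below_lod
    assert not iq.invert_calibration(curve, curve.lod_intensity * 1.1).below_lod


def test_fit_invert_mutually_inverse_on_exact_line():
    pts = [(8, 8050), (4, 4050), (2, 2050), (1, 1050), (0.5, 550)]
    curve = iq.fit_calibration(pts)
    for c, i in pts:
        assert iq.invert_calibration(curve, i).concentration_ug_per_mL == pytest.approx(
            c, rel=1e-12
        )


# ---------------------------------------------------------------------------
# estimate_lysate_concentration
# ---------------------------------------------------------------------------


def _unit_curve():
    return iq.CalibrationCurve(
        slope=1.0,
        intercept=0.0,
        r_squared=1.0,
        residual_sd=0.0,
        lod_intensity=0.0,
        fit_range=(0.0, 10.0),
        n_points=2,
    )


def test_estimate_consistent_wells(cfg):
    series = make_series([2.0, 1.0, 0.5])
    rng = iq.select_linear_range(series, cfg)
    est = iq.estimate_lysate_concentration(series, rng, _unit_curve())
    assert est.lysate_concentration_ug_per_mL == pytest.approx(2.0)
    assert est.cv == pytest.approx(0.0)
    assert est.n_wells_used == 3


def test_estimate_cv_hand_formula(cfg):
    # per-well lysate estimates 1.8, 2.0, 2.2 -> mean 2.0, cv = sd/mean = 0.1
    series = make_series([1.8, 1.0, 0.55])
    cfg_loose = iq.StudyConfig(linearity_tolerance=0.3)
    rng = iq.select_linear_range(series, cfg_loose)
    est = iq.estimate_lysate_concentration(series, rng, _unit_curve())
    assert est.lysate_concentration_ug_per_mL == pytest.approx(2.0)
    assert est.cv == pytest.approx(0.1)
    assert est.per_well_estimates == ((0, 1.8), (1, 2.0), (2, pytest.approx(2.2)))


def test_estimate_noiseless_simulation_closure(cfg):
    """Noiseless, unquenched, unsaturated series recovers truth to 1e-9."""
    params = iq.SimulationParams(
        intensity_noise_cv=0.0, quench_K=1e12, detector_ceiling=1e12
    )
    truth = 3.7
    rng = np.random.default_rng(0)
    intensities = iq.simulate_dilution_series(truth, params, rng)
    series = make_series(list(intensities))
    lin = iq.select_linear_range(series, cfg)
    curve = iq.CalibrationCurve(
        slope=params.detector_gain,
        intercept=0.0,
        r_squared=1.0,
        residual_sd=0.0,
        lod_intensity=0.0,
        fit_range=(0.0, 10.0),
        n_points=2,
    )
    est = iq.estimate_lysate_concentration(series, lin, curve)
    assert est.lysate_concentration_ug_per_mL == pytest.approx(truth, rel=1e-9)
    spread = [v for _, v in est.per_well_estimates]
    assert max(spread) - min(spread) <= 1e-9 * truth


def test_estimate_all_below_lod_flags_zero(cfg):
    series = make_series([2.0, 1.0, 0.5])
    rng = iq.select_linear_range(series, cfg)
    dim_curve = iq.CalibrationCurve(
        slope=1.0,
        intercept=0.0,
        r_squared=1.0,
        residual_sd=10.0,
        lod_intensity=30.0,
        fit_range=(0.0, 10.0),
        n_points=5,
    )
    est = iq.estimate_lysate_concentration(series, rng, dim_curve)
    assert est.lysate_concentration_ug_per_mL == 0.0
    assert "below_lod" in est.flags
    assert est.n_wells_used == 0


def test_quenching_guard_full_series_underestimates(cfg):
    """With quench + ceiling, the all-wells estimate sits below the
    linear-range estimate, which is close to truth."""
    params = iq.SimulationParams()
    truth = 50.0
    rng = np.random.default_rng(3)
    series = make_series(list(iq.simulate_dilution_series(truth, params, rng)))
    series = iq.flag_saturation(series, params.detector_ceiling)
    curve = iq.CalibrationCurve(
        slope=params.detector_gain,
        intercept=0.0,
        r_squared=1.0,
        residual_sd=0.0,
        lod_intensity=0.0,
        fit_range=(0.0, 10.0),
        n_points=2,
    )
    lin = iq.select_linear_range(series, cfg)
    est_linear = iq.estimate_lysate_concentration(series, lin, curve)
    all_range = iq.LinearRange(
        sample_id=series.sample_id,
        retained_indices=series.indices,
        excluded_indices={},
    )
    est_all = iq.estimate_lysate_concentration(series, all_range, curve)
    assert est_all.lysate_concentration_ug_per_mL < est_linear.lysate_concentration_ug_per_mL
    assert est_linear.lysate_concentration_ug_per_mL == pytest.approx(truth, rel=0.05)
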