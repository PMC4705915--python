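"""Sigmoid fitting, reactivity and vascular reserves."""

import dataclasses

import numpy as np
import pytest

import cvreact as cv
from cvreact.errors import ValidationError
from cvreact.sigmoid import DEFAULT_BOUNDS


def test_fixed_minimum_constant_plateau(sl_processed):
    """Hyperventilation held at the constriction floor gives it back."""
    assert cv.fixed_minimum(sl_processed) == pytest.approx(-40.0, abs=1e-9)


def test_fixed_minimum_requires_segment(sl_noiseless):
    trial = cv.simulate_trial(sl_noiseless)
    keep = trial.segment != "hyperventilation"
    clipped = cv.RebreathingTrial(
        subject_id="t",
        condition="SL",
        time_s=trial.time_s[keep],
        petco2_mmHg=trial.petco2_mmHg[keep],
        peto2_mmHg=trial.peto2_mmHg[keep],
        mcav_cm_s=trial.mcav_cm_s[keep],
        abp_mmHg=trial.abp_mmHg[keep],
        segment=trial.segment[keep],
    )
    proc = cv.normalize_mcav(clipped)
    with pytest.raises(ValidationError):
        cv.fixed_minimum(proc)


@pytest.mark.parametrize(
    "condition, amplitude, midpoint, rng",
    [("SL", 95.0, 36.5, 5.9), ("ALT1", 129.0, 35.4, 4.5), ("ALT16", 177.0, 28.6, 4.2)],
)
def test_noiseless_fit_recovers_group_means(analyze_noiseless, condition, amplitude, midpoint, rng):
    """Noiseless generated trials refit to their generating parameters."""
    rec = analyze_noiseless(condition)
    assert rec["amplitude_pct"] == pytest.approx(amplitude, abs=1e-3)
    assert rec["midpoint_mmHg"] == pytest.approx(midpoint, abs=1e-3)
    assert rec["range_mmHg"] == pytest.approx(rng, abs=1e-3)
    assert rec["r_squared"] == pytest.approx(1.0, abs=1e-9)
    assert rec["converged"]


def test_slope_parameterized_reactivity_recovery():
    """A trial generated at reactivity 10.3 %/mmHg refits to 10.3."""
    sc = cv.TrialScenario.with_slope(
        10.3, 177.0, midpoint_mmHg=28.6, resting_petco2_mmHg=23.0, condition="ALT16"
    ).noiseless(sample_rate_hz=1.0)
    rec = cv.analyze_trial(cv.simulate_trial(sc))
    assert rec["reactivity_pct_per_mmHg"] == pytest.approx(10.3, abs=1e-6)


def test_reactivity_identity_and_derivative(sl_processed):
    """reactivity == amplitude/(4*range) and equals the numerical slope of
    the fitted sigmoid at its midpoint."""
    x, y = sl_processed.pairs("rebreathe")
    f = cv.fit(x, y, cv.fixed_minimum(sl_processed))
    assert f.reactivity_pct_per_mmHg == f.amplitude_pct / (4.0 * f.range_mmHg)
    h = 1e-5
    num = (f.predict(f.midpoint_mmHg + h) - f.predict(f.midpoint_mmHg - h)) / (2 * h)
    assert num == pytest.approx(f.reactivity_pct_per_mmHg, rel=1e-6)


def test_degenerate_flat_response_flagged():
    x = np.linspace(18, 50, 40)
    y = np.full_like(x, -40.0)
    f = cv.fit(x, y, -40.0)
    assert not f.converged
    assert f.amplitude_pct < 1e-3  # pinned at the no-response floor
    assert f.amplitude_pct >= DEFAULT_BOUNDS[0][0]


def test_fit_preconditions():
    with pytest.raises(ValidationError):
        cv.fit(np.linspace(18, 50, 5), np.zeros(5), -40.0)  # too few points
    with pytest.raises(ValidationError):
        cv.fit(np.linspace(30, 34, 20), np.zeros(20), -40.0)  # span < 8


def test_censoring_robustness(scenarios, analyze_noiseless):
    """Dropping data above the upper plateau barely moves the midpoint."""
    rec_full = analyze_noiseless("SL")
    sc = scenarios["SL"].noiseless(sample_rate_hz=1.0)
    proc = cv.normalize_mcav(cv.simulate_trial(sc))
    x, y = proc.pairs("rebreathe")
    keep = x <= sc.midpoint_mmHg + 2 * sc.range_mmHg
    f = cv.fit(x[keep], y[keep], cv.fixed_minimum(proc))
    assert abs(f.midpoint_mmHg - rec_full["midpoint_mmHg"]) < 0.2


def test_noisy_parameter_recovery(scenarios):
    """100 noisy trials (5 % MCAv noise): midpoint MAE <= 0.5 mmHg and
    reactivity MAE <= 10 % relative."""
    sc0 = scenarios["SL"]
    true_react = sc0.amplitude_pct / (4 * sc0.range_mmHg)
    mid_err, rea_err = [], []
    for seed in range(1, 101):
        sc = dataclasses.replace(sc0, seed=seed, sample_rate_hz=1.0)
        rec = cv.analyze_trial(cv.simulate_trial(sc))
        mid_err.append(abs(rec["midpoint_mmHg"] - sc0.midpoint_mmHg))
        rea_err.append(abs(rec["reactivity_pct_per_mmHg"] - true_react) / true_react)
    assert np.mean(mid_err) <= 0.5
    assert np.mean(rea_err) <= 0.10


def test_linear_reactivity_close_to_analytic(sl_processed):
    x, y = sl_processed.pairs("rebreathe")
    f = cv.fit(x, y, cv.fixed_minimum(sl_processed))
    linear = cv.linear_reactivity(x, y, f)
    # the central chord is slightly shallower than the tangent at the midpoint
    assert linear == pytest.approx(f.reactivity_pct_per_mmHg, rel=0.10)


def test_reserves_worked_example():
    """minimum -40, amplitude 95, midpoint 36.5, range 5.9, resting 40,
    no threshold: constriction 61.2 %, dilation 33.8 %."""
    f = cv.SigmoidFit(
        minimum_pct=-40.0, amplitude_pct=95.0, midpoint_mmHg=36.5, range_mmHg=5.9,
        r_squared=1.0, n_points=97, converged=True,
    )
    res = cv.compute_reserves(f, 40.0, None)
    assert res.constriction_pct == pytest.approx(61.2, abs=0.05)
    assert res.dilation_pct == pytest.approx(33.8, abs=0.05)
    assert res.constriction_pct + res.dilation_pct == pytest.approx(95.0, abs=1e-9)


def test_reserves_symmetry_and_boundaries():
    f = cv.SigmoidFit(
        minimum_pct=-40.0, amplitude_pct=95.0, midpoint_mmHg=36.5, range_mmHg=5.9,
        r_squared=1.0, n_points=97, converged=True,
    )
    # resting at the midpoint: both reserves are amplitude/2
    res = cv.compute_reserves(f, 36.5, None)
    assert res.constriction_pct == pytest.approx(47.5, abs=1e-9)
    assert res.dilation_pct == pytest.approx(47.5, abs=1e-9)
    # threshold at resting PETCO2: no dilation reserve left
    thr = cv.AbpThreshold(40.0, 0.0, 1.2, 0.0, detected=True)
    assert cv.compute_reserves(f, 40.0, thr).dilation_pct == pytest.approx(0.0, abs=1e-9)
    with pytest.raises(ValidationError):
        cv.compute_reserves(f, 65.0, None)


def test_fit_minimum_option(sl_processed):
    """Freeing the minimum still recovers it on noiseless data."""
    x, y = sl_processed.pairs("rebreathe")
    f = cv.fit(x, y, 0.0, fit_minimum=True)
    assert f.minimum_fitted
    assert f.minimum_pct == pytest.approx(-40.0, abs=1e-2)
    assert f.midpoint_mmHg == pytest.approx(36.5, abs=1e-2)
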