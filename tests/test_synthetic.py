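"""Generator contracts: protocol shape, logistic ground truth, determinism."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import cvreact as cv
from cvreact.errors import ConfigurationError


def test_logistic_half_amplitude_at_midpoint(sl_noiseless):
    """MCAv% at the sigmoid midpoint is minimum + amplitude/2, and the
    generated ramp lies exactly on the logistic."""
    sc = sl_noiseless
    assert cv.logistic_pct(
        sc.midpoint_mmHg, sc.minimum_pct, sc.amplitude_pct, sc.midpoint_mmHg, sc.range_mmHg
    ) == pytest.approx(-40 + 95 / 2, abs=1e-12)
    trial = cv.simulate_trial(sc)
    m = trial.segment_mask("rebreathe")
    pct = 100.0 * (trial.mcav_cm_s[m] / sc.resting_mcav_cm_s - 1.0)
    expected = cv.logistic_pct(
        trial.petco2_mmHg[m], sc.minimum_pct, sc.amplitude_pct, sc.midpoint_mmHg, sc.range_mmHg
    )
    np.testing.assert_allclose(pct, expected, atol=1e-9)


def test_slope_parameterization_range_and_derivative():
    """range = amplitude/(4*slope); the generated curve's numerical slope at
    the midpoint equals the requested reactivity."""
    sc = cv.TrialScenario.with_slope(7.5, 129.0, midpoint_mmHg=35.4).noiseless(
        sample_rate_hz=1.0
    )
    assert sc.range_mmHg == pytest.approx(4.3, abs=1e-12)
    h = 1e-4
    num = (
        cv.logistic_pct(sc.midpoint_mmHg + h, sc.minimum_pct, sc.amplitude_pct,
                        sc.midpoint_mmHg, sc.range_mmHg)
        - cv.logistic_pct(sc.midpoint_mmHg - h, sc.minimum_pct, sc.amplitude_pct,
                          sc.midpoint_mmHg, sc.range_mmHg)
    ) / (2 * h)
    assert num == pytest.approx(7.5, rel=1e-6)


def test_trial_determinism(scenarios):
    sc = dataclasses.replace(scenarios["SL"], seed=7, sample_rate_hz=1.0)
    a = cv.simulate_trial(sc)
    b = cv.simulate_trial(sc)
    assert np.array_equal(a.mcav_cm_s, b.mcav_cm_s)
    assert np.array_equal(a.abp_mmHg, b.abp_mmHg)
    c = cv.simulate_trial(dataclasses.replace(sc, seed=8))
    assert not np.array_equal(a.mcav_cm_s, c.mcav_cm_s)


def test_protocol_segments(sl_noiseless):
    trial = cv.simulate_trial(sl_noiseless)
    rest = trial.segment_mask("rest")
    hv = trial.segment_mask("hyperventilation")
    reb = trial.segment_mask("rebreathe")
    assert np.all(trial.petco2_mmHg[rest] == sl_noiseless.resting_petco2_mmHg)
    assert np.all(trial.petco2_mmHg[hv] == sl_noiseless.hypocapnic_plateau_mmHg)
    ramp = trial.petco2_mmHg[reb]
    assert np.all(np.diff(ramp) >= 0)
    assert ramp[-1] == pytest.approx(sl_noiseless.ramp_end_mmHg)
    assert np.all(trial.peto2_mmHg > 250.0)


@pytest.mark.parametrize(
    "field, value",
    [
        ("amplitude_pct", -1.0),
        ("range_mmHg", 0.0),
        ("sample_rate_hz", 0.0),
        ("midpoint_mmHg", 10.0),  # below the hypocapnic plateau
        ("t_abp_mmHg", 10.0),  # outside (plateau, ramp_end]
    ],
)
def test_invalid_scenario_names_field(field, value):
    with pytest.raises(ConfigurationError) as exc:
        cv.TrialScenario(**{field: value})
    assert field.split("_")[0] in str(exc.value)


def test_shallow_abp_slope_with_threshold_rejected():
    with pytest.raises(ConfigurationError):
        cv.TrialScenario(t_abp_mmHg=45.0, abp_upper_slope_mmHg_per_mmHg=0.4)


@given(
    amplitude=st.floats(20, 300),
    midpoint=st.floats(25, 45),
    rng=st.floats(2, 12),
    minimum=st.floats(-80, -5),
)
def test_noiseless_response_monotone(amplitude, midpoint, rng, minimum):
    """Noiseless generated MCAv% is monotone non-decreasing in PETCO2."""
    sc = cv.TrialScenario(
        minimum_pct=minimum,
        amplitude_pct=amplitude,
        midpoint_mmHg=midpoint,
        range_mmHg=rng,
    ).noiseless(sample_rate_hz=1.0)
    trial = cv.simulate_trial(sc)
    order = np.argsort(trial.petco2_mmHg, kind="stable")
    pct = 100.0 * (trial.mcav_cm_s[order] / sc.resting_mcav_cm_s - 1.0)
    # rest sits at the reference (0) with PETCO2 above the hyperventilation
    # plateau; compare only within the CO2-driven segments
    drive = trial.segment != "rest"
    pct_sorted = pct[np.isin(order, np.nonzero(drive)[0])]
    assert np.all(np.diff(pct_sorted) >= -1e-9)


def test_arterial_samples_ph_from_line(scenarios):
    """h_intercept 0, h_slope 1 puts pH = 9 - log10(PaCO2)."""
    sc = dataclasses.replace(
        scenarios["SL"], h_intercept_nEq_L=0.0, h_slope_nEq_L_per_mmHg=1.0
    )
    samples = cv.simulate_arterial_samples(sc, {"clamp": 39.81})
    assert samples[0].ph == pytest.approx(9.0 - np.log10(39.81), abs=1e-12)
    assert samples[0].ph == pytest.approx(7.4, abs=1e-3)


def test_arterial_samples_default_protocol_points(scenarios):
    samples = cv.simulate_arterial_samples(scenarios["SL"])
    assert len(samples) == 4
    assert {s.protocol_point for s in samples} == {
        "room air", "clamp", "hyperventilation", "end-rebreathing"
    }
    again = cv.simulate_arterial_samples(scenarios["SL"])
    assert [s.ph for s in samples] == [s.ph for s in again]


def test_arterial_setpoint_out_of_range(scenarios):
    with pytest.raises(ConfigurationError):
        cv.simulate_arterial_samples(scenarios["SL"], {"bad": 65.0})


def test_noiseless_samples_recover_generating_line(scenarios):
    """Generator -> fit_h_line round trip is exact without noise."""
    sc = scenarios["ALT16"]
    line = cv.fit_h_line(cv.simulate_arterial_samples(sc))
    assert line.intercept_nEq_L == pytest.approx(sc.h_intercept_nEq_L, abs=1e-9)
    assert line.slope_nEq_L_per_mmHg == pytest.approx(sc.h_slope_nEq_L_per_mmHg, abs=1e-12)
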