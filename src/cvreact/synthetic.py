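"""Synthetic modified-rebreathing trials with known ground truth.

The generator emulates the Duffin-type modified rebreathing protocol:
a room-air resting baseline, a 3-min voluntary hyperventilation holding
PETCO2 near 18 mmHg, then a rebreathing ramp that ends near PETCO2 =
50 mmHg, all in background hyperoxia (PETO2 > 250 mmHg).  MCAv follows a
logistic (sigmoid) function of PETCO2,

    mcav_pct = minimum + amplitude / (1 + exp(-(PETCO2 - midpoint)/range)),

expressed as percent change from the resting value.  Two protocol-driven
conventions make the generator the exact inverse of the analysis on
noiseless data:

* the resting segment sits at the resting reference itself (0 % change,
  i.e. raw MCAv equals the scenario's resting value), and
* the hyperventilation segment sits at the full-constriction floor
  ``minimum_pct`` — the analysis assumes hyperventilation produces full
  hypocapnia-induced vasoconstriction, and the generator realizes that
  assumption literally.

Mean ABP is flat below an optional PETCO2 breakpoint and rises linearly
above it, the confound the threshold-censoring stage exists to remove.
Arterial acid-base status is generated from a linear [H+]-PaCO2 relation.

Noise is additive Gaussian, drawn independently per 1-s epoch and held
constant within the epoch, so the effective noise level after 1-s
reduction does not depend on the raw sampling rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.special import expit

from .errors import ConfigurationError
from .io import ArterialSample, RebreathingTrial

__all__ = [
    "TrialScenario",
    "simulate_trial",
    "simulate_arterial_samples",
    "reference_scenarios",
    "logistic_pct",
]


def logistic_pct(
    petco2: np.ndarray | float,
    minimum_pct: float,
    amplitude_pct: float,
    midpoint_mmHg: float,
    range_mmHg: float,
) -> np.ndarray | float:
    """The sigmoid MCAv%-vs-PETCO2 model shared by generator and fitter."""
    return minimum_pct + amplitude_pct * expit(
        (np.asarray(petco2, dtype=float) - midpoint_mmHg) / range_mmHg
    )


@dataclass(frozen=True)
class TrialScenario:
    """Ground-truth parameters of one synthetic rebreathing trial.

    ``range_mmHg`` may alternatively be specified through the maximal
    slope of the sigmoid via :meth:`with_slope` (range = amplitude/(4*slope)).
    """

    minimum_pct: float = -40.0
    amplitude_pct: float = 95.0
    midpoint_mmHg: float = 36.5
    range_mmHg: float = 5.9
    resting_petco2_mmHg: float = 40.0
    hypocapnic_plateau_mmHg: float = 18.0
    ramp_end_mmHg: float = 50.0
    ramp_rate_mmHg_per_s: float = 1.0 / 3.0
    abp_baseline_mmHg: float = 90.0
    t_abp_mmHg: float | None = None
    abp_upper_slope_mmHg_per_mmHg: float = 2.0
    h_intercept_nEq_L: float = 11.5
    h_slope_nEq_L_per_mmHg: float = 0.71
    noise_sd_mcav_pct: float = 5.0
    noise_sd_abp_mmHg: float = 2.0
    resting_mcav_cm_s: float = 60.0
    rest_duration_s: float = 120.0
    hyperventilation_duration_s: float = 180.0
    sample_rate_hz: float = 10.0
    seed: int = 0
    subject_id: str = "synthetic"
    condition: str = "SL"

    def __post_init__(self) -> None:
        def bad(name: str, why: str) -> ConfigurationError:
            return ConfigurationError(f"scenario field {name!r}: {why}")

        if self.amplitude_pct <= 0:
            raise bad("amplitude_pct", "must be > 0")
        if self.range_mmHg <= 0:
            raise bad("range_mmHg", "must be > 0")
        if self.sample_rate_hz <= 0:
            raise bad("sample_rate_hz", "must be > 0")
        if self.ramp_rate_mmHg_per_s <= 0:
            raise bad("ramp_rate_mmHg_per_s", "must be > 0")
        if not self.hypocapnic_plateau_mmHg < self.midpoint_mmHg < self.ramp_end_mmHg:
            raise bad(
                "midpoint_mmHg",
                "must lie strictly between hypocapnic_plateau_mmHg and ramp_end_mmHg",
            )
        if self.t_abp_mmHg is not None:
            if not self.hypocapnic_plateau_mmHg < self.t_abp_mmHg <= self.ramp_end_mmHg:
                raise bad(
                    "t_abp_mmHg",
                    "must lie in (hypocapnic_plateau_mmHg, ramp_end_mmHg]",
                )
            if self.abp_upper_slope_mmHg_per_mmHg <= 0.5:
                raise bad(
                    "abp_upper_slope_mmHg_per_mmHg",
                    "must exceed 0.5 for the threshold to be detectable",
                )
        if self.noise_sd_mcav_pct < 0 or self.noise_sd_abp_mmHg < 0:
            raise bad("noise_sd", "noise standard deviations must be >= 0")

    @classmethod
    def with_slope(
        cls, slope_pct_per_mmHg: float, amplitude_pct: float, **kwargs
    ) -> "TrialScenario":
        """Build a scenario from the maximal sigmoid slope (reactivity).

        The logistic's maximal slope is amplitude/(4*range), so
        range = amplitude/(4*slope).
        """
        if slope_pct_per_mmHg <= 0:
            raise ConfigurationError("slope_pct_per_mmHg must be > 0")
        return cls(
            amplitude_pct=amplitude_pct,
            range_mmHg=amplitude_pct / (4.0 * slope_pct_per_mmHg),
            **kwargs,
        )

    def noiseless(self, **overrides) -> "TrialScenario":
        return replace(self, noise_sd_mcav_pct=0.0, noise_sd_abp_mmHg=0.0, **overrides)

    def to_dict(self) -> dict:
        return {k: v for k, v in vars(self).items()}

    @classmethod
    def from_dict(cls, d: dict) -> "TrialScenario":
        return cls(**d)


def _per_second_noise(rng: np.random.Generator, sd: float, time_s: np.ndarray) -> np.ndarray:
    """Gaussian noise drawn per integer second and held within the second."""
    seconds = np.floor(time_s).astype(int)
    draws = rng.normal(0.0, sd, seconds[-1] + 1)
    return draws[seconds]


def simulate_trial(scenario: TrialScenario) -> RebreathingTrial:
    """Generate one rebreathing trial from a scenario.

    Segments: rest at the resting PETCO2, hyperventilation at the
    hypocapnic plateau, then a linear-in-time PETCO2 ramp from the plateau
    to the ramp end.  Identical scenario (including seed) gives
    bit-identical output.
    """
    sc = scenario
    fs = sc.sample_rate_hz
    rng = np.random.default_rng(sc.seed)

    n_rest = round(sc.rest_duration_s * fs)
    n_hv = round(sc.hyperventilation_duration_s * fs)
    ramp_duration = (sc.ramp_end_mmHg - sc.hypocapnic_plateau_mmHg) / sc.ramp_rate_mmHg_per_s
    n_ramp = math.floor(ramp_duration * fs) + 1
    n = n_rest + n_hv + n_ramp
    time_s = np.arange(n) / fs
    segment = np.concatenate(
        [
            np.repeat("rest", n_rest),
            np.repeat("hyperventilation", n_hv),
            np.repeat("rebreathe", n_ramp),
        ]
    ).astype(object)

    petco2 = np.empty(n)
    petco2[:n_rest] = sc.resting_petco2_mmHg
    petco2[n_rest : n_rest + n_hv] = sc.hypocapnic_plateau_mmHg
    t_ramp = time_s[n_rest + n_hv :] - time_s[n_rest + n_hv]
    petco2[n_rest + n_hv :] = np.minimum(
        sc.hypocapnic_plateau_mmHg + sc.ramp_rate_mmHg_per_s * t_ramp, sc.ramp_end_mmHg
    )

    mcav_pct = np.empty(n)
    mcav_pct[:n_rest] = 0.0  # resting reference by definition of % change
    mcav_pct[n_rest : n_rest + n_hv] = sc.minimum_pct  # full hypocapnic constriction
    mcav_pct[n_rest + n_hv :] = logistic_pct(
        petco2[n_rest + n_hv :],
        sc.minimum_pct,
        sc.amplitude_pct,
        sc.midpoint_mmHg,
        sc.range_mmHg,
    )
    if sc.noise_sd_mcav_pct > 0:
        mcav_pct = mcav_pct + _per_second_noise(rng, sc.noise_sd_mcav_pct, time_s)
    mcav = sc.resting_mcav_cm_s * (1.0 + mcav_pct / 100.0)

    abp = np.full(n, sc.abp_baseline_mmHg)
    if sc.t_abp_mmHg is not None:
        abp = abp + sc.abp_upper_slope_mmHg_per_mmHg * np.maximum(
            petco2 - sc.t_abp_mmHg, 0.0
        )
    if sc.noise_sd_abp_mmHg > 0:
        abp = abp + _per_second_noise(rng, sc.noise_sd_abp_mmHg, time_s)

    peto2 = np.full(n, 300.0)  # hyperoxic background throughout

    return RebreathingTrial(
        subject_id=sc.subject_id,
        condition=sc.condition,
        time_s=time_s,
        petco2_mmHg=petco2,
        peto2_mmHg=peto2,
        mcav_cm_s=mcav,
        abp_mmHg=abp,
        segment=segment,
    )


#: protocol points at which arterial blood was drawn, and the PaCO2
#: set-point each implies (room air at rest, end-tidal clamp at 40 mmHg,
#: hyperventilation plateau, end of rebreathing)
def default_arterial_setpoints(scenario: TrialScenario) -> dict[str, float]:
    return {
        "room air": scenario.resting_petco2_mmHg,
        "clamp": 40.0,
        "hyperventilation": scenario.hypocapnic_plateau_mmHg,
        "end-rebreathing": scenario.ramp_end_mmHg,
    }


def simulate_arterial_samples(
    scenario: TrialScenario,
    conditions: dict[str, float] | None = None,
    noise_sd_nEq_L: float = 0.0,
) -> list[ArterialSample]:
    """Generate arterial (pH, PaCO2) pairs from the scenario's [H+] line.

    ``conditions`` maps protocol-point labels to PaCO2 set-points (mmHg);
    the default is the four-point protocol.  [H+] is linear in PaCO2 and
    pH = 9 - log10([H+] in nEq/L).
    """
    sc = scenario
    if conditions is None:
        conditions = default_arterial_setpoints(sc)
    rng = np.random.default_rng(sc.seed + 1)  # decoupled from the trial stream
    samples = []
    for point, paco2 in conditions.items():
        if not 10.0 <= paco2 <= 60.0:
            raise ConfigurationError(
                f"arterial set-point {point!r} = {paco2} mmHg outside [10, 60]"
            )
        h = sc.h_intercept_nEq_L + sc.h_slope_nEq_L_per_mmHg * paco2
        if noise_sd_nEq_L > 0:
            h += rng.normal(0.0, noise_sd_nEq_L)
        if h <= 0:
            raise ConfigurationError(
                f"generated [H+] {h:.3g} nEq/L is non-positive at PaCO2 {paco2}"
            )
        samples.append(
            ArterialSample(
                subject_id=sc.subject_id,
                condition=sc.condition,
                protocol_point=point,
                ph=9.0 - math.log10(h),
                paco2_mmHg=paco2,
            )
        )
    return samples


def reference_scenarios() -> dict[str, TrialScenario]:
    """Group-mean scenarios for the three study conditions.

    SL is sea level; ALT1 and ALT16 are day 1 and day 16 at 5260 m.  The
    sigmoid parameters are the published group means for each condition;
    resting PETCO2 reflects the hyperventilation-induced hypocapnia at
    altitude (~12 and ~17 mmHg below the 40 mmHg sea-level value).  The
    [H+]-PaCO2 lines are chosen so the mmHg-domain group parameters map
    onto the published [H+]-domain ones (slope = range_nEq/range_mmHg,
    intercept anchored at the midpoints).  The hypocapnic floor
    ``minimum_pct`` is a fixed plausible value per condition; it sets the
    sigmoid's lower plateau but no recovered parameter depends on it.
    """
    common = dict(t_abp_mmHg=None, noise_sd_mcav_pct=5.0, noise_sd_abp_mmHg=2.0)
    return {
        "SL": TrialScenario(
            condition="SL",
            minimum_pct=-40.0,
            amplitude_pct=95.0,
            midpoint_mmHg=36.5,
            range_mmHg=5.9,
            resting_petco2_mmHg=40.0,
            h_intercept_nEq_L=11.517,
            h_slope_nEq_L_per_mmHg=4.2 / 5.9,
            **common,
        ),
        "ALT1": TrialScenario(
            condition="ALT1",
            minimum_pct=-30.0,
            amplitude_pct=129.0,
            midpoint_mmHg=35.4,
            range_mmHg=4.5,
            resting_petco2_mmHg=28.0,
            h_intercept_nEq_L=14.887,
            h_slope_nEq_L_per_mmHg=2.9 / 4.5,
            **common,
        ),
        "ALT16": TrialScenario(
            condition="ALT16",
            minimum_pct=-25.0,
            amplitude_pct=177.0,
            midpoint_mmHg=28.6,
            range_mmHg=4.2,
            resting_petco2_mmHg=23.0,
            h_intercept_nEq_L=16.290,
            h_slope_nEq_L_per_mmHg=3.1 / 4.2,
            **common,
        ),
    }
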