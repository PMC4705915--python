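"""Sigmoid fitting of the MCAv-PETCO2 response and derived quantities.

The response model is

    mcav_pct = minimum + amplitude / (1 + exp(-(PETCO2 - midpoint)/range))

with *minimum* fixed from the hyperventilation data (the hypocapnic
floor) and (amplitude, midpoint, range) fitted by bounded nonlinear
least squares.  Cerebrovascular CO2 reactivity — the slope of the
quasi-linear central portion — is the analytic maximal slope of the
logistic, amplitude/(4*range); a secondary regression-based estimator
over the central portion is also provided.  Vascular reserves measure
the distance from the resting operating point down to the constriction
floor and up to the response at T_ABP (or the upper plateau when no
threshold was reached).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import linregress

from .abp import AbpThreshold
from .errors import ValidationError
from .preprocess import ProcessedTrial
from .synthetic import logistic_pct

__all__ = [
    "SigmoidFit",
    "Reserves",
    "fixed_minimum",
    "fit",
    "compute_reserves",
    "linear_reactivity",
]

logger = logging.getLogger(__name__)

#: parameter bounds for (amplitude %, midpoint mmHg, range mmHg)
DEFAULT_BOUNDS = ((1e-6, 10.0, 0.1), (500.0, 60.0, 20.0))
MINIMUM_WINDOW_S = 60.0
_RESTART_SEED = 1729  # fixed restart seed for jittered re-initialization


@dataclass
class SigmoidFit:
    """Fitted logistic parameters and derived reactivity."""

    minimum_pct: float
    amplitude_pct: float
    midpoint_mmHg: float
    range_mmHg: float
    r_squared: float
    n_points: int
    converged: bool
    minimum_fitted: bool = False

    @property
    def reactivity_pct_per_mmHg(self) -> float:
        """Maximal slope of the fitted logistic, amplitude/(4*range)."""
        return self.amplitude_pct / (4.0 * self.range_mmHg)

    def predict(self, petco2):
        return logistic_pct(
            petco2, self.minimum_pct, self.amplitude_pct, self.midpoint_mmHg, self.range_mmHg
        )


@dataclass
class Reserves:
    """Vasoconstriction and vasodilation reserves in MCAv %."""

    constriction_pct: float
    dilation_pct: float


def fixed_minimum(processed: ProcessedTrial, window_s: float = MINIMUM_WINDOW_S) -> float:
    """Hypocapnic floor: mean MCAv% over the final ``window_s`` seconds
    of the hyperventilation segment (at least 30 s required)."""
    trial = processed.trial
    mask = trial.segment_mask("hyperventilation")
    if not mask.any():
        raise ValidationError("trial has no hyperventilation segment")
    t = trial.time_s[mask]
    if t[-1] - t[0] < 30.0 - 1e-9:
        raise ValidationError("hyperventilation segment shorter than 30 s")
    sel = mask & (trial.time_s >= t[-1] - window_s)
    return float(processed.mcav_pct[sel].mean())


def _initial_guess(
    x: np.ndarray, y: np.ndarray, minimum_pct: float, bounds
) -> np.ndarray:
    lo, hi = np.asarray(bounds[0]), np.asarray(bounds[1])
    a0 = np.clip(y.max() - minimum_pct, lo[0] * 10 + 1e-3, hi[0])
    half = minimum_pct + a0 / 2.0
    above = np.nonzero(y >= half)[0]
    m0 = x[above[0]] if above.size else float(np.median(x))
    m0 = float(np.clip(m0, lo[1], hi[1]))
    r0 = float(np.clip(4.0, lo[2], hi[2]))
    return np.array([a0, m0, r0])


def fit(
    petco2: np.ndarray,
    mcav_pct: np.ndarray,
    minimum_pct: float,
    bounds=DEFAULT_BOUNDS,
    fit_minimum: bool = False,
    max_restarts: int = 5,
) -> SigmoidFit:
    """Bounded least-squares fit of the logistic response.

    (amplitude, midpoint, range) are free; *minimum* is fixed unless
    ``fit_minimum`` is set (sensitivity analysis).  On non-convergence
    the fit is restarted up to ``max_restarts`` times from jittered
    initial values (fixed restart seed); if still unconverged the last
    parameters are returned with ``converged=False`` and a warning.
    """
    x = np.asarray(petco2, dtype=float)
    y = np.asarray(mcav_pct, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("petco2 and mcav_pct have different lengths")
    if x.size < 8:
        raise ValidationError(f"need >= 8 points for the sigmoid fit, got {x.size}")
    span = x.max() - x.min()
    if span < 8.0:
        raise ValidationError(f"PETCO2 span {span:.2f} mmHg < 8 mmHg")
    if span == 0:
        raise ValidationError("all PETCO2 values identical")

    if fit_minimum:
        def residuals(p):
            return logistic_pct(x, p[3], p[0], p[1], p[2]) - y

        lo = (*bounds[0], -200.0)
        hi = (*bounds[1], 100.0)
        p0 = np.append(_initial_guess(x, y, minimum_pct, bounds), minimum_pct)
    else:
        def residuals(p):
            return logistic_pct(x, minimum_pct, p[0], p[1], p[2]) - y

        lo, hi = bounds
        p0 = _initial_guess(x, y, minimum_pct, bounds)

    rng = np.random.default_rng(_RESTART_SEED)
    res = None
    for attempt in range(max_restarts + 1):
        start = p0
        if attempt > 0:
            jitter = rng.uniform(0.8, 1.2, size=len(p0))
            start = np.clip(p0 * jitter, np.asarray(lo) + 1e-9, np.asarray(hi) - 1e-9)
        res = least_squares(residuals, start, bounds=(lo, hi), method="trf")
        if res.success:
            break
    assert res is not None
    params = res.x
    amplitude, midpoint, rng_mmHg = params[:3]
    min_out = params[3] if fit_minimum else minimum_pct
    sse = float(2.0 * res.cost)
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - sse / sst if sst > 0 else 0.0
    # an amplitude collapsed to (near) its lower bound means no response
    # was found: report the parameters but flag the fit
    converged = bool(res.success and amplitude > 1e-3)
    if not converged:
        logger.warning(
            "sigmoid fit did not converge (status %s, amplitude %.3g)",
            res.status,
            amplitude,
        )
    return SigmoidFit(
        minimum_pct=float(min_out),
        amplitude_pct=float(amplitude),
        midpoint_mmHg=float(midpoint),
        range_mmHg=float(rng_mmHg),
        r_squared=float(np.clip(r2, 0.0, 1.0)),
        n_points=int(x.size),
        converged=converged,
        minimum_fitted=fit_minimum,
    )


def linear_reactivity(
    petco2: np.ndarray,
    mcav_pct: np.ndarray,
    fitres: SigmoidFit,
    central_halfwidth_ranges: float = 1.0,
) -> float:
    """Regression-based reactivity over the central linear portion.

    Secondary estimator: ordinary least squares of MCAv% on PETCO2
    restricted to points within ``central_halfwidth_ranges`` range
    parameters of the fitted midpoint (the quasi-linear zone of the
    logistic).  The analytic amplitude/(4*range) is the default
    estimator; this one exists for sensitivity analysis.
    """
    x = np.asarray(petco2, dtype=float)
    y = np.asarray(mcav_pct, dtype=float)
    half = central_halfwidth_ranges * fitres.range_mmHg
    mask = np.abs(x - fitres.midpoint_mmHg) <= half
    if mask.sum() < 3:
        raise ValidationError("fewer than 3 points in the central linear portion")
    return float(linregress(x[mask], y[mask]).slope)


def compute_reserves(
    fitres: SigmoidFit,
    resting_petco2_mmHg: float,
    thr: AbpThreshold | None = None,
) -> Reserves:
    """Vascular reserves relative to the resting operating point.

    constriction = S(resting PETCO2) - minimum; dilation = S(T_ABP) -
    S(resting PETCO2) when a threshold was detected, otherwise
    (minimum + amplitude) - S(resting PETCO2), with S the fitted sigmoid.
    """
    if not fitres.converged:
        raise ValidationError("reserves require a converged sigmoid fit")
    if not 10.0 <= resting_petco2_mmHg <= 60.0:
        raise ValidationError(
            f"resting PETCO2 {resting_petco2_mmHg} mmHg outside [10, 60]"
        )
    s_rest = float(fitres.predict(resting_petco2_mmHg))
    if thr is not None and thr.detected and thr.t_abp_mmHg is not None:
        upper = float(fitres.predict(thr.t_abp_mmHg))
    else:
        upper = fitres.minimum_pct + fitres.amplitude_pct
    return Reserves(
        constriction_pct=s_rest - fitres.minimum_pct,
        dilation_pct=upper - s_rest,
    )
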