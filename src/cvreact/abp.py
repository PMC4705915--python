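"""Blood-pressure threshold (T_ABP) detection and censoring.

Rising CO2 eventually raises mean arterial pressure, and the
pressure-driven rise in MCAv would contaminate an estimate of the
vascular CO2 response.  T_ABP is the PETCO2 from which mean ABP rises
faster than 0.5 mmHg per mmHg CO2.  It is found by a constrained
two-segment linear fit of ABP against PETCO2: over every candidate
breakpoint, the lower segment is fitted with its slope clipped below the
criterion and the upper segment is fitted unconstrained; the breakpoint
minimizing the total sum of squared residuals wins, with ties broken
toward the lowest PETCO2 (conservative censoring).  The threshold counts
as detected only when the upper slope exceeds the criterion.  MCAv data
above a detected threshold are censored from the sigmoid fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .preprocess import ProcessedTrial

__all__ = ["AbpThreshold", "detect_t_abp", "censor_above_threshold"]

DEFAULT_SLOPE_CRITERION = 0.5
DEFAULT_MIN_SEGMENT_POINTS = 4
_CLIP_EPS = 1e-9


@dataclass
class AbpThreshold:
    """Result of the two-segment ABP-vs-PETCO2 fit."""

    t_abp_mmHg: float | None
    lower_slope_mmHg_per_mmHg: float
    upper_slope_mmHg_per_mmHg: float
    sse: float
    detected: bool


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    xm, ym = x.mean(), y.mean()
    var = float(((x - xm) ** 2).sum())
    slope = float(((x - xm) * (y - ym)).sum() / var) if var > 0 else 0.0
    return slope, ym - slope * xm


def _segment_fit(
    x: np.ndarray, y: np.ndarray, slope_cap: float | None
) -> tuple[float, float, float]:
    """Least-squares line, optionally with the slope clipped below a cap.

    With a fixed slope the least-squares intercept is mean(y - slope*x).
    Returns (slope, intercept, sse).
    """
    slope, intercept = _ols(x, y)
    if slope_cap is not None and slope >= slope_cap:
        slope = slope_cap
        intercept = float((y - slope * x).mean())
    resid = y - (slope * x + intercept)
    return slope, intercept, float((resid**2).sum())


def detect_t_abp(
    petco2: np.ndarray,
    abp: np.ndarray,
    slope_criterion: float = DEFAULT_SLOPE_CRITERION,
    min_segment_points: int = DEFAULT_MIN_SEGMENT_POINTS,
) -> AbpThreshold:
    """Locate the ABP breakpoint over the rebreathing PETCO2 span.

    Candidates are the observed PETCO2 values with at least
    ``min_segment_points`` points on each side; for each the lower
    segment is fitted with slope clipped below ``slope_criterion`` and
    the upper segment unconstrained, and the total SSE is minimized.
    """
    petco2 = np.asarray(petco2, dtype=float)
    abp = np.asarray(abp, dtype=float)
    if petco2.shape != abp.shape:
        raise ValidationError("petco2 and abp series have different lengths")
    n = petco2.size
    if n < 10:
        raise ValidationError(f"need >= 10 paired samples, got {n}")
    if petco2.max() - petco2.min() < 5.0:
        raise ValidationError("PETCO2 span < 5 mmHg; breakpoint search unreliable")

    order = np.argsort(petco2, kind="stable")
    x, y = petco2[order], abp[order]
    cap = slope_criterion - _CLIP_EPS

    best: tuple[float, float, float, float] | None = None  # sse, t, lo, up
    for k in range(min_segment_points, n - min_segment_points + 1):
        lo_slope, _, lo_sse = _segment_fit(x[:k], y[:k], cap)
        up_slope, _, up_sse = _segment_fit(x[k:], y[k:], None)
        sse = lo_sse + up_sse
        # strict < keeps the earliest (lowest-PETCO2) breakpoint on ties
        if best is None or sse < best[0] - 1e-12:
            best = (sse, float(x[k - 1]), lo_slope, up_slope)
    assert best is not None
    sse, t_abp, lower, upper = best
    detected = upper > slope_criterion
    return AbpThreshold(
        t_abp_mmHg=t_abp if detected else None,
        lower_slope_mmHg_per_mmHg=lower,
        upper_slope_mmHg_per_mmHg=upper,
        sse=sse,
        detected=detected,
    )


def censor_above_threshold(
    processed: ProcessedTrial, thr: AbpThreshold
) -> tuple[tuple[np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray]]:
    """Split the rebreathing (PETCO2, MCAv%) pairs at the threshold.

    Returns ``(below, above)`` where each is a (petco2, mcav_pct) pair of
    arrays; the partition is exhaustive and disjoint.  Without a detected
    threshold everything is "below".
    """
    petco2, mcav_pct = processed.pairs("rebreathe")
    if not thr.detected or thr.t_abp_mmHg is None:
        empty = (np.empty(0), np.empty(0))
        return (petco2, mcav_pct), empty
    mask = petco2 <= thr.t_abp_mmHg
    return (petco2[mask], mcav_pct[mask]), (petco2[~mask], mcav_pct[~mask])
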