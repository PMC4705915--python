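"""Acid-base transformation of the CO2 response.

Arterial pH converts to hydrogen-ion concentration as
[H+] = 10^(9 - pH) nEq/L.  Per trial, [H+] is regressed linearly on
PaCO2, and that line re-expresses the sigmoid parameters in [H+] units:
a linear map of the abscissa moves the midpoint through the line and
scales the range by its slope, leaving the response amplitude untouched.
This is the operation behind the observation that a leftward PETCO2
shift driven purely by acid-base buffering disappears when the response
is plotted against [H+].

End-tidal CO2 is treated as a proxy for arterial CO2 when the arterial
line is applied to end-tidal-domain parameters; an optional linear
PETCO2 -> PaCO2 calibration hook is provided.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import linregress

from .errors import ValidationError
from .io import ArterialSample
from .sigmoid import SigmoidFit

__all__ = ["HLine", "SigmoidFitH", "ph_to_h", "h_to_ph", "fit_h_line", "transform_fit"]

logger = logging.getLogger(__name__)


def ph_to_h(ph):
    """[H+] in nEq/L from pH: 10^(9 - pH)."""
    ph = np.asarray(ph, dtype=float)
    if np.any(ph <= 6.5) or np.any(ph >= 8.0):
        raise ValidationError("pH outside (6.5, 8.0)")
    out = np.power(10.0, 9.0 - ph)
    return float(out) if out.ndim == 0 else out


def h_to_ph(h_nEq_L):
    """Inverse of :func:`ph_to_h`."""
    h = np.asarray(h_nEq_L, dtype=float)
    if np.any(h <= 0):
        raise ValidationError("[H+] must be positive")
    out = 9.0 - np.log10(h)
    return float(out) if out.ndim == 0 else out


@dataclass
class HLine:
    """Per-trial linear [H+]-vs-PaCO2 relation."""

    intercept_nEq_L: float
    slope_nEq_L_per_mmHg: float
    r_squared: float
    n_samples: int

    def h_at(self, paco2_mmHg):
        return self.intercept_nEq_L + self.slope_nEq_L_per_mmHg * np.asarray(
            paco2_mmHg, dtype=float
        )


@dataclass
class SigmoidFitH:
    """Sigmoid parameters re-expressed on the [H+] axis."""

    midpoint_nEq_L: float
    range_nEq_L: float
    reactivity_pct_per_nEq_L: float
    source: SigmoidFit
    line: HLine


def fit_h_line(samples: list[ArterialSample]) -> HLine:
    """Ordinary least squares of [H+] on PaCO2 over arterial samples."""
    if len(samples) < 2:
        raise ValidationError("need >= 2 arterial samples")
    paco2 = np.array([s.paco2_mmHg for s in samples], dtype=float)
    if np.ptp(paco2) == 0:
        raise ValidationError("all PaCO2 values identical; line is undefined")
    h = ph_to_h(np.array([s.ph for s in samples]))
    res = linregress(paco2, h)
    if res.slope <= 0:
        logger.warning(
            "[H+]-PaCO2 slope %.3g is non-positive; physiologically implausible",
            res.slope,
        )
    r2 = float(res.rvalue**2) if not np.isnan(res.rvalue) else 1.0
    return HLine(
        intercept_nEq_L=float(res.intercept),
        slope_nEq_L_per_mmHg=float(res.slope),
        r_squared=r2,
        n_samples=len(samples),
    )


def transform_fit(
    fitres: SigmoidFit,
    line: HLine,
    petco2_to_paco2: tuple[float, float] = (0.0, 1.0),
) -> SigmoidFitH:
    """Map a PETCO2-domain sigmoid fit into [H+] units through a line.

    midpoint -> intercept + slope*midpoint, range -> slope*range,
    reactivity -> amplitude/(4*range_H).  ``petco2_to_paco2`` is an
    optional (offset, gain) calibration applied to the end-tidal axis
    before the arterial line; the default treats PETCO2 as PaCO2.
    """
    if line.slope_nEq_L_per_mmHg <= 0:
        raise ValidationError(
            "cannot transform through a non-positive [H+]-PaCO2 slope: "
            "[H+] would not increase with CO2"
        )
    off, gain = petco2_to_paco2
    if gain <= 0:
        raise ValidationError("PETCO2->PaCO2 calibration gain must be > 0")
    mid_pa = off + gain * fitres.midpoint_mmHg
    range_pa = gain * fitres.range_mmHg
    range_h = line.slope_nEq_L_per_mmHg * range_pa
    return SigmoidFitH(
        midpoint_nEq_L=line.intercept_nEq_L + line.slope_nEq_L_per_mmHg * mid_pa,
        range_nEq_L=range_h,
        reactivity_pct_per_nEq_L=fitres.amplitude_pct / (4.0 * range_h),
        source=fitres,
        line=line,
    )
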