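"""Reduction to 1-s averages and percent-normalization of MCAv.

Raw channels (up to 200 Hz) are averaged over left-closed 1-s bins
[t, t+1); MCAv is then re-expressed as percent change from its mean over
a resting reference window, by default the final 60 s of the room-air
baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .io import RebreathingTrial

__all__ = ["ProcessedTrial", "reduce_to_1s", "normalize_mcav"]

#: default length (s) of the resting reference window
DEFAULT_RESTING_WINDOW_S = 60.0
#: minimum data required inside the resting window
MIN_RESTING_S = 30.0


@dataclass
class ProcessedTrial:
    """A 1-Hz trial with MCAv expressed as % change from resting."""

    trial: RebreathingTrial
    resting_mcav_cm_s: float
    resting_petco2_mmHg: float
    mcav_pct: np.ndarray

    def pairs(self, segment: str = "rebreathe") -> tuple[np.ndarray, np.ndarray]:
        """(PETCO2, MCAv%) pairs restricted to one protocol segment."""
        m = self.trial.segment_mask(segment)
        return self.trial.petco2_mmHg[m], self.mcav_pct[m]


def _median_dt(time_s: np.ndarray) -> float:
    if time_s.size < 2:
        raise ValidationError("trial has fewer than 2 samples")
    return float(np.median(np.diff(time_s)))


def reduce_to_1s(trial: RebreathingTrial) -> RebreathingTrial:
    """Average every numeric channel over 1-s bins [t, t+1).

    Output samples are stamped at bin centers; the segment label of a bin
    is the majority label of its samples.  A partial trailing bin is
    dropped.  Input already at 1 Hz is returned unchanged.
    """
    dt = _median_dt(trial.time_s)
    if dt > 1.0 + 1e-9:
        raise ValidationError(f"sample interval {dt:.3g}s > 1s; need rate >= 1 Hz")
    if abs(dt - 1.0) <= 1e-9:
        return trial

    df = trial.to_frame()
    bins = np.floor(trial.time_s).astype(int)
    counts = np.bincount(bins - bins.min())
    # a trailing bin with fewer samples than a full bin is incomplete
    full = counts.max()
    keep_last = counts[-1] == full
    numeric = df.drop(columns="segment").groupby(bins).mean()
    labels = (
        df["segment"]
        .groupby(bins)
        .agg(lambda s: s.value_counts().idxmax())
    )
    if not keep_last:
        numeric = numeric.iloc[:-1]
        labels = labels.iloc[:-1]
    out = RebreathingTrial(
        subject_id=trial.subject_id,
        condition=trial.condition,
        time_s=numeric.index.to_numpy(dtype=float) + 0.5,
        petco2_mmHg=numeric["petco2_mmHg"].to_numpy(),
        peto2_mmHg=numeric["peto2_mmHg"].to_numpy(),
        mcav_cm_s=numeric["mcav_cm_s"].to_numpy(),
        abp_mmHg=numeric["abp_mmHg"].to_numpy(),
        segment=labels.to_numpy(),
        extras={
            c: numeric[c].to_numpy()
            for c in numeric.columns
            if c not in ("time_s", "petco2_mmHg", "peto2_mmHg", "mcav_cm_s", "abp_mmHg")
        },
    )
    return out


def normalize_mcav(
    trial: RebreathingTrial,
    resting_window: tuple[float, float] | None = None,
) -> ProcessedTrial:
    """Express MCAv as percent change from its resting-window mean.

    ``resting_window`` is a (start, end) time interval in seconds that
    must lie inside the rest segment and contain at least 30 s of data;
    the default is the final 60 s of the rest segment.
    """
    rest = trial.segment_mask("rest")
    if not rest.any():
        raise ValidationError("trial has no rest segment")
    t_rest = trial.time_s[rest]
    if resting_window is None:
        resting_window = (t_rest[-1] - DEFAULT_RESTING_WINDOW_S, t_rest[-1])
    lo, hi = resting_window
    if lo < t_rest[0] - 1e-9 or hi > t_rest[-1] + 1e-9:
        raise ValidationError(
            f"resting window [{lo}, {hi}] extends outside the rest segment "
            f"[{t_rest[0]}, {t_rest[-1]}]"
        )
    in_win = rest & (trial.time_s >= lo) & (trial.time_s <= hi)
    t_win = trial.time_s[in_win]
    if t_win.size < 2 or (t_win[-1] - t_win[0]) < MIN_RESTING_S - 1e-9:
        raise ValidationError(
            f"resting window covers {(t_win[-1] - t_win[0]) if t_win.size else 0:.1f}s "
            f"of data; need >= {MIN_RESTING_S:.0f}s"
        )
    resting_mcav = float(trial.mcav_cm_s[in_win].mean())
    resting_petco2 = float(trial.petco2_mmHg[in_win].mean())
    mcav_pct = 100.0 * (trial.mcav_cm_s - resting_mcav) / resting_mcav
    return ProcessedTrial(
        trial=trial,
        resting_mcav_cm_s=resting_mcav,
        resting_petco2_mmHg=resting_petco2,
        mcav_pct=mcav_pct,
    )
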