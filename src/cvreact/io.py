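"""Trial and results I/O in stable delimited-text formats.

The interchange format is plain CSV (UTF-8, header row, ``.`` decimal).
Units are fixed by column-name suffix (``_mmHg``, ``_cm_s``); there is no
unit auto-detection.  Trial files carry subject/condition metadata as
leading ``# key: value`` comment lines.  Results are written both as tidy
CSV tables and as JSON with a schema version field.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1.0"

#: segment labels of a modified rebreathing protocol
SEGMENTS = ("rest", "hyperventilation", "rebreathe")

TRIAL_COLUMNS = ("time_s", "petco2_mmHg", "peto2_mmHg", "mcav_cm_s", "abp_mmHg", "segment")

# physiological sanity gates (configurable at validation time)
PETCO2_GATE = (5.0, 80.0)
ABP_GATE = (30.0, 250.0)


@dataclass
class RebreathingTrial:
    """Time series of one modified rebreathing test.

    Channels: end-tidal CO2 and O2 partial pressures (mmHg), middle
    cerebral artery velocity (cm/s) and mean arterial blood pressure
    (mmHg), with a per-sample protocol segment label
    (rest / hyperventilation / rebreathe).
    """

    subject_id: str
    condition: str
    time_s: np.ndarray
    petco2_mmHg: np.ndarray
    peto2_mmHg: np.ndarray
    mcav_cm_s: np.ndarray
    abp_mmHg: np.ndarray
    segment: np.ndarray
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("time_s", "petco2_mmHg", "peto2_mmHg", "mcav_cm_s", "abp_mmHg"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.segment = np.asarray(self.segment, dtype=object)
        self.validate()

    def validate(
        self,
        petco2_gate: tuple[float, float] = PETCO2_GATE,
        abp_gate: tuple[float, float] = ABP_GATE,
    ) -> None:
        n = self.time_s.size
        if n == 0:
            raise ValidationError("trial is empty")
        for name in ("petco2_mmHg", "peto2_mmHg", "mcav_cm_s", "abp_mmHg", "segment"):
            if getattr(self, name).size != n:
                raise ValidationError(f"series {name!r} length != time_s length")
        if not np.all(np.diff(self.time_s) > 0):
            raise ValidationError("time_s must be strictly increasing")
        if self.petco2_mmHg.min() <= petco2_gate[0] or self.petco2_mmHg.max() >= petco2_gate[1]:
            raise ValidationError(
                f"petco2_mmHg outside physiological gate {petco2_gate}"
            )
        if self.mcav_cm_s.min() <= 0:
            raise ValidationError("mcav_cm_s must be positive")
        if self.abp_mmHg.min() <= abp_gate[0] or self.abp_mmHg.max() >= abp_gate[1]:
            raise ValidationError(f"abp_mmHg outside physiological gate {abp_gate}")
        unknown = set(self.segment) - set(SEGMENTS)
        if unknown:
            raise ValidationError(f"unknown segment labels: {sorted(unknown)}")

    @property
    def n_samples(self) -> int:
        return int(self.time_s.size)

    def segment_mask(self, label: str) -> np.ndarray:
        return self.segment == label

    def to_frame(self) -> pd.DataFrame:
        data = {c: getattr(self, c) for c in TRIAL_COLUMNS}
        data.update(self.extras)
        return pd.DataFrame(data)


@dataclass
class ArterialSample:
    """One arterial blood-gas sample (pH and PaCO2) at a protocol point."""

    subject_id: str
    condition: str
    protocol_point: str
    ph: float
    paco2_mmHg: float

    def __post_init__(self) -> None:
        if not 6.8 < self.ph < 7.8:
            raise ValidationError(f"pH {self.ph} outside (6.8, 7.8)")
        if not 10.0 < self.paco2_mmHg < 70.0:
            raise ValidationError(f"paco2_mmHg {self.paco2_mmHg} outside (10, 70)")


# ---------------------------------------------------------------------------
# trial files


def write_trial(trial: RebreathingTrial, path: str | Path) -> Path:
    """Write one trial as CSV with ``# key: value`` metadata lines."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# subject_id: {trial.subject_id}\n")
        fh.write(f"# condition: {trial.condition}\n")
        # %.17g is lossless for float64, so read(write(x)) is bit-exact
        trial.to_frame().to_csv(fh, index=False, float_format="%.17g")
    return path


def read_trial(path: str | Path) -> RebreathingTrial:
    """Read and validate a trial CSV written by :func:`write_trial`.

    Unknown columns are preserved in ``trial.extras``.  A missing required
    column raises :class:`FormatError` naming it; a non-monotone time axis
    raises :class:`ValidationError`.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line.lstrip("# ").partition(":")
            meta[key.strip()] = value.strip()
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    for col in TRIAL_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"trial file {path} is missing required column {col!r}")
    extras = {c: df[c].to_numpy() for c in df.columns if c not in TRIAL_COLUMNS}
    return RebreathingTrial(
        subject_id=meta.get("subject_id", path.stem),
        condition=meta.get("condition", "unknown"),
        time_s=df["time_s"].to_numpy(),
        petco2_mmHg=df["petco2_mmHg"].to_numpy(),
        peto2_mmHg=df["peto2_mmHg"].to_numpy(),
        mcav_cm_s=df["mcav_cm_s"].to_numpy(),
        abp_mmHg=df["abp_mmHg"].to_numpy(),
        segment=df["segment"].to_numpy(),
        extras=extras,
    )


# ---------------------------------------------------------------------------
# arterial sample files


ARTERIAL_COLUMNS = ("subject_id", "condition", "protocol_point", "ph", "paco2_mmHg")


def write_arterial_samples(samples: list[ArterialSample], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame([vars(s) for s in samples], columns=ARTERIAL_COLUMNS).to_csv(
        path, index=False
    )
    return path


def read_arterial_samples(path: str | Path) -> list[ArterialSample]:
    df = pd.read_csv(path)
    for col in ARTERIAL_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"arterial file {path} is missing required column {col!r}")
    return [ArterialSample(**row) for row in df[list(ARTERIAL_COLUMNS)].to_dict("records")]


# ---------------------------------------------------------------------------
# results tables

#: per-trial parameter columns, in the row order of the condition summary
PARAMETER_COLUMNS = (
    "amplitude_pct",
    "midpoint_mmHg",
    "range_mmHg",
    "reactivity_pct_per_mmHg",
    "constriction_pct",
    "dilation_pct",
    "midpoint_nEq_L",
    "range_nEq_L",
    "reactivity_pct_per_nEq_L",
)


def results_tables(records: list[dict]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build the per-trial parameter table and per-condition summary.

    The summary mirrors the conventional reporting layout for this test:
    one row per parameter (amplitude, midpoint, range, reactivity, the two
    vascular reserves, then the [H+]-domain block), columns per condition
    with n, mean and t-based 95% CI.
    """
    from .stats import summarize  # deferred to avoid an import cycle

    base_cols = ["subject_id", "condition", "minimum_pct", "r_squared", "converged",
                 "t_abp_mmHg", "n_points"]
    all_cols = base_cols[:2] + list(PARAMETER_COLUMNS) + base_cols[2:]
    per_trial = pd.DataFrame(records)
    if per_trial.empty:
        logger.warning("results_tables called with no records; emitting headers only")
        per_trial = pd.DataFrame(columns=all_cols)
        return per_trial, pd.DataFrame(
            columns=["parameter", "condition", "n", "mean", "ci95_low", "ci95_high", "sd"]
        )
    per_trial = per_trial.reindex(columns=[c for c in all_cols if c in per_trial.columns]
                                  + [c for c in per_trial.columns if c not in all_cols])
    rows = []
    for param in PARAMETER_COLUMNS:
        if param not in per_trial.columns:
            continue
        groups = {
            cond: sub[param].dropna().to_numpy()
            for cond, sub in per_trial.groupby("condition", sort=False)
        }
        groups = {c: v for c, v in groups.items() if v.size > 0}
        if not groups:
            continue
        for s in summarize(groups):
            rows.append(
                {"parameter": param, "condition": s.condition, "n": s.n, "mean": s.mean,
                 "ci95_low": s.ci95_low, "ci95_high": s.ci95_high, "sd": s.sd}
            )
    return per_trial, pd.DataFrame(rows)


def write_results(records: list[dict], out_dir: str | Path) -> dict[str, Path]:
    """Write per-trial and summary tables (CSV) plus a JSON export.

    Returns a mapping of artifact name to written path.  Empty input
    produces header-only files and logs a warning.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    per_trial, summary = results_tables(records)
    paths = {
        "per_trial": out_dir / "per_trial_parameters.csv",
        "summary": out_dir / "condition_summary.csv",
        "json": out_dir / "results.json",
    }
    per_trial.to_csv(paths["per_trial"], index=False, float_format="%.10g")
    summary.to_csv(paths["summary"], index=False, float_format="%.10g")
    payload = {
        "schema_version": SCHEMA_VERSION,
        "per_trial": json.loads(per_trial.to_json(orient="records")),
        "summary": json.loads(summary.to_json(orient="records")),
    }
    paths["json"].write_text(json.dumps(payload, indent=2))
    return paths
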