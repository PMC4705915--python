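"""End-to-end orchestration: simulate -> preprocess -> threshold -> fit
-> acid-base transform -> group statistics.

`analyze_trial` runs the per-trial chain and returns a flat parameter
record; `run` executes a whole configuration (synthetic scenarios and/or
trial files), writes tidy result tables and a reproducibility manifest,
and returns everything in memory as well.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .abp import (
    DEFAULT_MIN_SEGMENT_POINTS,
    DEFAULT_SLOPE_CRITERION,
    censor_above_threshold,
    detect_t_abp,
)
from .acid_base import fit_h_line, transform_fit
from .errors import CvreactError, ValidationError
from .io import ArterialSample, RebreathingTrial, read_trial, write_results, write_trial
from .preprocess import ProcessedTrial, normalize_mcav, reduce_to_1s
from .sigmoid import SigmoidFit, compute_reserves, fit, fixed_minimum
from .stats import pairwise_compare
from .synthetic import TrialScenario, reference_scenarios, simulate_arterial_samples, simulate_trial

__all__ = ["PipelineConfig", "PipelineResult", "analyze_trial", "run", "demo_config", "subject_overlap", "group_comparisons"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything one reproducible pipeline run depends on."""

    scenarios: list[TrialScenario] = field(default_factory=list)
    trial_paths: list[Path] = field(default_factory=list)
    resting_window_s: float = 60.0
    abp_slope_criterion: float = DEFAULT_SLOPE_CRITERION
    min_segment_points: int = DEFAULT_MIN_SEGMENT_POINTS
    fit_minimum: bool = False
    fit_bounds: tuple | None = None
    simulate_arterial: bool = True
    out_dir: Path | None = None
    log_level: str = "INFO"

    def validate(self) -> None:
        if not self.scenarios and not self.trial_paths:
            raise ValidationError("pipeline config lists no scenarios and no trial files")
        for p in self.trial_paths:
            if not Path(p).exists():
                raise ValidationError(f"trial file does not exist: {p}")

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        d["scenarios"] = [sc.to_dict() for sc in self.scenarios]
        d["trial_paths"] = [str(p) for p in self.trial_paths]
        d["out_dir"] = str(self.out_dir) if self.out_dir else None
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_jsonable(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    records: list[dict]
    per_trial: pd.DataFrame
    summary: pd.DataFrame
    comparisons: pd.DataFrame
    manifest: dict


def analyze_trial(
    trial: RebreathingTrial,
    arterial_samples: list[ArterialSample] | None = None,
    resting_window: tuple[float, float] | None = None,
    abp_slope_criterion: float = DEFAULT_SLOPE_CRITERION,
    min_segment_points: int = DEFAULT_MIN_SEGMENT_POINTS,
    fit_minimum: bool = False,
    fit_bounds=None,
) -> dict:
    """Run the full per-trial analysis and return a flat record.

    Stages: 1-s reduction, percent-normalization, T_ABP detection and
    censoring, fixed-minimum sigmoid fit, vascular reserves, and — when
    arterial samples are supplied — the [H+]-domain re-expression.
    A stage failure is re-raised naming the stage and trial.
    """
    tid = f"{trial.subject_id}/{trial.condition}"

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except CvreactError as exc:
            raise type(exc)(f"stage {name!r} failed for trial {tid}: {exc}") from exc

    one_hz = stage("reduce_to_1s", reduce_to_1s, trial)
    proc: ProcessedTrial = stage("normalize_mcav", normalize_mcav, one_hz, resting_window)
    petco2, _ = proc.pairs("rebreathe")
    abp = one_hz.abp_mmHg[one_hz.segment_mask("rebreathe")]
    thr = stage(
        "detect_t_abp",
        detect_t_abp,
        petco2,
        abp,
        abp_slope_criterion,
        min_segment_points,
    )
    (below_x, below_y), _above = censor_above_threshold(proc, thr)
    minimum = stage("fixed_minimum", fixed_minimum, proc)
    fit_kwargs = {"fit_minimum": fit_minimum}
    if fit_bounds is not None:
        fit_kwargs["bounds"] = fit_bounds
    fitres: SigmoidFit = stage("fit", fit, below_x, below_y, minimum, **fit_kwargs)

    record = {
        "subject_id": trial.subject_id,
        "condition": trial.condition,
        "minimum_pct": fitres.minimum_pct,
        "amplitude_pct": fitres.amplitude_pct,
        "midpoint_mmHg": fitres.midpoint_mmHg,
        "range_mmHg": fitres.range_mmHg,
        "reactivity_pct_per_mmHg": fitres.reactivity_pct_per_mmHg,
        "r_squared": fitres.r_squared,
        "n_points": fitres.n_points,
        "converged": fitres.converged,
        "t_abp_mmHg": thr.t_abp_mmHg,
        "resting_petco2_mmHg": proc.resting_petco2_mmHg,
        "resting_mcav_cm_s": proc.resting_mcav_cm_s,
    }
    if fitres.converged:
        reserves = stage(
            "compute_reserves", compute_reserves, fitres, proc.resting_petco2_mmHg, thr
        )
        record["constriction_pct"] = reserves.constriction_pct
        record["dilation_pct"] = reserves.dilation_pct
    if arterial_samples:
        line = stage("fit_h_line", fit_h_line, arterial_samples)
        fith = stage("transform_fit", transform_fit, fitres, line)
        record.update(
            h_intercept_nEq_L=line.intercept_nEq_L,
            h_slope_nEq_L_per_mmHg=line.slope_nEq_L_per_mmHg,
            midpoint_nEq_L=fith.midpoint_nEq_L,
            range_nEq_L=fith.range_nEq_L,
            reactivity_pct_per_nEq_L=fith.reactivity_pct_per_nEq_L,
        )
    return record


#: parameters compared across conditions in the group stage
COMPARED_PARAMETERS = (
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


def subject_overlap(per_trial: pd.DataFrame) -> dict[str, list[str]]:
    """Subjects appearing in more than one condition, per condition pair.

    The designs of repeated-measures studies partially overlap in
    subjects; the group tests treat conditions as independent, so the
    overlap is recorded alongside the comparisons rather than modelled.
    """
    import itertools

    by_cond = {
        cond: set(sub["subject_id"]) for cond, sub in per_trial.groupby("condition", sort=False)
    }
    return {
        f"{a} & {b}": sorted(by_cond[a] & by_cond[b])
        for a, b in itertools.combinations(by_cond, 2)
        if by_cond[a] & by_cond[b]
    }


def group_comparisons(per_trial: pd.DataFrame) -> pd.DataFrame:
    """Pairwise condition contrasts for every comparable parameter."""
    rows = []
    for param in COMPARED_PARAMETERS:
        if param not in per_trial.columns:
            continue
        groups = {
            cond: sub[param].dropna().to_numpy()
            for cond, sub in per_trial.groupby("condition", sort=False)
        }
        groups = {c: v for c, v in groups.items() if v.size >= 2}
        if len(groups) < 2:
            continue
        for es in pairwise_compare(groups):
            rows.append(
                {
                    "parameter": param,
                    "pair": f"{es.pair[0]} vs {es.pair[1]}",
                    "cohens_d": es.cohens_d,
                    "magnitude": es.magnitude,
                    "p_raw": es.p_raw,
                    "p_adjusted": es.p_adjusted,
                    "significant": es.significant,
                }
            )
    return pd.DataFrame(rows)


def run(config: PipelineConfig) -> PipelineResult:
    """Execute a configuration end to end.

    Identical config (including scenario seeds) produces identical
    outputs.  When ``config.out_dir`` is set, trials, tables, a
    comparisons CSV and a manifest are written there.
    """
    config.validate()
    logging.basicConfig(level=config.log_level)
    records = []
    written_trials = []
    for sc in config.scenarios:
        logger.info("simulating %s/%s (seed %s)", sc.subject_id, sc.condition, sc.seed)
        trial = simulate_trial(sc)
        samples = simulate_arterial_samples(sc) if config.simulate_arterial else None
        records.append(
            analyze_trial(
                trial,
                arterial_samples=samples,
                abp_slope_criterion=config.abp_slope_criterion,
                min_segment_points=config.min_segment_points,
                fit_minimum=config.fit_minimum,
                fit_bounds=config.fit_bounds,
            )
        )
        if config.out_dir is not None:
            trial_dir = Path(config.out_dir) / "trials"
            trial_dir.mkdir(parents=True, exist_ok=True)
            written_trials.append(
                str(write_trial(trial, trial_dir / f"{sc.subject_id}_{sc.condition}.csv"))
            )
    for path in config.trial_paths:
        trial = read_trial(path)
        logger.info("analyzing trial file %s", path)
        records.append(
            analyze_trial(
                trial,
                abp_slope_criterion=config.abp_slope_criterion,
                min_segment_points=config.min_segment_points,
                fit_minimum=config.fit_minimum,
                fit_bounds=config.fit_bounds,
            )
        )

    per_trial = pd.DataFrame(records)
    comparisons = group_comparisons(per_trial) if not per_trial.empty else pd.DataFrame()
    manifest = {
        "cvreact_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "config_hash": config.config_hash(),
        "config": config.to_jsonable(),
        "n_trials": len(records),
        "trial_files": written_trials,
        "subject_overlap": subject_overlap(per_trial) if records else {},
    }
    summary = pd.DataFrame()
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = write_results(records, out)
        summary = pd.read_csv(paths["summary"]) if records else summary
        comparisons.to_csv(out / "comparisons.csv", index=False, float_format="%.10g")
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    else:
        from .io import results_tables

        _, summary = results_tables(records)
    return PipelineResult(
        records=records,
        per_trial=per_trial,
        summary=summary,
        comparisons=comparisons,
        manifest=manifest,
    )


def demo_config(
    seed: int = 0,
    n_subjects: dict[str, int] | None = None,
    out_dir: Path | None = None,
) -> PipelineConfig:
    """The group-mean recovery experiment as a ready-made configuration.

    Simulates noisy trials (5 % MCAv noise) per condition around the
    group-mean scenarios, with per-condition sample sizes matching the
    study (13 SL, 9 ALT1, 7 ALT16 trials).
    """
    if n_subjects is None:
        n_subjects = {"SL": 13, "ALT1": 9, "ALT16": 7}
    scenarios = []
    base = reference_scenarios()
    for j, (cond, n) in enumerate(n_subjects.items()):
        for i in range(n):
            scenarios.append(
                dataclasses.replace(
                    base[cond],
                    subject_id=f"s{i + 1:02d}",
                    seed=seed * 10_000 + j * 100 + i,
                )
            )
    return PipelineConfig(scenarios=scenarios, out_dir=out_dir)


def plot_fit(
    processed: ProcessedTrial,
    fitres: SigmoidFit,
    thr=None,
    path: str | Path = "fit.png",
):
    """Scatter of the rebreathing MCAv%-PETCO2 data with the fitted curve."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x, y = processed.pairs("rebreathe")
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(x, y, ".", ms=3, alpha=0.6, label="rebreathing data")
    grid = np.linspace(x.min(), x.max(), 200)
    ax.plot(grid, fitres.predict(grid), "-", lw=2, label="sigmoid fit")
    if thr is not None and getattr(thr, "detected", False):
        ax.axvline(thr.t_abp_mmHg, ls="--", color="gray", label="T_ABP")
    ax.axvline(processed.resting_petco2_mmHg, ls=":", color="k", label="resting PETCO2")
    ax.set_xlabel("PETCO2 (mmHg)")
    ax.set_ylabel("MCAv (% change)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
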