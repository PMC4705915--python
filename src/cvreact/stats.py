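"""Condition-level summaries, effect sizes and pairwise comparisons.

Per-condition descriptives are mean, SD and a t-based 95% CI.  Effect
size is Cohen's d with the SD of the pooled (concatenated) data in the
denominator, labeled by the conventional 0.2/0.5/0.8/1.3 magnitude
thresholds.  Pairwise condition contrasts use Welch two-sample t-tests
with Holm-Sidak step-down adjustment at alpha = 0.05; conditions are
treated as independent groups (the designs partially overlap in
subjects, which the records track but the tests ignore).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError

__all__ = ["GroupSummary", "EffectSize", "summarize", "cohens_d", "pairwise_compare"]

logger = logging.getLogger(__name__)

ALPHA = 0.05
#: |d| thresholds for negligible / small / moderate / large / very large
MAGNITUDE_THRESHOLDS = (0.2, 0.5, 0.8, 1.3)
MAGNITUDE_LABELS = ("negligible", "small", "moderate", "large", "very large")


@dataclass
class GroupSummary:
    condition: str
    n: int
    mean: float
    ci95_low: float | None
    ci95_high: float | None
    sd: float


@dataclass
class EffectSize:
    pair: tuple[str, str]
    cohens_d: float
    magnitude: str
    p_raw: float | None = None
    p_adjusted: float | None = None
    significant: bool | None = None


def summarize(groups: dict[str, np.ndarray]) -> list[GroupSummary]:
    """Mean, SD and t-distribution 95% CI per condition.

    A singleton group gets no CI (logged); SD of a singleton is 0.
    """
    out = []
    for cond, values in groups.items():
        v = np.asarray(values, dtype=float)
        if v.size == 0:
            raise ValidationError(f"condition {cond!r} has no values")
        mean = float(v.mean())
        if v.size == 1:
            logger.warning("condition %r has a single value; CI omitted", cond)
            out.append(GroupSummary(cond, 1, mean, None, None, 0.0))
            continue
        sd = float(v.std(ddof=1))
        half = sps.t.ppf(0.975, v.size - 1) * sd / np.sqrt(v.size)
        out.append(
            GroupSummary(cond, int(v.size), mean, mean - half, mean + half, sd)
        )
    return out


def _magnitude(d: float) -> str:
    idx = int(np.searchsorted(MAGNITUDE_THRESHOLDS, abs(d), side="right"))
    return MAGNITUDE_LABELS[idx]


def cohens_d(group_a: np.ndarray, group_b: np.ndarray) -> EffectSize:
    """d = (mean_A - mean_B) / SD of the concatenated data.

    Note the denominator is the SD of the pooled *data*, not the
    bias-corrected pooled-variance formula.  Zero pooled SD gives
    d = nan, flagged by magnitude "negligible" and a warning.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("Cohen's d needs n >= 2 in both groups")
    pooled_sd = float(np.concatenate([a, b]).std(ddof=1))
    if pooled_sd == 0:
        logger.warning("zero pooled SD; Cohen's d undefined")
        return EffectSize(pair=("A", "B"), cohens_d=float("nan"), magnitude="negligible")
    d = float((a.mean() - b.mean()) / pooled_sd)
    return EffectSize(pair=("A", "B"), cohens_d=d, magnitude=_magnitude(d))


def holm_sidak(p_raw: np.ndarray) -> np.ndarray:
    """Holm-Sidak step-down adjusted p-values.

    Sorted ascending, p_adj(i) = 1 - (1 - p(i))^(m - i + 1), made
    monotone non-decreasing.  Delegates to statsmodels; the closed-form
    definition above is its contract.
    """
    p = np.asarray(p_raw, dtype=float)
    if p.size == 0:
        return p
    with np.errstate(divide="ignore"):  # log1p(-1) when a raw p is exactly 1
        return multipletests(p, alpha=ALPHA, method="holm-sidak")[1]


def pairwise_compare(
    groups: dict[str, np.ndarray], alpha: float = ALPHA
) -> list[EffectSize]:
    """Welch tests over all condition pairs with Holm-Sidak adjustment."""
    names = list(groups)
    if len(names) < 2:
        raise ValidationError("need >= 2 conditions to compare")
    pairs = list(itertools.combinations(names, 2))
    results = []
    p_raw = []
    for a, b in pairs:
        es = cohens_d(groups[a], groups[b])
        es.pair = (a, b)
        t_res = sps.ttest_ind(groups[a], groups[b], equal_var=False)
        es.p_raw = float(t_res.pvalue)
        p_raw.append(es.p_raw)
        results.append(es)
    p_adj = holm_sidak(np.array(p_raw))
    for es, p in zip(results, p_adj):
        es.p_adjusted = float(p)
        es.significant = bool(p < alpha)
    return results
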