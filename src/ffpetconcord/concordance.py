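"""Scoring FFPET workflows against the fresh-frozen gold standard.

Per probe set, the *effect size* is the difference of mean log2 expression
between ER+ and ER- samples. A probe set is *relevant* when its absolute
effect exceeds a 2-fold threshold (1.0 in log2). Comparing FF and FFPET
effects classifies every probe set into one of five quadrants:

========  =======================================================
TP        relevant in both, same direction
TN        relevant in neither
FN        relevant in FF only (the finding is lost in FFPET)
FP        relevant in FFPET only
WP        relevant in both but direction flips ("wrong positive")
========  =======================================================

With FF assumed to have 100% sensitivity and specificity,

* sensitivity = 100 * TP / (TP + FN + WP)  (all FF-relevant sets), and
* specificity = 100 * TN / (TN + FP)       (all FF-nonrelevant sets).

A sign-flipped finding (WP) counts against sensitivity by default; set
``count_wp_as_miss=False`` for the alternative convention (the two agree
whenever no WP occurs).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix
from .errors import AnalysisError, InputError

__all__ = [
    "EffectRecord",
    "ConcordanceSummary",
    "effect_sizes",
    "classify_quadrant",
    "build_effect_records",
    "sensitivity_specificity",
    "binned_sensitivity",
    "probe_set_t_test",
    "power_simulation",
    "DEFAULT_BIN_EDGES",
]

logger = logging.getLogger(__name__)

QUADRANTS = ("TP", "TN", "FN", "FP", "WP")
DEFAULT_BIN_EDGES = (1.0, 1.5, 2.5, math.inf)


@dataclass(frozen=True)
class EffectRecord:
    probe_set_id: str
    effect_ff: float
    effect_ffpet: float
    quadrant: str


@dataclass
class ConcordanceSummary:
    sensitivity: Optional[float]
    specificity: Optional[float]
    counts: dict[str, int]
    n_scored: int
    threshold: float
    bins: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "counts": self.counts,
            "n_scored": self.n_scored,
            "threshold": self.threshold,
            "bins": self.bins,
        }


# ----------------------------------------------------------------------
def effect_sizes(
    expr: ExpressionMatrix,
    sheet: pd.DataFrame,
    group_field: str = "er_status",
    positive_group: str = "ER+",
    negative_group: str = "ER-",
) -> pd.Series:
    """Per-probe-set effect: mean log2 expression (ER+) minus (ER-).

    Missing values are dropped per probe set; a probe set with an empty
    group gets a missing effect (excluded downstream, count logged).
    """
    info = sheet[sheet["sample_id"].isin(expr.values.columns)]
    pos = info.loc[info[group_field] == positive_group, "sample_id"]
    neg = info.loc[info[group_field] == negative_group, "sample_id"]
    if len(pos) < 2 or len(neg) < 2:
        raise InputError("effect_sizes needs >= 2 samples per group")
    mean_pos = expr.values[list(pos)].mean(axis=1)
    mean_neg = expr.values[list(neg)].mean(axis=1)
    effect = mean_pos - mean_neg
    n_missing = int(effect.isna().sum())
    if n_missing:
        logger.warning("%d probe set(s) have undefined effect; excluded", n_missing)
    effect.name = "effect_log2"
    return effect


def classify_quadrant(
    effect_ff: float, effect_ffpet: float, threshold: float = 1.0
) -> str:
    """Concordance quadrant of one probe set (see module docstring)."""
    if not (np.isfinite(effect_ff) and np.isfinite(effect_ffpet)):
        raise InputError("classify_quadrant requires finite effects")
    rel_ff = abs(effect_ff) > threshold
    rel_fp = abs(effect_ffpet) > threshold
    if rel_ff and rel_fp:
        return "TP" if effect_ff * effect_ffpet > 0 else "WP"
    if rel_ff:
        return "FN"
    if rel_fp:
        return "FP"
    return "TN"


def build_effect_records(
    effect_ff: pd.Series,
    effect_ffpet: pd.Series,
    threshold: float = 1.0,
) -> list[EffectRecord]:
    """Join FF and FFPET effects on shared probe sets and classify each."""
    shared = effect_ff.index.intersection(effect_ffpet.index)
    records = []
    for set_id in shared:
        a, b = float(effect_ff[set_id]), float(effect_ffpet[set_id])
        if not (np.isfinite(a) and np.isfinite(b)):
            continue
        records.append(EffectRecord(set_id, a, b, classify_quadrant(a, b, threshold)))
    return records


def sensitivity_specificity(
    records: Sequence[EffectRecord],
    threshold: float = 1.0,
    count_wp_as_miss: bool = True,
) -> ConcordanceSummary:
    """Global sensitivity/specificity from classified effect records.

    An empty denominator reports the corresponding value as missing
    (None), never as 0.
    """
    counts = {q: 0 for q in QUADRANTS}
    for r in records:
        counts[r.quadrant] += 1
    if count_wp_as_miss:
        sens_num, sens_den = counts["TP"], counts["TP"] + counts["FN"] + counts["WP"]
    else:
        sens_num = counts["TP"] + counts["WP"]
        sens_den = counts["TP"] + counts["FN"] + counts["WP"]
    spec_num, spec_den = counts["TN"], counts["TN"] + counts["FP"]
    sensitivity = 100.0 * sens_num / sens_den if sens_den else None
    specificity = 100.0 * spec_num / spec_den if spec_den else None
    if sens_den == 0 or spec_den == 0:
        logger.warning("empty denominator: sensitivity/specificity reported missing")
    return ConcordanceSummary(
        sensitivity=sensitivity,
        specificity=specificity,
        counts=counts,
        n_scored=len(records),
        threshold=threshold,
    )


def binned_sensitivity(
    records: Sequence[EffectRecord],
    bin_edges: Sequence[float] = DEFAULT_BIN_EDGES,
    threshold: float = 1.0,
    low_n: int = 10,
) -> list[dict]:
    """Sensitivity/specificity within |FF effect| bins.

    The first stated edge also bounds the nonrelevant stratum: records
    with ``|effect_ff| <= bin_edges[0]`` form a bin of their own whose
    specificity is meaningful and whose sensitivity is undefined.
    """
    edges = list(bin_edges)
    if any(b >= a for b, a in zip(edges, edges[1:])) or len(edges) < 2:
        raise InputError("bin edges must be strictly increasing")
    bins = []
    intervals = [(-math.inf, edges[0])] + list(zip(edges, edges[1:]))
    for lo, hi in intervals:
        sub = [r for r in records if lo < abs(r.effect_ff) <= hi]
        summary = sensitivity_specificity(sub, threshold=threshold)
        bins.append(
            {
                "interval": [None if math.isinf(lo) else lo, None if math.isinf(hi) else hi],
                "sensitivity": summary.sensitivity,
                "specificity": summary.specificity,
                "counts": summary.counts,
                "n": len(sub),
                "low_n": len(sub) < low_n,
            }
        )
    return bins


# ----------------------------------------------------------------------
def probe_set_t_test(
    expr: ExpressionMatrix,
    sheet: pd.DataFrame,
    probe_set_id: str,
    group_field: str = "er_status",
    positive_group: str = "ER+",
    negative_group: str = "ER-",
    equal_var: bool = True,
) -> tuple[float, float]:
    """Two-sample t test of one probe set's log2 expression between groups.

    Pooled-variance by default (``equal_var=False`` switches to Welch).
    The sign convention is (ER+ minus ER-). Zero pooled variance is an
    error: the statistic is undefined.
    """
    if probe_set_id not in expr.values.index:
        raise InputError(f"unknown probe set id: {probe_set_id}")
    info = sheet[sheet["sample_id"].isin(expr.values.columns)]
    pos = info.loc[info[group_field] == positive_group, "sample_id"]
    neg = info.loc[info[group_field] == negative_group, "sample_id"]
    if len(pos) < 2 or len(neg) < 2:
        raise InputError("probe_set_t_test needs >= 2 samples per group")
    a = expr.values.loc[probe_set_id, list(pos)].to_numpy(float)
    b = expr.values.loc[probe_set_id, list(neg)].to_numpy(float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        raise AnalysisError(f"{probe_set_id}: zero pooled variance, t undefined")
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def power_simulation(
    n_per_group: int,
    effect_log2: float,
    sigma_log2: float,
    alpha: float = 0.05,
    n_reps: int = 10_000,
    seed: int = 0,
) -> float:
    """Monte-Carlo power of the pooled two-sample t test.

    Draws ``n_reps`` experiments of ``n_per_group`` log2 values per group
    from N(0, sigma) and N(effect, sigma) and reports the fraction of
    two-sided p-values below ``alpha``. The variance assumption is the
    caller's: ``sigma_log2`` must be supplied explicitly.
    """
    if min(n_per_group, n_reps) < 1 or sigma_log2 <= 0 or not 0 < alpha < 1:
        raise InputError("power_simulation: all parameters must be positive")
    if n_reps < 100:
        logger.warning("n_reps=%d gives a wide power confidence interval", n_reps)
    rng = np.random.default_rng(seed)
    x = rng.normal(0.0, sigma_log2, size=(n_reps, n_per_group))
    y = rng.normal(effect_log2, sigma_log2, size=(n_reps, n_per_group))
    nx = ny = n_per_group
    vx = x.var(axis=1, ddof=1)
    vy = y.var(axis=1, ddof=1)
    sp2 = ((nx - 1) * vx + (ny - 1) * vy) / (nx + ny - 2)
    t = (y.mean(axis=1) - x.mean(axis=1)) / np.sqrt(sp2 * (1.0 / nx + 1.0 / ny))
    df = nx + ny - 2
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return float(np.mean(p < alpha))
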