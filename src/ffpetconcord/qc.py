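"""Sample- and design-level quality metrics.

* limit of blank (LOB): the 95th percentile of the complete-mismatch
  probe-set expression per sample (linear interpolation between closest
  order statistics);
* present calls: fraction of probe sets whose expression exceeds the LOB;
* probe-set consistency: fraction of multi-probe-set genes whose related
  probe sets fail to correlate (median pairwise Pearson r <= 0.5);
* matched-pair correlation between FF and FFPET expression;
* the in-silico 3'/5' intensity ratio of a designated control transcript
  (intact RNA gives a ratio of ~1; degradation raises it).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .annotate import ProbeRecord, TranscriptRecord
from .containers import ExpressionMatrix, IntensityMatrix
from .errors import AnalysisError, InputError

__all__ = [
    "QCReport",
    "estimate_lob",
    "present_calls",
    "probe_set_consistency",
    "pair_correlation",
    "three_prime_ratio",
]

logger = logging.getLogger(__name__)


@dataclass
class QCReport:
    """Per-cohort quality summary (Table-2-style columns)."""

    lob: dict[str, float] = field(default_factory=dict)
    percent_present: dict[str, float] = field(default_factory=dict)
    percent_probe_sets_above_lob: Optional[float] = None
    percent_inconsistent_genes: Optional[float] = None
    three_prime_ratio: dict[str, float] = field(default_factory=dict)
    pair_correlation: dict[str, float] = field(default_factory=dict)
    pair_correlation_summary: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "lob": self.lob,
            "percent_present": self.percent_present,
            "percent_probe_sets_above_lob": self.percent_probe_sets_above_lob,
            "percent_inconsistent_genes": self.percent_inconsistent_genes,
            "three_prime_ratio": self.three_prime_ratio,
            "pair_correlation": self.pair_correlation,
            "pair_correlation_summary": self.pair_correlation_summary,
        }


# ----------------------------------------------------------------------
def estimate_lob(expr: ExpressionMatrix, blank_set_ids: Sequence[str]) -> pd.Series:
    """Per-sample limit of blank: 95th percentile of blank-set expression.

    Uses linear interpolation between the closest order statistics (the
    convention under which blanks 1..20 give LOB = 19.05). Raises when no
    blank sets are available; logs a warning below 20 sets (the percentile
    is then coarse).
    """
    blank_ids = [s for s in blank_set_ids if s in expr.values.index]
    if not blank_ids:
        raise AnalysisError("no complete-mismatch probe sets: LOB undefined")
    if len(blank_ids) < 20:
        logger.warning("only %d blank sets; LOB estimate will be coarse", len(blank_ids))
    blanks = expr.values.loc[blank_ids]
    lob = blanks.quantile(0.95, axis=0, interpolation="linear")
    lob.name = "lob"
    return lob


def present_calls(
    expr: ExpressionMatrix,
    lob: pd.Series,
    blank_set_ids: Sequence[str] = (),
) -> tuple[pd.Series, float]:
    """Percent of probe sets called present (expression > LOB).

    Blank control sets are excluded from numerator and denominator.
    Returns per-sample percentages and the pooled percentage of probe
    sets whose median expression across samples exceeds the median LOB.
    """
    keep = expr.values.index.difference(pd.Index(blank_set_ids))
    v = expr.values.loc[keep]
    above = v.gt(lob, axis=1)
    percent = 100.0 * above.sum(axis=0) / len(keep)
    percent.name = "percent_present"
    pooled = 100.0 * float(
        (v.median(axis=1) > float(lob.median())).sum()
    ) / len(keep)
    return percent, pooled


# ----------------------------------------------------------------------
def probe_set_consistency(
    expr: ExpressionMatrix,
    set_gene: dict[str, Optional[str]],
    threshold: float = 0.5,
) -> tuple[float, pd.DataFrame]:
    """Percent of multi-probe-set genes with inconsistent sequence detection.

    For every gene measured by >= 2 probe sets in ``expr``, the Pearson
    correlation across samples is computed for each probe-set pair; the
    gene is inconsistent when the median pairwise correlation does not
    exceed ``threshold``. Zero-variance probe-set vectors make a pair's
    correlation undefined and the pair is excluded with a warning.
    """
    if expr.values.shape[1] < 3:
        raise InputError("probe-set consistency needs >= 3 samples")
    genes: dict[str, list[str]] = {}
    for set_id in expr.values.index:
        gene = set_gene.get(set_id)
        if gene is not None:
            genes.setdefault(gene, []).append(set_id)
    rows = []
    for gene in sorted(genes):
        sets = genes[gene]
        if len(sets) < 2:
            continue
        corrs = []
        for a, b in combinations(sets, 2):
            va = expr.values.loc[a].to_numpy(float)
            vb = expr.values.loc[b].to_numpy(float)
            keep = np.isfinite(va) & np.isfinite(vb)
            if keep.sum() < 3 or va[keep].std() == 0 or vb[keep].std() == 0:
                logger.warning(
                    "gene %s: correlation of %s vs %s undefined; excluded", gene, a, b
                )
                continue
            corrs.append(float(np.corrcoef(va[keep], vb[keep])[0, 1]))
        if not corrs:
            continue
        med = float(np.median(corrs))
        rows.append((gene, len(sets), med, med <= threshold))
    detail = pd.DataFrame(
        rows, columns=["gene_id", "n_probe_sets", "median_pairwise_r", "inconsistent"]
    )
    if detail.empty:
        return float("nan"), detail
    percent = 100.0 * float(detail["inconsistent"].sum()) / len(detail)
    return percent, detail


# ----------------------------------------------------------------------
def pair_correlation(
    expr_ff: ExpressionMatrix,
    expr_ffpet: ExpressionMatrix,
    sheet: pd.DataFrame,
) -> tuple[pd.Series, dict[str, float]]:
    """Pearson r of log2 expression between matched FF and FFPET samples.

    Pairs are linked through ``pair_id``; samples without a counterpart in
    both matrices are excluded with a warning. Missing expression values
    are dropped pairwise. Returns per-pair correlations plus the median
    and quartile summary.
    """
    ff_of = sheet[sheet["sample_id"].isin(expr_ff.values.columns)].set_index("pair_id")[
        "sample_id"
    ]
    fp_of = sheet[sheet["sample_id"].isin(expr_ffpet.values.columns)].set_index(
        "pair_id"
    )["sample_id"]
    shared_sets = expr_ff.values.index.intersection(expr_ffpet.values.index)
    rs = {}
    for pair in sorted(set(ff_of.index) | set(fp_of.index)):
        if pair not in ff_of.index or pair not in fp_of.index:
            logger.warning("pair %s lacks a matched sample; excluded", pair)
            continue
        a = expr_ff.values.loc[shared_sets, ff_of[pair]].to_numpy(float)
        b = expr_ffpet.values.loc[shared_sets, fp_of[pair]].to_numpy(float)
        keep = np.isfinite(a) & np.isfinite(b)
        if keep.sum() < 3 or a[keep].std() == 0 or b[keep].std() == 0:
            raise AnalysisError(f"pair {pair}: correlation undefined (constant column)")
        rs[pair] = float(np.corrcoef(a[keep], b[keep])[0, 1])
    series = pd.Series(rs, name="pearson_r")
    summary = {
        "median": float(series.median()),
        "q25": float(series.quantile(0.25)),
        "q75": float(series.quantile(0.75)),
    }
    return series, summary


# ----------------------------------------------------------------------
def three_prime_ratio(
    intensities: IntensityMatrix,
    design: Sequence[ProbeRecord],
    transcript: TranscriptRecord,
    min_probes: int = 2,
) -> pd.Series:
    """In-silico 3'/5' intensity ratio of a designated control transcript.

    The transcript is split into terminal thirds by each probe's distance
    from the 3' end; the ratio is the mean linear intensity of probes in
    the 3'-most third over the mean in the 5'-most third, per sample.
    Intact (undegraded) RNA gives a ratio near 1; 3'-biased degradation
    raises it. Samples whose 5' mean is not positive get a missing ratio.
    """
    length = len(transcript.sequence)
    gene = transcript.gene_id
    probes = [
        p for p in design if p.target_gene == gene and p.d3prime is not None
    ]
    three = [p.probe_id for p in probes if p.d3prime < length / 3.0]
    five = [p.probe_id for p in probes if p.d3prime > 2.0 * length / 3.0]
    if len(three) < min_probes or len(five) < min_probes:
        raise InputError(
            f"control transcript {transcript.transcript_id} needs >= {min_probes} "
            f"probes in each terminal third (got {len(three)} / {len(five)})"
        )
    v = intensities.masked_values()
    mean3 = v.loc[[p for p in three if p in v.index]].mean(axis=0)
    mean5 = v.loc[[p for p in five if p in v.index]].mean(axis=0)
    ratio = mean3 / mean5
    ratio[mean5 <= 0] = np.nan
    ratio.name = "three_prime_ratio"
    return ratio
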