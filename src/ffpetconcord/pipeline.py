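"""End-to-end orchestration: simulate -> revise -> preprocess -> qc ->
concordance -> pca, with one config, fixed artifact names, and a single
machine-readable report.

Stage outputs land under ``outdir`` with fixed names so downstream stages
can be rerun from cached upstream artifacts. The report JSON is written
last; rerunning with the same config and seed reproduces it byte for byte
(all randomness derives from the master seed, and the report carries no
timestamps).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__, io
from .annotate import revise_design
from .concordance import (
    DEFAULT_BIN_EDGES,
    binned_sensitivity,
    build_effect_records,
    effect_sizes,
    sensitivity_specificity,
)
from .config import SimulationConfig
from .containers import ExpressionMatrix
from .errors import FFPETConcordError
from .multivariate import pca_samples
from .preprocess import expression_index
from .qc import (
    QCReport,
    estimate_lob,
    pair_correlation,
    present_calls,
    probe_set_consistency,
    three_prime_ratio,
)
from .synthetic import (
    CONTROL_GENE,
    generate_array_design,
    generate_reference,
    simulate_cohort,
)

__all__ = ["run_pipeline"]

logger = logging.getLogger(__name__)


def _stage(name: str):
    logger.info("stage %s: start", name)
    return time.perf_counter()


def _done(name: str, t0: float) -> None:
    logger.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)


def _config_hash(config: SimulationConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()


def run_pipeline(
    config,
    outdir,
    seed: Optional[int] = None,
    threshold: float = 1.0,
    background: str = "rma",
    n_pca_components: int = 3,
) -> dict:
    """Run the whole workflow and return the report dict.

    ``config`` may be a :class:`SimulationConfig`, a mapping, or a path to
    a YAML file; ``seed`` overrides the config seed. Any stage failure
    aborts with the stage name; partial outputs are retained for
    debugging.
    """
    if isinstance(config, (str, Path)):
        config = SimulationConfig.from_yaml(config)
    elif isinstance(config, dict):
        config = SimulationConfig.from_dict(config)
    config = config.with_seed(seed)
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    stage = "simulate"
    try:
        t0 = _stage(stage)
        reference = generate_reference(config)
        design, truth, reference = generate_array_design(reference, config)
        ff, ffpet, sheet = simulate_cohort(reference, design, truth, config)
        io.write_reference_fasta(reference, outdir / "reference.fa")
        io.write_design_tsv(design, outdir / "probes.tsv")
        io.write_probe_fasta(design, outdir / "probes.fa")
        io.write_sample_sheet(sheet, outdir / "samples.tsv")
        io.write_json(truth.to_dict(), outdir / "truth.json")
        io.write_matrix_tsv(ff.values, outdir / "intensities_ff.tsv", "probe_id")
        for kit, m in ffpet.items():
            io.write_matrix_tsv(m.values, outdir / f"intensities_{kit}.tsv", "probe_id")
        _done(stage, t0)

        stage = "revise"
        t0 = _stage(stage)
        revised = revise_design(design, reference)
        io.write_revised_design(revised, outdir / "revised_design.tsv")
        pd.Series(revised.probe_class, name="probe_class").rename_axis("probe_id").to_csv(
            outdir / "probe_classes.tsv", sep="\t"
        )
        _done(stage, t0)

        stage = "preprocess"
        t0 = _stage(stage)
        cohorts = {"ff": ff, **ffpet}
        expr: dict[str, ExpressionMatrix] = {}
        spatial_qc = {}
        for label, m in cohorts.items():
            e, affin, sqc = expression_index(
                m, revised, background=background, design_ref=label
            )
            expr[label] = e
            spatial_qc[label] = sqc
            io.write_matrix_tsv(e.values, outdir / f"expression_{label}.tsv", "probe_set_id")
            affin.to_frame().to_csv(outdir / f"affinity_{label}.tsv", sep="\t", index=False)
        _done(stage, t0)

        stage = "qc"
        t0 = _stage(stage)
        control = next((t for t in reference if t.gene_id == CONTROL_GENE), None)
        qc_reports: dict[str, QCReport] = {}
        for label, e in expr.items():
            report = QCReport()
            lob = estimate_lob(e, revised.complete_mismatch_set_ids)
            report.lob = {k: float(v) for k, v in lob.items()}
            percent, pooled = present_calls(e, lob, revised.complete_mismatch_set_ids)
            report.percent_present = {k: float(v) for k, v in percent.items()}
            report.percent_probe_sets_above_lob = float(pooled)
            consistency, detail = probe_set_consistency(e, truth.set_gene)
            report.percent_inconsistent_genes = (
                None if pd.isna(consistency) else float(consistency)
            )
            detail.to_csv(outdir / f"consistency_{label}.tsv", sep="\t", index=False)
            if control is not None:
                ratio = three_prime_ratio(cohorts[label], design, control)
                report.three_prime_ratio = {
                    k: (None if pd.isna(v) else float(v)) for k, v in ratio.items()
                }
            if label != "ff":
                pairs, summary = pair_correlation(expr["ff"], e, sheet)
                report.pair_correlation = {k: float(v) for k, v in pairs.items()}
                report.pair_correlation_summary = summary
            qc_reports[label] = report

        def _qc_dict(label: str) -> dict:
            d = qc_reports[label].to_dict()
            sqc = spatial_qc[label]
            if sqc is not None:
                d["optical_noise"] = {k: float(v) for k, v in sqc.optical_noise.items()}
                d["masked_probes"] = {k: int(v) for k, v in sqc.masked_counts.items()}
            return d

        io.write_json({label: _qc_dict(label) for label in qc_reports}, outdir / "qc.json")
        _done(stage, t0)

        stage = "concordance"
        t0 = _stage(stage)
        eff_ff = effect_sizes(expr["ff"], sheet)
        keep = eff_ff.index.difference(pd.Index(revised.complete_mismatch_set_ids))
        eff_ff = eff_ff.loc[keep]
        concord = {}
        for label, e in expr.items():
            if label == "ff":
                continue
            eff_fp = effect_sizes(e, sheet).reindex(keep)
            records = build_effect_records(eff_ff, eff_fp, threshold=threshold)
            summary = sensitivity_specificity(records, threshold=threshold)
            summary.bins = binned_sensitivity(records, DEFAULT_BIN_EDGES, threshold)
            concord[label] = summary
            pd.DataFrame(
                [(r.probe_set_id, r.effect_ff, r.effect_ffpet, r.quadrant) for r in records],
                columns=["probe_set_id", "effect_ff", "effect_ffpet", "quadrant"],
            ).to_csv(outdir / f"effects_{label}.tsv", sep="\t", index=False)
        io.write_json(
            {label: s.to_dict() for label, s in concord.items()},
            outdir / "concordance.json",
        )
        _done(stage, t0)

        stage = "pca"
        t0 = _stage(stage)
        pca_summaries = {}
        for label, e in expr.items():
            res = pca_samples(e, n_components=n_pca_components)
            scores = res.scores.copy()
            meta = sheet.set_index("sample_id")
            scores["er_status"] = meta.loc[scores.index, "er_status"]
            scores.to_csv(outdir / f"pca_scores_{label}.tsv", sep="\t", index_label="sample_id")
            pca_summaries[label] = {
                "variance_explained": [float(v) for v in res.variance_explained],
                "n_rows_dropped": res.n_rows_dropped,
            }
        _done(stage, t0)

        stage = "report"
        t0 = _stage(stage)
        report = {
            "provenance": {
                "config_hash": _config_hash(config),
                "seed": config.seed,
                "version": __version__,
            },
            "design": {
                "set_classes": revised.class_counts(),
                "n_complete_mismatch_sets": len(revised.complete_mismatch_set_ids),
                "n_probes": len(design),
            },
            "qc": {label: _qc_dict(label) for label in qc_reports},
            "concordance": {label: s.to_dict() for label, s in concord.items()},
            "pca": pca_summaries,
        }
        io.write_json(report, outdir / "report.json")
        _done(stage, t0)
        return report
    except FFPETConcordError as exc:
        raise FFPETConcordError(f"stage '{stage}' failed: {exc}") from exc
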