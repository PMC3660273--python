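"""Readers and writers for the pipeline's plain-text artifact formats.

FASTA carries the reference transcriptome (gene ids in a ``gene=<id>``
header token) and probe sequences; TSV carries the probe design, intensity
matrices, sample sheets, revised designs, and effect tables; JSON carries
ground truth, QC and concordance reports. All writers are deterministic.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
from Bio import SeqIO

from .annotate import ProbeRecord, RevisedDesign, TranscriptRecord
from .containers import ExpressionMatrix, IntensityMatrix
from .errors import InputError

__all__ = [
    "write_reference_fasta",
    "read_reference_fasta",
    "write_probe_fasta",
    "write_design_tsv",
    "read_design_tsv",
    "write_matrix_tsv",
    "read_intensity_tsv",
    "read_expression_tsv",
    "write_sample_sheet",
    "read_sample_sheet",
    "write_revised_design",
    "read_revised_design",
    "write_json",
]

_WRAP = 80


def write_reference_fasta(records: Sequence[TranscriptRecord], path) -> None:
    with open(path, "w") as fh:
        for t in records:
            fh.write(f">{t.transcript_id} gene={t.gene_id}\n")
            for i in range(0, len(t.sequence), _WRAP):
                fh.write(t.sequence[i : i + _WRAP] + "\n")


def read_reference_fasta(path) -> list[TranscriptRecord]:
    """Parse transcripts; ``gene_id`` comes from a ``gene=<id>`` header token."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        gene = None
        for token in rec.description.split():
            if token.startswith("gene="):
                gene = token[5:]
        if gene is None:
            raise InputError(f"transcript {rec.id}: no gene=<id> token in header")
        records.append(TranscriptRecord(rec.id, gene, str(rec.seq).upper()))
    if not records:
        raise InputError(f"no FASTA records in {path}")
    return records


def write_probe_fasta(design: Sequence[ProbeRecord], path) -> None:
    with open(path, "w") as fh:
        for p in design:
            fh.write(f">{p.probe_id} set={p.probe_set_id}\n{p.sequence}\n")


_DESIGN_COLS = ["probe_id", "probe_set_id", "sequence", "x", "y", "d3prime", "target_gene"]


def write_design_tsv(design: Sequence[ProbeRecord], path) -> None:
    frame = pd.DataFrame(
        [
            (p.probe_id, p.probe_set_id, p.sequence, p.x, p.y,
             "" if p.d3prime is None else p.d3prime,
             "" if p.target_gene is None else p.target_gene)
            for p in design
        ],
        columns=_DESIGN_COLS,
    )
    frame.to_csv(path, sep="\t", index=False)


def read_design_tsv(path) -> list[ProbeRecord]:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(_DESIGN_COLS[:5]) - set(frame.columns)
    if missing:
        raise InputError(f"design TSV missing column(s): {sorted(missing)}")
    out = []
    for row in frame.itertuples(index=False):
        d3 = getattr(row, "d3prime", "")
        gene = getattr(row, "target_gene", "")
        out.append(
            ProbeRecord(
                probe_id=row.probe_id,
                probe_set_id=row.probe_set_id,
                sequence=row.sequence,
                x=int(row.x),
                y=int(row.y),
                d3prime=None if d3 == "" else int(float(d3)),
                target_gene=gene or None,
            )
        )
    return out


def write_matrix_tsv(values: pd.DataFrame, path, index_label: str) -> None:
    values.to_csv(path, sep="\t", index_label=index_label, float_format="%.6f")


def read_intensity_tsv(path, geometry: Optional[pd.DataFrame] = None) -> IntensityMatrix:
    values = pd.read_csv(path, sep="\t", index_col=0)
    return IntensityMatrix(values, geometry)


def read_expression_tsv(path, design_ref: str = "") -> ExpressionMatrix:
    values = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(values, design_ref=design_ref)


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    sheet.to_csv(path, sep="\t", index=False)


def read_sample_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "preparation", "kit", "er_status", "pair_id"}
    missing = required - set(sheet.columns)
    if missing:
        raise InputError(f"sample sheet missing column(s): {sorted(missing)}")
    return sheet


def write_revised_design(revised: RevisedDesign, path) -> None:
    rows = []
    for set_id in sorted(revised.set_class):
        rows.append(
            (
                set_id,
                revised.set_class[set_id],
                ",".join(revised.retained.get(set_id, [])),
                "yes" if set_id in revised.complete_mismatch_set_ids else "no",
            )
        )
    pd.DataFrame(
        rows, columns=["probe_set_id", "set_class", "retained_probe_ids", "complete_mismatch"]
    ).to_csv(path, sep="\t", index=False)


def read_revised_design(path, design: Sequence[ProbeRecord]) -> RevisedDesign:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    probes = {p.probe_id: p for p in design}
    set_class, retained, blanks = {}, {}, []
    for row in frame.itertuples(index=False):
        set_class[row.probe_set_id] = row.set_class
        if row.retained_probe_ids:
            retained[row.probe_set_id] = row.retained_probe_ids.split(",")
        if row.complete_mismatch == "yes":
            blanks.append(row.probe_set_id)
    probe_class = {}
    for set_id, ids in retained.items():
        for pid in ids:
            probe_class[pid] = "MATCH_UNIQUE"
    return RevisedDesign(
        probe_class=probe_class,
        set_class=set_class,
        retained=retained,
        complete_mismatch_set_ids=blanks,
        probes=probes,
    )


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
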