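"""Synthetic matched FF/FFPET microarray cohorts with ground truth.

The generator emulates the statistical structure the downstream analysis
assumes:

* a random reference transcriptome (one transcript per gene, i.i.d. bases);
* an Affymetrix-style probe design (11 probes of 25 nt per probe set, 1-3
  probe sets per gene) with planted flaws — non-matching probes (random
  sequences verified absent from the reference at Hamming <= 3) and
  cross-hybridizing probes (the probe's target window copied into a second
  gene's transcript) — plus whole complete-mismatch control sets;
* a matched tumor cohort: each tumor is split into mirrored FF and FFPET
  sections sharing one latent expression draw; group structure is ER+
  versus ER- with a designed fraction of genes differentially expressed by
  more than 2-fold;
* kit-specific FFPET degradation, additive in log2: global attenuation,
  linear 3'-distance decay, extra noise, and probe dropout. Intensities are
  emitted on the linear scale as ``2**signal + background`` and floored at 1.

A densely tiled control transcript (the in-silico analog of the beta-actin
3'/5' assay) is appended by default so the 3'/5' intensity ratio can be
estimated with small probe-sampling error.

All randomness derives from ``config.seed`` through fixed named PCG64
streams, so outputs are byte-identical for a fixed seed regardless of call
order or platform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .annotate import ProbeRecord, ReferenceIndex, TranscriptRecord, revcomp
from .config import DegradationProfile, SimulationConfig
from .containers import IntensityMatrix
from .errors import ConfigurationError, GenerationError

__all__ = [
    "GroundTruth",
    "CONTROL_GENE",
    "generate_reference",
    "generate_array_design",
    "simulate_cohort",
    "predicted_ffpet_effect",
    "expected_three_prime_ratio",
]

CONTROL_GENE = "GCTRL"
CONTROL_TRANSCRIPT = "TCTRL"

# probe true classes recorded in the ground truth
CLASS_MATCHING = "matching-unique"
CLASS_CROSSHYB = "crosshyb"
CLASS_NONMATCHING = "nonmatching"
CLASS_BLANK = "blank-control"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# named RNG stream ids (documented so streams stay stable across versions)
_STREAM_REFERENCE = 1
_STREAM_DESIGN = 2
_STREAM_FLAWS = 3
_STREAM_EFFECTS = 4
_STREAM_COHORT = 5
_STREAM_KIT_BASE = 6


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *key]))


@dataclass
class GroundTruth:
    """The simulator's hidden state: the acceptance surface for recovery tests.

    ``gene_effects`` holds the true log2 effect delta_g (ER+ minus ER-);
    ``probe_classes`` the planted class of every probe; ``probe_d3`` the
    distance from the probe's 3'-most base to the transcript 3' end.
    ``baselines`` and ``samples`` are filled in by :func:`simulate_cohort`.
    """

    gene_effects: dict[str, float]
    probe_classes: dict[str, str]
    probe_d3: dict[str, Optional[int]]
    crosshyb_partners: dict[str, tuple[str, int]] = field(default_factory=dict)
    silenced_genes: list[str] = field(default_factory=list)
    blank_set_ids: list[str] = field(default_factory=list)
    set_gene: dict[str, Optional[str]] = field(default_factory=dict)
    baselines: dict[str, float] = field(default_factory=dict)
    samples: Optional[pd.DataFrame] = None

    def expected_set_class(self, probe_set_id: str, min_retained: int = 3) -> str:
        """Set class implied by the planted per-probe classes alone."""
        probes = [p for p, _ in self._set_members(probe_set_id)]
        classes = [self.probe_classes[p] for p in probes]
        n_unique = sum(c == CLASS_MATCHING for c in classes)
        if n_unique >= min_retained:
            return "unique"
        if any(c == CLASS_CROSSHYB for c in classes):
            return "nonunique"
        return "mismatched"

    def _set_members(self, probe_set_id: str):
        return [
            (p, c) for p, c in self.probe_classes.items()
            if p.rsplit("_p", 1)[0] == probe_set_id
        ]

    def de_genes(self, threshold: float = 1.0) -> list[str]:
        return sorted(g for g, d in self.gene_effects.items() if abs(d) > threshold)

    def to_dict(self) -> dict:
        return {
            "gene_effects": self.gene_effects,
            "probe_classes": self.probe_classes,
            "probe_d3": self.probe_d3,
            "crosshyb_partners": {k: list(v) for k, v in self.crosshyb_partners.items()},
            "silenced_genes": self.silenced_genes,
            "blank_set_ids": self.blank_set_ids,
            "set_gene": self.set_gene,
            "baselines": self.baselines,
        }


# ----------------------------------------------------------------------
def generate_reference(config: SimulationConfig) -> list[TranscriptRecord]:
    """Random reference transcriptome: one transcript per gene.

    Bases are i.i.d. uniform over {A,C,G,T}; lengths are uniform over
    ``transcript_length_range``. When ``include_degradation_control`` is
    set, a fixed-length control transcript (gene ``GCTRL``) is appended
    for the in-silico 3'/5' integrity assay.
    """
    config.validate()
    rng = _rng(config.seed, _STREAM_REFERENCE)
    lo, hi = config.transcript_length_range
    records = []
    width = max(4, len(str(config.n_genes)))
    for i in range(config.n_genes):
        length = int(rng.integers(lo, hi + 1))
        seq = rng.choice(_BASES, size=length).tobytes().decode("ascii")
        gid = f"G{i + 1:0{width}d}"
        records.append(TranscriptRecord(f"T{i + 1:0{width}d}", gid, seq))
    if config.include_degradation_control:
        seq = rng.choice(
            _BASES, size=config.control_transcript_length
        ).tobytes().decode("ascii")
        records.append(TranscriptRecord(CONTROL_TRANSCRIPT, CONTROL_GENE, seq))
    return records


# ----------------------------------------------------------------------
def _sample_offsets(rng, length: int, probe_len: int, n: int) -> np.ndarray:
    n_windows = length - probe_len + 1
    n = min(n, n_windows)
    offs = rng.choice(n_windows, size=n, replace=False)
    return np.sort(offs)


def _random_absent_probe(
    rng, index: ReferenceIndex, probe_len: int, max_mismatches: int, max_tries: int = 50
) -> str:
    for _ in range(max_tries):
        seq = rng.choice(_BASES, size=probe_len).tobytes().decode("ascii")
        if not index.has_any_match(seq, max_mismatches):
            return seq
    raise GenerationError(
        f"could not draw a probe absent from the reference at Hamming <= "
        f"{max_mismatches} after {max_tries} tries"
    )


def generate_array_design(
    reference: list[TranscriptRecord], config: SimulationConfig
) -> tuple[list[ProbeRecord], GroundTruth, list[TranscriptRecord]]:
    """Build a flawed probe design over ``reference`` with known truth.

    Flaw planting uses ``round(fraction * n_candidate_probes)`` probes
    (ties rounded half-to-even by numpy convention). Cross-hybridization
    is planted by copying a probe's target window into a second gene's
    transcript, so the **returned reference is mutated accordingly** and
    must be used for all downstream matching. Control probes (densely
    tiled control transcript) and complete-mismatch sets are appended last.

    Returns ``(design, truth, mutated_reference)``.
    """
    if not reference:
        raise GenerationError("reference is empty")
    config.validate()
    rng_design = _rng(config.seed, _STREAM_DESIGN)
    rng_flaws = _rng(config.seed, _STREAM_FLAWS)
    rng_eff = _rng(config.seed, _STREAM_EFFECTS)
    L = config.probe_length

    by_gene = {t.gene_id: t for t in reference}
    gene_ids = [t.gene_id for t in reference if t.gene_id != CONTROL_GENE]
    seqs = {t.transcript_id: t.sequence for t in reference}

    set_counts = sorted(config.probe_sets_per_gene)
    set_probs = np.array([config.probe_sets_per_gene[k] for k in set_counts], float)
    set_probs /= set_probs.sum()

    probes: list[dict] = []
    set_gene: dict[str, Optional[str]] = {}
    # window occupancy per transcript, to keep cross-hyb insertions away
    # from designed probe windows
    occupied: dict[str, list[tuple[int, int]]] = {t.transcript_id: [] for t in reference}

    for gid in gene_ids:
        t = by_gene[gid]
        n_sets = int(rng_design.choice(set_counts, p=set_probs))
        for s in range(1, n_sets + 1):
            set_id = f"{gid}_ps{s}"
            set_gene[set_id] = gid
            offs = _sample_offsets(rng_design, len(t.sequence), L, config.probes_per_set)
            for j, off in enumerate(offs, start=1):
                occupied[t.transcript_id].append((int(off), int(off) + L))
                probes.append(
                    dict(
                        probe_id=f"{set_id}_p{j:02d}",
                        probe_set_id=set_id,
                        transcript_id=t.transcript_id,
                        offset=int(off),
                        gene=gid,
                        cls=CLASS_MATCHING,
                    )
                )

    # ---- plant cross-hybridizing probes (mutates the reference) ----
    n_candidates = len(probes)
    crosshyb_partners: dict[str, tuple[str, int]] = {}
    n_xh = int(round(config.frac_crosshyb_probes * n_candidates))
    n_nm = int(round(config.frac_nonmatching_probes * n_candidates))
    flaw_idx = rng_flaws.choice(n_candidates, size=n_xh + n_nm, replace=False)
    xh_idx, nm_idx = flaw_idx[:n_xh], flaw_idx[n_xh:]

    if n_xh > 0 and len(gene_ids) < 2:
        raise GenerationError("cross-hybridization planting needs >= 2 genes")
    for i in sorted(int(k) for k in xh_idx):
        p = probes[i]
        window = seqs[p["transcript_id"]][p["offset"] : p["offset"] + L]
        for _ in range(200):
            gid_b = gene_ids[int(rng_flaws.integers(len(gene_ids)))]
            if gid_b == p["gene"]:
                continue
            t_b = by_gene[gid_b]
            n_windows = len(seqs[t_b.transcript_id]) - L + 1
            pos = int(rng_flaws.integers(n_windows))
            clash = any(
                pos < hi and lo < pos + L for lo, hi in occupied[t_b.transcript_id]
            )
            if clash:
                continue
            seq_b = seqs[t_b.transcript_id]
            seqs[t_b.transcript_id] = seq_b[:pos] + window + seq_b[pos + L :]
            occupied[t_b.transcript_id].append((pos, pos + L))
            p["cls"] = CLASS_CROSSHYB
            d3_b = len(seqs[t_b.transcript_id]) - (pos + L)
            crosshyb_partners[p["probe_id"]] = (gid_b, d3_b)
            break
        else:
            raise GenerationError("could not place a cross-hybridization copy")

    mutated_reference = [
        TranscriptRecord(t.transcript_id, t.gene_id, seqs[t.transcript_id])
        for t in reference
    ]
    index = ReferenceIndex(mutated_reference)

    # ---- plant non-matching probes (verified absent at Hamming <= 3) ----
    for i in sorted(int(k) for k in nm_idx):
        probes[i]["cls"] = CLASS_NONMATCHING
        probes[i]["replacement"] = _random_absent_probe(rng_flaws, index, L, 3)

    # ---- densely tiled degradation-control probe sets ----
    if config.include_degradation_control:
        t = by_gene[CONTROL_GENE]
        offs = list(range(0, len(t.sequence) - L + 1, config.control_tiling_step))
        n_full = len(offs) // config.probes_per_set
        for s in range(n_full):
            set_id = f"{CONTROL_GENE}_ps{s + 1}"
            set_gene[set_id] = CONTROL_GENE
            for j in range(config.probes_per_set):
                off = offs[s * config.probes_per_set + j]
                probes.append(
                    dict(
                        probe_id=f"{set_id}_p{j + 1:02d}",
                        probe_set_id=set_id,
                        transcript_id=t.transcript_id,
                        offset=off,
                        gene=CONTROL_GENE,
                        cls=CLASS_MATCHING,
                    )
                )

    # ---- complete-mismatch control sets ----
    blank_set_ids = []
    for s in range(1, config.n_complete_mismatch_sets + 1):
        set_id = f"MM{s:03d}"
        blank_set_ids.append(set_id)
        set_gene[set_id] = None
        for j in range(1, config.probes_per_set + 1):
            probes.append(
                dict(
                    probe_id=f"{set_id}_p{j:02d}",
                    probe_set_id=set_id,
                    transcript_id=None,
                    offset=None,
                    gene=None,
                    cls=CLASS_BLANK,
                    replacement=_random_absent_probe(rng_flaws, index, L, 3),
                )
            )

    # ---- chip grid coordinates (shuffled so sets scatter spatially) ----
    n_total = len(probes)
    side = math.ceil(math.sqrt(n_total))
    order = rng_design.permutation(n_total)
    coords = [(int(k % side), int(k // side)) for k in order]

    # ---- ground-truth gene effects ----
    silenced: list[str] = []
    effects = {g: 0.0 for g in gene_ids}
    n_de = int(round(config.frac_de_genes * len(gene_ids)))
    n_sil = int(round(config.frac_silenced_genes * len(gene_ids)))
    special = rng_eff.choice(len(gene_ids), size=n_de + n_sil, replace=False)
    e_lo, e_hi = config.effect_log2_range
    for k in special[:n_de]:
        g = gene_ids[int(k)]
        sign = 1.0 if rng_eff.random() < 0.5 else -1.0
        effects[g] = float(sign * rng_eff.uniform(e_lo, e_hi))
    silenced = sorted(gene_ids[int(k)] for k in special[n_de:])
    if config.include_degradation_control:
        effects[CONTROL_GENE] = 0.0

    design: list[ProbeRecord] = []
    probe_classes: dict[str, str] = {}
    probe_d3: dict[str, Optional[int]] = {}
    for p, (x, y) in zip(probes, coords):
        if p["cls"] in (CLASS_NONMATCHING, CLASS_BLANK):
            seq = p["replacement"]
            d3 = None
            gene = None if p["cls"] == CLASS_BLANK else p["gene"]
        else:
            tseq = seqs[p["transcript_id"]]
            seq = tseq[p["offset"] : p["offset"] + L]
            d3 = len(tseq) - (p["offset"] + L)
            gene = p["gene"]
        probe_classes[p["probe_id"]] = p["cls"]
        probe_d3[p["probe_id"]] = d3
        design.append(
            ProbeRecord(
                probe_id=p["probe_id"],
                probe_set_id=p["probe_set_id"],
                sequence=seq,
                x=x,
                y=y,
                d3prime=d3,
                target_gene=gene,
            )
        )

    truth = GroundTruth(
        gene_effects=effects,
        probe_classes=probe_classes,
        probe_d3=probe_d3,
        crosshyb_partners=crosshyb_partners,
        silenced_genes=silenced,
        blank_set_ids=blank_set_ids,
        set_gene=set_gene,
    )
    return design, truth, mutated_reference


# ----------------------------------------------------------------------
def simulate_cohort(
    reference: list[TranscriptRecord],
    design: list[ProbeRecord],
    truth: GroundTruth,
    config: SimulationConfig,
) -> tuple[IntensityMatrix, dict[str, IntensityMatrix], pd.DataFrame]:
    """Simulate matched FF and per-kit FFPET probe-level intensities.

    Model (log2 unless stated):

    * latent expression ``e_gt = baseline_g + delta_g * [ER+] + N(0, tissue_sd)``
      drawn once per tumor and shared by the tumor's mirrored FF/FFPET
      sections;
    * FF probe signal ``s = e_gt + a_p + N(0, measurement_sd_ff)`` with
      fixed probe affinities ``a_p ~ N(0, probe_affinity_sd)``;
    * FFPET signal for kit k reuses the FF draw and subtracts
      ``global_attenuation + three_prime_decay * d3prime``, adds
      ``N(0, extra_noise_sd)``, and drops probes to background with
      probability ``dropout_prob``;
    * non-matching and blank probes emit background only; cross-hybridizing
      probes emit the sum of both source genes' linear signals;
    * linear intensity ``= 2**signal + b_t * max(N(background_mean,
      background_sd), 0)``, floored at 1, where ``b_t`` is a per-array
      log-normal background scale (``background_scale_sd``) emulating
      chip-to-chip variation in nonspecific background. Background draws
      are shared by the mirrored sections, so an all-zero degradation
      profile reproduces FF byte-identically.

    Returns ``(ff_matrix, {kit: ffpet_matrix}, sample_sheet)`` and records
    baselines and the sample sheet on ``truth``.
    """
    config.validate()
    for label in config.kit_profiles:
        if not isinstance(config.kit_profiles[label], DegradationProfile):
            raise ConfigurationError(f"kit_profiles[{label}] is not a DegradationProfile")

    rng = _rng(config.seed, _STREAM_COHORT)
    probe_ids = [p.probe_id for p in design]
    n_probes = len(design)
    genes = sorted({g for g in (p.target_gene for p in design) if g is not None})
    gene_pos = {g: i for i, g in enumerate(genes)}
    tr_len = {t.gene_id: len(t.sequence) for t in reference}

    n_tumors = 2 * config.n_pairs_per_group
    er = np.array([1] * config.n_pairs_per_group + [0] * config.n_pairs_per_group)
    pair_ids = [f"P{i + 1:02d}" for i in range(n_tumors)]

    b_lo, b_hi = config.baseline_log2_range
    baselines = rng.uniform(b_lo, b_hi, size=len(genes))
    for i, g in enumerate(genes):
        if g in config.baseline_overrides:
            baselines[i] = float(config.baseline_overrides[g])
    delta = np.array([truth.gene_effects.get(g, 0.0) for g in genes])
    silenced = np.array([g in set(truth.silenced_genes) for g in genes])

    tissue = rng.normal(0.0, config.tissue_sd, size=(len(genes), n_tumors))
    latent = baselines[:, None] + delta[:, None] * er[None, :] + tissue  # genes x tumors

    affinity = rng.normal(0.0, config.probe_affinity_sd, size=n_probes)
    eps1 = rng.normal(0.0, config.measurement_sd_ff, size=(n_probes, n_tumors))
    eps2 = rng.normal(0.0, config.measurement_sd_ff, size=(n_probes, n_tumors))
    # per-array background level varies (shared by the mirrored sections)
    bg_scale = np.exp2(rng.normal(0.0, config.background_scale_sd, size=n_tumors))
    background = bg_scale[None, :] * np.clip(
        rng.normal(config.background_mean, config.background_sd, size=(n_probes, n_tumors)),
        0.0,
        None,
    )

    cls = np.array([truth.probe_classes[p] for p in probe_ids])
    gene_idx = np.array(
        [gene_pos.get(p.target_gene, -1) if p.target_gene else -1 for p in design]
    )
    d3 = np.array(
        [p.d3prime if p.d3prime is not None else 0 for p in design], dtype=float
    )
    has_signal = (cls == CLASS_MATCHING) | (cls == CLASS_CROSSHYB)
    has_signal &= gene_idx >= 0
    has_signal &= ~np.where(gene_idx >= 0, silenced[np.maximum(gene_idx, 0)], False)

    sig1 = np.full((n_probes, n_tumors), -np.inf)
    sig1[has_signal] = (
        latent[gene_idx[has_signal]] + affinity[has_signal, None] + eps1[has_signal]
    )

    # second component of cross-hybridizing probes
    is_xh = cls == CLASS_CROSSHYB
    xh_gene = np.full(n_probes, -1)
    xh_d3 = np.zeros(n_probes)
    for i, p in enumerate(design):
        if p.probe_id in truth.crosshyb_partners:
            g_b, d3_b = truth.crosshyb_partners[p.probe_id]
            xh_gene[i] = gene_pos[g_b]
            xh_d3[i] = d3_b
    has_xh = is_xh & (xh_gene >= 0)
    has_xh &= ~np.where(xh_gene >= 0, silenced[np.maximum(xh_gene, 0)], False)
    sig2 = np.full((n_probes, n_tumors), -np.inf)
    sig2[has_xh] = (
        latent[xh_gene[has_xh]] + affinity[has_xh, None] + eps2[has_xh]
    )

    def _linear(s1: np.ndarray, s2: np.ndarray) -> np.ndarray:
        lin = np.exp2(s1, where=np.isfinite(s1), out=np.zeros_like(s1))
        lin += np.exp2(s2, where=np.isfinite(s2), out=np.zeros_like(s2))
        return np.maximum(lin + background, 1.0)

    geometry = pd.DataFrame(
        {"x": [p.x for p in design], "y": [p.y for p in design]}, index=probe_ids
    )

    ff_cols = [f"{pid}_FF" for pid in pair_ids]
    ff_values = pd.DataFrame(_linear(sig1, sig2), index=probe_ids, columns=ff_cols)
    ff = IntensityMatrix(ff_values, geometry.copy())

    sheet_rows = [
        dict(
            sample_id=c,
            preparation="FF",
            kit="ff",
            er_status="ER+" if er[i] else "ER-",
            pair_id=pair_ids[i],
        )
        for i, c in enumerate(ff_cols)
    ]

    ffpet: dict[str, IntensityMatrix] = {}
    for k_i, label in enumerate(sorted(config.kit_profiles)):
        profile = config.kit_profiles[label]
        krng = _rng(config.seed, _STREAM_KIT_BASE, k_i)
        z = krng.normal(0.0, 1.0, size=(n_probes, n_tumors))
        u = krng.random(size=(n_probes, n_tumors))
        shift = profile.global_attenuation + profile.three_prime_decay * d3
        shift2 = profile.global_attenuation + profile.three_prime_decay * xh_d3
        s1 = sig1 - shift[:, None] + profile.extra_noise_sd * z
        s2 = sig2 - shift2[:, None] + profile.extra_noise_sd * z
        dropped = u < profile.dropout_prob
        s1 = np.where(dropped, -np.inf, s1)
        s2 = np.where(dropped, -np.inf, s2)
        cols = [f"{pid}_FFPET_{label}" for pid in pair_ids]
        values = pd.DataFrame(_linear(s1, s2), index=probe_ids, columns=cols)
        ffpet[label] = IntensityMatrix(values, geometry.copy())
        sheet_rows += [
            dict(
                sample_id=c,
                preparation="FFPET",
                kit=label,
                er_status="ER+" if er[i] else "ER-",
                pair_id=pair_ids[i],
            )
            for i, c in enumerate(cols)
        ]

    sheet = pd.DataFrame(sheet_rows)
    truth.baselines = {g: float(baselines[i]) for i, g in enumerate(genes)}
    truth.samples = sheet
    return ff, ffpet, sheet


# ----------------------------------------------------------------------
def predicted_ffpet_effect(
    baseline: float,
    delta: float,
    attenuation: float,
    background_mean: float,
) -> float:
    """Closed-form log2 group effect after signal-to-background compression.

    With linear intensity ``2**(s - A) + B`` and no background correction,
    a true log2 effect ``delta`` at gene baseline ``b`` is observed as::

        log2((2**(b + delta - A) + B) / (2**(b - A) + B))

    Attenuation ``A`` pushes the signal toward the additive background
    floor ``B``, compressing the observed effect; this is the analytic
    oracle for the false-negative set under attenuation. ``A = 0`` gives
    the compression already present in FF material.
    """
    hi = 2.0 ** (baseline + delta - attenuation) + background_mean
    lo = 2.0 ** (baseline - attenuation) + background_mean
    return math.log2(hi / lo)


def expected_three_prime_ratio(decay_per_nt: float, delta_d3: float) -> float:
    """Expected 3'/5' intensity ratio for probe groups ``delta_d3`` nt apart.

    The degradation model attenuates log2 signal linearly in the distance
    from the 3' end, so two probe groups whose 3' distances differ by
    ``delta_d3`` have expected intensity ratio ``2**(decay * delta_d3)``
    (background and compression aside).
    """
    return 2.0 ** (decay_per_nt * delta_d3)
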