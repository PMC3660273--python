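"""In-silico probe re-annotation and probe-set revision.

Every 25-mer probe is re-mapped against the reference transcriptome on both
orientations with up to ``max_mismatches`` substitutions (Hamming distance;
no gaps). Probes are classified as uniquely matching, multi-gene matching
(cross-hybridizing), or non-matching, and each original probe set is revised
into one of three classes:

``unique``
    at least ``min_retained`` uniquely matching probes; only those probes
    are retained for summarization.
``nonunique``
    not unique, but at least one probe matches transcripts of multiple genes.
``mismatched``
    everything else (the set carries no usable sequence signal).

Probe sets whose probes fail to match anywhere even at Hamming distance 3
form the *complete mismatch* control collection used downstream as the
blank distribution for the limit of blank.

The matcher is a pigeonhole seed-and-verify scheme over an exact k-mer
index: a probe with at most k mismatches against some window must contain
at least one of k+1 disjoint exact seed segments, so candidate windows are
found by exact seed lookup and verified by direct Hamming count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .errors import InputError

__all__ = [
    "ProbeRecord",
    "TranscriptRecord",
    "ProbeHit",
    "RevisedDesign",
    "ReferenceIndex",
    "match_probe",
    "classify_probe",
    "revise_design",
    "build_complete_mismatch_set",
    "MATCH_UNIQUE",
    "MATCH_MULTI",
    "NO_MATCH",
]

logger = logging.getLogger(__name__)

MATCH_UNIQUE = "MATCH_UNIQUE"
MATCH_MULTI = "MATCH_MULTI"
NO_MATCH = "NO_MATCH"

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_VALID_BASES = frozenset("ACGT")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class TranscriptRecord:
    """One reference transcript with its owning gene."""

    transcript_id: str
    gene_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise InputError(f"transcript {self.transcript_id} has empty sequence")
        if not self.gene_id:
            raise InputError(f"transcript {self.transcript_id} has empty gene_id")


@dataclass(frozen=True)
class ProbeRecord:
    """One probe of the array design.

    ``target_gene`` and ``d3prime`` (distance in nt from the probe's
    3'-most aligned base to the transcript 3' end) are design metadata;
    both are None for synthetic mismatch-control probes.
    """

    probe_id: str
    probe_set_id: str
    sequence: str
    x: int = 0
    y: int = 0
    d3prime: Optional[int] = None
    target_gene: Optional[str] = None


@dataclass(frozen=True, order=True)
class ProbeHit:
    """An aligned probe window: 0-based half-open [offset, offset+L)."""

    transcript_id: str
    offset: int
    strand: str  # "forward" | "revcomp"
    gene_id: str
    mismatches: int


@dataclass
class RevisedDesign:
    """Outcome of in-silico probe-set revision."""

    probe_class: dict[str, str]
    set_class: dict[str, str]
    retained: dict[str, list[str]]  # unique sets -> retained probe ids
    complete_mismatch_set_ids: list[str] = field(default_factory=list)
    probes: dict[str, ProbeRecord] = field(default_factory=dict)
    min_retained: int = 3

    def class_counts(self) -> dict[str, int]:
        counts = {"unique": 0, "nonunique": 0, "mismatched": 0}
        for c in self.set_class.values():
            counts[c] += 1
        return counts

    def set_ids(self, set_class: Optional[str] = None) -> list[str]:
        if set_class is None:
            return sorted(self.set_class)
        return sorted(s for s, c in self.set_class.items() if c == set_class)

    def probes_for_summarization(self, probe_set_id: str) -> list[str]:
        """Retained probes for unique sets; all probes for blank control sets."""
        if probe_set_id in self.retained:
            return self.retained[probe_set_id]
        if probe_set_id in self.complete_mismatch_set_ids:
            return sorted(
                p.probe_id for p in self.probes.values() if p.probe_set_id == probe_set_id
            )
        return []

    @classmethod
    def identity(cls, design: Sequence[ProbeRecord]) -> "RevisedDesign":
        """A no-op revision retaining every probe of every set.

        Stands in for the original vendor design when comparing revised
        against unrevised summarization.
        """
        sets: dict[str, list[str]] = {}
        for p in design:
            sets.setdefault(p.probe_set_id, []).append(p.probe_id)
        return cls(
            probe_class={p.probe_id: MATCH_UNIQUE for p in design},
            set_class={s: "unique" for s in sets},
            retained={s: sorted(ids) for s, ids in sets.items()},
            complete_mismatch_set_ids=[],
            probes={p.probe_id: p for p in design},
        )


def _check_sequence(seq: str, label: str) -> None:
    for i, base in enumerate(seq):
        if base not in _VALID_BASES:
            raise InputError(f"probe {label}: invalid base {base!r} at position {i}")


class ReferenceIndex:
    """Exact k-mer index over a transcript set, built lazily per seed length."""

    def __init__(self, transcripts: Iterable[TranscriptRecord]):
        self.transcripts: list[TranscriptRecord] = sorted(
            transcripts, key=lambda t: t.transcript_id
        )
        if not self.transcripts:
            raise InputError("reference is empty")
        ids = [t.transcript_id for t in self.transcripts]
        if len(set(ids)) != len(ids):
            raise InputError("duplicate transcript_id in reference")
        self._arrays = [
            np.frombuffer(t.sequence.encode("ascii"), dtype=np.uint8)
            for t in self.transcripts
        ]
        self._seed_indexes: dict[int, dict[str, list[tuple[int, int]]]] = {}

    @property
    def min_transcript_length(self) -> int:
        return min(len(t.sequence) for t in self.transcripts)

    def _seed_index(self, length: int) -> dict[str, list[tuple[int, int]]]:
        idx = self._seed_indexes.get(length)
        if idx is None:
            idx = {}
            for t_i, t in enumerate(self.transcripts):
                seq = t.sequence
                for pos in range(len(seq) - length + 1):
                    idx.setdefault(seq[pos : pos + length], []).append((t_i, pos))
            self._seed_indexes[length] = idx
        return idx

    def _match_oriented(
        self, query: str, max_mismatches: int, strand: str
    ) -> list[ProbeHit]:
        L = len(query)
        bounds = np.linspace(0, L, max_mismatches + 2).astype(int)
        qarr = np.frombuffer(query.encode("ascii"), dtype=np.uint8)
        hits: list[ProbeHit] = []
        seen: set[tuple[int, int]] = set()
        for s in range(max_mismatches + 1):
            lo, hi = int(bounds[s]), int(bounds[s + 1])
            index = self._seed_index(hi - lo)
            for t_i, pos in index.get(query[lo:hi], ()):  # candidate windows
                start = pos - lo
                tarr = self._arrays[t_i]
                if start < 0 or start + L > len(tarr) or (t_i, start) in seen:
                    continue
                seen.add((t_i, start))
                mm = int(np.count_nonzero(tarr[start : start + L] != qarr))
                if mm <= max_mismatches:
                    t = self.transcripts[t_i]
                    hits.append(ProbeHit(t.transcript_id, start, strand, t.gene_id, mm))
        return hits

    def match(self, probe_sequence: str, max_mismatches: int, label: str = "probe") -> list[ProbeHit]:
        """All windows within ``max_mismatches`` on either orientation.

        Deterministically ordered by (transcript_id, offset, strand).
        """
        if max_mismatches < 0:
            raise InputError("max_mismatches must be >= 0")
        _check_sequence(probe_sequence, label)
        if len(probe_sequence) > self.min_transcript_length:
            raise InputError(
                f"probe {label} is longer than the shortest reference transcript"
            )
        hits = self._match_oriented(probe_sequence, max_mismatches, "forward")
        hits += self._match_oriented(revcomp(probe_sequence), max_mismatches, "revcomp")
        hits.sort(key=lambda h: (h.transcript_id, h.offset, h.strand != "forward"))
        return hits

    def has_any_match(self, probe_sequence: str, max_mismatches: int) -> bool:
        return bool(self.match(probe_sequence, max_mismatches))


def _as_index(reference) -> ReferenceIndex:
    return reference if isinstance(reference, ReferenceIndex) else ReferenceIndex(reference)


def match_probe(probe_sequence: str, reference, max_mismatches: int) -> list[ProbeHit]:
    """Map one probe against the reference; see :meth:`ReferenceIndex.match`."""
    return _as_index(reference).match(probe_sequence, max_mismatches)


def classify_probe(hits: Sequence[ProbeHit]) -> str:
    """NO_MATCH if empty, MATCH_UNIQUE if one gene, MATCH_MULTI otherwise."""
    if not hits:
        return NO_MATCH
    genes = {h.gene_id for h in hits}
    return MATCH_UNIQUE if len(genes) == 1 else MATCH_MULTI


def revise_design(
    design: Sequence[ProbeRecord],
    reference,
    min_retained: int = 3,
    blank_max_mismatches: int = 3,
    find_complete_mismatch: bool = True,
) -> RevisedDesign:
    """Classify every probe at 0 mismatches and revise every probe set.

    A set is ``unique`` when it keeps at least ``min_retained`` uniquely
    matching probes (the retained probes); ``nonunique`` when it is not
    unique but contains a multi-gene probe; ``mismatched`` otherwise.
    """
    design = list(design)
    if not design:
        raise InputError("design is empty")
    ids = [p.probe_id for p in design]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise InputError(f"duplicate probe_id(s): {dup[:5]}")
    index = _as_index(reference)

    probe_class: dict[str, str] = {}
    sets: dict[str, list[ProbeRecord]] = {}
    for p in design:
        probe_class[p.probe_id] = classify_probe(index.match(p.sequence, 0, p.probe_id))
        sets.setdefault(p.probe_set_id, []).append(p)

    set_class: dict[str, str] = {}
    retained: dict[str, list[str]] = {}
    for set_id, probes in sets.items():
        unique_ids = sorted(
            p.probe_id for p in probes if probe_class[p.probe_id] == MATCH_UNIQUE
        )
        has_multi = any(probe_class[p.probe_id] == MATCH_MULTI for p in probes)
        if len(unique_ids) >= min_retained:
            set_class[set_id] = "unique"
            retained[set_id] = unique_ids
        elif has_multi:
            set_class[set_id] = "nonunique"
        else:
            set_class[set_id] = "mismatched"

    revised = RevisedDesign(
        probe_class=probe_class,
        set_class=set_class,
        retained=retained,
        probes={p.probe_id: p for p in design},
        min_retained=min_retained,
    )
    if find_complete_mismatch:
        revised.complete_mismatch_set_ids = build_complete_mismatch_set(
            design, index, max_mismatches=blank_max_mismatches
        )
    return revised


def build_complete_mismatch_set(
    design: Sequence[ProbeRecord], reference, max_mismatches: int = 3
) -> list[str]:
    """Probe sets whose probes all miss the reference even at Hamming <= k.

    These sets see no sample-derived signal and provide the blank
    distribution for the limit of blank. Returns a sorted list of set ids;
    logs a warning when empty (LOB is then undefined downstream).
    """
    index = _as_index(reference)
    sets: dict[str, list[ProbeRecord]] = {}
    for p in design:
        sets.setdefault(p.probe_set_id, []).append(p)
    out = []
    for set_id in sorted(sets):
        probes = sets[set_id]
        # cheap exact screen first; most real sets match verbatim
        if any(index.has_any_match(p.sequence, 0) for p in probes):
            continue
        if any(index.has_any_match(p.sequence, max_mismatches) for p in probes):
            continue
        out.append(set_id)
    if not out:
        logger.warning(
            "no complete-mismatch probe sets found; limit of blank will be undefined"
        )
    return out
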