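"""Independent reference implementations used only as test oracles."""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def brute_force_hits(probe: str, transcripts, max_mismatches: int):
    """Sliding-window Hamming scan over every transcript and orientation.

    Returns sorted tuples (transcript_id, offset, strand, mismatches).
    """
    L = len(probe)
    queries = (("forward", probe), ("revcomp", revcomp(probe)))
    hits = []
    for t in transcripts:
        seq = t.sequence
        for strand, q in queries:
            for off in range(len(seq) - L + 1):
                mm = sum(a != b for a, b in zip(seq[off : off + L], q))
                if mm <= max_mismatches:
                    hits.append((t.transcript_id, off, strand, mm))
    return sorted(hits)


def brute_force_mismatch_counts(probe: str, transcripts):
    """Vectorized per-window mismatch counts for both orientations.

    Returns {(transcript_id, strand): array of Hamming distances per
    offset}. Faster than :func:`brute_force_hits` for exhaustive scans,
    still entirely index-free.
    """
    L = len(probe)
    out = {}
    for t in transcripts:
        arr = np.frombuffer(t.sequence.encode(), dtype=np.uint8)
        n_win = len(arr) - L + 1
        windows = np.lib.stride_tricks.sliding_window_view(arr, L)[:n_win]
        for strand, q in (("forward", probe), ("revcomp", revcomp(probe))):
            qarr = np.frombuffer(q.encode(), dtype=np.uint8)
            out[(t.transcript_id, strand)] = (windows != qarr).sum(axis=1)
    return out


def median_polish_oracle(x, tol=1e-6, max_sweeps=100):
    """Plain-loop Tukey median polish (row sweep, then column sweep)."""
    z = [list(map(float, row)) for row in x]
    nr, nc = len(z), len(z[0])

    def med(vals):
        vals = sorted(v for v in vals if v == v)  # drop NaN
        n = len(vals)
        if n == 0:
            return 0.0
        mid = n // 2
        return vals[mid] if n % 2 else 0.5 * (vals[mid - 1] + vals[mid])

    overall, row, col = 0.0, [0.0] * nr, [0.0] * nc
    oldsum = 0.0
    for _ in range(max_sweeps):
        for i in range(nr):
            d = med(z[i])
            row[i] += d
            z[i] = [v - d for v in z[i]]
        d = med(col)
        overall += d
        col = [c - d for c in col]
        for j in range(nc):
            d = med([z[i][j] for i in range(nr)])
            col[j] += d
            for i in range(nr):
                z[i][j] -= d
        d = med(row)
        overall += d
        row = [r - d for r in row]
        newsum = sum(abs(v) for r in z for v in r if v == v)
        if newsum == 0 or abs(newsum - oldsum) < tol * newsum:
            break
        oldsum = newsum
    return overall, np.array(row), np.array(col), np.array(z)
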