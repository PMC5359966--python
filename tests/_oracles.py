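"""Independent brute-force oracles used to check pipeline operations.

These deliberately share no code with the implementation: alignment is
a position-by-position Hamming scan over numpy byte arrays, clustering
is transitive closure of the overlap relation, trimming scans every
3'-anchored overlap.
"""

from __future__ import annotations

from typing import Dict, Optional, Sequence, Set, Tuple

import numpy as np

_N = ord("N")


def brute_hits(
    read: str,
    entries: Sequence[Tuple[str, str]],
    max_mm: int,
    delimiters: Optional[Dict[str, Set[int]]] = None,
) -> Set[Tuple[str, int, int]]:
    """All (entry_id, start, mismatches) placements within max_mm.

    N in read or reference counts as a mismatch; spans overlapping a
    delimiter position are rejected outright.
    """
    r = np.frombuffer(read.upper().encode(), dtype=np.uint8)
    L = len(r)
    out: Set[Tuple[str, int, int]] = set()
    for eid, seq in entries:
        s = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
        if len(s) < L:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(s, L)
        mm = ((windows != r) | (windows == _N) | (r == _N)).sum(axis=1)
        delim = (delimiters or {}).get(eid, set())
        for start in np.flatnonzero(mm <= max_mm):
            start = int(start)
            if delim and any((start + i) in delim for i in range(L)):
                continue
            out.add((eid, start, int(mm[start])))
    return out


def min_stratum(hits: Set[Tuple[str, int, int]]) -> Set[Tuple[str, int, int]]:
    if not hits:
        return set()
    best = min(h[2] for h in hits)
    return {h for h in hits if h[2] == best}


def brute_clusters(
    occurrences: Sequence[Tuple[str, str, int, int]]
) -> Set[frozenset]:
    """Connected components of the overlap graph by transitive closure.

    ``occurrences`` are (mature, hairpin, start, end) tuples; two
    matures are adjacent iff they have interval-overlapping occurrences
    on a shared hairpin.
    """
    matures = sorted({o[0] for o in occurrences})
    idx = {m: i for i, m in enumerate(matures)}
    n = len(matures)
    adj = np.eye(n, dtype=bool)
    for a in occurrences:
        for b in occurrences:
            if a[1] == b[1] and a[2] < b[3] and b[2] < a[3]:
                adj[idx[a[0]], idx[b[0]]] = True
    for _ in range(n):
        adj = adj @ adj
    comps = set()
    for i in range(n):
        comps.add(frozenset(matures[j] for j in range(n) if adj[i, j]))
    return comps


def brute_trim_point(
    read: str, adapter: str, max_error_rate: float, min_overlap: int
) -> Optional[int]:
    """Leftmost cut point of the 3'-anchored adapter match, or None."""
    read, adapter = read.upper(), adapter.upper()
    for p in range(0, len(read) - min_overlap + 1):
        overlap = min(len(adapter), len(read) - p)
        if overlap < min_overlap:
            continue
        mism = sum(
            1
            for a, b in zip(read[p : p + overlap], adapter[:overlap])
            if a != b or a == "N" or b == "N"
        )
        if mism <= max_error_rate * overlap:
            return p
    return None
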