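"""Adapter trimming, length filtering and read collapsing.

Small-RNA inserts (~22 nt) are shorter than the sequenced read, so the
3' adapter is present in nearly every read and must be removed before
alignment. Trimming here is 3'-anchored prefix matching of the adapter
under a Hamming error budget (no indels): the leftmost read position at
which the adapter's prefix matches the remainder of the read within
``max_error_rate`` is the cut point. Reads shorter than ``min_len``
after trimming are discarded.

Identical reads are then collapsed into unique reads with per-sample
counts, first within and then across samples; downstream stages align
each distinct sequence once, which is what makes joint multi-sample
processing cheap.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from ._io import read_fastq_sequences

DEFAULT_MIN_LEN = 16


@dataclass(frozen=True)
class TrimmedRead:
    seq: str
    had_adapter: bool
    original_len: int


@dataclass
class TrimStats:
    """Per-sample trimming QC (adapter incidence, survivorship, lengths)."""

    sample: str
    n_input: int = 0
    n_with_adapter: int = 0
    n_surviving: int = 0
    n_discarded_short: int = 0
    n_discarded_untrimmed: int = 0
    length_histogram: Dict[int, int] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "sample": self.sample,
            "n_input": self.n_input,
            "n_with_adapter": self.n_with_adapter,
            "n_surviving": self.n_surviving,
            "n_discarded_short": self.n_discarded_short,
            "n_discarded_untrimmed": self.n_discarded_untrimmed,
            "length_histogram": {str(k): v for k, v in sorted(self.length_histogram.items())},
        }


def trim_adapter(
    read_seq: str,
    adapter: str,
    max_error_rate: float = 0.1,
    min_overlap: int = 3,
) -> TrimmedRead:
    """Remove the 3' adapter from one read.

    Scans cut points left to right. At position ``p`` the adapter prefix
    of length ``min(len(adapter), len(read) - p)`` is compared to the
    read suffix; a match within the error budget (mismatches/overlap <=
    ``max_error_rate``, N never matches) trims the read to ``read[:p]``.
    A full internal adapter occurrence removes everything from its
    start. No match leaves the read untouched.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    if not 0 <= max_error_rate < 0.5:
        raise ValueError("max_error_rate must be in [0, 0.5)")
    read = read_seq.upper()
    adapter = adapter.upper()
    n = len(read)
    for p in range(0, n - min_overlap + 1):
        overlap = min(len(adapter), n - p)
        budget = int(max_error_rate * overlap)
        mism = 0
        ok = True
        for i in range(overlap):
            a, b = read[p + i], adapter[i]
            if a != b or a == "N" or b == "N":
                mism += 1
                if mism > budget:
                    ok = False
                    break
        if ok:
            return TrimmedRead(seq=read[:p], had_adapter=True, original_len=n)
    return TrimmedRead(seq=read, had_adapter=False, original_len=n)


def length_filter(
    reads: Sequence[TrimmedRead], min_len: int = DEFAULT_MIN_LEN
) -> Tuple[List[TrimmedRead], int]:
    """Keep reads of length >= min_len; return (survivors, n_discarded)."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    survivors = [r for r in reads if len(r.seq) >= min_len]
    return survivors, len(reads) - len(survivors)


def collapse_within(seqs: Iterable[str]) -> Counter:
    """Collapse identical sequences of one sample into counts."""
    return Counter(seqs)


def collapse_joint(per_sample: Sequence[Tuple[str, Counter]]) -> pd.DataFrame:
    """Merge per-sample unique-read counters into one seq x sample matrix.

    Sample column order follows the input order; rows are sorted by
    sequence so output is deterministic. Column sums equal each sample's
    surviving read total.
    """
    samples = [name for name, _ in per_sample]
    if len(set(samples)) != len(samples):
        raise ValueError("duplicate sample names")
    all_seqs = sorted(set().union(*[set(c) for _, c in per_sample])) if per_sample else []
    data = {name: [counter.get(s, 0) for s in all_seqs] for name, counter in per_sample}
    df = pd.DataFrame(data, index=pd.Index(all_seqs, name="seq"), dtype="int64")
    return df[samples]


@dataclass(frozen=True)
class TrimConfig:
    adapter: str
    max_error_rate: float = 0.1
    min_overlap: int = 3
    min_len: int = DEFAULT_MIN_LEN
    discard_untrimmed: bool = False


def process_fastq(
    path: str,
    sample: str,
    config: TrimConfig,
    _trim_cache: Optional[Dict[str, TrimmedRead]] = None,
) -> Tuple[Counter, TrimStats]:
    """Trim, filter and collapse one FASTQ file.

    Identical raw reads trim identically, so raw reads are collapsed
    first and each distinct sequence trimmed once; ``_trim_cache`` lets
    callers share that memo across samples.
    """
    cache = _trim_cache if _trim_cache is not None else {}
    raw = collapse_within(read_fastq_sequences(path))
    stats = TrimStats(sample=sample)
    out: Counter = Counter()
    for seq, count in raw.items():
        trimmed = cache.get(seq)
        if trimmed is None:
            trimmed = trim_adapter(seq, config.adapter, config.max_error_rate, config.min_overlap)
            cache[seq] = trimmed
        stats.n_input += count
        if trimmed.had_adapter:
            stats.n_with_adapter += count
        elif config.discard_untrimmed:
            stats.n_discarded_untrimmed += count
            continue
        if len(trimmed.seq) < config.min_len:
            stats.n_discarded_short += count
            continue
        stats.n_surviving += count
        out[trimmed.seq] += count
        L = len(trimmed.seq)
        stats.length_histogram[L] = stats.length_histogram.get(L, 0) + count
    return out, stats
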