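"""Noise filtering, miRNA/isomiR count tables and RPM normalization.

Sequencing depth reveals genuinely expressed miRNAs in most samples of
a study, while background reads tend to appear in only a few. The
cross-sample noise filter exploits this: a unique read is flagged noisy
from the *pattern* of its counts across samples — zero in more than
``zero_fraction_threshold`` of samples, or mean count below
``min_mean_count``. The two predicates can be combined with OR (the
default) or AND; both conventions appear in the field and differ
materially for reads that are rare but ubiquitous, so the choice is
explicit, logged, and configurable.

IsomiRs are identified purely by their 5'/3' end offsets relative to
the annotated mature: reads sharing (entry, offset5, offset3) are one
isomiR species regardless of internal substitutions. Substitutions
surface instead through the companion mismatch-only tables, which count
only mismatch-carrying reads; subtracting a companion table from its
standard counterpart yields perfect-match-only counts without
re-running the pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .align import AlignmentHit, CascadeResult
from .refbuild import ExtendedReferenceEntry, ReferenceBuild

logger = logging.getLogger(__name__)

ISOMIR_KEY = ("entry_id", "offset5", "offset3")


@dataclass(frozen=True)
class NoiseFilterParams:
    """Cross-sample noise-read filter thresholds.

    Defaults: a read is noisy when zero in > 60% of samples or when its
    mean count across samples is below 2 (OR combination).
    """

    zero_fraction_threshold: float = 0.60
    min_mean_count: float = 2.0
    combine: str = "OR"

    def __post_init__(self):
        if not 0 <= self.zero_fraction_threshold <= 1:
            raise ValueError("zero_fraction_threshold must be in [0, 1]")
        if self.min_mean_count < 0:
            raise ValueError("min_mean_count must be >= 0")
        if self.combine not in ("OR", "AND"):
            raise ValueError("combine must be 'OR' or 'AND'")


def filter_noise(
    counts: pd.DataFrame, params: NoiseFilterParams = NoiseFilterParams()
) -> Tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Split a unique-read x sample count matrix into (kept, removed).

    OR mode removes a row iff zero-fraction > threshold OR mean <
    min_mean_count; AND mode iff both hold. Stats report unique-read and
    total-count attrition.
    """
    if counts.shape[1] < 1:
        raise ValueError("need at least one sample")
    zero_frac = (counts == 0).sum(axis=1) / counts.shape[1]
    sparse = zero_frac > params.zero_fraction_threshold
    low = counts.mean(axis=1) < params.min_mean_count
    noisy = (sparse | low) if params.combine == "OR" else (sparse & low)
    kept, removed = counts.loc[~noisy], counts.loc[noisy]
    logger.info(
        "noise filter (%s mode): removed %d of %d unique reads",
        params.combine, int(noisy.sum()), len(counts),
    )
    stats = {
        "combine": params.combine,
        "zero_fraction_threshold": params.zero_fraction_threshold,
        "min_mean_count": params.min_mean_count,
        "n_unique_before": int(len(counts)),
        "n_unique_after": int(len(kept)),
        "total_counts_before": int(counts.values.sum()),
        "total_counts_after": int(kept.values.sum()),
    }
    return kept, removed, stats


def compute_offsets(
    hit: AlignmentHit, entry: ExtendedReferenceEntry, read_len: int
) -> Tuple[int, int]:
    """5'/3' end offsets of a hit relative to its segment's mature.

    offset5 = read 5' start - mature 5' start (negative: the read begins
    upstream, i.e. a longer 5' end); offset3 = read 3' end - mature 3'
    end (positive: longer 3' end). (0, 0) is the canonical annotated
    form. The aligner never reports delimiter-spanning placements, so
    the hit lies within exactly one segment.
    """
    for ps in entry.segments:
        if ps.offset <= hit.start and hit.start + read_len <= ps.end:
            o5 = hit.start - ps.mature_start_in_full
            o3 = (hit.start + read_len) - ps.mature_end_in_full
            return o5, o3
    raise AssertionError(
        f"hit at {hit.entry_id}:{hit.start} (len {read_len}) spans a delimiter"
    )


def attribute_reads(
    cascade: CascadeResult, reference: ReferenceBuild
) -> pd.DataFrame:
    """Per-unique-read miRNA attribution table.

    One row per read with retained miRNA hits; columns: entry_id,
    mismatches, offset5, offset3, valid. Offsets are taken from the
    first retained placement (placements of one read within one entry
    share offsets by construction when the extended contexts are
    identical, and ties are broken deterministically by position).
    """
    rows = []
    for seq in sorted(cascade.mirna_hits):
        hits = cascade.mirna_hits[seq]
        if not hits:
            continue
        hit = hits[0]
        entry = reference.entry_by_id[hit.entry_id]
        o5, o3 = compute_offsets(hit, entry, len(seq))
        rows.append(
            {
                "seq": seq,
                "entry_id": hit.entry_id,
                "mismatches": hit.mismatches,
                "offset5": o5,
                "offset3": o3,
                "valid": all(h.valid for h in hits),
            }
        )
    df = pd.DataFrame(
        rows, columns=["seq", "entry_id", "mismatches", "offset5", "offset3", "valid"]
    )
    return df.set_index("seq")


def _grouped_counts(
    attr: pd.DataFrame,
    counts: pd.DataFrame,
    keys: Sequence[str],
    mismatch_only: bool,
) -> pd.DataFrame:
    sel = attr[attr["valid"]]
    if mismatch_only:
        sel = sel[sel["mismatches"] >= 1]
    joined = sel.join(counts, how="inner")
    if joined.empty:
        idx = pd.MultiIndex.from_arrays([[] for _ in keys], names=keys) if len(keys) > 1 else pd.Index([], name=keys[0])
        return pd.DataFrame(0, index=idx, columns=counts.columns, dtype="int64")
    out = joined.groupby(list(keys), sort=True)[list(counts.columns)].sum()
    return out.astype("int64")


def count_mirna(
    attr: pd.DataFrame, counts: pd.DataFrame
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """miRNA x sample count tables: (standard, mismatch-only companion).

    ``attr`` is the per-read attribution restricted upstream to kept
    (noise-filtered) reads; ``counts`` the unique-read count matrix.
    The companion is re-indexed onto the standard table's features so
    standard - companion is the perfect-match-only table.
    """
    standard = _grouped_counts(attr, counts, ["entry_id"], mismatch_only=False)
    companion = _grouped_counts(attr, counts, ["entry_id"], mismatch_only=True)
    companion = companion.reindex(standard.index, fill_value=0)
    return standard, companion


def count_isomir(
    attr: pd.DataFrame, counts: pd.DataFrame
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """IsomiR-keyed count tables: (standard, mismatch-only companion).

    Rows are keyed by (entry_id, offset5, offset3); reads with identical
    offsets are added up, so per entry the isomiR rows sum to the miRNA
    table's cell for every sample.
    """
    standard = _grouped_counts(attr, counts, list(ISOMIR_KEY), mismatch_only=False)
    companion = _grouped_counts(attr, counts, list(ISOMIR_KEY), mismatch_only=True)
    companion = companion.reindex(standard.index, fill_value=0)
    return standard, companion


def rpm_normalize(
    matrix: pd.DataFrame, denominators: Mapping[str, float]
) -> pd.DataFrame:
    """Reads-per-million normalization with per-sample denominators.

    With the miRNA-mapped totals as denominators every non-empty
    sample's RPM column sums to 1e6. Zero-denominator samples are
    emitted as missing values with a warning.
    """
    out = matrix.astype(float).copy()
    for sample in matrix.columns:
        denom = float(denominators.get(sample, 0.0))
        if denom <= 0:
            logger.warning("sample %s has zero denominator; RPM set to NA", sample)
            out[sample] = np.nan
        else:
            out[sample] = matrix[sample] * 1e6 / denom
    return out
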