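"""Sense-strand short-read alignment with bounded mismatches.

Small-RNA libraries ligate adapters to the RNA molecule, so reads carry
the sense strand of their source transcript. Aligning to the
reverse-complement strand creates false assignments — hairpin arms can
even be exact reverse complements of each other — so alignment here is
sense-only by default.

The aligner reports *all* placements of a read on a reference within a
Hamming-distance bound, then keeps only the minimum-mismatch stratum.
Candidate placements come from exact k-mer seeds: a read is split into
``max_mm + 1`` blocks, at least one of which must be error-free in any
placement within the bound (pigeonhole), and the leading k-mer of each
block is looked up in the reference index. Reads too short for that
guarantee fall back to a full scan. The contract is the hit set — it
must equal a position-by-position Hamming scan — not the algorithm.

Unique reads are annotated by cascading through the references in the
fixed order miRNA -> hairpin -> smallRNA -> mRNA: the first stage with a
hit wins, so the categories are mutually exclusive and exhaustive.
Finally, miRNA hits carrying mismatches can be invalidated by remapping:
a mismatch read that matches the genome perfectly somewhere (either
strand) more plausibly originates from that locus than from a miRNA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

from ._io import read_fasta, revcomp
from .refbuild import ExtendedReferenceEntry, SequenceRecord

logger = logging.getLogger(__name__)

CASCADE_ORDER = ("miRNA", "hairpin", "smallRNA", "mRNA")
UNALIGNED = "unaligned"


@dataclass
class AlignmentHit:
    """One placement of a read on a reference entry (sense coordinates)."""

    entry_id: str
    start: int  # 0-based offset in the entry sequence
    mismatches: int
    strand: str = "+"
    valid: bool = True


@dataclass(frozen=True)
class _Entry:
    entry_id: str
    seq: str  # upper case
    delimiters: frozenset  # positions a hit span may never cover


class ReferenceIndex:
    """Exact k-mer index over a set of reference entries."""

    def __init__(self, entries: Sequence[_Entry], k: int = 8):
        if k < 8:
            raise ValueError("seed length k must be >= 8")
        if not entries:
            raise ValueError("reference is empty")
        self.k = k
        self.entries = list(entries)
        self._kmers: Dict[str, List[Tuple[int, int]]] = {}
        self._short: List[int] = []  # entries shorter than k: full-scan fallback
        for idx, entry in enumerate(self.entries):
            if len(entry.seq) < k:
                self._short.append(idx)
                continue
            seq = entry.seq
            for pos in range(len(seq) - k + 1):
                kmer = seq[pos : pos + k]
                if "N" in kmer:
                    continue
                self._kmers.setdefault(kmer, []).append((idx, pos))

    @classmethod
    def from_extended(cls, entries: Sequence[ExtendedReferenceEntry], k: int = 8) -> "ReferenceIndex":
        """Index an extended miRNA reference; every N is a delimiter."""
        prepared = [
            _Entry(
                entry_id=e.entry_id,
                seq=e.full_seq.upper(),
                delimiters=frozenset(e.delimiter_positions),
            )
            for e in entries
        ]
        return cls(prepared, k=k)

    @classmethod
    def from_sequences(cls, records: Iterable[Union[SequenceRecord, Tuple[str, str]]], k: int = 8) -> "ReferenceIndex":
        """Index plain sequences (hairpin/smallRNA/mRNA); N is an ordinary
        never-matching base, not a delimiter."""
        prepared = []
        for rec in records:
            if isinstance(rec, SequenceRecord):
                name, seq = rec.id, rec.seq
            else:
                name, seq = rec
            prepared.append(_Entry(entry_id=name, seq=seq.upper(), delimiters=frozenset()))
        return cls(prepared, k=k)

    @classmethod
    def from_fasta(cls, path: str, k: int = 8) -> "ReferenceIndex":
        return cls.from_sequences(((name, seq) for name, _, seq in read_fasta(path)), k=k)

    def _verify(self, entry: _Entry, start: int, read: str, max_mm: int) -> Optional[int]:
        """Hamming distance of ``read`` at ``start``, or None if out of
        bounds, over budget, or spanning a delimiter."""
        L = len(read)
        if start < 0 or start + L > len(entry.seq):
            return None
        seq = entry.seq
        delims = entry.delimiters
        mism = 0
        for i in range(L):
            pos = start + i
            if delims and pos in delims:
                return None
            a = read[i]
            b = seq[pos]
            if a != b or a == "N" or b == "N":
                mism += 1
                if mism > max_mm:
                    return None
        return mism

    def _candidates(self, read: str, max_mm: int):
        """Candidate (entry_idx, start) placements covering all hits
        within max_mm (pigeonhole over max_mm + 1 seed blocks)."""
        L = len(read)
        nb = max_mm + 1
        out = set()
        if L >= nb * self.k and "N" not in read[: nb * (L // nb)]:
            block = L // nb
            for j in range(nb):
                s = j * block
                seed = read[s : s + self.k]
                for idx, pos in self._kmers.get(seed, ()):
                    out.add((idx, pos - s))
            for idx in self._short:
                out.update((idx, st) for st in range(len(self.entries[idx].seq) - L + 1))
        else:
            # short read (or N in seed region): exhaustive placement scan
            for idx, entry in enumerate(self.entries):
                out.update((idx, st) for st in range(len(entry.seq) - L + 1))
        return out

    def align(self, read: str, max_mm: int, strand: str = "+") -> List[AlignmentHit]:
        """All placements of ``read`` within ``max_mm`` on one strand
        (the read is pre-oriented by the caller; coordinates are always
        on the entry's forward sequence)."""
        hits = []
        for idx, start in self._candidates(read, max_mm):
            mism = self._verify(self.entries[idx], start, read, max_mm)
            if mism is not None:
                hits.append(
                    AlignmentHit(
                        entry_id=self.entries[idx].entry_id,
                        start=start,
                        mismatches=mism,
                        strand=strand,
                    )
                )
        return hits


def align_read(
    seq: str,
    index: ReferenceIndex,
    max_mm: int = 1,
    sense_only: bool = True,
) -> List[AlignmentHit]:
    """Align one read; keep only the minimum-mismatch stratum.

    With ``sense_only`` (the default, correct for stranded small-RNA
    data) only forward-strand placements are considered; otherwise the
    reverse complement is also aligned and competes in the same stratum,
    mimicking a strand-unaware aligner.
    """
    read = seq.upper()
    hits = index.align(read, max_mm, strand="+")
    if not sense_only:
        hits.extend(index.align(revcomp(read), max_mm, strand="-"))
    if not hits:
        return []
    best = min(h.mismatches for h in hits)
    hits = [h for h in hits if h.mismatches == best]
    hits.sort(key=lambda h: (h.entry_id, h.start, h.strand))
    return hits


@dataclass
class CascadeResult:
    """Per-read category assignment plus retained miRNA-stage hits."""

    categories: Dict[str, str]
    mirna_hits: Dict[str, List[AlignmentHit]]
    multi_entry_reads: int = 0

    def category_counts(self) -> Dict[str, int]:
        out: Dict[str, int] = {}
        for cat in self.categories.values():
            out[cat] = out.get(cat, 0) + 1
        return out


def resolve_multi_entry(hits: Sequence[AlignmentHit]) -> Tuple[List[AlignmentHit], bool]:
    """Attribute a read hitting several entries to one of them.

    The read is counted once, on the lexicographically smallest
    entry_id; the caller tallies how often this happened so the residual
    ambiguity the reference grouping did not remove stays auditable.
    """
    entry_ids = {h.entry_id for h in hits}
    if len(entry_ids) <= 1:
        return list(hits), False
    chosen = min(entry_ids)
    return [h for h in hits if h.entry_id == chosen], True


def annotate_cascade(
    seqs: Iterable[str],
    refs: Mapping[str, Optional[ReferenceIndex]],
    max_mm: Union[int, Mapping[str, int]] = 1,
    sense_only: bool = True,
) -> CascadeResult:
    """Assign each unique read its first hitting category.

    ``refs`` maps stage name -> index (missing/None stages are skipped
    with a log note; the miRNA stage is mandatory). ``max_mm`` may be a
    single bound or a per-stage mapping.
    """
    if refs.get("miRNA") is None:
        raise ValueError("the miRNA reference is mandatory")
    for stage in refs:
        if stage not in CASCADE_ORDER:
            raise ValueError(f"unknown cascade stage {stage!r}")
    skipped = [s for s in CASCADE_ORDER if refs.get(s) is None]
    if skipped:
        logger.info("cascade stages skipped (no reference): %s", ", ".join(skipped))

    def bound(stage: str) -> int:
        return max_mm if isinstance(max_mm, int) else max_mm.get(stage, 1)

    categories: Dict[str, str] = {}
    mirna_hits: Dict[str, List[AlignmentHit]] = {}
    multi = 0
    for seq in seqs:
        categories[seq] = UNALIGNED
        for stage in CASCADE_ORDER:
            index = refs.get(stage)
            if index is None:
                continue
            hits = align_read(seq, index, max_mm=bound(stage), sense_only=sense_only)
            if hits:
                categories[seq] = stage
                if stage == "miRNA":
                    hits, was_multi = resolve_multi_entry(hits)
                    mirna_hits[seq] = hits
                    multi += was_multi
                break
    return CascadeResult(categories=categories, mirna_hits=mirna_hits, multi_entry_reads=multi)


class GenomeScanner:
    """Exact-occurrence queries against a genome, both strands."""

    def __init__(self, contigs: Sequence[Tuple[str, str]]):
        seqs = [seq.upper() for _, seq in contigs]
        self._fwd = "#".join(seqs)
        self._rev = "#".join(revcomp(s) for s in seqs)

    @classmethod
    def from_fasta(cls, path: str) -> "GenomeScanner":
        return cls([(name, seq) for name, _, seq in read_fasta(path)])

    def has_perfect_match(self, seq: str) -> bool:
        s = seq.upper()
        return s in self._fwd or s in self._rev


@dataclass
class RemapStats:
    n_candidates_unique: int
    n_invalidated_unique: int
    candidate_total_count: int
    invalidated_total_count: int

    @property
    def rate_unique_pct(self) -> float:
        if self.n_candidates_unique == 0:
            return 0.0
        return 100.0 * self.n_invalidated_unique / self.n_candidates_unique

    @property
    def rate_total_pct(self) -> float:
        if self.candidate_total_count == 0:
            return 0.0
        return 100.0 * self.invalidated_total_count / self.candidate_total_count


def remap_invalidate(
    mirna_hits: Dict[str, List[AlignmentHit]],
    read_totals: Mapping[str, int],
    genome: Optional[GenomeScanner],
) -> Tuple[set, RemapStats]:
    """Invalidate mismatch miRNA hits whose read matches the genome
    perfectly anywhere (either strand).

    Only reads whose retained hits carry >= 1 mismatch are candidates;
    perfect-match reads are never touched. With no genome the step is a
    no-op. Hits of invalidated reads are flagged ``valid=False`` in
    place; the invalidated read set and rate statistics are returned.
    Rates are reported both over unique mismatch reads and over their
    total read counts — the two diverge when invalidated reads are
    low-copy.
    """
    candidates = [s for s, hits in mirna_hits.items() if hits and hits[0].mismatches >= 1]
    cand_total = sum(int(read_totals.get(s, 0)) for s in candidates)
    if genome is None:
        return set(), RemapStats(len(candidates), 0, cand_total, 0)
    invalidated = {s for s in candidates if genome.has_perfect_match(s)}
    for s in invalidated:
        for h in mirna_hits[s]:
            h.valid = False
    inv_total = sum(int(read_totals.get(s, 0)) for s in invalidated)
    return invalidated, RemapStats(len(candidates), len(invalidated), cand_total, inv_total)
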