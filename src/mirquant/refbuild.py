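"""Build the extended, clustered, N-delimited miRNA alignment reference.

Mature miRNAs and their hairpin precursors (miRBase dialect: RNA
alphabet, ``>id description`` headers) are deduplicated, every mature is
located on every hairpin (sense strand, exact match), overlapping
matures on a shared hairpin are clustered, and each mature occurrence is
extended into its hairpin flanks. Extended segments of one mature are
concatenated with a single ``N`` delimiter; in per-cluster mode,
segments of different matures within one cluster are joined with ``NN``.
Flank bases are lower case, mature bases upper case, so downstream
consumers can recover the annotated mature span from the sequence alone.

The extension captures isomiR length variants: reads whose 5'/3' ends
deviate from the annotation by up to the extension width still align
without mismatches.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from ._io import read_fasta, write_fasta

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGTN")


@dataclass(frozen=True)
class SequenceRecord:
    """A parsed FASTA record, DNA upper case."""

    id: str
    seq: str
    description: str = ""


@dataclass(frozen=True)
class IdenticalGroup:
    """All input records sharing one exact sequence.

    ``rep_id`` is the lexicographically smallest member id; every member
    id is preserved for traceability.
    """

    rep_id: str
    member_ids: Tuple[str, ...]
    seq: str

    @property
    def size(self) -> int:
        return len(self.member_ids)


@dataclass(frozen=True)
class MatureOccurrence:
    """One exact sense-strand placement of a mature group on a hairpin."""

    mature_rep: str
    hairpin_id: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive


@dataclass(frozen=True)
class MiRNACluster:
    """Mature groups connected by overlap chains on shared hairpins."""

    cluster_id: str
    mature_reps: Tuple[str, ...]
    occurrences: Tuple[MatureOccurrence, ...]


@dataclass(frozen=True)
class ExtendedSegment:
    """A mature occurrence plus clipped hairpin flanks, case-encoded."""

    hairpin_id: str
    segment_seq: str  # flanks lower case, mature upper case
    mature_start_in_segment: int
    mature_len: int
    flank5: int
    flank3: int


@dataclass(frozen=True)
class PlacedSegment:
    """An ExtendedSegment placed at an offset within an entry's full_seq."""

    segment: ExtendedSegment
    offset: int  # 0-based offset of segment start in full_seq
    mature_rep: str

    @property
    def mature_start_in_full(self) -> int:
        return self.offset + self.segment.mature_start_in_segment

    @property
    def mature_end_in_full(self) -> int:
        return self.mature_start_in_full + self.segment.mature_len

    @property
    def end(self) -> int:
        return self.offset + len(self.segment.segment_seq)


@dataclass(frozen=True)
class ExtendedReferenceEntry:
    """One alignment-reference entry: concatenated extended segments.

    Runs of ``N`` in ``full_seq`` have length 1 (same mature) or 2
    (different matures of one cluster) and occur nowhere else.
    """

    entry_id: str
    full_seq: str
    segments: Tuple[PlacedSegment, ...]

    @property
    def delimiter_positions(self) -> Tuple[int, ...]:
        return tuple(i for i, c in enumerate(self.full_seq) if c.upper() == "N")


def parse_fasta(path: str, species_prefix: Optional[str] = None) -> List[SequenceRecord]:
    """Parse a miRBase-dialect FASTA into DNA records.

    U/u is converted to T, everything upper-cased. When
    ``species_prefix`` is given (e.g. ``"hsa-"``), records whose id does
    not start with it are dropped. Duplicate ids and non-ACGTN bases are
    rejected.
    """
    records: List[SequenceRecord] = []
    seen: set = set()
    for name, desc, raw in read_fasta(path):
        if species_prefix and not name.startswith(species_prefix):
            continue
        seq = raw.upper().replace("U", "T")
        bad = set(seq) - _VALID_BASES
        if bad:
            raise ValueError(
                f"{path}: record {name!r} contains invalid characters "
                f"{sorted(bad)} (allowed: A,C,G,T,U,N)"
            )
        if not seq:
            raise ValueError(f"{path}: record {name!r} has an empty sequence")
        if name in seen:
            raise ValueError(f"{path}: duplicate record id {name!r}")
        seen.add(name)
        records.append(SequenceRecord(id=name, seq=seq, description=desc))
    return records


def dedup_sequences(records: Sequence[SequenceRecord]) -> List[IdenticalGroup]:
    """Collapse byte-identical sequences into groups.

    Groups partition the input; the representative is the
    lexicographically smallest member id. Output is sorted by rep_id.
    """
    by_seq: Dict[str, List[str]] = {}
    for rec in records:
        by_seq.setdefault(rec.seq, []).append(rec.id)
    groups = [
        IdenticalGroup(rep_id=min(ids), member_ids=tuple(sorted(ids)), seq=seq)
        for seq, ids in by_seq.items()
    ]
    groups.sort(key=lambda g: g.rep_id)
    return groups


def map_matures_to_hairpins(
    matures: Sequence[IdenticalGroup], hairpins: Sequence[IdenticalGroup]
) -> Tuple[List[MatureOccurrence], List[str]]:
    """Locate every exact sense-strand occurrence of each mature.

    Returns (occurrences, orphan mature rep_ids). Multiple occurrences
    per hairpin (including overlapping ones) are all reported; antisense
    matches are never reported. Orphans are logged and excluded from the
    reference downstream.
    """
    occurrences: List[MatureOccurrence] = []
    orphans: List[str] = []
    for m in matures:
        found = False
        for h in hairpins:
            start = h.seq.find(m.seq)
            while start != -1:
                occurrences.append(
                    MatureOccurrence(
                        mature_rep=m.rep_id,
                        hairpin_id=h.rep_id,
                        start=start,
                        end=start + len(m.seq),
                    )
                )
                found = True
                start = h.seq.find(m.seq, start + 1)
        if not found:
            orphans.append(m.rep_id)
    if orphans:
        logger.warning(
            "%d mature group(s) have no hairpin occurrence and are excluded: %s",
            len(orphans),
            ", ".join(orphans[:10]) + ("..." if len(orphans) > 10 else ""),
        )
    return occurrences, orphans


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def cluster_and_merge(occurrences: Sequence[MatureOccurrence]) -> List[MiRNACluster]:
    """Group mature groups into clusters by overlap on shared hairpins.

    Two matures are co-clustered iff connected by a chain of
    same-hairpin interval overlaps; i.e. clusters are the connected
    components of the overlap graph. The cluster id is derived from the
    sorted member rep_ids, so output is deterministic.
    """
    reps = sorted({o.mature_rep for o in occurrences})
    uf = _UnionFind(reps)
    by_hairpin: Dict[str, List[MatureOccurrence]] = {}
    for occ in occurrences:
        by_hairpin.setdefault(occ.hairpin_id, []).append(occ)
    for occs in by_hairpin.values():
        occs = sorted(occs, key=lambda o: (o.start, o.end))
        for i, a in enumerate(occs):
            for b in occs[i + 1 :]:
                if b.start >= a.end:
                    break  # sorted by start: no later occ overlaps a
                uf.union(a.mature_rep, b.mature_rep)
    members: Dict[str, List[str]] = {}
    for rep in reps:
        members.setdefault(uf.find(rep), []).append(rep)
    clusters = []
    for root in sorted(members):
        group = tuple(sorted(members[root]))
        occs = tuple(
            sorted(
                (o for o in occurrences if o.mature_rep in group),
                key=lambda o: (o.hairpin_id, o.start, o.mature_rep),
            )
        )
        clusters.append(
            MiRNACluster(cluster_id="+".join(group), mature_reps=group, occurrences=occs)
        )
    return clusters


def extend_mature(occ: MatureOccurrence, hairpin_seq: str, extension: int) -> ExtendedSegment:
    """Extend one occurrence into its hairpin flanks, clipped at the ends.

    The segment is ``lower(5' flank) + UPPER(mature) + lower(3' flank)``
    with each flank at most ``extension`` nt and shorter where the
    hairpin boundary intervenes.
    """
    if extension < 0:
        raise ValueError("extension must be >= 0")
    L = len(hairpin_seq)
    f5 = min(extension, occ.start)
    f3 = min(extension, L - occ.end)
    seg = (
        hairpin_seq[occ.start - f5 : occ.start].lower()
        + hairpin_seq[occ.start : occ.end].upper()
        + hairpin_seq[occ.end : occ.end + f3].lower()
    )
    return ExtendedSegment(
        hairpin_id=occ.hairpin_id,
        segment_seq=seg,
        mature_start_in_segment=f5,
        mature_len=occ.end - occ.start,
        flank5=f5,
        flank3=f3,
    )


def _place_segments(
    parts: Sequence[Tuple[str, ExtendedSegment]], delim_for_pair
) -> Tuple[str, Tuple[PlacedSegment, ...]]:
    """Concatenate (mature_rep, segment) pairs with computed delimiters."""
    pieces: List[str] = []
    placed: List[PlacedSegment] = []
    offset = 0
    prev_rep = None
    for rep, seg in parts:
        if prev_rep is not None:
            d = delim_for_pair(prev_rep, rep)
            pieces.append(d)
            offset += len(d)
        pieces.append(seg.segment_seq)
        placed.append(PlacedSegment(segment=seg, offset=offset, mature_rep=rep))
        offset += len(seg.segment_seq)
        prev_rep = rep
    return "".join(pieces), tuple(placed)


def assemble_reference(
    clusters: Sequence[MiRNACluster],
    hairpin_seqs: Dict[str, str],
    extension: int,
    mode: str = "per-mature",
) -> List[ExtendedReferenceEntry]:
    """Assemble reference entries from clustered occurrences.

    per-mature mode: one entry per mature group; its segments (one per
    hairpin occurrence, ordered by hairpin then position) joined by "N".
    per-cluster mode: one entry per cluster; same-mature segments joined
    by "N", boundaries between different matures joined by "NN".
    """
    if mode not in ("per-mature", "per-cluster"):
        raise ValueError(f"unknown reference mode {mode!r}")
    entries: List[ExtendedReferenceEntry] = []
    seen_ids: set = set()

    def _segments_for(reps: Sequence[str], occs: Sequence[MatureOccurrence]):
        parts = []
        for rep in reps:
            rep_occs = sorted(
                (o for o in occs if o.mature_rep == rep),
                key=lambda o: (o.hairpin_id, o.start),
            )
            for occ in rep_occs:
                parts.append((rep, extend_mature(occ, hairpin_seqs[occ.hairpin_id], extension)))
        return parts

    for cluster in clusters:
        if mode == "per-mature":
            for rep in cluster.mature_reps:
                parts = _segments_for([rep], cluster.occurrences)
                full, placed = _place_segments(parts, lambda a, b: "N")
                if rep in seen_ids:
                    raise ValueError(f"duplicate entry id {rep!r}")
                seen_ids.add(rep)
                entries.append(
                    ExtendedReferenceEntry(entry_id=rep, full_seq=full, segments=placed)
                )
        else:
            parts = _segments_for(cluster.mature_reps, cluster.occurrences)
            full, placed = _place_segments(
                parts, lambda a, b: "N" if a == b else "NN"
            )
            if cluster.cluster_id in seen_ids:
                raise ValueError(f"duplicate entry id {cluster.cluster_id!r}")
            seen_ids.add(cluster.cluster_id)
            entries.append(
                ExtendedReferenceEntry(
                    entry_id=cluster.cluster_id, full_seq=full, segments=placed
                )
            )
    entries.sort(key=lambda e: e.entry_id)
    return entries


@dataclass
class ReferenceBuild:
    """The full product of reference construction."""

    entries: List[ExtendedReferenceEntry]
    mature_groups: List[IdenticalGroup]
    hairpin_groups: List[IdenticalGroup]
    occurrences: List[MatureOccurrence]
    clusters: List[MiRNACluster]
    orphans: List[str]
    extension: int
    mode: str
    entry_by_id: Dict[str, ExtendedReferenceEntry] = field(default_factory=dict)

    def __post_init__(self):
        self.entry_by_id = {e.entry_id: e for e in self.entries}

    @property
    def members_by_rep(self) -> Dict[str, Tuple[str, ...]]:
        return {g.rep_id: g.member_ids for g in self.mature_groups}

    def annotation(self) -> pd.DataFrame:
        """Segment-level annotation table (1-based inclusive coordinates)."""
        members = self.members_by_rep
        rows = []
        for entry in self.entries:
            for i, ps in enumerate(entry.segments):
                rows.append(
                    {
                        "entry_id": entry.entry_id,
                        "segment_index": i,
                        "hairpin_id": ps.segment.hairpin_id,
                        "mature_id": ps.mature_rep,
                        "member_ids": ",".join(members.get(ps.mature_rep, (ps.mature_rep,))),
                        "mature_start_1based": ps.mature_start_in_full + 1,
                        "mature_end_1based": ps.mature_end_in_full,
                        "flank5": ps.segment.flank5,
                        "flank3": ps.segment.flank3,
                    }
                )
        return pd.DataFrame(rows)

    def write(self, outdir: str) -> None:
        import os

        os.makedirs(outdir, exist_ok=True)
        write_fasta(
            os.path.join(outdir, "mirna.extended.fa"),
            [(e.entry_id, e.full_seq) for e in self.entries],
        )
        write_fasta(
            os.path.join(outdir, "hairpin.unique.fa"),
            [(g.rep_id, g.seq) for g in self.hairpin_groups],
        )
        ann = self.annotation()
        ann_path = os.path.join(outdir, "annotation.tsv")
        with open(ann_path, "w") as fh:
            fh.write("# mature coordinates are 1-based inclusive within entry full_seq\n")
            ann.to_csv(fh, sep="\t", index=False)
        for label, groups in (
            ("mature", self.mature_groups),
            ("hairpin", self.hairpin_groups),
        ):
            df = pd.DataFrame(
                {
                    "rep_id": [g.rep_id for g in groups],
                    "n_members": [g.size for g in groups],
                    "member_ids": [",".join(g.member_ids) for g in groups],
                    "seq": [g.seq for g in groups],
                }
            )
            df.to_csv(os.path.join(outdir, f"{label}.groups.tsv"), sep="\t", index=False)
        with open(os.path.join(outdir, "orphan_matures.txt"), "w") as fh:
            for rep in self.orphans:
                fh.write(rep + "\n")


def build_reference(
    matures: Sequence[SequenceRecord],
    hairpins: Sequence[SequenceRecord],
    extension: int = 4,
    mode: str = "per-mature",
) -> ReferenceBuild:
    """Run the full reference-construction chain on parsed records."""
    mature_groups = dedup_sequences(matures)
    hairpin_groups = dedup_sequences(hairpins)
    occurrences, orphans = map_matures_to_hairpins(mature_groups, hairpin_groups)
    clusters = cluster_and_merge(occurrences)
    hairpin_seqs = {g.rep_id: g.seq for g in hairpin_groups}
    entries = assemble_reference(clusters, hairpin_seqs, extension, mode)
    return ReferenceBuild(
        entries=entries,
        mature_groups=mature_groups,
        hairpin_groups=hairpin_groups,
        occurrences=occurrences,
        clusters=clusters,
        orphans=orphans,
        extension=extension,
        mode=mode,
    )
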