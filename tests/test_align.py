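"""Sense-only bounded-mismatch alignment, cascade annotation and
genome remap invalidation."""

import numpy as np
import pytest

from _oracles import brute_hits, min_stratum
from mirquant._io import revcomp
from mirquant.align import (
    GenomeScanner,
    ReferenceIndex,
    align_read,
    annotate_cascade,
    remap_invalidate,
    resolve_multi_entry,
)
from mirquant.refbuild import ExtendedReferenceEntry


def plain_index(pairs, k=8):
    return ReferenceIndex.from_sequences(pairs, k=k)


def extended_index(pairs, k=8):
    entries = [ExtendedReferenceEntry(eid, seq, ()) for eid, seq in pairs]
    return ReferenceIndex.from_extended(entries, k=k)


def as_set(hits):
    return {(h.entry_id, h.start, h.mismatches) for h in hits}


class TestIndexConstruction:
    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            plain_index([])

    def test_small_k_rejected(self):
        with pytest.raises(ValueError, match=">= 8"):
            plain_index([("e", "ACGTACGTACGT")], k=4)

    def test_single_entry_single_kmer(self):
        idx = plain_index([("e", "ACGTACGT")], k=8)
        hits = align_read("ACGTACGT", idx, max_mm=0)
        assert as_set(hits) == {("e", 0, 0)}


class TestAlignRead:
    REF = "TTTTACGTACGTACGTACGTCCCCGGGG"

    def test_exact_substring_single_hit(self):
        idx = plain_index([("e", self.REF)])
        hits = align_read("ACGTACGTACGTACGT", idx, max_mm=1)
        # exact placement at 4 plus internal repeats at 0 mm
        assert all(h.mismatches == 0 for h in hits)
        assert ("e", 4, 0) in as_set(hits)

    def test_reverse_complement_has_no_sense_hit(self):
        idx = plain_index([("e", self.REF)])
        read = "GGGGACGTACGTACGT"
        assert align_read(read, idx, max_mm=1) == [] or all(
            h.mismatches > 0 for h in align_read(read, idx, max_mm=1)
        )
        rc = revcomp("TTTTACGTACGTACGT")
        assert rc not in self.REF
        assert align_read(rc, idx, max_mm=0) == []

    def test_strand_unaware_mode_reports_antisense_placement(self):
        # the classic confusion: a read maps sense to one miRNA and
        # antisense to another; sense-only must keep only the former
        read = "AGCAGCATTGTACAGGGCTATGT"
        mir103a = "gcttAGCAGCATTGTACAGGGCTATGTttct"  # read is a sense substring
        mir103b = "aagt" + revcomp(read) + "ccag"  # read matches antisense only
        idx = plain_index([("hsa-miR-103a-3p", mir103a), ("hsa-miR-103b", mir103b)])
        sense = align_read(read, idx, max_mm=1, sense_only=True)
        assert {h.entry_id for h in sense} == {"hsa-miR-103a-3p"}
        both = align_read(read, idx, max_mm=1, sense_only=False)
        assert {h.entry_id for h in both} == {"hsa-miR-103a-3p", "hsa-miR-103b"}
        assert {h.strand for h in both} == {"+", "-"}

    def test_delimiter_spanning_placement_rejected(self):
        seq = "ACGTACGTAC" + "N" + "GTACGTACGT"
        idx = extended_index([("e", seq)])
        # this read would need to cross the N
        read = "ACGTACGTACAGTACGTA"[:18]
        assert all(
            h.start + len(read) <= 10 or h.start >= 11
            for h in align_read(read, idx, max_mm=2)
        )

    def test_n_in_plain_reference_counts_as_mismatch(self):
        idx = plain_index([("e", "ACGTNCGTACGTACGTAA")])
        hits = align_read("ACGTACGTACGTACGT", idx, max_mm=1)
        assert as_set(hits) == {("e", 0, 1)}

    def test_minimum_stratum_only(self):
        # read matches entry a exactly and entry b with 1 mismatch
        read = "ACGTACGTACGTACGTACGT"
        b = read[:10] + ("A" if read[10] != "A" else "C") + read[11:]
        idx = plain_index([("a", "TT" + read + "GG"), ("b", "TT" + b + "GG")])
        hits = align_read(read, idx, max_mm=1)
        assert {h.entry_id for h in hits} == {"a"}

    @pytest.mark.parametrize("max_mm", [0, 1, 2])
    def test_hit_sets_equal_bruteforce_oracle(self, max_mm):
        rng = np.random.default_rng(40 + max_mm)
        bases = np.array(list("ACGT"))
        entries = [
            (f"e{j:02d}", "".join(rng.choice(bases, size=int(rng.integers(25, 60)))))
            for j in range(20)
        ]
        idx = plain_index(entries)
        for _ in range(60):
            choice = rng.random()
            if choice < 0.4:
                eid, seq = entries[int(rng.integers(0, len(entries)))]
                L = int(rng.integers(16, min(26, len(seq) + 1)))
                start = int(rng.integers(0, len(seq) - L + 1))
                read = seq[start : start + L]
            else:
                read = "".join(rng.choice(bases, size=int(rng.integers(16, 30))))
            if choice >= 0.4 and choice < 0.7 and len(read) > 3:
                # mutate a few positions of a random read
                for pos in rng.integers(0, len(read), size=int(rng.integers(1, 3))):
                    read = read[:pos] + str(rng.choice(bases)) + read[pos + 1 :]
            got = as_set(align_read(read, idx, max_mm=max_mm))
            expected = min_stratum(brute_hits(read, entries, max_mm))
            assert got == expected


class TestResolveMultiEntry:
    def test_single_entry_untouched(self):
        from mirquant.align import AlignmentHit

        hits = [AlignmentHit("a", 0, 0), AlignmentHit("a", 5, 0)]
        kept, multi = resolve_multi_entry(hits)
        assert len(kept) == 2 and not multi

    def test_smallest_entry_id_wins(self):
        from mirquant.align import AlignmentHit

        hits = [AlignmentHit("b", 0, 0), AlignmentHit("a", 3, 0)]
        kept, multi = resolve_multi_entry(hits)
        assert multi and [h.entry_id for h in kept] == ["a"]


class TestCascade:
    MIR = "TTTTAGCAGCATTGTACAGGGCTATGTCCCC"
    MRNA = "GGGGCCCCAAAATTTTGGGGCCCCAAAATTTTGGGG"

    def _refs(self):
        return {
            "miRNA": plain_index([("mir", self.MIR)]),
            "mRNA": plain_index([("gene", self.MRNA)]),
        }

    def test_first_matching_stage_wins(self):
        # a read present in both references is assigned to miRNA
        shared = "AGCAGCATTGTACAGG"
        refs = {
            "miRNA": plain_index([("mir", self.MIR)]),
            "mRNA": plain_index([("gene", "AAAA" + shared + "TTTT")]),
        }
        res = annotate_cascade([shared], refs)
        assert res.categories[shared] == "miRNA"

    def test_unmatched_read_is_unaligned(self):
        res = annotate_cascade(["T" * 20], self._refs())
        assert res.categories["T" * 20] == "unaligned"

    def test_mrna_read_falls_through(self):
        read = self.MRNA[4:24]
        res = annotate_cascade([read], self._refs())
        assert res.categories[read] == "mRNA"

    def test_missing_mirna_reference_is_fatal(self):
        with pytest.raises(ValueError, match="mandatory"):
            annotate_cascade(["ACGT" * 5], {"mRNA": plain_index([("g", self.MRNA)])})

    def test_categories_are_exhaustive(self):
        reads = [self.MIR[4:27], self.MRNA[0:20], "T" * 20]
        res = annotate_cascade(reads, self._refs())
        assert set(res.categories) == set(reads)
        assert all(v in ("miRNA", "hairpin", "smallRNA", "mRNA", "unaligned") for v in res.categories.values())


class TestRemapInvalidate:
    MIR = "TTTTAGCAGCATTGTACAGGGCTATGTCCCC"

    def _hits_for(self, reads, max_mm=1):
        idx = plain_index([("mir", self.MIR)])
        return {
            r: align_read(r, idx, max_mm=max_mm)
            for r in reads
            if align_read(r, idx, max_mm=max_mm)
        }

    def test_mismatch_read_with_perfect_genomic_match_invalidated(self):
        canonical = self.MIR[4:27]
        variant = "C" + canonical[1:]  # 1 mismatch to the miRNA
        genome = GenomeScanner([("chr1", "AAAA" + variant + "GGGG")])
        hits = self._hits_for([canonical, variant])
        assert hits[variant][0].mismatches == 1
        invalidated, stats = remap_invalidate(
            hits, {canonical: 10, variant: 2}, genome
        )
        assert invalidated == {variant}
        assert not hits[variant][0].valid
        assert hits[canonical][0].valid  # perfect reads are never candidates
        assert stats.n_candidates_unique == 1 and stats.n_invalidated_unique == 1

    def test_mismatch_read_without_genomic_match_kept(self):
        variant = "C" + self.MIR[5:27]
        genome = GenomeScanner([("chr1", "T" * 50)])
        hits = self._hits_for([variant])
        invalidated, stats = remap_invalidate(hits, {variant: 1}, genome)
        assert invalidated == set() and hits[variant][0].valid
        assert stats.rate_unique_pct == 0.0

    def test_reverse_strand_genomic_match_also_invalidates(self):
        variant = "C" + self.MIR[5:27]
        genome = GenomeScanner([("chr1", "AA" + revcomp(variant) + "TT")])
        hits = self._hits_for([variant])
        invalidated, _ = remap_invalidate(hits, {variant: 1}, genome)
        assert invalidated == {variant}

    def test_no_genome_keeps_everything_valid(self):
        variant = "C" + self.MIR[5:27]
        hits = self._hits_for([variant])
        invalidated, stats = remap_invalidate(hits, {variant: 1}, None)
        assert invalidated == set() and hits[variant][0].valid
        assert stats.n_candidates_unique == 1

    def test_rate_over_totals_uses_read_counts(self):
        canonical = self.MIR[4:27]
        v1 = "C" + canonical[1:]
        v2 = canonical[:-1] + ("A" if canonical[-1] != "A" else "G")
        genome = GenomeScanner([("chr1", v1)])
        hits = self._hits_for([v1, v2])
        _, stats = remap_invalidate(hits, {v1: 1, v2: 99}, genome)
        assert stats.n_candidates_unique == 2
        assert stats.rate_unique_pct == pytest.approx(50.0)
        assert stats.rate_total_pct == pytest.approx(1.0)
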