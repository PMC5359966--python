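"""Reference construction: parsing, dedup, mapping, clustering,
extension and assembly."""

import re

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from _oracles import brute_clusters
from mirquant.refbuild import (
    MatureOccurrence,
    SequenceRecord,
    assemble_reference,
    build_reference,
    cluster_and_merge,
    dedup_sequences,
    extend_mature,
    map_matures_to_hairpins,
    parse_fasta,
)

dna = st.text(alphabet="ACGT", min_size=1, max_size=30)


def write(tmp_path, name, content):
    p = tmp_path / name
    p.write_text(content)
    return str(p)


class TestParseFasta:
    def test_rna_alphabet_converted_to_dna(self, tmp_path):
        path = write(tmp_path, "a.fa", ">x\nUGAGG\n")
        recs = parse_fasta(path)
        assert [(r.id, r.seq) for r in recs] == [("x", "TGAGG")]

    def test_mixed_case_upper_cased(self, tmp_path):
        path = write(tmp_path, "a.fa", ">x\nacgU\n")
        assert parse_fasta(path)[0].seq == "ACGT"

    def test_empty_file_gives_empty_list(self, tmp_path):
        assert parse_fasta(write(tmp_path, "e.fa", "")) == []

    def test_species_prefix_filters_records(self, tmp_path):
        path = write(tmp_path, "a.fa", ">hsa-mir-1\nACGT\n>mmu-mir-1\nGGGG\n")
        recs = parse_fasta(path, species_prefix="hsa-")
        assert [r.id for r in recs] == ["hsa-mir-1"]

    def test_duplicate_id_rejected(self, tmp_path):
        path = write(tmp_path, "a.fa", ">x\nACGT\n>x\nGGGG\n")
        with pytest.raises(ValueError, match="duplicate"):
            parse_fasta(path)

    def test_invalid_character_names_record(self, tmp_path):
        path = write(tmp_path, "a.fa", ">bad\nACXT\n")
        with pytest.raises(ValueError, match="bad"):
            parse_fasta(path)

    def test_non_fasta_names_line(self, tmp_path):
        path = write(tmp_path, "a.fa", "ACGT\n>x\nACGT\n")
        with pytest.raises(ValueError, match="line 1"):
            parse_fasta(path)

    def test_description_preserved(self, tmp_path):
        path = write(tmp_path, "a.fa", ">x some description\nACGT\n")
        assert parse_fasta(path)[0].description == "some description"


class TestDedup:
    def test_all_distinct_gives_singletons(self):
        recs = [SequenceRecord(i, s) for i, s in [("a", "AC"), ("b", "GG"), ("c", "TT")]]
        groups = dedup_sequences(recs)
        assert all(g.size == 1 for g in groups) and len(groups) == 3

    def test_identical_sequences_grouped_with_smallest_rep(self):
        recs = [
            SequenceRecord("b", "ACGT"),
            SequenceRecord("a", "ACGT"),
            SequenceRecord("c", "GGGG"),
        ]
        groups = {g.rep_id: g for g in dedup_sequences(recs)}
        assert set(groups) == {"a", "c"}
        assert groups["a"].member_ids == ("a", "b")

    @given(st.lists(st.tuples(st.integers(0, 30), dna), max_size=30))
    def test_groups_partition_the_input(self, pairs):
        recs = [SequenceRecord(f"id{i}_{n}", s) for i, (n, s) in enumerate(pairs)]
        groups = dedup_sequences(recs)
        assert sum(g.size for g in groups) == len(recs)
        members = [m for g in groups for m in g.member_ids]
        assert sorted(members) == sorted(r.id for r in recs)
        for g in groups:
            seqs = {r.seq for r in recs if r.id in g.member_ids}
            assert seqs == {g.seq}


def _groups(pairs):
    return dedup_sequences([SequenceRecord(i, s) for i, s in pairs])


class TestMapMatures:
    def test_single_occurrence_coordinates(self):
        occs, orphans = map_matures_to_hairpins(
            _groups([("m", "ACG")]), _groups([("h", "TTACGTT")])
        )
        assert orphans == []
        assert [(o.start, o.end) for o in occs] == [(2, 5)]
        assert occs[0].hairpin_id == "h"

    def test_multiple_hairpins_all_reported(self):
        occs, _ = map_matures_to_hairpins(
            _groups([("m", "ACGT")]),
            _groups([("h1", "AAACGTAA"), ("h2", "ACGTGGGG")]),
        )
        assert {(o.hairpin_id, o.start) for o in occs} == {("h1", 2), ("h2", 0)}

    def test_overlapping_occurrences_within_one_hairpin(self):
        occs, _ = map_matures_to_hairpins(_groups([("m", "AA")]), _groups([("h", "AAA")]))
        assert [(o.start, o.end) for o in occs] == [(0, 2), (1, 3)]

    def test_antisense_only_match_is_an_orphan(self):
        # mature is the reverse complement of a hairpin substring but
        # never a sense substring: mapping is sense-only, so no hit
        mature = "TTGGC"  # revcomp = GCCAA
        hairpin = "AAAGCCAAAAA"
        assert mature not in hairpin and "GCCAA" in hairpin
        occs, orphans = map_matures_to_hairpins(_groups([("m", mature)]), _groups([("h", hairpin)]))
        assert occs == [] and orphans == ["m"]


class TestClusterAndMerge:
    def test_three_overlapping_matures_form_one_cluster(self):
        occs = [
            MatureOccurrence("m1", "h", 0, 22),
            MatureOccurrence("m2", "h", 4, 26),
            MatureOccurrence("m3", "h", 8, 30),
        ]
        clusters = cluster_and_merge(occs)
        assert len(clusters) == 1
        assert clusters[0].mature_reps == ("m1", "m2", "m3")

    def test_disjoint_matures_stay_singletons(self):
        occs = [
            MatureOccurrence("m1", "h1", 0, 20),
            MatureOccurrence("m2", "h2", 0, 20),
        ]
        assert [c.mature_reps for c in cluster_and_merge(occs)] == [("m1",), ("m2",)]

    def test_adjacent_but_non_overlapping_not_merged(self):
        occs = [
            MatureOccurrence("m1", "h", 0, 20),
            MatureOccurrence("m2", "h", 20, 40),  # half-open: no overlap
        ]
        assert len(cluster_and_merge(occs)) == 2

    def test_chain_through_shared_member_merges(self):
        # m1 overlaps m2 on h1; m2 overlaps m3 on h2 -> all one cluster
        occs = [
            MatureOccurrence("m1", "h1", 0, 20),
            MatureOccurrence("m2", "h1", 10, 30),
            MatureOccurrence("m2", "h2", 0, 20),
            MatureOccurrence("m3", "h2", 5, 25),
        ]
        assert len(cluster_and_merge(occs)) == 1

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_transitive_closure_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 13))
        occs = []
        tuples = []
        for i in range(n):
            for _ in range(int(rng.integers(1, 3))):
                h = f"h{int(rng.integers(0, 4))}"
                start = int(rng.integers(0, 40))
                end = start + int(rng.integers(5, 25))
                occs.append(MatureOccurrence(f"m{i:02d}", h, start, end))
                tuples.append((f"m{i:02d}", h, start, end))
        got = {frozenset(c.mature_reps) for c in cluster_and_merge(occs)}
        assert got == brute_clusters(tuples)


class TestExtendMature:
    def test_clipped_at_hairpin_start(self):
        occ = MatureOccurrence("m", "h", 0, 4)
        seg = extend_mature(occ, "ACGTTTTT", extension=4)
        assert (seg.flank5, seg.flank3) == (0, 4)
        assert seg.segment_seq == "ACGT" + "tttt"

    def test_hand_checked_slicing(self):
        occ = MatureOccurrence("m", "h", 3, 7)
        seg = extend_mature(occ, "AAAACGTTTT", extension=2)
        assert seg.segment_seq == "aaACGTtt"
        assert seg.mature_start_in_segment == 2

    def test_case_encodes_mature_vs_flank(self):
        occ = MatureOccurrence("m", "h", 5, 9)
        seg = extend_mature(occ, "GGGGGACGTCCCCC", extension=3)
        core = seg.segment_seq[seg.mature_start_in_segment :][: seg.mature_len]
        assert core.isupper() and core == "ACGT"
        flanks = seg.segment_seq[: seg.mature_start_in_segment]
        assert flanks.islower()

    def test_zero_extension(self):
        occ = MatureOccurrence("m", "h", 2, 6)
        seg = extend_mature(occ, "AAACGTAA", extension=0)
        assert seg.segment_seq == "ACGT" and seg.flank5 == seg.flank3 == 0


class TestAssembleReference:
    def _build(self, matures, hairpins, **kw):
        return build_reference(
            [SequenceRecord(i, s) for i, s in matures],
            [SequenceRecord(i, s) for i, s in hairpins],
            **kw,
        )

    def test_multi_precursor_mature_joined_by_single_n(self):
        # one mature in 3 hairpins -> one entry, 3 segments, 2 single-N runs
        m = "ACGTACGTACGTACGTACGT"
        flanks = ["TTTT", "CCCC", "GGAA"]  # distinct loci, diverged flanks
        hps = [(f"h{i}", f + m + "GGGG") for i, f in enumerate(flanks)]
        ref = self._build([("let7", m)], hps, extension=2)
        assert len(ref.entries) == 1
        entry = ref.entries[0]
        runs = re.findall("N+", entry.full_seq.upper())
        assert runs == ["N", "N"]
        assert len(entry.segments) == 3

    def test_single_mature_single_hairpin_no_delimiter(self):
        m = "ACGTACGTACGTACGTACGT"
        ref = self._build([("m", m)], [("h", "AA" + m + "CC")], extension=2)
        assert "N" not in ref.entries[0].full_seq.upper()

    def test_per_cluster_two_matures_one_double_n(self):
        h = "AAAA" + "ACGTACGTACGTACGTACGT" + "CCCC"
        m1 = h[4:24]
        m2 = h[8:28]
        ref = self._build([("m1", m1), ("m2", m2)], [("h", h)], mode="per-cluster")
        assert len(ref.entries) == 1
        runs = re.findall("N+", ref.entries[0].full_seq.upper())
        assert runs == ["NN"]

    def test_uppercase_region_reconstructs_mature(self):
        m = "ACGTACGTACGTACGTACGT"
        ref = self._build([("m", m)], [("h", "TTTT" + m + "GGGG")], extension=3)
        ps = ref.entries[0].segments[0]
        seg = ps.segment.segment_seq
        core = seg[ps.segment.mature_start_in_segment :][: ps.segment.mature_len]
        assert core == m

    def test_annotation_coordinates_match_full_seq(self):
        m = "ACGTACGTACGTACGTACGT"
        hps = [("h1", "TTTT" + m + "GGGG"), ("h2", m + "AAAA")]
        ref = self._build([("m", m)], hps, extension=4)
        ann = ref.annotation()
        entry = ref.entries[0]
        for _, row in ann.iterrows():
            s, e = row["mature_start_1based"] - 1, row["mature_end_1based"]
            assert entry.full_seq[s:e].upper() == m

    def test_orphan_mature_excluded_from_entries(self):
        ref = self._build(
            [("m", "ACGTACGTACGTACGTACGT"), ("orphan", "GGGGGGGGGGGGGGGGGGGG")],
            [("h", "AA" + "ACGTACGTACGTACGTACGT" + "CC")],
        )
        assert ref.orphans == ["orphan"]
        assert [e.entry_id for e in ref.entries] == ["m"]

    def test_duplicate_entry_id_fatal(self):
        from mirquant.refbuild import MiRNACluster

        occ = MatureOccurrence("m", "h", 0, 4)
        cluster = MiRNACluster("m", ("m",), (occ,))
        with pytest.raises(ValueError, match="duplicate"):
            assemble_reference([cluster, cluster], {"h": "ACGTAA"}, 2)


class TestDelimiterGrammarOnSynthetic:
    def test_n_runs_have_length_one_or_two_only(self, small_dataset):
        ref = build_reference(
            [SequenceRecord(m.id, m.seq) for m in small_dataset.reference.matures],
            [SequenceRecord(h.id, h.seq) for h in small_dataset.reference.hairpins],
            mode="per-cluster",
        )
        for entry in ref.entries:
            runs = re.findall("N+", entry.full_seq.upper())
            assert all(len(r) in (1, 2) for r in runs)
            assert len(entry.segments) == len(runs) + 1

    def test_build_is_deterministic(self, tmp_path, small_dataset):
        recs_m = [SequenceRecord(m.id, m.seq) for m in small_dataset.reference.matures]
        recs_h = [SequenceRecord(h.id, h.seq) for h in small_dataset.reference.hairpins]
        out1, out2 = tmp_path / "r1", tmp_path / "r2"
        build_reference(recs_m, recs_h).write(str(out1))
        build_reference(recs_m, recs_h).write(str(out2))
        for f in out1.iterdir():
            assert f.read_bytes() == (out2 / f.name).read_bytes()
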