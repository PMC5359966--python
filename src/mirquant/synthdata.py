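"""Deterministic generator of miRBase-like references and stranded
multi-sample miRNA-seq reads with a complete ground truth.

The generated reference deliberately contains the structures that make
real miRNA annotation awkward and that the reference builder must
handle:

* a pair of distinct hairpins carrying one identical mature sequence
  (paralogous loci with diverged flanks),
* one hairpin with three mutually overlapping matures (a miRNA
  cluster),
* one hairpin whose 5p and 3p arms are exact reverse complements of
  each other (the case that breaks strand-unaware alignment),
* matures that appear in the reference but receive no reads.

Reads are hairpin substrings sampled at planted 5'/3' end offsets
(isomiRs), given per-base substitution errors, a 3' adapter and a fixed
downstream filler, then cut to the machine read length. Noise reads are
drawn from decoy genome contigs, and a planted "decoy" read — a
one-substitution variant of a mature that occurs verbatim in the decoy
genome — exercises genome remap invalidation: it aligns to the miRNA
with one mismatch but matches the genome perfectly. Decoy reads are
emitted error-free so that invalidation recall on them is exactly
testable.

Every read id encodes its origin (truth row or noise/decoy source); the
pipeline never consults read ids, they exist so tests can audit
attribution read by read. All randomness flows from one seed;
identical parameters and seed give byte-identical output files.

Overlapping-cluster matures, the reverse-complement arm pair and the
decoy donor default to zero expression weight. Reads from mutually
overlapping matures are genuinely indistinguishable at per-mature
resolution (the reason clustering exists), so exact truth recovery is
only defined without them (``express_cluster=True`` re-enables them for
per-cluster references). Reads from perfect reverse-complement arms
whose flank bases carry sequencing errors can become exact antisense
genome matches of the sister arm, which the remap rule invalidates by
definition; the arms therefore stay unexpressed
(``express_rc_pair=True`` overrides) and strand handling is tested with
reads constructed directly from the planted arms.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from ._io import revcomp, write_fasta, write_fastq
from .refbuild import SequenceRecord

_BASES = np.frombuffer(b"ACGT", dtype="S1")

# fixed post-adapter filler emulating the invariant downstream library
# sequence a real protocol leaves after the 3' adapter
PAD_TAIL = "ATCTCGTATGCCGTCTTCTGCTTG" * 4


@dataclass
class GeneratorParams:
    """Study-condition knobs for the generator.

    Defaults describe an 8-sample small-RNA experiment at 50,000 reads
    per sample with error-free reads; offset supports are +/-1 nt at
    the 5' end and +/-3 nt at the 3' end, the 3' end being the more
    variable one, as observed in real libraries.
    """

    n_hairpins: int = 24
    hairpin_len: Tuple[int, int] = (60, 90)
    mature_len: int = 22
    margin: int = 4  # flank kept around every planted mature; >= max |offset|
    n_samples: int = 8
    reads_per_sample: int = 50_000
    read_length: int = 50
    adapter: str = "TGGAATTCTCGGGTGCCAAGG"
    offset5_probs: Dict[int, float] = field(
        default_factory=lambda: {-1: 0.1, 0: 0.8, 1: 0.1}
    )
    offset3_probs: Dict[int, float] = field(
        default_factory=lambda: {-3: 0.045, -2: 0.08, -1: 0.2, 0: 0.35, 1: 0.2, 2: 0.08, 3: 0.045}
    )
    error_rate: float = 0.0
    noise_fraction: float = 0.0
    decoy_reads_per_sample: int = 25
    n_rare: int = 3
    n_noise_decoys: int = 3
    decoy_len: int = 200
    expression_sigma: float = 1.25
    express_cluster: bool = False
    express_rc_pair: bool = False

    def __post_init__(self):
        for probs in (self.offset5_probs, self.offset3_probs):
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ValueError("offset probabilities must sum to 1")
        if not 0 <= self.error_rate < 0.1:
            raise ValueError("error_rate must be in [0, 0.1)")
        if self.margin < max(
            max(abs(k) for k in self.offset5_probs),
            max(abs(k) for k in self.offset3_probs),
        ):
            raise ValueError("margin must cover the largest planted offset")
        if self.n_hairpins < 6 + self.n_rare:
            raise ValueError("n_hairpins too small to host the planted structures")
        if self.hairpin_len[0] < 2 * self.mature_len + 3 * self.margin:
            raise ValueError("hairpins too short to host a mature with flanks")


@dataclass(frozen=True)
class PlantedMature:
    id: str
    seq: str
    hairpin_id: str
    start: int
    end: int


@dataclass
class SynthReference:
    matures: List[SequenceRecord]
    hairpins: List[SequenceRecord]
    planted: List[PlantedMature]
    manifest: dict

    def mature_groups(self) -> Dict[str, List[str]]:
        """Expected identical groups: entry rep id -> member ids."""
        by_seq: Dict[str, List[str]] = {}
        for m in self.matures:
            by_seq.setdefault(m.seq, []).append(m.id)
        return {min(ids): sorted(ids) for ids in by_seq.values()}

    def entry_of(self, mature_id: str) -> str:
        for rep, members in self.mature_groups().items():
            if mature_id in members:
                return rep
        raise KeyError(mature_id)


@dataclass
class SynthGenome:
    records: List[Tuple[str, str]]
    variant_seq: str
    donor_mature_id: str
    variant_contig: str
    decoy_contigs: List[str]


@dataclass
class SynthDataset:
    params: GeneratorParams
    seed: int
    reference: SynthReference
    genome: SynthGenome
    truth: pd.DataFrame  # sample, entry_id, offset5, offset3, count, kind
    sample_names: List[str]
    fastq_paths: Dict[str, str]
    outdir: str

    def truth_matrix(self) -> pd.DataFrame:
        """Planted counts pivoted to (entry, offset5, offset3) x sample."""
        if self.truth.empty:
            idx = pd.MultiIndex.from_arrays(
                [[], [], []], names=["entry_id", "offset5", "offset3"]
            )
            return pd.DataFrame(0, index=idx, columns=self.sample_names, dtype="int64")
        piv = self.truth.pivot_table(
            index=["entry_id", "offset5", "offset3"],
            columns="sample",
            values="count",
            aggfunc="sum",
            fill_value=0,
        )
        piv.columns.name = None
        piv = piv.reindex(columns=self.sample_names, fill_value=0)
        return piv.astype("int64").sort_index()

    def truth_mirna_matrix(self) -> pd.DataFrame:
        return self.truth_matrix().groupby(level="entry_id").sum()


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return b"".join(rng.choice(_BASES, size=length)).decode()


def make_reference(params: GeneratorParams, rng: np.random.Generator) -> SynthReference:
    """Build mature/hairpin FASTA records with the planted structures."""
    m = params.mature_len
    g = params.margin
    lens = rng.integers(params.hairpin_len[0], params.hairpin_len[1] + 1, params.n_hairpins)
    hairpins = [_random_seq(rng, int(L)) for L in lens]
    hp_ids = [f"syn-hp-{i:03d}" for i in range(params.n_hairpins)]
    planted: List[PlantedMature] = []
    counter = 0

    def embed(hp_idx: int, seq: str, start: int, arm: str) -> PlantedMature:
        nonlocal counter
        h = hairpins[hp_idx]
        assert 0 <= start and start + len(seq) <= len(h)
        hairpins[hp_idx] = h[:start] + seq + h[start + len(seq):]
        pm = PlantedMature(
            id=f"syn-mir-{counter:03d}-{arm}",
            seq=seq,
            hairpin_id=hp_ids[hp_idx],
            start=start,
            end=start + len(seq),
        )
        counter += 1
        planted.append(pm)
        return pm

    # (i) identical mature on two hairpins with diverged flanks
    shared = _random_seq(rng, m)
    dup_a = embed(0, shared, g, "5p")
    dup_b = embed(1, shared, g + 6, "5p")

    # (ii) three mutually overlapping matures on one hairpin
    cluster_members = []
    base = hairpins[2]
    for j in range(3):
        start = g + 4 * j
        seq = base[start : start + m]
        cluster_members.append(embed(2, seq, start, "3p"))

    # (iii) reverse-complement arm pair on one hairpin
    arm5_seq = _random_seq(rng, m)
    arm5 = embed(3, arm5_seq, g, "5p")
    arm3_start = g + m + g  # non-overlapping, separated by one margin
    arm3 = embed(3, revcomp(arm5_seq), arm3_start, "3p")

    # decoy donor: in the reference, never expressed
    donor = embed(4, hairpins[4][g : g + m], g, "5p")

    # rare matures: expressed at one read in one sample
    rare = [
        embed(5 + j, hairpins[5 + j][g : g + m], g, "5p") for j in range(params.n_rare)
    ]

    # ordinary matures: alternate two-arm and single-arm hairpins
    for i in range(5 + params.n_rare, params.n_hairpins):
        h = hairpins[i]
        embed(i, h[g : g + m], g, "5p")
        if (i % 2) == 0 and len(h) >= 2 * m + 3 * g:
            start3 = len(h) - g - m
            embed(i, h[start3 : start3 + m], start3, "3p")

    seqs = [p.seq for p in planted]
    n_dups = len(seqs) - len(set(seqs))
    if n_dups != 1:  # only the planted identical pair may collide
        raise RuntimeError("unexpected mature sequence collision; change the seed")

    matures = [SequenceRecord(id=p.id, seq=p.seq, description=f"planted on {p.hairpin_id}") for p in planted]
    hairpin_records = [
        SequenceRecord(id=hp_ids[i], seq=hairpins[i], description="synthetic hairpin")
        for i in range(params.n_hairpins)
    ]
    manifest = {
        "planted_matures": [asdict(p) for p in planted],
        "identical_pair": [dup_a.id, dup_b.id],
        "cluster_ids": [p.id for p in cluster_members],
        "rc_pair": {"arm5": arm5.id, "arm3": arm3.id},
        "decoy_donor": donor.id,
        "rare_ids": [p.id for p in rare],
    }
    return SynthReference(
        matures=matures, hairpins=hairpin_records, planted=planted, manifest=manifest
    )


def make_genome(
    reference: SynthReference, params: GeneratorParams, rng: np.random.Generator
) -> SynthGenome:
    """Genome = hairpin loci + decoy contigs.

    Decoy contig 0 carries a one-substitution variant of the decoy-donor
    mature, so reads matching that variant align to the miRNA reference
    with one mismatch while matching the genome perfectly.
    """
    donor_id = reference.manifest["decoy_donor"]
    donor = next(p for p in reference.planted if p.id == donor_id)
    pos = params.mature_len // 2
    alternatives = [b for b in "ACGT" if b != donor.seq[pos]]
    variant = donor.seq[:pos] + alternatives[int(rng.integers(0, 3))] + donor.seq[pos + 1 :]
    if any(variant in h.seq for h in reference.hairpins):
        raise RuntimeError("decoy variant collides with a hairpin; change the seed")

    records: List[Tuple[str, str]] = [(h.id, h.seq) for h in reference.hairpins]
    decoy_names = []
    for j in range(params.n_noise_decoys):
        seq = _random_seq(rng, params.decoy_len)
        if j == 0:
            mid = params.decoy_len // 2
            seq = seq[:mid] + variant + seq[mid + len(variant):]
        name = f"decoy-{j:03d}"
        decoy_names.append(name)
        records.append((name, seq))
    return SynthGenome(
        records=records,
        variant_seq=variant,
        donor_mature_id=donor_id,
        variant_contig=decoy_names[0] if decoy_names else "",
        decoy_contigs=decoy_names,
    )


def _apply_errors(read: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return read
    arr = np.frombuffer(read.encode(), dtype="S1").copy()
    hit = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hit:
        cur = arr[i]
        choices = [b for b in (b"A", b"C", b"G", b"T") if b != cur]
        arr[i] = choices[int(rng.integers(0, len(choices)))]
    return arr.tobytes().decode()


def simulate_reads(
    reference: SynthReference,
    genome: SynthGenome,
    params: GeneratorParams,
    rng: np.random.Generator,
    outdir: str,
) -> Tuple[pd.DataFrame, Dict[str, str], List[str]]:
    """Emit per-sample FASTQ and the truth table.

    Per sample, the main reads are a multinomial draw over (entry,
    offset5, offset3) species whose probabilities combine lognormal
    entry expression with the planted offset distributions; multi-
    precursor matures pick a hairpin of origin uniformly per read.
    Rare species add one extra read in one sample each. Decoy and noise
    reads are appended as configured.
    """
    os.makedirs(outdir, exist_ok=True)
    groups = reference.mature_groups()
    planted_by_id = {p.id: p for p in reference.planted}
    hairpin_seq = {h.id: h.seq for h in reference.hairpins}

    excluded = set(reference.manifest["rare_ids"]) | {reference.manifest["decoy_donor"]}
    if not params.express_cluster:
        excluded |= set(reference.manifest["cluster_ids"])
    if not params.express_rc_pair:
        # reads from perfect reverse-complement arms whose flank bases
        # carry errors can coincide exactly with the genome's antisense
        # strand, so remap invalidates them by definition; keeping the
        # arms unexpressed keeps the decoy-invalidation oracle exact
        excluded |= set(reference.manifest["rc_pair"].values())
    expressed = [
        rep
        for rep, members in sorted(groups.items())
        if not any(mid in excluded for mid in members)
    ]
    weights = rng.lognormal(mean=0.0, sigma=params.expression_sigma, size=len(expressed))
    weights /= weights.sum()

    o5_keys = sorted(params.offset5_probs)
    o3_keys = sorted(params.offset3_probs)
    species: List[Tuple[str, int, int]] = []
    probs: List[float] = []
    for rep, w in zip(expressed, weights):
        for o5 in o5_keys:
            for o3 in o3_keys:
                species.append((rep, o5, o3))
                probs.append(w * params.offset5_probs[o5] * params.offset3_probs[o3])
    probs_arr = np.asarray(probs)
    probs_arr /= probs_arr.sum()

    occurrences: Dict[str, List[PlantedMature]] = {
        rep: [planted_by_id[mid] for mid in members]
        for rep, members in groups.items()
    }

    rare_sample_idx = {
        rid: int(rng.integers(0, params.n_samples))
        for rid in reference.manifest["rare_ids"]
    }

    sample_names = [f"S{i + 1:02d}" for i in range(params.n_samples)]
    n_noise = int(round(params.noise_fraction * params.reads_per_sample))
    n_decoy = min(params.decoy_reads_per_sample, max(0, params.reads_per_sample - n_noise))
    n_main = params.reads_per_sample - n_noise - n_decoy
    if n_main < 0:
        raise ValueError("reads_per_sample too small for the configured noise reads")
    decoy_pool = [
        (name, seq) for name, seq in genome.records if name in genome.decoy_contigs
    ]
    if n_noise > 0 and not decoy_pool:
        raise ValueError("noise reads requested but no decoy contigs configured")

    truth_rows = []
    fastq_paths: Dict[str, str] = {}

    def build_read(insert: str) -> str:
        full = insert + params.adapter + PAD_TAIL
        return full[: params.read_length]

    for s_idx, sample in enumerate(sample_names):
        reads: List[Tuple[str, str]] = []
        counts = rng.multinomial(n_main, probs_arr) if n_main > 0 else np.zeros(len(species), int)
        serial = 0
        for (rep, o5, o3), c in zip(species, counts):
            if c == 0:
                continue
            occs = occurrences[rep]
            pick = rng.integers(0, len(occs), size=int(c)) if len(occs) > 1 else np.zeros(int(c), int)
            for r in range(int(c)):
                occ = occs[int(pick[r])]
                h = hairpin_seq[occ.hairpin_id]
                insert = h[occ.start + o5 : occ.end + o3]
                read = _apply_errors(build_read(insert), params.error_rate, rng)
                reads.append((f"{rep}|{o5}|{o3}|{sample}|{serial}", read))
                serial += 1
            truth_rows.append(
                {"sample": sample, "entry_id": rep, "offset5": o5, "offset3": o3,
                 "count": int(c), "kind": "main"}
            )
        for rid, target in rare_sample_idx.items():
            if target != s_idx or params.reads_per_sample == 0:
                continue
            rep = reference.entry_of(rid)
            occ = planted_by_id[rid]
            insert = hairpin_seq[occ.hairpin_id][occ.start : occ.end]
            reads.append((f"{rep}|0|0|{sample}|{serial}", build_read(insert)))
            serial += 1
            truth_rows.append(
                {"sample": sample, "entry_id": rep, "offset5": 0, "offset3": 0,
                 "count": 1, "kind": "rare"}
            )
        for d in range(n_decoy):
            reads.append((f"decoy|{sample}|{d}", build_read(genome.variant_seq)))
        for j in range(n_noise):
            contig, cseq = decoy_pool[int(rng.integers(0, len(decoy_pool)))]
            pos = int(rng.integers(0, len(cseq) - params.mature_len + 1))
            insert = cseq[pos : pos + params.mature_len]
            read = _apply_errors(build_read(insert), params.error_rate, rng)
            reads.append((f"noise|{contig}|{pos}|{sample}|{j}", read))
        order = rng.permutation(len(reads))
        reads = [reads[int(i)] for i in order]
        path = os.path.join(outdir, f"{sample}.fastq.gz")
        write_fastq(path, reads)
        fastq_paths[sample] = path

    truth = pd.DataFrame(
        truth_rows, columns=["sample", "entry_id", "offset5", "offset3", "count", "kind"]
    )
    return truth, fastq_paths, sample_names


def generate(
    params: Optional[GeneratorParams] = None,
    outdir: str = "synth",
    seed: int = 42,
) -> SynthDataset:
    """Run the full generator and write all artifacts to ``outdir``.

    Emits mature.fa, hairpin.fa, genome.fa, per-sample FASTQ (gzipped),
    truth.tsv and manifest.json.
    """
    params = params or GeneratorParams()
    rng = np.random.default_rng(seed)
    os.makedirs(outdir, exist_ok=True)
    reference = make_reference(params, rng)
    genome = make_genome(reference, params, rng)
    truth, fastq_paths, sample_names = simulate_reads(
        reference, genome, params, rng, outdir
    )
    write_fasta(os.path.join(outdir, "mature.fa"), [(m.id, m.seq) for m in reference.matures])
    write_fasta(os.path.join(outdir, "hairpin.fa"), [(h.id, h.seq) for h in reference.hairpins])
    write_fasta(os.path.join(outdir, "genome.fa"), genome.records)
    truth.to_csv(os.path.join(outdir, "truth.tsv"), sep="\t", index=False)
    manifest = dict(reference.manifest)
    manifest["decoy_variant_seq"] = genome.variant_seq
    manifest["variant_contig"] = genome.variant_contig
    manifest["sample_names"] = sample_names
    manifest["seed"] = seed
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return SynthDataset(
        params=params,
        seed=seed,
        reference=reference,
        genome=genome,
        truth=truth,
        sample_names=sample_names,
        fastq_paths=fastq_paths,
        outdir=outdir,
    )
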