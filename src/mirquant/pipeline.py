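"""End-to-end orchestration: reference build, trimming, joint
collapsing, cascade alignment, remap invalidation, noise filtering,
count tables, QC.

``run_pipeline`` is a pure function of its :class:`RunConfig`; all
artifacts live on the returned :class:`PipelineResult`, and
``PipelineResult.write`` materializes the output directory. With the
noise filter disabled, jointly processed samples and per-sample runs
yield identical tables — joint collapsing is purely an efficiency
device; only the cross-sample filter couples samples.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass
from typing import Dict, List, Optional

import pandas as pd

from .align import (
    CascadeResult,
    GenomeScanner,
    ReferenceIndex,
    RemapStats,
    annotate_cascade,
    remap_invalidate,
)
from .config import RunConfig
from .preprocess import TrimConfig, TrimStats, collapse_joint, process_fastq
from .qcreport import (
    OffsetDistribution,
    SampleQC,
    compute_offset_distribution,
    compute_sample_qc,
    emit_reports,
)
from .quantify import (
    NoiseFilterParams,
    attribute_reads,
    count_isomir,
    count_mirna,
    filter_noise,
    rpm_normalize,
)
from .refbuild import ReferenceBuild, build_reference, parse_fasta

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    config: RunConfig
    reference: ReferenceBuild
    trim_stats: Dict[str, TrimStats]
    counts: pd.DataFrame  # unique read x sample
    cascade: CascadeResult
    attr: pd.DataFrame  # per-read miRNA attribution (all, incl. invalidated)
    invalidated: set
    remap_stats: RemapStats
    filter_stats: dict
    kept_seqs: pd.Index  # miRNA-attributed valid reads surviving the filter
    mirna_prefilter: pd.DataFrame
    mirna_counts: pd.DataFrame
    mirna_mismatch: pd.DataFrame
    isomir_counts: pd.DataFrame
    isomir_mismatch: pd.DataFrame
    mirna_rpm: pd.DataFrame
    sample_qcs: List[SampleQC]
    offsets: OffsetDistribution

    @property
    def sample_names(self) -> List[str]:
        return list(self.counts.columns)

    def hits_table(self) -> pd.DataFrame:
        """Per-unique-read annotation: category plus miRNA placement."""
        cats = pd.Series(self.cascade.categories, name="category")
        cats.index.name = "seq"
        df = cats.to_frame()
        attr = self.attr.copy()
        if not attr.empty:
            attr = attr.rename(columns={"entry_id": "entry_id", "mismatches": "mismatches"})
            starts = {
                seq: hits[0].start + 1
                for seq, hits in self.cascade.mirna_hits.items()
                if hits
            }
            attr["start_1based"] = pd.Series(starts)
            df = df.join(attr[["entry_id", "start_1based", "mismatches", "offset5", "offset3", "valid"]])
        return df.sort_index()

    def write(self, outdir: Optional[str] = None) -> str:
        outdir = outdir or self.config.out
        os.makedirs(outdir, exist_ok=True)
        self.reference.write(os.path.join(outdir, "reference"))

        counts = self.counts.copy()
        counts.index.name = "seq"
        counts.to_csv(os.path.join(outdir, "unique.reads.tsv"), sep="\t")
        self.hits_table().to_csv(os.path.join(outdir, "hits.tsv"), sep="\t")

        cat_rows = {}
        for sample in self.sample_names:
            col = self.counts[sample]
            sums: Dict[str, int] = {}
            for seq, cat in self.cascade.categories.items():
                sums[cat] = sums.get(cat, 0) + int(col.get(seq, 0))
            cat_rows[sample] = sums
        pd.DataFrame(cat_rows).fillna(0).astype(int).to_csv(
            os.path.join(outdir, "category_summary.tsv"), sep="\t"
        )

        self.mirna_counts.to_csv(os.path.join(outdir, "miRNA.counts.tsv"), sep="\t")
        self.mirna_mismatch.to_csv(os.path.join(outdir, "miRNA.mismatch.counts.tsv"), sep="\t")
        self.isomir_counts.reset_index().to_csv(
            os.path.join(outdir, "isomiR.counts.tsv"), sep="\t", index=False
        )
        self.isomir_mismatch.reset_index().to_csv(
            os.path.join(outdir, "isomiR.mismatch.counts.tsv"), sep="\t", index=False
        )
        self.mirna_rpm.to_csv(
            os.path.join(outdir, "miRNA.rpm.tsv"), sep="\t", float_format="%.4f"
        )

        with open(os.path.join(outdir, "filter.stats.json"), "w") as fh:
            json.dump(
                {
                    "noise_filter": self.filter_stats,
                    "remap": {
                        "n_candidates_unique": self.remap_stats.n_candidates_unique,
                        "n_invalidated_unique": self.remap_stats.n_invalidated_unique,
                        "candidate_total_count": self.remap_stats.candidate_total_count,
                        "invalidated_total_count": self.remap_stats.invalidated_total_count,
                        "rate_unique_pct": self.remap_stats.rate_unique_pct,
                        "rate_total_pct": self.remap_stats.rate_total_pct,
                    },
                    "multi_entry_reads": self.cascade.multi_entry_reads,
                },
                fh,
                indent=2,
                sort_keys=True,
            )
            fh.write("\n")

        hist_rows = [
            {"sample": s, "length": L, "count": c}
            for s, st in self.trim_stats.items()
            for L, c in sorted(st.length_histogram.items())
        ]
        pd.DataFrame(hist_rows, columns=["sample", "length", "count"]).to_csv(
            os.path.join(outdir, "length_histograms.tsv"), sep="\t", index=False
        )

        with open(os.path.join(outdir, "trim.stats.json"), "w") as fh:
            json.dump(
                {s: st.as_dict() for s, st in self.trim_stats.items()},
                fh,
                indent=2,
                sort_keys=True,
            )
            fh.write("\n")

        emit_reports(self.sample_qcs, self.offsets, outdir, plots=self.config.plots)
        return outdir


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full quantification workflow for one configuration."""
    logger.info("building reference (%s, extension=%d)", config.ref_mode, config.extension)
    matures = parse_fasta(config.mature, config.species_prefix)
    hairpins = parse_fasta(config.hairpin, config.species_prefix)
    reference = build_reference(
        matures, hairpins, extension=config.extension, mode=config.ref_mode
    )

    trim_cfg = TrimConfig(
        adapter=config.adapter,
        max_error_rate=config.max_error_rate,
        min_overlap=config.min_overlap,
        min_len=config.min_len,
        discard_untrimmed=config.discard_untrimmed,
    )
    cache: dict = {}
    per_sample = []
    trim_stats: Dict[str, TrimStats] = {}
    for name, path in zip(config.sample_names, config.samples):
        counter, stats = process_fastq(path, name, trim_cfg, _trim_cache=cache)
        per_sample.append((name, counter))
        trim_stats[name] = stats
        logger.info("%s: %d reads in, %d surviving", name, stats.n_input, stats.n_surviving)
    counts = collapse_joint(per_sample)
    logger.info("joint collapsing: %d unique reads across %d samples", len(counts), len(per_sample))

    refs: Dict[str, Optional[ReferenceIndex]] = {
        "miRNA": ReferenceIndex.from_extended(reference.entries, k=config.kmer),
        "hairpin": ReferenceIndex.from_sequences(
            [(g.rep_id, g.seq) for g in reference.hairpin_groups], k=config.kmer
        ),
        "smallRNA": ReferenceIndex.from_fasta(config.smallrna, k=config.kmer)
        if config.smallrna
        else None,
        "mRNA": ReferenceIndex.from_fasta(config.mrna, k=config.kmer)
        if config.mrna
        else None,
    }
    cascade = annotate_cascade(
        counts.index, refs, max_mm=config.max_mm, sense_only=config.sense_only
    )

    scanner = GenomeScanner.from_fasta(config.genome) if config.genome else None
    read_totals = counts.sum(axis=1)
    invalidated, remap_stats = remap_invalidate(cascade.mirna_hits, read_totals, scanner)
    if scanner is not None:
        logger.info(
            "remap invalidation: %.2f%% of unique mismatch reads, %.2f%% of total",
            remap_stats.rate_unique_pct,
            remap_stats.rate_total_pct,
        )

    attr = attribute_reads(cascade, reference)
    mirna_prefilter, _ = count_mirna(attr, counts)

    valid_seqs = attr.index[attr["valid"]]
    if config.apply_filter:
        params = NoiseFilterParams(
            zero_fraction_threshold=config.zero_fraction,
            min_mean_count=config.min_mean,
            combine=config.filter_mode,
        )
        logger.info(
            "noise filter: %s(zero_fraction > %.2f, mean < %.2f)",
            params.combine, params.zero_fraction_threshold, params.min_mean_count,
        )
        kept, _removed, filter_stats = filter_noise(counts.loc[valid_seqs], params)
        kept_seqs = kept.index
    else:
        kept_seqs = pd.Index(valid_seqs)
        filter_stats = {"combine": "disabled"}

    kept_attr = attr.loc[kept_seqs]
    mirna_counts, mirna_mismatch = count_mirna(kept_attr, counts)
    isomir_counts, isomir_mismatch = count_isomir(kept_attr, counts)

    if config.rpm_denominator == "mirna_mapped":
        denom = mirna_counts.sum(axis=0)
    else:
        denom = pd.Series(
            {s: trim_stats[s].n_surviving for s in counts.columns}, dtype=float
        )
    mirna_rpm = rpm_normalize(mirna_counts, denom)

    attr_valid = attr[attr["valid"]]
    sample_qcs = [
        compute_sample_qc(
            sample,
            trim_stats[sample],
            cascade.categories,
            counts,
            attr_valid,
            mirna_prefilter,
            mirna_counts,
            min_detect_count=config.min_detect_count,
        )
        for sample in counts.columns
    ]
    offsets = compute_offset_distribution(attr)

    return PipelineResult(
        config=config,
        reference=reference,
        trim_stats=trim_stats,
        counts=counts,
        cascade=cascade,
        attr=attr,
        invalidated=invalidated,
        remap_stats=remap_stats,
        filter_stats=filter_stats,
        kept_seqs=pd.Index(kept_seqs),
        mirna_prefilter=mirna_prefilter,
        mirna_counts=mirna_counts,
        mirna_mismatch=mirna_mismatch,
        isomir_counts=isomir_counts,
        isomir_mismatch=isomir_mismatch,
        mirna_rpm=mirna_rpm,
        sample_qcs=sample_qcs,
        offsets=offsets,
    )
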