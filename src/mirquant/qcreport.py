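"""QC metric computation and machine-readable report emission.

The QC surface mirrors what an analyst inspects on a small-RNA run:
adapter incidence and trimming survivorship, the per-sample breakdown
of reads over the annotation categories (miRNA, hairpin, smallRNA,
mRNA, unaligned), read redundancy (total/unique — high for genuine
miRNA libraries, low for noise), trimmed-length distributions (expected
to peak near 22 nt), the 5'/3' offset distributions of miRNA reads
(5' ends are functionally constrained by the seed region and vary far
less than 3' ends), and detected-miRNA counts before/after the noise
filter.

TSV/JSON outputs are the contract and are byte-deterministic for fixed
inputs; static plots are optional conveniences.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .preprocess import TrimStats

CATEGORIES = ("miRNA", "hairpin", "smallRNA", "mRNA", "unaligned")


@dataclass
class SampleQC:
    """All per-sample QC numbers; every field is re-derivable from the
    per-read artifacts shipped alongside the report."""

    sample: str
    n_raw: int
    n_with_adapter: int
    n_surviving: int
    category_totals: Dict[str, int]
    category_uniques: Dict[str, int]
    mismatch_read_fraction: Optional[float]
    detected_mirnas_prefilter: int
    detected_mirnas_postfilter: int
    length_histogram: Dict[int, int] = field(default_factory=dict)

    @property
    def redundancy(self) -> Dict[str, Optional[float]]:
        """total/unique per category; missing where the sample has no
        reads in a category."""
        out: Dict[str, Optional[float]] = {}
        for cat in CATEGORIES:
            u = self.category_uniques.get(cat, 0)
            out[cat] = self.category_totals.get(cat, 0) / u if u > 0 else None
        return out

    def as_dict(self) -> dict:
        return {
            "sample": self.sample,
            "n_raw": self.n_raw,
            "n_with_adapter": self.n_with_adapter,
            "n_surviving": self.n_surviving,
            "category_totals": dict(self.category_totals),
            "category_uniques": dict(self.category_uniques),
            "redundancy": {k: v for k, v in self.redundancy.items()},
            "mismatch_read_fraction": self.mismatch_read_fraction,
            "detected_mirnas_prefilter": self.detected_mirnas_prefilter,
            "detected_mirnas_postfilter": self.detected_mirnas_postfilter,
            "length_histogram": {str(k): v for k, v in sorted(self.length_histogram.items())},
        }


def compute_sample_qc(
    sample: str,
    trim_stats: TrimStats,
    categories: Mapping[str, str],
    counts: pd.DataFrame,
    attr: pd.DataFrame,
    mirna_prefilter: pd.DataFrame,
    mirna_postfilter: pd.DataFrame,
    min_detect_count: int = 1,
) -> SampleQC:
    """Assemble one sample's QC record.

    ``categories`` maps unique read -> cascade category, ``counts`` is
    the unique-read count matrix, ``attr`` the per-read miRNA
    attribution, and the two miRNA matrices give detected-miRNA counts
    before and after the noise filter (detected = count >=
    ``min_detect_count``).
    """
    col = counts[sample]
    cat_series = pd.Series({s: categories[s] for s in counts.index}, name="category")
    totals: Dict[str, int] = {c: 0 for c in CATEGORIES}
    uniques: Dict[str, int] = {c: 0 for c in CATEGORIES}
    present = col > 0
    for cat in CATEGORIES:
        in_cat = cat_series == cat
        totals[cat] = int(col[in_cat].sum())
        uniques[cat] = int((in_cat & present).sum())

    mm_frac: Optional[float] = None
    if totals["miRNA"] > 0 and not attr.empty:
        mirna_counts = col.reindex(attr.index, fill_value=0)
        mm_total = int(mirna_counts[attr["mismatches"] >= 1].sum())
        denom = int(mirna_counts.sum())
        mm_frac = mm_total / denom if denom > 0 else None

    def detected(matrix: pd.DataFrame) -> int:
        if sample not in matrix.columns or matrix.empty:
            return 0
        return int((matrix[sample] >= min_detect_count).sum())

    return SampleQC(
        sample=sample,
        n_raw=trim_stats.n_input,
        n_with_adapter=trim_stats.n_with_adapter,
        n_surviving=trim_stats.n_surviving,
        category_totals=totals,
        category_uniques=uniques,
        mismatch_read_fraction=mm_frac,
        detected_mirnas_prefilter=detected(mirna_prefilter),
        detected_mirnas_postfilter=detected(mirna_postfilter),
        length_histogram=dict(trim_stats.length_histogram),
    )


@dataclass
class OffsetDistribution:
    """5'/3' offset histograms over unique mapped miRNA reads."""

    hist5: Dict[int, int]
    hist3: Dict[int, int]
    joint: Dict[Tuple[int, int], int]
    n_unique: int

    @property
    def frac_no_variation(self) -> float:
        return self.joint.get((0, 0), 0) / self.n_unique if self.n_unique else 0.0

    @property
    def frac_5p_variation(self) -> float:
        if not self.n_unique:
            return 0.0
        return sum(v for (o5, _), v in self.joint.items() if o5 != 0) / self.n_unique

    @property
    def frac_3p_variation(self) -> float:
        if not self.n_unique:
            return 0.0
        return sum(v for (_, o3), v in self.joint.items() if o3 != 0) / self.n_unique


def compute_offset_distribution(attr: pd.DataFrame) -> OffsetDistribution:
    """Offset histograms from the per-read attribution table.

    Each unique read contributes one observation (the convention for
    offset-variation summaries); only valid attributions count.
    """
    sel = attr[attr["valid"]] if not attr.empty else attr
    joint: Dict[Tuple[int, int], int] = {}
    hist5: Dict[int, int] = {}
    hist3: Dict[int, int] = {}
    for o5, o3 in zip(sel["offset5"], sel["offset3"]):
        key = (int(o5), int(o3))
        joint[key] = joint.get(key, 0) + 1
        hist5[key[0]] = hist5.get(key[0], 0) + 1
        hist3[key[1]] = hist3.get(key[1], 0) + 1
    return OffsetDistribution(hist5=hist5, hist3=hist3, joint=joint, n_unique=int(len(sel)))


def qc_summary_frame(qcs: Sequence[SampleQC]) -> pd.DataFrame:
    rows = []
    for qc in qcs:
        red = qc.redundancy
        row = {
            "sample": qc.sample,
            "n_raw": qc.n_raw,
            "n_with_adapter": qc.n_with_adapter,
            "pct_with_adapter": 100.0 * qc.n_with_adapter / qc.n_raw if qc.n_raw else 0.0,
            "n_surviving": qc.n_surviving,
        }
        for cat in CATEGORIES:
            row[f"{cat}_total"] = qc.category_totals.get(cat, 0)
            row[f"{cat}_unique"] = qc.category_uniques.get(cat, 0)
            row[f"{cat}_redundancy"] = red[cat]
        row["mismatch_read_fraction"] = qc.mismatch_read_fraction
        row["detected_mirnas_prefilter"] = qc.detected_mirnas_prefilter
        row["detected_mirnas_postfilter"] = qc.detected_mirnas_postfilter
        rows.append(row)
    return pd.DataFrame(rows)


def emit_reports(
    qcs: Sequence[SampleQC],
    offsets: OffsetDistribution,
    outdir: str,
    plots: bool = False,
) -> List[str]:
    """Write qc_summary.tsv/.json and the offset-distribution TSVs.

    Returns the list of paths written. With ``plots=True`` static PNG
    figures (category breakdown, redundancy, length and offset
    distributions) are added under ``plots/``.
    """
    os.makedirs(outdir, exist_ok=True)
    written: List[str] = []

    path = os.path.join(outdir, "qc_summary.tsv")
    qc_summary_frame(qcs).to_csv(path, sep="\t", index=False, float_format="%.6g")
    written.append(path)

    path = os.path.join(outdir, "qc_summary.json")
    with open(path, "w") as fh:
        json.dump([qc.as_dict() for qc in qcs], fh, indent=2, sort_keys=True)
        fh.write("\n")
    written.append(path)

    for name, hist in (("offsets5.tsv", offsets.hist5), ("offsets3.tsv", offsets.hist3)):
        path = os.path.join(outdir, name)
        pd.DataFrame(
            {"offset": sorted(hist), "unique_reads": [hist[k] for k in sorted(hist)]}
        ).to_csv(path, sep="\t", index=False)
        written.append(path)

    path = os.path.join(outdir, "offsets_joint.tsv")
    keys = sorted(offsets.joint)
    pd.DataFrame(
        {
            "offset5": [k[0] for k in keys],
            "offset3": [k[1] for k in keys],
            "unique_reads": [offsets.joint[k] for k in keys],
        }
    ).to_csv(path, sep="\t", index=False)
    written.append(path)

    path = os.path.join(outdir, "offset_summary.json")
    with open(path, "w") as fh:
        json.dump(
            {
                "n_unique_mapped": offsets.n_unique,
                "frac_no_variation": offsets.frac_no_variation,
                "frac_5p_variation": offsets.frac_5p_variation,
                "frac_3p_variation": offsets.frac_3p_variation,
            },
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")
    written.append(path)

    if plots:
        written.extend(_emit_plots(qcs, offsets, os.path.join(outdir, "plots")))
    return written


def _emit_plots(qcs: Sequence[SampleQC], offsets: OffsetDistribution, plotdir: str) -> List[str]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    os.makedirs(plotdir, exist_ok=True)
    written = []
    samples = [qc.sample for qc in qcs]

    fig, ax = plt.subplots(figsize=(max(4, len(samples)), 4))
    bottom = [0] * len(samples)
    for cat in CATEGORIES:
        vals = [qc.category_totals.get(cat, 0) for qc in qcs]
        ax.bar(samples, vals, bottom=bottom, label=cat)
        bottom = [b + v for b, v in zip(bottom, vals)]
    ax.set_ylabel("reads")
    ax.set_title("Annotation breakdown")
    ax.legend(fontsize=8)
    plt.setp(ax.get_xticklabels(), rotation=45, ha="right")
    path = os.path.join(plotdir, "annotation_breakdown.png")
    fig.tight_layout(); fig.savefig(path, dpi=100); plt.close(fig)
    written.append(path)

    fig, ax = plt.subplots(figsize=(max(4, len(samples)), 4))
    for cat in CATEGORIES:
        vals = [qc.redundancy.get(cat) or 0 for qc in qcs]
        ax.plot(samples, vals, marker="o", label=cat)
    ax.set_ylabel("total / unique reads")
    ax.set_title("Read redundancy per category")
    ax.legend(fontsize=8)
    plt.setp(ax.get_xticklabels(), rotation=45, ha="right")
    path = os.path.join(plotdir, "redundancy.png")
    fig.tight_layout(); fig.savefig(path, dpi=100); plt.close(fig)
    written.append(path)

    fig, ax = plt.subplots(figsize=(6, 4))
    for qc in qcs:
        lengths = sorted(qc.length_histogram)
        ax.plot(lengths, [qc.length_histogram[k] for k in lengths], label=qc.sample, lw=1)
    ax.set_xlabel("trimmed read length (nt)")
    ax.set_ylabel("reads")
    ax.set_title("Length distribution after trimming")
    if len(qcs) <= 12:
        ax.legend(fontsize=7)
    path = os.path.join(plotdir, "length_distribution.png")
    fig.tight_layout(); fig.savefig(path, dpi=100); plt.close(fig)
    written.append(path)

    fig, axes = plt.subplots(1, 2, figsize=(8, 4))
    for ax_i, (hist, label) in zip(axes, ((offsets.hist5, "5' offset"), (offsets.hist3, "3' offset"))):
        ks = sorted(hist)
        ax_i.bar(ks, [hist[k] for k in ks])
        ax_i.set_xlabel(label)
        ax_i.set_ylabel("unique reads")
    fig.suptitle("IsomiR end-offset distributions")
    path = os.path.join(plotdir, "offset_distributions.png")
    fig.tight_layout(); fig.savefig(path, dpi=100); plt.close(fig)
    written.append(path)
    return written
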