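"""Plain-text run configuration.

A run is described by ``key=value`` lines (``#`` starts a comment), the
same information the :class:`RunConfig` dataclass carries. Keeping the
whole run in one small text file makes analyses reproducible and
shareable.

Required keys: ``mature``, ``hairpin``, ``samples`` (comma-separated
FASTQ paths) and ``adapter`` (protocols differ and no default is safe).
Everything else has defaults documented on the dataclass.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, fields
from typing import Dict, List, Optional


@dataclass
class RunConfig:
    mature: str
    hairpin: str
    samples: List[str]
    adapter: str
    sample_names: Optional[List[str]] = None
    smallrna: Optional[str] = None
    mrna: Optional[str] = None
    genome: Optional[str] = None  # remap genome; None disables the step
    out: str = "mirquant_run"
    species_prefix: Optional[str] = None

    # trimming / collapsing
    min_len: int = 16
    max_error_rate: float = 0.1
    min_overlap: int = 3
    discard_untrimmed: bool = False

    # reference construction
    extension: int = 4
    ref_mode: str = "per-mature"

    # alignment
    kmer: int = 8
    sense_only: bool = True
    max_mm_mirna: int = 1
    max_mm_hairpin: int = 1
    max_mm_smallrna: int = 1
    max_mm_mrna: int = 1

    # noise filter / quantification
    apply_filter: bool = True
    zero_fraction: float = 0.60
    min_mean: float = 2.0
    filter_mode: str = "OR"
    rpm_denominator: str = "mirna_mapped"  # or "all_reads"
    min_detect_count: int = 1
    plots: bool = False

    def __post_init__(self):
        if self.sample_names is None:
            self.sample_names = [
                os.path.basename(p).split(".")[0] for p in self.samples
            ]
        if len(self.sample_names) != len(self.samples):
            raise ValueError("sample_names and samples differ in length")
        if len(set(self.sample_names)) != len(self.sample_names):
            raise ValueError("sample names must be unique")
        if self.rpm_denominator not in ("mirna_mapped", "all_reads"):
            raise ValueError("rpm_denominator must be 'mirna_mapped' or 'all_reads'")
        if self.ref_mode not in ("per-mature", "per-cluster"):
            raise ValueError("ref_mode must be 'per-mature' or 'per-cluster'")

    @property
    def max_mm(self) -> Dict[str, int]:
        return {
            "miRNA": self.max_mm_mirna,
            "hairpin": self.max_mm_hairpin,
            "smallRNA": self.max_mm_smallrna,
            "mRNA": self.max_mm_mrna,
        }

    @classmethod
    def from_file(cls, path: str) -> "RunConfig":
        raw: Dict[str, str] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}: line {lineno}: expected key=value")
                key, value = line.split("=", 1)
                raw[key.strip()] = value.strip()
        return cls.from_mapping(raw)

    @classmethod
    def from_mapping(cls, raw: Dict[str, str]) -> "RunConfig":
        kwargs: dict = {}
        known = {f.name: f for f in fields(cls)}
        for key, value in raw.items():
            if key not in known:
                raise ValueError(f"unknown configuration key {key!r}")
            kwargs[key] = _coerce(key, value)
        missing = [k for k in ("mature", "hairpin", "samples", "adapter") if k not in kwargs]
        if missing:
            raise ValueError(f"missing required configuration keys: {', '.join(missing)}")
        return cls(**kwargs)

    def to_file(self, path: str) -> None:
        lines = []
        for f in fields(self):
            value = getattr(self, f.name)
            if value is None:
                continue
            if isinstance(value, list):
                value = ",".join(value)
            elif isinstance(value, bool):
                value = "true" if value else "false"
            lines.append(f"{f.name}={value}")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")


_LIST_KEYS = {"samples", "sample_names"}
_BOOL_KEYS = {"discard_untrimmed", "sense_only", "apply_filter", "plots"}
_INT_KEYS = {
    "min_len", "min_overlap", "extension", "kmer", "min_detect_count",
    "max_mm_mirna", "max_mm_hairpin", "max_mm_smallrna", "max_mm_mrna",
}
_FLOAT_KEYS = {"max_error_rate", "zero_fraction", "min_mean"}
_OPTIONAL_PATHS = {"smallrna", "mrna", "genome", "species_prefix"}


def _coerce(key: str, value: str):
    if key in _LIST_KEYS:
        return [v.strip() for v in value.split(",") if v.strip()]
    if key in _BOOL_KEYS:
        low = value.lower()
        if low not in ("true", "false", "1", "0", "yes", "no"):
            raise ValueError(f"configuration key {key}: expected boolean, got {value!r}")
        return low in ("true", "1", "yes")
    if key in _INT_KEYS:
        return int(value)
    if key in _FLOAT_KEYS:
        return float(value)
    if key in _OPTIONAL_PATHS and value.lower() in ("none", ""):
        return None
    return value
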