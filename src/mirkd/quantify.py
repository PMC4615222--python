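"""Quantification of size-selected small-RNA reads into a mature-miRNA expression table.

The stage mirrors a conventional small RNA-seq preprocessing chain —
3' adapter trimming, 18–22 nt size selection, assignment of reads to a
mature-miRNA reference, and per-million normalization — but replaces the
aligner with an exact-sequence matcher.  With 18–22 nt reads and a
mature-sequence reference, exact matching (T/U-insensitive, case-insensitive)
is a faithful and fully testable stand-in for short-read alignment; mismatch
tolerance is deliberately out of scope.

Reads that match more than one reference feature (identical mature sequences
under different ids) are split fractionally, 1/k to each of the k features,
and the matrix is kept in real numbers to avoid order-dependent assignment.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "CountMatrix",
    "ExpressionTable",
    "trim_adapter",
    "size_select",
    "count_reads",
    "normalize_per_million",
    "detect",
    "read_fastq",
    "quantify_fastq",
]

# Inclusive size-selection window of the library preparation (nt).
DEFAULT_MIN_LEN = 18
DEFAULT_MAX_LEN = 22
DEFAULT_MIN_OVERLAP = 5

NORMALIZATION_MODES = ("per_million_assigned", "per_million_total")


def _normalize_seq(seq: str) -> str:
    """Uppercase and convert RNA to DNA alphabet so T and U compare equal."""
    return seq.upper().replace("U", "T")


@dataclass
class CountMatrix:
    """Reads per (feature, sample), tied to a sample design.

    Parameters
    ----------
    counts
        feature × sample matrix of non-negative read counts.  Values may be
        fractional when multi-mapping reads were split.
    design
        One row per sample with columns ``sample_id``, ``genotype``,
        ``replicate``; sample order must match the count columns.
    total_reads
        Per-sample number of size-selected reads entering assignment
        (assigned + unassigned).  Defaults to the column sums, i.e. every
        read assigned.
    """

    counts: pd.DataFrame
    design: pd.DataFrame
    total_reads: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.total_reads is None:
            self.total_reads = self.counts.sum(axis=0)
        if (np.asarray(self.counts.values, dtype=float) < 0).any():
            raise ValueError("counts must be non-negative")
        design_ids = list(self.design["sample_id"])
        if list(self.counts.columns) != design_ids:
            raise ValueError(
                "count matrix columns must match design sample_ids in order: "
                f"{list(self.counts.columns)} vs {design_ids}"
            )
        dup = self.design.duplicated(subset=["genotype", "replicate"])
        if dup.any():
            raise ValueError("(genotype, replicate) pairs must be unique")
        assigned = self.assigned_reads
        if ((assigned - self.total_reads.loc[assigned.index]) > 1e-6).any():
            raise ValueError("assigned_reads cannot exceed total_reads")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def assigned_reads(self) -> pd.Series:
        """Per-sample sum of counts over all reference features."""
        return self.counts.sum(axis=0)

    def samples_of(self, genotype: str) -> list[str]:
        sel = self.design[self.design["genotype"] == genotype]
        return list(sel["sample_id"])

    def to_tsv(self, path: str | Path) -> None:
        out = self.counts.copy()
        out.index.name = "feature_id"
        out.to_csv(path, sep="\t")


@dataclass
class ExpressionTable:
    """Per-(feature, sample) normalized expression in reads per million."""

    values: pd.DataFrame
    design: pd.DataFrame
    normalization_mode: str = "per_million_assigned"

    def __post_init__(self) -> None:
        if self.normalization_mode not in NORMALIZATION_MODES:
            raise ValueError(f"unknown normalization mode {self.normalization_mode!r}")

    def samples_of(self, genotype: str) -> list[str]:
        sel = self.design[self.design["genotype"] == genotype]
        return list(sel["sample_id"])

    def genotype_means(self) -> pd.DataFrame:
        """Feature × genotype matrix of mean expression over replicates."""
        cols = {}
        for genotype in self.design["genotype"].unique():
            cols[genotype] = self.values[self.samples_of(genotype)].mean(axis=1)
        return pd.DataFrame(cols)

    def to_tsv(self, path: str | Path) -> None:
        out = self.values.copy()
        out.index.name = "feature_id"
        out.to_csv(path, sep="\t")


def trim_adapter(read: str, adapter: str, min_overlap: int = DEFAULT_MIN_OVERLAP) -> str:
    """Remove the 3' sequencing adapter from a read.

    The trim point is the leftmost full occurrence of the adapter; failing
    that, the longest adapter *prefix* of length >= ``min_overlap`` found at
    the read's 3' end.  Reads with no adapter evidence are returned unchanged
    (untrimmed reads are expected to fail the downstream size selection).
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    if not read:
        raise ValueError("cannot trim an empty read")
    read_n = _normalize_seq(read)
    adapter_n = _normalize_seq(adapter)
    idx = read_n.find(adapter_n)
    if idx >= 0:
        return read[:idx]
    # partial adapter hanging off the 3' end: longest prefix wins
    max_k = min(len(adapter_n) - 1, len(read_n))
    for k in range(max_k, min_overlap - 1, -1):
        if read_n.endswith(adapter_n[:k]):
            return read[: len(read) - k]
    return read


def size_select(
    reads: Iterable[str],
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> list[str]:
    """Keep reads whose length lies in [min_len, max_len], bounds inclusive."""
    if min_len > max_len:
        raise ValueError(f"min_len ({min_len}) must not exceed max_len ({max_len})")
    return [r for r in reads if min_len <= len(r) <= max_len]


def _mature_lookup(reference) -> dict[str, list[str]]:
    """Map normalized mature sequence -> feature ids sharing that sequence."""
    lookup: dict[str, list[str]] = {}
    for rec in reference:
        lookup.setdefault(_normalize_seq(rec.mature_seq), []).append(rec.feature_id)
    return lookup


def count_reads(
    reads_by_sample: Mapping[str, Sequence[str]],
    reference,
    design: pd.DataFrame | None = None,
) -> CountMatrix:
    """Assign trimmed, size-selected reads to mature reference sequences.

    A read is assigned to every feature whose mature sequence it exactly
    equals (T/U- and case-insensitive); a read matching k > 1 features
    contributes 1/k to each.  Unassigned reads count toward ``total_reads``
    only.

    Parameters
    ----------
    reads_by_sample
        sample_id -> sequence of read strings (already trimmed/size-selected).
    reference
        Iterable of records with ``feature_id`` and ``mature_seq`` attributes.
    design
        Optional sample design; defaults to one "unspecified" genotype row
        per sample.
    """
    reference = list(reference)
    if not reference:
        raise ValueError("reference must contain at least one feature")
    lookup = _mature_lookup(reference)
    feature_ids = [rec.feature_id for rec in reference]
    if len(set(feature_ids)) != len(feature_ids):
        raise ValueError("reference feature_ids must be unique")

    sample_ids = list(reads_by_sample)
    counts = pd.DataFrame(0.0, index=feature_ids, columns=sample_ids)
    totals = pd.Series(0, index=sample_ids, dtype=int)
    for sample_id, reads in reads_by_sample.items():
        totals[sample_id] = len(reads)
        tally = Counter(_normalize_seq(r) for r in reads)
        for seq, n in tally.items():
            hits = lookup.get(seq)
            if hits:
                share = n / len(hits)
                for fid in hits:
                    counts.loc[fid, sample_id] += share

    if design is None:
        design = pd.DataFrame(
            {
                "sample_id": sample_ids,
                "genotype": "unspecified",
                "replicate": range(1, len(sample_ids) + 1),
            }
        )
    return CountMatrix(counts=counts, design=design.reset_index(drop=True), total_reads=totals)


def normalize_per_million(
    counts: CountMatrix, mode: str = "per_million_assigned"
) -> ExpressionTable:
    """Scale counts to reads per million.

    ``per_million_assigned`` divides by the per-sample sum of reads assigned
    to reference features (the default: column sums then equal 1e6 exactly);
    ``per_million_total`` divides by all size-selected reads including
    unassigned ones.
    """
    if mode not in NORMALIZATION_MODES:
        raise ValueError(f"unknown normalization mode {mode!r}")
    denom = counts.assigned_reads if mode == "per_million_assigned" else counts.total_reads
    zero = denom[denom <= 0]
    if len(zero):
        raise ValueError(
            f"zero normalization denominator for sample(s): {', '.join(map(str, zero.index))}"
        )
    values = counts.counts * 1e6 / denom
    return ExpressionTable(values=values, design=counts.design, normalization_mode=mode)


def detect(counts: CountMatrix, min_reads: float = 1) -> list[str]:
    """Features with raw count strictly greater than ``min_reads`` in every sample."""
    mask = (counts.counts > min_reads).all(axis=1)
    return list(counts.counts.index[mask])


def read_fastq(path: str | Path) -> list[str]:
    """Read sequences from a plain or gzipped FASTQ file."""
    path = Path(path)
    if path.suffix == ".gz":
        import gzip

        with gzip.open(path, "rt") as fh:
            return [str(rec.seq) for rec in SeqIO.parse(fh, "fastq")]
    return [str(rec.seq) for rec in SeqIO.parse(str(path), "fastq")]


def quantify_fastq(
    fastq_by_sample: Mapping[str, str | Path | Sequence[str]],
    reference,
    adapter: str,
    design: pd.DataFrame | None = None,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> CountMatrix:
    """Full preprocessing chain: trim -> size-select -> count, per sample.

    ``fastq_by_sample`` values may be FASTQ paths or in-memory read lists.
    """
    processed: dict[str, list[str]] = {}
    for sample_id, source in fastq_by_sample.items():
        if isinstance(source, (str, Path)):
            reads = read_fastq(source)
        else:
            reads = list(source)
        trimmed = [trim_adapter(r, adapter, min_overlap) for r in reads if r]
        processed[sample_id] = size_select(trimmed, min_len, max_len)
    return count_reads(processed, reference, design=design)
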