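"""Read-level filtering, PCR-duplicate removal, coverage, and FPKM.

Read placements are aligned read intervals; they arrive either from a SAM
file (via pysam, keeping uniquely mapped reads by mapping quality) or from
a lightweight BED dialect (chrom, start, end, read_id, score, strand).
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, read_bed

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReadPlacement:
    """One aligned read: an interval plus identity and ambiguity count."""

    interval: GenomicInterval
    read_id: str = ""
    n_count: int = 0


@dataclass
class CoverageTrack:
    """Per-base read depth over a region (pooled strands by default)."""

    region: GenomicInterval
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth)
        if self.depth.shape != (len(self.region),):
            raise ValueError("depth array length must equal region length")
        if (self.depth < 0).any():
            raise ValueError("depths must be non-negative")


@dataclass
class ExpressionMatrix:
    """Gene × sample expression values with per-sample group labels."""

    values: pd.DataFrame  # index: gene_id, columns: sample_id
    groups: dict[str, str] = field(default_factory=dict)  # sample -> group

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene_ids in expression matrix")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.samples if self.groups.get(s) == group]


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def filter_reads(
    reads: Iterable[tuple[str, str]],
    max_n: int = 2,
    min_length: int = 16,
) -> list[tuple[str, str]]:
    """Keep raw reads with at most *max_n* ambiguous bases and length ≥ *min_length*.

    *reads* are ``(read_id, sequence)`` pairs; order is preserved.  Reads
    containing more than two Ns, or shorter than 16 nt, are discarded at
    the defaults.
    """
    kept = []
    for read_id, seq in reads:
        if len(seq) < min_length:
            continue
        if seq.upper().count("N") > max_n:
            continue
        kept.append((read_id, seq))
    return kept


def dedup_placements(placements: Sequence[ReadPlacement]) -> list[ReadPlacement]:
    """Remove PCR duplicates: keep the first placement per
    (chrom, start, end, strand) key."""
    seen: set[tuple[str, int, int, str]] = set()
    out = []
    for p in placements:
        key = (p.interval.chrom, p.interval.start, p.interval.end, p.interval.strand)
        if key in seen:
            continue
        seen.add(key)
        out.append(p)
    return out


# ---------------------------------------------------------------------------
# Coverage
# ---------------------------------------------------------------------------

def compute_coverage(
    placements: Iterable[ReadPlacement],
    region: GenomicInterval,
    strand: str | None = None,
) -> CoverageTrack:
    """Per-base depth over *region*; placements are clipped to the region.

    Strands are pooled unless *strand* is given, in which case only
    placements on that strand contribute.
    """
    n = len(region)
    diff = np.zeros(n + 1, dtype=np.int64)
    for p in placements:
        iv = p.interval
        if iv.chrom != region.chrom:
            continue
        if strand is not None and iv.strand != strand:
            continue
        lo = max(iv.start, region.start) - region.start
        hi = min(iv.end, region.end) - region.start
        if lo < hi:
            diff[lo] += 1
            diff[hi] -= 1
    return CoverageTrack(region, np.cumsum(diff[:-1]))


# ---------------------------------------------------------------------------
# FPKM
# ---------------------------------------------------------------------------

def fpkm(
    counts: ExpressionMatrix,
    transcript_lengths: Mapping[str, int],
    library_sizes: Mapping[str, int],
) -> ExpressionMatrix:
    """Fragments per kilobase of transcript per million mapped fragments.

    ``FPKM[g, s] = counts[g, s] * 1e9 / (length[g] * library_size[s])``.
    The per-gene length is by convention the longest annotated transcript.
    """
    missing = [g for g in counts.genes if g not in transcript_lengths]
    if missing:
        raise KeyError(f"missing transcript length for genes: {missing}")
    lengths = np.array([transcript_lengths[g] for g in counts.genes], dtype=float)
    libs = np.array([library_sizes[s] for s in counts.samples], dtype=float)
    if (lengths <= 0).any():
        raise ValueError("transcript lengths must be positive")
    if (libs <= 0).any():
        raise ValueError("library sizes must be positive")
    vals = counts.values.to_numpy(dtype=float) * 1e9 / (
        lengths[:, None] * libs[None, :]
    )
    return ExpressionMatrix(
        pd.DataFrame(vals, index=counts.values.index, columns=counts.values.columns),
        dict(counts.groups),
    )


# ---------------------------------------------------------------------------
# Placement I/O
# ---------------------------------------------------------------------------

def read_placements_bed(path: str | os.PathLike) -> list[ReadPlacement]:
    """Read placements from the BED dialect (name column = read_id)."""
    return [
        ReadPlacement(iv, read_id=name)
        for iv, name, _score in read_bed(path)
    ]


def write_placements_bed(
    placements: Sequence[ReadPlacement], path: str | os.PathLike
) -> None:
    with open(path, "w") as fh:
        for p in placements:
            iv = p.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.read_id}\t0\t{iv.strand}\n"
            )


def read_placements_sam(
    path: str | os.PathLike, min_mapq: int = 20
) -> list[ReadPlacement]:
    """Read uniquely mapped reads from a SAM/BAM file.

    "Uniquely mapped" is operationalised as mapping quality ≥ *min_mapq*;
    unmapped and secondary/supplementary records are dropped.
    """
    import pysam

    out = []
    with pysam.AlignmentFile(os.fspath(path), check_sq=False) as af:
        for rec in af:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.mapping_quality < min_mapq:
                continue
            seq = rec.query_sequence or ""
            out.append(
                ReadPlacement(
                    GenomicInterval(
                        rec.reference_name,
                        rec.reference_start,
                        rec.reference_end,
                        "-" if rec.is_reverse else "+",
                    ),
                    read_id=rec.query_name,
                    n_count=seq.upper().count("N"),
                )
            )
    return out


def read_expression_tsv(
    path: str | os.PathLike, groups: Mapping[str, str] | None = None
) -> ExpressionMatrix:
    """Read a gene × sample TSV (first column gene_id, one header row)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(df, dict(groups or {}))
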