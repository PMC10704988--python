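"""Genomic intervals, gene models, and annotation/interval file I/O.

All coordinates are 0-based, half-open ``[start, end)`` internally.  GTF
input (1-based, closed) is converted on read; BED is written natively.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

STRANDS = ("+", "-", ".")


class GTFParseError(ValueError):
    """Raised for a malformed GTF line; message names the line number."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the two intervals share at least one base.

    Half-open semantics: ``[100, 200)`` and ``[200, 300)`` do not overlap.
    Strand is ignored; different chromosomes never overlap.
    """
    return a.chrom == b.chrom and max(a.start, b.start) < min(a.end, b.end)


def gap(a: GenomicInterval, b: GenomicInterval) -> float:
    """Gap in bp between two intervals on the same chromosome.

    0 for overlapping or book-ended intervals; ``inf`` across chromosomes.
    """
    if a.chrom != b.chrom:
        return math.inf
    return max(0, max(a.start, b.start) - min(a.end, b.end))


@dataclass
class TranscriptModel:
    transcript_id: str
    exons: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for prev, nxt in zip(self.exons, self.exons[1:]):
            if nxt.start < prev.end:
                raise ValueError(
                    f"transcript {self.transcript_id}: overlapping exons"
                )

    @property
    def length(self) -> int:
        """Spliced transcript length: sum of exon lengths."""
        return sum(len(e) for e in self.exons)

    @property
    def interval(self) -> GenomicInterval:
        first, last = self.exons[0], self.exons[-1]
        return GenomicInterval(first.chrom, first.start, last.end, first.strand)


@dataclass
class GeneModel:
    gene_id: str
    interval: GenomicInterval
    biotype: str = "unknown"  # coding | noncoding | unknown
    transcripts: list[TranscriptModel] = field(default_factory=list)

    @property
    def longest_transcript_length(self) -> int:
        if not self.transcripts:
            return len(self.interval)
        return max(t.length for t in self.transcripts)


def distance_to_nearest_gene(
    t: GenomicInterval, genes: Iterable[GeneModel]
) -> float:
    """Minimum gap in bp from *t* to any gene on the same chromosome.

    0 if *t* overlaps or abuts a gene; ``inf`` if no gene shares the
    chromosome (or the gene set is empty).
    """
    best = math.inf
    for g in genes:
        d = gap(t, g.interval)
        if d < best:
            best = d
            if best == 0:
                break
    return best


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

_BIOTYPE_MAP = {
    "protein_coding": "coding",
    "coding": "coding",
    "lncRNA": "noncoding",
    "lincRNA": "noncoding",
    "noncoding": "noncoding",
}


def _parse_attributes(attr: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for chunk in attr.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if " " not in chunk:
            continue
        key, _, value = chunk.partition(" ")
        out[key] = value.strip().strip('"')
    return out


def read_gtf(path: str | os.PathLike) -> dict[str, GeneModel]:
    """Read an Ensembl-dialect GTF into gene models keyed by gene_id.

    1-based closed GTF coordinates are converted to 0-based half-open.
    Exon features are grouped per transcript_id; a gene's interval is
    taken from its ``gene`` feature line when present, otherwise from
    the span of its exons.  Records without a gene_id are skipped with
    a warning; structurally malformed lines raise :class:`GTFParseError`
    naming the line number.
    """
    gene_rows: dict[str, dict] = {}
    tx_exons: dict[str, list[GenomicInterval]] = {}
    tx_gene: dict[str, str] = {}

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GTFParseError(
                    f"line {lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attr = fields
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise GTFParseError(
                    f"line {lineno}: non-integer coordinates "
                    f"({start_s!r}, {end_s!r})"
                ) from exc
            if start1 < 1 or end1 < start1:
                raise GTFParseError(
                    f"line {lineno}: invalid coordinate range {start1}-{end1}"
                )
            attrs = _parse_attributes(attr)
            gene_id = attrs.get("gene_id")
            if not gene_id:
                logger.warning("GTF line %d: missing gene_id, skipped", lineno)
                continue
            iv = GenomicInterval(
                chrom, start1 - 1, end1, strand if strand in STRANDS else "."
            )
            if feature == "gene":
                biotype_raw = attrs.get("gene_biotype", attrs.get("gene_type", ""))
                gene_rows[gene_id] = {
                    "interval": iv,
                    "biotype": _BIOTYPE_MAP.get(biotype_raw, "unknown"),
                }
            elif feature == "exon":
                tx_id = attrs.get("transcript_id")
                if not tx_id:
                    logger.warning(
                        "GTF line %d: exon missing transcript_id, skipped", lineno
                    )
                    continue
                tx_exons.setdefault(tx_id, []).append(iv)
                tx_gene[tx_id] = gene_id

    genes: dict[str, GeneModel] = {}
    for gene_id, row in gene_rows.items():
        genes[gene_id] = GeneModel(gene_id, row["interval"], row["biotype"])
    for tx_id, exons in tx_exons.items():
        gene_id = tx_gene[tx_id]
        tx = TranscriptModel(tx_id, exons)
        if gene_id not in genes:
            # no explicit gene line: infer the gene interval from exons
            genes[gene_id] = GeneModel(gene_id, tx.interval)
        else:
            g = genes[gene_id]
            span = tx.interval
            if span.start < g.interval.start or span.end > g.interval.end:
                g.interval = GenomicInterval(
                    g.interval.chrom,
                    min(g.interval.start, span.start),
                    max(g.interval.end, span.end),
                    g.interval.strand,
                )
        genes[gene_id].transcripts.append(tx)
    return genes


# ---------------------------------------------------------------------------
# BED6
# ---------------------------------------------------------------------------

def write_bed(
    intervals: Sequence[GenomicInterval],
    path: str | os.PathLike,
    names: Sequence[str] | None = None,
    scores: Sequence[float] | None = None,
) -> None:
    """Write intervals as BED6 (0-based half-open, native convention)."""
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else f"region_{i + 1}"
            score = scores[i] if scores is not None else 0
            if isinstance(score, float) and score.is_integer():
                score = int(score)
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n"
            )


def read_bed(path: str | os.PathLike) -> list[tuple[GenomicInterval, str, float]]:
    """Read a BED file (3+ columns) into (interval, name, score) tuples."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"BED line {lineno}: fewer than 3 columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 else f"region_{lineno}"
            score = float(fields[4]) if len(fields) > 4 else 0.0
            strand = fields[5] if len(fields) > 5 and fields[5] in STRANDS else "."
            out.append((GenomicInterval(chrom, start, end, strand), name, score))
    return out
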