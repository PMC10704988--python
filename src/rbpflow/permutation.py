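"""Read-redistribution permutation null and peak screening.

The null model re-places every deduplicated read of a gene at an
independent uniform start within the gene, preserving read lengths, and
records the maximum per-base depth the gene attains under each
permutation.  Because reads are exchangeable under this null, the
empirical p-value of the observed maximum is calibrated even for regions
that were selected by the window scan (see docs/methods.md).
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np

from .intervals import GenomicInterval
from .peaks import Peak, PeakParams
from .reads import CoverageTrack, ReadPlacement

logger = logging.getLogger(__name__)


@dataclass
class NullDistribution:
    """Per-gene null maxima under read redistribution."""

    gene_id: str
    null_max_depths: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        self.null_max_depths = np.asarray(self.null_max_depths)
        if self.null_max_depths.size == 0:
            raise ValueError("null distribution must be non-empty")
        if (self.null_max_depths < 0).any():
            raise ValueError("null max depths must be non-negative")


def gene_subseed(base_seed: int, gene_id: str) -> int:
    """Stable per-gene seed: mix the base seed with a CRC of the gene id."""
    return (int(base_seed) & 0x7FFFFFFF) ^ zlib.crc32(gene_id.encode())


def _permuted_starts(
    gene: GenomicInterval,
    read_lengths: np.ndarray,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """(n, n_reads) array of uniform random start offsets within the gene."""
    glen = len(gene)
    spans = glen - read_lengths + 1
    too_long = spans < 1
    if too_long.any():
        logger.warning(
            "%d read(s) longer than gene [%s:%d-%d); placed at gene start",
            int(too_long.sum()), gene.chrom, gene.start, gene.end,
        )
        spans = np.maximum(spans, 1)
    # one uniform draw per read per permutation
    u = rng.random((n, read_lengths.shape[0]))
    return (u * spans[None, :]).astype(np.int64)


def permute_reads(
    gene: GenomicInterval,
    placements: list[ReadPlacement],
    n: int,
    seed: int,
) -> list[CoverageTrack]:
    """*n* synthetic coverage tracks with the gene's reads re-placed uniformly.

    Read lengths are preserved (clipped to the gene for reads longer than
    the gene, which are pinned to the gene start).  Deterministic given
    *seed*.
    """
    rng = np.random.default_rng(seed)
    lengths = np.array(
        [len(p.interval) for p in placements], dtype=np.int64
    )
    starts = _permuted_starts(gene, lengths, n, rng)
    glen = len(gene)
    ends = np.minimum(starts + lengths[None, :], glen)
    tracks = []
    for k in range(n):
        diff = np.zeros(glen + 1, dtype=np.int64)
        np.add.at(diff, starts[k], 1)
        np.add.at(diff, ends[k], -1)
        tracks.append(CoverageTrack(gene, np.cumsum(diff[:-1])))
    return tracks


def null_max_depths(
    gene: GenomicInterval,
    placements: list[ReadPlacement],
    n: int,
    seed: int,
) -> np.ndarray:
    """Maximum per-base depth of the gene under each of *n* permutations.

    Vectorised equivalent of taking ``max(track.depth)`` over
    :func:`permute_reads`; identical output for the same seed.
    """
    rng = np.random.default_rng(seed)
    lengths = np.array([len(p.interval) for p in placements], dtype=np.int64)
    if lengths.size == 0:
        return np.zeros(n, dtype=np.int64)
    starts = _permuted_starts(gene, lengths, n, rng)
    glen = len(gene)
    ends = np.minimum(starts + lengths[None, :], glen)
    diff = np.zeros((n, glen + 1), dtype=np.int32)
    rows = np.repeat(np.arange(n), lengths.shape[0])
    np.add.at(diff, (rows, starts.ravel()), 1)
    np.add.at(diff, (rows, ends.ravel()), -1)
    return np.cumsum(diff[:, :-1], axis=1).max(axis=1)


def build_null(
    gene_id: str,
    gene: GenomicInterval,
    placements: list[ReadPlacement],
    params: PeakParams,
    base_seed: int,
) -> NullDistribution:
    seed = gene_subseed(base_seed, gene_id)
    return NullDistribution(
        gene_id, null_max_depths(gene, placements, params.perm_n, seed), seed
    )


def empirical_pvalue(observed_max_depth: float, null: NullDistribution) -> float:
    """Add-one permutation p-value: ``(1 + #{null >= obs}) / (1 + n)``."""
    arr = null.null_max_depths
    return float((1 + int((arr >= observed_max_depth).sum())) / (1 + arr.size))


def significance_screen(peaks: list[Peak], params: PeakParams) -> list[Peak]:
    """Flag peaks significant when p < alpha OR max depth meets the floor.

    Mutates and returns *peaks*.  Setting ``params.min_max_depth`` to
    ``inf`` disables the depth disjunct (pure permutation screen).
    """
    for pk in peaks:
        p_ok = pk.empirical_p is not None and pk.empirical_p < params.perm_alpha
        d_ok = pk.max_depth >= params.min_max_depth
        pk.significant = bool(p_ok or d_ok)
    return peaks


def peak_abundance(
    peak: Peak, track: CoverageTrack, library_size: float, pseudocount: float = 1.0
) -> float:
    """Library-size-normalised mean depth within the peak, plus a pseudocount.

    Units: (mean depth + pseudocount) per million mapped reads.
    """
    region = track.region
    lo = peak.interval.start - region.start
    hi = peak.interval.end - region.start
    mean_depth = float(np.mean(track.depth[lo:hi]))
    return (mean_depth + pseudocount) * 1e6 / float(library_size)


def ip_input_screen(
    peak: Peak,
    ip_track: CoverageTrack,
    input_track: CoverageTrack | None,
    ip_libsize: float,
    input_libsize: float | None,
    params: PeakParams,
) -> Peak:
    """Fill ``ip_input_fold`` and the final pass flag on *peak*.

    Fold = IP abundance / input abundance, both per-million-normalised
    with pseudocount 1; pass requires fold > ``params.ip_input_fc`` and
    the peak to already be flagged significant.  With no input track the
    fold is undefined and the screen passes by default (input is a
    control, used when available).
    """
    if ip_libsize <= 0 or (input_libsize is not None and input_libsize <= 0):
        raise ValueError("library sizes must be positive")
    sig = bool(peak.significant) if peak.significant is not None else True
    if input_track is None:
        logger.warning(
            "peak %s: no input track; IP/input screen passed by default",
            peak.peak_id or str(peak.interval),
        )
        peak.ip_input_fold = None
        peak.passed_filters = sig
        return peak
    ip_ab = peak_abundance(peak, ip_track, ip_libsize)
    input_ab = peak_abundance(peak, input_track, input_libsize)
    peak.ip_input_fold = ip_ab / input_ab
    peak.passed_filters = sig and peak.ip_input_fold > params.ip_input_fc
    return peak
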