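"""Sliding-window peak calling on read-coverage tracks.

The caller scans a coverage track with fixed-width windows at a fixed
step.  A peak opens at the first window of a run of ``consec_windows``
windows that are each at least ``start_ratio`` times the background
baseline, or of a run whose median window depth exceeds ``median_start``.
An open peak extends window by window while tracking its running maximum
window depth, and terminates immediately before the first run of
``consec_windows`` windows that each drop below ``end_fraction`` of that
running maximum (or at the end of the track).  Peak statistics are then
recomputed at single-base resolution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .intervals import GenomicInterval
from .reads import CoverageTrack, ReadPlacement


@dataclass
class PeakParams:
    """Tunable peak-calling and screening parameters (all units in doc)."""

    window_size: int = 5          # bp
    step: int = 5                 # bp
    start_ratio: float = 2.5      # window depth / baseline to open
    consec_windows: int = 8       # run length for both start and end rules
    median_start: float = 50.0    # alternative start rule: run median depth
    end_fraction: float = 0.04    # fraction of running max to terminate
    min_max_depth: float = 10.0   # depth disjunct of the significance screen
    perm_n: int = 500             # permutations of the read-redistribution null
    perm_alpha: float = 0.05      # empirical-p cutoff
    ip_input_fc: float = 4.0      # IP/input abundance fold-change screen

    def __post_init__(self) -> None:
        for name in ("window_size", "step", "consec_windows", "perm_n"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if not 0 < self.end_fraction < 1:
            raise ValueError("end_fraction must be in (0, 1)")
        if not 0 < self.perm_alpha < 1:
            raise ValueError("perm_alpha must be in (0, 1)")
        if self.start_ratio <= 0 or self.ip_input_fc <= 0:
            raise ValueError("ratios must be positive")


@dataclass
class Peak:
    """A called binding region with its screening statistics."""

    interval: GenomicInterval
    gene_id: str | None = None
    peak_id: str = ""
    max_depth: float = 0.0
    median_depth: float = 0.0
    read_count: int = 0
    empirical_p: float | None = None
    ip_input_fold: float | None = None
    significant: bool | None = None
    passed_filters: bool = False


def window_depths(
    track: CoverageTrack, params: PeakParams
) -> list[tuple[GenomicInterval, float]]:
    """Mean depth per scan window tiling the track.

    Windows start every ``step`` bp; a trailing partial window is included
    with its actual length.  A track shorter than one window yields an
    empty list.
    """
    means = _window_means(np.asarray(track.depth, dtype=float), params)
    region = track.region
    out = []
    for i, m in enumerate(means):
        lo = region.start + i * params.step
        hi = min(lo + params.window_size, region.end)
        out.append((GenomicInterval(region.chrom, lo, hi, region.strand), float(m)))
    return out


def _window_means(depth: np.ndarray, params: PeakParams) -> np.ndarray:
    n = depth.shape[0]
    w, s = params.window_size, params.step
    if n < w:
        return np.zeros(0)
    starts = np.arange(0, n - w + 1, s)
    csum = np.concatenate(([0.0], np.cumsum(depth)))
    means = (csum[starts + w] - csum[starts]) / w
    last_end = starts[-1] + w
    if last_end < n:
        # trailing partial windows, stepped past the last full window
        tail_starts = np.arange(starts[-1] + s, n, s)
        tail = (csum[n] - csum[tail_starts]) / (n - tail_starts)
        means = np.concatenate([means, tail])
    return means


def call_peaks(
    track: CoverageTrack, baseline: float, params: PeakParams | None = None
) -> list[Peak]:
    """Run the start/extend/terminate window automaton over a track.

    *baseline* is the background depth the start rule is measured against
    (conventionally the mean per-base depth of the enclosing gene, floored
    at 1).  Returned peaks are disjoint, sorted, window-aligned, and carry
    base-resolution ``max_depth`` / ``median_depth``.
    """
    if params is None:
        params = PeakParams()
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    depth = np.asarray(track.depth, dtype=float)
    means = _window_means(depth, params)
    nw = means.shape[0]
    c = params.consec_windows
    thr = params.start_ratio * baseline

    high = means >= thr
    # run_high[i]: length of the run of consecutive high windows starting at i
    run_high = np.zeros(nw, dtype=np.int64)
    for i in range(nw - 1, -1, -1):
        if high[i]:
            run_high[i] = 1 + (run_high[i + 1] if i + 1 < nw else 0)

    peaks: list[Peak] = []
    i = 0
    while i <= nw - c:
        opened = run_high[i] >= c
        if not opened and float(np.median(means[i : i + c])) > params.median_start:
            opened = True
        if not opened:
            i += 1
            continue
        # extend: track running max window depth, close on a low run of c
        running_max = 0.0
        low_run = 0
        last_good = i
        j = i
        closed = False
        while j < nw:
            if means[j] < params.end_fraction * running_max:
                low_run += 1
                if low_run == c:
                    closed = True
                    break
            else:
                low_run = 0
                if means[j] > running_max:
                    running_max = means[j]
                last_good = j
            j += 1
        end_w = last_good if closed else nw - 1
        peaks.append(_make_peak(track, i, end_w, params))
        i = j + 1  # resume after the closing run (or past track end)
    return peaks


def _make_peak(
    track: CoverageTrack, start_w: int, end_w: int, params: PeakParams
) -> Peak:
    region = track.region
    lo = start_w * params.step
    hi = min(end_w * params.step + params.window_size, len(region))
    base = np.asarray(track.depth[lo:hi], dtype=float)
    return Peak(
        interval=GenomicInterval(
            region.chrom, region.start + lo, region.start + hi, region.strand
        ),
        max_depth=float(base.max()),
        median_depth=float(np.median(base)),
    )


def peak_stats(
    interval: GenomicInterval,
    track: CoverageTrack,
    placements: Sequence[ReadPlacement],
) -> tuple[float, float, int]:
    """(max depth, median depth, overlapping read count) within *interval*."""
    region = track.region
    if (
        interval.chrom != region.chrom
        or interval.start < region.start
        or interval.end > region.end
    ):
        raise ValueError("interval must lie within the track region")
    lo = interval.start - region.start
    hi = interval.end - region.start
    base = np.asarray(track.depth[lo:hi], dtype=float)
    count = sum(
        1
        for p in placements
        if p.interval.chrom == interval.chrom
        and max(p.interval.start, interval.start) < min(p.interval.end, interval.end)
    )
    return float(base.max()), float(np.median(base)), count


def gene_baseline(track: CoverageTrack, floor: float = 1.0) -> float:
    """Background depth for the start rule: track mean, floored at *floor*."""
    return max(float(np.mean(track.depth)), floor)
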