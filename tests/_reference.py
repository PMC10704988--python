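"""Independent straight-line reference implementations used as oracles.

Deliberately naive: explicit loops and literal transcriptions of the
scan/start/extend/terminate rules, kept separate from the library code
they are used to check.
"""

from __future__ import annotations

import statistics


def reference_window_means(depth, window, step):
    """Window means by explicit slicing, trailing partial window included."""
    n = len(depth)
    if n < window:
        return []
    means = []
    pos = 0
    while pos + window <= n:
        means.append(sum(depth[pos : pos + window]) / window)
        pos += step
    while pos < n:
        means.append(sum(depth[pos:n]) / (n - pos))
        pos += step
    return means


def reference_call_peaks(depth, baseline, window=5, step=5, ratio=2.5,
                         consec=8, median_start=50.0, end_frac=0.04):
    """The window automaton, transcribed literally.

    Returns (start_bp, end_bp, max_base_depth) tuples relative to the
    track origin.  A peak opens at the first window of a run of *consec*
    windows each >= ratio * baseline, or of a run whose median exceeds
    median_start; it extends while tracking the running max window depth
    and closes immediately before a run of *consec* windows each below
    end_frac * running max, or at the end of the track.
    """
    means = reference_window_means(depth, window, step)
    nw = len(means)
    peaks = []
    i = 0
    while i + consec <= nw:
        run = means[i : i + consec]
        open_here = all(m >= ratio * baseline for m in run) or (
            statistics.median(run) > median_start
        )
        if not open_here:
            i += 1
            continue
        running_max = 0.0
        low = 0
        last_good = i
        j = i
        hit_close = False
        while j < nw:
            if means[j] < end_frac * running_max:
                low += 1
                if low == consec:
                    hit_close = True
                    break
            else:
                low = 0
                running_max = max(running_max, means[j])
                last_good = j
            j += 1
        end_w = last_good if hit_close else nw - 1
        lo = i * step
        hi = min(end_w * step + window, len(depth))
        peaks.append((lo, hi, max(depth[lo:hi])))
        i = j + 1
    return peaks


def reference_bh(pvals):
    """Step-up BH by explicit sort / suffix minimum, order preserved."""
    n = len(pvals)
    indexed = sorted(range(n), key=lambda k: pvals[k])
    raw = [pvals[indexed[k]] * n / (k + 1) for k in range(n)]
    suffix = raw[:]
    for k in range(n - 2, -1, -1):
        suffix[k] = min(suffix[k], suffix[k + 1])
    out = [0.0] * n
    for k in range(n):
        out[indexed[k]] = min(suffix[k], 1.0)
    return out


def reference_hypergeom_upper(k, M, K, N):
    """Exact P[X >= k] for hypergeometric(M, K, N) by rational enumeration."""
    from fractions import Fraction
    from math import comb

    total = Fraction(0)
    for i in range(k, min(K, N) + 1):
        total += Fraction(comb(K, i) * comb(M - K, N - i), comb(M, N))
    return float(total)


def reference_coverage(placements, region_start, region_end):
    """Per-base depth by counting every read at every base."""
    depth = [0] * (region_end - region_start)
    for (start, end) in placements:
        for pos in range(max(start, region_start), min(end, region_end)):
            depth[pos - region_start] += 1
    return depth


def reference_pearson_p(r, n):
    """Two-sided p for Pearson r via the textbook t transform, n-2 df."""
    import math

    from scipy import stats

    if abs(r) >= 1.0:
        return 0.0
    t = r * math.sqrt(n - 2) / math.sqrt(1 - r * r)
    return 2 * stats.t.sf(abs(t), n - 2)
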