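"""Call RBP binding peaks: window scan, permutation null, IP/input screen.

Simulates a study, runs the full per-gene peak-calling chain, and scores
the final peaks against the planted truth at 50% reciprocal overlap.
"""

from rbpflow.pipeline import call_peaks_for_genes
from rbpflow.simulate import (
    SimulationConfig, score_peak_recovery, simulate_dataset,
)

cfg = SimulationConfig(seed=11)
ds = simulate_dataset(cfg)

peaks = call_peaks_for_genes(
    ds.genes, ds.ip_reads, ds.input_reads, seed=cfg.seed
)
final = [p for p in peaks if p.passed_filters]
recall, precision = score_peak_recovery(ds.manifest.peaks, final)

print(f"peaks called: {len(peaks)}   passing all screens: {len(final)}")
print(f"recall {recall:.2f}  precision {precision:.2f} "
      f"(vs {len(ds.manifest.peaks)} planted sites)")
for p in final[:3]:
    print(f"  {p.peak_id}: {p.interval.chrom}:{p.interval.start}-"
          f"{p.interval.end}  max depth {p.max_depth:.0f}  "
          f"p = {p.empirical_p:.4g}  IP/input fold {p.ip_input_fold:.2f}")
# Each final peak has an empirical p from 500 within-gene read
# redistributions and an IP-over-input abundance fold > 4.
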