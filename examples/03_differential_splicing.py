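"""Differential alternative splicing from junction counts.

Tests each event's alt/(alt+model) splicing ratio between control and
knockdown with Student's t-test under 5% FDR (Benjamini-Hochberg), then
tabulates significant events by type and direction.
"""

from rbpflow.simulate import SimulationConfig, simulate_dataset
from rbpflow.splicing import (
    ASEventRecord, classify_event_direction, differential_asevents,
    implied_p_cutoff,
)

cfg = SimulationConfig(seed=11, n_as_events=500, n_shifted_events=50,
                       n_genes=30, n_planted_peaks=0, n_lncrnas=0,
                       n_cis_pairs=0)
ds = simulate_dataset(cfg)
events = [
    ASEventRecord(
        d["event_id"], d["gene_id"], d["event_type"],
        {s: d[f"model_{s}"] for s in cfg.sample_names},
        {s: d[f"alt_{s}"] for s in cfg.sample_names},
    )
    for d in (r._asdict() for r in ds.as_events.itertuples(index=False))
]

results = differential_asevents(events, cfg.sample_groups)
sig = [r for r in results if r.significant]
truth = {d["event_id"] for d in ds.manifest.shifted_events}
print(f"events tested: {len(results)}  significant at FDR 5%: {len(sig)}")
print(f"of which planted shifts: {len(truth & {r.event_id for r in sig})} "
      f"/ {len(truth)} planted")
print(f"implied raw-p cutoff: {implied_p_cutoff(results):.2e}")
print(classify_event_direction(results))
# A positive t means the alternative isoform is used more after
# knockdown; the table mirrors the per-type direction summary a
# splicing-regulation figure would show.
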