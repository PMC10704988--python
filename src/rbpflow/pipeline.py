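"""Stage orchestration: per-gene peak calling with screens, and run-all.

These functions chain the library modules the way the full analysis runs:
dedup -> per-gene coverage -> window-scan peak calling -> read-redistribution
permutation significance -> IP/input abundance screen, then differential
expression, differential splicing, lncRNA screening, and set integration,
all on files a dataset directory provides (or that the simulator emits).
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GeneModel, GenomicInterval, read_gtf, write_bed
from .peaks import Peak, PeakParams, call_peaks, gene_baseline, peak_stats
from .permutation import (
    build_null, empirical_pvalue, ip_input_screen, significance_screen,
)
from .reads import (
    ReadPlacement, compute_coverage, dedup_placements, read_placements_bed,
)
from .integrate import deg_filter, deg_gene_set, overlap_sets
from .lncrna import (
    LncRNACandidate, cis_targets, coexpression_screen, colocated_pairs,
    filter_lncrna_candidates, write_cis_pairs_tsv,
)
from .intervals import distance_to_nearest_gene, overlaps
from .splicing import (
    classify_event_direction, differential_asevents, read_asevents_tsv,
    write_asresults_tsv,
)


class _ReadIndex:
    """Reads grouped per chromosome, sorted by start, for gene lookup."""

    def __init__(self, placements: Sequence[ReadPlacement]):
        self.by_chrom: dict[str, list[ReadPlacement]] = {}
        for p in placements:
            self.by_chrom.setdefault(p.interval.chrom, []).append(p)
        self.starts: dict[str, list[int]] = {}
        self.max_len: dict[str, int] = {}
        for c, reads in self.by_chrom.items():
            reads.sort(key=lambda p: (p.interval.start, p.interval.end, p.read_id))
            self.starts[c] = [p.interval.start for p in reads]
            self.max_len[c] = max(len(p.interval) for p in reads)

    def overlapping(self, iv: GenomicInterval) -> list[ReadPlacement]:
        reads = self.by_chrom.get(iv.chrom)
        if not reads:
            return []
        starts = self.starts[iv.chrom]
        lo = bisect.bisect_left(starts, iv.start - self.max_len[iv.chrom])
        hi = bisect.bisect_left(starts, iv.end)
        return [p for p in reads[lo:hi] if p.interval.end > iv.start]


def call_peaks_for_genes(
    genes: Mapping[str, GeneModel],
    ip_reads: Sequence[ReadPlacement],
    input_reads: Sequence[ReadPlacement] | None,
    params: PeakParams | None = None,
    seed: int = 0,
    dedup: bool = True,
) -> list[Peak]:
    """The full iRIP screening chain over every gene.

    Per gene: IP coverage, baseline (gene mean depth floored at 1),
    window-scan calling, per-gene read-redistribution null and empirical
    p-values, significance screen (p < alpha or max depth >= floor), and
    the IP/input abundance fold-change screen.  Returns all called peaks;
    final peaks are those with ``passed_filters``.
    """
    if params is None:
        params = PeakParams()
    if dedup:
        ip_reads = dedup_placements(ip_reads)
        input_reads = (
            dedup_placements(input_reads) if input_reads is not None else None
        )
    ip_index = _ReadIndex(ip_reads)
    input_index = _ReadIndex(input_reads) if input_reads is not None else None
    ip_lib = len(ip_reads)
    input_lib = len(input_reads) if input_reads is not None else None

    all_peaks: list[Peak] = []
    for gene_id in sorted(genes):
        gene = genes[gene_id]
        g_ip = ip_index.overlapping(gene.interval)
        if not g_ip:
            continue
        track = compute_coverage(g_ip, gene.interval)
        baseline = gene_baseline(track)
        peaks = call_peaks(track, baseline, params)
        if not peaks:
            continue
        null = build_null(gene_id, gene.interval, g_ip, params, seed)
        input_track = None
        if input_index is not None:
            input_track = compute_coverage(
                input_index.overlapping(gene.interval), gene.interval
            )
        for k, pk in enumerate(peaks):
            pk.gene_id = gene_id
            pk.peak_id = f"{gene_id}_pk{k + 1}"
            _, _, pk.read_count = peak_stats(pk.interval, track, g_ip)
            pk.empirical_p = empirical_pvalue(pk.max_depth, null)
        significance_screen(peaks, params)
        for pk in peaks:
            ip_input_screen(pk, track, input_track, ip_lib, input_lib, params)
        all_peaks.extend(peaks)
    return all_peaks


def peaks_to_dataframe(peaks: Sequence[Peak]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "peak_id": p.peak_id,
                "gene_id": p.gene_id,
                "chrom": p.interval.chrom,
                "start": p.interval.start,
                "end": p.interval.end,
                "strand": p.interval.strand,
                "max_depth": p.max_depth,
                "median_depth": p.median_depth,
                "read_count": p.read_count,
                "empirical_p": p.empirical_p,
                "ip_input_fold": p.ip_input_fold,
                "significant": p.significant,
                "final_pass": p.passed_filters,
            }
            for p in peaks
        ],
        columns=[
            "peak_id", "gene_id", "chrom", "start", "end", "strand",
            "max_depth", "median_depth", "read_count", "empirical_p",
            "ip_input_fold", "significant", "final_pass",
        ],
    )


def write_peaks(peaks: Sequence[Peak], outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    df = peaks_to_dataframe(peaks)
    df.to_csv(outdir / "peaks.tsv", sep="\t", index=False)
    final = [p for p in peaks if p.passed_filters]
    write_bed(
        [p.interval for p in final],
        outdir / "final_peaks.bed",
        names=[p.peak_id for p in final],
        scores=[p.max_depth for p in final],
    )


def lncrna_candidates_from_table(
    table: pd.DataFrame,
    votes: Mapping[str, Mapping[str, bool]],
    genes: Mapping[str, GeneModel],
) -> list[LncRNACandidate]:
    """Assemble candidates: fill overlap/nearest-gene fields from annotation."""
    coding = [g for g in genes.values() if g.biotype in ("coding", "unknown")]
    out = []
    for row in table.itertuples(index=False):
        iv = GenomicInterval(row.chrom, int(row.start), int(row.end), row.strand)
        out.append(
            LncRNACandidate(
                transcript_id=str(row.transcript_id),
                interval=iv,
                length=int(row.length),
                noncoding_votes=dict(votes.get(str(row.transcript_id), {})),
                overlaps_coding=any(overlaps(iv, g.interval) for g in coding),
                nearest_gene_distance=distance_to_nearest_gene(
                    iv, genes.values()
                ),
            )
        )
    return out


@dataclass
class RunResult:
    outdir: Path
    peaks: list[Peak] = field(default_factory=list)
    deg_table: pd.DataFrame | None = None
    as_results: list = field(default_factory=list)
    cis_pairs: list = field(default_factory=list)
    gene_sets: dict[str, set[str]] = field(default_factory=dict)


def run_all(config, outdir: str | Path, params: PeakParams | None = None) -> RunResult:
    """One-shot end-to-end run on a freshly simulated dataset.

    Simulates every input, then runs peak calling + screens, differential
    expression (DESeq2-style via pydeseq2) + DEG filter, differential
    splicing, the lncRNA credibility and cis-target screens, and the
    DEG/RASG/peak-gene overlap integration.  Every stage writes its table
    under *outdir*; all randomness derives from ``config.seed``.
    """
    from .diffexpr import differential_expression
    from .simulate import simulate_dataset, write_dataset

    outdir = Path(outdir)
    params = params or PeakParams()
    ds = simulate_dataset(config)
    write_dataset(ds, outdir / "dataset")
    res = RunResult(outdir)

    # iRIP peak calling
    res.peaks = call_peaks_for_genes(
        ds.genes, ds.ip_reads, ds.input_reads, params, seed=config.seed
    )
    write_peaks(res.peaks, outdir / "peaks")
    peak_genes = {
        p.gene_id for p in res.peaks if p.passed_filters and p.gene_id
    }

    # differential expression + DEG filter
    res.deg_table = differential_expression(ds.counts)
    res.deg_table.to_csv(outdir / "deg_table.tsv", sep="\t", index=False)
    degs = deg_filter(res.deg_table)
    deg_set = deg_gene_set(degs)
    pd.DataFrame(
        [d.__dict__ for d in degs if d.direction != "none"]
    ).to_csv(outdir / "deg_filtered.tsv", sep="\t", index=False)

    # differential splicing
    events = read_asevents_tsv(outdir / "dataset" / "as_events.tsv")
    res.as_results = differential_asevents(events, ds.config.sample_groups)
    write_asresults_tsv(res.as_results, outdir / "as_results.tsv")
    classify_event_direction(res.as_results).rename_axis("event_type").to_csv(
        outdir / "as_direction_counts.tsv", sep="\t"
    )
    rasg = {r.gene_id for r in res.as_results if r.significant}

    # lncRNA credibility + cis targets
    cands = lncrna_candidates_from_table(ds.lncrna_table, ds.votes, ds.genes)
    credible = filter_lncrna_candidates(cands)
    coloc = colocated_pairs(credible, list(ds.genes.values()))
    coexp = coexpression_screen(coloc, ds.fpkm)
    res.cis_pairs = cis_targets(coloc, coexp)
    write_cis_pairs_tsv(res.cis_pairs, outdir / "cis_pairs.tsv")

    # integration (the Venn analyses)
    res.gene_sets = {"DEG": deg_set, "RASG": rasg, "peak": peak_genes}
    inter, regions = overlap_sets(res.gene_sets)
    report = pd.DataFrame(
        [
            {"sets": "&".join(combo), "count": len(members),
             "members": ",".join(sorted(members))}
            for combo, members in sorted(inter.items())
        ]
    )
    report.to_csv(outdir / "overlap_report.tsv", sep="\t", index=False)
    return res
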