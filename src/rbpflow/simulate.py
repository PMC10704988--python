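"""Synthetic dataset generator with a machine-readable ground-truth manifest.

Generates every input the pipeline consumes — annotation (GTF), IP/input
read placements (BED dialect, optionally SAM), replicate count/FPKM
matrices, junction-count tables for splicing events, lncRNA candidate
transcripts with four-predictor coding-potential votes — together with
the planted truth (peak intervals, DEG folds, shifted events, cis pairs,
duplicate read ids), so every stage can be scored against known answers.

The defaults emulate the study design the pipeline targets: three
biological replicates per condition, 150-bp reads, ~2x per-base
background coverage in the IP/input libraries, 8-fold read concentration
inside planted binding sites, 4-fold planted expression changes, and a
0.3 splicing-ratio shift in regulated events.  Binding sites are placed
in the distal (3') portion of genes, as is typical of many RBPs.
Everything is deterministic given (config, seed).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, GeneModel, TranscriptModel
from .reads import ExpressionMatrix, ReadPlacement, fpkm
from .splicing import EVENT_TYPES, CONTROL, KNOCKDOWN


@dataclass
class SimulationConfig:
    seed: int = 0
    n_chroms: int = 2
    n_genes: int = 60
    gene_length_range: tuple[int, int] = (8_000, 12_000)
    # iRIP reads
    n_planted_peaks: int = 20
    peak_length: int = 1_000            # bp, window-aligned
    peak_enrichment: float = 8.0        # IP read concentration multiplier
    background_reads_per_kb: float = 80.0
    read_length: int = 150              # PE150-style read span
    duplicate_fraction: float = 0.05    # planted PCR duplicates
    # expression
    n_replicates_per_group: int = 3
    n_deg_up: int = 5
    n_deg_down: int = 5
    deg_fold: float = 4.0
    dispersion: float = 0.05            # NB dispersion alpha
    # splicing
    n_as_events: int = 200
    n_shifted_events: int = 20
    ratio_shift: float = 0.3
    junction_depth: int = 100
    # lncRNA / cis
    n_lncrnas: int = 10
    n_cis_pairs: int = 5
    cis_correlation: float = 0.9

    def __post_init__(self) -> None:
        for name in (
            "n_chroms", "n_genes", "n_planted_peaks", "n_deg_up", "n_deg_down",
            "n_as_events", "n_shifted_events", "n_lncrnas", "n_cis_pairs",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.background_reads_per_kb <= 0:
            raise ValueError("background_reads_per_kb must be positive")
        if self.n_planted_peaks > self.n_genes:
            raise ValueError("cannot plant more peaks than genes")
        if self.n_shifted_events > self.n_as_events:
            raise ValueError("n_shifted_events must be <= n_as_events")
        if self.n_cis_pairs > min(self.n_lncrnas, self.n_genes):
            raise ValueError("n_cis_pairs exceeds available lncRNAs/genes")
        if self.n_deg_up + self.n_deg_down + self.n_cis_pairs > self.n_genes:
            raise ValueError(
                "n_deg_up + n_deg_down + n_cis_pairs must not exceed n_genes "
                "(DEGs and cis partner genes are disjoint)"
            )
        if not 0 <= self.ratio_shift <= 0.85:
            # base ratios are drawn in [0.1, 0.6]; the shift must keep
            # knockdown ratios within [0, 1]
            raise ValueError("ratio_shift must keep ratios in [0, 1]")

    @classmethod
    def for_n_genes(cls, seed: int, n_genes: int, **overrides) -> "SimulationConfig":
        """Defaults with the planted structure scaled to a gene count."""
        f = n_genes / cls.n_genes
        scaled = {
            "n_planted_peaks": int(cls.n_planted_peaks * f),
            "n_deg_up": int(cls.n_deg_up * f),
            "n_deg_down": int(cls.n_deg_down * f),
            "n_lncrnas": max(int(cls.n_lncrnas * f), 1) if n_genes else 0,
            "n_cis_pairs": int(cls.n_cis_pairs * f),
        }
        scaled.update(overrides)
        return cls(seed=seed, n_genes=n_genes, **scaled)

    @property
    def sample_names(self) -> list[str]:
        r = self.n_replicates_per_group
        return [f"ctrl_{i+1}" for i in range(r)] + [f"kd_{i+1}" for i in range(r)]

    @property
    def sample_groups(self) -> dict[str, str]:
        r = self.n_replicates_per_group
        g = {f"ctrl_{i+1}": CONTROL for i in range(r)}
        g.update({f"kd_{i+1}": KNOCKDOWN for i in range(r)})
        return g


@dataclass
class TruthManifest:
    """Planted ground truth: what a perfect analysis should recover."""

    peaks: list[dict] = field(default_factory=list)        # gene_id, chrom, start, end
    degs: list[dict] = field(default_factory=list)         # gene_id, direction, fold
    shifted_events: list[dict] = field(default_factory=list)  # event_id, delta, direction
    cis_pairs: list[dict] = field(default_factory=list)    # lncrna_id, gene_id
    duplicate_read_ids: list[str] = field(default_factory=list)
    credible_lncrnas: list[str] = field(default_factory=list)


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    genes: dict[str, GeneModel]
    lncrna_table: pd.DataFrame          # transcript_id, chrom, start, end, strand, length
    votes: dict[str, dict[str, bool]]   # transcript -> predictor -> noncoding?
    ip_reads: list[ReadPlacement]
    input_reads: list[ReadPlacement]
    counts: ExpressionMatrix
    fpkm: ExpressionMatrix
    as_events: pd.DataFrame
    manifest: TruthManifest


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def simulate_annotation(
    config: SimulationConfig,
) -> tuple[dict[str, GeneModel], TruthManifest]:
    """Place non-overlapping genes on synthetic chromosomes.

    Inter-gene gaps are drawn from a mixture spanning both sides of the
    1-kb nearest-gene and 100-kb co-location thresholds so the positional
    screens are exercised by construction.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    genes: dict[str, GeneModel] = {}
    manifest = TruthManifest()
    if config.n_genes == 0:
        return genes, manifest
    chrom_of = np.sort(rng.integers(0, config.n_chroms, config.n_genes))
    lo, hi = config.gene_length_range
    pos = {c: 10_000 for c in range(config.n_chroms)}
    for i in range(config.n_genes):
        c = int(chrom_of[i])
        chrom = f"chrS{c + 1}"
        length = int(rng.integers(lo, hi + 1))
        u = rng.random()
        if u < 0.1:
            gap = int(rng.integers(200, 900))
        elif u < 0.85:
            gap = int(rng.integers(5_000, 50_000))
        else:
            gap = int(rng.integers(110_000, 200_000))
        start = pos[c] + gap
        end = start + length
        pos[c] = end
        strand = "+" if rng.random() < 0.5 else "-"
        gene_id = f"gene_{i + 1:04d}"
        iv = GenomicInterval(chrom, start, end, strand)
        gene = GeneModel(gene_id, iv, biotype="coding")
        # 1-2 transcripts, 1-3 exons each, exons tiled inside the gene
        n_tx = int(rng.integers(1, 3))
        for t in range(n_tx):
            n_ex = int(rng.integers(1, 4))
            cuts = np.sort(rng.choice(np.arange(1, length), 2 * n_ex - 2, replace=False)) if n_ex > 1 else np.array([], dtype=int)
            bounds = np.concatenate(([0], cuts, [length]))
            exons = [
                GenomicInterval(chrom, start + int(bounds[2 * k]), start + int(bounds[2 * k + 1]), strand)
                for k in range(n_ex)
            ]
            gene.transcripts.append(TranscriptModel(f"{gene_id}.t{t + 1}", exons))
        genes[gene_id] = gene
    return genes, manifest


def write_gtf(genes: dict[str, GeneModel], path: str | os.PathLike) -> None:
    """Emit the annotation as Ensembl-dialect GTF (1-based, closed)."""
    with open(path, "w") as fh:
        for gene_id in sorted(genes):
            g = genes[gene_id]
            iv = g.interval
            biotype = {"coding": "protein_coding", "noncoding": "lncRNA"}.get(
                g.biotype, "misc_RNA"
            )
            attrs = f'gene_id "{gene_id}"; gene_biotype "{biotype}";'
            fh.write(
                f"{iv.chrom}\tsim\tgene\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t{attrs}\n"
            )
            for tx in g.transcripts:
                tattrs = f'gene_id "{gene_id}"; transcript_id "{tx.transcript_id}";'
                tiv = tx.interval
                fh.write(
                    f"{iv.chrom}\tsim\ttranscript\t{tiv.start + 1}\t{tiv.end}\t.\t{iv.strand}\t.\t{tattrs}\n"
                )
                for ex in tx.exons:
                    fh.write(
                        f"{iv.chrom}\tsim\texon\t{ex.start + 1}\t{ex.end}\t.\t{iv.strand}\t.\t{tattrs}\n"
                    )


# ---------------------------------------------------------------------------
# iRIP reads
# ---------------------------------------------------------------------------

def _uniform_reads(
    rng: np.random.Generator,
    gene: GenomicInterval,
    n: int,
    read_length: int,
    prefix: str,
) -> list[ReadPlacement]:
    span = max(len(gene) - read_length, 0)
    starts = gene.start + rng.integers(0, span + 1, n)
    # sequencing libraries here are unstranded: reads land on either strand,
    # and adapter trimming leaves a spread of read lengths
    strands = rng.integers(0, 2, n)
    lengths = read_length - rng.integers(0, min(11, read_length), n)
    return [
        ReadPlacement(
            GenomicInterval(
                gene.chrom, int(s), int(s) + min(int(ln), len(gene)),
                "+" if st == 0 else "-",
            ),
            read_id=f"{prefix}_{i + 1:06d}",
        )
        for i, (s, st, ln) in enumerate(zip(starts, strands, lengths))
    ]


def simulate_rip_reads(
    config: SimulationConfig, genes: dict[str, GeneModel], manifest: TruthManifest
) -> tuple[list[ReadPlacement], list[ReadPlacement]]:
    """IP and input read placements with planted binding sites.

    Input reads are uniform within each gene at ``background_reads_per_kb``;
    IP reads share that background and add ``(enrichment - 1)``-fold extra
    reads concentrated inside each planted peak, so the expected IP/input
    depth ratio inside a peak equals ``peak_enrichment``.  Peaks are
    window-aligned, ``peak_length`` bp long, and sit in the distal portion
    of the gene (right margin 0.2-0.7 peak lengths).  A configurable
    fraction of planted exact-duplicate reads emulates PCR duplication.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    gene_ids = sorted(genes)
    peak_gene_ids = list(
        rng.choice(gene_ids, size=config.n_planted_peaks, replace=False)
    ) if config.n_planted_peaks else []
    ip_reads: list[ReadPlacement] = []
    input_reads: list[ReadPlacement] = []
    bg_per_gene = {
        g: config.background_reads_per_kb * len(genes[g].interval) / 1000
        for g in gene_ids
    }
    for g in gene_ids:
        iv = genes[g].interval
        n_in = int(rng.poisson(bg_per_gene[g]))
        input_reads.extend(
            _uniform_reads(rng, iv, n_in, config.read_length, f"in_{g}")
        )
        n_ip_bg = int(rng.poisson(bg_per_gene[g]))
        ip_reads.extend(
            _uniform_reads(rng, iv, n_ip_bg, config.read_length, f"ip_{g}")
        )
        if g in peak_gene_ids:
            plen = (config.peak_length // 5) * 5
            margin = int(rng.integers(int(0.15 * plen), int(0.3 * plen)))
            margin = (margin // 5) * 5
            pk_end = iv.end - margin
            pk_start = pk_end - plen
            pk_start = iv.start + ((pk_start - iv.start) // 5) * 5
            pk_end = pk_start + plen
            peak_iv = GenomicInterval(iv.chrom, pk_start, pk_end, iv.strand)
            bg_depth = config.background_reads_per_kb * config.read_length / 1000
            n_extra = int(
                rng.poisson(
                    (config.peak_enrichment - 1) * bg_depth * plen / config.read_length
                )
            )
            starts = pk_start + rng.integers(
                0, max(plen - config.read_length, 0) + 1, n_extra
            )
            pk_strands = rng.integers(0, 2, n_extra)
            pk_lengths = config.read_length - rng.integers(
                0, min(11, config.read_length), n_extra
            )
            ip_reads.extend(
                ReadPlacement(
                    GenomicInterval(
                        iv.chrom, int(s), int(s) + int(ln),
                        "+" if st == 0 else "-",
                    ),
                    read_id=f"pk_{g}_{i + 1:05d}",
                )
                for i, (s, st, ln) in enumerate(zip(starts, pk_strands, pk_lengths))
            )
            manifest.peaks.append(
                {"gene_id": g, "chrom": iv.chrom, "start": pk_start, "end": pk_end}
            )
    # planted PCR duplicates: exact copies of existing reads
    for reads, tag in ((ip_reads, "ip"), (input_reads, "in")):
        n_dup = int(config.duplicate_fraction * len(reads))
        if n_dup:
            idx = rng.choice(len(reads), size=n_dup, replace=False)
            for k, i in enumerate(sorted(idx)):
                src = reads[i]
                dup = ReadPlacement(src.interval, read_id=f"dup_{tag}_{k + 1:06d}")
                reads.append(dup)
                manifest.duplicate_read_ids.append(dup.read_id)
    return ip_reads, input_reads


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """Negative-binomial counts with mean mu and dispersion alpha."""
    mu = np.maximum(np.asarray(mu, dtype=float), 1e-8)
    if alpha <= 0:
        return rng.poisson(mu)
    size = 1.0 / alpha
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


def _latent_sd_for_corr(r: float, noise_logvar: float) -> float:
    """Shared log-normal latent SD giving linear-scale Pearson corr ~ r.

    For two jointly log-normal variables sharing a latent log-variance
    tau^2 with independent log-noise s^2 each, the linear correlation is
    (e^{tau^2}-1)/(e^{tau^2+s^2}-1); inverted here for tau.
    """
    s2 = noise_logvar
    denom = 1.0 - r * np.exp(s2)
    if denom <= 0:  # target not attainable at this noise level: saturate
        return 3.0 * np.sqrt(s2)
    tau2 = np.log((1.0 - r) / denom)
    return float(np.sqrt(max(tau2, 0.0)))


def simulate_expression(
    config: SimulationConfig,
    genes: dict[str, GeneModel],
    lncrna_table: pd.DataFrame,
    manifest: TruthManifest,
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Replicate NB counts with planted fold changes and cis correlations.

    Planted DEGs have the knockdown mean multiplied (up) or divided
    (down) by ``deg_fold``.  Each planted cis pair (lncRNA, nearby gene)
    shares a per-sample log-normal latent factor scaled so the Pearson
    correlation of the pair across samples is approximately
    ``cis_correlation``; all other genes fluctuate independently.
    Returns (counts, FPKM).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    gene_ids = sorted(genes)
    lnc_ids = list(lncrna_table["transcript_id"])
    all_ids = gene_ids + lnc_ids
    samples = config.sample_names
    r = config.n_replicates_per_group
    base = rng.lognormal(mean=5.0, sigma=0.8, size=len(all_ids))

    # planted DEGs among genes not used as cis partners
    cis_partner_genes = [d["gene_id"] for d in manifest.cis_pairs]
    eligible = [g for g in gene_ids if g not in cis_partner_genes]
    deg_pick = list(
        rng.choice(eligible, size=config.n_deg_up + config.n_deg_down, replace=False)
    ) if config.n_deg_up + config.n_deg_down else []
    up_set = set(deg_pick[: config.n_deg_up])
    down_set = set(deg_pick[config.n_deg_up:])
    for g in deg_pick:
        manifest.degs.append(
            {
                "gene_id": g,
                "direction": "up" if g in up_set else "down",
                "fold": config.deg_fold if g in up_set else 1.0 / config.deg_fold,
            }
        )

    mean_mu = float(np.exp(5.0 + 0.32))  # E[lognormal(5, 0.8)]
    noise_logvar = config.dispersion + 1.0 / mean_mu
    tau = _latent_sd_for_corr(config.cis_correlation, noise_logvar)
    # per-sample latent factor per cis pair, mean-one log-normal
    pair_of: dict[str, int] = {}
    for k, d in enumerate(manifest.cis_pairs):
        pair_of[d["lncrna_id"]] = k
        pair_of[d["gene_id"]] = k
    factors = np.exp(
        tau * rng.standard_normal((len(manifest.cis_pairs), len(samples)))
        - tau * tau / 2
    ) if manifest.cis_pairs else np.zeros((0, len(samples)))

    counts = np.zeros((len(all_ids), len(samples)), dtype=np.int64)
    for i, gid in enumerate(all_ids):
        mu = np.full(len(samples), base[i])
        if gid in up_set:
            mu[r:] *= config.deg_fold
        elif gid in down_set:
            mu[r:] /= config.deg_fold
        if gid in pair_of:
            mu = mu * factors[pair_of[gid]]
        counts[i] = _nb_draw(rng, mu, config.dispersion)

    cdf = pd.DataFrame(counts, index=all_ids, columns=samples)
    counts_em = ExpressionMatrix(cdf, config.sample_groups)
    lengths = {g: genes[g].longest_transcript_length for g in gene_ids}
    lengths.update(
        dict(zip(lncrna_table["transcript_id"], lncrna_table["length"]))
    )
    libs = {s: int(cdf[s].sum()) for s in samples}
    fpkm_em = fpkm(counts_em, lengths, libs)
    return counts_em, fpkm_em


# ---------------------------------------------------------------------------
# Splicing events
# ---------------------------------------------------------------------------

def simulate_asevents(
    config: SimulationConfig, genes: dict[str, GeneModel], manifest: TruthManifest
) -> pd.DataFrame:
    """Binomial junction counts with a planted ratio shift in knockdown.

    Per event and sample, alt ~ Binomial(junction_depth, ratio) and
    model = junction_depth - alt.  Null events share one base ratio in
    both groups; shifted events add ``ratio_shift`` (alternating sign
    direction where the base ratio allows) in the knockdown group.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 4]))
    gene_ids = sorted(genes) or ["gene_none"]
    samples = config.sample_names
    r = config.n_replicates_per_group
    rows = []
    shifted = set(range(config.n_shifted_events))
    for e in range(config.n_as_events):
        event_id = f"ase_{e + 1:05d}"
        gene_id = str(rng.choice(gene_ids))
        etype = str(rng.choice(EVENT_TYPES))
        base_ratio = float(rng.uniform(0.1, 0.6))
        kd_ratio = base_ratio
        if e in shifted:
            sign = 1 if (e % 2 == 0 or base_ratio - config.ratio_shift < 0) else -1
            kd_ratio = base_ratio + sign * config.ratio_shift
            kd_ratio = min(max(kd_ratio, 0.0), 1.0)
            manifest.shifted_events.append(
                {
                    "event_id": event_id,
                    "delta": kd_ratio - base_ratio,
                    "direction": "increased" if kd_ratio > base_ratio else "decreased",
                    "event_type": etype,
                }
            )
        row: dict = {"event_id": event_id, "gene_id": gene_id, "event_type": etype}
        for j, s in enumerate(samples):
            ratio = kd_ratio if j >= r else base_ratio
            alt = int(rng.binomial(config.junction_depth, ratio)) if config.junction_depth else 0
            row[f"model_{s}"] = config.junction_depth - alt
            row[f"alt_{s}"] = alt
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# lncRNA candidates
# ---------------------------------------------------------------------------

def simulate_lncrnas(
    config: SimulationConfig, genes: dict[str, GeneModel], manifest: TruthManifest
) -> tuple[pd.DataFrame, dict[str, dict[str, bool]]]:
    """Candidate lncRNA transcripts with coding-potential votes.

    ``n_lncrnas`` credible lncRNAs are placed >= 1 kb from any gene, the
    first ``n_cis_pairs`` of them within 100 kb of a partner gene (the
    planted cis pairs); the rest far beyond the co-location window.
    Four decoys exercise each removal rule: short, coding-vote,
    gene-overlapping, and too close to a gene.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 5]))
    from .lncrna import PREDICTORS

    rows, votes = [], {}
    gene_ids = sorted(genes)
    chrom_max: dict[str, int] = {}
    for g in genes.values():
        chrom_max[g.interval.chrom] = max(
            chrom_max.get(g.interval.chrom, 0), g.interval.end
        )

    def add(tid, chrom, start, end, strand, noncoding=True, miss=None):
        rows.append(
            {
                "transcript_id": tid, "chrom": chrom, "start": start,
                "end": end, "strand": strand, "length": end - start,
            }
        )
        votes[tid] = {p: noncoding for p in PREDICTORS}
        if miss:
            votes[tid][miss] = False

    by_chrom: dict[str, list[GenomicInterval]] = {}
    for g in genes.values():
        by_chrom.setdefault(g.interval.chrom, []).append(g.interval)
    for c in by_chrom:
        by_chrom[c].sort(key=lambda iv: iv.start)

    def place_near(partner: GenomicInterval, length: int) -> int | None:
        """Start for an interval >= 1 kb from every gene, <= 100 kb from
        the partner's 3' end (first fitting inter-gene gap)."""
        ivs = by_chrom[partner.chrom]
        idx = ivs.index(partner)
        nxt = ivs[idx + 1].start if idx + 1 < len(ivs) else partner.end + 10**7
        lo, hi = partner.end + 1_000, nxt - 1_000 - length
        hi = min(hi, partner.end + 100_000 - length)
        if hi >= lo:
            return int(rng.integers(lo, hi + 1))
        prev_end = ivs[idx - 1].end if idx > 0 else 0
        lo2 = max(prev_end + 1_000, partner.start - 100_000)
        hi2 = partner.start - 1_000 - length
        if hi2 >= lo2:
            return int(rng.integers(lo2, hi2 + 1))
        return None

    partner_pool = list(rng.permutation(gene_ids)) if config.n_cis_pairs else []
    n_paired = 0
    for k in range(config.n_lncrnas):
        tid = f"lnc_{k + 1:03d}"
        length = int(rng.integers(400, 2_000))
        start = None
        if n_paired < config.n_cis_pairs:
            while partner_pool and start is None:
                partner = genes[partner_pool.pop()]
                start = place_near(partner.interval, length)
            if start is not None:
                chrom = partner.interval.chrom
                manifest.cis_pairs.append(
                    {"lncrna_id": tid, "gene_id": partner.gene_id}
                )
                n_paired += 1
        if start is None:
            chrom = sorted(chrom_max)[0] if chrom_max else "chrS1"
            start = chrom_max.get(chrom, 0) + 300_000 + 250_000 * k
        add(tid, chrom, start, start + length, "+" if rng.random() < 0.5 else "-")
        manifest.credible_lncrnas.append(tid)
        chrom_max[chrom] = max(chrom_max.get(chrom, 0), start + length)
    # decoys, one per removal rule
    far = (chrom_max.get("chrS1", 0) if chrom_max else 0) + 500_000
    add("decoy_short", "chrS1", far, far + 150, "+")
    add("decoy_coding_vote", "chrS1", far + 10_000, far + 10_800, "+",
        miss="CPAT")
    if gene_ids:
        g0 = genes[gene_ids[0]].interval
        add("decoy_overlap", g0.chrom, g0.start + 10, g0.start + 700, "+")
        add("decoy_near_gene", g0.chrom, g0.end + 400, g0.end + 900, "+")
    return pd.DataFrame(rows), votes


# ---------------------------------------------------------------------------
# Dataset assembly and emission
# ---------------------------------------------------------------------------

def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate the full synthetic study (all stages' inputs + truth)."""
    genes, manifest = simulate_annotation(config)
    ip_reads, input_reads = simulate_rip_reads(config, genes, manifest)
    lnc_table, votes = simulate_lncrnas(config, genes, manifest)
    counts, fpkm_m = simulate_expression(config, genes, lnc_table, manifest)
    as_events = simulate_asevents(config, genes, manifest)
    return SyntheticDataset(
        config, genes, lnc_table, votes, ip_reads, input_reads,
        counts, fpkm_m, as_events, manifest,
    )


def self_check(ds: SyntheticDataset) -> None:
    """Validate manifest/file cross-references; raise on any dangling id."""
    gene_ids = set(ds.genes)
    for d in ds.manifest.peaks:
        if d["gene_id"] not in gene_ids:
            raise AssertionError(f"manifest peak gene {d['gene_id']} missing")
    expr_ids = set(ds.counts.values.index)
    for d in ds.manifest.degs:
        if d["gene_id"] not in expr_ids:
            raise AssertionError(f"manifest DEG {d['gene_id']} missing")
    event_ids = set(ds.as_events["event_id"])
    for d in ds.manifest.shifted_events:
        if d["event_id"] not in event_ids:
            raise AssertionError(f"manifest event {d['event_id']} missing")
    lnc_ids = set(ds.lncrna_table["transcript_id"])
    for d in ds.manifest.cis_pairs:
        if d["lncrna_id"] not in lnc_ids or d["gene_id"] not in gene_ids:
            raise AssertionError("manifest cis pair member missing")
        if d["lncrna_id"] not in expr_ids or d["gene_id"] not in expr_ids:
            raise AssertionError("manifest cis pair member not in expression")
    read_ids = {p.read_id for p in ds.ip_reads} | {p.read_id for p in ds.input_reads}
    for rid in ds.manifest.duplicate_read_ids:
        if rid not in read_ids:
            raise AssertionError(f"manifest duplicate read {rid} missing")


def write_dataset(ds: SyntheticDataset, outdir: str | os.PathLike) -> dict[str, Path]:
    """Emit every input file plus the truth manifest as plain text."""
    from .reads import write_placements_bed
    import yaml

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "gtf": out / "annotation.gtf",
        "ip_bed": out / "ip_reads.bed",
        "input_bed": out / "input_reads.bed",
        "counts": out / "counts.tsv",
        "fpkm": out / "fpkm.tsv",
        "as_events": out / "as_events.tsv",
        "lncrna": out / "lncrna_candidates.tsv",
        "votes": out / "predictor_votes.tsv",
        "run_info": out / "run_info.yaml",
    }
    write_gtf(ds.genes, paths["gtf"])
    write_placements_bed(ds.ip_reads, paths["ip_bed"])
    write_placements_bed(ds.input_reads, paths["input_bed"])
    ds.counts.values.rename_axis("gene_id").to_csv(paths["counts"], sep="\t")
    ds.fpkm.values.rename_axis("gene_id").to_csv(paths["fpkm"], sep="\t")
    ds.as_events.to_csv(paths["as_events"], sep="\t", index=False)
    ds.lncrna_table.to_csv(paths["lncrna"], sep="\t", index=False)
    vrows = [
        {"transcript_id": t, **{p.lower(): ("noncoding" if v else "coding")
                                for p, v in d.items()}}
        for t, d in ds.votes.items()
    ]
    pd.DataFrame(vrows).to_csv(paths["votes"], sep="\t", index=False)
    for name, records in (
        ("manifest_peaks", ds.manifest.peaks),
        ("manifest_degs", ds.manifest.degs),
        ("manifest_shifted_events", ds.manifest.shifted_events),
        ("manifest_cis_pairs", ds.manifest.cis_pairs),
    ):
        p = out / f"{name}.tsv"
        pd.DataFrame(records).to_csv(p, sep="\t", index=False)
        paths[name] = p
    (out / "manifest_duplicates.txt").write_text(
        "".join(f"{r}\n" for r in ds.manifest.duplicate_read_ids)
    )
    (out / "manifest_credible_lncrnas.txt").write_text(
        "".join(f"{t}\n" for t in ds.manifest.credible_lncrnas)
    )
    info = {"seed": ds.config.seed, "groups": ds.config.sample_groups,
            "config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in asdict(ds.config).items()}}
    paths["run_info"].write_text(yaml.safe_dump(info, sort_keys=True))
    return paths


def reciprocal_overlap(
    a: tuple[int, int], b: tuple[int, int], min_frac: float = 0.5
) -> bool:
    """True when the intervals overlap by >= *min_frac* of each one's length."""
    ov = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    return ov >= min_frac * (a[1] - a[0]) and ov >= min_frac * (b[1] - b[0])


def score_peak_recovery(
    manifest_peaks: list[dict],
    called: list,
    min_frac: float = 0.5,
) -> tuple[float, float]:
    """(recall, precision) of called peaks against the planted truth.

    A planted peak is recovered when some called peak on its chromosome
    matches at >= *min_frac* reciprocal overlap; a called peak is a true
    positive when it matches some planted peak the same way.
    """
    truth = [(d["chrom"], (d["start"], d["end"])) for d in manifest_peaks]
    calls = [
        (p.interval.chrom, (p.interval.start, p.interval.end)) for p in called
    ]
    tp_truth = sum(
        1
        for c, span in truth
        if any(cc == c and reciprocal_overlap(span, s, min_frac) for cc, s in calls)
    )
    tp_called = sum(
        1
        for cc, s in calls
        if any(c == cc and reciprocal_overlap(span, s, min_frac) for c, span in truth)
    )
    recall = tp_truth / len(truth) if truth else float("nan")
    precision = tp_called / len(calls) if calls else float("nan")
    return recall, precision


def write_sam(
    reads: list[ReadPlacement],
    genes: dict[str, GeneModel],
    path: str | os.PathLike,
) -> None:
    """Optional SAM emission (text) for exercising the real-format reader."""
    chrom_len: dict[str, int] = {}
    for g in genes.values():
        chrom_len[g.interval.chrom] = max(
            chrom_len.get(g.interval.chrom, 0), g.interval.end + 10_000
        )
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for c in sorted(chrom_len):
            fh.write(f"@SQ\tSN:{c}\tLN:{chrom_len[c]}\n")
        for p in reads:
            iv = p.interval
            flag = 16 if iv.strand == "-" else 0
            cigar = f"{len(iv)}M"
            seq = "A" * len(iv)
            fh.write(
                f"{p.read_id}\t{flag}\t{iv.chrom}\t{iv.start + 1}\t60\t{cigar}"
                f"\t*\t0\t0\t{seq}\t*\n"
            )
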