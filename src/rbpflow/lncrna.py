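"""lncRNA candidate filtering and the cis-target co-location/co-expression screen.

A transcript is a credible lncRNA only when all four coding-potential
predictors (CPC2, LGC, CNCI, CPAT) vote noncoding, it is at least 200 bp
long, does not overlap any known coding gene, and lies at least 1,000 bp
from the nearest gene.  Cis-target candidates are genes within 100 kb of
a lncRNA whose expression also correlates (|r| > 0.6, p <= 0.01, Pearson
with the t transform) across samples; the final cis set is the
intersection of the two screens.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomicInterval, GeneModel, gap
from .reads import ExpressionMatrix

logger = logging.getLogger(__name__)

PREDICTORS = ("CPC2", "LGC", "CNCI", "CPAT")


@dataclass
class LncRNACandidate:
    transcript_id: str
    interval: GenomicInterval
    length: int
    noncoding_votes: dict[str, bool]
    overlaps_coding: bool = False
    nearest_gene_distance: float = float("inf")


@dataclass
class CisPair:
    lncrna_id: str
    gene_id: str
    genomic_distance: float
    pearson_r: float | None = None
    p_value: float | None = None
    passes: bool = False


def filter_lncrna_candidates(
    candidates: Iterable[LncRNACandidate],
    min_length: int = 200,
    min_gene_distance: int = 1000,
) -> list[LncRNACandidate]:
    """Keep transcripts that survive every lncRNA credibility rule.

    Keep iff all four predictors vote noncoding AND length >= 200 bp AND
    no coding-gene overlap AND nearest-gene distance >= 1,000 bp.
    Boundaries are strict as printed: length 199 is removed, 200 kept.
    Transcripts with incomplete votes are rejected.
    """
    kept = []
    for c in candidates:
        if set(c.noncoding_votes) != set(PREDICTORS):
            logger.warning(
                "transcript %s rejected: incomplete votes", c.transcript_id
            )
            continue
        if not all(c.noncoding_votes[p] for p in PREDICTORS):
            continue
        if c.length < min_length:
            continue
        if c.overlaps_coding:
            continue
        if c.nearest_gene_distance < min_gene_distance:
            continue
        kept.append(c)
    return sorted(kept, key=lambda c: c.transcript_id)


def colocated_pairs(
    lncrnas: Sequence[LncRNACandidate],
    genes: Sequence[GeneModel],
    window: int = 100_000,
) -> list[CisPair]:
    """All (lncRNA, gene) pairs within *window* bp on the same chromosome.

    The gap is measured between interval boundaries (0 for overlap);
    a gap of exactly *window* is retained, window + 1 is excluded.
    """
    pairs = []
    for lnc in lncrnas:
        for g in genes:
            d = gap(lnc.interval, g.interval)
            if d <= window:
                pairs.append(CisPair(lnc.transcript_id, g.gene_id, d))
    return pairs


def pearson_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r and its two-sided p via the t transform with n-2 df."""
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def coexpression_screen(
    pairs: Sequence[CisPair],
    expr: ExpressionMatrix,
    r_cut: float = 0.6,
    p_cut: float = 0.01,
    adjust_p: bool = False,
) -> list[CisPair]:
    """Fill Pearson r/p on each pair and flag those passing both cuts.

    passes iff |r| > r_cut and p <= p_cut.  Pairs with a member missing
    from the matrix, fewer than 3 samples, or a zero-variance profile
    fail with a logged reason.  *adjust_p* applies BH across the tested
    pairs before the p cut.
    """
    values = expr.values
    tested: list[CisPair] = []
    for pair in pairs:
        if pair.lncrna_id not in values.index or pair.gene_id not in values.index:
            logger.warning(
                "pair %s-%s: member missing from expression matrix",
                pair.lncrna_id, pair.gene_id,
            )
            pair.passes = False
            continue
        x = values.loc[pair.lncrna_id].to_numpy(dtype=float)
        y = values.loc[pair.gene_id].to_numpy(dtype=float)
        if x.size < 3:
            pair.passes = False
            continue
        if np.std(x) == 0 or np.std(y) == 0:
            logger.warning(
                "pair %s-%s: zero-variance expression, correlation undefined",
                pair.lncrna_id, pair.gene_id,
            )
            pair.passes = False
            continue
        pair.pearson_r, pair.p_value = pearson_test(x, y)
        tested.append(pair)
    if adjust_p and tested:
        from .integrate import bh_fdr

        adj = bh_fdr(np.array([p.p_value for p in tested]))
        for pair, a in zip(tested, adj):
            pair.p_value = float(a)
    for pair in tested:
        pair.passes = abs(pair.pearson_r) > r_cut and pair.p_value <= p_cut
    return list(pairs)


def cis_targets(
    colocated: Sequence[CisPair], coexpressed: Sequence[CisPair]
) -> list[CisPair]:
    """Intersection of the co-location and co-expression screens.

    A pair is a cis target iff it appears in the co-location set and its
    co-expression screen passed.
    """
    coloc_keys = {(p.lncrna_id, p.gene_id) for p in colocated}
    return [
        p
        for p in coexpressed
        if p.passes and (p.lncrna_id, p.gene_id) in coloc_keys
    ]


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

def read_votes_tsv(path) -> dict[str, dict[str, bool]]:
    """Predictor-vote TSV (transcript_id, cpc2, lgc, cnci, cpat) with
    coding/noncoding entries -> transcript -> predictor -> noncoding?"""
    df = pd.read_csv(path, sep="\t")
    cols = {c.upper(): c for c in df.columns}
    out: dict[str, dict[str, bool]] = {}
    for row in df.itertuples(index=False):
        d = row._asdict()
        tid = str(d[df.columns[0]])
        out[tid] = {
            p: str(d[cols[p]]).strip().lower() == "noncoding"
            for p in PREDICTORS
            if p in cols
        }
    return out


def write_cis_pairs_tsv(pairs: Sequence[CisPair], path) -> None:
    pd.DataFrame([p.__dict__ for p in pairs]).to_csv(path, sep="\t", index=False)
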