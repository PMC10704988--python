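"""DEG threshold filtering, set overlaps, and hypergeometric enrichment.

These are the integration steps that combine differential-expression
results, regulated splicing genes, and peak target genes, and test
annotation terms for over-representation with the hypergeometric test
under Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class DEGRecord:
    gene_id: str
    fold_change: float  # knockdown / control, linear scale
    p_value: float
    direction: str  # up | down | none


@dataclass
class EnrichmentResult:
    term_id: str
    term_size: int
    overlap: int
    p_value: float
    bh_adjusted_p: float


def bh_fdr(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved.

    adjusted[i] = min over j with p_(j) >= p_(i) of p_(j) * n / rank(j),
    clipped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    out = np.empty(n, dtype=float)
    out[order] = adj_sorted
    return out


def deg_filter(
    table: pd.DataFrame,
    fc_hi: float = 2.0,
    fc_lo: float = 0.5,
    alpha: float = 0.05,
    log2_input: bool = False,
    adjust_p: bool = False,
) -> list[DEGRecord]:
    """Apply the strict DEG thresholds to a (gene, fold_change, p_value) table.

    up: p < alpha and fc > fc_hi; down: p < alpha and fc < fc_lo — all
    inequalities strict, so fc exactly 2.0 is excluded.  *log2_input*
    converts log2 fold changes to linear first; *adjust_p* applies BH to
    the p column before thresholding.
    """
    required = {"gene_id", "fold_change", "p_value"}
    if not required.issubset(table.columns):
        raise ValueError(f"DEG table must have columns {sorted(required)}")
    fc = table["fold_change"].astype(float).to_numpy()
    if log2_input:
        fc = 2.0 ** fc
    bad = np.flatnonzero(~(fc > 0))
    if bad.size:
        raise ValueError(f"non-positive fold change in rows: {bad.tolist()}")
    p = table["p_value"].astype(float).to_numpy()
    if adjust_p:
        p = bh_fdr(p)
    out = []
    for gene, f, pv in zip(table["gene_id"], fc, p):
        if pv < alpha and f > fc_hi:
            direction = "up"
        elif pv < alpha and f < fc_lo:
            direction = "down"
        else:
            direction = "none"
        out.append(DEGRecord(str(gene), float(f), float(pv), direction))
    return out


def deg_gene_set(records: Iterable[DEGRecord]) -> set[str]:
    """Gene ids passing the filter in either direction."""
    return {r.gene_id for r in records if r.direction != "none"}


def overlap_sets(
    named_sets: Mapping[str, set[str]]
) -> tuple[dict[tuple[str, ...], set[str]], dict[str, set[str]]]:
    """Pairwise/three-way intersections plus exclusive Venn regions.

    Returns ``(intersections, venn_regions)``: *intersections* maps each
    combination of set names (size >= 2) to the plain intersection;
    *venn_regions* maps a membership signature like ``"A&B"`` or
    ``"A_only"`` to the genes exactly in those sets.
    """
    names = list(named_sets)
    if len(names) < 2:
        raise ValueError("need at least two sets")
    inter: dict[tuple[str, ...], set[str]] = {}
    for k in range(2, len(names) + 1):
        for combo in combinations(names, k):
            s = set.intersection(*(named_sets[n] for n in combo))
            inter[combo] = s
    universe = set.union(*named_sets.values())
    regions: dict[str, set[str]] = {}
    for g in universe:
        members = tuple(n for n in names if g in named_sets[n])
        key = "&".join(members) if len(members) > 1 else f"{members[0]}_only"
        regions.setdefault(key, set()).add(g)
    return inter, regions


def hypergeom_enrichment(
    query: set[str],
    annotation: Mapping[str, set[str]],
    background: set[str],
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric enrichment of *query* in each term.

    For each term: population = |background|, successes = |term within
    background|, draws = |query|, p = P[X >= overlap].  Query genes
    absent from the background are dropped (logged implicitly via the
    returned sizes); BH adjustment spans all tested terms.
    """
    q = query & background
    if len(q) < len(query):
        import logging

        logging.getLogger(__name__).warning(
            "%d query gene(s) absent from background dropped",
            len(query) - len(q),
        )
    M, N = len(background), len(q)
    terms, pvals, sizes, olaps = [], [], [], []
    for term, genes in annotation.items():
        tset = genes & background
        if not tset:
            continue
        k = len(tset & q)
        p = float(stats.hypergeom.sf(k - 1, M, len(tset), N))
        terms.append(term)
        pvals.append(min(p, 1.0))
        sizes.append(len(tset))
        olaps.append(k)
    adj = bh_fdr(np.array(pvals)) if pvals else np.array([])
    return [
        EnrichmentResult(t, s, k, p, float(a))
        for t, s, k, p, a in zip(terms, sizes, olaps, pvals, adj)
    ]


def read_deg_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_annotation_tsv(path) -> dict[str, set[str]]:
    """Two-column TSV (gene_id, term_id) -> term -> gene set."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, set[str]] = {}
    for gene, term in zip(df.iloc[:, 0], df.iloc[:, 1]):
        out.setdefault(str(term), set()).add(str(gene))
    return out
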