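import numpy as np
import pandas as pd
import pytest

from rbpflow.intervals import GeneModel, GenomicInterval
from rbpflow.lncrna import (
    PREDICTORS, CisPair, LncRNACandidate, cis_targets, coexpression_screen,
    colocated_pairs, filter_lncrna_candidates,
)
from rbpflow.reads import ExpressionMatrix
from _reference import reference_pearson_p


def cand(tid, length=500, votes=True, overlap=False, dist=5000.0,
         start=1_000_000):
    return LncRNACandidate(
        transcript_id=tid,
        interval=GenomicInterval("chr1", start, start + length),
        length=length,
        noncoding_votes={p: votes for p in PREDICTORS},
        overlaps_coding=overlap,
        nearest_gene_distance=dist,
    )


class TestCredibilityFilter:
    def test_short_transcript_removed_at_199_kept_at_200(self):
        kept = filter_lncrna_candidates([cand("a", 199), cand("b", 200)])
        assert [c.transcript_id for c in kept] == ["b"]

    def test_single_coding_vote_removes(self):
        c = cand("a")
        c.noncoding_votes["CNCI"] = False
        assert filter_lncrna_candidates([c]) == []

    def test_overlap_or_proximity_removes(self):
        assert filter_lncrna_candidates([cand("a", overlap=True)]) == []
        assert filter_lncrna_candidates([cand("a", dist=999)]) == []
        assert filter_lncrna_candidates([cand("a", dist=1000)]) != []

    def test_fully_credible_kept(self):
        assert len(filter_lncrna_candidates([cand("a")])) == 1

    def test_incomplete_votes_rejected(self):
        c = cand("a")
        del c.noncoding_votes["CPAT"]
        assert filter_lncrna_candidates([c]) == []

    def test_order_invariant(self):
        cands = [cand(f"t{i}", length=150 + i * 40) for i in range(8)]
        fwd = [c.transcript_id for c in filter_lncrna_candidates(cands)]
        rev = [c.transcript_id for c in filter_lncrna_candidates(cands[::-1])]
        assert fwd == rev


class TestColocation:
    def _genes(self, spans):
        return [
            GeneModel(f"g{i}", GenomicInterval("chr1", s, e))
            for i, (s, e) in enumerate(spans)
        ]

    def test_boundary_inclusive_at_100kb(self):
        lnc = cand("L", length=500, start=0)
        inside = self._genes([(100_500, 101_500)])   # gap exactly 100,000
        outside = self._genes([(100_501, 101_501)])  # gap 100,001
        assert len(colocated_pairs([lnc], inside)) == 1
        assert len(colocated_pairs([lnc], outside)) == 0

    def test_overlap_distance_zero(self):
        lnc = cand("L", length=500, start=1000)
        pairs = colocated_pairs([lnc], self._genes([(1200, 2000)]))
        assert pairs[0].genomic_distance == 0

    def test_matches_all_pairs_brute_force(self, rng):
        lncs = [
            cand(f"L{i}", length=300, start=int(s))
            for i, s in enumerate(rng.integers(0, 3_000_000, 50))
        ]
        genes = self._genes(
            [(int(s), int(s) + 2000) for s in rng.integers(0, 3_000_000, 200)]
        )
        got = {(p.lncrna_id, p.gene_id) for p in colocated_pairs(lncs, genes)}
        want = set()
        for ln in lncs:
            for g in genes:
                gap = max(
                    0,
                    max(ln.interval.start, g.interval.start)
                    - min(ln.interval.end, g.interval.end),
                )
                if gap <= 100_000:
                    want.add((ln.transcript_id, g.gene_id))
        assert got == want

    def test_tighter_window_yields_subset(self, rng):
        lncs = [cand(f"L{i}", start=int(s))
                for i, s in enumerate(rng.integers(0, 10**6, 20))]
        genes = self._genes(
            [(int(s), int(s) + 1500) for s in rng.integers(0, 10**6, 60)]
        )
        wide = {(p.lncrna_id, p.gene_id) for p in colocated_pairs(lncs, genes)}
        narrow = {
            (p.lncrna_id, p.gene_id)
            for p in colocated_pairs(lncs, genes, window=20_000)
        }
        assert narrow <= wide


class TestCoexpression:
    def _expr(self, rows):
        return ExpressionMatrix(
            pd.DataFrame(rows, index=["L", "G"],
                         columns=[f"s{i}" for i in range(len(rows[0]))])
        )

    def test_identical_profiles_pass(self):
        expr = self._expr([[1, 2, 3, 4, 5, 6], [1, 2, 3, 4, 5, 6]])
        pairs = coexpression_screen([CisPair("L", "G", 0)], expr)
        assert pairs[0].pearson_r == pytest.approx(1.0)
        assert pairs[0].passes

    def test_uncorrelated_profiles_fail(self):
        expr = self._expr([[1, -1, 1, -1], [1, 1, -1, -1]])
        pairs = coexpression_screen([CisPair("L", "G", 0)], expr)
        assert pairs[0].pearson_r == pytest.approx(0.0)
        assert not pairs[0].passes

    def test_p_matches_textbook_t_transform_six_samples(self):
        x = np.array([2.0, 4.1, 5.9, 8.2, 9.8, 12.1])
        y = np.array([1.1, 2.3, 2.8, 4.4, 4.9, 6.2])
        expr = self._expr([x, y])
        pair = coexpression_screen([CisPair("L", "G", 0)], expr)[0]
        assert pair.p_value == pytest.approx(
            reference_pearson_p(pair.pearson_r, 6), abs=1e-6
        )

    def test_zero_variance_profile_fails_with_reason(self, caplog):
        expr = self._expr([[3, 3, 3, 3], [1, 2, 3, 4]])
        pairs = coexpression_screen([CisPair("L", "G", 0)], expr)
        assert pairs[0].pearson_r is None
        assert not pairs[0].passes

    def test_tighter_r_cut_yields_subset(self, rng):
        n_pairs = 40
        rows, index = [], []
        pairs = []
        for k in range(n_pairs):
            shared = rng.standard_normal(8)
            rows.append(shared + 0.5 * rng.standard_normal(8) + 5)
            rows.append(shared + 0.5 * rng.standard_normal(8) + 5)
            index += [f"L{k}", f"G{k}"]
            pairs.append(CisPair(f"L{k}", f"G{k}", 0))
        expr = ExpressionMatrix(
            pd.DataFrame(rows, index=index, columns=[f"s{i}" for i in range(8)])
        )
        loose = {
            (p.lncrna_id, p.gene_id)
            for p in coexpression_screen(
                [CisPair(p.lncrna_id, p.gene_id, 0) for p in pairs], expr,
                r_cut=0.5)
            if p.passes
        }
        tight = {
            (p.lncrna_id, p.gene_id)
            for p in coexpression_screen(
                [CisPair(p.lncrna_id, p.gene_id, 0) for p in pairs], expr,
                r_cut=0.9)
            if p.passes
        }
        assert tight <= loose


class TestCisTargets:
    def test_requires_both_screens(self):
        passing = CisPair("L", "G", 500, pearson_r=0.95, p_value=1e-4, passes=True)
        corr_only = CisPair("L", "X", 500_000, pearson_r=0.95, p_value=1e-4,
                            passes=True)
        coloc = [CisPair("L", "G", 500)]
        final = cis_targets(coloc, [passing, corr_only])
        assert [(p.lncrna_id, p.gene_id) for p in final] == [("L", "G")]

    def test_planted_pairs_recovered_among_decoys(self):
        """10 planted cis pairs (target r 0.9) among co-located decoys in a
        20-sample design: recall >= 0.9 at the default cuts."""
        from rbpflow.pipeline import lncrna_candidates_from_table
        from rbpflow.simulate import SimulationConfig, simulate_dataset

        cfg = SimulationConfig(
            seed=9, n_replicates_per_group=10, n_lncrnas=10, n_cis_pairs=10
        )
        ds = simulate_dataset(cfg)
        credible = filter_lncrna_candidates(
            lncrna_candidates_from_table(ds.lncrna_table, ds.votes, ds.genes)
        )
        coloc = colocated_pairs(credible, list(ds.genes.values()))
        assert len(coloc) > len(ds.manifest.cis_pairs)  # decoys present
        coexp = coexpression_screen(coloc, ds.fpkm)
        final = {(p.lncrna_id, p.gene_id) for p in cis_targets(coloc, coexp)}
        truth = {(d["lncrna_id"], d["gene_id"]) for d in ds.manifest.cis_pairs}
        recall = len(final & truth) / len(truth)
        assert recall >= 0.9
        # decoy pairs share no latent factor: none should sneak through
        assert len(final - truth) <= 2
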