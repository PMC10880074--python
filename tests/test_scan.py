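"""Bipartite placement enumeration, best-hit selection and E-values."""

import numpy as np
import pytest
from Bio.Seq import reverse_complement

from conftest import random_dna
from ecfscan.pssm import MINUS10, MINUS35, PssmPair, consensus, pssm_from_frequencies
from ecfscan.scan import (
    SequenceWindow,
    all_hits,
    best_hit,
    empirical_evalue,
    null_best_totals,
    tss_anchored_scan,
    window_from_genome,
)
from ecfscan.tss import TssRecord
from oracles import brute_best


def synthetic_window(seq, anchor=None, wid="w"):
    return SequenceWindow(
        window_id=wid, source="synthetic", contig=None, strand="+",
        genomic_start=1, genomic_end=len(seq), seq=seq, anchor_tss_offset=anchor,
    )


def consensus_window(pair, rng, spacer=16, d=4, lead=0, gc=0.5):
    """lead random nt + consensus site + d intervening nt + TSS base."""
    site = (consensus(pair.pssm35) + random_dna(rng, spacer, gc)
            + consensus(pair.pssm10))
    seq = random_dna(rng, lead, gc) + site + random_dna(rng, d + 1, gc)
    return synthetic_window(seq, anchor=len(seq) - 1)


def uniform_pair(l35=2, l10=2):
    return PssmPair(
        "UNI",
        pssm_from_frequencies("u35", MINUS35, np.full((4, l35), 0.25), 0.0),
        pssm_from_frequencies("u10", MINUS10, np.full((4, l10), 0.25), 0.0),
    )


class TestAllHits:
    def test_planted_consensus_site_is_found(self, pair02):
        rng = np.random.default_rng(0)
        w = consensus_window(pair02, rng, spacer=16, d=4)
        hits = all_hits(w, pair02)
        best = max(hits, key=lambda h: h.total)
        assert best.pos35 == 0
        assert best.spacer == 16
        assert best.tss_distance == 4
        assert best.total == pytest.approx(pair02.consensus_total())

    def test_window_below_minimal_geometry_is_empty(self, pair02):
        n = pair02.pssm35.length + 14 + pair02.pssm10.length  # max spacer 14
        rng = np.random.default_rng(1)
        assert all_hits(synthetic_window(random_dna(rng, n)), pair02) == []

    @pytest.mark.parametrize("n", range(40, 81, 8))
    def test_unanchored_count_matches_closed_form(self, pair02, n):
        rng = np.random.default_rng(n)
        hits = all_hits(synthetic_window(random_dna(rng, n)), pair02)
        l35, l10 = pair02.pssm35.length, pair02.pssm10.length
        expected = sum(
            max(0, n - l35 - l10 - sp + 1)
            for sp in range(pair02.spacer_min, pair02.spacer_max + 1)
        )
        assert len(hits) == expected

    def test_geometry_invariants_on_all_outputs(self, pair02):
        rng = np.random.default_rng(7)
        for anchor in (None, "last"):
            seq = random_dna(rng, 60)
            w = synthetic_window(seq, anchor=59 if anchor else None)
            for h in all_hits(w, pair02):
                assert pair02.spacer_min <= h.spacer <= pair02.spacer_max
                assert h.total == pytest.approx(h.s35 + h.s10)
                if anchor:
                    assert pair02.tss_dist_min <= h.tss_distance <= pair02.tss_dist_max

    def test_invalid_characters_rejected(self, pair02):
        with pytest.raises(ValueError, match="non-ACGT"):
            all_hits(synthetic_window("N" * 60), pair02)


class TestBestHit:
    @pytest.mark.parametrize("anchored", [False, True])
    def test_matches_bruteforce_enumeration(self, pair02, anchored):
        rng = np.random.default_rng(3 if anchored else 4)
        for _ in range(100):
            seq = random_dna(rng, 60, gc=float(rng.uniform(0.3, 0.7)))
            w = synthetic_window(seq, anchor=59 if anchored else None)
            got = best_hit(w, pair02)
            exp = brute_best(seq, pair02, anchor=59 if anchored else None)
            assert (got is None) == (exp is None)
            if got:
                assert (got.pos35, got.pos10, got.spacer) == (
                    exp["p35"], exp["p10"], exp["spacer"])
                assert got.total == pytest.approx(exp["s35"] + exp["s10"])

    def test_total_is_max_over_all_hits(self, pair11):
        rng = np.random.default_rng(9)
        w = synthetic_window(random_dna(rng, 70))
        hits = all_hits(w, pair11)
        assert best_hit(w, pair11).total == pytest.approx(
            max(h.total for h in hits)
        )

    def test_tie_breaks_smaller_spacer_then_three_prime(self):
        # a uniform pair scores every placement equally, so only the
        # documented tie-breaks decide
        pair = uniform_pair()
        w = synthetic_window("ACGT" * 8)  # 32 nt
        h = best_hit(w, pair)
        assert h.spacer == pair.spacer_min
        # 3'-most -10 box among spacer-15 placements
        expected_p10 = max(
            b.pos10 for b in all_hits(w, pair) if b.spacer == pair.spacer_min
        )
        assert h.pos10 == expected_p10

    def test_score_never_exceeds_consensus(self, pair02):
        rng = np.random.default_rng(12)
        cap = pair02.consensus_total()
        for _ in range(50):
            h = best_hit(synthetic_window(random_dna(rng, 80)), pair02)
            assert h.total <= cap + 1e-9


class TestEvalue:
    def test_extremes(self, pair02):
        rng = np.random.default_rng(2)
        w = synthetic_window(random_dna(rng, 60))
        observed = best_hit(w, pair02)
        lo = type(observed)(**{**observed.__dict__, "total": 999.0})
        hi = type(observed)(**{**observed.__dict__, "total": -999.0})
        assert empirical_evalue(w, pair02, lo, n=50, seed=0) == 0.0
        assert empirical_evalue(w, pair02, hi, n=50, seed=0) == 1.0

    def test_add_one_estimator(self, pair02):
        rng = np.random.default_rng(2)
        w = synthetic_window(random_dna(rng, 60))
        observed = best_hit(w, pair02)
        lo = type(observed)(**{**observed.__dict__, "total": 999.0})
        assert empirical_evalue(w, pair02, lo, n=99, seed=0,
                                estimator="k1n1") == pytest.approx(1 / 100)

    def test_seeded_reproducibility(self, pair02):
        rng = np.random.default_rng(6)
        w = synthetic_window(random_dna(rng, 50), anchor=49)
        h = best_hit(w, pair02)
        e1 = empirical_evalue(w, pair02, h, n=200, seed=11)
        e2 = empirical_evalue(w, pair02, h, n=200, seed=11)
        assert e1 == e2

    def test_null_rate_roughly_uniform(self, pair02):
        # random windows are shuffles of themselves, so P(E <= 0.05) ~ 0.05
        rng = np.random.default_rng(8)
        hits = 0
        n_windows = 200
        for i in range(n_windows):
            w = synthetic_window(random_dna(rng, 40), anchor=39, wid=f"w{i}")
            h = best_hit(w, pair02)
            if empirical_evalue(w, pair02, h, n=200, seed=i) <= 0.05:
                hits += 1
        assert 0.01 <= hits / n_windows <= 0.11

    def test_invariant_under_base_relabeling(self, pair02):
        # relabel bases jointly in the window and the matrices: scores and
        # E-values are unchanged (the shuffle null permutes positions only)
        perm = np.array([2, 3, 1, 0])  # A->G, C->T, G->C, T->A
        letters = dict(zip("ACGT", "GTCA"))
        rng = np.random.default_rng(13)
        seq = random_dna(rng, 50)
        seq_perm = "".join(letters[b] for b in seq)
        relabel = lambda pssm, box: pssm_from_frequencies(
            pssm.motif_id, box, pssm.probabilities()[np.argsort(perm)], 0.0
        )
        pair_perm = PssmPair(
            "perm", relabel(pair02.pssm35, MINUS35), relabel(pair02.pssm10, MINUS10)
        )
        w, wp = synthetic_window(seq), synthetic_window(seq_perm)
        h, hp = best_hit(w, pair02), best_hit(wp, pair_perm)
        assert hp.total == pytest.approx(h.total)
        assert empirical_evalue(wp, pair_perm, hp, n=100, seed=3) == pytest.approx(
            empirical_evalue(w, pair02, h, n=100, seed=3)
        )

    def test_null_scores_bounded_by_consensus(self, pair02):
        rng = np.random.default_rng(14)
        w = synthetic_window(random_dna(rng, 60))
        null = null_best_totals(w, pair02, n=100, rng=np.random.default_rng(0))
        assert (null <= pair02.consensus_total() + 1e-9).all()


class TestStrandHandling:
    def test_minus_strand_window_is_reverse_complement(self):
        genome = {"c": "ACGTACGTACGTACGTACGT"}
        w = window_from_genome(genome, "c", "-", 3, 10, "w", "feature_window")
        assert w.seq == reverse_complement(genome["c"][2:10])

    def test_planted_site_scores_identically_on_both_strands(self, pair02):
        rng = np.random.default_rng(21)
        core = random_dna(rng, 120)
        genome_fwd = {"c": core}
        genome_rev = {"c": reverse_complement(core)}
        w_fwd = window_from_genome(genome_fwd, "c", "+", 11, 90, "wf", "feature_window")
        w_rev = window_from_genome(genome_rev, "c", "-", 120 - 90 + 1, 120 - 11 + 1,
                                   "wr", "feature_window")
        assert w_fwd.seq == w_rev.seq
        hf, hr = best_hit(w_fwd, pair02), best_hit(w_rev, pair02)
        assert hf.total == pytest.approx(hr.total)
        # genomic coordinates mirror each other
        assert hr.g35_end == 120 - (hf.g35_start - 1)
        assert hr.g35_start == 120 - (hf.g35_end - 1)


class TestAnchoredScan:
    def test_recovers_planted_upstream_site(self, pair02):
        rng = np.random.default_rng(30)
        d = 3
        site = (consensus(pair02.pssm35) + random_dna(rng, 15)
                + consensus(pair02.pssm10))
        upstream = random_dna(rng, 30)
        tss_base = random_dna(rng, 1)
        seq = upstream + site + random_dna(rng, d) + tss_base + random_dna(rng, 20)
        tss_pos = len(upstream) + len(site) + d + 1
        tss = [TssRecord("c", "+", tss_pos, 100, 50.0)]
        hits = tss_anchored_scan(tss, {"c": seq}, pair02, n_null=100, seed=5)
        assert len(hits) == 1
        assert hits[0].tss_distance == d
        assert hits[0].evalue == 0.0
        assert hits[0].g35_start == len(upstream) + 1

    def test_random_upstream_is_rarely_retained(self, pair02):
        rng = np.random.default_rng(31)
        genome = {"c": random_dna(rng, 5000)}
        tss = [TssRecord("c", "+", p, 10, 10.0) for p in range(100, 2100, 40)]
        hits = tss_anchored_scan(tss, genome, pair02, n_null=200, seed=6)
        assert len(hits) / len(tss) <= 0.15

    def test_off_contig_tss_is_an_error(self, pair02):
        with pytest.raises(ValueError, match="off contig"):
            tss_anchored_scan(
                [TssRecord("c", "+", 500, 1, 5.0)], {"c": "ACGT" * 20}, pair02
            )

    def test_clipped_window_near_edge_is_skipped_or_scanned(self, pair02):
        rng = np.random.default_rng(32)
        genome = {"c": random_dna(rng, 200)}
        # TSS at position 10: the 40-nt window clips to 10 bases, too short
        hits = tss_anchored_scan(
            [TssRecord("c", "+", 10, 5, 5.0)], genome, pair02, n_null=50, seed=0
        )
        assert hits == []
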