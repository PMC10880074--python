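"""Synthetic-data generator: ground truth, signal model, determinism."""

import numpy as np
import pytest

from ecfscan.calibrate import DE_LOG2FC_MIN
from ecfscan.pipeline import extract_feature_windows
from ecfscan.pssm import consensus, score_subsequence
from ecfscan.scan import best_hit
from ecfscan.simulate import (
    generate_genome,
    sample_site,
    simulate_dataset,
    simulate_de_table,
    simulate_tss_counts,
    write_dataset,
)
from ecfscan.tss import compute_rrs


class TestSampleSite:
    def test_consensus_mode_scores_maximal(self, pair02):
        rng = np.random.default_rng(0)
        site = sample_site(pair02, "consensus", rng)
        s = (score_subsequence(pair02.pssm35, site.seq[: site.l35])
             + score_subsequence(pair02.pssm10, site.seq[-site.l10:]))
        assert s == pytest.approx(pair02.consensus_total())

    def test_spacer_always_in_range(self, pair02):
        rng = np.random.default_rng(1)
        spacers = {sample_site(pair02, "sampled", rng).spacer for _ in range(60)}
        assert spacers <= {15, 16, 17}
        assert len(spacers) == 3  # all values reached over 60 draws

    def test_sampled_mean_score_matches_negative_entropy(self, pair02):
        # E[score] = sum_j sum_b p_bj log2 p_bj (the negative column entropy)
        rng = np.random.default_rng(2)
        pssm = pair02.pssm35
        p = pssm.probabilities()
        expected = float((p * pssm.logprob).sum())
        var = float((p * pssm.logprob ** 2).sum() -
                    ((p * pssm.logprob).sum(axis=0) ** 2).sum())
        n = 2000
        scores = []
        for _ in range(n):
            site = sample_site(pair02, "sampled", rng)
            scores.append(score_subsequence(pssm, site.seq[: site.l35]))
        assert np.mean(scores) == pytest.approx(
            expected, abs=4 * np.sqrt(var / n)
        )

    def test_unknown_strength_rejected(self, pair02):
        with pytest.raises(ValueError, match="strength"):
            sample_site(pair02, "huge")


class TestGenerateGenome:
    def test_gc_content_within_one_percent(self, pair02):
        genome, _, _ = generate_genome(pair02, n_regulated=0, gc=0.6, seed=3)
        seq = genome["chr"]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert gc == pytest.approx(0.6, abs=0.01)

    def test_no_regulated_features_means_no_truth(self, pair02):
        _, _, truth = generate_genome(pair02, n_regulated=0, seed=4)
        assert truth.planted_promoters == []
        assert truth.planted_tss == []

    def test_planted_consensus_sites_recovered_exactly(self, pair02):
        genome, features, truth = generate_genome(pair02, seed=5)
        windows = extract_feature_windows(genome, features)
        by_feature = {w.window_id.removeprefix("feat:"): w for w in windows}
        for p in truth.planted_promoters:
            h = best_hit(by_feature[p.feature_id], pair02)
            assert h.total == pytest.approx(pair02.consensus_total())
            assert (h.g35_start, h.g35_end) == p.m35_span
            assert (h.g10_start, h.g10_end) == p.m10_span
            assert h.spacer == p.spacer

    def test_planted_geometry_within_spec(self, pair02):
        _, _, truth = generate_genome(pair02, n_regulated=30, seed=6)
        for p in truth.planted_promoters:
            assert 15 <= p.spacer <= 17
            assert 3 <= p.tss_distance <= 6

    def test_infeasible_packing_is_an_error(self, pair02):
        with pytest.raises(ValueError, match="packing"):
            generate_genome(pair02, n_features=100, contig_len=5000)

    def test_site_sequence_matches_genome(self, pair02):
        genome, _, truth = generate_genome(pair02, seed=7)
        from Bio.Seq import reverse_complement

        for p in truth.planted_promoters:
            lo = min(p.m35_span[0], p.m10_span[0])
            hi = max(p.m35_span[1], p.m10_span[1])
            fwd = genome[p.contig][lo - 1: hi]
            assert (fwd if p.strand == "+" else reverse_complement(fwd)) == p.site_seq


class TestSimulateCounts:
    def test_zero_depth_gives_empty_tracks(self, pair02):
        genome, _, truth = generate_genome(pair02, seed=8)
        tracks = simulate_tss_counts(truth, genome, depth=0, seed=0)
        for t in tracks["treatment"] + tracks["control"]:
            assert t.positions.size == 0
        with pytest.raises(ValueError, match="empty sample"):
            compute_rrs(tracks["treatment"][0])

    def test_rt_equals_emitted_totals(self, pair02):
        genome, _, truth = generate_genome(pair02, seed=9)
        tracks = simulate_tss_counts(truth, genome, depth=100_000, seed=1)
        for sample in ("treatment", "control"):
            total = sum(t.total for t in tracks[sample])
            assert all(t.rt == total for t in tracks[sample])

    def test_signal_concentrates_on_planted_tss(self, pair02):
        genome, _, truth = generate_genome(pair02, seed=10)
        tracks = simulate_tss_counts(truth, genome, depth=1_000_000,
                                     signal_fraction=0.1, seed=2)
        by_key = {(t.contig, t.strand): t for t in tracks["treatment"]}
        for contig, strand, pos, _ in truth.planted_tss:
            t = by_key[(contig, strand)]
            i = np.searchsorted(t.positions, pos)
            assert t.positions[i] == pos
            # ~80% of this TSS's 10k reads land on the exact base
            assert t.counts[i] > 6000

    def test_control_has_no_signal(self, pair02):
        genome, _, truth = generate_genome(pair02, seed=11)
        tracks = simulate_tss_counts(truth, genome, depth=1_000_000, seed=3)
        control_total = sum(t.total for t in tracks["control"])
        assert control_total < 1000  # background only

    def test_seed_determinism(self, pair02):
        genome, _, truth = generate_genome(pair02, seed=12)
        a = simulate_tss_counts(truth, genome, seed=7)
        b = simulate_tss_counts(truth, genome, seed=7)
        for ta, tb in zip(a["treatment"], b["treatment"]):
            np.testing.assert_array_equal(ta.positions, tb.positions)
            np.testing.assert_array_equal(ta.counts, tb.counts)


class TestDeTable:
    def test_effect_above_threshold_flags_exactly_planted(self, pair02):
        _, features, truth = generate_genome(pair02, seed=13)
        units = simulate_de_table(truth, features, effect_log2fc=4.0, seed=0)
        flagged = {u.unit_id for u in units if u.is_regulated()}
        assert flagged == set(truth.planted_regulated_units)
        assert all(fc == 4.0 for fc in truth.planted_regulated_units.values())

    def test_effect_below_threshold_flags_nothing(self, pair02):
        _, features, truth = generate_genome(pair02, seed=14)
        units = simulate_de_table(truth, features, effect_log2fc=1.0, seed=0)
        assert not any(u.is_regulated() for u in units)
        assert 1.0 <= DE_LOG2FC_MIN  # the filter is log2fc > 2

    def test_one_unit_per_feature(self, pair02):
        _, features, truth = generate_genome(pair02, seed=15)
        units = simulate_de_table(truth, features, seed=0)
        assert len(units) == len(features)


class TestDataset:
    def test_dataset_determinism(self, pair02):
        a = simulate_dataset(pair02, n_features=40, contig_len=25_000,
                             n_regulated=4, seed=20)
        b = simulate_dataset(pair02, n_features=40, contig_len=25_000,
                             n_regulated=4, seed=20)
        assert a.genome == b.genome
        assert a.truth.to_dict() == b.truth.to_dict()
        for ta, tb in zip(a.tracks["treatment"], b.tracks["treatment"]):
            np.testing.assert_array_equal(ta.counts, tb.counts)

    def test_write_dataset_emits_all_files(self, tmp_path, pair02):
        ds = simulate_dataset(pair02, n_features=30, contig_len=20_000,
                              n_regulated=3, depth=100_000, seed=21)
        write_dataset(ds, tmp_path)
        for name in ("genome.fasta", "features.gff3", "de_table.tsv",
                     "truth.json", "treatment.fwd.bedgraph",
                     "control.rev.bedgraph", "treatment.rt.txt"):
            assert (tmp_path / name).exists(), name
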