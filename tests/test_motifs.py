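"""Motif entropies, disruptive mutations, insertion protocol and activity scores."""

import numpy as np
import pandas as pd
import pytest

from seqens import consistency, motifs, simulate
from seqens.types import ActivityScore, GenomicWindow, PWMMotif


def _pwm(rows, motif_id="m"):
    return PWMMotif(motif_id, np.asarray(rows, dtype=float))


class TestColumnEntropy:
    @pytest.mark.parametrize("row, entropy", [
        ((0.25, 0.25, 0.25, 0.25), 2.0),
        ((1, 0, 0, 0), 0.0),
        ((0.5, 0.5, 0, 0), 1.0),
    ])
    def test_reference_values(self, row, entropy):
        assert motifs.column_entropy(_pwm([row]))[0] == pytest.approx(entropy)


class TestDesignDisruptiveMutation:
    def test_one_hot_column_targets_first_zero_base(self):
        rows = [[0.25] * 4, [0.25] * 4, [0.25] * 4, [1, 0, 0, 0], [0.25] * 4]
        pos, base = motifs.design_disruptive_mutation(_pwm(rows))
        assert (pos, base) == (3, "C")

    def test_lowest_probability_base_chosen(self):
        pos, base = motifs.design_disruptive_mutation(_pwm([[0.7, 0.1, 0.15, 0.05]]))
        assert (pos, base) == (0, "T")

    def test_entropy_tie_breaks_leftmost(self):
        col = [0.89, 0.05, 0.03, 0.03]
        pos, _ = motifs.design_disruptive_mutation(_pwm([col, col]))
        assert pos == 0

    def test_never_returns_consensus(self, small_model):
        for motif in small_model.motifs:
            pos, base = motifs.design_disruptive_mutation(motif)
            assert base != motif.consensus()[pos]

    def test_uniform_column_avoids_consensus(self):
        pos, base = motifs.design_disruptive_mutation(_pwm([[0.25] * 4]))
        assert base == "C"  # consensus is A (alphabetical argmax); C is next


class TestMutationProbability:
    def test_zero_probability_base(self):
        assert motifs.mutation_probability(_pwm([[1, 0, 0, 0]]), 0, "C") == 0.0

    def test_lookup(self):
        assert motifs.mutation_probability(
            _pwm([[0.7, 0.1, 0.15, 0.05]]), 0, "T") == pytest.approx(0.05)

    def test_designed_mutation_never_more_probable_than_consensus(self, small_model):
        for motif in small_model.motifs:
            pos, base = motifs.design_disruptive_mutation(motif)
            consensus = motif.consensus()[pos]
            assert (motifs.mutation_probability(motif, pos, base)
                    <= motifs.mutation_probability(motif, pos, consensus))


class TestSampleMotif:
    def test_one_hot_pwm_is_deterministic(self, one_hot_motif):
        assert motifs.sample_motif(one_hot_motif, 0, "sample") == "ACGT"
        assert motifs.sample_motif(one_hot_motif, 0, "consensus") == "ACGT"

    def test_sampling_frequencies(self):
        pwm = _pwm([[0.5, 0.5, 0, 0]])
        draws = [motifs.sample_motif(pwm, seed) for seed in range(10000)]
        freq_a = sum(d == "A" for d in draws) / len(draws)
        assert abs(freq_a - 0.5) < 0.015  # 3 SE of Binomial(10000, .5)

    def test_seeded_determinism(self, small_model):
        m = small_model.motifs[0]
        assert motifs.sample_motif(m, 42) == motifs.sample_motif(m, 42)


class TestInsertMotif:
    def test_identity_substitution(self, toy_window):
        sub = toy_window.sequence[toy_window.anchor - 18:toy_window.anchor - 10]
        out = motifs.insert_motif(toy_window, sub, 10)
        assert out.sequence == toy_window.sequence

    def test_length_preserved(self, toy_window):
        out = motifs.insert_motif(toy_window, "ACGTACGT", 100)
        assert out.length == toy_window.length

    def test_replaced_interval_coordinates(self):
        win = GenomicWindow(chrom="t", start=0, sequence="A" * 64, anchor=32)
        out = motifs.insert_motif(win, "CCCCCCCC", 10)
        # [anchor-18, anchor-10) replaced, everything else untouched
        assert out.sequence[14:22] == "CCCCCCCC"
        assert out.sequence[:14] == "A" * 14 and out.sequence[22:] == "A" * 42

    def test_tss_overlap_rejected(self, toy_window):
        with pytest.raises(ValueError, match="TSS"):
            motifs.insert_motif(toy_window, "ACGT", 0)

    def test_window_exit_rejected(self):
        win = GenomicWindow(chrom="t", start=0, sequence="A" * 64, anchor=8)
        with pytest.raises(ValueError, match="exits"):
            motifs.insert_motif(win, "C" * 8, 4)


class TestSelectBackgrounds:
    def _table(self):
        rows = []
        for gene, n_correct in [("gA", 10), ("gB", 3), ("gC", 10)]:
            for t in range(12):
                rows.append({"gene_id": gene, "track_id": f"t{t}",
                             "category": "CONSISTENT_CORRECT" if t < n_correct
                             else "INCONSISTENT"})
        return pd.DataFrame(rows)

    def test_ranking(self):
        assert motifs.select_backgrounds(self._table(), n=1) == ["gA"]

    def test_tie_broken_lexicographically(self):
        assert motifs.select_backgrounds(self._table(), n=2) == ["gA", "gC"]

    def test_zero_requested(self):
        assert motifs.select_backgrounds(self._table(), n=0) == []

    def test_overlong_request_warns_and_returns_all(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            got = motifs.select_backgrounds(self._table(), n=10)
        assert got == ["gA", "gC", "gB"]
        assert any("10" in r.message for r in caplog.records)


class _ConstEnsemble:
    """Mock ensemble: every member ignores sequence content."""

    def __init__(self, m=3, n_bins=8):
        class _Member:
            def __init__(self, n_bins):
                self.n_bins = n_bins

            def predict(self, window, track=None):
                return np.full(self.n_bins, 1.5)

        self.members = [_Member(n_bins) for _ in range(m)]


class TestActivityScores:
    def test_sequence_blind_predictor_scores_zero(self, toy_window, small_model):
        score = motifs.tf_activity_score(
            _ConstEnsemble(n_bins=4), [toy_window], small_model.motifs[0], offset=10)
        np.testing.assert_allclose(score.per_replicate_scores, 0.0)

    def test_planted_activator_positive_at_short_offset(self, small_model, toy_window):
        widx = int(np.argmax(small_model.weights[0]))
        ens = simulate.make_replicate_ensemble(small_model, m=2, sigma=0.0,
                                               seeds=[1, 2])
        score = motifs.tf_activity_score(
            ens, [toy_window], small_model.motifs[widx], offset=10,
            track=small_model.track_ids[0], mode="consensus")
        assert np.all(score.per_replicate_scores > 0)

    def test_single_background_matches_two_call_subtraction(self, small_model,
                                                            toy_window):
        ens = simulate.make_replicate_ensemble(small_model, m=2, sigma=0.0,
                                               seeds=[1, 2])
        motif = small_model.motifs[0]
        score = motifs.tf_activity_score(ens, [toy_window], motif, offset=25,
                                         track=small_model.track_ids[0],
                                         mode="consensus")
        inserted = motifs.insert_motif(toy_window, motif.consensus(), 25)
        expect = []
        for member in ens.members:
            pi = consistency.robust_predict(member, inserted,
                                            track=small_model.track_ids[0])
            pb = consistency.robust_predict(member, toy_window,
                                            track=small_model.track_ids[0])
            expect.append((pi[1] + pi[2]) - (pb[1] + pb[2]))
        np.testing.assert_allclose(score.per_replicate_scores, expect, atol=1e-12)

    def test_disrupting_one_hot_activator_is_negative(self):
        # a one-hot 6-mer activator; the designed mutation zeroes the site
        mat = np.zeros((6, 4))
        mat[np.arange(6), [0, 1, 2, 3, 0, 1]] = 1.0
        motif = PWMMotif("onehot6", mat)
        model = simulate.GroundTruthModel(
            motifs=[motif], weights=np.array([[0.5]]), track_ids=["t"],
            assay_classes=["CAGE"], decay_scale=150.0, receptive_field=512)
        ens = simulate.make_replicate_ensemble(model, m=2, sigma=0.0, seeds=[1, 2])
        rng = np.random.default_rng(1)
        bg = GenomicWindow(chrom="b", start=0,
                           sequence="".join(rng.choice(list("ACGT"), size=512)),
                           anchor=256)
        score = motifs.tf_mutation_activity_score(ens, [bg], motif, offset=10,
                                                  track="t", mode="consensus")
        assert np.all(score.per_replicate_scores < 0)

    def test_mutation_score_is_difference_of_activity_scores(self, small_model,
                                                             toy_window):
        ens = simulate.make_replicate_ensemble(small_model, m=2, sigma=0.0,
                                               seeds=[1, 2])
        motif = small_model.motifs[1]
        kw = dict(track=small_model.track_ids[0], mode="consensus")
        mut_vs_canon = motifs.tf_mutation_activity_score(
            ens, [toy_window], motif, 15, **kw).per_replicate_scores
        canon_vs_bg = motifs.tf_activity_score(
            ens, [toy_window], motif, 15, **kw).per_replicate_scores
        pos, base = motifs.design_disruptive_mutation(motif)
        mutated_seq = motif.consensus()
        mutated_seq = mutated_seq[:pos] + base + mutated_seq[pos + 1:]
        inserted = motifs.insert_motif(toy_window, mutated_seq, 15)
        mut_vs_bg = []
        for member in ens.members:
            pi = consistency.robust_predict(member, inserted,
                                            track=small_model.track_ids[0])
            pb = consistency.robust_predict(member, toy_window,
                                            track=small_model.track_ids[0])
            mut_vs_bg.append((pi[1] + pi[2]) - (pb[1] + pb[2]))
        np.testing.assert_allclose(mut_vs_canon, np.array(mut_vs_bg) - canon_vs_bg,
                                   atol=1e-10)

    def test_odd_bin_count_rejected(self, small_model):
        win = GenomicWindow(chrom="t", start=0, sequence="A" * 384, anchor=192)
        ens = _ConstEnsemble(n_bins=3)
        with pytest.raises(ValueError, match="even"):
            motifs.tf_activity_score(ens, [win], small_model.motifs[0], offset=10)


class TestInconsistencyFraction:
    def _score(self, values):
        return ActivityScore(motif_id="m", track_id="t", offset=10,
                             per_replicate_scores=values, kind="CANONICAL")

    def test_unanimous_scores(self):
        scores = [self._score([1, 2, 3]), self._score([-1, -2, -0.5])]
        assert motifs.inconsistency_fraction(scores) == 0.0

    def test_one_mixed_of_ten(self):
        scores = [self._score([1, 2, 3]) for _ in range(9)]
        scores.append(self._score([1, -2, 3]))
        assert motifs.inconsistency_fraction(scores) == pytest.approx(0.1)

    def test_activity_score_increases_with_motif_weight(self, toy_window):
        import numpy as np

        from seqens.types import PWMMotif

        mat = np.full((6, 4), 0.02)
        mat[np.arange(6), [0, 1, 2, 3, 0, 1]] = 0.94
        motif = PWMMotif("act6", mat / mat.sum(axis=1, keepdims=True))
        scores = []
        for w in (0.2, 0.4):
            model = simulate.GroundTruthModel(
                motifs=[motif], weights=np.array([[w]]), track_ids=["t"],
                assay_classes=["CAGE"], decay_scale=150.0, receptive_field=512,
                match_threshold=0.25, site_saturation=0.8)
            ens = simulate.make_replicate_ensemble(model, m=2, sigma=0.0,
                                                   seeds=[1, 2])
            s = motifs.tf_activity_score(ens, [toy_window], motif, offset=10,
                                         track="t", mode="consensus")
            scores.append(s.per_replicate_scores[0])
        assert scores[1] > scores[0]

    def test_sigma_zero_ensemble_never_inconsistent(self, small_model, toy_window):
        ens = simulate.make_replicate_ensemble(small_model, m=3, sigma=0.0,
                                               seeds=[1, 2, 3])
        scores = [
            motifs.tf_activity_score(ens, [toy_window], motif, offset=o,
                                     track=t, mode="consensus")
            for motif in small_model.motifs[:2]
            for o in (10, 100)
            for t in small_model.track_ids
        ]
        assert motifs.inconsistency_fraction(scores) == 0.0
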