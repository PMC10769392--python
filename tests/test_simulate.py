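"""Synthetic genome, ground-truth model and replicate-ensemble behavior."""

import numpy as np
import pytest
from scipy import stats

from seqens import consistency, simulate
from seqens.types import GenomicWindow, PWMMotif


def brute_force_rates(model, sequence):
    """Independent re-implementation of the ground truth: explicit loops over
    every site, strand and bin (no shared code with the scanner)."""
    import math

    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    n_bins = len(sequence) // model.bin_width
    pre = np.full(n_bins, model.score0)
    for mi, motif in enumerate(model.motifs):
        mat = np.clip(motif.matrix, 1e-6, None)
        l = len(motif)
        tau = simulate.motif_score_threshold(motif, model.match_threshold)
        for strand in ("+", "-"):
            for p in range(len(sequence) - l + 1):
                site = sequence[p:p + l]
                if strand == "-":
                    site = "".join(comp[b] for b in reversed(site))
                score = 0.0
                for j, b in enumerate(site):
                    if b != "N":
                        score += math.log2(mat[j, "ACGT".index(b)] / 0.25)
                score -= tau
                if score <= 0:
                    continue
                if model.site_saturation is not None:
                    score = model.site_saturation * math.tanh(score / model.site_saturation)
                center = p + l / 2.0
                for b in range(n_bins):
                    d = abs(center - (b + 0.5) * model.bin_width)
                    if d <= model.receptive_field / 2.0:
                        pre[b] += (model.weights[0, mi] * score *
                                   math.exp(-d / model.decay_scale))
    return np.log1p(np.exp(pre))  # softplus, sharpness 1


class TestSimulateRegulatoryGenome:
    def test_gc_fraction_concentrates(self, small_model):
        windows, _ = simulate.simulate_regulatory_genome(
            40, 1024, gc=0.5, motif_density=0.0, seed=1,
            motif_library=small_model.motifs)
        gc = np.mean([sum(b in "GC" for b in w.sequence) / w.length for w in windows])
        # binomial: sd of pooled GC over 40*1024 bases ~ 0.0025; 0.02 band
        assert abs(gc - 0.5) < 0.02

    def test_zero_density_plants_nothing(self, small_model):
        _, sites = simulate.simulate_regulatory_genome(
            5, 1024, motif_density=0.0, seed=2, motif_library=small_model.motifs)
        assert sites.empty

    def test_seed_determinism(self, small_model):
        a, sa = simulate.simulate_regulatory_genome(
            4, 1024, seed=9, motif_library=small_model.motifs)
        b, sb = simulate.simulate_regulatory_genome(
            4, 1024, seed=9, motif_library=small_model.motifs)
        assert [w.sequence for w in a] == [w.sequence for w in b]
        assert sa.equals(sb)

    def test_anchor_at_center(self, small_model):
        windows, _ = simulate.simulate_regulatory_genome(
            2, 1024, seed=3, motif_library=small_model.motifs)
        assert all(w.anchor == 512 for w in windows)

    def test_motif_longer_than_window_rejected(self):
        big = PWMMotif("big", np.full((300, 4), 0.25))
        with pytest.raises(ValueError, match="longer"):
            simulate.simulate_regulatory_genome(1, 256, seed=0, motif_library=[big])

    def test_invalid_gc_rejected(self, small_model):
        with pytest.raises(ValueError):
            simulate.simulate_regulatory_genome(1, 256, gc=1.5, seed=0,
                                                motif_library=small_model.motifs)


class TestGroundTruthPredict:
    def test_null_sequence_gives_baseline(self, small_model):
        win = GenomicWindow(chrom="n", start=0, sequence="N" * 1024, anchor=512)
        rates = simulate.ground_truth_predict(small_model, win)
        np.testing.assert_allclose(rates.values, small_model.baseline_rate, rtol=1e-9)

    def test_planted_activator_raises_anchor_bin(self, small_model):
        widx = int(np.argmax(small_model.weights[0]))  # strongest activator
        motif = small_model.motifs[widx]
        base = GenomicWindow(chrom="b", start=0, sequence="N" * 1024, anchor=512)
        seq = list(base.sequence)
        seq[512:512 + len(motif)] = motif.consensus()
        planted = base.with_sequence("".join(seq))
        b = 512 // small_model.bin_width
        before = small_model.predict(base)[b]
        after = small_model.predict(planted)[b]
        assert after > before

    def test_matches_brute_force_oracle(self, small_model):
        rng = np.random.default_rng(5)
        seq = list(rng.choice(list("ACGT"), size=512))
        for widx, pos in [(0, 40), (1, 300)]:
            motif = small_model.motifs[widx]
            seq[pos:pos + len(motif)] = motif.consensus()
        win = GenomicWindow(chrom="o", start=0, sequence="".join(seq), anchor=256)
        np.testing.assert_allclose(
            small_model.predict(win), brute_force_rates(small_model, win.sequence),
            rtol=1e-9)

    def test_strictly_positive_everywhere(self, small_model, small_windows):
        for w in small_windows[0]:
            assert np.all(small_model.predict(w) > 0)

    def test_distal_base_outside_receptive_field_is_ignored(self, small_model):
        # receptive field 512 -> bin 0 (center 64) cannot see position 900
        windows, _ = simulate.simulate_regulatory_genome(
            1, 1024, seed=13, motif_library=small_model.motifs)
        win = windows[0]
        edited = win.with_sequence(
            win.sequence[:900] + ("A" if win.sequence[900] != "A" else "C")
            + win.sequence[901:])
        assert small_model.predict(win)[0] == small_model.predict(edited)[0]


class TestReplicateEnsemble:
    def test_sigma_zero_members_equal_ground_truth(self, small_model, toy_window):
        ens = simulate.make_replicate_ensemble(small_model, m=3, sigma=0.0,
                                               seeds=[1, 2, 3])
        truth = small_model.predict(toy_window)
        for member in ens.members:
            np.testing.assert_array_equal(member.predict(toy_window), truth)

    def test_sigma_positive_members_differ(self, small_ensemble, small_windows):
        preds = simulate.ensemble_robust_predict(
            small_ensemble, small_windows[0],
            track=small_ensemble.model.track_ids[0])
        table = consistency.pairwise_correlation(preds.reshape(5, -1).T)
        assert (table["correlation"] < 1.0).all()

    def test_duplicate_seeds_rejected(self, small_model):
        with pytest.raises(ValueError, match="duplicate"):
            simulate.make_replicate_ensemble(small_model, m=3, sigma=0.1,
                                             seeds=[1, 1, 2])

    def test_m_below_two_rejected(self, small_model):
        with pytest.raises(ValueError, match="M >= 2"):
            simulate.make_replicate_ensemble(small_model, m=1, sigma=0.1, seeds=[1])

    def test_lognormal_weight_mean(self):
        # with unit weight noise and every other component off, member weights
        # are truth * exp(sigma z): mean over draws = exp(sigma^2/2) * truth
        model = simulate.make_ground_truth(n_tracks=1, n_motifs=2, motif_length=5,
                                           seed=3, receptive_field=256,
                                           decay_scale=100, bin_width=128)
        sigma = 0.5
        draws = []
        for block in range(100):
            ens = simulate.make_replicate_ensemble(
                model, m=10, sigma=sigma, seeds=range(block * 10, block * 10 + 10),
                weight_noise=1.0, shared_weight_noise=0.0,
                pwm_noise=0.0, shared_pwm_noise=0.0,
                damaged_weight=0.0, shared_damaged_weight=0.0,
                n_spurious=0, n_shared_spurious=0)
            draws.extend(mem.motif_weights[0] for mem in ens.members)
        draws = np.array(draws)  # (1000, 2)
        expected = np.exp(sigma ** 2 / 2) * model.weights[0]
        se = np.abs(model.weights[0]) * np.sqrt(
            (np.exp(2 * sigma ** 2) - np.exp(sigma ** 2)) / len(draws))
        assert np.all(np.abs(draws.mean(axis=0) - expected) < 3 * se)

    def test_fast_path_equals_generic_robust_predict(self, small_ensemble, toy_window):
        track = small_ensemble.model.track_ids[1]
        fast = simulate.ensemble_robust_predict(small_ensemble, [toy_window],
                                                track=track)[:, 0, :]
        generic = np.array([consistency.robust_predict(m, toy_window, track=track)
                            for m in small_ensemble.members])
        np.testing.assert_allclose(fast, generic, atol=1e-12)


class TestScanner:
    def test_matches_naive_site_scan(self):
        motif = PWMMotif("m", np.array([[0.88, 0.04, 0.04, 0.04],
                                        [0.04, 0.88, 0.04, 0.04],
                                        [0.04, 0.04, 0.88, 0.04]]))
        rng = np.random.default_rng(8)
        seq = "".join(rng.choice(list("ACGT"), size=256)) + "ACG" + "T" * 253
        c = simulate.batch_contributions([motif], [seq], 128, 100.0, 512)[0, 0]
        model = simulate.GroundTruthModel(
            motifs=[motif], weights=np.array([[1.0]]), track_ids=["t"],
            assay_classes=["CAGE"], decay_scale=100.0, receptive_field=512)
        # brute_force_rates uses weight 1 and softplus; invert to compare pre-link
        rates = brute_force_rates(model, seq)
        pre = np.log(np.expm1(rates))
        np.testing.assert_allclose(model.score0 + c, pre, rtol=1e-8)

    def test_n_bases_contribute_zero(self):
        # G background matches neither the A-rich motif nor its T-rich revcomp
        motif = PWMMotif("m", np.array([[0.97, 0.01, 0.01, 0.01]] * 4))
        clean = motif.consensus() + "G" * 124
        with_n = "N" * 4 + "G" * 124
        c1 = simulate.batch_contributions([motif], [with_n], 128, 100.0, 256)
        assert np.all(c1 == 0.0)
        c2 = simulate.batch_contributions([motif], [clean], 128, 100.0, 256)
        assert c2.sum() > 0


class TestSimulateTrackCounts:
    def test_determinism(self, small_model, small_windows):
        rates = simulate.ground_truth_predict(small_model, small_windows[0][0])
        a = simulate.simulate_track_counts(rates, seed=5)
        b = simulate.simulate_track_counts(rates, seed=5)
        np.testing.assert_array_equal(a.values, b.values)

    def test_poisson_mean_concentration(self):
        from seqens.types import TrackTable

        rates = TrackTable("t", "CAGE", np.full(10000, 3.0))
        counts = simulate.simulate_track_counts(rates, seed=1)
        total, expected = counts.values.sum(), 30000.0
        assert abs(total - expected) < 3 * np.sqrt(expected)

    def test_poisson_equidispersion(self):
        from seqens.types import TrackTable

        rates = TrackTable("t", "CAGE", np.full(10000, 4.0))
        counts = simulate.simulate_track_counts(rates, seed=2).values
        assert 0.95 < counts.var() / counts.mean() < 1.05

    def test_nonpositive_rates_rejected(self):
        from seqens.types import TrackTable

        rates = TrackTable("t", "CAGE", np.zeros(4))
        with pytest.raises(ValueError, match="positive"):
            simulate.simulate_track_counts(rates, seed=0)


class TestSimulateEqtls:
    def test_truth_sign_matches_oracle(self, small_model, small_windows):
        from seqens import variants as variant_mod

        windows, sites = small_windows
        eqtls = simulate.simulate_eqtls(windows, sites, n_pos=10, n_neg=5, seed=4,
                                        model=small_model)
        by = {w.chrom: w for w in windows}
        for v in eqtls:
            if v.true_sign is None:
                continue
            w = by[v.chrom]
            anchored = GenomicWindow(chrom=w.chrom, start=0, sequence=w.sequence,
                                     anchor=v.pos)
            sad = variant_mod.sad_score(small_model, anchored, v.ref_allele,
                                        v.alt_allele)
            assert np.sign(sad) == v.true_sign

    def test_no_positives_requested(self, small_model, small_windows):
        windows, sites = small_windows
        eqtls = simulate.simulate_eqtls(windows, sites, n_pos=0, n_neg=8, seed=4,
                                        model=small_model)
        assert len(eqtls) == 8 and all(v.true_sign is None for v in eqtls)

    def test_no_sites_is_an_error(self, small_model, small_windows):
        import pandas as pd

        windows, _ = small_windows
        with pytest.raises(ValueError, match="planted sites"):
            simulate.simulate_eqtls(windows, pd.DataFrame(), n_pos=3, n_neg=0,
                                    seed=0, model=small_model)


@pytest.fixture(scope="module")
def pop_windows(small_model):
    # 10-bin windows: the minimum for the central-ten-bin average
    windows, _ = simulate.simulate_regulatory_genome(
        2, 1280, motif_density=2.0, seed=21, motif_library=small_model.motifs)
    return windows


class TestSimulatePopulation:
    def _panel(self, window):
        out = []
        for pos in (200, 350, 500, 700):
            ref = window.sequence[pos]
            alt = "A" if ref != "A" else "G"
            from seqens.types import VariantRecord

            out.append(VariantRecord(chrom=window.chrom, pos=pos, ref_allele=ref,
                                     alt_allele=alt))
        return out

    def test_full_heritability_perfect_rank_correlation(self, small_model,
                                                        pop_windows):
        from seqens import personal

        window = pop_windows[0]
        panel = self._panel(window)
        genotypes, measured = simulate.simulate_population(
            window, panel, n_individuals=30, allele_freqs=[0.5] * 4, h2=1.0,
            seed=3, model=small_model)
        preds = personal.population_predictions(small_model, window, genotypes, panel)
        if np.ptp(preds[0]) > 0:
            rho = personal.cross_individual_correlation(preds[0], measured)
            assert rho == pytest.approx(1.0)

    def test_null_heritability_centered_at_zero(self, small_model, pop_windows):
        from seqens import personal

        window = pop_windows[1]
        panel = self._panel(window)
        rhos = []
        for seed in range(25):
            genotypes, measured = simulate.simulate_population(
                window, panel, n_individuals=40, allele_freqs=[0.3] * 4, h2=0.0,
                seed=seed, model=small_model)
            preds = personal.population_predictions(small_model, window,
                                                    genotypes, panel)
            r = personal.cross_individual_correlation(preds[0], measured)
            if not np.isnan(r):
                rhos.append(r)
        se = np.std(rhos, ddof=1) / np.sqrt(len(rhos))
        assert abs(np.mean(rhos)) < 3 * se + 1e-12

    def test_dosage_mean_matches_frequency(self, small_model, pop_windows):
        window = pop_windows[0]
        panel = self._panel(window)
        genotypes, _ = simulate.simulate_population(
            window, panel, n_individuals=400, allele_freqs=[0.5] * 4, h2=0.5,
            seed=7, model=small_model)
        mean_dosage = genotypes.sum(axis=2).mean(axis=0)
        se = np.sqrt(0.5 * 0.5 * 2 / 400)
        assert np.all(np.abs(mean_dosage - 1.0) < 3 * se)

    def test_invalid_frequency_rejected(self, small_model, pop_windows):
        window = pop_windows[0]
        panel = self._panel(window)
        with pytest.raises(ValueError, match="frequencies"):
            simulate.simulate_population(window, panel, 10, [1.5] * 4, 0.5, 0,
                                         model=small_model)
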