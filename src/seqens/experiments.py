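"""Reusable experiment drivers over the synthetic ensemble.

Each function sets up a seeded miniature study (ground truth, replicate
ensemble, synthetic dataset), runs one of the pipeline's analyses and
returns its summary numbers. They back the numbered analysis scripts,
the acceptance checks and the test suite, so every reported quantity is
recomputed from scratch at run time.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import motifs as motifs_mod, personal, simulate, variants
from .types import GenomicWindow, VariantEffect, VariantRecord

__all__ = [
    "eqtl_experiment",
    "sigma_sweep_eqtl",
    "motif_direction_experiment",
    "majority_vote_simulation",
    "driver_recovery_run",
    "driver_uncertainty_experiment",
]


def _small_model(seed: int, n_motifs: int = 4, n_tracks: int = 1,
                 length: int = 512) -> simulate.GroundTruthModel:
    return simulate.make_ground_truth(
        n_tracks=n_tracks, n_motifs=n_motifs, seed=seed,
        receptive_field=length // 2, decay_scale=150.0, bin_width=128)


def eqtl_experiment(
    seed: int,
    sigma: float = 0.5,
    n_variants: int = 200,
    n_windows: int = 10,
    length: int = 512,
    m: int = 5,
    ensemble_kwargs: Optional[dict] = None,
) -> pd.DataFrame:
    """Per-variant SAD consistency records for one seeded miniature study.

    Returns the record table from :func:`seqens.variants.eqtl_consistency_table`
    (columns include category and mean_abs_sad).
    """
    model = _small_model(seed, length=length)
    windows, sites = simulate.simulate_regulatory_genome(
        n_windows, length, motif_density=3.0, seed=seed + 1,
        motif_library=model.motifs, bin_width=model.bin_width)
    eqtls = simulate.simulate_eqtls(windows, sites, n_pos=n_variants, n_neg=0,
                                    seed=seed + 2, model=model)
    ens = simulate.make_replicate_ensemble(
        model, m=m, sigma=sigma, seeds=[seed * 100 + i for i in range(m)],
        **(ensemble_kwargs or {}))
    by = {w.chrom: w for w in windows}
    effects = variants.ensemble_sad_table(ens, by, eqtls)
    _, records = variants.eqtl_consistency_table(effects)
    return records


def sigma_sweep_eqtl(
    seed: int,
    sigmas: Sequence[float] = (0.0, 0.1, 0.3, 1.0),
    n_variants: int = 500,
    n_windows: int = 10,
    m: int = 5,
) -> pd.DataFrame:
    """Inconsistent eQTL fraction across a replicate-disagreement grid.

    The windows, variants and member seeds are shared across the sigma
    grid, so the sweep isolates the effect of the perturbation scale.
    """
    model = _small_model(seed)
    windows, sites = simulate.simulate_regulatory_genome(
        n_windows, 512, motif_density=3.0, seed=seed + 1,
        motif_library=model.motifs, bin_width=model.bin_width)
    eqtls = simulate.simulate_eqtls(windows, sites, n_pos=n_variants, n_neg=0,
                                    seed=seed + 2, model=model)
    by = {w.chrom: w for w in windows}
    rows = []
    for sigma in sigmas:
        ens = simulate.make_replicate_ensemble(
            model, m=m, sigma=sigma, seeds=[seed * 100 + i for i in range(m)],
            n_spurious=1, n_shared_spurious=1)
        effects = variants.ensemble_sad_table(ens, by, eqtls)
        _, records = variants.eqtl_consistency_table(effects)
        rows.append({
            "sigma": sigma,
            "inconsistent_fraction": float((records["category"] == "INCONSISTENT").mean()),
        })
    return pd.DataFrame(rows)


def motif_direction_experiment(
    seed: int,
    sigma: float = 0.5,
    offsets: Sequence[int] = (10, 100, 1000),
    n_backgrounds: int = 10,
    n_tracks: int = 4,
    n_motifs: int = 6,
    length: int = 4096,
    m: int = 5,
) -> pd.DataFrame:
    """Canonical vs mutated motif-score inconsistency per track and offset.

    Scores average over ``n_backgrounds`` background genes (the full-scale
    protocol averages over 100): with too few backgrounds, background-texture
    noise swamps the systematic mutation-specific disagreement.
    """
    model = simulate.make_ground_truth(
        n_tracks=n_tracks, n_motifs=n_motifs, seed=seed, receptive_field=length // 2,
        decay_scale=500.0, bin_width=128)
    windows, _ = simulate.simulate_regulatory_genome(
        n_backgrounds, length, motif_density=0.5, seed=seed + 1,
        motif_library=model.motifs, bin_width=model.bin_width)
    ens = simulate.make_replicate_ensemble(
        model, m=m, sigma=sigma, seeds=[seed * 100 + i for i in range(m)])
    _, fracs, _ = motifs_mod.motif_consistency_analysis(
        ens, windows, model.motifs, model.track_ids, offsets=offsets,
        base_seed=seed)
    return fracs


def majority_vote_simulation(
    seed: int,
    n_variants: int = 2000,
    flip_rate: float = 0.3,
    m: int = 5,
) -> Tuple[float, float]:
    """(single, majority) sign accuracies under independent replicate flips.

    Each replicate reports the true sign flipped independently with
    probability ``flip_rate``; the binomial prediction for the majority
    accuracy at m=5, rate 0.3 is sum_{k>=3} C(5,k) 0.7^k 0.3^(5-k).
    """
    rng = np.random.default_rng(seed)
    effects = []
    for i in range(n_variants):
        truth = 1 if rng.random() < 0.5 else -1
        flips = rng.random(m) < flip_rate
        sads = np.where(flips, -truth, truth).astype(float)
        effects.append(VariantEffect(
            variant=VariantRecord(chrom="sim", pos=200 + i, ref_allele="A",
                                  alt_allele="C", true_sign=truth),
            track_id="sim", per_replicate_sad=sads))
    return variants.ensemble_vs_single_accuracy(effects)


def _population_study(model, window, panel, n_individuals, h2, seed, ens):
    genotypes, measured = simulate.simulate_population(
        window, panel, n_individuals=n_individuals, h2=h2, seed=seed, model=model)
    preds = personal.population_predictions(ens, window, genotypes, panel)
    return genotypes, measured, preds


def driver_recovery_run(
    seed: int,
    n_individuals: int = 200,
    n_decoys: int = 30,
    m: int = 5,
) -> bool:
    """One planted-driver recovery run at sigma=0 (noise-free replicates).

    An activator site sits near the TSS; the dominant variant is the
    single-base substitution in that site with the largest ground-truth
    effect on the gene's predicted expression, while ``n_decoys``
    background variants have negligible effects. True iff every
    replicate ranks the planted variant first.
    """
    length = 1280
    # scenario ground truth: stringent matching and no response saturation,
    # so planted sites are strong, the background is quiet, and "dominant"
    # has a sharp meaning (the recovery test probes the driver machinery,
    # not the background-texture regime)
    model = simulate.make_ground_truth(
        n_tracks=1, n_motifs=4, seed=seed, receptive_field=512,
        decay_scale=150.0, bin_width=128,
        match_threshold=0.5, site_saturation=None, pseudocount=0.02)
    site_start = 640 - 40

    # dominant variant: the in-site substitution with the largest effect on
    # the central-ten-bin mean, evaluated under the ground truth. Decoys sit
    # on a spaced grid (so their effects stay additive) and the n_decoys
    # candidates with the smallest effects are kept; windows are resampled
    # until the planted effect truly dominates the decoys' joint variance.
    widx = int(np.argmax(np.abs(model.weights[0])))
    motif = model.motifs[widx]
    best_panel = None
    best_ratio = -1.0
    for attempt in range(12):
        rng = np.random.default_rng(seed + 1 + 10000 * attempt)
        seq = list(rng.choice(list("ACGT"), size=length))
        site_seq = motifs_mod.sample_motif(motif, rng_seed=seed + 5 + 1000 * attempt)
        seq[site_start:site_start + len(motif)] = site_seq
        window = GenomicWindow(chrom=f"run{seed}", start=0, sequence="".join(seq),
                               anchor=640)
        candidates = []
        for pos in range(site_start, site_start + len(motif)):
            ref = window.sequence[pos]
            for alt in "ACGT":
                if alt != ref:
                    candidates.append((pos, ref, alt))
        alt_windows = [window.with_sequence(
            window.sequence[:pos] + alt + window.sequence[pos + 1:])
            for pos, _, alt in candidates]
        preds = simulate.model_robust_predict(model, [window] + alt_windows)
        base10 = preds[0, 3:13].mean()
        effects = np.abs(preds[1:, 3:13].mean(axis=1) - base10)
        dominant_effect = float(effects.max())
        pos0, ref0, alt0 = candidates[int(np.argmax(effects))]

        grid = [p for p in range(140, length - 140, 26)
                if not (site_start - 24 <= p < site_start + len(motif) + 24)]
        rng.shuffle(grid)
        cand = []
        for p in grid:
            ref = window.sequence[p]
            cand.append(VariantRecord(chrom=window.chrom, pos=p, ref_allele=ref,
                                      alt_allele="A" if ref != "A" else "T"))
        alt_w = [window.with_sequence(
            window.sequence[:v.pos] + v.alt_allele + window.sequence[v.pos + 1:])
            for v in cand]
        pp = simulate.model_robust_predict(model, alt_w)
        eff = np.sort(np.abs(pp[:, 3:13].mean(axis=1) - base10),
                      kind="stable")[:n_decoys]
        order = np.argsort(np.abs(pp[:, 3:13].mean(axis=1) - base10),
                           kind="stable")[:n_decoys]
        # the planted variant must dominate both the strongest single decoy
        # and the decoys' joint variance for rank-1 recovery to be expected
        max_e = float(eff.max()) if eff.size else 0.0
        score = min(dominant_effect / max(2.0 * max_e, 1e-9),
                    dominant_effect ** 2 / max(np.sum(eff ** 2), 1e-12))
        if score > best_ratio:
            best_ratio = score
            pan = [VariantRecord(chrom=window.chrom, pos=pos0,
                                 ref_allele=ref0, alt_allele=alt0)]
            pan.extend(cand[i] for i in order)
            best_panel = (window, pan)
        if score >= 2.0:
            break
    window, panel = best_panel

    ens = simulate.make_replicate_ensemble(
        model, m=m, sigma=0.0, seeds=[seed * 100 + i for i in range(m)])
    freqs = np.full(len(panel), 0.3)
    genotypes, _ = simulate.simulate_population(
        window, panel, n_individuals=n_individuals, allele_freqs=freqs, h2=1.0,
        seed=seed + 2, model=model)
    preds = personal.population_predictions(ens, window, genotypes, panel)
    dosages = genotypes.sum(axis=2)
    for rep in range(m):
        drivers = personal.identify_drivers(dosages, preds[rep], panel,
                                            window.chrom, replicate_index=rep)
        if not drivers or drivers[0].variant.pos != pos0:
            return False
    return True


def driver_uncertainty_experiment(
    seed: int,
    sigma: float = 0.5,
    n_genes: int = 6,
    n_individuals: int = 36,
    n_variants_per_gene: int = 14,
    n_extremes: int = 2,
    h2: float = 0.4,
    m: int = 5,
) -> pd.DataFrame:
    """Driver reproducibility for high- vs low-uncertainty genes.

    Returns one row per (gene, driver variant) with the number of
    replicates that identified it and the gene's uncertainty class.
    """
    length = 1280
    model = simulate.make_ground_truth(
        n_tracks=1, n_motifs=4, seed=seed, receptive_field=512,
        decay_scale=150.0, bin_width=128)
    windows, sites = simulate.simulate_regulatory_genome(
        n_genes, length, motif_density=2.0, seed=seed + 1,
        motif_library=model.motifs, bin_width=model.bin_width)
    ens = simulate.make_replicate_ensemble(
        model, m=m, sigma=sigma, seeds=[seed * 100 + i for i in range(m)],
        n_spurious=1, n_shared_spurious=1)
    rng = np.random.default_rng(seed + 3)

    per_gene_rhos: Dict[str, List[float]] = {}
    gene_data = {}
    for w in windows:
        gene_sites = sites[sites["chrom"] == w.chrom]
        positions: List[int] = []
        for _, row in gene_sites.iterrows():
            positions.extend(p for p in range(int(row["start"]), int(row["end"]))
                             if 128 <= p < length - 128)
        rng.shuffle(positions)
        positions = positions[:n_variants_per_gene // 2]
        while len(positions) < n_variants_per_gene:
            p = int(rng.integers(128, length - 128))
            if p not in positions:
                positions.append(p)
        panel = []
        for p in sorted(set(positions)):
            ref = w.sequence[p]
            panel.append(VariantRecord(chrom=w.chrom, pos=p, ref_allele=ref,
                                       alt_allele="A" if ref != "A" else "T"))
        genotypes, measured, preds = _population_study(
            model, w, panel, n_individuals, h2, int(rng.integers(2**31)), ens)
        rhos = [personal.cross_individual_correlation(preds[i], measured)
                for i in range(m)]
        per_gene_rhos[w.chrom] = rhos
        gene_data[w.chrom] = (panel, genotypes, preds)

    table = personal.gene_uncertainty_table(per_gene_rhos)
    high, low = personal.select_uncertainty_extremes(table, n=n_extremes)
    classes = {g.gene_id: g.uncertainty_class for g in table}

    driver_sets = {}
    for g in list(high) + list(low):
        panel, genotypes, preds = gene_data[g.gene_id]
        dosages = genotypes.sum(axis=2)
        for rep in range(m):
            driver_sets[(g.gene_id, rep)] = personal.identify_drivers(
                dosages, preds[rep], panel, g.gene_id, replicate_index=rep)
    repro, _ = personal.driver_concordance(driver_sets, pd.DataFrame(), classes, m=m)
    return repro
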