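# seqens

Ensemble-consistency uncertainty analysis for genomic sequence-to-activity
models, with a synthetic replicate-ensemble simulator.

Deep sequence-to-activity models predict accessibility, TF binding,
histone marks and expression in 128 bp bins directly from DNA. An
inexpensive way to ask *where such a model is uncertain* is to train
several replicates that differ only in their random seeds and measure
where their predictions agree. `seqens` implements that analysis as a
reusable pipeline — consistency classification on reference sequences,
motif-perturbed sequences, variants (eQTLs) and personal genomes — with
a fully synthetic stand-in for the expensive part: a known ground-truth
regulatory model plus an ensemble of seed-perturbed replicate predictors
with tunable disagreement. It is aimed at people studying uncertainty
quantification for regulatory genomics models who want a controlled,
CPU-sized test bed where the true effect of every variant is known.

## The statistic at the core

For a binary question derived from predictions (does the alternate
allele increase expression? is this bin a peak?), the ensemble sign
probability over M replicates f<sub>θ1</sub> … f<sub>θM</sub> is

&nbsp;&nbsp;&nbsp;&nbsp;Pr(y<sub>alt</sub> − y<sub>ref</sub> > 0) ≈ (1/M) Σᵢ 1{ f<sub>θi</sub>(x<sub>alt</sub>) − f<sub>θi</sub>(x<sub>ref</sub>) > 0 }.

A unit is **consistent** when the probability is exactly 0 or 1,
**inconsistent** otherwise; against ground truth, consistent units split
into **consistently correct** and **consistently incorrect**. Because
per-replicate predictions are Poisson rates, the ensemble average is a
Poisson mixture and always overdispersed (law of total variance); the
package carries the closed-form moments. The same recipe is applied to
Poisson-null peak calls (BH-corrected at 1% FDR), TF activity scores
(motif insertion at fixed offsets upstream of a TSS, with a designed
disruptive mutation), signed SAD variant-effect scores (alt − ref over
the three bins at the variant), and cross-individual expression
predictions from phased haplotypes, exactly mirroring the analysis
stages used with real replicate ensembles. All predictions average the
six augmentations {±1 bp shift, 0} × {forward, reverse complement}.

The synthetic ensemble is documented in `docs/methods.md`: a thresholded,
saturating PWM-match ground truth, and replicates that share it up to
seeded perturbations (weight noise, motif-recognition noise, a
member-random damaged-site response, positional bias, spurious motifs —
each with a component shared across members to emulate common
training-data bias). At `sigma = 0` every replicate equals the ground
truth bitwise, and every inconsistency measure collapses to zero.

## Worked example

```python
from seqens import simulate, variants

# ground truth + five seed-perturbed replicates
model = simulate.make_ground_truth(n_tracks=2, n_motifs=6, seed=0)
ensemble = simulate.make_replicate_ensemble(model, m=5, sigma=0.5)

# a small synthetic regulatory genome with planted motif instances
windows, sites = simulate.simulate_regulatory_genome(
    n_windows=12, length=4096, motif_density=1.0, seed=0,
    motif_library=model.motifs)

# variants in planted motifs with known true effect direction
eqtls = simulate.simulate_eqtls(windows, sites, n_pos=60, n_neg=0,
                                seed=0, model=model)

# per-replicate SAD scores and sign-consistency categories
effects = variants.ensemble_sad_table(
    ensemble, {w.chrom: w for w in windows}, eqtls,
    track=model.track_ids[0])
proportions, records = variants.eqtl_consistency_table(effects)
print(proportions)
single, majority = variants.ensemble_vs_single_accuracy(effects)
print(f"sign accuracy: single replicate {single:.3f}, majority vote {majority:.3f}")
```

prints

```
CONSISTENT_CORRECT      0.416667
INCONSISTENT            0.516667
CONSISTENT_INCORRECT    0.066667
Name: proportion, dtype: float64
sign accuracy: single replicate 0.733, majority vote 0.750
```

Half of the variant effect signs are predicted inconsistently across the
five replicates; of the consistently predicted ones most — but not all —
are correct; and the ensemble majority vote barely improves on a single
replicate. These are the qualitative signatures of replicate-ensemble
uncertainty on out-of-distribution (variant) sequences.

## Analysis scripts and CLI

The numbered scripts under `analysis/` walk the full study and write
their tables under `results/`:

1. `01_simulate_ensemble.py` — synthetic genome + replicate agreement,
2. `02_reference_consistency.py` — Poisson peak calls and the per-bin
   consistency breakdown (all bins / peaks / TSS peaks),
3. `03_motif_perturbation.py` — TF activity and mutation activity scores,
4. `04_eqtl_consistency.py` — SAD sign consistency, effect-size
   stratification, majority vote, and the disagreement-scale sweep,
5. `05_personal_genomes.py` — haplotype predictions, gene uncertainty,
   drivers and their reproducibility.

The same stages are available as a subcommand CLI (`seqens simulate|
peaks|consistency|motif|eqtl|personal|report --out DIR [--config cfg.yaml]`),
driven by a YAML config; reruns with the same config and seed produce
byte-identical tables.

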