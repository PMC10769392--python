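# Methods

`seqens` studies a single question: when several replicates of a genomic
sequence-to-activity model are trained identically except for their random
seeds, where do their predictions agree and where do they diverge? Because
training real replicate networks is outside the scope of a desk-scale
package, the replicates here are *simulated*: a known ground-truth model
generates activity from sequence, and an ensemble of seed-perturbed copies
of that ground truth stands in for independently trained replicates. Every
downstream analysis (peak consistency, motif perturbation, variant effects,
personal genomes) then runs exactly as it would against real model output.

## Consistency framework

For any binary question derived from predictions (is this bin a peak? does
this variant increase expression?), the ensemble sign probability is the
fraction of the M replicates answering "yes":

    Pr(delta > 0) ~ (1/M) * #{i : delta_i > 0}.

A strict inequality is used, so a delta of exactly zero counts as "not
increased"; with continuous predictors exact zeros arise only in degenerate
inputs. A unit is **consistent** when the fraction is exactly 0 or 1 and
**inconsistent** otherwise; with ground truth available, consistent units
split into **consistently correct** and **consistently incorrect**. The
same recipe is applied to peak labels, TF activity score signs, SAD signs
and driver effect signs, via a caller-supplied binarization.

Because each replicate's predicted counts are Poisson rates, the ensemble
average is a Poisson mixture; its moments follow the law of total variance
(mean `sum w_i lam_i`, variance `mean + sum w_i (lam_i - mean)^2`), so the
mixture is overdispersed whenever the components disagree.
`poisson_mixture_moments` implements this closed form.

All predictions are augmentation-averaged (`robust_predict`): the mean over
six variants of the input — shifts of −1/0/+1 bp crossed with forward and
reverse-complement orientation, reverse-complement outputs re-reversed to
forward bin order, shifted ends padded with N. Six (not four) terms are
used: it is the standard augmentation ensemble for this model family, and
the alternative reading changes nothing qualitative.

## The ground-truth model

The ground truth is a miniature sequence-to-activity function:

* **Geometry.** Windows of 4,096 bp in 128 bp bins (32 bins), TSS at the
  central bin junction; receptive field 2,048 bp (a bin only sees sequence
  within ±1,024 bp of its center); all sizes configurable. This preserves
  the geometry of the full-scale convention (131 kb windows, 128 bp bins,
  ~55 kb receptive field, TSS between the central two bins) at roughly
  1/32 scale.
* **Motif matches.** A library of synthetic PWMs (default 8 motifs of 8 bp,
  per-column consensus probability 0.6–0.95 with a 0.06 pseudocount floor,
  as applied to empirical count matrices — a single disruptive substitution
  weakens a site without erasing it). Both strands are scanned with
  log2-odds scores against a uniform background; only sites scoring above
  25% of a motif's maximum achievable score contribute. A threshold is
  essential: with an unthresholded rule the dense field of weak partial
  matches accumulates over the decay range and saturates the link, burying
  planted signals (we observed pre-link scores of ±70).
* **Saturating response.** A site's contribution is not its raw excess
  score but `0.8 * tanh(excess / 0.8)`: strong sites respond by *presence*
  rather than score, as trained networks do. This is load-bearing for the
  uncertainty structure. Without saturation, a one-base disruption removes
  more score than a sampled site holds above threshold, so mutation
  effects are as large and as sign-stable as canonical insertion effects —
  the opposite of what real replicate ensembles show. With it, intact
  sites sit on the flat part of the response (stable across replicates)
  while damaged sites carry small residual effects whose direction is
  member-dependent.
* **Rates.** Each (saturated) site contribution is weighted by a signed
  per-track effect weight (~0.1–0.5, 70% activators, lognormal per-track
  modulation) and an exponential distance decay `exp(-d / 500 bp)`
  truncated at half the receptive field. Per-bin rate = softplus(baseline
  + contributions), baseline 2 counts per bin, so rates are strictly
  positive. Experimental data are Poisson samples of these rates.

## The replicate ensemble

Replicates trained from different seeds agree on what the data pin down
and diverge where the data are uninformative. The simulator realizes this
with a perturbation family whose overall scale is `sigma` (default 0.5);
every component has a member-specific part and a part **shared** by all
members (the bias inherited from the common finite training set — shared
errors are what produce *consistently incorrect* predictions). At
`sigma = 0` all members equal the ground truth bitwise.

1. **Effect-weight noise** — each motif weight multiplied by
   `exp(sigma * (0.25 z_shared + 0.35 z_i))`. Magnitude-only: it cannot
   flip a prediction's direction.
2. **Recognition noise** — each member carries its own perturbed copy of
   every PWM, with log-probability noise damped by (1 − p): consensus
   recognition is stable across members, rare-base entries (partial and
   mutated matches) are member-dependent (scales 0.6 member / 0.8 shared).
3. **Damaged-site response** — a triangular score band between half the
   match threshold and the threshold itself (zero for intact sites)
   carries a member-random *signed* weight, normalized to unit
   background-field standard deviation and acting over a 1.6× longer
   decay range (scales 0.45 member / 0.35 shared). This encodes genuine disagreement about whether a broken or
   partial motif retains function — the ingredient that produces sign
   flips for mutated motifs and weak variants, which no multiplicative
   perturbation can.
4. **Positional bias** — a low-amplitude smooth cosine field per member
   and track (0.1 member / 0.05 shared), affecting absolute levels but
   cancelling in any insertion or allele difference.
5. **Spurious motifs** — a few member-private low-information PWMs with
   small weights and a short (64 bp) interaction range, again normalized
   to unit background-field std: local sequence texture only that member
   responds to.

The scales were fixed during generator design so that, at the default
`sigma = 0.5`, the ensemble reproduces the qualitative regime reported for
real replicate ensembles — high agreement on reference sequences (median
pairwise Pearson r ≈ 0.8 across bins at the 4 kb geometry), roughly half
of variant-effect signs inconsistent, a small nonzero consistently-
incorrect fraction, mutation scores less consistent than canonical
scores, and inconsistency growing with the disagreement scale and with
insertion distance. `sigma` and every component scale are exposed as
parameters; nothing downstream depends on the defaults beyond this
qualitative regime.

For efficiency, all members' motif variants are scanned in one pass per
sequence (the scan is identical for every track), and augmented-window
contributions can be cached and reused across members and across a sigma
grid built from the same member seeds. The batch path is verified
bit-compatible with the naive per-member, per-window path.

## Stage-specific procedures

* **Peaks.** Per track, per-bin upper-tail p-values against a Poisson null
  with lambda = mean activity over all bins; values rounded half-up before
  the integer-valued tail; Benjamini-Hochberg across the track's bins at
  FDR 0.01 (the FDR procedure is BH by choice; an all-zero track yields no
  peaks). A TSS bin is a central bin flanking the TSS junction. Ten-fold
  reference downsampling is deterministic stride-10 after coordinate sort.
* **Saliency.** Attributions are per-nucleotide in-silico substitution
  scores (mean |change| of the central-two-bin output over the three
  alternative bases) — a gradient-free stand-in exact for any predictor —
  summed as absolute values in 128 bp bins before replicate comparison.
* **Motif perturbation.** Insertion means in-place substitution ending
  `offset` bp upstream of the TSS (window length fixed; a true insertion
  would shift all downstream coordinates). One motif realization is
  sampled per (motif, background) pair, seeded by that pair and fixed
  across replicates, isolating model uncertainty from sampling noise; a
  consensus mode gives deterministic tests. The disruptive mutation is the
  lowest-entropy PWM position mutated to its lowest-probability base
  (never the consensus; ties leftmost / alphabetical). Scores sum the
  central two bins; backgrounds are the genes predicted consistently
  correctly across the most tracks.
* **Variant effects.** The signed SAD score sums alt-minus-ref over the
  bin containing the variant ±1 (variants within one bin of the window
  edge are rejected rather than truncated). Simulated positives play the
  role of fine-mapped eQTLs: candidate substitutions in planted motifs
  are resampled until their ground-truth effect exceeds 0.02 counts, so
  every positive has a real effect of known direction. Sign analyses need the signed
  value; the absolute value is derived from it. Variant filters, in
  order: drop variants with opposite effect signs on different genes, drop
  pairs farther from the TSS than the receptive field, keep the closest
  gene per variant. Matched negatives carry unknown truth and are excluded
  from accuracy. Majority vote breaks exact 0.5 ties toward "non-positive".
* **Personal genomes.** Haplotypes substitute phased SNV alleles into the
  reference window; individual prediction = mean of the two haplotype
  means over the ten bins centered on the TSS junction (5 per side).
  Cross-individual Spearman uses average ranks; a constant vector is
  flagged undefined, and such genes are never classified. Gene uncertainty
  = sample variance (ddof 1) of the M correlations, restricted to genes
  with mean |rho| >= 0.1. The ensemble predictor averages within-replicate
  expression ranks. The driver rule is a reconstruction (the procedure in
  the source literature is not fully specified): variants ranked by
  squared dosage-prediction Pearson correlation, accepted greedily while
  the residualized incremental explained variance is >= 0.05, at most 6
  per gene; records are ordered by explained variance.

## Scenario constructions

Two analyses use purpose-built scenarios rather than the default genome:

* The **motif-perturbation comparison** averages activity scores over 10
  background genes (the full-scale protocol uses 100). The number of
  backgrounds matters: the canonical score compares a motif-inserted
  window against background and therefore carries the member-private
  texture response of the whole replaced interval, which the mutation
  score (mutated vs canonical insertion) cancels. With too few
  backgrounds that asymmetric noise swamps the systematic
  mutation-specific disagreement.
* The **planted-driver recovery** scenario uses a ground truth with
  stringent matching (50% threshold, no saturation) so that the
  background is quiet and "dominant" is sharply defined: the dominant
  variant is the in-site substitution with the largest ground-truth
  effect, and the 30 decoys are spaced (additive) background variants
  screened for negligible effects. The scenario probes the
  driver-identification machinery, not the background-texture regime.

## Synthetic population

Haplotype alleles are drawn independently at their stated frequencies —
no linkage disequilibrium, no relatedness, no coalescent structure.
Measured expression is the standardized ground-truth individual prediction
scaled to variance h² (default 0.3) plus Gaussian noise of variance 1−h².
Passing tests therefore demonstrate the *consistency machinery* and the
qualitative uncertainty structure, not performance on real cohorts: real
training data add LD between variants, shared technical noise between
experiments and model, and far richer sequence context.

## Problem sizes

Default desk-scale runs use 24–48 windows of 4,096 bp, 8 tracks, M = 5,
150 positive + 150 negative variants, 6–8 backgrounds × 8 motifs × 3
offsets, and 8–12 genes × 60–100 individuals; the test suite uses smaller
windows (512–1,280 bp) with the same geometry rules. The full-scale
replicate count (M = 5) and the offset grid {10, 100, 1000} bp are kept;
the 10,000 bp offset of the full-scale protocol exceeds the miniature
receptive field and is omitted.

## Known limitations

* The perturbation family is a modeling choice; no generative account of
  real replicate disagreement exists to calibrate against, so only the
  qualitative orderings above are meaningful.
* At full scale, real replicates combine reference correlations > 0.9 with
  ~55% inconsistent eQTL signs; the miniature model reaches reference
  correlations ~0.8 at paper-like variant inconsistency. The
  mutation-vs-canonical inconsistency ordering is reproduced but with a
  small margin (~0.03): in any monotone site-scoring ground truth a
  member's scorer ranks a canonical site above its mutated version, so
  mutation-score sign flips can only arise through the damaged-site
  response and background texture, not through score ordering itself.
* The consistently-incorrect fraction for variants stays small (a few
  percent): shared perturbations flip few true signs in the miniature
  model, whereas real ensembles share much stronger training-data biases.
* Ground-truth SAD signs define variant truth, so "correctness" here means
  agreement with the data-generating model, not with any experiment.
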