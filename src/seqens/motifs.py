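"""TF motif insertion and mutation protocol.

For each TF motif, a sampled motif sequence is substituted in place at a
fixed offset upstream of a background gene's TSS. The TF activity score
is the central-two-bin prediction difference between the inserted and
background sequence; the TF mutation activity score compares the
canonical insertion against the same insertion carrying a single
disruptive point mutation (lowest-entropy PWM position mutated to its
lowest-probability base). Replicate disagreement on score signs is
summarized as an inconsistency fraction per track/offset.
"""

from __future__ import annotations

import zlib
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import consistency
from .types import CONSISTENT_CORRECT, ActivityScore, GenomicWindow, PWMMotif

__all__ = [
    "column_entropy",
    "design_disruptive_mutation",
    "mutation_probability",
    "sample_motif",
    "insert_motif",
    "select_backgrounds",
    "tf_activity_score",
    "tf_mutation_activity_score",
    "inconsistency_fraction",
    "motif_consistency_analysis",
    "DEFAULT_OFFSETS",
]

DEFAULT_OFFSETS = (10, 100, 1000, 10000)
_BASES = "ACGT"


def column_entropy(pwm: PWMMotif) -> np.ndarray:
    """Shannon entropy (bits) of each PWM position."""
    return pwm.column_entropies


def design_disruptive_mutation(pwm: PWMMotif) -> Tuple[int, str]:
    """The single most disruptive point mutation for a motif.

    Position: lowest-entropy PWM column (leftmost on ties). Base: the
    lowest-probability base there (alphabetical on ties), never the
    consensus base.
    """
    entropies = pwm.column_entropies
    position = int(np.argmin(entropies))
    row = pwm.matrix[position]
    consensus = int(np.argmax(row))
    candidates = [i for i in range(4) if i != consensus]
    base = min(candidates, key=lambda i: (row[i], i))
    return position, _BASES[base]


def mutation_probability(pwm: PWMMotif, position: int, base: str) -> float:
    """PWM probability of the mutant base at the mutated position."""
    return float(pwm.matrix[position, _BASES.index(base)])


def sample_motif(pwm: PWMMotif, rng_seed: int = 0, mode: str = "sample") -> str:
    """Draw a motif sequence from the PWM (or its consensus)."""
    if mode == "consensus":
        return pwm.consensus()
    if mode != "sample":
        raise ValueError(f"mode must be 'sample' or 'consensus', got {mode!r}")
    rng = np.random.default_rng(rng_seed)
    return "".join(_BASES[rng.choice(4, p=row)] for row in pwm.matrix)


def insert_motif(background: GenomicWindow, motif_seq: str, offset_upstream: int) -> GenomicWindow:
    """Substitute ``motif_seq`` in place, ending ``offset_upstream`` bp before the TSS.

    The replaced interval is [anchor - offset - L, anchor - offset) in
    0-based half-open coordinates; window length is preserved.
    """
    if offset_upstream < 1:
        raise ValueError("offset must be >= 1 bp (motif may not overlap the TSS)")
    end = background.anchor - offset_upstream
    start = end - len(motif_seq)
    if start < 0:
        raise ValueError(
            f"motif of length {len(motif_seq)} at offset {offset_upstream} "
            "exits the window")
    seq = background.sequence
    return background.with_sequence(seq[:start] + motif_seq + seq[end:])


def select_backgrounds(consistency_table: pd.DataFrame, n: int = 100) -> List[str]:
    """Genes predicted consistently correctly across the most tracks.

    ``consistency_table`` has columns gene_id, track_id, category; genes
    are ranked by the count of CONSISTENT_CORRECT tracks (ties broken by
    gene id) and the top ``n`` returned.
    """
    if consistency_table.empty:
        raise ValueError("empty consistency table")
    counts = (
        consistency_table.assign(correct=lambda d: d["category"] == CONSISTENT_CORRECT)
        .groupby("gene_id")["correct"].sum()
    )
    ranked = sorted(counts.index, key=lambda g: (-counts[g], g))
    if n > len(ranked):
        import logging

        logging.getLogger(__name__).warning(
            "requested %d backgrounds but only %d genes available", n, len(ranked))
    return ranked[:max(n, 0)]


def _central_two_bins(n_bins: int) -> Tuple[int, int]:
    if n_bins % 2 != 0:
        raise ValueError("central-two-bin scoring needs an even bin count "
                         "(TSS at a bin junction)")
    return n_bins // 2 - 1, n_bins // 2


def _pair_seed(motif_id: str, background_id: str, base_seed: int = 0) -> int:
    return (zlib.crc32(f"{base_seed}|{motif_id}|{background_id}".encode()) & 0x7FFFFFFF)


def _robust_matrix(ensemble, windows: Sequence[GenomicWindow], track) -> np.ndarray:
    """(M, n_windows, n_bins) robust predictions; fast path for synthetic ensembles."""
    from . import simulate

    if isinstance(ensemble, simulate.ReplicateEnsemble):
        return simulate.ensemble_robust_predict(ensemble, windows, track=track)
    members = getattr(ensemble, "members", ensemble)
    return np.array([
        [consistency.robust_predict(m, w, track=track) for w in windows]
        for m in members
    ])


def _central_scores(pred: np.ndarray) -> np.ndarray:
    lo, hi = _central_two_bins(pred.shape[-1])
    return pred[..., lo] + pred[..., hi]


def _motif_windows(backgrounds, motif, offset, mode, base_seed, mutate):
    out = []
    for bg in backgrounds:
        seq = sample_motif(motif, rng_seed=_pair_seed(motif.motif_id, bg.chrom, base_seed),
                           mode=mode)
        if mutate:
            pos, base = design_disruptive_mutation(motif)
            seq = seq[:pos] + base + seq[pos + 1:]
        out.append(insert_motif(bg, seq, offset))
    return out


def tf_activity_score(
    ensemble,
    backgrounds: Sequence[GenomicWindow],
    motif: PWMMotif,
    offset: int,
    track: Optional[str] = None,
    mode: str = "sample",
    base_seed: int = 0,
    background_predictions: Optional[np.ndarray] = None,
) -> ActivityScore:
    """Per-replicate TF activity score (canonical motif vs background).

    One motif realization is sampled per (motif, background) pair, fixed
    across replicates; for each replicate the score is the mean over
    backgrounds of the central-two-bin prediction difference between the
    motif-inserted and the background window.
    """
    if not backgrounds:
        raise ValueError("need at least one background window")
    inserted = _motif_windows(backgrounds, motif, offset, mode, base_seed, mutate=False)
    if background_predictions is None:
        background_predictions = _robust_matrix(ensemble, backgrounds, track)
    ins_pred = _robust_matrix(ensemble, inserted, track)
    scores = (_central_scores(ins_pred) - _central_scores(background_predictions)).mean(axis=1)
    return ActivityScore(motif_id=motif.motif_id, track_id=track or "",
                         offset=offset, per_replicate_scores=scores, kind="CANONICAL")


def tf_mutation_activity_score(
    ensemble,
    backgrounds: Sequence[GenomicWindow],
    motif: PWMMotif,
    offset: int,
    track: Optional[str] = None,
    mode: str = "sample",
    base_seed: int = 0,
) -> ActivityScore:
    """Per-replicate TF mutation activity score (mutated vs canonical motif)."""
    if not backgrounds:
        raise ValueError("need at least one background window")
    canonical = _motif_windows(backgrounds, motif, offset, mode, base_seed, mutate=False)
    mutated = _motif_windows(backgrounds, motif, offset, mode, base_seed, mutate=True)
    canon_pred = _robust_matrix(ensemble, canonical, track)
    mut_pred = _robust_matrix(ensemble, mutated, track)
    scores = (_central_scores(mut_pred) - _central_scores(canon_pred)).mean(axis=1)
    return ActivityScore(motif_id=motif.motif_id, track_id=track or "",
                         offset=offset, per_replicate_scores=scores, kind="MUTATION")


def inconsistency_fraction(scores: Sequence[ActivityScore]) -> float:
    """Fraction of motifs whose per-replicate score signs are not unanimous."""
    if not scores:
        raise ValueError("need at least one motif score")
    n_mixed = 0
    for s in scores:
        p = consistency.ensemble_sign_probability(s.per_replicate_scores)
        if 0.0 < p < 1.0:
            n_mixed += 1
    return n_mixed / len(scores)


def motif_consistency_analysis(
    ensemble,
    backgrounds: Sequence[GenomicWindow],
    motif_library: Sequence[PWMMotif],
    tracks: Sequence[str],
    offsets: Sequence[int] = (10, 100, 1000),
    mode: str = "sample",
    base_seed: int = 0,
) -> Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """The full canonical-vs-mutation comparison over tracks and offsets.

    Returns (long score table, per track/offset/kind inconsistency table,
    per-offset summary with one-sided Mann-Whitney p-values for
    "mutation-score inconsistency exceeds canonical-score inconsistency"
    across tracks, BH-adjusted over offsets).
    """
    from . import simulate

    fast = isinstance(ensemble, simulate.ReplicateEnsemble)

    def _contrib(windows):
        if not fast:
            return None
        model = ensemble.model
        return simulate.robust_window_contributions(
            ensemble.scan_motifs, windows, model.bin_width, model.decay_scale,
            model.receptive_field, decay_scales=ensemble.scan_decay_scales,
            match_threshold=model.match_threshold,
            match_fractions=ensemble.scan_match_fractions)

    def _preds(windows, contrib, track):
        if fast:
            return simulate.ensemble_robust_predict(ensemble, windows, track=track,
                                                    contributions=contrib)
        return _robust_matrix(ensemble, windows, track)

    # sequence scans are track-independent: build and scan each window set
    # once, then score every track against the cached contributions
    bg_contrib = _contrib(backgrounds)
    window_sets = {}
    for offset in offsets:
        for motif in motif_library:
            canon = _motif_windows(backgrounds, motif, offset, mode, base_seed, False)
            mut = _motif_windows(backgrounds, motif, offset, mode, base_seed, True)
            window_sets[(offset, motif.motif_id)] = (
                canon, _contrib(canon), mut, _contrib(mut))

    score_rows, frac_rows = [], []
    fracs: Dict[Tuple[int, str], List[float]] = {}
    for track in tracks:
        bg_pred = _central_scores(_preds(backgrounds, bg_contrib, track))
        for offset in offsets:
            per_kind = {"CANONICAL": [], "MUTATION": []}
            for motif in motif_library:
                canon_w, canon_c, mut_w, mut_c = window_sets[(offset, motif.motif_id)]
                canon_pred = _central_scores(_preds(canon_w, canon_c, track))
                mut_pred = _central_scores(_preds(mut_w, mut_c, track))
                canon = ActivityScore(
                    motif_id=motif.motif_id, track_id=track, offset=offset,
                    per_replicate_scores=(canon_pred - bg_pred).mean(axis=1),
                    kind="CANONICAL")
                mut = ActivityScore(
                    motif_id=motif.motif_id, track_id=track, offset=offset,
                    per_replicate_scores=(mut_pred - canon_pred).mean(axis=1),
                    kind="MUTATION")
                for score in (canon, mut):
                    per_kind[score.kind].append(score)
                    for rep, val in enumerate(score.per_replicate_scores):
                        score_rows.append({
                            "motif_id": motif.motif_id, "track_id": track,
                            "offset": offset, "kind": score.kind,
                            "replicate": rep, "score": val,
                        })
            for kind, kscores in per_kind.items():
                frac = inconsistency_fraction(kscores)
                frac_rows.append({"track_id": track, "offset": offset,
                                  "kind": kind, "inconsistency_fraction": frac})
                fracs.setdefault((offset, kind), []).append(frac)

    summary_rows = []
    for offset in offsets:
        p = consistency.group_compare(fracs[(offset, "MUTATION")],
                                      fracs[(offset, "CANONICAL")],
                                      alternative="greater")
        summary_rows.append({
            "offset": offset,
            "mean_canonical_inconsistency": float(np.mean(fracs[(offset, "CANONICAL")])),
            "mean_mutation_inconsistency": float(np.mean(fracs[(offset, "MUTATION")])),
            "p_value": p,
        })
    summary = pd.DataFrame(summary_rows)
    summary["p_adjusted"] = consistency.benjamini_hochberg(summary["p_value"].to_numpy())
    return pd.DataFrame(score_rows), pd.DataFrame(frac_rows), summary
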