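"""Ensemble-consistency machinery.

The central quantity is the ensemble sign probability: the fraction of
replicate models whose point estimates predict an increase,

    Pr(delta > 0) ~ (1/M) * #{i : delta_i > 0},

used as a coarse uncertainty estimate for binary questions (does a
variant increase expression? is a bin a peak?). A unit is *consistent*
when the fraction is exactly 0 or 1 and *inconsistent* otherwise;
consistent units split into correct/incorrect when ground truth exists.
"""

from __future__ import annotations

import itertools
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import (
    CONSISTENT_CORRECT,
    CONSISTENT_INCORRECT,
    CONSISTENT_NO_TRUTH,
    INCONSISTENT,
    ConsistencyRecord,
    GenomicWindow,
    MixtureMoments,
)

__all__ = [
    "ensemble_sign_probability",
    "classify_consistency",
    "poisson_mixture_moments",
    "robust_predict",
    "augmented_windows",
    "saliency_window_scores",
    "pairwise_correlation",
    "group_compare",
    "benjamini_hochberg",
    "ism_attributions",
    "downsample_stride",
]


def ensemble_sign_probability(per_replicate_deltas: Sequence[float]) -> float:
    """Fraction of replicates with a strictly positive delta.

    A delta of exactly 0 counts as "not increased" (strict inequality).
    """
    deltas = np.asarray(per_replicate_deltas, dtype=float)
    if deltas.size < 2:
        raise ValueError("need at least 2 replicates")
    nan_idx = np.flatnonzero(np.isnan(deltas))
    if nan_idx.size:
        raise ValueError(f"NaN delta for replicate(s) {nan_idx.tolist()}")
    return float(np.count_nonzero(deltas > 0) / deltas.size)


def classify_consistency(
    per_replicate_labels: Sequence[int],
    truth: Optional[int] = None,
    unit_id: str = "",
) -> ConsistencyRecord:
    """Classify a unit from M binary replicate labels (and optional truth).

    Unanimous labels are consistent (correct/incorrect against truth when
    available); any disagreement is inconsistent.
    """
    labels = np.asarray(per_replicate_labels, dtype=int)
    if labels.size < 2:
        raise ValueError("need at least 2 replicates")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary")
    p = float(labels.mean())
    if p not in (0.0, 1.0):
        category = INCONSISTENT
    elif truth is None:
        category = CONSISTENT_NO_TRUTH
    elif int(p) == int(truth):
        category = CONSISTENT_CORRECT
    else:
        category = CONSISTENT_INCORRECT
    return ConsistencyRecord(
        unit_id=unit_id,
        sign_probability=p,
        category=category,
        n_replicates=int(labels.size),
        truth=truth,
    )


def poisson_mixture_moments(
    component_means: Sequence[float], weights: Sequence[float]
) -> MixtureMoments:
    """Moments of a convex combination of Poisson components.

    mean = sum w_i lam_i and, by the law of total variance,
    variance = sum w_i lam_i + sum w_i (lam_i - mean)^2, hence the mixture
    is always overdispersed (variance >= mean, equality iff all means equal).
    """
    lam = np.asarray(component_means, dtype=float)
    w = np.asarray(weights, dtype=float)
    if lam.shape != w.shape:
        raise ValueError("means and weights must have the same length")
    if np.any(lam < 0):
        raise ValueError("component means must be nonnegative")
    if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("weights must be a probability simplex")
    mean = float(np.dot(w, lam))
    variance = float(mean + np.dot(w, (lam - mean) ** 2))
    return MixtureMoments(mean=mean, variance=variance)


def _shift_sequence(seq: str, k: int) -> str:
    if k == 0:
        return seq
    if k > 0:
        return seq[k:] + "N" * k
    return "N" * (-k) + seq[: len(seq) + k]


def augmented_windows(window: GenomicWindow):
    """The six augmentation variants: shifts {-1, 0, +1} x {forward, revcomp}.

    Yields (window, is_revcomp) pairs; revcomp predictions must be
    re-reversed to forward bin order before averaging.
    """
    out = []
    for k in (-1, 0, 1):
        shifted = window.with_sequence(_shift_sequence(window.sequence, k))
        out.append((shifted, False))
        out.append((shifted.reverse_complement(), True))
    return out


def robust_predict(predictor, window: GenomicWindow, track: Optional[str] = None) -> np.ndarray:
    """Average predictions over forward/reverse-complement and +/-1 bp shifts.

    This 6-term augmentation average is applied wherever a prediction is
    consumed downstream (peaks, activity scores, SAD, personal genomes).
    """
    preds = []
    for aug, is_rc in augmented_windows(window):
        p = np.asarray(predictor.predict(aug, track=track), dtype=float)
        preds.append(p[::-1] if is_rc else p)
    return np.mean(preds, axis=0)


def saliency_window_scores(per_nucleotide_attributions: Sequence[float], bin_width: int = 128) -> np.ndarray:
    """Sum |attribution| over consecutive bins of ``bin_width`` nucleotides."""
    attr = np.asarray(per_nucleotide_attributions, dtype=float)
    if attr.ndim != 1:
        raise ValueError("attributions must be a 1-D vector")
    if attr.size % bin_width != 0:
        raise ValueError(
            f"attribution length {attr.size} is not a multiple of bin width {bin_width}"
        )
    return np.abs(attr).reshape(-1, bin_width).sum(axis=1)


def pairwise_correlation(matrix: np.ndarray, method: str = "pearson") -> pd.DataFrame:
    """All replicate-pair correlations of a units x replicates matrix.

    Pairs involving a constant column are reported with correlation NaN and
    ``defined`` False rather than dropped.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 3:
        raise ValueError("need a units x replicates matrix with >= 3 units")
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    m = x.shape[1]
    rows = []
    for i, j in itertools.combinations(range(m), 2):
        a, b = x[:, i], x[:, j]
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            r = float("nan")
        elif method == "pearson":
            r = float(stats.pearsonr(a, b).statistic)
        else:
            r = float(stats.spearmanr(a, b).statistic)
        rows.append({"replicate_i": i, "replicate_j": j, "correlation": r,
                     "defined": not np.isnan(r)})
    return pd.DataFrame(rows)


def group_compare(
    group_a: Sequence[float],
    group_b: Sequence[float],
    alternative: str = "greater",
) -> float:
    """One-sided Mann-Whitney U test of ``group_a`` against ``group_b``.

    Uses the exact U null distribution when both groups have <= 8
    observations and no ties, and the tie-corrected normal approximation
    otherwise. ``alternative='greater'`` tests whether group_a is
    stochastically larger.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (a.size <= 8 and b.size <= 8 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return float(res.pvalue)


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH step-up adjusted p-values over a family of tests."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def ism_attributions(
    predictor,
    window: GenomicWindow,
    track: Optional[str] = None,
    output: Optional[Callable[[np.ndarray], float]] = None,
    positions: Optional[Sequence[int]] = None,
) -> np.ndarray:
    """Per-nucleotide attributions by in-silico substitution.

    For each position, the mean absolute change of a scalar output (by
    default the sum of the two bins flanking the anchor) over the three
    alternative bases. Serves as a gradient-free saliency map for
    non-differentiable predictors; N positions get attribution 0.
    ``positions`` restricts the substituted positions (others get 0).
    """
    seq = window.sequence
    preds = _predict_many(predictor, window, [seq], track)
    n_bins = preds.shape[1]
    if output is None:
        if n_bins % 2 != 0:
            raise ValueError("default output needs an even bin count (central junction)")
        c = n_bins // 2

        def output(p: np.ndarray) -> float:
            return float(p[c - 1] + p[c])

    base_out = output(preds[0])
    if positions is None:
        positions = range(len(seq))
    mutants, meta = [], []
    for pos in positions:
        ref = seq[pos]
        if ref == "N":
            continue
        for alt in "ACGT":
            if alt == ref:
                continue
            mutants.append(seq[:pos] + alt + seq[pos + 1:])
            meta.append(pos)
    outs = np.array([output(p) for p in _predict_many(predictor, window, mutants, track)])
    attr = np.zeros(len(seq))
    np.add.at(attr, meta, np.abs(outs - base_out))
    return attr / 3.0


def _predict_many(predictor, template: GenomicWindow, sequences, track):
    """Predict on many same-length sequences, using a batch path when offered."""
    if hasattr(predictor, "predict_sequences"):
        return np.asarray(predictor.predict_sequences(sequences, track=track), dtype=float)
    return np.array(
        [predictor.predict(template.with_sequence(s), track=track) for s in sequences]
    )


def downsample_stride(windows: Iterable[GenomicWindow], k: int = 10):
    """Deterministic k-fold downsampling: sort by coordinate, keep every k-th."""
    if k < 1:
        raise ValueError("stride must be >= 1")
    ordered = sorted(windows, key=lambda w: (w.chrom, w.start))
    return ordered[::k]
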