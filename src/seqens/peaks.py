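"""Poisson-null peak calling and the reference-stage consistency breakdown.

Peaks are called per track against a Poisson null whose rate lambda is
the mean activity over all bins; per-bin upper-tail p-values are
BH-corrected across the track's bins at the requested FDR (default 0.01).
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Set

import numpy as np
import pandas as pd
from scipy import stats

from . import consistency
from .types import (
    CONSISTENT_CORRECT,
    CONSISTENT_INCORRECT,
    INCONSISTENT,
    PeakCallResult,
    TrackTable,
)

__all__ = ["call_peaks", "bin_consistency_breakdown", "gene_track_consistency"]

STRATA = ("all_bins", "experimental_peaks", "tss_experimental_peaks")
_REPORT_CATEGORIES = (CONSISTENT_CORRECT, INCONSISTENT, CONSISTENT_INCORRECT)


def call_peaks(track: TrackTable, fdr: float = 0.01) -> PeakCallResult:
    """Call peak bins against a Poisson(mean activity) null.

    Continuous values are rounded half-up before the Poisson tail
    p = P(Poisson(lambda) >= round(v)); an all-zero track yields
    lambda = 0 with p = 1 everywhere (no peaks).
    """
    values = track.values
    if values.size < 2:
        raise ValueError("need at least 2 bins to call peaks")
    lam = float(values.mean())
    counts = np.floor(values + 0.5)
    if lam == 0.0:
        p = np.ones_like(values)
        is_peak = np.zeros(values.shape, dtype=bool)
    else:
        # P(X >= k) = sf(k - 1); guaranteed in (0, 1]
        p = stats.poisson.sf(counts - 1, lam)
        adj = consistency.benjamini_hochberg(p)
        is_peak = adj <= fdr
    return PeakCallResult(track_id=track.track_id, lam=lam, p_values=p,
                          is_peak=is_peak, fdr=fdr)


def bin_consistency_breakdown(
    experimental: PeakCallResult,
    predicted: Sequence[PeakCallResult],
    tss_bins: Optional[Set[int]] = None,
) -> pd.DataFrame:
    """Consistency proportions over all bins / experimental peaks / TSS peaks.

    Each bin is classified from the M predicted peak labels with the
    experimental call as truth; each stratum row reports the proportions
    of the three categories (summing to 1 where the stratum is nonempty).
    """
    n = experimental.n_bins
    if any(p.n_bins != n for p in predicted):
        raise ValueError("experimental and predicted tracks must share binning")
    if len(predicted) < 2:
        raise ValueError("need >= 2 predicted replicates")
    tss_bins = tss_bins or set()

    labels = np.stack([p.is_peak.astype(int) for p in predicted], axis=1)  # (n, M)
    truth = experimental.is_peak.astype(int)
    categories = np.array([
        consistency.classify_consistency(labels[b], truth=int(truth[b]),
                                         unit_id=str(b)).category
        for b in range(n)
    ])

    tss_mask = np.zeros(n, dtype=bool)
    for b in tss_bins:
        if 0 <= b < n:
            tss_mask[b] = True
    masks = {
        "all_bins": np.ones(n, dtype=bool),
        "experimental_peaks": experimental.is_peak,
        "tss_experimental_peaks": experimental.is_peak & tss_mask,
    }
    rows = []
    for stratum in STRATA:
        mask = masks[stratum]
        total = int(mask.sum())
        row = {"stratum": stratum, "n_bins": total}
        for cat in _REPORT_CATEGORIES:
            row[cat] = float((categories[mask] == cat).sum() / total) if total else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def gene_track_consistency(
    experimental: Dict[str, PeakCallResult],
    predicted: Dict[str, Sequence[PeakCallResult]],
    central_bins: Sequence[int],
) -> pd.DataFrame:
    """Per-(gene, track) consistency category at the TSS.

    Inputs are keyed by gene id; each gene's binary label per source is
    "any peak among the central bins flanking the TSS". Used to pick
    motif-insertion backgrounds (genes consistently correct across the
    most tracks).
    """
    rows = []
    for gene, exp in experimental.items():
        truth = int(exp.is_peak[list(central_bins)].any())
        labels = [int(p.is_peak[list(central_bins)].any()) for p in predicted[gene]]
        rec = consistency.classify_consistency(labels, truth=truth, unit_id=gene)
        rows.append({"gene_id": gene, "track_id": exp.track_id, "category": rec.category})
    return pd.DataFrame(rows)
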