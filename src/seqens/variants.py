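"""eQTL-style variant effect analysis.

The primitive is the signed SAD (SNP activity difference) score: the
alternate-allele prediction minus the reference-allele prediction summed
over the three bins centered on the variant, with each prediction
augmentation-averaged. Replicate sign agreement on SADs feeds the
consistency categories; downstream summaries stratify by effect size,
TSS distance or external annotations and compare ensemble majority vote
to a single replicate.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import consistency
from .types import (
    CONSISTENT_CORRECT,
    CONSISTENT_INCORRECT,
    INCONSISTENT,
    GenomicWindow,
    VariantEffect,
    VariantRecord,
)

__all__ = [
    "sad_score",
    "ensemble_sad_table",
    "filter_variants",
    "eqtl_consistency_table",
    "ensemble_vs_single_accuracy",
    "stratify",
]

_REPORT_CATEGORIES = (CONSISTENT_CORRECT, INCONSISTENT, CONSISTENT_INCORRECT)


def _variant_bins(window: GenomicWindow, bin_width: int) -> Tuple[int, int, int]:
    n_bins = window.length // bin_width
    b = window.anchor // bin_width
    if b == 0 or b >= n_bins - 1:
        raise ValueError(
            "variant lies within one bin of the window edge; center the window")
    return b - 1, b, b + 1


def _substitute(seq: str, pos: int, base: str) -> str:
    return seq[:pos] + base + seq[pos + 1:]


def sad_score(
    predictor,
    window: GenomicWindow,
    ref_allele: str,
    alt_allele: str,
    track: Optional[str] = None,
    bin_width: int = 128,
) -> float:
    """Signed SAD: alt minus ref prediction over the 3 bins nearest the variant.

    The window's anchor marks the variant; the reference sequence must
    carry ``ref_allele`` there (guards coordinate bugs). Swapping alleles
    negates the score bit-exactly.
    """
    if window.sequence[window.anchor] != ref_allele:
        raise ValueError(
            f"reference mismatch at anchor {window.anchor}: window has "
            f"{window.sequence[window.anchor]!r}, expected {ref_allele!r}")
    bins = _variant_bins(window, bin_width)
    alt_window = window.with_sequence(_substitute(window.sequence, window.anchor, alt_allele))
    ref_pred = consistency.robust_predict(predictor, window, track=track)
    alt_pred = consistency.robust_predict(predictor, alt_window, track=track)
    return float(sum(alt_pred[b] - ref_pred[b] for b in bins))


def ensemble_sad_table(
    ensemble,
    windows: Dict[str, GenomicWindow],
    variants: Sequence[VariantRecord],
    track: Optional[str] = None,
    contributions: Optional[np.ndarray] = None,
) -> List[VariantEffect]:
    """Per-replicate SADs for many variants at once.

    ``windows`` maps chrom (window id) to its reference window. Uses the
    synthetic ensemble's shared-scan batch path; ``contributions`` from a
    previous call with the same variants can be reused (e.g. across a
    sigma grid built from the same member seeds).
    """
    from . import simulate

    # predictions depend only on the sequence, so each reference window is
    # scanned once however many variants it carries
    ordered: List[GenomicWindow] = []
    ref_index: Dict[str, int] = {}
    spans: List[Tuple[VariantRecord, Tuple[int, int, int], int, int]] = []
    bw = ensemble.model.bin_width
    for v in variants:
        ref = windows[v.chrom]
        if ref.sequence[v.pos] != v.ref_allele:
            raise ValueError(f"reference mismatch for {v.variant_id}")
        anchored = GenomicWindow(chrom=ref.chrom, start=ref.start,
                                 sequence=ref.sequence, anchor=v.pos, strand=ref.strand)
        bins = _variant_bins(anchored, bw)
        if v.chrom not in ref_index:
            ref_index[v.chrom] = len(ordered)
            ordered.append(anchored)
        alt = anchored.with_sequence(_substitute(ref.sequence, v.pos, v.alt_allele))
        alt_i = len(ordered)
        ordered.append(alt)
        spans.append((v, bins, ref_index[v.chrom], alt_i))
    if contributions is None:
        contributions = simulate.robust_window_contributions(
            ensemble.scan_motifs, ordered, bw,
            ensemble.model.decay_scale, ensemble.model.receptive_field,
            decay_scales=ensemble.scan_decay_scales,
            match_threshold=ensemble.model.match_threshold,
            match_fractions=ensemble.scan_match_fractions,
            saturations=ensemble.scan_saturations)
    preds = simulate.ensemble_robust_predict(ensemble, ordered, track=track,
                                             contributions=contributions)
    out = []
    for v, bins, ref_i, alt_i in spans:
        ref_pred, alt_pred = preds[:, ref_i, :], preds[:, alt_i, :]
        sads = np.sum(alt_pred[:, list(bins)] - ref_pred[:, list(bins)], axis=1)
        out.append(VariantEffect(variant=v, track_id=track or "", per_replicate_sad=sads))
    return out


def filter_variants(variant_gene_table: pd.DataFrame, receptive_field: int) -> List[VariantRecord]:
    """Apply the three eQTL filters in order.

    1. drop variants with opposite directions of effect on different genes,
    2. drop gene-variant pairs farther from the TSS than the receptive field,
    3. keep only the closest gene per variant (ties by gene id).

    Expects columns chrom, pos, ref_allele, alt_allele, gene_id,
    tss_distance, true_sign (nullable).
    """
    df = variant_gene_table.copy()
    df["_vid"] = df["chrom"].astype(str) + ":" + df["pos"].astype(str) + ":" + \
        df["ref_allele"] + ">" + df["alt_allele"]

    def _mixed(signs: pd.Series) -> bool:
        known = {s for s in signs if pd.notna(s)}
        return 1 in known and -1 in known

    mixed = df.groupby("_vid")["true_sign"].apply(_mixed)
    df = df[~df["_vid"].map(mixed)]
    df = df[df["tss_distance"].abs() <= receptive_field]
    df = df.sort_values(["_vid", "gene_id"], kind="stable")
    df = df.loc[df.groupby("_vid")["tss_distance"].transform(
        lambda d: d.abs() == d.abs().min())]
    df = df.drop_duplicates("_vid", keep="first")
    out = []
    for _, row in df.iterrows():
        sign = row["true_sign"]
        out.append(VariantRecord(
            chrom=row["chrom"], pos=int(row["pos"]), ref_allele=row["ref_allele"],
            alt_allele=row["alt_allele"], gene_id=row["gene_id"],
            tss_distance=int(row["tss_distance"]),
            true_sign=None if pd.isna(sign) else int(sign),
        ))
    return out


def eqtl_consistency_table(effects: Sequence[VariantEffect]) -> Tuple[pd.Series, pd.DataFrame]:
    """Category proportions and per-variant records for truth-bearing variants."""
    rows = []
    for e in effects:
        if e.variant.true_sign is None:
            raise ValueError(f"variant {e.variant.variant_id} has no true sign")
        rows.append({
            "variant_id": e.variant.variant_id, "gene_id": e.variant.gene_id,
            "track_id": e.track_id, "sign_probability": e.sign_probability,
            "mean_abs_sad": e.mean_abs_sad, "category": e.category,
            "true_sign": e.variant.true_sign,
            "tss_distance": e.variant.tss_distance,
        })
    records = pd.DataFrame(rows)
    counts = records["category"].value_counts()
    proportions = pd.Series(
        {cat: counts.get(cat, 0) / len(records) for cat in _REPORT_CATEGORIES},
        name="proportion",
    )
    return proportions, records


def ensemble_vs_single_accuracy(
    effects: Sequence[VariantEffect],
    single_replicate_index: int = 0,
) -> Tuple[float, float]:
    """(single-replicate, majority-vote) sign accuracies over truth-bearing variants.

    Majority label is sign_probability > 0.5; an exact 0.5 tie counts as
    "non-positive" (same strict rule as the sign probability itself).
    """
    labeled = [e for e in effects if e.variant.true_sign is not None]
    if not labeled:
        raise ValueError("no variants with known true sign")
    single = np.array([e.per_replicate_sad[single_replicate_index] > 0 for e in labeled])
    majority = np.array([e.sign_probability > 0.5 for e in labeled])
    truth = np.array([e.variant.true_sign > 0 for e in labeled])
    return float((single == truth).mean()), float((majority == truth).mean())


def _first_containing(annotations: pd.DataFrame, chrom: str, pos: int) -> str:
    hits = annotations[(annotations["chrom"] == chrom) &
                       (annotations["start"] <= pos) & (pos < annotations["end"])]
    if hits.empty:
        return "unannotated"
    return str(hits.iloc[0]["name"])


def stratify(
    effects: Sequence[VariantEffect],
    by: str = "effect_size_bins",
    n_bins: int = 3,
    annotations: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Per-stratum consistency-category proportions.

    ``by`` is one of effect_size_bins (quantile bins of the mean |SAD|),
    tss_distance_bins (quantile bins of |TSS distance|), or annotation
    (first containing BED interval; variants outside all intervals form
    the "unannotated" stratum).
    """
    if not effects:
        raise ValueError("no effects to stratify")
    df = pd.DataFrame({
        "chrom": [e.variant.chrom for e in effects],
        "pos": [e.variant.pos for e in effects],
        "category": [e.category for e in effects],
        "mean_abs_sad": [e.mean_abs_sad for e in effects],
        "abs_tss_distance": [abs(e.variant.tss_distance) for e in effects],
    })
    if by == "effect_size_bins":
        df["stratum"] = pd.qcut(df["mean_abs_sad"], q=n_bins, duplicates="drop").astype(str)
    elif by == "tss_distance_bins":
        df["stratum"] = pd.qcut(df["abs_tss_distance"], q=n_bins, duplicates="drop").astype(str)
    elif by == "annotation":
        if annotations is None:
            raise ValueError("annotation stratification needs a BED table")
        required = {"chrom", "start", "end", "name"}
        if not required.issubset(annotations.columns):
            raise ValueError("malformed BED table: need chrom/start/end/name columns")
        df["stratum"] = [
            _first_containing(annotations, c, p) for c, p in zip(df["chrom"], df["pos"])
        ]
    else:
        raise ValueError(f"unknown stratification {by!r}")
    rows = []
    for stratum, grp in df.groupby("stratum"):
        row = {"stratum": stratum, "n_variants": len(grp),
               "mean_abs_sad": float(grp["mean_abs_sad"].mean())}
        for cat in _REPORT_CATEGORIES:
            row[cat] = float((grp["category"] == cat).mean())
        rows.append(row)
    return pd.DataFrame(rows)
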