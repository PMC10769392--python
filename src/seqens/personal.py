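"""Personal-genome stage: haplotypes, cross-individual correlations, drivers.

For each individual, the two phased haplotype sequences are built by
substituting SNV alternate alleles into the reference window; a gene's
predicted expression per individual is the mean of the two haplotype
predictions, each averaged over the central ten bins around the TSS.
Per replicate, the cross-individual Spearman correlation against
measured expression summarizes performance; the variance of that
correlation across replicates defines a gene's uncertainty. Drivers are
the few variants whose allele dosages explain most of the variance of a
replicate's predictions.
"""

from __future__ import annotations

import logging
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from . import consistency
from .types import DriverRecord, GeneUncertainty, GenomicWindow, VariantRecord

__all__ = [
    "build_haplotypes",
    "predict_individual",
    "population_predictions",
    "cross_individual_correlation",
    "gene_uncertainty_table",
    "select_uncertainty_extremes",
    "identify_drivers",
    "driver_concordance",
    "ensemble_rank_predictions",
]

logger = logging.getLogger(__name__)


def build_haplotypes(
    reference_window: GenomicWindow,
    phased_genotypes: np.ndarray,
    variants: Sequence[VariantRecord],
) -> Tuple[GenomicWindow, GenomicWindow]:
    """The two personal haplotype sequences for one individual.

    ``phased_genotypes`` is an (n_variants, 2) array of 0/1 alleles;
    every variant must match the reference base at its position.
    """
    gt = np.asarray(phased_genotypes)
    if gt.shape != (len(variants), 2):
        raise ValueError("phased genotypes must be (n_variants, 2)")
    haps = []
    for h in (0, 1):
        seq = list(reference_window.sequence)
        for v, alleles in zip(variants, gt):
            if not (0 <= v.pos < reference_window.length):
                raise ValueError(f"variant {v.variant_id} outside the window")
            if reference_window.sequence[v.pos] != v.ref_allele:
                raise ValueError(
                    f"reference mismatch at {v.pos}: window has "
                    f"{reference_window.sequence[v.pos]!r}, variant expects {v.ref_allele!r}")
            if alleles[h]:
                seq[v.pos] = v.alt_allele
        haps.append(reference_window.with_sequence("".join(seq)))
    return haps[0], haps[1]


def _central_ten(pred: np.ndarray, anchor_bin: int) -> float:
    n_bins = pred.shape[-1]
    if n_bins < 10:
        raise ValueError("need at least 10 bins around the TSS")
    lo, hi = anchor_bin - 5, anchor_bin + 5
    if lo < 0 or hi > n_bins:
        raise ValueError("TSS too close to the window edge for a 10-bin average")
    return float(pred[lo:hi].mean())


def predict_individual(
    predictor,
    hap1: GenomicWindow,
    hap2: GenomicWindow,
    track: Optional[str] = None,
    bin_width: int = 128,
) -> float:
    """Mean of the two haplotype predictions over the central ten bins.

    The TSS anchor must sit at a bin junction; five bins are taken on
    each side of it.
    """
    values = []
    for hap in (hap1, hap2):
        if hap.anchor % bin_width != 0:
            raise ValueError("TSS anchor must lie at a bin junction")
        pred = consistency.robust_predict(predictor, hap, track=track)
        values.append(_central_ten(pred, hap.anchor // bin_width))
    return float(np.mean(values))


def population_predictions(
    predictor,
    window: GenomicWindow,
    genotypes: np.ndarray,
    variants: Sequence[VariantRecord],
    track: Optional[str] = None,
) -> np.ndarray:
    """Per-individual predictions for a whole cohort at once.

    ``genotypes`` is (n_individuals, n_variants, 2). Returns an
    (M, n_individuals) matrix for a replicate ensemble, or (1, n) for a
    single model/member. Uses the synthetic models' shared-scan batch
    path; results match looping :func:`predict_individual`.
    """
    from . import simulate

    genotypes = np.asarray(genotypes)
    n_ind = genotypes.shape[0]
    haps: List[GenomicWindow] = []
    for i in range(n_ind):
        h1, h2 = build_haplotypes(window, genotypes[i], variants)
        haps.extend([h1, h2])
    bw = getattr(getattr(predictor, "model", predictor), "bin_width", 128)
    if window.anchor % bw != 0:
        raise ValueError("TSS anchor must lie at a bin junction")
    anchor_bin = window.anchor // bw

    if isinstance(predictor, simulate.ReplicateEnsemble):
        preds = simulate.ensemble_robust_predict(predictor, haps, track=track)
    elif isinstance(predictor, simulate.GroundTruthModel):
        preds = simulate.model_robust_predict(predictor, haps, track=track)[None, :, :]
    else:
        preds = np.array([[consistency.robust_predict(predictor, h, track=track)
                           for h in haps]])
    n_bins = preds.shape[-1]
    if n_bins < 10:
        raise ValueError("need at least 10 bins around the TSS")
    lo, hi = anchor_bin - 5, anchor_bin + 5
    if lo < 0 or hi > n_bins:
        raise ValueError("TSS too close to the window edge for a 10-bin average")
    hap_values = preds[:, :, lo:hi].mean(axis=2)          # (M, 2*n_ind)
    return hap_values.reshape(preds.shape[0], n_ind, 2).mean(axis=2)


def cross_individual_correlation(predicted: Sequence[float], measured: Sequence[float]) -> float:
    """Spearman correlation between predicted and measured expression.

    Average ranks on ties; NaN (undefined) when either vector is constant.
    """
    x = np.asarray(predicted, dtype=float)
    y = np.asarray(measured, dtype=float)
    if x.shape != y.shape:
        raise ValueError("predicted and measured must have the same length")
    if x.size < 3:
        raise ValueError("need at least 3 individuals")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(stats.spearmanr(x, y).statistic)


def ensemble_rank_predictions(per_replicate_predictions: np.ndarray) -> np.ndarray:
    """Ensemble prediction as the mean of within-replicate expression ranks."""
    preds = np.asarray(per_replicate_predictions, dtype=float)
    ranks = np.apply_along_axis(stats.rankdata, 1, preds)
    return ranks.mean(axis=0)


def gene_uncertainty_table(per_gene_rhos: Dict[str, Sequence[float]]) -> List[GeneUncertainty]:
    """Per-gene uncertainty records from per-replicate correlations.

    Also counts replicates with rho > 0 (the 0..M segmentation of genes);
    genes with undefined correlations stay UNCLASSIFIED.
    """
    return [GeneUncertainty(gene_id=g, per_replicate_rho=np.asarray(r, dtype=float))
            for g, r in per_gene_rhos.items()]


def select_uncertainty_extremes(
    table: Sequence[GeneUncertainty], n: int = 100
) -> Tuple[List[GeneUncertainty], List[GeneUncertainty]]:
    """Top-n and bottom-n eligible genes by replicate-correlation variance.

    Only genes with mean |rho| >= 0.1 are eligible; if fewer than 2n
    exist the pool is split (with a logged warning). Returned records are
    tagged HIGH/LOW in place.
    """
    eligible = sorted((g for g in table if g.eligible),
                      key=lambda g: (-g.variance_rho, g.gene_id))
    if len(eligible) < 2 * n:
        logger.warning("only %d eligible genes for 2x%d uncertainty extremes",
                       len(eligible), n)
    n_high = min(n, (len(eligible) + 1) // 2)
    n_low = min(n, len(eligible) - n_high)
    high = eligible[:n_high]
    low = eligible[::-1][:n_low]
    for g in high:
        g.uncertainty_class = "HIGH"
    for g in low:
        g.uncertainty_class = "LOW"
    return high, low


def identify_drivers(
    dosages: np.ndarray,
    predictions: Sequence[float],
    variants: Sequence[VariantRecord],
    gene_id: str,
    replicate_index: int = 0,
    delta: float = 0.05,
    max_drivers: int = 6,
) -> List[DriverRecord]:
    """Variants that explain most of the variance in a replicate's predictions.

    Variants are ranked by squared Pearson correlation between allele
    dosage (0/1/2) and the prediction vector, then accepted greedily
    while the incremental explained variance (after residualizing on the
    accepted dosages) is at least ``delta``, up to ``max_drivers``. This
    forward-selection rule is a reconstruction of the driver analyses
    used with personal-genome prediction benchmarks; ``delta`` and the
    cap are configurable.
    """
    y = np.asarray(predictions, dtype=float)
    d = np.asarray(dosages, dtype=float)
    if d.ndim != 2 or d.shape != (y.size, len(variants)):
        raise ValueError("dosages must be (n_individuals, n_variants)")
    if y.size < 3:
        raise ValueError("need at least 3 individuals")
    total_var = float(np.var(y))
    if total_var == 0:
        logger.warning("constant prediction vector for gene %s; no drivers", gene_id)
        return []

    r2 = np.zeros(len(variants))
    for j in range(len(variants)):
        x = d[:, j]
        if np.ptp(x) == 0:
            continue
        r = np.corrcoef(x, y)[0, 1]
        r2[j] = r * r
    order = np.argsort(-r2, kind="stable")

    resid = y - y.mean()
    accepted: List[Tuple[int, float]] = []
    basis: List[np.ndarray] = []
    for j in order:
        if len(accepted) >= max_drivers:
            break
        if r2[j] == 0:
            break
        x = d[:, j] - d[:, j].mean()
        for b in basis:
            x = x - np.dot(x, b) * b
        norm = np.linalg.norm(x)
        if norm < 1e-12:
            continue
        b = x / norm
        gain = float(np.dot(resid, b) ** 2 / (y.size * total_var))
        if gain < delta:
            break
        resid = resid - np.dot(resid, b) * b
        basis.append(b)
        accepted.append((int(j), gain))

    accepted.sort(key=lambda t: -t[1])
    return [
        DriverRecord(gene_id=gene_id, variant=variants[j],
                     replicate_index=replicate_index,
                     variance_explained=gain, rank=rank + 1)
        for rank, (j, gain) in enumerate(accepted)
    ]


def driver_concordance(
    driver_sets: Dict[Tuple[str, int], Sequence[DriverRecord]],
    sad_signs: pd.DataFrame,
    gene_classes: Dict[str, str],
    m: int = 5,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Driver reproducibility and SAD-sign agreement across replicates.

    ``driver_sets`` maps (gene, replicate) to that replicate's drivers;
    ``sad_signs`` has columns gene_id, variant_id, replicate, sign.
    Returns (reproducibility table: counts of drivers found by k
    replicates x HIGH/LOW; sign-agreement table: for drivers found by
    k in {3..M} replicates, the majority sign-agreement count x class).
    """
    found: Dict[Tuple[str, str], set] = {}
    for (gene, rep), records in driver_sets.items():
        for rec in records:
            found.setdefault((gene, rec.variant.variant_id), set()).add(rep)

    repro_rows = []
    for (gene, vid), reps in found.items():
        repro_rows.append({
            "gene_id": gene, "variant_id": vid,
            "n_replicates_found": len(reps),
            "uncertainty_class": gene_classes.get(gene, "UNCLASSIFIED"),
        })
    reproducibility = pd.DataFrame(repro_rows)

    sign_rows = []
    if not sad_signs.empty:
        signs = sad_signs.set_index(["gene_id", "variant_id", "replicate"])["sign"]
        for (gene, vid), reps in found.items():
            k = len(reps)
            if k < 3:
                continue
            s = [signs.get((gene, vid, rep)) for rep in range(m)]
            s = [x for x in s if x is not None and not pd.isna(x)]
            if not s:
                continue
            pos = sum(1 for x in s if x > 0)
            sign_rows.append({
                "gene_id": gene, "variant_id": vid,
                "n_replicates_found": k,
                "n_sign_agree": max(pos, len(s) - pos),
                "uncertainty_class": gene_classes.get(gene, "UNCLASSIFIED"),
            })
    return reproducibility, pd.DataFrame(sign_rows)
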