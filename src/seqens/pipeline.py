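"""Stage-chained pipeline over the synthetic ensemble.

Stages (``simulate -> peaks -> consistency -> motif -> eqtl -> personal
-> report``) communicate through plain-text files in the output
directory; every stage rebuilds the deterministic ground-truth model and
replicate ensemble from the config seed, so a rerun with the same config
produces byte-identical tables.
"""

from __future__ import annotations

import logging
import sys
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import consistency, io, motifs, peaks, personal, simulate, variants as variant_mod
from .types import GenomicWindow, TrackTable, VariantRecord

__all__ = ["DEFAULT_CONFIG", "resolve_config", "run_pipeline", "STAGES"]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "peaks", "consistency", "motif", "eqtl", "personal", "report")

DEFAULT_CONFIG: Dict[str, object] = {
    # geometry (desk-scale miniature of the 131 kb / 128 bp convention)
    "window_length": 4096,
    "bin_width": 128,
    "receptive_field": 2048,
    "decay_scale": 500.0,
    # ground truth
    "n_tracks": 8,
    "n_motifs": 8,
    "motif_length": 8,
    "baseline_rate": 2.0,
    "gc": 0.41,
    "motif_density": 0.5,
    "pseudocount": 0.06,
    "match_threshold": 0.25,
    "site_saturation": 0.8,
    # ensemble
    "m": 5,
    "sigma": 0.5,
    "pwm_noise": 0.6,
    "shared_pwm_noise": 0.8,
    "damaged_weight": 0.45,
    "shared_damaged_weight": 0.35,
    "n_spurious": 2,
    "spurious_weight": 0.15,
    "bias_amplitude": 0.1,
    # reference stage
    "n_windows": 48,
    "reference_downsample": 1,
    "fdr": 0.01,
    # motif stage
    "n_backgrounds": 8,
    "offsets": [10, 100, 1000],
    "motif_mode": "sample",
    # eqtl stage
    "n_eqtl_pos": 150,
    "n_eqtl_neg": 150,
    # personal stage
    "n_genes_personal": 12,
    "n_individuals": 100,
    "n_variants_per_gene": 24,
    "h2": 0.3,
    "uncertainty_extremes": 3,
    "driver_delta": 0.05,
    "driver_max": 6,
    # misc
    "seed": 0,
    "stages": list(STAGES),
    "plots": False,
}


def resolve_config(config) -> dict:
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(io.load_config(config))
    if int(cfg["m"]) < 2:
        raise ValueError("consistency analysis requires M >= 2 replicates")
    unknown = set(cfg) - set(DEFAULT_CONFIG)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return cfg


def build_models(cfg: dict):
    """Deterministically rebuild the ground truth and ensemble from the config."""
    model = simulate.make_ground_truth(
        n_tracks=int(cfg["n_tracks"]), n_motifs=int(cfg["n_motifs"]),
        motif_length=int(cfg["motif_length"]), seed=int(cfg["seed"]),
        baseline_rate=float(cfg["baseline_rate"]), decay_scale=float(cfg["decay_scale"]),
        receptive_field=int(cfg["receptive_field"]), bin_width=int(cfg["bin_width"]),
        pseudocount=float(cfg["pseudocount"]),
        match_threshold=float(cfg["match_threshold"]),
        site_saturation=(None if cfg["site_saturation"] in (None, 0, "none")
                         else float(cfg["site_saturation"])),
    )
    ensemble = simulate.make_replicate_ensemble(
        model, m=int(cfg["m"]), sigma=float(cfg["sigma"]),
        seeds=[int(cfg["seed"]) * 1000 + i for i in range(int(cfg["m"]))],
        pwm_noise=float(cfg["pwm_noise"]), shared_pwm_noise=float(cfg["shared_pwm_noise"]),
        damaged_weight=float(cfg["damaged_weight"]),
        shared_damaged_weight=float(cfg["shared_damaged_weight"]),
        n_spurious=int(cfg["n_spurious"]), spurious_weight=float(cfg["spurious_weight"]),
        bias_amplitude=float(cfg["bias_amplitude"]),
    )
    return model, ensemble


def _require(path: Path, upstream: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing input {path.name}; run the '{upstream}' stage first")
    return path


def _central_bins(n_bins: int) -> List[int]:
    return [n_bins // 2 - 1, n_bins // 2]


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: dict, out: Path) -> None:
    model, _ = build_models(cfg)
    windows, sites = simulate.simulate_regulatory_genome(
        n_windows=int(cfg["n_windows"]), length=int(cfg["window_length"]),
        gc=float(cfg["gc"]), motif_density=float(cfg["motif_density"]),
        seed=int(cfg["seed"]), motif_library=model.motifs,
        bin_width=int(cfg["bin_width"]),
    )
    io.windows_to_fasta(windows, out / "windows.fasta")
    io.write_bed(sites[["chrom", "start", "end", "motif_id", "strand"]],
                 out / "planted_sites.bed")
    tss = pd.DataFrame({
        "chrom": [w.chrom for w in windows],
        "start": [w.anchor for w in windows],
        "end": [w.anchor + 1 for w in windows],
        "name": [f"gene_{w.chrom}" for w in windows],
    })
    io.write_bed(tss, out / "tss.bed")
    io.write_pwm(model.motifs, out / "motifs.meme")
    logger.info("simulate: %d windows, %d planted sites", len(windows), len(sites))


def _load_windows(cfg: dict, out: Path, upstream: str = "simulate") -> List[GenomicWindow]:
    return io.fasta_to_windows(_require(out / "windows.fasta", upstream))


def stage_peaks(cfg: dict, out: Path) -> None:
    model, ensemble = build_models(cfg)
    windows = _load_windows(cfg, out)
    stride = int(cfg["reference_downsample"])
    if stride > 1:
        windows = consistency.downsample_stride(windows, stride)
    n_bins = int(cfg["window_length"]) // int(cfg["bin_width"])
    central = _central_bins(n_bins)
    rng = np.random.default_rng(int(cfg["seed"]) + 17)

    # scans are track-independent; do them once for all windows
    contrib = simulate.robust_window_contributions(
        ensemble.scan_motifs, windows, model.bin_width, model.decay_scale,
        model.receptive_field, decay_scales=ensemble.scan_decay_scales,
        match_threshold=model.match_threshold,
        match_fractions=ensemble.scan_match_fractions,
        saturations=ensemble.scan_saturations)
    true_rates = {
        track: model.predict_sequences([w.sequence for w in windows], track=track)
        for track in model.track_ids
    }

    breakdown_rows, gene_rows, peak_rows = [], [], []
    for t, track in enumerate(model.track_ids):
        preds_all = simulate.ensemble_robust_predict(
            ensemble, windows, track=track, contributions=contrib)  # (M, n_win, B)
        counts_all = rng.poisson(true_rates[track]).astype(float)   # (n_win, B)
        tss_bins = {wi * n_bins + b for wi in range(len(windows)) for b in central}
        per_gene_exp = {w.chrom: counts_all[wi] for wi, w in enumerate(windows)}
        per_gene_pred = {w.chrom: preds_all[:, wi, :] for wi, w in enumerate(windows)}
        exp_track = TrackTable(track_id=track, assay_class=model.assay_classes[t],
                               values=counts_all.ravel(),
                               bin_width=int(cfg["bin_width"]))
        exp_call = peaks.call_peaks(exp_track, fdr=float(cfg["fdr"]))
        member_calls = []
        for i in range(ensemble.m):
            tt = TrackTable(track_id=track, assay_class=model.assay_classes[t],
                            values=preds_all[i].ravel(),
                            bin_width=int(cfg["bin_width"]))
            member_calls.append(peaks.call_peaks(tt, fdr=float(cfg["fdr"])))
        table = peaks.bin_consistency_breakdown(exp_call, member_calls, tss_bins)
        table.insert(0, "track_id", track)
        breakdown_rows.append(table)

        for b in np.flatnonzero(exp_call.is_peak):
            wi, local = divmod(int(b), n_bins)
            peak_rows.append({"chrom": windows[wi].chrom,
                              "start": local * int(cfg["bin_width"]),
                              "end": (local + 1) * int(cfg["bin_width"]),
                              "p_value": exp_call.p_values[b], "track_id": track})

        # per-gene TSS-label consistency feeding background selection
        exp_by_gene, pred_by_gene = {}, {}
        for gene, counts in per_gene_exp.items():
            tt = TrackTable(track_id=track, assay_class=model.assay_classes[t],
                            values=counts, bin_width=int(cfg["bin_width"]))
            exp_by_gene[gene] = peaks.call_peaks(tt, fdr=float(cfg["fdr"]))
            pred_by_gene[gene] = [
                peaks.call_peaks(TrackTable(track_id=track,
                                            assay_class=model.assay_classes[t],
                                            values=per_gene_pred[gene][i],
                                            bin_width=int(cfg["bin_width"])),
                                 fdr=float(cfg["fdr"]))
                for i in range(ensemble.m)
            ]
        gene_rows.append(peaks.gene_track_consistency(exp_by_gene, pred_by_gene, central))

    io.write_tsv(pd.concat(breakdown_rows, ignore_index=True),
                 out / "reference_consistency.tsv")
    io.write_tsv(pd.concat(gene_rows, ignore_index=True),
                 out / "gene_track_consistency.tsv")
    io.write_bed(pd.DataFrame(peak_rows, columns=["chrom", "start", "end",
                                                  "p_value", "track_id"]),
                 out / "experimental_peaks.bed")
    logger.info("peaks: %d tracks over %d windows", model.n_tracks, len(windows))


def stage_consistency(cfg: dict, out: Path) -> None:
    model, ensemble = build_models(cfg)
    windows = _load_windows(cfg, out)
    contrib = simulate.robust_window_contributions(
        ensemble.scan_motifs, windows, model.bin_width, model.decay_scale,
        model.receptive_field, decay_scales=ensemble.scan_decay_scales,
        match_threshold=model.match_threshold,
        match_fractions=ensemble.scan_match_fractions,
        saturations=ensemble.scan_saturations)
    rows = []
    for track in model.track_ids:
        preds = simulate.ensemble_robust_predict(ensemble, windows, track=track,
                                                 contributions=contrib)
        mat = preds.reshape(ensemble.m, -1).T  # (windows*bins, M)
        table = consistency.pairwise_correlation(mat, method="pearson")
        table.insert(0, "track_id", track)
        rows.append(table)
    io.write_tsv(pd.concat(rows, ignore_index=True), out / "replicate_correlations.tsv")

    # substitution-based saliency maps around the TSS of the first window
    half = min(128, int(cfg["window_length"]) // 4)
    sal_rows = []
    for w in windows[:1]:
        span = range(w.anchor - half, w.anchor + half)
        attr = np.stack([
            consistency.saliency_window_scores(
                consistency.ism_attributions(member, w, track=model.track_ids[0],
                                             positions=span),
                bin_width=int(cfg["bin_width"]))
            for member in ensemble.members
        ], axis=1)
        table = consistency.pairwise_correlation(attr, method="pearson")
        table.insert(0, "chrom", w.chrom)
        sal_rows.append(table)
    io.write_tsv(pd.concat(sal_rows, ignore_index=True),
                 out / "saliency_correlations.tsv")


def stage_motif(cfg: dict, out: Path) -> None:
    model, ensemble = build_models(cfg)
    windows = _load_windows(cfg, out)
    gt_table = io.read_tsv(_require(out / "gene_track_consistency.tsv", "peaks"))
    chosen = motifs.select_backgrounds(gt_table, n=int(cfg["n_backgrounds"]))
    chosen_ids = {g.removeprefix("gene_") if g.startswith("gene_") else g for g in chosen}
    backgrounds = [w for w in windows if w.chrom in chosen_ids or
                   f"gene_{w.chrom}" in chosen]
    scores, fracs, summary = motifs.motif_consistency_analysis(
        ensemble, backgrounds, model.motifs, model.track_ids,
        offsets=[int(o) for o in cfg["offsets"]], mode=str(cfg["motif_mode"]),
        base_seed=int(cfg["seed"]),
    )
    io.write_tsv(scores, out / "motif_scores.tsv")
    io.write_tsv(fracs, out / "motif_inconsistency.tsv")
    io.write_tsv(summary, out / "motif_summary.tsv")
    logger.info("motif: %d backgrounds, %d motifs", len(backgrounds), len(model.motifs))


def stage_eqtl(cfg: dict, out: Path) -> None:
    model, ensemble = build_models(cfg)
    windows = _load_windows(cfg, out)
    sites = io.read_bed(_require(out / "planted_sites.bed", "simulate"))
    sites = sites.rename(columns={"name": "motif_id"})
    track = model.track_ids[0]
    eqtls = simulate.simulate_eqtls(
        windows, sites, n_pos=int(cfg["n_eqtl_pos"]), n_neg=int(cfg["n_eqtl_neg"]),
        seed=int(cfg["seed"]) + 29, model=model, track=track)
    io.write_phased_vcf(eqtls, None, [], out / "eqtls.vcf")

    table = pd.DataFrame([{
        "chrom": v.chrom, "pos": v.pos, "ref_allele": v.ref_allele,
        "alt_allele": v.alt_allele, "gene_id": v.gene_id,
        "tss_distance": v.tss_distance, "true_sign": v.true_sign,
    } for v in eqtls])
    kept = variant_mod.filter_variants(table, receptive_field=int(cfg["receptive_field"]))
    by_chrom = {w.chrom: w for w in windows}
    effects = variant_mod.ensemble_sad_table(ensemble, by_chrom, kept, track=track)
    labeled = [e for e in effects if e.variant.true_sign is not None]
    proportions, records = variant_mod.eqtl_consistency_table(labeled)
    io.write_tsv(records, out / "eqtl_records.tsv")
    io.write_tsv(proportions.rename_axis("category").reset_index(),
                 out / "eqtl_consistency.tsv")
    io.write_tsv(variant_mod.stratify(labeled, by="effect_size_bins"),
                 out / "eqtl_by_effect_size.tsv")
    single, majority = variant_mod.ensemble_vs_single_accuracy(labeled)
    io.write_tsv(pd.DataFrame([{"accuracy_single": single,
                                "accuracy_majority": majority,
                                "n_eqtls": len(labeled)}]),
                 out / "eqtl_accuracy.tsv")
    logger.info("eqtl: %d variants after filtering (%d with truth)",
                len(kept), len(labeled))


def _gene_panel(window: GenomicWindow, sites: pd.DataFrame, cfg: dict,
                rng: np.random.Generator) -> List[VariantRecord]:
    """A variant panel for one gene: planted-motif positions plus background."""
    bw = int(cfg["bin_width"])
    n_var = int(cfg["n_variants_per_gene"])
    gene_sites = sites[sites["chrom"] == window.chrom]
    positions: List[int] = []
    for _, row in gene_sites.iterrows():
        for p in range(int(row["start"]), int(row["end"])):
            if bw <= p < window.length - bw:
                positions.append(p)
    rng.shuffle(positions)
    positions = positions[: n_var // 2]
    while len(positions) < n_var:
        p = int(rng.integers(bw, window.length - bw))
        if p not in positions and window.sequence[p] != "N":
            positions.append(p)
    out = []
    for p in sorted(set(positions)):
        ref = window.sequence[p]
        if ref == "N":
            continue
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        out.append(VariantRecord(chrom=window.chrom, pos=p, ref_allele=ref,
                                 alt_allele=alt, gene_id=f"gene_{window.chrom}",
                                 tss_distance=p - window.anchor))
    return out


def stage_personal(cfg: dict, out: Path) -> None:
    model, ensemble = build_models(cfg)
    windows = _load_windows(cfg, out)
    sites = io.read_bed(_require(out / "planted_sites.bed", "simulate"))
    sites = sites.rename(columns={"name": "motif_id"})
    track = model.track_ids[0]
    rng = np.random.default_rng(int(cfg["seed"]) + 41)
    genes = windows[: int(cfg["n_genes_personal"])]

    rho_rows, per_gene_rhos = [], {}
    gene_data = {}
    for w in genes:
        panel = _gene_panel(w, sites, cfg, rng)
        genotypes, measured = simulate.simulate_population(
            w, panel, n_individuals=int(cfg["n_individuals"]), h2=float(cfg["h2"]),
            seed=int(rng.integers(2**31)), model=model, track=track)
        preds = personal.population_predictions(ensemble, w, genotypes, panel, track=track)
        rhos = [personal.cross_individual_correlation(preds[i], measured)
                for i in range(ensemble.m)]
        gene_id = f"gene_{w.chrom}"
        per_gene_rhos[gene_id] = rhos
        gene_data[gene_id] = (w, panel, genotypes, preds)
        ens_rank = personal.ensemble_rank_predictions(preds)
        rho_rows.append({
            "gene_id": gene_id,
            **{f"rho_rep{i}": rhos[i] for i in range(ensemble.m)},
            "rho_ensemble": personal.cross_individual_correlation(ens_rank, measured),
        })
    io.write_tsv(pd.DataFrame(rho_rows), out / "personal_correlations.tsv")

    table = personal.gene_uncertainty_table(per_gene_rhos)
    high, low = personal.select_uncertainty_extremes(
        table, n=int(cfg["uncertainty_extremes"]))
    io.write_tsv(pd.DataFrame([{
        "gene_id": g.gene_id, "variance_rho": g.variance_rho,
        "mean_abs_rho": g.mean_abs_rho, "eligible": g.eligible,
        "positive_count": g.positive_count, "uncertainty_class": g.uncertainty_class,
    } for g in table]), out / "gene_uncertainty.tsv")

    driver_sets, sign_rows, driver_rows = {}, [], []
    classes = {g.gene_id: g.uncertainty_class for g in table}
    by_chrom = {w.chrom: w for w in windows}
    for g in list(high) + list(low):
        w, panel, genotypes, preds = gene_data[g.gene_id]
        dosages = genotypes.sum(axis=2)
        effects = variant_mod.ensemble_sad_table(ensemble, by_chrom, panel, track=track)
        for e in effects:
            for rep in range(ensemble.m):
                sign_rows.append({"gene_id": g.gene_id,
                                  "variant_id": e.variant.variant_id,
                                  "replicate": rep,
                                  "sign": 1 if e.per_replicate_sad[rep] > 0 else -1})
        for rep in range(ensemble.m):
            recs = personal.identify_drivers(
                dosages, preds[rep], panel, g.gene_id, replicate_index=rep,
                delta=float(cfg["driver_delta"]), max_drivers=int(cfg["driver_max"]))
            driver_sets[(g.gene_id, rep)] = recs
            for r in recs:
                driver_rows.append({
                    "gene_id": r.gene_id, "variant_id": r.variant.variant_id,
                    "replicate": rep, "rank": r.rank,
                    "variance_explained": r.variance_explained,
                    "uncertainty_class": classes[g.gene_id],
                })
    io.write_tsv(pd.DataFrame(driver_rows, columns=[
        "gene_id", "variant_id", "replicate", "rank", "variance_explained",
        "uncertainty_class"]), out / "drivers.tsv")
    repro, agree = personal.driver_concordance(
        driver_sets, pd.DataFrame(sign_rows), classes, m=ensemble.m)
    io.write_tsv(repro, out / "driver_reproducibility.tsv")
    io.write_tsv(agree, out / "driver_sign_agreement.tsv")
    logger.info("personal: %d genes, %d/%d high/low uncertainty",
                len(genes), len(high), len(low))


def stage_report(cfg: dict, out: Path) -> None:
    summary = {}
    ref = out / "reference_consistency.tsv"
    if ref.exists():
        df = io.read_tsv(ref)
        allb = df[df["stratum"] == "all_bins"]
        summary["reference_inconsistent_fraction"] = float(allb["INCONSISTENT"].mean())
        summary["reference_consistent_correct_fraction"] = float(
            allb["CONSISTENT_CORRECT"].mean())
    mot = out / "motif_inconsistency.tsv"
    if mot.exists():
        df = io.read_tsv(mot)
        for kind, grp in df.groupby("kind"):
            summary[f"motif_{kind.lower()}_inconsistency"] = float(
                grp["inconsistency_fraction"].mean())
    eq = out / "eqtl_consistency.tsv"
    if eq.exists():
        df = io.read_tsv(eq).set_index("category")["proportion"]
        for cat, val in df.items():
            summary[f"eqtl_{cat.lower()}"] = float(val)
    pers = out / "personal_correlations.tsv"
    if pers.exists():
        df = io.read_tsv(pers)
        rep_cols = [c for c in df.columns if c.startswith("rho_rep")]
        pos = (df[rep_cols] > 0).sum(axis=1)
        summary["personal_sign_disagreement_fraction"] = float(
            ((pos > 0) & (pos < len(rep_cols))).mean())
    io.write_tsv(pd.DataFrame(sorted(summary.items()),
                              columns=["quantity", "value"]),
                 out / "summary.tsv")
    if cfg.get("plots"):
        _write_plots(out)


def _write_plots(out: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    eq = out / "eqtl_consistency.tsv"
    if eq.exists():
        df = io.read_tsv(eq)
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.bar(df["category"], df["proportion"])
        ax.set_ylabel("proportion of eQTLs")
        ax.tick_params(axis="x", rotation=30)
        fig.tight_layout()
        fig.savefig(out / "eqtl_consistency.png", dpi=120)
        plt.close(fig)


_STAGE_FN = {
    "simulate": stage_simulate,
    "peaks": stage_peaks,
    "consistency": stage_consistency,
    "motif": stage_motif,
    "eqtl": stage_eqtl,
    "personal": stage_personal,
    "report": stage_report,
}


def run_pipeline(config, outdir) -> Path:
    """Run the configured stages; returns the report directory.

    Deterministic given (config, seed): reruns produce byte-identical
    TSVs. Raises on the first stage failure (callers exit nonzero).
    """
    cfg = resolve_config(config)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    with open(out / "run.log", "a") as fh:
        fh.write(f"seqens run: seed={cfg['seed']} m={cfg['m']} sigma={cfg['sigma']} "
                 f"stages={','.join(map(str, cfg['stages']))} "
                 f"numpy={np.__version__} pandas={pd.__version__} "
                 f"python={sys.version.split()[0]}\n")
    for stage in cfg["stages"]:
        if stage not in _STAGE_FN:
            raise ValueError(f"unknown stage {stage!r}; choose from {STAGES}")
        logger.info("running stage %s", stage)
        _STAGE_FN[stage](cfg, out)
    return out
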