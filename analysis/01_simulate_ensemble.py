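#!/usr/bin/env python
"""Build the synthetic regulatory genome and the replicate ensemble.

Writes the reference windows (FASTA), planted motif sites (BED), TSS
annotations (BED) and the motif library (MEME-like) under
results/pipeline/, and summarizes how strongly the five seed-perturbed
replicates agree on reference-sequence predictions.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from seqens import consistency, io, pipeline, simulate

OUT = Path("results/pipeline")
CONFIG = {"seed": 1, "stages": ["simulate"]}


def main() -> None:
    cfg = pipeline.resolve_config(CONFIG)
    pipeline.run_pipeline(CONFIG, OUT)
    model, ensemble = pipeline.build_models(cfg)
    windows = io.fasta_to_windows(OUT / "windows.fasta")
    sites = io.read_bed(OUT / "planted_sites.bed")
    print(f"simulated {len(windows)} windows of {windows[0].length} bp "
          f"({len(sites)} planted motif instances, {model.n_tracks} tracks, "
          f"M={ensemble.m} replicates at sigma={ensemble.sigma})")

    rows = []
    for track in model.track_ids:
        preds = simulate.ensemble_robust_predict(ensemble, windows, track=track)
        table = consistency.pairwise_correlation(preds.reshape(ensemble.m, -1).T)
        rows.append({"track_id": track,
                     "median_pairwise_pearson": table["correlation"].median()})
    summary = pd.DataFrame(rows)
    io.write_tsv(summary, Path("results") / "01_replicate_agreement.tsv")
    print("replicate agreement on reference predictions "
          f"(median pairwise Pearson r per track): "
          f"median {summary['median_pairwise_pearson'].median():.3f}, "
          f"min {summary['median_pairwise_pearson'].min():.3f}")
    print("-> replicates agree on relative activity across the reference "
          "genome; disagreement is reserved for perturbed sequences")


if __name__ == "__main__":
    main()
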