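#!/usr/bin/env python
"""Deletion-carrier association: per-stratum odds ratios and the pooled
Mantel-Haenszel analysis from the packaged count tables, plus the
threshold-sensitivity sweep on the simulated cohort."""

from pathlib import Path

import numpy as np

from tandemcnv import association as assoc
from tandemcnv import pipeline, prt_genotyping as prt

# published counts -> per-stratum and pooled statistics
cfg = pipeline.PipelineConfig(
    seed=20240901, outdir=Path("results/pipeline"),
    counts_table=pipeline.packaged_path("table_counts.tsv"),
)
paths = pipeline.run_associate(cfg)
strata = pipeline.read_tsv(paths["stratum"])
meta = pipeline.read_tsv(paths["meta"]).iloc[0]
print("per-stratum deletion-carrier association:")
print(strata[["stratum", "odds_ratio", "ci95_low", "ci95_high", "p"]]
      .round(4).to_string(index=False))
print(f"\npooled MH OR = {meta['or_mh']:.3f} "
      f"[{meta['ci95_low']:.3f}, {meta['ci95_high']:.3f}], "
      f"P = {meta['p_mh']:.3g}; "
      f"Woolf heterogeneity P = {meta['woolf_p']:.2f} (pooling justified)")

# threshold sensitivity on the simulated Swedish-scale cohort
outdir = Path("results/pipeline")
calls = pipeline.read_tsv(outdir / "calls_prt.tsv")
pheno = pipeline.read_tsv(outdir / "phenotypes.tsv")
grid = [round(t, 2) for t in np.arange(-1.3, -0.449, 0.1)]
sweep = prt.threshold_sensitivity(calls, pheno[["sample", "status"]], grid)
pipeline.write_tsv(sweep, outdir / "threshold_sweep.tsv",
                   "deletion-threshold sensitivity sweep")
print("\nthreshold sweep on the simulated cohort:")
print(sweep.round(4).to_string(index=False))
n_sig = int((sweep["p"] < 0.05).sum())
print(f"{n_sig}/{len(sweep)} thresholds significant at 5%; the most extreme "
      "thresholds strand the tight simulated deletion cluster (centred at -1) "
      "and lose the carriers, unlike the broader real-data clusters")
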