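#!/usr/bin/env python
"""Call the CNV from simulated SNP BAF/LRR data and cross-tabulate the
SNP-intensity calls against the PRT calls (the 99.7%-style QC check)."""

from pathlib import Path

from tandemcnv import pipeline, prt_genotyping as prt

outdir = Path("results/pipeline")
prt_calls = pipeline.read_tsv(outdir / "calls_prt.tsv")
snp_calls = pipeline.read_tsv(outdir / "calls_snp.tsv")
truth = pipeline.read_tsv(outdir / "truth.tsv")

rate, crosstab = prt.concordance(prt_calls, snp_calls)
print(f"PRT vs SNP concordance over {len(truth)} samples: {rate:.4f}")
print(crosstab)

merged = snp_calls.merge(truth, on="sample")
acc = (merged["category"] == merged["true_class"]).mean()
print(f"SNP-caller accuracy vs truth: {acc:.4f}")
qc = pipeline.read_tsv(outdir / "snp_qc.tsv")
print("cluster centroids (mean LRR, BAF deviation) by call:")
print(qc.groupby("call")[["mean_lrr", "baf_deviation"]].mean())
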