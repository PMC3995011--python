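"""Regional CNV calling from SNP array BAF/LRR summaries.

Instead of a genome-wide hidden-Markov caller, the regional copy number
is called from the two summary features that separate the copy-number
clusters in this region: the mean log R ratio (LRR) over in-region SNPs
and the B-allele-frequency (BAF) deviation of apparently heterozygous
SNPs from 0.5. A one-copy (deletion-carrier) region has depressed LRR
and no true heterozygotes; a three-copy region has elevated LRR and
heterozygote BAF clusters at 1/3 and 2/3 (deviation ~1/6). Deletion is
tested first, so no sample can receive both variant calls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import GenomicInterval
from .prt_genotyping import DELETION, DUPLICATION, NORMAL, SOURCE_SNP


class NoDataError(ValueError):
    """A sample has no SNPs inside the CNV region."""


DEFAULT_REGION = GenomicInterval("chr12", 7_996_000, 8_125_000)


@dataclass(frozen=True)
class SnpCallerConfig:
    """Decision surface on (mean LRR, het fraction, BAF deviation)."""

    region: GenomicInterval = DEFAULT_REGION
    del_lrr_max: float = -0.30
    del_het_fraction_max: float = 0.02
    dup_lrr_min: float = 0.15
    dup_baf_dev_min: float = 0.08
    informative_baf_window: tuple[float, float] = (0.25, 0.75)

    def __post_init__(self) -> None:
        if not self.del_lrr_max < 0 < self.dup_lrr_min:
            raise ValueError("need del_lrr_max < 0 < dup_lrr_min")
        lo, hi = self.informative_baf_window
        if not 0 <= lo < hi <= 1:
            raise ValueError("informative BAF window must be within [0, 1]")


@dataclass(frozen=True)
class RegionSnpSummary:
    sample: str
    mean_lrr: float
    baf_deviation: float
    het_fraction: float
    n_snps: int


def summarize_region(
    snps: pd.DataFrame, cfg: SnpCallerConfig = SnpCallerConfig()
) -> RegionSnpSummary:
    """Two-feature summary of one sample's SNPs over the CNV region.

    Informative (apparently heterozygous) SNPs are those with BAF inside
    the informative window; baf_deviation is their mean |BAF - 0.5| (0 if
    there are none) and het_fraction their share of in-region SNPs.
    """
    samples = snps["sample"].unique()
    if len(samples) != 1:
        raise ValueError("summarize_region expects SNPs for exactly one sample")
    region = cfg.region
    inside = snps[
        (snps["chrom"] == region.chrom)
        & (snps["position"] >= region.start)
        & (snps["position"] <= region.end)
    ]
    if inside.empty:
        raise NoDataError(f"sample {samples[0]!r} has no SNPs inside {region}")
    lo, hi = cfg.informative_baf_window
    informative = inside[(inside["baf"] >= lo) & (inside["baf"] <= hi)]
    baf_dev = (
        float((informative["baf"] - 0.5).abs().mean()) if len(informative) else 0.0
    )
    return RegionSnpSummary(
        sample=str(samples[0]),
        mean_lrr=float(inside["lrr"].mean()),
        baf_deviation=baf_dev,
        het_fraction=len(informative) / len(inside),
        n_snps=len(inside),
    )


def call_from_summary(
    summary: RegionSnpSummary, cfg: SnpCallerConfig = SnpCallerConfig()
) -> str:
    """Three-class call from a region summary; deletion has precedence."""
    if summary.mean_lrr <= cfg.del_lrr_max and (
        summary.het_fraction <= cfg.del_het_fraction_max
    ):
        return DELETION
    if summary.mean_lrr >= cfg.dup_lrr_min and (
        summary.baf_deviation >= cfg.dup_baf_dev_min
    ):
        return DUPLICATION
    return NORMAL


def call_samples(
    snps: pd.DataFrame, cfg: SnpCallerConfig = SnpCallerConfig()
) -> pd.DataFrame:
    """Summaries and calls for every sample in a SNP table.

    Returns a DataFrame with columns sample, mean_lrr, baf_deviation,
    het_fraction, n_snps, category, source.
    """
    region = cfg.region
    inside = snps[
        (snps["chrom"] == region.chrom)
        & (snps["position"] >= region.start)
        & (snps["position"] <= region.end)
    ].copy()
    missing = set(snps["sample"].unique()) - set(inside["sample"].unique())
    if missing:
        raise NoDataError(
            f"{len(missing)} samples have no SNPs inside {region}"
        )
    lo, hi = cfg.informative_baf_window
    informative = (inside["baf"] >= lo) & (inside["baf"] <= hi)
    inside["abs_dev"] = np.where(informative, (inside["baf"] - 0.5).abs(), np.nan)
    grouped = inside.groupby("sample", sort=True)
    out = pd.DataFrame(
        {
            "mean_lrr": grouped["lrr"].mean(),
            "baf_deviation": grouped["abs_dev"].mean().fillna(0.0),
            "het_fraction": grouped["abs_dev"].count() / grouped.size(),
            "n_snps": grouped.size(),
        }
    ).reset_index()
    is_del = (out["mean_lrr"] <= cfg.del_lrr_max) & (
        out["het_fraction"] <= cfg.del_het_fraction_max
    )
    is_dup = (
        ~is_del
        & (out["mean_lrr"] >= cfg.dup_lrr_min)
        & (out["baf_deviation"] >= cfg.dup_baf_dev_min)
    )
    out["category"] = np.select([is_del, is_dup], [DELETION, DUPLICATION], NORMAL)
    out["source"] = SOURCE_SNP
    return out[
        ["sample", "mean_lrr", "baf_deviation", "het_fraction", "n_snps",
         "category", "source"]
    ]


def visual_qc_table(calls: pd.DataFrame) -> pd.DataFrame:
    """Cluster-QC scatter data: (sample, mean_lrr, baf_deviation, call)."""
    if calls.empty:
        return pd.DataFrame(columns=["sample", "mean_lrr", "baf_deviation", "call"])
    out = calls[["sample", "mean_lrr", "baf_deviation", "category"]].copy()
    return out.rename(columns={"category": "call"})
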