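"""PRT ratio normalization and three-class CNV calling.

The P1 assay co-amplifies homologous targets in the two repeat units;
the unit-B/unit-A product intensity ratio reflects their relative copy
number. Per gel row, raw ratios are normalized by the reciprocal of the
row median (removing multiplicative batch effects shared by a row) and
log2-transformed. Samples are then categorized by fixed log2-ratio
thresholds: deletion carriers below -0.75, duplication carriers above
+0.45, normal otherwise, with boundary values assigned normal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import association

logger = logging.getLogger(__name__)

DELETION = "deletion"
NORMAL = "normal"
DUPLICATION = "duplication"
CATEGORIES = (DELETION, NORMAL, DUPLICATION)

SOURCE_PRT = "PRT"
SOURCE_SNP = "SNP"


@dataclass(frozen=True)
class ClassifierConfig:
    """Log2-ratio category boundaries (deletion below, duplication above)."""

    del_threshold: float = -0.75
    dup_threshold: float = 0.45

    def __post_init__(self) -> None:
        if not self.del_threshold < self.dup_threshold:
            raise ValueError("del_threshold must be below dup_threshold")


def normalize_and_ratio(gel: pd.DataFrame) -> pd.DataFrame:
    """Per-replicate normalized log2(B/A) ratios from raw band intensities.

    Expects columns sample, plate, row, replicate, intensity_a,
    intensity_b. Records with non-positive intensities are excluded (and
    logged); rows of a gel with no usable record are skipped with a
    warning. Within each (plate, row, replicate) group every raw ratio is
    multiplied by the reciprocal of the group median (the median over an
    even count being the mean of the central order statistics) and then
    log2-transformed.

    Returns a DataFrame with columns sample, plate, row, replicate,
    log2_ratio.
    """
    usable = (gel["intensity_a"] > 0) & (gel["intensity_b"] > 0)
    n_bad = int((~usable).sum())
    if n_bad:
        logger.warning("excluding %d gel records with non-positive intensities", n_bad)
    gel = gel.loc[usable].copy()
    if gel.empty:
        logger.warning("no usable gel records after filtering")
        return pd.DataFrame(
            columns=["sample", "plate", "row", "replicate", "log2_ratio"]
        )
    gel["raw_ratio"] = gel["intensity_b"] / gel["intensity_a"]
    row_median = gel.groupby(["plate", "row", "replicate"])["raw_ratio"].transform(
        "median"
    )
    gel["log2_ratio"] = np.log2(gel["raw_ratio"] / row_median)
    return gel[["sample", "plate", "row", "replicate", "log2_ratio"]].reset_index(
        drop=True
    )


def classify(log2_ratio: float, cfg: ClassifierConfig = ClassifierConfig()) -> str:
    """Three-class call from one log2 ratio; boundary values are normal."""
    if not np.isfinite(log2_ratio):
        raise ValueError("log2 ratio must be finite")
    if log2_ratio < cfg.del_threshold:
        return DELETION
    if log2_ratio > cfg.dup_threshold:
        return DUPLICATION
    return NORMAL


def classify_series(
    log2_ratio: pd.Series, cfg: ClassifierConfig = ClassifierConfig()
) -> pd.Series:
    """Vectorized :func:`classify`."""
    out = pd.Series(NORMAL, index=log2_ratio.index, dtype=object)
    out[log2_ratio < cfg.del_threshold] = DELETION
    out[log2_ratio > cfg.dup_threshold] = DUPLICATION
    return out


def aggregate_replicates(
    ratios: pd.DataFrame, cfg: ClassifierConfig = ClassifierConfig()
) -> pd.DataFrame:
    """Consensus call per sample from per-replicate log2 ratios.

    Each replicate is classified on its own, then the majority category
    wins; any replicate disagreement sets the discordant flag, and a tie
    resolves conservatively to normal. The consensus log2 ratio is the
    median over replicates.

    Returns a DataFrame with columns sample, log2_ratio,
    n_replicates_used, category, discordant, source.
    """
    ratios = ratios.copy()
    ratios["category"] = classify_series(ratios["log2_ratio"], cfg)
    rows = []
    for sample, grp in ratios.groupby("sample", sort=True):
        counts = grp["category"].value_counts()
        top = counts[counts == counts.max()].index.tolist()
        discordant = len(counts) > 1
        category = top[0] if len(top) == 1 else NORMAL
        rows.append(
            {
                "sample": sample,
                "log2_ratio": float(grp["log2_ratio"].median()),
                "n_replicates_used": int(len(grp)),
                "category": category,
                "discordant": discordant,
                "source": SOURCE_PRT,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["sample", "log2_ratio", "n_replicates_used", "category",
                 "discordant", "source"],
    )


def threshold_sensitivity(
    calls: pd.DataFrame,
    phenotypes: pd.DataFrame,
    del_threshold_grid: list[float],
    cfg: ClassifierConfig = ClassifierConfig(),
) -> pd.DataFrame:
    """Deletion-carrier association at each deletion threshold in a grid.

    ``calls`` needs sample + log2_ratio columns (consensus per sample);
    ``phenotypes`` needs sample + status. For each grid value samples are
    re-classified with that deletion boundary and tested by Pearson
    chi-square on the carrier-by-status 2x2 table. Grids must be strictly
    increasing and stay below the duplication threshold. Thresholds with
    an empty carrier (or non-carrier) class yield an undefined-P row with
    the flag set.
    """
    grid = list(del_threshold_grid)
    if grid != sorted(grid) or len(set(grid)) != len(grid):
        raise ValueError("threshold grid must be strictly increasing")
    if grid and grid[-1] >= cfg.dup_threshold:
        raise ValueError("deletion thresholds must stay below the duplication threshold")
    merged = calls[["sample", "log2_ratio"]].merge(phenotypes, on="sample")
    rows = []
    for thr in grid:
        carrier = merged["log2_ratio"] < thr
        case = merged["status"] == "case"
        a = int((carrier & case).sum())
        b = int((~carrier & case).sum())
        c = int((carrier & ~case).sum())
        d = int((~carrier & ~case).sum())
        table = association.ContingencyTable2x2(a=a, b=b, c=c, d=d, label=f"thr={thr}")
        try:
            chi2, p = association.pearson_chi2(table)
            flagged = False
        except association.UndefinedStatisticError:
            chi2, p = float("nan"), float("nan")
            flagged = True
        rows.append(
            {"threshold": thr, "a": a, "b": b, "c": c, "d": d,
             "chi2": chi2, "p": p, "undefined": flagged}
        )
    return pd.DataFrame(rows)


def concordance(
    calls_a: pd.DataFrame, calls_b: pd.DataFrame
) -> tuple[float, pd.DataFrame]:
    """Category agreement rate and cross-tabulation over shared samples."""
    merged = calls_a[["sample", "category"]].merge(
        calls_b[["sample", "category"]], on="sample", suffixes=("_a", "_b")
    )
    if merged.empty:
        raise ValueError("no shared samples between call sets")
    rate = float((merged["category_a"] == merged["category_b"]).mean())
    crosstab = pd.crosstab(merged["category_a"], merged["category_b"])
    return rate, crosstab


def ratio_histogram(calls: pd.DataFrame, bin_width: float = 0.05) -> pd.DataFrame:
    """Binned counts of consensus log2 ratios (data for a spread plot)."""
    values = calls["log2_ratio"].to_numpy()
    lo = np.floor(values.min() / bin_width) * bin_width
    hi = np.ceil(values.max() / bin_width) * bin_width
    edges = np.arange(lo, hi + bin_width, bin_width)
    counts, edges = np.histogram(values, bins=edges)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )
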