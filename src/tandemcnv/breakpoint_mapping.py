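"""NAHR crossover-interval inference from pPRT step profiles.

A variant haplotype changes the unit-B/unit-A abundance ratio on the two
sides of its crossover: a heterozygous deletion carrier shows log2(B/A)
of -1 upstream and +1 downstream, a heterozygous expansion carrier
+log2(3/2) upstream and -log2(3/2) downstream. Over an ordered panel of
assays the profile is therefore a single-step function, and the
crossover is localized to the interval between the two assays flanking
the step. Because exactly one crossover underlies each ancestral event
and panels are tiny (<= ~10 loci), the fit is an exhaustive search over
all 2*(L-1)+1 single-changepoint hypotheses by sum of squared residuals.

Junction-spanning PCR across the AB1 stretch (primer pairs AF+UR for the
deletion junction, BF+UR for the duplication junction) can then refine a
consistent pPRT interval to the ~1.1 kb AB1 coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .intervals import GenomicInterval
from .repeat_model import LOG2_3_2, RepeatArchitecture


@dataclass(frozen=True)
class PprtProfile:
    """Per-locus log2(B/A) values for one sample over an ordered panel."""

    sample: str
    panel: tuple[str, ...]
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.panel) < 2:
            raise ValueError("a pPRT profile needs at least 2 loci")
        if len(self.panel) != len(self.values):
            raise ValueError("panel and values lengths differ")
        if not all(math.isfinite(v) for v in self.values):
            raise ValueError("profile values must be finite")


@dataclass(frozen=True)
class BreakpointInterval:
    """Inferred crossover interval between two adjacent panel assays."""

    sample: str
    variant_type: str  # 'DEL', 'DUP' or 'NONE'
    left_locus: str | None
    right_locus: str | None
    interval_a: GenomicInterval | None
    interval_b: GenomicInterval | None
    sse: float
    ab1_refined: bool = False
    junction_consistent: bool | None = None


@dataclass(frozen=True)
class JunctionAssayResult:
    """Presence/absence of the AB1 junction-spanning PCR products."""

    sample: str
    deletion_junction_present: bool
    duplication_junction_present: bool


def _step_vector(level_up: float, level_down: float, k: int, n: int) -> np.ndarray:
    return np.array([level_up] * k + [level_down] * (n - k))


def infer_crossover(
    profile: PprtProfile, arch: RepeatArchitecture
) -> BreakpointInterval:
    """Best single-changepoint fit of a profile to the NAHR step model.

    Hypotheses are NONE (flat zero) and (type, k) for type in {DEL, DUP}
    and changepoint after locus k (1 <= k <= L-1), with model levels
    fixed by the repeat architecture rather than estimated. Ties in SSE
    resolve to NONE first, then to the changepoint closest to the panel
    centre, then DEL before DUP.
    """
    loci = [arch.locus(name) for name in profile.panel]
    offsets = [loc.offset for loc in loci]
    ascending = offsets == sorted(offsets)
    if not ascending and offsets == sorted(offsets, reverse=True):
        rev = PprtProfile(profile.sample, profile.panel[::-1], profile.values[::-1])
        return infer_crossover(rev, arch)
    if not ascending:
        raise ValueError("panel loci must be ordered by homologous offset")

    values = np.asarray(profile.values, dtype=float)
    n = len(values)
    centre = (n - 1) / 2  # changepoint index k sits between loci k-1 and k (0-based)

    # (sse, tie-rank tuple, hypothesis)
    candidates: list[tuple[float, tuple, str, int | None]] = []
    sse_none = float(np.sum(values**2))
    candidates.append((sse_none, (0, 0.0, 0), "NONE", None))
    for k in range(1, n):
        for rank, (vtype, up, down) in enumerate(
            [("DEL", -1.0, 1.0), ("DUP", LOG2_3_2, -LOG2_3_2)]
        ):
            sse = float(np.sum((values - _step_vector(up, down, k, n)) ** 2))
            candidates.append((sse, (1, abs(k - 0.5 - centre), rank), vtype, k))

    eps = 1e-12
    best_sse = min(c[0] for c in candidates)
    tied = [c for c in candidates if c[0] <= best_sse + eps]
    tied.sort(key=lambda c: c[1])
    sse, _, vtype, k = tied[0]

    if vtype == "NONE":
        return BreakpointInterval(
            sample=profile.sample,
            variant_type="NONE",
            left_locus=None,
            right_locus=None,
            interval_a=None,
            interval_b=None,
            sse=sse,
        )
    assert k is not None
    left, right = loci[k - 1], loci[k]
    interval_a = GenomicInterval(
        left.target_a.chrom, left.target_a.end + 1, right.target_a.start - 1
    )
    interval_b = GenomicInterval(
        left.target_b.chrom, left.target_b.end + 1, right.target_b.start - 1
    )
    return BreakpointInterval(
        sample=profile.sample,
        variant_type=vtype,
        left_locus=left.name,
        right_locus=right.name,
        interval_a=interval_a,
        interval_b=interval_b,
        sse=sse,
    )


def interval_widths(
    bp: BreakpointInterval, arch: RepeatArchitecture
) -> tuple[int, int]:
    """Crossover-interval widths (bp) in unit A and unit B.

    The width is the gap strictly between the inner edges of the flanking
    assay targets in each unit.
    """
    if bp.variant_type == "NONE":
        raise ValueError("no crossover interval for a NONE call")
    left = arch.locus(bp.left_locus)
    right = arch.locus(bp.right_locus)
    width_a = right.target_a.start - left.target_a.end - 1
    width_b = right.target_b.start - left.target_b.end - 1
    return width_a, width_b


def integrate_junction(
    bp: BreakpointInterval,
    junction: JunctionAssayResult,
    arch: RepeatArchitecture,
) -> BreakpointInterval:
    """Refine a pPRT interval with the AB1 junction-PCR result.

    A junction product matching the called variant type replaces the
    interval by the AB1 coordinates and marks the call consistent; a
    mismatch keeps the pPRT interval and flags the inconsistency.
    """
    if bp.sample != junction.sample:
        raise ValueError("breakpoint and junction results are for different samples")
    if bp.variant_type == "DEL":
        supported = junction.deletion_junction_present
    elif bp.variant_type == "DUP":
        supported = junction.duplication_junction_present
    else:
        consistent = not (
            junction.deletion_junction_present or junction.duplication_junction_present
        )
        return replace(bp, junction_consistent=consistent)
    if supported:
        return replace(
            bp,
            interval_a=arch.ab1_interval_a,
            interval_b=arch.ab1_interval_b,
            ab1_refined=True,
            junction_consistent=True,
        )
    return replace(bp, junction_consistent=False)


def breakpoint_census(refined: Iterable[BreakpointInterval]) -> tuple[float, int, int]:
    """Fraction of variant samples whose breakpoint is AB1-consistent.

    Returns (fraction, n_consistent, n_variant).
    """
    variants = [bp for bp in refined if bp.variant_type != "NONE"]
    if not variants:
        raise ValueError("no variant samples in census")
    consistent = sum(1 for bp in variants if bp.junction_consistent)
    return consistent / len(variants), consistent, len(variants)
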