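"""Structural model of the chr12p13.31 two-unit tandem duplication.

The locus is a tandem pair of diverged ~100 kb ("A") and ~145 kb ("B")
repeat units containing NANOG, SLC2A14, NANOGP1 and SLC2A3. Nonallelic
homologous recombination (NAHR) between misaligned units creates
reciprocal single-unit deletion and expansion chromosomes. A deletion
chromosome carries one hybrid unit (A-form sequence upstream of the
crossover joined to B-form sequence downstream); the reciprocal
expansion carries three units: a full A, a hybrid (B-form upstream,
A-form downstream), and a full B.

From that construction, for any assay locus with a homologous offset x
and a crossover at offset c (offsets measured on the A-unit scale):

===========  =================  =================
allele       x < c              x > c
===========  =================  =================
normal       (1 A, 1 B)         (1 A, 1 B)
deletion     (1 A, 0 B)         (0 A, 1 B)
expansion    (1 A, 2 B)         (2 A, 1 B)
===========  =================  =================

Summing over the two alleles of a diploid genotype gives the expected
B/A product ratio of a paralogue ratio test (PRT) at that locus; with
one normal allele the attainable ratios are exactly
{1/2, 2/3, 1, 3/2, 2}.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .intervals import GenomicInterval

ASSEMBLY = "GRCh37"
CHROM = "chr12"

LOG2_3_2 = math.log2(1.5)


class UndefinedLocusError(ValueError):
    """An assay locus coincides with a crossover: its copy form is undefined."""


class DivisionUndefinedError(ZeroDivisionError):
    """No A-form copies present; the B/A ratio is undefined."""


class InvalidCrossoverError(ValueError):
    """Crossover intervals ordered inconsistently with the unit layout."""


class AlleleKind(enum.Enum):
    """Structural allele classes, named by which P1 target they remove/add."""

    NORMAL = "normal"
    DEL_A = "del_a"
    DEL_B = "del_b"
    DUP_A = "dup_a"
    DUP_B = "dup_b"

    @property
    def is_deletion(self) -> bool:
        return self in (AlleleKind.DEL_A, AlleleKind.DEL_B)

    @property
    def is_duplication(self) -> bool:
        return self in (AlleleKind.DUP_A, AlleleKind.DUP_B)


class GeneEffect(enum.Enum):
    FULL = "full"
    PARTIAL = "partial"
    NONE = "none"


@dataclass(frozen=True)
class AssayLocus:
    """One PRT/pPRT assay: paired homologous targets in unit A and unit B.

    ``offset`` is the homologous coordinate of the locus: the distance in
    bp of the A-unit target start from the A-unit start. Crossovers are
    expressed on the same scale, so only the ordering of offsets matters
    for inference.
    """

    name: str
    target_a: GenomicInterval
    target_b: GenomicInterval
    offset: int

    def __post_init__(self) -> None:
        if self.offset < 0:
            raise ValueError(f"locus {self.name}: offset must be >= 0")


@dataclass(frozen=True)
class RepeatArchitecture:
    """The two repeat units, the assay panel, and the AB1 crossover stretch."""

    unit_a: GenomicInterval
    unit_b: GenomicInterval
    loci: tuple[AssayLocus, ...]
    ab1_interval_a: GenomicInterval
    ab1_interval_b: GenomicInterval

    def __post_init__(self) -> None:
        if self.unit_a.chrom != self.unit_b.chrom:
            raise ValueError("repeat units must share a chromosome")
        if self.unit_a.end >= self.unit_b.start:
            raise ValueError("unit A must precede unit B without overlap")
        offsets = [loc.offset for loc in self.loci]
        if len(set(offsets)) != len(offsets):
            raise ValueError("assay locus offsets must be unique")
        if offsets != sorted(offsets):
            raise ValueError("assay loci must be ordered by homologous offset")
        for loc in self.loci:
            if not self.unit_a.contains(loc.target_a):
                raise ValueError(f"locus {loc.name}: A target outside unit A")
            if not self.unit_b.contains(loc.target_b):
                raise ValueError(f"locus {loc.name}: B target outside unit B")

    @property
    def unit_length(self) -> int:
        """Length of unit A, the scale on which offsets live."""
        return self.unit_a.length

    def locus(self, name: str) -> AssayLocus:
        for loc in self.loci:
            if loc.name == name:
                return loc
        raise KeyError(f"no assay locus named {name!r}")

    @property
    def ab1_offset(self) -> float:
        """Homologous offset of the AB1 midpoint on the A-unit scale."""
        return self.ab1_interval_a.midpoint - self.unit_a.start


@dataclass(frozen=True)
class StructuralAllele:
    """One haplotype's repeat architecture.

    ``crossover_offset`` is present for every non-normal allele and marks
    the NAHR crossover on the A-unit offset scale; it must lie strictly
    inside the unit span.
    """

    kind: AlleleKind
    crossover_offset: float | None = None

    def __post_init__(self) -> None:
        if self.kind is AlleleKind.NORMAL:
            if self.crossover_offset is not None:
                raise ValueError("normal allele carries no crossover")
        else:
            if self.crossover_offset is None:
                raise ValueError(f"{self.kind.value} allele needs a crossover offset")
            if self.crossover_offset <= 0:
                raise ValueError("crossover offset must lie strictly inside the unit")

    def copy_contribution(self, locus: AssayLocus) -> tuple[int, int]:
        """(A-form, B-form) copies this haplotype contributes at ``locus``."""
        if self.kind is AlleleKind.NORMAL:
            return (1, 1)
        assert self.crossover_offset is not None
        if locus.offset == self.crossover_offset:
            raise UndefinedLocusError(
                f"locus {locus.name} (offset {locus.offset}) coincides with a "
                f"crossover at {self.crossover_offset}"
            )
        upstream = locus.offset < self.crossover_offset
        if self.kind.is_deletion:
            return (1, 0) if upstream else (0, 1)
        return (1, 2) if upstream else (2, 1)


NORMAL_ALLELE = StructuralAllele(AlleleKind.NORMAL)


@dataclass(frozen=True)
class DiploidGenotype:
    """Two structural alleles; carriers are assumed to keep one normal allele."""

    allele1: StructuralAllele
    allele2: StructuralAllele

    @property
    def has_normal_allele(self) -> bool:
        return (
            self.allele1.kind is AlleleKind.NORMAL
            or self.allele2.kind is AlleleKind.NORMAL
        )


def copy_numbers(genotype: DiploidGenotype, locus: AssayLocus) -> tuple[int, int]:
    """Diploid (A-form, B-form) copy counts at one assay locus."""
    a1 = genotype.allele1.copy_contribution(locus)
    a2 = genotype.allele2.copy_contribution(locus)
    return (a1[0] + a2[0], a1[1] + a2[1])


def expected_ratio(
    genotype: DiploidGenotype, locus: AssayLocus
) -> tuple[float, float]:
    """Expected B/A product ratio at ``locus`` and its log2.

    A normal diploid returns exactly (1.0, 0.0).
    """
    n_a, n_b = copy_numbers(genotype, locus)
    if n_a == 0:
        raise DivisionUndefinedError(
            f"zero A-form copies at {locus.name} for genotype "
            f"({genotype.allele1.kind.value}/{genotype.allele2.kind.value})"
        )
    ratio = n_b / n_a
    return ratio, math.log2(ratio)


@dataclass(frozen=True)
class RearrangementSpan:
    """The genomic segment gained/lost by a crossover between the two units."""

    interval: GenomicInterval
    length_bp: float
    length_kb_rounded: int
    uncertainty_bp: float  # half the summed crossover-interval widths


def rearrangement_span(
    arch: RepeatArchitecture,
    cross_a: GenomicInterval,
    cross_b: GenomicInterval,
) -> RearrangementSpan:
    """Span deleted (or duplicated, reciprocally) by a crossover.

    The crossover is localized only to homologous intervals in each unit;
    the span is taken midpoint-to-midpoint, with the interval half-widths
    carried as uncertainty.
    """
    if not arch.unit_a.contains(cross_a):
        raise InvalidCrossoverError(f"crossover A interval {cross_a} outside unit A")
    if not arch.unit_b.contains(cross_b):
        raise InvalidCrossoverError(f"crossover B interval {cross_b} outside unit B")
    mid_a = cross_a.midpoint
    mid_b = cross_b.midpoint
    if mid_b <= mid_a:
        raise InvalidCrossoverError(
            f"crossover midpoints out of order: B {mid_b} <= A {mid_a}"
        )
    length = mid_b - mid_a
    interval = GenomicInterval(arch.unit_a.chrom, int(mid_a), int(math.ceil(mid_b)))
    uncertainty = (cross_a.length + cross_b.length) / 2
    return RearrangementSpan(
        interval=interval,
        length_bp=length,
        length_kb_rounded=round(length / 1000),
        uncertainty_bp=uncertainty,
    )


def gene_consequences(
    span: GenomicInterval,
    genes: Iterable[tuple[str, GenomicInterval]],
    gene_assembly: str | None = None,
    expected_assembly: str = ASSEMBLY,
) -> Mapping[str, GeneEffect]:
    """Classify each gene as fully inside, partially overlapping, or outside a span."""
    if gene_assembly is not None and gene_assembly != expected_assembly:
        raise ValueError(
            f"gene coordinates are {gene_assembly}, span is {expected_assembly}"
        )
    out: dict[str, GeneEffect] = {}
    for name, iv in genes:
        if span.contains(iv):
            out[name] = GeneEffect.FULL
        elif span.overlaps(iv):
            out[name] = GeneEffect.PARTIAL
        else:
            out[name] = GeneEffect.NONE
    return out


def default_architecture() -> RepeatArchitecture:
    """The packaged chr12p13.31 architecture (GRCh37).

    P1 target and AB1 coordinates are the published ones. The pPRT
    (B5-B10) targets are reconstructed: their exact coordinates are not
    public, so they are placed to honour the known constraints - panel
    order B5 < B6 < B8 < P1 < B9 < B10 along the units, an 8.8 kb
    B5[A]-B6[A] gap and a 6.1 kb B5[B]-B6[B] gap, and AB1 falling between
    B9 and B10. Unit boundaries are similarly approximate (~100 kb A,
    ~145 kb B); only the ordering of offsets enters any inference.
    """
    unit_a = GenomicInterval(CHROM, 7_896_500, 7_996_999)
    unit_b = GenomicInterval(CHROM, 7_997_000, 8_141_999)

    def locus(name: str, a_start: int, a_end: int, b_start: int, b_end: int) -> AssayLocus:
        return AssayLocus(
            name=name,
            target_a=GenomicInterval(CHROM, a_start, a_end),
            target_b=GenomicInterval(CHROM, b_start, b_end),
            offset=a_start - unit_a.start,
        )

    loci = (
        locus("B5", 7_936_001, 7_936_200, 8_049_001, 8_049_200),
        locus("B6", 7_945_001, 7_945_200, 8_055_301, 8_055_500),
        locus("B8", 7_956_001, 7_956_200, 8_066_001, 8_066_200),
        # P1: published product coordinates (unit A target in SLC2A14
        # 3'UTR-equivalent, unit B target in the SLC2A3 3'UTR).
        locus("P1", 7_966_286, 7_966_484, 8_073_299, 8_073_582),
        locus("B9", 7_986_001, 7_986_200, 8_118_001, 8_118_200),
        locus("B10", 7_996_701, 7_996_900, 8_130_001, 8_130_200),
    )
    return RepeatArchitecture(
        unit_a=unit_a,
        unit_b=unit_b,
        loci=loci,
        ab1_interval_a=GenomicInterval(CHROM, 7_995_630, 7_996_700),
        ab1_interval_b=GenomicInterval(CHROM, 8_124_315, 8_125_390),
    )


def expected_pprt_profile(
    allele: StructuralAllele, panel: Sequence[AssayLocus]
) -> list[float]:
    """Noise-free log2(B/A) profile of a NORMAL/``allele`` genotype over a panel."""
    genotype = DiploidGenotype(NORMAL_ALLELE, allele)
    return [expected_ratio(genotype, loc)[1] for loc in panel]
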