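"""Single-changepoint NAHR crossover inference and junction integration."""

import math

import pytest

from tandemcnv.breakpoint_mapping import (
    BreakpointInterval,
    JunctionAssayResult,
    PprtProfile,
    breakpoint_census,
    infer_crossover,
    integrate_junction,
    interval_widths,
)
from tandemcnv.repeat_model import (
    AlleleKind,
    StructuralAllele,
    expected_pprt_profile,
)

LOG32 = math.log2(1.5)


def profile(arch, values, sample="s"):
    return PprtProfile(sample, tuple(l.name for l in arch.loci), tuple(values))


def test_noiseless_deletion_step(arch):
    bp = infer_crossover(profile(arch, [-1, -1, -1, -1, 1, 1]), arch)
    assert bp.variant_type == "DEL"
    assert (bp.left_locus, bp.right_locus) == ("P1", "B9")
    assert bp.sse == pytest.approx(0.0, abs=1e-12)


def test_flat_profile_is_none(arch):
    bp = infer_crossover(profile(arch, [0.0] * 6), arch)
    assert bp.variant_type == "NONE"
    assert bp.interval_a is None and bp.sse == 0.0


def test_sse_tie_prefers_none(arch):
    # two-locus profile equidistant from the flat and the DUP step model
    x = LOG32 / 2
    two = PprtProfile("s", tuple(l.name for l in arch.loci[:2]), (x, -x))
    bp = infer_crossover(two, arch)
    assert bp.variant_type == "NONE"


def test_generating_hypothesis_is_unique_zero_residual(arch):
    """Every noiseless step profile is fit exactly and only by its generator."""
    panel = list(arch.loci)
    for kind in (AlleleKind.DEL_B, AlleleKind.DUP_B):
        for k in range(1, len(panel)):
            crossover = (panel[k - 1].offset + panel[k].offset) / 2
            values = expected_pprt_profile(StructuralAllele(kind, crossover), panel)
            bp = infer_crossover(profile(arch, values), arch)
            assert bp.sse == pytest.approx(0.0, abs=1e-12)
            assert bp.variant_type == ("DEL" if kind is AlleleKind.DEL_B else "DUP")
            assert bp.left_locus == panel[k - 1].name
            assert bp.right_locus == panel[k].name


def test_deletion_and_duplication_levels_never_confusable(arch):
    """The noiseless DEL level set {-1,+1} is never best fit by a DUP model."""
    values = [-1, -1, 1, 1, 1, 1]
    bp = infer_crossover(profile(arch, values), arch)
    assert bp.variant_type == "DEL"
    values = [LOG32, LOG32, -LOG32, -LOG32, -LOG32, -LOG32]
    assert infer_crossover(profile(arch, values), arch).variant_type == "DUP"


def test_panel_reversal_equivariance(arch):
    fwd = infer_crossover(profile(arch, [-1, -1, -1, -1, 1, 1]), arch)
    rev = PprtProfile(
        "s", tuple(l.name for l in arch.loci)[::-1], (1, 1, -1, -1, -1, -1)
    )
    bwd = infer_crossover(rev, arch)
    assert (bwd.left_locus, bwd.right_locus) == (fwd.left_locus, fwd.right_locus)
    assert bwd.interval_a == fwd.interval_a
    assert bwd.interval_b == fwd.interval_b


def test_too_few_loci_rejected(arch):
    with pytest.raises(ValueError):
        PprtProfile("s", ("P1",), (0.0,))


def test_interval_widths_match_panel_construction(arch):
    """B5-B6 crossovers localize to 8.8 kb in unit A and 6.1 kb in unit B."""
    bp = infer_crossover(
        profile(arch, [LOG32, -LOG32, -LOG32, -LOG32, -LOG32, -LOG32]), arch
    )
    assert (bp.left_locus, bp.right_locus) == ("B5", "B6")
    assert interval_widths(bp, arch) == (8_800, 6_100)


def test_interval_widths_undefined_for_none(arch):
    bp = infer_crossover(profile(arch, [0.0] * 6), arch)
    with pytest.raises(ValueError):
        interval_widths(bp, arch)


def test_junction_refines_to_ab1(arch):
    bp = infer_crossover(profile(arch, [-1, -1, -1, -1, -1, 1]), arch)
    assert (bp.left_locus, bp.right_locus) == ("B9", "B10")
    j = JunctionAssayResult("s", True, False)
    refined = integrate_junction(bp, j, arch)
    assert refined.ab1_refined and refined.junction_consistent
    assert refined.interval_a == arch.ab1_interval_a
    assert refined.interval_a.start == 7_995_630 and refined.interval_a.end == 7_996_700
    assert refined.interval_b == arch.ab1_interval_b


def test_junction_mismatch_keeps_interval(arch):
    bp = infer_crossover(profile(arch, [-1, -1, -1, -1, -1, 1]), arch)
    refined = integrate_junction(bp, JunctionAssayResult("s", False, False), arch)
    assert refined.junction_consistent is False
    assert not refined.ab1_refined
    assert refined.interval_a == bp.interval_a


def test_none_call_with_no_products_is_consistent(arch):
    bp = infer_crossover(profile(arch, [0.0] * 6), arch)
    refined = integrate_junction(bp, JunctionAssayResult("s", False, False), arch)
    assert refined.junction_consistent is True


def test_junction_sample_mismatch_rejected(arch):
    bp = infer_crossover(profile(arch, [0.0] * 6), arch)
    with pytest.raises(ValueError):
        integrate_junction(bp, JunctionAssayResult("other", False, False), arch)


def census_fixture(n_variant, n_consistent):
    out = []
    for i in range(n_variant):
        out.append(
            BreakpointInterval(
                sample=f"v{i}", variant_type="DEL", left_locus="B9",
                right_locus="B10", interval_a=None, interval_b=None, sse=0.0,
                junction_consistent=i < n_consistent,
            )
        )
    return out


def test_breakpoint_census_rates():
    frac, num, den = breakpoint_census(census_fixture(308, 297))
    assert (num, den) == (297, 308)
    assert round(100 * frac, 1) == 96.4
    assert breakpoint_census(census_fixture(10, 10))[0] == 1.0
    assert breakpoint_census(census_fixture(10, 5))[0] == 0.5
    # a cohort in which 193 of 200 variant chromosomes carry the AB1 junction
    assert 100 * breakpoint_census(census_fixture(200, 193))[0] == pytest.approx(96.5)


def test_census_requires_variants():
    bp = BreakpointInterval("s", "NONE", None, None, None, None, 0.0)
    with pytest.raises(ValueError):
        breakpoint_census([bp])


def test_noisy_recovery_monte_carlo(arch):
    """Crossover between loci 5 and 6 recovered >=99% at noise sd 0.1."""
    from tandemcnv.synthetic_data import simulate_pprt

    panel = list(arch.loci)
    crossover = (panel[4].offset + panel[5].offset) / 2
    allele = StructuralAllele(AlleleKind.DUP_B, crossover)
    hits = 0
    n = 300
    for i in range(n):
        prof = simulate_pprt(allele, panel, noise_sd=0.1, seed=10_000 + i)
        bp = infer_crossover(prof, arch)
        hits += (
            bp.variant_type == "DUP"
            and bp.left_locus == "B9"
            and bp.right_locus == "B10"
        )
    assert hits / n >= 0.99
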