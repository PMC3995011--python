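"""Generator fidelity: frequencies, noise structure, and determinism."""

import math

import numpy as np
import pandas as pd
import pytest

from tandemcnv import synthetic_data as sim
from tandemcnv.prt_genotyping import aggregate_replicates, normalize_and_ratio
from tandemcnv.repeat_model import (
    AlleleKind,
    NORMAL_ALLELE,
    StructuralAllele,
    expected_pprt_profile,
)
from tandemcnv.snp_cnv_calling import DEFAULT_REGION


def test_case_frequency_odds_transform():
    """Control odds 33/1236 and OR 0.442 imply ~1.17% case carriers."""
    f = sim.case_frequency(33 / 1269, 0.442)
    assert f == pytest.approx(28 / 2403, abs=2e-4)
    assert f == pytest.approx(0.0117, abs=1e-4)


def test_null_odds_ratio_preserves_frequency():
    assert sim.case_frequency(0.05, 1.0) == pytest.approx(0.05)


def test_empty_case_stratum_is_valid():
    cfg = sim.CohortSimConfig(n_cases=0, n_controls=10, seed=1)
    truth = sim.simulate_cohort(cfg)
    assert len(truth) == 10
    assert (truth["status"] == "control").all()


def test_cohort_deterministic_under_seed():
    cfg = sim.CohortSimConfig(n_cases=200, n_controls=100, seed=3)
    pd.testing.assert_frame_equal(sim.simulate_cohort(cfg), sim.simulate_cohort(cfg))


def test_invalid_frequencies_rejected():
    with pytest.raises(sim.ConfigError):
        sim.CohortSimConfig(control_del_carrier_freq=1.2)
    with pytest.raises(sim.ConfigError):
        sim.CohortSimConfig(or_del=-1.0)


def test_control_carrier_frequency_recovery():
    """Empirical control deletion-carrier rate within 3 SE over 50,000."""
    n = 50_000
    f = 33 / 1269
    cfg = sim.CohortSimConfig(n_cases=0, n_controls=n, seed=17)
    truth = sim.simulate_cohort(cfg)
    rate = (truth["true_class"] == sim.CLASS_DELETION).mean()
    se = math.sqrt(f * (1 - f) / n)
    assert abs(rate - f) < 3 * se


def test_noiseless_gel_ratio_is_exact(arch):
    truth = pd.DataFrame(
        {
            "sample": ["s1", "s2", "s3"],
            "status": "control",
            "true_class": ["deletion", "normal", "duplication"],
        }
    )
    cfg = sim.GelSimConfig(
        row_effect_sd_log=0.0, band_noise_sd_log=0.0,
        relative_efficiency_b=1.0, n_replicates=1, seed=0,
    )
    gel = sim.simulate_gel(truth, arch, cfg)
    ratio = (gel["intensity_b"] / gel["intensity_a"]).to_numpy()
    assert ratio == pytest.approx([0.5, 1.0, 1.5])


def test_row_effects_cancel_in_ratio(arch):
    """With band noise off, row batch effects leave every ratio at 1."""
    truth = pd.DataFrame(
        {
            "sample": [f"s{i}" for i in range(48)],
            "status": "control",
            "true_class": "normal",
        }
    )
    cfg = sim.GelSimConfig(
        row_effect_sd_log=0.5, band_noise_sd_log=0.0, n_replicates=2, seed=5
    )
    gel = sim.simulate_gel(truth, arch, cfg)
    assert (gel["intensity_b"] / gel["intensity_a"]).to_numpy() == pytest.approx(1.0)
    # but the bands themselves do vary between rows
    assert gel.groupby("row")["intensity_a"].mean().nunique() > 1


def test_gel_class_means_match_model(arch):
    """Empirical log2-ratio means per class within 0.1 of expectation."""
    rng = np.random.default_rng(0)
    classes = rng.choice(sim.CLASSES, size=1000, p=[0.2, 0.6, 0.2])
    truth = pd.DataFrame(
        {
            "sample": [f"s{i:04d}" for i in range(1000)],
            "status": "control",
            "true_class": classes,
        }
    )
    gel = sim.simulate_gel(truth, arch, sim.GelSimConfig(seed=6))
    calls = aggregate_replicates(normalize_and_ratio(gel))
    merged = calls.merge(truth, on="sample")
    expected = {"deletion": -1.0, "normal": 0.0, "duplication": math.log2(1.5)}
    for cls, mean_log2 in merged.groupby("true_class")["log2_ratio"].mean().items():
        assert mean_log2 == pytest.approx(expected[cls], abs=0.1)


def test_noiseless_snp_baf_clusters():
    truth = pd.DataFrame(
        {
            "sample": ["del", "nor", "dup"],
            "status": "control",
            "true_class": ["deletion", "normal", "duplication"],
        }
    )
    cfg = sim.SnpSimConfig(lrr_sd=0.0, baf_sd=0.0, seed=2)
    snps = sim.simulate_snps(truth, DEFAULT_REGION, cfg)
    region = snps[
        (snps["position"] >= DEFAULT_REGION.start)
        & (snps["position"] <= DEFAULT_REGION.end)
    ]
    by = {s: g for s, g in region.groupby("sample")}

    def only_values(series, allowed):
        return np.isclose(
            series.to_numpy()[:, None], np.asarray(allowed)[None, :]
        ).any(axis=1).all()

    # one copy: BAF only 0 or 1, LRR at the one-copy mean
    assert only_values(by["del"]["baf"], [0.0, 1.0])
    assert by["del"]["lrr"].to_numpy() == pytest.approx(-0.66)
    # three copies: heterozygous BAF at thirds
    assert only_values(by["dup"]["baf"], [0.0, 1 / 3, 2 / 3, 1.0])
    assert by["dup"]["lrr"].to_numpy() == pytest.approx(0.40)
    assert by["nor"]["lrr"].to_numpy() == pytest.approx(0.0)
    # flanks are two-copy for everyone
    flank = snps[~snps.index.isin(region.index)]
    assert only_values(flank["baf"], [0.0, 0.5, 1.0])


def test_normal_sample_mean_lrr_centred():
    truth = pd.DataFrame(
        {"sample": ["n"], "status": "control", "true_class": ["normal"]}
    )
    cfg = sim.SnpSimConfig(n_snps_region=2000, seed=3)
    snps = sim.simulate_snps(truth, DEFAULT_REGION, cfg)
    region = snps[
        (snps["position"] >= DEFAULT_REGION.start)
        & (snps["position"] <= DEFAULT_REGION.end)
    ]
    assert region["lrr"].mean() == pytest.approx(0.0, abs=0.02)


def test_unknown_class_rejected(arch):
    truth = pd.DataFrame(
        {"sample": ["x"], "status": "control", "true_class": ["triplication"]}
    )
    with pytest.raises(sim.ConfigError):
        sim.simulate_snps(truth, DEFAULT_REGION, sim.SnpSimConfig())
    with pytest.raises(sim.ConfigError):
        sim.genotype_for_class("triplication", arch)


@pytest.mark.parametrize(
    "kind, expected",
    [
        (AlleleKind.DEL_B, [-1.0] * 4 + [1.0] * 2),
        (AlleleKind.DUP_B, [math.log2(1.5)] * 4 + [-math.log2(1.5)] * 2),
    ],
)
def test_pprt_step_profiles(arch, kind, expected):
    """A crossover between the 4th and 5th of 6 loci steps the profile there."""
    panel = list(arch.loci)
    crossover = (panel[3].offset + panel[4].offset) / 2
    prof = sim.simulate_pprt(
        StructuralAllele(kind, crossover), panel, noise_sd=0.0, seed=0
    )
    assert list(prof.values) == pytest.approx(expected)


def test_pprt_normal_profile_flat(arch):
    prof = sim.simulate_pprt(NORMAL_ALLELE, list(arch.loci), noise_sd=0.0)
    assert list(prof.values) == pytest.approx([0.0] * 6)
    assert expected_pprt_profile(NORMAL_ALLELE, list(arch.loci)) == [0.0] * 6
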