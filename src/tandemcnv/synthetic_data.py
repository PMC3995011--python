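"""Synthetic cohorts, gel intensities, SNP intensity tracks and pPRT profiles.

The generator reproduces the statistical structure every downstream
stage assumes, so the whole pipeline runs and is testable without any
external data:

* carrier genotypes at configurable control frequencies, with case
  frequencies derived from a per-variant odds ratio on the carrier odds;
* P1 gel band intensities with multiplicative per-gel-row batch effects
  (shared by both bands, hence removable by per-row median
  normalization) and lognormal per-band noise;
* SNP B-allele-frequency clusters and log-R-ratio shifts for 1, 2 or 3
  regional copies;
* single-step pPRT profiles for crossover-bearing haplotypes.

All randomness flows from the seed in each config; a fixed seed gives
bit-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .breakpoint_mapping import PprtProfile
from .intervals import GenomicInterval
from .repeat_model import (
    AlleleKind,
    AssayLocus,
    DiploidGenotype,
    NORMAL_ALLELE,
    RepeatArchitecture,
    StructuralAllele,
    copy_numbers,
    expected_pprt_profile,
)

CLASS_DELETION = "deletion"
CLASS_NORMAL = "normal"
CLASS_DUPLICATION = "duplication"
CLASSES = (CLASS_DELETION, CLASS_NORMAL, CLASS_DUPLICATION)


class ConfigError(ValueError):
    pass


def case_frequency(p_control: float, odds_ratio: float) -> float:
    """Case carrier frequency implied by a control frequency and an OR."""
    if not 0 <= p_control < 1:
        raise ConfigError(f"control frequency {p_control} outside [0, 1)")
    if odds_ratio <= 0:
        raise ConfigError("odds ratio must be positive")
    odds = odds_ratio * p_control / (1 - p_control)
    return odds / (1 + odds)


@dataclass(frozen=True)
class CohortSimConfig:
    """Case-control cohort at the Swedish study scale by default.

    Control carrier frequencies default to the Swedish control counts
    (33/1,269 deletion carriers, 55/1,269 duplication carriers) and the
    deletion odds ratio to the protective 0.442; the duplication OR
    defaults to the null-ish 0.889 the Swedish counts imply.
    """

    n_cases: int = 2403
    n_controls: int = 1269
    control_del_carrier_freq: float = 33 / 1269
    control_dup_carrier_freq: float = 55 / 1269
    or_del: float = 0.442
    or_dup: float = 0.889
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("control_del_carrier_freq", "control_dup_carrier_freq"):
            f = getattr(self, name)
            if not 0 <= f < 1:
                raise ConfigError(f"{name}={f} outside [0, 1)")
        if self.control_del_carrier_freq + self.control_dup_carrier_freq >= 1:
            raise ConfigError("control carrier frequencies sum to >= 1")
        p_del = case_frequency(self.control_del_carrier_freq, self.or_del)
        p_dup = case_frequency(self.control_dup_carrier_freq, self.or_dup)
        if p_del + p_dup >= 1:
            raise ConfigError("implied case carrier frequencies sum to >= 1")

    @property
    def case_del_carrier_freq(self) -> float:
        return case_frequency(self.control_del_carrier_freq, self.or_del)

    @property
    def case_dup_carrier_freq(self) -> float:
        return case_frequency(self.control_dup_carrier_freq, self.or_dup)


def simulate_cohort(config: CohortSimConfig) -> pd.DataFrame:
    """Simulate sample status and true CNV class.

    Carriers are heterozygous only (one normal allele), matching the
    classification assumption that holds at these allele frequencies.
    Returns a DataFrame with columns sample, status, true_class.
    """
    rng = np.random.default_rng(config.seed)
    frames = []
    arms = [
        ("case", config.n_cases, config.case_del_carrier_freq, config.case_dup_carrier_freq),
        ("control", config.n_controls, config.control_del_carrier_freq, config.control_dup_carrier_freq),
    ]
    for status, n, p_del, p_dup in arms:
        classes = rng.choice(
            CLASSES, size=n, p=[p_del, 1 - p_del - p_dup, p_dup]
        ) if n else np.array([], dtype=object)
        prefix = "case" if status == "case" else "ctrl"
        frames.append(
            pd.DataFrame(
                {
                    "sample": [f"{prefix}_{i + 1:06d}" for i in range(n)],
                    "status": [status] * n,
                    "true_class": classes,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def genotype_for_class(
    true_class: str,
    arch: RepeatArchitecture,
    crossover_offset: float | None = None,
) -> DiploidGenotype:
    """Heterozygous genotype for a simulated class; crossover defaults to AB1."""
    if true_class not in CLASSES:
        raise ConfigError(f"unknown CNV class {true_class!r}")
    if true_class == CLASS_NORMAL:
        return DiploidGenotype(NORMAL_ALLELE, NORMAL_ALLELE)
    offset = arch.ab1_offset if crossover_offset is None else crossover_offset
    kind = AlleleKind.DEL_B if true_class == CLASS_DELETION else AlleleKind.DUP_B
    return DiploidGenotype(NORMAL_ALLELE, StructuralAllele(kind, offset))


@dataclass(frozen=True)
class GelSimConfig:
    """P1 gel readout: per-row batch effects and per-band lognormal noise.

    Noise standard deviations are on the log2 intensity scale (the scale
    on which ratios are classified). Rows emulate the rows of a 96-well
    plate (12 samples); replicates are independent gel runs with their
    own row effects.
    """

    samples_per_row: int = 12
    rows_per_plate: int = 8
    row_effect_sd_log: float = 0.15
    band_noise_sd_log: float = 0.10
    relative_efficiency_b: float = 1.0
    n_replicates: int = 3
    base_intensity: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.row_effect_sd_log < 0 or self.band_noise_sd_log < 0:
            raise ConfigError("noise standard deviations must be >= 0")
        if self.n_replicates < 1:
            raise ConfigError("need at least one replicate")
        if self.relative_efficiency_b <= 0 or self.base_intensity <= 0:
            raise ConfigError("efficiencies and base intensity must be positive")


def simulate_gel(
    truth: pd.DataFrame,
    arch: RepeatArchitecture,
    config: GelSimConfig,
) -> pd.DataFrame:
    """Simulate P1 band intensities for every sample in a truth table.

    intensity_A = base * cA * rowEffect * eps_A and
    intensity_B = base * cB * efficiency_B * rowEffect * eps_B, with cA/cB
    the diploid P1 copy numbers of the sample's class, rowEffect shared
    by all samples on a gel row within one replicate, and eps lognormal.
    """
    rng = np.random.default_rng(config.seed)
    p1 = arch.locus("P1")
    class_counts = {
        c: copy_numbers(genotype_for_class(c, arch), p1) for c in CLASSES
    }
    n = len(truth)
    c_a = np.array([class_counts[c][0] for c in truth["true_class"]], dtype=float)
    c_b = np.array([class_counts[c][1] for c in truth["true_class"]], dtype=float)

    row_index = np.arange(n) // config.samples_per_row
    plate_index = row_index // config.rows_per_plate
    n_rows = int(row_index.max()) + 1 if n else 0

    frames = []
    for rep in range(1, config.n_replicates + 1):
        row_effect = np.exp2(
            rng.normal(0.0, config.row_effect_sd_log, size=n_rows)
        )[row_index]
        eps_a = np.exp2(rng.normal(0.0, config.band_noise_sd_log, size=n))
        eps_b = np.exp2(rng.normal(0.0, config.band_noise_sd_log, size=n))
        frames.append(
            pd.DataFrame(
                {
                    "sample": truth["sample"].to_numpy(),
                    "plate": [f"plate{p + 1:03d}" for p in plate_index],
                    "row": [f"row{r + 1:05d}" for r in row_index],
                    "replicate": rep,
                    "intensity_a": config.base_intensity * c_a * row_effect * eps_a,
                    "intensity_b": config.base_intensity
                    * c_b
                    * config.relative_efficiency_b
                    * row_effect
                    * eps_b,
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=["sample", "plate", "row", "replicate", "intensity_a", "intensity_b"]
        )
    return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class SnpSimConfig:
    """SNP array readout over the CNV region and flanks.

    LRR means per regional copy number default to literature-typical
    array behaviour (1 copy: -0.66, 2: 0.0, 3: +0.40).
    """

    n_snps_region: int = 30
    n_snps_flank: int = 16
    lrr_mean_by_copy: dict = field(
        default_factory=lambda: {1: -0.66, 2: 0.0, 3: 0.40}
    )
    lrr_sd: float = 0.15
    baf_sd: float = 0.03
    allele_freq: float = 0.5
    flank_bp: int = 50_000
    seed: int = 0

    def __post_init__(self) -> None:
        means = self.lrr_mean_by_copy
        if not (means[1] < means[2] < means[3]):
            raise ConfigError("lrr_mean_by_copy must increase with copy number")
        if self.lrr_sd < 0 or self.baf_sd < 0:
            raise ConfigError("noise standard deviations must be >= 0")
        if not 0 < self.allele_freq < 1:
            raise ConfigError("allele_freq must be in (0, 1)")


REGION_COPY_BY_CLASS = {CLASS_DELETION: 1, CLASS_NORMAL: 2, CLASS_DUPLICATION: 3}


def simulate_snps(
    truth: pd.DataFrame,
    region: GenomicInterval,
    config: SnpSimConfig,
) -> pd.DataFrame:
    """Simulate BAF/LRR records for every sample in a truth table.

    In-region SNPs follow the sample's regional copy number (1 for
    deletion heterozygotes, 2 for normals, 3 for duplication
    heterozygotes); flanking SNPs are always 2-copy. Per SNP the B-allele
    count is binomial(copy number, allele_freq), BAF is the allelic
    fraction plus clipped Gaussian noise and LRR is the copy-number mean
    plus Gaussian noise.
    """
    rng = np.random.default_rng(config.seed)
    half_flank = config.n_snps_flank // 2
    pos_region = np.linspace(
        region.start, region.end, config.n_snps_region, dtype=int
    )
    pos_left = np.linspace(
        max(1, region.start - config.flank_bp), region.start - 1, half_flank, dtype=int
    )
    pos_right = np.linspace(
        region.end + 1,
        region.end + config.flank_bp,
        config.n_snps_flank - half_flank,
        dtype=int,
    )
    positions = np.concatenate([pos_left, pos_region, pos_right])
    in_region = np.concatenate(
        [
            np.zeros(half_flank, dtype=bool),
            np.ones(config.n_snps_region, dtype=bool),
            np.zeros(config.n_snps_flank - half_flank, dtype=bool),
        ]
    )
    n_snps = len(positions)

    try:
        cn_sample = np.array(
            [REGION_COPY_BY_CLASS[c] for c in truth["true_class"]], dtype=int
        )
    except KeyError as exc:
        raise ConfigError(f"unsupported CNV class {exc.args[0]!r}") from exc

    # copy number matrix (samples x snps): regional cn inside, 2 outside
    cn = np.where(in_region[None, :], cn_sample[:, None], 2)
    b_count = rng.binomial(cn, config.allele_freq)
    baf = b_count / cn + rng.normal(0.0, config.baf_sd, size=cn.shape)
    baf = np.clip(baf, 0.0, 1.0)
    lrr_mean = np.vectorize(config.lrr_mean_by_copy.__getitem__)(cn)
    lrr = lrr_mean + rng.normal(0.0, config.lrr_sd, size=cn.shape)

    n_samples = len(truth)
    return pd.DataFrame(
        {
            "sample": np.repeat(truth["sample"].to_numpy(), n_snps),
            "chrom": region.chrom,
            "position": np.tile(positions, n_samples),
            "baf": baf.ravel(),
            "lrr": lrr.ravel(),
        }
    )


def simulate_pprt(
    allele: StructuralAllele,
    panel: list[AssayLocus],
    noise_sd: float = 0.0,
    seed: int = 0,
    sample: str = "sample",
) -> PprtProfile:
    """Noisy pPRT profile of a NORMAL/``allele`` genotype over a panel."""
    offsets = [loc.offset for loc in panel]
    if offsets != sorted(offsets):
        raise ValueError("panel must be ordered by homologous offset")
    rng = np.random.default_rng(seed)
    expected = np.array(expected_pprt_profile(allele, panel))
    values = expected + rng.normal(0.0, noise_sd, size=len(panel))
    return PprtProfile(
        sample=sample,
        panel=tuple(loc.name for loc in panel),
        values=tuple(float(v) for v in values),
    )
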