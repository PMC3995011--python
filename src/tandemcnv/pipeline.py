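"""Pipeline orchestration: config, file I/O, logging, and run steps.

TSV with a header row and '#' comment lines is the interchange format
throughout; genomic intervals travel as BED (0-based half-open on disk,
converted centrally in :mod:`tandemcnv.intervals`). Every run step
writes a JSON log with the config hash, library versions and row
counts, and identical config + seed produces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import association, breakpoint_mapping, prt_genotyping, snp_cnv_calling
from . import synthetic_data as sim
from .intervals import GenomicInterval, read_bed, bed_to_intervals, write_bed
from .repeat_model import RepeatArchitecture, default_architecture

logger = logging.getLogger(__name__)

_DATA = resources.files("tandemcnv") / "data"


def packaged_path(name: str) -> Path:
    """Path of a packaged fixture file (counts tables, BEDs, profiles)."""
    return Path(str(_DATA / name))


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a reproducible run needs; seeds derive from ``seed``."""

    seed: int = 0
    assembly: str = "GRCh37"
    outdir: Path = Path("results/pipeline")
    cohort: sim.CohortSimConfig = field(default_factory=sim.CohortSimConfig)
    gel: sim.GelSimConfig = field(default_factory=sim.GelSimConfig)
    snp_sim: sim.SnpSimConfig = field(default_factory=sim.SnpSimConfig)
    classifier: prt_genotyping.ClassifierConfig = field(
        default_factory=prt_genotyping.ClassifierConfig
    )
    snp_caller: snp_cnv_calling.SnpCallerConfig = field(
        default_factory=snp_cnv_calling.SnpCallerConfig
    )
    genes_bed: Path | None = None  # packaged default when None
    counts_table: Path | None = None  # counts-only association input
    profiles_table: Path | None = None
    junctions_table: Path | None = None

    def with_derived_seeds(self) -> "PipelineConfig":
        """Give each simulation config its own child seed of ``seed``."""
        ss = np.random.SeedSequence(self.seed)
        s_cohort, s_gel, s_snp = [
            int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(3)
        ]
        return replace(
            self,
            cohort=replace(self.cohort, seed=s_cohort),
            gel=replace(self.gel, seed=s_gel),
            snp_sim=replace(self.snp_sim, seed=s_snp),
        )


def config_from_yaml(path: str | Path) -> PipelineConfig:
    """Load a PipelineConfig from a YAML mapping of section -> fields."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs: dict = {}
    for key in ("seed", "assembly"):
        if key in raw:
            kwargs[key] = raw[key]
    for key in ("outdir", "genes_bed", "counts_table", "profiles_table",
                "junctions_table"):
        if key in raw and raw[key] is not None:
            kwargs[key] = Path(raw[key])
    sections = {
        "cohort": sim.CohortSimConfig,
        "gel": sim.GelSimConfig,
        "snp_sim": sim.SnpSimConfig,
        "classifier": prt_genotyping.ClassifierConfig,
    }
    for name, cls in sections.items():
        if name in raw:
            kwargs[name] = cls(**raw[name])
    if "snp_caller" in raw:
        section = dict(raw["snp_caller"])
        if "region" in section:
            chrom, span = section["region"].split(":")
            start, end = span.replace(",", "").split("-")
            section["region"] = GenomicInterval(chrom, int(start), int(end))
        kwargs["snp_caller"] = snp_cnv_calling.SnpCallerConfig(**section)
    return PipelineConfig(**kwargs)


def _config_hash(config: PipelineConfig) -> str:
    def default(obj):
        if isinstance(obj, (Path, GenomicInterval)):
            return str(obj)
        return str(obj)

    blob = json.dumps(asdict(config), sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write_log(config: PipelineConfig, step: str, info: dict) -> None:
    config.outdir.mkdir(parents=True, exist_ok=True)
    log = {
        "step": step,
        "config_hash": _config_hash(config),
        "tandemcnv_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        **info,
    }
    with open(config.outdir / f"run_{step}.log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)


def write_tsv(df: pd.DataFrame, path: Path, comment: str | None = None) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def load_architecture() -> RepeatArchitecture:
    return default_architecture()


def run_simulate(config: PipelineConfig) -> dict[str, Path]:
    """Simulate a cohort and write gel, SNP, phenotype and truth tables."""
    config = config.with_derived_seeds()
    arch = load_architecture()
    truth = sim.simulate_cohort(config.cohort)
    gel = sim.simulate_gel(truth, arch, config.gel)
    snps = sim.simulate_snps(truth, config.snp_caller.region, config.snp_sim)
    phenotypes = truth[["sample", "status"]].copy()
    phenotypes["stratum"] = "simulated"

    out = config.outdir
    paths = {
        "truth": out / "truth.tsv",
        "gel": out / "gel.tsv",
        "snps": out / "snps.tsv",
        "phenotypes": out / "phenotypes.tsv",
    }
    write_tsv(truth, paths["truth"], "simulated truth: sample, status, true CNV class")
    write_tsv(gel, paths["gel"], "simulated P1 gel band intensities")
    write_tsv(snps, paths["snps"], "simulated SNP BAF/LRR records")
    write_tsv(phenotypes, paths["phenotypes"], "simulated phenotypes")
    _write_log(config, "simulate", {
        "n_samples": int(len(truth)),
        "n_gel_records": int(len(gel)),
        "n_snp_records": int(len(snps)),
    })
    return paths


def run_genotype(config: PipelineConfig) -> dict[str, Path]:
    """Call CNV genotypes from whichever intensity tables are present."""
    out = config.outdir
    gel_path = out / "gel.tsv"
    snp_path = out / "snps.tsv"
    produced: dict[str, Path] = {}
    info: dict = {}
    prt_calls = snp_calls = None
    if gel_path.exists():
        gel = read_tsv(gel_path)
        ratios = prt_genotyping.normalize_and_ratio(gel)
        prt_calls = prt_genotyping.aggregate_replicates(ratios, config.classifier)
        produced["prt_calls"] = out / "calls_prt.tsv"
        write_tsv(prt_calls, produced["prt_calls"], "PRT consensus CNV calls")
        hist = prt_genotyping.ratio_histogram(prt_calls)
        produced["ratio_histogram"] = out / "ratio_histogram.tsv"
        write_tsv(hist, produced["ratio_histogram"], "log2-ratio histogram")
        info["n_prt_calls"] = int(len(prt_calls))
    if snp_path.exists():
        snps = read_tsv(snp_path)
        snp_calls = snp_cnv_calling.call_samples(snps, config.snp_caller)
        produced["snp_calls"] = out / "calls_snp.tsv"
        write_tsv(snp_calls, produced["snp_calls"], "SNP-intensity CNV calls")
        qc = snp_cnv_calling.visual_qc_table(snp_calls)
        produced["snp_qc"] = out / "snp_qc.tsv"
        write_tsv(qc, produced["snp_qc"], "per-sample (mean LRR, BAF deviation) QC table")
        info["n_snp_calls"] = int(len(snp_calls))
    if prt_calls is None and snp_calls is None:
        raise FileNotFoundError(
            f"no usable inputs: neither {gel_path} nor {snp_path} exists"
        )
    if prt_calls is not None and snp_calls is not None:
        rate, crosstab = prt_genotyping.concordance(prt_calls, snp_calls)
        produced["concordance"] = out / "concordance.tsv"
        write_tsv(
            crosstab.reset_index(),
            produced["concordance"],
            f"PRT vs SNP concordance rate = {rate:.4f}",
        )
        info["prt_snp_concordance"] = rate
    _write_log(config, "genotype", info)
    return produced


def run_breakpoints(config: PipelineConfig) -> dict[str, Path]:
    """Infer NAHR crossover intervals from a pPRT profile table."""
    profiles_path = config.profiles_table or packaged_path("pprt_profiles.tsv")
    arch = load_architecture()
    long = read_tsv(profiles_path)
    junctions = None
    if config.junctions_table is not None:
        jdf = read_tsv(config.junctions_table)
        junctions = {
            str(r.sample): breakpoint_mapping.JunctionAssayResult(
                sample=str(r.sample),
                deletion_junction_present=bool(r.del_junction),
                duplication_junction_present=bool(r.dup_junction),
            )
            for r in jdf.itertuples(index=False)
        }
    rows = []
    bed_entries = []
    for sample, grp in long.groupby("sample", sort=True):
        loci = [arch.locus(name) for name in grp["locus"]]
        order = np.argsort([loc.offset for loc in loci])
        panel = tuple(grp["locus"].to_numpy()[order])
        values = tuple(grp["log2_value"].to_numpy()[order])
        profile = breakpoint_mapping.PprtProfile(str(sample), panel, values)
        bp = breakpoint_mapping.infer_crossover(profile, arch)
        if junctions is not None and sample in junctions:
            bp = breakpoint_mapping.integrate_junction(bp, junctions[sample], arch)
        rows.append(
            {
                "sample": bp.sample,
                "variant_type": bp.variant_type,
                "left_locus": bp.left_locus or "",
                "right_locus": bp.right_locus or "",
                "interval_a": str(bp.interval_a) if bp.interval_a else "",
                "interval_b": str(bp.interval_b) if bp.interval_b else "",
                "sse": bp.sse,
                "ab1_refined": bp.ab1_refined,
                "junction_consistent": (
                    "" if bp.junction_consistent is None else bp.junction_consistent
                ),
            }
        )
        if bp.variant_type != "NONE":
            bed_entries.append((f"{bp.sample}_A", bp.interval_a))
            bed_entries.append((f"{bp.sample}_B", bp.interval_b))
    out = config.outdir
    paths = {"breakpoints": out / "breakpoints.tsv", "bed": out / "breakpoints.bed"}
    write_tsv(pd.DataFrame(rows), paths["breakpoints"], "inferred NAHR crossover intervals")
    write_bed(bed_entries, paths["bed"], assembly=config.assembly)
    _write_log(config, "breakpoints", {"n_profiles": int(long["sample"].nunique())})
    return paths


def run_associate(config: PipelineConfig) -> dict[str, Path]:
    """Per-stratum and Mantel-Haenszel association; counts-only mode.

    When ``config.counts_table`` is set, the 2x2 counts are read directly
    (stratum, a, b, c, d); otherwise calls and phenotypes from the run
    directory are tabulated per stratum first.
    """
    out = config.outdir
    if config.counts_table is not None:
        counts = read_tsv(config.counts_table)
        tables = association.tables_from_counts(counts)
    else:
        calls_path = out / "calls_prt.tsv"
        if not calls_path.exists():
            calls_path = out / "calls_snp.tsv"
        calls = read_tsv(calls_path)
        phenotypes = read_tsv(out / "phenotypes.tsv")
        tables = []
        for stratum in sorted(phenotypes["stratum"].unique()):
            table = association.build_table(calls, phenotypes, stratum)
            if table.a + table.c == 0 and table.b + table.d == 0:
                logger.warning("stratum %s empty; skipped", stratum)
                continue
            tables.append(table)
    strata = [association.odds_ratio(t) for t in tables]
    meta = association.meta_analysis(tables)
    stratum_df = pd.DataFrame(
        {
            "stratum": [s.label for s in strata],
            "a": [s.table.a for s in strata],
            "b": [s.table.b for s in strata],
            "c": [s.table.c for s in strata],
            "d": [s.table.d for s in strata],
            "odds_ratio": [s.or_estimate for s in strata],
            "ci95_low": [s.ci95[0] for s in strata],
            "ci95_high": [s.ci95[1] for s in strata],
            "chi2": [s.chi2 for s in strata],
            "p": [s.p for s in strata],
        }
    )
    meta_df = pd.DataFrame(
        [
            {
                "or_mh": meta.or_mh,
                "ci95_low": meta.ci95_rbg[0],
                "ci95_high": meta.ci95_rbg[1],
                "chi2_mh": meta.chi2_mh,
                "p_mh": meta.p_mh,
                "woolf_q": meta.woolf_q,
                "woolf_df": meta.woolf_df,
                "woolf_p": meta.woolf_p,
            }
        ]
    )
    forest = association.forest_table(strata, meta)
    paths = {
        "stratum": out / "association_strata.tsv",
        "meta": out / "association_meta.tsv",
        "forest": out / "forest.tsv",
    }
    write_tsv(stratum_df, paths["stratum"], "per-stratum deletion-carrier association")
    write_tsv(meta_df, paths["meta"], "Mantel-Haenszel meta-analysis")
    write_tsv(forest, paths["forest"], "forest-plot table")
    _write_log(config, "associate", {"n_strata": len(tables)})
    return paths


def run_all(config: PipelineConfig) -> dict[str, Path]:
    """simulate -> genotype -> associate on one config."""
    paths = run_simulate(config)
    paths |= run_genotype(config)
    paths |= run_associate(config)
    return paths
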