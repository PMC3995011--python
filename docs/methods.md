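# Methods

## The locus and its structural model

chr12p13.31 carries a tandem pair of diverged repeat units, "A" (~100 kb,
containing NANOG and most of SLC2A14) and "B" (~145 kb, containing NANOGP1
and SLC2A3). Nonallelic homologous recombination (NAHR) between misaligned
units produces reciprocal products: a deletion chromosome with one hybrid
unit (A-form sequence upstream of the crossover fused to B-form sequence
downstream) and an expansion chromosome with three units (full A, hybrid,
full B). The predominant European crossover falls in AB1, a ~1.1 kb
homologous stretch (GRCh37 chr12:7,995,630-7,996,700 in unit A /
8,124,315-8,125,390 in unit B); midpoint-to-midpoint the deleted segment is
128.7 kb, i.e. 129 kb to the nearest kilobase, removing SLC2A3 and NANOGP1
entirely and truncating SLC2A14.

`repeat_model` encodes this as a `RepeatArchitecture` (unit intervals, an
ordered assay panel, the AB1 intervals) and `StructuralAllele`s
(normal / deletion / expansion, each non-normal allele carrying a crossover
offset). Each assay locus has paired genomic targets in both units plus a
single scalar *homologous offset*: the distance of its A-unit target start
from the unit-A start. Crossovers live on the same scale, so the whole
inference machinery depends only on the *ordering* of offsets, never on
absolute inter-unit distances — the two units differ in length, and any
monotone common coordinate gives identical results.

Per-locus copy contributions follow from the hybrid-unit construction
(normal (1A,1B); deletion (1,0) upstream of the crossover, (0,1)
downstream; expansion (1,2) upstream, (2,1) downstream). With the standing
assumption that carriers keep one normal chromosome — reasonable at carrier
frequencies of 1-4%, where homozygous variants are expected in well under
one sample per thousand — the attainable B/A expected ratios are exactly
{1/2, 2/3, 1, 3/2, 2}. Genotypes violating the assumption are representable
(the simulator may emit them) and are flagged rather than rejected.

Unit boundaries and the pPRT target coordinates (B5, B6, B8, B9, B10) are
not public; the packaged architecture reconstructs them to satisfy the
known constraints: panel order B5 < B6 < B8 < P1 < B9 < B10, a B5-B6 gap of
8.8 kb in unit A and 6.1 kb in unit B, and AB1 between B9 and B10. The P1
product and AB1 coordinates are the published ones. The packaged gene BED
is likewise an approximate, synthetic placement preserving the qualitative
layout; `rearrangement_span` + `gene_consequences` therefore report exact
arithmetic on approximate inputs, with the crossover-interval half-widths
carried as explicit uncertainty.

## PRT genotyping

The P1 assay co-amplifies one target per unit; the B/A product-intensity
ratio estimates relative unit copy number. Raw per-replicate ratios are
normalized per gel row by the reciprocal of the row median (median over an
even count = mean of the central order statistics), then log2-transformed.
Any effect multiplicative within a row — loading, staining, imaging —
cancels exactly; this invariance is property-tested.

Calls use fixed boundaries: deletion below −0.75, duplication above +0.45,
normal otherwise. Both inequalities are strict, so a value exactly at a
boundary is called normal (the conservative reading of "< −0.75 … > 0.45").
Replicates are classified individually and vote; any disagreement sets a
`discordant` flag, and a tie resolves to normal — a pipeline cannot
re-assay, and a no-call would silently change association denominators.
The consensus log2 ratio is the replicate median.

## SNP-intensity calling

Rather than a genome-wide HMM caller, the regional copy number is called
from the two features that cleanly separate the clusters over a ~129 kb,
multi-SNP region: mean LRR over in-region SNPs, and the BAF deviation
(mean |BAF − 0.5|) of apparently-heterozygous SNPs, operationalized as
those with BAF in [0.25, 0.75]. One-copy carriers have no true
heterozygotes, so deletions are caught by depressed LRR (≤ −0.30) plus an
informative-SNP fraction ≤ 0.02; three-copy carriers show elevated LRR
(≥ +0.15) plus BAF deviation ≥ 0.08 (true hets sit at 1/3 and 2/3,
deviation 1/6). Deletion is tested first, making the two variant calls
mutually exclusive by construction. All thresholds are configurable; the
defaults were chosen once from the noiseless cluster geometry (−0.66 / 0 /
+0.40 LRR means, deviation 0 vs 1/6) with margins of several standard
errors of a 30-SNP mean.

## Breakpoint mapping

A variant haplotype turns the pPRT panel profile into a single-step
function: −1 → +1 for deletions, +log2(3/2) → −log2(3/2) for expansions.
`infer_crossover` fits all 2(L−1)+1 single-changepoint hypotheses (plus
flat-zero) by sum of squared residuals, with the expected levels fixed by
the structural model rather than estimated — a model-based classification
that is robust at L = 6. A generic changepoint method is deliberately not
used: the biology admits exactly one crossover per ancestral event, the
hypothesis space is tiny, and the exhaustive fit is its own oracle. Ties
resolve deterministically: flat first, then the changepoint nearest the
panel centre, then deletion before expansion. Noiseless step profiles are
identifiable (unique zero-residual hypothesis; the DEL and DUP level sets
are disjoint), and at Gaussian noise sd 0.1 the correct interval is
recovered in >99% of simulations, because adjacent hypotheses differ by at
least 2·log2(3/2) ≈ 1.17 at one locus.

A junction-spanning PCR result (AF+UR for the deletion junction, BF+UR for
the duplication junction) that matches the called type refines the interval
to the AB1 coordinates; a mismatch keeps the pPRT interval and flags the
inconsistency. `breakpoint_census` reports the AB1-consistent fraction of
variant samples.

## Association

Carrier status is deletion-only (duplications count as non-carriers).
Per-stratum: crude OR ad/bc, Woolf log-scale SE √(1/a+1/b+1/c+1/d) and its
95% CI, and the uncorrected Pearson chi-square (1 df). Pooling:
Mantel-Haenszel OR Σ(aᵢdᵢ/nᵢ)/Σ(bᵢcᵢ/nᵢ), Robins-Breslow-Greenland
variance for the pooled CI, the uncorrected Mantel-Haenszel chi-square with
hypergeometric moments, and Woolf's inverse-variance heterogeneity test to
justify pooling. No continuity correction is applied anywhere; the
corrected variants do not reproduce the reference P values (0.0012, 0.036,
0.000194) and the uncorrected forms do, exactly. The single-stratum MH
statistic relates to Pearson's by the exact factor (n−1)/n, which is
asserted in the tests, and the whole stratified path is cross-checked
against `statsmodels.stats.contingency_tables.StratifiedTable` as an
independent oracle.

One count-table subtlety: the Swedish case categories as printed sum to one
more than the stated case total (2,404 vs 2,403). Case non-carriers are
therefore derived from the stated total (b = 2,403 − 28 = 2,375), which is
the only reading that reproduces the printed OR and P value.

## Synthetic cohorts

The generator's defaults are the Swedish study conditions: 2,403 cases /
1,269 controls, control deletion-carrier frequency 33/1,269, duplication
55/1,269, deletion OR 0.442 (duplication OR 0.889, the near-null value the
counts imply). Case frequencies derive from the odds transform
p_case = OR·odds_control/(1 + OR·odds_control) per variant class; carriers
are heterozygous-only, consistent with the one-normal-allele assumption.

Gel intensities are base · copy-number · rowEffect · ε per band, with
rowEffect shared by the 12 samples of a row within a replicate and both
noises lognormal on the log2 scale (row sd 0.15, band sd 0.10); replicates
(default 3) are independent gel runs. No published noise magnitudes exist
for this assay; the band sd was fixed at 0.1 so that the class clusters
separate cleanly while remaining visibly noisy, and the row sd was made
larger than the band sd specifically so the row-normalization step has real
work to do. The simulator is deliberately idealized in one important way:
class means sit at the exact model ratios (−1, 0, +0.585), whereas real
deletion clusters sit lower (observed means around −1.2 in cases and −1.1
in controls) and broader, presumably from amplification-efficiency
differences between one- and two-copy templates. Consequences: (i) passing accuracy/concordance tests
bound performance under the idealized noise model, not under real gel
chemistry; (ii) a deletion-threshold sweep on simulated data loses its
carriers below about −1.1 — with the cluster at −1 and consensus sd ~0.1,
P(consensus < −1.3) < 0.5% — so significance across the full extreme range
[−1.3, −0.5] holds on real data but *cannot* hold under this generator,
and the corresponding acceptance test fails by design rather than by a
hidden relaxation. PCR saturation, allele dropout and SNP-SNP LD are
likewise not modelled.

SNP tracks use LRR means {1: −0.66, 2: 0.0, 3: +0.40} (literature-typical
array behaviour; configurable), LRR sd 0.15, BAF sd 0.03, 30 SNPs in the
region and 8 per flank, allele frequency 0.5 per SNP. B-allele counts are
binomial in the regional copy number; flanks are always two-copy.

All randomness flows from per-config seeds (the pipeline derives child
seeds from one master seed via `numpy.random.SeedSequence`), and a fixed
seed yields byte-identical output tables.

## Problem sizes

Simulation-based checks use: 10,000 samples for caller accuracy and
cross-platform concordance; 1,000 replicates for noisy breakpoint
recovery; 500 three-strata cohorts at the full study sizes for pooled-CI
coverage; the Swedish-scale cohort (3,672 samples) for the threshold
sweep. These sizes put Monte-Carlo standard errors well inside the asserted
margins (e.g. ±0.07% on a 99.4% concordance) while keeping any single run
in seconds.

## Limitations

* Unit boundaries, pPRT targets and gene placements are reconstructions;
  interval *widths* and span arithmetic are exact only relative to those
  placements.
* The SNP caller is a two-feature threshold classifier intended for this
  one region with known cluster geometry; it is not a general CNV caller.
* Only single-crossover (one net unit) alleles are modelled — no
  multi-unit gains/losses, no gene-conversion-like double crossovers.
* Association is single-locus by design: no covariates, no logistic
  regression, no antibody-status stratification.
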