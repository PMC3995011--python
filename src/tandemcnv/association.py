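"""Case-control association of deletion-carrier status.

Per stratum, carriers (deletion calls) versus non-carriers are tabulated
2x2 against case/control status and summarized by the odds ratio with a
Woolf (log-scale) confidence interval and a Pearson chi-square test.
Strata are pooled by Mantel-Haenszel:

    OR_MH = sum_i(a_i d_i / n_i) / sum_i(b_i c_i / n_i)

with its confidence interval from the Robins-Breslow-Greenland (RBG)
variance of log OR_MH, the Mantel-Haenszel chi-square test without
continuity correction, and Woolf's heterogeneity test to justify
pooling. No continuity corrections are applied anywhere: the printed
headline statistics of the study design this reproduces require the
uncorrected forms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


class UndefinedStatisticError(ValueError):
    """A statistic is undefined for the given table (zero margin or cells)."""


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Carrier-by-status counts for one stratum.

    a = case carriers, b = case non-carriers, c = control carriers,
    d = control non-carriers.
    """

    a: int
    b: int
    c: int
    d: int
    label: str = ""

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def swapped_status(self) -> "ContingencyTable2x2":
        """Swap the case and control rows."""
        return ContingencyTable2x2(self.c, self.d, self.a, self.b, self.label)


@dataclass(frozen=True)
class StratumAssociation:
    label: str
    table: ContingencyTable2x2
    or_estimate: float
    log_or_se_woolf: float
    ci95: tuple[float, float]
    chi2: float
    p: float


@dataclass(frozen=True)
class MetaAssociation:
    or_mh: float
    ci95_rbg: tuple[float, float]
    chi2_mh: float
    p_mh: float
    woolf_q: float | None = None
    woolf_df: int | None = None
    woolf_p: float | None = None


def build_table(
    calls: pd.DataFrame,
    phenotypes: pd.DataFrame,
    stratum: str | None = None,
    carrier_category: str = "deletion",
) -> ContingencyTable2x2:
    """Deletion-carrier 2x2 table for one stratum.

    Carrier status is deletion-only: duplication and normal calls both
    count as non-carriers, matching the replication analyses which
    considered only the putative aetiological deletion. ``phenotypes``
    needs sample + status (+ stratum when ``stratum`` is given); every
    phenotyped sample lacking a call is dropped with a log-free merge
    (callers log upstream).
    """
    pheno = phenotypes
    if stratum is not None:
        pheno = phenotypes[phenotypes["stratum"] == stratum]
    bad = set(pheno["status"]) - {"case", "control"}
    if bad:
        raise ValueError(f"unknown phenotype status values: {sorted(bad)}")
    merged = pheno.merge(calls[["sample", "category"]], on="sample", how="inner")
    carrier = merged["category"] == carrier_category
    case = merged["status"] == "case"
    return ContingencyTable2x2(
        a=int((case & carrier).sum()),
        b=int((case & ~carrier).sum()),
        c=int((~case & carrier).sum()),
        d=int((~case & ~carrier).sum()),
        label=stratum or "all",
    )


def odds_ratio(t: ContingencyTable2x2) -> StratumAssociation:
    """Crude OR with Woolf CI and uncorrected Pearson chi-square test."""
    if t.b == 0 or t.c == 0 or t.d == 0:
        raise UndefinedStatisticError(
            f"stratum {t.label!r}: odds ratio undefined with b/c/d zero"
        )
    or_est = (t.a * t.d) / (t.b * t.c)
    if t.a == 0:
        se = math.inf
        ci = (0.0, math.inf)
    else:
        se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
        ci = (
            math.exp(math.log(or_est) - Z_95 * se),
            math.exp(math.log(or_est) + Z_95 * se),
        )
    chi2, p = pearson_chi2(t)
    return StratumAssociation(
        label=t.label,
        table=t,
        or_estimate=or_est,
        log_or_se_woolf=se,
        ci95=ci,
        chi2=chi2,
        p=p,
    )


def pearson_chi2(t: ContingencyTable2x2) -> tuple[float, float]:
    """Two-sided Pearson chi-square on a 2x2 table, 1 df, no correction."""
    a, b, c, d = t.a, t.b, t.c, t.d
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if t.n == 0 or any(m == 0 for m in margins):
        raise UndefinedStatisticError(
            f"stratum {t.label!r}: chi-square undefined with a zero margin"
        )
    chi2 = t.n * (a * d - b * c) ** 2 / math.prod(margins)
    return chi2, float(stats.chi2.sf(chi2, df=1))


def mantel_haenszel(tables: Sequence[ContingencyTable2x2]) -> MetaAssociation:
    """Mantel-Haenszel pooled OR, RBG 95% CI, and uncorrected MH test.

    A single stratum returns its crude OR exactly, with the MH test
    differing from Pearson only by the n/(n-1) variance factor.
    """
    if not tables:
        raise ValueError("need at least one stratum")
    R = sum(t.a * t.d / t.n for t in tables)
    S = sum(t.b * t.c / t.n for t in tables)
    if S == 0:
        raise UndefinedStatisticError("sum of b*c/n is zero; MH OR undefined")
    or_mh = R / S

    # Robins-Breslow-Greenland variance of log OR_MH
    sum_pr = sum((t.a + t.d) / t.n * (t.a * t.d / t.n) for t in tables)
    sum_ps_qr = sum(
        (t.a + t.d) / t.n * (t.b * t.c / t.n)
        + (t.b + t.c) / t.n * (t.a * t.d / t.n)
        for t in tables
    )
    sum_qs = sum((t.b + t.c) / t.n * (t.b * t.c / t.n) for t in tables)
    var_log = sum_pr / (2 * R**2) + sum_ps_qr / (2 * R * S) + sum_qs / (2 * S**2)
    se = math.sqrt(var_log)
    ci = (
        math.exp(math.log(or_mh) - Z_95 * se),
        math.exp(math.log(or_mh) + Z_95 * se),
    )

    # MH test: (sum a - sum E[a])^2 / sum Var(a), hypergeometric moments
    e_sum = sum((t.a + t.b) * (t.a + t.c) / t.n for t in tables)
    v_sum = sum(
        (t.a + t.b) * (t.c + t.d) * (t.a + t.c) * (t.b + t.d) / (t.n**2 * (t.n - 1))
        for t in tables
    )
    a_sum = sum(t.a for t in tables)
    chi2_mh = (a_sum - e_sum) ** 2 / v_sum
    p_mh = float(stats.chi2.sf(chi2_mh, df=1))
    return MetaAssociation(or_mh=or_mh, ci95_rbg=ci, chi2_mh=chi2_mh, p_mh=p_mh)


def woolf_heterogeneity(
    tables: Sequence[ContingencyTable2x2],
) -> tuple[float, int, float]:
    """Woolf's test of homogeneity of stratum odds ratios.

    Strata with a zero cell have no Woolf variance and are excluded
    (noted by the reduced df). Returns (Q, df, p).
    """
    usable = [t for t in tables if min(t.a, t.b, t.c, t.d) > 0]
    if len(usable) < 2:
        raise UndefinedStatisticError(
            "Woolf heterogeneity needs >= 2 strata with all cells positive"
        )
    log_ors = np.array([math.log(t.a * t.d / (t.b * t.c)) for t in usable])
    weights = np.array(
        [1 / (1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d) for t in usable]
    )
    pooled = float(np.sum(weights * log_ors) / np.sum(weights))
    q = float(np.sum(weights * (log_ors - pooled) ** 2))
    df = len(usable) - 1
    return q, df, float(stats.chi2.sf(q, df=df))


def meta_analysis(tables: Sequence[ContingencyTable2x2]) -> MetaAssociation:
    """Mantel-Haenszel pooling plus Woolf heterogeneity when computable."""
    meta = mantel_haenszel(tables)
    try:
        q, df, p = woolf_heterogeneity(tables)
    except UndefinedStatisticError:
        return meta
    return MetaAssociation(
        or_mh=meta.or_mh,
        ci95_rbg=meta.ci95_rbg,
        chi2_mh=meta.chi2_mh,
        p_mh=meta.p_mh,
        woolf_q=q,
        woolf_df=df,
        woolf_p=p,
    )


def forest_table(
    strata: Sequence[StratumAssociation], meta: MetaAssociation
) -> pd.DataFrame:
    """Forest-plot data: one row per stratum plus the pooled summary.

    weight_share is each stratum's share of the MH weight
    (a_i d_i + b_i c_i)/n_i.
    """
    if not strata:
        raise ValueError("forest table needs at least one stratum")
    weights = [(s.table.a * s.table.d + s.table.b * s.table.c) / s.table.n
               for s in strata]
    total = sum(weights)
    rows = [
        {
            "label": s.label,
            "or": s.or_estimate,
            "ci_low": s.ci95[0],
            "ci_high": s.ci95[1],
            "weight_share": w / total,
        }
        for s, w in zip(strata, weights)
    ]
    rows.append(
        {
            "label": "MH summary",
            "or": meta.or_mh,
            "ci_low": meta.ci95_rbg[0],
            "ci_high": meta.ci95_rbg[1],
            "weight_share": 1.0,
        }
    )
    return pd.DataFrame(rows)


def tables_from_counts(counts: pd.DataFrame) -> list[ContingencyTable2x2]:
    """Build stratum tables from a counts DataFrame (stratum, a, b, c, d)."""
    return [
        ContingencyTable2x2(int(r.a), int(r.b), int(r.c), int(r.d), str(r.stratum))
        for r in counts.itertuples(index=False)
    ]
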