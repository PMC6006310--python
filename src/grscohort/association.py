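"""Per-SNP allelic case-control association with Bonferroni correction.

Each analysed SNP is tested on its 2×2 allele-count table (risk vs non-risk
allele, cases vs controls), the convention of PLINK's basic allelic test:
odds ratio from the cross product, 95% CI by Woolf's log method with the
Haldane–Anscombe 0.5 correction when a cell is empty, and a 1-df Pearson
chi-square P value. Sub-phenotype analyses (non-permanent and permanent AF)
reuse the full control group. Multiple testing is handled by Bonferroni:
the P value multiplied by the number of analysed SNPs, capped at 1.

Missing genotypes are dropped per SNP (pairwise deletion), so the genotyped
N may differ between SNPs — distinct from the complete-case rule used for
the genetic risk score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from grscohort.cohort_io import (
    GROUP_AF,
    GROUP_NP_AF,
    GROUP_P_AF,
    GenotypeMatrix,
    PhenotypeTable,
    SNPPanel,
)

__all__ = [
    "AlleleTable2x2",
    "OddsRatioCI",
    "ChiSquareResult",
    "AssociationResult",
    "allele_table",
    "allelic_or",
    "allelic_chi2_p",
    "bonferroni",
    "run_association",
    "association_frame",
]

Z_95 = 1.96  # conventional 95% normal quantile, as printed in the tables


@dataclass(frozen=True)
class AlleleTable2x2:
    """Allele-count table: (a, b) risk/non-risk in cases, (c, d) in controls."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("allele counts must be non-negative")

    @property
    def n_case(self) -> int:
        return (self.a + self.b) // 2

    @property
    def n_control(self) -> int:
        return (self.c + self.d) // 2

    @property
    def raf_case(self) -> float:
        return self.a / (self.a + self.b)

    @property
    def raf_control(self) -> float:
        return self.c / (self.c + self.d)


@dataclass(frozen=True)
class OddsRatioCI:
    value: float
    ci_low: float
    ci_high: float
    haldane_corrected: bool = False
    undefined: bool = False


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    pvalue: float
    method: str = "chi2"
    degenerate: bool = False


@dataclass
class AssociationResult:
    rsid: str
    group: str
    n_case: int
    n_control: int
    raf_case: float
    raf_control: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_uncorr: float
    p_corr: float
    m: int
    flags: list[str] = field(default_factory=list)

    @property
    def p_corr_nominal(self) -> Optional[float]:
        """Corrected P, reported only for nominal (P < 0.05) associations —
        the convention used in the sub-phenotype table."""
        return self.p_corr if self.p_uncorr < 0.05 else None


def allele_table(
    matrix: GenotypeMatrix,
    phenotypes: PhenotypeTable,
    rsid: str,
    case_group: str = GROUP_AF,
) -> AlleleTable2x2:
    """Build the 2×2 allele table at ``rsid`` for a case group vs controls.

    ``case_group`` selects all AF cases or a subtype (NP-AF / P-AF); the
    control column is always the full non-AF group. Samples missing the
    genotype at this SNP are dropped for this SNP only.
    """
    col = matrix.column(rsid)

    def counts(ids: Sequence[str]) -> tuple[int, int]:
        vals = col.loc[list(ids)].dropna()
        risk = int(vals.sum())
        return risk, 2 * len(vals) - risk

    a, b = counts(phenotypes.group_ids(case_group))
    c, d = counts(phenotypes.group_ids("NAF"))
    if a + b == 0 or c + d == 0:
        raise ValueError(f"{rsid}: no genotyped samples in one group")
    return AlleleTable2x2(a, b, c, d)


def allelic_or(table: AlleleTable2x2, z: float = Z_95) -> OddsRatioCI:
    """Allelic odds ratio with Woolf's 95% confidence interval.

    OR = (a·d)/(b·c). The CI is exp(ln OR ± z·sqrt(1/a + 1/b + 1/c + 1/d)).
    If any cell is zero, 0.5 is added to every cell first (Haldane–Anscombe)
    and the result is flagged; if both cells of a diagonal are zero the OR
    is undefined.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if (a == 0 and d == 0) or (b == 0 and c == 0):
        return OddsRatioCI(math.nan, math.nan, math.nan, undefined=True)
    corrected = 0 in (a, b, c, d)
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return OddsRatioCI(
        value=or_,
        ci_low=math.exp(math.log(or_) - z * se),
        ci_high=math.exp(math.log(or_) + z * se),
        haldane_corrected=corrected,
    )


def allelic_chi2_p(table: AlleleTable2x2, *, use_fisher_if_sparse: bool = False) -> ChiSquareResult:
    """Two-sided allele-frequency test on the 2×2 table.

    1-df Pearson chi-square without continuity correction; optionally falls
    back to Fisher's exact test when any expected cell is below 5. A table
    with a degenerate margin returns P = 1 with a flag.
    """
    obs = np.array([[table.a, table.b], [table.c, table.d]], dtype=float)
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        return ChiSquareResult(0.0, 1.0, degenerate=True)
    expected = stats.contingency.expected_freq(obs)
    if use_fisher_if_sparse and (expected < 5).any():
        _, p = stats.fisher_exact(obs.astype(int))
        return ChiSquareResult(math.nan, float(p), method="fisher")
    stat, p, _, _ = stats.chi2_contingency(obs, correction=False)
    return ChiSquareResult(float(stat), float(p))


def bonferroni(p_uncorr: float, m: int) -> float:
    """Bonferroni correction: P multiplied by the number of analysed SNPs,
    capped at 1."""
    if not 0 <= p_uncorr <= 1:
        raise ValueError(f"p must be in [0, 1], got {p_uncorr}")
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    return min(1.0, m * p_uncorr)


def run_association(
    matrix: GenotypeMatrix,
    phenotypes: PhenotypeTable,
    panel: SNPPanel,
    analysed: Optional[Sequence[str]] = None,
    groups: Sequence[str] = (GROUP_AF, GROUP_NP_AF, GROUP_P_AF),
    *,
    use_fisher_if_sparse: bool = False,
) -> list[AssociationResult]:
    """Allelic association for every analysed SNP in every case group.

    ``analysed`` defaults to every panel SNP present in the matrix; its size
    is the Bonferroni denominator m applied to all groups. Monomorphic or
    otherwise degenerate SNPs yield flagged results rather than errors.
    """
    if analysed is None:
        analysed = [r for r in panel.rsids if r in matrix.dosage.columns]
    analysed = list(analysed)
    m = len(analysed)
    if m == 0:
        raise ValueError("no analysed SNPs")
    results = []
    for group in groups:
        for rsid in analysed:
            t = allele_table(matrix, phenotypes, rsid, case_group=group)
            orci = allelic_or(t)
            chi = allelic_chi2_p(t, use_fisher_if_sparse=use_fisher_if_sparse)
            flags = []
            if orci.haldane_corrected:
                flags.append("haldane_corrected")
            if orci.undefined:
                flags.append("or_undefined")
            if chi.degenerate:
                flags.append("degenerate_margins")
            if chi.method == "fisher":
                flags.append("fisher_exact")
            results.append(
                AssociationResult(
                    rsid=rsid,
                    group=group,
                    n_case=t.n_case,
                    n_control=t.n_control,
                    raf_case=t.raf_case,
                    raf_control=t.raf_control,
                    odds_ratio=orci.value,
                    ci_low=orci.ci_low,
                    ci_high=orci.ci_high,
                    p_uncorr=chi.pvalue,
                    p_corr=bonferroni(chi.pvalue, m),
                    m=m,
                    flags=flags,
                )
            )
    return results


def association_frame(results: Iterable[AssociationResult]) -> pd.DataFrame:
    """Flatten association results into a report table.

    ``p_corr`` is always present; ``p_corr_nominal`` is filled only where
    the uncorrected P is below 0.05, mirroring the printed table convention.
    """
    rows = []
    for r in results:
        rows.append(
            {
                "rsid": r.rsid,
                "group": r.group,
                "n_case": r.n_case,
                "n_control": r.n_control,
                "raf_case": round(r.raf_case, 2),
                "raf_control": round(r.raf_control, 2),
                "or": round(r.odds_ratio, 2) if math.isfinite(r.odds_ratio) else math.nan,
                "ci_low": round(r.ci_low, 2) if math.isfinite(r.ci_low) else math.nan,
                "ci_high": round(r.ci_high, 2) if math.isfinite(r.ci_high) else math.nan,
                "p_uncorr": float(f"{r.p_uncorr:.3g}"),
                "p_corr": float(f"{r.p_corr:.3g}"),
                "p_corr_nominal": (
                    float(f"{r.p_corr_nominal:.3g}") if r.p_corr_nominal is not None else math.nan
                ),
                "m": r.m,
                "flags": ";".join(r.flags),
            }
        )
    return pd.DataFrame(rows)
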