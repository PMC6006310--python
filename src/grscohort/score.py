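"""Weighted multilocus genetic risk score (GRS) and group comparisons.

The GRS of a sample is the sum over analysed SNPs of its risk-allele dosage
times the natural log of the SNP's published odds ratio. Weights come from
the panel's literature ORs and are never re-estimated from the cohort.
Missing genotypes are handled by complete-case exclusion: a sample missing
any analysed genotype receives no score (an optional renormalised variant
rescales over the observed SNPs instead).

Group comparisons use the two-sample pooled-variance Student t test; a
Welch variant is available for robustness checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from grscohort.cohort_io import (
    GROUP_AF,
    GROUP_NAF,
    GROUP_NP_AF,
    GROUP_P_AF,
    GenotypeMatrix,
    PhenotypeTable,
    SNPPanel,
)

__all__ = ["GRSResult", "GroupComparison", "compute_grs", "compare_grs", "compare_all"]


@dataclass
class GRSResult:
    """Per-sample weighted scores plus the complete-case exclusion set."""

    scores: pd.Series  # indexed by included sample ids
    excluded_ids: list[str]
    weights_used: dict[str, float]

    @property
    def included_ids(self) -> list[str]:
        return list(self.scores.index)


@dataclass(frozen=True)
class GroupComparison:
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    t_statistic: float
    df: float
    p_value: float
    flag: str = ""


def compute_grs(
    matrix: GenotypeMatrix,
    panel: SNPPanel,
    analysed_snps: Sequence[str],
    *,
    renormalise_missing: bool = False,
) -> GRSResult:
    """Compute GRS = Σ dosage_i × ln(OR_i) over the analysed SNPs.

    By default samples missing any analysed genotype are excluded
    (complete-case); with ``renormalise_missing`` a sample's score is
    instead computed over its observed SNPs and rescaled by the ratio of
    total to observed absolute weight.
    """
    analysed_snps = list(analysed_snps)
    if not analysed_snps:
        raise ValueError("analysed SNP set is empty")
    for rsid in analysed_snps:
        panel.get(rsid)  # raises if not a panel SNP
        if rsid not in matrix.dosage.columns:
            raise KeyError(f"rsid {rsid} not in genotype matrix")
    weights = {rsid: panel.get(rsid).weight for rsid in analysed_snps}
    w = pd.Series(weights)
    sub = matrix.dosage[analysed_snps]
    complete = sub.notna().all(axis=1)
    if renormalise_missing:
        total_abs = float(np.abs(w).sum())
        scores = []
        index = []
        excluded = []
        for sample_id, row in sub.iterrows():
            obs = row.dropna()
            if obs.empty:
                excluded.append(sample_id)
                continue
            obs_abs = float(np.abs(w[obs.index]).sum())
            scale = total_abs / obs_abs if obs_abs > 0 else 1.0
            scores.append(float(obs @ w[obs.index]) * scale)
            index.append(sample_id)
        return GRSResult(pd.Series(scores, index=index, dtype=float), excluded, weights)
    scores = sub.loc[complete] @ w
    excluded = list(sub.index[~complete])
    return GRSResult(scores.astype(float), excluded, weights)


def _pooled_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float, str]:
    n1, n2 = len(a), len(b)
    df = n1 + n2 - 2
    v1 = a.var(ddof=1) if n1 > 1 else 0.0
    v2 = b.var(ddof=1) if n2 > 1 else 0.0
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    diff = a.mean() - b.mean()
    if sp2 == 0:
        if diff == 0:
            return 0.0, df, 1.0, "zero_variance_equal_means"
        return math.copysign(math.inf, diff), df, 0.0, "zero_variance_unequal_means"
    t = diff / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = 2 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p), ""


def compare_grs(
    result: GRSResult,
    phenotypes: PhenotypeTable,
    group_a: str,
    group_b: str = GROUP_NAF,
    *,
    welch: bool = False,
) -> GroupComparison:
    """Two-sample Student t test of GRS between two phenotype groups.

    Only samples with a score (complete-case included set) enter. Pooled
    variance with df = n1 + n2 − 2 by default; Welch's unequal-variance
    test via ``welch=True``.
    """
    included = set(result.included_ids)
    a_ids = [s for s in phenotypes.group_ids(group_a) if s in included]
    b_ids = [s for s in phenotypes.group_ids(group_b) if s in included]
    if len(a_ids) < 2 or len(b_ids) < 2:
        raise ValueError("each group needs at least two scored samples")
    a = result.scores.loc[a_ids].to_numpy()
    b = result.scores.loc[b_ids].to_numpy()
    if welch:
        res = stats.ttest_ind(a, b, equal_var=False)
        t, df, p, flag = float(res.statistic), float(res.df), float(res.pvalue), "welch"
    else:
        t, df, p, flag = _pooled_t(a, b)
    return GroupComparison(
        group_a=group_a,
        group_b=group_b,
        n_a=len(a),
        n_b=len(b),
        mean_a=float(a.mean()),
        sd_a=float(a.std(ddof=1)),
        mean_b=float(b.mean()),
        sd_b=float(b.std(ddof=1)),
        t_statistic=t,
        df=df,
        p_value=p,
        flag=flag,
    )


def compare_all(
    result: GRSResult, phenotypes: PhenotypeTable, *, welch: bool = False
) -> list[GroupComparison]:
    """The standard comparison set: AF, NP-AF and P-AF each versus controls."""
    return [
        compare_grs(result, phenotypes, g, GROUP_NAF, welch=welch)
        for g in (GROUP_AF, GROUP_NP_AF, GROUP_P_AF)
    ]


def comparison_frame(comparisons: Sequence[GroupComparison]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "group": [c.group_a for c in comparisons],
            "versus": [c.group_b for c in comparisons],
            "n": [c.n_a for c in comparisons],
            "n_control": [c.n_b for c in comparisons],
            "grs_mean": [round(c.mean_a, 3) for c in comparisons],
            "grs_sd": [round(c.sd_a, 3) for c in comparisons],
            "control_mean": [round(c.mean_b, 3) for c in comparisons],
            "control_sd": [round(c.sd_b, 3) for c in comparisons],
            "t": [round(c.t_statistic, 3) for c in comparisons],
            "df": [c.df for c in comparisons],
            "p": [float(f"{c.p_value:.3g}") for c in comparisons],
        }
    )
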