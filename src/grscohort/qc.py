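"""Per-SNP quality control: call rate and exact Hardy-Weinberg test.

A SNP is excluded from analysis when its genotyping call rate falls below
80% (strictly below — a SNP at exactly 0.80 is retained) or when the exact
Hardy-Weinberg equilibrium (HWE) test rejects at alpha = 0.05. The HWE test
is by default computed in controls only, the standard case-control practice,
and is the exact conditional test: given the observed allele counts, the
P value sums the probabilities of all heterozygote configurations that are
no more probable than the observed one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from grscohort.cohort_io import GenotypeMatrix, PhenotypeTable

__all__ = [
    "HWEResult",
    "SNPQCRecord",
    "call_rate",
    "genotype_counts",
    "hwe_exact_test",
    "hwe_chi2_test",
    "apply_snp_qc",
    "analysed_rsids",
]

REASON_NONE = "none"
REASON_CALL_RATE = "low_call_rate"
REASON_HWE = "hwe_deviation"


@dataclass(frozen=True)
class HWEResult:
    """Exact HWE test result: P value plus a monomorphic-site flag."""

    pvalue: float
    monomorphic: bool = False


@dataclass(frozen=True)
class SNPQCRecord:
    rsid: str
    call_rate: float
    hwe_p: float
    monomorphic: bool
    excluded: bool
    reason: str


def call_rate(matrix: GenotypeMatrix, rsid: str) -> Fraction:
    """Fraction of samples with a non-missing genotype at ``rsid``.

    Returned as an exact rational so that threshold comparisons (e.g. the
    80% boundary) are not subject to float rounding.
    """
    col = matrix.column(rsid)
    return Fraction(int(col.notna().sum()), len(col))


def genotype_counts(
    matrix: GenotypeMatrix, rsid: str, sample_ids: Optional[Iterable[str]] = None
) -> tuple[int, int, int]:
    """Genotype counts (risk-hom, het, other-hom) at ``rsid``.

    Missing genotypes are ignored; an optional sample subset restricts the
    tally (e.g. to controls for the HWE stratum).
    """
    col = matrix.column(rsid)
    if sample_ids is not None:
        col = col.loc[list(sample_ids)]
    vals = col.dropna().to_numpy()
    return int((vals == 2).sum()), int((vals == 1).sum()), int((vals == 0).sum())


def _het_weight(n: int, n_a: int, h: int) -> int:
    """Integer weight proportional to Pr(h heterozygotes | allele counts).

    Conditional on the minor-allele count ``n_a`` out of 2n alleles, the
    probability of ``h`` heterozygotes is proportional to the multinomial
    count of genotype configurations times 2**h.
    """
    n_aa = (n_a - h) // 2
    n_AA = n - h - n_aa
    coeff = math.factorial(n) // (
        math.factorial(n_AA) * math.factorial(h) * math.factorial(n_aa)
    )
    return coeff * (2**h)


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> HWEResult:
    """Exact conditional Hardy-Weinberg test on genotype counts.

    Enumerates every heterozygote count compatible with the observed allele
    totals and sums the (exact, integer-arithmetic) conditional probabilities
    of all configurations no more probable than the observed one. A
    monomorphic site (one allele absent) returns P = 1 with a flag. The test
    is symmetric in the homozygote labels.
    """
    for label, v in (("n_AA", n_AA), ("n_Aa", n_Aa), ("n_aa", n_aa)):
        if v < 0:
            raise ValueError(f"{label} must be non-negative, got {v}")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("at least one genotyped sample is required")
    n_a = 2 * n_aa + n_Aa  # count of the 'a' allele
    n_A = 2 * n_AA + n_Aa
    minor = min(n_a, n_A)
    if minor == 0:
        return HWEResult(pvalue=1.0, monomorphic=True)
    # heterozygote count shares the parity of the minor-allele count
    hs = range(minor % 2, minor + 1, 2)
    weights = {h: _het_weight(n, minor, h) for h in hs}
    total = sum(weights.values())
    w_obs = weights[n_Aa]
    tail = sum(w for w in weights.values() if w <= w_obs)
    return HWEResult(pvalue=float(Fraction(tail, total)), monomorphic=False)


def hwe_chi2_test(n_AA: int, n_Aa: int, n_aa: int) -> HWEResult:
    """One-df chi-square HWE goodness-of-fit test (cross-check variant)."""
    from scipy import stats

    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("at least one genotyped sample is required")
    p = (2 * n_AA + n_Aa) / (2 * n)
    if p in (0.0, 1.0):
        return HWEResult(pvalue=1.0, monomorphic=True)
    expected = np.array([n * p * p, 2 * n * p * (1 - p), n * (1 - p) * (1 - p)])
    observed = np.array([n_AA, n_Aa, n_aa], dtype=float)
    stat = float(((observed - expected) ** 2 / expected).sum())
    return HWEResult(pvalue=float(stats.chi2.sf(stat, df=1)), monomorphic=False)


def _as_exact_fraction(threshold: float | Fraction) -> Fraction:
    # Fraction(str(0.8)) == 4/5 exactly; Fraction(0.8) would carry binary
    # rounding error across the call-rate boundary.
    if isinstance(threshold, Fraction):
        return threshold
    return Fraction(str(threshold))


def apply_snp_qc(
    matrix: GenotypeMatrix,
    phenotypes: Optional[PhenotypeTable] = None,
    *,
    call_rate_min: float | Fraction = Fraction(4, 5),
    hwe_alpha: float = 0.05,
    hwe_stratum: str = "controls",
    hwe_method: str = "exact",
) -> list[SNPQCRecord]:
    """Run call-rate and HWE QC on every SNP in the matrix.

    The call rate is computed over all samples; the HWE test over the
    configured stratum (``controls`` by default, ``all`` to use every
    sample). When a SNP fails both rules the recorded reason is
    ``low_call_rate`` (call rate is checked first). The surviving SNPs form
    the analysed set whose size is the Bonferroni denominator m.
    """
    if hwe_stratum not in ("controls", "all"):
        raise ValueError("hwe_stratum must be 'controls' or 'all'")
    if hwe_stratum == "controls" and phenotypes is None:
        raise ValueError("phenotypes are required to test HWE in controls")
    stratum_ids = phenotypes.control_ids if hwe_stratum == "controls" else None
    test = hwe_exact_test if hwe_method == "exact" else hwe_chi2_test
    threshold = _as_exact_fraction(call_rate_min)

    records = []
    for rsid in matrix.snp_ids:
        cr = call_rate(matrix, rsid)
        counts = genotype_counts(matrix, rsid, stratum_ids)
        if sum(counts) == 0:
            hwe = HWEResult(pvalue=1.0, monomorphic=True)
        else:
            hwe = test(*counts)
        if cr < threshold:
            excluded, reason = True, REASON_CALL_RATE
        elif hwe.pvalue < hwe_alpha:
            excluded, reason = True, REASON_HWE
        else:
            excluded, reason = False, REASON_NONE
        records.append(
            SNPQCRecord(
                rsid=rsid,
                call_rate=float(cr),
                hwe_p=hwe.pvalue,
                monomorphic=hwe.monomorphic,
                excluded=excluded,
                reason=reason,
            )
        )
    return records


def analysed_rsids(records: Iterable[SNPQCRecord]) -> list[str]:
    """rsIDs surviving QC, in input order."""
    return [r.rsid for r in records if not r.excluded]


def qc_frame(records: Iterable[SNPQCRecord]) -> pd.DataFrame:
    records = list(records)
    return pd.DataFrame(
        {
            "rsid": [r.rsid for r in records],
            "call_rate": [r.call_rate for r in records],
            "hwe_p": [r.hwe_p for r in records],
            "monomorphic": [r.monomorphic for r in records],
            "excluded": [r.excluded for r in records],
            "reason": [r.reason for r in records],
        }
    )
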