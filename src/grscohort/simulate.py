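"""Synthetic case-control cohorts with the structure the analysis assumes.

The generator draws a population in which each SNP's genotype is
Binomial(2, RAF) — Hardy-Weinberg proportions by construction, no linkage
disequilibrium (the candidate loci sit in different genes) — clinical
covariates follow simple parametric distributions, and disease status is
Bernoulli with logit(P) = intercept + Σ beta_snp·dosage + Σ beta_cov·cov.
Case-control ascertainment is by rejection sampling: population draws are
accepted into the case or control arm until both requested sizes are
filled. Genotype missingness is injected missing-completely-at-random.

Defaults emulate a dialysis AF study cohort: 113 cases / 157 controls,
13 analysed SNPs (plus 3 extra panel SNPs for QC exercises), covariate
prevalences at the cohort scale (55% male, 30% MI, 45% smokers, age
~ Normal(70, 10)), and 48.65% of cases labelled permanent AF.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from grscohort.cohort_io import (
    CASE,
    CONTROL,
    SUBTYPE_NONPERM,
    SUBTYPE_PERM,
    GenotypeMatrix,
    PhenotypeTable,
    SNPPanel,
    make_panel_record,
    write_dosage_tsv,
    write_panel,
    write_phenotypes,
)

__all__ = [
    "CovariateSpec",
    "SimConfig",
    "example_panel",
    "default_config",
    "simulate_cohort",
    "inject_missingness",
    "make_fixture_suite",
    "make_qc_demo_cohort",
]

# Scenario panel: rsID, gene, risk allele, scenario published OR, population RAF.
# ORs are plausible literature-scale effect sizes and RAFs plausible European
# control frequencies for these loci; they parameterise the simulation
# scenario and are not estimates from any cohort.
_EXAMPLE_SNPS: list[tuple[str, str, str, float, float]] = [
    ("rs1805127", "KCNE1", "C", 1.20, 0.67),
    ("rs3807989", "CAV1", "G", 1.11, 0.55),
    ("rs2106261", "ZFHX3", "T", 1.21, 0.18),
    ("rs2200733", "PITX2", "T", 1.64, 0.14),
    ("rs3853445", "PITX2", "T", 1.12, 0.72),
    ("rs13376333", "KCNN3", "T", 1.52, 0.29),
    ("rs1805123", "KCNH2", "T", 1.10, 0.82),
    ("rs4845625", "IL6R", "T", 1.07, 0.50),
    ("rs11047543", "SOX5", "G", 1.14, 0.88),
    ("rs10465885", "GJA5", "T", 1.18, 0.44),
    ("rs13038095", "SULF2", "T", 1.30, 0.10),
    ("rs6800541", "SCN10A", "T", 1.14, 0.66),
    ("rs251253", "NKX2-5", "T", 1.10, 0.57),
    # extra panel SNPs used to exercise the QC exclusion path
    ("rs3825214", "TBX5", "G", 1.39, 0.40),
    ("rs1131820", "KCNN3", "A", 1.12, 0.35),
    ("rs11708996", "SCN5A", "C", 1.20, 0.15),
]


def example_panel(n_snps: int = 13) -> SNPPanel:
    """A ready-made candidate-SNP panel (13 analysed SNPs, up to 16 total).

    The published-OR column holds scenario weights at the scale reported in
    AF genome-wide studies, labelled as such — users analysing real cohorts
    supply their own panel file.
    """
    if not 1 <= n_snps <= len(_EXAMPLE_SNPS):
        raise ValueError(f"n_snps must be in [1, {len(_EXAMPLE_SNPS)}]")
    return SNPPanel(
        make_panel_record(rsid, gene, allele, or_pub, source="scenario")
        for rsid, gene, allele, or_pub, _ in _EXAMPLE_SNPS[:n_snps]
    )


def example_rafs(n_snps: int = 13) -> dict[str, float]:
    return {rsid: raf for rsid, _, _, _, raf in _EXAMPLE_SNPS[:n_snps]}


@dataclass(frozen=True)
class CovariateSpec:
    """One covariate: sampling distribution plus per-unit log-OR on disease.

    ``binary`` covariates are Bernoulli(p) and enter the linear predictor
    as 0/1; ``normal`` covariates are Normal(mean, sd) and enter centred at
    their mean, so the intercept keeps its interpretation at the covariate
    means.
    """

    name: str
    kind: str  # "binary" | "normal"
    beta: float = 0.0
    p: Optional[float] = None
    mean: Optional[float] = None
    sd: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind == "binary":
            if self.p is None or not 0 <= self.p <= 1:
                raise ValueError(f"{self.name}: binary covariate needs p in [0, 1]")
        elif self.kind == "normal":
            if self.mean is None or self.sd is None or self.sd < 0:
                raise ValueError(f"{self.name}: normal covariate needs mean and sd >= 0")
        else:
            raise ValueError(f"{self.name}: kind must be 'binary' or 'normal'")

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.kind == "binary":
            return (rng.random(n) < self.p).astype(float)
        return rng.normal(self.mean, self.sd, size=n)

    def effect_input(self, values: np.ndarray) -> np.ndarray:
        return values - self.mean if self.kind == "normal" else values


def _default_covariates() -> list[CovariateSpec]:
    return [
        CovariateSpec("sex_male", "binary", beta=math.log(2.3), p=0.55),
        CovariateSpec("age", "normal", beta=0.01, mean=70.0, sd=10.0),
        CovariateSpec("bmi", "normal", beta=0.0, mean=27.5, sd=5.5),
        CovariateSpec("ever_smoker", "binary", beta=math.log(1.3), p=0.45),
        CovariateSpec("diuresis", "binary", beta=0.0, p=0.83),
        CovariateSpec("cad", "binary", beta=0.0, p=0.62),
        CovariateSpec("mi", "binary", beta=math.log(2.6), p=0.30),
        CovariateSpec("hypertrophy", "binary", beta=0.0, p=0.75),
    ]


@dataclass
class SimConfig:
    """Full parameterisation of a synthetic cohort.

    With ``intercept=None`` the intercept is calibrated (from a dedicated
    calibration stream) so the population case probability matches
    ``target_case_fraction``. Output is bit-reproducible for a fixed seed.
    """

    panel: SNPPanel
    snp_rafs: dict[str, float]
    snp_betas: dict[str, float]
    n_case: int = 113
    n_control: int = 157
    covariates: list[CovariateSpec] = field(default_factory=_default_covariates)
    intercept: Optional[float] = None
    target_case_fraction: float = 113 / 270
    perm_fraction: float = 0.4865
    missing_rate: float = 0.0
    subtype_effect_snp: Optional[str] = None
    subtype_effect_beta: float = 0.0
    seed: int = 0
    max_draw_factor: int = 500

    def __post_init__(self) -> None:
        if self.n_case < 2 or self.n_control < 2:
            raise ValueError("n_case and n_control must be at least 2")
        for rsid, raf in self.snp_rafs.items():
            if not 0.0 < raf < 1.0:
                raise ValueError(f"{rsid}: RAF must be in (0, 1), got {raf}")
        missing = set(self.panel.rsids) - set(self.snp_rafs)
        if missing:
            raise ValueError(f"panel SNPs without a RAF: {sorted(missing)}")
        if not 0 <= self.perm_fraction <= 1:
            raise ValueError("perm_fraction must be in [0, 1]")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")


def default_config(
    n_snps: int = 13,
    *,
    n_case: int = 113,
    n_control: int = 157,
    missing_rate: float = 0.0,
    seed: int = 0,
    null_effects: bool = False,
) -> SimConfig:
    """The default scenario: example panel, RAFs at their scenario values,
    per-allele effects equal to the panel weights (ln of the scenario ORs).

    ``null_effects=True`` zeroes every SNP and covariate effect, giving a
    pure null model useful for calibration checks.
    """
    panel = example_panel(n_snps)
    betas = {r: 0.0 for r in panel.rsids} if null_effects else dict(panel.weights)
    covs = _default_covariates()
    if null_effects:
        covs = [replace(c, beta=0.0) for c in covs]
    return SimConfig(
        panel=panel,
        snp_rafs=example_rafs(n_snps),
        snp_betas=betas,
        n_case=n_case,
        n_control=n_control,
        covariates=covs,
        intercept=0.0 if null_effects else None,
        missing_rate=missing_rate,
        seed=seed,
    )


def _logit(p: float) -> float:
    return math.log(p / (1 - p))


def _draw_population(
    rng: np.random.Generator, config: SimConfig, n: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw genotypes, covariates and the (interceptless) linear predictor."""
    rafs = np.array([config.snp_rafs[r] for r in config.panel.rsids])
    betas = np.array([config.snp_betas.get(r, 0.0) for r in config.panel.rsids])
    dosage = rng.binomial(2, rafs, size=(n, len(rafs))).astype(float)
    if config.covariates:
        cov = np.column_stack([spec.draw(rng, n) for spec in config.covariates])
        cov_lp = sum(
            spec.effect_input(cov[:, j]) * spec.beta
            for j, spec in enumerate(config.covariates)
        )
    else:
        cov = np.empty((n, 0))
        cov_lp = 0.0
    lp = dosage @ betas + cov_lp
    return dosage, cov, lp


def calibrate_intercept(config: SimConfig, rng: np.random.Generator, n: int = 20000) -> float:
    """Intercept making the mean population linear predictor hit the target
    case fraction (first-order calibration on a dedicated sample)."""
    _, _, lp = _draw_population(rng, config, n)
    return _logit(config.target_case_fraction) - float(lp.mean())


def simulate_cohort(
    config: SimConfig, seed: Optional[int] = None
) -> tuple[GenotypeMatrix, PhenotypeTable, dict]:
    """Simulate a case-control cohort under the configured disease model.

    Returns the risk-allele dosage matrix, the phenotype table (AF status,
    subtype, covariates) and a truth record holding every parameter
    actually used, including the realised intercept and draw count.
    Raises ``RuntimeError`` if the requested arm sizes cannot be filled
    within ``max_draw_factor`` × (n_case + n_control) population draws.
    """
    seed = config.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    rng_cal, rng_main, rng_miss, rng_sub = [np.random.default_rng(s) for s in ss.spawn(4)]

    intercept = (
        config.intercept
        if config.intercept is not None
        else calibrate_intercept(config, rng_cal)
    )

    n_total = config.n_case + config.n_control
    max_draws = config.max_draw_factor * n_total + 10_000
    cases: list[tuple[np.ndarray, np.ndarray]] = []
    controls: list[tuple[np.ndarray, np.ndarray]] = []
    draws = 0
    batch = max(1024, n_total)
    while len(cases) < config.n_case or len(controls) < config.n_control:
        if draws >= max_draws:
            raise RuntimeError(
                f"could not fill {config.n_case}/{config.n_control} case/control "
                f"arms within {max_draws} draws; check intercept and effects"
            )
        dosage, cov, lp = _draw_population(rng_main, config, batch)
        prob = 1.0 / (1.0 + np.exp(-(intercept + lp)))
        is_case = rng_main.random(batch) < prob
        draws += batch
        for i in range(batch):
            if is_case[i] and len(cases) < config.n_case:
                cases.append((dosage[i], cov[i]))
            elif not is_case[i] and len(controls) < config.n_control:
                controls.append((dosage[i], cov[i]))

    status = [CASE] * config.n_case + [CONTROL] * config.n_control
    rows = cases + controls
    sample_ids = [f"S{i + 1:04d}" for i in range(n_total)]
    dosage_df = pd.DataFrame(
        np.vstack([r[0] for r in rows]), index=sample_ids, columns=config.panel.rsids
    )
    cov_df = pd.DataFrame(
        np.vstack([r[1] for r in rows]),
        index=sample_ids,
        columns=[c.name for c in config.covariates],
    )

    # permanent / non-permanent labels for cases, optionally genotype-enriched
    subtype = np.array([""] * n_total, dtype=object)
    case_idx = np.arange(config.n_case)
    if config.subtype_effect_snp is not None:
        j = config.panel.rsids.index(config.subtype_effect_snp)
        d = dosage_df.iloc[case_idx, j].to_numpy()
        base = _logit(min(max(config.perm_fraction, 1e-9), 1 - 1e-9))
        p_perm = 1.0 / (1.0 + np.exp(-(base + config.subtype_effect_beta * (d - d.mean()))))
    else:
        p_perm = np.full(config.n_case, config.perm_fraction)
    is_perm = rng_sub.random(config.n_case) < p_perm
    subtype[case_idx] = np.where(is_perm, SUBTYPE_PERM, SUBTYPE_NONPERM)
    subtype[config.n_case:] = "none"

    pheno_df = cov_df.copy()
    pheno_df.insert(0, "af_status", status)
    pheno_df.insert(1, "af_subtype", subtype)

    matrix = GenotypeMatrix(dosage_df)
    if config.missing_rate > 0:
        matrix = inject_missingness(matrix, config.missing_rate, rng=rng_miss)

    truth = {
        "seed": seed,
        "intercept": intercept,
        "n_case": config.n_case,
        "n_control": config.n_control,
        "snp_rafs": dict(config.snp_rafs),
        "snp_betas": {r: config.snp_betas.get(r, 0.0) for r in config.panel.rsids},
        "covariates": [
            {"name": c.name, "kind": c.kind, "beta": c.beta, "p": c.p, "mean": c.mean, "sd": c.sd}
            for c in config.covariates
        ],
        "perm_fraction": config.perm_fraction,
        "missing_rate": config.missing_rate,
        "population_draws": draws,
    }
    return matrix, PhenotypeTable(pheno_df), truth


def inject_missingness(
    matrix: GenotypeMatrix,
    rate: float,
    seed: Optional[int] = None,
    *,
    rng: Optional[np.random.Generator] = None,
) -> GenotypeMatrix:
    """Set each dosage missing independently with probability ``rate`` (MCAR).

    The expected complete-case loss per sample over m SNPs is
    1 − (1 − rate)^m; a rate of ~0.0115 over 13 SNPs reproduces the ~14%
    exclusion scale seen in candidate-gene panels of this size.
    """
    if not 0 <= rate < 1:
        raise ValueError("rate must be in [0, 1)")
    if rate == 0:
        return matrix
    if rng is None:
        rng = np.random.default_rng(seed)
    values = matrix.dosage.to_numpy().copy()
    mask = rng.random(values.shape) < rate
    values[mask] = np.nan
    return GenotypeMatrix(
        pd.DataFrame(values, index=matrix.dosage.index, columns=matrix.dosage.columns)
    )


def _hwe_rounded_counts(n: int, p: float) -> tuple[int, int, int]:
    """Genotype counts closest to exact Hardy-Weinberg proportions."""
    n_aa = round(n * p * p)
    n_oo = round(n * (1 - p) * (1 - p))
    return n_aa, n - n_aa - n_oo, n_oo


def make_qc_demo_cohort(
    seed: int = 0, n_case: int = 113, n_control: int = 157
) -> tuple[GenotypeMatrix, PhenotypeTable]:
    """A designed cohort in which exactly 3 of the 16 panel SNPs violate QC.

    The 13 analysed SNPs are laid out in (rounded) exact Hardy-Weinberg
    proportions within each phenotype stratum, so they pass QC for every
    seed; the three designated failures are deterministic by construction:
    one SNP with ~75% call rate, one with universal heterozygosity and one
    with no heterozygotes at all. The seed only shuffles genotype placement
    within strata, which the QC statistics are invariant to. This is the
    package's Hardy-Weinberg-violation hook, intended for exercising the
    exclusion accounting (16 genotyped − 3 failed = 13 analysed).
    """
    panel = example_panel(16)
    rafs = example_rafs(16)
    rng = np.random.default_rng(seed)
    n_total = n_case + n_control
    sample_ids = [f"S{i + 1:04d}" for i in range(n_total)]
    fail_call, fail_het, fail_hom = "rs3825214", "rs1131820", "rs11708996"

    def stratum_column(n: int, p: float) -> np.ndarray:
        n2, n1, n0 = _hwe_rounded_counts(n, p)
        vals = np.array([2.0] * n2 + [1.0] * n1 + [0.0] * n0)
        rng.shuffle(vals)
        return vals

    cols: dict[str, np.ndarray] = {}
    for rsid in panel.rsids:
        if rsid == fail_het:
            cols[rsid] = np.ones(n_total)
        elif rsid == fail_hom:
            cols[rsid] = np.tile([0.0, 2.0], n_total // 2 + 1)[:n_total]
        else:
            cols[rsid] = np.concatenate(
                [stratum_column(n_case, rafs[rsid]), stratum_column(n_control, rafs[rsid])]
            )
    # 25% missing calls -> call rate 0.75, below the 0.80 threshold
    miss_at = rng.choice(n_total, size=int(round(0.25 * n_total)), replace=False)
    cols[fail_call][miss_at] = np.nan

    matrix = GenotypeMatrix(pd.DataFrame(cols, index=sample_ids, columns=panel.rsids))
    subtype = np.where(np.arange(n_case) % 2 == 0, SUBTYPE_PERM, SUBTYPE_NONPERM)
    phenotypes = PhenotypeTable(
        pd.DataFrame(
            {
                "af_status": [CASE] * n_case + [CONTROL] * n_control,
                "af_subtype": list(subtype) + ["none"] * n_control,
            },
            index=sample_ids,
        )
    )
    return matrix, phenotypes


# ---------------------------------------------------------------------------
# deterministic on-disk fixture used by the test-suite and demos
# ---------------------------------------------------------------------------

_OTHER_BASE = {"A": "G", "G": "A", "C": "T", "T": "C"}


def _write_vcf(
    matrix: GenotypeMatrix, panel: SNPPanel, path: Path, risk_is_alt: dict[str, bool]
) -> None:
    """Write dosages as a minimal VCF v4.2 with GT-only genotype fields."""
    lines = [
        "##fileformat=VCFv4.2",
        "##contig=<ID=1>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(matrix.sample_ids),
    ]
    for pos, rsid in enumerate(panel.rsids, start=1):
        risk = panel.get(rsid).risk_allele
        other = _OTHER_BASE[risk]
        ref, alt = (other, risk) if risk_is_alt[rsid] else (risk, other)
        gts = []
        for v in matrix.column(rsid):
            if np.isnan(v):
                gts.append("./.")
                continue
            alt_copies = int(v) if risk_is_alt[rsid] else 2 - int(v)
            gts.append({0: "0/0", 1: "0/1", 2: "1/1"}[alt_copies])
        lines.append(
            f"1\t{100 * pos}\t{rsid}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t" + "\t".join(gts)
        )
    path.write_text("\n".join(lines) + "\n")


def make_fixture_suite(out_dir: str | Path, seed: int = 7) -> dict[str, Path]:
    """Write a small deterministic fixture: 20 samples × 5 SNPs.

    Emits panel.tsv, dosage.tsv, genotypes.vcf, phenotypes.tsv and
    truth.json. The fixture is designed to cover the awkward paths: it
    contains at least one missing genotype, one monomorphic SNP, and VCF
    sites with the risk allele on both the REF and the ALT side.
    Regeneration with the same seed is byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    panel = example_panel(5)
    config = SimConfig(
        panel=panel,
        snp_rafs=example_rafs(5),
        snp_betas=dict(panel.weights),
        n_case=10,
        n_control=10,
        covariates=_default_covariates(),
        seed=seed,
    )
    matrix, phenotypes, truth = simulate_cohort(config)
    dosage = matrix.dosage.copy()
    dosage.iloc[0, 2] = np.nan  # designed missing call
    dosage[panel.rsids[4]] = 0.0  # designed monomorphic SNP
    matrix = GenotypeMatrix(dosage)
    truth["designed"] = {"missing_cell": [matrix.sample_ids[0], panel.rsids[2]],
                         "monomorphic_snp": panel.rsids[4]}

    paths = {
        "panel": out_dir / "panel.tsv",
        "dosage": out_dir / "dosage.tsv",
        "vcf": out_dir / "genotypes.vcf",
        "phenotypes": out_dir / "phenotypes.tsv",
        "truth": out_dir / "truth.json",
    }
    write_panel(panel, paths["panel"])
    write_dosage_tsv(matrix, paths["dosage"])
    risk_is_alt = {rsid: (i % 2 == 0) for i, rsid in enumerate(panel.rsids)}
    _write_vcf(matrix, panel, paths["vcf"], risk_is_alt)
    write_phenotypes(phenotypes, paths["phenotypes"])
    paths["truth"].write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    return paths
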