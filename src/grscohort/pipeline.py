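"""End-to-end study orchestration: ingest → QC → association → GRS → model.

``run_study`` binds the stages in fixed order and enforces the
cross-section consistency the workflow depends on: the analysed-SNP set
produced by QC feeds both the Bonferroni denominator m used for every
corrected P value and the SNP set entering the genetic risk score. The
report also carries a provenance block (config hash, seed, package
version, per-stage row counts) so every number is recomputable.

Configuration is a single YAML (or plain dict): input paths or a
``simulate`` block, QC thresholds, association groups, and model terms.
Every analysis threshold (call-rate 0.80, HWE alpha 0.05, classification
threshold 0.5, GRS OR step 0.1) is a config default, never hard-coded in
a stage.
"""

from __future__ import annotations

import copy
import hashlib
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from grscohort.association import association_frame, run_association
from grscohort.cohort_io import (
    CASE,
    GenotypeMatrix,
    PhenotypeTable,
    SNPPanel,
    read_genotypes,
    read_panel,
    read_phenotypes,
    write_tables,
)
from grscohort.modeling import (
    classification_accuracy,
    fit_logistic,
    mcfadden_r2,
    model_frame,
    reduced_model,
)
from grscohort.qc import analysed_rsids, apply_snp_qc, qc_frame
from grscohort.score import compare_all, comparison_frame, compute_grs
from grscohort.simulate import default_config, simulate_cohort

__all__ = ["StudyReport", "run_study", "summarize_cohort", "load_config", "DEFAULT_CONFIG"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "qc": {"call_rate_min": 0.8, "hwe_alpha": 0.05, "hwe_stratum": "controls"},
    "association": {"groups": ["AF", "NP-AF", "P-AF"]},
    "model": {
        "predictors": [
            "age",
            "sex_male",
            "ever_smoker",
            "bmi",
            "diuresis",
            "cad",
            "mi",
            "hypertrophy",
            "grs",
        ],
        "reduce": True,
        "selection_alpha": 0.05,
        "classification_threshold": 0.5,
        "grs_or_delta": 0.1,
    },
}

_CONTINUOUS_VARS = ["age", "bmi"]
_BINARY_VARS = ["sex_male", "ever_smoker", "diuresis", "cad", "mi", "hypertrophy"]


def load_config(path: str | Path) -> dict:
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("study config must be a mapping")
    return cfg


def _merged_config(config: dict) -> dict:
    merged = copy.deepcopy(DEFAULT_CONFIG)
    for key, value in config.items():
        if isinstance(value, dict) and isinstance(merged.get(key), dict):
            merged[key].update(value)
        else:
            merged[key] = value
    return merged


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


@dataclass
class StudyReport:
    cohort_summary: pd.DataFrame
    qc: pd.DataFrame
    association: pd.DataFrame
    grs_scores: pd.DataFrame
    grs_summary: pd.DataFrame
    model_full: pd.DataFrame
    model_reduced: Optional[pd.DataFrame]
    model_stats: dict
    provenance: dict

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        tables = {
            "cohort_summary": self.cohort_summary,
            "qc": self.qc,
            "association": self.association,
            "grs_scores": self.grs_scores,
            "grs_summary": self.grs_summary,
            "model_full": self.model_full,
        }
        if self.model_reduced is not None:
            tables["model_reduced"] = self.model_reduced
        write_tables(tables, out_dir)
        payload = {"provenance": self.provenance, "model_stats": self.model_stats}
        (out_dir / "provenance.json").write_text(
            json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n"
        )


def summarize_cohort(phenotypes: PhenotypeTable) -> pd.DataFrame:
    """Cohort characteristics table: mean (SD) or n (%) per group with a
    group-difference P value.

    Continuous variables are compared with the two-sample pooled t test,
    categorical ones with the 1-df Pearson chi-square (no continuity
    correction); per-group available-n columns record missingness.
    """
    frame = phenotypes.frame
    cases = frame[frame["af_status"] == CASE]
    controls = frame[frame["af_status"] != CASE]
    rows = []

    def add(variable, af_value, naf_value, n_af, n_naf, p, test):
        rows.append(
            {
                "variable": variable,
                "af": af_value,
                "naf": naf_value,
                "n_af": n_af,
                "n_naf": n_naf,
                "p": float(f"{p:.3g}") if isinstance(p, float) and math.isfinite(p) else p,
                "test": test,
            }
        )

    add("N", str(len(cases)), str(len(controls)), len(cases), len(controls), "", "")
    for var in _CONTINUOUS_VARS:
        if var not in frame.columns:
            continue
        a = cases[var].dropna().astype(float)
        b = controls[var].dropna().astype(float)
        if len(a) > 1 and len(b) > 1:
            p = float(stats.ttest_ind(a, b, equal_var=True).pvalue)
        else:
            p = math.nan
        add(
            var,
            f"{a.mean():.2f} ({a.std(ddof=1):.2f})",
            f"{b.mean():.2f} ({b.std(ddof=1):.2f})",
            len(a),
            len(b),
            p,
            "t",
        )
    for var in _BINARY_VARS:
        if var not in frame.columns:
            continue
        a = cases[var].dropna().astype(float)
        b = controls[var].dropna().astype(float)
        table = np.array(
            [[a.sum(), len(a) - a.sum()], [b.sum(), len(b) - b.sum()]], dtype=float
        )
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            p = 1.0
        else:
            p = float(stats.chi2_contingency(table, correction=False)[1])
        add(
            var,
            f"{int(a.sum())} ({100 * a.mean():.2f}%)" if len(a) else "0 (0%)",
            f"{int(b.sum())} ({100 * b.mean():.2f}%)" if len(b) else "0 (0%)",
            len(a),
            len(b),
            p,
            "chi2",
        )
    subtype = cases["af_subtype"].dropna()
    for level in ("non-permanent", "permanent"):
        n = int((subtype == level).sum())
        pct = 100 * n / len(subtype) if len(subtype) else 0.0
        add(f"af_{level}", f"{n} ({pct:.2f}%)", "n/a", len(subtype), 0, "", "")
    return pd.DataFrame(rows)


def _load_inputs(
    config: dict,
) -> tuple[SNPPanel, GenotypeMatrix, PhenotypeTable, dict]:
    """Materialise panel/genotypes/phenotypes from paths or a simulate block."""
    provenance: dict = {}
    if "simulate" in config:
        sim = dict(config["simulate"])
        sim.setdefault("seed", config.get("seed", 0))
        sim_config = default_config(
            n_snps=sim.pop("n_snps", 13),
            n_case=sim.pop("n_case", 113),
            n_control=sim.pop("n_control", 157),
            missing_rate=sim.pop("missing_rate", 0.0),
            seed=sim.pop("seed"),
            null_effects=sim.pop("null_effects", False),
        )
        if sim:
            raise ValueError(f"unknown simulate options: {sorted(sim)}")
        matrix, phenotypes, truth = simulate_cohort(sim_config)
        provenance["simulated"] = {
            k: truth[k] for k in ("seed", "intercept", "n_case", "n_control", "missing_rate")
        }
        return sim_config.panel, matrix, phenotypes, provenance
    inputs = config.get("inputs")
    if not inputs:
        raise ValueError("config needs either an 'inputs' or a 'simulate' section")
    panel = read_panel(inputs["panel"])
    matrix = read_genotypes(
        inputs["genotypes"], panel, format=inputs.get("genotype_format", "dosage_tsv")
    )
    phenotypes = read_phenotypes(inputs["phenotypes"])
    provenance["inputs"] = {k: str(v) for k, v in inputs.items()}
    return panel, matrix, phenotypes, provenance


def run_study(config: dict | str | Path, out_dir: Optional[str | Path] = None) -> StudyReport:
    """Run the full workflow and (optionally) write the report directory.

    Stage order: ingest/simulate, cohort summary, per-SNP QC, allelic
    association for each group (Bonferroni m = analysed-SNP count), GRS
    over the analysed SNPs with complete-case exclusion and group t tests,
    then the multivariable logistic model (full and, by default, the
    backward-reduced version) with McFadden R², per-0.1-unit GRS OR and
    resubstitution accuracy.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    config = _merged_config(config)
    panel, matrix, phenotypes, input_prov = _load_inputs(config)

    qc_cfg = config["qc"]
    qc_records = apply_snp_qc(
        matrix,
        phenotypes,
        call_rate_min=qc_cfg["call_rate_min"],
        hwe_alpha=qc_cfg["hwe_alpha"],
        hwe_stratum=qc_cfg["hwe_stratum"],
    )
    analysed = analysed_rsids(qc_records)
    m = len(analysed)
    if m == 0:
        raise ValueError("QC excluded every SNP; nothing to analyse")

    assoc_results = run_association(
        matrix, phenotypes, panel, analysed, groups=config["association"]["groups"]
    )
    if any(r.m != m for r in assoc_results):
        raise AssertionError("Bonferroni m inconsistent with analysed-SNP count")

    grs_result = compute_grs(matrix, panel, analysed)
    comparisons = compare_all(grs_result, phenotypes)
    scores_df = pd.DataFrame(
        {"sample_id": grs_result.included_ids, "grs": grs_result.scores.to_numpy()}
    )

    model_cfg = config["model"]
    predictors = list(model_cfg["predictors"])
    design_cols = {}
    for name in predictors:
        if name == "grs":
            design_cols["grs"] = grs_result.scores.reindex(phenotypes.ids)
        else:
            design_cols[name] = phenotypes.frame[name].astype(float)
    design = pd.DataFrame(design_cols, index=phenotypes.ids)
    outcome = (phenotypes.frame["af_status"] == CASE).astype(float)

    fit_full = fit_logistic(design, outcome)
    model_stats: dict = {
        "n_model_rows": fit_full.n_obs,
        "n_dropped_rows": fit_full.n_dropped_rows,
        "full": {},
        "reduced": {},
    }
    delta = model_cfg["grs_or_delta"]
    thresh = model_cfg["classification_threshold"]
    if fit_full.converged:
        model_stats["full"] = {
            "mcfadden_r2": mcfadden_r2(fit_full),
            "accuracy": classification_accuracy(fit_full, threshold=thresh),
        }
    full_df = model_frame(fit_full, grs_term="grs", delta=delta)

    reduced_df = None
    if model_cfg.get("reduce", True) and fit_full.converged:
        fit_red = reduced_model(fit_full, alpha=model_cfg["selection_alpha"])
        reduced_df = model_frame(fit_red, grs_term="grs", delta=delta)
        if fit_red.converged:
            model_stats["reduced"] = {
                "mcfadden_r2": mcfadden_r2(fit_red),
                "accuracy": classification_accuracy(fit_red, threshold=thresh),
                "terms": fit_red.terms,
            }

    from grscohort import __version__ as pkg_version

    provenance = {
        "package_version": pkg_version,
        "config_hash": _config_hash(config),
        "seed": config.get("seed", 0),
        "n_samples": len(phenotypes.ids),
        "n_cases": len(phenotypes.case_ids),
        "n_controls": len(phenotypes.control_ids),
        "n_panel_snps": len(panel),
        "n_analysed_snps": m,
        "bonferroni_m": m,
        "n_grs_included": len(grs_result.included_ids),
        "n_grs_excluded": len(grs_result.excluded_ids),
        **input_prov,
    }

    report = StudyReport(
        cohort_summary=summarize_cohort(phenotypes),
        qc=qc_frame(qc_records),
        association=association_frame(assoc_results),
        grs_scores=scores_df,
        grs_summary=comparison_frame(comparisons),
        model_full=full_df,
        model_reduced=reduced_df,
        model_stats=model_stats,
        provenance=provenance,
    )
    if out_dir is not None:
        report.write(out_dir)
    return report
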