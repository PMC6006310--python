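"""Synthetic-cohort generator: determinism, calibration and truth recovery."""

import json
import math

import numpy as np
import pandas as pd
import pytest

import grscohort as g
from grscohort.modeling import fit_logistic
from grscohort.qc import apply_snp_qc
from grscohort.score import compare_grs, compute_grs
from grscohort.simulate import (
    CovariateSpec,
    SimConfig,
    default_config,
    example_panel,
    example_rafs,
    inject_missingness,
    make_fixture_suite,
    simulate_cohort,
)


class TestConfig:
    def test_example_panel_sizes(self):
        assert len(example_panel(13)) == 13
        assert len(example_panel(16)) == 16
        with pytest.raises(ValueError):
            example_panel(17)

    def test_invalid_parameters_rejected(self):
        panel = example_panel(2)
        rafs = example_rafs(2)
        with pytest.raises(ValueError):
            SimConfig(panel=panel, snp_rafs=rafs, snp_betas={}, n_case=1)
        with pytest.raises(ValueError):
            SimConfig(panel=panel, snp_rafs={panel.rsids[0]: 1.5}, snp_betas={})
        with pytest.raises(ValueError):
            CovariateSpec("x", "binary", p=None)
        with pytest.raises(ValueError):
            CovariateSpec("x", "poisson", p=0.5)


class TestSimulateCohort:
    def test_requested_arm_sizes_and_dosage_domain(self):
        cfg = default_config(n_case=40, n_control=60, seed=1)
        matrix, phenotypes, truth = simulate_cohort(cfg)
        assert len(phenotypes.case_ids) == 40
        assert len(phenotypes.control_ids) == 60
        vals = matrix.dosage.to_numpy()
        assert np.isin(vals, (0.0, 1.0, 2.0)).all()
        assert truth["population_draws"] >= 100

    def test_same_seed_bitwise_reproducible(self):
        cfg = default_config(n_case=30, n_control=30, seed=42, missing_rate=0.01)
        m1, p1, t1 = simulate_cohort(cfg)
        m2, p2, t2 = simulate_cohort(cfg)
        pd.testing.assert_frame_equal(m1.dosage, m2.dosage)
        pd.testing.assert_frame_equal(p1.frame, p2.frame)
        assert t1 == t2

    def test_different_seeds_differ(self):
        m1, _, _ = simulate_cohort(default_config(n_case=30, n_control=30, seed=1))
        m2, _, _ = simulate_cohort(default_config(n_case=30, n_control=30, seed=2))
        assert not m1.dosage.equals(m2.dosage)

    def test_null_model_calibration(self):
        """Betas 0, intercept 0: ~half the draws are cases and control RAFs
        track the configured population frequencies."""
        cfg = default_config(n_case=1000, n_control=1000, seed=5, null_effects=True)
        matrix, phenotypes, truth = simulate_cohort(cfg)
        assert truth["intercept"] == 0.0
        # acceptance probability 0.5 -> draws close to 2 * n_total
        assert truth["population_draws"] <= 4 * 2000
        ctrl = matrix.dosage.loc[phenotypes.control_ids]
        for rsid, raf in cfg.snp_rafs.items():
            se = math.sqrt(raf * (1 - raf) / (2 * len(ctrl)))
            assert abs(ctrl[rsid].mean() / 2 - raf) <= 4 * se

    def test_single_snp_effect_recovered_in_allelic_or(self):
        """One SNP with OR 1.5, everything else null: the fitted allelic OR
        lands in a sampling band around 1.5 in (nearly) every replicate."""
        from grscohort.association import allele_table, allelic_or

        hits = 0
        for seed in range(10):
            panel = example_panel(3)
            betas = {r: 0.0 for r in panel.rsids}
            betas[panel.rsids[0]] = math.log(1.5)
            cfg = SimConfig(
                panel=panel,
                snp_rafs=example_rafs(3),
                snp_betas=betas,
                n_case=1000,
                n_control=1000,
                covariates=[],
                intercept=None,
                seed=40_000 + seed,
            )
            matrix, phenotypes, _ = simulate_cohort(cfg)
            t = allele_table(matrix, phenotypes, panel.rsids[0], "AF")
            hits += 1.2 <= allelic_or(t).value <= 1.9
        assert hits >= 9

    def test_unattainable_case_count_errors(self):
        panel = example_panel(2)
        cfg = SimConfig(
            panel=panel,
            snp_rafs=example_rafs(2),
            snp_betas={r: 0.0 for r in panel.rsids},
            n_case=50,
            n_control=50,
            covariates=[],
            intercept=-30.0,  # case probability ~1e-13
            max_draw_factor=10,
            seed=0,
        )
        with pytest.raises(RuntimeError, match="draws"):
            simulate_cohort(cfg)

    def test_subtype_fractions(self):
        cfg = default_config(n_case=400, n_control=50, seed=9)
        _, phenotypes, _ = simulate_cohort(cfg)
        perm = len(phenotypes.group_ids("P-AF"))
        nperm = len(phenotypes.group_ids("NP-AF"))
        assert perm + nperm == 400
        assert 0.4 < perm / 400 < 0.6  # perm_fraction 0.4865


class TestInjectMissingness:
    def test_rate_zero_is_identity(self, tiny_matrix):
        assert inject_missingness(tiny_matrix, 0.0, seed=0) is tiny_matrix

    def test_half_rate_on_one_snp(self):
        m = g.GenotypeMatrix(
            pd.DataFrame({"rs1": np.ones(2000)}, index=[f"s{i}" for i in range(2000)])
        )
        out = inject_missingness(m, 0.5, seed=3)
        frac = out.dosage["rs1"].isna().mean()
        assert 0.45 < frac < 0.55

    def test_complete_case_loss_matches_expectation(self):
        """rate ~0.0115 over 13 SNPs loses ~14% of samples to complete-case
        (the scale of the 40-of-270 exclusions the workflow must absorb)."""
        rate = 1 - (1 - 0.14) ** (1 / 13)
        losses = []
        for seed in range(5):
            cfg = default_config(n_case=113, n_control=157, seed=50_000 + seed)
            matrix, _, _ = simulate_cohort(cfg)
            m2 = inject_missingness(matrix, rate, seed=seed)
            lost = (~m2.dosage.notna().all(axis=1)).sum()
            losses.append(lost)
        mean_loss = np.mean(losses)
        assert 20 <= mean_loss <= 60  # binomial band around 270 * 0.14 ~ 38


class TestParameterRecovery:
    def test_logistic_refit_covers_true_betas(self):
        """95% Wald CIs from a refit on the simulated data cover the true
        per-allele log-ORs at roughly the nominal rate (20 seeds)."""
        hits = total = 0
        for seed in range(20):
            cfg = default_config(n_case=1000, n_control=1000, seed=10_000 + seed)
            matrix, phenotypes, truth = simulate_cohort(cfg)
            covs = [c["name"] for c in truth["covariates"]]
            design = matrix.dosage.join(phenotypes.frame[covs].astype(float))
            y = (phenotypes.frame["af_status"] == "case").astype(float)
            fit = fit_logistic(design, y)
            assert fit.converged
            for rsid, beta in truth["snp_betas"].items():
                lo = fit.beta[rsid] - 1.96 * fit.se[rsid]
                hi = fit.beta[rsid] + 1.96 * fit.se[rsid]
                total += 1
                hits += lo <= beta <= hi
        assert hits / total >= 0.90

    def test_true_weight_grs_separates_groups(self):
        """A GRS built from the true effects separates cases from controls
        (t-test P < 0.01) in at least 19 of 20 seeds at n = 1000/1000."""
        successes = 0
        for seed in range(20):
            cfg = default_config(n_case=1000, n_control=1000, seed=10_000 + seed)
            matrix, phenotypes, _ = simulate_cohort(cfg)
            res = compute_grs(matrix, cfg.panel, cfg.panel.rsids)
            successes += compare_grs(res, phenotypes, "AF", "NAF").p_value < 0.01
        assert successes >= 19

    def test_hwe_holds_in_simulated_controls(self):
        """Exact-test rejections in controls stay near the nominal 5% rate."""
        below = total = 0
        for seed in range(20):
            cfg = default_config(n_case=113, n_control=157, seed=60_000 + seed)
            matrix, phenotypes, _ = simulate_cohort(cfg)
            for rec in apply_snp_qc(matrix, phenotypes, hwe_stratum="controls"):
                total += 1
                below += rec.hwe_p < 0.05
        assert below / total < 0.10


class TestFixtureSuite:
    def test_fixture_is_regenerable_byte_identical(self, fixture_dir, tmp_path):
        again = tmp_path / "again"
        paths = make_fixture_suite(again, seed=7)
        for name, p in paths.items():
            assert p.read_bytes() == (fixture_dir / p.name).read_bytes()

    def test_fixture_designed_coverage(self, fixture_dir):
        panel = g.read_panel(fixture_dir / "panel.tsv")
        matrix = g.read_genotypes(fixture_dir / "dosage.tsv", panel)
        truth = json.loads((fixture_dir / "truth.json").read_text())
        assert matrix.dosage.isna().sum().sum() >= 1
        mono = truth["designed"]["monomorphic_snp"]
        col = matrix.column(mono).dropna()
        assert col.nunique() == 1
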