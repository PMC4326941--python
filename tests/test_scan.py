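import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from leanscan import (
    ContingencyTable2x2,
    GeneticModel,
    PhenotypeTable,
    adjust_for_age,
    collapse_genotypes,
    fisher_exact_2x2,
    relative_risk,
    scan_panel,
    scan_thresholds,
)
from leanscan.io import MISSING
from leanscan.simulate import SimConfig, simulate_genotypes

from oracles import fisher_two_sided_oracle


class TestAdjustForAge:
    def test_constant_age_returns_trait_unchanged(self):
        ph = PhenotypeTable(pd.DataFrame(
            {"lean_mass_pct": [30.0, 35.0, 40.0], "age_years": [65.0] * 3},
            index=["a", "b", "c"]))
        assert adjust_for_age(ph).tolist() == [30.0, 35.0, 40.0]

    def test_perfectly_linear_trait_collapses_to_mean(self):
        ph = PhenotypeTable(pd.DataFrame(
            {"lean_mass_pct": [30.0, 32.0, 34.0, 36.0],
             "age_years": [50.0, 60.0, 70.0, 80.0]},
            index=list("abcd")))
        assert adjust_for_age(ph).to_numpy() == pytest.approx([33.0] * 4)

    def test_hand_computed_residuals(self):
        # trait 30,32,34,36 plus noise +1,-1,+1,-1; slope = 80/500 = 0.16;
        # residuals + mean = 33.4, 31.8, 34.2, 32.6 by hand OLS
        ph = PhenotypeTable(pd.DataFrame(
            {"lean_mass_pct": [31.0, 31.0, 35.0, 35.0],
             "age_years": [50.0, 60.0, 70.0, 80.0]},
            index=list("abcd")))
        assert adjust_for_age(ph).to_numpy() == pytest.approx(
            [33.4, 31.8, 34.2, 32.6])

    def test_identity_mode_and_minimum_sample(self):
        ph = PhenotypeTable(pd.DataFrame(
            {"lean_mass_pct": [31.0, 35.0], "age_years": [50.0, 80.0]},
            index=list("ab")))
        assert adjust_for_age(ph, mode="none").tolist() == [31.0, 35.0]
        with pytest.raises(ValueError, match="at least 3"):
            adjust_for_age(ph)


class TestCollapseGenotypes:
    def test_dominant_rule(self):
        labels = collapse_genotypes(np.array([0, 1, 2]),
                                    GeneticModel.DOMINANT_MINOR)
        assert labels.tolist() == [0, 1, 1]

    def test_recessive_rule(self):
        labels = collapse_genotypes(np.array([0, 1, 2]),
                                    GeneticModel.RECESSIVE_MINOR)
        assert labels.tolist() == [0, 0, 1]

    def test_missing_excluded(self):
        labels = collapse_genotypes(np.array([0, MISSING, 2]),
                                    GeneticModel.DOMINANT_MINOR)
        assert labels.tolist() == [0, -1, 1]


class TestFisherExact:
    def test_perfect_separation_4x4(self):
        assert fisher_exact_2x2(ContingencyTable2x2(4, 0, 0, 4)) == \
            pytest.approx(2 / 70, rel=1e-10)

    def test_enumeration_oracle_example(self):
        assert fisher_exact_2x2(ContingencyTable2x2(1, 9, 11, 3)) == \
            pytest.approx(fisher_two_sided_oracle(1, 9, 11, 3), abs=1e-12)
        assert fisher_exact_2x2(ContingencyTable2x2(1, 9, 11, 3)) == \
            pytest.approx(0.002759, abs=5e-7)

    def test_zero_margin_returns_one(self):
        assert fisher_exact_2x2(ContingencyTable2x2(0, 0, 5, 5)) == 1.0
        assert fisher_exact_2x2(ContingencyTable2x2(5, 0, 5, 0)) == 1.0

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(-1, 2, 3, 4)

    @settings(max_examples=200, derandomize=True)
    @given(st.tuples(st.integers(0, 25), st.integers(0, 25),
                     st.integers(0, 25), st.integers(0, 25)))
    def test_matches_oracle_on_random_tables(self, cells):
        a, b, c, d = cells
        p = fisher_exact_2x2(ContingencyTable2x2(a, b, c, d))
        assert p == pytest.approx(fisher_two_sided_oracle(a, b, c, d),
                                  abs=1e-10)
        assert 0.0 < p <= 1.0

    def test_agrees_with_scipy(self):
        from scipy.stats import fisher_exact as scipy_fisher
        rng = np.random.default_rng(3)
        for _ in range(100):
            a, b, c, d = (int(v) for v in rng.integers(0, 40, 4))
            ours = fisher_exact_2x2(ContingencyTable2x2(a, b, c, d))
            if (a + b) and (c + d) and (a + c) and (b + d):
                assert ours == pytest.approx(
                    scipy_fisher([[a, b], [c, d]])[1], rel=1e-9, abs=1e-12)


class TestRelativeRisk:
    def test_closed_form_example(self):
        rr = relative_risk(ContingencyTable2x2(30, 70, 50, 50))
        assert rr.rr == pytest.approx(0.6)
        assert rr.ci_low == pytest.approx(0.42, abs=0.005)
        assert rr.ci_high == pytest.approx(0.86, abs=0.005)
        assert not rr.corrected

    def test_equal_risks_give_unit_rr_symmetric_ci(self):
        rr = relative_risk(ContingencyTable2x2(8, 8, 8, 8))
        assert rr.rr == pytest.approx(1.0)
        assert rr.ci_low * rr.ci_high == pytest.approx(1.0)  # log-symmetric

    def test_haldane_correction_path(self):
        rr = relative_risk(ContingencyTable2x2(0, 10, 5, 5))
        assert rr.corrected
        assert rr.rr == pytest.approx((0.5 / 11) / (5.5 / 11))

    def test_zero_row_total_rejected(self):
        with pytest.raises(ValueError):
            relative_risk(ContingencyTable2x2(0, 0, 5, 5))


class TestScanThresholds:
    def test_perfect_separation(self):
        trait = np.array([10, 11, 12, 13, 1, 2, 3, 4], dtype=float)
        groups = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        r = scan_thresholds(trait, groups, min_group_cells=1)
        assert r.best_threshold == pytest.approx(7.0)
        assert r.min_p == pytest.approx(2 / 70, rel=1e-10)
        assert (r.table.a, r.table.b, r.table.c, r.table.d) == (0, 4, 4, 0)
        assert r.n_thresholds_tested == 7
        assert not r.degenerate

    def test_constant_trait_degenerate(self):
        r = scan_thresholds(np.full(10, 34.2), np.array([1] * 5 + [0] * 5))
        assert r.degenerate and r.min_p == 1.0

    def test_single_group_degenerate(self):
        r = scan_thresholds(np.arange(10.0), np.ones(10, dtype=int))
        assert r.degenerate

    def test_min_p_never_exceeds_median_split(self):
        rng = np.random.default_rng(21)
        for _ in range(30):
            n = int(rng.integers(20, 60))
            trait = rng.normal(34, 3.5, n)
            groups = (rng.random(n) < 0.4).astype(int)
            if groups.sum() < 2 or (1 - groups).sum() < 2:
                continue
            r = scan_thresholds(trait, groups, min_group_cells=1)
            k = int((trait < np.median(trait)).sum())
            a = int(((trait < np.median(trait)) & (groups == 1)).sum())
            m = int(groups.sum())
            table = ContingencyTable2x2(a, m - a, k - a, n - m - (k - a))
            assert r.min_p <= fisher_exact_2x2(table) + 1e-12

    def test_min_p_is_brute_force_minimum_over_midpoint_grid(self):
        rng = np.random.default_rng(8)
        for _ in range(25):
            n = int(rng.integers(15, 45))
            trait = np.round(rng.normal(34, 3.5, n), 1)  # ties likely
            groups = (rng.random(n) < 0.5).astype(int)
            if groups.sum() < 2 or n - groups.sum() < 2:
                continue
            mgc = int(rng.integers(1, 6))
            r = scan_thresholds(trait, groups, min_group_cells=mgc)
            sv = np.unique(trait)
            best = 1.0
            n_tested = 0
            for t in (sv[:-1] + sv[1:]) / 2:
                k = int((trait < t).sum())
                if k < mgc or n - k < mgc:
                    continue
                n_tested += 1
                a = int(((trait < t) & (groups == 1)).sum())
                m = int(groups.sum())
                p = fisher_exact_2x2(
                    ContingencyTable2x2(a, m - a, k - a, n - m - (k - a)))
                best = min(best, p)
            if n_tested == 0:
                assert r.degenerate
            else:
                assert r.n_thresholds_tested == n_tested
                assert r.min_p == pytest.approx(best, abs=1e-12)

    def test_swapping_group_labels_inverts_rr_keeps_p(self):
        rng = np.random.default_rng(4)
        trait = rng.normal(34, 3.5, 60)
        groups = (rng.random(60) < 0.45).astype(int)
        r1 = scan_thresholds(trait, groups)
        r2 = scan_thresholds(trait, 1 - groups)
        assert r1.min_p == pytest.approx(r2.min_p, rel=1e-12)
        assert r1.best_threshold == pytest.approx(r2.best_threshold)
        assert r1.rr.rr == pytest.approx(1.0 / r2.rr.rr, rel=1e-10)


class TestScanPanel:
    def test_one_snp_two_models_two_results(self):
        panel = simulate_genotypes(SimConfig(n_subjects=50, n_snps=1, seed=2))
        trait = np.random.default_rng(2).normal(34, 3.5, 50)
        results = scan_panel(panel, trait)
        assert len(results) == 2
        assert {r.model for r in results} == {GeneticModel.DOMINANT_MINOR,
                                              GeneticModel.RECESSIVE_MINOR}

    def test_planted_separating_snp_attains_panel_minimum(self):
        rng = np.random.default_rng(9)
        panel = simulate_genotypes(SimConfig(n_subjects=80, n_snps=20, seed=9))
        trait = rng.normal(34, 3.5, 80)
        # plant: carriers of SNP 0 (dominant) get a large positive shift
        carriers = collapse_genotypes(panel.calls[:, 0],
                                      GeneticModel.DOMINANT_MINOR) == 1
        trait = trait + 25 * carriers
        results = scan_panel(panel, trait,
                             models=[GeneticModel.DOMINANT_MINOR])
        best = min(results, key=lambda r: r.min_p)
        assert best.snp_id == panel.snp_ids[0]

    def test_subject_permutation_invariance(self):
        rng = np.random.default_rng(13)
        panel = simulate_genotypes(SimConfig(n_subjects=40, n_snps=5,
                                             missing_rate=0.05, seed=13))
        trait = rng.normal(34, 3.5, 40)
        perm = rng.permutation(40)
        permuted = panel.select_subjects(panel.subject_ids[perm])
        r1 = scan_panel(panel, trait)
        r2 = scan_panel(permuted, trait[perm])
        for x, y in zip(r1, r2):
            assert x.min_p == y.min_p
            assert x.degenerate == y.degenerate
            if not x.degenerate:
                assert x.best_threshold == y.best_threshold
                assert (x.table.a, x.table.b) == (y.table.a, y.table.b)
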