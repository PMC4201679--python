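"""Fold designs, corrected phenotypes and evaluation statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import gpcross as g
from gpcross.crossval import (
    accuracy,
    bias_regression,
    corrected_phenotypes,
    make_family_folds,
    make_random_folds,
    paired_t_test,
    power_correlation,
    _fit_predict,
)
from gpcross.lmm import ai_reml, design_from_phenotypes, solve_mme
from gpcross.popsim import Pedigree
from gpcross.relmat import pedigree_a_matrix


def _family_pedigree(sizes):
    """Synthetic pedigree with one half-sib F2 family per requested size."""
    rows = []
    for f in range(len(sizes)):
        rows.append((f"S{f}", "0", "0", "M", "F0", 0))
        rows.append((f"D{f}", "0", "0", "F", "F0", 0))
    k = 0
    for f, size in enumerate(sizes):
        for _ in range(size):
            rows.append((f"O{k:04d}", f"S{f}", f"D{f}", "MF"[k % 2], "F2", k % 4 + 1))
            k += 1
    return Pedigree(pd.DataFrame(rows, columns=["id", "sire", "dam", "sex", "generation", "hatch"]))


class TestRandomFolds:
    def test_reference_design_fold_sizes(self):
        plan = make_random_folds([f"i{j}" for j in range(511)], k=4, seed=0)
        assert plan.fold_sizes == [128, 128, 128, 127]
        assert plan.train_sizes == [383, 383, 383, 384]

    def test_divisible_case(self):
        plan = make_random_folds(list("abcdefgh"), k=4, seed=1)
        assert plan.fold_sizes == [2, 2, 2, 2]

    def test_folds_partition_ids(self):
        ids = [f"i{j}" for j in range(97)]
        plan = make_random_folds(ids, k=4, seed=3)
        union = sorted(sum((plan.test_ids(f) for f in range(4)), []))
        assert union == sorted(ids)
        for f in range(4):
            assert set(plan.test_ids(f)).isdisjoint(plan.train_ids(f))
            assert sorted(plan.test_ids(f) + plan.train_ids(f)) == sorted(ids)

    def test_empty_ids_rejected(self):
        with pytest.raises(ValueError):
            make_random_folds([], k=4)


class TestFamilyFolds:
    def test_eight_equal_families_give_two_per_fold(self):
        ped = _family_pedigree([64] * 8)
        plan = make_family_folds(ped, k=4)
        assert plan.fold_sizes == [128] * 4
        f2 = ped.table[ped.table["generation"] == "F2"].set_index("id")
        for f in range(4):
            sires = set(f2.loc[plan.test_ids(f), "sire"])
            assert len(sires) == 2

    def test_greedy_matches_exhaustive_partition_oracle(self):
        sizes = [70, 68, 66, 65, 64, 63, 60, 55]
        ped = _family_pedigree(sizes)
        plan = make_family_folds(ped, k=4)
        spread = max(plan.fold_sizes) - min(plan.fold_sizes)
        # exhaustive search over all 2-families-per-fold pairings
        best = None
        for perm in itertools.permutations(range(8)):
            pairs = sorted(tuple(sorted(perm[i : i + 2])) for i in (0, 2, 4, 6))
            totals = [sizes[a] + sizes[b] for a, b in pairs]
            s = max(totals) - min(totals)
            best = s if best is None else min(best, s)
        assert spread <= 8
        assert spread == best

    def test_no_test_individual_has_sibs_in_training(self, ref_population):
        ped = ref_population.pedigree
        plan = make_family_folds(ped, k=4)
        f2 = ped.table[ped.table["generation"] == "F2"].set_index("id")
        for f in range(4):
            test_parents = set(f2.loc[plan.test_ids(f), "sire"]) | set(
                f2.loc[plan.test_ids(f), "dam"]
            )
            train_parents = set(f2.loc[plan.train_ids(f), "sire"]) | set(
                f2.loc[plan.train_ids(f), "dam"]
            )
            assert test_parents.isdisjoint(train_parents)

    def test_fewer_families_than_folds_rejected(self):
        with pytest.raises(ValueError):
            make_family_folds(_family_pedigree([10, 10, 10]), k=4)


@pytest.fixture(scope="module")
def fit(small_population):
    pheno = small_population.phenotypes.for_trait("BW6")
    A = pedigree_a_matrix(small_population.pedigree)
    design = design_from_phenotypes(pheno)
    vc = ai_reml(design, A)
    return pheno, A, solve_mme(design, A, vc)


class TestCorrectedPhenotypes:

    def test_removing_fixed_noise_raises_signal_correlation(self, fit, small_population):
        """corr(y_c, TBV + e) >= corr(y, TBV + e): subtracting estimated
        sex/hatch effects removes non-genetic structure."""
        pheno, _, sol = fit
        y_c = corrected_phenotypes(pheno, sol)
        arch = small_population.architectures["BW6"]
        true_fixed = (
            pheno["sex"].map(arch.sex_effects).to_numpy()
            + np.array([arch.hatch_effects[(h - 1) % 4] for h in pheno["hatch"]])
        )
        target = pheno["y"].to_numpy() - true_fixed  # = mean + TBV + e
        r_raw = np.corrcoef(pheno["y"], target)[0, 1]
        r_corr = np.corrcoef(y_c.to_numpy(), target)[0, 1]
        assert r_corr >= r_raw

    def test_location_shift_passes_through(self, fit, small_population):
        pheno, A, sol = fit
        shifted = pheno.copy()
        shifted["y"] = shifted["y"] + 500.0
        design = design_from_phenotypes(shifted)
        sol2 = solve_mme(design, A, sol.vc)
        y_c1 = corrected_phenotypes(pheno, sol)
        y_c2 = corrected_phenotypes(shifted, sol2)
        np.testing.assert_allclose(y_c2.to_numpy() - y_c1.to_numpy(), 500.0, atol=1e-6)

    def test_unknown_factor_level_rejected(self, fit):
        pheno, _, sol = fit
        bad = pheno.copy()
        bad.loc[bad.index[0], "hatch"] = 99
        with pytest.raises(ValueError, match="level"):
            corrected_phenotypes(bad, sol)


class TestAccuracy:
    def test_perfect_and_inverted_agreement(self):
        x = np.array([0.3, -1.2, 2.0, 0.7])
        assert accuracy(x, x) == pytest.approx(1.0)
        assert accuracy(x, -x) == pytest.approx(-1.0)

    def test_hand_example(self):
        # deviations (-1.5,-0.5,0.5,1.5) vs (-0.5,-1.5,1.5,0.5):
        # covariance 3, each variance 5 -> r = 3/5
        assert accuracy([1, 2, 3, 4], [2, 1, 4, 3]) == pytest.approx(0.6)

    def test_zero_variance_is_an_explicit_error(self):
        with pytest.raises(ValueError, match="zero variance"):
            accuracy([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestBiasRegression:
    def test_identity_has_unit_slope(self):
        x = np.array([1.0, 2.0, 4.0, 8.0])
        assert bias_regression(x, x) == pytest.approx(1.0)

    def test_doubling_predictions_halves_slope(self, rng):
        yc = rng.standard_normal(50)
        pred = 0.5 * yc + rng.standard_normal(50) * 0.1
        assert bias_regression(yc, 2 * pred) == pytest.approx(
            bias_regression(yc, pred) / 2
        )

    def test_zero_variance_predictions_rejected(self):
        with pytest.raises(ValueError):
            bias_regression([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])


class TestPairedT:
    def test_identical_folds_give_null_result(self):
        res = paired_t_test([0.4, 0.5, 0.6, 0.3], [0.4, 0.5, 0.6, 0.3])
        assert res.t == 0.0 and res.p == 1.0

    def test_hand_example(self):
        """d = (0.02, 0.04, 0.01, 0.03): dbar = 0.025, S_D ~ 0.01291,
        t = dbar / (S_D / sqrt(4)) ~ 3.873 on 3 df."""
        a = np.array([0.52, 0.54, 0.51, 0.53])
        res = paired_t_test(a, a - np.array([0.02, 0.04, 0.01, 0.03]))
        assert res.d_bar == pytest.approx(0.025)
        assert res.s_d == pytest.approx(0.012909944, abs=1e-8)
        assert res.t == pytest.approx(3.8729833, abs=1e-6)
        assert res.df == 3
        assert res.p == pytest.approx(0.030466, abs=1e-4)

    @given(
        st.lists(st.floats(-0.9, 0.9), min_size=3, max_size=8),
        st.integers(0, 10_000),
    )
    @settings(max_examples=50, deadline=None)
    def test_antisymmetry(self, vals, salt):
        a = np.asarray(vals)
        b = np.asarray(vals) * 0.9 + np.sin(salt + np.arange(len(vals)))
        if np.std(a - b, ddof=1) == 0:
            return
        fwd = paired_t_test(a, b)
        rev = paired_t_test(b, a)
        assert fwd.t == pytest.approx(-rev.t, rel=1e-12, abs=1e-12)
        assert fwd.p == pytest.approx(rev.p, rel=1e-12, abs=1e-12)

    def test_degenerate_spread_with_nonzero_mean_rejected(self):
        with pytest.raises(ValueError):
            paired_t_test([0.5, 0.6], [0.4, 0.5])


class TestPower:
    def test_null_correlation_power_equals_alpha(self):
        assert power_correlation(0.0, 100) == pytest.approx(0.05, abs=1e-12)
        assert power_correlation(0.0, 50, alpha=0.1) == pytest.approx(0.1, abs=1e-12)

    def test_monotone_in_n_and_r(self):
        assert power_correlation(0.3, 128) < power_correlation(0.3, 256)
        assert power_correlation(0.2, 128) < power_correlation(0.4, 128)

    def test_against_monte_carlo_oracle(self):
        """Fisher-z power for r = 0.3, n = 128 agrees with 50,000 simulated
        bivariate-normal experiments tested at alpha = 0.05."""
        from scipy import stats

        rho, n, reps = 0.3, 128, 50_000
        rng = np.random.default_rng(64)
        x = rng.standard_normal((reps, n))
        y = rho * x + np.sqrt(1 - rho**2) * rng.standard_normal((reps, n))
        xc = x - x.mean(1, keepdims=True)
        yc = y - y.mean(1, keepdims=True)
        r = (xc * yc).sum(1) / np.sqrt((xc**2).sum(1) * (yc**2).sum(1))
        t = r * np.sqrt((n - 2) / (1 - r**2))
        crit = stats.t.ppf(0.975, n - 2)
        mc_power = float((np.abs(t) > crit).mean())
        assert power_correlation(rho, n) == pytest.approx(mc_power, abs=0.02)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            power_correlation(1.0, 100)
        with pytest.raises(ValueError):
            power_correlation(0.5, 3)


class TestPooling:
    def test_pooled_correlation_is_not_mean_of_fold_correlations(self):
        """Constructed counterexample: per-fold correlations are perfect
        but fold-specific offsets destroy the pooled correlation."""
        rng = np.random.default_rng(8)
        preds, ycs, fold_rs = [], [], []
        for f in range(4):
            p = rng.standard_normal(50)
            yc = p + 100.0 * (-1) ** f  # perfect within fold, offset between
            fold_rs.append(accuracy(p, yc))
            preds.append(p)
            ycs.append(yc)
        pooled = accuracy(np.concatenate(preds), np.concatenate(ycs))
        assert np.mean(fold_rs) == pytest.approx(1.0)
        assert pooled < 0.2


class TestStudyDriver:
    def test_masked_phenotypes_cannot_leak_into_predictions(self, small_population):
        """Randomizing held-out phenotypes leaves every model's
        predictions unchanged: fits see training records only."""
        from gpcross.qc import filter_snps, impute_missing
        from gpcross.relmat import genomic_g_matrix

        pop = small_population
        pheno = pop.phenotypes.for_trait("BW6")
        plan = make_family_folds(pop.pedigree, k=4)
        test_ids = plan.test_ids(0)
        train = pheno[~pheno["id"].isin(test_ids)].reset_index(drop=True)
        geno = impute_missing(filter_snps(pop.genotypes, 0.95, 0.01)[0])
        A = pedigree_a_matrix(pop.pedigree)
        G = genomic_g_matrix(geno)
        from gpcross.wgr import MCMCConfig

        cfg = MCMCConfig(600, 200, 2)
        # masking by exclusion: scrambling the held-out phenotypes before
        # the exclusion step must leave every prediction bit-identical
        scrambled = pheno.copy()
        mask = scrambled["id"].isin(test_ids)
        scrambled.loc[mask, "y"] = np.random.default_rng(0).normal(0, 1e6, mask.sum())
        train2 = scrambled[~scrambled["id"].isin(test_ids)].reset_index(drop=True)
        for model in ("blup", "gblup", "lasso", "mix4"):
            p1 = _fit_predict(model, train, test_ids, A, G, geno, cfg, chain_seed=5)
            p2 = _fit_predict(model, train2, test_ids, A, G, geno, cfg, chain_seed=5)
            np.testing.assert_array_equal(p1, p2)

    def test_report_is_deterministic_for_a_seed(self):
        from gpcross.wgr import MCMCConfig

        pop = g.simulate_population(n_snps=150, n_f2=80, n_f1=16, n_sires_f1=4, seed=55)
        kwargs = dict(
            traits=["BW6"], models=("blup", "lasso"), scenarios=("random",),
            mcmc=MCMCConfig(400, 100, 2), seed=9,
        )
        r1 = g.run_study(pop, **kwargs)
        r2 = g.run_study(pop, **kwargs)
        pd.testing.assert_frame_equal(r1.records, r2.records)
        pd.testing.assert_frame_equal(r1.paired_tests, r2.paired_tests)

    def test_unknown_model_rejected(self, small_population):
        with pytest.raises(ValueError):
            g.run_study(small_population, models=("blup", "krige"))
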