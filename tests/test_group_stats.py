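"""Mass-univariate contrasts, blueprints, symmetry, and tail summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dfcprint import (ProfileCohort, age_matched_subsets, blueprint,
                      bonferroni_threshold, case_control_comparison,
                      category_contrast, mass_ttest, mirror_correlation,
                      percentile_subsets, region_incidence,
                      simulate_profile_cohort)
from dfcprint.errors import InsufficientDataError


class TestBonferroni:
    @pytest.mark.parametrize("m, expected", [
        (132_825, 3.76e-7),
        (41_616, 1.20e-6),
    ])
    def test_published_thresholds(self, m, expected):
        assert bonferroni_threshold(0.05, m) == pytest.approx(expected, rel=5e-3)

    def test_single_comparison(self):
        assert bonferroni_threshold(0.05, 1) == 0.05

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.0, 10)
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)


class TestAgeMatching:
    def test_balanced_cohort_keeps_everyone(self):
        meta = pd.DataFrame({"age": [50, 51, 60, 61], "sex": ["F", "M", "F", "M"]})
        subsets = age_matched_subsets(meta, "sex", n_repeats=5, seed=0)
        for s in subsets:
            assert np.array_equal(s, np.arange(4))

    def test_unbalanced_bin_downsampled(self):
        meta = pd.DataFrame({
            "age": [52.0] * 22,
            "sex": ["M"] * 10 + ["F"] * 12,
        })
        subsets = age_matched_subsets(meta, "sex", n_repeats=20, seed=1)
        kept_f = {tuple(s[np.isin(s, np.arange(10, 22))]) for s in subsets}
        for s in subsets:
            assert np.sum(s < 10) == 10 and np.sum(s >= 10) == 10
        assert len(kept_f) > 1  # the excluded females vary across repeats

    def test_confounded_ages_are_balanced_after_matching(self):
        rng = np.random.default_rng(2)
        n = 120
        sex = np.array(["F", "M"])[np.arange(n) % 2]
        age = np.where(sex == "F", rng.normal(55, 6, n), rng.normal(65, 6, n))
        meta = pd.DataFrame({"age": age, "sex": sex})
        pooled_sd = age.std()
        subsets = age_matched_subsets(meta, "sex", n_repeats=100, seed=3)
        ok = 0
        for s in subsets:
            f = age[s][sex[s] == "F"].mean()
            m = age[s][sex[s] == "M"].mean()
            ok += abs(f - m) < 0.2 * pooled_sd
        assert ok >= 95

    def test_single_level_rejected(self):
        meta = pd.DataFrame({"age": [50, 60], "sex": ["F", "F"]})
        with pytest.raises(InsufficientDataError):
            age_matched_subsets(meta, "sex")


class TestMassTTest:
    def test_identical_groups_nothing_significant(self):
        cohort = simulate_profile_cohort(40, 500, noise_sd=0.05, seed=4)
        diff = mass_ttest(cohort.profiles["alpha1"], cohort.meta, "sex",
                          n_comparisons=26_565)
        assert diff.n_significant == 0

    def test_planted_shift_recovered(self):
        cohort = simulate_profile_cohort(
            120, 2000, noise_sd=0.05, effect_indices=np.arange(100),
            effect_size=0.15, seed=5)
        diff = mass_ttest(cohort.profiles["alpha1"], cohort.meta, "sex",
                          n_comparisons=26_565)
        assert diff.significant[:100].sum() >= 95
        assert diff.significant[100:].sum() == 0
        # direction: first level (F) is higher on planted coefficients
        assert np.all(diff.delta[:100] > 0)

    def test_t_statistic_matches_hand_calculation(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([2.0, 3.0, 4.0, 7.0])
        meta = pd.DataFrame({"sex": ["F"] * 4 + ["M"] * 4,
                             "age": [50.0] * 8})
        X = np.concatenate([a, b])[:, None]
        diff = mass_ttest(X, meta, "sex")
        t_exp, p_exp = stats.ttest_ind(a, b, equal_var=False)
        assert diff.t_values[0] == pytest.approx(t_exp, abs=1e-12)
        assert diff.p_values[0] == pytest.approx(p_exp, abs=1e-12)
        assert diff.delta[0] == pytest.approx(a.mean() - b.mean())

    def test_matched_subset_count_reported(self):
        cohort = simulate_profile_cohort(
            60, 300, noise_sd=0.05, effect_indices=np.arange(20),
            effect_size=0.2, seed=6)
        subsets = age_matched_subsets(cohort.meta, "sex", n_repeats=10, seed=7)
        diff = mass_ttest(cohort.profiles["alpha1"], cohort.meta, "sex",
                          matched_subsets=subsets)
        assert diff.n_significant_matched is not None
        assert diff.n_significant_matched >= 15

    def test_familywise_null_rate_controlled(self):
        """Across simulated null cohorts, any-flag frequency stays near alpha."""
        rng = np.random.default_rng(8)
        flags = 0
        n_runs = 60
        for k in range(n_runs):
            cohort = simulate_profile_cohort(40, 2000, noise_sd=0.05,
                                             seed=int(rng.integers(2**31)))
            diff = mass_ttest(cohort.profiles["alpha1"], cohort.meta, "sex")
            flags += diff.n_significant > 0
        rate = flags / n_runs
        se = np.sqrt(0.05 * 0.95 / n_runs)
        assert rate <= 0.05 + 3 * se


class TestBlueprint:
    def _cohort(self, X, ages=None, sexes=None):
        n = X.shape[0]
        meta = pd.DataFrame({
            "id": [f"S{i}" for i in range(n)],
            "age": ages if ages is not None else np.full(n, 55.0),
            "sex": sexes if sexes is not None else ["F", "M"] * (n // 2),
        })
        return ProfileCohort(meta, {"alpha1": X})

    def test_identical_profiles_returned_exactly(self):
        v = np.linspace(-0.5, 0.5, 50)
        bp = blueprint(self._cohort(np.tile(v, (6, 1))), "alpha1",
                       n_resamples=20, seed=0)
        np.testing.assert_allclose(bp.mean, v, atol=1e-12)

    def test_two_subject_mean(self):
        X = np.array([[0.0, 1.0], [1.0, 0.0]])
        bp = blueprint(self._cohort(X, sexes=["F", "F"]), "alpha1",
                       n_resamples=5, seed=1)
        np.testing.assert_allclose(bp.mean, [0.5, 0.5])

    def test_resampled_mean_close_to_plain_mean_when_balanced(self):
        rng = np.random.default_rng(9)
        X = rng.normal(0, 0.02, size=(40, 300))
        cohort = self._cohort(X, ages=np.full(40, 60.0))
        bp = blueprint(cohort, "alpha1", n_resamples=50, seed=2)
        np.testing.assert_allclose(bp.mean, X.mean(axis=0), atol=1e-3)


class TestMirrorAndTails:
    def test_symmetric_profile_correlates_to_one(self, parc):
        rng = np.random.default_rng(10)
        v = rng.normal(size=parc.n_coefficients)
        sym = (v + parc.mirror(v)) / 2
        assert mirror_correlation(sym, parc) == pytest.approx(1.0)

    def test_antisymmetric_profile_correlates_to_minus_one(self, parc):
        rng = np.random.default_rng(11)
        v = rng.normal(size=parc.n_coefficients)
        anti = v - parc.mirror(v)  # mirror flips its sign about 0
        fixed = parc.coefficient_mirror == np.arange(parc.n_coefficients)
        anti[fixed] = 0.0
        if np.ptp(anti) > 0:
            assert mirror_correlation(anti, parc) == pytest.approx(-1.0)

    def test_random_profile_matches_permutation_oracle(self, parc):
        """corr(v, v[perm]) must equal the brute-force formula on the
        permuted copy (independent evaluation, no corrcoef)."""
        rng = np.random.default_rng(12)
        v = rng.normal(size=parc.n_coefficients)
        w = v[parc.coefficient_mirror]
        num = np.sum((v - v.mean()) * (w - w.mean()))
        den = np.sqrt(np.sum((v - v.mean()) ** 2) * np.sum((w - w.mean()) ** 2))
        assert mirror_correlation(v, parc) == pytest.approx(num / den, abs=1e-12)

    def test_constant_vector_undefined(self, parc):
        with pytest.warns(UserWarning):
            assert np.isnan(mirror_correlation(np.ones(parc.n_coefficients), parc))

    def test_percentile_tails_nearest_rank(self):
        bottom, top = percentile_subsets(np.arange(1.0, 101.0), 1, 99)
        assert bottom.tolist() == [0]
        assert top.tolist() == [99]

    def test_percentile_tail_sizes(self):
        rng = np.random.default_rng(13)
        bottom, top = percentile_subsets(rng.normal(size=26_565))
        assert bottom.size == 266 == top.size

    def test_constant_vector_degenerates_with_warning(self):
        with pytest.warns(UserWarning):
            bottom, top = percentile_subsets(np.ones(100))
        assert bottom.size == top.size == 100


class TestRegionIncidence:
    def test_single_three_region_coefficient(self, parc):
        # edges L.FP-L.FM and L.FM-L.FL share L.FM
        e1 = parc.edge_index(0, 1)
        e2 = parc.edge_index(1, 2)
        k = parc.coefficient_index(e1, e2)
        inc = region_incidence(np.array([k]), parc)
        # L occurrences averaged with (zero) R occurrences
        assert inc.loc["FP", "three_region"] == 0.5
        assert inc.loc["FM", "three_region"] == 0.5
        assert inc.loc["FL", "three_region"] == 0.5
        assert inc["four_region"].sum() == 0

    def test_empty_subset_all_zero(self, parc):
        inc = region_incidence(np.array([], dtype=int), parc)
        assert (inc.to_numpy() == 0).all()

    def test_full_set_matches_exhaustive_count(self, parc):
        """Every region partakes in the same number of coefficients; check
        the total region slots by brute-force accounting."""
        inc = region_incidence(np.arange(parc.n_coefficients), parc)
        # total region slots = 3*4620 + 4*21945; averaged over 2 hemispheres
        assert inc.to_numpy().sum() == pytest.approx((3 * 4620 + 4 * 21945) / 2)
        # symmetry: all 11 names get identical counts
        totals = inc.sum(axis=1)
        assert np.allclose(totals, totals.iloc[0])


class TestCategoryContrast:
    def test_planted_three_region_dominance(self, parc):
        rng = np.random.default_rng(14)
        v = np.where(parc.coef_n_regions == 3, 0.3, 0.1)
        v = v + rng.normal(0, 0.02, size=v.size)
        out = category_contrast(v, parc)
        assert out["three_vs_four"]["t"] > 0
        assert out["three_vs_four"]["p"] < 1e-3
        assert out["three_vs_four"]["n"] == (4620, 21945)

    def test_identical_category_means_give_small_t(self, parc):
        rng = np.random.default_rng(15)
        v = rng.normal(0, 0.05, size=parc.n_coefficients)
        out = category_contrast(v, parc)
        assert abs(out["three_vs_four"]["t"]) < 3


class TestCaseControl:
    def test_mask_restricts_comparisons(self):
        cohort = simulate_profile_cohort(
            80, 600, noise_sd=0.05, effect_indices=np.arange(30),
            effect_size=0.2, factor="group", levels=("PD", "HC"), seed=16)
        gender_p = np.ones(600)
        gender_p[:10] = 0.01  # sensitive coefficients excluded from the test
        diff = case_control_comparison(cohort.profiles["alpha1"], cohort.meta,
                                       gender_p)
        assert diff.threshold == pytest.approx(0.05 / 590)
        assert diff.coefficient_indices.min() == 10
        # planted PD-vs-HC effect on indices 10..29 recovered; delta = HC - PD < 0
        hits = diff.significant[:20]
        assert hits.sum() >= 18
        assert np.all(diff.delta[:20][hits] < 0)

    def test_identical_groups_nothing_significant(self):
        cohort = simulate_profile_cohort(40, 300, noise_sd=0.05,
                                         factor="group", levels=("PD", "HC"),
                                         seed=17)
        diff = case_control_comparison(cohort.profiles["alpha1"], cohort.meta,
                                       np.ones(300))
        assert diff.n_significant == 0

    def test_empty_mask_rejected(self):
        cohort = simulate_profile_cohort(20, 50, factor="group",
                                         levels=("PD", "HC"), seed=18)
        with pytest.raises(InsufficientDataError):
            case_control_comparison(cohort.profiles["alpha1"], cohort.meta,
                                    np.zeros(50))
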