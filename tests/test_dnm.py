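"""Poisson parental-age model: filters, MLE, bootstrap, predictions."""

import numpy as np
import pandas as pd
import pytest

import mutspectra as ms
from mutspectra.dnm import trio_phased_fractions
from mutspectra.simulate import TrioScenario, simulate_trio_dataset


def wide_trios(father_ages, mother_ages, yp, ym, yu, ids=None):
    n = len(father_ages)
    return pd.DataFrame(
        {
            "trio_id": ids if ids is not None else np.arange(n),
            "father_age": father_ages,
            "mother_age": mother_ages,
            "phased_paternal": yp,
            "phased_maternal": ym,
            "unphased": yu,
        }
    )


class TestTrioFilters:
    def test_maternal_age_boundary(self):
        trios = wide_trios([30, 30, 30], [41, 40, 39], [1] * 3, [1] * 3, [1] * 3)
        kept = ms.apply_trio_filters(trios)
        assert kept["mother_age"].tolist() == [40, 39]

    def test_outlier_ids_removed(self):
        trios = wide_trios([30, 31], [30, 30], [1, 1], [1, 1], [1, 1],
                           ids=["a", "b"])
        kept = ms.apply_trio_filters(trios, outlier_ids=["b"])
        assert kept["trio_id"].tolist() == ["a"]


class TestFit:
    def test_recovers_simulated_parameters(self, single_class_trios):
        truth, trios = single_class_trios
        model = ms.ParentalAgeModel(random_state=0).fit(trios)
        boot = ms.bootstrap_effects(trios, n_reps=80, seed=5)
        se = boot.standard_errors()
        assert abs(model.alpha_p_ - truth.alpha_p) < 3 * se["alpha_p"]
        assert abs(model.beta_p_ - truth.beta_p) < 3 * se["beta_p"]
        assert abs(model.alpha_m_ - truth.alpha_m) < 3 * se["alpha_m"]
        assert abs(model.beta_m_ - truth.beta_m) < 3 * se["beta_m"]

    def test_all_zero_counts_boundary_mle(self):
        trios = wide_trios([20, 30, 40], [19, 29, 39], [0] * 3, [0] * 3, [0] * 3)
        model = ms.ParentalAgeModel().fit(trios)
        assert (model.alpha_p_, model.beta_p_, model.alpha_m_, model.beta_m_) == (
            0.0, 0.0, 0.0, 0.0,
        )

    def test_identical_ages_unidentifiable(self):
        trios = wide_trios([30] * 5, [28] * 5, [3] * 5, [1] * 5, [4] * 5)
        with pytest.raises(ValueError, match="unidentifiable"):
            ms.ParentalAgeModel().fit(trios)

    def test_mle_beats_truth_on_most_datasets(self):
        """The maximized likelihood is at least the likelihood at the true
        parameters on nearly all synthetic datasets."""
        truth = ms.ParentalAgeEffect("x", 7.6, 1.35, 2.0, 0.4)
        wins = 0
        n_datasets = 20
        for seed in range(n_datasets):
            trios = simulate_trio_dataset(
                TrioScenario(n_trios=3000, effects={"x": truth},
                             phased_fraction=0.4, seed=100 + seed)
            )
            model = ms.ParentalAgeModel().fit(trios)
            wins += model.loglik_ >= model.loglik(trios, truth) - 1e-6
        assert wins >= 0.95 * n_datasets

    def test_slope_signs_recovered(self, single_class_trios):
        _, trios = single_class_trios
        model = ms.ParentalAgeModel().fit(trios)
        assert model.beta_p_ > 0 and model.beta_m_ > 0

    def test_phased_fraction_pooled_per_trio(self):
        trios = pd.concat(
            [
                wide_trios([20, 40], [20, 40], [2, 4], [1, 1], [3, 5]).assign(
                    mutation_class="A"
                ),
                wide_trios([20, 40], [20, 40], [0, 2], [1, 1], [1, 1]).assign(
                    mutation_class="B"
                ),
            ]
        )
        phi = trio_phased_fractions(trios)
        assert phi.loc[0] == pytest.approx((2 + 1 + 0 + 1) / 8)
        assert phi.loc[1] == pytest.approx((4 + 1 + 2 + 1) / 14)


class TestPredictRatio:
    def test_identity(self):
        e = ms.ParentalAgeEffect("x", 7.6, 1.35, 2.0, 0.4)
        for g in (15, 30, 45):
            assert ms.predict_ratio(e, e, g, g) == 1.0

    def test_arithmetic(self):
        e1 = ms.ParentalAgeEffect("a", 5.0, 1.0, 3.0, 0.5)
        e2 = ms.ParentalAgeEffect("b", 5.0, 0.5, 3.0, 0.25)
        assert ms.predict_ratio(e1, e2, 30, 30) == pytest.approx(53 / 30.5)

    def test_invariant_to_common_rescaling(self):
        e1 = ms.ParentalAgeEffect("a", 5.0, 1.0, 3.0, 0.5)
        e2 = ms.ParentalAgeEffect("b", 5.0, 0.5, 3.0, 0.25)
        s = 3.7
        e1s = ms.ParentalAgeEffect("a", 5.0 * s, 1.0 * s, 3.0 * s, 0.5 * s)
        e2s = ms.ParentalAgeEffect("b", 5.0 * s, 0.5 * s, 3.0 * s, 0.25 * s)
        assert ms.predict_ratio(e1, e2, 25, 32) == pytest.approx(
            ms.predict_ratio(e1s, e2s, 25, 32), rel=1e-12
        )

    def test_ratio_decreases_when_parents_older(self):
        """A numerator class with weaker age dependence than its denominator
        yields a lower ratio at (40, 40) than at (20, 20)."""
        e1 = ms.ParentalAgeEffect("a", 8.0, 0.10, 3.0, 0.03)
        e2 = ms.ParentalAgeEffect("b", 1.0, 0.12, 0.4, 0.04)
        assert ms.predict_ratio(e1, e2, 40, 40) < ms.predict_ratio(e1, e2, 20, 20)


class TestBootstrap:
    def test_seeded_determinism(self, single_class_trios):
        _, trios = single_class_trios
        sample = trios.iloc[:500]
        b1 = ms.bootstrap_effects(sample, n_reps=5, seed=9)
        b2 = ms.bootstrap_effects(sample, n_reps=5, seed=9)
        pd.testing.assert_frame_equal(b1.replicates, b2.replicates)

    def test_single_replicate_ci_collapses(self, single_class_trios):
        _, trios = single_class_trios
        boot = ms.bootstrap_effects(trios.iloc[:300], n_reps=1, seed=2)
        ci = boot.percentile_ci()
        assert np.allclose(ci.loc["ci_lower"], ci.loc["ci_upper"])


class TestQuintileCpGTest:
    @staticmethod
    def cpg_trios(num_effect, den_effect, n=3000, seed=0):
        scenario = TrioScenario(
            n_trios=n,
            effects={"C>T_CpG": num_effect, "C>A_CpG": den_effect},
            phased_fraction=0.4,
            seed=seed,
        )
        return simulate_trio_dataset(scenario)

    def test_age_independent_spectrum_shows_no_contrast(self):
        # both classes scale identically with age -> constant expected ratio
        num = ms.ParentalAgeEffect("C>T_CpG", 8.0, 0.4, 3.0, 0.1)
        den = ms.ParentalAgeEffect("C>A_CpG", 0.8, 0.04, 0.3, 0.01)
        trios = self.cpg_trios(num, den, seed=21)
        ratio_young, ratio_old, _ = ms.quintile_cpg_ratio_test(trios)
        assert ratio_young == pytest.approx(ratio_old, rel=0.15)

    def test_declining_cpg_fraction_detected(self):
        # numerator nearly age-flat, denominator age-increasing:
        # the C>T/C>A ratio at CpG sites declines with parental age
        num = ms.ParentalAgeEffect("C>T_CpG", 14.0, 0.05, 5.0, 0.02)
        den = ms.ParentalAgeEffect("C>A_CpG", 0.2, 0.03, 0.1, 0.015)
        trios = self.cpg_trios(num, den, seed=22)
        ratio_young, ratio_old, p = ms.quintile_cpg_ratio_test(trios)
        assert ratio_young > ratio_old
        assert p < 0.05
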