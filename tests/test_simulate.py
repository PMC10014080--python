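"""Synthetic variant and trio generators."""

import numpy as np
import pandas as pd
import pytest

import mutspectra as ms
from mutspectra.classes import classify_table


def uniform_fractions(labels):
    return {c: 1.0 / len(labels) for c in labels}


class TestSpectrumScenario:
    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            ms.Epoch(0, 100, {"T>A": 0.5, "C>G": 0.4})

    def test_epochs_must_not_overlap(self):
        fr = uniform_fractions(["T>A", "C>G"])
        with pytest.raises(ValueError, match="overlap"):
            ms.SpectrumScenario(
                epochs=[ms.Epoch(0, 100, fr), ms.Epoch(50, 200, fr)], n_variants=10
            )

    def test_empty_epochs_rejected(self):
        with pytest.raises(ValueError):
            ms.SpectrumScenario(epochs=[], n_variants=10)


class TestVariantGenerator:
    def scenario(self, **kwargs):
        defaults = dict(
            epochs=[ms.Epoch(0.0, 1000.0, {"T>A": 0.10, "C>G": 0.90})],
            n_variants=1000,
            seed=1,
        )
        defaults.update(kwargs)
        return ms.SpectrumScenario(**defaults)

    def test_seeded_determinism_byte_identical(self, tmp_path):
        t1 = ms.simulate_variant_dataset(self.scenario())
        t2 = ms.simulate_variant_dataset(self.scenario())
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        t1.to_csv(p1, sep="\t", index=False)
        t2.to_csv(p2, sep="\t", index=False)
        assert p1.read_bytes() == p2.read_bytes()

    def test_class_fractions_match_binomial_oracle(self):
        n = 100_000
        table = ms.simulate_variant_dataset(self.scenario(n_variants=n, seed=2))
        frac = (table["true_class"] == "T>A").mean()
        assert abs(frac - 0.10) <= 3 * np.sqrt(0.1 * 0.9 / n)

    def test_interval_contains_true_age(self):
        table = ms.simulate_variant_dataset(self.scenario(n_variants=5000, seed=3))
        assert (table["age_lower"] <= table["true_age"]).all()
        assert (table["true_age"] <= table["age_upper"]).all()
        assert (table["age_lower"] >= 0).all()

    def test_contexts_consistent_with_classes(self):
        table = ms.simulate_variant_dataset(
            self.scenario(
                n_variants=4000,
                epochs=[
                    ms.Epoch(
                        0.0,
                        1000.0,
                        uniform_fractions(
                            ["C>T_CpG", "C>T_nonCpG", "T>C_TpG", "T>C_nonTpG"]
                        ),
                    )
                ],
                seed=4,
            )
        )
        classified = classify_table(table)
        assert (classified["mutation_class"] == classified["true_class"]).all()

    def test_epoch_presence_probabilities(self):
        fr = uniform_fractions(["T>A", "C>G"])
        scenario = ms.SpectrumScenario(
            epochs=[ms.Epoch(0, 100, fr), ms.Epoch(100, 200, fr)],
            n_variants=20_000,
            populations={"A": [1.0, 1.0], "B": [1.0, 0.0]},
            seed=5,
        )
        table = ms.simulate_variant_dataset(scenario)
        old = table["true_age"] >= 100
        assert table["A"].all()
        # epoch-0 variants present in B; epoch-1 ones only via orphan rescue
        assert table.loc[~old, "B"].mean() > 0.99
        assert table.loc[old, "B"].mean() < 0.05

    def test_step_scenario_shifts_downstream_ratio(self):
        """A doubling of the C>G fraction in the recent epoch produces a step
        in the binned C>G/T>A ratio exceeding the older bins' 95% CIs."""
        old = {"C>G": 0.2, "T>A": 0.2, "C>A": 0.6}
        recent = {"C>G": 0.4, "T>A": 0.2, "C>A": 0.4}
        scenario = ms.SpectrumScenario(
            epochs=[ms.Epoch(0, 500, recent), ms.Epoch(500, 3000, old)],
            n_variants=60_000,
            interval_halfwidth_median=0.1,
            interval_halfwidth_sigma=0.3,
            seed=6,
        )
        table = classify_table(ms.simulate_variant_dataset(scenario))
        binner = ms.AgeBinner(n_bins=6, random_state=0).fit(table)
        counts = ms.build_pseudocount_table(table, binner)
        ests = [
            ms.ratio_with_ci(counts.loc["C>G", b], counts.loc["T>A", b])
            for b in counts.columns
        ]
        # 1/6 of the mass is recent (epoch durations 500 vs 2500), so the
        # first of six equal-occupancy bins sits inside the recent epoch
        assert binner.boundaries_[1] <= 550
        recent_bins = [0]
        old_bins = [b for b in counts.columns if binner.boundaries_[b] >= 600]
        assert old_bins
        worst_recent = min(ests[b].ci_lower for b in recent_bins)
        best_old = max(ests[b].ci_upper for b in old_bins)
        assert worst_recent > best_old  # the step clears both 95% CIs


class TestTrioGenerator:
    def test_zero_slopes_give_age_independent_counts(self):
        eff = ms.ParentalAgeEffect("x", 7.6, 0.0, 2.0, 0.0)
        trios = ms.simulate_trio_dataset(
            ms.TrioScenario(n_trios=8000, effects={"x": eff},
                            phased_fraction=0.5, seed=7)
        )
        total = trios["phased_paternal"] + trios["phased_maternal"] + trios["unphased"]
        age = trios["father_age"].to_numpy()
        slope, intercept = np.polyfit(age, total, 1)
        resid = total - (slope * age + intercept)
        se = np.sqrt(np.sum(resid**2) / (len(age) - 2) / np.sum((age - age.mean()) ** 2))
        assert abs(slope) <= 3 * se

    def test_poisson_mean_oracle(self):
        eff = ms.ParentalAgeEffect("x", 7.6, 1.35, 0.0, 0.0)
        n = 10_000
        trios = ms.simulate_trio_dataset(
            ms.TrioScenario(n_trios=n, effects={"x": eff},
                            father_age_mean=30.0, father_age_sd=1e-9,
                            phased_fraction=1.0, seed=8)
        )
        mean_pat = trios["phased_paternal"].mean()
        assert abs(mean_pat - 48.1) <= 3 * np.sqrt(48.1 / n)

    def test_unphased_boundary(self):
        eff = ms.ParentalAgeEffect("x", 7.6, 1.35, 2.0, 0.4)
        trios = ms.simulate_trio_dataset(
            ms.TrioScenario(n_trios=500, effects={"x": eff},
                            phased_fraction=0.0, seed=9)
        )
        assert (trios["phased_paternal"] == 0).all()
        assert (trios["phased_maternal"] == 0).all()
        assert (trios["unphased"] > 0).any()

    def test_negative_mean_rejected(self):
        eff = ms.ParentalAgeEffect("x", -100.0, 1.0, 2.0, 0.4)
        with pytest.raises(ValueError, match="negative predicted mean"):
            ms.simulate_trio_dataset(
                ms.TrioScenario(n_trios=10, effects={"x": eff}, seed=0)
            )

    def test_ages_within_reproductive_range(self, decode_effects):
        trios = ms.simulate_trio_dataset(
            ms.TrioScenario(n_trios=2000, effects=decode_effects, seed=10)
        )
        assert trios["father_age"].between(10, 60).all()
        assert trios["mother_age"].between(10, 60).all()

    def test_phasing_conserves_totals(self, decode_effects):
        """Totals equal phased-paternal + phased-maternal + unphased exactly
        by construction; phased share concentrates around the configured
        fraction."""
        trios = ms.simulate_trio_dataset(
            ms.TrioScenario(n_trios=4000, effects=decode_effects,
                            phased_fraction=0.4, seed=11)
        )
        phased = trios["phased_paternal"] + trios["phased_maternal"]
        total = phased + trios["unphased"]
        assert (total >= phased).all()
        assert phased.sum() / total.sum() == pytest.approx(0.4, abs=0.01)
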