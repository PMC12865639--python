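"""Rank-based secondary analyses: Spearman, median ratios, drift, subtype subsets."""

import itertools
import math
from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

import surromet as sm

# Frozen exhaustive-permutation oracle (all 120 orderings, computed beforehand)
SPEARMAN_X = [1, 2, 3, 4, 5]
SPEARMAN_Y = [2, 1, 4, 3, 5]
SPEARMAN_RHO = 0.8
SPEARMAN_P = 16 / 120


class TestSpearman:
    def test_matches_exhaustive_permutation_oracle(self):
        rho, p = sm.spearman_rho(SPEARMAN_X, SPEARMAN_Y)
        assert rho == pytest.approx(SPEARMAN_RHO, abs=1e-12)
        assert p == pytest.approx(SPEARMAN_P, abs=1e-12)

    def test_independent_bruteforce_recount(self):
        """Re-derive the frozen p here by brute force over all orderings."""
        rx, ry = np.array(SPEARMAN_X, float), np.array(SPEARMAN_Y, float)
        obs = stats.pearsonr(rx, ry).statistic  # distinct ranks: spearman == pearson of ranks
        count = sum(
            1
            for perm in itertools.permutations(ry)
            if abs(stats.pearsonr(rx, np.array(perm)).statistic) >= abs(obs) - 1e-12
        )
        assert count / math.factorial(5) == pytest.approx(SPEARMAN_P)

    def test_strictly_monotone_pairing_gives_unity(self, rng):
        x = np.sort(rng.normal(size=8))
        y = np.exp(x)
        rho, _ = sm.spearman_rho(x, y)
        assert rho == pytest.approx(1.0)

    @pytest.mark.parametrize("transform", [np.exp, lambda v: v**3, lambda v: 5 * v - 2])
    def test_invariant_under_monotone_transforms(self, rng, transform):
        x, y = rng.normal(size=12), rng.normal(size=12)
        rho, p = sm.spearman_rho(x, y)
        rho_t, p_t = sm.spearman_rho(transform(x), y)
        assert rho_t == pytest.approx(rho, abs=1e-12)
        assert p_t == pytest.approx(p, abs=1e-12)

    def test_ties_use_average_ranks(self):
        rho, _ = sm.spearman_rho([1.0, 1.0, 2.0, 3.0], [4.0, 5.0, 6.0, 7.0])
        assert rho == pytest.approx(stats.spearmanr([1, 1, 2, 3], [4, 5, 6, 7]).statistic)

    def test_large_n_uses_scipy_approximation(self, rng):
        x, y = rng.normal(size=20), rng.normal(size=20)
        rho, p = sm.spearman_rho(x, y)
        ref = stats.spearmanr(x, y)
        assert (rho, p) == (pytest.approx(ref.statistic), pytest.approx(ref.pvalue))

    def test_constant_sequence_raises(self):
        with pytest.raises(sm.DegenerateInputError):
            sm.spearman_rho([1.0, 1.0, 1.0], [0.1, 0.2, 0.3])


class TestMedianRatios:
    @staticmethod
    def _arm(tid, pfs2, os, arm="intervention"):
        return sm.ArmObservation(tid, arm, pfs2, os)

    def test_sorting_oracle(self):
        arms = [self._arm("A", 4, 10), self._arm("B", 5, 10), self._arm("C", 6, 10)]
        s = sm.median_ratio_summary(arms, "intervention")
        assert (s.central, s.min, s.max) == (0.5, 0.4, 0.6)
        assert s.n_below_half == 1  # 0.4 only; the tie at 0.50 is not "earlier half"

    def test_single_arm_identity_ratio(self):
        s = sm.median_ratio_summary([self._arm("A", 12.0, 12.0)], "intervention")
        assert (s.central, s.min, s.max) == (1.0, 1.0, 1.0)

    def test_even_count_central_is_mean_of_middle_two(self):
        arms = [self._arm(t, r, 1.0) for t, r in zip("ABCD", (0.4, 0.5, 0.6, 0.9))]
        s = sm.median_ratio_summary(arms, "intervention")
        assert s.central == pytest.approx(0.55)
        assert s.min <= s.central <= s.max

    def test_arms_are_kept_separate(self):
        arms = [self._arm("A", 4, 10, "intervention"), self._arm("A", 9, 10, "control")]
        si = sm.median_ratio_summary(arms, "intervention")
        sc = sm.median_ratio_summary(arms, "control")
        assert (si.central, sc.central) == (0.4, 0.9)

    def test_ratio_above_one_is_flagged_but_kept(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="surromet.secondary"):
            obs = self._arm("A", 15.0, 10.0)
        assert obs.ratio == 1.5
        assert any("exceeds median OS" in r.message for r in caplog.records)

    def test_pooled_alternative_close_to_per_trial_form(self, synth15):
        trials, _ = synth15
        arms = sm.arm_observations(trials)
        per_trial = sm.median_ratio_summary(arms, "control").central
        pooled = sm.pooled_median_ratio(arms, "control")
        assert abs(per_trial - pooled) < 0.2  # same scale, different estimator

    def test_missing_arm_rejected(self):
        with pytest.raises(ValueError):
            sm.median_ratio_summary([self._arm("A", 4, 10)], "control")


class TestDrift:
    def test_no_drift_is_degenerate(self, synth15):
        trials, _ = synth15
        frozen = sm.TrialSet(
            tuple(
                replace(r, hr_os_longterm=r.hr_os_initial if r.hr_os_longterm else None)
                for r in trials
            ),
            "frozen",
        )
        with pytest.raises(sm.DegenerateInputError, match="no drift"):
            sm.drift_analysis(frozen)

    def test_attenuation_produces_negative_rho(self):
        """Crossover shrinking long-term OS effects makes drift anti-correlate with PFS2."""
        cfg = sm.SyntheticConfig(
            n_trials=30, seed=13, missing_rate=0.0, longterm_fraction=1.0,
            crossover_range=(40.0, 50.0), crossover_attenuation=1.0, sigma=0.05,
            n_range=(5000, 8000),  # large trials keep estimation noise below the drift signal
        )
        trials, _ = sm.generate_trials(cfg)
        res = sm.drift_analysis(trials)
        assert res.rho < 0

    def test_deltas_are_log_differences(self, synth15):
        trials, _ = synth15
        res = sm.drift_analysis(trials)
        for obs in res.observations:
            rec = trials[obs.trial_id]
            assert obs.delta_log_hr_os == pytest.approx(
                math.log(rec.hr_os_longterm.hr) - math.log(rec.hr_os_initial.hr)
            )

    def test_requires_three_complete_trials(self, synth15):
        trials, _ = synth15
        few = sm.TrialSet(tuple(r for r in trials.records if r.hr_os_longterm is None), "few")
        with pytest.raises(sm.InsufficientTrialsError):
            sm.drift_analysis(few)


class TestValidationLongterm:
    def test_equals_primary_when_longterm_copies_initial(self, synth15):
        trials, _ = synth15
        frozen = sm.TrialSet(
            tuple(replace(r, hr_os_longterm=r.hr_os_initial) for r in trials), "frozen"
        )
        a = sm.run_surrogacy(frozen, "pfs2", "os_initial", seed=4, n_boot=400)
        b = sm.validation_longterm(frozen, "pfs2", seed=4, n_boot=400)
        assert a.r == b.r
        assert a.fit == b.fit
        assert (a.r_ci_low, a.r_ci_high) == (b.r_ci_low, b.r_ci_high)

    def test_crossover_attenuation_weakens_longterm_surrogacy(self):
        """With OS benefit diluted at follow-up, long-term r falls below initial r."""
        cfg = sm.SyntheticConfig(
            n_trials=40, seed=21, missing_rate=0.0, longterm_fraction=1.0,
            crossover_range=(45.0, 50.0), crossover_attenuation=1.0,
        )
        trials, _ = sm.generate_trials(cfg)
        initial = sm.run_surrogacy(trials, "pfs2", "os_initial", seed=0, n_boot=300)
        longterm = sm.validation_longterm(trials, "pfs2", seed=0, n_boot=300)
        assert longterm.r < initial.r


class TestSubtypeSubsets:
    def test_restricts_to_subtype(self, paperlike):
        res = sm.subtype_subset_analysis(paperlike, "HRpos_HER2neg", seed=0, n_boot=300)
        subtypes = {paperlike[t].subtype for t in res.trial_ids}
        assert subtypes == {"HRpos_HER2neg"}

    def test_two_trials_is_insufficient(self, paperlike):
        two = sm.TrialSet(
            tuple(r for r in paperlike if r.subtype == "HER2pos")[:2], "two"
        )
        with pytest.raises(sm.InsufficientTrialsError):
            sm.subtype_subset_analysis(two, "HER2pos", seed=0)

    def test_minimum_n_warns_about_precision(self, caplog):
        import logging

        trials, _ = sm.generate_trials(sm.SyntheticConfig(n_trials=12, seed=3))
        three = sm.TrialSet(
            tuple(replace(r, subtype="HER2pos") for r in trials.records[:3]), "three"
        )
        with caplog.at_level(logging.WARNING, logger="surromet.secondary"):
            sm.subtype_subset_analysis(three, "HER2pos", seed=0, n_boot=300)
        assert any("insufficient precision" in r.message for r in caplog.records)
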