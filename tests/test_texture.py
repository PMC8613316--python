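"""Touch events, touch responses, detection probability, classification."""

import numpy as np
import pytest

from cortexcal import synthgen as sg
from cortexcal import texture as tx
from cortexcal._validate import InsufficientDataError

FPS = 10.0


def brute_force_dp(pre, con):
    """Exhaustive pair counting: (wins + ties/2) / (n1 * n2)."""
    wins = sum(c > p for c in con for p in pre)
    ties = sum(c == p for c in con for p in pre)
    return (wins + 0.5 * ties) / (len(con) * len(pre))


class TestExtractTouchEvents:
    @pytest.mark.parametrize(
        "duration,kept",
        [(0.8, False), (1.5, True), (1.0, False)],  # strictly more than 1 s
    )
    def test_duration_rule(self, duration, kept):
        sched = tx.extract_touch_events([("novel", 5.0, 5.0 + duration)])
        assert (len(sched.contacts) == 1) == kept

    def test_malformed_interval(self):
        with pytest.raises(ValueError, match="exceed"):
            tx.extract_touch_events([("novel", 5.0, 4.0)])

    def test_overlapping_same_texture_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            tx.ContactSchedule(
                (tx.Contact("novel", 0.0, 3.0), tx.Contact("novel", 2.0, 5.0))
            )


class TestTouchResponse:
    def schedule(self):
        return tx.ContactSchedule(
            (
                tx.Contact("novel", 10.0, 12.0),
                tx.Contact("familiar", 20.0, 22.0),
                tx.Contact("novel", 30.0, 32.0),
                tx.Contact("familiar", 40.0, 42.0),
            )
        )

    def test_constant_trace_zero_response(self):
        resp = tx.touch_response(np.full(500, 0.3), FPS, self.schedule())
        assert resp["novel"] == pytest.approx(0.0)
        assert resp["familiar"] == pytest.approx(0.0)

    def test_novel_only_step(self):
        dff = np.zeros(500)
        for start in (10.0, 30.0):
            dff[int(start * FPS) : int((start + 2) * FPS)] = 0.4
        resp = tx.touch_response(dff, FPS, self.schedule())
        assert resp["novel"] == pytest.approx(0.4)
        assert resp["familiar"] == pytest.approx(0.0)

    def test_planted_amplitudes_recovered(self):
        sel = sg.SelectivityGroundTruth(
            ("NTS", "FTS", "non-responsive"),
            np.array([0.4, 0.0, 0.0]),
            np.array([0.0, 0.3, 0.0]),
        )
        sched = sg.alternating_contact_schedule(8)
        cfg = sg.PopulationConfig(
            n_neurons=3, duration_s=120.0, firing_rate_hz=0.0,
            baseline_drift_amplitude=0.0, noise_sd=0.02, seed=9,
        )
        F, _ = sg.generate_texture_session(sel, sched, cfg)
        from cortexcal import traces as tr

        resp0 = tx.touch_response(tr.compute_dff(tr.RawTrace(F[0], FPS)).dff, FPS, sched)
        resp1 = tx.touch_response(tr.compute_dff(tr.RawTrace(F[1], FPS)).dff, FPS, sched)
        assert resp0["novel"] == pytest.approx(0.4, abs=0.05)
        assert resp0["familiar"] == pytest.approx(0.0, abs=0.05)
        assert resp1["familiar"] == pytest.approx(0.3, abs=0.05)

    def test_no_usable_contacts(self):
        sched = tx.ContactSchedule((tx.Contact("novel", 0.2, 2.0), tx.Contact("familiar", 10.0, 12.0)))
        with pytest.warns(UserWarning):
            with pytest.raises(InsufficientDataError, match="novel"):
                tx.touch_response(np.zeros(300), FPS, sched)


class TestDpScore:
    def test_all_ties_half(self):
        assert tx.dp_from_dvs([0.2, 0.2, 0.2], [0.2, 0.2, 0.2]) == pytest.approx(0.5)

    def test_perfect_separation(self):
        assert tx.dp_from_dvs([1, 2, 3, 4, 5], [6, 7, 8, 9, 10]) == 1.0

    def test_printed_example(self):
        pre, con = [1.0, 3.0, 5.0], [2.0, 4.0, 6.0]
        assert tx.dp_from_dvs(pre, con) == pytest.approx(brute_force_dp(pre, con))
        assert tx.dp_from_dvs(pre, con) == pytest.approx(6 / 9)

    def test_random_instances_match_pair_counting(self, rng):
        for _ in range(200):
            n1 = rng.integers(2, 11)
            n2 = rng.integers(2, 11)
            # mix of continuous values and ties
            pre = np.round(rng.normal(size=n2), 1)
            con = np.round(rng.normal(0.3, 1, size=n1), 1)
            assert tx.dp_from_dvs(pre, con) == pytest.approx(brute_force_dp(pre, con))

    def test_cross_check_against_mannwhitney(self, rng):
        from scipy.stats import mannwhitneyu

        pre = rng.normal(size=8)
        con = rng.normal(0.5, 1, size=8)
        u = mannwhitneyu(con, pre, alternative="two-sided").statistic
        assert tx.dp_from_dvs(pre, con) == pytest.approx(u / 64)


class TestPermutationTest:
    def test_deterministic_given_seed(self, rng):
        pre, con = rng.normal(size=8), rng.normal(size=8)
        p1 = tx.permutation_test(pre, con, n_perm=200, seed=5)
        p2 = tx.permutation_test(pre, con, n_perm=200, seed=5)
        assert p1 == p2

    def test_perfect_separation_small_p(self):
        pre = np.arange(10.0)
        con = np.arange(10.0) + 100
        p = tx.permutation_test(pre, con, n_perm=1000, seed=1)
        assert p < 0.05
        assert p >= 1 / 1001  # add-one estimator floor

    def test_add_one_never_zero(self):
        p = tx.permutation_test([0.0, 0.0], [1.0, 1.0], n_perm=10, seed=0)
        assert p > 0.0

    def test_paired_variant_runs(self, rng):
        pre, con = rng.normal(size=8), rng.normal(size=8)
        p = tx.permutation_test(pre, con, n_perm=200, seed=2, paired=True)
        assert 0 < p <= 1


class TestClassify:
    @pytest.mark.parametrize(
        "p_novel,p_familiar,expected",
        [
            (0.01, 0.20, "NTS"),
            (0.20, 0.01, "FTS"),
            (0.01, 0.01, "non-selective"),
            (0.50, 0.50, "non-responsive"),
        ],
    )
    def test_definitions(self, p_novel, p_familiar, expected):
        assert tx.classify(p_novel, p_familiar) == expected

    def test_monotone_in_p(self, rng):
        # lowering a p-value never removes responsiveness for that texture
        for _ in range(100):
            pn, pf = rng.random(), rng.random()
            cat = tx.classify(pn, pf)
            cat_lower = tx.classify(pn * 0.5, pf)
            if cat in ("NTS", "non-selective"):
                assert cat_lower in ("NTS", "non-selective")


class TestInteractionActivity:
    def schedule(self):
        return tx.ContactSchedule((tx.Contact("novel", 2.0, 4.0), tx.Contact("familiar", 6.0, 8.0)))

    def test_constant(self):
        inside, outside = tx.interaction_activity(np.full(100, 0.3), FPS, self.schedule())
        assert inside == pytest.approx(0.3)
        assert outside == pytest.approx(0.3)

    def test_indicator(self):
        dff = np.zeros(100)
        dff[20:40] = 1.0
        dff[60:80] = 1.0
        inside, outside = tx.interaction_activity(dff, FPS, self.schedule())
        assert (inside, outside) == (1.0, 0.0)

    def test_brute_force_masked_means(self, rng):
        dff = rng.normal(size=100)
        sched = self.schedule()
        inside, outside = tx.interaction_activity(dff, FPS, sched)
        mask = np.zeros(100, dtype=bool)
        mask[20:40] = mask[60:80] = True
        assert inside == pytest.approx(dff[mask].mean())
        assert outside == pytest.approx(dff[~mask].mean())

    def test_full_coverage_rejected(self):
        sched = tx.ContactSchedule((tx.Contact("novel", 0.0, 10.0),))
        with pytest.raises(InsufficientDataError):
            tx.interaction_activity(np.zeros(100), FPS, sched)


class TestClassifyPopulation:
    def test_planted_strong_nts_recovered(self):
        # one NTS neuron, amplitude >> noise, 10 novel contacts
        sel = sg.SelectivityGroundTruth(("NTS",), np.array([0.5]), np.array([0.0]))
        sched = sg.alternating_contact_schedule(10)
        cfg = sg.PopulationConfig(
            n_neurons=1, duration_s=150.0, firing_rate_hz=0.05, noise_sd=0.02, seed=21
        )
        F, _ = sg.generate_texture_session(sel, sched, cfg)
        prof = tx.classify_population(F, FPS, sched, n_perm=500, seed=22)
        assert prof.table.category.tolist() == ["NTS"]

    def test_silent_neuron_excluded(self):
        sched = sg.alternating_contact_schedule(4)
        F = np.full((1, 600), 100.0) + np.random.default_rng(0).normal(0, 0.001, (1, 600))
        prof = tx.classify_population(F, FPS, sched, n_perm=50, seed=1)
        assert prof.table.category.tolist() == ["excluded"]
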