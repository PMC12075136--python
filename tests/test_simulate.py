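"""Steady-state cell-cycle simulator: fork kinematics, expected profiles,
initiation-failure mixtures and read sampling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from replifork import (
    ConfigurationError,
    SimulationError,
    circular_span,
    marker_ratio,
)
from replifork.simulate import (
    PopulationClass,
    SimConfig,
    SpeedProfile,
    build_population,
    expected_copy_profile,
    expected_population_profile,
    fork_schedule,
    make_bias_track,
    mix_classes,
    sample_reads,
    segment_average_speeds,
    synchrony_failure_curve,
)

V = 1000.0  # bp/s


def _t_at(t, pos):
    return t[pos // 1000]


class TestForkSchedule:
    def test_two_origin_meeting_and_trap_times(self, toy_strain):
        """Hand-computed landmarks of the toy two-origin schedule at 1 kbp/s:
        converging forks meet 425 kb from each origin at 425 s, the leftward
        oriX fork is arrested at terA after 1,150 kb, and the oriC rightward
        fork completes replication there after 2,000 kb."""
        t = fork_schedule(toy_strain, SpeedProfile.constant(V),
                          ("oriC", "oriX"), 1000)
        # bin centred at 2,574,500: 424.5 kb right of oriX
        assert _t_at(t, 2_574_000) == pytest.approx(424.5)
        # bin centred at 1,000,500: 1,149.5 kb left of oriX (past terC)
        assert _t_at(t, 1_000_000) == pytest.approx(1149.5)
        # bin centred at 999,500: 1,999.5 kb right of oriC (end of the cycle)
        assert _t_at(t, 999_000) == pytest.approx(1999.5)
        assert t.max() == pytest.approx(1999.5)

    def test_single_origin_distance_over_speed(self, toy_strain):
        """Symmetric toy arms: every locus is replicated at min arc distance
        from oriC divided by the speed, with forks meeting at terA."""
        t = fork_schedule(toy_strain, SpeedProfile.constant(V), ("oriC",), 1000)
        centers = np.arange(4000) * 1000 + 500.0
        d_right = (centers - 3_000_000) % 4_000_000
        d_left = (3_000_000 - centers) % 4_000_000
        np.testing.assert_allclose(t, np.minimum(d_right, d_left) / V, atol=1e-6)

    def test_oriX_only_fork_trapped_then_met(self, toy_strain):
        """oriX-only cells: the leftward fork is arrested at terA after
        1,150 kb; the rightward fork travels the remaining 2,850 kb around
        the circle and terminates at terA."""
        t = fork_schedule(toy_strain, SpeedProfile.constant(V), ("oriX",), 1000)
        # just left of terA: replicated by the rightward fork near the end,
        # 2,849.5 kb clockwise from oriX
        assert _t_at(t, 999_000) == pytest.approx(2849.5)
        assert t.max() == pytest.approx(2849.5)
        # terC is passed by the leftward fork, not a barrier for it
        assert _t_at(t, 1_300_000) == pytest.approx((2_150_000 - 1_300_500) / V)
        # just right of terA: the leftward fork, shortly before its arrest
        assert _t_at(t, 1_000_000) == pytest.approx(1149.5)

    def test_speed_switches_with_moving_fork_count(self, toy_strain):
        """v4 applies until the converging forks meet, v2 until the terA
        arrest, v1 afterwards; checked against hand-computed arc arithmetic."""
        sp = SpeedProfile.from_kbps(0.5, 0.8, 1.0)
        t = fork_schedule(toy_strain, sp, ("oriC", "oriX"), 1000)
        # X_L outer edge: bin centre 424.5 kb left of oriX, all at v4
        assert _t_at(t, 1_725_000) == pytest.approx(424.5 / 0.5)
        # terA arrest: 425 kb at v4 then 725 kb at v2
        t_trap = 425 / 0.5 + 725 / 0.8
        assert _t_at(t, 1_000_000) == pytest.approx(t_trap, abs=1.5)
        # completion: remaining 850 kb of the right fork path at v1
        assert t.max() == pytest.approx(t_trap + 850 / 1.0, abs=1.5)

    def test_speeds_must_be_positive(self):
        with pytest.raises(ConfigurationError):
            SpeedProfile.constant(0.0)


class TestExpectedCopyProfile:
    def test_ori_ter_ratio_two_when_C_equals_tau(self, toy_strain):
        """With C = tau the origin/terminus frequency ratio is 2 (the
        classic exponential-culture result)."""
        t = fork_schedule(toy_strain, SpeedProfile.constant(V), ("oriC",), 1000)
        tau = float(t.max())  # C = tau
        n = expected_copy_profile(t, tau)
        # exact closed form at bin centres, and ~2 up to the half-bin offset
        # of the first/last evaluated centres
        assert n.max() / n.min() == pytest.approx(
            2 ** ((t.max() - t.min()) / tau), rel=1e-9
        )
        assert n.max() / n.min() == pytest.approx(2.0, rel=1e-3)

    def test_matches_marker_frequency_equation(self, toy_strain):
        """Simulated single-origin frequencies reproduce the closed-form
        marker ratio at arbitrary locus pairs on one replichore."""
        t = fork_schedule(toy_strain, SpeedProfile.constant(V), ("oriC",), 1000)
        tau = 3600.0
        n = expected_copy_profile(t, tau)
        R = 2_000_000.0  # toy replichore length
        C = R / V
        rng = np.random.default_rng(0)
        # bin offsets along the right replichore, measured from oriC
        pairs = rng.integers(0, 1_990, size=(25, 2))
        for a, b in pairs:
            lo, hi = sorted((int(a), int(b)))
            if lo == hi:
                continue
            x = (3_000_000 + lo * 1000 + 500) % 4_000_000
            y = (3_000_000 + hi * 1000 + 500) % 4_000_000
            m_x = (lo * 1000 + 500) / R
            m_y = (hi * 1000 + 500) / R
            expected = marker_ratio(C, tau, m_x, m_y)
            assert n[x // 1000] / n[y // 1000] == pytest.approx(
                expected, rel=1e-6
            )

    def test_log2_profile_linear_with_slope_one_over_tau_v(self, toy_strain):
        t = fork_schedule(toy_strain, SpeedProfile.constant(V), ("oriC",), 1000)
        tau = 3600.0
        n = expected_copy_profile(t, tau, 60.0)
        # right replichore interior
        idx = np.arange(3_010, 3_990)
        y = np.log2(n[[i % 4000 for i in idx]])
        x = (idx - 3_000) * 1000.0
        slope = np.polyfit(x, y, 1)[0]
        assert slope == pytest.approx(-1 / (tau * V), rel=1e-9)

    def test_instantaneous_replication_gives_flat_profile(self):
        n = expected_copy_profile(np.zeros(100), 3600.0, 600.0)
        np.testing.assert_allclose(n, 1.0)

    def test_replication_must_complete_within_the_cycle(self, toy_strain):
        t = fork_schedule(toy_strain, SpeedProfile.constant(V), ("oriC",), 1000)
        with pytest.raises(SimulationError):
            expected_copy_profile(t, 2100.0, 200.0)  # 200 + 2000 > 2100


class TestMixtures:
    def test_zero_failure_is_identity(self, constant_speed_sim):
        from dataclasses import replace

        pure = expected_population_profile(constant_speed_sim)
        classes = build_population(replace(constant_speed_sim,
                                           failure_fraction=0.0))
        assert [c.label for c in classes] == ["both-origins"]
        np.testing.assert_allclose(
            mix_classes(classes, constant_speed_sim.tau,
                        constant_speed_sim.initiation_age),
            pure, rtol=1e-12,
        )

    def test_total_failure_is_even_single_origin_mixture(self, constant_speed_sim):
        from dataclasses import replace

        sim = replace(constant_speed_sim, failure_fraction=1.0)
        classes = build_population(sim)
        assert sorted(c.label for c in classes) == ["oriC-only", "oriX-only"]
        assert [c.weight for c in classes] == [0.5, 0.5]

    def test_weights_must_sum_to_one(self, constant_speed_sim):
        classes = build_population(constant_speed_sim)
        bad = [PopulationClass(c.label, c.weight * 0.9, c.schedule)
               for c in classes]
        with pytest.raises(ConfigurationError):
            mix_classes(bad, constant_speed_sim.tau, 60.0)

    def test_failure_flattens_converging_segments_only(self, constant_speed_sim,
                                                       oriCX_segset):
        """A 25% initiation-failure mixture reduces the converging-segment
        gradient while leaving the diverging segments at the pure-culture
        gradient."""
        from dataclasses import replace

        from replifork import CorrectedProfile, fit_connecting_points, segment_slopes

        def slopes(f):
            sim = replace(constant_speed_sim, failure_fraction=f)
            prof = CorrectedProfile.from_rel_freq(
                expected_population_profile(sim), 1000,
                sim.strain.genome_length,
            )
            return segment_slopes(
                fit_connecting_points(prof, oriCX_segset), oriCX_segset
            )

        s0, s25 = slopes(0.0), slopes(0.25)
        for name in ("X_R", "C_L"):
            assert s25[name] < 0.85 * s0[name], name
        # diverging segments keep the pure-culture gradient (small leakage
        # through the knots shared with the flattened converging segments)
        for name in ("X_L", "C_R"):
            assert s25[name] == pytest.approx(s0[name], rel=0.02), name

    def test_synchrony_curve_monotone_from_one(self, constant_speed_sim):
        curve = synchrony_failure_curve(constant_speed_sim,
                                        [0.0, 0.1, 0.25, 0.5])
        values = [s for _, s in curve]
        assert values[0] == pytest.approx(1.0, abs=0.01)
        assert all(a > b for a, b in zip(values, values[1:]))


class TestSampleReads:
    def test_fixed_seed_reproducible(self):
        expected = np.linspace(0.5, 1.5, 100)
        a = sample_reads(expected, 100_000, 100_000, seed=12)
        b = sample_reads(expected, 100_000, 100_000, seed=12)
        np.testing.assert_array_equal(a.counts, b.counts)
        c = sample_reads(expected, 100_000, 100_000, seed=13)
        assert (a.counts != c.counts).any()

    def test_noise_free_counts_proportional_and_exact_total(self):
        expected = np.linspace(0.5, 1.5, 100)
        bias = np.ones(100)
        bias[10] = 2.0
        prof = sample_reads(expected, 1_000_000, 100_000, bias_track=bias,
                            noise="none")
        assert prof.counts.sum() == 1_000_000
        lam = 1_000_000 * expected * bias / (expected * bias).sum()
        assert np.max(np.abs(prof.counts - lam)) <= 1.0

    def test_poisson_depth_controls_relative_error(self):
        expected = np.ones(4000)
        prof = sample_reads(expected, 10_000_000, 4_000_000, seed=5)
        rel = prof.counts / prof.counts.mean() - 1
        assert np.std(rel) == pytest.approx(1 / np.sqrt(2500), rel=0.1)

    def test_bias_must_be_positive(self):
        with pytest.raises(ConfigurationError):
            sample_reads(np.ones(10), 100, 10_000,
                         bias_track=np.zeros(10))

    def test_bias_track_is_locally_centred(self):
        b = np.log2(make_bias_track(2000, 0.1, seed=3))
        assert np.std(b) == pytest.approx(0.1, rel=0.15)
        smooth = np.convolve(np.concatenate([b, b[:61]]), np.ones(61) / 61,
                             mode="valid")[:2000]
        assert np.std(smooth) < 0.01


class TestGroundTruthSpeeds:
    def test_pure_segments_match_configured_speeds(self, oriCX_strain,
                                                   oriCX_segset):
        sp = SpeedProfile.from_kbps(0.5, 0.8, 1.0)
        truth = segment_average_speeds(oriCX_strain, sp, oriCX_segset)
        for name in ("X_L", "X_R", "C_L", "C_R"):
            assert truth[name] == pytest.approx(500.0, rel=0.005), name
        for name in ("L2", "R2"):
            assert truth[name] == pytest.approx(800.0, rel=0.005), name
        # R3 straddles the 2->1 fork switch (the left fork crosses half the
        # ter window before its arrest), so its average sits below v1.
        assert 800.0 < truth["R3"] < 1000.0
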