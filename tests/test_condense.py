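"""Condensation statistics: curves, ratio, work, hysteresis, steps."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import tetherkit as tk
from tetherkit.condense import ForceExtensionCurve
from tests.conftest import make_trajectory


def curve(force, ext, label=""):
    force = np.asarray(force, float)
    return ForceExtensionCurve(force, np.asarray(ext, float),
                               np.zeros(force.size), np.ones(force.size, int),
                               label)


class TestBuildFec:
    def test_constant_z_gives_flat_curve(self):
        force = np.concatenate([np.full(240, 2.0), np.full(240, 1.0)])
        traj = make_trajectory(np.full(480, 777.0), force=force)
        fec = tk.build_fec(traj)
        assert np.allclose(fec.mean_extension, 777.0)
        assert np.array_equal(fec.force, [2.0, 1.0])
        assert np.all(fec.n_molecules == 1)

    @staticmethod
    def boltzmann_mean_extension(force, params):
        """Independent oracle: exact thermal-average extension of a WLC
        held at constant force, <z> = int z e^(-U/kBT) / int e^(-U/kBT)
        with U(z) = int F_wlc - F z.  (The deterministic inversion
        wlc_extension(F) sits slightly above this whenever the force law
        is convex over the fluctuation range.)"""
        lc = params.contour_length
        z = np.linspace(1e-3, lc * 0.9999, 20000)
        u = np.concatenate([[0.0], np.cumsum(
            (np.asarray(tk.wlc_force(z, params)) - force)[:-1] * np.diff(z))])
        w = np.exp(-(u - u.min()) / params.thermal_energy)
        return float(np.trapezoid(z * w, z) / np.trapezoid(w, z))

    def test_bare_simulation_matches_wlc_within_3_sem(self, config):
        sched = tk.ForceSchedule(tuple((20.0, f) for f in (4.0, 1.0, 0.3, 0.1)))
        traj = tk.simulate_tether(config, sched, seed=71)
        fec = tk.build_fec(traj, sched)
        t0 = 0.0
        for (dur, f), z in zip(sched.segments, fec.mean_extension):
            expected = self.boltzmann_mean_extension(f, config.dna)
            # blocked SEM: samples are OU-correlated, so the naive
            # within-segment SEM would be optimistic
            seg = traj.window(t0 + 0.1 * dur, t0 + dur).z
            blocks = np.array_split(seg, 10)
            sem_b = np.std([b.mean() for b in blocks], ddof=1) / np.sqrt(10)
            assert abs(z - expected) < 3.5 * sem_b
            t0 += dur

    def test_schedule_past_trajectory_end_rejected(self, config):
        traj = tk.simulate_tether(config, tk.ForceSchedule(((5.0, 1.0),)), seed=1)
        with pytest.raises(ValueError, match="past the end"):
            tk.build_fec(traj, tk.ForceSchedule(((10.0, 1.0),)))

    def test_too_few_retained_samples_rejected(self):
        traj = make_trajectory(np.full(8, 500.0))
        with pytest.raises(ValueError, match="samples"):
            tk.build_fec(traj)


class TestAggregate:
    def test_identical_curves_have_zero_sem(self):
        c = curve([4.0, 1.0], [1900.0, 1700.0])
        agg = tk.aggregate_fec([c, c, c])
        assert np.allclose(agg.mean_extension, c.mean_extension)
        assert np.allclose(agg.sem, 0.0)
        assert np.all(agg.n_molecules == 3)

    def test_two_offset_curves_give_sem_delta(self):
        delta = 25.0
        base = np.array([1900.0, 1700.0])
        agg = tk.aggregate_fec([
            curve([4.0, 1.0], base - delta),
            curve([4.0, 1.0], base + delta),
        ])
        assert np.allclose(agg.mean_extension, base)
        # sample sd of {-d, +d} is d*sqrt(2); sem = sd/sqrt(2) = d
        assert np.allclose(agg.sem, delta)

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError, match="grids"):
            tk.aggregate_fec([
                curve([4.0, 1.0], [1900.0, 1700.0]),
                curve([4.0, 0.5], [1900.0, 1600.0]),
            ])


class TestCondensationRatio:
    @pytest.mark.parametrize(
        "z0,z,expected", [(800.0, 800.0, 0.0), (800.0, 0.0, 1.0),
                          (800.0, 200.0, 0.75)]
    )
    def test_ratio_identities(self, z0, z, expected):
        stats = tk.condensation_ratio(z0, z)
        assert stats.cr == pytest.approx(expected, abs=1e-15)
        assert not stats.negative

    def test_lengthened_tether_flagged_not_clamped(self):
        stats = tk.condensation_ratio(800.0, 900.0)
        assert stats.cr == pytest.approx(-0.125)
        assert stats.negative

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            tk.condensation_ratio(0.0, 100.0)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(z0=st.floats(1.0, 5000.0), z=st.floats(0.0, 5000.0),
           c=st.floats(1e-3, 1e3))
    def test_scale_invariance(self, z0, z, c):
        a = tk.condensation_ratio(z0, z).cr
        b = tk.condensation_ratio(c * z0, c * z).cr
        assert b == pytest.approx(a, rel=1e-9, abs=1e-12)

    def test_from_trajectory_null_is_near_zero(self, config):
        traj = tk.simulate_tether(
            config, tk.ForceSchedule(((450.0, 0.34),)), seed=55
        )
        stats = tk.condensation_ratio_from_traj(traj, t_eval=400.0)
        # no condensation: fractional shortening consistent with zero
        assert abs(stats.cr) < 0.03

    def test_from_trajectory_recovers_ground_truth(self, config):
        cmodel = tk.CondensationModel()
        bare = tk.simulate_tether(config, tk.ForceSchedule(((60.0, 0.34),)), seed=1)
        cond = tk.simulate_condensation(
            config, cmodel, tk.ForceSchedule(((420.0, 0.34),)), seed=2
        )
        traj = tk.Trajectory.concatenate([bare, cond])
        z0 = bare.z[60:].mean()
        stats = tk.condensation_ratio_from_traj(traj, t_eval=60.0 + 390.0, z0=z0)
        # ground truth from the simulator's effective contour at evaluation
        sel = (traj.time > 430.0) & (traj.time < 470.0)
        lc_eval = traj.effective_contour[sel].mean()
        p = config.dna
        z_truth = tk.wlc_extension(0.34, tk.WLCParams(
            p.persistence_length, lc_eval, p.thermal_energy))
        cr_truth = (z0 - z_truth) / z0
        assert stats.cr == pytest.approx(cr_truth, abs=0.05)
        assert stats.cr > 0.5  # strongly condensed at the floor

    def test_t_eval_outside_trajectory_rejected(self, config):
        traj = tk.simulate_tether(config, tk.ForceSchedule(((30.0, 0.34),)), seed=3)
        with pytest.raises(ValueError):
            tk.condensation_ratio_from_traj(traj, t_eval=400.0)

    def test_missing_reference_segment_rejected(self, config):
        traj = tk.simulate_tether(config, tk.ForceSchedule(((60.0, 1.0),)), seed=3)
        with pytest.raises(ValueError, match="permissive"):
            tk.condensation_ratio_from_traj(traj, t_eval=30.0)


class TestCondensationWork:
    def test_identical_curves_give_zero_work(self):
        c = curve([0.02, 0.1, 1.0, 4.0], [300.0, 1000.0, 1700.0, 1940.0])
        res = tk.condensation_work(c, c)
        assert res.delta_w == pytest.approx(0.0, abs=1e-12)
        assert res.zmax == 1940.0

    def test_uniform_offset_is_rectangle_area(self):
        z = np.array([0.0, 250.0, 500.0, 750.0, 1000.0])
        f_bare = np.array([0.0, 0.5, 1.0, 2.0, 4.0])
        bare = curve(f_bare, z)
        protein = curve(f_bare + 0.5, z)
        res = tk.condensation_work(protein, bare)
        assert res.delta_w == pytest.approx(500.0, abs=1e-9)
        assert res.delta_w_kbt == pytest.approx(500.0 / 4.114)

    def test_triangular_difference_integrates_exactly(self):
        z = np.array([0.0, 500.0, 1000.0])
        bare = curve([0.0, 2.0, 4.0], z)
        protein = curve([0.0 + 0.0, 2.0 + 1.0, 4.0 + 0.0], z)
        res = tk.condensation_work(protein, bare)
        assert res.delta_w == pytest.approx(500.0, abs=1e-12)

    def test_row_permutation_invariance(self, rng):
        z = np.array([0.0, 250.0, 500.0, 750.0, 1000.0])
        f = np.array([0.0, 0.5, 1.0, 2.0, 4.0])
        bare = curve(f, z)
        protein = curve(f + 0.3, z)
        perm = rng.permutation(5)
        res_a = tk.condensation_work(protein, bare)
        res_b = tk.condensation_work(curve(f[perm] + 0.3, z[perm]),
                                     curve(f[perm], z[perm]))
        assert res_b.delta_w == pytest.approx(res_a.delta_w, abs=1e-12)

    def test_swapping_inputs_negates_work(self):
        z = np.array([0.0, 500.0, 1000.0])
        bare = curve([0.0, 1.0, 4.0], z)
        protein = curve([0.5, 1.5, 4.5], z)
        a = tk.condensation_work(protein, bare).delta_w
        b = tk.condensation_work(bare, protein).delta_w
        assert b == pytest.approx(-a)
        assert a >= 0  # protein curve at/above bare force everywhere

    def test_nonmonotone_bare_curve_rejected(self):
        bad = curve([0.5, 1.0, 2.0, 4.0], [800.0, 700.0, 900.0, 1000.0])
        good = curve([0.5, 1.0, 2.0, 4.0], [700.0, 800.0, 900.0, 1000.0])
        with pytest.raises(ValueError, match="non-monotone"):
            tk.condensation_work(good, bad)

    def test_condensed_protein_curve_is_monotonised_and_flagged(self):
        bare = curve([0.02, 0.1, 1.0, 4.0], [300.0, 1000.0, 1700.0, 1940.0])
        protein = curve([0.02, 0.1, 1.0, 4.0], [420.0, 400.0, 1500.0, 1930.0])
        res = tk.condensation_work(protein, bare)
        assert res.monotonised
        assert res.delta_w > 0

    def test_disjoint_extension_ranges_rejected(self):
        bare = curve([1.0, 2.0, 4.0], [1500.0, 1700.0, 1900.0])
        protein = curve([1.0, 2.0, 4.0], [100.0, 200.0, 300.0])
        with pytest.raises(ValueError, match="overlap"):
            tk.condensation_work(protein, bare)


class TestHysteresis:
    def test_identical_traces_zero_area_no_steps(self):
        turns = np.arange(0.0, 61.0)
        ext = 1900.0 - 10.0 * turns
        res = tk.hysteresis((turns, ext), (turns, ext))
        assert res.area == 0.0
        assert res.max_deviation == 0.0
        assert res.steps_detected == ()

    def test_offset_backward_trace_gives_rectangle_area(self):
        turns = np.arange(0.0, 41.0)
        ext = np.full(41, 1500.0)
        delta = 30.0
        res = tk.hysteresis((turns, ext), (turns, ext + delta))
        # backward ABOVE forward by delta: area = -delta * N under the
        # forward-minus-backward convention (positive = unwinding lags)
        assert abs(res.area) == pytest.approx(delta * 40.0)
        assert res.area == pytest.approx(-delta * 40.0)

    def test_disjoint_turn_ranges_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            tk.hysteresis((np.arange(0, 10.0), np.ones(10)),
                          (np.arange(20.0, 30.0), np.ones(10)))

    def test_simulated_bridged_run_positive_unbridged_null(self, config):
        sched = tk.winding_schedule(60, 0.1)

        def area(bridged, seed):
            traj = tk.simulate_rotation_extension(config, sched, bridged, seed)
            tf, zf, tb, zb = tk.rotation_branches(traj)
            return tk.hysteresis((tf, zf), (tb, zb)).area

        null = np.array([area(False, s) for s in range(200, 208)])
        bridged = area(True, 300)
        assert abs(area(False, 210)) < 3 * null.std() + abs(null.mean())
        assert bridged > 3 * null.std()


class TestStepDetector:
    def test_noiseless_staircase_recovered_exactly(self):
        s = np.concatenate([np.full(100, 0.0), np.full(100, 50.0),
                            np.full(100, 100.0), np.full(100, 150.0)])
        found = tk.detect_steps(s, threshold_sigmas=5.0, window=20)
        assert [i for i, _ in found] == [100, 200, 300]
        assert all(size == pytest.approx(50.0, abs=1e-9) for _, size in found)

    def test_single_central_step_located(self):
        s = np.concatenate([np.zeros(150), np.full(150, 40.0)])
        found = tk.detect_steps(s, window=10)
        assert len(found) == 1
        assert found[0][0] == 150

    def test_preconditions(self):
        with pytest.raises(ValueError, match="window"):
            tk.detect_steps(np.zeros(100), window=3)
        with pytest.raises(ValueError, match="3\\*window"):
            tk.detect_steps(np.zeros(20), window=10)

    def test_noise_only_false_positive_rate(self, rng):
        # quick null check; the full 100-trial calibration runs in the
        # acceptance suite
        count = 0
        for _ in range(30):
            found = tk.detect_steps(rng.normal(0, 5.0, 1000),
                                    threshold_sigmas=5.0, window=20)
            count += len(found)
        assert count / 30 < 0.1
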