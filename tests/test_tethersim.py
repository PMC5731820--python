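"""Brownian tether simulator, fixture generators, and hairpin folding."""

import numpy as np
import pytest

import tetherkit as tk
from tetherkit.tethersim import _WC

SHORT = tk.ForceSchedule(((5.0, 1.0),))


class TestTetherDynamics:
    def test_same_seed_bitwise_identical(self, config):
        a = tk.simulate_tether(config, SHORT, seed=7)
        b = tk.simulate_tether(config, SHORT, seed=7)
        for col in ("x", "y", "z"):
            assert np.array_equal(getattr(a, col), getattr(b, col))

    def test_different_seed_differs(self, config):
        a = tk.simulate_tether(config, SHORT, seed=7)
        b = tk.simulate_tether(config, SHORT, seed=8)
        assert not np.array_equal(a.z, b.z)

    def test_equipartition_converges_with_window_length(self, config):
        # Var(x) * F / (kBT <z>) -> 1; tolerance bands shrink with window
        force = 1.0
        tols = {5.0: 0.30, 20.0: 0.15, 60.0: 0.10}
        for dur, tol in tols.items():
            traj = tk.simulate_tether(
                config, tk.ForceSchedule(((dur, force),)), seed=303
            )
            ratio = traj.x.var(ddof=1) * force / (config.kbt * traj.z.mean())
            assert abs(ratio - 1.0) < tol

    def test_force_floor_stays_finite(self, config):
        traj = tk.simulate_tether(config, tk.ForceSchedule(((10.0, 0.01),)), seed=5)
        assert np.all(np.isfinite(traj.x)) and np.all(np.isfinite(traj.z))
        assert traj.x.var() > 0

    def test_below_force_floor_rejected(self):
        with pytest.raises(ValueError, match="floor"):
            tk.ForceSchedule(((10.0, 0.001),))

    def test_unstable_timestep_rejected(self, config):
        with pytest.raises(tk.ConfigurationError, match="unstable"):
            tk.simulate_tether(config, tk.ForceSchedule(((1.0, 4.0),)), seed=1,
                               dt_override=1.0)

    def test_time_axis_uniform(self, config):
        traj = tk.simulate_tether(config, SHORT, seed=1)
        dt = np.diff(traj.time)
        assert np.allclose(dt, 1.0 / config.acquisition_rate)


class TestCondensation:
    def test_zero_capture_rate_degenerates_to_bare(self, config):
        null = tk.CondensationModel(capture_rate_zero_force=0.0,
                                    release_rate_zero_force=0.0)
        a = tk.simulate_tether(config, SHORT, seed=21)
        b = tk.simulate_condensation(config, null, SHORT, seed=21)
        assert np.array_equal(a.z, b.z)
        assert np.array_equal(a.x, b.x)

    def test_default_kinetics_condense_at_permissive_force(self, config):
        cmodel = tk.CondensationModel()
        traj = tk.simulate_condensation(
            config, cmodel, tk.ForceSchedule(((300.0, 0.3),)), seed=99
        )
        initial = traj.z[: 2 * int(config.acquisition_rate)].mean()
        final = traj.z[-3 * int(config.acquisition_rate):].mean()
        assert final < (cmodel.min_tether_fraction + 0.1) * initial

    def test_effective_contour_never_below_floor(self, config):
        cmodel = tk.CondensationModel()
        traj = tk.simulate_condensation(
            config, cmodel, tk.ForceSchedule(((60.0, 0.2),)), seed=4
        )
        floor = cmodel.min_tether_fraction * config.dna.contour_length
        assert np.all(traj.effective_contour >= floor - 1e-9)
        assert np.all(traj.z < traj.effective_contour)

    def test_high_force_releases_condensed_tether(self, config):
        cmodel = tk.CondensationModel()
        sched = tk.ForceSchedule(((120.0, 0.2), (60.0, 4.0)))
        traj = tk.simulate_condensation(config, cmodel, sched, seed=17)
        # condensed by the end of the low-force phase, re-extended at 4 pN
        mid = traj.window(110.0, 120.0).z.mean()
        end = traj.window(170.0, 180.0).z.mean()
        assert mid < 0.4 * end


class TestRotationExtension:
    def test_zero_turns_matches_bare_extension(self, config):
        sched = [(1.0, 0)] * 30
        traj = tk.simulate_rotation_extension(config, sched, bridged=False, seed=2)
        z0 = tk.wlc_extension(4.0, config.dna)
        assert traj.z.mean() == pytest.approx(z0, rel=0.02)

    def test_winding_shortens_beyond_buckling(self, config):
        traj = tk.simulate_rotation_extension(
            config, tk.winding_schedule(60, 0.1, unwind=False),
            bridged=False, seed=3,
        )
        z_flat = traj.z[traj.turns <= 20].mean()
        z_wound = traj.z[traj.turns == 60].mean()
        assert z_wound < z_flat - 500.0

    def test_bridged_unwinding_lags_forward_branch(self, config):
        sched = tk.winding_schedule(60, 0.1)
        traj = tk.simulate_rotation_extension(config, sched, bridged=True, seed=11)
        tf, zf, tb, zb = tk.rotation_branches(traj)
        common = np.intersect1d(tf, tb)
        mid = common[(common > 5) & (common < 30)]
        f = np.interp(mid, tf, zf)
        b = np.interp(mid, tb, zb)
        assert (f - b).mean() > 100.0


class TestFixtureGenerators:
    def test_titration_midpoint_and_monotone(self):
        data = tk.simulate_titration(noise_sd=0.0, seed=0,
                                     concentrations=[90.0, 180.0, 361.0, 722.0])
        resp_at_kd = data.responses[data.concentrations == 361.0]
        assert resp_at_kd == pytest.approx(0.5)  # bmax/2 at Kd
        assert np.all(np.diff(data.responses) > 0)

    def test_titration_reproducible(self):
        a = tk.simulate_titration(noise_sd=0.05, seed=9)
        b = tk.simulate_titration(noise_sd=0.05, seed=9)
        assert np.array_equal(a.responses, b.responses)

    def test_melt_midpoint_and_monotone(self):
        m = tk.simulate_melt(tm=68.0, noise_sd=0.0,
                             temperatures=np.arange(5.0, 91.0, 1.0))
        mid = 0.5 * (-15000.0 + -3000.0)
        at_tm = np.interp(68.0, m.temperature, m.signal)
        assert at_tm == pytest.approx(mid, rel=1e-12)
        assert np.all(np.diff(m.signal) > 0)

    def test_charge_series_monotone_and_roundtrip(self):
        mz = tk.simulate_charge_series(8096.1, [5, 6, 7, 8])
        assert mz.size == 4
        assert np.all(np.diff(mz) < 0)  # descending m/z with ascending charge
        est = tk.deconvolve_charge_series(mz)
        assert est.mass == pytest.approx(8096.1, abs=1e-9)

    def test_single_charge_has_one_peak(self):
        mz = tk.simulate_charge_series(8096.1, [7])
        assert mz.size == 1
        with pytest.raises(ValueError):
            tk.deconvolve_charge_series(mz)


def brute_force_stem(seq: str) -> int:
    """Independent oracle: longest contiguous terminal WC duplex leaving a
    >= 3 nt loop, found by scanning fold pairings directly."""
    n = len(seq)
    best = 0
    for s in range(1, (n - 3) // 2 + 1):
        ok = all(_WC[seq[i]] == seq[n - 1 - i] for i in range(s))
        if ok:
            best = s
        else:
            break
    return best


class TestHairpin:
    def test_printed_25mer_folds_to_10bp_stem(self):
        assert tk.hairpin_stem("GCGTACATCATTCCCTGATGTACGC") == (10, 5)

    def test_printed_35mer_folds_to_15bp_stem(self):
        assert tk.hairpin_stem("GCATAGCGTACATCATTCCCTGATGTACGCTATGC") == (15, 5)

    def test_homopolymer_has_no_hairpin(self):
        with pytest.raises(tk.NoHairpinError):
            tk.hairpin_stem("AAAAAAA")

    def test_bad_alphabet_and_short_input(self):
        with pytest.raises(ValueError, match="non-ACGT"):
            tk.hairpin_stem("GCGTNCGC")
        with pytest.raises(ValueError, match="7 nt"):
            tk.hairpin_stem("GCGCGC")

    def test_agrees_with_brute_force_scan(self, rng):
        bases = np.array(list("ACGT"))
        for _ in range(200):
            n = int(rng.integers(7, 40))
            seq = "".join(rng.choice(bases, n))
            expected = brute_force_stem(seq)
            if expected == 0:
                with pytest.raises(tk.NoHairpinError):
                    tk.hairpin_stem(seq)
            else:
                stem, loop = tk.hairpin_stem(seq)
                assert stem == expected
                assert loop == n - 2 * stem and loop >= 3
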