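"""Tests of the fixed-time-step lattice simulator."""

import numpy as np
import pytest

from motorlattice.analytic import bound_distribution_limited, bound_distribution_unlimited
from motorlattice.lattice import (
    LatticeState,
    SimulationConfig,
    StallNotReachedError,
    estimate_stall_force,
    initial_width_rule,
    initialize,
    run,
    step,
)
from motorlattice.parameters import MotorParameters


def quiet_motor(**kw):
    """Motor that neither steps nor exchanges unless overridden."""
    defaults = dict(p=0.0, q=0.0, delta=0.5, k_on=0.0, k_off=0.0, dx=8.0)
    defaults.update(kw)
    return MotorParameters(**defaults)


class TestInitialize:
    def test_width_rule(self):
        assert initial_width_rule(2) == 10
        assert initial_width_rule(9) == 10
        assert initial_width_rule(10) == 20
        assert initial_width_rule(100) == 110

    def test_processive_distinct_positions_in_width(self, kinesin, rng):
        cfg = SimulationConfig(scenario="processive", N=8, n_steps=10, burn_in=1)
        state = initialize(cfg, kinesin, rng)
        assert state.bound.all()
        assert np.unique(state.positions).size == 8
        assert state.positions.min() >= 0 and state.positions.max() <= 9
        assert state.leader == int(np.argmax(state.positions))

    def test_nonprocessive_starts_unbound(self, ncd, rng):
        cfg = SimulationConfig(scenario="B", N=10, n_steps=10, burn_in=1)
        state = initialize(cfg, ncd, rng)
        assert not state.bound.any()
        assert state.window == (0, initial_width_rule(10) - 1)

    def test_scenario_a_window_is_m_fixed(self, ncd, rng):
        cfg = SimulationConfig(scenario="A", N=4, M_fixed=25, n_steps=10, burn_in=1)
        state = initialize(cfg, ncd, rng)
        assert state.window == (0, 24)

    def test_same_seed_same_state(self, kinesin):
        cfg = SimulationConfig(scenario="processive", N=5, n_steps=10, burn_in=1)
        s1 = initialize(cfg, kinesin, np.random.default_rng(7))
        s2 = initialize(cfg, kinesin, np.random.default_rng(7))
        np.testing.assert_array_equal(s1.positions, s2.positions)

    def test_overfull_width_rejected(self, kinesin, rng):
        cfg = SimulationConfig(
            scenario="processive", N=8, n_steps=10, burn_in=1, initial_width=5
        )
        with pytest.raises(ValueError):
            initialize(cfg, kinesin, rng)


class TestConfigValidation:
    def test_unknown_scenario(self):
        with pytest.raises(ValueError):
            SimulationConfig(scenario="C", N=1)

    def test_scenario_a_needs_window(self):
        with pytest.raises(ValueError):
            SimulationConfig(scenario="A", N=2)

    def test_rate_dt_warning_and_error(self, kinesin):
        cfg = SimulationConfig(scenario="processive", N=1, f=0.0, dt=2e-3,
                               n_steps=10, burn_in=1)
        with pytest.warns(UserWarning, match="0.1"):
            cfg.validate_rates(kinesin)
        bad = SimulationConfig(scenario="processive", N=1, f=0.0, dt=2e-2,
                               n_steps=10, burn_in=1)
        with pytest.raises(ValueError, match="exceeds 1"):
            bad.validate_rates(kinesin)


class TestStep:
    def test_single_motor_mean_displacement(self, rng):
        """A lone bound motor with q = 0 advances p*dt sites per step on
        average (Bernoulli stepping)."""
        prm = quiet_motor(p=80.0)
        cfg = SimulationConfig(scenario="processive", N=1, dt=1e-3,
                               n_steps=10, burn_in=1)
        state = LatticeState(np.array([0]), np.array([True]), (0, 9), 0)
        n, total = 4000, 0
        for _ in range(n):
            new = step(state, prm, cfg, rng)
            total += int(new.positions[0] - state.positions[0])
            state = new
        mean = total / n
        assert mean == pytest.approx(0.08, abs=3 * np.sqrt(0.08 / n))

    def test_exclusion_blocks_trailing_motor(self, rng):
        """With deterministic forward attempts, motors stay distinct and
        ordered: a move onto an occupied site fails silently."""
        prm = quiet_motor(p=1000.0)  # p*dt = 1: always attempts
        cfg = SimulationConfig(scenario="processive", N=3, dt=1e-3,
                               n_steps=10, burn_in=1)
        state = LatticeState(np.array([0, 1, 2]), np.ones(3, bool), (0, 9), 2)
        for _ in range(200):
            state = step(state, prm, cfg, rng)
            state.check_invariants("processive")
            assert np.all(np.diff(np.sort(state.positions)) >= 1)
        # trailing motors are throttled by exclusion: the column stays compact
        assert 2 <= state.positions.max() - state.positions.min() <= 20

    @pytest.mark.parametrize("bound_idx,expected_offset", [(0, 1), (1, -1)])
    def test_scenario_b_end_extension_sites(self, rng, bound_idx, expected_offset):
        """With one motor bound at x, the other may only bind at the single
        end-extension site: x+1 if its index is above, x-1 if below."""
        prm = quiet_motor(k_on=900.0, k_off=0.0)
        cfg = SimulationConfig(scenario="B", N=2, dt=1e-3, n_steps=10, burn_in=1)
        landing = set()
        for trial in range(60):
            positions = np.array([50, 50])
            bound = np.zeros(2, bool)
            bound[bound_idx] = True
            state = LatticeState(positions, bound, (45, 55), bound_idx)
            while not state.bound.all():
                state = step(state, prm, cfg, rng)
            other = 1 - bound_idx
            landing.add(int(state.positions[other]))
        assert landing == {50 + expected_offset}

    def test_scenario_b_sequence_preserved_under_churn(self, ncd, rng):
        cfg = SimulationConfig(scenario="B", N=6, f=1.0, dt=1e-3, n_steps=10,
                               burn_in=1)
        state = initialize(cfg, ncd, rng)
        for _ in range(3000):
            state = step(state, ncd, cfg, rng)
            state.check_invariants("B")
            bp = state.positions[state.bound]
            assert np.all(np.diff(bp) > 0)  # index order == position order

    def test_scenario_a_binding_stays_in_window(self, ncd, rng):
        cfg = SimulationConfig(scenario="A", N=5, M_fixed=12, dt=1e-3,
                               n_steps=10, burn_in=1)
        state = initialize(cfg, ncd, rng)
        prm = ncd.with_(p=0.0, q=0.0)  # binding only: window is static
        for _ in range(2000):
            state = step(state, prm, cfg, rng)
            state.check_invariants("A")
            if state.n_bound:
                bp = state.positions[state.bound]
                assert bp.min() >= state.window[0]
                assert bp.max() <= state.window[1]


class TestRun:
    def test_deterministic_given_seed(self, ncd):
        cfg = SimulationConfig(scenario="B", N=3, f=1.0, n_steps=20_000,
                               burn_in=1000, n_runs=3, seed=99)
        r1 = run(cfg, ncd)
        r2 = run(cfg, ncd)
        for a, b in zip(r1.replicates, r2.replicates):
            np.testing.assert_array_equal(a.episode_velocities, b.episode_velocities)
            np.testing.assert_array_equal(a.occupancy_counts, b.occupancy_counts)
            np.testing.assert_array_equal(a.run_lengths, b.run_lengths)

    def test_processive_single_motor_velocity(self, kinesin):
        """Biased random walk: end-to-end velocity equals p - q within 3 SE."""
        cfg = SimulationConfig(scenario="processive", N=1, f=0.0,
                               n_steps=400_000, burn_in=1000, n_runs=6, seed=5)
        v, se, _ = run(cfg, kinesin).velocity()
        assert abs(v - 90.0) < 3 * se

    def test_occupancy_normalizes(self, ncd):
        cfg = SimulationConfig(scenario="B", N=4, f=0.0, n_steps=50_000,
                               burn_in=2500, n_runs=3, seed=17)
        probs, _ = run(cfg, ncd).occupancy()
        assert probs.sum() == pytest.approx(1.0)
        assert probs.size == 5

    def test_scenario_b_small_cluster_matches_unlimited(self, ncd):
        """N=2 occupancy follows the unlimited binomial: the end-extension
        sites mean a partner site is always available."""
        cfg = SimulationConfig(scenario="B", N=2, f=0.0, n_steps=400_000,
                               burn_in=2500, n_runs=6, seed=23)
        probs, se = run(cfg, ncd).occupancy()
        expected = bound_distribution_unlimited(ncd, 2).probs
        for n in range(3):
            assert abs(probs[n] - expected[n]) < 4 * se[n]

    def test_scenario_a_occupancy_matches_limited_distribution(self, ncd):
        cfg = SimulationConfig(scenario="A", N=6, M_fixed=10, f=0.0,
                               n_steps=300_000, burn_in=2500, n_runs=6, seed=29)
        probs, se = run(cfg, ncd).occupancy()
        expected = bound_distribution_limited(ncd, 6, 10).probs
        for n in range(7):
            assert abs(probs[n] - expected[n]) < 4 * max(se[n], 1e-4)

    def test_run_length_sign_structure(self, ncd):
        """Under load, single Ncd runs are often backward; a ten-motor
        cluster almost always moves forward."""
        cfg1 = SimulationConfig(scenario="B", N=1, f=2.0, n_steps=300_000,
                                burn_in=2500, n_runs=4, seed=31)
        runs1 = run(cfg1, ncd).run_values()
        nonzero1 = runs1[runs1 != 0]
        assert nonzero1.size > 500
        assert (nonzero1 < 0).mean() > 0.2

        cfg10 = SimulationConfig(scenario="B", N=10, f=2.0, n_steps=2_000_000,
                                 burn_in=2500, n_runs=8, seed=37)
        runs10 = run(cfg10, ncd).run_values()
        assert runs10.size > 20
        assert (runs10 < 0).mean() < 0.05
        assert runs10.mean() > 0

    def test_absent_observables_reported_as_absent(self, kinesin):
        """Processive runs complete no episodes or attachment periods."""
        cfg = SimulationConfig(scenario="processive", N=2, f=0.0,
                               n_steps=5000, burn_in=100, n_runs=2, seed=3)
        res = run(cfg, kinesin)
        v, se, n = res.run_length()
        assert n == 0 and np.isnan(v)
        assert res.replicates[0].run_length_mean is None
        assert res.replicates[0].episode_velocity_mean is None


def test_trajectory_dump_roundtrip(tmp_path, ncd):
    import gzip

    from motorlattice.lattice import dump_trajectory

    cfg = SimulationConfig(scenario="B", N=3, f=0.0, n_steps=5000,
                           burn_in=100, n_runs=1, seed=8)
    path = tmp_path / "traj.tsv.gz"
    dump_trajectory(cfg, ncd, str(path), n_steps=50)
    with gzip.open(path, "rt") as fh:
        header = fh.readline().strip().split("\t")
        rows = [line.strip().split("\t") for line in fh]
    assert header == ["step", "time_s", "motor_index", "position_site",
                      "bound_flag", "is_leader"]
    assert len(rows) == 50 * 3
    assert {r[2] for r in rows} == {"0", "1", "2"}


class TestStallEstimation:
    def test_processive_single_motor(self, kinesin):
        cfg = SimulationConfig(scenario="processive", N=1, n_steps=150_000,
                               burn_in=1000, n_runs=4, seed=41)
        fs = estimate_stall_force(kinesin, cfg, f_grid=np.arange(0.0, 2.81, 0.4))
        assert fs == pytest.approx(np.log(10.0), abs=0.25)

    def test_threshold_never_met_signals(self, kinesin):
        cfg = SimulationConfig(scenario="processive", N=1, n_steps=30_000,
                               burn_in=1000, n_runs=2, seed=43)
        with pytest.raises(StallNotReachedError) as exc:
            estimate_stall_force(kinesin, cfg, f_grid=[0.0, 0.5, 1.0])
        assert np.isfinite(exc.value.last_velocity)

    def test_rejects_degenerate_grid(self, kinesin):
        cfg = SimulationConfig(scenario="processive", N=1, n_steps=1000,
                               burn_in=10, n_runs=1)
        with pytest.raises(ValueError):
            estimate_stall_force(kinesin, cfg, f_grid=[1.0])
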