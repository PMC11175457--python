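import numpy as np
import pytest

import s2w._kernel as K
from s2w.control import seated_hold_config
from s2w.engine import (DelayBuffer, SimulationEngine, Trajectory,
                        delayed_value, detect_fall, detect_steps)
from s2w.scenario import (ScenarioConfig, chair_position, seated_posture,
                          simulate_scenario)


class TestDetectFall:
    def test_below_threshold(self):
        assert detect_fall(0.59, 1.0) is True

    def test_above_threshold(self):
        assert detect_fall(0.61, 1.0) is False

    def test_boundary_is_not_fall(self):
        assert detect_fall(0.60, 1.0) is False

    def test_invalid_initial(self):
        with pytest.raises(ValueError):
            detect_fall(0.5, 0.0)


class TestDelayBuffer:
    def test_constant_channel(self):
        buf = DelayBuffer()
        for t in np.arange(0, 1.0, 0.01):
            buf.append("c", t, 5.0)
        for t, d in [(0.5, 0.1), (0.9, 0.055), (0.2, 0.0)]:
            assert delayed_value(buf, "c", t, d) == pytest.approx(5.0)

    def test_shifted_ramp(self):
        buf = DelayBuffer()
        for t in np.arange(0, 1.5, 0.01):
            buf.append("s", t, t)
        assert delayed_value(buf, "s", 1.0, 0.035) == pytest.approx(0.965)

    def test_hold_at_start(self):
        buf = DelayBuffer()
        for t in np.arange(0, 1.0, 0.01):
            buf.append("s", t, 3.0 + t)
        assert delayed_value(buf, "s", 0.0, 0.05) == pytest.approx(3.0)
        assert delayed_value(buf, "s", 0.02, 0.5) == pytest.approx(3.0)

    def test_unknown_channel(self):
        buf = DelayBuffer()
        buf.append("a", 0.0, 1.0)
        with pytest.raises(KeyError):
            delayed_value(buf, "b", 0.0, 0.0)

    def test_interpolation_error_order(self):
        """Quadratic signal: linear interpolation error is O(dt^2)."""
        buf = DelayBuffer()
        dt = 0.01
        for t in np.arange(0, 2.0, dt):
            buf.append("q", t, t * t)
        err = abs(delayed_value(buf, "q", 1.5, 0.0351) - (1.5 - 0.0351) ** 2)
        assert err < dt * dt

    def test_out_of_order_rejected(self):
        buf = DelayBuffer()
        buf.append("a", 1.0, 0.0)
        with pytest.raises(ValueError):
            buf.append("a", 0.5, 0.0)


class TestForwardStep:
    def test_uniform_motion_without_forces(self, engine, model):
        q0 = model.standing_posture().to_q()
        qd0 = np.zeros(11)
        qd0[0] = 0.5
        traj = engine.rollout(q0, qd0, gravity=0.0, enable_contact=False,
                              enable_muscles=False, t_max=1.0, fall_ratio=0.0)
        assert traj.coordinate("pelvis_tx")[-1] == pytest.approx(0.5, abs=1e-9)
        assert np.allclose(traj.col("qd_pelvis_tx"), 0.5)

    def test_passive_pendulum_energy_drift(self, frictionless_engine):
        """Leg swinging as a passive double pendulum: < 1% drift over 5 s."""
        eng = frictionless_engine
        model = eng.model
        q0 = model.standing_posture().to_q()
        q0[1] = 3.0   # high above the ground, no contact
        q0[model.coordinate_index("hip_r")] = np.radians(60)
        q0[model.coordinate_index("knee_r")] = np.radians(20)
        locked = [c for c in model.coordinates if c not in ("hip_r", "knee_r")]
        traj = eng.rollout(q0, locked=locked, enable_contact=False,
                           enable_muscles=False, t_max=5.0, fall_ratio=0.0)
        E = np.array([eng.total_energy(row[1:12], row[12:23])
                      for row in traj.data])
        drift = (E.max() - E.min()) / abs(E[0])
        assert drift < 0.01

    def test_static_grf_equals_weight(self, engine, model):
        """Vertical drop onto the ground: settled GRF = body weight."""
        q0 = model.standing_posture().to_q()
        locked = [c for c in model.coordinates if c != "pelvis_ty"]
        traj = engine.rollout(q0, locked=locked, enable_muscles=False,
                              t_max=2.0, fall_ratio=0.0)
        grf = traj.grf("r")[-1, 1] + traj.grf("l")[-1, 1]
        assert grf == pytest.approx(75 * 9.81, rel=0.02)


class TestSimulate:
    def test_zero_excitation_seated_hold(self, engine, model):
        """Zero muscle excitation + trunk servos: stays seated for 12 s with
        positive seat force throughout."""
        sc = ScenarioConfig()
        traj = simulate_scenario(engine, sc, controller=seated_hold_config())
        assert traj.end_time == pytest.approx(12.0, abs=0.02)
        assert not traj.fell
        assert traj.seat_force[:, 1].min() > 0.0

    def test_max_time_truncation(self, engine, model):
        sc = ScenarioConfig(max_time=1.0)
        traj = simulate_scenario(engine, sc, controller=seated_hold_config())
        assert traj.end_time == pytest.approx(1.0, abs=0.02)

    def test_destructive_controller_falls(self, engine, model):
        """A controller that yanks the trunk down triggers the fall rule."""
        cfg = seated_hold_config()
        cfg["p1.lumbar.KP"] = 2000.0
        cfg["p1.lumbar.Q0"] = -1.0
        cfg["p1.thoracic.KP"] = 2000.0
        cfg["p1.thoracic.Q0"] = -1.0
        for side in ("r", "l"):
            cfg[f"p1.{side}.ILIAC.C0"] = 1.0
            cfg[f"p1.{side}.PSOAS.C0"] = 1.0
            cfg[f"p1.{side}.HAM.C0"] = 1.0
        sc = ScenarioConfig()
        traj = simulate_scenario(engine, sc, controller=cfg)
        assert traj.fell
        assert traj.end_time < 12.0

    def test_determinism(self, engine, model):
        sc = ScenarioConfig()
        t1 = simulate_scenario(engine, sc, controller=seated_hold_config(),
                               )
        t2 = simulate_scenario(engine, sc, controller=seated_hold_config(),
                               )
        assert np.array_equal(t1.data, t2.data)

    def test_momentum_balance(self, engine, model):
        """Sum of external forces tracks mass * COM acceleration (within 1%
        of body weight at every sample)."""
        sc = ScenarioConfig()
        traj = simulate_scenario(engine, sc, controller=seated_hold_config())
        bw = model.total_mass * 9.81
        fext = traj.data[:, K.COL_FEXT:K.COL_FEXT + 2]
        macc = traj.data[:, K.COL_MACOM:K.COL_MACOM + 2]
        err = np.hypot(*(fext - macc).T)
        assert np.percentile(err, 99) < 0.01 * bw


class TestTrajectoryIO:
    def test_csv_roundtrip(self, engine, model, tmp_path):
        sc = ScenarioConfig(max_time=1.0)
        traj = simulate_scenario(engine, sc, controller=seated_hold_config())
        path = tmp_path / "traj.csv"
        traj.write_csv(path)
        back = Trajectory.read_csv(path)
        assert back.fell == traj.fell
        assert np.allclose(back.data, traj.data, atol=1e-9)
        assert list(back.phase) == list(traj.phase)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            Trajectory(np.zeros((0, K.NCOLS)), 0.01, False)


class TestStepDetection:
    def _make_traj(self, heel_r):
        n = len(heel_r)
        data = np.zeros((n, K.NCOLS))
        data[:, K.COL_T] = np.arange(n) * 0.01
        data[:, K.COL_HEEL_R] = heel_r
        return Trajectory(data, 0.01, False)

    def test_step_after_unloaded_interval(self):
        f = np.zeros(100)
        f[:20] = 100.0       # loaded
        f[60:] = 100.0       # loads again after 0.4 s unloaded
        traj = self._make_traj(f)
        events = detect_steps(traj)
        assert len(events) == 1
        assert events[0] == (pytest.approx(0.60), "r")

    def test_short_unload_ignored(self):
        f = np.full(100, 100.0)
        f[50:53] = 0.0       # 30 ms dip < 50 ms minimum
        traj = self._make_traj(f)
        assert detect_steps(traj) == []

    def test_initial_unloaded_then_loading_counts(self):
        f = np.zeros(100)
        f[10:] = 100.0
        # unloaded from t=0 for 100 ms then loads: a step event
        traj = self._make_traj(f)
        assert len(detect_steps(traj)) == 1
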