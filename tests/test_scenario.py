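import math

import numpy as np
import pytest

import s2w._kernel as K
from s2w import scenario as S
from s2w.control import seated_hold_config
from s2w.engine import Trajectory
from s2w.model import COORDINATES


class TestLoadScenario:
    def test_normal_seat_fixture(self):
        sc = S.load_scenario(S.default_scenario_dir() / "normal_seat.yaml")
        assert sc.seat_height == pytest.approx(0.44)

    def test_low_seat_fixture(self):
        sc = S.load_scenario(S.default_scenario_dir() / "low_seat.yaml")
        assert sc.seat_height == pytest.approx(0.35)

    def test_asym_fixture(self):
        sc = S.load_scenario(S.default_scenario_dir() / "asym_feet.yaml")
        assert sc.foot_offset_r == pytest.approx(-0.10)
        assert sc.foot_offset_l == 0.0

    def test_unknown_key_rejected(self, tmp_path):
        p = tmp_path / "bad.yaml"
        p.write_text("seat_height: 0.44\nbanana: 1\n")
        with pytest.raises(ValueError, match="banana"):
            S.load_scenario(p)

    def test_incomplete_posture_rejected(self, tmp_path):
        p = tmp_path / "bad.yaml"
        p.write_text("seat_height: 0.44\nposture:\n  pelvis_tx: 0.0\n")
        with pytest.raises(Exception, match="pelvis_ty"):
            S.load_scenario(p)

    def test_invalid_seat_height(self):
        with pytest.raises(ValueError):
            S.ScenarioConfig(seat_height=0.0)


class TestSeatedPosture:
    def test_knee_near_90(self, model):
        p = S.seated_posture(model, S.ScenarioConfig())
        assert p["knee_r"] == pytest.approx(90.0, abs=8.0)
        assert p["knee_l"] == p["knee_r"]

    def test_low_seat_deeper_flexion(self, model):
        p44 = S.seated_posture(model, S.ScenarioConfig(seat_height=0.44))
        p35 = S.seated_posture(model, S.ScenarioConfig(seat_height=0.35))
        assert p35["knee_r"] > p44["knee_r"]

    def test_feet_flat_on_ground(self, model):
        p = S.seated_posture(model, S.ScenarioConfig())
        q = p.to_q()
        poses = model.body_transforms(q)
        for side in ("r", "l"):
            th, _ = poses[f"foot_{side}"]
            assert abs(th) < 1e-9

    def test_asymmetric_offsets(self, model):
        sc = S.ScenarioConfig(foot_offset_r=-0.10)
        p = S.seated_posture(model, sc)
        q = p.to_q()
        poses = model.body_transforms(q)
        ankle_r = model._joint_world_center(poses, model.pin_joints["foot_r"])
        ankle_l = model._joint_world_center(poses, model.pin_joints["foot_l"])
        assert ankle_r[0] - ankle_l[0] == pytest.approx(-0.10, abs=1e-6)

    def test_explicit_posture_override(self, model):
        posture = {c: 0.0 for c in COORDINATES}
        posture["pelvis_ty"] = 0.7
        sc = S.ScenarioConfig()
        sc.posture = S.Posture(posture)
        p = S.seated_posture(model, sc)
        assert p["pelvis_ty"] == 0.7


class TestTrunkAngle:
    def _traj(self, tilt=0.0, lumbar=0.0, thoracic=0.0, n=100):
        data = np.zeros((n, K.NCOLS))
        data[:, K.COL_T] = np.arange(n) * 0.01
        from s2w.engine import TRAJ_COLUMNS
        data[:, TRAJ_COLUMNS.index("q_pelvis_tilt")] = tilt
        data[:, TRAJ_COLUMNS.index("q_lumbar")] = lumbar
        data[:, TRAJ_COLUMNS.index("q_thoracic")] = thoracic
        return Trajectory(data, 0.01, False)

    def test_vertical_torso(self):
        assert S.peak_trunk_angle(self._traj()) == pytest.approx(0.0)

    def test_constant_pitch(self):
        # anterior pelvis tilt of 30 deg pitches the whole trunk forward
        traj = self._traj(tilt=math.radians(30.0))
        assert S.peak_trunk_angle(traj) == pytest.approx(30.0)

    def test_lumbar_flexion_adds_forward_lean(self):
        traj = self._traj(lumbar=math.radians(-20.0))
        assert S.peak_trunk_angle(traj) == pytest.approx(20.0)

    def test_sinusoidal_peak(self):
        n = 200
        t = np.arange(n) * 0.01
        amp = math.radians(25.0)
        traj = self._traj(tilt=amp * np.sin(2 * np.pi * t), n=n)
        assert S.peak_trunk_angle(traj) == pytest.approx(25.0, rel=1e-3)

    def test_phase_selection_missing_phase(self):
        traj = self._traj()
        with pytest.raises(ValueError):
            S.peak_trunk_angle(traj, "GAIT")


class TestJointLoad:
    @pytest.fixture(scope="class")
    def seated_traj(self, engine, model):
        sc = S.ScenarioConfig(max_time=3.0)
        return S.simulate_scenario(engine, sc,
                                   controller=seated_hold_config())

    def test_static_hip_load_positive(self, engine, model, seated_traj):
        load = S.joint_reaction_load(seated_traj, model, "hip_r")
        assert np.all(load >= 0)

    def test_ankle_load_tracks_grf_when_static(self, engine, model,
                                               seated_traj):
        """Settled seated: ankle load ~ |GRF on foot - foot weight| plus
        crossing muscle forces (small here)."""
        load = S.joint_reaction_load(seated_traj, model, "ankle_r")
        grf = seated_traj.grf("r")[:, 1]
        foot_w = model.segments["foot_r"].mass * 9.81
        i = len(load) - 10
        crossing = sum(
            seated_traj.data[i, K.COL_FM + mi]
            for mi, name in enumerate(
                __import__("s2w.engine", fromlist=["MUSCLES_RL"]).MUSCLES_RL)
            if name in ("GAS_r", "SOL_r", "TA_r"))
        assert load[i] == pytest.approx(grf[i] - foot_w + crossing, rel=0.5)

    def test_zero_gravity_static_no_muscle_zero_load(self, engine, model):
        q0 = model.standing_posture().to_q()
        locked = list(model.coordinates)
        traj = engine.rollout(q0, locked=locked, gravity=0.0,
                              enable_contact=False, enable_muscles=False,
                              t_max=0.5, fall_ratio=0.0)
        load = S.joint_reaction_load(traj, model, "knee_r", gravity=0.0)
        assert np.all(load[2:-2] < 1e-6)

    def test_muscle_tension_adds_to_load(self, engine, model):
        """Constant excitation of a single-joint muscle increases the load
        roughly by its tension."""
        q0 = model.standing_posture().to_q()
        locked = list(model.coordinates)
        u = np.zeros(20)
        from s2w.engine import MUSCLES_RL
        vas = MUSCLES_RL.index("VAS_r")
        traj0 = engine.rollout(q0, locked=locked, gravity=0.0,
                               enable_contact=False, t_max=0.5,
                               fall_ratio=0.0, u_const=u)
        u[vas] = 0.8
        traj1 = engine.rollout(q0, locked=locked, gravity=0.0,
                               enable_contact=False, t_max=0.5,
                               fall_ratio=0.0, u_const=u)
        load0 = S.joint_reaction_load(traj0, model, "knee_r")[-5]
        load1 = S.joint_reaction_load(traj1, model, "knee_r")[-5]
        tension = traj1.data[-5, K.COL_FM + vas]
        assert tension > 100.0
        assert load1 - load0 == pytest.approx(tension, rel=0.2)


class TestCompareConditions:
    def test_identical_zero(self):
        s = {"peak": 100.0, "other": 2.0}
        assert all(v == 0.0 for v in S.compare_conditions(s, s).values())

    def test_fifteen_percent(self):
        assert S.compare_conditions({"m": 100.0}, {"m": 115.0})["m"] == \
            pytest.approx(15.0)

    def test_antisymmetry_up_to_base_change(self):
        a, b = {"m": 100.0}, {"m": 120.0}
        fwd = S.compare_conditions(a, b)["m"]
        rev = S.compare_conditions(b, a)["m"]
        assert fwd == pytest.approx(20.0)
        assert rev == pytest.approx(-fwd * 100.0 / 120.0)

    def test_non_numeric_skipped(self):
        out = S.compare_conditions({"leg": "r", "m": 1.0},
                                   {"leg": "l", "m": 2.0})
        assert "leg" not in out


class TestResultIO:
    def test_write_and_recompute(self, engine, model, tmp_path):
        from s2w.objectives import MeasureConfig, evaluate
        sc = S.ScenarioConfig(max_time=1.5)
        traj = S.simulate_scenario(engine, sc,
                                   controller=seated_hold_config())
        rep = evaluate(traj, model, MeasureConfig(corridor=None))
        summary = S.summarize(traj, model)
        bundle = S.ResultBundle(traj, rep, summary,
                                controller=seated_hold_config())
        files = S.write_results(bundle, tmp_path / "out")
        assert (tmp_path / "out" / "trajectory.csv").exists()
        assert (tmp_path / "out" / "best.par").exists()
        back = Trajectory.read_csv(tmp_path / "out" / "trajectory.csv")
        summary2 = S.summarize(back, model)
        for k, v in summary.items():
            if isinstance(v, float):
                assert summary2[k] == pytest.approx(v, rel=1e-6, abs=1e-9), k
            else:
                assert summary2[k] == v, k

    def test_phase_labels_roundtrip(self, engine, model, tmp_path):
        cfg = seated_hold_config()
        cfg["T1"] = 0.4
        cfg["T2"] = 0.8
        sc = S.ScenarioConfig(max_time=1.2)
        traj = S.simulate_scenario(engine, sc, controller=cfg)
        p = tmp_path / "t.csv"
        traj.write_csv(p)
        back = Trajectory.read_csv(p)
        assert set(back.phase) == {0, 1, 2}
        assert np.array_equal(back.phase, traj.phase)

    def test_empty_trajectory_refused(self, tmp_path):
        import s2w._kernel as K2
        data = np.zeros((1, K2.NCOLS))
        traj = Trajectory(data, 0.01, False)
        from s2w.objectives import ObjectiveReport
        bundle = S.ResultBundle(traj, ObjectiveReport(), {})
        with pytest.raises(ValueError):
            S.write_results(bundle, tmp_path / "x")
        assert not (tmp_path / "x" / "trajectory.csv").exists()
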