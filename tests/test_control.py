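import numpy as np
import pytest

import s2w._kernel as K
from s2w import control as C


class TestLatencyDerivation:
    def test_monosynaptic_sol(self):
        assert C.derive_monosynaptic_latency("SOL") == 35

    def test_monosynaptic_gmax(self):
        assert C.derive_monosynaptic_latency("GMAX") == 10

    def test_monosynaptic_rfem(self):
        assert C.derive_monosynaptic_latency("RFEM") == 20

    def test_monosynaptic_ham(self):
        assert C.derive_monosynaptic_latency("HAM") == 15

    def test_unknown_muscle(self):
        with pytest.raises(KeyError):
            C.derive_monosynaptic_latency("DELTOID")

    def test_antagonistic_gmax_iliac(self):
        assert C.derive_antagonistic_latency("GMAX", "ILIAC") == 10

    def test_antagonistic_ham_vas_half_up(self):
        # mean(15, 20) = 17.5 rounds up to 20
        assert C.derive_antagonistic_latency("HAM", "VAS") == 20

    def test_antagonistic_ta_sol(self):
        assert C.derive_antagonistic_latency("TA", "SOL") == 35

    def test_vestibular_gmax_floor(self):
        # 55 - 35/2 + 10/2 = 42.5 floors to 40
        assert C.derive_vestibular_latency("GMAX") == 40

    def test_vestibular_ta(self):
        assert C.derive_vestibular_latency("TA") == 55

    def test_vestibular_ham(self):
        assert C.derive_vestibular_latency("HAM") == 45

    def test_vestibular_lumbar(self):
        assert C.derive_vestibular_latency("lumbar") == 35

    def test_vestibular_thoracic(self):
        assert C.derive_vestibular_latency("thoracic") == 30

    def test_full_table_reproduction(self):
        assert C.latency_table() == C.REFERENCE_LATENCIES

    def test_all_entries_multiples_of_5(self):
        for key, val in C.latency_table().items():
            vals = val if isinstance(val, tuple) else (val,)
            assert all(v % 5 == 0 for v in vals), key


class TestReflexExcitation:
    def test_constant_only(self):
        p = C.ReflexPathway("VAS", "VAS", c0=0.1)
        assert C.reflex_excitation(p, 1.0, 0.0, 0.0) == pytest.approx(0.1)

    def test_length_term(self):
        p = C.ReflexPathway("VAS", "VAS", k_l=0.5, l0=1.0)
        assert C.reflex_excitation(p, 1.3, 0.0, 0.0) == pytest.approx(0.15)

    def test_force_term(self):
        p = C.ReflexPathway("VAS", "VAS", k_f=0.2)
        assert C.reflex_excitation(p, 1.0, 0.5, 0.0) == pytest.approx(0.10)

    def test_inhibitory_negation(self):
        p = C.ReflexPathway("VAS", "HAM", k_l=0.5, l0=1.0, inhibitory=True)
        assert C.reflex_excitation(p, 1.3, 0.0, 0.0) == pytest.approx(-0.15)


class TestVestibularExcitation:
    def test_zero_at_reference(self):
        p = C.VestibularPathway("GMAX", k_p=2.0, theta0=0.1)
        assert C.vestibular_excitation(p, 0.1, 0.0) == 0.0

    def test_proportional(self):
        p = C.VestibularPathway("GMAX", k_p=2.0)
        assert C.vestibular_excitation(p, 0.1, 0.0) == pytest.approx(0.2)

    def test_antagonist_routing_signs(self):
        """Positive tilt error excites extensors, inhibits flexors equally."""
        assert C.VESTIBULAR_SIGN["GMAX"] == +1
        assert C.VESTIBULAR_SIGN["ILIAC"] == -1
        ext = C.VestibularPathway("GMAX", k_p=2.0, sign=+1)
        flx = C.VestibularPathway("ILIAC", k_p=2.0, sign=-1)
        assert C.vestibular_excitation(ext, 0.1, 0.0) == \
            -C.vestibular_excitation(flx, 0.1, 0.0)


class TestGaitStateMachine:
    def test_loaded_stance(self):
        assert C.gait_state_update(K.ST_STANCE, 0.5, 0.5, 0.1) == K.ST_STANCE

    def test_unloading_to_liftoff(self):
        assert C.gait_state_update(K.ST_STANCE, 0.05, 0.5, 0.1) == K.ST_LIFTOFF

    def test_no_liftoff_when_contra_unloaded(self):
        assert C.gait_state_update(K.ST_STANCE, 0.05, 0.05, 0.1) == K.ST_STANCE

    def test_liftoff_to_swing(self):
        assert C.gait_state_update(K.ST_LIFTOFF, 0.0, 0.5, 0.1) == K.ST_SWING

    def test_swing_to_stance_on_loading(self):
        assert C.gait_state_update(K.ST_SWING, 0.3, 0.2, 0.1) == K.ST_STANCE

    def test_dwell_blocks_transition(self):
        assert C.gait_state_update(K.ST_STANCE, 0.0, 0.5, 0.1,
                                   dwell_ok=False) == K.ST_STANCE

    def test_periodic_load_gives_periodic_states(self):
        """Synthetic periodic loads produce a periodic state sequence with
        the load period and no chatter."""
        t = np.arange(0, 4, 0.01)
        period = 1.0
        load = 0.5 * (1 + np.sin(2 * np.pi * t / period))
        contra = 0.5 * (1 + np.sin(2 * np.pi * t / period + np.pi))
        state, states = K.ST_STANCE, []
        dwell = 0
        for li, ci in zip(load, contra):
            new = C.gait_state_update(state, li, ci, 0.1, dwell_ok=dwell <= 0)
            if new != state:
                dwell = 2
                state = new
            dwell -= 1
            states.append(state)
        states = np.array(states)
        first, second = states[100:200], states[200:300]
        assert np.array_equal(first, second)
        assert set(states) == {K.ST_STANCE, K.ST_LIFTOFF, K.ST_SWING}
        # no chatter: few transitions per cycle
        assert np.count_nonzero(np.diff(states[:100])) <= 3


class TestControllerConfig:
    def test_default_count_is_551(self):
        cfg = C.default_config()
        assert C.count_free_parameters(cfg) == 551

    def test_symmetric_mode_shares_leg_parameters(self):
        cfg = C.default_config("symmetric")
        # 551 = 2*(2*108 + 7) + 2*48 + 6 + 3 in per-leg mode; symmetric mode
        # halves every per-side muscle block: 2*(108 + 7) + 48 + 6 + 3
        assert C.count_free_parameters(cfg) == 287

    def test_minimal_enumeration_example(self):
        """One muscle, one phase, mono pathway only -> C0 + KL + KF + KV."""
        cfg = C.default_config()
        mono = [p for p in cfg.names()
                if p.startswith("p1.r.HAM.mono.") or p == "p1.r.HAM.C0"]
        assert len(mono) == 4

    def test_starred_gait_gains_not_state_split(self):
        cfg = C.default_config()
        names = cfg.names()
        # SOL/GAS force gains and the TA pathways carry one gain, not three
        assert "gait.r.SOL.KF" in names
        assert "gait.r.SOL.KF_st" not in names
        assert "gait.r.TA.KL" in names
        # BFSH/RFEM modulate per state
        for st in ("st", "lo", "sw"):
            assert f"gait.r.BFSH.KL_{st}" in names

    def test_phase_schedule_ordering(self):
        cfg = C.default_config()
        cfg["T1"] = 2.0
        cfg["T2"] = 1.0
        assert cfg.t2 > cfg.t1

    def test_value_clipping(self):
        cfg = C.default_config()
        cfg["p1.r.HAM.C0"] = 7.0
        assert cfg["p1.r.HAM.C0"] == 1.0

    def test_set_values_roundtrip(self, rng):
        cfg = C.default_config()
        lo, hi = cfg.bounds()
        x = lo + (hi - lo) * rng.uniform(0.1, 0.9, len(lo))
        cfg.set_values(x)
        assert np.allclose(cfg.values(), x)

    def test_delays_are_on_5ms_grid(self):
        cfg = C.default_config()
        for p in cfg.pathways:
            assert p.delay_ms % 5 == 0
            assert 0 <= p.delay_ms <= 55

    def test_parameter_file_roundtrip(self, tmp_path):
        cfg = C.default_config()
        cfg["p2.l.VAS.C0"] = 0.321
        path = tmp_path / "test.par"
        cfg.save(path)
        cfg2 = C.default_config()
        cfg2.load(path)
        assert np.allclose(cfg2.values(), cfg.values())

    def test_parameter_file_rejects_unknown(self, tmp_path):
        path = tmp_path / "bad.par"
        path.write_text("nonsense\t1\t0.1\t0\t2\n")
        with pytest.raises(ValueError, match="nonsense"):
            C.default_config().load(path)

    def test_seated_hold_has_no_muscle_drive(self):
        cfg = C.seated_hold_config()
        for name in cfg.names():
            if name.endswith(".C0"):
                assert cfg[name] == 0.0


class TestControllerStep:
    """Pathway evaluation through the packed arrays (kernel contract)."""

    def test_phase_schedule(self, engine, model):
        from s2w.scenario import (ScenarioConfig, chair_position,
                                  seated_posture)
        cfg = C.seated_hold_config()
        cfg["T1"] = 0.5
        cfg["T2"] = 1.0
        sc = ScenarioConfig()
        posture = seated_posture(model, sc)
        traj = engine.rollout(posture.to_q(), controller=cfg,
                              box_pos=chair_position(model, sc, posture),
                              t_max=2.0, fall_ratio=0.0)
        t = traj.time
        ph = traj.phase
        assert np.all(ph[t < 0.5] == 0)
        assert np.all(ph[(t >= 0.51) & (t < 1.0)] == 1)
        assert np.all(ph[t >= 1.01] == 2)
        assert np.count_nonzero(np.diff(ph)) == 2

    def test_constant_c0_yields_constant_excitation(self, engine, model):
        from s2w.scenario import (ScenarioConfig, chair_position,
                                  seated_posture)
        cfg = C.seated_hold_config()
        for name in cfg.names():
            if name.startswith("p1.") and name.endswith(".C0"):
                cfg[name] = 0.25
        cfg["T1"] = 3.0
        sc = ScenarioConfig()
        posture = seated_posture(model, sc)
        traj = engine.rollout(posture.to_q(), controller=cfg,
                              box_pos=chair_position(model, sc, posture),
                              t_max=0.5, fall_ratio=0.0)
        assert np.allclose(traj.excitations[1:], 0.25)

    def test_trunk_torque_saturation(self, engine, model):
        from s2w.scenario import (ScenarioConfig, chair_position,
                                  seated_posture)
        cfg = C.seated_hold_config()
        cfg["p1.lumbar.KP"] = 2000.0
        cfg["p1.lumbar.Q0"] = -1.0    # demands ~2000 N*m at start
        sc = ScenarioConfig()
        posture = seated_posture(model, sc)
        traj = engine.rollout(posture.to_q(), controller=cfg,
                              box_pos=chair_position(model, sc, posture),
                              t_max=0.3, fall_ratio=0.0)
        tau = traj.col("tau_lumbar")
        assert np.max(np.abs(tau)) <= 1000.0 + 1e-9
        assert np.max(np.abs(tau)) == pytest.approx(1000.0)

    def test_excitations_clamped(self, engine, model):
        from s2w.scenario import (ScenarioConfig, chair_position,
                                  seated_posture)
        cfg = C.default_config()
        for name in cfg.names():
            if name.endswith(".C0"):
                cfg[name] = 1.0
            if ".mono.KL" in name:
                cfg[name] = 10.0
        sc = ScenarioConfig()
        posture = seated_posture(model, sc)
        traj = engine.rollout(posture.to_q(), controller=cfg,
                              box_pos=chair_position(model, sc, posture),
                              t_max=0.5, fall_ratio=0.0)
        assert np.all(traj.excitations >= 0.0)
        assert np.all(traj.excitations <= 1.0)
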