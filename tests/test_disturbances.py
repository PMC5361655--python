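"""Disturbance protocols: grids, physics, and trial isolation."""

import numpy as np
import pytest

from reflexwalk.disturbances import (
    DisturbanceSpec,
    condition_grid,
    run_protocol,
    run_trial,
)


class TestConditionGrids:
    def test_grid_counts_and_spacing(self):
        for proto, n in (("MMR", 16), ("TR", 16), ("SR", 8)):
            g = condition_grid(proto)
            assert len(g) == n
            np.testing.assert_allclose(np.diff(g), 1.0 / n)
        trip = condition_grid("TRIP")
        assert trip[0] == pytest.approx(0.05)
        assert trip[-1] == pytest.approx(0.75)
        slip = condition_grid("SLIP")
        np.testing.assert_allclose(slip, [0.1, 0.2, 0.3, 0.4, 0.5])

    def test_hammer_energy_arithmetic(self):
        spec = DisturbanceSpec("TR", hammer_mass=0.090, hammer_speed=1.5)
        assert spec.hammer_energy == pytest.approx(0.10125)

    def test_unknown_protocol_rejected(self):
        with pytest.raises(ValueError):
            DisturbanceSpec("SHAKE")


class TestTendonTap:
    def test_stretch_inversely_proportional_to_tension(self, walker,
                                                       params097, snap097):
        """Tap the quadriceps at two phases with different tension: the
        imposed stretch scales as 1/tension (below the cap)."""
        T = snap097.stride_period
        t_base = snap097.state.t + T
        dur = 2.2 * T + 0.7
        und, _ = walker.simulate(params097, dur, state=snap097.state)
        results = []
        for frac in (0.05, 0.3):
            t0 = t_base + frac * T
            spec = DisturbanceSpec("TR", t0=t0, leg=0, muscle="VAS")
            tr = run_trial(walker, params097, snap097, spec, duration=dur,
                           undisturbed=und)
            # imposed stretch stored by the kernel at tap onset
            dl = tr.disturbed.misc[5]
            i = np.searchsorted(und.t, t0)
            F = und.force_afferent(0, "VAS")[i] * walker.MF[4, 0]
            results.append((dl, F))
        (dl1, F1), (dl2, F2) = results
        cap = 0.05 * walker.MF[4, 1]
        assert F1 > 0 and F2 > 0 and F1 != pytest.approx(F2, rel=0.05)
        for dl, F in results:
            if dl < cap * 0.999:
                assert dl == pytest.approx(spec.hammer_energy / F, rel=0.05)
        if dl1 < 0.999 * cap and dl2 < 0.999 * cap:
            assert dl1 * F1 == pytest.approx(dl2 * F2, rel=0.1)

    def test_tap_evokes_response_in_tapped_muscle(self, walker, params097,
                                                  snap097):
        T = snap097.stride_period
        t0 = snap097.state.t + T * 1.3
        spec = DisturbanceSpec("TR", t0=t0, leg=0, muscle="VAS")
        tr = run_trial(walker, params097, snap097, spec,
                       duration=2.2 * T + 0.7)
        from reflexwalk.analysis import extract_response

        resp = extract_response(tr.response_trace("VAS"))
        assert resp != 0.0


class TestStretchReflex:
    def test_ramp_achieves_8_degrees_in_32_ms(self, walker, params097,
                                              snap097):
        T = snap097.stride_period
        t0 = snap097.state.t + T * 1.25
        spec = DisturbanceSpec("SR", t0=t0, leg=0)
        tr = run_trial(walker, params097, snap097, spec,
                       duration=2.2 * T + 0.7, rec_dt=5e-4)
        t = tr.disturbed.t
        i0 = np.searchsorted(t, t0)
        i1 = np.searchsorted(t, t0 + 0.032)
        ach = tr.disturbed.ankle_angle(0)[i1] - tr.disturbed.ankle_angle(0)[i0]
        assert np.rad2deg(ach) == pytest.approx(8.0, abs=0.2)

    def test_sol_lengthening_velocity_exceeds_undisturbed(self, walker,
                                                          params097, snap097):
        T = snap097.stride_period
        t0 = snap097.state.t + T * 1.25
        spec = DisturbanceSpec("SR", t0=t0, leg=0)
        tr = run_trial(walker, params097, snap097, spec,
                       duration=2.2 * T + 0.7)
        t = tr.disturbed.t
        sel = (t >= t0 + 0.002) & (t <= t0 + 0.032)
        # velocity afferent is shortening-positive: lengthening is negative
        v_dist = tr.disturbed.velocity_afferent(0, "SOL")[sel]
        v_und = tr.undisturbed.velocity_afferent(0, "SOL")[sel]
        assert v_dist.min() < v_und.min() - 0.1


class TestTrip:
    def test_early_vs_late_swing_distinct_response_timing(self, walker,
                                                          params097, snap097):
        trials = run_protocol(walker, params097, snap097, "TRIP",
                              conditions=[0.15, 0.35])
        assert len(trials) == 2
        t_peaks = []
        for tr in trials:
            # a hard trip may end the trial early; compare the overlap
            n = min(len(tr.disturbed.t), len(tr.undisturbed.t))
            d = np.abs(tr.disturbed.activation(0, "TA")[:n]
                       - tr.undisturbed.activation(0, "TA")[:n])
            t_peaks.append(tr.onset)
            assert d.max() > 0.005  # the obstacle does evoke a response
        assert abs(t_peaks[1] - t_peaks[0]) > 0.1

    def test_unrealizable_geometry_excluded(self, walker, params097,
                                            snap097):
        trials = run_protocol(walker, params097, snap097, "TRIP",
                              conditions=[0.4],
                              spec_kw={"obstacle_height": 1e-4})
        assert trials == []


class TestSlip:
    def test_onset_150ms_after_detected_heel_strike(self, walker, params097,
                                                    snap097):
        T = snap097.stride_period
        spec = DisturbanceSpec("SLIP", t0=snap097.state.t + T, leg=0,
                               delta_v=0.3)
        tr = run_trial(walker, params097, snap097, spec,
                       duration=2.2 * T + 0.7)
        onset = tr.disturbed.misc[7]
        assert onset > 0
        hs = tr.disturbed.heel_strikes[0]
        hs_before = hs[hs <= onset + 1e-9]
        assert len(hs_before) > 0
        assert onset - hs_before[-1] == pytest.approx(0.150,
                                                      abs=walker.dt + 1e-9)

    def test_backward_tangential_impulse_grows_with_delta_v(
            self, walker, params097, snap097):
        """Belt speed-up under the loaded foot drags it backward; the
        tangential impulse is negative and grows with the speed change."""
        T = snap097.stride_period
        dur = 2.2 * T + 0.7
        und, _ = walker.simulate(params097, dur, state=snap097.state)
        impulses = []
        for dv in (0.1, 0.3, 0.5):
            spec = DisturbanceSpec("SLIP", t0=snap097.state.t + T, leg=0,
                                   delta_v=dv)
            tr = run_trial(walker, params097, snap097, spec, duration=dur,
                           undisturbed=und)
            onset = tr.disturbed.misc[7]
            t = tr.disturbed.t
            sel = (t >= onset) & (t <= onset + 0.15)
            dt_rec = t[1] - t[0]
            imp = np.sum((tr.disturbed.grf(0)[sel, 0]
                          - tr.undisturbed.grf(0)[sel, 0])) * dt_rec
            impulses.append(imp)
        assert all(i < 0 for i in impulses)
        assert impulses[0] > impulses[1] > impulses[2]


class TestTrialIsolation:
    def test_trials_do_not_accumulate_state(self, walker, params097,
                                            snap097):
        """Each trial restarts from the snapshot: running one disturbance
        does not alter a subsequent trial."""
        T = snap097.stride_period
        spec = DisturbanceSpec("MMR", t0=snap097.state.t + 1.3 * T, leg=0)
        a = run_trial(walker, params097, snap097, spec, duration=1.0)
        _ = run_trial(walker, params097, snap097,
                      DisturbanceSpec("SR", t0=snap097.state.t + 1.25 * T,
                                      leg=0), duration=1.0)
        b = run_trial(walker, params097, snap097, spec, duration=1.0)
        np.testing.assert_array_equal(a.disturbed.rec, b.disturbed.rec)

    def test_periodicity_of_evoked_responses(self, walker, params097,
                                             snap097):
        """Pulses one stride apart in steady gait evoke similar responses
        (limit-cycle periodicity, loose tolerance)."""
        from reflexwalk.analysis import extract_response

        T = snap097.stride_period
        dur = 3.3 * T + 0.7
        r = []
        for k in (1, 2):
            spec = DisturbanceSpec("MMR", t0=snap097.state.t + (k + 0.3) * T,
                                   leg=0)
            tr = run_trial(walker, params097, snap097, spec, duration=dur)
            r.append(extract_response(tr.response_trace("SOL")))
        assert r[0] != 0
        assert r[1] == pytest.approx(r[0], rel=0.35, abs=0.05)
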