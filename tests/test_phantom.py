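import numpy as np
import pandas as pd
import pytest

import oispec as o
from oispec.errors import ConfigurationError, ValidationError
from oispec.phantom import (
    DEFAULT_RESPONSES,
    experiment_events,
    stimulus_regressor,
)


class TestDefaultProtocol:
    def test_printed_timings(self):
        p = o.default_protocol()
        assert p["exp1"].total_length_s == 750.0
        assert p["exp2"].total_length_s == 750.0
        assert p["exp5"].total_length_s == 1050.0
        assert p["exp7"].total_length_s == 1050.0
        assert p["exp8"].total_length_s == 750.0
        assert p["exp3"].gas_switch_s == 105.0

    def test_total_stimulation_trials(self):
        assert o.default_protocol().total_stim_trials == 120

    def test_trial_geometry(self):
        p = o.default_protocol()
        e1, e5 = p["exp1"], p["exp5"]
        assert (e1.n_trials, e1.trial_length_s, e1.stim_onset_s,
                e1.stim_duration_s, e1.stim_rate_hz) == (30, 25.0, 5.0, 2.0, 5.0)
        assert (e5.n_trials, e5.trial_length_s, e5.stim_onset_s,
                e5.stim_duration_s) == (15, 70.0, 10.0, 16.0)

    def test_frame_count_arithmetic(self):
        p = o.default_protocol()
        assert int(p["exp1"].total_length_s * 8.0) == 6000

    def test_invalid_experiment_rejected(self):
        with pytest.raises(ValidationError):
            o.ExperimentSpec("bad", "stim2s_oxygen", total_length_s=100.0,
                             n_trials=5, trial_length_s=25.0, stim_onset_s=5.0,
                             stim_duration_s=2.0, stim_rate_hz=5.0)

    def test_events_per_trial(self):
        ev = experiment_events(o.default_protocol()["exp1"])
        assert (ev["kind"] == "stim_train_on").sum() == 30
        # 2 s at 5 Hz -> 10 deflections per trial
        assert (ev["kind"] == "stim_pulse").sum() == 300


class TestMakePhantom:
    def test_deterministic_given_seed(self):
        a = o.make_phantom(shape=(48, 48), seed=9)
        b = o.make_phantom(shape=(48, 48), seed=9)
        assert np.array_equal(a.artery_mask, b.artery_mask)
        assert np.array_equal(a.vein_mask, b.vein_mask)

    def test_compartments_disjoint_and_nonempty(self, phantom48):
        assert not (phantom48.artery_mask & phantom48.vein_mask).any()
        assert not (phantom48.artery_mask & phantom48.parenchyma_mask).any()
        for m in (phantom48.artery_mask, phantom48.vein_mask,
                  phantom48.parenchyma_mask, phantom48.active_mask):
            assert m.any()

    def test_window_scale_metadata(self):
        ph = o.make_phantom(shape=(184, 184))
        assert ph.pixel_um == 75.0
        # circular window spans ~92% of the grid
        assert ph.window_diameter_mm == pytest.approx(
            0.92 * 184 * 75.0 / 1000.0, rel=0.05)

    def test_grid_too_small_rejected(self):
        with pytest.raises(ConfigurationError):
            o.make_phantom(shape=(16, 16))


class TestEvokedTimecourse:
    COND = o.ConditionSpec("WT-like", "chronic")

    def _single_stim_events(self, dur_s):
        rows = [(5.0, "stim_train_on", "")]
        rows += [(5.0 + j / 5.0, "stim_pulse", "") for j in range(int(dur_s * 5))]
        rows.append((5.0 + dur_s, "stim_train_off", ""))
        return pd.DataFrame(rows, columns=["time_s", "kind", "value"])

    def test_no_events_gives_zero(self):
        ev = pd.DataFrame(columns=["time_s", "kind", "value"])
        hbt, hbr = o.evoked_timecourse(ev, DEFAULT_RESPONSES["artery"],
                                       self.COND, "air", 30.0)
        assert not hbt.any() and not hbr.any()

    def test_air_undershoot_oxygen_none(self):
        ev = self._single_stim_events(2.0)
        hbt_air, _ = o.evoked_timecourse(ev, DEFAULT_RESPONSES["artery"],
                                         self.COND, "air", 30.0)
        hbt_oxy, _ = o.evoked_timecourse(ev, DEFAULT_RESPONSES["artery"],
                                         self.COND, "oxygen", 30.0)
        assert hbt_air.min() < 0          # biphasic: post-stimulus undershoot
        assert hbt_air.max() > 0
        assert hbt_oxy.min() >= -1e-12    # monotone return to baseline

    def test_longer_drive_larger_peak(self):
        """Convolution with a non-negative kernel is monotone in the
        drive: the 16 s response peak cannot fall below the 2 s peak."""
        p = DEFAULT_RESPONSES["parenchyma"]
        h2, _ = o.evoked_timecourse(self._single_stim_events(2.0), p,
                                    self.COND, "oxygen", 60.0)
        h16, _ = o.evoked_timecourse(self._single_stim_events(16.0), p,
                                     self.COND, "oxygen", 60.0)
        assert h16.max() >= h2.max()

    def test_hbr_negative_going_with_lag(self):
        ev = self._single_stim_events(2.0)
        hbt, hbr = o.evoked_timecourse(ev, DEFAULT_RESPONSES["vein"],
                                       self.COND, "oxygen", 40.0)
        assert hbr.min() < 0
        assert np.argmin(hbr) > np.argmax(hbt)

    def test_evoked_scale_applies(self):
        ev = self._single_stim_events(2.0)
        weak = o.ConditionSpec("AD-like", "acute", csd_amplitude=0.2,
                               evoked_scale=0.5)
        full, _ = o.evoked_timecourse(ev, DEFAULT_RESPONSES["artery"],
                                      self.COND, "oxygen", 30.0)
        half, _ = o.evoked_timecourse(ev, DEFAULT_RESPONSES["artery"],
                                      weak, "oxygen", 30.0)
        assert np.allclose(half, 0.5 * full)


class TestCsdPerturbation:
    def test_chronic_is_identity(self):
        cond = o.ConditionSpec("WT-like", "chronic")
        assert np.array_equal(o.csd_perturbation(cond, 100.0, 8.0),
                              np.ones(800))

    def test_ad_like_dip_exceeds_wt_like(self):
        wt = o.ConditionSpec.default("WT-like", "acute")
        ad = o.ConditionSpec.default("AD-like", "acute")
        m_wt = o.csd_perturbation(wt, 10.0, 8.0)
        m_ad = o.csd_perturbation(ad, 10.0, 8.0)
        assert abs(1.0 - m_ad[0]) > abs(1.0 - m_wt[0])

    def test_recovery_envelope_closed_form(self):
        """By the end of a session the damped-cosine envelope
        A exp(-t/tau) has shrunk below 1%."""
        ad = o.ConditionSpec.default("AD-like", "acute")
        t_end = 3600.0
        envelope = ad.csd_amplitude * np.exp(-t_end / ad.csd_recovery_tau_s)
        assert envelope < 0.01
        m = o.csd_perturbation(ad, 10.0, 8.0, t0_s=t_end)
        assert np.abs(m - 1.0).max() < 0.01

    def test_chronic_with_amplitude_rejected(self):
        with pytest.raises(ValidationError):
            o.ConditionSpec("WT-like", "chronic", csd_amplitude=0.1)


class TestSimulateSession:
    def test_bit_identical_given_seed(self, phantom48, reduced_proto,
                                      ext_table, paths_fast):
        cond = o.ConditionSpec.default("WT-like", "chronic")
        a = o.simulate_session(phantom48, reduced_proto, cond, ext_table,
                               paths_fast, seed=21, experiments=("exp1",))
        b = o.simulate_session(phantom48, reduced_proto, cond, ext_table,
                               paths_fast, seed=21, experiments=("exp1",))
        assert np.array_equal(a.intensities["exp1"], b.intensities["exp1"])
        assert np.array_equal(a.dark_frames["gap1"], b.dark_frames["gap1"])

    def test_frame_counts_match_protocol(self, chronic_recording,
                                         reduced_proto):
        for exp in reduced_proto.experiments:
            movie = chronic_recording.intensities[exp.exp_id]
            assert movie.shape[1] == int(exp.total_length_s * 8.0)
            assert movie.shape[0] == 4

    def test_full_length_exp1_has_6000_frames(self, phantom48, ext_table,
                                              paths_fast, noisefree_phantom):
        cond = o.ConditionSpec.default("WT-like", "chronic")
        rec = o.simulate_session(noisefree_phantom, o.default_protocol(),
                                 cond, ext_table, paths_fast, seed=1,
                                 experiments=("exp1",))
        assert rec.intensities["exp1"].shape[1] == 6000

    def test_intensities_nonnegative_and_events_in_range(
            self, chronic_recording, reduced_proto):
        for exp_id, movie in chronic_recording.intensities.items():
            assert (movie >= 0).all()
            ev = chronic_recording.experiment_events(exp_id)
            if len(ev):
                assert ev["time_s"].max() <= reduced_proto[exp_id].total_length_s

    def test_truth_carried_with_session(self, chronic_recording):
        t1 = chronic_recording.truth["exp1"]
        assert t1.evoked["artery"][0].any()
        assert len(t1.components) >= 3


class TestStimulusRegressor:
    def test_boxcar_duration(self):
        ev = experiment_events(o.reduced_protocol()["exp1"])
        r = stimulus_regressor(ev, 100.0, 8.0)
        assert r.sum() == pytest.approx(4 * 2.0 * 8.0)  # 4 trials x 2 s
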