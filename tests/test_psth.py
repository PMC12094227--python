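import numpy as np
import pytest

from omispike import psth, synth


class TestComputePsth:
    def test_delta_train(self):
        events = np.arange(10.0, 20.0)
        p = psth.compute_psth(events.copy(), events, window=(-0.05, 0.05))
        peak = p.rate[p.bin_centers > 0][0]  # the [0, 10 ms) bin
        assert peak == pytest.approx(100.0)
        assert p.rate.sum() == pytest.approx(100.0)

    def test_linearity_exact(self, rng):
        events = np.arange(5.0, 50.0, 1.0)
        a = np.sort(rng.uniform(0, 50, 300))
        b = np.sort(rng.uniform(0, 50, 200))
        merged = np.sort(np.concatenate([a, b]))
        w = (-0.2, 0.2)
        pa = psth.compute_psth(a, events, w).rate
        pb = psth.compute_psth(b, events, w).rate
        pm = psth.compute_psth(merged, events, w).rate
        assert np.allclose(pm, pa + pb)

    def test_homogeneous_rate_within_poisson_error(self, rng):
        spikes = synth.homogeneous_poisson_train(5.0, 1000.0, rng)
        events = np.arange(1.0, 999.0, 1.0)
        p = psth.compute_psth(spikes, events, window=(-0.25, 0.25))
        se = np.sqrt(5.0 / (0.01 * events.size))
        assert np.all(np.abs(p.rate - 5.0) < 4 * se + 1e-9)

    def test_empty_train_and_zero_events(self):
        p = psth.compute_psth(np.array([]), np.array([1.0, 2.0]), (-0.1, 0.1))
        assert np.all(p.rate == 0) and p.zero_variance
        with pytest.raises(ValueError):
            psth.compute_psth(np.array([1.0]), np.array([]), (-0.1, 0.1))


class TestRampingIndex:
    def test_log2_values(self):
        z = np.r_[np.full(10, 1.0), np.zeros(5), np.full(10, 3.0)]
        ri, re, rl, ok = psth.ramping_index(z)
        assert ok and ri == pytest.approx(1.0) and re == 1.0 and rl == 3.0
        z2 = np.r_[np.zeros(10), np.zeros(5), np.ones(10)]
        assert psth.ramping_index(z2)[0] == pytest.approx(0.0)

    def test_undefined_when_not_increasing(self):
        z = np.ones(25)
        ri, _, _, ok = psth.ramping_index(z)
        assert not ok and np.isnan(ri)

    def test_window_too_short(self):
        with pytest.raises(ValueError):
            psth.ramping_index(np.ones(10))


class TestOmissionModulation:
    def test_step_archetype_up(self, sched_dense):
        u = synth.generate_units(
            sched_dense, [synth.UnitSpec(synth.DEFAULT_TEMPLATES["hippocampal_step"], 1)],
            noise=synth.NoiseConfig(0.0, 0.0), seed=31,
        )[0]
        m = psth.omission_modulation(u, sched_dense)
        assert m.sign_class == "up" and m.delta_z > 0

    def test_sustained_archetype_down(self, sched_dense):
        u = synth.generate_units(
            sched_dense, [synth.UnitSpec(synth.DEFAULT_TEMPLATES["sustained_on"], 1)],
            noise=synth.NoiseConfig(0.0, 0.0), seed=32,
        )[0]
        m = psth.omission_modulation(u, sched_dense)
        assert m.sign_class == "down" and m.delta_z < 0

    def test_too_few_omissions_flagged(self):
        sched = synth.generate_schedule(synth.ScheduleConfig(
            n_trials=3, omission_prob=0.0, seed=1))
        m = psth.omission_modulation(np.arange(0.0, 10.0, 0.1), sched)
        assert m.flag == "too_few_omissions" and np.isnan(m.p_value)

    def test_inverse_stimulus_omission_relation(self, archetype_session):
        sched, units = archetype_session
        stim = np.array([psth.stimulus_modulation(u, sched) for u in units])
        mod = psth.modulation_table(units, sched)
        r = np.corrcoef(stim, mod["delta_z"].to_numpy())[0, 1]
        assert r < -0.3


class TestOmissionSpecificity:
    def test_injected_preferred_omission_response(self, sched_dense):
        # tuned unit whose omission rate doubles only for its preferred image
        rng = np.random.default_rng(40)
        base = synth.homogeneous_poisson_train(4.0, sched_dense.duration_s, rng)
        pref = 3
        extras = []
        D = sched_dense.image_duration_s
        for onset, img in zip(sched_dense.presented_onsets(),
                              sched_dense.presented_images()):
            if img == pref:  # stimulus tuning
                extras.append(onset + np.sort(rng.uniform(0, D, rng.poisson(4.0))))
        for onset, img in zip(sched_dense.omission_onsets(),
                              sched_dense.omission_images()):
            if img == pref:  # omission response only for the preferred image
                extras.append(onset + np.sort(rng.uniform(0, D, rng.poisson(4.0))))
        spikes = np.sort(np.concatenate([base] + extras))
        u = synth.UnitRecord("inj", spikes, mean_rate_hz=spikes.size / sched_dense.duration_s)
        df = psth.omission_specificity([u], sched_dense)
        row = df.iloc[0]
        assert row["tuned"] and row["preferred_image"] == pref
        assert row["significant"]

    def test_insufficient_omissions_flagged(self):
        sched = synth.generate_schedule(synth.ScheduleConfig(n_trials=40, seed=2))
        rng = np.random.default_rng(41)
        # tuned unit, but almost no omissions of any single image in 40 trials
        base = synth.homogeneous_poisson_train(3.0, sched.duration_s, rng)
        extras = [o + np.sort(rng.uniform(0, 0.25, 8))
                  for o, im in zip(sched.presented_onsets(), sched.presented_images())
                  if im == 0]
        spikes = np.sort(np.concatenate([base] + extras))
        u = synth.UnitRecord("t", spikes)
        df = psth.omission_specificity([u], sched)
        row = df.iloc[0]
        if row["tuned"]:
            assert row["flag"] in (None, "too_few_omissions")
        else:
            assert row["flag"] == "untuned"
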