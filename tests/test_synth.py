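import numpy as np
import pytest
from scipy import stats

from omispike import psth, synth


class TestSchedule:
    def test_invariants(self, sched_small):
        s = sched_small
        assert np.allclose(np.diff(s.onsets), s.cycle_period_s)
        assert s.image_duration_s < s.cycle_period_s
        # every omitted slot sits strictly inside its trial and its
        # flanking presented images carry the same identity
        om = np.flatnonzero(s.omitted)
        img = s.slots["image_id"].to_numpy()
        ti = s.slots["trial_index"].to_numpy()
        for i in om:
            assert ti[i - 1] == ti[i] == ti[i + 1]
            assert img[i - 1] == img[i] == img[i + 1]
        # within a trial one image; consecutive trials differ
        per_trial = s.slots.groupby("trial_index")["image_id"].nunique()
        assert (per_trial == 1).all()
        trial_imgs = s.slots.groupby("trial_index")["image_id"].first().to_numpy()
        assert (np.diff(trial_imgs) != 0).all()

    def test_first_last_never_omitted(self, sched_small):
        s = sched_small.slots
        firsts = s.groupby("trial_index").head(1)["omitted"]
        lasts = s.groupby("trial_index").tail(1)["omitted"]
        assert not firsts.any() and not lasts.any()

    def test_omission_rate_matches_probability(self):
        sched = synth.generate_schedule(synth.ScheduleConfig(n_trials=3000, seed=5))
        eligible = sched.eligible_mask()
        n = int(eligible.sum())
        frac = sched.omitted[eligible].mean()
        half = 4 * np.sqrt(0.05 * 0.95 / n)
        assert abs(frac - 0.05) < half

    def test_zero_probability_and_determinism(self):
        sched = synth.generate_schedule(synth.ScheduleConfig(omission_prob=0.0, seed=3))
        assert sched.omitted.sum() == 0
        a = synth.generate_schedule(synth.ScheduleConfig(seed=7))
        b = synth.generate_schedule(synth.ScheduleConfig(seed=7))
        assert a.slots.equals(b.slots)

    @pytest.mark.parametrize(
        "kw",
        [dict(omission_prob=1.0), dict(repeats_min=9, repeats_max=5),
         dict(repeats_min=2), dict(n_images=1),
         dict(image_duration_s=0.8)],
    )
    def test_invalid_configs(self, kw):
        with pytest.raises(ValueError):
            synth.generate_schedule(synth.ScheduleConfig(**kw))

    def test_trial_length_distribution(self):
        sched = synth.generate_schedule(synth.ScheduleConfig(n_trials=10_000, seed=9))
        lengths = sched.slots.groupby("trial_index").size().to_numpy()
        assert lengths.min() >= 5 and lengths.max() <= 11
        obs = np.bincount(lengths, minlength=12)[5:12]
        exp = synth.truncated_geometric_pmf(0.3, 5, 11) * 10_000
        p = stats.chisquare(obs, exp).pvalue
        assert p > 1e-3


class TestUnits:
    def test_unmodulated_poisson_count(self, sched_small):
        tpl = synth.ArchetypeTemplate("unmodulated", baseline_rate=5.0, response_rate=0.0)
        units = synth.generate_units(
            sched_small, [synth.UnitSpec(tpl, 1)],
            noise=synth.NoiseConfig(0.0, 0.0), seed=2,
        )
        T = sched_small.duration_s
        n = units[0].spike_times.size
        assert abs(n - 5.0 * T) < 4 * np.sqrt(5.0 * T)

    def test_ramp_off_peaks_at_stimulus_onset(self, sched_small):
        units = synth.generate_units(
            sched_small, [synth.UnitSpec(synth.DEFAULT_TEMPLATES["ramp_off"], 1)],
            noise=synth.NoiseConfig(0.0, 0.0), seed=3,
        )
        p = psth.compute_psth(units[0], sched_small.presented_onsets(),
                              window=(0.0, sched_small.cycle_period_s), bin_s=0.05)
        # rate climbs through the ISI and is maximal in the bin ending at
        # the next stimulus onset
        assert int(np.argmax(p.rate)) == p.rate.size - 1

    def test_zero_template_zero_spikes(self, sched_small):
        tpl = synth.ArchetypeTemplate("unmodulated", baseline_rate=0.0, response_rate=0.0)
        units = synth.generate_units(sched_small, [synth.UnitSpec(tpl, 1)],
                                     noise=synth.NoiseConfig(0.0, 0.0), seed=4)
        assert units[0].spike_times.size == 0

    def test_empty_schedule_rejected(self, sched_small):
        import pandas as pd

        empty = synth.StimulusSchedule(
            sched_small.slots.iloc[:0], sched_small.cycle_period_s,
            sched_small.image_duration_s, sched_small.n_images,
        )
        with pytest.raises(ValueError):
            synth.generate_units(empty, [synth.UnitSpec(synth.DEFAULT_TEMPLATES["unmodulated"], 1)])

    def test_fano_factor_near_one(self, sched_small):
        tpl = synth.ArchetypeTemplate("unmodulated", baseline_rate=8.0, response_rate=0.0)
        u = synth.generate_units(sched_small, [synth.UnitSpec(tpl, 1)],
                                 noise=synth.NoiseConfig(0.0, 0.0), seed=5)[0]
        P = sched_small.cycle_period_s
        counts = np.diff(np.searchsorted(u.spike_times, np.append(sched_small.onsets,
                                                                  sched_small.onsets[-1] + P)))
        fano = counts.var() / counts.mean()
        # var(Fano) ~ 2/(n-1) for Poisson
        assert abs(fano - 1.0) < 4 * np.sqrt(2 / (counts.size - 1))

    def test_stim_off_untuned(self, sched_small):
        units = synth.generate_units(
            sched_small,
            [synth.UnitSpec(synth.DEFAULT_TEMPLATES["ramp_off"], 2),
             synth.UnitSpec(synth.DEFAULT_TEMPLATES["sustained_on"], 2)],
            seed=6,
        )
        assert all(np.allclose(u.tuning_gains, 1.0) for u in units[:2])
        assert not any(np.allclose(u.tuning_gains, 1.0) for u in units[2:])

    def test_determinism(self, sched_small):
        mk = lambda: synth.generate_units(
            sched_small, [synth.UnitSpec(synth.DEFAULT_TEMPLATES["sustained_on"], 2)], seed=8
        )
        a, b = mk(), mk()
        for ua, ub in zip(a, b):
            assert np.array_equal(ua.spike_times, ub.spike_times)


class TestBehavior:
    def test_pupil_median_one(self, sched_small):
        tr = synth.generate_behavior(sched_small, seed=1)
        assert np.median(tr.pupil_diameter) == 1.0

    def test_flat_when_no_slowdown(self, sched_small):
        cfg = synth.BehaviorConfig(slowdown_depth=0.0, pupil_constriction=0.0,
                                   speed_noise_sd=0.5)
        tr = synth.generate_behavior(sched_small, cfg, seed=2)
        lags, avg = psth.event_triggered_average(
            tr.timestamps, tr.running_speed, sched_small.omission_onsets(), (-0.5, 2.0)
        )
        assert np.ptp(avg) < 2.0  # noise only, no systematic dip

    def test_slowdown_minimum_after_post_omission_image(self, sched_small):
        tr = synth.generate_behavior(sched_small, seed=3)
        lags, avg = psth.event_triggered_average(
            tr.timestamps, tr.running_speed, sched_small.omission_onsets(), (-0.5, 2.5)
        )
        t_min = lags[np.argmin(avg)]
        assert t_min > sched_small.cycle_period_s  # after the next image onset
        assert t_min < 2.0
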