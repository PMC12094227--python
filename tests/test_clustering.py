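import numpy as np
import pandas as pd
import pytest

from omispike import clustering, synth


@pytest.fixture(scope="module")
def matrix(archetype_session):
    sched, units = archetype_session
    return clustering.build_response_matrix(units, sched)


class TestResponseMatrix:
    def test_identical_units_fully_correlated(self, sched_small):
        u = synth.generate_units(
            sched_small, [synth.UnitSpec(synth.DEFAULT_TEMPLATES["sustained_on"], 1)],
            seed=60,
        )[0]
        twin = synth.UnitRecord("twin", u.spike_times.copy())
        m = clustering.build_response_matrix([u, twin], sched_small)
        assert m.corr[0, 1] == pytest.approx(1.0)

    def test_corr_properties(self, matrix):
        assert np.allclose(matrix.corr, matrix.corr.T)
        assert np.allclose(np.diag(matrix.corr), 1.0)

    def test_within_archetype_correlation_exceeds_between(self, matrix, archetype_session):
        _, units = archetype_session
        arch = np.array([u.archetype for u in units])
        same = arch[:, None] == arch[None, :]
        off_diag = ~np.eye(len(units), dtype=bool)
        assert matrix.corr[same & off_diag].mean() > matrix.corr[~same].mean()

    def test_zero_variance_unit_excluded(self, sched_small):
        u = synth.generate_units(
            sched_small, [synth.UnitSpec(synth.DEFAULT_TEMPLATES["sustained_on"], 2)],
            seed=61,
        )
        silent = synth.UnitRecord("silent", np.array([]))
        with pytest.warns(UserWarning):
            m = clustering.build_response_matrix(u + [silent], sched_small)
        assert "silent" in m.excluded and len(m.unit_ids) == 2


class TestChooseK:
    def test_planted_five_archetypes(self):
        X, _ = synth.synthetic_feature_population(
            {n: 24 for n in clustering.VISUAL_ARCHETYPES}, noise_sd=0.6, seed=3)
        sel = clustering.choose_k(np.corrcoef(X), B_montecarlo=20, seed=4)
        assert sel.k_gap == 5 and sel.k_elbow == 5 and sel.k_opt == 5

    def test_single_blob_gap_is_one(self, rng):
        blob = rng.normal(size=(120, 40))
        sel = clustering.choose_k(blob, B_montecarlo=20, seed=5)
        assert sel.k_gap == 1

    def test_w_monotone_and_deterministic(self, rng):
        X = rng.normal(size=(60, 20))
        a = clustering.choose_k(X, B_montecarlo=10, seed=6)
        b = clustering.choose_k(X, B_montecarlo=10, seed=6)
        assert np.all(np.diff(a.W_k) <= 1e-9)
        assert np.array_equal(a.gap, b.gap) and a.k_opt == b.k_opt

    def test_degenerate_rows(self):
        X = np.ones((30, 5))
        sel = clustering.choose_k(X)
        assert sel.k_opt == 1 and sel.flag == "degenerate"


class TestClusterUnits:
    def test_archetype_label_recovery(self, matrix, archetype_session):
        _, units = archetype_session
        model = clustering.cluster_units(matrix, 5, seed=7)
        truth = {u.unit_id: u.archetype for u in units}
        hits = np.mean([model.semantic[int(l)] == truth[uid]
                        for uid, l in zip(model.unit_ids, model.labels)])
        assert hits >= 0.9
        assert set(model.classes.values()) == {"STIM_ON", "STIM_OFF"}

    def test_seed_stability(self, matrix):
        a = clustering.cluster_units(matrix, 5, seed=1)
        b = clustering.cluster_units(matrix, 5, seed=2)
        assert clustering.partition_overlap(a.labels, b.labels) > 0.9

    def test_duplication_invariance(self, archetype_session):
        sched, units = archetype_session
        twins = [synth.UnitRecord(u.unit_id + "_b", u.spike_times.copy())
                 for u in units]
        m = clustering.build_response_matrix(units + twins, sched)
        model = clustering.cluster_units(m, 5, seed=8)
        n = len(units)
        agree = np.mean(model.labels[:n] == model.labels[n:])
        assert agree >= 0.95

    def test_k_below_two_rejected(self, matrix):
        with pytest.raises(ValueError):
            clustering.cluster_units(matrix, 1)


class TestComposition:
    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({
            "session": rng.integers(0, 3, 300),
            "cluster": rng.integers(0, 5, 300),
            "area": rng.choice(["VISp", "VISl"], 300),
        })
        out = clustering.cluster_composition(df, "area")
        sums = out["mean"].sum(axis=1)
        assert np.allclose(sums, 1.0)

    def test_planted_even_mix(self):
        df = pd.DataFrame({
            "session": np.repeat(np.arange(10), 40),
            "cluster": np.tile([0, 1], 200),
            "area": "VISp",
        })
        out = clustering.cluster_composition(df, "area")
        assert np.allclose(out["mean"].loc["VISp"], 0.5)

    def test_single_archetype_fraction_one(self):
        df = pd.DataFrame({"session": 0, "cluster": 2, "area": ["VISp"] * 20})
        out = clustering.cluster_composition(df, "area")
        assert out["mean"].loc["VISp", 2] == 1.0


class TestDecodeTimeBin:
    def test_noiseless_linear_rate_near_zero_error(self):
        sched = synth.generate_schedule(synth.ScheduleConfig(n_trials=200, seed=70))
        events = sched.omission_onsets()
        # deterministic counts: b spikes in bin b of every omission
        spikes = []
        for e in events:
            for b in range(5):
                spikes.extend(e + 0.05 * b + 0.01 * (np.arange(b) + 0.5))
        u = synth.UnitRecord("lin", np.sort(spikes))
        mae = clustering.decode_time_bin([u], np.zeros(1), sched, seed=1)[0]
        assert np.mean(mae) < 0.1

    def test_ramp_cluster_decodes_time_better_than_sustained(self, sched_dense):
        units = synth.generate_units(
            sched_dense,
            [synth.UnitSpec(synth.ArchetypeTemplate("ramp_off", 4.0, 40.0), 12),
             synth.UnitSpec(synth.DEFAULT_TEMPLATES["sustained_on"], 12)],
            seed=71,
        )
        labels = np.r_[np.zeros(12), np.ones(12)]
        mae = clustering.decode_time_bin(units, labels, sched_dense, seed=2)
        assert np.mean(mae[0]) < np.mean(mae[1])

    def test_shuffled_rates_at_chance(self, sched_dense, rng):
        units = synth.generate_units(
            sched_dense, [synth.UnitSpec(synth.ArchetypeTemplate("ramp_off", 4.0, 40.0), 8)],
            seed=72,
        )
        shuffled = [synth.UnitRecord(u.unit_id, np.sort(
            rng.uniform(0, sched_dense.duration_s, u.spike_times.size))) for u in units]
        mae = clustering.decode_time_bin(shuffled, np.zeros(8), sched_dense, seed=3)
        chance = np.mean(np.abs(np.arange(5) - 2.0))  # always guessing the mean bin
        assert abs(np.mean(mae[0]) - chance) < 0.35


class TestCv2:
    def test_regular_and_poisson(self, rng):
        assert clustering.cv2(np.arange(0.0, 100.0, 0.1)) < 1e-9
        poisson = synth.homogeneous_poisson_train(10.0, 2000.0, rng)
        assert abs(clustering.cv2(poisson) - 1.0) < 0.1

    def test_stim_off_spontaneous_rates_higher(self, archetype_session):
        sched, units = archetype_session
        labels = np.array([0 if u.archetype in synth.STIM_ON else 1 for u in units])
        df = clustering.cluster_spontaneous_summary(units, labels, (0.0, sched.duration_s))
        on = df[df["cluster"] == 0]["spontaneous_rate_hz"].median()
        off = df[df["cluster"] == 1]["spontaneous_rate_hz"].median()
        assert off > on
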