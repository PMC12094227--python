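import numpy as np
import pytest

from omispike import coupling, synth


@pytest.fixture(scope="module")
def coupled_pop():
    units, latent = synth.generate_coupled_population(15, 10, 180.0, seed=80)
    return units, latent


class TestPopulationCoupling:
    def test_duplicate_in_sparse_population(self, rng):
        spikes = synth.homogeneous_poisson_train(10.0, 120.0, rng)
        unit = synth.UnitRecord("a", spikes)
        twin = synth.UnitRecord("b", spikes.copy())
        sparse = synth.UnitRecord("c", np.array([1.0, 60.0, 119.0]))
        res = coupling.population_coupling(unit, [unit, twin, sparse], (0.0, 120.0))
        assert res.coupling_index > 0.7

    def test_independent_units_uncoupled(self, rng):
        pop = [synth.UnitRecord(f"u{i}", synth.homogeneous_poisson_train(8.0, 120.0, rng))
               for i in range(10)]
        res = coupling.population_coupling(pop[0], pop, (0.0, 120.0))
        assert abs(res.coupling_index) < 4 / np.sqrt(12000)

    def test_stim_off_less_coupled(self, coupled_pop):
        units, _ = coupled_pop
        idx = [coupling.population_coupling(u, units, (0.0, 180.0)).coupling_index
               for u in units]
        on, off = np.median(idx[:15]), np.median(idx[15:])
        assert on > 0 > off

    def test_silent_unit_flagged(self, rng):
        pop = [synth.UnitRecord(f"u{i}", synth.homogeneous_poisson_train(8.0, 120.0, rng))
               for i in range(3)]
        silent = synth.UnitRecord("s", np.array([]))
        res = coupling.population_coupling(silent, pop + [silent], (0.0, 120.0))
        assert res.flag == "silent_unit" and np.isnan(res.coupling_index)

    def test_short_epoch_rejected(self, rng):
        pop = [synth.UnitRecord(f"u{i}", np.arange(0.0, 30.0)) for i in range(3)]
        with pytest.raises(ValueError):
            coupling.population_coupling(pop[0], pop, (0.0, 30.0))

    def test_stpr_peak_at_zero_lag_for_synchronous_unit(self, coupled_pop):
        units, _ = coupled_pop
        res = coupling.population_coupling(units[0], units, (0.0, 180.0))
        mid = res.stpr.size // 2
        assert res.stpr[mid] > res.stpr[0] and res.stpr[mid] > res.stpr[-1]

    def test_population_duplication_invariance(self, coupled_pop):
        # doubling every population train rescales the summed rate by 2;
        # the Pearson coupling index is unchanged
        units, _ = coupled_pop
        unit = units[0]
        doubled = [unit] + [synth.UnitRecord(u.unit_id + k, u.spike_times.copy())
                            for u in units[1:] for k in ("", "_b")]
        r1 = coupling.population_coupling(unit, units, (0.0, 180.0)).coupling_index
        r2 = coupling.population_coupling(unit, doubled, (0.0, 180.0)).coupling_index
        assert r2 == pytest.approx(r1, abs=1e-12)


class TestBehaviorScores:
    def _trace_from_rate(self, unit, bin_s=0.25, epoch=(0.0, 120.0)):
        counts = coupling._bin_train(unit.spike_times, epoch, bin_s)
        centers = epoch[0] + (np.arange(counts.size) + 0.5) * bin_s
        return counts / bin_s, centers

    def test_affine_and_sign_symmetry(self, rng):
        u = synth.UnitRecord("u", synth.homogeneous_poisson_train(10.0, 120.0, rng))
        rate, centers = self._trace_from_rate(u)
        tr_pos = synth.BehaviorTrace(centers, 2 * rate + 3, np.ones_like(rate))
        tr_neg = synth.BehaviorTrace(centers, -2 * rate + 3, np.ones_like(rate))
        s_pos, _ = coupling.behavior_scores(u, tr_pos, (0.0, 120.0))
        s_neg, _ = coupling.behavior_scores(u, tr_neg, (0.0, 120.0))
        assert s_pos == pytest.approx(1.0)
        assert s_neg == pytest.approx(s_pos)

    def test_independent_near_zero(self, rng):
        u = synth.UnitRecord("u", synth.homogeneous_poisson_train(10.0, 300.0, rng))
        t = np.arange(0.0, 300.0, 1 / 60)
        tr = synth.BehaviorTrace(t, rng.normal(40, 3, t.size), np.ones(t.size))
        s, _ = coupling.behavior_scores(u, tr, (0.0, 300.0))
        assert s < 0.15

    def test_constant_trace_flagged(self, rng):
        u = synth.UnitRecord("u", synth.homogeneous_poisson_train(10.0, 120.0, rng))
        t = np.arange(0.0, 120.0, 1 / 60)
        tr = synth.BehaviorTrace(t, np.full(t.size, 40.0), np.ones(t.size))
        s, p = coupling.behavior_scores(u, tr, (0.0, 120.0))
        assert np.isnan(s) and np.isnan(p)


class TestClusterCcg:
    def test_subsampling_equalizes_counts_and_self_dominates(self, coupled_pop, rng):
        units, _ = coupled_pop
        mua = {
            "on": np.sort(np.concatenate([u.spike_times for u in units[:15]])),
            "off": np.sort(np.concatenate([u.spike_times for u in units[15:]])),
        }
        targets = {
            "self_on": mua["on"],
            "indep": synth.homogeneous_poisson_train(50.0, 180.0, rng),
        }
        out = coupling.cluster_subcortical_ccg(mua, targets, (0.0, 180.0), seed=1)
        counts = {cl: out[(cl, "self_on")]["n_spikes"] for cl in ("on", "off")}
        assert counts["on"] == counts["off"]
        # the autocorrelation carries a central peak: its near-zero-lag AUC
        # exceeds the pair's own flat baseline; an independent target does not
        for key, peaked in ((("on", "self_on"), True), (("on", "indep"), False)):
            r = out[key]
            baseline = r["ccg"].mean() * np.count_nonzero(np.abs(r["lags"]) <= 0.02)
            excess = r["auc"] - baseline
            assert excess > 1.0 if peaked else abs(excess) < 1.0

    def test_shared_latent_favors_on_cluster(self, coupled_pop):
        units, _ = coupled_pop
        target_units, _ = synth.generate_coupled_population(10, 0, 180.0, seed=81)
        # same latent statistics but independent draw: use the ON cluster of
        # the *same* population as the coherent target instead
        mua = {
            "on": np.sort(np.concatenate([u.spike_times for u in units[:7]])),
            "off": np.sort(np.concatenate([u.spike_times for u in units[15:22]])),
        }
        target = {"pop": np.sort(np.concatenate([u.spike_times for u in units[7:15]]))}
        out = coupling.cluster_subcortical_ccg(mua, target, (0.0, 180.0), seed=2)
        assert out[("on", "pop")]["auc"] > out[("off", "pop")]["auc"]

    def test_empty_cluster_skipped(self, coupled_pop, rng):
        units, _ = coupled_pop
        mua = {"on": units[0].spike_times, "empty": np.array([])}
        with pytest.warns(UserWarning):
            out = coupling.cluster_subcortical_ccg(
                mua, {"t": synth.homogeneous_poisson_train(10.0, 180.0, rng)},
                (0.0, 180.0))
        assert ("empty", "t") not in out
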