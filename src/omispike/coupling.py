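"""Population coupling, behavior scores, and cluster cross-correlations.

Population coupling follows the leave-one-out scheme: the summed rate of
the N-1 other units is binned, mean-centered and smoothed with a narrow
Gaussian kernel (half-width 6 ms by default); the coupling index is the
Pearson correlation of the left-out unit's binned rate with that
population trace ("choristers" high, "soloists" low).  The spike-
triggered population rate (stPR) is the average of the same population
trace around the unit's spikes over +-0.4-s lags.  Speed and pupil
scores are the absolute Pearson correlation between a unit's
instantaneous rate and the interpolated behavior variable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.stats import pearsonr

from .synth import BehaviorTrace

__all__ = [
    "CouplingResult",
    "population_coupling",
    "behavior_scores",
    "cluster_subcortical_ccg",
]


@dataclass
class CouplingResult:
    unit_id: str
    coupling_index: float
    stpr_lags: np.ndarray
    stpr: np.ndarray
    flag: str | None = None


def _bin_train(spikes: np.ndarray, epoch: tuple[float, float], bin_s: float) -> np.ndarray:
    t0, t1 = epoch
    n = int(round((t1 - t0) / bin_s))
    edges = t0 + np.arange(n + 1) * bin_s
    counts, _ = np.histogram(spikes, bins=edges)
    return counts.astype(float)


def population_coupling(
    unit,
    population,
    epoch: tuple[float, float],
    bin_s: float = 0.010,
    smooth_halfwidth_ms: float = 6.0,
    stpr_lag_s: float = 0.4,
) -> CouplingResult:
    """Leave-one-out coupling index and spike-triggered population rate.

    ``population`` includes the unit itself or not — the unit is removed
    by identity before summing.  The Gaussian half-width is the HWHM of
    the smoothing kernel.
    """
    others = [p for p in population if p is not unit]
    if len(others) < 1:
        raise ValueError("population must contain at least 2 units")
    t0, t1 = epoch
    if t1 - t0 < 60.0:
        raise ValueError("spontaneous epoch must span at least 60 s")
    own = _bin_train(unit.spike_times, epoch, bin_s)
    uid = getattr(unit, "unit_id", "unit")
    if own.sum() == 0:
        return CouplingResult(uid, float("nan"), np.array([]), np.array([]), "silent_unit")
    pop = np.sum([_bin_train(o.spike_times, epoch, bin_s) for o in others], axis=0)
    pop = pop - pop.mean()
    sigma_bins = (smooth_halfwidth_ms / 1000.0) / (math.sqrt(2 * math.log(2)) * bin_s)
    pop = gaussian_filter1d(pop, sigma_bins)
    r = float(pearsonr(own, pop).statistic) if pop.std() > 0 else float("nan")

    k = int(round(stpr_lag_s / bin_s))
    lags = np.arange(-k, k + 1) * bin_s
    spikes = unit.spike_times
    spikes = spikes[(spikes >= t0) & (spikes < t1)]
    centers = np.floor((spikes - t0) / bin_s).astype(int)
    centers = centers[(centers >= k) & (centers < pop.size - k)]
    if centers.size:
        idx = centers[:, None] + np.arange(-k, k + 1)[None, :]
        stpr = pop[idx].mean(axis=0)
    else:
        stpr = np.full(lags.size, np.nan)
    return CouplingResult(uid, r, lags, stpr)


def behavior_scores(
    unit,
    trace: BehaviorTrace,
    epoch: tuple[float, float] | None = None,
    bin_s: float = 0.250,
) -> tuple[float, float]:
    """(speed_score, pupil_score): |Pearson r| of rate with behavior.

    Behavior variables are linearly interpolated onto the spike-rate bin
    centers.  A constant behavior trace yields NaN.
    """
    if epoch is None:
        epoch = (float(trace.timestamps[0]), float(trace.timestamps[-1]))
    counts = _bin_train(unit.spike_times, epoch, bin_s)
    centers = epoch[0] + (np.arange(counts.size) + 0.5) * bin_s
    rate = counts / bin_s
    out = []
    for values in (trace.running_speed, trace.pupil_diameter):
        v = np.interp(centers, trace.timestamps, values)
        if v.std() == 0 or rate.std() == 0:
            out.append(float("nan"))
        else:
            out.append(abs(float(pearsonr(rate, v).statistic)))
    return out[0], out[1]


def cluster_subcortical_ccg(
    cluster_mua: dict,
    target_populations: dict,
    epoch: tuple[float, float],
    bin_s: float = 0.010,
    window_s: float = 2.0,
    auc_window_s: float = 0.020,
    seed: int = 0,
) -> dict:
    """Scaled cluster-vs-area cross-correlograms and +-20-ms AUC.

    ``cluster_mua`` maps cluster -> pooled spike times; spike counts are
    equalized across clusters by random subsampling before the CCG is
    computed against each target area's pooled activity.  CCGs are
    min-max scaled per (cluster, target); the summary statistic is the
    area under the scaled CCG within ``auc_window_s`` of zero lag.
    Empty clusters are skipped with a warning.
    """
    import warnings

    rng = np.random.default_rng(seed)
    t0, t1 = epoch
    clipped = {}
    for cl, s in cluster_mua.items():
        s = np.asarray(s, dtype=float)
        clipped[cl] = s[(s >= t0) & (s < t1)]
    nonempty = {cl: s for cl, s in clipped.items() if s.size > 0}
    for cl in set(clipped) - set(nonempty):
        warnings.warn(f"cluster {cl!r} has no spikes in the epoch; skipped")
    if not nonempty:
        return {}
    n_min = min(s.size for s in nonempty.values())
    sub = {
        cl: np.sort(rng.choice(s, size=n_min, replace=False)) for cl, s in nonempty.items()
    }

    k = int(round(window_s / bin_s))
    lags = np.arange(-k, k + 1) * bin_s
    auc_mask = np.abs(lags) <= auc_window_s + 1e-12
    out = {}
    for cl, s in sub.items():
        a = _bin_train(s, epoch, bin_s)
        for area, tsp in target_populations.items():
            b = _bin_train(np.asarray(tsp, dtype=float), epoch, bin_s)
            full = np.correlate(b, a, mode="full")
            mid = b.size - 1
            ccg = full[mid - k: mid + k + 1]
            rng_span = ccg.max() - ccg.min()
            scaled = (ccg - ccg.min()) / rng_span if rng_span > 0 else np.zeros_like(ccg)
            out[(cl, area)] = {
                "lags": lags,
                "ccg": scaled,
                "auc": float(scaled[auc_mask].sum()),
                "n_spikes": int(n_min),
            }
    return out
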