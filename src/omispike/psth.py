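"""Event-aligned rate estimation and omission-modulation statistics.

A PSTH is the event-aligned, trial-averaged rate in 10-ms bins:
rate[b] = (total spike count in bin b across events) / (bin_s * n_events).
z-scored PSTHs are normalized against the unit's own mean/SD over the
full displayed window.

Omission modulation compares, per unit, the firing rate during the
omitted-stimulus window against the immediately preceding baseline
window with a two-sample Wilcoxon rank-sum test over events; the sign
class (up / down / ns) follows the z-scored rate change when the test is
significant.  The ramping index RI = log2(R_late - R_early) uses the
mean responses in the first and last 100 ms of the omitted-stimulus
window and is undefined when the late response does not exceed the early
one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synth import StimulusSchedule, UnitRecord

__all__ = [
    "Psth",
    "OmissionModulation",
    "compute_psth",
    "omission_modulation",
    "modulation_table",
    "ramping_index",
    "omission_specificity",
    "event_triggered_average",
    "event_window_rates",
]


@dataclass
class Psth:
    unit_id: str
    bin_edges: np.ndarray      # seconds relative to the alignment event
    rate: np.ndarray           # Hz per bin
    zrate: np.ndarray          # z-scored over the displayed window
    alignment: str
    n_events: int
    zero_variance: bool = False

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def _spikes_of(unit) -> np.ndarray:
    return unit.spike_times if isinstance(unit, UnitRecord) else np.asarray(unit, dtype=float)


def compute_psth(
    unit,
    events: np.ndarray,
    window: tuple[float, float],
    bin_s: float = 0.010,
    alignment: str = "omission",
    unit_id: str | None = None,
) -> Psth:
    """Event-aligned rate estimate in fixed-width bins.

    ``unit`` may be a UnitRecord or a bare spike-time array; ``window``
    is (pre_s, post_s) relative to each event, pre_s typically negative.
    """
    spikes = _spikes_of(unit)
    events = np.asarray(events, dtype=float)
    if events.size == 0:
        raise ValueError("events must be non-empty")
    pre, post = window
    n_bins = int(round((post - pre) / bin_s))
    edges = pre + np.arange(n_bins + 1) * bin_s
    counts = np.zeros(n_bins)
    lo = np.searchsorted(spikes, events + pre)
    hi = np.searchsorted(spikes, events + post)
    rel = np.concatenate(
        [spikes[a:b] - e for a, b, e in zip(lo, hi, events)]
    ) if spikes.size else np.empty(0)
    if rel.size:
        counts, _ = np.histogram(rel, bins=edges)
    rate = counts / (bin_s * events.size)
    sd = rate.std()
    zero_var = sd == 0
    zrate = np.zeros_like(rate) if zero_var else (rate - rate.mean()) / sd
    uid = unit_id or (unit.unit_id if isinstance(unit, UnitRecord) else "unit")
    return Psth(uid, edges, rate, zrate, alignment, events.size, zero_var)


def event_window_rates(spikes: np.ndarray, events: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    """Per-event firing rate: spike count in the window / window length."""
    lo = np.searchsorted(spikes, events + window[0])
    hi = np.searchsorted(spikes, events + window[1])
    return (hi - lo) / (window[1] - window[0])


@dataclass
class OmissionModulation:
    unit_id: str
    delta_z: float
    p_value: float
    sign_class: str            # up / down / ns
    RI: float                  # log2(R_late - R_early); NaN when undefined
    R_early: float
    R_late: float
    n_events: int
    ri_defined: bool = False
    flag: str | None = None


def ramping_index(zresp: np.ndarray, bin_s: float = 0.010, segment_s: float = 0.100):
    """RI = log2(R_late - R_early) over the omitted-stimulus window.

    ``zresp`` is the (z-scored) response across the omission window; the
    early/late segments are its first and last ``segment_s``.  Returns
    (RI, R_early, R_late, defined).
    """
    zresp = np.asarray(zresp, dtype=float)
    if zresp.size * bin_s < 0.2:
        raise ValueError("omission window must span at least 200 ms")
    k = max(1, int(round(segment_s / bin_s)))
    r_early = float(zresp[:k].mean())
    r_late = float(zresp[-k:].mean())
    diff = r_late - r_early
    if diff <= 0:
        return float("nan"), r_early, r_late, False
    return float(np.log2(diff)), r_early, r_late, True


def omission_modulation(
    unit,
    schedule: StimulusSchedule,
    alpha: float = 0.05,
    bin_s: float = 0.010,
) -> OmissionModulation:
    """Per-unit omission-window rate change and its significance.

    The per-event rate in the omitted-stimulus window is compared with
    the rate in the immediately preceding equal-length baseline window
    (rank-sum over events); delta_z is the mean z-scored PSTH over the
    omission window, z-scored against the full displayed window
    [-cycle, 2*cycle].
    """
    spikes = _spikes_of(unit)
    uid = unit.unit_id if isinstance(unit, UnitRecord) else "unit"
    events = schedule.omission_onsets()
    D = schedule.image_duration_s
    P = schedule.cycle_period_s
    if events.size < 2:
        return OmissionModulation(uid, float("nan"), float("nan"), "ns",
                                  float("nan"), float("nan"), float("nan"),
                                  int(events.size), False, "too_few_omissions")
    psth = compute_psth(unit, events, window=(-P, 2 * P), bin_s=bin_s, unit_id=uid)
    centers = psth.bin_centers
    om_mask = (centers >= 0) & (centers < D)
    delta_z = float(psth.zrate[om_mask].mean())

    om_rates = event_window_rates(spikes, events, (0.0, D))
    base_rates = event_window_rates(spikes, events, (-D, 0.0))
    # Mann-Whitney (= Wilcoxon rank-sum) with tie correction: spike counts
    # in short windows are heavily tied
    p = float(stats.mannwhitneyu(om_rates, base_rates,
                                 alternative="two-sided",
                                 method="asymptotic").pvalue)

    if p < alpha:
        direction = delta_z if delta_z != 0 else om_rates.mean() - base_rates.mean()
        sign = "up" if direction > 0 else "down"
    else:
        sign = "ns"
    ri, r_early, r_late, defined = ramping_index(psth.zrate[om_mask], bin_s=bin_s)
    flag = "zero_variance" if psth.zero_variance else None
    return OmissionModulation(uid, delta_z, p, sign, ri, r_early, r_late,
                              int(events.size), defined, flag)


def modulation_table(units, schedule: StimulusSchedule, alpha: float = 0.05) -> pd.DataFrame:
    rows = [omission_modulation(u, schedule, alpha=alpha) for u in units]
    return pd.DataFrame(
        {
            "unit_id": [r.unit_id for r in rows],
            "delta_z": [r.delta_z for r in rows],
            "p_value": [r.p_value for r in rows],
            "sign_class": [r.sign_class for r in rows],
            "RI": [r.RI for r in rows],
            "ri_defined": [r.ri_defined for r in rows],
        }
    )


def stimulus_modulation(unit, schedule: StimulusSchedule, alpha: float = 0.05) -> float:
    """Mean z-scored rate during presented-stimulus windows (for the
    inverse stimulus/omission relation)."""
    events = schedule.presented_onsets()
    psth = compute_psth(unit, events, window=(-schedule.cycle_period_s,
                                              schedule.cycle_period_s))
    centers = psth.bin_centers
    mask = (centers >= 0) & (centers < schedule.image_duration_s)
    return float(psth.zrate[mask].mean())


def _preferred_image(spikes, schedule: StimulusSchedule, tune_alpha: float):
    """One-vs-rest tuning: the unit is 'tuned' if exactly one image wins a
    Bonferroni-corrected one-sided rank-sum against the rest."""
    onsets = schedule.presented_onsets()
    images = schedule.presented_images()
    rates = event_window_rates(spikes, onsets, (0.0, schedule.image_duration_s))
    wins = []
    for img in range(schedule.n_images):
        a, b = rates[images == img], rates[images != img]
        if a.size < 2 or b.size < 2:
            continue
        p = stats.mannwhitneyu(a, b, alternative="greater", method="asymptotic").pvalue
        if p * schedule.n_images < tune_alpha:
            wins.append(img)
    if len(wins) == 1:
        return wins[0]
    return None


def omission_specificity(
    units,
    schedule: StimulusSchedule,
    alpha: float = 0.05,
    tune_alpha: float = 0.05,
) -> pd.DataFrame:
    """Preferred- vs non-preferred-image omission responses per tuned unit.

    For units tuned to exactly one image, compares the omission-window
    rates on trials where the omitted image is the preferred one against
    all other omissions (two-sided rank-sum).  Units that are untuned,
    or with < 2 omissions in either group, are flagged.
    """
    om_onsets = schedule.omission_onsets()
    om_images = schedule.omission_images()
    D = schedule.image_duration_s
    rows = []
    for u in units:
        spikes = _spikes_of(u)
        uid = u.unit_id if isinstance(u, UnitRecord) else "unit"
        pref = _preferred_image(spikes, schedule, tune_alpha)
        if pref is None:
            rows.append({"unit_id": uid, "preferred_image": -1, "tuned": False,
                         "p_value": float("nan"), "significant": False, "flag": "untuned"})
            continue
        rates = event_window_rates(spikes, om_onsets, (0.0, D))
        sel = om_images == pref
        a, b = rates[sel], rates[~sel]
        if a.size < 2 or b.size < 2:
            rows.append({"unit_id": uid, "preferred_image": pref, "tuned": True,
                         "p_value": float("nan"), "significant": False,
                         "flag": "too_few_omissions"})
            continue
        p = float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                     method="asymptotic").pvalue)
        rows.append({"unit_id": uid, "preferred_image": pref, "tuned": True,
                     "p_value": p, "significant": p < alpha, "flag": None})
    return pd.DataFrame(rows)


def event_triggered_average(
    timestamps: np.ndarray,
    values: np.ndarray,
    events: np.ndarray,
    window: tuple[float, float],
) -> tuple[np.ndarray, np.ndarray]:
    """Average of a sampled trace around events (for behavior dips)."""
    dt = float(np.median(np.diff(timestamps)))
    i_pre, i_post = int(round(window[0] / dt)), int(round(window[1] / dt))
    offsets = np.arange(i_pre, i_post)
    segs = []
    for e in events:
        i0 = int(round((e - timestamps[0]) / dt))
        idx = i0 + offsets
        if idx[0] < 0 or idx[-1] >= timestamps.size:
            continue
        segs.append(values[idx])
    lags = offsets * dt
    return lags, np.mean(segs, axis=0)
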