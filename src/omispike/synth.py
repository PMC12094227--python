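"""Synthetic stimulus schedules, spike trains, and behavior traces.

Emulates the statistical structure of a visual change-detection session:
a continuous stream of 250-ms natural-image presentations (eight images,
one image identity per trial, 5-11 repeats per trial drawn from a
truncated geometric distribution), stochastic 5% omissions flanked by
identical images, inhomogeneous-Poisson units drawn from a small set of
functional archetypes, and running-speed / pupil traces with a delayed
post-omission slowdown.

The archetypes mirror the functional classes seen in visual cortex:

``transient_on``
    short transient at stimulus onset (plus a smaller offset response)
``sustained_on``
    elevated rate throughout the image, slow decay after offset
``ramp_to_offset``
    rate climbs during the image, peaks at offset, decays in the ISI
``step_off_on``
    suppressed by the image, step up to an elevated rate in the ISI
``ramp_off``
    suppressed by the image, then ramps through the ISI reaching its
    maximum at the next stimulus onset; the ramp continues uninterrupted
    through an omitted presentation
``hippocampal_step``
    no image response; a step-like rate change at the expected onset of
    an omitted image, held until the post-omission image
``unmodulated``
    homogeneous Poisson at the baseline rate

STIM-ON archetypes receive per-image multiplicative tuning gains;
STIM-OFF archetypes are untuned.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ARCHETYPES",
    "STIM_ON",
    "STIM_OFF",
    "ScheduleConfig",
    "StimulusSchedule",
    "ArchetypeTemplate",
    "DEFAULT_TEMPLATES",
    "UnitSpec",
    "NoiseConfig",
    "UnitRecord",
    "BehaviorConfig",
    "BehaviorTrace",
    "generate_schedule",
    "generate_units",
    "generate_behavior",
    "archetype_omission_trace",
    "synthetic_feature_population",
    "homogeneous_poisson_train",
    "generate_synapse_pair",
    "generate_coupled_population",
]

ARCHETYPES = (
    "transient_on",
    "sustained_on",
    "ramp_to_offset",
    "step_off_on",
    "ramp_off",
    "hippocampal_step",
    "unmodulated",
)
STIM_ON = frozenset({"transient_on", "sustained_on", "ramp_to_offset"})
STIM_OFF = frozenset({"step_off_on", "ramp_off"})


# ---------------------------------------------------------------------------
# stimulus schedule
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScheduleConfig:
    """Parameters of the change-detection stimulus stream.

    Defaults are the task conditions: eight images shown for 250 ms on a
    750-ms cycle (250-ms image + 500-ms gray), 5% omission probability,
    trial lengths truncated-geometric on [5, 11].
    """

    n_images: int = 8
    image_duration_s: float = 0.25
    cycle_period_s: float = 0.75
    omission_prob: float = 0.05
    repeats_min: int = 5
    repeats_max: int = 11
    geometric_p: float = 0.3
    n_trials: int = 200
    seed: int = 0


@dataclass
class StimulusSchedule:
    """Ordered presentation slots; the clock for all event-aligned analyses.

    ``slots`` columns: onset_s, image_id, omitted, trial_index.
    """

    slots: pd.DataFrame
    cycle_period_s: float
    image_duration_s: float
    n_images: int

    @property
    def onsets(self) -> np.ndarray:
        return self.slots["onset_s"].to_numpy()

    @property
    def omitted(self) -> np.ndarray:
        return self.slots["omitted"].to_numpy(dtype=bool)

    def omission_onsets(self) -> np.ndarray:
        return self.onsets[self.omitted]

    def omission_images(self) -> np.ndarray:
        return self.slots.loc[self.slots["omitted"], "image_id"].to_numpy()

    def presented_onsets(self) -> np.ndarray:
        return self.onsets[~self.omitted]

    def presented_images(self) -> np.ndarray:
        return self.slots.loc[~self.slots["omitted"], "image_id"].to_numpy()

    def eligible_mask(self) -> np.ndarray:
        """Interior slots of each trial (first/last are never omitted)."""
        ti = self.slots["trial_index"].to_numpy()
        first = np.r_[True, ti[1:] != ti[:-1]]
        last = np.r_[ti[:-1] != ti[1:], True]
        return ~(first | last)

    @property
    def duration_s(self) -> float:
        return float(self.onsets[-1] + self.cycle_period_s)

    def validate(self) -> None:
        onsets = self.onsets
        if len(onsets) < 3:
            raise ValueError("schedule too short")
        spacing = np.diff(onsets)
        if not np.allclose(spacing, self.cycle_period_s):
            raise ValueError("onsets must be evenly spaced at cycle_period_s")
        if not self.image_duration_s < self.cycle_period_s:
            raise ValueError("image_duration_s must be < cycle_period_s")
        om = np.flatnonzero(self.omitted)
        img = self.slots["image_id"].to_numpy()
        ti = self.slots["trial_index"].to_numpy()
        for i in om:
            if i == 0 or i == len(img) - 1:
                raise ValueError("first/last slot omitted")
            if self.omitted[i - 1] or self.omitted[i + 1]:
                # allowed in principle, but flankers must still match
                pass
            if img[i - 1] != img[i] or img[i + 1] != img[i]:
                raise ValueError("omitted slot without identical flankers")
            if ti[i - 1] != ti[i] or ti[i + 1] != ti[i]:
                raise ValueError("omitted slot at trial boundary")


def generate_schedule(config: ScheduleConfig | None = None, **overrides) -> StimulusSchedule:
    """Draw a stimulus schedule.

    Trial lengths are i.i.d. truncated geometric on
    [repeats_min, repeats_max]; each trial's image differs from the
    previous trial's; each interior slot is independently omitted with
    ``omission_prob`` (first/last slots of a trial never are, which
    guarantees identical flanking images).
    """
    cfg = config if config is not None else ScheduleConfig(**overrides)
    if config is not None and overrides:
        cfg = replace(cfg, **overrides)
    if not (0.0 <= cfg.omission_prob < 1.0):
        raise ValueError("omission_prob must be in [0, 1)")
    if cfg.repeats_min > cfg.repeats_max:
        raise ValueError("repeats_min must be <= repeats_max")
    if cfg.repeats_min < 3:
        raise ValueError("repeats_min must be >= 3 (an omission needs flankers)")
    if cfg.n_images < 2:
        raise ValueError("n_images must be >= 2")
    if not cfg.image_duration_s < cfg.cycle_period_s:
        raise ValueError("image_duration_s must be < cycle_period_s")
    rng = np.random.default_rng(cfg.seed)

    ks = np.arange(cfg.repeats_min, cfg.repeats_max + 1)
    pmf = cfg.geometric_p * (1.0 - cfg.geometric_p) ** (ks - cfg.repeats_min)
    pmf = pmf / pmf.sum()
    lengths = rng.choice(ks, size=cfg.n_trials, p=pmf)

    images = np.empty(cfg.n_trials, dtype=np.int64)
    images[0] = rng.integers(cfg.n_images)
    for i in range(1, cfg.n_trials):
        step = rng.integers(1, cfg.n_images)  # never the same image twice
        images[i] = (images[i - 1] + step) % cfg.n_images

    n_slots = int(lengths.sum())
    trial_index = np.repeat(np.arange(cfg.n_trials), lengths)
    image_id = np.repeat(images, lengths)
    onset = np.arange(n_slots) * cfg.cycle_period_s
    start = np.r_[0, np.cumsum(lengths)[:-1]]
    within = np.arange(n_slots) - np.repeat(start, lengths)
    eligible = (within > 0) & (within < np.repeat(lengths, lengths) - 1)
    omitted = eligible & (rng.random(n_slots) < cfg.omission_prob)

    slots = pd.DataFrame(
        {
            "onset_s": onset,
            "image_id": image_id,
            "omitted": omitted,
            "trial_index": trial_index,
        }
    )
    sched = StimulusSchedule(
        slots=slots,
        cycle_period_s=cfg.cycle_period_s,
        image_duration_s=cfg.image_duration_s,
        n_images=cfg.n_images,
    )
    sched.validate()
    return sched


def truncated_geometric_pmf(p: float, kmin: int, kmax: int) -> np.ndarray:
    ks = np.arange(kmin, kmax + 1)
    pmf = p * (1.0 - p) ** (ks - kmin)
    return pmf / pmf.sum()


# ---------------------------------------------------------------------------
# archetype rate templates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArchetypeTemplate:
    """A functional response archetype.

    ``baseline_rate`` is the tonic rate in Hz; ``response_rate`` scales
    the stimulus/omission-modulated component (Hz at its peak).
    """

    name: str
    baseline_rate: float = 3.0
    response_rate: float = 12.0

    def __post_init__(self):
        if self.name not in ARCHETYPES:
            raise ValueError(f"unknown archetype {self.name!r}")
        if self.baseline_rate < 0 or self.response_rate < 0:
            raise ValueError("rates must be non-negative")


DEFAULT_TEMPLATES: Mapping[str, ArchetypeTemplate] = {
    "transient_on": ArchetypeTemplate("transient_on", 3.0, 30.0),
    "sustained_on": ArchetypeTemplate("sustained_on", 3.0, 14.0),
    "ramp_to_offset": ArchetypeTemplate("ramp_to_offset", 3.0, 14.0),
    # STIM-OFF classes have a higher tonic drive (reflected in higher
    # spontaneous rates, a property the analysis checks downstream)
    "step_off_on": ArchetypeTemplate("step_off_on", 7.0, 9.0),
    "ramp_off": ArchetypeTemplate("ramp_off", 7.0, 9.0),
    "hippocampal_step": ArchetypeTemplate("hippocampal_step", 5.0, 5.0),
    "unmodulated": ArchetypeTemplate("unmodulated", 5.0, 0.0),
}


def _gauss(t: np.ndarray, mu: float, sd: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - mu) / sd) ** 2)


def _phase_curves(
    template: ArchetypeTemplate, cycle_period_s: float, image_duration_s: float, dt: float
):
    """Per-cycle rate curves in Hz.

    Returns (pres_base, pres_mod, omit_base, omit_mod) sampled at bin
    centers over one cycle: rate = base + gain * mod, where ``gain`` is
    the unit's tuning gain for the trial's image (1 for untuned classes).
    """
    P, D = cycle_period_s, image_duration_s
    n = int(round(P / dt))
    t = (np.arange(n) + 0.5) * dt
    b, a = template.baseline_rate, template.response_rate
    zero = np.zeros(n)
    base_b = np.full(n, b)
    name = template.name

    if name == "transient_on":
        mod = _gauss(t, 0.03, 0.012) + 0.3 * _gauss(t, D + 0.03, 0.012)
        return base_b, a * mod, base_b, zero
    if name == "sustained_on":
        tail = np.exp(-(t - D) / 0.2)
        pres = np.where(t < D, 1.0, tail)
        omit = np.exp(-(t + P - D) / 0.2)  # decay continuing from last offset
        return base_b, a * pres, base_b, a * omit
    if name == "ramp_to_offset":
        pres = np.where(t < D, t / D, np.exp(-(t - D) / 0.08))
        omit = np.exp(-(t + P - D) / 0.08)
        return base_b, a * pres, base_b, a * omit
    if name == "step_off_on":
        pres = np.where(t < D, 0.2 * b, b + a)
        omit = np.full(n, b + a)  # no image -> elevated rate all cycle
        return pres, zero, omit, zero
    if name == "ramp_off":
        low = 0.2 * b
        pres = np.where(t < D, low, low + a * (t - D) / (P - D))
        # ramp continues, uninterrupted, through the omitted presentation
        omit = low + a * (t + P - D) / (P - D)
        return pres, zero, omit, zero
    if name == "hippocampal_step":
        omit = np.full(n, b + a)  # step at expected onset, held a full cycle
        return base_b, zero, omit, zero
    if name == "unmodulated":
        return base_b, zero, base_b, zero
    raise AssertionError(name)


# ---------------------------------------------------------------------------
# units
# ---------------------------------------------------------------------------

@dataclass
class UnitRecord:
    """One unit's spike times plus metadata and quality metrics."""

    unit_id: str
    spike_times: np.ndarray
    area: str = "VISp"
    layer: str = "L4"
    archetype: str | None = None
    waveform_duration_ms: float = 0.55
    genotype_line: str = "wt"
    opto_epochs: list | None = None
    isi_violation_rate: float = 0.001
    presence_ratio: float = 0.99
    amplitude_cutoff: float = 0.01
    mean_rate_hz: float = float("nan")
    cell_type: str | None = None
    tuning_gains: np.ndarray | None = None

    def __post_init__(self):
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.spike_times.size and np.any(np.diff(self.spike_times) < 0):
            self.spike_times = np.sort(self.spike_times)


@dataclass(frozen=True)
class UnitSpec:
    """A homogeneous group of units to generate."""

    template: ArchetypeTemplate
    count: int
    area: str = "VISp"
    layer: str = "L4"
    gains: np.ndarray | None = None  # fixed per-image tuning gains (optional)


@dataclass(frozen=True)
class NoiseConfig:
    rate_jitter_sd: float = 0.15       # log-normal SD of per-unit rate scaling
    tuning_gain_sd: float = 0.35       # log-normal SD of per-image gains (STIM-ON)


def _unit_spikes(
    rng: np.random.Generator,
    schedule: StimulusSchedule,
    curves,
    gains: np.ndarray,
    jitter: float,
    dt: float,
) -> np.ndarray:
    pres_base, pres_mod, omit_base, omit_mod = curves
    onsets = schedule.onsets
    omitted = schedule.omitted
    images = schedule.slots["image_id"].to_numpy()
    n_phase = pres_base.size
    phase_start = np.arange(n_phase) * dt

    out = []
    for om in (False, True):
        base = omit_base if om else pres_base
        mod = omit_mod if om else pres_mod
        for img in np.unique(images[omitted == om] if om else images[~omitted]):
            sel = np.flatnonzero((omitted == om) & (images == img))
            if sel.size == 0:
                continue
            rate = jitter * (base + gains[img] * mod)
            counts = rng.poisson(rate * dt, size=(sel.size, n_phase))
            si, pi = np.nonzero(counts)
            if si.size == 0:
                continue
            reps = counts[si, pi]
            starts = np.repeat(onsets[sel[si]] + phase_start[pi], reps)
            out.append(starts + rng.random(starts.size) * dt)
    if not out:
        return np.empty(0)
    return np.sort(np.concatenate(out))


def generate_units(
    schedule: StimulusSchedule,
    mix: Sequence[UnitSpec],
    noise: NoiseConfig = NoiseConfig(),
    seed: int = 0,
    dt: float = 0.001,
) -> list[UnitRecord]:
    """Inhomogeneous-Poisson realizations of archetype templates.

    Each unit's rate is its template composed with the schedule; omitted
    slots drive the template's omission branch.  STIM-ON archetypes get
    log-normal per-image multiplicative gains, STIM-OFF archetypes do not.
    """
    if len(schedule.slots) == 0:
        raise ValueError("empty schedule")
    rng = np.random.default_rng(seed)
    duration = schedule.duration_s
    units: list[UnitRecord] = []
    uid = 0
    for spec in mix:
        if spec.count < 0:
            raise ValueError("counts must be >= 0")
        tpl = spec.template
        curves = _phase_curves(tpl, schedule.cycle_period_s, schedule.image_duration_s, dt)
        for _ in range(spec.count):
            jitter = float(rng.lognormal(0.0, noise.rate_jitter_sd)) if noise.rate_jitter_sd else 1.0
            if spec.gains is not None:
                gains = np.asarray(spec.gains, dtype=float)
            elif tpl.name in STIM_ON and noise.tuning_gain_sd:
                gains = rng.lognormal(0.0, noise.tuning_gain_sd, schedule.n_images)
            else:
                gains = np.ones(schedule.n_images)
            spikes = _unit_spikes(rng, schedule, curves, gains, jitter, dt)
            units.append(
                UnitRecord(
                    unit_id=f"u{uid:04d}",
                    spike_times=spikes,
                    area=spec.area,
                    layer=spec.layer,
                    archetype=tpl.name,
                    mean_rate_hz=spikes.size / duration,
                    tuning_gains=gains,
                )
            )
            uid += 1
    return units


# ---------------------------------------------------------------------------
# behavior traces
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BehaviorConfig:
    base_speed_cm_s: float = 40.0
    speed_noise_sd: float = 3.0
    slowdown_lag_s: float = 0.5        # dip onset lags the omitted-slot onset
    slowdown_tau_s: float = 0.4        # dip minimum at lag + tau
    slowdown_depth: float = 12.0       # cm/s at dip minimum
    pupil_noise_sd: float = 0.02
    pupil_constriction: float = 0.05   # fractional constriction at dip minimum
    sampling_hz: float = 60.0
    seed: int = 0


@dataclass
class BehaviorTrace:
    timestamps: np.ndarray
    running_speed: np.ndarray
    pupil_diameter: np.ndarray


def _ar1(rng: np.random.Generator, n: int, sd: float, dt: float, tau: float = 1.0) -> np.ndarray:
    rho = math.exp(-dt / tau)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd)
    innov = rng.normal(0.0, sd * math.sqrt(1 - rho * rho), n - 1)
    for i in range(1, n):
        x[i] = rho * x[i - 1] + innov[i - 1]
    return x


def generate_behavior(
    schedule: StimulusSchedule, params: BehaviorConfig = BehaviorConfig(), seed: int | None = None
) -> BehaviorTrace:
    """Running speed and median-normalized pupil diameter.

    Each omission triggers an alpha-shaped slowdown whose onset lags the
    omitted-slot onset by ``slowdown_lag_s`` and whose minimum falls at
    ``slowdown_lag_s + slowdown_tau_s`` (after the post-omission image
    onset under the defaults).  The pupil constricts slightly with the
    same time course.
    """
    if params.slowdown_lag_s < 0:
        raise ValueError("slowdown_lag_s must be >= 0")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    dt = 1.0 / params.sampling_hz
    t = np.arange(0.0, schedule.duration_s + 2.0, dt)
    n = t.size

    dip = np.zeros(n)
    tau = params.slowdown_tau_s
    support = np.arange(0.0, 6.0 * tau, dt)
    kernel = (support / tau) * np.exp(1.0 - support / tau)  # peak 1 at s = tau
    for onset in schedule.omission_onsets():
        i0 = int(round((onset + params.slowdown_lag_s) / dt))
        if i0 >= n:
            continue
        i1 = min(n, i0 + kernel.size)
        dip[i0:i1] += kernel[: i1 - i0]

    speed = params.base_speed_cm_s + _ar1(rng, n, params.speed_noise_sd, dt) - params.slowdown_depth * dip
    pupil = 1.0 + _ar1(rng, n, params.pupil_noise_sd, dt) - params.pupil_constriction * dip
    pupil = pupil / np.median(pupil)
    return BehaviorTrace(timestamps=t, running_speed=speed, pupil_diameter=pupil)


# ---------------------------------------------------------------------------
# analytic traces & auxiliary generators (oracles and harnesses)
# ---------------------------------------------------------------------------

def archetype_omission_trace(
    template: ArchetypeTemplate | str,
    cycle_period_s: float = 0.75,
    image_duration_s: float = 0.25,
    window: tuple[float, float] = (-0.75, 1.5),
    bin_s: float = 0.01,
    zscore: bool = True,
) -> np.ndarray:
    """Expected omission-aligned rate of an archetype (noise-free).

    The timeline is presented slot / omitted slot / presented slot; the
    window is relative to the omitted-slot onset and must lie within
    [-cycle, 2*cycle].  Used both as the feature-template for semantic
    cluster labeling and to build analytic feature populations.
    """
    if isinstance(template, str):
        template = DEFAULT_TEMPLATES[template]
    P = cycle_period_s
    pres_base, pres_mod, omit_base, omit_mod = _phase_curves(
        template, P, image_duration_s, bin_s
    )
    full = np.concatenate(
        [pres_base + pres_mod, omit_base + omit_mod, pres_base + pres_mod]
    )  # [-P, 2P)
    n = pres_base.size
    i0 = int(round((window[0] + P) / bin_s))
    i1 = int(round((window[1] + P) / bin_s))
    if i0 < 0 or i1 > 3 * n:
        raise ValueError("window must lie within [-cycle, 2*cycle]")
    tr = full[i0:i1].astype(float)
    if zscore:
        sd = tr.std()
        tr = (tr - tr.mean()) / (sd if sd > 0 else 1.0)
    return tr


def synthetic_feature_population(
    counts: Mapping[str, int],
    noise_sd: float = 0.5,
    window: tuple[float, float] = (-0.75, 1.5),
    bin_s: float = 0.01,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Archetype feature vectors (z-scored trace + i.i.d. noise).

    Returns (features, labels); labels are archetype names.  This is the
    light-weight stand-in for a full spiking session used by clustering
    harnesses.
    """
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for name, cnt in counts.items():
        tr = archetype_omission_trace(name, window=window, bin_s=bin_s)
        for _ in range(cnt):
            v = tr + rng.normal(0.0, noise_sd, tr.size)
            sd = v.std()
            rows.append((v - v.mean()) / (sd if sd > 0 else 1.0))
            labels.append(name)
    return np.asarray(rows), np.asarray(labels)


def homogeneous_poisson_train(
    rate_hz: float, duration_s: float, rng: np.random.Generator, t0: float = 0.0
) -> np.ndarray:
    n = rng.poisson(rate_hz * duration_s)
    return t0 + np.sort(rng.random(n) * duration_s)


def generate_synapse_pair(
    duration_s: float,
    pre_rate_hz: float,
    post_rate_hz: float,
    kind: str = "excitatory",
    transmission: float = 0.1,
    delay_s: float = 0.0015,
    jitter_s: float = 0.0002,
    suppression: float = 0.5,
    suppression_duration_s: float = 0.003,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """A Poisson pair with a planted monosynaptic connection.

    ``excitatory``: each presynaptic spike evokes a postsynaptic spike
    with probability ``transmission`` at ``delay_s`` (Gaussian timing
    jitter).  ``inhibitory``: postsynaptic spikes within
    [delay_s, delay_s + suppression_duration_s] after a presynaptic
    spike are deleted with probability ``suppression``.  ``none``: two
    independent trains.
    """
    rng = np.random.default_rng(seed)
    pre = homogeneous_poisson_train(pre_rate_hz, duration_s, rng)
    post = homogeneous_poisson_train(post_rate_hz, duration_s, rng)
    if kind == "excitatory":
        evoked_mask = rng.random(pre.size) < transmission
        evoked = pre[evoked_mask] + delay_s + rng.normal(0.0, jitter_s, int(evoked_mask.sum()))
        post = np.sort(np.concatenate([post, evoked]))
    elif kind == "inhibitory":
        idx = np.searchsorted(pre, post) - 1
        valid = idx >= 0
        since_pre = np.full(post.size, np.inf)
        since_pre[valid] = post[valid] - pre[idx[valid]]
        in_win = (since_pre >= delay_s) & (since_pre < delay_s + suppression_duration_s)
        drop = in_win & (rng.random(post.size) < suppression)
        post = post[~drop]
    elif kind != "none":
        raise ValueError(kind)
    return pre, np.clip(post, 0.0, duration_s)


def generate_coupled_population(
    n_on: int,
    n_off: int,
    duration_s: float,
    base_rate_hz: float = 6.0,
    coupling: float = 0.8,
    latent_tau_s: float = 0.2,
    bin_s: float = 0.01,
    seed: int = 0,
) -> tuple[list[UnitRecord], np.ndarray]:
    """Spontaneous-epoch population with a shared slow latent.

    STIM-ON-like units follow the latent (positive coupling); STIM-OFF-
    like units are driven anti-phase (negative coupling), emulating cells
    that fall silent during population bursts.  Returns (units, latent).
    """
    rng = np.random.default_rng(seed)
    n_bins = int(round(duration_s / bin_s))
    latent = _ar1(rng, n_bins, 1.0, bin_s, tau=latent_tau_s)
    units: list[UnitRecord] = []
    for i in range(n_on + n_off):
        c = coupling if i < n_on else -coupling
        # linear loading keeps anti-phase units genuinely anti-correlated
        # with the summed population rate
        rate = base_rate_hz * np.clip(1.0 + c * latent, 0.05, None)
        counts = rng.poisson(rate * bin_s)
        bi = np.repeat(np.arange(n_bins), counts)
        spikes = np.sort(bi * bin_s + rng.random(bi.size) * bin_s)
        units.append(
            UnitRecord(
                unit_id=f"c{i:03d}",
                spike_times=spikes,
                archetype="sustained_on" if i < n_on else "step_off_on",
                mean_rate_hz=spikes.size / duration_s,
            )
        )
    return units, latent
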