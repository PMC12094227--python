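"""Monosynaptic connectivity from jitter-corrected cross-correlograms.

The cross-correlogram (CCG) counts (pre, post) spike pairs by lag
(post - pre) in 0.4-ms bins.  Putative monosynaptic connections are
detected against surrogate CCGs in which the postsynaptic train is
interval-jittered (each spike re-drawn uniformly within its 5-ms
interval), which destroys fine-timescale structure while preserving slow
comodulation and per-interval spike counts.  A connection is excitatory
when the observed counts exceed the surrogate acceptance band in the
short positive-lag window (0.8-2.8 ms), and inhibitory when they fall
below the lower band (0.8-4 ms); significance uses the maximum (minimum)
statistic over the lag window, which controls the family-wise error over
bins.  Connection strength is the excess (deficit) of pairs per
presynaptic spike.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Ccg",
    "JitterConfig",
    "Edge",
    "compute_ccg",
    "jitter_surrogate",
    "detect_monosynaptic",
    "build_synaptic_graph",
    "connectivity_summary",
]


@dataclass
class Ccg:
    lags: np.ndarray           # bin centers, seconds (post - pre)
    counts: np.ndarray
    bin_s: float
    n_pre: int
    n_post: int


def _window_bin_counts(pre: np.ndarray, post: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Counts of (pre, post) pairs with post-pre in each [edges[i], edges[i+1])."""
    pos = np.searchsorted(post, pre[:, None] + edges[None, :])
    return np.diff(pos, axis=1).sum(axis=0)


def compute_ccg(
    pre_spikes: np.ndarray,
    post_spikes: np.ndarray,
    bin_s: float = 0.0004,
    window_s: float = 0.05,
) -> Ccg:
    """Raw cross-correlogram with lag bins symmetric around zero."""
    pre = np.asarray(pre_spikes, dtype=float)
    post = np.asarray(post_spikes, dtype=float)
    if pre.size == 0 or post.size == 0:
        raise ValueError("both spike trains must be non-empty")
    n = int(round(window_s / bin_s))
    edges = np.arange(-n, n + 1) * bin_s
    counts = _window_bin_counts(pre, post, edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return Ccg(centers, counts.astype(int), bin_s, pre.size, post.size)


def jitter_surrogate(spikes: np.ndarray, interval_s: float, rng: np.random.Generator) -> np.ndarray:
    """Interval jitter: each spike re-drawn uniformly within its interval.

    Preserves the spike count in every interval exactly.
    """
    base = np.floor(spikes / interval_s) * interval_s
    return np.sort(base + rng.random(spikes.size) * interval_s)


@dataclass(frozen=True)
class JitterConfig:
    interval_ms: float = 5.0
    n_surrogates: int = 200
    alpha: float = 0.01


@dataclass
class Edge:
    pre: str
    post: str
    sign: str                  # excitatory / inhibitory
    peak_lag_ms: float
    strength: float            # excess (deficit) pairs per presynaptic spike
    p_value: float


def detect_monosynaptic(
    pre_spikes: np.ndarray,
    post_spikes: np.ndarray,
    jitter: JitterConfig = JitterConfig(),
    bin_s: float = 0.0004,
    exc_window_ms: tuple[float, float] = (0.8, 2.8),
    inh_window_ms: tuple[float, float] = (0.8, 4.0),
    min_pairs: int = 10,
    pre_id: str = "pre",
    post_id: str = "post",
    seed: int = 0,
) -> Edge | None:
    """Test one directed pair for a monosynaptic CCG peak or trough.

    Returns an Edge, or None when neither band is crossed.  Pairs whose
    surrogate CCG carries fewer than ``min_pairs`` expected pairs in the
    tested window are reported as None with a warning (band unstable).
    """
    if jitter.n_surrogates < 100:
        raise ValueError("need at least 100 surrogates")
    pre = np.asarray(pre_spikes, dtype=float)
    post = np.asarray(post_spikes, dtype=float)
    if pre.size == 0 or post.size == 0:
        raise ValueError("both spike trains must be non-empty")
    rng = np.random.default_rng(seed)

    lo = min(exc_window_ms[0], inh_window_ms[0]) / 1000.0
    hi = max(exc_window_ms[1], inh_window_ms[1]) / 1000.0
    n0 = int(round(lo / bin_s))
    n1 = int(round(hi / bin_s))
    edges = np.arange(n0, n1 + 1) * bin_s
    centers_ms = 1000.0 * 0.5 * (edges[:-1] + edges[1:])
    exc_mask = (centers_ms > exc_window_ms[0]) & (centers_ms < exc_window_ms[1])
    inh_mask = (centers_ms > inh_window_ms[0]) & (centers_ms < inh_window_ms[1])

    obs = _window_bin_counts(pre, post, edges)
    interval = jitter.interval_ms / 1000.0
    surr = np.empty((jitter.n_surrogates, obs.size))
    for b in range(jitter.n_surrogates):
        surr[b] = _window_bin_counts(pre, jitter_surrogate(post, interval, rng), edges)
    if surr.mean(axis=0)[exc_mask | inh_mask].sum() < min_pairs:
        warnings.warn("too few pairs for a stable acceptance band")
        return None

    # maximum/minimum statistic over the lag window (family-wise control)
    obs_max = obs[exc_mask].max()
    surr_max = surr[:, exc_mask].max(axis=1)
    p_exc = (1.0 + np.sum(surr_max >= obs_max)) / (1.0 + jitter.n_surrogates)
    obs_min = obs[inh_mask].min()
    surr_min = surr[:, inh_mask].min(axis=1)
    p_inh = (1.0 + np.sum(surr_min <= obs_min)) / (1.0 + jitter.n_surrogates)

    mean_surr = surr.mean(axis=0)
    sign = None
    if p_exc < jitter.alpha and (p_inh >= jitter.alpha or p_exc <= p_inh):
        sign, p = "excitatory", p_exc
        dev = np.where(exc_mask, obs - mean_surr, -np.inf)
        peak = int(np.argmax(dev))
        strength = float((obs[exc_mask] - mean_surr[exc_mask]).sum() / pre.size)
    elif p_inh < jitter.alpha:
        sign, p = "inhibitory", p_inh
        dev = np.where(inh_mask, obs - mean_surr, np.inf)
        peak = int(np.argmin(dev))
        strength = float((obs[inh_mask] - mean_surr[inh_mask]).sum() / pre.size)
    if sign is None:
        return None
    return Edge(pre_id, post_id, sign, float(centers_ms[peak]), strength, float(p))


def build_synaptic_graph(
    units,
    jitter: JitterConfig = JitterConfig(),
    seed: int = 0,
    **detect_kwargs,
) -> pd.DataFrame:
    """Directed edges over all ordered within-session pairs (no self-edges)."""
    rows = []
    rng = np.random.default_rng(seed)
    for i, a in enumerate(units):
        for j, b in enumerate(units):
            if i == j or a.spike_times.size == 0 or b.spike_times.size == 0:
                continue
            edge = detect_monosynaptic(
                a.spike_times, b.spike_times, jitter=jitter,
                pre_id=a.unit_id, post_id=b.unit_id,
                seed=int(rng.integers(2**31)), **detect_kwargs,
            )
            if edge is not None:
                rows.append(
                    {"pre": edge.pre, "post": edge.post, "sign": edge.sign,
                     "peak_lag_ms": edge.peak_lag_ms, "strength": edge.strength,
                     "p_value": edge.p_value}
                )
    return pd.DataFrame(rows, columns=["pre", "post", "sign", "peak_lag_ms",
                                       "strength", "p_value"])


def connectivity_summary(
    edges: pd.DataFrame,
    clusters: dict,
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> dict:
    """Per-cluster connectivity summaries.

    ``clusters`` maps unit_id -> cluster label.  Returns fractions of
    units with at least one outgoing / incoming connection per cluster
    (with bootstrap 95% CIs), mean divergence (out-degree) and
    convergence (in-degree), and cluster-pair connection-probability
    matrices per sign (detected edges / tested ordered pairs).
    """
    rng = np.random.default_rng(seed)
    unit_ids = list(clusters)
    cl_of = clusters
    labels = sorted(set(clusters.values()))
    by_sign = {s: edges[edges["sign"] == s] if len(edges) else edges for s in
               ("excitatory", "inhibitory")}

    frac_rows = []
    for sign, e in by_sign.items():
        srcs = set(e["pre"]) if len(e) else set()
        dsts = set(e["post"]) if len(e) else set()
        for cl in labels:
            members = [u for u in unit_ids if cl_of[u] == cl]
            if not members:
                continue
            out_flags = np.array([u in srcs for u in members], dtype=float)
            in_flags = np.array([u in dsts for u in members], dtype=float)
            boot_out = [out_flags[rng.integers(len(members), size=len(members))].mean()
                        for _ in range(n_bootstrap)]
            boot_in = [in_flags[rng.integers(len(members), size=len(members))].mean()
                       for _ in range(n_bootstrap)]
            frac_rows.append(
                {"cluster": cl, "sign": sign, "n_units": len(members),
                 "frac_outgoing": out_flags.mean(),
                 "frac_outgoing_ci_lo": float(np.percentile(boot_out, 2.5)),
                 "frac_outgoing_ci_hi": float(np.percentile(boot_out, 97.5)),
                 "frac_incoming": in_flags.mean(),
                 "frac_incoming_ci_lo": float(np.percentile(boot_in, 2.5)),
                 "frac_incoming_ci_hi": float(np.percentile(boot_in, 97.5))}
            )
    fractions = pd.DataFrame(frac_rows)

    div = {u: 0 for u in unit_ids}
    conv = {u: 0 for u in unit_ids}
    for _, r in edges.iterrows():
        if r["pre"] in div:
            div[r["pre"]] += 1
        if r["post"] in conv:
            conv[r["post"]] += 1
    degrees = pd.DataFrame(
        {"unit_id": unit_ids,
         "cluster": [cl_of[u] for u in unit_ids],
         "divergence": [div[u] for u in unit_ids],
         "convergence": [conv[u] for u in unit_ids]}
    )

    prob = {}
    for sign, e in by_sign.items():
        M = pd.DataFrame(0.0, index=labels, columns=labels)
        for ca in labels:
            na = sum(1 for u in unit_ids if cl_of[u] == ca)
            for cb in labels:
                nb = sum(1 for u in unit_ids if cl_of[u] == cb)
                tested = na * nb - (na if ca == cb else 0)
                if tested == 0:
                    M.loc[ca, cb] = float("nan")
                    continue
                k = (
                    ((e["pre"].map(cl_of) == ca) & (e["post"].map(cl_of) == cb)).sum()
                    if len(e) else 0
                )
                M.loc[ca, cb] = k / tested
        prob[sign] = M
    return {"fractions": fractions, "degrees": degrees, "connection_probability": prob}
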