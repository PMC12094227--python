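"""Functional clustering of visual-cortex units.

Units are described by their z-scored PSTH concatenated over the omitted
stimulus and the immediately preceding and following stimuli; k-means is
run on the rows of the unit-by-unit Pearson correlation matrix.  The
number of clusters is selected per session by two complementary
criteria — the elbow of the pooled within-cluster dispersion W_k and the
gap statistic

    Gap_n(k) = E*_n{log W_k} - log(W_k)

with the reference expectation from Monte-Carlo draws uniform over the
feature bounding box — and the final clustering uses the mode of the
per-session optima.  Clusters are given semantic archetype labels by
matching their mean response profiles to the archetype templates
(one-to-one Hungarian assignment); transient/sustained/ramp-to-offset
clusters form the STIM-ON class, step-OFF/ON and ramp-OFF clusters the
STIM-OFF class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import KFold

from . import synth
from .psth import compute_psth, event_window_rates
from .synth import STIM_OFF, STIM_ON, StimulusSchedule

__all__ = [
    "ResponseMatrix",
    "ClusterSelection",
    "ClusterModel",
    "build_response_matrix",
    "choose_k",
    "cluster_units",
    "partition_overlap",
    "cluster_composition",
    "decode_time_bin",
    "cv2",
    "cluster_spontaneous_summary",
]

VISUAL_ARCHETYPES = ("transient_on", "sustained_on", "ramp_to_offset", "step_off_on", "ramp_off")


@dataclass
class ResponseMatrix:
    unit_ids: list
    features: np.ndarray       # units x time-bins, z-scored per unit
    corr: np.ndarray           # unit x unit Pearson correlation
    window: tuple
    bin_s: float
    cycle_period_s: float
    image_duration_s: float
    excluded: list = field(default_factory=list)


def build_response_matrix(
    units,
    schedule: StimulusSchedule,
    window: tuple[float, float] | None = None,
    bin_s: float = 0.010,
) -> ResponseMatrix:
    """Omission-aligned feature vectors and their correlation matrix.

    The default window spans the preceding stimulus, the omission, and
    the following stimulus ([-cycle, 2*cycle] around omission onset).
    Zero-variance units are excluded with a warning.
    """
    if len(units) < 2:
        raise ValueError("need at least 2 units")
    events = schedule.omission_onsets()
    if events.size < 2:
        raise ValueError("need at least 2 omissions")
    P = schedule.cycle_period_s
    if window is None:
        window = (-P, 2 * P)
    feats, ids, excluded = [], [], []
    for u in units:
        p = compute_psth(u, events, window=window, bin_s=bin_s)
        if p.zero_variance:
            excluded.append(u.unit_id)
            continue
        feats.append(p.zrate)
        ids.append(u.unit_id)
    if excluded:
        warnings.warn(f"excluded {len(excluded)} zero-variance unit(s)")
    if len(feats) < 2:
        raise ValueError("fewer than 2 units with non-degenerate responses")
    X = np.asarray(feats)
    corr = np.corrcoef(X)
    return ResponseMatrix(ids, X, corr, window, bin_s, P, schedule.image_duration_s,
                          excluded)


@dataclass
class ClusterSelection:
    k_grid: np.ndarray
    W_k: np.ndarray
    log_W: np.ndarray
    E_star: np.ndarray
    gap: np.ndarray
    se: np.ndarray
    k_elbow: int
    k_gap: int
    k_opt: int
    flag: str | None = None


def _dispersion(X: np.ndarray, k: int, seed: int, n_init: int) -> tuple[float, np.ndarray]:
    """Pooled within-cluster dispersion (sum of pairwise squared distances
    normalized by 2 n_r, which equals the k-means inertia)."""
    if k == 1:
        mu = X.mean(axis=0)
        return float(np.sum((X - mu) ** 2)), np.zeros(len(X), dtype=int)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(X)
    return float(km.inertia_), km.labels_


def choose_k(
    corr_rows: np.ndarray,
    k_grid=range(1, 11),
    B_montecarlo: int = 50,
    seed: int = 0,
    n_init: int = 10,
    ref_n_init: int = 4,
    gap_rule: str = "one_se",
) -> ClusterSelection:
    """Elbow + gap-statistic selection of the number of clusters.

    ``k_elbow`` is the argmax of the second discrete difference of
    log W_k (the point where the dispersion slope changes most
    drastically, measured on the scale where post-elbow decline is
    flat); ``k_gap`` follows the one-SE rule (first k with
    Gap(k) >= Gap(k+1) - SE(k+1)) by default, or the global argmax with
    ``gap_rule='max'``.  The Monte-Carlo reference is uniform over the
    principal-component-aligned bounding box of the data, which keeps
    the reference dispersion honest for strongly correlated features.
    ``k_opt`` is the mean of the two criteria, rounded half-up.
    """
    X = np.asarray(corr_rows, dtype=float)
    ks = np.asarray(list(k_grid))
    if len(X) <= ks.max():
        raise ValueError("need more rows than max(k_grid)")
    if np.allclose(X, X[0]):
        return ClusterSelection(ks, np.zeros(len(ks)), np.full(len(ks), -np.inf),
                                np.zeros(len(ks)), np.zeros(len(ks)), np.zeros(len(ks)),
                                1, 1, 1, "degenerate")
    rng = np.random.default_rng(seed)
    W = np.array([_dispersion(X, k, seed, n_init)[0] for k in ks])
    logW = np.log(W)
    Xc = X - X.mean(axis=0)
    _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
    Z = Xc @ Vt.T
    lo, hi = Z.min(axis=0), Z.max(axis=0)
    ref_logW = np.empty((B_montecarlo, len(ks)))
    for b in range(B_montecarlo):
        ref = rng.uniform(lo, hi, size=Z.shape) @ Vt
        ref_seed = int(rng.integers(2**31))
        ref_logW[b] = [np.log(_dispersion(ref, k, ref_seed, ref_n_init)[0]) for k in ks]
    E_star = ref_logW.mean(axis=0)
    gap = E_star - logW
    se = ref_logW.std(axis=0) * np.sqrt(1.0 + 1.0 / B_montecarlo)

    if gap_rule == "one_se":
        k_gap = int(ks[-1])
        for i in range(len(ks) - 1):
            if gap[i] >= gap[i + 1] - se[i + 1]:
                k_gap = int(ks[i])
                break
    elif gap_rule == "max":
        k_gap = int(ks[int(np.argmax(gap))])
    else:
        raise ValueError(gap_rule)

    if len(ks) >= 3:
        d2 = logW[:-2] - 2 * logW[1:-1] + logW[2:]
        k_elbow = int(ks[1:-1][int(np.argmax(d2))])
    else:
        k_elbow = int(ks[int(np.argmin(W))])
    k_opt = int(np.floor((k_elbow + k_gap) / 2.0 + 0.5))
    return ClusterSelection(ks, W, logW, E_star, gap, se, k_elbow, k_gap, k_opt)


@dataclass
class ClusterModel:
    k: int
    labels: np.ndarray                 # cluster index per unit
    centroids: np.ndarray              # in correlation-row space
    unit_ids: list
    semantic: dict                     # cluster index -> archetype name
    classes: dict                      # cluster index -> STIM_ON / STIM_OFF
    flag: str | None = None


def cluster_units(
    matrix: ResponseMatrix,
    k: int,
    seed: int = 0,
    n_init: int = 20,
    archetypes=VISUAL_ARCHETYPES,
    label_semantics: bool = True,
) -> ClusterModel:
    """k-means on correlation-matrix rows with semantic archetype labels.

    Cluster mean response profiles are matched one-to-one to the
    archetype templates by highest Pearson correlation (Hungarian
    assignment over min(k, n_archetypes) pairs).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(matrix.corr)
    labels = km.labels_
    flag = None
    if len(np.unique(labels)) < k:
        flag = "empty_cluster"

    semantic = {}
    if label_semantics:
        means = np.array([matrix.features[labels == j].mean(axis=0) for j in range(k)])
        tpl = np.array(
            [
                synth.archetype_omission_trace(
                    name,
                    cycle_period_s=matrix.cycle_period_s,
                    image_duration_s=matrix.image_duration_s,
                    window=matrix.window,
                    bin_s=matrix.bin_s,
                )
                for name in archetypes
            ]
        )
        C = np.corrcoef(means, tpl)[:k, k:]
        ri, ci = linear_sum_assignment(-C)
        semantic = {int(r): archetypes[c] for r, c in zip(ri, ci)}
    for j in range(k):
        semantic.setdefault(j, "unassigned")
    classes = {
        j: ("STIM_ON" if semantic[j] in STIM_ON else
            "STIM_OFF" if semantic[j] in STIM_OFF else "other")
        for j in range(k)
    }
    return ClusterModel(k, labels, km.cluster_centers_, matrix.unit_ids,
                        semantic, classes, flag)


def partition_overlap(labels_a: np.ndarray, labels_b: np.ndarray) -> float:
    """Fraction of items agreeing under the best one-to-one cluster matching."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    ua, ub = np.unique(a), np.unique(b)
    cont = np.zeros((ua.size, ub.size))
    for i, x in enumerate(ua):
        for j, y in enumerate(ub):
            cont[i, j] = np.sum((a == x) & (b == y))
    ri, ci = linear_sum_assignment(-cont)
    return float(cont[ri, ci].sum() / a.size)


def cluster_composition(assignments: pd.DataFrame, stratum: str) -> pd.DataFrame:
    """Mean +- SEM (across sessions) of per-stratum cluster fractions.

    ``assignments`` needs columns [session, cluster, <stratum>]; within
    every (session, stratum) cell the fractions across clusters sum to 1.
    """
    counts = (
        assignments.groupby(["session", stratum, "cluster"]).size().rename("n").reset_index()
    )
    totals = counts.groupby(["session", stratum])["n"].transform("sum")
    counts["fraction"] = counts["n"] / totals
    wide = counts.pivot_table(
        index=["session", stratum], columns="cluster", values="fraction", fill_value=0.0
    )
    mean = wide.groupby(level=stratum).mean()
    sem = wide.groupby(level=stratum).sem(ddof=1)
    out = pd.concat({"mean": mean, "sem": sem}, axis=1)
    return out


def decode_time_bin(
    units,
    labels: np.ndarray,
    schedule: StimulusSchedule,
    bin_s: float = 0.050,
    folds: int = 10,
    seed: int = 0,
) -> dict:
    """Per-cluster error in decoding elapsed time within the omission.

    For each cluster, a 10-fold cross-validated linear regression
    predicts the within-omission time-bin index from the cluster units'
    normalized rates; the result is the distribution of per-fold mean
    absolute errors.  Folds are built over omission events so that bins
    of one event never straddle the train/test split.
    """
    events = schedule.omission_onsets()
    D = schedule.image_duration_s
    n_bins = int(round(D / bin_s))
    out = {}
    for cl in np.unique(labels):
        members = [u for u, l in zip(units, labels) if l == cl]
        if events.size < max(20, folds):
            raise ValueError("need at least 20 omission events")
        # rates: events x bins x units
        R = np.stack(
            [
                np.stack(
                    [
                        event_window_rates(u.spike_times, events, (b * bin_s, (b + 1) * bin_s))
                        for b in range(n_bins)
                    ],
                    axis=1,
                )
                for u in members
            ],
            axis=2,
        )
        mu = R.reshape(-1, R.shape[2]).mean(axis=0)
        sd = R.reshape(-1, R.shape[2]).std(axis=0)
        sd[sd == 0] = 1.0
        Rn = (R - mu) / sd
        y_bins = np.tile(np.arange(n_bins), (events.size, 1))
        maes = []
        kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
        for tr, te in kf.split(np.arange(events.size)):
            Xtr = Rn[tr].reshape(-1, R.shape[2])
            ytr = y_bins[tr].ravel()
            Xte = Rn[te].reshape(-1, R.shape[2])
            yte = y_bins[te].ravel()
            model = LinearRegression().fit(Xtr, ytr)
            maes.append(float(np.mean(np.abs(model.predict(Xte) - yte))))
        out[int(cl)] = np.asarray(maes)
    return out


def cv2(spike_times: np.ndarray) -> float:
    """Local inter-spike-interval variability 2|isi_{i+1}-isi_i|/(isi_{i+1}+isi_i)."""
    isi = np.diff(np.asarray(spike_times, dtype=float))
    if isi.size < 2:
        return float("nan")
    num = 2.0 * np.abs(np.diff(isi))
    den = isi[1:] + isi[:-1]
    ok = den > 0
    return float(np.mean(num[ok] / den[ok])) if ok.any() else float("nan")


def cluster_spontaneous_summary(units, labels: np.ndarray, epoch: tuple[float, float]) -> pd.DataFrame:
    """Simple export: spontaneous-epoch rate and CV^2 per unit with cluster."""
    t0, t1 = epoch
    rows = []
    for u, l in zip(units, labels):
        s = u.spike_times
        seg = s[(s >= t0) & (s < t1)]
        rows.append(
            {
                "unit_id": u.unit_id,
                "cluster": int(l),
                "spontaneous_rate_hz": seg.size / (t1 - t0),
                "cv2": cv2(seg),
            }
        )
    return pd.DataFrame(rows)
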