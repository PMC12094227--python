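"""Linear vs sigmoidal fits to population omission responses.

Session-level population responses (mean z-scored rate of significantly
up-modulated units, +-250 ms around the expected onset of the omitted
image) are fitted with a line and with the four-parameter sigmoid

    y = Delta + A / (1 + exp(-sigma * (x - c)))

by SSE minimization with multi-start local optimization; goodness of fit
is the mean coefficient of determination over held-out contiguous
blocks (eight-fold cross-validation).  An area is deemed sigmoidal when
its per-session sigmoid R^2 distribution is significantly above the
linear one (one-sided rank-sum) and its median exceeds the linear
median.  Pooled fitted slopes ``sigma`` across areas form a multimodal
distribution whose KDE troughs separate linearly ramping, intermediate,
and step-like areas.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .psth import compute_psth
from .synth import StimulusSchedule

__all__ = [
    "sigmoid",
    "LinearFit",
    "SigmoidFit",
    "AreaModelDecision",
    "SlopeModes",
    "fit_linear",
    "fit_sigmoid",
    "compare_models",
    "classify_slope_modes",
    "population_response",
]


def sigmoid(x: np.ndarray, delta: float, A: float, sigma: float, c: float) -> np.ndarray:
    from scipy.special import expit

    return delta + A * expit(sigma * (np.asarray(x, dtype=float) - c))


@dataclass
class LinearFit:
    slope: float
    intercept: float
    r2_cv: float


@dataclass
class SigmoidFit:
    delta: float
    A: float
    sigma: float               # slope parameter, 1/s
    c: float                   # horizontal shift, s
    r2_cv: float
    sse: float
    converged: bool = True
    negated: bool = False


def _contiguous_folds(n: int, folds: int):
    return np.array_split(np.arange(n), folds)


def _cv_r2(t, y, fit_fn, predict_fn, folds):
    """Mean held-out R^2 over contiguous blocks (SST against the
    training-fold mean, the usual out-of-sample convention)."""
    if len(t) < folds:
        raise ValueError("need at least as many points as folds")
    scores = []
    for test_idx in _contiguous_folds(len(t), folds):
        train = np.ones(len(t), dtype=bool)
        train[test_idx] = False
        params = fit_fn(t[train], y[train])
        pred = predict_fn(t[test_idx], params)
        resid = y[test_idx] - pred
        sst = np.sum((y[test_idx] - y[train].mean()) ** 2)
        scores.append(1.0 - np.sum(resid**2) / sst if sst > 0 else 0.0)
    return float(np.mean(scores))


def fit_linear(t: np.ndarray, y: np.ndarray, folds: int = 8) -> LinearFit:
    """SSE-minimizing line with contiguous-block cross-validated R^2."""
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    r2 = _cv_r2(t, y, lambda tt, yy: np.polyfit(tt, yy, 1),
                lambda tt, p: np.polyval(p, tt), folds)
    slope, intercept = np.polyfit(t, y, 1)
    return LinearFit(float(slope), float(intercept), r2)


_SIGMA_GRID = (5.0, 50.0, 500.0)


def _fit_sigmoid_once(t, y, starts, sigma_max):
    """Best-of-restarts sigmoid parameters by training SSE (ties: lower sigma).

    Variable projection: for fixed (sigma, c) the model is linear in
    (Delta, A), which are solved in closed form; the 2-d outer problem
    over (log10 sigma, c) is polished by Nelder-Mead from the supplied
    (sigma0, c0) starts.  Always returns parameters (the linear solve
    cannot fail).
    """
    from scipy.special import expit

    log_smax = np.log10(sigma_max)

    def profile(theta):
        ls, c = theta
        s = expit(10.0 ** min(ls, log_smax) * (t - c))
        smean = s.mean()
        sc = s - smean
        denom = float(sc @ sc)
        if denom < 1e-14:
            A = 0.0
        else:
            A = float(sc @ (y - y.mean())) / denom
        delta = float(y.mean() - A * smean)
        r = y - (delta + A * s)
        return float(r @ r), (delta, A)

    best = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for s0, c0 in starts:
            res = optimize.minimize(
                lambda th: profile(th)[0],
                x0=(np.log10(s0), float(c0)),
                method="Nelder-Mead",
                options={"maxiter": 200, "xatol": 1e-4, "fatol": 1e-12},
            )
            ls, c = res.x
            ls = min(ls, log_smax)
            sse, (delta, A) = profile((ls, c))
            sig = 10.0 ** ls
            if best is None or sse < best[0] * (1 - 1e-9) or (
                abs(sse - best[0]) <= 1e-9 * max(best[0], 1e-30)
                and sig < best[1][2]
            ):
                best = (sse, np.array([delta, A, sig, c]))
    return best


def fit_sigmoid(
    t: np.ndarray,
    y: np.ndarray,
    folds: int = 8,
    sigma_grid=_SIGMA_GRID,
    sigma_max: float = 5e3,
    allow_negated: bool = True,
) -> SigmoidFit:
    """Multi-start SSE fit of the four-parameter sigmoid with CV R^2.

    ``sigma`` is constrained positive (responses ramp upward into the
    expected onset); a decreasing trace is fitted on its negation and
    flagged ``negated`` (Delta and A reported on the original scale).
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(t) < 8:
        raise ValueError("need at least 8 time points for a 4-parameter fit")
    negated = False
    if allow_negated and len(t) > 2 and np.polyfit(t, y, 1)[0] < 0:
        y = -y
        negated = True

    c_grid = np.quantile(t, (0.25, 0.5, 0.75))
    starts = [(s0, float(c0)) for s0 in sigma_grid for c0 in c_grid]
    best = _fit_sigmoid_once(t, y, starts, sigma_max)
    if best is None:
        return SigmoidFit(*(float("nan"),) * 4, r2_cv=float("nan"), sse=float("nan"),
                          converged=False, negated=negated)
    sse, popt = best

    # training folds are warm-started from the full multistart solution
    warm = [(float(popt[2]), float(popt[3]))]

    def fit_fn(tt, yy):
        b = _fit_sigmoid_once(tt, yy, warm, sigma_max)
        return b[1] if b is not None else None

    def predict_fn(tt, params):
        if params is None:
            return np.full(len(tt), np.nan)
        return sigmoid(tt, *params)

    r2 = _cv_r2(t, y, fit_fn, predict_fn, folds)
    delta, A, sig, c = (float(v) for v in popt)
    if negated:
        delta, A = -delta, -A
    return SigmoidFit(delta, A, float(sig), float(c), r2, float(sse), True, negated)


@dataclass
class AreaModelDecision:
    area: str | None
    p_value: float
    label: str | None          # sigmoidal / not_sigmoidal
    median_linear: float
    median_sigmoid: float
    flag: str | None = None


def compare_models(
    linear_r2s,
    sigmoid_r2s,
    alpha: float = 0.05,
    area: str | None = None,
) -> AreaModelDecision:
    """One-sided rank-sum of per-session sigmoid vs linear R^2 distributions.

    An area is ``sigmoidal`` iff p < alpha and the sigmoid median exceeds
    the linear median.
    """
    lin = np.asarray(linear_r2s, dtype=float)
    sig = np.asarray(sigmoid_r2s, dtype=float)
    if lin.size != sig.size:
        raise ValueError("same sessions required in both lists")
    if lin.size < 3:
        return AreaModelDecision(area, float("nan"), None, float("nan"),
                                 float("nan"), "too_few_sessions")
    p = float(stats.ranksums(sig, lin, alternative="greater").pvalue)
    ml, ms = float(np.median(lin)), float(np.median(sig))
    label = "sigmoidal" if (p < alpha and ms > ml) else "not_sigmoidal"
    return AreaModelDecision(area, p, label, ml, ms)


MODE_NAMES_BY_COUNT = {
    1: ("intermediate",),
    2: ("linear_ramp", "step_like"),
    3: ("linear_ramp", "intermediate", "step_like"),
}


@dataclass
class SlopeModes:
    boundaries: np.ndarray     # sigma values of KDE troughs between modes
    mode_positions: np.ndarray
    area_modes: dict
    unimodal: bool


def classify_slope_modes(sigma_by_area: dict, grid_size: int = 512) -> SlopeModes:
    """Label areas by the mode of the pooled fitted-slope distribution.

    The pooled sigma values (positive, spanning decades) are examined on
    a log10 scale with a Gaussian KDE (Silverman bandwidth); the up to
    three largest local maxima define the modes and the KDE minima
    between them the boundaries.  Each area is labeled by the mode
    interval containing its median sigma.  A unimodal distribution is
    flagged and all areas share one mode.
    """
    pooled = np.concatenate([np.asarray(v, dtype=float) for v in sigma_by_area.values()])
    pooled = pooled[np.isfinite(pooled) & (pooled > 0)]
    if pooled.size < 30:
        raise ValueError("need at least 30 pooled sigma values")
    logs = np.log10(pooled)
    if np.ptp(logs) < 1e-12:
        # degenerate: a single spike; no KDE possible
        modes = np.array([10 ** logs[0]])
        return SlopeModes(np.array([]), modes,
                          {a: MODE_NAMES_BY_COUNT[1][0] for a in sigma_by_area}, True)
    kde = stats.gaussian_kde(logs, bw_method="silverman")
    grid = np.linspace(logs.min() - 0.3, logs.max() + 0.3, grid_size)
    dens = kde(grid)
    interior = np.flatnonzero((dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:])) + 1
    if interior.size == 0:
        interior = np.array([int(np.argmax(dens))])
    # keep up to the three highest peaks, in slope order
    keep = interior[np.argsort(dens[interior])[::-1][:3]]
    keep = np.sort(keep)
    troughs = []
    for a, b in zip(keep[:-1], keep[1:]):
        troughs.append(a + int(np.argmin(dens[a:b + 1])))
    boundaries = 10 ** grid[np.asarray(troughs, dtype=int)] if troughs else np.array([])
    names = MODE_NAMES_BY_COUNT[len(keep)]
    area_modes = {}
    for area, vals in sigma_by_area.items():
        med = float(np.median(np.asarray(vals, dtype=float)))
        k = int(np.searchsorted(boundaries, med))
        area_modes[area] = names[k]
    return SlopeModes(boundaries, 10 ** grid[keep], area_modes, len(keep) == 1)


def population_response(
    units,
    schedule: StimulusSchedule,
    modulation,
    window: tuple[float, float] = (-0.25, 0.25),
    bin_s: float = 0.010,
):
    """Session population response: mean z-scored PSTH of up-modulated units.

    ``modulation`` is the per-unit table from :func:`psth.modulation_table`
    (only units with ``sign_class == 'up'`` contribute).  Returns
    (time grid, mean z-rate).
    """
    up = set(modulation.loc[modulation["sign_class"] == "up", "unit_id"])
    events = schedule.omission_onsets()
    P = schedule.cycle_period_s
    traces = []
    centers = None
    for u in units:
        if u.unit_id not in up:
            continue
        p = compute_psth(u, events, window=(-P, 2 * P), bin_s=bin_s)
        c = p.bin_centers
        mask = (c >= window[0]) & (c < window[1])
        traces.append(p.zrate[mask])
        centers = c[mask]
    if not traces:
        raise ValueError("no significantly up-modulated units in this session")
    return centers, np.mean(traces, axis=0)
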