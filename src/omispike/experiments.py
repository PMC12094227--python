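"""Calibration and recovery experiments on synthetic data.

Each function runs one self-contained validation of the pipeline under
the study conditions (8 images at 250 ms, 5% omissions, 5-11 repeats)
and returns a small dict of computed quantities.  They are shared by the
test suite and the reproduction script so both report the same numbers.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from . import clustering, connectivity, crossarea, decoding, fitting, psth, synth

__all__ = [
    "schedule_fidelity",
    "decoder_chance",
    "sigmoid_recovery",
    "ramp_step_classification",
    "k_selection_recovery",
    "cluster_label_recovery",
    "monosynaptic_validation",
    "ridge_equivalence",
    "interaction_sign_recovery",
    "type_one_calibration",
]


def _seed(seed: int, k: int) -> int:
    return (seed * 7919 + k) % 2**31


# ---------------------------------------------------------------------------

def schedule_fidelity(seed: int = 0, n_eligible_target: int = 50_000) -> dict:
    """Omission rate and design parameters on a large schedule."""
    # mean eligible slots per trial under the truncated geometric
    pmf = synth.truncated_geometric_pmf(0.3, 5, 11)
    mean_eligible = float(np.sum(pmf * (np.arange(5, 12) - 2)))
    n_trials = int(np.ceil(n_eligible_target / mean_eligible))
    cfg = synth.ScheduleConfig(n_trials=n_trials, seed=seed)
    sched = synth.generate_schedule(cfg)
    eligible = sched.eligible_mask()
    n_eligible = int(eligible.sum())
    frac = float(sched.omitted[eligible].mean())
    lengths = sched.slots.groupby("trial_index").size()
    return {
        "n_eligible": n_eligible,
        "omitted_fraction": frac,
        "omission_prob": cfg.omission_prob,
        "n_images": int(sched.slots["image_id"].nunique()),
        "image_duration_ms": 1000.0 * sched.image_duration_s,
        "trial_len_min": int(lengths.min()),
        "trial_len_max": int(lengths.max()),
    }


# ---------------------------------------------------------------------------

def _tuned_session(seed: int, n_trials: int, units_per_archetype: int = 14,
                   tuning_gain_sd: float = 0.6):
    sched = synth.generate_schedule(synth.ScheduleConfig(n_trials=n_trials, seed=seed))
    mix = [
        synth.UnitSpec(synth.DEFAULT_TEMPLATES[n], units_per_archetype)
        for n in ("transient_on", "sustained_on", "ramp_to_offset")
    ]
    units = synth.generate_units(
        sched, mix, noise=synth.NoiseConfig(tuning_gain_sd=tuning_gain_sd),
        seed=seed + 1,
    )
    return sched, units


def decoder_chance(seed: int = 0, n_trials: int = 400, units_per_archetype: int = 14) -> dict:
    """Permuted-label chance calibration plus true-label reference.

    Reports the mean permuted-label accuracy over bins with its binomial
    CI half-width, the chance level 1/8, and true-label accuracies
    inside and outside the omission window.
    """
    sched, units = _tuned_session(_seed(seed, 1), n_trials)
    window = (-0.75, 1.0)   # spans the flanking images at [-0.75,-0.5] and [0.75,1.0]
    # permutation null averaged over several label permutations: a single
    # permutation retains chance class-enrichment that informative features
    # can pick up
    perms = [
        decoding.decode_image_identity(
            units, sched, window=window, seed=_seed(seed, 2 + 17 * r),
            permute_labels=True,
        )
        for r in range(5)
    ]
    perm = perms[0]
    perm_acc = np.mean([p.accuracy for p in perms], axis=0)
    true = decoding.decode_image_identity(units, sched, window=window, seed=_seed(seed, 2))
    in_stim = ((true.bin_centers >= -0.75) & (true.bin_centers < -0.5)) | (
        (true.bin_centers >= 0.75) & (true.bin_centers < 1.0))
    in_om = (true.bin_centers >= 0) & (true.bin_centers < 0.25)
    n_events = perm.n_events
    # simultaneous 99% binomial band across bins (Bonferroni): a family of
    # per-bin assertions needs family-wise coverage
    n_bins = perm.accuracy.size
    z = stats.norm.ppf(1.0 - 0.01 / (2 * n_bins))
    half = z * np.sqrt(perm.chance * (1 - perm.chance) / n_events)
    return {
        "chance": perm.chance,
        "permuted_accuracy_mean": float(perm_acc.mean()),
        "permuted_accuracy_per_bin": perm_acc.tolist(),
        "binomial_ci_halfwidth": float(half),
        "n_events": n_events,
        "true_accuracy_stimulus_bins": float(true.accuracy[in_stim].mean()),
        "true_accuracy_omission_bins": float(true.accuracy[in_om].mean()),
    }


# ---------------------------------------------------------------------------

def sigmoid_recovery(seed: int = 0, n_replicates: int = 100, n_points: int = 500,
                     sigma_true: float = 40.0, noise_sd: float = 0.05) -> dict:
    """Slope-parameter recovery from the sigmoid generative model
    (Delta=0, A=1, sigma=40/s, c=0, noise SD 0.05, 500 points)."""
    rng = np.random.default_rng(_seed(seed, 3))
    t = np.linspace(-0.25, 0.25, n_points)
    truth = fitting.sigmoid(t, 0.0, 1.0, sigma_true, 0.0)
    hits, errs = 0, []
    for _ in range(n_replicates):
        y = truth + rng.normal(0.0, noise_sd, n_points)
        fit = fitting.fit_sigmoid(t, y, folds=8)
        rel = abs(fit.sigma - sigma_true) / sigma_true
        errs.append(rel)
        hits += rel <= 0.20
    return {
        "recovery_rate": hits / n_replicates,
        "median_relative_error": float(np.median(errs)),
        "n_replicates": n_replicates,
    }


# ---------------------------------------------------------------------------

def _session_trace(rng, archetype: str, noise_sd: float = 0.08,
                   window=(-0.25, 0.25), bin_s=0.01):
    tr = synth.archetype_omission_trace(archetype, window=window, bin_s=bin_s)
    n = tr.size
    t = window[0] + (np.arange(n) + 0.5) * bin_s
    return t, tr + rng.normal(0.0, noise_sd, n)


def ramp_step_classification(seed: int = 0, n_meta: int = 100, n_sessions: int = 20,
                             noise_sd: float = 0.08) -> dict:
    """Area-level sigmoidal vs not_sigmoidal labels from simulated sessions.

    Step-like areas (hippocampal_step populations) should be labeled
    ``sigmoidal``; linearly ramping areas (ramp_off populations)
    ``not_sigmoidal``.  Reports the fraction of meta-replicates with
    both labels correct.
    """
    rng = np.random.default_rng(_seed(seed, 4))
    ok_step = ok_ramp = 0
    for _ in range(n_meta):
        labels = {}
        for arch in ("hippocampal_step", "ramp_off"):
            lin_r2, sig_r2 = [], []
            for _s in range(n_sessions):
                t, y = _session_trace(rng, arch, noise_sd)
                lin_r2.append(fitting.fit_linear(t, y).r2_cv)
                sig_r2.append(fitting.fit_sigmoid(t, y).r2_cv)
            labels[arch] = fitting.compare_models(lin_r2, sig_r2).label
        ok_step += labels["hippocampal_step"] == "sigmoidal"
        ok_ramp += labels["ramp_off"] == "not_sigmoidal"
    return {
        "step_sigmoidal_rate": ok_step / n_meta,
        "ramp_not_sigmoidal_rate": ok_ramp / n_meta,
        "n_meta_replicates": n_meta,
        "n_sessions": n_sessions,
    }


# ---------------------------------------------------------------------------

def k_selection_recovery(seed: int = 0, n_seeds: int = 50,
                         units_per_archetype: int = 24, noise_sd: float = 0.6,
                         B_montecarlo: int = 20) -> dict:
    """Gap/elbow k-selection on planted five-archetype populations and on
    a single isotropic blob (where the gap statistic should pick k=1)."""
    counts = {n: units_per_archetype for n in clustering.VISUAL_ARCHETYPES}
    k5 = 0
    for s in range(n_seeds):
        X, _ = synth.synthetic_feature_population(counts, noise_sd=noise_sd,
                                                  seed=_seed(seed, 100 + s))
        corr = np.corrcoef(X)
        sel = clustering.choose_k(corr, B_montecarlo=B_montecarlo,
                                  seed=_seed(seed, 200 + s))
        k5 += sel.k_opt == 5
    rng = np.random.default_rng(_seed(seed, 5))
    blob = rng.normal(size=(5 * units_per_archetype, 40))
    sel_blob = clustering.choose_k(blob, B_montecarlo=B_montecarlo, seed=_seed(seed, 6))
    return {
        "k5_recovery_rate": k5 / n_seeds,
        "n_seeds": n_seeds,
        "single_blob_k_gap": sel_blob.k_gap,
    }


# ---------------------------------------------------------------------------

def cluster_label_recovery(seed: int = 0, n_trials: int = 80,
                           units_per_archetype: int = 30) -> dict:
    """Semantic-label recovery on a full spiking session at k=5, and the
    partition overlap when the omission window is excluded."""
    sched = synth.generate_schedule(synth.ScheduleConfig(n_trials=n_trials,
                                                         seed=_seed(seed, 7)))
    mix = [
        synth.UnitSpec(synth.DEFAULT_TEMPLATES[n], units_per_archetype)
        for n in clustering.VISUAL_ARCHETYPES
    ]
    units = synth.generate_units(sched, mix, seed=_seed(seed, 8))
    matrix = clustering.build_response_matrix(units, sched)
    model = clustering.cluster_units(matrix, 5, seed=_seed(seed, 9))
    truth = {u.unit_id: u.archetype for u in units}
    recovered = np.mean(
        [model.semantic[int(l)] == truth[uid]
         for uid, l in zip(model.unit_ids, model.labels)]
    )
    # repeat with the omitted-stimulus window excluded from the features
    P = sched.cycle_period_s
    m_pre = clustering.build_response_matrix(units, sched, window=(-P, 0.0))
    m_post = clustering.build_response_matrix(units, sched, window=(P, 2 * P))
    feats = np.hstack([m_pre.features, m_post.features])
    corr = np.corrcoef(feats)
    m_no_om = clustering.ResponseMatrix(
        m_pre.unit_ids, feats, corr, (-P, 2 * P), m_pre.bin_s, P, sched.image_duration_s
    )
    model2 = clustering.cluster_units(m_no_om, 5, seed=_seed(seed, 10),
                                      label_semantics=False)
    overlap = clustering.partition_overlap(model.labels, model2.labels)
    return {
        "label_recovery": float(recovered),
        "no_omission_overlap": float(overlap),
        "n_units": len(units),
    }


# ---------------------------------------------------------------------------

def monosynaptic_validation(seed: int = 0, n_planted: int = 40, n_null: int = 1000,
                            n_pre_spikes: int = 3000, alpha: float = 0.01,
                            n_surrogates: int = 100) -> dict:
    """Planted-synapse sensitivity and null false-positive calibration.

    Excitatory synapses: transmission 0.1 at +1.5 ms (0.2-ms jitter),
    ~3000 presynaptic spikes.  Null: independent Poisson pairs; the
    excitatory-band false-positive rate should not exceed alpha.
    """
    jitter = connectivity.JitterConfig(n_surrogates=n_surrogates, alpha=alpha)
    pre_rate = 5.0
    duration = n_pre_spikes / pre_rate
    detected = 0
    for i in range(n_planted):
        pre, post = synth.generate_synapse_pair(
            duration, pre_rate, 5.0, kind="excitatory", transmission=0.1,
            seed=_seed(seed, 300 + i),
        )
        edge = connectivity.detect_monosynaptic(pre, post, jitter,
                                                seed=_seed(seed, 400 + i))
        detected += edge is not None and edge.sign == "excitatory"
    fp = 0
    null_duration = 120.0
    for i in range(n_null):
        pre, post = synth.generate_synapse_pair(
            null_duration, 8.0, 8.0, kind="none", seed=_seed(seed, 1000 + i)
        )
        edge = connectivity.detect_monosynaptic(pre, post, jitter,
                                                seed=_seed(seed, 5000 + i))
        fp += edge is not None and edge.sign == "excitatory"
    return {
        "sensitivity": detected / n_planted,
        "n_planted": n_planted,
        "false_positive_rate": fp / n_null,
        "n_null": n_null,
        "alpha": alpha,
    }


# ---------------------------------------------------------------------------

def ridge_equivalence(seed: int = 0, n: int = 80, p: int = 20, q: int = 12,
                      lam: float = 3.7) -> dict:
    """Closed-form ridge vs an independent iterative solver (LSQR on the
    lambda-augmented system), and the lambda=0 OLS limit."""
    from scipy.sparse.linalg import lsqr

    rng = np.random.default_rng(_seed(seed, 11))
    X = rng.normal(size=(n, p))
    Y = rng.normal(size=(n, q))
    B = crossarea.ridge_solve(X, Y, lam)
    Xa = np.vstack([X, np.sqrt(lam) * np.eye(p)])
    Ya = np.vstack([Y, np.zeros((p, q))])
    B_iter = np.column_stack(
        [lsqr(Xa, Ya[:, j], atol=1e-14, btol=1e-14, iter_lim=10_000)[0]
         for j in range(q)]
    )
    B_ols = np.linalg.lstsq(X, Y, rcond=None)[0]
    return {
        "max_coefficient_difference": float(np.max(np.abs(B - B_iter))),
        "ols_limit_difference": float(np.max(np.abs(crossarea.ridge_solve(X, Y, 0.0) - B_ols))),
    }


# ---------------------------------------------------------------------------

def interaction_sign_recovery(seed: int = 0, n_sessions: int = 100, rho: float = 0.8,
                              n_trials: int = 60, n_bins: int = 5, n_units: int = 10) -> dict:
    """Sign of the interaction strength under planted shared latents.

    A latent shared only during omission trials must yield a negative
    difference (better omission prediction); a stimulus-only latent a
    positive one.
    """
    out = {}
    for scenario, key in (("omission", "omission_negative_rate"),
                          ("stimulus", "stimulus_positive_rate")):
        rng = np.random.default_rng(_seed(seed, 12 if scenario == "omission" else 13))
        correct = 0
        for _ in range(n_sessions):
            X, Y = {}, {}
            for cond in ("stimulus", "omission"):
                cx = rng.normal(size=(n_trials, n_bins, n_units))
                cy = rng.normal(size=(n_trials, n_bins, n_units))
                if cond == scenario:
                    z = rng.normal(size=(n_trials, 1, 1))
                    cx = cx + rho * z
                    cy = cy + rho * z
                X[cond], _ = crossarea.residualize(cx)
                Y[cond], _ = crossarea.residualize(cy)
            res = crossarea.ridge_interaction(X, Y, seed=int(rng.integers(2**31)))
            correct += (res.difference < 0) if scenario == "omission" else (res.difference > 0)
        out[key] = correct / n_sessions
    out["n_sessions"] = n_sessions
    return out


# ---------------------------------------------------------------------------

def type_one_calibration(seed: int = 0, n_units: int = 1000, n_spec_units: int = 500,
                         n_trials: int = 400, alpha: float = 0.05) -> dict:
    """Type-I rates of the omission statistics under exchangeable nulls.

    Modulation: homogeneous Poisson units, so the omission and baseline
    windows are exchangeable.  Specificity: tuned units whose omission
    branch is image-independent, so preferred- and non-preferred-image
    omissions are exchangeable.
    """
    sched = synth.generate_schedule(synth.ScheduleConfig(n_trials=n_trials,
                                                         seed=_seed(seed, 14)))
    rng = np.random.default_rng(_seed(seed, 15))
    duration = sched.duration_s
    sig = 0
    for _ in range(n_units):
        spikes = synth.homogeneous_poisson_train(4.0, duration, rng)
        m = psth.omission_modulation(spikes, sched, alpha=alpha)
        sig += m.sign_class != "ns"
    mod_rate = sig / n_units

    # strongly tuned units whose omission branch is image-independent
    # (transient_on falls back to its baseline during an omitted image)
    mix = []
    for i in range(n_spec_units):
        gains = np.ones(sched.n_images)
        gains[i % sched.n_images] = 3.0
        mix.append(synth.UnitSpec(synth.DEFAULT_TEMPLATES["transient_on"], 1,
                                  gains=gains))
    units = synth.generate_units(sched, mix, noise=synth.NoiseConfig(0.0, 0.0),
                                 seed=_seed(seed, 16))
    spec = psth.omission_specificity(units, sched, alpha=alpha)
    tuned = spec[spec["tuned"] & spec["flag"].isna()]
    spec_rate = float(tuned["significant"].mean()) if len(tuned) else float("nan")
    return {
        "modulation_type1_rate": mod_rate,
        "specificity_type1_rate": spec_rate,
        "n_units": n_units,
        "n_tuned": int(len(tuned)),
        "alpha": alpha,
    }
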