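"""End-to-end synthetic demonstration pipeline.

Executes synth -> qc -> psth -> fitting -> clustering -> coupling ->
connectivity -> crossarea -> decoding on one generated session and
writes tab-separated tables plus a machine-readable JSON summary.  A
single global seed fans out to per-stage seeds through a counter scheme
(stage i uses ``(seed * 1000 + i) % 2**31``), so a run is reproducible
bit-for-bit from its config.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clustering, connectivity, coupling, crossarea, decoding, fitting, io, psth, qc, synth

__all__ = ["PipelineConfig", "PipelineDependencyError", "run_pipeline"]

STAGES = ("synth", "qc", "psth", "fitting", "clustering", "coupling",
          "connectivity", "crossarea", "decoding")


class PipelineDependencyError(RuntimeError):
    def __init__(self, stage: str, needs: str):
        super().__init__(f"stage {stage!r} requires disabled stage {needs!r}")
        self.stage, self.needs = stage, needs


@dataclass
class PipelineConfig:
    seed: int = 0
    n_trials: int = 120
    units_per_archetype: int = 12
    n_hippocampal: int = 8
    out_dir: str | None = None
    stages: tuple = STAGES
    # connectivity is expensive; run it on a planted-pair demo of this size
    n_connectivity_pairs: int = 6

    def stage_seed(self, stage: str) -> int:
        return (self.seed * 1000 + STAGES.index(stage)) % 2**31

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def run_pipeline(config: PipelineConfig = PipelineConfig()) -> dict:
    """Run the enabled stages and return the machine-readable summary."""
    cfg_hash = io.config_hash(config.as_dict())
    enabled = set(config.stages)
    for stage in enabled:
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}")
    deps = {
        "qc": "synth", "psth": "qc", "fitting": "psth", "clustering": "qc",
        "coupling": "clustering", "connectivity": "synth",
        "crossarea": "synth", "decoding": "qc",
    }
    for stage in STAGES:
        if stage in enabled and deps.get(stage) and deps[stage] not in enabled:
            raise PipelineDependencyError(stage, deps[stage])
    out = Path(config.out_dir) if config.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config_hash": cfg_hash, "seed": config.seed,
                     "stage_seeds": {s: config.stage_seed(s) for s in STAGES}}

    # --- synth -------------------------------------------------------------
    schedule = synth.generate_schedule(
        synth.ScheduleConfig(n_trials=config.n_trials, seed=config.stage_seed("synth"))
    )
    mix = [
        synth.UnitSpec(synth.DEFAULT_TEMPLATES[name], config.units_per_archetype,
                       area="VISp", layer="L4")
        for name in clustering.VISUAL_ARCHETYPES
    ] + [
        synth.UnitSpec(synth.DEFAULT_TEMPLATES["hippocampal_step"],
                       config.n_hippocampal, area="CA1", layer="sp")
    ]
    units = synth.generate_units(schedule, mix, seed=config.stage_seed("synth") + 1)
    behavior = synth.generate_behavior(schedule, seed=config.stage_seed("synth") + 2)
    summary["synth"] = {
        "n_slots": int(len(schedule.slots)),
        "n_omissions": int(schedule.omitted.sum()),
        "n_units": len(units),
    }
    if out:
        io.write_schedule(schedule, out / "schedule.tsv", cfg_hash)
        io.write_spikes(units, out / "spikes.tsv", cfg_hash)

    # --- qc ----------------------------------------------------------------
    if "qc" in enabled:
        kept = qc.filter_units(units)
        qc.classify_units(kept)
        summary["qc"] = {"n_in": len(units), "n_pass": len(kept)}
        if out:
            io.write_units_manifest(kept, out / "units.tsv", cfg_hash)
        units = kept

    # --- psth --------------------------------------------------------------
    if "psth" in enabled:
        mod = psth.modulation_table(units, schedule)
        summary["psth"] = {
            "n_up": int((mod["sign_class"] == "up").sum()),
            "n_down": int((mod["sign_class"] == "down").sum()),
            "n_ns": int((mod["sign_class"] == "ns").sum()),
        }
        if out:
            io.write_table(mod, out / "omission_modulation.tsv", cfg_hash)

    # --- fitting -----------------------------------------------------------
    if "fitting" in enabled:
        fits = {}
        for area in sorted({u.area for u in units}):
            au = [u for u in units if u.area == area]
            am = mod[mod["unit_id"].isin([u.unit_id for u in au])]
            try:
                t, y = fitting.population_response(au, schedule, am)
            except ValueError:
                continue
            lin = fitting.fit_linear(t, y)
            sig = fitting.fit_sigmoid(t, y)
            fits[area] = {"linear_r2_cv": lin.r2_cv, "sigmoid_r2_cv": sig.r2_cv,
                          "sigma": sig.sigma}
        summary["fitting"] = fits
        if out and fits:
            io.write_table(
                pd.DataFrame([{"area": a, **v} for a, v in fits.items()]),
                out / "fits.tsv", cfg_hash,
            )

    # --- clustering --------------------------------------------------------
    if "clustering" in enabled:
        vis = [u for u in units if u.area == "VISp"]
        matrix = clustering.build_response_matrix(vis, schedule)
        sel = clustering.choose_k(matrix.corr, seed=config.stage_seed("clustering"),
                                  B_montecarlo=20)
        model = clustering.cluster_units(matrix, max(sel.k_opt, 2),
                                         seed=config.stage_seed("clustering"))
        summary["clustering"] = {
            "k_elbow": sel.k_elbow, "k_gap": sel.k_gap, "k_final": sel.k_opt,
            "semantic": {str(k): v for k, v in model.semantic.items()},
        }
        assign = pd.DataFrame(
            {"unit_id": model.unit_ids, "session": "demo",
             "cluster": model.labels,
             "semantic": [model.semantic[int(l)] for l in model.labels],
             "class": [model.classes[int(l)] for l in model.labels]}
        )
        if out:
            io.write_table(assign, out / "clusters.tsv", cfg_hash)

    # --- coupling ----------------------------------------------------------
    if "coupling" in enabled:
        pop, _ = synth.generate_coupled_population(
            20, 10, 120.0, seed=config.stage_seed("coupling")
        )
        idx = [coupling.population_coupling(u, pop, (0.0, 120.0)).coupling_index
               for u in pop]
        scores = [coupling.behavior_scores(units[0], behavior)]
        summary["coupling"] = {
            "median_coupling_on": float(np.median(idx[:20])),
            "median_coupling_off": float(np.median(idx[20:])),
            "speed_score_example": scores[0][0],
        }

    # --- connectivity ------------------------------------------------------
    if "connectivity" in enabled:
        rng = np.random.default_rng(config.stage_seed("connectivity"))
        pairs = []
        for i in range(config.n_connectivity_pairs):
            kind = "excitatory" if i % 2 == 0 else "none"
            pre, post = synth.generate_synapse_pair(
                200.0, 8.0, 8.0, kind=kind, seed=int(rng.integers(2**31))
            )
            edge = connectivity.detect_monosynaptic(
                pre, post, connectivity.JitterConfig(n_surrogates=100),
                pre_id=f"p{i}", post_id=f"q{i}", seed=int(rng.integers(2**31)),
            )
            pairs.append({"pair": i, "planted": kind,
                          "detected": edge.sign if edge else "none"})
        summary["connectivity"] = {"pairs": pairs,
                                   "edge_count": sum(p["detected"] != "none" for p in pairs)}
        if out:
            io.write_table(pd.DataFrame(pairs), out / "synapses.tsv", cfg_hash)

    # --- crossarea ---------------------------------------------------------
    if "crossarea" in enabled:
        rng = np.random.default_rng(config.stage_seed("crossarea"))
        sessions = []
        for s in range(5):
            data = _synthetic_interaction_session(rng, latent_condition="omission")
            sessions.append(crossarea.ridge_interaction(
                data["X"], data["Y"], seed=int(rng.integers(2**31))))
        diff, p = crossarea.interaction_difference(sessions)
        summary["crossarea"] = {"mean_difference": diff, "p_value": p}

    # --- decoding ----------------------------------------------------------
    if "decoding" in enabled:
        try:
            res = decoding.decode_image_identity(
                [u for u in units if u.area == "VISp"], schedule,
                window=(-0.75, 1.0), seed=config.stage_seed("decoding"),
            )
            in_stim = ((res.bin_centers >= -0.75) & (res.bin_centers < -0.5)) | (
                (res.bin_centers >= 0.75) & (res.bin_centers < 1.0))
            in_om = (res.bin_centers >= 0) & (res.bin_centers < 0.25)
            summary["decoding"] = {
                "chance": res.chance,
                "mean_accuracy_omission": float(res.accuracy[in_om].mean()),
                "mean_accuracy_stimulus": float(res.accuracy[in_stim].mean()),
            }
        except ValueError as err:
            summary["decoding"] = {"skipped": str(err)}

    if out:
        (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    return summary


def _synthetic_interaction_session(rng, latent_condition="omission",
                                   n_trials=60, n_bins=5, n_units=10, rho=0.8):
    X, Y = {}, {}
    for cond in ("stimulus", "omission"):
        cx = rng.normal(size=(n_trials, n_bins, n_units))
        cy = rng.normal(size=(n_trials, n_bins, n_units))
        if cond == latent_condition:
            z = rng.normal(size=(n_trials, 1, 1))
            cx = cx + rho * z
            cy = cy + rho * z
        X[cond], _ = crossarea.residualize(cx)
        Y[cond], _ = crossarea.residualize(cy)
    return {"X": X, "Y": Y}
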