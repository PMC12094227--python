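"""Plain-text table I/O for schedules, spikes, and derived tables.

All tables are tab-separated; derived tables carry the pipeline config
hash in a leading ``# config_hash:`` comment line.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synth import StimulusSchedule, UnitRecord

__all__ = [
    "config_hash",
    "write_table",
    "read_table",
    "write_schedule",
    "read_schedule",
    "write_spikes",
    "write_units_manifest",
]


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_table(df: pd.DataFrame, path, cfg_hash: str | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if cfg_hash:
            fh.write(f"# config_hash: {cfg_hash}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_schedule(schedule: StimulusSchedule, path, cfg_hash: str | None = None) -> None:
    write_table(schedule.slots, path, cfg_hash)
    sidecar = Path(path).with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {
                "cycle_period_s": schedule.cycle_period_s,
                "image_duration_s": schedule.image_duration_s,
                "n_images": schedule.n_images,
            },
            indent=2,
        )
    )


def read_schedule(path) -> StimulusSchedule:
    slots = read_table(path)
    meta = json.loads(Path(path).with_suffix(".json").read_text())
    return StimulusSchedule(slots=slots, **meta)


def write_spikes(units: list[UnitRecord], path, cfg_hash: str | None = None) -> None:
    frames = [
        pd.DataFrame({"unit_id": u.unit_id, "spike_time_s": u.spike_times}) for u in units
    ]
    write_table(pd.concat(frames, ignore_index=True), path, cfg_hash)


def write_units_manifest(units: list[UnitRecord], path, cfg_hash: str | None = None) -> None:
    df = pd.DataFrame(
        {
            "unit_id": [u.unit_id for u in units],
            "area": [u.area for u in units],
            "layer": [u.layer for u in units],
            "archetype": [u.archetype for u in units],
            "genotype_line": [u.genotype_line for u in units],
            "waveform_duration_ms": [u.waveform_duration_ms for u in units],
            "isi_violation_rate": [u.isi_violation_rate for u in units],
            "presence_ratio": [u.presence_ratio for u in units],
            "amplitude_cutoff": [u.amplitude_cutoff for u in units],
            "mean_rate_hz": [u.mean_rate_hz for u in units],
            "cell_type": [u.cell_type for u in units],
        }
    )
    write_table(df, path, cfg_hash)
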