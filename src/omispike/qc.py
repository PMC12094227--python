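"""Unit inclusion filters and cell-type classification.

Units enter the analysis only if they pass four quality criteria
(strict inequalities): ISI violation rate < 0.5%, presence ratio > 0.9,
amplitude cutoff < 0.1, and mean firing rate > 0.1 Hz.

Cell types: SST and VIP interneurons are identified in the matching
transgenic lines by their response to optogenetic pulses (rate at least
1 SD above baseline and a significant Kolmogorov-Smirnov difference);
among the remaining units, narrow fast-firing cells (< 0.4 ms waveform,
> 10 Hz) are putative PV interneurons and wide slow-firing cells
(> 0.4 ms, < 10 Hz) putative pyramidal cells; everything else is
unclassified.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .synth import UnitRecord

__all__ = ["QcThresholds", "filter_units", "classify_cell_type", "classify_units"]

CELL_TYPES = ("SST", "VIP", "putative_PV", "putative_pyramidal", "unclassified")


@dataclass(frozen=True)
class QcThresholds:
    max_isi_viol: float = 0.005
    min_presence: float = 0.9
    max_amp_cutoff: float = 0.1
    min_rate_hz: float = 0.1

    def __post_init__(self):
        if min(self.max_isi_viol, self.min_presence, self.max_amp_cutoff, self.min_rate_hz) <= 0:
            raise ValueError("thresholds must be positive")


def filter_units(
    units: Iterable[UnitRecord], thresholds: QcThresholds = QcThresholds()
) -> list[UnitRecord]:
    """Units strictly satisfying all four quality inequalities."""
    out = []
    for u in units:
        if (
            u.isi_violation_rate < thresholds.max_isi_viol
            and u.presence_ratio > thresholds.min_presence
            and u.amplitude_cutoff < thresholds.max_amp_cutoff
            and u.mean_rate_hz > thresholds.min_rate_hz
        ):
            out.append(u)
    return out


def classify_cell_type(
    unit: UnitRecord,
    opto_stats: Mapping[str, Sequence[float]] | None = None,
    alpha: float = 0.05,
) -> str:
    """Assign one of SST / VIP / putative_PV / putative_pyramidal / unclassified.

    ``opto_stats`` holds per-trial rates: ``baseline_rates_per_trial`` and
    ``stim_rates_per_trial``.  A tagged line without opto trials falls
    through to the waveform rules with a warning.
    """
    line = unit.genotype_line
    if line in ("Sst", "Vip"):
        if opto_stats is None:
            warnings.warn(
                f"unit {unit.unit_id}: tagged line {line!r} without opto trials; "
                "using waveform rules only"
            )
        else:
            base = np.asarray(opto_stats["baseline_rates_per_trial"], dtype=float)
            stim = np.asarray(opto_stats["stim_rates_per_trial"], dtype=float)
            mu, sd = base.mean(), base.std(ddof=1) if base.size > 1 else 0.0
            elevated = stim.mean() >= mu + sd
            p = stats.ks_2samp(stim, base).pvalue if stim.size and base.size else 1.0
            if elevated and p < alpha:
                return "SST" if line == "Sst" else "VIP"
            return "unclassified"
    dur, rate = unit.waveform_duration_ms, unit.mean_rate_hz
    if dur < 0.4 and rate > 10.0:
        return "putative_PV"
    if dur > 0.4 and rate < 10.0:
        return "putative_pyramidal"
    return "unclassified"


def classify_units(
    units: Iterable[UnitRecord],
    opto_stats: Mapping[str, Mapping[str, Sequence[float]]] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Classify every unit; sets ``unit.cell_type`` and returns a table."""
    rows = []
    for u in units:
        per_unit = None if opto_stats is None else opto_stats.get(u.unit_id)
        label = classify_cell_type(u, per_unit, alpha=alpha)
        u.cell_type = label
        rows.append({"unit_id": u.unit_id, "area": u.area, "cell_type": label})
    return pd.DataFrame(rows)
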