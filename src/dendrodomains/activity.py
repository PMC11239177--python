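"""Per-synapse activity summaries and inclusion filters.

A synapse's transmission frequency f is the number of detected transmission
events divided by the total recorded time, in events · min⁻¹; per-recording
frequencies f_r feed the trend analysis.  Synapses transmitting slower than
0.03 min⁻¹ are treated as non-functional and excluded from all functional
statistics.  Within each age group, synapses in the top 20th percentile of f
are flagged high-activity; these anchor the dendritic domains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .detection import Barrage, TransmissionEvent
from .morphology import DendriteTree, TreePosition

__all__ = [
    "Recording",
    "Synapse",
    "Experiment",
    "compute_frequencies",
    "filter_active",
    "classify_high_activity",
    "synapse_summary_table",
]

DEFAULT_F_MIN = 0.03  # min⁻¹
DEFAULT_PERCENTILE = 80.0


@dataclass
class Recording:
    recording_id: str
    duration_min: float

    def __post_init__(self) -> None:
        if self.duration_min <= 0:
            raise ValueError("recording duration must be positive")


@dataclass
class Synapse:
    synapse_id: str
    position: TreePosition
    kind: str  # "spine" | "shaft"
    events: list[TransmissionEvent] = field(default_factory=list)
    f_per_recording: dict[str, float] = field(default_factory=dict)
    f: float | None = None  # overall frequency, min⁻¹
    high_activity: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("spine", "shaft"):
            raise ValueError(f"synapse kind must be spine or shaft, got {self.kind}")


@dataclass
class Experiment:
    dendrite_id: str
    tree: DendriteTree
    synapses: list[Synapse]
    recordings: list[Recording]
    barrages: list[Barrage] = field(default_factory=list)
    age: int = 10  # postnatal day

    def __post_init__(self) -> None:
        if not 8 <= self.age <= 13:
            raise ValueError(f"age P{self.age} outside the studied window P8–13")

    @property
    def age_group(self) -> str:
        return "P8-10" if self.age <= 10 else "P12-13"

    @property
    def total_minutes(self) -> float:
        return float(sum(r.duration_min for r in self.recordings))


def compute_frequencies(experiment: Experiment) -> Experiment:
    """Fill per-recording frequencies f_r and the overall frequency f
    (duration-weighted mean of f_r) for every synapse, in min⁻¹."""
    total = experiment.total_minutes
    if total <= 0:
        raise ValueError("total recording duration is zero")
    rec_ids = {r.recording_id for r in experiment.recordings}
    for syn in experiment.synapses:
        counts = {r.recording_id: 0 for r in experiment.recordings}
        for ev in syn.events:
            if ev.recording_id not in rec_ids:
                raise ValueError(
                    f"event of synapse {syn.synapse_id} references unknown "
                    f"recording {ev.recording_id}"
                )
            counts[ev.recording_id] += 1
        syn.f_per_recording = {
            r.recording_id: counts[r.recording_id] / r.duration_min
            for r in experiment.recordings
        }
        syn.f = sum(counts.values()) / total
    return experiment


def filter_active(synapses: list[Synapse], f_min: float = DEFAULT_F_MIN) -> list[Synapse]:
    """Retain synapses with overall transmission frequency f ≥ f_min
    (default 0.03 min⁻¹); idempotent."""
    for s in synapses:
        if s.f is None:
            raise ValueError("frequencies must be computed before filtering")
    return [s for s in synapses if s.f >= f_min]


def classify_high_activity(
    experiments: list[Experiment],
    percentile: float = DEFAULT_PERCENTILE,
    per_dendrite: bool = False,
    exact_day: bool = False,
) -> dict[str, float]:
    """Flag high-activity synapses: those at or above the given percentile of
    transmission frequency within their age group (synapses pooled over all
    dendrites of the group; ties at the threshold are included).

    Returns the frequency threshold used per group.  ``per_dendrite`` computes
    the cut within each dendrite instead of pooling; ``exact_day`` groups by
    postnatal day instead of by age group.
    """
    def group_key(e: Experiment) -> str:
        return f"P{e.age}" if exact_day else e.age_group

    groups: dict[str, list[Synapse]] = {}
    for e in experiments:
        key_base = group_key(e)
        for s in e.synapses:
            if s.f is None:
                raise ValueError("frequencies must be computed before classifying")
            key = f"{key_base}/{e.dendrite_id}" if per_dendrite else key_base
            groups.setdefault(key, []).append(s)
    thresholds: dict[str, float] = {}
    for key, syns in groups.items():
        if len(syns) < 5:
            raise ValueError(f"group {key}: need ≥ 5 synapses to take a percentile")
        fs = np.array([s.f for s in syns], dtype=float)
        thr = float(np.percentile(fs, percentile))  # linear interpolation
        thresholds[key] = thr
        for s in syns:
            s.high_activity = bool(s.f >= thr)
    return thresholds


def synapse_summary_table(experiments: list[Experiment]) -> pd.DataFrame:
    """One row per synapse: id, dendrite, age, age group, type, f, flag."""
    rows = []
    for e in experiments:
        for s in e.synapses:
            rows.append(
                {
                    "synapse_id": s.synapse_id,
                    "dendrite_id": e.dendrite_id,
                    "age": e.age,
                    "age_group": e.age_group,
                    "type": s.kind,
                    "f": s.f,
                    "n_events": len(s.events),
                    "high_activity": s.high_activity,
                }
            )
    return pd.DataFrame(rows)
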