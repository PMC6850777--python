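"""Core domain records shared across the pipeline.

A *GLM* (genome-level missegregation) is a mitotic failure in which the
majority of a mother cell's chromatin transiently enters the daughter bud
before anaphase.  Most GLMs are corrected by retrograde transport of the
chromatin back to the mother; a GLM that is not corrected before cytokinesis
or mother death is *terminal* and ends the mother's replicative lifespan.

Replicative lifespan (RLS) is the number of daughter cells a mother produces
before irreversible cell-cycle exit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "FATES",
    "OUTCOMES",
    "CellRecord",
    "GLMEvent",
    "TracePair",
    "DaughterSegment",
]

#: Terminal fates of a mother cell. ``died`` = visible loss of cell-wall
#: integrity; ``senesced`` = irreversible arrest with the wall intact;
#: censored cells left observation by trap loss or end of the run.
FATES = ("died", "senesced", "censored_lost", "censored_end")

#: Resolutions of a GLM. ``corrected`` = chromatin returned to the mother;
#: the two terminal outcomes distinguish what interrupted the correction.
OUTCOMES = ("corrected", "terminal_cytokinesis", "terminal_death")


@dataclass
class CellRecord:
    """One mother cell's division history and fate.

    ``rls`` always equals the number of recorded division times; division
    times are strictly increasing and the fate time never precedes the last
    division.
    """

    cell_id: str
    strain: str
    first_detection_min: float
    division_times_min: list[float]
    fate: str
    fate_time_min: float

    @property
    def rls(self) -> int:
        """Replicative lifespan: number of daughters produced."""
        return len(self.division_times_min)

    @property
    def censored(self) -> bool:
        return self.fate in ("censored_lost", "censored_end")

    def validate(self) -> None:
        if self.fate not in FATES:
            raise ValueError(f"unknown fate {self.fate!r} for cell {self.cell_id}")
        t = np.asarray(self.division_times_min, dtype=float)
        if t.size and not np.all(np.diff(t) > 0):
            raise ValueError(f"division times not strictly increasing for cell {self.cell_id}")
        if t.size and self.fate_time_min < t[-1] - 1e-9:
            raise ValueError(
                f"fate_time_min {self.fate_time_min} precedes last division for cell {self.cell_id}"
            )


@dataclass
class GLMEvent:
    """One genome-level missegregation, ground-truth or called.

    ``cycle_index`` is the mother's replicative age at the event (1-based:
    the cycle that produces daughter number ``cycle_index``).  A corrected
    event carries a ``resolution_min``; terminal events do not.  At most one
    event exists per (cell, cycle) in a scored set: when several occur in
    one cycle only the final one is scored, and the generator records the
    superseded onset separately so traces can reproduce the earlier dip.
    """

    cell_id: str
    cycle_index: int
    onset_min: float
    resolution_min: Optional[float] = None
    outcome: str = "corrected"
    superseded_onset_min: Optional[float] = None

    @property
    def duration_min(self) -> Optional[float]:
        """Arrest duration; defined only for corrected events."""
        if self.resolution_min is None:
            return None
        return self.resolution_min - self.onset_min

    def validate(self) -> None:
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if (self.outcome == "corrected") != (self.resolution_min is not None):
            raise ValueError(
                f"event {self.cell_id}/{self.cycle_index}: corrected outcome and "
                "resolution_min must be present together"
            )
        if self.resolution_min is not None and self.resolution_min <= self.onset_min:
            raise ValueError(
                f"event {self.cell_id}/{self.cycle_index}: resolution must follow onset"
            )


@dataclass
class DaughterSegment:
    """Daughter-bud fluorescence from bud emergence to washout.

    The segment lies entirely within one mother cycle; ``start_min`` is the
    time of its first sample and values share the mother's sampling cadence.
    """

    cycle_index: int
    start_min: float
    signal: np.ndarray

    def times(self, interval: float) -> np.ndarray:
        return self.start_min + interval * np.arange(len(self.signal))


@dataclass
class TracePair:
    """Uniformly sampled mother signal plus per-cycle daughter segments.

    Acquisition cadence defaults to 5 min, matching timelapse microscopy of
    histone-tagged mother cells in microfluidic traps.
    """

    cell_id: str
    start_min: float
    mother_signal: np.ndarray
    daughter_segments: list[DaughterSegment] = field(default_factory=list)
    sampling_interval_min: float = 5.0
    mother_death_flag_min: Optional[float] = None

    @property
    def n_frames(self) -> int:
        return len(self.mother_signal)

    def times(self) -> np.ndarray:
        return self.start_min + self.sampling_interval_min * np.arange(self.n_frames)

    def frame_of(self, t_min: float) -> int:
        """Nearest frame index for an absolute time (clipped to the trace)."""
        f = int(round((t_min - self.start_min) / self.sampling_interval_min))
        return min(max(f, 0), self.n_frames - 1)

    def daughter_at(self, frame: int) -> Optional[float]:
        """Daughter signal at a mother frame, or None if no bud is present."""
        t = self.start_min + frame * self.sampling_interval_min
        for seg in self.daughter_segments:
            j = (t - seg.start_min) / self.sampling_interval_min
            jr = int(round(j))
            if -0.25 <= j <= len(seg.signal) - 0.75 and 0 <= jr < len(seg.signal):
                return float(seg.signal[jr])
        return None

    def validate(self) -> None:
        if self.sampling_interval_min <= 0:
            raise ValueError("sampling_interval_min must be positive")
        if np.any(np.asarray(self.mother_signal) < 0):
            raise ValueError(f"negative mother signal for cell {self.cell_id}")
        spans: list[tuple[float, float]] = []
        for seg in self.daughter_segments:
            end = seg.start_min + (len(seg.signal) - 1) * self.sampling_interval_min
            spans.append((seg.start_min, end))
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            if b0 <= a1:
                raise ValueError(f"overlapping daughter segments for cell {self.cell_id}")


def events_by_cell(events: Sequence[GLMEvent]) -> dict[str, list[GLMEvent]]:
    """Group events per cell, sorted by cycle index."""
    out: dict[str, list[GLMEvent]] = {}
    for ev in events:
        out.setdefault(ev.cell_id, []).append(ev)
    for evs in out.values():
        evs.sort(key=lambda e: (e.cycle_index, e.onset_min))
    return out
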