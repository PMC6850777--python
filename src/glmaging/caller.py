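"""Automated GLM scoring on mother/daughter fluorescence traces.

The caller reproduces, as explicit rules, what a human scorer does on the
histone channel:

* a **GLM onset** is a sustained collapse of the mother signal far below the
  normal 1N post-anaphase level (the majority of the chromatin has entered
  the daughter bud), with a concurrent gain in the daughter;
* a **correction** is a simultaneous daughter-signal decrease and
  mother-signal increase, after which the mother regains a normal 1N level;
* an event is **terminal** when the daughter visibly separates (its signal
  segment ends in washout) or the mother dies before any correction;
* when one cycle contains several candidate events only the **final** one
  is scored.

All thresholds live in :class:`CallerParams`; the defaults quantify
"majority of the signal in the daughter" as retention below 35% of the
cycle's 2N reference (normal anaphase retains ~50%) with two-frame
persistence at the 5-min cadence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import CellRecord, GLMEvent, TracePair

__all__ = [
    "CallerParams",
    "CycleSegmentation",
    "segment_cycles",
    "call_glms",
    "detect_correction",
    "classify_outcome",
    "measure_durations",
    "call_cohort",
]


@dataclass
class CallerParams:
    glm_retention_threshold: float = 0.35
    min_persist_frames: int = 2
    derivative_z: float = 3.0
    correction_window_frames: int = 3
    recovery_fraction: float = 0.8

    def validate(self) -> None:
        if not (0.0 < self.glm_retention_threshold < 0.5):
            raise ValueError(
                "glm_retention_threshold must lie in (0, 0.5): normal anaphase "
                "retains ~50% of the 2N signal"
            )
        if self.min_persist_frames < 1:
            raise ValueError("min_persist_frames must be >= 1")
        if self.correction_window_frames < 1:
            raise ValueError("correction_window_frames must be >= 1")


@dataclass
class CycleSegmentation:
    """Cycle boundaries (frame indices of divisions) and reference levels.

    Cycle ``a`` (1-based) spans frames ``[boundaries[a-1], boundaries[a])``
    with an implicit leading boundary at frame 0; a trailing partial cycle
    after the last division is indexed ``len(boundaries) + 1``.
    """

    cell_id: str
    boundaries: list[int]
    ref_2n: list[float]
    ref_1n: list[float]

    def n_cycles(self) -> int:
        return len(self.ref_2n)

    def cycle_span(self, a: int, n_frames: int) -> tuple[int, int]:
        starts = [0] + self.boundaries
        ends = self.boundaries + [n_frames]
        return starts[a - 1], ends[a - 1]

    def validate(self) -> None:
        b = np.asarray(self.boundaries)
        if b.size and not np.all(np.diff(b) > 0):
            raise ValueError(f"cycle boundaries not strictly increasing for {self.cell_id}")
        for a, (hi, lo) in enumerate(zip(self.ref_2n, self.ref_1n), start=1):
            if not hi > lo:
                raise ValueError(
                    f"cycle {a} of {self.cell_id}: 2N reference {hi} not above 1N {lo}"
                )


def _reference_levels(vals: np.ndarray) -> tuple[float, float]:
    """Robust 2N/1N plateau levels for one cycle's mother samples."""
    vmax = float(np.quantile(vals, 0.97))
    plateau = vals[vals >= 0.85 * vmax]
    ref2 = float(np.median(plateau)) if plateau.size else vmax
    near_1n = vals[(vals >= 0.35 * ref2) & (vals <= 0.65 * ref2)]
    ref1 = float(np.median(near_1n)) if near_1n.size >= 2 else 0.5 * ref2
    return ref2, ref1


def segment_cycles(
    trace: TracePair, annotations: Optional[Sequence[float]] = None
) -> CycleSegmentation:
    """Segment a mother trace into cell cycles.

    With ``annotations`` (division times in minutes) the boundaries follow
    them exactly. Without annotations, divisions are located from daughter
    washouts when daughter segments are present, falling back to sustained
    mother-signal drops of >= 30% from the running plateau (a normal
    anaphase halving qualifies; the deeper collapse of a GLM arrest does
    not end a cycle until its daughter washes out).
    """
    m = np.asarray(trace.mother_signal, dtype=float)
    dt = trace.sampling_interval_min
    if annotations is not None:
        bset: list[int] = []
        for t_div in annotations:
            f = int(np.ceil((t_div - trace.start_min) / dt - 1e-9))
            f = min(max(f, 1), trace.n_frames)
            if not bset or f > bset[-1]:
                bset.append(f)
        boundaries = bset
    elif trace.daughter_segments:
        boundaries = []
        for seg in trace.daughter_segments:
            f_end = trace.frame_of(seg.start_min + (len(seg.signal) - 1) * dt) + 1
            if f_end <= trace.n_frames and (not boundaries or f_end > boundaries[-1]):
                boundaries.append(f_end)
    else:
        boundaries = _boundaries_from_drops(m)
        if len(boundaries) < 2:
            raise ValueError(
                f"trace {trace.cell_id}: unannotated segmentation found fewer than "
                "2 cycles"
            )

    ref2, ref1 = [], []
    starts = [0] + boundaries
    ends = boundaries + [trace.n_frames]
    for s, e in zip(starts, ends):
        if e - s < 2:
            # Degenerate trailing sliver: reuse previous references.
            if ref2:
                ref2.append(ref2[-1]); ref1.append(ref1[-1])
                continue
            s, e = 0, trace.n_frames
        hi, lo = _reference_levels(m[s:e])
        ref2.append(hi); ref1.append(lo)

    seg = CycleSegmentation(trace.cell_id, boundaries, ref2, ref1)
    seg.validate()
    return seg


def _boundaries_from_drops(m: np.ndarray) -> list[int]:
    """Division boundaries as sustained >=30% drops from a running plateau."""
    boundaries: list[int] = []
    plateau = m[0]
    last = -3
    for f in range(1, len(m) - 1):
        plateau = max(plateau * 0.995, m[f - 1])
        dropped = m[f] < 0.7 * plateau and m[f + 1] < 0.7 * plateau
        anaphase_like = m[f] > 0.38 * plateau  # deeper collapse = GLM, not division
        if dropped and anaphase_like and f - last > 2:
            boundaries.append(f + 2)  # washout trails the anaphase drop
            last = f
            plateau = m[f]
    return boundaries


def _noise_floor(m: np.ndarray, seg: CycleSegmentation, n_frames: int) -> float:
    """Per-trace plateau noise: median |successive difference| at the 1N level."""
    diffs: list[float] = []
    for a in range(1, seg.n_cycles() + 1):
        s, e = seg.cycle_span(a, n_frames)
        vals = m[s:e]
        ref1 = seg.ref_1n[a - 1]
        sel = (vals >= 0.8 * ref1) & (vals <= 1.2 * ref1)
        v = vals[sel]
        if v.size >= 3:
            diffs.extend(np.abs(np.diff(v)))
    if not diffs:
        diffs = list(np.abs(np.diff(m)))
    floor = float(np.median(diffs)) if diffs else 0.0
    return max(floor, 1e-9 * float(np.max(m, initial=1.0)))


def call_glms(
    trace: TracePair,
    seg: CycleSegmentation,
    params: Optional[CallerParams] = None,
) -> list[GLMEvent]:
    """Call GLM onsets; at most one (the final candidate) per cycle."""
    params = params or CallerParams()
    params.validate()
    seg.validate()
    m = np.asarray(trace.mother_signal, dtype=float)
    dt = trace.sampling_interval_min
    events: list[GLMEvent] = []

    for a in range(1, seg.n_cycles() + 1):
        s, e = seg.cycle_span(a, trace.n_frames)
        if e - s < 2:
            continue
        ref2 = seg.ref_2n[a - 1]
        thr = params.glm_retention_threshold * ref2
        below = m[s:e] < thr
        # A low run truncated by the cycle end is an arrest interrupted by
        # washout (or death): it counts even below the persistence window.
        runs = [
            (r0, r1)
            for r0, r1 in _runs(below, 1)
            if r1 - r0 >= params.min_persist_frames or r1 == e - s
        ]
        onset_frame: Optional[int] = None
        for r0, r1 in runs:
            f0 = s + r0
            probe = range(f0, min(s + r1, f0 + 3))
            d_now = [trace.daughter_at(f) for f in probe]
            d_now = [d for d in d_now if d is not None]
            if not d_now:
                continue
            d_pre = [trace.daughter_at(f) for f in range(s, f0)]
            d_pre = [d for d in d_pre if d is not None]
            baseline = float(np.median(d_pre)) if d_pre else 0.0
            lost = ref2 - float(np.mean(m[f0 : min(s + r1, f0 + 3)]))
            if float(np.mean(d_now)) - baseline >= 0.5 * lost:
                onset_frame = f0  # keep scanning: only the final event is scored
        if onset_frame is not None:
            events.append(
                GLMEvent(
                    cell_id=trace.cell_id,
                    cycle_index=a,
                    onset_min=trace.start_min + onset_frame * dt,
                    resolution_min=None,
                    outcome="terminal_cytokinesis",  # provisional; classified later
                )
            )
    return events


def _runs(mask: np.ndarray, min_len: int) -> list[tuple[int, int]]:
    """(start, end) index pairs of True runs with length >= min_len."""
    out = []
    n = len(mask)
    f = 0
    while f < n:
        if mask[f]:
            g = f
            while g < n and mask[g]:
                g += 1
            if g - f >= min_len:
                out.append((f, g))
            f = g
        else:
            f += 1
    return out


def detect_correction(
    event: GLMEvent,
    trace: TracePair,
    seg: CycleSegmentation,
    params: Optional[CallerParams] = None,
) -> Optional[float]:
    """Time of correction (simultaneous daughter fall / mother rise), or None.

    The first frame after onset where, over the correction window, the
    daughter slope is below ``-z * noise_floor`` while the mother slope is
    above ``+z * noise_floor`` — both with an immediate same-direction step —
    and the mother subsequently regains ``recovery_fraction`` of the 1N
    level.
    """
    params = params or CallerParams()
    m = np.asarray(trace.mother_signal, dtype=float)
    dt = trace.sampling_interval_min
    a = event.cycle_index
    s, e = seg.cycle_span(a, trace.n_frames)
    floor = _noise_floor(m, seg, trace.n_frames)
    z = params.derivative_z
    w = params.correction_window_frames
    ref1 = seg.ref_1n[a - 1]
    f_on = trace.frame_of(event.onset_min)

    for f in range(f_on + 1, e - 1):
        fw = min(f + w, trace.n_frames - 1)
        if fw <= f:
            break
        d0 = trace.daughter_at(f)
        if d0 is None:
            continue
        # The daughter washes out at division; clamp its window to the last
        # frame where the bud is still present.
        fw_d = fw
        dw = trace.daughter_at(fw_d)
        while dw is None and fw_d > f + 1:
            fw_d -= 1
            dw = trace.daughter_at(fw_d)
        if dw is None:
            continue
        # Timing anchor: the mother's first departure from the arrest
        # plateau (median of samples since onset). Simultaneity: over the
        # correction window the mother gains and the daughter loses signal,
        # each beyond z times the plateau noise of a sample difference.
        arrest_level = float(np.median(m[f_on : f + 1]))
        if m[f + 1] - arrest_level > z * floor and dw - d0 < -z * floor:
            # Recovery may complete just after the division boundary (the
            # daughter separates once the transfer is done); look a window
            # past the cycle end. Terminal arrests never recover there.
            f_hi = min(e + w + 1, trace.n_frames)
            if float(np.max(m[f:f_hi])) >= params.recovery_fraction * ref1:
                return trace.start_min + f * dt
    return None


def classify_outcome(
    event: GLMEvent,
    trace: TracePair,
    record: Optional[CellRecord] = None,
    resolution_min: Optional[float] = None,
) -> str:
    """Assign corrected / terminal_cytokinesis / terminal_death.

    ``resolution_min`` is the result of :func:`detect_correction` (None if
    no correction was found). For an uncorrected event the question is what
    interrupted the arrest first: when the birth annotations (``record``)
    show the event's cycle completed, the daughter visibly separated —
    terminal cytokinesis; an event in an uncompleted final cycle of a cell
    with a death flag is a terminal death. Without a record the death flag
    must strictly precede the daughter washout to score a death.
    """
    if resolution_min is not None:
        return "corrected"
    death = trace.mother_death_flag_min
    if record is not None:
        if event.cycle_index > record.rls and death is not None:
            return "terminal_death"
        return "terminal_cytokinesis"
    seg_end = None
    dt = trace.sampling_interval_min
    for dseg in trace.daughter_segments:
        end = dseg.start_min + (len(dseg.signal) - 1) * dt
        if dseg.start_min - dt <= event.onset_min <= end + dt:
            seg_end = end
            break
    if death is not None and (seg_end is None or death < seg_end - dt):
        return "terminal_death"
    return "terminal_cytokinesis"


def measure_durations(events: Sequence[GLMEvent]) -> pd.DataFrame:
    """Duration table (minutes) for corrected events; terminal excluded."""
    rows = []
    for ev in events:
        if ev.outcome == "corrected":
            if ev.resolution_min is None:
                raise ValueError(
                    f"corrected event {ev.cell_id}/{ev.cycle_index} lacks a resolution time"
                )
            rows.append(
                {
                    "cell_id": ev.cell_id,
                    "cycle_index": ev.cycle_index,
                    "onset_min": ev.onset_min,
                    "duration_min": ev.resolution_min - ev.onset_min,
                }
            )
    return pd.DataFrame(rows, columns=["cell_id", "cycle_index", "onset_min", "duration_min"])


def call_cohort(
    traces: Sequence[TracePair],
    records: Optional[Sequence[CellRecord]] = None,
    params: Optional[CallerParams] = None,
) -> list[GLMEvent]:
    """End-to-end calling for a cohort: segment, call, resolve, classify.

    Division-time annotations are taken from the matching records when
    provided (the cohort table is the birth-annotation channel of the
    experiment); otherwise traces are segmented unannotated.
    """
    params = params or CallerParams()
    by_id = {r.cell_id: r for r in records} if records is not None else {}
    out: list[GLMEvent] = []
    for trace in traces:
        rec = by_id.get(trace.cell_id)
        ann = rec.division_times_min if rec is not None else None
        seg = segment_cycles(trace, annotations=ann)
        for ev in call_glms(trace, seg, params):
            res = detect_correction(ev, trace, seg, params)
            ev.resolution_min = res
            ev.outcome = classify_outcome(ev, trace, rec, resolution_min=res)
            if ev.outcome != "corrected":
                ev.resolution_min = None
            ev.validate()
            out.append(ev)
    return out
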