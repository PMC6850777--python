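"""Mother/daughter fluorescence trace synthesis.

The histone signal of a cycling mother alternates between a 1N post-mitotic
plateau and a 2N pre-mitotic plateau: flat through G1, a linear S-phase rise
as chromatin doubles, a 2N plateau through G2/M, and an anaphase drop back
to 1N as half the chromatin enters the daughter. The daughter bud appears at
the start of S phase and carries essentially no histone signal until
anaphase, when it briefly holds its 1N share before separating (washout).

During a GLM the anaphase-time transfer is abnormal: the mother retains only
``leak``×2N (leak drawn per event from the preset's leak range) and the
daughter holds the complementary (1-leak)×2N throughout the arrest. A
correction returns the missegregated chromatin over a 10-15 min window —
daughter falling while the mother rises, summed signal conserved — after
which both sit at 1N until the daughter separates. Terminal events end the
daughter segment (cytokinesis washout) or the mother trace (death) without
restoration.

Multiplicative Gaussian noise and exponential photobleaching are applied
last; with both disabled the summed mother+daughter signal is exactly
conserved through any GLM transfer and its correction.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from ..presets import StrainPreset
from ..types import CellRecord, DaughterSegment, GLMEvent, TracePair, events_by_cell

__all__ = ["synthesize_traces", "CORRECTION_TRANSITION_MIN"]

#: Duration of the simultaneous daughter-fall / mother-rise during correction.
CORRECTION_TRANSITION_MIN = 12.5
#: Anaphase-to-cytokinesis lag in a normal division.
ANAPHASE_LEAD_MIN = 10.0
#: Fractions of the normal cycle spent in G1 and in S phase.
G1_FRAC, S_FRAC = 0.3, 0.3
#: 1N signal level in arbitrary units (2N is twice this).
LEVEL_1N = 1.0


def _ramp(t: np.ndarray, t0: float, t1: float, v0: float, v1: float) -> np.ndarray:
    """Piecewise-linear interpolation of the [t0, t1] transition."""
    frac = np.clip((t - t0) / max(t1 - t0, 1e-9), 0.0, 1.0)
    return v0 + (v1 - v0) * frac


def synthesize_traces(
    records: Sequence[CellRecord],
    events: Sequence[GLMEvent],
    preset: StrainPreset,
    seed: int,
) -> list[TracePair]:
    """Render noisy mother/daughter traces for simulated cells.

    Every event must reference an existing record and a cycle within its
    lifespan (terminal-death events occupy the cycle after the last
    completed division); offenders are reported by id.
    """
    by_id = {r.cell_id: r for r in records}
    bad = [
        f"{e.cell_id}/{e.cycle_index}"
        for e in events
        if e.cell_id not in by_id
        or e.cycle_index > len(by_id[e.cell_id].division_times_min) + 1
        or e.cycle_index < 1
    ]
    if bad:
        raise ValueError(f"events reference unknown cells or cycles: {', '.join(bad)}")

    rng = np.random.default_rng(seed)
    by_cell = events_by_cell(events)
    out = []
    for rec in records:
        out.append(_one_trace(rec, by_cell.get(rec.cell_id, []), preset, rng))
    return out


def _one_trace(
    rec: CellRecord, cell_events: Sequence[GLMEvent], preset: StrainPreset,
    rng: np.random.Generator,
) -> TracePair:
    dt = 5.0
    t0 = rec.first_detection_min
    end = rec.fate_time_min
    n = max(2, int(np.floor((end - t0) / dt)) + 1)
    t = t0 + dt * np.arange(n)
    mother = np.full(n, LEVEL_1N)
    segments: list[DaughterSegment] = []
    ev_by_cycle = {e.cycle_index: e for e in cell_events}

    bounds = [t0] + list(rec.division_times_min)
    death_flag: Optional[float] = rec.fate_time_min if rec.fate == "died" else None

    n_cycles = len(rec.division_times_min)
    # A trailing cycle exists when the mother died mid-cycle (terminal-death
    # event) or kept cycling until censoring/senescence; render its pre-event
    # portion too so the trace continues to the end of observation.
    trailing_event = ev_by_cycle.get(n_cycles + 1)

    for a in range(1, n_cycles + 1):
        _render_cycle(mother, segments, t, dt, bounds[a - 1], bounds[a], a,
                      ev_by_cycle.get(a), preset, rng, rec)
    if trailing_event is not None:
        _render_terminal_death_cycle(mother, segments, t, dt, bounds[-1], trailing_event,
                                     preset, rng, rec)

    # Measurement model: photobleaching then multiplicative shot/readout noise.
    if preset.bleach_per_frame > 0:
        for arr in [mother]:
            arr *= (1.0 - preset.bleach_per_frame) ** np.arange(n)
        for seg in segments:
            f0 = (seg.start_min - t0) / dt
            seg.signal *= (1.0 - preset.bleach_per_frame) ** (f0 + np.arange(len(seg.signal)))
    if preset.trace_noise_cv > 0:
        mother *= 1.0 + preset.trace_noise_cv * rng.standard_normal(n)
        np.clip(mother, 0.0, None, out=mother)
        for seg in segments:
            seg.signal *= 1.0 + preset.trace_noise_cv * rng.standard_normal(len(seg.signal))
            np.clip(seg.signal, 0.0, None, out=seg.signal)

    tp = TracePair(
        cell_id=rec.cell_id,
        start_min=t0,
        mother_signal=mother,
        daughter_segments=segments,
        sampling_interval_min=dt,
        mother_death_flag_min=death_flag,
    )
    tp.validate()
    return tp


def _cycle_phases(start: float, div: float, event: Optional[GLMEvent]):
    """(s_start, plateau_start, anaphase) times for one cycle."""
    if event is not None:
        anaphase = event.onset_min
    else:
        anaphase = div - ANAPHASE_LEAD_MIN
    normal_len = max(anaphase - start, 1e-6)
    return start + G1_FRAC * normal_len, start + (G1_FRAC + S_FRAC) * normal_len, anaphase


def _write(mother: np.ndarray, t: np.ndarray, lo: float, hi: float, values: np.ndarray) -> None:
    sel = (t >= lo - 1e-9) & (t < hi - 1e-9)
    mother[sel] = values[sel]


def _render_cycle(mother, segments, t, dt, start, div, a, event, preset, rng, rec) -> None:
    s_start, plat_start, anaphase = _cycle_phases(start, div, event)
    lvl2 = 2.0 * LEVEL_1N

    # Mother: G1 at 1N, S-phase rise, 2N plateau up to anaphase/onset.
    _write(mother, t, start, s_start, np.full_like(t, LEVEL_1N))
    _write(mother, t, s_start, plat_start, _ramp(t, s_start, plat_start, LEVEL_1N, lvl2))
    _write(mother, t, plat_start, anaphase, np.full_like(t, lvl2))

    seg_start = _snap_up(s_start, rec.first_detection_min, dt)

    if event is None:
        # Normal anaphase: drop to 1N, daughter holds 1N until washout at div.
        _write(mother, t, anaphase, div, np.full_like(t, LEVEL_1N))
        _write(mother, t, div, np.inf, np.full_like(t, LEVEL_1N))  # next cycle overwrites
        seg_t = _seg_times(seg_start, div, dt)
        d = np.where(seg_t >= anaphase - 1e-9, LEVEL_1N, 0.0)
        segments.append(DaughterSegment(a, seg_start, d))
        return

    leak = rng.uniform(*preset.leak_range)
    m_arrest = leak * lvl2
    d_arrest = (1.0 - leak) * lvl2
    seg_t = _seg_times(seg_start, div, dt)
    d = np.zeros_like(seg_t)

    # Optional superseded transient: a brief earlier transfer, fully reversed
    # before the scored (final) onset.
    if event.superseded_onset_min is not None:
        s_on = event.superseded_onset_min
        s_off = min(s_on + 2 * dt, anaphase - dt)
        leak2 = rng.uniform(*preset.leak_range)
        _write(mother, t, s_on, s_off, np.full_like(t, leak2 * lvl2))
        d += np.where((seg_t >= s_on - 1e-9) & (seg_t < s_off - 1e-9), (1 - leak2) * lvl2, 0.0)

    if event.outcome == "corrected":
        res = event.resolution_min
        trans_end = res + CORRECTION_TRANSITION_MIN
        _write(mother, t, anaphase, res, np.full_like(t, m_arrest))
        _write(mother, t, res, trans_end, _ramp(t, res, trans_end, m_arrest, LEVEL_1N))
        _write(mother, t, trans_end, div, np.full_like(t, LEVEL_1N))
        d += np.where((seg_t >= anaphase - 1e-9) & (seg_t < res - 1e-9), d_arrest, 0.0)
        in_trans = (seg_t >= res - 1e-9) & (seg_t < trans_end - 1e-9)
        d += np.where(in_trans, _ramp(seg_t, res, trans_end, d_arrest, LEVEL_1N), 0.0)
        d += np.where(seg_t >= trans_end - 1e-9, LEVEL_1N, 0.0)
    else:  # terminal_cytokinesis: arrest until the daughter separates at div
        _write(mother, t, anaphase, div, np.full_like(t, m_arrest))
        _write(mother, t, div, np.inf, np.full_like(t, m_arrest))
        d += np.where(seg_t >= anaphase - 1e-9, d_arrest, 0.0)

    segments.append(DaughterSegment(a, seg_start, d))


def _render_terminal_death_cycle(mother, segments, t, dt, start, event, preset, rng, rec) -> None:
    """Final, uncompleted cycle of a mother that died during a GLM arrest."""
    s_start, plat_start, anaphase = _cycle_phases(start, rec.fate_time_min, event)
    lvl2 = 2.0 * LEVEL_1N
    _write(mother, t, start, s_start, np.full_like(t, LEVEL_1N))
    _write(mother, t, s_start, plat_start, _ramp(t, s_start, plat_start, LEVEL_1N, lvl2))
    _write(mother, t, plat_start, anaphase, np.full_like(t, lvl2))

    leak = rng.uniform(*preset.leak_range)
    _write(mother, t, anaphase, np.inf, np.full_like(t, leak * lvl2))
    seg_start = _snap_up(s_start, rec.first_detection_min, dt)
    seg_t = _seg_times(seg_start, rec.fate_time_min + dt, dt)
    d = np.where(seg_t >= anaphase - 1e-9, (1.0 - leak) * lvl2, 0.0)
    segments.append(DaughterSegment(event.cycle_index, seg_start, d))


def _snap_up(t_min: float, origin: float, dt: float) -> float:
    """Snap a time onto the sampling grid, rounding up."""
    return origin + dt * int(np.ceil((t_min - origin) / dt - 1e-9))


def _seg_times(seg_start: float, end_exclusive: float, dt: float) -> np.ndarray:
    n = max(1, int(np.floor((end_exclusive - 1e-9 - seg_start) / dt)) + 1)
    return seg_start + dt * np.arange(n)
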