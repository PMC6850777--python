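"""Cohort simulation with ground-truth missegregation events.

Each mother cell receives a baseline death age L from the preset's Gompertz
lifespan law. Every division carries a GLM probability that is flat while
young and ramps over the last five divisions before L (the hazard conditions
on L, a frailty-style parameterization that reproduces the death-aligned
rise of event rates without modelling mechanism). A GLM arrests the cell in
metaphase with the bulk of its chromatin in the daughter bud; three clocks
then compete:

* correction after ``T_r`` ~ log-normal(duration law) — the cell resumes and
  completes the division;
* daughter cytokinesis after ``T_c`` ~ Exp(lambda_cytokinesis) — a terminal
  event: the daughter separates carrying the genome and the mother's
  lifespan ends at this division;
* mother death after ``T_d`` ~ Exp(terminal_death_hazard) — terminal, the
  division never completes.

Cells are censored by per-division trap loss and by the 72 h end of the run.
Events whose cycle was not observed to completion are unobservable and are
not part of the ground truth, mirroring manual scoring of a truncated movie.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np

from ..presets import StrainPreset
from ..types import CellRecord, GLMEvent

__all__ = ["simulate_cohort", "RUN_END_MIN", "CORRECTION_LAG_MIN"]

#: Observation window (72 h run), minutes.
RUN_END_MIN = 72 * 60.0
#: Time between the start of chromatin return and daughter separation; the
#: retrograde transfer itself takes 10-15 min, so cytokinesis follows it.
CORRECTION_LAG_MIN = 15.0
#: Lead of a superseded transient event before the scored (final) onset.
SUPERSEDED_LEAD_MIN = 25.0


def simulate_cohort(
    preset: StrainPreset,
    n_cells: int,
    seed: int,
    fixed_lifespan: Optional[int] = None,
    run_end_min: float = RUN_END_MIN,
) -> tuple[list[CellRecord], list[GLMEvent]]:
    """Simulate ``n_cells`` mother cells under one strain preset.

    Returns the cell records and the scored ground-truth events (one per
    cell and cycle at most; superseded transient events are recorded on the
    final event via ``superseded_onset_min``).  Identical
    ``(preset, n_cells, seed)`` triples reproduce identical output.

    ``fixed_lifespan`` pins every cell's baseline death age, bypassing the
    Gompertz draw (used for closed-form checks of the hazard machinery).
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    preset.validate()
    rng = np.random.default_rng(seed)

    if fixed_lifespan is not None:
        lifespans = np.full(n_cells, int(fixed_lifespan))
    else:
        lifespans = preset.draw_lifespans(n_cells, rng)
    first_detect = rng.uniform(0.0, 120.0, size=n_cells)

    lam_c = preset.lambda_cytokinesis_per_h / 60.0
    lam_d = preset.terminal_death_hazard_per_h / 60.0
    mu_dur = math.log(preset.duration_median_min)

    records: list[CellRecord] = []
    events: list[GLMEvent] = []

    for i in range(n_cells):
        L = int(lifespans[i])
        cell_id = f"{preset.name}_{i:05d}"
        t = float(first_detect[i])
        div_times: list[float] = []
        fate: Optional[str] = None
        fate_time = t

        u_event = rng.random(L)
        u_censor = rng.random(L)

        for a in range(1, L + 1):
            dur = preset.cycle_duration_min(a, L)
            anaphase = t + dur
            has_event = u_event[a - 1] < preset.hazard(a, L)

            ev: Optional[GLMEvent] = None
            div: Optional[float] = None
            if has_event:
                t_r = float(np.exp(mu_dur + preset.duration_sigma_log * rng.standard_normal()))
                t_c = rng.exponential(1.0 / lam_c) if lam_c > 0 else math.inf
                t_d = rng.exponential(1.0 / lam_d) if lam_d > 0 else math.inf
                superseded = None
                if rng.random() < preset.multi_event_prob and dur >= 2.0 * SUPERSEDED_LEAD_MIN:
                    superseded = anaphase - SUPERSEDED_LEAD_MIN
                if t_r < min(t_c, t_d):
                    resolution = anaphase + t_r
                    div = resolution + CORRECTION_LAG_MIN
                    ev = GLMEvent(cell_id, a, anaphase, resolution, "corrected",
                                  superseded_onset_min=superseded)
                elif t_c <= t_d:
                    div = anaphase + t_c
                    ev = GLMEvent(cell_id, a, anaphase, None, "terminal_cytokinesis",
                                  superseded_onset_min=superseded)
                else:
                    death = anaphase + t_d
                    if death > run_end_min:
                        fate, fate_time = "censored_end", run_end_min
                        break
                    events.append(GLMEvent(cell_id, a, anaphase, None, "terminal_death",
                                           superseded_onset_min=superseded))
                    fate, fate_time = "died", death
                    break
            else:
                div = anaphase

            if div > run_end_min:
                # Cycle not observed to completion: any event in it is
                # unobservable and the cell leaves as end-of-run censored.
                fate, fate_time = "censored_end", run_end_min
                break

            div_times.append(div)
            if ev is not None:
                events.append(ev)
                if ev.outcome == "terminal_cytokinesis":
                    fate = "died" if rng.random() >= preset.senescence_prob else "senesced"
                    fate_time = div
                    break
            if u_censor[a - 1] < preset.censor_hazard:
                fate = "censored_lost"
                fate_time = min(div + 0.5 * dur, run_end_min)
                break
            t = div

        if fate is None:
            # Baseline (non-GLM) death after the final division.
            last = div_times[-1] if div_times else float(first_detect[i])
            obs = last + 1.5 * preset.cycle_base_min
            if obs > run_end_min:
                fate, fate_time = "censored_end", run_end_min
            else:
                fate = "died" if rng.random() >= preset.senescence_prob else "senesced"
                fate_time = obs
        fate_time = max(fate_time, div_times[-1] if div_times else first_detect[i])

        rec = CellRecord(
            cell_id=cell_id,
            strain=preset.name,
            first_detection_min=float(first_detect[i]),
            division_times_min=div_times,
            fate=fate,
            fate_time_min=float(fate_time),
        )
        rec.validate()
        records.append(rec)

    for ev in events:
        ev.validate()
    return records, events
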