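"""Shared fixtures: simulated cohorts reused across the suite."""

from __future__ import annotations

import time
from dataclasses import dataclass

import pytest
from hypothesis import HealthCheck, settings

from glmaging.caller import call_cohort
from glmaging.presets import get_preset
from glmaging.synthetic.cohort import simulate_cohort
from glmaging.synthetic.traces import synthesize_traces

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@dataclass
class CohortRun:
    preset: object
    records: list
    truth: list
    traces: list
    called: list
    elapsed_s: float


def _run(preset, n_cells, seed_cohort, seed_traces):
    t0 = time.perf_counter()
    records, truth = simulate_cohort(preset, n_cells, seed=seed_cohort)
    traces = synthesize_traces(records, truth, preset, seed=seed_traces)
    called = call_cohort(traces, records)
    return CohortRun(preset, records, truth, traces, called, time.perf_counter() - t0)


@pytest.fixture(scope="session")
def wt_run() -> CohortRun:
    """Wild-type cohort at study scale (n=410), default noise, fixed seeds."""
    return _run(get_preset("wild_type"), 410, seed_cohort=11, seed_traces=12)


@pytest.fixture(scope="session")
def wt_run_noiseless() -> CohortRun:
    """Noise- and bleach-free wild-type cohort for exactness checks."""
    preset = get_preset("wild_type").with_(trace_noise_cv=0.0, bleach_per_frame=0.0)
    return _run(preset, 200, seed_cohort=21, seed_traces=22)


def match_events(truth, called):
    """Pair truth/called events on (cell, cycle); returns (pairs, fp, fn)."""
    t = {(e.cell_id, e.cycle_index): e for e in truth}
    c = {(e.cell_id, e.cycle_index): e for e in called}
    pairs = [(t[k], c[k]) for k in t.keys() & c.keys()]
    fp = [c[k] for k in c.keys() - t.keys()]
    fn = [t[k] for k in t.keys() - c.keys()]
    return pairs, fp, fn


def f1_score(truth, called) -> float:
    pairs, fp, fn = match_events(truth, called)
    tp = len(pairs)
    if tp == 0:
        return 0.0
    precision = tp / (tp + len(fp))
    recall = tp / (tp + len(fn))
    return 2 * precision * recall / (precision + recall)
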