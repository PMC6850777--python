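"""Readers and writers for the pipeline's file formats.

All tabular artifacts are CSV so diffs stay reviewable; images are
multi-page TIFF; presets and run configurations are YAML. Every writer is
deterministic: identical inputs produce byte-identical files. Readers
validate schemas and report offending columns and row numbers.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import tifffile
import yaml

from .presets import StrainPreset
from .types import FATES, OUTCOMES, CellRecord, DaughterSegment, GLMEvent, TracePair

__all__ = [
    "write_cohort", "read_cohort",
    "write_events", "read_events",
    "write_traces", "read_traces",
    "write_stack", "read_stack",
    "write_presets", "read_presets",
]

PathLike = Union[str, Path]

COHORT_COLUMNS = [
    "cell_id", "strain", "first_detection_min", "rls",
    "division_times_min", "fate", "fate_time_min",
]
EVENT_COLUMNS = [
    "cell_id", "cycle_index", "onset_min", "resolution_min",
    "outcome", "duration_min", "superseded_onset_min",
]
TRACE_COLUMNS = ["cell_id", "time_min", "compartment", "cycle_index", "signal_au"]


def _write_csv(df: pd.DataFrame, path: PathLike, header_comment: Optional[str]) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index=False, float_format="%.6f")


def _read_csv(path: PathLike, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df


# -- cohort tables ---------------------------------------------------------

def write_cohort(
    records: Sequence[CellRecord], path: PathLike, comment: Optional[str] = None
) -> None:
    rows = [
        {
            "cell_id": r.cell_id,
            "strain": r.strain,
            "first_detection_min": r.first_detection_min,
            "rls": r.rls,
            "division_times_min": ";".join(f"{t:.6f}" for t in r.division_times_min),
            "fate": r.fate,
            "fate_time_min": r.fate_time_min,
        }
        for r in records
    ]
    _write_csv(pd.DataFrame(rows, columns=COHORT_COLUMNS), path, comment)


def read_cohort(path: PathLike) -> list[CellRecord]:
    df = _read_csv(path, COHORT_COLUMNS)
    records = []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        if row["fate"] not in FATES:
            raise ValueError(f"{path}: row {line}: unknown fate {row['fate']!r}")
        raw = row["division_times_min"]
        div = [float(x) for x in str(raw).split(";") if x] if not _isna(raw) else []
        if len(div) != int(row["rls"]):
            raise ValueError(
                f"{path}: row {line}: rls={row['rls']} disagrees with "
                f"{len(div)} division times"
            )
        rec = CellRecord(
            cell_id=str(row["cell_id"]),
            strain=str(row["strain"]),
            first_detection_min=float(row["first_detection_min"]),
            division_times_min=div,
            fate=str(row["fate"]),
            fate_time_min=float(row["fate_time_min"]),
        )
        try:
            rec.validate()
        except ValueError as err:
            raise ValueError(f"{path}: row {line}: {err}") from None
        records.append(rec)
    return records


def _isna(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x)) or x == ""


# -- event tables ----------------------------------------------------------

def write_events(
    events: Sequence[GLMEvent], path: PathLike, comment: Optional[str] = None
) -> None:
    rows = [
        {
            "cell_id": e.cell_id,
            "cycle_index": e.cycle_index,
            "onset_min": e.onset_min,
            "resolution_min": e.resolution_min,
            "outcome": e.outcome,
            "duration_min": e.duration_min,
            "superseded_onset_min": e.superseded_onset_min,
        }
        for e in events
    ]
    _write_csv(pd.DataFrame(rows, columns=EVENT_COLUMNS), path, comment)


def read_events(path: PathLike) -> list[GLMEvent]:
    df = _read_csv(path, EVENT_COLUMNS[:5])
    events = []
    for i, row in df.iterrows():
        line = i + 2
        if row["outcome"] not in OUTCOMES:
            raise ValueError(f"{path}: row {line}: unknown outcome {row['outcome']!r}")
        res = None if _isna(row["resolution_min"]) else float(row["resolution_min"])
        sup = row.get("superseded_onset_min")
        ev = GLMEvent(
            cell_id=str(row["cell_id"]),
            cycle_index=int(row["cycle_index"]),
            onset_min=float(row["onset_min"]),
            resolution_min=res,
            outcome=str(row["outcome"]),
            superseded_onset_min=None if _isna(sup) else float(sup),
        )
        try:
            ev.validate()
        except ValueError as err:
            raise ValueError(f"{path}: row {line}: {err}") from None
        events.append(ev)
    return events


# -- long-format traces ----------------------------------------------------

def write_traces(
    traces: Sequence[TracePair], path: PathLike, comment: Optional[str] = None
) -> None:
    """Long format: one row per (cell, time, compartment) sample.

    Mother rows carry cycle_index -1 (the cycle is a property of the
    segmentation, not of the raw sample); daughter rows carry their
    segment's cycle index.
    """
    frames = []
    for tr in traces:
        t = tr.times()
        frames.append(
            pd.DataFrame(
                {
                    "cell_id": tr.cell_id,
                    "time_min": t,
                    "compartment": "mother",
                    "cycle_index": -1,
                    "signal_au": np.asarray(tr.mother_signal, dtype=float),
                }
            )
        )
        for seg in tr.daughter_segments:
            frames.append(
                pd.DataFrame(
                    {
                        "cell_id": tr.cell_id,
                        "time_min": seg.times(tr.sampling_interval_min),
                        "compartment": "daughter",
                        "cycle_index": seg.cycle_index,
                        "signal_au": np.asarray(seg.signal, dtype=float),
                    }
                )
            )
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=TRACE_COLUMNS)
    _write_csv(df[TRACE_COLUMNS], path, comment)


def read_traces(
    path: PathLike, records: Optional[Sequence[CellRecord]] = None
) -> list[TracePair]:
    """Rebuild TracePairs from a long-format CSV.

    Mother samples must be uniformly spaced; otherwise the offending cell
    is reported. When cohort ``records`` are supplied, death flags are
    restored from cells with fate ``died``.
    """
    df = _read_csv(path, TRACE_COLUMNS)
    death = {
        r.cell_id: r.fate_time_min for r in (records or []) if r.fate == "died"
    }
    traces = []
    for cell_id, group in df.groupby("cell_id", sort=False):
        mom = group[group["compartment"] == "mother"].sort_values("time_min")
        if len(mom) < 2:
            raise ValueError(f"{path}: cell {cell_id}: mother trace has <2 samples")
        t = mom["time_min"].to_numpy(dtype=float)
        steps = np.diff(t)
        dt = steps[0]
        if not np.allclose(steps, dt, atol=1e-6):
            bad = int(np.argmax(np.abs(steps - dt) > 1e-6))
            raise ValueError(
                f"{path}: cell {cell_id}: non-uniform sampling at time "
                f"{t[bad + 1]:.4f} (expected step {dt:.4f})"
            )
        segments = []
        dau = group[group["compartment"] == "daughter"]
        for cyc, seg in dau.groupby("cycle_index", sort=True):
            seg = seg.sort_values("time_min")
            segments.append(
                DaughterSegment(
                    cycle_index=int(cyc),
                    start_min=float(seg["time_min"].iloc[0]),
                    signal=seg["signal_au"].to_numpy(dtype=float),
                )
            )
        tp = TracePair(
            cell_id=str(cell_id),
            start_min=float(t[0]),
            mother_signal=mom["signal_au"].to_numpy(dtype=float),
            daughter_segments=segments,
            sampling_interval_min=float(dt),
            mother_death_flag_min=death.get(str(cell_id)),
        )
        tp.validate()
        traces.append(tp)
    return traces


# -- images and presets ----------------------------------------------------

def write_stack(stack: np.ndarray, path: PathLike) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(stack, dtype=np.float32), photometric="minisblack")


def read_stack(path: PathLike) -> np.ndarray:
    return tifffile.imread(path).astype(float)


def write_presets(presets: dict[str, StrainPreset], path: PathLike) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {name: p.to_dict() for name, p in sorted(presets.items())}
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def read_presets(path: PathLike) -> dict[str, StrainPreset]:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return {name: StrainPreset.from_dict(d) for name, d in payload.items()}
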