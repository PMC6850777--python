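"""Cohort-level aging statistics for GLM events.

Implements the statistical conventions of single-cell replicative-aging
studies in microfluidic devices:

* event-probability curves aligned from birth (risk set = every cell with
  that many completed divisions observed, censored cells included up to
  their last fully observed age) or from death (cells that died or senesced
  only, indexed by divisions before death);
* Kaplan-Meier survival on division counts with optional right-censoring,
  plus the log-rank test;
* Cochran's Q for an age-related trend in per-cell binary event indicators
  across age bins (complete-case cells only);
* cell-level bootstrap percentile intervals, in two calibrations: plain 95%
  intervals, and 83.4% intervals whose non-overlap between two comparable
  groups corresponds to p ≈ 0.05;
* the Spearman correlation between having an event at an age and the
  remaining lifespan of cells alive at that age;
* history dependence (event probability given prior events vs none, pooled
  over age-matched divisions);
* the counterfactual lifespan gain: how much longer cells live than if
  every first GLM had been terminal;
* a pooled-variance t-test for arrest duration vs mother age, and
  event-aligned trace averaging normalized to the 1N level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.utils import restricted_mean_survival_time
from scipy import stats as sps
from statsmodels.stats.contingency_tables import cochrans_q as _sm_cochrans_q

from .types import CellRecord, GLMEvent, TracePair, events_by_cell

__all__ = [
    "AgeAlignedCurve",
    "SurvivalCurve",
    "BootstrapConfig",
    "filter_first_hours",
    "glm_probability_by_age",
    "cochran_q_trend",
    "km_survival",
    "logrank",
    "mean_rls",
    "bootstrap_ci",
    "spearman_event_vs_remaining",
    "history_dependence",
    "counterfactual_lifespan_gain",
    "duration_vs_age_test",
    "align_to_event",
    "terminal_fraction_stats",
]


@dataclass
class AgeAlignedCurve:
    alignment: str  # "birth" or "death"
    ages: np.ndarray
    p: np.ndarray
    sem: np.ndarray
    n_at_risk: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"age": self.ages, "p": self.p, "sem": self.sem, "n_at_risk": self.n_at_risk}
        )


@dataclass
class SurvivalCurve:
    times: np.ndarray
    survival: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray
    n_censored: np.ndarray
    durations: np.ndarray = field(repr=False, default=None)
    observed: np.ndarray = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "divisions": self.times,
                "survival": self.survival,
                "n_at_risk": self.n_at_risk,
                "n_events": self.n_events,
                "n_censored": self.n_censored,
            }
        )


@dataclass
class BootstrapConfig:
    n_boot: int = 2000
    level_mode: str = "nonoverlap_p05"
    seed: int = 0

    def validate(self) -> None:
        if self.n_boot < 100:
            raise ValueError("n_boot must be >= 100")
        if self.level_mode not in ("nonoverlap_p05", "percentile95"):
            raise ValueError(f"unknown level_mode {self.level_mode!r}")

    @property
    def level(self) -> float:
        # 83.4% intervals: non-overlap of two equal-variance intervals
        # corresponds to |z| > 2 * 1.386 = 2.77 ≈ the 0.05 two-sided cutoff.
        return 0.834 if self.level_mode == "nonoverlap_p05" else 0.95


def filter_first_hours(
    records: Sequence[CellRecord], cutoff_min: float = 180.0
) -> list[CellRecord]:
    """Keep cells first detected within the start-up window (default 3 h).

    Restricting to cells identified early ensures the cohort consists of
    young, healthy mothers rather than cells that drifted into traps later.
    """
    return [r for r in records if r.first_detection_min <= cutoff_min]


def _first_event_age(events: Sequence[GLMEvent]) -> Optional[int]:
    return min((e.cycle_index for e in events), default=None)


def glm_probability_by_age(
    records: Sequence[CellRecord],
    events: Sequence[GLMEvent],
    alignment: str = "birth",
) -> AgeAlignedCurve:
    """Per-age GLM probability with the field's censoring convention.

    Birth alignment: at age ``a`` the risk set is every cell with at least
    ``a`` completed divisions observed — a cell lost at age 20 contributes
    up to age 19, exactly as a censored cell is "included in the plots until
    age 19". Death alignment restricts to cells that died or senesced and
    counts divisions back from death (1 = the final completed division).
    """
    if alignment not in ("birth", "death"):
        raise ValueError(f"alignment must be 'birth' or 'death', got {alignment!r}")
    by_cell = events_by_cell(events)
    if alignment == "birth":
        cells = list(records)
        max_age = max((r.rls for r in cells), default=0)
        ages, p, sem, n_risk = [], [], [], []
        for a in range(1, max_age + 1):
            at_risk = [r for r in cells if r.rls >= a]
            if not at_risk:
                break
            n = len(at_risk)
            k = sum(
                1
                for r in at_risk
                if any(e.cycle_index == a for e in by_cell.get(r.cell_id, []))
            )
            ages.append(a); n_risk.append(n); p.append(k / n)
    else:
        cells = [r for r in records if r.fate in ("died", "senesced")]
        max_back = max((r.rls for r in cells), default=0)
        ages, p, sem, n_risk = [], [], [], []
        for d in range(1, max_back + 1):
            at_risk = [r for r in cells if r.rls >= d]
            if not at_risk:
                break
            n = len(at_risk)
            k = sum(
                1
                for r in at_risk
                if any(e.cycle_index == r.rls - d + 1 for e in by_cell.get(r.cell_id, []))
            )
            ages.append(d); n_risk.append(n); p.append(k / n)
    p = np.asarray(p, dtype=float)
    n_risk = np.asarray(n_risk, dtype=int)
    sem = np.sqrt(p * (1.0 - p) / n_risk)
    return AgeAlignedCurve(alignment, np.asarray(ages), p, sem, n_risk)


def cochran_q_trend(
    records: Sequence[CellRecord],
    events: Sequence[GLMEvent],
    age_bins: Sequence[tuple[int, int]] = ((1, 5), (6, 10), (11, 15), (16, 20)),
) -> tuple[float, float]:
    """Cochran's Q for an age-related change in per-cell GLM occurrence.

    Each complete-case cell (observed through the last bin) contributes one
    binary outcome per age bin: whether it had any GLM in that bin. Returns
    (Q, p) with p from chi-square on k-1 degrees of freedom.
    """
    bins = [tuple(b) for b in age_bins]
    if len(bins) < 2:
        raise ValueError("need at least 2 age bins")
    last_age = max(hi for _, hi in bins)
    by_cell = events_by_cell(events)
    rows = []
    for r in records:
        if r.rls < last_age:
            continue
        ages = {e.cycle_index for e in by_cell.get(r.cell_id, [])}
        rows.append([int(any(lo <= a <= hi for a in ages)) for lo, hi in bins])
    if len(rows) < 2:
        raise ValueError(
            f"only {len(rows)} complete-case cells observed through age {last_age}; "
            "need at least 2"
        )
    x = np.asarray(rows)
    row_sums = x.sum(axis=1)
    k = x.shape[1]
    if k * np.sum(row_sums) - np.sum(row_sums**2) == 0:
        # Every subject is constant across bins: no discordance, no trend.
        return 0.0, 1.0
    res = _sm_cochrans_q(x, return_object=True)
    return float(res.statistic), float(res.pvalue)


def _km_inputs(
    records: Sequence[CellRecord], include_censored: bool
) -> tuple[np.ndarray, np.ndarray]:
    if include_censored:
        durations = np.array([r.rls for r in records], dtype=float)
        observed = np.array([not r.censored for r in records], dtype=bool)
    else:
        kept = [r for r in records if not r.censored]
        durations = np.array([r.rls for r in kept], dtype=float)
        observed = np.ones(len(kept), dtype=bool)
    return durations, observed


def km_survival(
    records: Sequence[CellRecord], include_censored: bool = True
) -> SurvivalCurve:
    """Kaplan-Meier survival on division counts.

    With ``include_censored`` lost cells enter as right-censored at their
    last completed division; otherwise they are dropped (microdissection
    convention). With no censoring present the estimate equals the
    empirical survival function.
    """
    durations, observed = _km_inputs(records, include_censored)
    if durations.size == 0:
        raise ValueError("no cells to build a survival curve from")
    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=observed)
    table = kmf.event_table
    times = table.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy()
    return SurvivalCurve(
        times=times,
        survival=surv,
        n_at_risk=table["at_risk"].to_numpy(),
        n_events=table["observed"].to_numpy(),
        n_censored=table["censored"].to_numpy(),
        durations=durations,
        observed=observed,
    )


def logrank(curve_a: SurvivalCurve, curve_b: SurvivalCurve) -> tuple[float, float]:
    """Log-rank test between two survival curves; (chi-square, p)."""
    if curve_a.observed.sum() == 0 or curve_b.observed.sum() == 0:
        raise ValueError("log-rank undefined: a group has zero observed deaths")
    res = _ll_logrank(
        curve_a.durations,
        curve_b.durations,
        event_observed_A=curve_a.observed,
        event_observed_B=curve_b.observed,
    )
    return float(res.test_statistic), float(res.p_value)


def mean_rls(
    records: Sequence[CellRecord],
    include_censored: bool = False,
    restriction: float = 100.0,
) -> float:
    """Mean replicative lifespan.

    Uncensored-cells arithmetic mean by default; with ``include_censored``
    the censor-aware Kaplan-Meier restricted mean (restriction far beyond
    any observed lifespan makes it the KM mean).
    """
    if not include_censored:
        vals = [r.rls for r in records if not r.censored]
        if not vals:
            raise ValueError("no uncensored cells")
        return float(np.mean(vals))
    durations, observed = _km_inputs(records, include_censored=True)
    kmf = KaplanMeierFitter().fit(durations, event_observed=observed)
    return float(restricted_mean_survival_time(kmf, t=restriction))


def bootstrap_ci(
    statistic: Callable[[Sequence], float],
    records: Sequence,
    config: BootstrapConfig,
) -> tuple[float, float]:
    """Cell-level bootstrap percentile interval for any cohort statistic.

    The resampling unit is the cell (carrying its events via whatever the
    statistic closes over). Errors if the statistic is undefined on more
    than 1% of resamples.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    records = list(records)
    n = len(records)
    if n == 0:
        raise ValueError("empty cell set")
    vals = np.empty(config.n_boot)
    failures = 0
    for b in range(config.n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            vals[b] = statistic([records[i] for i in idx])
        except Exception:
            failures += 1
            vals[b] = np.nan
    if failures > 0.01 * config.n_boot:
        raise ValueError(
            f"statistic undefined on {failures}/{config.n_boot} bootstrap resamples"
        )
    alpha = (1.0 - config.level) / 2.0
    lo, hi = np.nanquantile(vals, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def spearman_event_vs_remaining(
    records: Sequence[CellRecord], events: Sequence[GLMEvent], age: int
) -> float:
    """Spearman rho between having a GLM at ``age`` and remaining lifespan.

    Computed over the population of cells alive at that age (rls >= age),
    with midrank ties. Negative rho means an event predicts a shorter
    remaining lifespan.
    """
    by_cell = events_by_cell(events)
    alive = [r for r in records if r.rls >= age]
    if not alive:
        raise ValueError(f"no cells alive at age {age}")
    indicator = np.array(
        [
            int(any(e.cycle_index == age for e in by_cell.get(r.cell_id, [])))
            for r in alive
        ]
    )
    remaining = np.array([r.rls - age for r in alive], dtype=float)
    if indicator.min() == indicator.max():
        raise ValueError(
            f"event indicator constant ({indicator[0]}) at age {age}; rho undefined"
        )
    rho, _ = sps.spearmanr(indicator, remaining)
    return float(rho)


def history_dependence(
    records: Sequence[CellRecord],
    events: Sequence[GLMEvent],
    boot: Optional[BootstrapConfig] = None,
) -> dict:
    """P(event | >=1 prior event) vs P(event | no prior), age-matched.

    For every division of every cell, the mother is classified by whether
    she had any GLM at a strictly earlier age; divisions are pooled over
    ages at which both strata are populated. Confidence intervals are
    cell-level bootstrap percentiles.
    """
    by_cell = events_by_cell(events)

    def _pooled(cells: Sequence[CellRecord]) -> tuple[float, float]:
        max_age = max((r.rls for r in cells), default=0)
        num = {True: 0, False: 0}
        den = {True: 0, False: 0}
        for a in range(1, max_age + 1):
            strata: dict[bool, list[int]] = {True: [], False: []}
            for r in cells:
                if r.rls < a:
                    continue
                evs = by_cell.get(r.cell_id, [])
                prior = any(e.cycle_index < a for e in evs)
                strata[prior].append(
                    int(any(e.cycle_index == a for e in evs))
                )
            if strata[True] and strata[False]:
                for key in (True, False):
                    num[key] += sum(strata[key])
                    den[key] += len(strata[key])
        p_prior = num[True] / den[True] if den[True] else np.nan
        p_none = num[False] / den[False] if den[False] else np.nan
        return p_prior, p_none

    p_prior, p_none = _pooled(records)
    out = {"p_given_prior": p_prior, "p_given_none": p_none}
    if boot is not None:
        out["ci_given_prior"] = bootstrap_ci(lambda c: _pooled(c)[0], records, boot)
        out["ci_given_none"] = bootstrap_ci(
            lambda c: _pooled(c)[1], records,
            BootstrapConfig(boot.n_boot, boot.level_mode, boot.seed + 1),
        )
    return out


def counterfactual_lifespan_gain(
    records: Sequence[CellRecord], events: Sequence[GLMEvent]
) -> float:
    """Percent lifespan gained by correcting GLMs rather than dying of them.

    Each uncensored cell's counterfactual lifespan is its observed RLS
    truncated at the age of its first GLM (as if that event had been
    terminal); the gain is ``100 * (mean observed / mean counterfactual - 1)``.
    """
    by_cell = events_by_cell(events)
    obs, cf = [], []
    for r in records:
        if r.censored:
            continue
        first = _first_event_age(by_cell.get(r.cell_id, []))
        obs.append(r.rls)
        cf.append(r.rls if first is None else min(r.rls, first))
    if not obs:
        raise ValueError("no uncensored cells")
    return float(100.0 * (np.mean(obs) / np.mean(cf) - 1.0))


def duration_vs_age_test(durations: pd.DataFrame) -> tuple[float, float]:
    """Equal-variance two-tailed t-test of arrest duration vs mother age.

    Events are split at the cohort's median event age into young-mother and
    old-mother groups; a non-significant p is consistent with arrest
    duration being independent of replicative age.
    """
    if not {"duration_min", "cycle_index"} <= set(durations.columns):
        raise ValueError("need columns duration_min and cycle_index")
    med = durations["cycle_index"].median()
    young = durations.loc[durations["cycle_index"] < med, "duration_min"].to_numpy()
    old = durations.loc[durations["cycle_index"] >= med, "duration_min"].to_numpy()
    if len(young) < 2 or len(old) < 2:
        raise ValueError("need at least 2 durations per age group")
    if np.ptp(young) == 0 and np.ptp(old) == 0:
        raise ValueError("degenerate (zero-variance) duration groups")
    t, p = sps.ttest_ind(young, old, equal_var=True)
    return float(t), float(p)


def align_to_event(
    traces: Sequence[TracePair],
    events: Sequence[GLMEvent],
    min_duration_min: float = 30.0,
    window_min: tuple[float, float] = (-120.0, 60.0),
) -> pd.DataFrame:
    """Average mother traces aligned to their correction times.

    Each trace is normalized at the single-cell level so its post-anaphase
    1N plateau is 1, shifted so the correction happens at t = 0, and
    averaged pointwise over corrected events lasting longer than
    ``min_duration_min``. Returns columns t_min / mean / sem / n.
    """
    by_id = {t.cell_id: t for t in traces}
    qualifying = [
        e
        for e in events
        if e.outcome == "corrected"
        and e.duration_min is not None
        and e.duration_min > min_duration_min
        and e.cell_id in by_id
    ]
    if not qualifying:
        raise ValueError(
            f"no corrected events longer than {min_duration_min} min to align"
        )
    dt = by_id[qualifying[0].cell_id].sampling_interval_min
    offsets = np.arange(
        int(np.floor(window_min[0] / dt)), int(np.ceil(window_min[1] / dt)) + 1
    )
    rows = np.full((len(qualifying), offsets.size), np.nan)
    for i, ev in enumerate(qualifying):
        tr = by_id[ev.cell_id]
        m = np.asarray(tr.mother_signal, dtype=float)
        one_n = _one_n_level(m)
        f0 = tr.frame_of(ev.resolution_min)
        for j, off in enumerate(offsets):
            f = f0 + off
            if 0 <= f < tr.n_frames:
                rows[i, j] = m[f] / one_n
    n = np.sum(~np.isnan(rows), axis=0)
    mean = np.nanmean(rows, axis=0)
    sem = np.nanstd(rows, axis=0, ddof=1) / np.sqrt(np.maximum(n, 1))
    return pd.DataFrame(
        {"t_min": offsets * dt, "mean": mean, "sem": sem, "n": n}
    )


def _one_n_level(m: np.ndarray) -> float:
    """Post-anaphase 1N plateau level of a mother trace (robust median)."""
    hi = np.quantile(m, 0.97)
    low = m[(m > 0.35 * hi) & (m < 0.65 * hi)]
    return float(np.median(low)) if low.size else float(np.median(m) / 1.5)


def terminal_fraction_stats(
    records: Sequence[CellRecord],
    events: Sequence[GLMEvent],
    boot: Optional[BootstrapConfig] = None,
) -> dict:
    """Terminal-GLM death fraction and uncorrected-event fraction.

    The death fraction (deaths attributable to a terminal GLM) uses
    uncensored cells only; the uncorrected fraction uses all scored events.
    Both come with cell-level bootstrap intervals when ``boot`` is given.
    """
    by_cell = events_by_cell(events)

    def _death_frac(cells: Sequence[CellRecord]) -> float:
        dead = [r for r in cells if not r.censored]
        if not dead:
            raise ValueError("no uncensored cells for the death fraction")
        n_term = sum(
            1
            for r in dead
            if any(e.outcome != "corrected" for e in by_cell.get(r.cell_id, []))
        )
        return n_term / len(dead)

    def _uncorr_frac(cells: Sequence[CellRecord]) -> float:
        evs = [e for r in cells for e in by_cell.get(r.cell_id, [])]
        if not evs:
            raise ValueError("no events for the uncorrected fraction")
        return sum(1 for e in evs if e.outcome != "corrected") / len(evs)

    out = {
        "death_fraction": _death_frac(records),
        "uncorrected_fraction": _uncorr_frac(records),
    }
    if boot is not None:
        out["death_fraction_ci"] = bootstrap_ci(_death_frac, records, boot)
        out["uncorrected_fraction_ci"] = bootstrap_ci(
            _uncorr_frac, records,
            BootstrapConfig(boot.n_boot, boot.level_mode, boot.seed + 1),
        )
    return out
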