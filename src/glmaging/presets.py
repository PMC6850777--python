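"""Generative strain presets.

A :class:`StrainPreset` bundles everything the cohort generator needs for one
genotype: a Gompertz replicative-lifespan law, an age-dependent GLM hazard
(low and flat while young, ramping sharply over the last five divisions
before baseline death), a log-normal arrest-duration law, competing terminal
hazards (daughter cytokinesis and mother death during the arrest), censoring,
cell-cycle timing, and the fluorescence-trace noise model.

The mutant presets are qualitative emulations: the *direction* of each
perturbation follows the genetics (e.g. fob1Δ extends lifespan and lowers GLM
rates; rad9Δ removes the age-dependent rise and nearly abolishes terminal
events; bfa1Δ leaves GLM rates intact but makes events overwhelmingly
terminal), while the magnitudes are free parameters of the generator chosen
to give clearly separated phenotypes at cohort sizes of a few hundred cells.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, replace

import numpy as np
from scipy import stats

__all__ = ["StrainPreset", "PRESETS", "get_preset", "expected_corrected_fraction"]


def _check_prob(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"preset field {name}={value} must lie in [0, 1]")


def _check_nonneg(name: str, value: float) -> None:
    if value < 0:
        raise ValueError(f"preset field {name}={value} must be nonnegative")


@dataclass(frozen=True)
class StrainPreset:
    """Generative parameters for one genotype.

    Parameters
    ----------
    lifespan_modal, lifespan_shape, lifespan_scale
        Gompertz law on continuous division count: the unit Gompertz variate
        with shape ``c`` is rescaled so its mode sits at ``lifespan_modal``
        divisions, then multiplied by ``lifespan_scale`` and rounded.
    h_young
        Per-division GLM probability for divisions more than 5 before the
        cell's baseline death age.
    late_ramp
        Per-division GLM probabilities for the last five divisions before
        baseline death (oldest entry last).
    duration_median_min, duration_sigma_log
        Log-normal arrest-duration law (median in minutes, sigma of the log).
    lambda_cytokinesis_per_h, terminal_death_hazard_per_h
        Exponential hazards, during the arrest, of daughter separation and of
        mother death; whichever of correction/cytokinesis/death fires first
        resolves the event.
    censor_hazard
        Per-division probability that the mother is washed out of its trap.
    cycle_base_min, cycle_late_slowdown
        Baseline cell-cycle duration and the fractional per-division
        lengthening applied over the last five divisions of life.
    trace_noise_cv, bleach_per_frame
        Multiplicative Gaussian noise CV and fractional photobleaching per
        frame applied to synthesized traces.
    leak_range
        Interval for the residual mother fraction of the 2N signal during a
        GLM; strictly inside (0, 0.5) because the majority of detectable
        histones enter the daughter during an event.
    multi_event_prob
        Probability that a GLM cycle also contains an earlier transient
        event that the final-event scoring rule must supersede.
    """

    name: str
    lifespan_modal: float = 27.7
    lifespan_shape: float = 0.05
    lifespan_scale: float = 1.0
    h_young: float = 0.023
    late_ramp: tuple[float, ...] = (0.0475, 0.095, 0.19, 0.285, 0.38)
    duration_median_min: float = 40.0
    duration_sigma_log: float = 0.9
    lambda_cytokinesis_per_h: float = 0.1
    terminal_death_hazard_per_h: float = 0.01
    censor_hazard: float = 0.003
    cycle_base_min: float = 90.0
    cycle_late_slowdown: float = 0.15
    trace_noise_cv: float = 0.05
    bleach_per_frame: float = 0.001
    leak_range: tuple[float, float] = (0.05, 0.25)
    multi_event_prob: float = 0.1
    senescence_prob: float = 0.3

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        _check_prob("h_young", self.h_young)
        if len(self.late_ramp) != 5:
            raise ValueError(
                f"preset field late_ramp must have exactly 5 entries, got {len(self.late_ramp)}"
            )
        for i, h in enumerate(self.late_ramp):
            _check_prob(f"late_ramp[{i}]", h)
        _check_prob("censor_hazard", self.censor_hazard)
        _check_prob("multi_event_prob", self.multi_event_prob)
        _check_prob("senescence_prob", self.senescence_prob)
        for name in (
            "lifespan_modal",
            "lifespan_scale",
            "duration_median_min",
            "lambda_cytokinesis_per_h",
            "terminal_death_hazard_per_h",
            "cycle_base_min",
            "cycle_late_slowdown",
            "trace_noise_cv",
            "bleach_per_frame",
        ):
            _check_nonneg(name, getattr(self, name))
        if not (0 < self.lifespan_shape < 1):
            raise ValueError(
                f"preset field lifespan_shape={self.lifespan_shape} must lie in (0, 1)"
            )
        lo, hi = self.leak_range
        if not (0.0 < lo <= hi < 0.5):
            raise ValueError(
                f"preset field leak_range={self.leak_range} must lie strictly inside (0, 0.5): "
                "during a GLM the mother retains a minority of the pre-mitotic signal"
            )

    # -- lifespan law ------------------------------------------------------

    def draw_lifespans(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Baseline death ages in divisions (integer, >= 3)."""
        c = self.lifespan_shape
        unit_mode = math.log(1.0 / c)
        scale = self.lifespan_modal / unit_mode
        z = stats.gompertz.rvs(c, scale=scale, size=n, random_state=rng)
        return np.maximum(3, np.rint(self.lifespan_scale * z)).astype(int)

    def hazard(self, age: int, baseline_death_age: int) -> float:
        """Per-division GLM probability at replicative age ``age`` (1-based).

        The five ``late_ramp`` entries cover the last five divisions
        {L-4, ..., L} before baseline death at age ``L``; earlier divisions
        use the flat young hazard.
        """
        offset = age - (baseline_death_age - 4)
        if offset < 0:
            return self.h_young
        return self.late_ramp[min(offset, 4)]

    def cycle_duration_min(self, age: int, baseline_death_age: int) -> float:
        """Cell-cycle duration at a given age, with late-life slowdown."""
        n_late = max(0, age - (baseline_death_age - 5))
        return self.cycle_base_min * (1.0 + self.cycle_late_slowdown * n_late)

    def with_(self, **kwargs) -> "StrainPreset":
        """Copy with selected fields replaced."""
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["late_ramp"] = list(self.late_ramp)
        d["leak_range"] = list(self.leak_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StrainPreset":
        d = dict(d)
        if "late_ramp" in d:
            d["late_ramp"] = tuple(d["late_ramp"])
        if "leak_range" in d:
            d["leak_range"] = tuple(d["leak_range"])
        return cls(**d)


def expected_corrected_fraction(preset: StrainPreset) -> float:
    """Analytic P(correction wins) = E[exp(-λ_t T_r)] by quadrature.

    The arrest resolves by correction at ``T_r`` (log-normal) unless a
    terminal transition (total exponential hazard λ_t = cytokinesis + death)
    fires first; independence gives P(corrected) = E[exp(-λ_t T_r)],
    evaluated with Gauss-Hermite quadrature over log duration.
    """
    lam = (preset.lambda_cytokinesis_per_h + preset.terminal_death_hazard_per_h) / 60.0
    mu = math.log(preset.duration_median_min)
    sig = preset.duration_sigma_log
    nodes, weights = np.polynomial.hermite_e.hermegauss(80)
    t = np.exp(mu + sig * nodes)
    return float(np.sum(weights * np.exp(-lam * t)) / math.sqrt(2 * math.pi))


def _wt() -> StrainPreset:
    return StrainPreset(name="wild_type")


#: Registry of genotype presets. Magnitudes for the mutants are invented
#: (qualitative emulations); only the wild-type constants are calibrated.
PRESETS: dict[str, StrainPreset] = {}


def _register(p: StrainPreset) -> StrainPreset:
    PRESETS[p.name] = p
    return p


_register(_wt())

_WT_RAMP = _wt().late_ramp
_WT_HY = _wt().h_young

# rDNA-stabilized: longer lifespan, lower GLM rates, otherwise wild-type-like.
_register(
    _wt().with_(
        name="fob1",
        lifespan_scale=1.3,
        h_young=_WT_HY * 0.7,
        late_ramp=tuple(h * 0.7 for h in _WT_RAMP),
    )
)
# Checkpoint-blind: flat low hazard, essentially no terminal events, shorter life.
_register(
    _wt().with_(
        name="rad9",
        lifespan_scale=0.8,
        h_young=0.01,
        late_ramp=(0.01,) * 5,
        lambda_cytokinesis_per_h=0.001,
        terminal_death_hazard_per_h=0.0001,
    )
)
# Recombination-deficient: constant high hazard, longer arrests, short life.
_register(
    _wt().with_(
        name="rad52",
        lifespan_scale=0.6,
        h_young=0.15,
        late_ramp=(0.15,) * 5,
        duration_median_min=40.0 * 1.8,
    )
)
# Reduced damage-induced histone degradation: halved hazards, longer life.
_register(_wt().with_(name="tom1", lifespan_scale=1.2, h_young=_WT_HY * 0.5,
                      late_ramp=tuple(h * 0.5 for h in _WT_RAMP)))
_register(_wt().with_(name="ies4", lifespan_scale=1.15, h_young=_WT_HY * 0.5,
                      late_ramp=tuple(h * 0.5 for h in _WT_RAMP)))
_register(_wt().with_(name="hpc2", lifespan_scale=1.15, h_young=_WT_HY * 0.5,
                      late_ramp=tuple(h * 0.5 for h in _WT_RAMP)))
# Reduced histone transcription: elevated hazards and faster cytokinesis.
_register(
    _wt().with_(
        name="spt21",
        h_young=_WT_HY * 1.5,
        late_ramp=tuple(min(1.0, h * 1.5) for h in _WT_RAMP),
        lambda_cytokinesis_per_h=0.2,
    )
)
# Spindle-positioning-checkpoint null: wild-type hazards, terminal-dominated.
_register(_wt().with_(name="bfa1", lambda_cytokinesis_per_h=1.0, lifespan_scale=0.9))
# Spindle-assembly-checkpoint null behaves like wild type for GLM statistics.
_register(_wt().with_(name="mad3"))
# Flat-hazard null with wild-type lifespan: every division shares h_young and
# events are always corrected — the exchangeable null for trend-test
# calibration.
_register(
    _wt().with_(
        name="flat_null",
        h_young=0.05,
        late_ramp=(0.05,) * 5,
        lambda_cytokinesis_per_h=0.0,
        terminal_death_hazard_per_h=0.0,
        censor_hazard=0.0,
        multi_event_prob=0.0,
    )
)


def get_preset(name: str) -> StrainPreset:
    """Look up a registered preset; error names the available ones."""
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available presets: {', '.join(sorted(PRESETS))}"
        ) from None
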