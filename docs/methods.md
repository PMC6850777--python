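# Methods

This note documents the generative models, the event-calling rules, the
statistical conventions, and the numerical choices behind `glmaging`.

## Cohort generator

Each simulated mother cell receives a **baseline death age** `L` (in
divisions) from a Gompertz law on continuous division count, discretized by
rounding with a floor of 3. The unit Gompertz variate with shape `c` is
rescaled so its mode sits at `lifespan_modal` divisions and multiplied by
`lifespan_scale`. Wild type uses shape 0.05 and modal 27.7, giving mean RLS
≈ 23–24 with SD ≈ 9.5 — the dispersion typical of BY-background replicative
lifespans. Only the resulting mean/spread matter downstream; the Gompertz
form is the standard choice for RLS and is not itself a claim under test.

The **GLM hazard** conditions on `L` (a frailty-style parameterization):
divisions more than five before `L` carry the flat young hazard
`h_young = 0.023`; the last five divisions {L−4, …, L} carry the ramp
(0.0475, 0.095, 0.19, 0.285, 0.38). These constants were calibrated once so
that the ground-truth cohort jointly satisfies the three headline gates —
penetrance ≈ 75%, corrected fraction ≈ 90%, counterfactual gain ≈ 30% —
while keeping the hazard rise near death dramatic (≈ 16-fold from young to
final division). Conditioning on `L` reproduces the death-aligned rise of
event probability without modelling mechanism, and induces both the
history dependence and the negative event-vs-remaining-lifespan
correlation observed in aging cohorts, since events mark cells close to
their (latent) death age.

A GLM arrests the cell in metaphase with the bulk of its chromatin in the
daughter. Three independent clocks compete:

| clock | law | wild-type default |
|---|---|---|
| correction `T_r` | LogNormal(median, σ_log) | 40 min, σ = 0.9 |
| daughter cytokinesis `T_c` | Exponential | 0.1 h⁻¹ |
| mother death `T_d` | Exponential | 0.01 h⁻¹ |

The corrected fraction therefore equals `E[exp(−λ_t T_r)]` with
`λ_t = 0.11 h⁻¹`, evaluated by 80-node Gauss–Hermite quadrature over log
duration: 0.902 for wild type. A corrected cycle completes 15 min after
the start of retrograde transfer (the transfer itself takes 12.5 min); a
terminal cytokinesis records the division (a daughter was produced) and
ends the lifespan; a terminal death ends the trace with no division.

Cell-cycle duration is 90 min, lengthening by 15% per division over the
last five divisions. Censoring: per-division trap-loss probability
(default 0.003) and a 72 h end-of-run. Cycles not observed to completion
contribute no events — a truncated movie cannot be scored. With
probability `multi_event_prob = 0.1` a GLM cycle also contains an earlier
transient event 25 min before the scored onset, fully reversed before it;
the final-event scoring rule must supersede it.

Mutant presets scale these constants qualitatively (directions follow the
genetics; magnitudes are invented): `fob1` lifespan ×1.3 and hazards ×0.7;
`rad9` flat hazard 0.01, terminal hazards ≈ 0, lifespan ×0.8; `rad52` flat
hazard 0.15, duration ×1.8, lifespan ×0.6; `tom1`/`ies4`/`hpc2` hazards
×0.5, lifespan ×1.15–1.2; `spt21` hazards ×1.5 and cytokinesis ×2; `bfa1`
cytokinesis ×10 (terminal-dominated); `mad3` = wild type; `flat_null` is
the exchangeable all-corrected null used for trend-test calibration.

## Trace model

Mother signal per cycle: 1N plateau through G1 (30% of the cycle), linear
S-phase rise to 2N (next 30%), 2N plateau, anaphase drop to 1N two frames
before the division (daughter washout). During a GLM the mother instead
drops to `leak × 2N` with `leak ~ U(0.05, 0.25)` — the majority of
detectable histones are in the daughter — and the daughter holds the
complement. Correction moves the signal back over 12.5 min with the summed
mother+daughter signal exactly conserved; terminal events end the daughter
segment (washout) or the mother trace (death) without restoration.
Sampling is uniform at 5 min. The measurement model applies exponential
photobleaching (0.001/frame) then multiplicative Gaussian noise
(CV 0.05), clipped at zero. The defaults make event calling nontrivial but
attainable; both are parameters.

What the generator does **not** emulate: segmentation/tracking errors,
focus drift, neighbouring-cell crosstalk, autofluorescence trends, or any
mechanistic coupling between damage state and arrest duration. Passing
tests therefore demonstrate correctness of the analysis chain under the
stated phenomenology, not robustness to every artifact of real imaging.

## Image fixtures and calibration

`dark` stacks are a fixed per-pixel bias pattern plus Gaussian read noise;
the bias estimate is the per-pixel mean. `dye` stacks are a smooth radial
vignette (amplitude 30%) times the dye level, with integer stage offsets
per frame and 1-px dark device features that move with the stage; the
flat-field estimate grayscale-dilates each frame with a disk of radius
3 px (removing the narrow features), takes the per-pixel median across
frames, and inverts. The correction is normalized to mean exactly 1 — note
`mean(field)/field` cannot have mean 1 (Jensen), so `1/field` is rescaled
explicitly. Recovery on fixtures is within 2% RMS away from an ~10-px
border, where stage offsets import out-of-field content. `cells` images
are disk cells with bright nuclear foci; the stored true asymmetry score
is the scorer applied to the noiseless image, making the fixture
self-consistent by construction.

The nucleolar asymmetry score takes the `ceil(0.02 n)` brightest pixels
(at least one — the rounding on small masks is unspecified in common
usage) over the whole-mask median.

## Event caller

Cycle segmentation uses division annotations when available (the cohort
table is the birth-annotation channel); unannotated traces are segmented
from daughter washouts, falling back to sustained ≥30% mother-signal
drops. Per-cycle 2N reference: median of samples within 15% of the 97th
percentile; 1N reference: median of samples between 35% and 65% of the 2N
reference.

An onset is the first frame of a run below
`glm_retention_threshold × 2N = 0.35 × 2N` lasting ≥ 2 frames — normal
anaphase retains ≈ 50% and is never called — with a concurrent daughter
gain of at least half the mother's loss. A run truncated by the cycle end
counts regardless of length: that is an arrest interrupted by washout or
death. If a cycle has several qualifying runs, only the final one is
scored.

Correction detection anchors timing on the mother's first departure from
the arrest plateau (median of samples since onset) by more than
`z × floor`, requires the daughter to fall by more than `z × floor` over
the 3-frame correction window (both signals moving, simultaneously, in
opposite directions), and requires the mother to subsequently regain 80%
of the 1N level — the recovery window extends a few frames past the cycle
boundary because cytokinesis follows completion of the transfer. The noise
floor is the per-trace median absolute successive difference on 1N plateau
samples (an honest scale for a one-frame difference), floored at 10⁻⁹ of
the trace maximum so noiseless traces behave. `z = 3` by default.

Outcomes: corrected if a resolution was found; otherwise terminal
cytokinesis when the event's cycle completed (the daughter visibly
separated), terminal death when the event sits in an uncompleted final
cycle of a cell with a death flag. Durations are resolution − onset for
corrected events only.

Arrests spanning fewer than two 5-min frames can fall entirely between
samples; they are invisible to any scorer at this cadence (~1% of events
under the wild-type duration law). The zero-noise exactness tests
therefore compare against observable ground truth; F1 is computed against
all ground truth and still exceeds 0.95 (typically ≈ 0.99) at default
noise.

## Statistical conventions

- **Birth alignment**: the risk set at age *a* is every cell with ≥ *a*
  completed divisions observed; a cell lost at age 20 contributes through
  age 19. **Death alignment**: only cells that died or senesced, indexed
  by divisions before death (1 = final completed division). Terminal-death
  events occupy the never-completed cycle after the last division (~1% of
  events) and fall outside the birth-aligned risk sets.
- **Survival**: Kaplan-Meier on division counts via `lifelines`, censored
  cells entering at their last completed division when included; the
  censor-aware mean RLS is the KM restricted mean with the horizon far
  beyond the support. The uncensored arithmetic mean is the
  microdissection-style alternative.
- **Cochran's Q** (via `statsmodels`): binary per-cell outcome per age bin
  (any GLM in the bin), complete-case cells observed through the last bin;
  default bins are four equal widths over ages 1–20. If every cell is
  constant across bins the statistic is defined as Q = 0, p = 1. Type-I
  error on the flat-hazard null is 5% ± 2% (1000 cohorts of 60 cells).
  Complete-case conditioning costs power: on a single wild-type run of a
  few hundred cells the trend test can land above p = 0.05 even though the
  underlying hazard ramps steeply (the ramp of long-lived cells lies
  beyond age 20).
- **Bootstrap**: the resampling unit is the cell with all its events;
  percentile intervals at 95% (`percentile95`) or 83.4%
  (`nonoverlap_p05`) — the calibration under which non-overlap of two
  equal-variance intervals corresponds to p ≈ 0.05. Measured non-overlap
  rate under the two-group null: 5% ± 2% (2000 simulations, n = 50 per
  group, 500 resamples). Both modes exist because practice reports 95%
  intervals in text and non-overlap bars in figures; neither is resolved
  into the other.
- **Counterfactual gain** uses uncensored cells only:
  `100 × (mean RLS / mean min(RLS, first-event age) − 1)`.
- **Duration vs age**: pooled-variance two-tailed t-test with events split
  at the cohort's median event age — the generator draws durations
  independently of age, a true null the test must not reject.
- **Event-aligned averaging** normalizes each trace so its 1N plateau is
  1, shifts correction to t = 0, and averages corrected events lasting
  > 30 min.

## Problem sizes and seeds

The flagship cohort is 410 mother cells at default noise (simulation +
traces + calling ≈ 5 s); genotype contrasts use 200 cells per strain. The
lifespan contrast (`fob1` vs wild type) runs without the 72 h movie cap —
it emulates a lifespan assay, and the cap would censor ~29% of the
long-lived cohort and bias the restricted mean — with per-division
trap-loss hazard solved so ~15% of cells are lost before death, and with
both strains sharing one seed (common random numbers), which cuts the
seed-to-seed spread of the percent-difference estimate from ±7.6 to
±2.7 percentage points. Calibration suites use 1000 (Cochran) and 2000
(bootstrap non-overlap) replicates; closed-form hazard checks use 50 000
cells at a fixed lifespan. Every generator, caller and bootstrap entry
point takes an explicit integer seed and is deterministic given it.

## Known limitations

- The generator is phenomenological: no DNA-damage-checkpoint signalling,
  histone pools, or spindle mechanics; hazards conditioned on the latent
  death age stand in for all of them.
- The per-cycle rate of multiple GLMs is unconstrained by data;
  `multi_event_prob` defaults to 0.1 and is exposed as a parameter.
- Unannotated segmentation relies on daughter washouts; without daughter
  segments it falls back to mother-drop detection, which cannot place the
  boundary after a corrected GLM cycle (the mother is already at 1N).
- The caller's cytokinesis/death distinction without birth annotations
  requires the death flag to precede the washout by more than one frame.
- Whole-mask medians are used in the asymmetry score; a
  background-excluded median would shift scores on dim cells.
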