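# glmaging

Analysis toolkit for **genome-level missegregation (GLM) during yeast
replicative aging**, built for single-cell timelapse data of histone-tagged
mother cells aging in microfluidic traps.

As budding-yeast mothers approach the end of their replicative lifespan
(RLS — the number of daughters a mother produces before irreversible
arrest), mitosis increasingly fails in a dramatic way: the majority of the
chromatin transiently moves into the daughter bud before anaphase. Most of
these GLMs are *corrected* by retrograde transport of the chromatin back to
the mother; an uncorrected event is *terminal* — the daughter separates
with the genome, or the mother dies. The package provides the full analysis
chain for quantifying these dynamics:

- **`glmaging.synthetic`** — a calibrated generator of cohorts
  (Gompertz lifespans, age-ramped GLM hazard, competing
  correction/cytokinesis/death resolution, censoring), of noisy
  mother/daughter fluorescence traces (S-phase doubling, anaphase halving,
  transfer/correction dynamics, photobleaching), and of microscopy image
  fixtures with pixel-level ground truth.
- **`glmaging.imagequant`** — camera-bias and flat-field calibration
  (dark-stack mean; dilation + median of an offset dye stack) and the
  nucleolar asymmetry score (mean of the brightest 2% of a cell's pixels
  over the cell median).
- **`glmaging.caller`** — automated event scoring on traces: cycle
  segmentation, onset calls (sustained mother collapse below 35% of the 2N
  level with a matching daughter gain), correction detection (simultaneous
  daughter fall and mother rise), outcome classification, durations. One
  event per cycle: when several occur, only the final one is scored.
- **`glmaging.stats`** — censoring-aware aging statistics: birth- and
  death-aligned event-probability curves, Kaplan-Meier survival and
  log-rank, Cochran's Q age trend, cell-level bootstrap intervals (95%, or
  83.4% so that non-overlap of two bars ≈ p = 0.05), Spearman
  event-vs-remaining-lifespan correlation, history dependence,
  counterfactual lifespan gain, duration-vs-age t-test, and event-aligned
  trace averaging.
- **`glmaging.cli` / `glmaging.pipeline`** — a `glmaging` command with
  `simulate`, `synthesize`, `call-events`, `stats`, `quantify-images` and
  `report` subcommands; fully seeded and byte-reproducible.

## The statistics at the core

For a cohort of mother cells, each division at replicative age *a* carries
a GLM probability *h(a; L)* that is low and flat in youth and ramps
steeply over the last five divisions before the cell's baseline death age
*L*. An event arrests the cell in metaphase; correction at
*T*<sub>r</sub> ~ LogNormal competes with terminal transitions at total
exponential hazard λ<sub>t</sub>, so the corrected fraction is
E[exp(−λ<sub>t</sub>·*T*<sub>r</sub>)] ≈ 0.90 for the wild-type
parameters. Cohort quantities reported:

- penetrance: fraction of mothers with ≥ 1 event over their lifespan;
- corrected fraction of events;
- counterfactual lifespan gain:
  100 × (mean RLS / mean min(RLS, age of first GLM) − 1), i.e. how much
  longer cells live than if every first event had been terminal;
- birth-aligned curves include censored cells up to their last fully
  observed division; death-aligned curves use only cells that died or
  senesced, indexed by divisions before death.

## Worked example

Regenerate the wild-type study (410 mother cells, 5-min sampling, default
noise) and score it end to end:

```
glmaging report --preset wild_type --n-cells 410 --seed 1 --out run_wt
```

which prints (abridged):

```json
{
  "n_cells": 410,
  "n_events_called": 532,
  "penetrance": 0.7804878048780488,
  "corrected_fraction": 0.8984962406015038,
  "counterfactual_gain_percent": 35.427330541337064,
  "mean_rls_uncensored": 22.736979166666668,
  "mean_rls_km": 23.391475406503247,
  "terminal_death_fraction": 0.140625,
  "uncorrected_event_fraction": 0.10150375939849623
}
```

Read: 78% of mothers experienced at least one GLM; 89.8% of the 532 called
events were corrected; successful correction let cells live ~35% longer
than if every first event had been terminal; 14% of uncensored deaths were
attributable to a terminal missegregation. The directory `run_wt/` also
contains the cohort, trace and event tables (CSV), birth/death-aligned
event-probability curves, and the Kaplan-Meier survival table, all stamped
with the run's configuration hash.

Mutant presets (`fob1`, `rad9`, `rad52`, `tom1`, `ies4`, `hpc2`, `spt21`,
`bfa1`, `mad3`) emulate the studied genotype contrasts, e.g.:

```
glmaging report --preset bfa1 --n-cells 200 --seed 2 --out run_bfa1
```

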