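# nestcoord

Quantifying how seabird partners coordinate parental care from nest-camera
event logs.

In species with long biparental care — here modeled on the Dovekie (Little
Auk, *Alle alle*), a small Arctic seabird — each parent trades off offspring
care (incubating the egg, provisioning the chick) against self-maintenance
(foraging at sea). Coordination mitigates that conflict: during incubation
one partner sits on the egg while the other forages and they exchange;
during chick rearing partners interleave short provisioning trips with long
self-maintenance trips so that both are rarely on a long trip at once.
`nestcoord` implements the full analysis chain used to measure this from
48-hour video-recording sessions, for behavioral ecologists who have
per-event annotations (bird appears/vanishes on frame, enters/exits nest,
food-load on return) and want session-level coordination statistics and
season-level trends.

## What it computes

**Activity bouts.** Each bird's event stream becomes a sequence of
`NEST` / `COLONY` / `FORAGING` bouts tiling the session: time in the nest is
NEST; an absence ≥ 1 h is a foraging trip during incubation; during chick
rearing a trip is an absence ending with a full gular pouch; everything else
is COLONY. Intervals are half-open integer seconds.

**Overlap statistics.** For incubation, the opposite-activity time

&nbsp;&nbsp;&nbsp;&nbsp;S = |{t : one partner in NEST, the other FORAGING}|,

and for chick rearing the short×long trip time, computed by an exact sweep
over merged bout breakpoints.

**Constrained randomization null.** Each partner's timeline is shuffled
10,000 times preserving the bout multiset and the colony-sandwich structure
(a colony bout before and after every nest/foraging bout): colony bouts
permute among colony slots, away bouts among away slots, uniformly and
independently per partner. The session p-value is

&nbsp;&nbsp;&nbsp;&nbsp;p = #{S_obs < S_null,i} / N,

(strict inequality, ties not counted) and the coordination index is

&nbsp;&nbsp;&nbsp;&nbsp;I = (obs − exp) / exp,&nbsp;&nbsp; exp = mean of the null overlaps.

**Short/long trip split.** Chick-rearing trips are classified per
phase × season by the threshold minimizing
Var(log d | short) + Var(log d | long) over every cut between consecutive
order statistics (threshold = geometric mean of the boundary pair).

**Trend models.** Incubation coordination (raw overlap seconds) is modeled
as a Gamma GLMM with inverse link, `overlap ~ phase * year + (1|pair)`, with
type-III Wald χ² tests (the GLMM likelihood is maximized directly with
Gauss–Hermite quadrature over the pair intercept). The chick-rearing index
uses a Gaussian LMM with Tukey-adjusted contrasts of all phase × year cells,
and the cross-stage link uses per-phase linear models
`chick index ~ early + mid + late incubation coordination` with VIF checks
and a pair-resampling bootstrap (B = 10,000, percentile intervals).

**Synthetic data.** A semi-Markov generator produces two-partner sessions
with the same structure (lognormal bout durations, bimodal trip mixture)
and a coupling strength κ ∈ [0, 1]: κ = 0 is exactly the randomization null,
κ → 1 approaches tight nest-relief exchange. Every pipeline stage is
testable without field data.

## Worked example

```python
import json
from nestcoord import RunConfig, run_pipeline
from nestcoord.simulate import StudyDesign

result = run_pipeline(RunConfig(
    out_dir="demo-run", seed=7, n_iter=1000, n_boot=1000,
    design=StudyDesign(n_pairs_incubation=6, n_pairs_chick=6),
))
print(json.dumps(result.summary, indent=2, sort_keys=True))
```

prints

```json
{
  "alpha": 0.05,
  "chick_rearing": {
    "fraction_coordinated": 0.16666666666666666,
    "mean_index": 0.07920481512479392,
    "mean_shortlong_proportion": 0.2472113715277778,
    "n_sessions": 24
  },
  "incubation": {
    "fraction_coordinated": 1.0,
    "iqr_opposite_proportion": [0.9070413773148148, 0.9438556134259259],
    "mean_opposite_proportion": 0.8602932098765432,
    "n_sessions": 36
  },
  "n_iter": 1000,
  "seed": 7,
  "trip_thresholds_h": {
    "EARLY_2019": 5.808680445550308,
    "EARLY_2020": 5.104617893887121,
    "MID_2019": 6.853823581416813,
    "MID_2020": 6.576258974429568
  }
}
```

Read: partners in this simulated study spent on average 86% of each
incubation session doing opposite activities, and every session exceeded its
randomization null (`fraction_coordinated: 1.0` at α = 0.05) — strong
incubation coordination, as built into the generator (κ = 0.9). During chick
rearing, short×long trip overlap averaged 25% of a session but only 17% of
sessions beat chance (κ = 0.3), with a mean coordination index of 0.08; the
trip split put the short/long threshold at 5.1–6.9 h depending on phase and
season. The run directory contains the per-session results CSV, trip table,
model reports (JSON and text), figures, a deterministic log, and a SHA-256
manifest; rerunning with the same seed reproduces every file byte for byte.

The same analysis is available from the shell:

```bash
nestcoord simulate --out data --seed 7 --pairs-incubation 6 --pairs-chick 6
nestcoord analyze --events data/events.csv --out run --seed 7 --n-iter 1000
nestcoord report --run-dir run
```

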