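# Methods

This note documents the statistical machinery behind `nestcoord`: the
session model, the randomization null and its guarantees, the trip split,
the trend models, the synthetic-data generator, and the numerical and
design choices made where more than one convention was defensible.

## Session model

A recording session is a fixed window of `T` seconds (nominally 48 h =
172,800 s) over which each of two partners occupies exactly one behavioral
category at every instant: `NEST` (inside the nest), `COLONY` (visible
around the nest, or absent less than the foraging gap), or `FORAGING`.
Timestamps are integer seconds — the annotation precision — and all
intervals are half-open `[start, end)`, so a bird's bout sequence tiles
`[0, T)` exactly and two touching intervals share no time. Adjacent bouts
never share a category (they are merged), and NEST and FORAGING are never
adjacent: a bird passes through the colony between the nest and the sea.
This "colony sandwich" is a structural fact of the annotation process, and
the randomization below conditions on it.

Bout derivation from raw events is deterministic. The one genuinely
ambiguous case is the session edge: before the first event and after the
last, the bird's state is inferred from the adjacent event (a bird that
*vanishes* was visible before; a bird that *appears* was away). A trailing
absence truncated by the session end has unknown outcome (no return
observed), so it is labeled by the gap rule alone and the session is
flagged as containing extrapolated spans; during chick rearing such an
absence can never be a provisioning trip and, if long enough to be labeled
FORAGING, is flagged non-provisioning and excluded from the trip
statistics. Long chick-rearing absences that end *without* food are likewise
kept on the timeline as FORAGING but excluded from the short/long split —
the split concerns provisioning trips, which are defined by the food-load
return.

## Overlap statistics

Both statistics are measures of a set of instants and are computed exactly
by sweeping the union of the two birds' bout breakpoints; no discretization
or sampling is involved, which is why the tests can demand bit-exact
agreement with a second-by-second scanner. Proportions divide by the full
session duration `T`.

## The constrained randomization null

The null hypothesis is that partners time their activities independently.
Because bout *durations* carry strong autocorrelation and diel structure, a
plain permutation of states would be far too liberal; instead the null
preserves each bird's bout multiset exactly and randomizes only the
ordering, under the colony-sandwich constraint:

1. the timeline is normalized to alternating slots `C, A, C, A, …, C`,
   where `A` is a NEST or FORAGING bout (incubation) or a foraging trip
   (chick rearing, with NEST and COLONY merged into at-colony time);
   a timeline that starts or ends with an away bout receives a zero-length
   sentinel colony slot at that edge;
2. the multiset of real colony durations is permuted uniformly among the
   real colony slots, and the multiset of away bouts (each carrying its
   category or trip label and duration) uniformly among the away slots,
   independently for the two partners;
3. the timeline is rebuilt cumulatively from t = 0.

Zero-length sentinels stay pinned to their edge: moving an empty colony
slot between two away bouts would glue them together and break the
sandwich constraint, so arrangements with interior empty slots are not
admissible and are not generated.

Per-category bout counts and total times are conserved exactly on every
iteration (verified exhaustively in the tests), and for small sessions the
shuffle's support and probabilities match brute-force enumeration of all
admissible arrangements.

The session p-value is the proportion of the `N = 10,000` iterations whose
overlap strictly exceeds the observed one; ties do not count. This is the
strict count rule, with no add-one smoothing (a smoothed variant is
available but off by default). With a discrete null this makes p slightly
conservative in distribution but matches the convention of the analysis
this package implements. A session is called coordinated when p < 0.05.
The coordination index `(obs − exp)/exp` uses the null mean as `exp`; when
the null mean is zero (a partner that never forages) the index is undefined
and reported as missing with a warning.

For the incubation analysis the downstream response is the raw
opposite-activity duration rather than the index: with two long-bout
activities dominating a finite 48-h window, the constrained null leaves
little room for chance and the index would be flattened; the duration
itself varies informatively.

## Short/long trip split

Chick-rearing trip durations are pooled per phase × season and split by the
threshold minimizing the summed within-group variance of log durations,
scanned over every cut between consecutive distinct order statistics.
Conventions:

* **variance**: population variance (divide by n); since singleton groups
  would trivially minimize it, each side must have at least 2 trips
  (configurable), matching the two-strategy biology;
* **tie-breaks**: equal objectives go to the cut with the larger log-gap
  between its boundary durations, then to the smaller threshold;
* **threshold placement**: the geometric mean of the boundary pair — any
  point inside the gap yields the same labels, so the reported number is a
  convention;
* degenerate inputs (all durations equal, or fewer than 4 trips) are
  errors that advise pooling, never silent labels.

The split is scale-equivariant (multiplying all durations by c multiplies
the threshold by c and fixes the labels), a direct consequence of working
on logs.

## Trend models

**Incubation.** `overlap_seconds ~ phase * year + (1|pair)` with a Gamma
family and inverse link (the response is a positive duration). No installed
Python library fits a Gamma GLMM, so the marginal likelihood is maximized
directly: the single random intercept is integrated by 40-node
Gauss–Hermite quadrature, and the optimizer works on
(fixed effects, log random-SD, log shape) with L-BFGS-B (Nelder-Mead
fallback), starting from the marginal Gamma GLM. The response is internally
rescaled to unit mean — inverse-link coefficients scale as 1/response, and
raw seconds (coefficients ~1e−6) are numerically hostile; estimates and
standard errors are mapped back. The quadrature nodes can push the linear
predictor η = 1/μ below zero far in the tails; such nodes contribute zero
likelihood. The coefficient covariance comes from the numerical Hessian at
the optimum; when the random-intercept variance collapses to the boundary
the joint Hessian flattens, and the covariance then conditions on the
variance parameters (with a warning). An independent cross-check against
`lme4::glmer` (adaptive quadrature, through Rscript) agrees on fixed
effects to well under 1%.

**Type-III Wald tests.** Each term's coefficient block is tested with
χ² = b′V⁻¹b in the presence of all other terms, with sum-to-zero coding for
categorical factors so the tests do not depend on the reference level.
Wald and likelihood-ratio statistics agree asymptotically, and the tests
check they give the same call on clear effects; exact equality is not
expected in finite samples.

**Chick rearing.** `index ~ phase * year + (1|pair)` as a Gaussian LMM
(statsmodels MixedLM, REML; several optimizers are tried because boundary
variance estimates can trip any single one). All pairwise contrasts of the
phase × year cell means are reported with Tukey adjustment via the
studentized range on the full number of cells — deliberately conservative —
using the large-sample residual df (observations minus fixed-effect
parameters). With a single pair the random intercept is unidentifiable and
the fit falls back to ordinary least squares with a warning.

**Cross-stage link.** One OLS per chick-rearing phase on the complete-case
per-pair table (all three incubation phases of the first season plus both
chick sessions), F tests per term, variance-inflation factors (error on
perfect collinearity), and a case-resampling bootstrap over pairs:
B = 10,000, percentile 95% intervals, two-sided p as twice the fraction of
bootstrap estimates crossing zero, capped at 1. The bootstrap scheme and B
are this package's convention, stated openly.

## Synthetic-data generator

Each bird is an alternating renewal process `colony, away, colony, …` with
lognormal durations. Defaults (all overridable) anchor to the species'
scales:

| quantity | median | sdlog |
|---|---|---|
| incubation NEST bout | 12 h | 0.35 |
| incubation FORAGING bout | 12 h (≥ 1 h floor) | 0.35 |
| incubation colony spell | 0.5 h | 0.5 |
| short provisioning trip | 2.2 h | 0.30 |
| long trip | 12 h | 0.30 |
| chick at-colony spell | 1 h | 0.5 |

Chick trips are a 70:30 short:long mixture; incubation away bouts are NEST
with probability 0.5, drawn independently. The independent draw (rather
than forced nest/forage alternation) is deliberate: it makes each bird's
bout ordering exchangeable, so at coupling κ = 0 the generated sessions are
*exactly* draws from the constrained-shuffle null and randomization
p-values are uniform. Real birds do alternate; the generator trades that
realism for an exact null, which is what calibration tests require.

Coupling strength κ ∈ [0, 1] is applied by one bird (the follower) per
departure, with probability κ:

* **incubation — complement-and-relieve**: the follower aligns its next
  away bout with the partner's current-or-next away bout, performing the
  complementary activity until the partner's bout ends, as an incubating
  bird stays on the egg until relieved. A pure "wait until the partner is
  in the right state, then do your own thing" rule was evaluated first and
  cannot produce strong coordination (the follower's independently drawn
  bout durations waste most of the partner's bout); the relieve rule drives
  the opposite-activity share to 0.94 ± 0.02 at κ = 1 — the near-ceiling
  regime actually observed in highly coordinated pairs — while κ = 0 is
  untouched.
* **chick rearing — long-trip avoidance**: a long-trip departure is delayed
  until the partner is not itself on a long trip; short-trip departures and
  all trip durations are unaffected, so trip-duration marginals stay
  exactly as configured.

Default κ is 0.9 for incubation and 0.3 for chick rearing: strong
incubation coordination, occasional provisioning coordination. The default
study design mirrors the field protocol: two seasons, three incubation
sessions per pair-season (starting 26/15/5 and 20/12/4 days before
hatching) and two chick-rearing sessions (early, mid), for 19 incubation
and 21 chick-rearing pairs.

What the generator does **not** emulate: diel rhythm and weather forcing;
nest visits during chick rearing (at-colony time is emitted as COLONY);
drift of bout durations across the season; observation error. Passing
tests therefore demonstrate correctness of the statistical machinery under
the stated model, not robustness to every feature of field data. Two window
effects are worth knowing about: (i) completed trips inside a finite window
slightly under-sample long durations (edge truncation), so the marginal
distribution check runs on a 60-day horizon where the effect is negligible;
(ii) the truncated final bout of a session is not perfectly exchangeable
with the shuffle null, which leaves a small residual anticonservatism in
the κ = 0 calibration — visible as a KS statistic near, but inside, the
acceptance bound. Real recordings share both effects.

## Determinism and problem sizes

All randomness flows from one master seed through `numpy` `SeedSequence`
spawning, in a fixed session order; identical configuration and seed
reproduce every output file byte for byte (the run manifest records SHA-256
checksums). The test suite exercises the stack at sizes chosen to keep the
full run within a few minutes on one CPU: 1,000 random small sessions for
the overlap oracle, 10,000-iteration shuffles for exactness and
conservation, 200 sessions × 1,000 iterations for null calibration,
100 sessions per κ on a five-point grid for monotonicity, 500 random
duration sets for the split oracle, and 100 seeded replicates for model
recovery (bootstrap B = 500 inside replicates). The acceptance script runs
the full default study at the analysis-scale 10,000 iterations per session.

## Known limitations

* The Gamma GLMM uses non-adaptive quadrature; with very large
  random-effect variances relative to the linear predictor the 40-node rule
  could lose accuracy (not a regime these data produce).
* Tukey contrasts use a large-sample residual df rather than a
  Satterthwaite/Kenward-Roger correction; with many pairs the difference is
  negligible, with very few pairs the contrasts are mildly liberal.
* The randomization conditions on the observed bout multiset; it tests
  ordering, not durations. Pairs that coordinate by adjusting bout
  *lengths* rather than timing would be invisible to it.
* `phase` enters the incubation model linearly in days before hatching;
  nonlinear within-stage trends require a user-supplied transform.
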