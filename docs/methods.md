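# Methods

This note records the models, conventions, and numerical choices behind
`ethochunk`, and what the synthetic-data tests do and do not establish
about real data.

## Event model

Annotations are event streams per recording. Interval events are
half-open `[start_s, stop_s)`; abutting intervals therefore never
double-count a boundary instant, and splitting an interval into abutting
sub-intervals is score-invariant (union semantics). Point events are
stored with `stop_s == start_s` plus an explicit `point` type, so both
kinds share one CSV schema. Times are seconds with millisecond
precision; frame indices are derived as `round(t * fps)` when needed and
never stored, because frame rate can vary per recording. Overlapping
intervals of the same behavior are permitted and scoring treats them as
a union.

Validation returns violations as data rather than raising, so
questionable files can be loaded, inspected, and repaired; each event is
judged independently, making the report order-independent and
idempotent.

## Chunk sampling

Sampling is stratified: `pieces_n` equal contiguous pieces anchored at
time 0, then `chunks_per_piece` chunks of `chunk_dur_s` drawn uniformly
without replacement *from an aligned slot grid* of
`floor(piece_dur_s / chunk_dur_s)` slots per piece. The slot grid is a
design choice (a continuous-start scheme would also be "random"): it
guarantees non-overlap by construction, makes the uniformity of the draw
directly testable against the binomial null, and degrades gracefully to
the tiling edge case where `chunks_per_piece` equals the slot count.
Recordings longer than `pieces_n x piece_dur_s` have the trailing
remainder excluded with a logged warning (recordings often overrun a few
seconds); shorter recordings are an error.

Randomness is decomposed into substreams: the RNG for (recording,
piece) is seeded from a BLAKE2b hash of `(master_seed, video_id,
piece_index)`. Consequently adding or removing a recording never
perturbs another recording's chunks, and one master seed makes the whole
pipeline byte-reproducible.

Defaults (3 pieces x 600 s, 10 chunks x 10 s) reflect the standard
30-min maternal-behavior assay: 30 chunks, 300 s scored per recording.

## Blinding

The presentation schedule is a seeded uniformly random permutation of
all pooled chunks. Blind codes are fixed-length strings drawn without
replacement from a seeded code space (not sequential — sequential codes
would leak pooling order). The scorer-facing schedule file contains only
`presentation_rank,blind_code,dur_s`; the code-to-chunk map is a
separate file. Unblinding is a checked bijection that fails loudly on
stale codes.

## Whole-video measures and censoring

The initiation latency is the earliest start of any "pup retrieval"
event; if none occurs before the cutoff (default 300 s) the measure is
the cutoff value with a censored flag. The completion latency uses the
earliest start of "all pups retrieved and grouped" with the assay length
(default 1800 s) as its horizon — only initiation has a conventional
300 s cutoff in this assay, so completion is censored at the assay end.
Whole-video measures are always computed from the full event stream,
never from sampled chunks. A completion event preceding the first
retrieval is logically odd but tolerated with a warning (annotators own
the record). Nest scores are validated as integers 0–4; booleans and
non-integral floats are rejected.

In the group analysis, censored latencies enter at their cutoff value —
the same convention used when such data are plotted — rather than via a
survival model. This understates differences when censoring is heavy,
which is acceptable for a rank-based test (the cutoff value is simply
the largest tied rank) and keeps the analysis faithful to how the assay
is conventionally reported.

## Rank-sum test

`rank_sum_exact` enumerates all C(n1+n2, n1) assignments of the observed
pooled values to group 1 and computes the two-sided p as
`2 * min(P(W <= w_obs), P(W >= w_obs))`, capped at 1 — the convention
most exact-test software documents. Ties need no special correction
because the observed (possibly tied) values themselves are enumerated;
tail comparisons use a 1e-9 tolerance to absorb float summation error in
midranks. Enumeration is refused above a pooled size of 14 by default
(C(14,7) = 3432 assignments) and the caller is pointed to the normal
method; `compare_groups` switches automatically. The normal route uses
the tie-corrected variance

    Var(W) = n1 n2 / 12 * [(N + 1) - sum(t^3 - t) / (N (N - 1))]

with a 0.5 continuity correction shrinking |W - E(W)| toward zero, and
returns p = 1 with a warning when every pooled value is identical.
Quartiles are computed by linear interpolation of order statistics
(numpy's default); the same definition is used by the test oracles. No
multiple-testing correction is applied across strata — per-stratum raw
p-values are reported, matching how per-day comparisons are
conventionally presented.

## Synthetic cohort generator

The generator emulates a 30-min pup-retrieval session:

* **Initiation latency** L ~ lognormal(log-median mu, sigma), unless a
  Bernoulli(p_fail) failure suppresses retrieval for the session.
  Lognormal was chosen for positive support and a closed-form median
  (exp(mu)), which the recovery tests exploit.
* **Retrieval sequence**: one 5-s carry per pup, gaps gamma(shape,
  scale). Gamma gives a flexible positive gap distribution with two
  interpretable parameters.
* **Completion** T = end of the last carry; from T to assay end the
  stream contains single "all pups retrieved and grouped" and "all pups
  nested" state intervals (in reality nesting can lapse; kept simple and
  so documented), plus alternating pup-directed vs solo bouts with
  exponential durations.
* **Background**: sporadic nest-building and pup-interaction bouts as
  renewal processes.
* **Nest score** drawn from a 5-category distribution.

Event times are rounded to the millisecond grid at generation time, so
CSV round-trips are lossless and pipeline-vs-truth comparisons can
demand exact equality. Each session is seeded from `(seed, strain,
animal, day)`, so cohorts grow without perturbing existing sessions.

Default parameters are invented fixtures: C57BL/6 (n = 5 per day;
median latency 45 s, sigma 0.6, p_fail 0.02, strong nests) vs DBA/2J
(n = 6; median 200 s, sigma 0.9, p_fail 0.25, weak nests), three pups,
lactation days 1/3/5. They are tuned only so the *direction* of the
known strain contrast (DBA/2J slower to retrieve, failing more often,
weaker nests) is reproduced in ≥95% of seeded replicates at n = 5 vs 6;
no published magnitudes are claimed or reproduced, and nothing about the
defaults is validated against real animals. Passing tests therefore
demonstrate the pipeline's correctness (exact truth recovery, censoring
arithmetic, determinism), not any biological effect size. The generator
also omits circadian structure, pup development, day-to-day correlation
within a dam (days are simulated independently), and scorer error.

The closed-form censoring probability used in calibration checks is
`P(censored) = p_fail + (1 - p_fail) * P(L >= cutoff)` with L lognormal.

## Acquisition utilities

Drive capacity truncates (floors) to one decimal — `0.5 h x 256 / 3 GB
= 42.66... -> 42.6 h` — because a conservative figure is the useful one
when provisioning; the 3.0 GB default stands in for "just under 3 GB"
half-hour files at 1296x972/30 fps. Environment logs are CSV with
ISO-8601 timestamps (no standard file format exists for these rigs);
timestamps must be strictly increasing, windows are half-open
`[t0, t1)`, and an empty window is an explicit empty result rather than
an exception so batch reviews don't abort.

## Problem sizes in the test suite

The statistical property tests use sizes chosen for tight Monte-Carlo
bounds at interactive runtimes: 200 random datasets (pooled n ≤ 10,
tie-rich) for the exact-test oracle comparison; 10^4 master seeds for
slot-frequency uniformity (3-sigma binomial bands per slot); 500
simulated dams for censoring calibration (3-sigma binomial) and median
recovery (±5% of exp(mu)); 100 seeded replicate cohorts for the
strain-contrast direction. The whole suite runs in well under a minute.

## Known limitations

* Exact enumeration is factorial; above the configured limit only the
  normal approximation is available (no network/recursive exact
  algorithm for mid-sized samples).
* Presence scoring implements only the any-overlap rule; a
  majority-of-chunk rule would need a new `presence_rule`.
* No inter-rater reliability statistics and no survival-analysis
  treatment of censored latencies.
* The blind-code space (29^6 ≈ 5.9e8) is drawn with rejection on
  collision; schedules beyond ~10^4 chunks should lengthen the code.
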