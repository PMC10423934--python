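# ethochunk

Blinded, randomized chunk sampling and scoring for home-cage behavior
video — a headless library and CLI for labs that score long video
recordings by hand and want the sampling, blinding, and statistics to be
reproducible.

Manual scoring of long behavior videos is slow and vulnerable to
experimenter bias: the rater knows which animal, group, and day they are
watching, and behavior often depends on where in a session it occurs.
`ethochunk` addresses both problems for any video-based assay, with the
mouse maternal-behavior test (pup retrieval, nesting) as its worked
exemplar. No pixel data is ever read — videos enter only as metadata
(identifier, duration, frame rate), and all annotation is event-based
CSV.

## What it does

* **Stratified chunk sampling.** A recording of duration `D` is split
  into `P` contiguous *pieces*; within each piece, `k` *chunks* of fixed
  duration `c` are drawn uniformly without replacement from an aligned
  slot grid, so chunks never overlap and every scored session covers the
  beginning, middle, and end of the assay. With the defaults
  (`P = 3` pieces of 600 s, `k = 10` chunks of `c = 10` s), a 30-min
  video is scored from only 5 min of material.
* **Blinded presentation.** Chunks pooled across any number of
  recordings are presented in a seeded uniformly random order under
  opaque blind codes; the code→chunk map is a separate artifact the
  scorer never sees. Unblinding is an exact bijection.
* **Scoring.** Chunk-scored behaviors are reduced to a binary
  chunk × behavior matrix (presence = any positive-measure overlap with
  the half-open chunk window). Whole-video measures come from the full
  event stream: latency to initiate pup retrieval (censored at 300 s),
  latency to complete retrieval (censored at the assay end, 1800 s), and
  an ordinal 0–4 nest score.
* **Statistics.** Two-group Wilcoxon rank-sum comparison, exact by full
  enumeration of all C(n₁+n₂, n₁) assignments (two-sided
  p = 2·min(P(W ≤ w), P(W ≥ w)), capped at 1) or by tie-corrected normal
  approximation, stratified e.g. by lactation day, with median ± IQR
  summaries. Censored latencies enter at their cutoff value.
* **Synthetic cohorts.** A generative model of the maternal-behavior
  assay (lognormal initiation latency, Bernoulli retrieval failure,
  gamma inter-retrieval gaps, exponential bout alternation, categorical
  nest score) with per-session ground-truth records, so the entire
  pipeline is testable end to end without any video.
* **Acquisition utilities.** Drive-capacity arithmetic, repeated
  recording schedules, and min/mean/max summaries of
  temperature/humidity logs over arbitrary windows.

## Worked example

Simulate the default two-strain cohort (5 C57BL/6 and 6 DBA/2J dams,
lactation days 1, 3, 5), compute whole-video measures, and compare
strains per day:

```python
import pandas as pd
import ethochunk as ec
from ethochunk.scoring import measures_row

sets, truth = ec.simulate_cohort(ec.SimConfig(seed=7))
rows = []
for ann in sets:
    nest = int(truth.loc[truth["video_id"] == ann.video_id, "nest_score"].iloc[0])
    rows.append(measures_row(ann, ec.whole_video_measures(ann, nest)))
table = pd.DataFrame(rows)
print(ec.compare_groups(table, "latency_initiate_s", "strain", "lactation_day"))
```

which prints (columns abridged):

```
 stratum  group1  median1 group2  median2  w_stat  p_two_sided            method
       1 C57BL/6   47.213 DBA/2J  300.000    15.0     0.004329 exact_enumeration
       3 C57BL/6   52.517 DBA/2J  245.889    20.0     0.082251 exact_enumeration
       5 C57BL/6   48.732 DBA/2J  300.000    15.0     0.004329 exact_enumeration
```

Each row is one lactation day: the group medians of the
retrieval-initiation latency in seconds (300.000 is the censoring
cutoff — on days 1 and 5 the median simulated DBA/2J dam never initiated
within 300 s), the rank sum W of the first group, and the exact
two-sided p-value. W = 15 with n₁ = 5 is the smallest possible rank sum,
i.e. complete separation, giving p = 2/462 ≈ 0.004329. The synthetic
strain parameters are invented fixtures tuned only so the *direction* of
the contrast (DBA/2J slower, weaker nests) is realistic; the magnitudes
are not estimates of any real cohort.

The same pipeline is available from the shell:

```bash
ethochunk simulate --seed 7 --out cohort/
ethochunk plan --video-id c57bl6-dam00-ld1 --duration 1800 --seed 7 --out plan.csv
ethochunk present --plans plan.csv --seed 7 \
    --out-schedule schedule.csv --out-blind-map blind_map.csv
ethochunk score --annotations cohort/c57bl6-dam00-ld1.csv --plan plan.csv --out scores.csv
ethochunk capacity --drive-gb 256          # -> 42.6 (hours of video)
```

`schedule.csv` contains only `presentation_rank,blind_code,dur_s` — the
scorer-facing file carries nothing from which animal, day, or group
could be recovered.

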