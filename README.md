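# rfidcontacts

Cleaning and validity analysis of face-to-face contact data recorded by
wearable proximity (RFID) badges.

Badges worn on the chest record when two participants face each other at
short range, producing a time-stamped dyadic event log (`start, id_a,
id_b, end`). The signal is imperfect in characteristic ways: one
continuous conversation is fragmented into several short on-intervals
("flicker"), pairs inside larger conversation groups are missed because
of the badges' narrow detection angle, and the firmware rounds very
short detections up to a 10-second minimum. This package implements the
standard validation workflow for such data:

* **Event-log algebra** — parsing, normalization (canonical dyads,
  merged overlapping/abutting intervals, half-open `[start, end)`
  seconds), rasterization to a dyads × seconds binary matrix, aggregation
  to weighted contact matrices, and descriptive summaries.
* **Cleaning strategies** — minimal-duration filtering (drop events
  shorter than a cutoff), gap interpolation (merge same-dyad events at
  most *x* seconds apart), and iterated triadic closure (impute B–C
  whenever A is simultaneously in contact with B and C), plus parameter
  sweeps against a ground-truth log.
* **Construct validity** — dyad-second classification against
  human-coded ground truth:

  TP = Σ_d Σ_i 1{R_i^d + V_i^d = 2}, and analogously FP, FN, TN, over
  all D = N(N−1)/2 dyads and S seconds; sensitivity = TP/(TP+FN),
  specificity = TN/(TN+FP), accuracy = (TP+TN)/(TP+FP+FN+TN). Cohen's κ
  summarizes agreement between two human raters; rater codings can be
  spliced so each accounts for half of the coded time.
* **Criterion validity** — aggregated contact minutes vs. a directed
  self-report nomination matrix: weak/strong symmetrization,
  reciprocity, a pooled two-sample t test with Cohen's d, logistic
  regression of nomination on minutes with McFadden's pseudo-R²
  = 1 − ℓ/ℓ₀, and descriptive deviance comparisons between fits.
* **Synthetic worlds** — a seeded generator producing ground truth from
  a conversation-group Markov process (per-second clique structure), a
  flickering sensor (geometric on/off renewal gate, group-size detection
  decay, rare false positives, 10-s rounding), noisy raters, and
  duration-driven self-reports. This is first-class, tested code: no raw
  field data ship with validation studies of this kind, so all
  statistical claims are exercised on generated worlds with known
  parameters.

## Worked example

```sh
python analysis/01_simulate_world.py --seed 1
python analysis/02_construct_validity.py --seed 1
```

prints (seed 1):

```
truth: 570 events, mean duration 77.7 s; observed: 908 events, mean duration 32.3 s
the sensor fragments long true contacts into more, shorter events
      raw: TP=28751 FP=534 FN=15529 TN=208296  sensitivity=64.9% specificity=99.7% accuracy=93.7%
processed: TP=30764 FP=2183 FN=13516 TN=206647  sensitivity=69.5% specificity=99.0% accuracy=93.8%
    steps: [{'kind': 'interpolate', 'value': 75}, {'kind': 'min_duration', 'value': 55}]
    min_duration: optimum at   0 (accuracy 0.9365, +0.0000 vs unprocessed)
     interpolate: optimum at  70 (accuracy 0.9556, +0.0191 vs unprocessed)
 triadic_closure: optimum at   1 (accuracy 0.9672, +0.0307 vs unprocessed)
```

Reading: the simulated badges see only ~65% of true interaction seconds
but almost never invent contact (specificity 99.7%). Deleting short
events can only hurt (optimum at cutoff 0); merging flicker gaps of up
to ~70 s recovers about 2 accuracy points; closing triads recovers
contacts missed inside larger groups. `analysis/03_rater_reliability.py`
and `analysis/04_criterion_validity.py` continue with inter-rater κ and
the self-report stage; all tables land under `results/`.

The same stages are available as a CLI for real event-log CSVs:

```sh
rfidcontacts simulate --out world --seed 1
rfidcontacts validate --observed world/observed.csv --truth world/truth.csv
rfidcontacts sweep --observed world/observed.csv --truth world/truth.csv \
    --strategy interpolate --grid 0:150:15 --out sweep.csv
rfidcontacts associate --durations world/observed_minutes.csv \
    --nominations world/nominations.csv
```

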