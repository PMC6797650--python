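# Methods

This note documents the models, conventions and numerical choices behind
`rfidcontacts`, and what the synthetic-data experiments do and do not
establish about real badge data.

## Time and interval conventions

All internal times are integer seconds from an observation origin;
intervals are half-open `[start, end)`, so `duration = end − start` and
durations are additive. One second is the analysis resolution: badge
hardware reports at sub-second granularity, but every validity
computation here (and in field practice) happens on the dyad-second
grid. Normalization canonicalizes each dyad (lower identifier first),
sorts events, and merges same-dyad events that overlap *or abut* — at
1-s resolution a zero-length gap is indistinguishable from a continuous
signal. Clock times (`HH:MM:SS`) are parsed within a single day and
records that appear to cross midnight are rejected; multi-day
collections must use date-stamped ISO times, which are referenced to
midnight of the earliest date.

## Cleaning strategies

* `min_duration(c)` deletes events with duration strictly less than
  `c` ("shorter than" the cutoff); an event exactly at the cutoff
  survives.
* `interpolate(x)` merges consecutive same-dyad events whose gap is at
  most `x` seconds (inclusive reading of "maximally x apart"). Merging
  is transitive in one start-sorted pass, which matches the per-second
  semantics "fill every zero-run of length ≤ x flanked by ones" and
  makes the operation idempotent and monotone in `x` — both properties
  are tested.
* `triadic_closure(k)` works on the per-second graph: an iteration adds
  every edge B–C for which some A is adjacent to both B and C, with
  synchronous updates (computed from the pre-iteration state), so the
  result is independent of participant order. Per-second clique
  components are the fixpoint, reached in at most ⌈log₂ N⌉ iterations;
  the interval implementation is verified cell-for-cell against a
  triple-loop brute force on random small instances.

The combined recommended default is `interpolate(75)` then
`min_duration(55)`. Sources describing this combination also mention a
50-s deletion in one place; 55 s is taken as the default and any other
value remains configurable. Step order is significant and preserved —
reversing the two steps on short fragmented events deletes everything
first, which the tests demonstrate.

Sweeps evaluate one strategy over a grid (defaults: cutoffs 0–150 s in
5-s steps, closure iterations 0–4) and score each point by accuracy;
the sum sensitivity + specificity is available as an alternative
criterion. Ties break toward the smaller parameter.

## Validity metrics

Observed and truth logs are rasterized over the *same* roster and
window, and every dyad-second is classified as TP/FP/FN/TN. Sensitivity
is TP/(TP+FN), specificity TN/(TN+FP), accuracy (TP+TN)/total — the
standard definitions, which reproduce the published example table's
49.7% / 97.0% / 87.5% at one-decimal rounding. Ratios with empty
denominators are NaN rather than errors; reporting rounds percentages
to one decimal while internal values stay unrounded.

Cohen's κ is computed on dyad-second indicator vectors (the same unit
as the fit framework), κ = (p_o − p_e)/(1 − p_e) with p_e from the
raters' marginal frequencies. Two constant, identical codings give
κ = 1 by convention; constant disagreeing codings give 0. The
implementation is cross-checked against scikit-learn's
`cohen_kappa_score` in the tests. Rater merging splices coder A before
a split time and coder B after it, truncating straddling events, which
equals the raster-level splice.

## Criterion-validity stage

The unit of analysis is the directed dyad (each undirected duration
assigned to both directions) because nominations are directed; an
undirected unit over a pre-symmetrized nomination matrix is available.
Dyad counts are always recomputed from the input roster rather than
taken from any external description. The t test is Student's pooled
two-sample test (integer df); Cohen's d uses the pooled SD and is
positive when nominated dyads interacted longer, while t is reported
for the (not-nominated − nominated) contrast. Zero variance in both
groups raises an error rather than returning an unstable statistic.
The logistic model is fit by maximum likelihood via statsmodels; a
constant-duration predictor is flagged as degenerate and fit
intercept-only; non-convergence (perfect separation) raises an
explicit error. `compare_fits` returns 2·|ℓ_a − ℓ_b| with a
caller-supplied reference df (default 2) and is labelled a descriptive
deviance difference: the compared models use differently processed
predictors and are not nested, so no p-value machinery is attached.
Survey non-responders can be excluded listwise from outcome rows while
duration matrices stay intact.

## Synthetic world generator

**Ground truth.** A per-second Markov chain over conversation-group
partitions: each participant independently reconsiders their position at
`switch_rate` (default 1/120 per second — people re-decide about every
two minutes); a mover goes solo with probability 0.2 or joins a
uniformly chosen other person's group unless that would exceed
`max_group_size` (default 5). Starting from everyone solo, 1200 s of
burn-in precede the recorded window (11 participants, 4602 s ≈ 76.7 min
by default). Group co-members interact pairwise, so the per-second truth
graph is a union of cliques and triadic closure fixes truth — a key
differential against flickered observations, and a tested invariant. The
defaults were chosen once to put long-run truth prevalence near 20% of
dyad-seconds, the figure reported for small get-together settings; a
discrete-time chain (rather than an event-driven continuous-time one)
was chosen because 1 s is already the analysis resolution. The empirical
prevalence is checked against an independently coded simulation of the
same chain.

**Sensor.** Each dyad's truth signal passes through an alternating
on/off renewal gate with geometric run lengths (defaults 50 s on, 20 s
off, echoing the canonical description of one interaction recorded as
several ~50-s fragments); the gate starts in its stationary state, and
geometric memorylessness makes the long-run detected fraction
on/(on+off) — verified against that closed form. When an on-run starts
inside a group of size k, it is accepted with probability
`group_decay^(k−2)` (default 0.9), encoding narrow-angle missingness
that grows with group size. False positives occur at a small per-second
rate (default 2·10⁻⁵) between members of distinct co-existing groups.
Finally, events shorter than 10 s are extended to 10 s (the firmware's
minimum reported duration), which deliberately breaks the
observed ⊆ truth inclusion that holds before rounding.

**Raters and self-reports.** Raters miss whole events (default 5%) and
jitter boundaries with rounded N(0, 3 s) noise. Directed nominations
are independent Bernoulli draws with probability
`expit(−2.16 + 0.02 · minutes)` — published logistic estimates reused
as generating values, driven by *true* aggregated minutes (people
report what happened; the sensor measures it with error). For
weekend-scale association analyses a direct matrix generator
(`simulate_minutes_matrix`) draws per-dyad minutes as zero with
probability 0.0984 and lognormal (mean 15.5 min, log-SD 1.5, hence
SD ≈ 45 min) otherwise, matching reported field descriptives in mean,
tail weight and silent-dyad share; it is a labelled synthetic stand-in,
not a second-by-second simulation.

**Seeding.** All component seeds derive from one master seed by stable
hashing of (seed, component name), so adding components never perturbs
existing streams; identical seeds give bit-identical worlds.

## What the synthetic experiments show — and a known limitation

Passing tests establish that the pipeline's algebra is exact (oracle
equivalence with per-second brute force), that its statistical stages
recover known generating parameters (logistic coefficients within 3 SE;
permuted predictors give McFadden R² ≈ 0), and that the qualitative
cleaning findings reproduce: interpolation beats the unprocessed
baseline with a rise-then-fall accuracy curve, while minimal-duration
deletion never helps. They do not calibrate the generator to any real
dataset: flicker-gap distributions in the field are unknown beyond
qualitative descriptions, real conversation dynamics are not Markovian,
and real false positives cluster spatially.

One expectation encoded in the acceptance suite fails by design of the
model rather than by implementation error: the accuracy-optimal
interpolation cutoff does *not* track the mean flicker gap. With
geometric gaps of mean 20 s, filling gaps up to the mean leaves the
long half of the gap mass unrepaired; the marginal benefit of a larger
cutoff decays like (1 − 1/mean)^g while the false-positive cost stays
small until the cutoff reaches typical true inter-contact gaps
(minutes). The optimum therefore sits near the ~95th percentile of the
gap distribution (≈ 60–90 s for a 20-s mean) — consistent with field
reports where a 75-s optimum accompanies ~10-s typical interruptions.
The corresponding mean-tracking assertion is kept in the acceptance
suite and documented as failing, rather than silently weakened.

Within-test problem sizes (windows of 10–80 s for oracle checks, ten
4602-s worlds for sweep recovery, one 56-person matrix for the
logistic stage) were chosen as the smallest scales at which the checked
effects are stable across seeds.

## Triadic closure on synthetic vs. field data

On these synthetic worlds one closure iteration *improves* accuracy:
group-size-dependent missingness is exactly the error closure repairs,
and the truth is clique-structured by construction. Field studies have
found closure unhelpful, suggesting real group interactions are either
rarer or better detected than this generator's decay parameter implies.
The driver `analysis/02_construct_validity.py` reports whichever
strategies help on the simulated world it actually ran.
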