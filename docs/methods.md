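# Methods

## Session protocols

A session is a timed sequence of stimulus edges over real-valued seconds
with session start at 0; every interval in the package is half-open
`[on, off)`. All sessions open with a 180 s stimulus-free baseline and a
30 s, 75 dB white-noise CS; reinforced trials co-terminate with a 2 s,
0.6 mA footshock (US onset = CS offset − 2 s). The four built-in designs:

| kind | CS count | reinforced | inter-trial interval (s) | post period (s) |
|---|---|---|---|---|
| FRF | 3 | all 3 | 60–90 | 120 |
| PRF | 6 | trials 1, 2, 5 | 15–60 | 120 |
| CS_ONLY | 6 | none | 15–60 | 120 |
| RETRIEVAL | 6 | none | 20–60 | 20 |

PRF and FRF therefore deliver the same number of pairings (3) while
differing in reinforcement rate — the design equivalence the validator
checks.

Inter-trial intervals are drawn i.i.d. uniform-continuous on the stated
range, measured CS offset → next CS onset; the source procedure states
only a variable interval within the range, and a uniform draw is the
simplest seedable choice respecting it. Whether the PRF 15–60 s interval
applies uniformly between all six stimuli or only around the interleaved
unreinforced trials is not specified; it is applied uniformly between
consecutive trials here. US events are always emitted even when spikes
are not simulated during conditioning: the timeline is the single source
of truth for alignment. Coincident events sort in a fixed order
(CS_ON, US_ON, US_OFF, CS_OFF) so serialized timelines are byte-stable.

## Freezing scoring

Freezing is a set of sorted, disjoint, half-open bouts; everything else
is movement. Percentages are computed per epoch (pre-CS baseline, each
CS, pooled CS) by sampling the state every `sample_interval` (default
5 s, the manual-scoring cadence) and taking
`100 × n_frozen / n_observations` with
`n_observations = floor(epoch_dur / sample_interval)`.

Sampling convention: observations are made at the *end* of each
interval, `t = epoch_start + k·sample_interval`, reading the left-limit
state (a bout `(s, e]` contains `t`). End-of-interval sampling avoids
counting the epoch-start instant twice across adjacent epochs; the
left-limit read means a bout running exactly up to a tick still counts
as frozen there, which is what makes the scoring exact on closed-form
cases (a bout covering an entire 30 s CS scores 6/6 = 100%; a bout over
[0, 90) of a 180 s baseline scores 18/36 = 50%) and makes scores
invariant to splitting a bout into touching pieces. An epoch shorter
than one interval has zero observations and its percentage is reported
as missing, never as 0.

Freeze onsets are bout starts and cessations bout ends. Events with less
than `pre_window` (default 2 s, the span of the shifted baseline) of
session before them are excluded and logged, as are events closer than
`min_separation` (default 0 — the source imposes none) to the previous
retained event of the same type; exclusions never shift remaining event
times. Freeze events inside CS periods are retained by default. No
minimum bout duration is imposed on event-aligned analysis.

## Peri-event classification

For each unit and event type, spikes are counted in contiguous 100 ms
half-open bins spanning `[−(baseline_offset + 1 s), +0.5 s)` around each
event; a spike exactly on an interior edge belongs to the later bin, and
a spike at the event time itself to response bin 0. Events without full
window coverage inside the session are dropped per event and logged.
Counts are averaged **across events first** (one trial-averaged profile
per unit, matching the one-z-trace-per-unit convention of heat-map
displays; per-event z-scoring is out of scope), then z-scored:
μ and σ are the mean and SD of the 10 baseline-bin averages and
`z_b = (x̄_b − μ)/σ`. σ uses the n−1 denominator by default
(`sd_ddof` is switchable; the convention is not specified upstream).

The responsiveness rule: a unit is responsive to an alignment when at
least `min_supra_bins = 2` response-window bins of the same sign
strictly exceed the threshold, `z > 1.96` (excited) or `z < −1.96`
(inhibited). "Same sign" is read literally: positive- and
negative-exceeding bins are counted separately and either count alone
can qualify; mixed-direction bins never jointly qualify. If both
directions qualify independently, the reported direction is that of the
largest-|z| bin (earliest on a tie). CS alignment uses
`baseline_offset = 0` (baseline −1…0 s); freeze onset/cessation use
`baseline_offset = 1` (baseline −2…−1 s) so the transition itself stays
out of the baseline. The bins in −1…0 s before a freeze event are
computed but belong to neither baseline nor response window.

Degenerate profiles (σ = 0, e.g. a silent or perfectly regular
baseline) are excluded from that alignment's classification and logged
rather than assigned infinite z — empty baselines must not produce
spurious certainty. Exclusion is per alignment, not per unit.

The peak response is the largest-|z| response bin (earliest on ties),
reported with its latency in seconds from the event. Reported peak
latencies are necessarily below 0.5 s; a source description of peaks at
"200–300 s" is dimensionally inconsistent with the 500 ms window and is
almost certainly milliseconds, but the package reports seconds and takes
no position on intent.

Because σ is estimated from only 10 bins of trial-averaged Poisson
counts, the rule's null rate is well above the nominal two-sided 5%:
homogeneous 4 Hz units with 6 CS presentations are classified responsive
roughly 7–8% of the time. This is a property of the rule itself — the
test suite pins it against an independently coded brute-force
Monte-Carlo oracle rather than a normal approximation.

## Synthetic data

The generator produces the statistical structure the analysis assumes,
not a biophysical simulation. Spike trains are inhomogeneous Poisson
processes with piecewise-constant rate
`λ(t) = baseline_rate × ∏ active multipliers`, realized by thinning
against λ_max (exact for piecewise-constant rates and simple to audit).
Event-locked effects are boxcar multipliers with latency 0 and duration
0.5 s by default, matching the fixed response window and keeping
detection power analytically approachable. Baseline rates are drawn
log-normal (default arithmetic mean 3 Hz, σ_log 0.4) — strictly
positive and right-skewed like cortical rate distributions, and spanning
the 1–5 Hz range typical of prefrontal recordings. No quantitative
effect sizes are available upstream for unit modulation; the default 3×
multiplier is chosen for testability (detection ≈ 85–95% at 3–4 Hz
baselines) and is a parameter, not an estimate. Freeze-onset-modulated
units default to a multiplier < 1, emulating the observed firing
decrease at freezing onset; the direction is a parameter.

Behavior is a two-state (move/freeze) continuous-time Markov chain whose
transition rates switch when the CS is on (defaults: move→freeze
0.30 s⁻¹ and freeze→move 0.05 s⁻¹ during CS; 0.02 and 0.25 s⁻¹
outside), giving low spontaneous freezing (~5–10%) and strong CS-evoked
freezing (~80%+), with bouts a few seconds long. Within each
constant-rate span, holding times are exponential; at CS boundaries the
clock is re-drawn, which is valid by memorylessness. Segments shorter
than `min_bout` (default 1 s) are absorbed into the surrounding state,
shortest first, so very brief flickers do not generate freeze events.

Cohorts assign exactly `floor(fraction × n_units)` units per group to
each modulation (floor rule; CS-modulated from the front of the roster,
freeze-modulated from the back) and retain ground-truth labels for
recovery tests. All randomness derives from one integer seed via
`SeedSequence([seed, …path])` keying — collapsing spawned children to a
single truncated word was found to produce measurably correlated
streams and is deliberately avoided.

What the generator does **not** emulate: refractory periods, spike
waveforms and sorting artifacts, rate drift and non-Poisson variability,
behavior–spike latency structure beyond the boxcar, or chemogenetic
dose–response. Passing recovery tests therefore demonstrates the
analysis code is correct under the stated model, not that the biological
effects are of any particular size.

## Group statistics

Fisher's exact test is computed from first principles: the full
hypergeometric support of tables with the observed margins is
enumerated with log-space (`gammaln`) probabilities, and the two-sided
p is the sum over tables whose probability does not exceed the observed
table's — the probability-ordering convention of mainstream
implementations, stated explicitly because two-sided exact p-values are
convention-dependent. A relative tolerance of 1e−12 guards
floating-point ties; when the whole support qualifies the p-value is
exactly 1. The paired t-test is the closed form
`t = mean(d)/(sd(d)/√n)`, df = n−1, with the two-sided p from the t
distribution; zero-variance differences are flagged degenerate with no
p. No multiple-testing correction is applied across pairwise group
comparisons (raw p-values are reported); apply one downstream if
desired.

The pipeline's default paired comparison takes, per responsive unit,
the mean z over the 10 baseline bins versus the mean z over the 5
response bins. Note the baseline mean z is identically 0 under
within-profile normalization, so this default reduces to a one-sample
test on response-window z; whether upstream analyses paired mean z or
mean raw rate is not stated, and `paired_t` accepts any pairing.

## Numerical choices and problem sizes

Bins and bouts are half-open and left-closed throughout; event-time
ties in timelines sort in a fixed label order; CSV floats are written
with shortest round-trip precision and read back exactly, making
end-to-end runs byte-identical for a given config and seed. Stage seeds
derive from the master seed as `SeedSequence([seed, stage_index])`.

Verification runs use desk-scale sizes chosen to make Monte-Carlo
bands tight while keeping the suite quick: 500 replicates for Poisson
moment checks, 10,000 simulated units against a 100,000-unit null
oracle for rule calibration, 1,000 units per effect level for power
monotonicity, 20 replicate two-group cohorts (50 units/group) for
ground-truth recovery, and an exhaustive sweep of all 2×2 tables with
row margins ≤ 20 for the exact test.
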