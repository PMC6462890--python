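# Methods

## The stratified-scale screening model

A screening protocol presents pure tones at 500, 1000, 2000 and 4000 Hz.
The scale-based method organizes stimulus levels into a ladder of scales:

    level(f, s) = 5 dB × (s − 1) + offset(f),   offset(500 Hz) = 5 dB,
                                                offset(1/2/4 kHz) = 0 dB

so adjacent scales differ by exactly 5 dB at every frequency, S₁ is
0 dB HL at 1/2/4 kHz and 5 dB at 500 Hz, and the screening ladder
(max_scale = 10) tops out at 45/50 dB. The same formula extends to a
full-range ladder (max_scale = 20, up to 95/100 dB) as a configuration
option. The 500 Hz offset reflects the conventional practice of screening
the lowest frequency 5 dB higher, where ambient noise intrudes most.

The **adaptive engine** starts at the mid-ladder scale S₅ (the boundary of
normal hearing: 25 dB at 500 Hz, 20 dB elsewhere) and presents the four
tones in the fixed order 1000, 2000, 4000, 500 Hz. If every tone at the
current scale is heard it descends one scale; at the first scale with a
miss it stops and returns the last fully heard scale. If S₅ itself has a
miss it ascends one scale at a time and returns the first fully heard
scale, or the no-response outcome (NR) if S₁₀ is not fully heard. Scales
S₁–S₅ classify as *pass*; S₆+ and NR as *fail*.

For a deterministic listener this search returns exactly the minimum
audible scale — the smallest s with level(f, s) ≥ threshold(f) at every f
— because "all four tones heard at s" is monotone in s. The package ships
an exhaustive oracle (`minimum_audible_scale_oracle`) computing that
minimum directly; a property test checks engine/oracle equivalence over
10,000 random threshold vectors in [−5, 60] dB.

### Interpretation choices in the search

- *Descent termination.* The descent narrative ("decrease until no
  response") is implemented as "descend until a scale that is not fully
  heard, return the last fully heard scale", which is the only reading
  consistent with the minimum-audible-scale definition (all four tones
  heard).
- *Early abort.* A scale is abandoned at its first missed tone by default,
  since later tones cannot change that scale's outcome; a strict mode
  presents all four for log fidelity (`abort_scale_on_first_miss=False`).
- *Re-presentation during ascent.* Every tone is re-presented at each new
  scale, even if heard at a lower level, keeping the all-four-at-one-scale
  semantics literal.
- *Boundary convention.* A deterministic listener hears a tone iff the
  presented level ≥ its threshold (closed at equality). This makes scale
  assignment a well-defined step function and is mirrored by the oracle.
- `max_scale` lives on the scale table only (not duplicated in the engine
  config) so there is a single source of truth; the engine validates its
  start scale against the table it is given.

### Fixed-level protocols

Guideline presets are fixed-level screens: every tone is presented at one
level and the ear passes if some procedure hears them all; after 2
consecutive procedures without that, the ear fails. Presets: AAP (20 dB at
all four frequencies) and two ASHA variants — as recommended (20 dB at
1/2/4 kHz) and as administered in the validation study (15 dB at all
four). Both ASHA variants are shipped because the two published
descriptions disagree; neither is silently "the" ASHA.

## Simulated listeners

Responses come from a psychometric function

    P(heard) = γ + (1 − γ − λ) · F((L − θ)/σ)

with logistic F, guess rate γ, lapse rate λ, threshold θ and spread σ
(`slope_db`); σ = 0 degenerates to the step listener. The logistic family
is a configuration default — nothing in the screening logic depends on the
sigmoid shape. The rng is consumed only when P is strictly between 0 and
1, so deterministic listeners draw no randomness.

Listeners deliberately carry two level domains: **app-domain thresholds**
(what the screening device produces at the eardrum) drive responses, while
the **booth PTA** (clinical reference audiometry, different transducer and
environment) is the label against which sensitivity and specificity are
scored. Impairment is booth PTA strictly greater than 25 dB; PTA = 25 is
normal.

### The study cohort fixture

The validation cohort of 170 ears is reconstructed from its published
per-scale group summary: counts 16/58/59/27/8 at S₁–S₅ with mean booth
PTAs 5/7/9/11/12 dB, one ear at S₇ (PTA 31 dB) and one at S₈ (36 dB).
Each fixture listener gets *flat* app-domain thresholds equal to its
group's 1000 Hz scale level — which pins its minimum audible scale to the
group's scale exactly, the 500 Hz offset only adding headroom — and its
group's mean booth PTA as reference label. Flat thresholds are used
because the summary contains no per-frequency information. Separate
app-domain and booth values are required to reproduce simultaneously the
group summary (e.g. the S₂ group's booth mean of 7 dB, not the app's
5 dB scale level) and the perfect 2×2 table.

What the fixture does **not** emulate: per-frequency threshold structure,
response variability (listeners are deterministic), ambient-noise
intrusions, and attention/instruction effects in children. Passing the
fixture-based checks therefore shows the machinery is faithful to the
published summary, not that the screen would achieve those operating
characteristics in the field. In particular, the fixed-level protocols'
published sub-100 % sensitivities arise from per-ear per-frequency booth
thresholds that were never printed, so they are not reproducible from the
summary; the protocol-comparison machinery is instead validated with
constructed discriminating cohorts (an impaired ear with thresholds
between two protocols' levels is caught by the stricter one only).
`sample_cohort` provides randomized cohorts (two-component PTA mixture,
per-frequency jitter, configurable prevalence) for such experiments; its
defaults (normal PTA ≈ N(8, 5) truncated at ≤25 dB, impaired ≈ N(40, 10)
truncated at >25 dB, 3 dB per-frequency jitter) are plausible for a
school-age population dominated by normal hearing and mild-to-moderate
losses.

## Calibration staircases

The calibration procedure is modeled in two stages: a coarse ascending
pre-scan (5 dB steps; stands in for the conventional-audiometer
determination of the lowest response level, whose exact procedure is not
published) followed by a fine 2-down-1-up staircase with 1 dB steps
starting 10 dB below the pre-scan level and terminating after 3 reversals
(all configurable; a `max_trials` cap flags non-converged runs). "Two
down" is evaluated on consecutive heard responses since the last level
change. The threshold estimate is the mean of the reversal levels — the
estimator is not published, and mean-of-reversals is the standard
transformed up-down reading. The 2-down-1-up rule converges to the level
where P(heard) = 2^(−1/2) ≈ 70.7 %; a Monte-Carlo test (200 seeded runs,
8 reversals, logistic spread 2 dB) checks the mean estimate lands within
1.5 dB of that point, and deterministic responders are recovered within
1 dB.

## Stimulus synthesis and the level chain

Levels convert as SPL = HL + RETSPL(f), then to a digital amplitude
fraction 10^((SPL − max_output_SPL(f))/20), where max_output_SPL is the
SPL at digital full scale with the user volume at 100 % (the assumed
volume policy). A 5 dB HL step therefore scales amplitude by exactly
10^(1/4). Requests above the device maximum raise an error naming the
missing headroom. The shipped profile is a clearly labelled synthetic
placeholder — real use requires user-measured RETSPLs and maximum output
levels per device/earphone pairing, supplied as JSON.

Tones are 1.5 s sinusoids, amplitude-modulated at 100 % depth so the
envelope pinches to silence once per modulation cycle (the attention-
holding "warble"). The modulation *rate* is not specified anywhere, so
20 Hz is the documented default assumption; 20 ms cosine on/off ramps
(also an assumption, configurable to 0) limit spectral splatter. Silent
intervals between tones are uniform on [2, 3] s, seeded. WAV export is
16-bit PCM; out-of-range samples raise rather than clip, and write/read
round-trips within one quantization step.

## Evaluation conventions

The 2×2 table counts screen *fail* as test-positive against the
impairment reference. Ratios with empty denominators are NaN, never 0;
single-ear group SDs are NaN. The scale-vs-PTA association is the Pearson
product-moment correlation between scale index and booth PTA; NR ears are
excluded by default (their count reported separately) or ranked
max_scale + 1 on request — the source protocol is silent on this.
Rank-based group testing (Kruskal–Wallis) and box-plot regression of the
original analysis are out of scope; group summaries and the correlation
are the in-scope substitutes. Protocol comparisons run every protocol on
the same cohort with per-listener rng streams derived from one seed, so
stochastic listeners see identical randomness across protocols.

CLI output prints percentages to one decimal; stored values are full
precision.

## Problem sizes and numerics

All simulation-based checks run at desk scale: the cohort is 170 ears
(fully determined by its group counts), engine/oracle equivalence uses
10,000 random listeners, staircase Monte-Carlo 200 runs, response-rate
checks 10,000 Bernoulli trials (binomial SE ≈ 0.005 at p ≈ 0.05, inside
the ±0.01 assertion), and the ISI uniformity check is a Kolmogorov–Smirnov
test at a 1 % level on 2,000 draws. Floating-point equalities are asserted
exactly only where the arithmetic is exact (5 dB grid levels, counts);
amplitude ratios use a 1e−12 relative tolerance.

## Known limitations

- Fixture listeners are deterministic and frequency-flat; real children
  produce response variability the test–retest machinery can model
  (steep-slope stochastic listeners) but the fixture does not.
- The synthetic calibration profile is illustrative only; no values in
  this package describe any real earphone.
- The engine consumes one boolean per presentation; response windows,
  reaction times and false starts are simulation-level concerns outside
  its contract.
- Ambient noise, transducer placement, and device-to-device output spread
  are not modeled.
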