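# hearscreen

A toolkit for smartphone-style pure-tone hearing screening built around a
**stratified hearing-scale method**. School hearing screens conventionally
present a handful of tones at one fixed level and report only *pass* or
*fail*. The scale-based method instead searches a ladder of stimulus levels
— scales S₁, S₂, … spaced 5 dB apart, with 500 Hz offset +5 dB relative to
1000/2000/4000 Hz — for the **minimum audible scale**: the lowest scale at
which all four test tones are heard. That single index both classifies the
ear (S₁–S₅ ⇒ pass, S₆+ or no-response ⇒ fail) and grades its hearing
status for follow-up.

The package is aimed at audiology/psychoacoustics researchers and
screening-program developers who want to prototype, simulate, and evaluate
such protocols without hardware or human subjects. It provides:

- **`protocols`** — the scale table (level(f, s) = 5·(s−1) + offset(f)),
  fixed-level guideline presets (AAP 20 dB ×4 frequencies; ASHA both as
  recommended, 20 dB ×3, and as commonly administered, 15 dB ×4), and the
  pass/fail rules, including the fail-after-2-procedures fixed-level screen.
- **`hst_engine`** — the adaptive state machine: start at S₅, present
  1000/2000/4000/500 Hz in fixed order, descend while every tone is heard,
  ascend on a miss, declare NR past the top of the ladder; plus an
  exhaustive minimum-audible-scale oracle, test–retest agreement, and
  session-duration estimates.
- **`listener_sim`** — simulated listeners with a logistic psychometric
  function (guess/lapse rates, step-function limit) and cohort builders,
  including a 170-ear fixture reconstructing a published validation cohort
  from its per-scale group counts and booth pure-tone averages (PTA).
- **`staircase`** — calibration staircases: ascending pre-scan, then a
  2-down-1-up track (1 dB steps, mean-of-reversals estimate) that converges
  to the ≈70.7 % point of the psychometric function.
- **`stimulus`** — the calibrated level chain dB HL → dB SPL → digital
  amplitude via per-frequency RETSPLs and maximum-output SPLs, 100 %-depth
  amplitude-modulated tone synthesis with cosine ramps, randomized 2–3 s
  silent intervals, and 16-bit WAV export.
- **`evaluation`** — 2×2 contingency tables against the impairment
  reference (booth PTA > 25 dB), sensitivity / specificity / PPV / NPV and
  false rates, per-scale group summaries, scale-vs-PTA correlation, and
  side-by-side protocol comparison with matched seeds.

## Worked example

Screen one simulated ear whose true thresholds are 18/10/5 dB HL at
1/2/4 kHz and 12 dB at 500 Hz:

```sh
$ hearscreen screen --protocol HST --thresholds "1000:18,2000:10,4000:5,500:12"
assigned scale: S_5
classification: pass
presentations: 5
```

S₅ presents 20 dB at 1/2/4 kHz and 25 dB at 500 Hz — all above this
listener's thresholds, so S₅ is fully heard; at S₄ the 1000 Hz tone
(15 dB < 18 dB) is missed, so S₅ is the minimum audible scale and the ear
passes (S₅ ≤ the S₅ cutoff). Five presentations: four at S₅, one at S₄
(the scale is abandoned at its first miss).

Rebuild the 170-ear validation cohort and screen it:

```sh
$ hearscreen cohort --fixture study
170 ears screened with HST: 168 pass, 2 fail
 scale  n  mean_pta_db  sd_pta_db
     1 16          5.0        0.0
     2 58          7.0        0.0
     3 59          9.0        0.0
     4 27         11.0        0.0
     5  8         12.0        0.0
     7  1         31.0        NaN
     8  1         36.0        NaN

$ hearscreen evaluate --fixture study --protocol HST --protocol AAP
HST: sensitivity 100.0%, specificity 100.0%, PPV 100.0%, NPV 100.0%, false-positive 0.0%, false-negative 0.0%
AAP: sensitivity 100.0%, specificity 100.0%, PPV 100.0%, NPV 100.0%, false-positive 0.0%, false-negative 0.0%
```

The two fail ears are exactly the two with booth PTA above 25 dB (31 and
36 dB), so both sensitivity and specificity against the impairment
reference are 100 %. The per-scale rows reproduce the cohort's published
group counts and mean booth PTAs by construction; the SD column is 0
within groups (each fixture listener carries its group's mean PTA) and
undefined (NaN) for single-ear groups. Note the fixture's deterministic
listeners make AAP perfect here too — separating the protocols requires
per-frequency threshold structure the published group summary does not
contain (see `docs/methods.md`).

Synthesize a calibrated test tone:

```sh
$ hearscreen stimuli --frequency 1000 --level-hl 20 --out tone.wav
1000 Hz at 20 dB HL (amplitude 1.884e-04 full scale) -> tone.wav
```

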