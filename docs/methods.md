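# Methods

## Background and scope

The brown planthopper (BPH, *Nilaparvata lugens*) communicates during
courtship through substrate-borne vibrations transmitted along rice stems.
Males locate females by exchanging vibrational courtship calls, which makes
the recognition step a target for physical pest control: broadcasting an
artificial signal that masks or confuses the female call suppresses male
replies and localization ("courtship disruption"). `bphvib` implements a
desk-scale version of the screening pipeline for such disruptive signals:
parametric synthesis of the natural signal classes, synthesis of candidate
disruptors, spectral measurement, and simulation plus nonparametric
analysis of playback trials. No hardware (transducers, amplifiers, plants,
insects) is modelled; the synthetic-data generators stand in for recordings
and live trials.

## Signal model

All natural BPH signals are modelled as a sine carrier at the individual's
main vibration frequency (MVF) amplitude-modulated by a periodic pulse
envelope:

    x(t) = A · e(t) · sin(2π f_mvf t)

where `e(t)` is a symmetric triangular pulse repeating at the pulse rate
(PR), occupying a fraction `duty` of each pulse period (default 0.8) with a
zero floor between pulses. The triangular envelope is the same construction
used for the artificial continuous pulse signal (CPS), reused for the
natural classes: published oscillograms show pulse shape only
qualitatively, and a shared analytic envelope keeps generation and
ground-truth boundaries exact.

Per-individual parameters are drawn from the reported population
statistics:

| class                | MVF (Hz)   | PR (Hz)  |
|----------------------|------------|----------|
| female courtship     | 236 ± 43   | 23 ± 2   |
| male courtship (b)   | 255 ± 24   | 82 ± 5*  |
| male competition (a) | 281 ± 46   | 82 ± 5*  |

Draws are normal, truncated at ±3 SD (symmetric, so means are unaffected),
and re-drawn until MVF > 2 × PR so the carrier oscillates within each
pulse. *The male train pulse rate is reported only as a single abstract
figure (82 Hz) with no spread; the 5 Hz SD is a nominal choice and both are
configurable.

Multi-part male calls are assembled as: male courtship = 3–10 irregular
pulses (part a), a 1 s continuous train (part b), 0–5 wide pulses (part c);
male competition = a 1 s train (part a) then 2–4 short pulses (part b).
Quantities the field descriptions leave qualitative are fixed as: irregular
pulses 15 ms long with amplitudes uniform in [0.3, 1.0] of the train
amplitude and gaps uniform in [20, 80] ms; wide pulses 3 × the train pulse
width, short pulses 0.5 ×, amplitudes uniform in [0.5, 1.0]; 100 ms gaps
between parts; 50 ms lead-in/tail silence. Ground-truth part boundaries are
0-based half-open `[start, end)` sample intervals spanning each part's
pulses.

Background noise is additive white Gaussian at 20 dB SNR by default
(recording-noise statistics are not reported; 20 dB makes the envelope
floor clearly separable from pulses while still exercising the estimators
under noise). Default sample rate is 8 kHz — all energy of interest is
below 500 Hz — at 2 s per female signal (≥ 40 pulse periods for envelope
spectra).

## Disruptive signals

Seven screened disruptors of three types: pure tones (PT) at 150/225/300 Hz;
CPS at the same carriers with a constant 22 Hz triangular pulse envelope;
and white Gaussian noise (WGN) at 0 dBW, mapped to unit sample variance in
the dimensionless amplitude convention (1 W into unit impedance — the
electrical reference of the original playback chain is unspecified).
Playback mixing scales the disruptor to the courtship signal's RMS before
summation ("uniform intensity" is not defined by the protocol description;
equal RMS is this package's reading, with equal-peak behind a flag), then
rescales to peak 1 if the sum would clip. At equal RMS the CPS spectral
line at the carrier is necessarily weaker than the PT's — pulse modulation
spreads energy into sidebands — which is the standing explanation for the
PT's stronger disruption; the test suite asserts this ordering.

## Feature extraction

* **Band-pass front end** — the analog sixth-order Chebyshev band-pass is
  emulated as a digital Chebyshev type-I design (order-3 low-pass
  prototype → order-6 band-pass, 0.5 dB ripple, default band 100–500 Hz,
  chosen to cover all reported MVFs plus population spread; the analog
  corner frequencies are not published). It is applied forward-backward so
  detected pulse boundaries are not delayed — a deliberate deviation from
  the causal analog original, at the cost of squaring the magnitude
  response (≤ 1 dB passband loss).
* **MVF** — magnitude spectrum of the Hann-windowed signal, zero-padded to
  the next power of two ≥ 8 × the signal length; the in-band maximum bin
  (lowest bin on exact ties) is refined by quadratic interpolation over its
  three-bin neighbourhood. An in-band peak more than 100 dB below the
  global spectral peak is treated as window leakage and reported as "no
  MVF detectable".
* **Pulse rate** — amplitude envelope (analytic-signal magnitude by
  default; rectify + 100 Hz low-pass selectable), mean-subtracted, then the
  dominant envelope-spectrum line within the search band (5–60 Hz for
  female-type trains and CPS; 40–120 Hz for the faster male trains).
  Input with envelope coefficient of variation below 0.05, or with no
  envelope line at least twice the median in-band magnitude, returns
  "none" (unmodulated).
* **Segmentation** — the envelope is smoothed by a 3 ms moving average and
  thresholded at 20 % of its 95th percentile; above-threshold runs closer
  than 10 ms are merged (so a dense train coalesces into one run) and runs
  shorter than 2 ms are dropped. The longest run is taken as the
  continuous-train part; preceding runs form the irregular-pulse part and
  trailing runs the wide/short-pulse part, with empty intervals for absent
  parts. This positional rule replaces a width/interval-heuristic
  classification considered during design: with one train per call —
  which the generative model guarantees and the field descriptions imply —
  position is sufficient and far more robust. Thresholds are heuristics,
  documented as such; none are load-bearing for the headline numbers,
  which measure the train part only.

## Playback-trial model

A subject qualifies by the active-reply-period rule (two consecutive
replies within 10 s; implemented as a run scan, validated against
exhaustive enumeration). Each simulated trial is an independent subject
(subjects are discarded after testing, so there is no repeated-measures
structure): reply ~ Bernoulli(p) with p the condition's published reply
rate, and, for repliers, delay ~ normal truncated to (0, 45 s]. The
published delay mean ± SD describe the *observed* delays, which are
necessarily positive, so the parent normal is moment-matched (via root
finding on the truncated-normal moments) rather than used directly as
loc/scale; otherwise the floor at zero would inflate simulated means by
over a second for the high-variance conditions. A lognormal delay family
was considered and left out: with only mean ± SD published, the truncated
normal is the weaker assumption.

The screening table itself is carried as data (counts, printed rates,
delay moments). One published row is internally inconsistent — 17 replies
of 42 tests is 40.5 %, printed as 33.3 % — and `validate_printed_rates()`
flags it; aggregation always recomputes rates from counts.

## Statistics

Kruskal–Wallis H is implemented from the rank-sum formula on midranks with
the tie correction `1 − Σ(t³−t)/(N³−N)`; p from the chi-square upper tail,
df = k − 1. Dunn's pairwise z uses pooled midranks with the same tie term,
two-sided normal p, and optional Bonferroni/Holm adjustment (default: no
adjustment, matching how the published pairwise p-values are reported).
Both are cross-checked in the tests against independent oracles: a literal
sorted-position implementation of each formula, `scipy.stats.kruskal`, and
a full-enumeration exact permutation distribution (all 756 756 assignments
at 5/5/5). The chi-square approximation agrees with the exact permutation
p to within 0.01 in the decision-relevant regime (exact p < 0.2); in the
middle of the distribution (p ≈ 0.4–0.6) it can deviate by ~0.03 at these
sample sizes, so the agreement check is scoped to the regime where the
test is used. The published omnibus result on live-insect delays
(H = 19.550, df = 7, p = 0.007) cannot be recomputed — the raw delays are
not published — and is not asserted anywhere.

## What the synthetic data do and do not show

The generators reproduce the *parametric* structure of the signals
(population moments, part structure, pulse counts) and of the trials
(reply rates, delay moments, window truncation). They do not emulate
plant-substrate filtering, overlapping callers, amplitude decay with
distance, non-stationary noise, or within-subject correlation. Passing
round-trip tests therefore demonstrates internal consistency of
generation + estimation at realistic parameter values — not field
performance of the estimators on recorded signals.

## Problem sizes

Corpus-level checks use 2 000 signals per class (population means then
recovered within 3 standard errors, e.g. ±2.9 Hz for the female MVF);
simulator fidelity uses 10 000 trials per condition; structural invariants
1 000 seeded calls per class; segmentation boundary recovery 200 calls at a
50 ms tolerance. All randomness flows through explicit
`numpy.random.Generator` seeds; every generator is bit-reproducible under
a fixed seed.

## Known limitations

* Envelope shape, irregular-pulse statistics and part gaps are modelling
  choices constrained only by qualitative descriptions; estimators tuned
  on them (thresholds above) may need re-tuning for recorded data.
* The Hilbert envelope degrades when the carrier is below ~3 × the pulse
  rate; the generators enforce MVF > 2 × PR, and male-train pulse-rate
  estimates (ratio ≈ 3) are rougher than female ones (ratio ≈ 10).
* The equal-RMS mixing convention and the 0 dBW → unit-variance mapping
  are package conventions for unspecified physical calibrations.
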