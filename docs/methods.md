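# Methods

## The categorization model

The model implements the hypothesis that oscillatory phase separates
linguistic representations by event probability.  It has three layers: an
input layer of word nodes (the four study words plus an "empty" node
carrying the rhythmic entrainment stimulus), a phoneme layer (/x/, /d/,
/a/, /ɑ/ plus empty), and a word layer.  At every integration step the
activation of a node is

    A[l,T] = C[l-1→l] · A[l-1,T] + postThresAct(Ta) + osc(T).

- `C` is binary connectivity: input→phoneme has a 1 wherever the phoneme
  belongs to the input word (the empty word connects to the empty
  phoneme); input→word is the identity.  In the hierarchical variant the
  word layer is instead driven by the phoneme layer (entry 1 iff the
  phoneme belongs to the word), scaled by 0.5 so a word's drive is the
  mean of its two phonemes.
- `osc(T) = A·cos(2πfT/1000 + φ0)` is a global excitability oscillation,
  6.25 Hz by default.
- `postThresAct(Ta)` depends on the time since the node last reached its
  threshold: −3B (an excitatory burst) for 0 ≤ Ta < 20 ms, +3B (strong
  self-inhibition) for 20 ≤ Ta ≤ 100 ms, and B for Ta > 100 ms and for
  nodes that were never active.  B < 0 is the base inhibition.  A node in
  its burst/inhibition cycle cannot re-trigger; afterwards it may cross
  again.  The 20/100 ms window bounds are configurable; the lower burst
  edge is inclusive, the inhibition window is closed at both ends.

Sensitivity to the statistics of the language: units whose trait (initial
consonant, vowel, or whole word) has high corpus frequency — /d/, /ɑ/,
/dɑt/, /xat/ — get threshold `1 − r` with reduction `r ∈ [0, 0.5]`; all
others, and the empty nodes, keep threshold 1.  The decision between the
two interpretations of a morphed stimulus is the candidate node that
becomes active first after probe onset.

### Tie-breaking at simultaneous crossings

With a 1 ms step two candidates can reach threshold at the same step.
Ties are resolved toward the node with the larger *suprathreshold*
activation (activation minus that node's own threshold): between two
nodes crossing within the same step, the larger-margin node is the one
that reached its own threshold first in continuous time.  Resolving ties
by raw activation instead systematically hands the shared peak-excitability
phases to the stronger-input (lower-sensitivity) candidate and distorts
the circular phase readout of the random-phase experiment (the
high-frequency reference category loses its peak phases, rotating the
cross-continuum phase differences by ~0.3π).  An exact tie in margin —
which occurs for symmetric inputs at equal thresholds — is a guess.

### Calibration (frozen defaults)

The oscillation amplitude and base inhibition are not identified by the
qualitative model description; they were calibrated once, jointly, and
frozen as the package defaults: `osc_amplitude = 0.63`,
`base_inhibition = −0.2`, threshold 1, 1 ms steps, 80 ms rectangular
stimulus pulses (one half cycle at 6.25 Hz), entrainment stimuli arriving
at the cosine peak (φ0 = 0).  The calibration region is bounded by four
requirements: (i) rest stability — oscillation plus rest inhibition stays
below every threshold for all reductions up to 0.5 (A − |B| < 0.5);
(ii) no "ambiguity dead zone" at moderate reductions — the most ambiguous
morph must be resolvable at some phases (2A ≥ 1 − r + 2|B|); (iii) the
sensitivity-off control must stay flat (A < 0.5 + |B|); (iv) a 1 Hz
oscillator must not resolve the ambiguous morph anywhere in the SOA
window (0.81·A below the crossing margin).  Within this region the
model's qualitative behavior is insensitive to the exact values; at its
edges single cells of the reduction sweep flip.  `A = 0.63, B = −0.2`
satisfies all four with the reduction sweep phase-dependent from r ≈ 0.1
upward.

### Simulated experiments

*Psychometric sweep.*  Each morph proportion p puts amplitude p on one
endpoint's input node and 1−p on the other (total 1).  Every level of the
10-step continuum is presented at 16 phases evenly spanning one cycle;
the choice value (0/0.5/1, averaged over the phoneme and word levels,
guesses = 0.5) is averaged across phases.  A two-parameter logistic
(least squares) is fitted; its 50% point is the most ambiguous morph.
The fitted midpoint is used *as a continuous amplitude proportion* rather
than snapped to the nearest discrete level: the model accepts any
proportion, and snapping breaks the exact cross-level symmetry that makes
the opposing-trait continua phase-independent (a snapped midpoint of
0.444 instead of 0.5 introduces a spurious SOA dependence of up to 0.25
in choice value).

*Entrainment experiment.*  Five empty-word events at the oscillator
period (enough for the oscillator/inhibition state to be periodic before
the probe), then the ambiguous morph at 12 SOAs from 0.10 to 0.42 s —
exactly two 6.25 Hz cycles.  Deterministic decisions; guesses count 0.5.

*Random-phase experiment.*  The ambiguous morph is presented at a uniform
random phase on each of 1000 trials; decisions are per level, and guesses
are resolved by a seeded coin flip.  The circular mean presentation phase
of each choice category is compared with the /dɑt/ (all-traits-high)
category, wrapped to [−π, π).

## Behavioral statistics

Response tables carry one row per trial (participant, SOA in seconds or
phase in radians, morph, binary response, experiment half).  Proportions
per participant × SOA are demeaned within participant and averaged into a
group curve; a sinusoid of fixed frequency (regressors sin/cos(2πf·SOA))
is fitted by least squares; the statistic is its r².  The permutation
null shuffles SOA labels independently within each participant and refits
(default 10 000 permutations); p-values use the add-one rule, so the
smallest attainable p is 1/(n_perm+1).  The split-half comparison fits
each half separately; its null redistributes trials between halves within
each participant × SOA cell by a hypergeometric redraw, keeping per-cell
trial counts fixed; the p-value is one-sided (first-half fit stronger).

## Neural statistics

Single-trial phase is extracted with Morlet wavelets (5 cycles) on a
time–frequency grid of 1–15 Hz (1 Hz steps) × −0.5–0 s (20 ms steps).
Grid points whose wavelet half-width (2.5/f s) extends beyond the epoch
are flagged missing and excluded from all downstream maps: their phase
estimates would be edge-contaminated.  With the default 1.9 s epochs the
1–2 Hz rows are unavailable — a real constraint of prestimulus phase
analysis, not an implementation limit.

At every valid grid point the binary response is regressed on
[1, sin φ, cos φ] by maximum likelihood.  The per-participant summary map
is the magnitude √(β_sin² + β_cos²).  Because a magnitude is positively
biased under the null, each participant's observed map is centered by the
mean of 100 within-participant response-permutation maps (each
permutation reuses one shuffled response vector across the whole grid,
preserving the maps' spatial correlation).  The group statistic is a
one-sample t across participants at each grid point; clusters are
4-connected suprathreshold regions (pointwise one-sided p < 0.05,
t distribution); the cluster statistic is the sum of member t-values.
The group null draws one permutation map per participant, recomputes the
t-map, and records the maximum cluster statistic (default 1000 draws);
cluster p-values are add-one.  Drawing with replacement from 100 maps per
participant makes the test very slightly anti-conservative; the
calibration tests assert a family-wise error of at most 0.075 at nominal
0.05 over 500 null simulations, and the acceptance script reports the
rate it measures.

The grid-level fits use a batched Newton solver specialized to the shared
[1, sin, cos] design (float32 accumulation, ridge 10⁻⁶); it matches
`statsmodels` coefficients to ~10⁻⁴ and the reference float64 IRLS to
optimizer tolerance, and the test suite asserts both.  The phase readout
extracts, per participant, the phase at that participant's own peak
effect-magnitude point within the significant cluster, takes the circular
mean difference between the two response categories, and tests the
per-participant differences with a v-test toward π.  The v-test is
V = n·R̄·cos(θ̄−μ) with one-sided normal approximation p = 1 − Φ(V√(2/n));
region-level probabilities are combined as a plain product — the joint
probability of the individually expected effects under independence,
deliberately without a multiple-testing correction.

## Synthetic data

*Behavioral generator.*  Bernoulli responses with probability
base + amplitude·sin(2πf·SOA + phase) per trial; defaults emulate the
entrainment psychophysics design: 18 participants, 12 SOAs spanning two
6.25 Hz cycles, 40 trials per SOA, base probability 0.5.  The modulation
phase is common across participants by default (the entrainment train
provides an external phase reference); `phase_jitter` adds a uniform
per-participant offset.  The power calibration of the permutation test
uses jitter 2.5 rad — individual entrained-phase offsets of up to ±64 ms
at 6.25 Hz, reflecting between-participant differences in auditory
processing delay.  Under perfectly aligned phases the group test
saturates (power ≈ 1 from amplitude 0.05 at these sample sizes), so the
heterogeneous condition is also the one in which the power ordering of
amplitudes is empirically resolvable; the type-I calibration is
unaffected by jitter.

*Neural generator.*  Two labeled streams per participant ("STG-like",
"MTG-like") stand in for source-localized ROI time courses: 20
participants × 150 trials at 200 Hz, epochs −1.2 to +0.7 s.  Each stream
is 1/f noise (power ∝ 1/f, unit variance) plus narrowband oscillations —
a 10 Hz background band and one band at every effect frequency — built
from Gaussian-smoothed complex envelopes (1 Hz bandwidth, coherence time
~0.3 s) so that instantaneous phase is exactly known and decorrelates
across the epoch.  Both streams receive identical band structure; an
"effect" couples one labeling's responses to one stream's true phase at
one (frequency, time) point via P(response=1) = σ(β·cos(φ − φ0)), with
the preferred phase φ0 fixed within and uniformly random across
participants.  Defaults couple the consonant labeling to STG phase at
(7.6 Hz, −0.2 s) and the word labeling to MTG phase at (6.4 Hz, −0.1 s),
β = 1.  Labelings without a coupling draw fair coins.

What the generator does *not* emulate: sensor-level mixing and source
leakage between regions, evoked responses and post-stimulus activity,
non-stationary oscillatory power, participant-specific spectra, and
artifacts.  Passing the detection and dissociation tests therefore shows
that the statistics recover phase–behavior couplings of realistic
strength in clean ROI signals with realistic 1/f backgrounds — not that
they would survive source leakage, which can duplicate a coupling across
streams.

## Problem sizes and determinism

Calibration suites run at the sizes their claims require: 1000 null
datasets for the behavioral type-I rate, 1000 datasets per amplitude for
the power ordering, 500 Gaussian-map simulations for the family-wise
error, 50 replicates for detection, and 25 full stream-by-labeling
replicates (50 pooled mismatched cells) for the regional dissociation.
The model itself is fully deterministic; every stochastic stage
(generators, permutation tests, guess resolution) takes an explicit seed,
and identical seeds reproduce outputs bit for bit.

## Known limitations

- The model has no acoustic front end, no /t/ coda, no reaction-time
  account, and no neural delays; its phase predictions are therefore
  relative, not absolute (which oscillatory phase maps to which SOA is a
  calibration convention).
- The calibration margins of the 1 Hz control and the low-reduction end
  of the sensitivity sweep are small; configurations near the documented
  boundaries can flip single sweep cells.
- The cluster test is slightly anti-conservative at nominal 0.05, an
  inherent cost of resampling a finite per-participant permutation pool;
  the calibration suite bounds it at 0.075.
- The split-half null assumes exchangeable trials within participant ×
  SOA cells; drifts within a half are not modeled.
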