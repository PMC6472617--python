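# Methods

`agdep` implements the computational apparatus of a
familiarization–discrimination playback experiment probing whether
common marmosets perceive non-adjacent dependencies in tone sequences.
This note documents the models, the defaults and their rationale, the
numerical choices, and what the synthetic fixtures do and do not show.

## Stimulus model

Stimuli are sequences of pure sine tones from two pitch classes placed
at the marmoset audiogram's sensitivity peaks: low (L), uniform on
1800–2200 Hz, and high (H), uniform on 9900–12100 Hz (±10% around 2 and
11 kHz). Durations are uniform on 210–240 ms. Each class pool holds 44
tones sampled once per inventory seed. For independent uniform draws on
a width-W interval the expected absolute pairwise difference is W/3, so
low-class tone pairs differ by ≈133 Hz on average — roughly twice the
~70 Hz discrimination threshold expected for this species near 2 kHz,
which is what makes within-class variation perceptually safe to ignore.

Sequences follow the grammar L Hⁿ L (Test 1) or its element-reversal
H Lⁿ H (Test 2): the dependent first and last tones enclose n tones of
the other class. Tone onsets are spaced exactly 250 ms, so silent gaps
are 250 − duration ∈ [10, 40] ms by construction. The familiarization
track holds 360 grammatical sequences (n = 1: 160, n = 2: 120,
n = 4: 80), one onset every 5 s (30 min); the re-familiarization track
is 60/30/30 (10 min). The 160/120/80 proportions equalize the three
within-sequence bigram counts (H→H = H→L = L→H = 360), removing local
transition probability as a discrimination cue; symbolically the
balance holds whenever Σ count(n)·(n−1) = Σ count(n). Bigrams are not
counted across sequence boundaries, which are separated by seconds of
silence.

A discrimination session holds 16 trials: 8 consistent (repetition
n ∈ {1, 2, 4, 4}; variation n ∈ {3, 3, 5, 5}) and 8 inconsistent
(missing-first and missing-last at n = 1..4), in randomized order.
Grammatical strings with lengths outside this design space classify as
consistent/variation; {L,H}-strings matching no schema are
inconsistent/other.

Decisions where the design was open: tones are drawn per token *with
replacement* from the 44-tone pool; frequencies and durations are
i.i.d. uniform (the minimal reading of "sampled between"); audio is
rendered at 44.1 kHz, 16-bit PCM mono, amplitude 0.8 full scale, with
5 ms raised-cosine ramps to suppress onset clicks (the ramps do not
alter the gap structure materially). Randomization derives
per-subject/role/trial child seeds from one master seed via CRC-32
hashing, so every subject receives an individual stimulus set while
the whole study is reproducible from a single integer.

## Head-direction coding

Trials are filmed from above at nominally 100 frames/s; the box floor
is black and the ear tufts are white, so the pipeline needs only
contrast and geometry. Per frame: (1) the head is located by
normalized cross-correlation against a template image (the positional
contract — within 10 px on fixtures — is what matters, not the
matcher brand); a featureless frame or a correlation below threshold
is an explicit no-detection. (2) Pixels above a fixed fraction (0.75)
of the head box's dynamic range are labelled and the two largest blobs
give the tuft centroids, ordered by image x; one blob (head tilted,
tuft hidden) marks the frame invalid. Because the threshold is
relative, summaries are invariant to overall brightness scaling.
(3) The facing direction is the perpendicular of the inter-tuft axis;
of the two perpendicular candidates, 180° apart, the one closer to the
previous frame's angle is kept (first frame: the stored entry
direction — the animal can only enter the box from one side).

Angles are behavioral: 0° = front wall (feeding opening),
±180° = loudspeaker, range (−180°, 180°].

Corrections: invalid frames carry the last valid angle forward
(leading invalid frames take the entry direction); an isolated sample
differing from *both* neighbours by 180° ± 15° is flipped by 180°.
The original workflow fixed such head/back confusions manually during
video review; the automated rule reproduces that check and logs every
flip and carried frame for audit. Corrections never alter valid,
unflipped samples.

A head turn is coded when the corrected |angle| crosses 90° from
below, within 5 s of stimulus onset; dropping back below the threshold
re-arms detection. A trial already oriented past ±90° at onset
contributes no turn until the angle re-enters the frontal zone — a
turn is a crossing, not a state. Trial summaries are the mean and
maximum |angle| over the window, the turn count, and the first
crossing's latency (undefined when no turn occurred). The response
window is anchored at stimulus onset by default; the analyst can pass
the decoded stimulus-offset time as the window start instead, since
the post-playback window is an equally defensible reading of the
protocol. Angles are used as detected, without temporal smoothing,
so event counts on noiseless fixtures are exact.

LED synchronization: the infrared LEDs first flash a session-ID pulse
train (default 5 bits, MSB first, one 10-frame slot per bit, 4-frame
flashes), then single flashes mark each stimulus onset and offset.
The decoder thresholds the LED-region brightness midway between its
extremes, reads rising edges, decodes the ID from slot occupancy and
labels later flashes alternately on/off; an odd number flags an
incomplete trial.

## Statistics

Trial summaries are aggregated per subject × test × subclass (64
records for the full design): mean of trial mean-orientations, max of
max-rotations, number of trials with at least one turn out of the 4
subclass trials (the Binomial response), and mean latency of turned
trials. Consistency derives from the subclass (repetition/variation →
consistent; missing-first/last → inconsistent).

GLMMs use Gamma with log link for the angle magnitudes (positive,
right-skewed; the log link also makes the consistency effect
multiplicative), Binomial with logit for turn counts out of trials,
and Gaussian with log link on latency+1. Random intercepts for social
group and subject-within-group are always present. Fitting is
Laplace-approximate maximum likelihood: for fixed variance components,
fixed effects and random-effect modes are maximized jointly by
penalized Fisher scoring (PIRLS) with step halving, and the variance
components plus dispersion are optimized by Nelder-Mead on the log
scale. ML (not REML-like) estimation keeps AIC = 2k − 2 log L valid
across fixed-effect structures; candidate models run from
intercept-only to consistency × test-type × subject-order structures,
the lowest AIC wins, ties break to fewer parameters, and non-converged
candidates are excluded with a warning rather than silently dropped.
Fixed effects use treatment coding with "consistent" and Test 1 as
reference levels. Boundary fits (a variance component collapsing to
zero — common with only two groups) are flagged, not hidden.

Inference on fixed effects is conditional on the estimated variance
components. For the dispersion families the Wald covariance uses the
Pearson moment estimate of dispersion on the *effective* residual
degrees of freedom, n − trace(H⁻¹·C'WC) (which counts shrunken random
effects fractionally), rather than the ML dispersion — the ML shape is
biased upward at these sample sizes and would understate standard
errors. p-values come from a t reference on those effective df, and
the reported z is the standard-normal equivalent of that p. On
64-record designs with 8 subjects this keeps the nominal 5% test at
its level (simulation checks in the suite), where a raw ML-Wald z
rejects at 8–9%.

Exact Wilcoxon signed-rank tests: zero differences are dropped, ties
among non-zero |differences| get mid-ranks, and the two-sided p is
computed from the *full* distribution of W⁺ over all 2^m sign
assignments (dynamic-programming convolution of the rank generating
polynomial; tests cross-check a literal 2^m enumeration and, for
tie-free cases, `scipy.stats.wilcoxon(method="exact")`, which does not
handle mid-ranks). p = 2·min(tail probabilities), capped at 1; the
tie-corrected normal approximation z is reported alongside. Effect
sizes use r = z/√n, converted to Cohen's d = 2r/√(1−r²) by default;
the convention is a parameter because reporting practices vary.

## Synthetic data

The renderer draws a schematic head — ellipse with its major axis
along the facing direction, two bright tuft disks on the perpendicular
axis — on a dark 120×160 frame, with optional Gaussian pixel noise,
occlusion windows (one tuft hidden) and LED flashes. Trajectories are
raised-cosine excursions between target angles at 100 samples/s, with
turn schedules derived by directly scanning the ground-truth angle
series. θ and θ+180° render identically, deliberately reproducing the
ambiguity the tracker must resolve.

The behavioral generator draws subclass-level mean orientations from a
Gamma distribution with log-mean = log 40° + log(effect)·[consistent ∧
Test 1] + group + subject-within-group intercepts, turn counts from
Binomial(4, p) with the analogous logit structure, and latencies of
turned trials from a log-normal. Defaults: 8 subjects in 2 groups,
consistency effect 1.5, turn odds ratio 2.5, baseline turn probability
0.45, subject SD 0.25 and group SD 0.10 (log scale), Gamma shape 6 —
values a behavioral playback study of this size would consider
realistic effect and noise magnitudes. The effect sits in Test 1 only,
so the pipeline's interaction term is exercised the way the design
intends.

What the fixtures do *not* emulate: real fur appearance and lighting,
marmoset motion statistics beyond smooth excursions, camera noise
structure, or the true effect sizes of live animals. Passing tests
therefore demonstrate correctness of the algorithms under their stated
contrast/geometry assumptions and calibration of the statistics under
the stated generative model — not behavioral findings. The published
coefficient tables require the real response data and are explicitly
not a test target; the same pipeline can be pointed at such a table
via `agdep analyze`.

## Problem sizes and numerics

Test fixtures use 120×160 px frames and clips of a few hundred frames;
the Monte-Carlo checks of GLMM sign recovery and type-I error use 200
replicates of the full 64-record design, and the tone-statistics check
uses 2×10⁵ pairs — sizes chosen to give stable Monte-Carlo bands while
keeping the whole suite around a minute. Variance components are
bounded to [10⁻⁴, 10²] (SD scale) and dispersions to [10⁻³, 10⁶] on
the log scale for numerical stability; a component at its lower bound
is reported as a boundary fit. Tuft-blob ties are broken by image x
then y; the sequence-assembly rounding rule is `round(duration ×
sample_rate)` samples.

## Known limitations

- The head detector is plain normalized cross-correlation with a
  front-facing template; it is position-accurate on schematic fixtures
  but not rotation-optimal — adequate because only the head *region*
  feeds the tuft step.
- With two social groups the group-level variance is weakly
  identified and routinely hits the boundary; subject-level variance
  carries the random structure.
- The Laplace approximation is known to be slightly biased for
  Binomial responses with few trials per record; adaptive quadrature
  is not implemented.
- Latency models drop no-turn records rather than modelling the
  turn/no-turn mixture jointly.
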