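# Methods

## The problem being modeled

A vowel token is a bundle of acoustic cues — F0, the first three formants
(Hz), and duration (ms) — produced by a particular talker. Because
vocal-tract length scales formants roughly multiplicatively, pitch
baselines differ across talkers, and speaking rate stretches durations,
the same category occupies different cue regions for different talkers.
Normalization accounts are hypotheses about the transform listeners apply
before mapping cues to categories. This package operationalizes "how good
is a normalization account" as: how accurately does a Bayes-optimal
categorizer recognize held-out productions after that transform?

## Ideal observer

Each category's likelihood is multivariate Gaussian, with mean and
covariance estimated as sample moments (n−1 denominator) of the normalized
training tokens, pooled across talkers within category. Priors are uniform
over the categories in play (1/21, 1/11, 1/10 for all/long/short). The
posterior is computed from log densities via Cholesky factors with
log-sum-exp normalization, so crowded high-dimensional spaces cannot
underflow; posteriors sum to one to ~1e−15 and match a naive direct
density computation to better than 1e−12.

Decisions use the criterion rule (argmax posterior); ties break to the
first category in sorted-label order, deterministically. Luce's rule
(sample proportionally to the posterior) is provided and requires an
explicit seeded generator. Accuracy is the fraction of held-out tokens
whose predicted label equals the produced vowel; per-token posteriors of
the intended category are retained for diagnostics.

Covariance fitting requires at least dim+1 tokens per category and fails
loudly on singular fits; an optional ridge (ε·I, default 0) exists as an
explicit, logged rescue, never a silent default.

## Normalization accounts

Fitting and application are strictly separated: a fitted model carries the
talker statistics it needs (means, sds, ranges, log means, geometric-mean
F0) computed on training tokens pooled over all of a talker's categories,
and raises on unseen talkers instead of silently refitting.

Choices the account definitions leave open, fixed here:

- **Semitones**: 12·log2(f/100 Hz); reference configurable.
- **Miller**: k = 168 Hz and log base 10 (the published constants), both
  configurable. In the two-formant condition the dimensions are
  log10(F1/SR), log10(F2/F1); with F3, log10(F3/F2) is added.
- **Nearey2** pools its single grand log-mean over the formants in the
  active cue set only.
- **Sample sd** uses n−1 throughout.
- **Gerstman** maps the training range to [0, 999]; held-out values
  outside the range pass through un-clipped (clipping would destroy
  information).
- **Five-cue condition**: plain transforms also transform F0; extrinsic
  accounts normalize F0 like a formant (Nearey2 centers it by its own log
  mean, since pooling F0 with formants would contaminate the formant grand
  mean); Miller maps F0 to log10(F0/SR), staying on the account's own log
  scale; duration stays raw in ms for every account except C-CuRE, which
  centers it to the talker's mean — C-CuRE is the one account defined for
  arbitrary cue types.
- **Syrdal–Gopal** is defined only for the F1–F2 comparison (height
  F1−F0, backness F2−F1, in Bark); other cue sets are rejected as
  incompatible, and the grid records them as skipped cells.

Exact algebraic invariants (all tested): refit-on-self Lobanov gives
per-talker mean 0 / sd 1; centering accounts give per-talker mean 0;
Gerstman training outputs attain exactly 0 and 999. Lobanov is invariant
under per-talker affine cue maps, Nearey under per-talker multiplicative
maps. Miller's cube-root reference compensates exactly only when formants
scale by c while F0 scales by c³ — the physiological coupling the account
assumes — so its invariance test uses that coupled perturbation; under
uniform scaling of all cues its F1/SR dimension shifts by (2/3)·log c,
which is a property of the account, not of this implementation.

## Cross-validation and uncertainty

Tokens of every talker × vowel cell are shuffled under a seed and dealt
round-robin into k = 5 folds, so cell fold sizes differ by at most one.
Per fold, normalization parameters and observer moments are fitted on the
other four folds only; mutating test tokens provably leaves every fitted
parameter bit-identical. Per-fold accuracy gets a percentile-bootstrap 95%
CI (B = 1000, resampling test tokens within the fold); the summary CI
averages the endpoint across folds, and the output metadata records this
choice. A label-shuffling diagnostic is provided: any pipeline evaluated
on shuffled labels should score ≈ 1/K, guarding against leakage bugs.

## Outlier screening

Measurement-error candidates are flagged per talker × vowel cell from the
joint Gaussian over all five raw cues. Under Gaussianity the squared
Mahalanobis distance is χ²(dim); the default 0.5th–99.5th quantile band
maps to [χ²₀.₀₀₅, χ²₀.₉₉₅] (≈ [0.41, 16.75] at dim 5) on the distance, and
tokens outside it are flagged — above as conventional outliers, below as
suspiciously hyper-central (duplicate or imputed values produce exactly
this signature). The two-sided band flags 1% of clean Gaussian data
asymptotically; in-sample at n = 200 the exact rate is 0.89% (the
in-sample distance follows a scaled Beta, not χ²). Setting the lower bound
to 0 recovers purely one-sided screening. Cells smaller than dim+2 or with
singular covariance are skipped with a warning. Screening only flags; it
never drops or corrects.

## Synthetic data generator

The generator emulates the design of a dense single-variety hVd corpus:
by default 17 talkers × 21 categories (11 long, 10 short) × 10 tokens.
Talker effects are explicit ground truth: a log-normal formant scale
(sd 0.06), a log-normal duration rate (sd 0.12), a log-normal F0 baseline
(median 200 Hz, sd 0.10), and small idiosyncratic per-formant log offsets
(sd 0.02). Tokens are drawn log-normally around category prototypes with
per-category covariance (formant log-sd 0.05, adjacent-formant correlation
0.3); any draw violating F1 < F2 < F3 is resampled.

The prototype layout places 11 long categories on a vowel-quadrilateral-
like grid in log F1–F2 with F3 tied to frontness/rounding; the 10 short
counterparts are shrunk toward the long-inventory centroid by factor 0.85
in log space with 0.8× the noise sd, and duration bases are 220 ms (long)
vs 120 ms (short) with token noise sd 0.10 — so quantity is separated
primarily by duration, short categories are more centralized and less
variable, and per-talker formant means track the ground-truth formant
scale. All numeric values are invented, documented testing defaults chosen
to be realistic for adult female speakers of a Central-Swedish-like
variety; nothing downstream depends on matching any real corpus
numerically. Talker gender is not modeled.

What the generator does **not** emulate: formant dynamics and
diphthongization, measurement error from formant tracking, male-talker
physiology, socio-indexical variation, or non-Gaussian category shapes.
Passing tests therefore show that the pipeline draws the right
conclusions when its distributional assumptions hold and talker variation
is multiplicative — not that any particular account is the right model of
human listeners or of a specific real corpus.

## Problem sizes and numerical choices

The full evaluation grid (15 accounts × 3 cue sets × 3 vowel subsets,
minus the 6 undefined Syrdal–Gopal cells, at 5 folds and B = 1000) on the
default 3,570-token dataset runs in well under a minute on one CPU; the
test suite uses the same design size. Monte-Carlo checks use 10⁵ draws for
the closed-form Bayes accuracy comparison and 10⁴ talkers for the
talker-scale-sd recovery check. Fold-to-fold accuracy spread at this
design size (~700 test tokens per fold) is dominated by binomial noise, so
stability is asserted as a median spread under 5 accuracy points across
grid conditions (a corpus several times larger would tighten all
conditions below that bound). Equality tolerances: exact invariants at
1e−10, oracle agreement at 1e−12, CSV round trips are bit-exact
(%.17g writing, correctly rounded parsing).

## Known limitations

- Timepoint-resolved formants are carried through I/O and averaging, but
  normalization and categorization operate on steady-state values (average
  of the 35/50/65% points by default); formant dynamics are out of scope.
- Accounts are evaluated singly; multi-stage normalization chains are not
  supported.
- The bootstrap CI endpoint-averaging across folds is one of several
  defensible aggregation choices; pooled-resample aggregation would differ
  slightly.
- Covariances are pooled across talkers within category; talker-specific
  category representations (adaptation/exemplar accounts) are outside this
  package's scope.
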