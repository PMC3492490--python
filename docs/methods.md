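# Methods

## The state-space projection

A single EEG channel is cut into non-overlapping 5-s epochs (500 samples at
100 Hz; a trailing partial epoch is dropped). Each epoch is multiplied by a
Hann window, zero-padded to the next power of two (512 points) and Fourier
transformed; the one-sided periodogram is scaled by `1/(fs·Σw²)` with
interior-bin doubling. Only *ratios* of band sums are ever used, so the
absolute scaling convention is irrelevant to every downstream result; one
convention is fixed purely for reproducibility.

Band powers are sums over bins whose center frequency satisfies
`lo ≤ f ≤ hi`, inclusive at both edges — band edges are specified to
0.1 Hz while bins are 0.1953 Hz apart, so an explicit inclusive rule keeps
the mapping deterministic. The two coordinates of an epoch are
`log10(P_num/P_den)` for the two band pairs; the default pair is
Ratio1 = (8.6–19.3)/(1.0–10.9) Hz and Ratio2 = (11.5–20.3)/(17.9–31.5) Hz.
Log base 10 is a display convention: any base rescales both axes by a
constant, and both the LDA classifier and the velocity ordering are
invariant under common affine maps of the plane.

Numerics: each epoch's spectrum can optionally be normalized by its total
power first (`normalize=True`, the default). This is analytically a no-op
for the ratios but keeps intermediates in a safe floating range. Band
powers are floored at `1e-12 × (total power + ε)` so silent or clipped
epochs give large-but-finite coordinates instead of infinities.

Coordinate series are denoised with a running Hann-window average: the
kernel is the interior of a Hann window (all weights positive), normalized
to unit sum, truncated and renormalized at the series edges — no padding,
so no fabricated data at recording boundaries. A window at least as long
as the series degenerates to the series mean. Three window widths are
used: 10 points before staging, 50 points for the slow/fast cluster
analysis (the longer window suppresses within-cluster jitter and
emphasizes state-to-state trajectories), and no smoothing for laterality
velocities, where epoch-to-epoch time resolution is the point. Note that
an even-span centred moving average shifts a linear trend by half a
sample; this is inherent to even windows and immaterial at these
timescales.

## Staging: pooled-covariance LDA

Stages are modelled as Gaussian classes sharing one pooled covariance,
with empirical class frequencies as priors — classic LDA used as a
discrete classifier. The pooled covariance receives a ridge of
`1e-6 × trace` on its diagonal for stability on near-degenerate clusters;
this is far below any data scale. Posterior ties (measure zero) are broken
toward the larger prior, then the fixed stage order
WAKE < NREM1 < NREM2 < NREM3 < REM. Fitting requires ≥ 2 stages with ≥ 3
epochs each.

Agreement with a reference is summarized as the positive predictive value:
overall, the fraction of epochs where automatic = manual; per stage,
conditioned on the *predicted* stage. A stage never predicted is reported
as missing, not 0. The train/test protocol concatenates training subjects,
fits once, and evaluates only on held-out subjects; overlapping subject
sets are rejected.

The classifier is a scikit-learn-style estimator
(`PooledCovarianceLDA.fit/predict/predict_proba`, with a
`BandRatioTransform` front end for pipeline composition); the module-level
functions wrap it.

## Band optimization

The eight band edges are optimized to maximize overall PPV on a labelled
cohort (coordinates smoothed per subject with the 10-point window; one
classifier fitted on the pooled epochs — held-out evaluation is
deliberately a separate, post-hoc step). The genetic algorithm uses
paired-regrouping crossover (each of the four bands inherited as an intact
(lo, hi) pair from either parent), per-gene Gaussian mutation (σ = 1 Hz,
rate 10 %), tournament selection (size 3), and single-genome elitism, so
best-so-far fitness is monotone non-decreasing. Defaults: population 50,
100 generations; only the mutation rate and operator are externally
prescribed, the remaining hyperparameters are package defaults exposed in
config. Edges live in [0.5, 45] Hz — below the box sits DC drift, above it
mains-adjacent content, and all default optimized edges (1.0–31.5 Hz)
are interior. Constraint violations during search are repaired (clip +
swap); a band that captures no spectral bin scores fitness 0. Nelder–Mead
then minimizes `1 − PPV` from the best genome with the same penalty, and
the refined genome is kept only if no worse than its input.

Band locations are not identifiable in general — many band pairs separate
the same spectral templates — so recovery is judged by fitness, not by
edge positions.

## Velocity and the slow/fast partition

Velocity is the Euclidean step length between consecutive state-space
points divided by the epoch length (units: log₁₀-ratio per second). Entry
i is labelled with the stage of the *arrival* epoch i+1, so transition
speed is attributed to the stage being entered. The slow/fast cutoff is
heuristic by nature; the default is the 75th percentile of each
recording's own velocity distribution (adaptive across recordings and
channels), overridable by an absolute value. Ties at the cutoff go to
fast. Per-stage statistics (means, between-subject SEM, paired two-sided
t-tests across subjects) default to unsmoothed velocities, with the
smoothed variant available. A constant nonzero paired difference across
subjects is reported as t = ±∞, p = 0 rather than an error.

## Laterality and the interhemispheric oscillation

The laterality score `(v_R − v_L)/(v_R + v_L)` uses unsmoothed-trajectory
velocities of a homologous pair. It is antisymmetric under swapping
hemispheres, 0 iff velocities are equal, ±1 iff one velocity is zero; a
both-zero pair (perfectly stationary) is symmetric and maps to 0. The
series is cut into non-overlapping 100-epoch (500 s) bouts, optionally
restricted to runs of one stage (REM by default in the multi-pair report);
trailing partial runs are dropped, and every channel pair is analysed over
the identical bout windows.

Per bout, the sample autocorrelation (mean-subtracted, biased 1/n
estimator — guaranteeing |acf| ≤ 1 — normalized at lag 0) is computed to
lag 90, alongside the approximate white-noise band ±z₀.₉₇₅/√n. The
mean-subtracted ACF is zero-padded to 256 points and Fourier transformed;
the ACF is sampled once per epoch, so its Nyquist frequency is
1/(2×5 s) = 0.1 Hz, and the spectral peak is searched in [0.005, 0.1] Hz
(the lower edge excludes bout-length-scale trends; the bout fundamental is
0.002 Hz). The report carries the peak frequency and period, and also the
first ACF side-lobe lag as an alternative period estimate — the two can
differ by up to a coarse ACF bin, so both are exposed.

Bias note: the biased ACF tapers by (n−k)/n, which broadens the spectral
peak symmetrically but does not shift its location; the fixed ±1.96/√n
band is *nominal* — the biased estimator's variance at lag k is
≈ (n−k)/n², so the band over-covers at high lags, and its measured
coverage over lags 1–90 of uncorrelated bouts is ≈ 98.6 %, not 95 %.

**Detection rule.** Two sub-criteria are reported separately so users can
apply their own rule: (1) whether any non-zero-lag local extremum of the
ACF exceeds the white-noise band, and (2) the peak dominance, spectral max
over median inside the search range. The `significant` flag requires (1)
*and* that the dominance exceeds its white-noise (1−α) quantile. That
quantile has no convenient closed form (ACF spectra are strongly
correlated across bins), so it is Monte-Carlo calibrated at run time from
500 white-noise bouts with a fixed internal seed and cached — an α-level
calibration, not a fitted constant. A fixed fold-over-median threshold
cannot control the error rate here: essentially every white-noise ACF
spectrum has max ≥ 2× median, so a rule of that form fires on most null
bouts. The calibrated rule's measured false-positive rate is ≈ 4–5 % at
α = 0.05, and injected oscillations with periods 32–80 s at modulation
depth 0.3 are located within one spectral bin (0.78 mHz) in ≥ 94 % of
runs.

## Synthetic polysomnography

The generator exists so every pipeline stage is testable against known
ground truth. Stage sequence: a sticky five-state Markov chain starting in
WAKE; self-transition probabilities encode mean bout lengths (WAKE 5 min,
NREM1 2 min, NREM2/NREM3/REM 10 min at 5-s epochs) and the remainder goes
to plausible successor stages. Signals: per epoch and channel, a sum of
narrowband components (white noise through second-order resonators —
simple, spectrally controllable, stationary within an epoch) over 1/f
background, with stage templates: WAKE α (10 Hz) + β; NREM1 θ (5.5 Hz);
NREM2 spindle-band (13 Hz) + weak δ; NREM3 dominant δ (1.8 Hz); REM
low-amplitude mixed θ (6 Hz) + weak β (15 Hz). Templates were chosen once
so the default optimized band ratios separate the stages; REM carries content in
both ratio planes so that jitter reaches both coordinates. Epoch-to-epoch
lognormal jitter (σ = 0.5 in log power, independent per component and
channel) creates the spectral variability that state-space velocity
measures.

The interhemispheric oscillation is injected as *antiphase modulation of
the jitter scale* of one channel pair, `σ·(1 ± depth·sin(2πt/T))` — not as
amplitude asymmetry — because the phenomenon of interest is an oscillation
of velocity (spectral variability), and a pure amplitude modulation would
cancel exactly in the band ratios. Null models: `rayleigh_null` (two
independent Rayleigh velocity draws per epoch through the laterality
score) and `sinusoid_model` (sinusoid plus uniform noise, clipped to
[−1, 1]); `modulated_rayleigh_laterality` injects the oscillation directly
at the velocity level for calibration studies.

What the generator does *not* emulate: biophysically realistic EEG
(no neural-mass dynamics), artifacts, EOG/EMG, inter-subject template
variability, within-stage spectral drift, or continuity of phase across
epoch boundaries (the Hann window suppresses edge effects). Passing tests
therefore demonstrate correctness and calibration of the *analysis* under
its own model assumptions — well-separated Gaussian-ish clusters — not
expected staging accuracy on clinical recordings, where agreement is
bounded by inter-scorer variability and cluster overlap.

## Problem sizes and other defaults

Tests and the acceptance surface run on 90-minute, 6-subject synthetic
cohorts and 100-epoch bouts — large enough that every stage appears with
stable cluster estimates and several bouts per night, while a full suite
run stays fast. Recordings are 100 Hz, six channels (F3, F4, C3, C4, O1,
O2) in microvolts; EDF is read via MNE and written by a built-in minimal
16-bit writer (1-s records, per-channel physical scaling; requires integer
sampling rate and whole seconds). Channels with differing sampling rates
are rejected rather than resampled so spectral bins stay identical across
channels. Hypnograms are `epoch_start_s,stage` CSV; UNSCORED epochs are
excluded from agreement denominators (how artifact epochs were handled
upstream is an assumption, made explicit here). A 30-s hypnogram is
expanded to the 5-s grid by 6× label replication.

## Known limitations

- The staging surface is a single-channel, two-ratio model; no temporal
  label smoothing (e.g. HMM) is applied on top of the LDA.
- The slow/fast cutoff is a percentile heuristic; absolute thresholds
  across cohorts require the user's own calibration.
- Period estimates are quantized by the ACF-spectrum grid (0.78 mHz);
  oscillations faster than 0.1 Hz alias and are undetectable by design.
- The GA explores a non-convex, plateaued fitness landscape; different
  seeds can return different band sets of equivalent fitness.
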