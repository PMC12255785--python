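# Methods

## Data model

The unit of observation is one minute of beta-band power from a sensing
DBS pulse generator, a non-negative scalar in device units.  Timestamps
are patient-local clock times (ISO-8601, no timezone arithmetic): day and
awake-window boundaries are clinical constructs, so a "day" is the
calendar date of the sample and the awake window defaults to
[9:00, 21:00).  Missing minutes are kept as gaps and never imputed; a day
enters the analysis only if it holds at least 80 % of its expected
samples (configurable), because sparser days produce degenerate
histograms.  Setting epochs — the date intervals over which one aDBS
parameter set (β_min, β_max, A_min, A_max, stimulation frequency, pulse
width, driver hemisphere) applies — are closed on both ends and must not
overlap.

Each usable day becomes a histogram on a fixed uniform grid spanning the
patient's power window (206 bins by default).  Bins are half-open
[eᵢ, eᵢ₊₁) with the last bin closed; out-of-window samples are clipped
into the end bins and counted, since the power window is defined to
contain all of a patient's distributions and clipping should be rare and
visible.  The histogram is min–max normalised per day; a constant count
vector maps to all-zeros rather than dividing by zero, keeping outputs in
the sigmoid range.  Raw counts are retained alongside: percentiles and
threshold fractions are always computed from counts (with linear
interpolation inside the crossing bin — the estimator is a choice, made
once), never from the normalised vector, which is not a probability mass.

## Drift diagnostics

For each day we compute the fractions of minutes below β_min, between
the thresholds, and above β_max; samples exactly at a threshold count as
"between" (at the limit the device still modulates).  A day counts as a
clinically meaningful shift when its tail fraction exceeds the
calibration-day reference by more than 10 percentage points — one-sided,
because the concern is *excess* time pinned at A_min/A_max (10 points of
a 24 h day is 2.4 h); a two-sided option is exposed.  The per-epoch
variability σ is 100 times the fraction of such days.

The temporal structure of the minute series is summarised by its raw
one-sided periodogram (mean removed, no taper; frequency grid from
Δf = 1/T to the 0.5 cycles/min Nyquist of 1-minute sampling), split at
the circadian cutoff 1/1440 cycles/min and fitted on each side with
C·f^(−α) by unweighted OLS in log10–log10 coordinates.  α ≈ 0 indicates
white (uncorrelated) fluctuations, α ≈ 1 pink, α ≈ 2 Brownian.  Days
failing the coverage threshold are dropped and the series concatenated
before the spectrum — the simplest reproducible choice, flagged in the
output.

## The forecaster

Each normalised daily histogram is a token of dimension M = n_bins, with
M doubling as the embedding width.  A sequence of N consecutive days
(never spanning an epoch boundary or calendar gap) receives a fixed
sinusoidal positional encoding and passes through three encoder and six
decoder multi-head-attention layers, non-autoregressively: the same
sequence is source and target and no causal mask is applied, because
generating each horizon directly avoids error propagation through
intermediate predictions.  The decoder's last-position representation is
mapped by an affine head and a sigmoid to the predicted distribution of
day N + K, K ∈ [1, 6]; one model is trained per (N, K) task.

Training minimises wMAPE(y, ŷ) = Σ|yᵢ−ŷᵢ| / Σ|yᵢ| — actual-magnitude
weighting, so genuinely zero bins contribute zero penalty — with RMSProp
(lr 1e-4, α 0.99) in full batches; the datasets involved are small
enough that mini-batching buys nothing.  Defaults: 2 attention heads
(206 = 2 × 103 leaves few divisors), feed-forward width 512, dropout
0.1, 20 000 epochs, no early stopping.  The single-setting regime splits
examples 85/15 with the validation set taken as the chronological tail
(time-series hygiene: validation lies in the training data's future) and
the training subset shuffled by seed.  The multi-setting regime first
trains on all setting epochs but one, then fine-tunes at lr 1e-5 on a
shuffled half of the held-out epoch and validates on the other half.
One seed initialises every stochastic component (weights, shuffles,
dropout masks); identical seeds give bit-identical runs.

The optimal history length N\* is selected as the smallest N whose mean
validation wMAPE lies within one standard deviation of the best N's —
shorter histories are preferred when statistically indistinguishable.

Two implementation choices matter numerically.  First, the network runs
on a small bundled reverse-mode autodiff engine over numpy arrays; its
gradients are verified against central finite differences across the
full encoder–decoder stack in the test suite.  Second, the output head
uses prior-based initialisation: weights scaled by 0.1 and bias set to
the logit of the per-bin mean training label.  Normalised histograms are
sparse, and a head starting at sigmoid(0) = 0.5 everywhere forces
RMSProp — whose per-step movement is essentially the learning rate — to
spend thousands of epochs just drifting the output bias; starting at the
base-rate distribution removes that plateau without touching the
optimiser or the architecture.

## Baselines

The zero-order baseline returns the last observed distribution.  The
linear baseline fits an independent affine map per bin on consecutive-day
pairs: for a two-day history the closed form a = x₂/x₁, b = 0 (or a = 0,
b = x₂ when x₁ = 0); for longer histories per-bin least squares via the
pseudo-inverse, with zero-variance bins falling back to the zero-order
value (bounded behaviour at the two-day limit).  Multi-step predictions
iterate the fitted one-step map; a refit-per-horizon option exists but
iteration is the default.  The random-forest baseline fits an
independent 100-tree forest per bin on the scalar map x_{t,i} → x_{t+1,i}
(scikit-learn), one-day-ahead only — the forest has no notion of
sequence.  Baseline outputs are not clipped to [0, 1]; the evaluation
layer renormalises predictions (clip at zero, rescale to unit mass)
before extracting percentiles or tail fractions.

Percentile inaccuracy is reported as 100·|v_pred(q) − v_obs(q)| divided
by the power-window span, which bounds the metric in [0, 100];
normalising by the observed percentile value is available as an option.
The threshold alarm flags any forecast day whose predicted tail fraction
deviates from the calibration reference by more than a safe range
(default 10 percentage points).

## Synthetic patients

Real device exports cannot be shared, so the pipeline is exercised on
generated patients.  Minute power is exp(μ + circadian sinusoid +
medication-cycle sinusoid + day-level drift + noise): lognormal because
beta power is positive and right-skewed (a fixture modelling choice, not
a claim about the device).  Defaults: circadian amplitude 0.35 and
medication amplitude 0.12 in log-power units, three medication cycles
per day, noise σ 0.08 with spectral exponent α = 1.  Noise variants: any
power-law exponent in [0, 2]; an AR(1) mode with a configurable sub-day
correlation time (steep within-day spectrum, flat beyond a day); and a
frozen mode that reuses one intra-day noise pattern every day,
eliminating day-to-day sampling variance for clean control fixtures.
Drift moves either the location or the scale (width) of the daily
distribution and comes as: none; linear (constant daily increment);
regime-switching (two attracting levels ±drift_scale/2, per-day switch
probability, low-pass smoothed over a few days — predictable from recent
history, poorly captured by per-bin affine maps); or a smoothed random
walk.  Each generated epoch's β_min/β_max sit at the 10th/90th
percentiles of its first day, mirroring day-0 calibration.

The frozen study profiles (betadrift.profiles) and what they emulate:

* **SYN-NL** (60 days, regime switching, σ 0.04, 3-day smoothing, switch
  probability 0.12): drift whose *direction* is visible from two days of
  history.  Parameters were tuned by search so the fixture sits in this
  regime, and then frozen.
* **SYN-LIN** (90 days, linear width drift, frozen white noise σ 0.2):
  the control regime where per-bin dynamics are smooth and monotone and
  the per-example affine baseline is near-optimal.  Location drift cannot
  serve here: a shifting histogram's per-bin trajectories are
  non-monotone (a bin fills and then empties as the peak passes), which
  no per-bin affine recursion fits.
* **SYN-CONST** (no drift, white noise): nothing should alarm.  White
  rather than pink noise because pink minute noise by itself wanders the
  day-level location — that is real drift under the noise model, not an
  artefact.
* **SYN-2SET**: SYN-NL split into two 30-day setting epochs for the
  multi-setting regime.

What these fixtures do not emulate: closed-loop feedback of stimulation
on beta power, artifacts, medication-schedule changes, or any
biophysical LFP structure.  Passing tests therefore demonstrate that the
pipeline recovers the statistical structure it was built for — not
clinical performance on patient recordings.

## Desk-scale profile and test design

The production defaults (20 000 epochs, 206 bins) are impractical for a
routine test run, so the suite and the results script use a documented
desk-scale profile, chosen once: 52-bin grids (104 for the memorisation
check), feed-forward width 256, and 400–2000 training epochs depending
on the experiment; learning rates, architecture depth, split fractions
and seed handling are the production values.  Comparisons against
baselines are paired — every model sees byte-identical validation
examples.  On SYN-NL the forecaster's median validation wMAPE over five
seeds beats the zero-order and linear regressors at horizons 1–3 and the
random forest beats the linear regressor at horizon 1; on SYN-LIN the
per-example linear baseline reaches wMAPE < 0.05 and the forecaster
stays within twice of it; the multi-setting run stays within 1.5× of the
single-setting run for a majority of seeds.  The expected values frozen
in the unit tests (hand-counted histograms, closed-form coefficients,
the 0.4/1.5 wMAPE example, shift-by-5 % percentile errors) were computed
with independent oracles: brute-force enumeration for dataset windows,
explicit normal equations for the least squares, CDF inversion on raw
samples for percentiles, finite differences for gradients.

## Known limitations

* Horizon-K forecasts require a model trained for that K; there is no
  joint multi-horizon head.
* The forecaster extrapolates monotone trends conservatively: on drifts
  that keep leaving the training range its error grows with distance
  from the last training day, which is why local baselines win on purely
  linear drift (by design, and measurably).
* The autodiff engine is minimal and CPU-only; at production scale
  (20 000 epochs, 206 bins) a single-setting training run takes hours,
  not minutes.
* Per-patient, per-hemisphere modelling only (the driver channel);
  cross-patient transfer is out of scope.
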