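# Methods

This note documents the models, parameter choices and numerical decisions
behind `arrayqc`, and what the synthetic-data tests do and do not establish
about real recordings.

## Acquisition model

A session consists of `n_files = n_arrays / 2` raw files, one per neural
signal processor (NSP).  Each NSP digitises the two 64-electrode Utah arrays
that share one hardware reference wire, so within-NSP channels 1–64 are the
first array of the pair and 65–128 the second, and reference group *k*
covers arrays 2k−1 and 2k.  NSP 1 additionally records four analog eye
channels (X/Y gaze on labels 129/130, X/Y pupil diameter on 131/132).
Channels above the documented range carry no data and are dropped during
alignment.  Within-array numbering is fixed to row-major order of the 8×8
grid; the physical wiring order of a real implant is a property of its
deposited lookup table, which `read_lut` loads in place of the synthetic
default.

Recording start/stop is staggered across NSPs by up to a few seconds.  The
digital event stream — identical on all NSPs — is a random code in {1..8}
every second at rest, or trial codes during tasks (single active bit *N* →
decimal code 2^N: stimulus onset 2; checkerboard offset 4 and reward 8;
bar-sweep direction codes 8/16/32/64 for rightward/upward/leftward/downward,
with reward on code 4).

## Alignment

Offsets are found by exact matching of the (code, inter-event-interval)
sequence between files, not cross-correlation: codes are discrete and
sample-exact, so a single consistent event-index lag with ≥ 3 overlapping
events determines the integer sample offset.  Zero consistent lags (any
code mismatch in the overlap) or more than one (possible only for short
periodic sequences) raise an alignment error rather than guessing.  Offsets
are reported relative to the latest-starting file; trimming leaves all
files the same length with every common event at the same sample index.
Clock drift is not modelled: the NSP clocks are treated as rate-locked.

## MUAe and LFP

MUAe: Butterworth order-4 band-pass with half-power edges 500–9000 Hz →
full-wave rectification → order-4 low-pass at 200 Hz → keep samples
{0, 30, 60, …} (1 kHz).  LFP: order-4 low-pass at 150 Hz → keep samples
{0, 60, …} (500 Hz).  The low-passes double as anti-alias filters for the
decimated rates.  All filtering is zero-phase (`sosfiltfilt`), chosen so
that derived latencies carry no filter group delay; one-pass implementations
will sit a few ms later and attenuate twice as little per pass.  Outputs
cover the full trace with the first/last 50 ms flagged as edge-affected in
the provenance rather than trimmed.  Output length is
`floor(n_raw / decimation)`.

A note on discrete sampling: a sinusoid commensurate with the 30-kHz grid
(e.g. exactly 3 kHz = 10 samples/cycle) has a sampled rectified mean of
0.6155, not 2/π ≈ 0.6366; the analytic steady-state check therefore uses an
incommensurate in-band frequency (3150 Hz, 200 distinct phases), which
matches 2/π to < 0.1%.

## Evoked metrics

Per trial, the spontaneous mean and SD are computed over the 300 ms before
stimulus onset; the scalar `Mean_spontaneous` and `SD_spontaneous` are the
across-trial arithmetic means of those per-trial statistics (the aggregation
is otherwise underdetermined by the definition's per-trial phrasing).
`Peak_stimulus_evoked` is the maximum, within the stimulus window, of the
trial-averaged MUAe smoothed with a 20-bin centred moving average (edge
bins use a truncated window).  SNR is undefined (flagged, never ±inf) when
`SD_spontaneous` is zero.  The good-channel threshold defaults to SNR ≥ 2.

Latency deliberately uses the *unsmoothed* trial average: the first
post-onset bin where 5 consecutive bins exceed `Mean_spontaneous +
2·SD_spontaneous`.  Values < 20 ms or > 150 ms are flagged implausible
(`too_early` / `too_late`) instead of being reported numerically.

## RF mapping

Per direction, a Gaussian `offset + A·exp(−(t−μ)²/2σ²)` is fitted to the
trial-averaged MUAe (initialisation: μ at the argmax, σ from the half-max
width, A from max − baseline).  A direction fit is accepted only if
A > 2× the baseline SD and σ ≥ 5 ms — the width gate rejects single-bin
noise spikes that can otherwise satisfy the amplitude gate with a narrow
zero-width Gaussian.  Response onset/offset are μ ∓ 1.65σ; positions along
the motion axis are `start + sign·speed·(t − sweep_onset)`, with the bar
position defined as the centre of its leading edge (this convention shifts
boundaries by at most half the bar thickness, ≤ 0.1 dva).  Each boundary
averages the onset position of one direction with the offset position of
the opposite direction, which cancels the response latency exactly; the
centre is the midpoint of the boundaries and `D = hypot(r−l, t−b)`.
Coordinates: x positive rightward, y positive upward, fixation at the
origin; planted RFs sit in the lower-right quadrant.

When thin-bar and thick-bar maps are merged, each channel keeps only its
assigned stimulus set; channels unmappable under their assigned set are
reported missing rather than silently substituted.

## Eye state

Each pupil trace is corrected by subtracting its session minimum (the
recordings have a nonzero baseline), the X/Y traces are combined with the
Euclidean norm, and the result is reduced to 1 Hz by non-overlapping block
means — which also averages away sub-100-ms blinks, the stated purpose of
the down-sampling.  Seconds below threshold are "closed".  The threshold
default is scale-free (10% of the 95th percentile of the 1-Hz combined
diameter) because the acquisition defines no physical pupil units; it is
configurable.  Any residual state run at or below 100 ms inherits the
surrounding state before segment statistics.  Validation correlates the
binary open indicator (open = 1) with the 1-Hz array-mean MUAe (Pearson);
zero variance in either series is reported as undefined rather than 0.

## Synchrofact detection and pruning

Raw traces are band-passed at 250–9000 Hz (Butterworth order 4, zero-phase,
matching the MUAe band-pass design) and, within each reference group, the
projection onto the group's first principal component is removed — this
strips the shared reference-wire signal ("roughly the mean of the
signals").  Threshold crossings use the robust noise estimate
`σ_n = median(|x|)/0.6745` with a −5σ_n threshold; one crossing is kept per
excursion with a 1-ms per-electrode lockout; only negative crossings count
(standard extracellular polarity).

Crossings whose 1/30-ms bins are identical or adjacent are chained
transitively into one event; complexity = number of distinct participating
electrodes.  Chance levels come from 1000 surrogates (configurable) that
dither every crossing independently and uniformly within ±5 ms (clipped to
the session); a complexity c ≥ 2 is above chance when its observed count
exceeds the empirical (1−α) surrogate quantile, α = 0.05 one-sided,
unadjusted.  Complexity-1 "events" are isolated crossings, not synchronous
events: they stay in the histogram (so event sizes sum to the crossing
total) but are never tested.  Testing c = 1 would flag ~α of electrodes
with SP ≈ 1 under the null, because the observed c = 1 count is just one
more draw from the surrogate distribution.

SP = N_aboveChance / N_total per electrode, where N_total counts *all*
events the electrode participates in (including isolated crossings) — this
is the normalisation that removes the firing-rate bias — and N_aboveChance
counts its events at complexities flagged in its own per-electrode
histogram (a global-histogram mode is available).  Electrodes with SNR < 2
(when an SNR table is supplied) or crossing rate < 0.1/s are excluded from
the analysis entirely.  Pruning removes the argmax-SP electrode (ties →
lowest global ID) and recomputes synchrony, chance levels and SP on the
remainder, stopping at the removal budget or when no electrode exceeds the
SP floor (default 0.1; the floor sits between the null ceiling of ~2× the
chance-coincidence fraction and the participation of genuine group
members).  When a planted group is pruned, its final member necessarily
survives: once all partners are removed it participates in no synchronous
event, so n−1 of n members is the attainable recovery.

## Synthetic signal model

Each channel is white Gaussian noise (SD `noise_sd`, arbitrary volts) plus
shared reference-group noise (`common_reference_sd`, default 1.0× noise_sd)
plus a Poisson train (default 3 Hz) of biphasic ~1-ms spike waveforms with
peak 8× noise_sd.  The common-reference component matters: without it a
synthetic session has no common mode, and the sparse synchrofact direction
itself becomes the top principal component, so PC removal would absorb the
very artifacts under study.  Conversely, cross-talk dense within a single
reference group *is* largely absorbed by PC removal — planted groups should
span reference groups sparsely, as real cross-talk does.

Evoked responses are an amplitude-modulated 3150-Hz carrier (inside the
MUAe band; incommensurate with the sample grid).  The amplitude that
realises a planted SNR is solved deterministically: baseline MUAe mean/SD
per unit noise come from a 30-s fixed-seed simulation of the exact
background model, the plateau MUAe level for carrier amplitude A is the
closed form E|N(A·sinθ, σ²)| averaged over phase, and A is found by
root-finding so the SNR definition holds in expectation.  The realized SNR
of any finite session remains stochastic.  Checkerboard envelopes are a
plateau from onset+latency to offset; bar-sweep envelopes are temporal
Gaussians centred when the bar crosses the planted centre (plus latency,
which the opposing-direction estimator cancels) with
σ_t = rf_size / (2·1.65·√2·speed), chosen so the recovered `D` equals the
planted size for an isotropic RF.  With `noise_sd = 0` the background
spikes (whose amplitude scales with noise_sd) vanish and trials are
bit-identical; an explicit `evoked_amplitude` is then required.

Resting activity is modulated by eye state per channel (open epochs get
50% extra broadband amplitude and double the spike rate of closed epochs),
independently across channels.  Pupil traces rest at planted baseline
offsets (1.2/0.9 V) and drop toward them during scheduled closures and
random < 100-ms blinks (0.2 Hz default), with 150-ms ramps.

What the generator does *not* emulate: real spike waveform diversity,
oscillatory LFP structure, electrode impedance drift, eye-position signals
tied to actual gaze behaviour, clock drift, or amplitude-diverse cross-talk
coupling.  Passing recovery tests therefore demonstrates the correctness of
the pipeline's computations under the stated statistical model, not
performance bounds on real tissue data.

## Problem sizes used by the test and acceptance runs

Chosen as the package's own balance of statistical resolution and runtime:
printed constants on a 60-s, 2-array session; oracle equivalence on 1000
random ≤10-electrode rasters; SNR/latency recovery on 12 channels (four
each at SNR 1/3/8) × 100 trials; RF recovery on 64 channels at 20
trials/direction (planted SNR 8) and 4 trials/direction in the noiseless
limit (trials are identical there); synchrofact sensitivity on 20 seeded
128-electrode, 60-s sessions with one planted 30-electrode group at 1 Hz,
200 surrogates inside the pruning loop (1000 remains the default for
single analyses); specificity on a null 128-electrode session with 500
surrogates.

## Known limitations

- Bit-exact agreement with the reference processing of the deposited real
  data is not expected: the upstream filter direction and decimation phase
  are underdetermined, and this implementation fixes zero-phase filtering
  and phase-0 decimation.
- Blackrock `.ns6`/`.nev` readers are not included; real sessions must be
  converted to the HDF5 + CSV session layout first.
- The Gaussian RF model assumes a single compact response per sweep;
  multi-peaked or strongly skewed responses are flagged unmappable rather
  than decomposed.
- `D` is mildly underestimated at high SNR because the MUAe floor adds in
  quadrature under the response, sharpening the apparent Gaussian; centre
  estimates are unaffected (the bias is symmetric).
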