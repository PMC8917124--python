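# arrayqc

Preprocessing, signal derivation and quality control for chronic 1024-channel
Utah-array recordings from macaque visual cortex (V1/V4), together with a
synthetic session generator that plants ground truth for every quantity the
pipeline estimates.

In this acquisition setup, eight neural signal processors (NSPs) each record
128 channels at 30 kHz into separate files, plus a shared digital event
stream; NSP 1 also carries four analog eye channels.  `arrayqc` implements
the downstream computations such a dataset needs before any scientific
analysis:

- **Temporal alignment** of the eight per-NSP files by exact matching of the
  shared event-code sequence (codes 1–8 at 1-s intervals during rest;
  trial codes during tasks), then trimming to the common segment.
- **Signal derivation**: envelope multiunit activity (MUAe: band-pass
  500–9000 Hz, full-wave rectification, low-pass 200 Hz, all Butterworth
  order 4, ×30 decimation to 1 kHz) and local field potentials (LFP:
  low-pass 150 Hz, ×60 decimation to 500 Hz).
- **Channel lookup tables** mapping global (1–1024), per-NSP (1–128) and
  per-array (1–64) indices, with area (V1/V4) and reference-wire groups.
- **Evoked quality metrics** from a checkerboard task:
  `SNR = (Peak_stimulus_evoked − Mean_spontaneous) / SD_spontaneous`,
  with the spontaneous statistics from the 300 ms before stimulus onset,
  and the response latency as the first time the trial-averaged MUAe
  exceeds 2·SD_spontaneous for 5 consecutive 1-ms bins.
- **Receptive-field mapping** from bars sweeping in the four cardinal
  directions: Gaussian fits to the trial-averaged MUAe, response onset and
  offset at μ ∓ 1.65σ, boundaries from opposing-direction pairs, and size
  `D = sqrt((r−l)² + (t−b)²)`.
- **Eye-state segmentation** from pupil diameter (minimum-subtraction
  baseline correction, Euclidean combination of X/Y, 1-Hz block means,
  thresholding), validated by its Pearson correlation with array-mean MUAe.
- **Cross-talk (synchrofact) detection**: threshold crossings at −5× the
  robust noise level after band-passing and removal of each reference
  group's first principal component; transitive chaining of crossings in
  identical/adjacent 1/30-ms bins into events whose *complexity* is the
  number of distinct electrodes; a one-sided Monte Carlo test against
  ±5-ms dithering surrogates; per-electrode synchrofact participation
  `SP = N_aboveChance / N_total`; and greedy highest-SP pruning with chance
  levels recomputed after every removal.

The synthetic generator (`arrayqc.synthetic`) builds complete multi-NSP
sessions — staggered file starts, sync/trial event codes, background noise
plus Poisson spike trains, shared reference-wire noise, calibrated
stimulus-evoked responses, pupil traces with blinks and scheduled closures,
and injected cross-electrode artifacts — so the whole pipeline is testable
without any animal data.  Readers for the deposited Blackrock files are out
of scope; session I/O uses HDF5 + CSV.

## Worked example

```bash
array-qc simulate --task snr --duration 60 --n-arrays 2 \
    --electrodes-per-array 8 --seed 102 --out scratch/demo
array-qc snr --session scratch/demo --out scratch/demo_out
```

or, through the library (as in `analysis/03_evoked_quality.py`, which also
compares against the planted values):

```
$ python analysis/01_simulate_sessions.py && python analysis/03_evoked_quality.py
12 good channels (SNR >= 2) of 16; planted split predicts 12
median |SNR error| on responsive channels: 0.19
```

Sixteen channels were planted at SNRs {0.5, 2, 4, 8} (four each); the
pipeline recovers the 12 channels whose planted SNR reaches the quality
threshold of 2, with a median SNR error of 0.19 on the responsive channels.
The other drivers under `analysis/` run alignment/extraction, RF mapping
(`max centre error 0.006 dva` on a 16-channel bar-sweep session), eye-state
segmentation (planted 12-s closure recovered as 11 closed seconds at 1-Hz
resolution, r(open, MUAe) = 0.96) and synchrofact pruning (5 of a planted
6-electrode group removed; the final member participates in no synchronous
event once its partners are gone).  Tables land in `results/`.

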