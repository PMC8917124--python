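"""Per-channel evoked-response quality metrics from checkerboard-task MUAe.

SNR of a channel is defined on its 1-kHz MUAe around stimulus onset:

    SNR = (Peak_stimulus_evoked - Mean_spontaneous) / SD_spontaneous

where the spontaneous mean and SD are computed per trial over the 300-ms
window before stimulus onset and then averaged across trials, and the evoked
peak is the maximum of the 20-ms moving-average-smoothed trial-averaged MUAe
within the stimulus window.  Response latency is the first post-onset
millisecond bin at which the *unsmoothed* trial average exceeds the
spontaneous mean by more than twice the spontaneous SD for 5 consecutive
bins; latencies below 20 ms or above 150 ms are flagged as implausible
rather than reported numerically.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import SignalError
from .session import MUAE_RATE

BASELINE_MS = 300
SMOOTH_BINS = 20
SNR_THRESHOLD = 2.0
LATENCY_CONSECUTIVE = 5
LATENCY_SD_FACTOR = 2.0
LATENCY_MIN_MS = 20.0
LATENCY_MAX_MS = 150.0
MIN_TRIALS = 30

#: latency flags
LAT_NONE = "none"
LAT_TOO_EARLY = "too_early"
LAT_TOO_LATE = "too_late"
LAT_UNDEFINED = "undefined"


@dataclass
class EvokedSummary:
    """Eq.-style per-channel quality record for one checkerboard session."""
    channel: int
    mean_spontaneous: float
    sd_spontaneous: float
    peak_evoked: float
    snr: float                  # NaN when SD_spontaneous == 0
    snr_defined: bool
    latency_ms: float           # NaN unless latency_flag == "ok"
    latency_flag: str           # "ok" | none | too_early | too_late | undefined
    good: bool                  # snr >= threshold


def moving_average(x: np.ndarray, bins: int = SMOOTH_BINS) -> np.ndarray:
    """Centred moving average with edge truncation (shorter window at edges)."""
    x = np.asarray(x, dtype=float)
    kernel = np.ones(bins)
    sums = np.convolve(x, kernel, mode="same")
    counts = np.convolve(np.ones_like(x), kernel, mode="same")
    return sums / counts


def extract_trials(muae: np.ndarray, onset_bins: np.ndarray, pre_bins: int,
                   post_bins: int) -> np.ndarray:
    """Cut a (n_trials, pre+post) matrix out of one channel's 1-kHz MUAe."""
    muae = np.asarray(muae, dtype=float)
    onset_bins = np.asarray(onset_bins, dtype=np.int64)
    if ((onset_bins - pre_bins < 0) | (onset_bins + post_bins > muae.size)).any():
        raise SignalError("trial window extends beyond the MUAe trace")
    idx = onset_bins[:, None] + np.arange(-pre_bins, post_bins)[None, :]
    return muae[idx]


def compute_snr(trials: np.ndarray, onset_bin: int, stim_duration_ms: float,
                channel: int = 0, baseline_ms: float = BASELINE_MS,
                snr_threshold: float = SNR_THRESHOLD,
                rate: float = MUAE_RATE) -> EvokedSummary:
    """Evoked summary from a (n_trials, n_bins) MUAe matrix.

    ``onset_bin`` indexes stimulus onset within each trial row; each row must
    cover at least ``baseline_ms`` before onset and the stimulus window after.
    """
    trials = np.atleast_2d(np.asarray(trials, dtype=float))
    n_trials, n_bins = trials.shape
    base_bins = int(round(baseline_ms * rate / 1000.0))
    stim_bins = int(round(stim_duration_ms * rate / 1000.0))
    if onset_bin < base_bins:
        raise SignalError(f"trials must cover {baseline_ms} ms before onset")
    if onset_bin + stim_bins > n_bins:
        raise SignalError("trials must cover the full stimulus window")
    if n_trials < MIN_TRIALS:
        warnings.warn(f"only {n_trials} trials (< {MIN_TRIALS} recommended)",
                      stacklevel=2)

    baseline = trials[:, onset_bin - base_bins:onset_bin]
    mean_spont = float(baseline.mean(axis=1).mean())
    sd_spont = float(baseline.std(axis=1, ddof=1).mean())

    avg = trials.mean(axis=0)
    smoothed = moving_average(avg)
    peak = float(smoothed[onset_bin:onset_bin + stim_bins].max())

    if sd_spont > 0:
        snr = (peak - mean_spont) / sd_spont
        snr_defined = True
    else:
        snr, snr_defined = float("nan"), False

    lat_ms, lat_flag = compute_latency(avg, onset_bin, mean_spont, sd_spont,
                                       rate=rate)
    return EvokedSummary(
        channel=channel, mean_spontaneous=mean_spont, sd_spontaneous=sd_spont,
        peak_evoked=peak, snr=snr, snr_defined=snr_defined,
        latency_ms=lat_ms, latency_flag=lat_flag,
        good=bool(snr_defined and snr >= snr_threshold),
    )


def compute_latency(trial_avg: np.ndarray, onset_bin: int, mean_spontaneous: float,
                    sd_spontaneous: float, rate: float = MUAE_RATE,
                    consecutive: int = LATENCY_CONSECUTIVE,
                    sd_factor: float = LATENCY_SD_FACTOR,
                    min_ms: float = LATENCY_MIN_MS,
                    max_ms: float = LATENCY_MAX_MS) -> tuple[float, str]:
    """(latency_ms, flag) from the unsmoothed trial-averaged MUAe.

    The latency path deliberately uses the unsmoothed average (unlike the
    SNR peak), so a step response is not blurred across bins.
    """
    if sd_spontaneous <= 0:
        return float("nan"), LAT_UNDEFINED
    avg = np.asarray(trial_avg, dtype=float)
    above = (avg[onset_bin:] - mean_spontaneous) > sd_factor * sd_spontaneous
    if above.size < consecutive:
        return float("nan"), LAT_NONE
    window = np.lib.stride_tricks.sliding_window_view(above, consecutive)
    hits = np.flatnonzero(window.all(axis=1))
    if hits.size == 0:
        return float("nan"), LAT_NONE
    latency_ms = hits[0] * 1000.0 / rate
    if latency_ms < min_ms:
        return float("nan"), LAT_TOO_EARLY
    if latency_ms > max_ms:
        return float("nan"), LAT_TOO_LATE
    return float(latency_ms), "ok"
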