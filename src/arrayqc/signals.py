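"""MUAe and LFP derivation from 30-kHz raw traces.

MUAe (envelope multiunit activity): band-pass 500-9000 Hz (Butterworth order
4), full-wave rectification, low-pass 200 Hz (Butterworth order 4), then
decimation by 30 to a 1-kHz signal.  LFP: low-pass 150 Hz (Butterworth order
4), decimation by 60 to 500 Hz.

All filtering is zero-phase (forward-backward, ``sosfiltfilt``), so effective
attenuation is twice the one-pass order and derived features carry no filter
group delay; implementations using one-pass filtering will show a latency
offset relative to this one.  Decimation keeps indices {0, 30, 60, ...}
(MUAe) / {0, 60, ...} (LFP); the 200-Hz and 150-Hz low-passes double as the
anti-alias filters for the 1-kHz and 500-Hz output rates.  Band edges are
half-power (-3 dB) frequencies of the designed filters.

Outputs cover the full trace; the first/last 50 ms are edge-affected by the
filter warm-up and flagged as such in the provenance rather than trimmed.
"""
from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy import signal as sps

from .errors import SignalError
from .session import DerivedSignal, LFP_RATE, MUAE_RATE, RAW_RATE

MUAE_BAND = (500.0, 9000.0)
MUAE_LOWPASS = 200.0
MUAE_DECIMATE = 30
LFP_LOWPASS = 150.0
LFP_DECIMATE = 60
FILTER_ORDER = 4
EDGE_MS = 50.0


@lru_cache(maxsize=None)
def _sos_bandpass(low: float, high: float, fs: float, order: int = FILTER_ORDER):
    return sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")


@lru_cache(maxsize=None)
def _sos_lowpass(cut: float, fs: float, order: int = FILTER_ORDER):
    return sps.butter(order, cut, btype="lowpass", fs=fs, output="sos")


def _check_finite(x: np.ndarray, channel_ids=None) -> None:
    bad = ~np.isfinite(x)
    if bad.any():
        if x.ndim == 2 and channel_ids is not None:
            rows = np.flatnonzero(bad.any(axis=1))
            names = [int(np.asarray(channel_ids)[r]) for r in rows]
            raise SignalError(f"non-finite samples on channel(s) {names}")
        raise SignalError("non-finite samples in input trace")


def compute_muae(raw: np.ndarray, fs: float = RAW_RATE,
                 channel_ids: np.ndarray | None = None) -> DerivedSignal:
    """Envelope multiunit activity at 1 kHz from a 30-kHz trace.

    ``raw`` may be 1-D (one channel) or 2-D (channels x samples).
    """
    x = np.asarray(raw, dtype=np.float64)
    _check_finite(x, channel_ids)
    band = sps.sosfiltfilt(_sos_bandpass(*MUAE_BAND, fs), x, axis=-1)
    rect = np.abs(band)
    env = sps.sosfiltfilt(_sos_lowpass(MUAE_LOWPASS, fs), rect, axis=-1)
    out = env[..., ::MUAE_DECIMATE][..., : x.shape[-1] // MUAE_DECIMATE]
    return DerivedSignal(
        kind="MUAe", rate=MUAE_RATE, data=out, channel_ids=channel_ids,
        provenance={
            "bandpass_hz": list(MUAE_BAND), "lowpass_hz": MUAE_LOWPASS,
            "order": FILTER_ORDER, "zero_phase": True,
            "decimation": MUAE_DECIMATE, "source_rate_hz": fs,
            "edge_affected_ms": EDGE_MS,
        },
    )


def compute_lfp(raw: np.ndarray, fs: float = RAW_RATE,
                channel_ids: np.ndarray | None = None) -> DerivedSignal:
    """Local field potential at 500 Hz from a 30-kHz trace."""
    x = np.asarray(raw, dtype=np.float64)
    _check_finite(x, channel_ids)
    low = sps.sosfiltfilt(_sos_lowpass(LFP_LOWPASS, fs), x, axis=-1)
    out = low[..., ::LFP_DECIMATE][..., : x.shape[-1] // LFP_DECIMATE]
    return DerivedSignal(
        kind="LFP", rate=LFP_RATE, data=out, channel_ids=channel_ids,
        provenance={
            "lowpass_hz": LFP_LOWPASS, "order": FILTER_ORDER,
            "zero_phase": True, "decimation": LFP_DECIMATE,
            "source_rate_hz": fs, "edge_affected_ms": EDGE_MS,
        },
    )


def muae_sample_count(n_raw: int) -> int:
    """Output length of :func:`compute_muae` for an ``n_raw``-sample input."""
    return n_raw // MUAE_DECIMATE


def lfp_sample_count(n_raw: int) -> int:
    return n_raw // LFP_DECIMATE
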