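"""Preprocessing of raw floor-sensor recordings into a mono signal.

Four steps, applied in order:

1. zero-lag low-pass Butterworth filter per channel (10 Hz cutoff, order 5
   by default — the usual band for gait signals; forward-backward
   application gives zero phase and squares the magnitude response);
2. least-squares removal of the linear trend per channel;
3. zeroing of quiet channels, i.e. channels whose peak amplitude is small
   relative to the loudest channel and therefore carry only noise;
4. summation of the channels into a single mono signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from floorgait.dataset import Recording

__all__ = [
    "MonoSignal",
    "lowpass_zero_lag",
    "detrend_ls",
    "zero_quiet_channels",
    "preprocess",
]

DEFAULT_CUTOFF_HZ = 10.0
DEFAULT_ORDER = 5
DEFAULT_QUIET_REL = 0.05


@dataclass
class MonoSignal:
    """Channel-summed, filtered and detrended signal."""

    s: np.ndarray
    rate_hz: float = 100.0
    source_id: str = ""

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float).ravel()
        if not np.all(np.isfinite(self.s)):
            raise ValueError("mono signal contains non-finite values")

    def __len__(self) -> int:
        return self.s.size


def lowpass_zero_lag(
    x: np.ndarray,
    rate_hz: float,
    cutoff_hz: float = DEFAULT_CUTOFF_HZ,
    order: int = DEFAULT_ORDER,
) -> np.ndarray:
    """Zero-phase Butterworth low-pass via forward-backward filtering.

    The effective magnitude response is the square of the single-pass
    Butterworth response ``|H(f)|^2 = 1 / (1 + (f / cutoff)^(2 * order))``
    and the phase is identically zero.  Edges are handled by odd
    (anti-symmetric) extension of ``3 * (order + 1)`` samples, which
    passes straight lines through the filter exactly.
    """
    x = np.asarray(x, dtype=float)
    if cutoff_hz >= rate_hz / 2:
        raise ValueError(f"cutoff {cutoff_hz} Hz must be below Nyquist {rate_hz / 2} Hz")
    padlen = 3 * (order + 1)
    if x.shape[-1] <= padlen:
        raise ValueError(f"signal too short for order-{order} zero-lag filtering")
    sos = sps.butter(order, cutoff_hz, btype="low", fs=rate_hz, output="sos")
    return sps.sosfiltfilt(sos, x, axis=-1, padtype="odd", padlen=padlen)


def detrend_ls(x: np.ndarray) -> np.ndarray:
    """Remove the least-squares affine fit ``a * t + b`` along the last axis.

    Output is orthogonal to the constant and linear trends; applying it
    twice equals applying it once.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] < 2:
        raise ValueError("need at least 2 samples to detrend")
    return sps.detrend(x, axis=-1, type="linear")


def zero_quiet_channels(channels: np.ndarray, rel_threshold: float = DEFAULT_QUIET_REL) -> np.ndarray:
    """Zero every channel whose peak magnitude falls below ``rel_threshold``
    times the loudest channel's peak. An all-zero input passes through."""
    if not 0.0 < rel_threshold < 1.0:
        raise ValueError("rel_threshold must lie in (0, 1)")
    channels = np.atleast_2d(np.asarray(channels, dtype=float))
    peaks = np.max(np.abs(channels), axis=1)
    loudest = peaks.max()
    if loudest == 0.0:
        return channels.copy()
    out = channels.copy()
    out[peaks < rel_threshold * loudest] = 0.0
    return out


def preprocess(
    rec: Recording,
    cutoff_hz: float = DEFAULT_CUTOFF_HZ,
    order: int = DEFAULT_ORDER,
    rel_threshold: float = DEFAULT_QUIET_REL,
) -> MonoSignal:
    """Full four-step preprocessing of a recording into a mono signal."""
    filtered = lowpass_zero_lag(rec.channels, rec.rate_hz, cutoff_hz, order)
    detrended = detrend_ls(filtered)
    kept = zero_quiet_channels(detrended, rel_threshold)
    return MonoSignal(s=kept.sum(axis=0), rate_hz=rec.rate_hz, source_id=rec.id)
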