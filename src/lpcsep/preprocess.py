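"""Signal conditioning chain and windowing.

The chain applied to every session before feature extraction is: per-channel
zero-phase FIR bandpass (2.5-50 Hz by default), per-channel normalization to
unit power, then pointwise averaging of the channels into a single series.
Because each channel is rescaled to unit power before averaging, the chain is
invariant to per-channel amplifier gain.

Windowing utilities cut the averaged series into non-overlapping epochs or
into an expanding sequence of prefixes (the real-time emulation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .signal_io import Recording

__all__ = [
    "Epoch",
    "bandpass_zero_phase",
    "signal_power",
    "normalize_unit_power",
    "average_channels",
    "preprocess_session",
    "segment",
    "expanding_windows",
]

#: FIR length per Hz of sampling rate: ~1 Hz transition width with a Hamming
#: window, >= 40 dB stopband attenuation outside the passband skirts.
_TAPS_PER_HZ = 3.3


def _round_half_away(v: float) -> int:
    """Round to nearest integer, halves away from zero (platform-stable)."""
    return int(np.floor(v + 0.5)) if v >= 0 else -int(np.floor(-v + 0.5))


def default_numtaps(fs: float) -> int:
    """Default (odd) FIR length for the preprocessing bandpass at rate fs."""
    n = int(round(_TAPS_PER_HZ * fs))
    return n + 1 if n % 2 == 0 else n


def design_bandpass(fs: float, lo: float, hi: float, numtaps: int | None = None) -> np.ndarray:
    """Linear-phase Hamming-window FIR bandpass taps for [lo, hi] Hz."""
    if not 0 < lo < hi < fs / 2:
        raise ValueError(f"need 0 < lo < hi < fs/2, got lo={lo}, hi={hi}, fs={fs}")
    if numtaps is None:
        numtaps = default_numtaps(fs)
    if numtaps % 2 == 0:
        raise ValueError("numtaps must be odd for an exactly zero-phase filter")
    return sps.firwin(numtaps, [lo, hi], pass_zero=False, window="hamming", fs=fs)


def bandpass_zero_phase(
    x: np.ndarray, fs: float, lo: float = 2.5, hi: float = 50.0,
    numtaps: int | None = None,
) -> np.ndarray:
    """Zero-phase FIR bandpass.

    A symmetric (linear-phase) windowed-sinc filter is applied in a single
    pass and its known group delay removed by centering the convolution, so
    passband components come out neither delayed nor phase-shifted.  Edges
    are implicitly zero-padded.  Output length equals input length.
    """
    x = np.asarray(x, dtype=float)
    h = design_bandpass(fs, lo, hi, numtaps)
    if x.shape[-1] <= len(h):
        raise ValueError(
            f"series of {x.shape[-1]} samples is shorter than the "
            f"{len(h)}-tap filter; use a longer series or pass a smaller numtaps"
        )
    # overlap-add convolution: fast for long series, exact 'same' alignment
    h = h.reshape((1,) * (x.ndim - 1) + (-1,))
    return sps.oaconvolve(x, h, mode="same", axes=-1)


def signal_power(x: np.ndarray) -> float:
    """Mean squared sample value, P = (1/L) * sum |x(n)|^2."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("cannot compute power of an empty series")
    return float(np.mean(x**2))


def normalize_unit_power(x: np.ndarray) -> np.ndarray:
    """Rescale a series to unit power (divide by sqrt of its mean square)."""
    x = np.asarray(x, dtype=float)
    p = signal_power(x)
    if p == 0.0:
        raise ValueError("cannot normalize a zero-power (all-zero) series")
    return x / np.sqrt(p)


def average_channels(rec: Recording | np.ndarray) -> np.ndarray:
    """Pointwise arithmetic mean across channels."""
    if isinstance(rec, Recording):
        chans = rec.channels
    else:
        chans = rec
        if isinstance(chans, (list, tuple)):
            lengths = {len(np.atleast_1d(c)) for c in chans}
            if len(lengths) > 1:
                raise ValueError(f"channel lengths differ: {sorted(lengths)}")
        chans = np.atleast_2d(np.asarray(chans, dtype=float))
    return chans.mean(axis=0)


def preprocess_session(
    rec: Recording, lo: float = 2.5, hi: float = 50.0,
    numtaps: int | None = None,
) -> np.ndarray:
    """Full chain: bandpass each channel, normalize to unit power, average.

    Returns the single combined series used for all downstream features.
    """
    filtered = bandpass_zero_phase(rec.channels, rec.fs, lo, hi, numtaps)
    normalized = np.stack([normalize_unit_power(ch) for ch in filtered])
    return average_channels(normalized)


@dataclass
class Epoch:
    """A contiguous segment of a session, analyzed as one unit."""

    samples: np.ndarray
    fs: float
    start_s: float
    epoch_index: int
    epoch_length_s: float


def segment(x: np.ndarray, fs: float, epoch_length_min: float) -> list[Epoch]:
    """Cut a series into maximal non-overlapping epochs from t=0.

    A trailing remainder shorter than one epoch is discarded (a 40-min
    session at 3-min epochs yields 13 epochs with 60 s unused).
    """
    if epoch_length_min <= 0:
        raise ValueError("epoch_length_min must be positive")
    x = np.asarray(x, dtype=float)
    epoch_length_s = epoch_length_min * 60.0
    n = _round_half_away(epoch_length_s * fs)
    count = len(x) // n
    if count == 0:
        warnings.warn(
            f"series of {len(x)/fs:.1f} s is shorter than one "
            f"{epoch_length_s:.0f}-s epoch; returning no epochs",
            stacklevel=2,
        )
        return []
    return [
        Epoch(
            samples=x[k * n : (k + 1) * n],
            fs=fs,
            start_s=k * n / fs,
            epoch_index=k,
            epoch_length_s=epoch_length_s,
        )
        for k in range(count)
    ]


def expanding_windows(
    x: np.ndarray, fs: float, init_s: float = 1.0, step_s: float = 1.0
):
    """Yield the expanding sequence of prefixes of a series.

    Window k holds the first round((init_s + k*step_s) * fs) samples;
    emission stops once the series is exhausted.  Windows are views, not
    copies.
    """
    if not (init_s >= step_s > 0):
        raise ValueError("need init_s >= step_s > 0")
    x = np.asarray(x, dtype=float)
    k = 0
    while True:
        n = _round_half_away((init_s + k * step_s) * fs)
        if n > len(x):
            return
        yield x[:n]
        k += 1
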