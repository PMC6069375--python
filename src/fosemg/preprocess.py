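"""Channel repair, rectification, envelope extraction and normalization.

The envelope chain is the classical amplitude estimator for surface EMG:
full-wave rectification followed by a low-pass FIR filter (51-tap Hanning
window, 5 Hz cutoff by default). The filter is applied forward-backward
(zero phase) so envelopes stay aligned with the simultaneously sampled
force trace.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .core import (
    ActivationSignal,
    EnvelopeMatrix,
    InvalidArgumentError,
    SignalMatrix,
)

DEFAULT_CUTOFF_HZ = 5.0
DEFAULT_ORDER = 50  # taps - 1


def replace_bad_channels(s: SignalMatrix, bad: list[int]) -> SignalMatrix:
    """Replace bad channels by a copy of an adjacent good electrode.

    Each bad channel is overwritten with the row of its nearest good grid
    neighbor in the 4-neighborhood (up/down/left/right); ties are broken by
    the smallest channel index. Raises if a bad channel has no good neighbor
    or every channel is bad.
    """
    grid = s.grid
    bad_set = set(int(b) for b in bad)
    for b in bad_set:
        if not (0 <= b < s.n_channels):
            raise InvalidArgumentError(f"bad channel {b} out of range")
    if len(bad_set) >= s.n_channels:
        raise InvalidArgumentError("all channels marked bad; nothing to repair from")
    out = s.data.copy()
    for b in sorted(bad_set):
        row, col = grid.channel_position(b)
        neighbors = []
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            r, c = row + dr, col + dc
            if 0 <= r < grid.n_rows and 0 <= c < grid.n_cols:
                idx = grid.channel_index(r, c)
                if idx not in bad_set:
                    neighbors.append(idx)
        if not neighbors:
            raise InvalidArgumentError(
                f"bad channel {b} has no good neighbor in the 4-neighborhood"
            )
        out[b] = s.data[min(neighbors)]
    return SignalMatrix(out, s.sampling_rate, grid, s.muscle_label)


def rectify(s: SignalMatrix) -> SignalMatrix:
    """Full-wave rectification (elementwise absolute value)."""
    return SignalMatrix(np.abs(s.data), s.sampling_rate, s.grid, s.muscle_label)


def envelope_fir(
    sampling_rate: float,
    cutoff: float = DEFAULT_CUTOFF_HZ,
    order: int = DEFAULT_ORDER,
) -> np.ndarray:
    """Design the Hanning-window low-pass FIR used for envelope extraction.

    Returns ``order + 1`` taps with exact unit DC gain. The raised-cosine
    window includes its zero endpoints.
    """
    if cutoff <= 0 or cutoff >= sampling_rate / 2:
        raise InvalidArgumentError("cutoff must lie in (0, Nyquist)")
    if order < 2:
        raise InvalidArgumentError("filter order must be at least 2")
    return sps.firwin(order + 1, cutoff, window="hann", fs=sampling_rate)


def lowpass_envelope(
    x: np.ndarray,
    sampling_rate: float,
    cutoff: float = DEFAULT_CUTOFF_HZ,
    order: int = DEFAULT_ORDER,
) -> np.ndarray:
    """Zero-phase low-pass filtering along the last axis.

    The forward-backward application doubles the stopband attenuation of the
    designed FIR and leaves no group delay, keeping envelopes aligned with
    the force trace.
    """
    arr = np.asarray(x, dtype=float)
    n = arr.shape[-1]
    if n <= order:
        raise InvalidArgumentError(
            f"signal length {n} must exceed the filter order {order}"
        )
    taps = envelope_fir(sampling_rate, cutoff, order)
    padlen = min(3 * order, n - 1)
    return sps.filtfilt(taps, [1.0], arr, axis=-1, padlen=padlen)


def envelope(s: SignalMatrix, cutoff: float = DEFAULT_CUTOFF_HZ, order: int = DEFAULT_ORDER) -> EnvelopeMatrix:
    """Rectify then low-pass filter every channel.

    Tiny negative filter undershoot is clipped to keep envelopes nonnegative.
    """
    env = lowpass_envelope(np.abs(s.data), s.sampling_rate, cutoff, order)
    return EnvelopeMatrix(np.clip(env, 0.0, None), s.sampling_rate)


def normalize_to_max(x) -> np.ndarray:
    """Scale a time series so its maximum is exactly 1."""
    arr = np.asarray(x, dtype=float).ravel()
    m = arr.max() if arr.size else 0.0
    if not np.isfinite(m) or m <= 0:
        raise InvalidArgumentError("cannot normalize: maximum is not positive")
    return arr / m


def avg_envelope(
    s: SignalMatrix,
    cutoff: float = DEFAULT_CUTOFF_HZ,
    order: int = DEFAULT_ORDER,
) -> ActivationSignal:
    """AVG-ENVLP baseline: the mean of all channel envelopes of one grid."""
    env = envelope(s, cutoff, order)
    return ActivationSignal(
        env.data.mean(axis=0), muscle_label=s.muscle_label, source_method="avg"
    )
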