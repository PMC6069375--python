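"""Shared data containers for the HD-SEMG force-estimation pipeline.

The containers mirror the stages of the pipeline: a :class:`SignalMatrix`
holds raw multichannel surface EMG from one electrode grid, an
:class:`EnvelopeMatrix` holds its rectified low-pass envelopes, and an
:class:`ActivationSignal` is the single nonnegative time series per muscle
that drives the force model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class InvalidArgumentError(ValueError):
    """An argument violates a documented precondition."""


class ConvergenceError(RuntimeError):
    """An iterative algorithm failed to converge.

    Attributes
    ----------
    n_iter : int
        Number of iterations performed before giving up.
    """

    def __init__(self, message: str, n_iter: int):
        super().__init__(message)
        self.n_iter = n_iter


@dataclass(frozen=True)
class GridSpec:
    """Geometry of one high-density electrode grid.

    Channels are numbered row-major: channel ``r * n_cols + c`` sits at grid
    position ``(r, c)``. The inter-electrode distance is metadata only; no
    computation depends on it.
    """

    n_rows: int = 4
    n_cols: int = 8
    inter_electrode_distance_mm: float = 10.0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise InvalidArgumentError("grid dimensions must be positive")

    @property
    def n_channels(self) -> int:
        return self.n_rows * self.n_cols

    def channel_index(self, row: int, col: int) -> int:
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise InvalidArgumentError(f"position ({row}, {col}) outside grid")
        return row * self.n_cols + col

    def channel_position(self, channel: int) -> tuple[int, int]:
        if not (0 <= channel < self.n_channels):
            raise InvalidArgumentError(f"channel {channel} outside grid")
        return divmod(channel, self.n_cols)


@dataclass(frozen=True)
class ProtocolSpec:
    """Timing and intensity of one isometric contraction trial.

    The default protocol is a 6 s trial sampled at 1000 Hz: force ramps
    linearly from zero to ``target_level`` (a fraction of maximum voluntary
    contraction) over the first 3 s and is held there for the remaining 3 s.
    """

    sampling_rate: float = 1000.0
    trial_duration: float = 6.0
    ramp_duration: float = 3.0
    target_level: float = 0.4
    n_repetitions: int = 7

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise InvalidArgumentError("sampling_rate must be positive")
        if self.trial_duration <= 0 or self.ramp_duration <= 0:
            raise InvalidArgumentError("durations must be positive")
        if self.ramp_duration > self.trial_duration:
            raise InvalidArgumentError("ramp_duration must not exceed trial_duration")
        if not (0.0 < self.target_level <= 1.0):
            raise InvalidArgumentError("target_level must be in (0, 1]")
        if self.n_repetitions < 1:
            raise InvalidArgumentError("n_repetitions must be at least 1")
        n = self.sampling_rate * self.trial_duration
        if abs(n - round(n)) > 1e-9:
            raise InvalidArgumentError("sampling_rate * trial_duration must be an integer")

    @property
    def n_samples(self) -> int:
        return int(round(self.sampling_rate * self.trial_duration))

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate


def _as_finite_2d(data: np.ndarray, what: str) -> np.ndarray:
    arr = np.asarray(data, dtype=float)
    if arr.ndim != 2:
        raise InvalidArgumentError(f"{what} must be 2-D (channels x samples)")
    if not np.all(np.isfinite(arr)):
        raise InvalidArgumentError(f"{what} contains non-finite values")
    return arr


@dataclass
class SignalMatrix:
    """Raw multichannel SEMG from one grid: channels x samples."""

    data: np.ndarray
    sampling_rate: float
    grid: GridSpec = field(default_factory=GridSpec)
    muscle_label: str = "agonist"

    def __post_init__(self) -> None:
        self.data = _as_finite_2d(self.data, "signal matrix")
        if self.sampling_rate <= 0:
            raise InvalidArgumentError("sampling_rate must be positive")
        if self.data.shape[0] != self.grid.n_channels:
            raise InvalidArgumentError(
                f"{self.data.shape[0]} rows but grid has {self.grid.n_channels} channels"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class EnvelopeMatrix:
    """Nonnegative per-channel envelopes: channels x samples."""

    data: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        self.data = _as_finite_2d(self.data, "envelope matrix")
        if np.any(self.data < 0):
            raise InvalidArgumentError("envelope values must be nonnegative")
        if self.sampling_rate <= 0:
            raise InvalidArgumentError("sampling_rate must be positive")


@dataclass
class ActivationSignal:
    """One nonnegative activation time series for one muscle.

    This is the input to the force model: either the average channel envelope
    (AVG-ENVLP baseline) or the normalized sum of factorization activation
    curves.
    """

    values: np.ndarray
    muscle_label: str = "agonist"
    source_method: str = "unknown"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(self.values)):
            raise InvalidArgumentError("activation signal contains non-finite values")
        if np.any(self.values < 0):
            raise InvalidArgumentError("activation signal must be nonnegative")

    def __len__(self) -> int:
        return self.values.size


def signal_values(x) -> np.ndarray:
    """Coerce an ActivationSignal or array-like to a 1-D float array."""
    if isinstance(x, ActivationSignal):
        return x.values
    return np.asarray(x, dtype=float).ravel()
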