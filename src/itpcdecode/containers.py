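"""In-memory containers for trial-resolved epoch data.

Arrays are always ``(n_trials, n_locations, n_times)``; ``locations`` are
sensors before source projection and source-space vertices afterwards.
Times are in milliseconds relative to stimulus onset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

from .bands import BandSpec

__all__ = ["LabeledEpochs", "AnalyticEpochs"]


def _validate_epochs(obj: "LabeledEpochs | AnalyticEpochs") -> None:
    if obj.data.ndim != 3:
        raise ValueError(
            f"epoch data must be (n_trials, n_locations, n_times), got shape {obj.data.shape}"
        )
    if len(obj.labels) != obj.data.shape[0]:
        raise ValueError(
            f"label count {len(obj.labels)} does not match trial count {obj.data.shape[0]}"
        )
    if len(obj.times) != obj.data.shape[2]:
        raise ValueError(
            f"time axis length {len(obj.times)} does not match data {obj.data.shape[2]}"
        )
    dt = np.diff(obj.times)
    if obj.data.shape[2] > 1:
        if np.any(dt <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValueError("times must be uniformly sampled")
    if obj.sampling_rate <= 0:
        raise ValueError("sampling_rate must be positive")


@dataclass
class LabeledEpochs:
    """Real-valued single-trial epochs with per-trial condition labels.

    Parameters
    ----------
    data
        ``(n_trials, n_locations, n_times)`` float array.
    labels
        Per-trial condition label (one entry per trial).
    times
        Epoch time axis in ms, strictly increasing and uniform.
    sampling_rate
        Sampling rate in Hz.
    subject
        Subject identifier the epochs belong to.
    band
        Set after band-pass filtering; ``None`` for broadband data.
    """

    data: np.ndarray
    labels: np.ndarray
    times: np.ndarray
    sampling_rate: float
    subject: str = "s00"
    band: BandSpec | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels)
        self.times = np.asarray(self.times, dtype=float)
        _validate_epochs(self)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_locations(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    def with_data(self, data: np.ndarray, **changes: Any) -> "LabeledEpochs":
        """Copy of the container with ``data`` (and optional metadata) replaced."""
        return replace(self, data=data, **changes)


@dataclass
class AnalyticEpochs:
    """Complex analytic (band-limited + Hilbert) single-trial epochs.

    ``np.angle(data)`` is instantaneous phase, ``np.abs(data)`` the
    envelope.  ``edge_ms`` flags the span at either epoch edge where the
    transform is contaminated by boundary effects; phase statistics there
    should be treated with caution.
    """

    data: np.ndarray
    labels: np.ndarray
    times: np.ndarray
    sampling_rate: float
    band: BandSpec
    subject: str = "s00"
    edge_ms: float = 50.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=complex)
        self.labels = np.asarray(self.labels)
        self.times = np.asarray(self.times, dtype=float)
        _validate_epochs(self)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_locations(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    def with_data(self, data: np.ndarray, **changes: Any) -> "AnalyticEpochs":
        return replace(self, data=data, **changes)
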