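"""Shared fixtures and small builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from itpcdecode import (
    AnalyticEpochs,
    CANONICAL_BANDS,
    ContrastSpec,
    DecodingDataset,
    ITPCMap,
    LabeledEpochs,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def grid_orientation_oracle(L, c_inv, step_deg=1.0):
    """Brute-force max-power orientation over a 1-degree sphere grid."""
    theta = np.deg2rad(np.arange(0.0, 180.0 + step_deg, step_deg))
    phi = np.deg2rad(np.arange(0.0, 360.0, step_deg))
    tt, pp = np.meshgrid(theta, phi, indexing="ij")
    dirs = np.stack(
        [np.sin(tt) * np.cos(pp), np.sin(tt) * np.sin(pp), np.cos(tt)], axis=-1
    ).reshape(-1, 3)
    A = L.T @ c_inv @ L
    quad = np.einsum("ni,ij,nj->n", dirs, A, dirs)
    return dirs[np.argmin(quad)]


def angle_deg(u, v):
    c = abs(float(np.dot(u, v))) / (np.linalg.norm(u) * np.linalg.norm(v))
    return np.degrees(np.arccos(np.clip(c, -1, 1)))


def make_epochs(
    data: np.ndarray, sampling_rate: float = 500.0, t0: float = -100.0, **kw
) -> LabeledEpochs:
    n_trials, _, n_times = data.shape
    times = t0 + np.arange(n_times) * 1000.0 / sampling_rate
    labels = kw.pop("labels", np.array(["a"] * n_trials))
    return LabeledEpochs(
        data=data, labels=labels, times=times, sampling_rate=sampling_rate, **kw
    )


def make_analytic(
    data: np.ndarray,
    sampling_rate: float = 500.0,
    band: str = "alpha",
    labels: np.ndarray | None = None,
) -> AnalyticEpochs:
    """Wrap a complex (trials, locations, times) array as AnalyticEpochs."""
    n_trials, _, n_times = data.shape
    if labels is None:
        labels = np.array(["a"] * n_trials)
    times = np.arange(n_times) * 1000.0 / sampling_rate
    return AnalyticEpochs(
        data=data,
        labels=labels,
        times=times,
        sampling_rate=sampling_rate,
        band=CANONICAL_BANDS[band],
    )


def phasor_trials(phases: np.ndarray, amplitudes: np.ndarray | None = None) -> AnalyticEpochs:
    """Analytic container from per-trial phase angles (one location, one timepoint)."""
    phases = np.asarray(phases, dtype=float)
    z = np.exp(1j * phases)
    if amplitudes is not None:
        z = np.asarray(amplitudes) * z
    return make_analytic(z.reshape(-1, 1, 1))


def toy_dataset(
    rng: np.random.Generator,
    n_subjects: int = 17,
    n_features: int = 6,
    n_times: int = 4,
    effect: float = 0.0,
    effect_features: slice = slice(0, 2),
    effect_times: slice | None = None,
    t0: float = 0.0,
) -> DecodingDataset:
    """Across-subject 1:1 dataset with optional additive class effect."""
    contrast = ContrastSpec(
        name="toy",
        classes={"a": "A", "b": "B"},
        positive_class="A",
        dp_ms=0.0,
    )
    n_rows = 2 * n_subjects
    X = rng.normal(size=(n_rows, n_features, n_times))
    y = np.tile([1, 0], n_subjects)
    if effect:
        sl_t = effect_times if effect_times is not None else slice(None)
        X[np.flatnonzero(y == 1)[:, None], np.arange(n_features)[effect_features], sl_t] += effect
    groups = np.repeat([f"s{i:02d}" for i in range(n_subjects)], 2)
    times = t0 + np.arange(n_times) * 2.0  # 2-ms steps
    return DecodingDataset(
        X=X,
        y=y,
        groups=groups,
        times=times,
        contrast=contrast,
        band=CANONICAL_BANDS["gamma_low"],
    )
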