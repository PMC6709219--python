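"""LCMV beamformer: spatial filters from unregularized data covariance.

The filter for a source with oriented gain l is the classic unit-gain
minimum-variance solution

    w = (lᵀ C⁻¹ l)⁻¹ lᵀ C⁻¹,

with the dipole orientation chosen to maximize output power and the
output scaled as a neural activity index (NAI): source power divided by
the power the filter would pass from white sensor noise.  The covariance
is pooled over all trials and timepoints of the real band-passed data
and is *not* regularized; rank-deficient covariances are handled by a
Moore–Penrose pseudo-inverse with a relative singular-value cutoff.
The filter is then applied to the complex analytic single-trial data.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .containers import AnalyticEpochs, LabeledEpochs
from .simulate import LeadField

__all__ = [
    "Covariance",
    "SpatialFilter",
    "data_covariance",
    "max_power_orientation",
    "lcmv_filter",
    "apply_filter",
]

logger = logging.getLogger(__name__)

#: relative singular-value cutoff for pseudo-inversion of the covariance
PINV_RCOND = 1e-10


@dataclass(frozen=True)
class Covariance:
    """Sensor covariance matrix with bookkeeping of the samples used."""

    matrix: np.ndarray
    n_samples_used: int

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError(f"covariance must be square, got {m.shape}")
        if not np.allclose(m, m.T, atol=1e-10 * max(1.0, np.abs(m).max())):
            raise ValueError("covariance must be symmetric")

    @property
    def n_sensors(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class SpatialFilter:
    """Unit-gain LCMV weights with orientations and NAI scaling.

    ``weights[source, sensor]`` satisfies ``weights[s] @ l_s == 1`` for
    every valid source; ``nai_scale[s]`` is the per-source amplitude
    factor implementing the white-noise NAI normalization (applied on
    top of the unit-gain weights when the filter is used).  Sources whose
    oriented gain vanished are marked invalid and excluded downstream.
    """

    weights: np.ndarray
    orientations: np.ndarray
    nai_scale: np.ndarray
    valid: np.ndarray

    @property
    def n_sources(self) -> int:
        return self.weights.shape[0]


def data_covariance(epochs: LabeledEpochs) -> Covariance:
    """Covariance pooled over all trials and all timepoints.

    Channels are mean-removed over the pooled samples; no regularization
    is added.  If there are fewer pooled samples than sensors (or the
    matrix is otherwise rank deficient) the condition is logged — the
    inversion downstream uses a pseudo-inverse, so the filter remains
    defined.
    """
    if epochs.n_trials < 2:
        raise ValueError("covariance needs at least 2 trials")
    # (sensors, trials*times)
    x = np.transpose(epochs.data, (1, 0, 2)).reshape(epochs.n_locations, -1)
    x = x - x.mean(axis=1, keepdims=True)
    n = x.shape[1]
    cov = (x @ x.T) / (n - 1)
    cov = (cov + cov.T) / 2.0
    if n < epochs.n_locations:
        logger.warning(
            "covariance from %d samples for %d sensors is rank deficient", n, epochs.n_locations
        )
    else:
        rank = np.linalg.matrix_rank(cov, tol=PINV_RCOND * np.abs(cov).max())
        if rank < epochs.n_locations:
            logger.warning(
                "covariance rank %d < %d sensors (rank deficient)", rank, epochs.n_locations
            )
    return Covariance(matrix=cov, n_samples_used=n)


def _fix_sign(vec: np.ndarray) -> np.ndarray:
    """Sign convention: the largest-magnitude component is positive."""
    i = int(np.argmax(np.abs(vec)))
    return -vec if vec[i] < 0 else vec


def max_power_orientation(source_gains: np.ndarray, cov_inverse: np.ndarray) -> np.ndarray:
    """Dipole orientation maximizing unit-gain beamformer output power.

    Output power at orientation η is (ηᵀ Lᵀ C⁻¹ L η)⁻¹, so the optimum is
    the eigenvector of the 3×3 matrix Lᵀ C⁻¹ L with the *smallest*
    eigenvalue.  Degenerate (near-tied) spectra fall back to the
    lexicographically smallest coordinate axis spanning the optimal
    subspace; a singular 3×3 matrix falls back to the largest-gain axis
    with a warning.  The sign makes the largest-magnitude component
    positive.
    """
    L = np.asarray(source_gains, dtype=float)
    if L.ndim != 2 or L.shape[1] != 3:
        raise ValueError(f"source gains must be (sensors, 3), got {L.shape}")
    A = L.T @ cov_inverse @ L
    A = (A + A.T) / 2.0
    scale = np.abs(A).max()
    tol = 1e-9 * scale if scale > 0 else 0.0
    vals, vecs = np.linalg.eigh(A) if np.isfinite(scale) and scale > 0 else (None, None)
    if vals is None or vals[0] <= tol:
        # a zero-power direction means the 3x3 problem is singular; the
        # minimum-eigenvalue direction would have zero gain entirely
        warnings.warn("singular orientation matrix; falling back to largest-gain axis")
        return _fix_sign(np.eye(3)[int(np.argmax(np.linalg.norm(L, axis=0)))])
    # near-tied smallest eigenvalues: prefer coordinate axes inside the
    # optimal eigenspace, smallest index first
    tied = np.flatnonzero(vals <= vals[0] + tol)
    if len(tied) > 1:
        basis = vecs[:, tied]
        for axis in range(3):
            e = np.zeros(3)
            e[axis] = 1.0
            if np.linalg.norm(basis @ (basis.T @ e)) >= 1.0 - 1e-6:
                return e
    return _fix_sign(vecs[:, 0])


def lcmv_filter(leadfield: LeadField, cov: Covariance) -> SpatialFilter:
    """Unit-gain LCMV filter with max-power orientations and NAI scaling.

    The white-noise level for the NAI is taken as the smallest nonzero
    covariance eigenvalue (the standard convention when no separate noise
    recording exists); ``nai_scale[s] = 1/√(σ²·wᵀw)`` so that scaled
    outputs are in noise-power units.
    """
    if leadfield.n_sensors != cov.n_sensors:
        raise ValueError(
            f"lead field has {leadfield.n_sensors} sensors, covariance {cov.n_sensors}"
        )
    c_inv = np.linalg.pinv(cov.matrix, rcond=PINV_RCOND, hermitian=True)
    eigvals = np.linalg.eigvalsh(cov.matrix)
    nonzero = eigvals[eigvals > PINV_RCOND * max(eigvals.max(), 0) + 0.0]
    noise_var = float(nonzero.min()) if nonzero.size else 1.0
    rank = int((eigvals > PINV_RCOND * eigvals.max()).sum()) if eigvals.max() > 0 else 0
    logger.info("lcmv_filter: covariance effective rank %d / %d", rank, cov.n_sensors)

    n_src = leadfield.n_sources
    weights = np.zeros((n_src, leadfield.n_sensors))
    orientations = np.zeros((n_src, 3))
    nai_scale = np.zeros(n_src)
    valid = np.ones(n_src, dtype=bool)
    for s in range(n_src):
        L = leadfield.gains[:, s, :]
        eta = max_power_orientation(L, c_inv)
        l = L @ eta
        denom = float(l @ c_inv @ l)
        if np.linalg.norm(l) == 0 or not np.isfinite(denom) or denom <= 0:
            valid[s] = False
            logger.warning("source %d has zero oriented gain; marked invalid", s)
            continue
        w = (c_inv @ l) / denom
        # sign is unidentifiable; fix it so the largest-|w| entry is positive
        if w[int(np.argmax(np.abs(w)))] < 0:
            w = -w
            eta = -eta
        weights[s] = w
        orientations[s] = eta
        nai_scale[s] = 1.0 / np.sqrt(noise_var * float(w @ w))
    return SpatialFilter(
        weights=weights, orientations=orientations, nai_scale=nai_scale, valid=valid
    )


def apply_filter(
    spatial_filter: SpatialFilter, analytic: AnalyticEpochs, nai: bool = True
) -> AnalyticEpochs:
    """Project complex single-trial sensor data into source space.

    Linear map ``source[trial, s, t] = w_s · sensor[trial, :, t]``; with
    ``nai=True`` (default) each source series is additionally scaled by
    its NAI factor.  Scaling is real and positive, so phase — and hence
    ITPC — is unaffected.  Invalid sources come out as zeros.
    """
    if analytic.n_locations != spatial_filter.weights.shape[1]:
        raise ValueError(
            f"filter expects {spatial_filter.weights.shape[1]} sensors, "
            f"data has {analytic.n_locations}"
        )
    w = spatial_filter.weights
    if nai:
        w = w * spatial_filter.nai_scale[:, np.newaxis]
    source = np.einsum("sk,nkt->nst", w, analytic.data)
    return analytic.with_data(source)
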