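"""Band-pass filtering, analytic-signal construction, and temporal smoothing.

Phase statistics tolerate no phase distortion from the filter, so the
band-pass is a linear-phase FIR applied with its group delay compensated
(equivalently: zero-phase).  Epochs are short relative to narrow-band
filter lengths, so both the filter and the Hilbert transform operate on
reflection-padded copies that are trimmed back to the original length.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy import signal as sps

from .bands import BandSpec, band as _resolve_band
from .containers import AnalyticEpochs, LabeledEpochs

__all__ = ["bandpass_epochs", "analytic_signal", "rolling_mean", "design_bandpass"]

#: fraction of the lower band edge used as the filter transition width
TRANSITION_FRACTION = 0.15

#: span (ms) at each epoch edge flagged as contaminated by boundary effects
EDGE_CONTAMINATED_MS = 50.0


def design_bandpass(band_spec: BandSpec, sampling_rate: float) -> np.ndarray:
    """Design the linear-phase FIR band-pass used by :func:`bandpass_epochs`.

    Hamming-window FIR with cutoffs at the band edges and a transition
    width of 15% of the lower edge (the narrower of the two edges, which
    dominates the required filter order).
    """
    nyq = sampling_rate / 2.0
    if band_spec.high >= nyq:
        raise ValueError(
            f"band {band_spec.name} upper edge {band_spec.high} Hz is not below "
            f"the Nyquist frequency {nyq} Hz"
        )
    width = TRANSITION_FRACTION * band_spec.low
    # Hamming-window design rule of thumb: ~3.3 / (normalized transition width)
    numtaps = int(np.ceil(3.3 * sampling_rate / width))
    numtaps += 1 - numtaps % 2  # odd length -> integer group delay, type-I FIR
    return sps.firwin(
        numtaps, [band_spec.low, band_spec.high], pass_zero=False, fs=sampling_rate
    )


def _reflect_pad(x: np.ndarray, pad: int) -> np.ndarray:
    """Reflection-pad the last axis by ``pad`` samples, tiling if needed."""
    n = x.shape[-1]
    if n < 2:
        raise ValueError("cannot reflection-pad a series shorter than 2 samples")
    out = x
    remaining = pad
    # np.pad(mode="reflect") caps the pad at n-1; apply repeatedly for
    # filters longer than the epoch itself.
    while remaining > 0:
        step = min(remaining, out.shape[-1] - 1)
        width = [(0, 0)] * (out.ndim - 1) + [(step, step)]
        out = np.pad(out, width, mode="reflect")
        remaining -= step
    return out


def _zero_phase_filter(x: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Apply an odd-length symmetric FIR with zero net phase shift."""
    pad = len(taps)  # generous: covers the group delay and ringing
    padded = _reflect_pad(x, pad)
    # odd symmetric taps + mode="same" realigns the integer group delay
    filtered = sps.fftconvolve(padded, taps[np.newaxis, np.newaxis, :], mode="same")
    return filtered[..., pad:-pad]


def bandpass_epochs(epochs: LabeledEpochs, band_spec: BandSpec | str) -> LabeledEpochs:
    """Zero-phase band-pass of single-trial epochs into one canonical band.

    The per-trial signal is filtered as is — the trial-average (evoked)
    component is deliberately *not* subtracted, because stimulus-locked
    phase alignment is exactly what the downstream ITPC statistic
    measures.
    """
    band_spec = _resolve_band(band_spec)
    taps = design_bandpass(band_spec, epochs.sampling_rate)
    filtered = _zero_phase_filter(epochs.data, taps)
    return epochs.with_data(filtered, band=band_spec)


def analytic_signal(epochs: LabeledEpochs) -> AnalyticEpochs:
    """Complex analytic signal of band-limited epochs via the Hilbert transform.

    The real part equals the input; the angle is instantaneous phase and
    the modulus the envelope.  The transform runs on a reflection-padded
    copy (one epoch length each side) and is trimmed back, which confines
    boundary contamination to roughly the first/last 50 ms; that span is
    recorded on the output as ``edge_ms``.
    """
    if epochs.band is None:
        raise ValueError(
            "analytic_signal expects band-limited input; run bandpass_epochs first"
        )
    n = epochs.n_times
    pad = n - 1
    padded = _reflect_pad(epochs.data, pad)
    analytic = sps.hilbert(padded, axis=-1)[..., pad : pad + n]
    return AnalyticEpochs(
        data=analytic,
        labels=epochs.labels,
        times=epochs.times,
        sampling_rate=epochs.sampling_rate,
        band=epochs.band,
        subject=epochs.subject,
        edge_ms=EDGE_CONTAMINATED_MS,
    )


def rolling_mean(
    series: np.ndarray, window_ms: float, sampling_rate: float
) -> np.ndarray:
    """Centered moving average over ``window_ms`` along the last axis.

    The window is ``round(window_ms * fs / 1000)`` samples, forced odd so
    the average is centered on the sample it replaces (no latency shift);
    at the series edges the window shrinks to the available samples.
    Length is preserved.
    """
    series = np.asarray(series, dtype=float)
    n = series.shape[-1]
    w = int(round(window_ms * sampling_rate / 1000.0))
    if w < 1:
        raise ValueError(
            f"window of {window_ms} ms is shorter than one sample period"
        )
    if w % 2 == 0:
        w += 1
    if w > n:
        raise ValueError(f"window of {w} samples exceeds series length {n}")
    if w == 1:
        return series.copy()
    kernel = np.ones(w)
    sums = ndimage.convolve1d(series, kernel, axis=-1, mode="constant", cval=0.0)
    counts = np.convolve(np.ones(n), kernel, mode="same")
    return sums / counts
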