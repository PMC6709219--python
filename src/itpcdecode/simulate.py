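"""Synthetic multi-subject oscillatory trial data with known phase locking.

The generator emulates the structure of a passive listening study:
17 subjects, several stimulus conditions with 100 repetitions each,
1000-ms epochs (−100 to 900 ms around stimulus onset) sampled at 500 Hz.
Class-conditional "phase resetting" is injected as a windowed sinusoidal
carrier whose phase at window onset is drawn from a von Mises
distribution with per-class concentration κ: κ = 0 gives uniform phases
(null), large κ aligns phases across trials and therefore raises the
intertrial phase coherence toward I₁(κ)/I₀(κ).

All randomness descends from a single integer seed through
``numpy.random.SeedSequence(seed, spawn_key=(subject_index,))``, so a
subject's data is reproducible in isolation and the subject set is
reproducible as a whole.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import special

from .bands import BandSpec, band as _resolve_band
from .containers import LabeledEpochs

__all__ = [
    "EffectSpec",
    "GeneratorConfig",
    "LeadField",
    "simulate_trials",
    "simulate_subject_set",
    "expected_itpc_vonmises",
    "simulate_leadfield",
    "noise_sd_for_band_snr",
]


@dataclass(frozen=True)
class EffectSpec:
    """A class-conditional phase-locking effect.

    Parameters
    ----------
    band
        Name of the canonical band the carrier lives in.
    locations
        Location (channel/vertex) indices carrying the effect.
    window_ms
        ``(start, end)`` of the effect window in epoch time (ms).
    kappa_by_class
        Von Mises concentration κ ≥ 0 per class label.  Classes missing
        from the mapping get κ = 0 (uniform onset phase).
    carrier_freq
        Carrier frequency in Hz; must lie inside the named band.
    amplitude
        Peak carrier amplitude (arbitrary units, default 1).
    """

    band: str
    locations: tuple[int, ...]
    window_ms: tuple[float, float]
    kappa_by_class: Mapping[str, float]
    carrier_freq: float
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "locations", tuple(self.locations))
        object.__setattr__(self, "kappa_by_class", dict(self.kappa_by_class))
        start, end = self.window_ms
        if not start < end:
            raise ValueError(f"effect window must have start < end, got {self.window_ms}")
        for label, kappa in self.kappa_by_class.items():
            if kappa < 0:
                raise ValueError(f"kappa for class {label!r} must be >= 0, got {kappa}")
        spec = _resolve_band(self.band)
        if not spec.contains(self.carrier_freq):
            raise ValueError(
                f"carrier frequency {self.carrier_freq} Hz outside band "
                f"{spec.name} [{spec.low}, {spec.high}] Hz"
            )


@dataclass(frozen=True)
class GeneratorConfig:
    """Full description of a simulated data set.

    ``conditions`` maps condition names (stimulus types) to class labels;
    each condition is simulated with ``n_trials_per_condition`` trials.
    ``between_subject_sd`` is the SD of a multiplicative log-normal
    jitter applied to every effect κ per subject (0 = identical
    subjects).  ``noise_model`` is ``"white"`` (default; keeps the
    uniform-phase null exact in every band) or ``"pink"`` (1/f spectrum).
    """

    conditions: Mapping[str, str]
    n_trials_per_condition: int = 100
    n_subjects: int = 17
    n_locations: int = 200
    sampling_rate: float = 500.0
    epoch_span_ms: tuple[float, float] = (-100.0, 900.0)
    effects: tuple[EffectSpec, ...] = ()
    noise_sd: float = 1.0
    between_subject_sd: float = 0.0
    noise_model: str = "white"
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "conditions", dict(self.conditions))
        object.__setattr__(self, "effects", tuple(self.effects))
        if self.n_trials_per_condition < 1 or self.n_subjects < 1 or self.n_locations < 1:
            raise ValueError("all counts must be >= 1")
        if not self.conditions:
            raise ValueError("at least one condition is required")
        if self.noise_model not in ("white", "pink"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        start, end = self.epoch_span_ms
        if not start < end:
            raise ValueError("epoch span must have start < end")
        for eff in self.effects:
            spec = _resolve_band(eff.band)
            if self.sampling_rate <= 2 * spec.high:
                raise ValueError(
                    f"sampling rate {self.sampling_rate} Hz too low for band "
                    f"{spec.name} (needs > {2 * spec.high} Hz)"
                )
            if eff.window_ms[0] < start or eff.window_ms[1] > end:
                raise ValueError(
                    f"effect window {eff.window_ms} outside epoch span {self.epoch_span_ms}"
                )
            bad = [i for i in eff.locations if not 0 <= i < self.n_locations]
            if bad:
                raise ValueError(f"effect location indices out of range: {bad}")

    @property
    def times_ms(self) -> np.ndarray:
        start, end = self.epoch_span_ms
        n = int(round((end - start) * self.sampling_rate / 1000.0)) + 1
        return start + np.arange(n) * 1000.0 / self.sampling_rate


@dataclass(frozen=True)
class LeadField:
    """Forward gain matrix: ``gains[sensor, source, orientation]``."""

    gains: np.ndarray

    def __post_init__(self) -> None:
        g = np.asarray(self.gains, dtype=float)
        object.__setattr__(self, "gains", g)
        if g.ndim != 3 or g.shape[2] != 3:
            raise ValueError(f"lead field must be (sensors, sources, 3), got {g.shape}")
        if not np.all(np.isfinite(g)):
            raise ValueError("lead field gains must be finite")
        norms = np.linalg.norm(g, axis=(0, 2))
        if np.any(norms == 0):
            raise ValueError("lead field contains an all-zero source block")

    @property
    def n_sensors(self) -> int:
        return self.gains.shape[0]

    @property
    def n_sources(self) -> int:
        return self.gains.shape[1]


def _subject_rng(seed: int, subject_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(subject_index,)))


def _pink_noise(rng: np.random.Generator, shape: tuple[int, ...], sd: float) -> np.ndarray:
    """Gaussian noise with a 1/f amplitude spectrum, unit-free scale ``sd``."""
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(shape[-1])
    scale = np.ones_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    scale[0] = 0.0
    shaped = np.fft.irfft(spec * scale, n=shape[-1], axis=-1)
    shaped /= shaped.std()
    return sd * shaped


def simulate_trials(config: GeneratorConfig, subject_index: int) -> LabeledEpochs:
    """Simulate one subject's labeled epochs.

    Within each effect window/location, the carrier phase at window onset
    is drawn von Mises(0, κ·jitter) per trial, where κ comes from the
    trial's class; the carrier then evolves deterministically at
    ``carrier_freq`` across the window.  Everywhere else the data is pure
    noise, whose band-limited phases are uniform.  Deterministic given
    ``(config.seed, subject_index)``.
    """
    if not 0 <= subject_index < config.n_subjects:
        raise ValueError(
            f"subject_index {subject_index} outside 0..{config.n_subjects - 1}"
        )
    rng = _subject_rng(config.seed, subject_index)

    # Per-subject multiplicative jitter on every effect's kappa, drawn
    # first so the downstream stream layout is stable.
    if config.between_subject_sd > 0:
        jitters = np.exp(config.between_subject_sd * rng.standard_normal(len(config.effects)))
    else:
        jitters = np.ones(len(config.effects))
        rng.standard_normal(len(config.effects))  # keep the stream position fixed

    times = config.times_ms
    cond_names = sorted(config.conditions)
    n_trials = len(cond_names) * config.n_trials_per_condition
    labels = np.repeat(cond_names, config.n_trials_per_condition)

    shape = (n_trials, config.n_locations, len(times))
    if config.noise_model == "white":
        data = config.noise_sd * rng.standard_normal(shape)
    else:
        data = _pink_noise(rng, shape, config.noise_sd)

    for eff, jitter in zip(config.effects, jitters):
        in_window = (times >= eff.window_ms[0]) & (times <= eff.window_ms[1])
        t_rel = (times[in_window] - eff.window_ms[0]) / 1000.0  # s from onset
        locs = list(eff.locations)
        for cond in cond_names:
            kappa = float(eff.kappa_by_class.get(config.conditions[cond], 0.0)) * jitter
            rows = np.flatnonzero(labels == cond)
            phases = rng.vonmises(0.0, kappa, size=(len(rows), len(locs)))
            carrier = eff.amplitude * np.cos(
                2 * np.pi * eff.carrier_freq * t_rel[np.newaxis, np.newaxis, :]
                + phases[:, :, np.newaxis]
            )
            data[np.ix_(rows, locs, np.flatnonzero(in_window))] += carrier

    return LabeledEpochs(
        data=data,
        labels=labels,
        times=times,
        sampling_rate=config.sampling_rate,
        subject=f"s{subject_index:02d}",
    )


def simulate_subject_set(config: GeneratorConfig) -> list[LabeledEpochs]:
    """Simulate all subjects of a study; subjects are mutually independent."""
    if config.n_subjects < 2:
        raise ValueError("a subject set needs n_subjects >= 2")
    return [simulate_trials(config, i) for i in range(config.n_subjects)]


def expected_itpc_vonmises(kappa: float | np.ndarray) -> float | np.ndarray:
    """Large-n expectation of ITPC for von Mises phases: I₁(κ)/I₀(κ).

    The mean resultant length of the von Mises distribution; 0 at κ = 0
    (uniform phases) and → 1 as κ → ∞ (perfect alignment).
    """
    kappa = np.asarray(kappa, dtype=float)
    if np.any(kappa < 0):
        raise ValueError("kappa must be >= 0")
    # exponentially scaled Bessel functions keep the ratio stable for large kappa
    out = special.i1e(kappa) / special.i0e(kappa)
    return float(out) if out.ndim == 0 else out


def noise_sd_for_band_snr(
    band_spec: BandSpec | str,
    sampling_rate: float,
    amplitude: float = 1.0,
    snr_db: float = 0.0,
) -> float:
    """White-noise SD giving a target in-band SNR against a sinusoidal carrier.

    White noise of SD σ sampled at ``fs`` spreads its power σ² evenly
    over 0..fs/2, so the power falling inside a band of width B is
    σ²·B/(fs/2).  Matching that to the carrier power A²/2 at the target
    SNR gives σ.  Used to set generator defaults at ≈0 dB band SNR.
    """
    spec = _resolve_band(band_spec)
    carrier_power = amplitude**2 / 2.0
    target_noise_power = carrier_power / 10.0 ** (snr_db / 10.0)
    return float(np.sqrt(target_noise_power * (sampling_rate / 2.0) / spec.width))


def simulate_leadfield(n_sensors: int, n_sources: int, seed: int = 0) -> LeadField:
    """Random smooth free-orientation lead field for beamformer tests.

    Sensors sit on a unit sphere (Fibonacci lattice); sources are placed
    at random inside a concentric ball of radius 0.7, and the gain of a
    source dipole component q at a sensor follows the 1/r² potential
    falloff ``(r − p)·e_q / |r − p|³``.  Every per-source 3-column block
    is checked for full rank (degenerate draws are redrawn).
    Deterministic given ``seed``.
    """
    if n_sensors < 4:
        raise ValueError("need at least 4 sensors")
    if n_sensors <= 3 * n_sources:
        warnings.warn(
            f"{n_sensors} sensors for {n_sources} sources (3 orientations each) "
            "leaves the inverse problem badly underdetermined",
            stacklevel=2,
        )
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0xF0,)))

    # Fibonacci lattice on the unit sphere
    i = np.arange(n_sensors) + 0.5
    phi = np.arccos(1 - 2 * i / n_sensors)
    theta = np.pi * (1 + 5**0.5) * i
    sensors = np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )

    gains = np.empty((n_sensors, n_sources, 3))
    for j in range(n_sources):
        for _attempt in range(100):
            pos = 0.7 * rng.uniform(-1, 1, size=3)
            if np.linalg.norm(pos) > 0.7:
                continue
            diff = sensors - pos  # (n_sensors, 3)
            dist = np.linalg.norm(diff, axis=1)
            block = diff / dist[:, np.newaxis] ** 3
            if np.linalg.matrix_rank(block, tol=1e-8 * np.abs(block).max()) == 3:
                gains[:, j, :] = block
                break
        else:  # pragma: no cover - essentially impossible for random geometry
            raise RuntimeError("could not draw a full-rank source block")
    return LeadField(gains=gains)
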