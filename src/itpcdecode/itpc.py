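"""Intertrial phase coherence maps and decoding-dataset assembly.

ITPC at a location/timepoint is the modulus of the mean unit phasor of
the per-trial instantaneous phases,

    ITPC = | (1/n) Σ_r exp(i k_r) |,

where k_r is the phase angle of trial r's analytic signal at that point.
It is 1 when all trials share a phase and concentrates around 1/√n for
uniform phases.  Amplitude never enters: each trial's complex value is
normalized to a unit phasor before averaging.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .bands import BandSpec
from .containers import AnalyticEpochs
from .spectral import rolling_mean

__all__ = [
    "ITPCMap",
    "ContrastSpec",
    "DecodingDataset",
    "itpc_timecourse",
    "amplitude_timecourse",
    "build_dataset",
    "lexical_contrast",
    "semantic_contrast",
    "syntax_contrast",
]

logger = logging.getLogger(__name__)


@dataclass
class ITPCMap:
    """Per-subject, per-condition feature map: ``values[location, time]``.

    ``feature_mode`` is ``"itpc"`` (phase coherence, values in [0, 1]) or
    ``"amplitude"`` (trial-mean envelope, non-negative).
    """

    values: np.ndarray
    n_trials: int
    times: np.ndarray
    band: BandSpec
    subject: str
    condition: str
    feature_mode: str = "itpc"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("ITPCMap values must be (locations, times)")
        if self.feature_mode == "itpc" and (
            self.values.min() < -1e-9 or self.values.max() > 1 + 1e-9
        ):
            raise ValueError("ITPC values must lie in [0, 1]")


@dataclass(frozen=True)
class ContrastSpec:
    """A binary linguistic-style contrast over stimulus conditions.

    ``classes`` maps each condition name to its class label;
    ``positive_class`` is the label scored as the positive class by the
    classifier; ``dp_ms`` is the divergence point — the epoch time at
    which the contrasted property first becomes available — and all
    reported latencies are re-referenced to it.
    """

    name: str
    classes: Mapping[str, str]
    positive_class: str
    dp_ms: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "classes", dict(self.classes))
        labels = set(self.classes.values())
        if len(labels) != 2:
            raise ValueError(f"a contrast needs exactly 2 class labels, got {labels}")
        if self.positive_class not in labels:
            raise ValueError(f"positive_class {self.positive_class!r} not in {labels}")

    @property
    def conditions(self) -> tuple[str, ...]:
        return tuple(self.classes)


def lexical_contrast(dp_ms: float = 300.0) -> ContrastSpec:
    """Word vs pseudoword: three real-word conditions against one pseudoword (3:1)."""
    return ContrastSpec(
        name="lexical",
        classes={
            "word_a": "word",
            "word_b": "word",
            "word_c": "word",
            "pseudoword": "pseudoword",
        },
        positive_class="word",
        dp_ms=dp_ms,
    )


def semantic_contrast(dp_ms: float = 300.0) -> ContrastSpec:
    """Action verb vs object noun (1:1)."""
    return ContrastSpec(
        name="semantic",
        classes={"action_verb": "action_verb", "object_noun": "object_noun"},
        positive_class="action_verb",
        dp_ms=dp_ms,
    )


def syntax_contrast(dp_ms: float = 408.0) -> ContrastSpec:
    """Grammatical vs ungrammatical inflected forms (1:1, two conditions per class)."""
    return ContrastSpec(
        name="syntax",
        classes={
            "gram_a": "grammatical",
            "gram_b": "grammatical",
            "ungram_a": "ungrammatical",
            "ungram_b": "ungrammatical",
        },
        positive_class="ungrammatical",
        dp_ms=dp_ms,
    )


@dataclass
class DecodingDataset:
    """Across-subject samples for time-resolved decoding.

    ``X[row, feature, time]`` with one row per (subject, condition) cell;
    ``y`` holds binary class codes (1 = the contrast's positive class)
    and ``groups`` the subject of each row.  ``times`` are in ms relative
    to the contrast's divergence point.
    """

    X: np.ndarray
    y: np.ndarray
    groups: np.ndarray
    times: np.ndarray
    contrast: ContrastSpec
    band: BandSpec
    feature_mode: str = "itpc"

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 3:
            raise ValueError("X must be (rows, features, times)")
        if len(self.y) != self.X.shape[0] or len(self.groups) != self.X.shape[0]:
            raise ValueError("labels/groups must match the number of rows")
        if len(np.unique(self.y)) != 2:
            raise ValueError("dataset must contain both classes")

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def n_times(self) -> int:
        return self.X.shape[2]


def _unit_phasor_mean(data: np.ndarray) -> tuple[np.ndarray, int, int]:
    """Mean unit phasor over axis 0, excluding exact-zero complex values."""
    magnitude = np.abs(data)
    zero = magnitude == 0
    n_zero = int(zero.sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        phasors = np.where(zero, 0.0, data / np.where(zero, 1.0, magnitude))
    counts = data.shape[0] - zero.sum(axis=0)
    counts_safe = np.where(counts == 0, 1, counts)
    mean = phasors.sum(axis=0) / counts_safe
    return mean, n_zero, int((counts == 0).sum())


def itpc_timecourse(analytic: AnalyticEpochs, condition: str | None = None) -> ITPCMap:
    """ITPC of complex single-trial data per location and timepoint.

    If ``condition`` is given, only trials with that label enter; the
    returned map records the trial count used.  Trials whose complex
    value is exactly zero at a point (undefined phase) are excluded there
    and the per-point trial count adjusted; exclusions are logged.
    """
    data = analytic.data
    if condition is not None:
        rows = analytic.labels == condition
        if not rows.any():
            raise ValueError(f"no trials with condition {condition!r}")
        data = data[rows]
    if data.shape[0] < 2:
        raise ValueError("ITPC needs at least 2 trials")
    mean, n_zero, n_empty = _unit_phasor_mean(data)
    if n_zero:
        logger.info(
            "itpc_timecourse: excluded %d zero-valued (undefined-phase) samples", n_zero
        )
    if n_empty:
        logger.warning(
            "itpc_timecourse: %d points had no valid trial at all; ITPC set to 0", n_empty
        )
    return ITPCMap(
        values=np.abs(mean),
        n_trials=data.shape[0],
        times=analytic.times,
        band=analytic.band,
        subject=analytic.subject,
        condition=condition if condition is not None else "all",
    )


def amplitude_timecourse(
    analytic: AnalyticEpochs, condition: str | None = None
) -> ITPCMap:
    """Trial-mean envelope |z| per location/timepoint (amplitude feature mode).

    Same container as :func:`itpc_timecourse` but phase-blind: multiplying
    any trial by a unit phasor leaves the output unchanged.
    """
    data = analytic.data
    if condition is not None:
        rows = analytic.labels == condition
        if not rows.any():
            raise ValueError(f"no trials with condition {condition!r}")
        data = data[rows]
    if data.shape[0] < 2:
        raise ValueError("amplitude averaging needs at least 2 trials")
    return ITPCMap(
        values=np.abs(data).mean(axis=0),
        n_trials=data.shape[0],
        times=analytic.times,
        band=analytic.band,
        subject=analytic.subject,
        condition=condition if condition is not None else "all",
        feature_mode="amplitude",
    )


def build_dataset(
    maps: Sequence[ITPCMap],
    contrast: ContrastSpec,
    smooth_ms: float = 10.0,
) -> DecodingDataset:
    """Assemble per-timepoint design matrices from subject/condition maps.

    Every subject must contribute exactly one map per contrast condition;
    maps are smoothed with a centered ``smooth_ms`` rolling mean (10 ms
    by default) and stacked as rows ordered by subject then condition.
    Times are re-referenced to the contrast's divergence point.  With
    synthetic subjects sharing one location grid, morphing to a common
    surface is the identity; for real data this is the injection point
    for a subject-to-template morph.
    """
    by_cell: dict[tuple[str, str], ITPCMap] = {}
    for m in maps:
        key = (m.subject, m.condition)
        if key in by_cell:
            raise ValueError(f"duplicate map for subject/condition cell {key}")
        by_cell[key] = m

    subjects = sorted({s for s, _ in by_cell})
    missing = [
        (s, c) for s in subjects for c in contrast.conditions if (s, c) not in by_cell
    ]
    if missing:
        raise ValueError(f"missing subject/condition cells: {missing}")

    reference = by_cell[(subjects[0], contrast.conditions[0])]
    fs = 1000.0 / float(np.diff(reference.times)[0])
    rows, y, groups = [], [], []
    for s in subjects:
        for cond in contrast.conditions:
            m = by_cell[(s, cond)]
            if m.values.shape != reference.values.shape or not np.allclose(
                m.times, reference.times
            ):
                raise ValueError(f"map for cell {(s, cond)} has mismatching grid")
            if m.band != reference.band or m.feature_mode != reference.feature_mode:
                raise ValueError(f"map for cell {(s, cond)} has mismatching band/mode")
            if smooth_ms > 0:
                rows.append(rolling_mean(m.values, smooth_ms, fs))
            else:
                rows.append(m.values)
            y.append(int(contrast.classes[cond] == contrast.positive_class))
            groups.append(s)

    return DecodingDataset(
        X=np.stack(rows),
        y=np.asarray(y),
        groups=np.asarray(groups),
        times=reference.times - contrast.dp_ms,
        contrast=contrast,
        band=reference.band,
        feature_mode=reference.feature_mode,
    )
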