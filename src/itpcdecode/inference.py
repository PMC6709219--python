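"""Permutation significance testing of decoding curves with cluster correction.

Testing every timepoint with 2000 permutations is wasteful, so the test
is gated: only timepoints whose observed mean ROC-AUC exceeds a
band-specific threshold — baseline mean + 1.5 baseline SDs — are
permuted.  At a gated timepoint, labels are shuffled and the *full*
pipeline (standardize, select, classify inside cross-validation) is
rerun m times; the p value is (b+1)/(m+1) where b counts permutations
scoring at least the observed value, so p can never reach 0 and never
falls below 1/(m+1).  Runs of consecutive significant timepoints
shorter than 10 ms are discarded as likely noise (cluster-duration
correction); surviving clusters are summarized in a table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .decoding import DecodingResult, PipelineConfig, decode_matrix, stratified_folds
from .itpc import DecodingDataset

__all__ = [
    "PermutationConfig",
    "ClusterRecord",
    "SignificanceResult",
    "compute_threshold",
    "permutation_null",
    "permutation_p",
    "permutation_test_curve",
    "find_clusters",
    "cluster_table",
    "CLUSTER_TABLE_COLUMNS",
]

CLUSTER_TABLE_COLUMNS = [
    "Band",
    "Peak (%)",
    "Peak SD (%)",
    "Peak time (ms)",
    "Cluster start (ms)",
    "Cluster end (ms)",
    "Cluster length (ms)",
    "Cluster mean (%)",
    "Cluster SD (%)",
]


@dataclass(frozen=True)
class PermutationConfig:
    """Settings of the threshold-gated permutation test.

    ``baseline_window`` (ms, relative to the divergence point) defines
    the stretch of the curve used for the 1.5-SD gate; ``None`` means
    all timepoints before the divergence point.  ``within_subject``
    restricts label shuffles to each subject's rows; the default
    shuffles across all rows.  ``restratify`` redraws the fold
    assignment per permutation instead of reusing the observed one.
    """

    n_perm: int = 2000
    alpha: float = 0.05
    threshold_sd_mult: float = 1.5
    min_cluster_ms: float = 10.0
    baseline_window: tuple[float, float] | None = None
    within_subject: bool = False
    restratify: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.min_cluster_ms <= 0:
            raise ValueError("min_cluster_ms must be positive")


@dataclass
class ClusterRecord:
    """One significant cluster, in the layout of the summary tables.

    Scores are ROC-AUC in percent.  ``peak_sd`` is the SD across
    cross-validation folds at the peak timepoint; ``sd`` is the SD
    across folds of the cluster-mean score.  Times are ms from the
    divergence point; ``length = end - start``.
    """

    band: str
    peak: float
    peak_sd: float
    peak_time: float
    start: float
    end: float
    length: float
    mean: float
    sd: float

    def as_row(self) -> dict:
        return {
            "Band": self.band,
            "Peak (%)": self.peak,
            "Peak SD (%)": self.peak_sd,
            "Peak time (ms)": self.peak_time,
            "Cluster start (ms)": self.start,
            "Cluster end (ms)": self.end,
            "Cluster length (ms)": self.length,
            "Cluster mean (%)": self.mean,
            "Cluster SD (%)": self.sd,
        }


@dataclass
class SignificanceResult:
    """Gate threshold, per-timepoint p values, and surviving clusters.

    ``p`` is NaN at timepoints that never passed the gate (treated as
    non-significant); ``tested`` marks gated timepoints; ``clusters``
    holds (start_index, end_index) pairs (inclusive) into the result's
    time axis.
    """

    threshold: float
    p: np.ndarray
    tested: np.ndarray
    clusters: list[tuple[int, int]]
    times: np.ndarray


def compute_threshold(
    auc_curve: np.ndarray,
    times: np.ndarray,
    baseline_window: tuple[float, float] | None = None,
    sd_mult: float = 1.5,
) -> float:
    """Gate threshold: baseline mean + ``sd_mult`` baseline SDs.

    ``baseline_window`` is in the same (divergence-point-referenced) ms
    units as ``times``; ``None`` takes every timepoint before 0.
    """
    auc_curve = np.asarray(auc_curve, dtype=float)
    times = np.asarray(times, dtype=float)
    if baseline_window is None:
        mask = times < 0
    else:
        mask = (times >= baseline_window[0]) & (times <= baseline_window[1])
    if not mask.any():
        raise ValueError("baseline window contains no timepoints")
    base = auc_curve[mask]
    if len(base) == 1:
        warnings.warn("single-sample baseline: SD is 0, threshold equals that value")
    return float(base.mean() + sd_mult * base.std())


def _permuted_labels(
    y: np.ndarray,
    groups: np.ndarray | None,
    rng: np.random.Generator,
    within_subject: bool,
) -> np.ndarray:
    if not within_subject:
        return y[rng.permutation(len(y))]
    if groups is None:
        raise ValueError("within-subject permutation needs group labels")
    out = y.copy()
    for g in np.unique(groups):
        rows = np.flatnonzero(groups == g)
        out[rows] = y[rows[rng.permutation(len(rows))]]
    return out


def permutation_null(
    dataset: DecodingDataset,
    timepoint: int,
    pipeline: PipelineConfig,
    config: PermutationConfig,
) -> np.ndarray:
    """Null distribution of the mean fold AUC at one timepoint.

    Each of the m permutations shuffles the labels once and reruns the
    complete pipeline inside cross-validation.  By default the observed
    stratified fold assignment is reused (so the only difference is the
    labels); ``config.restratify`` redraws folds from the permuted
    labels instead.  Deterministic given ``(config.seed, timepoint)``.
    """
    X = dataset.X[:, :, int(timepoint)]
    y = dataset.y
    folds = stratified_folds(y, pipeline.outer_folds, pipeline.seed)
    rng = np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(int(timepoint),))
    )
    null = np.empty(config.n_perm)
    for b in range(config.n_perm):
        y_perm = _permuted_labels(y, dataset.groups, rng, config.within_subject)
        f = (
            stratified_folds(y_perm, pipeline.outer_folds, pipeline.seed)
            if config.restratify
            else folds
        )
        aucs, _ = decode_matrix(X, y_perm, f, pipeline)
        # folds left single-class by the shuffle score NaN and drop out; a
        # permutation with no scoreable fold at all counts as chance
        defined = aucs[~np.isnan(aucs)]
        null[b] = defined.mean() if defined.size else 0.5
    return null


def permutation_p(observed: float, null: np.ndarray) -> float:
    """p = (b+1)/(m+1), b = #{null scores >= observed}.

    The +1s guarantee p > 0 (the minimum attainable p is 1/(m+1)) and a
    valid test under exchangeability.
    """
    null = np.asarray(null, dtype=float)
    if null.size == 0:
        raise ValueError("null distribution is empty")
    b = int((null >= observed).sum())
    return (b + 1) / (null.size + 1)


def permutation_test_curve(
    dataset: DecodingDataset,
    result: DecodingResult,
    config: PermutationConfig,
    analysis_start_ms: float = 0.0,
) -> SignificanceResult:
    """Threshold-gated permutation test along the decoding curve.

    The gate threshold comes from the baseline stretch of the *observed*
    curve; only post-divergence timepoints (``times >= analysis_start_ms``)
    whose mean AUC surpasses the threshold are permuted.  Ungated
    timepoints keep p = NaN and count as non-significant for
    clustering.  Clusters shorter than ``min_cluster_ms`` are discarded.
    """
    times = result.times
    threshold = compute_threshold(
        result.mean_auc, times, config.baseline_window, config.threshold_sd_mult
    )
    tested = (result.mean_auc > threshold) & (times >= analysis_start_ms)
    # map from the result's time axis back to dataset time indices
    dataset_indices = np.searchsorted(dataset.times, times)
    p = np.full(len(times), np.nan)
    for j in np.flatnonzero(tested):
        null = permutation_null(dataset, int(dataset_indices[j]), result.config, config)
        p[j] = permutation_p(result.mean_auc[j], null)
    clusters = find_clusters(p, times, config)
    return SignificanceResult(
        threshold=threshold, p=p, tested=tested, clusters=clusters, times=times
    )


def find_clusters(
    p_curve: np.ndarray,
    times: np.ndarray,
    config: PermutationConfig,
) -> list[tuple[int, int]]:
    """Maximal runs of consecutive significant timepoints, duration-corrected.

    A timepoint is significant when its p value is defined (the gate
    passed) and p <= alpha.  A run spanning ``end - start`` of at least
    ``min_cluster_ms`` (boundary inclusive) is kept; shorter runs are
    discarded.  Returns (start_index, end_index) inclusive pairs.
    """
    p_curve = np.asarray(p_curve, dtype=float)
    times = np.asarray(times, dtype=float)
    sig = np.zeros(len(p_curve), dtype=bool)
    defined = ~np.isnan(p_curve)
    sig[defined] = p_curve[defined] <= config.alpha
    clusters: list[tuple[int, int]] = []
    i = 0
    n = len(sig)
    while i < n:
        if sig[i]:
            j = i
            while j + 1 < n and sig[j + 1]:
                j += 1
            if times[j] - times[i] >= config.min_cluster_ms:
                clusters.append((i, j))
            i = j + 1
        else:
            i += 1
    return clusters


def cluster_table(
    clusters: Sequence[tuple[int, int]],
    result: DecodingResult,
    band_name: str,
) -> pd.DataFrame:
    """Summary table of significant clusters (one row per cluster).

    Scores are reported in percent: the peak mean AUC in the cluster
    with its across-fold SD, peak/start/end times (ms from the
    divergence point — the result's time axis is already re-referenced),
    cluster length, the time-average of the mean-AUC curve over the
    cluster, and the SD across folds of the cluster-mean score.  Rows
    are sorted by start time.
    """
    records = []
    for start_i, end_i in clusters:
        sl = slice(start_i, end_i + 1)
        curve = result.mean_auc[sl]
        peak_j = int(np.argmax(curve)) + start_i
        fold_cluster_means = result.fold_aucs[:, sl].mean(axis=1)
        records.append(
            ClusterRecord(
                band=band_name,
                peak=100 * float(result.mean_auc[peak_j]),
                peak_sd=100 * float(result.fold_sd[peak_j]),
                peak_time=float(result.times[peak_j]),
                start=float(result.times[start_i]),
                end=float(result.times[end_i]),
                length=float(result.times[end_i] - result.times[start_i]),
                mean=100 * float(curve.mean()),
                sd=100 * float(fold_cluster_means.std(ddof=1)),
            )
        )
    records.sort(key=lambda r: r.start)
    return pd.DataFrame([r.as_row() for r in records], columns=CLUSTER_TABLE_COLUMNS)
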