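"""Metadynamics reweighting, CV binning and conditional observable maps.

Frames from a biased run are assigned unnormalized statistical weights
``w = exp(+V_bias_final(cv)/kT)`` from the *final* accumulated bias (the
time-independent reweighting variant; an optional flag restricts the frame
set to the second half of the run to suppress early, non-equilibrium bias).
Frames are binned on a CV grid, the top-K weighted frames per bin become
that bin's representatives, and a conditional map averages an observable
(typically an effective pKa) over those representatives — the machinery
behind per-macrostate pKa maps conditioned on the positions of both
chloride ions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from sklearn.cluster import KMeans

from .metad_engine import BiasState
from .toy_system import WalkerFrame

__all__ = [
    "ConditionalMap",
    "ClusterResult",
    "frame_weight",
    "frame_weights",
    "bin_frames",
    "select_top_k",
    "conditional_map",
    "kmeans_cluster",
]

log = logging.getLogger(__name__)


@dataclass
class ConditionalMap:
    """Per-CV-bin averaged observable with representative bookkeeping.

    ``mean_observable`` is NaN on empty bins (also flagged by
    ``counts == 0``); ``representatives`` stores, per bin, the frame indices
    (into the input frame list) whose observables were averaged.
    """

    bin_edges: list[np.ndarray]
    mean_observable: np.ndarray
    counts: np.ndarray
    representatives: np.ndarray  # object array of lists of frame indices

    def __post_init__(self) -> None:
        shape = tuple(len(e) - 1 for e in self.bin_edges)
        if self.mean_observable.shape != shape or self.counts.shape != shape:
            raise ValueError("map arrays do not match bin edges")


def frame_weight(frame: WalkerFrame, final_bias: BiasState, kt: float = 1.0) -> float:
    """Unnormalized reweighting factor ``exp(V_bias_final(cv)/kT)`` for one
    frame; normalization is the caller's concern."""
    v = final_bias.value(frame.cv)
    if not math.isfinite(v):
        raise FloatingPointError(f"non-finite bias at frame cv {frame.cv}")
    return math.exp(v / kt)


def frame_weights(frames: Sequence[WalkerFrame], final_bias: BiasState,
                  kt: float = 1.0, last_half_only: bool = False,
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized weights for a frame list.

    Returns ``(weights, kept)`` where ``kept`` is the boolean frame mask
    (all True unless ``last_half_only`` drops the first half of the time
    range, a mitigation for early non-equilibrium bias).
    """
    cvs = np.array([f.cv for f in frames])
    times = np.array([f.time for f in frames])
    kept = np.ones(len(frames), dtype=bool)
    if last_half_only and len(frames):
        tmid = 0.5 * (times.min() + times.max())
        kept = times >= tmid
    v = final_bias.values(cvs)
    if not np.all(np.isfinite(v)):
        raise FloatingPointError("non-finite bias among frame weights")
    w = np.exp((v - v.max()) / kt)  # global constant is irrelevant
    return w, kept


def bin_frames(frames: Sequence[WalkerFrame], bin_edges: Sequence[np.ndarray],
               ) -> tuple[np.ndarray, int]:
    """Assign frames to half-open CV bins ``[lo, hi)``.

    Returns an object array (per-bin lists of frame indices) and the count
    of discarded out-of-range frames (frames at or beyond the last edge are
    discarded, logged).
    """
    edges = [np.asarray(e, dtype=float) for e in bin_edges]
    for e in edges:
        if e.ndim != 1 or e.size < 2 or np.any(np.diff(e) <= 0):
            raise ValueError("bin edges must be monotone 1D arrays of length >= 2")
    shape = tuple(e.size - 1 for e in edges)
    bins = np.empty(shape, dtype=object)
    for idx in np.ndindex(*shape):
        bins[idx] = []
    if len(frames) == 0:
        return bins, 0
    cvs = np.array([f.cv for f in frames])
    ok = np.ones(len(frames), dtype=bool)
    digit = np.empty((len(frames), len(edges)), dtype=int)
    for d, e in enumerate(edges):
        j = np.searchsorted(e, cvs[:, d], side="right") - 1
        digit[:, d] = j
        ok &= (j >= 0) & (j < e.size - 1)
    for i in np.nonzero(ok)[0]:
        bins[tuple(digit[i])].append(int(i))
    discarded = int((~ok).sum())
    if discarded:
        log.info("bin_frames: discarded %d frames outside the bin range", discarded)
    return bins, discarded


def select_top_k(binned: np.ndarray, weights: np.ndarray,
                 frames: Sequence[WalkerFrame], k: int = 10) -> np.ndarray:
    """Per bin, the (up to) ``k`` highest-weight frame indices.

    The default k = 10 reflects the usual "up to 10 frames with the highest
    statistical weights in each bin" selection.  Ties are broken by earlier
    frame time, so the result is invariant to frame ordering.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    times = np.array([f.time for f in frames])
    out = np.empty(binned.shape, dtype=object)
    for idx in np.ndindex(*binned.shape):
        members = binned[idx]
        ranked = sorted(members, key=lambda i: (-weights[i], times[i], i))
        out[idx] = ranked[:k]
    return out


def conditional_map(frames: Sequence[WalkerFrame],
                    observable: Callable[[WalkerFrame], float],
                    bin_edges: Sequence[np.ndarray],
                    final_bias: BiasState | None = None,
                    weights: np.ndarray | None = None,
                    k: int = 10, kt: float = 1.0,
                    last_half_only: bool = False) -> ConditionalMap:
    """Average an observable over the top-k weighted representatives per bin.

    The per-bin mean is unweighted across the representatives.  Observable
    failures on individual frames are logged and skipped; bins with no
    evaluable representative are flagged empty (NaN mean, count 0).
    """
    if weights is None:
        if final_bias is None:
            weights = np.ones(len(frames))
            kept = np.ones(len(frames), dtype=bool)
        else:
            weights, kept = frame_weights(frames, final_bias, kt=kt,
                                          last_half_only=last_half_only)
    else:
        weights = np.asarray(weights, dtype=float)
        kept = np.ones(len(frames), dtype=bool)
    sub = [i for i in range(len(frames)) if kept[i]]
    binned, _ = bin_frames([frames[i] for i in sub], bin_edges)
    # remap local indices back to the original frame list
    for idx in np.ndindex(*binned.shape):
        binned[idx] = [sub[j] for j in binned[idx]]
    reps = select_top_k(binned, weights, frames, k=k)

    shape = binned.shape
    mean = np.full(shape, np.nan)
    counts = np.zeros(shape, dtype=int)
    for idx in np.ndindex(*shape):
        vals = []
        used = []
        for i in reps[idx]:
            try:
                vals.append(float(observable(frames[i])))
                used.append(i)
            except Exception:  # noqa: BLE001 - per-frame failure is recoverable
                log.warning("observable failed on frame %d; skipping", i)
        reps[idx] = used
        if vals:
            mean[idx] = float(np.mean(vals))
            counts[idx] = len(vals)
    return ConditionalMap(bin_edges=[np.asarray(e, dtype=float) for e in bin_edges],
                          mean_observable=mean, counts=counts, representatives=reps)


@dataclass(frozen=True)
class ClusterResult:
    labels: np.ndarray
    centroids: np.ndarray
    inertia: float


def kmeans_cluster(features: np.ndarray, k: int, seed: int = 0) -> ClusterResult:
    """k-means (Lloyd's algorithm, k-means++ init) on caller-provided
    feature vectors — the representative-frame clustering used to pick
    structures for tunnel analysis.  Deterministic given ``seed``."""
    x = np.asarray(features, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > x.shape[0]:
        raise ValueError("k cannot exceed the number of points")
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, max_iter=300,
                algorithm="lloyd", random_state=int(seed)).fit(x)
    return ClusterResult(labels=km.labels_.astype(int),
                         centroids=km.cluster_centers_,
                         inertia=float(km.inertia_))
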