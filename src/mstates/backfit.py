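"""Winner-takes-all backfitting of group maps onto individual EEG.

Every frame (not only GFP peaks) is labeled with the group map of maximum
absolute spatial correlation, frames below the correlation threshold stay
unassigned, the labeling is temporally smoothed with a windowed-vote
rescoring, and segments of five frames or fewer are rejected — split in half,
the first half absorbed by the preceding segment, the second by the following
one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    UNASSIGNED,
    ChannelMismatchError,
    MicrostateMapSet,
    Recording,
    Segmentation,
    segments_from_labels,
)
from .cluster import _center_normalize
from .preprocess import average_reference, gfp


@dataclass
class SmoothingParams:
    window_half_width_frames: int = 5   # sliding window of 11 frames
    smoothness_weight: float = 15.0
    min_segment_frames: int = 5         # segments <= this many frames rejected
    min_corr: float = 0.5
    max_sweeps: int = 50

    def __post_init__(self) -> None:
        if (self.window_half_width_frames < 0 or self.smoothness_weight < 0
                or self.min_segment_frames < 0 or not 0 <= self.min_corr <= 1):
            raise ValueError("smoothing parameters must be non-negative")


try:
    from numba import njit
except ImportError:  # pragma: no cover - numba ships with the target stack
    def njit(**kwargs):
        def wrap(fn):
            return fn
        return wrap


@njit(cache=False)
def _smoothing_sweeps(labels, evidence, k, half, weight, max_sweeps):
    """Left-to-right Gauss-Seidel sweeps of the windowed-vote rescoring."""
    n = labels.size
    counts = np.zeros(k)
    for _sweep in range(max_sweeps):
        changed = 0
        for t in range(n):
            if labels[t] == UNASSIGNED:
                continue
            lo = max(0, t - half)
            hi = min(n, t + half + 1)
            counts[:] = 0.0
            total = 0
            unanimous = True
            for u in range(lo, hi):
                if u == t or labels[u] == UNASSIGNED:
                    continue
                counts[labels[u]] += 1.0
                total += 1
                if labels[u] != labels[t]:
                    unanimous = False
            if total > 0 and unanimous:
                continue  # unanimous neighborhood: leave untouched
            best_s = 0
            best_score = -1.0
            denom = total if total > 0 else 1
            for s in range(k):
                score = evidence[t, s] + weight * counts[s] / denom
                if score > best_score:
                    best_score = score
                    best_s = s
            if best_s != labels[t]:
                labels[t] = best_s
                changed += 1
        if changed == 0:
            break


def _correlation_matrix(recording: Recording, group_maps: MicrostateMapSet
                        ) -> tuple[np.ndarray, np.ndarray]:
    """|spatial correlation| of every frame with every map, plus frame GFP."""
    if list(recording.channel_names) != list(group_maps.channel_names):
        raise ChannelMismatchError(
            "recording channels do not match the group maps "
            f"({recording.n_channels} vs {len(group_maps.channel_names)})")
    rec = average_reference(recording)
    g = gfp(rec).values
    mn = _center_normalize(group_maps.maps)
    x = rec.data.T  # frames x channels, zero-mean rows after average reference
    norms = np.linalg.norm(x, axis=1, keepdims=True)
    safe = np.where(norms == 0, 1.0, norms)
    corr = np.abs((x / safe) @ mn.T)
    corr[norms.ravel() == 0] = 0.0
    return corr, g


def label_frames(recording: Recording, group_maps: MicrostateMapSet,
                 min_corr: float = 0.5) -> Segmentation:
    """Assign each frame its argmax-|correlation| map; below threshold -> unassigned."""
    corr, g = _correlation_matrix(recording, group_maps)
    labels = np.argmax(corr, axis=1)
    best = corr[np.arange(len(labels)), labels]
    labels = np.where(best >= min_corr, labels, UNASSIGNED)
    return Segmentation(labels=labels, sampling_rate=recording.sampling_rate,
                        corr=best, gfp=g)


def smooth_labels(segmentation: Segmentation, map_correlations: np.ndarray,
                  params: SmoothingParams | None = None) -> Segmentation:
    """Windowed-vote temporal smoothing of a frame labeling.

    Each assigned frame is rescored as evidence + smoothness:
    ``(GFP_t * corr_st)^2 / mean(GFP^2)`` plus ``smoothness_weight`` times the
    fraction of the surrounding window (current frame excluded) already
    carrying label s; sweeps run left-to-right to a fixed point (capped).
    Frames whose window is unanimous are never changed, and unassigned frames
    never gain a label.
    """
    params = params or SmoothingParams()
    labels = segmentation.labels.copy()
    n = labels.size
    corr = np.asarray(map_correlations, dtype=float)
    if corr.shape[0] != n:
        raise ValueError("map_correlations must have one row per frame")
    k = corr.shape[1]
    if params.smoothness_weight == 0 or params.window_half_width_frames == 0:
        return Segmentation(labels=labels, sampling_rate=segmentation.sampling_rate,
                            corr=segmentation.corr, gfp=segmentation.gfp)
    g = segmentation.gfp if segmentation.gfp is not None else np.ones(n)
    g2 = g ** 2
    # evidence scaled by the residual (unexplained) variance, so the
    # smoothness weight acts as the gentle tie-breaker it is meant to be
    best = corr.max(axis=1)
    noise_var = float(np.mean(g2 * (1.0 - best ** 2)))
    noise_var = max(noise_var, 1e-12 * max(float(np.mean(g2)), 1e-300))
    evidence = (g2[:, None] * corr ** 2) / (2.0 * noise_var)

    _smoothing_sweeps(labels, evidence, k, params.window_half_width_frames,
                      float(params.smoothness_weight), params.max_sweeps)
    winning = corr[np.arange(n), np.where(labels == UNASSIGNED, 0, labels)]
    winning = np.where(labels == UNASSIGNED,
                       segmentation.corr if segmentation.corr is not None else 0.0,
                       winning)
    return Segmentation(labels=labels, sampling_rate=segmentation.sampling_rate,
                        corr=winning, gfp=segmentation.gfp)


def reject_small_segments(segmentation: Segmentation,
                          min_segment_frames: int = 5) -> Segmentation:
    """Reject segments of ``min_segment_frames`` frames or fewer.

    A rejected segment is split in half: the first floor(n/2) frames take the
    label of the directly adjacent preceding segment, the rest the label of
    the directly adjacent following segment. A short segment at a recording
    edge (or against an unassigned gap) is wholly absorbed by its single
    adjacent neighbor; with no adjacent labeled neighbor at all it becomes
    unassigned. Absorption can merge runs and create new short segments, so
    the rule is re-applied to a fixed point.
    """
    labels = segmentation.labels.copy()
    # one segment at a time (leftmost first), re-deriving runs after each
    # absorption: simultaneous rewrites of adjacent short runs can oscillate
    for _step in range(4 * (labels.size + 1)):
        segs = segments_from_labels(labels)
        short = next((i for i, s in enumerate(segs)
                      if s.length <= min_segment_frames), None)
        if short is None:
            break
        s = segs[short]
        prev_seg = segs[short - 1] if short > 0 else None
        next_seg = segs[short + 1] if short + 1 < len(segs) else None
        prev_adj = prev_seg is not None and prev_seg.stop == s.start
        next_adj = next_seg is not None and next_seg.start == s.stop
        if prev_adj and next_adj:
            split = s.length // 2
            labels[s.start:s.start + split] = prev_seg.state
            labels[s.start + split:s.stop] = next_seg.state
        elif prev_adj:
            labels[s.start:s.stop] = prev_seg.state
        elif next_adj:
            labels[s.start:s.stop] = next_seg.state
        else:
            labels[s.start:s.stop] = UNASSIGNED
    return Segmentation(labels=labels, sampling_rate=segmentation.sampling_rate,
                        corr=segmentation.corr, gfp=segmentation.gfp)


def backfit_subject(recording: Recording, group_maps: MicrostateMapSet,
                    params: SmoothingParams | None = None) -> Segmentation:
    """Full backfitting stage: label, smooth, reject small segments.

    The per-frame winning correlation and GFP are retained on the result so
    source imaging can apply its 0.9 correlation gate afterwards.
    """
    params = params or SmoothingParams()
    corr, _g = _correlation_matrix(recording, group_maps)
    seg = label_frames(recording, group_maps, params.min_corr)
    seg = smooth_labels(seg, corr, params)
    seg = reject_small_segments(seg, params.min_segment_frames)
    n = seg.labels.size
    idx = np.where(seg.labels == UNASSIGNED, 0, seg.labels)
    winning = corr[np.arange(n), idx]
    winning[seg.labels == UNASSIGNED] = 0.0
    seg.corr = winning
    return seg
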