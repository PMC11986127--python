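"""Per-subject, per-state temporal microstate parameters.

Four parameters per state: GEV (% of GFP^2-weighted variance explained),
mean duration (ms), time coverage (% of labeled time) and occurrence rate
(segments per second of labeled time). "Labeled time" excludes unassigned
frames from every denominator except GEV's, whose denominator is the total
GFP^2 over all frames.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import UNASSIGNED, MicrostateMapSet, Recording, Segmentation
from .backfit import _correlation_matrix
from .io import METRIC_COLUMNS


def _labeled_frames(segmentation: Segmentation) -> int:
    return int(np.sum(segmentation.labels != UNASSIGNED))


def duration_ms(segmentation: Segmentation, state: int) -> float:
    """Mean segment length of ``state`` in ms; NaN when the state never occurs."""
    lengths = [s.length for s in segmentation.segments if s.state == state]
    if not lengths:
        return float("nan")
    return float(np.mean(lengths) * 1000.0 / segmentation.sampling_rate)


def occurrence_per_s(segmentation: Segmentation, state: int) -> float:
    """Segments of ``state`` per second of total labeled time (all states)."""
    labeled = _labeled_frames(segmentation)
    if labeled == 0:
        raise ValueError("occurrence undefined: no labeled frames")
    count = sum(1 for s in segmentation.segments if s.state == state)
    return float(count * segmentation.sampling_rate / labeled)


def coverage_pct(segmentation: Segmentation, state: int) -> float:
    """Percentage of labeled time spent in ``state``."""
    labeled = _labeled_frames(segmentation)
    if labeled == 0:
        raise ValueError("coverage undefined: no labeled frames")
    return float(np.sum(segmentation.labels == state) / labeled * 100.0)


def gev_pct(recording: Recording, segmentation: Segmentation,
            group_maps: MicrostateMapSet, state: int) -> float:
    """State-wise GEV: 100 * sum_{t: label=s} (GFP_t corr_t)^2 / sum_all GFP_t^2."""
    corr, g = _correlation_matrix(recording, group_maps)
    denom = float(np.sum(g ** 2))
    if denom == 0:
        raise ValueError("GEV undefined: all-zero GFP")
    mask = segmentation.labels == state
    c = corr[mask, state]
    return float(100.0 * np.sum((g[mask] * c) ** 2) / denom)


def subject_metrics(recording: Recording | None, segmentation: Segmentation,
                    group_maps: MicrostateMapSet, subject_id: str = "s0",
                    group: str = "g0") -> pd.DataFrame:
    """Tidy one-subject metrics table over every group-map state.

    Absent states get NaN duration and zero coverage/occurrence/GEV. When no
    recording is given (label-sequence-only input) GEV is NaN.
    """
    rows = []
    gevs = None
    if recording is not None:
        corr, g = _correlation_matrix(recording, group_maps)
        denom = float(np.sum(g ** 2))
        if denom == 0:
            raise ValueError("GEV undefined: all-zero GFP")
        gevs = []
        for state in range(group_maps.n_maps):
            mask = segmentation.labels == state
            gevs.append(100.0 * np.sum((g[mask] * corr[mask, state]) ** 2) / denom)
    for state in range(group_maps.n_maps):
        present = bool(np.any(segmentation.labels == state))
        rows.append({
            "subject_id": subject_id, "group": group, "state": group_maps.labels[state],
            "gev_pct": (gevs[state] if gevs is not None else float("nan")),
            "duration_ms": duration_ms(segmentation, state) if present else float("nan"),
            "coverage_pct": coverage_pct(segmentation, state) if present else 0.0,
            "occurrence_per_s": occurrence_per_s(segmentation, state) if present else 0.0,
        })
    return pd.DataFrame(rows, columns=METRIC_COLUMNS)


def metrics_table(cohort: list[tuple[str, str, Recording | None, Segmentation]],
                  group_maps: MicrostateMapSet) -> pd.DataFrame:
    """Stack per-subject metrics into one tidy table.

    ``cohort`` holds (subject_id, group, recording-or-None, segmentation)
    tuples; an empty cohort yields an empty table with the standard columns.
    """
    if not cohort:
        return pd.DataFrame(columns=METRIC_COLUMNS)
    frames = [subject_metrics(rec, seg, group_maps, sid, grp)
              for sid, grp, rec, seg in cohort]
    return pd.concat(frames, ignore_index=True)
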