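"""Frame-to-frame cell linking by minimum-cost (Munkres-style) assignment.

The cost of linking two detections is the Euclidean distance between their
nucleus centroids; pairs farther apart than a gating distance are forbidden.
The matching returned is of maximum cardinality among matchings avoiding
forbidden pairs, and of minimum total cost among those — the behaviour of
the Hungarian/Munkres algorithm with unmatchable entries.  Tracks are chained
over frames, with detections unmatched to any live track starting new
tracks and tracks allowed to bridge up to ``max_gap`` missing frames.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

__all__ = [
    "MISSING",
    "TrackTable",
    "build_cost_matrix",
    "solve_assignment",
    "link_tracks",
    "track_movie",
]

MISSING = -1  # label sentinel for a bridged (gap) frame


def build_cost_matrix(
    centroids_t: np.ndarray,
    centroids_t1: np.ndarray,
    max_link_dist_px: float = 15.0,
) -> np.ndarray:
    """Euclidean-distance cost matrix with gated entries set to +inf."""
    a = np.asarray(centroids_t, dtype=float).reshape(-1, 2)
    b = np.asarray(centroids_t1, dtype=float).reshape(-1, 2)
    if a.size == 0 or b.size == 0:
        return np.empty((len(a), len(b)))
    cost = cdist(a, b)
    cost[cost > max_link_dist_px] = np.inf
    return cost


def solve_assignment(
    cost: np.ndarray,
) -> Tuple[List[Tuple[int, int]], List[int], List[int]]:
    """Minimum-cost matching respecting forbidden (+inf) entries.

    Maximizes cardinality first, then minimizes total cost, via a padded
    square problem solved with an optimal linear-assignment routine.
    Returns (matches, unmatched_rows, unmatched_cols).
    """
    cost = np.asarray(cost, dtype=float)
    n, m = cost.shape
    if n == 0 or m == 0:
        return [], list(range(n)), list(range(m))
    finite = cost[np.isfinite(cost)]
    big = float(finite.sum()) + 1.0 if finite.size else 1.0
    forbidden = 4.0 * big  # > 2*big: never preferred over two dummies
    padded = np.full((n + m, n + m), forbidden)
    tl = np.where(np.isfinite(cost), cost, forbidden)
    padded[:n, :m] = tl
    padded[:n, m:] = forbidden
    padded[n:, :m] = forbidden
    padded[np.arange(n), m + np.arange(n)] = big
    padded[n + np.arange(m), np.arange(m)] = big
    padded[n:, m:] = 0.0
    rows, cols = linear_sum_assignment(padded)
    matches = [
        (int(i), int(j))
        for i, j in zip(rows, cols)
        if i < n and j < m and np.isfinite(cost[i, j])
    ]
    matched_rows = {i for i, _ in matches}
    matched_cols = {j for _, j in matches}
    return (
        sorted(matches),
        [i for i in range(n) if i not in matched_rows],
        [j for j in range(m) if j not in matched_cols],
    )


@dataclass
class TrackTable:
    """Identity linkage of per-frame labels into tracks.

    ``table`` is a long DataFrame (track_id, frame, label, centroid_y,
    centroid_x); ``label == MISSING`` marks a bridged interior frame.
    Track ids are dense from 1 in order of birth.
    """

    table: pd.DataFrame

    @property
    def track_ids(self) -> np.ndarray:
        return np.unique(self.table["track_id"].to_numpy())

    def track(self, track_id: int) -> pd.DataFrame:
        sub = self.table[self.table["track_id"] == track_id]
        return sub.sort_values("frame").reset_index(drop=True)

    def spans(self) -> pd.DataFrame:
        g = self.table.groupby("track_id")["frame"]
        return pd.DataFrame({"birth": g.min(), "end": g.max()})

    def n_tracks(self) -> int:
        return len(self.track_ids)


class _Track:
    __slots__ = ("track_id", "rows", "last_frame", "last_pos")

    def __init__(self, track_id, frame, label, pos):
        self.track_id = track_id
        self.rows = [(frame, label, pos[0], pos[1])]
        self.last_frame = frame
        self.last_pos = pos

    def extend(self, frame, label, pos):
        for gap_frame in range(self.last_frame + 1, frame):
            self.rows.append((gap_frame, MISSING, np.nan, np.nan))
        self.rows.append((frame, label, pos[0], pos[1]))
        self.last_frame = frame
        self.last_pos = pos


def link_tracks(
    centroids_per_frame: Sequence[np.ndarray],
    labels_per_frame: Optional[Sequence[np.ndarray]] = None,
    max_link_dist_px: float = 15.0,
    max_gap: int = 0,
) -> TrackTable:
    """Chain per-frame detections into tracks by gated optimal assignment.

    Live tracks (seen within the last ``max_gap + 1`` frames) compete for
    the detections of each new frame; unmatched detections are births,
    tracks unmatched for more than ``max_gap`` frames are closed.
    """
    live: List[_Track] = []
    done: List[_Track] = []
    next_id = 1
    for frame, cents in enumerate(centroids_per_frame):
        cents = np.asarray(cents, dtype=float).reshape(-1, 2)
        labels = (
            np.asarray(labels_per_frame[frame])
            if labels_per_frame is not None
            else np.arange(1, len(cents) + 1)
        )
        still_live = [tr for tr in live if frame - tr.last_frame <= max_gap + 1]
        done.extend(tr for tr in live if frame - tr.last_frame > max_gap + 1)
        live = still_live
        if live and len(cents):
            prev = np.array([tr.last_pos for tr in live])
            cost = build_cost_matrix(prev, cents, max_link_dist_px)
            matches, _, unmatched_cols = solve_assignment(cost)
        else:
            matches, unmatched_cols = [], list(range(len(cents)))
        for i, j in matches:
            live[i].extend(frame, int(labels[j]), cents[j])
        for j in unmatched_cols:
            live.append(_Track(next_id, frame, int(labels[j]), cents[j]))
            next_id += 1
    done.extend(live)
    rows = []
    for tr in sorted(done, key=lambda tr: tr.track_id):
        for f, lab, cy, cx in tr.rows:
            rows.append((tr.track_id, f, lab, cy, cx))
    table = pd.DataFrame(
        rows, columns=["track_id", "frame", "label", "centroid_y", "centroid_x"]
    )
    return TrackTable(table)


def track_movie(
    masks_per_frame,
    max_link_dist_px: float = 15.0,
    max_gap: int = 0,
) -> TrackTable:
    """Link the segmented nuclei of a movie (list of CellMasks) into tracks."""
    cents, labels = [], []
    for masks in masks_per_frame:
        cents.append(masks.centroids())
        labels.append(masks.labels)
    return link_tracks(cents, labels, max_link_dist_px, max_gap)
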