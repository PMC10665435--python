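"""Per-cell C/N intensity-ratio time series and normalization.

For each tracked cell and frame, the raw C/N value is the arithmetic mean
of the reporter channel over the cell's cytoplasm-ring pixels divided by
the mean over its nucleus pixels.  Traces are normalized to the single
frame just prior to stimulation, so the normalized value there is exactly
1.  The ratio is invariant to any positive scaling of the reporter channel,
and to constant background provided subtraction is applied identically to
numerator and denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .movie import MovieStack
from .segment import CellMasks
from .tracking import MISSING, TrackTable

__all__ = ["CNTrace", "measure_cn", "normalize_trace", "traces_to_frame"]


@dataclass
class CNTrace:
    """One cell's C/N ratio time series (times in s relative to stimulation)."""

    track_id: int
    frames: np.ndarray
    times_s: np.ndarray
    cn_raw: np.ndarray
    cn_norm: Optional[np.ndarray] = None
    border_cell: bool = False
    n_missing: int = 0
    n_undefined: int = 0
    exclusion_reason: Optional[str] = None

    def valid(self) -> np.ndarray:
        return np.isfinite(self.cn_raw)


def measure_cn(
    movie: MovieStack,
    masks_per_frame: Sequence[CellMasks],
    tracks: TrackTable,
) -> List[CNTrace]:
    """Raw C/N trace per track: mean ring / mean nucleus reporter intensity.

    Frames where the track is MISSING, the nuclear mean is non-positive, or
    a mask is empty yield undefined (NaN) entries and are flagged, never
    interpolated.
    """
    if len(masks_per_frame) != movie.n_frames:
        raise ValueError("masks and movie must cover the same frames")
    reporter = movie.channel("reporter")
    times = movie.times_s()
    out: List[CNTrace] = []
    border_per_frame = [set(m.border_labels().tolist()) for m in masks_per_frame]
    # per-frame, per-label intensity sums and pixel counts in one pass
    nuc_mean_pf: List[np.ndarray] = []
    ring_mean_pf: List[np.ndarray] = []
    for f, masks in enumerate(masks_per_frame):
        img = reporter[f].ravel().astype(float)
        nl = masks.nucleus_labels.ravel()
        rl = masks.ring_labels.ravel()
        n_lab = int(max(nl.max(), rl.max())) + 1
        with np.errstate(invalid="ignore", divide="ignore"):
            nuc_mean = np.bincount(nl, weights=img, minlength=n_lab) / np.bincount(
                nl, minlength=n_lab
            )
            ring_mean = np.bincount(rl, weights=img, minlength=n_lab) / np.bincount(
                rl, minlength=n_lab
            )
        nuc_mean_pf.append(nuc_mean)
        ring_mean_pf.append(ring_mean)
    for tid in tracks.track_ids:
        sub = tracks.track(tid)
        frames = sub["frame"].to_numpy()
        labels = sub["label"].to_numpy()
        cn = np.full(len(frames), np.nan)
        n_missing = 0
        n_undefined = 0
        border = False
        for k, (f, lab) in enumerate(zip(frames, labels)):
            if lab == MISSING:
                n_missing += 1
                continue
            if lab in border_per_frame[f]:
                border = True
            nm = nuc_mean_pf[f]
            rm = ring_mean_pf[f]
            if lab >= len(nm):
                n_undefined += 1
                continue
            nuc_mean = nm[lab]
            ring_mean = rm[lab]
            if not np.isfinite(nuc_mean) or not np.isfinite(ring_mean) or nuc_mean <= 0:
                n_undefined += 1
                continue
            cn[k] = float(ring_mean) / float(nuc_mean)
        out.append(
            CNTrace(
                track_id=int(tid),
                frames=frames,
                times_s=times[frames],
                cn_raw=cn,
                border_cell=border,
                n_missing=n_missing,
                n_undefined=n_undefined,
            )
        )
    return out


def normalize_trace(trace: CNTrace, stimulation_frame: int) -> CNTrace:
    """Divide by the value at the frame just prior to stimulation.

    The reference frame is index ``stimulation_frame - 1``.  A trace with no
    defined positive value there is excluded with an explicit reason and
    left unnormalized.
    """
    ref_frame = stimulation_frame - 1
    where = np.nonzero(trace.frames == ref_frame)[0]
    if len(where) == 0:
        trace.exclusion_reason = "no_reference_frame"
        return trace
    ref = trace.cn_raw[where[0]]
    if not np.isfinite(ref) or ref <= 0:
        trace.exclusion_reason = "undefined_reference_value"
        return trace
    trace.cn_norm = trace.cn_raw / ref
    return trace


def traces_to_frame(traces: Sequence[CNTrace]) -> pd.DataFrame:
    """Long-format table: track_id, frame, time_s, cn_raw, cn_norm, flags."""
    rows = []
    for tr in traces:
        norm = tr.cn_norm if tr.cn_norm is not None else np.full_like(tr.cn_raw, np.nan)
        for f, t, raw, cn in zip(tr.frames, tr.times_s, tr.cn_raw, norm):
            rows.append(
                {
                    "track_id": tr.track_id,
                    "frame": int(f),
                    "time_s": float(t),
                    "cn_raw": raw,
                    "cn_norm": cn,
                    "border_cell": tr.border_cell,
                    "excluded": tr.exclusion_reason or "",
                }
            )
    return pd.DataFrame(rows)
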