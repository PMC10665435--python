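"""Reading and writing movies, truth, masks, traces and fits on disk.

A movie directory holds ``movie.tif`` (frames x channels, 16-bit
multi-page TIFF), a ``meta.yaml`` sidecar (pixel size, frame interval,
stimulation frame, channel roles), and — for synthetic movies — the truth
channel: ``truth_params.csv`` and ``truth_labels.tif``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import tifffile
import yaml

from .kinetics import KineticParams
from .movie import MovieStack
from .simulate import CellTruth, GroundTruth

__all__ = ["write_movie", "read_movie", "write_truth", "read_truth_params"]


def write_movie(movie: MovieStack, out_dir) -> Path:
    """Write movie.tif (uint16) and meta.yaml into ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    data = np.clip(np.round(movie.pixels), 0, np.iinfo(np.uint16).max).astype(
        np.uint16
    )
    tifffile.imwrite(out_dir / "movie.tif", data, metadata={"axes": "TCYX"})
    meta = {
        "pixel_size_um": float(movie.pixel_size_um),
        "frame_interval_s": float(movie.frame_interval_s),
        "stimulation_frame": int(movie.stimulation_frame),
        "channel_roles": {k: int(v) for k, v in movie.channel_roles.items()},
    }
    (out_dir / "meta.yaml").write_text(yaml.safe_dump(meta))
    return out_dir


def read_movie(in_dir) -> MovieStack:
    in_dir = Path(in_dir)
    pixels = tifffile.imread(in_dir / "movie.tif").astype(np.float32)
    if pixels.ndim == 3:  # single-frame-axis fallback
        pixels = pixels[:, None]
    meta = yaml.safe_load((in_dir / "meta.yaml").read_text())
    return MovieStack(
        pixels=pixels,
        pixel_size_um=meta["pixel_size_um"],
        frame_interval_s=meta["frame_interval_s"],
        stimulation_frame=meta["stimulation_frame"],
        channel_roles=meta["channel_roles"],
    )


def write_truth(truth: GroundTruth, out_dir) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, cell in enumerate(truth.cells):
        p = cell.params
        rows.append(
            {
                "cell": i,
                "archetype": cell.archetype,
                "variant": p.variant,
                "k_on": p.k_on,
                "t_on": p.t_on,
                "R_eq": p.R_eq,
                "k_off": p.k_off if p.k_off is not None else np.nan,
                "t_off": p.t_off if p.t_off is not None else np.nan,
            }
        )
    pd.DataFrame(rows).to_csv(out_dir / "truth_params.csv", index=False)
    tifffile.imwrite(out_dir / "truth_labels.tif", truth.label_images)
    return out_dir


def read_truth_params(in_dir) -> pd.DataFrame:
    return pd.read_csv(Path(in_dir) / "truth_params.csv")
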