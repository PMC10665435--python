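"""Ground-truthed synthetic two-channel KTR movies and C/N traces.

Emulates the acquisition the analysis assumes: a Hoechst-like nuclear dye in
channel 0, the translocation reporter in channel 1, frames every 15 s for
30 min after serum stimulation plus a few pre-stimulation frames.  Cells are
drawn from three archetypes — young and mid-old respond with the monotone
kinetic model, old cells with the transient recovery model — and rendered as
hard (non-anti-aliased) disks so pixel-count oracles are exact.  The reporter
is painted so that (mean ring intensity)/(mean nucleus intensity) equals the
true C/N ratio before noise; only the ratio is constrained by the model, so
the nuclear mean is held at a constant gain.

Not emulated: photobleaching, shot-noise camera statistics, defocus blur,
cell division and apoptosis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .kinetics import KineticParams, eval_model
from .movie import MovieStack

__all__ = [
    "ARCHETYPES",
    "DEFAULT_PARAM_DISTS",
    "PopulationSpec",
    "ImagingSpec",
    "GroundTruth",
    "CellTruth",
    "sample_population",
    "synthesize_traces",
    "render_movie",
    "simulate_movie",
]

ARCHETYPES = ("young", "mid_old", "old")

# Per-archetype uniform sampling ranges for the true kinetic parameters.
# Rates in 1/s, delays in s.  Old cells carry the recovery-model extension;
# the t_off range lies strictly above every archetype's t_on range.
DEFAULT_PARAM_DISTS: Dict[str, Dict[str, Tuple[float, float]]] = {
    "young": {"k_on": (0.008, 0.020), "t_on": (30.0, 90.0), "R_eq": (2.0, 3.5)},
    "mid_old": {"k_on": (0.006, 0.015), "t_on": (40.0, 120.0), "R_eq": (1.8, 3.0)},
    "old": {
        "k_on": (0.003, 0.010),
        "t_on": (60.0, 150.0),
        "R_eq": (1.8, 3.0),
        "k_off": (0.002, 0.006),
        "t_off": (400.0, 800.0),
    },
}


@dataclass(frozen=True)
class PopulationSpec:
    """How many cells of which archetype, and their parameter ranges."""

    n_cells: int
    archetype_mix: Mapping[str, float]
    param_dists: Mapping[str, Mapping[str, Tuple[float, float]]] = field(
        default_factory=lambda: DEFAULT_PARAM_DISTS
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        mix = dict(self.archetype_mix)
        unknown = set(mix) - set(ARCHETYPES)
        if unknown:
            raise ValueError(f"unknown archetypes {sorted(unknown)}")
        if any(not (0.0 <= p <= 1.0) for p in mix.values()):
            raise ValueError("archetype proportions must lie in [0, 1]")
        if abs(sum(mix.values()) - 1.0) > 1e-9:
            raise ValueError(
                f"archetype proportions must sum to 1, got {sum(mix.values())}"
            )
        for arch in mix:
            dists = self.param_dists[arch]
            required = {"k_on", "t_on", "R_eq"} | (
                {"k_off", "t_off"} if arch == "old" else set()
            )
            missing = required - set(dists)
            if missing:
                raise ValueError(f"{arch}: missing parameter ranges {sorted(missing)}")
            for name in required:
                lo, hi = dists[name]
                if not (lo <= hi):
                    raise ValueError(f"{arch}.{name}: empty range ({lo}, {hi})")
                if name in ("k_on", "k_off") and lo <= 0:
                    raise ValueError(f"{arch}.{name}: rates must be strictly positive")
            if arch == "old" and dists["t_off"][0] <= dists["t_on"][1]:
                raise ValueError("old: t_off range must lie strictly above t_on range")


@dataclass(frozen=True)
class ImagingSpec:
    """Acquisition geometry, schedule, noise and motion of the rendering.

    Defaults follow the study schedule: one frame every 15 s for 30 min after
    stimulation, at 0.22 um/px so that the 5-px measurement ring spans
    ~1.1 um.  ``n_prestim_frames`` pre-stimulation frames precede t = 0.
    """

    frame_interval_s: float = 15.0
    duration_s: float = 1800.0
    n_prestim_frames: int = 4
    image_size: Tuple[int, int] = (256, 256)
    pixel_size_um: float = 0.22
    nucleus_radius_px: int = 8
    cyto_width_px: int = 8
    noise_sd: float = 0.0
    background_level: float = 0.0
    motion_sd_px: float = 0.0
    global_drift_px: Tuple[float, float] = (0.0, 0.0)
    dye_intensity: float = 100.0
    nucleus_intensity: float = 100.0
    on_collision: str = "resample"  # or "raise"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be > 0")
        if self.n_frames < 2:
            raise ValueError("schedule must yield at least 2 frames")
        if self.n_prestim_frames < 1:
            raise ValueError("at least one pre-stimulation frame is required")
        if self.on_collision not in ("resample", "raise"):
            raise ValueError("on_collision must be 'resample' or 'raise'")

    @property
    def n_post_frames(self) -> int:
        return int(round(self.duration_s / self.frame_interval_s)) + 1

    @property
    def n_frames(self) -> int:
        return self.n_prestim_frames + self.n_post_frames

    @property
    def stimulation_frame(self) -> int:
        return self.n_prestim_frames

    def times_s(self) -> np.ndarray:
        return (
            np.arange(self.n_frames, dtype=float) - self.stimulation_frame
        ) * self.frame_interval_s

    @property
    def min_separation_px(self) -> float:
        return 2.0 * (self.nucleus_radius_px + self.cyto_width_px) + 1.0


@dataclass(frozen=True)
class CellTruth:
    archetype: str
    params: KineticParams


@dataclass
class GroundTruth:
    """Truth channel for testing: what the generator actually drew."""

    cells: List[CellTruth]
    centroids: np.ndarray  # (frames, n_cells, 2) float, (row, col)
    true_cn: np.ndarray  # (n_cells, frames)
    label_images: np.ndarray  # (frames, H, W) int; cell i has label i+1
    times_s: np.ndarray

    @property
    def n_cells(self) -> int:
        return len(self.cells)


def sample_population(spec: PopulationSpec, rng: Optional[np.random.Generator] = None):
    """Draw per-cell true kinetic parameter sets; deterministic given seed."""
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    archs = sorted(spec.archetype_mix)
    probs = np.array([spec.archetype_mix[a] for a in archs], dtype=float)
    chosen = rng.choice(len(archs), size=spec.n_cells, p=probs / probs.sum())
    cells: List[CellTruth] = []
    for idx in chosen:
        arch = archs[int(idx)]
        dists = spec.param_dists[arch]
        draw = {name: float(rng.uniform(*dists[name])) for name in sorted(dists)}
        if arch == "old":
            params = KineticParams(
                "recovery",
                k_on=draw["k_on"],
                t_on=draw["t_on"],
                R_eq=draw["R_eq"],
                k_off=draw["k_off"],
                t_off=draw["t_off"],
            )
        else:
            params = KineticParams(
                "monotone", k_on=draw["k_on"], t_on=draw["t_on"], R_eq=draw["R_eq"]
            )
        cells.append(CellTruth(arch, params))
    return cells


def synthesize_traces(cells: Sequence[CellTruth] | Sequence[KineticParams], times_s):
    """Noiseless model C/N series, one row per cell, at the given times.

    ``times_s`` must be strictly increasing and include at least one
    pre-stimulation time (t < 0); there the model value is exactly 1.
    """
    times_s = np.asarray(times_s, dtype=float)
    if np.any(np.diff(times_s) <= 0):
        raise ValueError("times_s must be strictly increasing")
    if not np.any(times_s < 0):
        raise ValueError("times_s must include a pre-stimulation time (t < 0)")
    rows = []
    for cell in cells:
        params = cell.params if isinstance(cell, CellTruth) else cell
        rows.append(eval_model(params, times_s))
    return np.array(rows) if rows else np.empty((0, len(times_s)))


def _initial_positions(n: int, shape, margin: float, sep: float, rng) -> np.ndarray:
    """Jittered-grid placement keeping centers >= sep apart and off borders."""
    h, w = shape
    usable_h, usable_w = h - 2 * margin, w - 2 * margin
    if n == 0:
        return np.empty((0, 2))
    if usable_h <= 0 or usable_w <= 0:
        raise ValueError("image too small for the requested cell geometry")
    cols = max(1, int(usable_w // sep))
    rows_needed = math.ceil(n / cols)
    pitch_r = usable_h / max(rows_needed, 1)
    pitch_c = usable_w / cols
    if (pitch_r < sep and rows_needed > 1) or (pitch_c < sep and n > 1):
        raise ValueError(
            f"cannot place {n} cells with separation {sep:.0f}px in {shape}"
        )
    nodes = []
    for i in range(rows_needed):
        for j in range(cols):
            nodes.append((margin + (i + 0.5) * pitch_r, margin + (j + 0.5) * pitch_c))
    order = rng.permutation(len(nodes))[:n]
    pos = np.array([nodes[k] for k in order], dtype=float)
    jit_r = max((pitch_r - sep) / 2.0, 0.0)
    jit_c = max((pitch_c - sep) / 2.0, 0.0)
    pos += rng.uniform(-1.0, 1.0, size=pos.shape) * np.array([jit_r, jit_c])
    return pos


def _trajectories(pos0: np.ndarray, imaging: ImagingSpec, rng) -> np.ndarray:
    """Seeded random walk + global drift, with pairwise-collision rejection."""
    n = len(pos0)
    T = imaging.n_frames
    out = np.empty((T, n, 2))
    out[0] = pos0
    drift = np.asarray(imaging.global_drift_px, dtype=float)
    sep = imaging.min_separation_px
    for t in range(1, T):
        for attempt in range(200):
            step = (
                rng.normal(0.0, imaging.motion_sd_px, size=(n, 2))
                if imaging.motion_sd_px > 0
                else np.zeros((n, 2))
            )
            cand = out[t - 1] + step + drift
            if n < 2:
                out[t] = cand
                break
            d = np.sqrt(
                ((cand[:, None, :] - cand[None, :, :]) ** 2).sum(-1)
            )
            np.fill_diagonal(d, np.inf)
            if d.min() >= sep:
                out[t] = cand
                break
            if imaging.on_collision == "raise":
                raise RuntimeError(f"cell collision at frame {t}")
        else:
            raise RuntimeError(f"could not resolve cell collision at frame {t}")
    return out


def render_movie(
    cells: Sequence[CellTruth], imaging: ImagingSpec
) -> Tuple[MovieStack, GroundTruth]:
    """Render a two-channel movie for the given cells; returns pixel truth.

    Channel 0 (dye): nuclei as hard bright disks on ``background_level``.
    Channel 1 (reporter): nucleus pixels at ``nucleus_intensity``, a
    cytoplasm annulus of width ``cyto_width_px`` at ``nucleus_intensity *
    C/N(t)``, so the ring/nucleus mean ratio equals the true C/N exactly
    before noise.  Additive Gaussian pixel noise of SD ``noise_sd``.
    """
    rng = np.random.default_rng(imaging.seed)
    h, w = imaging.image_size
    T = imaging.n_frames
    n = len(cells)
    times = imaging.times_s()
    true_cn = synthesize_traces(cells, times) if n else np.empty((0, T))

    r_nuc = imaging.nucleus_radius_px
    r_out = r_nuc + imaging.cyto_width_px
    margin = r_out + 2.0
    pos0 = _initial_positions(n, (h, w), margin, imaging.min_separation_px, rng)
    centroids = (
        _trajectories(pos0, imaging, rng) if n else np.empty((T, 0, 2))
    )

    label_dtype = np.uint8 if n < 255 else np.uint16
    labels = np.zeros((T, h, w), dtype=label_dtype)
    pixels = np.full((T, 2, h, w), float(imaging.background_level), dtype=np.float32)

    yy, xx = np.mgrid[0:h, 0:w]
    for t in range(T):
        for i in range(n):
            cy, cx = centroids[t, i]
            y0, y1 = int(max(cy - r_out - 1, 0)), int(min(cy + r_out + 2, h))
            x0, x1 = int(max(cx - r_out - 1, 0)), int(min(cx + r_out + 2, w))
            d2 = (yy[y0:y1, x0:x1] - cy) ** 2 + (xx[y0:y1, x0:x1] - cx) ** 2
            nuc = d2 <= r_nuc**2
            cyto = (d2 > r_nuc**2) & (d2 <= r_out**2)
            labels[t, y0:y1, x0:x1][nuc] = i + 1
            pixels[t, 0, y0:y1, x0:x1][nuc] += imaging.dye_intensity
            pixels[t, 1, y0:y1, x0:x1][nuc] += imaging.nucleus_intensity
            pixels[t, 1, y0:y1, x0:x1][cyto] += imaging.nucleus_intensity * true_cn[i, t]
    if imaging.noise_sd > 0:
        pixels += rng.normal(0.0, imaging.noise_sd, size=pixels.shape).astype(
            np.float32
        )
        np.clip(pixels, 0.0, None, out=pixels)

    movie = MovieStack(
        pixels=pixels,
        pixel_size_um=imaging.pixel_size_um,
        frame_interval_s=imaging.frame_interval_s,
        stimulation_frame=imaging.stimulation_frame,
    )
    truth = GroundTruth(
        cells=list(cells),
        centroids=centroids,
        true_cn=true_cn,
        label_images=labels,
        times_s=times,
    )
    return movie, truth


def simulate_movie(
    pop: PopulationSpec, imaging: ImagingSpec
) -> Tuple[MovieStack, GroundTruth]:
    """Sample a population and render it: the one-call generator."""
    cells = sample_population(pop)
    return render_movie(cells, imaging)
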