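"""Self-contained validation experiments for the reconstruction pipeline.

Each function regenerates its own synthetic inputs from a seed, runs the
relevant stage(s) of the package, and measures accuracy against ground
truth or an independent reference computation (exhaustive permutation
search for assignment, brute-force pixel enumeration for ring geometry,
full rank-arrangement enumeration for the Mann-Whitney test).  The
reference computations here are deliberately naive and share no code with
the implementations they check.
"""

from __future__ import annotations

import itertools
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .kinetics import FitConfig, KineticParams, eval_monotone, eval_recovery, fit_trace
from .pipeline import PipelineConfig, run_pipeline
from .segment import make_cytoplasm_rings
from .simulate import (
    CellTruth,
    GroundTruth,
    ImagingSpec,
    PopulationSpec,
    render_movie,
    sample_population,
    synthesize_traces,
)
from .stats import mann_whitney_one_tailed
from .tracking import solve_assignment

__all__ = [
    "model_identity_residuals",
    "brute_force_assignment",
    "assignment_optimality",
    "ring_pixels_brute_force",
    "ring_geometry_check",
    "noiseless_roundtrip",
    "noisy_recovery",
    "mw_exact_vs_enumeration",
    "mw_type_i_error",
]


# ---------------------------------------------------------------- kinetics

def model_identity_residuals() -> Dict[str, float]:
    """Structural identities of the two kinetic models.

    Value at onset, continuity gap at t_off, approach to the asymptotes.
    All should be at machine-precision scale.
    """
    p = KineticParams("monotone", k_on=0.02, t_on=100.0, R_eq=3.0)
    at_onset = float(eval_monotone(p, p.t_on))
    asymptote = float(
        abs(eval_monotone(p, p.t_on + 20.0 / p.k_on) - p.R_eq) / abs(1 - p.R_eq)
    )
    q = KineticParams("recovery", 0.02, 100.0, 3.0, k_off=0.01, t_off=500.0)
    lo = np.nextafter(q.t_off, -np.inf)
    hi = np.nextafter(q.t_off, np.inf)
    gap = float(abs(eval_recovery(q, lo) - eval_recovery(q, hi)))
    recovery_tail = float(abs(eval_recovery(q, q.t_off + 5000.0) - 1.0))
    return {
        "monotone_value_at_onset": at_onset,
        "monotone_asymptote_residual": asymptote,
        "recovery_continuity_gap": gap,
        "recovery_tail_residual": recovery_tail,
    }


# ---------------------------------------------------------------- tracking

def brute_force_assignment(cost: np.ndarray) -> Tuple[int, float]:
    """(max cardinality, min cost) over all matchings, by permutation search.

    Every partial matching is induced by some permutation of the padded
    square problem, so scanning permutations and dropping forbidden pairs
    covers all of them.
    """
    cost = np.asarray(cost, dtype=float)
    n, m = cost.shape
    size = max(n, m)
    best = (-1, np.inf)
    for perm in itertools.permutations(range(size)):
        card = 0
        total = 0.0
        for i in range(n):
            j = perm[i]
            if j < m and np.isfinite(cost[i, j]):
                card += 1
                total += cost[i, j]
        if card > best[0] or (card == best[0] and total < best[1]):
            best = (card, total)
    return best


def assignment_optimality(
    n_matrices: int = 500, max_size: int = 6, seed: int = 0
) -> Dict[str, float]:
    """Fraction of random gated instances where the solver matches brute force."""
    rng = np.random.default_rng(seed)
    agree = 0
    for k in range(n_matrices):
        n = int(rng.integers(1, max_size + 1))
        m = int(rng.integers(1, max_size + 1))
        cost = rng.uniform(0.0, 10.0, size=(n, m))
        if k % 2 == 1:  # half the instances carry forbidden entries
            cost[rng.random(cost.shape) < 0.3] = np.inf
        matches, _, _ = solve_assignment(cost)
        got = (len(matches), float(sum(cost[i, j] for i, j in matches)))
        want = brute_force_assignment(cost)
        if got[0] == want[0] and abs(got[1] - want[1]) <= 1e-9:
            agree += 1
    return {"optimal_fraction": agree / n_matrices, "n": n_matrices}


# ---------------------------------------------------------------- geometry

def ring_pixels_brute_force(radius: int, width: int) -> int:
    """Ring pixel count by naive enumeration of distances to the disk raster."""
    r_out = radius + width + 2
    disk = [
        (i, j)
        for i in range(-radius, radius + 1)
        for j in range(-radius, radius + 1)
        if i * i + j * j <= radius * radius
    ]
    disk = np.array(disk)
    count = 0
    for i in range(-r_out, r_out + 1):
        for j in range(-r_out, r_out + 1):
            if i * i + j * j <= radius * radius:
                continue
            d2 = ((disk[:, 0] - i) ** 2 + (disk[:, 1] - j) ** 2).min()
            if d2 <= width * width:
                count += 1
    return count


def ring_geometry_check(
    radii: Tuple[int, ...] = (8, 10, 15), width: int = 5
) -> Dict[str, float]:
    """Ring areas vs the continuous annulus and the brute-force enumeration."""
    max_rel_err = 0.0
    exact_matches = 0
    for r in radii:
        size = 2 * (r + width) + 9
        labels = np.zeros((size, size), dtype=np.int32)
        yy, xx = np.mgrid[0:size, 0:size] - size // 2
        labels[yy**2 + xx**2 <= r**2] = 1
        masks = make_cytoplasm_rings(labels, width)
        area = int((masks.ring_labels == 1).sum())
        expected = np.pi * ((r + width) ** 2 - r**2)
        max_rel_err = max(max_rel_err, abs(area - expected) / expected)
        if area == ring_pixels_brute_force(r, width):
            exact_matches += 1
    return {
        "max_rel_err": max_rel_err,
        "exact_match_fraction": exact_matches / len(radii),
        "n": len(radii),
    }


# ---------------------------------------------------------------- pipeline

def _truth_correspondence(result, truth: GroundTruth, radius: float) -> float:
    """Fraction of truth cells recovered as one full-length, consistent track."""
    n_frames = truth.label_images.shape[0]
    good = 0
    tracks = result.tracks
    assigned: Dict[int, int] = {}
    for tid in tracks.track_ids:
        sub = tracks.track(tid)
        if len(sub) != n_frames or (sub["label"].to_numpy() < 0).any():
            continue
        cents = sub[["centroid_y", "centroid_x"]].to_numpy()
        frames = sub["frame"].to_numpy()
        d = np.linalg.norm(truth.centroids[frames] - cents[:, None, :], axis=2)
        nearest = d.argmin(axis=1)
        if (d[np.arange(len(frames)), nearest] < radius).all() and len(
            set(nearest.tolist())
        ) == 1:
            cell = int(nearest[0])
            if cell not in assigned:
                assigned[cell] = int(tid)
                good += 1
    return good / truth.n_cells if truth.n_cells else 1.0


def _fit_errors(fits: pd.DataFrame, truth: GroundTruth, result) -> pd.DataFrame:
    """Join fitted parameters to the truth cell each track follows."""
    rows = []
    tracks = result.tracks
    for _, row in fits.iterrows():
        if not row.get("converged", False):
            continue
        sub = tracks.track(int(row["track_id"]))
        ok = sub["label"].to_numpy() >= 0
        cents = sub[["centroid_y", "centroid_x"]].to_numpy()[ok]
        frames = sub["frame"].to_numpy()[ok]
        d = np.linalg.norm(truth.centroids[frames] - cents[:, None, :], axis=2)
        cell = int(np.bincount(d.argmin(axis=1)).argmax())
        p = truth.cells[cell].params
        rows.append(
            {
                "track_id": int(row["track_id"]),
                "cell": cell,
                "archetype": truth.cells[cell].archetype,
                "true_variant": p.variant,
                "fit_variant": row["variant"],
                "k_on_err": abs(row["k_on"] - p.k_on) / p.k_on,
                "t_on_err": abs(row["t_on"] - p.t_on) / p.t_on,
                "R_eq_err": abs(row["R_eq"] - p.R_eq) / p.R_eq,
            }
        )
    return pd.DataFrame(rows)


def noiseless_roundtrip(seed: int = 0, n_cells: int = 20) -> Dict[str, float]:
    """Render stationary noiseless cells; run the full pipeline; measure errors.

    Study schedule: one frame every 15 s for 30 min after stimulation.
    Reports the worst per-cell relative error of (k_on, t_on, R_eq) and the
    track-truth correspondence fraction.
    """
    pop = PopulationSpec(
        n_cells=n_cells,
        archetype_mix={"young": 0.4, "mid_old": 0.3, "old": 0.3},
        seed=seed,
    )
    imaging = ImagingSpec(image_size=(360, 360), seed=seed + 1)
    cells = sample_population(pop)
    movie, truth = render_movie(cells, imaging)
    result = run_pipeline(movie)
    errs = _fit_errors(result.fits, truth, result)
    agreement = _truth_correspondence(result, truth, imaging.nucleus_radius_px)
    max_err = float(
        errs[["k_on_err", "t_on_err", "R_eq_err"]].to_numpy().max()
    ) if len(errs) else np.inf
    return {
        "n_cells": n_cells,
        "n_fitted": int(len(errs)),
        "max_param_rel_err": max_err,
        "track_truth_agreement": agreement,
    }


def noisy_recovery(seed: int = 0, n_cells: int = 100, noise_sd: float = 0.05):
    """Parameter recovery and variant selection under noise and motion.

    Cells move by a 1 px/frame random walk and are reconstructed through the
    full segmentation/tracking pipeline; Gaussian noise of SD ``noise_sd``
    (normalized-trace units) is then added to each extracted normalized
    trace before fitting, so the stated trace-level noise is exact.
    """
    rng = np.random.default_rng(seed)
    pop = PopulationSpec(
        n_cells=n_cells,
        archetype_mix={"young": 0.35, "mid_old": 0.35, "old": 0.30},
        seed=seed,
    )
    side = int(np.ceil(np.sqrt(n_cells)))
    size = max(64 * side + 80, 256)
    imaging = ImagingSpec(image_size=(size, size), motion_sd_px=1.0, seed=seed + 1)
    cells = sample_population(pop)
    movie, truth = render_movie(cells, imaging)
    result = run_pipeline(movie, PipelineConfig(variant="none"))
    # Map each full track to its truth cell, perturb its normalized trace,
    # and refit with auto variant selection.
    errors = []
    correct = {"monotone": 0, "recovery": 0}
    totals = {"monotone": 0, "recovery": 0}
    radius = imaging.nucleus_radius_px
    cfg = FitConfig()
    for tr in result.traces:
        if tr.cn_norm is None or tr.exclusion_reason:
            continue
        ok = np.isfinite(tr.cn_norm)
        cents_sub = result.tracks.track(tr.track_id)
        good = cents_sub["label"].to_numpy() >= 0
        cents = cents_sub[["centroid_y", "centroid_x"]].to_numpy()[good]
        frames = cents_sub["frame"].to_numpy()[good]
        d = np.linalg.norm(truth.centroids[frames] - cents[:, None, :], axis=2)
        cell = int(np.bincount(d.argmin(axis=1)).argmax())
        p = truth.cells[cell].params
        y = tr.cn_norm.copy()
        y[ok] += rng.normal(0.0, noise_sd, size=int(ok.sum()))
        chosen, fit, _, _ = fit_trace((tr.times_s, y), "auto", cfg)
        totals[p.variant] += 1
        if chosen == p.variant:
            correct[p.variant] += 1
        if fit.converged:
            errors.append(
                {
                    "true_variant": p.variant,
                    "k_on_err": abs(fit.params.k_on - p.k_on) / p.k_on,
                    "R_eq_err": abs(fit.params.R_eq - p.R_eq) / p.R_eq,
                }
            )
    errs = pd.DataFrame(errors)
    return {
        "n_cells": n_cells,
        "n_fitted": int(len(errs)),
        "k_on_median_rel_err": float(errs["k_on_err"].median()),
        "R_eq_median_rel_err": float(errs["R_eq_err"].median()),
        "recovery_selection_accuracy": (
            correct["recovery"] / totals["recovery"] if totals["recovery"] else np.nan
        ),
        "monotone_selection_accuracy": (
            correct["monotone"] / totals["monotone"] if totals["monotone"] else np.nan
        ),
        "track_truth_agreement": _truth_correspondence(result, truth, radius),
    }


# ---------------------------------------------------------------- statistics

def _enumerate_p(x: np.ndarray, y: np.ndarray, alternative: str) -> float:
    """Reference p: enumerate every split of the pooled sample (no ties)."""
    pooled = np.concatenate([x, y])
    n1 = len(x)

    def u_of(sample, rest):
        return sum(1 for a in sample for b in rest if a > b)

    u_obs = u_of(x, y)
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        mask = np.zeros(len(pooled), dtype=bool)
        mask[list(idx)] = True
        u = u_of(pooled[mask], pooled[~mask])
        total += 1
        if alternative == "less" and u <= u_obs:
            count += 1
        elif alternative == "greater" and u >= u_obs:
            count += 1
    return count / total


def mw_exact_vs_enumeration(max_total: int = 10, seed: int = 0) -> Dict[str, float]:
    """Max |p_impl - p_enumeration| over random tie-free configurations."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    n_checked = 0
    for n1 in range(1, max_total):
        for n2 in range(1, max_total - n1 + 1):
            for _ in range(3):
                pooled = rng.permutation(rng.uniform(0, 100, size=n1 + n2))
                x, y = pooled[:n1], pooled[n1:]
                for alt in ("less", "greater"):
                    _, p = mann_whitney_one_tailed(x, y, alt)
                    p_ref = _enumerate_p(x, y, alt)
                    worst = max(worst, abs(p - p_ref))
                    n_checked += 1
    return {"max_abs_diff": worst, "n": n_checked}


def mw_type_i_error(
    n_reps: int = 1000, n_per_group: int = 10, alpha: float = 0.05, seed: int = 0
) -> Dict[str, float]:
    """Rejection rate under identically distributed groups."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_reps):
        x = rng.normal(size=n_per_group)
        y = rng.normal(size=n_per_group)
        _, p = mann_whitney_one_tailed(x, y, "less")
        if p < alpha:
            rejections += 1
    return {"rate": rejections / n_reps, "n": n_reps}
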