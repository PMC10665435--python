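"""Piecewise exponential kinetics of reporter translocation.

The normalized cytoplasm/nucleus (C/N) ratio ``r(t)`` of a kinase
translocation reporter after stimulation at ``t = 0`` is modelled by two
variants:

*monotone* (sustained response)::

    r(t) = 1                                               for t <= t_on
    r(t) = R_eq + (1 - R_eq) * exp(-k_on * (t - t_on))     for t >  t_on

*recovery* (transient response, reporter returns to the nucleus)::

    r(t) = 1                                               for t <= t_on
    r(t) = R_eq + (1 - R_eq) * exp(-k_on * (t - t_on))     for t_on < t <= t_off
    r(t) = 1 + (r(t_off) - 1) * exp(-k_off * (t - t_off))  for t >  t_off

with trans-localization rate ``k_on`` (1/s), onset delay ``t_on`` (s),
equilibrium ratio ``R_eq`` (dimensionless), return rate ``k_off`` (1/s) and
recovery onset ``t_off`` (s).  Continuity at ``t_off`` is structural:
``r(t_off)`` of the third piece is the middle piece evaluated at ``t_off``,
never a free parameter.

Fitting is bounded nonlinear least squares with a deterministic multi-start
grid; see :func:`fit_trace`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "KineticParams",
    "KineticFit",
    "FitConfig",
    "eval_monotone",
    "eval_recovery",
    "eval_model",
    "fit_trace",
    "fit_arrays",
    "select_variant",
]

Variant = Literal["monotone", "recovery"]


@dataclass(frozen=True)
class KineticParams:
    """Parameters of one model variant (rates in 1/s, times in s)."""

    variant: Variant
    k_on: float
    t_on: float
    R_eq: float
    k_off: Optional[float] = None
    t_off: Optional[float] = None

    def __post_init__(self) -> None:
        if self.k_on <= 0:
            raise ValueError(f"k_on must be > 0, got {self.k_on}")
        if self.t_on < 0:
            raise ValueError(f"t_on must be >= 0, got {self.t_on}")
        if self.R_eq <= 0:
            raise ValueError(f"R_eq must be > 0, got {self.R_eq}")
        if self.variant == "recovery":
            if self.k_off is None or self.t_off is None:
                raise ValueError("recovery variant requires k_off and t_off")
            if self.k_off <= 0:
                raise ValueError(f"k_off must be > 0, got {self.k_off}")
            if self.t_off <= self.t_on:
                raise ValueError(
                    f"t_off ({self.t_off}) must exceed t_on ({self.t_on})"
                )
        elif self.variant != "monotone":
            raise ValueError(f"unknown variant {self.variant!r}")


def eval_monotone(params: KineticParams, t) -> np.ndarray:
    """Evaluate the monotone model at times ``t`` (s, relative to stimulation)."""
    t = np.asarray(t, dtype=float)
    dt = t - params.t_on
    r = np.where(
        dt <= 0.0,
        1.0,
        params.R_eq + (1.0 - params.R_eq) * np.exp(-params.k_on * np.maximum(dt, 0.0)),
    )
    return r


def eval_recovery(params: KineticParams, t) -> np.ndarray:
    """Evaluate the recovery model at times ``t`` (s, relative to stimulation)."""
    if params.k_off is None or params.t_off is None or params.t_off <= params.t_on:
        raise ValueError("recovery model requires k_off and t_off > t_on")
    t = np.asarray(t, dtype=float)
    rise = params.R_eq + (1.0 - params.R_eq) * np.exp(
        -params.k_on * np.maximum(t - params.t_on, 0.0)
    )
    # value at t_off comes from the middle piece: continuity is structural
    r_off = params.R_eq + (1.0 - params.R_eq) * np.exp(
        -params.k_on * (params.t_off - params.t_on)
    )
    fall = 1.0 + (r_off - 1.0) * np.exp(-params.k_off * np.maximum(t - params.t_off, 0.0))
    r = np.where(t <= params.t_on, 1.0, np.where(t <= params.t_off, rise, fall))
    return r


def eval_model(params: KineticParams, t) -> np.ndarray:
    if params.variant == "monotone":
        return eval_monotone(params, t)
    return eval_recovery(params, t)


@dataclass(frozen=True)
class KineticFit:
    """Result of fitting one trace."""

    params: Optional[KineticParams]
    sse: float = np.nan
    rmse: float = np.nan
    n_points: int = 0
    converged: bool = False
    exclusion_reason: Optional[str] = None
    flags: tuple = ()


@dataclass(frozen=True)
class FitConfig:
    """Optimizer bounds and multi-start grids.

    Defaults cover a 30-minute acquisition window in seconds.  ``t_max`` is
    taken from the data when None.  Fitting in other time units requires
    scaling the rate bounds and start grid accordingly.
    """

    k_bounds: tuple = (1e-5, 1.0)
    r_eq_bounds: tuple = (0.1, 10.0)
    t_max: Optional[float] = None
    k_on_starts: tuple = (1e-3, 1e-2, 1e-1)
    k_off_starts: tuple = (1e-3, 1e-2)
    n_t_on_knots: int = 5
    min_points: int = 8
    flat_tol: float = 0.2


def _fit_one_start(model, t, y, x0, lb, ub):
    res = least_squares(
        lambda x: model(x, t) - y,
        x0=np.clip(x0, lb, ub),
        bounds=(lb, ub),
        method="trf",
        xtol=1e-12,
        ftol=1e-12,
        gtol=1e-12,
        max_nfev=400,
    )
    sse = float(np.sum(res.fun**2))
    return res, sse


def _monotone_vec(x, t):
    k_on, t_on, r_eq = x
    dt = np.maximum(t - t_on, 0.0)
    r = np.where(t <= t_on, 1.0, r_eq + (1.0 - r_eq) * np.exp(-k_on * dt))
    return r


def _recovery_vec(x, t):
    k_on, t_on, r_eq, k_off, d_off = x
    t_off = t_on + d_off
    rise = r_eq + (1.0 - r_eq) * np.exp(-k_on * np.maximum(t - t_on, 0.0))
    r_off = r_eq + (1.0 - r_eq) * np.exp(-k_on * d_off)
    fall = 1.0 + (r_off - 1.0) * np.exp(-k_off * np.maximum(t - t_off, 0.0))
    return np.where(t <= t_on, 1.0, np.where(t <= t_off, rise, fall))


def fit_arrays(
    t,
    y,
    variant: Variant = "monotone",
    config: FitConfig = FitConfig(),
) -> KineticFit:
    """Fit one model variant to ``(t, y)`` samples of a normalized C/N trace.

    Bounded least squares from a deterministic multi-start grid: ``t_on``
    on ``n_t_on_knots`` knots over the observed post-stimulation times,
    ``k_on`` over ``k_on_starts``, ``R_eq`` from the trace tail mean (and for
    recovery, ``t_off`` initialized at the trace peak).  Best SSE wins; SSE
    ties are broken toward the smallest ``k_on``.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(t) & np.isfinite(y)
    t, y = t[ok], y[ok]
    n_post = int(np.sum(t > 0))
    if n_post < config.min_points:
        return KineticFit(
            None, n_points=len(t), exclusion_reason="too_few_points"
        )
    post = y[t > 0]
    if np.max(np.abs(post - 1.0)) < config.flat_tol:
        return KineticFit(
            None,
            n_points=len(t),
            exclusion_reason="unidentifiable_flat",
            flags=("R_eq_unidentifiable",),
        )

    t_max = config.t_max if config.t_max is not None else float(np.max(t))
    t_on_knots = np.linspace(0.0, t_max, config.n_t_on_knots)
    tail = float(np.mean(y[np.argsort(t)][-5:]))
    r_eq0 = float(np.clip(tail, *config.r_eq_bounds))

    k_lo, k_hi = config.k_bounds
    best = None
    if variant == "monotone":
        lb = np.array([k_lo, 0.0, config.r_eq_bounds[0]])
        ub = np.array([k_hi, t_max, config.r_eq_bounds[1]])
        starts = [
            np.array([k0, ton0, r_eq0])
            for k0, ton0 in itertools.product(config.k_on_starts, t_on_knots)
        ]
        model = _monotone_vec
    elif variant == "recovery":
        i_peak = int(np.argmax(np.abs(y - 1.0)))
        t_peak = max(float(t[i_peak]), 2.0)
        peak = float(np.clip(y[i_peak], *config.r_eq_bounds))
        knots = np.linspace(0.0, t_peak, 3)
        lb = np.array([k_lo, 0.0, config.r_eq_bounds[0], k_lo, 1.0])
        ub = np.array([k_hi, t_max, config.r_eq_bounds[1], k_hi, t_max])
        starts = [
            np.array([k0, ton0, peak, koff0, max(t_peak - ton0, 2.0)])
            for k0, ton0, koff0 in itertools.product(
                config.k_on_starts, knots, config.k_off_starts
            )
        ]
        model = _recovery_vec
    else:
        raise ValueError(f"unknown variant {variant!r}")

    for x0 in starts:
        res, sse = _fit_one_start(model, t, y, x0, lb, ub)
        if not res.success:
            continue
        if best is None or sse < best[1] * (1 - 1e-12) or (
            abs(sse - best[1]) <= 1e-12 * max(best[1], 1.0)
            and res.x[0] < best[0].x[0]
        ):
            best = (res, sse)

    if best is None:
        return KineticFit(None, n_points=len(t), exclusion_reason="no_convergence")

    res, sse = best
    if variant == "monotone":
        params = KineticParams("monotone", *map(float, res.x))
    else:
        k_on, t_on, r_eq, k_off, d_off = map(float, res.x)
        params = KineticParams("recovery", k_on, t_on, r_eq, k_off, t_on + d_off)
    return KineticFit(
        params,
        sse=sse,
        rmse=float(np.sqrt(sse / len(t))),
        n_points=len(t),
        converged=True,
    )


def fit_trace(trace, variant="auto", config: FitConfig = FitConfig()):
    """Fit a :class:`~ktr.traces.CNTrace` (or ``(t, y)`` arrays).

    ``variant='auto'`` fits both models and applies :func:`select_variant`.
    Returns a ``KineticFit`` for a named variant, or
    ``(chosen_variant, KineticFit, fit_mono, fit_recov)`` for ``'auto'``.
    """
    if hasattr(trace, "times_s"):
        if trace.cn_norm is None:
            return KineticFit(None, exclusion_reason=trace.exclusion_reason or "not_normalized")
        t, y = trace.times_s, trace.cn_norm
    else:
        t, y = trace
    if variant in ("monotone", "recovery"):
        return fit_arrays(t, y, variant, config)
    if variant != "auto":
        raise ValueError(f"unknown variant {variant!r}")
    fit_mono = fit_arrays(t, y, "monotone", config)
    fit_recov = fit_arrays(t, y, "recovery", config)
    chosen = select_variant((t, y), fit_mono, fit_recov)
    return chosen, (fit_mono if chosen == "monotone" else fit_recov), fit_mono, fit_recov


def select_variant(
    trace,
    fit_mono: KineticFit,
    fit_recov: KineticFit,
    decline_frac: float = 0.25,
    sse_improvement: float = 0.10,
) -> Variant:
    """Choose between the monotone and recovery fits of one trace.

    ``recovery`` is chosen iff (a) the trace's decline after its peak exceeds
    ``decline_frac`` of its rise above baseline, and (b) the recovery fit
    reduces SSE by at least ``sse_improvement`` relative to the monotone fit.
    Otherwise ``monotone``.
    """
    if hasattr(trace, "times_s"):
        t, y = trace.times_s, trace.cn_norm
    else:
        t, y = trace
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(t) & np.isfinite(y) & (t >= 0)
    t, y = t[ok], y[ok]
    if len(y) == 0 or not (fit_recov.converged and fit_mono.converged):
        return "monotone"
    i_peak = int(np.argmax(y))
    rise = y[i_peak] - 1.0
    if rise <= 0:
        return "monotone"
    tail = float(np.mean(y[-3:])) if len(y) - i_peak >= 3 else float(y[-1])
    decline = y[i_peak] - tail
    if decline < decline_frac * rise:
        return "monotone"
    if fit_recov.sse > (1.0 - sse_improvement) * fit_mono.sse:
        return "monotone"
    return "recovery"
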