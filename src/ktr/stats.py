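"""Cell-status classification and nonparametric group comparison.

Cultured fibroblast status is read off doubling time (DT, days) and
SA-beta-galactosidase positivity (percent): young (DT in [1, 2], SA-b-Gal
< 1%), mid-old (DT in [5, 7], < 5%), old (DT > 14, > 65%).  Inputs in none
of the printed bands — e.g. DT between 2 and 5 days — are unclassified.

Kinetic parameters are compared between status groups with a one-tailed
Mann-Whitney U test (exact p by enumeration for small tie-free samples,
normal approximation with tie correction otherwise); summaries are
mean +/- SD.  A two-tailed Student's t test is provided for normally
distributed samples.  No multiple-testing correction is applied; p values
are per comparison.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CellStatus",
    "GroupComparison",
    "classify_cell_status",
    "mann_whitney_one_tailed",
    "student_t_two_tailed",
    "compare_groups",
]

STATUS_ORDER = ("young", "mid_old", "old")


@dataclass(frozen=True)
class CellStatus:
    status: str
    doubling_time_days: float
    sa_b_gal_pct: float


def classify_cell_status(dt_days: float, sabgal_pct: float) -> CellStatus:
    """Map (doubling time, SA-b-Gal %) to young / mid_old / old / unclassified."""
    if not (dt_days > 0):
        raise ValueError(f"doubling time must be > 0 days, got {dt_days}")
    if not (0.0 <= sabgal_pct <= 100.0):
        raise ValueError(f"SA-b-Gal must lie in [0, 100] %, got {sabgal_pct}")
    if 1.0 <= dt_days <= 2.0 and sabgal_pct < 1.0:
        status = "young"
    elif 5.0 <= dt_days <= 7.0 and sabgal_pct < 5.0:
        status = "mid_old"
    elif dt_days > 14.0 and sabgal_pct > 65.0:
        status = "old"
    else:
        status = "unclassified"
    return CellStatus(status, float(dt_days), float(sabgal_pct))


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for sample x via midrank sum: U1 = R1 - n1(n1+1)/2."""
    n1 = len(x)
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)
    r1 = float(ranks[:n1].sum())
    return r1 - n1 * (n1 + 1) / 2.0


def _exact_p(u_obs: float, n1: int, n2: int, alternative: str) -> float:
    """P(U <= u) or P(U >= u) by enumerating rank subsets (no ties)."""
    ranks = range(1, n1 + n2 + 1)
    count = 0
    total = 0
    offset = n1 * (n1 + 1) / 2.0
    for subset in itertools.combinations(ranks, n1):
        u = sum(subset) - offset
        total += 1
        if alternative == "less" and u <= u_obs + 1e-9:
            count += 1
        elif alternative == "greater" and u >= u_obs - 1e-9:
            count += 1
    return count / total


def _approx_p(u_obs: float, x: np.ndarray, y: np.ndarray, alternative: str) -> float:
    """Normal approximation with tie correction and continuity correction."""
    n1, n2 = len(x), len(y)
    n = n1 + n2
    mu = n1 * n2 / 2.0
    combined = np.concatenate([x, y])
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if sigma2 <= 0:
        return 1.0
    sigma = math.sqrt(sigma2)
    if alternative == "less":
        z = (u_obs - mu + 0.5) / sigma
        return float(sps.norm.cdf(z))
    z = (u_obs - mu - 0.5) / sigma
    return float(sps.norm.sf(z))


def mann_whitney_one_tailed(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "less",
) -> Tuple[float, float]:
    """One-tailed Mann-Whitney U test of sample ``x`` against ``y``.

    ``alternative='less'`` tests whether x tends to be smaller than y,
    ``'greater'`` the reverse.  Exact p by full enumeration of rank
    arrangements when n1 + n2 <= 12 and there are no ties; otherwise the
    tie-corrected normal approximation with continuity correction.
    Returns (U, p) with U the statistic of sample x, U in [0, n1*n2].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    if alternative not in ("less", "greater"):
        raise ValueError("alternative must be 'less' or 'greater'")
    u = _u_statistic(x, y)
    combined = np.concatenate([x, y])
    has_ties = len(np.unique(combined)) < len(combined)
    if len(combined) <= 12 and not has_ties:
        p = _exact_p(u, len(x), len(y), alternative)
    else:
        p = _approx_p(u, x, y, alternative)
    return u, min(max(p, np.finfo(float).tiny), 1.0)


def student_t_two_tailed(x, y) -> Tuple[float, float]:
    """Two-tailed two-sample Student's t test (equal variances)."""
    res = sps.ttest_ind(np.asarray(x, float), np.asarray(y, float))
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class GroupComparison:
    parameter: str
    group_x: str
    group_y: str
    n_x: int
    n_y: int
    u_statistic: float
    p_one_tailed: float
    alternative: str
    mean_x: float
    sd_x: float
    mean_y: float
    sd_y: float


def compare_groups(
    fits: pd.DataFrame,
    parameters: Sequence[str] = ("k_on", "t_on", "R_eq"),
    alternatives: Union[str, Mapping[str, str]] = "greater",
    status_column: str = "status",
    min_group_size: int = 2,
) -> List[GroupComparison]:
    """Pairwise one-tailed Mann-Whitney comparisons of kinetic parameters.

    ``fits`` holds one row per converged fit with a status column and one
    column per parameter.  ``alternatives`` declares the one-tailed
    direction — a single direction for all comparisons or a mapping from
    parameter name to 'less'/'greater' (direction of the first-listed group
    against the second).  Groups appear in canonical order (young, mid_old,
    old, then any others alphabetically), so the output is invariant to
    input row order.  Groups with fewer than ``min_group_size`` rows for a
    parameter are skipped.
    """
    present = list(fits[status_column].dropna().unique())
    ordered = [s for s in STATUS_ORDER if s in present] + sorted(
        s for s in present if s not in STATUS_ORDER
    )
    out: List[GroupComparison] = []
    for param in parameters:
        if param not in fits.columns:
            continue
        alt = alternatives if isinstance(alternatives, str) else alternatives[param]
        for gx, gy in itertools.combinations(ordered, 2):
            x = fits.loc[fits[status_column] == gx, param].dropna().to_numpy()
            y = fits.loc[fits[status_column] == gy, param].dropna().to_numpy()
            if len(x) < min_group_size or len(y) < min_group_size:
                continue
            u, p = mann_whitney_one_tailed(x, y, alt)
            out.append(
                GroupComparison(
                    parameter=param,
                    group_x=gx,
                    group_y=gy,
                    n_x=len(x),
                    n_y=len(y),
                    u_statistic=u,
                    p_one_tailed=p,
                    alternative=alt,
                    mean_x=float(np.mean(x)),
                    sd_x=float(np.std(x, ddof=1)),
                    mean_y=float(np.mean(y)),
                    sd_y=float(np.std(y, ddof=1)),
                )
            )
    return out
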