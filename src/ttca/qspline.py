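"""Penalized median (L1) spline regression and the dynamics score.

A gene's time course is fitted with the continuous piecewise-linear
function ``g`` minimising

    sum_j w_j |y_j - g(t_j)|  +  lambda * TV(g')

where ``TV(g')`` is the total variation of the derivative, i.e. the L1 sum
of slope changes at interior knots — the discrete counterpart of the
integrated absolute second derivative.  The knots are the distinct
measurement times; with both loss and penalty piecewise linear the problem
is an exact linear program.  Median (absolute) loss keeps single outliers
from dragging the curve the way a least-squares fit would.

The loss weights ``w_j`` default to 1.  The dynamics score fits with
replication weights (replicates at a time point share that point's unit
weight) so that a time point measured in quadruplicate counts no more than
one measured once, and so that the pooled null-hypothesis fit and the
per-condition fits are penalized on the same footing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy.optimize import linprog
from scipy.sparse import csr_matrix

from .data_model import GeneProfile

logger = logging.getLogger("ttca")

#: sentinel returned by dynamics_score when only the denominator vanishes;
#: callers replace it by the maximum finite score over their dataset.
DYNAMICS_SENTINEL = np.inf


@dataclass(frozen=True)
class FittedCurve:
    """A fitted piecewise-linear median regression curve.

    Evaluation interpolates linearly between knots and extrapolates as a
    constant outside the first/last knot.
    """

    knots: np.ndarray
    knot_values: np.ndarray
    lam: float
    residuals: np.ndarray  # |y_j - g(t_j)| per fitted measurement

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.knots) > 0):
            raise ValueError("knots must be strictly increasing")
        if (self.residuals < 0).any():
            raise ValueError("residuals must be non-negative")

    def __call__(self, t: float | np.ndarray) -> np.ndarray:
        return np.interp(np.asarray(t, dtype=float), self.knots, self.knot_values)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.knots[0]), float(self.knots[-1])


@lru_cache(maxsize=256)
def _lp_structure(
    knot_key: tuple[float, ...],
    idx_key: tuple[int, ...],
    weight_key: tuple[float, ...],
    lam: float,
):
    """Constraint matrix, cost vector and bounds for one fit design.

    Designs repeat across thousands of genes, so the sparse matrix is
    cached on (knots, measurement->knot map, weights, lambda).
    """
    knots = np.asarray(knot_key)
    idx = np.asarray(idx_key)
    w = np.asarray(weight_key)
    m, n = len(knots), len(idx)
    p = max(m - 2, 0)
    nvar = m + 2 * n + 2 * p  # g, u, v, a, b
    rows, cols, data = [], [], []
    for j in range(n):
        rows += [j, j, j]
        cols += [int(idx[j]), m + j, m + n + j]
        data += [1.0, 1.0, -1.0]
    dt = np.diff(knots)
    for k in range(p):
        r = n + k
        rows += [r, r, r, r, r]
        cols += [k, k + 1, k + 2, m + 2 * n + k, m + 2 * n + p + k]
        data += [1.0 / dt[k], -(1.0 / dt[k] + 1.0 / dt[k + 1]), 1.0 / dt[k + 1], -1.0, 1.0]
    A = csr_matrix((data, (rows, cols)), shape=(n + p, nvar))
    c = np.concatenate([np.zeros(m), w, w, lam * np.ones(2 * p)])
    bounds = [(None, None)] * m + [(0, None)] * (2 * n + 2 * p)
    return A, c, bounds, m, p


def replication_weights(times: Sequence[float]) -> np.ndarray:
    """Loss weights 1 / (number of measurements at that time point)."""
    t = np.asarray(times, dtype=float)
    _, inv, counts = np.unique(t, return_inverse=True, return_counts=True)
    return 1.0 / counts[inv]


def fit_median_spline(
    times: Sequence[float],
    values: Sequence[float],
    lam: float,
    weights: Sequence[float] | None = None,
) -> FittedCurve:
    """Fit the roughness-penalized L1 spline by linear programming.

    Parameters
    ----------
    times, values:
        Measurements; replicated times are allowed, at least 3 distinct
        times are required.
    lam:
        Non-negative penalty on the total variation of the slope.  ``0``
        interpolates the per-time medians of the data; in the large-lambda
        regime the fit collapses to the L1 (median) regression line.
    weights:
        Optional non-negative per-measurement loss weights (default 1).
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("times and values must be 1-d and of equal length")
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(y))):
        raise ValueError("times and values must be finite")
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    if weights is None:
        w = np.ones_like(y)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != y.shape or (w < 0).any():
            raise ValueError("weights must be non-negative and match the measurements")
    knots, idx = np.unique(t, return_inverse=True)
    if len(knots) < 3:
        raise ValueError("need at least 3 distinct time points for a spline fit")

    # centre values for numerical conditioning; the problem is
    # translation-equivariant so the solution just shifts back
    offset = float(np.median(y))
    A, c, bounds, m, p = _lp_structure(
        tuple(knots), tuple(int(i) for i in idx), tuple(w), float(lam)
    )
    b_eq = np.concatenate([y - offset, np.zeros(p)])
    res = linprog(c, A_eq=A, b_eq=b_eq, bounds=bounds, method="highs")
    if not res.success:  # pragma: no cover - highs is reliable on these LPs
        raise RuntimeError(f"median-spline LP failed: {res.message}")
    g = res.x[:m] + offset
    residuals = np.abs(y - g[idx])
    return FittedCurve(knots=knots, knot_values=g, lam=float(lam), residuals=residuals)


def build_weights(
    times: Sequence[float],
    conditions: Sequence[str] | None = None,
    hypothesis: str = "H0",
    n_union_times: int | None = None,
) -> np.ndarray:
    """Per-measurement residual weights balancing the uneven design.

    Three rules: (i) replicates at a time point share that point's weight
    equally, so every time point counts once regardless of replication;
    (ii) under the per-condition (alternative) hypothesis each condition's
    weights are scaled so both conditions contribute equally even when one
    was sampled more densely; (iii) the whole vector is rescaled to a fixed
    total — the number of distinct time points of the union design — so
    null and alternative residual sums are on the same footing.
    """
    t = np.asarray(times, dtype=float)
    if t.size == 0:
        raise ValueError("empty design")
    if hypothesis not in ("H0", "per-condition"):
        raise ValueError(f"unknown hypothesis {hypothesis!r}")
    if hypothesis == "per-condition" and conditions is not None:
        cond = np.asarray(conditions)
        w = np.empty_like(t)
        labels = list(dict.fromkeys(cond))
        for lab in labels:
            mask = cond == lab
            wc = replication_weights(t[mask])
            # rule (ii): equal total contribution per condition
            w[mask] = wc / wc.sum() / len(labels)
    else:
        w = replication_weights(t)
        w = w / w.sum()
    total = n_union_times if n_union_times is not None else len(np.unique(t))
    return w * total


def dynamics_score(profile: GeneProfile, lam: float) -> float:
    """Ratio of pooled-fit to per-condition-fit weighted residual sums.

    ``D = <W_H0, R_H0> / (<W_stim, R_stim> + <W_ctrl, R_ctrl>)``.  The null
    hypothesis residuals come from one fit to the pooled measurements of
    both conditions, the alternative from separate per-condition fits; all
    fits use replication loss weights.  Values near 1 mean the conditions
    are described as well jointly as separately; large values indicate
    differential dynamics.  A 0/0 degenerate gene scores 1; a perfect
    per-condition fit with remaining pooled error returns ``inf`` as a
    sentinel for "maximal separation" (replaced dataset-wide by the caller).
    """
    return dynamics_and_fits(profile, lam)[0]


def dynamics_and_fits(
    profile: GeneProfile, lam: float
) -> tuple[float, dict[str, FittedCurve]]:
    """Dynamics score plus the per-condition fits it is based on."""
    conds = sorted(profile.data)
    if len(conds) != 2:
        raise ValueError("dynamics score needs exactly two conditions")
    t_pool, y_pool = profile.pooled()
    # pooled() sorts by time; rebuild the matching condition labels
    cond_unsorted = np.concatenate([np.repeat(c, len(profile.times(c))) for c in conds])
    t_unsorted = np.concatenate([profile.times(c) for c in conds])
    order = np.argsort(t_unsorted, kind="stable")
    cond_pool = cond_unsorted[order]
    n_union = len(np.unique(t_pool))

    fit0 = fit_median_spline(t_pool, y_pool, lam, weights=replication_weights(t_pool))
    w0 = build_weights(t_pool, hypothesis="H0", n_union_times=n_union)
    num = float(w0 @ fit0.residuals)

    den = 0.0
    fits: dict[str, FittedCurve] = {}
    w1 = build_weights(t_pool, cond_pool, hypothesis="per-condition", n_union_times=n_union)
    for c in conds:
        mask = cond_pool == c
        tc, yc = t_pool[mask], y_pool[mask]
        fit_c = fit_median_spline(tc, yc, lam, weights=replication_weights(tc))
        fits[c] = fit_c
        den += float(w1[mask] @ fit_c.residuals)

    scale = max(1.0, float(np.max(np.abs(y_pool))))
    tol = 1e-10 * scale
    if den <= tol:
        return (1.0 if num <= tol else DYNAMICS_SENTINEL), fits
    return num / den, fits


def condition_fits(profile: GeneProfile, lam: float) -> dict[str, FittedCurve]:
    """Per-condition median-spline fits of one gene (for integral scoring)."""
    return {
        c: fit_median_spline(t, y, lam, weights=replication_weights(t))
        for c, (t, y) in profile.data.items()
    }
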