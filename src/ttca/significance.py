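"""Score significance: empirical null fitting, p-values, effect sizes,
consensus ranking.

No analytic null exists for the dynamics, peak or integral scores on an
arbitrary design, and permuting time points would merely shift — not
destroy — a sharp transient peak.  Instead the observed score distribution
itself is treated as the null: seven candidate families (Cauchy, gamma,
log-normal, logistic, normal, Poisson, Weibull) are fitted by maximum
likelihood and the best one supplies one-sided upper-tail p-values.
Families with positive support are fitted after shifting the x-axis when
non-positive values occur; p-values are computed on the original scale.

The consensus score averages the z-transformed dynamics, peak, combined
integral and relevance scores and is min-max normalised to [0, 1]; a gene
counts as significant overall when at least two constituent scores are
individually significant.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .scores import zscore

logger = logging.getLogger("ttca")

#: candidate families in the canonical order (also the tie-break order)
FAMILIES = ("cauchy", "gamma", "lognormal", "logistic", "normal", "poisson", "weibull")

_CONTINUOUS = {
    "cauchy": stats.cauchy,
    "gamma": stats.gamma,
    "lognormal": stats.lognorm,
    "logistic": stats.logistic,
    "normal": stats.norm,
    "weibull": stats.weibull_min,
}
#: families defined only for positive values (fitted with loc fixed at 0
#: after shifting the data when non-positive values occur)
_POSITIVE = {"gamma", "lognormal", "weibull"}


@dataclass
class FittedDistribution:
    """One fitted null-distribution family.

    ``shift`` was added to the data before fitting (0 if none); p-values of
    original-scale scores are computed as the upper tail at ``x + shift``.
    """

    family: str
    params: tuple
    shift: float
    loglik: float
    n: int
    degenerate: bool = False

    @property
    def aic(self) -> float:
        return 2 * len(self.params) - 2 * self.loglik

    def sf(self, x) -> np.ndarray:
        """Upper-tail probability P(X >= x) on the original scale."""
        xs = np.asarray(x, dtype=float) + self.shift
        if self.degenerate:
            return np.ones_like(xs)
        if self.family == "poisson":
            k = np.round(xs)
            return stats.poisson.sf(k - 1, *self.params)
        return _CONTINUOUS[self.family].sf(xs, *self.params)


def _fit_family(family: str, x: np.ndarray) -> FittedDistribution | None:
    xmin, xmax = float(x.min()), float(x.max())
    rng = xmax - xmin
    shift = 0.0
    if family == "poisson":
        if xmin < 0:
            shift = -xmin
        k = np.round(x + shift)
        # a pseudo-discrete pile-up carries no tail information
        _, counts = np.unique(k, return_counts=True)
        if counts.max() > 0.5 * len(k):
            logger.info("poisson excluded: >50%% of rounded scores share one integer")
            return None
        lam = float(k.mean())
        if lam <= 0:
            return None
        ll = float(stats.poisson.logpmf(k, lam).sum())
        return FittedDistribution("poisson", (lam,), shift, ll, len(x))
    dist = _CONTINUOUS[family]
    xs = x
    fit_kwargs = {}
    if family in _POSITIVE:
        if xmin <= 0:
            shift = -xmin + 1e-6 * (rng if rng > 0 else 1.0)
            xs = x + shift
        fit_kwargs["floc"] = 0.0
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            params = dist.fit(xs, **fit_kwargs)
            ll = float(dist.logpdf(xs, *params).sum())
    except Exception as err:  # noqa: BLE001 - any fit failure excludes the family
        logger.info("distribution family %s failed to fit: %s", family, err)
        return None
    if not np.isfinite(ll):
        return None
    return FittedDistribution(family, tuple(params), shift, ll, len(x))


def fit_best_distribution(scores, min_n: int = 100) -> FittedDistribution:
    """Fit all candidate families by ML and return the highest-likelihood one.

    Ties are broken by the canonical family order.  Fewer than ``min_n``
    values triggers a warning and a plain normal fit; constant input yields
    a degenerate fit under which every p-value is 1.
    """
    x = np.asarray(scores, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("no finite score values to fit")
    if x.std(ddof=0) == 0:
        logger.warning("constant score distribution: degenerate null, all p-values 1")
        return FittedDistribution(
            "normal", (float(x.mean()), 1e-12), 0.0, float("inf"), len(x), degenerate=True
        )
    candidates = FAMILIES
    if x.size < min_n:
        logger.warning("only %d score values (<%d): falling back to a normal null", x.size, min_n)
        candidates = ("normal",)
    fits = [f for fam in candidates if (f := _fit_family(fam, x)) is not None]
    if not fits:
        raise RuntimeError("no distribution family could be fitted")
    best = max(fits, key=lambda f: (f.loglik, -FAMILIES.index(f.family)))
    logger.info(
        "null family selected: %s (loglik %.1f); AICs: %s",
        best.family, best.loglik,
        {f.family: round(f.aic, 1) for f in fits},
    )
    return best


def score_pvalue(dist: FittedDistribution, score) -> np.ndarray | float:
    """One-sided upper-tail p-value of a score under the fitted null."""
    p = np.clip(dist.sf(score), 1e-300, 1.0)
    if np.isscalar(score) or np.ndim(score) == 0:
        return float(p)
    return p


def effect_size(
    kind: str,
    raw,
    value_max: float,
    value_min: float,
    interval_length: float | None = None,
):
    """Score magnitude relative to the dataset's detection range.

    Peak and instability effects are the raw value over the detection range
    (dataset-wide max minus min expression); integral effects additionally
    divide by the interval length in hours, the maximal possible area being
    range x duration.  Results are clipped to [0, 1].
    """
    if kind not in ("peak", "instability", "integral"):
        raise ValueError(f"unknown effect-size kind {kind!r}")
    span = value_max - value_min
    if span <= 0:
        return np.zeros_like(np.asarray(raw, dtype=float)) if np.ndim(raw) else 0.0
    denom = span
    if kind == "integral":
        if interval_length is None or interval_length <= 0:
            raise ValueError("integral effect size needs a positive interval length")
        denom = span * interval_length
    eff = np.clip(np.asarray(raw, dtype=float) / denom, 0.0, 1.0)
    return float(eff) if np.ndim(raw) == 0 else eff


def _relevance_z(r: np.ndarray) -> np.ndarray:
    """z-transform of the relevance score over its non-zero values.

    Zero-count genes sit at an arbitrary floor, so they are excluded from
    the transform and then imputed one spread unit below the smallest
    observed non-zero z value.
    """
    r = np.asarray(r, dtype=float)
    nz = r > 0
    if nz.sum() < 2 or r[nz].std(ddof=0) == 0:
        return np.zeros_like(r)
    z = np.zeros_like(r)
    z[nz] = zscore(r[nz])
    z[~nz] = z[nz].min() - 1.0
    return z


def consensus(
    D, P, I_comb, R=None
) -> tuple[np.ndarray, np.ndarray]:
    """Consensus score: min-max normalised mean of z-transformed inputs.

    Returns ``(C, C_raw)`` where ``C_raw`` is the plain mean of the z
    scores (used for the consensus p-value) and ``C`` lies in [0, 1].  When
    ``R`` is None (no publication counts supplied) the mean runs over the
    three remaining scores.
    """
    parts = [zscore(np.asarray(D, dtype=float)), zscore(np.asarray(P, dtype=float)),
             zscore(np.asarray(I_comb, dtype=float))]
    if R is not None:
        parts.append(_relevance_z(np.asarray(R, dtype=float)))
    c_raw = np.mean(parts, axis=0)
    lo, hi = c_raw.min(), c_raw.max()
    if hi == lo:
        return np.zeros_like(c_raw), c_raw
    return (c_raw - lo) / (hi - lo), c_raw


def consensus_significant(flags: pd.DataFrame | np.ndarray) -> np.ndarray:
    """True where at least two constituent scores are significant."""
    arr = flags.to_numpy() if isinstance(flags, pd.DataFrame) else np.asarray(flags)
    return arr.sum(axis=1) >= 2
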