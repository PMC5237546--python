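"""Domain types and input parsing for time-course expression experiments.

The universal input is a :class:`TimeSeriesExperiment`: a genes x samples
matrix of normalised expression intensities plus a sample sheet assigning
each sample a time point (hours), a condition label (``stim`` / ``ctrl``)
and a replicate index.  For single-condition designs (e.g. two-channel
ratios) a constant per-gene control profile can be synthesised with
:func:`synthesize_control`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("ttca")

STIM = "stim"
CTRL = "ctrl"

#: labels recognised case-insensitively for each canonical condition
_STIM_ALIASES = {"stim", "stimulated", "stimulus", "treat", "treated", "treatment", "case"}
_CTRL_ALIASES = {"ctrl", "control", "untreated", "reference", "ref", "mock"}


@dataclass(frozen=True)
class GeneProfile:
    """Per-gene view: sorted (time, value) measurements per condition."""

    feature: str
    #: condition label -> (times, values), times sorted non-decreasing
    data: dict[str, tuple[np.ndarray, np.ndarray]]

    def times(self, condition: str) -> np.ndarray:
        return self.data[condition][0]

    def values(self, condition: str) -> np.ndarray:
        return self.data[condition][1]

    def pooled(self) -> tuple[np.ndarray, np.ndarray]:
        """All measurements of both conditions, sorted by time."""
        t = np.concatenate([v[0] for v in self.data.values()])
        y = np.concatenate([v[1] for v in self.data.values()])
        order = np.argsort(t, kind="stable")
        return t[order], y[order]


@dataclass
class AnalysisConfig:
    """Tunable parameters of a full analysis run.

    ``lam`` is the roughness penalty of the median-spline fit (0.6 is
    calibrated for within-array standardised microarray intensities).
    ``interval_bounds`` split the observed time span into early /
    intermediate / late windows for the integral scores; when ``None`` the
    tertiles of the distinct time points (by index, not clock time) are
    used.
    """

    lam: float = 0.6
    interval_bounds: tuple[float, float] | None = None
    quantile: float = 0.5
    control_mode: Literal["measured", "constant_first", "constant_mean"] = "measured"
    min_group_size: int = 1000
    min_groups: int = 8
    sd_quantile: float = 0.95
    peak_factor: float = 2.0
    instability_factor: float = 2.0
    significance_alpha: float = 0.05
    use_relevance: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lambda must be non-negative")
        if not (0 < self.sd_quantile < 1):
            raise ValueError("sd_quantile must lie in (0, 1)")
        if self.peak_factor <= 0 or self.instability_factor <= 0:
            raise ValueError("threshold factors must be positive")
        if self.quantile != 0.5:
            raise ValueError("only the median (quantile 0.5) is supported")
        if self.interval_bounds is not None:
            b1, b2 = self.interval_bounds
            if not b1 < b2:
                raise ValueError("interval bounds must satisfy bound1 < bound2")

    def resolve_bounds(self, times: Sequence[float]) -> tuple[float, float]:
        """Interval bounds, defaulting to tertiles of the distinct times by index."""
        ts = np.unique(np.asarray(times, dtype=float))
        if self.interval_bounds is not None:
            b1, b2 = self.interval_bounds
            if not (ts[0] < b1 < b2 < ts[-1]):
                raise ValueError(
                    f"interval bounds {self.interval_bounds} must lie strictly "
                    f"inside the observed span [{ts[0]}, {ts[-1]}]"
                )
            return float(b1), float(b2)
        n = len(ts)
        b1 = float(ts[max(1, n // 3)])
        b2 = float(ts[min(n - 2, (2 * n) // 3)])
        logger.info("interval bounds defaulted to time-point tertiles: %g, %g", b1, b2)
        return b1, b2


@dataclass
class TimeSeriesExperiment:
    """Expression matrix plus per-sample annotations.

    ``values`` is a features x samples DataFrame; ``samples`` is indexed by
    sample id with columns ``time`` (hours), ``condition`` and ``replicate``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    condition_mapping: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- accessors -------------------------------------------------------

    @property
    def features(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def conditions(self) -> list[str]:
        return sorted(self.samples["condition"].unique())

    def distinct_times(self, condition: str | None = None) -> np.ndarray:
        sheet = self.samples
        if condition is not None:
            sheet = sheet[sheet["condition"] == condition]
        return np.unique(sheet["time"].to_numpy(dtype=float))

    def profile(self, feature: str) -> GeneProfile:
        row = self.values.loc[feature]
        data: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for cond, sub in self.samples.groupby("condition", sort=True):
            order = np.argsort(sub["time"].to_numpy(dtype=float), kind="stable")
            ids = sub.index.to_numpy()[order]
            data[cond] = (
                sub["time"].to_numpy(dtype=float)[order],
                row[ids].to_numpy(dtype=float),
            )
        return GeneProfile(feature=feature, data=data)

    def condition_means(self, condition: str) -> pd.DataFrame:
        """Replicate-mean expression per (feature, time) for one condition."""
        sub = self.samples[self.samples["condition"] == condition]
        vals = self.values[sub.index]
        return vals.T.groupby(sub["time"]).mean().T

    def replicated_cells(self) -> list[tuple[float, str, list[str]]]:
        """(time, condition, sample ids) for every cell with >= 2 replicates."""
        cells = []
        for (time, cond), sub in self.samples.groupby(["time", "condition"], sort=True):
            if len(sub) >= 2:
                cells.append((float(time), str(cond), list(sub.index)))
        return cells

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        vals, sheet = self.values, self.samples
        if list(vals.columns) != list(sheet.index):
            missing = set(vals.columns) ^ set(sheet.index)
            if missing:
                raise ValueError(f"sample ids of matrix and sheet disagree: {sorted(missing)}")
            # same ids, different order: align sheet to matrix order
            self.samples = sheet = sheet.loc[vals.columns]
        if vals.index.has_duplicates:
            dup = vals.index[vals.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dup[:10]}")
        triples = sheet[["time", "condition", "replicate"]]
        if triples.duplicated().any():
            dup = sheet.index[triples.duplicated()].tolist()
            raise ValueError(f"duplicate (time, condition, replicate) triples at samples {dup}")
        times = sheet["time"].to_numpy(dtype=float)
        if not np.all(np.isfinite(times)) or (times < 0).any():
            raise ValueError("time points must be finite and non-negative")
        if (sheet["replicate"].to_numpy() < 1).any():
            raise ValueError("replicate indices must be positive integers")
        if sheet["condition"].nunique() > 2:
            raise ValueError(
                f"at most two condition labels supported, got {sorted(sheet['condition'].unique())}"
            )
        for cond, sub in sheet.groupby("condition"):
            if sub["time"].nunique() < 3:
                raise ValueError(
                    f"condition {cond!r} has fewer than 3 distinct time points; "
                    "a spline fit needs at least 3"
                )
        # drop genes with missing values (the fits assume complete profiles)
        incomplete = vals.isna().any(axis=1)
        if incomplete.any():
            logger.warning("dropping %d features with missing values", int(incomplete.sum()))
            self.values = vals.loc[~incomplete]

    def copy(self) -> "TimeSeriesExperiment":
        return TimeSeriesExperiment(
            values=self.values.copy(),
            samples=self.samples.copy(),
            condition_mapping=dict(self.condition_mapping),
        )


# -- parsing ---------------------------------------------------------------


def _read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    """Read a delimited text file, sniffing tab vs. comma from the header."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") >= header.count(",") else ","
    return pd.read_csv(path, sep=sep, float_precision="round_trip", **kwargs)


def _normalize_conditions(labels: pd.Series) -> tuple[pd.Series, dict[str, str]]:
    """Map arbitrary condition labels to the canonical {stim, ctrl} pair."""
    uniq = list(dict.fromkeys(labels))  # sheet order
    if len(uniq) > 2:
        raise ValueError(f"more than two condition labels present: {uniq}")
    mapping: dict[str, str] = {}
    for lab in uniq:
        low = str(lab).strip().lower()
        if low in _STIM_ALIASES:
            mapping[lab] = STIM
        elif low in _CTRL_ALIASES:
            mapping[lab] = CTRL
    unmapped = [lab for lab in uniq if lab not in mapping]
    taken = set(mapping.values())
    # unrecognised labels are assigned by sample-sheet order: first free slot
    for lab in unmapped:
        slot = STIM if STIM not in taken else CTRL
        mapping[lab] = slot
        taken.add(slot)
        logger.warning("condition label %r mapped to %r by sample-sheet order", lab, slot)
    if len(set(mapping.values())) != len(mapping):
        raise ValueError(f"condition labels {uniq} map to the same canonical condition")
    return labels.map(mapping), mapping


def load_experiment(expr_path: str | Path, samples_path: str | Path) -> TimeSeriesExperiment:
    """Load an expression matrix and its sample sheet into an experiment.

    The matrix is delimited text with feature ids in the first column and
    one column per sample; the sheet has columns ``sample``, ``time``,
    ``condition``, ``replicate``.  Matrix columns and sheet rows are matched
    by sample id regardless of order.
    """
    vals = _read_table(expr_path, index_col=0)
    sheet = _read_table(samples_path)
    required = {"sample", "time", "condition", "replicate"}
    missing_cols = required - set(sheet.columns)
    if missing_cols:
        raise ValueError(f"sample sheet lacks columns: {sorted(missing_cols)}")
    sheet = sheet.set_index("sample")
    sheet.index = sheet.index.astype(str)
    vals.columns = vals.columns.astype(str)
    vals.index = vals.index.astype(str)

    unmatched = [c for c in vals.columns if c not in sheet.index]
    if unmatched:
        raise ValueError(f"matrix columns missing from sample sheet: {unmatched}")
    extra = [s for s in sheet.index if s not in set(vals.columns)]
    if extra:
        logger.warning("sample sheet rows without matrix columns ignored: %s", extra)
    sheet = sheet.loc[vals.columns]

    non_numeric = vals.apply(pd.to_numeric, errors="coerce")
    bad = vals.notna() & non_numeric.isna()
    if bad.any().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric expression value at feature {vals.index[r]!r}, "
            f"sample {vals.columns[c]!r}: {vals.iat[r, c]!r}"
        )
    vals = non_numeric.astype(float)

    sheet["time"] = pd.to_numeric(sheet["time"])
    sheet["replicate"] = pd.to_numeric(sheet["replicate"]).astype(int)
    cond, mapping = _normalize_conditions(sheet["condition"])
    sheet = sheet.assign(condition=cond)
    return TimeSeriesExperiment(values=vals, samples=sheet, condition_mapping=mapping)


def write_experiment(exp: TimeSeriesExperiment, expr_path: str | Path, samples_path: str | Path) -> None:
    """Write an experiment back to matrix + sheet TSVs (full float precision)."""
    # default float formatting is the shortest exact representation, so a
    # load -> write -> load round trip preserves values bit-for-bit
    exp.values.to_csv(expr_path, sep="\t", index_label="feature")
    sheet = exp.samples.reset_index()
    sheet = sheet.rename(columns={sheet.columns[0]: "sample"})
    sheet.to_csv(samples_path, sep="\t", index=False)


def synthesize_control(
    exp: TimeSeriesExperiment,
    mode: Literal["constant_first", "constant_mean"] = "constant_mean",
) -> TimeSeriesExperiment:
    """Add a constant per-gene control profile to a single-condition design.

    One control pseudo-sample is added per existing time point.  The control
    value of a gene is time-invariant: either the gene's (replicate-mean)
    value at the earliest time point (``constant_first``) or its mean over
    all measurements (``constant_mean``).  Measured values are untouched.
    """
    conds = exp.samples["condition"].unique()
    if len(conds) != 1:
        raise ValueError("control synthesis requires a single-condition experiment")
    measured = str(conds[0])
    times = exp.distinct_times()
    if mode == "constant_first":
        first = times[0]
        first_samples = exp.samples.index[exp.samples["time"] == first]
        const = exp.values[first_samples].mean(axis=1)
    elif mode == "constant_mean":
        const = exp.values.mean(axis=1)
    else:
        raise ValueError(f"unknown control mode {mode!r}")

    ctrl_ids = [f"__ctrl_t{t:g}" for t in times]
    ctrl_vals = pd.DataFrame(
        np.tile(const.to_numpy()[:, None], (1, len(times))),
        index=exp.values.index,
        columns=ctrl_ids,
    )
    ctrl_sheet = pd.DataFrame(
        {"time": times, "condition": CTRL, "replicate": 1}, index=ctrl_ids
    )
    stim_sheet = exp.samples.assign(condition=STIM)
    mapping = dict(exp.condition_mapping)
    mapping.setdefault(measured, STIM)
    return TimeSeriesExperiment(
        values=pd.concat([exp.values, ctrl_vals], axis=1),
        samples=pd.concat([stim_sheet, ctrl_sheet]),
        condition_mapping=mapping,
    )
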