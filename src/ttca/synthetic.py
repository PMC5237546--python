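"""Synthetic perturbation-response time courses.

Emulates the structure of a stimulation experiment sampled on a sparse,
irregular grid (default 0, 0.5, 1, 2, 4, 6, 8, 12, 24, 48 h) with uneven
replication: some time points are measured once, some in duplicate.  Gene
archetypes cover the dynamic regimes the scores target:

* ``flat`` — no condition effect, pure noise around a gene baseline;
* ``slow_monotone`` — a sigmoid rise in the stimulated condition whose
  10-90% transition lies inside the 6-48 h range;
* ``transient_peak`` — a spike spanning 1-2 consecutive time points with
  amplitude ``effect x noise_sd``;
* ``late_response`` — a shift appearing only after the late-interval bound;
* ``unstable`` — no mean effect, but replicate noise inflated twenty-fold
  (the wild replicate-divergence pattern the instability flag is built to
  catch; absent from the default mix, enable it via ``fractions``).

Noise is Gaussian and homoscedastic by default; ``mean_dependent_noise``
scales each gene's noise SD with its baseline to exercise the stratified
noise model.  Everything is driven by one seed, so identical specs give
byte-identical experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import CTRL, STIM, TimeSeriesExperiment, write_experiment

#: sampling grid (hours) of a typical stimulation time course
DEFAULT_TIMES = (0.0, 0.5, 1.0, 2.0, 4.0, 6.0, 8.0, 12.0, 24.0, 48.0)
#: time points measured in duplicate by default (4 of 10)
DEFAULT_REPLICATED = (1.0, 4.0, 8.0, 24.0)

ARCHETYPES = ("flat", "slow_monotone", "transient_peak", "late_response", "unstable")

#: archetypes that carry a true condition effect (positives for recovery)
DIFFERENTIAL = ("slow_monotone", "transient_peak", "late_response")


@dataclass
class SimSpec:
    """Study conditions of one simulated experiment."""

    n_genes: int = 2000
    times: tuple[float, ...] = DEFAULT_TIMES
    replicated_times: tuple[float, ...] = DEFAULT_REPLICATED
    n_replicates: int = 2
    fractions: dict[str, float] = field(
        default_factory=lambda: {
            "flat": 0.90,
            "slow_monotone": 0.05,
            "transient_peak": 0.05,
            "late_response": 0.0,
            "unstable": 0.0,
        }
    )
    noise_sd: float = 0.25
    effect: float = 4.0  # amplitude in units of noise_sd
    outlier_rate: float = 0.0
    outlier_sd: float = 2.0  # outlier displacement in expression units
    unstable_inflation: float = 20.0
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    mean_dependent_noise: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.fractions.get(a, 0.0) for a in ARCHETYPES)
        if not np.isclose(total, 1.0):
            raise ValueError(f"archetype fractions must sum to 1, got {total}")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        unknown = set(self.fractions) - set(ARCHETYPES)
        if unknown:
            raise ValueError(f"unknown archetypes: {sorted(unknown)}")


def _sample_sheet(spec: SimSpec) -> pd.DataFrame:
    rows = []
    for cond in (CTRL, STIM):
        for t in spec.times:
            reps = spec.n_replicates if t in spec.replicated_times else 1
            for r in range(1, reps + 1):
                rows.append((f"{cond}_t{t:g}_r{r}", t, cond, r))
    return pd.DataFrame(
        rows, columns=["sample", "time", "condition", "replicate"]
    ).set_index("sample")


def _archetype_assignment(spec: SimSpec) -> np.ndarray:
    counts = {a: int(round(spec.fractions.get(a, 0.0) * spec.n_genes)) for a in ARCHETYPES}
    # rounding remainder goes to flat
    counts["flat"] += spec.n_genes - sum(counts.values())
    labels = np.concatenate([np.repeat(a, counts[a]) for a in ARCHETYPES])
    return labels[: spec.n_genes]


def _signal(archetype: str, times: np.ndarray, amp: float, rng: np.random.Generator):
    """Stimulated-condition mean shift over the grid; returns (shift, params)."""
    shift = np.zeros_like(times)
    params: dict[str, float] = {}
    if archetype == "slow_monotone":
        t50 = rng.uniform(15.0, 27.0)
        tau = rng.uniform(2.5, 6.0)
        sig = amp / (1.0 + np.exp(-(times - t50) / tau))
        shift = sig - sig[0]  # starts at baseline
        params = {"t50": t50, "tau": tau}
    elif archetype == "transient_peak":
        span = int(rng.integers(1, 3))  # spike covers 1 or 2 consecutive points
        start = int(rng.integers(1, len(times) - span))  # never at t=0
        shift[start : start + span] = amp
        params = {"start_index": start, "span": span}
    elif archetype == "late_response":
        onset = times[(2 * len(times)) // 3]
        shift[times >= onset] = amp
        params = {"onset": float(onset)}
    return shift, params


def simulate(spec: SimSpec) -> tuple[TimeSeriesExperiment, pd.DataFrame]:
    """Draw one experiment and its truth table from the spec.

    Returns the experiment plus a DataFrame indexed by gene with columns
    ``archetype`` and ``is_differential`` (True for archetypes with a real
    condition effect).
    """
    rng = np.random.default_rng(spec.seed)
    sheet = _sample_sheet(spec)
    times = sheet["time"].to_numpy(dtype=float)
    is_stim = (sheet["condition"] == STIM).to_numpy()
    n_samples = len(sheet)

    genes = [f"G{i:05d}" for i in range(spec.n_genes)]
    archetypes = _archetype_assignment(spec)
    baselines = rng.normal(spec.baseline_mean, spec.baseline_sd, spec.n_genes)
    amp = spec.effect * spec.noise_sd

    grid = np.asarray(spec.times)
    values = np.empty((spec.n_genes, n_samples))
    truth_rows = []
    for i, (gene, arche) in enumerate(zip(genes, archetypes)):
        mean = np.full(n_samples, baselines[i])
        shift, params = _signal(arche, grid, amp, rng)
        if shift.any():
            per_sample = np.interp(times, grid, shift)
            # effects apply exactly at grid points; interp is identity here
            mean = mean + np.where(is_stim, per_sample, 0.0)
        sd = spec.noise_sd
        if spec.mean_dependent_noise:
            sd = spec.noise_sd * (0.5 + baselines[i] / (2.0 * spec.baseline_mean))
        if arche == "unstable":
            sd = sd * spec.unstable_inflation
        row = mean + rng.normal(0.0, sd, n_samples)
        if spec.outlier_rate > 0:
            hits = rng.random(n_samples) < spec.outlier_rate
            row = row + hits * rng.normal(0.0, spec.outlier_sd, n_samples)
        values[i] = row
        truth_rows.append((gene, arche, arche in DIFFERENTIAL, params))

    exp = TimeSeriesExperiment(
        values=pd.DataFrame(values, index=genes, columns=sheet.index),
        samples=sheet,
    )
    truth = pd.DataFrame(
        truth_rows, columns=["gene", "archetype", "is_differential", "params"]
    ).set_index("gene")
    return exp, truth


def write_simulation(
    exp: TimeSeriesExperiment, truth: pd.DataFrame, out_dir: str | Path
) -> dict[str, Path]:
    """Write expression matrix, sample sheet and truth table as TSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expr": out / "expr.tsv",
        "samples": out / "samples.tsv",
        "truth": out / "truth.tsv",
    }
    write_experiment(exp, paths["expr"], paths["samples"])
    truth.drop(columns=["params"]).to_csv(paths["truth"], sep="\t")
    return paths
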