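"""Shared fixtures: small hand-built experiments and session-scoped
simulation runs reused by the heavier statistical tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ttca import AnalysisConfig, SimSpec, TimeSeriesExperiment, run_analysis, simulate


def make_experiment(values: dict, sheet_rows: list[tuple]) -> TimeSeriesExperiment:
    """Build an experiment from {gene: [values]} plus (sample, time, condition, replicate) rows."""
    samples = pd.DataFrame(
        sheet_rows, columns=["sample", "time", "condition", "replicate"]
    ).set_index("sample")
    vals = pd.DataFrame(values, index=samples.index).T
    return TimeSeriesExperiment(values=vals, samples=samples)


def two_condition_sheet(times, replicated=()):
    """Sheet rows for both conditions over a time grid, duplicating some points."""
    rows = []
    for cond in ("ctrl", "stim"):
        for t in times:
            reps = 2 if t in replicated else 1
            for r in range(1, reps + 1):
                rows.append((f"{cond}_{t:g}_{r}", t, cond, r))
    return rows


@pytest.fixture(scope="session")
def recovery_sim():
    """Default simulation: 2000 genes, 5% transient peaks + 5% slow risers."""
    return simulate(SimSpec(seed=1))


@pytest.fixture(scope="session")
def recovery_run(recovery_sim):
    exp, truth = recovery_sim
    return run_analysis(exp), truth


@pytest.fixture(scope="session")
def instability_sim():
    """Same conditions with 5% of the flat genes re-assigned to the unstable archetype."""
    spec = SimSpec(
        seed=2,
        fractions={
            "flat": 0.85,
            "slow_monotone": 0.05,
            "transient_peak": 0.05,
            "late_response": 0.0,
            "unstable": 0.05,
        },
    )
    return simulate(spec)


@pytest.fixture(scope="session")
def instability_run(instability_sim):
    exp, truth = instability_sim
    return run_analysis(exp), truth


@pytest.fixture(scope="session")
def null_sim():
    """Pure-noise simulation: 5000 flat genes, no condition effect anywhere."""
    spec = SimSpec(
        n_genes=5000,
        seed=3,
        fractions={
            "flat": 1.0,
            "slow_monotone": 0.0,
            "transient_peak": 0.0,
            "late_response": 0.0,
            "unstable": 0.0,
        },
    )
    return simulate(spec)


@pytest.fixture(scope="session")
def null_run(null_sim):
    exp, truth = null_sim
    return run_analysis(exp), truth


def auroc(score: np.ndarray, positive: np.ndarray) -> float:
    """Rank-based AUROC of a score against boolean ground truth."""
    from scipy.stats import rankdata

    r = rankdata(score)
    n_pos = int(positive.sum())
    n_neg = len(positive) - n_pos
    return float((r[positive].mean() - (n_pos + 1) / 2) / n_neg)
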