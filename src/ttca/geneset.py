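"""Gene-set temporal analysis: baseline-anchored bands and the minimal
overlap score.

Each gene's expression is first anchored at zero by subtracting its value
at the earliest measured time point, so only the change relative to
baseline matters.  Per group, condition and time point the member values
are pooled into a band: mean plus an *asymmetric* pair of standard
deviations — sd_u over the points above the mean, sd_l over those below —
which reveals one-sided shifts that a symmetric SD would blur.

The minimal overlap score compares the stimulated and control bands at
each shared time point,

    theta_j = max[(mean_C - sd_l_C) - (mean_S + sd_u_S);
                  (mean_S - sd_l_S) - (mean_C + sd_u_C)]
              / (0.5 * (sd_u_S + sd_l_S + sd_u_C + sd_l_C)),

and Theta = max_j theta_j.  Positive Theta means the bands separate at
some time point; negative means they always overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import CTRL, STIM, AnalysisConfig, TimeSeriesExperiment

logger = logging.getLogger("ttca")


@dataclass
class GeneSetBand:
    """Per-condition band of one gene group.

    ``parts`` maps a condition label to a DataFrame indexed by time with
    columns ``mean``, ``sd_u``, ``sd_l`` and ``n`` (pooled value count).
    """

    group: str
    parts: dict[str, pd.DataFrame]
    member_count: int


def read_gene_sets(path: str | Path) -> dict[str, list[str]]:
    """Parse gene sets from GMT or a two-column (gene, group) mapping.

    GMT lines are ``name <tab> description <tab> gene1 <tab> gene2 ...``;
    a file whose every data line has exactly two fields is read as the
    mapping dialect instead.
    """
    path = Path(path)
    lines = [
        ln.rstrip("\n") for ln in path.read_text().splitlines()
        if ln.strip() and not ln.lstrip().startswith("#")
    ]
    if not lines:
        raise ValueError("no usable gene sets: file is empty")
    rows = [ln.split("\t") if "\t" in ln else ln.split() for ln in lines]
    groups: dict[str, list[str]] = {}
    if all(len(r) == 2 for r in rows):
        for gene, group in rows:
            groups.setdefault(group, []).append(gene)
    else:
        for r in rows:
            if len(r) < 3:
                raise ValueError(f"malformed GMT line (need name, description, genes): {r}")
            name, _desc, *genes = r
            groups[name] = [g for g in genes if g]
    groups = {k: v for k, v in groups.items() if v}
    if not groups:
        raise ValueError("no usable gene sets")
    return groups


def _baselined(exp: TimeSeriesExperiment, members: list[str], condition: str) -> pd.DataFrame:
    """Member-gene values of one condition minus each gene's value at its
    earliest time point (replicate mean), columns = samples of the condition."""
    sheet = exp.samples[exp.samples["condition"] == condition]
    vals = exp.values.loc[members, sheet.index]
    t0 = sheet["time"].min()
    first = sheet.index[sheet["time"] == t0]
    baseline = vals[first].mean(axis=1)
    return vals.sub(baseline, axis=0), sheet


def _asym_sd(values: np.ndarray, mean: float) -> tuple[float, float]:
    """Population SDs around ``mean`` of the values strictly above / below it.

    A side with fewer than 2 values gets SD 0 (an SD of a singleton is
    undefined and a spread estimate from one point is meaningless).
    """
    above = values[values > mean]
    below = values[values < mean]
    sd_u = float(np.sqrt(np.mean((above - mean) ** 2))) if len(above) >= 2 else 0.0
    sd_l = float(np.sqrt(np.mean((below - mean) ** 2))) if len(below) >= 2 else 0.0
    return sd_u, sd_l


def build_band(
    exp: TimeSeriesExperiment, members, condition: str
) -> pd.DataFrame:
    """Mean +/- asymmetric-SD band of one gene group in one condition.

    Returns a DataFrame indexed by time with columns ``mean``, ``sd_u``,
    ``sd_l``, ``n``; all member-gene replicate values at a time point are
    pooled.
    """
    members = [m for m in members if m in exp.values.index]
    if len(members) < 2:
        raise ValueError("a gene-set band needs at least 2 member genes")
    vals, sheet = _baselined(exp, members, condition)
    records = []
    for time, sub in sheet.groupby("time", sort=True):
        pooled = vals[sub.index].to_numpy().ravel()
        mean = float(pooled.mean())
        sd_u, sd_l = _asym_sd(pooled, mean)
        records.append((float(time), mean, sd_u, sd_l, len(pooled)))
    return pd.DataFrame.from_records(
        records, columns=["time", "mean", "sd_u", "sd_l", "n"]
    ).set_index("time")


def build_geneset_band(exp: TimeSeriesExperiment, group: str, members) -> GeneSetBand:
    """Bands of both conditions for one group."""
    present = [m for m in members if m in exp.values.index]
    return GeneSetBand(
        group=group,
        parts={c: build_band(exp, present, c) for c in exp.conditions},
        member_count=len(present),
    )


def overlap_score(band: GeneSetBand) -> float:
    """Minimal overlap score Theta of a two-condition band."""
    if STIM not in band.parts or CTRL not in band.parts:
        raise ValueError("overlap score needs bands for both conditions")
    s, c = band.parts[STIM], band.parts[CTRL]
    shared = s.index.intersection(c.index)
    if len(shared) == 0:
        raise ValueError("conditions share no time point")
    thetas = []
    for t in shared:
        num = max(
            (c.loc[t, "mean"] - c.loc[t, "sd_l"]) - (s.loc[t, "mean"] + s.loc[t, "sd_u"]),
            (s.loc[t, "mean"] - s.loc[t, "sd_l"]) - (c.loc[t, "mean"] + c.loc[t, "sd_u"]),
        )
        den = 0.5 * (s.loc[t, "sd_u"] + s.loc[t, "sd_l"] + c.loc[t, "sd_u"] + c.loc[t, "sd_l"])
        if den == 0:
            theta = np.inf if num > 0 else (-np.inf if num < 0 else 0.0)
            logger.info("zero bandwidth at t=%g in group %s: theta=%s", t, band.group, theta)
        else:
            theta = num / den
        thetas.append(theta)
    return float(np.max(thetas))


def group_pseudo_experiment(
    exp: TimeSeriesExperiment, groups: dict[str, list[str]]
) -> tuple[TimeSeriesExperiment, dict[str, int]]:
    """Collapse each usable group to one pseudo-gene per sample.

    The pseudo-gene value at a sample is the mean over member genes of the
    baseline-subtracted expression.  Groups with fewer than 2 mapped
    members are skipped (logged).  Genes may belong to several groups.
    """
    rows = {}
    counts = {}
    for group, members in groups.items():
        present = [m for m in members if m in exp.values.index]
        if len(present) < 2:
            logger.warning("gene set %r skipped: %d mapped member(s)", group, len(present))
            continue
        profile = pd.Series(0.0, index=exp.values.columns)
        for cond in exp.conditions:
            vals, sheet = _baselined(exp, present, cond)
            profile[sheet.index] = vals.mean(axis=0)
        rows[group] = profile
        counts[group] = len(present)
    if not rows:
        raise ValueError("no usable gene sets (all groups have < 2 mapped members)")
    pseudo = TimeSeriesExperiment(
        values=pd.DataFrame(rows).T[exp.values.columns],
        samples=exp.samples.copy(),
        condition_mapping=dict(exp.condition_mapping),
    )
    return pseudo, counts


def group_scores(
    exp: TimeSeriesExperiment,
    groups: dict[str, list[str]],
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Score gene groups: average-profile scores plus the overlap score.

    Each group's per-condition mean profile is treated as a single
    pseudo-gene and run through the dynamics / peak / integral scoring;
    Theta is appended and groups are ranked by the group-level consensus
    (z-mean of dynamics, peak and combined integral scores).
    """
    from .pipeline import run_analysis  # deferred: pipeline imports this module

    config = config or AnalysisConfig()
    pseudo, counts = group_pseudo_experiment(exp, groups)
    result = run_analysis(pseudo, config, counts=None, noise=False).table
    theta = {
        g: overlap_score(build_geneset_band(exp, g, groups[g])) for g in counts
    }
    result = result.assign(
        member_count=pd.Series(counts), theta=pd.Series(theta)
    )
    cols = ["member_count", "theta"] + [
        c for c in result.columns if c not in ("member_count", "theta")
    ]
    return result[cols]
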