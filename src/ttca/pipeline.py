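"""End-to-end analysis: load -> fit -> score -> significance -> ranked table.

:func:`run_analysis` turns a :class:`TimeSeriesExperiment` into a
ScoreTable — one row per gene with the dynamics, peak, integral, relevance
and consensus scores, per-score p-values and effect sizes, the instability
flag, and the final consensus rank.  :func:`run_geneset_analysis` does the
same at gene-group level with the minimal overlap score appended.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import CTRL, STIM, AnalysisConfig, GeneProfile, TimeSeriesExperiment, synthesize_control
from .qspline import DYNAMICS_SENTINEL, dynamics_and_fits
from .relevance import PublicationCounts, relevance_scores
from .scores import (
    IntervalSet,
    build_noise_model,
    combined_integral,
    integral_score,
    peak_scores,
)
from .significance import (
    consensus,
    consensus_significant,
    effect_size,
    fit_best_distribution,
    score_pvalue,
)

logger = logging.getLogger("ttca")


@dataclass
class AnalysisResult:
    """Ranked score table plus run metadata."""

    table: pd.DataFrame
    distributions: dict[str, object]
    intervals: IntervalSet
    timings: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)


class _WarningCollector(logging.Handler):
    def __init__(self) -> None:
        super().__init__(level=logging.WARNING)
        self.messages: list[str] = []

    def emit(self, record: logging.LogRecord) -> None:
        self.messages.append(record.getMessage())


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """Step-up FDR adjustment (reported as an extension column)."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.clip(ranked, 0.0, 1.0)
    return q


def _profiles(exp: TimeSeriesExperiment):
    """Fast per-gene profile iterator (precomputes the sample layout once)."""
    layout = {}
    for cond, sub in exp.samples.groupby("condition", sort=True):
        order = np.argsort(sub["time"].to_numpy(dtype=float), kind="stable")
        ids = sub.index.to_numpy()[order]
        col_idx = np.array([exp.values.columns.get_loc(s) for s in ids])
        layout[cond] = (sub["time"].to_numpy(dtype=float)[order], col_idx)
    mat = exp.values.to_numpy()
    for i, gene in enumerate(exp.values.index):
        data = {c: (t, mat[i, idx]) for c, (t, idx) in layout.items()}
        yield gene, GeneProfile(feature=gene, data=data)


def run_analysis(
    exp: TimeSeriesExperiment,
    config: AnalysisConfig | None = None,
    counts: PublicationCounts | None = None,
    noise: bool = True,
) -> AnalysisResult:
    """Run the full per-gene scoring pipeline.

    Parameters
    ----------
    exp:
        Two-condition experiment, or a single-condition one if
        ``config.control_mode`` requests constant-control synthesis.
    config:
        Analysis parameters (defaults are sensible for log-scale arrays).
    counts:
        Optional publication counts; without them the relevance score is
        omitted and the consensus runs over the three remaining scores.
    noise:
        Set False to skip the replicate noise model (e.g. for gene-group
        pseudo-profiles, where replicate scatter is no longer meaningful).
    """
    config = config or AnalysisConfig()
    collector = _WarningCollector()
    logger.addHandler(collector)
    timings: dict[str, float] = {}
    try:
        t0 = time.perf_counter()
        if len(exp.conditions) == 1:
            if config.control_mode == "measured":
                raise ValueError(
                    "experiment has a single condition; choose control_mode "
                    "'constant_first' or 'constant_mean' to synthesise a control"
                )
            exp = synthesize_control(exp, config.control_mode)
        if set(exp.conditions) != {STIM, CTRL}:
            raise ValueError(f"expected conditions {{stim, ctrl}}, got {exp.conditions}")
        genes = exp.values.index
        n = len(genes)
        times = exp.distinct_times()
        b1, b2 = config.resolve_bounds(times)
        intervals = IntervalSet(float(times[0]), b1, b2, float(times[-1]))
        timings["setup"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        noise_model = build_noise_model(
            exp, config.sd_quantile, config.min_group_size, config.min_groups
        ) if noise else None
        timings["noise_model"] = time.perf_counter() - t0

        # per-gene median-spline fits: dynamics + integrals
        t0 = time.perf_counter()
        D = np.empty(n)
        I = {name: np.empty(n) for name, _ in intervals.items()}
        for i, (gene, profile) in enumerate(_profiles(exp)):
            d, fits = dynamics_and_fits(profile, config.lam)
            D[i] = d
            for name, window in intervals.items():
                I[name][i] = integral_score(fits[STIM], fits[CTRL], window)
        finite = np.isfinite(D)
        if not finite.all():
            sentinel = float(D[finite].max()) if finite.any() else 1.0
            logger.warning(
                "%d gene(s) with perfect per-condition fits: dynamics score set "
                "to the dataset maximum %.4g", int((~finite).sum()), sentinel,
            )
            D[~finite] = sentinel
        timings["fits"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        P = peak_scores(exp).loc[genes].to_numpy()
        I_df = pd.DataFrame({k: v for k, v in I.items()}, index=genes)
        I_comb = combined_integral(I_df[["early", "intermediate", "late"]]).to_numpy()
        R = relevance_scores(counts, genes) if counts is not None else None
        timings["scores"] = time.perf_counter() - t0

        # significance
        t0 = time.perf_counter()
        dists: dict[str, object] = {}
        dists["dynamics"] = fit_best_distribution(D)
        dists["peak"] = fit_best_distribution(P)
        dists["integral_combined"] = fit_best_distribution(I_comb)
        p_D = score_pvalue(dists["dynamics"], D)
        p_P = score_pvalue(dists["peak"], P)
        p_I = score_pvalue(dists["integral_combined"], I_comb)
        if R is not None and np.count_nonzero(R) >= 2 and np.ptp(R[R > 0]) > 0:
            dists["relevance"] = fit_best_distribution(R[R > 0])
            p_R = np.ones(n)
            p_R[R > 0] = score_pvalue(dists["relevance"], R[R > 0])
        else:
            p_R = np.ones(n)

        alpha = config.significance_alpha
        sig_D = p_D < alpha
        if noise_model is not None and noise_model.available and noise_model.n_replicated_cells >= 4:
            thr = np.array([noise_model.threshold(g) for g in genes])
            sig_P = P > config.peak_factor * thr
            med_sd = noise_model.median_sd.loc[genes].to_numpy()
            instab = med_sd > config.instability_factor * thr
        else:
            if noise_model is not None:
                logger.warning(
                    "fewer than 4 replicated measurement points: peak significance "
                    "falls back to the distribution-based p-value"
                )
            sig_P = p_P < alpha
            med_sd = np.full(n, np.nan)
            instab = np.zeros(n, dtype=bool)
        sig_I = p_I < alpha
        sig_R = p_R < alpha
        flags = np.column_stack([sig_D, sig_P, sig_I, sig_R])
        significant = consensus_significant(flags)

        C, C_raw = consensus(D, P, I_comb, R if config.use_relevance else None)
        dists["consensus"] = fit_best_distribution(C_raw)
        p_C = score_pvalue(dists["consensus"], C_raw)
        timings["significance"] = time.perf_counter() - t0

        # effect sizes relative to the detection range
        vmax = float(exp.values.to_numpy().max())
        vmin = float(exp.values.to_numpy().min())
        eff_P = effect_size("peak", P, vmax, vmin)
        eff_instab = np.where(
            np.isfinite(med_sd), effect_size("instability", np.nan_to_num(med_sd), vmax, vmin), 0.0
        )
        eff_I = {
            name: effect_size("integral", I_df[name].to_numpy(), vmax, vmin, hi - lo)
            for name, (lo, hi) in intervals.items()
        }

        table = pd.DataFrame(
            {
                "dynamics": D,
                "peak": P,
                "integral_early": I_df["early"],
                "integral_intermediate": I_df["intermediate"],
                "integral_late": I_df["late"],
                "integral_complete": I_df["complete"],
                "integral_combined": I_comb,
                "relevance": R if R is not None else np.zeros(n),
                "consensus": C,
                "consensus_p": p_C,
                "consensus_q_bh": _benjamini_hochberg(p_C),
                "p_dynamics": p_D,
                "p_peak": p_P,
                "p_integral_combined": p_I,
                "p_relevance": p_R,
                "effect_peak": eff_P,
                "effect_instability": eff_instab,
                "effect_integral_early": eff_I["early"],
                "effect_integral_intermediate": eff_I["intermediate"],
                "effect_integral_late": eff_I["late"],
                "effect_integral_complete": eff_I["complete"],
                "instability": instab,
                "sig_dynamics": sig_D,
                "sig_peak": sig_P,
                "sig_integral_combined": sig_I,
                "sig_relevance": sig_R,
                "significant": significant,
            },
            index=genes,
        )
        # rank by consensus descending, ties broken by feature id (stable sort
        # on an index-sorted table) for deterministic output
        table = table.sort_index(kind="mergesort").sort_values(
            "consensus", ascending=False, kind="mergesort"
        )
        table.insert(0, "rank", np.arange(1, n + 1))
        table.index.name = "gene"

        return AnalysisResult(
            table=table,
            distributions=dists,
            intervals=intervals,
            timings=timings,
            warnings=list(collector.messages),
        )
    finally:
        logger.removeHandler(collector)


def run_geneset_analysis(
    exp: TimeSeriesExperiment,
    groups: dict[str, list[str]],
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Group-level score table with the minimal overlap score appended."""
    from .geneset import group_scores

    return group_scores(exp, groups, config)


# -- output ------------------------------------------------------------------


def _file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_results(
    result: AnalysisResult,
    out_dir: str | Path,
    config: AnalysisConfig,
    inputs: dict[str, str | Path] | None = None,
    table_name: str = "genes.tsv",
    status: str = "ok",
    failure_stage: str | None = None,
) -> dict[str, Path]:
    """Write the ranked table and a JSON manifest of the run."""
    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    if result is not None:
        table_path = out / table_name
        result.table.to_csv(table_path, sep="\t", float_format="%.10g")
        paths["table"] = table_path
    manifest = {
        "version": __version__,
        "status": status,
        "failure_stage": failure_stage,
        "seed": config.seed,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(config).items()
        },
        "inputs": {
            name: {"path": str(p), "sha256": _file_digest(p)}
            for name, p in (inputs or {}).items()
            if Path(p).exists()
        },
        "timings_s": {k: round(v, 3) for k, v in (result.timings if result else {}).items()},
        "warnings": result.warnings if result else [],
        "null_distributions": {
            name: {
                "family": d.family,
                "params": [float(x) for x in d.params],
                "shift": d.shift,
                "loglik": None if not np.isfinite(d.loglik) else d.loglik,
                "degenerate": d.degenerate,
            }
            for name, d in (result.distributions if result else {}).items()
        },
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    paths["manifest"] = manifest_path
    return paths
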