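"""Peak score, stratified noise model, instability flag, integral scores."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from conftest import make_experiment, two_condition_sheet
from ttca import (
    build_noise_model,
    combined_integral,
    fit_median_spline,
    instability_flag,
    integral_score,
    peak_significant,
)
from ttca.qspline import FittedCurve
from ttca.scores import NoiseModel, peak_scores


def curve(knots, values):
    return FittedCurve(
        knots=np.asarray(knots, float),
        knot_values=np.asarray(values, float),
        lam=0.0,
        residuals=np.zeros(len(knots)),
    )


class TestPeakScore:
    def test_direct_maximum_of_mean_differences(self):
        rows = two_condition_sheet([0, 1, 2])
        exp = make_experiment({"G1": [1, 1, 1, 1, 5, 1]}, rows)  # ctrl flat, stim peaks at t=1
        assert peak_scores(exp).loc["G1"] == pytest.approx(4.0)

    def test_identical_conditions_score_zero(self):
        rows = two_condition_sheet([0, 1, 2])
        exp = make_experiment({"G1": [1, 2, 3, 1, 2, 3]}, rows)
        assert peak_scores(exp).loc["G1"] == 0.0

    def test_condition_symmetry_and_replicate_order_invariance(self):
        rows = two_condition_sheet([0, 1, 2], replicated=(1,))
        vals = [1.0, 2.0, 2.6, 3.0, 1.2, 5.0, 5.4, 2.8]
        exp = make_experiment({"G1": vals}, rows)
        p = peak_scores(exp).loc["G1"]
        # swap conditions
        swapped = exp.samples.assign(
            condition=exp.samples["condition"].map({"stim": "ctrl", "ctrl": "stim"})
        )
        exp_sw = make_experiment({"G1": vals}, list(zip(swapped.index, swapped["time"], swapped["condition"], swapped["replicate"])))
        assert peak_scores(exp_sw).loc["G1"] == pytest.approx(p)

    def test_matches_brute_force_on_random_genes(self):
        rng = np.random.default_rng(0)
        times = [0, 1, 2, 4, 8]
        rows = two_condition_sheet(times, replicated=(2, 8))
        n = 1000
        vals = {f"G{i}": rng.normal(5, 1, len(rows)) for i in range(n)}
        exp = make_experiment(vals, rows)
        p = peak_scores(exp)
        sheet = exp.samples
        for gene in list(vals)[::97] + ["G0", f"G{n-1}"]:
            best = 0.0
            for t in times:
                s = exp.values.loc[gene, sheet.index[(sheet["time"] == t) & (sheet["condition"] == "stim")]].mean()
                c = exp.values.loc[gene, sheet.index[(sheet["time"] == t) & (sheet["condition"] == "ctrl")]].mean()
                best = max(best, abs(s - c))
            assert p.loc[gene] == pytest.approx(best)


def experiment_with_sds(n_genes, rng, sd=1.0, times=(0, 1, 2, 4), replicated=(1, 2)):
    rows = two_condition_sheet(times, replicated=replicated)
    base = rng.uniform(2, 12, n_genes)
    vals = {
        f"G{i:05d}": base[i] + rng.normal(0, sd, len(rows)) for i in range(n_genes)
    }
    return make_experiment(vals, rows)


class TestNoiseModel:
    def test_group_count_follows_size_floor(self):
        rng = np.random.default_rng(1)
        exp = experiment_with_sds(2500, rng)
        nm = build_noise_model(exp, min_group_size=1000)
        assert len(nm.thresholds) == 2
        assert set(nm.group_of.values()) == {0, 1}

    def test_equal_replicate_sds_give_that_threshold(self):
        # replicate pairs differing by exactly d have SD d/sqrt(2)
        rows = two_condition_sheet([0, 1, 2], replicated=(1,))
        d = 0.7
        vals = {}
        for i in range(50):
            base = float(i)
            # order: ctrl t0, t1 r1, t1 r2, t2 | stim t0, t1 r1, t1 r2, t2
            vals[f"G{i:03d}"] = [base, base, base + d, base] * 2
        exp = make_experiment(vals, rows)
        nm = build_noise_model(exp, min_group_size=25)
        assert np.allclose(nm.thresholds, d / np.sqrt(2))

    def test_threshold_monotone_under_added_high_variance_gene(self):
        rng = np.random.default_rng(2)
        exp = experiment_with_sds(200, rng, sd=0.5)
        nm = build_noise_model(exp, min_group_size=200)
        wild = exp.values.iloc[0] + rng.normal(0, 25, exp.values.shape[1])
        exp2 = make_experiment(
            {**{g: exp.values.loc[g].to_numpy() for g in exp.features}, "WILD": wild.to_numpy()},
            list(zip(exp.samples.index, exp.samples["time"], exp.samples["condition"], exp.samples["replicate"])),
        )
        nm2 = build_noise_model(exp2, min_group_size=201)
        assert nm2.thresholds[0] >= nm.thresholds[0]

    def test_unreplicated_design_marks_model_unavailable(self):
        rng = np.random.default_rng(3)
        rows = two_condition_sheet([0, 1, 2])
        exp = make_experiment({f"G{i}": rng.normal(size=6) for i in range(10)}, rows)
        nm = build_noise_model(exp)
        assert not nm.available
        with pytest.raises(ValueError, match="replicated"):
            peak_significant(1.0, "G0", nm)


class TestPeakSignificance:
    def make_model(self, threshold):
        return NoiseModel(
            available=True,
            thresholds=np.array([threshold]),
            group_of={"G": 0},
            n_replicated_cells=4,
            median_sd=pd.Series({"G": 0.0}),
        )

    def test_strictly_above_twice_threshold(self):
        nm = self.make_model(1.0)
        assert peak_significant(2.1, "G", nm) is True
        assert peak_significant(2.0, "G", nm) is False  # exactly 2x is not enough

    def test_planted_peaks_rank_above_null_genes(self, recovery_run):
        """The typical planted transient peak scores above the bulk (95th
        percentile) of the flat-gene peak distribution."""
        result, truth = recovery_run
        tab = result.table.sort_index()
        tr = truth.sort_index()
        planted = (tr["archetype"] == "transient_peak").to_numpy()
        flat = (tr["archetype"] == "flat").to_numpy()
        cutoff = np.quantile(tab["peak"].to_numpy()[flat], 0.95)
        assert np.median(tab["peak"].to_numpy()[planted]) > cutoff


class TestInstability:
    def build(self, target_sds, noise_sd=1.0):
        """50 background genes with replicate SD = noise_sd, one target gene
        whose three replicated cells have the requested SDs."""
        rows = two_condition_sheet([0, 1, 2], replicated=(0, 1, 2))[:12]  # ctrl only has 6... build manually
        rows = []
        for cond in ("ctrl", "stim"):
            for t in (0, 1, 2):
                reps = 2 if cond == "ctrl" else 1
                for r in range(1, reps + 1):
                    rows.append((f"{cond}_{t}_{r}", t, cond, r))
        vals = {}
        d = noise_sd * np.sqrt(2)
        for i in range(50):
            base = 5.0
            vals[f"G{i:03d}"] = [base, base + d, base, base + d, base, base + d, base, base, base]
        target = [5.0, 5.0 + target_sds[0] * np.sqrt(2), 5.0,
                  5.0 + target_sds[1] * np.sqrt(2), 5.0, 5.0 + target_sds[2] * np.sqrt(2),
                  5.0, 5.0, 5.0]
        vals["TARGET"] = target
        return make_experiment(vals, rows)

    def test_median_replicate_sd_above_twice_threshold_flags(self):
        exp = self.build([3.0, 3.0, 0.1])
        nm = build_noise_model(exp, min_group_size=51)
        assert nm.thresholds[0] == pytest.approx(1.0, rel=0.05)
        assert instability_flag(exp, "TARGET", nm) is True
        assert instability_flag(exp, "G000", nm) is False

    def test_perfect_replicates_not_flagged(self):
        exp = self.build([0.0, 0.0, 0.0])
        nm = build_noise_model(exp, min_group_size=51)
        assert instability_flag(exp, "TARGET", nm) is False

    def test_wildly_divergent_replicates_flagged(self):
        """Replicates far apart at every time point mark a likely false positive."""
        exp = self.build([8.0, 9.0, 10.0])
        nm = build_noise_model(exp, min_group_size=51)
        assert instability_flag(exp, "TARGET", nm) is True


class TestIntegralScore:
    def test_triangle_area(self):
        stim = curve([0, 1], [0, 1])
        ctrl = curve([0, 1], [0, 0])
        assert integral_score(stim, ctrl, (0, 1)) == pytest.approx(0.5)

    def test_crossing_handled_exactly(self):
        stim = curve([0, 2], [0, 2])       # g(t) = t
        ctrl = curve([0, 2], [1, -1])      # g(t) = 1 - t
        assert integral_score(stim, ctrl, (0, 2)) == pytest.approx(2.5)

    def test_identical_curves_zero(self):
        c1 = curve([0, 1, 3], [2, 5, 1])
        assert integral_score(c1, c1, (0, 3)) == 0.0

    def test_additivity_over_interior_split(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            k1 = np.concatenate([[0], np.sort(rng.choice(np.arange(1, 47, 0.5), 4, replace=False)), [48]])
            k2 = np.concatenate([[0], np.sort(rng.choice(np.arange(1, 47, 0.5), 2, replace=False)), [48]])
            c1 = curve(k1, rng.normal(0, 2, 6))
            c2 = curve(k2, rng.normal(0, 2, 4))
            a, c = 1.0, 40.0
            b = rng.uniform(a + 0.1, c - 0.1)
            left = integral_score(c1, c2, (a, b))
            right = integral_score(c1, c2, (b, c))
            whole = integral_score(c1, c2, (a, c))
            assert abs(left + right - whole) < 1e-9

    def test_matches_fine_grid_integration(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            k1 = np.sort(rng.choice(np.arange(0, 49, 0.25), 8, replace=False))
            k2 = np.sort(rng.choice(np.arange(0, 49, 0.25), 8, replace=False))
            c1 = curve(k1, rng.normal(0, 3, 8))
            c2 = curve(k2, rng.normal(0, 3, 8))
            a, b = 0.0, 48.0
            exact = integral_score(c1, c2, (a, b))
            grid = np.linspace(a, b, 100_001)
            approx = np.trapezoid(np.abs(c1(grid) - c2(grid)), grid)
            assert exact == pytest.approx(approx, rel=1e-6, abs=1e-9)

    def test_interval_outside_span_rejected(self):
        c1 = curve([0, 1], [0, 1])
        with pytest.raises(ValueError, match="outside"):
            integral_score(c1, c1, (5, 6))


class TestCombinedIntegral:
    def test_gene_at_mean_scores_zero(self):
        df = pd.DataFrame(
            {"early": [1, 2, 3], "intermediate": [10, 20, 30], "late": [5, 6, 7]},
            index=["a", "b", "c"],
        )
        assert combined_integral(df).loc["b"] == pytest.approx(0.0)

    def test_all_equal_scores_zero_via_zero_sd_rule(self):
        df = pd.DataFrame(
            {"early": [1, 1], "intermediate": [2, 2], "late": [3, 3]}, index=["a", "b"]
        )
        assert np.allclose(combined_integral(df), 0.0)

    def test_two_sd_above_mean_everywhere_scores_two(self):
        rng = np.random.default_rng(8)
        base = rng.normal(0, 1, 500)
        df = pd.DataFrame({
            "early": base, "intermediate": 3 * base + 1, "late": 0.5 * base - 2,
        }, index=[f"g{i}" for i in range(500)])
        mu, sd = base.mean(), base.std()
        df.loc["special"] = [mu + 2 * sd, 3 * (mu + 2 * sd) + 1, 0.5 * (mu + 2 * sd) - 2]
        out = combined_integral(df)
        assert out.loc["special"] == pytest.approx(2.0, rel=0.01)
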