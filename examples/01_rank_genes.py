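"""Rank genes by differential temporal expression on a simulated time course.

Builds a small stimulation experiment (irregular 0-48 h grid, duplicates at
4 of 10 time points, 10% of genes with planted responses), runs the full
scoring pipeline and prints the top of the consensus ranking.
"""

from ttca import AnalysisConfig, SimSpec, run_analysis, simulate

spec = SimSpec(
    n_genes=300,
    seed=7,
    fractions={
        "flat": 0.90,
        "slow_monotone": 0.05,
        "transient_peak": 0.05,
        "late_response": 0.0,
        "unstable": 0.0,
    },
)
exp, truth = simulate(spec)
result = run_analysis(exp, AnalysisConfig(min_group_size=150))

cols = ["rank", "dynamics", "peak", "integral_combined", "consensus", "consensus_p", "significant"]
top = result.table[cols].head(10).join(truth["archetype"])
print(top.to_string(float_format=lambda x: f"{x:.3f}"))
hits = truth.loc[result.table.index[:15], "is_differential"].sum()
print(f"\n{hits} of the top 15 genes carry a planted response (30 planted in total).")
print("dynamics > 1 means two per-condition fits beat one pooled fit;")
print("peak is the largest replicate-mean gap between conditions at a shared time;")
print("consensus in [0, 1] is the min-max normalised mean of the z-scored constituents.")
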