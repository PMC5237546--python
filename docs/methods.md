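# Methods

This note records the model behind each score, the numerical choices made
where the design was genuinely open, what the synthetic-data generator
does and does not emulate, and the known limitations.

## Data model

An experiment is a features × samples matrix of normalised, log-scale-like
expression intensities plus a sample sheet assigning each sample a time
point in hours, a condition in {stim, ctrl} and a replicate index.  Every
(time, condition, replicate) triple must be unique; each condition needs
at least three distinct time points (the minimum for a spline fit).
Genes with any missing value are dropped rather than imputed — all scores
assume complete per-gene profiles, and imputation on sparse irregular
grids would have to invent exactly the dynamics the method is trying to
detect.  Condition labels are normalised case-insensitively through an
alias table (treatment/case/… → stim, control/reference/… → ctrl);
unrecognised pairs are assigned by sample-sheet order and the mapping is
logged.

Single-condition designs (e.g. two-channel ratios) get a synthesised
constant control: one control pseudo-sample per time point, each gene
constant at either its first-time-point value (`constant_first`; the mean
over replicates when the first point is replicated) or its overall mean
(`constant_mean`).  Inputs are assumed to be on the analysis scale
already; control synthesis does not transform them.

## Penalized median spline

Each time course is fitted with the continuous piecewise-linear `g`
minimising

    Σ_j w_j |y_j − g(t_j)| + λ · TV(g′),

where `TV(g′)` is the total variation of the slope — the sum of absolute
slope changes at interior knots, which for piecewise-linear `g` equals the
integrated absolute second derivative exactly.  Knots are the distinct
measurement times: on sparse designs there is no information between
samples, and free interior knots would only add degeneracy.  The problem
is a linear program (residual and slope-change magnitudes split into
positive parts) and is solved exactly with HiGHS; the constraint matrix is
cached per design because thousands of genes share one design.  Values are
median-centred before solving for conditioning; the problem is
translation-equivariant so the solution shifts back.

Numerical notes:

- The penalty is *added* to the loss.  A subtracted penalty would be
  unbounded below; the roughness term exists to avoid over-fitting, which
  only an added penalty does.
- λ defaults to 0.6, a constant calibrated for within-array standardised
  microarray intensities.  Quantile-regression software conventions for
  the absolute-loss scale and penalty boundary terms differ; this package
  fixes the objective exactly as written above and documents λ relative to
  it.
- Evaluation interpolates linearly between knots and extrapolates as a
  constant beyond the first/last knot, which keeps interval integrals
  finite and stable at the edges.
- Ties between multiple optimal `g` are broken by the solver's
  deterministic pivoting on a fixed problem ordering; downstream scores
  depend on residual sums, which are part of the optimal objective.
- Absolute loss makes the fit robust: a gross outlier is followed only
  when its time point is isolated enough that the slope-change cost per
  unit height stays below the point's loss weight; in densely sampled
  regions it is ignored entirely (see `examples/02_median_spline_fit.py`).

## Dynamics score

`D = ⟨Ω_H0, R_H0⟩ / (⟨Ω_stim, R_stim⟩ + ⟨Ω_ctrl, R_ctrl⟩)` compares one
pooled fit (null hypothesis: the stimulus changes nothing) against two
per-condition fits.  The weight vectors Ω implement three rules: replicates
at a time point share that point's unit weight; both conditions contribute
equal totals under the alternative even when sampled unequally; and both
the null and alternative vectors are rescaled to the same fixed total (the
number of distinct time points in the pooled design) so the ratio is not
biased by vector length.

The fits themselves use the replication weights (rule one) as loss
weights.  This is a deliberate design choice: with unweighted loss, the
pooled fit of two identical conditions sees every point twice, which
halves the penalty's relative strength and makes `D` drift below 1 for
genes with no effect.  With replication-weighted loss the pooled and
per-condition objectives coincide exactly when the conditions carry the
same data, giving the clean calibration `D = 1` for "no difference".

Degenerate cases: 0/0 (e.g. a constant gene) scores 1 — no evidence either
way; a zero denominator with positive numerator (perfect per-condition
fits that disagree) returns a sentinel replaced by the dataset's maximum
finite `D`, keeping such genes at the top without breaking the z-transform
with infinities.

## Peak score and noise model

`P` is the maximum absolute difference between replicate-mean expression
of the two conditions over *shared* time points only; no interpolation is
used, because the score is defined on measurements and interpolating into
gaps would manufacture peaks.  Significance uses an empirical noise model:
genes are sorted by mean expression and split into `floor(n/1000)`
contiguous strata (at least one; at least eight once the dataset reaches
8000 genes — for 1000–8000 genes the 1000-gene floor wins and fewer strata
are used), and each stratum's threshold is the 0.95 quantile of all
within-(time, condition) replicate standard deviations (ddof 1) of its
genes, pooled across cells and conditions.  A peak is significant when
`P` exceeds *strictly* twice the threshold.  When fewer than four
replicated measurement points exist the threshold rule is unavailable and
peak significance falls back to the distribution-based p-value like every
other score.

The instability flag fires when the median of a gene's replicate SDs
exceeds twice its stratum threshold; genes without replication are never
flagged (logged).  Note a structural consequence of quantile thresholds:
if a non-trivial fraction of genes is genuinely unstable, those genes
*are* the upper tail of the SD distribution and inflate the threshold for
everyone in their stratum — peak sensitivity on clean genes degrades
accordingly.  This is inherent to an empirical 0.95-quantile noise floor,
not an implementation artifact.

## Integral scores

`I = ∫_a^b |g_stim − g_ctrl| dt` is computed exactly for piecewise-linear
curves: both are evaluated on the union of their knots, the interval
endpoints and every crossing point of the difference, then the trapezium
rule is applied to |difference|.  The early/intermediate/late windows
default to the tertiles of the distinct time points *by index*, not by
clock time — on a geometric-like sampling grid clock-time tertiles would
put almost all points into "early".  Users can override the bounds.  The
combined integral `I_comb` is the mean of the three per-window z-scores; a
window with zero spread contributes zero for every gene (logged).

## Relevance score

`R = log(p)/log(p_max)` for publication count `p ≥ 1`, `R = 0` for `p = 0`
(the logarithm is left undefined there; zero is the natural "nothing
known" value), clipped to [0, 1].  Counts come from an offline two-column
table; a live literature-query client could be plugged in behind the same
interface but is not shipped — results must be reproducible offline.  If
`p_max < 2` the log base degenerates and all scores are zero (warned).

## Significance and consensus

Each score's observed distribution is its own null: permutation nulls are
unusable here because permuting time points merely relocates a sharp peak
without destroying it.  Seven families — Cauchy, gamma, log-normal,
logistic, normal, Poisson, Weibull — are fitted by maximum likelihood.
Positive-support families (gamma, log-normal, Weibull) are fitted with
location fixed at zero after shifting the data by `−min + 10⁻⁶·range` when
non-positive values occur; the shift is recorded and p-values are computed
on the original scale.  Poisson is fitted on rounded (shifted) values and
excluded when more than half the mass collapses onto one integer, since a
pseudo-discrete pile-up carries no tail information.  The
highest-log-likelihood family wins (the candidates have 1–2 parameters, so
likelihood and AIC order almost always agree; AICs are logged); ties break
by the canonical family order.  Fewer than 100 values triggers a normal
fallback; constant input yields a degenerate null under which every
p-value is 1.  P-values are one-sided upper tails, floored at 10⁻³⁰⁰.

Effect sizes express score magnitudes on the dataset's scale: peak and
instability effects divide by the detection range (max − min expression);
integral effects divide by range × window length (the maximal possible
area).

The consensus is the mean of the z-transformed dynamics, peak, combined
integral and relevance scores, min-max normalised to [0, 1].  The
relevance z-transform uses non-zero values only (the zero pile-up would
otherwise dominate mean and SD); zero-count genes are imputed one spread
unit below the smallest observed non-zero z.  Without a counts table the
consensus runs over the three remaining scores.  A consensus p-value is
obtained by fitting the same null machinery to the raw (pre-normalisation)
consensus distribution.  A gene is "significant" when at least two of the
four constituent scores are individually significant (dynamics, combined
integral and relevance at α = 0.05 on their p-values; peak via the
noise-threshold rule when available).  No multiple-testing correction is
applied to the reported p-values; a Benjamini–Hochberg column on the
consensus p-value is emitted additionally as a clearly separate extension.

Ranks order by consensus descending with ties broken by feature id, so
identical inputs give byte-identical output tables.

## Gene-set extension

Member genes are anchored at zero by subtracting each gene's value at its
earliest measured time point (replicate mean), so only expression *change*
matters.  Per group, condition and time point the pooled member values
form a band: mean, plus separate SDs for the points above (sd_u) and below
(sd_l) the mean — both computed around the band mean, not the side-subset
mean, so a one-sided expression shift shows up as an enlarged one-sided
SD.  A side with fewer than two points gets SD 0 (a singleton has no
spread estimate).  The minimal overlap score at a time point is the larger
of the two band gaps (control above stimulus, stimulus above control)
divided by the mean bandwidth; `Θ` is the maximum over shared time points.
Positive `Θ` means full separation somewhere; with an unreplicated shared
t = 0 both bands are anchored at (0, 0) there, so `Θ ≥ 0` by construction
and only clearly positive values are informative.  Zero bandwidth yields a
signed infinite (or zero) θ, logged.  Groups may overlap; no correction is
attempted for shared members.  Group-level dynamics/peak/integral scores
come from treating each group's per-condition mean profile as a
pseudo-gene; the group consensus omits relevance and the replicate noise
model (replicate scatter is not meaningful for an averaged pseudo-profile).

## Synthetic data

The generator emulates a stimulation time course on the irregular grid
0, 0.5, 1, 2, 4, 6, 8, 12, 24, 48 h with duplicates at 4 of the 10 points
(1, 4, 8, 24 h) in both arms — 28 samples.  Gene baselines are N(7, 1)
(log2-like), measurement noise is Gaussian with SD 0.25 by default
(homoscedastic; an optional mode scales noise with baseline to exercise
the stratified noise model).  Archetypes: `flat` (no effect),
`slow_monotone` (sigmoid rise in the stimulated arm, midpoint 15–27 h,
time constant 2.5–6 h, so the 10–90% transition lies inside 6–48 h),
`transient_peak` (a spike of amplitude `effect × noise SD` on 1–2
consecutive points, never at t = 0), `late_response` (a step after the
late-window bound) and `unstable` (no mean effect, replicate SD inflated
20-fold — clearly above the flag's 2×-threshold boundary even after the
threshold inflation its own presence causes).  The default mix is 90%
flat, 5% slow, 5% transient at effect 4 — the package's reference recovery
conditions; the unstable archetype is enabled explicitly for instability
studies.  An optional outlier process adds large displacements at a given
rate (off by default).  Everything derives from a single seed;
identical specs are byte-identical.

What passing tests on these data do *not* show: real arrays have
mean-dependent, non-Gaussian noise, batch effects, correlated genes and
probe-level artifacts; the generator's independence across genes makes
z-transforms and quantile thresholds better behaved than on real data.
Recovery numbers here characterise the scores under controlled conditions,
not expected performance on any particular platform.

## Problem sizes and defaults

Reference studies use 2000 genes (recovery, instability) and 5000 genes
(null calibration); with ~30 measurements per gene the three LP fits per
gene dominate the runtime (a few milliseconds per gene).  Key defaults:
λ = 0.6, sd quantile 0.95, stratum size ≥ 1000, peak and instability
factors 2.0, α = 0.05, interval bounds at time-point tertiles (2 h and 8 h
on the reference grid).

## Known limitations

- The dynamics and integral scores inherit the spline's stiffness: at
  λ = 0.6 a one-to-two-point transient is largely invisible to them, by
  design — the peak score exists for exactly that pattern.  Consequently
  the consensus for transient genes rests mostly on one constituent.
- At a planted amplitude of 4× the noise SD the strict 2×-quantile peak
  rule is a near coin flip per spike point (the threshold sits at
  ~3.9× noise for duplicate-based SDs), so its sensitivity plateaus in the
  60–80% range under the reference conditions; ranking-based detection is
  considerably stronger than the binary rule there.
- Empirical-null p-values are calibrated against the dataset's own score
  distribution; with a large fraction of truly differential genes the null
  is contaminated and p-values become conservative in the tail the signal
  occupies.
- Oscillatory dynamics are out of scope; dedicated periodicity methods
  should be used for those.
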