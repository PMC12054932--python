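# Methods

## Model and assumptions

Both count methods estimate the concentration of a target specimen type
from its ratio to exotic markers of known total quantity. The
statistical model treats targets and markers as independent homogeneous
Poisson point processes over the study surface (equivalently, specimens
scattered independently and uniformly). Under that model:

* every raw count (targets x, markers n, per-field-of-view counts) is a
  Poisson/binomial variate, so its squared proportional standard error
  is `1/count`;
* the marker spike adds a count-independent variance term
  `T = s1P²/N1`, where `s1P` is the proportional SD of markers per dose
  and `N1` the number of doses (the dose statistics are taken as quoted
  by the supplier; no small-sample correction is applied to them);
* for the FOVS method the common specimen's error term is the empirical
  between-field variance of the calibration mean. The sample SD is
  divided by the c4 factor, `c4(n) = √(2/(n−1))·Γ(n/2)/Γ((n−1)/2)`,
  because E[s] = c4·σ under normality and calibration counts are small
  (typically 11–17 fields of view).

The two total-error models, in percent of the concentration, are

    σ_L = 100·√(T + 1/x + 1/n)
    σ_F = 100·√(T + s3P²/N3C + 1/n)

Effort is a time proxy: one unit per specimen identified plus ω units
per field-of-view transition. ω defaults to 2 (measured microscope
trials put a transition at roughly twice one identification); it is a
per-observer parameter. An optional effort-asymmetry factor ≥ 1 scales
target identifications for high-taxonomic-resolution work; it defaults
to 1 (targets and markers equally fast to identify).

## Design calculus

Writing û for the common-to-rare ratio and Ȳ3x for the common density
per field of view, the linear effort is `e_L = A·x` with
`A = ω/Ȳ3x + 1 + 1/û`, giving

    σ_L(e) = 100·√(T + (1+û)·A/e).

The FOVS error as a function of (N3C, N3E) uses the Poisson
approximation for the calibration term — justified because per-field
counts are Poisson under the scatter model and the optimum is rounded to
integers anyway:

    σ_F(N3C, N3E) = 100·√(T + 1/(N3C·Ȳ3x) + û/(N3E·Ȳ3x)).

Setting the derivative along the fixed-effort line to zero yields the
optimal allocation

    N3C* = e / (ω + Ȳ3x + √((ω+Ȳ3x)(ωû+Ȳ3x)))
    N3E* = e·û / (ωû + Ȳ3x + √((ω+Ȳ3x)(ωû+Ȳ3x)))
    δ*   = N3E*/N3C* = û·√((ω+Ȳ3x)/(ωû+Ȳ3x)),

an error-versus-effort curve σ_F(e) of the same `1/√e` shape as the
linear one, and exact closed-form inverses for the effort (or
field-of-view counts) needed to reach a target error. Equating
σ_L and σ_F at equal effort gives a quadratic dividing line whose
positive root is the critical density

    Ȳ3x* = 2ω·(û² + √(û³(1+û(û−1)))) / ((û+1)(û−1)²),

infinite at û = 1 (the linear method is then always marginally better)
and strictly decreasing in û. The method-determination rule recommends
the FOVS method iff the observed density exceeds Ȳ3x*; exact ties
resolve to the linear method, which needs no extra conditions (marker
contrast, matched count regions).

Numerical choices: planned field-of-view counts are rounded half away
from zero with a floor of one, which reproduces all published allocation
pairs and is confirmed integer-optimal by an exhaustive search oracle in
the tests. All formulas assume û ≥ 1 (targets common); marker-common
assemblages are handled by an explicit role swap (û → 1/û, density read
against markers per field of view), and the primal entry points refuse
û < 1 rather than silently mis-orienting the asymmetric effort terms.

## The simulator: what it emulates and what it does not

`SimConfig` defaults encode the validation conditions: 30 000 targets
scattered uniformly on a unit square, a 33 × 33 grid of half-open
field-of-view cells (1089 non-overlapping fields of view), ω = 2, an
exactly known spike (T = 0), and marker totals varied between runs to
set the true ratio. The linear window is a bottom-anchored horizontal
strip swept left to right until the pre-set target count; its height in
field-of-view rows is configurable (one row holds ≈ 909 targets in
expectation, so scenarios with pre-set counts near 900 use two rows).
The FOVS replicate samples disjoint calibration and extrapolation cell
sets uniformly without replacement; the half-open cells implement the
margin rule (count one side of each boundary) with no double counting.
The finite-population correction √((N−n)/(N−1)) multiplies the
calibration standard-error term, since up to a third of a finite grid
may be sampled.

The default engine samples the sufficient statistics of this geometry
directly — multinomial per-cell counts, binomial region counts, and a
Beta order statistic for the window length — which is distributionally
exact and roughly three orders of magnitude faster than scattering
coordinates; the coordinate engine remains available (`engine="area"`)
and the suite checks the two agree. Iteration counts of 1e4–1e5 are used
throughout the tests; the experiments this emulates used 1e6, and the
config accepts any count.

Ratio estimators of the form x·K/n are biased upward by a factor
≈ 1 + CV²(n); with marker counts as low as 15 per window this bias
reaches several percent and would dominate any accuracy assessment. The
simulator therefore reports, alongside the textbook ratios, Chapman-type
mean-unbiased variants — `(x−1)(K+1)/(n+1)` for the stop-at-x window and
`x̂(K+1)/(n+1)` for the FOVS ratio — which are exactly unbiased under
the sampling model (up to a truncation term below 1e-6) and are used in
the summary statistics by default (`bias_correction=False` restores the
raw ratios, excluding zero-marker replicates, which are undefined, and
reporting their rate). The "empirical error" of a summary is the RMS
relative deviation of the estimates from the known truth, in percent.

What passing simulations do **not** show about real data: real slides
violate the uniform-scatter assumption (clumping, edge effects, density
gradients), so the calibration variance s3 on real material absorbs
spatial heterogeneity that the simulator never generates; identification
error, marker/target behavioural differences during preparation, and
non-constant ω are likewise outside the model. Heterogeneous point
processes are deliberately out of scope.

## Confidence intervals

The published parametric interval construction for marker-based
concentrations is summarised only in supplementary material not
available here; the package instead reports a documented
normal-approximation interval `c·(1 ± z·σ/100)` (default z for 95%),
floored at zero, and labels it as such. For the count sizes these
methods target (hundreds of specimens) the normal approximation is
adequate; at very small marker counts it will undercover.

## Known limitations

* Spatial heterogeneity is not modelled; the simulator's uniform
  scatter is the best case for the FOVS method's calibration variance.
* The linear-method error model is known (and shown in the tests) to
  drift from the empirical error of the raw ratio estimator at high
  û, where marker counts are tiny; the FOVS error estimate remains
  within ~10% of empirical for û ≤ 30 under the study conditions.
* Multiple simultaneous targets are supported only by repeated
  single-target calls; no joint optimisation is attempted.
* The supplementary spreadsheet reader maps column headers
  heuristically and tolerates derived columns; unusual layouts need an
  explicit column map.
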