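# fovcount

Absolute abundance estimation with exotic markers: the classical
**linear** count method, the **field-of-view subsampling (FOVS)** method,
the closed-form sampling-design calculus that chooses between them, and a
Monte Carlo simulator of virtual study areas that validates all of it.

## The problem

Many questions in palynology, micropalaeontology, cell counting and
ecology need *absolute* abundances — specimens per gram, millilitre or
square centimetre — rather than proportions. The exotic-marker technique
gets there by spiking each sample with a known quantity of distinctive
markers (classically *Lycopodium clavatum* spores in tablets) before
preparation: the ratio of indigenous *targets* (x) to counted *markers*
(n) then converts directly into a concentration,

```
c = x · N1 · Ȳ1 / (n · V̄)
```

where `N1` doses of `Ȳ1` markers each were added to a sample of total
size `V̄`. The traditional (linear) protocol tallies targets and markers
jointly in one contiguous window until a pre-set count is reached, with
total standard error (in %)

```
σ_L = 100 · √( T + 1/x + 1/n ),      T = s1P² / N1
```

(`T` is the marker-dose variance contribution; both count terms are
Poisson). When targets greatly outnumber markers (ratio û = x/n ≫ 1) the
linear method wastes nearly all its effort on targets while precision is
throttled by the few markers seen.

The FOVS method splits counting into two stages: **calibration counts**
measure the mean Ȳ₃ and SD s₃ of the common specimen over N₃C microscope
fields of view, then **extrapolation counts** rapidly scan N₃E further
fields of view for the rare specimen only. The common count is
extrapolated as `x̂ = Ȳ₃ₓ · N₃E` and

```
c_F = x̂ · N1 · Ȳ1 / (n · V̄),
σ_F = 100 · √( T + s₃P²/N₃C + 1/n ),   s₃P = s₃ / (c₄(N₃C) · Ȳ₃ₓ)
```

with the small-sample c₄ correction de-biassing the proportional SD.

Counting effort is modelled in time units — one per specimen identified
plus ω per field-of-view transition (ω ≈ 2 in microscope trials). From
(û, Ȳ₃ₓ, ω, T) the `design` module derives error-versus-effort curves for
both methods, the optimal split of a FOVS budget
(δ\* = N₃E\*/N₃C\* = û·√((ω+Ȳ₃ₓ)/(ωû+Ȳ₃ₓ))), the critical density Ȳ₃ₓ\*
above which the FOVS method wins, and the effort needed for any target
error.

## Worked example

An assemblage shows roughly 27 targets per field of view and about ten
targets for every marker (û ≈ 10); transitions cost about twice a
specimen identification (ω = 2), and the spike error is negligible.

```python
from fovcount import DesignPoint, choose_method, optimal_allocation

dp = DesignPoint(u_hat=10.0, density=27.0, omega=2.0)
mc = choose_method(dp)
# critical density 1.8032 targets/FOV; observed 27 >> 1.80 -> "fovs"
# error ratio sigma_L/sigma_F = 1.526 at equal effort

alloc = optimal_allocation(dp, effort=1000.0)
# N3C* = 15 calibration and N3E* = 119 extrapolation fields of view
# (delta* = 7.855): at 1000 effort units sigma_F = 7.45% vs sigma_L = 11.36%
```

The printed numbers mean: for this assemblage the FOVS method is the
efficient choice (its error at matched effort is 1.5× smaller), and a
1000-unit budget is best spent as 15 calibration plus 119 extrapolation
fields of view. The simulator confirms this on synthetic study areas:

```python
from fovcount import SimConfig, run_experiment

res = run_experiment(SimConfig(n_targets=30_000, n_markers=3_000,
                               x_stop=852, iterations=100_000, seed=11,
                               window_height_fovs=2))
# allocation (15, 119); mean estimates 29987 (linear) and 30008 (FOVS)
# against a true 30000; empirical errors 11.35% vs 7.18%, estimated
# errors 11.41% vs 7.42%; mean efforts 999 vs 1009 units
```

Both estimators recover the truth; the FOVS method is markedly more
precise at the same effort and its error estimate tracks the empirical
spread closely.

A CLI mirrors the library:

```bash
fovcount design choose --u 10 --density 27
fovcount design allocate --u 10 --density 27 --effort 1000
fovcount estimate --linear counts.csv --calibration cal.csv --extrapolation ext.csv
fovcount simulate sim.yaml --seed 1
fovcount fixtures sim.yaml --seed 1 --outdir fixtures/
```

See `docs/methods.md` for the model, its assumptions and the numerical
choices.

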