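# Methods

## The model

`stochclock` studies a deliberately minimal model of aging data: a
per-feature *ground state* at age zero, plus accumulating random
variation.  Nothing in the generative process encodes age directly —
samples of simulated age *a* receive *a* independent noise applications
— yet an elastic-net regression trained on such data predicts the age
of independent samples.  The package provides the generators, the clock
machinery, and the evaluation harness to quantify when and why that
works.

### Bulk simulations

A sample of age *a* is

    x = bound( ground + jitter + e_1 + ... + e_a ),

with `jitter ~ N(0, baseline_sd²)` drawn once per sample (inter-sample
biological variation, default `baseline_sd = 0.01`) and each
`e_i ~ N(0, per_step_sd²)` i.i.d. per feature.  Three bounding rules:

* **clamped** — values are clipped to [0, 1] after *every* addition;
* **logit** — jitter and noise are added in logit space and the result
  mapped back through the inverse logit (values are then bounded by
  construction);
* **unbounded** — no bounding; the negative control.

The age signal is regression to the mean: a clipped (or
sigmoid-squashed) symmetric noise process has expected drift toward the
middle of the range, with magnitude and direction set by the feature's
starting value.  Features near 0 acquire positive elastic-net weights,
features near 1 negative ones; unbounded noise has zero expected drift
and supports no clock.

Clamping is applied per step, not once at the end.  The additions are
sequential independent applications and the boundary interaction is the
signal source; a single terminal clamp is a different (censored-
Gaussian) model and is available for comparison via
`NoiseConfig(terminal_clamp=True)`.  The per-step rule also reproduces
the package's small-σ benchmark (median validation R² ≈ 0.79 at
σ = 0.005, which `scripts/acceptance.py` recomputes), while the
terminal rule does not.

**Default σ.**  Validation accuracy is robust over a range (plateau) of
per-step σ, falling off when σ is so small that drift drowns in the
baseline jitter and when σ is so large that the clamped walk mixes to
its stationary law well before the maximum age (mixing time is roughly
σ⁻² steps; the stationary law is uniform on the interior of [0, 1] with
point masses at the bounds).  The package's σ-sweep locates the clamped
plateau around σ ≈ 0.02–0.05 and the logit plateau around σ ≈ 0.2 over
a 100-step lifespan — logit-space accumulation needs a larger σ because
the sigmoid's slope dilutes noise near the boundaries.  The headline
defaults are fixed once at σ = 0.05 (clamped) and σ = 0.2 (logit).

### Single-cell DNA-methylation simulations

Each CpG site is a population of `n_cells` (default 1000) binary cells
initialized by rounding the ground-state beta half-up
(0.13 → 130 of 1000 methylated).  Per time-step every methylated cell
stays methylated with probability E_m and every unmethylated cell gains
methylation with probability E_d (E_u = 1 − E_d).  The methylated count
is advanced with the exact aggregate law

    count' ~ Binomial(count, E_m) + Binomial(n_cells − count, E_d),

which is distributionally identical to per-cell coin flips (cells are
exchangeable) and ~n_cells-fold cheaper; the test suite keeps an
explicit per-cell Bernoulli implementation as the independent oracle
and checks distributional equivalence on small populations.

The expected beta obeys `E[b'] = b·E_m + (1 − b)·E_d`, converging
geometrically (factor E_m − E_d) to the equilibrium
`M_eq = E_d / (1 + E_d − E_m)`; E_m = 1, E_d = 0 is flagged as
perfectly maintained (no unique equilibrium) rather than given a
number.  Rates may be *universal* (one value for all sites; by
convention E_u = E_m, so symmetric rates equilibrate at 0.5), *random*
within validity limits, or *estimated* from data: the oldest sample's
betas are taken as the site equilibria, one rate is drawn uniformly
inside its limits and the other solved from the equilibrium equation,
redrawing (up to 1000 times, then a per-feature error) until both rates
are admissible.  E_m is fixed by default; both directions are exposed.
M_eq ∈ {0, 1} short-circuits to E_d = 0 / E_m = 1.  The oldest-sample
assumption is an acknowledged approximation — old sites need not have
converged — and no correction is attempted.

Validity limits: default 95% < E_m ≤ 100%, 0% ≤ E_d < 23% (the span of
published maintenance-rate estimates); a narrower "improved" set
97% < E_m ≤ 100%, 0% ≤ E_d < 5% is provided as
`IMPROVED_LIMITS`.

Every sample restarts its populations from the ground state and
advances `age` steps on its own RNG stream, mirroring the bulk design's
independent samples (one sample per age 0–99 per replicate set).

### Gillespie variant

The event-based variant replaces discrete steps with two reactions per
site — unmethylated→methylated at rate 0.1 per cell and the reverse at
0.1 — drawing exponential waiting times from the total propensity until
`tmax = 5` or `nrmax = 8000` events (truncation warns and freezes the
trajectory).  States are recorded on an even grid of observation times
including 0 and tmax (count configurable), and observation times are
min–max rescaled to the reporting age range (a monotone rescaling that
leaves correlations untouched; dataset ages are therefore nonnegative
reals here, while step-based generators always emit integer ages).

### Clocks and transforms

Clock fitting is sklearn `ElasticNetCV` with l1_ratio grid 0.1–0.9,
automatic alpha grid (pinnable, e.g. `alphas=[1]` for the human-style
configuration), 5-fold CV with a fixed seed, `max_iter = 5000`.
Sparsity (exact zeros) is expected and reported.  Optional invertible
age transforms: min–max to [0, 1] then ×400 − 120 (human-year-like
range; min/max fit on training ages and stored in the model), a
constant ×k rescaling (k = 2 for the transcriptomic configuration), and
the relative-age double-log transform −log(−log(age/max_age)) with
inverse exp(−exp(−x)) returning relative age in (0, 1); relative ages
are clipped to [1e−6, 1 − 1e−6] before the double log.  Published
coefficient tables load into the same model type (TSV/CSV of feature id
and coefficient, optional intercept and transform rows; a missing
intercept warns and assumes 0).

### Preprocessing

*Binarization*: per sample, log10(count + 1), min–max normalize over
genes, drop genes zero in all samples, median over zero-masked values,
strictly-greater-than-median → 1, everything else (ties, zeros) → 0.
Min–max is per sample; the zero mask applies only to the median.
*Cell-type adjustment*: per CpG, least-squares projection of betas on
the fraction matrix (with intercept); adjusted value = feature mean +
residual, clipped to [0, 1].  Means are preserved exactly before
clipping; a rank-deficient fraction matrix degrades to the
intercept-only projection (betas unchanged) rather than erroring.
*Covariate regressions*: plain OLS (statsmodels) with explicit
interaction columns and two-sided t-based p-values; rank-deficient
designs error.

### Evaluation

R² is the out-of-sample coefficient of determination
(1 − SS_res/SS_tot of predictions against truth) and may be negative;
it is never the squared correlation.  Permutation controls shuffle ages
against fixed predictions.  The sweep harness runs any experiment over
a parameter grid with per-value replicate counts and seeds spawned from
one root (boxplot summaries: median, quartiles, 1.5×IQR).

## Benchmark problem sizes

The registered benchmarks run the full published designs: 2000-feature
bulk experiments with 6×100 samples (3 train / 3 validation sets), and
single-cell experiments at 500 features × 1000 cells (2000 features for
the equilibrium-start configuration, 32 for the feature-plateau point).
Medians are over 3 independent repeats with different ground states
(10 at 32 features).  The feature-sweep benchmarks evaluate the
registered plateau grid point; the full 8–4096 grid runs through the
same sweep harness when wanted.

## What the generators do and do not emulate

The synthetic ground states are uniform (bulk) or uniform/constant
betas (single-cell); the beta-matrix fixture adds the empirically
observed structure of methylation arrays — bimodal betas with
between-sample variance shrinking toward the 0/1 extremes — plus a
young/old sample pair produced by the forward simulator so rate
estimation has a self-consistent target.  Not emulated: feature–feature
correlation (noise is i.i.d. per feature), non-normal noise families,
hemimethylation or allele-resolved states, array measurement error, and
batch structure.  Passing benchmarks therefore show that bounded
stochastic drift suffices to build clocks *in this model class*; they
do not show that biological clocks measure nothing else.

## Numerical choices

* Logit guard: values clipped to [1e−6, 1 − 1e−6] before `logit`
  (uniform ground states never hit 0/1; binarized or biological ones
  do).
* Rounding in population initialization: half-up, at most one cell per
  site.
* Rate estimation: tolerance of the equilibrium round trip is exact to
  ~1e−12 (pure algebra); redraw budget 1000 per site.
* RNG discipline: one root seed expands via `SeedSequence.spawn` to
  per-sample streams, so any replicate set is reproducible in
  isolation; CLI runs write a manifest (config, seed, versions).
* Elastic-net convergence warnings at very low-variance designs are
  suppressed in training; `max_iter = 5000` keeps duality gaps small.

## Known limitations

* Exact scale equivariance of training holds at the lasso end of the
  elastic-net family (with the penalty rescaled); the quadratic penalty
  term scales differently, so mixed l1_ratio fits are only
  approximately equivariant.
* At very high maintenance (E_m = E_u = 99.995%) the per-feature
  drift-to-noise ratio is near 1 and measured validation R² is
  sensitive to design details (independent-restart vs shared-trajectory
  sampling differ visibly there and nowhere else).
* The Gillespie variant records one trajectory per site per replicate
  set; its observation times, not event times, define the age grid.
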