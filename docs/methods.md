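# Methods notes

## Model and estimation

The package estimates time-varying MVAR coefficients for multi-trial,
multichannel signals. At each sample `t ≥ p` a lagged design matrix `H_t`
(trials × `d·p`, lag-major column blocks: all senders at lag 1, then lag 2,
…) and a present-sample matrix `z_t` (trials × `d`) are formed; all trials
enter one regression jointly. The latent coefficient state follows a random
walk — the transition matrix is the identity and is never materialized —
and the recursive update is a convex combination of the previous state and
a per-time measurement estimate, weighted by an adaptation constant `c_t`.

The measurement estimate uses a *damped pseudoinverse*: the SVD of `H_t`
with the smallest trailing set of singular values set to zero so the
retained cumulative squared singular values reach a fraction `f` of the
total. Singular values tied with the last retained one are also kept, so
isotropic designs (e.g. an identity design) are never truncated. `f`
defaults to 0.99, appropriate for low-dimensional, well-conditioned
recordings; around 0.9 is a better choice for high-dimensional source-space
data where volume conduction makes the design strongly collinear.

The structurally informed variant solves, per receiver `i`, a generalized
Tikhonov system `(H̃ᵀH̃ + Q⁻¹_i) b = H̃ᵀ z_i` built from the *same* damped
factorization (`H̃ᵀH̃ = V S̃² Vᵀ`), by Cholesky factorization — the matrix
is symmetric positive definite because every precision entry is strictly
positive. The general form with a nonzero prior mean `x0` is implemented,
but the default (and the only mode used by the pipeline) is `x0 = 0`: the
prior expectation is no functional connectivity.

### Assumptions

- Linear, directed, lag-based statistical dependence (Granger-style
  "effects", not biophysical mechanisms).
- Innovations are zero-mean white noise; trials are exchangeable
  realizations of the same time-locked process.
- Structure constrains function: a direct functional influence is most
  plausible where an anatomical connection exists. The prior enters as a
  variance, never as a mask, so the data can override it in either
  direction.

## Structural priors

A raw nonnegative SC matrix is oriented receiver ← sender, its diagonal
overwritten with a chosen self-connection value *before* normalization by
the global maximum (matching the convention of ranked tracer connectomes,
where self-connections get the top rank). Normalized weights in [0, 1] are
then mapped linearly to prior variances in `[lo, hi]`:

- `lo = 1e-4` (default): the variance assigned to *absent* SC. Strictly
  positive so the precision stays finite — absent structure means strong
  shrinkage, not exclusion.
- `hi = 0.1` (default): the variance of the strongest connection. Larger
  values weaken regularization toward the uninformed filter; smaller values
  shrink everything. `sweep_scaling_max` reports, per candidate `hi`, the
  Spearman correlation between SC and time-averaged MDI (how much the prior
  imprints on the estimate) and the Pearson correlation between informed
  and uninformed estimates (how much it distorts them); the choice is left
  to the user and no automatic selection is performed.

The map is linear because nothing stronger is warranted by the inputs
(tracer ranks are ordinal); a log-spaced option exists for priors spanning
orders of magnitude. The SC value of a node pair is replicated across all
`p` lags — priors are defined per connection, not per lag.

## Self-tuning adaptation constant

The filter's speed constant is `c_t = clip(c_base · e_t / ē_t, c_min,
c_max)` with `e_t` the mean squared one-step innovation against the prior
state and `ē_t` its exponential moving average (half-life 10 samples by
default; `c_base = 0.05`, bounds `1e-3` and `1`). The rule speeds the filter
up exactly when residuals grow relative to their recent history — at abrupt
dynamic changes — and slows it down in stationary stretches. A fixed-`c`
mode is provided; its algebraic limits (`c = 0` freezes the state, `c → ∞`
yields the pure per-time least-squares estimate) are tested. The precise
functional form of the rule is a design choice of this package, honoring
the contract that the constant be driven by the filter's own residuals; it
is deliberately replaceable.

## Directed-influence metrics

`MDI_{i←j,t}` is the root-sum-square of the `p` lag coefficients (default);
a sum-of-squares mode is exposed and the choice is recorded in the output.
Outflow sums and proportional adjacencies exclude the diagonal. Proportional
thresholding keeps the top `⌈keep · count⌉` off-diagonal entries and retains
all values tied with the cutoff. Consistency between a perturbed and a
reference adjacency is the intersection size over the reference edge count;
it errors when the two adjacencies retain different edge counts (different
keep conventions are not comparable), and a Jaccard option is available.

The group permutation test flips the sign of each subject's condition
difference, rebuilds the group mean, and reports two-sided p-values as
`min(1, 2·min(p_hi, p_lo))` with the add-one correction
`(1 + count)/(1 + n_perm)` so p-values are never zero. Each edge/time entry
is tested separately and no multiple-comparison correction is applied by
default. Exhaustive enumeration over all `2^S` sign patterns is available
for small groups and uses raw proportions (the identity pattern is always
included).

## Simulator and benchmark

The simulator realizes stable piecewise-constant tv-MVAR schedules
(companion-matrix spectral radius checked strictly below 1 at
construction), with Gaussian innovations and a discarded burn-in under the
first scheduled tensor. The default evoked-like scenario is a 5-node
AR(2) baseline (self-coefficients 0.5 and −0.2) in which a designated
driver node sends three lag-1 influences of strength 0.35 during a window
(samples 80–160 of 200), plus one secondary edge between non-driver nodes
— an abrupt engagement and release of a small directed subnetwork, giving
a defined peak-latency analog. Defaults of 40 trials and 200 samples keep a
full 30-iteration, six-ratio benchmark in the tens of seconds on one CPU;
coefficient-recovery runs use 100 trials and 300 samples.

Noise perturbation is a convex mixture `(1−r)·signal + r·noise` with
Gaussian noise whose standard deviation equals the 95th percentile of the
absolute data values ("amplitude" read as the noise standard deviation;
both the percentile and the distribution are configurable). The benchmark
fits each filter on the clean data once (baseline), then refits on each
noisy redraw and scores (a) consistency of the thresholded peak-latency
network against that filter's own zero-noise adjacency and (b) the driver
score of the designated node. The same noise realization is fed to both
filters at a given ratio/iteration. Zero-noise consistency is 1 by
construction.

The simulator emulates trial-locked nonstationary network dynamics at the
node-signal level. It does **not** emulate volume conduction or leadfield
mixing, 1/f spectra, between-trial latency jitter, or nonlinearity — so
passing tests demonstrate correctness and the claimed relative advantages
of the informed filter under the stated noise model, not performance on
raw scalp recordings.

## Evaluation conventions (open design choices)

- **Noise-robustness RMSE.** Under heavy mixed noise every least-squares
  estimate is attenuation-biased toward zero; absolute closeness to the
  generating coefficients is then dominated by that shared bias and slightly
  *penalizes* any additional shrinkage. The package therefore scores noise
  robustness as the distance between the noisy-data estimate and the same
  filter's zero-noise estimate — the zero-noise fit is the baseline
  throughout the benchmark — while absolute recovery is asserted on clean
  data only.
- **False-positive robustness.** "A strong structural prior must not
  inflate an unsupported connection" is evaluated against the uninformed
  filter's null-edge distribution: the promoted edge's informed estimate
  must not exceed the 95th percentile of what the uninformed filter
  attributes to no-FC edges on the same data. Comparing it with the
  informed filter's *other* null edges would be vacuous — they are shrunk
  by construction.
- **Ties.** Thresholding operations retain all values tied with the cutoff;
  ranked outflows break ties by node label.
- **Validity margin.** Estimates are undefined (NaN) for the first `p`
  samples rather than padded; every summary respects `valid_from`.

## Known limitations

- The coefficient state is estimated jointly across trials; the method
  needs multiple trials (or long stationary stretches) to condition the
  per-time regressions.
- Regularization strength is relative to the scale of `H̃ᵀH̃`, hence to
  trial count and signal variance; the scaling range that "produces clear
  effects" is data-dependent, which is exactly why `sweep_scaling_max`
  exists.
- Model order is a user input; no order-selection criterion is provided.
- The permutation test assumes subject exchangeability under the null and
  tests each edge/time point marginally.
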