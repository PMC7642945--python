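# Methods

## The threshold model and its MAP estimator

The package fits the cumulative probit ("threshold") model for an ordinal
response `y_i ∈ {1..C}` observed on records of a multi-environment trial.  A
latent liability `l_i = −η_i + ε_i`, with linear predictor `η_i = x_iᵀβ` and
standard-normal residual, falls between ordered cut-points
`−∞ = γ₀ < γ₁ < … < γ_C = ∞`, so

    P(y_i = c) = Φ(γ_c + η_i) − Φ(γ_{c−1} + η_i).

Priors are flat on the cut-points, `β_j | σβ² ~ N(0, σβ²)` with one common
variance for all penalised columns, and `σβ² ~ Scaled-Inv-χ²(v_β, S_β)`.
Design blocks can be flagged unpenalised, in which case their coefficients
take the flat-prior (unridged) update and are excluded from the variance
update; with `PriorSpec(flat=True)` the whole model becomes ordinal-probit
maximum likelihood.

Estimation maximises the log posterior by expectation–conditional
maximisation.  The thresholds are reparameterised as increments `δ₁ = γ₁`,
`δ_c = γ_c − γ_{c−1}` for `c = 2..C−1`, with the notational constant
`δ_C ≡ 1` (never estimated), converting the ordering constraint into
positivity of the interior increments; `δ₁` is unrestricted in sign.  Each
record's latent variable is mapped to a *working* variable whose conditional
distribution given `y_i` and the current parameters is truncated normal:

* `y_i = 1`: `N(−(η_i + δ₁), 1)` on `(−∞, 0)`;
* `y_i = c`, `2 ≤ c ≤ C−1`: `N(−(η_i + γ_{c−1})/δ_c, (1/δ_c)²)` on `(0, 1)`;
* `y_i = C`: `N(−(η_i + γ_{C−1}), 1)` on `(0, ∞)`.

The E-step computes each record's truncated mean `l*` and variance `l**`;
the CM-steps maximise the expected complete-data log posterior one
coordinate at a time, in the order `δ₁`, `δ₂..δ_{C−1}`, `β₁..β_p`, `σβ²`,
each step using the freshest values from the preceding ones.  All four
updates are closed forms: `δ₁` is a sample average; each interior `δ_k` is
the positive root of a quadratic `a δ_k² + b δ_k − n_k = 0`, guaranteeing
positivity as long as category `k` is observed; each `β_j` is a ridge
(or unridged) coordinate update; and `σβ² = (S_β + βᵀβ)/(2 + v_β + p)`.
Because each step maximises the same minorising objective, the observed log
posterior never decreases — the test suite asserts this to 1e−10 and checks
every update against a one-dimensional numerical maximiser of the
Q-function to 1e−6.

Two readings of the working-variable distribution in the source material are
ambiguous; we adopt the versions consistent with the complete-data
likelihood: the lowest category truncates on `(−∞, 0)` (not `(−∞, δ₁)`),
and the interior categories use *standard deviation* `1/δ_c` (not variance).
Under either alternative reading the printed Q-function would not be the
correct conditional expectation.

## Genomic design

Markers are standardised per column (centre, unit population SD);
monomorphic columns are dropped and `q` is the retained count.  The genomic
relationship matrix is `G = WWᵀ/q`; its symmetric PSD square root (eigen
decomposition, eigenvalues below 1e−10 clamped to zero — duplicated lines
make G rank-deficient) post-multiplies the line-incidence matrix so that a
ridge prior on the resulting G-block coefficients induces the GBLUP
covariance `σβ² G` on the line effects.  The GE block is the row-wise
(face-splitting) product of the E and G blocks, whose implied kernel is the
Hadamard product of the two kernels; A (pedigree) and Rep (replicate) blocks
and their interactions are built analogously.  No intercept column is
included: the location of the liability scale belongs to the thresholds.

## Prior elicitation

With `msq = tr(XXᵀ)/n` the average latent variance is
`Vl = msq·σβ² + 1`.  Assigning a proportion `1−R²` of `Vl` to the predictor
gives the prior mean `E(σβ²) = (1−R²)·Vl/msq` and the scale
`S_β = E(σβ²)(v_β − 2)`.  The defining relation for `Vl` is circular (it
contains `σβ²`); we resolve it self-consistently via `Vl = (1−R²)Vl + 1`,
i.e. `Vl = 1/R²`, which reproduces the stated prior-mean form; callers can
override `Vl` explicitly.  The prior's coefficient of variation depends only
on the degrees of freedom, `CV = sqrt(2/(v_β − 4))`; the inverse is
`v_β = 2/CV² + 4`, so CV targets of 5%, 10% and 15% correspond to
`v_β` = 804, 204 and 92.89.  (A CV of 7.5% maps to `v_β ≈ 359.6` under this
formula.)  Defaults are `R² = 0.5` and `v_β = 1000` (CV ≈ 4.48%).

## Numerical choices

* Truncated-normal moments are computed vectorised; intervals are reflected
  to non-negative midpoint and, beyond a standardised lower bound of 6, the
  moment ratios are rewritten with the scaled complementary error function
  (`erfcx`) so differences of Φ never underflow.  Standardised bounds are
  clipped at ±30, past which the distribution is numerically a point mass.
  Agreement with adaptive quadrature is asserted to 1e−8 and with
  `scipy.stats.truncnorm` to ~1e−12.
* Initialisation: `β = 0`, `γ_c` at probit quantiles of the empirical
  cumulative category proportions, `σβ²` at its prior mean.
* Convergence: relative change of the observed log posterior below `tol`
  (default 1e−8), `max_iter` default 1000; non-convergence is reported in
  the result, not raised.
* The β sweep maintains the linear predictor and the E-step residual
  incrementally (O(n) per coordinate, fixed ascending column order).
* An empty training category is a hard error ("merge categories"): the
  quadratic update for its increment would be degenerate.
* Category-probability evaluation uses survival functions in the upper tail
  and returns `−∞` (not an exception) when a record's probability
  underflows.

## Synthetic trials

`simulate_trial` emulates a balanced multi-environment screening nursery:
binomial(2, maf) marker dosages with maf uniform on (0.05, 0.5); the E+G
(optionally +GE) design built by the same code path used for real data;
coefficients drawn i.i.d. with per-column variance `((1−R²)/R²)/msq`;
liabilities `−η + ε`; cut-points at the target marginal-probability
quantiles of the liability distribution.  Two identifiability-motivated
choices: environment main effects are drawn sum-to-zero (the scale location
belongs to the cut-points, and the G/GE columns already have exactly zero
record means because standardised markers give `G·1 = 0`), and the drawn
coefficients are rescaled so the realised variance split
`Var(η)/(Var(η)+1)` equals `R²_target` exactly — the usual device for
hitting a target heritability in breeding simulations, which makes the
scenario's signal level a property rather than an expectation.

Defaults (100 lines × 15 environments = 1500 records, 500 markers, C = 5
with uniform marginal frequencies, R² = 0.5) mirror the scale of wheat
nurseries scored on 5-point ordinal scales.  The generator draws independent
binomial markers: no linkage disequilibrium, population structure, selection
or missingness, and trials are balanced.  Passing parameter-recovery and
cross-validation tests on these data therefore demonstrates correctness of
the estimator and the pipeline, not expected accuracy on real breeding
data.  At these settings, recovery over 10 seeds gives a median
`corr(β̂, β_true) ≈ 0.93` and median worst-case cut-point error ≈ 0.05, and
fivefold cross-validated PCCC ≈ 0.37–0.41 against a 0.20 chance level.

## Cross-validation

Folds partition *records* (not lines), so a line may be in training for some
environments and in testing for others — the sparse-testing situation the
model targets.  Folds are a seeded random partition with sizes differing by
at most one, not stratified.  Classification uses the modal category of the
fitted probabilities with ties broken to the lowest index.  Each fold's PCCC
gets a bootstrap standard error (default 500 resamples of
observed–predicted pairs within the fold); reported summaries are the means
of the per-fold PCCC and SE values, from a single replication.

## Known limitations

* One common `σβ²` for all penalised columns; no per-block variance
  components or marker-specific shrinkage.
* MAP, not full posterior: no credible intervals; uncertainty is summarised
  only through cross-validation and the bootstrap.
* ECM convergence is linear; heavily unbalanced categories slow it.
* No MCMC baseline, no multinomial-ridge or SVM comparators, and no marker
  QC/imputation — genotype files must be complete and numeric.
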