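# thresholdgp

Genomic prediction of **ordinal traits** (disease scores, lodging scales,
discretised phenology classes, ...) with the Bayesian **threshold
(cumulative probit) model**, fitted to its **maximum a posteriori** estimate
by an expectation–conditional-maximisation (ECM) algorithm instead of MCMC.
The target audience is plant and animal breeders running genomic selection on
large multi-environment trials, where a Gibbs sampler over thousands of
GBLUP coefficients is the bottleneck.

## Model

An observed category `y_i ∈ {1..C}` arises from a latent liability
`l_i = −x_iᵀβ + ε_i`, `ε_i ~ N(0,1)`, cut by ordered thresholds
`−∞ = γ₀ < γ₁ < … < γ_C = ∞`:

    P(y_i = c) = Φ(γ_c + x_iᵀβ) − Φ(γ_{c−1} + x_iᵀβ)

The covariates are design blocks built from a multi-environment trial:
environment indicators (**E**), genomic features (**G**) obtained by
post-multiplying the line-incidence matrix with the matrix square root of the
genomic relationship matrix `G = WWᵀ/q` (W = column-standardised markers, q =
number of markers), their interaction (**GE**, the row-wise product whose
kernel is the Hadamard product of the E and G kernels), and optionally
pedigree (**A**) and replicate (**Rep**) blocks.  Priors: flat on the
thresholds, `β_j ~ N(0, σβ²)` with a common variance, and
`σβ² ~ Scaled-Inv-χ²(v_β, S_β)` elicited so that a chosen proportion `1−R²`
of the latent variance is genetic (defaults `R² = 0.5`, `v_β = 1000`, a prior
coefficient of variation of 4.48%).

The posterior mode is found by ECM after reparameterising the thresholds as
positive increments (`δ₁ = γ₁`, `δ_c = γ_c − γ_{c−1}`): the E-step computes
truncated-normal moments of a per-record working latent variable, and each
CM-step (δ₁; each interior δ_k; each β_j; σβ²) has a closed form.  The
observed log posterior is non-decreasing at every iteration.  With a flat
prior the algorithm returns the ordinal-probit maximum-likelihood estimate.

Accuracy is measured as the proportion of cases correctly classified (PCCC)
under record-level fivefold cross-validation, with a 500-replicate bootstrap
standard error per fold.

## Worked example

```python
import numpy as np
from thresholdgp import (SimScenario, simulate_trial, elicit_scale,
                         mean_sq_design, fit_mapt, kfold_cv)

scenario = SimScenario(n_lines=100, n_markers=500, n_envs=15, C=5,
                       R2_target=0.5, seed=7)
data, truth = simulate_trial(scenario)

prior = elicit_scale(R2=0.5, v_beta=1000,
                     mean_sq_design=mean_sq_design(data.X))
print(f"prior: S_beta={prior.S_beta:.3f}, mean={prior.prior_mean:.4f}, "
      f"CV={100*prior.cv:.2f}%")

fit = fit_mapt(data, prior)
print(f"converged={fit.converged} after {fit.iterations} iterations")
print("gamma_hat  =", np.round(fit.thresholds.gamma, 3))
print("gamma_true =", np.round(truth.gamma_true, 3))

cv = kfold_cv(data, prior, k=5, seed=7)
print(f"mean PCCC = {cv.mean_pccc:.3f} (mean bootstrap SE = {cv.mean_se:.4f})")
```

Output:

```
prior: S_beta=499.000, mean=0.5000, CV=4.48%
converged=True after 207 iterations
gamma_hat  = [-1.203 -0.347  0.398  1.149]
gamma_true = [-1.19  -0.358  0.358  1.19 ]
mean PCCC = 0.379 (mean bootstrap SE = 0.0276)
```

The elicited prior puts the coefficient variance at 0.5 (half of the unit
residual variance relative to the average squared row norm of the design),
the fitted cut-points land within a few hundredths of the generating ones,
and fivefold cross-validated accuracy (0.38) is roughly double the 0.20
chance level of a balanced five-category trait.

The same pipeline is available from the shell:

```sh
thresholdgp simulate --n-lines 100 --n-envs 15 --seed 7 --out sim/
thresholdgp fit --phenotypes sim/phenotypes.tsv --markers sim/markers.tsv \
    --design E+G --out fit.json
thresholdgp cv  --phenotypes sim/phenotypes.tsv --markers sim/markers.tsv \
    --design E+G --folds 5 --seed 7 --out metrics.json
```

## Layout

- `src/thresholdgp/design.py` — marker scaling, GRM, PSD square root, E/G/GE/A/Rep blocks
- `src/thresholdgp/priors.py` — scaled-inverse-χ² prior elicitation
- `src/thresholdgp/ecm.py` — E-step, CM-steps, MAP fitting loop
- `src/thresholdgp/evaluate.py` — category probabilities, PCCC, bootstrap SE, k-fold CV
- `src/thresholdgp/simulate.py` — liability-model trial generator
- `src/thresholdgp/io.py`, `cli.py` — TSV/JSON interchange and the `thresholdgp` command

See `docs/methods.md` for the statistical details and design choices.
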