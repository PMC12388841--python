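# Methods

## Data model

The experiment is a 3×3×3 full factorial over extraction temperature
(30/45/60 °C), sonication time (30/45/60 min) and ethanol fraction
(0/50/100 %).  Factors are coded as x = (value − center)/half-range with
centers (45, 45, 50) and half-ranges (15, 15, 50), so the design levels map
to −1/0/+1 exactly.  Responses are stored as run-level triplicate summaries
(mean, SD, n); all model fitting operates on the run means.  For a balanced
design with equal replication this yields the same coefficient estimates as
replicate-level fitting, and R² is defined on the means — consistent with
how such experiments are conventionally reported.  The per-run SDs are kept
as data but are not used in fitting; a pure-error/lack-of-fit ANOVA is a
documented extension point, not implemented.

The packaged dataset (`data/pflaccida_tas.csv` inside the package) holds the
published 27-run *P. flaccida* TAS table verbatim, in its original
experiment order.  The generic `full_factorial` generator emits standard
product order (first factor slowest, last fastest).

## Response-surface models

Four nested families in the coded factors: linear (4 terms), two-factor
interaction (7), quadratic (10), cubic (17).  On a three-level design the
pure cubes are aliased with the linear terms (xᵢ ∈ {−1,0,1} ⇒ xᵢ³ = xᵢ), so
the cubic family consists of the quadratic terms plus x₁x₂x₃ and the six
xᵢ²xⱼ terms; this keeps the design matrix full rank (verified rank 17 on
the 27-run design).

Fitting is OLS via SVD (`numpy.linalg.lstsq`); rank deficiency is reported
with the aliased columns named.  The ANOVA table decomposes SS_total into
regression and residual on the run means, with the overall F on
(k, n−k−1) df.

Two related but distinct operations are exposed:

* `compare_models` ranks all families by adjusted R² (reported with R² and
  SSE).  Note that between nested OLS models the adjusted-R² comparison
  favors the richer model whenever the partial F of its extra terms exceeds
  1, which under a pure-noise increment happens almost half the time — so
  this ranking is descriptive, not a selection rule.
* `select_model` performs sequential partial F-tests up the family ladder
  at α = 0.05 (the sequential-sum-of-squares procedure standard in DoE
  software) and is what the pipeline uses.  On the packaged dataset the
  quadratic increment is overwhelming (p < 10⁻¹⁰) and the cubic increment
  is not significant (p ≈ 0.22), so the quadratic is selected.

The stationary point solves the exact 3×3 linear system ∇ŷ = 0 and is
classified by the Hessian's eigenvalue signs.  Box-constrained maximization
uses a deterministic 101³ coarse grid (ties broken lexicographically)
followed by an L-BFGS-B polish (ftol 1e-15); on concave quadratics this
agrees with the stationary point to ~1e-6 in coded units.  Surface grids
over any two factors (third fixed) are exported as CSV; no 3-D rendering.

## ANN surrogate

Architecture: 3 inputs → h tanh units → 1 linear output, h ∈ [1, 20].
Inputs are scaled to [−1, 1] by the design box, the output by the data
range.  Training is Levenberg–Marquardt on the training-split SSE: solve
(JᵀJ + λI)δ = −Jᵀr with the analytic residual Jacobian; accepted steps
divide λ by 10, rejected steps multiply by 10 (λ₀ = 1e-3, giving a
monotone accepted-step SSE); training stops at 500 iterations, when the SSE
improvement falls below 1e-5, when λ exceeds 1e10, or when the validation
SSE has not improved for 50 consecutive accepted steps.  The returned
weights are always the validation-best seen.  A learning rate and momentum
of 0.5 are recorded in the config for provenance but unused: plain LM has
neither; its effective step size is governed entirely by the damping
schedule.

The topology search re-draws the random 80/10/10 split (largest-remainder
sizes, 27 → 21/3/3) and the uniform(−0.5, 0.5) initial weights for every
restart from per-(h, restart) children of one master seed, keeps the
restart with the lowest all-data MSE per h, and ranks architectures by that
MSE (ties toward fewer neurons).  All-data MSE is used as the selection
metric, with per-scope metrics (train/validation/test/all) reported so the
choice is transparent.  MSE and MAPE follow the conventional definitions on
original-unit values, MAPE = (1/n)Σ|eᵢ−pᵢ|/eᵢ·100; R is the Pearson
correlation of observed vs predicted.

Default search scale is 50 restarts per h; the acceptance script and the
corresponding test use 1000 restarts over h ∈ 3..8, the protocol scale a
desk machine completes in about half a minute.

## Genetic algorithm

Real-coded chromosomes of length 3 in natural units.  Selection is
roulette-wheel on min-shifted fitness, P(i) = (fᵢ − f_min + ε)/Σ(fⱼ − f_min + ε)
with ε = 1e-12, which degrades gracefully to uniform selection when all
fitnesses are equal.  Crossover is single-point at gene boundaries
(probability 0.9); mutation perturbs each gene with probability 0.1 by
Gaussian noise with SD 0.1× the gene range, clipped to bounds; one elite
individual is carried unchanged, making the best-so-far trace monotone.
Runs stop at 100 generations or after 25 stalled generations.  Campaigns
repeat the run 30 times from spawned seeds (raising the chance of hitting
a global optimum) and report per-run bests, the overall best and the
between-run dispersion; a scenario sweep repeats the campaign per
population size (default 5/10/20/50).  Mutation and elitism settings are
package choices — the operators' names are standard but their rates are
rarely reported — and all are configurable.

## Summary statistics

All procedures accept (mean, SD, n) group summaries, the form in which
assay tables are published.  OSI = TOS/(TAS·10) with TAS in mmol/L and TOS
in µmol/L.  The two-sample t-test is pooled Student's by default (Welch
optional) and delegates to `scipy.stats.ttest_ind_from_stats`; one-way
ANOVA reconstructs between/within SS from the summaries.  Duncan's multiple
range test computes critical ranges R_p = q(α_p; p, df_w)·√(MS_w/n_h) with
the protection level α_p = 1 − (1−α)^(p−1), studentized-range quantiles
from `scipy.stats.studentized_range`, and the harmonic mean group size n_h
for unequal n.  Lettering orders groups by descending mean ("a" = highest),
finds maximal non-significant runs testing the largest span first (so a
non-significant range protects its interior, per Duncan's procedure), and
assigns one letter per maximal run.  Degenerate inputs (zero within-group
variance) yield p = 1 for equal means and a flagged p = 0 otherwise.

## Synthetic data generator

`GeneratorSpec` draws, for each of the 27 design points, n_rep replicates
from a known quadratic surface on the coded scale plus homoscedastic
Gaussian noise, then summarizes them as mean/SD/n — the same shape as the
real table.  Defaults are the study conditions: the fitted quadratic's
coefficients as truth, noise SD 0.06 mmol/L (the replicate scale implied by
an R² near 0.99 on 27 means), and n_rep 3.  Homoscedasticity is justified
by the narrow spread of the published per-run SDs (0.013–0.036 mmol/L).
What the generator does *not* emulate: any lack of fit of the true response
to a quadratic, heteroscedastic or non-Gaussian assay error, and drift or
blocking across runs — so recovery tests validate the estimation machinery,
not the adequacy of the quadratic model for real extracts.

## Numerical choices and limitations

* OLS via SVD; stationary point via direct solve; deterministic optimizer
  ties broken lexicographically; all stochastic components seeded through
  `numpy.random.SeedSequence` spawning, so every result is reproducible
  from one master seed.
* The box optimizer's reported coordinates are polish-accurate (~1e-6
  coded); tests compare against dense-grid oracles.
* **Surrogate-argmax instability.** A network that interpolates all 27
  grid responses is unconstrained between grid nodes; on surfaces that are
  nearly flat around the optimum its argmax can move by several minutes or
  several percent ethanol while losing only ~0.1 mmol/L of true response.
  The package therefore treats ANN-GA optimum *coordinates* as inherently
  less stable than the RSM stationary point, reports both optima with their
  predicted responses, and flags route agreement only within a
  ±(2 °C, 5 min, 10 %) window.  This is a property of surrogate
  optimization at this data density, not a defect of either optimizer.
* MAPE is undefined when an observed response is zero; the metric raises in
  that case (TAS values are bounded well away from zero).
* Duncan letters follow the "highest mean = a" convention; for
  lower-is-better endpoints (e.g. IC50) the letters still order by mean.
  Published letterings are kept as annotation only and are not test
  targets, since printed tables of this kind are not always internally
  consistent with their own SDs.
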