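# Methods

## Model

Both variables are compositions: `x ∈ S^p` (predictor) and `y ∈ S^q`
(response), where `S^d` is the unit simplex with zeros allowed.  The
conditional-mean model is `E(y|x) = Bx` with `B` a q×p column-stochastic
("rectangular Markov") matrix.  Column-stochasticity is exactly the
condition making `Bx` a composition for every compositional `x`; reading
compositions as probability mass functions, `B` is the transition kernel
carrying the predictor PMF to the mean response PMF.

Individual entries of `B` are not interpretable on their own (compositions
carry only relative information); the meaningful quantities are column
contrasts: moving `δ` mass from predictor `j'` to predictor `j` shifts the
mean response by `δ(B_.j − B_.j')`.  Accordingly, "no association with
predictor j" means `B_.j` equals the barycenter column `(1/q,…,1/q)` — the
null element of the response simplex — not zero.  `contrast_effect` and
`pairwise_column_distances` expose these quantities; exports can subtract
the barycenter (`centered=True`) since the deviation matrix is the object
worth visualizing.

## Estimation

The fit criterion is the Kullback–Leibler divergence between observed and
fitted compositions.  Up to a `B`-free entropy constant this equals the
objective actually minimized,

    Q(B) = −Σ_i Σ_k y_ik log(Σ_j x_ij B_kj) + λ Σ_j ‖B_.j − 1/q‖₂ ,

over the feasible set of column-stochastic matrices.  The group (L2,1)
penalty shrinks whole columns toward the barycenter, the compositional
analogue of a group lasso: a column hit by full shrinkage is declared
unassociated.  `penalty()` and `objective()` report both pieces; reported
divergences (`kld`) are never clipped or smoothed.

### Solver

Unpenalized case (the classical low-dimensional estimator, `method="dr"`):
each unit of response mass `y_ik` is attributed to a latent predictor
source `j` with posterior weight `∝ x_ij B_kj`; the M-step re-normalizes
the accumulated weights column-wise.  This multiplicative EM update keeps
every iterate feasible and never increases the criterion.

Penalized case (`method="coc"`): proximal EM.  Each outer iteration takes
one EM update to a candidate matrix `C`, then applies a group
soft-threshold toward the barycenter,

    B_.j ← 1/q + max(0, 1 − t·λ/(m_j ‖v_j‖₂)) · v_j,   v_j = C_.j − 1/q,

where `m_j` is the E-step posterior mass of column j (the evidence weight
of that column in the EM surrogate, Σ_j m_j = n), and `t ∈ (0,1]` is a
backtracking step: the step is accepted only if the true penalized
objective does not increase, otherwise `t` is halved (30 halvings before
giving up and declaring convergence).  Because `v_j` sums to zero and the
shrinkage factor lies in [0,1], the update is a convex combination with the
barycenter and feasibility needs no projection.  Scaling the threshold by
`1/m_j` makes the prox consistent with the per-column curvature of the EM
surrogate: columns with little observed mass are shrunk harder, which is
also what makes `λ_max` available in closed form — starting from `B0`, the
fit stays at `B0` for all `λ ≥ max_j m_j‖c_j − 1/q‖`, computed from a
single E-step.

Numerical choices: iterates are started at `B0` (feasible, deterministic,
the natural null start; seeded Dirichlet columns available for multistart
checks); fitted values are floored at 1e-12 inside logs during iteration
only; convergence is relative objective change below `tol` (default 1e-8)
or `max_iter` (default 5000); a predictor column never observed (all-zero
in `x`) is unidentifiable, pinned at the barycenter, excluded from the
penalty, and reported with a warning.

### Choosing λ

`select_lambda` runs K-fold cross-validation (default 5) of the mean
held-out KLD over a path of 25 log-spaced values from `λ_max` down to
`λ_max·1e-4` plus 0, warm-starting each fit from the previous (larger) λ.
The default selection is the one-standard-error rule: the largest λ whose
CV score is within one fold-SE of the minimum.  Near `λ_max` the CV curve
is typically flat to within a few thousandths of a nat while fold-to-fold
variation is larger, so the literal minimizer is noise; the 1-SE convention
resolves that region toward more shrinkage, the standard conservative
choice for sparsity tuning.  `cv_rule="min"` gives the exact minimizer
(ties toward the larger λ).  Held-out predictions are floored at 1e-12 in
the CV score only, so a single structurally-zero prediction does not void a
fold.

A consequence worth knowing: in very noisy regimes (e.g. q=100 response
categories at Dirichlet concentration 10, where most response mass sits in
a few random categories per sample) the cross-validated fit frequently
collapses to `B0` exactly.  That is the correct call for prediction — and
its estimation error, `‖B−B0‖_F`, has the closed form `√(m(q−1)/(q(q+1)))`
in expectation-square for `m` Dirichlet(1_q) signal columns
(`null_distance`), a useful oracle for sanity-checking benchmark output.

## Inference

Global null `H0: B = B0` (no association at all).  Two resampling tests,
both using the statistic `T = ‖B̂ − B0‖_F` and the add-one p-value
`(1 + #{T* ≥ T}) / (1 + R)`:

* **Residual bootstrap.**  Compositional residuals `e_i = y_i ⊖ ŷ_i`
  (Aitchison inverse perturbation against the fitted values) are resampled
  with replacement and applied to the null fitted value; since `B0 x` is
  the barycenter and perturbing the barycenter is the identity, the null
  responses are simply resampled residuals.  Responses and fitted values
  get a 1e-6 pseudocount (then renormalization) before the ratio — only
  here, never in reported divergences.  The penalty weight is selected once
  on the observed data and reused across resamples (per-resample
  reselection is a config option, off by default for speed and for
  exchangeability of the statistic's tuning).
* **Permutation test.**  Re-fits after permuting the response rows against
  the predictor rows; the statistic's model is selectable (`"dr"` or
  `"coc"`).

CV selection of λ is part of the bootstrap procedure, not a refinement: at
a fixed under-shrunk λ the residuals of the overfit model understate the
null variation and the test becomes anti-conservative.  With CV the test is
valid and typically conservative — under the null the fit collapses to
`B0`, `T = 0`, and ties force the p-value to 1.  The flip side is low power
in regimes where CV (correctly) judges the signal unpredictive; the
benchmark runner reports whatever the test does, and the conservative
behavior is the price of validity here.

**Conformal prediction.**  Conformity of a candidate response is its KLD
from the model prediction.  The full-conformal p-value refits the model on
the dataset augmented with `(x_new, y_cand)` and ranks the candidate's
score among all n+1; mapping a whole region requires a candidate lattice
over `S^q`, so the implementation refuses q > 10 and points users to the
split variant.  Split conformal fits on a random half (the larger half for
odd n), computes calibration scores `R_i = KLD(y_i, B̂x_i)` on the other
half, and takes the cutoff `c` as the `⌈(n₂+1)(1−α)⌉`-th smallest score
(+∞, flagged, when that rank exceeds n₂ — the region is the whole simplex).
The region is the KLD ball `{y : KLD(y, B̂x_new) ≤ c}`; a candidate
supported where the prediction is zero has infinite divergence and is
outside any finite region.  `conformal_projection_grid` rasterizes the
region over all coordinate pairs (k,k′): the pair takes lattice masses
(u,v), u+v ≤ 1, and the remainder is spread uniformly over the other q−2
coordinates (resolution 50 by default).

## Synthetic data

The generator emulates paired relative-abundance surveys; it defines the
conditions under which all shipped benchmarks run.

* **Predictors.**  `homogeneous`: rows i.i.d. Dirichlet(1_p) —
  exchangeable components of comparable size.  `heterogeneous`: softmax of
  latent Gaussian rows `N_p(θ, Σ)` with `θ_j = log(0.5p)` for the first
  five coordinates (these then dominate the composition, together carrying
  well over half the mass) and AR(1) correlation `Σ_ij = 0.5^|i−j|`
  (simulated by the exact recursion).
* **Coefficients.**  A fraction of columns — 1% ("extremely sparse", with
  a floor of one column), 5% ("sparse"), or all ("dense") — drawn
  Dirichlet(1_q) at uniformly chosen positions; remaining columns exactly
  the barycenter; "null" is `B0` itself.
* **Responses.**  `y_i ~ Dirichlet(10·Bx_i)` by default: concentration 10
  means roughly "ten effective reads" of dispersion, producing the heavy
  zero-inflation of sequencing data (a mean coordinate of 0.01 has
  Dirichlet weight 0.1 and is very often sampled as ~0).  A zero mean
  coordinate yields an exactly-zero response coordinate (gamma draws with
  shape 0).

Every replicate draws from an independent, reproducible substream
(`replicate_rng(seed, r)`), so partial runs and single replicates can be
reproduced in isolation.

What the generator does **not** emulate: integer read counts and
sequencing depth variation, taxon-taxon correlation beyond what `Bx`
induces, overdispersion families other than Dirichlet, and any nonlinearity
in `E(y|x)`.  Benchmarks passing under these conditions validate the
estimator and its inference under the stated model, not robustness to
real-data misspecification.

## Benchmark runners and desk-scale choices

`run_estimation_benchmark` reports the mean (±SE) Frobenius error
`‖B̂−B‖_F` per method; `run_prediction_benchmark` the mean leave-one-out
KLD, selecting λ once per replicate on the full data and warm-starting the
n leave-one-out refits from the full-data solution;
`run_test_benchmark` the rejection proportion of either test;
`run_coverage_benchmark` split-conformal coverage for new predictors at the
center of `S^p` perturbed by δ in one coordinate, regenerating the full
dataset (and truth) for every repeat and cross-validating λ on each
training half.

Shipped problem sizes: estimation benchmarks use 20 replicates,
leave-one-out prediction 10 replicates, test error rates 50 simulations ×
100 resamples (with bootstrap refits capped at 150 EM iterations — the cap
applies uniformly across resamples, so the statistic's ranking is
unaffected), and coverage ≥200 trials per design×δ cell.  These sizes put
every Monte-Carlo standard error well below the effect sizes of interest
while keeping the full reproduction run in the tens of minutes on one CPU.

## Known limitations

* The penalized objective is non-convex in general; the solver guarantees
  monotone descent to a stationary point, not a global minimum.  The
  deterministic barycenter start makes runs reproducible; multistart from
  random columns is available for sensitivity checks.
* In overparameterized unpenalized fits (p·(q−1) ≫ n·q) the KLD minimizer
  is non-unique and the attained stationary point — and hence the reported
  DR estimation error — depends on the stopping rule (deeper convergence
  drifts further toward degenerate columns; the error varies by a few
  percent between tol 1e-6 and 1e-14).
* The bootstrap test inherits the conservativeness of CV-tuned shrinkage:
  power is essentially zero whenever CV fully collapses the fit, even if
  the truth is not exactly `B0`.
* Conformal coverage is marginal, not conditional; for a fixed (non-random)
  new predictor the exchangeability argument is approximate, and observed
  coverage at center-perturbed points runs slightly above nominal in our
  simulations.
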