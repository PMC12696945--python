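# Methods

## Model and estimation

A GAMLSS relates up to four parameters of the response distribution —
location μ, scale σ, skewness ν, kurtosis τ — to covariates through link
functions and additive predictors η_k = X_k β_k + Σ_j Z_kj γ_kj. The P-spline
terms use B-spline bases (default: cubic, 20 equal-width interior intervals,
so 23 basis functions) with a second-order difference penalty G = DᵀD; knots
extend `degree` equal steps beyond each boundary without multiplicity, so the
basis is a proper P-spline basis. A pb(x) term always implies a linear x
column in the parametric part; the spline models the deviation from
linearity (see "identification" below).

Fitting maximizes the penalized likelihood by the RS scheme, three nested
iterations:

1. **Outer** — cycle over the distribution parameters in the order
   μ, σ, ν, τ until the global deviance (−2 × log-likelihood) changes by less
   than `outer_tol` (default 1e-3) over a full cycle, capped at `max_outer`
   (50).
2. **Inner** — for one parameter, compute the predictor-scale score
   u = ∂ℓ/∂η and iterative weight w, form the working response z = η + u/w,
   and solve the resulting penalized weighted least-squares problem;
   repeat until the deviance change falls below `inner_tol` (1e-3), capped at
   `max_inner` (30).
3. **Backfitting** — within one inner step, fit the parametric part and each
   smooth in turn to its partial residuals (weights and working response held
   fixed), until the assembled predictor changes by less than `backfit_tol`
   (1e-6) in the sup norm, capped at `max_backfit` (30).

**Step control.** A completed inner step is accepted only if it does not
increase the penalized deviance evaluated at the step's smoothing parameters;
otherwise the coefficient step is halved toward the previous accepted state,
up to 10 times. Steps are linear in the coefficients, so halving is exact
client-side arithmetic. If no fraction of the step helps, the previous state
is kept and a warning recorded. The trace of penalized deviance at accepted
steps is therefore non-increasing while λ is fixed; λ re-estimation can move
the objective between steps.

**Initialization.** All parameters start as constants computed from three
aggregated response moments (n, Σy, Σy²): mean for μ, SD for σ under NO,
coefficient of variation for σ under BCCG/BCPE, ν = 1, τ = 2 (a normal-like
start). Starting from an intercept-only *coefficient vector* — rather than a
per-observation vector — keeps the predictor representable by coefficients
from the first step, which is what makes client-side step-halving and the
pooled/federated identical-path property exact.

**Linear algebra.** Each term's system (CᵀWC + λG)b = CᵀWz is solved by QR on
the small aggregated matrix with two steps of extended-precision iterative
refinement (cheap at these dimensions, and it keeps heavily penalized,
stiff systems accurate). A Jacobi-scaled condition number above 1e12 on an
unpenalized (linear-term) system raises a rank-deficiency error naming the
most collinear columns; penalized systems are exempt because a dominant
penalty legitimately inflates the condition number while leaving the
solution well-determined in the data directions.

## Families

Densities follow the standard Box-Cox constructions: z = ((y/μ)^ν − 1)/(σν)
(log form at ν = 0, evaluated via expm1 for small ν) follows a standardized
power exponential with kurtosis τ, truncated to the region compatible with
y > 0. The truncation normalizer F_T(1/(σ|ν|)) is included in the density and
the quantile function inverts the full truncated CDF, so densities integrate
to one exactly and quantile/CDF round trips hold to 1e-8 (both are asserted
by quadrature and property tests rather than trusted from transcription).
BCCG is implemented as the τ = 2 section of the same code path, so the
nesting BCPE(μ,σ,ν,2) ≡ BCCG(μ,σ,ν) holds to machine precision for
densities, quantiles and samples alike.

Scores are analytic in all parameters. The σ and ν derivatives of the
truncation normalizer are closed-form; the τ derivative of that (tiny)
normalizer is obtained by centrally differencing its analytic
incomplete-gamma expression, which keeps the full score accurate to ~1e-9
against finite differences of the log-density. Iterative weights use the
expected information where a closed form exists — NO (both parameters), BCCG
μ and σ, with the truncation mass ignored as is standard LMS practice — and
squared-score quasi-Newton weights elsewhere (BCCG ν; all BCPE parameters),
floored at 1e-10. Weights only precondition the step; the step-halving
deviance monitor guarantees progress regardless. Domain floors σ, τ ≥ 1e-8
and μ ≥ 1e-8 (positive-support families) absorb transient extreme
predictors.

Links: identity for μ and ν, log for σ and τ. μ of the Box-Cox families uses
a guarded identity link (the conventional default for anthropometric
responses, whose fitted μ stays far from zero).

## Smoothing parameters

λ is estimated *locally*, inside backfitting, as the fixed point of
λ = σ̂²_e / σ̂²_b with σ̂²_e = weighted RSS/(n − edf),
σ̂²_b = γᵀGγ/(edf − order), edf = tr[(ZᵀWZ + λG)⁻¹ ZᵀWZ] — at most 30
sub-iterations, relative tolerance 1e-3, λ clamped to [1e-7, 1e7]. Everything
the update needs is an additive aggregate, so it runs on the client with no
extra communication. When the fitted smooth lies in the penalty null space
(γᵀGγ ≈ 0), λ is pinned to the upper cap with a warning rather than an
error. Against an independent grid search of the mixed-model profile
likelihood the fixed point lands within a few percent of the maximizer on
simulated data. Alternatives per term: a fixed λ, or a target effective df
solved by monotone root search.

**Identification.** The B-spline basis can represent constants and (for
degree ≥ 1) linear functions exactly, which overlaps with the intercept and
the implied linear term. After each smooth solve the smooth's exactly-linear
content (its coefficient-space projection onto the penalty null-space
directions 1 and the Greville abscissae) is transferred into the
corresponding parametric coefficients. The transfer changes neither the
assembled predictor nor the penalty value (the directions are in null(G));
it only makes the parametric/smooth decomposition unique and keeps
backfitting well-behaved.

## Federation

Nodes hold private tables; the client drives the same RS engine but sources
every per-term solve from the elementwise sum of per-node sufficient
statistics: CᵀWC (term-df squared), CᵀWz (term df), the weighted
partial-residual sum of squares, the node's n, and log-likelihood
contributions. Weights and working responses are recomputed node-side from
broadcast coefficients each step and never transmitted. All traffic crosses
a JSON wire format (plain numbers only) and is recorded round-by-round in a
communication log, so the payload-size invariant — every message bounded by
a function of the model dimension, independent of n — is checkable after any
fit. Aggregation order is fixed (nodes sorted by id) for bitwise
reproducibility. With one node the federated path is bitwise identical to
the pooled fitter; with several, estimates differ from pooled only through
floating-point summation order (observed: coefficients first differ at the
10th decimal or later in the linear example, and fitted distribution
parameters agree far beyond three decimals in the BCPE example, provided
both paths use the same knots).

Disclosure guards run per node before any design matrix is built: the node
must hold at least `k_anonymity` (3) observations; every category of every
factor used by the model must contain at least `category_min` (3)
observations on that node; and the model's coefficient count must not exceed
`df_ratio` (0.33) × the node's n. Per-individual factor columns are thereby
rejected automatically (every level fails the category minimum).
Thresholds belong to the data owner and are configurable per session.

**Anonymized knot range.** Exact pooled extremes are themselves disclosive.
By default the shared knots span an *anonymized* range: per-node extremes
rounded outward to a granularity grid (default: pooled span/32, rounded to
one significant digit). The anonymized range always covers every observed
value, so no in-sample prediction can fall outside the knot domain; fits
with anonymized knots differ slightly from pooled fits (different basis),
which is the accepted price of not revealing the extremes. The rounding rule
is this package's own choice of a deterministic, reproducible anonymization.

## Synthetic data

`simulate_growth` draws ages uniformly on [2, 18] years rounded to one
decimal (mimicking field-recorded age) and heights from the scenario family
with smoothly age-varying truth: a decelerating cubic median (≈90 cm at age
2 to ≈155 cm at 18), ≈4% coefficient of variation with a mild age trend,
mild age-decreasing skewness, and constant kurtosis ≈2.2 for BCPE — the
shape, not the identity, of a pediatric growth reference. `simulate_sbp`
draws systolic blood pressure from μ = 80 − 0.7·female + 1.3·BMI (mmHg) with
log σ = 2.0 + 0.1·Spain, one country per node — the structure of a
two-country heteroscedastic meta-analysis. Generators are deterministic
under their seed and return the generating truth, enabling recovery tests
against exact standard errors. They deliberately do not emulate multi-wave
designs, within-person repeats, or covariate measurement error — so passing
recovery tests demonstrate correctness of the estimator, not robustness to
those real-data features.

Default problem sizes in the tests and the acceptance script (n = 4000 for
the linear example, n = 2000 for the BCPE centile example, two nodes) mirror
the package's flagship analyses at a scale where Monte-Carlo error is small
relative to the tested tolerances while a full run stays fast.

## Known limitations

- Only the RS algorithm is implemented (no cross-derivative CG steps); RS is
  the stabler choice for these families but can need more iterations when
  parameters are strongly correlated.
- No standard errors or confidence bands: honest inference after federated
  penalized fitting needs care about what per-node information may be
  disclosed, and is out of scope.
- No residual-based diagnostics (worm plots etc.): they require
  per-observation residuals, which the federation layer refuses to release.
- Random-effect terms are not supported; subject-level columns are blocked
  by the disclosure guard by construction.
- Quantiles/z-scores assume the fitted family is correct; model criticism
  must currently happen on data one is allowed to pool.
- The communication count grows with iterations × terms (routinely >1000
  rounds for a four-parameter P-spline model); the in-process transport makes
  this cheap here, but a networked deployment would pay latency per round.
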