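# Methods

This note records the modelling and numerical choices behind `hbggm`, in
the spirit of a statistical software appendix: what is assumed, what is
tunable, how the samplers are constructed, and what the synthetic
benchmarks do and do not demonstrate.

## Likelihood and column decomposition

Each subject's demeaned data matrix `Y_s ∈ R^{p×n_s}` is modelled as
`n_s` independent draws from `N(0, Ω_s⁻¹)`, where the precision `Ω_s` is
restricted to the cone of symmetric positive-definite matrices, optionally
with zeros off a shared graph.  Writing `S_s = Y_s Y_sᵀ`, the conditional
posterior of one column of `Ω_s` given the rest factorises, after the
change of variables

```
(u_s, ν_s) = (ω_12s, ω_22s − ω_12sᵀ Ω_11s⁻¹ ω_12s),
```

into a Gaussian on `u_s` with precision `Υ_s + D⁻¹` (where
`Υ_s = (S_22s + λ_s) Ω_11s⁻¹` and `D` collects the slab variances) and a
`Gamma(n_s/2 + 1, (S_22s + λ_s)/2)` distribution on the Schur complement
`ν_s`.  Because `ν_s` is strictly positive, re-assembling the column as
`ω_22s = ν_s + u_sᵀΩ_11s⁻¹u_s` keeps `Ω_s` positive definite at every
update, provided the chain starts inside the cone.  This is the invariant
the test suite checks for 100% of draws.

## Priors

Off-diagonal elements get a spike-and-non-central-slab prior with the
sparsity pattern `Z` shared across subjects; the slab mean `μ_ij` carries
the group-level connectivity and its scale `χ` is pooled over all edges
with a half-Cauchy prior `C⁺(0, A)`.  Defaults (`m_σ = 0.5`, `s_σ = 1`,
`A = 0.7`, `a_π = b_π = 6`) suit variance-scaled data in which partial
correlations rarely exceed 0.7; all are overridable through
`HyperConstants` or the config file.  The diagonal rate `λ_s` uses the
neutral `Ga(1/3, 0)` hyperprior, which is improper and therefore only ever
used through its conjugate `Gamma(1/3 + p, Σ_i ω_iis / 2)` update.

The half-Cauchy scale is implemented by the standard parameter expansion
`χ² | ξ ~ Inv-Gamma(1/2, 1/ξ)`, `ξ ~ Inv-Gamma(1/2, 1/A²)`, giving
inverse-gamma full conditionals for both.  Correctness is enforced by a
marginal test: cycling these updates with the group means refreshed from
their prior reproduces `C⁺(0, A)` to Kolmogorov–Smirnov distance < 0.02.
Any equivalent expansion would be acceptable under that test.

Edges currently excluded (`z_ij = 0`) keep `μ_ij` and `σ_ij` alive by
refreshing them from their priors each sweep, so the chain moves on the
full parameter space and the collapsed acceptance ratio below stays
well-defined.  The `χ` update pools `μ_ij` over **all** pairs, included or
not; with excluded means refreshed from `N(0, χ²)` this is self-consistent
(it is exactly the construction the prior-marginal test exercises), but it
is a choice — conditioning `χ` on included pairs only would also be
coherent and slightly decouple the layers.

## The collapsed update of the edge indicators

Within one column, the strengths `{u_s}` and the group means `μ_12` are
jointly Gaussian given the scales, so they can be integrated out
analytically.  For an included set of size `k` with slab variances `D` and
`Q_s = Υ_s[in,in] + D⁻¹`:

```
log E(z) = −N Σ_i log σ_i − ½ Σ_s log|Q_s| + ½ Σ_s c_sᵀQ_s⁻¹c_s
           − k log χ − ½ log|A| + ½ bᵀA⁻¹b,
A = N D⁻¹ + χ⁻²I − D⁻¹(Σ_s Q_s⁻¹)D⁻¹,   b = D⁻¹ Σ_s Q_s⁻¹ c_s,   c_s = −S_12s[in],
```

normalised so the empty pattern has `log E = 0`.  A Metropolis–Hastings
step proposes flipping one randomly chosen entry of the column's
indicators per sweep (a deliberately simple reversible scheme) and accepts
with probability `min(1, exp(ΔlogE) · a/(1−a))` (or its inverse for a
removal).  After the flip decision, `μ_12` is drawn from its u-collapsed
conditional `N(A⁻¹b, A⁻¹)` and then `u_s | μ_12` from
`N(Q_s⁻¹(−S_12s + D⁻¹μ), Q_s⁻¹)` — a partially collapsed Gibbs step that
is exact jointly.  The evidence formula is validated against nested
Gauss–Hermite quadrature over `(u_s, μ)` to 1e-6 on small instances; that
quadrature oracle is the acceptance surface for the whole derivation.

The weakly sparse variant pins `a = 1` and `z ≡ 1` and skips the MH step.
The single-subject variant concatenates all subjects, fixes the slab at
`N(0, 0.7²)` with no group-mean layer, and keeps the spike-and-slab graph.
The Bayesian graphical lasso variant replaces the slab with the
exponential scale mixture of the Laplace prior (per-subject latent
variances, inverse-Gaussian conditional; `λ` defaults to 1, a fixed
configuration choice), and the SSVS variant uses an elementwise
two-component normal mixture (`v₀ = 0.05`, `v₁ = 2.5`, `a = 0.5`) with
per-subject indicators; both run per subject through the same column
machinery.

## Sampler engineering

- **Initialisation**: `Ω_s` from Tikhonov inverses (`λ = 0.01`); `Z` by
  thresholding the group-mean |partial correlation| at 0.05; `μ` at the
  group-mean precision; `σ` at `m_σ`; `χ` at `A`; `a` at 0.5.  A warm
  start inside the PD cone is required; these are cheap and adequate.
- **Maintained inverses**: each subject's covariance `Σ_s = Ω_s⁻¹` is
  carried along and updated in closed form after every column draw
  (`Ω_11⁻¹ = Σ_11 − σ_12σ_12ᵀ/σ_22`, then the Schur blocks of the new
  column), avoiding a fresh `O(p³)` factorisation per column.  Inverses
  are refreshed from scratch every 50 sweeps; observed drift between
  refreshes is ~1e-14, far inside the 1e-8 agreement required of any such
  scheme.
- **σ updates**: random-walk MH on `log σ_ij`, all pairs vectorised,
  proposal scale 0.1 adapted by Robbins–Monro toward 40% acceptance during
  warm-up and frozen afterwards.
- **Sweep order** over columns is re-randomised each sweep from the run
  seed.  All randomness descends from `SamplerConfig.seed` (chains use
  `seed, chain_index` streams), so runs are bit-reproducible.
- **Storage**: thinned draws (default 10) in double precision, written as
  a `.npz` archive plus JSON index.  Posterior-mean partial correlations
  and edge probabilities are accumulated over *every* post-warm-up sweep,
  so summaries do not lose precision to thinning; the summary is the mean
  of per-draw partial correlations, not the partial correlation of a mean.
- **Diagnostics**: split-chain potential scale reduction on the log
  likelihood, `χ`, `a` and five randomly chosen edges; values above 1.05
  are logged as warnings, not failures.
- **Run lengths**: the configured default is 30 000 samples after 10 000
  warm-up in one chain, matching common practice for these models.  The
  test suite and the acceptance script use 2 000–5 000 sweeps on problems
  with 6–30 nodes, sizes at which the benchmark conclusions below are
  already stable.

## Baselines

Tikhonov (`(Σ + λI)⁻¹`) and the graphical lasso select `λ` from 30
log-spaced points in `[1e-4, 1]` by minimising the mean off-diagonal RMS
distance between regularised per-subject partial correlations and the
unregularised group average — a selection rule that needs no ground truth.
The distance is computed in partial-correlation space (precision space
would be the alternative; partial correlations are scale-free, which makes
the rule invariant to per-subject variance normalisation).  The graphical
lasso maximises `logdet Ω − tr(ΣΩ) − λ‖Ω‖₁` with the penalty over all
entries, by Friedman-style blockwise coordinate descent (stopping on max
elementwise change < 1e-6, 500 outer cycles); tests verify its objective
against an independent convex solver.  The Wishart baseline is the
closed-form posterior mean `(p+1+n_s)((p+1)I + S_s)⁻¹`.  The hierarchical
Wishart alternates `Ω_s ~ W(ν₀+n_s, (B+S_s)⁻¹)` with
`B ~ W(Nν₀+3, (I+ΣΩ_s)⁻¹)` (1 500 iterations after 1 000 warm-up), with
`ν₀` chosen by 5 bootstrapped half-splits of the subjects against mildly
regularised graphical-lasso estimates (`λ = 0.01`); the split-level error
is again off-diagonal RMS of mean partial correlations.

## Synthetic benchmarks

The generators emulate the standard designs for sparse multi-subject
precision estimation:

- **Circle**: `ω_ii = 1`, `ω_{i,i+1} = 0.5`, `ω_{1,p} = 0.4` — a sparse,
  poorly conditioned ring shared by all subjects (presets vary subjects ∈
  {5, 25}, `n_s` ∈ {18, 25, 500, 1000, 1100}, p ∈ {6, 30}).
- **Perturbed circle**: the ring as group mean; random signs per edge
  (shared across subjects), subject strengths `N(signed mean, sd²)` with
  sd ∈ {0.05, 0.15}; each matrix repaired to the PD cone by eigenvalue
  clipping (floor 1e-4 so the repaired matrix stays invertible) and
  rescaled so the implied covariance has unit variances (precision
  `Ω → DΩD`, which preserves zeros and partial correlations).  The ring
  sits near the PD boundary, so at sd = 0.15 the repair fires for most
  subjects; repair + rescale *amplifies* the nominal perturbation, and the
  realised coefficient of variation of edge strengths (≈0.4 at sd 0.05,
  ≈1.3 at sd 0.15) — not the nominal sd — is the meaningful measure of
  subject variability.  The repair also densifies: exact zeros survive
  only when no repair is needed.
- **Random edges**: pair-inclusion probabilities drawn uniformly from
  {0, 0.5, 1}; subject strengths `N(0.25, 0.05²)`; at each time point the
  probability-½ edges toggle independently and the realised matrix is
  PD-repaired before one sample is drawn.  Ground truth is the
  probability-weighted strength matrix (not itself PD in general — it is
  normalised like a precision for evaluation).  How positive definiteness
  was maintained under toggling is unspecified in the designs this
  emulates; per-realisation repair is this package's interpretation.
- **G-Wishart hierarchies**: a group matrix drawn from a G-Wishart on a
  user-supplied graph (identity scale, `df = p − 1`), subjects drawn from
  a G-Wishart with the group matrix as scale and `df_subject` controlling
  concentration (larger → subjects closer to the group).  The sampler is
  block Gibbs over columns using the same Gaussian/Gamma column
  conditionals, so draws respect the graph's zeros exactly and stay PD.
  We use the density convention `|Ω|^{(df−2)/2} exp(−tr(V⁻¹Ω)/2)`, under
  which a complete graph reduces to a standard Wishart with `df + p − 1`
  degrees of freedom and `df = p − 1` is proper; the complete- and
  empty-graph reductions are the correctness tests, not any particular
  sampling algorithm.

What these benchmarks do **not** emulate: temporal autocorrelation,
haemodynamics or oscillatory envelopes, measurement/leakage noise, and
heterogeneous graph structure across subjects.  Passing them shows the
inference machinery is correct and that hierarchical pooling helps in the
sampled-Gaussian regime; it does not by itself establish performance on
real neuroimaging data.

## Evaluation conventions

Reconstruction error is RMS over the `p(p−1)/2` unordered off-diagonal
pairs, computed in partial-correlation space (truth normalised the same
way), and reported as a proportion of the error of naive per-subject
covariance inversion, so the naive estimator scores exactly 1.  A
precision-space option exists behind a flag.  Graph recovery is ROC AUC of
the absolute inferred strengths against the true adjacency (midrank tie
convention, Mann–Whitney formulation); for the spike-and-slab models the
thresholded quantity is still the strength — posterior edge probabilities
are reported separately rather than fed into the ROC.

One caution on reading normalised scores: the denominator (the naive
error) itself shrinks like `1/√n`, so normalised RMS compares estimators
at a fixed sample size but is not a meaningful scale for sample-size
trends — an estimator whose absolute error falls strictly with `n` can
show a flat or even rising normalised score.  Absolute RMS is the right
scale for data-quantity comparisons.

## Degenerate inputs, tolerances, tie-breaks

PD certification uses Cholesky with a minimum-pivot tolerance of 1e-10.
Zero-variance regions fail variance scaling with a dedicated error; n_s <
2 is rejected at panel construction; more nodes than total samples
produces a warning but proceeds (the prior dominates).  `nearest_pd` uses
eigenvalue clipping with floor 1e-8 by default.  Evidence computations at
extreme scales (σ → 0) lose a few digits to cancellation; the collapsed-MH
ratio is exercised in tests down to differences of 1e-3 at σ = 1e-7.
There are no ties to break anywhere: the state is continuous and the
column order is randomised.

## Known limitations

- The spike-and-slab indicators mix by single-entry flips; on large dense
  graphs their autocorrelation is high, and the weakly sparse model is the
  pragmatic choice when edge probabilities are not needed.
- Complex-valued data, within-subject missingness and subject-specific
  graphs are out of scope.
- The per-subject variants (Bayesian graphical lasso, SSVS) are reference
  implementations fitted independently per subject; they share no
  information across subjects by design.
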