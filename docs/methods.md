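# Methods

## The problem

Genomic prediction in a numerically small breed is limited by its own
reference population. Adding a large breed's data helps only if the model
(i) recognises that marker effects are not identical across breeds and
(ii) does not let the many markers that merely tag QTL within one breed
drown the few markers that are close to the causal variants and therefore
transfer across breeds. `mbgp` implements the multi-breed GREML family that
addresses this: phenotypes of two breeds are treated as two correlated
traits, genetic covariance is structured through one or more multi-breed
genomic relationship matrices (GRMs) built from named marker sets, and the
between-breed genetic correlation is estimated per marker-set component.

## Multi-breed GRM

For breeds A and B with centered dosage matrices
`Z_k = X_k − 2 p_k` (breed-specific allele frequencies `p_k`):

```
GRM = [ Z_A Z_A' / s_A              Z_A Z_B' / sqrt(s_A s_B) ]
      [ Z_B Z_A' / sqrt(s_A s_B)    Z_B Z_B' / s_B           ]
s_k = Σ_j 2 p_kj (1 − p_kj)
```

Each within-breed block is the standard VanRaden method-1 GRM with that
breed's own frequencies; the cross-breed block is scaled by the geometric
mean of the two denominators, making the matrix symmetric by construction.
Frequencies are always recomputed from the currently included individuals
of each breed — one GRM per marker set serves all cross-validation folds.
Numerators are additive over disjoint marker sets, which the tests exploit.
Missing genotypes are rejected rather than imputed; the matrices target
complete post-QC data.

A consequence worth noting: breed-wise centering makes every within-breed
block exactly singular along that breed's mean vector. This is harmless for
REML (the direction coincides with the fixed breed means and is projected
out) but it means V = Σ K_c ⊗ GRM_c + R is only positive definite while the
residual variances are strictly positive — see the boundary handling below.

## Variance-component model

With phenotypes stacked breed-A block first,

```
y = X μ + Σ_c g_c + e,       g_c ~ N(0, K_c ⊗ GRM_c),
K_c = [ v_cA  c_c ]          e ~ N(0, R),  R = diag(v_e,breed(i) / w_i)
      [ c_c   v_cB ]
```

`X` carries one mean per breed. `⊗` here means expansion over the GRM's
breed blocks: within-breed blocks are multiplied by the component's
variances, cross-breed blocks by its covariance. Residuals are independent
across breeds (no individual is phenotyped in both breeds, so a cross-breed
residual covariance would not be identifiable) and per-breed rather than
pooled — the general case, which nests a single shared variance. The
weights `w_i` implement the deregressed-proof convention (residual variance
∝ 1/dEDC); they are 1 in simulation mode.

With one breed the same machinery reduces to univariate GREML (scalar
variance per component), which is how the within-breed (WB) and
across-breed (AB) reference designs are fitted; AB designs reach the other
breed's candidates through the cross-breed GRM block at prediction time.

## REML fitting

The restricted log-likelihood

```
l = −½ [ log|V| + log|X'V⁻¹X| + y'Py + (n−p) log 2π ],
P = V⁻¹ − V⁻¹X(X'V⁻¹X)⁻¹X'V⁻¹
```

is maximised by average-information (AI) updates with:

* **Internal standardization.** y is divided by its standard deviation, so
  the phenotypic variance is 1, tolerances are scale-free, and estimates
  are exactly scale-equivariant after back-transformation.
* **Monotone acceptance with step-halving.** An AI step that leaves the
  positive-definite region or decreases the likelihood is halved (up to 30
  times); if the AI direction fails entirely, a normalized gradient step is
  tried. Updates are clipped to max |Δ| ≤ 1 on the standardized scale,
  which only suppresses early-iteration overshoot.
* **Boundary handling.** Genetic variances are constrained nonnegative:
  a variance driven below 0 is pinned at exactly 0 with a boundary flag and
  re-enters the active set only when its gradient turns positive. Residual
  variances are instead floored at 1e-6 (standardized scale), because V is
  singular at zero residual (see above). Covariances are never constrained:
  K need not stay positive semi-definite (only V must), so estimated
  genetic correlations may exceed 1 and are reported as-is; when either
  variance of a component is on the zero boundary its correlation is
  undefined and reported as NA.
* **Convergence** when the largest accepted parameter update is below 1e-6
  and the likelihood gain below 1e-8 (standardized scale), with a flat-
  gradient escape when no uphill step exists (a supremum on the
  positive-definiteness boundary).
* **Precision.** Standard errors come from the inverse AI matrix over the
  free parameters at the optimum; genetic correlations and heritabilities
  get delta-method SEs from the same matrix (a parametric-bootstrap check
  in the tests agrees within 20% relative).

Starting values give every component and the residual an equal share of
each breed's phenotypic variance, with covariances at a quarter of the
geometric mean of the paired variances — strictly inside the parameter
space and symmetric across components.

All linear algebra is dense (Cholesky of V per iteration); the package
targets desk-scale problems (a few thousand individuals), where a bivariate
two-component fit at n = 1,400 takes seconds.

## Prediction and cross-validation

GEBVs use the selection-index identity: per component,
`ĝ_c(t) = Cov_c(t, ref) V_ref⁻¹ (y_ref − X β̂)` with GLS breed means, and
the total GEBV is the sum over components. This equals solving the full
mixed-model equations jointly (pinned by an MME oracle test to 1e-8) and
never requires inverting a GRM. A target appearing in the reference is a
hard error.

The five-fold protocol masks one fold of the validation breed at a time,
re-estimates all variance components on the remainder (plus the other breed
for multi-breed designs), predicts the fold, and averages the per-fold
Pearson correlations between GEBV and TBV (simulation) or DRP (real data).
Across-breed designs are fitted once on the other breed. The fold split
depends only on the seed and the validation IDs, so every design compared
under one seed shares validation sets. In real-data mode the mean accuracy
can be divided by the mean DRP accuracy; we take the mean over individuals
of √(reliability) (accuracy is conventionally per-animal √r²), with
√(mean r²) available as a documented alternative, and the divisor used is
always reported.

## Synthetic data

The generator emulates two diverged breeds without any real genotypes:
ancestral frequencies uniform on (0.1, 0.5); breed frequencies
Beta-distributed around them with variance FST·p(1−p) (Balding–Nichols,
default FST 0.1 — chosen for its closed-form moments, which the tests use);
genotypes Binomial(2, p_breed); QC keeps markers with ≥ 10 minor-allele
copies in each breed. A causal architecture of 283 markers (133 playing the
pre-selected "TOP" role plus 150 random causal) receives paired
allele-substitution effects from a bivariate standard normal with
correlation rg ∈ {1, 0.5, 0.25}; TBVs are raw-dosage sums; residuals give
heritability 0.8 within each breed using the replicate's realized TBV
variance. The random causal markers and the random-noise markers of the
TOP+RN set are redrawn each replicate, averaging over set choice.

What the generator deliberately omits: linkage disequilibrium (markers are
independent given breed frequencies), family structure, selection, and
sequence-level variation. Consequently non-causal markers carry almost no
information here — more extreme than on real chip data, where LD and
kinship let unselected markers capture substantial variance. Passing tests
therefore validate parameter recovery and the model machinery, not the
empirical accuracy levels of real cattle data; cells of the published
study that depend on real LD structure (e.g. heritability captured by
non-causal sets fitted alone) are out of the reproduction's reach by
design.

Default scaled dimensions — 1,000 + 400 individuals, 3,000 markers, 20
replicates — keep the full study in the tens of minutes on one CPU while
leaving every qualitative and quantitative recovery pattern intact; the
chip-scale dimensions are available through the same configuration.

Per-replicate seeds derive from `SeedSequence(master_seed, spawn_key=(rep,))`
and are recorded in the outputs, so any subset of replicates can be re-run
independently and identical configurations are byte-identical.

## Known limitations

* Exactly one or two breeds; no pedigree blending, dominance/epistatic
  relationships, metafounders, or Bayesian marker-class models.
* Real-data mode (DRP/dEDC weighting, file-based marker sets) is wired
  through the same runner but ships with no data; deregression itself is
  out of scope — DRP and dEDC are inputs.
* Dense algebra bounds practical size to a few thousand genotyped
  individuals.
* At very small n the REML surface can have its supremum on the
  positive-definiteness boundary (a zero variance with a free covariance);
  the optimizer converges there and flags the boundary, but such fits
  should be read as degenerate rather than biologically meaningful.
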