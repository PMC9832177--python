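# Methods

`pmutual` implements a three-pronged statistical test of dynamic mutualism
theory for co-occurring psychopathology: the idea that a general severity
dimension (the p-factor) may emerge from progressively strengthening
interactions among lower-level symptom processes, rather than from a single
common cause. The package fits (1) longitudinal bifactor structural
equation models with factor-strength and model-based reliability indices,
(2) the random-intercept cross-lagged panel model (RI-CLPM) comparison
family, and (3) between- and within-person Gaussian graphical models with
resampling diagnostics and permutation comparisons — plus a synthetic panel
generator that emulates an eight-wave annual cohort of symptom composites
under competing developmental processes.

## Data model

All analyses operate on a `PanelDataset`: a dense `(subject, wave,
variable)` array with a boolean observation mask. Waves are integer age
labels (annual design; calendar spacing is out of scope). The canonical
measure set is eight severity scores — five symptom composites (ADHD,
CD/ASPD traits, ODD, GAD, MDD) and three substance-use frequencies
(alcohol, marijuana, tobacco: FAU/FMU/FTU). The SEM stages use six
composites, with substance use collapsed to its mean frequency (SUB);
the network stage keeps each substance as its own node.

Item-level inputs are optional. When provided, heterogeneous Likert items
are equated by proportion-of-maximum scaling `(x − min)/(max − min)` and
aggregated by per-scale sum or mean rules. A composite is treated as
missing at a wave when more than 25% of its items are missing there
(configurable; single-item gaps should not destroy a composite).
Scale reliability is McDonald's omega from a one-factor ML fit,
`ω = (Σλ)² / ((Σλ)² + Σθ)`.

## Covariance-structure engine

The SEM engine (`sem_core`) estimates LISREL-form models

    Σ(θ) = Λ (I − B)⁻¹ Ψ (I − B)⁻ᵀ Λᵀ + Θ,   μ(θ) = ν + Λ (I − B)⁻¹ α

by maximizing the multivariate-normal log-likelihood in the N-denominator
convention (this shifts χ² values slightly relative to the Wishart N−1
form). Missing data are handled listwise or by full-information maximum
likelihood: rows are grouped into missingness patterns and pattern-wise
Gaussian log-likelihoods are summed — exact, not imputation-based. The
saturated log-likelihood under missingness is evaluated at the EM estimate
of the unstructured mean and covariance.

Free parameters are string labels in pattern matrices; cells sharing a
label are constrained equal, which also expresses the measurement-
invariance ladder (configural → metric → scalar by label merging).

Numerical choices:

- Analytic gradients of the (FIML) objective via the standard
  moment-gradient chain rule; L-BFGS-B with variance parameters bounded
  below at 1e−6, followed by a damped Newton polish in the
  non-bound-active subspace (Hessian by central differences of the
  analytic gradient).
- Convergence: max absolute gradient of `−2 logL / N` below 1e−5. Fits
  that stall on a numerically flat likelihood ridge — common when the
  bifactor model is fit to coupling-generated (misspecified) data — are
  accepted when no line-search direction improves the likelihood and the
  gradient is below 5e−3, and carry an explicit flat-ridge warning.
- Standard errors from the inverse observed information; standardized
  coefficients from model-implied latent and observed variances.
- Fit indices: χ² against the saturated model; CFI/TLI against the
  independence (diagonal) model; RMSEA with a 90% CI from the noncentral
  χ² distribution; adequacy labeled at CFI/TLI ≥ .90 and RMSEA ≤ .06.
- Robust (sandwich/scaled) corrections are not implemented: the synthetic
  panels are multivariate normal, so normal-theory ML is exact for them.

Tests: likelihood-ratio tests along nesting lattices; Wald tests of linear
label constraints; and a chi-bar-square boundary test for variances fixed
at zero, whose null distribution is approximated by parametric simulation
under the restricted fit (default 500 draws, seeded). For a single
boundary variance the simulated mixture weights on χ²₀:χ²₁ are reported
and are close to (½, ½), with small-sample skew toward slightly larger
zero mass.

## Longitudinal bifactor models

Every composite loads on a wave-specific general factor p and on its
domain factor (GAD, MDD → internalizing; ADHD, CD/ASPD, ODD, SUB →
externalizing); factors are mutually orthogonal within wave, which the
ECV/ω_H index family presupposes. Identification fixes wave-1 factor
variances to 1 and the *residual* variances of endogenous factors to 1
(the standardized-latent convention): with per-wave free loadings, free
AR paths, and free endogenous residual variances the scale of each
endogenous factor would be indeterminate. The two internalizing
indicators' specific loadings are constrained equal within wave: a
two-indicator specific factor identifies only the product of its loadings
cross-sectionally, and the tau-equivalent constraint is the standard
remedy. Same-indicator residual autocorrelations are off by default
(flag available).

The autoregressive variant has lag-1 paths for p, INT, EXT; the
cross-lagged variant adds all six cross paths per transition and is
compared by LRT. Starting values come from the first principal component
per wave, and the cross-lagged fit warm-starts from the autoregressive
solution.

Per wave, the bifactor index set is computed from loadings rescaled to
standardized factors (endogenous factors do not have unit variance under
the AR structure): global ECV (summing to 1 across factors) and
subscale-relative ECV_SS — both are emitted because published per-specific
tables are ambiguous between them; ω and ω_S; ω_H and ω_HS with the
model-implied total-score variance in the denominator; relative ω as
their ratios; and Hancock–Mueller H from fully standardized loadings
(flagged undefined when a standardized loading reaches 1).

Endpoint loading tests constrain each indicator's p-loading to be equal
at the first and last wave and apply a single-df Wald test. The reported
direction is the sign of the change in the *standardized* loading: raw
loadings at different waves live on different factor-variance scales, so
the standardized loading is the quantity a loading table is read from,
while the raw-parameter equality remains the Wald null (so type-I
calibration under a matched generator is preserved).

## RI-CLPM family

Two observed series — the internalizing and externalizing composite sums —
are decomposed into random intercepts (unit loadings on every wave) and
per-wave within-person deviations. Lag-1 autoregressions are always free;
cross-lags define the family: baseline (none), two unidirectional
variants, bidirectional ("mutualism"). Grand means are free per-wave
intercepts; wave-1 deviations are exogenous with free covariance;
within-time deviation covariances are free at every wave; all lag-1 only.
The traditional CLPM is the bidirectional model with the three
random-intercept parameters (two variances, one covariance) fixed to
zero, a boundary restriction tested with the chi-bar-square machinery;
an independently constructed CLPM specification (no RI latents at all)
reproduces its estimates to 1e−6 as a cross-check. Families are compared
by χ² difference tests along the nesting lattice and by AIC.

## Network models

Networks are unregularized Gaussian graphical models on the eight nodes.
Estimation runs a graphical-lasso path (default 100 log-spaced penalties,
min/max ratio 0.01, on the correlation matrix) to propose sparsity
patterns, refits every distinct pattern without penalty by constrained ML
(covariance-update/modified-regression algorithm), scores patterns by the
extended BIC (γ = 0.5, edge count as df), then greedily adds/removes
single edges until the EBIC stops improving. Edges are partial
correlations of the final unpenalized precision matrix. Under missingness
the input covariance comes from the exact EM estimator.

Between-person networks use raw cross-sections at an age; within-person
networks use scores centered at each subject's per-node grand mean over
their observed waves (subjects with a single observed wave are excluded
and counted). Cross-sections default to three equidistant ages starting
at the first wave — 14/17/20 on the 8-wave design, dropping the last
wave when equal spacing requires it.

Centrality: closeness `(n−1)/Σ distances` with edge length `1/|weight|`
(isolates get 0), betweenness with fractional tie-splitting, expected
influence as the signed row sum. Small-worldness uses the binarized
nonzero-edge graph with analytic random-graph expectations
(`C_rand = density`, `L_rand = ln n / ln k̄`) — one of several SWI
conventions, chosen because it is deterministic; note that under this
normalization uniform densification *lowers* the index, so rising
small-worldness requires shortcut-like (concentrated) edge growth.

Stability: non-parametric subject bootstraps give 95% percentile CIs per
edge and CI-based difference tests for edges and centralities; case-drop
bootstraps give the correlation-stability coefficient (largest drop
proportion at which ≥95% of subsamples keep r ≥ .70 with the full-sample
centrality, scanned from small drops upward), labeled by the
.70/.50/.25 tiers.

Comparisons: permutation network comparison tests of the maximum edge
difference (M) and the global-strength difference (S; sum of |edges| by
default, signed sum by flag — published phrasing is ambiguous between the
two). Per-edge permutation tests with Holm adjustment over all node pairs
follow a significant M. The paired (within-subject) mode is provided but
experimental; unpaired is the default. Resampling inside bootstraps and
permutations may use a smaller penalty grid (default 30) for speed; all
resampling is exactly reproducible given (B, seed).

## Synthetic data: the study conditions

The generator emulates 2,339 subjects × 8 annual waves × 8 measures with
monotone attrition (per-wave hazards, first wave always observed; optional
logistic dependence on the previous-wave score for MAR dropout) and
optional Likert discretization.

- **Common cause**: latent p, INT, EXT follow independent AR(1) chains
  (unit innovation variance, N(0,1) start — exactly the family the
  bifactor model estimates, so endpoint-Wald calibration is meaningful);
  measures load on p and their domain factor with *heterogeneous*
  loadings (equal loadings within a domain would put the bifactor on a
  non-identified ridge). Loadings are wave-constant: nothing strengthens.
- **Mutualism**: no latent factors; measures follow a VAR(1) whose
  cross-domain coupling grows linearly across transitions. The plain
  configuration grows all cross-domain coefficients (0 → 0.12; 0.15 is
  explosive for this node set). The *canonical study condition*
  (`study_conditions("mutualism")`) concentrates growth (0 → 0.25) on six
  directed hub pairs (ADHD↔GAD, ADHD↔MDD, MDD↔CD/ASPD), reflecting the
  theory's centrality/sampling mechanisms; concentrated growth produces
  the qualitative mutualism signature — a strengthening general factor
  and rising within-person small-worldness — whereas uniform
  densification mechanically lowers the SWI under its density-based
  normalization.
- **Differentiation**: the same VAR with coupling decaying (0.12 → 0).

VAR panels start from a correlated baseline (within-domain r = .30,
cross-domain r = .10 — symptoms already covary at age 14) and receive
within-domain correlated innovations (r = .25: same-domain measures share
yearly influences), which sustains domain clustering across the panel.
A growing cross-domain innovation-correlation schedule is available to
represent mutualistic interaction faster than the annual sampling
interval, but is not part of the canonical condition. Stationarity is
enforced at configuration time by a spectral-radius check on every
transition matrix. Ground truth (loadings or the A_t sequence) is always
returned, and every draw is bit-reproducible from its seed.

What the generator does *not* emulate: item-level ordinal measurement
(composites are generated directly), cohort effects, non-normal
severity distributions, and informative attrition unless requested.
Passing tests therefore certify the statistical machinery under
normal-theory conditions, not robustness to real-data pathologies.

## Evidence checklist

`run_all` chains composites → bifactor (both variants, indices, endpoint
Walds) → RI-CLPM family (+ boundary test) → networks at the three ages,
then scores four hypotheses with configurable thresholds:

- **H1** ≥ half of the endpoint Wald tests reject with positive
  (standardized) direction, and both ECV and ω_H of the general factor
  are higher at the last wave than the first. Indices and Walds come from
  the autoregressive fit — the cleaner per-wave measurement model, since
  cross-lagged paths absorb part of the trajectory.
- **H2** at least one significant positive cross-lag in each direction
  in the bidirectional RI-CLPM.
- **H3** the cross-lagged bifactor beats the autoregressive variant by
  LRT (α = .05) *and* the bidirectional RI-CLPM has the lowest AIC. The
  LRT is accepted from a flat-ridge cross-lagged fit (an under-optimized
  full model can only make the test conservative).
- **H4** within-person small-worldness exceeds 1 at every compared age
  and is higher at the last age than the first (the within-person
  trajectory is the sharper signal; the level is configurable).

Verdict: `consistent-with-mutualism` only when all four hypotheses were
evaluated and hold; `inconsistent` when none holds; `mixed` otherwise.
Reports are a pure function of panel + configuration + seed, and every
reported statistic is traceable to a stage output file.

## Problem sizes used in the test suite

Oracle equalities run at full precision (50 index configurations; 25
exhaustive 4-node GGM enumerations). Recovery and calibration use
n = 2,000 panels (20 seeds) for loading recovery, 200 null simulations
for each test-calibration check at n = 300–500 with small models, 50
simulations for the RI-CLPM AIC selection, 100 replications × 500
permutations (4 nodes, reduced penalty grid) for NCT calibration and 20
for its power check, and 20 seeds per generator at n = 1,000 × 8 waves
for the end-to-end discrimination check. `scripts/acceptance.py` re-runs
the pipeline at the design size (n = 2,339) plus 12 reduced-size seeds
per generator for the discrimination rates.

## Known limitations

- The flat-ridge convergence fallback reports parameter values on a
  likelihood plateau; their individual values (not the likelihood) can
  drift within the ridge, so SEs there should not be over-read.
- The chi-bar-square p-value is a parametric-bootstrap tail probability;
  with few draws its resolution is limited to ~1/draws.
- The SWI convention is analytic and binarized; other conventions
  (rewired-ensemble references, weighted clustering) give different
  absolute values.
- The paired network comparison permutes subject rows wholesale and has
  not been validated against dependent-samples alternatives.
- H estimation requires all standardized loadings strictly inside the
  unit interval; Heywood-adjacent fits flag H as undefined.
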