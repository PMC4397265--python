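# Methods

## Model family

All models are covariance-structure models in the all-latent
formulation: Σ(θ) = Λ(I−B)⁻¹Ψ(I−B)⁻ᵀΛᵀ + Θ, with Λ the manifest
loadings, B the (acyclic) structural paths among latents, Ψ the latent
variances/covariances (disturbance variances for endogenous latents)
and Θ a diagonal matrix of manifest residual variances.

Two identification conventions coexist:

- **Traditional (congeneric) scaling** — loadings free, latent variance
  fixed to 1. Used for the one-factor working-memory model.
- **Fixed-links scaling** — loadings fixed to a predetermined course,
  latent variance free. Because loadings are fixed, several latents may
  load on the same indicators; they are separable iff no two fixed
  courses are proportional (checked by `validate_spec`).

The measurement family over the five task conditions comprises the
congeneric model and four two-latent fixed-links models pairing a
constant course (1,1,1,1,1) with a linear (.1–.5), quadratic
(.01–.25), logarithmic (.30,.48,.60,.70,.78) or inverted-u
(.36,.80,.99,.94,.64) dynamic course; the two latents are fixed to be
uncorrelated, since the decomposition's purpose is to separate
independent sources of variance. Courses are stored at two-decimal
precision, the precision at which they enter the published analyses.
The logarithmic course is generated as log₁₀(k+1) for k = 1…5 — the set
sizes are 2–6 items — which reproduces the published series after
rounding; the published material states only the series, so the
generating rule is an inference. The inverted-u course evaluates
f(x) = (−x²+100)/100 at x = −8, −4.5, −1, 2.5, 6.

The structural models add a reasoning factor measured by three
composites. Its scale is set by fixing the first composite loading to
1 (the disturbance variance stays free); standardized solutions are
invariant to this choice, and standardized paths are what the package
emphasizes. Degrees of freedom: congeneric 5; fixed-links measurement
models 8; one-factor structural model 19; two-latent structural model
21.

## Estimation and inference

- **Objective**: F_ML = ln|Σ| − ln|S| + tr(SΣ⁻¹) − p, minimized over
  free parameters by BFGS with numerical gradients, followed by a
  Nelder–Mead polish from the BFGS optimum. Convergence requires a
  max-gradient below 1e-4; non-convergence is reported on the result,
  never silently replaced by best-so-far. Maximum 5,000 evaluations.
- **Start values**: free loadings at 0.5·sd(indicator); residual
  variances at half the observed variance; latent variances from a
  least-squares projection of the observed off-diagonal covariances
  onto the fixed course (these moment-based starts matter because the
  hit-rate and composite variables differ in scale by a factor ~30);
  structural paths at 0.
- **Non-PD excursions** of Σ(θ) during optimization return a finite
  penalty (1e6 + ‖θ‖²), keeping the quasi-Newton path in admissible
  territory.
- **Test statistic**: T = (n−1)·F_min. The multiplier is configurable
  (`FitOptions.multiplier`) because software conventions differ between
  n and n−1; at n = 200 the difference is within printed rounding.
- **Standard errors**: inverse of the central-difference observed
  information of (multiplier·F)/2 at the optimum.
- **Variances are unbounded**: negative (Heywood) estimates are
  reported with a flag, matching common SEM-software behaviour and
  keeping boundary problems visible.
- **Sign convention**: the first free loading of each latent is made
  nonnegative; the flip is propagated to paths and covariances
  involving that latent so Σ is unchanged.
- **Latent-variance z-test**: z = ψ̂/SE, two-sided normal p.
- **Wald constraint test** on a *standardized* path: delta-method
  variance of the standardized coefficient (default), or a
  fit-difference variant that refits with an SLSQP equality constraint
  on the standardized value and reports T_constrained − T.
- **Satorra–Bentler rescaling**: c = tr(UΓ̂)/df with Γ̂ the
  fourth-moment (ADF) estimate of the asymptotic covariance of vech(S)
  and U = V − VΔ(ΔᵀVΔ)⁻¹ΔᵀV the normal-theory residual weight operator
  at θ̂; T_scaled = T/c. Requires raw data; warns when
  n < p(p+1)/2. Point estimates are unaffected by the rescaling.

## Fit evaluation

χ² p-value from the central χ²(df); CFI against the independence
baseline (whose ML solution is analytic: T_b = −(n−1)·ln|R|,
df_b = p(p−1)/2); RMSEA = √(max(T−df,0)/(df·(n−1))); SRMR as the RMS of
correlation-scaled residuals over nonduplicated elements; information
criterion AIC = T − 2·df. The difference convention for AIC is used
deliberately — it reproduces the published comparison table and orders
models identically to −2lnL + 2q on the same data. Model comparison
follows the joint rule: a model is better when its AIC is lower *and*
its CFI exceeds the other's by more than .01; fixed-links models whose
dynamic-variance z-test fails at α = .05 are rejected regardless of
fit. The reported "preferred" model is the one dominating all
non-rejected candidates by the joint rule, falling back to lowest AIC
among non-rejected candidates when no model dominates outright.

## Synthetic-data generator

The generator emulates the study design: five hit-rate variables
y_i = μ_i + ξ_c + g_i·ξ_d + ε_i with ξ_c ⊥ ξ_d, and three unit-variance
reasoning composites loading on a criterion factor regressed on the
standardized latents. Defaults are the study conditions: ψ_c = .0120,
ψ_d = .0121, inverted-u course, standardized criterion paths .45
(constant) and .48 (dynamic), condition means (.88,.77,.77,.61,.55) and
total SDs (.18,.21,.19,.23,.24). The fifth condition's mean/SD are an
extrapolation of the observed difficulty trend (the available
descriptives stop at condition four) and are overridable. Residual
variances are derived as θ_i = SD_i² − ψ_c − g_i²ψ_d and must be
positive. Composite loadings solve l_i·l_j = r_ij for the observed
inter-composite correlations .58/.40/.42, giving (.743, .780, .538).

Error families:

- `normal`: the data are exactly multivariate normal with the implied
  covariance (clipping off), so moment-level oracles are exact.
- `scaled_t`: every latent score and residual of a participant shares
  one chi-square scale mixture (a multivariate-t construction) with
  unit-variance t(df) marginals. The shared mixing is a deliberate
  design choice: with *independent* heavy-tailed components the ML
  chi-square is asymptotically robust and the kurtosis correction
  converges to 1, leaving nothing for a robust-scaling study to
  detect; the shared mixture produces the common-kurtosis violation the
  Satorra–Bentler correction is built for.

Hit-rate clipping to [0, 1] is off by default (keeping moment oracles
exact) and available as an explicit misspecification stressor. One
master seed drives everything; replication seeds are derived by
counter, so studies are exactly reproducible.

What the generator does *not* emulate: trial-level responses, floor/
ceiling shape of real hit rates (unless clipping is enabled), unequal
subtest reliabilities within a composite, and sampling of the
correlation metric. Passing recovery tests therefore show the
estimator recovers the assumed structure under the study conditions,
not that real dot-span data satisfy that structure.

## Parameter recovery

`parameter_recovery_study` generates, refits the structural model
matching the population's course, and summarizes bias, empirical SD,
95% Wald coverage of the unstandardized parameters, variance z-test
power, and how often each dynamic course wins the comparison rule on
the measurement block. At the default study conditions (n = 200) the
standardized-path bias is well below .05 and the inverted-u course is
selected in a clear majority of replications; the default acceptance
run uses 200 replications at n = 200, a size chosen to keep the full
study in the minutes range on one core.

## Known limitations and open points

- **Metric dependence**: the bundled input is the published
  *correlation* matrix at two printed decimals. Standardized results
  refit cleanly (the one-factor structural path reproduces at .65), but
  covariance-metric latent variances (.0120/.0121 etc.) are not
  recoverable from a correlation matrix, and the variance z-tests are
  attenuated in this metric — on this input the z-rejection rule fires
  for all fixed-links models even though the inverted-u model still
  attains the best AIC and CFI. The pipeline warns whenever it fits a
  correlation matrix.
- The published robust (SB-scaled) χ² values, SRMR values and exact z
  statistics depend on unpublished raw fourth moments and cannot be
  reproduced from printed summaries; the engine's SB machinery is
  instead validated by simulation (c → 1 under normality, c > 1 under
  shared-scale t errors).
- The constrained value .68 used in the published Wald contrast differs
  from the .65 reported for the traditional path; the test accepts an
  arbitrary constraint value and the pipeline defaults to .68.
- No missing-data (FIML) estimation, mean structures, categorical
  indicators, or multi-group models; robust *standard errors* (as
  opposed to the robust test statistic) are out of scope.
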