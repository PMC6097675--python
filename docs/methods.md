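# Methods

## The model

`krillassess` implements a length-based, age-structured integrated
assessment for Antarctic krill (*Euphausia superba*) fitted simultaneously
to acoustic and net-trawl biomass indices, survey and fishery length
compositions, and annual catches, under penalized maximum likelihood.

**Population dynamics.** Ages 1 through a plus group at age 7, calendar
years 1976–2016. Numbers-at-age follow

    N[y+1, a+1] = N[y, a] * exp(-Z[y, a]),      Z[y, a] = M + s_f(a) * F_y,

with the plus group accumulating. Recruitment is
`R_y = exp(ln R̄ + ε_y^R − σ_R²/2)`; the lognormal bias correction makes
`R̄` a mean rather than a median and can be switched off on
`ModelStructure`. Five pre-data deviations (1971–1975) build the initial
age structure under natural mortality alone; the 1976 plus group carries
the accumulated mean-recruitment equilibrium. The deviation vector
therefore has 46 entries and the fishing-mortality deviation vector 41
(`F_y = exp(μ_f + ε_y^f)`), reproducing the 118-parameter census.

**Observation model.** Catch-at-age is Baranov:
`C[y,a] = s_f(a) F_y / Z[y,a] * (1 − exp(−Z[y,a])) * N[y,a]`; predicted
catch biomass multiplies by weight-at-age and fishery catchability `q_f`.
Survey indices are `q_s · Σ_a s_s(a) w_a N[y,a]` (biomass). All
selectivities are logistic in age, `s(a) = 1/(1 + exp(−(a−α)/β))`.
Age compositions are mapped to 2-mm length bins (10–70 mm) through a von
Bertalanffy age–length matrix: lengths at age `a` are Normal(L∞(1−e^{−ka}),
σ_v) integrated over bins with the tails folded into the end bins.
Weight-at-age is allometric, `w = c·L(a)^d` with defaults `c = 1e-9`
tonnes·mm⁻³ and `d = 3` (an internal scale constant; no absolute-biomass
claims are attached to it). Maturity is knife-edge at age 3. Both are
`ModelStructure` fields.

**Likelihood.** Lognormal deviances for indices and catches with
`σ² = ln(1 + CV²)` (the `ln σ` normalization is retained so the catch CV is
estimable); multinomial deviances `−N Σ_b o_b ln p_b` for compositions at
the stated effective sample sizes, with predicted proportions floored at
1e-10 before the log. Density constants are dropped consistently, so
breakdowns are comparable across configurations but not across packages.

**Penalty stack.** Six penalties close the model:

| | form | default weight |
|---|---|---|
| Λ1 | `Σ ε_R²/(2σ_R²) + n ln σ_R` | 1 (likelihood-like) |
| Λ2 | `Σ_years (ln R_y − ln BH(SSB_y))²` | 1 |
| Λ3 | same, pre-data years at first-year SSB | 1 |
| Λ4 | `n (mean ε_R)²` | 0.1 |
| Λ5 | `Σ ε_f²` | 0.1 |
| Λ6 | `Σ max(0, F_y − 1.5)²` | 10 |

`BH` is Beverton–Holt in the steepness parameterization,
`R(S) = 4hR₀S/(B₀(1−h) + (5h−1)S)`, so `R(B₀) = R₀` and `R(0.2B₀) = hR₀`.
Λ3 uses first-year spawning biomass because pre-data SSB is undefined.
These functional forms and weights are this package's reconstruction of a
conventional penalty stack; they reproduce the qualitative behaviors the
design calls for (pre-data shrinkage toward the stock–recruit curve, a
small downward bias in the highest fishing mortalities that disappears
when Λ5–Λ6 are zeroed) and are fully exposed on `PenaltyStack`.

## Estimation

Each configuration activates a subset of 13 parameter groups (the 12
standard groups plus the never-estimated catch CV); everything else stays
at the pre-specified initial values. Estimation is phased: every active
group draws a uniform random phase in 1..7 and phase `p` minimizes over
all groups activated at or before `p`, through a terminal phase 9. A
replicate redraws phase orders until the fit converges (below) or a
reordering budget runs out; the replicate tournament reports the median
number of reorderings, the percentage of replicates tying the lowest NLL
(ties within 0.5 units, matching integer-precision reporting), and the
best replicate.

Bounded parameters are estimated through a scaled-logit transform so
estimates stay strictly interior; a post-fit check flags estimates within
0.1% of a bound. Selectivity spreads and the catch CV carry narrow
positivity guards ((1e-3, 20) and (1e-4, 5)) that the parameter table
leaves unbounded; they never bind in practice.

**Gradients.** The objective is analytic in every parameter except the
growth group (which passes through the normal CDF), and growth is fixed
in all 22 shipped configurations. Gradients therefore use complex-step
differentiation — exact to machine precision at one objective evaluation
per parameter — with a central finite-difference fallback when growth is
active. The within-phase minimizer is L-BFGS-B; after the terminal phase
the Hessian is assembled from forward differences of the exact gradient
and a Levenberg–Marquardt-damped Newton polish (with eigendirection line
searches for the strongly curved M/R̄/μ_f and fishery-selectivity ridges)
drives the maximum absolute gradient below the 0.001 convergence gate on
the estimation scale. "Invertible Hessian" is operationalized as positive
definite after symmetrization with condition number below 1e12; a fit is
converged iff both gates hold.

## Uncertainty

**Asymptotic (delta approximation).** The inverse Hessian at the optimum
approximates the covariance of the estimates on the estimation scale;
intervals `±1.96 SD` are mapped back through the bound transform, and
derived quantities (e.g. terminal-year spawning biomass) get first-order
Taylor SDs.

**MCMC.** Random-walk Metropolis–Hastings with a multivariate-normal
proposal scaled from the inverse Hessian (`2.4²/d` times an adaptive
scalar tuned toward 30% acceptance during a pre-phase and frozen before
any recorded sample, preserving detailed balance). Monitored quantities
are the estimated scalar parameters plus 2015 spawning biomass, 2015
recruitment and the 2011 F-deviation when present, capped at 27; derived
quantities are recomputed by replaying the model at each saved draw. Desk
scale defaults are 100 000 samples, thin 20, 10% burn-in; the
production-scale bookkeeping (10 M samples, thin 2000, 5000 saved) is the
same arithmetic, `saved = ⌊(total − burn-in)/thin⌋`, and all scales are
caller knobs.

**Diagnostics.** Heidelberger–Welch stationarity (Cramér–von Mises on the
standardized Brownian bridge of cumulative sums, iteratively discarding
10% up to 50%; 5% critical value 0.4613) and halfwidth
(`1.96·√(s₀/n) / |mean| < 0.1`; a near-zero mean takes the
pass-with-warning branch); Geweke z (first 10% vs last 50% with spectral
variances); autocorrelations and an effective sample size from the
positive-prefix autocorrelation sum. The spectral density at frequency
zero comes from an AIC-selected autoregressive fit,
`s₀ = σ²/(1 − Σφ)²`.

## Model comparison

`AIC = 2·NLL + 2k`, `BIC = 2·NLL + ln(n)·k`, with `n` the total number of
data-years across the six surveys and the fishery (143 at the standard
design: 35 + 54 + 41 + 13). Deltas are computed unrounded against the
minimum-criterion row and rounded half-up for display — this policy
reproduces every published delta cell from the published (NLL, k) columns,
which ship as packaged reference data because the underlying survey data
are not public. Utilities convert instantaneous natural mortality to
annual death fractions (`100(1 − e^{−M})`: 0.8 → 55%, 1.37 → 75%,
2.46 → 91%) and count ordered phase assignments as the conventional
product `n_groups!·(n_groups − n_phases)!` (≈5.7e10 for 12 groups in 7
phases) — the printed convention, noted here because the falling-factorial
reading gives a different number.

## Simulation testing

`generate_pseudodata` replaces observations with model-predicted values
(no noise), keeping years, CVs and effective sample sizes. A self-test
refits the same configuration from the standard initial values; a
cross-test refits a structurally different one. Reports give per-year
relative errors of recruitment, SSB, fishing mortality and catches, the
replicate NLL spread, and the mean signed F error over the
top-quartile-F years (the high-F bias summary). Fishing mortality is
compared as **effective F**, `q_f · F_y`: when catchability is estimated,
only that product is identified (q_f and F slide along a ridge) and raw-F
comparisons measure ridge position, not fit.

The F-penalty experiment repeats a rich self-test with Λ5–Λ6 zeroed in
the refit only, starting both refits at the operating parameters so the
measured quantity is the penalty-induced displacement of the optimum
rather than replicate basin noise (replicates of the rich configurations
find genuinely distinct local minima). Because Λ1–Λ4 remain active in
both refits and also displace the trajectory, the meaningful signal is
the *contrast*: the with-penalty refit sits below the penalty-free refit
in the highest-F years — the F penalties bias effective F downward
exactly where F is largest.

An important structural property, documented rather than hidden: on
pseudo-data the data components are exactly minimized at the generating
parameters, but the penalties are not — their gradient there equals minus
the original data gradient. The refit optimum is therefore displaced by
roughly `H⁻¹·∇Λ`, which is negligible where data are informative and
grows in data-poor years (the catches-only years before 1982). Self-test
recovery is consequently excellent in well-observed years and degrades at
the design's edges; the shipped tests measure recovery at a strict 1%
tolerance for every year and the simulation reports carry the actual
errors. The same mechanism produces the deliberate downward F bias under
Λ5–Λ6 in the highest-F years.

## Synthetic data

The generator emulates the Subarea 48.1 design: six surveys
(summer/winter acoustic, summer/winter IKMT, summer/winter RMT8) with
index years laid out over the real survey eras (German-era trawls in the
1980s, research surveys 1992–2016, winter series in the 2010s) totalling
54 index and 35 composition years; 41 catch years and 13
fishery-composition years. True parameters default to the pre-specified
initial values; recruitment deviations are drawn at σ_R = 0.7 and log-F
deviations follow a power ramp to F = 0.35 in the terminal year with
lognormal jitter (a developing fishery). Index CVs are 0.3 (acoustic) and
0.4 (trawl), catches use the 0.1 catch CV, and effective sample sizes
default to 100 — field-typical values; the real per-survey CVs and
effective sample sizes are not public. What the generator does **not**
emulate: spatial extrapolation from the survey grid to the subarea,
time-varying growth or selectivity, and sex structure. Passing tests on
these data demonstrate the machinery's correctness under the assumed
error structure, not the field accuracy of any krill assessment.

## Scale choices

Everything heavy is scaled for a single desktop core and exposed as
arguments: replicate counts (tests use 1–2; the full protocol uses 20,
with 5 for simulation refits), MCMC length (50 000 on toy targets;
100 000 default on fits), and the dominance chain (one seeded bundle).
The published 22-configuration grid, 20-replicate tournaments and
10M–100M-sample chains run through exactly the same code paths.

## Known limitations

- Absolute negative log-likelihoods are not comparable to ADMB output
  (different dropped constants, penalty reconstruction, synthetic data).
- The growth group, when estimated, falls back to finite-difference
  gradients and converges poorly — consistent with growth being treated
  as inestimable in the source assessment.
- The self-test displacement analysis above bounds what "recovery" can
  mean under penalized likelihood; a 1%-everywhere criterion is not
  attainable in data-void years under any realistic error setting.
- Configurations estimating σ_R or steepness alongside many other groups
  sit on likelihood ridges; they converge at desk scale but their
  uncertainty estimates should be read with the same caution the
  diagnostics imply.
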