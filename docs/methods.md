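# Methods

## Growth response

Ring widths (mm, two cores per tree, North and South) are averaged per
year; years covered by a single core use that core alone. Historical
diameter is reconstructed backwards from the diameter measured on the
standing tree, `dbh_{y-1} = dbh_y − 2·w_y/10` (two radii per diameter,
mm→cm), with no bark correction — the measured dbh is treated as the
outermost ring boundary. Basal area increment is the year-on-year
difference of stem cross-sectional area; its increments telescope exactly
to the total area change, which the tests exploit as an identity. The
analysis window is clipped after reconstruction (default 1981–2021).
Chronology reliability is summarized by the expressed population signal,
EPS = n·r̄/(n·r̄ + (1 − r̄)), with r̄ the mean pairwise Pearson correlation
of raw widths over common years — no detrending is applied before the
correlations, so EPS values are not comparable with chronologies built on
detrended indices.

## Community covariates

Fungal tables (counts or relative abundances; AMF virtual taxa or EMF
genera) are row-normalized and Hellinger-transformed (elementwise square
root), putting each tree's community on the unit sphere. Seven dominant
taxa enter the model. The selection rule — PCA of the column-centered
Hellinger matrix, importance_j = Σ_{c≤3} |loading_{j,c}|·varfrac_c, ties
broken by mean abundance then taxon id — is a deterministic stand-in for
an ordination-guided choice whose exact weighting cannot be pinned down;
an abundance-ranking alternative is exposed (`method="abundance"`). Using
absolute loadings makes the score invariant to the SVD sign ambiguity.
Per-tree coverage of the selection is the summed relative abundance
(squared Hellinger values) of the chosen taxa.

## The hierarchical model

BAI is log-normal with a process mean linear in: intercept, ln dbh, net N
mineralization, the previous year's per-tree standardized BAI (lag), age,
minimum May temperature, optional neighborhood basal-area covariates, and
the seven fungal abundances in linear, quadratic and Nmin-interaction
form. Continuous covariates are z-scored over the model rows (first year
per tree dropped — it has no lag); the quadratic and interaction terms are
formed *after* standardization, so all reported coefficients are on the
standardized scale. The variance grows with tree size, σ² = a + b·ln dbh.

Two conventions deserve note:

- **Size timing.** The size covariate and the variance function use the
  start-of-year diameter (the dbh at the end of year y−1) for the row of
  year y. Growth in a year cannot depend on the diameter that growth
  itself produces; using the lagged boundary keeps the generative model
  well-defined and is applied identically on the fitting side.
- **Prior scale reading.** The diffuse priors Normal(0, 1000) and
  logNormal(1, 1000) read their second argument as a **variance** (a
  precision reading would make them sharply informative, contradicting
  their purpose); a configuration switch (`PriorConfig.scale_is_variance`)
  provides the precision convention. Likewise the Wishart(I₇, 7) prior
  sits on the **precision** matrix Ω shared by the β and γ blocks
  (conjugate Gibbs update); a covariance reading is available behind
  `wishart_on="covariance"` with a Metropolis update. β and γ are two
  7-dimensional blocks sharing Ω, not one 14-dimensional block.

### Sampling

Metropolis-within-Gibbs over blocks (α | β | γ | μ | (a,b) | Ω), plus one
joint move across all coefficient blocks per sweep — cross-block posterior
correlations (intercept vs quadratic terms, linear vs interaction terms)
throttle pure blockwise updates, and the joint kernel restores mixing.
Random-walk proposals are preconditioned by each block's conditional
Gaussian covariance (recomputed mid-burn-in); scalar proposal scales adapt
only during burn-in toward ~30% acceptance, then freeze, so the retained
chain has the exact invariant distribution. The (a,b) proposal is shaped
by the Fisher information in centered coordinates σ² = c + b·(ln dbh −
mean); the raw pair is nearly collinear because ln dbh varies little
within a stand. σ² positivity is enforced by rejection (−∞ sentinel), not
reparameterization. Per-chain seeds derive deterministically from the
master seed; defaults are 3 chains, 10,000 burn-in, 50,000 iterations,
thinning 10. Convergence is summarized by split-R̂ and effective sample
size (via ArviZ); R̂ > 1.1 warns but does not abort.

Model comparison uses DIC = D̄ + p_D with p_D = D̄ − D(θ̄); if the
posterior mean lies outside the valid variance region, p_D falls back to
half the deviance variance (flagged). Fit quality is the squared Pearson
correlation between exp(D̄) and observed BAI.

### Scenario engine

All four simulation sets draw coefficient vectors (resampled posterior
rows, or a multivariate normal on the posterior mean and full coefficient
covariance when only a summary is available; non-positive-definite
covariances are repaired by eigenvalue clipping at 1e-10) and report the
systematic component exp(D) per draw — the log-normal *median* — so
intervals reflect coefficient uncertainty alone. Flags add the σ²/2 mean
correction and/or observation noise. Non-focal covariates sit at their
dataset averages; grids span observed ranges only (no extrapolation).
Contrast significance uses the 95% interval of the *paired* difference,
which is correct under correlated draws, not interval overlap. Note that
the high/low five-tree profiles deliberately carry their own soil-N
averages ("realistic levels"), so a direct N effect alone can separate
them even when every fungal coefficient is zero.

## The synthetic study

The generator emulates the field design: 12 even-aged locations spanning
an N-mineralization gradient (location means evenly spaced over 2–12
assay units, 5% CV within-location jitter), five trees per location, 40
ring years, initial dbh uniform on 5–20 cm, final ages 80–120 yr, minimum
May temperature iid Normal(5, 1.5²) per location-year, and Dirichlet
communities of 20 taxa whose seven dominant members (concentrations
2.2–1.4, each ≳6% of the community, jointly ~85–89% coverage — comparable
to the 54–83% the dominant block covers in field data) shift log-linearly
along the gradient with slopes ±0.45–0.7, over a tail of 13 rare taxa
(concentration 0.15 each). Growth is then simulated forward from the
model's own process: D from the truth coefficients on standardized
covariates, BAI ~ LogNormal(D, a + b·ln dbh), diameter updated by
inverting the BAI formula, ring widths = 5·Δdbh split into two cores with
mean-preserving multiplicative noise (±15%). Default truth coefficients
(α = 2.0, 0.5, 0.15, 0.2, −0.2, 0.1; |β| 0.06–0.12; γ mostly negative;
|μ| 0.05–0.08; a = 0.010, b = 0.012) place the fungal effects well below
the size and climate effects, mirroring the effect hierarchy reported for
mature stands.

**Standardization self-consistency.** The fitting stage z-scores
covariates over the realized model rows, so the generator must use those
same moments for the truth coefficients to be the estimands. Exogenous
covariate moments are computed up front. The two endogenous pieces — the
ln-dbh moments and the per-tree BAI mean/SD behind the lag term — satisfy
a fixed-point system solved with common random numbers: a lag-free pass
for starting values, damped iteration with per-tree best-iterate
tracking, and a joint Newton polish. When the polish converges (the usual
case) the system is exact to ~1e-12 and the design matrix times the truth
reproduces the latent process mean to machine precision. The
self-referential lag dynamics are, however, chaotic for a small fraction
of trees — tame and explosive trajectory branches with no common root —
and for those trees the generator freezes the best tame reference
moments; the residual gap behaves as mild per-tree heterogeneity around
the nominal lag coefficient, and a saturating bound (|z| ≤ 8) on the lag
transfer keeps such trajectories finite. The first ring year is generated
with the lag anomaly at zero and is never a model row.

**What the generator does not emulate:** spatial autocorrelation beyond
location structure, crossdating error, missing or locally absent rings,
sequencing depth variation and compositional zero-inflation beyond what
the Dirichlet produces, and climate trends (May temperature is iid). A
passing recovery test therefore shows the estimator is correct under the
model's own assumptions, not that those assumptions hold in any field
data set.

## Known limitations

- **Lag-term endogeneity.** The lag covariate is the per-tree z-score of
  the full observed BAI series, whose mean and SD involve the same-year
  response. The resulting regressor-error correlation attenuates the lag
  coefficient by roughly −0.02 to −0.04 on the standardized scale
  regardless of sample size (verified by least squares on exact designs),
  so at large n its 95% interval sits reliably below the truth. This is a
  property of the full-series standardization itself and would affect any
  implementation of it; all other coefficients are essentially unbiased.
- Taxon selection at small tree counts (~30) occasionally swaps the
  weakest dominant taxon for a rare one; the omitted-variable confounding
  that follows is an identification failure of the ordination stage, not
  of the model fit, and disappears at the full design size.
- The DIC fallback p_D and the covariance reading of the Wishart prior
  are implemented but exercised far less than the defaults.
- Runtime-oriented problem sizes are used throughout the test suite (30
  trees × 20 years with 5,000-iteration chains for replicated
  experiments; one 60-tree × 40-year fit with 10,000 + 10,000 iterations
  for the full-pipeline recovery check), chosen so the whole suite runs
  on a single CPU in minutes while leaving Monte-Carlo error well below
  the tolerances tested.
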