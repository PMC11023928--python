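# Methods

This note documents the statistical model, the conventions the pipeline
commits to, what the synthetic generator does and does not emulate, and
the numerical choices — in enough detail to audit or re-derive any number
the package prints.

## Design and data model

The unit of inference is a *concession pair*: an FSC-certified logging
concession matched to a nearby non-certified one.  Each concession holds a
systematic grid of cameras (28–36 by default) deployed simultaneously for
a fixed window.  Three input tables describe a survey:

- **photos** — `camera_id, timestamp, species_label, n_individuals,
  is_status_photo`.  Timestamps are timezone-naive local time; only their
  ordering within a camera matters.
- **deployments** — camera → concession → pair membership, certification
  status, deployment window, recorded downtime, site covariates
  (visibility, slope, trail type, fruiting trees, water), hunting-sign
  counts and standardized geographic covariates.
- **traits** — one row per retained species label: mean body mass (kg,
  averaged across sexes), IUCN category, taxonomic group.

Ingest conventions: humans, birds, bats, reptiles and domestic dogs are
excluded; records not identifiable to species ("indet") are excluded from
*all* rate computations, including the pooled all-mammal rate —
unidentifiable records cannot be classified by mass, IUCN status or taxon,
and using them only in the pooled analysis would make the aggregation
levels inconsistent with each other.  This is configurable
(`include_indet`) and the ingest disposition log always reports the count.
Small mammals are pooled into three identification groups (squirrels;
rats and mice; shrews).  Shrews carry taxon `rodents`; hyraxes and
aardvarks carry taxon `other`, which the taxon-level analysis omits (low
sample sizes) while every other level retains them.

Body-mass classes are half-open intervals `(lower, upper]` with default
interior edges {1, 10, 30, 100} kg.  The upper three classes are fixed by
the analysis design; the lower two edges (1 and 10 kg) are a package
choice exposed as a parameter.

## Detection events

A photo joins the current event of its camera × species stream iff its
gap to the *previous photo in the event* is strictly below the threshold
(default 10 min); a gap at or above the threshold starts a new event.
Measuring gaps photo-to-photo (rather than from the event's first photo)
is the camera-trap community norm and makes the rule independent of row
order; the alternative anchor (`event_start`) is available and caps event
duration at the threshold.  Group size is the maximum per-photo count
within the event.  Status photos never seed or extend events but do extend
the active window.  Duplicate photo rows collapse with a warning.

Effort: a camera's active window ends at `min(scheduled end, last photo +
12 h)` — the status-photo schedule exists precisely so that a dead camera
is detected within half a day — then recorded `downtime_days` are
subtracted and the result clipped at zero.  Effort is kept in fractional
days.  Only a single contiguous downtime subtraction is supported;
scattered mid-deployment obstruction windows are not modelled.

## Rates and the biomass proxy

`rate = Σ(event group sizes) / effort`, at camera level (model input) or
concession level (display, biomass).  Rates are additive over disjoint
species sets, so aggregated rates are sums of member-species rates, and
absences are explicit zero rows.  The biomass proxy is `Σ_s rate_s ×
mass_s` (kg per camera-trap day).  A literal second division by effort —
an alternative reading of the same verbal recipe, which would double-count
effort since the rate already contains it — is available behind
`literal_effort_division` for comparison.  The proxy is relative: it ranks
concessions but is not an absolute biomass estimate.

## Mixed model and contrasts

Response: camera-level encounter rate, identity scale by default.  The
identity scale matches plotting model predictions directly on rate axes;
`log1p` is first-class for heavy-tailed communities and every report names
the transform used.  Fixed effects: certification status, optionally a
group factor (mass class, IUCN category or taxon) with its interaction,
optionally standardized geographic covariates with quadratic terms.
Random intercepts: pair, concession-within-pair, camera-within-concession.
Fitting uses statsmodels `MixedLM` (pair as the grouping factor; lower
levels as variance components).  A level whose units contribute a single
row each (e.g. cameras in the pooled analysis) is aliased with the
residual and dropped automatically.  Variance components hitting the zero
boundary flag the fit `singular` but are not an error.

- **Estimation:** REML for reported fits; ML likelihoods for model
  comparison.  `BIC = −2 logL_ML + k log n` with `n` = camera-level
  observations and `k` counting fixed effects plus variance parameters.
  Covariate selection is exhaustive over subsets of ≤ 2 z-scored
  candidates (each optionally quadratic), continuing forward if more
  candidates exist; ties break toward fewer parameters.
- **Contrast df (containment):** certification varies between concessions
  within pairs, so contrasts use `df = n_concessions − n_pairs − 1` (6 in
  the 7-pair design) — equivalently the paired t-test df — rather than
  anti-conservative camera-level df.
- **Effect scale:** per group, estimated marginal means (EMMs) at
  covariate means for each status; the reported effect is the
  response-scale ratio `EMM_cert / EMM_noncert` with a delta-method SE
  (gradient through `expm1` under `log1p`).  A non-positive denominator
  leaves the ratio undefined (NaN) rather than fabricated.
- **Multiplicity:** within a family of m group contrasts, adjusted
  p-values are `P(max_j |T_j| ≥ |t_i|)` under the m-variate t with the
  contrasts' estimated correlation and the containment df, evaluated by
  scrambled-Sobol quasi-Monte-Carlo (default 2^17 draws, fixed seed, MC
  standard error reported).  Estimates are clamped to the exact bounds
  `p_raw ≤ p_adj ≤ min(1, m·p_raw)`; with m = 1 the raw p is returned
  unchanged.

Degenerate behaviour is pinned by tests: in balanced designs the fixed
effects equal OLS exactly; collapsed to concession means with only the
pair intercept, the certification test reproduces the closed-form paired
t-test.

## Paired tests

Wilcoxon signed-rank, two-sided: zero differences dropped (Wilcoxon's
convention — with 7 pairs each convention is visible, so it is stated
here), absolute differences mid-ranked, `W` = rank sum over positive
differences.  For ≤ 25 non-zero differences the p-value is exact: the
distribution of `W` over all 2^n sign assignments is built by integer
convolution over the (doubled, hence integral) rank multiset, which
enumerates exactly the 2^n assignments without materializing them.  Beyond
that, a normal approximation with tie-corrected variance and continuity
correction.  Hunting signs are compared as the per-concession proportion
of camera sites with ≥ 1 sign (cartridges + snares + camps on approach).

Habituation: daily observation counts per concession, aligned to
deployment day 1 with explicit zero days, truncated to the first 68 days
(the shortest deployment in the target design; longer windows are
truncated with a warning).  OLS of `log(n_obs + 1)` on
`day + day:status + concession intercepts`; the status main effect is
absorbed by the concession intercepts.  The `+1` offset is the standard
remedy for zero-count days.  The day × status interaction is the reported
quantity: a certification-dependent time trend would indicate differential
trap-shyness rather than abundance differences.  The unit is the
concession-day; pooling cameras within concessions matches the level at
which the status is defined.

## Synthetic generator

Detections of species s at camera c in concession j of pair i arrive as a
Poisson process with rate

`base_rate_s × multiplier_s^[certified] × exp(u_i + u_j + u_c)`,
`u ~ N(0, sd²)` on the log scale,

the simplest positive-valued hierarchy that yields the nested variance
structure the model assumes.  Defaults mirror the target design: 7 pairs,
28–36 cameras per concession, 80-day deployments, triple-photo bursts
(1.5 s apart, per-photo counts ≤ the event's group size with the maximum
attained at least once), 12-h status photos, log-scale sds (0.40, 0.25,
0.50) for pair/concession/camera.  Group sizes are shifted-Poisson
(`1 + Poisson(mean−1)`), drawn once per event.  Downtime is a single
terminal outage (10% of cameras, mean 8 days lost): the camera's photo
stream simply stops, and recorded downtime stays 0, so effort recovery is
exercised through the status-photo rule exactly as in the field protocol.
Hunting signs are Poisson per camera (mean 0.25 certified / 0.90 not).

The default community has 27 species covering all five mass classes, six
analysable taxa plus `other`, and five IUCN categories, with heavy-tailed
rates (common duikers and rodents, rare elephants and pangolins).
Certification multipliers are class-based — 1.0 below 10 kg, 3.5 / 2.5 /
2.7 for 10–30 / 30–100 / >100 kg — and the rate composition was chosen
analytically so the pooled group-weighted ratio sits near 1.5.  Per-species
rate magnitudes are plausible for central-African forest camera grids, not
calibrated to any deposited dataset.

What the generator does *not* emulate: spatial structure (the 1-km grid is
metadata), animal movement and home ranges, diel activity, detection-
probability variation with vegetation or camera model, overdispersed
(non-Poisson) clumping of visits, mid-deployment outages and seasonal
trends.  Passing tests therefore demonstrate correctness of the estimators
under the model's own assumptions and calibrated inference under realistic
hierarchical noise — not robustness to every field pathology.

## Numerical choices and problem sizes

- Optimizer: `MixedLM.fit` with lbfgs, falling back to bfgs then powell on
  non-convergence; warnings suppressed inside the fit wrapper and surfaced
  as `converged` / `singular` flags.
- Quasi-Monte-Carlo draws are rounded up to a power of two (Sobol balance).
- Determinism: every stochastic routine takes an explicit seed or
  generator; identical seeds give byte-identical CSV outputs.
- Simulation studies in the test suite run at the design sizes they make
  claims about: ratio recovery and small-class null behaviour at the full
  default design over 200 replicates; type-I error of the certification
  contrast over 500 replicates (observed rejection within [0.03, 0.07] at
  nominal 0.05); the event-clustering oracle over 1,000 random streams of
  up to 200 photos; exact Wilcoxon against full enumeration for all
  n ≤ 12.  Smaller designs (3 pairs, fewer cameras, 30–40 days) are used
  for BIC-selection consistency and habituation power checks, where the
  claim is qualitative.
- The acceptance script reports single-survey descriptors at the default
  design and ratio estimates averaged over 40 replicate surveys.

## Known limitations

- Rates are treated as Gaussian at the camera level; a count GLMM
  (Poisson/negative-binomial with an effort offset) is the natural
  extension for very rare species, where the identity-scale LMM relies on
  averaging.
- The ingest path accepts only the documented CSV schema (plus an alias
  table); exports from annotation tools must be mapped to it upstream.
- Containment df is a deliberate conservative choice; Satterthwaite or
  Kenward–Roger approximations are not implemented.
- The biomass proxy inherits every detection-probability caveat of
  encounter rates, amplified by body-mass weighting.
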