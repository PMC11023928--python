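# camtrap-pairs

Encounter-rate analysis for paired camera-trap surveys of logging
concessions, built for the question: *do mammals fare better under
FSC-certified forest management than under conventional logging?*  The
package takes photo-level camera-trap annotations from a blocked design —
pairs of nearby concessions, one certified and one not, each carrying a
systematic 1-km camera grid — and carries them through to
multiplicity-adjusted certification-effect estimates.  A synthetic-survey
generator with the same hierarchical structure makes every stage testable
without field data.

Intended users are quantitative ecologists and conservation analysts who
work with camera-trap data in Python.

## What it computes

1. **Independent detection events.** Photos of one species at one camera
   are clustered with a temporal-independence rule: a photo extends the
   current event while its gap to the previous photo is `< t` (10 min by
   default); a gap `>= t` starts a new event.  The event's group size is
   the maximum per-photo individual count.  A sensitivity table recomputes
   event counts at 10/30/60/1440 min.
2. **Effort-corrected encounter rates.** Sampling effort is active
   camera-days: the deployment span, truncated where the photo stream
   (status photos every 12 h) shows a camera died, minus recorded
   downtime.  The encounter rate is

   `rate = (sum of event group sizes) / effort`   [observations per camera-trap day]

   computed per camera or per concession, for all mammals pooled and
   aggregated by body-mass class ((0,1], (1,10], (10,30], (30,100],
   (100,inf) kg), IUCN category and taxonomic group, plus a relative
   biomass proxy `sum_s rate_s * mass_s`.
3. **Nested mixed-effects inference.** Camera-level rates are modelled as

   `y_ijkg = beta0 + beta1 * cert_ij (+ group + cert:group + covariates) + u_i + v_ij + w_ijk + e`

   with random intercepts for pair `u_i`, concession-within-pair `v_ij`
   and camera `w_ijk` (statsmodels `MixedLM`; REML for reporting, ML for
   BIC-based covariate selection).  Certification contrasts use
   containment degrees of freedom (`n_concessions - n_pairs - 1`), and
   per-group families are adjusted with a multivariate-t max-|T|
   procedure on the contrasts' estimated correlation.  Effects are
   reported as response-scale rate ratios (certified : non-certified).
4. **Paired tests and diagnostics.** Exact two-sided Wilcoxon signed-rank
   tests (full sign-flip enumeration, mid-ranked ties, zeros dropped) for
   hunting-sign and site-covariate comparisons across pairs, and a
   habituation check regressing log daily observation counts on
   deployment day x certification status.

## Worked example

`examples/encounter_rates_and_ratios.py` simulates a 7-pair survey from
the default community (certification multipliers 3.5/2.5/2.7 above 10 kg,
none below), fits the interaction model and prints:

```
    group  emm_certified  emm_noncert  ratio       t  p_raw  p_adj
   0-1 kg         0.9260       0.9333 0.9922 -0.0611 0.9532 1.0000
  1-10 kg         1.1494       1.1261 1.0207  0.1952 0.8517 0.9927
 10-30 kg         1.3879       0.3917 3.5433  8.3574 0.0002 0.0003
30-100 kg         0.7731       0.3012 2.5671  3.9596 0.0075 0.0135
  >100 kg         0.3547       0.1235 2.8721  1.9397 0.1005 0.1677

contrast df (containment): 6; variance components: {'pair': 0.1164, 'concession': 0.1728, 'camera': 0.0406, 'resid': 0.1183}
```

`emm_*` are estimated marginal mean encounter rates (observations per
camera-trap day) by status; `ratio` is their quotient — the estimated
certification effect per body-mass class — and `p_adj` the max-|T|
adjusted p-value.  The >10 kg classes recover their simulated 2.5-3.5x
effects; the sub-10 kg classes sit at ratio ~1 and stay non-significant.
Other example scripts cover survey simulation, event clustering, the
paired hunting-sign/habituation tests and the one-call pipeline
(`cp.run_pipeline(RunConfig(...))`), which writes rate tables, ratio
tables, test results, figures and a `summary.json`, every file stamped
with the configuration hash.  A thin CLI mirrors the stages:
`camtrap-pairs simulate | events | rates | fit | test | report`.

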