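# Methods

## The experimental system being modelled

One microcosm is a jar with 48 leaf discs drawn from 1–4 riparian species
(equal disc numbers per species), incubated 21 days at constant temperature,
with water changes on days 7, 14 and 21 whose outflow is filtered to collect
fine particulate organic matter (FPOM). Half of the microcosms receive three
leaf-shredding caddisfly larvae. The full design crosses every non-empty
subset of the species pool with detritivore presence: 15 composition
treatments × 10 replicates = 150 microcosms for a four-species pool, five
replicates per treatment in each arm. Masses are mg throughout; time is in
days.

The bundled default species pool is the four-species set A (*Alnus
glutinosa*, a nitrogen fixer with soft, nutrient-rich leaves), C (*Corylus
avellana*), Q (*Quercus robur*) and I (*Ilex aquifolium*, evergreen, tough),
with their measured trait table (N%, P%, SLA, toughness, ash%),
per-species leaching factors (0.753, 0.843, 0.844, 0.767) and the case-length
allometry DM = 0.0043·CL^2.8041. The species set is open: any trait table
with the canonical columns works.

## Derived responses

* **Mass loss** = air-dry initial mass × leaching factor − final AFDM, per
  species. The leaching factor maps pre-leach air-dry mass directly to
  post-leach AFDM in a single multiplicative step, because it is estimated
  from extra microcosms measured as post-leaching AFDM; no separate ash
  correction is applied on the initial side. Negative losses (apparent mass
  gain from handling variance) are preserved and flagged, never clipped.
* **Normalisation**: in the detritivore arm, mass loss and FPOM are divided
  by the summed allometric initial dry mass of the three larvae; the initial
  mass is always the allometric estimate, never measured. Per-species and
  total responses share the same divisor, so the partition is unaffected by
  where the division happens.
* **Growth** = (final − initial)/initial × 100 on detritivore dry mass.

## Additive partitioning

Implemented exactly in the classical form: with proportions p_i, monoculture
means M_i and per-species mixture responses Y_O,i,
ΔRY_i = Y_O,i/M_i − p_i, net = ΣY_O − Σp_i·M_i, CE = N·mean(ΔRY)·mean(M),
SE = N·cov(ΔRY, M) with the *population* covariance (divide by N) — the only
convention under which net = CE + SE is an exact identity, which the code
asserts to 1e−9. Proportions default to 1/N (equal disc numbers); a
mass-based weighting hook exists but is off by default because the design
seeds equal disc counts, not equal masses.

Partitioning is computed per mixture replicate against monoculture *means*
(microcosms are unpaired); an `on_means` mode collapses replicates first —
the means coincide because the statistic is linear in the observed responses,
only the spread differs. Contribution percentages use absolute values,
CE% = 100·|CE|/(|CE|+|SE|), the convention that remains meaningful when SE is
negative. For FPOM only the net effect (observed − expected total) is
defined, since species contributions to a mixture's FPOM cannot be separated.

**Testing a net effect against zero.** The net effect estimate subtracts
monoculture means that are themselves noisy; a one-sample t-test across
mixture replicates conditions on those means and is anti-conservative
(in the no-detritivore arm the monoculture-mean term dominates the sampling
variance). `net_effect_test` therefore combines both variance sources,
s²_obs/n_obs + Σp_i²s_i²/n_i, with Welch–Satterthwaite degrees of freedom.
CE/SE p-values remain replicate-level t-tests conditional on the monoculture
means, and are documented as such.

## Trait metrics

Traits are z-scored across the species included in the analysis; the scale is
the sample SD (ddof = 1) by default, configurable to the population SD. Trait
distance is Euclidean in z-space; mixture trait variability is the mean over
the C(N,2) within-mixture pairs; mixture trait means weight each species by
its corrected initial AFDM. The original study's clustering software and its
standardisation settings are not recoverable, so this convention is
documented and configurable rather than claimed to reproduce any printed
distance table bit-for-bit.

## Inference

The group-comparison model is one-way with a separate residual variance per
group, the `gls` + `varIdent` variance-structure model. Because the mean
structure is saturated, the REML estimates have closed form
s_k² = SS_k/(n_k − 1); the group test is a Wald F on the means with
covariance diag(s_k²/n_k), denominator df = N − K (containment, matching
conventional gls output). With variances constrained equal the F collapses to
the textbook one-way ANOVA F, and with two groups the unconstrained F equals
the squared Welch t — both are asserted in tests, along with agreement with
nlme's gls/varIdent fit (F, p, per-group variances and REML log-likelihood)
on a frozen dataset.

Pairwise comparisons use group-specific SEs, per-pair Satterthwaite df and
the Tukey–Kramer studentized-range tail; the adjusted p is floored at the raw
p. Letters come from the sweep algorithm (split an all-inclusive set on each
significant pair, drop absorbed subsets), ordered by group means with ties
broken by label.

Trait–effect regressions are OLS with an F test of the slope. With the log
transform requested, both sides are logged when all values are positive;
non-positive predictors are an error listing the offending rows, while
non-positive effects (possible for selection) trigger a logged fallback to an
untransformed response. Replicate-level effects are regressed on
mixture-level trait summaries. α = 0.05 throughout.

## Synthetic data generator

Noise-free mechanics per microcosm (T = duration, B = detritivore biomass):

* post-leach AFDM m_i = discs × disc mass × leaching factor; disc mass
  defaults to disc area / SLA;
* microbial loss m_i(1 − e^(−k_i T)); default k = 0.016, 0.010, 0.007,
  0.005 d⁻¹ for A, C, Q, I — fastest for the nutrient-rich species, slowest
  for the evergreen, giving 10–30% microbial mass loss over 21 days;
* consumption demand C = γ^[N>1]·c·B·T (default c = 0.15 mg·mg⁻¹·d⁻¹,
  γ = 1.3), allocated across species ∝ seeded proportion × preference
  weight, where the weight is the species' leaf-N concentration raised to
  the preference exponent (default 1). Allocation is capped at each
  species' availability, with surplus redistributed proportionally among
  uncapped species. Allocating on seeded proportions (rather than realised
  availability) is what makes the γ = 1, equal-preference configuration
  *exactly* null: each mixture species then loses precisely p_i times its
  monoculture loss;
* FPOM = 0.05 × microbial loss + 0.40 × consumption (egestion), split across
  water changes in proportion to elapsed time;
* growth: final DM = B + AE·C − maintenance·B·T with AE = 0.30 and
  maintenance = 0.0349 d⁻¹, calibrated so the design-wide mean detritivore
  growth is ≈42% over 21 days;
* larvae: three per microcosm, mean 5.94 mg each (≈17.8 mg per microcosm),
  CV 12%; case lengths are back-solved through the inverse allometry so the
  pipeline recovers the biomass exactly.

Noise is multiplicative lognormal with unit mean on final masses and larval
masses (CV 5% and 12%) and additive truncated-at-zero Gaussian on filter
masses (SD 0.3 mg). A single seed drives per-microcosm substreams keyed by
(treatment, arm, replicate), so adding replicates never alters existing
microcosms and identical configurations are byte-identical.

With both mechanisms on (the default), the generator reproduces the headline
structure of the study system: diversity effects on decomposition and FPOM
appear only in the detritivore arm, complementarity dominates (CE% ≈ 74–80 in
mixtures containing species A, ≈99 in CQI), and the selection effect is
positive only where species A — which has both the preference weight and the
top monoculture loss — is present, slightly negative in CQI.

What the generator does *not* emulate: time series of litter mass (endpoint
only), microbial community dynamics, temperature effects, density-dependent
feeding, and the observed *absence* of a growth response to diversity — the
growth budget follows consumption, so mixtures grow larvae faster, whereas
real detritivores appear to modulate growth efficiency. Passing recovery
tests therefore demonstrates correctness of the analysis chain under the
stated mechanisms, not realism of any particular dataset.

Two closed-form caveats surfaced by the exact ground truth: (i) with γ
applied to consumption only, the expected selection effect in mixtures is not
exactly zero under equal preferences — the consumption share interacts with
between-species microbial variation — but is < 10% of CE in magnitude, so
recovery tests assert |SE| small rather than zero; (ii) pure preference
re-allocation conserves total consumption, so its net effect is ≈0 and CE
≈ −SE rather than 0; the selection-only scenario is therefore checked on the
sign and magnitude of SE.

## Problem sizes and numerical choices

Tests run the 15×10 design (150 microcosms) for recovery checks and a 15×20
variant for the qualitative-structure checks, where the CE/SE split needs
more Monte-Carlo resolution than five replicates per arm provide; both
complete in seconds. Partition identities are asserted at 1e−9; REML closed
forms are exact, so no iteration or convergence tolerance exists; degenerate
inputs (zero-variance groups, flat regression responses, single-species
distance matrices) return defined values (F = 0, p = 1, empty matrix with a
warning) rather than NaNs. All randomness flows through
`numpy.random.default_rng` seeded explicitly.

## Known limitations

* The heteroscedastic Wald F with containment df is approximate for small,
  unbalanced groups; it matches gls conventions, not a simulation-calibrated
  small-sample correction.
* Compact letter displays are not guaranteed minimal in pathological
  significance patterns (the sweep algorithm can over-letter).
* The supplementary-workbook importer expects the flat canonical schema on
  the first worksheet and refuses layouts without per-species mass columns.
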