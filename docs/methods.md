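# Methods

This note records the statistical model behind `vcarm`, the conventions and
numerical choices the implementation fixes where the method leaves room,
what the synthetic-data generator does and does not emulate, and the known
limitations.

## Model and procedure

A virtual control arm replaces a randomised standard-of-care (SOC) group
with a per-patient prediction of survival under SOC. The pipeline assumes a
black-box baseline predictor that maps each patient's covariates to a
15-year overall-survival probability ŝ15; the package never looks inside
the predictor and consumes its output as an input column.

**Calibration.** Baseline predictors are routinely miscalibrated for a
specific trial population. The correction is a per-subgroup
observed/expected ratio at the horizon: c_g = KM_g(15) / mean_g(ŝ15),
fitted on a training trial and applied multiplicatively (clipped to [0,1])
to each new patient. Subgroups are age band (20–39, 40–59) × receptor
class (ER−/PR−, ER+/PR−, ER−/PR+); ER+/PR+ tumours and ages above 60 are
excluded before any fitting. Corrections are stored and applied at full
precision; ratios of rounded table entries demonstrably do not reproduce
full-precision multipliers, so rounding is display-only (3–4 decimals).
Corrections above 1 are allowed (an under-predicting baseline). No
shrinkage is applied to small subgroups; an empty subgroup yields no
correction and, by default, an error when a validation patient needs it
(an explicit flag falls back to the pooled correction with a warning).

**Mortality fraction.** A single horizon probability carries no yearly
shape, so a reference cohort supplies one: f_t = (S_ref(t−1) − S_ref(t)) /
(1 − S_ref(15)), the share of total 15-year mortality occurring in year t.
The published reference table's caption describes this ratio in the inverse
orientation (total mortality divided by the survival difference), which
cannot yield fractions ≤ 1; the implementation uses the orientation above,
which reproduces the table's printed columns and sums to 1 — an
erratum-style note rather than a methodological choice. Two fixtures ship:
the full SEER 1993–96 breast-cancer cohort, and the analysis-matched
non-ER+/PR+ / ages 20–60 / stage II/III subset (the default, because the
full cohort skews toward better-prognosis ER+/PR+ disease and
underestimates early mortality for the analysis population). The subset's
printed fractions sum to 1.001 under rounding; they are renormalised on
load (logged, raw values retained) because the allocation identity
S_15 = s15 requires Σf = 1 exactly. Whether the original analysis
renormalised is unknown; the choice is ours and is flagged in provenance.

**Allocation.** S_t = 1 − (1 − s15)·Σ_{i≤t} f_i, with conditional death
probabilities q_t = (S_{t−1} − S_t)/S_{t−1} (defined as 1 where S_{t−1}=0,
which is unreachable by simulation and preserves q ∈ [0,1]). Composing
`compute_fractions` with `allocate_schedule` at s15 = S_ref(15) returns the
reference curve exactly; reconstructing S from q recovers S to machine
precision.

**Simulation.** Per patient, sequential yearly draws X_t ~ Uniform(0,1):
death in the first year with X_t < q_t, otherwise administrative censoring
at 15 years. The default is a single simulated realisation per patient,
matching the method as originally applied; a replicates flag repeats the
simulation with independent streams and reports comparisons per replicate
(never pooled) for sensitivity analysis. Seeding: one master seed spawns a
substream per (replicate, patient) keyed by a SHA-256 hash of the patient
id, so results are deterministic and invariant to cohort row order.

**Comparison.** Kaplan–Meier product-limit curves with Greenwood variance
S(t)² Σ d_j/(n_j(n_j−d_j)), evaluated on the yearly grid by carrying the
last step forward. Conventions: tied deaths form one risk-set step with
d_j > 1; censorings at a death time remain in that risk set; where the
curve reaches 0 the Greenwood sum is undefined and the SE is reported as 0.
Confidence intervals are plain Wald, Ŝ ± 1.96·SE clipped to [0,1] — chosen
because the published intervals are symmetric around the estimate and are
reproduced by width/3.92 arithmetic; transformed (log(−log)) intervals
would not match. The critical value is fixed at 1.96 (configurable);
whether the original analysis used a longer expansion is indeterminable
from rounded tables. Observed vs virtual arms are compared at each year
1..15 with a two-sided two-sample Z test on the KM estimates,
z = ΔŜ/√(SE²+SE²); no multiplicity adjustment is applied by default (a
Bonferroni switch exists for users who want one). p-values are reported to
3 decimals, with values below 0.001 rendered "<0.001".

Note the Greenwood SE is *not* monotone in t even while events accrue: the
cumulative sum Σ d/(n(n−d)) is nondecreasing, but SE = S·√Σ can fall when
S drops sharply. The property tests assert monotonicity of the relative
variance, which is the correct invariant.

**Edge rules.** Age exactly 60: the exclusion rule drops ages *above* 60
while the band labels stop at 59; the package keeps age 60, maps it into
the 40–59 band (so it receives that band's correction) and warns. This is
our resolution of an ambiguity, not an inference about the original
analysts' intent. Follow-up may be supplied in years or days (converted by
365.25). Records with a missing baseline prediction are rejected unless a
flag routes them to a caller-registered predictor. If no subject remains
at risk at the horizon, the KM plateau is carried forward with a warning.

## Synthetic-data generator

`vcarm.synth` draws trials whose ground truth is known exactly, so every
pipeline stage can be tested against a closed form:

- subgroup mix defaulting to the training trial's published sizes
  (250/70/61/634/295/140 over the six subgroups);
- true 15-year survival per subgroup defaulting to the published observed
  values (0.527/0.337/0.508/0.488/0.413/0.529), spread over years by the
  SEER-subset fractions — i.e. truth follows the same discrete-time
  mechanism the simulator uses;
- a treatment effect entering as a discrete-time proportional-hazards
  multiplier q′_t = 1 − (1 − q_t)^hr on the experimental arm (default 0.7,
  a paclitaxel-sized benefit). Modelling the effect on hazards rather than
  as a shift in s15 keeps the generator aligned with the simulation
  mechanism while making the virtual control (which assumes SOC) wrong for
  the treated arm in exactly the way the design exploits;
- a miscalibrated predictor emitting clip(s_g/c_g + ε, 0, 1) with
  ε ~ Normal(0, σ), σ = 0.02 by default — additive Gaussian noise was
  chosen over a beta model for transparency, as no per-patient error model
  is prescribed anywhere;
- yearly independent dropout, default 0.03/year, chosen to reproduce the
  published at-risk-column attrition beyond deaths (679 → 242 at year 15
  in the experimental arm implies roughly 3%/year losses);
- arm sizes defaulting to the validation trial's ≈680/arm and a training
  cohort of 1450.

What the generator does **not** emulate: covariate-driven prediction (the
synthetic predictor sees the subgroup truth, not tumour size or nodes),
continuous event times (everything is integer years), competing risks,
non-independent censoring, calendar-time drift between training and
validation eras, and any real predictor's error structure. Passing tests
therefore validate the pipeline's arithmetic and its operating
characteristics under the stated mechanism — they say nothing about
whether any particular real predictor is transportable to a given trial.

## Test and acceptance design

Problem sizes were chosen so each check estimates its quantity with
sampling error well inside the stated tolerance: correction recovery
averages 20 independent replicates of n = 2000 per subgroup (a single
replicate's KM noise on the ratio reaches σ ≈ 0.035 where the baseline
prediction is small, so one draw cannot resolve a ±0.03 band); the
simulated-arm consistency check pools 10⁵ follow-ups; the null
(type-I) study runs 500 replicate trials at validation scale with a large
(n = 20,000) training cohort so the comparison's calibration is isolated
from correction-estimation noise; power uses 200 replicates at hr = 0.7
and ≈680/arm with paper-scale training. The type-I assertion tests the
mean per-year rejection rate against the binomial 95% band at the
replicate count — fifteen simultaneous per-year bands would false-alarm
even for a perfect implementation, and within-trial correlation across
years makes the mean-based band conservative.

## Known limitations

- **Correction noise propagates.** The yearly Z test treats the virtual
  arm's curve as independent of the observed arm's, but both depend on the
  training fit. At paper-scale training (n ≈ 1450) the correction's
  sampling error is comparable to the comparison SEs at late years and
  inflates the type-I error above nominal (rough calculation: variance
  inflation ≈1.3 at year 15, rejection ≈0.085). The method as specified
  carries this property; the package reproduces it faithfully rather than
  correcting for it. Users running confirmatory analyses should either
  train on substantially larger cohorts or account for correction
  uncertainty.
- The simulated virtual arm adds Monte-Carlo noise on top of the analytic
  allocated curve (one draw per patient by default); the comparison's SE
  accounts for it via the virtual arm's own Greenwood variance, but the
  analytic curve itself is available (`allocate_schedule`) when a
  noise-free prediction is preferred.
- Discrete yearly time: observed real-valued follow-up is compared on the
  yearly grid only.
- No competing risks, no covariate-continuous recalibration, no log-rank
  or whole-curve tests — comparisons are pointwise by design.
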