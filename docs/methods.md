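# Methods

## The developmental model

The package models honeybee caste determination as a deterministic map
from a nurse-imposed feeding regime to an expected adult phenotype,
with stochastic realization layered on top.  A feeding regime is a
triple q = (q1, q2, q3) of normalized diet coordinates in [0, 1]:

* **q1** — sugar content of the food in the pooled first three instars
  (L1–L3).  The early instars are treated as one phase because queens and
  workers each receive constant feeding schedules over it and early
  effects can be overridden in L3.
* **q2** — quality/quantity of the L4 diet (restricted for
  worker-destined larvae).
* **q3** — quantity of the L5 diet (partially restored sugar for
  workers).

The phenotype of an individual is (x, y): adult body weight x in mg and
total ovariole count y summed over both ovaries.

### JH titers

Each phase's log10 hemolymph juvenile-hormone titer (log10 pmol/mL)
responds logistically to an effective diet d:

    h = h_W + (h_Q − h_W) / (1 + exp(−(d − q_mid) / s))

where h_W and h_Q are the worker- and queen-diet asymptotes, q_mid the
diet midpoint and s > 0 the steepness scale (small s = threshold-like,
large s = graded).  Because the titer in a later phase also reflects
earlier feeding, the effective diet of L4 is a convex combination of q1
and q2, and that of L5 of q1, q2, q3, with nonnegative carryover weights
summing to one (default: equal weights).  This is the most parsimonious
form that reproduces the observed ordering of L4 titer curves for larvae
with rich versus poor early diets.

### Ovariole rescue from programmed cell death

All larvae lay down the same number y0 of ovariole primordia (queens do
not make more); workers lose most of theirs to programmed cell death
(PCD).  An ovariole escapes PCD iff the titer of its rescue phase
exceeds its own threshold h_t, with thresholds normal(mu0, sigma0)
shared across phases.  Proportions r1, r2, r3 (summing to one) of the
primordia are available for rescue in L3, L4 and L5.  The expected count
is therefore

    y = y0 · [ r1 F((h1−mu0)/sigma0) + r2 F((h2−mu0)/sigma0)
             + r3 F((h3−mu0)/sigma0) ]

with F the standard normal CDF.  Realized individuals draw each
primordium's phase label (categorical in r) and threshold independently;
the implementation samples the distributionally equivalent
multinomial-then-binomial composition, and the tests verify it against an
explicit per-ovariole simulation.

`sigma0 = 0` is rejected at construction; the step-response limit is
exercised in the tests at `sigma0 = 1e-6` instead, to keep the CDF well
defined everywhere.

### Size determination

Following the critical-weight framework for holometabolous insects, the
L4 diet sets the larval critical weight u (logistic in q2 between u_min
and u_max), the L5 diet sets the post-critical growth increment v
(logistic in q3 between v_min and v_max), and the adult eclosion weight
is the scaled maximal larval weight

    x = a0 · (u + v),   a0 ∈ (0, 1].

Adult weight deliberately has no q1 dependence: early diet acts on the
JH/ovariole axis, while the size axis is driven by L4/L5 feeding.  (A
JH-mediated growth-rate effect on size is biologically plausible but is
not modelled; see Limitations.)

Degenerate flat responses (h_Q = h_W, u_min = u_max, v_min = v_max) are
legal and useful for tests; diet coordinates exactly 0 or 1 are legal.

## Default parameters

The default parameter set (`demo_params()`) is an illustrative fixture,
not a set of literature estimates.  It is chosen once so that the
morphospace spans realistic worker-like to queen-like honeybee
phenotypes:

| parameter | value | units / meaning |
|---|---|---|
| h_W, h_Q (all phases) | 1.0, 2.6 | log10 pmol/mL JH asymptotes |
| q_mid, s (all phases) | 0.5, 0.12 | diet midpoint, steepness |
| carryover weights | equal per phase | effective-diet weights |
| mu0, sigma0 | 1.8, 0.3 | rescue threshold mean (the JH midpoint) and SD |
| r1, r2, r3 | 0.25, 0.50, 0.25 | rescue availability per phase |
| y0 | 160 | ovariole primordia (both ovaries) |
| u_min–u_max | 60–260 mg | critical-weight range |
| v_min–v_max | 20–160 mg | growth-increment range |
| a0 | 0.8 | eclosion scaling |

With these values a worker-regime larva ((0.2, 0.3, 0.5)) develops to
about 153 mg with ≈4 ovarioles, and a queen-regime larva
((0.85, 0.9, 0.9)) to about 318 mg with ≈159 ovarioles, matching the
qualitative spread of hive-reared castes.  y0 = 160 is consistent with
upper queen ovariole counts; no published point estimate exists for it.

## Synthetic rearing data

`synthetic_data` emulates the structure of hive and laboratory rearing
studies.  Regime presets:

* `queen_hive` — means (0.85, 0.90, 0.90), per-component normal spread
  0.05, clipped to [0, 1] (unrestricted, sugar-rich feeding).
* `worker_hive` — means (0.20, 0.30, 0.50), spread 0.05 (low early
  sugar, restricted L4, partially restored L5 — hence the q3 mean above
  the q2 mean).
* `continuum` — a single latent t ~ uniform(0.1, 0.9) applied to all
  three coordinates (artificial rearing along a feeding continuum).

Weight noise is multiplicative lognormal with mean one and coefficient
of variation 0.08 (keeps weights positive; matches the visual spread of
hive-reared clouds); ovariole noise is the per-ovariole rescue draw, or
the deterministic expectation in `expected_value` mode.  Each cohort owns
one seed and each individual a spawned substream, so an individual's
draw does not depend on cohort size or ordering.  Two-strain and
cross-fostering designs combine any strain's larval parameters with any
strain's nurse preset; a q2 shift of the nurse preset moves both weight
and ovariole means in the expected direction.

What the generator does **not** emulate: the empirical 3610-individual
cloud's exact shape, JH time-courses within instars, instar durations,
cell-sealing/starvation dynamics, or measurement error in ovariole
counting.  Passing tests therefore demonstrate internal consistency and
statistical behaviour of the estimators under the model's own
assumptions, not goodness of fit to any real data set.

## Fitting

Individual feeding regimes are unobserved in phenotype tables, so the
model is fitted as a latent-variable curve: as q1 = q2 = q3 = t varies,
the developmental map traces a one-parameter curve in (x, y) space.  The
loss of a parameter vector is the sum over individuals of the squared
orthogonal distance, in standardized log10 phenotype space, from the
individual's point to the curve, with each individual's latent t
profiled out by minimization along the curve.  Standardization uses
z-scores of the log phenotypes (weight and ovariole count are on
incommensurate scales); rows with zero ovarioles cannot be
log-transformed and are excluded with an explicit count.

Rows whose rearing label is covered by a known regime preset can instead
be measured against the expected phenotype at the preset's mean regime
(`regime_models=`).  This matters because hive regimes do not lie on the
parallel diet path: treating them as latent-path points would introduce
systematic misfit, whereas treating them as replicated known designs
keeps parameter recovery unbiased.

The latent minimization is a dense grid over t (default 129 points on
[0, 1]) followed by three 9-point local-grid zoom stages and a final
parabolic step, re-evaluating the true curve each time; this reproduces
the continuous projection to well below 1e-6 in squared distance, as the
tests verify against a polished dense-grid oracle.

Free parameters are named by their flat serialization keys, with tied
keys (`jh.s`, `jh.h_q`, …) broadcasting over the three phases,
`regime.q2_offset` shifting the L4 coordinate of the latent path, and
`l4.w1` re-splitting the L4 carryover weights.  Optimization is seeded
multi-start (Latin hypercube over the bounds plus the base values)
with bounded trust-region least-squares refinement (Nelder–Mead
available as an alternative), tolerance 1e-8, ties across starts broken
by start order.  A fit where no start converges is returned flagged,
never silently.  A heuristic non-identifiability flag fires when the
per-start losses are flat while the minimizers scatter — e.g. the L4
weight split under parallel diet variation, which provably cannot affect
the fit.

**Identifiability.** Ovariole number depends on titers only through
(h − mu0)/sigma0, so absolute JH position and scale are not identifiable
from phenotypes; mu0 and sigma0 are fixed by default (mu0 at the JH
midpoint), and users anchoring to measured titers can free them.

**Uncertainty.** `bootstrap_parameters` implements a parametric
bootstrap: cohorts re-simulated from the fitted parameters under the
original designs and refitted warm-started at the estimate.  The
profiled-distance estimator carries a small finite-sample bias (driven by
the zero-ovariole truncation and the heteroscedastic log-scale noise)
which the bootstrap reproduces faithfully, so the default interval is the
bias-corrected normal interval — centred at 2·θ̂ − mean(θ*) with
half-width t(1−α/2, B−1)·sd(θ*) — which corrects the bias to first order
and uses small bootstrap samples efficiently; basic (pivotal) and raw
percentile intervals are available for comparison.  Raw percentile
intervals double the bias rather than removing it and undercover badly
here; this is documented, not default, behaviour.

## Between-strain tests

`compare_strains` tests whether two strains share designated parameters:
`jh_response` frees the tied JH asymptote and steepness (is the larval
response to diet strain-specific?), `l4_diet` frees the latent-path q2
offset (is the nurse-supplied L4 diet strain-specific?).  The statistic
is the loss reduction from the shared-parameter (null) fit to the
strain-specific (alternative) fit — a likelihood-ratio analogue for the
distance loss.  Because the alternative fits are started from the null
optimum, nesting (alternative loss ≤ null loss) holds by construction.
The null distribution comes from a parametric bootstrap under the fitted
null (both strains re-simulated from shared parameters and refitted),
with the +1-corrected p-value p = (1 + #{boot ≥ observed})/(1 + B), so p
is never exactly zero.  Rejection at level alpha uses the standard rule
p ≤ alpha; with B = 19 the null rejection probability at alpha = 0.05 is
exactly 0.05.  The default B is 199; the validation experiments use
B = 19 to keep hundreds of replicate experiments tractable.

## Cloud-structure statistic

The caste-gap statistic quantifies the contrast between "two distinct
phenotype distributions" and "a single continuous cloud": standardized
log phenotypes are split by 2-means and scored by the mean silhouette
width truncated to [0, 1].  Well-separated queen and worker clouds score
near 1; an elongated continuum scores low; a degenerate table of
identical points is defined as 0.  The statistic is deterministic given
its clustering seed.

## Problem sizes in the validation experiments

The test suite and `scripts/acceptance.py` use these sizes, chosen to
make each statistical check informative while keeping a full run in the
minutes range: 10 random parameter sets × 1e6 ovarioles for the
Monte-Carlo equivalence; 5 parameter sets × 9³ regimes for monotonicity;
500 individuals per rearing mode, 50 replicate experiments and B = 49
bootstrap refits for coverage; 200 null experiments (100/strain) and 100
power experiments (300/strain) at B = 19 for the strain test; 20 seeds ×
600 individuals per design for the dimorphism contrast.

## Known limitations

* The logistic response forms and all default parameter values are the
  package's own choices; none are fitted to empirical bee data.
* The latent-path loss is a distance criterion, not a likelihood; its
  p-values and intervals are calibrated by parametric bootstrap rather
  than asymptotic theory, and inherit the model's assumptions.
* Excluding zero-ovariole workers from the log-space loss slightly
  truncates the worker tail; the parametric bootstrap replicates the
  same truncation, so intervals remain calibrated under the model, but
  heavy truncation (very poor regimes) would bias point estimates.
* Other caste-dimorphic traits (mandibles, corbicula, wax mirrors),
  royalactin/Egfr/TOR/insulin signalling, and within-instar JH dynamics
  are out of scope.
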