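# beecaste

Modelling honeybee caste determination: how nurse feeding regimes shape
larval juvenile-hormone (JH) profiles, ovariole numbers and body size —
and how to fit that developmental model to phenotype data.

## The scientific problem

Honeybee queens and workers develop from the same genome into radically
different phenotypes: queens are heavy with hundreds of ovarioles,
workers light with a handful.  Is this a discrete developmental switch
inside the larva, or the imprint of the discrete feeding programs that
nurse workers impose?  This package implements a quantitative
developmental model supporting the second reading: larval development is
a continuous reaction norm, and the dimorphism arises because nurses
feed queen- and worker-destined larvae in two distinct regimes.

It is aimed at researchers in developmental plasticity and social-insect
biology who want to simulate the model, explore its morphospace, and fit
it to (body weight, ovariole count) phenotype tables, including testing
for genetic differences between selected strains.

## The model

A feeding regime is q = (q1, q2, q3) ∈ [0,1]³: normalized diet
quality/quantity in the pooled instars L1–L3, in L4 and in L5.  Each
phase's log10 JH titer follows a logistic response of an effective diet
d (a convex-weighted combination of the current and earlier phases'
coordinates):

    h = h_W + (h_Q − h_W) / (1 + exp(−(d − q_mid)/s))

Each of y0 ovariole primordia carries a rescue threshold
h_t ~ N(μ₀, σ₀) and escapes programmed cell death iff its rescue phase's
titer exceeds it; with proportions r1, r2, r3 of primordia assignable to
the three phases, the expected adult ovariole count is

    y = y0 · [ r1 F((h1−μ₀)/σ₀) + r2 F((h2−μ₀)/σ₀) + r3 F((h3−μ₀)/σ₀) ]

(F = standard normal CDF).  Body size follows the critical-weight
framework: q2 sets the critical weight u, q3 the post-critical increment
v (both logistic), and adult weight is x = a₀(u + v).

Fitting treats each individual's diet as latent: the model traces a
one-parameter curve in (x, y) space as the diets vary in parallel, and
the loss is the summed squared orthogonal distance in standardized log
space, with each individual's latent coordinate profiled out.  Strain
differences (in the JH response, or in the nurse-supplied L4 diet) are
tested by a nested-fit statistic calibrated with a parametric bootstrap.
See `docs/methods.md` for the full account.

## Worked example

```python
import beecaste as bc

params = bc.demo_params()

# a queen-reared and a worker-reared larva
queen = bc.develop(bc.FeedingRegime(0.85, 0.9, 0.9), params)
worker = bc.develop(bc.FeedingRegime(0.2, 0.3, 0.5), params)
print(f"queen:  {queen.x:6.1f} mg, {queen.y:6.1f} ovarioles")
print(f"worker: {worker.x:6.1f} mg, {worker.y:6.1f} ovarioles")

# simulate a hive study and an artificial feeding continuum
noise = bc.NoiseModel()
hive = bc.PhenotypeTable.concat([
    bc.simulate_cohort(bc.CohortSpec(300, bc.QUEEN_HIVE, params, noise, seed=1)),
    bc.simulate_cohort(bc.CohortSpec(300, bc.WORKER_HIVE, params, noise, seed=2)),
])
cont = bc.simulate_cohort(bc.CohortSpec(600, bc.CONTINUUM, params, noise, seed=3))
print(f"caste gap, hive regimes: {bc.caste_gap_statistic(hive):.3f}")
print(f"caste gap, continuum:    {bc.caste_gap_statistic(cont):.3f}")

# recover the JH steepness from the continuum cohort
cfg = bc.FitConfig(free=("jh.s",), n_starts=6, seed=0)
fit = bc.CasteDevelopmentModel(cont, cfg, base_params=params).fit()
print(fit.summary())
```

prints

```
queen:   318.3 mg,  158.8 ovarioles
worker:  153.4 mg,    4.2 ovarioles
caste gap, hive regimes: 0.849
caste gap, continuum:    0.695
Caste development model fit (orthogonal distance, latent diet profiled)
  observations: 586 (excluded zero-ovariole rows: 14)
  free parameters: 1; starts: 6; method: trf
  loss: 11.2962   converged: True   non-identifiable: False
  parameter               estimate       lower       upper
  jh.s                    0.122614        0.02         0.6
```

The two hive regimes produce two well-separated phenotype clouds (high
gap statistic) while the same developmental model under a feeding
continuum produces one connected cloud (lower gap statistic) — the
dimorphism lives in the nurses' behaviour, not in a larval switch.  The
fitted JH steepness 0.123 recovers the generating value 0.12 from 600
noisy individuals; 14 workers with zero ovarioles cannot enter the
log-space fit and are counted, not silently dropped.

The same pipeline is scriptable from the shell:

```bash
beecaste simulate --preset continuum --n 600 --seed 3 --out cont.csv
beecaste fit --data cont.csv --config fit.cfg --out fit.txt
beecaste compare --data-a high.csv --data-b low.csv --which jh_response --out cmp.txt
```

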