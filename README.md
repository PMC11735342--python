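# bpdrisk

Probabilistic dietary risk assessment for benzophenone (BP) and its
derivatives (BPDs) — UV stabilizers and printing-ink photoinitiators that
migrate from packaging into food — measured in cereal surveys where many
samples fall below the limit of detection (LOD).

The package is for exposure scientists and biostatisticians who have (or
want to simulate) a censored residue table plus per-age-group consumption
statistics, and need defensible population risk numbers out the other end.

## What it computes

**Residue model.** Each sample truly contains no analyte with probability
p₀ (zero inflation); otherwise its concentration is lognormal,
ln C ~ N(μ, σ²). A sample is a non-detect when it is a true zero or below
the LOD, so with α = (ln LOD − μ)/σ the non-detect count among N samples is

    N₀ ~ Bin(N, p₀ + (1 − p₀)·Φ(α))

Posterior inference uses a data-augmentation Gibbs sampler with priors
p₀ ~ Beta(1, 1), μ ~ N(0, precision 0.01), σ⁻² ~ Gamma(0.1, 0.1); the
population-mean residue is E[C] = (1 − p₀)·exp(μ + σ²/2). A direct
censored-MLE lognormal fit is available as the second (Monte-Carlo-only)
concentration model.

**Exposure.** Estimated daily intake per age group,
EDI = C × IR / BW (ng/kg bw/day), simulated with 10,000 Monte-Carlo
iterations: C from the posterior predictive or the fitted lognormal, IR
(ingestion rate, g/day) lognormal, BW (body weight, kg) normal truncated
at zero. P97.5 is reported as the high-exposure scenario.

**Risk.** Hazard quotient HQ = EDI/RfD, hazard index HI = ΣHQ over
congeners with a shared mode of action (BP, 4-MBP, BP-3; RfDs 30, 30,
100 μg/kg/day); chronic daily intake CDI = EDI·ED·EF/AT and lifetime
cancer risk LTCR = CDI·CSF with CSF = 4.8 × 10⁻³ (mg/kg/day)⁻¹.
Contribution-to-variance sensitivity (signed, normalized squared rank
correlation) ranks the inputs driving HI.

A synthetic-data module generates residue surveys and consumption
profiles with exactly this structure, so the whole pipeline is testable
without restricted survey data.

## Worked example

```python
from bpdrisk import (CensoredCount, McmcSettings, fit_mcmc, generate_residues,
                     posterior_mean_concentration, table2_preset)

truth = table2_preset("rice_flour", "BP")      # p0=0.016, mu=3.53, sigma=0.42
dataset = generate_residues([truth], seed=42)  # 59 samples, censored at the LOD
counts = CensoredCount.from_dataset(dataset, "BP", "rice_flour")
draws = fit_mcmc(counts, settings=McmcSettings(seed=1))
dist = posterior_mean_concentration(draws)
```

Running `python examples/01_censored_bayes_fit.py` prints:

```
survey: 59 samples, 1 below the LOD (11.94 ng/g)
true (p0, mu, sigma) = (0.016, 3.53, 0.42)
posterior p0    = 2.8% +- 2.2%
posterior mu    = 3.532 +- 0.057  (log ng/g)
posterior sigma = 0.431 +- 0.043
mean concentration E[C] = 36.55 +- 2.32 ng/g (plug-in 36.46)
```

The sampler recovers the generating parameters within posterior
uncertainty, and E[C] is the mean residue level a consumer of this cereal
experiences — the quantity fed into the intake simulation. The other
examples walk through exposure simulation (`02`), risk metrics (`03`),
sensitivity (`04`) and the full seeded pipeline with CSV artifacts (`05`).

A thin CLI wraps the pipeline:

```sh
bpdrisk write-config --out cfg.yaml --seed 7
bpdrisk run-all --config cfg.yaml --out results/
```

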