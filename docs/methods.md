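# Methods

## Residue model and inference

Concentrations of each analyte in each food are modeled as a zero-inflated
left-censored lognormal: a sample is a true zero with probability p₀,
otherwise ln C ~ N(μ, σ²), and anything below its record's LOD is observed
only as a non-detect. Detected values contribute the full normal density
of ln C (a *censored*, not truncated, likelihood: the detection event adds
no extra normalizer); each non-detect contributes
p₀ + (1 − p₀)·Φ((ln LOD − μ)/σ). Per-record LODs are supported because
surveys report LOD ranges per analyte; with a shared LOD the non-detect
terms collapse to the familiar binomial form.

Priors: p₀ ~ Beta(1, 1), μ ~ Normal(0, precision 0.01) — i.e. variance
100; the precision reading follows the BUGS-family convention this prior
set comes from, and a variance-0.01 prior would be irreconcilable with
fitted log-means near 3.5 — and σ⁻² ~ Gamma(0.1, 0.1). Both μ-prior
parameterizations are selectable in `PriorSpec`.

Sampling is data-augmentation Gibbs. Each sweep: (1) label every
non-detect true-zero vs censored-positive with probability
p₀ / (p₀ + (1 − p₀)Φ(α)); (2) draw a latent log-value for each
censored-positive from N(μ, σ²) truncated above at ln LOD (inverse-CDF,
vectorized); (3) update p₀ | labels ~ Beta, μ | values ~ Normal,
σ⁻² | values ~ Gamma — all conjugate, so the sampler needs no tuning and
its conditionals can be checked exactly against closed forms (the test
suite clamps σ and verifies the μ draws against the Normal–Normal
posterior by KS distance, and p₀ against the Beta posterior).

Defaults are a single chain of 14,000 sweeps with 4,000 burn-in.
Multi-chain runs are supported and a split-R̂ diagnostic is provided
(`split_rhat`); for production analyses ≥2 chains with R̂ < 1.01 is
recommended. When every sample is a non-detect the model is only weakly
identified (p₀ trades off against mass below the LOD); the sampler runs
and warns rather than failing.

The reported mean concentration averages (1 − p₀)·exp(μ + σ²/2) over
retained draws; the plug-in at posterior means is reported alongside
because the two differ under σ-uncertainty (Jensen) and published tables
do not always say which convention they use. Neither is forced to match
the other.

## The second concentration model

The Monte-Carlo-only branch fits a plain lognormal directly: by default
left-censored maximum likelihood (each non-detect contributes the normal
log-CDF at its LOD; Nelder–Mead over (μ, ln σ)), optionally LOD/2
substitution followed by log-moments. Censored MLE is the default because
substitution is known to bias both parameters; a simulation test confirms
the MLE's lower error at 30% censoring. A fit with numerically zero σ is
flagged `degenerate` rather than rejected.

## Exposure simulation

EDI = C × IR / BW in ng/kg bw/day. IR is lognormal parameterized by
arithmetic mean and SD (converted internally via
σ² = ln(1 + (sd/mean)²)); BW is normal truncated at zero by redrawing,
with a warning when mean ≤ 3·SD since truncation then visibly reshapes
the distribution. C, IR and BW are sampled independently — observed
between-analyte correlations are not propagated — and each (age group ×
food × analyte) cell uses its own named substream of the root seed, so
results are reproducible and independent of dictionary ordering.

Totals over foods/analytes are summed draw-wise *before* quantiles are
taken (sum-then-quantile); quantiles use linear interpolation between
order statistics, fixed explicitly because P97.5 on 10,000 draws is
sensitive to the convention. In joint simulations the body-weight stream
is shared by all foods of an age group and each food's ingestion-rate
stream by its analytes, which is what aligns inputs and outputs for the
sensitivity analysis.

## Risk metrics

The package carries EDI in ng/kg/day everywhere and converts units only
inside the risk functions (÷10³ to μg for HQ, ÷10⁶ to mg for the cancer
slope factor), because the source formulas mix three scales. HI sums the
HQs of BP, 4-MBP and BP-3 by default (congeners with a shared mode of
action and adequate detection frequency); the component list is
configurable. LTCR uses ED per age group of 2/6/12/16/18/65/70 years —
the >65 value of 70 is kept as conventionally tabulated even though it
overlaps the adult band — EF = 365 d/y and AT = 25,550 d. The tabulated
P97.5 LTCR is computed from the P97.5 EDI (the reporting convention of
such tables), not as the LTCR distribution's own quantile; computing the
latter is possible from the draws but is not the default. Threshold
labels (HI < 1, LTCR within 10⁻⁶–10⁻⁴) are emitted as classifications,
never as hard failures.

## Sensitivity

Contribution to variance is the spreadsheet-simulator convention:
squared Spearman correlation of each input with the output, normalized
across inputs to 100%, signed by the correlation's direction. It is
first-order only (no interaction decomposition) and invariant under
monotone transforms of inputs. A Pearson variant is available for
comparison. Constant inputs contribute 0% with a warning.

## Synthetic data

The generator emulates exactly the structures the analysis assumes:
zero-inflated lognormal concentrations censored at per-record LODs,
lognormal ingestion rates, normal body weights. Presets expose the fitted
posterior point estimates for the 9 (cereal × analyte) cells and 3 pooled
totals as ground truth, with the survey's sample sizes (59/61/60). Preset
LODs sit at exp(μ − 2.5σ), adding ≈0.6% censored positives on top of p₀,
matching the way reported zero-inflation shares track total non-detect
shares in such surveys. True zeros and censored positives are emitted
identically (as non-detects), as in real data; tests can request a
ground-truth side channel.

Consumption profiles are stand-ins, not survey values: per-age-group
means/SDs chosen so that toddlers (0–3 y) — low body weight, rice- and
oat-heavy cereal intake — end up with a total P97.5 EDI in the
few-hundred ng/kg/day range, tapering through adolescence with an oatmeal
rebound for older adults. Passing tests on this synthetic world
demonstrates the *machinery* (inference, simulation, arithmetic,
determinism), not agreement with any real population's intake; real
consumption statistics should replace the defaults via the config for
substantive use. Features of real data the generator does not emulate:
packaging/source covariate effects, between-analyte correlation, batch
structure.

## Numerical choices and problem sizes

Truncated-normal draws use inverse-CDF with clipping at ~1e-300 /
1 − 1e-16 to avoid boundary infinities. The censored-MLE optimizer runs
Nelder–Mead with tight tolerances from a moment-based start. Test and
example runs use reduced sizes — MCMC chains of 1,000–6,000 sweeps and
2,000–10,000 Monte-Carlo iterations — chosen as the package's own
fast-feedback defaults; the library defaults (14,000/4,000 and 10,000)
are used wherever a quantitative claim about the sampler itself is
tested (conjugate-oracle KS checks, parameter recovery at n = 200 over
20 replicates).

## Known limitations

Single-route dietary exposure only; no toxicokinetics or dose–response
beyond the linear slope factor; no partial pooling across foods (each
cell is fit independently, plus an optional pooled fit); independence
between C, IR and BW; first-order sensitivity only. Posterior summaries
assume the chain has mixed — trivially true for the conjugate-conditional
sampler on well-identified data, but the all-non-detect corner relies on
priors and is flagged by a warning rather than resolved.
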