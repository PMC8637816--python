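# Methods

## Concentration panels and non-detects

A panel records one Pb concentration (mg/kg ≡ μg/g) per product plus
retail metadata. Non-detects — readings below the analytical detection
limit — are stored as 0 with `detected=False` and are **included** in
means, standard deviations and extrema. This zeros-as-zero convention is
what makes a panel with ~41% non-detects and a handful of values up to
~0.5 mg/kg average ~0.058 mg/kg; substituting half a detection limit
would shift every downstream dose estimate upward. A half-detection-limit
substitution (`SamplePanel.with_substitution`) and two alternative
fitting policies are provided for sensitivity analyses, never as
defaults. Standard deviations use the n−1 denominator, conventional for a
market sample of a few dozen products; a single-member group reports its
sd as unavailable rather than 0.

Correlation of Pb against product category or price defaults to Spearman:
category is ordinal-coded (lipstick = 1, lip gloss = 2, lip balm = 3,
overridable), and rank correlation is the defensible choice for an
ordinal regressor with heavily tied, zero-inflated concentrations.
Pearson is available for sensitivity.

QC validation implements the three instrument-run rules as stated
thresholds: replicate relative deviation |a−b|/mean(a,b) ≤ 0.10,
standard-curve correlation ≥ 0.995 (inclusive), and all blanks strictly
below the detection limit. A replicate pair with zero mean has no defined
relative deviation and is an error, not a pass.

## Deterministic ingestion risk

The oral-ingestion dose model is linear:
`ADD = C·IR·EF·ED·CF/(BW·AT)` in mg/(kg·d), `HQ = ADD/RfD`,
`LCR = ADD·SF`. Defaults describe lifetime daily use by a 60 kg adult:
EF = 365 d/a, ED = 70 a, AT = 25550 d (so EF·ED/AT = 1 exactly and ADD
reduces to C·IR·CF/BW), RfD = 4×10⁻⁴ mg/(kg·d) and SF = 8.5×10⁻³
(kg·d)/mg for Pb. Two consequences are used as internal consistency
anchors throughout the tests: LCR/HQ = RfD·SF = 3.4×10⁻⁶ for any positive
concentration, and the high/average user ratio of any risk metric equals
the intake-rate ratio 0.14902/0.02578 = 5.7804.

Units: C is mg Pb per kg product, IR grams of product per day; CF = 0.001
kg/g bridges them. Classification thresholds (1 for HQ, 10⁻⁶ for LCR) are
strict: a value exactly at the threshold is acceptable.

## Probabilistic risk

Panel concentrations are modelled as a zero-inflated lognormal: mass
`p_zero` at 0 and lognormal(μ, σ) above. The default `inflate` policy
estimates `p_zero` as the zero fraction and fits the lognormal to
positive values only — the natural model when ~41% of products are
censored at a detection limit far below the positive values. Two fitting
methods:

- `moment_match`: σ² = ln(1+(s/m)²), μ = ln m − σ²/2 from the positive
  subset's mean and sd; the fitted lognormal reproduces m and s exactly
  (round-trip tested to 1e−9 relative). This also admits a
  summary-statistics-only entry point (`fit_from_summary`) for published
  tables without raw data; m = 0.05791, s = 0.10146 gives
  μ = −3.550638, σ = 1.184714.
- `log_mle`: mean and 1/n-denominator sd of the logs.

Degeneracy is detected with a relative spread threshold (s ≤ m·10⁻¹²)
because constant inputs carry ~10⁻¹⁷ float round-off spread.

Monte Carlo propagation draws one concentration stream per run
(default 10,000 iterations, seeded NumPy `default_rng`) and pushes every
draw through the dose equations for each exposure preset. Reusing the
stream across presets makes preset ratios exact rather than noisy.
Percentiles use linear interpolation between order statistics
(`numpy.percentile` default); the estimator is documented because
spreadsheet Monte Carlo tools differ here. Every summary embeds its seed
and iteration count for replay.

The closed-form mixture quantile (0 for q ≤ p_zero, otherwise the
lognormal quantile at the rescaled level) serves as the sampler's
independent oracle. A conditioning caveat governs how it is tested: just
above the zero mass the quantile density is strongly amplified, so at
10⁵ draws the mixture *median* carries ≈1.3% relative Monte Carlo error
while the 95th percentile carries ≈0.9% and the uninflated quantiles
≈0.5%. Sampler-vs-oracle checks therefore compare the well-conditioned
levels (all three levels for the uninflated fit; exact zero at the 5th
and the 95th percentile for the inflated fit) at 2% relative tolerance.

Published 95th-percentile risk values for this kind of survey cannot be
reproduced absolutely without the raw per-sample concentrations and the
exact commercial fitting procedure; the package instead verifies the
structural properties any such run must satisfy (the two exact ratios
above and sampler-oracle agreement).

## Adult Lead Model and scenarios

`PbB = Pbs·BKSF·IR_SD·AF_SD·EF_S/AT + PbL·BKSF·IR_L·AF_L·EF_L/AT + PbB0`,
with defaults Pbs = 282 μg/g (Chinese soil reference), PbL = 0.05791 μg/g
(panel mean), PbB0 = 1.62 μg/dl, BKSF = 0.4 d/dl, soil intake 0.05 g/d
absorbed at 12% over 220 of 365 days, lip intake 0.0258 (average) or
0.1490 g/d (high) absorbed completely every day. Note the blood-lead
model's lip intakes are the two-significant-figure values its source
table prints, slightly coarser than the ingestion-risk IRs.

Two background scenarios: *low* uses the 1.62 μg/dl baseline alone (the
soil term is computed and reported but excluded from the total — the only
reading consistent with a 1.6206 total leaving no room for a 0.408 μg/dl
soil term), and *high* adds the soil term, giving 1.62 + 0.4079 ≈ 2.03.
Maternal-fetal transfer is a fixed fraction of the adult total: 0.85
(ALM convention) or 0.90 (IEUBK convention). The maternal input for a
child model is the mean of the four fetal values (2 user classes × 2
rates) of one background scenario.

Rounding modes. `full_precision` (default for real use) carries floats
through. `paper_emulation` reproduces spreadsheet-style report tables
digit-for-digit: the lip term is rounded half-up to 4 decimals and the
background to 2 decimals *before* summing, and the fetal product is
truncated toward zero at 4 decimals. Truncation (not rounding) is forced
by cells like 1.6235×0.85 = 1.379975 → 1.3799 and
2.0335×0.85 = 1.728475 → 1.7284. Emulation arithmetic runs in decimal,
not binary floating point, so boundary cases cannot flip a displayed
digit. The two modes agree within 3×10⁻³ μg/dl per cell — the
granularity of rounding a ~2.028 background to 2.03 — and the additive
decomposition `total = background + lip_term` holds in both at their own
precision.

## Child multi-media uptake

Per medium, absorbed Pb (μg/d) = concentration × intake rate × absorption
fraction; air uses ventilation volume as the intake rate. Backgrounds:
air 0.5 μg/m³ (annual ambient limit) at 30% absorption; drinking water
0.01 μg/L with age-banded intakes 0.2–0.59 L/d over seven bands from 0.5
to 7 years; dietary background 8 μg/d under age 3 and 20 μg/d for 3–7;
soil 282 μg/g at 45% absorption for children. Children are assumed to
contact lip balm only (mean 0.0738 μg/g by default); other categories
reach them through the maternal pathway. Parameters the source material
leaves unstated are shipped as the package's own editable defaults:
water and diet absorption 0.5, and age-banded ventilation (2–7 m³/d) and
soil ingestion (0.085–0.135 g/d) following standard child-exposure
guidance.

The calculator deliberately stops at absorbed μg/d per medium. Turning
uptake into a blood-lead prediction requires a biokinetic compartment
solver that is out of scope; a user-supplied uptake→BLL response function
can be applied to the totals instead.

## Synthetic panels

The generator emulates the survey structure the analysis assumes:
category counts 12/13/9 (lipstick/gloss/balm), non-detect probability
0.41, positive concentrations lognormal(μ = −3.5507, σ = 1.1848) — the
values moment-matched to the overall mean 0.05791 and sd 0.10146 mg/kg —
and prices uniform within one of the market terciles (edges 95 and
266 RMB). Brand/colour/country vocabularies are neutral placeholders. QC
runs attach replicate pairs with multiplicative lognormal noise of a
chosen CV (mean-one parameterisation), a target calibration correlation,
and blanks below the detection limit.

What the generator does *not* emulate: any dependence of concentration on
category, brand or price (fields are sampled independently), measurement
error structure beyond a constant CV, or values straddling a detection
limit (non-detects are exact zeros). Passing end-to-end tests on
synthetic panels therefore demonstrates that the pipeline inverts its own
generative assumptions — e.g. fitting a 10⁴-sample panel recovers
(p_zero, μ, σ) within 2% relative — not that real panels satisfy those
assumptions.

## Problem sizes and numerical choices

Monte Carlo defaults to 10,000 iterations (sub-second); sampler-oracle
and parameter-recovery checks use 10⁵ and 10⁴ draws respectively, sizes
at which the binomial/quantile standard errors sit comfortably inside the
2% test tolerances. All randomness flows through seeded NumPy generators
recorded in output artifacts. Percentile estimation, tie handling in
Spearman correlation, and p-values come from NumPy/SciPy defaults.

Known limitations: oral route only (no dermal/inhalation); Pb only (no
multi-metal correlation); the lognormal family is assumed, not selected
(no Weibull/gamma alternatives); the ALM is linear and steady-state, with
no pharmacokinetic time course; regulatory-limit and risk thresholds are
strict inequalities by design.
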