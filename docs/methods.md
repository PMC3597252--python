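# Methods

This note documents the models, unit conventions, numerical choices and
known limitations of the `coastbalance` pipeline.

## Phytoplankton production

The photosynthesis–irradiance (P–I) response is the saturating tangential
model P(I) = P_max·tanh(α·I/P_max): linear at low light with slope α,
saturating at P_max, no photoinhibition term. Fitting uses bounded
nonlinear least squares started from a coarse deterministic grid
(P_max near the observed plateau; α spanning saturation onsets from 2% to
100% of the observed light range), keeping the best residual sum of
squares, so results do not depend on a random seed. Degenerate inputs
(fewer than three distinct light levels, non-positive maximum uptake) and
non-convergence raise rather than returning silent values.

Underwater irradiance follows Beer's law with a surface transmittance of
0.82 — interpreted as the fraction of surface light entering the water and
exposed as a parameter, since the empirical constant could also absorb
other near-surface losses. The attenuation coefficient k comes from OLS of
ln(I) on depth; points whose externally studentized residual exceeds 3
(default) are excluded once and the fit repeated, a reproducible stand-in
for manual screening of ship-shadowed or otherwise deviating bottles. The
screen is skipped when residual scatter is at numerical noise, and a
non-positive fitted k is an error. A fitted profile's intercept,
back-divided by the transmittance, also provides the midday surface
irradiance when no separate surface sensor record accompanies a profile.

The diel surface course is reconstructed as a half-sine over the
photoperiod with a sinusoidal seasonal daylength for the high-boreal coast
(about 3.5 h at winter solstice, 20.5 h midsummer). Daily fixation at each
grid depth sums the P–I response over the 24 hourly mean irradiances
(midpoint-hour discretization); one P–I curve, estimated from
upper-water-column samples, is applied down to the 20 m integration cap.
Against a 1-minute × 0.1 m brute-force quadrature on smooth fields the
hourly/9-point-depth discretization agrees within 0.5% (2% asserted).

Depth integration is trapezoidal over [0, cap]: the 0 m boundary copies
the shallowest measurement and values below the deepest measurement extend
it constantly — the least-assumption choices where the sampling design is
silent; both are unit-tested explicitly. Annual integration is trapezoidal
over day-of-year with nearest-value extension to January 1 and
December 31, so a constant daily rate r integrates to exactly
r × (days in year).

The historical in situ strategy multiplies a short-incubation uptake
profile by the diel-to-incubation irradiance quotient. This scaling is
exact where the response is light-limited and biased low where it is
saturated; with a morning (08–11 h) incubation window the annual
in-situ:incubator ratio on shared truth is ≈0.88, inside the
between-method calibration band [0.8, 1.35] used in testing. A noon
window would sit at the lower edge of that band — the quotient method's
main systematic.

## Bacterial production

Thymidine uptake (mol TdR m⁻³ h⁻¹, blank-corrected) × 1.4×10¹⁸ cells
mol⁻¹ × per-cell carbon × 24 h gives mg C m⁻³ d⁻¹. Per-cell carbon is
either fixed (default 20 fg C) or scale·V^exponent from measured mean cell
volume; the default coefficients (120 fg C µm⁻³, exponent 0.7) are a
configuration choice in the range of published volume-to-carbon functions
and should be overridden where a study's own calibration exists. The whole
chain is linear in uptake. Bacterial profiles integrate over the *basin
mean depth* (bacterial production continues below the euphotic zone),
unlike carbon fixation's 20 m cap; the difference is asserted in tests.

## Riverine loads

Annual freshwater volume sums daily gauge flows (m³ s⁻¹ × 86 400 s); gaps
up to 10% of a year (configurable) are linearly interpolated, larger gaps
raise. Annual constituent load is Σ over months of (monthly discharge
volume × that month's single concentration) — the monitoring design
provides one sample per river-month, so no daily concentration
interpolation is attempted. Area-specific TOC load divides by basin area
(g C m⁻² yr⁻¹); for the estuary only the locally retained 10% counts by
default (90% is exported onward), switchable because the accounting
convention is genuinely ambiguous.

Molar C:N and C:P ratios are computed under both conventions —
mean-of-annual-ratios (default) and ratio-of-period-means — because the
two differ on variable data and reported tables do not always say which
was used; the convention is echoed in every result. Period comparisons
use one-way ANOVA with pairwise equal-variance t-tests,
Bonferroni-adjusted. The package ships the reference period-mean flows of
the three-basin scenario (1994–1997, 1998–2001, 2002–2006) for desk
checks of the period arithmetic.

## Trophic-balance statistics

The annual ratio series allows a single interior missing year, filled by
linear interpolation of the *ratio* and flagged; leading/trailing gaps are
never filled and two or more gaps raise. Lag convention: the driver in
calendar year y is paired with the response in year y + lag, so 13
overlapping years at lag 2 give 11 pairs.

The exponential response fit is OLS on ln(y) — exactly the classical
curve-estimation model. a = exp(intercept), with SE by the delta method
(a × SE of the intercept) and p-values from the linear fit; R² is on the
ln scale. A nonlinear refit is available behind `method="nls"`. At n = 11
a ±2 SE interval is slightly narrower than the t₉ 95% interval, so its
per-coefficient coverage is ≈91–92% rather than 95%.

The cubic time fit centres t at the series midpoint for conditioning; the
peak year is the real root of the fitted derivative inside the observed
span with negative second derivative, reported on the original scale.
Model II regression uses the reduced-major-axis slope sign(r)·s_y/s_x
through the centroid, with case-resampling bootstrap SEs (default 2000
replicates; the seed is a mandatory argument). ARI(p, d) differences the
series d times and fits AR(p) with drift by least squares, checking
residual lag-1 autocorrelation against ±2/√n and AR-root stationarity;
when differencing annihilates the series (a polynomial of degree ≤ d) the
AR coefficients are defined as zero. The method-calibration operation
returns the geometric-mean ratio of two methods on ln scale (the RMA line
through the centroid implies exactly this factor there) with bootstrap
percentile CIs.

The uncertainty partition applies first-order propagation for R = Pb/Pp
with independent components: (u_R/R)² = (u_Pb/Pb)² + (u_Pp/Pp)², each
term's share of the sum being its percentage contribution. The operation
takes explicit means and SDs so it can be driven by period summaries or
annual series alike. α = 0.05, two-tailed, throughout; the assumption
checker recommends Pearson correlation only when no group rejects
Shapiro–Wilk normality at α.

## Synthetic-data generator

The generator's defaults encode the study conditions: a 13-year campaign
(1994–2006) over three basins (areas 36 800 / 50 / 66 000 km², volumes
1490 / 1 / 4340 km³, mean depths 43 / 16 / 68 m, reference flows
52 / 0.85 / 68 km³ yr⁻¹ and TOC loads 329 / 12 / 483 ×10⁶ kg yr⁻¹;
the estuary exports 90% of its TOC), 13–26 samplings yr⁻¹, a 1998–2001
discharge pulse at 1.5× and a 2-year lagged exponential response with
baseline a = 0.5 and sensitivity b = 0.09 (g C)⁻¹ m² yr.

Daily flow is a fixed seasonal template (baseflow + spring-melt Gaussian
at day ≈135 + smaller autumn bump) × per-year lognormal factor (CV 15%) ×
pulse multiplier × daily lognormal noise (CV 10%), scaled to the basin
reference flow. Monthly concentrations follow c = c₀·(Q/Q₀)^γ with γ = 0.6
(TOC), 0.5 (TN) and 0 (TP), monthly noise CVs of 5/5/30% and an extra
20%-CV yearly factor for TP; baselines 5.0 / 0.30 / 0.020 mg L⁻¹ are
typical of humic boreal rivers at these loads. These choices reproduce the
intended contrasts: annual TOC and TN loads regress on annual flow with
R² > 0.92 in ≈100% of realizations, while TP sits near R² ≈ 0.5.

Station records couple to the river record twice: light attenuation
increases linearly with the *current* year's specific TOC load
(k = k₀(1 + 0.4·L/10), k₀ = 0.25 m⁻¹), and thymidine uptake is scaled so
the noise-free annual P_b:P_p equals a·e^(b·L_lagged). Because the target
daily bacterial rate is proportional to the noise-free daily fixation,
trapezoidal annual integration preserves the ratio exactly; at zero noise
the downstream pipeline recovers P_max and the annual ratio to better
than 1%. Measurement noise is multiplicative lognormal (mean-one
parameterization), default CV 20% for rate assays — configurable, since
assay CVs are rarely published — with smaller CVs for irradiance profiles
(3%) and cell volumes (half the rate CV). Sub-seeding is deterministic:
CRC32 of "master:basin:year:stream" labels, so basins and years are
independent and any subset is reproducible in isolation.

What the generator does *not* emulate: salinity and stratification
physics, species composition, within-day weather variability in light,
spatial heterogeneity between replicate stations, isotope-dilution effects
in the thymidine assay, and bacterial responses that deviate from the
stated exponential model. Passing recovery tests therefore demonstrate
that the estimation chain is consistent and unbiased under the stated
generative model — not that the model captures every feature of real
coastal series. In particular the generator's annual-scale noise is
mild (per-measurement noise averages over ~20 dates), so recovery R²
values run higher than typically observed in the field.

## Problem sizes and runtime choices

Simulation studies use 500 seeds for coverage and P–I error, 200 for lag
identification, 100 for load–flow coupling and the RMA identity; the
end-to-end pipeline runs 13 years × 3 basins × 20 samplings. These sizes
give Monte-Carlo standard errors of 1–2 percentage points on the reported
rates while keeping the whole acceptance script around a minute on one
CPU. The lag-identification study generates annual series from the river
simulator plus the response model directly, rather than re-running the
full station-level chain per seed, which would add nothing to lag
discrimination.

## Known limitations

* The ln-linear exponential fit weights relative errors; truly additive
  response noise would favour the nonlinear option.
* The Bonferroni post hoc uses pairwise two-sample t-tests rather than a
  pooled-MSE contrast; with balanced small groups the difference is minor.
* Single-pass outlier screening can miss masked multiple outliers in
  attenuation profiles.
* The diel light reconstruction assumes clear-sky half-sine shape; heavy
  overcast days are not represented.
* ARI models have no moving-average terms, and no automatic order
  selection is attempted beyond reporting R² and residual-ACF flags.
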