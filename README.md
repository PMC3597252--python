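# coastbalance

Tools for deriving the **coastal trophic balance** — the ratio of
bacterioplankton to phytoplankton biomass production, P_b:P_p — from raw
marine monitoring measurements, and for relating it to riverine freshwater
and total organic carbon (TOC) discharge under a multi-year lag.

The package is aimed at aquatic microbial ecologists and coastal monitoring
programmes. A P_b:P_p ratio below 1 indicates that carbon flow at the food
web base is dominated by phytoplankton (autotrophy); above 1, heterotrophic
microbial production dominates, with poorer transfer efficiency towards fish
and benthos. Quantifying how riverine carbon pushes this balance is central
to anticipating the effects of increased precipitation on coastal seas.

## What it computes

**Phytoplankton production P_p.** Volumetric carbon fixation follows the
saturating tangential photosynthesis–irradiance model

    P(I) = P_max · tanh(α·I / P_max)

with P_max the photosynthetic maximum (mg C m⁻³ h⁻¹) and α the maximum
light-utilisation coefficient. (P_max, α) are fitted per sampling date from
incubation bottles; underwater light follows Beer's law I(z) = 0.82·I₀·e^(−kz)
with k fitted from irradiance profiles (outliers from ship shadowing screened
by studentized residuals). Daily fixation sums the P–I response over 24
hourly mean irradiances per depth, is trapezoid-integrated to 20 m, and
dated daily rates are trapezoid-integrated to annual g C m⁻² yr⁻¹. The
historical in situ strategy (short incubation scaled by the diel irradiance
quotient) is implemented alongside.

**Bacterial production P_b.** ³H-thymidine uptake is converted to cells with
the empirical factor 1.4×10¹⁸ cells (mol TdR)⁻¹ and to carbon via a
volume-to-carbon power law on measured cell volumes, then integrated over
the basin mean water column and the year.

**Riverine loads.** Annual freshwater volume from daily gauge flows;
TOC/TN/TP loads as monthly flow volume × monthly concentration
(flow-weighted by construction); area-specific loads per basin (with 90% of
estuarine TOC exported onward); molar C:N and C:P ratios; ANOVA with
Bonferroni post hoc tests across multi-year periods.

**Trophic statistics.** The annual ratio series is aligned with specific TOC
load under a lag (load in year *y* drives the ratio in year *y + lag*) and
fitted with the exponential response

    P_b:P_p = a · e^(b · TOC_r)

by ln-linear least squares, alongside a cubic time-trend fit with peak-year
location, Model II (reduced major axis) regression with bootstrap standard
errors, ARI(p, d) models for autocorrelated series, assumption checks
(Shapiro–Wilk, Levene, ACF), and a GUM-style combined-standard-uncertainty
partition attributing ratio variance to its P_b and P_p components.

**Synthetic data.** Because monitoring series of this kind live in
institutional databases, `coastbalance.synthetic_data` generates a full
campaign — three reference basins, 13–26 samplings per year, daily river
flows with a spring flood and a configurable multi-year discharge pulse,
flow-coupled concentrations — from a known ground truth, so every stage
supports parameter-recovery testing.

## Worked example

Simulate a 13-year campaign with a known response (a = 0.5, b = 0.09,
lag = 2 yr), run the production chains, and refit the response:

```python
import pandas as pd
from coastbalance.synthetic_data import GroundTruth, simulate_campaign
from coastbalance.io_cli import derive_annual_pp, derive_annual_bp, fit_balance

truth = GroundTruth(seed=42)           # a = 0.5, b = 0.09, lag = 2 years
campaign = simulate_campaign(range(1994, 2007), truth=truth, n_dates=16)
basin = campaign.basins[0]             # Bothnian Bay

pp, pb = {}, {}
for year in campaign.years:
    frame = campaign.stations[(basin.name, year)].copy()
    frame["date"] = pd.to_datetime(frame["date"])
    pp[year] = derive_annual_pp(frame, basin, year).value
    pb[year] = derive_annual_bp(frame, basin, year).value

fit = fit_balance(pp, pb, campaign.specific_loads[basin.name],
                  lag=truth.true_lag, basin=basin.name)
print(f"a = {fit['a']:.3f} +/- {fit['se_a']:.3f}  (truth 0.5)")
print(f"b = {fit['b']:.4f} +/- {fit['se_b']:.4f} (g C)-1 m2 yr (truth 0.09)")
print(f"R2 = {fit['r2']:.3f}, n = {fit['n']}")
```

Output:

```
a = 0.495 +/- 0.021  (truth 0.5)
b = 0.0899 +/- 0.0039 (g C)-1 m2 yr (truth 0.09)
R2 = 0.980, n = 13
```

The fitted intercept is the baseline trophic balance at zero riverine load
(autotrophic, a < 1), and b is the sensitivity of the balance to the
area-specific TOC load; both recover the generating truth within two
standard errors. Annual production magnitudes are realistic for the region
(here P_p ≈ 121 and P_b ≈ 132 g C m⁻² yr⁻¹ in 1994).

The same pipeline is scriptable from the shell:

```bash
coastbalance simulate --seed 7 --out data/
coastbalance balance --data-dir data/ --out fits.json
coastbalance report --fits fits.json
```

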